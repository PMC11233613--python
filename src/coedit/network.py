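"""Co-editing network inference.

Four-step construction over the binary tumor editing matrix:

1. candidate pairs — unordered site pairs co-edited in >= 3 tumor samples,
   screened by an upper-tail hypergeometric co-occurrence test (BH,
   FDR < 0.05);
2. permutation null — empirical p from >= co-counts over margin-preserving
   randomizations of the editing matrix (curveball trades keep every row
   and column sum exactly), BH, FDR < 0.05;
3. shared-gene filter — pairs whose (direction-consistent) editing-
   associated gene sets overlap more than hypergeometrically expected
   (BH, FDR < 0.05);
4. assembly into a simple undirected graph.

The empirical p uses the add-one convention, (1 + #{permuted >= observed})
/ (B + 1), so it is never zero and remains a valid p-value.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .datatypes import EditingMatrix
from .stats import bh_adjust, hypergeom_upper_tail

log = logging.getLogger(__name__)

__all__ = [
    "PairStats",
    "PermutationEnsemble",
    "CoEditingNetwork",
    "candidate_pairs",
    "hypergeom_cooccurrence",
    "permute_editing_matrix",
    "empirical_p",
    "shared_gene_test",
    "build_network",
    "genomic_pair_summary",
]


@dataclass
class PairStats:
    site_i: str
    site_j: str
    n_samples: int
    k_i: int
    k_j: int
    co_count: int
    hypergeom_p: float = np.nan
    hypergeom_fdr: float = np.nan
    perm_p: float = np.nan
    perm_fdr: float = np.nan
    shared_up: int = 0
    shared_down: int = 0
    shared_gene_p: float = np.nan
    shared_gene_fdr: float = np.nan

    def __post_init__(self):
        if self.co_count > min(self.k_i, self.k_j):
            raise ValueError(
                f"co_count {self.co_count} exceeds min(k_i, k_j) for "
                f"({self.site_i}, {self.site_j})"
            )


@dataclass
class PermutationEnsemble:
    """Per-permutation co-counts for a fixed list of candidate pairs."""

    B: int
    seed: int
    pair_index: dict  # (site_i, site_j) -> column in co_counts
    co_counts: np.ndarray  # B x n_pairs
    degenerate: bool = False


# ------------------------------------------------------------ step 1


def candidate_pairs(edit_status: pd.DataFrame, min_co: int = 3) -> list[tuple[str, str]]:
    """All unordered site pairs co-edited in at least ``min_co`` samples.

    Returned in deterministic lexicographic order.
    """
    m = edit_status.to_numpy(np.int64)
    co = m @ m.T
    sites = list(edit_status.index)
    out = []
    ii, jj = np.nonzero(np.triu(co >= min_co, k=1))
    for i, j in zip(ii, jj):
        a, b = sites[i], sites[j]
        out.append((a, b) if a <= b else (b, a))
    out.sort()
    return out


def hypergeom_cooccurrence(pair: PairStats) -> float:
    """Upper-tail hypergeometric co-occurrence p for one pair.

    The k_j edited samples of site j are draws from N samples of which k_i
    are edited at site i; p = P(overlap >= observed co-count).
    """
    p = hypergeom_upper_tail(pair.co_count, pair.k_j, pair.k_i, pair.n_samples)
    pair.hypergeom_p = p
    return p


# ------------------------------------------------------------ step 2


def _curveball_trades(rows: list[set], n_trades: int, rng: np.random.Generator) -> None:
    """In-place curveball trades: swap exclusive column memberships between
    two random rows, preserving all row and column sums."""
    n = len(rows)
    ra = rng.integers(0, n, size=n_trades)
    rb = rng.integers(0, n, size=n_trades)
    for a, b in zip(ra, rb):
        if a == b:
            continue
        ab = rows[a] - rows[b]
        ba = rows[b] - rows[a]
        total = len(ab) + len(ba)
        if len(ab) == 0 or len(ba) == 0:
            continue
        pool = list(ab | ba)
        pool_arr = np.array(pool)
        rng.shuffle(pool_arr)
        new_a = set(pool_arr[: len(ab)])
        new_b = set(pool_arr[len(ab):])
        common = rows[a] & rows[b]
        rows[a] = common | new_a
        rows[b] = common | new_b


def permute_editing_matrix(
    edit_status: pd.DataFrame,
    B: int = 1000,
    seed: int = 0,
    pairs: list[tuple[str, str]] | None = None,
    thin_factor: int = 5,
) -> PermutationEnsemble:
    """Margin-preserving randomization ensemble of a binary matrix.

    Produces ``B`` matrices by a curveball trade chain (every trade keeps
    all row and column sums exactly). Burn-in and between-matrix thinning
    are ``thin_factor`` x the number of rows in trades, a standard mixing
    budget for curveball chains. Records co-counts for ``pairs`` (all
    site pairs if None).

    Degenerate matrices with no valid trade yield an ensemble of identical
    matrices and a warning.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    sites = list(edit_status.index)
    idx = {s: i for i, s in enumerate(sites)}
    if pairs is None:
        pairs = [(sites[i], sites[j]) for i in range(len(sites)) for j in range(i + 1, len(sites))]
    pair_index = {tuple(sorted(p)): c for c, p in enumerate(map(tuple, pairs))}
    m = edit_status.to_numpy(bool)
    rows = [set(np.nonzero(r)[0]) for r in m]
    rng = np.random.default_rng(seed)

    # degenerate: no pair of rows has exchangeable columns
    degenerate = all(
        not (rows[a] - rows[b]) or not (rows[b] - rows[a])
        for a in range(len(rows)) for b in range(a + 1, len(rows))
    )
    if degenerate:
        warnings.warn("matrix margins admit no swap; ensemble is identical matrices",
                      stacklevel=2)

    n_thin = max(thin_factor * len(rows), 100)
    ordered = sorted(pair_index, key=pair_index.get)
    pi = np.array([idx[a] for a, _ in ordered], dtype=np.intp)
    pj = np.array([idx[b] for _, b in ordered], dtype=np.intp)

    co_counts = np.empty((B, len(pair_index)), dtype=np.int32)
    _curveball_trades(rows, 2 * n_thin, rng)  # burn-in
    dense = np.zeros_like(m)
    for b in range(B):
        _curveball_trades(rows, n_thin, rng)
        dense[:] = False
        for r, cols in enumerate(rows):
            dense[r, list(cols)] = True
        co = dense[pi] & dense[pj]
        co_counts[b] = co.sum(axis=1)
    return PermutationEnsemble(B=B, seed=seed, pair_index=pair_index,
                               co_counts=co_counts, degenerate=degenerate)


def permuted_matrices(edit_status: pd.DataFrame, B: int, seed: int,
                      thin_factor: int = 5):
    """Yield B margin-preserving randomized copies of the matrix."""
    rows_init = edit_status.to_numpy(bool)
    rows = [set(np.nonzero(r)[0]) for r in rows_init]
    rng = np.random.default_rng(seed)
    n_thin = max(thin_factor * len(rows), 100)
    _curveball_trades(rows, 2 * n_thin, rng)
    for _ in range(B):
        _curveball_trades(rows, n_thin, rng)
        dense = np.zeros_like(rows_init)
        for r, cols in enumerate(rows):
            dense[r, list(cols)] = True
        yield pd.DataFrame(dense.astype(np.int8), index=edit_status.index,
                           columns=edit_status.columns)


def empirical_p(pair: PairStats, ensemble: PermutationEnsemble) -> float:
    """Add-one empirical p: (1 + #{permuted co-count >= observed}) / (B + 1)."""
    key = tuple(sorted((pair.site_i, pair.site_j)))
    if key not in ensemble.pair_index:
        raise KeyError(f"pair {key} not covered by the ensemble")
    col = ensemble.pair_index[key]
    exceed = int((ensemble.co_counts[:, col] >= pair.co_count).sum())
    p = (1 + exceed) / (ensemble.B + 1)
    pair.perm_p = p
    return p


# ------------------------------------------------------------ step 3


def shared_gene_test(
    assoc_i: list, assoc_j: list, universe_size: int
) -> tuple[int, int, float]:
    """Direction-consistent shared-gene hypergeometric test.

    ``assoc_i`` / ``assoc_j`` are association records (with ``gene_id`` and
    ``direction``) for the two sites; the universe is the genes tested for
    both. Overlap = |up_i ∩ up_j| + |down_i ∩ down_j|; upper-tail
    hypergeometric with draws = |assoc_i|, successes = |assoc_j|.
    Returns (shared_up, shared_down, p).
    """
    if not assoc_i or not assoc_j:
        raise ValueError("empty association set; pair cannot share genes")
    up_i = {r.gene_id for r in assoc_i if r.direction == "up"}
    dn_i = {r.gene_id for r in assoc_i if r.direction == "down"}
    up_j = {r.gene_id for r in assoc_j if r.direction == "up"}
    dn_j = {r.gene_id for r in assoc_j if r.direction == "down"}
    shared_up = len(up_i & up_j)
    shared_down = len(dn_i & dn_j)
    n_i = len(up_i | dn_i)
    n_j = len(up_j | dn_j)
    k = shared_up + shared_down
    if universe_size < max(n_i, n_j):
        raise ValueError("universe smaller than an association set")
    k_eff = min(k, n_i, n_j)
    p = hypergeom_upper_tail(k_eff, n_i, n_j, universe_size)
    return shared_up, shared_down, p


# ------------------------------------------------------------ step 4


def build_network(pairs: list[PairStats]) -> nx.Graph:
    """Assemble retained pairs into a simple undirected network.

    Idempotent on duplicate pairs; isolated sites never appear; node and
    edge insertion order is deterministic (lexicographic).
    """
    g = nx.Graph()
    for p in sorted(pairs, key=lambda q: tuple(sorted((q.site_i, q.site_j)))):
        a, b = sorted((p.site_i, p.site_j))
        if a == b:
            raise ValueError(f"self-edge on {a}")
        g.add_edge(
            a, b,
            co_count=int(p.co_count),
            hypergeom_p=float(p.hypergeom_p),
            hypergeom_fdr=float(p.hypergeom_fdr),
            perm_p=float(p.perm_p),
            perm_fdr=float(p.perm_fdr),
            shared_gene_p=float(p.shared_gene_p),
            shared_gene_fdr=float(p.shared_gene_fdr),
        )
    return g


def genomic_pair_summary(net: nx.Graph, annotations: pd.DataFrame) -> dict:
    """Per-edge genomic relationships and cohort-level fractions.

    Flags each edge as same-chromosome / same-gene, computes genomic
    distance for intra-chromosomal pairs, and reports fractions with
    distance bins < 1 kb and < 10 Mb.
    """
    per_edge = []
    for u, v in sorted(net.edges()):
        if u not in annotations.index or v not in annotations.index:
            per_edge.append({"site_i": u, "site_j": v, "known": False})
            continue
        au, av = annotations.loc[u], annotations.loc[v]
        same_chrom = au["chrom"] == av["chrom"]
        dist = abs(int(au["pos"]) - int(av["pos"])) if same_chrom else np.nan
        per_edge.append({
            "site_i": u, "site_j": v, "known": True,
            "same_chromosome": bool(same_chrom),
            "same_gene": bool(au.get("gene") == av.get("gene") and au.get("gene")),
            "distance": dist,
        })
    df = pd.DataFrame(per_edge)
    known = df[df["known"]] if len(df) else df
    n_known = len(known)
    same = known[known["same_chromosome"]] if n_known else known
    summary = {
        "n_edges": int(net.number_of_edges()),
        "n_known": int(n_known),
        "frac_same_chromosome": float(len(same) / n_known) if n_known else np.nan,
        "frac_same_gene": float(known["same_gene"].mean()) if n_known else np.nan,
        "frac_lt_1kb_of_same_chrom": (
            float((same["distance"] < 1_000).mean()) if len(same) else np.nan
        ),
        "frac_lt_10mb_of_same_chrom": (
            float((same["distance"] < 10_000_000).mean()) if len(same) else np.nan
        ),
    }
    return {"per_edge": df, "summary": summary}


# ------------------------------------------------------------ estimator


class CoEditingNetwork(BaseEstimator):
    """Full four-step co-editing network inference.

    ``fit(edit, assoc_by_site=None)`` runs the co-occurrence screen, the
    margin-preserving permutation filter and (when association records are
    supplied) the direction-consistent shared-gene filter, then assembles
    the surviving pairs into ``network_``.

    Parameters
    ----------
    min_co : minimum co-edited samples for a candidate pair (default 3).
    fdr : BH threshold applied at each of the three filtering steps.
    n_permutations : size of the permutation null ensemble (default 1000).
    random_state : seed for the permutation chain.
    require_shared_genes : if True and association records are given, pairs
        with an empty association set on either side are dropped; if False
        the shared-gene step is skipped entirely.

    Attributes
    ----------
    pairs_ : list of PairStats for all candidate pairs (with the statistics
        populated as far as each pair survived).
    network_ : networkx.Graph of retained pairs.
    """

    def __init__(self, min_co: int = 3, fdr: float = 0.05,
                 n_permutations: int = 1000, random_state: int = 0,
                 require_shared_genes: bool = True):
        self.min_co = min_co
        self.fdr = fdr
        self.n_permutations = n_permutations
        self.random_state = random_state
        self.require_shared_genes = require_shared_genes

    def fit(self, edit: EditingMatrix | pd.DataFrame,
            assoc_by_site: dict[str, list] | None = None,
            tumor_samples: list[str] | None = None):
        status = edit.status if isinstance(edit, EditingMatrix) else edit
        if tumor_samples is not None:
            status = status[tumor_samples]
        n = status.shape[1]
        k = status.sum(axis=1)

        cands = candidate_pairs(status, self.min_co)
        m = status.to_numpy(np.int64)
        idx = {s: i for i, s in enumerate(status.index)}
        pairs = []
        for a, b in cands:
            co = int((m[idx[a]] & m[idx[b]]).sum())
            pairs.append(PairStats(site_i=a, site_j=b, n_samples=n,
                                   k_i=int(k[a]), k_j=int(k[b]), co_count=co))
        self.pairs_ = pairs
        if not pairs:
            self.network_ = nx.Graph()
            return self

        # step 1: hypergeometric screen
        pvals = np.array([hypergeom_cooccurrence(p) for p in pairs])
        fdrs = bh_adjust(pvals)
        for p, q in zip(pairs, fdrs):
            p.hypergeom_fdr = float(q)
        survivors = [p for p in pairs if p.hypergeom_fdr < self.fdr]
        log.info("hypergeometric screen: %d / %d pairs retained", len(survivors), len(pairs))
        if not survivors:
            self.network_ = nx.Graph()
            return self

        # step 2: permutation null (computed only for survivors to bound cost)
        ens = permute_editing_matrix(
            status, B=self.n_permutations, seed=self.random_state,
            pairs=[(p.site_i, p.site_j) for p in survivors],
        )
        self.ensemble_ = ens
        perm_ps = np.array([empirical_p(p, ens) for p in survivors])
        perm_fdrs = bh_adjust(perm_ps)
        for p, q in zip(survivors, perm_fdrs):
            p.perm_fdr = float(q)
        survivors = [p for p in survivors if p.perm_fdr < self.fdr]
        log.info("permutation filter: %d pairs retained", len(survivors))

        # step 3: shared-gene filter
        if assoc_by_site is not None and self.require_shared_genes and survivors:
            universe = self._universe_size
            if universe <= 0:
                # fall back to the genes appearing in any association record
                universe = len({r.gene_id for recs in assoc_by_site.values() for r in recs})
                log.warning("gene universe not declared; using %d observed genes", universe)
            tested, shared_ps = [], []
            for p in survivors:
                ai = assoc_by_site.get(p.site_i, [])
                aj = assoc_by_site.get(p.site_j, [])
                if not ai or not aj:
                    continue
                su, sd, sp = shared_gene_test(ai, aj, universe)
                p.shared_up, p.shared_down, p.shared_gene_p = su, sd, sp
                tested.append(p)
                shared_ps.append(sp)
            if tested:
                sfdr = bh_adjust(shared_ps)
                for p, q in zip(tested, sfdr):
                    p.shared_gene_fdr = float(q)
                survivors = [p for p in tested if p.shared_gene_fdr < self.fdr]
            else:
                survivors = []
            log.info("shared-gene filter: %d pairs retained", len(survivors))

        self.retained_pairs_ = survivors
        self.network_ = build_network(survivors)
        return self

    _universe_size: int = 0

    def set_gene_universe(self, n_genes: int) -> "CoEditingNetwork":
        """Declare the size of the gene universe for the shared-gene test
        (the genes screened for association at every site)."""
        self._universe_size = int(n_genes)
        return self
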