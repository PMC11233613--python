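"""Synthetic tumor-cohort generator with planted, parameterized structure.

Every downstream stage of the pipeline can be exercised against ground
truth: planted co-editing pairs (excess joint editing with preserved
marginals), planted editing-associated genes (expression shifts in edited
samples), planted survival risk pairs (proportional-hazards effects for
co-edited carriers), and planted co-amplified copy-number loci.

Joint editing for a planted pair uses a mixture of the comonotone coupling
and the independent coupling with mixing weight ``joint_boost`` b:
P(both edited) = b * min(p_i, p_j) + (1 - b) * p_i * p_j, while each site's
marginal editing probability is preserved exactly. b = 0 is independence;
b = 1 maximal overlap.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .datatypes import ClinicalTable, CopyNumberSegments, EditingMatrix, ExpressionBundle

__all__ = ["CohortConfig", "SyntheticTruth", "CohortGenerator", "generate_cohort"]


@dataclass
class CohortConfig:
    """Parameters of the synthetic cohort.

    ``planted_pairs`` entries are (site_i, site_j, joint_boost in (0, 1]).
    ``assoc_effects`` entries are (site, gene, log2 shift in edited samples).
    ``hazard_pairs`` entries are ((site_i, site_j), log hazard ratio).
    ``cn_coamp_pairs`` entries are (site_i, site_j, joint amplification prob).
    """

    n_tumor: int = 300
    n_normal: int = 50
    n_sites: int = 200
    n_genes: int = 500
    base_edit_freq_range: tuple[float, float] = (0.10, 0.40)
    planted_pairs: list = field(default_factory=list)
    assoc_effects: list = field(default_factory=list)
    hazard_pairs: list = field(default_factory=list)
    baseline_hazard: float = 1.0 / 1000.0  # per day; median OS ~ 2 years
    censor_rate: float = 1.0 / 4000.0
    cn_coamp_pairs: list = field(default_factory=list)
    cn_background_amp_prob: float = 0.05
    log2_mu_range: tuple[float, float] = (3.0, 8.0)
    log2_sigma: float = 0.8
    tumor_normal_lfc: dict = field(default_factory=dict)  # gene -> log2 shift in tumor
    seed: int = 0

    def __post_init__(self):
        lo, hi = self.base_edit_freq_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("base_edit_freq_range must satisfy 0 <= lo <= hi <= 1")
        if self.baseline_hazard <= 0:
            raise ValueError("baseline_hazard must be positive")
        if self.censor_rate < 0:
            raise ValueError("censor_rate must be non-negative")
        seen = set()
        for si, sj, b in self.planted_pairs:
            if not (0 <= b <= 1):
                raise ValueError(f"joint_boost {b} outside [0, 1] for pair ({si}, {sj})")
            if si in seen or sj in seen or si == sj:
                raise ValueError(f"site reused across planted pairs: ({si}, {sj})")
            seen |= {si, sj}

    def site_ids(self) -> list[str]:
        # deterministic genome placement: sites spread over 4 chromosomes
        ids = []
        for i in range(self.n_sites):
            chrom = f"chr{(i % 4) + 1}"
            pos = 10_000 + (i // 4) * 50_000
            ids.append(f"{chrom}:{pos}:G{i:04d}")
        return ids

    def gene_ids(self) -> list[str]:
        return [f"GENE{i:04d}" for i in range(self.n_genes)]


@dataclass
class SyntheticTruth:
    """Planted ground truth for scoring recovery."""

    planted_pairs: list  # (site_i, site_j, joint_boost)
    assoc_genes: list  # (site, gene, direction)
    hazard_pairs: list  # ((site_i, site_j), log_hr)
    risk_carriers: pd.Series | None  # patient -> bool
    coamp_pairs: list  # (site_i, site_j)

    def to_dict(self) -> dict:
        return {
            "planted_pairs": [list(p) for p in self.planted_pairs],
            "assoc_genes": [list(a) for a in self.assoc_genes],
            "hazard_pairs": [[list(p), lhr] for p, lhr in self.hazard_pairs],
            "risk_carriers": (
                {k: bool(v) for k, v in self.risk_carriers.items()}
                if self.risk_carriers is not None else None
            ),
            "coamp_pairs": [list(p) for p in self.coamp_pairs],
        }


class CohortGenerator:
    """Deterministic cohort generator; fixed seed gives identical output."""

    def __init__(self, config: CohortConfig):
        self.config = config
        self.site_ids = config.site_ids()
        self.gene_ids = config.gene_ids()
        known = set(self.site_ids)
        for si, sj, _ in config.planted_pairs:
            if si not in known or sj not in known:
                raise ValueError(f"planted pair references unknown site: ({si}, {sj})")
        for s, g, _ in config.assoc_effects:
            if s not in known:
                raise ValueError(f"association effect references unknown site {s!r}")
        for (si, sj), _ in config.hazard_pairs:
            if si not in known or sj not in known:
                raise ValueError(f"hazard pair references unknown site: ({si}, {sj})")

    # ------------------------------------------------------------ editing

    def generate_editing_matrix(self, rng: np.random.Generator) -> EditingMatrix:
        cfg = self.config
        n = cfg.n_tumor + cfg.n_normal
        samples = [f"T{i:04d}" for i in range(cfg.n_tumor)] + [
            f"N{i:04d}" for i in range(cfg.n_normal)
        ]
        lo, hi = cfg.base_edit_freq_range
        freqs = pd.Series(rng.uniform(lo, hi, size=cfg.n_sites), index=self.site_ids)
        status = np.zeros((cfg.n_sites, n), dtype=np.int8)
        planted_sites = {s for si, sj, _ in cfg.planted_pairs for s in (si, sj)}
        idx = {s: i for i, s in enumerate(self.site_ids)}
        for s in self.site_ids:
            if s not in planted_sites:
                status[idx[s]] = rng.random(n) < freqs[s]
        for si, sj, b in cfg.planted_pairs:
            pi, pj = freqs[si], freqs[sj]
            u = rng.random(n)          # shared uniform (comonotone component)
            ui, uj = rng.random(n), rng.random(n)
            use_com = rng.random(n) < b
            xi = np.where(use_com, u < pi, ui < pi)
            xj = np.where(use_com, u < pj, uj < pj)
            status[idx[si]] = xi
            status[idx[sj]] = xj
        status_df = pd.DataFrame(status, index=self.site_ids, columns=samples)
        levels = pd.DataFrame(np.nan, index=self.site_ids, columns=samples)
        mask = status_df.to_numpy(bool)
        levels.values[mask] = rng.uniform(0.1, 0.9, size=int(mask.sum()))
        ann = pd.DataFrame(
            [
                {"site_id": s, "chrom": s.split(":")[0], "pos": int(s.split(":")[1]),
                 "strand": "+", "gene": s.split(":")[2]}
                for s in self.site_ids
            ]
        ).set_index("site_id")
        return EditingMatrix(status=status_df, levels=levels, annotations=ann)

    # --------------------------------------------------------- expression

    def generate_expression(
        self, editing: EditingMatrix, rng: np.random.Generator
    ) -> ExpressionBundle:
        cfg = self.config
        samples = editing.sample_ids
        n = len(samples)
        mu = rng.uniform(*cfg.log2_mu_range, size=cfg.n_genes)
        log2 = rng.normal(mu[:, None], cfg.log2_sigma, size=(cfg.n_genes, n))
        gidx = {g: i for i, g in enumerate(self.gene_ids)}
        is_tumor = np.array([s.startswith("T") for s in samples])
        for gene, lfc in cfg.tumor_normal_lfc.items():
            log2[gidx[gene], is_tumor] += lfc
        for site, gene, shift in cfg.assoc_effects:
            edited = editing.status.loc[site].to_numpy(bool)
            log2[gidx[gene], edited] += shift
        values = np.power(2.0, log2)
        counts = rng.poisson(values)  # library scale ~ values themselves
        sample_class = pd.Series(
            np.where(is_tumor, "tumor", "normal"), index=samples, name="class"
        )
        return ExpressionBundle(
            values=pd.DataFrame(values, index=self.gene_ids, columns=samples),
            counts=pd.DataFrame(counts, index=self.gene_ids, columns=samples),
            sample_class=sample_class,
        )

    # ----------------------------------------------------------- survival

    def risk_carrier_flags(self, editing: EditingMatrix) -> pd.DataFrame:
        """Per-patient indicator of carrying each planted hazard pair."""
        tumor = [s for s in editing.sample_ids if s.startswith("T")]
        flags = {}
        for (si, sj), _ in self.config.hazard_pairs:
            both = (editing.status.loc[si, tumor] == 1) & (editing.status.loc[sj, tumor] == 1)
            flags[(si, sj)] = both.astype(int)
        return pd.DataFrame(flags, index=tumor)

    def generate_clinical_survival(
        self, editing: EditingMatrix, rng: np.random.Generator
    ) -> tuple[ClinicalTable, pd.Series]:
        cfg = self.config
        tumor = [s for s in editing.sample_ids if s.startswith("T")]
        nt = len(tumor)
        carriers = self.risk_carrier_flags(editing)
        log_hr = np.zeros(nt)
        for (pair, lhr) in cfg.hazard_pairs:
            log_hr += carriers[tuple(pair)].to_numpy() * lhr
        hazard = cfg.baseline_hazard * np.exp(log_hr)
        t_event = rng.exponential(1.0 / hazard)
        if cfg.censor_rate > 0:
            t_cens = rng.exponential(1.0 / cfg.censor_rate, size=nt)
        else:
            t_cens = np.full(nt, np.inf)
        os_time = np.minimum(t_event, t_cens)
        os_event = (t_event <= t_cens).astype(int)
        data = pd.DataFrame(
            {
                "age": np.round(rng.normal(60, 10, nt)).clip(18, 95),
                "gender": rng.choice(["male", "female"], nt),
                "bmi": np.round(rng.normal(25, 4, nt), 1).clip(14, 55),
                "stage": rng.choice([1, 2, 3, 4], nt, p=[0.4, 0.25, 0.25, 0.1]).astype(float),
                "grade": rng.choice([1, 2, 3, 4], nt, p=[0.15, 0.45, 0.3, 0.1]).astype(float),
                "afp": np.round(rng.lognormal(3.0, 1.5, nt), 1),
                "os_time": np.maximum(os_time, 0.5),
                "os_event": os_event,
            },
            index=pd.Index(tumor, name="patient_id"),
        )
        # AFP is missing for a realistic minority of patients
        miss = rng.random(nt) < 0.10
        data.loc[miss, "afp"] = np.nan
        any_risk = carriers.sum(axis=1) > 0 if len(carriers.columns) else pd.Series(False, index=tumor)
        return ClinicalTable(data), any_risk

    # -------------------------------------------------------- copy number

    def generate_copy_number(
        self, editing: EditingMatrix, rng: np.random.Generator
    ) -> CopyNumberSegments:
        """Per-sample single-base segments at each site locus.

        Background amplification is independent per site/sample; planted
        co-amplified pairs are amplified jointly with their stated
        probability (and independently at background rate otherwise).
        """
        cfg = self.config
        tumor = [s for s in editing.sample_ids if s.startswith("T")]
        ann = editing.annotations
        coamp_sites = {s for si, sj, _ in cfg.cn_coamp_pairs for s in (si, sj)}
        rows = []
        amp_log2 = 0.585  # log2(3/2): one extra copy
        neutral = 0.0
        background = {
            s: rng.random(len(tumor)) < cfg.cn_background_amp_prob
            for s in self.site_ids if s not in coamp_sites
        }
        joint = {}
        for si, sj, p in cfg.cn_coamp_pairs:
            joint_amp = rng.random(len(tumor)) < p
            joint[si] = joint_amp
            joint[sj] = joint_amp
        for s in self.site_ids:
            amp = joint.get(s, background.get(s))
            pos = int(ann.loc[s, "pos"])
            chrom = ann.loc[s, "chrom"]
            for k, sample in enumerate(tumor):
                rows.append(
                    {
                        "sample_id": sample,
                        "chrom": chrom,
                        "start": pos - 1,
                        "end": pos,
                        "log2_ratio": amp_log2 if amp[k] else neutral,
                    }
                )
        return CopyNumberSegments(pd.DataFrame(rows))

    # -------------------------------------------------------------- whole

    def generate(self):
        """Generate the full cohort deterministically from config.seed."""
        cfg = self.config
        root = np.random.SeedSequence(cfg.seed)
        rng_edit, rng_expr, rng_clin, rng_cn = (
            np.random.Generator(np.random.PCG64(s)) for s in root.spawn(4)
        )
        editing = self.generate_editing_matrix(rng_edit)
        expression = self.generate_expression(editing, rng_expr)
        clinical, any_risk = self.generate_clinical_survival(editing, rng_clin)
        segments = self.generate_copy_number(editing, rng_cn)
        truth = SyntheticTruth(
            planted_pairs=list(cfg.planted_pairs),
            assoc_genes=[(s, g, "up" if shift > 0 else "down")
                         for s, g, shift in cfg.assoc_effects],
            hazard_pairs=[(tuple(p), lhr) for p, lhr in cfg.hazard_pairs],
            risk_carriers=any_risk,
            coamp_pairs=[(si, sj) for si, sj, _ in cfg.cn_coamp_pairs],
        )
        return editing, expression, clinical, segments, truth


def generate_cohort(config: CohortConfig):
    """Convenience wrapper: build a generator and produce the full cohort."""
    return CohortGenerator(config).generate()


def default_planted_config(seed: int = 0, n_tumor: int = 300, n_sites: int = 200,
                           n_pairs: int = 20, joint_boost: float = 0.8,
                           genes_per_pair: int = 5, shift: float = 2.0,
                           n_hazard_pairs: int = 3, log_hr: float = 1.0) -> CohortConfig:
    """The standard planted-structure study condition.

    20 co-editing pairs at joint_boost 0.8 among 200 sites and 300 tumors;
    each planted pair's two sites share ``genes_per_pair`` up-shifted
    associated genes; the first ``n_hazard_pairs`` planted pairs also carry a
    survival log hazard ratio of ``log_hr``.
    """
    cfg = CohortConfig(n_tumor=n_tumor, n_sites=n_sites, seed=seed)
    sites = cfg.site_ids()
    genes = cfg.gene_ids()
    planted, assoc, hazards = [], [], []
    g = 0
    for k in range(n_pairs):
        si, sj = sites[2 * k], sites[2 * k + 1]
        planted.append((si, sj, joint_boost))
        for _ in range(genes_per_pair):
            assoc.append((si, genes[g], shift))
            assoc.append((sj, genes[g], shift))
            g += 1
        if k < n_hazard_pairs:
            hazards.append(((si, sj), log_hr))
    cfg.planted_pairs = planted
    cfg.assoc_effects = assoc
    cfg.hazard_pairs = hazards
    return cfg
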