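"""Readers and writers for the pipeline's on-disk formats.

Conventions: dense/triplet TSV for matrices, BED for site coordinates
(0-based half-open on disk, 1-based in memory), GMT for gene sets, GraphML
or edge-list TSV for networks, plain TSV for clinical / copy-number /
infiltration tables. Every reader/writer pair round-trips losslessly.
"""

from __future__ import annotations

import json
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .datatypes import (
    ClinicalTable,
    CopyNumberSegments,
    EditingMatrix,
    ExpressionBundle,
    GeneSetCollection,
)

EDGE_ATTRS = (
    "co_count",
    "hypergeom_p",
    "hypergeom_fdr",
    "perm_p",
    "perm_fdr",
    "shared_gene_p",
    "shared_gene_fdr",
)


# ---------------------------------------------------------------- editing


def read_editing_matrix(path, format: str = "dense_tsv", levels_path=None) -> EditingMatrix:
    """Read a binary editing matrix.

    dense_tsv: sites as rows, samples as columns, 0/1 cells.
    triplet_tsv: header ``site\tsample\tstatus[\tlevel]``; unlisted cells are
    0 (and missing level). The triplet universe is the set of observed ids
    unless the file carries ``#sites:`` / ``#samples:`` header comments.
    """
    path = Path(path)
    if format == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        arr = df.to_numpy()
        bad = ~np.isin(arr, (0, 1))
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: non-binary status {arr[i, j]!r} at row "
                f"{df.index[i]!r}, column {df.columns[j]!r}"
            )
        levels = None
        if levels_path is not None:
            levels = pd.read_csv(levels_path, sep="\t", index_col=0)
        return EditingMatrix(status=df.astype(np.int8), levels=levels)
    if format == "triplet_tsv":
        sites, samples = None, None
        with open(path) as fh:
            for line in fh:
                if line.startswith("#sites:"):
                    sites = line[len("#sites:"):].strip().split(",")
                elif line.startswith("#samples:"):
                    samples = line[len("#samples:"):].strip().split(",")
                elif not line.startswith("#"):
                    break
        df = pd.read_csv(path, sep="\t", comment="#")
        if not {"site", "sample", "status"} <= set(df.columns):
            raise ValueError(f"{path}: triplet file needs site/sample/status columns")
        if not df["status"].isin([0, 1]).all():
            bad = df.index[~df["status"].isin([0, 1])][0]
            raise ValueError(f"{path}: non-binary status at data row {bad}")
        sites = sites if sites is not None else sorted(df["site"].unique())
        samples = samples if samples is not None else sorted(df["sample"].unique())
        status = pd.DataFrame(0, index=pd.Index(sites, name="site"), columns=samples, dtype=np.int8)
        status.values[
            status.index.get_indexer(df["site"]), status.columns.get_indexer(df["sample"])
        ] = df["status"].to_numpy()
        levels = None
        if "level" in df.columns:
            levels = pd.DataFrame(np.nan, index=status.index, columns=status.columns)
            levels.values[
                levels.index.get_indexer(df["site"]), levels.columns.get_indexer(df["sample"])
            ] = df["level"].to_numpy()
        return EditingMatrix(status=status, levels=levels)
    raise ValueError(f"unknown editing-matrix format {format!r}")


def write_editing_matrix(edit: EditingMatrix, path) -> None:
    edit.status.to_csv(path, sep="\t")


def read_site_annotations(path) -> tuple[pd.DataFrame, list[str]]:
    """Read per-site annotations from a BED file of single-base intervals.

    BED is 0-based half-open; each interval must have length 1. The name
    field is the site id; column 5 (if present) is strand and column 7 the
    gene symbol. Returns (annotation table indexed by site_id with 1-based
    ``pos``, list of warnings).
    """
    rows, warnings = [], []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{ln}: BED line needs >= 4 fields")
            chrom, start, end, name = f[0], int(f[1]), int(f[2]), f[3]
            if end - start != 1:
                raise ValueError(
                    f"{path}:{ln}: editing-site interval must have length 1, got {end - start}"
                )
            strand = f[5] if len(f) > 5 else "."
            gene = f[6] if len(f) > 6 else (name.split(":")[2] if name.count(":") >= 2 else "")
            rows.append({"site_id": name, "chrom": chrom, "pos": start + 1,
                         "strand": strand, "gene": gene})
    ann = pd.DataFrame(rows).set_index("site_id")
    if ann.index.has_duplicates:
        raise ValueError("duplicate site ids in BED")
    return ann, warnings


def write_site_annotations(ann: pd.DataFrame, path) -> None:
    """Write annotations back to BED (1-based pos -> 0-based half-open)."""
    with open(path, "w") as fh:
        for site_id, row in ann.iterrows():
            fh.write(
                f"{row['chrom']}\t{row['pos'] - 1}\t{row['pos']}\t{site_id}\t0\t"
                f"{row.get('strand', '.')}\t{row.get('gene', '')}\n"
            )


# ---------------------------------------------------------------- gene sets


def read_gene_sets(path) -> GeneSetCollection:
    """Read a GMT file: name, description, tab-separated members."""
    sets, descs = {}, {}
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{ln}: GMT line needs >= 3 tab-separated fields")
            name, desc, members = f[0], f[1], [m for m in f[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{ln}: duplicate gene-set name {name!r}")
            sets[name] = set(members)
            descs[name] = desc
    return GeneSetCollection(sets=sets, descriptions=descs)


def write_gene_sets(gsc: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in gsc:
            desc = gsc.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- networks


def write_network(net: nx.Graph, path, format: str = "graphml") -> None:
    """Write a co-editing network as GraphML or an edge-attribute TSV."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(net, path)
    elif format == "edge_tsv":
        with open(path, "w") as fh:
            fh.write("site_i\tsite_j\t" + "\t".join(EDGE_ATTRS) + "\n")
            for u, v, attrs in sorted(net.edges(data=True)):
                a, b = sorted((u, v))
                vals = "\t".join(repr(attrs.get(k, "")) for k in EDGE_ATTRS)
                fh.write(f"{a}\t{b}\t{vals}\n")
    else:
        raise ValueError(f"unknown network format {format!r}")


def read_network(path, format: str = "graphml") -> nx.Graph:
    path = Path(path)
    if format == "graphml":
        g = nx.read_graphml(path)
        return nx.Graph(g)
    if format == "edge_tsv":
        df = pd.read_csv(path, sep="\t")
        g = nx.Graph()
        for _, row in df.iterrows():
            attrs = {k: row[k] for k in EDGE_ATTRS if k in row and row[k] != ""}
            g.add_edge(str(row["site_i"]), str(row["site_j"]), **attrs)
        return g
    raise ValueError(f"unknown network format {format!r}")


# ---------------------------------------------------------------- tables


def read_expression(values_path, counts_path=None, class_path=None) -> ExpressionBundle:
    """Read an expression bundle from TSV files (genes x samples)."""
    values = pd.read_csv(values_path, sep="\t", index_col=0)
    counts = pd.read_csv(counts_path, sep="\t", index_col=0) if counts_path else None
    sample_class = None
    if class_path:
        sc = pd.read_csv(class_path, sep="\t", index_col=0)
        sample_class = sc.iloc[:, 0]
    return ExpressionBundle(values=values, counts=counts, sample_class=sample_class)


def write_expression(bundle: ExpressionBundle, values_path, counts_path=None, class_path=None):
    bundle.values.to_csv(values_path, sep="\t")
    if counts_path and bundle.counts is not None:
        bundle.counts.to_csv(counts_path, sep="\t")
    if class_path and bundle.sample_class is not None:
        bundle.sample_class.rename("class").to_csv(class_path, sep="\t")


def read_clinical(path) -> ClinicalTable:
    return ClinicalTable(pd.read_csv(path, sep="\t", index_col=0))


def write_clinical(clin: ClinicalTable, path) -> None:
    clin.data.to_csv(path, sep="\t")


def read_copy_number(path) -> CopyNumberSegments:
    """Read segments (1-based inclusive on disk -> half-open internally)."""
    df = pd.read_csv(path, sep="\t")
    bad = df.index[df["start"] > df["end"]]
    if len(bad):
        raise ValueError(f"{path}: malformed segment (start > end) at data row {bad[0]}")
    df = df.copy()
    df["start"] = df["start"] - 1  # to 0-based half-open
    return CopyNumberSegments(df)


def write_copy_number(cns: CopyNumberSegments, path) -> None:
    out = cns.data.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def intersect_samples(*sample_lists) -> tuple[list[str], dict[int, list[str]]]:
    """Ordered intersection of sample ids across tables.

    Returns (kept ids in the order of the first list, mapping of input index
    -> ids dropped from that input).
    """
    common = set(sample_lists[0])
    for ids in sample_lists[1:]:
        common &= set(ids)
    kept = [s for s in sample_lists[0] if s in common]
    dropped = {i: sorted(set(ids) - common) for i, ids in enumerate(sample_lists)}
    return kept, dropped


def read_json(path):
    with open(path) as fh:
        return json.load(fh)


def write_json(obj, path) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (set, tuple)):
        return sorted(o) if isinstance(o, set) else list(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
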