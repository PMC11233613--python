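"""End-to-end orchestration: simulate (or load) -> association screen ->
network inference -> topology -> survival screen -> downstream analyses.

A single global seed is fanned out to per-stage child seeds through
``numpy.random.SeedSequence`` so each stage is independently reproducible.
Identical config + seed gives an identical run report.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .association import EditingAssociationScreen
from .datatypes import EditingMatrix
from .downstream import (
    RankSumDE,
    SignatureModel,
    call_amplifications,
    coamplification_test,
    coediting_associated_genes,
    shared_dysregulated_intersection,
)
from .network import CoEditingNetwork, genomic_pair_summary
from .simulate import CohortConfig, generate_cohort
from .survival import PairSurvivalScreen, assign_risk_groups, logrank_test
from .topology import MCODEParams, degree_and_power_law, hub_nodes, mcode

log = logging.getLogger(__name__)

__all__ = ["RunConfig", "RunReport", "run_pipeline"]


@dataclass
class RunConfig:
    """Pipeline thresholds plus either a simulate block or input paths."""

    simulate: CohortConfig | None = None
    inputs: dict = field(default_factory=dict)  # paths: edit, expr, counts, class, clinical, cn
    fdr: float = 0.05
    min_co: int = 3
    B: int = 1000
    hub_fraction: float = 0.10
    de_lfc: float = 1.0
    cn_threshold: float = 0.30
    min_pairs: int = 3
    min_group: int = 3
    seed: int = 0
    out_dir: str | None = None

    def __post_init__(self):
        if self.B < 1:
            raise ValueError("B must be >= 1")
        if not (0 < self.fdr < 1):
            raise ValueError("fdr must be in (0, 1)")
        if not (0 < self.hub_fraction <= 1):
            raise ValueError("hub_fraction must be in (0, 1]")
        if self.min_co < 1 or self.min_pairs < 1:
            raise ValueError("min_co and min_pairs must be >= 1")
        if self.cn_threshold < 0 or self.de_lfc < 0:
            raise ValueError("thresholds must be non-negative")
        if self.simulate is None and not self.inputs:
            raise ValueError("config needs a simulate block or input paths")


@dataclass
class RunReport:
    seed: int
    stage_counts: dict = field(default_factory=dict)
    manifest: dict = field(default_factory=dict)  # path -> sha256
    version: str = "0.1.0"

    def to_dict(self) -> dict:
        return asdict(self)


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31 - 1)) for s in ss.spawn(n)]


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute every stage in order, writing intermediates when an output
    directory is configured; returns the machine-readable run report."""
    out = Path(config.out_dir) if config.out_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
    report = RunReport(seed=config.seed)
    seeds = _child_seeds(config.seed, 4)  # simulate, network, topology, reserved

    # ---- stage 0: data
    if config.simulate is not None:
        cfg = config.simulate
        cfg.seed = seeds[0]
        editing, expression, clinical, segments, truth = generate_cohort(cfg)
        if out:
            io.write_editing_matrix(editing, out / "editing.tsv")
            io.write_expression(expression, out / "expr.tsv", out / "counts.tsv",
                                out / "classes.tsv")
            io.write_clinical(clinical, out / "clinical.tsv")
            io.write_copy_number(segments, out / "copy_number.tsv")
            io.write_json(truth.to_dict(), out / "truth.json")
    else:
        editing = io.read_editing_matrix(config.inputs["edit"])
        expression = io.read_expression(config.inputs["expr"],
                                        config.inputs.get("counts"),
                                        config.inputs.get("class"))
        clinical = io.read_clinical(config.inputs["clinical"]) if "clinical" in config.inputs else None
        segments = io.read_copy_number(config.inputs["cn"]) if "cn" in config.inputs else None
        truth = None
    tumor = [s for s in expression.tumor_samples() if s in editing.status.columns]
    normal = [s for s in expression.normal_samples() if s in editing.status.columns]
    report.stage_counts["n_tumor"] = len(tumor)
    report.stage_counts["n_normal"] = len(normal)
    report.stage_counts["n_sites"] = len(editing.site_ids)

    # ---- stage 1: editing-associated genes
    screen = EditingAssociationScreen(min_group=config.min_group, fdr=config.fdr)
    screen.fit(editing, expression, clinical)
    report.stage_counts["n_assoc_records"] = len(screen.records_)
    report.stage_counts["n_sites_with_assoc"] = len(screen.by_site_)

    # ---- stage 2: co-editing network
    net_est = (
        CoEditingNetwork(min_co=config.min_co, fdr=config.fdr,
                         n_permutations=config.B, random_state=seeds[1])
        .set_gene_universe(len(expression.gene_ids))
    )
    net_est.fit(editing.subset_samples(tumor), assoc_by_site=screen.by_site_)
    net = net_est.network_
    report.stage_counts["n_candidate_pairs"] = len(net_est.pairs_)
    report.stage_counts["n_edges"] = net.number_of_edges()
    report.stage_counts["n_nodes"] = net.number_of_nodes()
    if out:
        io.write_network(net, out / "network.graphml", "graphml")
        io.write_network(net, out / "edges.tsv", "edge_tsv")

    # ---- stage 3: topology
    if net.number_of_nodes() > 0:
        modules = mcode(net, MCODEParams())
        report.stage_counts["n_modules"] = len(modules)
        hubs, _ = hub_nodes(net, config.hub_fraction)
        report.stage_counts["n_hubs"] = len(hubs)
        try:
            _, exponent, r2 = degree_and_power_law(net)
            report.stage_counts["power_law_exponent"] = round(exponent, 4)
            report.stage_counts["power_law_r2"] = round(r2, 4)
        except ValueError:
            report.stage_counts["power_law_r2"] = None
        if editing.annotations is not None:
            gsum = genomic_pair_summary(net, editing.annotations)
            report.stage_counts["frac_same_chromosome"] = gsum["summary"][
                "frac_same_chromosome"]
    else:
        report.stage_counts["n_modules"] = 0
        report.stage_counts["n_hubs"] = 0

    # ---- stage 4: survival screen & risk groups
    risk_pairs = []
    if clinical is not None and net.number_of_edges() > 0:
        pairs = sorted(net.edges())
        surv = PairSurvivalScreen().fit(pairs, editing, clinical)
        risk_pairs = surv.risk_pairs_
        if out and len(surv.results_):
            surv.results_.to_csv(out / "survival_screen.tsv", sep="\t", index=False)
    report.stage_counts["n_risk_pairs"] = len(risk_pairs)
    assignments = assign_risk_groups(editing, risk_pairs, tumor)
    high = [a.patient_id for a in assignments if a.group == "high"]
    low = [a.patient_id for a in assignments if a.group == "low"]
    report.stage_counts["n_high_risk"] = len(high)
    report.stage_counts["n_low_risk"] = len(low)
    if clinical is not None and high and low:
        sub = clinical.data.loc[[p for p in high + low if p in clinical.data.index]]
        grp = ["high" if p in set(high) else "low" for p in sub.index]
        _, p = logrank_test(sub["os_time"], sub["os_event"], grp)
        report.stage_counts["risk_group_logrank_p"] = float(p)

    # ---- stage 5: downstream
    de_counts = {}
    shared = {"up": set(), "down": set(), "all": set()}
    if expression.counts is not None and normal and len(high) >= 3 and len(low) >= 3:
        de_hi = RankSumDE(fdr=config.fdr, lfc_threshold=config.de_lfc).fit(
            expression.counts, high, normal)
        de_lo = RankSumDE(fdr=config.fdr, lfc_threshold=config.de_lfc).fit(
            expression.counts, low, normal)
        shared = shared_dysregulated_intersection(de_hi.results_, de_lo.results_)
        de_counts = {
            "de_high_vs_normal": int((de_hi.results_["status"] != "ns").sum()),
            "de_low_vs_normal": int((de_lo.results_["status"] != "ns").sum()),
            "shared_up": len(shared["up"]), "shared_down": len(shared["down"]),
        }
    report.stage_counts.update(de_counts)

    sig_genes = coediting_associated_genes(
        risk_pairs, screen.by_site_,
        shared_de_genes=shared["all"] if shared["all"] else None,
        min_pairs=config.min_pairs,
    )
    report.stage_counts["n_signature_genes"] = len(sig_genes)
    if sig_genes and normal:
        try:
            sig = SignatureModel(sig_genes).fit(expression.values, expression.sample_class)
            report.stage_counts["signature_auc"] = round(float(sig.train_auc_), 4)
        except ValueError as e:
            log.warning("signature stage skipped: %s", e)

    if segments is not None and net.number_of_edges() > 0 and editing.annotations is not None:
        amp = call_amplifications(segments, editing.annotations.loc[list(net.nodes)],
                                  tumor, config.cn_threshold)
        coamp = coamplification_test(sorted(net.edges()), amp)
        n_co = int((coamp["fdr"] < config.fdr).sum()) if len(coamp) else 0
        report.stage_counts["n_coamplified_edges"] = n_co
        if out and len(coamp):
            coamp.to_csv(out / "coamplification.tsv", sep="\t", index=False)

    if out:
        for f in sorted(out.iterdir()):
            if f.is_file():
                report.manifest[f.name] = _checksum(f)
        io.write_json(report.to_dict(), out / "run_report.json")
        report.manifest["run_report.json"] = _checksum(out / "run_report.json")
    return report
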