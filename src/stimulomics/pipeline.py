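"""End-to-end orchestration over an emitted fixture directory.

Stages run in dependency order: contig features -> primary bins -> TNF
refinement -> linkage rescue -> bin metrics -> OCS grouping -> cytochrome
annotation -> expression/normalization -> responsive genes -> ordinations ->
pilin screening -> report.  All tabular outputs are TSV with a commented
header carrying the configuration hash; identical config + inputs yield
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np
import pandas as pd

from . import binning, cytscan, epili, exprnorm, io, simcom, stimresp, taxgroup

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    input_dir: str
    output_dir: str
    seed: int = 0
    min_contig_len: int = 500
    cluster_eps: float = 0.5
    cluster_min_samples: int = 5
    min_tnf_corr: float = 0.90
    min_links: int = 3
    ani_threshold: float = 97.0
    tetra_threshold: float = 0.99
    anib_frag_len: int = 1020
    evalue_threshold: float = 1e-6
    fold_threshold: float = 5.0
    min_rpkm: float = 50.0
    aromatic_pct_threshold: float = 9.0
    required_essential_hits: int = 7
    run_ani: bool = True

    def validate(self) -> None:
        if not 0 < self.ani_threshold <= 100:
            raise ValueError("ani_threshold must lie in (0, 100]")
        if not -1 <= self.tetra_threshold <= 1:
            raise ValueError("tetra_threshold must lie in [-1, 1]")
        if self.fold_threshold <= 0 or self.min_rpkm < 0:
            raise ValueError("response thresholds must be positive")
        if self.min_contig_len < 0 or self.min_links < 0:
            raise ValueError("min_contig_len/min_links must be non-negative")
        if self.evalue_threshold <= 0:
            raise ValueError("evalue_threshold must be positive")

    def hash(self) -> str:
        """Hash of the analytic parameters (paths excluded, so reruns into a
        different directory remain byte-comparable)."""
        params = {k: v for k, v in dataclasses.asdict(self).items()
                  if k not in ("input_dir", "output_dir")}
        payload = json.dumps(params, sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def run_pipeline(config: PipelineConfig) -> Dict[str, object]:
    """Execute all stages on the fixture in ``config.input_dir``."""
    config.validate()
    fx = io.Fixture(config.input_dir)
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    tag = config.hash()
    manifest: Dict[str, object] = {"config": dataclasses.asdict(config),
                                   "config_hash": tag, "stages": {}}

    def _save(df: pd.DataFrame, name: str) -> None:
        io.write_tsv(df, out / name, header_comment=f"config_hash={tag}")
        manifest["stages"][name] = len(df)

    design_df = fx.design
    conditions = list(design_df["condition_id"])
    comparisons = {
        row.stimulus: (row.baseline, row.response)
        for row in fx.comparisons.itertuples(index=False)
    }
    design = simcom.ConditionDesign(
        condition_ids=tuple(conditions),
        stimulus_labels=dict(zip(design_df["condition_id"], design_df["stimulus"])),
        comparisons=comparisons,
    )

    # --- binning ---------------------------------------------------------
    contigs = fx.contigs
    features = binning.compute_features(
        contigs, fx.contig_dna_counts, conditions, min_len=config.min_contig_len)
    assignment = binning.cluster_bins(
        features, eps=config.cluster_eps,
        min_samples=config.cluster_min_samples, seed=config.seed)
    assignment = binning.refine_bins_tnf(assignment, features,
                                         min_corr=config.min_tnf_corr)
    assignment = binning.rescue_by_linkage(assignment, fx.linkage,
                                           min_links=config.min_links)
    _save(assignment.as_frame().sort_values("contig_id"), "bin_membership.tsv")

    marker_hits = fx.marker_hits
    expected_markers = sorted(marker_hits["marker_id"].unique())
    metrics = binning.bin_metrics(assignment, features, marker_hits,
                                  expected_markers)
    metrics_df = pd.DataFrame([dataclasses.asdict(m) for m in metrics])
    _save(metrics_df, "bin_metrics.tsv")

    comp = binning.community_composition(assignment, features, method="coverage")
    comp_df = comp.rename("frequency").rename_axis("bin").reset_index()
    _save(comp_df, "composition.tsv")

    # --- OCS -------------------------------------------------------------
    ocs_df = pd.DataFrame(columns=["bin", "ocs_id"])
    bin_to_ocs: Dict[str, str] = {}
    if config.run_ani and assignment.bins:
        bin_seqs = {
            b: taxgroup.concat_bin([contigs[c] for c in sorted(assignment.members(b))])
            for b in assignment.bins
        }
        bin_seqs = {b: s for b, s in bin_seqs.items()
                    if len(s) >= config.anib_frag_len}
        _, _, groups = taxgroup.pairwise_ocs(
            bin_seqs, config.ani_threshold, config.tetra_threshold,
            frag_len=config.anib_frag_len)
        rows = []
        for g in groups:
            for m in g.members:
                rows.append({"bin": m, "ocs_id": g.ocs_id})
                bin_to_ocs[m] = g.ocs_id
        ocs_df = pd.DataFrame(rows)
    _save(ocs_df, "ocs_membership.tsv")

    # --- cytochrome annotation ------------------------------------------
    proteins = fx.proteins
    annotations = cytscan.annotate_proteins(proteins)
    ann_df = pd.DataFrame(
        [
            {
                "orf_id": a.protein_id,
                "heme_count": a.heme_count,
                "cytc_class": a.cytc_class,
                "motif_positions": ",".join(map(str, a.motif_positions)),
            }
            for a in annotations
        ]
    )
    _save(ann_df, "cytc_annotation.tsv")

    # --- expression ------------------------------------------------------
    expr = exprnorm.expression_table(fx.dna_counts, fx.mrna_counts, conditions)
    _save(expr.round(6), "expression.tsv")

    orfs = fx.orfs
    orf_bins = pd.Series(
        [assignment.labels.get(c, binning.UNASSIGNED) for c in orfs["contig_id"]],
        index=orfs["orf_id"],
    )
    abund, weights = exprnorm.bin_expression(expr, orf_bins, conditions)
    _save(abund.rename_axis("bin").reset_index().round(6), "bin_abundance.tsv")

    # --- responses -------------------------------------------------------
    calls = stimresp.responsive_genes(expr, design, fold=config.fold_threshold,
                                      min_rpkm=config.min_rpkm)
    _save(calls.round(4), "responsive_calls.tsv")
    mh = {a.protein_id: a.cytc_class == "multi_heme" for a in annotations}
    taxon_map = {b: bin_to_ocs.get(b, b) for b in assignment.bins}
    tally = stimresp.tally_by_taxon(calls, orf_bins, taxon_map, mh)
    _save(tally, "responsive_tally.tsv")

    # --- ordinations -----------------------------------------------------
    ordinations: Dict[str, stimresp.Ordination] = {}
    abund_kept = abund.drop(index=[binning.UNASSIGNED], errors="ignore")
    if len(abund_kept) >= 3:
        mds = stimresp.wmds(abund_kept, weights.reindex(abund_kept.index),
                            seed=config.seed)
        _save(mds.points.rename_axis("bin").reset_index().round(6),
              "wmds_scores.tsv")
        ordinations["wMDS"] = mds
    X = pd.DataFrame(
        {
            var: [1.0 if c in conds else 0.0 for c in conditions]
            for var, conds in design.variable_map.items()
        },
        index=conditions,
    )
    norm_cols = [f"norm_mrna_{c}" for c in conditions]
    Y = expr.set_index("orf_id")[norm_cols].dropna()
    Y.columns = conditions
    Y = Y[Y.sum(axis=1) > 0]
    if len(Y) >= 3:
        cca = stimresp.wcca(Y, X)
        _save(cca.points.rename_axis("orf_id").reset_index().round(6),
              "wcca_gene_scores.tsv")
        part = stimresp.partition_by_arrow_midpoints(cca)
        part_df = part.rename("variable").rename_axis("orf_id").reset_index()
        _save(part_df.fillna(""), "wcca_partition.tsv")
        ordinations["wCCA"] = cca

    # --- pilins ----------------------------------------------------------
    pilin_ids = [o for o, k in zip(orfs["orf_id"], orfs["kind"]) if k == "pilin"]
    pilin_df = pd.DataFrame()
    if pilin_ids:
        anns = epili.annotate_pilins(
            {p: proteins[p] for p in pilin_ids},
            simcom.REFERENCE_PILIN, simcom.ESSENTIAL_POSITIONS,
            pct_threshold=config.aromatic_pct_threshold,
            required_hits=config.required_essential_hits)
        pilin_df = pd.DataFrame([dataclasses.asdict(a) for a in anns])
        _save(pilin_df, "pilin_annotation.tsv")

    io.write_json(manifest, out / "manifest.json")
    return {
        "manifest": manifest,
        "features": features,
        "assignment": assignment,
        "metrics": metrics_df,
        "composition": comp_df,
        "ocs": ocs_df,
        "cytc": ann_df,
        "expression": expr,
        "bin_abundance": abund,
        "calls": calls,
        "tally": tally,
        "ordinations": ordinations,
        "pilins": pilin_df,
    }


def write_report(results: Dict[str, object], out_path) -> dict:
    """Machine-readable summary over completed stage outputs.

    Missing stages leave explicit gaps rather than failing.
    """
    report: Dict[str, object] = {"gaps": []}
    metrics = results.get("metrics")
    if metrics is not None and len(metrics):
        report["bins"] = metrics.to_dict(orient="records")
    else:
        report["gaps"].append("bin metrics missing")
    cytc = results.get("cytc")
    if cytc is not None and len(cytc):
        n_cytc = int((cytc["heme_count"] >= 1).sum())
        n_mh = int((cytc["heme_count"] >= cytscan.MULTIHEME_MIN).sum())
        report["cytc_census"] = {"n_cytC": n_cytc, "n_MH_cytC": n_mh}
    else:
        report["gaps"].append("cytochrome annotation missing")
    tally = results.get("tally")
    if tally is not None:
        report["responsive_tally"] = tally.to_dict(orient="records")
    else:
        report["gaps"].append("responsive tally missing")
    pilins = results.get("pilins")
    if pilins is not None and len(pilins):
        report["pilins"] = pilins.to_dict(orient="records")
    comp = results.get("composition")
    if comp is not None:
        report["composition"] = comp.to_dict(orient="records")
    io.write_json(report, out_path)
    return report
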