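#!/usr/bin/env python
"""Classify stimulus-responsive genes, tally them by taxon, ordinate
expression profiles (wMDS over bins, wCCA over genes) and partition genes
to stimuli by arrow midpoints.  Outputs under results/responses/.
"""

from pathlib import Path

import pandas as pd

from stimulomics import exprnorm, io, simcom, stimresp

OUT = Path("results/responses")


def main() -> None:
    fx = io.Fixture("results/fixture")
    conds = list(fx.design["condition_id"])
    design = simcom.ConditionDesign(
        condition_ids=tuple(conds),
        stimulus_labels=dict(zip(fx.design["condition_id"],
                                 fx.design["stimulus"])),
        comparisons={r.stimulus: (r.baseline, r.response)
                     for r in fx.comparisons.itertuples(index=False)})
    membership = io.read_tsv("results/binning/bin_membership.tsv")
    labels = dict(zip(membership["contig_id"], membership["bin"]))
    orfs = fx.orfs
    orf_bins = pd.Series(
        [labels.get(c, "UNASSIGNED") for c in orfs["contig_id"]],
        index=orfs["orf_id"])
    expr = io.read_tsv("results/expression/expression.tsv")
    cytc = io.read_tsv("results/annotation/cytc_annotation.tsv")
    ocs = io.read_tsv("results/species/ocs_membership.tsv")

    calls = stimresp.responsive_genes(expr, design)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_tsv(calls.round(4), OUT / "responsive_calls.tsv")

    mh = dict(zip(cytc["orf_id"], cytc["cytc_class"] == "multi_heme"))
    taxon_map = dict(zip(ocs["bin"], ocs["ocs_id"]))
    tally = stimresp.tally_by_taxon(calls, orf_bins, taxon_map, mh)
    io.write_tsv(tally, OUT / "responsive_tally.tsv")

    abund = io.read_tsv("results/expression/bin_abundance.tsv").set_index("bin")
    weights = io.read_tsv("results/expression/bin_weights.tsv") \
        .set_index("bin")["weight"]
    kept = abund.drop(index=["UNASSIGNED"], errors="ignore")
    mds = stimresp.wmds(kept, weights.reindex(kept.index), seed=1)
    io.write_tsv(mds.points.rename_axis("bin").reset_index().round(6),
                 OUT / "wmds_scores.tsv")

    X = pd.DataFrame(
        {v: [1.0 if c in cs else 0.0 for c in conds]
         for v, cs in design.variable_map.items()}, index=conds)
    norm_cols = [f"norm_mrna_{c}" for c in conds]
    Y = expr.set_index("orf_id")[norm_cols].dropna()
    Y.columns = conds
    Y = Y[Y.sum(axis=1) > 0]
    cca = stimresp.wcca(Y, X)
    io.write_tsv(cca.points.rename_axis("orf_id").reset_index().round(6),
                 OUT / "wcca_gene_scores.tsv")
    part = stimresp.partition_by_arrow_midpoints(cca)
    io.write_tsv(part.rename("variable").rename_axis("orf_id").reset_index()
                 .fillna(""), OUT / "wcca_partition.tsv")

    truth_plan = fx.truth["response_plan"]
    hits = calls[calls["direction"] != "none"]
    recovered = {(o, r["stimulus"], r["direction"]) for o, r in
                 truth_plan.items()} & {
        (r.orf_id, r.stimulus, r.direction)
        for r in hits.itertuples(index=False)}
    print(f"responsive calls: {len(hits)} of {len(calls)} ORF x stimulus")
    print(f"planted responders recovered: {len(recovered)}/{len(truth_plan)}")
    print("tally by taxon:")
    print(tally.to_string(index=False))
    print(f"wMDS stress: {mds.stress:.4g}")
    print(f"wCCA eigenvalues: {[round(e, 4) for e in cca.eigenvalues]}"
          f" (aliased: {cca.aliased})")
    counts = part.value_counts(dropna=True)
    print("arrow-midpoint partition sizes:", dict(counts))


if __name__ == "__main__":
    main()
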