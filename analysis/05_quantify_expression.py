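#!/usr/bin/env python
"""Compute DNA/mRNA RPKM, DNA-mean-normalized expression and bin-level
relative mRNA abundance per condition.  Outputs under results/expression/.
"""

from pathlib import Path

import pandas as pd

from stimulomics import exprnorm, io

OUT = Path("results/expression")


def main() -> None:
    fx = io.Fixture("results/fixture")
    conds = list(fx.design["condition_id"])
    membership = io.read_tsv("results/binning/bin_membership.tsv")
    labels = dict(zip(membership["contig_id"], membership["bin"]))
    orfs = fx.orfs

    expr = exprnorm.expression_table(fx.dna_counts, fx.mrna_counts, conds)
    OUT.mkdir(parents=True, exist_ok=True)
    io.write_tsv(expr.round(6), OUT / "expression.tsv")

    orf_bins = pd.Series(
        [labels.get(c, "UNASSIGNED") for c in orfs["contig_id"]],
        index=orfs["orf_id"])
    abund, weights = exprnorm.bin_expression(expr, orf_bins, conds)
    io.write_tsv(abund.rename_axis("bin").reset_index().round(6),
                 OUT / "bin_abundance.tsv")
    io.write_tsv(weights.rename("weight").rename_axis("bin").reset_index()
                 .round(4), OUT / "bin_weights.tsv")

    print(f"expression table: {len(expr)} ORFs x {len(conds)} conditions")
    n_undef = int(expr[[f"norm_mrna_{c}" for c in conds]].isna().sum().sum())
    print(f"undefined ORF x condition cells (zero DNA): {n_undef}")
    print("bin relative mRNA abundance per condition:")
    print(abund.round(3).to_string())


if __name__ == "__main__":
    main()
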