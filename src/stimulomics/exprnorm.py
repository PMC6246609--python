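"""RPKM computation with DNA-mean normalization and bin-level aggregation.

DNA-RPKM measures gene dosage, mRNA-RPKM expression.  Because community
composition drifts slightly between the five sampled conditions, each
condition's mRNA-RPKM is corrected by that condition's relative DNA-RPKM:

    normalized_c = mRNA_RPKM_c / (DNA_RPKM_c / mean_c'(DNA_RPKM_c'))

Conditions with zero DNA-RPKM are marked undefined (NaN) and excluded from
fold-change and ordination computations rather than imputed.
"""

from __future__ import annotations

import logging
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


def rpkm(counts, lengths_bp, total_mapped: float):
    """Reads Per Kilobase per Million mapped reads: C x 1e9 / (N x L)."""
    if total_mapped <= 0:
        raise ValueError("total mapped reads must be positive")
    counts = np.asarray(counts, dtype=float)
    lengths = np.asarray(lengths_bp, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("ORF lengths must be positive")
    return counts * 1e9 / (total_mapped * lengths)


def expression_table(dna_counts: pd.DataFrame, mrna_counts: pd.DataFrame,
                     conditions: Sequence[str],
                     dna_totals: Optional[Dict[str, float]] = None,
                     mrna_totals: Optional[Dict[str, float]] = None,
                     ) -> pd.DataFrame:
    """Build the ORF x condition expression table.

    Input tables carry ``orf_id, length`` plus one count column per
    condition.  Totals default to the per-condition column sums (totals are
    kept separate for DNA and mRNA).  Output columns per condition c:
    ``dna_rpkm_c, mrna_rpkm_c, norm_mrna_c, ratio_c`` plus ``dna_rpkm_mean``.
    """
    dna = dna_counts.set_index("orf_id")
    mrna = mrna_counts.set_index("orf_id").reindex(dna.index)
    out = pd.DataFrame(index=dna.index)
    out["length"] = dna["length"]
    lengths = dna["length"].to_numpy(dtype=float)
    for c in conditions:
        n_dna = dna_totals[c] if dna_totals else float(dna[c].sum())
        n_mrna = mrna_totals[c] if mrna_totals else float(mrna[c].sum())
        out[f"dna_rpkm_{c}"] = rpkm(dna[c].to_numpy(), lengths, n_dna)
        out[f"mrna_rpkm_{c}"] = rpkm(mrna[c].to_numpy(), lengths, n_mrna)
    dna_cols = [f"dna_rpkm_{c}" for c in conditions]
    out["dna_rpkm_mean"] = out[dna_cols].mean(axis=1)
    n_undefined = 0
    for c in conditions:
        out[f"norm_mrna_{c}"] = normalize_mrna(
            out[f"mrna_rpkm_{c}"], out[f"dna_rpkm_{c}"], out["dna_rpkm_mean"])
        out[f"ratio_{c}"] = mrna_dna_ratio(
            out[f"mrna_rpkm_{c}"], out[f"dna_rpkm_{c}"])
        n_undefined += int(out[f"norm_mrna_{c}"].isna().sum())
    if n_undefined:
        logger.info("%d ORF x condition cells undefined (zero DNA-RPKM)",
                    n_undefined)
    return out.reset_index()


def normalize_mrna(mrna_rpkm, dna_rpkm, dna_rpkm_mean):
    """DNA-mean normalization; NaN where the condition's DNA-RPKM is zero."""
    mrna = np.asarray(mrna_rpkm, dtype=float)
    dna = np.asarray(dna_rpkm, dtype=float)
    mean = np.asarray(dna_rpkm_mean, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        norm = mrna / (dna / mean)
    norm = np.where(dna > 0, norm, np.nan)
    if np.all(~(dna > 0)):
        logger.warning("all-zero DNA-RPKM: normalized expression undefined")
    return pd.Series(norm, index=getattr(mrna_rpkm, "index", None))


def mrna_dna_ratio(mrna_rpkm, dna_rpkm):
    """mRNA/DNA RPKM ratio; NaN where DNA-RPKM is zero."""
    mrna = np.asarray(mrna_rpkm, dtype=float)
    dna = np.asarray(dna_rpkm, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = mrna / dna
    ratio = np.where(dna > 0, ratio, np.nan)
    return pd.Series(ratio, index=getattr(mrna_rpkm, "index", None))


def bin_expression(expression: pd.DataFrame, orf_bins: pd.Series,
                   conditions: Sequence[str]) -> Tuple[pd.DataFrame, pd.Series]:
    """Per-bin per-condition relative mRNA abundance and expression weight.

    Per condition, bin abundance is the sum of mrna_rpkm x length over
    member ORFs, normalized across bins; ORFs without a bin pool under
    UNASSIGNED.  The weight is the mean over conditions of the bin's summed
    mRNA-RPKM (used as row weight in ordinations).
    """
    expr = expression.set_index("orf_id")
    bins = orf_bins.reindex(expr.index).fillna("UNASSIGNED")
    rows = {}
    weights = {}
    for b, idx in expr.groupby(bins).groups.items():
        sub = expr.loc[idx]
        per_cond = np.array([
            float((sub[f"mrna_rpkm_{c}"] * sub["length"]).sum())
            for c in conditions
        ])
        rows[b] = per_cond
        weights[b] = float(np.mean([sub[f"mrna_rpkm_{c}"].sum()
                                    for c in conditions]))
    abund = pd.DataFrame(rows, index=list(conditions)).T
    totals = abund.sum(axis=0)
    abund = abund / totals.replace(0, np.nan)
    return abund.fillna(0.0), pd.Series(weights)


# ---------------------------------------------------------------------------
# Optional pseudo-mapper (secondary path; counts are the primary fixture)
# ---------------------------------------------------------------------------

def pseudo_map(reads: Dict[str, str], orf_seqs: Dict[str, str],
               min_length_fraction: float = 0.6, min_similarity: float = 0.95,
               seed: int = 0) -> pd.DataFrame:
    """Best-hit read counting with coverage/identity filters.

    A read counts toward an ORF iff its best local alignment covers
    >= ``min_length_fraction`` of the read with >= ``min_similarity``
    identity over the aligned part; ties split by a seeded random draw.
    Intended for small fixtures; supply count tables directly at scale.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.match_score = 1
    aligner.mismatch_score = -2
    aligner.open_gap_score = -3
    aligner.extend_gap_score = -1
    rng = np.random.default_rng(seed)
    counts = dict.fromkeys(orf_seqs, 0)
    orf_ids = sorted(orf_seqs)
    for read_id in sorted(reads):
        read = reads[read_id]
        best_score = None
        best_orfs = []
        for oid in orf_ids:
            try:
                aln = aligner.align(read, orf_seqs[oid])[0]
            except (IndexError, ValueError):
                continue
            q_aln = sum(e - s for s, e in aln.aligned[0])
            if q_aln == 0:
                continue
            matches = sum(
                1
                for (qs, qe), (ts, te) in zip(aln.aligned[0], aln.aligned[1])
                for a, b in zip(read[qs:qe], orf_seqs[oid][ts:te])
                if a == b
            )
            columns = sum(qe - qs for qs, qe in aln.aligned[0])
            identity = matches / columns
            coverage = q_aln / len(read)
            if coverage < min_length_fraction or identity < min_similarity:
                continue
            if best_score is None or aln.score > best_score:
                best_score = aln.score
                best_orfs = [oid]
            elif aln.score == best_score:
                best_orfs.append(oid)
        if best_orfs:
            pick = best_orfs[int(rng.integers(len(best_orfs)))]
            counts[pick] += 1
    return pd.DataFrame(
        {"orf_id": list(counts), "count": list(counts.values())}
    )
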