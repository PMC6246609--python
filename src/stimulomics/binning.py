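"""Contig binning by coverage-GC and differential coverage, with
tetranucleotide refinement, paired-end rescue, marker-based quality metrics
(MAG quality tiers) and community composition.

The primary clustering mechanizes the visual picking of clusters on
coverage-GC% / differential-coverage plots: density-based clustering on the
standardized ``[gc, log10(coverage) per condition]`` feature space, which
needs no preset cluster count.  Contigs in low-density regions stay
UNASSIGNED and may be rescued through paired-end links.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.preprocessing import StandardScaler

from .simcom import revcomp

logger = logging.getLogger(__name__)

UNASSIGNED = "UNASSIGNED"

MIN_CONTIG_LEN = 500  # contigs over 500 bp enter the analysis


# ---------------------------------------------------------------------------
# Features
# ---------------------------------------------------------------------------

_TNF_DIM = 256
_BASE_TO_IDX = np.full(256, -1, dtype=np.int64)
for _i, _b in enumerate("ACGT"):
    _BASE_TO_IDX[ord(_b)] = _i


def _kmer_counts(seq: str, k: int) -> np.ndarray:
    """Count k-mers over the forward strand (positions with non-ACGT skipped)."""
    arr = _BASE_TO_IDX[np.frombuffer(seq.encode(), dtype=np.uint8)]
    n = len(arr) - k + 1
    if n <= 0:
        return np.zeros(4 ** k, dtype=np.int64)
    idx = np.zeros(n, dtype=np.int64)
    valid = np.ones(n, dtype=bool)
    for j in range(k):
        w = arr[j: j + n]
        idx = idx * 4 + np.where(w < 0, 0, w)
        valid &= w >= 0
    return np.bincount(idx[valid], minlength=4 ** k)


def tetranucleotide_frequencies(seq: str) -> np.ndarray:
    """Strand-pooled tetranucleotide frequencies (sum over both strands,
    normalized to 1); entries for a 4-mer and its reverse complement carry
    mirrored mass."""
    counts = _kmer_counts(seq, 4) + _kmer_counts(revcomp(seq), 4)
    total = counts.sum()
    if total == 0:
        return np.zeros(_TNF_DIM)
    return counts / total


def compute_features(contig_seqs: Dict[str, str],
                     contig_counts: pd.DataFrame,
                     conditions: Sequence[str],
                     min_len: int = MIN_CONTIG_LEN,
                     read_len: float = 100.0) -> pd.DataFrame:
    """Per-contig GC, per-condition mean coverage, and TNF vector.

    Coverage is per-condition DNA read count converted to mean per-base
    depth (count x read_len / length).  Contigs below ``min_len`` are
    excluded with a logged reason.
    """
    counts = contig_counts.set_index("contig_id")
    rows = []
    for cid, seq in contig_seqs.items():
        if len(seq) == 0:
            raise ValueError(f"contig {cid} has zero length")
        if len(seq) < min_len:
            logger.info("excluding contig %s: length %d < %d", cid, len(seq), min_len)
            continue
        cov = counts.loc[cid, list(conditions)].to_numpy(dtype=float) * read_len / len(seq)
        rows.append({
            "contig_id": cid,
            "length": len(seq),
            "gc": (seq.count("G") + seq.count("C")) / len(seq),
            "coverage": cov,
            "tnf": tetranucleotide_frequencies(seq),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

@dataclass
class BinAssignment:
    """contig -> bin label (or UNASSIGNED) with per-contig provenance."""

    labels: Dict[str, str]
    provenance: Dict[str, str]

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "contig_id": list(self.labels),
                "bin": [self.labels[c] for c in self.labels],
                "provenance": [self.provenance.get(c, "") for c in self.labels],
            }
        )

    def members(self, bin_label: str) -> List[str]:
        return [c for c, b in self.labels.items() if b == bin_label]

    @property
    def bins(self) -> List[str]:
        return sorted({b for b in self.labels.values() if b != UNASSIGNED})


def cluster_bins(features: pd.DataFrame, eps: Optional[float] = None,
                 min_samples: int = 5, eps_factor: float = 2.0,
                 seed: int = 0) -> BinAssignment:
    """Primary clusters on standardized [gc, log10(coverage+0.1)] space.

    When ``eps`` is not given it adapts to the data density as
    ``eps_factor`` x the median ``min_samples``-th nearest-neighbour
    distance (the usual DBSCAN elbow heuristic), so sparse and dense
    communities cluster with the same defaults.  DBSCAN is deterministic
    for a fixed input; ``seed`` is accepted for interface stability.
    Noise points are left UNASSIGNED.
    """
    if len(features) < 2:
        raise ValueError("need at least 2 contigs to cluster")
    cov = np.vstack(features["coverage"].to_numpy())
    X = np.column_stack([features["gc"].to_numpy(), np.log10(cov + 0.1)])
    if np.allclose(X.std(axis=0), 0):
        labels = np.zeros(len(features), dtype=int)
    else:
        Xs = StandardScaler().fit_transform(X)
        if eps is None:
            from sklearn.neighbors import NearestNeighbors

            k = min(min_samples, len(Xs) - 1)
            nn = NearestNeighbors(n_neighbors=k + 1).fit(Xs)
            dist, _ = nn.kneighbors(Xs)
            eps = float(eps_factor * np.median(dist[:, -1]))
        labels = DBSCAN(eps=eps, min_samples=min_samples).fit_predict(Xs)
    # Stable bin names: order clusters by total length, largest first.
    sizes: Dict[int, int] = {}
    for lab, ln in zip(labels, features["length"]):
        if lab >= 0:
            sizes[lab] = sizes.get(lab, 0) + int(ln)
    order = sorted(sizes, key=lambda k: (-sizes[k], k))
    rename = {lab: f"bin_{i + 1:03d}" for i, lab in enumerate(order)}
    out = {}
    prov = {}
    for cid, lab in zip(features["contig_id"], labels):
        out[cid] = rename.get(lab, UNASSIGNED)
        prov[cid] = "primary_cluster" if lab >= 0 else ""
    return BinAssignment(out, prov)


def refine_bins_tnf(assignment: BinAssignment, features: pd.DataFrame,
                    min_corr: float = 0.90) -> BinAssignment:
    """Demote contigs whose TNF correlation to their bin's length-weighted
    mean TNF falls below ``min_corr`` (single pass; means recomputed once
    afterwards, implicitly, by downstream consumers)."""
    feats = features.set_index("contig_id")
    labels = dict(assignment.labels)
    prov = dict(assignment.provenance)
    for bin_label in assignment.bins:
        members = assignment.members(bin_label)
        tnfs = np.vstack([feats.loc[c, "tnf"] for c in members])
        weights = feats.loc[members, "length"].to_numpy(dtype=float)
        mean_tnf = (tnfs * weights[:, None]).sum(axis=0) / weights.sum()
        for cid, tnf in zip(members, tnfs):
            r = _pearson(tnf, mean_tnf)
            if r < min_corr:
                labels[cid] = UNASSIGNED
                prov[cid] = ""
                logger.info("TNF demotion: %s from %s (r=%.3f)", cid, bin_label, r)
            else:
                if prov.get(cid) == "primary_cluster":
                    prov[cid] = "primary_cluster"
    return BinAssignment(labels, prov)


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = np.sqrt((a * a).sum() * (b * b).sum())
    if denom == 0:
        return 0.0
    return float((a * b).sum() / denom)


def rescue_by_linkage(assignment: BinAssignment, linkage: pd.DataFrame,
                      min_links: int = 3) -> BinAssignment:
    """Assign/reassign contigs by paired-end link support.

    An UNASSIGNED contig joins the bin it has >= ``min_links`` summed links
    to, provided that is >= 2x the links to any other bin.  An assigned
    contig with >= 2x more links to a different bin is reassigned.  Ties
    break toward UNASSIGNED.
    """
    labels = dict(assignment.labels)
    prov = dict(assignment.provenance)
    link_sum: Dict[str, Dict[str, int]] = {}
    for row in linkage.itertuples(index=False):
        for me, other in ((row.contig_a, row.contig_b), (row.contig_b, row.contig_a)):
            other_bin = labels.get(other, UNASSIGNED)
            if other_bin == UNASSIGNED:
                continue
            link_sum.setdefault(me, {}).setdefault(other_bin, 0)
            link_sum[me][other_bin] += int(row.n_links)
    for cid, per_bin in link_sum.items():
        if cid not in labels:
            continue
        ranked = sorted(per_bin.items(), key=lambda kv: (-kv[1], kv[0]))
        best_bin, best = ranked[0]
        second = ranked[1][1] if len(ranked) > 1 else 0
        current = labels[cid]
        if current == UNASSIGNED:
            if best >= min_links and best >= 2 * second and (len(ranked) == 1 or best > second):
                labels[cid] = best_bin
                prov[cid] = "linkage_rescued"
        else:
            own = per_bin.get(current, 0)
            if best_bin != current and best >= 2 * own and best > own:
                labels[cid] = best_bin
                prov[cid] = "linkage_rescued"
    return BinAssignment(labels, prov)


# ---------------------------------------------------------------------------
# Quality metrics and MAG tiers
# ---------------------------------------------------------------------------

@dataclass
class BinMetrics:
    bin: str
    total_length: int
    n_contigs: int
    completeness: float  # % of expected single-copy markers present
    contamination: float  # % of extra marker copies
    rrna_5s: bool = False
    rrna_16s: bool = False
    rrna_23s: bool = False
    n_trna: int = 0
    mimag_tier: str = "low"


def estimate_completeness(bin_contigs: Iterable[str], marker_hits: pd.DataFrame,
                          expected_markers: Sequence[str]) -> tuple[float, float]:
    """Single-copy-marker completeness / contamination percentages.

    completeness = 100 x distinct expected markers present / expected;
    contamination = 100 x sum of extra copies / expected.
    """
    expected = list(dict.fromkeys(expected_markers))
    if not expected:
        raise ValueError("expected marker set is empty")
    members = set(bin_contigs)
    hits = marker_hits[marker_hits["contig_id"].isin(members)]
    copies = hits["marker_id"].value_counts()
    present = [m for m in expected if copies.get(m, 0) >= 1]
    extra = sum(max(0, int(copies.get(m, 0)) - 1) for m in expected)
    completeness = 100.0 * len(present) / len(expected)
    contamination = 100.0 * extra / len(expected)
    return completeness, contamination


def classify_mimag(completeness: float, contamination: float,
                   rrna_5s: bool, rrna_16s: bool, rrna_23s: bool,
                   n_trna: int) -> str:
    """MAG quality tier decision table (high / medium / low)."""
    if (completeness > 90 and contamination < 5
            and rrna_5s and rrna_16s and rrna_23s and n_trna >= 18):
        return "high"
    if completeness >= 50 and contamination < 10:
        return "medium"
    return "low"


def bin_metrics(assignment: BinAssignment, features: pd.DataFrame,
                marker_hits: pd.DataFrame, expected_markers: Sequence[str],
                rna_flags: Optional[pd.DataFrame] = None) -> List[BinMetrics]:
    """Assemble per-bin metrics; rRNA/tRNA flags come from an external
    annotation table (bin, rrna_5s, rrna_16s, rrna_23s, n_trna)."""
    feats = features.set_index("contig_id")
    flags = rna_flags.set_index("bin") if rna_flags is not None else None
    out = []
    for b in assignment.bins:
        members = assignment.members(b)
        comp, cont = estimate_completeness(members, marker_hits, expected_markers)
        kw = dict(rrna_5s=False, rrna_16s=False, rrna_23s=False, n_trna=0)
        if flags is not None and b in flags.index:
            row = flags.loc[b]
            kw = dict(rrna_5s=bool(row["rrna_5s"]), rrna_16s=bool(row["rrna_16s"]),
                      rrna_23s=bool(row["rrna_23s"]), n_trna=int(row["n_trna"]))
        out.append(BinMetrics(
            bin=b,
            total_length=int(feats.loc[members, "length"].sum()),
            n_contigs=len(members),
            completeness=comp,
            contamination=cont,
            mimag_tier=classify_mimag(comp, cont, **kw),
            **kw,
        ))
    return out


# ---------------------------------------------------------------------------
# Community composition
# ---------------------------------------------------------------------------

def community_composition(assignment: BinAssignment, features: pd.DataFrame,
                          method: str = "coverage",
                          marker_coverages: Optional[pd.DataFrame] = None,
                          mapped_reads: Optional[pd.DataFrame] = None,
                          ) -> pd.Series:
    """Relative bin frequencies by one of three estimators.

    ``core_genes``: mean over single-copy markers of each bin's share of
    that marker's coverage (needs ``marker_coverages`` with columns
    marker_id, bin, coverage).  ``coverage``: length-weighted mean contig
    coverage per bin, normalized.  ``raw_reads``: mapped-read fraction per
    bin (needs ``mapped_reads`` with columns contig_id, reads).
    """
    feats = features.set_index("contig_id")
    groups = {b: assignment.members(b) for b in assignment.bins}
    groups[UNASSIGNED] = [c for c, b in assignment.labels.items() if b == UNASSIGNED]
    if method == "coverage":
        vals = {}
        for b, members in groups.items():
            if not members:
                vals[b] = 0.0
                continue
            lens = feats.loc[members, "length"].to_numpy(dtype=float)
            covs = np.vstack(feats.loc[members, "coverage"].to_numpy()).mean(axis=1)
            vals[b] = float((covs * lens).sum() / lens.sum())
    elif method == "raw_reads":
        if mapped_reads is None:
            raise ValueError("raw_reads method needs a mapped_reads table")
        reads = mapped_reads.set_index("contig_id")["reads"]
        vals = {b: float(reads.reindex(members).fillna(0).sum())
                for b, members in groups.items()}
    elif method == "core_genes":
        if marker_coverages is None:
            raise ValueError("core_genes method needs marker coverages")
        vals = dict.fromkeys(groups, 0.0)
        per_marker = []
        for _, sub in marker_coverages.groupby("marker_id"):
            total = sub["coverage"].sum()
            if total == 0:
                continue
            shares = sub.groupby("bin")["coverage"].sum() / total
            per_marker.append(shares)
        if not per_marker:
            raise ValueError("no marker coverage available")
        mean_share = pd.concat(per_marker, axis=1).fillna(0.0).mean(axis=1)
        for b, v in mean_share.items():
            vals[b] = float(v)
    else:
        raise ValueError(f"unknown composition method {method!r}")
    series = pd.Series(vals, dtype=float)
    total = series.sum()
    if total > 0:
        series = series / total
    return series.sort_index()
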