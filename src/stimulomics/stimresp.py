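"""Stimulus-response analysis: responsive-gene calls, taxon tallies,
weighted MDS / weighted CCA ordinations, arrow-midpoint partitioning and
marker-panel selection.

A gene responds to a stimulus when its DNA-normalized mRNA-RPKM changes
>= 5-fold between the stimulus' baseline and response conditions and the
direction-matched value exceeds 50 RPKM.  Ordinations relate expression
profiles to the three operational variables SucEET (sucrose-fed EET),
SucOC (open circuit) and AcProEET (acetate/propionate-fed EET); weighting
multiplies row masses by each row's average expression level.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .simcom import ConditionDesign

logger = logging.getLogger(__name__)

PSEUDOCOUNT_RPKM = 0.01  # replaces zero before fold-change ratios


# ---------------------------------------------------------------------------
# Responsive genes
# ---------------------------------------------------------------------------

@dataclass
class ResponsiveCall:
    orf_id: str
    stimulus: str
    direction: str  # positive | negative | none
    fold_change: float
    gating_rpkm: float


def responsive_genes(expression: pd.DataFrame, design: ConditionDesign,
                     fold: float = 5.0, min_rpkm: float = 50.0,
                     value_prefix: str = "norm_mrna_") -> pd.DataFrame:
    """Classify every ORF x stimulus as positive / negative / none.

    positive: after/before >= fold and after >= min_rpkm;
    negative: before/after >= fold and before >= min_rpkm (direction-matched
    gating).  Undefined expression in either condition skips the call.
    """
    rows = []
    n_skipped = 0
    for stim, (before_c, after_c) in design.comparisons.items():
        before = expression[f"{value_prefix}{before_c}"].to_numpy(dtype=float)
        after = expression[f"{value_prefix}{after_c}"].to_numpy(dtype=float)
        for oid, b, a in zip(expression["orf_id"], before, after):
            if np.isnan(b) or np.isnan(a):
                n_skipped += 1
                continue
            b_eff = max(b, PSEUDOCOUNT_RPKM)
            a_eff = max(a, PSEUDOCOUNT_RPKM)
            up = a_eff / b_eff
            if up >= fold and a >= min_rpkm:
                direction, fc, gate = "positive", up, a
            elif 1.0 / up >= fold and b >= min_rpkm:
                direction, fc, gate = "negative", 1.0 / up, b
            else:
                direction, fc, gate = "none", max(up, 1.0 / up), max(a, b)
            rows.append((oid, stim, direction, fc, gate))
    if n_skipped:
        logger.info("skipped %d ORF x stimulus calls (undefined expression)",
                    n_skipped)
    return pd.DataFrame(
        rows, columns=["orf_id", "stimulus", "direction", "fold_change",
                       "gating_rpkm"])


def tally_by_taxon(calls: pd.DataFrame, orf_bins: pd.Series,
                   bin_taxon: Dict[str, str],
                   mh_cytc: Optional[Dict[str, bool]] = None) -> pd.DataFrame:
    """Stimulus x direction x taxon counts with an MH-cytC overlay count."""
    mh_cytc = mh_cytc or {}
    hits = calls[calls["direction"] != "none"].copy()
    if hits.empty:
        return pd.DataFrame(
            columns=["stimulus", "direction", "taxon", "n_genes", "n_mh_cytc"])
    bins = orf_bins.reindex(hits["orf_id"]).fillna("UNASSIGNED").to_numpy()
    hits["taxon"] = [bin_taxon.get(b, b) for b in bins]
    hits["is_mh"] = [bool(mh_cytc.get(o, False)) for o in hits["orf_id"]]
    out = (
        hits.groupby(["stimulus", "direction", "taxon"])
        .agg(n_genes=("orf_id", "size"), n_mh_cytc=("is_mh", "sum"))
        .reset_index()
    )
    out["n_mh_cytc"] = out["n_mh_cytc"].astype(int)
    return out


# ---------------------------------------------------------------------------
# Ordinations
# ---------------------------------------------------------------------------

@dataclass
class Ordination:
    method: str  # wMDS | wCCA
    points: pd.DataFrame  # rows x 2+ axes
    eigenvalues: np.ndarray = field(default_factory=lambda: np.array([]))
    stress: Optional[float] = None
    arrows: Optional[pd.DataFrame] = None  # variable arrow endpoints
    condition_scores: Optional[pd.DataFrame] = None
    row_weights: Optional[pd.Series] = None
    total_inertia: Optional[float] = None
    constrained_inertia: Optional[float] = None
    unconstrained_inertia: Optional[float] = None
    aliased: List[str] = field(default_factory=list)


def wmds(profiles: pd.DataFrame, weights: Optional[pd.Series] = None,
         dims: int = 2, seed: int = 0, max_iter: int = 500,
         tol: float = 1e-10) -> Ordination:
    """Weighted metric MDS by SMACOF stress majorization.

    ``profiles``: rows (bins) x conditions relative-expression proportions;
    distances are Euclidean between rows.  Per-point weights multiply the
    stress contribution of every pair they participate in (w_ij = w_i w_j).
    Deterministic given the seed; stress is non-increasing by construction.
    """
    n = len(profiles)
    if n < 3:
        raise ValueError("need at least 3 rows for MDS")
    X0 = profiles.to_numpy(dtype=float)
    diff = X0[:, None, :] - X0[None, :, :]
    D = np.sqrt((diff ** 2).sum(-1))
    if weights is None:
        w = np.ones(n)
    else:
        w = weights.reindex(profiles.index).to_numpy(dtype=float)
    w = np.clip(w, 1e-12, None)
    w = w / w.mean()
    W = np.outer(w, w)
    np.fill_diagonal(W, 0.0)

    rng = np.random.default_rng(seed)
    X = rng.normal(scale=D[D > 0].mean() if (D > 0).any() else 1.0,
                   size=(n, dims))
    V = -W.copy()
    np.fill_diagonal(V, W.sum(axis=1))
    Vp = np.linalg.pinv(V)

    def distances(Y):
        d = np.sqrt(((Y[:, None, :] - Y[None, :, :]) ** 2).sum(-1))
        return d

    def stress(Y):
        d = distances(Y)
        return float(0.5 * (W * (d - D) ** 2).sum())

    last = stress(X)
    for _ in range(max_iter):
        d = distances(X)
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(d > 0, D / d, 0.0)
        B = -W * ratio
        np.fill_diagonal(B, 0.0)
        np.fill_diagonal(B, -B.sum(axis=1))
        X = Vp @ (B @ X)
        cur = stress(X)
        if last - cur < tol:
            last = cur
            break
        last = cur
    points = pd.DataFrame(X, index=profiles.index,
                          columns=[f"axis{i + 1}" for i in range(dims)])
    return Ordination(method="wMDS", points=points, stress=last,
                      row_weights=pd.Series(w, index=profiles.index))


def wcca(Y: pd.DataFrame, X: pd.DataFrame,
         row_weights: Optional[pd.Series] = None, scaling: int = 2,
         strict_rank: bool = False) -> Ordination:
    """Weighted canonical correspondence analysis.

    ``Y``: non-negative response matrix, rows = genes (or bins), columns =
    conditions.  ``X``: conditions x indicator/explanatory variables.  Row
    weights multiply each row's mass (chi-square row masses) after
    normalization.  Returns eigenvalues of the constrained axes, gene
    scores, condition (linear-combination) scores and variable arrows
    (weighted correlations of X columns with the axes, rescaled to the
    gene-score cloud).  Axis signs are fixed by making the largest-magnitude
    gene loading positive.

    Indicator designs that are collinear after weighted centering (e.g. a
    complete partition of the conditions) are handled by dropping aliased
    columns with a warning, unless ``strict_rank`` is set.
    """
    Ymat = Y.to_numpy(dtype=float)
    if (Ymat < 0).any():
        raise ValueError("Y must be non-negative")
    keep = Ymat.sum(axis=1) > 0
    if not keep.all():
        logger.info("dropping %d all-zero rows", int((~keep).sum()))
        Y = Y.loc[keep]
        Ymat = Ymat[keep]
    if row_weights is not None:
        w = row_weights.reindex(Y.index).to_numpy(dtype=float)
        if (w < 0).any():
            raise ValueError("row weights must be non-negative")
        w = w / w.sum()
        Ymat = Ymat * w[:, None]

    conditions = list(Y.columns)
    Xmat = X.reindex(conditions).to_numpy(dtype=float)
    var_names = list(X.columns)

    # Correspondence-analysis scaffolding on the transposed table:
    # "sites" are conditions (constrained), "species" are genes.
    M = Ymat.T  # conditions x genes
    total = M.sum()
    if total <= 0:
        raise ValueError("Y has no positive mass")
    P = M / total
    r = P.sum(axis=1)  # condition masses
    c = P.sum(axis=0)  # gene masses
    with np.errstate(divide="ignore", invalid="ignore"):
        Qbar = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Qbar[~np.isfinite(Qbar)] = 0.0
    total_inertia = float((Qbar ** 2).sum())

    # Weighted centering of the constraints, then pivoted-QR alias handling.
    Xc = Xmat - (r @ Xmat)
    Xs = np.sqrt(r)[:, None] * Xc
    q_, r_, piv = _qr_pivot(Xs)
    tol = max(Xs.shape) * np.finfo(float).eps * (abs(r_[0, 0]) if r_.size else 0)
    rank = int((np.abs(np.diag(r_)) > tol).sum()) if r_.size else 0
    aliased = [var_names[j] for j in piv[rank:]]
    if aliased:
        msg = f"collinear constraint columns dropped: {aliased}"
        if strict_rank:
            raise ValueError(msg)
        logger.warning(msg)
    Qproj = q_[:, :rank]
    H = Qproj @ Qproj.T
    Yfit = H @ Qbar

    U, s, Vt = np.linalg.svd(Yfit, full_matrices=False)
    n_axes = int((s > max(s[0], 1e-300) * 1e-12).sum()) if s.size and s[0] > 0 else 0
    n_axes = min(n_axes, rank)
    U, s, Vt = U[:, :n_axes], s[:n_axes], Vt[:n_axes]
    eigenvalues = s ** 2
    constrained = float(eigenvalues.sum())
    unconstrained = float(((Qbar - Yfit) ** 2).sum())

    with np.errstate(divide="ignore", invalid="ignore"):
        gene_scores = (Vt.T / np.sqrt(c)[:, None])
        cond_scores = (U / np.sqrt(r)[:, None])
    if scaling == 2:
        gene_scores = gene_scores * s[None, :]
    else:
        cond_scores = cond_scores * s[None, :]

    # Fix axis signs on the gene loadings.
    for j in range(n_axes):
        i_max = int(np.argmax(np.abs(gene_scores[:, j])))
        if gene_scores[i_max, j] < 0:
            gene_scores[:, j] *= -1
            cond_scores[:, j] *= -1
            U[:, j] *= -1

    # Variable arrows: weighted correlations of X columns with the axes.
    axis_site = cond_scores  # LC scores in site space
    arrows = np.zeros((len(var_names), n_axes))
    for v in range(len(var_names)):
        xv = Xc[:, v]
        for j in range(n_axes):
            arrows[v, j] = _weighted_corr(xv, axis_site[:, j], r)
    # Rescale arrows to the gene-score cloud so midpoints partition it.
    if n_axes and len(gene_scores):
        g_norm = np.sqrt((gene_scores[:, : min(2, n_axes)] ** 2).sum(axis=1)).max()
        a_norm = np.sqrt((arrows[:, : min(2, n_axes)] ** 2).sum(axis=1)).max()
        if a_norm > 0 and g_norm > 0:
            arrows = arrows * (g_norm / a_norm)

    axes = [f"axis{i + 1}" for i in range(n_axes)]
    return Ordination(
        method="wCCA",
        points=pd.DataFrame(gene_scores, index=Y.index, columns=axes),
        eigenvalues=eigenvalues,
        arrows=pd.DataFrame(arrows, index=var_names, columns=axes),
        condition_scores=pd.DataFrame(cond_scores, index=conditions, columns=axes),
        row_weights=None if row_weights is None else pd.Series(
            row_weights.reindex(Y.index)),
        total_inertia=total_inertia,
        constrained_inertia=constrained,
        unconstrained_inertia=unconstrained,
        aliased=aliased,
    )


def _qr_pivot(A: np.ndarray) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    from scipy.linalg import qr

    if A.size == 0:
        return np.zeros((A.shape[0], 0)), np.zeros((0, 0)), np.arange(A.shape[1])
    q, r, piv = qr(A, mode="economic", pivoting=True)
    return q, r, piv


def _weighted_corr(x: np.ndarray, y: np.ndarray, w: np.ndarray) -> float:
    w = w / w.sum()
    mx, my = (w * x).sum(), (w * y).sum()
    cov = (w * (x - mx) * (y - my)).sum()
    vx = (w * (x - mx) ** 2).sum()
    vy = (w * (y - my) ** 2).sum()
    if vx <= 0 or vy <= 0:
        return 0.0
    return float(cov / np.sqrt(vx * vy))


def partition_by_arrow_midpoints(ordination: Ordination,
                                 origin_radius: Optional[float] = None,
                                 ) -> pd.Series:
    """Assign each gene point to the nearest variable-arrow midpoint.

    Midpoint = 0.5 x arrow endpoint in the first two axes.  Points within
    ``origin_radius`` of the origin stay unassigned (default radius: 10% of
    the maximum point norm).  Ties break toward lexicographic variable
    order (logged).
    """
    if ordination.arrows is None or len(ordination.arrows) < 2:
        raise ValueError("ordination must carry at least 2 variable arrows")
    axes = list(ordination.points.columns[:2])
    pts = ordination.points[axes].to_numpy(dtype=float)
    mids = 0.5 * ordination.arrows[axes].to_numpy(dtype=float)
    names = np.array(ordination.arrows.index)
    order = np.argsort(names, kind="stable")  # lexicographic tie priority
    mids, names = mids[order], names[order]
    norms = np.sqrt((pts ** 2).sum(axis=1))
    r0 = origin_radius if origin_radius is not None else 0.1 * norms.max()
    out = []
    for p, nrm in zip(pts, norms):
        if nrm <= r0:
            out.append(None)
            continue
        d = np.sqrt(((mids - p) ** 2).sum(axis=1))
        best = int(np.argmin(d))  # argmin keeps the first (lexicographic) tie
        if (d == d[best]).sum() > 1:
            logger.info("midpoint tie for point at %s; using %s", p, names[best])
        out.append(str(names[best]))
    return pd.Series(out, index=ordination.points.index, dtype=object)


# ---------------------------------------------------------------------------
# Marker panels and heat-map matrix
# ---------------------------------------------------------------------------

def select_marker_genes(expression: pd.DataFrame, labels: pd.Series,
                        conditions: Sequence[str], top_n: int = 50,
                        value_prefix: str = "norm_mrna_") -> pd.DataFrame:
    """Top-N labels (KO groups or cytC families) by summed normalized
    expression across conditions; stable sort, ties by label."""
    cols = [f"{value_prefix}{c}" for c in conditions]
    df = expression.set_index("orf_id")
    lab = labels.reindex(df.index)
    total = df[cols].sum(axis=1, skipna=True)
    summed = total.groupby(lab).sum().reset_index()
    summed.columns = ["label", "summed_expression"]
    summed = summed.sort_values(["summed_expression", "label"],
                                ascending=[False, True], kind="stable")
    if len(summed) < top_n:
        logger.info("only %d labels available (requested %d)", len(summed), top_n)
    return summed.head(top_n).reset_index(drop=True)


def marker_heatmap(expression: pd.DataFrame, labels: pd.Series,
                   conditions: Sequence[str], baseline: str = "con1",
                   fold_flag: float = 2.0) -> pd.DataFrame:
    """mRNA/DNA-ratio matrix (label x condition) with fold-change flags.

    Per label: mean mRNA/DNA ratio per condition; a condition is flagged
    when its ratio changes more than ``fold_flag``-fold against baseline.
    """
    df = expression.set_index("orf_id")
    lab = labels.reindex(df.index)
    rows = []
    for label, idx in df.groupby(lab).groups.items():
        sub = df.loc[idx]
        means = {c: float(np.nanmean(sub[f"ratio_{c}"])) for c in conditions}
        base = means[baseline]
        row = {"label": label}
        for c in conditions:
            row[c] = means[c]
            if base > 0 and means[c] >= 0:
                ratio = means[c] / base if base else np.nan
                row[f"{c}_flag"] = bool(ratio >= fold_flag or
                                        (ratio > 0 and ratio <= 1.0 / fold_flag))
            else:
                row[f"{c}_flag"] = False
        rows.append(row)
    return pd.DataFrame(rows)
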