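"""Responsive-gene rule, taxon tallies, weighted MDS/CCA against
independent eigen-solvers (numpy/scipy and R vegan), arrow-midpoint
partitioning and marker selection."""

import shutil
import subprocess

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh

from stimulomics import simcom, stimresp

DESIGN = simcom.DEFAULT_DESIGN
CONDS = list(DESIGN.condition_ids)


def _expr(values):
    """Expression frame with norm_mrna columns from {orf: [5 values]}."""
    rows = []
    for oid, vals in values.items():
        row = {"orf_id": oid}
        for c, v in zip(CONDS, vals):
            row[f"norm_mrna_{c}"] = v
        rows.append(row)
    return pd.DataFrame(rows)


class TestResponsiveGenes:
    @pytest.mark.parametrize("before,after,expected", [
        (10, 60, "positive"),     # fold 6, gate 60 >= 50
        (60, 10, "negative"),     # symmetric rule
        (10, 45, "none"),         # fold 4.5 < 5
        (5, 40, "none"),          # fold 8 but gate 40 < 50
        (10, 50, "positive"),     # boundaries inclusive
        (0, 60, "positive"),      # zero handled via pseudocount
    ])
    def test_rule(self, before, after, expected):
        expr = _expr({"o1": [before, 0, 0, 0, after]})
        calls = stimresp.responsive_genes(expr, DESIGN)
        call = calls[(calls.orf_id == "o1") & (calls.stimulus == "AcPro")]
        assert call.iloc[0]["direction"] == expected

    def test_oc_compares_con1_vs_con4(self):
        expr = _expr({"o1": [10, 10, 500, 80, 10]})
        calls = stimresp.responsive_genes(expr, DESIGN)
        oc = calls[(calls.orf_id == "o1") & (calls.stimulus == "OC")].iloc[0]
        assert oc["direction"] == "positive"  # 80/10, not 500/10
        assert oc["fold_change"] == pytest.approx(8.0)

    def test_undefined_expression_skipped(self):
        expr = _expr({"o1": [np.nan, 10, 10, 10, 400]})
        calls = stimresp.responsive_genes(expr, DESIGN)
        assert (calls["orf_id"] != "o1").all() or \
            calls[calls.orf_id == "o1"]["stimulus"].tolist() == []


class TestTally:
    def test_counts_and_overlay(self):
        calls = pd.DataFrame({
            "orf_id": [f"o{i}" for i in range(6)],
            "stimulus": ["SP+"] * 5 + ["OC"],
            "direction": ["positive"] * 5 + ["negative"],
            "fold_change": [8.0] * 6, "gating_rpkm": [100.0] * 6})
        bins = pd.Series({f"o{i}": "binA" for i in range(6)})
        tally = stimresp.tally_by_taxon(calls, bins, {"binA": "taxX"},
                                        {"o0": True})
        row = tally[(tally.stimulus == "SP+") &
                    (tally.direction == "positive")].iloc[0]
        assert row["taxon"] == "taxX" and row["n_genes"] == 5
        assert row["n_mh_cytc"] == 1

    def test_empty_calls(self):
        tally = stimresp.tally_by_taxon(
            pd.DataFrame(columns=["orf_id", "stimulus", "direction",
                                  "fold_change", "gating_rpkm"]),
            pd.Series(dtype=object), {})
        assert len(tally) == 0


class TestWmds:
    def test_perfect_embedding_recovers_distances(self, rng):
        pts = rng.normal(size=(7, 2))
        prof = pd.DataFrame(np.hstack([pts, np.zeros((7, 3))]),
                            index=[f"b{i}" for i in range(7)])
        ord_ = stimresp.wmds(prof, seed=0)
        assert ord_.stress < 1e-6
        d_in = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))
        out = ord_.points.to_numpy()
        d_out = np.sqrt(((out[:, None] - out[None]) ** 2).sum(-1))
        assert d_out == pytest.approx(d_in, abs=1e-4)

    def test_identical_profiles_coincide(self):
        prof = pd.DataFrame([[1, 0, 0, 0, 0]] * 2 + [[0, 1, 0, 0, 0]],
                            index=["a", "b", "c"], dtype=float)
        ord_ = stimresp.wmds(prof, seed=1)
        a, b = ord_.points.loc["a"], ord_.points.loc["b"]
        assert np.linalg.norm(a - b) < 1e-4

    def test_heavy_point_reproduced_best(self, rng):
        # a 3-D configuration cannot embed perfectly in 2-D; the heavy
        # point's distances must be reproduced better than the others'.
        pts = rng.normal(size=(8, 3))
        prof = pd.DataFrame(np.hstack([pts, np.zeros((8, 2))]),
                            index=[f"b{i}" for i in range(8)])
        D = np.sqrt(((pts[:, None] - pts[None]) ** 2).sum(-1))

        def per_point_error(weights):
            w = pd.Series(weights, index=prof.index)
            out = stimresp.wmds(prof, weights=w, seed=3).points.to_numpy()
            d = np.sqrt(((out[:, None] - out[None]) ** 2).sum(-1))
            return np.abs(d - D).sum(axis=1)

        heavy = per_point_error([50.0] + [1.0] * 7)
        flat = per_point_error([1.0] * 8)
        assert heavy[0] < flat[0]

    def test_fewer_than_three_rows_raises(self):
        with pytest.raises(ValueError, match="at least 3"):
            stimresp.wmds(pd.DataFrame([[1.0], [2.0]]))

    def test_deterministic_given_seed(self, rng):
        prof = pd.DataFrame(rng.uniform(size=(5, 5)))
        a = stimresp.wmds(prof, seed=9).points
        b = stimresp.wmds(prof, seed=9).points
        pd.testing.assert_frame_equal(a, b)


def cca_eigen_oracle(Y, X, w=None):
    """Independent route: dense generalized eigenproblem."""
    Ym = Y.to_numpy(float).copy()
    if w is not None:
        ww = w.to_numpy(float)
        ww = ww / ww.sum()
        Ym = Ym * ww[:, None]
    M = Ym.T
    P = M / M.sum()
    r, c = P.sum(1), P.sum(0)
    Q = (P - np.outer(r, c)) / np.sqrt(np.outer(r, c))
    Xc = X.to_numpy(float) - (r @ X.to_numpy(float))
    Xs = np.sqrt(r)[:, None] * Xc
    vals = eigh(Xs.T @ Q @ Q.T @ Xs, Xs.T @ Xs, eigvals_only=True)
    return np.sort(vals)[::-1]


class TestWcca:
    def _random(self, rng, n=11):
        Y = pd.DataFrame(rng.uniform(0.1, 10, size=(n, 5)),
                         index=[f"g{i}" for i in range(n)], columns=CONDS)
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=CONDS,
                         columns=["v1", "v2"])
        return Y, X

    def test_eigenvalues_match_generalized_eigenproblem(self, rng):
        for n in (10, 11, 12):
            Y, X = self._random(rng, n)
            w = pd.Series(rng.uniform(0.5, 2, n), index=Y.index)
            res = stimresp.wcca(Y, X, row_weights=w)
            oracle = cca_eigen_oracle(Y, X, w)[: len(res.eigenvalues)]
            assert res.eigenvalues == pytest.approx(oracle, abs=1e-8)

    def test_inertia_decomposition_closes(self, rng):
        Y, X = self._random(rng)
        res = stimresp.wcca(Y, X)
        assert res.constrained_inertia + res.unconstrained_inertia == \
            pytest.approx(res.total_inertia, abs=1e-8)

    def test_eigenvalues_nonnegative_decreasing(self, rng):
        Y, X = self._random(rng)
        ev = stimresp.wcca(Y, X).eigenvalues
        assert (ev >= 0).all()
        assert (np.diff(ev) <= 1e-12).all()

    def test_rank_one_single_variable_fixture(self, rng):
        X = pd.DataFrame({"AcProEET": [0, 0, 0, 0, 1.0]}, index=CONDS)
        Y = pd.DataFrame(np.outer(rng.uniform(1, 5, 10), np.ones(5)),
                         columns=CONDS)
        Y.iloc[:5] *= np.array([1, 1, 1, 1, 8.0])
        res = stimresp.wcca(Y, X)
        assert res.eigenvalues[0] >= 0.99 * res.constrained_inertia

    def test_orthogonal_constraints_give_null_eigenvalues(self, rng):
        # Y varies only between gene groups, identically across conditions
        Y = pd.DataFrame(np.outer(rng.uniform(1, 5, 8), np.ones(5)),
                         columns=CONDS)
        X = pd.DataFrame(rng.normal(size=(5, 2)), index=CONDS)
        res = stimresp.wcca(Y, X)
        assert res.constrained_inertia < 1e-10

    def test_aliased_partition_design_drops_one_column(self, rng):
        X = pd.DataFrame(
            {v: [1.0 if c in conds else 0.0 for c in CONDS]
             for v, conds in DESIGN.variable_map.items()}, index=CONDS)
        Y, _ = self._random(rng)
        res = stimresp.wcca(Y, X)
        assert len(res.aliased) == 1
        assert res.arrows.shape[0] == 3  # arrows still reported for all three
        with pytest.raises(ValueError, match="collinear"):
            stimresp.wcca(Y, X, strict_rank=True)

    def test_negative_y_rejected(self):
        Y = pd.DataFrame(-np.ones((3, 5)), columns=CONDS)
        with pytest.raises(ValueError, match="non-negative"):
            stimresp.wcca(Y, pd.DataFrame(np.eye(5)[:, :2], index=CONDS))

    @pytest.mark.skipif(shutil.which("Rscript") is None,
                        reason="R not available")
    def test_cross_check_against_vegan(self, rng, tmp_path):
        """Unweighted case agrees with the vegan CCA implementation."""
        Y, X = self._random(rng, 8)
        np.savetxt(tmp_path / "Y.csv", Y.to_numpy().T, delimiter=",")
        np.savetxt(tmp_path / "X.csv", X.to_numpy(), delimiter=",")
        r_code = (
            'suppressMessages(library(vegan));'
            f'M <- as.matrix(read.csv("{tmp_path}/Y.csv", header=FALSE));'
            f'X <- as.matrix(read.csv("{tmp_path}/X.csv", header=FALSE));'
            'fit <- cca(M ~ X[,1] + X[,2]);'
            'cat(fit$CCA$eig, sep="\\n")'
        )
        out = subprocess.run(["Rscript", "-e", r_code], capture_output=True,
                             text=True, timeout=120)
        if out.returncode != 0:
            pytest.skip(f"vegan unavailable: {out.stderr[:200]}")
        veig = np.array([float(x) for x in out.stdout.split()])
        res = stimresp.wcca(Y, X)
        assert res.eigenvalues == pytest.approx(veig, abs=1e-6)


class TestPartition:
    def _ordination(self, rng, m=200, effect=10.0):
        labels = rng.choice(list(DESIGN.variable_map), size=m)
        X = pd.DataFrame(
            {v: [1.0 if c in conds else 0.0 for c in CONDS]
             for v, conds in DESIGN.variable_map.items()}, index=CONDS)
        base = rng.uniform(50, 200, size=m)
        Y = np.outer(base, np.ones(5))
        for i, lab in enumerate(labels):
            for j, c in enumerate(CONDS):
                if c in DESIGN.variable_map[lab]:
                    Y[i, j] *= effect
        Y = pd.DataFrame(rng.poisson(Y).astype(float), columns=CONDS,
                         index=[f"g{i}" for i in range(m)])
        return stimresp.wcca(Y, X), labels

    def test_planted_single_variable_genes_recovered(self, rng):
        ord_, labels = self._ordination(rng)
        part = stimresp.partition_by_arrow_midpoints(ord_)
        assigned = part.notna()
        acc = (part[assigned].to_numpy() == labels[assigned]).mean()
        assert acc >= 0.90

    def test_origin_points_unassigned(self, rng):
        ord_, _ = self._ordination(rng, m=50)
        ord_.points.iloc[0] = 0.0  # force a point to the origin
        part = stimresp.partition_by_arrow_midpoints(ord_)
        assert part.iloc[0] is None

    def test_gene_order_permutation_invariant(self, rng):
        ord_, _ = self._ordination(rng, m=50)
        part = stimresp.partition_by_arrow_midpoints(ord_)
        shuffled = stimresp.Ordination(
            method="wCCA", points=ord_.points.iloc[::-1],
            arrows=ord_.arrows, eigenvalues=ord_.eigenvalues)
        part2 = stimresp.partition_by_arrow_midpoints(shuffled)
        pd.testing.assert_series_equal(part.sort_index(), part2.sort_index())

    def test_single_arrow_raises(self, rng):
        ord_, _ = self._ordination(rng, m=20)
        ord_.arrows = ord_.arrows.iloc[:1]
        with pytest.raises(ValueError, match="2 variable arrows"):
            stimresp.partition_by_arrow_midpoints(ord_)


class TestMarkerSelection:
    def test_top_n_by_summed_expression(self):
        expr = _expr({"o1": [50] * 5, "o2": [20] * 5, "o3": [2] * 5})
        labels = pd.Series({"o1": "famA", "o2": "famB", "o3": "famC"})
        top = stimresp.select_marker_genes(expr, labels, CONDS, top_n=2)
        assert list(top["label"]) == ["famA", "famB"]

    def test_boundary_tie_lexicographic(self):
        expr = _expr({"o1": [50] * 5, "o2": [10] * 5, "o3": [10] * 5})
        labels = pd.Series({"o1": "famA", "o2": "famC", "o3": "famB"})
        top = stimresp.select_marker_genes(expr, labels, CONDS, top_n=2)
        assert list(top["label"]) == ["famA", "famB"]

    def test_fewer_labels_than_requested(self):
        expr = _expr({"o1": [1] * 5})
        top = stimresp.select_marker_genes(
            expr, pd.Series({"o1": "famA"}), CONDS, top_n=15)
        assert len(top) == 1

    def test_heatmap_flags_fold_change(self):
        expr = _expr({"o1": [10, 10, 10, 10, 30]})
        for c in CONDS:  # marker_heatmap reads ratio_ columns
            expr[f"ratio_{c}"] = expr[f"norm_mrna_{c}"]
        hm = stimresp.marker_heatmap(expr, pd.Series({"o1": "famA"}), CONDS)
        row = hm.set_index("label").loc["famA"]
        assert bool(row["con5_flag"]) and not bool(row["con2_flag"])
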