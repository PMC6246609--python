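"""Binning: feature extraction, density clustering, TNF refinement,
linkage rescue, completeness/contamination, MAG tiers and composition."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from stimulomics import binning, simcom

CONDS = list(simcom.DEFAULT_DESIGN.condition_ids)


def _counts(d, length=1000):
    return pd.DataFrame([{"contig_id": k, "length": length,
                          **dict(zip(CONDS, v))} for k, v in d.items()])


class TestFeatures:
    def test_gc_of_repeat(self):
        seqs = {"c1": "ATGC" * 250}
        feats = binning.compute_features(seqs, _counts({"c1": [10] * 5}), CONDS)
        assert feats.iloc[0]["gc"] == 0.5

    def test_homopolymer_tnf_mass_on_pooled_entry(self):
        seqs = {"c1": "A" * 1000}
        feats = binning.compute_features(seqs, _counts({"c1": [10] * 5}), CONDS)
        tnf = feats.iloc[0]["tnf"]
        idx_aaaa = 0
        idx_tttt = 255
        assert tnf[idx_aaaa] + tnf[idx_tttt] == pytest.approx(1.0)
        assert tnf.sum() == pytest.approx(1.0, abs=1e-9)

    def test_short_contig_excluded(self, caplog):
        seqs = {"ok": "ACGT" * 200, "tiny": "ACGT" * 100}
        with caplog.at_level("INFO", logger="stimulomics.binning"):
            feats = binning.compute_features(
                seqs, _counts({"ok": [1] * 5, "tiny": [1] * 5}), CONDS)
        assert list(feats["contig_id"]) == ["ok"]
        assert any("excluding contig tiny" in r.message for r in caplog.records)

    def test_zero_length_contig_raises(self):
        with pytest.raises(ValueError, match="zero length"):
            binning.compute_features({"c": ""}, _counts({"c": [1] * 5}), CONDS)

    def test_coverage_is_depth(self):
        # 500 reads x 100 bp over 1000 bp -> mean depth 50
        seqs = {"c1": "ACGT" * 250}
        feats = binning.compute_features(seqs, _counts({"c1": [500] * 5}), CONDS)
        assert feats.iloc[0]["coverage"] == pytest.approx([50.0] * 5)


class TestClustering:
    def test_two_separated_genomes_recovered(self):
        specs = [simcom.GenomeSpec("gA", length=120_000, gc_target=0.35, n_orfs=8),
                 simcom.GenomeSpec("gB", length=120_000, gc_target=0.65, n_orfs=8)]
        depths = {"gA": dict(zip(CONDS, [40.0, 35, 30, 25, 20])),
                  "gB": dict(zip(CONDS, [5.0, 10, 30, 45, 60]))}
        com = simcom.build_community(specs, depths, mean_contig_len=5000, seed=3)
        feats = binning.compute_features(com.contig_seqs,
                                         com.contig_dna_counts, CONDS)
        asg = binning.cluster_bins(feats)
        asg = binning.refine_bins_tnf(asg, feats)
        asg = binning.rescue_by_linkage(asg, com.linkage)
        truth = com.truth["contig_to_genome"]
        big = feats[feats["length"] >= 2000]["contig_id"]
        labels = [asg.labels[c] for c in big]
        assert len(set(labels) - {binning.UNASSIGNED}) == 2
        ari = adjusted_rand_score([truth[c] for c in big], labels)
        assert ari >= 0.95

    def test_single_genome_single_cluster(self):
        g = simcom.build_genome(
            simcom.GenomeSpec("g", length=80_000, gc_target=0.5, n_orfs=6), seed=1)
        contigs, _ = simcom.fragment_to_contigs(g, 5000, seed=2)
        seqs = {c.contig_id: g.seq[c.start: c.end] for c in contigs}
        counts = _counts({c.contig_id: [20.0 * c.length / 100] * 5
                          for c in contigs})
        counts["length"] = [c.length for c in contigs]
        feats = binning.compute_features(seqs, counts, CONDS)
        asg = binning.cluster_bins(feats)
        assert len(asg.bins) == 1

    def test_identical_seed_identical_labels(self):
        g = simcom.build_genome(
            simcom.GenomeSpec("g", length=60_000, gc_target=0.5, n_orfs=6), seed=1)
        contigs, _ = simcom.fragment_to_contigs(g, 4000, seed=2)
        seqs = {c.contig_id: g.seq[c.start: c.end] for c in contigs}
        counts = _counts({c.contig_id: [20.0] * 5 for c in contigs})
        feats = binning.compute_features(seqs, counts, CONDS)
        a = binning.cluster_bins(feats, seed=0)
        b = binning.cluster_bins(feats, seed=0)
        assert a.labels == b.labels


class TestRefineAndRescue:
    def _mixed_assignment(self):
        gA = simcom.build_genome(
            simcom.GenomeSpec("gA", length=100_000, gc_target=0.40, n_orfs=6), seed=1)
        gB = simcom.build_genome(
            simcom.GenomeSpec("gB", length=100_000, gc_target=0.60, n_orfs=6), seed=2)
        seqs, counts = {}, {}
        for g in (gA, gB):
            contigs, _ = simcom.fragment_to_contigs(g, 15_000, seed=3)
            for c in contigs:
                seqs[c.contig_id] = g.seq[c.start: c.end]
                counts[c.contig_id] = [20.0] * 5
        feats = binning.compute_features(seqs, _counts(counts), CONDS)
        labels = {}
        for cid in seqs:
            labels[cid] = "bin_001" if cid.startswith("gA") else "bin_002"
        return feats, labels

    def test_misassigned_contig_demoted(self):
        feats, labels = self._mixed_assignment()
        intruder = next(c for c in labels if c.startswith("gB"))
        labels[intruder] = "bin_001"  # mis-seed a gB contig into the gA bin
        asg = binning.BinAssignment(labels, {c: "primary_cluster" for c in labels})
        refined = binning.refine_bins_tnf(asg, feats, min_corr=0.90)
        assert refined.labels[intruder] == binning.UNASSIGNED

    def test_pure_bins_untouched(self):
        feats, labels = self._mixed_assignment()
        asg = binning.BinAssignment(labels, {c: "primary_cluster" for c in labels})
        refined = binning.refine_bins_tnf(asg, feats, min_corr=0.90)
        assert refined.labels == labels

    def test_vacuous_threshold_changes_nothing(self):
        feats, labels = self._mixed_assignment()
        asg = binning.BinAssignment(labels, {})
        refined = binning.refine_bins_tnf(asg, feats, min_corr=-1.0)
        assert refined.labels == labels

    @pytest.mark.parametrize(
        "links,start,expected",
        [
            ([("x", "a1", 10)], binning.UNASSIGNED, "A"),  # strong single-bin
            ([("x", "a1", 3), ("x", "b1", 3)], binning.UNASSIGNED,
             binning.UNASSIGNED),  # tie
            ([("x", "a1", 2)], binning.UNASSIGNED, binning.UNASSIGNED),  # weak
            ([("x", "b1", 8), ("x", "a1", 2)], "A", "B"),  # 2x pull-over
        ],
    )
    def test_linkage_rescue_rules(self, links, start, expected):
        labels = {"a1": "A", "b1": "B", "x": start}
        linkage = pd.DataFrame(
            [{"contig_a": a, "end_a": "3p", "contig_b": b, "end_b": "5p",
              "n_links": n} for a, b, n in links])
        out = binning.rescue_by_linkage(
            binning.BinAssignment(labels, {}), linkage, min_links=3)
        assert out.labels["x"] == expected


class TestQualityMetrics:
    MARKERS = [f"m{i}" for i in range(107)]

    def _hits(self, marker_copies):
        rows = []
        for m, copies in marker_copies.items():
            for k in range(copies):
                rows.append({"contig_id": "c1", "marker_id": m,
                             "orf_id": f"{m}_{k}"})
        return pd.DataFrame(rows, columns=["contig_id", "marker_id", "orf_id"])

    def test_complete_single_copy(self):
        comp, cont = binning.estimate_completeness(
            ["c1"], self._hits({m: 1 for m in self.MARKERS}), self.MARKERS)
        assert (comp, cont) == (100.0, 0.0)

    def test_half_present(self):
        comp, cont = binning.estimate_completeness(
            ["c1"], self._hits({m: 1 for m in self.MARKERS[:54]}), self.MARKERS)
        assert comp == pytest.approx(50.5, abs=0.05)
        assert cont == 0.0

    def test_triplicated_marker(self):
        copies = {m: 1 for m in self.MARKERS}
        copies[self.MARKERS[0]] = 3
        comp, cont = binning.estimate_completeness(
            ["c1"], self._hits(copies), self.MARKERS)
        assert comp == 100.0
        assert cont == pytest.approx(100 * 2 / 107, abs=0.01)

    def test_empty_expected_set_raises(self):
        with pytest.raises(ValueError, match="empty"):
            binning.estimate_completeness(["c1"], self._hits({}), [])

    @pytest.mark.parametrize(
        "comp,cont,rrnas,trna,tier",
        [
            (95, 2, (True, True, True), 20, "high"),
            (95, 2, (True, False, True), 20, "medium"),  # missing 16S
            (40, 2, (True, True, True), 20, "low"),
            (90, 2, (True, True, True), 20, "medium"),  # boundary: needs > 90
            (91, 5, (True, True, True), 20, "medium"),  # contamination not < 5
            (91, 4.9, (True, True, True), 18, "high"),
            (91, 4.9, (True, True, True), 17, "medium"),  # tRNA below 18
            (50, 9.9, (False, False, False), 0, "medium"),
            (49.9, 2, (True, True, True), 20, "low"),
            (60, 10, (True, True, True), 20, "low"),  # contamination at 10
        ],
    )
    def test_mimag_decision_table(self, comp, cont, rrnas, trna, tier):
        assert binning.classify_mimag(comp, cont, *rrnas, trna) == tier


class TestComposition:
    def _feats(self):
        return pd.DataFrame({
            "contig_id": ["a", "b"],
            "length": [1000, 1000],
            "gc": [0.5, 0.5],
            "coverage": [np.full(5, 30.0), np.full(5, 10.0)],
            "tnf": [np.full(256, 1 / 256)] * 2,
        })

    def test_single_bin_is_one(self):
        asg = binning.BinAssignment({"a": "A", "b": "A"}, {})
        comp = binning.community_composition(asg, self._feats(), "coverage")
        assert comp["A"] == pytest.approx(1.0)

    def test_coverage_weighting(self):
        asg = binning.BinAssignment({"a": "A", "b": "B"}, {})
        comp = binning.community_composition(asg, self._feats(), "coverage")
        assert comp["A"] == pytest.approx(0.75)
        assert comp["B"] == pytest.approx(0.25)

    def test_core_genes_mean_of_marker_shares(self):
        asg = binning.BinAssignment({"a": "A", "b": "B"}, {})
        mc = pd.DataFrame([
            {"marker_id": "m1", "bin": "A", "coverage": 30.0},
            {"marker_id": "m1", "bin": "B", "coverage": 10.0},
            {"marker_id": "m2", "bin": "A", "coverage": 10.0},
            {"marker_id": "m2", "bin": "B", "coverage": 30.0},
            {"marker_id": "m3", "bin": "A", "coverage": 40.0},
        ])
        comp = binning.community_composition(asg, self._feats(), "core_genes",
                                             marker_coverages=mc)
        # mean of per-marker shares: A = (0.75 + 0.25 + 1.0)/3
        assert comp["A"] == pytest.approx((0.75 + 0.25 + 1.0) / 3)
        assert comp.sum() == pytest.approx(1.0)

    def test_missing_marker_table_raises(self):
        asg = binning.BinAssignment({"a": "A", "b": "B"}, {})
        with pytest.raises(ValueError, match="marker"):
            binning.community_composition(asg, self._feats(), "core_genes")

    @pytest.mark.parametrize("method", ["coverage", "raw_reads", "core_genes"])
    def test_compositions_sum_to_one(self, method):
        asg = binning.BinAssignment({"a": "A", "b": binning.UNASSIGNED}, {})
        kw = {}
        if method == "raw_reads":
            kw["mapped_reads"] = pd.DataFrame(
                {"contig_id": ["a", "b"], "reads": [700, 300]})
        if method == "core_genes":
            kw["marker_coverages"] = pd.DataFrame(
                [{"marker_id": "m1", "bin": "A", "coverage": 5.0},
                 {"marker_id": "m1", "bin": "UNASSIGNED", "coverage": 5.0}])
        comp = binning.community_composition(asg, self._feats(), method, **kw)
        assert comp.sum() == pytest.approx(1.0)
        assert (comp >= 0).all()
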