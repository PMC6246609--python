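"""ANIb, TETRA signatures and OCS grouping, checked against per-site
identity and brute-force enumeration oracles."""

import itertools

import numpy as np
import pytest

from stimulomics import simcom, taxgroup


@pytest.fixture(scope="module")
def base_genome():
    return simcom.build_genome(
        simcom.GenomeSpec("gA", length=100_000, gc_target=0.55, n_orfs=8), seed=1)


class TestANIb:
    def test_self_identity_is_exactly_100(self, base_genome):
        res = taxgroup.anib("A", base_genome.seq, "A", base_genome.seq)
        assert res.mean_ani == 100.0
        assert res.ani_qs == res.ani_sq == 100.0

    @pytest.mark.parametrize("divergence", [0.01, 0.02, 0.05, 0.10])
    def test_matches_per_site_identity_oracle(self, base_genome, divergence):
        strain = simcom.derive_strain(base_genome, divergence, seed=17)
        oracle = 100.0 * simcom.pairwise_identity(base_genome.seq, strain.seq)
        res = taxgroup.anib("A", base_genome.seq, "S", strain.seq)
        assert res.mean_ani == pytest.approx(oracle, abs=0.5)

    def test_two_percent_strain_near_98(self, base_genome):
        strain = simcom.derive_strain(base_genome, 0.02, seed=23)
        res = taxgroup.anib("A", base_genome.seq, "S", strain.seq)
        assert res.mean_ani == pytest.approx(98.0, abs=0.3)
        assert res.mean_ani == taxgroup.anib(
            "S", strain.seq, "A", base_genome.seq).mean_ani

    def test_unrelated_genomes_yield_na(self):
        a = simcom.build_genome(
            simcom.GenomeSpec("a", length=20_000, gc_target=0.45, n_orfs=3), seed=5)
        b = simcom.build_genome(
            simcom.GenomeSpec("b", length=20_000, gc_target=0.55, n_orfs=3), seed=6)
        res = taxgroup.anib("a", a.seq, "b", b.seq)
        assert res.mean_ani is None
        assert res.n_fragments_qs == 0

    def test_monotone_in_divergence(self, base_genome):
        anis = []
        for d in (0.01, 0.02, 0.05, 0.10):
            s = simcom.derive_strain(base_genome, d, seed=31)
            anis.append(taxgroup.anib("A", base_genome.seq, "S", s.seq).mean_ani)
        assert anis == sorted(anis, reverse=True)

    def test_short_genome_raises(self, base_genome):
        with pytest.raises(ValueError, match="fragment"):
            taxgroup.anib("A", base_genome.seq, "x", "ACGT" * 100)


def _brute_force_tetra(seq):
    """Direct dict-based count-and-formula oracle."""
    rc = seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]

    def count(s, k):
        out = {}
        for i in range(len(s) - k + 1):
            w = s[i: i + k]
            out[w] = out.get(w, 0) + 1
        return out

    c4, c3, c2 = {}, {}, {}
    for s in (seq, rc):
        for k, store in ((4, c4), (3, c3), (2, c2)):
            for w, n in count(s, k).items():
                store[w] = store.get(w, 0) + n
    bases = "ACGT"
    z = np.zeros(256)
    for i, word in enumerate(
            "".join(p) for p in itertools.product(bases, repeat=4)):
        left, right, mid = word[:3], word[1:], word[1:3]
        if mid not in c2:
            continue
        exp = c3.get(left, 0) * c3.get(right, 0) / c2[mid]
        var = exp * ((c2[mid] - c3.get(left, 0)) * (c2[mid] - c3.get(right, 0))
                     / c2[mid] ** 2)
        if var > 0:
            z[i] = (c4.get(word, 0) - exp) / np.sqrt(var)
    return z


class TestTetra:
    def test_small_fixture_matches_enumeration_oracle(self):
        seq = "ACGTACGGTACCGTATTGCA"
        assert taxgroup.tetra_signature(seq) == pytest.approx(
            _brute_force_tetra(seq), abs=1e-9)

    def test_random_sequences_match_oracle(self, rng):
        for _ in range(5):
            seq = "".join(rng.choice(list("ACGT"), size=500))
            assert taxgroup.tetra_signature(seq) == pytest.approx(
                _brute_force_tetra(seq), abs=1e-9)

    def test_self_correlation_is_one(self, base_genome):
        z = taxgroup.tetra_signature(base_genome.seq)
        assert taxgroup.tetra_correlation(z, z) == pytest.approx(1.0)

    def test_reverse_complement_invariance(self, base_genome):
        z = taxgroup.tetra_signature(base_genome.seq)
        z_rc = taxgroup.tetra_signature(simcom.revcomp(base_genome.seq))
        assert z == pytest.approx(z_rc, abs=1e-9)

    def test_same_model_genomes_correlate_above_cross_model(self, base_genome):
        strain = simcom.derive_strain(base_genome, 0.02, seed=3)
        other = simcom.build_genome(
            simcom.GenomeSpec("o", length=100_000, gc_target=0.35, n_orfs=8),
            seed=4)
        za = taxgroup.tetra_signature(base_genome.seq)
        r_same = taxgroup.tetra_correlation(za, taxgroup.tetra_signature(strain.seq))
        r_cross = taxgroup.tetra_correlation(za, taxgroup.tetra_signature(other.seq))
        assert r_same >= 0.99
        assert r_cross < r_same

    def test_constant_signature_raises(self):
        with pytest.raises(ValueError, match="constant"):
            taxgroup.tetra_correlation(np.zeros(256), np.ones(256))

    def test_empty_sequence_raises(self):
        with pytest.raises(ValueError, match="empty"):
            taxgroup.tetra_signature("")


class TestOCS:
    def _res(self, a, b, ani):
        return taxgroup.ANIResult(a, b, ani, ani, 10, 10)

    def test_both_criteria_required(self):
        bins = ["A", "B", "C"]
        ani = [self._res("A", "B", 98.0), self._res("A", "C", 98.0),
               self._res("B", "C", 98.0)]
        corr = {("A", "B"): 0.995, ("A", "C"): 0.95, ("B", "C"): 0.95}
        groups = taxgroup.group_ocs(bins, ani, corr)
        members = {frozenset(g.members) for g in groups}
        assert members == {frozenset({"A", "B"}), frozenset({"C"})}

    def test_single_linkage_transitivity(self):
        bins = ["A", "B", "C"]
        ani = [self._res("A", "B", 98.0), self._res("B", "C", 98.0),
               self._res("A", "C", 95.0)]
        corr = {("A", "B"): 0.995, ("B", "C"): 0.995, ("A", "C"): 0.995}
        groups = taxgroup.group_ocs(bins, ani, corr)
        assert len(groups) == 1 and sorted(groups[0].members) == ["A", "B", "C"]

    def test_input_order_invariance(self):
        bins = ["A", "B", "C", "D"]
        ani = [self._res("A", "B", 99.0), self._res("C", "D", 99.0)]
        corr = {("A", "B"): 0.999, ("C", "D"): 0.999}
        g1 = taxgroup.group_ocs(bins, ani, corr)
        g2 = taxgroup.group_ocs(bins[::-1], ani[::-1],
                                dict(reversed(list(corr.items()))))
        assert {frozenset(g.members) for g in g1} == \
               {frozenset(g.members) for g in g2}

    def test_na_ani_never_groups(self):
        bins = ["A", "B"]
        ani = [taxgroup.ANIResult("A", "B", None, None, 0, 0)]
        groups = taxgroup.group_ocs(bins, ani, {("A", "B"): 0.999})
        assert len(groups) == 2


class TestPanGenome:
    def _group(self):
        return taxgroup.OCSGroup("OCS_001", ["core", "s1", "s2", "s3"])

    def test_additive_coverage_detected(self):
        cov = {"core": np.array([30.0, 30, 30, 30, 30]),
               "s1": np.array([10.0, 10, 10, 10, 10]),
               "s2": np.array([12.0, 12, 12, 12, 12]),
               "s3": np.array([8.0, 8, 8, 8, 8])}
        links = {("core", "s1"): 10, ("core", "s2"): 8, ("core", "s3"): 6}
        g = taxgroup.detect_pan_genome(self._group(), links, cov)
        assert g.is_pan_genome and g.core == "core"
        assert sorted(g.substrains) == ["s1", "s2", "s3"]

    def test_unlinked_bins_not_flagged(self):
        cov = {"a": np.full(5, 10.0), "b": np.full(5, 10.0)}
        g = taxgroup.detect_pan_genome(
            taxgroup.OCSGroup("OCS_001", ["a", "b"]), {}, cov)
        assert not g.is_pan_genome

    def test_non_additive_coverage_not_flagged(self, caplog):
        cov = {"core": np.full(5, 100.0), "s1": np.full(5, 10.0),
               "s2": np.full(5, 10.0)}
        links = {("core", "s1"): 10, ("core", "s2"): 8}
        with caplog.at_level("WARNING", logger="stimulomics.taxgroup"):
            g = taxgroup.detect_pan_genome(
                taxgroup.OCSGroup("OCS_001", ["core", "s1", "s2"]), links, cov)
        assert not g.is_pan_genome
        assert any("non-additive" in r.message for r in caplog.records)


def test_pairwise_ocs_on_community(small_community):
    """2% strain pair groups into one OCS; distinct genomes stay separate."""
    seqs = {g.name: g.seq for g in small_community.genomes}
    _, _, groups = taxgroup.pairwise_ocs(seqs)
    members = {frozenset(g.members) for g in groups}
    assert frozenset({"gB", "gB2"}) in members
    assert frozenset({"gA"}) in members and frozenset({"gC"}) in members
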