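"""Motif density, prophage-vs-host comparison, host matching."""

import math

import numpy as np
import pytest
from scipy.stats import hypergeom

from metamethyl import phage_host as ph
from metamethyl.io_formats import Region
from metamethyl.motif_model import Motif


class TestMotifDensity:
    def test_prophage_spacing(self):
        """97 sites over a 63 960 bp prophage: one every 659 bp."""
        res = ph.motif_density(97, 63_960)
        assert res.spacing_bp == 659
        assert res.spacing_exact == pytest.approx(63_960 / 97)

    def test_host_spacing_truncated(self):
        """23 sites over 24 047 bp: exact 1045.5, printed 1045."""
        res = ph.motif_density(23, 24_047)
        assert res.spacing_bp == 1045

    def test_zero_count(self):
        res = ph.motif_density(0, 1_000)
        assert res.density_per_bp == 0.0
        assert res.spacing_bp is None
        assert math.isnan(res.spacing_exact)

    def test_density_spacing_reciprocal(self):
        res = ph.motif_density(7, 33_001)
        assert res.density_per_bp * res.spacing_exact == pytest.approx(1.0)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError):
            ph.motif_density(5, 0)


def fisher_two_sided_oracle(c1, l1, c2, l2):
    """Two-sided conditional p by direct hypergeometric enumeration."""
    total = c1 + c2
    rv = hypergeom(l1 + l2, total, l1)
    probs = rv.pmf(np.arange(max(0, total - l2), min(total, l1) + 1))
    p_obs = rv.pmf(c1)
    return float(probs[probs <= p_obs * (1 + 1e-9)].sum())


class TestDensityCompare:
    def test_equal_densities(self):
        ratio, p = ph.density_compare(10, 1_000, 100, 10_000)
        assert ratio == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_both_zero(self):
        ratio, p = ph.density_compare(0, 100, 0, 100)
        assert math.isnan(ratio)
        assert p == 1.0

    def test_swap_inverts_ratio_keeps_p(self):
        r12, p12 = ph.density_compare(50, 9_000, 20, 11_000)
        r21, p21 = ph.density_compare(20, 11_000, 50, 9_000)
        assert r12 == pytest.approx(1 / r21)
        assert p12 == pytest.approx(p21)

    def test_printed_gatc_counts(self):
        """GATC 180x in the 36 496 bp prophage vs 32x in 8 923 bp host."""
        ratio, p = ph.density_compare(180, 36_496, 32, 8_923)
        assert ratio == pytest.approx((180 / 36_496) / (32 / 8_923))
        assert 0.08 <= p <= 0.13

    def test_oracle_agreement_seeded_grid(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            c1 = int(rng.integers(0, 501))
            c2 = int(rng.integers(0, 501))
            if c1 == 0 and c2 == 0:
                continue
            l1 = int(rng.integers(2_000, 50_001))
            l2 = int(rng.integers(2_000, 50_001))
            _, p = ph.density_compare(c1, l1, c2, l2)
            oracle = fisher_two_sided_oracle(c1, l1, c2, l2)
            assert abs(p - oracle) <= 0.01

    def test_planted_depletion_detected(self):
        """rho = 0.5 prophage depletion flagged with the right direction."""
        from metamethyl.motif_model import count_occurrences
        from metamethyl.synthetic_data import simulate_depleted_contig

        rng = np.random.default_rng(21)
        hits = 0
        n_sim = 20
        motif = Motif("GATC", 1, "6mA")
        for _ in range(n_sim):
            seq, region = simulate_depleted_contig(motif, rng=rng)
            phage_seq = seq[region.start:region.end]
            host_seq = seq[:region.start] + seq[region.end:]
            c_phage = count_occurrences(phage_seq, "GATC")
            c_host = count_occurrences(host_seq, "GATC")
            assert c_host >= 100
            ratio, p = ph.density_compare(c_phage, len(region),
                                          c_host, len(host_seq))
            if p < 0.05 and ratio < 1:
                hits += 1
        assert hits >= 0.9 * n_sim


class TestExpectedCount:
    def test_uniform_sequence(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=40_000))
        exp = ph.expected_count("GATC", seq)
        assert exp == pytest.approx(2 * (40_000 - 3) / 256, rel=0.05)

    def test_obs_exp_near_one_on_random_sequence(self):
        from metamethyl.motif_model import count_occurrences
        rng = np.random.default_rng(1)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=60_000,
                                 p=[.3, .2, .2, .3]))
        n = count_occurrences(seq, "GATC")
        assert ph.observed_expected_ratio(n, "GATC", seq) == \
            pytest.approx(1.0, abs=0.2)


class TestRegionDensities:
    def test_host_remainder_accounting(self):
        from metamethyl.motif_model import count_occurrences
        rng = np.random.default_rng(3)
        seq = "".join(rng.choice(np.array(list("ACGT")), size=10_000))
        regions = [Region("c1", 2_000, 5_000, "prophage")]
        table = ph.region_densities({"c1": seq}, regions,
                                    [Motif("GATC", 1, "6mA")])
        by_region = table.set_index("region")
        assert by_region.loc["prophage", "length_bp"] == 3_000
        assert by_region.loc["host_remainder", "length_bp"] == 7_000
        total = count_occurrences(seq, "GATC")
        # boundary-spanning occurrences may be lost, never double-counted
        assert (by_region.loc["prophage", "count_both_strands"]
                + by_region.loc["host_remainder", "count_both_strands"]
                <= total)


class TestMatchHosts:
    def test_subsumption_ranks_true_host_first(self):
        """A phage ACAY profile matches the ACAYNNNNNRTT Type I recogniser."""
        matches = ph.match_hosts(
            {"phage1": {"ACAY"}},
            {"polaribacter": {"ACAYNNNNNRTT"}, "other": {"GATC"}})
        assert matches[0].host_id == "polaribacter"
        assert matches[0].score > 0
        assert matches[1].score == 0.0

    def test_identical_sets_score_one(self):
        (m, *_) = ph.match_hosts({"p": {"GATC", "GANTC"}},
                                 {"h": {"GATC", "GANTC"}})
        assert m.score == pytest.approx(1.0)

    def test_disjoint_sets_score_zero(self):
        (m,) = ph.match_hosts({"p": {"GATC"}}, {"h": {"CCWGG"}})
        assert m.score == 0.0

    def test_empty_profile_skipped(self):
        assert ph.match_hosts({"p": set()}, {"h": {"GATC"}}) == []

    def test_score_symmetric_in_sets(self):
        a, b = {"GATC", "CCWGG"}, {"GATC", "AAGACC"}
        (m1, ) = ph.match_hosts({"p": a}, {"h": b})
        (m2, ) = ph.match_hosts({"p": b}, {"h": a})
        assert m1.score == pytest.approx(m2.score)

    def test_information_weighting(self):
        # a shared specific motif outweighs an unshared degenerate one
        uniform = ph.match_hosts({"p": {"GATC", "NNAN"}}, {"h": {"GATC"}})
        info = ph.match_hosts({"p": {"GATC", "NNAN"}}, {"h": {"GATC"}},
                              weight="information")
        assert info[0].score > uniform[0].score

    def test_unknown_weight_rejected(self):
        with pytest.raises(ValueError):
            ph.match_hosts({"p": {"GATC"}}, {"h": {"GATC"}}, weight="x")
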