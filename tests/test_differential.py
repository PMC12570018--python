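"""KS/BH machinery, promoter windows, and the two differential views."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metamethyl import differential as dm
from metamethyl.io_formats import GeneRecord
from metamethyl.methylome_profile import InstanceProfile
from metamethyl.motif_model import Motif, MotifInstance
from metamethyl.synthetic_data import simulate_instance_profiles

MOTIF = Motif("GATC", 1, "6mA")


def ks_oracle_d(xs, ys):
    """Brute-force ECDF supremum distance over all pooled points."""
    xs, ys = np.asarray(xs, float), np.asarray(ys, float)
    grid = np.concatenate([xs, ys])
    d = 0.0
    for g in grid:
        fx = np.mean(xs <= g)
        fy = np.mean(ys <= g)
        d = max(d, abs(fx - fy))
    return d


def bh_oracle(pvals):
    """Textbook step-up: p(i) * n / i with running minimum from the top."""
    pvals = np.asarray(pvals, float)
    n = len(pvals)
    order = np.argsort(pvals)
    adjusted = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adjusted[i] = running
    return adjusted


class TestKSCompare:
    def test_identical_samples(self):
        assert dm.ks_compare([0.1, 0.5, 0.9], [0.1, 0.5, 0.9]) == (0.0, 1.0)

    def test_disjoint_supports_give_d_one(self):
        d, p = dm.ks_compare([0.1, 0.2, 0.3], [0.7, 0.8, 0.9])
        assert d == 1.0
        assert p < 0.2

    def test_matches_ecdf_oracle(self):
        d, _ = dm.ks_compare([0.1, 0.2, 0.3], [0.2, 0.3, 0.4])
        assert d == pytest.approx(ks_oracle_d([0.1, 0.2, 0.3],
                                              [0.2, 0.3, 0.4]), abs=1e-12)

    def test_oracle_agreement_random(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            xs = rng.random(int(rng.integers(2, 12)))
            ys = rng.random(int(rng.integers(2, 12)))
            d, _ = dm.ks_compare(xs, ys)
            assert d == pytest.approx(ks_oracle_d(xs, ys), abs=1e-12)

    def test_symmetry(self):
        rng = np.random.default_rng(1)
        xs, ys = rng.random(9), rng.random(5)
        assert dm.ks_compare(xs, ys) == dm.ks_compare(ys, xs)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            dm.ks_compare([0.5], [0.1, 0.2])


class TestBHAdjust:
    def test_textbook_example(self):
        assert dm.bh_adjust([0.01, 0.02, 0.04]) == \
            pytest.approx([0.03, 0.03, 0.04])

    def test_single_value(self):
        assert dm.bh_adjust([1.0]) == pytest.approx([1.0])

    def test_adjusted_at_least_raw_and_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 20)))
            adj = dm.bh_adjust(p)
            assert np.all(adj >= p - 1e-15)
            assert adj == pytest.approx(bh_oracle(p), abs=1e-12)

    def test_order_invariance(self):
        p = np.array([0.5, 0.001, 0.2, 0.04])
        perm = np.array([2, 0, 3, 1])
        adj = dm.bh_adjust(p)
        assert dm.bh_adjust(p[perm]) == pytest.approx(adj[perm])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            dm.bh_adjust([0.5, 1.5])


class TestPromoterSubset:
    GENES = [GeneRecord("c", 100, 400, "+", "gp"),
             GeneRecord("d", 100, 400, "-", "gm")]

    def _inst(self, contig, site):
        return MotifInstance(contig, "+", site - 1, site, MOTIF)

    @pytest.mark.parametrize("contig,site,kept", [
        ("c", 50, True),     # in [40, 100)
        ("c", 40, True),     # window start inclusive
        ("c", 39, False),
        ("c", 100, False),   # gene body, not promoter
        ("d", 459, True),    # minus strand: [400, 460)
        ("d", 400, True),
        ("d", 460, False),
    ])
    def test_window_rule(self, contig, site, kept):
        got = dm.promoter_subset([self._inst(contig, site)], self.GENES,
                                 window=60)
        assert (len(got) == 1) is kept

    def test_wider_window(self):
        got = dm.promoter_subset([self._inst("c", 35)], self.GENES, window=70)
        assert len(got) == 1


def _profile(site, counts_by_group):
    """counts_by_group: {group: (cov, nmod)} pooled over one sample each."""
    inst = MotifInstance("c", "+", site - 1, site, MOTIF)
    per_sample = {f"{g}_1": (cov, nmod, nmod / cov)
                  for g, (cov, nmod) in counts_by_group.items()}
    prof = InstanceProfile(inst, per_sample)
    for g, (cov, nmod) in counts_by_group.items():
        prof.group_counts[g] = (cov, nmod)
        prof.group_mean[g] = nmod / cov
        prof.group_se[g] = float("nan")
    return prof


class TestInstanceDifferential:
    def test_no_difference(self):
        df = dm.instance_differential(
            [_profile(5, {"top": (100, 10), "bottom": (100, 10)})])
        assert df["delta"].iloc[0] == pytest.approx(0.0)
        assert df["p_raw"].iloc[0] == pytest.approx(1.0)

    def test_strong_difference_sign_and_p(self):
        """More methylated in top -> negative delta; p near Fisher oracle."""
        df = dm.instance_differential(
            [_profile(5, {"top": (100, 90), "bottom": (100, 10)})])
        assert df["delta"].iloc[0] == pytest.approx(-0.8)
        oracle = stats.fisher_exact([[90, 10], [10, 90]])[1]
        assert oracle < 1e-6
        assert df["p_raw"].iloc[0] < 1e-6

    def test_positive_delta_means_bottom(self):
        df = dm.instance_differential(
            [_profile(5, {"top": (50, 5), "bottom": (50, 40)})])
        assert df["delta"].iloc[0] > 0

    def test_group_swap_negates_delta(self):
        profs = [_profile(5, {"top": (60, 50), "bottom": (80, 20)}),
                 _profile(15, {"top": (40, 4), "bottom": (40, 30)})]
        ab = dm.instance_differential(profs, "top", "bottom")
        ba = dm.instance_differential(profs, "bottom", "top")
        assert ba["delta"].to_numpy() == pytest.approx(-ab["delta"].to_numpy())
        assert ba["p_raw"].to_numpy() == pytest.approx(ab["p_raw"].to_numpy())

    def test_zero_coverage_group_skipped(self):
        prof = _profile(5, {"top": (100, 10)})
        prof.group_counts["bottom"] = (0, 0)
        prof.group_mean["bottom"] = float("nan")
        assert len(dm.instance_differential([prof])) == 0

    def test_gene_annotation(self):
        genes = [GeneRecord("c", 100, 400, "+", "g1")]
        df = dm.instance_differential(
            [_profile(50, {"top": (100, 90), "bottom": (100, 10)})],
            genes=genes)
        assert df["flanking_gene"].iloc[0] == "g1"
        assert bool(df["in_promoter"].iloc[0]) is True


class TestContigDifferential:
    def test_same_group_not_significant(self):
        rng = np.random.default_rng(0)
        profs = simulate_instance_profiles(n_instances=30, rng=rng)
        for p in profs:   # compare the group against itself
            p.group_mean["bottom"] = p.group_mean["top"]
            p.group_se["bottom"] = p.group_se["top"]
        df = dm.contig_differential(profs)
        assert df["d"].iloc[0] == 0.0
        assert not df["significant"].iloc[0]

    def test_insufficient_instances_flagged(self):
        rng = np.random.default_rng(0)
        profs = simulate_instance_profiles(n_instances=5, rng=rng)
        df = dm.contig_differential(profs, min_instances=10)
        assert df["status"].iloc[0] == "insufficient_data"
        assert not df["significant"].iloc[0]

    def test_standard_error_statistic_runs(self):
        rng = np.random.default_rng(0)
        profs = simulate_instance_profiles(n_instances=40, rng=rng)
        df = dm.contig_differential(profs, statistic_kind="standard_error")
        assert df["status"].iloc[0] == "ok"
        assert 0.0 <= df["d"].iloc[0] <= 1.0

    def test_promoter_scope_requires_genes(self):
        with pytest.raises(ValueError):
            dm.contig_differential([], scope="promoter_only")

    def test_shifted_subset_detected(self):
        rng = np.random.default_rng(5)
        profs = simulate_instance_profiles(
            n_instances=100, diff_fraction=0.2, diff_delta=0.3, rng=rng)
        df = dm.contig_differential(profs)
        assert df["significant_05"].iloc[0]


def test_two_proportion_fisher_fallback_small_counts():
    p_ours = dm.two_proportion_test(1, 6, 5, 6)
    p_fisher = stats.fisher_exact([[1, 5], [5, 1]])[1]
    assert p_ours == pytest.approx(p_fisher)
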