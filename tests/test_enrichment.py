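import math
import random

import pytest
from scipy.special import gammaln

from estmir.enrichment import (DEFAULT_THRESHOLDS, TAIL, build_table, format_p,
                               percent, representation_stat, threshold_sweep)
from estmir.simulate import null_enrichment_sim

from conftest import TABLE1_PRINTED_P, printed_tolerance


def logpmf_oracle(m, M, k, K) -> float:
    """Independent log-gamma evaluation of the binomial point mass."""
    q = m / M
    logc = gammaln(K + 1) - gammaln(k + 1) - gammaln(K - k + 1)
    if q in (0.0, 1.0):
        return 0.0 if (k == 0) == (q == 0.0) else -math.inf
    return logc + k * math.log(q) + (K - k) * math.log(1 - q)


class TestRepresentationStat:
    @pytest.mark.parametrize("m,k,expected,direction", [
        (32, 20, "2.0e-4", "over"),    # strong over-representation
        (84, 2, "6.3e-8", "under"),    # strong under-representation
        (1, 0, "0.773", "under"),      # closed form (1 - 1/1929)^497
        (98, 48, "1.1e-5", "over"),
    ])
    def test_published_extremes(self, m, k, expected, direction):
        p, d = representation_stat(m, 1929, k, 497)
        assert p == pytest.approx(float(expected), abs=printed_tolerance(expected))
        assert d == direction

    def test_closed_form_k0(self):
        p, _ = representation_stat(1, 1929, 0, 497)
        assert p == pytest.approx((1 - 1 / 1929) ** 497, rel=1e-12)

    def test_pmf_normalization(self):
        K = 10
        for q_num in (1, 7, 500):
            total = sum(representation_stat(q_num, 1000, k, K)[0]
                        for k in range(K + 1))
            assert total == pytest.approx(1.0, abs=1e-12)

    def test_log_space_stability_large_K(self):
        p, d = representation_stat(10, 1000, 5000, 10**6)
        assert 0 < p <= 1 and math.isfinite(p)

    def test_absent_species_with_matches_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            representation_stat(0, 100, 1, 50)

    def test_matches_loggamma_oracle(self):
        rng = random.Random(5)
        for _ in range(200):
            M = rng.randint(10, 5000)
            m = rng.randint(1, M - 1)
            K = rng.randint(1, 2000)
            k = rng.randint(0, K)
            p, _ = representation_stat(m, M, k, K)
            assert p > 0
            lo = min(logpmf_oracle(m, M, k, K), 0.0)
            if lo > -700:  # below this the exact mass underflows a float
                assert math.log(p) == pytest.approx(lo, abs=1e-9)

    def test_tail_mode_directions(self):
        p_over, d = representation_stat(32, 1929, 20, 497, mode=TAIL)
        assert d == "over" and p_over < 0.01
        p_under, d = representation_stat(84, 1929, 2, 497, mode=TAIL)
        assert d == "under" and p_under < 1e-6


class TestPercent:
    @pytest.mark.parametrize("x,total,expected", [
        (20, 497, 4.0), (48, 497, 9.7), (0, 497, 0.0),
        (43, 497, 8.7), (102, 497, 20.5), (207, 1929, 10.7),
    ])
    def test_published_percentages(self, x, total, expected):
        assert percent(x, total) == expected

    def test_zero_total(self):
        with pytest.raises(ValueError):
            percent(1, 0)


class TestBuildTable:
    def test_full_published_table(self, barley_counts):
        initial, matched = barley_counts
        rows = {r.species: r for r in build_table(initial, matched)}
        assert rows["Triticum aestivum"].M == 1929
        assert rows["Triticum aestivum"].K == 497
        for species, printed in TABLE1_PRINTED_P.items():
            assert rows[species].p_value == pytest.approx(
                float(printed), abs=printed_tolerance(printed)), species

    def test_degenerate_single_species(self):
        rows = build_table({"only": 5}, {"only": 3})
        assert rows[0].p_value == pytest.approx(1.0)
        assert rows[0].direction == "none"

    def test_simulated_counts_match_log_oracle(self, rng):
        initial = {f"sp{i}": rng.randint(1, 200) for i in range(10)}
        M = sum(initial.values())
        matched = {sp: rng.randint(0, min(m, 40)) for sp, m in initial.items()}
        rows = build_table(initial, matched)
        K = sum(matched.values())
        for r in rows:
            expected = math.exp(min(logpmf_oracle(r.m, M, r.k, K), 0.0))
            assert r.p_value == pytest.approx(expected, rel=1e-9)


class TestThresholdSweep:
    def test_published_strictest_threshold(self, barley_counts):
        initial, matched = barley_counts
        sweep = threshold_sweep(build_table(initial, matched))
        assert set(sweep.over[0.001]) == {"Triticum aestivum", "Zea mays"}
        assert set(sweep.under[0.001]) == {"Physcomitrella patens",
                                           "Chlamydomonas reinhardtii"}

    def test_published_loosest_threshold(self, barley_counts):
        initial, matched = barley_counts
        sweep = threshold_sweep(build_table(initial, matched))
        assert set(sweep.over[0.05]) == {
            "Triticum aestivum", "Populus trichocarpa", "Vitis vinifera",
            "Brassica napus", "Sorghum bicolor", "Zea mays",
            "Saccharum officinarum"}
        assert set(sweep.under[0.05]) == {
            "Arabidopsis thaliana", "Oryza sativa", "Glycine max",
            "Physcomitrella patens", "Chlamydomonas reinhardtii"}

    def test_nested_subset_property(self, barley_counts):
        initial, matched = barley_counts
        sweep = threshold_sweep(build_table(initial, matched))
        ordered = sorted(DEFAULT_THRESHOLDS)
        for lo, hi in zip(ordered, ordered[1:]):
            assert set(sweep.over[lo]) <= set(sweep.over[hi])
            assert set(sweep.under[lo]) <= set(sweep.under[hi])

    def test_threshold_one_lists_everything(self, barley_counts):
        initial, matched = barley_counts
        rows = build_table(initial, matched)
        sweep = threshold_sweep(rows, (1.0,))
        assert len(sweep.over[1.0]) + len(sweep.under[1.0]) == \
            sum(r.direction != "none" for r in rows)


class TestNullCalibration:
    def test_tail_mode_rate_bounded(self, barley_counts):
        initial, _ = barley_counts
        out = null_enrichment_sim(initial, K=497, reps=200, alpha=0.05, seed=3)
        bound = 0.05 + 3 * out["mc_se"]
        assert out["empirical_rate"] <= bound

    def test_direction_split_roughly_symmetric(self, barley_counts):
        initial, _ = barley_counts
        out = null_enrichment_sim(initial, K=497, reps=200, seed=9)
        total = out["n_over"] + out["n_under"]
        assert 0.35 < out["n_over"] / total < 0.65


class TestFormatting:
    @pytest.mark.parametrize("p,rendered", [
        (0.0193, "0.019"), (2.01e-4, "2.0e-04"), (0.773, "0.77"),
    ])
    def test_two_significant_digits(self, p, rendered):
        assert format_p(p) == rendered
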