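import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from endresect import (aggregate, bin_endpoints, compare_resection,
                       max_resection, mean_resection, min_resection, preset,
                       simulate_library, truth_hotspots)
from endresect.resection import estimate_resection, side_profile, summarize_resection

from oracles import oracle_max, oracle_mean, oracle_min, random_side_profile


class TestMeanResection:
    def test_delta_distribution(self):
        prof = np.zeros(400)
        prof[99] = 5.0           # all mass in (1-based) bin 100
        assert mean_resection(prof) == pytest.approx(995.0)

    def test_uniform_mass_over_scanned_bins(self):
        prof = np.zeros(400)
        prof[20:400] = 1.0
        assert mean_resection(prof) == pytest.approx(2100.0)

    def test_two_point_average(self):
        prof = np.zeros(400)
        prof[20] = prof[399] = 1.0
        assert mean_resection(prof) == pytest.approx((205 + 3995) / 2)

    def test_first_twenty_bins_never_contribute(self):
        prof = np.zeros(400)
        prof[:20] = 100.0
        assert np.isnan(mean_resection(prof))

    def test_all_zero_side_is_undefined(self):
        assert np.isnan(mean_resection(np.zeros(400)))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.floats(min_value=1e-3, max_value=1e3),
           st.integers(min_value=0, max_value=2**31 - 1))
    def test_scale_invariance(self, c, seed):
        prof = np.random.default_rng(seed).random(400)
        assert mean_resection(c * prof) == pytest.approx(mean_resection(prof),
                                                         rel=1e-9)


class TestMinResection:
    def test_step_profile_boundary_near_the_step(self):
        prof = np.zeros(400)
        prof[60:150] = 10.0       # RPM 10 for 600-1500 bp, 0 inside
        est = min_resection(prof)
        assert abs(est - 600) <= 30   # within one window half-width

    def test_flat_profile_undefined(self):
        assert np.isnan(min_resection(np.full(400, 7.0)))

    def test_empty_profile_undefined(self):
        assert np.isnan(min_resection(np.zeros(400)))


class TestMaxResection:
    def test_triangle_reaching_zero_at_1800(self):
        x = np.arange(300) * 20 + 10.0
        prof = np.clip(100 * (1 - np.abs(x - 900) / 900), 0, None)
        est, bg = max_resection(prof)
        assert bg == 0.0
        assert abs(est - 1800) <= 40  # within one bin of the foot

    def test_profile_below_background_undefined(self):
        prof = np.ones(300)
        prof[250:300] = 5.0           # background region dominates
        est, bg = max_resection(prof)
        assert np.isnan(est) and bg == 5.0

    def test_needs_profile_reaching_6_kb(self):
        with pytest.raises(ValueError):
            max_resection(np.ones(100))


class TestOracleEquivalence:
    """The sliding-window scans must equal exhaustive brute-force evaluation
    on arbitrary profiles (exact equality, NaN included)."""

    @pytest.mark.parametrize("kind", [0, 1, 2, 3])
    def test_min_matches_bruteforce(self, kind, rng):
        for _ in range(40):
            prof = random_side_profile(rng, int(rng.integers(40, 600)), kind)
            a, b = min_resection(prof), oracle_min(prof)
            assert (np.isnan(a) and np.isnan(b)) or a == b

    @pytest.mark.parametrize("kind", [0, 1, 2, 3])
    def test_max_matches_bruteforce(self, kind, rng):
        for _ in range(40):
            prof = random_side_profile(rng, int(rng.integers(300, 600)), kind)
            a, _ = max_resection(prof)
            b = oracle_max(prof)
            assert (np.isnan(a) and np.isnan(b)) or a == b

    def test_mean_matches_direct_weighted_mean(self, rng):
        for _ in range(100):
            prof = rng.random(int(rng.integers(400, 600))) * rng.integers(1, 100)
            assert mean_resection(prof) == pytest.approx(oracle_mean(prof),
                                                         rel=1e-12)


def test_unimodal_profile_orders_min_mode_max(rng):
    """For unimodal synthetic side profiles, min <= argmax <= max."""
    for seed in range(10):
        g = np.random.default_rng(seed)
        mu = g.uniform(800, 2500)
        sd = g.uniform(150, 400)
        x = np.arange(300) * 20 + 10.0
        prof = 1000 * np.exp(-0.5 * ((x - mu) / sd) ** 2)
        prof10 = np.repeat(prof, 2)[:400] / 2  # 10-bp version, same shape
        mn = min_resection(prof10)
        mx, _ = max_resection(prof)
        mode = x[np.argmax(prof)]
        if not np.isnan(mn):
            assert mn <= mode
        if not np.isnan(mx):
            assert mode <= mx


class TestCompare:
    def test_identical_groups_not_significant(self):
        a = np.full(100, 1200.0)
        out = compare_resection(a, a, mu_offset=10)
        assert out["p"] > 0.99

    def test_constant_shift_detected(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1200, 50, size=100)
        out = compare_resection(a, a + 500, mu_offset=10)
        assert out["p"] < 1e-10
        assert out["median_diff"] == pytest.approx(500)

    def test_null_simulation_rarely_rejects(self):
        """B = A + N(0, 5) with mu=10 stays non-significant at alpha=0.01 in
        >= 95% of seeded repeats (n=250)."""
        rejections = 0
        for seed in range(100):
            g = np.random.default_rng(seed)
            a = g.normal(1200, 100, size=250)
            b = a + g.normal(0, 5, size=250)
            if compare_resection(a, b, mu_offset=10)["p"] <= 0.01:
                rejections += 1
        assert rejections <= 5

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            compare_resection(np.array([]), np.array([1.0]))


@pytest.fixture(scope="module")
def wt_and_dmc1_aggregates():
    out = {}
    for name in ("WT", "Dmc1"):
        p = preset(name, n_hotspots=300, n_cells=1500, seed=77)
        track, _ = simulate_library(p)
        hs = truth_hotspots(p)
        out[name] = aggregate(bin_endpoints(track, hs, 6000, 10))
    return out


class TestGenotypeRecovery:
    def test_dmc1_minimum_resection_exceeds_wt_by_about_400(self, wt_and_dmc1_aggregates):
        diffs = []
        for side in ("left", "right"):
            vals = {}
            for name, agg in wt_and_dmc1_aggregates.items():
                n = len(agg.offsets) // 2
                prof = agg.top[n:] if side == "right" else agg.bottom[:n][::-1]
                vals[name] = min_resection(prof)
            diffs.append(vals["Dmc1"] - vals["WT"])
        assert 250 <= np.mean(diffs) <= 550


def test_estimate_resection_table_and_summary():
    p = preset("WT", n_hotspots=20, n_cells=60, seed=2)
    track, _ = simulate_library(p)
    hs = truth_hotspots(p)
    m10 = bin_endpoints(track, hs, 4000, 10)
    m20 = bin_endpoints(track, hs, 6000, 20)
    table = estimate_resection(m10, m20)
    assert len(table) == 40 and set(table["side"]) == {"left", "right"}
    defined = table["mean_resection"].dropna()
    assert ((defined > 210) & (defined < 4000)).all()
    summary = summarize_resection(table)
    assert summary.loc["mean_resection", "n_defined"] == len(defined)
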