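import logging

import numpy as np
import pandas as pd
import pytest
from scipy import special, stats

from seqrecog.errors import InvalidInputError
from seqrecog.window_stats import (
    WindowActivity,
    behavioral_correlation,
    contrast_map,
    correlation_map,
    grouped_correlation_maps,
    subaverage_windows,
)
from seqrecog.windows import N_WINDOWS, window_sample_indices


def _wa_from_diff(diff, novel=None):
    """WindowActivity whose memorized-minus-novel equals ``diff`` in every
    window (participants x voxels)."""
    n, v = diff.shape
    data = np.zeros((n, v, N_WINDOWS, 2))
    data[:, :, :, 0] = diff[:, :, None]
    if novel is not None:
        data[:, :, :, 0] += novel[:, :, None]
        data[:, :, :, 1] = novel[:, :, None]
    return WindowActivity(data=data, polarity_rule="signed")


class TestSubaverage:
    def test_constant_timecourse_gives_constant_windows(self):
        tc = np.ones((4, 188))
        out = subaverage_windows(
            {"memorized": tc, "novel": 2 * tc}, fs=150.0, t0_ms=0.0
        )
        assert np.allclose(out[:, :, 0], 1.0)
        assert np.allclose(out[:, :, 1], 2.0)

    def test_linear_ramp_windows_hit_midpoints(self):
        fs = 1000.0
        t = np.arange(1250)  # ms
        tc = np.tile(t.astype(float), (2, 1))
        out = subaverage_windows({"memorized": tc, "novel": tc}, fs=fs, t0_ms=0.0)
        midpoints = [125.0, 375.0, 625.0, 875.0, 1125.0]
        for w, mid in enumerate(midpoints):
            assert out[0, w, 0] == pytest.approx(mid, abs=1000.0 / fs / 2 + 1e-9)

    def test_150hz_window_samples_partition_first_188(self):
        times = np.arange(188) * 1000.0 / 150.0
        idx = [window_sample_indices(times, w) for w in range(1, 6)]
        assert [len(i) for i in idx] == [38, 37, 38, 37, 38]
        assert np.array_equal(np.concatenate(idx), np.arange(188))

    def test_short_timecourse_rejected(self):
        tc = np.ones((1, 100))
        with pytest.raises(InvalidInputError):
            subaverage_windows({"memorized": tc, "novel": tc}, fs=150.0, t0_ms=0.0)

    def test_rectified_takes_absolute_value_before_averaging(self):
        tc = -np.ones((2, 188))
        out = subaverage_windows(
            {"memorized": tc, "novel": tc}, fs=150.0, t0_ms=0.0,
            polarity_rule="rectified",
        )
        assert np.allclose(out, 1.0)


class TestContrast:
    def test_identical_conditions_give_zero_map(self, rng):
        act = rng.standard_normal((10, 50))
        wa = _wa_from_diff(np.zeros((10, 50)), novel=act)
        sm = contrast_map(wa, 3)
        assert np.allclose(sm.values, 0.0)
        assert sm.df == 9

    def test_swapping_conditions_flips_sign(self, rng):
        diff = rng.standard_normal((12, 30))
        wa = _wa_from_diff(diff)
        swapped = WindowActivity(data=wa.data[:, :, :, ::-1].copy())
        assert np.allclose(
            contrast_map(wa, 2).values, -contrast_map(swapped, 2).values
        )

    def test_planted_effect_matches_noncentral_t_expectation(self, rng):
        """diff ~ N(0.8, 1) at n = 70: E[t] = 0.8 sqrt(70) c4 ~ 6.77
        (closed-form noncentral-t mean oracle)."""
        n, v, d = 70, 600, 0.8
        diff = d + rng.standard_normal((n, v))
        sm = contrast_map(_wa_from_diff(diff), 1)
        c4 = np.sqrt((n - 1) / 2.0) * np.exp(
            special.gammaln((n - 2) / 2.0) - special.gammaln((n - 1) / 2.0)
        )
        oracle = d * np.sqrt(n) * c4
        assert oracle == pytest.approx(6.7, abs=0.15)  # sanity on the oracle itself
        assert sm.values.mean() == pytest.approx(oracle, abs=0.15)

    def test_null_tail_calibration_at_alpha_001(self, rng):
        n, v = 30, 50_000
        sm = contrast_map(_wa_from_diff(rng.standard_normal((n, v))), 1)
        crit = stats.t.ppf(1 - 0.0005, n - 1)
        frac = np.mean(np.abs(sm.values) > crit)
        assert 0.0004 < frac < 0.002

    def test_zero_variance_voxel_flagged_not_nan(self):
        diff = np.zeros((8, 3))
        diff[:, 1] = 1.0  # constant difference: sd = 0
        sm = contrast_map(_wa_from_diff(diff), 1)
        assert np.isfinite(sm.values).all()
        assert sm.flags[1] and sm.values[1] == 0.0

    def test_too_few_participants_rejected(self):
        with pytest.raises(InvalidInputError):
            contrast_map(_wa_from_diff(np.zeros((2, 5))), 1)


def _cov(wm, group=None, n_correct=None):
    n = len(wm)
    return pd.DataFrame(
        {
            "participant_id": [f"s{i}" for i in range(n)],
            "wm_score": wm,
            "group": group if group is not None else ["musician"] * n,
            "n_correct": n_correct if n_correct is not None else np.arange(n),
        }
    )


class TestCorrelation:
    def test_proportional_difference_gives_r_one(self, rng):
        wm = rng.uniform(80, 120, 20)
        diff = np.outer(wm, np.full(5, 2.0)) + 3.0
        sm = correlation_map(_wa_from_diff(diff), _cov(wm), 4)
        assert np.allclose(sm.values, 1.0, atol=1e-10)
        assert sm.df == 18

    def test_planted_r_within_fisher_interval(self, rng):
        """population r = 0.6 at n = 70: sample r in [0.42, 0.74] with ~95%
        coverage (Fisher-z oracle)."""
        lo, hi = np.tanh(np.arctanh(0.6) + np.array([-1.96, 1.96]) / np.sqrt(67))
        assert lo == pytest.approx(0.42, abs=0.01)
        assert hi == pytest.approx(0.74, abs=0.01)
        hits = 0
        for seed in range(10):
            r = np.random.default_rng(seed)
            wm = r.standard_normal(70)
            diff = (0.6 * wm[:, None] + 0.8 * r.standard_normal((70, 40))) / 1.0
            sm = correlation_map(_wa_from_diff(diff), _cov(wm), 1)
            hits += lo < sm.values.mean() < hi
        assert hits >= 9

    def test_affine_wm_rescaling_invariance(self, rng):
        wm = rng.uniform(80, 120, 25)
        diff = rng.standard_normal((25, 12))
        a = correlation_map(_wa_from_diff(diff), _cov(wm), 2).values
        b = correlation_map(_wa_from_diff(diff), _cov(3.7 * wm + 11.0), 2).values
        assert np.allclose(a, b, atol=1e-12)

    def test_constant_wm_rejected(self, rng):
        diff = rng.standard_normal((10, 4))
        with pytest.raises(InvalidInputError):
            correlation_map(_wa_from_diff(diff), _cov(np.full(10, 100.0)), 1)


class TestBehavioral:
    def test_perfect_linear_relation(self):
        wm = np.arange(20, dtype=float)
        r, p = behavioral_correlation(_cov(wm, n_correct=(2 * wm + 5).astype(int)))
        assert r == pytest.approx(1.0)
        assert p < 1e-12

    def test_independent_covariates_null_band(self):
        """|r| < 0.31 in ~99% of draws at n = 71 (t-transform null oracle:
        P = 2 * sf(0.31 * sqrt(69 / (1 - 0.31^2))) ~ 0.008)."""
        hits = 0
        for seed in range(20):
            g = np.random.default_rng(100 + seed)
            df = _cov(g.standard_normal(71), n_correct=g.integers(150, 240, 71))
            r, _ = behavioral_correlation(df)
            hits += abs(r) < 0.31
        assert hits >= 18

    def test_too_few_participants_rejected(self):
        with pytest.raises(InvalidInputError):
            behavioral_correlation(_cov(np.array([1.0, 2.0, 3.0])))


class TestGrouped:
    def test_single_group_matches_ungrouped(self, rng):
        wm = rng.uniform(80, 120, 16)
        diff = rng.standard_normal((16, 9))
        wa = _wa_from_diff(diff)
        cov = _cov(wm)
        maps = grouped_correlation_maps(wa, cov, 3)
        assert list(maps) == ["musician"]
        assert np.allclose(maps["musician"].values, correlation_map(wa, cov, 3).values)

    def test_small_group_skipped_with_warning(self, rng, caplog):
        wm = rng.uniform(80, 120, 10)
        group = ["musician"] * 8 + ["nonmusician"] * 2
        wa = _wa_from_diff(rng.standard_normal((10, 6)))
        with caplog.at_level(logging.WARNING, logger="seqrecog.window_stats"):
            maps = grouped_correlation_maps(wa, _cov(wm, group=group), 1)
        assert "nonmusician" not in maps and "musician" in maps
        assert any("skipped" in r.message for r in caplog.records)

    def test_group_specific_coupling_lands_in_own_voxels(self, rng):
        n = 40
        wm = rng.uniform(80, 120, n)
        z = (wm - wm.mean()) / wm.std()
        group = np.array(["musician"] * 20 + ["nonmusician"] * 20)
        diff = 0.3 * rng.standard_normal((n, 40))
        diff[group == "musician", :10] += 2.0 * z[group == "musician", None]
        diff[group == "nonmusician", 10:20] += 2.0 * z[group == "nonmusician", None]
        maps = grouped_correlation_maps(
            _wa_from_diff(diff), _cov(wm, group=group), 2
        )
        for gname, own in (("musician", slice(0, 10)), ("nonmusician", slice(10, 20))):
            sig = maps[gname].p_values() < 0.025
            assert sig[own].mean() > 0.8
            other = np.ones(40, bool)
            other[own] = False
            assert sig[other].mean() < 0.2
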