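import numpy as np
import pytest

from molconn.kinetics import (BPSeries, DynamicImage, FrameSchedule,
                              RegionalTimeSeries, discard_and_detrend,
                              framewise_bpnd, static_uptake)
from molconn.simulate import SimulationConfig, simulate_reference_tac


def _ts(values, region_ids, t=None):
    values = np.asarray(values, float)
    if t is None:
        t = np.arange(values.shape[1]) + 0.5
    return RegionalTimeSeries(values=values, region_ids=region_ids,
                              frame_mid_min=t)


class TestFramewiseBPND:
    def test_region_equal_to_reference_gives_zero(self):
        ref = np.linspace(1, 3, 10)
        bp = framewise_bpnd(_ts([ref, ref], ["a", "Cer"]))
        assert np.allclose(bp.values, 0.0)
        assert bp.region_ids == ["a"]

    def test_triple_activity_gives_bp_two(self):
        ref = np.linspace(1, 3, 10)
        bp = framewise_bpnd(_ts([3 * ref, ref], ["a", "Cer"]))
        assert np.allclose(bp.values, 2.0)

    def test_scale_invariance(self, rng):
        vals = rng.uniform(1, 5, size=(4, 12))
        ids = ["a", "b", "c", "Cer"]
        bp1 = framewise_bpnd(_ts(vals, ids))
        bp2 = framewise_bpnd(_ts(7.3 * vals, ids))
        assert np.allclose(bp1.values, bp2.values, atol=1e-12)

    def test_nonpositive_reference_names_frame(self):
        ref = np.ones(5)
        ref[3] = 0.0
        with pytest.raises(ValueError, match=r"frame\(s\) \[3\]"):
            framewise_bpnd(_ts([2 * np.ones(5), ref], ["a", "Cer"]))

    def test_equilibrium_estimate_covers_planted_value(self, rng):
        """Time-mean BP under 5% frame noise stays within the Monte-Carlo
        interval of the planted value (independent resimulation)."""
        planted, n_frames, noise = 1.5, 60, 0.05
        ref0 = 10.0
        estimates = []
        for _ in range(500):
            ref = ref0 * (1 + noise * rng.standard_normal(n_frames))
            tgt = ref0 * (1 + planted) * (1 + noise * rng.standard_normal(n_frames))
            estimates.append((tgt / ref - 1).mean())
        lo, hi = np.percentile(estimates, [2.5, 97.5])
        assert lo < planted * (1 + noise ** 2) < hi  # ratio bias ~ planted*noise^2
        assert np.mean(estimates) == pytest.approx(planted, rel=0.02)


class TestDetrend:
    def _piecewise(self, t, knots, values):
        return np.interp(t, knots, values)

    def test_exact_piecewise_linear_input_leaves_zero_residual(self):
        t = np.arange(80) + 0.5
        knots = np.array([20.5, 40.5, 60.5, 79.5])
        row = self._piecewise(t, knots, [1.0, 3.0, 2.0, 4.0])
        bp = BPSeries(values=np.vstack([row, -2 * row]), region_ids=["a", "b"],
                      frame_mid_min=t)
        out = discard_and_detrend(bp)
        assert np.abs(out.values).max() < 1e-9

    def test_idempotent(self, rng):
        t = np.arange(80) + 0.5
        vals = rng.normal(size=(3, 80)) + np.linspace(0, 2, 80)
        bp = BPSeries(values=vals, region_ids=list("abc"), frame_mid_min=t)
        once = discard_and_detrend(bp)
        twice = discard_and_detrend(once)
        assert np.abs(twice.values - once.values).max() < 1e-8

    def test_discards_first_20_minutes(self, rng):
        t = np.arange(80) + 0.5
        bp = BPSeries(values=rng.normal(size=(2, 80)), region_ids=["a", "b"],
                      frame_mid_min=t)
        out = discard_and_detrend(bp)
        assert out.frame_mid_min[0] >= 20.0
        assert out.retained_window_min[0] == 20.0
        assert np.allclose(out.values.mean(axis=1), 0.0, atol=1e-12)

    def test_ramp_plus_sine_preserves_sine(self):
        """The linear-spline trend absorbs the ramp while the 10-min sine
        survives: residual correlates > 0.95 with an independently fitted
        sine residual."""
        t = np.arange(80) + 0.5
        ramp = 0.05 * t
        sine = np.sin(2 * np.pi * t / 10.0)
        bp = BPSeries(values=(ramp + sine)[None, :], region_ids=["a"],
                      frame_mid_min=t)
        out = discard_and_detrend(bp)
        keep = t >= 20
        # independent oracle: least-squares linear spline on the same knots
        tk = t[keep]
        knots = np.array([20.5, 40.5, 60.5, 79.5])
        design = np.column_stack([
            np.clip(1 - np.abs(tk - k) / 20.0, 0, 1) for k in knots[1:-1]
        ] + [np.clip((knots[1] - tk) / 20.0, 0, 1),
             np.clip((tk - knots[-2]) / (knots[-1] - knots[-2]), 0, 1)])
        coef, *_ = np.linalg.lstsq(design, (ramp + sine)[keep], rcond=None)
        oracle = (ramp + sine)[keep] - design @ coef
        r = np.corrcoef(out.values[0], sine[keep])[0, 1]
        r_oracle = np.corrcoef(out.values[0], oracle - oracle.mean())[0, 1]
        assert r > 0.95
        assert r_oracle > 0.999

    def test_per_segment_variant_also_flattens_piecewise_input(self):
        t = np.arange(80) + 0.5
        row = self._piecewise(t, [20.5, 40.5, 60.5, 79.5], [1.0, 3.0, 2.0, 4.0])
        bp = BPSeries(values=row[None, :], region_ids=["a"], frame_mid_min=t)
        out = discard_and_detrend(bp, continuous=False)
        assert np.abs(out.values).max() < 1e-9


class TestStaticUptake:
    def _img(self, data):
        return DynamicImage(data=data, voxel_size_mm=(1, 1, 1), modality="PET",
                            timing=FrameSchedule.uniform(data.shape[3]))

    def test_constant_image_normalizes_to_one(self):
        img = self._img(np.full((3, 3, 3, 80), 2.0))
        out = static_uptake(img, (50, 60))
        assert np.allclose(out.data, 1.0)

    def test_window_50_60_sums_exactly_10_frames(self):
        data = np.ones((2, 2, 2, 80))
        out = static_uptake(self._img(data), (50, 60), normalization="none")
        assert np.allclose(out.data, 10.0)

    def test_matches_frame_loop_oracle(self, rng):
        data = rng.normal(size=(3, 2, 2, 80))
        out = static_uptake(self._img(data), (30, 40), normalization="none")
        mid = np.arange(80) + 0.5
        oracle = sum(data[..., f] for f in range(80) if 30 <= mid[f] < 40)
        assert np.allclose(out.data, oracle, atol=1e-12)

    def test_additive_over_disjoint_windows(self, rng):
        data = rng.uniform(1, 2, size=(2, 2, 2, 80))
        img = self._img(data)
        a = static_uptake(img, (30, 40), normalization="none").data
        b = static_uptake(img, (40, 50), normalization="none").data
        both = static_uptake(img, (30, 50), normalization="none").data
        assert np.allclose(a + b, both, atol=1e-12)

    def test_empty_window_errors(self):
        with pytest.raises(ValueError, match="no frame"):
            static_uptake(self._img(np.ones((2, 2, 2, 80))), (90, 95))


class TestReferenceTac:
    def test_plateau_is_stable_after_40_minutes(self):
        cfg = SimulationConfig(n_subjects=1)
        t = np.arange(0, 80, 0.5) + 0.25
        curve = simulate_reference_tac(cfg, t)
        late = curve[t >= 40]
        deriv = np.abs(np.diff(late)) / 0.5
        assert deriv.max() < 0.01 * curve[-1]
        drift = (late.max() - late.min()) / late[-1]
        assert drift < 0.05

    def test_linear_in_infusion_rate(self):
        t = np.arange(80) + 0.5
        c1 = simulate_reference_tac(SimulationConfig(infusion_rate=1.0), t)
        c2 = simulate_reference_tac(SimulationConfig(infusion_rate=2.0), t)
        assert np.allclose(c2, 2 * c1, rtol=1e-12)

    def test_zero_bolus_is_monotone_without_overshoot(self):
        t = np.arange(80) + 0.5
        curve = simulate_reference_tac(SimulationConfig(k_bol_min=0.0), t)
        assert np.all(np.diff(curve) > 0)
        assert curve.max() == curve[-1]
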