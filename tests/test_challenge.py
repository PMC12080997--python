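import numpy as np
import pytest
from scipy import stats

from molconn.challenge import (bp_change_vs_mc_change, detect_displacement_onset,
                               effect_tmap, regional_effect_scores,
                               regional_mc_change_tscores)
from molconn.connectivity import subject_connectome
from molconn.kinetics import StaticImage


def _static(data, window=(30, 40), norm="whole_brain_mean"):
    return StaticImage(data=np.asarray(data, float), window_min=window,
                       normalization=norm)


class TestEffectTmap:
    def test_identical_groups_give_zero_t(self, rng):
        imgs = [_static(rng.uniform(1, 2, (4, 4, 2))) for _ in range(5)]
        emap = effect_tmap(imgs, list(imgs))
        assert np.allclose(emap.t_volume, 0.0)
        assert not emap.fwe_mask.any()

    def test_antisymmetric_under_group_swap(self, rng):
        a = [_static(rng.normal(1, 0.1, (3, 3, 2))) for _ in range(6)]
        b = [_static(rng.normal(1.2, 0.1, (3, 3, 2))) for _ in range(6)]
        fwd = effect_tmap(a, b)
        rev = effect_tmap(b, a)
        assert np.allclose(fwd.t_volume, -rev.t_volume, atol=1e-12)

    def test_unnormalized_input_rejected(self, rng):
        good = [_static(rng.normal(size=(2, 2, 2))) for _ in range(3)]
        bad = [_static(rng.normal(size=(2, 2, 2)), norm="none") for _ in range(3)]
        with pytest.raises(ValueError, match="normalized"):
            effect_tmap(good, bad)

    def test_paired_variant_uses_within_subject_differences(self, rng):
        base = [_static(rng.normal(1, 0.2, (2, 2, 2))) for _ in range(8)]
        post = [_static(b.data - 0.3, window=(50, 60)) for b in base]
        emap = effect_tmap(base, post, paired=True)
        # constant within-subject shift: paired t is huge everywhere
        assert np.all(np.abs(emap.t_volume) > 100)

    def test_records_contrast_windows(self, rng):
        a = [_static(rng.normal(1, 0.1, (2, 2, 2)), window=(30, 40))
             for _ in range(3)]
        b = [_static(rng.normal(1, 0.1, (2, 2, 2)), window=(50, 60))
             for _ in range(3)]
        emap = effect_tmap(a, b)
        assert emap.windows == ((30, 40), (50, 60))


class TestRegionalScores:
    def test_constant_t_inside_region(self, toy_atlas):
        t_vol = np.zeros(toy_atlas.shape)
        t_vol[toy_atlas.label_volume == 5] = 2.0
        from molconn.challenge import EffectMap
        emap = EffectMap(t_volume=t_vol, contrast="x", fwe_mask=t_vol > 99,
                         alpha=0.05, mask=toy_atlas.mask())
        df = regional_effect_scores(emap, toy_atlas)
        assert len(df) == 48
        row = df[df.position == 5].iloc[0]
        assert row.mean_t == pytest.approx(2.0)
        assert row.sd_t == pytest.approx(0.0)

    def test_matches_voxel_loop_oracle(self, toy_atlas, rng):
        from molconn.challenge import EffectMap
        t_vol = rng.normal(size=toy_atlas.shape)
        emap = EffectMap(t_volume=t_vol, contrast="x", fwe_mask=t_vol > 99,
                         alpha=0.05, mask=toy_atlas.mask())
        df = regional_effect_scores(emap, toy_atlas)
        for pos in (1, 30, 47):
            idx = np.argwhere(toy_atlas.label_volume == pos)
            vals = [t_vol[i, j, k] for i, j, k in idx]
            row = df[df.position == pos].iloc[0]
            assert row.mean_t == pytest.approx(np.mean(vals), abs=1e-12)
            assert row.sd_t == pytest.approx(np.std(vals), abs=1e-12)


class TestMCChange:
    def test_planted_reduction_gives_negative_t(self, rng):
        n_sub, n_reg, n_t = 8, 10, 60
        base, post = [], []
        for _ in range(n_sub):
            shared = rng.normal(size=n_t)
            x = shared[None, :] + 0.5 * rng.normal(size=(n_reg, n_t))
            base.append(subject_connectome(x))
            y = 0.3 * shared[None, :] + rng.normal(size=(n_reg, n_t))
            post.append(subject_connectome(y))
        df = regional_mc_change_tscores(base, post)
        assert (df.mc_t < 0).all()

    def test_identical_connectomes_give_zero_t(self, rng):
        conns = [subject_connectome(rng.normal(size=(6, 30))) for _ in range(4)]
        df = regional_mc_change_tscores(conns, conns)
        assert np.allclose(df.mc_t, 0.0)


class TestBPvsMC:
    def test_identical_vectors_give_r_one(self, rng):
        v = rng.normal(size=48)
        r, table = bp_change_vs_mc_change(v, v)
        assert r == pytest.approx(1.0)
        assert len(table) == 48

    def test_independent_patterns_weakly_correlated(self, rng):
        """Null calibration: with independent 48-region vectors the sample r
        concentrates as the exact null predicts (sd = 1/sqrt(n-1))."""
        rs = np.array([bp_change_vs_mc_change(rng.normal(size=48),
                                              rng.normal(size=48))[0]
                       for _ in range(200)])
        # exact null: P(|r| < 0.2) = 2*Phi(0.2*sqrt(47)) - 1 ~ 0.83
        expected = 2 * stats.norm.cdf(0.2 * np.sqrt(47)) - 1
        assert abs((np.abs(rs) < 0.2).mean() - expected) < 0.08
        assert np.abs(rs).mean() < 0.2
        assert abs(rs.mean()) < 0.05


class TestOnsetDetection:
    def _curve(self, onset, amplitude, noise_sd, rng, tau=10 / np.log(20)):
        t = np.arange(80) + 0.5
        y = 2.0 * np.ones_like(t)
        after = t >= onset
        y[after] -= amplitude * (1 - np.exp(-(t[after] - onset) / tau))
        return t, y + noise_sd * rng.standard_normal(t.size)

    def test_clean_curve_onset_found_within_one_frame(self, rng):
        t, y = self._curve(40.0, 0.8, 0.0, rng)
        onset = detect_displacement_onset(t, y, (25, 40), n_sd=1e9,
                                          plateau_window_min=(65, 80))
        assert onset == pytest.approx(40.5, abs=1.0)

    def test_fractional_threshold_is_amplitude_invariant(self, rng):
        t, big = self._curve(40.0, 1.0, 0.01, rng)
        t, small = self._curve(50.0, 0.25, 0.01, rng)
        on_big = detect_displacement_onset(t, big, (25, 40),
                                           plateau_window_min=(65, 80))
        on_small = detect_displacement_onset(t, small, (25, 40),
                                             plateau_window_min=(65, 80))
        assert on_small - on_big == pytest.approx(10.0, abs=1.0)

    def test_flat_curve_returns_nan(self, rng):
        t = np.arange(80) + 0.5
        y = 1.0 + 0.01 * rng.standard_normal(80)
        onset = detect_displacement_onset(t, y, (25, 40), n_sd=6.0)
        assert np.isnan(onset)
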