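"""dF/F chain, response quantification and descriptive summaries."""
import warnings

import numpy as np
import pytest

from mbflex import imaging
from mbflex.types import (
    Epoch,
    ResponseWindow,
    StimulusSchedule,
    TrialTensor,
    window_frames,
)


def simple_tensor(values, rate=10.0, kind="raw", labels=None, background=0.0,
                  subtracted=False):
    values = np.asarray(values, dtype=float)
    return TrialTensor(
        values=values, frame_rate_hz=rate, kind=kind,
        trial_labels=labels or ["A"] * values.shape[2],
        background=background, background_subtracted=subtracted,
    )


def pulse_schedule(n_trials=1, onset=8.0, dur=5.0, label="A"):
    return StimulusSchedule(
        trials=[(Epoch(label, onset, onset + dur),)] * n_trials,
        labels=[label] * n_trials,
    )


class TestBackgroundSubtraction:
    def test_constant_field(self):
        t = simple_tensor(np.full((2, 10, 1), 5.0), background=1.0)
        out = imaging.subtract_background(t)
        assert np.all(out.values == 4.0)
        assert out.background_subtracted

    def test_zero_background_is_identity(self):
        t = simple_tensor(np.full((1, 4, 1), 3.0), background=0.0)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            with pytest.raises(UserWarning):
                # background == min fluorescence triggers the negative-F warning
                imaging.subtract_background(
                    simple_tensor(np.zeros((1, 4, 1)), background=0.0)
                )
        out = imaging.subtract_background(t)
        np.testing.assert_array_equal(out.values, t.values)

    def test_double_application_rejected(self):
        t = simple_tensor(np.full((1, 4, 1), 3.0), background=1.0)
        once = imaging.subtract_background(t)
        with pytest.raises(ValueError, match="already subtracted"):
            imaging.subtract_background(once)

    def test_dff_input_rejected(self):
        t = simple_tensor(np.zeros((1, 4, 1)), kind="dff")
        with pytest.raises(ValueError):
            imaging.subtract_background(t)


class TestDff:
    def make_raw(self, baseline_val, response_val, rate=10.0):
        # 8 s baseline then 5 s "response"
        vals = np.full((1, 160, 1), float(baseline_val))
        vals[:, 80:130, :] = response_val
        return simple_tensor(vals, rate=rate, subtracted=True)

    def test_flat_trace_gives_zero(self):
        t = self.make_raw(2.0, 2.0)
        d = imaging.compute_dff(t, pulse_schedule())
        np.testing.assert_allclose(d.values, 0.0)

    def test_printed_formula_value(self):
        # F_i = 3 against baseline F_0 = 2 -> dF/F = 0.5
        t = self.make_raw(2.0, 3.0)
        d = imaging.compute_dff(t, pulse_schedule())
        assert d.values[0, 100, 0] == pytest.approx(0.5)

    def test_joint_scale_invariance(self):
        t1 = self.make_raw(2.0, 3.0)
        t2 = t1.replace(values=t1.values * 7.5)
        d1 = imaging.compute_dff(t1, pulse_schedule())
        d2 = imaging.compute_dff(t2, pulse_schedule())
        np.testing.assert_allclose(d1.values, d2.values)

    def test_baseline_window_averages_to_zero(self, small_kc):
        _, tensor, schedule, _ = small_kc
        d = imaging.compute_dff(imaging.subtract_background(tensor), schedule)
        for trial in (0, tensor.n_trials - 1):
            onset = schedule.first_onset(trial)
            lo, hi = window_frames(onset - 8.0, onset, d.frame_rate_hz, d.n_frames)
            np.testing.assert_allclose(
                d.values[:, lo:hi, trial].mean(axis=1), 0.0, atol=1e-12
            )

    def test_nonpositive_baseline_lists_offenders(self):
        t = self.make_raw(0.0, 1.0)
        with pytest.raises(ValueError, match=r"\(0, 0\)"):
            imaging.compute_dff(t, pulse_schedule())

    def test_requires_background_subtraction(self):
        t = self.make_raw(2.0, 3.0).replace(background_subtracted=False)
        with pytest.raises(ValueError, match="background"):
            imaging.compute_dff(t, pulse_schedule())


class TestBoxcar:
    def test_constant_unchanged(self):
        x = np.full(50, 3.3)
        np.testing.assert_allclose(imaging.boxcar_filter(x, 10.0), x)

    def test_impulse_spreads_to_half_height_plateau(self):
        # 0.2 s at 10 Hz = 2 frames: an impulse becomes a 2-frame h/2 plateau
        x = np.zeros(30)
        x[10] = 4.0
        f = imaging.boxcar_filter(x, 10.0, width_s=0.2)
        np.testing.assert_allclose(f[10:12], 2.0)
        assert np.all(f[:10] == 0) and np.all(f[12:] == 0)

    def test_interior_mass_preserved(self):
        x = np.zeros(30)
        x[15] = 4.0
        f = imaging.boxcar_filter(x, 10.0, width_s=0.2)
        assert f.sum() == pytest.approx(x.sum())

    def test_subframe_width_rejected(self):
        with pytest.raises(ValueError):
            imaging.boxcar_filter(np.zeros(5), 10.0, width_s=0.05)


class TestResponseAmplitude:
    def test_constant_window(self):
        vals = np.zeros((1, 200, 1))
        vals[:, 80:160, :] = 0.4
        t = simple_tensor(vals, kind="dff")
        tab = imaging.response_amplitude(t, pulse_schedule(), "first",
                                         ResponseWindow(0.0, 8.0))
        assert tab["amplitude"].iloc[0] == pytest.approx(0.4)

    def test_linear_ramp_averages_to_half(self):
        vals = np.zeros((1, 200, 1))
        vals[0, 80:160, 0] = np.linspace(0.0, 1.0, 80)
        t = simple_tensor(vals, kind="dff")
        tab = imaging.response_amplitude(t, pulse_schedule(), "first",
                                         ResponseWindow(0.0, 8.0))
        assert tab["amplitude"].iloc[0] == pytest.approx(0.5, abs=1.0 / 80)

    def test_depression_ratio_recovered_from_generator(self, mbon_clean,
                                                       mbon_schedule):
        cfg, pre, post, _ = mbon_clean
        w = ResponseWindow()
        ratios = {}
        for name, raw in (("pre", pre), ("post", post)):
            d = imaging.compute_dff(imaging.subtract_background(raw),
                                    mbon_schedule)
            ratios[name] = imaging.response_amplitude(
                d, mbon_schedule, "first", w,
                trials=mbon_schedule.trials_for("A"),
            )["amplitude"].mean()
        assert ratios["post"] / ratios["pre"] == pytest.approx(0.30, abs=1e-6)

    def test_raw_tensor_rejected(self):
        t = simple_tensor(np.zeros((1, 100, 1)))
        with pytest.raises(ValueError):
            imaging.response_amplitude(t, pulse_schedule())


class TestTransitionContrast:
    def transition(self, first_vals, second_vals):
        vals = np.zeros((1, 250, 1))
        vals[0, 80:130, 0] = first_vals
        vals[0, 130:180, 0] = second_vals
        sched = StimulusSchedule(
            trials=[(Epoch("A", 8.0, 13.0), Epoch("A_prime", 13.0, 18.0))],
            labels=["A>A_prime"],
        )
        return simple_tensor(vals, kind="dff", labels=["A>A_prime"]), sched

    def test_direct_formula(self):
        t, sched = self.transition(0.1, 0.9)
        assert imaging.transition_contrast(t, sched, 0) == pytest.approx(0.8)

    def test_flat_trace_zero(self):
        t, sched = self.transition(0.0, 0.0)
        assert imaging.transition_contrast(t, sched, 0) == pytest.approx(0.0)

    def test_offset_invariance(self):
        t, sched = self.transition(0.1, 0.9)
        shifted = t.replace(values=t.values + 5.0)
        assert imaging.transition_contrast(shifted, sched, 0) == pytest.approx(
            imaging.transition_contrast(t, sched, 0)
        )

    def test_non_transition_trial_rejected(self):
        vals = np.zeros((1, 200, 1))
        t = simple_tensor(vals, kind="dff")
        with pytest.raises(ValueError, match="not a transition"):
            imaging.transition_contrast(t, pulse_schedule(), 0)


class TestTrialAverageSorted:
    def test_single_trial_averaging_is_identity_and_order(self):
        vals = np.zeros((2, 200, 1))
        vals[0, 80:130, 0] = 0.1   # low responder
        vals[1, 80:130, 0] = 0.9   # high responder
        t = simple_tensor(vals, kind="dff")
        averages, order = imaging.trial_average_sorted(t, pulse_schedule(), "A")
        np.testing.assert_array_equal(order, [1, 0])
        np.testing.assert_allclose(averages["A"], vals[[1, 0], :, 0])

    def test_cell_permutation_leaves_row_content_invariant(self, rng):
        vals = rng.normal(size=(6, 200, 2)).cumsum(axis=1) * 0.01
        vals[:, :80, :] = 0.0
        t = simple_tensor(vals, kind="dff", labels=["A", "A"])
        sched = pulse_schedule(2)
        avg1, order1 = imaging.trial_average_sorted(t, sched, "A")
        perm = rng.permutation(6)
        t2 = t.replace(values=vals[perm])
        avg2, order2 = imaging.trial_average_sorted(t2, sched, "A")
        np.testing.assert_allclose(avg1["A"], avg2["A"])
        np.testing.assert_array_equal(perm[order2], order1)


class TestPca:
    def eig_oracle(self, X):
        """Brute-force covariance eigen-decomposition."""
        Xc = X - X.mean(axis=0)
        cov = Xc.T @ Xc / len(X)
        w, v = np.linalg.eigh(cov)
        comps = v[:, np.argsort(w)[::-1][:2]].T
        return Xc, comps

    @pytest.mark.parametrize("shape", [(5, 4), (10, 10), (8, 3)])
    def test_matches_eigendecomposition_oracle(self, shape, rng):
        X = rng.normal(size=shape)
        coords, comps = imaging.pca_project(X)
        Xc, oracle = self.eig_oracle(X)
        for k in range(2):
            dot = abs(np.dot(comps[k], oracle[k]))
            assert dot == pytest.approx(1.0, abs=1e-8)
            np.testing.assert_allclose(
                np.abs(coords[:, k]), np.abs(Xc @ oracle[k]), atol=1e-8
            )

    def test_duplicated_trials_project_identically(self, rng):
        X = rng.normal(size=(4, 6))
        X2 = np.vstack([X, X])
        coords, _ = imaging.pca_project(X2)
        np.testing.assert_allclose(coords[:4], coords[4:], atol=1e-10)

    def test_projection_variance_bounded(self, rng):
        X = rng.normal(size=(12, 7))
        coords, _ = imaging.pca_project(X)
        assert coords.var(axis=0).sum() <= X.var(axis=0).sum() + 1e-10

    def test_cluster_geometry_preserved(self, rng):
        a = rng.normal(size=(10, 20)) * 0.1
        b = rng.normal(size=(10, 20)) * 0.1 + 2.0
        coords, _ = imaging.pca_project(np.vstack([a, b]))
        ca, cb = coords[:10].mean(0), coords[10:].mean(0)
        within = np.linalg.norm(coords[:10] - ca, axis=1).mean()
        assert np.linalg.norm(ca - cb) > within

    def test_rank_deficient_warns_and_zeroes_second_axis(self):
        X = np.outer(np.arange(5.0), np.ones(3))
        with pytest.warns(UserWarning, match="rank"):
            coords, _ = imaging.pca_project(X)
        np.testing.assert_allclose(coords[:, 1], 0.0)

    def test_agrees_with_sklearn(self, rng):
        sklearn = pytest.importorskip("sklearn.decomposition")
        X = rng.normal(size=(15, 9))
        coords, _ = imaging.pca_project(X)
        ref = sklearn.PCA(n_components=2).fit_transform(X)
        for k in range(2):
            np.testing.assert_allclose(
                np.abs(coords[:, k]), np.abs(ref[:, k]), atol=1e-8
            )


class TestOdorResponseCorrelation:
    def test_identical_and_negated_vectors(self, rng):
        v = rng.normal(size=20)
        assert imaging.odor_response_correlation(v, v)[0] == pytest.approx(1.0)
        assert imaging.odor_response_correlation(v, -v)[0] == pytest.approx(-1.0)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            imaging.odor_response_correlation(np.ones(5), np.arange(5.0))

    def test_too_few_cells_rejected(self):
        with pytest.raises(ValueError):
            imaging.odor_response_correlation(np.arange(2.0), np.arange(2.0))
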