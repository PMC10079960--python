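"""Encoding model: splines, design matrix, CV folding, FVE, lambda rule."""

import numpy as np
import pytest

from helpers import make_session
from revenc.choice_models import LatentSeries
from revenc.encoding import (EncodingConfig, SplineBasisSpec,
                             build_design_matrix, build_spline_basis,
                             compute_fve, default_predictor_specs,
                             extract_kernel, fit_encoding, make_cv_folds,
                             spline_knots, tuning_index)
from revenc.neural_sim import (sample_ground_truth, synthesize_head_velocity,
                               synthesize_trace)


def cox_de_boor(x, t, i, k):
    """Textbook recursive B-spline evaluation, the independent oracle."""
    if k == 0:
        # right-closed at the final knot so the last basis reaches 1
        if t[i] <= x < t[i + 1] or (x == t[-1] and t[i] < t[i + 1]
                                    and t[i + 1] == t[-1]):
            return 1.0
        return 0.0
    left = 0.0
    if t[i + k] > t[i]:
        left = (x - t[i]) / (t[i + k] - t[i]) * cox_de_boor(x, t, i, k - 1)
    right = 0.0
    if t[i + k + 1] > t[i + 1]:
        right = (t[i + k + 1] - x) / (t[i + k + 1] - t[i + 1]) * \
            cox_de_boor(x, t, i + 1, k - 1)
    return left + right


class TestSplineBasis:
    def test_partition_of_unity_inside_window(self):
        spec = SplineBasisSpec(window=(-1.0, 2.0), n_basis=7)
        lags, B = build_spline_basis(spec)
        np.testing.assert_allclose(B.sum(axis=1), 1.0, atol=1e-12)

    def test_zero_outside_window(self):
        spec = SplineBasisSpec(window=(-1.0, 2.0), n_basis=7)
        _, B = build_spline_basis(spec, np.array([-1.5, 2.5, 100.0]))
        assert np.all(B == 0.0)

    def test_matches_cox_de_boor_oracle(self):
        spec = SplineBasisSpec(window=(-1.0, 2.0), n_basis=6)
        t = spline_knots(spec)
        assert len(t) == spec.n_basis + 4
        xs = np.linspace(-1.0, 2.0, 23)
        _, B = build_spline_basis(spec, xs)
        expected = np.array([[cox_de_boor(x, t, i, 3)
                              for i in range(spec.n_basis)] for x in xs])
        np.testing.assert_allclose(B, expected, atol=1e-12)

    def test_too_few_bases_rejected(self):
        with pytest.raises(ValueError):
            SplineBasisSpec(window=(0.0, 1.0), n_basis=3)

    def test_inverted_window_rejected(self):
        with pytest.raises(ValueError):
            SplineBasisSpec(window=(2.0, -1.0), n_basis=5)


def _zero_latents(n):
    z = np.zeros(n)
    return LatentSeries(q_left=z, q_right=z, dq=z, sq=z, rpe=z)


class TestDesignMatrix:
    def test_event_columns_local_to_event_window(self):
        s = make_session(["left"], ["reward"], trial_spacing=40.0)
        frames = np.arange(0.0, 30.0, 0.05)
        d = build_design_matrix(s, frames, latents=_zero_latents(1))
        cols = d.columns_for(["o_plus"])
        active = np.any(d.X[:, cols] != 0, axis=1)
        # outcome at t=2.5, window [-0.5, 6]
        assert np.all(frames[active] >= 2.0 - 1e-9)
        assert np.all(frames[active] <= 8.5 + 1e-9)

    def test_value_columns_step_exactly_at_outcome(self):
        s = make_session(["left", "right", "left"],
                         ["reward", "none", "reward"], trial_spacing=10.0)
        lat = LatentSeries(q_left=np.array([0.0, 0.5, 0.2]),
                           q_right=np.array([0.0, 0.0, 0.3]),
                           dq=np.array([0.0, 0.5, -0.1]),
                           sq=np.array([0.0, 0.5, 0.5]),
                           rpe=np.array([1.0, -0.5, 0.8]))
        frames = np.arange(0.0, 30.0, 0.05)
        d = build_design_matrix(s, frames, latents=lat)
        dq_col = d.X[:, d.columns_for(["dq"])[0]]
        # outcomes at 2.5, 12.5, 22.5; value switches to the next trial's
        # pre-choice value at each outcome
        assert np.all(dq_col[frames < 2.5] == 0.0)
        seg2 = (frames >= 2.5) & (frames < 12.5)
        assert np.all(dq_col[seg2] == 0.5)
        seg3 = (frames >= 12.5) & (frames < 22.5)
        assert np.all(dq_col[seg3] == -0.1)
        # constant within every trial span between outcomes
        for seg in (seg2, seg3):
            assert len(np.unique(dq_col[seg])) == 1

    def test_hand_built_session_matches_cell_by_cell_construction(self):
        s = make_session(["left", "right", "left"],
                         ["reward", "punish", "none"], trial_spacing=12.0)
        lat = LatentSeries(q_left=np.array([0.1, 0.2, 0.3]),
                           q_right=np.array([0.0, 0.4, 0.1]),
                           dq=np.array([0.1, -0.2, 0.2]),
                           sq=np.array([0.1, 0.6, 0.4]),
                           rpe=np.array([0.9, -0.4, -0.1]))
        frames = np.arange(0.0, 36.0, 0.05)
        d = build_design_matrix(s, frames, latents=lat)
        # independent construction: loop over events and bases
        spec_by_name = {sp.name: sp for sp in d.specs}
        events = {
            "cue": [(0.0, 1), (12.0, 1), (24.0, 1)],
            "init": [(1.0, 1), (13.0, 1), (25.0, 1)],
            "choice": [(2.0, 1), (14.0, 1), (26.0, 1)],
            "o_plus": [(2.5, 1)],
            "o_minus": [(14.5, 1), (26.5, 1)],
            "ch_o_plus": [(2.5, -1)],
            "ch_o_minus": [(14.5, 1), (26.5, -1)],
            "rpe_plus": [(2.5, 0.9), (14.5, 0.0), (26.5, 0.0)],
            "rpe_minus": [(2.5, 0.0), (14.5, 0.4), (26.5, 0.1)],
        }
        for name, evs in events.items():
            spec = spec_by_name[name]
            cols = d.columns_for([name])
            expected = np.zeros((len(frames), len(cols)))
            for t_ev, amp in evs:
                lags = frames - t_ev
                m = (lags >= spec.basis.window[0]) & \
                    (lags <= spec.basis.window[1])
                _, B = build_spline_basis(spec.basis, lags[m])
                expected[m] += amp * B
            np.testing.assert_allclose(d.X[:, cols], expected, atol=1e-12,
                                       err_msg=name)

    def test_missing_latents_rejected(self):
        s = make_session(["left"], ["reward"])
        with pytest.raises(ValueError):
            build_design_matrix(s, np.arange(0.0, 10.0, 0.05), latents=None)


class TestComputeFve:
    def test_perfect_and_mean_predictions(self):
        y = np.array([1.0, 2.0, 3.0, 4.0])
        assert compute_fve(y, y) == 1.0
        assert compute_fve(np.full(4, y.mean()), y) == 0.0

    def test_hand_arithmetic(self):
        y = np.array([0.0, 1.0, 2.0])
        pred = np.array([0.0, 1.0, 1.0])
        # var(resid)=var([0,0,1])=2/9, var(y)=2/3
        assert compute_fve(pred, y) == pytest.approx(1 - (2 / 9) / (2 / 3))

    def test_zero_variance_is_undefined(self):
        assert np.isnan(compute_fve(np.zeros(5), np.ones(5)))


@pytest.fixture(scope="module")
def fitted_neuron(encoding_session):
    session, bfit, hv = encoding_session
    gt = sample_ground_truth(tuning_profile="reward_brief", seed=2,
                             noise_sigma=0.15)
    trace, design = synthesize_trace(session, gt, bfit.latents,
                                     head_velocity=hv, seed=3)
    fit = fit_encoding(design, trace, EncodingConfig(n_folds=50, seed=0))
    return gt, trace, design, fit


class TestCvFolds:
    def test_chunks_never_split_and_folds_balanced(self, fitted_neuron):
        _, _, design, fit = fitted_neuron
        folds = fit.fold_id
        for ck in np.unique(design.chunk_id):
            assert len(np.unique(folds[design.chunk_id == ck])) == 1
        counts = np.bincount(folds)
        assert np.all(np.abs(counts - counts.mean()) <= 0.2 * counts.mean())

    def test_trials_spread_across_folds(self, fitted_neuron):
        _, _, design, fit = fitted_neuron
        # every trial with >= n_folds chunks appears in most folds
        n_folds = len(np.unique(fit.fold_id))
        for tr in np.unique(design.trial_id):
            m = design.trial_id == tr
            n_chunks = len(np.unique(design.chunk_id[m]))
            if n_chunks >= n_folds:
                assert len(np.unique(fit.fold_id[m])) == n_folds

    def test_fold_assignment_deterministic(self, fitted_neuron):
        _, _, design, _ = fitted_neuron
        a = make_cv_folds(design, 50, seed=4)
        b = make_cv_folds(design, 50, seed=4)
        np.testing.assert_array_equal(a, b)


class TestFitEncoding:
    def test_one_se_rule_holds_by_construction(self, fitted_neuron):
        _, _, _, fit = fitted_neuron
        best = int(np.nanargmax(fit.cv_fve_mean))
        sel = int(np.nonzero(fit.lambda_path == fit.lambda_selected)[0][0])
        n_folds = len(np.unique(fit.fold_id))
        threshold = fit.cv_fve_mean[best] - \
            fit.cv_fve_sd[best] / np.sqrt(n_folds)
        assert fit.lambda_selected >= fit.lambda_path[best]
        assert fit.cv_fve_mean[sel] >= threshold
        # largest such lambda on the descending path
        assert np.all(fit.cv_fve_mean[:sel] < threshold)

    def test_pure_noise_trace_has_no_explainable_variance(
            self, encoding_session):
        session, bfit, hv = encoding_session
        gt = sample_ground_truth(tuning_profile="untuned", seed=5,
                                 noise_sigma=0.2)
        trace, design = synthesize_trace(session, gt, bfit.latents,
                                         head_velocity=hv, seed=6)
        fit = fit_encoding(design, trace, EncodingConfig(n_folds=20, seed=0))
        assert fit.fve <= 0.01

    def test_heavy_penalty_shrinks_all_coefficients(self, fitted_neuron):
        gt, trace, design, _ = fitted_neuron
        cfg = EncodingConfig(n_folds=20, n_lambda=5, lambda_min_ratio=0.9,
                             seed=0)
        # a path confined near lambda_max: the model is essentially the
        # intercept and cross-validated FVE cannot be positive
        fit = fit_encoding(design, trace, cfg)
        assert np.count_nonzero(fit.coef) <= 2
        assert fit.fve <= 0.01

    def test_misaligned_trace_rejected(self, fitted_neuron):
        _, trace, design, _ = fitted_neuron
        with pytest.raises(ValueError, match="aligned"):
            fit_encoding(design, trace.values[:-10])


class TestTuning:
    def test_dropping_nothing_gives_zero_index(self, fitted_neuron):
        _, trace, design, fit = fitted_neuron
        res = tuning_index(fit, design, trace, [])
        assert res.index == 0.0 and not res.tuned

    def test_unknown_predictor_rejected(self, fitted_neuron):
        _, trace, design, fit = fitted_neuron
        with pytest.raises(ValueError, match="unknown"):
            tuning_index(fit, design, trace, ["bogus"])


class TestExtractKernel:
    def test_zero_coefficients_give_zero_kernel(self, fitted_neuron):
        _, _, design, fit = fitted_neuron
        import copy
        f0 = copy.deepcopy(fit)
        f0.coef = np.zeros_like(f0.coef)
        k = extract_kernel(f0, "o_plus")
        assert np.all(k.values == 0.0)
        assert k.lags[0] == pytest.approx(-0.5)
        assert k.lags[-1] == pytest.approx(6.0)

    def test_continuous_predictor_rejected(self, fitted_neuron):
        _, _, _, fit = fitted_neuron
        with pytest.raises(ValueError, match="continuous"):
            extract_kernel(fit, "dq")
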