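"""Model zoo, cross-validated fitting, selection, LLR."""

import numpy as np
import pytest

from ringdrift.environment import (TrialRecord, generate_synthetic_subject,
                                   make_experiment_session)
from ringdrift.fitting import (BOUNDS, FitResult, MODEL_NAMES, crossval_fit, get_model,
                               mse_score, sample_parameter_sets, select_model,
                               simulate_model_responses, static_landscape, trial_llr)
from ringdrift.landscapes import landscape_gradient
from ringdrift.ring import circ_diff


class TestModelZoo:
    def test_eight_models_with_expected_arity(self):
        arity = {"Flat": 1, "StaticHet": 3, "OffsetHet": 4, "DualHet": 5,
                 "LearnTargetFlatPrior": 3, "LearnTargetHetPrior": 3,
                 "LearnTDFlatPrior": 3, "LearnTDHetPrior": 3}
        assert set(MODEL_NAMES) == set(arity)
        for name, k in arity.items():
            assert get_model(name).n_free == k

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            get_model("Cubic")

    def test_static_landscape_attractor_at_assigned_offset(self):
        spec = static_landscape(get_model("StaticHet"),
                                {"sigma": 0.05, "A_p": 1.0, "n": 4}, assigned_offset=0.37)
        assert landscape_gradient(spec, 0.37) == pytest.approx(0.0, abs=1e-12)


class TestParameterSampling:
    def test_flat_samples_only_sigma_in_bounds(self):
        sets = sample_parameter_sets(get_model("Flat"), 50, seed=0)
        assert all(set(p) == {"sigma"} for p in sets)
        assert all(0.01 <= p["sigma"] <= 0.2 for p in sets)

    def test_statichet_integer_wells(self):
        sets = sample_parameter_sets(get_model("StaticHet"), 50, seed=1)
        for p in sets:
            assert isinstance(p["n"], int) and 1 <= p["n"] <= 12
            assert 0.1 <= p["A_p"] <= 2.0

    def test_different_seeds_differ(self):
        a = sample_parameter_sets(get_model("StaticHet"), 1, seed=2)[0]
        b = sample_parameter_sets(get_model("StaticHet"), 1, seed=3)[0]
        assert a != b

    def test_reproducible(self):
        a = sample_parameter_sets(get_model("DualHet"), 5, seed=4)
        b = sample_parameter_sets(get_model("DualHet"), 5, seed=4)
        assert a == b


def _const_session(n, target, delay_s=0.5, distractor=1.0):
    cls = "short" if delay_s == 0.5 else "long"
    return [TrialRecord(i, cls, delay_s, target, distractor, False, False)
            for i in range(n)]


class TestSimulateResponses:
    def test_flat_zero_noise_returns_targets(self):
        trials = _const_session(5, 0.8)
        out = simulate_model_responses(get_model("Flat"), {"sigma": 0.0}, trials,
                                       n_rep=3, seed=0)
        assert np.allclose(out, 0.8)

    def test_statichet_zero_noise_descends_to_well(self):
        trials = _const_session(2, np.deg2rad(30), delay_s=4.0)
        out = simulate_model_responses(get_model("StaticHet"),
                                       {"sigma": 0.0, "A_p": 1.0, "n": 4}, trials,
                                       n_rep=1, seed=0)
        assert np.all(np.abs(out) < np.deg2rad(0.5))

    def test_learning_model_biases_late_trials_toward_peaks(self):
        session = make_experiment_session(0.0, n_short=0, n_long=150, p_biased=1.0, seed=5)
        out = simulate_model_responses(get_model("LearnTargetFlatPrior"),
                                       {"sigma": 0.0, "beta": 8.0, "s": 5.0},
                                       session, n_rep=1, seed=1)
        peaks = np.pi / 2 * np.arange(4)
        late = out[-50:, 0]
        late_t = np.array([t.target for t in session[-50:]])
        d_resp = np.min(np.abs(circ_diff(late[:, None], peaks[None, :])), axis=1)
        d_targ = np.min(np.abs(circ_diff(late_t[:, None], peaks[None, :])), axis=1)
        assert np.mean(d_targ - d_resp) > 0  # responses pulled toward the peaks

    def test_distractor_models_use_distractor(self):
        trials = _const_session(30, 0.0, delay_s=0.5, distractor=np.pi / 2)
        kw = dict(n_rep=1, seed=2)
        params = {"sigma": 0.0, "beta": 8.0, "s": 5.0}
        td = simulate_model_responses(get_model("LearnTDFlatPrior"), params, trials, **kw)
        to = simulate_model_responses(get_model("LearnTargetFlatPrior"), params, trials, **kw)
        assert not np.allclose(td, to)


class TestMSE:
    def test_identical_zero(self):
        assert mse_score(np.zeros((4, 3)), np.zeros(4)) == 0.0

    def test_antipodal_pi_squared(self):
        sim = np.full((4, 2), np.pi)
        assert mse_score(sim, np.zeros(4)) == pytest.approx(np.pi**2)

    def test_noise_moment(self):
        rng = np.random.default_rng(0)
        subj = rng.normal(0, 0.1, 2000)
        sim = np.zeros((2000, 1))
        assert mse_score(sim, subj) == pytest.approx(0.01, rel=0.1)

    def test_rotation_equivariance(self):
        rng = np.random.default_rng(1)
        sim = rng.uniform(-np.pi, np.pi, (50, 2))
        subj = rng.uniform(-np.pi, np.pi, 50)
        rot = 1.1
        from ringdrift.ring import wrap_angle
        assert mse_score(wrap_angle(sim + rot), wrap_angle(subj + rot)) == \
            pytest.approx(mse_score(sim, subj), abs=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mse_score(np.zeros((3, 2)), np.zeros(4))


class TestCrossval:
    def test_folds_partition_trials(self, small_session):
        ds = generate_synthetic_subject("Flat", {"sigma": 0.05}, small_session, seed=0)
        res = crossval_fit(ds, get_model("Flat"), k_sets=3, n_rep=3, seed=1,
                           delay_class="short")
        assert len(res.fold_test_mse) == 5
        assert res.mean_test_mse == pytest.approx(np.mean(res.fold_test_mse))

    def test_noiseless_subject_selects_smallest_sigma(self, small_session):
        ds = generate_synthetic_subject("Flat", {"sigma": 0.0}, small_session, seed=0)
        res = crossval_fit(ds, get_model("Flat"), k_sets=20, n_rep=10, seed=2,
                           delay_class="long")
        sampled = sample_parameter_sets(get_model("Flat"), 20,
                                        seed=np.random.default_rng(2).integers(2**31))
        smallest = min(p["sigma"] for p in sampled)
        for p in res.fold_best_params:
            assert p["sigma"] == pytest.approx(smallest)

    def test_statichet_recovers_well_count(self):
        session = make_experiment_session(0.0, n_short=0, n_long=40, seed=7)
        ds = generate_synthetic_subject("StaticHet", {"sigma": 0.05, "A_p": 1.0, "n": 4},
                                        session, seed=8, assigned_offset=0.0)
        res = crossval_fit(ds, get_model("StaticHet"), k_sets=25, n_rep=25, seed=9,
                           delay_class="long")
        ns = [p["n"] for p in res.fold_best_params]
        assert sum(n == 4 for n in ns) >= 3

    def test_too_few_trials(self, small_session):
        ds = generate_synthetic_subject("Flat", {"sigma": 0.05}, small_session[:3], seed=0)
        with pytest.raises(ValueError):
            crossval_fit(ds, get_model("Flat"), k_sets=2, n_rep=2, seed=0)


class TestSelect:
    def _fr(self, name, mses):
        return FitResult(name, "long", [{}] * 5, [0.0] * 5, mses)

    def test_lowest_mean_wins(self):
        a = self._fr("Flat", [0.5] * 5)
        b = self._fr("StaticHet", [0.1] * 5)
        assert select_model([a, b]).model_name == "StaticHet"
        assert b.selected and not a.selected

    def test_tie_breaks_toward_parsimony(self):
        a = self._fr("DualHet", [0.2] * 5)
        b = self._fr("Flat", [0.2] * 5)
        assert select_model([a, b]).model_name == "Flat"


def test_trial_llr_prefers_generating_class(small_session):
    learn_p = {"sigma": 0.05, "beta": 8.0, "s": 5.0}
    fixed_p = {"sigma": 0.05, "A_p": 1.0, "n": 4}
    ds = generate_synthetic_subject("LearnTargetFlatPrior", learn_p, small_session,
                                    seed=3, assigned_offset=0.3)
    out = trial_llr(ds, get_model("LearnTargetFlatPrior"), learn_p,
                    get_model("StaticHet"), fixed_p)
    assert out["llr"].shape == (len(small_session),)
    assert np.allclose(out["cumulative"], np.cumsum(out["llr"]))
    assert np.all(np.isfinite(out["llr"]))
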