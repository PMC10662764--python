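"""Environmental priors, stimulus sampling, and the synthetic task protocol."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import i0, i1
from scipy.stats import chisquare

from ringdrift.environment import (EnvironmentalPrior, dataset_to_frame, env_density,
                                   frame_to_datasets, generate_synthetic_subject,
                                   make_experiment_session, sample_stimuli)
from ringdrift.ring import circ_diff, make_grid


class TestEnvDensity:
    def test_normalization_all_forms(self, grid):
        for prior in (EnvironmentalPrior(form="uniform"),
                      EnvironmentalPrior(form="exp_cosine", amplitude=1.0, modes=4),
                      EnvironmentalPrior(form="peaked_arcs", offset=0.3)):
            d = env_density(prior, grid)
            assert np.all(d >= 0)
            assert d.sum() * grid.bin_width == pytest.approx(1.0, abs=1e-6)

    def test_zero_amplitude_is_uniform(self, grid):
        d = env_density(EnvironmentalPrior(amplitude=0.0, modes=7), grid)
        assert np.allclose(d, 1 / (2 * np.pi))

    def test_peaks_at_cardinal_angles(self, grid):
        d = env_density(EnvironmentalPrior(amplitude=1.0, modes=4, offset=0.0), grid)
        peaks = grid.centers[d == d.max()]
        expected = np.deg2rad([-180, -90, 0, 90])
        assert np.allclose(np.sort(peaks), np.sort(expected), atol=grid.bin_width)

    def test_exp_cosine_normalization_constant(self, grid):
        # density at a peak should equal e^A / (2 pi I0(A))
        d = env_density(EnvironmentalPrior(amplitude=1.0, modes=4), grid)
        assert d.max() == pytest.approx(np.e / (2 * np.pi * i0(1.0)), rel=1e-4)

    def test_unknown_form_rejected(self):
        with pytest.raises(ValueError):
            EnvironmentalPrior(form="gaussian")


class TestSampling:
    def test_uniform_chi2_not_rejected(self):
        s = sample_stimuli(EnvironmentalPrior(form="uniform"), 100_000, seed=0)
        counts = np.histogram(s, bins=36, range=(-np.pi, np.pi))[0]
        assert chisquare(counts).pvalue > 0.01

    def test_exp_cosine_circular_moment(self, prior4):
        s = sample_stimuli(prior4, 100_000, seed=1)
        assert np.mean(np.cos(4 * s)) == pytest.approx(i1(1.0) / i0(1.0), abs=0.01)

    def test_seed_reproducibility(self, prior4):
        a = sample_stimuli(prior4, 100, seed=7)
        b = sample_stimuli(prior4, 100, seed=7)
        assert np.array_equal(a, b)

    def test_rejects_nonpositive_n(self, prior4):
        with pytest.raises(ValueError):
            sample_stimuli(prior4, 0, seed=1)

    def test_peaked_arcs_all_mass_in_arcs(self):
        prior = EnvironmentalPrior(form="peaked_arcs", offset=0.2, p_biased=1.0,
                                   arc_width_deg=20.0)
        s = sample_stimuli(prior, 5000, seed=3)
        dist = np.min(np.abs(circ_diff(s[:, None],
                                       0.2 + np.pi / 2 * np.arange(4)[None, :])), axis=1)
        assert np.all(np.rad2deg(dist) <= 10.0 + 1e-9)


class TestSession:
    def test_counts_and_delays(self):
        trials = make_experiment_session(0.1, n_short=30, n_long=20, seed=5)
        assert len(trials) == 50
        shorts = [t for t in trials if t.delay_class == "short"]
        longs = [t for t in trials if t.delay_class == "long"]
        assert len(shorts) == 30 and len(longs) == 20
        assert all(t.delay_s == 0.5 for t in shorts)
        assert all(t.delay_s == 4.0 for t in longs)

    def test_no_bias_degenerate_mixture(self):
        trials = make_experiment_session(0.1, p_biased=0.0, seed=5)
        assert not any(t.biased_target or t.biased_distractor for t in trials)

    def test_biased_fraction_near_half(self):
        trials = make_experiment_session(0.0, n_short=2500, n_long=2500, seed=6)
        flags = [t.biased_target for t in trials] + [t.biased_distractor for t in trials]
        frac = np.mean(flags)
        assert abs(frac - 0.5) < 3 * 0.5 / np.sqrt(len(flags))

    def test_biased_targets_near_peaks(self):
        off = 0.4
        trials = make_experiment_session(off, n_short=200, n_long=200, seed=7)
        peaks = off + np.pi / 2 * np.arange(4)
        for t in trials:
            if t.biased_target:
                d = np.min(np.abs(circ_diff(t.target, peaks)))
                assert np.rad2deg(d) <= 10.0 + 1e-9

    def test_invalid_arc_width(self):
        for bad in (0.0, 95.0):
            with pytest.raises(ValueError):
                make_experiment_session(0.0, arc_width_deg=bad, seed=1)


class TestSyntheticSubject:
    def test_flat_model_zero_noise_reproduces_targets(self, small_session):
        ds = generate_synthetic_subject("Flat", {"sigma": 0.0}, small_session, seed=1)
        targets = np.array([t.target for t in ds.trials])
        assert np.allclose(ds.responses, targets)
        assert ds.generator_truth["model_name"] == "Flat"

    def test_static_het_narrower_at_attractors(self):
        # many replicates of single-trial responses at an attractor vs a saddle
        from ringdrift.environment import TrialRecord
        session_a = [TrialRecord(i, "long", 4.0, 0.0, 0.0, False, False) for i in range(200)]
        session_s = [TrialRecord(i, "long", 4.0, np.pi / 4, 0.0, False, False)
                     for i in range(200)]
        params = {"sigma": 0.05, "A_p": 1.0, "n": 4}
        da = generate_synthetic_subject("StaticHet", params, session_a, seed=2)
        dsd = generate_synthetic_subject("StaticHet", params, session_s, seed=2)
        err_a = circ_diff(da.responses, 0.0)
        err_s = circ_diff(dsd.responses, np.pi / 4)
        assert 1 - np.abs(np.mean(np.exp(1j * err_a))) < 1 - np.abs(np.mean(np.exp(1j * err_s)))

    def test_learning_subject_develops_four_wells(self):
        session = make_experiment_session(0.0, n_short=100, n_long=100, seed=9)
        ds = generate_synthetic_subject("LearnTargetFlatPrior",
                                        {"sigma": 0.05, "beta": 8.0, "s": 5.0},
                                        session, seed=10)
        # rebuild the landscape the generator evolved and check its shape
        from ringdrift.landscapes import LearningState, learning_update
        st = LearningState(beta=8.0, s=5.0)
        for t in ds.trials:
            st = learning_update(st, t.target)
        spec = np.abs(np.fft.rfft(st.U_est - st.U_est.mean()))
        assert np.argmax(spec[1:]) + 1 == 4

    def test_unknown_model_rejected(self, small_session):
        with pytest.raises(ValueError):
            generate_synthetic_subject("Mystery", {}, small_session, seed=1)


def test_csv_round_trip(small_session):
    ds = generate_synthetic_subject("Flat", {"sigma": 0.02}, small_session, seed=3,
                                    subject_id="s01", assigned_offset=0.25)
    df = dataset_to_frame(ds)
    assert list(df.columns) == ["subject_id", "trial_index", "delay_class", "delay_s",
                                "target_deg", "distractor_deg", "response_deg",
                                "assigned_offset_deg"]
    back = frame_to_datasets(df)[0]
    assert back.subject_id == "s01"
    assert back.assigned_offset == pytest.approx(0.25, abs=1e-9)
    assert np.allclose(circ_diff(back.responses, ds.responses), 0.0, atol=1e-9)
    assert np.allclose(circ_diff([t.target for t in back.trials],
                                 [t.target for t in ds.trials]), 0.0, atol=1e-9)
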