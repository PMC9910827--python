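"""Generators: exact fixed points, determinism, and statistical structure."""

import numpy as np
import pytest

import eyepatch as ep
from eyepatch.synthetic import (
    gen_adjustment,
    gen_cohort,
    gen_constant_stimuli,
    gen_eeg,
    gen_phase_session,
    gen_rivalry,
    gen_ssvep_recording,
)


class TestGenEEG:
    def test_pure_ssvep_sinusoid_spectrum(self):
        """A noise-free 15 Hz component lands exactly on-grid at 5 uV."""
        p = ep.EEGGenParams(noise_scale=0, alpha_amp=0, ssvep_amp=5.0,
                            duration=7.0, n_channels=1, seed=0)
        rec = gen_eeg(p)
        spec = ep.amplitude_spectrum(
            ep.epoch_resting(rec, discard=0.0, epoch_len=7.0)
        )
        assert spec.at(15.0) == pytest.approx(5.0, rel=1e-9)
        others = spec.amplitudes[np.abs(spec.frequencies - 15.0) > 0.01]
        assert np.max(others) < 1e-9

    def test_all_zero_when_everything_off(self):
        p = ep.EEGGenParams(noise_scale=0, alpha_amp=0, ssvep_amp=0,
                            duration=2.0, seed=0)
        assert not gen_eeg(p).samples.any()

    def test_fixed_seed_bit_identical(self):
        p = ep.EEGGenParams(duration=5.0, seed=42)
        a, b = gen_eeg(p), gen_eeg(p)
        np.testing.assert_array_equal(a.samples, b.samples)

    def test_invalid_sampling_rejected(self):
        with pytest.raises(ep.ParameterError):
            ep.EEGGenParams(sample_rate=25.0)  # below Nyquist for 15 Hz
        with pytest.raises(ep.ParameterError):
            ep.EEGGenParams(alpha_freq=5.0)
        with pytest.raises(ep.ParameterError):
            ep.EEGGenParams(duration=-1.0)

    def test_noise_spectral_slope_recovered(self):
        """Log-log regression on the noise-only spectrum returns the
        1/f exponent within +-0.2 at 40 epochs."""
        p = ep.EEGGenParams(alpha_amp=0, ssvep_amp=0, noise_exponent=1.0,
                            duration=290.0, n_channels=1, seed=7)
        spec = ep.amplitude_spectrum(
            ep.epoch_resting(gen_eeg(p), discard=10.0)
        )
        sel = (spec.frequencies >= 2.0) & (spec.frequencies <= 100.0)
        slope = np.polyfit(np.log(spec.frequencies[sel]),
                           np.log(spec.amplitudes[sel] ** 2), 1)[0]
        assert -slope == pytest.approx(1.0, abs=0.2)

    def test_alpha_peak_frequency_monte_carlo(self):
        """With a 4 uV alpha component over quiet 1/f noise the pipeline
        localizes the 10 Hz peak within +-0.5 Hz in >=95% of runs."""
        hits = 0
        n_runs = 100
        for seed in range(n_runs):
            p = ep.EEGGenParams(alpha_amp=4.0, noise_scale=6.0, ssvep_amp=0,
                                duration=290.0, n_channels=1, seed=seed)
            spec = ep.amplitude_spectrum(
                ep.epoch_resting(gen_eeg(p), discard=10.0)
            )
            feat = ep.alpha_peak(spec)
            hits += abs(feat.alpha_peak_freq - 10.0) <= 0.5
        assert hits >= 0.95 * n_runs

    def test_ssvep_recording_has_trial_structure(self):
        p = ep.EEGGenParams(noise_scale=0, alpha_amp=0, ssvep_amp=2.0, seed=0)
        rec = gen_ssvep_recording(p, n_trials=12, trial_duration=10.0)
        assert rec.duration == pytest.approx(120.0)
        assert len(rec.trial_boundaries) == 12


class TestGenConstantStimuli:
    def test_matches_closed_form_at_threshold(self):
        """Binomial sampling at the threshold level converges to the
        Quick-function value 0.816."""
        obs = ep.PsychoObserverParams(true_alpha=0.05, true_beta=3.0, seed=11)
        data = gen_constant_stimuli(obs, [0.05], n_per_level=10**6)
        frac = data.n_correct[0] / data.n_trials[0]
        assert frac == pytest.approx(0.816, abs=0.002)

    def test_asymptote_and_guessing_floor(self):
        obs = ep.PsychoObserverParams(true_alpha=0.01, true_beta=3.0, seed=3)
        hi = gen_constant_stimuli(obs, [1.0], n_per_level=10**5)
        assert hi.n_correct[0] / hi.n_trials[0] == pytest.approx(1.0, abs=1e-3)
        lo = gen_constant_stimuli(obs, [1e-6], n_per_level=10**5)
        assert lo.n_correct[0] / lo.n_trials[0] == pytest.approx(0.5, abs=0.01)

    def test_seeded_and_validated(self):
        obs = ep.PsychoObserverParams(seed=5)
        a = gen_constant_stimuli(obs, [0.01, 0.02], 75)
        b = gen_constant_stimuli(obs, [0.01, 0.02], 75)
        np.testing.assert_array_equal(a.n_correct, b.n_correct)
        with pytest.raises(ep.ParameterError):
            gen_constant_stimuli(obs, [0.0, 0.1], 75)


class TestGenAdjustment:
    def test_zero_jitter_returns_threshold_exactly(self):
        data = gen_adjustment(0.02, jitter_sd=0.0, n_trials=10, seed=0)
        np.testing.assert_allclose(data.trial_contrast, 0.02)

    def test_forty_trials_per_condition(self):
        assert gen_adjustment(0.01, n_trials=40, seed=1).trial_contrast.size == 40

    def test_geometric_mean_recovery_over_seeds(self):
        """The correct-trial geometric mean estimates the true threshold
        within 5% for nearly all seeds."""
        errs = []
        for seed in range(100):
            data = gen_adjustment(0.01, jitter_sd=0.1, n_trials=40, seed=seed)
            est = ep.adjustment_threshold(data)
            errs.append(abs(est / 0.01 - 1.0))
        assert np.quantile(errs, 0.95) < 0.05


class TestGenPhaseSession:
    @pytest.mark.parametrize(
        "wu, wp, expected",
        [
            (1.0, 1.0, 0.0),
            (1.0, 0.0, 22.5),
            (0.0, 1.0, -22.5),
            (2.0, 1.0, 7.861193404821713),
        ],
    )
    def test_noise_free_closed_form(self, wu, wp, expected):
        """The half-difference estimator applied to noise-free reports
        returns the gain-weighted closed-form phase."""
        obs = ep.PhaseObserverParams(weight_upe=wu, weight_pe=wp,
                                     report_noise_sd=0.0, seed=0)
        session = gen_phase_session(obs, n_per_config=8)
        assert ep.perceived_phase(session) == pytest.approx(expected, abs=1e-9)

    def test_config_signs(self):
        obs = ep.PhaseObserverParams(weight_upe=1.0, weight_pe=0.0,
                                     report_noise_sd=0.0, seed=0)
        s = gen_phase_session(obs, 4)
        assert np.allclose(s.reported_phase[s.configurations == 1], 22.5)
        assert np.allclose(s.reported_phase[s.configurations == 2], -22.5)

    def test_both_weights_zero_rejected(self):
        with pytest.raises(ep.ParameterError):
            ep.PhaseObserverParams(weight_upe=0.0, weight_pe=0.0)


class TestGenRivalry:
    def test_intervals_tile_block_exactly(self):
        for mixed in (0.0, 0.15):
            rec = gen_rivalry(
                ep.RivalryGenParams(mixed_fraction=mixed, seed=2)
            )
            assert rec.durations.sum() == pytest.approx(90.0, abs=1e-12)

    def test_no_mixed_intervals_when_fraction_zero(self):
        rec = gen_rivalry(ep.RivalryGenParams(mixed_fraction=0.0, seed=4))
        assert "mixed" not in rec.percepts
        assert rec.total("UPE") + rec.total("PE") == pytest.approx(90.0)

    def test_symmetric_ratio_converges_to_one(self):
        recs = [
            gen_rivalry(
                ep.RivalryGenParams(block_duration=5000.0, seed=k),
                configuration=k,
            )
            for k in (1, 2)
        ]
        assert 0.95 <= ep.dominance_ratio(recs) <= 1.05

    def test_asymmetric_ratio_tracks_mean_durations(self):
        recs = [
            gen_rivalry(
                ep.RivalryGenParams(mean_dur_upe=1.0, mean_dur_pe=2.0,
                                    block_duration=5000.0, seed=10 + k),
                configuration=k,
            )
            for k in (1, 2)
        ]
        assert ep.dominance_ratio(recs) == pytest.approx(0.5, abs=0.05)

    def test_mixed_fraction_realized(self):
        rec = gen_rivalry(
            ep.RivalryGenParams(mixed_fraction=0.2, block_duration=5000.0,
                                seed=6)
        )
        assert rec.total("mixed") / 5000.0 == pytest.approx(0.2, abs=0.05)


class TestGenCohort:
    def test_zero_effect_stays_at_baseline(self):
        design = ep.CohortDesign(
            effect_at_0={"perceived_phase_deg": {"PE_open": 0.0,
                                                 "PE_closed": 0.0}},
            seed=1,
        )
        table = gen_cohort(design)
        base = design.baselines["perceived_phase_deg"]
        means = table.groupby(["condition", "timepoint"], observed=True)[
            "value"
        ].mean()
        sem = 4.5 / np.sqrt(design.n_subjects)  # between+within spread
        assert (np.abs(means - base) < 4 * sem).all()

    def test_exponential_recovery_nearly_complete_at_30min(self):
        design = ep.CohortDesign(
            effect_at_0={"perceived_phase_deg": {"PE_open": -14.0}},
            conditions=("PE_open",),
            within_subject_sd={"perceived_phase_deg": 0.0},
            between_subject_sd={"perceived_phase_deg": 0.0},
            recovery_tau=10.0,
            seed=2,
        )
        table = gen_cohort(design)
        at30 = table[table.timepoint == "30"]["value"].mean()
        base = table[table.timepoint == "baseline"]["value"].mean()
        assert abs(at30 - base) < 0.05 * 14.0 + 1e-9

    def test_condition_effect_detectable_by_rm_anova(self):
        """Built-in open/closed asymmetry is detected by the two-way
        RM-ANOVA condition main effect in >=80% of replicates."""
        hits = 0
        n_rep = 100
        for seed in range(n_rep):
            design = ep.CohortDesign(
                effect_at_0={"perceived_phase_deg": {"PE_open": -14.0,
                                                     "PE_closed": -6.14}},
                between_subject_sd={"perceived_phase_deg": 4.0},
                within_subject_sd={"perceived_phase_deg": 4.0},
                seed=seed,
            )
            table = gen_cohort(design)
            res = ep.rm_anova_twoway(
                table[table.metric == "perceived_phase_deg"]
            )
            hits += res["condition"].p_value < 0.05
        assert hits >= 0.8 * n_rep

    def test_raw_tables_reproduce_latent_values(self):
        design = ep.CohortDesign(n_subjects=3, seed=9)
        table, raw = gen_cohort(design, include_raw=True)
        checked = 0
        for (subj, cond, tp, metric), raw_data in raw.items():
            latent = table.query(
                "subject == @subj and condition == @cond and "
                "timepoint == @tp and metric == @metric"
            )["value"].iloc[0]
            if metric == "perceived_phase_deg":
                est = ep.perceived_phase(raw_data)
                assert est == pytest.approx(min(max(latent, -21.8), 21.8),
                                            abs=3.0)
                checked += 1
            elif metric == "dominance_ratio":
                est = ep.dominance_ratio(raw_data)
                assert est == pytest.approx(max(latent, 0.05), rel=0.6)
                checked += 1
        assert checked > 50

    def test_deterministic_under_seed(self):
        d = ep.CohortDesign(seed=5)
        a, b = gen_cohort(d), gen_cohort(d)
        assert a.equals(b)
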