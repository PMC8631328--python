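import numpy as np
import pytest

from fatiguewave.entropy import renyi_entropy, session_entropy
from fatiguewave.preprocess import preprocess_recording
from fatiguewave.stats import pearson
from fatiguewave.synthetic import (
    BASE_PROFILE,
    DEFAULT_SESSIONS,
    BandSpec,
    CohortEffects,
    CohortSpec,
    OddballSpec,
    cell_profile,
    dyadic_bands,
    generate_cohort,
    generate_eeg,
    generate_oddball_log,
    monotone_entropy_targets,
    perturb_profile_entropy,
    profile_for_entropy,
    trajectory_from_entropy,
)
from oracles import periodogram_band_fractions


class TestBandSpecs:
    def test_dyadic_bands_disjoint_ordered(self):
        bands = dyadic_bands(62.5)
        assert [b.band_name for b in bands] == ["beta", "alpha", "theta", "delta"]
        ranges = [b.freq_range for b in bands]
        assert ranges[0] == (15.625, 31.25)
        for (lo1, hi1), (lo2, hi2) in zip(ranges, ranges[1:]):
            assert hi2 == lo1  # contiguous, descending in frequency
        assert sum(b.relative_power for b in bands) == pytest.approx(1.0, abs=1e-9)

    def test_negative_power_rejected(self):
        with pytest.raises(ValueError):
            BandSpec("beta", (15.625, 31.25), -0.1)

    def test_powers_must_sum_to_one(self):
        with pytest.raises(ValueError):
            dyadic_bands(62.5, powers=(0.5, 0.5, 0.5, 0.5))


class TestProfileParameterization:
    @pytest.mark.parametrize("target", [0.5, 0.65, 0.84, 0.99])
    def test_profile_hits_entropy_target(self, target):
        p = profile_for_entropy(target)
        assert renyi_entropy(p) == pytest.approx(target, abs=1e-6)

    def test_unattainable_target_clipped_to_base(self):
        p = profile_for_entropy(0.1)
        assert np.allclose(p, BASE_PROFILE)

    @pytest.mark.parametrize("target", [0.6, 0.8, 0.95])
    def test_perturbation_keeps_shape_and_hits_target(self, target):
        base = profile_for_entropy(0.7)
        p = perturb_profile_entropy(base, target)
        assert renyi_entropy(p) == pytest.approx(target, abs=1e-6)
        # ordering of bands preserved along the sharpening path
        assert np.array_equal(np.argsort(p), np.argsort(base))

    def test_uniform_profile_is_fixed_point(self):
        u = np.full(4, 0.25)
        assert np.allclose(perturb_profile_entropy(u, 0.5), u)


class TestGenerateEEG:
    def test_deterministic_given_seed(self, small_cohort_spec):
        a = generate_eeg(small_cohort_spec, 1, "Day2")
        b = generate_eeg(small_cohort_spec, 1, "Day2")
        assert np.array_equal(a.data, b.data)

    def test_shape_and_metadata(self, small_cohort_spec):
        rec = generate_eeg(small_cohort_spec, 0, "Day1")
        assert rec.data.shape == (4, int(24.0 * 250.0))
        assert rec.fs == 250.0
        assert rec.subject == 0 and rec.session == "Day1"

    def test_unknown_session_rejected(self, small_cohort_spec):
        with pytest.raises(ValueError, match="session"):
            generate_eeg(small_cohort_spec, 0, "Day9")

    def test_subject_out_of_range_rejected(self, small_cohort_spec):
        with pytest.raises(ValueError):
            generate_eeg(small_cohort_spec, 5, "Day1")

    def test_other_subjects_unperturbed_by_cohort_size(self):
        spec_a = CohortSpec(n_subjects=3, duration_s=16.0, seed=9)
        spec_b = CohortSpec(n_subjects=9, duration_s=16.0, seed=9)
        a = generate_eeg(spec_a, 2, "Day3")
        b = generate_eeg(spec_b, 2, "Day3")
        assert np.array_equal(a.data, b.data)

    def test_band_fidelity_against_periodogram(self):
        """Programmed relative band powers are recovered by an independent
        periodogram oracle within 15 % relative error, after accounting for
        the 1/f background contribution analytically."""
        spec = CohortSpec(
            n_subjects=2, duration_s=240.0, seed=13,
            between_subject_sd=0.0, within_subject_sd=0.0,
        )
        rec = generate_eeg(spec, 0, "Day1")
        programmed = cell_profile(spec, 0, "Day1")

        from scipy.signal import sosfiltfilt
        from fatiguewave.preprocess import _bandpass_sos

        filtered = sosfiltfilt(_bandpass_sos(3.0, 30.0, 250.0), rec.data[0])
        bands = [
            (max(b.freq_range[0], 3.0), min(b.freq_range[1], 30.0))
            for b in dyadic_bands(62.5)
        ]
        measured = periodogram_band_fractions(filtered, 250.0, bands)

        # background's analytic in-band split: |H(f)|^2 * f^-a integrated per band
        freqs = np.linspace(0.1, 125.0, 20000)
        from scipy.signal import sosfreqz

        _, h = sosfreqz(_bandpass_sos(3.0, 30.0, 250.0), worN=freqs, fs=250.0)
        shaped = np.abs(h) ** 4 * freqs ** (-spec.noise_exponent)
        q_bg = np.array([
            np.trapezoid(shaped[(freqs >= lo) & (freqs < hi)],
                         freqs[(freqs >= lo) & (freqs < hi)])
            for lo, hi in bands
        ])
        q_bg /= q_bg.sum()
        f = spec.background_fraction
        expected = (1 - f) * programmed + f * q_bg
        expected /= expected.sum()
        assert np.all(np.abs(measured - expected) / expected < 0.15)


class TestOddball:
    def test_stimulus_count(self):
        spec = OddballSpec(total_duration_s=240.0, isi_ms=1000.0, stim_dur_ms=50.0)
        assert spec.n_stimuli == 228  # floor(240 / 1.05)
        log = generate_oddball_log(spec)
        n_stim = (log.events["kind"] != "press").sum()
        assert n_stim == 228

    def test_no_deviants_no_presses(self):
        log = generate_oddball_log(OddballSpec(p_deviant=1e-12, seed=3))
        assert (log.events["kind"] == "press").sum() == 0
        assert (log.events["kind"] == "deviant").sum() == 0

    def test_deviant_fraction_concentrates(self):
        spec = OddballSpec(total_duration_s=10500.0, p_deviant=0.2, seed=11)
        assert spec.n_stimuli == 10000
        log = generate_oddball_log(spec)
        frac = (log.events["kind"] == "deviant").sum() / 10000
        assert abs(frac - 0.2) < 0.01

    def test_determinism(self, oddball_spec):
        a = generate_oddball_log(oddball_spec)
        b = generate_oddball_log(oddball_spec)
        assert a.events.equals(b.events)

    def test_presses_inside_valid_window(self, oddball_spec):
        log = generate_oddball_log(oddball_spec)
        deviants = log.times_of("deviant")
        for press in log.times_of("press"):
            lats = press - deviants
            lats = lats[(lats > 0)]
            assert np.any((lats >= 0.1) & (lats <= 1.0))

    def test_invalid_probability_rejected(self):
        with pytest.raises(ValueError):
            OddballSpec(p_deviant=1.5)


class TestCohort:
    def test_table_shape_and_clamping(self, small_cohort_spec, oddball_spec):
        cohort = generate_cohort(small_cohort_spec, oddball_spec,
                                 with_signals=False)
        t = cohort.session_table
        assert len(t) == 3 * 6
        assert t["sss"].between(1, 7).all()
        assert (t["sleep_min"] >= 0).all()

    def test_default_cohort_has_54_rows(self):
        spec = CohortSpec(duration_s=16.0, seed=1)
        cohort = generate_cohort(spec, OddballSpec(total_duration_s=30.0, seed=1),
                                 with_signals=False)
        assert len(cohort.session_table) == 54

    def test_zero_effects_zero_noise_constant_sss(self, small_cohort_spec):
        effects = CohortEffects(
            sss_session_means=(3.0,) * 6, sss_between_sd=0.0, sss_within_sd=0.0,
            sleep_session_means=(300.0,) * 6, sleep_within_sd=0.0,
        )
        cohort = generate_cohort(
            small_cohort_spec, OddballSpec(total_duration_s=30.0),
            effects, with_signals=False,
        )
        assert (cohort.session_table["sss"] == 3).all()

    def test_reproducible_from_seed(self, small_cohort_spec, oddball_spec):
        a = generate_cohort(small_cohort_spec, oddball_spec, with_signals=False)
        b = generate_cohort(small_cohort_spec, oddball_spec, with_signals=False)
        assert a.session_table.equals(b.session_table)
        key = (0, "Day1", "audio")
        assert a.logs[key].events.equals(b.logs[key].events)

    def test_negative_sleep_entropy_coupling_recovered(self):
        """With the default trajectories (entropy rising, sleep collapsing),
        the pooled entropy–sleep correlation must come out negative."""
        spec = CohortSpec(n_subjects=4, duration_s=40.0, seed=23, n_channels=1,
                          channel_labels=("Fp1h",))
        cohort = generate_cohort(spec, OddballSpec(total_duration_s=30.0, seed=23))
        ent, sleep = [], []
        for (subj, session), rec in sorted(cohort.recordings.items()):
            eps = preprocess_recording(rec)
            ent.append(session_entropy(eps["Fp1h"]).session_value)
            row = cohort.session_table.query(
                "subject == @subj and session == @session"
            )
            sleep.append(float(row["sleep_min"].iloc[0]))
        r, _ = pearson(np.array(ent), np.array(sleep))
        assert r < 0


class TestClosedLoopEntropy:
    def _measure(self, spec, subject, session):
        rec = generate_eeg(spec, subject, session)
        eps = preprocess_recording(rec, channels=[spec.channel_labels[0]])
        return session_entropy(eps[spec.channel_labels[0]]).session_value

    def test_uniform_trajectory_near_max_entropy(self):
        traj = {s: np.full(4, 0.25) for s in DEFAULT_SESSIONS}
        spec = CohortSpec(
            n_subjects=2, duration_s=60.0, band_trajectory=traj, seed=5,
            between_subject_sd=0.0, within_subject_sd=0.0,
        )
        assert abs(self._measure(spec, 0, "Day1") - 1.0) < 0.1

    def test_concentrated_below_uniform(self):
        conc = {s: np.array([0.04, 0.88, 0.04, 0.04]) for s in DEFAULT_SESSIONS}
        unif = {s: np.full(4, 0.25) for s in DEFAULT_SESSIONS}
        common = dict(n_subjects=2, duration_s=60.0, seed=5,
                      between_subject_sd=0.0, within_subject_sd=0.0)
        h_conc = self._measure(CohortSpec(band_trajectory=conc, **common), 0, "Day1")
        h_unif = self._measure(CohortSpec(band_trajectory=unif, **common), 0, "Day1")
        assert h_conc < h_unif

    def test_monotone_targets_are_monotone(self):
        t = monotone_entropy_targets()
        assert t[0] == 0.65 and t[-1] == 0.84
        assert np.all(np.diff(t) > 0)

    def test_trajectory_requires_all_sessions(self):
        with pytest.raises(ValueError, match="trajectory"):
            CohortSpec(band_trajectory={"Day1": np.full(4, 0.25)})
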