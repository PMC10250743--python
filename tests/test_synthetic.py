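"""Statistical structure of the synthetic sessions and cohorts."""

import numpy as np
import pytest

from texeeg import (ActionSchedule, DeviceProfile, SubjectProfile,
                    make_cohort, simulate_artifact_session,
                    simulate_movement_session, simulate_resting)
from texeeg.spectral import band_means, compute_psd
from texeeg.synthetic import ACTIONS, pink_noise

FS = 256.0


class TestRestingState:
    def test_alpha_reactivity_closed_above_open(self, subject, devices):
        ec = simulate_resting(subject, devices["dry"], "closed", 60, seed=1)
        eo = simulate_resting(subject, devices["dry"], "open", 60, seed=1)
        assert band_means(compute_psd(ec))["alpha"] > \
            band_means(compute_psd(eo))["alpha"]

    def test_zero_mains_leaves_background_level(self, subject):
        quiet = DeviceProfile("dry", mains_amp_uv=0.0, artifact_gain=1.0)
        loud = DeviceProfile("dry", mains_amp_uv=3.0, artifact_gain=1.0)
        rq = simulate_resting(subject, quiet, "closed", 60, seed=2)
        rl = simulate_resting(subject, loud, "closed", 60, seed=2)
        bq, bl = (band_means(compute_psd(r))["mains"] for r in (rq, rl))
        assert bl > bq + 0.1  # mains line clearly visible
        # without mains, 45-55 Hz sits on the 1/f background: its level must
        # match a log-log fit of the flanking 30-44 / 56-70 Hz bins within 1 dB
        spec = compute_psd(rq)
        flank = ((spec.freqs >= 30) & (spec.freqs < 45)) | \
                ((spec.freqs > 55) & (spec.freqs <= 60))
        sel_mains = (spec.freqs >= 45) & (spec.freqs <= 55)
        coef = np.polyfit(np.log10(spec.freqs[flank]),
                          spec.log_power[:, flank].mean(axis=0), 1)
        predicted = np.polyval(coef, np.log10(spec.freqs[sel_mains])).mean()
        observed = spec.log_power[:, sel_mains].mean()
        assert abs(10 * (observed - predicted)) < 1.0

    def test_seed_determinism(self, subject, devices):
        a = simulate_resting(subject, devices["garment"], "open", 10, seed=5)
        b = simulate_resting(subject, devices["garment"], "open", 10, seed=5)
        np.testing.assert_array_equal(a.data, b.data)

    def test_blinks_dominate_frontopolar_channels(self, subject, devices):
        eo = simulate_resting(subject, devices["dry"], "open", 120, seed=3)
        from texeeg import bandpass
        low = bandpass(eo, 0.3, 5.0)  # blink band
        p = low.data.var(axis=1)
        assert p[1] > p[0] and p[2] > p[3]  # Fp1 > F7, Fp2 > F8

    def test_unknown_state_rejected(self, subject, devices):
        with pytest.raises(ValueError, match="state"):
            simulate_resting(subject, devices["dry"], "shut", 10, seed=0)

    def test_pink_background_slope_near_minus_gamma(self):
        rng = np.random.default_rng(0)
        for gamma in (0.8, 1.0, 1.2):
            x = pink_noise(rng, 1, int(300 * FS), FS, gamma=gamma)
            from texeeg.io_core import Recording
            spec = compute_psd(Recording(data=x, fs=FS,
                                         channel_names=("F7",)))
            sel = (spec.freqs >= 2) & (spec.freqs <= 40)
            slope = np.polyfit(np.log10(spec.freqs[sel]),
                               spec.log_power[0, sel], 1)[0]
            assert slope == pytest.approx(-gamma, abs=0.3)


class TestMovementSession:
    def test_default_protocol_emits_80_movement_events(self, subject, devices):
        _, ev = simulate_movement_session(subject, devices["dry"], seed=0)
        moves = ev.select("movement")
        assert len(moves) == 80
        assert all(e.duration_samples == int(5 * FS) for e in moves)

    def test_rest_gaps_between_six_and_eight_seconds(self, subject, devices):
        _, ev = simulate_movement_session(subject, devices["dry"],
                                          n_blocks=1, trials_per_block=20,
                                          seed=1)
        moves = list(ev.select("movement"))
        gaps = [(b.onset_sample - (a.onset_sample + a.duration_samples)) / FS
                for a, b in zip(moves, moves[1:])]
        assert all(6.0 - 1e-6 <= g <= 8.0 + 1e-6 for g in gaps)

    def test_band_power_drops_by_erd_depth(self, devices):
        """Oracle: 8-30 Hz variance ratio movement vs pre-cue rest ~ 1-d."""
        prof = SubjectProfile(erd_depth=0.4)
        rec, ev = simulate_movement_session(prof, devices["dry"],
                                            n_blocks=2, trials_per_block=10,
                                            seed=2)
        from texeeg import bandpass
        band = bandpass(rec, 8.0, 30.0)
        ratios = []
        for e in ev.select("movement"):
            mv = band.data[:, e.onset_sample + 128:
                           e.onset_sample + e.duration_samples - 128]
            rest = band.data[:, e.onset_sample - int(5 * FS):
                             e.onset_sample - int(2 * FS)]
            ratios.append(mv.var() / rest.var())
        assert np.mean(ratios) == pytest.approx(0.6, abs=0.08)

    def test_seed_determinism(self, subject, devices):
        r1, e1 = simulate_movement_session(subject, devices["dry"],
                                           n_blocks=1, trials_per_block=3,
                                           seed=9)
        r2, e2 = simulate_movement_session(subject, devices["dry"],
                                           n_blocks=1, trials_per_block=3,
                                           seed=9)
        np.testing.assert_array_equal(r1.data, r2.data)
        assert e1 == e2


class TestArtifactSession:
    def test_event_list_is_nine_ten_second_segments(self, subject, devices):
        _, ev = simulate_artifact_session(subject, devices["dry"], seed=0)
        assert len(ev) == 9
        assert all(e.duration_samples == 2560 for e in ev)
        assert [e.label for e in ev] == list(ACTIONS)

    def test_garment_broadband_power_exceeds_dry(self, subject, devices):
        rg, _ = simulate_artifact_session(subject, devices["garment"], seed=4)
        rd, _ = simulate_artifact_session(subject, devices["dry"], seed=4)
        bg, bd = (band_means(compute_psd(r)) for r in (rg, rd))
        for band in ("delta", "theta", "alpha", "beta"):
            assert bg[band] > bd[band]

    def test_zero_action_amplitude_reduces_to_background(self, subject, devices):
        rec, _ = simulate_artifact_session(subject, devices["dry"], seed=5,
                                           action_amp_scale=0.0)
        bm = band_means(compute_psd(rec))
        ref = band_means(compute_psd(
            simulate_resting(subject, devices["dry"], "open", 90, seed=5)))
        assert bm["delta"] == pytest.approx(ref["delta"], abs=0.4)

    def test_wrong_schedule_rejected(self):
        with pytest.raises(ValueError, match="fixed 9 actions"):
            ActionSchedule(labels=("blink",))


class TestCohort:
    def test_reproducible_and_within_ranges(self):
        a = make_cohort(10, seed=11)
        b = make_cohort(10, seed=11)
        assert [p.alpha_freq_hz for p in a] == [p.alpha_freq_hz for p in b]
        for p in a:
            assert 9.0 <= p.alpha_freq_hz <= 11.0
            assert p.alpha_amp_open_uv < p.alpha_amp_closed_uv
            assert 0.0 <= p.erd_depth < 1.0

    def test_different_seeds_differ(self):
        a = make_cohort(5, seed=1)
        b = make_cohort(5, seed=2)
        assert [p.alpha_amp_closed_uv for p in a] != \
            [p.alpha_amp_closed_uv for p in b]

    def test_mains_contrast_positive_for_every_subject(self, devices):
        """Garment-minus-dry 45-55 Hz log power is positive per subject."""
        for i, prof in enumerate(make_cohort(6, seed=3)):
            bg = band_means(compute_psd(simulate_resting(
                prof, devices["garment"], "open", 60, seed=100 + i)))
            bd = band_means(compute_psd(simulate_resting(
                prof, devices["dry"], "open", 60, seed=200 + i)))
            assert bg["mains"] > bd["mains"]
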