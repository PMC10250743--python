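"""Morlet TFR, ERD/ERS maps, and bin-wise device statistics."""

import numpy as np
import pytest

from texeeg import binwise_device_comparison, erds, grand_average_erds, \
    morlet_tfr
from texeeg.io_core import EpochSet, PairingError
from texeeg.timefreq import ERDSMap, TFR

FS = 256.0


def make_epochs(data):
    n = data.shape[2]
    t = (np.arange(n) - n // 2) / FS
    return EpochSet(data=data, fs=FS, time_axis=t,
                    channel_names=("F7", "Fp1", "Fp2", "F8"))


def make_tfr(power, times=None, freqs=None):
    nf, nt = power.shape[-2:]
    return TFR(power=power,
               freqs=freqs if freqs is not None else 5 + 0.25 * np.arange(nf),
               times=times if times is not None else np.linspace(-6, 5, nt),
               channel_names=tuple(f"ch{i}" for i in range(power.shape[1])))


class TestMorletTfr:
    def test_zero_epochs_zero_power(self):
        tfr = morlet_tfr(make_epochs(np.zeros((2, 4, 3072))))
        assert tfr.power.shape == (2, 4, 101, 3072)
        np.testing.assert_allclose(tfr.power, 0.0)

    def test_peak_frequency_of_pure_sinusoid(self):
        n = 3072
        t = np.arange(n) / FS
        x = np.tile(np.sin(2 * np.pi * 15.0 * t), (1, 4, 1))
        tfr = morlet_tfr(make_epochs(x), decim=4)
        mid = tfr.power[..., 100:-100].mean(axis=(0, 1, 3))
        assert tfr.freqs[mid.argmax()] == pytest.approx(15.0, abs=0.25)

    def test_scaling_epochs_quadruples_power(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(1, 4, 2048))
        a = morlet_tfr(make_epochs(x), decim=8)
        b = morlet_tfr(make_epochs(2 * x), decim=8)
        np.testing.assert_allclose(b.power, 4 * a.power, rtol=1e-9)

    def test_power_time_course_matches_hand_built_wavelet(self):
        """Dual route: at one frequency, the TFR power time course must
        match a direct convolution with a hand-built complex Morlet
        wavelet (Gaussian-windowed exponential, sigma_t = n_cycles /
        (2 pi f)) up to a global normalization constant."""
        rng = np.random.default_rng(7)
        x = rng.normal(size=(1, 1, 2048))
        ep = EpochSet(data=np.tile(x, (1, 4, 1)), fs=FS,
                      time_axis=(np.arange(2048) - 1024) / FS,
                      channel_names=("F7", "Fp1", "Fp2", "F8"))
        f0, n_cycles = 10.0, 7.0
        tfr = morlet_tfr(ep, fmin=f0, fmax=f0, df=0.25, n_cycles=n_cycles)
        got = tfr.power[0, 0, 0]

        sigma_t = n_cycles / (2 * np.pi * f0)
        t = np.arange(-4 * sigma_t, 4 * sigma_t + 1 / FS, 1 / FS)
        wavelet = np.exp(2j * np.pi * f0 * t) * np.exp(-t**2 / (2 * sigma_t**2))
        ref = np.abs(np.convolve(x[0, 0], wavelet, mode="same")) ** 2

        mid = slice(300, -300)  # away from edge effects
        scale = ref[mid].mean() / got[mid].mean()
        # small residual differences: zero-mean wavelet correction and
        # support truncation differ between the two constructions
        np.testing.assert_allclose(got[mid] * scale, ref[mid], rtol=0.06)
        assert np.corrcoef(got[mid], ref[mid])[0, 1] > 0.9999

    def test_epoch_shorter_than_wavelet_support_raises(self):
        with pytest.raises(ValueError, match="support"):
            morlet_tfr(make_epochs(np.zeros((1, 4, 256))))  # 1 s < 7/5 s

    def test_edge_mask_flags_wavelet_half_lengths(self):
        tfr = morlet_tfr(make_epochs(np.zeros((1, 4, 3072))), decim=4)
        assert tfr.edge_mask[:, 0].all() and tfr.edge_mask[:, -1].all()
        # 5 Hz wavelet half-length (0.7 s) > 30 Hz one (0.12 s)
        assert tfr.edge_mask[0].sum() > tfr.edge_mask[-1].sum()


class TestErds:
    def test_power_halved_after_cue_gives_minus_fifty(self):
        nf, nt = 11, 100
        times = np.linspace(-6, 5, nt)
        power = np.ones((3, 2, nf, nt))
        power[..., times >= 0] = 0.5
        maps = erds(make_tfr(power, times=times), baseline_s=(-5, -2))
        for m in maps:
            np.testing.assert_allclose(m.values[:, times >= 0], -50.0)
            np.testing.assert_allclose(m.values[:, times < 0], 0.0)

    def test_baseline_interval_averages_to_zero(self):
        rng = np.random.default_rng(1)
        power = rng.gamma(2.0, 1.0, (5, 2, 8, 120))
        times = np.linspace(-6, 5, 120)
        maps = erds(make_tfr(power, times=times), baseline_s=(-5, -2))
        bsel = (times >= -5) & (times <= -2)
        for m in maps:
            np.testing.assert_allclose(m.values[:, bsel].mean(axis=1), 0.0,
                                       atol=1e-9)

    def test_map_floor_is_minus_hundred(self):
        power = np.ones((2, 1, 4, 50))
        power[..., 30:] = 0.0
        times = np.linspace(-6, 5, 50)
        maps = erds(make_tfr(power, times=times), baseline_s=(-5, -2))
        assert maps[0].values.min() == pytest.approx(-100.0)

    def test_degenerate_baseline_and_bad_interval_raise(self):
        power = np.zeros((1, 1, 4, 50))
        times = np.linspace(-6, 5, 50)
        with pytest.raises(ValueError, match="zero baseline"):
            erds(make_tfr(power, times=times))
        with pytest.raises(ValueError, match="outside epoch"):
            erds(make_tfr(np.ones((1, 1, 4, 50)), times=times),
                 baseline_s=(-20, -10))


class TestGrandAverage:
    def mk(self, v):
        return ERDSMap(values=np.full((3, 4), float(v)),
                       freqs=np.arange(3.0), times=np.arange(4.0))

    def test_identity_and_cancellation(self):
        m = self.mk(7)
        np.testing.assert_allclose(grand_average_erds([m]).values, 7.0)
        ga = grand_average_erds([self.mk(10), self.mk(-10)])
        np.testing.assert_allclose(ga.values, 0.0)

    def test_trial_then_electrode_order_matches_direct_mean(self):
        """With equal trial counts, averaging trials then electrodes equals
        the direct grand mean of all trial maps."""
        rng = np.random.default_rng(2)
        trial_maps = rng.normal(size=(2, 5, 3, 4))  # electrodes x trials
        per_electrode = [ERDSMap(values=trial_maps[e].mean(axis=0),
                                 freqs=np.arange(3.0), times=np.arange(4.0))
                         for e in range(2)]
        ga = grand_average_erds(per_electrode)
        np.testing.assert_allclose(ga.values,
                                   trial_maps.mean(axis=(0, 1)), atol=1e-12)

    def test_grid_mismatch_rejected(self):
        a = self.mk(1)
        b = ERDSMap(values=np.zeros((3, 5)), freqs=np.arange(3.0),
                    times=np.arange(5.0))
        with pytest.raises(ValueError, match="grids"):
            grand_average_erds([a, b])


class TestBinwiseComparison:
    freqs = np.arange(8.0, 13.0)
    times = np.arange(6.0)

    def mk(self, values):
        return ERDSMap(values=values, freqs=self.freqs, times=self.times)

    def random_maps(self, rng, n=10, offset=0.0):
        return [self.mk(rng.normal(offset, 1.0, (5, 6))) for _ in range(n)]

    def test_identical_map_sets_give_empty_mask(self):
        rng = np.random.default_rng(0)
        g = self.random_maps(rng)
        p, mask, md = binwise_device_comparison(g, g)
        assert not mask.any()
        np.testing.assert_allclose(p, 1.0)
        np.testing.assert_allclose(md.values, 0.0)

    def test_constant_shift_masks_everything_with_sign(self):
        rng = np.random.default_rng(1)
        g = self.random_maps(rng)
        d = [self.mk(m.values - 20.0) for m in g]
        p, mask, md = binwise_device_comparison(g, d)
        assert mask.all()
        np.testing.assert_allclose(p, 2 / 2**10)
        np.testing.assert_allclose(md.values, -20.0)

    def test_mask_monotone_in_alpha(self):
        rng = np.random.default_rng(2)
        g = self.random_maps(rng)
        d = self.random_maps(rng, offset=0.8)
        _, strict, _ = binwise_device_comparison(g, d, alpha=0.01)
        _, loose, _ = binwise_device_comparison(g, d, alpha=0.05)
        assert (loose | strict == loose).all()

    def test_tied_bins_fall_back_to_general_test(self):
        """Integer-valued maps create ties/zeros; result must still equal
        the scalar exact test at every bin."""
        from texeeg.stats import wilcoxon_signed_rank
        rng = np.random.default_rng(3)
        g = [self.mk(rng.integers(-2, 3, (5, 6)).astype(float))
             for _ in range(8)]
        d = [self.mk(rng.integers(-2, 3, (5, 6)).astype(float))
             for _ in range(8)]
        p, _, _ = binwise_device_comparison(g, d)
        G = np.stack([m.values for m in g])
        D = np.stack([m.values for m in d])
        for i in range(5):
            for j in range(6):
                _, ref = wilcoxon_signed_rank(D[:, i, j], G[:, i, j])
                assert p[i, j] == pytest.approx(ref, abs=1e-12)

    def test_unpaired_subjects_rejected(self):
        rng = np.random.default_rng(4)
        with pytest.raises(PairingError):
            binwise_device_comparison(self.random_maps(rng, 5),
                                      self.random_maps(rng, 4))
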