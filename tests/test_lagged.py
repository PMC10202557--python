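import numpy as np
import pytest

from srcconn.lagged import (CoherencyValue, complex_coherency, lagged_phase_coherence,
                            lpc_significance, lpc_table, ordinary_coherence_sq)
from srcconn.recording import EEGRecording, bandpass_filter
from srcconn.spectra import epoch_and_cross_spectra


def _cross_spectra(data, fs=128.0, epoch_len_s=4.0):
    labels = tuple(f"ch{i}" for i in range(data.shape[0]))
    rec = EEGRecording(data, fs, labels, reference="common_average")
    return epoch_and_cross_spectra(rec, epoch_len_s, amp_reject_uv=None)


class TestLaggedFormula:
    @pytest.mark.parametrize("c,expected", [
        (0.5j, 0.25),
        (0.6 + 0.0j, 0.0),
        (0.3 + 0.4j, 0.16 / 0.91),
    ])
    def test_formula_plug_in(self, c, expected):
        coh = CoherencyValue(0, 1, "alpha", c, 10, 2, "phase")
        assert lagged_phase_coherence(coh) == pytest.approx(expected, abs=1e-12)

    def test_degenerate_real_one_is_zero_with_warning(self):
        coh = CoherencyValue(0, 1, "alpha", 1.0 + 0.0j, 10, 2, "phase")
        with pytest.warns(UserWarning, match="instantaneous"):
            assert lagged_phase_coherence(coh) == 0.0

    def test_bounded_in_unit_interval(self, rng):
        for _ in range(200):
            re, im = rng.uniform(-0.99, 0.99), rng.uniform(-1, 1)
            if re**2 + im**2 >= 1:
                continue
            val = lagged_phase_coherence(
                CoherencyValue(0, 1, "alpha", complex(re, im), 10, 2, "phase"))
            assert 0.0 <= val < 1.0


class TestCoherency:
    def test_identical_signals_coherency_one(self, rng):
        x = bandpass_filter(rng.standard_normal(128 * 40), 8, 12, 128.0)
        cs = _cross_spectra(np.vstack([x, x]))
        c = complex_coherency(cs, 0, 1, "alpha", form="coherence")
        assert c.c == pytest.approx(1.0 + 0.0j, abs=1e-9)

    def test_quarter_period_delay_phase(self):
        # channel 2 delayed by a quarter period at 10 Hz -> |arg(c)| = pi/2,
        # positive under the S_xy = E[X conj(Y)] convention (x leads y)
        fs, f0 = 128.0, 10.0
        t = np.arange(int(fs * 60)) / fs
        rng = np.random.default_rng(0)
        x = np.sin(2 * np.pi * f0 * t + rng.uniform(0, 2 * np.pi))
        delay = int(round(fs / f0 / 4))
        y = np.roll(x, delay)
        cs = _cross_spectra(np.vstack([x, y]) + 0.01 * rng.standard_normal((2, x.size)))
        c = complex_coherency(cs, 0, 1, "alpha", form="coherence")
        assert np.angle(c.c) == pytest.approx(np.pi / 2, abs=0.2)

    def test_independent_noise_coherency_small(self, rng):
        cs = _cross_spectra(rng.standard_normal((2, 128 * 240)))
        c = complex_coherency(cs, 0, 1, "alpha")
        assert abs(c.c) < 0.15

    def test_same_channel_rejected(self, rng):
        cs = _cross_spectra(rng.standard_normal((2, 128 * 10)))
        with pytest.raises(ValueError, match="distinct"):
            complex_coherency(cs, 1, 1, "alpha")


class TestSignificance:
    def test_surrogate_p_uniform_under_independence(self, rng):
        pvals = []
        for i in range(60):
            cs = _cross_spectra(rng.standard_normal((2, 128 * 60)))
            _, p = lpc_significance(cs, 0, 1, "alpha", n_surrogates=100,
                                    seed=int(rng.integers(2**31)))
            pvals.append(p)
        rate = np.mean(np.asarray(pvals) < 0.2)
        assert 0.05 < rate < 0.4  # crude uniformity check at alpha=0.2

    def test_planted_lagged_coupling_detected(self, rng):
        fs = 128.0
        delay = int(round(fs / 10 / 4))  # 25 ms at 10 Hz
        detections = 0
        for i in range(10):
            x = bandpass_filter(rng.standard_normal(int(fs * 120)), 8, 12, fs)
            y = np.roll(x, delay) + 0.5 * bandpass_filter(
                rng.standard_normal(x.size), 8, 12, fs)
            cs = _cross_spectra(np.vstack([x, y]))
            _, p = lpc_significance(cs, 0, 1, "alpha", n_surrogates=200,
                                    seed=int(rng.integers(2**31)))
            detections += p < 0.05
        assert detections >= 9

    def test_asymptotic_matches_surrogate_roughly(self, rng):
        x = bandpass_filter(rng.standard_normal(128 * 120), 8, 12, 128.0)
        y = np.roll(x, 3) + bandpass_filter(rng.standard_normal(x.size), 8, 12, 128.0)
        cs = _cross_spectra(np.vstack([x, y]))
        v1, p_s = lpc_significance(cs, 0, 1, "alpha", n_surrogates=400, seed=0)
        v2, p_a = lpc_significance(cs, 0, 1, "alpha", method="asymptotic")
        assert v1 == v2
        assert (p_s < 0.05) == (p_a < 0.05)

    def test_too_few_epochs_rejected(self, rng):
        cs = _cross_spectra(rng.standard_normal((2, 128 * 16)))  # 4 epochs
        with pytest.raises(ValueError, match="8 epochs"):
            lpc_significance(cs, 0, 1, "alpha")

    def test_unknown_method_rejected(self, rng):
        cs = _cross_spectra(rng.standard_normal((2, 128 * 40)))
        with pytest.raises(ValueError, match="method"):
            lpc_significance(cs, 0, 1, "alpha", method="bootstrap")


class TestVolumeConductionContrast:
    def test_instantaneous_mixture_not_lagged_but_coherent(self, rng):
        # the defining contrast: mixtures of one source + noise show high
        # ordinary coherence but non-significant lagged phase coherence
        fs = 128.0
        n_sig, coh2 = 0, []
        for i in range(20):
            s = bandpass_filter(rng.standard_normal(int(fs * 60)), 8, 12, fs)
            n1 = 0.3 * bandpass_filter(rng.standard_normal(s.size), 8, 12, fs)
            n2 = 0.3 * bandpass_filter(rng.standard_normal(s.size), 8, 12, fs)
            data = np.vstack([1.0 * s + n1, 0.7 * s + n2])
            cs = _cross_spectra(data)
            c = complex_coherency(cs, 0, 1, "alpha", form="coherence")
            coh2.append(ordinary_coherence_sq(c))
            _, p = lpc_significance(cs, 0, 1, "alpha", n_surrogates=200,
                                    seed=int(rng.integers(2**31)))
            n_sig += p < 0.05
        assert np.mean(coh2) > 0.5
        assert n_sig <= 3

    def test_symmetry(self, rng):
        cs = _cross_spectra(rng.standard_normal((3, 128 * 40)))
        a = lagged_phase_coherence(complex_coherency(cs, 0, 2, "beta"))
        b = lagged_phase_coherence(complex_coherency(cs, 2, 0, "beta"))
        assert a == pytest.approx(b, abs=1e-15)


def test_lpc_table_long_format(rng):
    cs = _cross_spectra(rng.standard_normal((3, 128 * 60)))
    df = lpc_table(cs, n_surrogates=50, seed=0)
    assert set(df.columns) == {"roi_i", "roi_j", "band", "lpc", "p"}
    assert len(df) == 3 * 5  # 3 pairs x 5 bands
    assert ((df.lpc >= 0) & (df.lpc < 1)).all()
    assert ((df.p > 0) & (df.p <= 1)).all()
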