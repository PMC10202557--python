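"""Epoching and band-averaged Fourier cross-spectral matrices.

The recording is cut into non-overlapping tapered epochs; each epoch's
discrete Fourier transform yields per-bin cross-spectral matrices that are
averaged over epochs and over the Fourier bins inside each band.  The
per-epoch coefficients are retained so that phase-synchronization variants
(unit-modulus coefficients) and epoch-shuffling surrogates can be computed
without re-reading the data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import signal as _signal

from .bands import BandSpec, DEFAULT_BANDS, validate_bands
from .recording import EEGRecording

logger = logging.getLogger(__name__)


@dataclass
class BandCrossSpectra:
    """Per-band averaged cross-spectra and the per-epoch coefficients behind them.

    Attributes
    ----------
    S : dict band name -> (n_ch, n_ch) complex Hermitian matrix; bin-averaged
        cross-spectral density (power per Hz).
    coeffs : dict band name -> (n_epochs, n_bins, n_ch) complex DFT
        coefficients (density-scaled), for surrogate and phase-form use.
    df : frequency resolution in Hz (1 / epoch length).
    """

    S: dict[str, np.ndarray]
    coeffs: dict[str, np.ndarray]
    channel_labels: tuple[str, ...]
    bands: tuple[BandSpec, ...]
    n_epochs: int
    epoch_len_s: float
    df: float
    taper: str
    fs: float
    n_epochs_dropped: int = 0

    def n_bins(self, band: str) -> int:
        return self.coeffs[band].shape[1]

    def band_power(self, band: str) -> np.ndarray:
        """Per-channel band power (integrated spectral density, uV^2)."""
        return np.real(np.diag(self.S[band])) * self.n_bins(band) * self.df

    def phase_S(self, band: str) -> np.ndarray:
        """Cross-spectral matrix of unit-modulus (phase-only) coefficients."""
        c = self.coeffs[band]
        mag = np.abs(c)
        mag[mag == 0] = 1.0
        u = c / mag
        return np.einsum("ebi,ebj->ij", u, np.conj(u)) / (c.shape[0] * c.shape[1])


def _epoch_data(data: np.ndarray, fs: float, epoch_len_s: float,
                amp_reject_uv: float | None) -> tuple[np.ndarray, int]:
    nper = int(round(epoch_len_s * fs))
    n_full = data.shape[1] // nper
    if n_full < 1:
        raise ValueError("epoch length exceeds the recording length")
    epochs = data[:, : n_full * nper].reshape(data.shape[0], n_full, nper)
    epochs = np.moveaxis(epochs, 1, 0)  # (n_epochs, n_ch, nper)
    if amp_reject_uv is not None:
        keep = np.abs(epochs).max(axis=(1, 2)) <= amp_reject_uv
        dropped = int((~keep).sum())
        epochs = epochs[keep]
    else:
        dropped = 0
    return epochs, dropped


def epoch_and_cross_spectra(
    rec: EEGRecording,
    epoch_len_s: float = 4.0,
    bands: tuple[BandSpec, ...] = DEFAULT_BANDS,
    taper: str = "hann",
    amp_reject_uv: float | None = 100.0,
    check_reference: bool = True,
) -> BandCrossSpectra:
    """Cut into non-overlapping tapered epochs and average cross-spectra per band.

    Epochs whose absolute amplitude exceeds ``amp_reject_uv`` on any channel
    are dropped (an automatic stand-in for visual artifact review; pass
    ``None`` to disable).  At least two epochs must survive.
    """
    if check_reference and rec.reference != "common_average":
        raise ValueError("recording must be common-average referenced first "
                         "(or pass check_reference=False)")
    bands = validate_bands(bands)
    epochs, dropped = _epoch_data(rec.data, rec.fs, epoch_len_s, amp_reject_uv)
    n_epochs = epochs.shape[0]
    if dropped:
        logger.info("dropped %d/%d epochs above +/-%g uV", dropped, n_epochs + dropped,
                    amp_reject_uv)
    if n_epochs < 2:
        raise ValueError(f"need >= 2 epochs after artifact rejection, got {n_epochs}")

    nper = epochs.shape[2]
    if taper == "hann":
        win = _signal.windows.hann(nper, sym=False)
    elif taper in ("boxcar", "rect", "none"):
        win = np.ones(nper)
    else:
        raise ValueError(f"unknown taper {taper!r}")
    # density scaling: |X|^2 integrates to power per Hz (one-sided)
    scale = np.sqrt(2.0 / (rec.fs * np.sum(win**2)))
    X = np.fft.rfft(epochs * win[None, None, :], axis=2) * scale
    freqs = np.fft.rfftfreq(nper, 1.0 / rec.fs)

    S: dict[str, np.ndarray] = {}
    coeffs: dict[str, np.ndarray] = {}
    for band in bands:
        sel = (freqs >= band.lo) & (freqs < band.hi)
        if not sel.any():
            raise ValueError(
                f"band {band.name!r} contains no Fourier bins at df={freqs[1]:.3g} Hz; "
                "use longer epochs")
        c = np.moveaxis(X[:, :, sel], 1, 2)  # (n_epochs, n_bins, n_ch)
        coeffs[band.name] = c
        S[band.name] = np.einsum("ebi,ebj->ij", c, np.conj(c)) / (n_epochs * c.shape[1])

    return BandCrossSpectra(
        S=S, coeffs=coeffs, channel_labels=rec.channel_labels, bands=bands,
        n_epochs=n_epochs, epoch_len_s=epoch_len_s, df=float(freqs[1]),
        taper=taper, fs=rec.fs, n_epochs_dropped=dropped,
    )
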