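"""Canonical frequency bands for the 2-44 Hz resting-state analysis.

Bands are half-open intervals [lo, hi) so that adjacent bands never double
count a Fourier bin, and all lie inside the 2-44 Hz analysis range.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, ``[lo, hi)`` in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name!r}: lo must be < hi, got [{self.lo}, {self.hi})")
        if self.lo < 2.0 or self.hi > 44.0:
            raise ValueError(
                f"band {self.name!r} [{self.lo}, {self.hi}) lies outside the 2-44 Hz analysis range"
            )

    def contains(self, freq: float) -> bool:
        return self.lo <= freq < self.hi

    @property
    def center(self) -> float:
        return 0.5 * (self.lo + self.hi)


DELTA = BandSpec("delta", 2.0, 3.5)
THETA = BandSpec("theta", 4.0, 7.5)
ALPHA = BandSpec("alpha", 8.0, 12.0)
BETA = BandSpec("beta", 13.0, 30.0)
GAMMA = BandSpec("gamma", 30.5, 44.0)

DEFAULT_BANDS: tuple[BandSpec, ...] = (DELTA, THETA, ALPHA, BETA, GAMMA)

BAND_BY_NAME: dict[str, BandSpec] = {b.name: b for b in DEFAULT_BANDS}


def get_band(band: "str | BandSpec") -> BandSpec:
    """Resolve a band given by name or as a BandSpec instance."""
    if isinstance(band, BandSpec):
        return band
    try:
        return BAND_BY_NAME[band]
    except KeyError:
        raise KeyError(
            f"unknown band {band!r}; known bands: {sorted(BAND_BY_NAME)}"
        ) from None


def validate_bands(bands) -> tuple[BandSpec, ...]:
    """Check a band collection for overlap and return it as a tuple."""
    bands = tuple(get_band(b) for b in bands)
    ordered = sorted(bands, key=lambda b: b.lo)
    for a, b in zip(ordered, ordered[1:]):
        if b.lo < a.hi:
            raise ValueError(f"bands {a.name!r} and {b.name!r} overlap")
    return bands


def quarter_cycle_lag_ms(freq_hz: float) -> float:
    """Delay, in ms, of a quarter cycle at ``freq_hz``.

    This is the phase lag that separates a sine from its cosine counterpart:
    25 ms at 10 Hz, 12.5 ms at 20 Hz.  A nonzero lagged phase coherence at a
    given frequency indicates coherent oscillation at (multiples of) this
    kind of delay rather than instantaneous (volume-conducted) dependence.
    """
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 / (4.0 * freq_hz)


def period_ms(freq_hz: float) -> float:
    """Oscillation period in ms (100 ms at 10 Hz)."""
    if freq_hz <= 0:
        raise ValueError("frequency must be positive")
    return 1000.0 / freq_hz
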