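"""Frequency-band definitions.

Bands are half-open intervals [f_lo, f_hi) in Hz, so that the canonical
language-related set — theta (5–8), alpha (8–13), beta (13–25) and low
gamma (25–45) — tiles 5–45 Hz without double-counting any DFT bin.
Signals filtered into disjoint bands of this kind are exactly orthogonal
(Parseval), which is what makes cross-frequency envelope correlation
leakage-free by construction.
"""

from __future__ import annotations

from dataclasses import dataclass


class BandError(ValueError):
    """Raised for ill-formed or Nyquist-violating frequency bands."""


@dataclass(frozen=True)
class FrequencyBand:
    """A named half-open frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise BandError(
                f"band {self.name!r} requires 0 < f_lo < f_hi, "
                f"got [{self.f_lo}, {self.f_hi})"
            )

    @property
    def width(self) -> float:
        return self.f_hi - self.f_lo

    def check_nyquist(self, fs_hz: float) -> None:
        """Raise BandError unless the band lies strictly below Nyquist."""
        if self.f_hi >= fs_hz / 2:
            raise BandError(
                f"band {self.name!r} [{self.f_lo}, {self.f_hi}) Hz reaches "
                f"Nyquist ({fs_hz / 2} Hz at fs={fs_hz} Hz)"
            )


THETA = FrequencyBand("theta", 5.0, 8.0)
ALPHA = FrequencyBand("alpha", 8.0, 13.0)
BETA = FrequencyBand("beta", 13.0, 25.0)
LOW_GAMMA = FrequencyBand("low_gamma", 25.0, 45.0)

#: The canonical non-overlapping band set used throughout the pipeline.
CANONICAL_BANDS: tuple[FrequencyBand, ...] = (THETA, ALPHA, BETA, LOW_GAMMA)

BAND_BY_NAME = {b.name: b for b in CANONICAL_BANDS}


def get_band(band: "FrequencyBand | str") -> FrequencyBand:
    """Resolve a band given either a FrequencyBand or a canonical name."""
    if isinstance(band, FrequencyBand):
        return band
    try:
        return BAND_BY_NAME[band]
    except KeyError:
        raise BandError(
            f"unknown band name {band!r}; known: {sorted(BAND_BY_NAME)}"
        ) from None
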