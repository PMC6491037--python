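"""Frequency-band definitions for band-limited oscillatory analysis.

The canonical six-band scheme spans delta through high gamma.  A
:class:`BandSpec` is a named frequency interval; the defaults below are
the standard set used throughout the package, but any list of bands can
be supplied to the simulator and pipeline.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandSpec:
    """A named frequency band, ``f_low``–``f_high`` in Hz."""

    name: str
    f_low: float
    f_high: float

    def __post_init__(self) -> None:
        if not (0 < self.f_low < self.f_high):
            raise ValueError(
                f"band {self.name!r}: need 0 < f_low < f_high, "
                f"got [{self.f_low}, {self.f_high}]"
            )

    def check_nyquist(self, sampling_rate: float) -> None:
        """Raise if the band extends to or beyond the Nyquist frequency."""
        if self.f_high >= sampling_rate / 2:
            raise ValueError(
                f"band {self.name!r} upper edge {self.f_high} Hz is not below "
                f"Nyquist ({sampling_rate / 2} Hz at fs={sampling_rate} Hz)"
            )

    @property
    def bandwidth(self) -> float:
        return self.f_high - self.f_low


DELTA = BandSpec("Delta", 1.0, 4.0)
THETA = BandSpec("Theta", 3.0, 8.0)
ALPHA = BandSpec("Alpha", 8.0, 13.0)
BETA = BandSpec("Beta", 13.0, 30.0)
LOW_GAMMA = BandSpec("LowGamma", 40.0, 60.0)
HIGH_GAMMA = BandSpec("HighGamma", 60.0, 140.0)

#: The default six-band scheme (delta, theta, alpha, beta, low/high gamma).
DEFAULT_BANDS: tuple[BandSpec, ...] = (
    DELTA,
    THETA,
    ALPHA,
    BETA,
    LOW_GAMMA,
    HIGH_GAMMA,
)

#: Label used for the across-band vector-magnitude connectivity map.
COMBINED = "Combined"


def band_by_name(name: str, bands=DEFAULT_BANDS) -> BandSpec:
    for b in bands:
        if b.name == name:
            return b
    raise KeyError(f"no band named {name!r} among {[b.name for b in bands]}")
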