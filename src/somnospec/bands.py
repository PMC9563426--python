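"""Spectral band definitions used throughout the pipeline.

The quantified bands are non-contiguous by design: power in the gaps
(4-5, 10-11, 19-20, 30-40 and 100-130 Hz) is deliberately unassigned.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency interval with inclusive bounds in Hz."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not (0 < self.lo < self.hi):
            raise ValueError(
                f"band {self.name!r}: need 0 < lo < hi, got [{self.lo}, {self.hi}]"
            )

    def contains(self, freq_hz: float) -> bool:
        return self.lo <= freq_hz <= self.hi


DEFAULT_BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 0.5, 4.0),
    BandDefinition("theta", 5.0, 10.0),
    BandDefinition("spindle", 11.0, 19.0),
    BandDefinition("beta", 20.0, 30.0),
    BandDefinition("gamma", 40.0, 100.0),
    BandDefinition("ripple", 130.0, 180.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in DEFAULT_BANDS)


def band_by_name(name: str) -> BandDefinition:
    for b in DEFAULT_BANDS:
        if b.name == name:
            return b
    raise KeyError(name)


def band_of_frequency(freq_hz: float) -> str | None:
    """Name of the default band containing ``freq_hz``, or None if in a gap."""
    for b in DEFAULT_BANDS:
        if b.contains(freq_hz):
            return b.name
    return None
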