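"""Canonical EEG frequency bands and the power-ratio feature table.

The five bands follow the conventional clinical definitions used in
spectral EEG work: delta 1-4 Hz, theta 4-7 Hz, alpha 8-12 Hz, beta
13-29 Hz, gamma 30-50 Hz.  Intervals are half-open ``[low, high)`` and
the 7-8 Hz and 12-13 Hz gaps are real: a 1-Hz FFT bin falling there
belongs to no band.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class BandDefinition:
    """One frequency band: half-open interval ``[low, high)`` in Hz."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError(f"band {self.name}: low {self.low} must be < high {self.high}")

    @property
    def center(self) -> float:
        return 0.5 * (self.low + self.high)


#: The five analysis bands, in canonical low-to-high order.
BANDS: tuple[BandDefinition, ...] = (
    BandDefinition("delta", 1.0, 4.0),
    BandDefinition("theta", 4.0, 7.0),
    BandDefinition("alpha", 8.0, 12.0),
    BandDefinition("beta", 13.0, 29.0),
    BandDefinition("gamma", 30.0, 50.0),
)

BAND_NAMES: tuple[str, ...] = tuple(b.name for b in BANDS)
BAND_BY_NAME: dict[str, BandDefinition] = {b.name: b for b in BANDS}


@dataclass(frozen=True)
class RatioDescriptor:
    """An ordered band-power ratio numerator/denominator pair."""

    numerator: str
    denominator: str

    def __post_init__(self) -> None:
        for n in (self.numerator, self.denominator):
            if n not in BAND_BY_NAME:
                raise ValueError(f"unknown band {n!r}")
        if self.numerator == self.denominator:
            raise ValueError("ratio numerator and denominator must differ")

    @property
    def name(self) -> str:
        return f"{self.numerator}/{self.denominator}"

    @property
    def inverse(self) -> "RatioDescriptor":
        return RatioDescriptor(self.denominator, self.numerator)


def _ratio_table() -> tuple[RatioDescriptor, ...]:
    # Row-major order of the published ratio table: four rows of five,
    # each row pairing every band with delta, alpha, beta, gamma in turn.
    rows = [
        ("delta/theta", "theta/delta", "alpha/delta", "beta/delta", "gamma/delta"),
        ("delta/alpha", "theta/alpha", "alpha/theta", "beta/theta", "gamma/theta"),
        ("delta/beta", "theta/beta", "alpha/beta", "beta/alpha", "gamma/alpha"),
        ("delta/gamma", "theta/gamma", "alpha/gamma", "beta/gamma", "gamma/beta"),
    ]
    out = []
    for row in rows:
        for name in row:
            num, den = name.split("/")
            out.append(RatioDescriptor(num, den))
    return tuple(out)


#: The 20 ordered ratios (every ordered pair of distinct bands), in the
#: fixed table order used for feature naming.
RATIOS: tuple[RatioDescriptor, ...] = _ratio_table()

assert len(RATIOS) == 20 and len(set(r.name for r in RATIOS)) == 20
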