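"""Canonical frequency band definitions.

Five bands cover 1-80 Hz. Powerline interference windows are excluded from
the gamma band: 47.5-52.5 Hz (UK mains) for MEG, and additionally
57.5-62.5 Hz (US mains) for iEEG, whose normative cohort mixes both grids.
Band intervals are half-open [lo, hi); a frequency bin falling exactly on a
boundary belongs to the lower band.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

BAND_NAMES = ("delta", "theta", "alpha", "beta", "gamma")


@dataclass(frozen=True)
class BandDefinition:
    """A frequency band [lo, hi) in Hz with optional excluded sub-intervals."""

    name: str
    lo: float
    hi: float
    exclusions: tuple[tuple[float, float], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        if not self.lo < self.hi:
            raise ValueError(f"band {self.name}: lo must be < hi")
        for elo, ehi in self.exclusions:
            if not (self.lo <= elo < ehi <= self.hi):
                raise ValueError(
                    f"band {self.name}: exclusion ({elo}, {ehi}) not inside "
                    f"[{self.lo}, {self.hi}]"
                )

    def mask(self, freqs: np.ndarray) -> np.ndarray:
        """Boolean mask of frequency bins inside the band minus exclusions."""
        m = (freqs >= self.lo) & (freqs < self.hi)
        for elo, ehi in self.exclusions:
            m &= ~((freqs >= elo) & (freqs < ehi))
        return m


_MEG_GAMMA_EXCL = ((47.5, 52.5),)
_IEEG_GAMMA_EXCL = ((47.5, 52.5), (57.5, 62.5))


def canonical_bands(modality: str = "MEG") -> tuple[BandDefinition, ...]:
    """The five canonical bands for a modality.

    delta 1-4, theta 4-8, alpha 8-13, beta 13-30, gamma 30-80 Hz; gamma
    excludes powerline windows depending on modality ("MEG" or "iEEG").
    """
    mod = modality.lower()
    if mod == "meg":
        gamma_excl = _MEG_GAMMA_EXCL
    elif mod == "ieeg":
        gamma_excl = _IEEG_GAMMA_EXCL
    else:
        raise ValueError(f"unknown modality {modality!r}; expected 'MEG' or 'iEEG'")
    return (
        BandDefinition("delta", 1.0, 4.0),
        BandDefinition("theta", 4.0, 8.0),
        BandDefinition("alpha", 8.0, 13.0),
        BandDefinition("beta", 13.0, 30.0),
        BandDefinition("gamma", 30.0, 80.0, gamma_excl),
    )
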