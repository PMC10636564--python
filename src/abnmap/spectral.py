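"""Power spectral densities and relative band power.

Regional (or contact-level) source time series are reduced to power spectral
densities with Welch's method (2 s Hann windows, 1 s overlap, linear detrend
per window by default) and then to relative band power: the fraction of
spectral power each canonical band carries out of the total over the five
bands (1-80 Hz minus powerline exclusion windows). The five fractions per
entity form a composition summing to one, which makes them comparable across
subjects and recording scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal

from .bands import BAND_NAMES, BandDefinition, canonical_bands

__all__ = ["PSDTable", "welch_psd", "relative_band_power"]


@dataclass
class PSDTable:
    """One-sided power spectral densities, one row per entity.

    ``psd`` has shape (n_entities, n_freqs) with units of power per Hz;
    integrating a row over ``freqs`` approximates the signal variance.
    """

    entity_ids: list[str]
    freqs: np.ndarray
    psd: np.ndarray

    def __post_init__(self) -> None:
        self.freqs = np.asarray(self.freqs, dtype=float)
        self.psd = np.atleast_2d(np.asarray(self.psd, dtype=float))
        if self.psd.shape != (len(self.entity_ids), self.freqs.size):
            raise ValueError("psd shape does not match entity_ids x freqs")
        if np.any(self.psd < 0):
            raise ValueError("psd must be nonnegative")
        if np.any(np.diff(self.freqs) <= 0):
            raise ValueError("freqs must be strictly increasing")


def welch_psd(
    samples: np.ndarray,
    fs: float,
    entity_ids: Sequence[str] | None = None,
    window_s: float = 2.0,
    overlap_s: float = 1.0,
    detrend: str = "linear",
) -> PSDTable:
    """Welch PSD per entity (row) of a time-series matrix.

    Parameters
    ----------
    samples : array, shape (n_entities, n_samples) or (n_samples,)
        Signal values; arbitrary units.
    fs : float
        Sampling rate in Hz.
    window_s, overlap_s : float
        Sliding-window length and overlap in seconds. The frequency
        resolution is 1/window_s.
    detrend : str
        Per-window detrend mode passed to :func:`scipy.signal.welch`.
    """
    x = np.atleast_2d(np.asarray(samples, dtype=float))
    if entity_ids is None:
        entity_ids = [f"entity{i:03d}" for i in range(x.shape[0])]
    entity_ids = [str(e) for e in entity_ids]
    if len(entity_ids) != x.shape[0]:
        raise ValueError("entity_ids length does not match number of rows")
    if not np.isfinite(x).all():
        raise ValueError("non-finite samples in time series")
    if fs <= 0:
        raise ValueError("fs must be positive")
    if not 0 <= overlap_s < window_s:
        raise ValueError("require 0 <= overlap_s < window_s")
    nperseg = int(round(window_s * fs))
    if x.shape[1] < nperseg:
        raise ValueError(
            f"epoch too short: {x.shape[1] / fs:.3f} s of data, "
            f"window is {window_s} s"
        )
    noverlap = int(round(overlap_s * fs))
    freqs, psd = signal.welch(
        x,
        fs=fs,
        window="hann",
        nperseg=nperseg,
        noverlap=noverlap,
        detrend=detrend,
        scaling="density",
        axis=-1,
    )
    return PSDTable(entity_ids=list(entity_ids), freqs=freqs, psd=psd)


def relative_band_power(
    psd: PSDTable,
    bands: Sequence[BandDefinition] | None = None,
    modality: str = "MEG",
    log_power: bool = False,
) -> pd.DataFrame:
    """Relative band power per entity over the five canonical bands.

    Band power is the sum of PSD bins inside each band (half-open intervals,
    exclusion windows removed), divided by the total over all five bands so
    each row sums to one. ``log_power`` applies log10 to the PSD bins before
    summation (off by default).

    Returns a DataFrame indexed by entity id with columns
    delta/theta/alpha/beta/gamma and ``attrs["modality"]`` set.
    """
    if bands is None:
        bands = canonical_bands(modality)
    if len(bands) != len(BAND_NAMES):
        raise ValueError(f"expected {len(BAND_NAMES)} bands, got {len(bands)}")
    lo = min(b.lo for b in bands)
    hi = max(b.hi for b in bands)
    if psd.freqs[0] > lo or psd.freqs[-1] < hi - 1.0 / max(psd.freqs.size, 1):
        # require the grid to span the analysed range
        if psd.freqs[0] > lo or psd.freqs[-1] < bands[-1].lo:
            raise ValueError(
                f"PSD grid [{psd.freqs[0]}, {psd.freqs[-1]}] does not span "
                f"the band range [{lo}, {hi}] Hz"
            )
    values = psd.psd
    if log_power:
        # floor at a tiny positive value so empty bins do not produce -inf
        values = np.log10(np.maximum(values, np.finfo(float).tiny))
        values = values - values.min()  # keep band sums nonnegative
    power = np.column_stack(
        [values[:, band.mask(psd.freqs)].sum(axis=1) for band in bands]
    )
    total = power.sum(axis=1)
    bad = np.flatnonzero(total <= 0)
    if bad.size:
        raise ValueError(
            f"total band power is zero for entity {psd.entity_ids[bad[0]]!r}"
        )
    rbp = power / total[:, None]
    out = pd.DataFrame(rbp, index=pd.Index(psd.entity_ids, name="entity_id"),
                       columns=list(BAND_NAMES))
    out.attrs["modality"] = modality
    return out
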