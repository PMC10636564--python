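"""Normative band-power maps and patient abnormality maps.

A normative map holds, for every region x band, the mean and standard
deviation of relative band power across a healthy (MEG) or non-epileptic
(iEEG) reference cohort. A patient's abnormality map is the Z-score of their
regional band power against that baseline, summarised per region by the
maximum absolute Z across the five bands: a single nonnegative number per
region measuring how far the patient's spectrum deviates from normal in its
most deviant band.

The core fit/transform step is exposed as :class:`NormativeZScore`, a
scikit-learn compatible transformer over a subjects x features matrix;
:func:`build_normative_map` and :func:`abnormality_map` wrap it with the
domain's region/band bookkeeping, including iEEG contact-to-region
assignment and within-subject aggregation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .bands import BAND_NAMES

logger = logging.getLogger(__name__)

__all__ = [
    "Parcellation",
    "NormativeMap",
    "NormativeZScore",
    "assign_contacts",
    "aggregate_contacts_to_rois",
    "build_normative_map",
    "abnormality_map",
]

#: Relative floor applied to normative SDs: sd >= SD_FLOOR_REL * mean.
SD_FLOOR_REL = 1e-6


@dataclass(frozen=True)
class Parcellation:
    """An ordered set of cortical region labels with centroid coordinates (mm)."""

    roi_labels: tuple[str, ...]
    roi_centroids: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "roi_centroids",
                           np.asarray(self.roi_centroids, dtype=float))
        if len(set(self.roi_labels)) != len(self.roi_labels):
            raise ValueError("parcellation labels must be unique")
        if self.roi_centroids.shape != (len(self.roi_labels), 3):
            raise ValueError("centroids must have shape (n_rois, 3)")
        if not np.isfinite(self.roi_centroids).all():
            raise ValueError("centroids must be finite")

    @property
    def n_rois(self) -> int:
        return len(self.roi_labels)


class NormativeZScore(TransformerMixin, BaseEstimator):
    """Z-score features against a reference cohort's mean and sample SD.

    Fit on a reference matrix ``X`` of shape (n_subjects, n_features);
    ``transform`` maps new rows to ``(x - mean_) / scale_``. NaNs in the
    reference matrix mark features a subject does not contribute to (e.g.
    unimplanted regions); features with fewer than ``min_contributors``
    finite values are fitted as NaN and propagate NaN on transform.

    Parameters
    ----------
    sd_floor_rel : float
        Sample SDs below ``sd_floor_rel * |mean|`` are raised to that floor,
        preventing unbounded Z-scores on degenerate cohorts.
    min_contributors : int
        Minimum finite reference values required per feature.

    Attributes
    ----------
    mean_, scale_ : ndarray of shape (n_features,)
    n_contributors_ : ndarray of int
    """

    def __init__(self, sd_floor_rel: float = SD_FLOOR_REL,
                 min_contributors: int = 2):
        self.sd_floor_rel = sd_floor_rel
        self.min_contributors = min_contributors

    def fit(self, X, y=None):
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        import warnings as _warnings
        n = np.sum(np.isfinite(X), axis=0)
        with np.errstate(invalid="ignore"), _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(np.where(np.isfinite(X), X, np.nan), axis=0)
            sd = np.nanstd(np.where(np.isfinite(X), X, np.nan), axis=0, ddof=1)
        low = n < self.min_contributors
        if low.any():
            logger.warning("%d feature(s) have < %d contributors; excluded",
                           int(low.sum()), self.min_contributors)
            mean[low] = np.nan
            sd[low] = np.nan
        floor = self.sd_floor_rel * np.abs(mean)
        degenerate = np.isfinite(sd) & (sd < floor)
        if degenerate.any():
            logger.warning("%d feature(s) have degenerate spread; SD floored",
                           int(degenerate.sum()))
            sd = np.where(degenerate, floor, sd)
        if np.any(np.isfinite(sd) & (sd <= 0)):
            raise ValueError("zero SD after flooring (zero-mean feature)")
        self.mean_ = mean
        self.scale_ = sd
        self.n_contributors_ = n.astype(int)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X):
        check_is_fitted(self, "mean_")
        X = check_array(X, ensure_all_finite="allow-nan", dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError("feature count mismatch")
        return (X - self.mean_) / self.scale_


def assign_contacts(contacts: pd.DataFrame, parc: Parcellation) -> pd.DataFrame:
    """Assign each electrode contact to its nearest region centroid.

    ``contacts`` needs columns x, y, z (mm). Returns a copy with a ``roi``
    column set to the label minimising Euclidean distance; exact ties go to
    the label earlier in ``parc.roi_labels``.
    """
    if parc.n_rois == 0:
        raise ValueError("empty parcellation")
    xyz = contacts[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError("non-finite contact coordinates")
    d = cdist(xyz, parc.roi_centroids)
    idx = np.argmin(d, axis=1)  # argmin takes the first minimum: tie-break
    out = contacts.copy()
    out["roi"] = [parc.roi_labels[i] for i in idx]
    return out


def aggregate_contacts_to_rois(contacts: pd.DataFrame) -> pd.DataFrame:
    """Average contact-level band power within each assigned region.

    ``contacts`` needs a ``roi`` column and the five band columns. Returns a
    DataFrame indexed by roi with band columns (one row per implanted region).
    """
    missing = [c for c in ("roi", *BAND_NAMES) if c not in contacts.columns]
    if missing:
        raise ValueError(f"contact table missing columns: {missing}")
    return contacts.groupby("roi", sort=True)[list(BAND_NAMES)].mean()


@dataclass
class NormativeMap:
    """Per region x band normative mean/SD of relative band power.

    ``mean``, ``sd`` and ``n`` are DataFrames indexed by roi with the five
    band columns; regions excluded for lack of contributors carry NaN.
    """

    modality: str
    mean: pd.DataFrame
    sd: pd.DataFrame
    n: pd.DataFrame

    @property
    def roi_labels(self) -> list[str]:
        return list(self.mean.index)

    def to_tidy(self) -> pd.DataFrame:
        """Long-format table with columns roi, band, mean, sd, n."""
        frames = {"mean": self.mean, "sd": self.sd, "n": self.n}
        tidy = pd.concat(
            {k: v.stack(future_stack=True) for k, v in frames.items()}, axis=1
        ).reset_index()
        tidy.columns = ["roi", "band", "mean", "sd", "n"]
        return tidy.dropna(subset=["mean", "sd"])

    @classmethod
    def from_tidy(cls, tidy: pd.DataFrame, modality: str) -> "NormativeMap":
        piv = {
            col: tidy.pivot(index="roi", columns="band", values=col)
            .reindex(columns=list(BAND_NAMES))
            for col in ("mean", "sd", "n")
        }
        return cls(modality=modality, mean=piv["mean"], sd=piv["sd"],
                   n=piv["n"].fillna(0).astype(int))


def build_normative_map(
    tables: Mapping[str, pd.DataFrame],
    roi_of_entity: Mapping[str, str] | None = None,
    modality: str = "MEG",
    sd_floor_rel: float = SD_FLOOR_REL,
) -> NormativeMap:
    """Aggregate control band-power tables into a normative map.

    Each value in ``tables`` is one control subject's band-power table
    (entities x five bands). Entity ids are mapped to regions through
    ``roi_of_entity`` (identity if omitted); when a subject has several
    entities in one region (iEEG contacts) they are averaged within the
    subject first, so every subject contributes at most one value per
    (region, band). Cross-subject mean and sample SD (n-1) follow, with the
    relative SD floor of :class:`NormativeZScore`.
    """
    per_subject: dict[str, pd.DataFrame] = {}
    for subj, tbl in tables.items():
        t = tbl.copy()
        if roi_of_entity is not None:
            t.index = pd.Index([roi_of_entity[e] for e in t.index], name="roi")
        t = t.groupby(level=0, sort=True)[list(BAND_NAMES)].mean()
        per_subject[subj] = t
    all_rois = sorted(set().union(*(t.index for t in per_subject.values())))
    # wide matrix: one row per subject, one column per (roi, band); NaN where
    # a subject has no data for that region
    cols = pd.MultiIndex.from_product([all_rois, list(BAND_NAMES)],
                                      names=["roi", "band"])
    wide = pd.DataFrame(
        {s: t.reindex(all_rois).to_numpy().ravel() for s, t in per_subject.items()},
        index=cols,
    ).T
    zs = NormativeZScore(sd_floor_rel=sd_floor_rel).fit(wide.to_numpy())
    shape = (len(all_rois), len(BAND_NAMES))
    idx = pd.Index(all_rois, name="roi")
    band_idx = pd.Index(list(BAND_NAMES), name="band")
    mk = lambda v: pd.DataFrame(v.reshape(shape), index=idx, columns=band_idx)
    return NormativeMap(
        modality=modality,
        mean=mk(zs.mean_),
        sd=mk(zs.scale_),
        n=mk(zs.n_contributors_.astype(float)).astype(int),
    )


def abnormality_map(patient: pd.DataFrame, norm: NormativeMap) -> pd.DataFrame:
    """Z-score a patient band-power table against a normative map.

    ``patient`` is indexed by region (aggregate contacts first for iEEG).
    Returns a DataFrame indexed by region with the five per-band signed
    Z-scores plus ``max_abs_z``. Regions absent from the normative map (or
    excluded there) are dropped and logged.
    """
    bands = list(BAND_NAMES)
    pos = norm.mean.index.get_indexer(patient.index)
    present = pos >= 0
    if not present.all():
        logger.warning("dropping %d region(s) missing from normative map: %s",
                       int((~present).sum()),
                       list(patient.index[~present][:5]))
    if not present.any():
        raise ValueError("no patient regions overlap the normative map")
    p = patient.loc[present, bands].to_numpy(dtype=float)
    mu = norm.mean[bands].to_numpy(dtype=float)[pos[present]]
    sd = norm.sd[bands].to_numpy(dtype=float)[pos[present]]
    if np.any(sd <= 0):
        raise ValueError("normative SD <= 0 encountered")
    z = (p - mu) / sd
    keep = np.isfinite(z).all(axis=1)
    if not keep.all():
        logger.warning("dropping %d region(s) with excluded normative entries",
                       int((~keep).sum()))
    out = pd.DataFrame(z[keep], index=patient.index[present][keep],
                       columns=bands)
    out["max_abs_z"] = np.abs(z[keep]).max(axis=1)
    return out
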