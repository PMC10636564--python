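"""Localization rank statistics: abnormality coverage and DRS.

Both statistics are Mann-Whitney AUCs over regional abnormality values.

- Abnormality coverage asks whether implanted (electrode-covered) regions
  carry higher MEG abnormality than unimplanted regions: 1 means electrodes
  sampled exclusively the most abnormal neocortex, 0.5 is chance.
- DRS (distinguishability of resected vs spared tissue) asks whether the
  resected regions were the most abnormal of the sampled tissue; it is
  1 - AUC(resected vs spared), so 0 means the strongest abnormalities were
  resected. DRS is evaluated only on tissue with joint MEG and electrode
  coverage.

Resection masks come from either MRI volumetry (region resected if its
volume shrank by more than 10%) or electrode bookkeeping (region resected
if more than 25% of its contacts were resected); both thresholds are strict.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "rank_auc",
    "abnormality_coverage",
    "drs",
    "resection_from_volumes",
    "resection_from_contacts",
    "SubjectFeatures",
]

FEATURE_COLUMNS = ("abnormality_coverage", "drs_meg", "drs_ieeg")


@dataclass(frozen=True)
class SubjectFeatures:
    """Per-patient localization measures and surgical outcome.

    ``ilae`` is the 1-year ILAE class; 1 means completely seizure-free.
    """

    subject_id: str
    abnormality_coverage: float
    drs_meg: float
    drs_ieeg: float
    ilae: int

    def __post_init__(self) -> None:
        for name in FEATURE_COLUMNS:
            v = getattr(self, name)
            if not (np.isfinite(v) and 0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if self.ilae < 1:
            raise ValueError("ILAE class must be >= 1")

    @property
    def seizure_free(self) -> bool:
        return self.ilae == 1


def rank_auc(values_pos: Sequence[float], values_neg: Sequence[float]) -> float:
    """Mann-Whitney AUC: P(pos > neg) + 0.5 * P(pos = neg) over all pairs.

    Equals the area under the empirical ROC curve with the positive group's
    values as scores; ties receive half credit.
    """
    pos = np.asarray(values_pos, dtype=float)
    neg = np.asarray(values_neg, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("undefined AUC: empty group")
    if not (np.isfinite(pos).all() and np.isfinite(neg).all()):
        raise ValueError("undefined AUC: non-finite values")
    # midrank formulation: U = sum of pos ranks - n_pos(n_pos+1)/2
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def abnormality_coverage(abn: pd.DataFrame, covered: Sequence[str]) -> float:
    """AUC of electrode-covered vs uncovered regional MEG abnormality.

    ``abn`` is an abnormality map over the full parcellation with a
    ``max_abs_z`` column; ``covered`` the implanted region labels. Requires
    a non-empty strict subset of regions to be covered.
    """
    covered = set(covered)
    labels = list(abn.index)
    unknown = covered - set(labels)
    if unknown:
        raise ValueError(f"covered regions not in abnormality map: {sorted(unknown)[:5]}")
    pos = [r for r in labels if r in covered]
    neg = [r for r in labels if r not in covered]
    if not pos or not neg:
        raise ValueError("coverage AUC undefined: covered set must be a "
                         "non-empty strict subset of the parcellation")
    z = abn["max_abs_z"]
    return rank_auc(z.loc[pos].to_numpy(), z.loc[neg].to_numpy())


def drs(abn: pd.DataFrame, resected: Sequence[str],
        restrict_to: Sequence[str] | None = None,
        subject_id: str = "?") -> float:
    """Distinguishability of resected vs spared tissue by abnormality.

    ``1 - AUC`` with the resected regions as positives, computed after
    restricting both sets to ``restrict_to`` (the jointly sampled tissue).
    0 means every resected region was more abnormal than every spared one.
    """
    resected = set(resected)
    if restrict_to is None:
        universe = [r for r in abn.index]
    else:
        universe = [r for r in abn.index if r in set(restrict_to)]
    res = [r for r in universe if r in resected]
    spa = [r for r in universe if r not in resected]
    if not res or not spa:
        raise ValueError(
            f"DRS undefined for subject {subject_id}: "
            f"{'resected' if not res else 'spared'} set empty after restriction"
        )
    z = abn["max_abs_z"]
    return 1.0 - rank_auc(z.loc[res].to_numpy(), z.loc[spa].to_numpy())


def resection_from_volumes(vols: pd.DataFrame, threshold: float = 0.10) -> list[str]:
    """Regions whose pre-to-post volume loss strictly exceeds ``threshold``.

    ``vols`` is indexed by region with columns pre_volume, post_volume
    (mm^3). Growth or registration noise (negative loss) never counts.
    """
    pre = vols["pre_volume"].to_numpy(dtype=float)
    post = vols["post_volume"].to_numpy(dtype=float)
    if np.any(pre <= 0):
        raise ValueError("pre_volume must be positive")
    if np.any(post < 0):
        raise ValueError("post_volume must be nonnegative")
    change = (pre - post) / pre
    return [r for r, c in zip(vols.index, change) if c > threshold]


def resection_from_contacts(contacts: pd.DataFrame,
                            threshold: float = 0.25) -> list[str]:
    """Regions where strictly more than ``threshold`` of contacts were resected.

    ``contacts`` needs ``roi`` (assigned) and ``resected`` (0/1) columns.
    Regions with no contacts simply do not appear.
    """
    if contacts["roi"].isna().any():
        raise ValueError("all contacts must be assigned to a region")
    frac = contacts.groupby("roi")["resected"].mean()
    return sorted(frac.index[frac > threshold])
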