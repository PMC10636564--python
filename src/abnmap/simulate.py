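"""Synthetic cohorts with the statistical structure the analysis assumes.

No raw patient or control recordings are redistributable, so every pipeline
stage is exercised on simulated data whose generative law mirrors the study
design: a healthy cohort of regional band-power compositions, patients with
a contiguous epileptogenic zone (EZ) whose band composition is shifted to a
target abnormality |Z|, electrode implantations preferentially targeting the
truly abnormal regions, resections preferentially removing the most abnormal
sampled tissue, and seizure-freedom labels tied to whether the EZ was
resected.

Key dials (see :class:`CohortSimConfig`): targeting quality ``tau`` (the
probability each implantation slot is directed at a ground-truth EZ region),
resection quality ``rho`` (how strongly the resected set follows measured
abnormality rather than noise) and label noise ``eps`` (probability the
deterministic outcome is flipped). Band-power rows are drawn from a
Dirichlet law around a base spectrum, the only hard constraint being
compositionality (rows sum to one).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .bands import BAND_NAMES, canonical_bands
from .normative import (NormativeMap, Parcellation, abnormality_map,
                        build_normative_map)

__all__ = [
    "CohortSimConfig",
    "GroundTruth",
    "SimulatedCohort",
    "synthetic_parcellation",
    "simulate_cohort",
    "simulate_timeseries",
    "recover_parameters",
]

_LOBES = ("frontal", "temporal", "parietal", "occipital", "cingulate",
          "insula", "precentral", "postcentral")


def synthetic_parcellation(n_rois: int = 114) -> Parcellation:
    """A deterministic stand-in parcellation (synthetic geometry).

    Labels mimic a two-hemisphere neocortical scheme; centroids lie on a
    ring so that 'adjacent' regions are consecutive labels (used for EZ
    contiguity). Real cortical geometry is not required by any consumer.
    """
    labels = []
    half = (n_rois + 1) // 2
    for i in range(n_rois):
        hemi = "lh" if i < half else "rh"
        j = i if i < half else i - half
        lobe = _LOBES[j % len(_LOBES)]
        labels.append(f"{hemi}_{lobe}_{j // len(_LOBES) + 1:02d}")
    theta = 2.0 * np.pi * np.arange(n_rois) / n_rois
    centroids = np.column_stack([
        60.0 * np.cos(theta),
        60.0 * np.sin(theta),
        15.0 * np.sin(3.0 * theta),
    ])
    return Parcellation(tuple(labels), centroids)


@dataclass(frozen=True)
class CohortSimConfig:
    """Study-shaped simulation settings.

    Cohort sizes default to the study design (70 healthy MEG controls, a
    234-subject iEEG normative cohort, 32 surgical patients over 114
    neocortical regions). ``base_spectrum`` is a resting-state-like
    composition dominated by low frequencies; ``control_dispersion`` is the
    Dirichlet concentration (higher = tighter healthy variability).
    """

    seed: int = 0
    n_controls: int = 70
    n_patients: int = 32
    n_rois: int = 114
    base_spectrum: tuple[float, ...] = (0.35, 0.20, 0.20, 0.15, 0.10)
    control_dispersion: float = 150.0
    ez_size: int = 6
    effect_size_z: float = 4.0
    targeting_tau: float = 0.75
    targeting_concentration: float = 2.0
    n_implanted: int = 16
    resection_quality_rho: float = 0.85
    resection_margin: int = 0
    outcome_noise_eps: float = 0.1
    n_ieeg_norm_subjects: int = 234
    rois_per_norm_subject: int = 15
    contacts_per_roi: int = 4
    outcome_law: str = "flip"  # "flip" or "logistic"

    def __post_init__(self) -> None:
        if abs(sum(self.base_spectrum) - 1.0) > 1e-9 or min(self.base_spectrum) < 0:
            raise ValueError("base_spectrum must be 5 nonnegative fractions summing to 1")
        if len(self.base_spectrum) != len(BAND_NAMES):
            raise ValueError("base_spectrum needs one fraction per band")
        if not (0 < self.ez_size < self.n_rois):
            raise ValueError("require 0 < ez_size < n_rois")
        if not (0 < self.n_implanted < self.n_rois):
            raise ValueError("require 0 < n_implanted < n_rois")
        for name in ("targeting_tau", "resection_quality_rho"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0.0 <= self.outcome_noise_eps <= 0.5:
            raise ValueError("outcome_noise_eps must lie in [0, 0.5]")
        if self.outcome_law not in ("flip", "logistic"):
            raise ValueError("outcome_law must be 'flip' or 'logistic'")


@dataclass(frozen=True)
class GroundTruth:
    """Per-patient generative truth for recovery checks."""

    ez_rois: tuple[str, ...]
    implanted_rois: tuple[str, ...]
    resected_rois: tuple[str, ...]
    latent_p_seizure_free: float
    ilae: int


@dataclass
class SimulatedCohort:
    """Everything a full study run consumes, plus the generative truth."""

    config: CohortSimConfig
    parcellation: Parcellation
    control_meg: dict[str, pd.DataFrame]
    ieeg_norm_tables: dict[str, pd.DataFrame]
    ieeg_norm_roi_of_entity: dict[str, str]
    patient_meg: dict[str, pd.DataFrame]
    patient_contacts: dict[str, pd.DataFrame]
    patient_volumes: dict[str, pd.DataFrame]
    outcomes: pd.Series
    ground_truth: dict[str, GroundTruth] = field(default_factory=dict)


def _dirichlet_rows(rng: np.random.Generator, alpha: np.ndarray,
                    n_rows: int) -> np.ndarray:
    return rng.dirichlet(alpha, size=n_rows)


def _inject_effect(rows: np.ndarray, ez_idx: np.ndarray, band: int,
                   shift: float) -> np.ndarray:
    """Shift one band's fraction in the EZ rows, renormalizing the rest."""
    out = rows.copy()
    old = out[ez_idx, band]
    new = np.clip(old + shift, None, 0.97)
    scale = (1.0 - new) / (1.0 - old)
    out[ez_idx, :] *= scale[:, None]
    out[ez_idx, band] = new
    return out


def simulate_cohort(cfg: CohortSimConfig) -> SimulatedCohort:
    """Draw a full synthetic study cohort, reproducible from ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    parc = synthetic_parcellation(cfg.n_rois)
    labels = np.array(parc.roi_labels)
    bands = list(BAND_NAMES)
    alpha = np.asarray(cfg.base_spectrum) * cfg.control_dispersion

    # --- healthy MEG controls: one composition per region per subject
    control_meg = {
        f"control{i:03d}": pd.DataFrame(
            _dirichlet_rows(rng, alpha, cfg.n_rois),
            index=pd.Index(labels, name="roi"), columns=bands)
        for i in range(cfg.n_controls)
    }

    # analytic per-band SD of the Dirichlet law, used to size the injected effect
    p = np.asarray(cfg.base_spectrum)
    band_sd = np.sqrt(p * (1 - p) / (cfg.control_dispersion + 1.0))

    # --- iEEG normative cohort: contact-level tables over random regions
    ieeg_norm_tables: dict[str, pd.DataFrame] = {}
    ieeg_roi_of_entity: dict[str, str] = {}
    for i in range(cfg.n_ieeg_norm_subjects):
        sid = f"norm{i:03d}"
        rois = rng.choice(cfg.n_rois, size=cfg.rois_per_norm_subject,
                          replace=False)
        vals = _dirichlet_rows(rng, alpha, cfg.rois_per_norm_subject)
        cids = [f"{sid}_c{k:02d}" for k in range(cfg.rois_per_norm_subject)]
        ieeg_norm_tables[sid] = pd.DataFrame(
            vals, index=pd.Index(cids, name="entity_id"), columns=bands)
        for cid, r in zip(cids, rois):
            ieeg_roi_of_entity[cid] = labels[r]

    # --- patients
    patient_meg: dict[str, pd.DataFrame] = {}
    patient_contacts: dict[str, pd.DataFrame] = {}
    patient_volumes: dict[str, pd.DataFrame] = {}
    outcomes: dict[str, int] = {}
    ground_truth: dict[str, GroundTruth] = {}
    for i in range(cfg.n_patients):
        pid = f"patient{i:03d}"
        start = int(rng.integers(cfg.n_rois))
        ez_idx = (start + np.arange(cfg.ez_size)) % cfg.n_rois
        band = int(rng.integers(len(bands)))
        shift = cfg.effect_size_z * band_sd[band]
        rows = _inject_effect(_dirichlet_rows(rng, alpha, cfg.n_rois),
                              ez_idx, band, shift)
        meg = pd.DataFrame(rows, index=pd.Index(labels, name="roi"),
                           columns=bands)
        patient_meg[pid] = meg

        # implantation: each patient's presurgical hypothesis has a quality
        # q ~ Beta centred on tau; q of the true-abnormal (EZ) regions are
        # targeted in expectation, the remaining slots sample uniformly.
        # tau = 1 targets the whole EZ surely, tau = 0 never targets it.
        ez_set = set(int(j) for j in ez_idx)
        if cfg.targeting_tau in (0.0, 1.0):
            q = cfg.targeting_tau
        else:
            kappa = cfg.targeting_concentration
            q = rng.beta(kappa * cfg.targeting_tau,
                         kappa * (1.0 - cfg.targeting_tau))
        n_ez_target = int(rng.binomial(min(cfg.ez_size, cfg.n_implanted), q))
        targeted = rng.choice(np.array(sorted(ez_set)), size=n_ez_target,
                              replace=False)
        pool = np.array(sorted(set(range(cfg.n_rois)) - set(int(t) for t in targeted)))
        extra = rng.choice(pool, size=cfg.n_implanted - n_ez_target,
                           replace=False)
        implanted_arr = np.array(sorted([*targeted, *extra]))

        # resection: the surgical decision has its own per-patient quality
        # r ~ Beta centred on rho, blending the true (EZ) abnormality rank
        # with noise; the ez_size strongest candidates plus a margin are
        # resected (tissue outside electrode coverage never is). Measured
        # abnormality maps are the evaluation instrument, not the decision.
        in_ez = np.isin(implanted_arr, np.fromiter(ez_set, int))
        a_norm = rankdata(in_ez.astype(float)) / implanted_arr.size
        if cfg.resection_quality_rho in (0.0, 1.0):
            r = cfg.resection_quality_rho
        else:
            kappa = cfg.targeting_concentration
            r = rng.beta(kappa * cfg.resection_quality_rho,
                         kappa * (1.0 - cfg.resection_quality_rho))
        score = r * a_norm + (1.0 - r) * rng.random(implanted_arr.size)
        k = min(cfg.ez_size + cfg.resection_margin, implanted_arr.size - 1)
        resected = implanted_arr[np.argsort(score)[::-1][:k]]
        resected_set = set(int(r) for r in resected)

        # volumes consistent with the MRI resection rule (>10% loss)
        pre = 1200.0 + 600.0 * rng.random(cfg.n_rois)
        loss = rng.uniform(-0.05, 0.05, size=cfg.n_rois)
        loss[list(resected_set)] = rng.uniform(0.3, 0.6, size=len(resected_set))
        patient_volumes[pid] = pd.DataFrame(
            {"pre_volume": pre, "post_volume": pre * (1.0 - loss)},
            index=pd.Index(labels, name="roi"))

        # iEEG contacts: a few per implanted region, jittered around the
        # centroid; band power shares the patient's EZ effect
        recs = []
        c = 0
        for ridx in implanted_arr:
            n_c = cfg.contacts_per_roi
            jitter = rng.normal(0.0, 1.0, size=(n_c, 3))
            coords = parc.roi_centroids[ridx] + jitter
            vals = _dirichlet_rows(rng, alpha, n_c)
            if ridx in set(int(j) for j in ez_idx):
                vals = _inject_effect(vals, np.arange(n_c), band, shift)
            in_res = ridx in resected_set
            for m in range(n_c):
                flag = rng.random() < (0.9 if in_res else 0.05)
                recs.append({
                    "contact_id": f"{pid}_c{c:03d}",
                    "x": coords[m, 0], "y": coords[m, 1], "z": coords[m, 2],
                    "resected": int(flag), "roi": labels[ridx],
                    **{bn: vals[m, j] for j, bn in enumerate(bands)},
                })
                c += 1
        patient_contacts[pid] = pd.DataFrame(recs).set_index("contact_id")

        # outcome: seizure-free iff the EZ was fully resected, noise-flipped
        ez_resected = set(int(j) for j in ez_idx) <= resected_set
        if cfg.outcome_law == "flip":
            latent_p = 1.0 - cfg.outcome_noise_eps if ez_resected else cfg.outcome_noise_eps
            sf = rng.random() < latent_p
        else:
            frac_impl = len(ez_set & set(int(j) for j in implanted_arr)) / cfg.ez_size
            frac_res = len(set(int(j) for j in ez_idx) & resected_set) / cfg.ez_size
            latent_p = 1.0 / (1.0 + np.exp(-(-5.0 + 4.0 * frac_impl + 6.0 * frac_res)))
            sf = rng.random() < latent_p
        outcomes[pid] = 1 if sf else 2
        ground_truth[pid] = GroundTruth(
            ez_rois=tuple(labels[ez_idx]),
            implanted_rois=tuple(labels[implanted_arr]),
            resected_rois=tuple(labels[sorted(resected_set)]),
            latent_p_seizure_free=float(latent_p),
            ilae=outcomes[pid],
        )

    return SimulatedCohort(
        config=cfg,
        parcellation=parc,
        control_meg=control_meg,
        ieeg_norm_tables=ieeg_norm_tables,
        ieeg_norm_roi_of_entity=ieeg_roi_of_entity,
        patient_meg=patient_meg,
        patient_contacts=patient_contacts,
        patient_volumes=patient_volumes,
        outcomes=pd.Series(outcomes, name="ilae"),
        ground_truth=ground_truth,
    )


def simulate_timeseries(
    target_rbp: Sequence[float],
    fs: float = 600.0,
    duration: float = 70.0,
    seed: int | None = None,
    modality: str = "MEG",
    tone_50hz_ratio: float = 0.0,
) -> np.ndarray:
    """Band-limited Gaussian noise with prescribed relative band power.

    Builds one signal as a sum of independent noise components, each
    confined (by Fourier masking) to one canonical band minus its exclusion
    windows. Component powers are calibrated against the analysis definition
    itself: the per-band Welch powers (2 s Hann windows, 1 s overlap, linear
    detrend) of every component form a leakage matrix, and the component
    scales solve a non-negative least-squares fit of that matrix to the
    targets, so the recovered relative band power matches ``target_rbp``
    despite window leakage across band boundaries. ``tone_50hz_ratio``
    optionally adds a 50 Hz sinusoid with the stated power relative to the
    broadband total, to exercise the powerline exclusion windows downstream.
    """
    from scipy.optimize import nnls

    from .spectral import welch_psd
    targets = np.asarray(target_rbp, dtype=float)
    if targets.size != len(BAND_NAMES) or np.any(targets < 0) or \
            abs(targets.sum() - 1.0) > 1e-9:
        raise ValueError("target_rbp must be 5 nonnegative fractions summing to 1")
    if duration < 10.0:
        raise ValueError("duration must be at least 10 s")
    rng = np.random.default_rng(seed)
    n = int(round(duration * fs))
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    x = np.zeros(n)
    window_s = min(2.0, duration / 2.0)
    bands = canonical_bands(modality)
    comps: list[np.ndarray] = []
    active: list[int] = []
    leak_rows: list[np.ndarray] = []
    for bi, (target, band) in enumerate(zip(targets, bands)):
        if target == 0:
            continue
        spec = np.fft.rfft(rng.standard_normal(n))
        # trim one Welch bin-width off the top edge: band intervals are
        # half-open, so content just below the boundary would otherwise
        # leak into the boundary bin owned by the band above
        mask = band.mask(freqs) & (freqs < band.hi - 1.0 / window_s)
        spec[~mask] = 0.0
        comp = np.fft.irfft(spec, n)
        psd = welch_psd(comp, fs=fs, window_s=window_s,
                        overlap_s=window_s / 2.0)
        df = psd.freqs[1] - psd.freqs[0]
        row = np.array([psd.psd[0, b.mask(psd.freqs)].sum() * df
                        for b in bands])
        if row[bi] <= 0:
            raise ValueError(f"band {band.name} has no frequency support")
        comps.append(comp)
        active.append(bi)
        leak_rows.append(row)
    # per-component power scales: nnls fit of the leakage matrix to the
    # targets, so the mixture's Welch band powers reproduce the composition
    leak = np.array(leak_rows)  # (n_active, n_bands)
    scales, _ = nnls(leak.T, targets)
    for comp, s in zip(comps, scales):
        x += comp * np.sqrt(s)
    if tone_50hz_ratio > 0:
        t = np.arange(n) / fs
        x += np.sqrt(2.0 * tone_50hz_ratio) * np.sin(2.0 * np.pi * 50.0 * t)
    return x


def recover_parameters(cfg: CohortSimConfig) -> dict:
    """Run the full analysis on a simulated cohort and summarize recovery.

    Returns the group statistics the study design defines: per-feature
    outcome-group AUCs, the one-sample t of seizure-free coverage against
    chance, the combined weighted-logistic model's in-sample AUC and its
    leave-one-out summary, plus cohort bookkeeping.
    """
    from .pipeline import analyze_cohort  # late import; pipeline builds on this module

    cohort = simulate_cohort(cfg)
    return analyze_cohort(cohort)
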