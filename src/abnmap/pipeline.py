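"""End-to-end study pipeline: normative maps -> abnormality -> metrics -> model.

`analyze_cohort` takes a full cohort (simulated or loaded from disk) and
computes every patient's abnormality coverage and DRS measures, the group
statistics, the class-weighted logistic outcome model, its nomogram and the
leave-one-out summary. Patients whose resected or spared set is empty after
restriction to sampled tissue are excluded from the feature table and
counted in the report rather than failing the whole run.

`run_pipeline` wraps this with configuration, file output (features.tsv,
model.json, nomogram.tsv, stats.json) and an optional sensitivity sweep
over resection thresholds.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .metrics import (FEATURE_COLUMNS, abnormality_coverage, drs,
                      resection_from_contacts, resection_from_volumes)
from .normative import (abnormality_map, aggregate_contacts_to_rois,
                        assign_contacts, build_normative_map)
from .outcome import (build_nomogram, fit_weighted_logistic, loo_auc,
                      mann_whitney_auc_greater, one_sample_t_greater, rank_auc)

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "compute_features", "analyze_cohort",
           "run_pipeline"]


@dataclass
class PipelineConfig:
    """Fixed constants and switches of a pipeline run.

    ``mri_thresholds`` / ``contact_thresholds`` hold the fractional volume
    loss (default 0.10) and resected-contact fraction (default 0.25) above
    which a region counts as resected; several values trigger a sensitivity
    sweep with one stats report per combination.
    """

    seed: int = 0
    simulate: bool = True
    input_dir: str | None = None
    window_s: float = 2.0
    overlap_s: float = 1.0
    mri_thresholds: tuple[float, ...] = (0.10,)
    contact_thresholds: tuple[float, ...] = (0.25,)
    sd_floor_rel: float = 1e-6
    loo_heldout: bool = False
    sim: dict = field(default_factory=dict)  # CohortSimConfig overrides

    def __post_init__(self) -> None:
        for t in (*self.mri_thresholds, *self.contact_thresholds):
            if not 0.0 < t < 1.0:
                raise ValueError(f"resection threshold {t} outside (0, 1)")

    def to_dict(self) -> dict:
        return asdict(self)


def compute_features(cohort, mri_threshold: float = 0.10,
                     contact_threshold: float = 0.25,
                     sd_floor_rel: float = 1e-6) -> dict:
    """Per-patient abnormality coverage and DRS measures for a cohort.

    Builds both normative maps, Z-scores every patient against them and
    derives the three localization features plus the ILAE outcome. Returns
    a dict with the feature table, the normative maps, the patient MEG
    abnormality maps and the excluded-subject log.
    """
    meg_norm = build_normative_map(cohort.control_meg, modality="MEG",
                                   sd_floor_rel=sd_floor_rel)
    ieeg_norm = build_normative_map(cohort.ieeg_norm_tables,
                                    roi_of_entity=cohort.ieeg_norm_roi_of_entity,
                                    modality="iEEG", sd_floor_rel=sd_floor_rel)
    logger.info("normative maps built: MEG %d controls, iEEG %d subjects",
                len(cohort.control_meg), len(cohort.ieeg_norm_tables))

    rows = []
    excluded: dict[str, str] = {}
    abn_meg_maps: dict[str, pd.DataFrame] = {}
    for pid, meg in cohort.patient_meg.items():
        try:
            contacts = cohort.patient_contacts[pid]
            if "roi" not in contacts.columns or contacts["roi"].isna().any():
                contacts = assign_contacts(contacts, cohort.parcellation)
            implanted = sorted(contacts["roi"].unique())
            abn_meg = abnormality_map(meg, meg_norm)
            abn_meg_maps[pid] = abn_meg
            coverage = abnormality_coverage(abn_meg, implanted)
            abn_ieeg = abnormality_map(aggregate_contacts_to_rois(contacts),
                                       ieeg_norm)
            mri_mask = resection_from_volumes(cohort.patient_volumes[pid],
                                              threshold=mri_threshold)
            ieeg_mask = resection_from_contacts(contacts,
                                                threshold=contact_threshold)
            drs_meg = drs(abn_meg, mri_mask, restrict_to=implanted,
                          subject_id=pid)
            drs_ieeg = drs(abn_ieeg, ieeg_mask, restrict_to=implanted,
                           subject_id=pid)
        except ValueError as err:
            logger.warning("excluding subject %s: %s", pid, err)
            excluded[pid] = str(err)
            continue
        rows.append({"subject_id": pid, "abnormality_coverage": coverage,
                     "drs_meg": drs_meg, "drs_ieeg": drs_ieeg,
                     "ilae": int(cohort.outcomes[pid])})
    features = pd.DataFrame(rows).set_index("subject_id")
    return {"features": features, "meg_norm": meg_norm,
            "ieeg_norm": ieeg_norm, "abnormality_meg": abn_meg_maps,
            "excluded": excluded}


def analyze_cohort(cohort, mri_threshold: float = 0.10,
                   contact_threshold: float = 0.25,
                   sd_floor_rel: float = 1e-6,
                   loo_heldout: bool = False) -> dict:
    """Run the full analysis on an in-memory cohort.

    Returns a dict with the feature table, fitted model, nomogram, LOO
    summary, group statistics and exclusion bookkeeping.
    """
    t0 = time.perf_counter()
    base = compute_features(cohort, mri_threshold=mri_threshold,
                            contact_threshold=contact_threshold,
                            sd_floor_rel=sd_floor_rel)
    features = base["features"]
    excluded = base["excluded"]
    sf = features["ilae"] == 1
    n_sf = int(sf.sum())

    stats: dict[str, float] = {
        "n_patients": int(len(features)),
        "n_seizure_free": n_sf,
        "n_excluded": len(excluded),
    }

    def _safe(name, fn):
        try:
            return fn()
        except ValueError as err:
            logger.warning("statistic %s unavailable: %s", name, err)
            return None

    t_res = _safe("t_coverage", lambda: one_sample_t_greater(
        features.loc[sf, "abnormality_coverage"], 0.5))
    if t_res is not None:
        stats["t_coverage_seizure_free"] = t_res.statistic
        stats["p_coverage_seizure_free"] = t_res.one_tailed_p
    t_nsf = _safe("t_coverage_nsf", lambda: one_sample_t_greater(
        features.loc[~sf, "abnormality_coverage"], 0.5))
    if t_nsf is not None:
        stats["t_coverage_not_seizure_free"] = t_nsf.statistic
        stats["p_coverage_not_seizure_free"] = t_nsf.one_tailed_p

    # group separation AUCs, oriented so > 0.5 matches the hypothesized
    # direction: coverage higher, DRS lower, in seizure-free patients
    u_cov = _safe("auc_coverage", lambda: mann_whitney_auc_greater(
        features.loc[sf, "abnormality_coverage"],
        features.loc[~sf, "abnormality_coverage"]))
    u_dm = _safe("auc_drs_meg", lambda: mann_whitney_auc_greater(
        features.loc[~sf, "drs_meg"], features.loc[sf, "drs_meg"]))
    u_di = _safe("auc_drs_ieeg", lambda: mann_whitney_auc_greater(
        features.loc[~sf, "drs_ieeg"], features.loc[sf, "drs_ieeg"]))
    for key, res in (("coverage", u_cov), ("drs_meg", u_dm),
                     ("drs_ieeg", u_di)):
        if res is not None:
            stats[f"auc_{key}"] = res.auc_effect_size
            stats[f"p_{key}"] = res.one_tailed_p

    model = nomogram = loo = None
    if n_sf >= 2 and (len(features) - n_sf) >= 2:
        model = fit_weighted_logistic(features)
        nomogram = build_nomogram(model, features)
        scores = model.decision_function(
            features[list(FEATURE_COLUMNS)].to_numpy())
        stats["auc_model"] = rank_auc(scores[sf.to_numpy()],
                                      scores[~sf.to_numpy()])
        u_pts = _safe("p_model", lambda: mann_whitney_auc_greater(
            scores[sf.to_numpy()], scores[~sf.to_numpy()]))
        if u_pts is not None:
            stats["p_model"] = u_pts.one_tailed_p
        loo = loo_auc(features, heldout=loo_heldout)
        stats["loo_auc_mean"] = loo.mean
        stats["loo_auc_min"] = loo.min
        stats["loo_auc_max"] = loo.max
    else:
        logger.warning("too few subjects per outcome class to fit the model")

    logger.info("cohort analysed in %.2f s (%d subjects, %d excluded)",
                time.perf_counter() - t0, len(features), len(excluded))
    return {
        **base,
        "model": model,
        "nomogram": nomogram,
        "loo": loo,
        "stats": stats,
    }


def run_pipeline(cfg: PipelineConfig, out_dir) -> dict:
    """Execute the pipeline per configuration and write all artifacts.

    Returns ``{(mri_threshold, contact_threshold): report}``. The report for
    the first threshold pair is written to the canonical file names; sweep
    members get suffixed stats files.
    """
    from . import io as aio
    from .simulate import CohortSimConfig, simulate_cohort

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    chash = aio.config_hash(cfg.to_dict())
    if cfg.simulate:
        sim_cfg = CohortSimConfig(**{"seed": cfg.seed, **cfg.sim})
        cohort = simulate_cohort(sim_cfg)
    else:
        if cfg.input_dir is None:
            raise ValueError("input_dir required when simulate is off")
        cohort = aio.load_cohort(cfg.input_dir)

    reports = {}
    first = True
    for mt in cfg.mri_thresholds:
        for ct in cfg.contact_thresholds:
            report = analyze_cohort(cohort, mri_threshold=mt,
                                    contact_threshold=ct,
                                    sd_floor_rel=cfg.sd_floor_rel,
                                    loo_heldout=cfg.loo_heldout)
            reports[(mt, ct)] = report
            suffix = "" if first else f"_mri{mt:g}_contact{ct:g}"
            stats = {"config_hash": chash, "mri_threshold": mt,
                     "contact_threshold": ct, **report["stats"]}
            (out_dir / f"stats{suffix}.json").write_text(
                json.dumps(stats, indent=1, sort_keys=True), encoding="utf-8")
            if first:
                aio.write_features_table(report["features"],
                                         out_dir / "features.tsv",
                                         meta={"config_hash": chash})
                aio.write_normative_map(report["meg_norm"],
                                        out_dir / "normative_meg.tsv",
                                        meta={"config_hash": chash})
                aio.write_normative_map(report["ieeg_norm"],
                                        out_dir / "normative_ieeg.tsv",
                                        meta={"config_hash": chash})
                if report["model"] is not None:
                    model = report["model"]
                    blob = {
                        "coefficients": dict(zip(FEATURE_COLUMNS,
                                                 model.coef_.ravel().tolist())),
                        "intercept": float(model.intercept_[0]),
                        "class_weights": {str(k): v for k, v in
                                          model.class_weight_.items()},
                        "fit_meta": report["model"].fit_meta_,
                        "config_hash": chash,
                    }
                    (out_dir / "model.json").write_text(
                        json.dumps(blob, indent=1, sort_keys=True),
                        encoding="utf-8")
                    nomo = report["nomogram"]
                    tbl = nomo.breakpoint_table()
                    tbl.attrs["threshold_points"] = nomo.threshold_points
                    aio._write_tsv(tbl, out_dir / "nomogram.tsv",
                                   meta={"threshold_points": nomo.threshold_points,
                                         "config_hash": chash}, index=False)
            first = False
    return reports
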