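"""Tab-separated readers/writers for every on-disk table.

All files are UTF-8 TSV with ``#``-prefixed header comments carrying
provenance (tool version and, where relevant, a config hash plus a JSON
metadata header). Writers and readers round-trip values exactly (floats are
serialized with 17 significant digits). No timestamps are embedded, so
re-running with an unchanged configuration reproduces byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from . import __version__
from .bands import BAND_NAMES
from .normative import NormativeMap, Parcellation

__all__ = [
    "config_hash",
    "read_band_power_table", "write_band_power_table",
    "read_normative_map", "write_normative_map",
    "read_electrode_table", "write_electrode_table",
    "read_volume_table", "write_volume_table",
    "read_features_table", "write_features_table",
    "read_mask", "write_mask",
    "read_parcellation", "write_parcellation",
    "read_timeseries", "write_cohort", "load_cohort",
]

_FLOAT_FMT = "%.17g"


def config_hash(cfg: Mapping) -> str:
    """Stable short hash of a configuration mapping."""
    blob = json.dumps(cfg, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _write_tsv(df: pd.DataFrame, path: Path | str, meta: dict | None = None,
               index: bool = True) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    lines = [f"# abnmap {__version__}"]
    if meta:
        lines.append("# " + json.dumps(meta, sort_keys=True))
    body = df.to_csv(sep="\t", index=index, float_format=_FLOAT_FMT,
                     lineterminator="\n")
    path.write_text("\n".join(lines) + "\n" + body, encoding="utf-8")


def _read_tsv(path: Path | str) -> tuple[pd.DataFrame, dict]:
    path = Path(path)
    meta: dict = {}
    with open(path, encoding="utf-8") as fh:
        text = fh.read()
    for line in text.splitlines():
        if line.startswith("# {"):
            meta = json.loads(line[2:])
        elif not line.startswith("#"):
            break
    from io import StringIO
    df = pd.read_csv(StringIO(text), sep="\t", comment="#")
    return df, meta


def _require_columns(df: pd.DataFrame, cols, path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")


# --- band power -------------------------------------------------------------

def write_band_power_table(df: pd.DataFrame, path, modality: str | None = None,
                           meta: dict | None = None) -> None:
    modality = modality or df.attrs.get("modality", "MEG")
    out = df.reset_index()
    out.columns = ["entity_id", *df.columns]
    out["modality"] = modality
    _write_tsv(out, path, meta={"modality": modality, **(meta or {})}, index=False)


def read_band_power_table(path) -> pd.DataFrame:
    df, meta = _read_tsv(path)
    _require_columns(df, ("entity_id", *BAND_NAMES), path)
    if df["entity_id"].duplicated().any():
        dup = df.loc[df["entity_id"].duplicated(), "entity_id"].iloc[0]
        raise ValueError(f"{path}: duplicate entity_id {dup!r}")
    vals = df[list(BAND_NAMES)].to_numpy(dtype=float)
    if not np.isfinite(vals).all() or (vals < 0).any():
        raise ValueError(f"{path}: band power values must be finite and >= 0")
    out = df.set_index("entity_id")[list(BAND_NAMES)]
    out.attrs["modality"] = (df["modality"].iloc[0] if "modality" in df
                             else meta.get("modality", "MEG"))
    return out


# --- normative map ----------------------------------------------------------

def write_normative_map(norm: NormativeMap, path, meta: dict | None = None) -> None:
    tidy = norm.to_tidy()
    header = {"modality": norm.modality, "bands": list(BAND_NAMES),
              **(meta or {})}
    _write_tsv(tidy, path, meta=header, index=False)


def read_normative_map(path) -> NormativeMap:
    df, meta = _read_tsv(path)
    _require_columns(df, ("roi", "band", "mean", "sd", "n"), path)
    if (df["sd"].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: negative normative SD")
    return NormativeMap.from_tidy(df, modality=meta.get("modality", "MEG"))


# --- electrodes -------------------------------------------------------------

def write_electrode_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    out = df.reset_index()
    _write_tsv(out, path, meta=meta, index=False)


def read_electrode_table(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    _require_columns(df, ("contact_id", "x", "y", "z", "resected"), path)
    if df["contact_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate contact_id")
    xyz = df[["x", "y", "z"]].to_numpy(dtype=float)
    if not np.isfinite(xyz).all():
        raise ValueError(f"{path}: non-finite contact coordinates")
    res = df["resected"].to_numpy()
    if not np.isin(res, (0, 1)).all():
        bad = df.index[~np.isin(res, (0, 1))][0]
        raise ValueError(f"{path}: line {bad + 2}: resected must be 0 or 1")
    return df.set_index("contact_id")


# --- volumes ----------------------------------------------------------------

def write_volume_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(df.reset_index(), path, meta=meta, index=False)


def read_volume_table(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    _require_columns(df, ("roi", "pre_volume", "post_volume"), path)
    if (df["pre_volume"].to_numpy(dtype=float) <= 0).any():
        raise ValueError(f"{path}: pre_volume must be positive")
    if (df["post_volume"].to_numpy(dtype=float) < 0).any():
        raise ValueError(f"{path}: post_volume must be nonnegative")
    return df.set_index("roi")


# --- features ---------------------------------------------------------------

_FEATURES = ("abnormality_coverage", "drs_meg", "drs_ieeg")


def write_features_table(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    _write_tsv(df.reset_index(), path, meta=meta, index=False)


def read_features_table(path) -> pd.DataFrame:
    df, _ = _read_tsv(path)
    _require_columns(df, ("subject_id", *_FEATURES, "ilae"), path)
    for col in _FEATURES:
        vals = df[col].to_numpy(dtype=float)
        bad = ~np.isfinite(vals)
        if bad.any():
            subj = df.loc[np.flatnonzero(bad)[0], "subject_id"]
            raise ValueError(f"{path}: missing {col} for subject {subj!r}")
        if ((vals < 0) | (vals > 1)).any():
            raise ValueError(f"{path}: {col} out of range [0, 1]")
    return df.set_index("subject_id")


# --- masks, parcellation ----------------------------------------------------

def write_mask(rois, path, role: str = "mask") -> None:
    df = pd.DataFrame({"roi": sorted(rois), "flag": 1})
    _write_tsv(df, path, meta={"role": role}, index=False)


def read_mask(path) -> list[str]:
    df, _ = _read_tsv(path)
    _require_columns(df, ("roi", "flag"), path)
    return sorted(df.loc[df["flag"] == 1, "roi"].astype(str))


def write_parcellation(parc: Parcellation, path) -> None:
    df = pd.DataFrame(parc.roi_centroids, columns=["x", "y", "z"])
    df.insert(0, "roi", list(parc.roi_labels))
    _write_tsv(df, path, index=False)


def read_parcellation(path) -> Parcellation:
    df, _ = _read_tsv(path)
    _require_columns(df, ("roi", "x", "y", "z"), path)
    return Parcellation(tuple(df["roi"].astype(str)),
                        df[["x", "y", "z"]].to_numpy(dtype=float))


# --- time series ------------------------------------------------------------

def read_timeseries(path) -> tuple[np.ndarray, list[str], np.ndarray]:
    """Read a time-series TSV: first column time (s), one column per entity.

    Returns (samples matrix with one row per entity, entity ids, time grid).
    """
    df, _ = _read_tsv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: need a time column plus >=1 entity column")
    t = df.iloc[:, 0].to_numpy(dtype=float)
    entities = [str(c) for c in df.columns[1:]]
    samples = df.iloc[:, 1:].to_numpy(dtype=float).T
    return samples, entities, t


# --- whole simulated cohorts ------------------------------------------------

def write_cohort(cohort, outdir) -> None:
    """Write a simulated cohort to the directory layout the pipeline reads."""
    from dataclasses import asdict
    outdir = Path(outdir)
    write_parcellation(cohort.parcellation, outdir / "parcellation.tsv")
    for sid, tbl in cohort.control_meg.items():
        write_band_power_table(tbl, outdir / "controls_meg" / f"{sid}.tsv", "MEG")
    for sid, tbl in cohort.ieeg_norm_tables.items():
        write_band_power_table(tbl, outdir / "ieeg_norm" / f"{sid}.tsv", "iEEG")
    roi_map = pd.DataFrame(sorted(cohort.ieeg_norm_roi_of_entity.items()),
                           columns=["entity_id", "roi"])
    _write_tsv(roi_map, outdir / "ieeg_norm_roi_map.tsv", index=False)
    for pid, tbl in cohort.patient_meg.items():
        write_band_power_table(tbl, outdir / "patients" / f"{pid}_meg.tsv", "MEG")
    for pid, tbl in cohort.patient_contacts.items():
        write_electrode_table(tbl, outdir / "patients" / f"{pid}_electrodes.tsv")
    for pid, tbl in cohort.patient_volumes.items():
        write_volume_table(tbl, outdir / "patients" / f"{pid}_volumes.tsv")
    _write_tsv(cohort.outcomes.rename_axis("subject_id").reset_index(),
               outdir / "outcomes.tsv", index=False)
    gt = {pid: {**asdict(g), "ez_rois": list(g.ez_rois),
                "implanted_rois": list(g.implanted_rois),
                "resected_rois": list(g.resected_rois)}
          for pid, g in cohort.ground_truth.items()}
    (outdir / "ground_truth.json").write_text(
        json.dumps({"config": asdict(cohort.config), "patients": gt},
                   indent=1, sort_keys=True), encoding="utf-8")


def load_cohort(indir):
    """Load a cohort directory written by :func:`write_cohort`."""
    from .simulate import CohortSimConfig, SimulatedCohort
    indir = Path(indir)
    if not indir.exists():
        raise FileNotFoundError(f"cohort directory {indir} does not exist")
    parc = read_parcellation(indir / "parcellation.tsv")
    ctrl_dir = indir / "controls_meg"
    if not ctrl_dir.exists():
        raise FileNotFoundError(
            f"missing controls directory {ctrl_dir}: cannot build the MEG "
            "normative map")
    def _roi_indexed(path):
        tbl = read_band_power_table(path)
        tbl.index.name = "roi"
        return tbl

    controls = {p.stem: _roi_indexed(p) for p in sorted(ctrl_dir.glob("*.tsv"))}
    ieeg_norm = {p.stem: read_band_power_table(p)
                 for p in sorted((indir / "ieeg_norm").glob("*.tsv"))}
    roi_map_df, _ = _read_tsv(indir / "ieeg_norm_roi_map.tsv")
    roi_map = dict(zip(roi_map_df["entity_id"], roi_map_df["roi"]))
    patients_dir = indir / "patients"
    patient_meg = {p.stem.removesuffix("_meg"): _roi_indexed(p)
                   for p in sorted(patients_dir.glob("*_meg.tsv"))}
    contacts = {p.stem.removesuffix("_electrodes"): read_electrode_table(p)
                for p in sorted(patients_dir.glob("*_electrodes.tsv"))}
    volumes = {p.stem.removesuffix("_volumes"): read_volume_table(p)
               for p in sorted(patients_dir.glob("*_volumes.tsv"))}
    outcomes_df, _ = _read_tsv(indir / "outcomes.tsv")
    outcomes = outcomes_df.set_index("subject_id")["ilae"]
    gt_path = indir / "ground_truth.json"
    cfg = CohortSimConfig()
    ground_truth = {}
    if gt_path.exists():
        from .simulate import GroundTruth
        blob = json.loads(gt_path.read_text(encoding="utf-8"))
        cfg = CohortSimConfig(**blob["config"])
        ground_truth = {
            pid: GroundTruth(ez_rois=tuple(g["ez_rois"]),
                             implanted_rois=tuple(g["implanted_rois"]),
                             resected_rois=tuple(g["resected_rois"]),
                             latent_p_seizure_free=g["latent_p_seizure_free"],
                             ilae=g["ilae"])
            for pid, g in blob["patients"].items()}
    return SimulatedCohort(
        config=cfg, parcellation=parc, control_meg=controls,
        ieeg_norm_tables=ieeg_norm, ieeg_norm_roi_of_entity=roi_map,
        patient_meg=patient_meg, patient_contacts=contacts,
        patient_volumes=volumes, outcomes=outcomes, ground_truth=ground_truth)
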