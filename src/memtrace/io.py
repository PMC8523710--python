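"""File I/O: NIfTI-1 volumes and maps, BIDS-style TSV tables, YAML config.

TSV dialect: tab-separated, UTF-8, "n/a" for missing values. NIfTI headers
carry the TR in the 4th pixdim; a TR mismatch between header and
configuration is a named validation error.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
import yaml

from .datatypes import StatMap, Volume4D, default_affine
from .errors import ValidationError
from .simcohort import Cohort, CohortSpec

EVENT_COLUMNS = ["onset", "duration", "item_id", "emotion", "oldness", "run"]
RESPONSE_COLUMNS = ["subject", "item_id", "emotion", "oldness", "response"]
PARTICIPANT_COLUMNS = ["subject", "drug", "delay", "sex"]


# ---------------------------------------------------------------- volumes

def save_volume(vol: Volume4D, path) -> Path:
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, np.float32), vol.affine)
    zooms = list(img.header.get_zooms())
    zooms[3] = vol.tr
    img.header.set_zooms(zooms)
    img.header.set_xyzt_units("mm", "sec")
    nib.save(img, str(path))
    return path


def load_volume(path, mask=None, tr: float | None = None) -> Volume4D:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), float)
    if data.ndim != 4:
        raise ValidationError(f"{path}: expected a 4-D NIfTI")
    header_tr = float(img.header.get_zooms()[3])
    if tr is not None and header_tr > 0 and abs(header_tr - tr) > 1e-6:
        raise ValidationError(
            f"{path}: TR mismatch (header {header_tr} s vs config {tr} s)"
        )
    use_tr = tr if tr is not None else header_tr
    if use_tr <= 0:
        raise ValidationError(f"{path}: no TR in header; pass tr explicitly")
    m = np.ones(data.shape[:3], bool) if mask is None else np.asarray(mask, bool)
    if m.shape != data.shape[:3]:
        raise ValidationError(f"{path}: mask/grid mismatch")
    return Volume4D(data, use_tr, m, np.asarray(img.affine))


def save_map(map_or_array, path, affine=None) -> Path:
    path = Path(path)
    if isinstance(map_or_array, StatMap):
        data = map_or_array.data
    else:
        data = np.asarray(map_or_array, float)
    aff = default_affine() if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, np.float32), aff), str(path))
    return path


def load_map(path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), float)
    if data.ndim != 3:
        raise ValidationError(f"{path}: expected a 3-D NIfTI map")
    return data


def save_mask(mask, path, affine=None) -> Path:
    path = Path(path)
    aff = default_affine() if affine is None else affine
    nib.save(
        nib.Nifti1Image(np.asarray(mask, np.uint8), aff), str(path)
    )
    return path


def load_mask(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata()) > 0.5


# ----------------------------------------------------------------- tables

def write_tsv(df: pd.DataFrame, path) -> Path:
    path = Path(path)
    df.to_csv(path, sep="\t", index=False, na_rep="n/a")
    return path


def read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=["n/a"])


def read_events(path, n_scans: int | None = None, tr: float | None = None) -> pd.DataFrame:
    ev = read_tsv(path)
    missing = [c for c in ("onset", "duration") if c not in ev.columns]
    if missing:
        raise ValidationError(f"{path}: missing event columns {missing}")
    if (ev["onset"] < 0).any() or (ev["duration"] <= 0).any():
        raise ValidationError(f"{path}: onsets must be >= 0 and durations > 0")
    if n_scans is not None and tr is not None:
        if (ev["onset"] + ev["duration"] > n_scans * tr).any():
            raise ValidationError(f"{path}: event beyond the scan window")
    return ev


def read_participants(path) -> pd.DataFrame:
    tbl = read_tsv(path)
    missing = [c for c in ("subject", "drug", "delay") if c not in tbl.columns]
    if missing:
        raise ValidationError(f"{path}: missing participant columns {missing}")
    return tbl


def read_responses(path) -> pd.DataFrame:
    tbl = read_tsv(path)
    missing = [c for c in RESPONSE_COLUMNS if c not in tbl.columns]
    if missing:
        raise ValidationError(f"{path}: missing response columns {missing}")
    return tbl


# ----------------------------------------------------------------- config

@dataclass
class AnalysisSettings:
    """Analysis-stage toggles (units: seconds, mm, voxels)."""

    fwhm_mm: float = 8.0
    hp_cutoff: float = 128.0
    ar1: str = "global"
    searchlight_radius: int = 3
    searchlight_min_voxels: int = 10
    ers_variant: str = "trial_specific"
    ppi_seed_roi: str = "ifg"
    n_perm: int = 1000
    cluster_forming_p: float = 0.005


@dataclass
class RunConfig:
    seed: int
    out_dir: str = "memtrace_out"
    cohort: CohortSpec = field(default_factory=CohortSpec)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)

    def validate(self) -> "RunConfig":
        if self.seed is None:
            raise ValidationError("config must set an explicit seed")
        self.cohort.validate()
        return self


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration.

    Layout::

        seed: 7            # required
        out_dir: results/
        cohort:  {n_per_group: 4, grid_shape: [12, 12, 12], ...}
        analysis: {fwhm_mm: 8.0, n_perm: 1000, ...}
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "seed" not in raw:
        raise ValidationError(f"{path}: config must set a seed")
    cohort_kwargs = dict(raw.get("cohort", {}))
    if "grid_shape" in cohort_kwargs:
        cohort_kwargs["grid_shape"] = tuple(cohort_kwargs["grid_shape"])
    known = {f.name for f in fields(CohortSpec)}
    bad = set(cohort_kwargs) - known
    if bad:
        raise ValidationError(f"{path}: unknown cohort fields {sorted(bad)}")
    analysis_kwargs = dict(raw.get("analysis", {}))
    known_a = {f.name for f in fields(AnalysisSettings)}
    bad = set(analysis_kwargs) - known_a
    if bad:
        raise ValidationError(f"{path}: unknown analysis fields {sorted(bad)}")
    cfg = RunConfig(
        seed=int(raw["seed"]),
        out_dir=str(raw.get("out_dir", "memtrace_out")),
        cohort=CohortSpec(**cohort_kwargs),
        analysis=AnalysisSettings(**analysis_kwargs),
    )
    return cfg.validate()


# ------------------------------------------------------------ cohort dump

def write_cohort(cohort: Cohort, out_dir, volumes: bool = True) -> Path:
    """Write a cohort to disk: participants.tsv, responses.tsv, ROI masks,
    truth.json, and per-subject BOLD + events under sub-XX/ses-{enc,rec}."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_tsv(cohort.group, out / "participants.tsv")
    write_tsv(cohort.responses, out / "responses.tsv")
    aff = default_affine(cohort.spec.voxel_size_mm)
    for name, mask in cohort.rois.items():
        save_mask(mask, out / f"roi_{name}.nii.gz", aff)
    truth = {
        "seed": cohort.seed,
        "spec": {**asdict(cohort.spec), "grid_shape": list(cohort.spec.grid_shape)},
        "effects": _effects_to_json(cohort.effects),
    }
    (out / "truth.json").write_text(json.dumps(truth, indent=2))
    if not volumes:
        return out
    ses = {"encoding": "ses-enc", "recognition": "ses-rec"}
    for subject in cohort:
        for phase, runs in subject.volumes.items():
            d = out / subject.subject_id / ses[phase] / "func"
            d.mkdir(parents=True, exist_ok=True)
            ev = subject.events[phase]
            for r, vol in enumerate(runs):
                stem = f"{subject.subject_id}_{ses[phase]}_run-{r + 1}"
                save_volume(vol, d / f"{stem}_bold.nii.gz")
                write_tsv(
                    ev[ev["run"] == r][EVENT_COLUMNS],
                    d / f"{stem}_events.tsv",
                )
    return out


def _effects_to_json(effects) -> dict:
    def keyed(d):
        return {
            roi: {f"{drug}_{delay}": v for (drug, delay), v in cells.items()}
            for roi, cells in d.items()
        }

    return {
        "univariate": keyed(effects.univariate),
        "ers_r": keyed(effects.ers_r),
        "ppi_gain": keyed(effects.ppi_gain),
        "ppi_seed_roi": effects.ppi_seed_roi,
        "dprime": {
            f"{drug}_{delay}": dict(v)
            for (drug, delay), v in effects.dprime.items()
        },
        "decision_criterion": {
            f"{drug}_{delay}": v
            for (drug, delay), v in effects.decision_criterion.items()
        },
        "pattern_scale": effects.pattern_scale,
        "baseline_amplitude": effects.baseline_amplitude,
        "noise": asdict(effects.noise),
    }
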