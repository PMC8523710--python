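"""Psychophysiological interaction (PPI) connectivity.

A seed region's summary time course (its first eigenvariate), a
psychological regressor coding the task contrast (here old = +1 vs
new = -1, HRF-convolved), and their literal element-by-element product form
the PPI design; the interaction column's t-map tests context-dependent
coupling between the seed and every other voxel.

No hemodynamic deconvolution is applied to the seed: the interaction is the
plain product of the two regressors at scan resolution. The psychological
vector is HRF-convolved before the product so both factors live on the BOLD
time scale.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import Volume4D
from .errors import DegenerateDataError, DesignError, ValidationError
from .firstlevel import (
    DesignMatrix,
    GlmFit,
    _check_rank,
    _convolved_columns,
    contrast,
    dct_drift_basis,
    fit_glm,
)

__all__ = ["SeedSeries", "first_eigenvariate", "build_ppi_design", "ppi_map"]


@dataclass
class SeedSeries:
    """Standardized first-eigenvariate summary of an ROI's time courses."""

    series: np.ndarray  # (scans,), unit variance
    roi_label: str
    explained_variance: float
    n_voxels: int

    def __post_init__(self):
        self.series = np.asarray(self.series, dtype=float)


def first_eigenvariate(vol, roi_mask=None, roi_label: str = "seed") -> SeedSeries:
    """Leading left singular vector of the (scans x ROI voxels) matrix.

    Columns are centered first; the sign is fixed so that the mean
    correlation of the eigenvariate with the ROI voxel series is positive,
    and the series is standardized to unit variance.
    """
    if isinstance(vol, Volume4D):
        roi = np.asarray(roi_mask, bool)
        if roi.shape != vol.grid_shape:
            raise ValidationError("ROI mask shape does not match volume grid")
        Y = vol.timeseries(mask=roi)
    else:
        Y = np.asarray(vol, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValidationError("seed ROI needs at least 2 voxels")
    Yc = Y - Y.mean(axis=0, keepdims=True)
    total = float(np.sum(Yc**2))
    if total <= 1e-12:
        raise DegenerateDataError("constant ROI data: eigenvariate undefined")
    U, s, Vt = np.linalg.svd(Yc, full_matrices=False)
    u = U[:, 0] * s[0]
    # sign convention: align with the bulk of the ROI voxel series
    if Vt[0].sum() < 0:
        u = -u
    sd = u.std(ddof=1)
    if sd <= 0:
        raise DegenerateDataError("degenerate eigenvariate")
    return SeedSeries(
        series=u / sd,
        roi_label=roi_label,
        explained_variance=float(s[0] ** 2 / np.sum(s**2)),
        n_voxels=Y.shape[1],
    )


def build_ppi_design(
    seed: SeedSeries,
    events: pd.DataFrame,
    tr: float,
    n_scans,
    context: dict | None = None,
    hp_cutoff: float | None = 128.0,
    dt: float = 0.1,
    confounds: np.ndarray | None = None,
    include_task_confound: bool = True,
) -> DesignMatrix:
    """PPI design: [seed, psych, seed * psych, confounds, drifts, constants].

    ``context`` maps the ``oldness`` label of each event to its contrast
    code (default old = +1, new = -1); the psychological regressor is the
    contrast-coded event train convolved with the canonical HRF, and the
    interaction is the literal element-wise product of the seed and psych
    columns at scan resolution.

    With ``include_task_confound`` the HRF-convolved all-events train enters
    as a confound: the seed of a task-responsive region shares the common
    stimulus response with every other voxel, and without this column that
    shared component can leak into the interaction estimate. ``confounds``
    adds further user-supplied nuisance columns (scans x k).
    """
    context = {"old": 1.0, "new": -1.0} if context is None else context
    events = events.copy()
    if "run" not in events.columns:
        events["run"] = 0
    missing = sorted(set(events["oldness"]) - set(context))
    if missing:
        raise ValidationError(f"context code missing for labels: {missing}")
    runs = sorted(pd.unique(events["run"]))
    if isinstance(n_scans, dict):
        spr = {r: int(n_scans[r]) for r in runs}
    elif np.isscalar(n_scans):
        spr = {r: int(n_scans) for r in runs}
    else:
        seq = list(n_scans)
        if len(seq) != len(runs):
            raise ValidationError("n_scans sequence length != number of runs")
        spr = dict(zip(runs, (int(s) for s in seq)))

    psych_parts, task_parts = [], []
    for r in runs:
        ev = events[events["run"] == r]
        ns = spr[r]
        if (ev["onset"] + ev["duration"] > ns * tr).any():
            raise DesignError(f"run {r}: event beyond scan window")
        psych_r = np.zeros(ns)
        task_r = np.zeros(ns)
        for code in sorted(set(ev["oldness"])):
            grp = ev[ev["oldness"] == code]
            col = _convolved_columns(
                [(grp["onset"].to_numpy(float), grp["duration"].to_numpy(float))],
                ns,
                tr,
                dt,
            )[:, 0]
            psych_r = psych_r + float(context[code]) * col
            task_r = task_r + col
        psych_parts.append(psych_r)
        task_parts.append(task_r)
    psych = np.concatenate(psych_parts)
    task_mean = np.concatenate(task_parts)
    total = psych.size
    if seed.series.size != total:
        raise ValidationError(
            f"seed length {seed.series.size} != total scans {total}"
        )
    inter = seed.series * psych

    info_rows = [
        {"name": "seed", "kind": "task", "run": -1},
        {"name": "psych", "kind": "task", "run": -1},
        {"name": "ppi", "kind": "task", "run": -1},
    ]
    extra = []
    if include_task_confound:
        extra.append(task_mean)
        info_rows.append({"name": "task_mean", "kind": "confound", "run": -1})
    if confounds is not None:
        conf = np.atleast_2d(np.asarray(confounds, float))
        if conf.shape[0] != total:
            conf = conf.T
        if conf.shape[0] != total:
            raise ValidationError("confounds must have one row per scan")
        for k in range(conf.shape[1]):
            extra.append(conf[:, k])
            info_rows.append({"name": f"confound{k + 1}", "kind": "confound", "run": -1})
    drift = np.zeros((total, 0))
    row0 = 0
    blocks = []
    for r in runs:
        b = dct_drift_basis(spr[r], tr, hp_cutoff)
        blocks.append((r, row0, b))
        row0 += spr[r]
    n_drift = sum(b.shape[1] for _, _, b in blocks)
    drift = np.zeros((total, n_drift))
    c0 = 0
    for r, r0, b in blocks:
        drift[r0 : r0 + b.shape[0], c0 : c0 + b.shape[1]] = b
        for k in range(b.shape[1]):
            info_rows.append({"name": f"run{r}_drift{k + 1}", "kind": "drift", "run": r})
        c0 += b.shape[1]
    const = np.zeros((total, len(runs)))
    r0 = 0
    for j, r in enumerate(runs):
        const[r0 : r0 + spr[r], j] = 1.0
        info_rows.append({"name": f"run{r}_constant", "kind": "run_constant", "run": r})
        r0 += spr[r]

    X = np.column_stack([seed.series, psych, inter] + extra)
    X = np.hstack([X, drift, const])
    info = pd.DataFrame(info_rows)
    _check_rank(X, list(info["name"]))
    frame_times = np.arange(total) * tr
    row_run = np.concatenate([[r] * spr[r] for r in runs])
    return DesignMatrix(
        matrix=X, column_info=info, tr=tr, frame_times=frame_times, row_run=row_run
    )


def ppi_map(vol, design: DesignMatrix, ar1="global"):
    """Fit the PPI GLM and return the interaction (effect, t) maps."""
    fit = fit_glm(vol, design, ar1=ar1)
    w = np.zeros(design.n_columns)
    w[design.column("ppi")] = 1.0
    return contrast(fit, w)
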