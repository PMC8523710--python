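"""Second-level (group) inference.

Within-subject conditions are collapsed to per-subject difference maps so
the between-subjects 2x2 (drug x delay) ANOVA tests the crossed three-way
pattern. Family-wise error within an a-priori ROI is controlled by
max-statistic permutation (the desk-scale analog of parametric small-volume
correction): the corrected peak p-value is the rank of the observed ROI peak
|t| in the null distribution of permutation maxima, with optional Bonferroni
correction across ROIs. Post-hoc cell comparisons use Welch's t on
cluster-mean values.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, stats

from .behav import welch_t
from .datatypes import StatMap
from .errors import ValidationError

__all__ = [
    "GroupDesign",
    "ClusterResult",
    "difference_maps",
    "interaction_map",
    "permutation_fwe",
    "posthoc_cells",
]

CELLS = [("PLAC", "1d"), ("PLAC", "28d"), ("YOH", "1d"), ("YOH", "28d")]


@dataclass
class GroupDesign:
    """Subject-to-cell assignment plus the map kind under test."""

    table: pd.DataFrame  # columns: subject, drug, delay
    map_kind: str = "map"

    def __post_init__(self):
        need = {"subject", "drug", "delay"}
        if not need.issubset(self.table.columns):
            raise ValidationError("group table needs subject, drug, delay columns")
        for drug, delay in CELLS:
            n = int(
                ((self.table["drug"] == drug) & (self.table["delay"] == delay)).sum()
            )
            if n < 2:
                raise ValidationError(f"cell ({drug}, {delay}) has {n} < 2 subjects")

    @property
    def n_subjects(self) -> int:
        return len(self.table)

    def cell_indices(self) -> dict:
        d = {}
        for drug, delay in CELLS:
            sel = (self.table["drug"] == drug) & (self.table["delay"] == delay)
            d[(drug, delay)] = np.flatnonzero(sel.to_numpy())
        return d


@dataclass
class ClusterResult:
    roi: str
    peak_ijk: tuple
    peak_stat: float
    extent: int
    p_corr: float
    p_corr_bonferroni: float
    n_perm: int
    exhaustive: bool
    cluster_mask: np.ndarray = field(repr=False)
    subject_means: pd.DataFrame = field(repr=False, default=None)
    method: str = "max-statistic permutation (SVC analog)"


def _stack(maps, table) -> np.ndarray:
    """Subjects x voxels array from dict subject -> (3-D map | vector)."""
    if isinstance(maps, np.ndarray):
        return maps
    rows = []
    for sid in table["subject"]:
        if sid not in maps:
            raise ValidationError(f"missing map for subject {sid!r}")
        rows.append(np.asarray(maps[sid], dtype=float).ravel())
    return np.vstack(rows)


def difference_maps(maps_a: dict, maps_b: dict) -> dict:
    """Per-subject voxel-wise A - B, collapsing a 2-level within factor."""
    out = {}
    for sid, a in maps_a.items():
        if sid not in maps_b:
            raise ValidationError(f"subject {sid!r} missing the second condition")
        a = np.asarray(a, float)
        b = np.asarray(maps_b[sid], float)
        if a.shape != b.shape:
            raise ValidationError(f"subject {sid!r}: condition map shapes differ")
        out[sid] = a - b
    extra = set(maps_b) - set(maps_a)
    if extra:
        raise ValidationError(f"subjects missing the first condition: {sorted(extra)}")
    return out


def _interaction_t(Y: np.ndarray, cells: dict) -> tuple[np.ndarray, int]:
    """Signed t of (PLAC: 1d - 28d) - (YOH: 1d - 28d) per voxel.

    Pooled within-cell variance, df = N - 4. Voxels with zero pooled
    variance and zero contrast get t = 0 (all-equal guard).
    """
    n = Y.shape[0]
    means, ss, inv_n = {}, 0.0, 0.0
    for cell, idx in cells.items():
        sub = Y[idx]
        m = sub.mean(axis=0)
        means[cell] = m
        ss = ss + ((sub - m) ** 2).sum(axis=0)
        inv_n += 1.0 / len(idx)
    df = n - 4
    s2 = ss / df
    con = (means[("PLAC", "1d")] - means[("PLAC", "28d")]) - (
        means[("YOH", "1d")] - means[("YOH", "28d")]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(s2 * inv_n)
        t = np.where(se > 0, con / np.where(se > 0, se, 1.0), 0.0)
    return t, df


def interaction_map(maps, design: GroupDesign, mask=None):
    """Voxel-wise 2x2 interaction: returns (t StatMap, F StatMap).

    ``maps`` is a dict subject -> 3-D map (or an already-stacked subjects x
    voxels array with an explicit ``mask``). The t is the signed interaction
    contrast; F = t^2 (1 numerator df in a 2x2 design).
    """
    if isinstance(maps, dict):
        example = next(iter(maps.values()))
        grid_shape = np.asarray(example).shape
        mask = np.ones(grid_shape, bool) if mask is None else np.asarray(mask, bool)
        Y = _stack(maps, design.table)[:, mask.ravel()]
    else:
        if mask is None:
            raise ValidationError("stacked-array input requires an explicit mask")
        mask = np.asarray(mask, bool)
        Y = np.asarray(maps, float)
        if Y.shape[1] == mask.size:
            Y = Y[:, mask.ravel()]
    if np.isnan(Y).any():
        Y = np.nan_to_num(Y, nan=0.0)
    t, df = _interaction_t(Y, design.cell_indices())
    meta = {"df": df, "map_kind": design.map_kind, "effect": "drug x delay"}
    t_map = StatMap.from_vector(t, mask, "t", meta)
    f_map = StatMap.from_vector(t**2, mask, "F", {**meta, "df": (1, df)})
    return t_map, f_map


def _n_distinct_arrangements(cells: dict, n: int) -> float:
    denom = 1.0
    for idx in cells.values():
        denom *= math.factorial(len(idx))
    return math.factorial(n) / denom


def _label_arrangements(cells: dict, n: int):
    """All distinct assignments of subjects to cells (multiset permutations
    of the cell-label vector), as row-permutation index arrays."""
    from sympy.utilities.iterables import multiset_permutations

    labels = np.empty(n, dtype=int)
    for k, (cell, idx) in enumerate(cells.items()):
        labels[idx] = k
    for arrangement in multiset_permutations(list(labels)):
        arr = np.asarray(arrangement)
        # build a permutation mapping new labels onto subject rows
        perm = np.empty(n, dtype=int)
        taken = {k: list(np.flatnonzero(labels == k)) for k in range(len(cells))}
        pools = {k: list(v) for k, v in taken.items()}
        for pos, lab in enumerate(arr):
            perm[pos] = pools[lab].pop(0)
        yield perm


def permutation_fwe(
    maps,
    design: GroupDesign,
    roi_masks: dict,
    n_perm: int = 1000,
    cluster_forming_p: float = 0.005,
    seed: int | None = None,
    bonferroni: bool = True,
    mask=None,
) -> list[ClusterResult]:
    """ROI-restricted max-statistic permutation FWE for the 2x2 interaction.

    Random permutations follow the Freedman–Lane scheme: the maps are
    residualized against the main-effect (drug + delay) design, residual rows
    are permuted, the main-effect fit is added back, and the interaction t is
    recomputed; the corrected peak p is (1 + #{max_perm |t| >= |t_obs peak|})
    / (n_perm + 1) within each ROI. When fewer distinct label arrangements
    than n_perm exist, all arrangements are enumerated exhaustively (with a
    warning) and applied directly to the subject rows.
    """
    if n_perm < 100:
        raise ValidationError("n_perm must be >= 100")
    if not roi_masks:
        raise ValidationError("at least one ROI mask is required")
    if isinstance(maps, dict):
        example = np.asarray(next(iter(maps.values())))
        grid_shape = example.shape
        full_mask = np.ones(grid_shape, bool) if mask is None else np.asarray(mask, bool)
        Y = np.nan_to_num(_stack(maps, design.table), nan=0.0)
    else:
        if mask is None:
            raise ValidationError("stacked-array input requires an explicit mask")
        full_mask = np.asarray(mask, bool)
        grid_shape = full_mask.shape
        Y = np.nan_to_num(np.asarray(maps, float), nan=0.0)
    for name, roi in roi_masks.items():
        roi = np.asarray(roi, bool)
        if roi.shape != grid_shape:
            raise ValidationError(f"ROI {name!r} shape does not match maps")
        if not (roi & full_mask).any():
            raise ValidationError(f"ROI {name!r} is empty within the mask")

    cells = design.cell_indices()
    n = design.n_subjects
    rng = np.random.default_rng(seed)

    t_obs_vec, df = _interaction_t(Y[:, full_mask.ravel()], cells)
    t_obs = np.full(grid_shape, 0.0)
    t_obs[full_mask] = t_obs_vec

    distinct = _n_distinct_arrangements(cells, n)
    exhaustive = distinct <= n_perm
    roi_flat = {
        name: np.flatnonzero(np.asarray(roi, bool)[full_mask])
        for name, roi in roi_masks.items()
    }

    if exhaustive:
        warnings.warn(
            f"only {int(distinct)} distinct label arrangements; "
            "enumerating exhaustively",
            stacklevel=2,
        )
        max_null = {name: [] for name in roi_masks}
        n_used = 0
        for perm in _label_arrangements(cells, n):
            t_p, _ = _interaction_t(Y[perm][:, full_mask.ravel()], cells)
            for name, idx in roi_flat.items():
                max_null[name].append(np.max(np.abs(t_p[idx])))
            n_used += 1
        max_null = {k: np.asarray(v) for k, v in max_null.items()}
        # the identity arrangement is part of the enumeration, so the
        # observed statistic is already included in the null
        def _pval(name, obs):
            return float(np.mean(max_null[name] >= obs - 1e-12))
    else:
        # Freedman-Lane: permute residuals of the main-effects model
        drug = np.where(design.table["drug"].to_numpy() == "PLAC", 1.0, -1.0)
        delay = np.where(design.table["delay"].to_numpy() == "1d", 1.0, -1.0)
        Z = np.column_stack([np.ones(n), drug, delay])
        Ym = Y[:, full_mask.ravel()]
        beta_z, *_ = np.linalg.lstsq(Z, Ym, rcond=None)
        fitted = Z @ beta_z
        resid = Ym - fitted
        max_null = {name: np.empty(n_perm) for name in roi_masks}
        for p in range(n_perm):
            perm = rng.permutation(n)
            t_p, _ = _interaction_t(fitted + resid[perm], cells)
            for name, idx in roi_flat.items():
                max_null[name][p] = np.max(np.abs(t_p[idx]))
        n_used = n_perm

        def _pval(name, obs):
            return float(
                (1.0 + np.sum(max_null[name] >= obs - 1e-12)) / (n_used + 1.0)
            )

    thr = stats.t.ppf(1.0 - cluster_forming_p / 2.0, df)
    results = []
    n_rois = len(roi_masks)
    for name, roi in roi_masks.items():
        roi = np.asarray(roi, bool) & full_mask
        abs_t = np.where(roi, np.abs(t_obs), 0.0)
        peak_flat = int(np.argmax(abs_t))
        peak_ijk = np.unravel_index(peak_flat, grid_shape)
        peak_val = float(t_obs[peak_ijk])
        p_corr = _pval(name, abs(peak_val))
        supra = (abs_t >= thr) & roi
        labels, _ = ndimage.label(supra)
        peak_label = labels[peak_ijk]
        if peak_label > 0:
            cl_mask = labels == peak_label
        else:
            cl_mask = np.zeros(grid_shape, bool)
            cl_mask[peak_ijk] = True
        extent = int(cl_mask.sum())
        means = Y[:, cl_mask.ravel()].mean(axis=1)
        subject_means = pd.DataFrame(
            {
                "subject": design.table["subject"].to_numpy(),
                "drug": design.table["drug"].to_numpy(),
                "delay": design.table["delay"].to_numpy(),
                "value": means,
            }
        )
        results.append(
            ClusterResult(
                roi=name,
                peak_ijk=tuple(int(i) for i in peak_ijk),
                peak_stat=peak_val,
                extent=extent,
                p_corr=p_corr,
                p_corr_bonferroni=min(1.0, p_corr * n_rois) if bonferroni else p_corr,
                n_perm=n_used,
                exhaustive=exhaustive,
                cluster_mask=cl_mask,
                subject_means=subject_means,
            )
        )
    return results


def posthoc_cells(cluster: ClusterResult, design: GroupDesign | None = None) -> dict:
    """Welch post-hoc comparisons on cluster-mean values: 1d vs 28d within
    each drug and PLAC vs YOH within each delay."""
    tbl = cluster.subject_means
    if tbl is None:
        raise ValidationError("cluster carries no per-subject means")

    def _cell(drug=None, delay=None):
        sel = np.ones(len(tbl), bool)
        if drug is not None:
            sel &= (tbl["drug"] == drug).to_numpy()
        if delay is not None:
            sel &= (tbl["delay"] == delay).to_numpy()
        vals = tbl.loc[sel, "value"].to_numpy()
        if vals.size == 0:
            raise ValidationError("empty cell in post-hoc comparison")
        return vals

    return {
        "PLAC_1d_vs_28d": welch_t(_cell("PLAC", "1d"), _cell("PLAC", "28d")),
        "YOH_1d_vs_28d": welch_t(_cell("YOH", "1d"), _cell("YOH", "28d")),
        "1d_PLAC_vs_YOH": welch_t(_cell("PLAC", "1d"), _cell("YOH", "1d")),
        "28d_PLAC_vs_YOH": welch_t(_cell("PLAC", "28d"), _cell("YOH", "28d")),
    }
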