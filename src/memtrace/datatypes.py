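"""Shared in-memory containers for volumetric data, statistic maps and
trial-pattern matrices.

Conventions
-----------
* Volumes are stored ``(x, y, z, t)`` (NIfTI axis order); internal linear
  algebra uses the ``(scans, voxels)`` view returned by
  :meth:`Volume4D.timeseries`.
* In-mask voxels are flattened in C order (``np.flatnonzero(mask)``);
  every 1-D per-voxel vector in the package uses that ordering.
* Statistic maps carry NaN outside their mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError


def default_affine(voxel_size_mm: float = 3.0) -> np.ndarray:
    """Simple scaled-identity affine for the synthetic grid (mm units)."""
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = float(voxel_size_mm)
    return aff


@dataclass
class Volume4D:
    """A 4-D BOLD run on a regular grid.

    Parameters
    ----------
    data : ndarray, shape (x, y, z, t)
    tr : float
        Repetition time in seconds.
    mask : ndarray of bool, shape (x, y, z)
        Analysis mask; voxels outside are ignored by every stage.
    affine : ndarray (4, 4), optional
    """

    data: np.ndarray
    tr: float
    mask: np.ndarray
    affine: np.ndarray = field(default_factory=default_affine)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 4:
            raise ValidationError("Volume4D.data must be 4-D (x, y, z, t)")
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.data.shape[:3]:
            raise ValidationError(
                f"mask shape {self.mask.shape} does not match grid "
                f"{self.data.shape[:3]}"
            )
        if not self.tr > 0:
            raise ValidationError("TR must be positive")

    @property
    def n_scans(self) -> int:
        return self.data.shape[3]

    @property
    def grid_shape(self):
        return self.data.shape[:3]

    def timeseries(self, mask: np.ndarray | None = None) -> np.ndarray:
        """Return a (scans, in-mask voxels) array of the data."""
        m = self.mask if mask is None else np.asarray(mask, bool)
        if m.all():
            return self.data.reshape(-1, self.n_scans).T
        return self.data[m, :].T.copy()


def concat_runs(runs: list[Volume4D]) -> Volume4D:
    """Temporally concatenate runs sharing grid, TR and mask."""
    first = runs[0]
    for r in runs[1:]:
        if r.grid_shape != first.grid_shape or r.tr != first.tr:
            raise ValidationError("runs differ in grid shape or TR")
        if not np.array_equal(r.mask, first.mask):
            raise ValidationError("runs differ in mask")
    data = np.concatenate([r.data for r in runs], axis=3)
    return Volume4D(data, first.tr, first.mask, first.affine)


@dataclass
class StatMap:
    """Per-voxel statistic on a 3-D grid, NaN outside the mask."""

    data: np.ndarray
    kind: str  # beta | t | F | fisher_z
    mask: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.shape != self.mask.shape:
            raise ValidationError("StatMap data/mask shape mismatch")

    @classmethod
    def from_vector(cls, values, mask, kind, meta=None):
        """Scatter an in-mask voxel vector into a full NaN-padded grid."""
        mask = np.asarray(mask, bool)
        grid = np.full(mask.shape, np.nan)
        grid[mask] = np.asarray(values, float)
        return cls(grid, kind, mask, meta or {})

    def vector(self) -> np.ndarray:
        return self.data[self.mask]

    def roi_mean(self, roi_mask) -> float:
        roi = np.asarray(roi_mask, bool) & self.mask
        return float(np.nanmean(self.data[roi]))


@dataclass
class PatternMatrix:
    """Trials x voxels activation patterns keyed by item and phase.

    ``index`` has one row per pattern with at least ``item_id`` and ``phase``
    columns (plus ``run``, ``emotion``, ``oldness`` when available) and is
    positionally aligned with ``values``.
    """

    values: np.ndarray  # (n_patterns, n_in_mask_voxels)
    index: pd.DataFrame
    mask: np.ndarray
    kind: str = "t"

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape[0] != len(self.index):
            raise ValidationError("PatternMatrix values/index length mismatch")
        if self.values.shape[1] != int(self.mask.sum()):
            raise ValidationError(
                "PatternMatrix voxel count does not match mask size"
            )

    def select(self, **conditions) -> "PatternMatrix":
        """Subset patterns by index-column equality, e.g. phase='encoding'."""
        keep = np.ones(len(self.index), dtype=bool)
        for col, val in conditions.items():
            keep &= (self.index[col] == val).to_numpy()
        return PatternMatrix(
            self.values[keep],
            self.index.loc[keep].reset_index(drop=True),
            self.mask,
            self.kind,
        )

    def by_item(self, item_ids) -> np.ndarray:
        """Rows reordered to the given item ids (must be unique in index)."""
        lookup = {}
        for pos, item in enumerate(self.index["item_id"]):
            if item in lookup:
                raise ValidationError(f"item {item!r} is not unique in index")
            lookup[item] = pos
        missing = [i for i in item_ids if i not in lookup]
        if missing:
            raise ValidationError(f"items missing from pattern matrix: {missing}")
        rows = [lookup[i] for i in item_ids]
        return self.values[rows]
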