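"""Searchlight encoding–retrieval similarity (ERS).

For every in-mask voxel a sphere of integer offsets with squared norm
<= radius^2 is intersected with the mask; within each sphere the Pearson
correlation between an item's encoding pattern and a recognition-phase
pattern is computed, Fisher z-transformed, and averaged over items:

* encoding-old similarity (EOS): encoding pattern of item i vs the
  recognition pattern of the same old item i,
* encoding-new similarity (ENS): encoding pattern of item i vs the
  recognition pattern of its matched new item (trial-specific variant), and
* ERS = EOS - ENS, written at the sphere's center voxel.

The cross-trial variant replaces the one-to-one pairing by all
non-corresponding old pairings (EOS) and all old-by-new pairings (ENS).

Per-sphere Pearson sums are evaluated for all centers at once by convolving
voxel-wise product maps with the spherical kernel (FFT); this is numerically
identical to looping over spheres and is what makes whole-brain searchlights
affordable at desk scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .datatypes import PatternMatrix, StatMap
from .errors import ValidationError

__all__ = ["Searchlight", "build_searchlight", "fisher_z", "ErsMaps", "ers_map"]

log = logging.getLogger(__name__)

#: clipping constant applied before atanh so |r| -> 1 stays finite
R_CLIP = 1e-7


def sphere_offsets(radius: int) -> np.ndarray:
    """Integer offsets (k, 3) with squared Euclidean norm <= radius^2."""
    r = int(radius)
    g = np.arange(-r, r + 1)
    dx, dy, dz = np.meshgrid(g, g, g, indexing="ij")
    keep = dx**2 + dy**2 + dz**2 <= r**2
    return np.column_stack([dx[keep], dy[keep], dz[keep]])


@dataclass
class Searchlight:
    """Sphere geometry over a masked grid.

    A full interior sphere at radius 3 has 123 member voxels; spheres whose
    mask intersection falls below ``min_voxels`` are dropped from the center
    list (logged).
    """

    radius: int
    shape: tuple
    mask: np.ndarray
    min_voxels: int = 10
    offsets: np.ndarray = field(init=False)
    kernel: np.ndarray = field(init=False)
    counts: np.ndarray = field(init=False)
    centers: np.ndarray = field(init=False)  # (n, 3) in-mask, >= min_voxels

    def __post_init__(self):
        if self.radius < 1:
            raise ValidationError("searchlight radius must be >= 1")
        self.mask = np.asarray(self.mask, bool)
        if self.mask.shape != tuple(self.shape):
            raise ValidationError("mask shape does not match grid shape")
        if not self.mask.any():
            raise ValidationError("empty mask")
        self.offsets = sphere_offsets(self.radius)
        r = self.radius
        kern = np.zeros((2 * r + 1,) * 3)
        kern[tuple((self.offsets + r).T)] = 1.0
        self.kernel = kern
        counts = _sphere_sum(self.mask.astype(float)[None], kern)[0]
        self.counts = np.round(counts).astype(int)
        ok = self.mask & (self.counts >= self.min_voxels)
        dropped = int(self.mask.sum() - ok.sum())
        if dropped:
            log.info(
                "searchlight: dropped %d centers with < %d in-mask voxels",
                dropped,
                self.min_voxels,
            )
        self.centers = np.column_stack(np.nonzero(ok))

    @property
    def center_mask(self) -> np.ndarray:
        m = np.zeros(self.shape, bool)
        m[tuple(self.centers.T)] = True
        return m

    def sphere_indices(self, center) -> np.ndarray:
        """In-mask member voxel coordinates of the sphere at ``center``."""
        pts = np.asarray(center)[None, :] + self.offsets
        ok = np.all((pts >= 0) & (pts < np.asarray(self.shape)[None, :]), axis=1)
        pts = pts[ok]
        inmask = self.mask[tuple(pts.T)]
        return pts[inmask]


def build_searchlight(shape, mask, radius: int = 3, min_voxels: int = 10) -> Searchlight:
    return Searchlight(radius=int(radius), shape=tuple(shape), mask=mask, min_voxels=min_voxels)


def fisher_z(r):
    """atanh with clipping at +/-(1 - 1e-7); |r| beyond 1 + tol is an error."""
    r = np.asarray(r, dtype=float)
    if np.any(np.abs(r) > 1.0 + 1e-6):
        raise ValidationError("correlation outside [-1, 1]")
    return np.arctanh(np.clip(r, -(1.0 - R_CLIP), 1.0 - R_CLIP))


def _sphere_sum(stack: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Sum each (n, X, Y, Z) map over the spherical neighborhood of every
    voxel (kernel is symmetric, so convolution equals correlation)."""
    return fftconvolve(stack, kernel[None], mode="same", axes=(1, 2, 3))


def _to_grids(pm: PatternMatrix, rows: np.ndarray) -> np.ndarray:
    """Scatter selected pattern rows into (n, X, Y, Z) grids (0 off-mask)."""
    n = rows.shape[0]
    grids = np.zeros((n,) + pm.mask.shape)
    grids[:, pm.mask] = rows
    return grids


@dataclass
class ErsMaps:
    eos: StatMap
    ens: StatMap
    ers: StatMap
    variant: str
    pairing: "object" = None


def _pairwise_sphere_r(
    A: np.ndarray,
    B: np.ndarray,
    kernel: np.ndarray,
    counts: np.ndarray,
):
    """Per-center Pearson r between row-matched maps A[i] and B[i].

    A, B: (n, X, Y, Z) with zeros off-mask. Returns (n, X, Y, Z) r values
    (0 where a sphere has no variance).
    """
    V = counts.astype(float)[None]
    Sa = _sphere_sum(A, kernel)
    Sb = _sphere_sum(B, kernel)
    Saa = _sphere_sum(A * A, kernel)
    Sbb = _sphere_sum(B * B, kernel)
    Sab = _sphere_sum(A * B, kernel)
    with np.errstate(divide="ignore", invalid="ignore"):
        cov = Sab - Sa * Sb / V
        va = Saa - Sa**2 / V
        vb = Sbb - Sb**2 / V
        den = np.sqrt(np.clip(va, 0, None) * np.clip(vb, 0, None))
        r = np.where(den > 1e-12, cov / np.where(den > 0, den, 1.0), 0.0)
    return np.clip(r, -1.0, 1.0)


def _check_pairing(pairing, enc_items, rec_old_items, rec_new_items):
    need = {"old_item", "new_item"}
    if not need.issubset(pairing.columns):
        raise ValidationError("pairing table needs old_item and new_item columns")
    old = list(pairing["old_item"])
    new = list(pairing["new_item"])
    missing = (
        [i for i in old if i not in enc_items]
        + [i for i in old if i not in rec_old_items]
        + [i for i in new if i not in rec_new_items]
    )
    if missing:
        raise ValidationError(f"unmatched items in pairing: {sorted(set(missing))}")


def ers_map(
    enc: PatternMatrix,
    rec: PatternMatrix,
    pairing,
    sl: Searchlight,
    variant: str = "trial_specific",
    chunk: int = 512,
) -> ErsMaps:
    """Searchlight EOS / ENS / ERS maps.

    Parameters
    ----------
    enc : PatternMatrix
        Encoding patterns, one row per old item (e.g. the final encoding run).
    rec : PatternMatrix
        Recognition patterns covering all old and all new items.
    pairing : DataFrame (old_item, new_item)
        The supplied old-to-new item matching.
    variant : {"trial_specific", "cross_trial"}
    """
    if variant not in ("trial_specific", "cross_trial"):
        raise ValidationError(f"unknown ERS variant {variant!r}")
    if not np.array_equal(enc.mask, rec.mask):
        raise ValidationError("encoding/recognition masks differ")
    if not np.array_equal(enc.mask, sl.mask):
        # allow an ROI-restricted searchlight over a sub-mask of the patterns
        if np.any(sl.mask & ~enc.mask):
            raise ValidationError(
                "searchlight mask is not a subset of the pattern mask"
            )
        sub = sl.mask[enc.mask]

        def _restrict(pm: PatternMatrix) -> PatternMatrix:
            return PatternMatrix(pm.values[:, sub], pm.index, sl.mask, pm.kind)

        enc, rec = _restrict(enc), _restrict(rec)
    rec_old = rec.select(oldness="old") if "oldness" in rec.index.columns else rec
    rec_new = rec.select(oldness="new") if "oldness" in rec.index.columns else rec
    _check_pairing(
        pairing,
        set(enc.index["item_id"]),
        set(rec_old.index["item_id"]),
        set(rec_new.index["item_id"]),
    )
    old_items = list(pairing["old_item"])
    new_items = list(pairing["new_item"])
    E = _to_grids(enc, enc.by_item(old_items))
    O = _to_grids(rec_old, rec_old.by_item(old_items))
    N = _to_grids(rec_new, rec_new.by_item(new_items))
    counts = sl.counts

    if variant == "trial_specific":
        r_eos = _pairwise_sphere_r(E, O, sl.kernel, counts)
        r_ens = _pairwise_sphere_r(E, N, sl.kernel, counts)
        eos = fisher_z(r_eos).mean(axis=0)
        ens = fisher_z(r_ens).mean(axis=0)
    else:
        n_items = len(old_items)
        pairs_eos = [(i, j) for i in range(n_items) for j in range(n_items) if i != j]
        pairs_ens = [(i, j) for i in range(n_items) for j in range(n_items)]

        def _mean_z(pairs, B):
            acc = np.zeros(sl.mask.shape)
            for k0 in range(0, len(pairs), chunk):
                blk = pairs[k0 : k0 + chunk]
                ia = np.array([p[0] for p in blk])
                ib = np.array([p[1] for p in blk])
                r = _pairwise_sphere_r(E[ia], B[ib], sl.kernel, counts)
                acc += fisher_z(r).sum(axis=0)
            return acc / len(pairs)

        eos = _mean_z(pairs_eos, O)
        ens = _mean_z(pairs_ens, N)

    cm = sl.center_mask
    meta = {"variant": variant, "radius": sl.radius, "n_items": len(old_items)}
    eos_m = StatMap.from_vector(eos[cm], cm, "fisher_z", {**meta, "stat": "EOS"})
    ens_m = StatMap.from_vector(ens[cm], cm, "fisher_z", {**meta, "stat": "ENS"})
    ers_m = StatMap.from_vector((eos - ens)[cm], cm, "fisher_z", {**meta, "stat": "ERS"})
    return ErsMaps(eos=eos_m, ens=ens_m, ers=ers_m, variant=variant, pairing=pairing)
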