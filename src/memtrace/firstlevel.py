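"""First-level GLM engine.

Implements the canonical double-gamma HRF, condition-wise and trial-wise
design construction with discrete-cosine high-pass drift columns, AR(1)
prewhitened least squares, contrast/t maps, trial-pattern extraction
(beta -> t normalization), and Gaussian smoothing.

The model is the textbook mass-univariate GLM

    y_v = X b_v + e_v,   e_v ~ AR(1) with a single pooled coefficient rho,

estimated with one Cochrane–Orcutt pass: OLS residuals give a pooled lag-1
autocorrelation, both sides are filtered by the AR(1) square-root filter
(applied within run, never across run boundaries), and the whitened system is
solved by ordinary least squares.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage, signal

from .datatypes import PatternMatrix, StatMap, Volume4D
from .errors import DesignError, ValidationError

__all__ = [
    "canonical_hrf",
    "hrf_dense",
    "build_design",
    "DesignMatrix",
    "GlmFit",
    "fit_glm",
    "contrast",
    "trial_patterns",
    "smooth",
]

# Standard double-gamma constants: response/undershoot delays 6 s and 16 s,
# unit dispersions, undershoot ratio 1/6, 32-s support.
_PEAK_DELAY = 6.0
_UNDERSHOOT_DELAY = 16.0
_PEAK_DISP = 1.0
_UNDERSHOOT_DISP = 1.0
_UNDERSHOOT_RATIO = 1.0 / 6.0
_DEFAULT_LENGTH = 32.0


def hrf_dense(t: np.ndarray) -> np.ndarray:
    """Un-normalized double-gamma HRF evaluated at arbitrary times (s)."""
    from scipy.stats import gamma

    t = np.asarray(t, dtype=float)
    h = gamma.pdf(t, _PEAK_DELAY / _PEAK_DISP, scale=_PEAK_DISP)
    h = h - _UNDERSHOOT_RATIO * gamma.pdf(
        t, _UNDERSHOOT_DELAY / _UNDERSHOOT_DISP, scale=_UNDERSHOOT_DISP
    )
    return np.where(t >= 0, h, 0.0)


def canonical_hrf(tr: float, length: float = _DEFAULT_LENGTH) -> np.ndarray:
    """Canonical HRF kernel sampled every ``tr`` seconds, peak-normalized.

    Parameters
    ----------
    tr : float
        Sampling interval in seconds (> 0).
    length : float
        Kernel support in seconds (must be >= tr).
    """
    if not tr > 0:
        raise ValidationError("tr must be positive")
    if length < tr:
        raise ValidationError("kernel length must be at least one sample (>= tr)")
    t = np.arange(0.0, length + tr / 2, tr)
    h = hrf_dense(t)
    peak = h.max()
    if peak <= 0:
        raise ValidationError("degenerate HRF kernel")
    return h / peak


def _convolved_columns(
    groups: list[tuple[np.ndarray, np.ndarray]],
    n_scans: int,
    tr: float,
    dt: float = 0.1,
) -> np.ndarray:
    """HRF-convolved boxcar columns for groups of events in one run.

    Each group is (onsets, durations) in seconds; the returned array is
    (n_scans, n_groups). Convolution runs on a microtime grid of step ``dt``
    and is sampled at the acquisition times i * TR.
    """
    n_micro = int(np.ceil(n_scans * tr / dt)) + 1
    ind = np.zeros((len(groups), n_micro))
    tgrid = np.arange(n_micro) * dt
    for g, (onsets, durations) in enumerate(groups):
        for on, du in zip(np.atleast_1d(onsets), np.atleast_1d(durations)):
            ind[g, (tgrid >= on) & (tgrid < on + du)] = 1.0
    kern = canonical_hrf(dt)[None, :] * dt
    conv = signal.fftconvolve(ind, kern, mode="full", axes=1)[:, :n_micro]
    frame_idx = np.round(np.arange(n_scans) * tr / dt).astype(int)
    return conv[:, frame_idx].T


def dct_drift_basis(n_scans: int, tr: float, hp_cutoff: float) -> np.ndarray:
    """Unit-norm discrete-cosine drift columns with period > hp_cutoff (s)."""
    if hp_cutoff is None or hp_cutoff <= 0:
        return np.zeros((n_scans, 0))
    duration = n_scans * tr
    n_k = int(np.floor(2.0 * duration / hp_cutoff))
    i = np.arange(n_scans)
    cols = []
    for k in range(1, n_k + 1):
        c = np.cos(np.pi * k * (2 * i + 1) / (2 * n_scans))
        cols.append(c / np.linalg.norm(c))
    return np.column_stack(cols) if cols else np.zeros((n_scans, 0))


@dataclass
class DesignMatrix:
    """Scans x regressors design with per-column metadata.

    ``column_info`` has one row per column: name, kind (task / drift /
    run_constant), run, and — for trial-wise designs — the originating event's
    item_id / phase / emotion / oldness.
    """

    matrix: np.ndarray
    column_info: pd.DataFrame
    tr: float
    frame_times: np.ndarray
    row_run: np.ndarray  # run label per scan, used for per-run whitening

    @property
    def names(self) -> list[str]:
        return list(self.column_info["name"])

    @property
    def kinds(self) -> list[str]:
        return list(self.column_info["kind"])

    @property
    def n_scans(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_columns(self) -> int:
        return self.matrix.shape[1]

    def task_columns(self) -> np.ndarray:
        return np.flatnonzero(self.column_info["kind"].to_numpy() == "task")

    def column(self, name: str) -> int:
        names = self.names
        if name not in names:
            raise ValidationError(f"no design column named {name!r}")
        return names.index(name)


def _check_rank(X: np.ndarray, names: list[str]) -> None:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # pivoted QR identifies the most redundant columns
        from scipy.linalg import qr

        _, r, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(X.shape) * np.finfo(float).eps
        bad = [names[piv[i]] for i in range(len(diag)) if diag[i] <= tol]
        bad = bad or [names[p] for p in piv[rank:]]
        raise DesignError(
            f"design is rank deficient (rank {rank} < {X.shape[1]}); "
            f"collinear columns: {bad}",
            columns=bad,
        )


def build_design(
    events: pd.DataFrame,
    n_scans,
    tr: float,
    mode: str = "condition",
    condition_cols=("emotion",),
    hp_cutoff: float | None = 128.0,
    dt: float = 0.1,
    check_rank: bool = True,
) -> DesignMatrix:
    """Build a (possibly multi-run) first-level design matrix.

    Parameters
    ----------
    events : DataFrame
        Columns ``onset``, ``duration``, ``run`` plus, depending on mode,
        the condition columns or ``item_id``. Runs are concatenated in sorted
        order of the ``run`` label.
    n_scans : int | dict | sequence
        Scans per run (int applies to every run; dict keyed by run label;
        sequence aligned with sorted run labels).
    mode : {"condition", "trialwise"}
        Condition mode emits one HRF-convolved regressor per run per unique
        combination of ``condition_cols``; trial-wise mode emits one regressor
        per event row.
    hp_cutoff : float or None
        High-pass cutoff in seconds for the per-run discrete-cosine drift
        block (None disables drifts). Run constants are always included.
    """
    if mode not in ("condition", "trialwise"):
        raise ValidationError(f"unknown design mode {mode!r}")
    events = events.copy()
    if "run" not in events.columns:
        events["run"] = 0
    runs = sorted(pd.unique(events["run"])) if len(events) else [0]
    if isinstance(n_scans, dict):
        scans_per_run = {r: int(n_scans[r]) for r in runs}
    elif np.isscalar(n_scans):
        scans_per_run = {r: int(n_scans) for r in runs}
    else:
        seq = list(n_scans)
        if len(seq) != len(runs):
            raise ValidationError("n_scans sequence length != number of runs")
        scans_per_run = dict(zip(runs, (int(s) for s in seq)))

    task_blocks, drift_blocks, const_blocks = [], [], []
    info_rows = []
    row_run = []
    frame_times = []
    t_offset = 0.0
    extra_cols = [c for c in ("item_id", "phase", "emotion", "oldness") if c in events.columns]

    # first pass: per-run task column definitions
    run_task_defs = []  # (run, [(name, onsets, durations, meta)])
    for r in runs:
        ev = events[events["run"] == r]
        ns = scans_per_run[r]
        late = ev["onset"] + ev["duration"] > ns * tr
        if late.any():
            raise DesignError(
                f"run {r}: {int(late.sum())} event(s) extend beyond the "
                f"scan window of {ns * tr:.1f} s"
            )
        defs = []
        if mode == "condition":
            if len(ev):
                cols = list(condition_cols)
                for key, grp in ev.groupby(cols, sort=True):
                    key = key if isinstance(key, tuple) else (key,)
                    label = "_".join(f"{c}-{v}" for c, v in zip(cols, key))
                    defs.append(
                        (
                            f"run{r}_{label}",
                            grp["onset"].to_numpy(float),
                            grp["duration"].to_numpy(float),
                            {},
                        )
                    )
        else:
            for _, row in ev.iterrows():
                item = row["item_id"] if "item_id" in ev.columns else f"t{_}"
                meta = {c: row[c] for c in extra_cols}
                defs.append(
                    (
                        f"run{r}_trial-{item}",
                        np.array([row["onset"]], float),
                        np.array([row["duration"]], float),
                        meta,
                    )
                )
        run_task_defs.append((r, defs))

    n_task_total = sum(len(d) for _, d in run_task_defs)
    for r, defs in run_task_defs:
        ns = scans_per_run[r]
        block = np.zeros((ns, n_task_total))
        col0 = sum(len(d) for rr, d in run_task_defs if runs.index(rr) < runs.index(r))
        if defs:
            conv = _convolved_columns(
                [(on, du) for _, on, du, _ in defs], ns, tr, dt
            )
            block[:, col0 : col0 + len(defs)] = conv
        task_blocks.append(block)
        drift_blocks.append(dct_drift_basis(ns, tr, hp_cutoff))
        row_run.extend([r] * ns)
        frame_times.append(np.arange(ns) * tr + t_offset)
        t_offset += ns * tr

    for r, defs in run_task_defs:
        for name, _, _, meta in defs:
            info_rows.append({"name": name, "kind": "task", "run": r, **meta})

    task = np.vstack(task_blocks)
    # block-diagonal drift block
    total_scans = task.shape[0]
    n_drift = sum(b.shape[1] for b in drift_blocks)
    drift = np.zeros((total_scans, n_drift))
    row0, col0 = 0, 0
    for (r, _), b in zip(run_task_defs, drift_blocks):
        ns = scans_per_run[r]
        drift[row0 : row0 + ns, col0 : col0 + b.shape[1]] = b
        for k in range(b.shape[1]):
            info_rows.append(
                {"name": f"run{r}_drift{k + 1}", "kind": "drift", "run": r}
            )
        row0 += ns
        col0 += b.shape[1]

    const = np.zeros((total_scans, len(runs)))
    row0 = 0
    for j, r in enumerate(runs):
        ns = scans_per_run[r]
        const[row0 : row0 + ns, j] = 1.0
        info_rows.append({"name": f"run{r}_constant", "kind": "run_constant", "run": r})
        row0 += ns

    X = np.hstack([task, drift, const])
    info = pd.DataFrame(info_rows)
    if check_rank:
        _check_rank(X, list(info["name"]))
    return DesignMatrix(
        matrix=X,
        column_info=info,
        tr=tr,
        frame_times=np.concatenate(frame_times),
        row_run=np.asarray(row_run),
    )


@dataclass
class GlmFit:
    """Fitted mass-univariate GLM (possibly AR(1)-prewhitened)."""

    design: DesignMatrix
    beta: np.ndarray  # (regressors, voxels)
    sigma2: np.ndarray  # (voxels,)
    dof: int
    rho: float
    xtx_inv: np.ndarray  # (p, p) of the whitened design
    mask: np.ndarray | None = None
    grid_shape: tuple | None = None
    affine: np.ndarray | None = None

    def to_statmap(self, values, kind, meta=None) -> StatMap:
        if self.mask is None:
            raise ValidationError("fit has no mask; cannot build a StatMap")
        return StatMap.from_vector(values, self.mask, kind, meta)


def _run_slices(row_run: np.ndarray):
    """Contiguous (start, stop) ranges of each run in acquisition order."""
    rr = np.asarray(row_run)
    starts = [0] + list(np.flatnonzero(rr[1:] != rr[:-1]) + 1)
    stops = starts[1:] + [len(rr)]
    return list(zip(starts, stops))


def _ar1_whiten(A: np.ndarray, rho: float, row_run: np.ndarray) -> np.ndarray:
    """Apply the AR(1) square-root filter within each run (runs must occupy
    contiguous scan ranges, which build_design guarantees)."""
    W = np.array(A, dtype=float, copy=True)
    for a, b in _run_slices(row_run):
        W[a + 1 : b] -= rho * np.asarray(A[a : b - 1], dtype=float)
        W[a] *= np.sqrt(1.0 - rho**2)
    return W


def _pooled_rho(resid: np.ndarray, row_run: np.ndarray) -> float:
    """Pooled lag-1 autocorrelation of residuals, within runs."""
    num, den = 0.0, 0.0
    for r in pd.unique(row_run):
        idx = np.flatnonzero(row_run == r)
        e = resid[idx]
        num += float(np.sum(e[1:] * e[:-1]))
        den += float(np.sum(e**2))
    if den <= 0:
        return 0.0
    return float(np.clip(num / den, -0.99, 0.99))


def fit_glm(vol, design: DesignMatrix, ar1="global") -> GlmFit:
    """Fit the GLM with optional AR(1) prewhitening.

    Parameters
    ----------
    vol : Volume4D or ndarray (scans, voxels)
    ar1 : {"off", "global"} or float
        "global" estimates a single rho from pooled in-mask OLS residuals
        (one Cochrane–Orcutt pass); a float fixes rho; "off" disables
        whitening.
    """
    mask = grid_shape = affine = None
    if isinstance(vol, Volume4D):
        Y = vol.timeseries()
        mask, grid_shape, affine = vol.mask, vol.grid_shape, vol.affine
        if mask.sum() == 0:
            raise ValidationError("empty analysis mask")
    else:
        Y = np.asarray(vol, dtype=float)
    if Y.shape[0] != design.n_scans:
        raise ValidationError(
            f"data has {Y.shape[0]} scans but design has {design.n_scans}"
        )

    X = design.matrix
    p = X.shape[1]

    def _solve_normal(Xm, Ym):
        """Normal-equation solve; raises a named DesignError when singular.

        Returns (beta, xtx_inv, rss) with rss computed as y'y - b'X'y, which
        avoids forming the (scans x voxels) fitted values.
        """
        from scipy.linalg import cho_factor, cho_solve, LinAlgError

        xtx = Xm.T @ Xm
        try:
            cf = cho_factor(xtx)
        except (LinAlgError, np.linalg.LinAlgError):
            _check_rank(Xm, design.names)
            raise DesignError("whitened design is singular")
        # near-singular designs can still pass Cholesky: check conditioning
        diag = np.abs(np.diag(cf[0]))
        if diag.min() < np.sqrt(np.finfo(float).eps) * diag.max():
            _check_rank(Xm, design.names)
        Xt = Xm.T if Xm.dtype == Ym.dtype else Xm.T.astype(Ym.dtype)
        xty = np.asarray(Xt @ Ym, dtype=float)
        beta = cho_solve(cf, xty)
        rss = np.einsum("ij,ij->j", Ym, Ym, dtype=float) - np.sum(
            beta * xty, axis=0
        )
        return beta, cho_solve(cf, np.eye(p)), np.clip(rss, 0.0, None)

    if ar1 == "off":
        rho = 0.0
    elif ar1 == "global":
        # pooled rho from OLS residuals of a voxel subsample (the pooled
        # estimate stabilizes long before all voxels are used)
        nv = Y.shape[1]
        sub = Y[:, :: max(1, nv // 1024)]
        beta0, _, _ = _solve_normal(X, sub)
        resid0 = sub - X @ beta0
        rho = _pooled_rho(resid0, design.row_run)
    else:
        rho = float(ar1)
        if not -1.0 < rho < 1.0:
            raise ValidationError("AR(1) coefficient must be in (-1, 1)")

    if rho != 0.0:
        Xw = _ar1_whiten(X, rho, design.row_run)
        Yw = _ar1_whiten(Y, rho, design.row_run)
    else:
        Xw, Yw = X, Y

    beta, xtx_inv, rss = _solve_normal(Xw, Yw)
    dof = design.n_scans - p
    if dof <= 0:
        raise DesignError("no residual degrees of freedom")
    sigma2 = rss / dof
    return GlmFit(
        design=design,
        beta=beta,
        sigma2=sigma2,
        dof=dof,
        rho=rho,
        xtx_inv=xtx_inv,
        mask=mask,
        grid_shape=grid_shape,
        affine=affine,
    )


def contrast(fit: GlmFit, weights):
    """Beta-contrast and t maps for a weight vector over regressors.

    Returns ``(effect, t)`` as StatMaps when the fit carries a mask, else as
    plain per-voxel arrays.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (fit.beta.shape[0],):
        raise ValidationError(
            f"contrast length {w.size} != regressor count {fit.beta.shape[0]}"
        )
    if not np.any(w):
        raise ValidationError("all-zero contrast weights")
    kinds = np.asarray(fit.design.kinds)
    if np.any(w[kinds != "task"] != 0):
        warnings.warn(
            "contrast weights touch drift/constant columns", stacklevel=2
        )
    effect = w @ fit.beta
    var = fit.sigma2 * float(w @ fit.xtx_inv @ w)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(var > 0, effect / np.sqrt(var), 0.0)
    meta = {"weights": w.tolist(), "dof": fit.dof, "rho": fit.rho}
    if fit.mask is not None:
        return (
            fit.to_statmap(effect, "beta", {**meta, "stat": "effect"}),
            fit.to_statmap(t, "t", {**meta, "stat": "t"}),
        )
    return effect, t


def trial_patterns(
    fit: GlmFit,
    phase: str | None = None,
    last_run_only: bool = False,
) -> PatternMatrix:
    """Per-trial t patterns (beta / SE) from a trial-wise fit.

    ``phase`` filters on the design's per-column event phase; with
    ``last_run_only`` only the final run among the selected columns is kept
    (used for final-encoding-run patterns).
    """
    info = fit.design.column_info
    if "item_id" not in info.columns:
        raise ValidationError("fit does not come from a trialwise design")
    sel = (info["kind"] == "task").to_numpy()
    if phase is not None:
        if "phase" not in info.columns:
            raise ValidationError("design columns carry no phase labels")
        sel &= (info["phase"] == phase).to_numpy()
    if not sel.any():
        raise ValidationError("no trial regressors match the requested phase")
    if last_run_only:
        runs = info.loc[sel, "run"]
        sel &= (info["run"] == runs.max()).to_numpy()
    cols = np.flatnonzero(sel)
    se = np.sqrt(
        fit.sigma2[None, :] * np.diag(fit.xtx_inv)[cols, None]
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        tvals = np.where(se > 0, fit.beta[cols] / se, 0.0)
    keep_cols = [c for c in ("item_id", "phase", "run", "emotion", "oldness") if c in info.columns]
    index = info.loc[sel, keep_cols].reset_index(drop=True)
    if fit.mask is None:
        raise ValidationError("trial patterns require a masked (Volume4D) fit")
    return PatternMatrix(values=tvals, index=index, mask=fit.mask, kind="t")


def _fwhm_to_sigma(fwhm: float) -> float:
    return fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))


def smooth(data, fwhm_mm: float, voxel_size_mm: float = 3.0, mask=None):
    """Separable Gaussian smoothing (sigma = FWHM / 2*sqrt(2 ln 2)) in mm.

    Works on 3-D maps, 4-D (x, y, z, t) arrays and Volume4D. With a mask, the
    kernel is renormalized over in-mask support so edges are not darkened.
    """
    if fwhm_mm < 0:
        raise ValidationError("FWHM must be non-negative")
    if isinstance(data, Volume4D):
        sm = smooth(data.data, fwhm_mm, voxel_size_mm, mask=data.mask)
        return Volume4D(sm, data.tr, data.mask, data.affine)
    arr = np.asarray(data, dtype=float)
    if fwhm_mm == 0:
        return arr.copy()
    sigma_vox = _fwhm_to_sigma(fwhm_mm) / voxel_size_mm
    spatial = (sigma_vox, sigma_vox, sigma_vox)
    sigmas = spatial if arr.ndim == 3 else spatial + (0,)
    if mask is None or np.all(mask):
        return ndimage.gaussian_filter(arr, sigma=sigmas)
    m = np.asarray(mask, float)
    m4 = m if arr.ndim == 3 else m[..., None]
    num = ndimage.gaussian_filter(arr * m4, sigma=sigmas)
    den = ndimage.gaussian_filter(m, sigma=spatial)
    den4 = den if arr.ndim == 3 else den[..., None]
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den4 > 1e-12, num / den4, 0.0)
    return out * m4
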