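"""Synthetic cohort generator.

Emulates a two-day pharmacological memory-consolidation study: four
between-subject cells (drug PLAC/YOH x delay 1d/28d), three encoding runs in
which the same 60 pictures (half emotionally negative, half neutral) are
each shown once per run, and a recognition session (three runs) containing
the 60 old plus 60 pairwise-matched new pictures. Events are 3-s pictures
with 4 +/- 1 s jittered fixation; TR = 2 s.

The BOLD forward model mirrors the analysis GLM: per-trial amplitude images
(a shared baseline response, ROI-level old-minus-new amplitude shifts, and
item-specific multivariate patterns) are convolved with the canonical HRF,
then low-frequency cosine drift, a shared per-ROI AR(1) fluctuation (which
gives seed eigenvariates something real to find and carries the planted PPI
coupling), and AR(1) Gaussian noise are added.

Item patterns are Gaussian voxel vectors scaled to unit RMS per voxel; the
recognition-phase pattern of an old item is r * (encoding pattern) +
sqrt(1 - r^2) * (independent pattern) voxel-wise, with r set by the planted
per-ROI, per-cell encoding-retrieval similarity (0 outside effect ROIs), so
the expected encoding-to-test correlation inside an ROI equals the planted
value exactly. Recognition responses come from an equal-variance
signal-detection model with a decision criterion and symmetric confidence
criteria on the evidence axis.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .datatypes import Volume4D, default_affine
from .errors import ValidationError
from .firstlevel import _convolved_columns

__all__ = [
    "CohortSpec",
    "NoiseSpec",
    "EffectSpec",
    "default_effects",
    "make_items",
    "make_events",
    "make_group_table",
    "default_rois",
    "make_behavior",
    "Subject",
    "simulate_subject",
    "Cohort",
    "simulate_cohort",
]

DRUGS = ("PLAC", "YOH")
DELAYS = ("1d", "28d")
EMOTIONS = ("negative", "neutral")
CELLS = [(d, t) for d in DRUGS for t in DELAYS]

#: post-stimulus tail (s) appended to each run so the HRF can return to
#: baseline before the run ends
RUN_TAIL = 16.0


@dataclass(frozen=True)
class CohortSpec:
    """Design parameters of the simulated study (defaults = study design)."""

    n_per_group: int = 26
    grid_shape: tuple = (24, 24, 24)
    voxel_size_mm: float = 3.0
    tr: float = 2.0
    n_items_old: int = 60
    n_items_new: int = 60
    n_encoding_runs: int = 3
    n_recognition_runs: int = 3
    event_duration: float = 3.0
    iti_base: float = 4.0
    iti_jitter: float = 1.0
    rng_seed: int = 0

    def validate(self) -> "CohortSpec":
        if min(self.n_per_group, self.n_items_old, self.n_items_new) <= 0:
            raise ValidationError("counts must be positive")
        if self.n_encoding_runs <= 0 or self.n_recognition_runs <= 0:
            raise ValidationError("run counts must be positive")
        if self.n_items_old != self.n_items_new:
            raise ValidationError("n_items_old must equal n_items_new")
        if self.n_items_old % 2:
            raise ValidationError("item count must be even (half per emotion)")
        if self.event_duration <= 0 or self.tr <= 0:
            raise ValidationError("durations must be positive")
        if self.iti_base <= self.iti_jitter or self.iti_jitter < 0:
            raise ValidationError("need 0 <= iti_jitter < iti_base")
        if min(self.grid_shape) < 8:
            raise ValidationError("grid must be at least 8 voxels per axis")
        return self


@dataclass(frozen=True)
class NoiseSpec:
    """Noise and nuisance parameters of the forward model."""

    ar1: float = 0.3                #: AR(1) coefficient of the scan noise
    scan_noise_sd: float = 1.0      #: stationary SD of the AR(1) noise
    drift_amplitude: float = 1.0    #: SD of the slow-cosine drift coefficients
    n_drift_components: int = 2     #: cosines below the 1/128 Hz cutoff
    pattern_noise_sd: float = 0.0   #: iid noise added to emitted patterns
    roi_fluctuation_sd: float = 0.7 #: SD of the shared per-ROI AR(1) signal

    def validate(self):
        if not -1.0 < self.ar1 < 1.0:
            raise ValidationError("AR(1) coefficient must be in (-1, 1)")
        if self.scan_noise_sd < 0 or self.pattern_noise_sd < 0:
            raise ValidationError("noise SDs must be non-negative")
        return self


def _cell_dict(plac_1d, plac_28d, yoh_1d, yoh_28d) -> dict:
    return {
        ("PLAC", "1d"): plac_1d,
        ("PLAC", "28d"): plac_28d,
        ("YOH", "1d"): yoh_1d,
        ("YOH", "28d"): yoh_28d,
    }


@dataclass(frozen=True)
class EffectSpec:
    """Planted effect structure: per-ROI x cell univariate amplitudes,
    encoding-retrieval pattern correlations, PPI coupling gains, and the
    behavioral signal-detection parameters per cell and emotion.
    """

    #: old-minus-new recognition amplitude (percent-signal units) per ROI/cell
    univariate: dict = field(default_factory=dict)
    #: target encoding-to-recognition pattern correlation per ROI/cell
    ers_r: dict = field(default_factory=dict)
    #: old-trial coupling gain from the seed ROI per target ROI/cell
    ppi_gain: dict = field(default_factory=dict)
    ppi_seed_roi: str = "ifg"
    #: true d' per cell per emotion
    dprime: dict = field(default_factory=dict)
    #: decision criterion on the evidence axis per cell
    decision_criterion: dict = field(default_factory=lambda: {c: 1.7 for c in CELLS})
    confidence_offset: float = 0.5
    baseline_amplitude: float = 1.0
    pattern_scale: float = 3.0
    #: between-subject SDs of the planted effects
    subject_sd_univariate: float = 0.2
    subject_sd_ers_r: float = 0.05
    subject_sd_gain: float = 0.2
    subject_sd_dprime: float = 0.25
    noise: NoiseSpec = field(default_factory=NoiseSpec)

    def validate(self):
        for roi, cells in self.ers_r.items():
            for cell, r in cells.items():
                if not -1.0 < r < 1.0:
                    raise ValidationError(
                        f"target ERS r must be in (-1, 1); got {r} for {roi}/{cell}"
                    )
        for cell, per_emo in self.dprime.items():
            for emo, d in per_emo.items():
                if not np.isfinite(d):
                    raise ValidationError(f"d' must be finite ({cell}/{emo})")
        self.noise.validate()
        return self


def default_effects() -> EffectSpec:
    """Default planted structure: the qualitative study pattern.

    Hippocampus: old-minus-new amplitude and ERS decrease 1d -> 28d under
    PLAC but increase under YOH; the IFG-like ROI shows the reversed
    univariate pattern; the control ROI is flat. IFG -> hippocampus coupling
    during old trials increases over delay under PLAC and decreases under
    YOH. d' declines more over delay under PLAC than YOH, with a smaller
    decline for negative items.
    """
    return EffectSpec(
        univariate={
            "hippocampus": _cell_dict(0.8, 0.2, 0.2, 0.8),
            "ifg": _cell_dict(0.2, 0.8, 0.8, 0.2),
            "control": _cell_dict(0.5, 0.5, 0.5, 0.5),
        },
        ers_r={
            "hippocampus": _cell_dict(0.45, 0.15, 0.15, 0.45),
            "ifg": _cell_dict(0.30, 0.30, 0.30, 0.30),
            "control": _cell_dict(0.30, 0.30, 0.30, 0.30),
        },
        ppi_gain={
            "hippocampus": _cell_dict(0.2, 0.8, 0.8, 0.2),
        },
        dprime={
            ("PLAC", "1d"): {"neutral": 3.1, "negative": 3.2},
            ("PLAC", "28d"): {"neutral": 1.7, "negative": 2.1},
            ("YOH", "1d"): {"neutral": 3.0, "negative": 3.1},
            ("YOH", "28d"): {"neutral": 2.25, "negative": 2.65},
        },
    )


def make_items(spec: CohortSpec) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Item table (old + new, half per emotion) and the old-new pairing."""
    spec.validate()
    half = spec.n_items_old // 2
    rows = []
    for k in range(spec.n_items_old):
        emo = EMOTIONS[0] if k < half else EMOTIONS[1]
        rows.append({"item_id": f"old_{k:03d}", "emotion": emo, "oldness": "old"})
    for k in range(spec.n_items_new):
        emo = EMOTIONS[0] if k < half else EMOTIONS[1]
        rows.append({"item_id": f"new_{k:03d}", "emotion": emo, "oldness": "new"})
    items = pd.DataFrame(rows)
    pairing = pd.DataFrame(
        {
            "old_item": [f"old_{k:03d}" for k in range(spec.n_items_old)],
            "new_item": [f"new_{k:03d}" for k in range(spec.n_items_new)],
        }
    )
    return items, pairing


def _run_events(items: pd.DataFrame, spec: CohortSpec, rng, run: int, phase: str):
    order = rng.permutation(len(items))
    tbl = items.iloc[order].reset_index(drop=True)
    n = len(tbl)
    itis = spec.iti_base + (
        rng.uniform(-spec.iti_jitter, spec.iti_jitter, size=n)
        if spec.iti_jitter > 0
        else np.zeros(n)
    )
    onsets = np.empty(n)
    t = spec.iti_base  # fixed lead-in fixation
    for i in range(n):
        onsets[i] = t
        t += spec.event_duration + itis[i]
    out = tbl.copy()
    out.insert(0, "onset", onsets)
    out.insert(1, "duration", spec.event_duration)
    out["run"] = run
    out["phase"] = phase
    return out


def make_events(spec: CohortSpec, seed: int) -> dict:
    """Per-run event tables for one subject.

    Each encoding run presents every old item exactly once in random order;
    the recognition runs jointly present every old and new item exactly once,
    interleaved randomly and split evenly across runs. Returns a dict with
    'encoding' and 'recognition' DataFrames (run column, per-phase
    numbering) and 'n_scans' per phase/run.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    items, pairing = make_items(spec)
    old = items[items["oldness"] == "old"]

    enc = pd.concat(
        [_run_events(old, spec, rng, r, "encoding") for r in range(spec.n_encoding_runs)],
        ignore_index=True,
    )
    # recognition: shuffle all items once, split across runs
    shuffled = items.iloc[rng.permutation(len(items))].reset_index(drop=True)
    splits = np.array_split(np.arange(len(shuffled)), spec.n_recognition_runs)
    rec_parts = []
    for r, idx in enumerate(splits):
        part = shuffled.iloc[idx].reset_index(drop=True)
        # order within run already random; draw onsets
        ev = _run_events(part, spec, rng, r, "recognition")
        # _run_events reshuffles; harmless (still each item once overall)
        rec_parts.append(ev)
    rec = pd.concat(rec_parts, ignore_index=True)

    def _scans(ev):
        out = {}
        for r, grp in ev.groupby("run"):
            end = grp["onset"].max() + spec.event_duration + RUN_TAIL
            out[int(r)] = int(np.ceil(end / spec.tr))
        return out

    return {
        "encoding": enc,
        "recognition": rec,
        "items": items,
        "pairing": pairing,
        "n_scans": {"encoding": _scans(enc), "recognition": _scans(rec)},
    }


def make_group_table(spec: CohortSpec) -> pd.DataFrame:
    """Balanced subject-to-cell table with balanced sex per cell."""
    spec.validate()
    rows = []
    sid = 0
    for drug, delay in CELLS:
        for k in range(spec.n_per_group):
            rows.append(
                {
                    "subject": f"sub-{sid:03d}",
                    "drug": drug,
                    "delay": delay,
                    "sex": "m" if k < (spec.n_per_group + 1) // 2 else "f",
                }
            )
            sid += 1
    return pd.DataFrame(rows)


def default_rois(grid_shape) -> dict:
    """Three disjoint spherical ROIs scaled to the grid: a hippocampus-like
    target, an IFG-like neocortical ROI, and a null control ROI."""
    shape = np.asarray(grid_shape)
    radius = max(2, int(round(min(shape) / 8)))
    # corner-spread placement keeps the spheres disjoint down to 8^3 grids
    centers = {
        "hippocampus": (0.25, 0.25, 0.30),
        "ifg": (0.75, 0.75, 0.30),
        "control": (0.25, 0.75, 0.75),
    }
    ii, jj, kk = np.indices(tuple(shape))
    rois = {}
    for name, frac in centers.items():
        c = np.round(shape * np.asarray(frac)).astype(int)
        d2 = (ii - c[0]) ** 2 + (jj - c[1]) ** 2 + (kk - c[2]) ** 2
        rois[name] = d2 <= radius**2
    # disjointness check (centers are far apart for any grid >= 8^3)
    total = sum(m.sum() for m in rois.values())
    union = np.zeros(tuple(shape), bool)
    for m in rois.values():
        union |= m
    if union.sum() != total:
        raise ValidationError("default ROIs overlap on this grid")
    return rois


RESPONSE_BY_BIN = ("definitely_new", "rather_new", "rather_old", "definitely_old")


def make_behavior(
    effects: EffectSpec,
    group: pd.DataFrame,
    spec: CohortSpec,
    seed: int,
    subject_dprime: dict | None = None,
) -> pd.DataFrame:
    """Trial-level recognition responses for every subject.

    Evidence is N(d', 1) for old and N(0, 1) for new items; the decision
    criterion lambda splits old/new responses and symmetric confidence
    criteria at lambda +/- confidence_offset split definite from hesitant
    responses. ``subject_dprime`` optionally overrides the per-subject true
    d' (dict subject -> {emotion: d'}); otherwise cell values plus
    between-subject jitter are drawn here.
    """
    effects.validate()
    rng = np.random.default_rng(seed)
    items, _ = make_items(spec)
    is_old = (items["oldness"] == "old").to_numpy()
    emo = items["emotion"].to_numpy()
    frames = []
    for _, subj in group.iterrows():
        cell = (subj["drug"], subj["delay"])
        lam = effects.decision_criterion[cell]
        if subject_dprime and subj["subject"] in subject_dprime:
            dps = subject_dprime[subj["subject"]]
        else:
            shift = rng.normal(0.0, effects.subject_sd_dprime)
            dps = {e: effects.dprime[cell][e] + shift for e in EMOTIONS}
        true_d = np.array([dps[e] for e in emo])
        mu = np.where(is_old, true_d, 0.0)
        ev = rng.normal(mu, 1.0)
        lo, hi = lam - effects.confidence_offset, lam + effects.confidence_offset
        b = (ev >= lo).astype(int) + (ev >= lam) + (ev >= hi)
        frames.append(
            pd.DataFrame(
                {
                    "subject": subj["subject"],
                    "item_id": items["item_id"],
                    "emotion": emo,
                    "oldness": items["oldness"],
                    "response": np.asarray(RESPONSE_BY_BIN)[b],
                    "evidence": ev,
                    "true_dprime": true_d,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def _ar1_series(rng, n, rho, sd, size=()):
    """Stationary AR(1) series, shape size + (n,).

    The first innovation keeps the full stationary SD so the recursion is
    stationary from scan 0.
    """
    w = rng.normal(0.0, 1.0, size=size + (n,))
    if rho == 0.0:
        return sd * w
    w[..., 0] *= sd
    w[..., 1:] *= sd * np.sqrt(1.0 - rho**2)
    return lfilter([1.0], [1.0, -rho], w, axis=-1)


def _subject_patterns(spec, effects, cell, rois, brain_mask, rng, jitter_r):
    """Per-item voxel patterns for both phases over the brain mask.

    Returns dict phase -> DataFrame-free mapping item_id -> vector (n_brain,)
    as a single (n_items_total, n_brain) array keyed by the item table order.
    """
    items, _ = make_items(spec)
    nb = int(brain_mask.sum())
    n_items = len(items)
    # per-voxel ERS target r for this subject/cell (0 outside effect ROIs)
    r_map = np.zeros(nb)
    for roi, cells in effects.ers_r.items():
        if roi not in rois:
            continue
        r0 = float(np.clip(cells[cell] + jitter_r, -0.95, 0.95))
        r_map[rois[roi][brain_mask]] = r0
    enc = rng.normal(0.0, 1.0, size=(n_items, nb))
    fresh = rng.normal(0.0, 1.0, size=(n_items, nb))
    rec = r_map[None, :] * enc + np.sqrt(1.0 - r_map[None, :] ** 2) * fresh
    is_new = (items["oldness"] == "new").to_numpy()
    # new items never appear at encoding; their recognition pattern is
    # independent of everything by construction (r plays no role)
    rec[is_new] = rng.normal(0.0, 1.0, size=(int(is_new.sum()), nb))
    if effects.noise.pattern_noise_sd > 0:
        enc = enc + rng.normal(0.0, effects.noise.pattern_noise_sd, enc.shape)
        rec = rec + rng.normal(0.0, effects.noise.pattern_noise_sd, rec.shape)
    return items, enc, rec


@dataclass
class Subject:
    subject_id: str
    drug: str
    delay: str
    events: dict
    volumes: dict  # phase -> list[Volume4D]
    brain_mask: np.ndarray
    truth: dict


def simulate_subject(
    spec: CohortSpec,
    effects: EffectSpec,
    drug: str,
    delay: str,
    seed,
    rois: dict | None = None,
    subject_id: str = "sub-000",
    phases: tuple = ("encoding", "recognition"),
) -> Subject:
    """Generate one subject's events and BOLD runs with planted effects.

    ``phases`` restricts which sessions get BOLD volumes (events and
    patterns are always generated for both so the draw sequence is stable).
    """
    spec.validate()
    effects.validate()
    cell = (drug, delay)
    if cell not in CELLS:
        raise ValidationError(f"unknown cell {cell}")
    rng = np.random.default_rng(seed)
    rois = default_rois(spec.grid_shape) if rois is None else rois
    for name, m in rois.items():
        if m.shape != tuple(spec.grid_shape):
            raise ValidationError(f"ROI {name!r} does not fit the grid")
    brain_mask = np.ones(spec.grid_shape, bool)
    nb = int(brain_mask.sum())

    events = make_events(spec, int(rng.integers(2**31)))
    jit_r = rng.normal(0.0, effects.subject_sd_ers_r)
    items, enc_pat, rec_pat = _subject_patterns(
        spec, effects, cell, rois, brain_mask, rng, jit_r
    )
    item_pos = {it: k for k, it in enumerate(items["item_id"])}

    jit_uni = {
        roi: rng.normal(0.0, effects.subject_sd_univariate)
        for roi in effects.univariate
    }
    jit_gain = {
        roi: rng.normal(0.0, effects.subject_sd_gain) for roi in effects.ppi_gain
    }
    truth = {
        "cell": cell,
        "univariate": {
            roi: cells[cell] + jit_uni.get(roi, 0.0)
            for roi, cells in effects.univariate.items()
        },
        "ers_r": {
            roi: float(np.clip(cells[cell] + jit_r, -0.95, 0.95))
            for roi, cells in effects.ers_r.items()
        },
        "ppi_gain": {
            roi: cells[cell] + jit_gain.get(roi, 0.0)
            for roi, cells in effects.ppi_gain.items()
        },
        "seed": None,
    }

    noise = effects.noise
    affine = default_affine(spec.voxel_size_mm)
    volumes = {}
    for phase in ("encoding", "recognition"):
        if phase not in phases:
            continue
        runs = []
        ev_all = events[phase]
        pats = enc_pat if phase == "encoding" else rec_pat
        for r in sorted(ev_all["run"].unique()):
            ev = ev_all[ev_all["run"] == r].reset_index(drop=True)
            ns = events["n_scans"][phase][int(r)]
            C = _convolved_columns(
                [
                    (np.array([row["onset"]]), np.array([row["duration"]]))
                    for _, row in ev.iterrows()
                ],
                ns,
                spec.tr,
            )
            # trial amplitude images
            A = np.full((len(ev), nb), effects.baseline_amplitude)
            rows = np.array([item_pos[i] for i in ev["item_id"]])
            A = A + effects.pattern_scale * pats[rows]
            if phase == "recognition":
                for roi, cells in effects.univariate.items():
                    if roi not in rois:
                        continue
                    delta = cells[cell] + jit_uni.get(roi, 0.0)
                    sel = rois[roi][brain_mask]
                    signs = np.where(ev["oldness"].to_numpy() == "old", 0.5, -0.5)
                    A[:, sel] += np.outer(signs, np.full(sel.sum(), delta))
            Y = C @ A  # (scans, voxels)

            # shared per-ROI fluctuation (+ planted PPI coupling)
            roi_series = {
                name: _ar1_series(rng, ns, noise.ar1, noise.roi_fluctuation_sd)
                for name in rois
            }
            for name, series in roi_series.items():
                Y[:, rois[name][brain_mask]] += series[:, None]
            if phase == "recognition" and effects.ppi_gain:
                seed_series = roi_series.get(effects.ppi_seed_roi)
                if seed_series is not None:
                    old_ev = ev[ev["oldness"] == "old"]
                    if len(old_ev):
                        m_old = _convolved_columns(
                            [
                                (
                                    old_ev["onset"].to_numpy(float),
                                    old_ev["duration"].to_numpy(float),
                                )
                            ],
                            ns,
                            spec.tr,
                        )[:, 0]
                        mod = seed_series * m_old
                        for roi, cells in effects.ppi_gain.items():
                            if roi not in rois:
                                continue
                            g = cells[cell] + jit_gain.get(roi, 0.0)
                            Y[:, rois[roi][brain_mask]] += g * mod[:, None]

            # slow cosine drift below the high-pass cutoff
            if noise.drift_amplitude > 0 and noise.n_drift_components > 0:
                i = np.arange(ns)
                for k in range(1, noise.n_drift_components + 1):
                    basis = np.cos(np.pi * k * (2 * i + 1) / (2 * ns))
                    coef = rng.normal(0.0, noise.drift_amplitude, size=nb)
                    Y += np.outer(basis, coef)

            if noise.scan_noise_sd > 0:
                Y += _ar1_series(
                    rng, ns, noise.ar1, noise.scan_noise_sd, size=(nb,)
                ).T

            data = np.zeros(tuple(spec.grid_shape) + (ns,))
            data[brain_mask, :] = Y.T
            runs.append(Volume4D(data, spec.tr, brain_mask, affine))
        volumes[phase] = runs

    return Subject(
        subject_id=subject_id,
        drug=drug,
        delay=delay,
        events=events,
        volumes=volumes,
        brain_mask=brain_mask,
        truth=truth,
    )


@dataclass
class Cohort:
    """A full simulated cohort; subject volumes are generated on demand so
    large cohorts never have to be held in memory at once."""

    spec: CohortSpec
    effects: EffectSpec
    group: pd.DataFrame
    rois: dict
    seed: int
    responses: pd.DataFrame

    def subject(self, subject_id: str) -> Subject:
        row = self.group[self.group["subject"] == subject_id]
        if not len(row):
            raise ValidationError(f"unknown subject {subject_id!r}")
        idx = int(row.index[0])
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return simulate_subject(
            self.spec,
            self.effects,
            row.iloc[0]["drug"],
            row.iloc[0]["delay"],
            ss,
            rois=self.rois,
            subject_id=subject_id,
        )

    def __iter__(self):
        for sid in self.group["subject"]:
            yield self.subject(sid)


def simulate_cohort(
    spec: CohortSpec, effects: EffectSpec | None = None, seed: int = 0
) -> Cohort:
    """Assemble a cohort: group table, ROI masks, behavior; volumes lazily."""
    spec.validate()
    effects = default_effects() if effects is None else effects
    effects.validate()
    group = make_group_table(spec)
    rois = default_rois(spec.grid_shape)
    behav_seed = np.random.SeedSequence(entropy=seed, spawn_key=(10**6,))
    responses = make_behavior(
        effects, group, spec, np.random.default_rng(behav_seed).integers(2**31)
    )
    return Cohort(
        spec=spec,
        effects=effects,
        group=group,
        rois=rois,
        seed=seed,
        responses=responses,
    )
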