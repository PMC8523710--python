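"""End-to-end orchestration: subject-level analysis and group inference.

Per subject the pipeline runs

1. a condition-wise GLM on smoothed data (one model across all encoding and
   recognition runs, one regressor per run x condition, run constants,
   cosine drifts, AR(1) prewhitening) giving the old-minus-new and
   recognition-minus-encoding contrast maps;
2. a trial-wise GLM on unsmoothed data (one regressor per trial) whose
   beta/SE t-patterns feed the searchlight encoding-retrieval similarity
   maps (final encoding run vs recognition); and
3. a PPI model seeded on the configured ROI's first eigenvariate
   (high-passed, smoothed data), with the old-vs-new contrast as the
   psychological factor.

Group stage: per-subject maps enter a 2x2 drug x delay interaction test
with ROI-restricted max-statistic permutation FWE and Welch post-hoc cell
comparisons; behavioral d' enters the factorial interaction test.
"""

from __future__ import annotations

import json
import time
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import behav as bh
from . import ers as ers_mod
from . import firstlevel as fl
from . import grouplevel as gl
from . import ppi as ppi_mod
from .datatypes import Volume4D, concat_runs
from .errors import MemtraceError
from .io import AnalysisSettings, RunConfig, write_tsv
from .simcohort import Cohort, Subject, simulate_cohort

__all__ = ["combined_events", "analyze_subject", "group_inference", "run_all"]

MAP_KINDS = ("old_minus_new", "recognition_minus_encoding", "ers", "ppi_interaction")


def combined_events(subject: Subject) -> pd.DataFrame:
    """Concatenate encoding and recognition events into one 6-run table.

    Recognition run labels are offset past the encoding runs and a single
    ``condition`` column is added (emotion at encoding, emotion x oldness at
    recognition) so one condition-wise design covers both tasks.
    """
    enc = subject.events["encoding"].copy()
    rec = subject.events["recognition"].copy()
    n_enc_runs = int(enc["run"].max()) + 1
    rec["run"] = rec["run"] + n_enc_runs
    enc["condition"] = "enc_" + enc["emotion"].astype(str)
    rec["condition"] = (
        "rec_" + rec["emotion"].astype(str) + "_" + rec["oldness"].astype(str)
    )
    return pd.concat([enc, rec], ignore_index=True)


def _combined_scans(subject: Subject) -> dict:
    n_enc_runs = int(subject.events["encoding"]["run"].max()) + 1
    scans = dict(subject.events["n_scans"]["encoding"])
    for r, ns in subject.events["n_scans"]["recognition"].items():
        scans[r + n_enc_runs] = ns
    return scans


def _condition_contrasts(design: fl.DesignMatrix) -> dict:
    """Old-minus-new and recognition-minus-encoding weight vectors."""
    info = design.column_info
    names = [str(n) for n in info["name"]]
    task = (info["kind"] == "task").to_numpy()
    is_rec = np.array(["condition-rec_" in n for n in names]) & task
    is_enc = np.array(["condition-enc_" in n for n in names]) & task
    is_old = np.array([n.endswith("_old") for n in names]) & is_rec
    is_new = np.array([n.endswith("_new") for n in names]) & is_rec
    w_on = np.zeros(len(names))
    if is_old.any() and is_new.any():
        w_on[is_old] = 1.0 / is_old.sum()
        w_on[is_new] = -1.0 / is_new.sum()
    w_re = np.zeros(len(names))
    if is_rec.any() and is_enc.any():
        w_re[is_rec] = 1.0 / is_rec.sum()
        w_re[is_enc] = -1.0 / is_enc.sum()
    return {"old_minus_new": w_on, "recognition_minus_encoding": w_re}


def _highpass(Y: np.ndarray, row_run: np.ndarray, tr: float, cutoff: float) -> np.ndarray:
    """Project out per-run cosine drifts and run means."""
    out = Y.astype(float).copy()
    for r in pd.unique(row_run):
        idx = np.flatnonzero(row_run == r)
        basis = fl.dct_drift_basis(len(idx), tr, cutoff)
        B = np.column_stack([np.ones(len(idx)), basis])
        seg = out[idx]
        coef, *_ = np.linalg.lstsq(B, seg, rcond=None)
        out[idx] = seg - B @ coef
    return out


def analyze_subject(
    subject: Subject,
    rois: dict,
    settings: AnalysisSettings | None = None,
    voxel_size_mm: float = 3.0,
    searchlight=None,
    pairing=None,
    stages=("univariate", "ers", "ppi"),
) -> dict:
    """First-level maps for one subject (3-D arrays, NaN off-center).

    ``stages`` selects which map families to compute ("univariate" gives the
    condition-GLM contrasts, "ers" the searchlight similarity maps, "ppi"
    the connectivity interaction map).
    """
    settings = settings or AnalysisSettings()
    needs_full = {"univariate", "ers"} & set(stages)
    vol = None
    if needs_full:
        ev = combined_events(subject)
        scans = _combined_scans(subject)
        runs = subject.volumes["encoding"] + subject.volumes["recognition"]
        vol = concat_runs(runs)
        tr = vol.tr
    else:
        tr = subject.volumes["recognition"][0].tr
    out = {"meta": {}}

    sm = None
    if "univariate" in stages:
        sm = fl.smooth(vol, settings.fwhm_mm, voxel_size_mm)

    if "univariate" in stages:
        design_c = fl.build_design(
            ev, scans, tr, mode="condition", condition_cols=("condition",),
            hp_cutoff=settings.hp_cutoff,
        )
        fit_c = fl.fit_glm(sm, design_c, ar1=settings.ar1)
        weights = _condition_contrasts(design_c)
        eff_on, _ = fl.contrast(fit_c, weights["old_minus_new"])
        eff_re, _ = fl.contrast(fit_c, weights["recognition_minus_encoding"])
        out["old_minus_new"] = eff_on.data
        out["recognition_minus_encoding"] = eff_re.data
        out["meta"]["rho_condition"] = fit_c.rho

    if "ers" in stages:
        # trial-wise GLM on unsmoothed data -> t patterns -> searchlight
        design_t = fl.build_design(
            ev, scans, tr, mode="trialwise", hp_cutoff=settings.hp_cutoff,
        )
        fit_t = fl.fit_glm(vol, design_t, ar1=settings.ar1)
        enc_pat = fl.trial_patterns(fit_t, phase="encoding", last_run_only=True)
        rec_pat = fl.trial_patterns(fit_t, phase="recognition")
        if searchlight is None:
            searchlight = ers_mod.build_searchlight(
                vol.grid_shape,
                vol.mask,
                radius=settings.searchlight_radius,
                min_voxels=settings.searchlight_min_voxels,
            )
        pairing = subject.events["pairing"] if pairing is None else pairing
        ersm = ers_mod.ers_map(
            enc_pat, rec_pat, pairing, searchlight, variant=settings.ers_variant
        )
        out["ers"] = ersm.ers.data
        out["eos"] = ersm.eos.data
        out["ens"] = ersm.ens.data
        out["meta"]["rho_trialwise"] = fit_t.rho

    if "ppi" in stages:
        # PPI on the recognition runs only (sliced from the smoothed concat
        # when available, else smoothed directly)
        rec_scans = subject.events["n_scans"]["recognition"]
        n_rec = sum(rec_scans.values())
        if sm is not None:
            rec_sm = Volume4D(sm.data[..., -n_rec:], tr, vol.mask, vol.affine)
        else:
            rec_vol = concat_runs(subject.volumes["recognition"])
            rec_sm = fl.smooth(rec_vol, settings.fwhm_mm, voxel_size_mm)
        seed_roi = rois[settings.ppi_seed_roi]
        rec_ev = subject.events["recognition"]
        row_run = np.concatenate([[r] * rec_scans[r] for r in sorted(rec_scans)])
        seed_ts = _highpass(
            rec_sm.timeseries(mask=seed_roi), row_run, tr, settings.hp_cutoff
        )
        seed = ppi_mod.first_eigenvariate(seed_ts, roi_label=settings.ppi_seed_roi)
        design_p = ppi_mod.build_ppi_design(
            seed, rec_ev, tr, rec_scans, hp_cutoff=settings.hp_cutoff
        )
        eff_ppi, _ = ppi_mod.ppi_map(rec_sm, design_p, ar1=settings.ar1)
        out["ppi_interaction"] = eff_ppi.data
        out["meta"]["seed_explained_variance"] = seed.explained_variance

    return out


def behavioral_stats(responses: pd.DataFrame, group: pd.DataFrame) -> dict:
    """Per-subject d' (plain and confidence-weighted) and group tests."""
    rows = []
    for sid, tbl in responses.groupby("subject"):
        counts = bh.counts_from_responses(tbl)
        sdt = bh.d_prime(counts)
        wsdt = bh.weighted_d_prime(tbl)
        rows.append(
            {
                "subject": sid,
                "hit_rate": sdt.hit_rate,
                "fa_rate": sdt.fa_rate,
                "d_prime": sdt.d_prime,
                "criterion": sdt.criterion,
                "weighted_d_prime": wsdt.d_prime,
            }
        )
    per_subject = pd.DataFrame(rows).merge(
        group[["subject", "drug", "delay"]], on="subject"
    )
    tbl = per_subject.rename(columns={"d_prime": "value"})
    inter = bh.factorial_interaction(tbl)
    inter_w = bh.factorial_interaction(
        per_subject.rename(columns={"weighted_d_prime": "value"})
    )

    def _cell(drug, delay):
        sel = (per_subject["drug"] == drug) & (per_subject["delay"] == delay)
        return per_subject.loc[sel, "d_prime"].to_numpy()

    posthoc = {
        "PLAC_1d_vs_28d": bh.welch_t(_cell("PLAC", "1d"), _cell("PLAC", "28d")),
        "YOH_1d_vs_28d": bh.welch_t(_cell("YOH", "1d"), _cell("YOH", "28d")),
    }
    return {
        "per_subject": per_subject,
        "interaction": inter,
        "interaction_weighted": inter_w,
        "posthoc": posthoc,
        "mean_d_prime": float(per_subject["d_prime"].mean()),
        "mean_hit_rate": float(per_subject["hit_rate"].mean()),
        "mean_fa_rate": float(per_subject["fa_rate"].mean()),
    }


def group_inference(
    subject_maps: dict,
    group: pd.DataFrame,
    rois: dict,
    settings: AnalysisSettings,
    seed: int,
    map_kinds=MAP_KINDS,
) -> dict:
    """Interaction + permutation FWE per map kind per ROI."""
    out = {}
    for kind in map_kinds:
        maps = {sid: m[kind] for sid, m in subject_maps.items()}
        design = gl.GroupDesign(table=group, map_kind=kind)
        clusters = gl.permutation_fwe(
            maps,
            design,
            rois,
            n_perm=settings.n_perm,
            cluster_forming_p=settings.cluster_forming_p,
            seed=seed + zlib.crc32(kind.encode()) % 10007,
        )
        out[kind] = {}
        for cl in clusters:
            out[kind][cl.roi] = {
                "peak_t": cl.peak_stat,
                "peak_ijk": list(cl.peak_ijk),
                "extent": cl.extent,
                "p_corr": cl.p_corr,
                "p_corr_bonferroni": cl.p_corr_bonferroni,
                "posthoc": gl.posthoc_cells(cl),
            }
    return out


def run_all(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Simulate (unless given) and analyze a full cohort; return the report.

    The report records all seeds, the planted effect structure, behavioral
    statistics, and for every map kind x ROI the interaction peak, corrected
    p, and post-hoc Welch tests; it is written as JSON (plus cluster and
    per-subject tables as TSV) under ``config.out_dir``.
    """
    config.validate()
    t0 = time.time()
    timings = {}
    if cohort is None:
        cohort = simulate_cohort(config.cohort, seed=config.seed)
    timings["simulate"] = time.time() - t0

    stage = time.time()
    behav_report = behavioral_stats(cohort.responses, cohort.group)
    timings["behav"] = time.time() - stage

    stage = time.time()
    settings = config.analysis
    sl = None
    subject_maps = {}
    meta = {}
    for subject in cohort:
        try:
            res = analyze_subject(
                subject,
                cohort.rois,
                settings,
                voxel_size_mm=cohort.spec.voxel_size_mm,
                searchlight=sl,
            )
        except MemtraceError as exc:
            raise MemtraceError(
                f"first-level stage failed for {subject.subject_id}: {exc}"
            ) from exc
        subject_maps[subject.subject_id] = res
        meta[subject.subject_id] = res.pop("meta")
    timings["firstlevel"] = time.time() - stage

    stage = time.time()
    group_report = group_inference(
        subject_maps, cohort.group, cohort.rois, settings, seed=config.seed
    )
    timings["group"] = time.time() - stage

    from .io import _effects_to_json

    report = {
        "seed": config.seed,
        "spec": {
            "n_per_group": cohort.spec.n_per_group,
            "grid_shape": list(cohort.spec.grid_shape),
            "tr": cohort.spec.tr,
            "n_items_old": cohort.spec.n_items_old,
        },
        "planted": _effects_to_json(cohort.effects),
        "behavior": {
            "mean_d_prime": behav_report["mean_d_prime"],
            "mean_hit_rate": behav_report["mean_hit_rate"],
            "mean_fa_rate": behav_report["mean_fa_rate"],
            "interaction": behav_report["interaction"],
            "interaction_weighted": behav_report["interaction_weighted"],
            "posthoc": behav_report["posthoc"],
        },
        "group": group_report,
        "subject_meta": meta,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
    }

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "report.json").write_text(json.dumps(report, indent=2, default=float))
    write_tsv(behav_report["per_subject"], out / "sdt_per_subject.tsv")
    cluster_rows = []
    for kind, per_roi in group_report.items():
        for roi, res in per_roi.items():
            cluster_rows.append(
                {
                    "map_kind": kind,
                    "roi": roi,
                    "peak_x": res["peak_ijk"][0],
                    "peak_y": res["peak_ijk"][1],
                    "peak_z": res["peak_ijk"][2],
                    "peak_t": res["peak_t"],
                    "k": res["extent"],
                    "p_corr": res["p_corr"],
                    "p_corr_bonferroni": res["p_corr_bonferroni"],
                }
            )
    write_tsv(pd.DataFrame(cluster_rows), out / "clusters.tsv")
    return report
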