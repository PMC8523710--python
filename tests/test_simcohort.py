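"""Generator contracts: event structure, determinism, planted-pattern
self-checks, and the signal-detection response model."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import norm

from memtrace.errors import ValidationError
from memtrace.firstlevel import _convolved_columns
from memtrace.simcohort import (
    CohortSpec,
    EffectSpec,
    NoiseSpec,
    _cell_dict,
    _subject_patterns,
    default_effects,
    default_rois,
    make_behavior,
    make_events,
    make_group_table,
    make_items,
    simulate_subject,
)


class TestEvents:
    def test_default_structure(self):
        spec = CohortSpec()
        ev = make_events(spec, seed=3)
        enc, rec = ev["encoding"], ev["recognition"]
        assert sorted(enc["run"].unique()) == [0, 1, 2]
        for r in range(3):
            run = enc[enc["run"] == r]
            assert len(run) == 60
            # every old item exactly once per encoding run
            assert sorted(run["item_id"]) == sorted(ev["pairing"]["old_item"])
            assert run["onset"].is_monotonic_increasing
        assert len(rec) == 120
        assert rec["item_id"].is_unique
        assert set(rec["oldness"]) == {"old", "new"}

    def test_iti_bounds_and_order(self):
        spec = CohortSpec()
        ev = make_events(spec, seed=9)
        for phase in ("encoding", "recognition"):
            for _, run in ev[phase].groupby("run"):
                gaps = np.diff(run["onset"].to_numpy())
                lo = spec.event_duration + spec.iti_base - spec.iti_jitter
                hi = spec.event_duration + spec.iti_base + spec.iti_jitter
                assert np.all(gaps >= lo - 1e-9)
                assert np.all(gaps <= hi + 1e-9)

    def test_zero_jitter_gaps_are_exact(self):
        spec = CohortSpec(iti_jitter=0.0)
        ev = make_events(spec, seed=1)
        run = ev["encoding"][ev["encoding"]["run"] == 0]
        gaps = np.diff(run["onset"].to_numpy())
        assert np.allclose(gaps, spec.event_duration + spec.iti_base)

    def test_same_seed_identical(self):
        a = make_events(CohortSpec(), seed=5)
        b = make_events(CohortSpec(), seed=5)
        pd.testing.assert_frame_equal(a["encoding"], b["encoding"])
        pd.testing.assert_frame_equal(a["recognition"], b["recognition"])

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_items_old": 0, "n_items_new": 0},
            {"n_items_old": 60, "n_items_new": 40},
            {"n_encoding_runs": 0},
            {"iti_base": 1.0, "iti_jitter": 2.0},
            {"event_duration": -1.0},
        ],
    )
    def test_invalid_specs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            make_events(CohortSpec(**kwargs), seed=0)

    @settings(max_examples=15, deadline=None)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_event_timing_property(self, seed):
        spec = CohortSpec(n_items_old=10, n_items_new=10)
        ev = make_events(spec, seed=seed)
        for phase in ("encoding", "recognition"):
            for r, run in ev[phase].groupby("run"):
                onsets = run["onset"].to_numpy()
                assert np.all(np.diff(onsets) > 0)
                end = onsets.max() + spec.event_duration
                assert end <= ev["n_scans"][phase][int(r)] * spec.tr


class TestGroupAndItems:
    def test_group_table_balanced_cells_and_sex(self):
        tbl = make_group_table(CohortSpec())
        counts = tbl.groupby(["drug", "delay"]).size()
        assert (counts == 26).all() and len(counts) == 4
        sex = tbl.groupby(["drug", "delay", "sex"]).size()
        assert (sex == 13).all()

    def test_item_pairing_same_emotion(self):
        items, pairing = make_items(CohortSpec())
        emo = dict(zip(items["item_id"], items["emotion"]))
        for _, row in pairing.iterrows():
            assert emo[row["old_item"]] == emo[row["new_item"]]

    def test_default_rois_disjoint_and_inside(self):
        rois = default_rois((16, 16, 16))
        assert set(rois) == {"hippocampus", "ifg", "control"}
        union = sum(m.sum() for m in rois.values())
        stacked = np.zeros((16, 16, 16), int)
        for m in rois.values():
            stacked += m
        assert stacked.max() == 1 and stacked.sum() == union


def _pattern_effects(r0, **noise_kw):
    return EffectSpec(
        univariate={},
        ppi_gain={},
        ers_r={"hippocampus": _cell_dict(r0, r0, r0, r0)},
        dprime=default_effects().dprime,
        subject_sd_ers_r=0.0,
        noise=NoiseSpec(pattern_noise_sd=0.0, **noise_kw),
    )


class TestPlantedPatterns:
    def test_planted_correlation_self_check(self):
        """Emitted encoding/recognition patterns correlate at the planted r
        inside the ROI (generator self-check by direct correlation)."""
        spec = CohortSpec(grid_shape=(12, 12, 12))
        rois = default_rois(spec.grid_shape)
        brain = np.ones(spec.grid_shape, bool)
        rng = np.random.default_rng(0)
        items, enc, rec = _subject_patterns(
            spec, _pattern_effects(0.6), ("PLAC", "1d"), rois, brain, rng, 0.0
        )
        sel = rois["hippocampus"][brain]
        old = (items["oldness"] == "old").to_numpy()
        rs = [
            np.corrcoef(enc[i, sel], rec[i, sel])[0, 1]
            for i in np.flatnonzero(old)
        ]
        assert abs(np.mean(rs) - 0.6) < 0.05

    def test_null_correlation_matches_nonmatched(self):
        spec = CohortSpec(grid_shape=(12, 12, 12))
        rois = default_rois(spec.grid_shape)
        brain = np.ones(spec.grid_shape, bool)
        rng = np.random.default_rng(1)
        items, enc, rec = _subject_patterns(
            spec, _pattern_effects(0.0), ("PLAC", "1d"), rois, brain, rng, 0.0
        )
        sel = rois["hippocampus"][brain]
        old_idx = np.flatnonzero((items["oldness"] == "old").to_numpy())
        matched = [np.corrcoef(enc[i, sel], rec[i, sel])[0, 1] for i in old_idx]
        shuffled = [
            np.corrcoef(enc[i, sel], rec[j, sel])[0, 1]
            for i, j in zip(old_idx, np.roll(old_idx, 1))
        ]
        assert abs(np.mean(matched)) < 0.06
        assert abs(np.mean(matched) - np.mean(shuffled)) < 0.08

    def test_noiseless_forward_model_is_hrf_convolution(self):
        """With all noise off, every voxel's time course is exactly the sum
        of HRF-convolved boxcars times that voxel's trial amplitudes."""
        spec = CohortSpec(
            n_per_group=1, grid_shape=(8, 8, 8), n_items_old=4, n_items_new=4
        )
        eff = EffectSpec(
            univariate={},
            ppi_gain={},
            ers_r={},
            dprime=default_effects().dprime,
            subject_sd_univariate=0.0,
            subject_sd_ers_r=0.0,
            pattern_scale=0.0,
            noise=NoiseSpec(
                scan_noise_sd=0.0, drift_amplitude=0.0, roi_fluctuation_sd=0.0
            ),
        )
        subj = simulate_subject(spec, eff, "PLAC", "1d", seed=0)
        run0 = subj.volumes["encoding"][0]
        ev = subj.events["encoding"]
        ev = ev[ev["run"] == 0]
        C = _convolved_columns(
            [(ev["onset"].to_numpy(), ev["duration"].to_numpy())],
            run0.n_scans,
            spec.tr,
        )[:, 0]
        # amplitude is the shared baseline (patterns and deltas disabled)
        expected = eff.baseline_amplitude * C
        voxel = run0.data[4, 4, 4, :]
        assert np.allclose(voxel, expected, atol=1e-10)

    def test_bold_determinism(self):
        spec = CohortSpec(
            n_per_group=1, grid_shape=(8, 8, 8), n_items_old=4, n_items_new=4
        )
        a = simulate_subject(spec, default_effects(), "YOH", "28d", seed=11)
        b = simulate_subject(spec, default_effects(), "YOH", "28d", seed=11)
        np.testing.assert_array_equal(
            a.volumes["recognition"][0].data, b.volumes["recognition"][0].data
        )


class TestBehaviorModel:
    def _rates(self, d, lam, n_subj=40, seed=0):
        spec = CohortSpec(n_per_group=n_subj, grid_shape=(8, 8, 8))
        eff = EffectSpec(
            univariate={},
            ppi_gain={},
            ers_r={},
            dprime={c: {"neutral": d, "negative": d} for c in
                    [("PLAC", "1d"), ("PLAC", "28d"), ("YOH", "1d"), ("YOH", "28d")]},
            decision_criterion={c: lam for c in
                                [("PLAC", "1d"), ("PLAC", "28d"),
                                 ("YOH", "1d"), ("YOH", "28d")]},
            subject_sd_dprime=0.0,
        )
        group = make_group_table(spec).iloc[: n_subj]  # one cell is enough
        resp = make_behavior(eff, group, spec, seed=seed)
        old = resp[resp["oldness"] == "old"]
        new = resp[resp["oldness"] == "new"]
        is_old_resp = lambda s: s.isin(["rather_old", "definitely_old"])
        return (
            is_old_resp(old["response"]).mean(),
            is_old_resp(new["response"]).mean(),
        )

    def test_null_sensitivity_equal_rates(self):
        h, f = self._rates(d=0.0, lam=0.5)
        assert abs(h - f) < 0.03

    def test_closed_form_hit_and_fa_rates(self):
        """d' = 2, criterion at 1: hit rate -> Phi(1), FA rate -> Phi(-1)."""
        h, f = self._rates(d=2.0, lam=1.0)
        assert abs(h - norm.cdf(1.0)) < 0.02
        assert abs(f - norm.cdf(-1.0)) < 0.02

    def test_every_trial_answered_on_four_point_scale(self):
        spec = CohortSpec(n_per_group=2, grid_shape=(8, 8, 8))
        resp = make_behavior(
            default_effects(), make_group_table(spec), spec, seed=2
        )
        assert len(resp) == 8 * 120
        assert set(resp["response"]) <= {
            "definitely_new", "rather_new", "rather_old", "definitely_old"
        }

    def test_invalid_target_r_rejected(self):
        eff = EffectSpec(
            ers_r={"hippocampus": _cell_dict(1.2, 0.1, 0.1, 0.1)},
            dprime=default_effects().dprime,
        )
        with pytest.raises(ValidationError):
            eff.validate()
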