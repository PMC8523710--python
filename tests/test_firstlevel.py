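"""GLM engine: HRF shape, design construction, OLS/AR(1) estimation,
contrasts, trial patterns, smoothing."""

import warnings

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from memtrace.datatypes import Volume4D
from memtrace.errors import DesignError, ValidationError
from memtrace.firstlevel import (
    build_design,
    canonical_hrf,
    contrast,
    dct_drift_basis,
    fit_glm,
    hrf_dense,
    smooth,
    trial_patterns,
)


class TestHrf:
    def test_zero_at_origin(self):
        assert canonical_hrf(2.0)[0] == 0.0

    def test_peak_location(self):
        t = np.arange(0, 32, 0.001)
        h = hrf_dense(t)
        assert 4.5 <= t[np.argmax(h)] <= 5.5

    def test_late_tail_small(self):
        t = np.arange(28, 32, 0.01)
        assert np.max(np.abs(hrf_dense(t))) < 0.01 * hrf_dense(
            np.arange(0, 32, 0.01)
        ).max()

    def test_peak_normalized(self):
        assert canonical_hrf(0.1).max() == pytest.approx(1.0)

    def test_matches_nilearn_canonical(self):
        """Cross-check the double-gamma against nilearn's SPM-style kernel."""
        nilearn_hrf = pytest.importorskip(
            "nilearn.glm.first_level.hemodynamic_models"
        )
        ours = canonical_hrf(0.5, length=32.0)
        theirs = nilearn_hrf.spm_hrf(0.5, oversampling=1)
        theirs = theirs / theirs.max()
        n = min(len(ours), len(theirs))
        # small discretization offset between the two samplers is expected
        assert np.corrcoef(ours[:n], theirs[:n])[0, 1] > 0.98
        t = np.arange(n) * 0.5
        assert abs(t[np.argmax(ours[:n])] - t[np.argmax(theirs[:n])]) <= 1.0

    def test_bad_args(self):
        with pytest.raises(ValidationError):
            canonical_hrf(-1.0)
        with pytest.raises(ValidationError):
            canonical_hrf(2.0, length=1.0)


def _events(n, tr=2.0, run=0, start=8.0, gap=12.0, **cols):
    onsets = start + gap * np.arange(n)
    df = pd.DataFrame({"onset": onsets, "duration": 3.0, "run": run})
    for k, v in cols.items():
        df[k] = v if not np.isscalar(v) else [v] * n
    return df


class TestBuildDesign:
    def test_condition_mode_emotion_layout(self, tiny_subject):
        ev = tiny_subject.events["encoding"]
        scans = tiny_subject.events["n_scans"]["encoding"]
        d = build_design(ev, scans, 2.0, mode="condition", condition_cols=("emotion",))
        kinds = np.asarray(d.kinds)
        # 3 runs x 2 emotions task columns + 3 constants
        assert (kinds == "task").sum() == 6
        assert (kinds == "run_constant").sum() == 3
        assert (kinds == "drift").sum() > 0

    def test_trialwise_counts_default_cohort(self, tiny_subject):
        from memtrace.pipeline import _combined_scans, combined_events

        ev = combined_events(tiny_subject)
        d = build_design(ev, _combined_scans(tiny_subject), 2.0, mode="trialwise")
        kinds = np.asarray(d.kinds)
        assert (kinds == "task").sum() == 3 * 60 + 120
        assert (kinds == "run_constant").sum() == 6

    def test_zero_events_drifts_and_constants_only(self):
        d = build_design(
            pd.DataFrame(columns=["onset", "duration", "run"]), 100, 2.0
        )
        assert (np.asarray(d.kinds) == "task").sum() == 0
        assert d.matrix.shape[0] == 100

    def test_event_beyond_window_rejected(self):
        ev = _events(3, start=180.0, emotion="neutral")
        with pytest.raises(DesignError):
            build_design(ev, 50, 2.0, condition_cols=("emotion",))

    def test_duplicate_trial_rank_error_names_columns(self):
        ev = pd.concat([_events(4, item_id=[f"i{k}" for k in range(4)])] * 2)
        ev = ev.reset_index(drop=True)
        with pytest.raises(DesignError) as err:
            build_design(ev, 60, 2.0, mode="trialwise")
        assert err.value.columns  # collinear columns are named

    def test_drift_periods_exceed_cutoff(self):
        n, tr, cutoff = 200, 2.0, 128.0
        basis = dct_drift_basis(n, tr, cutoff)
        # k-th column has period 2 * n * tr / k > cutoff
        assert basis.shape[1] == int(np.floor(2 * n * tr / cutoff))


class TestFitGlm:
    def test_noiseless_recovery_exact(self, rng):
        ev = _events(6, item_id=[f"i{k}" for k in range(6)])
        d = build_design(ev, 60, 2.0, mode="trialwise")
        beta_true = rng.normal(size=(d.n_columns, 30))
        Y = d.matrix @ beta_true
        fit = fit_glm(Y, d, ar1="off")
        assert np.allclose(fit.beta, beta_true, atol=1e-8)
        assert np.all(fit.sigma2 < 1e-10)

    def test_ols_matches_normal_equations(self, rng):
        """ar1 = off equals the closed-form (X'X)^-1 X'y oracle."""
        X = rng.normal(size=(50, 5))
        Y = rng.normal(size=(50, 40))
        ev = pd.DataFrame(columns=["onset", "duration", "run"])
        d = build_design(ev, 50, 2.0, hp_cutoff=None)
        d.matrix = X
        d.column_info = pd.DataFrame(
            {"name": [f"c{i}" for i in range(5)], "kind": ["task"] * 5, "run": 0}
        )
        fit = fit_glm(Y, d, ar1="off")
        oracle = np.linalg.inv(X.T @ X) @ X.T @ Y
        assert np.max(np.abs(fit.beta - oracle)) / np.max(np.abs(oracle)) < 1e-10

    def test_fixed_rho_out_of_range(self, rng):
        ev = _events(3, emotion="neutral")
        d = build_design(ev, 40, 2.0, condition_cols=("emotion",))
        with pytest.raises(ValidationError):
            fit_glm(rng.normal(size=(40, 4)), d, ar1=1.5)

    def test_whitening_with_true_rho_calibrates_t(self, rng):
        """Null t-statistics have ~unit variance when the generating AR(1)
        coefficient is used for whitening, and are inflated when ignored."""
        from scipy.signal import lfilter

        rho = 0.5
        n, v = 120, 1500
        ev = _events(5, emotion="neutral", gap=20.0)
        d = build_design(ev, n, 2.0, condition_cols=("emotion",), hp_cutoff=None)
        w = rng.normal(size=(n, v)) * np.sqrt(1 - rho**2)
        noise = lfilter([1.0], [1.0, -rho], w, axis=0)
        wvec = np.zeros(d.n_columns)
        wvec[0] = 1.0
        fit_w = fit_glm(noise, d, ar1=rho)
        _, t_w = contrast(fit_w, wvec)
        fit_o = fit_glm(noise, d, ar1="off")
        _, t_o = contrast(fit_o, wvec)
        assert abs(np.var(t_w) - 1.0) < 0.2
        assert np.var(t_o) > np.var(t_w) + 0.1

    def test_global_rho_estimate_close_to_truth(self, rng):
        from scipy.signal import lfilter

        rho = 0.4
        n = 200
        ev = pd.DataFrame(columns=["onset", "duration", "run"])
        d = build_design(ev, n, 2.0)
        w = rng.normal(size=(n, 800)) * np.sqrt(1 - rho**2)
        noise = lfilter([1.0], [1.0, -rho], w, axis=0)
        fit = fit_glm(noise, d, ar1="global")
        assert abs(fit.rho - rho) < 0.08

    def test_null_t_follows_student_distribution(self, rng):
        """White-noise data: per-voxel t for a unit contrast follows
        Student-t with the model's residual df (KS check)."""
        n, v = 60, 2000
        ev = _events(4, emotion="neutral", gap=14.0)
        d = build_design(ev, n, 2.0, condition_cols=("emotion",), hp_cutoff=None)
        fit = fit_glm(rng.normal(size=(n, v)), d, ar1="off")
        w = np.zeros(d.n_columns)
        w[0] = 1.0
        _, t = contrast(fit, w)
        ks = stats.kstest(t, "t", args=(fit.dof,))
        assert ks.pvalue > 0.01

    def test_drift_regression_removes_slow_power(self, rng):
        """Planted sub-cutoff cosine drift: residual power below 1/128 Hz
        drops by >= 95% after the drift block is included."""
        n, tr = 256, 2.0
        ev = _events(5, emotion="neutral", gap=30.0)
        d = build_design(ev, n, tr, condition_cols=("emotion",), hp_cutoff=128.0)
        i = np.arange(n)
        drift = 3.0 * np.cos(np.pi * 1 * (2 * i + 1) / (2 * n)) + 2.0 * np.cos(
            np.pi * 2 * (2 * i + 1) / (2 * n)
        )
        Y = (drift[:, None] + rng.normal(size=(n, 50))).astype(float)
        fit = fit_glm(Y, d, ar1="off")
        resid = Y - d.matrix @ fit.beta
        freqs = np.fft.rfftfreq(n, d=tr)
        slow = freqs < 1.0 / 128.0

        def slow_power(M):
            F = np.fft.rfft(M, axis=0)
            return np.sum(np.abs(F[slow]) ** 2)

        assert slow_power(resid) < 0.05 * slow_power(Y)


@pytest.fixture(scope="module")
def toy_fit():
    rng = np.random.default_rng(0)
    ev = _events(6, item_id=[f"i{k}" for k in range(6)], phase="encoding")
    d = build_design(ev, 60, 2.0, mode="trialwise")
    mask = np.ones((4, 4, 4), bool)
    beta = rng.normal(size=(d.n_columns, 64))
    data = (d.matrix @ beta + 0.5 * rng.normal(size=(60, 64))).T.reshape(4, 4, 4, 60)
    vol = Volume4D(data, 2.0, mask)
    return fit_glm(vol, d, ar1="off"), d


class TestContrastAndPatterns:

    def test_zero_weights_rejected(self, toy_fit):
        fit, d = toy_fit
        with pytest.raises(ValidationError):
            contrast(fit, np.zeros(d.n_columns))

    def test_sign_flip_negates_maps(self, toy_fit):
        fit, d = toy_fit
        w = np.zeros(d.n_columns)
        w[0] = 1.0
        eff, t = contrast(fit, w)
        eff2, t2 = contrast(fit, -w)
        np.testing.assert_allclose(eff.data, -eff2.data)
        np.testing.assert_allclose(t.data, -t2.data)

    def test_drift_weight_warns(self, toy_fit):
        fit, d = toy_fit
        w = np.zeros(d.n_columns)
        w[-1] = 1.0  # run constant
        with pytest.warns(UserWarning):
            contrast(fit, w)

    def test_trial_pattern_t_matches_hand_formula(self, toy_fit):
        fit, d = toy_fit
        pats = trial_patterns(fit)
        j = 2
        se = np.sqrt(fit.sigma2 * fit.xtx_inv[j, j])
        np.testing.assert_allclose(pats.values[2], fit.beta[j] / se)

    def test_single_regressor_scalar_oracle(self, rng):
        """One-column GLM: t equals the scalar regression formula."""
        x = rng.normal(size=30)
        y = 2.0 * x + rng.normal(size=30)
        ev = pd.DataFrame(columns=["onset", "duration", "run"])
        d = build_design(ev, 30, 2.0, hp_cutoff=None)
        d.matrix = x[:, None]
        d.column_info = pd.DataFrame(
            {"name": ["x"], "kind": ["task"], "run": [0], "item_id": ["i0"]}
        )
        fit = fit_glm(y[:, None], d, ar1="off")
        b = float(x @ y / (x @ x))
        rss = float(np.sum((y - b * x) ** 2))
        t_hand = b / np.sqrt((rss / 29) / (x @ x))
        _, t = contrast(fit, [1.0])
        assert t[0] == pytest.approx(t_hand)


class TestSmooth:
    def test_zero_fwhm_identity(self, rng):
        a = rng.normal(size=(8, 8, 8))
        np.testing.assert_array_equal(smooth(a, 0.0, 3.0), a)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValidationError):
            smooth(np.zeros((4, 4, 4)), -1.0, 3.0)

    def test_delta_kernel_measured_fwhm(self):
        grid = np.zeros((41, 41, 41))
        grid[20, 20, 20] = 1.0
        fwhm_mm, vox = 9.0, 3.0
        out = smooth(grid, fwhm_mm, vox)
        profile = out[:, 20, 20]
        half = profile.max() / 2
        above = np.flatnonzero(profile >= half)
        # linear interpolation at the half-maximum crossings
        lo, hi = above[0], above[-1]
        f = lambda i, j: i + (half - profile[i]) / (profile[j] - profile[i]) * (j - i)
        width_vox = f(hi, hi + 1) - f(lo, lo - 1)
        assert abs(width_vox * vox - fwhm_mm) / fwhm_mm < 0.05

    def test_sum_preserved_interior(self, rng):
        a = np.zeros((24, 24, 24))
        a[8:16, 8:16, 8:16] = rng.normal(size=(8, 8, 8))
        out = smooth(a, 6.0, 3.0)
        assert out.sum() == pytest.approx(a.sum(), rel=1e-6)

    def test_shift_equivariance_interior(self):
        a = np.zeros((30, 30, 30))
        a[10, 12, 14] = 1.0
        b = np.roll(a, shift=2, axis=0)
        np.testing.assert_allclose(
            np.roll(smooth(a, 6.0, 3.0), 2, axis=0)[6:24, 6:24, 6:24],
            smooth(b, 6.0, 3.0)[6:24, 6:24, 6:24],
            atol=1e-12,
        )

    def test_masked_edges_not_darkened(self):
        mask = np.zeros((12, 12, 12), bool)
        mask[2:10, 2:10, 2:10] = True
        a = np.where(mask, 1.0, 0.0)
        out = smooth(a, 8.0, 3.0, mask=mask)
        assert np.allclose(out[mask], 1.0, atol=1e-6)
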