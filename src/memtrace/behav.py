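"""Signal-detection memory metrics and the behavioral statistics toolkit.

Recognition accuracy is summarized by the sensitivity index

    d' = z(H) - z(FA),        c = -(z(H) + z(FA)) / 2,

with an extreme-rate correction so the quantiles stay finite. Group effects
use Welch's t (unequal variances), Tukey-fence outlier handling, Pearson
correlation tests, and a 2x2 between-subjects factorial ANOVA whose quantity
of interest is the drug x delay interaction contrast
(PLAC: 1d - 28d) - (YOH: 1d - 28d).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateDataError, ValidationError

__all__ = [
    "RecognitionCounts",
    "SdtResult",
    "counts_from_responses",
    "d_prime",
    "weighted_d_prime",
    "welch_t",
    "tukey_outliers",
    "pearson_cor_test",
    "factorial_interaction",
]

#: response levels of the four-point confidence scale, in increasing
#: "oldness" order
RESPONSE_LEVELS = ("definitely_new", "rather_new", "rather_old", "definitely_old")
OLD_RESPONSES = ("rather_old", "definitely_old")

#: default confidence weights: definite responses count fully, hesitant ones
#: at half weight (the weighting scheme is configurable; no canonical choice
#: exists for this transform)
DEFAULT_CONFIDENCE_WEIGHTS = {"definitely": 1.0, "rather": 0.5}


@dataclass
class RecognitionCounts:
    """Hit/miss/false-alarm/correct-rejection counts for one subject."""

    n_old: int
    n_new: int
    hits: float
    false_alarms: float

    def __post_init__(self):
        if self.n_old <= 0 or self.n_new <= 0:
            raise ValidationError("n_old and n_new must be positive")
        if not (0 <= self.hits <= self.n_old):
            raise ValidationError("hits must lie in [0, n_old]")
        if not (0 <= self.false_alarms <= self.n_new):
            raise ValidationError("false_alarms must lie in [0, n_new]")

    @property
    def misses(self) -> float:
        return self.n_old - self.hits

    @property
    def correct_rejections(self) -> float:
        return self.n_new - self.false_alarms


@dataclass
class SdtResult:
    hit_rate: float
    fa_rate: float
    d_prime: float
    criterion: float
    correction_applied: bool


def counts_from_responses(responses: pd.DataFrame) -> RecognitionCounts:
    """Tally one subject's trial table (columns: oldness, response)."""
    old = responses[responses["oldness"] == "old"]
    new = responses[responses["oldness"] == "new"]
    hits = int(old["response"].isin(OLD_RESPONSES).sum())
    fas = int(new["response"].isin(OLD_RESPONSES).sum())
    return RecognitionCounts(len(old), len(new), hits, fas)


def _corrected_rates(counts: RecognitionCounts, correction: str):
    h_raw = counts.hits / counts.n_old
    f_raw = counts.false_alarms / counts.n_new
    if correction == "none":
        if h_raw in (0.0, 1.0) or f_raw in (0.0, 1.0):
            raise DegenerateDataError(
                "extreme hit/false-alarm rate with correction='none' gives "
                "a non-finite d'"
            )
        return h_raw, f_raw, False
    if correction == "loglinear":
        h = (counts.hits + 0.5) / (counts.n_old + 1.0)
        f = (counts.false_alarms + 0.5) / (counts.n_new + 1.0)
        return h, f, True
    if correction == "clamp":
        h = min(max(h_raw, 0.5 / counts.n_old), 1.0 - 0.5 / counts.n_old)
        f = min(max(f_raw, 0.5 / counts.n_new), 1.0 - 0.5 / counts.n_new)
        return h, f, (h != h_raw) or (f != f_raw)
    raise ValidationError(f"unknown correction {correction!r}")


def d_prime(counts: RecognitionCounts, correction: str = "loglinear") -> SdtResult:
    """Sensitivity index d' and criterion c from recognition counts.

    The log-linear correction adds 0.5 to the hit/false-alarm counts and 1 to
    the item counts before forming rates; "clamp" replaces 0 and 1 rates by
    1/(2N) and 1 - 1/(2N); "none" raises on extreme rates.
    """
    h, f, corrected = _corrected_rates(counts, correction)
    zh, zf = stats.norm.ppf(h), stats.norm.ppf(f)
    return SdtResult(
        hit_rate=float(h),
        fa_rate=float(f),
        d_prime=float(zh - zf),
        criterion=float(-0.5 * (zh + zf)),
        correction_applied=bool(corrected),
    )


def weighted_d_prime(
    responses: pd.DataFrame,
    weights: dict | None = None,
    correction: str = "loglinear",
) -> SdtResult:
    """Confidence-weighted d': 'old' responses contribute their confidence
    weight to the hit / false-alarm tallies before the usual d' computation.
    """
    weights = DEFAULT_CONFIDENCE_WEIGHTS if weights is None else weights
    for level in ("definitely", "rather"):
        if level not in weights:
            raise ValidationError(f"missing confidence weight for {level!r}")

    def w_old(resp: pd.Series) -> float:
        w = np.zeros(len(resp))
        w[resp.to_numpy() == "definitely_old"] = weights["definitely"]
        w[resp.to_numpy() == "rather_old"] = weights["rather"]
        return float(w.sum())

    old = responses[responses["oldness"] == "old"]
    new = responses[responses["oldness"] == "new"]
    counts = RecognitionCounts(len(old), len(new), w_old(old["response"]), w_old(new["response"]))
    return d_prime(counts, correction=correction)


def welch_t(a, b) -> dict:
    """Welch's two-sample t-test with Satterthwaite df and Cohen's d.

    Cohen's d uses the pooled SD. When both samples are constant with equal
    means the contract is t = 0; constant samples with different means are a
    degenerate error.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("each sample needs at least 2 observations")
    if not (np.isfinite(a).all() and np.isfinite(b).all()):
        raise ValidationError("samples must be finite")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = a.size, b.size
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return {"t": 0.0, "df": float(na + nb - 2), "p": 1.0, "cohen_d": 0.0}
        raise DegenerateDataError(
            "both samples constant with different means: t undefined"
        )
    res = stats.ttest_ind(a, b, equal_var=False)
    se2a, se2b = va / na, vb / nb
    df = (se2a + se2b) ** 2 / (se2a**2 / (na - 1) + se2b**2 / (nb - 1))
    sp = np.sqrt(((na - 1) * va + (nb - 1) * vb) / (na + nb - 2))
    d = (a.mean() - b.mean()) / sp if sp > 0 else 0.0
    return {
        "t": float(res.statistic),
        "df": float(df),
        "p": float(res.pvalue),
        "cohen_d": float(d),
    }


def tukey_outliers(x) -> np.ndarray:
    """Boolean mask of values outside [Q1 - 1.5 IQR, Q3 + 1.5 IQR]."""
    x = np.asarray(x, dtype=float)
    if x.size < 4:
        raise ValidationError("Tukey fences need at least 4 observations")
    q1, q3 = np.percentile(x, [25, 75])
    iqr = q3 - q1
    lo, hi = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    return (x < lo) | (x > hi)


def pearson_cor_test(x, y) -> dict:
    """Pearson correlation with t-test (df = n - 2), plus the same test after
    removing Tukey outliers flagged on either variable."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValidationError("need paired samples with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValidationError("samples must be finite")
    if x.std() == 0 or y.std() == 0:
        raise DegenerateDataError("zero variance: correlation undefined")

    def _test(xs, ys):
        r, p = stats.pearsonr(xs, ys)
        n = xs.size
        denom = max(1.0 - r**2, 1e-15)
        t = r * np.sqrt((n - 2) / denom)
        return {"r": float(r), "t": float(t), "df": int(n - 2), "p": float(p), "n": int(n)}

    full = _test(x, y)
    if x.size >= 4:
        out = tukey_outliers(x) | tukey_outliers(y)
        keep = ~out
        if keep.sum() >= 3 and x[keep].std() > 0 and y[keep].std() > 0:
            full["without_outliers"] = _test(x[keep], y[keep])
            full["n_outliers_removed"] = int(out.sum())
    return full


def _cell_arrays(d_table: pd.DataFrame, value_col: str):
    cells = {}
    for (drug, delay), grp in d_table.groupby(["drug", "delay"]):
        cells[(drug, delay)] = grp[value_col].to_numpy(dtype=float)
    for drug in ("PLAC", "YOH"):
        for delay in ("1d", "28d"):
            if (drug, delay) not in cells or cells[(drug, delay)].size < 2:
                raise ValidationError(
                    f"cell ({drug}, {delay}) missing or has < 2 subjects"
                )
    return cells


def factorial_interaction(d_table: pd.DataFrame, value_col: str = "value") -> dict:
    """2x2 between-subjects ANOVA interaction on subject-level values.

    Fits the effect-coded regression value ~ drug + delay + drug:delay by
    least squares (type-III style full-vs-reduced sums of squares, valid for
    unbalanced cells) and reports the interaction contrast
    (PLAC: 1d - 28d) - (YOH: 1d - 28d), F, p, and partial eta^2.
    """
    cells = _cell_arrays(d_table, value_col)
    y = d_table[value_col].to_numpy(dtype=float)
    drug = np.where(d_table["drug"].to_numpy() == "PLAC", 1.0, -1.0)
    delay = np.where(d_table["delay"].to_numpy() == "1d", 1.0, -1.0)
    X_full = np.column_stack([np.ones_like(y), drug, delay, drug * delay])
    X_red = X_full[:, :3]

    def _rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    rss_full = _rss(X_full)
    rss_red = _rss(X_red)
    n = y.size
    df_err = n - 4
    ss_int = max(rss_red - rss_full, 0.0)
    ms_err = rss_full / df_err
    m = {k: v.mean() for k, v in cells.items()}
    contrast_val = (m[("PLAC", "1d")] - m[("PLAC", "28d")]) - (
        m[("YOH", "1d")] - m[("YOH", "28d")]
    )
    if ms_err <= 0:
        # noiseless cells: the interaction is exact; p -> 0 when nonzero
        return {
            "interaction": float(contrast_val),
            "F": np.inf if ss_int > 0 else 0.0,
            "p": 0.0 if ss_int > 0 else 1.0,
            "partial_eta_sq": 1.0 if ss_int > 0 else 0.0,
            "df": (1, df_err),
        }
    F = ss_int / ms_err
    p = float(stats.f.sf(F, 1, df_err))
    return {
        "interaction": float(contrast_val),
        "F": float(F),
        "p": p,
        "partial_eta_sq": float(ss_int / (ss_int + rss_full)),
        "df": (1, df_err),
    }
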