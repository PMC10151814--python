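"""Statistical layer: paired tests, correlation pooling, ICC, agreement.

The comparisons mirror common practice for evaluating automated cardiac
function quantification against an expert:

* per-parameter mean differences ± sd with two-sided paired t-tests
  (α = 0.05, no multiple-testing correction across the seven parameters);
* Pearson correlations per parameter, pooled across parameters on the
  variance-stabilised Fisher-z scale;
* ICC(3,1) — two-way mixed-effects, consistency, single rater — with the
  F-distribution 95% confidence interval;
* Bland-Altman bias and limits of agreement;
* equivalence testing: a reader is equivalent for a parameter when the 95%
  CI of its mean error lies entirely within a pre-defined tolerance interval
  (derived from intraobserver variability and supplied as configuration).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .clinical_params import PARAM_COLUMNS
from .errors import AlignmentError, ValidationError


@dataclass(frozen=True)
class PairedTResult:
    t_stat: float
    p_value: float
    mean_diff: float
    sd_diff: float
    n: int
    degenerate: bool = False  # zero-variance nonzero-mean differences


def paired_t_test(x, y) -> PairedTResult:
    """Two-sided paired t-test on d = x − y with n−1 degrees of freedom."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("paired_t_test requires two equal-length 1D vectors")
    n = x.size
    if n < 2:
        raise ValidationError("paired_t_test requires n >= 2")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    if sd == 0.0:
        if mean == 0.0:
            return PairedTResult(0.0, 1.0, 0.0, 0.0, n)
        return PairedTResult(math.copysign(math.inf, mean), 0.0, mean, 0.0, n, True)
    t = mean / (sd / math.sqrt(n))
    p = 2.0 * float(sps.t.sf(abs(t), df=n - 1))
    return PairedTResult(t, p, mean, sd, n)


def fisher_z_mean(rs) -> float:
    """Pool Pearson correlations on the Fisher-z scale: tanh(mean(atanh(r)))."""
    rs = np.asarray(rs, dtype=float)
    if rs.size == 0:
        raise ValidationError("fisher_z_mean requires at least one correlation")
    if np.any(np.abs(rs) >= 1.0):
        raise ValidationError("correlations must lie strictly inside (-1, 1)")
    return float(np.tanh(np.mean(np.arctanh(rs))))


@dataclass(frozen=True)
class ICCResult:
    icc: float
    ci_low: float
    ci_high: float
    n_subjects: int
    k_raters: int

    @property
    def defined(self) -> bool:
        return not math.isnan(self.icc)


def icc_3_1(ratings, confidence: float = 0.95) -> ICCResult:
    """ICC(3,1): two-way mixed-effects, consistency, single rater.

    ``ratings`` is an (n_subjects, k_raters) complete grid. The estimate is
    (MS_R − MS_E)/(MS_R + (k−1)·MS_E) from the two-way ANOVA decomposition;
    the CI uses the F-distribution method for consistency ICCs. Zero
    between-subject variance yields NaN fields (an undefined marker).
    """
    m = np.asarray(ratings, dtype=float)
    if m.ndim != 2:
        raise ValidationError("ratings must be a 2D subjects × raters grid")
    n, k = m.shape
    if n < 2 or k < 2:
        raise ValidationError("ICC requires >= 2 subjects and >= 2 raters")
    if not np.all(np.isfinite(m)):
        raise ValidationError("ratings grid must be complete and finite")

    grand = m.mean()
    ss_rows = k * float(((m.mean(axis=1) - grand) ** 2).sum())
    ss_cols = n * float(((m.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((m - grand) ** 2).sum())
    ss_err = ss_total - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_e = max(ss_err / ((n - 1) * (k - 1)), 0.0)
    # numerical guard: per-rater additive shifts leave a residual of pure
    # rounding noise, which must read as zero error variance (ICC = 1)
    if ms_e < 1e-12 * ms_r:
        ms_e = 0.0

    if ms_r == 0.0 and ms_e == 0.0:
        return ICCResult(math.nan, math.nan, math.nan, n, k)
    icc = (ms_r - ms_e) / (ms_r + (k - 1) * ms_e)

    if ms_e == 0.0:
        return ICCResult(icc, icc, icc, n, k)
    alpha = 1.0 - confidence
    df1, df2 = n - 1, (n - 1) * (k - 1)
    f_obs = ms_r / ms_e
    fl = f_obs / sps.f.ppf(1 - alpha / 2, df1, df2)
    fu = f_obs * sps.f.ppf(1 - alpha / 2, df2, df1)
    ci_low = (fl - 1) / (fl + k - 1)
    ci_high = (fu - 1) / (fu + k - 1)
    return ICCResult(float(icc), float(ci_low), float(ci_high), n, k)


@dataclass(frozen=True)
class EquivalenceResult:
    parameter: str
    mean_diff: float
    ci_low: float
    ci_high: float
    tol_low: float
    tol_high: float
    equivalent: bool


def equivalence_test(
    diffs, tolerance: tuple[float, float], parameter: str = ""
) -> EquivalenceResult:
    """CI-within-tolerance equivalence test on per-case differences.

    The 95% CI of the mean difference is mean ± t₀.₉₇₅,ₙ₋₁·sd/√n; the reader
    is equivalent when the CI lies entirely within the tolerance interval,
    inclusive at the boundaries.
    """
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("equivalence_test requires n >= 2 differences")
    tol_low, tol_high = float(tolerance[0]), float(tolerance[1])
    if not tol_low < tol_high:
        raise ValidationError("tolerance interval must satisfy low < high")
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    half = float(sps.t.ppf(0.975, df=d.size - 1)) * sd / math.sqrt(d.size)
    ci_low, ci_high = mean - half, mean + half
    equivalent = (tol_low <= ci_low) and (ci_high <= tol_high)
    return EquivalenceResult(parameter, mean, ci_low, ci_high, tol_low, tol_high, equivalent)


def bland_altman(diffs) -> tuple[float, float, float]:
    """Bland-Altman bias and 95% limits of agreement: bias ± 1.96·sd."""
    d = np.asarray(diffs, dtype=float)
    if d.size < 2:
        raise ValidationError("bland_altman requires n >= 2 differences")
    bias = float(d.mean())
    sd = float(d.std(ddof=1))
    return bias, bias - 1.96 * sd, bias + 1.96 * sd


def pearson_r(x, y) -> float:
    """Pearson correlation; NaN marker when either vector is constant."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) or np.all(y == y[0]):
        return math.nan
    if np.array_equal(x, y):
        return 1.0
    return float(sps.pearsonr(x, y).statistic)


def compare_clinical(
    expert_params: pd.DataFrame, reader_params: pd.DataFrame
) -> pd.DataFrame:
    """Per-parameter comparison table (reader − expert) over matched cases.

    Input frames are indexed by case_id with the seven parameter columns.
    Output rows (one per parameter): n_cases, mean_diff, sd_diff, t_stat,
    p_value, pearson_r.
    """
    if set(expert_params.index) != set(reader_params.index):
        missing = set(expert_params.index) ^ set(reader_params.index)
        raise AlignmentError(f"case IDs do not match between readers: {sorted(missing)}")
    reader_params = reader_params.loc[expert_params.index]
    rows = []
    for param in PARAM_COLUMNS:
        e = expert_params[param].to_numpy(dtype=float)
        r = reader_params[param].to_numpy(dtype=float)
        test = paired_t_test(r, e)
        rows.append(
            {
                "parameter": param,
                "n_cases": test.n,
                "mean_diff": test.mean_diff,
                "sd_diff": test.sd_diff,
                "t_stat": test.t_stat,
                "p_value": test.p_value,
                "pearson_r": pearson_r(e, r),
            }
        )
    return pd.DataFrame(rows).set_index("parameter")
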