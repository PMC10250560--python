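"""Agreement and clinical-association statistics.

The battery used to validate a video-derived metric set against a reference
(sensor) set and against clinical scores:

* Spearman rank correlation with qualitative cut-offs
  (< 0.35 weak, 0.35-0.67 moderate, > 0.67 strong);
* ICC(2,1) — two-way random effects, absolute agreement, single measures —
  with cut-offs (< 0.50 poor, 0.50-0.75 moderate, 0.75-0.90 good,
  > 0.90 excellent);
* a normality check (skewness, excess kurtosis, Shapiro-Wilk at 0.05);
* the fractional-rank inverse-normal (Blom) transform applied to outcomes
  that fail the normality check;
* partial correlation controlling age, sex and BMI by the two-regression
  residual method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

SPEARMAN_CUTOFFS = ((0.35, "weak"), (0.67, "moderate"), (np.inf, "strong"))
ICC_CUTOFFS = ((0.50, "poor"), (0.75, "moderate"), (0.90, "good"), (np.inf, "excellent"))
MAPE_CUTOFFS = ((5.0, "high"), (25.0, "moderate"), (np.inf, "unacceptable"))

ALPHA = 0.05


def _label(value: float, cutoffs) -> str:
    for upper, name in cutoffs:
        if value < upper:
            return name
    return cutoffs[-1][1]


@dataclass(frozen=True)
class AssociationResult:
    statistic: float
    p_value: float
    kind: str  # spearman | icc | partial
    n: int
    label: str

    def __post_init__(self):
        if not -1.0 - 1e-12 <= self.statistic <= 1.0 + 1e-12:
            raise ValueError("association statistic must lie in [-1, 1]")
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value must lie in [0, 1]")

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def _validate_pair(a, b, min_n=3):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("paired measurements must be equal-length 1-D arrays")
    if len(a) < min_n:
        raise ValueError(f"need at least {min_n} pairs")
    if not (np.all(np.isfinite(a)) and np.all(np.isfinite(b))):
        raise ValueError("paired measurements must be finite")
    return a, b


def spearman(method_a, method_b) -> AssociationResult:
    """Spearman rank correlation (mid-ranks for ties, t-approximation p).

    Labelled weak / moderate / strong at the 0.35 and 0.67 cut-offs.
    """
    a, b = _validate_pair(method_a, method_b)
    if np.ptp(sps.rankdata(a)) == 0 or np.ptp(sps.rankdata(b)) == 0:
        raise ValueError("spearman undefined: a ranking has zero variance")
    rho, p = sps.spearmanr(a, b)
    return AssociationResult(float(rho), float(p), "spearman", len(a),
                             _label(abs(rho), SPEARMAN_CUTOFFS))


def icc(method_a, method_b) -> AssociationResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measures.

    Computed from the two-way ANOVA mean squares of the subjects x methods
    table with k = 2 raters:

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + k (MSC - MSE) / n)

    The p-value is the F test of MSR/MSE with (n-1, (n-1)(k-1)) df. Labelled
    poor / moderate / good / excellent at 0.50 / 0.75 / 0.90.
    """
    a, b = _validate_pair(method_a, method_b)
    data = np.column_stack([a, b])
    n, k = data.shape
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    if np.allclose(row_means, row_means[0]):
        raise ValueError("ICC undefined: zero between-subject variance")
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_total = np.sum((data - grand) ** 2)
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    value = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if mse <= 0:
        p = 0.0  # perfect agreement up to row effects
    else:
        f = msr / mse
        p = float(sps.f.sf(f, n - 1, (n - 1) * (k - 1)))
    value = float(np.clip(value, -1.0, 1.0))
    return AssociationResult(value, p, "icc", n, _label(value, ICC_CUTOFFS))


def normality_check(values, alpha: float = ALPHA) -> tuple[float, float, bool]:
    """Adjusted Fisher-Pearson skewness, excess kurtosis, and a normality flag.

    The flag is the Shapiro-Wilk test at the given alpha: True means the
    sample is consistent with a normal distribution.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 8:
        raise ValueError("normality check needs at least 8 values")
    if np.ptp(v) == 0:
        raise ValueError("normality check undefined for constant input")
    skew = float(sps.skew(v, bias=False))
    kurt = float(sps.kurtosis(v, bias=False))
    _, p = sps.shapiro(v)
    return skew, kurt, bool(p >= alpha)


def rank_inverse_normal(values, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Blom fractional-rank inverse-normal transform.

    Mid-ranks r (ties averaged) are mapped to quantiles
    (r - 3/8) / (n + 1/4) and then through the standard normal quantile
    function. The transform is monotone, so orderings are preserved.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 3:
        raise ValueError("rank-inverse-normal transform needs at least 3 values")
    ranks = sps.rankdata(v)
    quantiles = (ranks - offset) / (len(v) + 1.0 - 2.0 * offset)
    return sps.norm.ppf(quantiles)


def partial_correlation(
    x, y, covariates=None, transform_nonnormal_y: bool = True
) -> AssociationResult:
    """Partial correlation of x and y controlling for covariates.

    Both variables are regressed (least squares, with intercept) on the
    covariates and the Pearson correlation of the residuals is returned,
    with a two-sided p from the t distribution at n - 2 - k degrees of
    freedom. When ``transform_nonnormal_y`` and y fails the normality
    check, y is first passed through the rank-inverse-normal transform
    (the usual handling of skewed outcomes like TUG). An empty covariate
    set reduces exactly to Pearson.
    """
    x, y = _validate_pair(x, y, min_n=4)
    n = len(x)
    if covariates is None:
        covariates = np.empty((n, 0))
    cov = np.asarray(covariates, dtype=float)
    if cov.ndim == 1:
        cov = cov[:, None]
    if cov.shape[0] != n:
        raise ValueError("covariates must have one row per observation")
    k = cov.shape[1]
    if n <= k + 2:
        raise ValueError("need n > k + 2 observations")
    if transform_nonnormal_y and n >= 8:
        _, _, is_normal = normality_check(y)
        if not is_normal:
            y = rank_inverse_normal(y)
    design = np.column_stack([np.ones(n), cov])
    if np.linalg.matrix_rank(design) < design.shape[1]:
        raise ValueError("covariate matrix is rank-deficient")
    beta_x, *_ = np.linalg.lstsq(design, x, rcond=None)
    beta_y, *_ = np.linalg.lstsq(design, y, rcond=None)
    rx = x - design @ beta_x
    ry = y - design @ beta_y
    denom = np.sqrt(np.sum(rx**2) * np.sum(ry**2))
    if denom == 0:
        raise ValueError("partial correlation undefined: zero residual variance")
    r = float(np.clip(np.sum(rx * ry) / denom, -1.0, 1.0))
    df = n - 2 - k
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * np.sqrt(df / (1.0 - r**2))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return AssociationResult(r, p, "partial", n, _label(abs(r), SPEARMAN_CUTOFFS))
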