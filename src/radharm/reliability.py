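"""Between-profile reliability: two-way absolute-agreement single-measure ICC.

Each feature yields an n-subjects x k-raters matrix, where a "rater" is a
calculation-settings profile (standing in for a software platform or
version).  The intraclass correlation is the two-way, absolute-agreement,
single-measure form (ICC(A,1) in McGraw & Wong's nomenclature; the mixed-
and random-effects variants share this point estimate):

    ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR/MSC/MSE the row (subject), column (rater) and residual mean squares
of the two-way ANOVA.  The 95% confidence interval uses the F-based method
with Satterthwaite degrees of freedom.  Negative estimates and CI bounds are
truncated at zero and the upper bound capped at one.

Reliability categories follow the conventional thresholds: poor (< 0.5),
moderate (0.5-0.75), good (0.75-0.9), excellent (> 0.9), applied to the CI
lower bound (conservative); a category from the point estimate and a
straddle flag are reported alongside, since a CI can span several bands.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RatingsMatrix",
    "ICCResult",
    "icc_absolute_agreement",
    "classify_reliability",
    "reliability_study",
    "anova_mean_squares",
]

CATEGORIES = ("poor", "moderate", "good", "excellent")


@dataclass
class RatingsMatrix:
    """n subjects x k raters of one feature's values, complete cases only."""

    values: np.ndarray
    feature_name: str = ""
    n_dropped: int = 0  # subjects removed listwise for missing cells

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ratings must be a 2D (subjects x raters) array")
        keep = ~np.isnan(v).any(axis=1)
        self.n_dropped += int((~keep).sum())
        v = v[keep]
        if v.shape[0] < 2 or v.shape[1] < 2:
            raise ValueError("need at least 2 subjects and 2 raters after listwise deletion")
        self.values = v

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass
class ICCResult:
    estimate: float
    ci_low: float
    ci_high: float
    ms_rows: float
    ms_cols: float
    ms_error: float
    n: int
    k: int
    category: str = ""
    category_estimate: str = ""
    straddles: bool = False
    constant: bool = False  # all cells equal; ICC defined as 1 by convention
    feature_name: str = ""


def anova_mean_squares(values: np.ndarray) -> tuple[float, float, float]:
    """Two-way (subject x rater, one observation per cell) mean squares."""
    v = np.asarray(values, dtype=float)
    n, k = v.shape
    grand = v.mean()
    row_means = v.mean(axis=1)
    col_means = v.mean(axis=0)
    ss_rows = k * ((row_means - grand) ** 2).sum()
    ss_cols = n * ((col_means - grand) ** 2).sum()
    ss_total = ((v - grand) ** 2).sum()
    ss_err = ss_total - ss_rows - ss_cols
    return (
        ss_rows / (n - 1),
        ss_cols / (k - 1),
        ss_err / ((n - 1) * (k - 1)),
    )


def icc_absolute_agreement(r: RatingsMatrix, alpha: float = 0.05) -> ICCResult:
    """ICC(A,1) with a truncated 95% (or 1-alpha) confidence interval."""
    v = r.values
    n, k = r.n, r.k
    msr, msc, mse = anova_mean_squares(v)

    if np.ptp(v) == 0:
        res = ICCResult(1.0, 1.0, 1.0, msr, msc, mse, n, k,
                        constant=True, feature_name=r.feature_name)
        res.category, res.category_estimate = "excellent", "excellent"
        return res

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else 1.0

    # F-based CI (Satterthwaite df), as in the standard irr implementation
    if icc >= 1.0 or mse == 0 and msc == 0:
        low, high = 1.0, 1.0
    else:
        a = (k * icc) / (n * (1 - icc))
        b = 1 + (k * icc * (n - 1)) / (n * (1 - icc))
        num = (a * msc + b * mse) ** 2
        den = (a * msc) ** 2 / (k - 1) + (b * mse) ** 2 / ((n - 1) * (k - 1))
        vdf = num / den if den > 0 else (n - 1) * (k - 1)
        f_l = stats.f.ppf(1 - alpha / 2, n - 1, vdf)
        f_u = stats.f.ppf(1 - alpha / 2, vdf, n - 1)
        low = n * (msr - f_l * mse) / (f_l * (k * msc + (k * n - k - n) * mse) + n * msr)
        high = n * (f_u * msr - mse) / (k * msc + (k * n - k - n) * mse + n * f_u * msr)

    # truncation: negative estimate and bounds to 0, upper bound capped at 1
    est = float(np.clip(icc, 0.0, 1.0))
    low = float(np.clip(low, 0.0, 1.0))
    high = float(np.clip(high, 0.0, 1.0))
    low, high = min(low, est), max(high, est)

    res = ICCResult(est, low, high, msr, msc, mse, n, k, feature_name=r.feature_name)
    res.category = _category(low)
    res.category_estimate = _category(est)
    res.straddles = _category(low) != _category(high)
    return res


def _category(value: float) -> str:
    """Band thresholds 0.5 / 0.75 / 0.9; boundary values fall in the lower band."""
    if value <= 0.5:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.9:
        return "good"
    return "excellent"


def classify_reliability(res: ICCResult) -> str:
    """Category from the CI lower bound (conservative reading)."""
    return _category(res.ci_low)


def reliability_study(table: pd.DataFrame, raters: list[str],
                      features: list[str] | None = None) -> pd.DataFrame:
    """ICC per feature across the given profile 'raters'.

    ``table`` is a long-format feature table with columns ``subject_id``,
    ``profile`` and one column per canonical feature (the pipeline's
    :func:`radharm.pipeline.extract` output).  Returns one row per feature
    with the estimate, CI, mean squares and categories; features constant
    over all subjects and raters are flagged and carry NaN estimates.
    """
    if len(raters) < 2:
        raise ValueError("need at least two profiles to assess reliability")
    missing = set(raters) - set(table["profile"].unique())
    if missing:
        raise ValueError(f"profiles absent from the table: {sorted(missing)}")

    meta = {"subject_id", "profile"}
    if features is None:
        features = [c for c in table.columns if c not in meta]

    rows = []
    for feat in features:
        wide = (
            table[table["profile"].isin(raters)]
            .pivot(index="subject_id", columns="profile", values=feat)
            .loc[:, raters]
        )
        values = wide.to_numpy(dtype=float)
        complete = values[~np.isnan(values).any(axis=1)]
        if complete.size and np.ptp(complete) == 0:
            rows.append({"feature": feat, "estimate": np.nan, "ci_low": np.nan,
                         "ci_high": np.nan, "category": "constant",
                         "category_estimate": "constant", "straddles": False,
                         "n": complete.shape[0], "k": len(raters)})
            continue
        res = icc_absolute_agreement(RatingsMatrix(values, feature_name=feat))
        rows.append({"feature": feat, "estimate": res.estimate,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "category": res.category,
                     "category_estimate": res.category_estimate,
                     "straddles": res.straddles, "n": res.n, "k": res.k})
    return pd.DataFrame(rows)
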