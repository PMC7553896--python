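"""Univariable survival screen of standardised radiomic features.

Each feature column is standardised to mean 0, SD 1 (sample SD) and entered
alone into a Cox proportional-hazards model of overall survival (partial
likelihood, Efron tie handling).  The reported hazard ratio is therefore the
multiplicative change in hazard per one standard deviation of the feature,
comparable across features.  p values are Wald tests of beta = 0, binned at
the conventional 0.05 / 0.1 thresholds for the heat-map report.

Running the screen under two different settings profiles on the same
subjects exposes how calculation settings alter prognostic behaviour — a
feature can be significant under both yet with hazard ratios on opposite
sides of 1, because the settings change what the feature measures.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter
from lifelines.exceptions import ConvergenceError

__all__ = [
    "SurvivalCohort",
    "CoxResult",
    "standardise",
    "cox_univariable",
    "survival_screen",
    "p_value_bin",
]


class ConstantFeatureError(ValueError):
    """Feature has zero variance and cannot enter the screen."""


@dataclass
class SurvivalCohort:
    """Per-subject follow-up time (years) and death indicator."""

    time: np.ndarray
    event: np.ndarray
    ids: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if self.time.shape != self.event.shape or self.time.ndim != 1:
            raise ValueError("time and event must be aligned 1D arrays")
        if (self.time <= 0).any():
            raise ValueError("follow-up times must be positive")
        if not np.isin(self.event, (0, 1)).all():
            raise ValueError("event indicator must be 0/1")
        if self.ids is None:
            self.ids = np.array([f"s{i:04d}" for i in range(len(self.time))])
        else:
            self.ids = np.asarray(self.ids)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "time_years": self.time, "event": self.event})

    @classmethod
    def from_csv(cls, path) -> "SurvivalCohort":
        df = pd.read_csv(path)
        return cls(time=df["time_years"].to_numpy(), event=df["event"].to_numpy(),
                   ids=df["id"].to_numpy())


@dataclass
class CoxResult:
    beta: float      # log hazard per 1 SD
    hr: float        # exp(beta)
    se: float
    p: float
    bin: str
    converged: bool = True  # False marks monotone-likelihood (infinite HR) fits
    feature_name: str = ""


def p_value_bin(p: float) -> str:
    """Heat-map bins at the 0.05 and 0.1 thresholds."""
    if p < 0.05:
        return "lt_0.05"
    if p < 0.1:
        return "0.05_to_0.1"
    return "gt_0.1"


def standardise(column: np.ndarray) -> np.ndarray:
    """Centre to mean 0 and scale to (sample, n-1) SD 1."""
    x = np.asarray(column, dtype=float)
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ConstantFeatureError("constant feature, excluded from screen")
    return (x - x.mean()) / sd


def cox_univariable(cohort: SurvivalCohort, z: np.ndarray,
                    feature_name: str = "") -> CoxResult:
    """One-covariate Cox PH fit (Efron ties) with a Wald test of beta = 0."""
    z = np.asarray(z, dtype=float)
    if len(z) != len(cohort.time):
        raise ValueError("feature and cohort lengths differ")
    if cohort.n_events < 2:
        raise ValueError("need at least 2 events for a Cox fit")
    if np.ptp(z) == 0:
        raise ConstantFeatureError("constant feature, excluded from screen")

    df = pd.DataFrame({"time": cohort.time, "event": cohort.event, "z": z})
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except ConvergenceError:
        return CoxResult(beta=np.inf, hr=np.inf, se=np.inf, p=np.nan,
                         bin="gt_0.1", converged=False, feature_name=feature_name)
    beta = float(cph.params_["z"])
    se = float(cph.standard_errors_["z"])
    p = float(cph.summary.loc["z", "p"])
    return CoxResult(beta=beta, hr=float(np.exp(beta)), se=se, p=p,
                     bin=p_value_bin(p), feature_name=feature_name)


def survival_screen(table: pd.DataFrame, cohort: SurvivalCohort,
                    profiles: list[str] | None = None,
                    features: list[str] | None = None) -> pd.DataFrame:
    """Univariable Cox screen of every feature under every profile.

    ``table`` is the long-format feature table (``subject_id``, ``profile``,
    feature columns).  Each profile's columns are standardised independently.
    Per-feature failures (constant columns, non-convergence) become flagged
    rows, not exceptions.  Returns the heat-map table with columns
    ``feature, profile, beta, hr, se, p, bin, status``.
    """
    if profiles is None:
        profiles = list(table["profile"].unique())
    meta = {"subject_id", "profile"}
    if features is None:
        features = [c for c in table.columns if c not in meta]

    id_order = {s: i for i, s in enumerate(np.asarray(cohort.ids))}
    rows = []
    for prof in profiles:
        sub = table[table["profile"] == prof].copy()
        sub = sub[sub["subject_id"].isin(id_order)]
        sub = sub.sort_values("subject_id", key=lambda s: s.map(id_order))
        if len(sub) != len(cohort.time):
            raise ValueError(f"profile {prof!r}: table subjects do not align with cohort")
        for feat in features:
            try:
                z = standardise(sub[feat].to_numpy())
                res = cox_univariable(cohort, z, feature_name=feat)
                status = "ok" if res.converged else "non_convergence"
            except ConstantFeatureError:
                res = CoxResult(np.nan, np.nan, np.nan, np.nan, "gt_0.1",
                                converged=False, feature_name=feat)
                status = "constant_feature"
            except ValueError as err:
                res = CoxResult(np.nan, np.nan, np.nan, np.nan, "gt_0.1",
                                converged=False, feature_name=feat)
                status = "too_few_events" if "events" in str(err) else "error"
            rows.append({"feature": feat, "profile": prof, "beta": res.beta,
                         "hr": res.hr, "se": res.se, "p": res.p,
                         "bin": res.bin, "status": status})
    return pd.DataFrame(rows)
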