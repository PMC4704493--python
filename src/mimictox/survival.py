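"""Kaplan-Meier estimation, log-rank testing, and the train/validation
percentile cutoff-scan procedure for miRNA-survival association.

The cutoff scan mirrors a common biomarker-dichotomization protocol: the
cohort is split 2/3 training / 1/3 validation; in the training set every
integer expression percentile from the 25th to the 75th is tried as a
cutpoint (high group = expression strictly above the cutpoint value), the
two arms are compared by the log-rank test, and every cutpoint with
p < alpha is carried to the validation set where significance is checked
at the *same absolute expression value*.  No multiplicity correction is
applied inside the training scan (the held-out validation controls it);
the resulting familywise inflation on null data is quantified in the test
suite.  Kaplan-Meier curves and log-rank statistics are delegated to
lifelines; ties between event and censoring times follow the standard
events-first convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

from .datatypes import validate_survival
from .errors import ConfigError, DataError, DegenerateDataError


# ----------------------------------------------------------------- splitting

def split_cohort(cohort: pd.DataFrame, fractions: tuple[float, float] = (2 / 3, 1 / 3),
                 seed: int = 0) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seeded random partition into (training, validation) cohorts.

    Training size is round(n * fractions[0]); the split is disjoint and
    exhaustive, and reproducible for a given seed.
    """
    validate_survival(cohort)
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigError(f"fractions must sum to 1, got {fractions}")
    n = len(cohort)
    if n < 6:
        raise DataError(f"cohort too small to split (n={n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = int(np.floor(n * fractions[0] + 0.5))
    train = cohort.iloc[perm[:n_train]].reset_index(drop=True)
    valid = cohort.iloc[perm[n_train:]].reset_index(drop=True)
    return train, valid


# -------------------------------------------------------------- Kaplan-Meier

@dataclass
class KMEstimate:
    """Product-limit survival estimate.

    ``median_survival`` is the smallest observed time with S(t) <= 0.5,
    or None when the curve never reaches 0.5.
    """
    event_times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median_survival: float | None


def km_curve(records: pd.DataFrame) -> KMEstimate:
    validate_survival(records)
    if len(records) == 0:
        raise DataError("empty survival record set")
    kmf = KaplanMeierFitter()
    kmf.fit(records["time"], event_observed=records["event"].astype(bool))
    times = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(kmf.survival_function_.index
                                                 ).to_numpy(dtype=float)
    median = kmf.median_survival_time_
    return KMEstimate(times, surv, at_risk,
                      None if np.isinf(median) else float(median))


def logrank_test(group1: pd.DataFrame, group2: pd.DataFrame
                 ) -> tuple[float, float]:
    """Two-sample log-rank test; returns (chi-square statistic, p)."""
    for i, g in enumerate((group1, group2), 1):
        validate_survival(g)
        if len(g) == 0:
            raise DegenerateDataError(f"group {i} is empty")
    if int(group1["event"].sum() + group2["event"].sum()) == 0:
        raise DegenerateDataError("no events in either group")
    res = _ll_logrank(group1["time"], group2["time"],
                      event_observed_A=group1["event"].astype(bool),
                      event_observed_B=group2["event"].astype(bool))
    return float(res.test_statistic), float(res.p_value)


# --------------------------------------------------------------- cutoff scan

@dataclass
class CutoffScanResult:
    """Per-candidate training results plus the selected cutpoints.

    ``candidates`` columns: percentile, cutoff (expression value), n_low,
    n_high, chi_square, p (NaN where a side is empty or event-free).
    ``selected`` lists training-significant percentiles; ``primary`` is
    the minimum-training-p selected percentile (None when nothing was
    selected).
    """
    candidates: pd.DataFrame
    selected: list[int]
    primary: int | None
    alpha: float


def cutoff_scan(training: pd.DataFrame,
                percentile_range: tuple[int, int] = (25, 75),
                step: int = 1, alpha: float = 0.05) -> CutoffScanResult:
    validate_survival(training)
    expr = training["expression"].to_numpy(dtype=float)
    if np.ptp(expr) == 0:
        raise DegenerateDataError("constant expression: no cutoff can split the cohort")
    lo, hi = percentile_range
    if not (0 < lo <= hi < 100):
        raise ConfigError(f"invalid percentile range {percentile_range}")
    rows = []
    for pct in range(lo, hi + 1, step):
        cutoff = float(np.percentile(expr, pct))  # inclusive linear interpolation
        high = training[training["expression"] > cutoff]
        low = training[training["expression"] <= cutoff]
        rec = {"percentile": pct, "cutoff": cutoff,
               "n_low": len(low), "n_high": len(high),
               "chi_square": np.nan, "p": np.nan}
        if len(low) and len(high) and (low["event"].sum() + high["event"].sum()):
            try:
                rec["chi_square"], rec["p"] = logrank_test(low, high)
            except DegenerateDataError:
                pass
        rows.append(rec)
    candidates = pd.DataFrame(rows)
    if candidates["p"].isna().all():
        raise DegenerateDataError("no candidate percentile admits a log-rank test")
    sel = candidates.loc[candidates["p"] < alpha]
    selected = sel["percentile"].astype(int).tolist()
    primary = (int(sel.loc[sel["p"].idxmin(), "percentile"])
               if len(sel) else None)
    return CutoffScanResult(candidates, selected, primary, alpha)


@dataclass
class ValidationResult:
    cutoff: float
    p: float
    chi_square: float
    significant: bool
    n_low: int
    n_high: int
    median_low: float | None
    median_high: float | None


def validate_cutoff(validation: pd.DataFrame, cutoff_value: float,
                    alpha: float = 0.05) -> ValidationResult:
    """Log-rank test on the validation cohort at a training-derived
    absolute expression cutoff, with per-group KM median survival."""
    validate_survival(validation)
    high = validation[validation["expression"] > cutoff_value]
    low = validation[validation["expression"] <= cutoff_value]
    if len(high) == 0 or len(low) == 0:
        raise DegenerateDataError(
            f"cutoff {cutoff_value} leaves an empty group in the validation cohort")
    chi2, p = logrank_test(low, high)
    return ValidationResult(
        cutoff=float(cutoff_value), p=p, chi_square=chi2,
        significant=p < alpha, n_low=len(low), n_high=len(high),
        median_low=km_curve(low).median_survival,
        median_high=km_curve(high).median_survival)
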