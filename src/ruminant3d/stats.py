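"""Repeatability / reproducibility statistics for trait measurements.

The variability of a measurement procedure is quantified per trait by
the residual standard deviation of a one-way ANOVA with the animal as
the (only) factor: sigma^2 = SS_within / (N - k) for N records on k
animals, which removes the true morphological differences between
animals.  From sigma:

* the coefficient of variation, CV% = 100 * sigma / mean, with the
  mean taken over the same measurement population;
* the 95% limit r = 1.959964 * sqrt(2) * sigma ~= 2.772 * sigma — the
  value that the absolute difference of two determinations stays below
  with 95% probability under a Gaussian error model;
* a quality verdict: repeatability/reproducibility is considered good
  when the CV is below 4%.

Repeatability pools repeated landmark identifications on a single
acquisition; intra-facility reproducibility pools all sessions of an
animal, so it additionally contains posture and acquisition
variability and is never smaller in expectation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "VariabilityResult",
    "LIMIT_FACTOR",
    "CV_THRESHOLD_PERCENT",
    "residual_sd",
    "cv_percent",
    "error_from_cv",
    "limit_95",
    "assess",
    "load_table",
]

#: |x1 - x2| of two iid Gaussian determinations is below
#: z_{0.975} * sqrt(2) * sigma with 95% probability
LIMIT_FACTOR = float(sp_stats.norm.ppf(0.975) * math.sqrt(2.0))

#: CVs below this are considered good practice for morphometric devices
CV_THRESHOLD_PERCENT = 4.0

REQUIRED_COLUMNS = {"subject", "trait", "value"}


@dataclass
class VariabilityResult:
    """Per-trait variability summary.

    ``error`` equals ``sigma`` (the conventional "error" column of
    variability tables); ``limit_r`` is the 95% repeatability or
    reproducibility limit 2.772 * sigma.
    """

    trait: str
    sigma: float
    mean: float
    cv_percent: float
    error: float
    limit_r: float
    n_subjects: int
    n_records: int
    df: int
    verdict_below_4pct: bool
    unit: str = ""

    def as_dict(self) -> dict:
        return dict(
            trait=self.trait,
            sigma=self.sigma,
            mean=self.mean,
            cv_percent=self.cv_percent,
            error=self.error,
            limit_r=self.limit_r,
            n_subjects=self.n_subjects,
            n_records=self.n_records,
            df=self.df,
            verdict_below_4pct=self.verdict_below_4pct,
            unit=self.unit,
        )


def _check_table(table: pd.DataFrame) -> None:
    missing = REQUIRED_COLUMNS - set(table.columns)
    if missing:
        raise ValueError(f"measurement table lacks columns {sorted(missing)}")


def residual_sd(table: pd.DataFrame, trait: str) -> tuple[float, int]:
    """Residual SD of the one-way (animal-effect) ANOVA for one trait.

    Returns ``(sigma, df)`` with ``sigma = sqrt(SS_within / (N - k))``
    and ``df = N - k``.  Unbalanced designs are accepted; a trait needs
    at least one residual degree of freedom.
    """
    _check_table(table)
    sub = table[table["trait"] == trait]
    if sub.empty:
        raise ValueError(f"no records for trait {trait!r}")
    values = sub["value"].to_numpy(dtype=float)
    groups = sub["subject"].to_numpy()
    _, inverse = np.unique(groups, return_inverse=True)
    k = inverse.max() + 1
    n = len(values)
    df = n - k
    if df < 1:
        raise ValueError(
            f"trait {trait!r}: no residual degrees of freedom "
            f"({n} records, {k} subjects)"
        )
    means = np.bincount(inverse, weights=values) / np.bincount(inverse)
    ss = float(np.sum((values - means[inverse]) ** 2))
    return math.sqrt(ss / df), int(df)


def cv_percent(sigma: float, mean: float) -> float:
    """Coefficient of variation in percent, 100 * sigma / mean."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    if mean <= 0:
        raise ValueError(f"mean must be > 0 for a CV, got {mean}")
    return 100.0 * sigma / mean


def error_from_cv(cv: float, mean: float) -> float:
    """Absolute error implied by a CV and a mean: cv/100 * mean."""
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if mean <= 0:
        raise ValueError(f"mean must be > 0, got {mean}")
    return cv / 100.0 * mean


def limit_95(sigma: float) -> float:
    """95% repeatability/reproducibility limit: the difference between
    two determinations not exceeded with 95% probability,
    ``1.959964 * sqrt(2) * sigma``."""
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    return LIMIT_FACTOR * sigma


def assess(table: pd.DataFrame) -> list[VariabilityResult]:
    """One :class:`VariabilityResult` per trait in the table.

    The mean in the CV is the mean of the same measurement population,
    so repeatability and reproducibility panels each use their own
    animals' mean.
    """
    _check_table(table)
    results = []
    for trait, sub in table.groupby("trait", sort=True):
        sigma, df = residual_sd(table, trait)
        mean = float(sub["value"].mean())
        cv = cv_percent(sigma, mean)
        unit = str(sub["unit"].iloc[0]) if "unit" in sub.columns else ""
        results.append(
            VariabilityResult(
                trait=str(trait),
                sigma=sigma,
                mean=mean,
                cv_percent=cv,
                error=sigma,
                limit_r=limit_95(sigma),
                n_subjects=int(sub["subject"].nunique()),
                n_records=int(len(sub)),
                df=df,
                verdict_below_4pct=bool(cv < CV_THRESHOLD_PERCENT),
                unit=unit,
            )
        )
    return results


def assess_frame(table: pd.DataFrame) -> pd.DataFrame:
    """:func:`assess` as a DataFrame (one row per trait)."""
    return pd.DataFrame([r.as_dict() for r in assess(table)])


def load_table(path) -> pd.DataFrame:
    """Read a long-format measurement CSV
    (subject, session, repeat, trait, value[, unit])."""
    table = pd.read_csv(path)
    _check_table(table)
    return table
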