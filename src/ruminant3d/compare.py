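"""Device comparison: paired trait differences, per-trait regressions
and body-weight prediction validation.

A comparison study scans the same animals with a reference device
(gold standard) and a test device, pairs the measurements by animal
and trait, and reports for every trait the mean of each device, their
absolute and relative difference, and the ordinary-least-squares
regression of the test values on the reference values.  The relative
difference is expressed against the reference-device mean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "ComparisonRow",
    "RegressionResult",
    "DEFAULT_COMPARISON_TRAITS",
    "paired_differences",
    "regress_devices",
    "validate_bw",
]

#: traits compared between devices by default; heart girth is measured
#: but excluded from the default device-comparison panel
DEFAULT_COMPARISON_TRAITS = ("wh", "hw", "wb", "cd", "ac", "tv", "ts")


@dataclass
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    n: int
    rmse: float = float("nan")

    def __iter__(self):
        yield from (self.slope, self.intercept, self.r_squared)


@dataclass
class ComparisonRow:
    """Per-trait device comparison summary."""

    trait: str
    mean_reference: float
    mean_test: float
    abs_difference: float
    rel_difference_percent: float
    slope: float
    intercept: float
    r_squared: float
    n: int

    def as_dict(self) -> dict:
        return self.__dict__.copy()


def _paired_frame(pm: pd.DataFrame) -> pd.DataFrame:
    need = {"subject", "trait", "value_reference", "value_test"}
    missing = need - set(pm.columns)
    if missing:
        raise ValueError(f"paired table lacks columns {sorted(missing)}")
    unpaired = pm["value_reference"].isna() | pm["value_test"].isna()
    if unpaired.any():
        warnings.warn(
            f"excluding {int(unpaired.sum())} unpaired records: "
            f"subjects {sorted(pm.loc[unpaired, 'subject'].unique().tolist())}"
        )
        pm = pm[~unpaired]
    return pm


def paired_differences(pm: pd.DataFrame, with_regression: bool = True) -> list[ComparisonRow]:
    """Comparison rows for every trait of a paired measurement table.

    ``pm`` has columns (subject, trait, value_reference, value_test).
    ``abs_difference`` is |mean_ref - mean_test| and the relative
    difference is a percentage of the reference mean.  Negative-slope
    regressions are flagged with a warning.
    """
    pm = _paired_frame(pm)
    rows = []
    for trait, sub in pm.groupby("trait", sort=True):
        if len(sub) < 2:
            warnings.warn(f"trait {trait!r}: fewer than 2 pairs, skipped")
            continue
        mr = float(sub["value_reference"].mean())
        mt = float(sub["value_test"].mean())
        if with_regression and len(sub) >= 3 and sub["value_reference"].std() > 0:
            reg = regress_devices(pm, trait)
        else:
            reg = RegressionResult(float("nan"), float("nan"), float("nan"), len(sub))
        rows.append(
            ComparisonRow(
                trait=str(trait),
                mean_reference=mr,
                mean_test=mt,
                abs_difference=abs(mr - mt),
                rel_difference_percent=100.0 * abs(mr - mt) / mr,
                slope=reg.slope,
                intercept=reg.intercept,
                r_squared=reg.r_squared,
                n=int(len(sub)),
            )
        )
    return rows


def comparison_frame(pm: pd.DataFrame) -> pd.DataFrame:
    """:func:`paired_differences` as a DataFrame."""
    return pd.DataFrame([r.as_dict() for r in paired_differences(pm)])


def regress_devices(pm: pd.DataFrame, trait: str) -> RegressionResult:
    """OLS regression of test-device values on reference-device values
    for one trait; ``r_squared`` is the squared Pearson correlation."""
    pm = _paired_frame(pm)
    sub = pm[pm["trait"] == trait]
    x = sub["value_reference"].to_numpy(dtype=float)
    y = sub["value_test"].to_numpy(dtype=float)
    if len(x) < 3:
        raise ValueError(f"trait {trait!r}: need >= 3 pairs, got {len(x)}")
    if np.std(x) == 0:
        raise ValueError(f"trait {trait!r}: reference values have zero variance")
    res = sp_stats.linregress(x, y)
    if res.slope < 0:
        warnings.warn(f"trait {trait!r}: negative device slope {res.slope:.3f}")
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(len(x)),
    )


def validate_bw(predicted, scale) -> RegressionResult:
    """Regression of weigh-scale body weight on equation-predicted body
    weight, plus the RMSE of the prediction (both in kg)."""
    predicted = np.asarray(predicted, dtype=float)
    scale = np.asarray(scale, dtype=float)
    if predicted.shape != scale.shape:
        raise ValueError(
            f"length mismatch: {predicted.shape} predicted vs {scale.shape} scale"
        )
    if len(predicted) < 3:
        raise ValueError("need at least 3 paired weights")
    if np.std(predicted) == 0:
        raise ValueError("predicted weights have zero variance")
    res = sp_stats.linregress(predicted, scale)
    rmse = float(np.sqrt(np.mean((scale - predicted) ** 2)))
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        n=int(len(predicted)),
        rmse=rmse,
    )
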