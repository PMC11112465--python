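"""Slope-dependence statistics over per-step stance parameters.

Aggregates per-step parameters into per-grade summaries, normalizes the
per-grade means to percent of horizontal (0% grade) walking, and fits
ordinary least-squares regressions of the normalized series (and of the
raw per-step values) on treadmill grade.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .constants import PARAMETER_NAMES

#: p-value threshold used when reporting significance.
ALPHA = 0.05


@dataclass(frozen=True)
class RegressionResult:
    parameter: str
    slope: float
    r_squared: float
    f_statistic: float
    p_value: float
    n: int

    @property
    def significant(self) -> bool:
        return self.p_value < ALPHA


def summarize_by_grade(
    records: pd.DataFrame,
    pooling: str = "participant",
    parameters: tuple[str, ...] = PARAMETER_NAMES,
) -> pd.DataFrame:
    """Per-grade mean/SD/n for each parameter, both feet pooled.

    pooling="participant": average steps within each participant first,
    then mean/SD across participants (the default for group summaries).
    pooling="step": pool all steps directly.

    Grades with zero accepted steps for a parameter are omitted. Slope
    columns may contain NaN for flagged-undefined stances; those stances
    are excluded from that parameter's summary only.
    """
    if records.empty:
        raise ValueError("no records to summarize")
    if pooling not in ("participant", "step"):
        raise ValueError(f"unknown pooling mode: {pooling}")
    rows = []
    for param in parameters:
        sub = records[["grade", "participant_id", param]].dropna(subset=[param])
        for grade, chunk in sub.groupby("grade"):
            n_steps = len(chunk)
            if n_steps == 0:
                continue
            if pooling == "participant":
                per_part = chunk.groupby("participant_id")[param].mean()
                mean, sd = float(per_part.mean()), float(per_part.std(ddof=1))
            else:
                mean, sd = float(chunk[param].mean()), float(chunk[param].std(ddof=1))
            rows.append(
                {
                    "grade": int(grade),
                    "parameter": param,
                    "mean": mean,
                    "sd": 0.0 if np.isnan(sd) else sd,
                    "n_steps": n_steps,
                }
            )
    return pd.DataFrame(rows).sort_values(["parameter", "grade"]).reset_index(drop=True)


def normalize_to_horizontal(summaries: pd.DataFrame) -> pd.DataFrame:
    """Express each per-grade mean as percent of the 0%-grade mean.

    Plain division is used for negative-valued parameters too, so a
    more-negative unloading slope maps above 100%.
    """
    rows = []
    for param, chunk in summaries.groupby("parameter"):
        base = chunk.loc[chunk["grade"] == 0, "mean"]
        if base.empty:
            raise ValueError(f"{param}: no 0% grade present")
        base = float(base.iloc[0])
        if base == 0:
            raise ValueError(f"{param}: zero horizontal mean")
        for _, r in chunk.iterrows():
            rows.append(
                {
                    "parameter": param,
                    "grade": int(r["grade"]),
                    "percent_of_horizontal": 100.0 * float(r["mean"]) / base,
                }
            )
    return pd.DataFrame(rows).sort_values(["parameter", "grade"]).reset_index(drop=True)


def _ols(y: np.ndarray, x: np.ndarray, parameter: str) -> RegressionResult:
    model = sm.OLS(y, sm.add_constant(x)).fit()
    r2 = float(model.rsquared)
    if not np.isfinite(r2):  # zero response variance
        r2 = 0.0
    return RegressionResult(
        parameter=parameter,
        slope=float(model.params[1]),
        r_squared=max(r2, 0.0),
        f_statistic=float(model.fvalue),
        p_value=float(model.f_pvalue),
        n=int(y.size),
    )


def regress_normalized(series: pd.DataFrame, parameter: str | None = None) -> RegressionResult:
    """OLS of percent-of-horizontal on grade for one parameter's series."""
    if parameter is not None:
        series = series[series["parameter"] == parameter]
    elif series["parameter"].nunique() == 1:
        parameter = str(series["parameter"].iloc[0])
    else:
        raise ValueError("series contains several parameters; name one")
    if len(series) < 3:
        raise ValueError("need at least 3 grade points")
    x = series["grade"].to_numpy(dtype=float)
    if np.unique(x).size < 2:
        raise ValueError("all grades identical")
    return _ols(series["percent_of_horizontal"].to_numpy(dtype=float), x, parameter)


def anova_per_parameter(
    records: pd.DataFrame, parameters: tuple[str, ...] = PARAMETER_NAMES
) -> list[RegressionResult]:
    """Per-step linear-regression ANOVA of each parameter on grade."""
    if records["grade"].nunique() < 2:
        raise ValueError("records must span at least 2 grades")
    out = []
    for param in parameters:
        sub = records[["grade", param]].dropna(subset=[param])
        out.append(
            _ols(
                sub[param].to_numpy(dtype=float),
                sub["grade"].to_numpy(dtype=float),
                param,
            )
        )
    return out


def regression_table(results: list[RegressionResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parameter": r.parameter,
                "slope": r.slope,
                "r_squared": r.r_squared,
                "f_statistic": r.f_statistic,
                "p_value": r.p_value,
                "n": r.n,
            }
            for r in results
        ]
    )
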