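"""Sweetening-power/citric-acid scoring and the linear acceptability model.

The score divides a sweetness-weighted sum of the sugar relative areas
by the citrate relative area,

    ratio = (w_suc * A_suc + w_glc * (A_aGlc + A_bGlc) + w_fru * A_fru) / A_cit,

with Schiffman relative sweetness weights w_suc = 1.0, w_fru = 1.3 and
w_glc = 0.6 (applied to both anomers).  Consumer acceptability is then
regressed on the per-variety mean ratio by ordinary least squares; model
quality is summarised by R^2 and an RMSE computed with divisor n (the
population form, which reproduces the published model errors).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .quantify import RelativeAreas

__all__ = [
    "SweetnessWeights",
    "VarietyRecord",
    "AcceptabilityModel",
    "sweetening_power",
    "sweetness_acid_ratio",
    "fit_acceptability_model",
    "predict_acceptability",
    "squared_correlation",
    "compare_instruments",
    "load_reference_table",
]


@dataclass(frozen=True)
class SweetnessWeights:
    """Relative sweetness factors (sucrose = 1 scale)."""

    sucrose: float = 1.0
    fructose: float = 1.3
    glucose: float = 0.6

    def __post_init__(self) -> None:
        if min(self.sucrose, self.fructose, self.glucose) <= 0:
            raise ValueError("sweetness weights must be > 0")


@dataclass
class VarietyRecord:
    """One mandarin variety: sensory score plus its replicate ratios."""

    variety_id: str
    acceptability: float
    ratio_per_replicate: list[float] = field(default_factory=list)
    mean_ratio: Optional[float] = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.acceptability):
            raise ValueError("acceptability must be finite")
        if self.ratio_per_replicate:
            m = float(np.mean(self.ratio_per_replicate))
            if self.mean_ratio is None:
                self.mean_ratio = m
            elif not np.isclose(self.mean_ratio, m, rtol=1e-9, atol=1e-12):
                raise ValueError("mean_ratio inconsistent with replicate ratios")
        elif self.mean_ratio is None:
            raise ValueError("need replicate ratios or a mean_ratio")

    @property
    def rsd_percent(self) -> float:
        """Relative standard deviation of the replicate ratios, in %."""
        r = np.asarray(self.ratio_per_replicate, dtype=float)
        if r.size < 2:
            return float("nan")
        return float(100.0 * r.std(ddof=1) / r.mean())


@dataclass
class AcceptabilityModel:
    """OLS line acceptability = slope * ratio + intercept."""

    slope: float
    intercept: float
    r_squared: float
    rmse: float
    n: int
    fitted_values: np.ndarray
    variety_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.fitted_values = np.asarray(self.fitted_values, dtype=float)
        if self.n < 3:
            raise ValueError("model needs n >= 3")
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValueError("r_squared must be in [0, 1]")
        if self.rmse < 0:
            raise ValueError("rmse must be >= 0")
        if self.fitted_values.size != self.n:
            raise ValueError("fitted_values length != n")

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "rmse": self.rmse,
            "n": self.n,
            "fitted_values": self.fitted_values.tolist(),
            "variety_ids": list(self.variety_ids),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def sweetening_power(areas: RelativeAreas, weights: SweetnessWeights = SweetnessWeights()) -> float:
    """Sweetness-weighted sum of the sugar relative areas."""
    return (
        weights.sucrose * areas.sucrose
        + weights.glucose * (areas.alpha_glucose + areas.beta_glucose)
        + weights.fructose * areas.fructose
    )


def sweetness_acid_ratio(
    areas: RelativeAreas, weights: SweetnessWeights = SweetnessWeights()
) -> float:
    """Sweetening power divided by the citrate relative area."""
    if areas.citrate <= 0:
        raise ValueError(f"citrate relative area must be > 0, got {areas.citrate}")
    return sweetening_power(areas, weights) / areas.citrate


def fit_acceptability_model(varieties: Sequence[VarietyRecord]) -> AcceptabilityModel:
    """OLS of acceptability on per-variety mean ratio.

    R^2 is the coefficient of determination (identical to the squared
    Pearson correlation for a simple regression).  RMSE uses divisor n,
    i.e. sqrt(mean squared residual): this is the model-error convention
    the reference results follow, not the n-2 regression standard error.
    """
    if len(varieties) < 3:
        raise ValueError("need at least 3 varieties")
    x = np.array([v.mean_ratio for v in varieties], dtype=float)
    y = np.array([v.acceptability for v in varieties], dtype=float)
    if np.ptp(x) == 0:
        raise ValueError("degenerate design: all mean ratios equal")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    fitted = np.asarray(res.fittedvalues)
    resid = y - fitted
    return AcceptabilityModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        rmse=float(np.sqrt(np.mean(resid**2))),
        n=len(varieties),
        fitted_values=fitted,
        variety_ids=[v.variety_id for v in varieties],
    )


def predict_acceptability(model: AcceptabilityModel, ratio) -> float | np.ndarray:
    """Acceptability predicted by the fitted line."""
    out = model.slope * np.asarray(ratio, dtype=float) + model.intercept
    return float(out) if out.ndim == 0 else out


def squared_correlation(x: Sequence[float], y: Sequence[float]) -> float:
    """Squared Pearson correlation of two equal-length series."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("length mismatch")
    if x.size < 3:
        raise ValueError("need at least 3 points")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("zero variance")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def compare_instruments(
    varieties_a: Sequence[VarietyRecord], varieties_b: Sequence[VarietyRecord]
) -> dict:
    """Cross-instrument equivalence report.

    Both lists must cover the same varieties.  Returns the squared
    correlation of the mean ratios, both fitted acceptability models,
    and the squared correlation of their fitted values — the three
    quantities that establish that two field strengths give
    interchangeable acceptability models.
    """
    ids_a = [v.variety_id for v in varieties_a]
    ids_b = [v.variety_id for v in varieties_b]
    if set(ids_a) != set(ids_b):
        raise ValueError(f"variety mismatch: {sorted(set(ids_a) ^ set(ids_b))}")
    order = {vid: i for i, vid in enumerate(ids_a)}
    varieties_b = sorted(varieties_b, key=lambda v: order[v.variety_id])
    model_a = fit_acceptability_model(varieties_a)
    model_b = fit_acceptability_model(varieties_b)
    ratios_a = [v.mean_ratio for v in varieties_a]
    ratios_b = [v.mean_ratio for v in varieties_b]
    return {
        "variety_ids": ids_a,
        "ratio_r_squared": squared_correlation(ratios_a, ratios_b),
        "model_a": model_a,
        "model_b": model_b,
        "prediction_r_squared": squared_correlation(
            model_a.fitted_values, model_b.fitted_values
        ),
    }


def load_reference_table() -> pd.DataFrame:
    """Bundled five-variety reference table: sensory acceptability and
    the published mean sweetening-power/citric-acid ratios measured at
    both field strengths (columns ``variety_id``, ``acceptability``,
    ``ratio_400mhz``, ``ratio_60mhz``)."""
    with resources.files("citrusnmr.data").joinpath("reference_varieties.csv").open() as fh:
        return pd.read_csv(fh)


def records_from_table(df: pd.DataFrame, ratio_column: str) -> list[VarietyRecord]:
    """Build VarietyRecords from a table with per-variety mean ratios."""
    return [
        VarietyRecord(
            variety_id=str(r["variety_id"]),
            acceptability=float(r["acceptability"]),
            mean_ratio=float(r[ratio_column]),
        )
        for _, r in df.iterrows()
    ]
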