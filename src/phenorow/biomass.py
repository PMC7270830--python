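"""Seasonal dry-matter-yield prediction, plot aggregation and validation.

Per-plant biomass (grams) is an affine function of the combined
NDVI/height predictor, with season-specific intercept and slope::

    g = (b0 + d_int[season]) + (b1 + d_slope[season]) * predictor

with winter as the reference season (both offsets zero).  Two coefficient
modes are carried: ``reconstructed`` gives winter the shared base slope
5.088 that the other seasonal equations build their slope offsets on;
``as_printed`` keeps the winter slope at exactly 1 as the winter equation
is published.  Both agree at predictor 0.

Plot-level prediction is the sum of its plants' grams divided by 1000;
validation regresses measured on predicted and reports the slope, R^2
(squared Pearson correlation, sign-blind) and RMSE, the latter both on
raw prediction error and on regression residuals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "SEASONS",
    "SeasonModel",
    "ValidationReport",
    "predict_dmy",
    "fit_seasonal_model",
    "aggregate_plot",
    "validate",
]

SEASONS = ("winter2018", "late-spring2018_1", "late-spring2018_2")

GRAMS_PER_KILOGRAM = 1000.0


@dataclass(frozen=True)
class SeasonModel:
    """Intercept/slope structure of the seasonal biomass equations."""

    base_intercept: float = -4.62
    base_slope: float = 5.088
    intercept_offsets: tuple = (0.0, 5.76, 16.86)
    slope_offsets: tuple = (0.0, 1.49, 3.68)
    mode: str = "reconstructed"

    def __post_init__(self):
        if self.mode not in ("reconstructed", "as_printed"):
            raise ValueError("mode must be 'reconstructed' or 'as_printed'")

    def coefficients(self, season: str):
        """(intercept, slope) in grams / grams-per-predictor-unit."""
        try:
            i = SEASONS.index(season)
        except ValueError:
            raise ValueError(
                f"unknown season {season!r}; valid: {list(SEASONS)}"
            ) from None
        intercept = self.base_intercept + self.intercept_offsets[i]
        if self.mode == "as_printed" and season == "winter2018":
            slope = 1.0  # the winter equation as published carries no slope
        else:
            slope = self.base_slope + self.slope_offsets[i]
        return intercept, slope


def predict_dmy(predictor, season: str, model: SeasonModel | None = None):
    """Per-plant dry matter yield in grams for one season."""
    model = model or SeasonModel()
    intercept, slope = model.coefficients(season)
    return intercept + slope * np.asarray(predictor, dtype=float)


def fit_seasonal_model(table: pd.DataFrame):
    """OLS fit of the season-interaction biomass model.

    ``table`` columns: ``predictor``, ``season``, ``grams``.  The design is
    intercept + predictor + season dummies + predictor x season, with
    winter as the reference level.  Returns ``(SeasonModel, fit result)``.
    """
    seasons_present = [s for s in SEASONS if s in set(table["season"])]
    if len(seasons_present) < 2:
        raise ValueError(
            "need at least 2 seasons to identify the season interaction"
        )
    for s in seasons_present:
        if (table["season"] == s).sum() < 3:
            raise ValueError(f"season {s!r} has fewer than 3 observations")
    if float(np.var(table["predictor"])) == 0:
        raise ValueError("predictor has zero variance")
    x = table["predictor"].to_numpy(dtype=float)
    cols = [np.ones(len(table)), x]
    names = ["intercept", "predictor"]
    for s in seasons_present:
        if s == "winter2018":
            continue
        d = (table["season"] == s).to_numpy(dtype=float)
        cols += [d, d * x]
        names += [f"season[{s}]", f"predictor:season[{s}]"]
    design = np.column_stack(cols)
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        raise ValueError(
            "rank-deficient design (a season term is collinear); check that "
            "the predictor varies within every season"
        )
    res = sm.OLS(table["grams"].to_numpy(dtype=float), design).fit()
    params = dict(zip(names, res.params))
    int_off = [0.0, 0.0, 0.0]
    slope_off = [0.0, 0.0, 0.0]
    for i, s in enumerate(SEASONS):
        if s == "winter2018":
            continue
        int_off[i] = float(params.get(f"season[{s}]", 0.0))
        slope_off[i] = float(params.get(f"predictor:season[{s}]", 0.0))
    fitted = SeasonModel(
        base_intercept=float(params["intercept"]),
        base_slope=float(params["predictor"]),
        intercept_offsets=tuple(int_off),
        slope_offsets=tuple(slope_off),
        mode="reconstructed",
    )
    res.param_names = names
    return fitted, res


def aggregate_plot(plants: pd.DataFrame) -> pd.DataFrame:
    """Sum per-plant grams to per-plot kilograms.

    ``plants`` columns: ``plant_id``, ``plot_id``, ``predicted_g`` (NaN for
    plants with missing traits; these are excluded and counted).  Optional
    ``entry`` is carried through.
    """
    if plants["plot_id"].isna().any():
        bad = plants.loc[plants["plot_id"].isna(), "plant_id"].head(3).tolist()
        raise ValueError(f"plants with unknown plot: {bad}")
    rows = []
    for plot_id, grp in plants.groupby("plot_id", sort=True):
        ok = grp["predicted_g"].notna()
        rows.append(
            dict(
                plot_id=plot_id,
                entry=grp["entry"].iloc[0] if "entry" in grp else None,
                n_plants=int(ok.sum()),
                n_missing=int((~ok).sum()),
                predicted_kg=float(grp.loc[ok, "predicted_g"].sum())
                / GRAMS_PER_KILOGRAM,
                flagged=bool((~ok).any()),
            )
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ValidationReport:
    n: int
    slope: float
    intercept: float
    r_squared: float
    rmse_raw: float
    rmse_residual: float

    def to_dict(self):
        return dict(
            n=self.n, slope=self.slope, intercept=self.intercept,
            r2=self.r_squared, rmse_raw=self.rmse_raw,
            rmse_resid=self.rmse_residual,
        )


def validate(predicted, measured) -> ValidationReport:
    """Measured-on-predicted regression with R^2 and RMSE.

    R^2 is the squared Pearson correlation (sign-blind — the slope is
    reported alongside so anti-correlation is visible).  ``rmse_raw`` is
    sqrt(mean (measured - predicted)^2) on the raw pairs; ``rmse_residual``
    is the RMSE of the regression residuals.
    """
    predicted = np.asarray(predicted, dtype=float)
    measured = np.asarray(measured, dtype=float)
    if len(predicted) < 3:
        raise ValueError("need at least 3 pairs to validate")
    if not (np.all(np.isfinite(predicted)) and np.all(np.isfinite(measured))):
        raise ValueError("non-finite values in validation pairs")
    if float(np.var(predicted)) == 0:
        raise ValueError("predicted values have zero variance")
    slope, intercept = np.polyfit(predicted, measured, 1)
    r = float(np.corrcoef(predicted, measured)[0, 1])
    resid = measured - (slope * predicted + intercept)
    return ValidationReport(
        n=len(predicted),
        slope=float(slope),
        intercept=float(intercept),
        r_squared=r * r,
        rmse_raw=float(np.sqrt(np.mean((measured - predicted) ** 2))),
        rmse_residual=float(np.sqrt(np.mean(resid**2))),
    )
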