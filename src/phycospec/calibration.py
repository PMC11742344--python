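"""Concentration equations and calibration regression machinery.

Beer-Lambert (A = alpha * L * c) links absorbance to pigment concentration;
the Bennett-Bogorad two-wavelength equation gives phycocyanin concentration
from crude-extract absorbances.  Calibration models are ordinary least
squares fits of a spectral index on spiked pigment mass, reported with R²,
the two-sided t-test p-value of the slope, and a cross-validated root mean
square error of prediction (RMSEP) expressed as a percentage of the mean
observed response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.model_selection import KFold

from .indices import SpikeSeries, normalize_series

__all__ = [
    "CalibrationModel",
    "beer_lambert_concentration",
    "pc_concentration_bennett_bogorad",
    "fit_calibration",
    "rmsep_cv",
    "build_calibration_report",
]

SIGNIFICANCE_LEVEL = 0.05


@dataclass(frozen=True)
class CalibrationModel:
    """OLS calibration line with fit statistics and cross-validated RMSEP."""

    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int
    rmsep_percent: float | None = None
    folds: int | None = None

    @property
    def significant(self) -> bool:
        return self.p_value < SIGNIFICANCE_LEVEL

    def predict(self, x: np.ndarray) -> np.ndarray:
        return self.intercept + self.slope * np.asarray(x, dtype=float)

    def to_dict(self) -> dict:
        return {
            "slope": self.slope,
            "intercept": self.intercept,
            "r_squared": self.r_squared,
            "p_value": self.p_value,
            "n": self.n,
            "rmsep_percent": self.rmsep_percent,
            "folds": self.folds,
        }


def beer_lambert_concentration(absorbance: float, alpha: float, path_cm: float) -> float:
    """Concentration in g/l from A = alpha * L * c.

    ``alpha`` is the specific extinction coefficient in l g^-1 cm^-1
    (88.15 for chlorophyll a in 100% acetone) and ``path_cm`` the optical
    path length in cm.
    """
    if alpha <= 0 or path_cm <= 0:
        raise ValueError("alpha and path length must be positive")
    if absorbance < 0:
        raise ValueError("absorbance must be non-negative")
    return absorbance / (alpha * path_cm)


def pc_concentration_bennett_bogorad(
    a620: float,
    a652: float,
    chl_correction: float = 0.474,
    denominator: float = 5.34,
) -> float:
    """Phycocyanin concentration (mg/ml) from extract absorbances.

    PC = (A620 - 0.474 * A652) / 5.34, the standard two-wavelength equation
    correcting the 620 nm absorbance for allophycocyanin overlap.  Negative
    results are floored at 0 with a warning.
    """
    if a620 < 0 or a652 < 0:
        raise ValueError("absorbances must be non-negative")
    pc = (a620 - chl_correction * a652) / denominator
    if pc < 0:
        warnings.warn(
            f"negative phycocyanin concentration ({pc:.4g} mg/ml) floored at 0",
            stacklevel=2,
        )
        return 0.0
    return pc


def fit_calibration(x: np.ndarray, y: np.ndarray) -> CalibrationModel:
    """OLS of y on x with R² and the slope's two-sided t-test p-value.

    The p-value uses the t distribution with n-2 degrees of freedom.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 points for a calibration fit")
    if np.ptp(x) == 0:
        raise ValueError("x is constant; calibration line is undefined")
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CalibrationModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        r_squared=float(res.rsquared),
        p_value=float(res.pvalues[1]),
        n=int(x.size),
    )


def rmsep_cv(
    x: np.ndarray,
    y: np.ndarray,
    folds: int = 10,
    seed: int = 0,
    allow_reduce: bool = True,
) -> float:
    """Cross-validated RMSEP as a percentage of mean(y).

    Fold membership is assigned by a seeded shuffle; each fold is predicted
    from an OLS line fitted on the remaining points and the squared
    prediction errors are pooled:

        RMSEP% = 100 * sqrt(mean((y_hat - y)^2)) / mean(y)

    With n < folds the fold count is reduced to n (leave-one-out) and a
    warning is emitted, unless ``allow_reduce`` is False.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < folds:
        if not allow_reduce:
            raise ValueError(f"n={n} is smaller than folds={folds}")
        warnings.warn(
            f"n={n} < folds={folds}; reducing to leave-one-out", stacklevel=2
        )
        folds = n
    if folds < 2:
        raise ValueError("need at least 2 folds")
    mean_y = float(np.mean(y))
    if mean_y == 0:
        raise ValueError("mean response is zero; RMSEP%% undefined")
    kf = KFold(n_splits=folds, shuffle=True, random_state=int(seed) % (2**31))
    sq_errors = np.empty(n)
    # sort-order canonicalisation keeps fold membership invariant under
    # reordering of the (x, y) pairs
    order = np.lexsort((y, x))
    xs, ys = x[order], y[order]
    for train, test in kf.split(xs):
        slope, intercept = np.polyfit(xs[train], ys[train], 1)
        pred = intercept + slope * xs[test]
        sq_errors[test] = (pred - ys[test]) ** 2
    return float(100.0 * np.sqrt(sq_errors.mean()) / mean_y)


def build_calibration_report(
    series: SpikeSeries,
    folds: int = 10,
    seed: int = 0,
    use_normalized: bool = True,
) -> tuple[CalibrationModel, pd.DataFrame]:
    """Regress the (normalized) spike-series index on cumulative mass.

    Returns the fitted model (with cross-validated RMSEP attached) and a
    per-step residual table.  Fits with slope p-value >= 0.05 are flagged in
    the table's attrs; short series (n = 3-4) are frequently non-significant.
    """
    if series.masses_ug.size < 3:
        raise ValueError("need at least 3 spike steps")
    if use_normalized:
        if series.index_normalized is None:
            series = normalize_series(series)
        y = np.asarray(series.index_normalized, dtype=float)
    else:
        y = series.index
    x = series.masses_ug
    model = fit_calibration(x, y)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        rmsep = rmsep_cv(x, y, folds=folds, seed=seed)
    actual_folds = min(folds, x.size)
    model = CalibrationModel(
        **{**model.to_dict(), "rmsep_percent": rmsep, "folds": actual_folds}
    )
    table = pd.DataFrame(
        {
            "matrix": series.matrix,
            "pigment": series.pigment,
            "mass_ug": x,
            "index": y,
            "fitted": model.predict(x),
        }
    )
    table["residual"] = table["index"] - table["fitted"]
    table.attrs["significant"] = model.significant
    return model, table
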