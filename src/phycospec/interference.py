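"""Chlorophyll a interference with the phycocyanin index.

Chlorophyll a absorbs strongly near 673 nm; its trough shoulder reaches
into the phycocyanin window (600-640 nm), lowering the local two-point
continuum of RABD620 and thereby masking phycocyanin.  This module
quantifies that interference on series where phycocyanin mass is held
constant while chlorophyll a is spiked incrementally: the RABD620-vs-Chl a
regression (negative slope under overlap), the masking curve relating the
Chl a/PC mass ratio to the RABD620/RABD675 index ratio, and a detectability
threshold — the chlorophyll load at which the 620 nm local minimum of the
continuum-removed spectrum vanishes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .calibration import CalibrationModel, fit_calibration
from .indices import TROUGH_PROFILES, index_map, roi_mean
from .spectral import continuum_removed
from .synth import MatrixSpec, SpikePlan, apply_pigment_troughs, make_background, simulate_spiking_cubes
from .types import WavelengthAxis

__all__ = [
    "InterferenceSeries",
    "mass_ratio",
    "run_interference_experiment",
    "interference_regression",
    "masking_curve",
    "detectability_threshold",
]


@dataclass(frozen=True)
class InterferenceSeries:
    """ROI-mean RABD620/RABD675 along a Chl a spiking series at fixed PC."""

    pc_mass_ug: float
    chla_masses_ug: np.ndarray
    rabd620: np.ndarray
    rabd675: np.ndarray

    def __post_init__(self) -> None:
        if self.pc_mass_ug <= 0:
            raise ValueError("pc_mass_ug must be positive")
        chla = np.asarray(self.chla_masses_ug, dtype=float)
        if np.any(np.diff(chla) < 0):
            raise ValueError("chla masses must be non-decreasing")
        for name in ("chla_masses_ug", "rabd620", "rabd675"):
            object.__setattr__(self, name, np.asarray(getattr(self, name), dtype=float))
        if not (self.chla_masses_ug.shape == self.rabd620.shape == self.rabd675.shape):
            raise ValueError("per-step arrays must share one length")

    @property
    def mass_ratios(self) -> np.ndarray:
        return self.chla_masses_ug / self.pc_mass_ug

    @property
    def index_ratios(self) -> np.ndarray:
        return self.rabd620 / self.rabd675


def mass_ratio(chla_mass_ug: float, pc_mass_ug: float) -> float:
    """Chl a / PC mass ratio (reported to two decimals in summaries)."""
    if pc_mass_ug <= 0:
        raise ValueError("pc_mass_ug must be positive")
    return chla_mass_ug / pc_mass_ug


def run_interference_experiment(
    spec: MatrixSpec,
    pc_mass_ug: float = 150.0,
    chla_masses_ug: tuple[float, ...] = (0.0, 5.0, 10.0, 15.0, 20.0),
    shape: tuple[int, int] = (16, 16),
    axis: WavelengthAxis | None = None,
    seed: int | None = None,
) -> InterferenceSeries:
    """Simulate the fixed-PC / incremental-Chl a design and measure both indices."""
    plan = SpikePlan(pigment="ChlA", masses_ug=tuple(chla_masses_ug))
    cubes, _ = simulate_spiking_cubes(
        spec, plan, shape=shape, axis=axis, fixed_pc_mass=pc_mass_ug, seed=seed
    )
    r620 = [roi_mean(index_map(c, TROUGH_PROFILES["RABD620"])) for c in cubes]
    r675 = [roi_mean(index_map(c, TROUGH_PROFILES["RABD675"])) for c in cubes]
    return InterferenceSeries(
        pc_mass_ug=pc_mass_ug,
        chla_masses_ug=np.asarray(chla_masses_ug, dtype=float),
        rabd620=np.asarray(r620),
        rabd675=np.asarray(r675),
    )


def interference_regression(series: InterferenceSeries) -> CalibrationModel:
    """OLS of RABD620 on Chl a mass; a negative slope signals masking."""
    if series.chla_masses_ug.size < 3:
        raise ValueError("need at least 3 spiking steps")
    return fit_calibration(series.chla_masses_ug, series.rabd620)


def masking_curve(series: InterferenceSeries) -> pd.DataFrame:
    """Paired (mass ratio, index ratio) table with a Spearman monotonicity check.

    A decreasing index ratio with increasing mass ratio indicates that the
    growing chlorophyll trough progressively masks the phycocyanin trough.
    """
    if series.chla_masses_ug.size < 2:
        raise ValueError("need at least 2 steps")
    table = pd.DataFrame(
        {
            "chla_mass_ug": series.chla_masses_ug,
            "mass_ratio": series.mass_ratios,
            "rabd620": series.rabd620,
            "rabd675": series.rabd675,
            "index_ratio": series.index_ratios,
        }
    )
    if np.ptp(table["index_ratio"].to_numpy()) == 0:
        rho = 0.0
    else:
        rho = float(spearmanr(table["mass_ratio"], table["index_ratio"]).statistic)
    table.attrs["spearman_rho"] = rho
    table.attrs["monotone_decreasing"] = bool(
        np.all(np.diff(table["index_ratio"].to_numpy()) < 0)
    )
    return table


def _has_local_minimum(values: np.ndarray) -> bool:
    interior = np.arange(1, values.size - 1)
    return bool(
        np.any(
            (values[interior] < values[interior - 1])
            & (values[interior] < values[interior + 1])
        )
    )


def detectability_threshold(
    spec: MatrixSpec,
    pc_mass_ug: float,
    chla_grid_ug: np.ndarray,
    axis: WavelengthAxis | None = None,
    pc_window_nm: tuple[float, float] = (600.0, 640.0),
) -> float | None:
    """Smallest Chl a mass at which the 620 nm trough disappears.

    The trough is deemed to have disappeared when the continuum-removed
    noiseless spectrum has no local minimum inside the phycocyanin window.
    Returns None if the trough persists over the whole grid ("not reached").
    """
    chla_grid = np.asarray(chla_grid_ug, dtype=float)
    if np.any(np.diff(chla_grid) <= 0):
        raise ValueError("chla grid must be strictly increasing")
    background = make_background(spec, axis)
    idx = background.axis.window(*pc_window_nm)
    for chla in chla_grid:
        spectrum = apply_pigment_troughs(
            background, pc_mass=pc_mass_ug, chla_mass=float(chla), spec=spec
        )
        cr = continuum_removed(spectrum)
        if not _has_local_minimum(cr.values[idx]):
            return float(chla)
    return None
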