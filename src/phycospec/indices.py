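"""Relative absorbance band depth (RABD) and area (RABA) indices.

RABD for a trough with left/right shoulder bands and a minimum band is

    RABD_min = ((X_right * R_left + X_left * R_right) / (X_right + X_left)) / R_min

where X_left / X_right count band steps from the shoulders to the minimum
and R_* are reflectances at the snapped bands.  The numerator is the linear
two-point continuum evaluated at the minimum band; a flat spectrum gives
exactly 1 and a deeper trough a larger value.

RABA sums the relative deficit of reflectance below the shoulder chord
across the trough window; it is 0 for a spectrum lying on its chord and is
invariant to rescaling the whole spectrum.

The shipped trough profiles are conservative: the phycocyanin window
(600-640 nm) and the chlorin window (650-700 nm) share no band, so RABD620
reflects phycocyanin only and not a mixed signal with chlorophyll a.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from .types import HyperspectralCube, Spectrum

__all__ = [
    "TroughDefinition",
    "PigmentIndexMap",
    "SpikeSeries",
    "TROUGH_PROFILES",
    "rabd",
    "raba",
    "index_map",
    "roi_mean",
    "normalize_series",
    "index_ratio",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TroughDefinition:
    """Left shoulder, trough minimum and right shoulder wavelengths (nm).

    ``float_min=True`` lets the minimum float to the deepest band between the
    shoulders ("the deepest point of the trough") instead of the fixed centre.
    """

    name: str
    lambda_left: float
    lambda_min: float
    lambda_right: float
    float_min: bool = False

    def __post_init__(self) -> None:
        if not (self.lambda_left < self.lambda_min < self.lambda_right):
            raise ValueError(
                f"{self.name}: require lambda_left < lambda_min < lambda_right"
            )


#: Default trough profiles.  Centres follow the published trough positions
#: (phycocyanin 620 nm, chlorophyll a ~673 nm, total chlorins 660 nm for the
#: downcore application, bacteriopheophytin a 845 nm); widths keep the PC and
#: chlorin windows disjoint.
TROUGH_PROFILES: dict[str, TroughDefinition] = {
    "RABD620": TroughDefinition("RABD620", 600.0, 620.0, 640.0),
    "RABD675": TroughDefinition("RABD675", 650.0, 673.0, 700.0),
    "RABD660": TroughDefinition("RABD660", 650.0, 660.0, 690.0),
    "RABD845": TroughDefinition("RABD845", 800.0, 845.0, 880.0),
}


def _snap(spectrum: Spectrum, trough: TroughDefinition) -> tuple[int, int, int]:
    axis = spectrum.axis
    for lam in (trough.lambda_left, trough.lambda_min, trough.lambda_right):
        if not axis.contains(lam):
            raise ValueError(f"{trough.name}: {lam} nm outside the axis")
    i_left = axis.index_of(trough.lambda_left)
    i_right = axis.index_of(trough.lambda_right)
    if trough.float_min:
        inner = spectrum.values[i_left + 1 : i_right]
        if inner.size == 0:
            raise ValueError(f"{trough.name}: no interior band between shoulders")
        i_min = i_left + 1 + int(np.argmin(inner))
    else:
        i_min = axis.index_of(trough.lambda_min)
    if not (i_left < i_min < i_right):
        raise ValueError(
            f"{trough.name}: snapped bands do not bracket the minimum "
            f"(indices {i_left}, {i_min}, {i_right})"
        )
    return i_left, i_min, i_right


def rabd(spectrum: Spectrum, trough: TroughDefinition) -> float:
    """Relative absorbance band depth at the trough minimum."""
    i_left, i_min, i_right = _snap(spectrum, trough)
    x_left = i_min - i_left
    x_right = i_right - i_min
    r_left = spectrum.values[i_left]
    r_right = spectrum.values[i_right]
    r_min = spectrum.values[i_min]
    if r_min <= 0:
        raise ValueError(f"{trough.name}: non-positive reflectance at the minimum band")
    continuum = (x_right * r_left + x_left * r_right) / (x_right + x_left)
    return float(continuum / r_min)


def raba(spectrum: Spectrum, trough: TroughDefinition) -> float:
    """Relative absorbance band area between the shoulder bands.

    Sum over bands left..right of (C_i - R_i)/C_i where C is the straight
    chord between the shoulders.
    """
    i_left, i_min, i_right = _snap(spectrum, trough)
    axis = spectrum.axis
    bands = np.arange(i_left, i_right + 1)
    chord = np.interp(
        axis.centres[bands],
        [axis.centres[i_left], axis.centres[i_right]],
        [spectrum.values[i_left], spectrum.values[i_right]],
    )
    if np.any(chord <= 0):
        raise ValueError(f"{trough.name}: non-positive chord value")
    return float(np.sum((chord - spectrum.values[bands]) / chord))


@dataclass(frozen=True)
class PigmentIndexMap:
    """Per-pixel index values for one trough over one cube."""

    trough: TroughDefinition
    values: np.ndarray  # rows x cols, NaN where masked or failed
    pixel_size_um: float = 80.0

    @property
    def finite_count(self) -> int:
        return int(np.isfinite(self.values).sum())


def index_map(
    cube: HyperspectralCube,
    trough: TroughDefinition,
    statistic: str = "rabd",
    mask: np.ndarray | None = None,
) -> PigmentIndexMap:
    """Apply :func:`rabd` (or :func:`raba`) to every pixel of a cube.

    Masked or failing pixels become NaN; the failure count is logged.
    """
    if statistic == "rabd":
        # vectorised fast path for the fixed-centre RABD
        probe = cube.pixel(0, 0)
        i_left, i_min, i_right = _snap(probe, trough)
        if trough.float_min:
            window = cube.values[:, :, i_left + 1 : i_right]
            inner = np.argmin(window, axis=2) + i_left + 1
            r_min = np.take_along_axis(
                cube.values, inner[:, :, None], axis=2
            )[:, :, 0]
            x_left = inner - i_left
            x_right = i_right - inner
        else:
            r_min = cube.values[:, :, i_min]
            x_left = i_min - i_left
            x_right = i_right - i_min
        r_left = cube.values[:, :, i_left]
        r_right = cube.values[:, :, i_right]
        continuum = (x_right * r_left + x_left * r_right) / (x_right + x_left)
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(r_min > 0, continuum / r_min, np.nan)
    elif statistic == "raba":
        out = np.empty((cube.rows, cube.cols))
        for r in range(cube.rows):
            for c in range(cube.cols):
                try:
                    out[r, c] = raba(cube.pixel(r, c), trough)
                except ValueError:
                    out[r, c] = np.nan
    else:
        raise ValueError(f"unknown statistic {statistic!r}")

    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != out.shape:
            raise ValueError("mask shape must match cube rows x cols")
        out = np.where(mask, out, np.nan)
    failed = int(np.sum(~np.isfinite(out)))
    if failed:
        logger.info("%s: %d of %d pixels masked or failed", trough.name, failed, out.size)
    return PigmentIndexMap(trough, out, pixel_size_um=cube.pixel_size_um)


def roi_mean(imap: PigmentIndexMap, mask: np.ndarray | None = None) -> float:
    """Arithmetic mean of the index over unmasked finite pixels."""
    values = imap.values
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != values.shape:
            raise ValueError("mask shape must match the index map")
        values = np.where(mask, values, np.nan)
    finite = np.isfinite(values)
    if not finite.any():
        raise ValueError("ROI contains no finite index values")
    return float(values[finite].mean())


@dataclass(frozen=True)
class SpikeSeries:
    """Ordered cumulative pigment masses with matching ROI-mean indices."""

    matrix: str
    pigment: str
    masses_ug: np.ndarray
    index: np.ndarray
    index_normalized: np.ndarray | None = None

    def __post_init__(self) -> None:
        masses = np.asarray(self.masses_ug, dtype=float)
        index = np.asarray(self.index, dtype=float)
        if masses.shape != index.shape:
            raise ValueError("one index value per mass required")
        if np.any(masses < 0) or np.any(np.diff(masses) < 0):
            raise ValueError("masses must be non-negative and non-decreasing")
        object.__setattr__(self, "masses_ug", masses)
        object.__setattr__(self, "index", index)


def normalize_series(series: SpikeSeries) -> SpikeSeries:
    """Divide every index by the unspiked (mass 0) baseline value.

    This removes matrix-to-matrix differences in the raw index level; the
    step-0 normalized value is exactly 1.  Idempotent.
    """
    if series.masses_ug[0] != 0:
        raise ValueError("series must start with an unspiked (mass 0) step")
    baseline = series.index[0]
    if not baseline > 0:
        raise ValueError("unspiked baseline index must be positive")
    return replace(series, index_normalized=series.index / baseline)


def index_ratio(map_a: PigmentIndexMap, map_b: PigmentIndexMap,
                mask: np.ndarray | None = None) -> float:
    """Ratio of ROI means, mean(a)/mean(b), over a shared ROI."""
    denom = roi_mean(map_b, mask)
    if denom == 0:
        raise ValueError("denominator ROI mean is zero")
    return roi_mean(map_a, mask) / denom
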