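"""Core in-memory containers: wavelength axis, spectrum, hyperspectral cube.

A cube is indexed ``(row, col, band)`` where rows run downcore (row 0 is the
core top) and columns run across the core.  All reflectance values are on the
0-1 scale produced by white/dark calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

VNIR_MIN_NM = 400.0
VNIR_MAX_NM = 1000.0

__all__ = ["WavelengthAxis", "Spectrum", "HyperspectralCube", "default_axis"]


@dataclass(frozen=True)
class WavelengthAxis:
    """Strictly increasing band centres in nanometres (VNIR 400-1000 nm)."""

    centres: np.ndarray

    def __post_init__(self) -> None:
        centres = np.asarray(self.centres, dtype=float)
        if centres.ndim != 1 or centres.size < 2:
            raise ValueError("axis needs at least two band centres")
        if not np.all(np.diff(centres) > 0):
            raise ValueError("band centres must be strictly increasing")
        object.__setattr__(self, "centres", centres)

    @property
    def band_count(self) -> int:
        return self.centres.size

    def index_of(self, wavelength_nm: float) -> int:
        """Nearest band centre; ties go to the lower band."""
        d = np.abs(self.centres - float(wavelength_nm))
        # argmin returns the first (lower-wavelength) index on exact ties
        return int(np.argmin(d))

    def window(self, lo_nm: float, hi_nm: float) -> np.ndarray:
        """Indices of all bands with centre in [lo_nm, hi_nm]."""
        idx = np.nonzero((self.centres >= lo_nm) & (self.centres <= hi_nm))[0]
        return idx

    def contains(self, wavelength_nm: float) -> bool:
        return self.centres[0] <= wavelength_nm <= self.centres[-1]


def default_axis(step_nm: float = 2.0) -> WavelengthAxis:
    """VNIR axis emulating a 400-1000 nm pushbroom camera."""
    n = int(round((VNIR_MAX_NM - VNIR_MIN_NM) / step_nm)) + 1
    return WavelengthAxis(np.linspace(VNIR_MIN_NM, VNIR_MAX_NM, n))


@dataclass(frozen=True)
class Spectrum:
    """Reflectance values aligned to a :class:`WavelengthAxis`."""

    axis: WavelengthAxis
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.shape != (self.axis.band_count,):
            raise ValueError(
                f"spectrum length {values.shape} does not match axis "
                f"({self.axis.band_count} bands)"
            )
        object.__setattr__(self, "values", values)

    def at(self, wavelength_nm: float) -> float:
        return float(self.values[self.axis.index_of(wavelength_nm)])


@dataclass(frozen=True)
class HyperspectralCube:
    """rows (downcore) x cols (across-core) x bands reflectance cube."""

    axis: WavelengthAxis
    values: np.ndarray
    pixel_size_um: float = 80.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 3:
            raise ValueError("cube must be rows x cols x bands")
        if values.shape[2] != self.axis.band_count:
            raise ValueError("cube band dimension does not match axis")
        if self.pixel_size_um <= 0:
            raise ValueError("pixel_size_um must be positive")
        object.__setattr__(self, "values", values)

    @property
    def rows(self) -> int:
        return self.values.shape[0]

    @property
    def cols(self) -> int:
        return self.values.shape[1]

    @property
    def bands(self) -> int:
        return self.values.shape[2]

    def pixel(self, row: int, col: int) -> Spectrum:
        return Spectrum(self.axis, self.values[row, col])

    def mean_spectrum(self, mask: np.ndarray | None = None) -> Spectrum:
        if mask is None:
            return Spectrum(self.axis, self.values.mean(axis=(0, 1)))
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != (self.rows, self.cols):
            raise ValueError("mask shape must match cube rows x cols")
        if not mask.any():
            raise ValueError("mask selects no pixels")
        return Spectrum(self.axis, self.values[mask].mean(axis=0))
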