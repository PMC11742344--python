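"""Reflectance calibration and continuum removal.

Raw sensor counts are scaled to 0-1 reflectance against a white reference
(a BaSO4 panel approximating total reflectance) and a dark reference
(closed aperture, total absorbance).  Absorption features are then isolated
by continuum removal: the spectrum is divided by its upper convex hull,
fitted over the top of the spectrum with straight segments joining local
maxima, so that troughs become deviations below 1.
"""

from __future__ import annotations

import numpy as np

from .types import HyperspectralCube, Spectrum, WavelengthAxis

__all__ = [
    "calibrate_reflectance",
    "upper_hull",
    "continuum_hull",
    "continuum_removed",
    "DEFAULT_HULL_WINDOW",
]

#: Hull window (nm) used by default; avoids noisy edge bands of the VNIR range.
DEFAULT_HULL_WINDOW = (550.0, 850.0)


def calibrate_reflectance(
    raw: np.ndarray,
    white: np.ndarray,
    dark: np.ndarray,
    axis: WavelengthAxis,
    pixel_size_um: float = 80.0,
) -> HyperspectralCube:
    """Scale raw counts to 0-1 reflectance: R = (raw - dark)/(white - dark).

    Parameters
    ----------
    raw
        rows x cols x bands raw counts.
    white, dark
        Per-band reference frames; either 1-D ``(bands,)`` vectors or frames
        broadcastable against ``raw``.
    axis
        Wavelength axis shared by all three arrays.

    Values outside [0, 1] (sensor noise, specular overshoot) are clipped.
    """
    raw = np.asarray(raw, dtype=float)
    white = np.asarray(white, dtype=float)
    dark = np.asarray(dark, dtype=float)
    denom = white - dark
    bad = np.nonzero(~(denom > 0))
    if bad[0].size:
        band_axis = denom.ndim - 1
        bad_bands = np.unique(bad[band_axis])
        raise ValueError(
            "white reference does not exceed dark reference at band(s) "
            f"{bad_bands.tolist()} "
            f"({axis.centres[bad_bands].round(1).tolist()} nm)"
        )
    refl = (raw - dark) / denom
    np.clip(refl, 0.0, 1.0, out=refl)
    return HyperspectralCube(axis, refl, pixel_size_um=pixel_size_um)


def upper_hull(x: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Upper convex hull of (x, y) evaluated at every x.

    Monotone-chain over points sorted by x.  On reflectance ties the earlier
    (lower-wavelength) band is kept as the hull vertex.  Returns hull values
    with hull >= y everywhere and equality at the hull vertices.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 2:
        return y.copy()
    # monotone chain keeping only right turns (upper hull)
    stack: list[int] = []
    for i in range(n):
        while len(stack) >= 2:
            j, k = stack[-2], stack[-1]
            # cross product of (k - j) x (i - j); >= 0 means k is not above
            # the chord j->i, so k is dropped.  The >= keeps the earlier band
            # on collinear/tied runs.
            cross = (x[k] - x[j]) * (y[i] - y[j]) - (y[k] - y[j]) * (x[i] - x[j])
            if cross >= 0:
                stack.pop()
            else:
                break
        stack.append(i)
    verts = np.array(stack)
    return np.interp(x, x[verts], y[verts])


def continuum_hull(
    spectrum: Spectrum,
    window: tuple[float, float] = DEFAULT_HULL_WINDOW,
) -> Spectrum:
    """Upper convex hull of the spectrum inside ``window``.

    Outside the window the hull equals the spectrum, so continuum removal is
    a no-op there.
    """
    lo, hi = window
    if not (spectrum.axis.contains(lo) and spectrum.axis.contains(hi)):
        raise ValueError(f"hull window {window} nm lies outside the axis")
    idx = spectrum.axis.window(lo, hi)
    if idx.size < 3:
        raise ValueError("hull window must contain at least 3 bands")
    hull = spectrum.values.copy()
    hull[idx] = upper_hull(spectrum.axis.centres[idx], spectrum.values[idx])
    return Spectrum(spectrum.axis, hull)


def continuum_removed(
    spectrum: Spectrum,
    window: tuple[float, float] = DEFAULT_HULL_WINDOW,
) -> Spectrum:
    """Divide the spectrum by its continuum hull; troughs drop below 1.

    The continuum-removed trough depth at a band is ``1 - R/hull``.
    """
    idx = spectrum.axis.window(*window)
    if np.any(spectrum.values[idx] <= 0):
        raise ValueError("zero or negative reflectance inside the hull window")
    hull = continuum_hull(spectrum, window)
    # outside the window the hull equals the spectrum, so the ratio is 1
    out = np.ones_like(spectrum.values)
    out[idx] = spectrum.values[idx] / hull.values[idx]
    return Spectrum(spectrum.axis, out)
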