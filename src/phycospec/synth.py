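"""Synthetic spiking-experiment generator with known ground truth.

Emulates the measurement conditions of sediment-spiking experiments: a
smooth sediment background reflectance continuum per matrix class (organic,
clastic, dried certified reference material), Gaussian absorption troughs
at ~620 nm (phycocyanin), ~673 nm (chlorophyll a) and ~845 nm
(bacteriopheophytin a) whose depth responds linearly to spiked pigment mass
with matrix-specific sensitivity, i.i.d. Gaussian pixel noise, and
Beer-Lambert spectrophotometer absorbance series.

The reflectance model couples absorbance to reflectance through the
transmittance convention R = R_bg * 10^(-A), with

    A(lambda) = sum_p  sensitivity_p * visible_fraction * mass_p
                * exp(-(lambda - centre_p)^2 / (2 sigma_p^2)).

``visible_fraction`` represents the share of the spiked pigment remaining
optically visible at the sediment surface (mass infiltrating pore space is
invisible to the scanner); there is no measured value, so it defaults to 1.
All randomness flows from explicit seeds; no global random state is used.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.interpolate import PchipInterpolator

from .types import HyperspectralCube, Spectrum, WavelengthAxis, default_axis

__all__ = [
    "MatrixSpec",
    "SpikePlan",
    "GroundTruth",
    "TROUGH_CENTRES_NM",
    "TROUGH_SIGMAS_NM",
    "MATRIX_SPECS",
    "make_background",
    "apply_pigment_troughs",
    "simulate_spiking_cubes",
    "simulate_absorbance_series",
]

#: Absorption trough centres (nm): phycocyanin, chlorophyll a, bacteriopheophytin a.
TROUGH_CENTRES_NM = {"PC": 620.0, "ChlA": 673.0, "BpheA": 845.0}
#: Default Gaussian trough widths (nm).
TROUGH_SIGMAS_NM = {"PC": 12.0, "ChlA": 10.0, "BpheA": 15.0}

#: Chlorophyll a specific extinction coefficient in 100% acetone, l g^-1 cm^-1.
CHLA_EXTINCTION_ACETONE = 88.15


def _concave_knots(lo: float, hi: float, n: int = 9) -> tuple[tuple[float, float], ...]:
    """Knots sampled from a concave sqrt-shaped reflectance rise 400-1000 nm."""
    lam = np.linspace(400.0, 1000.0, n)
    refl = lo + (hi - lo) * np.sqrt((lam - 400.0) / 600.0)
    return tuple(zip(lam.tolist(), refl.tolist()))


@dataclass(frozen=True)
class MatrixSpec:
    """Synthetic sediment-matrix parameters.

    ``sensitivity_*`` are trough-absorbance units per microgram of spiked
    pigment; matrix classes differ in baseline brightness and sensitivity
    (the matrix effect).  ``noise_sd`` is per-pixel per-band reflectance
    noise.
    """

    name: str
    background_knots: tuple[tuple[float, float], ...]
    sensitivity_pc: float = 0.002
    sensitivity_chla: float = 0.0175
    sensitivity_bphe: float = 0.002
    trough_sigma_pc: float = TROUGH_SIGMAS_NM["PC"]
    trough_sigma_chla: float = TROUGH_SIGMAS_NM["ChlA"]
    trough_sigma_bphe: float = TROUGH_SIGMAS_NM["BpheA"]
    noise_sd: float = 0.01
    visible_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for _, r in self.background_knots:
            if not (0 < r <= 1):
                raise ValueError("background reflectance must lie in (0, 1]")
        if min(self.sensitivity_pc, self.sensitivity_chla, self.sensitivity_bphe) < 0:
            raise ValueError("sensitivities must be non-negative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not (0 <= self.visible_fraction <= 1):
            raise ValueError("visible_fraction must lie in [0, 1]")


#: Default matrix classes.  Organic sediment is dark with a clean, sensitive
#: phycocyanin response; wet clastic sediment is brighter with a damped
#: response; the dried, homogenized CRM is brightest with the steepest
#: response and the least pixel noise.
MATRIX_SPECS: dict[str, MatrixSpec] = {
    "organic": MatrixSpec(
        name="organic",
        background_knots=_concave_knots(0.12, 0.40),
        sensitivity_pc=0.002,
        sensitivity_chla=0.0175,
        noise_sd=0.010,
    ),
    "clastic": MatrixSpec(
        name="clastic",
        background_knots=_concave_knots(0.25, 0.60),
        sensitivity_pc=0.0008,
        sensitivity_chla=0.008,
        noise_sd=0.012,
    ),
    "crm": MatrixSpec(
        name="crm",
        background_knots=_concave_knots(0.35, 0.70),
        sensitivity_pc=0.003,
        sensitivity_chla=0.020,
        noise_sd=0.006,
    ),
}


@dataclass(frozen=True)
class SpikePlan:
    """Ordered cumulative pigment masses (ug) spiked onto one aliquot."""

    pigment: str
    masses_ug: tuple[float, ...]
    mixed_at_final_step: bool = False

    def __post_init__(self) -> None:
        if self.pigment not in TROUGH_CENTRES_NM:
            raise ValueError(f"unknown pigment {self.pigment!r}")
        m = np.asarray(self.masses_ug, dtype=float)
        if np.any(m < 0) or np.any(np.diff(m) < 0):
            raise ValueError("masses must be non-negative and non-decreasing")


@dataclass(frozen=True)
class GroundTruth:
    """Known truth for a simulated spiking series; reproducible from
    (MatrixSpec, SpikePlan, seed)."""

    matrix: str
    pigment: str
    masses_ug: tuple[float, ...]
    true_depths: tuple[float, ...]  # peak trough absorbance per step
    seed: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step": np.arange(len(self.masses_ug)),
                "pigment": self.pigment,
                "cumulative_mass_ug": self.masses_ug,
                "true_peak_absorbance": self.true_depths,
                "matrix": self.matrix,
                "seed": self.seed,
            }
        )


def make_background(spec: MatrixSpec, axis: WavelengthAxis | None = None) -> Spectrum:
    """Smooth monotone-interpolated background reflectance for one matrix.

    Shape-preserving (PCHIP) interpolation through the knots; no local
    absorption troughs are introduced.
    """
    if axis is None:
        axis = default_axis()
    knots = np.asarray(spec.background_knots, dtype=float)
    if knots.shape[0] < 2:
        raise ValueError("need at least 2 background knots")
    lam, refl = knots[:, 0], knots[:, 1]
    order = np.argsort(lam)
    lam, refl = lam[order], refl[order]
    if lam[0] > axis.centres[0] or lam[-1] < axis.centres[-1]:
        raise ValueError(
            f"background knots ({lam[0]:.0f}-{lam[-1]:.0f} nm) do not cover "
            f"the axis ({axis.centres[0]:.0f}-{axis.centres[-1]:.0f} nm)"
        )
    values = PchipInterpolator(lam, refl)(axis.centres)
    return Spectrum(axis, np.clip(values, 1e-12, 1.0))


def _total_absorbance(
    axis: WavelengthAxis,
    spec: MatrixSpec,
    pc_mass: float,
    chla_mass: float,
    bphe_mass: float,
) -> np.ndarray:
    lam = axis.centres
    a = np.zeros_like(lam)
    for mass, sens, sigma, centre in (
        (pc_mass, spec.sensitivity_pc, spec.trough_sigma_pc, TROUGH_CENTRES_NM["PC"]),
        (chla_mass, spec.sensitivity_chla, spec.trough_sigma_chla, TROUGH_CENTRES_NM["ChlA"]),
        (bphe_mass, spec.sensitivity_bphe, spec.trough_sigma_bphe, TROUGH_CENTRES_NM["BpheA"]),
    ):
        if mass:
            a += (
                sens
                * spec.visible_fraction
                * mass
                * np.exp(-((lam - centre) ** 2) / (2.0 * sigma**2))
            )
    return a


def apply_pigment_troughs(
    background: Spectrum,
    pc_mass: float = 0.0,
    chla_mass: float = 0.0,
    bphe_mass: float = 0.0,
    spec: MatrixSpec | None = None,
) -> Spectrum:
    """Superimpose Gaussian pigment troughs on a background spectrum.

    R(lambda) = background(lambda) * 10^(-A(lambda)); the output is clipped
    to (0, 1].  Zero masses return the background unchanged.
    """
    if min(pc_mass, chla_mass, bphe_mass) < 0:
        raise ValueError("pigment masses must be non-negative")
    if spec is None:
        spec = MATRIX_SPECS["organic"]
    a = _total_absorbance(background.axis, spec, pc_mass, chla_mass, bphe_mass)
    values = background.values * np.power(10.0, -a)
    return Spectrum(background.axis, np.clip(values, 1e-12, 1.0))


def simulate_spiking_cubes(
    spec: MatrixSpec,
    plan: SpikePlan,
    shape: tuple[int, int] = (16, 16),
    axis: WavelengthAxis | None = None,
    fixed_pc_mass: float = 0.0,
    seed: int | None = None,
) -> tuple[list[HyperspectralCube], GroundTruth]:
    """One calibrated cube per cumulative spike step, plus the ground truth.

    ``fixed_pc_mass`` holds a constant phycocyanin load across all steps
    (the chlorophyll-interference design: PC fixed while Chl a grows).
    Per-pixel i.i.d. Gaussian reflectance noise (sd = ``spec.noise_sd``) is
    added after trough application; identical seeds give identical cubes.
    """
    rows, cols = shape
    if rows < 4 or cols < 4:
        raise ValueError("cube shape must be at least 4x4")
    if axis is None:
        axis = default_axis()
    if seed is None:
        seed = spec.seed
    rng = np.random.default_rng(seed)
    background = make_background(spec, axis)
    cubes: list[HyperspectralCube] = []
    depths: list[float] = []
    for mass in plan.masses_ug:
        masses = {"PC": fixed_pc_mass, "ChlA": 0.0, "BpheA": 0.0}
        masses[plan.pigment] = masses.get(plan.pigment, 0.0) + mass
        spectrum = apply_pigment_troughs(
            background,
            pc_mass=masses["PC"],
            chla_mass=masses["ChlA"],
            bphe_mass=masses["BpheA"],
            spec=spec,
        )
        values = np.broadcast_to(
            spectrum.values, (rows, cols, axis.band_count)
        ).copy()
        if spec.noise_sd > 0:
            values += rng.normal(0.0, spec.noise_sd, size=values.shape)
        np.clip(values, 1e-12, 1.0, out=values)
        cubes.append(HyperspectralCube(axis, values))
        sens = {
            "PC": spec.sensitivity_pc,
            "ChlA": spec.sensitivity_chla,
            "BpheA": spec.sensitivity_bphe,
        }[plan.pigment]
        depths.append(sens * spec.visible_fraction * mass)
    truth = GroundTruth(
        matrix=spec.name,
        pigment=plan.pigment,
        masses_ug=tuple(float(m) for m in plan.masses_ug),
        true_depths=tuple(depths),
        seed=int(seed),
    )
    return cubes, truth


def simulate_absorbance_series(
    concentrations_ug_per_ml: np.ndarray,
    alpha: float = CHLA_EXTINCTION_ACETONE,
    path_cm: float = 1.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> np.ndarray:
    """Beer-Lambert spectrophotometer absorbance series A = alpha * L * c.

    Concentrations are in ug/ml (1 ug/ml = 1e-3 g/l); at ``noise_sd=0`` the
    series is the exact Beer-Lambert line.
    """
    c = np.asarray(concentrations_ug_per_ml, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentrations must be non-negative")
    a = alpha * path_cm * (c * 1e-3)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        a = a + rng.normal(0.0, noise_sd, size=a.shape)
    return a
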