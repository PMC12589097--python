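"""Density-to-material-property laws for cortical and trabecular bone.

Converts radiological (QCT-equivalent) volumetric densities into ash and
apparent densities, and from those into elastic moduli and compressive /
tensile yield stresses via compartment-specific power laws:

* trabecular  ``E = 0.003715 * rho_app^1.96``  (rho_app in kg/m^3, E in MPa)
* cortical    ``E = 10200 * rho_ash^2.01``     (rho_ash in g/cm^3, E in MPa)
* trabecular  ``sigma_yc = 38.5 * rho_app^1.48``, ``sigma_yt = 22.6 * rho_app^1.26``
  (rho_app in g/cm^3, stresses in MPa)
* cortical    ``sigma_yc = -0.41 + 0.0062 * E``, ``sigma_yt = 0.33 + 0.0039 * E``

The cortical compressive law admits two sign readings of its leading
coefficient; the default keeps the minus sign together with a positivity
floor, the alternative ``+0.41`` reading is selectable via
:class:`MaterialConfig`.  The trabecular elasticity law takes the apparent
density in kg/m^3 while the trabecular yield laws take it in g/cm^3; both
conversions are explicit here, never implicit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "TissueCompartment",
    "DensitySample",
    "MaterialPoint",
    "MaterialConfig",
    "ash_density",
    "apparent_density",
    "elastic_modulus",
    "yield_stresses",
    "material_point",
    "map_density_field",
    "materials_table",
]

ASH_SLOPE = 0.87
ASH_INTERCEPT = 0.079
ASH_APP_RATIO_DEFAULT = 0.6
ASH_APP_RATIO_RANGE = (0.55, 0.63)
POISSON_RATIO = 0.3


class TissueCompartment(str, Enum):
    """Bone tissue compartment of a mesh element."""

    CORTICAL = "cortical"
    TRABECULAR = "trabecular"


@dataclass(frozen=True)
class DensitySample:
    """Consistent triple of radiological, ash and apparent density (g/cm^3)."""

    rho_qct: float
    rho_ash: float
    rho_app: float

    @property
    def rho_app_kgm3(self) -> float:
        """Apparent density in kg/m^3 (1 g/cm^3 = 1000 kg/m^3)."""
        return self.rho_app * 1000.0

    @classmethod
    def from_qct(cls, rho_qct: float, ash_app_ratio: float = ASH_APP_RATIO_DEFAULT) -> "DensitySample":
        rho_ash = ash_density(rho_qct)
        rho_app = apparent_density(rho_ash, ash_app_ratio)
        return cls(rho_qct=float(rho_qct), rho_ash=float(rho_ash), rho_app=float(rho_app))


@dataclass(frozen=True)
class MaterialPoint:
    """Elastic and yield properties at one integration point (MPa)."""

    E: float
    sigma_yc: float
    sigma_yt: float
    nu: float = POISSON_RATIO

    def __post_init__(self) -> None:
        if self.E < 0:
            raise ValueError(f"negative elastic modulus {self.E}")
        if self.sigma_yc <= 0 or self.sigma_yt <= 0:
            raise ValueError("yield stresses must be positive")


@dataclass
class MaterialConfig:
    """Tunables of the density-to-property mapping.

    ``cortical_yc_sign``: reading of the cortical compressive-yield
    intercept, ``"minus"`` (default, with positivity floor) or ``"plus"``.
    ``yield_floor``: lower clamp for any computed yield stress, MPa.
    ``interpolation``: density sampling locus, ``"centroid"`` or ``"gauss"``.
    ``density_units``: units of the incoming density image; ``"mg/cm3"``
    (the volumetric-BMD convention) is divided by 1000 before the ash
    conversion, ``"g/cm3"`` is taken as is.
    """

    ash_app_ratio: float = ASH_APP_RATIO_DEFAULT
    cortical_yc_sign: str = "minus"
    yield_floor: float = 0.01
    interpolation: str = "centroid"
    density_units: str = "mg/cm3"

    def __post_init__(self) -> None:
        if self.ash_app_ratio <= 0:
            raise ValueError("ash/apparent ratio must be positive")
        lo, hi = ASH_APP_RATIO_RANGE
        if not lo <= self.ash_app_ratio <= hi:
            warnings.warn(
                f"ash/apparent ratio {self.ash_app_ratio} outside the reported "
                f"physiological range [{lo}, {hi}]",
                stacklevel=2,
            )
        if self.cortical_yc_sign not in ("minus", "plus"):
            raise ValueError("cortical_yc_sign must be 'minus' or 'plus'")
        if self.interpolation not in ("centroid", "gauss"):
            raise ValueError("interpolation must be 'centroid' or 'gauss'")
        if self.density_units not in ("mg/cm3", "g/cm3"):
            raise ValueError("density_units must be 'mg/cm3' or 'g/cm3'")

    def to_gcm3(self, rho):
        return np.asarray(rho, dtype=float) / 1000.0 if self.density_units == "mg/cm3" else np.asarray(rho, dtype=float)


def ash_density(rho_qct):
    """Ash density (g/cm^3) from radiological density (g/cm^3)."""
    rho_qct = np.asarray(rho_qct, dtype=float)
    if np.any(rho_qct < 0):
        raise ValueError("radiological density must be non-negative")
    out = ASH_SLOPE * rho_qct + ASH_INTERCEPT
    return float(out) if out.ndim == 0 else out


def apparent_density(rho_ash, ash_app_ratio: float = ASH_APP_RATIO_DEFAULT):
    """Apparent density (g/cm^3) from ash density via the ash/apparent ratio."""
    rho_ash = np.asarray(rho_ash, dtype=float)
    if np.any(rho_ash < 0):
        raise ValueError("ash density must be non-negative")
    if ash_app_ratio <= 0:
        raise ValueError("ash/apparent ratio must be positive")
    lo, hi = ASH_APP_RATIO_RANGE
    if not lo <= ash_app_ratio <= hi:
        warnings.warn(
            f"ash/apparent ratio {ash_app_ratio} outside [{lo}, {hi}]", stacklevel=2
        )
    out = rho_ash / ash_app_ratio
    return float(out) if out.ndim == 0 else out


def elastic_modulus(sample: DensitySample, compartment: TissueCompartment) -> float:
    """Elastic modulus in MPa from the compartment-specific power law."""
    compartment = TissueCompartment(compartment)
    if compartment is TissueCompartment.TRABECULAR:
        rho = sample.rho_app_kgm3
        if 0.0 < rho < 10.0:
            raise ValueError(
                f"trabecular apparent density {rho} kg/m^3 is implausibly small; "
                "a g/cm^3 value was probably passed where kg/m^3 is expected"
            )
        return 0.003715 * rho**1.96
    return 10200.0 * sample.rho_ash**2.01


def yield_stresses(
    sample: DensitySample,
    compartment: TissueCompartment,
    E: float,
    config: MaterialConfig | None = None,
) -> tuple[float, float]:
    """Compressive and tensile yield stress (MPa) for one material point."""
    config = config or MaterialConfig()
    compartment = TissueCompartment(compartment)
    if compartment is TissueCompartment.TRABECULAR:
        rho = sample.rho_app  # g/cm^3 in the trabecular yield laws
        syc = 38.5 * rho**1.48
        syt = 22.6 * rho**1.26
    else:
        if E < 0:
            raise ValueError("cortical yield laws need a non-negative modulus")
        intercept = -0.41 if config.cortical_yc_sign == "minus" else 0.41
        syc = intercept + 0.0062 * E
        syt = 0.33 + 0.0039 * E
    floor = config.yield_floor
    if syc < floor or syt < floor:
        warnings.warn(
            f"{compartment.value} yield stress below {floor} MPa clamped", stacklevel=2
        )
    return max(syc, floor), max(syt, floor)


def material_point(
    rho_qct: float,
    compartment: TissueCompartment,
    config: MaterialConfig | None = None,
) -> MaterialPoint:
    """Full density -> MaterialPoint chain for a single radiological density."""
    config = config or MaterialConfig()
    sample = DensitySample.from_qct(rho_qct, config.ash_app_ratio)
    E = elastic_modulus(sample, compartment)
    syc, syt = yield_stresses(sample, compartment, E, config)
    if E <= 0.0:
        # zero-density element: keep a vanishing but solvable stiffness
        E = 1e-6
    return MaterialPoint(E=E, sigma_yc=syc, sigma_yt=syt)


def map_density_field(mesh, density_image, config: MaterialConfig | None = None):
    """Map a density image onto mesh elements as one MaterialPoint each.

    ``density_image`` is either a per-node scalar array (interpolated with
    the element's trilinear shape functions) or an object with a
    ``probe(points)`` method (e.g. :class:`femofall.mesh.GridDensityImage`).
    Sampling locus is the element centroid by default, or the mean over the
    2x2x2 Gauss points with ``config.interpolation == "gauss"``.
    """
    config = config or MaterialConfig()
    pts = _sample_points(mesh, config.interpolation)  # (n_elem, n_loc, 3)
    if hasattr(density_image, "probe"):
        flat = pts.reshape(-1, 3)
        try:
            rho = density_image.probe(flat).reshape(pts.shape[:2])
        except ValueError as exc:
            raise ValueError(f"density image probe failed: {exc}") from exc
        bad = ~np.all(np.isfinite(rho), axis=1)
        if np.any(bad):
            raise ValueError(
                f"element {int(np.flatnonzero(bad)[0])} lies outside the density-image domain"
            )
    else:
        values = np.asarray(density_image, dtype=float)
        if values.shape != (len(mesh.nodes),):
            raise ValueError(
                "per-node density field must have one value per mesh node"
            )
        # trilinear shape-function interpolation == mean of nodal values at
        # the centroid; at Gauss points use the exact shape functions
        from ._hex8 import shape_functions

        loc = _natural_points(config.interpolation)
        N = shape_functions(loc)  # (n_loc, 8)
        rho = np.einsum("la,ea->el", N, values[mesh.elements])
    rho_gcm3 = config.to_gcm3(rho.mean(axis=1))
    return [
        material_point(r, c, config)
        for r, c in zip(rho_gcm3, mesh.compartment)
    ]


def materials_table(mesh, density_image, config: MaterialConfig | None = None) -> pd.DataFrame:
    """Per-element material table (CSV-exportable)."""
    config = config or MaterialConfig()
    points = map_density_field(mesh, density_image, config)
    rows = []
    pts = _sample_points(mesh, config.interpolation)
    if hasattr(density_image, "probe"):
        rho = density_image.probe(pts.reshape(-1, 3)).reshape(pts.shape[:2]).mean(axis=1)
    else:
        from ._hex8 import shape_functions

        N = shape_functions(_natural_points(config.interpolation))
        rho = np.einsum("la,ea->el", N, np.asarray(density_image, float)[mesh.elements]).mean(axis=1)
    rho = config.to_gcm3(rho)
    for eid, (mp, comp, r) in enumerate(zip(points, mesh.compartment, rho)):
        s = DensitySample.from_qct(r, config.ash_app_ratio)
        rows.append(
            dict(
                element_id=eid,
                compartment=TissueCompartment(comp).value,
                rho_qct=s.rho_qct,
                rho_ash=s.rho_ash,
                rho_app=s.rho_app,
                E=mp.E,
                sigma_yc=mp.sigma_yc,
                sigma_yt=mp.sigma_yt,
            )
        )
    return pd.DataFrame(rows)


def _natural_points(interpolation: str) -> np.ndarray:
    if interpolation == "centroid":
        return np.zeros((1, 3))
    from ._hex8 import GAUSS_POINTS

    return GAUSS_POINTS


def _sample_points(mesh, interpolation: str) -> np.ndarray:
    from ._hex8 import shape_functions

    loc = _natural_points(interpolation)
    N = shape_functions(loc)  # (n_loc, 8)
    return np.einsum("la,eaj->elj", N, mesh.nodes[mesh.elements])
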