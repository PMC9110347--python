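"""Theoretical spatial resolving power from cone density and lens size.

For a teleost eye the posterior nodal distance (PND) is approximated as
lens radius × Matthiessen's ratio (2.55). Given the photoreceptor cell
density D (cells·mm⁻², each double cone counting as two cells and each
triple cone as three), the Nyquist frequency of the sampling array is

    f_N = (π · PND / 360°) · (2 · D / √3)^(1/2)   [cycles per degree]

and the minimum resolvable angle is its inverse, θ = 1/f_N (degrees).
The distance at which a target of size s subtends exactly θ — the range
at which the retina could just detect, say, a 0.5 mm food item — is
d = (s/2) / tan(θ/2).
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from .datatypes import CELLS_PER_UNIT, ConeField

__all__ = [
    "AcuityResult",
    "cone_cell_density",
    "posterior_nodal_distance",
    "nyquist_frequency",
    "min_resolvable_angle",
    "detection_distance",
    "acuity_from_density",
    "acuity_from_field",
]

MATTHIESSEN_RATIO = 2.55  # mean for teleost eyes
DEFAULT_TARGET_SIZE_MM = 0.5


@dataclass(frozen=True)
class AcuityResult:
    pnd_mm: float
    nyquist_cpd: float  # cycles per degree
    min_angle_deg: float
    detection_distance_mm: float
    density_mm2: float
    target_size_mm: float


def cone_cell_density(field: ConeField) -> float:
    """Photoreceptor cell density (cells·mm⁻²) of a field.

    Each cone unit contributes its constituent cell count: one for a
    single cone, two for a double, three for a triple.
    """
    counts = field.class_counts()
    cells = sum(CELLS_PER_UNIT[c] * n for c, n in counts.items())
    return cells / field.window.area_mm2


def posterior_nodal_distance(lens_radius_mm: float,
                             matthiessen: float = MATTHIESSEN_RATIO) -> float:
    """PND (mm) = lens radius × Matthiessen's ratio."""
    if lens_radius_mm <= 0 or matthiessen <= 0:
        raise ValueError("lens radius and Matthiessen's ratio must be positive")
    return lens_radius_mm * matthiessen


def nyquist_frequency(density_mm2: float, pnd_mm: float) -> float:
    """Nyquist frequency (cycles·degree⁻¹) of a hexagonal sampling array."""
    if density_mm2 <= 0 or pnd_mm <= 0:
        raise ValueError("density and PND must be positive")
    return (math.pi * pnd_mm / 360.0) * math.sqrt(2.0 * density_mm2 / math.sqrt(3.0))


def min_resolvable_angle(nyquist_cpd: float) -> float:
    """Minimum resolvable angle (degrees) = 1 / f_N."""
    if nyquist_cpd <= 0:
        raise ValueError("Nyquist frequency must be positive")
    return 1.0 / nyquist_cpd


def detection_distance(theta_deg: float,
                       target_size_mm: float = DEFAULT_TARGET_SIZE_MM) -> float:
    """Distance (mm) at which a target subtends exactly theta degrees."""
    if not 0.0 < theta_deg < 180.0:
        raise ValueError("theta must lie strictly between 0 and 180 degrees")
    if target_size_mm <= 0:
        raise ValueError("target size must be positive")
    return (target_size_mm / 2.0) / math.tan(math.radians(theta_deg) / 2.0)


def acuity_from_density(density_mm2: float, lens_radius_mm: float,
                        matthiessen: float = MATTHIESSEN_RATIO,
                        target_size_mm: float = DEFAULT_TARGET_SIZE_MM) -> AcuityResult:
    """Full acuity chain from a cell density and lens radius."""
    pnd = posterior_nodal_distance(lens_radius_mm, matthiessen)
    fn = nyquist_frequency(density_mm2, pnd)
    theta = min_resolvable_angle(fn)
    dist = detection_distance(theta, target_size_mm)
    return AcuityResult(pnd, fn, theta, dist, density_mm2, target_size_mm)


def acuity_from_field(field: ConeField, lens_radius_mm: float,
                      matthiessen: float = MATTHIESSEN_RATIO,
                      target_size_mm: float = DEFAULT_TARGET_SIZE_MM) -> AcuityResult:
    """Full acuity chain from a cone field's cell density."""
    return acuity_from_density(cone_cell_density(field), lens_radius_mm,
                               matthiessen, target_size_mm)
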