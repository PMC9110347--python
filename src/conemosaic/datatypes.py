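"""Core containers: labelled cone point patterns and absorbance spectra.

Coordinates are continuous 2-D Cartesian positions in micrometres with the
origin at the lower-left corner of the sampling window (no pixelation).
Cone units are represented by a single centroid each: a double cone (two
fused cells) and a triple cone (three fused cells) are one labelled point.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

__all__ = [
    "CONE_CLASSES",
    "CELLS_PER_UNIT",
    "Window",
    "ConeField",
    "SomaSizes",
    "Spectrum",
    "SpectrumSpec",
    "PigmentTemplate",
]

#: Morphological cone unit classes.
CONE_CLASSES = ("single", "double", "triple")

#: Number of individual cone cells contributed by one unit of each class
#: (a double cone is two fused cells, a triple cone three).
CELLS_PER_UNIT = {"single": 1, "double": 2, "triple": 3}


@dataclass(frozen=True)
class Window:
    """Rectangular sampling window (µm), origin at (0, 0)."""

    width: float = 52.0
    height: float = 52.0

    def __post_init__(self) -> None:
        if not (self.width > 0 and self.height > 0):
            raise ValueError("window dimensions must be strictly positive")

    @property
    def area_um2(self) -> float:
        return self.width * self.height

    @property
    def area_mm2(self) -> float:
        return self.area_um2 * 1e-6

    def contains(self, points: np.ndarray, tol: float = 1e-9) -> np.ndarray:
        """Boolean mask of points inside the window (closed, with tolerance)."""
        pts = np.asarray(points, dtype=float).reshape(-1, 2)
        return (
            (pts[:, 0] >= -tol)
            & (pts[:, 0] <= self.width + tol)
            & (pts[:, 1] >= -tol)
            & (pts[:, 1] <= self.height + tol)
        )


@dataclass
class ConeField:
    """A labelled planar point pattern of cone centroids in a window.

    Parameters
    ----------
    points
        ``(n, 2)`` array of centroid coordinates in µm.
    labels
        Length-``n`` array of class labels from :data:`CONE_CLASSES`.
    window
        Rectangular sampling window; every point must lie inside it.
    meta
        Free-form tags (region, developmental stage, generator parameters).
    """

    points: np.ndarray
    labels: np.ndarray
    window: Window
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float).reshape(-1, 2)
        labels = np.asarray(self.labels, dtype=object)
        if labels.shape != (pts.shape[0],):
            raise ValueError(
                f"labels length {labels.shape} does not match {pts.shape[0]} points"
            )
        bad = set(labels.tolist()) - set(CONE_CLASSES)
        if bad:
            raise ValueError(f"unknown cone class labels: {sorted(bad)}")
        inside = self.window.contains(pts)
        if not inside.all():
            i = int(np.flatnonzero(~inside)[0])
            raise ValueError(
                f"point {i} at {tuple(pts[i])} lies outside the "
                f"{self.window.width} x {self.window.height} µm window"
            )
        self.points = pts
        self.labels = labels

    @property
    def n(self) -> int:
        return self.points.shape[0]

    def class_counts(self) -> dict[str, int]:
        return {c: int(np.sum(self.labels == c)) for c in CONE_CLASSES}

    def points_of(self, cone_class: str) -> np.ndarray:
        """Coordinates of one class, or of all points for ``"all"``."""
        if cone_class == "all":
            return self.points
        if cone_class not in CONE_CLASSES:
            raise ValueError(f"unknown cone class {cone_class!r}")
        return self.points[self.labels == cone_class]

    def min_pairwise_distance(self) -> float:
        """Smallest inter-centroid distance (inf for < 2 points)."""
        if self.n < 2:
            return float("inf")
        from scipy.spatial.distance import pdist

        return float(pdist(self.points).min())


@dataclass(frozen=True)
class SomaSizes:
    """Cone soma dimensions (µm) used as hard-core contact distances.

    Defaults are the measured mean single-cone diameter, double-cone short
    axis, and triple-cone median dimension of metamorphosing Atlantic
    halibut cones.
    """

    single: float = 2.2
    double: float = 3.0
    triple: float = 4.1

    def __post_init__(self) -> None:
        if not (self.single > 0 and self.double > 0 and self.triple > 0):
            raise ValueError("soma sizes must be strictly positive")

    def of(self, cone_class: str) -> float:
        return {"single": self.single, "double": self.double, "triple": self.triple}[
            cone_class
        ]

    def hardcore(self, class_a: str, class_b: str) -> float:
        """Cross-class minimum centre distance: the larger of the two somas."""
        return max(self.of(class_a), self.of(class_b))


@dataclass
class Spectrum:
    """An absorbance spectrum: wavelength (nm) versus absorbance."""

    wavelengths: np.ndarray
    absorbance: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelengths, dtype=float).ravel()
        ab = np.asarray(self.absorbance, dtype=float).ravel()
        if wl.size != ab.size:
            raise ValueError("wavelength and absorbance arrays differ in length")
        if wl.size < 2:
            raise ValueError("a spectrum needs at least two samples")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly ascending")
        self.wavelengths = wl
        self.absorbance = ab

    @property
    def step(self) -> float:
        return float(self.wavelengths[1] - self.wavelengths[0])

    @property
    def is_uniform(self) -> bool:
        d = np.diff(self.wavelengths)
        return bool(np.allclose(d, d[0], rtol=1e-8, atol=1e-9))


@dataclass(frozen=True)
class SpectrumSpec:
    """Forward-model specification for a synthetic pigment-mixture spectrum.

    The response is ``R(λ) = [Σ_i k_i A_i^p(λ)]^(1/p)`` over A1 templates
    ``A_i`` parameterized by their λ_max, plus additive Gaussian noise.
    """

    lambda_max_list: tuple[float, ...]
    k_list: tuple[float, ...]
    p: float = 1.0
    noise_sd: float = 0.0
    grid: tuple[float, float, float] = (350.0, 750.0, 2.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.lambda_max_list) == 0:
            raise ValueError("at least one pigment is required")
        if len(self.lambda_max_list) != len(self.k_list):
            raise ValueError("lambda_max_list and k_list must have equal length")
        if not self.p > 0:
            raise ValueError("exponent p must be positive")
        start, stop, step = self.grid
        if not step > 0 or stop <= start:
            raise ValueError("grid must be (start, stop, step) with step > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")

    def wavelength_grid(self) -> np.ndarray:
        start, stop, step = self.grid
        n = int(np.floor((stop - start) / step + 1e-9)) + 1
        return start + step * np.arange(n)


@dataclass
class PigmentTemplate:
    """A1 visual-pigment absorbance template, unit peak at λ_max.

    Carries both the α-band (main) and β-band (secondary short-wavelength)
    components summed, evaluated on a wavelength grid.
    """

    lambda_max: float
    wavelengths: np.ndarray
    values: np.ndarray
    chromophore: str = "A1"

    def __post_init__(self) -> None:
        self.wavelengths = np.asarray(self.wavelengths, dtype=float).ravel()
        self.values = np.asarray(self.values, dtype=float).ravel()
        if self.wavelengths.size != self.values.size:
            raise ValueError("grid and values differ in length")
        if np.any(self.values < -1e-12):
            raise ValueError("template absorbance must be non-negative")


def as_counts(density_per_class: Mapping[str, float], window: Window) -> dict[str, int]:
    """Convert per-class densities (cells·mm⁻²) to integer unit counts."""
    return {
        c: int(round(d * window.area_mm2)) for c, d in density_per_class.items()
    }
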