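"""Synthetic cone mosaics and absorbance spectra.

Generators emulate the mosaic geometries seen in metamorphosing flatfish
retinas — the larval honeycomb (hexagonal) lattice of single cones, the
adult square mosaic of four double cones around a centre single cone, and
the random mixed single/double/triple arrangement of the dorsotemporal
retina — together with noisy visual-pigment mixture spectra, so that every
downstream analysis is testable without digitized micrographs.

All generators are deterministic given their seed. Lattice jitter is an
isotropic Gaussian displacement applied after lattice construction and
re-drawn whenever it would push a point out of the window. Random fields
use sequential placement with rejection (random sequential adsorption): a
candidate of class *c* is accepted only if its distance to every placed
point is at least the larger of the two classes' soma sizes.
"""
from __future__ import annotations

from typing import Mapping

import numpy as np
from scipy.spatial import cKDTree

from .datatypes import (
    CONE_CLASSES,
    ConeField,
    SomaSizes,
    Spectrum,
    SpectrumSpec,
    Window,
)
from .errors import DegenerateFieldError, PackingError

__all__ = [
    "gen_honeycomb",
    "gen_square_mosaic",
    "gen_hardcore_random",
    "gen_mixed_triple_field",
    "gen_spectrum",
]


def _as_window(window) -> Window:
    if isinstance(window, Window):
        return window
    w, h = window
    return Window(float(w), float(h))


def _jitter(points: np.ndarray, jitter_sd: float, window: Window,
            rng: np.random.Generator, max_redraws: int = 1000) -> np.ndarray:
    """Displace each point by isotropic Gaussian noise, re-drawing any
    displacement that would leave the window. Sequential per point, so the
    output is reproducible for a given generator state."""
    if jitter_sd == 0:
        return points.copy()
    out = np.empty_like(points)
    for i, (x, y) in enumerate(points):
        for _ in range(max_redraws):
            dx, dy = rng.normal(0.0, jitter_sd, size=2)
            nx, ny = x + dx, y + dy
            if 0.0 <= nx <= window.width and 0.0 <= ny <= window.height:
                out[i] = (nx, ny)
                break
        else:  # pragma: no cover - essentially unreachable for sane jitter
            out[i] = (x, y)
    return out


def gen_honeycomb(spacing: float, window=Window(), jitter_sd: float = 0.0,
                  seed: int = 0) -> ConeField:
    """Triangular (hexagonal-packing) lattice of single cones.

    Emulates the larval honeycomb mosaic in which six neighbouring cones
    flank each single cone.

    Parameters
    ----------
    spacing
        Lattice constant (nearest-neighbour distance), µm.
    jitter_sd
        SD of the isotropic Gaussian positional jitter, µm.
    """
    window = _as_window(window)
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    row_height = spacing * np.sqrt(3.0) / 2.0
    n_rows = int(np.floor(window.height / row_height)) + 1
    n_cols = int(np.floor(window.width / spacing)) + 1
    if n_rows < 2 or n_cols < 2:
        raise DegenerateFieldError(
            f"spacing {spacing} µm does not fit at least two lattice rows and "
            f"columns in a {window.width} x {window.height} µm window"
        )
    pts = []
    for r in range(n_rows):
        y = r * row_height
        x0 = (spacing / 2.0) if (r % 2) else 0.0
        for c in range(n_cols + 1):
            x = x0 + c * spacing
            if x <= window.width:
                pts.append((x, y))
    points = np.asarray(pts, dtype=float)
    rng = np.random.default_rng(seed)
    points = _jitter(points, jitter_sd, window, rng)
    labels = np.asarray(["single"] * len(points), dtype=object)
    meta = {"generator": "honeycomb", "spacing_um": spacing,
            "jitter_sd_um": jitter_sd, "seed": seed}
    return ConeField(points, labels, window, meta)


def gen_square_mosaic(unit_spacing: float, window=Window(), jitter_sd: float = 0.0,
                      seed: int = 0) -> ConeField:
    """Square mosaic: centre single cones surrounded by four double cones.

    Single cones sit on a square lattice of pitch ``unit_spacing``; double
    cones occupy the two edge-midpoint positions of each unit cell, giving
    a double:single ratio of 2 in the window interior. Corner positions
    (cell centres of the fine lattice) are left empty, as single corner
    cones are absent or extremely rare in these mosaics.
    """
    window = _as_window(window)
    if unit_spacing <= 0:
        raise ValueError("unit_spacing must be positive")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be non-negative")
    a = unit_spacing
    n_cols = int(np.floor(window.width / a)) + 1
    n_rows = int(np.floor(window.height / a)) + 1
    if n_rows < 2 or n_cols < 2:
        raise DegenerateFieldError(
            f"unit spacing {a} µm does not fit at least one full mosaic unit "
            f"in a {window.width} x {window.height} µm window"
        )
    singles, doubles = [], []
    half = a / 2.0
    for i in range(n_cols):
        for j in range(n_rows):
            x, y = i * a, j * a
            singles.append((x, y))
            if x + half <= window.width:
                doubles.append((x + half, y))
            if y + half <= window.height:
                doubles.append((x, y + half))
    points = np.asarray(singles + doubles, dtype=float)
    labels = np.asarray(
        ["single"] * len(singles) + ["double"] * len(doubles), dtype=object
    )
    rng = np.random.default_rng(seed)
    points = _jitter(points, jitter_sd, window, rng)
    meta = {"generator": "square_mosaic", "unit_spacing_um": unit_spacing,
            "jitter_sd_um": jitter_sd, "seed": seed}
    return ConeField(points, labels, window, meta)


def gen_hardcore_random(density_per_class: Mapping[str, float],
                        soma: SomaSizes = SomaSizes(), window=Window(),
                        seed: int = 0, max_attempts: int = 10_000,
                        _counts: Mapping[str, int] | None = None) -> ConeField:
    """Soma-size-constrained random field (random sequential adsorption).

    ``density_per_class`` maps cone class to intended density in cells·mm⁻²
    (converted internally to unit counts for the window); exact counts are
    achieved. A candidate point of class *c* is accepted only if its
    distance to every already-placed point is at least the larger of the
    two classes' soma sizes. Placement order interleaves classes in a
    seed-determined random sequence.

    Raises
    ------
    PackingError
        If a point cannot be placed after ``max_attempts`` consecutive
        rejections (over-dense request), naming the failing class.
    """
    window = _as_window(window)
    if max_attempts < 1:
        raise ValueError("max_attempts must be >= 1")
    if _counts is not None:
        counts = {c: int(n) for c, n in _counts.items()}
    else:
        counts = {
            c: int(round(d * window.area_mm2))
            for c, d in density_per_class.items()
        }
    for c in counts:
        if c not in CONE_CLASSES:
            raise ValueError(f"unknown cone class {c!r}")
        if counts[c] < 0:
            raise ValueError("counts must be non-negative")
    # quick infeasibility bound: each unit excludes a disc of radius soma/2
    occupied = sum(n * np.pi * (soma.of(c) / 2.0) ** 2 for c, n in counts.items())
    if occupied > window.area_um2:
        worst = max(counts, key=lambda c: counts[c] * soma.of(c))
        raise PackingError(
            worst, 0, sum(counts.values()), 0,
            message=(
                f"requested packing is infeasible: soma discs would occupy "
                f"{occupied:.0f} µm² in a {window.area_um2:.0f} µm² window "
                f"(dominant class {worst!r})"
            ),
        )
    rng = np.random.default_rng(seed)
    sequence = np.asarray(
        [c for c in CONE_CLASSES for _ in range(counts.get(c, 0))], dtype=object
    )
    rng.shuffle(sequence)
    placed_pts: list[tuple[float, float]] = []
    placed_cls: list[str] = []
    for cls in sequence:
        radius_by_cls = {c: soma.hardcore(cls, c) for c in CONE_CLASSES}
        for attempt in range(max_attempts):
            x = rng.uniform(0.0, window.width)
            y = rng.uniform(0.0, window.height)
            ok = True
            for (px, py), pc in zip(placed_pts, placed_cls):
                r = radius_by_cls[pc]
                if (px - x) ** 2 + (py - y) ** 2 < r * r:
                    ok = False
                    break
            if ok:
                placed_pts.append((x, y))
                placed_cls.append(cls)
                break
        else:
            n_cls = placed_cls.count(cls)
            raise PackingError(cls, n_cls, counts[cls], max_attempts)
    points = np.asarray(placed_pts, dtype=float).reshape(-1, 2)
    labels = np.asarray(placed_cls, dtype=object)
    meta = {"generator": "hardcore_random", "counts": counts,
            "soma_um": {"single": soma.single, "double": soma.double,
                        "triple": soma.triple},
            "seed": seed}
    return ConeField(points, labels, window, meta)


def gen_mixed_triple_field(counts: Mapping[str, int],
                           soma: SomaSizes = SomaSizes(), window=Window(),
                           seed: int = 0, max_attempts: int = 10_000) -> ConeField:
    """Random mixed mosaic with exact class counts.

    Convenience wrapper over :func:`gen_hardcore_random` emulating the
    dorsotemporal mixed single/double/triple region, where all three cone
    types are distributed randomly subject to soma-size exclusion.
    """
    return gen_hardcore_random({}, soma=soma, window=window, seed=seed,
                               max_attempts=max_attempts, _counts=counts)


def gen_spectrum(spec: SpectrumSpec) -> Spectrum:
    """Synthesize a pigment-mixture absorbance spectrum.

    The noiseless curve is the mixture response
    ``R(λ) = [Σ_i k_i A_i^p(λ)]^(1/p)`` over A1 templates; Gaussian noise of
    SD ``spec.noise_sd`` is then added independently per wavelength.
    """
    from .spectra import mixture_response

    grid = spec.wavelength_grid()
    clean = mixture_response(spec.k_list, spec.p, spec.lambda_max_list, grid)
    rng = np.random.default_rng(spec.seed)
    noisy = clean.absorbance + rng.normal(0.0, spec.noise_sd, size=grid.size)
    meta = {"generator": "mixture", "lambda_max": list(spec.lambda_max_list),
            "k": list(spec.k_list), "p": spec.p, "noise_sd": spec.noise_sd,
            "seed": spec.seed}
    return Spectrum(grid, noisy, meta)


def min_same_class_distance(field: ConeField) -> float:
    """Smallest distance between any two points (hard-core check helper)."""
    if field.n < 2:
        return float("inf")
    tree = cKDTree(field.points)
    d, _ = tree.query(field.points, k=2)
    return float(d[:, 1].min())
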