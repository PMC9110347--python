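"""Readers and writers for centroid fields and absorbance spectra.

Centroid files are CSV with header ``x_um,y_um,cone_class`` preceded by
comment lines carrying the window and free-form metadata::

    # window_um=52.0,52.0
    # region=centrodorsotemporal
    x_um,y_um,cone_class
    3.1,4.7,single
    ...

Spectrum files are CSV with header ``wavelength_nm,absorbance``.
"""
from __future__ import annotations

import io as _io
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import CONE_CLASSES, ConeField, Spectrum, Window

__all__ = [
    "read_cone_field",
    "write_cone_field",
    "read_spectrum",
    "write_spectrum",
]


def _parse_comments(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta


def read_cone_field(path) -> ConeField:
    """Read and validate a centroid CSV into a :class:`ConeField`.

    Errors name the offending data row (1-based, excluding comments and
    header) for missing columns, non-numeric coordinates, unknown labels,
    and out-of-window points.
    """
    path = Path(path)
    meta = _parse_comments(path)
    if "window_um" not in meta:
        raise ValueError(f"{path}: missing '# window_um=w,h' header comment")
    try:
        w, h = (float(v) for v in meta.pop("window_um").split(","))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed window_um comment") from exc
    window = Window(w, h)
    df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    required = ["x_um", "y_um", "cone_class"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    points = np.empty((len(df), 2), dtype=float)
    labels = []
    for row_no, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            points[row_no - 1] = (float(row["x_um"]), float(row["y_um"]))
        except (TypeError, ValueError) as exc:
            raise ValueError(
                f"{path}: non-numeric coordinate in row {row_no}"
            ) from exc
        label = str(row["cone_class"]).strip()
        if label not in CONE_CLASSES:
            raise ValueError(
                f"{path}: unknown cone class {label!r} in row {row_no}"
            )
        labels.append(label)
        if not window.contains(points[row_no - 1:row_no]).all():
            raise ValueError(
                f"{path}: point {tuple(points[row_no - 1])} in row {row_no} "
                f"lies outside the {w} x {h} µm window"
            )
    return ConeField(points, np.asarray(labels, dtype=object), window, meta)


def write_cone_field(field: ConeField, path) -> None:
    path = Path(path)
    buf = _io.StringIO()
    buf.write(f"# window_um={float(field.window.width)!r},{float(field.window.height)!r}\n")
    for key, val in field.meta.items():
        if isinstance(val, (str, int, float)):
            buf.write(f"# {key}={val}\n")
    buf.write("x_um,y_um,cone_class\n")
    for (x, y), label in zip(field.points, field.labels):
        buf.write(f"{float(x)!r},{float(y)!r},{label}\n")
    path.write_text(buf.getvalue())


def read_spectrum(path) -> Spectrum:
    """Read a two-column wavelength/absorbance CSV into a :class:`Spectrum`.

    Descending or duplicate wavelengths and single-row files are
    rejected; non-uniform (but ascending) grids are accepted and flagged
    in ``meta['uniform_grid']`` — the Fourier filter will refuse them.
    """
    path = Path(path)
    meta = _parse_comments(path)
    df = pd.read_csv(path, comment="#", float_precision="round_trip")
    required = ["wavelength_nm", "absorbance"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    if len(df) < 2:
        raise ValueError(f"{path}: a spectrum needs at least 2 rows")
    wl = df["wavelength_nm"].to_numpy(dtype=float)
    if np.any(np.diff(wl) <= 0):
        raise ValueError(f"{path}: wavelengths must be strictly ascending "
                         "(no duplicates)")
    spec = Spectrum(wl, df["absorbance"].to_numpy(dtype=float), meta)
    spec.meta["uniform_grid"] = spec.is_uniform
    return spec


def write_spectrum(spectrum: Spectrum, path) -> None:
    path = Path(path)
    buf = _io.StringIO()
    for key, val in spectrum.meta.items():
        if isinstance(val, (str, int, float)) and key != "uniform_grid":
            buf.write(f"# {key}={val}\n")
    buf.write("wavelength_nm,absorbance\n")
    for wl, ab in zip(spectrum.wavelengths, spectrum.absorbance):
        buf.write(f"{float(wl)!r},{float(ab)!r}\n")
    path.write_text(buf.getvalue())
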