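"""Configuration and the two end-to-end analysis pipelines.

``run_mosaic_pipeline`` takes a cone field (from file or a generator),
computes per-class NND/Voronoi statistics, the density recovery profile
and effective radius, the random-null comparison, the cell density, and
(given a lens radius) the acuity chain, writing every artifact plus a
JSON manifest to an output directory. ``run_spectra_pipeline`` filters
spectra, estimates λ_max and bandwidth, and ranks pigment-mixture fits.

All randomness flows from one top-level seed: stage seeds are drawn from
``numpy.random.SeedSequence([seed, stage_index])`` (documented expansion
rule), so identical configurations replay bit-for-bit.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .acuity import acuity_from_field
from .datatypes import CONE_CLASSES, ConeField, SomaSizes, Spectrum
from .drp import autocorrelogram, density_recovery_profile
from .errors import DegenerateFieldError
from .io import write_cone_field, write_spectrum
from .nulls import compare_to_null, simulate_null_ensemble
from .spatial import exclude_border_cells, mosaic_summary, nearest_neighbour_distances, voronoi_domains
from .acuity import cone_cell_density
from .spectra import (
    estimate_lambda_max,
    fit_mixture,
    fourier_filter,
    half_max_bandwidth_wavenumber,
)

__all__ = ["PipelineConfig", "run_mosaic_pipeline", "run_spectra_pipeline",
           "stage_seed"]


@dataclass
class PipelineConfig:
    """Analysis settings; defaults follow the study conventions
    (20 null replicates, Matthiessen 2.55, 0.5 mm target, 2 nm spectral
    step, α = 0.05)."""

    seed: int = 0
    window_um: tuple[float, float] = (52.0, 52.0)
    soma_um: tuple[float, float, float] = (2.2, 3.0, 4.1)  # single, double, triple
    n_null_replicates: int = 20
    drp_bin_width_um: float = 1.0
    drp_max_radius_um: float = 15.0
    matthiessen_ratio: float = 2.55
    target_size_mm: float = 0.5
    alpha: float = 0.05
    spectra_grid_nm: tuple[float, float, float] = (350.0, 750.0, 2.0)
    fourier_cutoff_nm: float = 40.0
    fit_p_starts: tuple[float, ...] = (1.0, 2.0, 4.0)

    @property
    def soma(self) -> SomaSizes:
        return SomaSizes(*self.soma_um)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("window_um", "soma_um", "spectra_grid_nm", "fit_p_starts"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def config_hash(self) -> str:
        """Stable hash of every analysis-relevant setting."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage_index: int) -> int:
    """Deterministic per-stage seed expansion (< 2^31)."""
    return int(np.random.SeedSequence([seed, stage_index]).generate_state(1)[0]
               % (2**31))


def _jsonable(x):
    if isinstance(x, float) and (math.isinf(x) or math.isnan(x)):
        return str(x)
    return x


def _stats_dict(stats) -> dict:
    return {
        "cone_class": stats.cone_class,
        "n_total": stats.n_total,
        "n_interior": stats.n_interior,
        "nnd_um": {k: _jsonable(v) for k, v in dataclasses.asdict(stats.nnd).items()},
        "voronoi_um2": {k: _jsonable(v)
                        for k, v in dataclasses.asdict(stats.voronoi).items()},
    }


def run_mosaic_pipeline(field: ConeField, config: PipelineConfig, outdir,
                        lens_radius_mm: float | None = None) -> dict:
    """Full mosaic analysis of one field; returns the manifest dict.

    Writes, per analyzable class: a per-cell table, a DRP table, and a
    null-comparison report; plus the field itself, a density/acuity
    summary, and ``manifest.json`` linking everything. The manifest
    records seeds and the config hash but no timestamps, so repeated runs
    with identical inputs are byte-identical.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "classes": {},
    }
    write_cone_field(field, outdir / "field.csv")
    manifest["field"] = "field.csv"

    counts = field.class_counts()
    for stage, cone_class in enumerate(CONE_CLASSES):
        if counts.get(cone_class, 0) < 4:
            continue
        entry: dict = {}
        try:
            stats = mosaic_summary(field, cone_class)
        except DegenerateFieldError as exc:
            manifest["classes"][cone_class] = {"skipped": str(exc)}
            continue
        entry["stats"] = _stats_dict(stats)
        # per-cell table
        nnd = nearest_neighbour_distances(field, cone_class)
        vd = voronoi_domains(field, cone_class)
        interior = set(exclude_border_cells(field, cone_class).tolist())
        cell_path = outdir / f"cells_{cone_class}.csv"
        with open(cell_path, "w") as fh:
            fh.write("cell_id,nnd_um,voronoi_um2,interior\n")
            for i, (d, a) in enumerate(zip(nnd, vd)):
                fh.write(f"{i},{float(d)!r},{float(a)!r},{int(i in interior)}\n")
        entry["cells"] = cell_path.name
        # DRP
        try:
            cg = autocorrelogram(field, cone_class, config.drp_max_radius_um)
            drp = density_recovery_profile(cg, config.drp_bin_width_um)
            drp_path = outdir / f"drp_{cone_class}.csv"
            with open(drp_path, "w") as fh:
                fh.write("r_lo_um,r_hi_um,density_mm2\n")
                for lo, hi, d in zip(drp.bin_edges[:-1], drp.bin_edges[1:],
                                     drp.densities):
                    fh.write(f"{float(lo)!r},{float(hi)!r},{float(d)!r}\n")
            entry["drp"] = drp_path.name
            entry["drp_summary"] = {
                "mean_density_mm2": drp.mean_density,
                "effective_radius_um": drp.effective_radius,
                "n_reference": drp.n_reference,
            }
        except ValueError as exc:
            entry["drp_skipped"] = str(exc)
            drp = None
        # null comparison
        null_seed = stage_seed(config.seed, stage)
        ens = simulate_null_ensemble(
            field, cone_class, soma=config.soma,
            n_replicates=config.n_null_replicates, seed=null_seed,
            bin_width=config.drp_bin_width_um,
            max_radius=config.drp_max_radius_um,
            compute_drp=drp is not None,
        )
        observed = stats.scalars()
        if drp is not None:
            observed["effective_radius"] = drp.effective_radius
        comparisons = {}
        for name, value in observed.items():
            if not math.isfinite(value):
                continue
            null_mean, null_sd = ens.null_summary.get(name, (float("nan"),) * 2)
            if not (math.isfinite(null_mean) and math.isfinite(null_sd)):
                continue
            c = compare_to_null(value, ens, name, alpha=config.alpha)
            comparisons[name] = {
                "observed": _jsonable(c.observed),
                "null_mean": _jsonable(c.null_mean),
                "null_sd": _jsonable(c.null_sd),
                "z": _jsonable(c.z_score),
                "significant": c.significant,
            }
        entry["null_seed"] = null_seed
        entry["null_comparison"] = comparisons
        manifest["classes"][cone_class] = entry

    manifest["density_mm2"] = cone_cell_density(field)
    if lens_radius_mm is not None:
        ac = acuity_from_field(field, lens_radius_mm,
                               matthiessen=config.matthiessen_ratio,
                               target_size_mm=config.target_size_mm)
        manifest["acuity"] = dataclasses.asdict(ac)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True))
    return manifest


def run_spectra_pipeline(spectra: list[Spectrum], candidate_sets,
                         config: PipelineConfig, outdir) -> dict:
    """Filter, characterize, and unmix a batch of spectra.

    For each spectrum: Fourier-filtered curve written to CSV, λ_max
    estimate, half-maximum bandwidth (when both flanks are bracketed),
    and mixture fits against every candidate pigment set ranked by SS.
    """
    if len(spectra) == 0:
        raise ValueError("no input spectra")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config_hash": config.config_hash(), "spectra": []}
    for i, spec in enumerate(spectra):
        entry: dict = {"index": i, "n_samples": int(spec.wavelengths.size)}
        if spec.is_uniform:
            filt = fourier_filter(spec, config.fourier_cutoff_nm)
            fname = f"filtered_{i}.csv"
            write_spectrum(filt, outdir / fname)
            entry["filtered"] = fname
        else:
            filt = spec
            entry["filtered"] = None
        est = estimate_lambda_max(filt)
        entry["lambda_max_nm"] = est.lambda_max_nm
        entry["lambda_max_ss"] = est.ss
        try:
            entry["bandwidth_cm1"] = half_max_bandwidth_wavenumber(filt)
        except ValueError as exc:
            entry["bandwidth_cm1"] = None
            entry["bandwidth_error"] = str(exc)
        fits = fit_mixture(spec, candidate_sets, p_starts=config.fit_p_starts)
        entry["fits"] = [f.as_dict() for f in fits]
        report["spectra"].append(entry)
    (outdir / "spectra_report.json").write_text(
        json.dumps(report, indent=2, sort_keys=True))
    return report
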