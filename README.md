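# conemosaic

Quantitative analysis of cone photoreceptor mosaics and visual pigments in
metamorphosing flatfish retinas.

During flatfish metamorphosis the larval retina — a honeycomb (hexagonal)
lattice of single cones — reorganizes into the adult square mosaic, in
which four double cones surround each centre single cone, while a
restricted dorsotemporal region develops a random mixture of single,
double and triple cones. `conemosaic` packages the full measurement chain
used to characterize this transition from digitized cone centroids and
microspectrophotometric absorbance spectra:

- **Spatial statistics of labelled point patterns** — Delaunay neighbour
  graphs, nearest-neighbour distances (NND), window-clipped Voronoi
  domain areas with border-cell exclusion, and the regularity index
  RI = mean/SD.
- **Autocorrelation machinery** — the spatial autocorrelogram, the
  density recovery profile (DRP, mean cell density vs. distance from each
  cell), and the effective radius of the central exclusion zone via an
  equivalent-volume estimator.
- **Random-null testing** — ensembles of random fields matched for
  density and constrained by soma size (random sequential adsorption),
  z-score comparison of observed statistics against the null, and
  one-way ANOVA with Tukey HSD compact-letter grouping across retinal
  regions.
- **Theoretical visual acuity** — from cone cell density D (cells·mm⁻²,
  doubles counting twice and triples three times) and posterior nodal
  distance PND = lens radius × 2.55 (Matthiessen's ratio):

      f_N = (π · PND / 360°) · (2D/√3)^{1/2}        [cycles/degree]
      θ   = 1 / f_N                                  [degrees]
      d   = (s/2) / tan(θ/2)                         [detection distance]

- **Visual-pigment spectral unmixing** — Govardovskii-type A1 nomogram
  templates (α + β bands, parameterized by λ_max), Fourier low-pass
  filtering, λ_max and half-maximum bandwidth estimation, and
  decomposition of co-expression spectra with the response model
  R(λ) = [Σᵢ kᵢ·Aᵢᵖ(λ)]^{1/p}, fitted by Nelder–Mead simplex and ranked
  by least sum of squares (SS) across candidate pigment combinations.

A synthetic-data module generates honeycomb lattices, jittered square
mosaics, soma-constrained random fields and noisy mixture spectra with
the statistical structure these analyses assume, so the whole chain is
testable without micrographs. See `docs/methods.md` for models,
parameters, and limitations.

## Worked example

Simulate a square mosaic (8 µm unit spacing, 0.4 µm jitter) in the
standard 52 × 52 µm² sampling window and analyze the double cones:

```sh
conemosaic simulate-mosaic --generator square --spacing 8 --jitter 0.4 \
    --seed 1 --out field.csv
conemosaic mosaic-stats field.csv --cone-class double
```

```json
{
  "cone_class": "double",
  "n_total": 98,
  "n_interior": 61,
  "nnd_um":     {"mean": 5.126, "sd": 0.291, "min": 4.202, "max": 5.719,
                 "regularity_index": 17.64},
  "voronoi_um2": {"mean": 31.55, "sd": 1.75, "min": 28.31, "max": 35.37,
                 "regularity_index": 18.05}
}
```

Of 98 double cones, 61 survive border exclusion; their mean spacing is
5.1 µm — close to the ideal 8/√2 ≈ 5.66 µm double–double lattice distance
— and the regularity indices near 18 flag a strongly ordered lattice
(soma-constrained random fields of this density score ~3–4).

```sh
conemosaic drp field.csv --cone-class double --max-radius 12
```

```json
{"mean_density_mm2": 36242.6, "effective_radius_um": 4.83, "n_reference": 27}
```

The 4.8 µm effective radius is the exclusion zone around each double
cone, on the scale of the double-cone cross-section. Finally, the acuity
chain for this field viewed through a 0.32 mm-radius lens:

```sh
conemosaic acuity --field-csv field.csv --lens-radius 0.32
```

```json
{"pnd_mm": 0.816, "nyquist_cpd": 2.303, "min_angle_deg": 0.434,
 "detection_distance_mm": 65.98, "density_mm2": 90606.5,
 "target_size_mm": 0.5}
```

i.e. this (dense) mosaic resolves ~0.43° and would detect a 0.5 mm food
item at ~66 mm. Other subcommands: `null-test` (observed vs. matched
random null), `simulate-spectrum` / `fit-spectrum` (pigment-mixture
decomposition), and `run-all` (full mosaic pipeline with JSON manifest).

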