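# Methods

This note documents the models, estimators, defaults and numerical
choices behind `conemosaic`, and what the synthetic-data generators do
and do not emulate.

## Coordinate conventions and data model

Cone centroids are continuous 2-D positions in micrometres inside a
rectangular sampling window with origin at its lower-left corner; the
default window is 52 × 52 µm², the size of the micrograph fields the
package is designed around. Each cone *unit* is one labelled point:
`single`, `double` (two fused cells) or `triple` (three fused cells).
Where a cell-level density is needed (acuity), doubles count as two cells
and triples as three. Densities are reported in cells·mm⁻² externally;
all geometry is computed in µm.

## Synthetic mosaics

The generators provide fields with the statistical structure of the three
mosaic types the analyses target.

- **Honeycomb** (`gen_honeycomb`): a triangular lattice of single cones
  with lattice constant `spacing`, clipped to the window. Models the
  larval mosaic in which six cones flank each single cone.
- **Square mosaic** (`gen_square_mosaic`): single cones on a square
  lattice of pitch *a*; double cones at the two edge-midpoint sites of
  each unit cell, so each interior single cone is surrounded by four
  double cones and the interior double:single ratio is 2. Corner sites
  are left empty (single corner cones are absent or extremely rare in
  these mosaics).
- **Soma-constrained random fields** (`gen_hardcore_random`,
  `gen_mixed_triple_field`): random sequential adsorption (RSA). Points
  are placed one at a time in a seed-determined random interleaving of
  classes; a candidate of class *c* is accepted only if its distance to
  every placed point is at least the larger of the two classes' soma
  sizes (a conservative, symmetric cross-class rule; the within-class
  rule is the class's own soma). Defaults: single 2.2 µm (mean soma
  diameter), double 3.0 µm (short axis), triple 4.1 µm (median). Exact
  class counts are achieved or a `PackingError` names the class that
  could not be placed; a disc-area bound rejects clearly infeasible
  requests up front. RSA jams near 55% disc coverage, well above any
  realistic cone density.

**Jitter model.** Lattice generators apply isotropic Gaussian
displacement after lattice construction, re-drawing any displacement
that would leave the window. Real mosaics do not advertise their jitter
magnitude; tests use 1–6% of the lattice spacing, which keeps the
lattice topology intact while breaking co-circular degeneracies. Jitter
is a *positional* perturbation only — the generators do not model cone
shape, double-cone member orientation, partition membranes, or image
formation, so tests passing on synthetic fields certify the estimators,
not segmentation or imaging steps.

**Determinism.** Every generator takes an explicit seed (default 0) and
is bit-for-bit reproducible. Pipelines expand one top-level seed into
per-stage seeds via `numpy.random.SeedSequence([seed, stage_index])`.

## Spatial statistics

Nearest-neighbour distances and Voronoi domains are homotypic (within a
cone class); the Delaunay graph may also be built over all classes for
mosaic-unit queries (e.g. counting the double cones around a single
cone). NND uses a k-d tree; Delaunay/Voronoi use Qhull.

**Window clipping.** Voronoi polygons are clipped exactly to the window
by mirroring the point set across all four window edges and reading off
the original points' cells from the augmented tessellation; clipped
areas therefore tile the window exactly (tested to 1e-6 relative).
Discarding unbounded cells instead of clipping was the plausible
alternative; clipping was chosen so that every cell has a defined area
and the border-exclusion rule below can operate on it.

**Border exclusion.** A cell is a border cell when its clipped polygon
touches the window boundary (any vertex within 1e-7 of the relative
window scale): precisely those cells whose true NND or domain could be
affected by unseen neighbours outside the window. All summary statistics
(mean, SD, min, max, regularity index) cover interior cells only.
Shrinking the window can only remove interior cells, never add them.

**Regularity index.** RI = mean/SD with the sample SD (n−1 denominator;
the convention is not dictated by the measurement chain, and at the
field sizes involved the choice is immaterial). Zero SD (perfect
lattices) reports +inf. Jittered lattices score RI ≫ soma-constrained
random fields, which score above unconstrained random fields.

## Autocorrelogram and density recovery profile

For each same-class reference cell at least `max_radius` from every
window edge (guard zone), the displacements to all other same-class
cells within `max_radius` (circular support) are accumulated. The guard
zone makes every annulus lie fully inside the window, so annulus
densities are unbiased without area-intersection weighting; the cost is
fewer references, acceptable at the default `max_radius` = 15 µm in
52 µm fields. Defaults: bin width Δ = 1 µm (0.25 µm in recovery tests
needing finer resolution), densities converted to cells·mm⁻².

**Effective radius.** The exclusion zone is summarized by an
equivalent-volume (Rodieck-style) dip estimator: with D̄ the field mean
density, let r* be the inner edge of the first annulus whose density
reaches D̄; the deficit V = Σ max(0, D̄ − Dᵢ)·areaᵢ over annuli below r*
defines ER = √(V/(π·D̄)). For an ideal step profile this returns the
hard-core radius exactly; on RSA simulations with the 2.2 µm soma it
recovers the constraint within bin resolution (median over 20 seeds,
Δ = 0.25 µm). The estimator, not being uniquely determined by the
figure-level description it reimplements, is pinned down by these
recovery properties instead.

## Random-null comparison

`simulate_null_ensemble` generates (default) 20 RSA fields matched to
the observed field's class counts and window and computes per-replicate
statistics (NND/Voronoi means and RIs, optionally DRP effective radius).
An observed scalar is compared by z-score against the replicate mean and
SD, two-sided at α = 0.05. With only 20 replicates an empirical rank
test cannot reach p < 0.05 two-sided (minimum 2/21 ≈ 0.095), which is
why the parametric z-score is the default; the rank variant is available
via `method="rank"` for users who prefer it at larger replicate counts.
Calibration on fields generated under the null yields rejection rates of
~5–8% (the small excess over the nominal 5% comes from estimating the
null SD from 20 replicates and from the mild non-normality of ratio
statistics at small interior-cell counts). A 5%-jittered lattice is
detected as significantly more regular than its null in ≥95% of repeats.

Note that a full pipeline run tests several statistics per class; at
α = 0.05 some false positives among ~15 comparisons are expected, so
single flagged comparisons in an otherwise clean report should be read
accordingly.

**Regional comparison.** Cross-region densities are compared with
one-way ANOVA plus Tukey HSD (α = 0.05) and summarized as compact
letters computed from maximal cliques of the "statistically indistinct"
graph; regions sharing a letter are indistinguishable.
Student–Newman–Keuls is not implemented (Tukey HSD covers the same
grouping role with better-controlled error rates).

## Visual acuity

PND = lens radius × 2.55 (mean Matthiessen's ratio for teleost eyes);
f_N = (π·PND/360°)·√(2D/√3) cycles per degree for cell density D;
θ = 1/f_N degrees; detection distance for a target of size s (default
0.5 mm) uses the exact subtense d = (s/2)/tan(θ/2) — at sub-degree
angles this differs from the small-angle form s/θ by < 0.01%, but the
exact form remains valid for coarse sampling arrays. Density
normalization always uses the actual analyzed window area.

## Pigment templates and spectral unmixing

**Template.** The A1 (retinal chromophore) absorbance template is the
standard Govardovskii-type α-band log-normal-like expression plus the
Gaussian β-band, parameterized solely by λ_max (valid 330–620 nm) and
normalized to 1 at λ_max. The template's half-maximum bandwidth at
λ_max = 491 nm is ≈ 4270 cm⁻¹, inside the measured 4170 ± 234 cm⁻¹ range
for A1 rod pigments — the package's check that the template family is
appropriate. An alternative template can be substituted anywhere a
template function is accepted, since all operations consume the
evaluated `PigmentTemplate` values.

**Fourier filtering.** Plain rFFT low-pass on uniform grids: components
with period below the cutoff (default 40 nm) are zeroed; the DC term
(mean) is preserved exactly. Because the transform treats the spectrum
as periodic, the unequal endpoint absorbances of pigment spectra leave a
small Gibbs-ringing floor; with 0.05 SD white noise the RMS error versus
the clean curve is roughly halved (45–57% across seeds). No tapering or
detrending is applied, keeping the stop-band exact for in-band
components.

**λ_max estimation.** A single scaled template is scanned over a 1 nm
grid (least-squares scale per candidate), then the best candidate is
refined by bounded scalar minimization. Under 0.02 SD noise the mean
absolute error across the seven cone/rod pigments (431–550 nm) is well
under 3 nm, smaller than the 5–11 nm inter-cell spread of real records.

**Bandwidth.** Half-maximum crossings of the α-band are located by
linear interpolation on the wavenumber axis (ν = 10⁷/λ) on both flanks
of the peak; a flank that never crosses half-maximum raises an error
naming the flank.

**Mixture model and fit.** Co-expression spectra follow
R(λ) = [Σᵢ kᵢ·Aᵢᵖ(λ)]^{1/p} with coupling constants kᵢ ≥ 0 and exponent
p > 0 (which keeps the fitted absorbance function differentiable at the
origin); p = 1 reduces to a weighted sum, and a single pigment with
k = 1 reproduces its template for any p. Fitting minimizes
SS = Σ(R − A_obs)² by Nelder–Mead simplex over log-parameters (so
positivity is structural), with starts p₀ ∈ {1, 2, 4}, k₀ from peak
matching (k₀ᵢ = A_obs(λ_max,ᵢ)^{p₀}), and one restart from each
incumbent; tolerances 1e-12 on SS, 5000 iterations per start. Candidate
pigment sets are ranked by best SS. On a noiseless two-pigment spectrum
(k = 1.398, 0.061; p = 5.523; pigments 431 + 500 nm) the fit returns the
generating parameters to ~1e-9 relative with SS ~1e-24, and the correct
pair wins model selection in 100% of 50 replicates at 0.01 SD noise.
Spectra are fitted as given (no peak normalization) by default.

Default wavelength grid: 350–750 nm in 2 nm steps.

## Problem sizes used in tests

The shipped tests and acceptance script use 52 × 52 µm windows with
~60–300 points per field, 20-replicate null ensembles, 20-seed recovery
medians, 50-repeat calibration/model-selection loops and 201-point
spectra — sizes chosen to estimate every statistic stably while keeping
a full run around half a minute.

## Known limitations

- 2-D planar analysis only: no wholemount curvature correction, no 3-D
  soma shapes, no cross-class correlograms, no anisotropy decomposition.
- The guard-zone edge correction discards references near the window
  edge; for max radii approaching half the window size the correlogram
  empties and an error suggests a smaller radius.
- A2 (3,4-dehydroretinal) templates are not provided; the bandwidth
  check above is the supported way to confirm A1 suffices.
- The RSA null is one specific random model; mosaics violating its
  assumptions (e.g. density gradients) will reject for reasons other
  than lattice order.
- Published per-panel statistics from real micrographs depend on the
  digitized centroids, which are not distributed; the package therefore
  validates against closed forms, brute-force oracles and
  parameter-recovery simulations rather than against those panels.
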