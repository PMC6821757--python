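# Methods

`endoquant` quantifies where fluorescently tagged receptor complexes sit
and move in microscopy of polarized embryonic tissue. This note documents
the models behind each stage, the parameters that matter, what the
synthetic data emulate (and do not), and the numerical choices made where
the design was genuinely open.

## Conventions

All distances are micrometres; raster values are treated as photon counts
(camera gain 1 — gain calibration is out of scope). Pixel centres sit at
half-integer multiples of the pixel pitch with the origin at the image
top-left. The default pixel size is 0.1 µm/px — spinning-disc data of this
kind rarely ships with recorded calibration, so the default is an explicit,
overridable choice. Z-stacks hold 10 sections spaced 1 µm, ordered from
the basal side (plane 0, where cell protrusions face the substrate) to the
apical surface. Movies default to a 50 ms frame interval.

## Synthetic data generator

Each generator returns the artifact plus a truth object recording exactly
what was placed where. Recovery tests consume the truth only in
assertions.

**Cell images** (`make_cell_image`): one cell per field, outlined by an
ellipse-perturbed closed curve (low-order cosine perturbations of a base
radius — the simplest shape with a well-defined membrane band; real
explant cells are more irregular, but the downstream quantities only need
a closed boundary). Channel `membrane` carries the outline as a ridge of
Gaussian cross-section (PSF σ, default 0.2 µm); channel `clusters`
carries diffraction-limited spots of 5000 integrated photons, splatted by
exact per-pixel integration of an isotropic 2-D Gaussian (error-function
quadrature, so the integrated photon count is exact to the 5σ window).
Exactly `round(n_clusters · membrane_fraction)` spots are centred on the
ridge; the rest land in the cytoplasm interior with a minimum mutual
separation. The default membrane fraction is 0.8, the regime in which the
large majority of receptor clusters sit at the plasma membrane. Poisson
noise is applied per pixel.

**Ratio cells and profiles** (`make_ratio_cell`, `make_line_profile`): a
circular cell with inside level I_in (default 100 photons), outside level
I_out (50), and a membrane ridge whose *radial maximum* equals
I_out + ratio·(I_in − I_out). Because the ridge overlaps the
outside→inside smooth step, a closed-form ridge amplitude overshoots the
target peak for small ratios; the amplitude is instead solved by
bisection against the analytic radial intensity. `make_line_profile`
builds a 1-D profile directly with exactly flat outer zones and a centre
sample equal to the target peak, so noise-free analysis recovers the
configured ratio to floating point; it requires ratio ≥ 1 (the membrane
is modelled as a peak above the cytoplasmic level).

**Z-stacks** (`make_zstack`): spots are laid out on a jittered grid whose
pitch (10σ, jitter ±15% of pitch) guarantees that no neighbour's PSF mass
leaks into another spot's 4σ analysis window. Home sections realize the
configured basal→apical weight vector with *exact* per-plane counts
(largest-remainder apportionment, randomly permuted over spots): the
weight vector is a controlled ground truth, so recovery tolerances
measure the detector rather than multinomial sampling noise. Optional
z-bleed attenuates a spot's intensity in neighbouring sections by
exp(−(k − home)²/(2·z_spread²)).

**Brownian movies** (`simulate_brownian_paths`, `make_brownian_movie`):
2-D random walks with per-axis step variance 2·D·Δt, reflecting at the
field edges (no particle loss in short movies). The first
`n_comigrating_pairs` particles of the second channel share the
underlying path of the same-index particle in the first channel; every
observed trajectory adds independent Gaussian localization jitter
(default σ 0.02 µm, a typical two-colour registration-plus-localization
error for split-view detection). Rendering splats
each particle with the expected photon rate (default 5000/frame) and
draws per-pixel Poisson counts, so both spot photon numbers and
background statistics are Poisson.

**Expression tables** (`make_expression_table`): per-gene log2 baselines
N(8, 2), i.i.d. Gaussian replicate noise in log2 units (default 0.1),
regulated genes shifted by ±log2(fold_change) with alternating direction
(the screen is two-sided: down-regulated membrane-trafficking genes are
as interesting as up-regulated ones). Defaults: 2000 genes, 100 regulated at
4.0-fold, 4 replicates.

**Phenotype counts** (`make_phenotype_counts`): one multinomial draw per
condition over (wild_type, mild, severe).

What the generators do *not* emulate: tissue context (multiple touching
cells, explant curvature), out-of-focus haze and 3-D PSFs, bleaching and
stage drift, camera gain/read noise, chip-level microarray artefacts.
Passing recovery tests therefore demonstrates correctness of the
quantification logic under controlled optics, not robustness to every
property of real explant data.

## Spot detection

Candidates are local maxima of a difference-of-Gaussians band-pass (σ and
2σ), thresholded at 3× the expected DoG noise floor (background σ from
the median absolute deviation, scaled by the DoG white-noise gain).
Sub-pixel positions come from two passes of intensity-weighted centroids.
The centroid uses a 2σ-radius core window: at the minimum supported spot
separation (4σ) a full 4σ centroid window would overlap the neighbouring
spot and drag paired centroids toward each other until duplicate-merging
collapses them (measured: 3/50 spots lost). The integrated photon count
is the background-subtracted sum over the full 4σ-radius window.
Candidates closer than 2σ are merged keeping the brighter. The photon
gate is strict: only spots with *more than* `min_photons` (default 1000)
integrated photons are reported. PALM-style maximum-likelihood fitters would localize more precisely at
low photon counts, but at the signal-to-noise of the supported regimes
this simpler estimator localizes to well under half a pixel.

Per-section visibility of a spot (for z-distributions) is an automated
criterion for a call that is often made by eye: the
background-subtracted window sum must exceed `visibility_factor`
(default 5) times the expected noise of that sum (MAD-based background σ
times √window-pixels).

## Colocalization (M2) and cluster classes

M2 = Σ signal over pixels where marker > threshold ÷ Σ signal, defined on
intensities, signal-in-marker direction only. The marker threshold
defaults to Otsu's method (deterministic and parameter-free, unlike
interactive plugin thresholds, which are rarely reported) and
accepts a fixed override. The membrane band mask thresholds the marker,
skeletonizes it to the ridge, and dilates to a configurable total width
(default 0.4 µm ≈ 2 PSF σ). A cluster is "membrane" iff the pixel
containing its centroid lies in the band. M2 is undefined for zero total
signal and is signalled, never returned as 0.

## Membrane/cytoplasm ratio

ratio = (I_membrane − I_outside)/(I_inside − I_outside) on a profile
ordered outside→inside. Zones default to the first 25% of samples
(outside, mean), the middle 50% (membrane, maximum — the membrane is a
thin peak; a mean would dilute it), and the last 25% (inside, mean). The
ratio is undefined when |I_inside − I_outside| falls below 1e-6 of the
profile's dynamic range. Both differences scale identically under
I → a·I + b (a > 0), so the ratio is affine-invariant. Profiles are
sampled by bilinear interpolation; `average_width_um` (default 0.4 µm in
batch mode) averages parallel lines across the width of the drawn bar,
which suppresses the positive bias of the zone maximum under Poisson
noise without broadening the peak along the profile. Batch mode places
radial segments at K evenly spaced angles per cell (default 8).

## Z-distribution

Spots are selected once on the maximum-intensity projection, then every
section is scored for visibility of each spot. Default counting is
multi-plane: a spot visible in k sections contributes 1 to each and k to
the denominator; `mode="single"` instead assigns each spot to its
brightest visible section. Fractions sum to 1 for every non-empty cell,
are invariant to stack-wide intensity rescaling, and reverse exactly
under plane reversal. Aggregation averages cells within explants first,
then reports mean and SD across explants per plane; condition comparisons
use per-plane two-sample t-tests across explant means.

## Tracking and comigration

Frame-pair linking minimizes the total squared displacement over
one-to-one partial assignments gated at `max_disp_um` (default 2.5 µm,
strict), with each unlinked spot charged max_disp². This is the classic
nearest-neighbour linking objective, solved exactly via a padded linear
assignment problem; on small instances it equals exhaustive enumeration.
No gap closing: a missed detection terminates a trajectory. Drift
correction (optional, off by default) subtracts the per-frame median
displacement. Diffusion is estimated from the ensemble time-averaged MSD,
weighted by pair counts, with a straight-line fit over lags 1–4 whose
intercept absorbs the localization-noise floor; D = slope/(4Δt).

Comigration: every cross-channel trajectory pair overlapping ≥
`min_overlap_frames` (default 20) frames is scored by mean separation
over the overlap; pairs under `sep_threshold_um` (default 0.3 µm) are
resolved one-to-one greedily by ascending separation. Both defaults are
explicit stand-ins for a call usually made visually from trajectory
overlays.

## Statistics

Two-sample t-tests default to Welch (pooled-variance Student available);
two constant equal samples give p = 1 by convention with a warning. The
chi-square test is Pearson's on the R×C table without continuity
correction, warning when any expected count is below 5. The expression
screen passes genes with max(FC, 1/FC) strictly greater than 3.8 (with a
1e-9 relative tie tolerance so a table constructed at exactly 3.8-fold
does not pass through float rounding) and Welch p < 0.05, ranked by
|log2 FC|, truncated to the top 100; no multiple-testing correction by
default (raw per-gene significance, as such TOP-N screens
typically report; Benjamini–Hochberg is available). qPCR relative expression uses 2^−ΔΔCt with
amplification efficiency 2 and per-condition means taken on the ΔCt
scale, so the baseline condition is exactly 1.

## Problem sizes and determinism

Every generator is bitwise reproducible from its seed, and every pipeline
run is byte-reproducible from (config, seed); run metadata records the
seed, a config hash, and per-parameter provenance (default vs override).
The shipped demo and the test suite run at desk scale: fields of
256–640 px, 200–500 spots per stack, movies of 100–200 frames, diffusion
checks on ~10⁵ simulated steps, and 10⁴ replicates for the type-I-error
calibrations — sizes chosen so each check is statistically decisive while
the whole suite stays interactive.

## Known limitations

- No 3-D PSF or astigmatism model; z-bleed is a per-section Gaussian
  attenuation, not an optical model.
- No automatic membrane segmentation for profile placement on arbitrary
  real images; batch profiles assume a roughly stellate cell with a known
  centre, otherwise placements come from a CSV.
- The tracker is frame-to-frame optimal but not a global multi-frame
  tracker; dense scenes with crossing particles can swap identities.
- The screen's per-gene Welch t-test is a plain (unmoderated)
  statistic; vendor chip pipelines often use moderated variants.
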