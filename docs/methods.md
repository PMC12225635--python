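# Methods

## The decay model and its assumptions

A TCSPC acquisition records, per pixel, a histogram of photon arrival times
over `n_bins` = 256 bins spanning one laser repetition period. The measured
expectation is modelled as

    mu_k = A · [ IRF ⊛ m ](t_k) + C,
    m(t) ∝ α₁ e^(−t/τ₁) + α₂ e^(−t/τ₂),   α₁ + α₂ = 1,

where the bi-exponential mixture `m` is normalized to unit mass over the
window so `A` is the expected total signal photons, `C` is a constant
background per bin, and ⊛ is discrete linear convolution with the
instrument-response kernel. α₁ and α₂ are **pre-exponential (amplitude)
fractions** — the convention of commercial TCSPC fitting software — and the
reported mean lifetime τₘ = α₁τ₁ + α₂τ₂ is the amplitude-weighted mean.
Note that under this convention the *photon share* of component *i* is
αᵢτᵢ / (α₁τ₁ + α₂τ₂), not αᵢ.

Assumptions: decays are truncated at the window (no incomplete-decay
wrap-around term — the forward simulation and the fitted model make the same
choice, so simulation studies are internally consistent); the IRF is an
analytic Gaussian parameterized by its FWHM (a measured kernel can be
substituted via the `IRF` type); photon counts are Poisson and independent
across bins and pixels.

## Fitting

Per-pixel fits maximize the Poisson likelihood, implemented as trust-region
least squares on signed square-root deviance residuals (the sum of squares is
exactly the Poisson deviance, so the minimizer is the exact MLE while keeping
a Gauss–Newton Jacobian for speed and standard errors). Neyman-weighted least
squares (weights 1/max(n,1)) is available via `FitOptions(objective="wls")`
but is **not** the default: at the 10³–10⁴ photon counts typical of binned
pixels, Neyman weighting over-weights low-count tail bins and biases the long
lifetime downward by ~15%, which we measured directly on simulated decays;
the deviance MLE is unbiased to ~1% under the same conditions.

Parameters, bounds and defaults:

| parameter | init | bounds | unit | note |
|---|---|---|---|---|
| τ₁ | 0.4 | [0.05, 1.5] | ns | short (free NAD(P)H / bound FAD) |
| τ₂ | 2.5 | [1.0, 6.0] | ns | long component |
| α₁ | 0.7 | [0, 1] | — | α₂ stored as 1 − α₁ exactly |
| A | counts − n·C₀ | [0, ∞) | photons | C₀ = 10th percentile of bins |
| C | C₀ | [0, ∞) | photons/bin | free, per the model equation |
| shift | 0 | ±5 | bins | fractional IRF-to-decay alignment |

The lifetime bounds prevent component swapping during optimization; ordering
τ₁ ≤ τ₂ is additionally canonicalized on output (fractions swapped
accordingly). The IRF shift is fitted by default; for an ideal single-bin
delta kernel the shift likelihood is non-smooth and the shift should be
disabled (`fit_shift=False`) — with any realistic multi-bin kernel this does
not arise. Decays with fewer than `min_photons` = 100 photons are marked
invalid rather than fitted; reduced χ² is the Pearson statistic over
`n_bins − n_params` degrees of freedom.

**Attainable precision.** The Poisson Fisher information of this model puts a
floor under the fit's scatter: at 10⁴ photons (τ₁ = 0.5 ns, τ₂ = 2.5 ns,
α₁ = 0.7, 260 ps IRF, free background) the Cramér–Rao bound is ≈ 6% relative
on τ₁, ≈ 3% on τ₂ and ≈ 0.016 absolute on α₁. No estimator recovers both
lifetimes within 5% in ≥95% of such decays; at 10⁵ photons the fit does
(measured ≥ 98% over seeded replicates). Per-pixel estimates at 10³–10⁴
photons should be treated as inputs to per-cell averaging, not as precise in
themselves. Bias shrinks with the photon budget (measured over 10³/10⁴/10⁵).

## Timing, geometry and binning

The measurement window defaults to 12.5 ns (80 MHz Ti:sapphire repetition
rate, the instrument class these acquisitions come from) over 256 bins;
the IRF FWHM defaults to 260 ps. 3×3 binning is a moving-window sum (each
pixel's decay plus its 8 neighbours), resolution-preserving; edge pixels sum
only the neighbours that exist. Pixel coordinates are 0-based (row, col).

## The synthetic-data generator

The generator emulates what the instrument and segmentation deliver, so the
whole chain can be validated against known truth:

- **Cells** are non-overlapping ellipses (default radius 12 px ± 20% jitter,
  axis ratio up to 1.8) with concentric, co-oriented nuclei scaled by 0.45,
  clipped to their cell so nucleus ⊂ cell holds exactly.
- **Lifetime distributions** are truncated normals per parameter; defaults
  are literature-typical autofluorescence values — NAD(P)H τ₁ ~ N(0.4, 0.05)
  on [0.2, 0.8] ns, τ₂ ~ N(2.5, 0.3) on [1.5, 4.0] ns, α₁ ~ N(0.7, 0.05);
  FAD τ₂ centered at 2.8 on [1.8, 4.5] ns, α₁ at 0.75. No printed per-group
  values exist to anchor these, so they are documented as typical, not as
  reproductions. Finite mixtures express bimodal (heterogeneous) cohorts.
- **Photon budget** defaults to 5×10⁴ expected signal photons per cell,
  i.e. ~2×10³ per binned pixel for a ~200 px cell — the scale a 60 s
  integration accumulates, and enough for per-cell mean τₘ within ~3% of
  truth. (A 10× smaller budget leaves ~240 photons per binned decay, where
  the two-component fit is bias- and variance-dominated.)
- Each cell's expected signal is spread uniformly over its pixels, shaped in
  time by the IRF-convolved model, added to the background rate, and
  Poisson-sampled. Every stage is a pure function of its arguments including
  the seed (independent spawned streams per field).

What it does **not** emulate — and what passing tests therefore do not show
about real data: optical blur and pixel crosstalk, intracellular lifetime
heterogeneity (organelles, lipid droplets), photobleaching, detector
afterpulsing and dead time, segmentation errors, or field-to-field intensity
variation. Classifier and embedding results on synthetic cohorts quantify the
pipeline's behaviour under designed separations; they say nothing about the
separability of any real cell population.

## Single-cell aggregation

Cytoplasm masks are per-label set subtraction (whole cell minus own
nucleus); nuclear pixels outside their cell are ignored with a warning, and
cells with empty cytoplasm are dropped and reported. Each of the eight OMI
variables is the unweighted mean of the per-pixel fitted values over the
cell's valid cytoplasm pixels (not photon-weighted, not a pooled-decay
refit — matching common practice for exported fit maps). Cells with fewer
than `min_pixels` = 10 valid pixels in either channel are excluded and
tallied. The feature table reports α₁ for both channels; α₂ is implied as
1 − α₁ (the two are informationally equivalent).

## Cohort statistics

Group summaries are mean ± SD (n−1 denominator; singleton groups get missing
SD). Significance uses the unpaired two-tailed t-test, Welch by default
(equal-variance Student's by flag) at α = 0.05, with no multiple-testing
correction. Effect size is Glass's Δ = (mean(comparison) − mean(reference)) /
SD(reference); the reference is the temporally earlier or control condition
and must be named explicitly. Categories use half-open intervals [0, 0.2)
small, [0.2, 0.5) medium, [0.5, 0.8) large, [0.8, ∞) very large, fixing the
overlapping verbal boundaries. Whether rows are cells pooled across fields or
per-field means is the caller's choice; the functions operate on whatever
table they are given, so pseudoreplication handling is explicit, not hidden.

## Multivariate stage

UMAP runs on the eight OMI variables with n_neighbors 15, min_dist 0.1,
cosine metric, 2 components, fixed seed. Embedding geometry is seed- and
implementation-sensitive, so tests assert only coarse separation (silhouette
against design labels), never coordinates. The random forest uses 100 trees,
unlimited depth, min_samples_split 2; the 70/30 split is stratified per
class with test size ⌈0.3·n_class⌉ (per-class ceiling rounding reproduces the
published per-class counts exactly, e.g. 2235 → 1564/671 and 4990 →
3493/1497; a 1e-9 backoff guards binary-float fuzz in n·0.3). ROC comes from
the positive-class vote fraction with trapezoid AUC; the confusion matrix
uses a 0.5 vote threshold; features enter unscaled (forests are
scale-invariant and no scaling step is part of the protocol). Importances
are sklearn's normalized mean-decrease-in-impurity values, which sum to 1 by
construction.

## Pipeline and formats

`run_pipeline` executes simulate → fit → features → stats → embed/classify
from a strict YAML config (unknown keys rejected by name; every seed
explicit) and writes a manifest with per-stage counts (cells in = emitted +
excluded). Formats: multi-frame TIFF for cubes (frame = time bin, JSON
sidecar for window/channel/IRF metadata), 16-bit TIFF label masks, 32-bit
float TIFF parameter maps, CSV tables, JSON reports. All writer/reader pairs
round-trip losslessly.

Test and demonstration problem sizes are deliberately small — fields of
32–64 px, a handful of cells, 64–128 time bins, cohorts of 10²–10³ cells —
chosen so the full suite exercises every stage end-to-end in about a minute
while leaving the statistics of each assertion well-powered.

## Known limitations

- No phasor analysis, three-component fits, or incomplete-decay model.
- The Gaussian IRF surrogate cannot represent the asymmetric tails of real
  measured IRFs; supply a measured kernel where that matters.
- Per-cell aggregation assumes the cytoplasm is metabolically homogeneous;
  subcellular structure is averaged away.
- Vendor formats (.sdt) are out of scope; convert to TIFF + JSON first.
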