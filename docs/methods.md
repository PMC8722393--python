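# Methods

## Models

**Stochastic promoter activation.** Every allele at nuclear column *x*
activates permanently as the first event of a memoryless (Poisson)
process with per-minute rate *p(x)*. The waiting time is therefore
exponential, and the expected activated fraction after *T* minutes of
exposure to the stable Dorsal gradient is the exponential CDF
*F(x) = 1 − exp(−T·p(x))*. Two rate rules are implemented:
Dorsal-proportional, *p(x) = p₀·D(x)* (the graded mode of *T48*/*mist*),
and uniform *p(x) = p₀* (the switch mode of *twi*). Alleles are
independent, including the two alleles of one nucleus.

Inversion of an observed fraction, *p̂ = −ln(1−F̂)/T*, diverges at
*F̂ = 1*; a saturated column is capped at *F̂ = 1 − 1/(2n)* for *n*
observed alleles (half a count below saturation) and flagged. Pearson
correlations between per-column statistics and the Dorsal level are
computed on column (cell-row) values; zero-variance inputs are defined
as r = 0 with a warning rather than NaN, so that degenerate switch-mode
simulations average cleanly.

**Dorsal profile.** Measured per-column nuclear Dorsal levels are not
available in numeric form, so the package generates a parameterized
stand-in, *D(x) = exp(−x²/2σ²)* with σ = 4 columns over a 19-column
(±9) mesoderm, normalized to 1 at the ventral midline. All quantitative
results that depend on the profile state this stand-in explicitly in
their setup. Asymmetric (measured) profiles are accepted anywhere a
`DorsalProfile` is, provided levels do not rise away from the midline.

**mRNA accumulation.** Transcripts are stable on the ~15-min timescale
considered; an activated locus produces mRNA at deterministic rate
*r(x)* (constant = 1, or Dorsal-graded = *D(x)*, both normalized at the
midline). The expected accumulated mRNA per allele is the closed form
*M(x,t) = r(x)[t − (1−e^{−pt})/p]* with the *p→0* limit 0; a Monte-Carlo
mode sums *r(x)·(t−t_act)₊* over sampled activation times and is checked
against the closed form within sampling error. Production-rate noise is
deliberately not modeled — the model targets expectations per column.

**Elongation and intron delay.** Pol II initiates at the activation
time and advances deterministically at *v* = 2 kb/min (configurable). A
probe region becomes detectable when the first polymerase passes its
start; the first mature mRNA appears when it reaches the gene end, with
splicing treated as instantaneous (the delay argument rests on
elongation time only). Gene models: *T48* 29 kb with a 25 kb intron
(5′ exon 0–2 kb, 3′ exon 27–29 kb), its intronless cDNA 4 kb, *mist*
9.3 kb, *twi* 2.2 kb. The in-vivo 5′→3′ delay reported for *T48*
(~17 min at 20 °C) exceeds L/v = 14.5 min at 2 kb/min; the model keeps
*v* as a free parameter rather than resolving that tension.

## Image analysis

**2D TS detection.** The smFISH stack is max-projected, filtered with a
sign-flipped Laplacian-of-Gaussian (size 15 px, σ 2.5 px, reflective
boundaries, kernel mean-subtracted so constants map to 0), and
thresholded automatically (below). 8-connected components above the
threshold are TSs; intensities are summed over component pixels of the
measurement image.

**3D single-molecule detection.** The local background (median in a
moving sphere, radius 5 voxels, reflective boundaries, clipped at 0) is
subtracted, a 3D LoG (σ = 1.0, 1.5, 1.5 voxels, matched to the rendered
PSF) applied, and 18-connected components labeled.

**Automatic threshold.** Candidates are 100 geometrically spaced levels
between the 50th percentile and the maximum of the positive filter
response; for each the component count is recorded, a count of 0 ending
the scan. The guiding idea is to take the first threshold around which
the count stays relatively constant. Two readings are implemented. The
*literal* rule — step change in log₁₀ count smaller than half the
maximal change across the scan — works for coarse two-phase scans but
fails on a fine grid: per-step changes are everywhere small and the
normalizing maximum is dominated by the terminal cliff where the
brightest spots vanish, so it can trigger inside the noise decline. The
default *running* rule therefore compares the change over a 5-candidate
window with half the maximal change seen so far, starts the search at
the count maximum (below it, neighboring components are still merging,
so counts are not spot counts), and returns the midpoint of the
contiguous run satisfying the criterion, placing the threshold centrally
in the first plateau. Flat scans (identical clean spots) fall back to
the lowest candidate with a warning.

**Flux measurement.** Summing only super-threshold component voxels
under-counts PSF flux, dim spots more than bright ones, which biases the
TS/mRNA ratio. `call_spots` therefore supports (a) expanding each
component by a fixed distance for the cumulative sum only, without
overlap between neighbors (`skimage.segmentation.expand_labels`), and
(b) subtracting a per-voxel pedestal estimated as the median of the
measurement image *outside* all spot regions. The pipeline measures
flux on the raw stack with a 3-voxel expansion and the outside-pedestal
correction; a moving-window median was rejected for measurement because
at realistic spot densities neighboring spots contaminate the window
and carve a negative halo around each spot (it remains the detection
prefilter, where only contrast matters). On noise-free fixtures the
measured cumulative intensity of interior spots is within ~1.5% of the
planted flux.

**Classification.** Spots split into single mRNAs and TSs at the
minimum of the Gaussian-kernel density (Scott's bandwidth) of log₁₀
maximal intensity between its two largest modes. Working in log domain
makes the cutoff invariant to global intensity rescaling; a unimodal
density raises a dedicated error carrying the density for diagnosis.
The Pol II count is taken as *N = R* directly; no correction is applied
for partial (5′-biased) nascent transcripts — the dual-probe gating
(restricting to 3′-positive loci) is the intended mitigation.

**Geometry.** The midline is the intensity-weighted centroid of the
smoothed (FWHM two column spacings) summed expression profile, with
values below 10% of the profile maximum zeroed so background far from
the domain does not drag the centroid. Column spacing is the mean
distance between density peaks of nucleus centroids projected on the
DV axis; nuclei are detected by reusing the LoG detector at σ = 3 px
(matched to the rendered nucleus blobs; real images need this scaled to
their nucleus size). Column distances are signed real values,
(DV − midline)/spacing, binned to nearest integer; TSs are assigned to
nuclei by footprint containment, else nearest centroid within a radius
(ties to the lower nucleus id).

## Synthetic embryos

The generator emulates what the analysis needs and no more: a
hexagonal-offset nucleus grid (19 columns × 8 nuclei, spacing 14 px,
nucleus radius 5 px), one bright TS per active allele placed uniformly
inside the nucleus footprint (sister sites kept ≥ 5 px apart, as allele
territories are distinct in real nuclei), unit-intensity cytoplasmic
mRNA spots placed uniformly outside nuclei (20 per column by default,
optionally Dorsal-graded), Gaussian PSF blur (σ = 1.0, 1.3, 1.3
voxels), a uniform background baseline (10 counts, standing in for
autofluorescence/camera offset), Poisson shot noise and additive
Gaussian read noise (σ = 2). The unit mRNA integrated intensity is 500,
giving single molecules the clear ~5:1 peak SNR of real smFISH; a TS
carries `ratio` × unit (default 70). One master seed is split
deterministically per stage, so stacks are bit-identical under a fixed
seed.

Not emulated: embryo curvature, optical aberrations, anterior-posterior
patterning, nuclear elongation with embryo age, intensity variability
among TSs (each is planted at exactly `ratio` × unit), and transcription
bursting. Passing tests therefore certify the measurement chain and the
models on idealized geometry — they do not certify segmentation-free
performance on curved, aberrated real embryos.

## Problem sizes and numerical choices

Model-level studies use 10 one-sided columns (σ = 4), 200 nuclei × 2
alleles per column and 20 seeds for the graded mode, and 20 columns ×
100 nuclei × 50 seeds for the uniform control — large enough that
binomial noise is well below the correlation bounds, small enough to run
in seconds. Rendered-image studies use one embryo (152 nuclei, ~500
spots, 12×294×140 voxels), which detects and quantifies in ~10 s.
Monte-Carlo accumulation uses 10⁴ alleles per column and is compared to
the closed form within 3 standard errors. Saturation capping, the r = 0
degenerate-correlation rule, the nearest-integer column binning and the
lower-id nucleus tie-break are the only tie/degeneracy conventions; all
tolerances asserted in tests are stated inline there.

## Known limitations

* The activated-fraction inversion loses precision as *F̂ → 1* (double
  precision stores *F*, not *1−F*); the saturation cap bounds but does
  not remove this.
* 2D TS counting on projections merges sister sites that project within
  ~the PSF; the image-based per-nucleus 0/1/2 histograms undercount twos
  relative to the allele-level truth, exactly as in projection-based
  analyses of real embryos.
* The midline estimator tracks the flux-weighted center of the rendered
  expression, which at ~150 nuclei fluctuates by up to ~0.7 columns
  around the grid midline; image-based correlation fits inherit that
  scatter (model-level fits do not).
* The Dorsal profile stand-in is Gaussian; none of the quantitative
  conclusions depend on the exact family, but absolute probabilities do.
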