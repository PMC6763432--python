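# Methods

This note documents the models, parameter choices, and numerical decisions
behind the package, and what the synthetic-data validation does and does
not establish about real data.

## The measurement problem

Sequential-probe multiplexed imaging acquires each protein channel in its
own imaging round. Two nuisances accumulate across rounds: a multiplicative
illumination field (the excitation laser profile), and a rigid lateral
drift of the sample between rounds. Both must be removed before
intensities from different channels can be compared within a synapse.
After correction, synapses are defined on the synapsin-I channel and all
other channels are quantified inside or near those synapses, giving one
feature vector per synapse — the substrate of every downstream statistic.

## Flat-field correction

The background of each plane is estimated by grayscale morphological
opening with a disk structural element (default radius 100 px), which
removes any structure more compact than the disk while following the
smooth illumination profile. Backgrounds from all images of a channel on
one plate are averaged and rescaled to spatial mean 1 so that division
preserves average intensity and corrected values remain comparable across
plates (profiles are estimated per plate because the illumination varies
between experiments).

Numerics: an exact disk opening at radius 100 is prohibitively slow in the
underlying libraries, so the default footprint is skimage's sequence
decomposition of the disk — a close approximation whose deviations are a
small fraction of the local noise amplitude; `exact=True` restores the
literal footprint (and exact anti-extensivity/idempotence) for small
radii. The averaged profile is floored at 1% of its mean so division never
amplifies numerically empty pixels.

## Round registration

Drift between rounds is the integer (dx, dy), within a ±`max_shift`
window (default 50 px), that maximizes the Pearson correlation of the
overlapping region between the reference-channel images of the two rounds.
Ties break toward the smallest |dx|+|dy|, then lexicographically. The
estimate from the reference channel (MAP2, present in every round) is
applied to every channel of that round; pixels shifted in from outside the
frame are zero-filled and masked out of all downstream measurements.
Integer shifts avoid interpolation artifacts in intensity quantification;
a subpixel mode is deliberately not the default.

## Punctae segmentation

Each corrected channel is enhanced in three steps: contrast stretch
saturating the brightest and dimmest 1% of pixels (falling back to the
image maximum when bright structure occupies less than 1% of the image),
adaptive Wiener denoising in 5×5 windows, and a white top-hat with a disk
of radius 8 px that suppresses structures larger than the disk. Enhanced
values more than nine orders of magnitude below the maximum are zeroed
(float residue of the filter chain, not signal).

The binarization threshold is chosen by object count: 100 quantile-spaced
candidate thresholds over the nonzero enhanced pixels are scanned, the
number of 8-connected components with area ≥ `min_object_px` is counted at
each, and the lowest candidate achieving the maximum count wins. Quantile
spacing makes the choice invariant to affine intensity rescaling, which is
what makes one recipe work across channels with very different dynamic
ranges.

`min_object_px` defaults to 12 px — the largest punctum still excluded by
the 0.42 µm² synapse floor at 187 nm pixels. This choice matters: after
top-hat enhancement the image background reduces to spatially correlated
speckle, and near its percolation threshold that speckle fragments into
blobs at a density of roughly 0.007–0.012 per pixel. If such blobs are
allowed to inform the threshold (e.g. with a 2 px minimum), the
object-count criterion locks onto the noise regime whenever punctae are
sparse, and precision collapses. Objects below the minimum synapse
footprint carry no information about the right threshold for
synapse-scale structure, so they are excluded from the scan (the final
segmentation still keeps punctae of any size above the chosen threshold
and above `min_object_px`).

Touching punctae are split by a watershed on the negated Euclidean
distance transform, seeded at distance-transform maxima at least 3 px
apart; every foreground pixel keeps exactly one label, so the split
conserves area. Area, integrated intensity, and intensity-weighted
centroid are measured on the corrected image — never on the enhanced one,
whose top-hat distorts intensities.

## Synapse gating and colocalization

Nuclei are delineated on the DAPI channel by Otsu thresholding, hole
filling, removal of objects below 20 µm², and a 1 px dilation as a safety
margin (the source experiments only state that intranuclear synapsin
punctae were excluded, not how nuclei were segmented; this recipe is this
package's choice). A synapsin punctum is a synapse iff its area is
strictly greater than 0.42 µm² and its weighted centroid is outside the
nuclear mask. Punctae of other channels attach to their nearest synapse
when the weighted-centroid distance is strictly below 1 µm (ties toward
the lower synapse id; each punctum attaches to at most one synapse, and
each synapse keeps its nearest attached punctum). A synapse with no
colocalized punctum in a channel gets integrated intensity 0 and area 0
there; mean intensity is integrated/area where area > 0, else 0.

## Statistics

Per-synapse features are averaged in two stages — synapses to per-image
means, images to per-well means — with images weighted equally regardless
of synapse count. Treated and untreated wells are compared per feature by
a two-tailed two-sample Student's t-test (pooled variance; Welch behind a
flag), with group means scaled relative to the untreated mean and 95%
confidence intervals from the t distribution. Pearson correlations
between channel intensities are computed within each group (batch or
well) and averaged; network edges appear where the mean r is strictly
above 0.35. For treatment effects on correlations, each well's r is
centered on its biological replicate's untreated mean before a two-tailed
t-test per channel pair — this removes replicate-level culture
variability.

Raw p-values are reported without multiplicity adjustment, matching the
analysis this package reproduces; a Benjamini–Hochberg column can be added
by the caller and is deliberately not the default.

For embeddings and clustering, each feature is mapped x → log(x + 1),
divided by its standard deviation, and shifted to minimum 0. The +1
pseudocount is required because the zero-fill rule guarantees exact zeros,
which a bare log cannot handle; dividing by the sd before subtracting the
minimum satisfies both normalization constraints (sd 1, min 0)
simultaneously. t-SNE uses the exact gradient, perplexity 40, 5000
iterations and PCA initialization by default (tests use smaller settings
for speed); sub-type candidates are local maxima of a Gaussian KDE
(Scott's-rule bandwidth) above the median positive density, flagged
low-confidence when the density relief inside the data's bounding box is
weak. Hierarchical clustering uses Euclidean distance with Ward linkage
over both synapses and features.

## PAINT post-processing

The module consumes localization tables (frame, x, y in nm); spot
detection and fitting are upstream of this package. Fiducials are found by
greedy nearest-neighbor linking within 100 nm frame to frame (tracks may
go dark for up to 20 frames); tracks present in at least half of all
frames qualify — transient binding events, with lifetimes of a few frames,
never do. Drift is estimated per fiducial by LOESS smoothing of x(t) and
y(t) separately (span 0.1, local linear, tricube weights), anchored to
zero at frame 0, averaged over fiducials, and interpolated to every frame.
Correction subtracts the trajectory per frame; the same trajectory aligns
tables from different imaging rounds that share fiducials.

Rendering is a 2D histogram at 5.4 × 5.4 nm bins followed by Gaussian
smoothing (default 1 bin); the unsmoothed histogram conserves the
localization count. The radial cross-correlation of two rendered channels
is C(r) = ⟨A(x)·B(x+r)⟩ / (⟨A⟩⟨B⟩), computed by FFT with per-shift overlap
normalization and averaged over displacement angle, so statistically
independent channels give C ≡ 1. The structure-size readout is the
smallest r at which C(r) − 1 falls below (C(0) − 1)/e; a half-max variant
is available. This 1/e definition is this package's choice of a concrete
readout for a quantity often reported from the curve without a stated
rule. Two caveats measured during development: autocorrelating a single
channel adds a discrete self-pairing spike at r = 0 that shrinks the
apparent decay length (use two channels), and sparse fields of few
clusters add a slowly decaying ensemble term that inflates it (the
generator keeps clusters isolated on a field ≥ 25× the structure scale).

Cross-section FWHM estimates fit a Gaussian to the collapsed profile of a
rendered structure and remove the known rendering kernel — the smoothing
sigma and the bin-integration variance bin²/12 — in quadrature, so the
reported FWHM reflects the structure rather than the rendering. For a
Gaussian of sd σ, FWHM = 2√(2 ln 2)·σ ≈ 2.3548σ.

## LNA probe design

Confocal imaging probes are PAINT probe cores with a two-adenine 3′ anchor
and three nucleotides replaced by LNA. Because LNA substitutions raise the
melting temperature of any duplex they sit in, positions must avoid the
partially complementary regions each probe shares with non-cognate docking
strands. At 11–13 nt an exhaustive diagonal scan finds every maximal
ungapped complementary stretch of length ≥ 4 exactly and deterministically
(a heuristic aligner would add version-dependent nondeterminism for no
benefit at these lengths). The intended duplex — the region on the cognate
strand covering the full docking sequence — is excluded from penalties.

The original cost function is described only by its monotonicities (higher
cost for more LNAs in a region and for longer regions); the concrete form
used here is, per docking strand, Σ over regions of length^β · n_LNA^α
with α = 2, β = 1, and the scheme's assigned cost is the maximum over
strands. The exponents are free parameters exposed in the API. All C(13,3)
= 286 position sets are enumerated, so the optimizer is globally optimal by
construction; ties break toward the lexicographically smallest position
set. The shipped docking-strand panel is synthetic (the original sequences
live in non-redistributed supplementary tables) and exists purely to
exercise the algorithm.

## The synthetic-data generator

The generator is the package's study design, not a reconstruction of any
particular dataset. Defaults, chosen once as realistic conditions for a
mature (DIV 21) dissociated hippocampal culture imaged at 187 nm pixels:

- **Field**: 224 px (42 µm) square; 26 piecewise-linear dendrite
  backbones; 3 elliptical nuclei with 3–4 µm semi-axes.
- **Synapses**: 200 per field (≈ 0.2/µm²), sampled along dendrites with a
  minimum center separation of 12 px (2.2 µm — synapses are discrete
  structures and cannot overlap) and never inside nuclei; rendered as
  isotropic Gaussians of σ = 1.6 px (FWHM ≈ 0.7 µm).
- **Intensities**: multivariate lognormal — exp of correlated normals with
  per-channel log-sd 0.25 and configurable correlation matrix (default
  0.5 off-diagonal); integrated intensity of the rendered punctum equals
  the planted value. Sub-types suppress configured channels to 1% of
  their draw.
- **Nuisances**: smooth Gaussian vignette of ±30% (mean 1); integer
  per-round drift up to ±3 px (round 0 is the reference); Poisson noise
  plus Gaussian read noise (σ = 2) on a background of 20; six decoy
  intranuclear synapsin punctae so the nuclear-exclusion rule has a
  measurable effect.
- **PAINT**: docking sites as explicit points, filaments with Gaussian
  cross-section, or uniform discs; Bernoulli binding per site per frame
  (rate 0.002); fiducials detected in ≥ 95% of frames (default 98%);
  localization noise σ = 10 nm; drift as a box-smoothed Gaussian random
  walk (0.5 nm/frame steps) or a linear ramp, anchored at frame 0.

What passing tests show — and what they do not. The simulations plant the
exact generative structure the pipeline assumes: Gaussian punctae,
multiplicative vignette, rigid integer drift, lognormal intensities,
stationary background. Recovery under these conditions verifies the
implementation, the contracts between stages, and the statistical
calibration (e.g. the t-test's false-positive rate). It does not establish
performance on real micrographs, whose punctae are not Gaussian, whose
background contains structured out-of-focus light, and whose intensity
distributions are heavier-tailed. Two sensitivities found during
development are documented here deliberately: the object-count threshold
degrades when synapse density is far below the background speckle blob
density (sparse fields), and it sits high enough that the dimmest tail of
a wide intensity distribution (log-sd ≳ 0.4) can fall below threshold or
under the 13 px gate. The default conditions (realistic density, log-sd
0.25) are inside the method's working regime; users applying the recipe to
sparser or more variable data should inspect the count-versus-threshold
curve.

Problem sizes in the tests and the acceptance script (one 224 px field,
5000-frame PAINT acquisitions, 20 replicate treatment simulations at 100
synapses per image, t-SNE on a few hundred profiles) were chosen as the
smallest sizes at which the quantities of interest are statistically
stable; all scale up linearly through the configuration objects.

## Known limitations

- Registration is rigid and integer-valued; no rotation, scaling, or
  nonrigid deformation, and no axial (z) drift handling — stacks must be
  reduced to 2D (maximum-intensity projection by default) upstream.
- The object-count threshold assumes punctae outnumber residual
  background blobs (see above).
- LOESS drift estimation anchors at frame 0; an unlucky noise spike in
  the first frames biases the whole trajectory by a constant, which
  cancels in within-round comparisons but not across rounds.
- The probe-design cost is a surrogate with free exponents, not a
  thermodynamic model; no melting-temperature prediction is attempted.
- Localization-table ingestion assumes spot detection and fitting were
  done upstream (e.g. by a standard single-molecule localization tool).
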