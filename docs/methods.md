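# Methods

`focikit` quantifies ionizing-radiation-induced 53BP1 nuclear foci in
fluorescence images, classifies cells by how quickly they resolve those
foci, and computes the efficiency/purity statistics of rare-cell magnetic
capture experiments. Because the original microscopy data are not deposited
anywhere, the package ships a first-class synthetic-image generator with
full ground truth; every end-to-end claim the test suite makes is a
recovery claim against that generator.

## The biological model

After ~0.5–1 Gy of ionizing radiation, a U2OS cell expressing GFP-53BP1
shows on the order of ten bright nuclear foci at 45 min post-IR
(population mean 10.2, SD 2.5 foci/cell), superimposed on a diffuse
nucleoplasmic pool of free GFP-53BP1. Foci disappear as double-strand
breaks are repaired; by 2 h the average cell has resolved ~25% of its
foci, while a rare subpopulation (~1%) resolves more than 85% of them
("fast resolvers", strict `resolution_fraction > 0.85` between the first
and second observation). Crucially, 53BP1 redistributes rather than
degrades: whole-nucleus intensity carries essentially no information about
the focus count, which is why image-level spot counting (and not
intensity-gated sorting) is required to find fast resolvers.

## Synthetic data generator (`focikit.simulate`)

Per-cell kinetics. Initial counts are a discretized normal
(mean 10.2, SD 2.5; negative draws set to 0). Each cell draws an endpoint
resolved fraction `f` at the final timepoint: bulk cells from
Beta(mean 0.25, concentration 20); fast resolvers
(Bernoulli p = 0.01) uniform on [0.85, 1]. The remaining-focus fraction
decays as `(1 − f)^((t − t0)/(T − t0))` — a per-cell single exponential
pinned to 1 at the first timepoint and `1 − f` at the last — and integer
counts are realized by binomial thinning between consecutive timepoints,
so counts are non-increasing by construction. Only endpoint statistics are
published for the real population; the exponential-plus-thinning law and
the Beta/uniform mixture are the simplest families consistent with them,
and the mixture is an explicit stand-in, not an inference about the real
population. Ground truth stores both the drawn subpopulation flag and the
realized classification (`resolution > 0.85` on planted counts); recovery
is always scored against the latter, since thinning noise can push a
drawn-fast cell's realized resolution below threshold and no detector can
(or should) recover the unrealized label.

Rendering. Nuclei are filled ellipses (radius 30 ± 1.5 px, mild
ellipticity, hard-core placement with a 12 px minimum gap) at a per-cell
background level (2000 ADU, CV 0.1); each focus adds an isotropic Gaussian
(FWHM = 5 px, amplitude 6000 ADU). The geometry corresponds to ~0.3 µm/px
sampling: a ~18 µm U2OS nucleus spans ~60 px and a ~1.5 µm focus ~5 px;
the nucleus-to-focus area ratio matters because of the conservation rule
below. Pixel values are Poisson shot noise on the expected counts plus
Gaussian read noise (SD 3 ADU, gain 1), clipped to 16 bits. Defaults give
peak/background = 3.

GFP conservation. The integrated flux planted into a cell's foci
(`A·2πσ²` per focus) is subtracted from its diffuse background, floored at
10% of the background. Mean nuclear intensity is therefore independent of
focus count by construction; the pipeline-level Pearson correlation
between measured mean intensity and detected count retains a small
positive residual (r ≈ +0.2) because segmentation boundaries sample focus
tails slightly differently from the uniform depletion — comparable in
magnitude to the near-zero correlation reported for the real data, and
far from the r ≈ +0.8 an additive (non-conserving) renderer produces.

Distractors. One saturated blob (radius 25 px, at the saturation level)
and one sub-size speck per 10 nuclei, placed outside all nuclei, exercise
the saturation and area filters.

Foci are planted with a minimum pairwise separation (default = the focus
diameter, relaxed geometrically if a crowded nucleus cannot honour it) and
a 4 px margin from the nuclear boundary. Two foci closer than the
detector's merge radius are fundamentally unresolvable by any local-maxima
caller; the planted separation keeps the end-to-end checks about detector
fidelity rather than about the diffraction-style resolution limit, and the
methods-level limitation is stated below.

Capture simulation. Round 1 draws captured positives ~
Binomial(n_tagged, p_capture) and carried-over negatives ~
Binomial(n_total − n_tagged, p_carryover); each later round re-applies the
same retention probabilities to the previously captured cells. Purity is
non-decreasing in rounds whenever negatives are retained less efficiently
than positives.

## Detection pipeline (`focikit.detect`)

1. **Segmentation.** Gaussian smoothing (σ = 2 px), then a global Otsu
   threshold computed on log-intensities, `log(x + 10⁻³·max)`. The log
   domain makes the threshold robust to the strong dark/bright class
   imbalance of sparse fields and to rare saturated debris, and renders the
   whole decision exactly equivariant under multiplicative intensity
   rescaling (scaling becomes a shift in log space). Holes are filled and
   components labelled with 8-connectivity.
2. **Filtering.** Components are dropped if their area lies outside
   [800, 6000] px², their saturated-pixel fraction exceeds 0.05, their
   solidity is below 0.85, or (by default) they touch the image border.
   Survivors are relabelled consecutively. Touching nuclei that merge into
   one component generally fail the solidity test and are discarded rather
   than miscounted.
3. **Band-pass enhancement.** Difference of Gaussians with
   σ_low = d/4 = 1.25 px and σ_high = d/2 = 2.5 px (d = focus diameter).
   Both blurs are masked normalized convolutions over the eroded nucleus
   foreground, so the nuclear boundary step contributes no response and
   rim-proximal foci keep their true amplitude. The mask is eroded by
   `2σ_smooth + 2` px before enhancement because the smoothed-Otsu mask
   includes a dim boundary skirt whose internal bright/dark step would
   otherwise dominate the filter output.
4. **Focus calling.** Per retained nucleus, 3×3 local maxima of the
   enhanced image (plateaus resolved to their lexicographically smallest
   pixel) must exceed an automatic threshold. The default `'auto'` rule
   requires a candidate to clear *both* (a) the per-nucleus Otsu split of
   enhanced values — which adapts to arbitrarily dense signal, where any
   dispersion-based rule is contaminated by the foci themselves — and
   (b) a pixelwise noise floor, `median + k·σ_noise·f(x)` with k = 4,
   where σ_noise is the nucleus' white-noise SD estimated robustly from
   horizontal first differences of the raw image and `f(x)` is the exact
   noise-amplification map of the masked band-pass (computable from the
   kernels; it rises near the rim where fewer pixels contribute). The
   floor keeps empty, noise-only nuclei at ~0.01 false calls per nucleus;
   the Otsu part keeps dense nuclei unbiased. `mean + k·SD` and plain
   per-nucleus Otsu are available as alternative modes. Maxima closer than
   d/2 merge into the brighter one (ties toward the smaller (row, col)).
   All components of the rule are equivariant under intensity rescaling.

Measured on the generator at default SNR: per-cell count bias ≈ 0
(|bias| < 0.2 at 10.2 foci/cell), exact counts on noiseless
well-separated fields, ~0.01 false foci per empty nucleus.

## Kinetics (`focikit.kinetics`)

Nuclei are matched across timepoints by mutual-nearest centroids with a
displacement gate (default: the median nucleus radius); globally optimal
assignment is available as a verification mode. `resolution_fraction`
is `1 − n_t1/n_t0`, undefined (and excluded from classification) when
n_t0 = 0. Fast resolvers are `fraction > 0.85`, strictly. Population
summaries report n, mean, sample SD, median per timepoint plus a smoothed
normalized histogram (Gaussian kernel on integer count bins, bandwidth 1
count, renormalized to unit mass; bins extend 4 bandwidths above the
largest count so smoothing is not clipped). Comparisons: classical
pooled-variance two-sided Student t-test (Welch behind a flag; zero pooled
variance with equal means returns t = 0, p = 1), Pearson correlation of
mean nuclear intensity vs focus count, and a resolution speed ratio: for
the population median at time t_pop, linear interpolation on the reference
median-vs-time curve gives the time t_ref at which the reference reaches
the same median, and the ratio is t_ref/t_pop at the earliest comparable
timepoint (extrapolation outside the observed reference range is refused).
When both populations start from the same focus load — as irradiated
populations do at 45 min — the first timepoint trivially yields 1.0, so
analyses anchor at the second timepoint.

## Capture statistics (`focikit.capture`)

Efficiency = captured positives / targeted; the efficiency slope is OLS of
captured on targeted with a free intercept (through-origin available).
Purity/contamination accept non-integer (averaged) counts. Enrichment
reports fold and log₁₀ orders. In-silico PCR scans both template strands
for exact matches of the forward primer and of the reverse complement of
the reverse primer downstream of it; product length spans both primer
footprints inclusively, with a 5 kb default cap. Matching is exact-only,
consistent with clean species-specific amplification. The package bundles
the published dog/mouse mitochondrial cytochrome-b primer pairs and
*synthetic stand-in templates* (so labelled in filename, FASTA header and
docstring) in which those footprints are planted at the spacing that
yields the known 247 nt / 196 nt products; they verify the engine and the
length convention, not species identity — for a genuine species check,
supply the authentic mitochondrial sequences as FASTA.

## Problem sizes and numerical choices

End-to-end recovery checks run on 500-nucleus, 3000×3000 px fields (one
field for count recovery; ten seeded two-timepoint courses, ~5000 tracked
cells, for fast-resolver recall/precision) and 200-nucleus five-timepoint
courses for the population comparison — the package's chosen desk-scale
study conditions. Coordinates are 0-based (row, col); images 8/16-bit with
saturation at 2^bits − 1; all randomness flows from one integer seed via
`numpy.random.SeedSequence`, and every output table carries the seed and a
SHA-256 config hash.

## What passing tests do and do not show

The generator reproduces the statistical structure the analyses assume —
count levels and spread, per-cell endpoint-calibrated decay, a rare
fast-resolving tail, intensity–count independence, camera noise, debris —
but not real-microscopy nuisances: uneven illumination, out-of-focus
light, touching/overlapping nuclei, focus brightness heterogeneity,
mitotic and apoptotic morphologies, stage drift beyond rigid jitter, or
chromatic/temporal bleaching. Recovery results therefore validate the
implementation under the stated imaging model, not detector performance on
arbitrary real data. Two planted foci closer than half a focus diameter
are reported as one; cells with zero initial foci cannot be classified;
nuclei touching the border are discarded by default.
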