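# Methods

This note documents the models, conventions and numerical choices behind
`stapull`, and what the synthetic-data generator does and does not emulate.

## Imaging model and coordinate conventions

Pixel indices are 0-based; `x` is the column, `y` the row; continuous
centroid coordinates place pixel centers at integers. This convention is
load-bearing: the 2-px coincidence radius and the flip map
`(x, y) → (W−1−x, H−1−y)` are only reproducible against a fixed convention.

The dual-view sensor is split into two equal halves along a configurable
axis; splitting and reassembly are exact partitions (no resampling).
Projections (max for pulldown detection, mean for ThT) are plain per-pixel
reductions over frames.

### Registration

Channel registration is estimated from multi-color bead fiducial images by
phase cross-correlation with sub-pixel (upsampled) peak refinement,
translation-only by default. A similarity mode (rotation + isotropic scale
from log-polar FFT magnitude spectra, then translation) exists for optics
with measurable rotation; dual-view TIRF error is dominated by translation,
so it is off by default. The transform maps channel-B coordinates onto
channel-A coordinates; images are resampled bilinearly, and pixels pulled in
from outside the frame are filled with a declared value and masked out of
all downstream image statistics (otherwise fill values bias the SD-based
detection threshold). The transform carries the mean residual displacement
of independently re-detected and matched beads as a registration quality
metric; on simulated shifts up to ±10 px the residual stays below 0.15 px
and recovered shifts are accurate to better than 0.1 px.

## Spot detection

The projected image is Gaussian-smoothed (σ = 1 px), thresholded at
`center + k·spread` with k = 5, and 8-connected components above threshold
become candidate puncta. Components with equivalent diameter below the
resolution limit (`min_diameter_px`, default 2 px — FWHM/pixel-size rounded
down for the default 0.1 µm pixel) are rejected as noise. Centroids are
intensity-weighted over background-subtracted raw pixels (background = mean
of the unmasked raw image); spots touching the border or masked pixels are
kept but flagged and excluded from intensity statistics.

Two statistics conventions are provided:

- default: `center/spread` = mean/SD of the smoothed unmasked pixels — the
  literal reading of "k SD above image mean";
- robust: median and 1.4826·MAD. Bright aggregates inflate the global SD
  enough to push monomer puncta below a mean/SD threshold, so the robust
  variant is the appropriate choice for samples that mix dim monomers with
  very bright oligomers; blanks and monomer-only samples are insensitive to
  the choice. Mixed-sample analyses in the tests and examples use it.

The threshold is computed per image (a per-condition override is a matter of
pooling the statistics before thresholding).

The single-color (intensity-threshold) analysis subtracts
`mean + 3·SD` of the *peak pixel* signal of non-coincident spots from every
pixel (clipped at 0) and re-runs detection; "peak signal" rather than
integrated intensity is the chosen reading of per-pixel amplitude, and the
convention is documented here because the two differ by the spot area.

## Coincidence and chance correction

Matching is one-to-one and greedy by ascending distance with deterministic
tie-breaks. Greedy-by-distance accepts every mutual-nearest pair first and
never skips an unmatched cross-channel pair closer than an accepted pair;
on small sets it agrees with brute-force maximum matching (enumerated in the
tests). One-to-one assignment prevents a bright spot from being counted
against several neighbors.

The chance estimate flips channel-B *centroids* about the image center
(equivalent to flipping the image, without resampling artifacts) and
re-matches. The image center is a fixed point of the flip — a spot exactly
there stays matched to itself — a documented edge case that is negligible
for sparse fields. The analytic sparse-field rate n₁n₂πr²/A counts candidate
pairs; the one-to-one match count falls measurably below it once the
expected number of in-radius partners per spot approaches ~0.1 (at
0.01 spots/px² the deficit is ≈15%). At the surface densities the assay
operates at (≤0.05 events/µm², ≲10⁻³ spots/px²) the distinction is
negligible and the chance estimate is unbiased: over hundreds of simulated
monomer-only fields the mean chance-corrected density is statistically zero.

Per-FOV corrected densities are kept signed (a blank FOV can fluctuate
negative); clamping happens only at the pooled sample level, with a flag.
The pooled oligomeric fraction uses the chance-corrected numerator
`Σ(n_c − n_chance)`; the raw ratio is also reported. Total protein counts
each coincident event once (`n₁ + n₂ − n_c`); a multiplicity switch covers
the alternative convention of removing both members.

## ThT (SAVE) analysis

Mean projection, then: global baseline = mean intensity of the lowest 1% of
pixels (an aggregate of that subset, since a set of pixels has no single
"intensity"; the quantile value itself is available as an option); local
background = 11×11 mean (reflected edges) minus the baseline; the
baseline-removed image minus the local background, clipped at zero, is the
working image. The detection threshold is mean + 3·SD of pooled control
pixels (blank or monomer-only surfaces from the same batch). Controls must
be prepared *unclipped*: clipping folds the residual noise into a
half-normal and biases both the mean and the SD downward, which admits a
large false-feature floor. Clipping never changes which pixels exceed a
positive threshold, so the counted image itself may stay clipped. Features
are 8-connected components (4-connectivity exposed as an option).

## Detection limits and oligomer concentration

LoB and LoD use the printed Gaussian forms with sample (n−1) SDs —
replicates are typically triplicate, and the paper-form 1.645 multiplier is
implemented as stated even though blank counts are Poisson-like at very low
levels. Calibration is a least-squares second-order polynomial of mean
counts vs concentration, inverted in closed form; the admissible root must
lie within the fitted concentration range on the increasing branch
(derivative > 0), and ambiguity or absence is an error rather than a guess.

The LoD-recovery check compares this formula against a brute-force
definition (smallest concentration whose replicate counts exceed the LoB in
≥95% of 20 fresh replicates) on synthetic series. With triplicates the
per-seed SD estimate is chi-distributed with 2 degrees of freedom and
dominates any single-seed comparison, so the check pools 20 independent
seeds and compares geometric means, which agree within a factor of two.

## Synthetic scenes

`simulate_scene` places molecules uniformly at random: monomers carry
exactly one antibody label; each oligomer unit acquires a label by
Bernoulli(p) (default p = 0.5; a Poisson option models multivalent
binding); every label lands in channel 1 with probability `color_split`
(0.5 for the 1:1 dye mix). Images are sums of isotropic Gaussian PSFs
(σ = 1.3 px), then per-frame Poisson shot noise, Gaussian read noise
(SD 2), and a camera offset (100); channel-2 emitters can be shifted
sub-pixel to exercise registration. All randomness flows through one seeded
generator; identical spec + seed is bit-identical.

Default conditions reflect the assay's working regime: 0.1 µm pixels
(instrument-dependent and therefore a required configuration parameter —
densities are reported per µm²), surface densities in the
10⁻⁴–10⁻¹ events/µm² range, 1500 detected photons per label per frame
(SNR ≫ 10 for single labels). Calibration series scale the oligomer density
linearly with concentration over a constant nonspecific monomer background
(0.1 events/µm² in the detection-limit studies — blanks are not empty in
practice, and the LoB machinery degenerates without background counts).
Scene sizes in the tests (128²–256² px, 1–3 frames, 16 FOVs per replicate)
are scaled-down study conditions chosen to keep simulations compact while
leaving ≳10 expected events per measured quantity.

Not emulated: photophysics (blinking, bleaching), antibody affinity and
epitope accessibility (labeling efficiency is a free parameter precisely
because absolute stoichiometry is not determinable from intensity), surface
capture kinetics, illumination nonuniformity, temporal drift. Passing tests
therefore certify the *analysis* — detection, matching, correction and
calibration arithmetic — not robustness to those instrument effects.

## smFRET bursts

Traces are analyzed bin-wise at 100 µs (the expected confocal residence
time); consecutive suprathreshold bins count as separate events. A
coincident burst needs ≥8 counts in *each* channel (boundary inclusive).
Corrections are the two linear forms I_D = D − A_D and I_A = A − A_A − C·D;
the instrument constants A_D, A_A and C are required inputs (they are
setup-specific and not derivable from a trace). Corrected intensities and
efficiencies are never clamped; E outside [0, 1] is flagged and excluded
from histograms but retained in burst tables. Monomer brightness is the
mean corrected donor intensity of donor-only bursts (donor ≥ threshold,
acceptor < threshold); the size formula 2(I_D + I_A)/I_monomer doubles the
intensity ratio because each dye color labels about half the units. Size
classes are small < 5 ≤ medium ≤ 150 < large (boundaries closed on the
medium class, exposed as constants).

The generator makes bursts single-bin with Poisson donor/acceptor counts
whose means include the cross-talk and autofluorescence terms, so the
corrections are exact inverses in expectation; diffusion kinetics are out of
scope because the analysis itself is bin-wise.

Histogram fitting uses 0.05-wide bins on [0, 1] (bin width is not dictated
by the method and is configurable). The global two-Gaussian model shares
centers and widths across datasets with free per-dataset amplitudes
(lmfit least squares); initialization places centers at the 25th/75th
percentiles of the pooled distribution, making the fit deterministic.
Component A is defined as the lower-FRET population; fits whose centers
collapse within 0.02 are rejected as degenerate rather than reported.
Per-population event rates are analytic component integrals
(amp·σ·√(2π)), not numeric sums.

## Known limitations

- The mean/SD detection threshold is sensitive to very bright aggregates
  (use the robust variant for mixed samples); neither variant models
  structured background.
- The chance estimate assumes spatial stationarity of the spot field; a
  strongly vignetted field would bias it.
- Quadratic calibration is only invertible on its monotone branch; series
  whose LoD falls outside the fitted range error out by design.
- The LoB/LoD Gaussian forms are approximations at near-zero blank counts.
- Oligomer size from intensity is a proxy: labeling efficiency and dye
  count per antibody rescale it, so only relative comparisons are
  meaningful.
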