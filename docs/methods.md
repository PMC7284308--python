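# Methods

This note documents the models, parameter choices and numerical decisions
behind each `mtphen` pipeline, what the synthetic data does and does not
emulate, and the known limitations.

## Synthetic data model

The generator (`mtphen.synthgen`) is first-class, tested code; it defines
the conditions under which every downstream claim is verified.

**Stacks.** Nuclei are solid ellipsoids with in-plane semi-axes drawn from
5.0–6.5 μm, axial semi-axes 2.8–3.8 μm and random in-plane orientation —
10–13 μm nuclei, typical of hiPSC-derived cardiac cells. 200 nuclei are
packed by rejection sampling into a 160×160×64 μm field (0.5 μm/px,
1 μm z-steps) with a hard 14 μm minimum center spacing, matching the
separable-nuclei regime the reconstruction assumes; placement aborts with
an explicit error after 10⁴ failed tries for any nucleus. Identities
follow an exact largest-remainder allocation of the recipe composition
(default 70/15/15 CM/EC/CF, the standard tri-culture mixture; ties go to
the earlier-listed identity), not a stochastic draw, so composition
recovery can be asserted tightly. Each identity's marker channel paints
the nuclear footprint at 150 a.u. (off-target channels at 10 a.u. to
emulate bleed-through); DAPI paints every nucleus at 170 a.u.; Ki67 paints
a proliferative subset (20% by default) and, optionally, 45°-oriented
fibrous streak distractors spanning the stack. Degradations: a
multiplicative planar illumination ramp (±7.5%), per-slice exponential
z-attenuation (0.4%/slice), a constant camera offset (8 a.u.), additive
Gaussian noise with SD 17 a.u. (10% of the nuclear signal) and 8-bit
quantization. Not emulated: the confocal PSF, cytoplasmic marker
localization, nucleus shape irregularity, motion or chromatic shifts —
so passing tests demonstrate the pipelines' correctness and noise
robustness at realistic SNR, not performance on aberrated optics.

**Striation images.** Synthesized in the Fourier domain: spectral energy
on the 1/spacing ring with a Gaussian angular amplitude profile of SD
`jitter_deg` about the +x axis and independent random phases. The angular
energy spread therefore equals the requested orientation jitter exactly
(no wave-sampling variance), zero jitter reduces to a single coherent
sinusoid, and jitter near 180° approaches an isotropic band-pass texture.
The Z-band period itself does not jitter; disorder is purely
orientational.

**Movies.** A Gaussian-smoothed random texture is warped by a cumulative
ground-truth displacement (bilinear resampling) — uniform translation or
a beat train in which each contraction is a sin²-shaped velocity pulse
followed by a slower relaxation returning the tissue to rest (relaxation
peak 0.6× the contraction peak by default, so contraction is the dominant
speed peak, as in real profiles). Per-frame velocity fields and peak-speed
profiles are emitted analytically.

**Traces.** APs are piecewise-analytic (resting −80 mV, 2 ms linear
upstroke of 110 mV, optional raised-cosine notch dip, exponential
repolarization with τ calibrated so APD90 from the Vmax instant is exact);
the notch-region minimum derivative is computed from the analytic
derivative on a dense grid. Default period 2 s so the repolarization tail
decays below the APD90 level long before the next diastolic window.
Beat series are strictly periodic with amplitudes affinely rescaled to an
exact sample CV. Calcium transients rise linearly over
`time_to_peak/0.9` (so the 10%-of-amplitude onset rule recovers the
requested time-to-peak exactly) and decay single-exponentially
(τ = 200 ms, 2 s period: ≥9 decay constants of recovery, keeping the
measured baseline clean).

## Nuclei segmentation

All 2D operators scale with one kernel radius, KR = 5 px — the minimal
radius of objects of interest at 0.5 μm/px. The chain per slice:
opening-subtraction with a 5·KR disk (lighting homogenization; large-radius
disks use the fast sequence decomposition of the footprint, an octagonal
approximation within 1 grey level of the exact disk), local-median
subtraction over an 8·KR square window (pixels at or below the local
median are zeroed), then median (KR disk) → Gaussian (KR/2 SD) → maximum
(KR disk) enhancement. 8-bit inputs take sliding-histogram rank-filter
paths; `segment_stack` quantizes its channel to 8 bit with a stack-global
min-max map so slice statistics remain comparable through depth.

**Binarization.** The enhanced slice is thresholded at its median plus
6 median absolute deviations. The pad matters: with continuous Gaussian
noise, a plain median threshold necessarily admits ~half of the
background, and the blur+maximum stages correlate that speckle into
clusters larger than the KR² area filter. Six MADs is a ≈4σ pad for
near-Gaussian background — chosen so the expected number of false
foreground voxels across a multi-megavoxel stack stays far below one
cluster — while nuclei sit ~10× above it; on clean images the MAD is zero
and the rule reduces to the plain median threshold.

**Seeds and flood fill.** Seeds are local maxima of the Euclidean
distance transform of the foreground (lightly smoothed, σ = 1 px, to
collapse discrete plateaus into single maxima) with minimum separation
KR. The foreground is partitioned by nearest-seed growth constrained to
the foreground (seeded watershed on the distance-to-seed map), which is
deterministic and order-independent. Objects under KR² px² are dropped;
an object n times a user split threshold is re-seeded with its n
strongest EDT maxima (ties by scanline order) and re-partitioned.

## 3D reconstruction

Sections are summarised by moment-based ellipses rescaled to equal pixel
area (π·a·b = area exactly; degenerate collinear sets floor the minor
axis at 0.5 px); orientation is the principal-axis angle in (−π/2, π/2].
Overlap between ellipses of adjacent slices is measured by counting
common raster cells at 4× subpixel resolution (area error ≲1.5% against a
Monte-Carlo oracle); any shared area ≥ 1 px² is an interaction. Linking
is greedy and one-to-one per slice transition — candidates sorted by
descending shared area, ties by smaller section index — with new chains
started by sections lacking a previous-slice interaction. KZ is a hard
cap: a chain reaching KZ sections closes and its continuation starts a
new object; no minimum length is imposed. The condition table maps
day-7/21 cultures without fibroblasts to KZ = 18, with fibroblasts to 10,
CM+EC tissues to 46, and everything else to 36.

Ellipsoid fitting uses area-weighted mean in-plane semi-axes (μm) and
c = n_sections·z_step/2. The enhancement maximum filter dilates every
footprint by exactly KR, and the blur adds ≈1 px of boundary spread at
the low binarization threshold; `inplane_correction_px = KR + 1`
subtracts this known inflation, after which recovered volumes match the
rendered ground truth to ~10% (median ratio ≈ 1.0 on the reference
stack). The correction is off by default so the raw fitted geometry
remains available.

## Cell classification

Marker channels are Gaussian-smoothed (KR/2 SD per slice) and min-max
normalized per channel, which absorbs any per-channel gain; thresholds
(default 0.25 on the normalized scale) are user parameters, as threshold
choice against real stainings is inherently data-dependent. A section
votes for the above-threshold marker of highest mean intensity inside its
ellipse; the nucleus takes the modal vote, with ties resolved by the
higher chain-mean intensity ("unclassified" only wins when no marker ever
passes). Composition percentages are reported over classified nuclei,
with the unclassified share stated separately.

The presence/absence detector (Ki67, or COL1A1 where fibroblast identity
cannot be assumed) blurs (KR/2 SD), opens with a 135° digital line of
length 3·KR — longer than a fiber cross-section (~KR) but shorter than
the minimal nuclear diameter (4·KR), so diagonal fibers vanish and nuclei
survive; a 4·KR line was measured to crush borderline nuclei to
noise level — homogenizes lighting (5·KR opening subtraction), and zeroes
everything below mean + 3·SD of the processed stack. One SD is
insufficient against continuous noise (the processed background residual
reaches ≈6 background-SDs somewhere in a large stack), and per-slice
statistics degenerate on slices without genuine signal; the stack-wide
3-SD floor separates the measured residual tail from true staining with a
2–3× margin on both sides. A nucleus is positive iff its mean processed
intensity is strictly positive, measured inside its ellipses shrunk by KR
— undoing the maximum-filter inflation so staining spilling across a
~2 px inter-nuclear gap from a touching positive neighbour is not scored.
With these choices the detector holds sensitivity and specificity ≥ 0.95
across seeds on stacks with streak distractors.

## Spatial packing metric

Distances are Euclidean in μm (axial anisotropy enters through the
calibration before the metric). Each nucleus contributes the median of
its 12 nearest-neighbour distances (k capped at n−1; even-count medians
average the central pair); the tissue statistic is the mean and SD (n−1
denominator) of those medians. A kd-tree implementation is asserted to
agree exactly with an O(n²) all-pairs oracle; on a simple cubic lattice
the interior value is analytically d·(1+√2)/2.

## Sarcomere analysis

For 1D profiles the power spectrum is the rFFT power without DC. For 2D
images, the spectrum is collapsed along the dominant orientation (the
off-DC energy maximum): the 1D profile sums power per integer radius
inside a ±5° wedge about that axis, while the denominator of the index is
the angle-integrated radial power — misalignment moves energy out of the
wedge, lowering the peak without lowering the total, which is what makes
the index orientation-sensitive. The first-order peak is the dominant
local maximum within the physiological sarcomere band (1–3 μm spacing,
configurable); its support is ± the half-width at half-maximum; DC and
periods above 10 μm are excluded from the denominator so illumination
gradients cannot leak in. The index is gain/offset-invariant and bounded
in [0, 1] by construction; it decreases strictly with orientation jitter
on generated striations.

Sarcomere length is the mean Z-band peak-to-peak spacing (peaks by
prominence ≥ 10% of range, refined by parabolic interpolation), with the
spectral estimate 1/f₁ carried as a cross-check that must agree within 5%
on usable profiles.

## Contraction analysis

Horn–Schunck flow uses the original 2×2×2 cube-average derivative
stencils (applied by correlation, so motion toward +x gives positive u),
the 1/12–1/6 neighbour-average smoothness kernel, and Jacobi iterations
from zero flow — identical frames give exactly zero. Defaults: 100
iterations; α = 20 in brightness units, appropriate for 0–255 movies —
at α ≈ 1 the data term fits frame noise, producing a spatially correlated
resting-speed floor of ~25% of a typical contraction peak that defeats
beat segmentation, while α = 20 reduces it to ~2 μm/s with <2% bias on
recovered peak velocities. Frames are mean-normalized first to damp
global flicker.

Velocity *vectors* are averaged within 15×15 μm bins over a 300×300 μm
selection (centered by default) and the resultant's magnitude is the bin
speed — incoherent noise cancels inside a bin, coherent motion does not;
per-bin SDs across the constituent vector speeds are retained. Auto
selection fixes the single bin maximal at the recording's global peak
frame for the whole trace (per-frame re-selection would produce
discontinuous profiles); a manual position selects the containing bin.

Beats are contiguous supra-threshold runs (10% of the global peak) after
closing momentary dips shorter than 0.1 s — bridging the zero-speed
instant between the contraction and relaxation phases of one beat while
preserving inter-beat rest. Onset/offset are refined to 10% of each
beat's own peak with sub-frame interpolation; the contraction phase ends
at the trough between the beat's first and last speed humps. Upstroke and
relaxation velocities are the phase peak speeds; accelerations are the
extremal speed derivatives in the corresponding phase; beat duration is
onset-to-offset. At least 5 beats are required (configurable), matching
standard practice of averaging ≥5 contractions.

The pacing classifier uses the interval rate estimator
(n−1)/(t_last−t_first) and declares "follows" iff the rate is within ±15%
of the pacing rate and the amplitude CV (SD with n−1 over mean) is
strictly below 0.28. Contraction direction is atan2(v, u) per bin in
(−π, π], NaN-masked on zero vectors; normalized contraction duration is
CD/√IBI.

## AP and calcium analytics

Upstrokes are runs of dV/dt > 5 mV/ms sustained ≥ 1 ms (200 ms
refractory). RMP is the mean over the 50 ms before the upstroke; APA is
peak − RMP; Vmax the maximal dV/dt during the upstroke; APD90 runs from
the (first) Vmax instant to the interpolated crossing of peak − 0.9·APA;
features average over complete beats. The notch detector smooths with a
3-sample moving mean, differentiates, and takes the minimum over
[peak, peak + 50 ms]; a trace is notched iff that minimum is below
−3 mV/ms. Cutoff units are mV/ms (≡ V/s) and both cutoff and window are
configurable.

dF/F masks the tissue as maximum-projection pixels above mean + SD
(degenerate flat recordings fall back to the full frame and yield a zero
trace), subtracts the mean background-region intensity, and normalizes by
F0 = mean of the lowest-decile samples of F. Transient onsets are 10%-of-
amplitude crossings against the lowest-decile baseline; decay times are
interpolated crossings of 50% and 10% of amplitude above baseline;
transients without a complete 90% decay are excluded with a warning. The
caffeine ratio divides the first post-caffeine peak amplitude (from its
local pre-peak baseline) by the mean of the last four pre-caffeine
amplitudes.

## Problem sizes and limitations

The reference verification stack is 200 nuclei in 64×320×320 voxels
(segmentation + reconstruction ≈ 10 s, classification + Ki67 ≈ 7 s on one
CPU); movies are 96–128 px frames at 100 fps with 5-beat trains; traces
are sampled at 10 kHz (AP) and 1 kHz (calcium). These sizes make the full
suite and the acceptance script run in about a minute while leaving all
recovery margins comfortably wide of their thresholds.

Known limitations: the segmentation is 2D-first (no voxel-native 3D
segmentation) and assumes separable nuclei; linking handles no merges or
splits beyond the greedy one-to-one rule; the flow is single-scale
Horn–Schunck and underestimates displacements approaching a pixel per
frame (~5% at 0.5 px/frame with default iterations); identity thresholds
are user-set, as in the original semi-automated practice, and the
min-max normalization presumes each marker channel contains genuinely
positive cells; the alignment index's band, wedge and peak-support widths
are implementation-defined (the upstream plugin's exact windowing is not
public) — comparisons should use one configuration throughout a study.
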