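# Methods

This note documents the models and numerical choices behind `teledermo`:
what each stage computes, which parameters matter, what the synthetic data
does and does not emulate, and where the design was genuinely open.

## Profile features

A lesion is summarized by seven numbers. Four are texture statistics: the
weighted intensity-difference frequency `WIDF_{δ,θ} = Σ_i (ξ−i) f_i / ξ`
at inter-sample distance δ = 10 px and orientations 0°, 45°, 90°, 135°
(offset vector `(round(δ cos θ), round(δ sin θ))` in (row, col), θ
counterclockwise from the row axis; the 45° offset is therefore (7, 7)).
`f_i` is the *relative* frequency (counts normalized to sum to one) of
absolute gray-level difference `i` over all pixel pairs whose **both**
endpoints lie inside the lesion mask; normalization makes the statistic
image-size invariant and bounds it in (0, 1], and the in-mask restriction
makes it a lesion property rather than an image property. A constant
region scores exactly 1; heavier texture scores lower.

Three are shape features: the maximum Feret diameter (largest pairwise
distance between perimeter points, computed on the convex hull), the
box-counting geometric index of the boundary, and the contour steepness
`C_T = Var(D_r)/mean(D_r)` with `D_r` the centroid-to-perimeter distances
in trace order and *population* variance (sample variance would make the
value depend on an arbitrary trace resolution). Solidity
`S_I = PP²/(4πA_t)` and the pigment-deviation pair (mean and population
variance of the HSV V-channel gradient magnitude on a ~2-px boundary
band) are computed and reported but not placed in the profile.

Two estimator choices deserve a note:

* **Perimeter.** The ordered boundary is the marching-squares contour at
  level 0.5 (closed, non-self-intersecting, subpixel). Its polygon length,
  like an 8-connected chain code, hugs the pixel staircase and
  overestimates a smooth boundary by ~5–6 %, which would push a disc's
  solidity to ~1.11. `perimeter_length` is therefore the 4-direction
  Crofton estimate, which is unbiased for blob-like masks (disc r = 50:
  error < 0.5 %); the traced points still serve the radial-distance and
  diameter computations, which are insensitive to the staircase.
* **Geometric index.** Box counts `N_B(s)` are taken on dyadic grids with
  box side halving from half the boundary's bounding-box side down to
  2 px, anchored at the bounding-box origin. The index is the
  least-squares slope of `log N_B` against `log L_B` over the *fine*
  grids (`s ≤ side/8`): the two coarsest grids are area-dominated (a
  handful of boxes covers anything) and contaminate a single-scale ratio
  with the prefactor — a circle would read ~1.3. The slope estimator
  reads 0.99 for a rasterized circle, 1.00 for a line segment, and rises
  with boundary roughness, clipped to [0, 2].

Features are min-max scaled to [0, 1] by a `FeatureScaler` fit on the
training corpus and serialized beside the classifier: profile values share
a single watermark-strength weight α, so they must share one scale.
Out-of-range values at prediction time are clipped; constructing a DP from
unscaled values raises.

## Preprocessing

**Hair removal** re-implements the classic razor morphologically: a pixel
is a hair candidate when the maximum over grayscale closings with
9-px line elements at 0°/45°/90°/135° exceeds the original by more than 15
gray levels **and** a 7×7 median filter does too. The second condition is
load-bearing: the directional closing alone also fires on the lesion's own
boundary ring (locally it looks like one side of a dark line), while the
median filter erases thin lines but preserves region edges, so requiring
both isolates curvilinear artifacts. Flagged pixels (dilated by 1 px) are
replaced per channel by the maximal directional closing — the orientation
crossing the stroke — and a 3×3 median filter finishes the image. On
synthetic strokes of width 1–3 px the detector recovers ≥ 80 % of stroke
pixels at < 1 % false positives on moderate-texture lesions; very heavy
interior texture (the melanoma regime) can mimic hair darkness and is
inpainted too, which the classifier tolerates.

**Segmentation** decomposes the gray image one level with Daubechies-4,
thresholds the approximation band with Otsu (lesion = below threshold,
i.e. pigmented), and maps the half-resolution mask back to full resolution
compensating the analysis filter's phase offset (`dec_len − 2` pixels
under symmetric extension). After hole filling, a disk(2) opening, and
largest-component selection (raster order on ties), the mask is refined at
full resolution: the gray image is re-thresholded with Otsu and the
component overlapping the coarse mask replaces it (if it retains ≥ 25 % of
the coarse area). The refinement restores boundary detail the
half-resolution band cannot represent, which the geometric index needs.
Sharp-boundary lesions segment at IoU ≥ 0.9 against ground truth; very
soft, wide transitions (melanoma regime, 10-px luminance ramps) bottom out
near 0.7 because the rendered image genuinely does not contain the fine
boundary that the ground-truth mask records.

## Payload layouts and arithmetic

A DP is 7×7; N DPs collate three ways: `horizontal` (an ordered list of
blocks embedded separately with μ carrier samples between them; default
μ = 25), `diagonal` (block-diagonal 7N×7N, consuming 49 N² samples —
quadratic, so capacity for a 22,000-sample carrier is
⌊⌊√22000⌋/7⌋ = 21 DPs), and `sequential` (an R×⌈N/R⌉ block grid, one
class per row, R = 4). The sequential form carries two sample-count
conventions, both exposed: the published size rule `L = 49 (N/2)²` (used
for the headline 248-DP figure of 753,424 samples and the capacity
arithmetic 22000/(4·7) = 785 samples per column → 112 DPs), and the
"packed" count `49 R ⌈N/R⌉` that the embedded grid actually occupies.
They are mutually inconsistent in origin; the packed grid is what the
watermarking stage embeds. Serialized size is `N · 49 · 8` bytes — 392
bytes per profile, 97.2 KB for 248.

## SVD watermarking

The carrier maps into one of four domains: `time` (identity), `dct`
(orthonormal type-II), `dwt` (single-level, **periodization** mode — the
transform must be orthogonal, not merely invertible, because the receiver
re-applies it to modified coefficients; symmetric extension is redundant
and breaks the round trip), and `dst`. The DST is deliberately the classic
non-unitary DST-I pair (forward `M = dst1/2` with `M² = ((n+1)/2) I`,
inverse `dst1(·)/(n+1)`): the inverse maps a fixed-size coefficient
perturbation to a time-domain perturbation smaller by √((n+1)/2) — about
40 dB of carrier SNR at n = 22,000 — which is precisely why the DST
domain shows the best carrier quality and, symmetrically, the worst attack
robustness (the forward transform amplifies channel noise by the same
factor relative to the fixed-size payload). With an orthonormal DST both
effects would vanish and all four domains would be indistinguishable.

Embedding cuts the segment at `offset` (default 0; for dwt, within the
approximation band), multiplies it by β, reshapes row-major to the
payload's shape (rectangular SVDs with `full_matrices=False` handle the
4-row sequential grid), and runs `R = U S Vᵀ`, `D = S + αP`,
`D = U_w S_w V_wᵀ`, `R_w = U S_w Vᵀ`. The *amplified* `R_w` is written
back — the transmitted signal carries the loud segment. Extraction
re-transforms, takes the singular values `S_w*` of the received segment,
forms `D* = U_w S_w* V_wᵀ` and `P* = (D* − S)/α`, and recovers the
carrier as `U* S V*ᵀ/β` (the SVD sign ambiguity cancels because `U*` and
`V*` flip together). Side information `{U_w, V_w, S}` plus layout metadata
is persisted losslessly (npz); re-computing those factors instead of
persisting them would not reproduce the embedding. Noiselessly the round
trip is exact to ~1e-12 for every form, domain, α and β.

β matters only under attack, and only because the attack's noise power is
referenced to the **unamplified** carrier (the `ChannelConfig` default):
an attacker calibrates to the nominal programme level, so the singular
values of the amplified segment dwarf the noise and the extraction stays
in its linear regime. At β = 1 a −5 dB attack is comparable to the
segment itself and the sorted-positive singular values of the noisy matrix
bear little relation to the originals. Robustness saturates around
β ≈ 100–400 for the default study sizes.

## Channel and enhancement

The attack adds seeded white Gaussian noise at a stated SNR. Four receiver
filters are provided; all estimate noise blindly from the received signal,
and all default to a per-bin/per-window **median** statistic rather than
leading or trailing frames: with the payload at offset 0 the leading
frames are payload-loud, and the periodized DWT wraps a few loud samples
to the very end of the signal, so both ends are contaminated — the median
across frames is calibrated by the quiet majority. Spectral subtraction
works in the **power** domain (half-wave rectified), leaving loud payload
bins asymptotically unbiased; wavelet shrinkage uses the universal
threshold with **hard** thresholding by default (soft thresholding
subtracts the threshold from the loud payload coefficients and destroys
the watermark); the local-statistics Wiener uses the median of local
variances as its noise floor. A caveat inherent to blind estimation: fed a
noise-free *stationary* tone, the self-estimating filters attenuate their
own input (the signal is their noise estimate); they are meant for, and
tested on, nonstationary speech-like signals.

## Classification

A second-order polynomial SVM (kernel scale 1, offset 0, box constraint 1,
one-vs-one, SMO-style solver) on the seven scaled features; training
records stratified five-fold cross-validation accuracy. Prediction reads
the diagonal of each (extracted, de-noised) DP. Because clean-channel
extraction is exact to 1e-6 and the trained margins are far wider,
received profiles classify identically to the originals — asserted
bitwise in the end-to-end test.

## Synthetic data: what it emulates, what it does not

The generator renders one pigmented blob per image: a radially perturbed
ellipse (aspect 0.85) with a zero-mean unit-RMS harmonic boundary
modulation (wavenumbers 2–7, plus high-wavenumber harmonics whose count
grows with the irregularity amplitude, so box-counting complexity tracks
the regime), a sigmoidal luminance transition whose width is
1/edge_sharpness, a smooth interior texture field scaled to
`texture_contrast` gray levels, and 1–3-px quadratic Bézier hair strokes
40–60 % darker than the underlying pixel. Four parameter regimes stand in
for the four lesion classes, spread so that *all seven* selected features
separate the classes (between-class variance exceeds within-class variance
at 30 images per class, checked on ground-truth masks) and a quadratic SVM
reaches ≥ 0.9 five-fold CV accuracy through the full pipeline. Default
study sizes keep everything desk-scale: 160×160 images, 50 images per
class for the end-to-end run, a 22,000-sample 8 kHz carrier, 20-seed
replications for every stochastic trend.

The carrier is a stack of amplitude-modulated harmonics of a random
100–160 Hz pitch plus band-limited noise: zero-mean, peak < 1,
syllabic-rate envelope. It is speech-*like*, not speech.

None of this claims dermatological realism: there are no pigment networks,
globules, ruler marks or vignetting, the palette is fixed, and class
regimes are parameter presets rather than biology. Passing tests therefore
demonstrate that the *pipeline* — compression, embedding, transmission,
recovery, diagnosis — behaves as published under controlled conditions;
they do not certify accuracy on clinical images, and the published
accuracies on the real 1400-image corpus are out of scope (that data is
not bundled). Trend properties (domain orderings, β monotonicity,
filtering equivalence) replicate; absolute SNR/SD/LLR values depend on the
carrier recordings and are reported, not asserted.

## Degenerate inputs and tie-breaks

Uniform images raise a "no lesion detected" error; empty masks, zero-mean
radial distance, sub-4-px boundaries, zero-variance correlations, and
frames with singular autocorrelation each raise or are skipped with a
warning as documented per function. Largest-component ties resolve to the
first label in raster-scan order. LLR uses LPC order 10 on 240-sample
frames (30 ms at 8 kHz) and skips frames below 1e-3 of the maximum frame
energy; spectral distortion uses non-overlapping 256-sample frames, an
FFT of the same size, and a −200 dB magnitude floor, averaging |ΔdB| over
frames and bins (the normalization of the published double sum is
ambiguous; mean-over-everything keeps the unit dB and the
identical-signals → 0 identity).
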