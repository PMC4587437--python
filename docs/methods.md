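# Methods

This note records the models, parameter choices, and numerical decisions
behind `lungcad`, and what the synthetic validation does and does not
demonstrate.

## Preprocessing: adaptive Wiener filter

Per pixel, with `μ` and `σ²` the mean and variance over a sliding window
(default 3×3, odd dimensions enforced):

    F = μ + max(σ² − v², 0) / σ² · (I − μ)

The gain is clamped at zero — where local variance falls below the noise
floor `v²` the filter returns the local mean; an unclamped form would have
negative gain there. `v²` defaults to the mean of all local variances
("estimate"), a standard choice when the acquisition noise level is
unknown; a fixed HU² value can be configured. Borders use reflect
(symmetric) padding so no out-of-range HU values are synthesised at the
thorax edge. Because the clamped gain lies in [0, 1], the output is a
pixel-wise convex combination of the pixel and its local mean and can
never leave the input's value range.

## Lung segmentation

The HU histogram (default bin width 10 HU) is smoothed with a 5-bin
moving average; local maxima with prominence ≥ 1% of the largest smoothed
count *outside* the background band are kept. Referencing the prominence
to the non-background maximum matters: the −3024 HU padding spike can be
two orders of magnitude taller than the lung mode and would otherwise
mask it. Each smoothed maximum is snapped to the raw-count argmax within
the smoothing window (asymmetric neighbourhoods otherwise bias the
reported position), and raw-count maxima at a stricter 5%-prominence bar
are unioned in so that modes closer together than the smoothing width
(e.g. adjacent fat and muscle peaks) are still resolved. Counts are
zero-padded by one bin before peak finding so a mode in the first or last
bin is detectable.

Band assignment: background spike = tallest bin below −2000 HU; lung peak
= tallest maximum in [−1000, −400] HU; fat/muscle peaks = up to two
tallest maxima above −400 HU. The −400 HU split sits above the −500 HU
upper bound of lung parenchyma with margin.

Threshold: `T = (I_FM − I_L)/2 + I_L`, the midpoint between the lung peak
and the mean fat/muscle peak, hence always strictly between the two when
they differ (coincident peaks are tolerated and logged as degenerate).
After thresholding, only the largest connected component is kept as the
thorax (discarding the scanner table and bright artifacts); lungs =
`fill_holes(thorax) − thorax` with components below 0.5% of the image
area removed (airway/noise specks). One or two surviving cavities are
accepted; a single cavity spanning the midline is split at the column of
minimum thickness near the midline (merged anterior junction, logged).
Side naming follows radiological display: the component with the larger
centroid column is the patient's **left** lung. ROI bounding boxes are
0-based half-open ranges with a 5-pixel margin.

## AM-FM demodulation

The analytic image is built in the frequency domain by zeroing the
negative row-frequency half-plane and doubling the positive one (DC and
Nyquist rows at unit gain) — the standard discrete analytic-signal
construction, applied along the row axis, and the half-plane choice that
matches the filterbank below.

The filterbank has 25 ideal (brick-wall) supports on the FFT grid:
filter 1 a low-pass disc `|ω| < π/16`, then four annuli H `[π/2, π)`,
M `[π/4, π/2)`, L `[π/8, π/4)`, VL `[π/16, π/8)` — bandwidths halving per
scale — each cut into six 30° orientation wedges over the half-plane
(filters 2–7, 8–13, 14–19, 20–25). Ideal supports make the partition
property exact and testable: the 25 supports are pairwise disjoint and
tile the half-plane bin-for-bin. Two grid-level details: the outermost
(H) band's support extends beyond `|ω| = π` so the rectangular grid's
corner bins (radius up to π√2) are covered, and wedge boundaries are
half-open. Ringing from the sharp cut-offs is acceptable at ROI scale and
is what the amplitude gate below absorbs.

Per channel, IA `= |z|` and IP `= arg(z)` for the filtered analytic
response `z`; IF components are estimated as
`arg(z(k + s·e_axis) · conj(z(k))) / s` with variable spacing
`s = clamp(round(π / 2ω_c), 1, 4)` from the channel's radial centre
frequency `ω_c` — wider spacing lifts low-frequency phase increments
above the phase-difference noise floor, while `s = 1` at high frequency
avoids wrapping. Trailing borders replicate the nearest interior
estimate. Pixels with IA below 10⁻³ of the channel maximum report IF = 0:
phase is meaningless at null amplitude.

Dominant component analysis selects, per pixel, the channel with maximal
IA among those whose scale belongs to the active combination; the 11
combinations are {VL,L,M,H}, {LPF}, {VL}, {L}, {M}, {LPF,VL,L,M,H},
{LPF,VL}, {VL,L}, {L,M}, {M,H}, {H}, in that fixed order.

Demodulation runs on the full ROI rectangle (FFT-friendly); the feature
histograms below are restricted to masked lung pixels, so non-lung
corners never contribute.

## Histogram features

Per combination: 32 IA bins over [0, masked max] (adaptive range —
preserves histogram shape under global contrast changes), 32 |IF| bins
over [0, π] rad/pixel (values clipped), and 32 IP bins over (−π, π]
circularly rotated so the modal bin sits at centre index 16 (the only
centring consistent with a wrap-around phase histogram; only IP is
centred). Each 32-bin block is normalised to unit *mass* (sum = 1), not
unit area — bin widths differ per block and the classifiers consume
unitless vectors. 11 combinations × 96 values = 1056 columns per lung.
A consequence of the construction worth noting: the DC bin belongs to no
filter support, so feature rows are exactly invariant to a constant HU
offset of the ROI.

## PLSR reduction

Sequential PLS (NIPALS via scikit-learn, `scale=False`) on mean-centred
columns — no variance scaling, since histogram bins already share a
unit-mass scale. The x-scores are mutually orthogonal, so the cumulative
fraction of response variance explained by the first k factors,
`Σ_{j≤k} (t_j·y_c)²/|t_j|² / |y_c|²`, is non-decreasing by construction.
The selected factor count is the smallest k reaching the threshold
(default 0.90); if never reached, all fitted factors are used with a
warning. Reduction is projection to factor scores, not selection of
original columns. Inside every cross-validation repeat the PLSR is
refitted on the training split only — reusing whole-data factors would
leak label information into the holdout.

## Classification and evaluation

KNN (K = 5, odd, Euclidean), SVM (linear kernel, C = 1), Gaussian naive
Bayes, and a linear discriminant (Fisher LDA, pooled covariance) — all
configurable. Leave-M-out is realised as repeated stratified random
holdouts of size M (default 50 repeats): exhaustive enumeration of
C(n, M) splits is combinatorially infeasible beyond M = 1, for which an
exact leave-one-out mode exists (every sample tested once, pooled
confusion reported). Sensitivity, specificity, and accuracy follow the
usual confusion-count ratios in percent; a zero-denominator ratio is
reported as missing rather than 0.

## Synthetic phantoms

The phantom emulates exactly the structure the pipeline exploits:
background −3024 HU, elliptical fat/muscle thorax at −50 HU, two lung
ellipses at −700 HU (centres of the published HU bands) with band-limited
texture (Gaussian-smoothed white noise, sd 60 HU, correlation length
1.5 px), optional nodule disc at +20 HU — above −500 HU, as real
malignancies are — with a mildly roughened halo (2.5 radii, +50% texture
sd) so that *texture*, not only mean HU, separates the classes, plus 5 HU
global noise. `make_dataset` jitters geometry ±5%, centres by a few
pixels, and nodule radius over 1.8–3% of the image width, one nodule per
slice with alternating side — so n slices yield exactly n cancer and n
normal lungs. All randomness flows through one seeded generator per call.

What the phantoms do **not** emulate: ribs, vessels, airways, the scanner
table, beam hardening, juxtapleural nodules, or 3D anatomy. Passing the
synthetic suite therefore demonstrates the pipeline's internal
correctness and end-to-end separability under its stated model
assumptions — not clinical performance on real CT, which requires real
labelled data.

Closed-form AM-FM test images (pure sinusoid, Gaussian-AM sinusoid,
radial chirp) carry their exact IA/phase/IF, giving the demodulator an
analytic oracle; recovery tests draw carriers from channel-passband
interiors, since estimates at brick-wall band edges are dominated by
filter truncation of spectral leakage rather than estimator error.

## Problem sizes and determinism

The test suite and the acceptance script run the study at: 512×512
phantoms (83 for the ROI count, 20 jittered for segmentation and for the
classification demo → 40 lung ROIs), 128×128 AM-FM recovery images (10),
and PLSR recovery at n = 100, p = 1056. The end-to-end demo evaluates
M = 0.4n holdouts over 50 repeats. Every entry point takes an explicit
seed; reruns are bit-identical (the feature CSV reproduces byte-for-byte).

## Known limitations

- Single-slice 2D processing; no volumetric context.
- Ideal filters trade passband smoothness for an exactly testable
  partition; smooth (e.g. Gabor-like) prototypes would reduce ringing.
- The IF spacing rule is a simple centre-frequency heuristic; a fully
  adaptive per-pixel spacing could do better near channel edges.
- Histogram thresholding presumes the tri-modal HU structure; slices
  with extensive consolidation or pleural effusion would violate it.
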