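# Methods

This note documents the models, conventions and numerical choices behind
the package, including the places where the design was genuinely open and a
choice had to be made.

## Synthetic grasp generator

The generator emulates the statistical structure of tactile-glove grasping
recordings that the sparsification survey exploits; it is a statistical
stand-in, not a biomechanical model.

**Model.** Each trial is `frames(t, r, c) = P · e(t) · s(r, c) + ε`,
quantized to the ADC grid:

* `e(t)` — a C¹ smoothstep rise/plateau/fall bump, exactly zero before the
  grasp onset and after its release, with rise/fall time constant
  `temporal_smoothness`.  A smooth unimodal envelope matches the
  low-frequency grand-average shape of real grasp interactions; the
  smoothstep form was chosen over a logistic-difference bump because the
  generator's contract requires the signal to be exactly zero outside the
  grasp window, which no logistic satisfies.
* `s(r, c)` — a sum of `n_blobs` spatial Gaussians (σ = `blob_width`
  taxels) with random centers and relative amplitudes in [0.6, 1],
  normalized to unit peak over the masked-in taxels.  Contact patches on a
  grasped object are spatially compact; Gaussians are the minimal smooth
  model of that.
* sensor mask — the physical sensor layout of the emulated glove (548 of
  1024 grid positions) is not published, so the mask is a fixed seeded
  uniform subset; masked-out taxels are identically zero.
* `ε` — Gaussian sensor noise (σ = `noise_sd` counts) added on masked-in
  taxels before clipping to `[0, 2^bit_depth − 1]` and rounding.  Gaussian
  noise is the simplest model consistent with the use of a low-pass
  denoiser; the real glove's noise distribution is not characterized in
  public sources, so this is a stand-in, not a claim about the device.

**Defaults** (the study conditions): 32×32 grid, 548 active taxels, grasp
from 1.5 s to 6.5 s (~5 s hold) inside an 8 s trial, peak pressure 600
counts on the 10-bit scale, 3 blobs of σ = 2 taxels, noise σ = 2 counts,
sampling rate 32 Hz.  The frame rate of the source glove is not printed in
public descriptions; 32 Hz is a realistic tactile-array rate and gives 256
frames per trial, a convenient dyadic length for multilevel transforms.
Under these defaults about 10% of samples exceed 1% of peak pressure — the
spatiotemporal sparsity the survey exploits.

**Trial jitter.** Datasets draw per-trial onset shifts (σ = 0.2 s),
amplitude scales (1 + N(0, 0.1), floored at 0.1) and blob-center
perturbations (σ = 1 taxel) from independent seeded streams.  The sensor
noise stream is a deterministic function of the trial's realized parameters,
so a zero-jitter dataset consists of exactly identical recordings — a
contract the tests rely on — while jittered trials receive independent
noise.

**What the generator does not reproduce:** per-object grasp signatures,
slip/regrasp transients, sensor crosstalk and drift, non-Gaussian heavy-tail
noise, and the true glove layout.  Tests passing on this generator therefore
certify the pipeline's correctness and the qualitative structure of its
findings (e.g. the dimensionality ordering), not the numeric values any real
dataset would produce.

## Denoising

A second-order Butterworth low-pass at a pass-band edge of fs/7, applied
independently to each taxel's time series.  Only the order and the pass-band
fraction of the procedure are fixed by its description; the filter family
(Butterworth: the least-surprising maximally flat second-order IIR), the
reading of "pass-band frequency" as the −3 dB edge, and the phase handling
are this package's choices.  The default is zero-phase forward–backward
filtering so that temporal-error comparisons downstream are not biased by
phase lag; `causal: true` switches to a single forward pass.  Recordings
shorter than the filtfilt warm-up length (3 × max(len(a), len(b)) samples)
are rejected.

## Transforms

Multilevel DWTs are computed with PyWavelets (`wavedecn`/`waverecn`) along
the time axis (1D), the two spatial axes per frame (2D), or all three axes
(3D).  Decomposition depth follows `N = ⌊log₂ L⌋` with `L` the
transform-axis length in 1D and the smallest transformed dimension in 2D/3D.

**Extension mode.** Periodized extension is the default: the coefficient
count then equals the sample count, which makes the sparsity and NBP
denominators unambiguous.  Symmetric (expansive) extension — the default of
the toolbox the original survey used — is available as
`transform.extension_mode: symmetric`; results under the two modes differ
slightly because the expansive mode carries extra boundary coefficients.
Periodized reconstruction was verified to hold to ≤1e−12 relative error for
every PR-exact registry wavelet at full depth in all three dimensionalities,
including cases where deep-level subbands are shorter than the filter.

**Subband order.** Coefficients are serialized as [a_N, d_N, …, d_1] with
orientation keys sorted lexicographically within a level (1 band per level
in 1D, 3 in 2D, 7 in 3D).  The order is fixed so that bit accounting and
top-k tie-breaking are bit-for-bit reproducible.

**Registry.** 75 named wavelets in 12 families.  56 are backed by filter
quadruples (Daubechies incl. haar, Coiflets, Symlets, Discrete Meyer,
BiorSplines, ReverseBior).  For six families — Fejér–Korovkin,
Best-localized Daubechies, Morris minimum-bandwidth, Beylkin, Vaidyanathan,
Han linear-phase moments (19 wavelets) — no published filter taps are
available to this package; their entries carry `implemented=False`, surveys
record them as `unimplemented` rows, and no approximation is substituted.

**The dmey exception.** The canonical 62-tap discrete Meyer filter is a
truncation of an ideal infinite filter and only quasi-orthogonal
(‖lo‖² ≈ 1.0022): its reconstruction error floor is ~3e−3 relative in every
extension mode, in any toolbox.  It therefore cannot satisfy the 1e−7
perfect-reconstruction invariant that defines a valid filter quadruple here;
it remains usable in surveys but is flagged `pr_exact=False` and excluded
from exact-reconstruction guarantees, and very low error targets may be
unreachable with it (reported as unconverged, never silently).

**DCT baseline.** Orthonormal type-II DCT over the same axes as the DWT of
matching dimensionality, unblocked (one global transform per slice, the
same granularity as the DWT).

**1D granularity.** One transform per taxel per recording (the full trial
time series), vectorized across taxels — not one transform over a
concatenated dataset.

## Quantization and metrics

* Quantization: `w_q = Q · fix(w/Q)` with `fix` truncating toward zero,
  including for negative coefficients.  All subbands, including the
  approximation, are quantized.
* NMSE: `mean((y − ŷ)²) / mean(y)`.  Dividing by the signal mean rather
  than the mean square makes the quantity scale-covariant (rescaling data
  and target together leaves results invariant) and dimensionally odd, but
  it is the survey's definition and is implemented verbatim; a
  variance-normalized variant exists behind `sparsify.normalization:
  variance` and is never the default.  A zero-mean signal is a degenerate
  input and raises.
* Sparsity: nonzero coefficients over the input length (fraction; percent
  formatting is a reporting concern).
* NBP: nonzero count × b over the input length, with
  `b = 1 + ⌈log₂(max|k| + 1)⌉` bits per nonzero value and `k` the integer
  quantization indices.  This sign+magnitude fixed-width accounting is the
  closest literal reading of "bits necessary to represent the nonzero
  values"; it counts no positional/index overhead and is not an entropy-coded
  rate.  NBP can tick up locally when max|k| crosses a power of two but
  falls over decades of Q.
* Energy ratio: Σw_q²/Σw² ∈ [0, 1]; truncation toward zero never increases
  a coefficient's magnitude, so ER ≤ 1 always and ER and sparsity are
  non-increasing in Q.

## The Q search

Binary search on log Q over [1e−12 · max|w|, 2 · max|w|]; the upper bound
quantizes every coefficient to zero, so it brackets the maximal achievable
NMSE.  The search assumes NMSE is monotone non-decreasing in Q, which holds
to fine granularity on realistically sized recordings; on very short signals
(tens of samples) NMSE(Q) oscillates at the few-percent level because single
coefficients cross the threshold, which bounds the achievable convergence
tolerance there.  Defaults: tolerance 1e−4 × target, 60 iterations.
Non-convergence — including targets below the reconstruction floor or above
the all-zero ceiling — is flagged in the result and such cells are excluded
from rankings, never silently dropped or returned as converged.  Metrics
are computed at the best Q visited.

## Survey aggregation

One pooled NMSE per recording (n = the full sample count of the recording);
the search runs per recording and the three metrics are arithmetically
averaged across recordings for each (wavelet, dimensionality, target) cell.
Whether the original survey pooled over recordings, grasps, or the
concatenated dataset is not stated in public descriptions, so exact
reproduction of its table may depend on matching that convention; the
per-recording choice is recorded here as this package's convention.
Rankings sort converged cells only — ascending for sparsity and NBP,
descending for energy ratio — with ties broken lexicographically by wavelet
name.

## Diagnostics

* **Top-k curves**: keep the k largest-magnitude coefficients (ties broken
  by position in the fixed subband order, earlier kept), invert, score NMSE
  and PSNR.  For orthogonal wavelets, largest-coefficient selection is the
  best k-term approximation, so the curve is non-increasing in k.
* **Error decomposition**: NMSE per masked-in sensor (over time) and per
  frame (over masked-in taxels).  Zero-mean slices are degenerate under the
  NMSE definition and enter the profiles as NaN; summaries ignore them and
  report how many were dropped.  Per-slice NMSEs average exactly to the
  pooled NMSE only when all slices share the same mean; otherwise the two
  aggregations differ, which is documented rather than hidden.
* **Grand average**: per-trial total masked activity, aligned at onset (the
  first frame exceeding 10% of trial peak — the alignment rule is this
  package's choice), cropped to the common aligned length (cropping rather
  than per-trial stretching so onset jitter does not dilate trials
  differently), averaged with a per-frame standard deviation.
* **Filter-length trend**: OLS of sparsity on filter support length over
  converged 1D cells at one target, with the standard 95% CI of the slope.
* **Scaling similarity**: signed normalized cross-correlation (matched-
  filter convention: mean-removed, unit-normalized over full support,
  evaluated at the shift of maximum magnitude) between the cascade-algorithm
  approximation of the scaling function (5 iterations; the synthesis-side
  function for biorthogonal pairs, since reconstructions are built from it)
  and a temporal template.  It is a descriptive shape statistic: the sign is
  reported (an inverted template gives −1), and plateau-like templates can
  legitimately anti-match a peaked scaling function.

## Problem sizes and determinism

Desk-scale runs use ten 256×32×32 trials (≈2.6 M samples); the survey
drivers use a ten-wavelet reduced registry at these sizes, which keeps a
full sweep within a couple of minutes on one CPU while preserving the
dimensionality ordering and ranking structure.  Everything downstream of the
generator is deterministic given the dataset and configuration; the
generator itself is a pure function of (model, seed).  The CLI logs the
config hash, seed, registry version and convergence counts for every run.

## Known limitations

* 19 of the 75 registry wavelets lack published filter taps here and are
  carried as explicit unimplemented entries; rankings over the full registry
  are correspondingly partial.
* dmey participates in surveys but has a ~3e−3 reconstruction floor
  intrinsic to its truncated filter.
* NBP is payload accounting, not a real codec rate (no entropy coding, no
  index/positional cost).
* The NMSE definition divides by the signal mean; comparisons with
  variance-normalized errors from other work require the config switch.
* The synthetic generator's amplitude and noise distributions are stand-ins;
  quantitative survey values on real glove data will differ, and the
  published full-dataset table can only be checked with the real recordings
  on disk.
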