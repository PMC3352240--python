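# Methods

## The model

Aligned spikes are treated as d-dimensional vectors x(i) (d = 64 samples,
~2.56 ms at 25 kHz, absolute peak fixed at index 20). PCA-based sorting
projects each spike onto the leading l eigenvectors of the spike covariance
and clusters the scores. The eigenfilter replaces the covariance/eigen-
decomposition route with the generalized Hebbian algorithm (Sanger's rule):
for each presented zero-mean spike x,

    y  = W x                       (scores, length l)
    dW = η ( y xᵀ − LT(y yᵀ) W )   (LT zeroes above the diagonal)
    W ← W + dW

The LT operator deflates: row i of W is repelled from the subspace of rows
1..i−1, so at convergence row i approaches the i-th unit eigenvector. The
learner is run in two regimes:

- **Batch (HE)**: all n spikes are stored; the mean is computed over them,
  all are centered, and the learner cycles through the stored spikes in
  order until N presentations have occurred. The coupling between the
  presentation counter and the spike index is resolved as cyclic
  (presentation j uses spike (j−1) mod n); the streaming regime has no such
  ambiguity.
- **Stream (SHE)**: the first n spikes are only accumulated into the mean
  and discarded; the next N spikes are centered with the frozen mean and
  presented once each. This assumes pseudo-stationarity — waveforms and
  their statistics are stable across adjacent ~1000-spike blocks — which the
  block-mean error statistic (below) quantifies directly. The implementation
  holds exactly one spike vector at any time (an instrumentation hook
  reports the retained count so the contract is testable).

## Parameters and defaults

| parameter | default | meaning / rationale |
|---|---|---|
| d | 64 samples | spike window, ~2.5 ms at fs = 25 kHz |
| peak index | 20 | ~0.8 ms of pre-peak context |
| l | 2 | components kept (3 supported) |
| n | 1024 | spikes consumed for the mean |
| N | 1024 | learning presentations |
| η₀ | 0.1 | initial learning rate |
| W init | 0.5 | all weights (plus symmetry-breaking term, below) |
| w | 16 bits | word length in the memory model |

Two numerical choices depart from the plain textbook recipe, both made
because the plain form demonstrably stalls:

1. **Learning-rate schedule.** η decays harmonically,
   η_j = η₀ / (1 + (j−1)/τ) with τ = 2048, so η has fallen only to ~⅔ η₀
   after N = 1024 presentations. A much faster decay starves the second
   component (its effective rate is η·λ₂, and λ₂/λ₁ ≈ 0.1–0.25 on realistic
   spike blocks), while constant η leaves more late-stage jitter on the
   first component. A constant-η option is provided.
2. **Symmetry-breaking initialization.** With every weight equal, all rows
   of W are identical, which is a degenerate saddle of the GHA dynamics:
   after deflation the trailing rows must regrow from numerical residue and
   stall when the eigenvalue ratio is large. Rows 2..l therefore receive a
   small deterministic cosine perturbation (amplitude 0.05, one cycle count
   per row); the l = 1 case and the configured init level are untouched.

Inputs are also rescaled before learning so the RMS norm of centered spikes
is ≈ 1. The scale is estimated during the mean phase from running sums
(E‖x−μ‖² = E‖x‖² − ‖μ‖², so no spike storage is needed) and frozen. GHA
step-size stability depends on η‖x‖², so this makes the defaults
independent of the recording's amplitude units.

## Synthetic benchmark generator

The generator emulates single-channel extracellular recordings:

- **Templates**: difference-of-Gaussians biphasic waveforms (narrow
  depolarization peak, wider delayed trough), peak-normalized, with widths,
  trough delays and depths spread across neurons plus seeded jitter;
  pairwise correlation is checked < 0.99. Peak amplitudes are spread ±15%
  around 100 arbitrary units.
- **Firing**: per-neuron Poisson trains with a 2 ms refractory dead time;
  the exponential rate is adjusted so the expected count is exactly
  rate·duration. Overlaps across neurons are allowed; bursting is not
  modelled. Defaults: 100 s at 25 kHz.
- **Noise**: a Poisson train of 0.3×-attenuated templates (background
  units) plus white Gaussian noise. SNR is defined as mean template peak
  amplitude divided by the standard deviation of spike-free segments —
  a noise "level" made directly measurable — and the white-noise
  amplitude is solved against the measured background floor so the realized
  SNR matches the request within 5%.
- **SNR grid**: 11 levels {3.0, 3.5, 4.0, 4.5, 5.0, 5.5, 6.0, 7.0, 8.0,
  9.0, 10.0}, spanning near-chance classification (TPR ≈ 0.4) to
  near-perfect. The source literature never maps its noise levels to
  numbers; this grid covers the regime where published benchmark curves
  live (graceful degradation), not the deep-noise chance floor where
  energy-threshold detection itself collapses.

What the generator does **not** model: electrode-array geometry, waveform
drift and other non-stationarities, bursting, per-spike amplitude
variability, overlapping-spike decomposition, and colored (band-limited)
recording noise. Passing tests on this benchmark therefore show that the
streaming learner matches batch PCA under stationary conditions with
realistic waveform diversity and noise energy — they do not certify
robustness to drift or overlap, which the pseudo-stationarity assumption
explicitly excludes.

## Detection stage

Detection runs on a zero-phase Butterworth band-pass (300–3000 Hz, order
4) of the trace — the standard spike band; with full-spectrum white noise
the NEO floor would otherwise drown moderate spikes at the fixed threshold
rule. The NEO energy ψ(n) = x(n)² − x(n−1)x(n+1) (boundaries zero;
optional Bartlett smoothing, off by default) is thresholded at
8 × mean(ψ), upward crossings within 1.5 ms of a previous one are
suppressed, and each crossing is refined to the local absolute-amplitude
peak within ±1 ms. Aligned 64-sample windows are cut from the **raw**
trace (so feature extraction sees the unmodified waveform and its full
second-order structure), re-centering up to three times until the window's
absolute maximum sits at the peak index; boundary and duplicate events are
dropped and counted. Alignment on the absolute peak handles either
polarity.

## Evaluation statistics

- **error_mean** = Σ|μ₁−μ₂| / Σ|μ₂|: relative L1 discrepancy between the
  mean-phase mean and the learning block's true mean; the direct test of
  pseudo-stationarity.
- **error_pc** = 1 − |ŵ·p̂|: deviation between a learned weight row and
  the corresponding reference eigenvector, after unit normalization; zero
  for parallel or antiparallel vectors (eigenvector sign is arbitrary, so
  the absolute value is taken; orthogonal vectors give exactly 1).
- **TPR / FPR**: detections are paired one-to-one with ground-truth spikes
  (greedy nearest-in-time within ±0.5 ms); clusters are assigned to
  neurons by the Hungarian method maximizing correctly classified spikes;
  TPR averages, over matched neurons, correct spikes over *all* truth
  spikes of that neuron (missed detections count against it); FPR averages
  false spikes assigned to a neuron over that neuron's false-spike pool
  (other neurons' paired spikes plus unpaired detections). Surplus
  clusters stay unmapped and contribute only through the false pools.
- K-means uses K = the true neuron count with 10 seeded restarts;
  automatic model selection is out of scope.

## Complexity accounting

Per presentation the learning kernel costs 3ld + l(l+1)/2·(d+1)
multiplications (y = Wx; the lower triangle of yyᵀ; yxᵀ; LT·W; the η
scaling) and l(d−1) + d·l(l−1)/2 + 2ld additions; mean-phase additions are
excluded from the accounting, and the mean division by a power-of-two n is
a hardware shift, so divisions and square roots are zero. These formulas
are verified against an instrumented scalar evaluation that counts every
multiply and add and doubles as a brute-force oracle for the vectorized
update. Memory: n·d·w for the batch variant's spike buffer; (d + l·d)·w
for the stream variant's mean and weights; the conventional baselines add
covariance/eigenvector workspaces (2d²w; 3d²w for the QR route) to the
spike buffer. Baseline operation totals (orthogonal iteration, symmetric
QR, Jacobi, 8 solver iterations) are carried as published reference
constants, valid only at the default problem size — their constant factors
are not re-derivable from the algorithm descriptions, so the package
refuses to scale them.

## Benchmark problem sizes and known limitations

The accuracy experiments use full-scale 100-s trains (≈3000 detected
spikes, n = N = 1024) for the component-deviation and block-mean checks (5
seeds at SNR 4), and the full 2/3/4-neuron × 11-level grid at 5 seeds with
block sizes adapting to the detection yield for the sorting-parity and
trend measurements.

Known limitations, measured during development:

- Near the clustering transition of the 4-neuron benchmark, K-means on
  stream-learned versus reference-PCA features occasionally settles in
  different, near-degenerate global optima (per-run TPR differences up to
  ~0.3 in a minority of runs at those levels), so 5-seed medians can
  diverge there for unlucky seed sets even though typical per-run parity
  is ≤ 0.02.
- Median FPR falls steeply across the grid (≈0.45 → 0.01) but is not
  strictly monotone at ±0.005 resolution: small systematic bumps occur at
  the pre-transition plateau (where a neuron pair is still merged) and at
  the saturated floor. Median TPR is monotone in every configuration
  measured.
- The single-pass learner resolves component i only when the eigengap
  λᵢ−λᵢ₊₁ is a few percent of the total variance (roughly
  η·(λᵢ−λᵢ₊₁)·N ≳ 3 after input scaling); benchmarks whose second
  component is noise-dominated leave w₂ direction-undetermined, as any
  one-pass method must.
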