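# Methods

This note documents the models, numerical choices, and known limitations
of the `eodchirp` pipeline in the order the method runs.

## Oscillation-level signal model

The EOD of a single wave-type fish is treated as a narrow-band
quasi-sinusoid `v(t) = A(t) sin(2π ∫ f(τ) dτ)` with `f` in the species
band (650–1000 Hz) and both `f` and `A` varying slowly except during
chirps. All downstream analysis operates on the per-oscillation series
`(T_k, f_k, A_k)`: the upward-zero-crossing time, reciprocal period, and
half peak-to-peak amplitude of each EOD cycle.

**Extraction.** The trace is processed in `window_s = 3` s windows
advancing by `window_s − overlap_s = 1` s. Per window:

- The fundamental is the highest-power FFT peak inside the search band
  (default 500–1200 Hz, bracketing the species range), refined below bin
  resolution by quadratic interpolation of the log power. A window whose
  peak is less than 100× the in-band median power (20 dB) is declared
  carrier-free and contributes a gap; this rejects white noise (whose
  max/median power ratio is ~10 for these window lengths) while passing
  any physiological carrier.
- The window is band-passed to `[0.5, 1.5]·f0` with a zero-phase
  (forward–backward) 4th-order Butterworth filter. Zero phase is
  essential: causal filtering would shift crossing times.
- *Edge handling:* band-pass filtering a finite window leaves an edge
  transient that biases the first/last dozens of crossing estimates by
  several Hz. Before filtering, each window is therefore extended on
  both sides by a sinusoid at `f0` least-squares-fitted to the
  outermost four carrier periods (40 periods of padding), and the
  extension is cropped afterwards. For a locally sinusoidal carrier
  this removes the transient entirely; measured residual error on a
  pure tone is < 0.04 Hz and < 0.4% in amplitude at every crossing.
  For a carrier whose frequency is changing at the window edge the
  fixed-frequency extension is approximate; the affected crossings are
  the outermost few of the whole recording only, since interior window
  seams are covered by the stitching rule below.
- Upward crossings (`v_i < 0 ≤ v_{i+1}`) are located with linear
  sub-sample interpolation. Each window only reports oscillations whose
  crossing time falls in its central advancing sub-interval (the first
  window also covers its leading edge, the last its trailing edge), so
  the overlapping windows partition the time axis and no oscillation is
  duplicated or lost at seams.

Amplitude is half the peak-to-peak of the *filtered* voltage within the
oscillation interval, making it robust to DC offsets and out-of-band
noise. Segmentation into `n_s` equal-length segments assigns boundary
points half-open (`[lo, hi)`, last segment closed), giving a
deterministic partition.

## Ground-truth sample processing

An annotated chirp sample is the series points inside the annotated
interval; annotators are assumed to include pre- and post-chirp baseline
points. Base frequency and amplitude are medians of the pooled first and
last `n_med = 10` points. Normalization maps the peak frequency rise to
`φ = 1` exactly and expresses amplitude as a relative deviation `a`.

Centering uses a softplus rectifier
`h(φ) = ln(1 + e^{δ(|φ| − φ̄)}) / (δ − δ φ̄)` with smoothing `δ = 50`
and noise cutoff `φ̄ = 4·max(sd(first n_med φ), sd(last n_med φ))`
(unbiased n−1 standard deviation; the cutoff suppresses baseline jitter
while the rectifier grows linearly through genuine rises). `h` is
evaluated via `logaddexp`, so large arguments cannot overflow. The
center index is where the cumulative rectified mass crosses one half
(argmin `|H − ½|`, ties to the smallest index); samples whose cutoff
reaches `φ̄ ≥ 1` (edge noise as large as the peak itself) are rejected
as pure noise. The sample is trimmed to centered times within ±3× the
10–90% mass width, then re-windowed to the `10^r + 1` *raw* parent
points around the center (no interpolation), with `r` chosen so the
trimmed count lies in `(10^{r−1}+1, 10^r+1]`. Trimmed counts above 1001
are clamped to group 3 with a warning (chirps longer than ~0.5 s do not
occur physiologically); samples whose re-window would overrun the
recording edge are dropped rather than padded (padding would fabricate
oscillations). After re-windowing, `φ` and `a` are recomputed from the
raw points.

## Waveform model

Training rows are `[φ; a]` (frequency first, 2(10^r+1) columns).
Principal components are eigenvectors of `XᵀX` **without mean
centering** — deliberately different from conventional PCA. The
normalized waveforms already share a common baseline near zero, and the
uncentered decomposition keeps the back-projection `P_N μ` of a mixture
mean directly interpretable as a waveform. Components are ordered by
descending eigenvalue and oriented so each component's
largest-magnitude entry is positive (reproducible signs).

The projected scores are fitted with a full-covariance Gaussian mixture
(EM, k-means++ initialization, 10 restarts, covariance ridge `1e-6`,
tolerance `1e-6`, at most 500 iterations, mandatory seed). Each training
sample is assigned to its maximum-posterior component; the CoD of its
frequency waveform against the assigned component's back-projected mean
is `R² = 1 − ‖f − f̄_c‖²/‖f − mean(f)·1‖²` (constant waveforms score
−∞). A component is eliminated when its size falls below `δ_c` or the
5% percentile (linear-interpolation quantile) of its members' CoD falls
below `δ_R² = 0.3`; surviving proportions are renormalized to 1.

**Minimum cluster size at desk scale.** The default `δ_c = 30` presumes
training sets of hundreds of samples. A homogeneous training set of `m`
samples split over `C` components can only retain a component if
`δ_c < m/C`; with the synthetic studies' `m ≈ 40–60` the default would
eliminate everything. Desk-scale runs therefore scale the threshold to
`min(30, max(2, m/4))`; the detection thresholds and evaluation bands
are unaffected.

## Detection

Windows of `10^r + 1` oscillations slide one oscillation at a time over
the series (every full window is scored). Each window is normalized
exactly like a training sample from its own edge points; windows with no
positive rise cannot be normalized and are skipped (any positive `ε_f`
would reject them anyway).

- **MDB** accepts a window when its squared Mahalanobis distance to the
  maximum-posterior kept component is below the `1 − α` quantile of
  `χ²_N` (for scores truly drawn from a component the squared distance
  is exactly `χ²_N`) and its rise exceeds `ε_f`.
- **CDB** accepts when the best CoD against the kept mean waveforms
  exceeds `ε_R²` and the rise exceeds `ε_f`. CDB scores only the
  frequency half, so it is invariant to amplitude scaling.

Maximal runs of consecutive accepted windows become single events; the
representative window is the run's minimum-distance (MDB) or maximum-CoD
(CDB) window, ties toward the earliest. Event times are the
representative window's start time. Scoring is chunked (16384 windows
per block) so memory stays bounded on long recordings.

**TFSB baseline.** The reference detector matches the single-parameter
pulse `φ(T̃; α̃) = 2e^{α̃T̃}/(1 + e^{2α̃T̃}) = sech(α̃T̃)` (steepness
grid: 200 linear values in 100–800 s⁻¹) against 101-point windows, with
the template peak aligned to the window's frequency maximum. Two
choices fill gaps left open by the prior art this baseline represents:
(i) windows whose frequency maximum falls within the first/last `n_med`
points are skipped — those points are the baseline estimate, so a peak
there invalidates both the normalization and the alignment; (ii) the
event time is the matched peak time rather than the window start —
because the template is re-centered in every window, its fit quality is
nearly constant while the chirp lies anywhere inside the window, so the
best-fit *window position* is not time-locked to the chirp, whereas the
matched peak is. The template stack is evaluated in single precision
with preallocated buffers (the double-precision sums that form R² are
unaffected); this is the scan's dominant cost.

## Cross-validated evaluation

Ground-truth segments are shuffled (seeded) and split round-robin into k
folds. Per hyperparameter combination and fold, supervised detectors are
trained on the complement folds' samples (TFSB needs no training) and
run on the fold's segments. False positives are detections inside no
ground-truth interval (closed intervals spanning each processed sample's
first to last point); false negatives are ground-truth chirps containing
no detection; both pool counts over the fold's segments. Zero detections
define FP = 0, zero ground truth defines FN = 0 (the natural limits of
the ratios). Rates are averaged over folds; the optimizer minimizes mean
FN over combinations whose mean FP meets the budget (ties: lower FP,
then grid order), and `r_FN(r_FP)` curves are non-increasing by
construction. Training failures (e.g., all components eliminated) mark a
combination infeasible rather than aborting the search. Because the
trained model depends only on `(N, C)` and the training set, the
cross-validation factory caches models across threshold-only grid moves.

## Synthetic studies

The generator renders a phase-continuous carrier (`f0 = 750` Hz,
sampling 20 kHz) with slow Gaussian frequency jitter (sd 0.5 Hz, giving
a carrier cv ≈ 0.07%, inside the < 0.2% physiological bound) and slow
relative amplitude drift (sd 1%), both produced by smoothing white noise
on a 10 Hz grid. Chirps reuse the sech pulse family with the steepness
set so the pulse's full width at half maximum equals half the nominal
duration (e.g. ≈ 263 s⁻¹ for a 20 ms chirp, inside the TFSB grid).
Presets: type 1 (Δf 400 Hz, 50% amplitude drop, 20 ms, delayed negative
frequency lobe carrying 10% of the main lobe's area), type 2 (Δf 100 Hz,
8% drop, 20 ms, no undershoot), and a double-peaked 25 ms shape with
paired amplitude drops. Annotations span ±3 durations around each event
center, mirroring the instruction to include baseline points, and events
may not overlap.

The standard study used by the tests and the acceptance script is a
10-minute recording with 60 type-2 events in 12 equal segments, 3-fold
(tests) or 4-fold (acceptance script) cross-validation, and grids
`N = 2`, `C ∈ {2, 3}`, `ε_f ∈ {10, 20}` Hz, `ε_R² ∈ {0.3, 0.5, 0.7}`
(MDB: `α ∈ {0.01, 0.05, 0.10}`). These sizes keep a full run within a
few minutes on one CPU while leaving ~40 training and ~20 held-out
chirps per fold.

**What the synthetic studies do and do not show.** The generator
produces a single fish, stationary baseline, Gaussian noise, and chirps
drawn exactly from one waveform family. Passing them demonstrates that
the pipeline's mathematics — normalization, centering, training,
scoring, consolidation, bookkeeping — is implemented correctly and that
the detectors recover planted events at their nominal operating points.
It does not demonstrate robustness to movement artifacts, electrode
noise, multiple interacting fish, or chirp shapes outside the modeled
family; the near-zero synthetic error rates are a correctness check,
not a performance claim for real recordings.

## Numerical choices and degenerate inputs

- Argmin/argmax ties break toward the smallest index throughout
  (deterministic, reproducible).
- The rectifier and the sech template are evaluated via
  `logaddexp`/negative exponentials, exact to machine precision and
  overflow-safe for arbitrarily large arguments.
- Standard deviations use the unbiased (n−1) form; percentiles use
  linear interpolation between order statistics.
- Constant-frequency windows (zero total sum of squares) score −∞ CoD;
  zero-rise and zero-base-amplitude windows are flagged non-normalizable.
- Model files are JSON; Python emits the shortest decimal that
  round-trips each float64, so save/load restores arrays bit-exactly.
- One top-level seed is fanned out to fixed per-stage seeds (CRC-keyed
  seed sequences, all below 2³¹), so a single knob reproduces the whole
  pipeline byte-for-byte.

## Known limitations

- Single-fish recordings only; overlapping EODs from multiple fish need
  a source-separation front end.
- The crossing-based frequency estimate assumes the band-passed signal
  crosses zero twice per period; strongly non-sinusoidal or very low-SNR
  signals violate this.
- The uncentered decomposition ties component 1 to the dominant mean
  waveform; datasets dominated by two equally common shapes will split
  it across components, which is the intended behavior but differs from
  centered PCA intuition.
- Group routing assumes chirp durations under ~0.5 s; longer events are
  clamped into the largest group with a warning.
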