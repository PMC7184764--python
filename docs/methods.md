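# Methods

## Problem and pipeline

The package localizes the epileptic focus from *interictal* (between-
seizure) intracranial EEG.  The clinical ground truth is a per-channel
label: electrodes inside the seizure onset zone (SOZ) versus all
others.  The working hypothesis is that SOZ tissue emits more
high-frequency oscillatory activity — ripples (100–250 Hz) and fast
ripples (250–600 Hz) — so the complexity profile of the 100–600 Hz
band differs between SOZ and non-SOZ channels even between seizures.

The pipeline, stage by stage:

1. **Segmentation** (`ieegfocus.io`).  Each channel is cut into
   non-overlapping 20-s windows; a 30-minute recording at 2 kHz gives
   90 segments per channel of L = 40,000 samples.  Trailing remainders
   shorter than one window are dropped so every entropy estimator sees
   a fixed L.  Every segment of an SOZ channel is labelled focal — a
   deliberate simplification of the clinical annotation (labels live
   on channels, not on segments).
2. **Filter bank** (`ieegfocus.filterbank`).  A 3rd-order Butterworth
   bandpass extracts the global 100–600 Hz band, then ten contiguous
   50-Hz-wide 3rd-order Butterworth bands split it into subbands
   S1…S10.  Filters are applied forward–backward by default
   (`zero_phase=True`): subbands stay time-aligned, at the cost of the
   squared magnitude response absorbing roughly 15 % of the crossover
   energy (the causal single-pass mode, which partitions energy almost
   exactly, is a flag away).
3. **Entropy features** (`ieegfocus.entropy`).  Eight estimators per
   subband signal, ordered (APE, PE, Sh, Sp, Ts, S2, S1, Ren); see
   below.
4. **Sparse-LDA selection** (`ieegfocus.slda`).  Per subband, an
   elastic-net optimal-scoring fit keeps the G most discriminative
   entropies; the selected columns are concatenated across subbands
   into the classifier input V* (length N·G).
5. **ADASYN balancing** (`ieegfocus.adasyn`).  Focal rows are the
   minority; synthetic focal vectors are generated inside each
   training fold until the classes balance.
6. **SVM + evaluation** (`ieegfocus.evaluate`).  An RBF SVM is trained
   per fold; segment-level predictions are scored with the confusion-
   matrix metrics and the per-channel counts of detected focal
   segments are thresholded into a channel-level ROC/AUC.

## Entropy estimators

**Approximate entropy** (APE) and **sample entropy** (Sp) compare
delay-embedded templates X(i) = [x(i), …, x(i+d−1)] under the
Chebyshev (max-coordinate) distance with tolerance r = 0.2 × SD of the
subband signal, embedding d = 2.  APE is Φ_d − Φ_{d+1} with
Φ_m = mean_i ln C_i^m(r), self-matches included; Sp is −ln(A/B) with
both template sums taken over the first L−d templates and self-matches
excluded, so a no-match condition is possible and is reported as an
undefined sentinel rather than imputed.  The r scope is per subband
per segment, which makes both features invariant to channel gain.
The distance is switchable to Euclidean; Chebyshev is the field's
standard and the default.

Both estimators are O(L²).  The production path evaluates them on a
strided subsample capped at `max_samples = 4,000` points (a 20-s
segment at 2 kHz is subsampled 10:1); the exact path runs whenever the
input is already short, which covers every oracle comparison in the
test-suite.  Inside `entropy_vector` the two estimators share one set
of template-count arrays, which halves the cost and is verified to be
bit-equal to the standalone functions.

**Permutation entropy** (PE) uses ordinal patterns of length d = 3,
lag τ = 1, base-2 logarithm, ties broken by position (stable ranking).
It is bounded by log₂ d! = log₂ 6 and invariant to any strictly
monotone transform of the signal.

**Spectral entropies.**  The probability vector p_f is the one-sided
rectangular-window periodogram, DC bin excluded, normalized to sum 1.
Shannon: −Σ p ln p.  Rényi of order α = 2: (1/(1−α)) ln Σ p^α — the
standard form, which is ≤ Shannon for α > 1.  (A non-standard printed
variant (1/(1−α)) Σ ln p², which diverges on empty bins, is available
behind `literal_form=True` for comparison but is never used by the
pipeline.)  Tsallis with q = 2: (1 − Σ p²)/(q−1) ∈ [0, 1−1/F].

**Phase entropies** S1/S2 derive from the bispectrum
B(f1,f2) = E[F(f1)F(f2)F*(f1+f2)], estimated by the direct FFT method:
the segment is split into up to 31 non-overlapping demeaned epochs of
nfft = 1,024 samples, the triple product averaged across epochs, and
the principal triangular domain f1 ≥ f2 ≥ 1, f1+f2 ≤ Nyquist bin
retained.  S1 is the Shannon entropy of |B| normalized over the
domain; S2 the same for |B|².  S2 ≤ S1 always (squaring sharpens the
distribution).  The epoch count adapts downward for segments shorter
than 31 × 1,024 samples; fewer epochs means a noisier estimate, which
is acceptable for the desk-scale runs that use it.  Epoching, FFT
length and window are estimator config, not properties of the
definition — no canonical choice exists for this quantity.

**Degenerate inputs.**  A constant subband has APE = Sp = PE = 0 by
definition and no spectral mass; spectral and phase entropies are then
recorded as NaN with a warning and the whole (channel, segment) row is
dropped during matrix assembly, never imputed.

## Sparse LDA

Per subband, M_n (H × 8, H = channels × segments) and the two-column
class indicator C_n enter the penalized optimal-scoring criterion

  min ‖C θ − M β‖² + δ‖β‖² + δ₁‖β‖₁  s.t.  (1/H) θᵀCᵀCθ = 1.

With two classes the score vector θ is determined up to sign once the
trivial constant scoring is deflated: θ ∝ (H₂, −H₁)/√(H₁H₂) (focal
positive), so no θ/β alternation is needed.  The L1 control is
interpreted as a *stop-at-G* rule: β is taken at the first knot of the
LARS lasso path — run on ridge-augmented data [M; √δ·I], the LARS-EN
construction — where exactly G coefficients are active.  This
operationalizes the "|δ₁| equals the desired number of variables"
convention of the sparse-LDA literature (a literal negative L1 weight
is not a valid penalty).  At G = D, and for δ₁ = 0, the fit reduces to
the ridge closed form (MᵀM + δI)⁻¹MᵀCθ, which the tests verify, and
the path solutions converge to it as sparsity vanishes.  δ defaults
to 3; columns are z-scored with training-fold statistics before
fitting (entropies live on incommensurate scales) and the selection
indices always refer to the original columns.  Per-patient |δ₁|
presets for the reference cohort ship in `ieegfocus.presets`; the
default for new data is G = 3.

## ADASYN

With I minority (focal) and J majority rows, β = 1 requests
Ĩ = (J − I)·β synthetics so that I + Ĩ = J.  Each minority seed i gets
weight Γ_i ∝ Θ_i/K, where Θ_i counts majority samples among the K = 5
nearest neighbors of the seed in the *full* training set (Euclidean);
Γ normalizes to 1 and per-seed counts g_i = Γ_i·Ĩ are apportioned by
largest remainder so Σg_i = Ĩ exactly.  Each synthetic point is
seed + (neighbor − seed)·u with u ~ U[0,1] and the neighbor drawn
among the K nearest *minority* neighbors of the seed (the SMOTE step),
so synthetics never leave the segment between seed and neighbor.
Seeds in pure-minority neighborhoods (Θ = 0) generate nothing; when
every neighborhood is pure there is nothing to adapt to and the input
is returned unchanged.  K is reduced with a warning when the minority
class has fewer than K + 1 members.  Balancing runs strictly inside
each training fold, after selection, and is bit-reproducible given a
seed.

## Cross-validation and metrics

Folds partition *segment indices* into k contiguous blocks (k = 10 at
the 90-segment scale; desk-scale runs use k = 5 over 15 segments).
All channels of a segment share its fold, and block assignment avoids
adjacent-window leakage; nothing is shuffled, so fold membership is
independent of channel order.  Per fold: z-score by training
statistics → sparse-LDA selection → ADASYN → RBF SVM (C = 1,
gamma = 'scale', i.e. 1/(dim × variance); the decision sign is the
segment-level threshold, no calibration).  The selection-off and
balancing-off ablations are config switches on the same harness.

Segment metrics follow the confusion-matrix conventions: SEN, SPE,
PPV and fall-out (FPR) on the 0–100 % scale, F1 as a fraction,
PLR = SEN/FPR; SPE + FPR = 100 identically, and zero-denominator
metrics are NaN.  Channel-level AUC thresholds each channel's count
of detected focal segments at every integer from 0 to max+1,
traces the (FPR, SEN) polyline in descending-threshold order and
integrates by the trapezoid rule — numerically identical to the
Mann–Whitney statistic with half-credit ties, which the tests assert.
Fold AUCs are averaged for the final figure.

## Synthetic iEEG generator

Clinical recordings for this task are not publicly available, so the
generator emulates their *structure*: per-channel background noise
with a 1/f^γ spectrum (γ = 1, 25 µV SD) plus Poisson-timed
Gaussian-windowed sinusoidal bursts in the ripple (center sampled
inside 100–250 Hz, 60 ms, baseline 2/min) and fast-ripple (250–600 Hz,
25 ms, baseline 1/min) families, at 3× the background SD.  Burst
centers keep two spectral-envelope SDs of margin from the family band
edges so ≥ 80 % of burst energy stays in the declared band.  SOZ
channels receive `rate_ratio` times the baseline rate; that contrast
is the only systematic SOZ/non-SOZ difference.

Defaults are the desk-scale study conditions used by the test-suite
and the acceptance script: 12 channels, 2 SOZ, 5 minutes at 2 kHz
(15 segments per channel), rate ratio 8, amplitude 3 SD.  Under these
conditions the full pipeline should recover the SOZ channels almost
perfectly (mean channel AUC ≥ 0.9), and at rate ratio 1 (the null) it
should hover near chance.  Reference-cohort profiles (Pt1–Pt8
electrode counts and SOZ channel numbers, 30-minute duration) are
available through `make_cohort_recording` for full-scale runs.

What the generator does *not* model: nonstationary background,
artifacts, inter-channel correlation, electrode geometry, spikes, and
realistic HFO morphology variation.  Passing the synthetic-recovery
checks therefore shows the pipeline's machinery is sound and its
stages compose correctly — it is not clinical validation.

## Numerical choices and limitations

* APE/Sp subsampling trades a small bias for tractability at
  L = 40,000; the cap (4,000) and the estimator path are config.
* The bispectrum accumulates only over the principal domain, which is
  an exact restriction (symmetry), not an approximation.
* Largest-remainder apportionment makes ADASYN counts exact at any β.
* The LARS path can, in rare degenerate designs, skip the requested
  active-set size G (a drop-and-add step); the fit then takes the last
  knot with ≤ G active variables.
* Channel AUC from small folds is coarse: with 3 test segments per
  channel the counts take 4 values, and a fold in which the classifier
  detects nothing scores exactly 0.5.
* Reported problem sizes: unit tests use signals of L ≤ 500 against
  brute-force oracles; pipeline tests use the 12-channel desk scale;
  full 76-channel, 30-minute profiles are supported but are multi-hour
  computations and are exercised structurally (segment counts, shapes)
  rather than end-to-end.
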