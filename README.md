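# ieegfocus

Localization of the epileptic focus from **interictal** intracranial
EEG (iEEG).  For patients with focal cortical dysplasia undergoing
presurgical evaluation, the seizure onset zone (SOZ) is classically
identified by waiting for seizures during days of invasive monitoring.
This package implements an automatic alternative that works on
between-seizure recordings alone, exploiting the elevated rate of
high-frequency oscillations — ripples (100–250 Hz) and fast ripples
(250–600 Hz) — on SOZ electrodes.

## Method

Each channel of a multichannel recording (2 kHz typical) is cut into
20-s segments; every segment of an SOZ channel is labelled focal.  A
3rd-order Butterworth filter bank splits the 100–600 Hz band into
N = 10 contiguous 50-Hz subbands S₁…S₁₀.  Per subband signal, eight
entropies form the feature vector
vₙ = [APE, PE, Sh, Sp, Ts, S₂, S₁, Ren]:

* approximate / sample entropy: template-matching regularity with
  embedding d = 2, Chebyshev distance, tolerance r = 0.2 · SD;
* permutation entropy: base-2 entropy of ordinal patterns, d = 3, τ = 1;
* Shannon / Rényi (α = 2) / Tsallis (q = 2) entropies of the
  normalized power spectrum;
* phase entropies S₁/S₂ of the normalized bispectral magnitude.

Per subband, sparse LDA (elastic-net optimal scoring,
min ‖Cθ − Mβ‖² + δ‖β‖² + δ₁‖β‖₁ with δ = 3 and the L1 term read as a
stop-at-G rule) keeps the G most discriminative entropies; the
selected columns concatenate into V* ∈ ℝ^{N·G}.  Focal rows are the
minority class, so ADASYN (β = 1, K = 5) synthesizes minority vectors
inside each training fold; an RBF SVM (C = 1) classifies held-out
segments under 10-fold segment-wise cross-validation.  Segment
results are summarized by sensitivity/specificity/precision/fall-out,
F-score and the positive likelihood ratio PLR = SEN/FPR; channel-level
performance thresholds each channel's count of detected focal
segments and integrates the ROC by the trapezoid rule (equal to the
tie-aware Mann–Whitney statistic).

Because the clinical recordings this method was developed on are not
public, the package ships a synthetic iEEG generator (1/f background
plus Poisson-timed Gaussian-windowed HFO bursts, SOZ channels at a
configurable burst-rate multiple) whose defaults make the whole
pipeline testable end-to-end; see `docs/methods.md` for the model,
its parameters and its limits.

## Worked example

```python
import ieegfocus as ief

# 12-channel, 5-minute synthetic recording; 2 of 12 channels are SOZ
# and carry 8x the baseline burst rate
rec, annotations = ief.generate(ief.SynthConfig(seed=0))

features = ief.extract_features(rec)          # tidy (channel, segment, subband, entropy) table
result = ief.run_cv(features, ief.CVConfig(k=5, seed=0))

m = result.metrics
print(f"SEN {m.sen:.1f}%  SPE {m.spe:.1f}%  F1 {m.f1:.2f}  PLR {m.plr:.1f}")
print("fold channel AUCs:", [round(a, 3) for a in result.fold_aucs])
print("mean channel AUC:", round(result.mean_auc, 3))
```

Output:

```
SEN 76.7%  SPE 97.3%  F1 0.81  PLR 28.8
fold channel AUCs: [1.0, 1.0, 1.0, 0.975, 1.0]
mean channel AUC: 0.995
```

76.7 % of the focal 20-s segments are detected with a 2.7 % false
positive rate, and ranking channels by their detected-segment counts
separates the two SOZ channels from the ten others almost perfectly
(AUC 0.995).  With `rate_ratio=1` (no SOZ contrast) the same pipeline
stays at chance (mean AUC ≈ 0.5), as it should.

The same workflow is available from the shell:

```sh
ieegfocus simulate --channels 12 --soz 2 --duration 300 --seed 0 --out rec.tsv
ieegfocus extract  --data rec.tsv --out features.tsv
ieegfocus evaluate --features features.tsv --k 5 --algo fba-fs-ada --out report/
```

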