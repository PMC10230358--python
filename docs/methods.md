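# Methods

## Problem and scope

`vitalwatch` classifies every second of a multiparameter PICU monitoring
stream of a neonate with critical congenital heart disease as stable,
unstable, or sensor dysfunction, and aggregates the per-second labels into
counted episodes.  The package covers the full pipeline — data model and
I/O, preprocessing, the three submodels, fusion and episode aggregation, a
synthetic-data generator, evaluation, and a CLI.  Retrospective EHR
extraction, expert chart review, and real-time monitor integration are out
of scope.

## Data model and preprocessing

Records live on a contiguous 1 Hz integer-second grid from admission start;
readers align rows to the grid, fill gaps with all-missing seconds, and
resolve duplicate timestamps last-wins.  Missingness is explicit (NaN) and
never imputed.

* **RR trend.**  Neonatal respiratory rate fluctuates strongly within
  minutes, so the model uses a trailing 300-s moving average of RR over
  [t−300, t−1].  The protocol is silent on missingness inside the
  window; we require ≥150 observed seconds (50% coverage) and return
  missing otherwise, to avoid unstable means over sparse windows.
* **rSO₂ fusion.**  Mean of the two cerebral probes when both read; the
  single available probe otherwise (maximizing data use — the protocol only
  defines the both-present case); missing when neither reads.
* **Ventilation.**  EtCO₂ > 0 at t ⇔ currently mechanically ventilated.
  Missing EtCO₂ counts as not ventilated: the conservative choice, since
  the ventilation adjustment only inflates distances.
* **Stratification.**  Admission-mean SpO₂ over all non-missing seconds,
  before any artifact masking; exactly 90.0 maps to the ≥90% stratum.
* **Cohort filter.**  ≥12 h of seconds with a complete 5-parameter vector,
  birth weight ≥2000 g, age at admission <1 year.

## Submodel 1 — sensor dysfunction

Per-second rules: |Δ| > 25 points between consecutive IBP or SpO₂ readings
(strict inequality, no bridging across gaps); rSO₂ ≤15% or ≥95% (scale
limits, characteristic of escaping sensor light); raw RR < 5 breaths/min.
Each contiguous detection run [first, last] flags [first−60, last+60].
That per-run expansion is mathematically identical to a ±60 s binary
dilation of the event indicator, which is how it is computed; the test
suite checks it against an independent per-second scan.  The rSO₂ rule is
applied to the fused value *and* to each raw probe — a railing probe is an
artifact even when its partner is plausible — with provenance recording
which rule fired.  There is deliberately no HR rule.

## Submodel 2 — parameter-combination analysis

Complete 5-vectors are z-scored against stratum moments (sample mean/SD;
the z-score covariance is the correlation matrix, ridge-regularized by
1e−6·trace/5 only if not positive definite) and reduced to the Mahalanobis
distance.  Vectors beyond the 80th percentile (linear interpolation; ties
retained) are discarded as presumed-unstable; the remainder split 80:20
with a seeded shuffle, and a one-class SVM (RBF kernel, ν = 0.05) is
fitted on the training partition.  The held-out 20% serves only to log a
held-out inlier rate; it is never used for threshold tuning.

Choices the published description leaves open:

* **Kernel scale.**  γ defaults to 1/(5 · mean per-axis variance of the
  training z-scores) — the variance-heuristic family; configurable.
* **Static cutoffs.**  The intensivist-consensus values were never
  published.  The shipped defaults — HR outside [60, 230] /min, smoothed
  RR > 90 /min, IBP outside [20, 90] mm Hg — are the package's own
  placeholders, clearly overridable, and every report states the cutoffs
  in force.  Cutoffs apply to the smoothed RR trend (consistent with the
  preprocessing rationale) and support both one- and two-sided bounds.
* **Decision evaluation.**  The fitted decision function is evaluated from
  the support-vector expansion f(z) = Σᵢ aᵢ·exp(−γ‖z−svᵢ‖²) + b with
  coefficients persisted as full-precision text, so a reloaded model
  reproduces decisions bit-identically; equality with the library decision
  function is asserted in tests.

## Submodel 3 — baseline deviation

The raw distance stream d(t) (only from complete, artifact-free seconds;
masked seconds would otherwise poison the patient baseline) is inflated by
×1.2 while ventilated, giving d′(t).  Everything downstream is causal:

* trend Z(t): moving median of defined d′ over [t−300, t−1] (≥150 values);
* baseline B(t): median of all defined d′ before t, maintained by a
  two-heap streaming median (exact, O(log n) per update);
* noise scale SD(t): sample SD (ddof = 1) of the baseline-corrected values
  c(s) = d′(s) − B(s), s < t, after dropping the ⌊0.2·n⌋ largest — the SD
  of the presumed-stable seconds.  It is recomputed on a 60-s cadence
  (held constant between refreshes, cadence configurable) and requires
  ≥600 accumulated values.

Labels: improvement if Z−B < 0 (movement toward the stratum mean; treated
as non-unstable downstream), unstable if Z−B ≥ 2·SD, stable otherwise.
During the first admission hour state accumulates but no label is emitted.
A degenerate constant stream has SD = 0 and Z = B, which the ≥ rule labels
unstable by its letter; real streams always carry noise, and the behaviour
is documented rather than special-cased.

## Fusion, smoothing, episodes

Per-second precedence: warm-up → sensor dysfunction → unknown (no submodel
verdict, i.e. missing data) → unstable (either submodel) → stable.  The
4-of-5-minute rule is realized as a trailing-window smoother (anchoring
was left unstated; trailing windows preserve causality for
eventual real-time use): a classifiable second is unstable iff ≥240 of the
trailing 300 s are raw-unstable, nonconsecutive seconds counting.
Dysfunction and unknown seconds pass through and count as non-unstable
inside the window.  Episodes are maximal constant-label runs split
left-to-right at the 2-hour cap; unknown runs of ≤60 s flanked by the same
label are absorbed (longer gaps break the episode), and dysfunction
episodes come directly from the expanded mask without the smoother.

## Synthetic data

Each parameter is a clipped, correlated stationary process around the
stratum profile: centers are the cohort medians (cyanotic stratum: HR 159,
RR 34, SpO₂ 77, rSO₂ 55.0, IBP 51; acyanotic: 146/35/97/71.5/53) and SDs
derive from the cohort IQRs via SD = IQR/1.349.  Dynamics are the sum of
a slow AR(1) (φ = 0.999 per second; physiologic wander with a ~17-minute
correlation time) and a fast AR(1) (φ = 0.9; beat-to-beat and sensor
jitter), holding 30% and 70% of the SD respectively.  The split is a
simulator design choice: 1 Hz monitor feeds carry substantial second-scale
jitter, and the slow-wander share is calibrated so that default stable
records satisfy the generator's stability contract — the pipeline labels
them stable (<5% unstable seconds, no unstable episodes) — which is what
the published stable-time behaviour of the method implies about real
records.  Putting most of the variance into the slow component instead
produces multi-minute excursions beyond the population 80th-percentile
shell that no 4-of-5-minute rule can suppress.

Cross-parameter correlation defaults to mild positive HR–RR (0.3) and
SpO₂–rSO₂ (0.5), zero elsewhere (a package default, not a clinically derived structure; configurable).
Values are clipped to physiologic ranges after generation (clipped seconds
remain valid data); the rSO₂ clip range [16, 94] sits just inside the
artifact limits so that clipping itself never fabricates a rail artifact.
The two probes add independent N(0, 2²) offsets to the common rSO₂ signal.

Injected events carry ground truth: deterioration events apply a logistic
ramp of per-parameter shifts (profile-SD units, ≥2 parameters) and mark
[start, end] truth-unstable; jump artifacts step a channel by >25 points,
hold ~5 s, and decay in sub-threshold steps so exactly one jump event
fires; rail/RR-loss artifacts set the respective channels beyond their
rule limits; dropouts create missingness (truth: unknown, not artifact).
The generator does not model waveform morphology, pathology-specific
hemodynamics, feeding/handling artifacts, or circadian rhythm — so green
tests demonstrate the pipeline's mechanics and its behaviour under the
stated statistical conditions, not clinical performance on real patients.

## Evaluation protocol

The reference evaluation of this method scored the detector against
expert adjudication; with
synthetic truth the package substitutes interval overlap: a truth episode
(pre-split at the 2-h cap) is correctly detected when ≥1 same-class
predicted episode overlaps it, and partially correct when the summed
same-class overlap covers <50% of its duration.  Time-percentual
correctness is the per-class fraction of truth seconds with a matching
predicted label.  Warm-up and unknown seconds are excluded from all
denominators.  This is an evaluation-protocol substitution,
not a reimplementation of expert review.

## Problem sizes and numerics

End-to-end tests and examples train on 10 simulated records × 3 h per
stratum with a 20,000-vector subsampling cap before the SVM fit, and
classify 6-h records — the package's desk-scale stand-in for a full
clinical cohort (tens of patients, thousands of hours).  Training on very few simulated patients
narrows the SVM support (each record carries its own slow-wander offset)
and inflates fresh-record outlier rates; ten records suffice for the
support to cover the stratum distribution.  Covariance factorizations use
Cholesky decompositions; squared distances are clipped at zero before the
square root; percentiles use linear interpolation; all randomness flows
from explicit seeds and reruns are bit-identical.

## Known limitations

* Static cutoffs and the stratum correlation structure are package
  defaults, not published clinical values.
* The baseline B uses all history (no forgetting), so very long admissions
  make the baseline increasingly inert; this mirrors the reference design.
* Single-probe rSO₂ fallback and the missing-EtCO₂ convention are
  documented choices where the published description is silent.
* Synthetic benchmarks bound what passing tests prove: they validate
  mechanics and statistical behaviour under the generator's assumptions,
  not clinical accuracy.
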