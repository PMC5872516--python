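# Methods

This note documents the models, the numerical choices, and what the
synthetic experiments do and do not demonstrate.

## Cohort construction

**Baseline serum creatinine.** The baseline is the last measurement inside
the 48 h window before admission; if none exists, the first measurement at
or after admission. The source branch is recorded per encounter.

**KDIGO staging.** Per measurement, with `b` the baseline and `v` the value
(mg/dL):

| stage | criterion |
|---|---|
| 1 | `v − b > 0.3` or `v/b ∈ [1.5, 2.0)` |
| 2 | `v/b ∈ [2.0, 3.0)` |
| 3 | `v/b ≥ 3.0` or `v > 4.0` |

The encounter's stage is the maximum over inpatient measurements; onset is
the first measurement meeting the maximal stage's criterion. Two printed
conventions had to be resolved: the dual-unit thresholds disagree slightly
(26.4 µmol/L vs 0.3 mg/dL × 88.4 = 26.52), so mg/dL is canonical and
µmol/L inputs are converted (÷88.4) before comparison; and the ratio bands
are printed with gaps ("1.5–1.9", "2.0–2.9"), so they are implemented as
half-open intervals tiling the line. The absolute stage-3 criterion is read
as the SCr *value* exceeding 4.0 mg/dL, strict.

**Exclusions** (one reason code per encounter, fixed priority): age ≤ 18,
stay < 2 days, fewer than two SCr measurements, admission eGFR
< 60 mL/min/1.73 m², any SCr > 1.3 mg/dL within 24 h of admission. eGFR is
accepted as a precomputed column; no estimating formula is implemented. The
24 h window is applied to both the eGFR and the SCr rule.

**Matching.** Stage-3 cases are paired 1:1 to stage-0 controls, exact on
gender and race, nearest age within a caliper (default 5 years, chosen as
the common epidemiological convention). The greedy search processes the
most-constrained case first (fewest eligible controls); ties on age gap
break on the lowest control id, so matching is deterministic and invariant
to input row order. Greedy matching is not optimal assignment and can
strand a case that an exhaustive search would pair; the synthetic generator
sidesteps this (below), and unmatched cases are always reported.

## Feature encoding

Time-dependent variables (medications, history, labs, vitals) are frozen at
a **checkpoint**: 24 h before stage-3 onset for a case, and the case's
admission-to-checkpoint offset applied to the matched control's own
admission, capped at its discharge. Controls have no onset of their own, so
some transfer rule is unavoidable; the offset transfer keeps the "time into
stay" comparable within a pair and is flagged here as a design choice.
Encounters whose checkpoint would precede admission are dropped and logged.

Coding rules: labs take the last value strictly before the checkpoint and
become `present-normal` / `present-abnormal` / `unknown` against a
configurable reference range (defaults shipped for a 14-test panel, with the
standard adult ranges stated in the source). Vitals are binned into the
standard clinical categories; printed bin labels leave boundary gaps, so
bins are implemented left-closed right-open with internal edges at the
printed lower bounds (e.g. diastolic 99.5 → "[90-99]", 100.0 → "> 100").
Binary categories (medication, history, comorbidity, admission diagnosis)
are `yes` iff a qualifying event exists at/before the checkpoint;
comorbidities and admission diagnoses are time-independent and ignore it.
Age enters as decade bands so that every column is categorical. Missingness
always resolves to an explicit unknown state — the matrix has no null cells.

## Conditional-independence kernel

Pearson chi-square on contingency tables; conditional tests sum per-stratum
statistics and degrees of freedom over the observed joint states of the
conditioning set. Rows/columns with zero margin are dropped before the dof
computation. A test with `n < 5·dof` is flagged unreliable and treated as
"independence not rejected", so sparse strata can never manufacture
dependence. α defaults to 0.05 everywhere and is configurable.

## Structure learning

An interleaved grow/shrink (IAMB-style) blanket search. Two choices matter
on wide matrices:

* **Admission threshold.** Each grow round scans every remaining candidate,
  ~200 simultaneous tests at the study scale; at a raw α=0.05 one false
  admission per round is near-certain. The admission threshold is therefore
  Bonferroni-corrected to α/#candidates (the shrink pass stays at plain α).
  Genuine blanket members at the study's effect sizes reach p ≈ 1e−8 or
  smaller and are unaffected.
* **No re-admission.** The tests are deterministic, so a feature removed by
  shrink would be re-admitted by the identical grow test and the search
  would cycle; removed features are barred from re-admission.

Conditioning sets are capped at `max_cond_size` (default 3 — with ~358 rows
and the 5·dof reliability rule, larger sets are almost never reliable);
when the blanket exceeds the cap, the cap-sized subset most associated with
the outcome is used. Ties on p-values break lexicographically on feature
name, making the blanket invariant to column order.

## Direction learning

**Conversion.** `x̄ = g(x_1, …, x_k)` enumerates joint states mixed-radix
with the last component varying fastest, 1-based: `(v¹,…,v¹) → 1` and the
terminal tuple → `∏ m_i`. Encode/decode are exact inverses.

**Discrete ANM.** `f` is the conditional mode of the effect per `x̄` state
(ties to the smaller state; zero-support states fall back to the global
mode and are flagged). Residuals are taken **modulo the effect's state
count** — the cyclic-noise form of the discrete additive-noise model. For a
binary outcome the residual is then exactly the XOR noise term, which is
what makes the forward direction testable at all: a signed residual in
{−1, 0, +1} is structurally dependent on `x̄` whenever `f` is non-constant
(negative residuals can only occur where `f = 1`), and would reject the
true causal direction on any noisy binary outcome. Residual independence
is tested with the shared chi-square kernel; a constant residual is
independent of everything (p = 1).

**Subset search and uniqueness.** Subsets of the blanket up to
`max_set_size` (default 4) are tested; subsets with `n < 5·(m̄ − 1)` are
skipped as unreliable — with n ≈ 358 this bounds practical subsets near
four binary causes. A subset is admissible iff the forward test does not
reject (reliable, p > α) and the backward test rejects (reliable, p ≤ α).
The decision is taken at the **maximal admissible cardinality**: an
admissible proper subset only means the omitted causes' influence escaped
detection inside the noise term. If more than one subset of that size is
admissible, the evidence is ambiguous and the result is reported
unidentifiable (accepted = False) rather than resolved by a score — a
many-to-one structure is only tenable for a unique set of all causes. The
backward test regresses the converted feature jointly on the outcome
(`x̄ = f'(y) + N'`), keeping the two directions symmetric.

## Odds-ratio verification

For k discovered causes, all `2^k − 1` non-empty exposure profiles are
cross-tabulated against the outcome: OR = ad/bc with a 95% Wald CI on the
log scale, and the Haldane–Anscombe +0.5 correction when any cell is zero
(engaged iff a cell is zero; OR and CI then remain finite). The default
exposure reading is exact-profile — the mask specifies every cause's state,
so the `2^k` profiles partition the cohort; an "at-least" reading is
available behind a flag. Rows are ordered by combination size, then by the
binary value of the reversed mask (singletons first, in cause order).

## Predictive evaluation

Stratified k-fold CV (default 10) on one-hot encodings over each feature's
full declared alphabet. Models and hyperparameters (none dictated by the
underlying method; all configurable): KNN k=5; decision tree with minimum
leaf 5; one-hidden-layer (16-unit) backpropagation network; random forest
with 500 trees; soft-voting ensemble of the other four. Positive class is
stage-3; threshold 0.5 for precision/recall/F-score; AUC is
threshold-free. CIs are normal approximations on fold means. A fold with a
single outcome class raises rather than silently rescoring.

## Synthetic cohorts: what they emulate, and what they do not

The generator plants a known causal structure — by default four binary
medication causes among ~200 mixed-alphabet clinical features for 179 cases
and 179 controls, mirroring the target regime — and emits EHR-shaped long
tables (encounters, SCr measurements, feature events) that the cohort and
feature builders must process like real data. SCr trajectories are
piecewise linear with the stage-3 peak at 3.5× baseline, strictly inside
the stage-3 region and below the 4.0 mg/dL absolute criterion, so staging
is never decided at a boundary; re-staging generated series reproduces the
intended stage and onset exactly. All encounters pass the exclusion rules
by construction, and every case gets a demographically identical control
(same gender, race and age), which makes a perfect 1:1 matching provably
reachable by the greedy matcher.

Outcome mechanism: per-cause odds multipliers define a logistic table
`p(s)`; in `logistic` mode the outcome is Bernoulli(p(s)), while the
default `anm` mode thresholds the table (`f(s) = [p(s) > ½]`) and applies
flip noise — an exact discrete ANM, which is the assumption the direction
phase tests. One subtlety is handled explicitly: balanced case-control
sampling multiplies every state's outcome odds by a constant, so a
population-constant flip rate is **not** constant in the matched sample.
The generator solves for per-`f` population flip rates whose
balanced-sample conditionals are exactly `noise_flip_prob` and
`1 − noise_flip_prob`, so the analysis sample satisfies the ANM. Defaults
(base rate 0.08, multiplier 6 per cause, cause prevalence 0.2, flip 0.08)
give `f = "at least two of the four causes"` and a population outcome rate
around 12%.

Deliberate departures from real data, and hence limits on what passing
tests show: the stage-3 rate is scaled up by orders of magnitude (the real
phenomenon is ~0.2% of encounters; desk-scale cohorts cannot be sampled
from that rate); features are conditionally independent given the planted
graph, with none of the block correlation of real medication/diagnosis
data; demographics are independent of the clinical features; no
measurement timing irregularity, unit errors, or name-normalization noise
(feature names arrive pre-resolved); and real outcomes are not generated by
a discrete ANM at all — on real data the forward test's assumptions are an
idealization, and an unidentifiable verdict is the expected honest outcome
when they fail. Medication pharmacology is not modelled.

Determinism: a single integer seed drives every stream; sub-streams are
derived with fixed offsets, so outputs are byte-identical across reruns and
stable under call reordering. Per-stage wall-clock is written to
`timings.txt`, outside the manifest, precisely so the manifest and all
stage outputs stay byte-reproducible.

## Problem sizes used in the shipped experiments

Staging oracle: 1,000 random series. Kernel calibration: 200 null
replicates at n = 5,000. Blanket recovery: 20 networks (tests; 10 in the
acceptance script) at n = 3,000 with 200 features and a size-4 blanket.
Direction identification: 40 planted instances at n = 2,000. End-to-end
recovery: 20 cohorts (tests; 10 in the script) at the 358 × 200 study
scale. Reproducibility: two full runs at 120 × 80. These sizes were chosen
to estimate each property stably while keeping a full run in the
minutes range on a single CPU.
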