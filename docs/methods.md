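# Methods

## The screening problem

`stopflow` analyses high-throughput amide-coupling screens run on a
stopped-flow reactor. A campaign crosses a set of carboxylic acids with a set
of amines (each acid–amine pair defines one target *product*), a set of
coupling agents (HATU, PyCIU, TCFH, T3P by default), and an ordered ladder of
physical conditions running from *soft* (short time, low temperature) to
*harsh* (long time, high temperature). The measured response per reaction is
the UV peak area of the target amide relative to the total chromatogram area
at 254 nm, in percent. A reaction is *successful* when that relative area
reaches 10% — the rule-of-thumb level at which enough product can be
recovered for a bioassay — and *missing* when an instrument failure left no
chromatogram.

## Condition ladder

The 2-D (reaction time, temperature) space is collapsed onto a 1-D harshness
ranking anchored at soft (120 s, 50 °C), mid (360 s, 120 °C) and harsh
(600 s, 200 °C). Within `build_condition_grid`, reaction times interpolate
linearly soft→harsh; temperatures are piecewise linear through the mid
anchor (soft→mid over the first half of the ranking, mid→harsh over the
second), because a single linear ramp from 50 to 200 °C cannot pass through
120 °C at the middle rank. The exact intermediate points of the ladder are a
declared convention of this package: for the standard 9-point ladder the
times are 120, 180, …, 600 s and the temperatures 50, 67.5, 85, 102.5, 120,
140, 160, 180, 200 °C. Even-length grids cannot contain the mid anchor
exactly; it is snapped to the nearest rank with a warning.

## Stopped-flow arithmetic

Reaction time decomposes as Rt = transit + stationary hold, where transit is
one reactor volume moved at the total flow rate (reactor 1000 µL, three
pumps at 500 µL/min each → 40 s) and the hold time is set by a timer, so Rt
is decoupled from pump capacity. Reagent usage per reaction is one
safety-padded slug (500 µL × 2, the factor-2 padding guarding against axial
dispersion at the slug edges) versus the ~10 mL a continuous system consumes
reaching steady state — a 90% reduction. The comparison is scale-invariant,
which the tests exercise.

## Outcome labelling and success-rate tables

`label_outcomes` applies the 10% rule inclusively (≥ 10% is a success) by
default; the comparison operator is a flag because the boundary at exactly
10.0% is genuinely ambiguous in practice and both conventions are in use.
Success-rate tables count, per scope, the products with at least one
successful reaction: a single (agent, condition) bucket, one agent across
the whole ladder, or the full screen. Denominators always count designed
products — missing records reduce numerators only, so an instrument failure
can never inflate a success rate.

## Features

* **Reaction fingerprint** — the product's hashed Morgan *count* fingerprint
  (radius 3, 2048 slots by default) minus the acid and amine fingerprints,
  element-wise. Counts rather than bits, so the subtraction preserves
  environment multiplicity and the reactant sum reconstructs the product
  vector exactly (an identity asserted across every assembled matrix).
  The coupling agent is not subtracted: it does not enter the product and is
  encoded categorically instead.
* **Product fingerprint** — the product's own count fingerprint, restoring
  the shared structural context the subtraction removes. A
  `circular+path` variant appends the RDKit path-based fingerprint.
* **Condition one-hot** — one block per coupling agent, temperature level
  and time level; e.g. 4 agents + 5 temperatures + 5 times = 14 bits, always
  exactly 3 bits set. Temperature and time are deliberately categorical, not
  scaled numerics; out-of-vocabulary levels raise rather than silently
  extending the encoder.
* **Properties** — continuous physicochemical descriptors and pKa1–4 per
  reagent, ingested from tables and never computed here. Missing values are
  median-imputed with a companion 0/1 indicator column; only this continuous
  block is z-standardised, with statistics fitted on training rows only.

The default registry holds 12 named feature sets: {reaction, product,
reaction+product} fingerprints × {with/without conditions} × {with/without
properties}. The composition is configurable; the registry is a convention,
not a claim of uniqueness.

## Classifier

The outcome model is a small feed-forward network (1–3 hidden layers,
ReLU, minibatch adam) emitting a success score in [0, 1], implemented with
scikit-learn's `MLPClassifier`. L2 weight decay (`alpha`) is the
regulariser in the search space. Hyperparameters are chosen by seeded
random search (the sampler is pluggable) over: layers {1, 2, 3}, units
{16, 32, 64, 128}, alpha {0, 1e-4, 1e-3}, learning rate log-uniform
[1e-4, 1e-2], epochs {20, 50, 100}, batch {16, 32, 64}. Each candidate is
scored by stratified inner 3-fold cross-validation on binary accuracy at
the 0.5 cutoff (appropriate because the classes are roughly balanced);
ties break toward fewer parameters, then the earlier trial. All
randomness — weight init, folding, trial sampling, label shuffling —
derives from explicit seeds, so identical (data, config, seed) reproduce
identical scores bit for bit.

## Validation protocol

Two outer cross-validation strategies on the training campaign: 3 stratified
random 60/40 splits (stratification by outcome keeps small folds
two-class) and leave-one-amine-out (LOAO), one split per amine. For each
feature set and each of the 8 outer splits, one true-label and one
shuffled-label model are tuned and trained on the outer training rows only
(standardisation statistics included) and evaluated on the hold-out rows:
16 models per feature set, 8 of them permutation nulls. Feature sets are
ranked by mean hold-out precision of the true models (precision is preferred
over recall because the model's use is picking experiments to run — the
cost of a false positive is a wasted reaction), with mean ROC AUC and then
smaller feature width as tie-breaks; the winner must beat its shuffled
twins' mean precision or selection fails with a no-signal error.
Precision is aggregated as the mean over splits (pooling confusion counts is
the alternative; the mean weights each split equally regardless of size).

The final model is trained on the whole training campaign (re-tuned once,
or with a supplied config) and evaluated exactly once on the *temporal*
campaign — a later library with new amines. The model records its training
campaign id and data fingerprint; temporal evaluation refuses to run on the
training campaign or on overlapping records. The condition vocabulary used
for encoding may be built from the union of campaigns: it contains only the
categorical levels of the design, never outcomes, so it leaks nothing.

## Prioritization

Given temporal scores, `prioritization_analysis` tabulates what running only
experiments with score ≥ t would have delivered: experiments selected,
experimental successes/failures, distinct products with a selected success,
and distinct selected products with none ("failed products" are counted
among selected experiments only — a product never selected is absent from
both columns). The threshold is inclusive (≥), configurable. The
`highest_score_per_product` rule picks exactly one experiment per product —
its maximum-score experiment, ties broken by harsher condition then
lexicographic agent id for determinism (harsher-first mirrors the observed
trend that harsher conditions succeed more often). Counts are monotone
non-increasing in the threshold and the threshold-0 row equals the dataset
totals; both are asserted exactly in tests.

## Synthetic campaigns

The generator draws a latent success probability per experiment from

    p = logistic(β₀ + β_agent + β_T·z(T) + β_t·z(t) + u_acid + v_amine + w_pair)

with defaults: β₀ = logit(0.1) (placing the 10% threshold at the median of
the latent field, so classes balance near 50/50), temperature slope 1.5
log-odds per SD of the ladder's temperatures, time slope 0 (the screening
finding: temperature dominates, time barely matters), agent offsets
HATU −0.4, PyCIU +1.2, TCFH +0.8, T3P −1.6 (zero-mean, ordered
PyCIU > TCFH > HATU > T3P as observed), and acid/amine/pair random effects
with SD 0.8/0.8/0.6 for substrate-specific difficulty. The observed
response is 100·p plus N(0, 5²) noise on the percentage scale, clipped to
[0, 100] (relative areas are bounded by construction); instrument failures
drop records with probability 64/900 ≈ 7.1%. Default design: 5 acids ×
5 amines × 4 agents × 9 conditions = 900 reactions, leaving ~836 usable. A
temporal twin (6 acids × 5 new amines × 4 agents × 2 mid conditions = 240
reactions) reuses the training campaign's realized effects for shared
reagents and its z-scaling, so both campaigns live on one latent surface.
Reagents come from a packaged pool of 12 mono-functional acids and 12
amines whose 144 pairings all yield unique, unambiguous amides.

The logistic surface is a statistical surrogate: it reproduces the
*associations* the analysis assumes (temperature-dominant response,
agent-specific effectiveness, pair-specific difficulty, balanced classes,
sporadic dropouts), not the chemistry. Passing tests on generated data show
the pipeline recovers structure that is genuinely present; they do not show
that real amide screens satisfy the logistic form, and real descriptor
tables will carry far weaker and more collinear signal than the generator's
property tables at high ρ.

Two structural points discovered while testing, both inherent to the design:

* Time and temperature are *collinear along the screening ladder* by
  construction, so "time has no effect" can only be verified on a crossed
  time × temperature design; the chi-square structure test generates one
  (3 × 3) for exactly that purpose.
* Under the default temperature-dominant surface, a condition-only model
  sits near its achievable AUC ceiling, so property descriptors cannot
  demonstrably improve LOAO performance no matter how informative they are.
  The property-signal recovery test therefore uses a substrate-dominant
  construction (acid SD 2.0, pair SD 0.3, temperature slope 0.8) where the
  injected ρ = 0.9 signal has headroom to express itself.

## Problem sizes and numerical choices

The test suite and the acceptance script run the full protocol at reduced
search budgets (1–2 trials over a one/two-point space) and with the compact
conditions-only or 128-slot fingerprint featurizations; the protocol's
*structure* (8 splits × 2 label modes, inner 3-fold, leakage guards) is
identical at any budget, and these sizes keep a complete run to a few
minutes on one CPU. Degenerate cases are handled explicitly: single-class
training data and empty metric inputs raise; one-class ROC AUC is reported
as NaN (flagged, not fabricated); a zero product-peak area maps the DoE
objective (internal-standard area / product area) to +inf so optimisers can
still rank it; zero-variance property columns standardise to zero rather
than dividing by zero.

## Limitations

* No chromatogram integration, pump control, or NIR processing — the
  package starts from integrated relative areas.
* Descriptors and pKa values are ingested, never computed.
* No probability calibration: scores are used as raw network outputs.
* The hyperparameter space and the 12-set feature registry are declared
  conventions; both are configurable.
* Dropout regularisation is not available in the network implementation;
  L2 weight decay takes its place in the search space.
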