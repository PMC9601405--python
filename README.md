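# stopflow

Analytics and outcome modelling for stopped-flow amide library screening.

High-throughput library synthesis screens cross carboxylic acids × amines ×
coupling agents × reaction conditions and read out, per reaction, the UV
peak area of the target amide relative to the total chromatogram area (%).
`stopflow` is for chemists and modellers working with such screens. It
covers:

* **Design** — the soft→harsh condition ladder (anchored at 120 s/50 °C,
  360 s/120 °C, 600 s/200 °C), full factorial experiment enumeration, and
  stopped-flow timing/reagent-usage arithmetic (Rt = transit + hold;
  one padded slug vs ~10 mL of continuous steady-state feed → 90% less
  reagent).
* **Outcomes** — the 10% relative-area success rule
  (success ⇔ area ≥ 10%), library success-rate tables
  (LS = 100·SRxn/N_products per condition, per agent sequence, or full
  screen), campaign heatmaps with instrument failures masked, and the DoE
  objective IS-area/product-area.
* **Features** — reaction-difference fingerprints
  (Δ = FP_product − FP_acid − FP_amine on Morgan count fingerprints,
  radius 3), product fingerprints, condition one-hots (e.g. 4 agents +
  5 temperatures + 5 times = 14 bits), and ingested property/pKa blocks.
* **Model** — a small feed-forward classifier (1–3 hidden layers) scoring
  success probability in [0, 1], with seeded random hyperparameter search
  under inner 3-fold cross-validation.
* **Validation** — 3 random 60/40 splits + leave-one-amine-out (16 models
  per feature set: 8 true + 8 shuffled-label nulls), precision-first model
  selection, strictly held-out temporal evaluation, and score-threshold
  experiment prioritization.
* **Simulation** — virtual campaigns from a logistic latent surface
  (temperature-dominant, agent-ordered, pair-specific difficulty, ~50/50
  classes, ~7% dropouts) with ground truth retained for recovery tests.

See `docs/methods.md` for the model and its assumptions.

## Worked example

```python
from stopflow import data, simulate, validate
from stopflow.features import FeatureSetSpec

# a virtual 5x5x4x9 screening campaign (900 reactions)
config = simulate.SyntheticConfig(seed=3)
dataset, truth = simulate.generate_library(config)
labelled = data.label_outcomes(dataset, threshold_pct=10)

print(data.success_rate_table(labelled, "per_agent_sequence"))
```

```
   scope agent_id  SRxn  denominator  LS_pct
sequence     HATU    24           25    96.0
sequence    PyCIU    25           25   100.0
sequence      T3P    18           25    72.0
sequence     TCFH    25           25   100.0
```

Per agent, `SRxn` counts the products (of 25 designed) that succeeded under
at least one of the nine conditions, and `LS_pct` is the corresponding
library success rate — here the generator's agent ordering
(PyCIU ≈ TCFH > HATU > T3P) is visible directly in the screen analytics.

Running the cross-validation protocol on one feature set builds the
16-model ledger and selects a winner that must beat its shuffled-label
nulls:

```python
spec = FeatureSetSpec("cond_only", ("conditions",))
ledger = validate.run_cv_protocol(labelled, [spec], budget=20, seed=11)
print(ledger.to_frame().groupby("label_mode")[["precision", "accuracy", "auc"]].mean())
```

```
            precision  accuracy       auc
label_mode
shuffled     0.507715  0.433914  0.484696
true         0.749334  0.723095  0.854715
```

True-label models clearly separate from the permutation nulls (hold-out AUC
0.85 vs 0.48). `validate.train_final_model` then fits the winning feature
set on the whole campaign, `validate.evaluate_temporal` scores a later
campaign (leakage-guarded), and `validate.prioritization_analysis` tabulates
how many experiments and products each score threshold would retain.

A thin CLI wraps the same functions: `stopflow grid`, `stopflow simulate`,
`stopflow success-table`, `stopflow heatmap`, `stopflow run-cv`,
`stopflow prioritize`.

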