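"""Model validation, selection, temporal evaluation and prioritization.

The modelling protocol works entirely on the first (training) campaign:

* two cross-validation strategies — 3 stratified random 60/40 splits and one
  leave-one-amine-out (LOAO) split per amine — give 8 outer splits;
* on each outer training set, hyperparameters are tuned by random search
  with inner 3-fold CV, once on the true labels and once on shuffled labels,
  giving 16 best-hyperparameter models per feature set (8 true + 8 null);
* feature sets are ranked on mean hold-out precision of the true-label
  models (precision preferred over recall, to maximise the ratio of
  successful to failed experiments when the model picks what to run), with
  ROC AUC and feature width as tie-breaks, and the winner must beat its
  shuffled twins;
* the winning feature set is re-tuned and re-trained on the full first
  campaign and evaluated once on the held-out temporal (second) campaign,
  which never touches tuning, training, standardization or selection.

Classifier scores on the temporal campaign then drive experiment
prioritization: selecting only experiments scoring above a threshold, or
the single highest-scoring experiment per target product.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .data import LABEL_MISSING, LABEL_SUCCESS, ScreenDataset
from .errors import LeakageError, NoSignalError, NotLabelledError
from .features import (
    ConditionVocabulary,
    FeatureSetSpec,
    PropertySet,
    assemble_features,
)
from .model import (
    MetricReport,
    ModelConfig,
    TrainedClassifier,
    TrialLog,
    evaluate_metrics,
    predict_scores,
    shuffle_labels,
    train_classifier,
    tune_hyperparameters,
)


@dataclass(frozen=True)
class SplitPlan:
    """A set of (train, test) index pairs over the non-missing records."""

    kind: str  # "random_60_40" or "leave_one_amine_out"
    splits: tuple[tuple[tuple[int, ...], tuple[int, ...]], ...]
    seed: int | None = None
    held_out_amines: tuple[str, ...] = ()


def _usable_indices(dataset: ScreenDataset) -> list[int]:
    if not dataset.is_labelled:
        raise NotLabelledError("dataset must be labelled")
    return [i for i, r in enumerate(dataset.records) if r.label != LABEL_MISSING]


def make_random_splits(
    dataset: ScreenDataset,
    n_splits: int = 3,
    train_frac: float = 0.6,
    seed: int = 0,
) -> SplitPlan:
    """Stratified random outer splits (default 60% train / 40% hold-out)."""
    if not (0 < train_frac < 1):
        raise ValueError("train_frac must lie strictly in (0, 1)")
    idx = np.array(_usable_indices(dataset))
    if len(idx) < 10:
        raise ValueError("need at least 10 usable records")
    y = np.array(
        [1 if dataset.records[i].label == LABEL_SUCCESS else 0 for i in idx]
    )
    if min(np.bincount(y, minlength=2)) < n_splits:
        raise ValueError("too few records in one class for stratified splitting")
    sss = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_frac, random_state=seed
    )
    splits = tuple(
        (tuple(idx[tr].tolist()), tuple(idx[te].tolist()))
        for tr, te in sss.split(np.zeros(len(idx)), y)
    )
    return SplitPlan(kind="random_60_40", splits=splits, seed=seed)


def make_loao_splits(dataset: ScreenDataset) -> SplitPlan:
    """Leave-one-amine-out: each amine's experiments form one hold-out set."""
    idx = _usable_indices(dataset)
    amines = sorted({dataset.records[i].amine_id for i in idx})
    if len(amines) < 2:
        raise ValueError("leave-one-amine-out needs at least 2 amines")
    splits = []
    for amine in amines:
        test = tuple(i for i in idx if dataset.records[i].amine_id == amine)
        train = tuple(i for i in idx if dataset.records[i].amine_id != amine)
        splits.append((train, test))
    return SplitPlan(
        kind="leave_one_amine_out",
        splits=tuple(splits),
        held_out_amines=tuple(amines),
    )


@dataclass(frozen=True)
class LedgerEntry:
    feature_set: str
    split_kind: str
    split_index: int
    label_mode: str  # "true" or "shuffled"
    config: ModelConfig
    metrics: MetricReport
    feature_width: int


@dataclass
class ModelLedger:
    """All (feature set, split, label mode) models with hold-out metrics."""

    entries: list[LedgerEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    def for_feature_set(self, name: str) -> list[LedgerEntry]:
        return [e for e in self.entries if e.feature_set == name]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            rows.append(
                {
                    "feature_set": e.feature_set,
                    "split": f"{e.split_kind}[{e.split_index}]",
                    "label_mode": e.label_mode,
                    "precision": e.metrics.precision,
                    "recall": e.metrics.recall,
                    "accuracy": e.metrics.accuracy,
                    "auc": e.metrics.roc_auc,
                }
            )
        return pd.DataFrame(rows)


def _record_keys(dataset: ScreenDataset) -> set:
    return {r.key for r in dataset.records}


def run_cv_protocol(
    dataset: ScreenDataset,
    feature_specs: list[FeatureSetSpec],
    budget: int = 1000,
    seed: int = 0,
    properties: PropertySet | None = None,
    search_space: dict | None = None,
    inner_k: int = 3,
    vocab: ConditionVocabulary | None = None,
    temporal_guard: ScreenDataset | None = None,
) -> ModelLedger:
    """The dual cross-validation / shuffled-null protocol on one campaign.

    For every feature set and each of the 8 outer splits (3 random + 5 LOAO
    for a 5-amine library), tunes and trains a true-label and a
    shuffled-label model on the outer training rows only (standardization
    statistics included) and evaluates both on the hold-out rows, yielding
    2 x 8 ledger entries per feature set.

    ``temporal_guard``, when given, asserts that no temporal-campaign record
    sneaks into the training data.
    """
    if temporal_guard is not None:
        if temporal_guard.campaign_id == dataset.campaign_id or (
            _record_keys(temporal_guard) & _record_keys(dataset)
        ):
            raise LeakageError("temporal campaign overlaps the CV dataset")

    master = np.random.SeedSequence(seed)
    split_seed, tune_seed, shuffle_seed = (
        int(s.generate_state(1)[0] % (2**31)) for s in master.spawn(3)
    )

    random_plan = make_random_splits(dataset, seed=split_seed)
    loao_plan = make_loao_splits(dataset)
    all_splits = [
        (random_plan.kind, i, tr, te) for i, (tr, te) in enumerate(random_plan.splits)
    ] + [(loao_plan.kind, i, tr, te) for i, (tr, te) in enumerate(loao_plan.splits)]

    ledger = ModelLedger()
    for spec in feature_specs:
        X, y, standardizer, keys = assemble_features(
            dataset, spec, properties=properties, vocab=vocab
        )
        index_of = {k: row for row, k in enumerate(keys)}
        for split_kind, split_idx, train_idx, test_idx in all_splits:
            tr = np.array([index_of[dataset.records[i].key] for i in train_idx])
            te = np.array([index_of[dataset.records[i].key] for i in test_idx])
            std = standardizer.__class__(
                continuous_mask=standardizer.continuous_mask
            ).fit(X, rows=tr)
            Xs = std.transform(X)
            for label_mode in ("true", "shuffled"):
                y_train = y[tr]
                if label_mode == "shuffled":
                    y_train = shuffle_labels(
                        y_train, seed=shuffle_seed + 7919 * split_idx
                    )
                config, _ = tune_hyperparameters(
                    Xs[tr],
                    y_train,
                    search_space=search_space,
                    budget=budget,
                    inner_k=inner_k,
                    seed=tune_seed + 104729 * split_idx,
                )
                model = train_classifier(Xs[tr], y_train, config)
                metrics = evaluate_metrics(y[te], predict_scores(model, Xs[te]))
                ledger.entries.append(
                    LedgerEntry(
                        feature_set=spec.name,
                        split_kind=split_kind,
                        split_index=split_idx,
                        label_mode=label_mode,
                        config=config,
                        metrics=metrics,
                        feature_width=X.shape[1],
                    )
                )
    return ledger


def select_best_model(ledger: ModelLedger) -> tuple[str, ModelConfig]:
    """Pick the winning feature set by mean hold-out precision of true models.

    Ties break by mean ROC AUC, then smaller feature width.  The winner must
    out-precision its shuffled-label twins, otherwise :class:`NoSignalError`.
    Returns the feature-set name and the modal best config among its splits.
    """
    if not ledger.entries:
        raise ValueError("empty ledger")
    names = sorted({e.feature_set for e in ledger.entries})

    def _mean(entries, attr):
        vals = [getattr(e.metrics, attr) for e in entries]
        vals = [v for v in vals if not np.isnan(v)]
        return float(np.mean(vals)) if vals else float("nan")

    scored = []
    for name in names:
        true_e = [e for e in ledger.for_feature_set(name) if e.label_mode == "true"]
        null_e = [e for e in ledger.for_feature_set(name) if e.label_mode == "shuffled"]
        scored.append(
            (
                name,
                _mean(true_e, "precision"),
                _mean(true_e, "roc_auc"),
                true_e[0].feature_width,
                _mean(null_e, "precision"),
                true_e,
            )
        )
    scored.sort(key=lambda t: (-t[1], -t[2], t[3]))
    name, precision, _, _, null_precision, true_entries = scored[0]
    if not np.isnan(null_precision) and precision <= null_precision:
        raise NoSignalError(
            f"best feature set {name!r} does not beat its shuffled-label nulls "
            f"({precision:.3f} vs {null_precision:.3f})"
        )
    configs = [e.config for e in true_entries]
    counts: dict[ModelConfig, int] = {}
    for c in configs:
        counts[c] = counts.get(c, 0) + 1
    modal = max(counts, key=lambda c: (counts[c], -configs.index(c)))
    return name, modal


def train_final_model(
    dataset: ScreenDataset,
    spec: FeatureSetSpec,
    budget: int = 1000,
    seed: int = 0,
    properties: PropertySet | None = None,
    search_space: dict | None = None,
    vocab: ConditionVocabulary | None = None,
    config: ModelConfig | None = None,
) -> TrainedClassifier:
    """Re-tune (unless a config is given) and train on the whole campaign.

    The returned model embeds the fitted standardizer, the feature-set name,
    the condition vocabulary used, and the training campaign id, so temporal
    evaluation can verify there is no leakage.
    """
    if vocab is None and "conditions" in spec.blocks:
        vocab = ConditionVocabulary.from_datasets([dataset])
    X, y, standardizer, _ = assemble_features(
        dataset, spec, properties=properties, vocab=vocab
    )
    standardizer.fit(X)
    Xs = standardizer.transform(X)
    if config is None:
        config, _ = tune_hyperparameters(
            Xs, y, search_space=search_space, budget=budget, seed=seed
        )
    model = train_classifier(Xs, y, config)
    model.feature_set = spec.name
    model.standardizer = standardizer
    model.training_campaign = dataset.campaign_id
    model._spec = spec  # retained for temporal featurization
    model._vocab = vocab
    model._properties = properties
    return model


def evaluate_temporal(
    model: TrainedClassifier,
    temporal: ScreenDataset,
    properties: PropertySet | None = None,
) -> tuple[MetricReport, np.ndarray, list[tuple]]:
    """Score the held-out later campaign with the final model.

    Raises :class:`LeakageError` if the temporal campaign is the training
    campaign or shares any record with it.  Returns the metric report, the
    per-experiment scores (one per non-missing record) and the record keys.
    """
    if model.training_campaign is None:
        raise LeakageError("model lacks a recorded training campaign")
    if temporal.campaign_id == model.training_campaign:
        raise LeakageError("temporal evaluation on the training campaign itself")
    spec: FeatureSetSpec = getattr(model, "_spec")
    X, y, _, keys = assemble_features(
        temporal,
        spec,
        properties=properties if properties is not None else getattr(model, "_properties"),
        vocab=getattr(model, "_vocab"),
    )
    Xs = model.standardizer.transform(X)
    scores = predict_scores(model, Xs)
    return evaluate_metrics(y, scores), scores, keys


@dataclass(frozen=True)
class PrioritizationRow:
    """Outcome bookkeeping for one selection rule over scored experiments."""

    selector: str
    n_experiments: int
    n_success: int
    n_fail: int
    n_products_success: int
    n_products_fail: int


DEFAULT_THRESHOLDS = (0.0, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)


def prioritization_analysis(
    scores: np.ndarray,
    labels: np.ndarray,
    product_ids: list[tuple],
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS,
    highest_per_product: bool = True,
    inclusive: bool = True,
    condition_ranks: np.ndarray | None = None,
    agent_ids: list[str] | None = None,
) -> list[PrioritizationRow]:
    """What running only high-scoring experiments would have delivered.

    For each threshold t, selects experiments with score >= t (or > t with
    ``inclusive=False``) and counts selected experiments, experimental
    successes and failures, distinct products with a selected success, and
    distinct selected products with no selected success.  The
    ``highest_per_product`` rule instead picks exactly one experiment per
    product — the one with the maximal score, ties broken by harsher
    condition then lexicographic agent id when those vectors are supplied,
    else by record order.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if not (len(scores) == len(labels) == len(product_ids)):
        raise ValueError("scores, labels and product_ids must align")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary")

    def _row(selector: str, sel: np.ndarray) -> PrioritizationRow:
        n_sel = int(sel.sum())
        n_success = int(labels[sel].sum())
        succeeded = {p for p, s, l in zip(product_ids, sel, labels) if s and l}
        selected = {p for p, s in zip(product_ids, sel) if s}
        return PrioritizationRow(
            selector=selector,
            n_experiments=n_sel,
            n_success=n_success,
            n_fail=n_sel - n_success,
            n_products_success=len(succeeded),
            n_products_fail=len(selected - succeeded),
        )

    rows = []
    if highest_per_product:
        order = np.arange(len(scores))
        best_for: dict[tuple, int] = {}
        for i in order:
            p = product_ids[i]
            if p not in best_for:
                best_for[p] = i
                continue
            j = best_for[p]
            key_i = [scores[i]]
            key_j = [scores[j]]
            if condition_ranks is not None:
                key_i.append(condition_ranks[i])
                key_j.append(condition_ranks[j])
            if agent_ids is not None:
                # lexicographically smaller agent wins a residual tie
                key_i.append(-ord(agent_ids[i][0]))
                key_j.append(-ord(agent_ids[j][0]))
            if tuple(key_i) > tuple(key_j):
                best_for[p] = i
        sel = np.zeros(len(scores), dtype=bool)
        sel[list(best_for.values())] = True
        rows.append(_row("highest_score_per_product", sel))
    for t in thresholds:
        sel = scores >= t if inclusive else scores > t
        rows.append(_row(f"score>={t:g}" if inclusive else f"score>{t:g}", sel))
    return rows


def prioritization_frame(rows: list[PrioritizationRow]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "selector": r.selector,
                "n_experiments": r.n_experiments,
                "n_success": r.n_success,
                "n_fail": r.n_fail,
                "n_products_success": r.n_products_success,
                "n_products_fail": r.n_products_fail,
            }
            for r in rows
        ]
    )
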