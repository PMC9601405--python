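"""Synthetic screening campaigns with the statistical structure the analysis assumes.

The generator draws a latent success probability for every experiment from a
logistic model

    p = logistic(b0 + b_agent + b_T * z(T) + b_t * z(t) + u_acid + v_amine + w_pair)

with a strong temperature slope and a near-zero reaction-time slope (the
screening campaigns' dominant finding), coupling-agent-specific offsets
ordered PyCIU > TCFH > HATU > T3P, and per-acid, per-amine and per-pair
random effects for substrate-specific difficulty.  The observed response is
100*p plus Gaussian noise on the percentage scale, clipped to [0, 100];
sporadic instrument failures drop the response entirely.  With the default
intercept at logit(0.1) the 10% success threshold lands on the median of the
latent field, so classes come out roughly balanced.

The logistic surface is a statistical surrogate for testing the pipeline; it
makes no claim about the underlying amide-coupling chemistry.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field

import numpy as np

from .data import STATUS_FAILURE, STATUS_OK, ExperimentRecord, ScreenDataset
from .design import (
    ConditionGrid,
    ConditionPoint,
    ReagentSpec,
    build_condition_grid,
    enumerate_experiments,
    nine_point_grid,
)

#: Mono-functional carboxylic acids for virtual libraries (one COOH each).
ACID_SMILES_POOL = (
    "CC(=O)O",                # acetic
    "CCC(=O)O",               # propanoic
    "CCCC(=O)O",              # butanoic
    "CC(C)C(=O)O",            # 2-methylpropanoic
    "CC(C)(C)C(=O)O",         # pivalic
    "OC(=O)C1CC1",            # cyclopropanecarboxylic
    "OC(=O)C1CCCC1",          # cyclopentanecarboxylic
    "OC(=O)c1ccccc1",         # benzoic
    "Cc1ccc(cc1)C(=O)O",      # 4-methylbenzoic
    "OC(=O)c1ccco1",          # furan-2-carboxylic
    "OC(=O)c1ccncc1",         # pyridine-4-carboxylic
    "OC(=O)Cc1ccccc1",        # phenylacetic
)

#: Mono-functional primary/secondary amines (one N-H site each).
AMINE_SMILES_POOL = (
    "CN",                     # methylamine
    "CCN",                    # ethylamine
    "CCCN",                   # propylamine
    "CC(C)N",                 # isopropylamine
    "CCCCN",                  # butylamine
    "NC1CCCCC1",              # cyclohexylamine
    "NCc1ccccc1",             # benzylamine
    "Nc1ccccc1",              # aniline
    "Cc1ccc(N)cc1",           # 4-methylaniline
    "C1CCNC1",                # pyrrolidine
    "C1CCNCC1",               # piperidine
    "C1COCCN1",               # morpholine
)

#: Default agent log-odds offsets (zero mean), ordered as observed
#: effectiveness: PyCIU best, then TCFH, HATU, T3P worst.
DEFAULT_AGENT_EFFECTS = {"HATU": -0.4, "PyCIU": 1.2, "TCFH": 0.8, "T3P": -1.6}


@dataclass(frozen=True)
class SyntheticConfig:
    """Generator settings; the defaults are the standard study conditions."""

    n_acids: int = 5
    n_amines: int = 5
    agent_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_AGENT_EFFECTS)
    )
    beta0: float = math.log(0.1 / 0.9)  # logit of the 10% threshold
    temperature_slope: float = 1.5  # log-odds per SD of temperature
    time_slope: float = 0.0  # negligible reaction-time influence
    acid_sd: float = 0.8
    amine_sd: float = 0.8
    pair_sd: float = 0.6
    response_noise_sd: float = 5.0  # area-% units
    dropout_rate: float = 64.0 / 900.0  # instrument-failure probability
    threshold_pct: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_acids < 1 or self.n_amines < 1:
            raise ValueError("need at least one acid and one amine")
        if not (0.0 <= self.dropout_rate <= 1.0):
            raise ValueError("dropout_rate must lie in [0, 1]")
        for name in ("acid_sd", "amine_sd", "pair_sd", "response_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.n_acids > len(ACID_SMILES_POOL):
            raise ValueError("not enough acids in the SMILES pool")
        if self.n_amines > len(AMINE_SMILES_POOL):
            raise ValueError("not enough amines in the SMILES pool")


@dataclass
class GroundTruth:
    """Realized effects and per-experiment latent probabilities."""

    beta0: float
    agent_effects: dict
    temperature_slope: float
    time_slope: float
    temp_mean: float
    temp_sd: float
    time_mean: float
    time_sd: float
    acid_effects: dict = field(default_factory=dict)
    amine_effects: dict = field(default_factory=dict)
    pair_effects: dict = field(default_factory=dict)
    probabilities: dict = field(default_factory=dict)  # record key -> p
    success_fraction: float = float("nan")


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def ground_truth_probability(
    truth: GroundTruth,
    acid_id: str,
    amine_id: str,
    agent_id: str,
    condition: ConditionPoint,
) -> float:
    """Latent success probability of one experiment under realized effects."""
    z_T = (condition.temperature_C - truth.temp_mean) / truth.temp_sd
    z_t = (condition.reaction_time_s - truth.time_mean) / truth.time_sd
    eta = (
        truth.beta0
        + truth.agent_effects[agent_id]
        + truth.temperature_slope * z_T
        + truth.time_slope * z_t
        + truth.acid_effects[acid_id]
        + truth.amine_effects[amine_id]
        + truth.pair_effects[(acid_id, amine_id)]
    )
    return _logistic(eta)


def _reagents(config: SyntheticConfig, acid_start: int, amine_start: int):
    acids = [
        ReagentSpec(f"A{acid_start + i + 1}", "acid", smiles=ACID_SMILES_POOL[acid_start + i],
                    stock_concentration=0.13)
        for i in range(config.n_acids)
    ]
    amines = [
        ReagentSpec(f"B{amine_start + i + 1}", "amine",
                    smiles=AMINE_SMILES_POOL[amine_start + i],
                    stock_concentration=0.10)
        for i in range(config.n_amines)
    ]
    agents = [
        ReagentSpec(a, "coupling_agent", stock_concentration=0.15)
        for a in config.agent_effects
    ]
    return acids, amines, agents


def generate_library(
    config: SyntheticConfig,
    grid: ConditionGrid | None = None,
    campaign_id: str = "campaign-1",
    acid_start: int = 0,
    amine_start: int = 0,
    base_truth: GroundTruth | None = None,
    seed: int | None = None,
) -> tuple[ScreenDataset, GroundTruth]:
    """Generate one full-factorial virtual campaign plus its ground truth.

    With the defaults this is a 5 acids x 5 amines x 4 agents x 9 conditions
    campaign of 900 reactions with ~7% instrument-failure dropouts.  A later
    campaign sharing reagents with an earlier one reuses the earlier realized
    effects by passing ``base_truth`` (its z-scaling of temperature and time
    is reused too, so both campaigns live on one latent surface);
    ``acid_start``/``amine_start`` shift into unused regions of the SMILES
    pool to introduce new reagents.
    """
    grid = grid if grid is not None else nine_point_grid()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    acids, amines, agents = _reagents(config, acid_start, amine_start)
    plans = enumerate_experiments(acids, amines, agents, grid)

    temps = np.array([p.temperature_C for p in grid])
    times = np.array([p.reaction_time_s for p in grid])
    if base_truth is None:
        truth = GroundTruth(
            beta0=config.beta0,
            agent_effects=dict(config.agent_effects),
            temperature_slope=config.temperature_slope,
            time_slope=config.time_slope,
            temp_mean=float(temps.mean()),
            temp_sd=float(temps.std()) or 1.0,
            time_mean=float(times.mean()),
            time_sd=float(times.std()) or 1.0,
        )
    else:
        truth = dataclasses.replace(
            base_truth,
            acid_effects=dict(base_truth.acid_effects),
            amine_effects=dict(base_truth.amine_effects),
            pair_effects=dict(base_truth.pair_effects),
            probabilities={},
        )

    for a in acids:
        truth.acid_effects.setdefault(a.id, float(rng.normal(0, config.acid_sd)))
    for b in amines:
        truth.amine_effects.setdefault(b.id, float(rng.normal(0, config.amine_sd)))
    for a in acids:
        for b in amines:
            truth.pair_effects.setdefault(
                (a.id, b.id), float(rng.normal(0, config.pair_sd))
            )

    registry = {r.id: r for r in acids + amines + agents}
    records = []
    n_success = 0
    n_ok = 0
    for plan in plans:
        p = ground_truth_probability(
            truth, plan.acid_id, plan.amine_id, plan.agent_id, plan.condition
        )
        response = float(
            np.clip(100.0 * p + rng.normal(0, config.response_noise_sd), 0.0, 100.0)
        )
        failed = rng.random() < config.dropout_rate
        rec = ExperimentRecord(
            acid_id=plan.acid_id,
            amine_id=plan.amine_id,
            agent_id=plan.agent_id,
            condition=plan.condition,
            response_area_pct=None if failed else response,
            status=STATUS_FAILURE if failed else STATUS_OK,
        )
        records.append(rec)
        truth.probabilities[rec.key] = p
        if not failed:
            n_ok += 1
            n_success += int(response >= config.threshold_pct)
    truth.success_fraction = n_success / n_ok if n_ok else float("nan")
    dataset = ScreenDataset(campaign_id=campaign_id, records=records, registry=registry)
    return dataset, truth


def mid_pair_grid() -> ConditionGrid:
    """The two mid-ladder conditions used by a small follow-up campaign."""
    full = nine_point_grid()
    p4, p5 = full[3], full[4]
    return ConditionGrid(
        points=(
            ConditionPoint(p4.reaction_time_s, p4.temperature_C, 1),
            ConditionPoint(p5.reaction_time_s, p5.temperature_C, 2),
        ),
        anchors={"mid": ConditionPoint(p5.reaction_time_s, p5.temperature_C, 2)},
    )


def generate_temporal_pair(
    config: SyntheticConfig,
    temporal_n_acids: int = 6,
    temporal_n_amines: int = 5,
    seed: int | None = None,
) -> tuple[ScreenDataset, GroundTruth, ScreenDataset, GroundTruth]:
    """A training campaign plus a later validation campaign on one surface.

    The temporal campaign keeps the training acids (plus any extras from the
    pool), introduces entirely new amines, and runs only the two mid
    conditions — the structure of an external validation round.
    """
    base_seed = config.seed if seed is None else seed
    train_ds, train_truth = generate_library(config, seed=base_seed)
    temporal_cfg = dataclasses.replace(
        config, n_acids=temporal_n_acids, n_amines=temporal_n_amines
    )
    temporal_ds, temporal_truth = generate_library(
        temporal_cfg,
        grid=mid_pair_grid(),
        campaign_id="campaign-2",
        amine_start=config.n_amines,
        base_truth=train_truth,
        seed=base_seed + 1,
    )
    return train_ds, train_truth, temporal_ds, temporal_truth


def generate_property_table(
    reagents: list[ReagentSpec],
    n_properties: int = 8,
    seed: int = 0,
    rho: float = 0.0,
    truth: GroundTruth | None = None,
):
    """Per-reagent continuous descriptors, optionally carrying latent signal.

    Each property is ``rho * z + sqrt(1 - rho^2) * noise`` where ``z`` is the
    reagent's realized latent effect standardised over the supplied reagents;
    at ``rho = 0`` the table is pure noise, at high ``rho`` property-bearing
    feature sets can genuinely outperform.  Four pKa columns are appended.
    """
    import pandas as pd

    from .features import PropertySet

    if not reagents:
        raise ValueError("no reagents supplied")
    if not (0.0 <= abs(rho) <= 1.0):
        raise ValueError("rho must lie in [-1, 1]")
    rng = np.random.default_rng(seed)
    effects = {}
    for r in reagents:
        if truth is not None:
            effects[r.id] = truth.acid_effects.get(
                r.id, truth.amine_effects.get(r.id, 0.0)
            )
        else:
            effects[r.id] = 0.0
    vals = np.array([effects[r.id] for r in reagents], dtype=float)
    sd = vals.std()
    z = (vals - vals.mean()) / sd if sd > 0 else np.zeros_like(vals)

    rows = {}
    for i, r in enumerate(reagents):
        props = rho * z[i] + math.sqrt(1 - rho**2) * rng.normal(0, 1, n_properties)
        pkas = rng.uniform(2.0, 12.0, 4)
        rows[r.id] = np.concatenate([props, np.sort(pkas)])
    columns = [f"prop{i + 1}" for i in range(n_properties)] + [
        f"pka{i}" for i in range(1, 5)
    ]
    table = pd.DataFrame.from_dict(rows, orient="index", columns=columns)
    table.index.name = "reagent_id"
    return PropertySet(table=table)
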