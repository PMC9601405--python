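"""Experiment-grid design for stopped-flow library screening.

A screening campaign crosses a set of carboxylic acids with a set of amines,
a set of coupling agents, and an ordered ladder of physical reaction
conditions ranging from *soft* (short reaction time, low temperature) to
*harsh* (long time, high temperature).  This module defines the reagent and
condition value objects, builds the soft-to-harsh condition grid, enumerates
the full factorial experiment plan, and provides the stopped-flow timing and
reagent-usage arithmetic that motivates the reactor design.

The reaction time of a stopped-flow experiment decomposes into the transit
(residence) time while the slug is flowing plus the stationary hold time with
the pumps stopped; the hold time, not the pump, sets the reaction time.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .errors import DuplicateIdError, InvalidAnchorError, InvalidReagentError

ROLES = ("acid", "amine", "coupling_agent")


@dataclass(frozen=True)
class ReagentSpec:
    """One reagent stock: an acid, an amine, or a coupling agent.

    ``smiles`` may be omitted for coupling agents used purely as categorical
    levels.  ``base_partner``/``base_concentration`` record the activating
    base premixed with the acid for a given coupling agent.
    """

    id: str
    role: str
    smiles: str | None = None
    stock_concentration: float | None = None  # mol/L
    base_partner: str | None = None
    base_concentration: float | None = None  # mol/L

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise InvalidReagentError(
                f"role {self.role!r} for reagent {self.id!r}; expected one of {ROLES}"
            )
        if self.stock_concentration is not None and self.stock_concentration <= 0:
            raise InvalidReagentError(
                f"stock_concentration must be > 0 for {self.id!r}"
            )
        if self.smiles is not None:
            from rdkit import Chem

            if Chem.MolFromSmiles(self.smiles) is None:
                raise InvalidReagentError(
                    f"SMILES {self.smiles!r} for {self.id!r} does not parse"
                )


@dataclass(frozen=True, order=True)
class ConditionPoint:
    """A single (reaction time, temperature) screening condition."""

    reaction_time_s: float
    temperature_C: float
    harshness_rank: int = 1

    def __post_init__(self) -> None:
        if self.reaction_time_s <= 0:
            raise ValueError("reaction_time_s must be > 0")
        if self.temperature_C <= 0:
            raise ValueError("temperature_C must be > 0")
        if self.harshness_rank < 1:
            raise ValueError("harshness_rank must be >= 1")


@dataclass(frozen=True)
class ConditionGrid:
    """Ordered soft-to-harsh ladder of screening conditions."""

    points: tuple[ConditionPoint, ...]
    anchors: dict = field(default_factory=dict, compare=False)

    def __post_init__(self) -> None:
        ranks = [p.harshness_rank for p in self.points]
        if ranks != sorted(ranks) or len(set(ranks)) != len(ranks):
            raise ValueError("points must be sorted by unique harshness_rank")
        times = [p.reaction_time_s for p in self.points]
        temps = [p.temperature_C for p in self.points]
        if times != sorted(times) or temps != sorted(temps):
            raise ValueError(
                "reaction time and temperature must be non-decreasing along the ranking"
            )

    def __len__(self) -> int:
        return len(self.points)

    def __iter__(self):
        return iter(self.points)

    def __getitem__(self, i: int) -> ConditionPoint:
        return self.points[i]


@dataclass(frozen=True)
class FlowSetup:
    """Hydraulic description of the stopped-flow reactor and its comparator.

    ``steady_state_volume_mL`` is the reagent volume a fully continuous
    system would consume to reach steady state before sampling, used for the
    usage comparison.
    """

    reactor_volume_uL: float = 1000.0
    per_pump_flow_uL_min: float = 500.0
    n_pumps: int = 3
    slug_volume_uL: float = 500.0
    safety_multiplier: float = 2.0
    steady_state_volume_mL: float = 10.0

    def __post_init__(self) -> None:
        for name in (
            "reactor_volume_uL",
            "per_pump_flow_uL_min",
            "slug_volume_uL",
            "steady_state_volume_mL",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.n_pumps < 1:
            raise ValueError("n_pumps must be >= 1")
        if self.safety_multiplier < 1:
            raise ValueError("safety_multiplier must be >= 1")


@dataclass(frozen=True)
class ExperimentPlan:
    """One planned reaction: a reagent triple at one condition."""

    acid_id: str
    amine_id: str
    agent_id: str
    condition: ConditionPoint

    @property
    def product_id(self) -> tuple[str, str]:
        return (self.acid_id, self.amine_id)


def build_condition_grid(
    n_points: int,
    soft: ConditionPoint,
    mid: ConditionPoint,
    harsh: ConditionPoint,
) -> ConditionGrid:
    """Collapse the 2-D (time, temperature) space onto a 1-D harshness ladder.

    Reaction times are interpolated linearly from ``soft`` to ``harsh``.
    Temperatures are piecewise linear through the ``mid`` anchor — soft->mid
    over the first half of the ranking and mid->harsh over the second — so
    that the named mid condition is itself a member of any odd-length grid.

    Parameters
    ----------
    n_points
        Number of conditions; the screening campaigns here use 9.
    soft, mid, harsh
        Named anchor conditions, component-wise non-decreasing.
    """
    if n_points < 1:
        raise ValueError("n_points must be >= 1")
    for a, b in ((soft, mid), (mid, harsh)):
        if (
            a.reaction_time_s > b.reaction_time_s
            or a.temperature_C > b.temperature_C
        ):
            raise InvalidAnchorError(
                "anchors must satisfy soft <= mid <= harsh component-wise"
            )
    if n_points == 1:
        pts = (ConditionPoint(soft.reaction_time_s, soft.temperature_C, 1),)
        return ConditionGrid(points=pts, anchors={"soft": pts[0]})
    if n_points % 2 == 0:
        warnings.warn(
            "even n_points: the mid anchor is snapped to the nearest rank",
            stacklevel=2,
        )
    times = np.linspace(soft.reaction_time_s, harsh.reaction_time_s, n_points)
    mid_idx = (n_points - 1) // 2
    temps = np.concatenate(
        [
            np.linspace(soft.temperature_C, mid.temperature_C, mid_idx + 1),
            np.linspace(mid.temperature_C, harsh.temperature_C, n_points - mid_idx)[1:],
        ]
    )
    pts = tuple(
        ConditionPoint(float(t), float(T), rank)
        for rank, (t, T) in enumerate(zip(times, temps), start=1)
    )
    anchors = {"soft": pts[0], "mid": pts[mid_idx], "harsh": pts[-1]}
    return ConditionGrid(points=pts, anchors=anchors)


def enumerate_experiments(
    acids: Sequence[ReagentSpec],
    amines: Sequence[ReagentSpec],
    coupling_agents: Sequence[ReagentSpec],
    grid: ConditionGrid | Iterable[ConditionPoint],
) -> list[ExperimentPlan]:
    """Full factorial cross of acids x amines x coupling agents x conditions."""
    sets = {"acid": acids, "amine": amines, "coupling_agent": coupling_agents}
    for role, reagents in sets.items():
        if not reagents:
            raise ValueError(f"empty {role} list")
        for r in reagents:
            if r.role != role:
                raise InvalidReagentError(
                    f"reagent {r.id!r} has role {r.role!r}, expected {role!r}"
                )
        ids = [r.id for r in reagents]
        if len(set(ids)) != len(ids):
            raise DuplicateIdError(f"duplicate ids in {role} list: {ids}")
    points = list(grid)
    if not points:
        raise ValueError("empty condition grid")
    return [
        ExperimentPlan(a.id, b.id, ca.id, cond)
        for a, b, ca, cond in itertools.product(acids, amines, coupling_agents, points)
    ]


def reaction_time_components(
    setup: FlowSetup, stationary_time_s: float
) -> dict[str, float]:
    """Decompose reaction time Rt into transit and stationary contributions.

    Transit counts one reactor volume moved at the total flow rate
    (``n_pumps * per_pump_flow``); Rt = transit + stationary hold.  Because
    the hold time is set by a timer, not by the pump, Rt is decoupled from
    flow-rate capacity whenever the stationary term dominates.
    """
    if stationary_time_s < 0:
        raise ValueError("stationary_time_s must be >= 0")
    total_flow_uL_min = setup.n_pumps * setup.per_pump_flow_uL_min
    if total_flow_uL_min <= 0:
        raise ZeroDivisionError("total flow rate is zero")
    transit_s = setup.reactor_volume_uL / total_flow_uL_min * 60.0
    return {
        "transit_s": transit_s,
        "stationary_s": float(stationary_time_s),
        "reaction_time_s": transit_s + stationary_time_s,
    }


def reagent_usage_comparison(setup: FlowSetup) -> dict[str, float]:
    """Reagent volume per reaction: stopped-flow slug vs continuous steady state.

    The stopped-flow reactor consumes one safety-padded slug per reaction;
    the continuous comparator must flush to steady state first.  Returns the
    two volumes (mL) and the percentage reduction.
    """
    stopped_flow_mL = setup.slug_volume_uL * setup.safety_multiplier / 1000.0
    continuous_mL = setup.steady_state_volume_mL
    reduction_pct = 100.0 * (1.0 - stopped_flow_mL / continuous_mL)
    if reduction_pct <= 0:
        warnings.warn(
            "stopped-flow usage does not undercut the continuous comparator",
            stacklevel=2,
        )
    return {
        "stopped_flow_mL": stopped_flow_mL,
        "continuous_mL": continuous_mL,
        "reduction_pct": reduction_pct,
    }


# --- presets -----------------------------------------------------------------

SOFT_ANCHOR = ConditionPoint(120.0, 50.0, 1)
MID_ANCHOR = ConditionPoint(360.0, 120.0, 5)
HARSH_ANCHOR = ConditionPoint(600.0, 200.0, 9)


def nine_point_grid() -> ConditionGrid:
    """The campaign's 9-point soft->harsh screening ladder.

    Anchored at (120 s, 50 C), (360 s, 120 C) and (600 s, 200 C); times step
    linearly by 60 s, temperatures piecewise linearly through the mid anchor.
    """
    return build_condition_grid(9, SOFT_ANCHOR, MID_ANCHOR, HARSH_ANCHOR)


def default_flow_setup() -> FlowSetup:
    """1000 uL coil fed by three pumps at 0.5 mL/min each, 500 uL slug,
    2x safety padding, against a 10 mL continuous steady-state comparator."""
    return FlowSetup()


#: Coupling agents screened, with the base premixed with the acid stock.
COUPLING_AGENTS = (
    ReagentSpec("HATU", "coupling_agent", stock_concentration=0.15,
                base_partner="N,N-diisopropylethylamine", base_concentration=0.35),
    ReagentSpec("PyCIU", "coupling_agent", stock_concentration=0.15,
                base_partner="1-methyl-1H-imidazole", base_concentration=0.35),
    ReagentSpec("TCFH", "coupling_agent", stock_concentration=0.15,
                base_partner="1-methyl-1H-imidazole", base_concentration=0.35),
    ReagentSpec("T3P", "coupling_agent", stock_concentration=0.15,
                base_partner="triethylamine", base_concentration=0.35),
)

#: Stock concentrations used throughout: acid 0.13 M, amine 0.10 M (limiting),
#: coupling agent 0.15 M, base 0.35 M, toluene internal standard 0.10 M.
STOCK_CONCENTRATIONS = {
    "acid": 0.13,
    "amine": 0.10,
    "coupling_agent": 0.15,
    "base": 0.35,
    "internal_standard": 0.10,
}
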