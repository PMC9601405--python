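"""Screening results: storage, outcome labelling, and success-rate analytics.

The screening response is the UV peak area of the target amide relative to
the total chromatogram area at 254 nm, in percent.  A reaction counts as
*successful* when that relative area reaches a threshold (default 10%, the
rule-of-thumb proxy for recovering enough product for a bioassay); reactions
whose analysis was lost to an instrument failure carry no response and are
labelled *missing*.

Success-rate tables summarise a labelled campaign at three scopes: a single
(agent, condition) bucket, one agent across the whole condition ladder, and
the full screen across agents and conditions.  Denominators always count the
designed products, so missing data lower numerators only.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .design import ConditionPoint, ReagentSpec
from .errors import NotLabelledError, SchemaError

logger = logging.getLogger(__name__)

STATUS_OK = "ok"
STATUS_FAILURE = "instrument_failure"
LABEL_SUCCESS = "successful"
LABEL_FAILED = "failed"
LABEL_MISSING = "missing"

#: Exact column order of the dataset CSV schema.
CSV_COLUMNS = [
    "campaign_id",
    "acid_id",
    "amine_id",
    "agent_id",
    "reaction_time_s",
    "temperature_C",
    "response_area_pct",
    "is_area",
    "product_area",
    "status",
]


@dataclass(frozen=True)
class ExperimentRecord:
    """One reaction result.

    ``response_area_pct`` is present iff ``status == "ok"``; ``label`` is
    ``None`` until :func:`label_outcomes` has run, and ``"missing"`` exactly
    for instrument failures.
    """

    acid_id: str
    amine_id: str
    agent_id: str
    condition: ConditionPoint
    response_area_pct: float | None = None
    is_area: float | None = None
    product_area: float | None = None
    status: str = STATUS_OK
    label: str | None = None

    def __post_init__(self) -> None:
        if self.status not in (STATUS_OK, STATUS_FAILURE):
            raise ValueError(f"unknown status {self.status!r}")
        if self.status == STATUS_OK:
            if self.response_area_pct is None:
                raise ValueError("status=ok requires response_area_pct")
            if not (0.0 <= self.response_area_pct <= 100.0):
                raise ValueError(
                    f"response_area_pct {self.response_area_pct} outside [0, 100]"
                )
        else:
            if self.response_area_pct is not None:
                raise ValueError("instrument_failure records carry no response")
            if self.label not in (None, LABEL_MISSING):
                raise ValueError("instrument_failure records must be labelled missing")
        if self.label not in (None, LABEL_SUCCESS, LABEL_FAILED, LABEL_MISSING):
            raise ValueError(f"unknown label {self.label!r}")

    @property
    def product_id(self) -> tuple[str, str]:
        return (self.acid_id, self.amine_id)

    @property
    def key(self) -> tuple:
        return (
            self.acid_id,
            self.amine_id,
            self.agent_id,
            self.condition.reaction_time_s,
            self.condition.temperature_C,
        )


@dataclass
class ScreenDataset:
    """A screening campaign: records plus a reagent registry."""

    campaign_id: str
    records: list[ExperimentRecord]
    registry: dict[str, ReagentSpec] = field(default_factory=dict)

    def __post_init__(self) -> None:
        keys = [r.key for r in self.records]
        if len(set(keys)) != len(keys):
            raise ValueError("duplicate (acid, amine, agent, condition) keys")
        if self.registry:
            for r in self.records:
                for rid in (r.acid_id, r.amine_id, r.agent_id):
                    if rid not in self.registry:
                        raise ValueError(f"id {rid!r} not in reagent registry")

    def __len__(self) -> int:
        return len(self.records)

    @property
    def is_labelled(self) -> bool:
        return all(r.label is not None for r in self.records)

    @property
    def products(self) -> list[tuple[str, str]]:
        """Distinct designed products, in first-appearance order."""
        seen: dict[tuple[str, str], None] = {}
        for r in self.records:
            seen.setdefault(r.product_id)
        return list(seen)

    def usable_records(self) -> list[ExperimentRecord]:
        return [r for r in self.records if r.status == STATUS_OK]


def label_outcomes(
    dataset: ScreenDataset,
    threshold_pct: float = 10.0,
    inclusive: bool = True,
) -> ScreenDataset:
    """Apply the binary success rule to every record.

    successful iff status ok and response >= threshold (or > with
    ``inclusive=False``); failed iff ok and below; missing otherwise.
    Idempotent: relabelling a labelled dataset gives the same labels.
    """
    if not (0.0 < threshold_pct < 100.0):
        raise ValueError("threshold_pct must lie in (0, 100)")

    def _label(r: ExperimentRecord) -> str:
        if r.status != STATUS_OK:
            return LABEL_MISSING
        assert r.response_area_pct is not None
        hit = (
            r.response_area_pct >= threshold_pct
            if inclusive
            else r.response_area_pct > threshold_pct
        )
        return LABEL_SUCCESS if hit else LABEL_FAILED

    return replace(
        dataset, records=[replace(r, label=_label(r)) for r in dataset.records]
    )


def _require_labelled(dataset: ScreenDataset) -> None:
    if not dataset.is_labelled:
        raise NotLabelledError("dataset must be labelled first (label_outcomes)")


def success_rate_table(dataset: ScreenDataset, mode: str) -> pd.DataFrame:
    """Library success-rate table at one of three screening scopes.

    ``single_condition``: per (agent, condition) bucket — what a one-shot
    library attempt at that condition would have delivered.
    ``per_agent_sequence``: per agent across the full condition ladder.
    ``full_screen``: across all agents and conditions.

    SRxn counts products with at least one successful reaction in scope;
    the denominator is the number of designed products; LS_pct = 100*SRxn/denominator.
    """
    _require_labelled(dataset)
    denominator = len(dataset.products)
    rows = []

    def _srxn(records) -> int:
        return len({r.product_id for r in records if r.label == LABEL_SUCCESS})

    if mode == "single_condition":
        buckets: dict[tuple[str, int], list[ExperimentRecord]] = {}
        for r in dataset.records:
            buckets.setdefault((r.agent_id, r.condition.harshness_rank), []).append(r)
        for (agent, rank), recs in sorted(buckets.items()):
            cond = recs[0].condition
            rows.append(
                {
                    "scope": f"rank_{rank} ({cond.reaction_time_s:g} s, "
                    f"{cond.temperature_C:g} C)",
                    "agent_id": agent,
                    "SRxn": _srxn(recs),
                }
            )
    elif mode == "per_agent_sequence":
        buckets = {}
        for r in dataset.records:
            buckets.setdefault(r.agent_id, []).append(r)
        for agent, recs in sorted(buckets.items()):
            rows.append({"scope": "sequence", "agent_id": agent, "SRxn": _srxn(recs)})
    elif mode == "full_screen":
        rows.append(
            {"scope": "full_screen", "agent_id": "all", "SRxn": _srxn(dataset.records)}
        )
    else:
        raise ValueError(f"unknown mode {mode!r}")

    table = pd.DataFrame(rows)
    table["denominator"] = denominator
    table["LS_pct"] = 100.0 * table["SRxn"] / denominator
    return table


def heatmap_matrix(dataset: ScreenDataset) -> pd.DataFrame:
    """Campaign heatmap: rows (acid, condition rank), columns (amine, agent).

    Cells hold the relative response area; instrument-failure cells are NaN,
    distinct from a true 0% response.
    """
    _require_labelled(dataset)
    if not dataset.records:
        return pd.DataFrame()
    rows = sorted({(r.acid_id, r.condition.harshness_rank) for r in dataset.records})
    cols = sorted({(r.amine_id, r.agent_id) for r in dataset.records})
    index = pd.MultiIndex.from_tuples(rows, names=["acid_id", "harshness_rank"])
    columns = pd.MultiIndex.from_tuples(cols, names=["amine_id", "agent_id"])
    mat = pd.DataFrame(np.nan, index=index, columns=columns)
    for r in dataset.records:
        value = r.response_area_pct if r.status == STATUS_OK else np.nan
        mat.loc[(r.acid_id, r.condition.harshness_rank), (r.amine_id, r.agent_id)] = value
    return mat


def optimisation_objective(product_area: float, is_area: float) -> float:
    """DoE minimisation objective: internal-standard area over product area.

    Decreases as the product peak grows; a non-positive product area returns
    +inf (worst case) rather than raising, so optimisers can rank it.
    """
    if is_area <= 0:
        raise ValueError("is_area must be > 0")
    if product_area <= 0:
        logger.warning("non-positive product area %s; objective set to +inf", product_area)
        return math.inf
    return is_area / product_area


# --- CSV persistence ---------------------------------------------------------


def write_dataset(dataset: ScreenDataset, path: str | Path) -> None:
    """Write records to the declared CSV schema (labels are not persisted)."""
    rows = []
    for r in dataset.records:
        rows.append(
            {
                "campaign_id": dataset.campaign_id,
                "acid_id": r.acid_id,
                "amine_id": r.amine_id,
                "agent_id": r.agent_id,
                "reaction_time_s": r.condition.reaction_time_s,
                "temperature_C": r.condition.temperature_C,
                "response_area_pct": r.response_area_pct,
                "is_area": r.is_area,
                "product_area": r.product_area,
                "status": r.status,
            }
        )
    pd.DataFrame(rows, columns=CSV_COLUMNS).to_csv(path, index=False)


def read_dataset(
    path: str | Path, registry: dict[str, ReagentSpec] | None = None
) -> ScreenDataset:
    """Read a campaign CSV, enforcing the schema invariants.

    Condition ranks are reassigned by sorting the distinct (time,
    temperature) pairs in the file soft to harsh.
    """
    df = pd.read_csv(path)
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise SchemaError(f"missing columns: {missing_cols}")
    if df.empty:
        raise SchemaError("empty dataset file")
    campaigns = df["campaign_id"].unique()
    if len(campaigns) != 1:
        raise SchemaError(f"expected one campaign per file, found {list(campaigns)}")

    conds = sorted(
        {(float(t), float(T)) for t, T in zip(df["reaction_time_s"], df["temperature_C"])}
    )
    rank = {c: i + 1 for i, c in enumerate(conds)}

    records = []
    for i, row in df.iterrows():
        status = row["status"]
        resp = row["response_area_pct"]
        has_resp = pd.notna(resp)
        if status == STATUS_OK and not has_resp:
            raise SchemaError(f"row {i}: status ok but response_area_pct blank")
        if status == STATUS_FAILURE and has_resp:
            raise SchemaError(f"row {i}: instrument_failure with a response value")
        if has_resp and not (0.0 <= float(resp) <= 100.0):
            raise SchemaError(
                f"row {i}: response_area_pct {resp} outside [0, 100]"
            )
        cond_key = (float(row["reaction_time_s"]), float(row["temperature_C"]))
        try:
            records.append(
                ExperimentRecord(
                    acid_id=str(row["acid_id"]),
                    amine_id=str(row["amine_id"]),
                    agent_id=str(row["agent_id"]),
                    condition=ConditionPoint(*cond_key, rank[cond_key]),
                    response_area_pct=float(resp) if has_resp else None,
                    is_area=float(row["is_area"]) if pd.notna(row["is_area"]) else None,
                    product_area=(
                        float(row["product_area"])
                        if pd.notna(row["product_area"])
                        else None
                    ),
                    status=str(status),
                )
            )
        except ValueError as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    return ScreenDataset(
        campaign_id=str(campaigns[0]), records=records, registry=registry or {}
    )
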