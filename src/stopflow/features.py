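"""Model features for reaction-outcome classification.

Each experiment is described by some combination of:

* a *reaction fingerprint* — the product's circular count fingerprint minus
  the summed reactant (acid + amine) fingerprints, a signed vector of the
  atom environments created and destroyed by the coupling;
* a *product fingerprint* — the product's own count fingerprint, which
  restores the structural context the subtraction removes;
* a condition one-hot block — one bit group per coupling agent, temperature
  level and time level (e.g. 4 + 5 + 5 = 14 bits);
* continuous physicochemical property and pKa blocks per reagent, ingested
  from tables (never computed here).

Fingerprints are hashed Morgan count fingerprints at radius 3, optionally
concatenated with the RDKit path-based fingerprint; counts rather than bits
so that the reaction-difference subtraction preserves multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from rdkit import Chem
from rdkit.Chem import AllChem, rdFingerprintGenerator

from .data import LABEL_MISSING, LABEL_SUCCESS, ScreenDataset
from .errors import (
    AmbiguousProductError,
    EncodingError,
    IncompatibleFingerprintError,
    MissingBlockError,
    NoReactiveSiteError,
    NotLabelledError,
)

DEFAULT_FP_LENGTH = 2048
DEFAULT_RADIUS = 3

_AMIDATION = AllChem.ReactionFromSmarts(
    "[C:1](=[O:2])[OX2H1].[NX3;H3,H2,H1;!$(N[C,S]=[O,S,N]):3]>>[C:1](=[O:2])[N:3]"
)


def amide_product_smiles(acid_smiles: str, amine_smiles: str) -> str:
    """Canonical SMILES of the amide condensation product (water lost).

    Raises :class:`NoReactiveSiteError` when either partner lacks the
    required group, and :class:`AmbiguousProductError` when several distinct
    amides are possible (poly-functional reactants) — supply an explicit
    product SMILES in that case.
    """
    acid = Chem.MolFromSmiles(acid_smiles)
    amine = Chem.MolFromSmiles(amine_smiles)
    if acid is None:
        raise ValueError(f"invalid acid SMILES {acid_smiles!r}")
    if amine is None:
        raise ValueError(f"invalid amine SMILES {amine_smiles!r}")
    products = _AMIDATION.RunReactants((acid, amine))
    smiles = set()
    for (prod,) in products:
        try:
            Chem.SanitizeMol(prod)
        except Exception:
            continue
        smiles.add(Chem.MolToSmiles(prod))
    if not smiles:
        raise NoReactiveSiteError(
            f"no amide coupling possible between {acid_smiles!r} and {amine_smiles!r}"
        )
    if len(smiles) > 1:
        raise AmbiguousProductError(
            f"{len(smiles)} distinct amide products for {acid_smiles!r} + "
            f"{amine_smiles!r}; provide an explicit product SMILES"
        )
    return smiles.pop()


@dataclass(frozen=True)
class MoleculeFP:
    """Hashed circular count fingerprint of one molecule."""

    counts: np.ndarray
    radius: int = DEFAULT_RADIUS
    variant: str = "circular"

    def __post_init__(self) -> None:
        if self.variant not in ("circular", "circular+path"):
            raise ValueError(f"unknown variant {self.variant!r}")
        if np.any(self.counts < 0):
            raise ValueError("fingerprint counts must be >= 0")

    def __len__(self) -> int:
        return len(self.counts)


def circular_count_fp(
    smiles: str,
    radius: int = DEFAULT_RADIUS,
    length: int = DEFAULT_FP_LENGTH,
    variant: str = "circular",
) -> MoleculeFP:
    """Morgan count fingerprint folded to ``length``.

    ``variant="circular+path"`` appends the RDKit path-based fingerprint
    (as 0/1 counts) in a second block of the same length.
    """
    mol = Chem.MolFromSmiles(smiles)
    if mol is None:
        raise ValueError(f"invalid SMILES {smiles!r}")
    gen = rdFingerprintGenerator.GetMorganGenerator(radius=radius, fpSize=length)
    counts = np.array(gen.GetCountFingerprintAsNumPy(mol), dtype=np.int64)
    if variant == "circular+path":
        rdk = rdFingerprintGenerator.GetRDKitFPGenerator(fpSize=length)
        path_bits = np.array(rdk.GetFingerprintAsNumPy(mol), dtype=np.int64)
        counts = np.concatenate([counts, path_bits])
    return MoleculeFP(counts=counts, radius=radius, variant=variant)


@dataclass(frozen=True)
class ReactionFeature:
    """Signed difference fingerprint: product minus summed reactants."""

    values: np.ndarray


def reaction_fingerprint(
    product_fp: MoleculeFP, reactant_fps: list[MoleculeFP]
) -> ReactionFeature:
    """Element-wise product counts minus the sum of reactant counts.

    Adding the reactant sum back reconstructs the product counts exactly.
    """
    for fp in reactant_fps:
        if len(fp) != len(product_fp) or fp.variant != product_fp.variant:
            raise IncompatibleFingerprintError(
                "all fingerprints must share length and variant"
            )
    total = sum((fp.counts for fp in reactant_fps), np.zeros_like(product_fp.counts))
    return ReactionFeature(values=product_fp.counts - total)


@dataclass(frozen=True)
class ConditionVocabulary:
    """Categorical levels for the condition one-hot blocks."""

    agents: tuple[str, ...]
    temperatures: tuple[float, ...]
    times: tuple[float, ...]

    @property
    def width(self) -> int:
        return len(self.agents) + len(self.temperatures) + len(self.times)

    @classmethod
    def from_datasets(cls, datasets: list[ScreenDataset]) -> "ConditionVocabulary":
        agents: set[str] = set()
        temps: set[float] = set()
        times: set[float] = set()
        for ds in datasets:
            for r in ds.records:
                agents.add(r.agent_id)
                temps.add(r.condition.temperature_C)
                times.add(r.condition.reaction_time_s)
        return cls(tuple(sorted(agents)), tuple(sorted(temps)), tuple(sorted(times)))


@dataclass(frozen=True)
class ConditionEncoding:
    bits: np.ndarray
    block_sizes: tuple[int, int, int]


def encode_conditions(
    agent_id: str,
    temperature_C: float,
    reaction_time_s: float,
    vocab: ConditionVocabulary,
) -> ConditionEncoding:
    """Three concatenated one-hot blocks: agent, temperature, time.

    Out-of-vocabulary values raise :class:`EncodingError`; the vocabulary is
    never silently extended.
    """
    bits = np.zeros(vocab.width, dtype=np.int64)
    offset = 0
    for value, levels in (
        (agent_id, vocab.agents),
        (temperature_C, vocab.temperatures),
        (reaction_time_s, vocab.times),
    ):
        try:
            idx = levels.index(value)
        except ValueError:
            raise EncodingError(f"value {value!r} not in vocabulary {levels}") from None
        bits[offset + idx] = 1
        offset += len(levels)
    return ConditionEncoding(
        bits=bits,
        block_sizes=(len(vocab.agents), len(vocab.temperatures), len(vocab.times)),
    )


@dataclass
class PropertySet:
    """Continuous per-reagent descriptors (physicochemical properties, pKa).

    ``table`` is indexed by reagent id with one column per descriptor; NaN
    marks a missing value.
    """

    table: pd.DataFrame

    @classmethod
    def from_long_csv(cls, path) -> "PropertySet":
        """Read a long-format CSV: reagent_id, property_name, value."""
        df = pd.read_csv(path)
        wide = df.pivot(index="reagent_id", columns="property_name", values="value")
        return cls(table=wide)

    @classmethod
    def from_pka_csv(cls, path) -> "PropertySet":
        """Read a pKa CSV: reagent_id, pka1..pka4."""
        df = pd.read_csv(path).set_index("reagent_id")
        return cls(table=df)

    def merge(self, other: "PropertySet") -> "PropertySet":
        return PropertySet(
            table=self.table.join(other.table, how="outer")
        )

    def vector(self, reagent_id: str) -> np.ndarray:
        if reagent_id not in self.table.index:
            raise KeyError(f"no properties for reagent {reagent_id!r}")
        return self.table.loc[reagent_id].to_numpy(dtype=float)

    def to_long_frame(self) -> pd.DataFrame:
        long = self.table.reset_index().melt(
            id_vars="reagent_id", var_name="property_name", value_name="value"
        )
        return long.dropna(subset=["value"])


VALID_BLOCKS = ("reaction_fp", "product_fp", "conditions", "properties")


@dataclass(frozen=True)
class FeatureSetSpec:
    """A named combination of feature blocks."""

    name: str
    blocks: tuple[str, ...]
    fp_variant: str = "circular"
    fp_length: int = DEFAULT_FP_LENGTH
    fp_radius: int = DEFAULT_RADIUS

    def __post_init__(self) -> None:
        if not self.blocks:
            raise ValueError("feature-set spec needs at least one block")
        for b in self.blocks:
            if b not in VALID_BLOCKS:
                raise ValueError(f"unknown block {b!r}")


def default_registry(
    fp_variant: str = "circular", fp_length: int = DEFAULT_FP_LENGTH
) -> dict[str, FeatureSetSpec]:
    """The 12 standard feature sets: {reaction, product, reaction+product}
    fingerprints crossed with the optional condition and property blocks."""
    fp_choices = {
        "rxnfp": ("reaction_fp",),
        "prodfp": ("product_fp",),
        "rxnfp_prodfp": ("reaction_fp", "product_fp"),
    }
    registry = {}
    for fp_name, fp_blocks in fp_choices.items():
        for cond in (False, True):
            for props in (False, True):
                blocks = fp_blocks
                name = fp_name
                if cond:
                    blocks = blocks + ("conditions",)
                    name += "_cond"
                if props:
                    blocks = blocks + ("properties",)
                    name += "_props"
                registry[name] = FeatureSetSpec(
                    name=name, blocks=blocks, fp_variant=fp_variant, fp_length=fp_length
                )
    return registry


@dataclass
class FeatureStandardizer:
    """Column-wise z-scaling of the continuous (property) block only.

    Statistics are fitted on training rows and reused verbatim on any later
    matrix, so hold-out and temporal rows never leak into the fit.
    """

    continuous_mask: np.ndarray
    mean_: np.ndarray | None = None
    scale_: np.ndarray | None = None

    def fit(self, X: np.ndarray, rows: np.ndarray | None = None) -> "FeatureStandardizer":
        sub = X if rows is None else X[rows]
        cont = sub[:, self.continuous_mask]
        self.mean_ = cont.mean(axis=0) if cont.size else np.zeros(0)
        scale = cont.std(axis=0) if cont.size else np.zeros(0)
        self.scale_ = np.where(scale == 0, 1.0, scale)
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        if self.mean_ is None:
            raise ValueError("standardizer not fitted")
        out = X.astype(float).copy()
        if self.continuous_mask.any():
            out[:, self.continuous_mask] = (
                out[:, self.continuous_mask] - self.mean_
            ) / self.scale_
        return out


def _impute_with_indicators(block: pd.DataFrame) -> pd.DataFrame:
    """Median-impute NaNs; append a 0/1 missingness indicator per affected column."""
    out = block.copy()
    for col in block.columns:
        if block[col].isna().any():
            median = block[col].median()
            if np.isnan(median):
                raise ValueError(f"property column {col!r} entirely missing")
            out[f"{col}__missing"] = block[col].isna().astype(float)
            out[col] = block[col].fillna(median)
    return out


def assemble_features(
    dataset: ScreenDataset,
    spec: FeatureSetSpec,
    properties: PropertySet | None = None,
    vocab: ConditionVocabulary | None = None,
    product_smiles: dict[tuple[str, str], str] | None = None,
) -> tuple[np.ndarray, np.ndarray, FeatureStandardizer, list[tuple]]:
    """Build the feature matrix and label vector for one feature-set spec.

    Records labelled *missing* are dropped.  Blocks are concatenated in the
    order declared by ``spec.blocks``; row order follows the dataset's record
    order, so matrices are reproducible.  Returns ``(X, y, standardizer,
    keys)`` where the standardizer is **unfitted** — callers fit it on their
    training rows — and ``keys`` are the record keys row by row.

    Fingerprint blocks need SMILES in the dataset registry for every acid and
    amine; products are formed by :func:`amide_product_smiles` unless
    overridden via ``product_smiles``.
    """
    if not dataset.is_labelled:
        raise NotLabelledError("assemble_features needs a labelled dataset")
    records = [r for r in dataset.records if r.label != LABEL_MISSING]

    needs_fp = "reaction_fp" in spec.blocks or "product_fp" in spec.blocks
    fp_cache: dict[str, MoleculeFP] = {}

    def _fp(smiles: str) -> MoleculeFP:
        if smiles not in fp_cache:
            fp_cache[smiles] = circular_count_fp(
                smiles, spec.fp_radius, spec.fp_length, spec.fp_variant
            )
        return fp_cache[smiles]

    if needs_fp:
        if not dataset.registry:
            raise MissingBlockError("fingerprint blocks need a reagent registry")
        product_smiles = dict(product_smiles or {})
        for r in records:
            if r.product_id not in product_smiles:
                acid = dataset.registry[r.acid_id]
                amine = dataset.registry[r.amine_id]
                if acid.smiles is None or amine.smiles is None:
                    raise MissingBlockError(
                        f"reagents {r.acid_id}/{r.amine_id} lack SMILES"
                    )
                product_smiles[r.product_id] = amide_product_smiles(
                    acid.smiles, amine.smiles
                )

    if "conditions" in spec.blocks and vocab is None:
        vocab = ConditionVocabulary.from_datasets([dataset])

    prop_block: pd.DataFrame | None = None
    if "properties" in spec.blocks:
        if properties is None:
            raise MissingBlockError("spec requests properties but none supplied")
        acid_tab = properties.table.reindex([r.acid_id for r in records])
        amine_tab = properties.table.reindex([r.amine_id for r in records])
        if acid_tab.isna().all(axis=1).any() or amine_tab.isna().all(axis=1).any():
            raise MissingBlockError("a reagent has no property row")
        acid_tab = acid_tab.add_prefix("acid_").reset_index(drop=True)
        amine_tab = amine_tab.add_prefix("amine_").reset_index(drop=True)
        prop_block = _impute_with_indicators(pd.concat([acid_tab, amine_tab], axis=1))
        if prop_block.isna().any().any():
            raise ValueError("NaN left in property block after imputation")

    feature_rows = []
    cont_segments: list[tuple[int, int]] = []
    for i, r in enumerate(records):
        parts = []
        for block in spec.blocks:
            if block == "reaction_fp":
                prod = _fp(product_smiles[r.product_id])
                acid_fp = _fp(dataset.registry[r.acid_id].smiles)
                amine_fp = _fp(dataset.registry[r.amine_id].smiles)
                parts.append(
                    reaction_fingerprint(prod, [acid_fp, amine_fp]).values.astype(float)
                )
            elif block == "product_fp":
                parts.append(_fp(product_smiles[r.product_id]).counts.astype(float))
            elif block == "conditions":
                enc = encode_conditions(
                    r.agent_id,
                    r.condition.temperature_C,
                    r.condition.reaction_time_s,
                    vocab,
                )
                parts.append(enc.bits.astype(float))
            elif block == "properties":
                parts.append(prop_block.iloc[i].to_numpy(dtype=float))
        feature_rows.append(np.concatenate(parts))
        if i == 0:
            offset = 0
            for block, part in zip(spec.blocks, parts):
                if block == "properties":
                    cont_segments.append((offset, offset + len(part)))
                offset += len(part)

    X = np.vstack(feature_rows) if feature_rows else np.zeros((0, 0))
    y = np.array([1 if r.label == LABEL_SUCCESS else 0 for r in records], dtype=int)
    mask = np.zeros(X.shape[1] if X.size else 0, dtype=bool)
    for lo, hi in cont_segments:
        mask[lo:hi] = True
    standardizer = FeatureStandardizer(continuous_mask=mask)
    keys = [r.key for r in records]
    return X, y, standardizer, keys
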