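"""Heterogeneous drug/protein knowledge graph: data model, file I/O, degrees, splits.

The graph follows the Decagon convention: drug and protein nodes; one relation
per polypharmacy side-effect label, plus protein-protein interaction (PPI) and
drug-target relations.  Single-drug ("mono") side effects are kept out of the
triple store and attached as per-drug sets, since they are used for node
initialization and the weak-node anchor loss rather than as predicted edges.
Weighted drug-drug similarity edges are added later by :mod:`simvec.graph_enhance`
under a dedicated ``similarity`` relation kind.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DRUG = "drug"
PROTEIN = "protein"

POLY_SIDE_EFFECT = "poly_side_effect"
PPI = "ppi"
DRUG_TARGET = "drug_target"
SIMILARITY = "similarity"

#: relation kinds whose triples are semantically undirected
_SYMMETRIC_KINDS = frozenset({POLY_SIDE_EFFECT, PPI, SIMILARITY})


@dataclass(frozen=True)
class Entity:
    """A node: a drug (optionally with a SMILES string) or a protein."""

    entity_id: int
    kind: str  # DRUG or PROTEIN
    external_id: str
    smiles: str | None = None


@dataclass(frozen=True)
class Relation:
    """A typed edge label (one per side-effect type, plus ppi / drug_target / similarity)."""

    relation_id: int
    kind: str
    label: str


class KnowledgeGraph:
    """Triple store over typed entities with a degree index.

    Triples are held as an ``(n, 3)`` integer array of ``(head, relation, tail)``
    ids plus a parallel weight vector (1.0 everywhere except similarity edges).
    """

    def __init__(
        self,
        entities: Sequence[Entity],
        relations: Sequence[Relation],
        triples: np.ndarray,
        weights: np.ndarray | None = None,
        mono_side_effects: Mapping[int, frozenset[str]] | None = None,
    ):
        self.entities = list(entities)
        self.relations = list(relations)
        ids = [e.entity_id for e in self.entities]
        if sorted(ids) != list(range(len(ids))):
            raise ValueError("entity ids must be dense in [0, n_entities)")
        rids = [r.relation_id for r in self.relations]
        if sorted(rids) != list(range(len(rids))):
            raise ValueError("relation ids must be dense in [0, n_relations)")
        self.entities.sort(key=lambda e: e.entity_id)
        self.relations.sort(key=lambda r: r.relation_id)

        triples = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
        if weights is None:
            weights = np.ones(len(triples))
        self.triples = triples
        self.weights = np.asarray(weights, dtype=float)
        if len(self.weights) != len(self.triples):
            raise ValueError("weights must align with triples")
        self.mono_side_effects = {
            int(k): frozenset(v) for k, v in (mono_side_effects or {}).items()
        }
        self._validate()

    # -- basic accessors ---------------------------------------------------
    @property
    def n_entities(self) -> int:
        return len(self.entities)

    @property
    def n_relations(self) -> int:
        return len(self.relations)

    def entities_of_kind(self, kind: str) -> np.ndarray:
        return np.array([e.entity_id for e in self.entities if e.kind == kind], dtype=np.int64)

    @property
    def drug_ids(self) -> np.ndarray:
        return self.entities_of_kind(DRUG)

    @property
    def protein_ids(self) -> np.ndarray:
        return self.entities_of_kind(PROTEIN)

    def relations_of_kind(self, kind: str) -> np.ndarray:
        return np.array(
            [r.relation_id for r in self.relations if r.kind == kind], dtype=np.int64
        )

    @property
    def entity_kind(self) -> np.ndarray:
        """Array mapping entity_id -> kind string."""
        out = np.empty(self.n_entities, dtype=object)
        for e in self.entities:
            out[e.entity_id] = e.kind
        return out

    @property
    def relation_kind(self) -> np.ndarray:
        out = np.empty(self.n_relations, dtype=object)
        for r in self.relations:
            out[r.relation_id] = r.kind
        return out

    def entity_by_external_id(self, external_id: str) -> Entity:
        for e in self.entities:
            if e.external_id == external_id:
                return e
        raise KeyError(external_id)

    # -- validation --------------------------------------------------------
    def _validate(self) -> None:
        if len(self.triples):
            if self.triples[:, [0, 2]].max() >= self.n_entities or self.triples.min() < 0:
                raise ValueError("triple endpoint outside entity table")
            if self.triples[:, 1].max() >= self.n_relations:
                raise ValueError("triple relation outside relation table")
        rkind = self.relation_kind
        sim_mask = np.array([rkind[r] == SIMILARITY for r in self.triples[:, 1]], dtype=bool) \
            if len(self.triples) else np.zeros(0, dtype=bool)
        if sim_mask.any() and (self.triples[sim_mask, 0] == self.triples[sim_mask, 2]).any():
            raise ValueError("self-loop similarity triple")
        if (~sim_mask).any() and not np.allclose(self.weights[~sim_mask], 1.0):
            raise ValueError("non-similarity triples must have weight 1")
        seen = set(map(tuple, self.triples))
        if len(seen) != len(self.triples):
            raise ValueError("duplicate (h, r, t) triple")

    # -- degrees -----------------------------------------------------------
    def degrees(self, scope: str = "all") -> np.ndarray:
        """Per-entity incidence counts over non-similarity triples.

        scope="all" counts side-effect + PPI + drug-target triples;
        scope="drug_drug_only" restricts to polypharmacy side-effect triples.
        Each triple contributes once to each distinct endpoint.
        """
        if scope not in ("all", "drug_drug_only"):
            raise ValueError(f"unknown degree scope {scope!r}")
        rkind = self.relation_kind
        deg = np.zeros(self.n_entities, dtype=np.int64)
        if not len(self.triples):
            return deg
        kinds = rkind[self.triples[:, 1]]
        if scope == "all":
            mask = kinds != SIMILARITY
        else:
            mask = kinds == POLY_SIDE_EFFECT
        sel = self.triples[mask]
        np.add.at(deg, sel[:, 0], 1)
        # self-loops (h == t) count once
        tails = sel[sel[:, 0] != sel[:, 2], 2]
        np.add.at(deg, tails, 1)
        return deg

    def degree(self, entity: int, scope: str = "all") -> int:
        if not (0 <= entity < self.n_entities):
            raise KeyError(f"unknown entity {entity}")
        return int(self.degrees(scope)[entity])

    # -- positive-triple index (for filtered negative sampling) -----------
    def positive_set(self) -> frozenset[tuple[int, int, int]]:
        """All known (h, r, t), with both orientations for symmetric relation kinds."""
        rkind = self.relation_kind
        out = set(map(tuple, self.triples.tolist()))
        for h, r, t in self.triples.tolist():
            if rkind[r] in _SYMMETRIC_KINDS:
                out.add((t, r, h))
        return frozenset(out)

    def with_similarity_edges(
        self, sim_triples: np.ndarray, sim_weights: np.ndarray, label: str = "chem_similarity"
    ) -> "KnowledgeGraph":
        """Return a new KG with one similarity relation and the given weighted edges."""
        if any(r.kind == SIMILARITY for r in self.relations):
            raise ValueError("graph already has a similarity relation")
        sim_rel = Relation(self.n_relations, SIMILARITY, label)
        sim_triples = np.asarray(sim_triples, dtype=np.int64).reshape(-1, 3).copy()
        sim_triples[:, 1] = sim_rel.relation_id
        return KnowledgeGraph(
            self.entities,
            list(self.relations) + [sim_rel],
            np.vstack([self.triples, sim_triples]) if len(sim_triples) else self.triples,
            np.concatenate([self.weights, np.asarray(sim_weights, dtype=float)]),
            self.mono_side_effects,
        )


@dataclass
class DataSplit:
    """Disjoint train/valid/test triple sets; weak-nodes variant tags the weak drugs.

    ``n_weak_drugs`` is the number of lowest-degree drugs held out (N) and
    ``n_weak_triples`` the number of side-effect triples incident to them (M),
    of which M/2 go to test and M/2 to validation.
    """

    train: np.ndarray
    valid: np.ndarray
    test: np.ndarray
    train_weights: np.ndarray | None = None
    weak_drugs: frozenset[int] | None = None
    n_weak_drugs: int | None = None
    n_weak_triples: int | None = None
    seed: int | None = None

    def __post_init__(self):
        for name in ("train", "valid", "test"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=np.int64).reshape(-1, 3))
        if self.train_weights is None:
            self.train_weights = np.ones(len(self.train))
        sets = [set(map(tuple, s.tolist())) for s in (self.train, self.valid, self.test)]
        if sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]:
            raise ValueError("train/valid/test must be pairwise disjoint")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name in ("train", "valid", "test"):
            pd.DataFrame(getattr(self, name), columns=["head", "relation", "tail"]).to_csv(
                directory / f"{name}.tsv", sep="\t", index=False
            )
        manifest = {
            "seed": self.seed,
            "n_weak_drugs": self.n_weak_drugs,
            "n_weak_triples": self.n_weak_triples,
            "weak_drugs": sorted(self.weak_drugs) if self.weak_drugs is not None else None,
            "sizes": {
                "train": len(self.train),
                "valid": len(self.valid),
                "test": len(self.test),
            },
        }
        (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "DataSplit":
        directory = Path(directory)
        parts = {
            name: pd.read_csv(directory / f"{name}.tsv", sep="\t").to_numpy()
            for name in ("train", "valid", "test")
        }
        manifest = json.loads((directory / "manifest.json").read_text())
        weak = manifest.get("weak_drugs")
        return cls(
            parts["train"],
            parts["valid"],
            parts["test"],
            weak_drugs=frozenset(weak) if weak is not None else None,
            n_weak_drugs=manifest.get("n_weak_drugs"),
            n_weak_triples=manifest.get("n_weak_triples"),
            seed=manifest.get("seed"),
        )


# ---------------------------------------------------------------------------
# file loading
# ---------------------------------------------------------------------------

def _read_table(source, columns: Sequence[str]) -> pd.DataFrame:
    """Read a comma- or tab-separated table (header row required) or pass a DataFrame."""
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    else:
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(path)
        df = pd.read_csv(path, sep=None, engine="python")
    if len(df.columns) < len(columns):
        raise ValueError(
            f"table needs at least columns {list(columns)}, got {list(df.columns)}"
        )
    df = df.iloc[:, : len(columns)].copy()
    df.columns = list(columns)
    for c in columns:
        if df[c].isna().any():
            bad = int(df[c].isna().idxmax())
            raise ValueError(f"malformed row {bad} in column {c!r}")
        df[c] = df[c].astype(str)
    return df


def load_kg(
    combo_table,
    ppi_table=None,
    targets_table=None,
    mono_table=None,
    smiles_table=None,
) -> KnowledgeGraph:
    """Build a :class:`KnowledgeGraph` from Decagon-style edge tables.

    Each argument is a CSV/TSV path or a DataFrame with the columns
    combo: (drug1, drug2, side_effect_id[, name]); ppi: (gene1, gene2);
    targets: (drug, gene); mono: (drug, mono_side_effect_id);
    smiles: (drug_id, canonical_smiles).  Undirected drug-drug and
    protein-protein rows are deduplicated irrespective of orientation.
    """
    combo = _read_table(combo_table, ["drug1", "drug2", "side_effect_id"])
    ppi = _read_table(ppi_table, ["gene1", "gene2"]) if ppi_table is not None else None
    targets = _read_table(targets_table, ["drug", "gene"]) if targets_table is not None else None
    mono = _read_table(mono_table, ["drug", "mono_side_effect_id"]) if mono_table is not None else None
    smiles = _read_table(smiles_table, ["drug_id", "canonical_smiles"]) if smiles_table is not None else None

    drug_ids: set[str] = set(combo["drug1"]) | set(combo["drug2"])
    if targets is not None:
        drug_ids |= set(targets["drug"])
    if mono is not None:
        drug_ids |= set(mono["drug"])
    protein_ids: set[str] = set()
    if ppi is not None:
        protein_ids |= set(ppi["gene1"]) | set(ppi["gene2"])
    if targets is not None:
        protein_ids |= set(targets["gene"])

    smiles_map = dict(zip(smiles["drug_id"], smiles["canonical_smiles"])) if smiles is not None else {}
    missing_smiles = sorted(d for d in drug_ids if d not in smiles_map)
    if smiles is not None and missing_smiles:
        logger.warning("%d drugs have no SMILES entry: %s...", len(missing_smiles), missing_smiles[:5])

    entities: list[Entity] = []
    for ext in sorted(drug_ids):
        entities.append(Entity(len(entities), DRUG, ext, smiles_map.get(ext)))
    for ext in sorted(protein_ids):
        entities.append(Entity(len(entities), PROTEIN, ext))
    eid = {e.external_id: e.entity_id for e in entities}

    relations: list[Relation] = []
    for label in sorted(set(combo["side_effect_id"])):
        relations.append(Relation(len(relations), POLY_SIDE_EFFECT, label))
    rid = {r.label: r.relation_id for r in relations}

    rows: list[tuple[int, int, int]] = []
    seen: set[tuple[int, int, int]] = set()

    def _add(h: int, r: int, t: int, symmetric: bool) -> None:
        key = (min(h, t), r, max(h, t)) if symmetric else (h, r, t)
        if key not in seen:
            seen.add(key)
            rows.append(key)

    for d1, d2, se in combo.itertuples(index=False):
        _add(eid[d1], rid[se], eid[d2], symmetric=True)
    n_combo = len(rows)
    if ppi is not None and len(ppi):
        ppi_rel = Relation(len(relations), PPI, "ppi")
        relations.append(ppi_rel)
        for g1, g2 in ppi.itertuples(index=False):
            _add(eid[g1], ppi_rel.relation_id, eid[g2], symmetric=True)
    n_ppi = len(rows) - n_combo
    if targets is not None and len(targets):
        tgt_rel = Relation(len(relations), DRUG_TARGET, "drug_target")
        relations.append(tgt_rel)
        for d, g in targets.itertuples(index=False):
            _add(eid[d], tgt_rel.relation_id, eid[g], symmetric=False)
    logger.info(
        "loaded KG: %d drugs, %d proteins, %d relations, %d side-effect / %d PPI / %d target triples",
        len(drug_ids), len(protein_ids), len(relations), n_combo, n_ppi,
        len(rows) - n_combo - n_ppi,
    )

    mono_map: dict[int, frozenset[str]] = {}
    if mono is not None:
        grouped = mono.groupby("drug")["mono_side_effect_id"].agg(frozenset)
        mono_map = {eid[d]: s for d, s in grouped.items()}

    return KnowledgeGraph(
        entities, relations, np.array(rows, dtype=np.int64).reshape(-1, 3),
        mono_side_effects=mono_map,
    )


# ---------------------------------------------------------------------------
# splits
# ---------------------------------------------------------------------------

def _poly_mask(kg: KnowledgeGraph) -> np.ndarray:
    rkind = kg.relation_kind
    return np.array([rkind[r] == POLY_SIDE_EFFECT for r in kg.triples[:, 1]], dtype=bool)


def uniform_split(
    kg: KnowledgeGraph, fractions: tuple[float, float, float] = (0.8, 0.1, 0.1), seed: int = 0
) -> DataSplit:
    """Per-relation stratified random split of the side-effect triples.

    PPI and drug-target triples always stay in train: only drug-drug
    side-effect links are evaluated.  A relation with fewer than 3 triples is
    kept whole in train (with a warning).
    """
    f_train, f_valid, f_test = fractions
    if min(fractions) < 0 or not np.isclose(sum(fractions), 1.0):
        raise ValueError("fractions must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    poly = _poly_mask(kg)
    train_rows = [kg.triples[~poly]]
    valid_rows, test_rows = [], []
    for r in kg.relations_of_kind(POLY_SIDE_EFFECT):
        rows = kg.triples[poly & (kg.triples[:, 1] == r)]
        if len(rows) < 3 and (f_valid > 0 or f_test > 0):
            warnings.warn(f"relation {r} has {len(rows)} triples; all kept in train")
            train_rows.append(rows)
            continue
        perm = rng.permutation(len(rows))
        n_valid = int(round(f_valid * len(rows)))
        n_test = int(round(f_test * len(rows)))
        n_test = min(n_test, len(rows) - n_valid)
        valid_rows.append(rows[perm[:n_valid]])
        test_rows.append(rows[perm[n_valid : n_valid + n_test]])
        train_rows.append(rows[perm[n_valid + n_test :]])
    empty = np.zeros((0, 3), dtype=np.int64)
    return DataSplit(
        np.vstack(train_rows) if train_rows else empty,
        np.vstack(valid_rows) if valid_rows else empty,
        np.vstack(test_rows) if test_rows else empty,
        seed=seed,
    )


def weak_drug_set(kg: KnowledgeGraph, n_weak_drugs: int) -> frozenset[int]:
    """The ``n_weak_drugs`` lowest-degree drugs (drug-drug degree, ascending).

    Ties are broken by ascending external_id, then entity_id, so the set is
    deterministic across runs.
    """
    drugs = kg.drug_ids
    if not (0 < n_weak_drugs < len(drugs)):
        raise ValueError(f"n_weak_drugs must be in (0, {len(drugs)})")
    deg = kg.degrees("drug_drug_only")
    ext = {e.entity_id: e.external_id for e in kg.entities}
    order = sorted(drugs.tolist(), key=lambda d: (deg[d], ext[d], d))
    return frozenset(order[:n_weak_drugs])


def weak_nodes_split(kg: KnowledgeGraph, n_weak_drugs: int, seed: int = 0) -> DataSplit:
    """Hold out every side-effect triple touching the N lowest-degree drugs.

    The M weak triples are shuffled and assigned alternately to test and
    validation (test receives the extra one when M is odd); everything else,
    including all PPI and drug-target triples, stays in train.
    """
    weak = weak_drug_set(kg, n_weak_drugs)
    poly = _poly_mask(kg)
    weak_arr = np.array(sorted(weak))
    touches = poly & (
        np.isin(kg.triples[:, 0], weak_arr) | np.isin(kg.triples[:, 2], weak_arr)
    )
    weak_triples = kg.triples[touches]
    rng = np.random.default_rng(seed)
    weak_triples = weak_triples[rng.permutation(len(weak_triples))]
    test = weak_triples[0::2]
    valid = weak_triples[1::2]
    train = kg.triples[~touches]
    if not len(train):
        warnings.warn("weak-nodes split left an empty training set")
    return DataSplit(
        train, valid, test,
        weak_drugs=weak,
        n_weak_drugs=n_weak_drugs,
        n_weak_triples=int(len(weak_triples)),
        seed=seed,
    )
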