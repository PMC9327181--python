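"""Seeded generator of Decagon-like synthetic inputs with a planted chemistry signal.

The generator emits the exact table dialects consumed by
:func:`simvec.kg_store.load_kg` — drug-drug side-effect triples, PPIs,
drug-target pairs, mono side effects — plus a per-drug binary feature table
that stands in for chemical profiles (fingerprint-like, consumed as
morgan-kind vectors).

The planted structure mimics what makes the weak-node problem solvable by a
chemistry-aware model: drugs belong to latent "chemotypes" with prototype
feature vectors, pairs of chemically similar drugs are more likely to interact,
the side-effect *type* of an interacting pair is predictable from the two
chemotypes, and mono side effects cluster by chemotype.  ``signal_strength``
interpolates between pure noise (0: edges, relations and mono effects
independent of features) and a strong planted signal (1).  Degrees follow a
Pareto-tailed propensity so a population of weakly connected drugs always
exists.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import NamedTuple

import numpy as np
import pandas as pd

from . import kg_store
from .chem_features import MORGAN, ChemProfileSet
from .kg_store import DataSplit, KnowledgeGraph


@dataclass(frozen=True)
class SynthSpec:
    """Desk-scale benchmark defaults: 60 drugs, 200 proteins, 8 side-effect
    relations, 20 mono side effects, Pareto degree skew 2.0."""

    n_drugs: int = 60
    n_proteins: int = 200
    n_poly_relations: int = 8
    n_mono_effects: int = 20
    degree_skew: float = 2.0
    signal_strength: float = 0.9
    feature_dim: int = 100
    mean_drug_degree: float = 14.0
    min_drug_degree: float = 6.0
    n_ppi: int = 300
    n_targets: int = 150
    mono_per_chemotype: int = 5
    seed: int = 0

    def __post_init__(self):
        for name in ("n_drugs", "n_proteins", "n_poly_relations", "n_mono_effects",
                     "feature_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not 0.0 <= self.signal_strength <= 1.0:
            raise ValueError("signal_strength must lie in [0, 1]")
        if self.degree_skew <= 1.0:
            raise ValueError("degree_skew must exceed 1 (Pareto tail exponent)")
        max_edges = self.n_drugs * (self.n_drugs - 1) / 2
        if self.mean_drug_degree * self.n_drugs / 2 > max_edges:
            raise ValueError("requested edge density exceeds the complete graph")


class SynthTables(NamedTuple):
    combo: pd.DataFrame
    ppi: pd.DataFrame
    targets: pd.DataFrame
    mono: pd.DataFrame
    features: pd.DataFrame


class Benchmark(NamedTuple):
    kg: KnowledgeGraph
    profiles: ChemProfileSet
    weak_split: DataSplit
    uniform_split: DataSplit
    tables: SynthTables


def _drug_id(i: int) -> str:
    return f"D{i:04d}"


def _protein_id(i: int) -> str:
    return f"P{i:05d}"


def _pair_tanimoto(features: np.ndarray) -> np.ndarray:
    inter = features @ features.T
    ones = features.sum(axis=1)
    union = ones[:, None] + ones[None, :] - inter
    with np.errstate(invalid="ignore", divide="ignore"):
        tan = np.where(union > 0, inter / np.maximum(union, 1), 1.0)
    return tan


def generate(spec: SynthSpec) -> SynthTables:
    """Draw the full table set; identical spec + seed gives identical tables."""
    rng = np.random.default_rng(spec.seed)
    s = spec.signal_strength
    n = spec.n_drugs

    # latent chemotypes and fingerprint-like binary features
    n_chemo = spec.n_poly_relations
    chemotype = rng.integers(n_chemo, size=n)
    prototypes = (rng.random((n_chemo, spec.feature_dim)) < 0.2).astype(np.int64)
    flip = rng.random((n, spec.feature_dim)) < 0.05
    features = np.where(flip, 1 - prototypes[chemotype], prototypes[chemotype])

    # expected degrees: a floor (weak drugs still carry a few known triples,
    # as new drugs do) plus a Pareto tail producing hubs
    tail = rng.pareto(spec.degree_skew - 1.0, size=n)
    excess = max(spec.mean_drug_degree - spec.min_drug_degree, 0.0)
    d_exp = spec.min_drug_degree + (excess * tail / tail.mean() if tail.mean() > 0 else 0.0)
    tan = _pair_tanimoto(features)
    iu = np.triu_indices(n, k=1)
    # Chung-Lu pair probabilities, tilted toward chemically similar pairs
    f = (1.0 - s) + 2.0 * s * tan[iu]
    p_edge = np.minimum(
        d_exp[iu[0]] * d_exp[iu[1]] / d_exp.sum() * (f / f.mean()), 0.9
    )
    has_edge = rng.random(len(p_edge)) < p_edge

    # side-effect type: chemotype-determined with prob s, else uniform
    combo_rows = []
    for h, t in zip(iu[0][has_edge], iu[1][has_edge]):
        if rng.random() < s:
            rel = (int(chemotype[h]) + int(chemotype[t])) % spec.n_poly_relations
        else:
            rel = int(rng.integers(spec.n_poly_relations))
        combo_rows.append((_drug_id(h), _drug_id(t), f"SE{rel:03d}"))
    combo = pd.DataFrame(combo_rows, columns=["drug1", "drug2", "side_effect_id"])

    # mono side effects clustered by chemotype; every drug gets >= 1
    preferred = np.stack([
        rng.choice(spec.n_mono_effects, size=min(spec.mono_per_chemotype, spec.n_mono_effects),
                   replace=False)
        for _ in range(n_chemo)
    ])
    base_rate = 0.25
    mono_rows = []
    for d in range(n):
        pref = set(preferred[chemotype[d]].tolist())
        chosen = [
            m for m in range(spec.n_mono_effects)
            if rng.random() < ((1 - s) * base_rate + s * (0.85 if m in pref else 0.05))
        ]
        if not chosen:
            chosen = [int(sorted(pref)[0])]
        mono_rows.extend((_drug_id(d), f"MSE{m:03d}") for m in chosen)
    mono = pd.DataFrame(mono_rows, columns=["drug", "mono_side_effect_id"])

    # uniform random PPI and drug-target edges
    ppi_pairs = set()
    while len(ppi_pairs) < min(spec.n_ppi, spec.n_proteins * (spec.n_proteins - 1) // 2):
        i, j = rng.integers(spec.n_proteins, size=2)
        if i != j:
            ppi_pairs.add((min(i, j), max(i, j)))
    ppi = pd.DataFrame(
        [(_protein_id(i), _protein_id(j)) for i, j in sorted(ppi_pairs)],
        columns=["gene1", "gene2"],
    )
    tgt_pairs = set()
    while len(tgt_pairs) < min(spec.n_targets, n * spec.n_proteins):
        tgt_pairs.add((int(rng.integers(n)), int(rng.integers(spec.n_proteins))))
    targets = pd.DataFrame(
        [(_drug_id(d), _protein_id(g)) for d, g in sorted(tgt_pairs)],
        columns=["drug", "gene"],
    )

    feat = pd.DataFrame(features, columns=[f"f{i}" for i in range(spec.feature_dim)])
    feat.insert(0, "drug_id", [_drug_id(i) for i in range(n)])
    return SynthTables(combo, ppi, targets, mono, feat)


def write_tables(tables: SynthTables, directory: str | Path,
                 spec: SynthSpec | None = None) -> dict[str, Path]:
    """Write all tables as CSV in the kg_store dialect; spec serialized alongside."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name in tables._fields:
        path = directory / f"{name}.csv"
        getattr(tables, name).to_csv(path, index=False)
        paths[name] = path
    if spec is not None:
        import json
        (directory / "spec.json").write_text(json.dumps(asdict(spec), indent=2))
    return paths


def profiles_from_features(kg: KnowledgeGraph, features: pd.DataFrame) -> ChemProfileSet:
    """Interpret the synthetic binary feature table as morgan-kind profiles."""
    ext_to_id = {e.external_id: e.entity_id for e in kg.entities}
    rows = features[features["drug_id"].isin(ext_to_id)]
    ids = rows["drug_id"].map(ext_to_id).to_numpy()
    return ChemProfileSet(ids, rows.iloc[:, 1:].to_numpy(dtype=float), MORGAN)


def make_benchmark(spec: SynthSpec | None = None, n_weak: int = 10) -> Benchmark:
    """Generate tables, load them through kg_store, and build both split types.

    All randomness (generation and both splits) derives from ``spec.seed``.
    """
    spec = spec or SynthSpec()
    if not n_weak < spec.n_drugs:
        raise ValueError("n_weak must be smaller than n_drugs")
    tables = generate(spec)
    kg = kg_store.load_kg(
        tables.combo, tables.ppi, tables.targets, tables.mono, smiles_table=None
    )
    profiles = profiles_from_features(kg, tables.features)
    weak_split = kg_store.weak_nodes_split(kg, n_weak, seed=spec.seed)
    uniform = kg_store.uniform_split(kg, (0.8, 0.1, 0.1), seed=spec.seed)
    return Benchmark(kg, profiles, weak_split, uniform, tables)


#: a small pool of real molecules for exercising the RDKit featurization path
#: (synthetic stand-ins: common, hand-listed drug-like SMILES)
SMILES_POOL: dict[str, str] = {
    "aspirin": "CC(=O)Oc1ccccc1C(=O)O",
    "caffeine": "Cn1cnc2c1c(=O)n(C)c(=O)n2C",
    "paracetamol": "CC(=O)Nc1ccc(O)cc1",
    "ibuprofen": "CC(C)Cc1ccc(C(C)C(=O)O)cc1",
    "naproxen": "COc1ccc2cc(C(C)C(=O)O)ccc2c1",
    "benzene": "c1ccccc1",
    "toluene": "Cc1ccccc1",
    "phenol": "Oc1ccccc1",
    "ethanol": "CCO",
    "acetone": "CC(C)=O",
    "glycine": "NCC(=O)O",
    "alanine": "CC(N)C(=O)O",
    "urea": "NC(N)=O",
    "glucose": "OCC1OC(O)C(O)C(O)C1O",
    "nicotine": "CN1CCCC1c1cccnc1",
    "atenolol": "CC(C)NCC(O)COc1ccc(CC(N)=O)cc1",
    "propranolol": "CC(C)NCC(O)COc1cccc2ccccc12",
    "warfarin": "CC(=O)CC(c1ccccc1)c1c(O)c2ccccc2oc1=O",
    "diazepam": "CN1c2ccc(Cl)cc2C(c2ccccc2)=NCC1=O",
    "lidocaine": "CCN(CC)CC(=O)Nc1c(C)cccc1C",
}
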