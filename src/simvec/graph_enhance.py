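"""Degree-inverse node weights and weighted drug-drug similarity edges.

Poorly connected drugs should lean harder on chemistry: every drug pair gets a
candidate similarity edge whose weight grows with chemical similarity and with
the *inverse* (min-max normalized) training degree of both endpoints, so the
structural enhancement concentrates where the graph is thin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .chem_features import ChemProfileSet, similarity
from .kg_store import DataSplit, KnowledgeGraph, POLY_SIDE_EFFECT


@dataclass(frozen=True)
class WeightingScheme:
    """Edge-weighting rule: 'proportional' (similarity x InvDeg x InvDeg) or
    'window' (Gaussian with an InvDeg-widened bandwidth in [l_bound, u_bound])."""

    kind: str = "window"
    l_bound: float = 1.0
    u_bound: float = 4.0
    metric: str | None = None  # None -> profile set's default
    sigma: float | None = None  # gaussian metric only

    def __post_init__(self):
        if self.kind not in ("proportional", "window"):
            raise ValueError(f"unknown weighting kind {self.kind!r}")
        if self.kind == "window" and not self.l_bound < self.u_bound:
            raise ValueError("window weighting needs l_bound < u_bound")


def _train_drug_degrees(kg: KnowledgeGraph, split: DataSplit | None) -> np.ndarray:
    """Drug-drug degrees over the training side-effect triples.

    Degrees come from the train split so held-out edges never leak into the
    enhancement; with no split, the whole graph is the training set.
    """
    rkind = kg.relation_kind
    triples = split.train if split is not None else kg.triples
    deg = np.zeros(kg.n_entities, dtype=np.int64)
    if len(triples):
        mask = np.array([rkind[r] == POLY_SIDE_EFFECT for r in triples[:, 1]], dtype=bool)
        sel = triples[mask]
        np.add.at(deg, sel[:, 0], 1)
        np.add.at(deg, sel[sel[:, 0] != sel[:, 2], 2], 1)
    return deg


def inv_deg_table(kg: KnowledgeGraph, split: DataSplit | None = None) -> dict[int, float]:
    """InvDeg(x) = 1 - (deg_x - min deg) / (max deg - min deg) for every drug.

    Min/max run over all drug nodes.  If every drug has the same degree the
    normalization is degenerate and every drug gets InvDeg = 1.
    """
    drugs = kg.drug_ids
    deg = _train_drug_degrees(kg, split)[drugs]
    lo, hi = int(deg.min()), int(deg.max())
    if hi == lo:
        warnings.warn("all drug degrees equal; InvDeg degenerates to 1 for every drug")
        return {int(d): 1.0 for d in drugs}
    vals = 1.0 - (deg - lo) / (hi - lo)
    return {int(d): float(v) for d, v in zip(drugs, vals)}


def inv_deg(kg: KnowledgeGraph, drug: int, split: DataSplit | None = None) -> float:
    table = inv_deg_table(kg, split)
    if int(drug) not in table:
        raise KeyError(f"{drug} is not a drug node")
    return table[int(drug)]


def weight_proportional(similarity_value: float, inv_deg_h: float, inv_deg_t: float) -> float:
    """similarity(h,t) * InvDeg(h) * InvDeg(t); symmetric in the endpoints."""
    for v in (similarity_value, inv_deg_h, inv_deg_t):
        if not 0.0 <= v <= 1.0:
            raise ValueError("factors must lie in [0, 1]")
    return similarity_value * inv_deg_h * inv_deg_t


def window_size(inv_deg_h: float, inv_deg_t: float, scheme: WeightingScheme) -> float:
    """l_bound + InvDeg(h) * InvDeg(t) * (u_bound - l_bound)."""
    if scheme.kind != "window":
        raise ValueError("scheme must be of kind 'window'")
    return scheme.l_bound + inv_deg_h * inv_deg_t * (scheme.u_bound - scheme.l_bound)


def weight_window(
    h_vec: np.ndarray, t_vec: np.ndarray, inv_deg_h: float, inv_deg_t: float,
    scheme: WeightingScheme,
) -> float:
    """exp(-||h - t||^2 / window^2): a Gaussian whose bandwidth widens for
    weakly connected pairs, so their chemistry reaches further."""
    h_vec = np.asarray(h_vec, dtype=float)
    t_vec = np.asarray(t_vec, dtype=float)
    if h_vec.shape != t_vec.shape:
        raise ValueError("profile vectors must have equal length")
    w = window_size(inv_deg_h, inv_deg_t, scheme)
    return float(np.exp(-np.sum((h_vec - t_vec) ** 2) / w**2))


def build_similarity_edges(
    kg: KnowledgeGraph,
    profiles: ChemProfileSet,
    scheme: WeightingScheme,
    split: DataSplit | None = None,
    min_weight: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """One weighted, undirected edge per unordered drug pair with weight > min_weight.

    Returns (triples, weights); the relation column is a placeholder filled in
    by :meth:`KnowledgeGraph.with_similarity_edges`.  min_weight=0 keeps the
    complete drug-drug graph (n*(n-1)/2 edges for n drugs); raising it prunes
    negligible edges for scalability.
    """
    drugs = sorted(int(d) for d in kg.drug_ids)
    inv = inv_deg_table(kg, split)
    metric = scheme.metric or profiles.default_metric()
    rows, weights = [], []
    for i, h in enumerate(drugs):
        hv = profiles.vector(h)
        for t in drugs[i + 1 :]:
            tv = profiles.vector(t)
            if scheme.kind == "window":
                w = weight_window(hv, tv, inv[h], inv[t], scheme)
            else:
                s = similarity(hv, tv, metric, sigma=scheme.sigma, profiles=profiles)
                w = weight_proportional(s, inv[h], inv[t])
            if w > min_weight:
                rows.append((h, -1, t))
                weights.append(w)
    return (
        np.array(rows, dtype=np.int64).reshape(-1, 3),
        np.array(weights, dtype=float),
    )
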