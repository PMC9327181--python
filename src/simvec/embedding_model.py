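"""Trilinear triple-part embedding model: scorer, losses, gradients, initialization.

Every entity i and relation j carries three K-dimensional parts,
Theta_E(i) = {e_i^1, e_i^2, e_i^3} and Theta_R(j) = {w_j^1, w_j^2, w_j^3}.
A triple (s, p, o) is scored trilinearly with the parts cross-paired::

    phi(s, p, o) = sum_k  e_s^1 w_p^1 e_o^3  +  e_s^2 w_p^2 e_o^2  +  e_s^3 w_p^3 e_o^1

Training minimizes a two-sided multiclass softmax loss over candidate head and
tail corruptions plus an N3 (cubed-absolute-value) penalty::

    L = -phi_spo + log sum_{o'} exp(phi_spo')
        -phi_spo + log sum_{s'} exp(phi_s'po)
        + (lambda/3) sum_k sum_m |e_s^m|^3 + |w_p^m|^3 + |e_o^m|^3

All gradients are computed analytically in closed form (the model is
multilinear, the softmax gradient is the usual expected-embedding form, and
d|x|^3/dx = 3 sign(x) x^2); a finite-difference check in the test suite guards
every term.  Candidate sets are passed as fixed-width index arrays with a
boolean validity mask so ragged negative sets batch cleanly; the true entity
always occupies column 0.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .chem_features import ChemProfileSet
from .kg_store import DRUG, KnowledgeGraph


class TripleModel:
    """Embedding tables: E of shape (n_entities, 3, K), R of shape (n_relations, 3, K)."""

    def __init__(self, E: np.ndarray, R: np.ndarray, lambda_reg: float = 0.01):
        self.E = np.asarray(E, dtype=float)
        self.R = np.asarray(R, dtype=float)
        if self.E.ndim != 3 or self.R.ndim != 3 or self.E.shape[1] != 3 or self.R.shape[1] != 3:
            raise ValueError("embedding tables must have shape (n, 3, K)")
        if self.E.shape[2] != self.R.shape[2]:
            raise ValueError("entity and relation embeddings must share K")
        self.lambda_reg = float(lambda_reg)

    @property
    def K(self) -> int:
        return self.E.shape[2]

    def copy(self) -> "TripleModel":
        return TripleModel(self.E.copy(), self.R.copy(), self.lambda_reg)

    def score_batch(self, h: np.ndarray, r: np.ndarray, t: np.ndarray) -> np.ndarray:
        """Vectorized phi over aligned id arrays."""
        h = np.atleast_1d(np.asarray(h, dtype=np.int64))
        r = np.atleast_1d(np.asarray(r, dtype=np.int64))
        t = np.atleast_1d(np.asarray(t, dtype=np.int64))
        self._check_ids(h, r, t)
        # head part m pairs with tail part 2-m under the shared relation part m
        return np.einsum("bmk,bmk,bmk->b", self.E[h], self.R[r], self.E[t][:, ::-1, :])

    def score(self, h: int, r: int, t: int) -> float:
        return float(self.score_batch([h], [r], [t])[0])

    def _check_ids(self, h, r, t) -> None:
        if h.min(initial=0) < 0 or h.max(initial=0) >= len(self.E) \
                or t.min(initial=0) < 0 or t.max(initial=0) >= len(self.E):
            raise KeyError("unknown entity id")
        if r.min(initial=0) < 0 or r.max(initial=0) >= len(self.R):
            raise KeyError("unknown relation id")

    def save(self, path: str | Path, manifest: dict | None = None) -> None:
        np.savez(path, E=self.E, R=self.R, lambda_reg=self.lambda_reg,
                 manifest=np.array(repr(manifest or {})))

    @classmethod
    def load(cls, path: str | Path) -> "TripleModel":
        data = np.load(path, allow_pickle=False)
        return cls(data["E"], data["R"], float(data["lambda_reg"]))


def score(model: TripleModel, h: int, r: int, t: int) -> float:
    return model.score(h, r, t)


# ---------------------------------------------------------------------------
# losses and gradients
# ---------------------------------------------------------------------------

def _masked_softmax_lse(phi: np.ndarray, mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise logsumexp and softmax over masked candidate scores."""
    neg = np.where(mask, phi, -np.inf)
    mx = neg.max(axis=1, keepdims=True)
    ex = np.where(mask, np.exp(neg - mx), 0.0)
    z = ex.sum(axis=1, keepdims=True)
    lse = (mx + np.log(z)).ravel()
    return lse, ex / z


def trivec_loss(
    model: TripleModel,
    positives: np.ndarray,
    head_cands: np.ndarray,
    tail_cands: np.ndarray,
    head_mask: np.ndarray | None = None,
    tail_mask: np.ndarray | None = None,
    triple_weights: np.ndarray | None = None,
    lambda_reg: float | None = None,
    return_grad: bool = False,
):
    """Mean two-sided softmax loss with N3 regularization over a batch.

    positives: (B, 3) ids; head_cands/tail_cands: (B, C) candidate entity ids
    whose column 0 must be the true head/tail; masks flag valid candidates.
    With ``triple_weights`` each triple's whole loss (including its
    regularization term) is scaled, which is exactly the weighted similarity-
    edge loss.  Returns the scalar loss, or (loss, gradE, gradR).
    """
    E, R = model.E, model.R
    lam = model.lambda_reg if lambda_reg is None else float(lambda_reg)
    pos = np.asarray(positives, dtype=np.int64).reshape(-1, 3)
    B = len(pos)
    if B == 0:
        if return_grad:
            return 0.0, np.zeros_like(E), np.zeros_like(R)
        return 0.0
    hc = np.asarray(head_cands, dtype=np.int64)
    tc = np.asarray(tail_cands, dtype=np.int64)
    hm = np.ones(hc.shape, dtype=bool) if head_mask is None else np.asarray(head_mask, dtype=bool)
    tm = np.ones(tc.shape, dtype=bool) if tail_mask is None else np.asarray(tail_mask, dtype=bool)
    if not (hm.any(axis=1).all() and tm.any(axis=1).all()):
        raise ValueError("every triple needs at least one head and one tail candidate")
    if (hc[:, 0] != pos[:, 0]).any() or (tc[:, 0] != pos[:, 2]).any():
        raise ValueError("candidate column 0 must hold the true entity")
    w = np.ones(B) if triple_weights is None else np.asarray(triple_weights, dtype=float)

    s, p, o = pos[:, 0], pos[:, 1], pos[:, 2]
    Es, Rp, Eo = E[s], R[p], E[o]            # (B, 3, K)
    Eorev = Eo[:, ::-1, :]
    SWrev = (Es * Rp)[:, ::-1, :]            # phi(s,p,t) = sum SWrev * E[t]
    WT = Rp * Eorev                          # phi(s',p,o) = sum E[s'] * WT

    phi_pos = np.einsum("bmk,bmk->b", SWrev, Eo)
    phi_tail = np.einsum("bmk,bcmk->bc", SWrev, E[tc])
    phi_head = np.einsum("bcmk,bmk->bc", E[hc], WT)
    lse_tail, A_tail = _masked_softmax_lse(phi_tail, tm)
    lse_head, A_head = _masked_softmax_lse(phi_head, hm)

    reg = (lam / 3.0) * (
        np.abs(Es) ** 3 + np.abs(Rp) ** 3 + np.abs(Eo) ** 3
    ).sum(axis=(1, 2))
    per_triple = -2.0 * phi_pos + lse_tail + lse_head + reg
    loss = float((w * per_triple).mean())
    if not return_grad:
        return loss

    c = (w / B)[:, None, None]               # per-triple scale on gradients
    gradE = np.zeros_like(E)
    gradR = np.zeros_like(R)

    Tbar = np.einsum("bc,bcmk->bmk", A_tail, E[tc])   # expected tail embedding
    Hbar = np.einsum("bc,bcmk->bmk", A_head, E[hc])   # expected head embedding
    Tbar_rev = Tbar[:, ::-1, :]

    dEs = c * (-2.0 * Rp * Eorev + Rp * Tbar_rev + lam * np.sign(Es) * Es**2)
    dEo = c * (-2.0 * SWrev + (Hbar * Rp)[:, ::-1, :] + lam * np.sign(Eo) * Eo**2)
    dRp = c * (
        -2.0 * Es * Eorev + Es * Tbar_rev + Hbar * Eorev + lam * np.sign(Rp) * Rp**2
    )
    np.add.at(gradE, s, dEs)
    np.add.at(gradE, o, dEo)
    np.add.at(gradR, p, dRp)
    # softmax mass flowing into the candidates themselves
    np.add.at(gradE, tc, (c[:, :, 0] * A_tail)[:, :, None, None] * SWrev[:, None, :, :])
    np.add.at(gradE, hc, (c[:, :, 0] * A_head)[:, :, None, None] * WT[:, None, :, :])
    return loss, gradE, gradR


def similarity_edge_loss(
    model: TripleModel,
    sim_triples: np.ndarray,
    edge_weights: np.ndarray,
    head_cands: np.ndarray,
    tail_cands: np.ndarray,
    head_mask: np.ndarray | None = None,
    tail_mask: np.ndarray | None = None,
    return_grad: bool = False,
):
    """Weighted similarity-edge loss: weight(h, t) * L_trivec(h, r_sim, t)."""
    ew = np.asarray(edge_weights, dtype=float)
    if len(ew) and (ew.min() < 0 or ew.max() > 1):
        raise ValueError("edge weights must lie in [0, 1]")
    return trivec_loss(
        model, sim_triples, head_cands, tail_cands, head_mask, tail_mask,
        triple_weights=ew, return_grad=return_grad,
    )


def mono_neighbor_map(
    kg: KnowledgeGraph,
    weak_drugs: Sequence[int],
    n_sim_neighbors: int = 6,
) -> dict[int, np.ndarray]:
    """For each weak drug, the non-weak drugs sharing the most mono side effects.

    Ranking is by descending |mono(weak) ∩ mono(candidate)|, ties by ascending
    external_id.  If fewer than ``n_sim_neighbors`` candidates exist, all are
    used (with a warning).
    """
    weak = set(int(d) for d in weak_drugs)
    pool = [int(d) for d in kg.drug_ids if int(d) not in weak]
    if not pool:
        raise ValueError("no non-weak drugs available as anchors")
    ext = {e.entity_id: e.external_id for e in kg.entities}
    mono = kg.mono_side_effects
    out = {}
    for d in sorted(weak):
        own = mono.get(d, frozenset())
        ranked = sorted(pool, key=lambda c: (-len(own & mono.get(c, frozenset())), ext[c]))
        if len(ranked) < n_sim_neighbors:
            warnings.warn(
                f"only {len(ranked)} anchor candidates for drug {d} "
                f"(requested {n_sim_neighbors})"
            )
        out[d] = np.array(ranked[:n_sim_neighbors], dtype=np.int64)
    return out


def weak_node_anchor_loss(
    model: TripleModel,
    neighbor_map: Mapping[int, np.ndarray],
    return_grad: bool = False,
):
    """MSE pulling each weak drug's embedding toward its anchors' mean.

    The target is the element-wise mean over the neighbors' concatenated
    parts and is treated as a constant: gradients flow only into the weak
    drugs, so well-trained anchors are not dragged toward the weak nodes.
    """
    if not neighbor_map:
        if return_grad:
            return 0.0, np.zeros_like(model.E), np.zeros_like(model.R)
        return 0.0
    E = model.E
    n_weak = len(neighbor_map)
    dim = 3 * model.K
    loss = 0.0
    gradE = np.zeros_like(E)
    for d, nbrs in neighbor_map.items():
        diff = E[int(d)] - E[np.asarray(nbrs, dtype=np.int64)].mean(axis=0)
        loss += float((diff**2).mean())
        if return_grad:
            gradE[int(d)] += 2.0 * diff / (dim * n_weak)
    loss /= n_weak
    if return_grad:
        return loss, gradE, np.zeros_like(model.R)
    return loss


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class InitSpec:
    """How drug nodes are seeded: 'xavier' noise, 'chemical' profiles, or
    'mono_se' indicators over the K most frequent single side effects.
    Proteins and relations are always Xavier-initialized."""

    drug_init: str = "xavier"
    profiles: ChemProfileSet | None = None
    jitter: float = 0.01  # relative to the Xavier scale

    def __post_init__(self):
        if self.drug_init not in ("xavier", "chemical", "mono_se"):
            raise ValueError(f"unknown drug_init {self.drug_init!r}")
        if self.drug_init == "chemical" and self.profiles is None:
            raise ValueError("chemical init requires profiles")


def _fit_length(v: np.ndarray, K: int) -> np.ndarray:
    if len(v) >= K:
        return v[:K]
    return np.concatenate([v, np.zeros(K - len(v))])


def _rescale(v: np.ndarray, target_std: float) -> np.ndarray:
    rms = float(np.sqrt(np.mean(v**2)))
    return v * (target_std / rms) if rms > 0 else v


def initialize(
    kg: KnowledgeGraph,
    K: int = 100,
    init_spec: InitSpec | None = None,
    seed: int = 0,
    lambda_reg: float = 0.01,
) -> TripleModel:
    """Build the embedding tables for a graph.

    Xavier draws are uniform on [-sqrt(6/2K), sqrt(6/2K)] (std 1/sqrt(K)).
    Structured drug vectors (chemical profiles or mono-side-effect indicators)
    are copied into all three parts, rescaled to the Xavier standard deviation
    and given 1% Gaussian jitter so identical twins can still diverge.
    """
    init_spec = init_spec or InitSpec()
    rng = np.random.default_rng(seed)
    limit = np.sqrt(6.0 / (2 * K))
    xavier_std = 1.0 / np.sqrt(K)
    E = rng.uniform(-limit, limit, size=(kg.n_entities, 3, K))
    R = rng.uniform(-limit, limit, size=(kg.n_relations, 3, K))

    if init_spec.drug_init != "xavier":
        if init_spec.drug_init == "chemical":
            vec_of = {int(d): init_spec.profiles.vector(int(d)) for d in kg.drug_ids}
        else:  # mono_se indicators over the K most frequent single side effects
            counts: dict[str, int] = {}
            for effects in kg.mono_side_effects.values():
                for se in effects:
                    counts[se] = counts.get(se, 0) + 1
            vocab = sorted(counts, key=lambda se: (-counts[se], se))[:K]
            col = {se: i for i, se in enumerate(vocab)}
            vec_of = {}
            for d in kg.drug_ids:
                v = np.zeros(K)
                for se in kg.mono_side_effects.get(int(d), frozenset()):
                    if se in col:
                        v[col[se]] = 1.0
                vec_of[int(d)] = v
        for d, v in vec_of.items():
            base = _rescale(_fit_length(np.asarray(v, dtype=float), K), xavier_std)
            E[d] = base[None, :] + rng.normal(
                0.0, init_spec.jitter * xavier_std, size=(3, K)
            )
    return TripleModel(E, R, lambda_reg=lambda_reg)
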