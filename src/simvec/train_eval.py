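"""3-step training loop, early stopping, and the per-relation evaluation protocol.

One epoch runs up to three phases over the training graph:

1. minibatch passes over the side-effect / PPI / drug-target triples with the
   two-sided softmax loss and sampled negative corruptions;
2. minibatch passes over the weighted drug-drug similarity edges, each edge's
   loss scaled by its chemical-similarity weight (skipped when disabled);
3. one anchor step pulling each weak drug's embedding toward the mean of the
   drugs that share the most mono side effects with it (skipped when disabled).

Cache-based negative samplers get one cache refresh per epoch.  Training stops
when the validation macro ROC AUC fails to improve by more than ``epsilon``
for ``patience`` consecutive epochs, and the best-validation checkpoint is
returned.

Evaluation follows the link-prediction protocol used for polypharmacy graphs:
for every side-effect relation, each held-out triple is paired with one
filtered uniform corruption, all are scored, and ROC AUC / average precision
are computed per relation then macro-averaged with equal weight.  FPR and FNR
are reported at the sigmoid(phi) > 0.5 decision threshold.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from sklearn.metrics import average_precision_score, roc_auc_score

from .chem_features import ChemProfileSet, nearest_strong_neighbor
from .embedding_model import (
    InitSpec,
    TripleModel,
    initialize,
    mono_neighbor_map,
    trivec_loss,
    weak_node_anchor_loss,
)
from .graph_enhance import WeightingScheme, build_similarity_edges
from .kg_store import DRUG, POLY_SIDE_EFFECT, DataSplit, KnowledgeGraph
from .negative_sampling import SamplerSpec, UniformSampler, make_sampler


@dataclass
class TrainConfig:
    """Everything the trainer needs besides the graph and the split."""

    embedding_dim: int = 100
    lambda_reg: float = 0.01
    learning_rate: float = 0.001
    epochs_max: int = 50
    batch_size: int = 512
    early_stop_epsilon: float = 0.001
    patience: int = 7
    seed: int = 0
    # enhancement switches
    drug_init: str = "xavier"  # xavier | chemical | mono_se
    similarity_edges: bool = False
    weak_anchor_loss: bool = False
    # enhancement knobs
    weighting: WeightingScheme = field(default_factory=WeightingScheme)
    min_weight: float = 0.0
    n_sim_neighbors: int = 6
    weak_fraction: float = 1.0 / 6.0
    sampler: SamplerSpec = field(default_factory=SamplerSpec)

    def __post_init__(self):
        if self.patience < 1:
            raise ValueError("patience must be >= 1")
        if self.early_stop_epsilon < 0:
            raise ValueError("early_stop_epsilon must be >= 0")


@dataclass
class EvalReport:
    """Per-relation and macro metrics on a triple set."""

    per_relation: dict[int, dict[str, float]]
    macro_roc_auc: float
    macro_auc_pr: float
    fpr: float
    fnr: float
    n_triples: int

    def as_dict(self) -> dict:
        return {
            "macro_roc_auc": self.macro_roc_auc,
            "macro_auc_pr": self.macro_auc_pr,
            "fpr": self.fpr,
            "fnr": self.fnr,
            "n_triples": self.n_triples,
            "per_relation": {str(k): v for k, v in self.per_relation.items()},
        }


class _Adam:
    """Adam over the two embedding tables (dense; desk-scale graphs are small)."""

    def __init__(self, shapes, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros(s) for s in shapes]
        self.v = [np.zeros(s) for s in shapes]
        self.t = 0

    def step(self, params, grads):
        self.t += 1
        for p, g, m, v in zip(params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g**2
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def train_weak_drugs(kg: KnowledgeGraph, split: DataSplit, fraction: float) -> frozenset[int]:
    """Drugs considered weak *at training time*: the bottom ``fraction`` by
    train drug-drug degree (ties by external_id, then id)."""
    rkind = kg.relation_kind
    deg = np.zeros(kg.n_entities, dtype=np.int64)
    mask = np.array(
        [rkind[r] == POLY_SIDE_EFFECT for r in split.train[:, 1]], dtype=bool
    ) if len(split.train) else np.zeros(0, dtype=bool)
    sel = split.train[mask]
    if len(sel):
        np.add.at(deg, sel[:, 0], 1)
        np.add.at(deg, sel[sel[:, 0] != sel[:, 2], 2], 1)
    drugs = kg.drug_ids
    ext = {e.entity_id: e.external_id for e in kg.entities}
    n_weak = max(1, math.ceil(fraction * len(drugs)))
    order = sorted(drugs.tolist(), key=lambda d: (deg[d], ext[d], d))
    return frozenset(order[:n_weak])


def frozen_eval_negatives(
    kg: KnowledgeGraph, triples: np.ndarray, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """One filtered uniform corruption per triple, reproducible from the seed.

    Returns (negatives, ok_mask); a triple whose corruption cannot escape the
    known positives within the retry budget is masked out.
    """
    rng = np.random.default_rng(seed)
    sampler = UniformSampler(kg, SamplerSpec(kind="uniform", neg_ratio=1))
    pos = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    negs = pos.copy()
    ok = np.zeros(len(pos), dtype=bool)
    for i, (h, r, t) in enumerate(pos.tolist()):
        corrupt_head = rng.random() < 0.5
        cand = sampler._draw_replacement(h, r, t, corrupt_head, rng)
        if cand is None:
            continue
        negs[i] = (cand, r, t) if corrupt_head else (h, r, cand)
        ok[i] = True
    return negs, ok


def evaluate(
    model: TripleModel,
    triples: np.ndarray,
    kg: KnowledgeGraph,
    seed: int = 0,
    threshold: float = 0.5,
    negatives: tuple[np.ndarray, np.ndarray] | None = None,
) -> EvalReport:
    """Per-relation ROC AUC / AUC PR against one frozen negative per positive.

    ``threshold`` is on sigmoid(phi); 0.5 corresponds to phi > 0.  FPR/FNR are
    pooled over relations at that threshold.
    """
    pos = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
    if negatives is None:
        negatives = frozen_eval_negatives(kg, pos, seed)
    negs, ok = negatives
    rkind = kg.relation_kind
    phi_offset = -np.log(1.0 / threshold - 1.0) if 0 < threshold < 1 else 0.0

    per_rel: dict[int, dict[str, float]] = {}
    tp = fp = tn = fn = 0
    for r in sorted(set(pos[:, 1].tolist())):
        if rkind[r] != POLY_SIDE_EFFECT:
            continue
        sel = (pos[:, 1] == r) & ok
        if not sel.any():
            warnings.warn(f"relation {r}: no usable negatives; skipped")
            continue
        p, n = pos[sel], negs[sel]
        sp = model.score_batch(p[:, 0], p[:, 1], p[:, 2])
        sn = model.score_batch(n[:, 0], n[:, 1], n[:, 2])
        y = np.concatenate([np.ones(len(sp)), np.zeros(len(sn))])
        s = np.concatenate([sp, sn])
        per_rel[int(r)] = {
            "roc_auc": float(roc_auc_score(y, s)),
            "auc_pr": float(average_precision_score(y, s)),
            "n_pos": int(len(sp)),
        }
        tp += int((sp > phi_offset).sum())
        fn += int((sp <= phi_offset).sum())
        fp += int((sn > phi_offset).sum())
        tn += int((sn <= phi_offset).sum())
    if not per_rel:
        raise ValueError("no evaluable side-effect relation in the triple set")
    return EvalReport(
        per_relation=per_rel,
        macro_roc_auc=float(np.mean([m["roc_auc"] for m in per_rel.values()])),
        macro_auc_pr=float(np.mean([m["auc_pr"] for m in per_rel.values()])),
        fpr=fp / (fp + tn) if fp + tn else float("nan"),
        fnr=fn / (fn + tp) if fn + tp else float("nan"),
        n_triples=int(len(pos)),
    )


def predict_side_effects(
    model: TripleModel, kg: KnowledgeGraph, drug_a: int, drug_b: int, top_k: int = 10
) -> list[tuple[int, str, float]]:
    """Rank all side-effect relations for a drug pair, symmetrized over orientation."""
    kinds = kg.entity_kind
    for d in (drug_a, drug_b):
        if not (0 <= d < kg.n_entities) or kinds[d] != DRUG:
            raise KeyError(f"unknown drug {d}")
    rels = kg.relations_of_kind(POLY_SIDE_EFFECT)
    a = np.full(len(rels), drug_a)
    b = np.full(len(rels), drug_b)
    phi = np.maximum(model.score_batch(a, rels, b), model.score_batch(b, rels, a))
    order = np.argsort(-phi)[: min(top_k, len(rels))]
    labels = {r.relation_id: r.label for r in kg.relations}
    return [(int(rels[i]), labels[int(rels[i])], float(phi[i])) for i in order]


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class Trainer:
    """Wires the enhancements together and runs the 3-step epochs."""

    def __init__(
        self,
        kg: KnowledgeGraph,
        split: DataSplit,
        config: TrainConfig,
        profiles: ChemProfileSet | None = None,
    ):
        self.kg, self.split, self.config = kg, split, config
        self.profiles = profiles
        self.rng = np.random.default_rng(config.seed)

        needs_profiles = config.similarity_edges or config.drug_init == "chemical" \
            or config.sampler.kind == "strong_nscaching"
        if needs_profiles and profiles is None:
            raise ValueError("this configuration requires chemical profiles")

        init = InitSpec(drug_init=config.drug_init, profiles=profiles)
        self.model = initialize(
            kg, K=config.embedding_dim, init_spec=init, seed=config.seed,
            lambda_reg=config.lambda_reg,
        )

        # step-2 material: weighted similarity edges over the training degrees
        if config.similarity_edges:
            self.sim_triples, self.sim_weights = build_similarity_edges(
                kg, profiles, config.weighting, split=split, min_weight=config.min_weight
            )
        else:
            self.sim_triples = np.zeros((0, 3), dtype=np.int64)
            self.sim_weights = np.zeros(0)

        # step-3 material: weak drugs and their mono-side-effect anchors
        self.weak_train = train_weak_drugs(kg, split, config.weak_fraction)
        if config.weak_anchor_loss:
            self.neighbor_map = mono_neighbor_map(
                kg, sorted(self.weak_train), config.n_sim_neighbors
            )
        else:
            self.neighbor_map = {}

        strong_map = None
        if config.sampler.kind == "strong_nscaching":
            ext = {e.entity_id: e.external_id for e in kg.entities}
            strong = sorted(set(kg.drug_ids.tolist()) - set(self.weak_train))
            strong_map = {
                d: nearest_strong_neighbor(d, strong, profiles, ext)
                for d in sorted(self.weak_train)
            }
        self.sampler = make_sampler(
            kg, config.sampler, split.train,
            strong_map=strong_map, drug_degrees=kg.degrees("drug_drug_only"),
        )
        # the similarity graph is (near-)complete, so step-2 corruptions are
        # contrasted unfiltered against random drug pairs
        if config.similarity_edges:
            sim_kg = kg.with_similarity_edges(self.sim_triples, self.sim_weights)
            self._sim_rel = int(sim_kg.relations_of_kind("similarity")[0])
            self._sim_sampler = UniformSampler(
                sim_kg, SamplerSpec(kind="uniform", neg_ratio=config.sampler.neg_ratio),
                positives=frozenset(),
            )
            # the similarity relation gets one extra Xavier row in R
            self.model = TripleModel(
                self.model.E,
                np.concatenate([
                    self.model.R,
                    _xavier_relation(config.embedding_dim, self.rng),
                ]),
                lambda_reg=config.lambda_reg,
            )

        self.optimizer = _Adam(
            [self.model.E.shape, self.model.R.shape], lr=config.learning_rate
        )
        self._val_negs = (
            frozen_eval_negatives(kg, split.valid, seed=config.seed + 10_007)
            if len(split.valid) else None
        )
        self.history: list[dict] = []

    # -- epoch machinery ---------------------------------------------------
    def _minibatches(self, n: int):
        order = self.rng.permutation(n)
        bs = self.config.batch_size
        for i in range(0, n, bs):
            yield order[i : i + bs]

    def _sgd_step(self, loss_grads) -> float:
        loss, gE, gR = loss_grads
        if not np.isfinite(loss):
            raise RuntimeError(f"training diverged: non-finite loss {loss}")
        self.optimizer.step([self.model.E, self.model.R], [gE, gR])
        return loss

    def train_epoch(self) -> dict[str, float]:
        """One pass of the 3-step schedule; returns the mean loss per step."""
        cfg = self.config
        if cfg.sampler.is_cache_based:
            if self.sampler.cache is None:
                self.sampler.cache_init(self.rng)
            else:
                self.sampler.cache_update(self.model, self.rng)

        losses1 = []
        train = self.split.train
        for idx in self._minibatches(len(train)):
            batch = train[idx]
            hc, hm, tc, tm = self.sampler.sample(batch, self.rng)
            losses1.append(self._sgd_step(trivec_loss(
                self.model, batch, hc, tc, hm, tm, return_grad=True
            )))

        losses2 = []
        if cfg.similarity_edges and len(self.sim_triples):
            sim = self.sim_triples.copy()
            sim[:, 1] = self._sim_rel
            for idx in self._minibatches(len(sim)):
                batch, w = sim[idx], self.sim_weights[idx]
                hc, hm, tc, tm = self._sim_sampler.sample(batch, self.rng)
                losses2.append(self._sgd_step(trivec_loss(
                    self.model, batch, hc, tc, hm, tm,
                    triple_weights=w, return_grad=True,
                )))

        loss3 = None
        if cfg.weak_anchor_loss and self.neighbor_map:
            loss3 = self._sgd_step(
                weak_node_anchor_loss(self.model, self.neighbor_map, return_grad=True)
            )

        return {
            "step1_loss": float(np.mean(losses1)) if losses1 else float("nan"),
            "step2_loss": float(np.mean(losses2)) if losses2 else None,
            "step3_loss": loss3,
        }

    def fit(self) -> TripleModel:
        """Run epochs with early stopping on validation macro ROC AUC."""
        cfg = self.config
        best_auc, best_model, since_improve = -np.inf, self.model.copy(), 0
        for epoch in range(cfg.epochs_max):
            entry = self.train_epoch()
            entry["epoch"] = epoch
            if self._val_negs is not None:
                report = evaluate(
                    self.model, self.split.valid, self.kg, negatives=self._val_negs
                )
                entry["valid_roc_auc"] = report.macro_roc_auc
                if report.macro_roc_auc > best_auc + cfg.early_stop_epsilon:
                    best_auc = report.macro_roc_auc
                    best_model = self.model.copy()
                    since_improve = 0
                else:
                    since_improve += 1
            self.history.append(entry)
            if self._val_negs is not None and since_improve >= cfg.patience:
                break
        if self._val_negs is None:
            best_model = self.model.copy()
        self.best_valid_auc_ = best_auc
        return best_model


def _xavier_relation(K: int, rng: np.random.Generator) -> np.ndarray:
    limit = np.sqrt(6.0 / (2 * K))
    return rng.uniform(-limit, limit, size=(1, 3, K))


def fit(
    kg: KnowledgeGraph,
    split: DataSplit,
    config: TrainConfig | None = None,
    profiles: ChemProfileSet | None = None,
) -> tuple[TripleModel, list[dict]]:
    """Train a model on a split; returns (best checkpoint, per-epoch history)."""
    trainer = Trainer(kg, split, config or TrainConfig(), profiles)
    model = trainer.fit()
    return model, trainer.history
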