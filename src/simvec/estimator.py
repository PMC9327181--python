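"""Scikit-learn style estimator wrapping the full pipeline.

:class:`SimVec` exposes the knowledge-graph link predictor through the familiar
fit / decision_function / predict_proba surface, with ``get_params`` /
``set_params`` so it composes with sklearn model selection.  The named variants
of the method (which enhancements are switched on) are available as parameter
presets via :func:`variant_params`.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .chem_features import ChemProfileSet
from .graph_enhance import WeightingScheme
from .kg_store import DataSplit, KnowledgeGraph
from .negative_sampling import SamplerSpec
from .train_eval import (
    EvalReport,
    TrainConfig,
    Trainer,
    evaluate,
    predict_side_effects,
)

#: named model variants: which of the three enhancements each switches on.
#: "trivec" is the unenhanced baseline (its best learning rate is 0.005);
#: "se" is the mono-side-effect anchor loss, "weighted" the similarity edges,
#: "chem" the chemical node initialization; "full" enables all three.
VARIANTS: dict[str, dict] = {
    "trivec": dict(drug_init="xavier", similarity_edges=False, weak_anchor_loss=False,
                   learning_rate=0.005),
    "trivec_se": dict(drug_init="mono_se", similarity_edges=False,
                      weak_anchor_loss=False, learning_rate=0.005),
    "chem": dict(drug_init="chemical", similarity_edges=False, weak_anchor_loss=False),
    "se": dict(drug_init="xavier", similarity_edges=False, weak_anchor_loss=True),
    "weighted": dict(drug_init="xavier", similarity_edges=True, weak_anchor_loss=False),
    "chem_weighted": dict(drug_init="chemical", similarity_edges=True,
                          weak_anchor_loss=False),
    "se_chem": dict(drug_init="chemical", similarity_edges=False, weak_anchor_loss=True),
    "se_weighted": dict(drug_init="xavier", similarity_edges=True, weak_anchor_loss=True),
    "full": dict(drug_init="chemical", similarity_edges=True, weak_anchor_loss=True),
}


def variant_params(name: str) -> dict:
    """Estimator parameter overrides for a named model variant."""
    try:
        return dict(VARIANTS[name])
    except KeyError:
        raise ValueError(f"unknown variant {name!r}; choose from {sorted(VARIANTS)}")


class SimVec(BaseEstimator):
    """Polypharmacy side-effect link predictor over a drug/protein graph.

    Parameters mirror :class:`simvec.train_eval.TrainConfig`; the three
    enhancement switches (``drug_init='chemical'``, ``similarity_edges``,
    ``weak_anchor_loss``) turned off together give the plain trilinear
    (TriVec-style) baseline.

    After ``fit`` the estimator exposes ``model_`` (the embedding tables),
    ``history_`` (per-epoch losses and validation AUC) and
    ``best_valid_auc_``.
    """

    def __init__(
        self,
        embedding_dim: int = 100,
        lambda_reg: float = 0.01,
        learning_rate: float = 0.001,
        epochs_max: int = 50,
        batch_size: int = 512,
        early_stop_epsilon: float = 0.001,
        patience: int = 7,
        drug_init: str = "xavier",
        similarity_edges: bool = False,
        weak_anchor_loss: bool = False,
        weighting_kind: str = "window",
        l_bound: float = 1.0,
        u_bound: float = 4.0,
        min_weight: float = 0.0,
        n_sim_neighbors: int = 6,
        weak_fraction: float = 1.0 / 6.0,
        sampler: str = "uniform",
        neg_ratio: int | None = None,
        cache_size: int = 30,
        n_random: int = 30,
        alpha: float = 1.0 / 3.0,
        random_state: int = 0,
    ):
        self.embedding_dim = embedding_dim
        self.lambda_reg = lambda_reg
        self.learning_rate = learning_rate
        self.epochs_max = epochs_max
        self.batch_size = batch_size
        self.early_stop_epsilon = early_stop_epsilon
        self.patience = patience
        self.drug_init = drug_init
        self.similarity_edges = similarity_edges
        self.weak_anchor_loss = weak_anchor_loss
        self.weighting_kind = weighting_kind
        self.l_bound = l_bound
        self.u_bound = u_bound
        self.min_weight = min_weight
        self.n_sim_neighbors = n_sim_neighbors
        self.weak_fraction = weak_fraction
        self.sampler = sampler
        self.neg_ratio = neg_ratio
        self.cache_size = cache_size
        self.n_random = n_random
        self.alpha = alpha
        self.random_state = random_state

    # -- config assembly ---------------------------------------------------
    def _config(self) -> TrainConfig:
        return TrainConfig(
            embedding_dim=self.embedding_dim,
            lambda_reg=self.lambda_reg,
            learning_rate=self.learning_rate,
            epochs_max=self.epochs_max,
            batch_size=self.batch_size,
            early_stop_epsilon=self.early_stop_epsilon,
            patience=self.patience,
            seed=self.random_state,
            drug_init=self.drug_init,
            similarity_edges=self.similarity_edges,
            weak_anchor_loss=self.weak_anchor_loss,
            weighting=WeightingScheme(
                kind=self.weighting_kind, l_bound=self.l_bound, u_bound=self.u_bound
            ),
            min_weight=self.min_weight,
            n_sim_neighbors=self.n_sim_neighbors,
            weak_fraction=self.weak_fraction,
            sampler=SamplerSpec(
                kind=self.sampler, neg_ratio=self.neg_ratio,
                cache_size=self.cache_size, n_random=self.n_random, alpha=self.alpha,
            ),
        )

    # -- sklearn surface ---------------------------------------------------
    def fit(self, kg: KnowledgeGraph, split: DataSplit,
            profiles: ChemProfileSet | None = None) -> "SimVec":
        trainer = Trainer(kg, split, self._config(), profiles)
        self.model_ = trainer.fit()
        self.history_ = trainer.history
        self.best_valid_auc_ = trainer.best_valid_auc_
        self.kg_ = kg
        self.weak_drugs_train_ = trainer.weak_train
        return self

    def _require_fitted(self):
        if not hasattr(self, "model_"):
            raise RuntimeError("estimator is not fitted; call fit first")

    def decision_function(self, triples: np.ndarray) -> np.ndarray:
        """Raw trilinear scores phi for (head, relation, tail) rows."""
        self._require_fitted()
        t = np.asarray(triples, dtype=np.int64).reshape(-1, 3)
        return self.model_.score_batch(t[:, 0], t[:, 1], t[:, 2])

    def predict_proba(self, triples: np.ndarray) -> np.ndarray:
        """sigmoid(phi), as columns [P(absent), P(present)]."""
        p = 1.0 / (1.0 + np.exp(-self.decision_function(triples)))
        return np.column_stack([1.0 - p, p])

    def predict(self, triples: np.ndarray) -> np.ndarray:
        """Existence calls at the sigmoid-0.5 threshold."""
        return (self.decision_function(triples) > 0).astype(int)

    def evaluate(self, triples: np.ndarray, seed: int = 0) -> EvalReport:
        """Per-relation ROC AUC / AUC PR with one frozen negative per positive."""
        self._require_fitted()
        return evaluate(self.model_, triples, self.kg_, seed=seed)

    def predict_side_effects(self, drug_a: int, drug_b: int, top_k: int = 10):
        """Side-effect relations ranked for one drug pair (orientation-symmetrized)."""
        self._require_fitted()
        return predict_side_effects(self.model_, self.kg_, drug_a, drug_b, top_k)
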