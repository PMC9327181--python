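"""Negative-triple generation: uniform, Bernoulli, and cache-based samplers.

A knowledge graph records only positive facts, so training needs presumed-false
triples made by corrupting the head or tail of a true one.  All samplers here
are *filtered*: a corruption that reproduces any known positive (in either
orientation for symmetric relations) is rejected and redrawn.  Corrupted
entities are always drawn from the same kind (drug or protein) as the entity
they replace.

Cache-based samplers (NSCaching and variants) keep, per (head, relation) and
per (relation, tail) key, a small cache of high-scoring corruptions, refreshed
each epoch by scoring ``n_random`` fresh uniform candidates against the current
model and resampling the cache proportionally to the softmax of the scores.
The "exploration" variant doubles the fresh-candidate budget; the 6:1 variant
draws six negatives per positive; "strong" NSCaching lets a weak drug borrow
the cache of its chemically nearest strong neighbour with probability
p(h) = 1 / log(deg_h)^alpha.

Samplers return fixed-width candidate arrays shaped for
:func:`simvec.embedding_model.trivec_loss`: column 0 holds the true entity and
a boolean mask flags which candidate slots are in use.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from .embedding_model import TripleModel
from .kg_store import KnowledgeGraph

_CACHE_KINDS = frozenset({"nscaching", "nscaching_61", "exploration", "strong_nscaching"})
_ALL_KINDS = _CACHE_KINDS | {"uniform", "bernoulli"}


@dataclass(frozen=True)
class SamplerSpec:
    """Choice of negative-sampling strategy and its knobs.

    neg_ratio defaults to 1 (6 for the 6:1 variant); cache_size and n_random
    govern the per-key cache and its refresh budget; alpha controls how fast
    the strong-neighbour borrowing probability decays with degree.
    """

    kind: str = "uniform"
    neg_ratio: int | None = None
    cache_size: int = 30
    n_random: int = 30
    alpha: float = 1.0 / 3.0
    max_retries: int = 50

    def __post_init__(self):
        if self.kind not in _ALL_KINDS:
            raise ValueError(f"unknown sampler kind {self.kind!r}")
        if self.neg_ratio is None:
            object.__setattr__(self, "neg_ratio", 6 if self.kind == "nscaching_61" else 1)
        if self.neg_ratio < 1:
            raise ValueError("neg_ratio must be >= 1")

    @property
    def is_cache_based(self) -> bool:
        return self.kind in _CACHE_KINDS

    @property
    def effective_n_random(self) -> int:
        """Fresh candidates drawn per cache entry per update (doubled for exploration)."""
        return 2 * self.n_random if self.kind == "exploration" else self.n_random


@dataclass
class NegativeCache:
    """Per-key candidate caches: tails by (head, relation), heads by (relation, tail)."""

    tail_cache: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    head_cache: dict[tuple[int, int], np.ndarray] = field(default_factory=dict)
    last_update_draws: int | None = None

    def dump(self, path: str | Path, model: TripleModel | None = None) -> None:
        """Write cache contents as TSV (side, key1, key2, candidate, score)."""
        rows = []
        for (h, r), tails in sorted(self.tail_cache.items()):
            for t in tails:
                s = model.score(h, r, int(t)) if model is not None else float("nan")
                rows.append(("tail", h, r, int(t), s))
        for (r, t), heads in sorted(self.head_cache.items()):
            for h in heads:
                s = model.score(int(h), r, t) if model is not None else float("nan")
                rows.append(("head", r, t, int(h), s))
        with open(path, "w") as fh:
            fh.write("side\tkey1\tkey2\tcandidate\tscore\n")
            for row in rows:
                fh.write("\t".join(map(str, row)) + "\n")


class _SamplerBase:
    def __init__(self, kg: KnowledgeGraph, spec: SamplerSpec,
                 positives: frozenset[tuple[int, int, int]] | None = None):
        self.kg = kg
        self.spec = spec
        self.positives = kg.positive_set() if positives is None else positives
        kinds = kg.entity_kind
        self._pool = {
            k: np.array([e.entity_id for e in kg.entities if e.kind == k], dtype=np.int64)
            for k in set(kinds)
        }
        self._kind_of = kinds

    def _draw_replacement(self, h: int, r: int, t: int, corrupt_head: bool,
                          rng: np.random.Generator) -> int | None:
        """A same-kind filtered replacement, or None if retries are exhausted."""
        slot, other = (h, t) if corrupt_head else (t, h)
        pool = self._pool[self._kind_of[slot]]
        for _ in range(self.spec.max_retries):
            cand = int(pool[rng.integers(len(pool))])
            trip = (cand, r, t) if corrupt_head else (h, r, cand)
            # a corruption must not reproduce a positive or collapse to a self-loop
            if cand != slot and cand != other and trip not in self.positives:
                return cand
        return None

    def _head_probability(self, r: int) -> float:
        return 0.5

    def sample(self, positives: np.ndarray, rng: np.random.Generator):
        """Candidate arrays (head_cands, head_mask, tail_cands, tail_mask) of
        width 1 + neg_ratio; column 0 is the true entity."""
        pos = np.asarray(positives, dtype=np.int64).reshape(-1, 3)
        B, width = len(pos), 1 + self.spec.neg_ratio
        hc = np.repeat(pos[:, :1], width, axis=1)
        tc = np.repeat(pos[:, 2:], width, axis=1)
        hm = np.zeros((B, width), dtype=bool)
        tm = np.zeros((B, width), dtype=bool)
        hm[:, 0] = tm[:, 0] = True
        for b, (h, r, t) in enumerate(pos.tolist()):
            for j in range(1, width):
                corrupt_head = rng.random() < self._head_probability(r)
                cand = self._draw_replacement(h, r, t, corrupt_head, rng)
                if cand is None:
                    warnings.warn("negative-sampling retries exhausted; emitting fewer negatives")
                    continue
                if corrupt_head:
                    hc[b, j] = cand
                    hm[b, j] = True
                else:
                    tc[b, j] = cand
                    tm[b, j] = True
        return hc, hm, tc, tm


class UniformSampler(_SamplerBase):
    """Corrupt head or tail with a fair coin; replacement uniform over same-kind entities."""


class BernoulliSampler(_SamplerBase):
    """Head/tail choice weighted by relation cardinality.

    With tph the mean number of tails per (head, relation) and hpt the mean
    number of heads per (relation, tail) over the training triples, the head
    is corrupted with probability tph / (tph + hpt), which reduces false
    negatives on skewed (1-to-N / N-to-1) relations.
    """

    def __init__(self, kg, spec, train_triples: np.ndarray,
                 positives: frozenset | None = None):
        super().__init__(kg, spec, positives)
        self._p_head = relation_head_probabilities(train_triples)

    def _head_probability(self, r: int) -> float:
        return self._p_head.get(int(r), 0.5)


def relation_head_probabilities(train_triples: np.ndarray) -> dict[int, float]:
    """tph / (tph + hpt) per relation, from brute-force cardinality counts."""
    trips = np.asarray(train_triples, dtype=np.int64).reshape(-1, 3)
    out: dict[int, float] = {}
    for r in np.unique(trips[:, 1]):
        rows = trips[trips[:, 1] == r]
        heads, tails = rows[:, 0], rows[:, 2]
        tph = len(rows) / len(np.unique(heads))
        hpt = len(rows) / len(np.unique(tails))
        out[int(r)] = tph / (tph + hpt)
    return out


def strong_sampling_probability(degree: float, alpha: float) -> float:
    """p(h) = 1 / ln(deg_h)^alpha, with deg clamped to >= 2 and p capped at 1."""
    deg = max(float(degree), 2.0)
    return min(1.0, 1.0 / np.log(deg) ** alpha)


class CacheSampler(_SamplerBase):
    """NSCaching and its variants (6:1 ratio, exploration, strong-neighbour)."""

    def __init__(self, kg, spec: SamplerSpec, train_triples: np.ndarray,
                 positives: frozenset | None = None,
                 strong_map: Mapping[int, int] | None = None,
                 drug_degrees: np.ndarray | None = None):
        if not spec.is_cache_based:
            raise ValueError("CacheSampler needs a cache-based SamplerSpec")
        super().__init__(kg, spec, positives)
        self.train_triples = np.asarray(train_triples, dtype=np.int64).reshape(-1, 3)
        self.strong_map = dict(strong_map or {})
        self.drug_degrees = drug_degrees
        self.cache: NegativeCache | None = None

    # -- cache lifecycle ---------------------------------------------------
    def cache_init(self, rng: np.random.Generator) -> NegativeCache:
        """Fill every (h, r) and (r, t) key seen in train with uniform filtered candidates."""
        cache = NegativeCache()
        for h, r, t in self.train_triples.tolist():
            if (h, r) not in cache.tail_cache:
                cache.tail_cache[(h, r)] = self._fill(h, r, t, corrupt_head=False, rng=rng)
            if (r, t) not in cache.head_cache:
                cache.head_cache[(r, t)] = self._fill(h, r, t, corrupt_head=True, rng=rng)
        self.cache = cache
        return cache

    def _fill(self, h, r, t, corrupt_head, rng) -> np.ndarray:
        out = []
        for _ in range(self.spec.cache_size):
            cand = self._draw_replacement(h, r, t, corrupt_head, rng)
            if cand is not None:
                out.append(cand)
        return np.array(sorted(set(out)), dtype=np.int64)

    def cache_update(self, model: TripleModel, rng: np.random.Generator) -> NegativeCache:
        """Refresh each cache entry by importance sampling.

        Per key: draw ``effective_n_random`` fresh filtered candidates, score
        cache ∪ fresh with the current model, and keep ``cache_size`` entries
        sampled without replacement proportionally to the softmax of the
        scores (Gumbel top-k), so high-scoring ("hard") corruptions persist.
        """
        if self.cache is None:
            raise RuntimeError("cache_init must run before cache_update")
        n_fresh = self.spec.effective_n_random
        drawn = 0
        new_tail, new_head = {}, {}
        for (h, r), current in sorted(self.cache.tail_cache.items()):
            fresh = self._fresh_candidates(h, r, slot_is_head=False, rng=rng)
            drawn += n_fresh
            new_tail[(h, r)] = self._retain(
                current, fresh,
                score=lambda cands: model.score_batch(
                    np.full(len(cands), h), np.full(len(cands), r), cands),
                rng=rng,
            )
        for (r, t), current in sorted(self.cache.head_cache.items()):
            fresh = self._fresh_candidates(t, r, slot_is_head=True, rng=rng)
            drawn += n_fresh
            new_head[(r, t)] = self._retain(
                current, fresh,
                score=lambda cands: model.score_batch(
                    cands, np.full(len(cands), r), np.full(len(cands), t)),
                rng=rng,
            )
        self.cache = NegativeCache(new_tail, new_head, last_update_draws=drawn)
        return self.cache

    def _fresh_candidates(self, anchor: int, r: int, slot_is_head: bool,
                          rng: np.random.Generator) -> np.ndarray:
        """effective_n_random uniform filtered corruptions for one cache key."""
        out = []
        for _ in range(self.spec.effective_n_random):
            if slot_is_head:
                cand = self._draw_replacement(anchor, r, anchor, corrupt_head=True, rng=rng)
            else:
                cand = self._draw_replacement(anchor, r, anchor, corrupt_head=False, rng=rng)
            if cand is not None:
                out.append(cand)
        return np.array(out, dtype=np.int64)

    def _retain(self, current: np.ndarray, fresh: np.ndarray, score, rng) -> np.ndarray:
        union = np.array(sorted(set(current.tolist()) | set(fresh.tolist())), dtype=np.int64)
        if len(union) <= self.spec.cache_size:
            return union
        phi = np.asarray(score(union), dtype=float)
        # Gumbel top-k == sampling without replacement with probs softmax(phi)
        keys = phi + rng.gumbel(size=len(phi))
        keep = union[np.argsort(keys)[::-1][: self.spec.cache_size]]
        return np.sort(keep)

    # -- sampling ----------------------------------------------------------
    def _cache_keys(self, h: int, r: int, t: int, rng: np.random.Generator):
        """Resolve the (tail-cache, head-cache) keys, redirecting weak drugs
        to their nearest strong neighbour for the strong variant."""
        th, ht = h, t
        if self.spec.kind == "strong_nscaching":
            for slot, is_head in ((h, True), (t, False)):
                if slot in self.strong_map:
                    deg = int(self.drug_degrees[slot]) if self.drug_degrees is not None else 2
                    if rng.random() < strong_sampling_probability(deg, self.spec.alpha):
                        if is_head:
                            th = self.strong_map[slot]
                        else:
                            ht = self.strong_map[slot]
        return (th, r), (r, ht)

    def sample(self, positives: np.ndarray, rng: np.random.Generator):
        if self.cache is None:
            raise RuntimeError("cache_init must run before sampling")
        pos = np.asarray(positives, dtype=np.int64).reshape(-1, 3)
        B, width = len(pos), 1 + self.spec.neg_ratio
        hc = np.repeat(pos[:, :1], width, axis=1)
        tc = np.repeat(pos[:, 2:], width, axis=1)
        hm = np.zeros((B, width), dtype=bool)
        tm = np.zeros((B, width), dtype=bool)
        hm[:, 0] = tm[:, 0] = True
        fallback_warned = False
        for b, (h, r, t) in enumerate(pos.tolist()):
            tail_key, head_key = self._cache_keys(h, r, t, rng)
            tails = self.cache.tail_cache.get(tail_key, np.empty(0, dtype=np.int64))
            heads = self.cache.head_cache.get(head_key, np.empty(0, dtype=np.int64))
            # candidates tagged by which slot they corrupt
            sides = np.concatenate([np.zeros(len(heads), int), np.ones(len(tails), int)])
            cands = np.concatenate([heads, tails])
            if not len(cands):
                if not fallback_warned:
                    warnings.warn("empty cache entry; falling back to uniform corruption")
                    fallback_warned = True
                for j in range(1, width):
                    corrupt_head = rng.random() < 0.5
                    cand = self._draw_replacement(h, r, t, corrupt_head, rng)
                    if cand is None:
                        continue
                    if corrupt_head:
                        hc[b, j], hm[b, j] = cand, True
                    else:
                        tc[b, j], tm[b, j] = cand, True
                continue
            draws = rng.integers(len(cands), size=width - 1)
            for j, ix in enumerate(draws, start=1):
                if sides[ix] == 0:
                    hc[b, j], hm[b, j] = int(cands[ix]), True
                else:
                    tc[b, j], tm[b, j] = int(cands[ix]), True
        return hc, hm, tc, tm


def make_sampler(
    kg: KnowledgeGraph,
    spec: SamplerSpec,
    train_triples: np.ndarray,
    positives: frozenset | None = None,
    strong_map: Mapping[int, int] | None = None,
    drug_degrees: np.ndarray | None = None,
):
    """Factory dispatching on spec.kind."""
    if spec.kind == "uniform":
        return UniformSampler(kg, spec, positives)
    if spec.kind == "bernoulli":
        return BernoulliSampler(kg, spec, train_triples, positives)
    return CacheSampler(kg, spec, train_triples, positives, strong_map, drug_degrees)
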