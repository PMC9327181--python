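import numpy as np
import pandas as pd
import pytest

from simvec.embedding_model import TripleModel
from simvec.kg_store import load_kg
from simvec.negative_sampling import (
    BernoulliSampler,
    CacheSampler,
    SamplerSpec,
    UniformSampler,
    make_sampler,
    relation_head_probabilities,
    strong_sampling_probability,
)
from conftest import random_toy_kg


def emitted_negatives(kg, hc, hm, tc, tm, positives):
    """All corrupted triples a sampler produced for a batch."""
    out = []
    for b, (h, r, t) in enumerate(positives.tolist()):
        for j in range(1, hc.shape[1]):
            if hm[b, j]:
                out.append((int(hc[b, j]), r, t))
            if tm[b, j]:
                out.append((h, r, int(tc[b, j])))
    return out


class TestUniform:
    def test_filtered_guarantee_exhaustive(self):
        rng = np.random.default_rng(0)
        kg = random_toy_kg(rng, n_drugs=6, n_edges=10)
        sampler = UniformSampler(kg, SamplerSpec(neg_ratio=3))
        positives = kg.positive_set()
        gen = np.random.default_rng(1)
        for _ in range(20):
            hc, hm, tc, tm = sampler.sample(kg.triples, gen)
            for trip in emitted_negatives(kg, hc, hm, tc, tm, kg.triples):
                assert trip not in positives

    def test_same_kind_replacement(self):
        rng = np.random.default_rng(2)
        kg = random_toy_kg(rng, n_drugs=5, n_proteins=6)
        sampler = UniformSampler(kg, SamplerSpec())
        kinds = kg.entity_kind
        gen = np.random.default_rng(3)
        hc, hm, tc, tm = sampler.sample(kg.triples, gen)
        for b, (h, r, t) in enumerate(kg.triples.tolist()):
            if hm[b, 1]:
                assert kinds[hc[b, 1]] == kinds[h]
            if tm[b, 1]:
                assert kinds[tc[b, 1]] == kinds[t]

    def test_exhaustion_warns_and_masks(self):
        # 2 drugs, the only corruption of either slot is itself or a positive
        combo = pd.DataFrame([("a", "b", "s1")], columns=["drug1", "drug2", "side_effect_id"])
        kg = load_kg(combo)
        sampler = UniformSampler(kg, SamplerSpec(max_retries=20))
        with pytest.warns(UserWarning, match="retries exhausted"):
            hc, hm, tc, tm = sampler.sample(kg.triples, np.random.default_rng(0))
        assert not hm[:, 1:].any() and not tm[:, 1:].any()

    def test_neg_ratio_six(self):
        rng = np.random.default_rng(4)
        kg = random_toy_kg(rng, n_drugs=10, n_edges=12)
        sampler = UniformSampler(kg, SamplerSpec(neg_ratio=6))
        hc, hm, tc, tm = sampler.sample(kg.triples[:5], np.random.default_rng(5))
        per_pos = hm[:, 1:].sum(axis=1) + tm[:, 1:].sum(axis=1)
        assert (per_pos == 6).all()

    def test_head_tail_coin_is_fair(self):
        rng = np.random.default_rng(6)
        kg = random_toy_kg(rng, n_drugs=20, n_edges=30)
        sampler = UniformSampler(kg, SamplerSpec())
        gen = np.random.default_rng(7)
        batch = np.repeat(kg.triples[:1], 10_000, axis=0)
        hc, hm, tc, tm = sampler.sample(batch, gen)
        frac_head = hm[:, 1].mean()
        assert abs(frac_head - 0.5) < 0.02


class TestBernoulli:
    def test_cardinality_brute_force(self):
        trips = np.array([
            [0, 0, 1], [0, 0, 2], [0, 0, 3], [4, 0, 5],  # tph=(4/2)=2, hpt=(4/4)=1
            [0, 1, 1],                                     # 1-to-1
        ])
        p = relation_head_probabilities(trips)
        assert p[1] == pytest.approx(0.5)
        assert p[0] == pytest.approx(2 / 3)

    def test_empirical_head_fraction(self):
        # relation with tph=3, hpt=1: heads corrupted with p = 0.75
        rows = [("h", f"t{i}", "se0") for i in range(3)]
        rows += [(f"x{j}", f"y{j}", "se0") for j in range(6)]
        combo = pd.DataFrame(rows, columns=["drug1", "drug2", "side_effect_id"])
        kg = load_kg(combo)
        h = kg.entity_by_external_id("h").entity_id
        rel = 0
        trips = kg.triples
        p_expect = relation_head_probabilities(trips)[rel]
        sampler = BernoulliSampler(kg, SamplerSpec(), trips)
        gen = np.random.default_rng(8)
        batch = np.repeat(trips[:1], 10_000, axis=0)
        hc, hm, tc, tm = sampler.sample(batch, gen)
        frac = hm[:, 1].mean()
        sd = np.sqrt(p_expect * (1 - p_expect) / 10_000)
        assert abs(frac - p_expect) < 3 * sd + 1e-3


@pytest.fixture
def cache_setup():
    rng = np.random.default_rng(9)
    kg = random_toy_kg(rng, n_drugs=12, n_edges=25)
    spec = SamplerSpec(kind="nscaching", cache_size=5, n_random=5)
    sampler = CacheSampler(kg, spec, kg.triples)
    model = TripleModel(
        np.random.default_rng(0).normal(size=(kg.n_entities, 3, 4)),
        np.random.default_rng(1).normal(size=(kg.n_relations, 3, 4)),
    )
    return kg, sampler, model


class TestCache:
    def test_init_contracts(self, cache_setup):
        kg, sampler, _ = cache_setup
        cache = sampler.cache_init(np.random.default_rng(0))
        positives = kg.positive_set()
        for (h, r), tails in cache.tail_cache.items():
            assert len(tails) <= 5
            for t in tails:
                assert (h, r, int(t)) not in positives
        for (r, t), heads in cache.head_cache.items():
            for h in heads:
                assert (int(h), r, t) not in positives

    def test_init_deterministic(self, cache_setup):
        kg, sampler, _ = cache_setup
        a = sampler.cache_init(np.random.default_rng(42))
        b = CacheSampler(kg, sampler.spec, kg.triples).cache_init(np.random.default_rng(42))
        assert a.tail_cache.keys() == b.tail_cache.keys()
        for k in a.tail_cache:
            assert np.array_equal(a.tail_cache[k], b.tail_cache[k])

    def test_update_n_random_zero_is_noop(self, cache_setup):
        kg, _, model = cache_setup
        spec = SamplerSpec(kind="nscaching", cache_size=5, n_random=0)
        sampler = CacheSampler(kg, spec, kg.triples)
        before = sampler.cache_init(np.random.default_rng(0))
        snapshot = {k: v.copy() for k, v in before.tail_cache.items()}
        after = sampler.cache_update(model, np.random.default_rng(1))
        for k, v in snapshot.items():
            assert np.array_equal(after.tail_cache[k], v)

    def test_exploration_doubles_draws(self, cache_setup):
        kg, _, model = cache_setup
        base = SamplerSpec(kind="nscaching", cache_size=5, n_random=7)
        doubled = SamplerSpec(kind="exploration", cache_size=5, n_random=7)
        assert doubled.effective_n_random == 2 * base.effective_n_random
        s1 = CacheSampler(kg, base, kg.triples)
        s2 = CacheSampler(kg, doubled, kg.triples)
        s1.cache_init(np.random.default_rng(0))
        s2.cache_init(np.random.default_rng(0))
        s1.cache_update(model, np.random.default_rng(1))
        s2.cache_update(model, np.random.default_rng(1))
        assert s2.cache.last_update_draws == 2 * s1.cache.last_update_draws

    def test_mean_cache_score_trend_under_frozen_model(self, cache_setup):
        kg, _, model = cache_setup

        def mean_score(sampler):
            vals = []
            for (h, r), tails in sampler.cache.tail_cache.items():
                if len(tails):
                    vals.extend(model.score_batch(
                        np.full(len(tails), h), np.full(len(tails), r), tails))
            return float(np.mean(vals))

        deltas = []
        for seed in range(3):
            spec = SamplerSpec(kind="nscaching", cache_size=5, n_random=10)
            sampler = CacheSampler(kg, spec, kg.triples)
            rng = np.random.default_rng(seed)
            sampler.cache_init(rng)
            start = mean_score(sampler)
            for _ in range(10):
                sampler.cache_update(model, rng)
            deltas.append(mean_score(sampler) - start)
        assert np.mean(deltas) > 0  # caches accumulate high-scoring corruptions

    def test_sample_contracts(self, cache_setup):
        kg, sampler, _ = cache_setup
        rng = np.random.default_rng(3)
        sampler.cache_init(rng)
        positives = kg.positive_set()
        hc, hm, tc, tm = sampler.sample(kg.triples, rng)
        for trip in emitted_negatives(kg, hc, hm, tc, tm, kg.triples):
            assert trip not in positives

    def test_six_to_one_ratio(self):
        rng = np.random.default_rng(10)
        kg = random_toy_kg(rng, n_drugs=10, n_edges=20)
        spec = SamplerSpec(kind="nscaching_61", cache_size=4, n_random=4)
        assert spec.neg_ratio == 6
        sampler = CacheSampler(kg, spec, kg.triples)
        gen = np.random.default_rng(11)
        sampler.cache_init(gen)
        hc, hm, tc, tm = sampler.sample(kg.triples[:4], gen)
        per_pos = hm[:, 1:].sum(axis=1) + tm[:, 1:].sum(axis=1)
        assert (per_pos == 6).all()

    def test_missing_entry_falls_back_to_uniform(self, cache_setup):
        kg, sampler, _ = cache_setup
        sampler.cache_init(np.random.default_rng(0))
        sampler.cache.tail_cache.clear()
        sampler.cache.head_cache.clear()
        with pytest.warns(UserWarning, match="empty cache"):
            hc, hm, tc, tm = sampler.sample(kg.triples[:2], np.random.default_rng(1))
        assert (hm[:, 1:].sum() + tm[:, 1:].sum()) > 0


class TestStrongNSCaching:
    def test_probability_formula(self):
        assert strong_sampling_probability(np.e, 1.0) == pytest.approx(1.0)
        assert strong_sampling_probability(np.e**2, 1.0) == pytest.approx(0.5)
        # degree clamp avoids division by log(1) = 0; ln 2 < 1 caps p at 1
        assert strong_sampling_probability(1, 1.0) == 1.0
        # large alpha kills borrowing, recovering plain cache sampling
        assert strong_sampling_probability(8, 50.0) < 1e-3

    def test_redirects_to_strong_neighbor_cache(self):
        rng = np.random.default_rng(12)
        kg = random_toy_kg(rng, n_drugs=10, n_edges=20)
        weak = int(kg.triples[0, 0])
        strong = int(kg.triples[0, 2])
        spec = SamplerSpec(kind="strong_nscaching", cache_size=4, n_random=4, alpha=1.0)
        deg = np.full(kg.n_entities, 2)  # ln(2) < 1 -> p = 1: always borrow
        sampler = CacheSampler(kg, spec, kg.triples,
                               strong_map={weak: strong}, drug_degrees=deg)
        gen = np.random.default_rng(13)
        sampler.cache_init(gen)
        r = int(kg.triples[0, 1])
        allowed = set(sampler.cache.tail_cache.get((strong, r), []).tolist()) \
            | set(sampler.cache.head_cache.get((r, int(kg.triples[0, 2])), []).tolist())
        hc, hm, tc, tm = sampler.sample(kg.triples[:1], gen)
        got = {int(tc[0, j]) for j in range(1, 2) if tm[0, j]} \
            | {int(hc[0, j]) for j in range(1, 2) if hm[0, j]}
        assert got <= allowed


def test_make_sampler_dispatch():
    rng = np.random.default_rng(14)
    kg = random_toy_kg(rng)
    assert isinstance(make_sampler(kg, SamplerSpec(), kg.triples), UniformSampler)
    assert isinstance(
        make_sampler(kg, SamplerSpec(kind="bernoulli"), kg.triples), BernoulliSampler)
    assert isinstance(
        make_sampler(kg, SamplerSpec(kind="nscaching"), kg.triples), CacheSampler)
    with pytest.raises(ValueError):
        SamplerSpec(kind="bogus")
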