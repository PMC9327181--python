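import numpy as np
import pytest

from simvec.embedding_model import (
    InitSpec,
    TripleModel,
    initialize,
    mono_neighbor_map,
    similarity_edge_loss,
    trivec_loss,
    weak_node_anchor_loss,
)
from simvec.chem_features import ChemProfileSet


def tiny_model(seed=0, n_ent=5, n_rel=2, K=4, lam=0.7):
    rng = np.random.default_rng(seed)
    return TripleModel(
        rng.normal(size=(n_ent, 3, K)), rng.normal(size=(n_rel, 3, K)), lambda_reg=lam
    )


def finite_diff(f, arr, eps=1e-6):
    g = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        ix = it.multi_index
        arr[ix] += eps
        lp = f()
        arr[ix] -= 2 * eps
        lm = f()
        arr[ix] += eps
        g[ix] = (lp - lm) / (2 * eps)
    return g


class TestScore:
    def test_all_ones_k1(self):
        m = TripleModel(np.ones((2, 3, 1)), np.ones((1, 3, 1)))
        assert m.score(0, 0, 1) == 3.0

    def test_zero_entity_annihilates(self):
        m = tiny_model()
        m.E[2] = 0.0
        assert m.score(2, 0, 1) == 0.0
        assert m.score(1, 0, 2) == 0.0

    def test_linearity_in_relation(self):
        m = tiny_model(seed=1)
        base = m.score(0, 1, 3)
        m2 = m.copy()
        m2.R[1] *= 2.5
        assert m2.score(0, 1, 3) == pytest.approx(2.5 * base)

    def test_brute_force_formula(self):
        # independent scalar-loop evaluation of the cross-paired trilinear form
        m = tiny_model(seed=2, K=3)
        h, r, t = 1, 0, 4
        brute = sum(
            m.E[h, 0, k] * m.R[r, 0, k] * m.E[t, 2, k]
            + m.E[h, 1, k] * m.R[r, 1, k] * m.E[t, 1, k]
            + m.E[h, 2, k] * m.R[r, 2, k] * m.E[t, 0, k]
            for k in range(3)
        )
        assert m.score(h, r, t) == pytest.approx(brute)

    def test_unknown_ids(self):
        m = tiny_model()
        with pytest.raises(KeyError):
            m.score(99, 0, 1)
        with pytest.raises(KeyError):
            m.score(0, 9, 1)


class TestTrivecLoss:
    def test_collapse_with_true_only_candidates(self):
        m = tiny_model(lam=0.0)
        pos = np.array([[0, 0, 1], [2, 1, 3]])
        loss = trivec_loss(m, pos, pos[:, :1], pos[:, 2:])
        assert loss == pytest.approx(0.0, abs=1e-12)

    def test_n3_hand_value(self):
        # lambda=3, K=1, all nine touched scalars 1 -> reg = 9 and softmax terms vanish
        m = TripleModel(np.ones((2, 3, 1)), np.ones((1, 3, 1)), lambda_reg=3.0)
        loss = trivec_loss(m, np.array([[0, 0, 1]]), np.array([[0]]), np.array([[1]]))
        assert loss == pytest.approx(9.0)

    def test_loss_decreases_as_positive_score_rises(self):
        # at the score level: L(phi_p) = -2 phi_p + 2 lse([phi_p, negs]);
        # dL/dphi_p = -2 + 2 softmax_0 < 0 strictly whenever negatives exist
        negs = np.array([0.3, -1.2, 2.0])
        def L(phi_p):
            lse = np.logaddexp.reduce(np.concatenate([[phi_p], negs]))
            return -2 * phi_p + 2 * lse
        vals = [L(p) for p in (-1.0, 0.0, 1.0, 3.0)]
        assert all(a > b for a, b in zip(vals, vals[1:]))

    def test_requires_true_in_column_zero(self):
        m = tiny_model()
        pos = np.array([[0, 0, 1]])
        with pytest.raises(ValueError, match="column 0"):
            trivec_loss(m, pos, np.array([[2]]), pos[:, 2:])

    def test_empty_candidate_mask_rejected(self):
        m = tiny_model()
        pos = np.array([[0, 0, 1]])
        with pytest.raises(ValueError, match="at least one"):
            trivec_loss(m, pos, pos[:, :1], pos[:, 2:],
                        head_mask=np.array([[False]]))

    def test_gradient_matches_finite_differences(self):
        m = tiny_model(seed=3)
        pos = np.array([[0, 0, 1], [2, 1, 3], [4, 0, 0]])
        hc = np.array([[0, 2, 3], [2, 4, 0], [4, 1, 2]])
        tc = np.array([[1, 4, 2], [3, 0, 1], [0, 3, 4]])
        hm = np.array([[1, 1, 0], [1, 1, 1], [1, 0, 1]], dtype=bool)
        tm = np.ones((3, 3), dtype=bool)
        w = np.array([1.0, 0.5, 0.8])
        loss, gE, gR = trivec_loss(m, pos, hc, tc, hm, tm, triple_weights=w,
                                   return_grad=True)
        f = lambda: trivec_loss(m, pos, hc, tc, hm, tm, triple_weights=w)
        assert np.allclose(gE, finite_diff(f, m.E), rtol=1e-4, atol=1e-7)
        assert np.allclose(gR, finite_diff(f, m.R), rtol=1e-4, atol=1e-7)

    def test_regularizer_nonnegative_zero_iff_zero(self):
        m = tiny_model(seed=4, lam=1.0)
        pos = np.array([[0, 0, 1]])
        loss_soft = trivec_loss(m, pos, pos[:, :1], pos[:, 2:], lambda_reg=0.0)
        loss_full = trivec_loss(m, pos, pos[:, :1], pos[:, 2:])
        assert loss_full >= loss_soft
        m.E[:] = 0.0
        m.R[:] = 0.0
        assert trivec_loss(m, pos, pos[:, :1], pos[:, 2:]) == 0.0


class TestSimilarityEdgeLoss:
    def _parts(self, m):
        pos = np.array([[0, 1, 1], [2, 1, 3]])
        return pos, np.array([[0, 3], [2, 4]]), np.array([[1, 4], [3, 0]])

    def test_weight_one_identity_and_scaling(self):
        m = tiny_model(seed=5)
        pos, hc, tc = self._parts(m)
        base = trivec_loss(m, pos, hc, tc)
        assert similarity_edge_loss(m, pos, np.ones(2), hc, tc) == pytest.approx(base)
        half = similarity_edge_loss(m, pos, np.full(2, 0.5), hc, tc)
        assert half == pytest.approx(base / 2)

    def test_weight_zero_kills_loss(self):
        m = tiny_model(seed=6)
        pos, hc, tc = self._parts(m)
        assert similarity_edge_loss(m, pos, np.zeros(2), hc, tc) == 0.0

    def test_gradient(self):
        m = tiny_model(seed=7)
        pos, hc, tc = self._parts(m)
        w = np.array([0.9, 0.3])
        loss, gE, gR = similarity_edge_loss(m, pos, w, hc, tc, return_grad=True)
        f = lambda: similarity_edge_loss(m, pos, w, hc, tc)
        assert np.allclose(gE, finite_diff(f, m.E), rtol=1e-4, atol=1e-7)
        assert np.allclose(gR, finite_diff(f, m.R), rtol=1e-4, atol=1e-7)


class TestWeakAnchorLoss:
    def test_zero_when_already_at_mean(self):
        m = tiny_model(seed=8)
        m.E[0] = m.E[[1, 2]].mean(axis=0)
        loss = weak_node_anchor_loss(m, {0: np.array([1, 2])})
        assert loss == pytest.approx(0.0)

    def test_unit_difference_hand_value(self):
        m = tiny_model(seed=9)
        m.E[1] = m.E[0] + 1.0  # differs by 1 in every coordinate
        assert weak_node_anchor_loss(m, {0: np.array([1])}) == pytest.approx(1.0)

    def test_anchors_detached(self):
        m = tiny_model(seed=10)
        nm = {0: np.array([1, 2]), 3: np.array([2, 4])}
        _, gE, gR = weak_node_anchor_loss(m, nm, return_grad=True)
        assert np.allclose(gE[[1, 2, 4]], 0.0)  # gradients only at weak drugs
        assert not np.allclose(gE[[0, 3]], 0.0)
        assert np.allclose(gR, 0.0)

    def test_gradient(self):
        # anchors are held constant, so finite differences are exact only on
        # the weak-drug rows (perturbing a weak row never moves a target)
        m = tiny_model(seed=11)
        nm = {0: np.array([1, 2]), 3: np.array([4])}
        _, gE, _ = weak_node_anchor_loss(m, nm, return_grad=True)
        f = lambda: weak_node_anchor_loss(m, nm)
        fd = finite_diff(f, m.E)
        assert np.allclose(gE[[0, 3]], fd[[0, 3]], rtol=1e-4, atol=1e-8)


class TestMonoNeighborMap:
    def test_brute_force_intersection_counting(self, toy_kg):
        # weak drug a: mono {m1, m2}; candidates b {m1}, c {m3}
        a = toy_kg.entity_by_external_id("a").entity_id
        b = toy_kg.entity_by_external_id("b").entity_id
        c = toy_kg.entity_by_external_id("c").entity_id
        nm = mono_neighbor_map(toy_kg, [a], n_sim_neighbors=1)
        assert list(nm[a]) == [b]  # |{m1}| = 1 beats |{}| = 0
        with pytest.warns(UserWarning, match="anchor candidates"):
            nm2 = mono_neighbor_map(toy_kg, [a], n_sim_neighbors=5)
        assert set(nm2[a]) == {b, c}


class TestInitialize:
    def test_xavier_determinism(self, toy_kg):
        a = initialize(toy_kg, K=8, seed=3)
        b = initialize(toy_kg, K=8, seed=3)
        assert np.array_equal(a.E, b.E) and np.array_equal(a.R, b.R)
        assert not np.array_equal(a.E, initialize(toy_kg, K=8, seed=4).E)

    def test_chemical_init_twins_nearly_identical(self, toy_kg):
        ids = toy_kg.drug_ids
        mat = np.zeros((len(ids), 8))
        mat[:2] = 1.0  # two identical profiles
        mat[2, :4] = 1.0
        profs = ChemProfileSet(ids, mat, kind="morgan")
        m = initialize(toy_kg, K=8, init_spec=InitSpec("chemical", profs), seed=0)
        d0, d1, d2 = (int(i) for i in ids[:3])
        twin_gap = np.abs(m.E[d0] - m.E[d1]).max()
        other_gap = np.abs(m.E[d0] - m.E[d2]).max()
        assert 0 < twin_gap < 0.1 * other_gap  # jitter-scale only

    def test_mono_se_init_empty_drug_near_zero(self, toy_tables):
        import pandas as pd
        from simvec.kg_store import load_kg
        combo, ppi, targets, mono = toy_tables
        mono = mono[mono["drug"] != "c"]  # drug c loses all mono effects
        kg = load_kg(combo, ppi, targets, mono)
        m = initialize(kg, K=8, init_spec=InitSpec("mono_se"), seed=0)
        c = kg.entity_by_external_id("c").entity_id
        xavier_std = 1 / np.sqrt(8)
        assert np.abs(m.E[c]).max() < 0.1 * xavier_std  # jitter only

    def test_chemical_requires_profiles(self):
        with pytest.raises(ValueError):
            InitSpec("chemical", profiles=None)
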