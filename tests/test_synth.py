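"""Ground-truth generator, simulator, prior corruption and metrics."""

import numpy as np
import pytest

from omicsbn.evaluate import (auc_ci83, auc_ci_bootstrap, cis_overlap,
                              cohens_kappa, roc_auc)
from omicsbn.omics_io import NODE_CNV, NODE_GE, NODE_METH
from omicsbn.synth import (corrupt_prior, gold_standard, random_typed_dag,
                           simulate_multiomics)


class TestRandomTypedDag:
    def test_constraints_hold_over_many_seeds(self):
        from omicsbn.prior import ConstraintSet
        for seed in range(1000):
            rng = np.random.default_rng(seed)
            model = random_typed_dag(15, edge_density=0.3, rng=rng)
            model.validate(ConstraintSet())  # raises on any violation

    def test_zero_density_gives_empty_ge_skeleton(self):
        model = random_typed_dag(8, edge_density=0.0,
                                 rng=np.random.default_rng(0))
        assert model.ge_edges() == set()

    def test_same_seed_reproduces_model(self):
        a = random_typed_dag(10, rng=np.random.default_rng(3))
        b = random_typed_dag(10, rng=np.random.default_rng(3))
        assert a.coefficients == b.coefficients

    def test_exact_node_counts_when_requested(self):
        model = random_typed_dag(10, rng=np.random.default_rng(4),
                                 n_cnv=4, n_meth=6)
        types = list(model.table.types)
        assert types.count(NODE_GE) == 10
        assert types.count(NODE_CNV) == 4
        assert types.count(NODE_METH) == 6

    def test_cnv_coefficients_are_positive_dosage(self):
        model = random_typed_dag(10, rng=np.random.default_rng(5), n_cnv=5)
        types = model.table.types
        for (i, j), c in model.coefficients.items():
            if types[i] == NODE_CNV:
                assert c > 0
            assert abs(c) >= 0.3


class TestSimulate:
    def test_dosage_correlation_matches_closed_form(self):
        """Single edge cnv -> GE with coefficient 0.8 and unit noise:
        corr = 0.8 / sqrt(0.8^2 + 1)."""
        from omicsbn.omics_io import Node, NodeTable
        from omicsbn.synth import GroundTruthModel
        table = NodeTable([Node("G1", NODE_GE, "G1"),
                           Node("cnv_G1", NODE_CNV, "G1")])
        model = GroundTruthModel(table=table, coefficients={(1, 0): 0.8},
                                 noise_sd={0: 1.0, 1: 1.0})
        ds = simulate_multiomics(model, 5000, np.random.default_rng(6))
        r = np.corrcoef(ds.cnv["cnv_G1"], ds.ge["G1"])[0, 1]
        assert r == pytest.approx(0.8 / np.sqrt(0.8 ** 2 + 1), abs=0.02)

    def test_empty_model_columns_are_uncorrelated(self):
        model = random_typed_dag(6, edge_density=0.0,
                                 rng=np.random.default_rng(7),
                                 n_cnv=0, n_meth=0)
        ds = simulate_multiomics(model, 2000, np.random.default_rng(8))
        corr = np.corrcoef(ds.ge.to_numpy().T)
        off = corr[~np.eye(6, dtype=bool)]
        assert np.abs(off).max() < 3 / np.sqrt(2000)

    def test_beta_values_lie_in_open_unit_interval(self):
        model = random_typed_dag(5, rng=np.random.default_rng(9), n_meth=8)
        ds = simulate_multiomics(model, 100, np.random.default_rng(10))
        vals = ds.meth.to_numpy()
        assert np.all((vals > 0) & (vals < 1))


class TestCorruptPrior:
    def test_full_keep_marks_exactly_the_true_edges(self):
        model = random_typed_dag(8, edge_density=0.4,
                                 rng=np.random.default_rng(11))
        B = corrupt_prior(model, 1.0, np.random.default_rng(12))
        ones = {(int(i), int(j)) for i, j in zip(*np.nonzero(B.values == 1.0))}
        assert ones == model.ge_edges()

    def test_zero_keep_is_uniform(self):
        model = random_typed_dag(8, edge_density=0.4,
                                 rng=np.random.default_rng(13))
        B = corrupt_prior(model, 0.0, np.random.default_rng(14))
        assert np.all(B.values[B.admissible] == 0.5)

    def test_half_keep_uses_floor_convention(self):
        rng = np.random.default_rng(15)
        while True:  # draw until the skeleton has exactly 10 edges
            model = random_typed_dag(10, edge_density=0.3, rng=rng)
            if len(model.ge_edges()) == 10:
                break
        B = corrupt_prior(model, 0.5, np.random.default_rng(16))
        assert int((B.values == 1.0).sum()) == 5


class TestRocAuc:
    def _toy(self):
        universe = [("a", "b"), ("b", "a"), ("a", "c"), ("c", "a")]
        gold = {("a", "b"), ("a", "c")}
        return universe, gold

    def test_perfect_ranking_gives_auc_one(self):
        universe, gold = self._toy()
        weights = {("a", "b"): 0.9, ("a", "c"): 0.8, ("b", "a"): 0.1}
        assert roc_auc(weights, gold, universe).auc == 1.0

    def test_all_tied_gives_half(self):
        universe, gold = self._toy()
        weights = {p: 0.5 for p in universe}
        assert roc_auc(weights, gold, universe).auc == 0.5

    def test_random_weights_average_half(self):
        rng = np.random.default_rng(17)
        universe = [(f"n{i}", f"n{j}") for i in range(10) for j in range(10)
                    if i != j]
        gold = set(universe[:20])
        aucs = []
        for _ in range(1000):
            w = {p: rng.random() for p in universe}
            aucs.append(roc_auc(w, gold, universe).auc)
        assert np.mean(aucs) == pytest.approx(0.5, abs=0.02)

    def test_gold_outside_universe_is_rejected(self):
        with pytest.raises(ValueError):
            roc_auc({}, {("x", "y")}, [("a", "b"), ("b", "a")])


class TestAucCi:
    def test_z_multiplier_is_phi_inverse_0915(self):
        from scipy import stats
        lo, hi = auc_ci83(0.5, 10_000_000, 10_000_000)
        # interval symmetric and collapsing toward the point estimate
        assert hi - lo < 1e-2
        assert np.isclose(stats.norm.ppf(0.915), 1.372, atol=5e-4)

    def test_interval_symmetric_before_truncation(self):
        lo, hi = auc_ci83(0.6, 50, 200)
        assert (0.6 - lo) == pytest.approx(hi - 0.6, abs=1e-12)

    def test_truncation_to_unit_interval(self):
        lo, hi = auc_ci83(0.99, 3, 3)
        assert hi <= 1.0
        assert lo >= 0.0

    def test_overlap_decision(self):
        assert cis_overlap((0.4, 0.6), (0.55, 0.7))
        assert not cis_overlap((0.4, 0.5), (0.55, 0.7))

    def test_bootstrap_agrees_roughly_with_normal_approx(self):
        rng = np.random.default_rng(18)
        universe = [(f"n{i}", f"n{j}") for i in range(12) for j in range(12)
                    if i != j]
        gold = set(universe[:25])
        w = {p: (0.7 + 0.3 * rng.random() if p in gold else rng.random())
             for p in universe}
        res = roc_auc(w, gold, universe)
        lo_n, hi_n = auc_ci83(res.auc, res.n_pos, res.n_neg)
        lo_b, hi_b = auc_ci_bootstrap(w, gold, universe, n_boot=500,
                                      rng=np.random.default_rng(19))
        assert cis_overlap((lo_n, hi_n), (lo_b, hi_b))


class TestKappa:
    def _universe(self):
        return [(f"n{i}", f"n{j}") for i in range(10) for j in range(10)
                if i != j]

    def test_identical_sets_give_one(self):
        u = self._universe()
        s = set(u[:15])
        assert cohens_kappa(s, s, u) == 1.0

    def test_complementary_sets_are_nonpositive(self):
        u = self._universe()
        a = set(u[:45])
        b = set(u[45:])
        assert cohens_kappa(a, b, u) <= 0.0

    def test_hand_computed_two_by_two_table(self):
        # agreement table (40, 10; 20, 30): p_o = 0.7, p_e = 0.5, kappa 0.4
        u = [(f"x{k}", f"y{k}") for k in range(100)]
        a = set(u[:50])
        b = set(u[:40]) | set(u[50:70])
        kappa = cohens_kappa(a, b, u)
        assert kappa == pytest.approx(0.4, abs=1e-12)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import cohen_kappa_score
        rng = np.random.default_rng(20)
        u = self._universe()
        a = {p for p in u if rng.random() < 0.3}
        b = {p for p in u if rng.random() < 0.4}
        ours = cohens_kappa(a, b, u)
        skl = cohen_kappa_score([p in a for p in u], [p in b for p in u])
        assert ours == pytest.approx(skl, abs=1e-12)


def test_gold_standard_universe_options():
    model = random_typed_dag(6, edge_density=0.3,
                             rng=np.random.default_rng(21), n_cnv=2, n_meth=2)
    full = gold_standard(model)
    ge = gold_standard(model, ge_only=True)
    assert set(ge.universe) < set(full.universe)
    assert all(not a.startswith(("cnv_", "meth_")) for a, _ in ge.universe)
    assert ge.reference == model_ge_ids(model)


def model_ge_ids(model):
    ids = [nd.id for nd in model.table]
    return {(ids[i], ids[j]) for i, j in model.ge_edges()}
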