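"""Adaptive phases, empirical-knowledge counts, convergence diagnostics."""

import numpy as np
import pytest

from omicsbn.config import Config, McmcConfig
from omicsbn.engine import (ChainState, ChainTrace, EmpiricalCounts, Sampler,
                            c_rms_series, convergence_stop, merge_prior,
                            phase1_adapt, phase2_estimate, propose_beta,
                            run_inference, run_transient, sampling_phase,
                            transient_check, update_counts)
from omicsbn.prior import (PriorKnowledgeMatrix, PROV_DATABASE,
                           PROV_EMPIRICAL, PROV_UNKNOWN)
from omicsbn.structure import NetworkStructure

from conftest import make_ge_table, standardise


def make_sampler(n=3, m=30, seed=5, **mcmc_kw):
    table = make_ge_table(n)
    rng = np.random.default_rng(seed)
    X = standardise(rng.standard_normal((m, n)))
    B = PriorKnowledgeMatrix(table)
    return Sampler(X, B, mcmc=McmcConfig(**mcmc_kw))


class TestProposeBeta:
    def test_tiny_sigma_stays_at_current_value(self):
        st = ChainState(structure=None, beta=2.0, sigma=1e-12, log_score=0,
                        energy=0, log_z=0)
        assert propose_beta(st, np.random.default_rng(0)) == pytest.approx(2.0)

    def test_moments_match_gaussian(self):
        st = ChainState(structure=None, beta=3.0, sigma=1.5, log_score=0,
                        energy=0, log_z=0)
        rng = np.random.default_rng(1)
        draws = np.array([propose_beta(st, rng) for _ in range(10_000)])
        se_mean = 1.5 / np.sqrt(draws.size)
        assert abs(draws.mean() - 3.0) < 3 * se_mean
        assert abs(draws.std() - 1.5) < 3 * 1.5 / np.sqrt(2 * draws.size)

    def test_candidate_below_support_rejected_without_evaluation(self):
        sam = make_sampler()
        rng = np.random.default_rng(2)
        st = sam.fresh_state(rng)
        st.beta = 0.5
        st.sigma = 1e9  # nearly every candidate lands outside the support
        sam.refresh_state(st)
        rejected = sum(not sam.beta_step(st, rng) for _ in range(50))
        assert rejected >= 49
        assert st.beta == 0.5 or 0.5 <= st.beta <= sam.mcmc.beta_max


class TestPhase1:
    def test_acceptance_enters_band_on_small_problem(self):
        for seed in range(10):
            sam = make_sampler(n=5, m=40, seed=seed)
            rng = np.random.default_rng(100 + seed)
            st = sam.fresh_state(rng)
            info = phase1_adapt(sam, st, rng)
            assert info["in_band"], f"seed {seed} never reached the band"
            assert info["batches"] <= 20

    def test_sigma_decreases_when_acceptance_below_band(self):
        sam = make_sampler(n=3, adapt1_iterations=100)
        rng = np.random.default_rng(3)
        st = sam.fresh_state(rng)
        st.sigma = 1e6  # everything proposed leaves the support
        sigma0 = st.sigma
        phase1_adapt(sam, st, rng)
        assert st.sigma < sigma0


class TestTransientCheck:
    def test_climbing_trace_is_not_stationary(self):
        trace = list(np.linspace(0, 100, 200) +
                     np.random.default_rng(0).normal(0, 0.5, 200))
        assert not transient_check(trace, window=100)

    def test_constant_trace_is_stationary(self):
        assert transient_check([3.14] * 200, window=100)

    def test_iid_trace_passes_about_95_percent(self):
        rng = np.random.default_rng(4)
        passes = sum(
            transient_check(list(rng.standard_normal(200)), window=100)
            for _ in range(400))
        assert passes / 400 == pytest.approx(0.95, abs=0.03)


class TestUpdateCounts:
    def test_add_accepted(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("add", 0, 1), True)
        assert (c.f[0, 1], c.a[0, 1]) == (1, 1)

    def test_add_rejected(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("add", 0, 1), False)
        assert (c.f[0, 1], c.a[0, 1]) == (1, 0)

    def test_delete_accepted(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("delete", 0, 1), True)
        assert (c.f[0, 1], c.a[0, 1]) == (1, 0)

    def test_delete_rejected_counts_as_evidence_for_edge(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("delete", 0, 1), False)
        assert (c.f[0, 1], c.a[0, 1]) == (1, 1)

    def test_reverse_accepted_credits_opposite_direction(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("reverse", 0, 1), True)
        assert (c.f[0, 1], c.f[1, 0]) == (1, 1)
        assert (c.a[0, 1], c.a[1, 0]) == (0, 1)

    def test_reverse_rejected_credits_current_direction(self):
        c = EmpiricalCounts.zeros(3)
        update_counts(c, ("reverse", 0, 1), False)
        assert (c.f[0, 1], c.f[1, 0]) == (1, 1)
        assert (c.a[0, 1], c.a[1, 0]) == (1, 0)

    def test_mbr_moves_are_not_counted(self):
        c = EmpiricalCounts.zeros(3)
        with pytest.raises(ValueError):
            update_counts(c, ("mbr", 0, 0), True)

    def test_b_hat_arithmetic(self):
        c = EmpiricalCounts.zeros(2)
        c.f[0, 1] = 4
        c.a[0, 1] = 3
        bh = c.b_hat()
        assert bh[0, 1] == 0.75
        assert bh[1, 0] == 0.5  # never proposed -> no evidence


class TestPhase2:
    def test_counts_stay_consistent_and_beta_estimated(self):
        sam = make_sampler(n=4, m=50, adapt2_iterations=500)
        rng = np.random.default_rng(6)
        st = sam.fresh_state(rng)
        counts, beta_est, b_hat, info = phase2_estimate(sam, st, rng)
        assert np.all(counts.a <= counts.f)
        assert sam.mcmc.beta_min <= beta_est <= sam.mcmc.beta_max
        assert np.all((b_hat >= 0) & (b_hat <= 1))

    def test_directionality_on_collider_data(self):
        """Strong compelled edges G1 -> G3 <- G2: the acceptance-ratio
        estimate must favour the true direction in >= 9/10 seeds."""
        wins = 0
        for seed in range(10):
            rng = np.random.default_rng(200 + seed)
            m = 200
            x1 = rng.standard_normal(m)
            x2 = rng.standard_normal(m)
            x3 = 0.9 * x1 + 0.9 * x2 + rng.standard_normal(m)
            X = standardise(np.column_stack([x1, x2, x3]))
            B = PriorKnowledgeMatrix(make_ge_table(3))
            sam = Sampler(X, B, mcmc=McmcConfig(adapt2_iterations=2000))
            st = sam.fresh_state(rng)
            phase1_adapt(sam, st, rng)
            counts, _, b_hat, _ = phase2_estimate(sam, st, rng)
            if b_hat[0, 2] > 0.5 > b_hat[2, 0]:
                wins += 1
        assert wins >= 9


class TestMergePrior:
    def _setup(self):
        B = PriorKnowledgeMatrix(make_ge_table(3))
        B.set_entry(0, 1, 1.0, PROV_DATABASE)
        b_hat = np.full((3, 3), 0.8)
        f = np.ones((3, 3))
        return B, b_hat, f

    def test_curated_knowledge_takes_precedence(self):
        B, b_hat, f = self._setup()
        merged = merge_prior(B, b_hat, f)
        assert merged.values[0, 1] == 1.0
        assert merged.provenance[0, 1] == PROV_DATABASE

    def test_unknown_entries_become_empirical(self):
        B, b_hat, f = self._setup()
        merged = merge_prior(B, b_hat, f)
        assert merged.values[1, 2] == 0.8
        assert merged.provenance[1, 2] == PROV_EMPIRICAL

    def test_unproposed_pairs_keep_half(self):
        B, b_hat, f = self._setup()
        f[1, 2] = 0
        merged = merge_prior(B, b_hat, f)
        assert merged.values[1, 2] == 0.5
        assert merged.provenance[1, 2] == PROV_UNKNOWN


class TestSamplingPhase:
    def test_snapshot_arithmetic(self):
        """iterations / thin snapshots in total, the post-burn-in ones
        being (iterations - burn_in) / thin."""
        sam = make_sampler(n=3, sampling_iterations=2000, burn_in=1000,
                           thin=100)
        rng = np.random.default_rng(7)
        st = sam.fresh_state(rng)
        st.beta = 1.0
        sam.refresh_state(st)
        _, trace = sampling_phase(sam, st, rng)
        assert len(trace.snapshots) == 20
        assert len(trace.post_burn_snapshots()) == 10

    def test_kept_path_endpoint_is_the_recorded_state(self):
        """The state returned at the end of a horizon is the recorded
        winning path's endpoint (its log posterior closes the trace)."""
        sam = make_sampler(n=4, sampling_iterations=500, horizon=500,
                           n_paths=3)
        rng = np.random.default_rng(8)
        st = sam.fresh_state(rng)
        st.beta = 1.0
        sam.refresh_state(st)
        end, trace = sampling_phase(sam, st, rng)
        assert trace.log_posterior[-1] == pytest.approx(end.log_posterior())
        sam.check_consistency(end)  # cached score matches recomputation

    def test_single_path_matches_plain_mh_posterior(self, dags3):
        """n_paths = 1 reduces the phase to plain MH: 3-node edge
        posteriors still match exhaustive enumeration within 0.03."""
        from omicsbn.prior import graph_energy

        table = make_ge_table(3)
        rng = np.random.default_rng(10)
        X = standardise(rng.standard_normal((25, 3)))
        B = PriorKnowledgeMatrix(table)
        sam = Sampler(X, B, mcmc=McmcConfig(
            sampling_iterations=40_000, burn_in=0, thin=10, n_paths=1,
            horizon=500))
        beta = 1.0
        lp = np.array([sam.scorer.graph_score(ps)
                       - beta * graph_energy(ps, B) for ps in dags3])
        w = np.exp(lp - lp.max())
        w /= w.sum()
        exact = np.zeros((3, 3))
        for ps, wt in zip(dags3, w):
            for j, pa in enumerate(ps):
                for i in pa:
                    exact[i, j] += wt
        st = sam.fresh_state(rng)
        st.beta = beta
        sam.refresh_state(st)
        _, trace = sampling_phase(sam, st, rng)
        freq = np.zeros((3, 3))
        snaps = [ps for _, ps in trace.snapshots]
        for ps in snaps:
            for j, pa in enumerate(ps):
                for i in pa:
                    freq[i, j] += 1
        freq /= len(snaps)
        assert np.abs(freq - exact).max() < 0.03


class TestCrms:
    def _trace_from(self, snapshots, burn_in=0):
        t = ChainTrace(thin=1, burn_in=burn_in, beta=1.0)
        t.snapshots = [(k, ps) for k, ps in enumerate(snapshots)]
        t.log_posterior = [0.0] * len(snapshots)
        return t

    def test_identical_chains_give_zeros(self):
        ps = tuple([frozenset(), frozenset({0}), frozenset()])
        a = self._trace_from([ps] * 5)
        b = self._trace_from([ps] * 5)
        adm = ~np.eye(3, dtype=bool)
        crms = c_rms_series(a, b, 3, adm)
        np.testing.assert_allclose(crms, 0.0)

    def test_constant_frequency_offset_has_closed_form(self):
        # chain A always has the edge, chain B never: each of the two
        # ordered pairs (undirected evidence) differs by 1, rest equal
        with_edge = tuple([frozenset(), frozenset({0}), frozenset()])
        empty = tuple([frozenset(), frozenset(), frozenset()])
        a = self._trace_from([with_edge] * 4)
        b = self._trace_from([empty] * 4)
        adm = ~np.eye(3, dtype=bool)
        crms = c_rms_series(a, b, 3, adm)
        np.testing.assert_allclose(crms, np.sqrt(2.0 / 6.0))

    def test_symmetry(self):
        rng = np.random.default_rng(11)
        snapsA, snapsB = [], []
        for _ in range(6):
            ps = [frozenset(), frozenset(), frozenset()]
            if rng.random() < 0.5:
                ps[1] = frozenset({0})
            snapsA.append(tuple(ps))
            ps2 = [frozenset(), frozenset(), frozenset({1})]
            snapsB.append(tuple(ps2))
        a, b = self._trace_from(snapsA), self._trace_from(snapsB)
        adm = ~np.eye(3, dtype=bool)
        np.testing.assert_allclose(c_rms_series(a, b, 3, adm),
                                   c_rms_series(b, a, 3, adm))


class TestConvergenceStop:
    def test_constant_series_fails_strict_threshold(self):
        # all successive differences are 0 => threshold 0; strict < fails
        assert not convergence_stop(np.full(200, 0.2))

    def test_plateau_after_decay_stops(self):
        # plateau level must fall below the Q3 of successive differences
        # (~the decay step size) for the rule to fire
        rng = np.random.default_rng(12)
        decay = np.linspace(0.5, 0.002, 100)
        plateau = 0.001 + rng.normal(0, 1e-5, 120)
        assert convergence_stop(np.concatenate([decay, plateau]))

    def test_large_oscillation_continues(self):
        vals = 0.2 + 0.1 * (-1.0) ** np.arange(300)
        assert not convergence_stop(vals)

    def test_short_series_never_stops(self):
        assert not convergence_stop(np.zeros(50))


def test_full_run_is_deterministic_given_seed():
    from omicsbn.synth import random_typed_dag, simulate_multiomics

    rng = np.random.default_rng(13)
    model = random_typed_dag(4, edge_density=0.3, rng=rng, n_cnv=1, n_meth=0)
    ds = simulate_multiomics(model, 40, rng)
    cfg = Config()
    cfg.mcmc.sampling_iterations = 1000
    cfg.mcmc.burn_in = 500
    cfg.mcmc.thin = 50
    cfg.mcmc.adapt1_iterations = 300
    cfg.mcmc.adapt2_iterations = 300
    cfg.mcmc.transient_max_windows = 3
    cfg.mcmc.max_extensions = 0
    r1 = run_inference(ds, config=cfg, seed=21)
    r2 = run_inference(ds, config=cfg, seed=21)
    assert r1.beta == r2.beta
    for t1, t2 in zip(r1.traces, r2.traces):
        assert t1.snapshots == t2.snapshots
        assert t1.log_posterior == t2.log_posterior
    np.testing.assert_array_equal(r1.b_hat, r2.b_hat)


def test_beta_rises_when_prior_matches_the_data():
    """Evidence weighting: with the generating DAG encoded as the B = 1
    skeleton, the post-transient mean beta exceeds the one obtained
    under a source-permuted (mismatched) B in most seeds."""
    from omicsbn.prior import PROV_DATABASE
    from omicsbn.synth import random_typed_dag, simulate_multiomics

    wins = 0
    n_seeds = 10
    for seed in range(n_seeds):
        rng = np.random.default_rng(400 + seed)
        model = random_typed_dag(10, edge_density=0.25, rng=rng,
                                 n_cnv=0, n_meth=0)
        ds = simulate_multiomics(model, 100, rng)
        X = standardise(ds.ge.to_numpy())
        table = make_ge_table(10)
        edges = sorted(model.ge_edges())
        perm = rng.permutation(10)
        betas = {}
        for label, edge_set in (
                ("true", edges),
                ("permuted", [(int(perm[i]), j) for i, j in edges])):
            B = PriorKnowledgeMatrix(table)
            for i, j in edge_set:
                if i != j and B.admissible[i, j]:
                    B.set_entry(i, j, 1.0, PROV_DATABASE)
            sam = Sampler(X, B, mcmc=McmcConfig(
                adapt1_iterations=600, adapt2_iterations=1500,
                transient_max_windows=4, transient_window=250))
            rng_run = np.random.default_rng(1000 + seed)
            st = sam.fresh_state(rng_run)
            phase1_adapt(sam, st, rng_run)
            run_transient(sam, st, rng_run)
            _, beta_est, _, _ = phase2_estimate(sam, st, rng_run)
            betas[label] = beta_est
        wins += betas["true"] > betas["permuted"]
    assert wins >= 9


def test_forbidden_prior_with_strong_beta_empties_the_graph():
    """All-zero B at large fixed beta: the modal sampled structure is the
    empty graph when the data signal is weak."""
    table = make_ge_table(3)
    rng = np.random.default_rng(14)
    X = standardise(rng.standard_normal((15, 3)))
    B = PriorKnowledgeMatrix(table)
    from omicsbn.prior import PROV_FORBIDDEN
    B.values[B.admissible] = 0.0
    B.provenance[B.admissible] = PROV_FORBIDDEN
    sam = Sampler(X, B, mcmc=McmcConfig(sampling_iterations=3000, burn_in=0,
                                        thin=10))
    st = sam.fresh_state(rng)
    st.beta = 10.0
    sam.refresh_state(st)
    _, trace = sampling_phase(sam, st, rng)
    empty = tuple([frozenset()] * 3)
    from collections import Counter
    modal = Counter(ps for _, ps in trace.snapshots).most_common(1)[0][0]
    assert modal == empty
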