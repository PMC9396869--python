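"""Four-phase adaptive MCMC simulation.

The simulation proceeds through: (1) a rough adaptation phase that tunes
the spread of the Gaussian proposal for the prior-strength parameter
beta; (2) a transient phase that waits for the log-posterior trace to
stabilise; (3) a second adaptive phase that fine-tunes the proposal,
estimates beta, and accumulates per-ordered-pair proposal/acceptance
counts from which the *empirical* knowledge matrix B-hat = a/f is
derived; and (4) a sampling phase at fixed beta in which two independent
chains draw structures with a greedy horizon (best of three short
segments every 500 iterations), thinned and burn-in-discarded, until the
between-chain c_rms convergence rule is satisfied.

Empirical-knowledge bookkeeping (single-edge proposals only):

    add i->j:     f_ij += 1;  accepted  => a_ij += 1
    delete i->j:  f_ij += 1;  rejected  => a_ij += 1
    reverse i->j: f_ij += 1 and f_ji += 1;
                  accepted => a_ji += 1, rejected => a_ij += 1

i.e. evidence *for* the edge accrues when an add is accepted or a
delete/reverse is refused, and a reverse doubles as a delete of i->j
plus an add of j->i.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .bge import BgeHyperparams, BgeScorer, ScoreCache
from .config import Config, McmcConfig
from .omics_io import OmicsDataset, assemble_data_matrix, build_node_table, \
    screen_meth_probes
from .prior import (ConstraintSet, PriorKnowledgeMatrix, PROV_EMPIRICAL,
                    PROV_UNKNOWN, energy_edge_delta, graph_energy,
                    local_energy, log_partition_upper)
from .proposals import (ParentSetSpace, accept_structure, mbr_propose,
                        propose_single_edge)
from .structure import NetworkStructure
from .summary import cpdag_indicator, dag_to_cpdag

logger = logging.getLogger(__name__)


# ------------------------------------------------------------------
# empirical-knowledge counts (Markov-chain acceptance statistics)
# ------------------------------------------------------------------

@dataclass
class EmpiricalCounts:
    """Per-ordered-pair proposal frequency f and acceptance evidence a."""

    f: np.ndarray
    a: np.ndarray

    @classmethod
    def zeros(cls, n_nodes: int) -> "EmpiricalCounts":
        return cls(f=np.zeros((n_nodes, n_nodes)),
                   a=np.zeros((n_nodes, n_nodes)))

    def b_hat(self) -> np.ndarray:
        """a/f where proposed at least once, 0.5 (no evidence) elsewhere."""
        with np.errstate(invalid="ignore", divide="ignore"):
            out = np.where(self.f > 0, self.a / np.maximum(self.f, 1e-300), 0.5)
        return out

    def validate(self) -> None:
        if np.any(self.a > self.f):
            raise ValueError("acceptance count exceeds proposal count")


def update_counts(counts: EmpiricalCounts, move: tuple[str, int, int],
                  accepted: bool) -> EmpiricalCounts:
    """Apply the bookkeeping rules for one single-edge proposal."""
    kind, i, j = move
    if kind == "add":
        counts.f[i, j] += 1
        if accepted:
            counts.a[i, j] += 1
    elif kind == "delete":
        counts.f[i, j] += 1
        if not accepted:
            counts.a[i, j] += 1
    elif kind == "reverse":
        counts.f[i, j] += 1
        counts.f[j, i] += 1
        if accepted:
            counts.a[j, i] += 1
        else:
            counts.a[i, j] += 1
    else:
        raise ValueError(f"counts are only defined for single-edge moves, "
                         f"got {kind!r}")
    return counts


# ------------------------------------------------------------------
# chain state and trace
# ------------------------------------------------------------------

@dataclass
class ChainState:
    """Current structure, prior strength and cached target components."""

    structure: NetworkStructure
    beta: float
    sigma: float
    log_score: float
    energy: float
    log_z: float
    iteration: int = 0
    phase: str = "adapt1"

    def log_posterior(self) -> float:
        return self.log_score - self.beta * self.energy - self.log_z

    def copy(self) -> "ChainState":
        return ChainState(structure=self.structure.copy(), beta=self.beta,
                          sigma=self.sigma, log_score=self.log_score,
                          energy=self.energy, log_z=self.log_z,
                          iteration=self.iteration, phase=self.phase)


@dataclass
class ChainTrace:
    """Thinned structure snapshots and per-iteration diagnostics."""

    thin: int
    burn_in: int
    beta: float
    snapshots: list[tuple[int, tuple[frozenset, ...]]] = field(default_factory=list)
    log_posterior: list[float] = field(default_factory=list)
    acceptance: dict[str, float] = field(default_factory=dict)

    @property
    def n_iterations(self) -> int:
        return len(self.log_posterior)

    def post_burn_snapshots(self) -> list[tuple[frozenset, ...]]:
        return [ps for it, ps in self.snapshots if it >= self.burn_in]


# ------------------------------------------------------------------
# the sampler
# ------------------------------------------------------------------

class Sampler:
    """Bundles data scoring, the structure prior and the move kernels."""

    def __init__(self, data: np.ndarray, B: PriorKnowledgeMatrix,
                 constraints: ConstraintSet | None = None,
                 hyper: BgeHyperparams | None = None,
                 mcmc: McmcConfig | None = None):
        self.B = B
        self.table = B.table
        self.constraints = constraints if constraints is not None else ConstraintSet()
        self.mcmc = mcmc if mcmc is not None else McmcConfig()
        self.scorer = BgeScorer(data, hyper, ScoreCache())
        self.spaces: dict[int, ParentSetSpace] = {}
        self.debug = False

    # -- state management -------------------------------------------
    def fresh_state(self, rng: np.random.Generator) -> ChainState:
        """Empty structure; beta drawn from U[0, 10] then clamped >= 0.5."""
        G = NetworkStructure(self.table, self.constraints)
        beta = max(float(rng.uniform(0.0, self.mcmc.beta_init_upper)),
                   self.mcmc.beta_min)
        return self._make_state(G, beta, self.mcmc.sigma_init)

    def _make_state(self, G: NetworkStructure, beta: float,
                    sigma: float) -> ChainState:
        return ChainState(
            structure=G, beta=beta, sigma=sigma,
            log_score=self.scorer.graph_score(G.parent_sets),
            energy=graph_energy(G.parent_sets, self.B),
            log_z=log_partition_upper(beta, self.B, self.constraints))

    def refresh_state(self, state: ChainState) -> None:
        """Recompute cached target components (after a prior swap)."""
        state.log_score = self.scorer.graph_score(state.structure.parent_sets)
        state.energy = graph_energy(state.structure.parent_sets, self.B)
        state.log_z = log_partition_upper(state.beta, self.B, self.constraints)

    def check_consistency(self, state: ChainState, atol: float = 1e-8) -> None:
        expect = self.scorer.graph_score(state.structure.parent_sets)
        if abs(expect - state.log_score) > atol:
            raise AssertionError("cached log score drifted from recomputation")
        expect_e = graph_energy(state.structure.parent_sets, self.B)
        if abs(expect_e - state.energy) > atol:
            raise AssertionError("cached energy drifted from recomputation")

    # -- structure kernel -------------------------------------------
    def structure_step(self, state: ChainState, rng: np.random.Generator,
                       counts: EmpiricalCounts | None = None
                       ) -> tuple[bool, object]:
        """One MH structure move: MBR with probability p_mbr, else a
        uniform single-edge move.  Returns (accepted, move record)."""
        if rng.random() < self.mcmc.p_mbr:
            return self._mbr_step(state, rng)
        prop = propose_single_edge(state.structure, rng, self.constraints)
        kind, i, j = prop.move
        pa_j = state.structure.parent_sets[j]
        sc = self.scorer
        if kind == "add":
            d_score = sc.node_score(j, pa_j | {i}) - sc.node_score(j, pa_j)
            d_energy = energy_edge_delta(i, j, self.B)
        elif kind == "delete":
            d_score = sc.node_score(j, pa_j - {i}) - sc.node_score(j, pa_j)
            d_energy = -energy_edge_delta(i, j, self.B)
        else:  # reverse
            pa_i = state.structure.parent_sets[i]
            d_score = (sc.node_score(j, pa_j - {i}) - sc.node_score(j, pa_j)
                       + sc.node_score(i, pa_i | {j}) - sc.node_score(i, pa_i))
            d_energy = (-energy_edge_delta(i, j, self.B)
                        + energy_edge_delta(j, i, self.B))
        accepted = accept_structure(d_score, -state.beta * d_energy,
                                    prop.log_proposal_ratio, rng)
        if accepted:
            state.structure = prop.candidate
            state.log_score += d_score
            state.energy += d_energy
        if counts is not None:
            update_counts(counts, prop.move, accepted)
        if self.debug:
            self.check_consistency(state)
        return accepted, prop.move

    def _mbr_step(self, state: ChainState,
                  rng: np.random.Generator) -> tuple[bool, object]:
        prop = mbr_propose(state.structure, self.scorer, rng, self.spaces)
        old = state.structure.parent_sets
        new = prop.candidate.parent_sets
        d_score = 0.0
        d_energy = 0.0
        for v in range(len(old)):
            if old[v] != new[v]:
                d_score += (self.scorer.node_score(v, new[v])
                            - self.scorer.node_score(v, old[v]))
                d_energy += (local_energy(v, new[v], self.B)
                             - local_energy(v, old[v], self.B))
        accepted = accept_structure(d_score, -state.beta * d_energy,
                                    prop.log_proposal_ratio, rng)
        if accepted:
            state.structure = prop.candidate
            state.log_score += d_score
            state.energy += d_energy
        if self.debug:
            self.check_consistency(state)
        return accepted, prop.move

    # -- beta kernel -------------------------------------------------
    def beta_step(self, state: ChainState,
                  rng: np.random.Generator) -> bool:
        """One MH move on beta at fixed structure.

        The hyperprior on beta is uniform on [beta_min, beta_max] (the
        initialisation range): candidates outside the support are
        rejected without evaluating the ratio.  Without the upper bound
        beta performs a free upward random walk whenever the structure
        realises every high-B edge, because the prior ratio then
        saturates at 1.
        """
        cand = propose_beta(state, rng)
        if cand < self.mcmc.beta_min or cand > self.mcmc.beta_max:
            return False
        log_z_cand = log_partition_upper(cand, self.B, self.constraints)
        log_ratio = (-(cand - state.beta) * state.energy
                     - (log_z_cand - state.log_z))
        if log_ratio >= 0 or rng.random() < np.exp(log_ratio):
            state.beta = cand
            state.log_z = log_z_cand
            return True
        return False


def propose_beta(state: ChainState, rng: np.random.Generator) -> float:
    """Gaussian perturbation beta_c ~ N(beta_s, sigma_s^2)."""
    return float(state.beta + state.sigma * rng.standard_normal())


# ------------------------------------------------------------------
# phases
# ------------------------------------------------------------------

def phase1_adapt(sampler: Sampler, state: ChainState,
                 rng: np.random.Generator) -> dict:
    """Rough tuning of the beta proposal spread.

    Batches of structure + beta moves; after each batch of beta moves the
    proposal s.d. is scaled by exp(+-step) until the realised beta
    acceptance rate enters the target band.
    """
    cfg = sampler.mcmc
    state.phase = "adapt1"
    max_batches = max(1, cfg.adapt1_iterations // cfg.adapt1_batch)
    info = {"batches": 0, "beta_acceptance": float("nan"), "in_band": False}
    for batch in range(max_batches):
        acc = 0
        for _ in range(cfg.adapt1_batch):
            sampler.structure_step(state, rng)
            acc += sampler.beta_step(state, rng)
            state.iteration += 1
        rate = acc / cfg.adapt1_batch
        info["batches"] = batch + 1
        info["beta_acceptance"] = rate
        if cfg.accept_low <= rate <= cfg.accept_high:
            info["in_band"] = True
            break
        if rate < cfg.accept_low:
            state.sigma *= np.exp(-cfg.sigma_step)
        else:
            state.sigma *= np.exp(cfg.sigma_step)
    if not info["in_band"]:
        logger.warning("phase 1 ended outside the target acceptance band "
                       "(rate %.2f)", info["beta_acceptance"])
    return info


def transient_check(trace: list[float], window: int) -> bool:
    """Geweke-style stationarity check on the log-posterior trace.

    Compares the means of the last two non-overlapping windows with a
    two-sample z statistic; stationary when |z| < 1.96.
    """
    if len(trace) < 2 * window:
        raise ValueError("need at least two full windows of history")
    w1 = np.asarray(trace[-2 * window:-window])
    w2 = np.asarray(trace[-window:])
    se = np.sqrt(w1.var(ddof=1) / window + w2.var(ddof=1) / window)
    if se == 0.0:
        return bool(w1.mean() == w2.mean())
    return bool(abs(w1.mean() - w2.mean()) / se < 1.96)


def run_transient(sampler: Sampler, state: ChainState,
                  rng: np.random.Generator) -> dict:
    """Run until the chain appears to have reached the target's mode."""
    cfg = sampler.mcmc
    state.phase = "transient"
    trace: list[float] = []
    windows = 0
    passed = False
    while windows < cfg.transient_max_windows:
        for _ in range(cfg.transient_window):
            sampler.structure_step(state, rng)
            sampler.beta_step(state, rng)
            state.iteration += 1
            trace.append(state.log_posterior())
        windows += 1
        if windows >= 2 and transient_check(trace, cfg.transient_window):
            passed = True
            break
    if not passed:
        logger.warning("transient phase hit the window cap without passing "
                       "the stationarity check")
    return {"windows": windows, "passed": passed, "trace": trace}


def phase2_estimate(sampler: Sampler, state: ChainState,
                    rng: np.random.Generator,
                    counts: EmpiricalCounts | None = None
                    ) -> tuple[EmpiricalCounts, float, np.ndarray, dict]:
    """Fine tuning, beta estimation and empirical-knowledge accumulation.

    Every conventional single-edge proposal updates the (f, a) counts;
    MBR moves do not.  Returns the counts, the beta point estimate (mean
    of the phase's beta samples), the B-hat matrix and an info dict.
    """
    cfg = sampler.mcmc
    state.phase = "adapt2"
    if counts is None:
        counts = EmpiricalCounts.zeros(len(sampler.table))
    beta_samples = []
    acc_batch = 0
    n_beta = 0
    acc_total = 0
    for it in range(cfg.adapt2_iterations):
        sampler.structure_step(state, rng, counts=counts)
        accepted = sampler.beta_step(state, rng)
        acc_batch += accepted
        acc_total += accepted
        n_beta += 1
        state.iteration += 1
        beta_samples.append(state.beta)
        if (it + 1) % cfg.adapt1_batch == 0:
            rate = acc_batch / cfg.adapt1_batch
            if rate < cfg.accept_low:
                state.sigma *= np.exp(-cfg.sigma_step_fine)
            elif rate > cfg.accept_high:
                state.sigma *= np.exp(cfg.sigma_step_fine)
            acc_batch = 0
    counts.validate()
    beta_est = float(np.mean(beta_samples))
    info = {"beta_estimate": beta_est,
            "beta_acceptance": acc_total / max(n_beta, 1),
            "sigma": state.sigma}
    return counts, beta_est, counts.b_hat(), info


def merge_prior(B: PriorKnowledgeMatrix, b_hat: np.ndarray,
                f: np.ndarray) -> PriorKnowledgeMatrix:
    """Replace "no knowledge" (0.5) entries by the empirical estimate.

    Curated entries (database, TF/target, forbidden) are kept verbatim;
    pairs never proposed retain 0.5.
    """
    merged = B.copy()
    mask = (merged.admissible & (merged.provenance == PROV_UNKNOWN)
            & (f > 0))
    merged.values[mask] = b_hat[mask]
    merged.provenance[mask] = PROV_EMPIRICAL
    merged.validate()
    return merged


def sampling_phase(sampler: Sampler, state: ChainState,
                   rng: np.random.Generator, n_iterations: int | None = None,
                   trace: ChainTrace | None = None
                   ) -> tuple[ChainState, ChainTrace]:
    """Greedy-horizon sampling at fixed beta.

    Every horizon, three independent segments are run from the current
    state with the full move kernel (single-edge + MBR); the endpoint
    with the highest log posterior is kept and its trajectory recorded.
    Structures are thinned every ``thin`` iterations; iterations below
    ``burn_in`` are flagged as burn-in.  Passing an existing trace
    extends the chain (used by the convergence-driven extension).
    """
    cfg = sampler.mcmc
    state.phase = "sampling"
    if n_iterations is None:
        n_iterations = cfg.sampling_iterations
    if trace is None:
        trace = ChainTrace(thin=cfg.thin, burn_in=cfg.burn_in, beta=state.beta)
    t0 = trace.n_iterations
    done = 0
    accepted_total = 0
    while done < n_iterations:
        h = min(cfg.horizon, n_iterations - done)
        best = None
        for _ in range(cfg.n_paths):
            ps = state.copy()
            lp_path: list[float] = []
            snaps: list[tuple[int, tuple[frozenset, ...]]] = []
            acc = 0
            for k in range(h):
                t = t0 + done + k
                a, _ = sampler.structure_step(ps, rng)
                acc += a
                lp_path.append(ps.log_posterior())
                if (t + 1) % cfg.thin == 0:
                    snaps.append((t, tuple(ps.structure.parent_sets)))
            if best is None or lp_path[-1] > best[1][-1]:
                best = (ps, lp_path, snaps, acc)
        state = best[0]
        trace.log_posterior.extend(best[1])
        trace.snapshots.extend(best[2])
        accepted_total += best[3]
        done += h
    state.iteration += n_iterations
    trace.acceptance["sampling"] = accepted_total / max(n_iterations, 1)
    return state, trace


# ------------------------------------------------------------------
# convergence diagnostics
# ------------------------------------------------------------------

def _running_edge_freq(snapshots: list[tuple[frozenset, ...]],
                       n_nodes: int) -> np.ndarray:
    """K x N x N running relative edge frequencies of CPDAG snapshots."""
    out = np.zeros((len(snapshots), n_nodes, n_nodes))
    acc = np.zeros((n_nodes, n_nodes))
    for k, ps in enumerate(snapshots):
        acc += cpdag_indicator(dag_to_cpdag(ps), n_nodes)
        out[k] = acc / (k + 1)
    return out


def c_rms_series(trace_a: ChainTrace, trace_b: ChainTrace,
                 n_nodes: int, admissible: np.ndarray) -> np.ndarray:
    """Between-chain cumulative RMS discrepancy of edge frequencies.

    At thinned index k the running CPDAG edge frequencies of each chain
    (over its first k post-burn-in snapshots) are compared over all
    admissible directed pairs.
    """
    snaps_a = trace_a.post_burn_snapshots()
    snaps_b = trace_b.post_burn_snapshots()
    k = min(len(snaps_a), len(snaps_b))
    if k == 0:
        return np.zeros(0)
    pa = _running_edge_freq(snaps_a[:k], n_nodes)
    pb = _running_edge_freq(snaps_b[:k], n_nodes)
    diff2 = (pa - pb) ** 2
    return np.sqrt(diff2[:, admissible].mean(axis=1))


def convergence_stop(c_rms_values: np.ndarray, tail: int = 100) -> bool:
    """Stopping rule on the c_rms series.

    The threshold is the third quartile of successive absolute
    differences; the simulation stops when each of the last ``tail``
    values lies strictly below it.
    """
    values = np.asarray(c_rms_values, dtype=float)
    if values.size < tail + 1:
        return False
    diffs = np.abs(np.diff(values))
    threshold = float(np.quantile(diffs, 0.75))
    return bool(np.all(values[-tail:] < threshold))


# ------------------------------------------------------------------
# end-to-end driver
# ------------------------------------------------------------------

@dataclass
class InferenceResult:
    """Everything produced by a full run, plus provenance."""

    traces: tuple[ChainTrace, ChainTrace]
    merged_prior: PriorKnowledgeMatrix
    beta: float
    counts: EmpiricalCounts
    b_hat: np.ndarray
    table: object
    run_log: dict

    def pooled_cpdags(self):
        """Per-chain post-burn-in CPDAGs, deduplicated, then pooled."""
        from .summary import dedup_cpdags
        pooled = []
        for trace in self.traces:
            cpdags = [dag_to_cpdag(ps) for ps in trace.post_burn_snapshots()]
            pooled.extend(dedup_cpdags(cpdags))
        return pooled

    def edge_weights(self):
        from .summary import edge_weights
        return edge_weights(self.pooled_cpdags(), len(self.table))


def _resolve_prior(prior, table) -> PriorKnowledgeMatrix:
    from .prior import load_prior
    if prior is None:
        return PriorKnowledgeMatrix(table)
    if isinstance(prior, PriorKnowledgeMatrix):
        if prior.table is table or [n.id for n in prior.table] == \
                [n.id for n in table]:
            return prior
        # remap by node id: probe screening may have altered the node set
        remapped = PriorKnowledgeMatrix(table)
        old_index = prior.table.index
        for i, j in zip(*np.nonzero(remapped.admissible)):
            oi = old_index.get(table.nodes[i].id)
            oj = old_index.get(table.nodes[j].id)
            if oi is not None and oj is not None and prior.admissible[oi, oj]:
                remapped.values[i, j] = prior.values[oi, oj]
                remapped.provenance[i, j] = prior.provenance[oi, oj]
        remapped.validate()
        return remapped
    if isinstance(prior, (str, bytes)) or hasattr(prior, "__fspath__"):
        return load_prior(prior, table)
    raise TypeError("prior must be None, a PriorKnowledgeMatrix or a path")


def run_inference(dataset: OmicsDataset, prior=None,
                  config: Config | None = None, seed: int = 0,
                  constraints: ConstraintSet | None = None
                  ) -> InferenceResult:
    """Full pipeline: probe screening, adaptive phases, two sampling
    chains with convergence-driven extension.

    ``prior`` may be None (uniform "no knowledge"), a
    PriorKnowledgeMatrix over the same node set, or a path to a prior
    file.  All randomness derives from ``seed``.
    """
    if config is None:
        config = Config()
    screen = screen_meth_probes(dataset, config.meth.p_threshold,
                                config.meth.r2_threshold) \
        if len(dataset.meth_gene_map) else []
    selected = [r.probe for r in screen if r.selected]
    table = build_node_table(dataset, selected_probes=selected)
    data = assemble_data_matrix(dataset, table)
    B = _resolve_prior(prior, table)
    hyper = BgeHyperparams(n_nodes=len(table),
                           alpha_mu=config.bge.alpha_mu,
                           alpha_w=config.bge.alpha_w,
                           t_scale=config.bge.t_scale)
    sampler = Sampler(data, B, constraints, hyper, config.mcmc)

    ss = np.random.SeedSequence(seed)
    rng_adapt, rng_a, rng_b = [np.random.default_rng(s) for s in ss.spawn(3)]

    state = sampler.fresh_state(rng_adapt)
    log1 = phase1_adapt(sampler, state, rng_adapt)
    logt = run_transient(sampler, state, rng_adapt)
    counts, beta_est, b_hat, log2 = phase2_estimate(sampler, state, rng_adapt)
    beta_est = max(beta_est, config.mcmc.beta_min)

    merged = merge_prior(B, b_hat, counts.f)
    sampler.B = merged
    state.beta = beta_est
    sampler.refresh_state(state)

    traces = []
    states = []
    for rng_c in (rng_a, rng_b):
        st = state.copy()
        st, trace = sampling_phase(sampler, st, rng_c)
        traces.append(trace)
        states.append(st)

    adm = merged.admissible
    crms = c_rms_series(traces[0], traces[1], len(table), adm)
    extensions = 0
    while (not convergence_stop(crms)
           and extensions < config.mcmc.max_extensions):
        for idx, rng_c in enumerate((rng_a, rng_b)):
            states[idx], traces[idx] = sampling_phase(
                sampler, states[idx], rng_c,
                n_iterations=config.mcmc.extension_block, trace=traces[idx])
        crms = c_rms_series(traces[0], traces[1], len(table), adm)
        extensions += 1

    run_log = {
        "seed": seed,
        "n_nodes": len(table),
        "selected_probes": selected,
        "phase1": log1,
        "transient": {k: v for k, v in logt.items() if k != "trace"},
        "phase2": log2,
        "beta": beta_est,
        "extensions": extensions,
        "converged": bool(convergence_stop(crms)),
        "c_rms_final": float(crms[-1]) if crms.size else float("nan"),
        "sampling_acceptance": [t.acceptance.get("sampling") for t in traces],
    }
    return InferenceResult(traces=(traces[0], traces[1]), merged_prior=merged,
                           beta=beta_est, counts=counts, b_hat=b_hat,
                           table=table, run_log=run_log)
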