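"""Diluted autoassociative (attractor) network modelling the CA3 recurrent
collateral system.

Each of the N neurons receives exactly C recurrent afferents sampled at
random from the other neurons (dilution C/N; 12,000/300,000 = 0.04 in the
rat). Memories are stored by associative (Hebbian or covariance) weight
changes on those edges,

    delta_w_ij = k * r_i * r_j'        (postsynaptic rate x presynaptic rate)

and retrieved by iterating the drive h_i = sum_j w_ij r_j through a
k-winners-take-all nonlinearity standing in for global inhibition. The
module provides the analytic capacity estimate

    p_max ~= k * C / (a * ln(1/a))

with prefactor k roughly 0.2-0.3, a simulated capacity search under an
explicit retrieval criterion, and the multiple-synapse (duplicate-wiring)
distortion experiment that motivates diluted connectivity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .activation import kwta_batch
from .patterns import (
    CueSpec,
    PatternEnsemble,
    generate_binary_ensemble,
    make_cue,
    overlap,
    round_half_up,
)

__all__ = [
    "ConnectivityGraph",
    "WeightMatrix",
    "LearningRule",
    "RetrievalConfig",
    "RecallResult",
    "CapacityEstimate",
    "RetrievalCriterion",
    "DuplicateSynapseReport",
    "build_connectivity",
    "store_auto",
    "recall_auto",
    "capacity_analytic",
    "capacity_simulated",
    "duplicate_synapse_experiment",
]


@dataclass
class ConnectivityGraph:
    """Diluted wiring: per-postsynaptic-neuron afferent lists.

    ``afferents[i]`` holds the C presynaptic indices feeding neuron i.
    Autapses are forbidden; duplicate (pre, post) pairs only if allow_multi.
    """

    n: int
    c: int
    afferents: np.ndarray  # (n, c) int array
    allow_multi: bool
    seed: int

    def __post_init__(self) -> None:
        self.afferents = np.asarray(self.afferents, dtype=np.int64)
        if self.afferents.shape != (self.n, self.c):
            raise ValueError("afferent table must have shape (N, C)")
        if np.any(self.afferents == np.arange(self.n)[:, None]):
            raise ValueError("autapses are forbidden")
        if not self.allow_multi:
            for i in range(self.n):
                if np.unique(self.afferents[i]).size != self.c:
                    raise ValueError(f"duplicate afferents on neuron {i}")

    @property
    def dilution(self) -> float:
        return self.c / self.n


@dataclass
class WeightMatrix:
    """Learned synaptic strengths on a ConnectivityGraph (edge-list layout)."""

    graph: ConnectivityGraph
    w: np.ndarray  # (n, c), aligned with graph.afferents

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != self.graph.afferents.shape:
            raise ValueError("weights must align with the afferent table")
        if not np.all(np.isfinite(self.w)):
            raise ValueError("weights must be finite")


@dataclass(frozen=True)
class LearningRule:
    """Associative learning rule: pure Hebb or the covariance variant.

    The covariance variant subtracts ``a_prior * rbar`` (sparseness times the
    active rate scale) from both terms, providing the heterosynaptic LTD that
    efficient storage requires; it is the default throughout.
    """

    k: float = 1.0
    variant: Literal["hebb", "covariance"] = "covariance"
    a_prior: float = 0.05

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ValueError("learning-rate constant k must be > 0")
        if not (0 < self.a_prior < 1):
            raise ValueError("a_prior must lie in (0, 1)")

    def center(self, r: np.ndarray) -> np.ndarray:
        """Mean-subtracted rates used by the covariance variant."""
        if self.variant == "hebb":
            return np.asarray(r, dtype=float)
        active = r[r > 0]
        rbar = float(active.mean()) if active.size else 0.0
        return np.asarray(r, dtype=float) - self.a_prior * rbar


@dataclass(frozen=True)
class RetrievalConfig:
    """Retrieval dynamics settings.

    ``cue_gain`` sets the strength of the sustained external (perforant-path
    style) input that keeps applying the retrieval cue while the recurrent
    collaterals iterate; with the default weight scale it is comparable to
    the recurrent drive from two co-active afferents. ``cue_gain = 0`` gives
    free attractor dynamics from a transient cue.
    """

    a_retrieval: float = 0.05
    max_iters: int = 20
    tol: float = 1e-3
    update: Literal["synchronous", "asynchronous"] = "synchronous"
    output: Literal["binary", "graded"] = "binary"
    cue_gain: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iters < 1 or self.tol <= 0:
            raise ValueError("max_iters >= 1 and tol > 0 required")
        if self.cue_gain < 0:
            raise ValueError("cue_gain must be >= 0")


@dataclass
class RecallResult:
    state: np.ndarray
    converged: bool
    n_iters: int
    trace: list[float]  # overlap between successive states per iteration


@dataclass
class CapacityEstimate:
    p_max: int
    c: int
    a: float
    prefactor_k: float
    method: Literal["analytic", "simulated"]
    criterion: str = ""

    def __post_init__(self) -> None:
        if self.p_max < 0:
            raise ValueError("p_max must be >= 0")
        if self.method == "analytic" and self.prefactor_k <= 0:
            raise ValueError("analytic prefactor must be > 0")


@dataclass(frozen=True)
class RetrievalCriterion:
    """What counts as 'retrieved' in the simulated capacity search."""

    min_fraction: float = 0.9  # fraction of stored patterns retrieved
    min_overlap: float = 0.9  # cosine overlap threshold per pattern
    cue_fraction: float = 1.0  # full-pattern cues by default
    cue_gain: float = 2.0  # sustained external cue strength during recall
    n_test_max: int = 40  # retrieval evaluated on a random subsample

    def describe(self) -> str:
        return (
            f">= {self.min_fraction:.0%} of stored patterns retrieved with "
            f"overlap >= {self.min_overlap} from {self.cue_fraction:.0%} cues "
            f"sustained at gain {self.cue_gain}"
        )


def build_connectivity(
    n: int, c: int, seed: int, allow_multi: bool = False
) -> ConnectivityGraph:
    """Sample each neuron's C afferents uniformly, excluding itself."""
    if allow_multi:
        if not 1 <= c:
            raise ValueError("need C >= 1")
    elif not 1 <= c <= n - 1:
        raise ValueError(f"need 1 <= C <= N-1 without multi-synapses, got C={c}")
    rng = np.random.default_rng(seed)
    aff = np.empty((n, c), dtype=np.int64)
    for i in range(n):
        draw = rng.choice(n - 1, size=c, replace=allow_multi)
        draw[draw >= i] += 1  # skip self
        aff[i] = draw
    return ConnectivityGraph(n, c, aff, allow_multi, seed)


def store_auto(
    ensemble: PatternEnsemble | np.ndarray,
    graph: ConnectivityGraph,
    rule: LearningRule,
) -> WeightMatrix:
    """Accumulate associative weights for every pattern in the ensemble."""
    pats = ensemble.patterns if isinstance(ensemble, PatternEnsemble) else np.atleast_2d(ensemble)
    if pats.shape[1] != graph.n:
        raise ValueError("pattern length must equal the number of neurons")
    w = np.zeros((graph.n, graph.c))
    aff = graph.afferents
    # chunked accumulation keeps the (p_chunk, N, C) gather small
    centered = np.stack([rule.center(r) for r in pats])
    for start in range(0, centered.shape[0], 16):
        blk = centered[start : start + 16]
        w += np.einsum("pi,pic->ic", blk, blk[:, aff], optimize=True)
    return WeightMatrix(graph, rule.k * w)


def _recall_batch(
    weights: WeightMatrix,
    cues: np.ndarray,
    k_active: int,
    max_iters: int,
    cue_gain: float,
) -> np.ndarray:
    """Synchronous binary k-WTA recall for a batch of cues; returns states.

    The cue is held as a sustained external input with strength cue_gain
    while the recurrent drive iterates (cue_gain = 0: free dynamics).
    """
    aff, w = weights.graph.afferents, weights.w
    cues = np.atleast_2d(np.asarray(cues, dtype=float))
    prev = cues.copy()
    for _ in range(max_iters):
        h = np.einsum("ic,mic->mi", w, prev[:, aff], optimize=True)
        if cue_gain:
            h = h + cue_gain * cues
        r = kwta_batch(h, k_active)
        if np.array_equal(r, prev):
            break
        prev = r
    return prev


def recall_auto(
    weights: WeightMatrix, cue: np.ndarray, config: RetrievalConfig
) -> RecallResult:
    """Iterated attractor retrieval from a (possibly partial) cue.

    The cue is applied as a sustained external input of strength
    ``config.cue_gain`` on every iteration — the role the perforant path
    plays in initiating retrieval — while the recurrent collaterals complete
    the pattern; set ``cue_gain = 0`` for free dynamics from a transient
    cue. Synchronous default: every neuron's drive is recomputed from the
    previous state, then global inhibition (k-WTA at
    ``round(a_retrieval * N)`` winners) is applied. Asynchronous mode visits
    neurons in a seeded random sweep, each seeing the partially updated
    state, with inhibition applied at sweep end. Non-convergence is flagged,
    not raised.
    """
    graph = weights.graph
    cue = np.asarray(cue, dtype=float)
    if cue.size != graph.n:
        raise ValueError("cue length must equal the number of neurons")
    k_active = round_half_up(config.a_retrieval * graph.n)
    k_active = max(1, min(k_active, graph.n))
    aff, w = graph.afferents, weights.w
    rng = np.random.default_rng(config.seed)

    from .activation import kwta

    r = cue.copy()
    trace: list[float] = []
    converged = False
    it = 0
    theta = None  # adaptive firing threshold for asynchronous sweeps
    for it in range(1, config.max_iters + 1):
        if config.update == "synchronous":
            h = np.einsum("ic,ic->i", w, r[aff], optimize=True)
            if config.cue_gain:
                h = h + config.cue_gain * cue
        else:
            # seeded random sweep: each neuron sees the partially updated
            # state and fires against the previous sweep's winning threshold;
            # global inhibition (k-WTA) is re-applied at sweep end
            h = np.empty(graph.n)
            state = r.copy()
            for i in rng.permutation(graph.n):
                h[i] = float(w[i] @ state[aff[i]]) + config.cue_gain * cue[i]
                if theta is not None:
                    state[i] = 1.0 if h[i] >= theta else 0.0
        new = kwta(h, k_active, output=config.output)
        theta = float(np.min(h[new > 0]))
        try:
            m = overlap(new, r)
        except ValueError:  # cue or state all-zero
            m = 0.0
        trace.append(m)
        if m >= 1.0 - config.tol:
            r = new
            converged = True
            break
        r = new
    return RecallResult(r, converged, it, trace)


def capacity_analytic(c: int, a: float, prefactor_k: float) -> CapacityEstimate:
    """Analytic attractor capacity ``p_max = round(k * C / (a ln(1/a)))``.

    The prefactor depends weakly on the rate distribution and wiring and is
    roughly 0.2-0.3 for biologically plausible networks; it is exposed as a
    free parameter here.
    """
    if not (0 < a < 1):
        raise ValueError("sparseness must lie strictly in (0, 1)")
    if not (0.05 <= prefactor_k <= 1):
        raise ValueError("prefactor expected in [0.05, 1]")
    p_max = round_half_up(prefactor_k * c / (a * math.log(1.0 / a)))
    return CapacityEstimate(p_max, c, a, prefactor_k, "analytic")


def _criterion_met(
    weights: WeightMatrix,
    pats: np.ndarray,
    crit: RetrievalCriterion,
    a: float,
    rng: np.random.Generator,
) -> tuple[bool, float]:
    """Evaluate the retrieval criterion; returns (met, mean overlap)."""
    n = pats.shape[1]
    p = pats.shape[0]
    idx = (
        rng.choice(p, size=crit.n_test_max, replace=False)
        if p > crit.n_test_max
        else np.arange(p)
    )
    targets = pats[idx]
    if crit.cue_fraction >= 1.0:
        cues = targets
    else:
        cues = np.stack(
            [
                make_cue(t, CueSpec(crit.cue_fraction, seed=int(rng.integers(2**31))))
                for t in targets
            ]
        )
    k_active = max(1, round_half_up(a * n))
    finals = _recall_batch(weights, cues, k_active, max_iters=15, cue_gain=crit.cue_gain)
    norms = np.linalg.norm(finals, axis=1) * np.linalg.norm(targets, axis=1)
    ovl = np.where(norms > 0, np.einsum("mi,mi->m", finals, targets) / np.maximum(norms, 1e-30), 0.0)
    frac = float(np.mean(ovl >= crit.min_overlap))
    return frac >= crit.min_fraction, float(ovl.mean())


def capacity_simulated(
    n: int,
    c: int,
    a: float,
    rule: LearningRule | None = None,
    criterion: RetrievalCriterion | None = None,
    seed: int = 0,
) -> CapacityEstimate:
    """Largest pattern load still retrievable under the stated criterion.

    Doubles the load until the criterion fails, then binary-searches the
    bracket. Reports the empirical prefactor ``k_hat = p_max a ln(1/a) / C``.
    """
    if n > 2000:
        raise ValueError("simulated capacity is desk-scale only (N <= 2000)")
    rule = rule or LearningRule(a_prior=a)
    crit = criterion or RetrievalCriterion()
    ss = np.random.SeedSequence(seed)
    s_graph, s_pats, s_eval = (int(x.generate_state(1)[0] % 2**31) for x in ss.spawn(3))
    graph = build_connectivity(n, c, s_graph)
    # p can never usefully exceed the analytic bound with a generous prefactor
    p_cap = max(4, round_half_up(1.0 * c / (a * math.log(1.0 / a))))
    pats_all = generate_binary_ensemble(n, p_cap, a, s_pats).patterns
    rng = np.random.default_rng(s_eval)

    def ok(p: int) -> bool:
        w = store_auto(pats_all[:p], graph, rule)
        met, _ = _criterion_met(w, pats_all[:p], crit, a, np.random.default_rng(s_eval))
        return met

    if not ok(1):
        return CapacityEstimate(0, c, a, 0.0, "simulated", crit.describe())
    lo, hi = 1, 2
    while hi <= p_cap and ok(hi):
        lo, hi = hi, hi * 2
    if hi > p_cap:
        hi = p_cap + 1
    # binary search in (lo, hi): lo passes, hi fails (or is past the cap)
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if ok(mid):
            lo = mid
        else:
            hi = mid
    k_hat = lo * a * math.log(1.0 / a) / c
    return CapacityEstimate(lo, c, a, k_hat, "simulated", crit.describe())


@dataclass
class DuplicateSynapseReport:
    p_max_single: int
    p_max_multi: int
    duplicate_fraction: float
    n: int
    c: int
    a: float


def _duplicate_wiring(
    graph: ConnectivityGraph, duplicate_fraction: float, seed: int
) -> ConnectivityGraph:
    """Rewire a fraction of afferent slots to duplicate an existing pair.

    Replacement is sequential so duplicates can compound (at fraction 1 and
    C=2 every neuron ends with a single doubled afferent).
    """
    rng = np.random.default_rng(seed)
    aff = graph.afferents.copy()
    n_dup = round_half_up(duplicate_fraction * graph.c)
    for i in range(graph.n):
        slots = rng.choice(graph.c, size=n_dup, replace=False)
        for s in slots:
            others = np.delete(aff[i], s)
            aff[i, s] = rng.choice(others)
    return ConnectivityGraph(graph.n, graph.c, aff, True, seed)


def duplicate_synapse_experiment(
    n: int,
    c: int,
    a: float,
    duplicate_fraction: float,
    seed: int,
    rule: LearningRule | None = None,
    criterion: RetrievalCriterion | None = None,
) -> DuplicateSynapseReport:
    """Capacity with vs without multiple synapses between neuron pairs.

    Duplicated edges carry independent weights that sum in the drive, which
    distorts the energy landscape and lowers capacity — the argument for why
    recurrent cortical connectivity is diluted.
    """
    if not 0 <= duplicate_fraction <= 1:
        raise ValueError("duplicate_fraction must lie in [0, 1]")
    rule = rule or LearningRule(a_prior=a)
    crit = criterion or RetrievalCriterion()

    est_single = capacity_simulated(n, c, a, rule, crit, seed)
    if duplicate_fraction == 0:
        return DuplicateSynapseReport(est_single.p_max, est_single.p_max,
                                      0.0, n, c, a)
    # matched network: same sizes and seeds, duplicated wiring
    ss = np.random.SeedSequence(seed)
    s_graph, s_pats, s_eval, s_dup = (
        int(x.generate_state(1)[0] % 2**31) for x in ss.spawn(4)
    )
    graph = _duplicate_wiring(build_connectivity(n, c, s_graph), duplicate_fraction, s_dup)
    p_cap = max(4, round_half_up(1.0 * c / (a * math.log(1.0 / a))))
    pats_all = generate_binary_ensemble(n, p_cap, a, s_pats).patterns

    def ok(p: int) -> bool:
        w = store_auto(pats_all[:p], graph, rule)
        met, _ = _criterion_met(w, pats_all[:p], crit, a, np.random.default_rng(s_eval))
        return met

    if not ok(1):
        p_multi = 0
    else:
        lo, hi = 1, 2
        while hi <= p_cap and ok(hi):
            lo, hi = hi, hi * 2
        if hi > p_cap:
            hi = p_cap + 1
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if ok(mid):
                lo = mid
            else:
                hi = mid
        p_multi = lo
    return DuplicateSynapseReport(est_single.p_max, p_multi, duplicate_fraction, n, c, a)
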