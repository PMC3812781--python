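"""Feed-forward pattern associators and the hippocampo-neocortical
backprojection hierarchy.

A pattern associator maps an input rate vector to an output rate vector
through one associatively modified feed-forward synaptic stage — no
recurrence, so it generalizes input->output but cannot complete a pattern
and retrieves nothing in the reverse direction. Instances in the theory:
the perforant-path synapses onto CA3 (which relay the retrieval cue), the
CA3->CA1 Schaffer collaterals, and the multistage backprojection pathway
that reinstates neocortical activity during recall.

The analytic capacity is ``p_max = round(C_PA / (a_o ln(1/a_o)))`` with
C_PA the modifiable afferents per output neuron and a_o the output
sparseness — the same form as the recurrent capacity, so at equal
sparseness the feed-forward/recurrent capacity ratio is just C_PA/C_RC
(3,600/12,000 = 0.3 for the rat perforant path vs recurrent collaterals).
The recall signal grows as sqrt(C), which is why the numerically large
perforant path is suited to cueing retrieval. For recall back to neocortex,
each neocortical stage needs C_HBP = C_RC * a_nc / a_CA3 backprojection
afferents — as many as the recurrent collaterals themselves when the
sparsenesses match, forcing the backprojection pathway to be multistage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .activation import kwta
from .ca3 import CapacityEstimate, LearningRule
from .patterns import overlap, round_half_up

__all__ = [
    "PatternAssociator",
    "BackprojectionBudget",
    "BackprojectionHierarchy",
    "build_associator",
    "pa_store",
    "pa_recall",
    "pa_capacity_analytic",
    "recall_signal_snr",
    "SnrTable",
    "backprojection_budget",
    "build_hierarchy",
    "hierarchy_recall",
]


@dataclass
class PatternAssociator:
    """One feed-forward associative stage with diluted afferent sampling."""

    n_in: int
    n_out: int
    c_pa: int
    afferents: np.ndarray  # (n_out, c_pa) distinct input indices per output
    w: np.ndarray  # (n_out, c_pa) edge weights
    a_o: float
    seed: int = 0

    def __post_init__(self) -> None:
        self.afferents = np.asarray(self.afferents, dtype=np.int64)
        self.w = np.asarray(self.w, dtype=float)
        if self.afferents.shape != (self.n_out, self.c_pa):
            raise ValueError("afferent table must have shape (n_out, C_PA)")
        if self.w.shape != self.afferents.shape:
            raise ValueError("weights must align with the afferent table")
        if not (0 < self.a_o < 1):
            raise ValueError("a_o must lie in (0, 1)")


def build_associator(
    n_in: int, n_out: int, c_pa: int, a_o: float, seed: int
) -> PatternAssociator:
    """Untrained associator; each output samples C_PA distinct inputs."""
    if not 1 <= c_pa <= n_in:
        raise ValueError("need 1 <= C_PA <= n_in")
    rng = np.random.default_rng(seed)
    aff = np.stack([rng.choice(n_in, size=c_pa, replace=False) for _ in range(n_out)])
    return PatternAssociator(n_in, n_out, c_pa, aff, np.zeros((n_out, c_pa)), a_o, seed)


def pa_store(
    pa: PatternAssociator,
    pairs: Sequence[tuple[np.ndarray, np.ndarray]],
    rule: LearningRule,
) -> PatternAssociator:
    """Accumulate ``delta_w = k post pre`` over the wired edges for each pair.

    Returns a new associator; storage is additive and order-independent.
    """
    w = pa.w.copy()
    for x, y in pairs:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if x.size != pa.n_in or y.size != pa.n_out:
            raise ValueError("pair dimensions must match the associator")
        pre = rule.center(x)[pa.afferents]
        post = rule.center(y)
        w += rule.k * post[:, None] * pre
    return PatternAssociator(pa.n_in, pa.n_out, pa.c_pa, pa.afferents, w, pa.a_o, pa.seed)


def pa_recall(pa: PatternAssociator, cue: np.ndarray) -> np.ndarray:
    """Single feed-forward pass: drive then k-WTA; no recurrent iteration."""
    cue = np.asarray(cue, dtype=float)
    if cue.size != pa.n_in:
        raise ValueError("cue length must equal n_in")
    h = np.einsum("oc,oc->o", pa.w, cue[pa.afferents], optimize=True)
    k = max(1, round_half_up(pa.a_o * pa.n_out))
    return kwta(h, k, output="binary")


def pa_capacity_analytic(c_pa: int, a_o: float) -> CapacityEstimate:
    """Feed-forward capacity ``p_max = round(C_PA / (a_o ln(1/a_o)))``."""
    if not (0 < a_o < 1):
        raise ValueError("a_o must lie strictly in (0, 1)")
    p_max = round_half_up(c_pa / (a_o * math.log(1.0 / a_o)))
    return CapacityEstimate(p_max, c_pa, a_o, 1.0, "analytic")


@dataclass
class SnrTable:
    """Recall-signal measurements across afferent counts C."""

    c_values: list[int]
    snr: list[float]  # mean over seeds per C
    slope: float  # fitted log-log slope of SNR vs C


def recall_signal_snr(
    c_values: Sequence[int],
    n_in: int = 2000,
    a: float = 0.05,
    p: int = 20,
    n_out: int = 500,
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> SnrTable:
    """Measure how the retrieval signal grows with afferent count C.

    For each C: store p random binary pairs with the covariance rule, cue
    with a stored input, and compute (mean target drive - mean non-target
    drive) / s.d. of non-target drives. The crosstalk noise grows as
    sqrt(C) while the signal grows as C, so the SNR should scale as
    sqrt(C) — the fitted log-log slope is reported.
    """
    if len(set(c_values)) < 2:
        raise ValueError("need at least two distinct C values")
    from .patterns import generate_binary_ensemble

    mean_snr: list[float] = []
    for c in c_values:
        vals = []
        for seed in seeds:
            ss = np.random.SeedSequence([seed, c])
            s_net, s_in, s_out = (int(x.generate_state(1)[0] % 2**31) for x in ss.spawn(3))
            pa = build_associator(n_in, n_out, int(c), a, s_net)
            xs = generate_binary_ensemble(n_in, p, a, s_in).patterns
            ys = generate_binary_ensemble(n_out, p, a, s_out).patterns
            rule = LearningRule(a_prior=a)
            pa = pa_store(pa, list(zip(xs, ys)), rule)
            # drive from the first stored input
            h = np.einsum("oc,oc->o", pa.w, xs[0][pa.afferents])
            tgt = ys[0] > 0
            noise_sd = float(h[~tgt].std())
            if noise_sd == 0:
                continue
            vals.append((float(h[tgt].mean()) - float(h[~tgt].mean())) / noise_sd)
        mean_snr.append(float(np.mean(vals)))
    logc = np.log(np.asarray(c_values, dtype=float))
    logs = np.log(np.asarray(mean_snr))
    slope = float(np.polyfit(logc, logs, 1)[0])
    return SnrTable(list(map(int, c_values)), mean_snr, slope)


@dataclass(frozen=True)
class BackprojectionBudget:
    """Inputs to the backprojection afferent-count requirement."""

    c_rc: int
    a_nc: float
    a_ca3: float
    prefactor: float = 1.0  # slowly varying factor; ratio-only use by default

    def __post_init__(self) -> None:
        if not (0 < self.a_nc < 1 and 0 < self.a_ca3 < 1):
            raise ValueError("sparsenesses must lie in (0, 1)")


def backprojection_budget(b: BackprojectionBudget) -> int:
    """Required backprojection afferents: ``C_HBP = C_RC a_nc / a_CA3``."""
    return round_half_up(b.prefactor * b.c_rc * b.a_nc / b.a_ca3)


@dataclass
class BackprojectionHierarchy:
    """Chain of pattern associators from CA3 out to a neocortical surrogate.

    Stage sizes must not shrink toward neocortex (the anatomical divergence
    grows at each backprojection stage).
    """

    stages: list[PatternAssociator]
    stage_patterns: list[np.ndarray] | None = None  # (p, n_stage) per level

    def __post_init__(self) -> None:
        sizes = [self.stages[0].n_in] + [s.n_out for s in self.stages]
        for s_prev, s_next in zip(self.stages[:-1], self.stages[1:]):
            if s_prev.n_out != s_next.n_in:
                raise ValueError("consecutive stages are dimension-incompatible")
        if any(b < a for a, b in zip(sizes[:-1], sizes[1:])):
            raise ValueError("stage sizes must be non-decreasing toward neocortex")


def build_hierarchy(
    sizes: Sequence[int],
    c_per_stage: Sequence[int] | int,
    a: float,
    p: int,
    seed: int,
    rule: LearningRule | None = None,
) -> BackprojectionHierarchy:
    """Train a hierarchy on p random pattern chains (one pattern per level)."""
    from .patterns import generate_binary_ensemble

    if isinstance(c_per_stage, int):
        c_per_stage = [c_per_stage] * (len(sizes) - 1)
    if len(c_per_stage) != len(sizes) - 1:
        raise ValueError("need one afferent count per stage")
    rule = rule or LearningRule(a_prior=a)
    ss = np.random.SeedSequence(seed)
    kids = ss.spawn(2 * len(sizes))
    level_pats = [
        generate_binary_ensemble(n, p, a, int(kids[i].generate_state(1)[0] % 2**31)).patterns
        for i, n in enumerate(sizes)
    ]
    stages = []
    for i in range(len(sizes) - 1):
        s_net = int(kids[len(sizes) + i].generate_state(1)[0] % 2**31)
        pa = build_associator(sizes[i], sizes[i + 1], int(c_per_stage[i]), a, s_net)
        pa = pa_store(pa, list(zip(level_pats[i], level_pats[i + 1])), rule)
        stages.append(pa)
    return BackprojectionHierarchy(stages, level_pats)


def hierarchy_recall(
    h: BackprojectionHierarchy, ca3_state: np.ndarray, chain_index: int | None = None
) -> tuple[list[np.ndarray], list[float] | None]:
    """Propagate a CA3-side state stage by stage toward neocortex.

    Returns the per-stage retrieved states and, when the hierarchy carries
    its training patterns and ``chain_index`` names a stored chain, the
    per-stage overlaps with that chain's stored patterns.
    """
    if any(np.all(s.w == 0) for s in h.stages):
        raise ValueError("hierarchy has an untrained stage")
    states = []
    state = np.asarray(ca3_state, dtype=float)
    for pa in h.stages:
        state = pa_recall(pa, state)
        states.append(state)
    overlaps = None
    if h.stage_patterns is not None and chain_index is not None:
        overlaps = [
            overlap(st, h.stage_patterns[i + 1][chain_index])
            for i, st in enumerate(states)
        ]
    return states, overlaps
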