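"""Mixed continuous + discrete attractor memories (object-place networks).

Space is continuous, objects are discrete. A single recurrent attractor
network can store memories that combine a continuous spatial part — a
Gaussian bump of firing over a ring of spatially tuned neurons, each peaking
at its optimal location — with a discrete part, a random subset of binary
"object" neurons. After Hebbian storage, cueing with the object alone
reinstates the spatial bump at the associated location, and cueing with the
place alone reinstates the object code: retrieval is symmetric, the defining
contrast with a one-way feed-forward pattern associator. The same machinery
with a densely trained manifold of bump positions behaves as a continuous
attractor that holds a bump stably anywhere on the ring.

Global inhibition is applied per subpopulation (spatial pool and object pool
each keep their own number of winners), since a single global threshold
would let the larger pool silence the smaller.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

import numpy as np

from .activation import kwta
from .ca3 import LearningRule

__all__ = [
    "MixedMemory",
    "CannNetwork",
    "CannRecallResult",
    "make_mixed_memory",
    "mixed_pattern",
    "cann_store",
    "cann_recall",
    "bump_center",
    "bump_stability",
    "train_manifold",
]


@dataclass(frozen=True)
class MixedMemory:
    """One stored memory: Gaussian spatial bump + discrete object set."""

    center: int  # index within the continuous subpopulation
    sigma: float  # bump width in neuron-index units
    discrete_set: frozenset[int] = frozenset()  # indices within the discrete pool
    peak_rate: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be > 0")


@dataclass
class CannNetwork:
    """Joint recurrent network over [continuous | discrete] subpopulations."""

    n_continuous: int
    n_discrete: int
    w: np.ndarray | None = None  # (n, n) dense recurrent weights, zero diagonal
    k_continuous: int = 80  # active units kept in the spatial pool
    k_discrete: int = 25  # active units kept in the object pool

    def __post_init__(self) -> None:
        n = self.n_continuous + self.n_discrete
        if self.w is None:
            self.w = np.zeros((n, n))
        self.w = np.asarray(self.w, dtype=float)
        if self.w.shape != (n, n):
            raise ValueError("weight matrix must cover the joint population")
        if np.any(np.diag(self.w) != 0):
            raise ValueError("self-connections are forbidden")

    @property
    def n(self) -> int:
        return self.n_continuous + self.n_discrete


def _ring_distance(i: np.ndarray, center: int, n: int) -> np.ndarray:
    d = np.abs(i - center)
    return np.minimum(d, n - d)


def make_mixed_memory(
    center: int,
    sigma: float,
    discrete_set: Iterable[int] = (),
    peak_rate: float = 1.0,
) -> MixedMemory:
    return MixedMemory(int(center), float(sigma), frozenset(int(i) for i in discrete_set), peak_rate)


def mixed_pattern(mem: MixedMemory, net: CannNetwork) -> np.ndarray:
    """Render a memory as a joint rate vector on the network's layout.

    Continuous part: ``r_i = peak exp(-d(i, center)^2 / (2 sigma^2))`` with
    ring-wrapped distance d; discrete part: binary on the member indices.
    """
    if not 0 <= mem.center < net.n_continuous:
        raise ValueError("memory center outside the continuous span")
    if any(not 0 <= j < net.n_discrete for j in mem.discrete_set):
        raise ValueError("discrete indices outside the discrete span")
    idx = np.arange(net.n_continuous)
    d = _ring_distance(idx, mem.center, net.n_continuous)
    r = np.zeros(net.n)
    r[: net.n_continuous] = mem.peak_rate * np.exp(-(d**2) / (2 * mem.sigma**2))
    for j in mem.discrete_set:
        r[net.n_continuous + j] = mem.peak_rate
    return r


def cann_store(
    net: CannNetwork,
    memories: Sequence[MixedMemory],
    rule: LearningRule | None = None,
) -> CannNetwork:
    """Hebb/covariance accumulation of each joint pattern; no self-weights.

    The covariance variant centers each subpopulation on its own mean so
    that the cross-pool associations between co-active parts stay positive.
    Returns a new network; storage is additive and order-independent.
    """
    rule = rule or LearningRule(variant="hebb")
    w = net.w.copy()
    nc = net.n_continuous
    for mem in memories:
        r = mixed_pattern(mem, net)
        if rule.variant == "covariance":
            v = r.copy()
            v[:nc] -= r[:nc].mean()
            if net.n_discrete:
                v[nc:] -= r[nc:].mean()
        else:
            v = r
        w += rule.k * np.outer(v, v)
    np.fill_diagonal(w, 0.0)
    return CannNetwork(net.n_continuous, net.n_discrete, w, net.k_continuous, net.k_discrete)


def _joint_kwta(net: CannNetwork, h: np.ndarray) -> np.ndarray:
    """Per-subpopulation inhibition: graded bump, binary object code."""
    nc = net.n_continuous
    r = np.zeros(net.n)
    r[:nc] = kwta(h[:nc], min(net.k_continuous, nc), output="graded")
    if net.n_discrete:
        r[nc:] = kwta(h[nc:], min(net.k_discrete, net.n_discrete), output="binary")
    return r


@dataclass
class CannRecallResult:
    state: np.ndarray
    converged: bool
    n_iters: int

    def continuous(self, net: CannNetwork) -> np.ndarray:
        return self.state[: net.n_continuous]

    def discrete(self, net: CannNetwork) -> np.ndarray:
        return self.state[net.n_continuous :]


def cann_recall(
    net: CannNetwork,
    cue: np.ndarray,
    mode: Literal["object-to-place", "place-to-object", "completion"] = "completion",
    max_iters: int = 30,
    tol: float = 1e-6,
) -> CannRecallResult:
    """Iterate the joint dynamics from a cue until the state stops changing.

    Translation modes zero the other subpopulation in the cue: an
    object-to-place cue carries only discrete activity, a place-to-object
    cue only continuous activity.
    """
    cue = np.asarray(cue, dtype=float).copy()
    if cue.size != net.n:
        raise ValueError("cue must cover the joint population")
    nc = net.n_continuous
    if mode == "object-to-place":
        cue[:nc] = 0.0
    elif mode == "place-to-object":
        cue[nc:] = 0.0
    elif mode != "completion":
        raise ValueError(f"unknown mode {mode!r}")
    r = cue
    converged = False
    it = 0
    for it in range(1, max_iters + 1):
        h = net.w @ r
        new = _joint_kwta(net, h)
        if np.abs(new - r).max() <= tol:
            r = new
            converged = True
            break
        r = new
    return CannRecallResult(r, converged, it)


def bump_center(rates: np.ndarray) -> float:
    """Circular center of mass of supra-threshold continuous rates."""
    r = np.asarray(rates, dtype=float)
    if r.sum() <= 0:
        raise ValueError("no activity: bump center undefined")
    n = r.size
    ang = 2 * np.pi * np.arange(n) / n
    z = np.sum(r * np.exp(1j * ang))
    return float((np.angle(z) % (2 * np.pi)) / (2 * np.pi) * n)


def train_manifold(
    net: CannNetwork,
    sigma: float,
    spacing: int = 10,
    rule: LearningRule | None = None,
) -> CannNetwork:
    """Store a dense set of bump positions so the ring becomes a continuous
    attractor manifold (training centers every ``spacing`` indices)."""
    centers = range(0, net.n_continuous, spacing)
    mems = [MixedMemory(c, sigma) for c in centers]
    return cann_store(net, mems, rule)


def bump_stability(
    net: CannNetwork, init_center: int, sigma: float, t_iters: int
) -> np.ndarray:
    """Drift of a free-running bump: center-of-mass trajectory over T steps.

    Starts from an ideal bump at ``init_center``, runs the recurrent dynamics
    with no external input, and records the bump center each iteration.
    Raises if the activity collapses to silence.
    """
    r = mixed_pattern(MixedMemory(init_center, sigma), net)
    centers = [bump_center(r[: net.n_continuous])]
    for _ in range(t_iters):
        h = net.w @ r
        r = _joint_kwta(net, h)
        if r[: net.n_continuous].sum() <= 0:
            raise RuntimeError("bump collapsed: no continuous activity")
        centers.append(bump_center(r[: net.n_continuous]))
    return np.asarray(centers)
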