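"""Sparse firing-rate patterns and the metrics defined on them.

A *pattern* is a length-``N`` vector of non-negative firing rates — the
universal currency passed between the stages of the hippocampal model
(dentate granule cells, CA3 pyramidal cells, CA1, neocortical surrogates).
This module generates random sparse binary and graded ensembles, degrades
patterns into partial retrieval cues, and computes the population
sparseness measure

    a = (sum_i r_i / N)^2 / sum_i (r_i^2 / N)

which ranges from 1/N (a single active "grandmother" cell) to 1.0 (all
neurons firing at the same rate).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np

__all__ = [
    "PatternEnsemble",
    "CueSpec",
    "sparseness",
    "overlap",
    "pearson_overlap",
    "mean_pairwise_correlation",
    "generate_binary_ensemble",
    "generate_graded_ensemble",
    "generate_correlated_ensemble",
    "make_cue",
    "round_half_up",
    "save_ensemble",
    "load_ensemble",
]

ACTIVE_RATE = 1.0  # fixed rate of active units in binary patterns (scale-free)


def round_half_up(x: float) -> int:
    """Round half away from zero; avoids zero-active edge cases at small N."""
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def _validate_pattern(r: np.ndarray) -> np.ndarray:
    r = np.asarray(r, dtype=float)
    if r.ndim != 1 or r.size < 1:
        raise ValueError("a rate pattern must be a 1-D vector with N >= 1")
    if not np.all(np.isfinite(r)) or np.any(r < 0):
        raise ValueError("firing rates must be finite and non-negative")
    return r


@dataclass
class PatternEnsemble:
    """Ordered set of ``p`` rate patterns sharing a common length ``N``.

    ``patterns`` is a (p, N) array; rows are individual patterns.
    """

    patterns: np.ndarray
    target_sparseness: float
    kind: Literal["binary", "graded-exponential", "graded-gamma"]
    seed: int
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.patterns = np.atleast_2d(np.asarray(self.patterns, dtype=float))
        if self.patterns.shape[0] < 1:
            raise ValueError("ensemble must contain at least one pattern")
        if not (0 < self.target_sparseness <= 1):
            raise ValueError("target_sparseness must lie in (0, 1]")

    @property
    def p(self) -> int:
        return self.patterns.shape[0]

    @property
    def n(self) -> int:
        return self.patterns.shape[1]

    def __iter__(self):
        return iter(self.patterns)

    def __getitem__(self, i):
        return self.patterns[i]


@dataclass(frozen=True)
class CueSpec:
    """How to degrade a stored pattern into a partial retrieval cue."""

    fraction_kept: float = 0.5
    mode: Literal["drop-active", "additive-noise"] = "drop-active"
    noise_scale: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fraction_kept <= 1):
            raise ValueError("fraction_kept must lie in (0, 1]")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be >= 0")


def sparseness(r: np.ndarray) -> float:
    """Population sparseness ``(Σr_i/N)² / Σ(r_i²/N)`` of a rate vector.

    Equals the fraction of active units for binary vectors; bounded by
    [1/N, 1] with equality at a one-hot vector and a uniform vector.
    """
    r = _validate_pattern(r)
    ssq = float(np.dot(r, r))
    if ssq == 0.0:
        raise ValueError("sparseness is undefined for an all-zero pattern")
    n = r.size
    return (float(r.sum()) / n) ** 2 / (ssq / n)


def overlap(p1: np.ndarray, p2: np.ndarray) -> float:
    """Cosine similarity between two rate vectors (retrieval-quality metric)."""
    p1 = _validate_pattern(p1)
    p2 = _validate_pattern(p2)
    if p1.size != p2.size:
        raise ValueError("patterns must have equal length")
    n1 = float(np.linalg.norm(p1))
    n2 = float(np.linalg.norm(p2))
    if n1 == 0.0 or n2 == 0.0:
        raise ValueError("overlap is undefined for an all-zero pattern")
    return float(np.dot(p1, p2)) / (n1 * n2)


def pearson_overlap(p1: np.ndarray, p2: np.ndarray) -> float:
    """Pearson correlation variant of :func:`overlap`.

    Decorrelation claims about pattern separation are statements about
    correlations, so both metrics are exposed.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    if p1.size != p2.size:
        raise ValueError("patterns must have equal length")
    s1, s2 = p1.std(), p2.std()
    if s1 == 0.0 or s2 == 0.0:
        raise ValueError("correlation undefined for a constant pattern")
    return float(np.corrcoef(p1, p2)[0, 1])


def mean_pairwise_correlation(patterns: np.ndarray) -> float:
    """Mean Pearson correlation over all unordered pattern pairs."""
    x = np.atleast_2d(np.asarray(patterns, dtype=float))
    p = x.shape[0]
    if p < 2:
        raise ValueError("need at least two patterns")
    c = np.corrcoef(x)
    iu = np.triu_indices(p, k=1)
    return float(np.mean(c[iu]))


def generate_binary_ensemble(n: int, p: int, a: float, seed: int) -> PatternEnsemble:
    """``p`` random binary patterns of length ``n`` at sparseness ``a``.

    Each pattern has exactly ``round(a·n)`` active units (rate 1.0) chosen
    uniformly without replacement; deterministic given ``seed``.
    """
    if p < 1:
        raise ValueError("need at least one pattern")
    if not (0 < a <= 1):
        raise ValueError("sparseness must lie in (0, 1]")
    n_active = round_half_up(a * n)
    if n_active < 1:
        raise ValueError(f"a*N = {a * n:.3g} < 0.5: no active unit representable")
    rng = np.random.default_rng(seed)
    pats = np.zeros((p, n))
    for mu in range(p):
        pats[mu, rng.choice(n, size=n_active, replace=False)] = ACTIVE_RATE
    return PatternEnsemble(pats, a, "binary", seed)


def generate_correlated_ensemble(
    n: int, p: int, a: float, target_r: float, seed: int
) -> PatternEnsemble:
    """Binary ensemble with a prescribed mean pairwise Pearson correlation.

    Uses a shared-core construction: every pattern contains a common active
    core of ``s ≈ target_r·a·n`` units plus independent random active units.
    For s shared units the co-activation probability is
    ``P11 ≈ s/n + a²`` hence ``r ≈ s / (n·a·(1-a))`` for small a; solving
    for ``s`` gives the core size.
    """
    if not (0 <= target_r < 1):
        raise ValueError("target correlation must lie in [0, 1)")
    n_active = round_half_up(a * n)
    core = round_half_up(target_r * a * (1 - a) * n)
    core = min(core, n_active)
    rng = np.random.default_rng(seed)
    core_idx = rng.choice(n, size=core, replace=False)
    rest = np.setdiff1d(np.arange(n), core_idx)
    pats = np.zeros((p, n))
    for mu in range(p):
        pats[mu, core_idx] = ACTIVE_RATE
        extra = rng.choice(rest, size=n_active - core, replace=False)
        pats[mu, extra] = ACTIVE_RATE
    ens = PatternEnsemble(pats, a, "binary", seed)
    ens.meta["target_correlation"] = target_r
    return ens


def _rectify_to_sparseness(x: np.ndarray, a: float, tol: float = 0.01) -> np.ndarray:
    """Threshold-rectify a non-negative sample so its sparseness is ≈ a.

    Subtracts a threshold θ, rectifies at zero, and bisects on θ: raising
    the threshold silences weakly firing units, which always lowers the
    sparseness measure, so sparseness is monotone decreasing in θ.
    """
    if sparseness(x) <= a + tol:
        if sparseness(x) >= a - tol:
            return x
        raise ValueError(
            f"target sparseness {a} not attainable: raw sample already sparser"
        )
    lo, hi = 0.0, float(x.max())
    for _ in range(200):
        theta = 0.5 * (lo + hi)
        r = np.maximum(x - theta, 0.0)
        if not np.any(r > 0):
            hi = theta
            continue
        s = sparseness(r)
        if abs(s - a) <= tol * 0.5:
            return r
        if s > a:
            lo = theta
        else:
            hi = theta
    r = np.maximum(x - 0.5 * (lo + hi), 0.0)
    if not np.any(r > 0) or abs(sparseness(r) - a) > tol:
        raise ValueError(f"calibration failed to reach sparseness {a}")
    return r


def generate_graded_ensemble(
    n: int,
    p: int,
    a: float,
    dist: Literal["exponential", "gamma"],
    seed: int,
    gamma_shape: float = 2.0,
) -> PatternEnsemble:
    """Graded-rate ensemble with rates drawn i.i.d. then sparsified.

    Firing-rate distributions in cortex and hippocampus are approximately
    exponential or gamma; each drawn pattern is thresholded and rectified
    (bisection on the threshold) until its measured sparseness is within
    ±0.01 of ``a``.
    """
    if dist not in ("exponential", "gamma"):
        raise ValueError("dist must be 'exponential' or 'gamma'")
    if not (0 < a <= 1):
        raise ValueError("sparseness must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    pats = np.empty((p, n))
    for mu in range(p):
        if dist == "exponential":
            x = rng.exponential(1.0, size=n)
        else:
            x = rng.gamma(gamma_shape, 1.0, size=n)
        pats[mu] = _rectify_to_sparseness(x, a)
    kind = "graded-exponential" if dist == "exponential" else "graded-gamma"
    return PatternEnsemble(pats, a, kind, seed)


def make_cue(pattern: np.ndarray, spec: CueSpec) -> np.ndarray:
    """Degrade a pattern into a partial retrieval cue.

    ``drop-active`` keeps ``round(fraction_kept · n_active)`` of the active
    units (uniform seeded choice) and zeroes the rest; ``additive-noise``
    adds seeded zero-mean Gaussian noise then rectifies at zero.
    """
    r = _validate_pattern(pattern)
    active = np.flatnonzero(r > 0)
    if active.size == 0:
        raise ValueError("cannot cue an all-zero pattern")
    rng = np.random.default_rng(spec.seed)
    if spec.mode == "drop-active":
        keep = round_half_up(spec.fraction_kept * active.size)
        if keep < 1:
            raise ValueError("fraction_kept would retain zero active units")
        kept = rng.choice(active, size=keep, replace=False)
        cue = np.zeros_like(r)
        cue[kept] = r[kept]
        return cue
    if spec.mode == "additive-noise":
        noisy = r + rng.normal(0.0, spec.noise_scale, size=r.size)
        return np.maximum(noisy, 0.0)
    raise ValueError(f"unknown cue mode {spec.mode!r}")


# -- serialization: delimited text + JSON sidecar manifest -------------------


def save_ensemble(ens: PatternEnsemble, path: str | Path) -> None:
    """Write one pattern per row as tab-delimited floats, plus a manifest."""
    path = Path(path)
    np.savetxt(path, ens.patterns, fmt="%.10g", delimiter="\t")
    manifest = {
        "n": ens.n,
        "p": ens.p,
        "target_sparseness": ens.target_sparseness,
        "kind": ens.kind,
        "seed": ens.seed,
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(manifest, indent=1))


def load_ensemble(path: str | Path) -> PatternEnsemble:
    path = Path(path)
    pats = np.loadtxt(path, delimiter="\t", ndmin=2)
    manifest = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return PatternEnsemble(
        pats, manifest["target_sparseness"], manifest["kind"], manifest["seed"]
    )
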