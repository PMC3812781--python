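"""Global-inhibition surrogate: exact k-winners-take-all.

Feedback inhibition in the hippocampus keeps the number of simultaneously
active principal cells roughly constant. The deterministic surrogate used
throughout this package is exact k-WTA: given a dendritic drive vector, the
k most strongly driven units fire and the rest are silent. Ties at the
threshold are broken toward the lowest neuron index so every stage is
exactly reproducible.
"""

from __future__ import annotations

import numpy as np

__all__ = ["kwta", "kwta_batch"]


def kwta(h: np.ndarray, k: int, output: str = "binary") -> np.ndarray:
    """Apply k-winners-take-all to a drive vector.

    Parameters
    ----------
    h : drive (activation) per unit.
    k : number of winners; must satisfy 1 <= k <= len(h).
    output : "binary" -> winners fire at rate 1.0;
        "graded" -> winners fire at a threshold-linear rate
        ``max(h - theta, 0)`` with theta the largest losing drive (scaled so
        the peak rate is 1 when any winner exceeds theta).
    """
    h = np.asarray(h, dtype=float)
    if not 1 <= k <= h.size:
        raise ValueError(f"k must be in [1, {h.size}], got {k}")
    order = np.argsort(-h, kind="stable")  # stable: ties -> lowest index wins
    winners = order[:k]
    r = np.zeros_like(h)
    if output == "binary":
        r[winners] = 1.0
        return r
    if output == "graded":
        theta = h[order[k]] if k < h.size else float(h.min())
        vals = np.maximum(h[winners] - theta, 0.0)
        peak = vals.max()
        if peak <= 0:  # degenerate (all drives tied): fall back to binary
            r[winners] = 1.0
        else:
            r[winners] = vals / peak
        return r
    raise ValueError(f"unknown output mode {output!r}")


def kwta_batch(h: np.ndarray, k: int) -> np.ndarray:
    """Row-wise binary k-WTA for a (m, n) batch of drive vectors."""
    h = np.atleast_2d(np.asarray(h, dtype=float))
    m, n = h.shape
    if not 1 <= k <= n:
        raise ValueError(f"k must be in [1, {n}], got {k}")
    order = np.argsort(-h, axis=1, kind="stable")
    r = np.zeros_like(h)
    rows = np.repeat(np.arange(m), k)
    r[rows, order[:, :k].ravel()] = 1.0
    return r
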