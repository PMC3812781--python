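"""Dentate-gyrus pattern separation: grid-cell inputs, competitive learning,
and the sparse mossy-fiber projection into CA3.

Entorhinal grid cells are modelled as periodic tuning curves on a 1-D unit
ring (a cell with frequency f has f equally spaced firing peaks per
traversal). A competitive network of dentate granule units learns, without a
teacher, to respond to particular combinations of grid cells — converting
periodic grid codes into single place-like fields. The granule population
then reaches CA3 through very few (~46 per CA3 cell) strong mossy-fiber
synapses whose random sparse sampling, followed by an inhibitory threshold,
decorrelates ("separates") the representations handed to the CA3
autoassociator.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np

from .activation import kwta, kwta_batch
from .patterns import PatternEnsemble, mean_pairwise_correlation, round_half_up

__all__ = [
    "GridCellPopulation",
    "CompetitiveNetwork",
    "MossyProjection",
    "PlaceFieldMetrics",
    "grid_rates",
    "grid_rate_map",
    "competitive_train",
    "response_map",
    "drive_map",
    "place_field_metrics",
    "build_mossy_projection",
    "mossy_project",
    "separation_index",
]


@dataclass
class GridCellPopulation:
    """1-D periodic grid tuning over a unit-length circular track.

    Cell c fires at ``peak_rate * max(0, cos(2 pi f_c (x - phi_c)))**rho``;
    the sharpening exponent rho narrows the fields without changing the
    number of peaks (frequency f gives exactly f maxima per traversal).
    """

    frequencies: np.ndarray  # integer cycles per traversal, one per cell
    phases: np.ndarray  # in [0, 1), one per cell
    peak_rate: float = 1.0
    rho: float = 3.0

    def __post_init__(self) -> None:
        self.frequencies = np.asarray(self.frequencies, dtype=int)
        self.phases = np.asarray(self.phases, dtype=float)
        if self.frequencies.size != self.phases.size:
            raise ValueError("need one frequency and one phase per cell")
        if np.any(self.frequencies < 1):
            raise ValueError("frequencies must be >= 1")
        if np.any((self.phases < 0) | (self.phases >= 1)):
            raise ValueError("phases must lie in [0, 1)")
        if self.peak_rate <= 0:
            raise ValueError("peak_rate must be > 0")

    @property
    def n_cells(self) -> int:
        return self.frequencies.size

    @classmethod
    def random(
        cls,
        n_cells: int,
        seed: int,
        freq_range: tuple[int, int] = (2, 9),
        peak_rate: float = 1.0,
        rho: float = 3.0,
    ) -> "GridCellPopulation":
        rng = np.random.default_rng(seed)
        freqs = rng.integers(freq_range[0], freq_range[1] + 1, size=n_cells)
        phases = rng.uniform(0, 1, size=n_cells)
        return cls(freqs, phases, peak_rate, rho)


def grid_rates(pop: GridCellPopulation, position: float) -> np.ndarray:
    """Population rate vector at one track position (ring coordinate)."""
    x = position % 1.0
    arg = 2 * np.pi * pop.frequencies * (x - pop.phases)
    return pop.peak_rate * np.maximum(0.0, np.cos(arg)) ** pop.rho


def grid_rate_map(pop: GridCellPopulation, n_positions: int) -> np.ndarray:
    """(n_positions, n_cells) rates over a uniform scan of the track."""
    xs = np.arange(n_positions) / n_positions
    arg = 2 * np.pi * np.outer(xs, pop.frequencies) - 2 * np.pi * pop.frequencies * pop.phases
    return pop.peak_rate * np.maximum(0.0, np.cos(arg)) ** pop.rho


@dataclass
class CompetitiveNetwork:
    """Feed-forward competitive net: grid inputs -> dentate granule units.

    Weight rows (one per granule unit) are non-negative and kept at unit
    Euclidean norm, the canonical normalization that makes competitive
    learning converge to input-cluster directions.
    """

    w: np.ndarray  # (n_dg, n_in), non-negative, unit-norm rows
    a_dg: float
    eta: float = 0.05

    def __post_init__(self) -> None:
        self.w = np.asarray(self.w, dtype=float)
        if np.any(self.w < 0):
            raise ValueError("competitive weights must be non-negative")
        norms = np.linalg.norm(self.w, axis=1)
        if np.any(norms == 0):
            raise ValueError("every unit needs a non-zero weight vector")
        self.w = self.w / norms[:, None]
        if not (0 < self.a_dg <= 1):
            raise ValueError("a_dg must lie in (0, 1]")

    @property
    def n_dg(self) -> int:
        return self.w.shape[0]

    @property
    def n_in(self) -> int:
        return self.w.shape[1]

    @classmethod
    def random(
        cls, n_in: int, n_dg: int, a_dg: float, seed: int, eta: float = 0.05
    ) -> "CompetitiveNetwork":
        rng = np.random.default_rng(seed)
        w = rng.uniform(0.0, 1.0, size=(n_dg, n_in))
        return cls(w, a_dg, eta)


def competitive_train(
    net: CompetitiveNetwork,
    pop: GridCellPopulation,
    n_positions: int,
    epochs: int,
    seed: int,
) -> CompetitiveNetwork:
    """Unsupervised competitive learning on a uniform position scan.

    Per presented position: activations h = w r, k-WTA selects
    ``round(a_dg n_dg)`` winners, winners move toward the input
    (``delta_w = eta r``, Hebb with postsynaptic gating) and are renormalized
    to unit L2 norm. Presentation order is shuffled per epoch (seeded).
    Returns a new trained network; the input net is not modified.
    """
    if epochs < 1:
        raise ValueError("need at least one epoch")
    rng = np.random.default_rng(seed)
    w = net.w.copy()
    k = max(1, round_half_up(net.a_dg * net.n_dg))
    rates = grid_rate_map(pop, n_positions)  # (pos, n_in)
    for _ in range(epochs):
        for p_idx in rng.permutation(n_positions):
            r = rates[p_idx]
            h = w @ r
            order = np.argsort(-h, kind="stable")
            winners = order[:k]
            w[winners] += net.eta * r
            w[winners] /= np.linalg.norm(w[winners], axis=1)[:, None]
    return CompetitiveNetwork(w, net.a_dg, net.eta)


def response_map(net: CompetitiveNetwork, pop: GridCellPopulation, n_positions: int) -> np.ndarray:
    """(n_positions, n_dg) post-inhibition rate map of the granule layer.

    At each position the k-WTA winners fire at their (non-negative) drive;
    losers are silent — graded rate maps comparable to recorded profiles.
    """
    rates = grid_rate_map(pop, n_positions)
    h = rates @ net.w.T  # (pos, n_dg)
    k = max(1, round_half_up(net.a_dg * net.n_dg))
    mask = kwta_batch(h, k)
    return np.maximum(h, 0.0) * mask


def drive_map(net: CompetitiveNetwork, pop: GridCellPopulation, n_positions: int) -> np.ndarray:
    """(n_positions, n_dg) rectified pre-inhibition tuning curves.

    The drive profile reflects a unit's learned spatial tuning independent
    of how often it wins the inhibitory competition; its spatial sparseness
    is the natural measure of tuning selectivity.
    """
    rates = grid_rate_map(pop, n_positions)
    return np.maximum(rates @ net.w.T, 0.0)


@dataclass
class PlaceFieldMetrics:
    n_fields: int
    mean_field_width: float | None  # track units; None if no field
    spatial_sparsity: float | None  # sparseness across positions; None if silent


def place_field_metrics(responses: np.ndarray) -> PlaceFieldMetrics:
    """Field count, width, and spatial sparseness of one unit's rate map.

    A field is a maximal contiguous run of positions (circular track) with
    rate >= 50% of the unit's peak (half-max convention); width is the run
    length in track units. Spatial sparseness applies the population
    sparseness formula across positions.
    """
    r = np.asarray(responses, dtype=float)
    if r.ndim != 1:
        raise ValueError("one unit's response map must be 1-D")
    peak = r.max()
    if peak <= 0:
        return PlaceFieldMetrics(0, None, None)
    above = r >= 0.5 * peak
    n_pos = r.size
    if above.all():
        n_fields, widths = 1, [1.0]
    else:
        # rotate so position 0 is below threshold -> runs never wrap
        start = int(np.argmin(above))
        rolled = np.roll(above, -start)
        edges = np.diff(rolled.astype(int))
        starts = np.flatnonzero(edges == 1) + 1
        ends = np.flatnonzero(edges == -1) + 1
        if rolled[0]:
            starts = np.r_[0, starts]
        if rolled[-1]:
            ends = np.r_[ends, rolled.size]
        n_fields = starts.size
        widths = [(e - s) / n_pos for s, e in zip(starts, ends)]
    ssq = float(np.dot(r, r))
    sp = (float(r.sum()) / n_pos) ** 2 / (ssq / n_pos)
    return PlaceFieldMetrics(n_fields, float(np.mean(widths)) if widths else None, sp)


@dataclass
class MossyProjection:
    """Sparse strong dentate -> CA3 wiring (~46 fibers per CA3 cell).

    With 10^6 granule cells this gives the very low dilution 46/10^6 =
    0.000046 that makes the CA3 code effectively a random selection.
    """

    n_dg: int
    n_ca3: int
    fan_in: int
    afferents: np.ndarray  # (n_ca3, fan_in), distinct dentate indices per row
    strength: float
    seed: int

    def __post_init__(self) -> None:
        self.afferents = np.asarray(self.afferents, dtype=np.int64)
        if self.afferents.shape != (self.n_ca3, self.fan_in):
            raise ValueError("afferent table must have shape (n_ca3, fan_in)")
        for row in self.afferents:
            if np.unique(row).size != self.fan_in:
                raise ValueError("mossy afferents must be distinct per CA3 cell")
        if self.strength <= 0:
            raise ValueError("mossy strength must be > 0")

    @property
    def dilution(self) -> float:
        return self.fan_in / self.n_dg


def build_mossy_projection(
    n_dg: int, n_ca3: int, seed: int, fan_in: int = 46, strength: float = 1.0
) -> MossyProjection:
    if not 1 <= fan_in <= n_dg:
        raise ValueError("fan_in must lie in [1, n_dg]")
    rng = np.random.default_rng(seed)
    aff = np.stack([rng.choice(n_dg, size=fan_in, replace=False) for _ in range(n_ca3)])
    return MossyProjection(n_dg, n_ca3, fan_in, aff, strength, seed)


def mossy_project(
    dg_pattern: np.ndarray,
    proj: MossyProjection,
    a_ca3: float,
    facilitation: float = 0.0,
) -> np.ndarray:
    """Drive CA3 through the mossy fibers and threshold to sparseness a_ca3.

    CA3 drive is the strength-weighted sum over each cell's fan_in dentate
    afferents; the inhibitory threshold (k-WTA at ``round(a_ca3 n_ca3)``)
    converts it to a sparse binary CA3 pattern. ``facilitation`` > 0 enables
    an experimental non-associative boost that amplifies strongly firing
    fibers (drive term raised to ``1 + facilitation``); off by default.
    """
    r = np.asarray(dg_pattern, dtype=float)
    if r.size != proj.n_dg:
        raise ValueError("dentate pattern length must equal n_dg")
    pre = r[proj.afferents]
    if facilitation > 0:
        pre = pre ** (1.0 + facilitation)
    h = proj.strength * pre.sum(axis=1)
    k = max(1, round_half_up(a_ca3 * proj.n_ca3))
    return kwta(h, k, output="binary")


def separation_index(
    inputs: PatternEnsemble | np.ndarray, outputs: PatternEnsemble | np.ndarray
) -> float:
    """Mean pairwise output correlation over mean pairwise input correlation.

    Values below 1 mean the stage decorrelated (separated) its inputs;
    0 means the outputs are fully decorrelated.
    """
    pin = inputs.patterns if isinstance(inputs, PatternEnsemble) else np.atleast_2d(inputs)
    pout = outputs.patterns if isinstance(outputs, PatternEnsemble) else np.atleast_2d(outputs)
    if pin.shape[0] != pout.shape[0]:
        raise ValueError("need equal numbers of input and output patterns")
    if pin.shape[0] < 2:
        raise ValueError("need at least two patterns")
    c_in = mean_pairwise_correlation(pin)
    c_out = mean_pairwise_correlation(pout)
    if c_in == 0:
        raise ValueError("inputs are already uncorrelated; index undefined")
    return c_out / c_in
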