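"""Model 2: histone marks on an Early/Late-compartment lattice.

The lattice of Model 1 is reinterpreted: entries are histones carrying
either the mark of interest ("1") or some other mark ("2"); empty sites
are newly synthesized, unmarked histones.  Rows are split into two
replication-timing compartments -- the first R/2 rows Early (E, proxy for
euchromatin) and the last R/2 Late (L, heterochromatin).  Histone transfer
at replication follows the same Gaussian diffusion rule as Model 1 with
two differences:

- two diffusion constants, D_EE > D_LL (diffusion is faster in open
  chromatin), applied to within-E and within-L transitions respectively;
  cross-compartment transfer is forbidden (loci in different timing
  compartments do not replicate at the same time);
- inter-row distances are compartment-scaled, x = s_c * |i - i'| with
  s_E > s_L, because early-replicating loci are less compact and sit
  further apart on average.

After each division, empty daughter sites repeatedly adopt the mark of a
uniformly chosen non-empty horizontal neighbour (nearest-neighbour mark
copying) until no empty site remains; this keeps total mark levels from
diluting away and stabilizes the emergent patterns.  Row signals
(count of "1"s per row) feed the Q similarity statistic; over ~50 cell
cycles three patterns emerge: EE pairs are more similar than LL pairs at
every distance, similarity decays with distance in both compartments, and
the decay is steeper for LL pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from dadsim._engine import transfer_columns
from dadsim.lattice_model import build_transfer_kernel
from dadsim.similarity_stats import q_similarity

EMPTY = 0
MARK_OF_INTEREST = 1
OTHER_MARK = 2

__all__ = [
    "EMPTY",
    "MARK_OF_INTEREST",
    "OTHER_MARK",
    "MarkedLattice",
    "CompartmentConfig",
    "init_marked_parent",
    "assign_compartment_distances",
    "build_compartment_kernel",
    "replicate_with_marks",
    "copy_marks",
    "simulate_mark_patterns",
]


@dataclass
class MarkedLattice:
    """R x N grid of marked histones with per-row compartment labels."""

    grid: np.ndarray

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2 or self.grid.shape[0] % 2 != 0:
            raise ValueError("marked lattice needs an even number of rows")

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @property
    def compartments(self) -> np.ndarray:
        """'E' for the first R/2 rows, 'L' for the last R/2."""
        half = self.n_rows // 2
        return np.array(["E"] * half + ["L"] * half)

    def row_signals(self) -> np.ndarray:
        """signal_i = number of marks of interest in row i."""
        return (self.grid == MARK_OF_INTEREST).sum(axis=1)


@dataclass
class CompartmentConfig:
    """Parameters of the two-compartment mark model.

    ``d_ee``/``d_ll`` are the diffusion constants for within-Early and
    within-Late transfer (arbitrary lattice units; defaults are the
    headline simulation values 1.2 and 0.07).  ``scale_e``/``scale_l``
    stretch lattice distances per compartment (s_E > s_L so EE pairs sit
    further apart on average).  ``mean_marks`` is the exponential mean of
    initial marks-of-interest per row (``mean_marks_late`` overrides it
    for L rows, for unequal-initial-signal variants).  ``no_diffusion``
    replaces both kernels with the identity (the no-diffusion control).
    """

    d_ee: float = 1.2
    d_ll: float = 0.07
    characteristic_time: float = 1.0
    scale_e: float = 2.0
    scale_l: float = 1.0
    mean_marks: float = 130.0
    mean_marks_late: float | None = None
    checkpoints: tuple = (0, 2, 8, 50)
    enforce_inequality: bool = True
    no_diffusion: bool = False

    def __post_init__(self):
        if self.enforce_inequality and not self.no_diffusion:
            if not self.d_ee > self.d_ll:
                raise ValueError(
                    f"expected D_EE > D_LL, got {self.d_ee} <= {self.d_ll}"
                )
            if not self.scale_e > self.scale_l:
                raise ValueError(
                    f"expected s_E > s_L, got {self.scale_e} <= {self.scale_l}"
                )

    @property
    def mu_late(self) -> float:
        return self.mean_marks if self.mean_marks_late is None else self.mean_marks_late


def init_marked_parent(n_rows: int, n_cols: int, config: CompartmentConfig,
                       rng: np.random.Generator) -> MarkedLattice:
    """Random initial parent: per row, k ~ Exponential(mean mu) marks.

    The draw is rounded to the nearest integer and clipped to [0, N]; k
    marks of interest are placed at uniformly random distinct columns and
    every other site carries the other-mark label, so no site is empty.
    """
    if n_rows % 2 != 0:
        raise ValueError("number of rows must be even (R/2 per compartment)")
    if n_cols <= 0:
        raise ValueError("number of columns must be positive")
    half = n_rows // 2
    grid = np.full((n_rows, n_cols), OTHER_MARK, dtype=np.int8)
    for i in range(n_rows):
        mu = config.mean_marks if i < half else config.mu_late
        k = 0
        if mu > 0:
            k = int(np.clip(np.rint(rng.exponential(mu)), 0, n_cols))
        if k:
            cols = rng.choice(n_cols, size=k, replace=False)
            grid[i, cols] = MARK_OF_INTEREST
    return MarkedLattice(grid=grid)


def assign_compartment_distances(n_rows: int, config: CompartmentConfig) -> np.ndarray:
    """Compartment-scaled distances; cross-compartment pairs are infinite.

    x_{i,i'} = s_E * |i - i'| when both rows are Early, s_L * |i - i'|
    when both are Late, and +inf (non-transferable) across compartments:
    donor and acceptor loci must replicate at the same time.
    """
    if n_rows % 2 != 0:
        raise ValueError("number of rows must be even")
    half = n_rows // 2
    idx = np.arange(n_rows)
    base = np.abs(idx[:, None] - idx[None, :]).astype(float)
    is_early = idx < half
    same_e = is_early[:, None] & is_early[None, :]
    same_l = ~is_early[:, None] & ~is_early[None, :]
    x = np.full((n_rows, n_rows), np.inf)
    x[same_e] = config.scale_e * base[same_e]
    x[same_l] = config.scale_l * base[same_l]
    return x


def build_compartment_kernel(n_rows: int, config: CompartmentConfig):
    """Block-diagonal transfer kernel: D_EE on the E block, D_LL on L.

    Returns an (R, R) row-stochastic matrix with zero cross-compartment
    mass, plus its row-wise CDF for sampling.  With ``no_diffusion`` the
    kernel is the identity: every histone lands on its own row.
    """
    if n_rows % 2 != 0:
        raise ValueError("number of rows must be even")
    if config.no_diffusion:
        probs = np.eye(n_rows)
    else:
        half = n_rows // 2
        block = np.abs(np.subtract.outer(np.arange(half), np.arange(half))).astype(float)
        k_e = build_transfer_kernel(
            config.scale_e * block, config.d_ee, config.characteristic_time
        ).probabilities
        k_l = build_transfer_kernel(
            config.scale_l * block, config.d_ll, config.characteristic_time
        ).probabilities
        probs = np.zeros((n_rows, n_rows))
        probs[:half, :half] = k_e
        probs[half:, half:] = k_l
    cdf = np.cumsum(probs, axis=1)
    cdf[:, -1] = 1.0
    return probs, cdf


def replicate_with_marks(parent: MarkedLattice, config: CompartmentConfig,
                         rng: np.random.Generator, cdf: np.ndarray | None = None):
    """One replication of the marked lattice into two daughters.

    Mechanics are identical to Model 1's transfer -- column-serial,
    product measure (1/2 daughter choice) x (kernel row), resample on
    collision -- except the kernel is compartment-restricted.  Both mark
    types are conserved per column across the two daughters.
    """
    if cdf is None:
        _, cdf = build_compartment_kernel(parent.n_rows, config)
    if cdf.shape[0] != parent.n_rows:
        raise ValueError("kernel/lattice dimension mismatch")
    g1, g2 = transfer_columns(parent.grid, cdf, rng)
    return MarkedLattice(grid=g1), MarkedLattice(grid=g2)


def copy_marks(daughter: MarkedLattice, rng: np.random.Generator) -> MarkedLattice:
    """Fill empty sites by nearest-neighbour mark copying.

    Synchronous passes: every empty site with at least one non-empty
    horizontal neighbour (same row, adjacent column) adopts the mark of a
    neighbour chosen uniformly among the non-empty ones; passes repeat
    until no empty site remains.  A row left entirely empty (it received
    no histones) is filled with the other-mark label -- new histones with
    no parental mark to copy.
    """
    grid = daughter.grid.copy()
    while True:
        empty = grid == EMPTY
        if not empty.any():
            break
        left = np.full_like(grid, EMPTY)
        left[:, 1:] = grid[:, :-1]
        right = np.full_like(grid, EMPTY)
        right[:, :-1] = grid[:, 1:]
        left_ok = left != EMPTY
        right_ok = right != EMPTY
        fillable = empty & (left_ok | right_ok)
        if not fillable.any():
            grid[empty] = OTHER_MARK
            break
        take_left = left_ok & (~right_ok | (rng.random(grid.shape) < 0.5))
        new_vals = np.where(take_left, left, right)
        grid[fillable] = new_vals[fillable]
    return MarkedLattice(grid=grid)


def _within_compartment_pairs(n_rows: int):
    half = n_rows // 2
    pairs = []
    for lo, hi, cls in ((0, half, "EE"), (half, n_rows, "LL")):
        for i1 in range(lo, hi):
            for i2 in range(i1 + 1, hi):
                pairs.append((i1, i2, cls))
    return pairs


def simulate_mark_patterns(n_rows: int = 20, n_cols: int = 200,
                           config: CompartmentConfig | None = None,
                           n_cycles: int | None = None, n_repeats: int = 100,
                           seed: int = 0):
    """Simulate Model 2 and record Q for every within-compartment pair.

    For each repeat, runs ``n_cycles`` cell cycles (default: the largest
    checkpoint) and at each checkpoint computes per-row signals and
    Q(i1, i2) for all EE and LL pairs, tagged with the compartment-scaled
    pair distance.  Returns ``(pairs, bias)``: a pair table with columns
    ``repeat, checkpoint, i1, i2, pair_class, distance, Q`` and a
    per-(repeat, checkpoint) table of mean-Early minus mean-Late signal
    (the no-directional-bias diagnostic).  Reproducible from ``seed``.
    """
    config = config or CompartmentConfig()
    checkpoints = sorted(set(int(c) for c in config.checkpoints))
    if any(c < 0 for c in checkpoints):
        raise ValueError("checkpoints must be non-negative")
    if n_cycles is None:
        n_cycles = max(checkpoints)
    if max(checkpoints) > n_cycles:
        raise ValueError("checkpoint beyond n_cycles")
    _, cdf = build_compartment_kernel(n_rows, config)
    pair_index = _within_compartment_pairs(n_rows)
    scale = {"EE": config.scale_e, "LL": config.scale_l}
    half = n_rows // 2

    pair_rows = []
    bias_rows = []

    def record(rep: int, cycle: int, lattice: MarkedLattice):
        signals = lattice.row_signals().astype(float)
        for i1, i2, cls in pair_index:
            pair_rows.append(
                (rep, cycle, i1, i2, cls, scale[cls] * abs(i1 - i2),
                 q_similarity(signals[i1], signals[i2]))
            )
        bias_rows.append(
            (rep, cycle, float(signals[:half].mean() - signals[half:].mean()))
        )

    for rep in range(n_repeats):
        rng = np.random.default_rng([int(seed), rep])
        parent = init_marked_parent(n_rows, n_cols, config, rng)
        if 0 in checkpoints:
            record(rep, 0, parent)
        for cycle in range(1, n_cycles + 1):
            d1, d2 = replicate_with_marks(parent, config, rng, cdf=cdf)
            d1 = copy_marks(d1, rng)
            d2 = copy_marks(d2, rng)
            parent = d1 if rng.integers(0, 2) == 0 else d2
            if cycle in checkpoints:
                record(rep, cycle, parent)

    pairs = pd.DataFrame(
        pair_rows,
        columns=["repeat", "checkpoint", "i1", "i2", "pair_class", "distance", "Q"],
    )
    bias = pd.DataFrame(bias_rows, columns=["repeat", "checkpoint", "signal_diff"])
    return pairs, bias
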