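"""Model 1: stochastic histone dilution at the replication fork.

A parent chromatin lattice has R rows (genomic loci, on the same or
different chromosomes) and N columns (nucleosome sites along each locus).
Every site initially carries a histone; one special row ``R*`` carries
biotin-tagged histones.  Each cell cycle, the replication fork is swept
column by column and every histone moves to the same column of one of two
daughter lattices, landing on row i' with probability proportional to a
Gaussian diffusion weight

    w(i, i') = (4 pi D T)^(-1/2) * exp(-x_{i,i'}^2 / (4 D T)),

with lattice distance x_{i,i'} = |i - i'|, diffusion constant D and
characteristic diffusion time T.  Empty daughter sites are refilled with
new untagged histones and one daughter becomes the next parent.  The
tagged fraction at row R* therefore decays from 1 with kinetics controlled
by D (only the product D*T is identifiable; callers conventionally fix
T = 1).  D carries arbitrary lattice units and is not physically
interpretable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
from scipy import optimize

from dadsim._engine import transfer_columns

EMPTY = 0
HISTONE = 1
TAGGED_HISTONE = 2

__all__ = [
    "EMPTY",
    "HISTONE",
    "TAGGED_HISTONE",
    "ChromatinLattice",
    "TransferKernel",
    "DilutionCurve",
    "FitResult",
    "lattice_distances",
    "build_transfer_kernel",
    "replicate_once",
    "fill_and_select",
    "simulate_dilution",
    "expected_dilution_oracle",
    "fit_diffusion_constant",
    "dad_size_estimate",
]


@dataclass
class ChromatinLattice:
    """R x N grid of nucleosome sites with one tagged row.

    Site states are ``EMPTY`` (0), ``HISTONE`` (1) or ``TAGGED_HISTONE``
    (2).  ``tagged_row`` records the index of the biotin-tagged locus R*.
    """

    grid: np.ndarray
    tagged_row: int

    def __post_init__(self):
        self.grid = np.asarray(self.grid, dtype=np.int8)
        if self.grid.ndim != 2:
            raise ValueError("lattice grid must be 2-dimensional")
        if not 0 <= self.tagged_row < self.grid.shape[0]:
            raise ValueError(
                f"tagged_row {self.tagged_row} outside [0, {self.grid.shape[0]})"
            )

    @property
    def n_rows(self) -> int:
        return self.grid.shape[0]

    @property
    def n_cols(self) -> int:
        return self.grid.shape[1]

    @classmethod
    def initialize(cls, n_rows: int, n_cols: int, tagged_row: int) -> "ChromatinLattice":
        """Fully occupied parent: histones everywhere, tags along row R*."""
        if n_rows <= 0 or n_cols <= 0:
            raise ValueError("lattice dimensions must be positive")
        grid = np.full((n_rows, n_cols), HISTONE, dtype=np.int8)
        if not 0 <= tagged_row < n_rows:
            raise ValueError(f"tagged_row {tagged_row} outside [0, {n_rows})")
        grid[tagged_row, :] = TAGGED_HISTONE
        return cls(grid=grid, tagged_row=tagged_row)

    def tagged_fraction(self) -> float:
        """Fraction of sites in row R* still carrying a tagged histone."""
        return float(np.mean(self.grid[self.tagged_row] == TAGGED_HISTONE))


@dataclass
class TransferKernel:
    """Row-stochastic diffusion transfer matrix.

    ``weights`` holds the (symmetric, unnormalized) Gaussian weights;
    ``probabilities`` is the per-source-row normalization of ``weights`` so
    each row sums to 1 -- a dislodged histone must land somewhere on the
    finite lattice.  ``cdf`` caches the row-wise cumulative distribution
    used for sampling.
    """

    distances: np.ndarray
    diffusion_constant: float
    characteristic_time: float
    weights: np.ndarray
    probabilities: np.ndarray
    cdf: np.ndarray = field(repr=False, default=None)

    @property
    def n_rows(self) -> int:
        return self.probabilities.shape[0]


def lattice_distances(n_rows: int) -> np.ndarray:
    """Model 1 inter-row distance matrix x_{i,i'} = |i - i'|."""
    idx = np.arange(n_rows)
    return np.abs(idx[:, None] - idx[None, :]).astype(float)


def build_transfer_kernel(distances: np.ndarray, diffusion_constant: float,
                          characteristic_time: float = 1.0) -> TransferKernel:
    """Build the Gaussian transfer kernel from a distance matrix.

    Only the product D*T enters the weights, so D and T are not separately
    identifiable; the convention is T = 1 with D free.  Infinite distances
    mark forbidden transitions (zero weight).

    Raises
    ------
    ValueError
        If the distance matrix is not square/symmetric with a zero
        diagonal or has negative entries, or if D <= 0 or T <= 0.
    """
    x = np.asarray(distances, dtype=float)
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("distance matrix must be square")
    finite = np.isfinite(x)
    if np.any(x[finite] < 0):
        raise ValueError("distances must be non-negative")
    if not np.array_equal(x, x.T):
        raise ValueError("distance matrix must be symmetric")
    if np.any(np.diag(x) != 0):
        raise ValueError("distance matrix must have a zero diagonal")
    if diffusion_constant <= 0:
        raise ValueError(f"diffusion constant must be positive, got {diffusion_constant}")
    if characteristic_time <= 0:
        raise ValueError(f"characteristic time must be positive, got {characteristic_time}")

    dt4 = 4.0 * diffusion_constant * characteristic_time
    with np.errstate(over="ignore"):
        weights = np.exp(-np.square(np.where(finite, x, np.inf)) / dt4) / np.sqrt(np.pi * dt4)
    weights[~finite] = 0.0
    row_sums = weights.sum(axis=1, keepdims=True)
    if np.any(row_sums == 0):
        raise ValueError("a kernel row has zero total weight")
    probabilities = weights / row_sums
    cdf = np.cumsum(probabilities, axis=1)
    cdf[:, -1] = 1.0
    return TransferKernel(
        distances=x,
        diffusion_constant=float(diffusion_constant),
        characteristic_time=float(characteristic_time),
        weights=weights,
        probabilities=probabilities,
        cdf=cdf,
    )


def replicate_once(parent: ChromatinLattice, kernel: TransferKernel,
                   rng: np.random.Generator):
    """One replication: distribute the parent's histones to two daughters.

    Columns are processed serially and transfers never cross columns
    (diffusion is fast relative to fork progression).  Within a column each
    histone picks a daughter uniformly and a destination row from its
    kernel row, resampling occupied sites.  Histone and tag counts are
    conserved per column across the two daughters.
    """
    if kernel.n_rows != parent.n_rows:
        raise ValueError(
            f"kernel dimension {kernel.n_rows} != lattice rows {parent.n_rows}"
        )
    g1, g2 = transfer_columns(parent.grid, kernel.cdf, rng)
    d1 = ChromatinLattice(grid=g1, tagged_row=parent.tagged_row)
    d2 = ChromatinLattice(grid=g2, tagged_row=parent.tagged_row)
    return d1, d2


def fill_and_select(daughter1: ChromatinLattice, daughter2: ChromatinLattice,
                    rng: np.random.Generator) -> ChromatinLattice:
    """Refill empty sites with new untagged histones; promote one daughter.

    Every ``EMPTY`` site becomes ``HISTONE`` (new histones carry no tag);
    one of the two completed daughters is returned as the next parent with
    probability 1/2 each.
    """
    for d in (daughter1, daughter2):
        d.grid[d.grid == EMPTY] = HISTONE
    return daughter1 if rng.integers(0, 2) == 0 else daughter2


@dataclass
class DilutionCurve:
    """Tagged-histone signal at locus R* per generation, with dispersion."""

    generations: np.ndarray
    mean_fraction: np.ndarray
    sd: np.ndarray
    n_replicates: int

    def __post_init__(self):
        self.generations = np.asarray(self.generations, dtype=int)
        self.mean_fraction = np.asarray(self.mean_fraction, dtype=float)
        self.sd = np.asarray(self.sd, dtype=float)
        if not (len(self.generations) == len(self.mean_fraction) == len(self.sd)):
            raise ValueError("generation/mean/sd lengths disagree")
        if np.any((self.mean_fraction < 0) | (self.mean_fraction > 1)):
            raise ValueError("fractions must lie in [0, 1]")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "generation": self.generations,
                "mean_fraction": self.mean_fraction,
                "sd": self.sd,
                "n_replicates": self.n_replicates,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "DilutionCurve":
        import pandas as pd

        df = pd.read_csv(path)
        required = {"generation", "mean_fraction", "sd", "n_replicates"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"dilution-curve CSV missing columns: {sorted(missing)}")
        return cls(
            generations=df["generation"].to_numpy(),
            mean_fraction=df["mean_fraction"].to_numpy(),
            sd=df["sd"].to_numpy(),
            n_replicates=int(df["n_replicates"].iloc[0]),
        )


def _replicate_rng(seed: int, replicate: int) -> np.random.Generator:
    # Counter scheme: changing the replicate count never reshuffles the
    # streams of earlier replicates.
    return np.random.default_rng([int(seed), int(replicate)])


def simulate_dilution(n_rows: int, n_cols: int, tagged_row: int,
                      diffusion_constant: float, n_generations: int,
                      n_replicates: int, seed: int,
                      characteristic_time: float = 1.0) -> DilutionCurve:
    """Simulate tagged-histone dilution at row R* over cell cycles.

    Runs ``n_replicates`` independent chains of replicate -> refill ->
    promote, recording the tagged fraction at row R* after each of
    ``n_generations`` cycles.  Generation 0 is the initial state
    (fraction 1).  Fully reproducible from ``seed``.
    """
    if n_rows <= 0 or n_cols <= 0 or n_generations <= 0 or n_replicates <= 0:
        raise ValueError("all simulation sizes must be positive")
    kernel = build_transfer_kernel(
        lattice_distances(n_rows), diffusion_constant, characteristic_time
    )
    fractions = np.empty((n_replicates, n_generations + 1))
    fractions[:, 0] = 1.0
    for rep in range(n_replicates):
        rng = _replicate_rng(seed, rep)
        parent = ChromatinLattice.initialize(n_rows, n_cols, tagged_row)
        for g in range(1, n_generations + 1):
            d1, d2 = replicate_once(parent, kernel, rng)
            parent = fill_and_select(d1, d2, rng)
            fractions[rep, g] = parent.tagged_fraction()
    return DilutionCurve(
        generations=np.arange(n_generations + 1),
        mean_fraction=fractions.mean(axis=0),
        sd=fractions.std(axis=0, ddof=1) if n_replicates > 1 else np.zeros(n_generations + 1),
        n_replicates=n_replicates,
    )


def expected_dilution_oracle(kernel: TransferKernel, tagged_row: int,
                             n_generations: int) -> np.ndarray:
    """Deterministic expectation of the dilution curve, ignoring exclusion.

    In expectation a tagged histone at row i survives into the promoted
    daughter's row i' with probability (1/2) K[i, i'], so the expected
    tagged-count vector evolves as v_{g+1} = (1/2) K^T v_g.  Returns
    f(g) = v_g[R*] / v_0[R*] for g = 0..n_generations; f(0) = 1 and f is
    non-increasing.  Site exclusion (one histone per site) is ignored,
    which at half occupancy biases f by at most a few percent.
    """
    if not 0 <= tagged_row < kernel.n_rows:
        raise ValueError("tagged_row outside kernel dimension")
    v = np.zeros(kernel.n_rows)
    v[tagged_row] = 1.0
    half_kt = 0.5 * kernel.probabilities.T
    out = np.empty(n_generations + 1)
    out[0] = 1.0
    for g in range(1, n_generations + 1):
        v = half_kt @ v
        out[g] = v[tagged_row]
    return out


class FitResult(NamedTuple):
    diffusion_constant: float
    objective: float
    flat_objective: bool


def fit_diffusion_constant(observed: DilutionCurve, n_rows: int, n_cols: int,
                           tagged_row: int, search_interval=(1e-3, 10.0),
                           characteristic_time: float = 1.0,
                           n_replicates: int = 100, seed: int = 0,
                           use_simulation: bool = False,
                           n_grid: int = 25) -> FitResult:
    """One-parameter least-squares fit of the diffusion constant D.

    Minimizes the sum of squared differences between the observed mean
    curve and the model mean curve at the observed generations, over a
    25-point logarithmic grid on ``search_interval`` refined by
    golden-section search (relative tolerance 1e-3).  The model mean is
    the deterministic expectation by default; ``use_simulation=True``
    swaps in the stochastic simulator mean (same seed at every candidate D
    so the objective stays smooth).  D is the paper-style single free
    parameter; T stays fixed.
    """
    if len(observed.generations) < 3:
        raise ValueError("observed curve must span at least 3 generations")
    d_lo, d_hi = float(search_interval[0]), float(search_interval[1])
    if d_lo <= 0 or d_hi <= d_lo:
        raise ValueError("search interval must be positive and increasing")
    gens = observed.generations
    target = observed.mean_fraction
    n_gen = int(gens.max())
    distances = lattice_distances(n_rows)

    def objective(d: float) -> float:
        if use_simulation:
            curve = simulate_dilution(
                n_rows, n_cols, tagged_row, d, n_gen, n_replicates, seed,
                characteristic_time,
            ).mean_fraction
        else:
            kernel = build_transfer_kernel(distances, d, characteristic_time)
            curve = expected_dilution_oracle(kernel, tagged_row, n_gen)
        return float(np.sum((curve[gens] - target) ** 2))

    grid = np.geomspace(d_lo, d_hi, n_grid)
    values = np.array([objective(d) for d in grid])
    flat = float(values.max() - values.min()) < 1e-12
    if flat:
        warnings.warn("objective is flat across the search interval")
        return FitResult(float(grid[0]), float(values[0]), True)
    best = int(np.argmin(values))
    if best == 0 or best == n_grid - 1:
        return FitResult(float(grid[best]), float(values[best]), False)
    # Golden-section refinement on log10(D) inside the bracketing cells.
    lo, hi = np.log10(grid[best - 1]), np.log10(grid[best + 1])
    res = optimize.minimize_scalar(
        lambda t: objective(10.0 ** t),
        bounds=(lo, hi),
        method="bounded",
        options={"xatol": 1e-3 * max(abs(lo), abs(hi), 1.0)},
    )
    d_hat = float(10.0 ** res.x)
    obj = float(res.fun)
    if obj > values[best]:  # refinement never worsens the grid optimum
        d_hat, obj = float(grid[best]), float(values[best])
    return FitResult(d_hat, obj, False)


def dad_size_estimate(diffusion_constant_um2_s: float, time_s: float) -> float:
    """Rough upper bound on the diffusion-accessible-domain radius, in um.

    sqrt(6 * D * t) for a physical diffusion constant D (um^2/s) and a
    diffusion time t (s): the RMS 3D displacement of a freely diffusing
    particle.  With D ~ 10 um^2/s and t ~ 1 s this is ~8 um, comparable to
    inter-chromosome distances.
    """
    if diffusion_constant_um2_s <= 0 or time_s <= 0:
        raise ValueError("diffusion constant and time must be positive")
    return float(np.sqrt(6.0 * diffusion_constant_um2_s * time_s))
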