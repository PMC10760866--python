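"""Synthetic fixtures with planted diffusion-like similarity structure.

Everything the rest of the package consumes can be generated here without
downloads: tagged-histone dilution curves with a known diffusion constant,
and a coherent synthetic "genome" -- chromosome sizes, early/late
replication-timing bedGraph tracks whose score difference is bimodal,
per-mark ChIP-seq peak tracks, and a compartment-structured ("plaid")
Hi-C contact matrix.

The planted mark structure is a Gaussian field on log10 signals: bins of
the same replication class on the same chromosome are correlated with
exp(-separation / decay_scale), with a class-specific decay scale and
marginal sd.  For a bivariate normal pair with correlation rho the
difference of log-signals is N(0, 2 sigma^2 (1 - rho)), so the median Q
is 0.6745 * sigma * sqrt(2 (1 - rho)) -- analytically controllable.  The
default "planted" mark uses a longer decay scale and smaller sigma for
EARLY bins, planting all three diffusion patterns (EE more similar
everywhere, similarity decaying with distance, steeper decay for LL); the
"null" mark has no spatial structure and equal sigmas; the
"constitutive-like" negative control (an H3K9me3 analogue) has no spatial
structure and *more* similar LATE bins.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dadsim.lattice_model import (
    DilutionCurve,
    build_transfer_kernel,
    expected_dilution_oracle,
    lattice_distances,
)

__all__ = [
    "MarkSpec",
    "SyntheticGenomeSpec",
    "SyntheticGenome",
    "synth_dilution_curve",
    "make_truth_bins",
    "synth_timing_tracks",
    "planted_log_signals",
    "synth_peak_track",
    "synth_hic",
    "synth_genome",
]


def synth_dilution_curve(d_true: float, n_rows: int, n_cols: int,
                         tagged_row: int, n_generations: int,
                         noise_sd: float, seed: int,
                         characteristic_time: float = 1.0) -> DilutionCurve:
    """Expected dilution curve for a known D plus Gaussian noise.

    The deterministic expectation is perturbed with independent
    N(0, noise_sd^2) noise and clipped to [0, 1]; generation 0 stays
    exactly 1.  With ``noise_sd=0`` the curve is exactly the expectation.
    """
    kernel = build_transfer_kernel(
        lattice_distances(n_rows), d_true, characteristic_time
    )
    curve = expected_dilution_oracle(kernel, tagged_row, n_generations)
    rng = np.random.default_rng(seed)
    noisy = np.clip(curve + rng.normal(0.0, noise_sd, size=curve.shape), 0.0, 1.0)
    noisy[0] = 1.0
    return DilutionCurve(
        generations=np.arange(n_generations + 1),
        mean_fraction=noisy,
        sd=np.full(curve.shape, float(noise_sd)),
        n_replicates=1,
    )


@dataclass
class MarkSpec:
    """Planted per-mark signal structure.

    ``log_mean``: mean log10 aggregate signal per bin. ``sigma_early`` /
    ``sigma_late``: marginal sd of log10 signal for EARLY / LATE bins.
    ``decay_early`` / ``decay_late``: correlation ranges of the log-signal
    field in planted-coordinate units (0 = no spatial structure): bins of
    the same class closer than the range in the latent nuclear space are
    correlated, including across chromosomes.  For the diffusion pattern
    the EARLY range must be >= the LATE one (faster diffusion homogenizes
    euchromatin over larger neighbourhoods) and sigma_early <
    sigma_late (EE pairs more similar).
    """

    log_mean: float = 4.0
    sigma_early: float = 0.20
    sigma_late: float = 0.80
    decay_early: float = 20.0
    decay_late: float = 12.0


@dataclass
class SyntheticGenomeSpec:
    """Layout and planted structure of the synthetic genome.

    Eight 60 Mb chromosomes at 1 Mb bins (480 bins): large enough that
    per-seed bootstrap calls on the three patterns are well powered,
    small enough for seconds-scale analysis.  Replication
    classes alternate in blocks of ``block_bins`` bins, producing a plaid
    compartment pattern.  The timing score difference is bimodal with
    modes at +-``diff_mode`` (aggregated score units) and sd
    ``diff_sd``, straddling the +-1000 classification cutoff.

    Every bin also receives a latent 1D nuclear coordinate
    u = chromosome offset + coord_scale * bin position (offsets drawn so
    chromosome territories overlap).  The coordinate drives both the mark
    fields (correlation decays with |du| at class-specific ranges) and
    the Hi-C plaid (same-class pairs close in u contact more often), so
    spatial proximity measured from the contact matrix genuinely predicts
    planted mark similarity -- including for inter-chromosomal pairs, as
    diffusion-accessible domains would produce.
    """

    n_chromosomes: int = 8
    chrom_length: int = 60_000_000
    bin_size: int = 1_000_000
    block_bins: int = 6
    diff_mode: float = 3000.0
    diff_sd: float = 800.0
    base_score: float = 10000.0
    coord_scale: float = 0.5
    offset_factor: float = 7.0
    marks: dict = field(default_factory=lambda: {
        "planted": MarkSpec(),
        "null": MarkSpec(sigma_early=0.35, sigma_late=0.35,
                         decay_early=0.0, decay_late=0.0),
        "constitutive_like": MarkSpec(sigma_early=0.45, sigma_late=0.30,
                                      decay_early=0.0, decay_late=0.0),
    })
    hic_intra_base: float = 15.0
    hic_decay_exponent: float = 0.6
    hic_inter_base: float = 1.0
    hic_plaid_strength: float = 2.0
    hic_plaid_range: float = 6.0
    hic_noise_sd: float = 0.15

    def __post_init__(self):
        for name, m in self.marks.items():
            if m.decay_early or m.decay_late:
                if m.decay_early < m.decay_late:
                    raise ValueError(
                        f"mark {name!r}: EARLY decay scale must be >= LATE"
                    )

    def chrom_sizes(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "chrom": [f"chrS{i + 1}" for i in range(self.n_chromosomes)],
                "size": self.chrom_length,
            }
        )


def make_truth_bins(spec: SyntheticGenomeSpec) -> pd.DataFrame:
    """1 Mb bin table with the planted replication class per bin.

    Classes alternate deterministically in blocks of ``block_bins`` bins
    along each chromosome ('EARLY' first), mimicking A/B-compartment
    plaid structure.
    """
    rows = []
    for c in range(spec.n_chromosomes):
        chrom = f"chrS{c + 1}"
        n_bins = spec.chrom_length // spec.bin_size
        for b in range(n_bins):
            cls = "EARLY" if (b // spec.block_bins) % 2 == 0 else "LATE"
            rows.append((chrom, b * spec.bin_size, (b + 1) * spec.bin_size, cls))
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "true_class"])


def synth_timing_tracks(spec: SyntheticGenomeSpec, truth: pd.DataFrame,
                        rng: np.random.Generator):
    """Early and late bedGraph tracks realizing a bimodal score difference.

    Per bin the aggregated early-minus-late score is drawn from
    N(+diff_mode, diff_sd) for EARLY truth bins and N(-diff_mode, diff_sd)
    for LATE ones; the early and late per-bp values are chosen so the
    bin-aggregated scores (value * overlap bp) hit those targets.  Each
    bin is emitted as two bedGraph intervals split at a random interior
    point, so aggregation must be fragmentation-invariant to recover the
    targets.
    """
    sign = np.where(truth["true_class"].to_numpy() == "EARLY", 1.0, -1.0)
    diff = rng.normal(spec.diff_mode * sign, spec.diff_sd)
    early_total = spec.base_score + diff / 2.0
    late_total = spec.base_score - diff / 2.0
    width = (truth["end"] - truth["start"]).to_numpy()
    rows_e, rows_l = [], []
    for (chrom, start, end), ev, lv, w in zip(
        truth[["chrom", "start", "end"]].itertuples(index=False),
        early_total, late_total, width,
    ):
        split = start + int(rng.integers(1, w))
        for lo, hi in ((start, split), (split, end)):
            rows_e.append((chrom, lo, hi, ev / w))
            rows_l.append((chrom, lo, hi, lv / w))
    cols = ["chrom", "start", "end", "value"]
    return pd.DataFrame(rows_e, columns=cols), pd.DataFrame(rows_l, columns=cols)


def _corr_field(positions: np.ndarray, corr_range: float,
                rng: np.random.Generator) -> np.ndarray:
    """Standard-normal field with triangular correlation along positions.

    corr(z_i, z_j) = max(0, 1 - |x_i - x_j| / corr_range): the covariance
    of a moving average of white noise, so nearby bins are strongly
    correlated while bins further apart than ``corr_range`` are exactly
    independent -- high local similarity without long-range dependence.
    ``corr_range <= 0`` yields an i.i.d. field.
    """
    n = len(positions)
    if corr_range <= 0 or n == 0:
        return rng.standard_normal(n)
    cov = np.maximum(
        0.0, 1.0 - np.abs(positions[:, None] - positions[None, :]) / corr_range
    )
    cov[np.diag_indices(n)] += 1e-9
    return np.linalg.cholesky(cov) @ rng.standard_normal(n)


def planted_coordinates(spec: SyntheticGenomeSpec, truth: pd.DataFrame,
                        rng: np.random.Generator) -> np.ndarray:
    """Latent 1D nuclear coordinate per bin.

    u = chromosome offset + coord_scale * bin position, with offsets
    drawn uniformly over ``offset_factor`` chromosome coordinate spans so
    chromosome territories partially interleave: some inter-chromosomal
    bin pairs end up spatially close, as they do in a real nucleus.
    """
    chrom = truth["chrom"].to_numpy()
    bin_pos = (truth["start"].to_numpy() // spec.bin_size).astype(float)
    span = (spec.chrom_length // spec.bin_size) * spec.coord_scale
    offsets = {c: rng.uniform(0.0, spec.offset_factor * span)
               for c in pd.unique(chrom)}
    return np.array([offsets[c] for c in chrom]) + spec.coord_scale * bin_pos


def planted_log_signals(spec: SyntheticGenomeSpec, truth: pd.DataFrame,
                        coords: np.ndarray, mark: MarkSpec,
                        rng: np.random.Generator) -> np.ndarray:
    """Per-bin log10 aggregate signal with the planted covariance.

    EARLY and LATE bins carry two independent Gaussian fields whose
    correlation decays with the latent-coordinate separation |du| at the
    class-specific range (zero correlation across classes), so same-class
    bins that are spatially close -- on the same chromosome or not -- have
    similar signals.
    """
    n = len(truth)
    z = np.zeros(n)
    for cls, decay, sigma in (
        ("EARLY", mark.decay_early, mark.sigma_early),
        ("LATE", mark.decay_late, mark.sigma_late),
    ):
        idx = np.flatnonzero(truth["true_class"].to_numpy() == cls)
        z[idx] = sigma * _corr_field(coords[idx], decay, rng)
    return mark.log_mean + z


def synth_peak_track(spec: SyntheticGenomeSpec, truth: pd.DataFrame,
                     log_signals: np.ndarray,
                     rng: np.random.Generator) -> pd.DataFrame:
    """narrowPeak records whose per-bin sum(H_p * W_p) hits the target.

    Each bin's target aggregate 10**log_signal is split across 1-10 peaks
    with random widths and positions inside the bin; peak heights are set
    so the contributions sum exactly to the target.  Records are sorted by
    (chrom, start).
    """
    rows = []
    targets = np.power(10.0, np.asarray(log_signals, dtype=float))
    for (chrom, start, end), target in zip(
        truth[["chrom", "start", "end"]].itertuples(index=False), targets
    ):
        k = int(rng.integers(1, 11))
        widths = rng.integers(200, 2001, size=k)
        fractions = rng.dirichlet(np.ones(k))
        starts = rng.integers(start, end - int(widths.max()), size=k)
        for p in range(k):
            w = int(widths[p])
            h = fractions[p] * target / w
            rows.append(
                (chrom, int(starts[p]), int(starts[p]) + w,
                 f"{chrom}_{start}_{p}", 0, ".", h, -1.0, -1.0, -1)
            )
    df = pd.DataFrame(
        rows,
        columns=["chrom", "start", "end", "name", "score", "strand",
                 "signal_value", "p_value", "q_value", "peak"],
    )
    return df.sort_values(["chrom", "start"], kind="stable").reset_index(drop=True)


def synth_hic(spec: SyntheticGenomeSpec, truth: pd.DataFrame,
              coords: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Symmetric plaid contact matrix with power-law distance decay.

    Intra-chromosomal counts decay as (1 + separation)^(-alpha);
    inter-chromosomal counts start from a small base rate.  Same-class
    pairs that are close in the latent coordinate gain a plaid boost
    (1 + strength * max(0, 1 - |du| / range)), the compartment signature
    that makes Pearson row correlation track planted spatial proximity.
    Multiplicative lognormal noise; exactly symmetric and non-negative.
    """
    n = len(truth)
    chrom = truth["chrom"].to_numpy()
    cls = truth["true_class"].to_numpy()
    bin_pos = (truth["start"].to_numpy() // spec.bin_size).astype(float)
    same_chrom = chrom[:, None] == chrom[None, :]
    same_class = cls[:, None] == cls[None, :]
    sep = np.abs(bin_pos[:, None] - bin_pos[None, :])
    base = np.where(
        same_chrom,
        spec.hic_intra_base * np.power(1.0 + sep, -spec.hic_decay_exponent),
        spec.hic_inter_base,
    )
    du = np.abs(coords[:, None] - coords[None, :])
    plaid = np.maximum(0.0, 1.0 - du / spec.hic_plaid_range)
    boost = 1.0 + spec.hic_plaid_strength * plaid * same_class
    noise = np.exp(spec.hic_noise_sd * rng.standard_normal((n, n)))
    noise = np.sqrt(noise * noise.T)  # symmetric multiplicative noise
    return base * boost * noise


@dataclass
class SyntheticGenome:
    """In-memory bundle of one generated synthetic genome."""

    spec: SyntheticGenomeSpec
    truth: pd.DataFrame
    chrom_sizes: pd.DataFrame
    early_track: pd.DataFrame
    late_track: pd.DataFrame
    peaks: dict                      # mark -> narrowPeak DataFrame
    log_signals: dict                # mark -> per-bin log10 signal
    coords: np.ndarray               # latent nuclear coordinate per bin
    hic: np.ndarray

    def write(self, outdir) -> dict:
        """Write all files; returns {name: path}.  Formats round-trip
        losslessly through the pipeline's readers."""
        from dadsim.epigenome_pipeline import write_dense_hic

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {}
        p = outdir / "chrom.sizes"
        self.chrom_sizes.to_csv(p, sep="\t", header=False, index=False)
        paths["chrom_sizes"] = p
        for name, track in (("early", self.early_track), ("late", self.late_track)):
            p = outdir / f"{name}.bedGraph"
            track.to_csv(p, sep="\t", header=False, index=False)
            paths[f"{name}_track"] = p
        for mark, peaks in self.peaks.items():
            p = outdir / f"{mark}.narrowPeak"
            peaks.to_csv(p, sep="\t", header=False, index=False)
            paths[f"peaks_{mark}"] = p
        p = outdir / "hic_matrix.tsv"
        write_dense_hic(p, self.hic, self.truth)
        paths["hic"] = p
        p = outdir / "truth.tsv"
        self.truth.to_csv(p, sep="\t", index=False)
        paths["truth"] = p
        return paths


def synth_genome(spec: SyntheticGenomeSpec | None = None,
                 seed: int = 0) -> SyntheticGenome:
    """Generate the full synthetic genome bundle, reproducibly from seed.

    Component streams are derived from the root seed with fixed counters,
    so e.g. adding a mark never reshuffles the Hi-C matrix.
    """
    spec = spec or SyntheticGenomeSpec()
    truth = make_truth_bins(spec)
    coords = planted_coordinates(spec, truth, np.random.default_rng([seed, 3]))
    early, late = synth_timing_tracks(spec, truth, np.random.default_rng([seed, 0]))
    log_signals = {}
    peaks = {}
    for k, (mark, mspec) in enumerate(sorted(spec.marks.items())):
        rng = np.random.default_rng([seed, 1, k])
        ls = planted_log_signals(spec, truth, coords, mspec, rng)
        log_signals[mark] = ls
        peaks[mark] = synth_peak_track(spec, truth, ls, rng)
    hic = synth_hic(spec, truth, coords, np.random.default_rng([seed, 2]))
    return SyntheticGenome(
        spec=spec, truth=truth, chrom_sizes=spec.chrom_sizes(),
        early_track=early, late_track=late, peaks=peaks,
        log_signals=log_signals, coords=coords, hic=hic,
    )
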