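"""Detection of diffusion-induced histone-mark similarity patterns.

The empirical counterpart of the lattice predictions: the genome is tiled
into 1 Mb bins; each bin is classified as EARLY or LATE replicating from
the difference of aggregated early and late Repli-seq scores with a
symmetric cutoff (strictly greater than +cutoff -> EARLY, strictly less
than -cutoff -> LATE, otherwise UNCLASSIFIED); ChIP-seq peaks are
aggregated into a per-bin, per-mark signal sum(H_p * W_p) over peak
heights and (overlap-clipped) widths; spatial proximity between bins is
the Pearson correlation of their rows of the normalized Hi-C contact
matrix (observed counts and observed/expected enrichment are alternative
metrics).  All within-class pairs (EE = both EARLY, LL = both LATE) are
formed, optionally restricted to intra- or inter-chromosomal scope, their
Q values computed, and the binned-median / chance-median / slope /
delta-delta summaries assembled per mark.

Coordinates are 0-based half-open (BED convention) throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from dadsim import similarity_stats as ss

EARLY = "EARLY"
LATE = "LATE"
UNCLASSIFIED = "UNCLASSIFIED"

__all__ = [
    "read_chrom_sizes",
    "read_bedgraph",
    "read_narrowpeak",
    "read_dense_hic",
    "write_dense_hic",
    "bin_genome",
    "score_and_classify",
    "peak_signal_per_bin",
    "spatial_proximity",
    "ProximityMatrix",
    "build_pair_table",
    "run_pattern_analysis",
    "pattern_directions",
    "pattern_signs",
]


# ---------------------------------------------------------------- file I/O

def read_chrom_sizes(path) -> pd.DataFrame:
    """Two-column TSV of chromosome name and length."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 2:
                raise ValueError(f"{path}:{lineno}: expected 'chrom<TAB>size'")
            try:
                size = int(parts[1])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: size is not an integer") from exc
            if size <= 0:
                raise ValueError(f"{path}:{lineno}: size must be positive")
            rows.append((parts[0], size))
    return pd.DataFrame(rows, columns=["chrom", "size"])


def read_bedgraph(path) -> pd.DataFrame:
    df = pd.read_csv(
        path, sep="\t", comment="#", header=None,
        names=["chrom", "start", "end", "value"],
        dtype={"chrom": str, "start": np.int64, "end": np.int64, "value": float},
    )
    if (df["end"] <= df["start"]).any():
        raise ValueError(f"{path}: bedGraph interval with end <= start")
    return df

_NARROWPEAK_COLS = [
    "chrom", "start", "end", "name", "score",
    "strand", "signal_value", "p_value", "q_value", "peak",
]


def read_narrowpeak(path) -> pd.DataFrame:
    """ENCODE narrowPeak (BED6+4); also accepts 5-column BED with a score.

    The peak height H_p is narrowPeak's signalValue, or the score column
    for plain BED input.
    """
    df = pd.read_csv(path, sep="\t", comment="#", header=None)
    if df.shape[1] >= 10:
        df = df.iloc[:, :10]
        df.columns = _NARROWPEAK_COLS
    elif df.shape[1] >= 5:
        df = df.iloc[:, :5]
        df.columns = ["chrom", "start", "end", "name", "score"]
        df["signal_value"] = df["score"].astype(float)
    else:
        raise ValueError(f"{path}: expected narrowPeak (>=10 cols) or BED5")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_dense_hic(path):
    """Dense tab-delimited contact matrix with 'chrom:start-end' labels.

    Returns ``(matrix, labels)`` where labels is a DataFrame with columns
    chrom, start, end aligned to the matrix rows.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValueError(f"{path}: row and column bin labels disagree")
    labels = []
    for lab in df.index:
        chrom, span = lab.rsplit(":", 1)
        start, end = span.split("-")
        labels.append((chrom, int(start), int(end)))
    return df.to_numpy(float), pd.DataFrame(labels, columns=["chrom", "start", "end"])


def write_dense_hic(path, matrix: np.ndarray, bins: pd.DataFrame) -> None:
    labels = [f"{c}:{s}-{e}" for c, s, e in zip(bins["chrom"], bins["start"], bins["end"])]
    pd.DataFrame(matrix, index=labels, columns=labels).to_csv(path, sep="\t")


# ------------------------------------------------------------ binning

def bin_genome(chrom_sizes: pd.DataFrame, bin_size: int = 1_000_000) -> pd.DataFrame:
    """Tile each chromosome into fixed-size bins (last bin truncated)."""
    if bin_size <= 0:
        raise ValueError("bin size must be positive")
    rows = []
    for chrom, size in zip(chrom_sizes["chrom"], chrom_sizes["size"]):
        for start in range(0, int(size), bin_size):
            rows.append((chrom, start, min(start + bin_size, int(size))))
    return pd.DataFrame(rows, columns=["chrom", "start", "end"])


def _aggregate_track(bins: pd.DataFrame, track: pd.DataFrame,
                     bin_size: int) -> tuple[np.ndarray, int]:
    """Sum of value * overlap-bp per bin; returns (scores, n_skipped)."""
    offsets = {}
    pos = 0
    counts = {}
    for chrom, grp in bins.groupby("chrom", sort=False):
        offsets[chrom] = pos
        counts[chrom] = len(grp)
        pos += len(grp)
    scores = np.zeros(len(bins))
    n_skipped = 0
    for chrom, start, end, value in zip(
        track["chrom"], track["start"], track["end"], track["value"]
    ):
        if chrom not in offsets:
            n_skipped += 1
            continue
        off, n_bins_c = offsets[chrom], counts[chrom]
        b0 = int(start) // bin_size
        b1 = (int(end) - 1) // bin_size
        for b in range(b0, b1 + 1):
            if b >= n_bins_c:
                break
            lo = max(int(start), b * bin_size)
            hi = min(int(end), (b + 1) * bin_size)
            if hi > lo:
                scores[off + b] += value * (hi - lo)
    return scores, n_skipped


def score_and_classify(bins: pd.DataFrame, early_track: pd.DataFrame,
                       late_track: pd.DataFrame, cutoff: float = 1000.0,
                       bin_size: int = 1_000_000) -> pd.DataFrame:
    """Aggregate timing scores into bins and classify EARLY/LATE.

    The early/late score of a bin is the sum over track intervals of
    value * overlapping base pairs -- invariant to interval fragmentation.
    A bin is EARLY iff early - late > +cutoff, LATE iff < -cutoff, else
    UNCLASSIFIED (strict inequalities: ties are unclassified).  Track
    intervals on chromosomes absent from the bins are skipped with a
    warning and counted in ``df.attrs['n_skipped_intervals']``.
    """
    out = bins.copy()
    early, sk1 = _aggregate_track(bins, early_track, bin_size)
    late, sk2 = _aggregate_track(bins, late_track, bin_size)
    if sk1 + sk2:
        warnings.warn(f"skipped {sk1 + sk2} track intervals on unknown chromosomes")
    out["early_score"] = early
    out["late_score"] = late
    out["score_diff"] = early - late
    out["rep_class"] = np.select(
        [out["score_diff"] > cutoff, out["score_diff"] < -cutoff],
        [EARLY, LATE],
        default=UNCLASSIFIED,
    )
    out.attrs["n_skipped_intervals"] = sk1 + sk2
    return out


def peak_signal_per_bin(bins: pd.DataFrame, peaks: pd.DataFrame, mark: str,
                        bin_size: int = 1_000_000) -> pd.DataFrame:
    """Per-bin aggregate ChIP-seq signal sum_p H_p * W_p for one mark.

    A peak contributes to every bin it overlaps, with W_p clipped to the
    overlap width inside the bin, so total peak mass is conserved across
    bin boundaries.  Records with end <= start are rejected and counted in
    ``df.attrs['n_rejected_peaks']``.
    """
    valid = peaks["end"] > peaks["start"]
    n_rejected = int((~valid).sum())
    track = pd.DataFrame(
        {
            "chrom": peaks.loc[valid, "chrom"],
            "start": peaks.loc[valid, "start"],
            "end": peaks.loc[valid, "end"],
            "value": peaks.loc[valid, "signal_value"].astype(float),
        }
    )
    scores, n_skipped = _aggregate_track(bins, track, bin_size)
    out = bins.copy()
    out[f"signal_{mark}"] = scores
    out.attrs.update(bins.attrs)
    out.attrs["n_rejected_peaks"] = n_rejected
    out.attrs["n_skipped_intervals"] = out.attrs.get("n_skipped_intervals", 0) + n_skipped
    return out


# ------------------------------------------------------- spatial proximity

@dataclass
class ProximityMatrix:
    """Symmetric bin-by-bin spatial-proximity values plus a validity mask."""

    values: np.ndarray
    valid: np.ndarray
    metric: str


def _pearson_proximity(matrix: np.ndarray) -> np.ndarray:
    """Pairwise Pearson correlation of rows, masking self-contact entries.

    For a pair (a, b) the correlation is computed over all columns except
    a and b (the diagonal entries of the two rows), so a bin's
    self-contact never inflates its own proximity.
    """
    n = matrix.shape[0]
    out = np.eye(n)
    cols = np.arange(n)
    for a in range(n):
        row_a = matrix[a]
        for b in range(a + 1, n):
            keep = (cols != a) & (cols != b)
            x = row_a[keep]
            y = matrix[b][keep]
            xc = x - x.mean()
            yc = y - y.mean()
            denom = np.sqrt((xc @ xc) * (yc @ yc))
            r = (xc @ yc) / denom if denom > 0 else np.nan
            out[a, b] = out[b, a] = r
    return out


def _enrichment(matrix: np.ndarray, bins: pd.DataFrame) -> np.ndarray:
    """Observed / expected contact enrichment.

    Expected intra-chromosomal contact at genomic separation s is the mean
    observed intra count at that separation (pooled over chromosomes);
    expected inter-chromosomal contact is the genome-wide mean of all
    inter entries.
    """
    n = matrix.shape[0]
    chrom = bins["chrom"].to_numpy()
    # per-chromosome bin index
    local = np.zeros(n, dtype=int)
    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        local[idx] = np.arange(len(idx))
    same = chrom[:, None] == chrom[None, :]
    sep = np.abs(local[:, None] - local[None, :])
    expected = np.empty_like(matrix)
    inter_vals = matrix[~same]
    inter_mean = inter_vals.mean() if inter_vals.size else np.nan
    for s in np.unique(sep[same]):
        mask = same & (sep == s)
        expected[mask] = matrix[mask].mean()
    expected[~same] = inter_mean
    with np.errstate(divide="ignore", invalid="ignore"):
        return np.where(expected > 0, matrix / expected, np.nan)


def spatial_proximity(matrix: np.ndarray, metric: str = "pearson",
                      bins: pd.DataFrame | None = None) -> ProximityMatrix:
    """Spatial proximity between genome bins from a contact matrix.

    ``pearson`` (the default and the headline metric): correlation of
    contact-matrix rows with the self-contact entries masked; values in
    [-1, 1], closer to 1 meaning more frequent contact.  ``observed``:
    the raw counts.  ``enrichment``: observed over the distance-decay
    expectation (requires ``bins`` for chromosome assignment).  Bins with
    an all-zero contact row have no defined proximity and are flagged
    invalid.
    """
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError("contact matrix must be square")
    if not np.allclose(m, m.T):
        raise ValueError("contact matrix must be symmetric")
    if np.any(m < 0):
        raise ValueError("contact matrix must be non-negative")
    valid = m.any(axis=1)
    if metric == "pearson":
        values = _pearson_proximity(m)
    elif metric == "observed":
        values = m.copy()
    elif metric == "enrichment":
        if bins is None:
            raise ValueError("enrichment metric needs bin annotations")
        values = _enrichment(m, bins)
    else:
        raise ValueError(f"unknown proximity metric: {metric!r}")
    return ProximityMatrix(values=values, valid=valid, metric=metric)


# ------------------------------------------------------------ pair table

def build_pair_table(bins: pd.DataFrame, proximity: ProximityMatrix,
                     class_pair: str, mark: str,
                     scope: str = "all") -> pd.DataFrame:
    """Unordered distinct within-class bin pairs with proximity and Q.

    ``class_pair`` is 'EE' (both EARLY) or 'LL' (both LATE); ``scope``
    restricts to intra- or inter-chromosomal pairs.  Pairs with any zero
    mark signal are excluded and counted in
    ``df.attrs['n_dropped_zero_signal']``; pairs whose proximity is
    undefined are likewise dropped.  Raises if no pair survives.
    """
    if class_pair not in ("EE", "LL"):
        raise ValueError("class_pair must be 'EE' or 'LL'")
    if scope not in ("all", "intra", "inter"):
        raise ValueError("scope must be one of 'all', 'intra', 'inter'")
    want = EARLY if class_pair == "EE" else LATE
    sig_col = f"signal_{mark}"
    idx = np.flatnonzero((bins["rep_class"] == want).to_numpy() & proximity.valid)
    chrom = bins["chrom"].to_numpy()
    sig = bins[sig_col].to_numpy(float)
    rows = []
    n_zero = 0
    for ai, a in enumerate(idx):
        for b in idx[ai + 1:]:
            if scope == "intra" and chrom[a] != chrom[b]:
                continue
            if scope == "inter" and chrom[a] == chrom[b]:
                continue
            prox = proximity.values[a, b]
            if not np.isfinite(prox):
                continue
            if sig[a] <= 0 or sig[b] <= 0:
                n_zero += 1
                continue
            rows.append((a, b, class_pair, scope, prox,
                         float(np.abs(np.log10(sig[a] / sig[b])))))
    if not rows:
        raise ValueError(f"no {class_pair} pairs retained for mark {mark!r}")
    out = pd.DataFrame(
        rows, columns=["bin1", "bin2", "pair_class", "scope", "proximity", "Q"]
    )
    out.attrs["n_dropped_zero_signal"] = n_zero
    return out


# ------------------------------------------------------------ orchestration

@dataclass
class PipelineConfig:
    """Inputs and knobs of the pattern-detection pipeline."""

    chrom_sizes: Path
    early_track: Path
    late_track: Path
    peaks: dict                       # mark -> narrowPeak path
    hic: Path
    cutoff: float = 1000.0
    bin_size: int = 1_000_000
    metric: str = "pearson"
    scope: str = "all"
    n_bins: int = 8
    n_chance: int = 10000
    seed: int = 0
    outdir: Path | None = None


def run_pattern_analysis(config: PipelineConfig) -> dict:
    """Run the full pattern analysis; returns {mark: QSummary}.

    Chains binning, timing classification, per-mark peak aggregation,
    spatial proximity, pair construction and the Q summaries.  Proximity
    bins are equal-count bins over the pooled EE+LL proximity values so
    the two classes (and hence delta-delta) share edges.  Deterministic
    given ``config.seed``; if ``outdir`` is set, per-mark pair and summary
    TSVs are written (atomically, write-then-rename).
    """
    stage = "read-inputs"
    try:
        sizes = read_chrom_sizes(config.chrom_sizes)
        early = read_bedgraph(config.early_track)
        late = read_bedgraph(config.late_track)
        matrix, hic_bins = read_dense_hic(config.hic)

        stage = "bin-and-classify"
        bins = bin_genome(sizes, config.bin_size)
        if len(bins) != matrix.shape[0]:
            raise ValueError(
                f"Hi-C matrix has {matrix.shape[0]} bins but genome tiling has {len(bins)}"
            )
        bins = score_and_classify(bins, early, late, config.cutoff, config.bin_size)

        stage = "peak-signal"
        for mark, path in config.peaks.items():
            bins = peak_signal_per_bin(bins, read_narrowpeak(path), mark, config.bin_size)

        stage = "spatial-proximity"
        prox = spatial_proximity(matrix, config.metric, bins)

        stage = "q-summary"
        results = {}
        pairs_by_mark = {}
        for mark in config.peaks:
            rng = np.random.default_rng([int(config.seed), _stable_hash(mark)])
            pairs_ee = build_pair_table(bins, prox, "EE", mark, config.scope)
            pairs_ll = build_pair_table(bins, prox, "LL", mark, config.scope)
            pairs_by_mark[mark] = (pairs_ee, pairs_ll)
            results[mark] = summarize_mark(
                bins, prox, pairs_ee, pairs_ll, mark,
                scope=config.scope, n_bins=config.n_bins,
                n_chance=config.n_chance, rng=rng,
            )
        if config.outdir is not None:
            stage = "write-outputs"
            _write_outputs(config, results, pairs_by_mark)
        return results
    except Exception as exc:
        raise RuntimeError(f"pattern analysis failed at stage {stage!r}: {exc}") from exc


def _stable_hash(text: str) -> int:
    # Deterministic across processes (unlike hash()); bounded below 2**31.
    h = 0
    for ch in text:
        h = (h * 131 + ord(ch)) % 2_147_483_647
    return h


def _class_arrays(bins: pd.DataFrame, prox: ProximityMatrix, want: str,
                  mark: str, scope: str):
    """Per-class locus arrays for vectorized pair/bootstrap computation.

    Returns ``(log_sig, prox_sub, pair_ok)``: log10 signals of the
    positive-signal, proximity-valid loci of the class; their proximity
    sub-matrix; and a boolean matrix of scope-admissible pairs with
    defined proximity.
    """
    sig = bins[f"signal_{mark}"].to_numpy(float)
    sel = ((bins["rep_class"] == want).to_numpy()
           & prox.valid & (sig > 0))
    idx = np.flatnonzero(sel)
    chrom = bins["chrom"].to_numpy()[idx]
    p = prox.values[np.ix_(idx, idx)]
    ok = np.isfinite(p)
    same = chrom[:, None] == chrom[None, :]
    if scope == "intra":
        ok &= same
    elif scope == "inter":
        ok &= ~same
    return np.log10(sig[idx]), p, ok


def _boot_binned(log_sig: np.ndarray, p: np.ndarray, ok: np.ndarray,
                 edges: np.ndarray, centers: np.ndarray,
                 rng: np.random.Generator):
    """Binned medians and slope for one locus-resampled replicate."""
    n = len(log_sig)
    r = rng.integers(0, n, size=n)
    a, b = np.triu_indices(n, k=1)
    ra, rb = r[a], r[b]
    keep = (ra != rb) & ok[ra, rb]
    q = np.abs(log_sig[ra[keep]] - log_sig[rb[keep]])
    g = p[ra[keep], rb[keep]]
    bins_idx = ss.assign_bins(g, edges)
    med = np.array(
        [np.median(q[bins_idx == i]) if np.any(bins_idx == i) else np.nan
         for i in range(len(centers))]
    )
    return ss.regression_slope(centers, med)[0], med


def summarize_mark(bins: pd.DataFrame, prox: ProximityMatrix,
                   pairs_ee: pd.DataFrame, pairs_ll: pd.DataFrame, mark: str,
                   scope: str, n_bins: int, n_chance: int,
                   rng: np.random.Generator, n_boot: int = 200) -> ss.QSummary:
    """Binned medians, chance medians, slopes and delta-delta for a mark.

    Pattern uncertainty comes from a locus-level (cluster) bootstrap:
    loci, not pairs, are resampled with replacement, because all pairs
    sharing a locus are dependent.  ``extras['slope_ci']`` carries 95%
    intervals for the EE slope, the LL slope, |slope_LL| - |slope_EE|
    ('steeper') and the minimum per-bin MedianQ_LL - MedianQ_EE
    difference ('min_gap').
    """
    all_pairs = pd.concat([pairs_ee, pairs_ll], ignore_index=True)
    edges = ss.equal_count_edges(all_pairs["proximity"].to_numpy(float), n_bins)
    medians = ss.median_q_by_bin(all_pairs, "proximity", edges)
    sig = bins[f"signal_{mark}"].to_numpy(float)
    chance = {
        "EE": ss.chance_median_q(sig[bins["rep_class"] == EARLY], rng, n_chance),
        "LL": ss.chance_median_q(sig[bins["rep_class"] == LATE], rng, n_chance),
    }
    centers = 0.5 * (edges[:-1] + edges[1:])
    slopes = {}
    for cls in ("EE", "LL"):
        med = medians[medians["pair_class"] == cls].sort_values("bin")["median_q"]
        slopes[cls] = ss.regression_slope(centers, med.to_numpy(float))
    med_ee = medians[medians["pair_class"] == "EE"].sort_values("bin")["median_q"].to_numpy(float)
    med_ll = medians[medians["pair_class"] == "LL"].sort_values("bin")["median_q"].to_numpy(float)
    dd = ss.delta_delta(med_ll, med_ee, chance["LL"], chance["EE"])

    arrays = {
        "EE": _class_arrays(bins, prox, EARLY, mark, scope),
        "LL": _class_arrays(bins, prox, LATE, mark, scope),
    }
    draws = {"EE": [], "LL": [], "steeper": [], "min_gap": []}
    for _ in range(n_boot):
        boot, meds = {}, {}
        for cls in ("EE", "LL"):
            try:
                boot[cls], meds[cls] = _boot_binned(*arrays[cls], edges, centers, rng)
            except ValueError:
                boot[cls], meds[cls] = np.nan, np.full(len(centers), np.nan)
            draws[cls].append(boot[cls])
        draws["steeper"].append(abs(boot["LL"]) - abs(boot["EE"]))
        gap = meds["LL"] - meds["EE"]
        gap = gap[np.isfinite(gap)]
        draws["min_gap"].append(float(gap.min()) if gap.size else np.nan)
    cis = {}
    for key, vals in draws.items():
        vals = np.asarray(vals, dtype=float)
        vals = vals[np.isfinite(vals)]
        cis[key] = (
            (float(np.quantile(vals, 0.05)), float(np.quantile(vals, 0.95)))
            if vals.size else (np.nan, np.nan)
        )
    n_dropped = (pairs_ee.attrs.get("n_dropped_zero_signal", 0)
                 + pairs_ll.attrs.get("n_dropped_zero_signal", 0))
    return ss.QSummary(
        bin_edges=edges, medians=medians, chance=chance, slopes=slopes,
        delta_delta=dd, n_dropped=n_dropped,
        extras={"mark": mark, "slope_ci": cis},
    )


def pattern_directions(summary: ss.QSummary) -> dict:
    """Presence of the three predicted patterns in one mark summary.

    Each pattern is directional, so it is called present when its
    one-sided 95% bootstrap bound clears zero *and* the point estimate
    agrees:

    - pattern1: median Q_EE < median Q_LL in every proximity bin where
      both classes have pairs (lower bound of the minimum per-bin
      LL - EE gap above 0);
    - pattern2: median Q decreases with spatial proximity -- both
      classes' slope upper bounds below 0;
    - pattern3: the LL decay is steeper -- lower bound of
      |slope_LL| - |slope_EE| above 0.
    """
    med_ee = summary.median_series("EE")
    med_ll = summary.median_series("LL")
    both = np.isfinite(med_ee) & np.isfinite(med_ll)
    cis = summary.extras["slope_ci"]
    return {
        "pattern1": bool(both.any() and np.all(med_ee[both] < med_ll[both])
                         and cis["min_gap"][0] > 0),
        "pattern2": bool(cis["EE"][1] < 0 and cis["LL"][1] < 0),
        "pattern3": bool(abs(summary.slopes["LL"][0]) > abs(summary.slopes["EE"][0])
                         and cis["steeper"][0] > 0),
    }


def pattern_signs(summary: ss.QSummary) -> dict:
    """Point-estimate directions of the three patterns (no significance).

    Used for robustness comparisons (e.g. across classification cutoffs),
    where the question is whether the *direction* of each pattern
    changes, not whether a borderline bootstrap call flips.
    """
    med_ee = summary.median_series("EE")
    med_ll = summary.median_series("LL")
    both = np.isfinite(med_ee) & np.isfinite(med_ll)
    s_ee = summary.slopes["EE"][0]
    s_ll = summary.slopes["LL"][0]
    return {
        "pattern1": bool(both.any() and np.all(med_ee[both] < med_ll[both])),
        "pattern2": bool(s_ee < 0 and s_ll < 0),
        "pattern3": bool(abs(s_ll) > abs(s_ee)),
    }


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_name(path.name + ".tmp")
    tmp.write_text(text)
    tmp.replace(path)


def _write_outputs(config: PipelineConfig, results: dict, pairs_by_mark: dict) -> None:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for mark, summary in results.items():
        ee, ll = pairs_by_mark[mark]
        pairs = pd.concat([ee, ll], ignore_index=True)
        _atomic_write(outdir / f"pairs_{mark}_{config.scope}.tsv",
                      pairs.to_csv(sep="\t", index=False))
        _atomic_write(outdir / f"summary_{mark}.tsv",
                      summary.to_frame().to_csv(sep="\t", index=False))
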