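"""Copy-number estimation from binned counts.

log2-ratio normalization, circular binary segmentation (CBS) with a
permutation-calibrated arc-vs-complement statistic, profile averaging and
correlation, and Ward/Euclidean clustering of per-bin profiles.

The CBS variant here omits the original algorithm's segment-pruning
("undo") step; desk-scale profiles with strong signals do not need it.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

from .io_formats import BinnedCounts, GenomeBins

log = logging.getLogger(__name__)


@dataclass
class CbsParams:
    """Hyperparameters for the permutation split test."""

    alpha: float = 0.01
    n_perm: int = 1000
    min_width: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        if self.min_width < 2:
            raise ValueError("min_width must be >= 2")


@dataclass
class CopyNumberProfile:
    """Per-bin log2 ratios (NaN = masked) plus optional segmentation.

    Segments are (start_bin, end_bin, segment_mean) with half-open bin
    index ranges; together they partition all bins, and each mean is the
    mean log2 ratio of the segment's non-masked members.
    """

    bins: GenomeBins
    log2_ratio: np.ndarray
    segments: list[tuple[int, int, float]] = field(default_factory=list)
    sample_id: str = ""

    def __post_init__(self) -> None:
        self.log2_ratio = np.asarray(self.log2_ratio, dtype=float)
        if len(self.log2_ratio) != len(self.bins):
            raise ValueError("log2_ratio length must match bins")

    @property
    def segment_values(self) -> np.ndarray:
        """Per-bin vector of segment means (NaN where unsegmented/masked)."""
        out = np.full(len(self.bins), np.nan)
        for s, e, m in self.segments:
            out[s:e] = m
        out[np.isnan(self.log2_ratio) & np.isnan(out)] = np.nan
        return out


def normalize_to_log2(
    counts: BinnedCounts,
    gc_per_bin: np.ndarray | None = None,
    n_gc_bins: int = 10,
) -> CopyNumberProfile:
    """log2(count / mean over usable bins); zero-count bins masked NaN.

    With a per-bin GC table, counts are first rescaled by the median
    count of their GC decile (median-centred GC correction).
    """
    x = counts.counts.astype(float)
    if x.sum() <= 0:
        raise ValueError("all bins are zero")
    usable = x > 0
    if gc_per_bin is not None:
        gc = np.asarray(gc_per_bin, dtype=float)
        if len(gc) != len(x):
            raise ValueError("gc_per_bin length mismatch")
        deciles = np.quantile(gc[usable], np.linspace(0, 1, n_gc_bins + 1)[1:-1])
        which = np.digitize(gc, deciles)
        overall_median = np.median(x[usable])
        for d in range(n_gc_bins):
            sel = usable & (which == d)
            med = np.median(x[sel]) if sel.any() else 0.0
            if med > 0:
                x[sel] = x[sel] * overall_median / med
    mean = x[usable].mean()
    ratio = np.full(len(x), np.nan)
    ratio[usable] = np.log2(x[usable] / mean)
    return CopyNumberProfile(
        counts.bins, ratio, sample_id=counts.sample_id
    )


# ---------------------------------------------------------------------------
# CBS
# ---------------------------------------------------------------------------

def arc_statistic_max(
    values: np.ndarray, min_width: int
) -> tuple[float, int, int]:
    """Maximize the arc-vs-complement mean-difference statistic.

    T(i, j) = |mean(values[i:j]) - mean(complement)| / sqrt(1/k + 1/(n-k))
    over arcs of length k in [min_width, n - min_width] whose complement
    splits into flanks that are empty or at least min_width wide.
    Returns (max statistic, i, j); (nan, -1, -1) if no arc is admissible.
    """
    n = len(values)
    S = np.concatenate([[0.0], np.cumsum(values)])
    total = S[-1]
    best, best_i, best_j = -np.inf, -1, -1
    for k in range(min_width, n - min_width + 1):
        D = S[k:] - S[:-k]  # arc sums for i = 0 .. n-k
        i_idx = np.arange(n - k + 1)
        ok = ((i_idx == 0) | (i_idx >= min_width)) & (
            (i_idx + k == n) | (n - i_idx - k >= min_width)
        )
        if not ok.any():
            continue
        diff = np.abs(D / k - (total - D) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        diff = np.where(ok, diff, -np.inf)
        m = int(np.argmax(diff))
        if diff[m] > best:
            best, best_i, best_j = float(diff[m]), m, m + k
    if best_i < 0:
        return float("nan"), -1, -1
    if best_j == n and best_i > 0:
        # arc (i, n) and its complement (0, i) induce the same split with
        # the same statistic; report the canonical left form
        best_i, best_j = 0, best_i
    return best, best_i, best_j


def _perm_max_stats(
    values: np.ndarray, min_width: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Max arc statistic for each of n_perm within-segment shuffles."""
    n = len(values)
    perm = np.array([rng.permutation(values) for _ in range(n_perm)])
    S = np.zeros((n_perm, n + 1))
    np.cumsum(perm, axis=1, out=S[:, 1:])
    total = S[:, -1:]
    best = np.full(n_perm, -np.inf)
    for k in range(min_width, n - min_width + 1):
        D = S[:, k:] - S[:, :-k]
        i_idx = np.arange(n - k + 1)
        ok = ((i_idx == 0) | (i_idx >= min_width)) & (
            (i_idx + k == n) | (n - i_idx - k >= min_width)
        )
        if not ok.any():
            continue
        diff = np.abs(D / k - (total - D) / (n - k)) / np.sqrt(1.0 / k + 1.0 / (n - k))
        diff[:, ~ok] = -np.inf
        np.maximum(best, diff.max(axis=1), out=best)
    return best


def _split_accepted(
    values: np.ndarray,
    obs: float,
    params: CbsParams,
    rng: np.random.Generator,
) -> bool:
    """Permutation test: accept if obs exceeds the (1 - alpha) null quantile.

    Permutations run in batches with early stop once the exceedance count
    already implies p >= alpha.
    """
    needed = int(np.ceil(params.alpha * params.n_perm))  # exceedances that kill the split
    exceed, done = 0, 0
    batch = max(100, min(params.n_perm, 250))
    while done < params.n_perm:
        m = min(batch, params.n_perm - done)
        maxima = _perm_max_stats(values, params.min_width, m, rng)
        exceed += int(np.sum(maxima >= obs))
        done += m
        if exceed >= needed:
            return False
    return exceed < needed


def _segment_valid(
    values: np.ndarray, params: CbsParams, rng: np.random.Generator
) -> list[tuple[int, int]]:
    """Recursive CBS over a contiguous block of non-masked values."""
    n = len(values)
    if n < 2 * params.min_width:
        return [(0, n)]
    obs, i, j = arc_statistic_max(values, params.min_width)
    if i < 0 or not np.isfinite(obs):
        return [(0, n)]
    if not _split_accepted(values, obs, params, rng):
        return [(0, n)]
    pieces = [(a, b) for a, b in ((0, i), (i, j), (j, n)) if b > a]
    out: list[tuple[int, int]] = []
    for a, b in pieces:
        for s, e in _segment_valid(values[a:b], params, rng):
            out.append((a + s, a + e))
    return out


def cbs_segment(profile: CopyNumberProfile, params: CbsParams | None = None) -> CopyNumberProfile:
    """Circular binary segmentation of the log2-ratio profile.

    Each current segment is tested for the best arc-vs-complement split;
    the split is kept when its statistic exceeds the (1 - alpha) quantile
    of within-segment permutations, and recursion continues on the
    resulting pieces.  Masked bins are assigned to the enclosing segment
    afterward.  Chromosomes are segmented independently.
    """
    params = params or CbsParams()
    valid = ~np.isnan(profile.log2_ratio)
    if valid.sum() < 2 * params.min_width:
        warnings.warn("too few usable bins; returning a single segment")
        mean = float(np.nanmean(profile.log2_ratio)) if valid.any() else float("nan")
        return replace(profile, segments=[(0, len(profile.bins), mean)])
    rng = np.random.default_rng(params.seed)
    segments: list[tuple[int, int, float]] = []
    bins = profile.bins
    chrom_start = 0
    for end in range(1, len(bins) + 1):
        if end == len(bins) or bins.chrom[end] != bins.chrom[chrom_start]:
            segments.extend(
                _segment_chromosome(profile, chrom_start, end, params, rng)
            )
            chrom_start = end
    return replace(profile, segments=segments)


def _segment_chromosome(
    profile: CopyNumberProfile,
    lo: int,
    hi: int,
    params: CbsParams,
    rng: np.random.Generator,
) -> list[tuple[int, int, float]]:
    block = profile.log2_ratio[lo:hi]
    valid_idx = np.flatnonzero(~np.isnan(block))
    if len(valid_idx) == 0:
        return [(lo, hi, float("nan"))]
    values = block[valid_idx]
    pieces = _segment_valid(values, params, rng)
    # map valid-space boundaries back to bin space; masked bins go to the
    # segment whose valid range encloses/precedes them
    segments = []
    for pi, (a, b) in enumerate(pieces):
        start = lo if pi == 0 else lo + valid_idx[a]
        end = hi if pi == len(pieces) - 1 else lo + valid_idx[b]
        segments.append((int(start), int(end), float(values[a:b].mean())))
    return segments


# ---------------------------------------------------------------------------
# profile algebra
# ---------------------------------------------------------------------------

def profile_correlation(
    a: CopyNumberProfile,
    b: CopyNumberProfile,
    method: str = "pearson",
    use_segments: bool = False,
) -> float:
    """Pearson/Spearman correlation over shared non-masked bins."""
    if not a.bins.same_grid(b.bins):
        raise ValueError("profiles are on different bin grids")
    va = a.segment_values if use_segments else a.log2_ratio
    vb = b.segment_values if use_segments else b.log2_ratio
    shared = ~np.isnan(va) & ~np.isnan(vb)
    if shared.sum() < 3:
        warnings.warn("fewer than 3 shared bins; correlation undefined")
        return float("nan")
    x, y = va[shared], vb[shared]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("zero variance; correlation undefined")
        return float("nan")
    if method == "pearson":
        return float(sps.pearsonr(x, y).statistic)
    if method == "spearman":
        return float(sps.spearmanr(x, y).statistic)
    raise ValueError(f"unknown method {method!r}")


def average_profiles(profiles: list[CopyNumberProfile]) -> CopyNumberProfile:
    """Per-bin mean log2 ratio across profiles, ignoring masked bins."""
    if not profiles:
        raise ValueError("empty profile list")
    first = profiles[0]
    for p in profiles[1:]:
        if not p.bins.same_grid(first.bins):
            raise ValueError("profiles are on different bin grids")
    stack = np.vstack([p.log2_ratio for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN columns
        mean = np.nanmean(stack, axis=0)
    return CopyNumberProfile(first.bins, mean, sample_id="average")


def cluster_profiles(
    matrix: np.ndarray, k: int | None = None
) -> tuple[np.ndarray, np.ndarray | None]:
    """Ward-linkage hierarchical clustering on Euclidean distances.

    ``matrix`` is samples x bins; columns with any NaN are dropped
    listwise.  Returns the scipy linkage matrix and, if ``k`` is given,
    flat cluster labels at that cut.  Deterministic for a fixed row
    order (scipy's nearest-neighbor chain tie-breaking).
    """
    matrix = np.asarray(matrix, dtype=float)
    if matrix.ndim != 2 or matrix.shape[0] < 2:
        raise ValueError("need at least 2 samples")
    keep = ~np.isnan(matrix).any(axis=0)
    if not keep.any():
        raise ValueError("no complete bins for clustering")
    Z = hierarchy.linkage(matrix[:, keep], method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=k, criterion="maxclust") if k else None
    return Z, labels


def write_segments(profile: CopyNumberProfile, path: str | Path) -> None:
    """SEG-style TSV: sample, chrom, start, end, n_bins, seg_mean."""
    bins = profile.bins
    with open(path, "w") as fh:
        fh.write("sample\tchrom\tstart\tend\tn_bins\tseg_mean\n")
        for s, e, m in profile.segments:
            fh.write(
                f"{profile.sample_id}\t{bins.chrom[s]}\t{bins.start[s]}\t"
                f"{bins.end[e - 1]}\t{e - s}\t{m:.6g}\n"
            )
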