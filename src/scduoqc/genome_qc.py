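"""Sequencing metrics and coverage-uniformity statistics for single-cell WGS.

Covers alignment/duplication/pairing fractions, bin-to-bin coefficient of
variation, Lorenz curves with trapezoidal AUC, and per-chromosome power
spectra of normalized read depth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .io_formats import BinnedCounts, ReadRecord

log = logging.getLogger(__name__)

#: band edge for the power-spectrum summary: the part of the spectrum at
#: genomic length scales of 500 kb and larger.  Amplification bias lives at
#: large scales, so mean power in this band rises with spatially correlated
#: bias while the short-scale Poisson floor does not.
PSD_SUMMARY_MAX_FREQ = 1.0 / 500_000.0


@dataclass(frozen=True)
class SequencingMetrics:
    """Alignment-level quality fractions.

    ``frac_aligned`` is over all reads; duplication, proper pairing and
    mate-on-other-chromosome fractions are over mapped reads and are NaN
    when nothing mapped.
    """

    frac_aligned: float
    frac_duplicated: float
    frac_properly_paired: float
    frac_mate_diff_chrom: float
    n_reads: int


@dataclass(frozen=True)
class LorenzResult:
    x: np.ndarray  # cumulative genome (bin) fraction, starts at 0
    y: np.ndarray  # cumulative count fraction, starts at 0
    auc: float


@dataclass(frozen=True)
class PowerSpectrum:
    freqs: np.ndarray  # cycles per base pair, strictly increasing
    psd: np.ndarray
    summary: float  # mean psd over the >= 500 kb length-scale band


def sequencing_metrics(records: Sequence[ReadRecord]) -> SequencingMetrics:
    """Fractions of reads aligned, duplicated, properly paired, and with
    the mate mapped to a different chromosome."""
    n = len(records)
    if n == 0:
        raise ValueError("no read records")
    mapped = [r for r in records if r.is_mapped]
    n_mapped = len(mapped)
    frac_aligned = n_mapped / n
    if n_mapped == 0:
        return SequencingMetrics(0.0, math.nan, math.nan, math.nan, n)
    n_dup = sum(r.is_duplicate for r in mapped)
    n_proper = sum(r.is_proper_pair for r in mapped)
    n_diff = sum(
        r.mate_chrom not in ("*", r.chrom) for r in mapped
    )
    return SequencingMetrics(
        frac_aligned=frac_aligned,
        frac_duplicated=n_dup / n_mapped,
        frac_properly_paired=n_proper / n_mapped,
        frac_mate_diff_chrom=n_diff / n_mapped,
        n_reads=n,
    )


def bin_cv(counts: BinnedCounts, exclude_zero_bins: bool = False) -> float:
    """Coefficient of variation of per-bin counts (sample sd / mean)."""
    x = counts.counts.astype(float)
    if exclude_zero_bins:
        x = x[x > 0]
    if len(x) < 2:
        raise ValueError("need at least 2 usable bins")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero mean bin count")
    return float(x.std(ddof=1) / mean)


def lorenz_curve(counts: BinnedCounts) -> LorenzResult:
    """Lorenz curve of per-bin counts and its trapezoidal AUC.

    Bins are sorted ascending by count; the diagonal (AUC = 0.5) is
    perfect uniformity, and more unequal coverage pushes the curve (and
    AUC) down.
    """
    x = np.sort(counts.counts.astype(float))
    total = x.sum()
    if len(x) == 0 or total <= 0:
        raise ValueError("total count must be positive")
    n = len(x)
    xs = np.concatenate([[0.0], np.arange(1, n + 1) / n])
    ys = np.concatenate([[0.0], np.cumsum(x) / total])
    auc = float(np.trapezoid(ys, xs))
    return LorenzResult(x=xs, y=ys, auc=auc)


def _chrom_psd(x: np.ndarray, bin_size: int) -> tuple[np.ndarray, np.ndarray]:
    """One-chromosome one-sided PSD of mean-normalized depth.

    psd_k = |X_k|^2 / N with the mirrored negative-frequency power folded
    in, so sum(psd) = N * var(x) exactly (Parseval; DC is zero after mean
    removal and is dropped).
    """
    n = len(x)
    X = np.fft.rfft(x)
    psd = np.abs(X) ** 2 / n
    psd[1:] *= 2.0
    if n % 2 == 0:
        psd[-1] /= 2.0  # Nyquist bin has no mirror
    freqs = np.fft.rfftfreq(n, d=bin_size)
    return freqs[1:], psd[1:]  # drop DC


def power_spectrum(counts: BinnedCounts, min_bins: int = 8) -> PowerSpectrum:
    """Per-chromosome power spectrum of counts/mean - 1, averaged on a
    common frequency grid; summary = mean power at genomic length scales
    of 500 kb and larger.

    Chromosomes with fewer than ``min_bins`` bins (or zero mean) are
    skipped with a log entry.
    """
    bins = counts.bins
    bin_size = int(bins.bin_size)
    spectra: list[tuple[np.ndarray, np.ndarray]] = []
    start = 0
    for i in range(1, len(bins) + 1):
        if i == len(bins) or bins.chrom[i] != bins.chrom[start]:
            seg = counts.counts[start:i].astype(float)
            if len(seg) < min_bins or seg.mean() == 0:
                log.info("power_spectrum: skipping %s (%d bins)", bins.chrom[start], len(seg))
            else:
                x = seg / seg.mean() - 1.0
                spectra.append(_chrom_psd(x, bin_size))
            start = i
    if not spectra:
        raise ValueError("no chromosome with enough usable bins")
    if len(spectra) == 1:
        freqs, psd = spectra[0]
    else:
        # common grid = frequencies of the longest chromosome; linear interp
        freqs = max((f for f, _ in spectra), key=len)
        psd = np.mean([np.interp(freqs, f, p) for f, p in spectra], axis=0)
    band = freqs <= PSD_SUMMARY_MAX_FREQ
    summary = float(psd[band].mean()) if band.any() else math.nan
    return PowerSpectrum(freqs=freqs, psd=psd, summary=summary)


def downsample_reads(
    records: Sequence[ReadRecord],
    target_n: int,
    n_replicates: int = 1,
    seed: int = 0,
) -> list[list[ReadRecord]]:
    """Random subsets of reads without replacement, one per replicate."""
    if target_n > len(records):
        raise ValueError(f"target_n={target_n} exceeds available {len(records)}")
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_replicates):
        idx = rng.choice(len(records), size=target_n, replace=False)
        idx.sort()
        out.append([records[i] for i in idx])
    return out
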