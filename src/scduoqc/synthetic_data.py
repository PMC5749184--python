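"""Ground-truth simulators for paired single-cell DNA/RNA data.

The generators emulate the contrast between physically separated and
contaminated (co-amplified) preparations: binned WGS counts with
spatially autocorrelated lognormal amplification bias over a planted
copy-number profile, scRNA-seq counts with logistic dropout and spike-ins,
per-cell SNV call sets with stated sensitivity/false-positive rates, and
cross-fraction read contamination.

All randomness flows from ``SimTruth.seed``; a fixed per-cell offset
expands it into per-cell substreams so cell ``i`` is reproducible
independently of ``n_cells``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io_formats import (
    BinnedCounts,
    ExpressionMatrix,
    FractionType,
    GenomeBins,
    ReadAnnotation,
    ReadRecord,
    SAM_FLAG_DUPLICATE,
    VariantSet,
)

_CELL_STREAM_OFFSET = 10_000  # per-cell substream spacing in seed space


@dataclass
class SimTruth:
    """Ground truth and noise parameters for one synthetic dataset."""

    bins: GenomeBins
    cn_profile: np.ndarray  # integer copy number per bin, baseline 2
    bias_sigma: float = 0.3
    bias_rho: float = 0.5
    dropout_midpoint: float = 1.0  # in log mean-expression units (natural log)
    dropout_slope: float = 1.0
    contamination_rna_in_dna: float = 0.0
    contamination_dna_in_rna: float = 0.0
    true_variants: VariantSet = field(default_factory=lambda: VariantSet(set()))
    sensitivity: float = 1.0
    fp_rate: float = 0.0
    libsize_sigma: float = 0.3
    contaminant_dup_rate: float = 0.25
    seed: int = 0

    def __post_init__(self) -> None:
        self.cn_profile = np.asarray(self.cn_profile, dtype=np.int64)
        if len(self.cn_profile) != len(self.bins):
            raise ValueError("cn_profile length must match bins")
        if self.cn_profile.min() < 0:
            raise ValueError("copy number must be >= 0")
        for name in ("contamination_rna_in_dna", "contamination_dna_in_rna"):
            v = getattr(self, name)
            if not 0 <= v < 1:
                raise ValueError(f"{name} must be in [0, 1)")
        if not 0 <= self.sensitivity <= 1:
            raise ValueError("sensitivity must be in [0, 1]")
        if not 0 <= self.bias_rho < 1:
            raise ValueError("bias_rho must be in [0, 1)")
        if self.fp_rate < 0:
            raise ValueError("fp_rate must be >= 0")

    def cell_rng(self, stream: int, cell: int) -> np.random.Generator:
        return np.random.default_rng(
            np.random.SeedSequence([self.seed, stream, _CELL_STREAM_OFFSET + cell])
        )


def _ar1_log_bias(rng: np.random.Generator, n: int, sigma: float, rho: float) -> np.ndarray:
    """Stationary AR(1) Gaussian series with marginal sd ``sigma``."""
    if sigma == 0 or n == 0:
        return np.zeros(n)
    eps = rng.standard_normal(n)
    x = np.empty(n)
    x[0] = eps[0]
    innov_sd = np.sqrt(1.0 - rho * rho)
    for i in range(1, n):
        x[i] = rho * x[i - 1] + innov_sd * eps[i]
    return sigma * x


def simulate_wgs_bins(
    truth: SimTruth,
    mean_depth_per_bin: float,
    n_cells: int,
) -> tuple[list[BinnedCounts], np.ndarray]:
    """Poisson bin counts over the planted copy-number profile.

    Per cell: counts_b ~ Poisson(depth * cn_b / 2 * bias_b) where
    log(bias_b) follows a stationary AR(1) Gaussian process (marginal sd
    ``bias_sigma``, lag-1 correlation ``bias_rho``) computed per
    chromosome.  Returns the counts and the realized bias matrix
    (cells x bins).
    """
    if mean_depth_per_bin <= 0:
        raise ValueError("mean_depth_per_bin must be positive")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    bins = truth.bins
    chrom_starts = _chromosome_slices(bins)
    out: list[BinnedCounts] = []
    biases = np.empty((n_cells, len(bins)))
    for c in range(n_cells):
        rng = truth.cell_rng(1, c)
        log_bias = np.concatenate(
            [
                _ar1_log_bias(rng, stop - start, truth.bias_sigma, truth.bias_rho)
                for start, stop in chrom_starts
            ]
        ) if len(bins) else np.zeros(0)
        bias = np.exp(log_bias)
        lam = mean_depth_per_bin * truth.cn_profile / 2.0 * bias
        counts = rng.poisson(lam)
        biases[c] = bias
        out.append(
            BinnedCounts(bins, counts, sample_id=f"cell{c:03d}", fraction_type=FractionType.FD)
        )
    return out, biases


def _chromosome_slices(bins: GenomeBins) -> list[tuple[int, int]]:
    slices, start = [], 0
    for i in range(1, len(bins) + 1):
        if i == len(bins) or bins.chrom[i] != bins.chrom[start]:
            slices.append((start, i))
            start = i
    return slices


def _dropout_probability(log_mean: np.ndarray, midpoint: float, slope: float) -> np.ndarray:
    """Logistic dropout, decreasing in expression: 0.5 at the midpoint."""
    from scipy.special import expit

    return expit(-slope * (log_mean - midpoint))


def simulate_scrna(
    bulk_profile: np.ndarray,
    n_cells: int,
    truth: SimTruth,
    ercc_inputs: np.ndarray | None = None,
    mean_libsize: float = 100_000.0,
    gene_ids: list[str] | None = None,
) -> tuple[ExpressionMatrix, np.ndarray | None]:
    """scRNA-seq counts with library-size variation and logistic dropout.

    Gene g in cell c: kept with probability 1 - dropout(log p_g), then
    count ~ Poisson(libsize_c * p_g) where p_g are bulk proportions and
    libsize_c is lognormal around ``mean_libsize``.  Spike-ins pass
    through the same Poisson/library-size noise but are never dropped.
    Returns the matrix and, if spike-ins were given, a spikes x cells
    count array.
    """
    bulk_profile = np.asarray(bulk_profile, dtype=float)
    if bulk_profile.sum() <= 0:
        raise ValueError("bulk_profile must have positive total")
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    p = bulk_profile / bulk_profile.sum()
    with np.errstate(divide="ignore"):
        log_mean = np.where(p > 0, np.log(np.maximum(p * mean_libsize, 1e-300)), -np.inf)
    drop = np.where(
        p > 0,
        _dropout_probability(log_mean, truth.dropout_midpoint, truth.dropout_slope),
        1.0,
    )
    n_genes = len(bulk_profile)
    mat = np.zeros((n_genes, n_cells), dtype=float)
    spikes = None
    if ercc_inputs is not None:
        ercc_inputs = np.asarray(ercc_inputs, dtype=float)
        spikes = np.zeros((len(ercc_inputs), n_cells), dtype=float)
        spike_p = ercc_inputs / max(ercc_inputs.sum(), 1e-300)
    for c in range(n_cells):
        rng = truth.cell_rng(2, c)
        libsize = mean_libsize * rng.lognormal(
            -0.5 * truth.libsize_sigma**2, truth.libsize_sigma
        )
        kept = rng.random(n_genes) >= drop
        lam = np.where(kept, libsize * p, 0.0)
        mat[:, c] = rng.poisson(lam)
        if spikes is not None:
            # spike-ins see the same depth noise but no dropout
            spikes[:, c] = rng.poisson(0.05 * libsize * spike_p)
    em = ExpressionMatrix(
        gene_ids=gene_ids or [f"gene{i:05d}" for i in range(n_genes)],
        values=mat,
        cell_ids=[f"cell{c:03d}" for c in range(n_cells)],
        cell_fractions=[FractionType.FR] * n_cells,
    )
    return em, spikes


def simulate_reads(
    n_reads: int,
    annotation_probs: dict[ReadAnnotation, float],
    rng: np.random.Generator,
    chrom: str = "chr1",
    dup_rate: float = 0.0,
) -> list[ReadRecord]:
    """Annotated mapped reads with the given region mix and duplicate rate.

    Convenience generator for contamination experiments; all reads are
    mapped and single-chromosome.
    """
    anns = list(annotation_probs)
    probs = np.array([annotation_probs[a] for a in anns], dtype=float)
    probs = probs / probs.sum()
    choice = rng.choice(len(anns), size=n_reads, p=probs)
    dup = rng.random(n_reads) < dup_rate
    pos = rng.integers(0, 10_000_000, size=n_reads)
    return [
        ReadRecord(
            flags=SAM_FLAG_DUPLICATE if dup[i] else 0,
            chrom=chrom,
            mate_chrom=chrom,
            pos=int(pos[i]),
            annotation=anns[choice[i]],
        )
        for i in range(n_reads)
    ]


def simulate_fraction_contamination(
    dna_reads: list[ReadRecord],
    rna_reads: list[ReadRecord],
    truth: SimTruth,
) -> tuple[list[ReadRecord], list[ReadRecord]]:
    """Move reads across fractions to emulate a co-amplified preparation.

    A Binomial(len(rna_reads), contamination_rna_in_dna) subset of the
    RNA-derived reads lands in the DNA fraction (and symmetrically for
    DNA into RNA).  Contaminant reads are duplicate-flagged at
    ``contaminant_dup_rate``.  Total read count is conserved.
    """
    rng = np.random.default_rng(np.random.SeedSequence([truth.seed, 3]))
    rna_to_dna = _pick_contaminants(rna_reads, truth.contamination_rna_in_dna, rng)
    dna_to_rna = _pick_contaminants(dna_reads, truth.contamination_dna_in_rna, rng)
    moved_to_dna = [
        _mark_contaminant(rna_reads[i], rng, truth.contaminant_dup_rate) for i in rna_to_dna
    ]
    moved_to_rna = [
        _mark_contaminant(dna_reads[i], rng, truth.contaminant_dup_rate) for i in dna_to_rna
    ]
    dna_out = [r for i, r in enumerate(dna_reads) if i not in dna_to_rna] + moved_to_dna
    rna_out = [r for i, r in enumerate(rna_reads) if i not in rna_to_dna] + moved_to_rna
    return dna_out, rna_out


def _pick_contaminants(
    reads: list[ReadRecord], rate: float, rng: np.random.Generator
) -> set[int]:
    if not 0 <= rate < 1:
        raise ValueError("contamination fraction must be in [0, 1)")
    if rate == 0 or not reads:
        return set()
    mask = rng.random(len(reads)) < rate
    return set(np.flatnonzero(mask).tolist())


def _mark_contaminant(
    read: ReadRecord, rng: np.random.Generator, dup_rate: float
) -> ReadRecord:
    flags = read.flags
    if rng.random() < dup_rate:
        flags |= SAM_FLAG_DUPLICATE
    return ReadRecord(
        flags=flags,
        chrom=read.chrom,
        mate_chrom=read.mate_chrom,
        pos=read.pos,
        annotation=read.annotation,
    )


def simulate_snv_calls(
    truth: SimTruth,
    n_cells: int,
    fp_space: list[tuple[str, int, str, str]] | None = None,
) -> list[VariantSet]:
    """Per-cell SNV calls: Bernoulli(sensitivity)-thinned truth plus
    Poisson(fp_rate) false positives drawn outside the truth set.

    ``fp_space`` optionally constrains false-positive candidates; by
    default random positions on the truth chromosomes are drawn.
    """
    if len(truth.true_variants) == 0:
        raise ValueError("true_variants must be non-empty")
    truth_list = sorted(truth.true_variants.variants)
    truth_set = truth.true_variants.variants
    chroms = sorted({v[0] for v in truth_set}) or ["chr1"]
    alphabet = "ACGT"
    out: list[VariantSet] = []
    for c in range(n_cells):
        rng = truth.cell_rng(4, c)
        keep = rng.random(len(truth_list)) < truth.sensitivity
        calls = {v for v, k in zip(truth_list, keep) if k}
        n_fp = rng.poisson(truth.fp_rate)
        fps: set[tuple[str, int, str, str]] = set()
        if fp_space:
            candidates = [v for v in fp_space if v not in truth_set]
            if candidates:
                idx = rng.choice(len(candidates), size=min(n_fp, len(candidates)), replace=False)
                fps = {candidates[i] for i in idx}
        else:
            while len(fps) < n_fp:
                chrom = chroms[rng.integers(len(chroms))]
                pos = int(rng.integers(0, 100_000_000))
                ref, alt = rng.choice(list(alphabet), size=2, replace=False)
                v = (chrom, pos, str(ref), str(alt))
                if v not in truth_set:
                    fps.add(v)
        out.append(VariantSet(calls | fps, sample_id=f"cell{c:03d}"))
    return out


def make_cn_profile(
    n_bins: int,
    segments: list[tuple[int, int, int]] | None = None,
    chrom: str = "chr1",
    bin_size: int = 1_000_000,
) -> tuple[GenomeBins, np.ndarray]:
    """Diploid baseline with planted (start_bin, end_bin, copy_number) segments."""
    bins = GenomeBins.uniform({chrom: n_bins * bin_size}, bin_size=bin_size)
    cn = np.full(n_bins, 2, dtype=np.int64)
    for start, end, copy in segments or []:
        cn[start:end] = copy
    return bins, cn
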