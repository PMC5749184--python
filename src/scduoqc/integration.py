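"""Genome-transcriptome integration statistics.

Binned expression on the DNA bin grid, copy-number/expression dosage
correlation, permutation regression of bulk expression on single cells,
SNV concordance against bulk calls, read-annotation contamination
metrics, and qPCR relative-quantity arithmetic.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .cnv_profiling import CopyNumberProfile
from .io_formats import (
    ExpressionMatrix,
    GenomeBins,
    ReadAnnotation,
    ReadRecord,
    VariantSet,
)
from .rna_metrics import log_cpm


@dataclass
class BinnedExpression:
    """Mean log-normalized expression of genes with TSS in each bin,
    averaged across selected cells; bins without genes are NaN."""

    bins: GenomeBins
    value: np.ndarray
    n_genes: np.ndarray


@dataclass(frozen=True)
class RecoveryResult:
    cp_fraction: float
    cp_reference: float
    efficiency: float
    relative_quantity: float


def bin_expression(
    matrix: ExpressionMatrix,
    bins: GenomeBins,
    cells: list[str] | None = None,
) -> BinnedExpression:
    """Assign each gene to the bin containing its TSS and average
    log2(CPM+1) per bin, then across the selected cells."""
    if matrix.gene_coords is None:
        raise ValueError("expression matrix lacks gene coordinates")
    cell_idx = (
        [matrix.cell_ids.index(c) for c in cells]
        if cells is not None
        else list(range(len(matrix.cell_ids)))
    )
    norm = log_cpm(matrix.values)[:, cell_idx]
    bin_lookup: dict[str, list[tuple[int, int, int]]] = {}
    for b in range(len(bins)):
        bin_lookup.setdefault(bins.chrom[b], []).append(
            (int(bins.start[b]), int(bins.end[b]), b)
        )
    sums = np.zeros(len(bins))
    n_genes = np.zeros(len(bins), dtype=np.int64)
    for g, gene in enumerate(matrix.gene_ids):
        coord = matrix.gene_coords.get(gene)
        if coord is None:
            continue
        chrom, tss = coord
        for start, end, b in bin_lookup.get(chrom, []):
            if start <= tss < end:
                sums[b] += norm[g].mean()  # per-cell mean of this gene
                n_genes[b] += 1
                break
    if n_genes.sum() == 0:
        raise ValueError("no genes mapped to any bin")
    value = np.where(n_genes > 0, sums / np.maximum(n_genes, 1), np.nan)
    return BinnedExpression(bins=bins, value=value, n_genes=n_genes)


def cnv_expression_correlation(
    cn: CopyNumberProfile,
    expr: BinnedExpression,
    use_segments: bool = True,
) -> tuple[float, float]:
    """Pearson r (and p-value) between per-bin copy-number values and
    binned expression over shared non-NaN bins."""
    if not cn.bins.same_grid(expr.bins):
        raise ValueError("copy-number and expression bins differ")
    dna = cn.segment_values if use_segments and cn.segments else cn.log2_ratio
    shared = ~np.isnan(dna) & ~np.isnan(expr.value)
    if shared.sum() < 3:
        warnings.warn("fewer than 3 shared bins; correlation undefined")
        return math.nan, math.nan
    x, y = dna[shared], expr.value[shared]
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("degenerate variance; correlation undefined")
        return math.nan, math.nan
    res = sps.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def adjusted_r2(r2: float, n_obs: int, n_predictors: int) -> float:
    """1 - (1 - R^2)(G - 1)/(G - k - 1)."""
    return 1.0 - (1.0 - r2) * (n_obs - 1) / (n_obs - n_predictors - 1)


def bulk_explained_variance(
    single_cells: ExpressionMatrix,
    bulk: np.ndarray,
    n_cells_list: list[int],
    n_perm: int = 1000,
    seed: int = 0,
) -> dict[int, np.ndarray]:
    """Adjusted-R^2 distributions for regressing bulk on random cell subsets.

    For each n and permutation, n cells are drawn without replacement and
    bulk expression is regressed on their expression profiles by OLS with
    intercept; the adjusted R^2 (G genes, n regressors) is recorded.
    """
    bulk = np.asarray(bulk, dtype=float)
    X_all = single_cells.values
    G, n_avail = X_all.shape
    if len(bulk) != G:
        raise ValueError("bulk vector length must match gene count")
    if max(n_cells_list) > n_avail:
        raise ValueError("requested more cells than available")
    if G <= max(n_cells_list) + 1:
        raise ValueError("need more genes than regressors + 1")
    rng = np.random.default_rng(seed)
    tss = float(np.sum((bulk - bulk.mean()) ** 2))
    if tss == 0:
        raise ValueError("bulk vector is constant")
    out: dict[int, np.ndarray] = {}
    for n in n_cells_list:
        vals = np.empty(n_perm)
        for p in range(n_perm):
            idx = rng.choice(n_avail, size=n, replace=False)
            X = np.column_stack([np.ones(G), X_all[:, idx]])
            coef, _, rank, _ = np.linalg.lstsq(X, bulk, rcond=None)
            if rank < X.shape[1]:
                warnings.warn("collinear cell columns; rank-deficient fit")
            resid = bulk - X @ coef
            r2 = 1.0 - float(resid @ resid) / tss
            vals[p] = adjusted_r2(r2, G, n)
        out[n] = vals
    return out


def snv_concordance(
    cell: VariantSet,
    bulk: VariantSet,
    region_filter: list[tuple[str, int, int]] | None = None,
) -> float:
    """Fraction of the cell's variants verified in the bulk set,
    optionally restricted to 0-based half-open regions."""
    cell_vars = set(cell.variants)
    if region_filter is not None:
        cell_vars = {
            v
            for v in cell_vars
            if any(v[0] == c and s <= v[1] < e for c, s, e in region_filter)
        }
    if not cell_vars:
        warnings.warn("no cell variants after filtering; concordance undefined")
        return math.nan
    return len(cell_vars & bulk.variants) / len(cell_vars)


def region_fractions(records: list[ReadRecord]) -> tuple[float, float, float]:
    """(exonic, intronic, intergenic) fractions over mapped reads; sums to 1."""
    mapped = [r for r in records if r.is_mapped]
    if not mapped:
        raise ValueError("no mapped reads")
    n = len(mapped)
    counts = {
        ann: sum(r.annotation is ann for r in mapped)
        for ann in (
            ReadAnnotation.EXONIC,
            ReadAnnotation.INTRONIC,
            ReadAnnotation.INTERGENIC,
        )
    }
    return (
        counts[ReadAnnotation.EXONIC] / n,
        counts[ReadAnnotation.INTRONIC] / n,
        counts[ReadAnnotation.INTERGENIC] / n,
    )


def contamination_metrics(
    records: list[ReadRecord],
) -> tuple[float, float, float]:
    """(exonic fraction, overall duplication rate, coding-region duplication
    rate) over mapped reads; NaN components when denominators are empty."""
    mapped = [r for r in records if r.is_mapped]
    if not mapped:
        return math.nan, math.nan, math.nan
    exonic = [r for r in mapped if r.annotation is ReadAnnotation.EXONIC]
    exonic_fraction = len(exonic) / len(mapped)
    dup_overall = sum(r.is_duplicate for r in mapped) / len(mapped)
    dup_coding = (
        sum(r.is_duplicate for r in exonic) / len(exonic) if exonic else math.nan
    )
    return exonic_fraction, dup_overall, dup_coding


def qpcr_relative_quantity(
    cp_fraction: float, cp_reference: float, efficiency: float = 2.0
) -> RecoveryResult:
    """Relative quantity = efficiency^(Cp_reference - Cp_fraction).

    A fraction crossing one cycle later than the reference holds half the
    template (at perfect efficiency 2).
    """
    if efficiency <= 1:
        raise ValueError("amplification efficiency must exceed 1")
    rq = efficiency ** (cp_reference - cp_fraction)
    return RecoveryResult(
        cp_fraction=cp_fraction,
        cp_reference=cp_reference,
        efficiency=efficiency,
        relative_quantity=rq,
    )
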