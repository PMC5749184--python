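"""Single-cell RNA-seq quality and expression metrics.

Gene detection and saturation, ensemble pooling, transcript body
coverage by expression class, spike-in input/output correlation,
housekeeping-gene cell QC, and marker-based cell-cycle staging.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np
from scipy import stats as sps

from .io_formats import ExpressionMatrix


class CellCyclePhase(str, Enum):
    G1 = "G1"
    S = "S"
    G2M = "G2M"
    UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class BodyCoverageProfile:
    """Mean coverage along normalized transcript length per expression class,
    normalized to each class's own maximum."""

    percentile_grid: np.ndarray  # 0..100
    coverage_ratio: dict[str, np.ndarray]  # class name -> profile, max 1


@dataclass(frozen=True)
class CellCycleCall:
    cell_id: str
    phase: CellCyclePhase
    scores: dict[str, float]


def log_cpm(values: np.ndarray) -> np.ndarray:
    """log2(CPM + 1) per cell (column)."""
    values = np.asarray(values, dtype=float)
    totals = values.sum(axis=0, keepdims=True)
    totals = np.where(totals > 0, totals, 1.0)
    return np.log2(values / totals * 1e6 + 1.0)


def detect_genes(matrix: ExpressionMatrix, min_count: int = 1) -> np.ndarray:
    """Number of genes with count >= min_count, per cell."""
    return (matrix.values >= min_count).sum(axis=0)


def subsample_saturation(
    cell_counts: np.ndarray,
    depths: list[int],
    n_rep: int = 10,
    seed: int = 0,
    min_count: int = 1,
) -> np.ndarray:
    """Mean genes detected after subsampling reads to each depth.

    Reads are drawn without replacement (multivariate hypergeometric on
    the per-gene counts), ``n_rep`` independent replicates per depth.
    """
    counts = np.asarray(cell_counts, dtype=np.int64)
    total = int(counts.sum())
    rng = np.random.default_rng(seed)
    out = np.empty(len(depths))
    for di, depth in enumerate(depths):
        if depth > total:
            raise ValueError(f"depth {depth} exceeds total count {total}")
        detected = np.empty(n_rep)
        for r in range(n_rep):
            sub = rng.multivariate_hypergeometric(counts, depth)
            detected[r] = int((sub >= min_count).sum())
        out[di] = detected.mean()
    return out


def expected_detected_with_replacement(probs: np.ndarray, n: int) -> float:
    """Closed-form E[genes detected] for n reads with replacement."""
    probs = np.asarray(probs, dtype=float)
    return float(np.sum(1.0 - (1.0 - probs) ** n))


def ensemble_pool(cell_vectors: list[np.ndarray]) -> np.ndarray:
    """Element-wise sum of per-cell count vectors (pooled ensemble)."""
    if not cell_vectors:
        raise ValueError("no cells to pool")
    first = np.asarray(cell_vectors[0])
    for v in cell_vectors[1:]:
        if np.asarray(v).shape != first.shape:
            raise ValueError("mismatched gene index across cells")
    return np.sum([np.asarray(v) for v in cell_vectors], axis=0)


def body_coverage(
    coverage_vectors: np.ndarray,
    expression_ranks: np.ndarray,
    class_size: int = 1000,
    grid_points: int = 101,
) -> BodyCoverageProfile:
    """Mean transcript-body coverage for top/middle/bottom expression classes.

    ``coverage_vectors`` is transcripts x positions (positions already on
    a normalized-length grid); ``expression_ranks`` gives each
    transcript's expression rank (0 = highest).  Classes are the top
    ``class_size`` transcripts, the next block starting at the median
    rank, and the bottom block; each class profile is the transcript mean
    rescaled to its own maximum.
    """
    cov = np.asarray(coverage_vectors, dtype=float)
    ranks = np.asarray(expression_ranks)
    n = len(ranks)
    if cov.shape[0] != n:
        raise ValueError("coverage_vectors / expression_ranks length mismatch")
    if n < 3 * class_size:
        raise ValueError(
            f"{n} transcripts < 3 x class_size {class_size}; lower class_size"
        )
    order = np.argsort(ranks, kind="stable")
    mid_start = (n - class_size) // 2  # centered; ranks 1001-2000 for n=3000
    classes = {
        "top": order[:class_size],
        "middle": order[mid_start : mid_start + class_size],
        "bottom": order[n - class_size :],
    }
    grid = np.linspace(0, 100, grid_points)
    profiles: dict[str, np.ndarray] = {}
    src_grid = np.linspace(0, 100, cov.shape[1])
    for name, idx in classes.items():
        mean_cov = cov[idx].mean(axis=0)
        prof = np.interp(grid, src_grid, mean_cov)
        peak = prof.max()
        profiles[name] = prof / peak if peak > 0 else prof
    return BodyCoverageProfile(percentile_grid=grid, coverage_ratio=profiles)


def ercc_correlation(observed: np.ndarray, inputs: np.ndarray) -> float:
    """Pearson r of log2(observed + 1) vs log2(input molecules).

    Spike-ins with zero observed or zero input are excluded; NaN when
    fewer than 3 usable points remain.
    """
    observed = np.asarray(observed, dtype=float)
    inputs = np.asarray(inputs, dtype=float)
    usable = (observed > 0) & (inputs > 0)
    if usable.sum() < 3:
        return math.nan
    x = np.log2(observed[usable] + 1.0)
    y = np.log2(inputs[usable])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return math.nan
    return float(sps.pearsonr(x, y).statistic)


def select_housekeeping_genes(
    matrix: ExpressionMatrix, k: int = 8, top_fraction: float = 0.1
) -> list[str]:
    """The k least-variable (lowest CV) genes among the top-expressed
    ``top_fraction`` by mean; CV ties broken by gene id."""
    values = matrix.values
    means = values.mean(axis=1)
    n_top = max(int(math.ceil(len(matrix.gene_ids) * top_fraction)), k)
    if n_top > len(matrix.gene_ids):
        raise ValueError("not enough genes for the requested top fraction")
    top_idx = np.argsort(-means, kind="stable")[:n_top]
    with np.errstate(divide="ignore", invalid="ignore"):
        cv = np.where(
            means[top_idx] > 0,
            values[top_idx].std(axis=1, ddof=1) / means[top_idx],
            np.inf,
        )
    ranked = sorted(
        zip(cv, [matrix.gene_ids[i] for i in top_idx]), key=lambda t: (t[0], t[1])
    )
    if len(ranked) < k:
        raise ValueError(f"only {len(ranked)} candidate genes for k={k}")
    return [g for _, g in ranked[:k]]


def qc_filter_cells(
    matrix: ExpressionMatrix,
    housekeeping: list[str],
    min_detected_hk: int | None = None,
) -> np.ndarray:
    """Boolean pass/fail per cell: a cell passes when at least
    ``min_detected_hk`` housekeeping genes have count >= 1 (default: all)."""
    missing = [g for g in housekeeping if g not in matrix.gene_ids]
    if missing:
        raise ValueError(f"housekeeping genes absent from matrix: {missing}")
    if min_detected_hk is None:
        min_detected_hk = len(housekeeping)
    idx = [matrix.gene_ids.index(g) for g in housekeeping]
    detected = (matrix.values[idx] >= 1).sum(axis=0)
    return detected >= min_detected_hk


def cell_cycle_stage(
    matrix: ExpressionMatrix,
    marker_sets: dict[str, list[str]],
    tie_tol: float = 0.05,
) -> list[CellCycleCall]:
    """Assign each cell the phase with the highest mean marker z-score.

    Values are log2(CPM+1)-normalized then z-scored per gene across
    cells; a cell is unassigned when its top two phase scores are within
    ``tie_tol``.
    """
    overlap = {
        phase: [g for g in genes if g in matrix.gene_ids]
        for phase, genes in marker_sets.items()
    }
    if not any(overlap.values()):
        raise ValueError("no marker genes overlap the matrix")
    norm = log_cpm(matrix.values)
    sd = norm.std(axis=1, ddof=0)
    sd = np.where(sd > 0, sd, 1.0)
    z = (norm - norm.mean(axis=1, keepdims=True)) / sd[:, None]
    gene_index = {g: i for i, g in enumerate(matrix.gene_ids)}
    calls: list[CellCycleCall] = []
    for c, cell_id in enumerate(matrix.cell_ids):
        scores = {
            phase: float(np.mean([z[gene_index[g], c] for g in genes])) if genes else -np.inf
            for phase, genes in overlap.items()
        }
        ordered = sorted(scores.items(), key=lambda t: -t[1])
        if len(ordered) > 1 and ordered[0][1] - ordered[1][1] < tie_tol:
            phase = CellCyclePhase.UNASSIGNED
        else:
            phase = CellCyclePhase(ordered[0][0])
        calls.append(CellCycleCall(cell_id=cell_id, phase=phase, scores=scores))
    return calls
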