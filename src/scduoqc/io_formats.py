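"""Readers/writers for the plain-text formats the pipeline touches.

Internal coordinate convention is 0-based half-open everywhere; VCF
positions (1-based) are converted on read.  Strand is ignored.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

SAM_FLAG_PAIRED = 0x1
SAM_FLAG_PROPER_PAIR = 0x2
SAM_FLAG_UNMAPPED = 0x4
SAM_FLAG_MATE_UNMAPPED = 0x8
SAM_FLAG_DUPLICATE = 0x400


class FractionType(str, Enum):
    """Sample fraction labels: separated DNA/RNA (FD/FR), whole-lysate
    controls (WD/WR), or a bulk sample."""

    FD = "FD"
    WD = "WD"
    FR = "FR"
    WR = "WR"
    BULK = "bulk"


class ReadAnnotation(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    INTERGENIC = "intergenic"
    UNALIGNED = "unaligned"


class FormatError(ValueError):
    """Raised on malformed or inconsistent input files."""


@dataclass(frozen=True)
class GenomeBins:
    """Sorted, non-overlapping genomic bins (0-based half-open)."""

    chrom: np.ndarray  # str per bin
    start: np.ndarray  # int per bin
    end: np.ndarray  # int per bin
    bin_size: int = 1_000_000

    def __post_init__(self) -> None:
        chrom = np.asarray(self.chrom, dtype=object)
        start = np.asarray(self.start, dtype=np.int64)
        end = np.asarray(self.end, dtype=np.int64)
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "start", start)
        object.__setattr__(self, "end", end)
        if not (len(chrom) == len(start) == len(end)):
            raise FormatError("bin arrays must have equal length")
        if len(start) and start.min() < 0:
            raise FormatError("bin start < 0")
        if np.any(end <= start):
            raise FormatError("bin end must exceed start")
        if np.any(end - start > self.bin_size):
            raise FormatError("bin wider than bin_size")
        self._check_sorted_nonoverlapping()

    def _check_sorted_nonoverlapping(self) -> None:
        prev_chrom, prev_end = None, -1
        seen: set[str] = set()
        for c, s, e in zip(self.chrom, self.start, self.end):
            if c != prev_chrom:
                if c in seen:
                    raise FormatError(f"bins for {c} are not contiguous in file")
                seen.add(c)
                prev_chrom, prev_end = c, -1
            if s < prev_end:
                raise FormatError(f"overlapping/unsorted bins at {c}:{s}")
            prev_end = e

    def __len__(self) -> int:
        return len(self.start)

    def same_grid(self, other: "GenomeBins") -> bool:
        return (
            len(self) == len(other)
            and bool(np.all(self.chrom == other.chrom))
            and bool(np.all(self.start == other.start))
            and bool(np.all(self.end == other.end))
        )

    @classmethod
    def uniform(cls, chrom_sizes: dict[str, int], bin_size: int = 1_000_000) -> "GenomeBins":
        """Tile each chromosome with fixed-width bins (last bin truncated)."""
        chroms, starts, ends = [], [], []
        for chrom, size in chrom_sizes.items():
            for s in range(0, size, bin_size):
                chroms.append(chrom)
                starts.append(s)
                ends.append(min(s + bin_size, size))
        return cls(np.array(chroms, dtype=object), np.array(starts), np.array(ends), bin_size)


@dataclass
class BinnedCounts:
    """Per-bin read counts for a single sample."""

    bins: GenomeBins
    counts: np.ndarray
    sample_id: str = ""
    fraction_type: FractionType = FractionType.BULK

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if len(self.counts) != len(self.bins):
            raise FormatError(
                f"{len(self.counts)} counts for {len(self.bins)} bins"
            )
        if len(self.counts) and self.counts.min() < 0:
            raise FormatError("negative bin count")


@dataclass(frozen=True)
class ReadRecord:
    """Minimal alignment record: flags, placement and region annotation."""

    flags: int
    chrom: str
    mate_chrom: str
    pos: int
    annotation: ReadAnnotation = ReadAnnotation.INTERGENIC

    def __post_init__(self) -> None:
        unmapped = bool(self.flags & SAM_FLAG_UNMAPPED)
        if unmapped != (self.annotation is ReadAnnotation.UNALIGNED):
            raise FormatError(
                "annotation 'unaligned' must match the unmapped flag bit"
            )

    @property
    def is_mapped(self) -> bool:
        return not self.flags & SAM_FLAG_UNMAPPED

    @property
    def is_duplicate(self) -> bool:
        return bool(self.flags & SAM_FLAG_DUPLICATE)

    @property
    def is_proper_pair(self) -> bool:
        return bool(self.flags & SAM_FLAG_PROPER_PAIR)


@dataclass
class VariantSet:
    """SNVs keyed by (chrom, pos, ref, alt); positions 0-based."""

    variants: set[tuple[str, int, str, str]]
    sample_id: str = ""

    def __post_init__(self) -> None:
        for chrom, pos, ref, alt in self.variants:
            if len(ref) != 1 or len(alt) != 1:
                raise FormatError(f"not a SNV: {chrom}:{pos} {ref}>{alt}")
            if ref == alt:
                raise FormatError(f"ref == alt at {chrom}:{pos}")

    def __len__(self) -> int:
        return len(self.variants)


@dataclass
class ExpressionMatrix:
    """Gene x cell matrix of non-negative expression values."""

    gene_ids: list[str]
    values: np.ndarray  # genes x cells
    cell_ids: list[str]
    cell_fractions: list[FractionType] | None = None
    gene_coords: dict[str, tuple[str, int]] | None = None  # gene -> (chrom, tss)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"matrix shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if self.values.size and self.values.min() < 0:
            raise FormatError("negative expression value")
        if self.cell_fractions is not None and len(self.cell_fractions) != len(self.cell_ids):
            raise FormatError("cell_fractions length mismatch")


# ---------------------------------------------------------------------------
# binned count tables (BED-like)
# ---------------------------------------------------------------------------

def read_bin_counts(
    path: str | Path,
    sample_id: str = "",
    fraction_type: FractionType = FractionType.BULK,
    bin_size: int = 1_000_000,
) -> BinnedCounts:
    """Parse a 4-column chrom/start/end/count table into BinnedCounts.

    Input intervals are 0-based half-open.  Rows may arrive unsorted; they
    are sorted by (chrom, start) with chromosome order of first appearance.
    """
    rows: list[tuple[str, int, int, int]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise FormatError(f"{path}: line {lineno}: expected 4+ columns")
            try:
                rows.append((parts[0], int(parts[1]), int(parts[2]), int(parts[3])))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
    if not rows:
        raise FormatError(f"{path}: no bins")
    chrom_order = {c: i for i, c in enumerate(dict.fromkeys(r[0] for r in rows))}
    rows.sort(key=lambda r: (chrom_order[r[0]], r[1]))
    chrom = np.array([r[0] for r in rows], dtype=object)
    start = np.array([r[1] for r in rows], dtype=np.int64)
    end = np.array([r[2] for r in rows], dtype=np.int64)
    counts = np.array([r[3] for r in rows], dtype=np.int64)
    bins = GenomeBins(chrom, start, end, bin_size=max(bin_size, int((end - start).max())))
    return BinnedCounts(bins, counts, sample_id=sample_id or Path(path).stem, fraction_type=fraction_type)


def write_bin_counts(bc: BinnedCounts, path: str | Path) -> None:
    with open(path, "w") as fh:
        for c, s, e, n in zip(bc.bins.chrom, bc.bins.start, bc.bins.end, bc.counts):
            fh.write(f"{c}\t{s}\t{e}\t{n}\n")


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

def read_sam_records(
    path: str | Path,
    annotator=None,
) -> list[ReadRecord]:
    """Stream alignment lines of a SAM file into ReadRecord objects.

    ``annotator`` maps (chrom, pos) to a ReadAnnotation for mapped reads;
    by default mapped reads are labelled intergenic.  RNEXT "=" resolves
    to RNAME.
    """
    import pysam

    records: list[ReadRecord] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for aln in sam:
            if aln.is_unmapped:
                ann = ReadAnnotation.UNALIGNED
                chrom = aln.reference_name or "*"
            else:
                chrom = aln.reference_name
                ann = (
                    annotator(chrom, aln.reference_start)
                    if annotator is not None
                    else ReadAnnotation.INTERGENIC
                )
            mate_chrom = aln.next_reference_name or "*"
            records.append(
                ReadRecord(
                    flags=aln.flag,
                    chrom=chrom,
                    mate_chrom=mate_chrom,
                    pos=aln.reference_start if not aln.is_unmapped else -1,
                    annotation=ann,
                )
            )
    return records


def write_sam_records(
    records: Sequence[ReadRecord],
    path: str | Path,
    chrom_sizes: dict[str, int] | None = None,
) -> None:
    """Write minimal single-end SAM lines (for toy fixtures and round trips)."""
    if chrom_sizes is None:
        chrom_sizes = {}
        for r in records:
            for c in (r.chrom, r.mate_chrom):
                if c != "*":
                    chrom_sizes[c] = max(chrom_sizes.get(c, 0), r.pos + 1000)
    with open(path, "w") as fh:
        fh.write("@HD\tVN:1.6\tSO:unknown\n")
        for c, size in chrom_sizes.items():
            fh.write(f"@SQ\tSN:{c}\tLN:{size}\n")
        for i, r in enumerate(records):
            rname = r.chrom if r.is_mapped else "*"
            pos = r.pos + 1 if r.is_mapped else 0
            mapq = 60 if r.is_mapped else 0
            cigar = "50M" if r.is_mapped else "*"
            rnext = r.mate_chrom if r.mate_chrom != "*" else "*"
            pnext = pos if rnext != "*" else 0
            fh.write(
                f"read{i}\t{r.flags}\t{rname}\t{pos}\t{mapq}\t{cigar}\t"
                f"{rnext}\t{pnext}\t0\t*\t*\n"
            )


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def read_vcf_snvs(path: str | Path, sample_id: str = "") -> VariantSet:
    """Read SNVs from a VCF; indels/MNVs are skipped (count logged).

    VCF positions are 1-based; stored 0-based.  Multi-allelic ALT fields
    are split and each SNV allele kept.
    """
    variants: set[tuple[str, int, str, str]] = set()
    n_skipped = 0
    saw_header = False
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#CHROM"):
                saw_header = True
                continue
            if line.startswith("#"):
                continue
            if not saw_header:
                raise FormatError(f"{path}: data line {lineno} before #CHROM header")
            parts = line.split("\t")
            if len(parts) < 5:
                raise FormatError(f"{path}: line {lineno}: fewer than 8 VCF columns")
            chrom, pos_s, _id, ref, alts = parts[:5]
            try:
                pos = int(pos_s) - 1
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: bad POS") from exc
            for alt in alts.split(","):
                if len(ref) == 1 and len(alt) == 1 and alt in "ACGTN" and ref != alt:
                    variants.add((chrom, pos, ref, alt))
                else:
                    n_skipped += 1
    if n_skipped:
        log.info("read_vcf_snvs: skipped %d non-SNV allele(s) in %s", n_skipped, path)
    return VariantSet(variants, sample_id=sample_id or Path(path).stem)


def write_vcf_snvs(vs: VariantSet, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for chrom, pos, ref, alt in sorted(vs.variants):
            fh.write(f"{chrom}\t{pos + 1}\t.\t{ref}\t{alt}\t.\tPASS\t.\n")


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------

def read_expression_matrix(path: str | Path, coords_path: str | Path | None = None) -> ExpressionMatrix:
    """Load a genes x cells matrix; TSV or MatrixMarket by extension.

    For ``.mtx`` the row/column index files ``<stem>.genes.txt`` and
    ``<stem>.cells.txt`` must sit next to the matrix.
    """
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(str(path)).todense(), dtype=float)
        gene_ids = Path(path.with_suffix("")).with_suffix(".genes.txt").read_text().split()
        cell_ids = Path(path.with_suffix("")).with_suffix(".cells.txt").read_text().split()
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=float)
        gene_ids = [str(g) for g in df.index]
        cell_ids = [str(c) for c in df.columns]
    coords = read_gene_coords(coords_path) if coords_path else None
    return ExpressionMatrix(gene_ids, mat, cell_ids, gene_coords=coords)


def write_expression_matrix(em: ExpressionMatrix, path: str | Path) -> None:
    df = pd.DataFrame(em.values, index=em.gene_ids, columns=em.cell_ids)
    df.index.name = "gene"
    df.to_csv(path, sep="\t")


def read_gene_coords(path: str | Path) -> dict[str, tuple[str, int]]:
    """Three-column TSV gene/chrom/tss (0-based TSS position)."""
    coords: dict[str, tuple[str, int]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"{path}: line {lineno}: expected gene/chrom/tss")
            coords[parts[0]] = (parts[1], int(parts[2]))
    return coords


def write_gene_coords(coords: dict[str, tuple[str, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gene, (chrom, tss) in coords.items():
            fh.write(f"{gene}\t{chrom}\t{tss}\n")
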