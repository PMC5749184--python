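"""End-to-end pipeline driver: simulate -> genome QC -> CNV -> RNA QC ->
integration, with a machine-readable summary.

All randomness flows from config seeds; no stage reads the wall clock.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from . import __version__
from .cnv_profiling import (
    CbsParams,
    average_profiles,
    cbs_segment,
    cluster_profiles,
    normalize_to_log2,
    profile_correlation,
    write_segments,
)
from .genome_qc import bin_cv, lorenz_curve, power_spectrum
from .integration import bin_expression, cnv_expression_correlation
from .io_formats import write_bin_counts, write_expression_matrix, write_gene_coords, write_vcf_snvs
from .rna_metrics import detect_genes, ercc_correlation, qc_filter_cells, select_housekeeping_genes
from .synthetic_data import SimTruth, make_cn_profile, simulate_scrna, simulate_snv_calls, simulate_wgs_bins

log = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Inputs and knobs for one synthetic end-to-end run."""

    out_dir: str = "scduoqc_out"
    seed: int = 0
    bin_size: int = 1_000_000
    n_bins: int = 200
    n_cells: int = 12
    n_genes: int = 2000
    mean_depth_per_bin: float = 200.0
    bias_sigma: float = 0.3
    bias_rho: float = 0.5
    cn_segments: list = field(
        default_factory=lambda: [[40, 70, 3], [120, 150, 1]]
    )
    cbs_alpha: float = 0.01
    cbs_n_perm: int = 200
    cbs_min_width: int = 3

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yml", ".yaml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full synthetic pipeline; returns the report directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    summary: dict = {"version": __version__, "seed": config.seed}
    rng = np.random.default_rng(config.seed)

    stage = "simulate"
    try:
        bins, cn = make_cn_profile(
            config.n_bins,
            [tuple(s) for s in config.cn_segments],
            bin_size=config.bin_size,
        )
        truth = SimTruth(
            bins=bins,
            cn_profile=cn,
            bias_sigma=config.bias_sigma,
            bias_rho=config.bias_rho,
            seed=config.seed,
        )
        cells, _ = simulate_wgs_bins(truth, config.mean_depth_per_bin, config.n_cells)
        for bc in cells:
            write_bin_counts(bc, out / f"wgs_{bc.sample_id}.bed")
        bulk_profile = rng.lognormal(1.0, 1.5, size=config.n_genes)
        ercc_inputs = np.geomspace(1, 1e4, 92)
        em, spikes = simulate_scrna(bulk_profile, config.n_cells, truth, ercc_inputs)
        coords = {
            g: (bins.chrom[i % len(bins)], int(bins.start[i % len(bins)]) + 500)
            for i, g in enumerate(em.gene_ids)
        }
        em.gene_coords = coords
        write_expression_matrix(em, out / "expression.tsv")
        write_gene_coords(coords, out / "gene_coords.tsv")
        truth_vs = _random_truth_variants(rng)
        truth.true_variants = truth_vs
        truth.sensitivity, truth.fp_rate = 0.85, 5.0
        snv_cells = simulate_snv_calls(truth, config.n_cells)
        for vs in snv_cells:
            write_vcf_snvs(vs, out / f"snv_{vs.sample_id}.vcf")
        write_vcf_snvs(truth_vs, out / "snv_bulk.vcf")
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "genome-qc"
    try:
        with open(out / "genome_qc.tsv", "w") as fh:
            fh.write("sample\tbin_cv\tlorenz_auc\tpsd_summary\n")
            for bc in cells:
                fh.write(
                    f"{bc.sample_id}\t{bin_cv(bc):.6g}\t"
                    f"{lorenz_curve(bc).auc:.6g}\t{power_spectrum(bc).summary:.6g}\n"
                )
        summary["genome_qc"] = {
            "mean_bin_cv": float(np.mean([bin_cv(bc) for bc in cells])),
            "mean_lorenz_auc": float(np.mean([lorenz_curve(bc).auc for bc in cells])),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "cnv"
    try:
        params = CbsParams(
            alpha=config.cbs_alpha,
            n_perm=config.cbs_n_perm,
            min_width=config.cbs_min_width,
            seed=config.seed,
        )
        profiles = [cbs_segment(normalize_to_log2(bc), params) for bc in cells]
        for prof in profiles:
            write_segments(prof, out / f"segments_{prof.sample_id}.tsv")
        avg = average_profiles(profiles)
        corr = [profile_correlation(avg, p) for p in profiles]
        _, labels = cluster_profiles(
            np.vstack([p.log2_ratio for p in profiles]), k=2
        )
        summary["cnv"] = {
            "mean_profile_correlation_to_average": float(np.nanmean(corr)),
            "n_segments_per_cell": [len(p.segments) for p in profiles],
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "rna-qc"
    try:
        detected = detect_genes(em)
        hk = select_housekeeping_genes(em, k=8)
        passing = qc_filter_cells(em, hk)
        ercc_r = [
            ercc_correlation(spikes[:, c], ercc_inputs) for c in range(config.n_cells)
        ]
        with open(out / "rna_qc.tsv", "w") as fh:
            fh.write("cell\tgenes_detected\thk_pass\tercc_r\n")
            for c, cell_id in enumerate(em.cell_ids):
                fh.write(
                    f"{cell_id}\t{int(detected[c])}\t{bool(passing[c])}\t{ercc_r[c]:.4f}\n"
                )
        summary["rna_qc"] = {
            "mean_genes_detected": float(detected.mean()),
            "n_cells_pass_hk": int(passing.sum()),
            "mean_ercc_r": float(np.nanmean(ercc_r)),
        }
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    stage = "integrate"
    try:
        expr_bins = bin_expression(em, bins)
        r, p = cnv_expression_correlation(avg, expr_bins)
        summary["integration"] = {"cnv_expression_r": r, "cnv_expression_p": p}
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, exc) from exc

    with open(out / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    with open(out / "run.log", "w") as fh:
        fh.write(f"scduoqc {__version__} seed={config.seed}\n")
    return out


def _random_truth_variants(rng: np.random.Generator, n: int = 100):
    from .io_formats import VariantSet

    variants = set()
    while len(variants) < n:
        pos = int(rng.integers(0, 50_000_000))
        ref, alt = rng.choice(list("ACGT"), size=2, replace=False)
        variants.add(("chr1", pos, str(ref), str(alt)))
    return VariantSet(variants, sample_id="truth")
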