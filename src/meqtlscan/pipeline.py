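"""End-to-end driver: read inputs, call genotypes, QC, stratified scans,
annotation, differential calls; write one output directory.

All outputs are deterministic functions of the inputs and configuration, so
re-running a pipeline on the same files yields byte-identical results (the
run log records versions and stage counts but no timestamps).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy
import statsmodels

from . import __version__, annotate, calling, differential, io, qc, scan
from .config import PipelineConfig

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    """Wraps a failure with the name of the pipeline stage that raised it."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[{stage}] {cause}")
        self.stage = stage


@dataclass
class PipelineResult:
    out_dir: Path
    counts: dict = field(default_factory=dict)
    outputs: dict = field(default_factory=dict)


def _count_matrix_dims(path: Path) -> tuple[int, int]:
    """(n_features, n_samples) from a matrix TSV without loading values."""
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        n_samples = len(header.split("\t")) - 1
        n_features = sum(1 for line in fh if line.strip())
    return n_features, n_samples


def run_pipeline(config: PipelineConfig, dry_run: bool = False) -> PipelineResult:
    """Execute the full analysis (or a metadata-only dry run).

    A dry run reads only matrix dimensions and reports the number of
    SNP-CpG pairs a full scan would attempt, without fitting anything.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    counts: dict = {}
    log_lines: list[str] = [
        f"meqtlscan {__version__} "
        f"(numpy {np.__version__}, scipy {scipy.__version__}, "
        f"pandas {pd.__version__}, statsmodels {statsmodels.__version__})",
        f"alpha={config.alpha} window={config.window} "
        f"fdr_scope={config.fdr_scope} hwe_group={config.hwe_group} "
        f"qc=(maf>{config.qc.maf_min}, missing<{config.qc.missing_max}, "
        f"hwe_p>{config.qc.hwe_p_min}) seed={config.seed}",
    ]

    def note(msg: str) -> None:
        logger.info(msg)
        log_lines.append(msg)

    geno_path = config.probes if config.probes is not None else config.genotypes

    if dry_run:
        try:
            n_snps, _ = _count_matrix_dims(Path(geno_path))
            n_cpgs, n_samples = _count_matrix_dims(Path(config.methylation))
        except OSError as exc:
            raise StageError("read", exc) from exc
        pairs = scan.attempted_pairs(n_snps, n_cpgs)
        counts.update(
            snps_input=n_snps, cpgs_input=n_cpgs, samples=n_samples,
            pairs_attempted=pairs,
        )
        note(f"dry run: {n_snps} SNPs x {n_cpgs} CpGs on {n_samples} samples")
        note(f"pairs_attempted={pairs}")
        log_path = out_dir / "run_log.txt"
        log_path.write_text("\n".join(log_lines) + "\n")
        return PipelineResult(out_dir, counts, {"run_log": log_path})

    # ---- read ------------------------------------------------------------
    try:
        meth = io.read_methylation_matrix(config.methylation)
        samples = io.read_sample_table(config.samples)
    except Exception as exc:
        raise StageError("read", exc) from exc

    # ---- genotypes: call from probes, or load pre-called codes -----------
    try:
        if config.probes is not None:
            probes = io.read_matrix(config.probes, kind="probes")
            snp_meta = (
                io.read_bed(config.snp_bed).reindex(probes.index)
                if config.snp_bed is not None else None
            )
            genotypes = calling.call_matrix(
                probes, config.max_cluster_distance, snp_meta
            )
            note(f"called genotypes for {len(genotypes.snp_ids)} SNPs "
                 f"from probe signal")
        else:
            genotypes = io.read_genotype_matrix(config.genotypes)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("genotype_calling", exc) from exc
    counts["snps_input"] = len(genotypes.snp_ids)
    counts["cpgs_input"] = len(meth.cpg_ids)

    # ---- QC ---------------------------------------------------------------
    try:
        qc_result = qc.filter_snps(
            genotypes, config.qc, samples=samples, hwe_group=config.hwe_group
        )
    except Exception as exc:
        raise StageError("genotype_qc", exc) from exc
    genotypes = qc_result.genotypes
    counts["snps_pass_qc"] = len(genotypes.snp_ids)
    note(f"QC: {counts['snps_pass_qc']}/{counts['snps_input']} SNPs pass")

    # ---- stratified scans --------------------------------------------------
    results = {}
    for stratum in ("case", "control"):
        try:
            rec = scan.scan(
                meth, genotypes, samples, stratum=stratum,
                alpha=config.alpha, fdr_scope=config.fdr_scope,
            )
        except Exception as exc:
            raise StageError(f"scan_{stratum}", exc) from exc
        results[stratum] = rec
        counts[f"pairs_attempted_{stratum}"] = len(rec)
        counts[f"pairs_tested_{stratum}"] = int(
            (rec["status"] == scan.STATUS_OK).sum()
        )
        counts[f"significant_{stratum}"] = int(rec["significant"].sum())
        note(
            f"scan[{stratum}]: attempted={len(rec)} "
            f"tested={counts[f'pairs_tested_{stratum}']} "
            f"significant={counts[f'significant_{stratum}']}"
        )

    # ---- annotation --------------------------------------------------------
    annotated = {}
    if config.snp_bed is not None and config.cpg_bed is not None:
        try:
            snp_loci = io.read_bed(config.snp_bed)
            cpg_loci = io.read_bed(config.cpg_bed)
            for stratum, rec in results.items():
                sig = scan.significant_records(rec)
                annotated[stratum] = annotate.annotate_records(
                    sig, snp_loci, cpg_loci, window=config.window
                )
        except Exception as exc:
            raise StageError("annotation", exc) from exc

    # ---- differential ------------------------------------------------------
    try:
        diff = differential.compare(
            results["case"], results["control"], meth, samples,
            alpha=config.alpha,
        )
    except Exception as exc:
        raise StageError("differential", exc) from exc
    for cat in (differential.CASE_ONLY, differential.CONTROL_ONLY,
                differential.BOTH):
        counts[f"n_{cat}"] = int((diff["category"] == cat).sum())
    note(
        f"differential: case_only={counts['n_case_only']} "
        f"control_only={counts['n_control_only']} both={counts['n_both']}"
    )

    # ---- write -------------------------------------------------------------
    outputs = {}
    try:
        outputs["qc"] = out_dir / "qc.tsv"
        qc_result.report.reset_index().to_csv(
            outputs["qc"], sep="\t", index=False
        )
        for stratum, rec in results.items():
            outputs[f"scan_{stratum}"] = out_dir / f"scan_{stratum}.tsv"
            io.write_results(rec, outputs[f"scan_{stratum}"])
        if annotated:
            frames = [annotated["case"], annotated["control"]]
            outputs["annotated"] = out_dir / "annotated.tsv"
            io.write_results(
                pd.concat(frames, ignore_index=True), outputs["annotated"]
            )
        outputs["differential"] = out_dir / "differential.tsv"
        io.write_results(diff, outputs["differential"])
        outputs["run_log"] = out_dir / "run_log.txt"
        outputs["run_log"].write_text("\n".join(log_lines) + "\n")
    except Exception as exc:
        raise StageError("write", exc) from exc

    return PipelineResult(out_dir, counts, outputs)
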