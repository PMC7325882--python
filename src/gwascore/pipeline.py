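"""End-to-end orchestration: score -> regions -> summaries -> candidates.

Stages run in the analysis order: windowed scoring of the GWAS table,
high-confidence region selection, CNV genotype summaries, three-track
intersection, gene annotation and (optionally) CIRCOS export.  Each stage
logs its record counts so input/output bookkeeping is auditable; any
failure is re-raised as :class:`PipelineError` prefixed with the stage
name, before partial output from later stages is written.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

from . import io as gio
from .circos import TrackBundle, export_circos
from .cnv import genotype_class_distribution, shared_specific_summary
from .core import ScoreConfig, high_confidence_regions, score_genome
from .errors import GwascoreError, PipelineError
from .integrate import annotate_candidates, intersect_three_tracks

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run."""

    gwas_path: str
    qtl_path: str
    cnvr_path: str
    sample_sheet_path: str
    gff3_path: str
    out_dir: str
    score: ScoreConfig = field(default_factory=ScoreConfig)
    upstream_bp: int = 1000
    specificity_level: str = "class"
    chrom_lengths_path: str | None = None
    export_tracks: bool = True


@dataclass
class PipelineResult:
    windows: list
    regions: list
    candidates: list
    candidate_rows: list
    distribution: object
    shared_specific: object
    outputs: dict[str, str]


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except GwascoreError as e:
                raise PipelineError(f"{name}: {e}") from e

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write all outputs under ``config.out_dir``."""
    out = Path(config.out_dir)

    read = _stage("read")
    gwas = read(gio.read_gwas)(config.gwas_path)
    qtls = read(gio.read_qtl)(config.qtl_path)
    matrix = read(gio.read_cnvr)(config.cnvr_path)
    sheet = read(gio.read_sample_sheet)(config.sample_sheet_path)
    annotation = read(gio.read_gff3)(config.gff3_path)
    lengths = (
        read(gio.read_chrom_lengths)(config.chrom_lengths_path)
        if config.chrom_lengths_path
        else None
    )
    logger.info(
        "inputs: %d GWAS records, %d QTLs, %d CNVRs, %d samples, %d genes",
        len(gwas), len(qtls), len(matrix), len(matrix.samples),
        len(annotation.genes),
    )

    windows = _stage("score")(score_genome)(gwas, config.score, lengths)
    regions = _stage("regions")(high_confidence_regions)(windows, config.score)
    logger.info(
        "score: %d occupied windows, %d high-confidence regions "
        "(threshold %g, window %d bp)",
        len(windows), len(regions), config.score.score_threshold,
        config.score.window_size,
    )

    distribution = _stage("cnv-summary")(genotype_class_distribution)(matrix, sheet)
    shared = _stage("cnv-summary")(shared_specific_summary)(
        matrix, sheet, config.specificity_level
    )
    logger.info(
        "cnv: shared=%d, specific=%s (level=%s)",
        shared.shared, shared.specific, shared.level,
    )

    candidates = _stage("integrate")(intersect_three_tracks)(
        matrix.regions, qtls, regions
    )
    rows = _stage("annotate")(annotate_candidates)(
        candidates, annotation, config.upstream_bp
    )
    logger.info(
        "integrate: %d candidate CNVRs -> %d candidate rows",
        len(candidates), len(rows),
    )

    out.mkdir(parents=True, exist_ok=True)
    outputs: dict[str, str] = {}

    def emit(name: str, writer, *args) -> None:
        path = out / name
        writer(*args, path)
        outputs[name] = str(path)

    emit("score_windows.tsv", gio.write_score_windows, windows)
    emit("score_regions.tsv", gio.write_score_windows, regions)
    emit("score_regions.bed", gio.write_score_bed, regions)
    emit("candidates.tsv", gio.write_candidates, rows)
    emit("candidates.bed", gio.write_candidate_bed, rows)

    summary = {
        "cell_counts": distribution.cell_counts,
        "region_majority": distribution.region_majority,
        "specific": shared.specific,
        "shared": shared.shared,
        "specificity_level": shared.level,
    }
    (out / "cnv_summary.json").write_text(
        json.dumps(summary, indent=2, sort_keys=True) + "\n"
    )
    outputs["cnv_summary.json"] = str(out / "cnv_summary.json")

    if config.export_tracks:
        karyotype = lengths or _karyotype_from_tracks(gwas, qtls, matrix, regions)
        bundle = TrackBundle(
            karyotype=karyotype,
            qtls=qtls,
            score_windows=regions,
            gwas=gwas,
            cnvrs=matrix.regions,
        )
        track_paths = _stage("circos")(export_circos)(bundle, out / "circos")
        outputs.update({f"circos/{Path(v).name}": v for v in track_paths.values()})

    return PipelineResult(
        windows=windows,
        regions=regions,
        candidates=candidates,
        candidate_rows=rows,
        distribution=distribution,
        shared_specific=shared,
        outputs=outputs,
    )


def _karyotype_from_tracks(gwas, qtls, matrix, regions) -> dict[str, int]:
    """Fallback karyotype: the rightmost coordinate seen per chromosome."""
    lengths: dict[str, int] = {}

    def bump(chrom: str, end: int) -> None:
        lengths[chrom] = max(lengths.get(chrom, 0), end)

    for a in gwas:
        bump(a.chrom, a.pos)
    for q in qtls:
        bump(q.chrom, q.end)
    for r in matrix.regions:
        bump(r.chrom, r.end)
    for w in regions:
        bump(w.chrom, w.end)
    return lengths
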