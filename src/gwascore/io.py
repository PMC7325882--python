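"""Readers and writers for the package's tab-separated dialects and GFF3.

All on-disk tables are 1-based inclusive (the convention of Animal
QTLdb-style exports and of the candidate table); BED exports are 0-based
half-open.  Readers validate every record against the domain invariants and
report malformed values with their line number; chromosome names without a
``chr`` prefix are auto-prefixed with a logged notice.

Dialects
--------
GWAS associations   study_id, trait, chrom, pos, p_value
QTL intervals       qtl_id, trait, chrom, start, end
CNVR genotypes      chrom, start, end, <one column per sample>
Sample sheet        sample, breed
Score windows       chrom, start, end, n_gwas, n_snp, gwascore
Candidate table     Chromosome, Start, End, GWAScore, n_QTL, Gene, Location
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import gffutils
import pandas as pd

from .cnv import CnvRegion, GenotypeMatrix, SampleSheet
from .core import GwasAssociation, ScoreWindow, chrom_sort_key
from .errors import ValidationError
from .integrate import CandidateGene, Gene, GenomeAnnotation, QtlRecord

__all__ = [
    "read_gwas",
    "read_qtl",
    "read_cnvr",
    "read_sample_sheet",
    "read_gff3",
    "read_score_windows",
    "read_candidates",
    "read_chrom_lengths",
    "write_gwas",
    "write_qtl",
    "write_cnvr_matrix",
    "write_sample_sheet",
    "write_gff3",
    "write_score_windows",
    "write_score_bed",
    "write_candidates",
    "write_candidate_bed",
]

logger = logging.getLogger(__name__)

_GWAS_COLS = ["study_id", "trait", "chrom", "pos", "p_value"]
_QTL_COLS = ["qtl_id", "trait", "chrom", "start", "end"]
_SCORE_COLS = ["chrom", "start", "end", "n_gwas", "n_snp", "gwascore"]
_CAND_COLS = ["Chromosome", "Start", "End", "GWAScore", "n_QTL", "Gene", "Location"]


def _canon_chrom(name: str) -> str:
    name = str(name).strip()
    if not name.startswith("chr"):
        logger.info("auto-prefixing chromosome name %r with 'chr'", name)
        return f"chr{name}"
    return name


def _load_table(path, required: Sequence[str]) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(
            f"{path}: missing required column(s) {', '.join(missing)}"
        )
    return df


def _to_int(value: str, what: str, path, line: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(
            f"{path}, line {line}: unparseable {what} {value!r}"
        ) from None


def _to_float(value: str, what: str, path, line: int) -> float:
    try:
        return float(value)
    except ValueError:
        raise ValidationError(
            f"{path}, line {line}: unparseable {what} {value!r}"
        ) from None


def read_gwas(path) -> list[GwasAssociation]:
    """Read a GWAS association table; positions 1-based."""
    df = _load_table(path, _GWAS_COLS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2  # header is line 1
        assoc = GwasAssociation(
            study_id=str(row.study_id),
            trait=str(row.trait),
            chrom=_canon_chrom(row.chrom),
            pos=_to_int(row.pos, "position", path, line),
            p_value=_to_float(row.p_value, "p_value", path, line),
        )
        try:
            assoc.validate()
        except ValidationError as e:
            raise ValidationError(f"{path}, line {line}: {e}") from None
        out.append(assoc)
    logger.info("read %d GWAS associations from %s", len(out), path)
    return out


def read_qtl(path) -> list[QtlRecord]:
    """Read a QTL interval table; 1-based inclusive coordinates."""
    df = _load_table(path, _QTL_COLS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        start = _to_int(row.start, "start", path, line)
        end = _to_int(row.end, "end", path, line)
        try:
            out.append(
                QtlRecord(
                    qtl_id=str(row.qtl_id),
                    trait=str(row.trait),
                    chrom=_canon_chrom(row.chrom),
                    start=start - 1,
                    end=end,
                )
            )
        except ValidationError as e:
            raise ValidationError(f"{path}, line {line}: {e}") from None
    logger.info("read %d QTL records from %s", len(out), path)
    return out


def read_cnvr(path) -> GenotypeMatrix:
    """Read a CNVcaller-style genotype table (chrom, start, end, samples...)."""
    df = _load_table(path, ["chrom", "start", "end"])
    sample_cols = [c for c in df.columns if c not in ("chrom", "start", "end")]
    if not sample_cols:
        raise ValidationError(f"{path}: no sample columns after chrom/start/end")
    regions, rows = [], []
    for i, row in df.iterrows():
        line = i + 2
        chrom = _canon_chrom(row["chrom"])
        start = _to_int(row["start"], "start", path, line)
        end = _to_int(row["end"], "end", path, line)
        try:
            regions.append(CnvRegion(f"{chrom}:{start}-{end}", chrom, start - 1, end))
        except ValidationError as e:
            raise ValidationError(f"{path}, line {line}: {e}") from None
        rows.append([str(row[c]) for c in sample_cols])
    codes = pd.DataFrame(
        rows, index=[r.region_id for r in regions], columns=sample_cols
    )
    try:
        matrix = GenotypeMatrix(regions, codes)
    except ValidationError as e:
        raise ValidationError(f"{path}: {e}") from None
    logger.info(
        "read %d CNV regions x %d samples from %s",
        len(regions),
        len(sample_cols),
        path,
    )
    return matrix


def read_sample_sheet(path) -> SampleSheet:
    df = _load_table(path, ["sample", "breed"])
    mapping: dict[str, str] = {}
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        sample = str(row.sample)
        if sample in mapping:
            raise ValidationError(f"{path}, line {line}: duplicate sample {sample!r}")
        mapping[sample] = str(row.breed)
    logger.info("read %d samples (%d breeds) from %s", len(mapping),
                len(set(mapping.values())), path)
    return SampleSheet(mapping)


def read_chrom_lengths(path) -> dict[str, int]:
    """Two-column TSV (chrom, length) without header requirement."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    lengths: dict[str, int] = {}
    for i, raw in enumerate(path.read_text().splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        parts = raw.split("\t")
        if parts[0] in ("chrom", "chromosome"):
            continue
        if len(parts) < 2:
            raise ValidationError(f"{path}, line {i}: expected 2 columns")
        lengths[_canon_chrom(parts[0])] = _to_int(parts[1], "length", path, i)
    return lengths


def read_gff3(path) -> GenomeAnnotation:
    """Load gene models (gene spans, exons, UTRs) from a GFF3 file."""
    path = Path(path)
    if not path.exists():
        raise ValidationError(f"input file not found: {path}")
    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        keep_order=True,
        merge_strategy="create_unique",
        sort_attribute_values=True,
    )
    genes: list[Gene] = []
    for f in db.features_of_type("gene"):
        exons = sorted(
            (c.start - 1, c.end) for c in db.children(f, featuretype="exon")
        )
        utr5 = sorted(
            (c.start - 1, c.end)
            for c in db.children(f, featuretype="five_prime_UTR")
        )
        utr3 = sorted(
            (c.start - 1, c.end)
            for c in db.children(f, featuretype="three_prime_UTR")
        )
        attrs = f.attributes
        symbol = (attrs.get("Name") or attrs.get("gene_name") or [f.id])[0]
        biotype = (attrs.get("biotype") or attrs.get("gene_biotype") or [None])[0]
        genes.append(
            Gene(
                gene_id=f.id,
                symbol=symbol,
                chrom=_canon_chrom(f.seqid),
                start=f.start - 1,
                end=f.end,
                strand=f.strand if f.strand in ("+", "-") else "+",
                exons=tuple(exons),
                utr5=tuple(utr5),
                utr3=tuple(utr3),
                biotype=biotype,
            )
        )
    logger.info("read %d genes from %s", len(genes), path)
    return GenomeAnnotation(genes)


def read_score_windows(path) -> list[ScoreWindow]:
    df = _load_table(path, _SCORE_COLS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        out.append(
            ScoreWindow(
                chrom=_canon_chrom(row.chrom),
                start=_to_int(row.start, "start", path, line) - 1,
                end=_to_int(row.end, "end", path, line),
                n_gwas=_to_int(row.n_gwas, "n_gwas", path, line),
                n_snp=_to_int(row.n_snp, "n_snp", path, line),
                score=_to_float(row.gwascore, "gwascore", path, line),
            )
        )
    return out


def read_candidates(path) -> list[CandidateGene]:
    df = _load_table(path, _CAND_COLS)
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        line = i + 2
        gene = str(row.Gene)
        out.append(
            CandidateGene(
                chrom=_canon_chrom(row.Chromosome),
                start=_to_int(row.Start, "Start", path, line) - 1,
                end=_to_int(row.End, "End", path, line),
                gwascore=_to_float(row.GWAScore, "GWAScore", path, line),
                n_qtl=_to_int(row.n_QTL, "n_QTL", path, line),
                gene_id=None if gene == "." else gene,
                gene_symbol=None if gene == "." else gene,
                location=str(row.Location),
            )
        )
    return out


# ---------------------------------------------------------------------------
# writers — canonical formatting so write(read(f)) == f on canonical files


def _fmt(x: float) -> str:
    return repr(float(x))


def write_gwas(associations: Iterable[GwasAssociation], path) -> None:
    lines = ["\t".join(_GWAS_COLS)]
    for a in associations:
        lines.append(
            f"{a.study_id}\t{a.trait}\t{a.chrom}\t{a.pos}\t{_fmt(a.p_value)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_qtl(qtls: Iterable[QtlRecord], path) -> None:
    lines = ["\t".join(_QTL_COLS)]
    for q in qtls:
        lines.append(f"{q.qtl_id}\t{q.trait}\t{q.chrom}\t{q.start + 1}\t{q.end}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_cnvr_matrix(matrix: GenotypeMatrix, path) -> None:
    header = ["chrom", "start", "end"] + matrix.samples
    lines = ["\t".join(header)]
    for region in matrix.regions:
        row = matrix.codes.loc[region.region_id]
        cells = [str(row[s]) for s in matrix.samples]
        lines.append(
            f"{region.chrom}\t{region.start + 1}\t{region.end}\t" + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    lines = ["sample\tbreed"]
    for sample, breed in sheet.mapping.items():
        lines.append(f"{sample}\t{breed}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_gff3(
    genes: Sequence[Gene], chrom_lengths: Mapping[str, int], path
) -> None:
    """Write gene/mRNA/exon/UTR features in GFF3 (1-based inclusive)."""
    lines = ["##gff-version 3"]
    for chrom in sorted(chrom_lengths, key=chrom_sort_key):
        lines.append(f"##sequence-region {chrom} 1 {chrom_lengths[chrom]}")
    src = "gwascore-sim"
    for g in sorted(genes, key=lambda g: (chrom_sort_key(g.chrom), g.start, g.gene_id)):
        bt = f";biotype={g.biotype}" if g.biotype else ""
        lines.append(
            f"{g.chrom}\t{src}\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={g.gene_id};Name={g.symbol}{bt}"
        )
        tid = f"{g.gene_id}.t1"
        lines.append(
            f"{g.chrom}\t{src}\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\t"
            f"ID={tid};Parent={g.gene_id}"
        )
        for i, (s, e) in enumerate(g.exons, start=1):
            lines.append(
                f"{g.chrom}\t{src}\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.exon{i};Parent={tid}"
            )
        for i, (s, e) in enumerate(g.utr5, start=1):
            lines.append(
                f"{g.chrom}\t{src}\tfive_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.utr5.{i};Parent={tid}"
            )
        for i, (s, e) in enumerate(g.utr3, start=1):
            lines.append(
                f"{g.chrom}\t{src}\tthree_prime_UTR\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={g.gene_id}.utr3.{i};Parent={tid}"
            )
    Path(path).write_text("\n".join(lines) + "\n")


def write_score_windows(windows: Iterable[ScoreWindow], path) -> None:
    """Score windows as TSV, 1-based inclusive coordinates."""
    lines = ["\t".join(_SCORE_COLS)]
    for w in windows:
        lines.append(
            f"{w.chrom}\t{w.start + 1}\t{w.end}\t{w.n_gwas}\t{w.n_snp}\t"
            f"{_fmt(w.score)}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_score_bed(windows: Iterable[ScoreWindow], path) -> None:
    """Score windows as BED (0-based half-open); column 5 = round(score*100)."""
    lines = []
    for w in windows:
        lines.append(
            f"{w.chrom}\t{w.start}\t{w.end}\t"
            f"{w.chrom}:{w.start + 1}-{w.end}\t{round(w.score * 100)}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def write_candidates(rows: Iterable[CandidateGene], path) -> None:
    """Candidate table in the published column order (1-based inclusive)."""
    lines = ["\t".join(_CAND_COLS)]
    for c in rows:
        gene = c.gene_symbol if c.gene_symbol is not None else "."
        lines.append(
            f"{c.chrom}\t{c.start + 1}\t{c.end}\t{_fmt(c.gwascore)}\t{c.n_qtl}\t"
            f"{gene}\t{c.location}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_candidate_bed(rows: Iterable[CandidateGene], path) -> None:
    seen: set[tuple[str, int, int]] = set()
    lines = []
    for c in rows:
        key = (c.chrom, c.start, c.end)
        if key in seen:
            continue
        seen.add(key)
        lines.append(
            f"{c.chrom}\t{c.start}\t{c.end}\t{c.chrom}:{c.start + 1}-{c.end}\t"
            f"{round(c.gwascore * 100)}"
        )
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
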