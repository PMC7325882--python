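"""Three-track integration and gene-feature location annotation.

A CNV region becomes a positional candidate when it overlaps (>= 1 shared
bp) both a high-confidence score region and at least one QTL interval.  The
candidate carries the maximum score over overlapping score windows and the
number of distinct overlapping QTLs.  Candidates are then paired with the
genes they overlap (or flank within ``upstream_bp``) and each pair is given
a location label from the fixed vocabulary

    exonic > UTR5 > UTR3 > intronic > upstream > downstream > intergenic

with the precedence applied when a region touches several feature kinds.
"exonic" means overlap with the coding part of an exon (exon minus UTR), so
that a region confined to an annotated UTR is labelled UTR5/UTR3 rather
than exonic.  Flank distances are strand-aware.

All coordinates are 0-based half-open internally; readers and writers
convert from/to the 1-based inclusive convention of the TSV dialects.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .cnv import CnvRegion
from .core import ScoreWindow, chrom_sort_key
from .errors import ValidationError

__all__ = [
    "QtlRecord",
    "Gene",
    "GenomeAnnotation",
    "CandidateRegion",
    "CandidateGene",
    "LOCATION_LABELS",
    "intersect_three_tracks",
    "classify_location",
    "annotate_candidates",
    "location_distribution",
]

logger = logging.getLogger(__name__)

#: Location vocabulary in precedence order (most specific first).
LOCATION_LABELS = (
    "exonic",
    "UTR5",
    "UTR3",
    "intronic",
    "upstream",
    "downstream",
    "intergenic",
)
_RANK = {label: i for i, label in enumerate(LOCATION_LABELS)}


@dataclass(frozen=True)
class QtlRecord:
    """A trait-associated genomic interval (0-based half-open internally)."""

    qtl_id: str
    trait: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.trait:
            raise ValidationError(f"QTL {self.qtl_id}: empty trait")
        if self.end <= self.start:
            raise ValidationError(
                f"QTL {self.qtl_id}: end ({self.end}) must exceed start "
                f"({self.start})"
            )


@dataclass(frozen=True)
class Gene:
    """A gene model with exon and UTR sub-intervals (0-based half-open)."""

    gene_id: str
    symbol: str
    chrom: str
    start: int
    end: int
    strand: str
    exons: tuple[tuple[int, int], ...] = ()
    utr5: tuple[tuple[int, int], ...] = ()
    utr3: tuple[tuple[int, int], ...] = ()
    biotype: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValidationError(f"gene {self.gene_id}: strand {self.strand!r}")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValidationError(
                    f"gene {self.gene_id}: exon ({s},{e}) outside gene span"
                )

    @property
    def is_coding(self) -> bool:
        """True for gene records with >= 1 exon and no conflicting biotype."""
        if not self.exons:
            return False
        return self.biotype is None or self.biotype == "protein_coding"

    def coding_exons(self) -> list[tuple[int, int]]:
        """Exon intervals with UTR sub-intervals removed."""
        utrs = sorted(self.utr5 + self.utr3)
        out: list[tuple[int, int]] = []
        for s, e in self.exons:
            pieces = [(s, e)]
            for us, ue in utrs:
                nxt: list[tuple[int, int]] = []
                for ps, pe in pieces:
                    if ue <= ps or us >= pe:
                        nxt.append((ps, pe))
                        continue
                    if ps < us:
                        nxt.append((ps, us))
                    if ue < pe:
                        nxt.append((ue, pe))
                pieces = nxt
            out.extend(pieces)
        return out


class GenomeAnnotation:
    """Indexed collection of gene models for interval queries."""

    def __init__(self, genes: Iterable[Gene]):
        self.genes = sorted(
            genes, key=lambda g: (chrom_sort_key(g.chrom), g.start, g.gene_id)
        )
        self._trees: dict[str, IntervalTree] = {}

    def _tree(self, chrom: str, pad: int) -> IntervalTree:
        key = chrom
        if key not in self._trees:
            tree = IntervalTree()
            for i, g in enumerate(self.genes):
                if g.chrom == chrom:
                    tree.addi(g.start - self._max_pad, g.end + self._max_pad, i)
            self._trees[key] = tree
        return self._trees[key]

    _max_pad = 10_000  # genes are indexed with this flank; queries beyond it rescan

    def query(self, chrom: str, start: int, end: int, pad: int = 0) -> list[Gene]:
        """Genes whose span, extended by ``pad`` bp on both sides, overlaps
        [start, end)."""
        if pad > self._max_pad:
            return [
                g
                for g in self.genes
                if g.chrom == chrom and g.start - pad < end and g.end + pad > start
            ]
        hits = self._tree(chrom, pad).overlap(start, end)
        out = []
        for iv in hits:
            g = self.genes[iv.data]
            if g.start - pad < end and g.end + pad > start:
                out.append(g)
        return sorted(out, key=lambda g: (g.start, g.gene_id))


@dataclass(frozen=True)
class CandidateRegion:
    """A CNVR surviving the three-track intersection."""

    region: CnvRegion
    gwascore: float
    n_qtl: int
    qtl_ids: tuple[str, ...]


def _interval_overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start < b_end and b_start < a_end


def intersect_three_tracks(
    cnvrs: Sequence[CnvRegion],
    qtls: Sequence[QtlRecord],
    score_regions: Sequence[ScoreWindow],
) -> list[CandidateRegion]:
    """CNVRs overlapping >= 1 score region AND >= 1 QTL.

    Overlap means at least one shared bp.  Each survivor carries the
    maximum score over overlapping score regions and the count of distinct
    overlapping QTL ids.  Output is sorted by score descending, then
    (chrom, start).  Chromosome names present in one track but absent from
    the others produce a logged warning, not an error.
    """
    qtl_trees: dict[str, IntervalTree] = {}
    for q in qtls:
        qtl_trees.setdefault(q.chrom, IntervalTree()).addi(q.start, q.end, q)
    score_trees: dict[str, IntervalTree] = {}
    for w in score_regions:
        score_trees.setdefault(w.chrom, IntervalTree()).addi(w.start, w.end, w)

    cnv_chroms = {c.chrom for c in cnvrs}
    track_chroms = set(qtl_trees) | set(score_trees)
    orphans = sorted(cnv_chroms ^ track_chroms, key=chrom_sort_key)
    if orphans and cnvrs and (qtls or score_regions):
        logger.warning(
            "chromosome names present in only some tracks: %s", ", ".join(orphans)
        )

    out: list[CandidateRegion] = []
    for cnvr in cnvrs:
        score_hits = (
            score_trees[cnvr.chrom].overlap(cnvr.start, cnvr.end)
            if cnvr.chrom in score_trees
            else set()
        )
        if not score_hits:
            continue
        qtl_hits = (
            qtl_trees[cnvr.chrom].overlap(cnvr.start, cnvr.end)
            if cnvr.chrom in qtl_trees
            else set()
        )
        qtl_ids = sorted({iv.data.qtl_id for iv in qtl_hits})
        if not qtl_ids:
            continue
        out.append(
            CandidateRegion(
                region=cnvr,
                gwascore=max(iv.data.score for iv in score_hits),
                n_qtl=len(qtl_ids),
                qtl_ids=tuple(qtl_ids),
            )
        )
    out.sort(key=lambda c: (-c.gwascore, c.region.sort_key()))
    return out


def locate_relative_to_gene(
    start: int, end: int, gene: Gene, upstream_bp: int = 1000
) -> str | None:
    """Location label of interval [start, end) relative to one gene.

    Returns None when the interval neither overlaps the gene nor lies
    within ``upstream_bp`` of either strand-aware flank.
    """
    if _interval_overlaps(start, end, gene.start, gene.end):
        if any(_interval_overlaps(start, end, s, e) for s, e in gene.coding_exons()):
            return "exonic"
        if any(_interval_overlaps(start, end, s, e) for s, e in gene.utr5):
            return "UTR5"
        if any(_interval_overlaps(start, end, s, e) for s, e in gene.utr3):
            return "UTR3"
        return "intronic"
    if gene.strand == "+":
        up = (gene.start - upstream_bp, gene.start)
        down = (gene.end, gene.end + upstream_bp)
    else:
        up = (gene.end, gene.end + upstream_bp)
        down = (gene.start - upstream_bp, gene.start)
    if _interval_overlaps(start, end, *up):
        return "upstream"
    if _interval_overlaps(start, end, *down):
        return "downstream"
    return None


def classify_location(
    cnvr: CnvRegion, annotation: GenomeAnnotation, upstream_bp: int = 1000
) -> str:
    """Single location label for a CNVR against the whole annotation.

    The most specific label over all nearby genes wins; no nearby gene
    means intergenic.
    """
    best = "intergenic"
    for gene in annotation.query(cnvr.chrom, cnvr.start, cnvr.end, pad=upstream_bp):
        label = locate_relative_to_gene(cnvr.start, cnvr.end, gene, upstream_bp)
        if label is not None and _RANK[label] < _RANK[best]:
            best = label
    return best


@dataclass(frozen=True)
class CandidateGene:
    """One row of the candidate table: a surviving CNVR paired with a gene.

    ``gene_id``/``gene_symbol`` are None for intergenic candidates.
    """

    chrom: str
    start: int
    end: int
    gwascore: float
    n_qtl: int
    gene_id: str | None
    gene_symbol: str | None
    location: str


def annotate_candidates(
    candidates: Sequence[CandidateRegion],
    annotation: GenomeAnnotation,
    upstream_bp: int = 1000,
    coding_only: bool = True,
) -> list[CandidateGene]:
    """Pair each surviving CNVR with its overlapping or flanking genes.

    Emits one row per (CNVR, gene) pair; a CNVR with no gene within
    ``upstream_bp`` yields a single intergenic row with no gene.  With
    ``coding_only`` (default) only genes carrying exons and a
    protein-coding (or absent) biotype are considered.  Rows are ranked by
    score descending, ties broken by (chrom, start, gene symbol).
    """
    rows: list[CandidateGene] = []
    for cand in candidates:
        r = cand.region
        genes = annotation.query(r.chrom, r.start, r.end, pad=upstream_bp)
        if coding_only:
            genes = [g for g in genes if g.is_coding]
        emitted = False
        for gene in genes:
            label = locate_relative_to_gene(r.start, r.end, gene, upstream_bp)
            if label is None:
                continue
            rows.append(
                CandidateGene(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    gwascore=cand.gwascore,
                    n_qtl=cand.n_qtl,
                    gene_id=gene.gene_id,
                    gene_symbol=gene.symbol,
                    location=label,
                )
            )
            emitted = True
        if not emitted:
            rows.append(
                CandidateGene(
                    chrom=r.chrom,
                    start=r.start,
                    end=r.end,
                    gwascore=cand.gwascore,
                    n_qtl=cand.n_qtl,
                    gene_id=None,
                    gene_symbol=None,
                    location="intergenic",
                )
            )
    rows.sort(
        key=lambda c: (
            -c.gwascore,
            chrom_sort_key(c.chrom),
            c.start,
            c.gene_symbol or "",
        )
    )
    return rows


def location_distribution(
    cnvrs: Sequence[CnvRegion],
    annotation: GenomeAnnotation,
    upstream_bp: int = 1000,
) -> dict[str, float]:
    """Fraction of CNVRs per location label, over the full vocabulary.

    Fractions sum to 1; an empty input yields an all-zero distribution.
    """
    counts = {label: 0 for label in LOCATION_LABELS}
    for cnvr in cnvrs:
        counts[classify_location(cnvr, annotation, upstream_bp)] += 1
    total = len(cnvrs)
    if total == 0:
        return {label: 0.0 for label in LOCATION_LABELS}
    return {label: counts[label] / total for label in LOCATION_LABELS}
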