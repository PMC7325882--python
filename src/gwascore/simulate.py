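"""Synthetic dataset generator with a known truth set.

Emits all four input kinds the pipeline consumes — a GWAS association
table, a QTL interval table, a per-breed CNVR genotype matrix with sample
sheet, and a toy GFF3 gene annotation — from one seeded random stream, so
every stage can be tested end to end without external data.

Planted structure
-----------------
* *Hot windows*: score windows that receive SNPs from a fixed number of
  studies, all sharing one p-value ``10**-m``.  Because the score depends
  only on the per-window mean of ``-log P``, the expected score is closed
  form: ``n_studies * m / 0.1`` (log base 10, as-printed normalization),
  independent of the SNP count.
* *Planted candidates*: each one owns a hot window containing a gene, a QTL
  spanning the window and a CNV region positioned to earn a chosen location
  label (exonic, UTR5, UTR3, intronic, upstream, downstream or intergenic).
* *Planted breed-specific CNVRs*: one genotype class fixed across a breed
  and excluded from all other breeds.

Background features (genes, SNPs, QTLs, CNVRs) are kept out of the planted
windows (plus a safety margin), background p-values are bounded away from
the planted ones, and background genotype rows are resampled away from
accidental breed-specific patterns.  The truth set is therefore exact: a
score threshold separating planted from background windows exists by
construction and is computed analytically, never measured.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CODE_TO_CLASS, CnvRegion, GenotypeMatrix, SampleSheet
from .core import GwasAssociation, ScoreConfig, chrom_sort_key
from .errors import ValidationError
from .integrate import LOCATION_LABELS, Gene, GenomeAnnotation, QtlRecord

__all__ = [
    "HotWindow",
    "PlantedCandidate",
    "PlantedSpecific",
    "SimulationConfig",
    "TruthSet",
    "SimulatedBundle",
    "simulate_all",
    "expected_scores",
    "recovery_threshold",
    "study_scale_config",
]

_CLASS_CODES = {
    "Loss": ("dd", "Ad"),
    "Normal": ("AA",),
    "Gain": ("AB", "BB", "BC", "M"),
}
_PLANT_CODE = {"Loss": "dd", "Normal": "AA", "Gain": "BB"}

_GWAS_TRAITS = ("body weight", "growth rate", "carcass weight")
_QTL_TRAITS = (
    "carcass weight",
    "muscle depth",
    "fat thickness",
    "body weight",
    "loin muscle area",
)


@dataclass(frozen=True)
class HotWindow:
    """A window seeded with equal-p SNPs from ``n_studies`` studies."""

    chrom: str
    window_index: int
    neg_log10_p: float = 6.0
    n_studies: int = 2
    snps_per_study: int = 4


@dataclass(frozen=True)
class PlantedCandidate:
    """A hot window carrying a gene + QTL + CNVR triple overlap.

    ``location`` is the label the planted CNVR must earn relative to the
    planted gene ("intergenic" plants the CNVR far from it).
    """

    chrom: str
    window_index: int
    location: str = "intronic"
    neg_log10_p: float = 8.0
    n_studies: int = 2
    snps_per_study: int = 4


@dataclass(frozen=True)
class PlantedSpecific:
    """A CNVR whose genotype class is fixed in one breed, absent elsewhere."""

    breed: str
    genotype_class: str = "Loss"


def _default_genome() -> list[tuple[str, int]]:
    return [("chr1", 3_000_000), ("chr2", 3_000_000), ("chr3", 2_000_000)]


def _default_hot_windows() -> list[HotWindow]:
    return [
        HotWindow("chr1", 22, neg_log10_p=7.0, n_studies=2),
        HotWindow("chr2", 20, neg_log10_p=6.5, n_studies=3),
    ]


def _default_candidates() -> list[PlantedCandidate]:
    return [
        PlantedCandidate("chr1", 5, "exonic"),
        PlantedCandidate("chr1", 14, "intronic"),
        PlantedCandidate("chr2", 8, "UTR5"),
        PlantedCandidate("chr3", 3, "upstream"),
    ]


def _default_specific() -> list[PlantedSpecific]:
    return [
        PlantedSpecific("Chaka", "Loss"),
        PlantedSpecific("Hu", "Gain"),
        PlantedSpecific("STHS", "Loss"),
    ]


def _default_breeds() -> dict[str, int]:
    return {"Chaka": 10, "Hu": 10, "STHS": 9}


def _default_class_freqs() -> dict[str, float]:
    return {"Loss": 0.15, "Normal": 0.70, "Gain": 0.15}


@dataclass
class SimulationConfig:
    """All knobs of the generator; defaults give a small three-chromosome
    genome sized for fast tests.  :func:`study_scale_config` returns the
    study-scale preset (26 chromosomes, 440 markers, 729 QTLs, 4301 CNVRs,
    breeds of 10/10/9)."""

    seed: int = 0
    genome: list[tuple[str, int]] = field(default_factory=_default_genome)
    window_size: int = 100_000
    # GWAS background
    n_studies: int = 3
    snps_per_study: int = 40
    p_background: tuple[float, float] = (1e-4, 1e-2)
    hot_windows: list[HotWindow] = field(default_factory=_default_hot_windows)
    planted_candidates: list[PlantedCandidate] = field(
        default_factory=_default_candidates
    )
    # QTL track
    n_qtls: int = 40
    qtl_length: tuple[int, int] = (50_000, 250_000)
    # CNVR genotypes
    breeds: dict[str, int] = field(default_factory=_default_breeds)
    n_cnvrs: int = 150
    cnvr_length: tuple[int, int] = (1_500, 6_500)
    class_freqs: dict[str, float] = field(default_factory=_default_class_freqs)
    planted_specific: list[PlantedSpecific] = field(default_factory=_default_specific)
    # gene annotation
    n_genes: int = 50
    exons_per_gene: tuple[int, int] = (2, 5)
    exon_length: tuple[int, int] = (150, 400)
    intron_length: tuple[int, int] = (500, 2_500)
    utr5_length: int = 200
    utr3_length: int = 300
    intergenic_gap: tuple[int, int] = (10_000, 60_000)
    upstream_bp: int = 1_000
    margin: int = 10_000  # exclusion flank around planted windows

    def validate(self) -> None:
        lengths = dict(self.genome)
        if not lengths:
            raise ValidationError("genome must list at least one chromosome")
        for name, (lo, hi) in (
            ("qtl_length", self.qtl_length),
            ("cnvr_length", self.cnvr_length),
        ):
            if not (0 < lo <= hi):
                raise ValidationError(f"{name} bounds invalid: ({lo}, {hi})")
        if abs(sum(self.class_freqs.values()) - 1.0) > 1e-9:
            raise ValidationError("class_freqs must sum to 1")
        if set(self.class_freqs) != set(_CLASS_CODES):
            raise ValidationError("class_freqs must cover Loss/Normal/Gain")
        p_lo, p_hi = self.p_background
        if not (0 < p_lo < p_hi <= 1):
            raise ValidationError(f"p_background bounds invalid: {self.p_background}")
        planted = [(h.chrom, h.window_index) for h in self.hot_windows]
        planted += [(c.chrom, c.window_index) for c in self.planted_candidates]
        if len(set(planted)) != len(planted):
            raise ValidationError("planted windows must be distinct")
        for chrom, widx in planted:
            if chrom not in lengths:
                raise ValidationError(f"planted window on unknown chromosome {chrom}")
            if (widx + 1) * self.window_size > lengths[chrom]:
                raise ValidationError(
                    f"planted window {chrom}[{widx}] extends past the chromosome"
                )
        for cand in self.planted_candidates:
            if cand.location not in LOCATION_LABELS:
                raise ValidationError(f"unknown planted location {cand.location!r}")
        for spec in self.planted_specific:
            if spec.breed not in self.breeds:
                raise ValidationError(f"planted specific for unknown breed {spec.breed}")
            if spec.genotype_class not in _CLASS_CODES:
                raise ValidationError(
                    f"unknown genotype class {spec.genotype_class!r}"
                )
        for h in self.hot_windows:
            if h.n_studies > self.n_studies:
                raise ValidationError("hot window uses more studies than exist")
        for c in self.planted_candidates:
            if c.n_studies > self.n_studies:
                raise ValidationError("planted window uses more studies than exist")


def config_from_dict(d: Mapping) -> SimulationConfig:
    """Build a :class:`SimulationConfig` from a plain (YAML-loaded) mapping.

    Nested entries ``hot_windows``, ``planted_candidates`` and
    ``planted_specific`` are lists of mappings with the corresponding
    dataclass fields; ``genome`` is a list of ``[chrom, length]`` pairs.
    Unknown keys raise a validation error.
    """
    d = dict(d)
    known = set(SimulationConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown simulation config key(s): {sorted(unknown)}")
    if "genome" in d:
        d["genome"] = [(str(c), int(n)) for c, n in d["genome"]]
    for key, cls in (
        ("hot_windows", HotWindow),
        ("planted_candidates", PlantedCandidate),
        ("planted_specific", PlantedSpecific),
    ):
        if key in d:
            d[key] = [cls(**item) for item in d[key]]
    for key in ("p_background", "qtl_length", "cnvr_length", "exons_per_gene",
                "exon_length", "intron_length", "intergenic_gap"):
        if key in d:
            d[key] = tuple(d[key])
    return SimulationConfig(**d)


def study_scale_config(seed: int = 0) -> SimulationConfig:
    """Study-scale preset: 26 autosomes, ~440 GWAS markers across 10
    studies, 729 QTLs, 4301 CNVRs of ~4 kb mean length, three breeds of
    10/10/9 samples.  Counts mirror the target study's bookkeeping for
    realistic load; the genome itself stays desk-sized (10 Mb per
    chromosome)."""
    genome = [(f"chr{i}", 10_000_000) for i in range(1, 27)]
    return SimulationConfig(
        seed=seed,
        genome=genome,
        n_studies=10,
        snps_per_study=44,
        n_qtls=729,
        n_cnvrs=4301,
        cnvr_length=(1_500, 6_500),
        n_genes=600,
        hot_windows=[
            HotWindow("chr4", 50, neg_log10_p=9.0, n_studies=5),
            HotWindow("chr9", 12, neg_log10_p=8.0, n_studies=6),
        ],
        planted_candidates=[
            PlantedCandidate("chr14", 30, "intronic", neg_log10_p=8.0, n_studies=6),
            PlantedCandidate("chr17", 22, "intronic", neg_log10_p=8.0, n_studies=6),
            PlantedCandidate("chr6", 72, "exonic", neg_log10_p=9.0, n_studies=5),
            PlantedCandidate("chr6", 80, "UTR5", neg_log10_p=9.0, n_studies=5),
            PlantedCandidate("chr1", 95, "upstream", neg_log10_p=8.0, n_studies=6),
        ],
    )


# ---------------------------------------------------------------------------
# truth set


@dataclass(frozen=True)
class TruthHotWindow:
    chrom: str
    window_index: int
    n_gwas: int
    n_snp: int
    neg_log10_p: float


@dataclass(frozen=True)
class TruthCandidate:
    cnvr_id: str
    chrom: str
    window_index: int
    gene_id: str | None
    gene_symbol: str | None
    location: str


@dataclass
class TruthSet:
    """What was planted, with enough detail to predict pipeline output."""

    window_size: int
    n_studies: int
    background_max_neg_log10_p: float
    hot_windows: list[TruthHotWindow]
    candidates: list[TruthCandidate]
    specific: dict[str, list[str]]  # breed -> region ids (class level)

    def to_json(self) -> str:
        return json.dumps(
            {
                "window_size": self.window_size,
                "n_studies": self.n_studies,
                "background_max_neg_log10_p": self.background_max_neg_log10_p,
                "hot_windows": [asdict(h) for h in self.hot_windows],
                "candidates": [asdict(c) for c in self.candidates],
                "specific": self.specific,
            },
            indent=2,
            sort_keys=True,
        )

    @classmethod
    def from_json(cls, text: str) -> "TruthSet":
        d = json.loads(text)
        return cls(
            window_size=d["window_size"],
            n_studies=d["n_studies"],
            background_max_neg_log10_p=d["background_max_neg_log10_p"],
            hot_windows=[TruthHotWindow(**h) for h in d["hot_windows"]],
            candidates=[TruthCandidate(**c) for c in d["candidates"]],
            specific={b: list(v) for b, v in d["specific"].items()},
        )


def _log_conv(log_base: float) -> float:
    """-log_b(10^-1): one decade of p in the configured base."""
    return math.log(10.0) / math.log(log_base)


def expected_scores(
    truth: TruthSet, config: ScoreConfig | None = None
) -> dict[tuple[str, int], float]:
    """Closed-form score of every planted hot window.

    All planted SNPs in a window share p = 10^-m, so the window score is
    ``n_gwas * m * conv / 0.1`` (as-printed) or ``n_gwas * m * conv``
    (per-window mean), with ``conv`` converting decades into the configured
    log base.  The SNP count cancels (mean invariance).
    """
    config = config or ScoreConfig()
    conv = _log_conv(config.log_base)
    div = 0.1 if config.normalization == "as_printed" else 1.0
    return {
        (h.chrom, h.window_index): h.n_gwas * h.neg_log10_p * conv / div
        for h in truth.hot_windows
    }


def recovery_threshold(truth: TruthSet, config: ScoreConfig | None = None) -> float:
    """A score threshold guaranteed to separate planted from background.

    No background window can beat ``n_studies * max(-log10 p_background)``
    decades; the threshold is the midpoint between that bound and the
    weakest planted window.  Raises if the planted scores do not clear the
    bound (the configuration cannot guarantee exact recovery).
    """
    config = config or ScoreConfig()
    conv = _log_conv(config.log_base)
    div = 0.1 if config.normalization == "as_printed" else 1.0
    bound = truth.n_studies * truth.background_max_neg_log10_p * conv / div
    planted = expected_scores(truth, config)
    if not planted:
        return bound
    weakest = min(planted.values())
    if weakest <= bound:
        raise ValidationError(
            f"weakest planted window ({weakest:.3g}) does not clear the "
            f"background score bound ({bound:.3g}); raise neg_log10_p or "
            f"lower p_background"
        )
    return (bound + weakest) / 2.0


# ---------------------------------------------------------------------------
# generator internals


class _Reserved:
    """Per-chromosome exclusion zones around planted windows."""

    def __init__(self, zones: Mapping[str, list[tuple[int, int]]]):
        self.zones = {c: sorted(z) for c, z in zones.items()}

    def hits(self, chrom: str, start: int, end: int) -> bool:
        return any(s < end and start < e for s, e in self.zones.get(chrom, []))


def _build_gene(
    gene_id: str,
    symbol: str,
    chrom: str,
    gs: int,
    strand: str,
    coding_exon_lens: Sequence[int],
    intron_lens: Sequence[int],
    utr5_len: int,
    utr3_len: int,
) -> Gene:
    """Assemble a gene model left to right; UTRs extend the terminal exons
    (as in standard GFF3, exon features include UTR sequence)."""
    left_utr = utr5_len if strand == "+" else utr3_len
    right_utr = utr3_len if strand == "+" else utr5_len
    exons: list[tuple[int, int]] = []
    pos = gs
    for i, clen in enumerate(coding_exon_lens):
        es = pos
        if i == 0:
            clen_total = left_utr + clen
        else:
            clen_total = clen
        if i == len(coding_exon_lens) - 1:
            clen_total += right_utr
        exons.append((es, es + clen_total))
        pos = es + clen_total
        if i < len(intron_lens):
            pos += intron_lens[i]
    end = exons[-1][1]
    first_s, _ = exons[0]
    _, last_e = exons[-1]
    left_iv = ((first_s, first_s + left_utr),) if left_utr else ()
    right_iv = ((last_e - right_utr, last_e),) if right_utr else ()
    utr5 = left_iv if strand == "+" else right_iv
    utr3 = right_iv if strand == "+" else left_iv
    return Gene(
        gene_id=gene_id,
        symbol=symbol,
        chrom=chrom,
        start=gs,
        end=end,
        strand=strand,
        exons=tuple(exons),
        utr5=utr5,
        utr3=utr3,
        biotype="protein_coding",
    )


def _planted_gene(gene_id: str, symbol: str, chrom: str, ws: int) -> Gene:
    """Fixed-layout plus-strand gene used for planted candidates:
    UTR5 200 bp, two 400 bp coding exons around a 2 kb intron, UTR3 300 bp,
    starting 20 kb into the window."""
    return _build_gene(
        gene_id, symbol, chrom, ws + 20_000, "+", [400, 400], [2_000], 200, 300
    )


def _planted_cnvr_interval(location: str, gene: Gene, ws: int) -> tuple[int, int]:
    gs, ge = gene.start, gene.end
    if location == "exonic":
        return (gs + 300, gs + 500)  # inside coding part of exon 1
    if location == "UTR5":
        return (gs + 40, gs + 160)
    if location == "UTR3":
        return (ge - 250, ge - 50)
    if location == "intronic":
        return (gs + 1_000, gs + 2_000)
    if location == "upstream":
        return (gs - 800, gs - 300)
    if location == "downstream":
        return (ge + 200, ge + 700)
    if location == "intergenic":
        return (ws + 60_000, ws + 62_000)
    raise ValidationError(f"unknown planted location {location!r}")


def _specific_breeds_at(
    row: Mapping[str, str], breed_cols: Mapping[str, list[str]], as_class: bool
) -> set[str]:
    """Brute application of the breed-specific rule to one genotype row."""
    from .cnv import MISSING_MARKERS

    def val(code: str) -> str:
        return CODE_TO_CLASS[code].value if as_class else code

    hits: set[str] = set()
    for breed, cols in breed_cols.items():
        vals = [row[s] for s in cols]
        if any(v in MISSING_MARKERS for v in vals):
            continue
        mapped = {val(v) for v in vals}
        if len(mapped) != 1:
            continue
        g = next(iter(mapped))
        others = (
            val(row[s])
            for b, cols2 in breed_cols.items()
            if b != breed
            for s in cols2
            if row[s] not in MISSING_MARKERS
        )
        if all(v != g for v in others):
            hits.add(breed)
    return hits


@dataclass
class SimulatedBundle:
    """All generated inputs plus the truth set."""

    config: SimulationConfig
    gwas: list[GwasAssociation]
    qtls: list[QtlRecord]
    matrix: GenotypeMatrix
    sheet: SampleSheet
    genes: list[Gene]
    truth: TruthSet

    def annotation(self) -> GenomeAnnotation:
        return GenomeAnnotation(self.genes)

    def write(self, outdir) -> dict[str, str]:
        """Serialize the bundle to ``outdir`` in the canonical dialects.

        Returns a name -> path mapping for the six files written.
        """
        from . import io as gio
        from pathlib import Path

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "gwas": outdir / "gwas.tsv",
            "qtl": outdir / "qtl.tsv",
            "cnvr": outdir / "cnvr_genotypes.tsv",
            "samples": outdir / "samples.tsv",
            "gff3": outdir / "genes.gff3",
            "truth": outdir / "truth.json",
        }
        gio.write_gwas(self.gwas, paths["gwas"])
        gio.write_qtl(self.qtls, paths["qtl"])
        gio.write_cnvr_matrix(self.matrix, paths["cnvr"])
        gio.write_sample_sheet(self.sheet, paths["samples"])
        gio.write_gff3(self.genes, dict(self.config.genome), paths["gff3"])
        paths["truth"].write_text(self.truth.to_json() + "\n")
        return {k: str(v) for k, v in paths.items()}


def simulate_all(config: SimulationConfig | None = None) -> SimulatedBundle:
    """Generate the full dataset bundle; deterministic given ``config.seed``."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    lengths = dict(config.genome)
    chroms = [c for c, _ in config.genome]
    W = config.window_size

    planted_windows = [
        (h.chrom, h.window_index, h) for h in config.hot_windows
    ] + [(c.chrom, c.window_index, c) for c in config.planted_candidates]
    zones: dict[str, list[tuple[int, int]]] = {c: [] for c in chroms}
    for chrom, widx, _spec in planted_windows:
        zones[chrom].append(
            (max(0, widx * W - config.margin), (widx + 1) * W + config.margin)
        )
    reserved = _Reserved(zones)

    # --- genes -------------------------------------------------------------
    genes: list[Gene] = []
    gene_n = 0
    for chrom in chroms:
        L = lengths[chrom]
        pos = int(rng.integers(*config.intergenic_gap))
        while gene_n < config.n_genes:
            n_ex = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
            ex_lens = [int(rng.integers(*config.exon_length)) for _ in range(n_ex)]
            in_lens = [int(rng.integers(*config.intron_length)) for _ in range(n_ex - 1)]
            span = (
                sum(ex_lens) + sum(in_lens) + config.utr5_length + config.utr3_length
            )
            if pos + span + config.margin >= L:
                break
            if reserved.hits(chrom, pos - config.margin, pos + span + config.margin):
                # jump past the blocking zone
                blockers = [
                    e
                    for s, e in reserved.zones.get(chrom, [])
                    if s < pos + span + config.margin and pos - config.margin < e
                ]
                pos = max(blockers) + config.margin
                continue
            gene_n += 1
            strand = "+" if rng.random() < 0.5 else "-"
            genes.append(
                _build_gene(
                    f"G{gene_n:04d}",
                    f"SYN{gene_n:04d}",
                    chrom,
                    pos,
                    strand,
                    ex_lens,
                    in_lens,
                    config.utr5_length,
                    config.utr3_length,
                )
            )
            pos += span + int(rng.integers(*config.intergenic_gap))
        if gene_n >= config.n_genes:
            break

    truth_candidates: list[TruthCandidate] = []
    planted_genes: dict[tuple[str, int], Gene] = {}
    for i, cand in enumerate(config.planted_candidates, start=1):
        ws = cand.window_index * W
        gene = _planted_gene(f"PG{i:03d}", f"PLT{i:03d}", cand.chrom, ws)
        planted_genes[(cand.chrom, cand.window_index)] = gene
        genes.append(gene)
    genes.sort(key=lambda g: (chrom_sort_key(g.chrom), g.start, g.gene_id))

    # --- GWAS associations --------------------------------------------------
    study_ids = [f"GWAS{i:02d}" for i in range(1, config.n_studies + 1)]
    p_lo, p_hi = config.p_background
    chrom_w = np.array([lengths[c] for c in chroms], dtype=float)
    chrom_w /= chrom_w.sum()
    gwas: list[GwasAssociation] = []
    for sid in study_ids:
        trait = _GWAS_TRAITS[int(rng.integers(len(_GWAS_TRAITS)))]
        for _ in range(config.snps_per_study):
            while True:
                chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
                pos = int(rng.integers(1, lengths[chrom] + 1))
                if not reserved.hits(chrom, pos - 1, pos):
                    break
            p = float(rng.uniform(p_lo, p_hi))
            gwas.append(GwasAssociation(sid, trait, chrom, pos, p))

    truth_hot: list[TruthHotWindow] = []
    for chrom, widx, spec in planted_windows:
        ws = widx * W
        chosen = [str(s) for s in rng.choice(study_ids, size=spec.n_studies, replace=False)]
        p = 10.0 ** (-spec.neg_log10_p)
        for sid in sorted(chosen):
            for _ in range(spec.snps_per_study):
                pos = int(rng.integers(ws + 1, ws + W + 1))
                gwas.append(
                    GwasAssociation(sid, "planted trait", chrom, pos, p)
                )
        truth_hot.append(
            TruthHotWindow(
                chrom=chrom,
                window_index=widx,
                n_gwas=spec.n_studies,
                n_snp=spec.n_studies * spec.snps_per_study,
                neg_log10_p=spec.neg_log10_p,
            )
        )
    gwas.sort(key=lambda a: (chrom_sort_key(a.chrom), a.pos, a.study_id))

    # --- QTLs ---------------------------------------------------------------
    qtls: list[QtlRecord] = []
    qn = 0
    for _ in range(config.n_qtls):
        for _try in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
            qlen = int(rng.integers(*config.qtl_length))
            if qlen >= lengths[chrom]:
                continue
            qs = int(rng.integers(0, lengths[chrom] - qlen))
            if not reserved.hits(chrom, qs, qs + qlen):
                break
        else:  # pragma: no cover - pathological configs only
            raise ValidationError("could not place a background QTL")
        qn += 1
        trait = _QTL_TRAITS[int(rng.integers(len(_QTL_TRAITS)))]
        qtls.append(QtlRecord(f"QTL{qn:04d}", trait, chrom, qs, qs + qlen))
    for chrom, widx, _spec in (
        (c.chrom, c.window_index, c) for c in config.planted_candidates
    ):
        qn += 1
        ws = widx * W
        qtls.append(
            QtlRecord(f"QTL{qn:04d}", "carcass weight", chrom, ws + 5_000, ws + W - 5_000)
        )
    qtls.sort(key=lambda q: (chrom_sort_key(q.chrom), q.start, q.qtl_id))

    # --- CNVR genotype matrix ----------------------------------------------
    breeds = dict(config.breeds)
    samples = [
        f"{breed}_{i:02d}" for breed, n in breeds.items() for i in range(1, n + 1)
    ]
    sheet = SampleSheet({s: s.rsplit("_", 1)[0] for s in samples})
    breed_cols = {b: sheet.samples_of(b) for b in breeds}
    class_names = list(_CLASS_CODES)
    class_p = np.array([config.class_freqs[c] for c in class_names])

    def background_row() -> dict[str, str]:
        """One genotype row with no accidental breed-specific pattern."""
        for _try in range(200):
            row = {}
            for s in samples:
                cls = class_names[int(rng.choice(len(class_names), p=class_p))]
                codes = _CLASS_CODES[cls]
                row[s] = codes[int(rng.integers(len(codes)))]
            if not _specific_breeds_at(row, breed_cols, as_class=True) and not (
                _specific_breeds_at(row, breed_cols, as_class=False)
            ):
                return row
        raise ValidationError(
            "could not draw a non-specific background genotype row"
        )  # pragma: no cover

    intervals: list[tuple[str, int, int, dict[str, str]]] = []
    used: set[tuple[str, int, int]] = set()
    for _ in range(config.n_cnvrs):
        for _try in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
            clen = int(rng.integers(*config.cnvr_length))
            cs = int(rng.integers(0, lengths[chrom] - clen))
            if reserved.hits(chrom, cs, cs + clen):
                continue
            if (chrom, cs, cs + clen) in used:
                continue
            break
        else:  # pragma: no cover - pathological configs only
            raise ValidationError("could not place a background CNVR")
        used.add((chrom, cs, cs + clen))
        intervals.append((chrom, cs, cs + clen, background_row()))

    truth_specific: dict[str, list[str]] = {b: [] for b in breeds}
    for spec in config.planted_specific:
        for _try in range(1000):
            chrom = chroms[int(rng.choice(len(chroms), p=chrom_w))]
            clen = int(rng.integers(*config.cnvr_length))
            cs = int(rng.integers(0, lengths[chrom] - clen))
            if not reserved.hits(chrom, cs, cs + clen) and (
                (chrom, cs, cs + clen) not in used
            ):
                break
        else:  # pragma: no cover
            raise ValidationError("could not place a planted specific CNVR")
        used.add((chrom, cs, cs + clen))
        other_classes = [c for c in class_names if c != spec.genotype_class]
        other_p = np.array([config.class_freqs[c] for c in other_classes])
        other_p /= other_p.sum()
        for _try in range(200):
            row = {}
            for s in samples:
                if sheet.mapping[s] == spec.breed:
                    row[s] = _PLANT_CODE[spec.genotype_class]
                else:
                    cls = other_classes[int(rng.choice(len(other_classes), p=other_p))]
                    codes = _CLASS_CODES[cls]
                    row[s] = codes[int(rng.integers(len(codes)))]
            if _specific_breeds_at(row, breed_cols, as_class=True) == {spec.breed}:
                break
        else:  # pragma: no cover
            raise ValidationError("could not plant a clean specific row")
        intervals.append((chrom, cs, cs + clen, row))
        truth_specific[spec.breed].append(f"{chrom}:{cs + 1}-{cs + clen}")

    for i, cand in enumerate(config.planted_candidates, start=1):
        ws = cand.window_index * W
        gene = planted_genes[(cand.chrom, cand.window_index)]
        cs, ce = _planted_cnvr_interval(cand.location, gene, ws)
        used.add((cand.chrom, cs, ce))
        intervals.append((cand.chrom, cs, ce, background_row()))
        truth_candidates.append(
            TruthCandidate(
                cnvr_id=f"{cand.chrom}:{cs + 1}-{ce}",
                chrom=cand.chrom,
                window_index=cand.window_index,
                gene_id=None if cand.location == "intergenic" else gene.gene_id,
                gene_symbol=None if cand.location == "intergenic" else gene.symbol,
                location=cand.location,
            )
        )

    intervals.sort(key=lambda t: (chrom_sort_key(t[0]), t[1], t[2]))
    regions = [
        CnvRegion(f"{c}:{s + 1}-{e}", c, s, e) for c, s, e, _row in intervals
    ]
    codes = pd.DataFrame(
        [[row[s] for s in samples] for _c, _s, _e, row in intervals],
        index=[r.region_id for r in regions],
        columns=samples,
    )
    matrix = GenotypeMatrix(regions, codes)

    truth = TruthSet(
        window_size=W,
        n_studies=config.n_studies,
        background_max_neg_log10_p=-math.log10(p_lo),
        hot_windows=sorted(
            truth_hot, key=lambda h: (chrom_sort_key(h.chrom), h.window_index)
        ),
        candidates=sorted(truth_candidates, key=lambda c: c.cnvr_id),
        specific=truth_specific,
    )
    return SimulatedBundle(
        config=config,
        gwas=gwas,
        qtls=qtls,
        matrix=matrix,
        sheet=sheet,
        genes=genes,
        truth=truth,
    )
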