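"""CNV-region genotype matrices: Loss/Normal/Gain classing and breed analysis.

CNVcaller-style genotyping assigns each sample one of seven copy-state codes
per CNV region: ``dd`` (homozygous deletion), ``Ad`` (heterozygous
deletion), ``AA`` (reference copy number), and ``AB``, ``BB``, ``BC``, ``M``
(duplicated or complex states).  The three-way grouping used throughout is

    dd, Ad          -> Loss
    AA              -> Normal
    AB, BB, BC, M   -> Gain

A CNV region is *breed-specific* when every individual of one breed carries
the same genotype value and no individual of any other breed carries that
value.  By default "same genotype" is evaluated on the Loss/Normal/Gain
class; raw-code comparison is available via ``level="code"``.  A breed with
any missing call at a region is ineligible for specificity at that region.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping

import pandas as pd

from .core import chrom_sort_key
from .errors import ValidationError

__all__ = [
    "GenotypeClass",
    "CODE_TO_CLASS",
    "MISSING_MARKERS",
    "CnvRegion",
    "GenotypeMatrix",
    "SampleSheet",
    "classify_genotype",
    "breed_specific_cnvrs",
    "genotype_class_distribution",
    "shared_specific_summary",
    "DistributionSummary",
    "SharedSpecificSummary",
]


class GenotypeClass(str, enum.Enum):
    LOSS = "Loss"
    NORMAL = "Normal"
    GAIN = "Gain"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CODE_TO_CLASS: dict[str, GenotypeClass] = {
    "dd": GenotypeClass.LOSS,
    "Ad": GenotypeClass.LOSS,
    "AA": GenotypeClass.NORMAL,
    "AB": GenotypeClass.GAIN,
    "BB": GenotypeClass.GAIN,
    "BC": GenotypeClass.GAIN,
    "M": GenotypeClass.GAIN,
}

#: Cell values treated as a missing genotype call.
MISSING_MARKERS = frozenset({".", "", "NA", "nan"})


def classify_genotype(
    code: str, *, region: str | None = None, sample: str | None = None
) -> GenotypeClass:
    """Map a genotype code to its Loss/Normal/Gain class.

    Unknown codes raise :class:`ValidationError` naming the offending code
    and, when given, the region/sample context.
    """
    try:
        return CODE_TO_CLASS[code]
    except KeyError:
        ctx = ""
        if region is not None or sample is not None:
            ctx = f" (region {region}, sample {sample})"
        raise ValidationError(f"unknown genotype code {code!r}{ctx}") from None


@dataclass(frozen=True)
class CnvRegion:
    """A copy-number-variable region, 0-based half-open internally."""

    region_id: str
    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"region {self.region_id}: end ({self.end}) must exceed "
                f"start ({self.start})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start, self.end)


class GenotypeMatrix:
    """Region x sample grid of genotype codes.

    ``codes`` is a DataFrame indexed by region_id with one column per
    sample; cells hold genotype codes or a missing marker.  All non-missing
    cells are validated against the seven-code vocabulary on construction.
    """

    def __init__(self, regions: list[CnvRegion], codes: pd.DataFrame):
        ids = [r.region_id for r in regions]
        if list(codes.index) != ids:
            raise ValidationError("codes index must equal region ids, in order")
        if len(set(codes.columns)) != len(codes.columns):
            raise ValidationError("duplicate sample ids in genotype matrix")
        for rid, row in codes.iterrows():
            for sample, code in row.items():
                code = str(code)
                if code not in MISSING_MARKERS:
                    classify_genotype(code, region=str(rid), sample=str(sample))
        self.regions = list(regions)
        self.samples = [str(c) for c in codes.columns]
        self.codes = codes.astype(str)
        self._by_id = {r.region_id: r for r in self.regions}

    def region(self, region_id: str) -> CnvRegion:
        return self._by_id[region_id]

    def classes(self) -> pd.DataFrame:
        """Grid of Loss/Normal/Gain strings; missing cells stay missing."""
        return self.codes.map(
            lambda c: CODE_TO_CLASS[c].value if c not in MISSING_MARKERS else "."
        )

    def __len__(self) -> int:
        return len(self.regions)


class SampleSheet:
    """Mapping sample id -> breed label."""

    def __init__(self, mapping: Mapping[str, str]):
        if not mapping:
            raise ValidationError("sample sheet is empty")
        self.mapping = dict(mapping)

    @property
    def breeds(self) -> list[str]:
        seen: dict[str, None] = {}
        for b in self.mapping.values():
            seen.setdefault(b)
        return list(seen)

    def samples_of(self, breed: str) -> list[str]:
        return [s for s, b in self.mapping.items() if b == breed]

    def check_against(self, matrix: GenotypeMatrix) -> None:
        missing = [s for s in matrix.samples if s not in self.mapping]
        if missing:
            raise ValidationError(f"samples absent from sheet: {missing}")
        for breed in self.breeds:
            if not any(s in matrix.samples for s in self.samples_of(breed)):
                raise ValidationError(f"breed {breed!r} has no samples in matrix")


def _value_grid(matrix: GenotypeMatrix, level: str) -> pd.DataFrame:
    if level == "class":
        return matrix.classes()
    if level == "code":
        return matrix.codes
    raise ValidationError(f"level must be 'class' or 'code', got {level!r}")


def breed_specific_cnvrs(
    matrix: GenotypeMatrix, sheet: SampleSheet, level: str = "class"
) -> dict[str, list[tuple[CnvRegion, str]]]:
    """Regions whose genotype is fixed in one breed and absent elsewhere.

    Returns ``{breed: [(region, genotype_value), ...]}`` with every breed
    present as a key.  A region qualifies for breed B iff (a) B has no
    missing call at the region, (b) all B samples share one value ``g`` at
    the chosen level, and (c) no non-missing sample of any other breed
    carries ``g`` there.  Requires at least two breeds.
    """
    sheet.check_against(matrix)
    breeds = sheet.breeds
    if len(breeds) < 2:
        raise ValidationError("breed specificity needs at least 2 breeds")
    grid = _value_grid(matrix, level)
    cols = {b: [s for s in sheet.samples_of(b) if s in matrix.samples] for b in breeds}
    out: dict[str, list[tuple[CnvRegion, str]]] = {b: [] for b in breeds}
    for region in matrix.regions:
        row = grid.loc[region.region_id]
        for breed in breeds:
            vals = [row[s] for s in cols[breed]]
            if any(v in MISSING_MARKERS for v in vals):
                continue
            if len(set(vals)) != 1:
                continue
            g = vals[0]
            others = (
                row[s]
                for b in breeds
                if b != breed
                for s in cols[b]
            )
            if all(v != g for v in others):
                out[breed].append((region, g))
    return out


_CLASS_ORDER = [GenotypeClass.LOSS, GenotypeClass.NORMAL, GenotypeClass.GAIN]


@dataclass
class DistributionSummary:
    """Per-breed Loss/Normal/Gain composition.

    ``cell_counts`` counts non-missing genotype calls; ``region_majority``
    counts regions by the breed's majority class (ties resolved in
    Loss, Normal, Gain order; regions with no non-missing call in a breed
    are skipped for that breed).
    """

    cell_counts: dict[str, dict[str, int]]
    region_majority: dict[str, dict[str, int]]

    def to_frame(self, which: str = "cell_counts") -> pd.DataFrame:
        data = getattr(self, which)
        return pd.DataFrame(data).T[[c.value for c in _CLASS_ORDER]].fillna(0)


def genotype_class_distribution(
    matrix: GenotypeMatrix, sheet: SampleSheet
) -> DistributionSummary:
    """Count Loss/Normal/Gain per breed, by cell and by region majority."""
    sheet.check_against(matrix)
    classes = matrix.classes()
    cell: dict[str, dict[str, int]] = {}
    major: dict[str, dict[str, int]] = {}
    for breed in sheet.breeds:
        cols = [s for s in sheet.samples_of(breed) if s in matrix.samples]
        cell[breed] = {c.value: 0 for c in _CLASS_ORDER}
        major[breed] = {c.value: 0 for c in _CLASS_ORDER}
        for region in matrix.regions:
            counts = {c.value: 0 for c in _CLASS_ORDER}
            for s in cols:
                v = classes.loc[region.region_id, s]
                if v not in MISSING_MARKERS:
                    counts[v] += 1
                    cell[breed][v] += 1
            if sum(counts.values()) > 0:
                best = max(_CLASS_ORDER, key=lambda c: counts[c.value])
                # max() keeps the first of Loss/Normal/Gain on ties
                major[breed][best.value] += 1
    return DistributionSummary(cell_counts=cell, region_majority=major)


@dataclass
class SharedSpecificSummary:
    """Venn-style counts: per-breed specific regions and the all-breed
    shared count (regions where some genotype value is present in at least
    one sample of every breed)."""

    specific: dict[str, int]
    shared: int
    level: str


def shared_specific_summary(
    matrix: GenotypeMatrix, sheet: SampleSheet, level: str = "class"
) -> SharedSpecificSummary:
    """Count breed-specific regions per breed and all-breed shared regions."""
    specific = {
        b: len(v) for b, v in breed_specific_cnvrs(matrix, sheet, level).items()
    }
    grid = _value_grid(matrix, level)
    breeds = sheet.breeds
    cols = {b: [s for s in sheet.samples_of(b) if s in matrix.samples] for b in breeds}
    shared = 0
    for region in matrix.regions:
        row = grid.loc[region.region_id]
        present = [
            {row[s] for s in cols[b] if row[s] not in MISSING_MARKERS}
            for b in breeds
        ]
        if present and set.intersection(*present):
            shared += 1
    return SharedSpecificSummary(specific=specific, shared=shared, level=level)
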