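"""Shared fixtures and independent brute-force oracles.

The oracles here re-derive every result from first principles (direct
formula evaluation, all-pairs interval scans, exhaustive rule application)
and share no code with the package implementation they check.
"""

from __future__ import annotations

import math

import pandas as pd
import pytest

from gwascore import (
    CnvRegion,
    GenotypeMatrix,
    GwasAssociation,
    SampleSheet,
    ScoreConfig,
    SimulationConfig,
    simulate_all,
)


# ---------------------------------------------------------------------------
# oracles


def brute_force_score(p_values, study_ids, config: ScoreConfig) -> float:
    """Direct evaluation of -n_gwas * sum(log P) / (0.1 * n_snp)."""
    n_snp = len(p_values)
    n_gwas = len(set(study_ids))
    total = sum(math.log(p) / math.log(config.log_base) for p in p_values)
    if config.normalization == "as_printed":
        return -n_gwas * total / (0.1 * n_snp)
    return -n_gwas * total / n_snp


def brute_force_specific(matrix: GenotypeMatrix, sheet: SampleSheet, level: str):
    """Exhaustive region x breed scan of the breed-specificity rule."""
    class_of = {
        "dd": "Loss", "Ad": "Loss", "AA": "Normal",
        "AB": "Gain", "BB": "Gain", "BC": "Gain", "M": "Gain",
    }
    missing = {".", "", "NA", "nan"}

    def val(code):
        return class_of[code] if level == "class" else code

    result = {b: [] for b in sheet.breeds}
    for region in matrix.regions:
        row = matrix.codes.loc[region.region_id]
        for breed in sheet.breeds:
            mine = [row[s] for s in sheet.samples_of(breed) if s in matrix.samples]
            if any(c in missing for c in mine):
                continue
            vals = {val(c) for c in mine}
            if len(vals) != 1:
                continue
            g = vals.pop()
            clash = False
            for other in sheet.breeds:
                if other == breed:
                    continue
                for s in sheet.samples_of(other):
                    if s in matrix.samples and row[s] not in missing:
                        if val(row[s]) == g:
                            clash = True
            if not clash:
                result[breed].append((region.region_id, g))
    return result


def brute_force_intersect(cnvrs, qtls, score_regions):
    """All-pairs O(n*m) three-track intersection."""
    out = []
    for c in cnvrs:
        scores = [
            w.score
            for w in score_regions
            if w.chrom == c.chrom and w.start < c.end and c.start < w.end
        ]
        qtl_ids = sorted(
            {
                q.qtl_id
                for q in qtls
                if q.chrom == c.chrom and q.start < c.end and c.start < q.end
            }
        )
        if scores and qtl_ids:
            out.append((c.region_id, max(scores), len(qtl_ids)))
    return sorted(out)


# ---------------------------------------------------------------------------
# toy builders


def make_matrix(rows: dict[str, list[str]], samples: list[str]) -> GenotypeMatrix:
    """Matrix from {region_id 'chrom:start1-end': codes-per-sample}."""
    regions = []
    for rid in rows:
        chrom, span = rid.split(":")
        s, e = span.split("-")
        regions.append(CnvRegion(rid, chrom, int(s) - 1, int(e)))
    codes = pd.DataFrame(
        [rows[r.region_id] for r in regions],
        index=[r.region_id for r in regions],
        columns=samples,
    )
    return GenotypeMatrix(regions, codes)


@pytest.fixture
def three_breed_sheet():
    return SampleSheet({"a1": "A", "a2": "A", "b1": "B", "b2": "B", "c1": "C"})


@pytest.fixture(scope="session")
def small_bundle():
    """One default-config simulated bundle shared across read-only tests."""
    return simulate_all(SimulationConfig(seed=11))


def assoc(study="S1", trait="t", chrom="chr1", pos=1, p=0.01) -> GwasAssociation:
    return GwasAssociation(study, trait, chrom, pos, p)
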