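"""Windowed GWAScore statistic over GWAS summary data.

The genome is tiled into fixed, non-overlapping windows (default 100 kb)
anchored at position 1.  For every window that contains at least one
significant GWAS SNP the score

    GWAScore = -n_gwas * sum_i log(P_i) / (0.1 * n_snp)

is computed, where ``n_gwas`` is the number of distinct GWAS studies
contributing at least one SNP to the window, ``n_snp`` the number of SNP
records in the window and ``P_i`` their association p-values.  The score is
therefore ``10 * n_gwas`` times the mean negative log p-value of the window
(for log base 10 and the default ``as_printed`` normalization).  Windows
whose score exceeds a threshold (default 0, strict) are emitted as
high-confidence score regions; each region is a single window, so K regions
of window size W cover exactly K*W bp.

Coordinates are 0-based half-open internally; input positions are 1-based.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .errors import ValidationError

__all__ = [
    "GwasAssociation",
    "ScoreConfig",
    "ScoreWindow",
    "assign_windows",
    "compute_gwascore",
    "score_genome",
    "high_confidence_regions",
    "chrom_sort_key",
]

_CHROM_SPLIT = re.compile(r"(\d+)")


def chrom_sort_key(chrom: str) -> tuple:
    """Natural sort key so chr2 < chr10 < chrX."""
    return tuple(int(p) if p.isdigit() else p for p in _CHROM_SPLIT.split(chrom))


@dataclass(frozen=True)
class GwasAssociation:
    """One significant SNP reported by one GWAS study.

    ``pos`` is a 1-based base-pair position; ``p_value`` must lie in (0, 1].
    """

    study_id: str
    trait: str
    chrom: str
    pos: int
    p_value: float

    def validate(self) -> None:
        if not self.chrom:
            raise ValidationError(f"association {self!r}: empty chromosome name")
        if self.pos < 1:
            raise ValidationError(
                f"association {self.study_id} {self.chrom}:{self.pos}: "
                f"position must be >= 1 (1-based)"
            )
        if not (0.0 < self.p_value <= 1.0):
            raise ValidationError(
                f"association {self.study_id} {self.chrom}:{self.pos}: "
                f"p_value {self.p_value!r} outside (0, 1]"
            )


@dataclass(frozen=True)
class ScoreConfig:
    """Parameters of the windowed score.

    window_size
        Window width in bp; windows tile each chromosome from position 1.
    log_base
        Base of the logarithm applied to p-values (10 by GWAS convention).
    normalization
        ``as_printed`` divides the summed log p by ``0.1 * n_snp``;
        ``per_window_mean`` divides by ``n_snp`` only (the per-window mean
        of -log P scaled by n_gwas).
    p_max
        Optional inclusion threshold: associations with p_value > p_max are
        ignored.  ``None`` keeps every record (input tables are assumed to
        hold already-significant SNPs).
    score_threshold
        Minimum score for a high-confidence region; comparison is strict.
    """

    window_size: int = 100_000
    log_base: float = 10.0
    normalization: str = "as_printed"
    p_max: float | None = None
    score_threshold: float = 0.0

    def __post_init__(self) -> None:
        if self.window_size <= 0:
            raise ValidationError(f"window_size must be > 0, got {self.window_size}")
        if self.log_base <= 1.0:
            raise ValidationError(f"log_base must be > 1, got {self.log_base}")
        if self.normalization not in ("as_printed", "per_window_mean"):
            raise ValidationError(
                f"normalization must be 'as_printed' or 'per_window_mean', "
                f"got {self.normalization!r}"
            )
        if self.score_threshold < 0:
            raise ValidationError(
                f"score_threshold must be >= 0, got {self.score_threshold}"
            )


@dataclass(frozen=True)
class ScoreWindow:
    """A scored genomic window (0-based half-open coordinates).

    ``n_gwas`` counts distinct study ids with at least one association in
    the window; ``n_snp`` counts association records.
    """

    chrom: str
    start: int
    end: int
    n_gwas: int
    n_snp: int
    score: float

    @property
    def start_1based(self) -> int:
        return self.start + 1

    def sort_key(self) -> tuple:
        return (chrom_sort_key(self.chrom), self.start)


def assign_windows(
    associations: Iterable[GwasAssociation], config: ScoreConfig
) -> dict[tuple[str, int], list[GwasAssociation]]:
    """Group associations by (chrom, window index).

    Window ``k`` covers 1-based positions ``[k*W + 1, (k+1)*W]``.  Records
    failing validation raise :class:`ValidationError`; records above
    ``config.p_max`` (when set) are dropped.  Keys are returned in
    deterministic (chrom, index) order regardless of input order.
    """
    groups: dict[tuple[str, int], list[GwasAssociation]] = {}
    for assoc in associations:
        assoc.validate()
        if config.p_max is not None and assoc.p_value > config.p_max:
            continue
        key = (assoc.chrom, (assoc.pos - 1) // config.window_size)
        groups.setdefault(key, []).append(assoc)
    ordered = sorted(groups, key=lambda k: (chrom_sort_key(k[0]), k[1]))
    # within-window order is made deterministic as well
    return {
        k: sorted(groups[k], key=lambda a: (a.pos, a.study_id, a.p_value))
        for k in ordered
    }


def compute_gwascore(
    group: Sequence[GwasAssociation],
    config: ScoreConfig,
    *,
    chrom_length: int | None = None,
) -> ScoreWindow:
    """Score one window's worth of associations.

    All records must fall in the same window of the same chromosome.  A
    p-value of exactly 0 is rejected upstream (log undefined).  When
    ``chrom_length`` is given, the terminal window is truncated to it.
    """
    if not group:
        raise ValidationError("compute_gwascore requires a non-empty group")
    chrom = group[0].chrom
    widx = (group[0].pos - 1) // config.window_size
    for a in group:
        if a.chrom != chrom or (a.pos - 1) // config.window_size != widx:
            raise ValidationError(
                f"association {a.study_id} {a.chrom}:{a.pos} not in window "
                f"{chrom}[{widx}]"
            )
    log_div = math.log(config.log_base)
    sum_log_p = sum(math.log(a.p_value) / log_div for a in group)
    n_snp = len(group)
    n_gwas = len({a.study_id for a in group})
    denom = 0.1 * n_snp if config.normalization == "as_printed" else float(n_snp)
    score = -n_gwas * sum_log_p / denom
    start = widx * config.window_size
    end = start + config.window_size
    if chrom_length is not None:
        end = min(end, chrom_length)
    return ScoreWindow(
        chrom=chrom, start=start, end=end, n_gwas=n_gwas, n_snp=n_snp, score=score
    )


def score_genome(
    associations: Iterable[GwasAssociation],
    config: ScoreConfig | None = None,
    chrom_lengths: Mapping[str, int] | None = None,
) -> list[ScoreWindow]:
    """Score every occupied window of the genome.

    Returns one :class:`ScoreWindow` per window containing at least one
    association, sorted by (chrom, start).  Empty windows are omitted; an
    empty input yields an empty list.  ``chrom_lengths`` (optional) only
    truncates terminal windows.
    """
    config = config or ScoreConfig()
    out = []
    for (chrom, _widx), group in assign_windows(associations, config).items():
        length = chrom_lengths.get(chrom) if chrom_lengths else None
        out.append(compute_gwascore(group, config, chrom_length=length))
    return out


def high_confidence_regions(
    windows: Iterable[ScoreWindow], config: ScoreConfig | None = None
) -> list[ScoreWindow]:
    """Windows with score strictly above ``config.score_threshold``.

    Adjacent qualifying windows are deliberately not merged: each region is
    one window, so region count times window size equals covered bp.
    """
    config = config or ScoreConfig()
    return [w for w in windows if w.score > config.score_threshold]
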