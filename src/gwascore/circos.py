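"""CIRCOS track export: karyotype plus four plain-text data tracks.

The exported bundle mirrors the concentric-circle figure of the workflow:
a QTL tile track, a GWAScore histogram track (value = window score), a GWAS
scatter track (value = -log10 p per SNP) and a CNV tile track.  Only the
data files and a template ``circos.conf`` are written; rendering the image
is left to CIRCOS itself.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from .cnv import CnvRegion
from .core import GwasAssociation, ScoreWindow, chrom_sort_key
from .errors import ValidationError
from .integrate import QtlRecord

__all__ = ["TrackBundle", "export_circos"]

_CONF_TEMPLATE = """\
# template configuration; point CIRCOS at this directory
karyotype = karyotype.txt
<ideogram>
<spacing>
default = 0.005r
</spacing>
radius = 0.90r
thickness = 20p
fill = yes
</ideogram>
<plots>
<plot>
type = tile
file = qtl_tiles.txt
r0 = 0.80r
r1 = 0.90r
color = green
</plot>
<plot>
type = histogram
file = gwascore_histogram.txt
r0 = 0.65r
r1 = 0.79r
color = red
</plot>
<plot>
type = scatter
file = gwas_scatter.txt
r0 = 0.50r
r1 = 0.64r
color = blue
</plot>
<plot>
type = tile
file = cnv_tiles.txt
r0 = 0.38r
r1 = 0.49r
color = orange
</plot>
</plots>
<image>
<<include etc/image.conf>>
</image>
<<include etc/colors_fonts_patterns.conf>>
<<include etc/housekeeping.conf>>
"""


@dataclass
class TrackBundle:
    """Everything one CIRCOS figure needs, validated against a karyotype."""

    karyotype: Mapping[str, int]
    qtls: Sequence[QtlRecord] = field(default_factory=list)
    score_windows: Sequence[ScoreWindow] = field(default_factory=list)
    gwas: Sequence[GwasAssociation] = field(default_factory=list)
    cnvrs: Sequence[CnvRegion] = field(default_factory=list)

    def validate(self) -> None:
        def check(chrom: str, start: int, end: int, what: str) -> None:
            if chrom not in self.karyotype:
                raise ValidationError(f"{what} on unknown chromosome {chrom}")
            if start < 0 or end > self.karyotype[chrom]:
                raise ValidationError(
                    f"{what} [{start}, {end}) outside {chrom} "
                    f"(length {self.karyotype[chrom]})"
                )

        for q in self.qtls:
            check(q.chrom, q.start, q.end, f"QTL {q.qtl_id}")
        for w in self.score_windows:
            check(w.chrom, w.start, w.end, "score window")
        for a in self.gwas:
            check(a.chrom, a.pos - 1, a.pos, f"GWAS SNP {a.study_id}:{a.pos}")
        for c in self.cnvrs:
            check(c.chrom, c.start, c.end, f"CNVR {c.region_id}")


def export_circos(bundle: TrackBundle, outdir) -> dict[str, str]:
    """Write karyotype + four track files; returns name -> path.

    Track records use CIRCOS plain text (``chrom start end [value]``,
    0-based starts as CIRCOS expects numeric ranges, not bp conventions).
    Histogram values are window scores; scatter values are -log10 p.
    """
    bundle.validate()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}

    kary = []
    for chrom in sorted(bundle.karyotype, key=chrom_sort_key):
        label = chrom.removeprefix("chr")
        kary.append(
            f"chr - {chrom} {label} 0 {bundle.karyotype[chrom]} grey"
        )
    paths["karyotype"] = str(outdir / "karyotype.txt")
    Path(paths["karyotype"]).write_text("\n".join(kary) + ("\n" if kary else ""))

    def dump(name: str, lines: list[str]) -> None:
        paths[name.removesuffix(".txt")] = str(outdir / name)
        (outdir / name).write_text("\n".join(lines) + ("\n" if lines else ""))

    dump(
        "qtl_tiles.txt",
        [f"{q.chrom} {q.start} {q.end}" for q in bundle.qtls],
    )
    dump(
        "gwascore_histogram.txt",
        [
            f"{w.chrom} {w.start} {w.end} {w.score:.6f}"
            for w in bundle.score_windows
        ],
    )
    dump(
        "gwas_scatter.txt",
        [
            f"{a.chrom} {a.pos - 1} {a.pos} {-math.log10(a.p_value):.6f}"
            for a in bundle.gwas
        ],
    )
    dump(
        "cnv_tiles.txt",
        [f"{c.chrom} {c.start} {c.end}" for c in bundle.cnvrs],
    )
    paths["conf"] = str(outdir / "circos.conf")
    Path(paths["conf"]).write_text(_CONF_TEMPLATE)
    return paths
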