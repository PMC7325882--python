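"""Export CIRCOS track files for the four-ring integration figure.

Simulates a bundle, computes score regions, and writes the karyotype plus
QTL-tile, GWAScore-histogram, GWAS-scatter and CNV-tile data files that a
CIRCOS configuration can render as concentric circles.
"""

from pathlib import Path
from tempfile import mkdtemp

from gwascore import ScoreConfig, high_confidence_regions, score_genome, simulate_all
from gwascore.circos import TrackBundle, export_circos

bundle = simulate_all()
regions = high_confidence_regions(score_genome(bundle.gwas), ScoreConfig())

tracks = TrackBundle(
    karyotype=dict(bundle.config.genome),
    qtls=bundle.qtls,
    score_windows=regions,
    gwas=bundle.gwas,
    cnvrs=bundle.matrix.regions,
)
outdir = mkdtemp(prefix="circos_")
paths = export_circos(tracks, outdir)

for name, path in paths.items():
    n = len(Path(path).read_text().splitlines())
    print(f"{name:20s} {n:5d} lines  {path}")

print("\nHistogram values are window GWAScores; scatter values are -log10 p")
print("per SNP; QTL and CNV tracks are valueless tiles. Point circos at the")
print("written circos.conf to render the figure.")
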