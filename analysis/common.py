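"""Shared paths and parameters for the numbered analysis scripts.

The drivers write large intermediates (read BEDs, bedGraph tracks, peak
BEDs) under scratch/ and the small summary tables under results/.
"""

from pathlib import Path

ROOT = Path(__file__).resolve().parent.parent
SCRATCH = ROOT / "scratch"
DATA = SCRATCH / "data"
TRACKS = SCRATCH / "tracks"
PEAKS = SCRATCH / "peaks"
RESULTS = ROOT / "results"

SEED = 17
BINSIZE = 100
SIGMA_BINS = 2.0
PSEUDOCOUNT = 0.5
FDR = 0.15
WINDOW = 2000
COLOC_RUNS = 100

PHASES = ("G1", "S", "G2")


def ensure_dirs() -> None:
    for d in (DATA, TRACKS, PEAKS, RESULTS):
        d.mkdir(parents=True, exist_ok=True)


def load_layout_grid():
    from orimark import BinGrid, read_chrom_sizes

    layout = read_chrom_sizes(DATA / "chrom.sizes")
    return layout, BinGrid(layout, BINSIZE)
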