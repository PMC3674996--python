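"""Synthetic dataset generator with known ground truth.

The generator emulates the statistical structure of a replication-origin
mapping experiment with matched genomic control and phase-fractionated
chromatin-mark ChIP samples:

* a small genome with planted origin regions where nascent-strand reads pile
  up (triangular piles of configurable half-width) over a uniform background;
* a matched genomic-control sample with uniformly placed reads;
* chromatin-mark regions, each origin-associated with probability ``rho``
  (mark midpoint within ``assoc_window`` bp of a random origin center) and
  otherwise placed uniformly;
* phase-resolved mark sets: G1 is the base set, G2 is G1 with jittered
  boundaries, and S is G1 plus extra uniformly-placed, origin-unassociated
  marks whose widths are multiplied by the S expansion factor — so the mark
  covers more, wider domains in S-phase while the added coverage carries no
  origin signal;
* optionally a second "stable" mark with no S-phase expansion, as a
  phase-homogeneity control.

The planted association probability, origin positions and per-mark
association flags are retained so the analysis pipeline's output can be
checked against ground truth (parameter recovery). All randomness flows from
one master seed through named substreams, so each component is reproducible
independently of call order.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .genome import GenomeLayout
from .intervals import Region, RegionSet, TagAlignment, merge

_STREAMS = {
    "origins": 1,
    "marks": 2,
    "marks_extra": 3,
    "marks_jitter": 4,
    "stable": 5,
    "reads_nascent": 10,
    "reads_control": 11,
    "reads_chip_G1": 12,
    "reads_chip_S": 13,
    "reads_chip_G2": 14,
    "reads_chip2_G1": 15,
    "reads_chip2_S": 16,
    "reads_chip2_G2": 17,
}


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for the synthetic genome.

    Defaults are the conditions the pipeline is validated under: a 10-Mb
    two-chromosome genome, 100 origins, 200 marks with association
    probability 0.8, tenfold nascent enrichment over background, and 2x10^5
    reads per sample.
    """

    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chrS1": 6_000_000, "chrS2": 4_000_000}
    )
    n_origins: int = 100
    origin_spacing: str = "uniform"  # "uniform" or "grid"
    nascent_fold: float = 10.0
    nascent_halfwidth: int = 500
    reads_per_sample: int = 200_000
    read_length: int = 36
    n_marks: int = 200
    rho: float = 0.8
    mark_length_min: int = 500
    mark_length_max: int = 3000
    assoc_window: int = 1000
    s_expansion: float = 1.5
    g2_jitter: int = 50
    chip_fold: float = 10.0
    include_stable_mark: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.rho <= 1.0):
            raise ValueError("rho must be in [0, 1]")
        if self.nascent_fold < 1 or self.chip_fold < 1:
            raise ValueError("enrichment folds must be >= 1")
        if self.n_origins < 0 or self.n_marks < 0 or self.reads_per_sample < 0:
            raise ValueError("counts must be >= 0")
        if self.origin_spacing not in ("uniform", "grid"):
            raise ValueError(f"unknown origin spacing model {self.origin_spacing!r}")
        if self.s_expansion < 1:
            raise ValueError("S expansion factor must be >= 1")

    @property
    def layout(self) -> GenomeLayout:
        return GenomeLayout.from_dict(self.chrom_lengths)


@dataclass
class SyntheticTruth:
    """Planted ground truth for parameter-recovery tests."""

    layout: GenomeLayout
    origins: dict[str, np.ndarray]  # per-chromosome origin center positions
    marks: list[Region]  # base (asynchronous) mark intervals
    mark_associated: np.ndarray  # bool flag per base mark
    rho: float
    phase_marks: dict[str, RegionSet]  # merged per-phase sets, keys G1/S/G2
    stable_phase_marks: dict[str, RegionSet] | None = None

    @property
    def association_fraction(self) -> float:
        return float(np.mean(self.mark_associated)) if len(self.marks) else float("nan")

    @property
    def n_origins(self) -> int:
        return int(sum(len(v) for v in self.origins.values()))

    def to_dict(self) -> dict:
        d = {
            "layout": {"names": list(self.layout.names), "lengths": list(self.layout.lengths)},
            "origins": {c: [int(x) for x in v] for c, v in self.origins.items()},
            "marks": [[r.chrom, r.start, r.end] for r in self.marks],
            "mark_associated": [bool(x) for x in self.mark_associated],
            "rho": self.rho,
            "phase_marks": {
                p: [[r.chrom, r.start, r.end] for r in rs]
                for p, rs in self.phase_marks.items()
            },
        }
        if self.stable_phase_marks is not None:
            d["stable_phase_marks"] = {
                p: [[r.chrom, r.start, r.end] for r in rs]
                for p, rs in self.stable_phase_marks.items()
            }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SyntheticTruth":
        stable = None
        if d.get("stable_phase_marks") is not None:
            stable = {
                p: RegionSet([Region(c, s, e) for c, s, e in regs], merged=True)
                for p, regs in d["stable_phase_marks"].items()
            }
        return cls(
            layout=GenomeLayout(tuple(d["layout"]["names"]), tuple(d["layout"]["lengths"])),
            origins={c: np.asarray(v, dtype=np.int64) for c, v in d["origins"].items()},
            marks=[Region(c, s, e) for c, s, e in d["marks"]],
            mark_associated=np.asarray(d["mark_associated"], dtype=bool),
            rho=float(d["rho"]),
            phase_marks={
                p: RegionSet([Region(c, s, e) for c, s, e in regs], merged=True)
                for p, regs in d["phase_marks"].items()
            },
            stable_phase_marks=stable,
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SyntheticTruth):
            return NotImplemented
        return self.to_dict() == other.to_dict()


def _rng(config: SyntheticConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=(config.seed, _STREAMS[stream]))
    )


def _chrom_weights(layout: GenomeLayout) -> np.ndarray:
    lengths = np.asarray(layout.lengths, dtype=float)
    return lengths / lengths.sum()


def _place_origins(config: SyntheticConfig) -> dict[str, np.ndarray]:
    layout = config.layout
    rng = _rng(config, "origins")
    hw = config.nascent_halfwidth
    # apportion origins to chromosomes by length
    lengths = np.asarray(layout.lengths, dtype=float)
    quota = np.floor(config.n_origins * lengths / lengths.sum()).astype(int)
    remainder = config.n_origins - quota.sum()
    order = np.argsort(-(config.n_origins * lengths / lengths.sum() - quota))
    for i in range(remainder):
        quota[order[i]] += 1
    origins: dict[str, np.ndarray] = {}
    for name, length, k in zip(layout.names, layout.lengths, quota):
        if k == 0:
            origins[name] = np.empty(0, dtype=np.int64)
            continue
        if config.origin_spacing == "grid":
            spacing = length / (k + 1)
            if spacing < 2 * hw:
                raise ValueError(
                    f"{name}: {k} origins on {length} bp leave spacing {spacing:.0f} bp "
                    f"< 2 x pile half-width {hw}"
                )
            centers = (np.arange(1, k + 1) * spacing).astype(np.int64)
        else:
            if length < 2 * hw + 1:
                raise ValueError(f"{name}: chromosome shorter than one origin pile")
            centers = np.sort(rng.integers(hw, length - hw, size=k)).astype(np.int64)
        origins[name] = centers
    return origins


def _uniform_region(rng, layout: GenomeLayout, weights, length: int) -> Region:
    ci = int(rng.choice(len(layout.names), p=weights))
    chrom = layout.names[ci]
    chrom_len = layout.lengths[ci]
    length = min(length, chrom_len)
    start = int(rng.integers(0, chrom_len - length + 1))
    return Region(chrom, start, start + length)


def generate_truth(config: SyntheticConfig) -> SyntheticTruth:
    """Plant origins and phase-resolved mark regions; see module docstring."""
    layout = config.layout
    origins = _place_origins(config)
    weights = _chrom_weights(layout)
    all_origins = [(c, int(p)) for c in layout.names for p in origins[c]]

    rng = _rng(config, "marks")
    marks: list[Region] = []
    flags = np.zeros(config.n_marks, dtype=bool)
    for i in range(config.n_marks):
        length = int(rng.integers(config.mark_length_min, config.mark_length_max + 1))
        associated = bool(rng.random() < config.rho) and len(all_origins) > 0
        if associated:
            chrom, center = all_origins[int(rng.integers(0, len(all_origins)))]
            mid = center + int(rng.integers(-config.assoc_window, config.assoc_window + 1))
            chrom_len = layout.length_of(chrom)
            start = int(np.clip(mid - length // 2, 0, max(chrom_len - length, 0)))
            marks.append(Region(chrom, start, start + min(length, chrom_len)))
        else:
            marks.append(_uniform_region(rng, layout, weights, length))
        flags[i] = associated

    # S-phase expansion: extra origin-unassociated marks, widths x expansion
    rng_x = _rng(config, "marks_extra")
    n_extra = int(round((config.s_expansion - 1.0) * config.n_marks))
    extras = [
        _uniform_region(
            rng_x,
            layout,
            weights,
            int(round(config.s_expansion
                      * rng_x.integers(config.mark_length_min, config.mark_length_max + 1))),
        )
        for _ in range(n_extra)
    ]

    rng_j = _rng(config, "marks_jitter")
    g2 = [_jitter(r, config.g2_jitter, layout, rng_j) for r in marks]

    phase_marks = {
        "G1": merge(marks),
        "S": merge(marks + extras),
        "G2": merge(g2),
    }

    stable = None
    if config.include_stable_mark:
        rng_s = _rng(config, "stable")
        base2: list[Region] = []
        for _ in range(config.n_marks):
            length = int(rng_s.integers(config.mark_length_min, config.mark_length_max + 1))
            if rng_s.random() < config.rho and all_origins:
                chrom, center = all_origins[int(rng_s.integers(0, len(all_origins)))]
                mid = center + int(rng_s.integers(-config.assoc_window, config.assoc_window + 1))
                chrom_len = layout.length_of(chrom)
                start = int(np.clip(mid - length // 2, 0, max(chrom_len - length, 0)))
                base2.append(Region(chrom, start, start + min(length, chrom_len)))
            else:
                base2.append(_uniform_region(rng_s, layout, weights, length))
        stable = {
            "G1": merge(base2),
            "S": merge([_jitter(r, config.g2_jitter, layout, rng_s) for r in base2]),
            "G2": merge([_jitter(r, config.g2_jitter, layout, rng_s) for r in base2]),
        }

    return SyntheticTruth(
        layout=layout,
        origins=origins,
        marks=marks,
        mark_associated=flags,
        rho=config.rho,
        phase_marks=phase_marks,
        stable_phase_marks=stable,
    )


def _jitter(r: Region, j: int, layout: GenomeLayout, rng) -> Region:
    if j == 0:
        return Region(r.chrom, r.start, r.end)
    chrom_len = layout.length_of(r.chrom)
    start = int(np.clip(r.start + rng.integers(-j, j + 1), 0, chrom_len - 1))
    end = int(np.clip(r.end + rng.integers(-j, j + 1), start + 1, chrom_len))
    return Region(r.chrom, start, end)


def _signal_probability(fold: float, signal_bp: int, genome_bp: int) -> float:
    """Mixture weight p such that the expected in-signal / out-of-signal
    coverage-density ratio equals ``fold`` when a fraction p of reads falls
    in ``signal_bp`` of signal territory and the rest is uniform."""
    if fold <= 1 or signal_bp == 0:
        return 0.0
    a = float(signal_bp)
    return (fold - 1.0) * a / (genome_bp + (fold - 1.0) * a)


def _uniform_starts(rng, layout: GenomeLayout, n: int, read_len: int):
    weights = _chrom_weights(layout)
    ci = rng.choice(len(layout.names), p=weights, size=n)
    starts = np.empty(n, dtype=np.int64)
    for i, (name, length) in enumerate(zip(layout.names, layout.lengths)):
        sel = ci == i
        starts[sel] = rng.integers(0, max(length - read_len, 0) + 1, size=int(sel.sum()))
    return ci, starts


def simulate_reads(
    truth: SyntheticTruth, config: SyntheticConfig, role: str
) -> list[TagAlignment]:
    """Simulate fixed-length, strandless aligned reads for one sample role.

    ``control``: uniform read starts. ``nascent``: a mixture where a read is,
    with probability p_sig, drawn from a triangular pile (half-width
    ``nascent_halfwidth``) around a random origin and otherwise uniform;
    p_sig is set so the expected in-pile/background coverage ratio equals
    ``nascent_fold``. ``chip_G1``/``chip_S``/``chip_G2`` (and
    ``chip2_*`` for the stable mark): the same mixture with positions
    bp-uniform within that phase's mark regions at ``chip_fold``.
    """
    layout = truth.layout
    n = config.reads_per_sample
    rl = config.read_length
    rng = _rng(config, f"reads_{role}" if not role.startswith("reads_") else role)
    if n == 0:
        warnings.warn(f"zero reads requested for role {role!r}", stacklevel=2)
        return []

    names = layout.names
    if role == "control":
        ci, starts = _uniform_starts(rng, layout, n, rl)
    elif role == "nascent":
        all_origins = [(c, int(p)) for c in names for p in truth.origins[c]]
        hw = config.nascent_halfwidth
        p_sig = _signal_probability(config.nascent_fold, len(all_origins) * 2 * hw,
                                    layout.total_bp)
        is_sig = rng.random(n) < p_sig
        ci, starts = _uniform_starts(rng, layout, n, rl)
        n_sig = int(is_sig.sum())
        if n_sig and all_origins:
            oi = rng.integers(0, len(all_origins), size=n_sig)
            offsets = rng.triangular(-hw, 0, hw, size=n_sig)
            for k, (read_idx, origin_idx) in enumerate(zip(np.flatnonzero(is_sig), oi)):
                chrom, center = all_origins[int(origin_idx)]
                c = names.index(chrom)
                length = layout.lengths[c]
                pos = int(round(center + offsets[k])) - rl // 2
                ci[read_idx] = c
                starts[read_idx] = int(np.clip(pos, 0, length - rl))
    elif role.startswith("chip"):
        phase = role.split("_", 1)[1]
        sets = truth.phase_marks if role.startswith("chip_") else (truth.stable_phase_marks or {})
        if phase not in sets:
            raise ValueError(f"no mark regions for role {role!r}")
        regions = list(sets[phase])
        covered = sum(r.length for r in regions)
        p_sig = _signal_probability(config.chip_fold, covered, layout.total_bp)
        is_sig = rng.random(n) < p_sig
        ci, starts = _uniform_starts(rng, layout, n, rl)
        n_sig = int(is_sig.sum())
        if n_sig and covered:
            cum = np.cumsum([r.length for r in regions])
            u = rng.integers(0, covered, size=n_sig)
            ri = np.searchsorted(cum, u, side="right")
            for read_idx, region_idx, pos_u in zip(np.flatnonzero(is_sig), ri, u):
                r = regions[int(region_idx)]
                offset = int(pos_u - (cum[region_idx] - r.length))
                c = names.index(r.chrom)
                length = layout.lengths[c]
                pos = r.start + offset - rl // 2
                ci[read_idx] = c
                starts[read_idx] = int(np.clip(pos, 0, length - rl))
    else:
        raise ValueError(f"unknown sample role {role!r}")

    return [
        TagAlignment(names[int(c)], int(s), int(s) + rl) for c, s in zip(ci, starts)
    ]


def write_reads_bed(reads: list[TagAlignment], path: str | Path) -> int:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\n")
    return len(reads)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def emit_dataset(truth: SyntheticTruth, config: SyntheticConfig, outdir: str | Path) -> dict:
    """Write the full dataset (chrom.sizes, read BEDs, truth.json) plus a
    manifest with per-file sha256 checksums; returns the manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    files: dict[str, dict] = {}

    sizes_path = outdir / "chrom.sizes"
    with open(sizes_path, "w") as fh:
        for name, length in zip(truth.layout.names, truth.layout.lengths):
            fh.write(f"{name}\t{length}\n")
    files["chrom.sizes"] = {"path": sizes_path.name, "n_records": len(truth.layout.names)}

    roles = ["nascent", "control", "chip_G1", "chip_S", "chip_G2"]
    if truth.stable_phase_marks is not None:
        roles += ["chip2_G1", "chip2_S", "chip2_G2"]
    for role in roles:
        path = outdir / f"{role}.bed"
        n = write_reads_bed(simulate_reads(truth, config, role), path)
        files[f"{role}.bed"] = {"path": path.name, "n_records": n}

    truth_path = outdir / "truth.json"
    truth_path.write_text(json.dumps(truth.to_dict(), indent=1, sort_keys=True))
    files["truth.json"] = {"path": truth_path.name, "n_records": len(truth.marks)}

    for info in files.values():
        info["sha256"] = _sha256(outdir / info["path"])

    manifest = {"seed": config.seed, "config": asdict(config), "files": files}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return manifest


def load_truth(path: str | Path) -> SyntheticTruth:
    return SyntheticTruth.from_dict(json.loads(Path(path).read_text()))
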