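"""End-to-end orchestration: reads -> binned RPKM -> enrichment ratio ->
enriched-region calling -> colocalization and cell-cycle tables, driven by
one config, with a machine-readable JSON report plus per-table TSVs.

The run is a pure function of (input files, config, seeds): re-execution
reproduces every numeric output exactly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io
from .cellcycle import PHASES, build_phase_count_table, chi_square_phase_homogeneity, phase_coloc
from .coloc import ColocConfig, coloc_test, distance_profile
from .genome import BinGrid
from .intervals import RegionSet, union
from .peaks import PeakCallConfig, call_enriched_regions
from .tracks import compute_rpkm, count_reads_per_bin, enrichment_ratio, gaussian_smooth


@dataclass
class RunConfig:
    genome: str
    nascent: str
    control: str
    chip: dict[str, dict[str, str]]  # mark -> phase -> BED path
    outdir: str
    binsize: int = 100
    sigma_bins: float = 2.0
    pseudocount: float = 0.5
    replication_fdr: float = 0.15
    mark_fdr: float = 0.15
    peak_seed: int = 17
    peak_randomizations: int = 20
    min_width: int = 200
    merge_gap: int = 200
    window: int = 2000
    coloc_runs: int = 100
    coloc_seed: int = 17
    # called-region boundaries are only certain to about the smoothing scale,
    # so S-only fragments must exceed it to count as genuinely phase-specific
    s_only_min_width: int = 500

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def content_hash(self) -> str:
        fields = asdict(self)
        fields.pop("outdir")  # where outputs land does not affect the numbers
        canon = json.dumps(fields, sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


class StageError(RuntimeError):
    """A pipeline stage failed; partial outputs are preserved in outdir."""


def _rpkm_track(path: str, grid: BinGrid, label: str, log: list) -> tuple:
    alignments, skipped = io.load_alignments(path, grid.layout)
    counts = count_reads_per_bin(alignments, grid)
    counts.label = label
    log.append({"stage": f"read:{label}", "reads": len(alignments), "skipped": skipped})
    return compute_rpkm(counts)


def run_full_analysis(config: RunConfig) -> dict:
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[dict] = []
    report: dict = {
        "schema_version": 1,
        "config_hash": config.content_hash(),
        "seeds": {"peaks": config.peak_seed, "coloc": config.coloc_seed},
    }

    def stage(name):
        def wrap(fn, *args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as e:  # noqa: BLE001 - re-raise with stage name
                raise StageError(f"stage {name!r} failed: {e}") from e
        return wrap

    layout = stage("genome")(io.read_chrom_sizes, config.genome)
    grid = BinGrid(layout, config.binsize)

    # -- replication initiation ratio track ----------------------------------
    # The ratio is taken between *smoothed* RPKM tracks: smoothing the
    # denominator first keeps near-zero control bins from producing a heavy
    # ratio tail that would dominate peak calling.
    def build_ratio():
        nascent = _rpkm_track(config.nascent, grid, "nascent", log)
        control = _rpkm_track(config.control, grid, "control", log)
        ratio = enrichment_ratio(
            gaussian_smooth(nascent, config.sigma_bins),
            gaussian_smooth(control, config.sigma_bins),
            config.pseudocount,
        )
        io.write_signal_track(ratio, outdir / "ratio.bedgraph", merge_runs=True, decimals=4)
        return ratio

    ratio = stage("ratio")(build_ratio)

    # -- replication peaks ---------------------------------------------------
    def call_replication():
        cfg = PeakCallConfig(
            fdr=config.replication_fdr,
            n_randomizations=config.peak_randomizations,
            min_width=config.min_width,
            merge_gap=config.merge_gap,
            seed=config.peak_seed,
            sigma_bins=config.sigma_bins,
        )
        res = call_enriched_regions(ratio, cfg)
        io.write_regions(res.peaks, outdir / "replication_peaks.bed")
        res.fdr_table.to_csv(outdir / "replication_fdr_table.tsv", sep="\t", index=False)
        log.append({"stage": "callpeaks:replication", "peaks": len(res.peaks),
                    "threshold": res.threshold})
        return res

    repl = stage("replication_peaks")(call_replication)
    report["replication_peaks"] = {
        "n": len(repl.peaks),
        "covered_bp": repl.peaks.covered_bp,
        "threshold": repl.threshold,
        "estimated_fdr": repl.estimated_fdr,
    }

    # -- chromatin-mark peaks per phase --------------------------------------
    def call_marks():
        cfg = PeakCallConfig(
            fdr=config.mark_fdr,
            n_randomizations=config.peak_randomizations,
            min_width=config.min_width,
            merge_gap=config.merge_gap,
            seed=config.peak_seed,
            sigma_bins=config.sigma_bins,
        )
        out: dict[str, dict[str, RegionSet]] = {}
        for mark, phases in config.chip.items():
            out[mark] = {}
            for phase, path in phases.items():
                rpkm = _rpkm_track(path, grid, f"{mark}:{phase}", log)
                res = call_enriched_regions(rpkm, cfg)
                peaks = RegionSet([r for r in res.peaks], merged=True)
                io.write_regions(peaks, outdir / f"{mark}_{phase}.peaks.bed")
                log.append({"stage": f"callpeaks:{mark}:{phase}", "peaks": len(peaks)})
                out[mark][phase] = peaks
        return out

    mark_peaks = stage("mark_peaks")(call_marks)

    primary_mark = next(iter(config.chip))
    primary = mark_peaks[primary_mark]
    overall = primary.get("async") or union(
        union(primary["G1"], primary["S"]), primary["G2"]
    )

    # -- colocalization table (overall + phases + S-only) ---------------------
    def coloc_table():
        ccfg = ColocConfig(window=config.window, n_runs=config.coloc_runs,
                           seed=config.coloc_seed)
        rows = {"overall": coloc_test(overall, repl.peaks, layout, ccfg)}
        rows.update(
            phase_coloc(
                {p: primary[p] for p in PHASES}, repl.peaks, layout, ccfg,
                s_only_min_width=config.s_only_min_width,
            )
        )
        return rows

    coloc_rows = stage("coloc")(coloc_table)
    order = ["overall", "G1", "S", "S-only", "G2"]
    table1 = pd.DataFrame(
        [
            {
                "regions": name,
                "observed_pct": 100 * r.observed,
                "null_mean_pct": 100 * r.null_mean,
                "null_sd_pct": 100 * r.null_sd,
                "fold": r.fold,
                "p_empirical": r.p_empirical,
                "n_features": r.n_features,
            }
            for name in order
            if (r := coloc_rows.get(name)) is not None
        ]
    )
    table1.to_csv(outdir / "coloc_table.tsv", sep="\t", index=False)
    report["coloc_table"] = {
        name: coloc_rows[name].to_dict() for name in order if name in coloc_rows
    }

    # -- phase bin-count table + chi-square -----------------------------------
    def phase_tables():
        countable = {
            mark: phases for mark, phases in mark_peaks.items()
            if all(p in phases for p in PHASES)
        }
        table = build_phase_count_table(countable, grid)
        table.to_csv(outdir / "phase_bin_counts.tsv", sep="\t")
        chi = None
        if len(table) >= 2:
            stat, df, p = chi_square_phase_homogeneity(table.iloc[:2])
            chi = {"statistic": stat, "df": df, "p": p,
                   "marks": list(table.index[:2])}
        return table, chi

    count_table, chi = stage("phase_tables")(phase_tables)
    report["phase_bin_counts"] = {
        mark: {p: int(count_table.loc[mark, p]) for p in PHASES}
        for mark in count_table.index
    }
    report["chi_square"] = chi

    # -- distance profile ------------------------------------------------------
    def profile():
        prof = distance_profile(ratio, overall)
        prof.to_csv(outdir / "distance_profile.tsv", sep="\t", index=False)
        return prof

    prof = stage("distance_profile")(profile)
    report["distance_profile"] = prof.to_dict(orient="records")
    report["log"] = log

    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report
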