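"""Run orchestration: one configuration drives the analysis stages.

Stages are executed in dependency order (design -> mare, design -> scan,
y1h; scan + y1h -> benchmark; luciferase independent).  Every run directory
receives a ``provenance.json`` recording the configuration hash, seed,
package version and per-stage output counts, so a rerun with the same
configuration is verifiably identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from . import benchmark as bench
from . import landscape as lsc
from . import motifs as mot
from . import reporter as rep
from . import tiling
from . import y1h

logger = logging.getLogger(__name__)

STAGE_ORDER = ["design", "mare", "scan", "y1h", "benchmark", "luciferase"]


@dataclass
class RunConfig:
    seed: int = 17
    stages: list[str] = field(default_factory=lambda: list(STAGE_ORDER))
    options: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(seed=int(raw.get("seed", 17)),
                  stages=list(raw.get("stages", STAGE_ORDER)),
                  options={k: v for k, v in raw.items()
                           if k not in ("seed", "stages")})
        cfg.validate()
        return cfg

    def validate(self) -> None:
        unknown = set(self.stages) - set(STAGE_ORDER)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")
        for stage in self.stages:
            opts = self.options.get(stage, {})
            for key in ("fasta", "intensities", "motifs", "plates", "known",
                        "interactions", "nucleosome", "wells"):
                if key in opts and not Path(opts[key]).exists():
                    raise FileNotFoundError(
                        f"stage {stage}: input {key}={opts[key]} not found")

    def digest(self) -> str:
        canon = yaml.safe_dump(
            {"seed": self.seed, "stages": self.stages, "options": self.options},
            sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def run(config: RunConfig, outdir: str | Path) -> dict:
    """Execute the configured stages; returns the provenance record."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    config.validate()
    provenance: dict = {"config_hash": config.digest(), "seed": config.seed,
                        "version": __version__, "stages": {}}
    state: dict = {}

    for stage in STAGE_ORDER:
        if stage not in config.stages:
            continue
        opts = dict(config.options.get(stage, {}))
        logger.info("running stage %s", stage)
        counts = _STAGE_FUNCS[stage](opts, state, outdir, config.seed)
        provenance["stages"][stage] = counts

    (outdir / "provenance.json").write_text(
        json.dumps(provenance, indent=2, sort_keys=True) + "\n")
    return provenance


def _require(state: dict, key: str, stage: str, needed_by: str):
    if key not in state:
        raise RuntimeError(
            f"stage {needed_by!r} requires output of stage {stage!r}; "
            "enable it or provide the input explicitly")
    return state[key]


def _stage_design(opts, state, outdir, seed):
    element = tiling.read_element_fasta(opts["fasta"], opts["element"])
    library = tiling.design_fragments(
        element,
        fragment_length=int(opts.get("fragment_length", 36)),
        overlap=int(opts.get("overlap", 24)),
        flank=int(opts.get("flank", 24)))
    tiling.write_library(library, outdir / "design")
    state["element"] = element
    state["library"] = library
    return {"fragments": len(library)}


def _stage_mare(opts, state, outdir, seed):
    library = _require(state, "library", "design", "mare")
    intensities = lsc.read_intensities(opts["intensities"])
    tf_id = opts.get("tf", "TF")
    min_e = float(opts.get("min_enrichment", 2.0))
    normalize = bool(opts.get("normalize_by_protein", True))
    mare_dir = outdir / "mare"
    mare_dir.mkdir(parents=True, exist_ok=True)

    reps = sorted(intensities["replicate_id"].unique())
    peaks_per_rep = []
    for rep_id in reps:
        land = lsc.bin_signals(intensities, library, library.element_id,
                               tf_id, rep_id, normalize_by_protein=normalize)
        lsc.interpolate_landscape(land)
        cls = lsc.classify_positions(land, seed=seed)
        peaks = lsc.call_peaks(land, cls, min_enrichment=min_e)
        lsc.landscape_frame(land, cls).to_csv(
            mare_dir / f"landscape.{rep_id}.tsv", sep="\t", index=False)
        peaks_per_rep.append((rep_id, peaks))
    if len(peaks_per_rep) >= 2:
        lsc.reproducible_peaks(peaks_per_rep[0][1], peaks_per_rep[1][1])
    for rep_id, peaks in peaks_per_rep:
        lsc.peaks_to_bed(peaks, library.element_id, tf_id).to_csv(
            mare_dir / f"peaks.{rep_id}.bed", sep="\t", index=False,
            header=False)
    state["peaks"] = dict(peaks_per_rep)
    return {"replicates": len(reps),
            "peaks": {r: len(p) for r, p in peaks_per_rep},
            "reproducible": {r: sum(pk.reproducible for pk in p)
                             for r, p in peaks_per_rep}}


def _stage_scan(opts, state, outdir, seed):
    element = _require(state, "element", "design", "scan")
    pwms = mot.read_meme_minimal(opts["motifs"])
    p_threshold = float(opts.get("pvalue", 1e-4))
    hits: list[mot.MotifHit] = []
    for pwm in pwms:
        hits.extend(mot.scan(element, pwm, p_threshold=p_threshold,
                             both_strands=bool(opts.get("both_strands", True))))
    scan_dir = outdir / "scan"
    scan_dir.mkdir(parents=True, exist_ok=True)
    mot.hits_to_frame(hits).to_csv(scan_dir / "hits.tsv", sep="\t", index=False)
    (scan_dir / "hits.gff3").write_text(mot.hits_to_gff3(hits))
    state["hits"] = hits
    state["scan_pvalue"] = p_threshold
    return {"pwms": len(pwms), "hits": len(hits)}


def _stage_y1h(opts, state, outdir, seed):
    plates = y1h.read_plates(opts["plates"])
    threshold = float(opts.get("threshold", y1h.DEFAULT_THRESHOLD))
    calls = []
    for plate in plates:
        calls.extend(y1h.call_plate(plate, threshold=threshold))
    y1h_dir = outdir / "y1h"
    y1h_dir.mkdir(parents=True, exist_ok=True)
    calls_df = pd.DataFrame([vars(c) for c in calls])
    calls_df.to_csv(y1h_dir / "calls.tsv", sep="\t", index=False)

    # reproducible sets per (bait, method) when two screens are present
    repro: dict[str, dict[str, set]] = {m: {} for m in y1h.METHODS}
    for (bait, method), grp in calls_df.groupby(["bait_id", "method"]):
        screens = sorted(grp["screen_id"].unique())
        if len(screens) >= 2:
            by_screen = [
                [c for c in calls if c.bait_id == bait and c.method == method
                 and c.screen_id == s] for s in screens[:2]]
            repro[method][bait] = y1h.aggregate_method(*by_screen)["reproducible"]
    known = {}
    if "known" in opts:
        kdf = pd.read_csv(opts["known"], sep="\t")
        known = {b: set(g["tf_id"]) for b, g in kdf.groupby("bait_id")}
    summary = y1h.summarize_table(repro["transformation"], repro["mating"],
                                  known or None)
    summary.table.to_csv(y1h_dir / "summary.tsv", sep="\t", index=False)
    (y1h_dir / "summary.json").write_text(
        json.dumps(summary.totals, indent=2, default=float) + "\n")
    interactions = {(c.bait_id, c.tf_id) for c in calls if c.positive}
    state["interactions"] = interactions
    return {"plates": len(plates), "calls": len(calls),
            "positives": int(calls_df["positive"].sum())}


def _stage_benchmark(opts, state, outdir, seed):
    if "interactions" in opts:
        idf = pd.read_csv(opts["interactions"], sep="\t")
        interactions = set(zip(idf["bait_id"], idf["tf_id"]))
    else:
        interactions = _require(state, "interactions", "y1h", "benchmark")
    hits = _require(state, "hits", "scan", "benchmark")
    profiles = bench.read_nucleosome_tsv(opts["nucleosome"]) \
        if "nucleosome" in opts else None
    grid = bench.benchmark_grid(
        interactions, {state.get("scan_pvalue", 1e-4): hits},
        profiles=profiles)
    bench_dir = outdir / "benchmark"
    bench_dir.mkdir(parents=True, exist_ok=True)
    grid.to_csv(bench_dir / "grid.tsv", sep="\t", index=False)
    return {"interactions": len(interactions), "rows": len(grid)}


def _stage_luciferase(opts, state, outdir, seed):
    wells = rep.read_wells(opts["wells"])
    result = rep.analyze_wells(wells, alpha=float(opts.get("alpha", 0.05)))
    luc_dir = outdir / "luciferase"
    luc_dir.mkdir(parents=True, exist_ok=True)
    result.to_csv(luc_dir / "fold_changes.tsv", sep="\t", index=False)
    return {"interactions": len(result),
            "significant": int(result["significant"].sum()) if len(result) else 0}


_STAGE_FUNCS = {
    "design": _stage_design,
    "mare": _stage_mare,
    "scan": _stage_scan,
    "y1h": _stage_y1h,
    "benchmark": _stage_benchmark,
    "luciferase": _stage_luciferase,
}
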