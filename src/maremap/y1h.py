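"""Yeast one-hybrid screen scoring and cross-screen aggregation.

Each prey TF is spotted as a square of four technical-replicate colonies on
a selective plate; the well's "convoluted growth score" is the sum of its
four quadrant intensities.  A well is called positive when its score exceeds
the highest control (empty-prey) well score by at least the calling
threshold (default 20% above background; a documented per-well override
re-calls borderline wells at 10%, mirroring manual review).  Positives found
in both screens of a method are "reproducible"; interactions reproducible
under both the transformation and mating procedures form the consensus set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

DEFAULT_THRESHOLD = 0.20
RELAXED_THRESHOLD = 0.10
CONTROL_TAG = "CONTROL"
METHODS = ("transformation", "mating")

PLATE_COLUMNS = ["bait_id", "method", "screen_id", "row", "col", "tf_id",
                 "q1", "q2", "q3", "q4"]


@dataclass
class PlateGrid:
    bait_id: str
    method: str
    screen_id: str
    wells: pd.DataFrame        # columns: row, col, tf_id, q1..q4

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        q = self.wells[["q1", "q2", "q3", "q4"]]
        if (q < 0).any().any():
            raise ValueError("quadrant scores must be non-negative")


@dataclass(frozen=True)
class InteractionCall:
    bait_id: str
    tf_id: str
    method: str
    screen_id: str
    positive: bool
    relative_score: float      # convoluted score / max control background


@dataclass
class ScreenSummary:
    """Per-bait Table-1 style aggregation over two screens x two methods."""
    table: pd.DataFrame        # one row per bait
    totals: dict[str, float]


def read_plates(path: str | Path) -> list[PlateGrid]:
    df = pd.read_csv(path, sep="\t")
    missing = set(PLATE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"plate table missing columns {sorted(missing)}")
    plates = []
    for (bait, method, screen), sub in df.groupby(
            ["bait_id", "method", "screen_id"], sort=True):
        plates.append(PlateGrid(bait, method, str(screen),
                                sub.reset_index(drop=True)))
    return plates


def convoluted_score(quadrants: np.ndarray) -> np.ndarray:
    """Growth score of a well: the sum of its four quadrant intensities.

    Isolated here because it is the one deliberate simplification of the
    upstream image-analysis score (which operates on plate photographs).
    """
    return np.asarray(quadrants, float).sum(axis=-1)


def call_plate(plate: PlateGrid, threshold: float = DEFAULT_THRESHOLD,
               overrides: set[str] | None = None,
               relaxed_threshold: float = RELAXED_THRESHOLD,
               self_active_cap: float | None = None) -> list[InteractionCall]:
    """Call positive interactions on one plate.

    background = the maximal convoluted score over control (empty-prey)
    wells; a TF well is positive when its score > (1 + threshold) x
    background.  TFs listed in ``overrides`` (manually reviewed borderline
    wells) are re-called at ``relaxed_threshold``.  If ``self_active_cap``
    is given and the background exceeds it, the bait is flagged
    self-activating and the plate is rejected.
    """
    overrides = overrides or set()
    scores = convoluted_score(
        plate.wells[["q1", "q2", "q3", "q4"]].to_numpy())
    is_control = plate.wells["tf_id"].eq(CONTROL_TAG).to_numpy()
    if not is_control.any():
        raise ValueError(f"plate {plate.bait_id}/{plate.screen_id}: "
                         "no control wells")
    background = float(scores[is_control].max())
    if background <= 0:
        raise ValueError(f"plate {plate.bait_id}/{plate.screen_id}: "
                         "zero background, uninterpretable")
    if self_active_cap is not None and background > self_active_cap:
        raise SelfActivatingBait(plate.bait_id, background)

    calls = []
    for tf, score in zip(plate.wells["tf_id"], scores):
        if tf == CONTROL_TAG:
            continue
        thr = relaxed_threshold if tf in overrides else threshold
        calls.append(InteractionCall(
            bait_id=plate.bait_id, tf_id=tf, method=plate.method,
            screen_id=plate.screen_id,
            positive=bool(score > (1 + thr) * background),
            relative_score=float(score / background)))
    return calls


class SelfActivatingBait(RuntimeError):
    def __init__(self, bait_id: str, background: float):
        super().__init__(
            f"bait {bait_id} is self-activating (control background "
            f"{background:.1f} exceeds cap); exclude from screening")
        self.bait_id = bait_id


def positives(calls: list[InteractionCall]) -> set[str]:
    return {c.tf_id for c in calls if c.positive}


def aggregate_method(calls_screen1: list[InteractionCall],
                     calls_screen2: list[InteractionCall]) -> dict:
    """Reproducible positives of one (bait, method): found in both screens."""
    baits = {c.bait_id for c in calls_screen1} | {c.bait_id for c in calls_screen2}
    methods = {c.method for c in calls_screen1 + calls_screen2}
    if len(baits) > 1 or len(methods) > 1:
        raise ValueError("screens must share one bait and one method")
    s1, s2 = positives(calls_screen1), positives(calls_screen2)
    return {"screen1": len(s1), "screen2": len(s2),
            "reproducible": s1 & s2,
            "overlap_fraction": (len(s1 & s2) / len(s1)) if s1 else float("nan")}


def round_half_up_pct(numerator: float, denominator: float) -> int:
    """Percentage rounded half-up to an integer (32.5% -> 33%)."""
    import math

    return int(math.floor(100.0 * numerator / denominator + 0.5))


def summarize_table(reproducible_t: dict[str, set[str]],
                    reproducible_m: dict[str, set[str]],
                    known: dict[str, set[str]] | None = None,
                    screen_counts: dict | None = None) -> ScreenSummary:
    """Aggregate per-bait reproducible sets into a summary table.

    ``known`` maps baits to literature interactor sets; baits without one
    (e.g. orphan enhancers) are excluded from the sensitivity denominator.
    The totals row sums numerators and denominators across baits before
    forming percentages.
    """
    known = known or {}
    baits = sorted(set(reproducible_t) | set(reproducible_m))
    rows = []
    for bait in baits:
        t = reproducible_t.get(bait, set())
        m = reproducible_m.get(bait, set())
        consensus = t & m
        union = t | m
        row = {"bait_id": bait,
               "reproducible_transformation": len(t),
               "reproducible_mating": len(m),
               "consensus": len(consensus), "union": len(union)}
        if bait in known:
            row["known_total"] = len(known[bait])
            row["known_transformation"] = len(t & known[bait])
            row["known_mating"] = len(m & known[bait])
        rows.append(row)
    table = pd.DataFrame(rows)

    tot_consensus = int(table["consensus"].sum())
    tot_union = int(table["union"].sum())
    known_baits = [b for b in baits if b in known]
    kt = sum(len(reproducible_t.get(b, set()) & known[b]) for b in known_baits)
    km = sum(len(reproducible_m.get(b, set()) & known[b]) for b in known_baits)
    kd = sum(len(known[b]) for b in known_baits)
    totals = {
        "consensus": tot_consensus, "union": tot_union,
        "consensus_pct": round_half_up_pct(tot_consensus, tot_union)
        if tot_union else float("nan"),
        "known_transformation": kt, "known_mating": km, "known_total": kd,
        "sensitivity_transformation_pct": round_half_up_pct(kt, kd) if kd else float("nan"),
        "sensitivity_mating_pct": round_half_up_pct(km, kd) if kd else float("nan"),
    }
    if screen_counts:
        totals.update(screen_counts)
    return ScreenSummary(table=table, totals=totals)


# ---------------------------------------------------------------------------
# Packaged published screen summary (Table-1 style fixture)

def load_published_screen_table() -> pd.DataFrame:
    """Per-bait screen summary of the published benchmark (counts and
    overlap/known/consensus fractions), packaged as a TSV fixture."""
    with resources.files("maremap.data").joinpath("table1.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t", na_values=["-"])


def published_table_totals(table: pd.DataFrame | None = None) -> dict[str, float]:
    """Recompute the totals row of the published screen summary by summing
    per-bait numerators and denominators."""
    t = load_published_screen_table() if table is None else table
    totals: dict[str, float] = {
        "transformation_screen1": int(t["t_screen1"].sum()),
        "transformation_screen2": int(t["t_screen2"].sum()),
        "mating_screen1": int(t["m_screen1"].sum()),
        "mating_screen2": int(t["m_screen2"].sum()),
        "transformation_overlap_num": int(t["t_overlap_num"].sum()),
        "transformation_overlap_den": int(t["t_overlap_den"].sum()),
        "mating_overlap_num": int(t["m_overlap_num"].sum()),
        "mating_overlap_den": int(t["m_overlap_den"].sum()),
        "transformation_known_num": int(t["t_known_num"].sum()),
        "mating_known_num": int(t["m_known_num"].sum()),
        "known_den": int(t["t_known_den"].sum()),
        "consensus_num": int(t["consensus_num"].sum()),
        "consensus_den": int(t["consensus_den"].sum()),
    }
    totals["transformation_overlap_pct"] = round_half_up_pct(
        totals["transformation_overlap_num"], totals["transformation_overlap_den"])
    totals["mating_overlap_pct"] = round_half_up_pct(
        totals["mating_overlap_num"], totals["mating_overlap_den"])
    totals["transformation_known_pct"] = round_half_up_pct(
        totals["transformation_known_num"], totals["known_den"])
    totals["mating_known_pct"] = round_half_up_pct(
        totals["mating_known_num"], totals["known_den"])
    totals["consensus_pct"] = round_half_up_pct(
        totals["consensus_num"], totals["consensus_den"])
    return totals


# Clone-resource milestones of the published TF open-reading-frame library.
CLONE_RESOURCE_COUNTS = {
    "predicted_tf_genes": 1576,
    "cdna_templates": 1260,
    "templates_retained": 1218,
    "orfs_cloned": 1014,
    "fully_verified": 750,
}


def clone_resource_pct(numerator_stage: str = "fully_verified",
                       denominator_stage: str = "predicted_tf_genes",
                       counts: dict[str, int] | None = None) -> int:
    c = counts or CLONE_RESOURCE_COUNTS
    return round_half_up_pct(c[numerator_stage], c[denominator_stage])
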