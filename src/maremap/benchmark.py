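"""Benchmarking screen calls against motif predictions.

Positive predictive value (PPV) is the fraction of detected TF–bait
interactions supported by at least one motif hit of that TF in that bait;
sensitivity is the fraction of motif-predicted TF–bait pairs that the screen
detected.  Both are computed at each motif-calling stringency, optionally
after masking motif hits that touch DNA predicted to be occupied by
nucleosomes (a hit is discarded when any of its bases has occupancy
probability strictly above the mask threshold).  Interactions involving TFs
without a PWM cannot be motif-supported and are excluded from the PPV
denominator (reported separately).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .motifs import MotifHit

MASK_THRESHOLDS = (0.3, 0.5, 0.7)
STRINGENCIES = (1e-3, 1e-4, 1e-5)


@dataclass
class NucleosomeProfile:
    """Per-base nucleosome occupancy probability over an element."""

    element_id: str
    prob: np.ndarray
    offset: int = 0     # element coordinate of prob[0]

    def __post_init__(self) -> None:
        self.prob = np.asarray(self.prob, float)
        if np.any((self.prob < 0) | (self.prob > 1)):
            raise ValueError("occupancy probabilities must lie in [0, 1]")

    def window(self, start: int, end: int) -> np.ndarray:
        i, j = start - self.offset, end - self.offset
        if i < 0 or j > len(self.prob):
            raise ValueError(
                f"interval [{start},{end}) outside profile span of "
                f"{self.element_id}")
        return self.prob[i:j]


@dataclass
class BenchmarkResult:
    stringency: float
    mask_threshold: float | None
    ppv: float
    sensitivity: float
    n_supported: int          # detected pairs with >=1 hit
    n_interactions: int       # detected pairs with a PWM-ed TF
    n_predicted: int          # pairs with >=1 hit
    n_excluded_no_pwm: int


def read_nucleosome_tsv(path) -> dict[str, NucleosomeProfile]:
    df = pd.read_csv(path, sep="\t")
    profiles = {}
    for eid, sub in df.groupby("element_id"):
        sub = sub.sort_values("position")
        pos = sub["position"].to_numpy(int)
        if len(pos) > 1 and not np.array_equal(pos, np.arange(pos[0], pos[-1] + 1)):
            raise ValueError(f"non-contiguous positions for {eid}")
        profiles[eid] = NucleosomeProfile(eid, sub["prob"].to_numpy(float),
                                          offset=int(pos[0]))
    return profiles


def mask_hits(hits: list[MotifHit],
              profiles: dict[str, NucleosomeProfile] | NucleosomeProfile,
              threshold: float) -> list[MotifHit]:
    """Drop hits with any base at occupancy probability > threshold."""
    if isinstance(profiles, NucleosomeProfile):
        profiles = {profiles.element_id: profiles}
    kept = []
    for h in hits:
        prof = profiles.get(h.element_id)
        if prof is None:
            raise ValueError(f"no nucleosome profile for {h.element_id}")
        if not np.any(prof.window(h.start, h.end) > threshold):
            kept.append(h)
    return kept


def predicted_pairs(hits: list[MotifHit]) -> set[tuple[str, str]]:
    """(bait, tf) pairs with at least one motif hit."""
    return {(h.element_id, h.tf_id) for h in hits}


def compute_ppv(interactions: set[tuple[str, str]], hits: list[MotifHit],
                pwm_tfs: set[str] | None = None) -> tuple[float, int, int, int]:
    """PPV = supported / interactions-with-PWM.

    Returns (ppv, n_supported, n_with_pwm, n_excluded); ppv is NaN when the
    denominator is empty.
    """
    predicted = predicted_pairs(hits)
    if pwm_tfs is None:
        # without an explicit PWM list, only TFs that appear in the hit set
        # (hence had a PWM) can be assessed
        pwm_tfs = {h.tf_id for h in hits}
    with_pwm = {(b, t) for b, t in interactions if t in pwm_tfs}
    supported = with_pwm & predicted
    n_excluded = len(interactions) - len(with_pwm)
    ppv = len(supported) / len(with_pwm) if with_pwm else float("nan")
    return ppv, len(supported), len(with_pwm), n_excluded


def compute_sensitivity(interactions: set[tuple[str, str]],
                        hits: list[MotifHit]) -> tuple[float, int, int]:
    """Sensitivity = detected-and-predicted / predicted (pair level).

    Returns (sensitivity, n_detected_predicted, n_predicted); NaN when
    nothing is predicted.
    """
    predicted = predicted_pairs(hits)
    hit_and_detected = predicted & interactions
    sens = len(hit_and_detected) / len(predicted) if predicted else float("nan")
    return sens, len(hit_and_detected), len(predicted)


def benchmark_grid(interactions: set[tuple[str, str]],
                   hits_by_stringency: dict[float, list[MotifHit]],
                   profiles: dict[str, NucleosomeProfile] | None = None,
                   pwm_tfs: set[str] | None = None,
                   mask_thresholds=MASK_THRESHOLDS) -> pd.DataFrame:
    """PPV/sensitivity over stringency x nucleosome-mask threshold."""
    rows = []
    for stringency, hits in sorted(hits_by_stringency.items(), reverse=True):
        variants: list[tuple[float | None, list[MotifHit]]] = [(None, hits)]
        if profiles is not None:
            variants += [(thr, mask_hits(hits, profiles, thr))
                         for thr in mask_thresholds]
        for thr, kept in variants:
            ppv, n_sup, n_int, n_excl = compute_ppv(interactions, kept, pwm_tfs)
            sens, n_det, n_pred = compute_sensitivity(interactions, kept)
            rows.append(BenchmarkResult(
                stringency=stringency, mask_threshold=thr,
                ppv=ppv, sensitivity=sens, n_supported=n_sup,
                n_interactions=n_int, n_predicted=n_pred,
                n_excluded_no_pwm=n_excl))
    return pd.DataFrame([vars(r) for r in rows])


def motif_load_strata(interactions: set[tuple[str, str]],
                      hits: list[MotifHit],
                      count_bins=(1, 2, 3, 5, 10),
                      score_bins=None) -> pd.DataFrame:
    """Sensitivity stratified by motif load (hit count, best hit score).

    Pairs are binned by the number of hits of the TF in the bait and by the
    best log-odds score among those hits; empty strata get NaN.
    """
    if not hits:
        return pd.DataFrame(
            columns=["count_bin", "score_bin", "n_pairs", "n_detected",
                     "sensitivity"])
    frame = pd.DataFrame(
        {"pair": [(h.element_id, h.tf_id) for h in hits],
         "score": [h.score for h in hits]})
    per_pair = frame.groupby("pair")["score"].agg(["count", "max"])
    if score_bins is None:
        lo, hi = per_pair["max"].min(), per_pair["max"].max()
        score_bins = np.linspace(lo, np.nextafter(hi, np.inf), 4)
    count_idx = np.digitize(per_pair["count"], count_bins, right=False)
    score_idx = np.digitize(per_pair["max"], score_bins, right=False)
    per_pair = per_pair.assign(count_bin=count_idx, score_bin=score_idx,
                               detected=[p in interactions for p in per_pair.index])
    out = (per_pair.groupby(["count_bin", "score_bin"])
           .agg(n_pairs=("detected", "size"), n_detected=("detected", "sum"))
           .reset_index())
    out["sensitivity"] = out["n_detected"] / out["n_pairs"]
    return out
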