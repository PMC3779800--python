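"""Microfluidic DNA-occupancy landscapes and peak calling.

Per-fragment bound-DNA fluorescence (optionally normalized by the amount of
surface-immobilized protein in the same unit cell) is averaged per 12-bp bin
over the fragments containing that bin, interpolated to single-base
resolution with a cubic spline through the bin mid positions, and classified
into specific (SBP) and non-specific (NSBP) binding positions by 1-D 2-means
clustering.  The NSBP cluster center is the bait-specific mean background
signal (MBS); per-position enrichment E = signal/MBS, SBPs with E < 2 are
demoted, and the surviving consecutive SBP runs are the specific binding
regions (SBRs, i.e. peaks).  A peak is called reproducible when its maximum
falls inside a peak of the other replicate and vice versa.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, PchipInterpolator, interp1d

from .tiling import FragmentLibrary, bins_for_element, fragments_covering_bin

logger = logging.getLogger(__name__)

DEFAULT_MIN_ENRICHMENT = 2.0
DEFAULT_RESTARTS = 1000
DEFAULT_SEED = 17

INTENSITY_COLUMNS = ["element_id", "fragment_index", "replicate_id",
                     "dna_signal", "protein_signal"]


@dataclass
class OccupancyLandscape:
    element_id: str
    tf_id: str
    replicate_id: str
    bin_mids: np.ndarray          # representative position of each bin
    bin_signal: np.ndarray        # per-bin averaged signal S
    positions: np.ndarray | None = None   # integer grid between outer mids
    signal: np.ndarray | None = None      # interpolated per-position value


@dataclass
class LandscapeClassification:
    labels: np.ndarray            # boolean, True = SBP
    mbs: float                    # NSBP cluster center (mean background signal)
    sbp_center: float


@dataclass
class Sbr:
    """A specific binding region: a maximal run of consecutive SBPs with
    enrichment >= the threshold."""
    start: int                    # half-open positions
    end: int
    max_position: int
    max_enrichment: float
    reproducible: bool = False

    def __contains__(self, position: int) -> bool:
        return self.start <= position < self.end


# ---------------------------------------------------------------------------
# Binning

def read_intensities(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(INTENSITY_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"intensity table missing columns {sorted(missing)}")
    return df


def bin_signals(intensities: pd.DataFrame, library: FragmentLibrary,
                element_id: str, tf_id: str, replicate_id,
                normalize_by_protein: bool = True) -> OccupancyLandscape:
    """Average fragment signals into per-bin landscape values.

    Each bin's signal S is the arithmetic mean over the fragments containing
    it of dna_signal (divided by protein_signal when normalizing).  Bins with
    no measured covering fragment are dropped with a warning.
    """
    sub = intensities[
        (intensities["element_id"] == element_id)
        & (intensities["replicate_id"] == replicate_id)]
    if sub.duplicated("fragment_index").any():
        dup = sub[sub.duplicated("fragment_index")]["fragment_index"].tolist()
        raise ValueError(f"duplicate fragment/replicate records: {dup}")
    if (sub["dna_signal"] < 0).any():
        raise ValueError("negative dna_signal")
    if normalize_by_protein and (sub["protein_signal"] <= 0).any():
        raise ValueError("protein_signal must be positive for normalization")

    per_frag = dict(zip(
        sub["fragment_index"],
        sub["dna_signal"] / sub["protein_signal"] if normalize_by_protein
        else sub["dna_signal"]))

    mids, values = [], []
    for bin_start, mid in bins_for_element(library):
        covering = [per_frag[f.index]
                    for f in fragments_covering_bin(library, bin_start)
                    if f.index in per_frag]
        if not covering:
            warnings.warn(
                f"bin at {bin_start} of {element_id} has no measured "
                "covering fragment; dropped")
            continue
        mids.append(mid)
        values.append(float(np.mean(covering)))
    return OccupancyLandscape(element_id, tf_id, str(replicate_id),
                              np.asarray(mids, float),
                              np.asarray(values, float))


# ---------------------------------------------------------------------------
# Interpolation

def interpolate_landscape(landscape: OccupancyLandscape,
                          kind: str = "natural") -> OccupancyLandscape:
    """Fill per-position signal by cubic interpolation through the bin mids.

    ``kind`` selects the spline flavor: "natural" cubic (default) or "pchip"
    (monotone shape-preserving, immune to overshoot).  With fewer than four
    bins a linear interpolant is used instead, with a warning.  Values are
    only produced between the outermost mids (no extrapolation).
    """
    x, y = landscape.bin_mids, landscape.bin_signal
    if np.any(np.diff(x) <= 0):
        raise ValueError("bin mid positions must be strictly increasing")
    if len(x) < 4:
        warnings.warn("fewer than 4 bins: falling back to linear interpolation")
        f = interp1d(x, y)
    elif kind == "natural":
        f = CubicSpline(x, y, bc_type="natural")
    elif kind == "pchip":
        f = PchipInterpolator(x, y)
    else:
        raise ValueError(f"unknown interpolation kind {kind!r}")
    positions = np.arange(int(np.ceil(x[0])), int(np.floor(x[-1])) + 1)
    landscape.positions = positions
    landscape.signal = np.asarray(f(positions), float)
    return landscape


# ---------------------------------------------------------------------------
# SBP/NSBP classification (1-D 2-means)

def _kmeans_1d_two(values: np.ndarray, restarts: int, seed: int
                   ) -> tuple[float, float]:
    """2-means of 1-D data by Lloyd iteration, vectorized across restarts.

    Each restart initializes the two centers at a random pair of data points;
    assignment in 1-D is a threshold at the center midpoint, so the update
    reduces to prefix sums over the sorted data.  Returns the (lower, upper)
    centers of the lowest-SSE restart.
    """
    rng = np.random.default_rng(seed)
    v = np.sort(np.asarray(values, float))
    n = len(v)
    csum = np.concatenate([[0.0], np.cumsum(v)])
    csum2 = np.concatenate([[0.0], np.cumsum(v * v)])

    idx = rng.integers(0, n, size=(restarts, 2))
    centers = np.sort(v[idx], axis=1)
    # degenerate equal-pair draws: nudge the upper center to the data max
    same = centers[:, 0] == centers[:, 1]
    centers[same, 1] = v[-1]
    centers[same, 0] = v[0]

    m = np.zeros(restarts, dtype=int)
    for _ in range(200):
        thr = centers.mean(axis=1)
        m_new = np.clip(np.searchsorted(v, thr, side="right"), 1, n - 1)
        if np.array_equal(m_new, m):
            break
        m = m_new
        lo = csum[m] / m
        hi = (csum[n] - csum[m]) / (n - m)
        centers = np.stack([lo, hi], axis=1)

    lo, hi = centers[:, 0], centers[:, 1]
    sse = (csum2[m] - 2 * lo * csum[m] + m * lo**2) \
        + ((csum2[n] - csum2[m]) - 2 * hi * (csum[n] - csum[m]) + (n - m) * hi**2)
    best = int(np.argmin(sse))
    return float(centers[best, 0]), float(centers[best, 1])


def classify_positions(landscape: OccupancyLandscape,
                       restarts: int = DEFAULT_RESTARTS,
                       seed: int = DEFAULT_SEED,
                       use_bins: bool = False) -> LandscapeClassification:
    """Split per-position signal into NSBP (lower) and SBP (upper) classes.

    The lower cluster center is the mean background signal (MBS).  A flat
    landscape (all values identical) is entirely background.  With
    ``use_bins`` the clustering runs on bin-level S values instead of the
    interpolated per-position signal (positions are then labeled by their
    value against the same cut).
    """
    values = landscape.bin_signal if use_bins else landscape.signal
    if values is None:
        raise ValueError("landscape must be interpolated first")
    signal = landscape.signal if landscape.signal is not None else values
    if np.all(values == values[0]):
        return LandscapeClassification(
            labels=np.zeros(len(signal), dtype=bool),
            mbs=float(values[0]), sbp_center=float(values[0]))
    mbs, sbp_center = _kmeans_1d_two(values, restarts, seed)
    cut = (mbs + sbp_center) / 2
    return LandscapeClassification(labels=signal > cut, mbs=mbs,
                                   sbp_center=sbp_center)


# ---------------------------------------------------------------------------
# Peak calling

def call_peaks(landscape: OccupancyLandscape,
               classification: LandscapeClassification,
               min_enrichment: float = DEFAULT_MIN_ENRICHMENT) -> list[Sbr]:
    """Group consecutive enriched SBPs into specific binding regions.

    Per-position enrichment E = signal / MBS; SBP positions with E below
    ``min_enrichment`` are demoted to background.  Each maximal run of
    surviving consecutive SBPs becomes one SBR whose maximum is its
    largest-E position (leftmost on ties).
    """
    if classification.mbs <= 0:
        raise ValueError("mean background signal must be positive")
    positions = landscape.positions
    signal = landscape.signal
    enrichment = signal / classification.mbs
    keep = classification.labels & (enrichment >= min_enrichment)

    peaks: list[Sbr] = []
    i, n = 0, len(keep)
    while i < n:
        if not keep[i]:
            i += 1
            continue
        j = i
        while j < n and keep[j] and (j == i or positions[j] == positions[j - 1] + 1):
            j += 1
        run = slice(i, j)
        k = i + int(np.argmax(enrichment[run]))
        peaks.append(Sbr(start=int(positions[i]), end=int(positions[j - 1]) + 1,
                         max_position=int(positions[k]),
                         max_enrichment=float(enrichment[k])))
        i = j
    return peaks


def reproducible_peaks(peaks_rep1: list[Sbr], peaks_rep2: list[Sbr],
                       mode: str = "mutual-max") -> tuple[list[Sbr], list[Sbr]]:
    """Flag cross-replicate reproducibility.

    "mutual-max" (default): a rep-1 peak is reproducible iff its maximum lies
    inside some rep-2 peak whose own maximum lies inside some rep-1 peak
    (and symmetrically).  "interval" relaxes this to plain interval overlap
    between the two peak sets.
    """
    def interval_overlap(a: Sbr, b: Sbr) -> bool:
        return a.start < b.end and b.start < a.end

    for p in peaks_rep1 + peaks_rep2:
        p.reproducible = False
    if mode == "interval":
        for a in peaks_rep1:
            a.reproducible = any(interval_overlap(a, b) for b in peaks_rep2)
        for b in peaks_rep2:
            b.reproducible = any(interval_overlap(b, a) for a in peaks_rep1)
        return peaks_rep1, peaks_rep2
    if mode != "mutual-max":
        raise ValueError(f"unknown reproducibility mode {mode!r}")
    for a in peaks_rep1:
        for b in peaks_rep2:
            if a.max_position in b and any(b.max_position in a2 for a2 in peaks_rep1):
                a.reproducible = True
    for b in peaks_rep2:
        for a in peaks_rep1:
            if b.max_position in a and any(a.max_position in b2 for b2 in peaks_rep2):
                b.reproducible = True
    return peaks_rep1, peaks_rep2


def normalize_landscape(landscape: OccupancyLandscape) -> OccupancyLandscape:
    """Scale the landscape to a maximum of 1 (visualization/export only;
    classification always runs on unscaled signal)."""
    if landscape.signal is None:
        raise ValueError("landscape must be interpolated first")
    peak = float(np.max(landscape.signal))
    if peak <= 0:
        raise ValueError("maximal signal must be positive")
    out = OccupancyLandscape(
        landscape.element_id, landscape.tf_id, landscape.replicate_id,
        landscape.bin_mids.copy(), landscape.bin_signal / peak,
        None if landscape.positions is None else landscape.positions.copy(),
        landscape.signal / peak)
    return out


# ---------------------------------------------------------------------------
# Export

def landscape_frame(landscape: OccupancyLandscape,
                    classification: LandscapeClassification) -> pd.DataFrame:
    return pd.DataFrame({
        "position": landscape.positions,
        "signal": landscape.signal,
        "label": np.where(classification.labels, "SBP", "NSBP"),
        "enrichment": landscape.signal / classification.mbs})


def peaks_to_bed(peaks: list[Sbr], element_id: str, tf_id: str) -> pd.DataFrame:
    """BED6+ style table: score column carries the peak's max enrichment."""
    return pd.DataFrame({
        "chrom": element_id,
        "start": [p.start for p in peaks],
        "end": [p.end for p in peaks],
        "name": [f"{tf_id}_sbr{i}" for i in range(len(peaks))],
        "score": [p.max_enrichment for p in peaks],
        "strand": ".",
        "max_position": [p.max_position for p in peaks],
        "reproducible": [p.reproducible for p in peaks]})
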