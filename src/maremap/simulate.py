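"""Synthetic inputs with the statistical structure the analyses assume.

Every generator is a pure function of its parameters and a seed, so whole
pipeline runs are reproducible byte for byte.  The default occupancy
configuration emulates the benchmark experiment of the method: a 998-bp
element carrying two planted binding sites (at 25% and 65% of its length,
width 12 bp, 4-fold enrichment over baseline), measured in two replicates
with ~10% multiplicative log-normal noise — the regime in which the peak
caller is expected to recover both sites reproducibly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .tiling import FragmentLibrary, RegulatoryElement, design_fragments
from .motifs import BASES, Pwm, MotifHit

REPLICATE_SEED_STRIDE = 1000   # replicate r draws from seed + 1000*r


@dataclass
class PlantedSite:
    center: int            # element coordinate
    width: int = 12
    enrichment: float = 4.0

    @property
    def interval(self) -> tuple[int, int]:
        half = self.width // 2
        return (self.center - half, self.center - half + self.width)


@dataclass
class SyntheticSpec:
    """Parameters of the default synthetic study conditions."""

    seed: int = 0
    element_length: int = 998
    gc: float = 0.5
    planted_sites: list[PlantedSite] | None = None   # None -> two-site default
    baseline: float = 100.0
    noise_cv: float = 0.10
    protein_level: float = 1000.0
    protein_cv: float = 0.05
    replicates: int = 2
    # plate parameters
    n_tfs: int = 60
    n_controls: int = 4
    bg_mean: float = 25.0
    bg_sd: float = 2.0
    positive_fraction: float = 0.1
    positive_multiplier: float = 2.0
    # nucleosome track
    nucleosome_scale: float = 50.0

    def sites(self) -> list[PlantedSite]:
        if self.planted_sites is not None:
            return self.planted_sites
        L = self.element_length
        return [PlantedSite(center=int(0.25 * L)),
                PlantedSite(center=int(0.65 * L))]


# ---------------------------------------------------------------------------
# Sequence

def gen_element(length: int, gc: float = 0.5, seed: int = 0,
                element_id: str = "synthetic", flank: int = 24
                ) -> RegulatoryElement:
    """Random i.i.d. element (plus flanks) at the given GC content."""
    if not (0 < gc < 1):
        raise ValueError("gc must lie in (0, 1)")
    if length < 36:
        raise ValueError("element must be at least 36 bp")
    rng = np.random.default_rng(seed)
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    draw = lambda n: "".join(rng.choice(list(BASES), size=n, p=p))
    return RegulatoryElement(id=element_id, sequence=draw(length),
                             flank5=draw(flank), flank3=draw(flank))


# ---------------------------------------------------------------------------
# Occupancy (fragment intensity) tables

def _overlap_fraction(frag_start: int, frag_end: int,
                      site: PlantedSite) -> float:
    lo, hi = site.interval
    ov = max(0, min(frag_end, hi) - max(frag_start, lo))
    return ov / site.width


def gen_occupancy(spec: SyntheticSpec, library: FragmentLibrary,
                  tf_id: str = "TF") -> pd.DataFrame:
    """Per-fragment intensity table for all replicates.

    Expected fragment signal is baseline x (1 + sum over sites of
    (enrichment - 1) x overlap fraction), perturbed by multiplicative
    log-normal noise with sigma = log(1 + noise_cv); protein levels are
    log-normal around a constant.
    """
    lo, hi = library.span
    for site in spec.sites():
        s_lo, s_hi = site.interval
        if s_lo < lo or s_hi > hi:
            raise ValueError(f"planted site {site} outside covered span")
        if site.enrichment < 1:
            raise ValueError("enrichment must be >= 1")

    rows = []
    for r in range(spec.replicates):
        rng = np.random.default_rng(spec.seed + REPLICATE_SEED_STRIDE * r)
        for frag in library.fragments:
            mean = spec.baseline * (
                1 + sum((s.enrichment - 1) * _overlap_fraction(frag.start, frag.end, s)
                        for s in spec.sites()))
            noise = np.exp(rng.normal(0.0, np.log1p(spec.noise_cv))) \
                if spec.noise_cv > 0 else 1.0
            protein = spec.protein_level * np.exp(
                rng.normal(0.0, np.log1p(spec.protein_cv))) \
                if spec.protein_cv > 0 else spec.protein_level
            rows.append({"element_id": library.element_id,
                         "fragment_index": frag.index,
                         "replicate_id": f"rep{r + 1}",
                         "dna_signal": mean * noise * protein / spec.protein_level,
                         "protein_signal": protein})
    return pd.DataFrame(rows)


def default_two_site_run(seed: int = 0, noise_cv: float = 0.10,
                         enrichment: float = 4.0
                         ) -> tuple[SyntheticSpec, RegulatoryElement,
                                    FragmentLibrary, pd.DataFrame]:
    """The benchmark configuration: 998-bp element, two planted sites."""
    spec = SyntheticSpec(seed=seed, noise_cv=noise_cv)
    spec.planted_sites = [PlantedSite(center=int(0.25 * spec.element_length),
                                      enrichment=enrichment),
                          PlantedSite(center=int(0.65 * spec.element_length),
                                      enrichment=enrichment)]
    element = gen_element(spec.element_length, spec.gc, seed=spec.seed,
                          element_id="synthetic_element")
    library = design_fragments(element)
    intensities = gen_occupancy(spec, library)
    return spec, element, library, intensities


# ---------------------------------------------------------------------------
# Y1H plates

def gen_plate(spec: SyntheticSpec, bait_id: str = "bait",
              method: str = "transformation", screen_id: str = "1"
              ) -> tuple[pd.DataFrame, set[str]]:
    """Quadrant-score plate with planted positives; returns (wells, truth).

    Control and negative wells draw quadrant scores from a truncated
    normal background; the designated positive TFs' scores are multiplied
    by ``positive_multiplier``.
    """
    if spec.n_controls < 1:
        raise ValueError("need at least one control well")
    rng = np.random.default_rng(spec.seed)
    n_wells = spec.n_tfs + spec.n_controls
    tf_ids = [f"TF{i:03d}" for i in range(spec.n_tfs)] \
        + ["CONTROL"] * spec.n_controls
    n_pos = int(round(spec.positive_fraction * spec.n_tfs))
    positives = set(rng.choice(tf_ids[:spec.n_tfs], size=n_pos, replace=False)) \
        if n_pos else set()

    rows = []
    ncol = 12
    for i, tf in enumerate(tf_ids):
        q = np.clip(rng.normal(spec.bg_mean, spec.bg_sd, size=4), 0, None)
        if tf in positives:
            q = q * spec.positive_multiplier
        rows.append({"bait_id": bait_id, "method": method,
                     "screen_id": screen_id, "row": i // ncol, "col": i % ncol,
                     "tf_id": tf, "q1": q[0], "q2": q[1], "q3": q[2],
                     "q4": q[3]})
    return pd.DataFrame(rows), positives


# ---------------------------------------------------------------------------
# PWMs and planted motif occurrences

def gen_pwm_and_sites(spec: SyntheticSpec, element: RegulatoryElement,
                      consensus: str = "TGACGTCA",
                      consensus_prob: float = 0.97,
                      n_sites: int = 2, tf_id: str = "TF"
                      ) -> tuple[Pwm, list[MotifHit], RegulatoryElement]:
    """PWM concentrated on a consensus, with occurrences written into the
    element at recorded (non-overlapping) positions and strands."""
    if not (5 <= len(consensus) <= 15):
        raise ValueError("consensus length must be 5-15")
    rng = np.random.default_rng(spec.seed)
    w = len(consensus)
    mat = np.full((w, 4), (1 - consensus_prob) / 3)
    for i, b in enumerate(consensus):
        mat[i, BASES.index(b)] = consensus_prob
    pwm = Pwm(tf_id, mat)

    seq = list(element.sequence)
    placed: list[tuple[int, str]] = []
    attempts = 0
    while len(placed) < n_sites:
        attempts += 1
        if attempts > 1000:
            raise ValueError("could not place non-overlapping sites")
        start = int(rng.integers(0, len(seq) - w + 1))
        if any(start < s + w and s < start + w for s, _ in placed):
            continue
        strand = "+" if rng.random() < 0.5 else "-"
        word = consensus if strand == "+" else _revcomp(consensus)
        seq[start:start + w] = list(word)
        placed.append((start, strand))

    mutated = RegulatoryElement(id=element.id, sequence="".join(seq),
                                flank5=element.flank5, flank3=element.flank3)
    truth = [MotifHit(tf_id=tf_id, element_id=element.id, start=s, end=s + w,
                      strand=st, score=float("nan"), pvalue=float("nan"))
             for s, st in sorted(placed)]
    return pwm, truth, mutated


def _revcomp(seq: str) -> str:
    return seq.translate(str.maketrans("ACGT", "TGCA"))[::-1]


# ---------------------------------------------------------------------------
# Nucleosome occupancy tracks

def gen_nucleosome_profile(length: int, scale: float = 50.0, seed: int = 0,
                           element_id: str = "synthetic"):
    """Smooth (0,1) occupancy track: logistic-squashed Gaussian-smoothed
    white noise with autocorrelation length ~ ``scale``."""
    from .benchmark import NucleosomeProfile

    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(seed)
    raw = gaussian_filter1d(rng.standard_normal(length + int(8 * scale)),
                            sigma=scale, mode="wrap")
    raw = raw[int(4 * scale):int(4 * scale) + length]
    sd = raw.std()
    z = raw / sd if sd > 0 else raw
    prob = 1.0 / (1.0 + np.exp(-2.0 * z))
    return NucleosomeProfile(element_id, prob)
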