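import numpy as np
import pandas as pd
import pytest

import maremap as m
from maremap import landscape as lsc
from maremap.landscape import (OccupancyLandscape, Sbr, call_peaks,
                               classify_positions, interpolate_landscape,
                               normalize_landscape, reproducible_peaks)

from conftest import kmeans_oracle, run_landscape


def small_library():
    el = m.gen_element(60, seed=2, element_id="small")
    return m.design_fragments(el)


def intensity_frame(library, values, replicate="rep1", protein=1.0):
    return pd.DataFrame(
        [{"element_id": library.element_id, "fragment_index": f.index,
          "replicate_id": replicate, "dna_signal": values[f.index],
          "protein_signal": protein} for f in library.fragments])


def landscape_from_values(positions, signal):
    land = OccupancyLandscape("e", "TF", "rep1",
                              np.asarray(positions, float),
                              np.asarray(signal, float))
    land.positions = np.asarray(positions)
    land.signal = np.asarray(signal, float)
    return land


# ---------------------------------------------------------------------------
# Binning

def test_bin_signal_is_mean_of_covering_fragments():
    lib = small_library()       # 7 fragments, 9 bins
    values = np.arange(1.0, 8.0)
    land = lsc.bin_signals(intensity_frame(lib, values), lib,
                           lib.element_id, "TF", "rep1")
    # interior bin [0,12) is contained in fragments 0,1,2 -> mean of 1,2,3
    idx = list(land.bin_mids).index(6.0)
    assert land.bin_signal[idx] == pytest.approx(2.0)
    # second bin [-12,0) in fragments 0,1 -> mean of 1,2
    idx = list(land.bin_mids).index(-6.0)
    assert land.bin_signal[idx] == pytest.approx(1.5)


def test_constant_fragments_give_constant_bins():
    lib = small_library()
    land = lsc.bin_signals(intensity_frame(lib, [7.0] * len(lib)), lib,
                           lib.element_id, "TF", "rep1")
    assert np.allclose(land.bin_signal, 7.0)


def test_protein_normalization_divides_per_fragment():
    lib = small_library()
    df = intensity_frame(lib, [10.0] * len(lib), protein=4.0)
    land = lsc.bin_signals(df, lib, lib.element_id, "TF", "rep1")
    assert np.allclose(land.bin_signal, 2.5)
    raw = lsc.bin_signals(df, lib, lib.element_id, "TF", "rep1",
                          normalize_by_protein=False)
    assert np.allclose(raw.bin_signal, 10.0)


def test_bin_signals_agrees_with_per_position_recount(two_site_run):
    """Bin averaging matches a brute-force recount of covering fragments."""
    _, _, lib, intens = two_site_run
    land = lsc.bin_signals(intens, lib, lib.element_id, "TF", "rep1")
    sub = intens[intens["replicate_id"] == "rep1"]
    per_frag = dict(zip(sub["fragment_index"],
                        sub["dna_signal"] / sub["protein_signal"]))
    lo, hi = lib.span
    for (bin_start, mid), s in zip(
            m.bins_for_element(lib), land.bin_signal):
        bin_end = min(bin_start + lib.params.step, hi)
        covering = [per_frag[f.index] for f in lib.fragments
                    if f.start <= bin_start and f.end >= bin_end]
        assert s == pytest.approx(np.mean(covering))


def test_duplicate_and_negative_records_rejected():
    lib = small_library()
    df = intensity_frame(lib, [1.0] * len(lib))
    with pytest.raises(ValueError, match="duplicate"):
        lsc.bin_signals(pd.concat([df, df.iloc[:1]]), lib,
                        lib.element_id, "TF", "rep1")
    df.loc[0, "dna_signal"] = -1.0
    with pytest.raises(ValueError, match="negative"):
        lsc.bin_signals(df, lib, lib.element_id, "TF", "rep1")


# ---------------------------------------------------------------------------
# Interpolation

def test_spline_reproduces_knots_and_lines():
    mids = np.array([0.0, 12, 24, 36, 48])
    land = OccupancyLandscape("e", "TF", "r", mids, 2.0 * mids + 1)
    interpolate_landscape(land)
    assert np.allclose(land.signal, 2.0 * land.positions + 1)  # collinear
    land2 = OccupancyLandscape("e", "TF", "r", mids, np.array([1, 5, 2, 8, 3.0]))
    interpolate_landscape(land2)
    for mid, s in zip(mids, [1, 5, 2, 8, 3.0]):
        assert land2.signal[list(land2.positions).index(int(mid))] == pytest.approx(s)
    land3 = OccupancyLandscape("e", "TF", "r", mids, np.full(5, 4.2))
    interpolate_landscape(land3)
    assert np.allclose(land3.signal, 4.2)


def test_no_extrapolation_beyond_outer_mids():
    mids = np.array([-18.0, -6, 6, 18])
    land = OccupancyLandscape("e", "TF", "r", mids, np.array([1, 2, 3, 4.0]))
    interpolate_landscape(land)
    assert land.positions[0] == -18 and land.positions[-1] == 18


def test_few_bins_fall_back_to_linear():
    land = OccupancyLandscape("e", "TF", "r", np.array([0.0, 10, 20]),
                              np.array([0.0, 10, 20]))
    with pytest.warns(UserWarning, match="linear"):
        interpolate_landscape(land)
    assert np.allclose(land.signal, land.positions)


def test_non_monotone_mids_rejected():
    land = OccupancyLandscape("e", "TF", "r", np.array([0.0, 20, 10, 30]),
                              np.zeros(4))
    with pytest.raises(ValueError, match="increasing"):
        interpolate_landscape(land)


# ---------------------------------------------------------------------------
# Classification

def test_two_class_split_on_separated_data_matches_oracle():
    values = np.concatenate([np.full(50, 1.0), np.full(10, 10.0)])
    land = landscape_from_values(np.arange(60), values)
    cls = classify_positions(land, seed=1)
    assert cls.mbs == pytest.approx(1.0)
    assert cls.sbp_center == pytest.approx(10.0)
    assert np.array_equal(cls.labels, values > 5)
    lo, hi = kmeans_oracle(values)
    assert (cls.mbs, cls.sbp_center) == pytest.approx((lo, hi))


@pytest.mark.parametrize("seed", range(5))
def test_kmeans_matches_exhaustive_partition_oracle(seed):
    rng = np.random.default_rng(seed)
    values = np.concatenate([rng.normal(1, 0.15, 120), rng.normal(4, 0.3, 30)])
    land = landscape_from_values(np.arange(len(values)), values)
    cls = classify_positions(land, seed=seed)
    lo, hi = kmeans_oracle(values)
    assert cls.mbs == pytest.approx(lo, rel=1e-9)
    assert cls.sbp_center == pytest.approx(hi, rel=1e-9)


def test_flat_landscape_is_all_background():
    land = landscape_from_values(np.arange(20), np.full(20, 3.3))
    cls = classify_positions(land)
    assert cls.mbs == 3.3 and not cls.labels.any()


def test_classification_scale_equivariance():
    rng = np.random.default_rng(7)
    values = np.concatenate([rng.normal(1, 0.1, 80), rng.normal(5, 0.2, 20)])
    land1 = landscape_from_values(np.arange(100), values)
    land2 = landscape_from_values(np.arange(100), values * 13.7)
    c1 = classify_positions(land1, seed=3)
    c2 = classify_positions(land2, seed=3)
    assert np.array_equal(c1.labels, c2.labels)
    assert c2.mbs == pytest.approx(13.7 * c1.mbs)


# ---------------------------------------------------------------------------
# Peak calling

def test_subthreshold_sbp_is_demoted():
    land = landscape_from_values([0, 1, 2], [1.0, 1.9, 1.0])
    cls = lsc.LandscapeClassification(
        labels=np.array([False, True, False]), mbs=1.0, sbp_center=1.9)
    assert call_peaks(land, cls) == []


def test_sbr_maximum_by_brute_force_scan():
    positions = np.arange(100, 131)
    enrichment = 2.5 + 2.5 * np.exp(-((positions - 118) / 8.0) ** 2)
    land = landscape_from_values(positions, enrichment)  # mbs 1 below
    cls = lsc.LandscapeClassification(
        labels=np.ones(len(positions), bool), mbs=1.0, sbp_center=4.0)
    peaks = call_peaks(land, cls)
    assert len(peaks) == 1
    p = peaks[0]
    assert (p.start, p.end) == (100, 131)
    assert p.max_position == 118 == positions[np.argmax(enrichment)]
    assert p.max_enrichment == pytest.approx(5.0)


def test_leftmost_tie_break_and_no_sbp_cases():
    land = landscape_from_values([0, 1, 2, 3], [4.0, 4.0, 4.0, 4.0])
    cls = lsc.LandscapeClassification(
        labels=np.ones(4, bool), mbs=1.0, sbp_center=4.0)
    peaks = call_peaks(land, cls)
    assert peaks[0].max_position == 0     # leftmost on exact ties
    cls_none = lsc.LandscapeClassification(
        labels=np.zeros(4, bool), mbs=1.0, sbp_center=4.0)
    assert call_peaks(land, cls_none) == []


def test_corrupt_mbs_rejected():
    land = landscape_from_values([0, 1], [1.0, 2.0])
    cls = lsc.LandscapeClassification(np.ones(2, bool), mbs=0.0, sbp_center=2.0)
    with pytest.raises(ValueError):
        call_peaks(land, cls)


# ---------------------------------------------------------------------------
# Reproducibility

def test_mutual_max_rule():
    a = [Sbr(110, 131, 120, 5.0)]
    b = [Sbr(100, 140, 125, 4.0)]
    reproducible_peaks(a, b)
    assert a[0].reproducible and b[0].reproducible


def test_max_outside_other_replicate_not_reproducible():
    a = [Sbr(110, 131, 120, 5.0)]
    b = [Sbr(200, 240, 220, 4.0)]
    reproducible_peaks(a, b)
    assert not a[0].reproducible and not b[0].reproducible
    a2 = [Sbr(110, 131, 120, 5.0)]
    reproducible_peaks(a2, [])
    assert not a2[0].reproducible


def test_interval_mode_is_looser():
    # overlapping intervals whose maxima fall outside each other
    a = [Sbr(100, 120, 101, 3.0)]
    b = [Sbr(118, 140, 139, 3.0)]
    reproducible_peaks(a, b, mode="mutual-max")
    assert not a[0].reproducible
    reproducible_peaks(a, b, mode="interval")
    assert a[0].reproducible and b[0].reproducible


# ---------------------------------------------------------------------------
# Normalization and the end-to-end scale invariance

def test_normalize_landscape():
    land = landscape_from_values([0, 1, 2], [2.0, 4.0, 8.0])
    out = normalize_landscape(land)
    assert np.allclose(out.signal, [0.25, 0.5, 1.0])
    again = normalize_landscape(out)
    assert np.allclose(again.signal, out.signal)      # idempotent
    assert np.argmax(out.signal) == np.argmax(land.signal)
    flat = landscape_from_values([0], [0.0])
    with pytest.raises(ValueError):
        normalize_landscape(flat)


def test_full_pipeline_scale_invariance(two_site_run):
    """Multiplying all fragment intensities by c > 0 leaves labels, E
    values, SBR intervals and reproducibility unchanged."""
    _, _, lib, intens = two_site_run
    scaled = intens.assign(dna_signal=intens["dna_signal"] * 37.5)
    peaks = {}
    for df in (intens, scaled):
        per_rep = []
        for rep in ("rep1", "rep2"):
            land, cls, p = run_landscape(df, lib, rep, seed=9)
            per_rep.append(p)
        reproducible_peaks(*per_rep)
        peaks[id(df)] = per_rep
    for p1, p2 in zip(*peaks.values()):
        assert [(x.start, x.end, x.max_position, x.reproducible) for x in p1] \
            == [(x.start, x.end, x.max_position, x.reproducible) for x in p2]
        assert np.allclose([x.max_enrichment for x in p1],
                           [x.max_enrichment for x in p2])
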