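import itertools

import numpy as np
import pytest

from maremap.motifs import (Pwm, ScoreDistribution, annotate_peaks,
                            hits_to_frame, read_meme_minimal, read_pwm_tsv,
                            scan)
from maremap.landscape import Sbr
from maremap.tiling import RegulatoryElement


def random_pwm(length, seed=0, pseudocount=1e-3):
    rng = np.random.default_rng(seed)
    return Pwm("X", rng.dirichlet(np.ones(4), size=length),
               pseudocount=pseudocount)


def consensus_pwm(word, pseudocount=1e-9):
    mat = np.zeros((len(word), 4))
    for i, b in enumerate(word):
        mat[i, "ACGT".index(b)] = 1.0
    return Pwm("cons", mat, pseudocount=pseudocount)


def enumeration_pvalues(dist, background=0.25):
    """Brute-force distribution over all k-mers, on the same integer
    discretization grid."""
    w = dist.int_scores.shape[0]
    table = {}
    for word in itertools.product(range(4), repeat=w):
        s = int(sum(dist.int_scores[i, b] for i, b in enumerate(word)))
        table[s] = table.get(s, 0.0) + background ** w
    return table


def test_length1_uniform_distribution():
    pwm = Pwm("m1", np.array([[0.25, 0.25, 0.25, 0.25]]))
    dist = ScoreDistribution(pwm)
    support = list(dist.items())
    assert len(support) == 1          # all four bases score identically
    assert support[0][1] == pytest.approx(1.0)
    pwm2 = Pwm("m2", np.array([[0.7, 0.1, 0.1, 0.1]]))
    support2 = dict(ScoreDistribution(pwm2).items())
    assert sum(support2.values()) == pytest.approx(1.0)
    assert len(support2) == 2         # consensus base vs. the three others
    assert min(support2.values()) == pytest.approx(0.25)


@pytest.mark.parametrize("length,seed", [(4, 1), (6, 2), (8, 3)])
def test_dp_distribution_matches_exhaustive_enumeration(length, seed):
    dist = ScoreDistribution(random_pwm(length, seed))
    table = enumeration_pvalues(dist)
    assert sum(table.values()) == pytest.approx(1.0)
    for s in table:
        expected = sum(p for t, p in table.items() if t >= s)
        assert dist.pvalue_of_int(s) == pytest.approx(expected, abs=1e-12)


def test_max_score_pvalue_is_consensus_word_probability():
    pwm = random_pwm(5, seed=9)
    dist = ScoreDistribution(pwm)
    best = int(dist.int_scores.max(axis=1).sum())
    assert dist.pvalue_of_int(best) == pytest.approx(0.25 ** 5, rel=1e-9)


def test_consensus_only_hit_at_lenient_but_not_default_stringency():
    """A 5-mer single-word motif has analytic p-value 4^-5 ~ 9.8e-4: found
    at P<1e-3 but absent at P<1e-4."""
    pwm = consensus_pwm("ACGTC")
    el = RegulatoryElement("e", "TTTTTACGTCTTTTT")
    hits = scan(el, pwm, p_threshold=1e-3)
    assert [(h.start, h.end, h.strand) for h in hits] == [(5, 10, "+")]
    assert hits[0].pvalue == pytest.approx(4.0 ** -5)
    assert scan(el, pwm, p_threshold=1e-4) == []


def test_strand_symmetry_on_reverse_complemented_sequence():
    rng = np.random.default_rng(4)
    seq = "".join(rng.choice(list("ACGT"), size=300))
    el = RegulatoryElement("e", seq)
    rc = RegulatoryElement("e", seq.translate(str.maketrans("ACGT", "TGCA"))[::-1])
    pwm = random_pwm(7, seed=5)
    fwd = scan(el, pwm, p_threshold=1e-2)
    rev = scan(rc, pwm, p_threshold=1e-2)
    assert len(fwd) == len(rev)
    L = len(seq)
    assert {(L - h.end, L - h.start) for h in fwd} \
        == {(h.start, h.end) for h in rev}


def test_threshold_nesting():
    el = RegulatoryElement("e", "".join(
        np.random.default_rng(6).choice(list("ACGT"), size=500)))
    pwm = random_pwm(6, seed=6)
    sets = [{(h.start, h.strand) for h in scan(el, pwm, p_threshold=p)}
            for p in (1e-5, 1e-4, 1e-3)]
    assert sets[0] <= sets[1] <= sets[2]


def test_scan_threshold_validation():
    el = RegulatoryElement("e", "ACGTACGT")
    with pytest.raises(ValueError):
        scan(el, random_pwm(4), p_threshold=0.0)
    with pytest.raises(ValueError):
        scan(el, random_pwm(4), p_threshold=1.5)


def test_zero_background_rejected():
    pwm = random_pwm(3)
    pwm.background = np.array([0.0, 0.5, 0.25, 0.25])
    with pytest.raises(ValueError, match="background"):
        ScoreDistribution(pwm)


def test_annotate_peaks_interval_logic():
    hit = lambda s, e: type("H", (), {"start": s, "end": e})()
    peaks = [Sbr(100, 131, 118, 5.0)]
    assert annotate_peaks(peaks, [hit(115, 125)])[0]
    assert not annotate_peaks(peaks, [hit(200, 210)])[0]
    # a hit 5 bp outside the peak is rescued by slop 12
    outside = hit(131 + 5, 131 + 15)
    assert not annotate_peaks(peaks, [outside])[0]
    assert annotate_peaks(peaks, [outside], flank_slop=12)[0]


def test_meme_minimal_roundtrip(tmp_path):
    text = """MEME version 4

ALPHABET= ACGT

Background letter frequencies
A 0.3 C 0.2 G 0.2 T 0.3

MOTIF FOO
letter-probability matrix: alength= 4 w= 3
0.9 0.05 0.03 0.02
0.1 0.6 0.2 0.1
0.25 0.25 0.25 0.25
"""
    path = tmp_path / "m.meme"
    path.write_text(text)
    (pwm,) = read_meme_minimal(path)
    assert pwm.tf_id == "FOO" and len(pwm) == 3
    assert pwm.background == pytest.approx([0.3, 0.2, 0.2, 0.3])
    assert pwm.consensus == "AC" + pwm.consensus[2]


def test_pwm_tsv_reader(tmp_path):
    path = tmp_path / "p.tsv"
    path.write_text("A\tC\tG\tT\n0.7\t0.1\t0.1\t0.1\n0.1\t0.7\t0.1\t0.1\n")
    pwm = read_pwm_tsv(path, "BAR")
    assert pwm.consensus == "AC"


def test_invalid_matrices_rejected():
    with pytest.raises(ValueError):
        Pwm("bad", np.array([[0.5, 0.5, 0.5, 0.5]]))
    with pytest.raises(ValueError):
        Pwm("bad", np.array([[0.25, 0.25, 0.25]]))


from hypothesis import given, settings, strategies as st


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 10_000))
def test_hit_sets_nest_across_stringencies(seed):
    """Lowering the p-value threshold never adds hits."""
    rng = np.random.default_rng(seed)
    el = RegulatoryElement("e", "".join(rng.choice(list("ACGT"), size=120)))
    pwm = random_pwm(5, seed=seed)
    strict = {(h.start, h.strand) for h in scan(el, pwm, p_threshold=1e-4)}
    lenient = {(h.start, h.strand) for h in scan(el, pwm, p_threshold=1e-2)}
    assert strict <= lenient
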