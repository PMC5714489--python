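"""Annotator components against brute-force oracles and planted truth."""
import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heltrace.annotate import (
    AnnotatorConfig,
    FamilyRule,
    ScreenConfig,
    annotate_helitron,
    check_insertion_site,
    classify_family,
    coverage,
    detect_hairpin,
    detect_termini,
    find_orfs,
    scan_rep_motifs,
    screen_copies,
)
from heltrace.consensus import RepConsensus, default_rep_consensus
from heltrace.errors import AlphabetError, ConfigError, HeltraceError
from heltrace.records import SequenceRecord, pairs, revcomp
from heltrace.simulate import mutate_to_K

from .conftest import make_dna

DNA = st.text(alphabet="ACGT", min_size=1, max_size=120)


# ------------------------------------------------------------------ ORFs

def _orf_oracle(s: str, min_len: int):
    """Independent six-frame scan: first-ATG-after-stop to stop, both strands."""
    stops = {"TAA", "TAG", "TGA"}
    found = set()
    n = len(s)
    for strand, text in (("+", s), ("-", revcomp(s))):
        for frame in range(3):
            codons = [text[p : p + 3] for p in range(frame, len(text) - 2, 3)]
            start_codon = None
            for ci, codon in enumerate(codons):
                pos = frame + 3 * ci
                if codon in stops:
                    if start_codon is not None and pos + 3 - start_codon >= min_len:
                        a, b = start_codon, pos + 3
                        if strand == "-":
                            a, b = n - b, n - a
                        found.add((a, b, strand))
                    start_codon = None
                elif codon == "ATG" and start_codon is None:
                    start_codon = pos
    return found


def test_find_orfs_matches_bruteforce_on_random_sequence():
    s = make_dna(17, 10000)
    got = {(o.start, o.end, o.strand) for o in find_orfs(SequenceRecord("s", s), 300)}
    assert got == _orf_oracle(s, 300)


def test_find_orfs_planted_large_orf(default_helitron):
    rec, truth = default_helitron
    orf_truth = next(t for t in truth if t.feature_type == "orf")
    big = [o for o in find_orfs(rec, 4000)]
    assert len(big) == 1
    assert (big[0].start, big[0].end) == (orf_truth.start, orf_truth.end)


def test_find_orfs_all_stops_empty():
    assert find_orfs(SequenceRecord("s", "TAATAGTGA" * 30), 3) == []


def test_find_orfs_rejects_non_dna():
    with pytest.raises(AlphabetError, match="X"):
        find_orfs(SequenceRecord("s", "ATGXTAA"), 3)


# ------------------------------------------------------------------ Rep motifs

def test_scan_hxs_pattern_equals_class_enumeration():
    cons = RepConsensus(motifs=["hxs"])
    h, s_ = cons.class_sets["h"], cons.class_sets["s"]
    aas = "ACDEFGHIKLMNPQRSTVWY"
    for tri in itertools.product(aas, repeat=3):
        pep = "".join(tri)
        hits = scan_rep_motifs(SequenceRecord("p", pep), cons)
        expected = [(0, 0)] if (pep[0] in h and pep[2] in s_) else []
        assert hits == expected, pep


def test_scan_on_generated_orf_finds_exactly_three_in_order(default_helitron):
    from heltrace.records import translate

    rec, truth = default_helitron
    orf = next(t for t in truth if t.feature_type == "orf")
    prot = translate(rec.seq[orf.start : orf.end])
    hits = scan_rep_motifs(SequenceRecord("p", prot), default_rep_consensus())
    assert [m for m, _ in hits] == [0, 1, 2]
    assert hits[0][1] < hits[1][1] < hits[2][1]


def test_scan_empty_protein():
    assert scan_rep_motifs(SequenceRecord("p", ""), default_rep_consensus()) == []


def test_unknown_class_symbol_is_config_error():
    with pytest.raises(ConfigError):
        RepConsensus(motifs=["hzx"])


# ------------------------------------------------------------------ termini

def test_ctrr_expansions():
    for inst, ok in [("CTAA", True), ("CTAG", True), ("CTGA", True),
                     ("CTGG", True), ("CTCA", False), ("CTTT", False)]:
        seq = SequenceRecord("s", "TCGGGG" + inst)
        cands = detect_termini(seq, "TC", "CTRR")
        assert ((0, 10) in cands) is ok

    assert detect_termini(SequenceRecord("s", "TCAAAAAA"), "TC", "CTRR") == []


def test_termini_sorted_by_span_descending():
    seq = SequenceRecord("s", "TC" + "A" * 10 + "CTAA" + "A" * 10 + "CTGG")
    cands = detect_termini(seq, "TC", "CTRR")
    spans = [j - i for i, j in cands]
    assert spans == sorted(spans, reverse=True)


def test_planted_termini_found(default_helitron):
    rec, truth = default_helitron
    hel = next(t for t in truth if t.feature_type == "helitron")
    cands = detect_termini(rec, "TC", "CTRR")
    assert (hel.start, hel.end) in cands


# ------------------------------------------------------------------ hairpin

def _hairpin_oracle(s, window, min_stem, max_loop, max_mismatch):
    """Exhaustive enumeration over all (arm start, stem, loop) triples."""
    n = len(s)
    lo = max(0, n - window)
    best_key, best = None, None
    for ls in range(n):  # loop start
        for loop in range(1, max_loop + 1):
            le = ls + loop
            for stem in range(min_stem, n):
                i1, j2 = ls - stem, le + stem
                if i1 < 0 or j2 > n:
                    break
                arm_pairs = [pairs(s[ls - 1 - t], s[le + t]) for t in range(stem)]
                mism = arm_pairs.count(False)
                if mism > max_mismatch or not arm_pairs[-1]:
                    continue
                if le < lo or le + stem > n:
                    continue
                offset = n - (le + stem)
                key = (-(stem - mism), offset, mism, loop, ls)
                if best_key is None or key < best_key:
                    best_key, best = key, (stem, loop, offset, mism)
    return best


@pytest.mark.parametrize("seed", range(8))
def test_detect_hairpin_equals_exhaustive_oracle(seed):
    s = make_dna(seed + 100, 200)
    got = detect_hairpin(s, window_from_3prime=60, min_stem=4, max_loop=8,
                         max_mismatch=1)
    want = _hairpin_oracle(s, 60, 4, 8, 1)
    if want is None:
        assert got is None
    else:
        assert (got.stem, got.loop, got.offset_from_3prime, got.mismatches) == want


def test_planted_hairpin_recovered(default_helitron):
    rec, truth = default_helitron
    hel = next(t for t in truth if t.feature_type == "helitron")
    hp = detect_hairpin(rec.seq[: hel.end], window_from_3prime=40)
    assert (hp.stem, hp.loop, hp.offset_from_3prime) == (8, 4, 11)


def test_polyA_has_no_hairpin():
    assert detect_hairpin("A" * 100, window_from_3prime=50) is None


# ------------------------------------------------------------------ insertion site

def test_insertion_site_definition():
    assert check_insertion_site("GGA", "TCC") is True
    assert check_insertion_site("GGT", "TCC") is False
    assert check_insertion_site("GGA", "CTC") is False
    with pytest.raises(HeltraceError):
        check_insertion_site("", "T")


# ------------------------------------------------------------------ coverage

def test_coverage_values():
    assert abs(coverage(5294, 5667) - 93.4) <= 0.05
    assert coverage(100, 100) == 100.0
    assert abs(coverage(373, 5667) - 6.58) < 0.005
    with pytest.raises(HeltraceError):
        coverage(200, 100)


@given(st.integers(1, 1000), st.integers(1, 1000), st.integers(1, 50))
@settings(deadline=None, max_examples=50)
def test_coverage_scale_invariant(a, b, k):
    el, seg = min(a, b), max(a, b)
    assert coverage(k * el, k * seg) == pytest.approx(coverage(el, seg))


# ------------------------------------------------------------------ family rule

def _with_tail(tail, seed):
    return SequenceRecord("s", make_dna(seed, 40) + tail)


def test_family_boundary_is_inclusive_at_80_percent():
    base = make_dna(55, 30)
    a = _with_tail(base, 1)

    def mutated_tail(n_diff):
        tail = list(base)
        for i in range(n_diff):
            tail[i] = {"A": "C", "C": "A", "G": "T", "T": "G"}[tail[i]]
        return "".join(tail)

    assert classify_family(a, _with_tail(base, 2)) == "same_family"
    assert classify_family(a, _with_tail(mutated_tail(6), 2)) == "same_family"  # 24/30
    assert classify_family(a, _with_tail(mutated_tail(7), 2)) == "different_family"  # 23/30

    with pytest.raises(HeltraceError):
        classify_family(a, SequenceRecord("short", "ACGT"))


@given(st.integers(0, 2**31 - 1), st.integers(0, 2**31 - 1))
@settings(deadline=None, max_examples=30)
def test_family_symmetric_and_ignores_sequence_outside_window(sa, sb):
    tail_a, tail_b = make_dna(sa, 30), make_dna(sb, 30)
    a1 = SequenceRecord("a1", make_dna(sa + 1, 50) + tail_a)
    a2 = SequenceRecord("a2", make_dna(sa + 2, 90) + tail_a)
    b = SequenceRecord("b", make_dna(sb + 3, 70) + tail_b)
    assert classify_family(a1, b) == classify_family(b, a1)
    assert classify_family(a1, b) == classify_family(a2, b)


# ------------------------------------------------------------------ screen

def test_screen_planted_exact_copy():
    q = SequenceRecord("q", make_dna(5, 300))
    g = SequenceRecord("g", make_dna(6, 700) + q.seq + make_dna(8, 400))
    hits = screen_copies(q, g)
    assert len(hits) == 1
    assert (hits[0].start, hits[0].end) == (700, 1000)
    assert hits[0].cover == pytest.approx(1.0)
    assert hits[0].identity == pytest.approx(1.0)


def test_screen_identity_and_cover_filters():
    q = SequenceRecord("q", make_dna(9, 400))
    mut = mutate_to_K(q, 0.17, "JC", seed=3)  # ~85% identity, full length
    g1 = SequenceRecord("g1", make_dna(10, 300) + mut.seq + make_dna(11, 300))
    assert len(screen_copies(q, g1)) == 1
    trunc = q.seq[: int(0.6 * len(q.seq))]  # 60% of the query, exact
    g2 = SequenceRecord("g2", make_dna(12, 300) + trunc + make_dna(13, 300))
    assert screen_copies(q, g2) == []


def test_screen_reverse_strand_reported_forward():
    q = SequenceRecord("q", make_dna(14, 250))
    g = SequenceRecord("g", make_dna(15, 100) + revcomp(q.seq) + make_dna(16, 150))
    hits = screen_copies(q, g)
    assert len(hits) == 1
    assert hits[0].strand == "-"
    assert (hits[0].start, hits[0].end) == (100, 350)


def test_screen_zero_thresholds_give_superset():
    q = SequenceRecord("q", make_dna(21, 200))
    parts = make_dna(22, 150) + q.seq[:120] + make_dna(23, 100) + q.seq + make_dna(24, 80)
    g = SequenceRecord("g", parts)
    loose = screen_copies(q, g, ScreenConfig(min_cover=0.0, min_identity=0.0))
    strict = screen_copies(q, g, ScreenConfig(min_cover=0.7, min_identity=0.8))
    loose_keys = {(h.start, h.end, h.strand) for h in loose}
    assert {(h.start, h.end, h.strand) for h in strict} <= loose_keys
    assert len(loose) > len(strict)


def test_screen_intervals_match_ungapped_window_oracle():
    # with an exact planted copy the best local alignment is the full window
    q = SequenceRecord("q", make_dna(31, 60))
    g_seq = make_dna(32, 900) + q.seq + make_dna(33, 1040)
    hits = screen_copies(q, SequenceRecord("g", g_seq))
    best_window = max(
        range(len(g_seq) - 60 + 1),
        key=lambda i: sum(a == b for a, b in zip(g_seq[i : i + 60], q.seq)),
    )
    assert len(hits) == 1
    assert hits[0].start == best_window == 900


# ------------------------------------------------------------------ full annotation

def test_annotation_absent_on_random_sequence():
    for seed in (201, 202, 203):
        rec = SequenceRecord("r", make_dna(seed, 2000, gc=0.35))
        assert annotate_helitron(rec, AnnotatorConfig()) is None


def test_annotation_hallmarks_match_truth(default_helitron):
    rec, truth = default_helitron
    ann = annotate_helitron(rec, AnnotatorConfig())
    hel = next(t for t in truth if t.feature_type == "helitron")
    orf = next(t for t in truth if t.feature_type == "orf")
    assert ann.element_interval == (hel.start, hel.end)
    assert ann.strand == "+"
    assert ann.insertion_site_ok
    assert ann.orf_interval == (orf.start, orf.end)
    assert ann.hairpin is not None and ann.hairpin.offset_from_3prime == 11
    assert ann.hallmark_score == 4
    assert ann.coverage_percent == pytest.approx(100 * 5294 / 5667)
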