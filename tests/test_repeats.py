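"""Repeat finders against planted truth and brute-force oracles."""
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from heltrace.errors import HeltraceError
from heltrace.records import pairs, revcomp
from heltrace.repeats import at_content, find_direct, find_inverted, find_tandem

from .conftest import make_dna

DNA = st.text(alphabet="ACGT", min_size=10, max_size=100)


# ------------------------------------------------------------------ tandem

def _tandem_oracle(s: str, min_unit: int, min_copies: int):
    """Maximal exactly-periodic regions by definition (all unit/phase pairs),
    reported with the smallest primitive period."""
    n = len(s)
    regions = {}
    for u in range(1, n // 2 + 1):
        i = 0
        while i + 2 * u <= n:
            # maximal run of period u starting at or after i
            if s[i] == s[i + u]:
                j = i
                while j + u < n and s[j] == s[j + u]:
                    j += 1
                span = (i, j + u)
                if span[1] - span[0] >= 2 * u:
                    prev = regions.get(span)
                    if prev is None or u < prev:
                        # keep smallest period that explains this exact span
                        covered = any(
                            pu < u and u % pu == 0 and ps <= span[0] and span[1] <= pe
                            for (ps, pe), pu in regions.items()
                        )
                        if not covered:
                            regions[span] = u
                i = j + 1
            else:
                i += 1
    out = set()
    for (a, b), u in regions.items():
        copies = (b - a) // u
        if u >= min_unit and copies >= min_copies:
            out.add((a, b, u, copies))
    return out


@pytest.mark.parametrize(
    "s,expected",
    [
        ("ATATATAT", {(0, 8, 2, 4)}),
        # maximal extent includes the leading G that continues the period
        ("GGGACGACGACGTTT", {(2, 12, 3, 3)}),
        # and the trailing partial unit
        ("ACGTACGTAA", {(0, 9, 4, 2)}),
    ],
)
def test_tandem_small_examples(s, expected):
    hits = find_tandem(s, min_unit=2, min_copies=2, min_identity=1.0)
    got = {(h.start, h.end, h.unit_length, h.copies) for h in hits}
    assert got == expected


@pytest.mark.parametrize("seed", range(10))
def test_tandem_equals_bruteforce_on_planted_strings(seed):
    """Strings <= 64 bp with a planted exact array match the enumeration oracle."""
    unit = make_dna(seed, 5)
    s = make_dna(seed + 50, 12) + unit * 4 + make_dna(seed + 99, 12)
    got = {
        (h.start, h.end, h.unit_length, h.copies)
        for h in find_tandem(s, min_unit=3, min_copies=3, min_identity=1.0)
    }
    want = _tandem_oracle(s, 3, 3)
    assert got == want


def test_tandem_planted_array_in_locus(default_locus):
    rec, truth = default_locus
    arr = next(t for t in truth if t.feature_type == "tandem_array")
    hits = find_tandem(rec.seq, min_unit=100, min_copies=2, min_identity=0.95)
    assert len(hits) == 1
    h = hits[0]
    assert (h.unit_length, h.copies) == (396, 6)
    assert h.intervals[0] == arr.intervals[0]


def test_tandem_tolerates_scattered_mutations():
    # identity is computed against the consensus, so one bad copy
    # does not split the array
    unit = make_dna(77, 40)
    bad = list(unit)
    bad[10] = {"A": "C", "C": "A", "G": "T", "T": "G"}[bad[10]]
    s = make_dna(78, 20) + unit * 2 + "".join(bad) + unit * 2 + make_dna(79, 20)
    hits = find_tandem(s, min_unit=20, min_copies=4, min_identity=0.9)
    assert len(hits) == 1
    assert hits[0].copies == 5
    assert hits[0].identity >= 0.99


def test_tandem_rejects_bad_params():
    with pytest.raises(HeltraceError):
        find_tandem("ACGT", min_unit=1)
    with pytest.raises(HeltraceError):
        find_tandem("ACGT", min_copies=1)


# ------------------------------------------------------------------ direct

def _direct_oracle(s: str, min_len: int, max_spacer: int):
    """All maximal exact co-oriented pairs by diagonal scan, spacer > 0,
    excluding periodic (array-internal) pairs."""
    n = len(s)
    out = set()
    for d in range(1, n):
        i = 0
        while i < n - d:
            if s[i] == s[i + d]:
                j = i
                while j < n - d and s[j] == s[j + d]:
                    j += 1
                ell = j - i
                spacer = d - ell
                if ell >= min_len and 0 < spacer <= max_spacer:
                    m = min(ell, spacer)
                    if m < 8 or s[j : j + m] != s[i : i + m]:
                        out.add((i, j, i + d, j + d))
                i = j + 1
            else:
                i += 1
    return out


@pytest.mark.parametrize("seed", range(10))
def test_direct_equals_quadratic_oracle_on_toys(seed):
    unit = make_dna(seed + 10, 25)
    s = (
        make_dna(seed, 30)
        + unit
        + make_dna(seed + 20, 40)
        + unit
        + make_dna(seed + 30, 30)
    )
    got = {
        (h.intervals[0][0], h.intervals[0][1], h.intervals[1][0], h.intervals[1][1])
        for h in find_direct(s, min_len=12, min_identity=1.0, max_spacer=150)
    }
    want = _direct_oracle(s, 12, 150)
    assert got == want


def test_direct_planted_pair_in_locus(default_locus):
    rec, truth = default_locus
    hits = find_direct(rec.seq, min_len=100, min_identity=0.95, max_spacer=1000)
    assert len(hits) == 1
    h = hits[0]
    assert h.unit_length == 376
    assert h.spacer == 426
    assert h.identity >= 0.99
    dr = next(t for t in truth if t.feature_type == "direct_repeat")
    assert h.intervals == dr.intervals


def test_direct_does_not_report_tandem_array_internals(default_locus):
    # the 6x396 array offers many co-oriented internal pairs; none may leak
    rec, truth = default_locus
    arr = next(t for t in truth if t.feature_type == "tandem_array")
    hits = find_direct(rec.seq, min_len=100, min_identity=0.95, max_spacer=2500)
    for h in hits:
        assert not (arr.start <= h.start and h.end <= arr.end)


def test_direct_random_sequence_empty():
    assert find_direct(make_dna(123, 1000), min_len=100, min_identity=0.9) == []


# ------------------------------------------------------------------ inverted

def _inverted_oracle(s: str, min_stem: int, max_loop: int, max_mismatch: int):
    """All maximal arm pairs by definition: grow outward from every loop
    placement, trim to the outermost complementary pair."""
    n = len(s)
    out = set()
    for loop in range(0, max_loop + 1):
        for ls in range(1, n - loop):
            le = ls + loop
            k = mism = 0
            stem = stem_m = 0
            while ls - 1 - k >= 0 and le + k < n:
                if pairs(s[ls - 1 - k], s[le + k]):
                    k += 1
                    stem, stem_m = k, mism
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                    k += 1
            if stem >= min_stem:
                out.add((ls - stem, ls, le, le + stem))
    return out


def test_inverted_planted_palindrome():
    arm = "GATTACAGCA"
    s = make_dna(61, 40) + arm + "TTTTT" + revcomp(arm) + make_dna(62, 40)
    hits = find_inverted(s, min_stem=10, max_loop=8)
    assert any(h.unit_length >= 10 and h.spacer == 5 for h in hits)


def test_inverted_homopolymer_empty():
    assert find_inverted("A" * 80, min_stem=3, max_loop=5) == []


@pytest.mark.parametrize("seed", range(8))
def test_inverted_equals_exhaustive_oracle(seed):
    s = make_dna(seed + 300, 150)
    got = {
        (h.intervals[0][0], h.intervals[0][1], h.intervals[1][0], h.intervals[1][1])
        for h in find_inverted(s, min_stem=4, max_loop=6, max_mismatch=1)
    }
    assert got == _inverted_oracle(s, 4, 6, 1)


@given(DNA)
@settings(deadline=None, max_examples=60)
def test_inverted_revcomp_symmetry(s):
    n = len(s)
    fwd = {
        ((n - b2, n - b1), (n - a2, n - a1))
        for h in find_inverted(s, min_stem=3, max_loop=4)
        for (a1, a2), (b1, b2) in [h.intervals]
    }
    rev = {h.intervals for h in find_inverted(revcomp(s), min_stem=3, max_loop=4)}
    assert fwd == rev


def test_inverted_monotone_in_min_stem():
    s = make_dna(91, 200)
    strict = {h.intervals for h in find_inverted(s, min_stem=6, max_loop=6)}
    loose = {h.intervals for h in find_inverted(s, min_stem=4, max_loop=6)}
    assert strict <= loose


# ------------------------------------------------------------------ AT content

def test_at_content_values():
    assert at_content("ATAT") == 1.0
    assert at_content("ACGT") == 0.5
    assert at_content("ANNT") == 1.0  # ambiguity excluded from both sides
    with pytest.raises(HeltraceError):
        at_content("")
    with pytest.raises(HeltraceError):
        at_content("NNN")
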