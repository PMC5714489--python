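"""Tandem, direct and inverted repeat detection at desk scale.

These detectors characterise the repeat architecture of a proviral locus:
tandem arrays (reported with their smallest primitive unit), long co-oriented
direct-repeat pairs with spacers, and reverse-complement arm pairs able to
form stem-loops.  All coordinates are 0-based half-open; all searches are
exact (no heuristics beyond requiring a short mismatch-free seed inside a
degenerate repeat).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import HeltraceError
from .records import SequenceRecord, pairs


@dataclass(frozen=True)
class RepeatHit:
    """A detected repeat: tandem (unit x copies), direct pair, or inverted pair."""

    kind: str  # tandem | direct | inverted
    unit_length: int
    identity: float
    intervals: tuple[tuple[int, int], ...]
    copies: int | None = None  # tandem only
    spacer: int | None = None  # direct / inverted (loop) only

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[-1][1]


def _as_str(seq) -> str:
    return seq.seq if isinstance(seq, SequenceRecord) else str(seq)


# ------------------------------------------------------------------ run chaining

def _true_runs(eq: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, length)."""
    if eq.size == 0:
        return []
    padded = np.concatenate(([False], eq, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return [(int(s), int(e - s)) for s, e in zip(starts, ends)]


def _chain_runs(
    runs: list[tuple[int, int]], seed_len: int, mismatch_cost: int = 3
) -> list[tuple[int, int, int]]:
    """Greedily chain match-runs across mismatch gaps.

    A gap of g mismatches is bridged when both flanking context can pay for
    it (3g < incoming run and 3g < accumulated chain score); chains start and
    end on runs, so they never extend into background by chance.  Only chains
    containing at least one run of ``seed_len`` are kept.  Returns
    (start, end, matched) triples over the underlying boolean array.
    """
    chains = []
    cur = None  # [start, end, matched, has_seed]
    for s, l in runs:
        if cur is None:
            cur = [s, s + l, l, l >= seed_len]
            continue
        gap = s - cur[1]
        score = cur[2] - mismatch_cost * ((cur[1] - cur[0]) - cur[2])
        if mismatch_cost * gap < l and mismatch_cost * gap < score:
            cur[1] = s + l
            cur[2] += l
            cur[3] = cur[3] or l >= seed_len
        else:
            if cur[3]:
                chains.append((cur[0], cur[1], cur[2]))
            cur = [s, s + l, l, l >= seed_len]
    if cur is not None and cur[3]:
        chains.append((cur[0], cur[1], cur[2]))
    return chains


# ------------------------------------------------------------------ tandem

def _array_identity(arr: np.ndarray, start: int, unit: int, copies: int) -> float:
    """Mean per-copy identity against the column-majority consensus."""
    rows = arr[start : start + unit * copies].reshape(copies, unit)
    counts = np.stack([(rows == b).sum(axis=0) for b in _BASES4])
    return float(counts.max(axis=0).sum()) / (copies * unit)


_BASES4 = [np.bytes_(b) for b in (b"A", b"C", b"G", b"T")]


def find_tandem(
    seq,
    min_unit: int = 2,
    min_copies: int = 2,
    min_identity: float = 0.9,
    max_unit: int | None = None,
) -> list[RepeatHit]:
    """Maximal tandem arrays with unit identity (vs consensus) >= min_identity.

    Arrays are reported with the smallest primitive unit: a periodicity whose
    span is already explained by a smaller period dividing it (including
    homopolymer runs) is suppressed as a harmonic.
    """
    if min_unit < 2:
        raise HeltraceError("min_unit must be >= 2")
    if min_copies < 2:
        raise HeltraceError("min_copies must be >= 2")
    s = _as_str(seq)
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    if max_unit is None:
        max_unit = n // 2
    hits = []
    accepted: list[tuple[int, int, int]] = []  # (unit, start, end) incl. u < min_unit
    for u in range(1, max_unit + 1):
        if u >= n:
            break
        eq = arr[:-u] == arr[u:]
        runs = _true_runs(eq)
        seed = min(8, u)
        if not any(l >= seed for _, l in runs):
            continue
        for c_start, c_end, matched in _chain_runs(runs, seed):
            span = (c_start, c_end + u)
            copies = (span[1] - span[0]) // u
            if copies < 2:
                continue
            harmonic = False
            for au, a_s, a_e in accepted:
                if u % au == 0 and u != au:
                    overlap = min(span[1], a_e) - max(span[0], a_s)
                    if overlap >= 0.9 * (span[1] - span[0]):
                        harmonic = True
                        break
            if harmonic:
                continue
            identity = _array_identity(arr, span[0], u, copies)
            if identity < min_identity:
                continue
            accepted.append((u, span[0], span[1]))
            if u >= min_unit and copies >= min_copies:
                hits.append(
                    RepeatHit(
                        kind="tandem",
                        unit_length=u,
                        copies=copies,
                        identity=identity,
                        intervals=(span,),
                    )
                )
    hits.sort(key=lambda h: (-(h.end - h.start), -h.unit_length, h.start))
    return hits


# ------------------------------------------------------------------ direct

def _tandem_like(s: str, start: int, end: int, d: int, min_identity: float) -> bool:
    """True when a candidate pair is periodic continuation (part of an array).

    The spacer of an array-internal pair is itself made of repeat units, so
    its start matches the start of the first copy at high identity; a genuine
    direct-repeat pair has an unrelated spacer.
    """
    ell = end - start
    m = min(ell, d - ell)
    if m < 8:
        return False
    spacer_seg = s[end : end + m]
    head = s[start : start + m]
    ident = sum(x == y for x, y in zip(spacer_seg, head)) / m
    return ident >= min_identity


def find_direct(
    seq,
    min_len: int = 30,
    min_identity: float = 0.9,
    max_spacer: int = 1000,
) -> list[RepeatHit]:
    """Non-tandem co-oriented repeat pairs, longest first.

    For every offset d the two shifted copies of the sequence are compared,
    mismatch-interrupted match runs are chained, and each chained segment of
    length l becomes a candidate pair with spacer d - l.  Overlapping pairs
    (l >= d) and array-internal pairs (periodic spacer) are rejected.
    """
    if min_len < 8:
        raise HeltraceError("min_len must be >= 8")
    s = _as_str(seq)
    n = len(s)
    arr = np.frombuffer(s.encode(), dtype="S1")
    seed = min(12, min_len)
    hits = []
    for d in range(min_len + 1, n - min_len + 1):
        eq = arr[:-d] == arr[d:]
        runs = _true_runs(eq)
        if not any(l >= seed for _, l in runs):
            continue
        for c_start, c_end, matched in _chain_runs(runs, seed):
            ell = c_end - c_start
            spacer = d - ell
            if ell < min_len or spacer <= 0 or spacer > max_spacer:
                continue
            identity = matched / ell
            if identity < min_identity:
                continue
            if _tandem_like(s, c_start, c_end, d, min_identity):
                continue
            hits.append(
                RepeatHit(
                    kind="direct",
                    unit_length=ell,
                    spacer=spacer,
                    identity=identity,
                    intervals=((c_start, c_end), (c_start + d, c_end + d)),
                )
            )
    hits.sort(key=lambda h: (-h.unit_length, h.start, h.spacer))
    return hits


# ------------------------------------------------------------------ inverted

def find_inverted(
    seq,
    min_stem: int = 4,
    max_loop: int = 12,
    max_mismatch: int = 0,
) -> list[RepeatHit]:
    """Reverse-complement arm pairs (stem-loops), maximal per (center, loop).

    Arms grow outward from every possible loop placement until the mismatch
    budget is exhausted, then are trimmed back to the last complementary
    pair.  This is a superset of the 3'-window hairpin search.
    """
    if min_stem < 3:
        raise HeltraceError("min_stem must be >= 3")
    s = _as_str(seq)
    n = len(s)
    hits = []
    for loop in range(0, max_loop + 1):
        for ls in range(1, n):
            le = ls + loop
            if le > n - 1:
                break
            k = 0
            mism = 0
            stem, stem_mism = 0, 0
            while True:
                i1 = ls - 1 - k
                j2 = le + k
                if i1 < 0 or j2 >= n:
                    break
                if pairs(s[i1], s[j2]):
                    k += 1
                    stem, stem_mism = k, mism
                else:
                    mism += 1
                    if mism > max_mismatch:
                        break
                    k += 1
            if stem < min_stem:
                continue
            hits.append(
                RepeatHit(
                    kind="inverted",
                    unit_length=stem,
                    spacer=loop,
                    identity=(stem - stem_mism) / stem,
                    intervals=((ls - stem, ls), (le, le + stem)),
                )
            )
    hits.sort(key=lambda h: (-h.unit_length, h.start, h.spacer))
    return hits


# ------------------------------------------------------------------ composition

def at_content(seq) -> float:
    """(#A + #T) / #unambiguous bases; ambiguity codes excluded from both."""
    s = _as_str(seq)
    if len(s) == 0:
        raise HeltraceError("cannot compute AT content of an empty sequence")
    acgt = sum(s.count(b) for b in "ACGT")
    if acgt == 0:
        raise HeltraceError("sequence has no unambiguous bases")
    return (s.count("A") + s.count("T")) / acgt
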