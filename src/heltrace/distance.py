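"""Pairwise nucleotide divergence (K, substitutions per site).

Implements the p-distance and the Jukes-Cantor, Kimura two-parameter and
Tamura three-parameter corrections from transition/transversion fractions
counted with pairwise deletion of gapped or ambiguous columns.  Saturation
(a non-positive logarithm argument) is reported as a flagged result, never
as an exception, so distance matrices remain constructible.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import HeltraceError
from .records import SequenceRecord

MODELS = ("p", "JC", "K2P", "T92")

_TRANSITION_PAIRS = {frozenset("AG"), frozenset("CT")}


@dataclass
class PairwiseCounts:
    """Site counts for one aligned pair: P (transitions), Q (transversions),
    GC content theta of the compared columns, and h = 2*theta*(1-theta)."""

    sites: int
    P: float
    Q: float
    theta: float

    @property
    def h(self) -> float:
        return 2.0 * self.theta * (1.0 - self.theta)

    def validate(self) -> None:
        if self.sites <= 0:
            raise HeltraceError("sites must be positive")
        if self.P + self.Q > 1 + 1e-12:
            raise HeltraceError("P + Q cannot exceed 1")
        if not 0 <= self.theta <= 1:
            raise HeltraceError("theta must be in [0,1]")


@dataclass
class DistanceResult:
    K: float
    model: str
    sites_used: int
    saturated: bool = False


def _seq_str(x) -> str:
    return x.seq if isinstance(x, SequenceRecord) else str(x)


def count_differences(a, b, gap_policy: str = "pairwise_deletion") -> PairwiseCounts:
    """Count transitions/transversions over usable aligned columns.

    Columns with a gap or ambiguity code in either sequence are excluded
    (pairwise deletion); theta is the mean GC of the two sequences over the
    columns actually used.
    """
    if gap_policy != "pairwise_deletion":
        raise HeltraceError(f"unsupported gap policy {gap_policy!r}")
    sa, sb = _seq_str(a), _seq_str(b)
    if len(sa) != len(sb):
        raise HeltraceError(
            f"aligned sequences must have equal length ({len(sa)} != {len(sb)})"
        )
    aa = np.frombuffer(sa.upper().encode(), dtype="S1")
    bb = np.frombuffer(sb.upper().encode(), dtype="S1")
    acgt = np.array([b"A", b"C", b"G", b"T"])
    ok = np.isin(aa, acgt) & np.isin(bb, acgt)
    sites = int(ok.sum())
    if sites == 0:
        raise HeltraceError("no usable (unambiguous, ungapped) columns")
    ua, ub = aa[ok], bb[ok]
    diff = ua != ub
    ts = 0
    for x, y in ((b"A", b"G"), (b"G", b"A"), (b"C", b"T"), (b"T", b"C")):
        ts += int(((ua == x) & (ub == y)).sum())
    tv = int(diff.sum()) - ts
    gc_a = int(((ua == b"G") | (ua == b"C")).sum()) / sites
    gc_b = int(((ub == b"G") | (ub == b"C")).sum()) / sites
    return PairwiseCounts(sites=sites, P=ts / sites, Q=tv / sites,
                          theta=0.5 * (gc_a + gc_b))


def distance(counts: PairwiseCounts, model: str = "K2P") -> DistanceResult:
    """Model-corrected K from pairwise counts.

    p:   K = P + Q
    JC:  K = -(3/4) ln(1 - (4/3)(P+Q))
    K2P: K = -(1/2) ln(1 - 2P - Q) - (1/4) ln(1 - 2Q)
    T92: K = -h ln(1 - P/h - Q) - (1/2)(1 - h) ln(1 - 2Q),  h = 2*theta*(1-theta)
    """
    counts.validate()
    if model not in MODELS:
        raise HeltraceError(f"unknown model {model!r}; choose from {MODELS}")
    P, Q = counts.P, counts.Q
    p = P + Q

    def _logterm(x: float) -> float | None:
        return math.log(x) if x > 0 else None

    if model == "p":
        return DistanceResult(p, model, counts.sites)
    if model == "JC":
        t = _logterm(1 - 4 * p / 3)
        if t is None:
            return DistanceResult(math.inf, model, counts.sites, saturated=True)
        return DistanceResult(-0.75 * t + 0.0, model, counts.sites)
    if model == "K2P":
        t1 = _logterm(1 - 2 * P - Q)
        t2 = _logterm(1 - 2 * Q)
        if t1 is None or t2 is None:
            return DistanceResult(math.inf, model, counts.sites, saturated=True)
        return DistanceResult(-0.5 * t1 - 0.25 * t2 + 0.0, model, counts.sites)
    # T92
    h = counts.h
    if h == 0:  # degenerate composition: no GC mixing, fall back saturated
        return DistanceResult(math.inf, model, counts.sites, saturated=True)
    t1 = _logterm(1 - P / h - Q)
    t2 = _logterm(1 - 2 * Q)
    if t1 is None or t2 is None:
        return DistanceResult(math.inf, model, counts.sites, saturated=True)
    return DistanceResult(-h * t1 - 0.5 * (1 - h) * t2 + 0.0, model, counts.sites)


@dataclass
class DistanceMatrix:
    """Symmetric taxon-labeled K matrix with per-cell saturation flags."""

    ids: list[str]
    values: np.ndarray
    saturated: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.saturated is None:
            self.saturated = ~np.isfinite(self.values)
        n = len(self.ids)
        if self.values.shape != (n, n):
            raise HeltraceError("matrix shape does not match taxon list")

    def __getitem__(self, pair) -> float:
        i = self.ids.index(pair[0])
        j = self.ids.index(pair[1])
        return float(self.values[i, j])

    @property
    def any_saturated(self) -> bool:
        return bool(self.saturated.any())

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)


def pairwise_matrix(records: list[SequenceRecord], model: str = "K2P") -> DistanceMatrix:
    """All-pairs model-corrected distances for pre-aligned sequences."""
    if len(records) < 2:
        raise HeltraceError("need at least two sequences")
    lengths = {len(r.seq) for r in records}
    if len(lengths) != 1:
        raise HeltraceError("aligned sequences must all have the same length")
    n = len(records)
    ids = [r.id for r in records]
    if len(set(ids)) != n:
        raise HeltraceError("sequence ids must be unique")
    vals = np.zeros((n, n))
    sat = np.zeros((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            res = distance(count_differences(records[i], records[j]), model)
            vals[i, j] = vals[j, i] = res.K
            sat[i, j] = sat[j, i] = res.saturated
    return DistanceMatrix(ids, vals, sat)
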