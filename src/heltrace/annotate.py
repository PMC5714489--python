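"""Structural annotation of Helitron elements.

A Helitron is recognised here by the conjunction of its hallmarks rather than
by homology: conserved 5'/3' terminal motifs, a stem-loop close to the 3'
terminus, insertion between host A and T nucleotides, and a Rep/Helicase ORF
whose translation carries the three catalytic-core consensus motifs.  The
module also provides the 3'-terminus family rule and the cross-genome copy
screen (exact local alignment with cover/identity filtering).
"""
from __future__ import annotations

from dataclasses import dataclass

from Bio import Align
from Bio.Align import substitution_matrices

from .consensus import RepConsensus, default_rep_consensus
from .errors import HeltraceError
from .records import (
    SequenceRecord,
    iupac_matches,
    pairs,
    revcomp,
    translate,
    validate_dna,
)

# ------------------------------------------------------------------ ORFs


@dataclass(frozen=True)
class OrfHit:
    """A maximal start-to-stop span (stop codon included), forward coordinates."""

    start: int
    end: int
    strand: str
    frame: int


_STOPS = {"TAA", "TAG", "TGA"}


def _forward_orfs(s: str, min_length_bp: int) -> list[tuple[int, int, int]]:
    hits = []
    n = len(s)
    for frame in range(3):
        start = None
        for p in range(frame, n - 2, 3):
            codon = s[p : p + 3]
            if codon in _STOPS:
                if start is not None and p + 3 - start >= min_length_bp:
                    hits.append((start, p + 3, frame))
                start = None
            elif codon == "ATG" and start is None:
                start = p
    return hits


def find_orfs(seq: SequenceRecord, min_length_bp: int) -> list[OrfHit]:
    """All maximal ATG..stop spans >= min_length_bp on both strands.

    A span is maximal in its frame: it opens at the first ATG following the
    previous stop codon.  Results are sorted by forward start coordinate.
    """
    s = seq.seq
    validate_dna(s, where=f"sequence {seq.id!r}")
    n = len(s)
    out = [OrfHit(a, b, "+", f) for a, b, f in _forward_orfs(s, min_length_bp)]
    for a, b, f in _forward_orfs(revcomp(s), min_length_bp):
        out.append(OrfHit(n - b, n - a, "-", f))
    return sorted(out, key=lambda o: (o.start, o.end, o.strand))


# ------------------------------------------------------------------ Rep motifs


def scan_rep_motifs(
    protein: SequenceRecord, consensus: RepConsensus
) -> list[tuple[int, int]]:
    """All (motif index, position) hits of the consensus on a protein.

    A hit exists at position p for motif m iff every pattern character
    matches: an exact residue, a residue in the declared class set, or 'x'.
    Hits are reported motif-by-motif in pattern order; overlaps are allowed.
    """
    consensus.validate()
    prot = protein.seq
    hits = []
    for m_idx in range(len(consensus.motifs)):
        w = len(consensus.motifs[m_idx])
        for pos in range(len(prot) - w + 1):
            if consensus.matches_at(prot, pos, m_idx):
                hits.append((m_idx, pos))
    return hits


def _motifs_in_order(hits: list[tuple[int, int]], n_motifs: int) -> bool:
    firsts = {}
    for m, p in hits:
        firsts.setdefault(m, p)
    if len(firsts) < n_motifs:
        return False
    positions = [firsts[m] for m in range(n_motifs)]
    return all(positions[i] < positions[i + 1] for i in range(n_motifs - 1))


# ------------------------------------------------------------------ termini


def detect_termini(
    seq: SequenceRecord,
    term5: str,
    term3: str,
    search_window: int | None = None,
) -> list[tuple[int, int]]:
    """Candidate (start, end) element intervals bounded by the terminal motifs.

    Returns every pair with term5 matching at `start` and term3 ending at
    `end` (IUPAC degeneracy honoured, motifs non-overlapping), sorted by span
    length descending.  `search_window` restricts term5 matches to the first
    and term3 matches to the last `search_window` bp.
    """
    if not term5 or not term3:
        raise HeltraceError("terminal motif patterns must be non-empty")
    s = seq.seq
    n = len(s)
    starts = iupac_matches(term5, s)
    ends = [m + len(term3) for m in iupac_matches(term3, s)]
    if search_window is not None:
        starts = [i for i in starts if i < search_window]
        ends = [j for j in ends if j > n - search_window]
    cands = [
        (i, j)
        for i in starts
        for j in ends
        if i + len(term5) <= j - len(term3)
    ]
    cands.sort(key=lambda ij: (-(ij[1] - ij[0]), ij[0]))
    return cands


# ------------------------------------------------------------------ hairpin


@dataclass(frozen=True)
class Hairpin:
    """A stem-loop: arm length, loop length, end offset from the 3' terminus."""

    stem: int
    loop: int
    offset_from_3prime: int
    start: int  # start of 5' arm
    end: int  # end of 3' arm (half-open)
    mismatches: int

    @property
    def score(self) -> int:
        return self.stem - self.mismatches


def detect_hairpin(
    seq: SequenceRecord | str,
    window_from_3prime: int,
    min_stem: int = 5,
    max_loop: int = 12,
    max_mismatch: int = 1,
) -> Hairpin | None:
    """Best reverse-complement stem-loop whose 3' arm lies within the window.

    Score is stem length minus mismatches; ties prefer the smaller offset
    from the 3' terminus, then fewer mismatches, then the smaller loop.
    """
    s = seq.seq if isinstance(seq, SequenceRecord) else seq
    n = len(s)
    if window_from_3prime > n:
        raise HeltraceError("window_from_3prime exceeds sequence length")
    lo = max(0, n - window_from_3prime)
    best = None
    best_key = None
    for loop in range(1, max_loop + 1):
        for ls in range(max(0, lo - loop), n):
            le = ls + loop
            if le >= n:
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
            arm2_start, arm2_end = le, le + stem
            if arm2_start < lo or arm2_end > n:
                continue
            offset = n - arm2_end
            key = (-(stem - stem_mism), offset, stem_mism, loop, ls)
            if best_key is None or key < best_key:
                best_key = key
                best = Hairpin(
                    stem=stem,
                    loop=loop,
                    offset_from_3prime=offset,
                    start=ls - stem,
                    end=arm2_end,
                    mismatches=stem_mism,
                )
    return best


# ------------------------------------------------------------------ insertion site


def check_insertion_site(flank5: str, flank3: str) -> bool:
    """True iff the 5' host flank ends with A and the 3' one begins with T."""
    if not flank5 or not flank3:
        raise HeltraceError("insertion-site flanks must be non-empty")
    return flank5.endswith("A") and flank3.startswith("T")


# ------------------------------------------------------------------ coverage


def coverage(element_length: int, segment_length: int) -> float:
    """Percent of the host segment covered by the element."""
    if element_length <= 0 or segment_length <= 0:
        raise HeltraceError("lengths must be positive")
    if element_length > segment_length:
        raise HeltraceError("element cannot be longer than its host segment")
    return 100.0 * element_length / segment_length


# ------------------------------------------------------------------ family rule


@dataclass
class FamilyRule:
    """Family assignment by identity over the terminal 3' window (default 30 bp).

    The threshold is inclusive: exactly 80% identity is the same family;
    anything strictly below is a different family.
    """

    window: int = 30
    identity_threshold: float = 0.80

    def validate(self) -> None:
        if self.window < 1:
            raise HeltraceError("window must be >= 1")
        if not 0 < self.identity_threshold <= 1:
            raise HeltraceError("identity_threshold must be in (0,1]")


def classify_family(
    a: SequenceRecord, b: SequenceRecord, rule: FamilyRule | None = None
) -> str:
    rule = rule or FamilyRule()
    rule.validate()
    w = rule.window
    if len(a.seq) < w or len(b.seq) < w:
        raise HeltraceError(f"both sequences must be at least {w} bp")
    ta, tb = a.seq[-w:], b.seq[-w:]
    identity = sum(x == y for x, y in zip(ta, tb)) / w
    return "same_family" if identity >= rule.identity_threshold else "different_family"


# ------------------------------------------------------------------ copy screen


@dataclass
class ScreenConfig:
    min_cover: float = 0.70
    min_identity: float = 0.80

    def validate(self) -> None:
        for name in ("min_cover", "min_identity"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise HeltraceError(f"{name} must be in [0,1]")


@dataclass(frozen=True)
class ScreenHit:
    start: int
    end: int
    strand: str
    cover: float
    identity: float
    score: float


def _make_aligner() -> Align.PairwiseAligner:
    # match +2 / mismatch -3, gap of length k costs 5 + 2k; N never aligns
    mat = substitution_matrices.Array("ACGTN", dims=2)
    for x in "ACGTN":
        for y in "ACGTN":
            if "N" in (x, y):
                mat[x, y] = -1000.0
            else:
                mat[x, y] = 2.0 if x == y else -3.0
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = mat
    aligner.open_gap_score = -7.0
    aligner.extend_gap_score = -2.0
    return aligner


def _strand_hits(
    genome: str, query: str, strand: str, max_hits: int, floor: float
) -> list[ScreenHit]:
    aligner = _make_aligner()
    target = genome
    hits = []
    for _ in range(max_hits):
        alns = aligner.align(target, query)
        try:
            aln = alns[0]
        except IndexError:
            break
        if aln.score < floor:
            break
        t_blocks, q_blocks = aln.aligned
        matches = 0
        cols = 0
        for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
            cols += te - ts
            matches += sum(
                1 for k in range(te - ts) if target[ts + k] == query[qs + k]
            )
        if cols == 0:
            break
        t_start, t_end = int(t_blocks[0][0]), int(t_blocks[-1][1])
        hits.append(
            ScreenHit(
                start=t_start,
                end=t_end,
                strand=strand,
                cover=sum(qe - qs for qs, qe in q_blocks) / len(query),
                identity=matches / cols,
                score=float(aln.score),
            )
        )
        target = target[:t_start] + "N" * (t_end - t_start) + target[t_end:]
    return hits


def screen_copies(
    query: SequenceRecord,
    genome: SequenceRecord,
    cfg: ScreenConfig | None = None,
    *,
    max_hits: int = 16,
) -> list[ScreenHit]:
    """Local-alignment screen of a query element against a genome.

    Both strands are searched with exact affine-gap local alignment
    (match +2, mismatch -3, gap existence 5, extension 2); hits already found
    are masked and the search repeated.  A hit is reported iff its query
    cover exceeds ``min_cover`` AND its identity exceeds ``min_identity``
    (both strictly).  Results are sorted by alignment score.
    """
    cfg = cfg or ScreenConfig()
    cfg.validate()
    if len(query.seq) >= len(genome.seq):
        raise HeltraceError("query must be shorter than the genome")
    validate_dna(query.seq, where="query")
    validate_dna(genome.seq, where="genome")
    floor = max(16.0, float(len(query.seq)))
    raw = _strand_hits(genome.seq, query.seq, "+", max_hits, floor)
    raw += _strand_hits(genome.seq, revcomp(query.seq), "-", max_hits, floor)
    kept = [h for h in raw if h.cover > cfg.min_cover and h.identity > cfg.min_identity]
    return sorted(kept, key=lambda h: (-h.score, h.start))


# ------------------------------------------------------------------ annotation


@dataclass
class AnnotatorConfig:
    term5: str = "TC"
    term3: str = "CTRR"
    search_window: int | None = None
    hairpin_window: int = 40
    min_stem: int = 5
    max_loop: int = 12
    max_mismatch: int = 1
    min_orf_bp: int = 600
    min_hallmarks: int = 3
    scan_reverse: bool = True
    consensus: RepConsensus | None = None


@dataclass
class HelitronAnnotation:
    """A located element with all hallmark evidence populated."""

    element_interval: tuple[int, int]
    strand: str
    term5_match: tuple[str, int]
    term3_match: tuple[str, int]
    hairpin: Hairpin | None
    insertion_site_ok: bool
    orf_interval: tuple[int, int] | None
    rep_motif_hits: list[tuple[int, int]]
    coverage_percent: float
    hallmark_score: int

    @property
    def length(self) -> int:
        i, j = self.element_interval
        return j - i


def _annotate_one_strand(
    s: str, cfg: AnnotatorConfig, consensus: RepConsensus
) -> tuple | None:
    """Best candidate on one orientation; local (strand) coordinates."""
    cands = detect_termini(SequenceRecord("s", s), cfg.term5, cfg.term3, cfg.search_window)
    if not cands:
        return None
    cands = cands[:50000]
    n = len(s)

    orf_info = []
    for a, b, _frame in _forward_orfs(s, cfg.min_orf_bp):
        prot = translate(s[a:b])
        hits = scan_rep_motifs(SequenceRecord("orf", prot), consensus)
        orf_info.append((a, b, hits, _motifs_in_order(hits, len(consensus.motifs))))

    hairpin_by_end: dict[int, Hairpin | None] = {}
    for _, j in cands:
        if j not in hairpin_by_end:
            hairpin_by_end[j] = detect_hairpin(
                s[:j],
                window_from_3prime=min(cfg.hairpin_window, j),
                min_stem=cfg.min_stem,
                max_loop=cfg.max_loop,
                max_mismatch=cfg.max_mismatch,
            )

    best = None
    best_key = None
    for i, j in cands:
        hp = hairpin_by_end[j]
        insertion_ok = i > 0 and j < n and s[i - 1] == "A" and s[j] == "T"
        orf = None
        for a, b, hits, ordered in orf_info:
            if i <= a and b <= j and (orf is None or b - a > orf[1] - orf[0]):
                orf = (a, b, hits, ordered)
        motifs_ok = bool(orf and orf[3])
        score = int(hp is not None) + int(insertion_ok) + int(orf is not None) + int(motifs_ok)
        key = (score, j - i, -i)
        if best_key is None or key > best_key:
            best_key = key
            best = (i, j, hp, insertion_ok, orf, score)
    return best


def annotate_helitron(
    seq: SequenceRecord, config: AnnotatorConfig | None = None
) -> HelitronAnnotation | None:
    """Locate the best-supported Helitron element in a sequence.

    Composes terminal-motif detection, hairpin search, insertion-site check,
    ORF finding and Rep-motif scanning; the candidate satisfying the most
    hallmarks wins (ties to the longest element).  Returns None when no
    termini pair exists or no candidate reaches ``min_hallmarks`` of the four
    non-terminal hallmarks (hairpin, A/T insertion site, ORF, ordered Rep
    motifs).
    """
    cfg = config or AnnotatorConfig()
    consensus = cfg.consensus or default_rep_consensus()
    validate_dna(seq.seq, where=f"sequence {seq.id!r}")
    n = len(seq.seq)

    results = []
    fwd = _annotate_one_strand(seq.seq, cfg, consensus)
    if fwd:
        results.append(("+", seq.seq, fwd))
    if cfg.scan_reverse:
        rc = revcomp(seq.seq)
        rev = _annotate_one_strand(rc, cfg, consensus)
        if rev:
            results.append(("-", rc, rev))
    if not results:
        return None
    # prefer the higher hallmark score, then longer element, then '+' strand
    results.sort(
        key=lambda r: (r[2][5], r[2][1] - r[2][0], r[0] == "+"), reverse=True
    )
    strand, s, (i, j, hp, insertion_ok, orf, score) = results[0]
    if score < cfg.min_hallmarks:
        return None

    def fwd_iv(a: int, b: int) -> tuple[int, int]:
        return (a, b) if strand == "+" else (n - b, n - a)

    orf_interval = fwd_iv(orf[0], orf[1]) if orf else None
    hairpin = hp
    if hp is not None and strand == "-":
        hairpin = Hairpin(
            stem=hp.stem,
            loop=hp.loop,
            offset_from_3prime=hp.offset_from_3prime,
            start=n - hp.end,
            end=n - hp.start,
            mismatches=hp.mismatches,
        )
    t5 = (s[i : i + len(cfg.term5)], fwd_iv(i, i + len(cfg.term5))[0])
    t3 = (s[j - len(cfg.term3) : j], fwd_iv(j - len(cfg.term3), j)[0])
    return HelitronAnnotation(
        element_interval=fwd_iv(i, j),
        strand=strand,
        term5_match=t5,
        term3_match=t3,
        hairpin=hairpin,
        insertion_site_ok=insertion_ok,
        orf_interval=orf_interval,
        rep_motif_hits=list(orf[2]) if orf else [],
        coverage_percent=coverage(j - i, n),
        hallmark_score=score,
    )
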