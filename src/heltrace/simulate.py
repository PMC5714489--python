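"""Synthetic genomes with planted, machine-readable truth.

This module emits the study conditions the rest of the package is exercised
against: an autonomous Helitron with canonical structural hallmarks, a
proviral locus with its tandem/direct/palindromic repeat architecture, copies
diverged to a target substitutions-per-site K under standard nucleotide
models, and horizontal-transfer scenarios on a dated species tree.

Every generator is deterministic per (spec, seed) and returns the emitted
:class:`~heltrace.records.SequenceRecord` together with
:class:`TruthRecord` entries (0-based half-open coordinates) covering every
planted feature.

Host flanks around a planted element are "inert": occurrences of the terminal
motifs are scrubbed from them and guard bases are placed at feature
boundaries so that planted repeats and hairpins do not extend by chance into
their surroundings.  This makes the planted truth identifiable — detectors
can be required to recover planted intervals *exactly* on mutation-free
output, which is the round-trip contract the test suite enforces.
"""
from __future__ import annotations

import math
import re
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
from scipy.linalg import expm

from .consensus import AMINO_ACIDS, RepConsensus, default_rep_consensus
from .errors import HeltraceError, SaturationError, SpecError
from .records import IUPAC, SequenceRecord, gc_fraction, iupac_regex, pairs, revcomp

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_BASE_INDEX = {b: i for i, b in enumerate("ACGT")}

#: 12 bp containing a stop codon in each of the three forward frames
#: (TAA at offsets 0, 4 and 8); used to insulate the planted ORF.
_STOP_GUARD = "TAAGTAAGTAAG"

_CODONS_BY_AA: dict[str, list[str]] = {}
_SENSE_CODONS: list[str] = []


def _init_codons() -> None:
    from Bio.Data.CodonTable import standard_dna_table

    for codon, aa in standard_dna_table.forward_table.items():
        if set(codon) <= set("ACGT"):
            _CODONS_BY_AA.setdefault(aa, []).append(codon)
            _SENSE_CODONS.append(codon)
    for aa in _CODONS_BY_AA:
        _CODONS_BY_AA[aa].sort()
    _SENSE_CODONS.sort()


_init_codons()


# ------------------------------------------------------------------ truth

@dataclass
class TruthRecord:
    """One planted feature: type, interval(s), free-form attributes."""

    feature_type: str
    intervals: tuple[tuple[int, int], ...]
    attributes: dict = field(default_factory=dict)

    @property
    def start(self) -> int:
        return self.intervals[0][0]

    @property
    def end(self) -> int:
        return self.intervals[0][1]


def _check_truth(truth: list[TruthRecord], seq_len: int) -> None:
    for t in truth:
        for s, e in t.intervals:
            if not (0 <= s <= e <= seq_len):
                raise HeltraceError(
                    f"truth record {t.feature_type} interval ({s},{e}) "
                    f"outside sequence of length {seq_len}"
                )


# ------------------------------------------------------------------ specs

@dataclass
class HelitronSpec:
    """Geometry and composition of a planted autonomous Helitron.

    Defaults reproduce the study element: 5294 bp total with a 4539-bp
    Rep/Hel ORF (the largest codon multiple compatible with ~750 bp of
    noncoding flank inside the element), canonical ``TC``/``CTRR`` termini,
    an 8/4 stem-loop ending 11 bp upstream of the 3' terminus, insertion
    between host A and T nucleotides, and AT-rich background (GC 0.35).
    Host flanks total 373 bp so the emitted record is 5667 bp.
    """

    total_length: int = 5294
    orf_length: int = 4539
    term5_motif: str = "TC"
    term3_motif: str = "CTRR"
    hairpin_stem: int = 8
    hairpin_loop: int = 4
    hairpin_offset_from_3prime: int = 11
    insertion_flank5: str = "A"
    insertion_flank3: str = "T"
    gc_content: float = 0.35
    flank5_length: int = 186
    flank3_length: int = 187

    def validate(self) -> None:
        if not 0 < self.gc_content < 1:
            raise SpecError(f"gc_content must be in (0,1), got {self.gc_content}")
        if self.orf_length >= self.total_length:
            raise SpecError("orf_length must be smaller than total_length")
        if self.orf_length % 3 != 0 or self.orf_length < 9:
            raise SpecError("orf_length must be a positive codon multiple")
        if self.hairpin_stem < 1:
            raise SpecError("hairpin_stem must be >= 1 (no degenerate hairpins)")
        if self.hairpin_loop < 1:
            raise SpecError("hairpin_loop must be >= 1")
        span = self.hairpin_offset_from_3prime + 2 * self.hairpin_stem + self.hairpin_loop
        if span > self.total_length:
            raise SpecError(
                "hairpin_offset_from_3prime + 2*hairpin_stem + hairpin_loop "
                "exceeds total_length"
            )
        if self.hairpin_offset_from_3prime < len(self.term3_motif):
            raise SpecError("hairpin would overlap the 3' terminal motif")
        for name in ("insertion_flank5", "insertion_flank3"):
            if len(getattr(self, name)) != 1 or getattr(self, name) not in "ACGT":
                raise SpecError(f"{name} must be a single concrete nucleotide")
        if not self.term5_motif or not self.term3_motif:
            raise SpecError("terminal motifs must be non-empty")
        hp_start = (
            self.total_length
            - self.hairpin_offset_from_3prime
            - 2 * self.hairpin_stem
            - self.hairpin_loop
        )
        orf_end = hp_start - 16
        orf_start = orf_end - self.orf_length
        if orf_start < len(self.term5_motif) + len(_STOP_GUARD):
            raise SpecError(
                "element too short for orf_length plus hairpin and terminal motifs"
            )
        if min(self.flank5_length, self.flank3_length) < 16:
            raise SpecError("host flanks must be at least 16 bp")


@dataclass
class ProviralLocusSpec:
    """Repeat architecture of the proviral-locus fixture.

    Defaults follow the described locus: a 396-bp unit tandemly repeated six
    times, one pair of 376-bp direct repeats at ~99.5% identity separated by
    426 bp, and eight AT-rich motifs (mean AT 0.71) each with an internal
    palindrome able to form a stem-loop.
    """

    tandem_unit_length: int = 396
    tandem_copies: int = 6
    direct_repeat_length: int = 376
    direct_repeat_spacer: int = 426
    direct_repeat_identity: float = 0.995
    motif_count: int = 8
    motif_at_content: float = 0.71
    motif_palindrome_stem: int = 10
    motif_length: int = 150
    palindrome_loop: int = 5
    gc_content: float = 0.35

    def validate(self) -> None:
        if self.tandem_copies < 2:
            raise SpecError("tandem_copies must be >= 2")
        if self.tandem_unit_length < 2:
            raise SpecError("tandem_unit_length must be >= 2")
        if not 0.0 <= self.direct_repeat_identity <= 1.0:
            raise SpecError("direct_repeat_identity must be in [0,1]")
        if not 0.0 <= self.motif_at_content <= 1.0:
            raise SpecError("motif_at_content must be in [0,1]")
        if self.direct_repeat_length < 8:
            raise SpecError("direct_repeat_length must be >= 8")
        if self.direct_repeat_spacer < 4:
            raise SpecError("direct_repeat_spacer must be >= 4")
        if self.motif_count < 0:
            raise SpecError("motif_count must be >= 0")
        if 2 * self.motif_palindrome_stem + self.palindrome_loop + 2 > self.motif_length:
            raise SpecError("palindrome does not fit inside motif_length")
        if not 0 < self.gc_content < 1:
            raise SpecError("gc_content must be in (0,1)")


@dataclass
class ClockParams:
    """Molecular-clock parameters: per-generation rate and gen/yr of two taxa."""

    mu: float = 3.0e-9
    gen_per_year_a: float = 14.0
    gen_per_year_b: float = 14.0

    def validate(self) -> None:
        if min(self.mu, self.gen_per_year_a, self.gen_per_year_b) <= 0:
            raise SpecError("clock parameters must all be positive")


# ------------------------------------------------------------------ helpers

def random_dna(rng: np.random.Generator, n: int, gc: float) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    idx = rng.choice(4, size=n, p=p)
    return _BASES[idx].tobytes().decode()


def _different_base(rng: np.random.Generator, base: str) -> str:
    choices = [b for b in "ACGT" if b != base]
    return choices[int(rng.integers(3))]


def _scrub_pattern(
    seq: list[str],
    pattern: str,
    lo: int,
    hi: int,
    protected: frozenset[int],
) -> None:
    """Destroy matches of an IUPAC pattern starting within [lo, hi).

    Replacement is deterministic: the first editable position of each match is
    changed to the first base (alphabetical) outside the pattern's allowed
    set at that position.
    """
    if len(pattern) < 2:
        return
    rx = iupac_regex(pattern)
    for _ in range(400):
        s = "".join(seq)
        hit = None
        for m in re.finditer(f"(?=({rx.pattern}))", s):
            if lo <= m.start() < hi:
                hit = m.start()
                break
        if hit is None:
            return
        edited = False
        for k in range(len(pattern)):
            pos = hit + k
            if pos in protected or pos >= len(seq):
                continue
            allowed = set(IUPAC[pattern[k]])
            repl = next((b for b in "ACGT" if b not in allowed), None)
            if repl is None:
                continue
            seq[pos] = repl
            edited = True
            break
        if not edited:
            return


def _instantiate_iupac(rng: np.random.Generator, pattern: str) -> str:
    out = []
    for ch in pattern:
        opts = IUPAC.get(ch)
        if opts is None:
            raise SpecError(f"invalid IUPAC code {ch!r} in motif")
        out.append(opts[int(rng.integers(len(opts)))])
    return "".join(out)


def _instantiate_protein_motif(
    rng: np.random.Generator, pattern: str, class_sets
) -> str:
    out = []
    for ch in pattern:
        if ch == "x":
            pool = AMINO_ACIDS
        elif ch in class_sets:
            pool = "".join(sorted(class_sets[ch]))
        else:
            pool = ch
        out.append(pool[int(rng.integers(len(pool)))])
    return "".join(out)


def _codons_for(rng: np.random.Generator, peptide: str) -> str:
    codons = []
    for aa in peptide:
        opts = _CODONS_BY_AA[aa]
        codons.append(opts[int(rng.integers(len(opts)))])
    return "".join(codons)


def _break_pair(seq: list[str], i: int, j: int) -> None:
    """Ensure positions i and j cannot base-pair (set seq[i] = seq[j])."""
    if 0 <= i < len(seq) and 0 <= j < len(seq) and pairs(seq[i], seq[j]):
        seq[i] = seq[j]


def _scrub_chance_motifs(
    peptide: list[str], consensus: RepConsensus, planted: dict[int, int]
) -> None:
    """Destroy chance consensus matches so only the planted hits remain.

    The random background peptide can instantiate a motif by accident; each
    such hit is broken by replacing one residue (outside every planted span)
    with the first amino acid that violates the pattern at that position.
    """
    protected: set[int] = set()
    for m_idx, pos in planted.items():
        protected.update(range(pos, pos + len(consensus.motifs[m_idx])))
    for _ in range(100):
        pep = "".join(peptide)
        edited = False
        for m_idx, pat in enumerate(consensus.motifs):
            for p in range(len(pep) - len(pat) + 1):
                if p == planted.get(m_idx):
                    continue
                if not consensus.matches_at(pep, p, m_idx):
                    continue
                for k, ch in enumerate(pat):
                    if ch == "x" or p + k in protected:
                        continue
                    allowed = (
                        consensus.class_sets[ch] if ch in consensus.class_sets else {ch}
                    )
                    repl = next(a for a in AMINO_ACIDS if a not in allowed)
                    peptide[p + k] = repl
                    edited = True
                    break
                if edited:
                    break
            if edited:
                break
        if not edited:
            return


# ------------------------------------------------------------------ gen_helitron

def gen_helitron(
    spec: HelitronSpec, seed: int, *, consensus: RepConsensus | None = None
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Emit one host sequence carrying a planted autonomous Helitron.

    The element carries, at known coordinates: the 5' terminal motif at its
    start, an instantiation of the (possibly degenerate) 3' terminal motif at
    its end, a stem-loop of the requested geometry ending
    ``hairpin_offset_from_3prime`` bp before the 3' terminus, and an ORF whose
    translation contains one instantiation of each Rep-consensus motif, in
    order.  The host flank upstream ends with the 5' insertion nucleotide
    (canonically A) and the downstream flank starts with the 3' one (T).
    """
    spec.validate()
    if consensus is None:
        consensus = default_rep_consensus()
    rng = np.random.default_rng(seed)

    L = spec.total_length
    element = list(random_dna(rng, L, spec.gc_content))

    # terminal motifs
    element[0 : len(spec.term5_motif)] = list(spec.term5_motif)
    term3 = _instantiate_iupac(rng, spec.term3_motif)
    element[L - len(term3) :] = list(term3)

    # hairpin: arm1 + loop + revcomp(arm1), ending offset bp before the 3' end
    stem, loop = spec.hairpin_stem, spec.hairpin_loop
    hp_end = L - spec.hairpin_offset_from_3prime
    hp_start = hp_end - (2 * stem + loop)
    arm1 = random_dna(rng, stem, 0.5)
    loop_seq = random_dna(rng, loop, spec.gc_content)
    element[hp_start : hp_start + stem] = list(arm1)
    element[hp_start + stem : hp_start + stem + loop] = list(loop_seq)
    element[hp_start + stem + loop : hp_end] = list(revcomp(arm1))
    _break_pair(element, hp_start - 1, hp_end)  # no outward stem extension
    if loop >= 2:  # no inward extension eating the loop
        _break_pair(element, hp_start + stem, hp_end - stem - 1)

    # ORF flanked by stop-codon guards in all three frames
    orf_end = hp_start - 16
    orf_start = orf_end - spec.orf_length
    n_aa = spec.orf_length // 3 - 2  # residues after Met, before stop
    peptide = [AMINO_ACIDS[i] for i in rng.integers(len(AMINO_ACIDS), size=n_aa)]
    motif_positions = _motif_layout(n_aa, consensus)
    motif_truth = []
    planted = {}
    for m_idx, aa_pos in enumerate(motif_positions):
        inst = _instantiate_protein_motif(rng, consensus.motifs[m_idx], consensus.class_sets)
        peptide[aa_pos : aa_pos + len(inst)] = list(inst)
        planted[m_idx] = aa_pos
        motif_truth.append((m_idx, aa_pos + 1, len(inst)))  # +1: Met is residue 0
    _scrub_chance_motifs(peptide, consensus, planted)
    orf_seq = "ATG" + _codons_for(rng, "".join(peptide)) + "TAA"
    element[orf_start:orf_end] = list(orf_seq)
    element[orf_start - len(_STOP_GUARD) : orf_start] = list(_STOP_GUARD)
    element[orf_end : orf_end + len(_STOP_GUARD)] = list(_STOP_GUARD)

    # host flanks: insertion between A and T, inert for the terminal motifs
    flank5 = list(random_dna(rng, spec.flank5_length, spec.gc_content))
    flank5[-1] = spec.insertion_flank5
    _scrub_pattern(flank5, spec.term5_motif, 0, len(flank5), frozenset({len(flank5) - 1}))
    flank3 = list(random_dna(rng, spec.flank3_length, spec.gc_content))
    flank3[0] = spec.insertion_flank3
    _scrub_pattern(flank3, spec.term3_motif, 0, len(flank3), frozenset({0}))

    seq = "".join(flank5) + "".join(element) + "".join(flank3)
    f = len(flank5)
    truth = [
        TruthRecord(
            "helitron",
            ((f, f + L),),
            {
                "term5": spec.term5_motif,
                "term3": term3,
                "strand": "+",
                "insertion_flank5": spec.insertion_flank5,
                "insertion_flank3": spec.insertion_flank3,
            },
        ),
        TruthRecord(
            "orf",
            ((f + orf_start, f + orf_end),),
            {"strand": "+", "length_bp": spec.orf_length},
        ),
        TruthRecord(
            "hairpin",
            ((f + hp_start, f + hp_end),),
            {
                "stem": stem,
                "loop": loop,
                "offset_from_3prime": spec.hairpin_offset_from_3prime,
            },
        ),
    ]
    for m_idx, aa_pos, w in motif_truth:
        g0 = f + orf_start + 3 * aa_pos
        truth.append(
            TruthRecord(
                "motif",
                ((g0, g0 + 3 * w),),
                {"motif_index": m_idx, "protein_pos": aa_pos},
            )
        )
    _check_truth(truth, len(seq))
    record = SequenceRecord(id=f"helitron_seed{seed}", seq=seq)
    return record, truth


def _motif_layout(n_aa: int, consensus: RepConsensus) -> list[int]:
    """Non-overlapping, ordered protein positions for the consensus motifs."""
    k = len(consensus.motifs)
    widths = [len(p) for p in consensus.motifs]
    if n_aa >= 260 and k == 3:
        positions = [60, 140, 230]
    else:
        step = n_aa // (k + 2)
        positions = [step * (i + 1) for i in range(k)]
    for i in range(1, k):
        if positions[i] < positions[i - 1] + widths[i - 1]:
            raise SpecError("ORF too short to plant all consensus motifs")
    if positions[-1] + widths[-1] > n_aa:
        raise SpecError("ORF too short to plant all consensus motifs")
    return positions


# ------------------------------------------------------------------ gen_proviral_locus

def gen_proviral_locus(
    spec: ProviralLocusSpec, seed: int
) -> tuple[SequenceRecord, list[TruthRecord]]:
    """Emit a proviral-locus fixture with planted repeat architecture.

    Layout (5' to 3'): direct-repeat pair (copy, spacer, copy), the tandem
    array, then the AT-rich palindromic motifs, all separated by random pads.
    Guard bases at every feature boundary prevent chance extension of the
    planted periodicities into the background.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    gc = spec.gc_content

    chunks: list[str] = []
    truth: list[TruthRecord] = []
    pos = 0

    def emit(s: str) -> int:
        nonlocal pos
        chunks.append(s)
        start = pos
        pos += len(s)
        return start

    emit(random_dna(rng, 200, gc))

    # --- direct repeat pair
    dl, ds = spec.direct_repeat_length, spec.direct_repeat_spacer
    unit = random_dna(rng, dl, gc)
    copy2 = list(unit)
    n_mut = round((1.0 - spec.direct_repeat_identity) * dl)
    if n_mut:
        # mutations stay clear of the copy edges so the pair's planted
        # boundaries remain the detectable ones
        margin = min(8, max(0, (dl - n_mut) // 2 - 1))
        sites = rng.choice(dl - 2 * margin, size=n_mut, replace=False) + margin
        for s_i in sorted(int(x) for x in sites):
            copy2[s_i] = _different_base(rng, copy2[s_i])
    spacer = list(random_dna(rng, ds, gc))
    dr1_start = emit(unit)
    sp_start = emit("".join(spacer))
    dr2_start = emit("".join(copy2))
    pad_b = list(random_dna(rng, 300, gc))
    pad_b_start = emit("".join(pad_b))
    truth.append(
        TruthRecord(
            "direct_repeat",
            ((dr1_start, dr1_start + dl), (dr2_start, dr2_start + dl)),
            {
                "unit_length": dl,
                "spacer": ds,
                "identity": round(1.0 - n_mut / dl, 6),
            },
        )
    )

    # --- tandem array (exact copies)
    tu, tc = spec.tandem_unit_length, spec.tandem_copies
    t_unit = random_dna(rng, tu, gc)
    arr_start = emit(t_unit * tc)
    pad_c = list(random_dna(rng, 200, gc))
    pad_c_start = emit("".join(pad_c))
    truth.append(
        TruthRecord(
            "tandem_array",
            ((arr_start, arr_start + tu * tc),),
            {"unit_length": tu, "copies": tc, "identity": 1.0},
        )
    )

    # --- AT-rich palindromic motifs
    at = spec.motif_at_content
    p_at = [at / 2, (1 - at) / 2, (1 - at) / 2, at / 2]
    ps, pl = spec.motif_palindrome_stem, spec.palindrome_loop
    for _ in range(spec.motif_count):
        idx = rng.choice(4, size=spec.motif_length, p=p_at)
        motif = list(_BASES[idx].tobytes().decode())
        arm = random_dna(rng, ps, 0.5)
        loop_gc = min(max(1.0 - at, 0.05), 0.95)
        pal = arm + random_dna(rng, pl, loop_gc) + revcomp(arm)
        c0 = (spec.motif_length - len(pal)) // 2
        motif[c0 : c0 + len(pal)] = list(pal)
        _break_pair(motif, c0 - 1, c0 + len(pal))
        if pl >= 2:
            _break_pair(motif, c0 + ps, c0 + ps + pl - 1)
        m_start = emit("".join(motif))
        emit(random_dna(rng, 120, gc))
        truth.append(
            TruthRecord(
                "motif",
                ((m_start, m_start + spec.motif_length),),
                {
                    "at_content_target": at,
                    "palindrome_stem": ps,
                    "palindrome_interval": [m_start + c0, m_start + c0 + len(pal)],
                },
            )
        )

    seq = list("".join(chunks))

    # --- guard bases (work on the assembled sequence)
    # direct pair: break diagonal extension on both sides
    for k in (1, 2):
        if seq[dr1_start - k] == seq[dr2_start - k]:
            seq[dr2_start - k] = _different_base(rng, seq[dr2_start - k])
    for k in (0, 1):
        if seq[dr1_start + dl + k] == seq[dr2_start + dl + k]:
            seq[dr2_start + dl + k] = _different_base(rng, seq[dr2_start + dl + k])
    # tandem array: break the period at both boundaries
    for k in (1, 2):
        if seq[arr_start - k] == t_unit[tu - k]:
            seq[arr_start - k] = _different_base(rng, seq[arr_start - k])
    arr_end = arr_start + tu * tc
    for k in (0, 1):
        if seq[arr_end + k] == t_unit[k]:
            seq[arr_end + k] = _different_base(rng, seq[arr_end + k])

    record = SequenceRecord(id=f"proviral_locus_seed{seed}", seq="".join(seq))
    _check_truth(truth, len(record.seq))
    return record, truth


# ------------------------------------------------------------------ mutate_to_K

_MODELS = ("JC", "K2P", "T92")


def _rate_matrix(model: str, theta: float, kappa: float) -> tuple[np.ndarray, np.ndarray]:
    """Rate matrix (order ACGT) scaled to one expected substitution per unit K."""
    if model == "JC":
        pi = np.full(4, 0.25)
        kap = 1.0
    elif model == "K2P":
        pi = np.full(4, 0.25)
        kap = kappa
    elif model == "T92":
        pi = np.array([(1 - theta) / 2, theta / 2, theta / 2, (1 - theta) / 2])
        kap = kappa
    else:
        raise HeltraceError(f"unknown substitution model {model!r}; use one of {_MODELS}")
    transitions = {(0, 2), (2, 0), (1, 3), (3, 1)}  # A<->G, C<->T
    Q = np.zeros((4, 4))
    for i in range(4):
        for j in range(4):
            if i == j:
                continue
            Q[i, j] = pi[j] * (kap if (i, j) in transitions else 1.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    scale = -float(pi @ np.diag(Q))
    return Q / scale, pi


def mutate_to_K(
    seq: SequenceRecord,
    K_target: float,
    model: str = "K2P",
    seed: int = 0,
    *,
    kappa: float = 4.0,
) -> SequenceRecord:
    """Return a copy diverged from ``seq`` by an expected K substitutions/site.

    Substitutions are drawn site-independently from the transition-probability
    matrix ``expm(Q*K)`` of the named model (uniform rates across sites, no
    indels), so the model-corrected distance estimator is consistent for
    ``K_target``.  For T92 the GC parameter is taken from the input sequence.
    """
    if not seq.seq:
        raise HeltraceError("cannot mutate an empty sequence")
    if not math.isfinite(K_target) or K_target < 0:
        raise HeltraceError(f"K_target must be a finite non-negative number, got {K_target}")
    if K_target > 100:
        raise SaturationError(
            f"K_target={K_target} is beyond model saturation; divergence this deep "
            "is indistinguishable from random sequence"
        )
    if K_target == 0:
        return replace(seq)
    theta = gc_fraction(seq.seq) if model == "T92" else 0.5
    Q, _ = _rate_matrix(model, theta, kappa)
    P = expm(Q * K_target)
    P = np.clip(P, 0, None)
    P /= P.sum(axis=1, keepdims=True)

    rng = np.random.default_rng(seed)
    idx = np.frombuffer(seq.seq.encode(), dtype="S1")
    out = np.empty(len(seq.seq), dtype="S1")
    codes = np.full(len(seq.seq), -1, dtype=np.int64)
    for b, i in _BASE_INDEX.items():
        codes[idx == b.encode()] = i
    if (codes < 0).any():
        bad = int(np.flatnonzero(codes < 0)[0])
        raise HeltraceError(
            f"non-ACGT character {seq.seq[bad]!r} at position {bad}; "
            "mutate_to_K requires unambiguous DNA"
        )
    for b in range(4):
        mask = codes == b
        n = int(mask.sum())
        if n:
            out[mask] = _BASES[rng.choice(4, size=n, p=P[b])]
    return SequenceRecord(
        id=f"{seq.id}|K{K_target:g}", seq=out.tobytes().decode(), taxon=seq.taxon,
        region=seq.region,
    )


# ------------------------------------------------------------------ gen_ht_scenario

def _node_label(node: dendropy.Node) -> str:
    if node.taxon is not None:
        return node.taxon.label
    return node.label or ""


def gen_ht_scenario(
    species_tree,
    donor: str,
    recipient: str,
    ht_age_years: float,
    clock: ClockParams,
    seed: int,
    *,
    carriers: set[str] | None = None,
    seq_length: int = 1500,
    gc: float = 0.35,
    model: str = "K2P",
) -> tuple[list[SequenceRecord], list[TruthRecord]]:
    """Simulate TE copies across a dated species tree with one HT event.

    ``species_tree`` is an ultrametric tree (newick string/path or a dendropy
    Tree) with branch lengths in millions of years.  Copies of carrier taxa
    descend vertically from a single ancestral copy at the root; the
    recipient's copy instead derives from the donor's, with the two diverging
    for ``ht_age_years`` on each side.  Branch years are converted to
    generations with the mean of the two clock gen/yr values, and to expected
    substitutions/site with ``clock.mu``.  Non-carriers emit nothing.
    """
    clock.validate()
    if isinstance(species_tree, dendropy.Tree):
        tree = species_tree.clone(depth=1)
    else:
        from .io import read_newick

        tree = read_newick(species_tree)
    leaves = {_node_label(lf) for lf in tree.leaf_node_iter()}
    for taxon in (donor, recipient):
        if taxon not in leaves:
            raise HeltraceError(f"unknown taxon {taxon!r}: not a leaf of the species tree")
    if carriers is None:
        carriers = set(leaves)
    if not carriers <= leaves:
        raise HeltraceError(f"unknown carrier taxa: {sorted(carriers - leaves)}")
    if donor not in carriers or recipient not in carriers:
        raise HeltraceError("donor and recipient must both be carriers")

    g = 0.5 * (clock.gen_per_year_a + clock.gen_per_year_b)
    mu = clock.mu

    # split age of donor and recipient, in years (branch lengths are MY)
    pdm = tree.phylogenetic_distance_matrix()
    tax = {t.label: t for t in tree.taxon_namespace}
    split_years = 0.5 * pdm.distance(tax[donor], tax[recipient]) * 1e6
    if ht_age_years > split_years * (1 + 1e-9):
        raise HeltraceError(
            f"ht_age_years ({ht_age_years:g}) exceeds the donor-recipient "
            f"split age ({split_years:g} years)"
        )

    rng = np.random.default_rng(seed)
    root_seq = SequenceRecord(id="ancestor", seq=random_dna(rng, seq_length, gc))
    tree.seed_node._heltrace_seq = root_seq
    leaf_seqs: dict[str, SequenceRecord] = {}
    for node in tree.preorder_node_iter():
        if node is tree.seed_node:
            pass
        else:
            parent_seq = node.parent_node._heltrace_seq
            years = (node.edge.length or 0.0) * 1e6
            K_edge = mu * g * years
            node._heltrace_seq = mutate_to_K(
                parent_seq, K_edge, model=model, seed=int(rng.integers(2**31))
            )
        if node.is_leaf():
            leaf_seqs[_node_label(node)] = node._heltrace_seq

    K_ht = 2 * mu * g * ht_age_years
    recipient_seq = mutate_to_K(
        leaf_seqs[donor], K_ht, model=model, seed=int(rng.integers(2**31))
    )

    records = []
    for taxon in sorted(carriers):
        src = recipient_seq if taxon == recipient else leaf_seqs[taxon]
        records.append(SequenceRecord(id=taxon, seq=src.seq, taxon=taxon))
    truth = [
        TruthRecord(
            "ht_event",
            ((0, seq_length),),
            {
                "donor": donor,
                "recipient": recipient,
                "ht_age_years": ht_age_years,
                "planted_K": K_ht,
                "vertical_K": 2 * mu * g * split_years,
            },
        )
    ]
    return records, truth
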