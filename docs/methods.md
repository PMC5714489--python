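# Methods

## Scope and model

`heltrace` analyses the situation in which an autonomous Helitron transposon
is embedded in (and nearly coextensive with) a bracovirus segment, and the
same element appears with implausibly high identity in distantly related
insect orders. The package covers annotation of the element's structural
hallmarks, characterisation of the repeat architecture of the proviral locus
around it, cross-genome copy screening, divergence estimation, distance-tree
building, horizontal-transfer (HT) flagging, and molecular-clock dating.
Tree inference is distance-based neighbor-joining throughout: at the desk
scale this package targets (tens of taxa, kilobase alignments), NJ on an
additive matrix is exact, deterministic and cheap, and Bayesian/ML inference
is deliberately out of scope.

## Helitron annotation

An element is recognised by the *conjunction* of hallmarks, not by homology:

* terminal motifs — 5′ `TC`, 3′ `CTRR` (IUPAC `R` = A/G) by default. These
  are the canonical Helitron termini from the literature; the package treats
  them as configuration, not constants, because individual families deviate.
* a stem-loop whose 3′ arm lies within a window (default 40 bp) of the
  element's 3′ terminus. The hairpin search scores `stem − mismatches`
  (default: stem ≥ 5, loop ≤ 12, ≤ 1 mismatch); ties prefer the smaller
  offset from the 3′ terminus, then **fewer mismatches**, then the smaller
  loop. The mismatch tie-break matters: a perfect stem-8/loop-4 hairpin
  always ties in score and offset with a stem-9/loop-2 reading that spends a
  mismatch on the ring just outside the loop, and the geometry actually
  planted/folded is the mismatch-free one.
* insertion between host `A` and `T`: the base immediately 5′ of the element
  must be `A` and the base immediately 3′ must be `T`.
* a Rep/Helicase ORF (maximal ATG→stop spans, both strands, standard code)
  whose translation carries the three Rep catalytic-core motifs in
  N→C order. Motifs are degenerate patterns over exact residues plus the
  classes `h` (hydrophobic = AVLIMFWYC), `s` (small = AGSTCNDP) and `x`
  (any). The shipped three-motif consensus
  (`src/heltrace/data/rep_consensus.yaml`) is an editable default in the
  canonical style of published Rep-core summaries, not a transcription of
  any single alignment figure.

`annotate_helitron` enumerates every termini-compatible candidate interval,
scores the four non-terminal hallmarks, and returns the candidate with the
most hallmarks (ties to the longest element, then the leftmost; forward
strand preferred over reverse on full ties). Candidates scoring fewer than
`min_hallmarks` (default 3) are rejected, so random sequence normally yields
no annotation. Coverage is `100·element/segment`; the family rule compares
ungapped identity over the last 30 bp of two 3′ termini with an *inclusive*
80% threshold (exactly 80% ⇒ same family; "below 80%" ⇒ different).

## Copy screening

`screen_copies` is exact affine-gap local alignment (Biopython's
`PairwiseAligner`): match +2, mismatch −3, and gap costs 5 + 2k for a gap of
length k (open −7 / extend −2 in Biopython's convention, which charges the
opening score on the first gap column). Both strands are searched; found
intervals are masked with `N` and the search repeats, so multiple copies are
reported. A hit must have query cover strictly > 0.70 and identity strictly
> 0.80 by default ("cover" = aligned query positions / query length;
"identity" = matches / aligned columns excluding gaps — the two quantities
screening pipelines usually mean but rarely define). Raw hit collection is
independent of the thresholds, so loosening a filter can only add hits.

## Repeat architecture

* **Tandem arrays**: for each candidate period u the sequence is compared
  with itself shifted by u; maximal (near-)match runs are chained (a gap of
  g mismatches is bridged only when both the incoming run and the
  accumulated score exceed 3g, so chains start and end on matches) and a
  chain of length ℓ is an array spanning ℓ+u bp with ⌊(ℓ+u)/u⌋ full copies.
  Arrays are reported at maximal extent — including partial-unit
  continuation — with the smallest primitive unit (harmonics u, 2u, 3u…
  covering ≥90% of the same span are suppressed, including homopolymer
  period-1 runs). Identity is computed against the per-column majority
  consensus of the copies, which keeps copy counts stable under scattered
  mutations. A degenerate array must still contain a mismatch-free stretch
  of min(8, u) bp to seed detection.
* **Direct repeats**: the same per-offset scan; a chained segment of length
  ℓ at offset d is a pair with spacer d − ℓ, kept when ℓ ≥ min_len,
  0 < spacer ≤ max_spacer and identity ≥ min_identity. Two suppressions make
  the output mean what "direct-repeat pair" means in locus maps: overlapping
  pairs (ℓ ≥ d) are dropped, and *array-internal* pairs are dropped by the
  spacer-periodicity test (if the spacer matches the start of the first copy
  at ≥ min_identity, the "pair" is just periodic continuation of a tandem
  array). Without the second rule a 6×396 exact array would emit a spurious
  792-bp "pair" outranking a genuine 376-bp one.
* **Inverted repeats**: arms grow outward from every loop placement
  (loop ≤ max_loop) until the mismatch budget runs out, then are trimmed to
  the outermost complementary pair; maximal hits per (center, loop) are all
  reported, overlapping or not — consumers filter. Stem-loop plausibility is
  scored combinatorially (arm length, mismatches); no thermodynamic ΔG is
  computed.
* **AT content** is (A+T)/(unambiguous bases); ambiguity codes are excluded
  from numerator and denominator.

## Divergence and trees

Distances come from transition (P) and transversion (Q) fractions counted
with pairwise deletion (columns with a gap or ambiguity in either sequence
are dropped; on the short noncoding flank alignments this keeps the most
sites). With h = 2θ(1−θ), θ the mean GC of the pair over used columns:

* p-distance: K = P + Q
* JC:  K = −(3/4)·ln(1 − (4/3)(P+Q))
* K2P: K = −(1/2)·ln(1 − 2P − Q) − (1/4)·ln(1 − 2Q)
* T92: K = −h·ln(1 − P/h − Q) − (1/2)(1−h)·ln(1 − 2Q)

θ is estimated per pair, matching the per-pair T92 definition; T92 reduces
exactly to K2P at θ = 0.5. A non-positive logarithm argument marks the
result *saturated*: a flagged value, not an exception, so matrices stay
constructible; trees and dates refuse saturated inputs explicitly. K2P is
the default model (the transition/transversion correction is wanted; the
GC correction is optional refinement).

Neighbor-joining uses the standard Q-criterion with two determinism
refinements: ties are broken by the lexicographically smallest taxon-label
pair, and a negative branch length is clamped to zero with the deficit moved
to the sibling so the pair's total is preserved. On additive matrices the
algorithm reproduces the generating tree's path lengths exactly (tested
against an independent NJ implementation and against the input metric).

## HT flagging

For a cross-group (different taxonomic order) pair with host split time t
(MY), per-generation rate µ and pair-averaged generations/year g, vertical
descent predicts K_exp = 2µ·(t·10⁶·g). The identity test flags the pair when
K_obs/K_exp < 0.01; real HT cases sit 3–4 orders of magnitude below
expectation, so 0.01 is conservative while remaining testable on small
simulations. Three corroborating flags are attached, never gating alone:

* *incongruence*: the pair is mutual-nearest in the NJ element tree but not
  by host divergence times (a nearest-neighbour rank comparison — robust on
  small matrices, and the same form of argument as clade-membership
  incongruence);
* *patchiness*: Dollo loss count (single gain at the carriers' MRCA; each
  maximal carrier-free subtree below it is one loss) above a loss budget
  (default 1);
* *geography*: same label from a coarse eight-region controlled vocabulary.
  Range overlap is necessary for contact but never sufficient for a flag.

A missing divergence time for an evaluated pair is an error: the ratio is
undefined without it.

## Dating

T = K/2r generations for two neutrally evolving copies, with r ≡ µ under
neutrality. Defaults: µ = 3.0×10⁻⁹ substitutions/site/generation (direct
insect mutation-rate measurements); generations/year supplied per taxon and
averaged per pair (10 and 18 gen/yr average to 14; 18 and 4 to 11). Because
neutrality of the compared noncoding regions is an assumption, two bounds
are reported — minimum T = K/2µ (both copies neutral) and maximum T = K/µ
(one copy effectively static) — so t_max = 2·t_min identically, and the
central date is their midpoint (1.5·t_min). The midpoint is a design choice:
it is the only simple rule consistent with reporting a central value
bracketed by those bounds, and it is stated as such rather than attributed
to any external convention. Dates are reported in MYA to 3 significant
figures, and every human-readable report carries the neutrality caveat.

## Synthetic data: what it emulates, and what it does not

The generator produces the study conditions the detectors are validated
under, with truth records (0-based half-open internally; GFF3 written
1-based closed) for every planted feature.

* `gen_helitron` defaults: 5294-bp element inside a 5667-bp host record
  (flanks 186+187 = 373 bp, so element coverage is 93.4%); ORF 4539 bp — the
  codon multiple nearest the reported element geometry, leaving 755 bp ≈
  750 bp of intra-element noncoding flank; `TC`/`CTRR` termini; stem 8/loop
  4 hairpin ending 11 bp upstream of the 3′ terminus; insertion between
  A and T; background GC 0.35 (AT-rich, as in the real locus context —
  AT-richness drives palindrome false positives, so it must be the tested
  regime).
* `gen_proviral_locus` defaults: one 376-bp direct-repeat pair at 99.5%
  identity separated by 426 bp, a 396-bp × 6 exact tandem array, and eight
  150-bp motifs at AT 0.71 each containing a stem-10 palindrome.
* **Identifiability guards.** Planted truth is made *exactly* recoverable on
  mutation-free output: host flanks are scrubbed of terminal-motif matches,
  guard bases at feature boundaries break chance extension of stems, arrays
  and repeat pairs, chance instantiations of Rep motifs in the random
  peptide are edited out, and the direct-repeat identity mutations are
  placed ≥ 8 bp from the copy edges. Without these guards "recover the
  planted interval exactly" is not a well-posed contract — a 2-bp terminal
  motif recurs by chance every ~18 bp of random AT-rich sequence.
* `mutate_to_K` evolves sites i.i.d. under the chosen model's
  transition-probability matrix `expm(Q·K)` (rates scaled to one expected
  substitution per unit K; transition/transversion rate ratio κ = 4 for
  K2P/T92; T92 stationary GC taken from the input sequence). No indels, no
  rate heterogeneity across sites, no selection — the simplest process
  consistent with the clock arithmetic, which is exactly what the estimators
  assume. Recovery is calibrated: over 100 replicates at K ∈ {0.01, 0.05,
  0.2} the mean re-estimated K is within 3 standard errors of the target for
  every model (enforced by the test suite).
* `gen_ht_scenario` evolves one ancestral copy down an ultrametric species
  tree (branch lengths in MY), converting years to generations with the mean
  of the two clock gen/yr values; the recipient's copy derives from the
  donor's with 2µg·age expected substitutions. A transfer as old as the
  donor–recipient split is statistically indistinguishable from vertical
  descent (the null case the flagging tests exercise).

Passing tests on this generator therefore demonstrates correctness of the
detectors and estimators under the stated model — not robustness to indels,
nested/fragmented elements, segmental duplications, sequencing error, or
non-neutral evolution, none of which the generator produces.

## Numerical and degenerate-input conventions

Invalid specs fail fast naming the violated invariant (e.g. a zero-length
hairpin stem is rejected rather than emitting a degenerate hairpin). K = 0
dates to zero; negative K, empty flanks, empty carrier sets, ragged
alignments and non-DNA characters raise typed errors naming the offence.
`mutate_to_K` rejects K > 100 as beyond saturation. All generators are
byte-deterministic per (spec, seed); every stochastic stage of the pipeline
takes an explicit seed, and the pipeline stamps outputs with a config hash
so identical (config, seed) reruns are byte-identical and partial reruns
resume from completed stages.

## Problem sizes

The shipped tests and the reproduction script run at desk scale by design:
200 replicates × 750 bp for date recovery, 100 replicates × 5 kb for
estimator calibration, trees of ≤ 8 leaves, loci of ~6 kb. These sizes make
the statistical checks (3-standard-error bands) meaningful while keeping
the whole suite in well under a minute per module.

## Known limitations

Genome-scale heuristic search (seeding/indexing), nonautonomous or
fragmented element families, protein-domain HMMs, thermodynamic folding,
bootstrap support, relaxed clocks and fossil calibration are all out of
scope. The incongruence flag is a nearest-neighbour comparison, not a full
topology distance; it reports evidence, not verdicts, and pairs outside the
flagged clade deserve case-by-case analysis.
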