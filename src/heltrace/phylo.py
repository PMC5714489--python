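"""Distance trees, incongruence, patchiness, and horizontal-transfer flagging.

Horizontal transfer of a transposable element is inferred from four lines of
evidence: (i) anomalously high sequence identity between copies from species
whose hosts diverged long ago (the observed K is orders of magnitude below
the neutral vertical-descent expectation), (ii) incongruence between the
element tree and the species tree, (iii) a patchy presence/absence pattern
requiring many independent losses under vertical descent, and (iv) overlap
of the candidate species' geographic ranges.  Only the identity ratio gates
a candidate; the other three are corroborating flags.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import dendropy

from .distance import DistanceMatrix
from .errors import HeltraceError, SaturationError


# ------------------------------------------------------------------ NJ

def nj_tree(matrix: DistanceMatrix) -> dendropy.Tree:
    """Neighbor-joining tree from a distance matrix.

    Standard agglomeration with two refinements for reproducibility: ties in
    the Q criterion are broken by the lexicographically smallest taxon-label
    pair, and negative branch lengths are clamped to zero with the deficit
    moved to the sibling branch (total preserved).
    """
    if matrix.any_saturated:
        raise SaturationError(
            "distance matrix contains saturated cells; re-estimate with a "
            "different model before building a tree"
        )
    n0 = len(matrix.ids)
    if n0 < 2:
        raise HeltraceError("need at least two taxa")

    ns = dendropy.TaxonNamespace(matrix.ids)
    nodes: dict[str, dendropy.Node] = {}
    for label in matrix.ids:
        node = dendropy.Node()
        node.taxon = ns.get_taxon(label)
        nodes[label] = node
    # cluster key = lexicographically smallest leaf label inside it
    d: dict[frozenset, float] = {}
    for i in range(n0):
        for j in range(i + 1, n0):
            d[frozenset((matrix.ids[i], matrix.ids[j]))] = float(matrix.values[i, j])
    active = sorted(matrix.ids)

    while len(active) > 2:
        m = len(active)
        r = {a: sum(d[frozenset((a, b))] for b in active if b != a) for a in active}
        best = None
        best_pair = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                a, b = active[ii], active[jj]
                q = (m - 2) * d[frozenset((a, b))] - r[a] - r[b]
                key = (q, a, b)
                if best is None or key < best:
                    best = key
                    best_pair = (a, b)
        a, b = best_pair
        dab = d[frozenset((a, b))]
        la = 0.5 * dab + (r[a] - r[b]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            la, lb = 0.0, dab
        if lb < 0:
            la, lb = dab, 0.0
        parent = dendropy.Node()
        na, nb = nodes.pop(a), nodes.pop(b)
        parent.add_child(na)
        parent.add_child(nb)
        na.edge.length = la
        nb.edge.length = lb
        new_key = min(a, b)
        for c in active:
            if c in (a, b):
                continue
            duc = 0.5 * (d[frozenset((a, c))] + d[frozenset((b, c))] - dab)
            d[frozenset((new_key, c))] = max(duc, 0.0)
        active = sorted([c for c in active if c not in (a, b)] + [new_key])
        nodes[new_key] = parent

    a, b = active
    dab = d[frozenset((a, b))] if len(matrix.ids) > 1 else 0.0
    root = dendropy.Node()
    na, nb = nodes[a], nodes[b]
    root.add_child(na)
    root.add_child(nb)
    na.edge.length = dab / 2
    nb.edge.length = dab / 2
    tree = dendropy.Tree(taxon_namespace=ns, seed_node=root)
    tree.is_rooted = False
    return tree


def patristic_distances(tree: dendropy.Tree) -> dict[frozenset, float]:
    pdm = tree.phylogenetic_distance_matrix()
    out = {}
    taxa = list(tree.taxon_namespace)
    for i, t1 in enumerate(taxa):
        for t2 in taxa[i + 1 :]:
            out[frozenset((t1.label, t2.label))] = pdm.distance(t1, t2)
    return out


# ------------------------------------------------------------------ clock expectation

def expected_K_vertical(split_mya: float, mu: float, gen_per_year: float) -> float:
    """K expected between two copies under vertical descent since a split.

    Both lineages accumulate substitutions: K = 2 * mu * generations, with
    generations = split_mya * 1e6 * gen_per_year.
    """
    if min(split_mya, mu, gen_per_year) < 0:
        raise HeltraceError("all clock arguments must be non-negative")
    return 2.0 * mu * split_mya * 1e6 * gen_per_year


# ------------------------------------------------------------------ patchiness

def _leaf_label(node: dendropy.Node) -> str:
    return node.taxon.label if node.taxon is not None else (node.label or "")


def patchiness_losses(species_tree: dendropy.Tree, carriers: set[str]) -> int:
    """Minimum loss count explaining a presence/absence pattern (Dollo).

    The element is gained once at the MRCA of the carriers; every maximal
    carrier-free subtree below that node is one independent loss.  Zero iff
    the carriers form a clade.
    """
    if not carriers:
        raise HeltraceError("carrier set must be non-empty")
    leaves = {_leaf_label(lf) for lf in species_tree.leaf_node_iter()}
    unknown = set(carriers) - leaves
    if unknown:
        raise HeltraceError(f"unknown carrier taxa: {sorted(unknown)}")

    has_carrier: dict[int, bool] = {}
    for node in species_tree.postorder_node_iter():
        if node.is_leaf():
            has_carrier[id(node)] = _leaf_label(node) in carriers
        else:
            has_carrier[id(node)] = any(
                has_carrier[id(c)] for c in node.child_nodes()
            )
    # MRCA of carriers: deepest node whose subtree holds all carriers
    target = len(set(carriers))

    def count_in(node) -> int:
        if node.is_leaf():
            return 1 if _leaf_label(node) in carriers else 0
        return sum(count_in(c) for c in node.child_nodes())

    mrca = species_tree.seed_node
    descend = True
    while descend:
        descend = False
        for c in mrca.child_nodes():
            if count_in(c) == target:
                mrca = c
                descend = True
                break
    losses = 0
    stack = [mrca]
    while stack:
        node = stack.pop()
        for c in node.child_nodes():
            if has_carrier[id(c)]:
                stack.append(c)
            else:
                losses += 1
    return losses


# ------------------------------------------------------------------ metadata

#: the coarse controlled vocabulary of major geographical regions
REGIONS = (
    "east_southeast_asia",
    "south_asia",
    "europe",
    "africa",
    "north_america",
    "south_america",
    "oceania",
    "cosmopolitan",
)


@dataclass
class SpeciesMeta:
    """Per-taxon metadata: region, taxonomic group (order), generations/year."""

    taxon: str
    region: str
    group: str
    gen_per_year: float

    def validate(self) -> None:
        if self.region not in REGIONS:
            raise HeltraceError(
                f"region {self.region!r} not in controlled vocabulary {REGIONS}"
            )
        if self.gen_per_year <= 0:
            raise HeltraceError("gen_per_year must be positive")


class SpeciesTable:
    """A set of SpeciesMeta plus symmetric pairwise divergence times (MYA)."""

    def __init__(self, entries: list[SpeciesMeta], divergence_times: dict):
        self.entries = {e.taxon: e for e in entries}
        for e in entries:
            e.validate()
        self._times: dict[frozenset, float] = {}
        for pair, mya in divergence_times.items():
            self._times[frozenset(pair)] = float(mya)

    def __contains__(self, taxon: str) -> bool:
        return taxon in self.entries

    def meta(self, taxon: str) -> SpeciesMeta:
        return self.entries[taxon]

    def split_mya(self, a: str, b: str) -> float:
        key = frozenset((a, b))
        if key not in self._times:
            raise HeltraceError(f"missing divergence time for pair ({a}, {b})")
        return self._times[key]

    def has_split(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self._times

    @classmethod
    def from_yaml(cls, path) -> "SpeciesTable":
        import yaml
        from pathlib import Path

        data = yaml.safe_load(Path(path).read_text())
        entries = [
            SpeciesMeta(
                taxon=t["taxon"],
                region=t["region"],
                group=t["group"],
                gen_per_year=float(t["gen_per_year"]),
            )
            for t in data["taxa"]
        ]
        times = {
            (p["a"], p["b"]): float(p["mya"]) for p in data.get("divergence_times", [])
        }
        return cls(entries, times)


# ------------------------------------------------------------------ flagging

@dataclass
class HTCandidate:
    """A taxon pair whose TE divergence is anomalously low for its host split."""

    pair: tuple[str, str]
    K_obs: float
    K_exp: float
    ratio: float
    evidence: dict = field(default_factory=dict)


def _nearest(
    taxon: str, others: list[str], dist: dict[frozenset, float]
) -> str | None:
    best = None
    for o in sorted(others):
        key = frozenset((taxon, o))
        if key not in dist:
            continue
        if best is None or dist[key] < dist[frozenset((taxon, best))]:
            best = o
    return best


def flag_ht(
    matrix: DistanceMatrix,
    meta: SpeciesTable,
    ratio_threshold: float = 0.01,
    species_tree: dendropy.Tree | None = None,
    *,
    mu: float = 3.0e-9,
    loss_budget: int = 1,
) -> list[HTCandidate]:
    """Flag cross-group taxon pairs whose K is far below vertical expectation.

    For every pair of matrix taxa from different taxonomic groups the
    expected K under vertical descent is computed from the pair's divergence
    time and averaged gen/yr; the pair is flagged iff K_obs/K_exp falls below
    ``ratio_threshold``.  Flagged candidates carry corroborating evidence:
    ``incongruence`` (the pair is mutual-nearest in the element tree but not
    by host divergence), ``patchiness`` (Dollo losses above ``loss_budget``,
    needs ``species_tree``), ``identity`` (the gating ratio test) and
    ``geography`` (same region).
    """
    missing = [t for t in matrix.ids if t not in meta]
    if missing:
        raise HeltraceError(f"matrix taxa missing from metadata: {missing}")

    te_dist = None
    if not matrix.any_saturated and len(matrix.ids) >= 3:
        te_dist = patristic_distances(nj_tree(matrix))

    losses = None
    if species_tree is not None:
        losses = patchiness_losses(species_tree, set(matrix.ids))

    sp_dist = {
        frozenset((a, b)): meta.split_mya(a, b)
        for i, a in enumerate(matrix.ids)
        for b in matrix.ids[i + 1 :]
        if meta.has_split(a, b)
    }

    candidates = []
    ids = sorted(matrix.ids)
    for i, a in enumerate(ids):
        for b in ids[i + 1 :]:
            if meta.meta(a).group == meta.meta(b).group:
                continue
            K_obs = matrix[a, b]
            split = meta.split_mya(a, b)  # raises if missing
            g = 0.5 * (meta.meta(a).gen_per_year + meta.meta(b).gen_per_year)
            K_exp = expected_K_vertical(split, mu, g)
            if K_exp == 0:
                continue
            ratio = K_obs / K_exp
            if not ratio < ratio_threshold:
                continue
            evidence = {"identity": True}
            evidence["geography"] = meta.meta(a).region == meta.meta(b).region
            if te_dist is not None:
                others_a = [t for t in matrix.ids if t != a]
                others_b = [t for t in matrix.ids if t != b]
                te_nn = _nearest(a, others_a, te_dist) == b or _nearest(
                    b, others_b, te_dist
                ) == a
                sp_nn = _nearest(a, others_a, sp_dist) == b or _nearest(
                    b, others_b, sp_dist
                ) == a
                evidence["incongruence"] = bool(te_nn and not sp_nn)
            if losses is not None:
                evidence["patchiness"] = losses > loss_budget
            candidates.append(
                HTCandidate(pair=(a, b), K_obs=K_obs, K_exp=K_exp, ratio=ratio,
                            evidence=evidence)
            )
    candidates.sort(key=lambda c: c.ratio)
    return candidates
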