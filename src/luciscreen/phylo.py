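"""Distance-based trees and phenotype presence/absence association.

Neighbor joining stands in for ML tree inference: the claims carried by the
trees here are grouping claims (each gene family forms its own clade), and
NJ is deterministic, fast, and exactly recovers additive distances, which
is what the tests assert. Trees are dendropy objects so Newick IO and
traversal use a standard library.

The presence/absence contrast (candidate genes found only in luminous
species) is formalized as a two-sided Fisher exact test computed by
exhaustive hypergeometric enumeration; with 20 luminous species all
carrying the family and 2 non-luminous species lacking it the p-value is
1/C(22,2) = 1/231.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

from .seqio import GAP, MultipleAlignment, PhenotypeTable

__all__ = [
    "DistanceMatrix",
    "PresenceMatrix",
    "protein_distance",
    "nj_tree",
    "monophyly_check",
    "phenotype_association",
    "write_newick",
    "read_newick",
]


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape mismatch")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0):
            raise ValueError("distances must be non-negative")

    @property
    def n(self) -> int:
        return len(self.labels)


@dataclass
class PresenceMatrix:
    """Species x family boolean table plus the phenotype column."""

    species: list[str]
    families: list[str]
    present: np.ndarray  # bool, shape (n_species, n_families)
    phenotypes: PhenotypeTable = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.present = np.asarray(self.present, dtype=bool)
        if self.present.shape != (len(self.species), len(self.families)):
            raise ValueError("presence matrix shape mismatch")
        if self.phenotypes is not None:
            missing = set(self.species) - set(self.phenotypes.species)
            if missing:
                raise ValueError(f"species without phenotype: {sorted(missing)}")


def protein_distance(msa: MultipleAlignment, model: str = "p_distance") -> DistanceMatrix:
    """Pairwise protein distances from an MSA.

    p = mismatches / columns where both rows carry residues; the Poisson
    model applies d = -ln(1 - p). p = 1 under the Poisson model (or a pair
    with no comparable columns) raises, naming the pair.
    """
    if model not in ("p_distance", "poisson"):
        raise ValueError(f"unknown distance model {model!r}")
    ids = msa.ids
    n = len(ids)
    if n < 2:
        raise ValueError("need at least 2 rows")
    rows = [s.upper() for _, s in msa.rows]
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comp = mism = 0
            for ca, cb in zip(rows[i], rows[j]):
                if ca != GAP and cb != GAP:
                    comp += 1
                    if ca != cb:
                        mism += 1
            if comp == 0:
                raise ValueError(f"no comparable columns for pair ({ids[i]}, {ids[j]})")
            p = mism / comp
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError(
                        f"saturated pair ({ids[i]}, {ids[j]}): p = 1, "
                        "Poisson distance undefined"
                    )
                p = -math.log(1.0 - p)
            d[i, j] = d[j, i] = p
    return DistanceMatrix(labels=ids, values=d)


def nj_tree(dm: DistanceMatrix, allow_two: bool = False) -> dendropy.Tree:
    """Saitou-Nei neighbor joining.

    Q-matrix selection with ties broken by the lowest (i, j) index pair;
    negative branch lengths are clamped to 0. Returns an unrooted tree
    (trifurcating seed node) containing every input leaf.
    """
    n = dm.n
    if n < 2 or (n == 2 and not allow_two):
        raise ValueError("neighbor joining needs >= 3 labels (or allow_two=True)")

    taxa = dendropy.TaxonNamespace(dm.labels)
    tree = dendropy.Tree(taxon_namespace=taxa)
    nodes = []
    for lab in dm.labels:
        node = dendropy.Node(taxon=taxa.get_taxon(lab))
        nodes.append(node)

    if n == 2:
        tree.seed_node.add_child(nodes[0])
        tree.seed_node.add_child(nodes[1])
        nodes[0].edge.length = dm.values[0, 1] / 2.0
        nodes[1].edge.length = dm.values[0, 1] / 2.0
        tree.is_rooted = False
        return tree

    active = list(range(n))
    d = dm.values.copy()
    node_of = {i: nodes[i] for i in range(n)}
    next_id = n

    while len(active) > 3:
        m = len(active)
        r = {i: sum(d[i, k] for k in active if k != i) for i in active}
        best = None
        for ai in range(m):
            for aj in range(ai + 1, m):
                i, j = active[ai], active[aj]
                q = (m - 2) * d[i, j] - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2 * (m - 2))
        lj = d[i, j] - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        parent = dendropy.Node()
        parent.add_child(node_of[i])
        parent.add_child(node_of[j])
        node_of[i].edge.length = li
        node_of[j].edge.length = lj
        # distances from the new node
        dnew = np.zeros(d.shape[0] + 1)
        d = np.pad(d, ((0, 1), (0, 1)))
        for k in active:
            if k in (i, j):
                continue
            d[next_id, k] = d[k, next_id] = 0.5 * (d[i, k] + d[j, k] - d[i, j])
        node_of[next_id] = parent
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
        d = d  # grown in place above

    i, j, k = active
    li = 0.5 * (d[i, j] + d[i, k] - d[j, k])
    lj = 0.5 * (d[i, j] + d[j, k] - d[i, k])
    lk = 0.5 * (d[i, k] + d[j, k] - d[i, j])
    for idx, length in ((i, li), (j, lj), (k, lk)):
        tree.seed_node.add_child(node_of[idx])
        node_of[idx].edge.length = max(length, 0.0)
    tree.is_rooted = False
    return tree


def tree_leaf_labels(tree: dendropy.Tree) -> set[str]:
    return {lf.taxon.label for lf in tree.leaf_node_iter()}


def monophyly_check(tree: dendropy.Tree, leaf_set: set[str]) -> bool:
    """True iff some edge bipartition separates exactly ``leaf_set``."""
    all_leaves = tree_leaf_labels(tree)
    unknown = set(leaf_set) - all_leaves
    if unknown:
        raise ValueError(f"leaves not in tree: {sorted(unknown)}")
    target = frozenset(leaf_set)
    if target == frozenset(all_leaves):
        return True
    comp = frozenset(all_leaves - target)
    below: dict[int, frozenset] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            below[id(node)] = frozenset([node.taxon.label])
        else:
            acc = frozenset()
            for ch in node.child_nodes():
                acc |= below[id(ch)]
            below[id(node)] = acc
        if below[id(node)] in (target, comp):
            return True
    return False


def fisher_exact_enumeration(table: np.ndarray) -> float:
    """Two-sided Fisher exact p for a 2x2 table, by summing the exact
    hypergeometric probability of every table (with the same margins) whose
    probability does not exceed the observed one."""
    a, b = int(table[0][0]), int(table[0][1])
    c, dd = int(table[1][0]), int(table[1][1])
    row1, row2 = a + b, c + dd
    col1 = a + c
    ntot = row1 + row2
    if row1 == 0 or row2 == 0:
        raise ValueError("both phenotype classes must be represented")

    def prob(x: int) -> float:
        return (
            math.comb(row1, x)
            * math.comb(row2, col1 - x)
            / math.comb(ntot, col1)
        )

    lo = max(0, col1 - row2)
    hi = min(col1, row1)
    p_obs = prob(a)
    total = sum(
        p for x in range(lo, hi + 1) if (p := prob(x)) <= p_obs * (1 + 1e-9)
    )
    return min(total, 1.0)


def phenotype_association(pm: PresenceMatrix, family: str) -> dict:
    """Association of one family's presence with the luminous phenotype.

    Returns the 2x2 contingency table (rows: luminous / non-luminous,
    columns: present / absent) and the two-sided Fisher exact p. The test
    is an added formalization of the qualitative natural-control argument;
    output labels it as such.
    """
    if family not in pm.families:
        raise KeyError(family)
    fi = pm.families.index(family)
    lum = np.array([pm.phenotypes.luminous(sp) for sp in pm.species])
    if lum.all() or (~lum).all():
        raise ValueError("need at least one species per phenotype")
    pres = pm.present[:, fi]
    table = np.array(
        [
            [int((lum & pres).sum()), int((lum & ~pres).sum())],
            [int((~lum & pres).sum()), int((~lum & ~pres).sum())],
        ]
    )
    return {"contingency": table, "fisher_p": fisher_exact_enumeration(table)}


# ---------------------------------------------------------------------------
# Newick IO (unquoted-label dialect, 6 significant digits)

def _sanitize(label: str) -> str:
    return re.sub(r"[^0-9A-Za-z]", "_", label)


def _newick_node(node: dendropy.Node) -> str:
    if node.is_leaf():
        s = _sanitize(node.taxon.label)
    else:
        s = "(" + ",".join(_newick_node(ch) for ch in node.child_nodes()) + ")"
    if node.edge.length is not None:
        s += f":{node.edge.length:.6g}"
    return s


def write_newick(tree: dendropy.Tree, path: str) -> None:
    with open(path, "w") as fh:
        fh.write(_newick_node(tree.seed_node) + ";\n")


def newick_string(tree: dendropy.Tree) -> str:
    return _newick_node(tree.seed_node) + ";"


def read_newick(path: str) -> dendropy.Tree:
    return dendropy.Tree.get(path=str(path), schema="newick")
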