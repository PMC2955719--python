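"""Per-region neighbor-joining trees and topological discordance.

Concerted evolution by gene conversion shuffles which family members are each
other's closest relatives from one gene region to the next.  Building one
unrooted NJ tree per region and measuring pairwise Robinson-Foulds (RF)
distances between the region trees turns that visual signal into a number:
any off-diagonal RF > 0 flags the family as discordant.

NJ uses the Saitou-Nei Q-criterion with deterministic tie-breaking (lowest
(row, col) index) and clamps negative branch lengths to zero, transferring
the deficit to the sister branch created at the same join.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

from .gene_models import FamilySet, RegionKind


class PhylogenyError(ValueError):
    """Raised for invalid phylogenetic inputs."""


@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray
    model: str = "p_distance"

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise PhylogenyError("matrix shape does not match ids")
        if not np.allclose(np.diag(np.nan_to_num(m)), 0):
            raise PhylogenyError("distance matrix diagonal must be zero")
        if not np.allclose(np.nan_to_num(m), np.nan_to_num(m.T)):
            raise PhylogenyError("distance matrix must be symmetric")
        self.matrix = m


def _pairwise_sites(a: str, b: str) -> tuple[int, int]:
    """(mismatches, compared positions) over ungapped aligned columns."""
    if len(a) != len(b):
        a, b = _align_pair(a, b)
    mism = comp = 0
    for x, y in zip(a, b):
        if x == "-" or y == "-":
            continue
        comp += 1
        if x != y:
            mism += 1
    if comp == 0:
        raise PhylogenyError("all-gap pairwise overlap")
    return mism, comp


def _align_pair(a: str, b: str) -> tuple[str, str]:
    from Bio.Align import PairwiseAligner

    aligner = PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = 2
    aligner.mismatch_score = -1
    aligner.open_gap_score = -6
    aligner.extend_gap_score = -1
    aln = aligner.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def distances(seqs: dict[str, str], model: str = "p_distance") -> DistanceMatrix:
    """Pairwise p-distances or JC69 distances for a set of region sequences.

    Unequal-length pairs are globally aligned first; gapped columns are
    excluded pairwise.  JC69 distances with p >= 3/4 are flagged as NaN.
    """
    if model not in ("p_distance", "jc69"):
        raise PhylogenyError(f"unknown distance model {model!r}")
    ids = list(seqs)
    n = len(ids)
    mat = np.zeros((n, n))
    for i, j in itertools.combinations(range(n), 2):
        mism, comp = _pairwise_sites(seqs[ids[i]].upper(), seqs[ids[j]].upper())
        p = mism / comp
        if model == "jc69":
            if p >= 0.75:
                warnings.warn(
                    f"p-distance {p:.3f} >= 3/4 for {ids[i]}/{ids[j]}: "
                    "JC69 undefined"
                )
                d = float("nan")
            else:
                d = -0.75 * math.log(1 - 4 * p / 3)
        else:
            d = p
        mat[i, j] = mat[j, i] = d
    return DistanceMatrix(ids, mat, model)


# ---------------------------------------------------------------------------
# neighbor joining
# ---------------------------------------------------------------------------

class _Node:
    __slots__ = ("name", "children")

    def __init__(self, name=None, children=None):
        self.name = name
        self.children = children or []  # list of (child, branch_length)

    def newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{child.newick()}:{bl:.10g}" for child, bl in self.children
        )
        return f"({inner})"


@dataclass
class RegionTree:
    """An unrooted NJ tree for one gene region."""

    region_kind: str | None
    newick: str
    tree: dendropy.Tree = field(repr=False)

    @property
    def leaf_names(self) -> set[str]:
        return {lf.taxon.label for lf in self.tree.leaf_node_iter()}


def nj_tree(d: DistanceMatrix, region_kind: str | None = None) -> RegionTree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Q-criterion ties are broken by the lowest (row, col) index pair; a
    negative branch length at a join is clamped to 0 with the deficit moved
    to its sister branch.
    """
    n = len(d.ids)
    if n < 3:
        raise PhylogenyError("neighbor joining needs at least 3 taxa")
    if np.isnan(d.matrix).any():
        raise PhylogenyError("distance matrix contains undefined entries")
    nodes = [_Node(name) for name in d.ids]
    dist = {
        (i, j): float(d.matrix[i, j])
        for i in range(n) for j in range(n) if i != j
    }
    active = list(range(n))
    next_id = n

    def D(i, j):
        return dist[(i, j)] if i != j else 0.0

    node_of = {i: nodes[i] for i in range(n)}
    while len(active) > 3:
        m = len(active)
        r = {i: sum(D(i, k) for k in active if k != i) for i in active}
        best = None
        for ii in range(m):
            for jj in range(ii + 1, m):
                i, j = active[ii], active[jj]
                q = (m - 2) * D(i, j) - r[i] - r[j]
                if best is None or q < best[0] - 1e-12:
                    best = (q, i, j)
        _, i, j = best
        li = 0.5 * D(i, j) + (r[i] - r[j]) / (2 * (m - 2))
        lj = D(i, j) - li
        if li < 0:
            lj += li
            li = 0.0
        if lj < 0:
            li += lj
            lj = 0.0
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = _Node(children=[(node_of[i], li), (node_of[j], lj)])
        u = next_id
        next_id += 1
        node_of[u] = new
        for k in active:
            if k in (i, j):
                continue
            duk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
            dist[(u, k)] = dist[(k, u)] = max(duk, 0.0)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    li = 0.5 * (D(i, j) + D(i, k) - D(j, k))
    lj = 0.5 * (D(i, j) + D(j, k) - D(i, k))
    lk = 0.5 * (D(i, k) + D(j, k) - D(i, j))
    root = _Node(children=[
        (node_of[i], max(li, 0.0)),
        (node_of[j], max(lj, 0.0)),
        (node_of[k], max(lk, 0.0)),
    ])
    newick = root.newick() + ";"
    tree = dendropy.Tree.get(data=newick, schema="newick")
    tree.is_rooted = False
    return RegionTree(region_kind, newick, tree)


def tree_path_lengths(rt: RegionTree) -> DistanceMatrix:
    """Leaf-to-leaf path-length matrix of a tree (for additivity checks)."""
    pdm = rt.tree.phylogenetic_distance_matrix()
    taxa = sorted(rt.tree.taxon_namespace, key=lambda t: t.label)
    ids = [t.label for t in taxa]
    n = len(ids)
    mat = np.zeros((n, n))
    for a, b in itertools.combinations(range(n), 2):
        mat[a, b] = mat[b, a] = pdm.distance(taxa[a], taxa[b])
    return DistanceMatrix(ids, mat, model="path_length")


def rf_distance(t1: RegionTree, t2: RegionTree) -> int:
    """Robinson-Foulds distance (symmetric difference of bipartitions)."""
    if t1.leaf_names != t2.leaf_names:
        raise PhylogenyError(
            f"leaf sets differ: {sorted(t1.leaf_names)} vs {sorted(t2.leaf_names)}"
        )
    ns = dendropy.TaxonNamespace(sorted(t1.leaf_names))
    a = dendropy.Tree.get(data=t1.newick, schema="newick", taxon_namespace=ns)
    b = dendropy.Tree.get(data=t2.newick, schema="newick", taxon_namespace=ns)
    a.is_rooted = False
    b.is_rooted = False
    a.encode_bipartitions()
    b.encode_bipartitions()
    return int(dendropy.calculate.treecompare.symmetric_difference(a, b))


@dataclass
class DiscordanceResult:
    trees: dict[RegionKind, RegionTree]
    rf: pd.DataFrame
    discordant: bool


def region_discordance(
    family: FamilySet,
    model: str = "p_distance",
) -> DiscordanceResult:
    """One NJ tree per region kind plus the pairwise RF distance matrix.

    Regions present in fewer than 3 members are skipped with a warning.  The
    family is flagged ``discordant`` when any off-diagonal RF exceeds zero.
    """
    if len(family.members) < 3:
        raise PhylogenyError("discordance analysis needs >=3 family members")
    trees: dict[RegionKind, RegionTree] = {}
    for kind in family.shared_kinds(min_members=2):
        if kind == RegionKind.INTERGENIC:
            continue
        seqs = family.region_seqs(kind)
        if len(seqs) < 3:
            warnings.warn(f"region {kind.value}: fewer than 3 members; skipped")
            continue
        d = distances(seqs, model=model)
        trees[kind] = nj_tree(d, region_kind=kind.value)
    if len(trees) < 2:
        raise PhylogenyError("need >=2 region trees for discordance")
    kinds = list(trees)
    labels = [k.value for k in kinds]
    rf = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for a, b in itertools.combinations(range(len(kinds)), 2):
        v = rf_distance(trees[kinds[a]], trees[kinds[b]])
        rf.iloc[a, b] = rf.iloc[b, a] = v
    discordant = bool((rf.values[np.triu_indices(len(kinds), 1)] > 0).any())
    return DiscordanceResult(trees, rf, discordant)
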