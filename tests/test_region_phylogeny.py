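"""Distances, neighbor joining, RF distances and region-tree discordance."""

import itertools
import math

import dendropy
import numpy as np
import pytest

from tandemfam.gene_models import FamilySet, GeneModel, Region, RegionKind
from tandemfam.region_phylogeny import (
    DistanceMatrix,
    PhylogenyError,
    distances,
    nj_tree,
    region_discordance,
    rf_distance,
    tree_path_lengths,
)

from _oracles import five_taxon_topologies, ls_fit_sse, topology_newick


def test_p_distance_and_jc69_closed_forms(rng):
    a = "".join(rng.choice(list("ACGT"), 100))
    b = list(a)
    for i in range(10):
        b[i * 7] = {"A": "C", "C": "G", "G": "T", "T": "A"}[b[i * 7]]
    b = "".join(b)
    dp = distances({"a": a, "b": b}, model="p_distance")
    assert dp.matrix[0, 1] == pytest.approx(0.10)
    dj = distances({"a": a, "b": b}, model="jc69")
    assert dj.matrix[0, 1] == pytest.approx(-0.75 * math.log(1 - 0.4 / 3))
    ident = distances({"a": a, "b": a})
    assert ident.matrix[0, 1] == 0


def test_jc69_saturated_pair_flagged_nan():
    a, b = "AAAAAAAAAA", "CCCCCCCCCC"
    with pytest.warns(UserWarning, match="undefined"):
        d = distances({"a": a, "b": b}, model="jc69")
    assert np.isnan(d.matrix[0, 1])


def test_three_taxon_closed_form_branch_lengths():
    d = DistanceMatrix(["A", "B", "C"],
                       np.array([[0, 2, 4], [2, 0, 4], [4, 4, 0]], float))
    rt = nj_tree(d)
    pl = tree_path_lengths(rt)
    # branches a=1, b=1, c=3
    assert pl.matrix[pl.ids.index("A"), pl.ids.index("B")] == pytest.approx(2)
    assert pl.matrix[pl.ids.index("A"), pl.ids.index("C")] == pytest.approx(4)
    assert pl.matrix[pl.ids.index("B"), pl.ids.index("C")] == pytest.approx(4)


def test_nj_requires_three_taxa_and_defined_distances():
    with pytest.raises(PhylogenyError):
        nj_tree(DistanceMatrix(["A", "B"], np.zeros((2, 2))))
    m = np.zeros((3, 3))
    m[0, 1] = m[1, 0] = np.nan
    with pytest.raises(PhylogenyError):
        nj_tree(DistanceMatrix(["A", "B", "C"], m))


def test_zero_matrix_gives_zero_branch_star():
    d = DistanceMatrix(list("ABCD"), np.zeros((4, 4)))
    rt = nj_tree(d)
    pl = tree_path_lengths(rt)
    assert np.allclose(pl.matrix, 0)


def _random_tree_distances(rng, labels):
    """Additive distance matrix from a random binary tree with known newick."""
    taxa = dendropy.TaxonNamespace(labels)
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, taxon_namespace=taxa,
        num_extant_tips=len(labels),
        rng=__import__("random").Random(int(rng.integers(0, 2**31))),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is not None:
            edge.length = float(rng.uniform(0.05, 1.0))
    pdm = tree.phylogenetic_distance_matrix()
    n = len(labels)
    mat = np.zeros((n, n))
    tx = {t.label: t for t in taxa}
    for i, j in itertools.combinations(range(n), 2):
        mat[i, j] = mat[j, i] = pdm.distance(tx[labels[i]], tx[labels[j]])
    tree.is_rooted = False
    return DistanceMatrix(labels, mat), tree


def test_nj_recovers_additive_six_taxon_tree_and_path_lengths(rng):
    labels = list("ABCDEF")
    for _ in range(5):
        d, truth = _random_tree_distances(rng, labels)
        rt = nj_tree(d)
        # topology identical to the generating tree
        ns = truth.taxon_namespace
        inferred = dendropy.Tree.get(data=rt.newick, schema="newick",
                                     taxon_namespace=ns)
        inferred.is_rooted = False
        truth.encode_bipartitions()
        inferred.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            truth, inferred) == 0
        # path lengths reproduce the input exactly
        pl = tree_path_lengths(rt)
        order = [pl.ids.index(x) for x in labels]
        assert np.allclose(pl.matrix[np.ix_(order, order)], d.matrix,
                           atol=1e-9)


def test_nj_agrees_with_independent_skbio_implementation(rng):
    import io

    from skbio import DistanceMatrix as SkbioDM
    from skbio.tree import nj as skbio_nj

    labels = list("ABCDEF")
    d, _ = _random_tree_distances(rng, labels)
    rt = nj_tree(d)
    sk_tree = skbio_nj(SkbioDM(d.matrix, ids=labels))
    ns = dendropy.TaxonNamespace(labels)
    t1 = dendropy.Tree.get(data=rt.newick, schema="newick", taxon_namespace=ns)
    t2 = dendropy.Tree.get(data=str(sk_tree).strip(), schema="newick",
                           taxon_namespace=ns)
    t1.is_rooted = t2.is_rooted = False
    t1.encode_bipartitions()
    t2.encode_bipartitions()
    assert dendropy.calculate.treecompare.symmetric_difference(t1, t2) == 0


def test_nj_matches_exhaustive_least_squares_on_five_taxa(rng):
    labels = list("ABCDE")
    for _ in range(5):
        d, _ = _random_tree_distances(rng, labels)
        topologies = five_taxon_topologies(labels)
        assert len(topologies) == 15
        sses = [ls_fit_sse(e, labels, d.matrix) for e in topologies]
        best = topologies[int(np.argmin(sses))]
        ns = dendropy.TaxonNamespace(labels)
        t_best = dendropy.Tree.get(data=topology_newick(best, labels),
                                   schema="newick", taxon_namespace=ns)
        t_nj = dendropy.Tree.get(data=nj_tree(d).newick, schema="newick",
                                 taxon_namespace=ns)
        t_best.is_rooted = t_nj.is_rooted = False
        t_best.encode_bipartitions()
        t_nj.encode_bipartitions()
        assert dendropy.calculate.treecompare.symmetric_difference(
            t_best, t_nj) == 0


def test_rf_distance_basics():
    d1 = DistanceMatrix(list("ABCD"), np.array([
        [0, 1, 5, 5], [1, 0, 5, 5], [5, 5, 0, 1], [5, 5, 1, 0]], float))
    d2 = DistanceMatrix(list("ABCD"), np.array([
        [0, 5, 1, 5], [5, 0, 5, 1], [1, 5, 0, 5], [5, 1, 5, 0]], float))
    t1, t2 = nj_tree(d1), nj_tree(d2)
    assert rf_distance(t1, t1) == 0
    assert rf_distance(t1, t2) == 2  # the two distinct 4-taxon topologies
    d3 = DistanceMatrix(list("ABCE"), d1.matrix)
    with pytest.raises(PhylogenyError, match="leaf sets"):
        rf_distance(t1, nj_tree(d3))


def _evolve_on_tree(rng, newick, labels, seq_len, mut_per_branch):
    """Evolve a sequence along a fixed tree: region fixture with one truth."""
    ns = dendropy.TaxonNamespace(labels)
    tree = dendropy.Tree.get(data=newick, schema="newick", taxon_namespace=ns)
    root_seq = rng.choice(list("ACGT"), seq_len)
    seqs = {}

    def walk(node, seq):
        for child in node.child_nodes():
            s = seq.copy()
            for i in rng.choice(seq_len, mut_per_branch, replace=False):
                s[i] = rng.choice([b for b in "ACGT" if b != s[i]])
            if child.is_leaf():
                seqs[child.taxon.label] = "".join(s)
            else:
                walk(child, s)

    walk(tree.seed_node, root_seq)
    return seqs


def test_regions_sharing_one_history_are_concordant(rng):
    """Without conversion every region records the same topology (RF 0)."""
    labels = [f"g{i}" for i in range(6)]
    newick = "((g0:1,g1:1):1,((g2:1,g3:1):1,(g4:1,g5:1):1):1);"
    fam = FamilySet("onehistory")
    region_specs = [("promoter", 300), ("intron", 300), ("utr3", 300),
                    ("mpcr", 300), ("spcr", 60), ("utr5", 60)]
    per_region = {
        kind: _evolve_on_tree(rng, newick, labels, ln, max(6, ln // 20))
        for kind, ln in region_specs
    }
    pos = 0
    coords = {}
    for kind, ln in region_specs:
        coords[kind] = (pos, pos + ln)
        pos += ln
    for g in labels:
        regions = [Region(k, *coords[k]) for k, _ in region_specs]
        model = GeneModel(g, "chr", sorted(regions, key=lambda r: r.start))
        fam.members[g] = (model, {RegionKind(k): per_region[k][g]
                                  for k, _ in region_specs})
    disc = region_discordance(fam)
    big = [RegionKind.PROMOTER, RegionKind.INTRON, RegionKind.UTR3,
           RegionKind.MPCR]
    for a, b in itertools.combinations(big, 2):
        assert disc.rf.loc[a.value, b.value] == 0


def test_conversion_generates_region_discordance():
    """Conversion-shuffled families show promoter-vs-MPCR discordance."""
    from tandemfam import SimParams, simulate

    hits = 0
    n = 10
    for seed in range(n):
        fam = simulate(SimParams(seed=300 + seed)).to_family()
        disc = region_discordance(fam)
        if disc.rf.loc["promoter", "mpcr"] > 0:
            hits += 1
    assert hits >= 8
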