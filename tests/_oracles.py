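"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's code paths: alignment scores
come from exhaustive enumeration of alignment move sequences, codon effects
from Biopython translation, and pathway averaging from explicit path
simulation.
"""

from __future__ import annotations

import itertools

from Bio.Seq import Seq

_BASES = "ACGT"


def enumerate_alignments_best(a, b, match=2, mismatch=-1, gap_open=-5,
                              gap_extend=-1):
    """Exhaustively enumerate global alignments; return the lexicographic
    maximum of (affine-gap score, identity count).

    A gap of length g costs gap_open + g * gap_extend.  Feasible only for
    short sequences (len <= ~7).
    """
    best = [None]

    def step(i, j, score, idents, last):
        if i == len(a) and j == len(b):
            cand = (score, idents)
            if best[0] is None or cand > best[0]:
                best[0] = cand
            return
        if i < len(a) and j < len(b):
            hit = a[i] == b[j]
            step(i + 1, j + 1,
                 score + (match if hit else mismatch),
                 idents + (1 if hit else 0), "m")
        if i < len(a):
            extra = gap_extend if last == "x" else gap_open + gap_extend
            step(i + 1, j, score + extra, idents, "x")
        if j < len(b):
            extra = gap_extend if last == "y" else gap_open + gap_extend
            step(i, j + 1, score + extra, idents, "y")

    step(0, 0, 0, 0, None)
    return best[0]


def aa_of(codon: str) -> str:
    return str(Seq(codon).translate())


def syn_nonsyn_sites(codon: str) -> tuple[float, float]:
    """(S, N) site counts: each position weighs its synonymous fraction."""
    aa = aa_of(codon)
    s = 0.0
    for pos in range(3):
        for alt in _BASES:
            if alt == codon[pos]:
                continue
            mut = codon[:pos] + alt + codon[pos + 1:]
            if aa_of(mut) == aa and aa_of(mut) != "*":
                s += 1 / 3
    return s, 3 - s


def pathway_sd_nd(ca: str, cb: str) -> tuple[float, float]:
    """Pathway-averaged (Sd, Nd) for a codon pair, excluding stop-transit
    pathways unless every pathway transits a stop."""
    diff = [i for i in range(3) if ca[i] != cb[i]]
    if not diff:
        return 0.0, 0.0
    results = []
    for order in itertools.permutations(diff):
        cur = ca
        sd = nd = 0.0
        stop_transit = False
        for step_no, pos in enumerate(order):
            nxt = cur[:pos] + cb[pos] + cur[pos + 1:]
            if aa_of(nxt) == "*" and step_no < len(order) - 1:
                stop_transit = True
            if aa_of(cur) == aa_of(nxt) and aa_of(nxt) != "*":
                sd += 1
            else:
                nd += 1
            cur = nxt
        results.append((stop_transit, sd, nd))
    clean = [(sd, nd) for t, sd, nd in results if not t]
    if not clean:
        clean = [(sd, nd) for _, sd, nd in results]
    sd = sum(x[0] for x in clean) / len(clean)
    nd = sum(x[1] for x in clean) / len(clean)
    return sd, nd


def ng86_oracle(a: str, b: str):
    """Full NG86 tallies (N, S, Nd, Sd) for equal-length in-frame pairs."""
    assert len(a) == len(b) and len(a) % 3 == 0
    N = S = Nd = Sd = 0.0
    n_codons = 0
    for i in range(0, len(a), 3):
        ca, cb = a[i:i + 3], b[i:i + 3]
        if "-" in ca or "-" in cb:
            continue
        if aa_of(ca) == "*" or aa_of(cb) == "*":
            continue
        sa, na = syn_nonsyn_sites(ca)
        sb, nb = syn_nonsyn_sites(cb)
        sd, nd = pathway_sd_nd(ca, cb)
        S += (sa + sb) / 2
        N += (na + nb) / 2
        Sd += sd
        Nd += nd
        n_codons += 1
    return {"N": N, "S": S, "Nd": Nd, "Sd": Sd, "n_codons": n_codons}


SENSE_CODONS = [
    "".join(c) for c in itertools.product(_BASES, repeat=3)
    if aa_of("".join(c)) != "*"
]


def random_coding_pair(rng, n_codons: int, p_sub: float = 0.1):
    """A random in-frame pair: sense codons plus scattered substitutions."""
    a = [SENSE_CODONS[i] for i in rng.integers(0, len(SENSE_CODONS), n_codons)]
    b = []
    for codon in a:
        c = list(codon)
        for pos in range(3):
            if rng.random() < p_sub:
                c[pos] = _BASES[rng.integers(0, 4)]
        b.append("".join(c))
    return "".join(a), "".join(b)


# ---------------------------------------------------------------------------
# 5-taxon tree enumeration + least-squares fit
# ---------------------------------------------------------------------------

def five_taxon_topologies(labels):
    """All 15 unrooted binary topologies on 5 labels as edge lists.

    Nodes: labels are leaves; internal nodes are ints.  Built by sequential
    leaf insertion into every edge.
    """
    assert len(labels) == 5
    base = {"edges": [(labels[0], 100), (labels[1], 100), (labels[2], 100)]}
    trees = [base]
    nxt = 101
    for leaf in labels[3:]:
        new_trees = []
        for t in trees:
            for k in range(len(t["edges"])):
                edges = list(t["edges"])
                u, v = edges.pop(k)
                mid = nxt
                edges += [(u, mid), (mid, v), (leaf, mid)]
                new_trees.append({"edges": edges})
        nxt += 1
        trees = new_trees
    return [t["edges"] for t in trees]


def topology_newick(edges, labels):
    """Render an edge list as a newick string (unit branch lengths)."""
    adj = {}
    for u, v in edges:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    root = next(n for n in adj if isinstance(n, int))

    def render(node, parent):
        kids = [n for n in adj[node] if n != parent]
        if not kids:
            return str(node)
        return "(" + ",".join(render(k, node) + ":1" for k in kids) + ")"

    return render(root, None) + ";"


def ls_fit_sse(edges, labels, dmat):
    """Least-squares SSE of fitting distance matrix dmat on a topology."""
    import numpy as np

    adj = {}
    for ei, (u, v) in enumerate(edges):
        adj.setdefault(u, []).append((v, ei))
        adj.setdefault(v, []).append((u, ei))

    def path_edges(a, b):
        stack = [(a, None, [])]
        while stack:
            node, parent, path = stack.pop()
            if node == b:
                return path
            for nb, ei in adj[node]:
                if nb != parent:
                    stack.append((nb, node, path + [ei]))
        raise AssertionError

    pairs = list(itertools.combinations(range(len(labels)), 2))
    A = np.zeros((len(pairs), len(edges)))
    y = np.zeros(len(pairs))
    for r, (i, j) in enumerate(pairs):
        for ei in path_edges(labels[i], labels[j]):
            A[r, ei] = 1
        y[r] = dmat[i, j]
    x, res, *_ = np.linalg.lstsq(A, y, rcond=None)
    pred = A @ x
    return float(((pred - y) ** 2).sum())
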