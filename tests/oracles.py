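"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles and shares no code path
with the package: the genetic code is an explicit literal, the NG86
counting is plain loops plus permutation enumeration, the affine-gap
aligner is a direct Gotoh dynamic program, and tree distances are walked
edge by edge.
"""

from __future__ import annotations

import math
from itertools import permutations

# explicit standard genetic code (DNA codons), stops as '*'
GENETIC_CODE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}
STOPS = {c for c, aa in GENETIC_CODE.items() if aa == "*"}


def oracle_syn_sites(codon: str) -> float:
    total = 0.0
    for pos in range(3):
        for nt in "ACGT":
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            if alt in STOPS:
                continue
            if GENETIC_CODE[alt] == GENETIC_CODE[codon]:
                total += 1.0 / 3.0
    return total


def oracle_path_counts(c1: str, c2: str):
    diff = [i for i in range(3) if c1[i] != c2[i]]
    if not diff:
        return 0.0, 0.0
    syn_sum = non_sum = 0.0
    n_ok = 0
    for order in permutations(diff):
        cur, s, n = c1, 0, 0
        blocked = False
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                blocked = True
                break
            if GENETIC_CODE[nxt] == GENETIC_CODE[cur]:
                s += 1
            else:
                n += 1
            cur = nxt
        if not blocked:
            syn_sum += s
            non_sum += n
            n_ok += 1
    if n_ok == 0:
        return None
    return syn_sum / n_ok, non_sum / n_ok


def oracle_ng86(codons_a: list[str], codons_b: list[str]):
    """(ka, ks, S, N, sd, nd) for two gap-free codon lists."""
    S = sd = nd = 0.0
    used = 0
    for c1, c2 in zip(codons_a, codons_b):
        if c1 in STOPS or c2 in STOPS:
            continue
        counts = oracle_path_counts(c1, c2)
        if counts is None:
            continue
        S += (oracle_syn_sites(c1) + oracle_syn_sites(c2)) / 2.0
        sd += counts[0]
        nd += counts[1]
        used += 1
    N = 3.0 * used - S

    def jc(p):
        return float("nan") if p >= 0.75 else -0.75 * math.log(1.0 - 4.0 * p / 3.0)

    ps = sd / S if S else 0.0
    pn = nd / N if N else 0.0
    return jc(pn), jc(ps), S, N, sd, nd


def gotoh_score(a: str, b: str, sub, gap_open: float, gap_extend: float) -> float:
    """Global affine-gap alignment score; a gap of length L costs
    gap_open + gap_extend * (L - 1)."""
    neg = float("-inf")
    n, m = len(a), len(b)
    M = [[neg] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in b (a consumed)
    Y = [[neg] * (m + 1) for _ in range(n + 1)]  # gap in a (b consumed)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        X[i][0] = -gap_open - gap_extend * (i - 1)
    for j in range(1, m + 1):
        Y[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = sub[a[i - 1], b[j - 1]]
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s
            X[i][j] = max(M[i - 1][j] - gap_open, X[i - 1][j] - gap_extend,
                          Y[i - 1][j] - gap_open)
            Y[i][j] = max(M[i][j - 1] - gap_open, Y[i][j - 1] - gap_extend,
                          X[i][j - 1] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


# --- random additive trees ---------------------------------------------------


class _SimNode:
    __slots__ = ("name", "children", "length")

    def __init__(self, name=None, length=0.0):
        self.name = name
        self.children = []
        self.length = length


def random_additive_tree(n_taxa: int, rng):
    """Random unrooted binary tree with positive branch lengths; returns
    (leaf names, distance matrix, set of non-trivial bipartitions)."""
    import numpy as np

    names = [f"t{i}" for i in range(n_taxa)]
    nodes = [_SimNode(name=nm, length=float(rng.uniform(0.1, 2.0))) for nm in names]
    while len(nodes) > 3:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = _SimNode(length=float(rng.uniform(0.1, 2.0)))
        parent.children = [nodes[i], nodes[j]]
        nodes = [nd for k, nd in enumerate(nodes) if k not in (i, j)] + [parent]
    root = _SimNode()
    root.children = nodes
    root.length = 0.0

    # leaf depths and bipartitions by walking edges
    dist = {}
    splits = set()
    all_names = frozenset(names)
    ref = min(all_names)

    def walk(node, depth, path):
        if not node.children:
            dist[node.name] = (depth + node.length, path)
            return frozenset([node.name])
        below = frozenset()
        for c in node.children:
            below |= walk(c, depth + node.length, path + [c])
        if node is not root and 1 < len(below) < n_taxa - 1:
            splits.add(below if ref not in below else all_names - below)
        return below

    walk(root, 0.0, [])
    d = np.zeros((n_taxa, n_taxa))
    for x in range(n_taxa):
        for y in range(x + 1, n_taxa):
            px, py = dist[names[x]][1], dist[names[y]][1]
            shared = 0
            for nx, ny in zip(px, py):
                if nx is ny:
                    shared += nx.length
                else:
                    break
            d[x, y] = d[y, x] = dist[names[x]][0] + dist[names[y]][0] - 2 * shared
    return names, d, splits


def tree_path_distances(tree):
    """Leaf-to-leaf path lengths of a genefamkit phylo.Tree."""
    paths = {}

    def walk(node, acc):
        acc = acc + [(node, node.length or 0.0)]
        if node.is_leaf:
            paths[node.name] = acc
        for c in node.children:
            walk(c, acc)

    for child in tree.root.children:
        walk(child, [])
    out = {}
    for a, pa in paths.items():
        for b, pb in paths.items():
            if a >= b:
                continue
            shared = 0.0
            for (na, la), (nb, lb) in zip(pa, pb):
                if na is nb:
                    shared += la
                else:
                    break
            out[(a, b)] = sum(l for _, l in pa) + sum(l for _, l in pb) - 2 * shared
    return out


def brute_cherries(tree):
    """All leaf pairs sharing a parent with exactly two leaf children."""
    parent_of = {}

    def walk(node):
        for c in node.children:
            parent_of[id(c)] = node
            walk(c)

    walk(tree.root)
    leaves = tree.leaves()
    out = set()
    for i, u in enumerate(leaves):
        for v in leaves[i + 1 :]:
            p = parent_of[id(u)]
            if p is parent_of[id(v)] and len(p.children) == 2:
                out.add(tuple(sorted((u.name, v.name))))
    return out
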