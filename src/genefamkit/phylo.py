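"""Protein distances, neighbor-joining trees, bootstrap support, and
homolog-pair extraction.

Distances are p-distances under pairwise gap deletion: for each sequence
pair only alignment columns ungapped in both rows are compared, which lets
divergent (gappy) regions still contribute where they can. A Poisson
correction (-ln(1-p)) is available as an option. Trees are built with the
Saitou-Nei neighbor-joining algorithm; joins are chosen by the Q criterion
with a deterministic tie-break on the smallest id pair, and a negative
branch length is clamped to zero with its deficit moved to the sister
branch so the joined pair's distance is conserved.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io import GAP, SequenceRecord

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Alignments and distances


@dataclass
class Alignment:
    """Equal-length aligned rows (gap symbol '-')."""

    records: list[SequenceRecord]

    def __post_init__(self) -> None:
        if len(self.records) < 2:
            raise ValueError("alignment needs at least 2 rows")
        lengths = {len(r) for r in self.records}
        if len(lengths) != 1:
            raise ValueError(f"aligned rows differ in length: {sorted(lengths)}")

    @property
    def length(self) -> int:
        return len(self.records[0])

    @property
    def ids(self) -> list[str]:
        return [r.id for r in self.records]

    def row(self, i: int) -> str:
        return self.records[i].residues

    def take_columns(self, cols) -> "Alignment":
        recs = [
            SequenceRecord(r.id, r.description, "".join(r.residues[c] for c in cols), aligned=True)
            for r in self.records
        ]
        return Alignment(recs)


@dataclass
class DistanceMatrix:
    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"distance matrix shape {self.d.shape} != ({n}, {n})")
        if not np.allclose(self.d, self.d.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if (self.d < -1e-12).any():
            raise ValueError("distance matrix has negative entries")
        if not np.allclose(np.diag(self.d), 0.0, atol=1e-12):
            raise ValueError("distance matrix diagonal is not zero")


def p_distance(alignment: Alignment, i: int, j: int) -> float:
    """Proportion of differing sites over columns ungapped in both rows."""
    a, b = alignment.row(i), alignment.row(j)
    compared = diffs = 0
    for x, y in zip(a, b):
        if x == GAP or y == GAP:
            continue
        compared += 1
        if x != y:
            diffs += 1
    if compared == 0:
        raise ValueError(
            f"rows {alignment.ids[i]!r} and {alignment.ids[j]!r} share no comparable columns"
        )
    return diffs / compared


def distance_matrix(alignment: Alignment, model: str = "p") -> DistanceMatrix:
    """All pairwise distances; ``model`` is 'p' or 'poisson'."""
    n = len(alignment.records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = p_distance(alignment, i, j)
            if model == "poisson":
                if p >= 1.0:
                    raise ValueError("Poisson correction undefined at p >= 1")
                p = -np.log(1.0 - p)
            elif model != "p":
                raise ValueError(f"unknown distance model {model!r}")
            d[i, j] = d[j, i] = p
    return DistanceMatrix(alignment.ids, d)


# ---------------------------------------------------------------------------
# Pairwise protein alignment


def pairwise_align_protein(
    a: SequenceRecord,
    b: SequenceRecord,
    gap_open: float = 10.0,
    gap_extend: float = 0.5,
) -> Alignment:
    """Optimal global alignment under BLOSUM62 with affine gap penalties
    (``gap_open``/``gap_extend`` are positive costs). The first optimal
    traceback reported by Bio.Align.PairwiseAligner is taken, which is
    deterministic for fixed inputs."""
    from Bio import Align
    from Bio.Align import substitution_matrices

    for rec in (a, b):
        if not rec.ungapped():
            raise ValueError(f"{rec.id}: empty sequence")
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -float(gap_open)
    aligner.extend_gap_score = -float(gap_extend)
    best = aligner.align(a.ungapped(), b.ungapped())[0]
    row_a, row_b = str(best[0]), str(best[1])
    return Alignment(
        [
            SequenceRecord(a.id, a.description, row_a, aligned=True),
            SequenceRecord(b.id, b.description, row_b, aligned=True),
        ]
    )


def alignment_score(alignment: Alignment, gap_open: float = 10.0, gap_extend: float = 0.5) -> float:
    """Affine-gap BLOSUM62 score of a 2-row alignment (for oracle checks)."""
    from Bio.Align import substitution_matrices

    blosum = substitution_matrices.load("BLOSUM62")
    a, b = alignment.row(0), alignment.row(1)
    # a gap run of length L costs gap_open + gap_extend * (L - 1)
    score = 0.0
    in_gap_a = in_gap_b = False
    for x, y in zip(a, b):
        if x == GAP:
            score -= gap_extend if in_gap_a else gap_open
            in_gap_a, in_gap_b = True, False
        elif y == GAP:
            score -= gap_extend if in_gap_b else gap_open
            in_gap_a, in_gap_b = False, True
        else:
            score += blosum[x, y]
            in_gap_a = in_gap_b = False
    return score


# ---------------------------------------------------------------------------
# Trees


@dataclass
class Node:
    name: str | None = None
    length: float | None = None
    support: int | None = None
    children: list["Node"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list["Node"]:
        if self.is_leaf:
            return [self]
        out: list[Node] = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def _newick(self) -> str:
        if self.is_leaf:
            s = self.name or ""
        else:
            s = "(" + ",".join(c._newick() for c in self.children) + ")"
            if self.support is not None:
                s += str(int(self.support))
        if self.length is not None:
            s += f":{self.length:.6f}"
        return s


@dataclass
class Tree:
    """Unrooted tree stored with a (conventionally trifurcating) root."""

    root: Node

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    def leaf_names(self) -> list[str]:
        names = [l.name for l in self.leaves()]
        if any(not n for n in names):
            raise ValueError("tree has an unlabeled leaf")
        if len(set(names)) != len(names):
            raise ValueError("leaf labels are not unique")
        return names

    def to_newick(self) -> str:
        return "(" + ",".join(c._newick() for c in self.root.children) + ");"

    @classmethod
    def from_newick(cls, text: str) -> "Tree":
        import dendropy

        dt = dendropy.Tree.get(data=text, schema="newick", suppress_internal_node_taxa=True)

        def convert(dnode) -> Node:
            node = Node(length=dnode.edge.length)
            if dnode.is_leaf():
                node.name = dnode.taxon.label.replace(" ", "_") if dnode.taxon else None
            else:
                node.children = [convert(c) for c in dnode.child_nodes()]
                if dnode.label is not None:
                    try:
                        node.support = int(round(float(dnode.label)))
                    except ValueError:
                        pass
            return node

        root = convert(dt.seed_node)
        root.length = None
        return cls(root)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial splits, each canonicalized as the side not containing
        the lexicographically smallest leaf."""
        all_leaves = frozenset(self.leaf_names())
        ref = min(all_leaves)
        splits: set[frozenset] = set()

        def walk(node: Node) -> frozenset:
            if node.is_leaf:
                return frozenset([node.name])
            below = frozenset().union(*(walk(c) for c in node.children))
            if 1 < len(below) < len(all_leaves) - 1:
                side = below if ref not in below else all_leaves - below
                splits.add(side)
            return below

        for child in self.root.children:
            walk(child)
        return splits

    def internal_edges(self) -> list[Node]:
        """Internal nodes below the root, i.e. one per internal edge."""
        out: list[Node] = []

        def walk(node: Node, is_root: bool) -> None:
            if not node.is_leaf and not is_root:
                out.append(node)
            for c in node.children:
                walk(c, False)

        walk(self.root, True)
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Saitou-Nei neighbor joining.

    Iteratively joins the pair minimizing
    Q(i,j) = (n-2) d(i,j) - sum_k d(i,k) - sum_k d(j,k); Q ties are broken
    by the smallest (sorted) representative-id pair. Branch lengths follow
    the standard NJ formulas; a negative length is set to zero and its
    deficit moved to the sister branch (their sum, the joined distance, is
    conserved). The result is unrooted, rooted at a trifurcation.
    """
    n0 = len(dm.ids)
    if n0 < 3:
        raise ValueError("neighbor joining needs at least 3 taxa")
    d = {i: {} for i in range(n0)}
    for i in range(n0):
        for j in range(n0):
            if i != j:
                d[i][j] = float(dm.d[i, j])
    nodes: dict[int, Node] = {i: Node(name=dm.ids[i]) for i in range(n0)}
    # representative id per active cluster: smallest leaf label underneath
    rep: dict[int, str] = {i: dm.ids[i] for i in range(n0)}
    next_idx = n0

    def clamp(li: float, lj: float) -> tuple[float, float]:
        if li < 0:
            lj, li = lj + li, 0.0
        if lj < 0:
            li, lj = li + lj, 0.0
        return max(li, 0.0), max(lj, 0.0)

    while len(d) > 3:
        active = sorted(d)
        n = len(active)
        r = {i: sum(d[i].values()) for i in active}
        best = None
        for ai, i in enumerate(active):
            for j in active[ai + 1 :]:
                q = (n - 2) * d[i][j] - r[i] - r[j]
                key = (q, tuple(sorted((rep[i], rep[j]))))
                if best is None or key < best[0]:
                    best = (key, i, j)
        _, i, j = best
        li = d[i][j] / 2.0 + (r[i] - r[j]) / (2.0 * (n - 2))
        lj = d[i][j] - li
        li, lj = clamp(li, lj)
        parent = Node(children=[nodes[i], nodes[j]])
        nodes[i].length, nodes[j].length = li, lj
        u = next_idx
        next_idx += 1
        d[u] = {}
        for k in active:
            if k in (i, j):
                continue
            duk = (d[i][k] + d[j][k] - d[i][j]) / 2.0
            d[u][k] = d[k][u] = duk
        for k in (i, j):
            del d[k]
            for row in d.values():
                row.pop(k, None)
        nodes[u] = parent
        rep[u] = min(rep[i], rep[j])

    a, b, c = sorted(d)
    la = (d[a][b] + d[a][c] - d[b][c]) / 2.0
    lb = (d[a][b] + d[b][c] - d[a][c]) / 2.0
    lc = (d[a][c] + d[b][c] - d[a][b]) / 2.0
    nodes[a].length = max(la, 0.0)
    nodes[b].length = max(lb, 0.0)
    nodes[c].length = max(lc, 0.0)
    return Tree(Node(children=[nodes[a], nodes[b], nodes[c]]))


# ---------------------------------------------------------------------------
# Bootstrap


def bootstrap_support(
    alignment: Alignment,
    reps: int = 1000,
    rng_seed: int = 42,
    model: str = "p",
) -> Tree:
    """NJ tree from the full alignment with internal-branch support set to
    the percentage of column-resampled replicates containing the same
    bipartition. A replicate in which some pair has no comparable columns
    is skipped (and logged) rather than contributing zeros."""
    if reps < 1:
        raise ValueError("reps must be >= 1")
    tree = nj_tree(distance_matrix(alignment, model))
    rng = np.random.default_rng(rng_seed)
    counts: dict[frozenset, int] = {bp: 0 for bp in tree.bipartitions()}
    used = 0
    for rep in range(reps):
        cols = rng.integers(0, alignment.length, size=alignment.length)
        sub = alignment.take_columns(cols)
        try:
            bps = nj_tree(distance_matrix(sub, model)).bipartitions()
        except ValueError:
            logger.warning("bootstrap replicate %d skipped (all-gap pair)", rep)
            continue
        used += 1
        for bp in bps:
            if bp in counts:
                counts[bp] += 1
    if used == 0:
        raise ValueError("all bootstrap replicates were skipped")
    all_leaves = frozenset(tree.leaf_names())
    ref = min(all_leaves)
    for node in tree.internal_edges():
        below = frozenset(l.name for l in node.leaves())
        if not 1 < len(below) < len(all_leaves) - 1:
            continue
        side = below if ref not in below else all_leaves - below
        node.support = int(round(100.0 * counts.get(side, 0) / used))
    return tree


# ---------------------------------------------------------------------------
# Homolog pairs


def sister_pairs(tree: Tree, species_of) -> list[tuple[str, str, str]]:
    """All cherries (leaf pairs joined by one internal node), labeled
    'paralog' when both leaves belong to the same species and 'ortholog'
    otherwise. ``species_of`` maps gene id -> species label."""
    pairs: list[tuple[str, str, str]] = []
    tree.leaf_names()  # validates labels

    def lookup(gene: str) -> str:
        try:
            return species_of[gene] if hasattr(species_of, "__getitem__") else species_of(gene)
        except KeyError as exc:
            raise ValueError(f"no species mapping for leaf {gene!r}") from exc

    def walk(node: Node) -> None:
        if node.is_leaf:
            return
        if len(node.children) == 2 and all(c.is_leaf for c in node.children):
            a, b = sorted(c.name for c in node.children)
            kind = "paralog" if lookup(a) == lookup(b) else "ortholog"
            pairs.append((a, b, kind))
        for c in node.children:
            walk(c)

    walk(tree.root)
    return pairs
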