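"""UPGMA dendrograms, cophenetic correlation and profile-resampling bootstrap.

Trees are rooted, binary and ultrametric: every internal node carries
its merge height in distance units (half the between-cluster distance
at the merge), so the cophenetic distance between two leaves is twice
the height of their lowest common ancestor.  Bootstrap replicates are
obtained by resampling profile columns of the signature table with
replacement, rebuilding the GOMs and GOM signatures from the resampled
columns, and re-clustering; clade support is the fraction of replicate
trees containing the same leaf set as a clade.
"""

from __future__ import annotations

import numpy as np
from scipy import stats

from .annotation import SignatureTable, build_goms, gom_signature
from .similarity import DistanceMatrix, pairwise_distance_matrix


class Node:
    """A node of a rooted ultrametric dendrogram."""

    __slots__ = ("name", "children", "height", "support", "blen_repr")

    def __init__(self, name=None, children=(), height=0.0, support=None):
        self.name = name
        self.children = list(children)
        self.height = height
        self.support = support
        # Verbatim branch-length token from a parsed file; reused on
        # re-serialisation so a read/write cycle is byte-exact even when
        # height subtraction would round differently.  Cleared implicitly
        # by building trees programmatically (None).
        self.blen_repr = None

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        if self.is_leaf:
            return [self.name]
        out = []
        for c in self.children:
            out.extend(c.leaves())
        return out

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def clades(self) -> dict[frozenset, "Node"]:
        """Internal clades (leaf sets), excluding leaves and the root."""
        out = {}
        for node in self.walk():
            if node is self or node.is_leaf:
                continue
            out[frozenset(node.leaves())] = node
        return out

    def find_leaf(self, name: str) -> "Node | None":
        for node in self.walk():
            if node.is_leaf and node.name == name:
                return node
        return None

    def parent_of(self, target: "Node") -> "Node | None":
        for node in self.walk():
            if target in node.children:
                return node
        return None


def upgma(matrix: DistanceMatrix) -> Node:
    """Average-linkage (size-weighted) agglomerative clustering.

    Merge heights are half the between-cluster distance.  Ties are
    broken by the lexicographically smallest pair of cluster
    representative labels (the smallest leaf of each cluster), which
    makes the tree deterministic.
    """
    n = len(matrix)
    if n < 2:
        raise ValueError("need at least two labels")
    D = np.array(matrix.values, dtype=float)
    if not np.allclose(D, D.T):
        raise ValueError("matrix must be symmetric")
    active = list(range(n))
    nodes = {i: Node(name=matrix.labels[i]) for i in range(n)}
    reps = {i: matrix.labels[i] for i in range(n)}
    sizes = {i: 1 for i in range(n)}
    work = D.copy()
    np.fill_diagonal(work, np.inf)
    next_id = n
    while len(active) > 1:
        sub = work[np.ix_(active, active)]
        d_min = sub.min()
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                if sub[ai, aj] <= d_min:
                    i, j = active[ai], active[aj]
                    key = tuple(sorted((reps[i], reps[j])))
                    if best is None or key < best[0]:
                        best = (key, i, j)
        _, i, j = best
        d = float(work[i, j])
        left, right = sorted((i, j), key=lambda k: reps[k])
        parent = Node(children=[nodes[left], nodes[right]], height=d / 2.0)
        # size-weighted average linkage
        new_row = (sizes[i] * work[i] + sizes[j] * work[j]) / (sizes[i] + sizes[j])
        work = np.pad(work, ((0, 1), (0, 1)), constant_values=np.inf)
        work[next_id, :-1] = new_row
        work[:-1, next_id] = new_row
        work[next_id, next_id] = np.inf
        nodes[next_id] = parent
        reps[next_id] = min(reps[i], reps[j])
        sizes[next_id] = sizes[i] + sizes[j]
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return nodes[active[0]]


def cophenetic_matrix(tree: Node, labels: list[str] | None = None) -> DistanceMatrix:
    """All-pairs cophenetic distances (2x the LCA merge height)."""
    labels = labels or sorted(tree.leaves())
    idx = {lab: i for i, lab in enumerate(labels)}
    n = len(labels)
    C = np.zeros((n, n))

    def fill(node: Node) -> list[str]:
        if node.is_leaf:
            return [node.name]
        child_leaves = [fill(c) for c in node.children]
        for a in range(len(child_leaves)):
            for b in range(a + 1, len(child_leaves)):
                for la in child_leaves[a]:
                    for lb in child_leaves[b]:
                        i, j = idx[la], idx[lb]
                        C[i, j] = C[j, i] = 2.0 * node.height
        return [l for ls in child_leaves for l in ls]

    fill(tree)
    return DistanceMatrix(labels, C)


def cophenetic_correlation(tree: Node, matrix: DistanceMatrix) -> float:
    """Pearson correlation between cophenetic and input distances."""
    if len(matrix) < 3:
        raise ValueError("cophenetic correlation undefined for fewer than 3 taxa")
    if set(tree.leaves()) != set(matrix.labels):
        raise ValueError("tree and matrix label sets differ")
    C = cophenetic_matrix(tree, matrix.labels)
    iu = np.triu_indices(len(matrix), k=1)
    x, y = C.values[iu], matrix.values[iu]
    if np.std(x) == 0 or np.std(y) == 0:
        return 1.0 if np.allclose(x, y) else 0.0
    return float(stats.pearsonr(x, y).statistic)


# ---------------------------------------------------------------------------
# bootstrap


def resample_table(table: SignatureTable, indices: np.ndarray,
                   rank: str = "family") -> SignatureTable:
    """Rebuild a signature table from a resampled set of profile columns.

    Score and location columns are taken directly (duplicates appear
    multiply); GOMs and GOM signatures are recomputed from the
    resampled location columns, mirroring a full re-annotation.
    """
    pphmm = table.pphmm[:, indices]
    locations = table.locations[:, indices]
    goms = build_goms(table.accessions, table.taxonomies, locations, rank=rank)
    gsig = np.vstack([gom_signature(locations[i], goms) for i in range(len(table))]) \
        if len(table) and goms else np.zeros((len(table), len(goms)))
    return SignatureTable(
        list(table.accessions), list(table.taxonomies), pphmm, locations, gsig,
        [table.profile_ids[i] for i in indices], [g.label for g in goms],
    )


def bootstrap_trees(
    table: SignatureTable, n_reps: int = 100, seed: int = 0, rank: str = "family"
) -> list[Node]:
    """UPGMA trees from profile-resampled replicates of a signature table."""
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    rng = np.random.default_rng(seed)
    P = len(table.profile_ids)
    trees = []
    for _ in range(n_reps):
        idx = rng.integers(0, P, size=P)
        rep = resample_table(table, idx, rank=rank)
        trees.append(upgma(pairwise_distance_matrix(rep)))
    return trees


def clade_support(best: Node, replicates: list[Node]) -> dict[frozenset, float]:
    """Support (%) per internal clade of the best tree.

    A replicate supports a clade when it contains an identical leaf
    set as a clade.  The root and leaves are excluded.
    """
    leafset = set(best.leaves())
    for t in replicates:
        if set(t.leaves()) != leafset:
            raise ValueError("replicate leaf set differs from the best tree")
    rep_clades = [set(t.clades()) for t in replicates]
    support = {}
    for clade in best.clades():
        count = sum(clade in rc for rc in rep_clades)
        support[clade] = 100.0 * count / len(replicates)
    return support


def annotate_support(best: Node, support: dict[frozenset, float]) -> Node:
    for clade, node in best.clades().items():
        node.support = support.get(clade)
    return best


def prune_table(table: SignatureTable, clade_leaves: list[str],
                rank: str = "family") -> SignatureTable:
    """Restrict to clade members and drop profiles none of them hit.

    GOMs of families without clade members disappear automatically when
    the GOM set is rebuilt from the retained rows.
    """
    rows = [table.index_of(a) for a in clade_leaves]
    if len(rows) < 2:
        raise ValueError("need at least two clade members")
    sub = table.subset(rows)
    keep = np.flatnonzero((sub.pphmm != 0).any(axis=0))
    pphmm = sub.pphmm[:, keep]
    locations = sub.locations[:, keep]
    goms = build_goms(sub.accessions, sub.taxonomies, locations, rank=rank)
    gsig = np.vstack([gom_signature(locations[i], goms) for i in range(len(sub))]) \
        if goms else np.zeros((len(sub), 0))
    return SignatureTable(
        sub.accessions, sub.taxonomies, pphmm, locations, gsig,
        [sub.profile_ids[i] for i in keep], [g.label for g in goms],
    )


def pruned_rebootstrap(
    table: SignatureTable, clade_leaves: list[str], n_reps: int = 100,
    seed: int = 0, rank: str = "family",
) -> tuple[Node, dict[frozenset, float]]:
    """Re-bootstrap a sub-clade after removing irrelevant profiles and GOMs."""
    pruned = prune_table(table, clade_leaves, rank=rank)
    best = upgma(pairwise_distance_matrix(pruned))
    reps = bootstrap_trees(pruned, n_reps=n_reps, seed=seed, rank=rank)
    support = clade_support(best, reps)
    annotate_support(best, support)
    return best, support


# ---------------------------------------------------------------------------
# Newick I/O


def write_newick(tree: Node) -> str:
    """Serialise a dendrogram: heights become branch lengths, supports labels."""

    def fmt(node: Node, parent_height: float | None) -> str:
        if node.is_leaf:
            body = node.name
        else:
            inner = ",".join(fmt(c, node.height) for c in node.children)
            label = "" if node.support is None else repr(node.support)
            body = f"({inner}){label}"
        if parent_height is None:
            return body
        blen = node.blen_repr or repr(parent_height - node.height)
        return f"{body}:{blen}"

    return fmt(tree, None) + ";"


def read_newick(text: str) -> Node:
    """Parse a Newick string produced by :func:`write_newick`.

    Branch lengths are reassembled into ultrametric heights (leaf
    height 0); internal node labels are read back as support values.
    Malformed input raises ``NewickError`` with the offending position.
    """
    parser = _NewickParser(text)
    root, _ = parser.parse()
    _assign_heights(root)
    return root


class NewickError(ValueError):
    def __init__(self, message: str, pos: int):
        super().__init__(f"{message} at position {pos}")
        self.pos = pos


class _NewickParser:
    def __init__(self, text: str):
        self.text = text.strip()
        self.pos = 0

    def parse(self):
        node, blen = self._node()
        if self.pos >= len(self.text) or self.text[self.pos] != ";":
            raise NewickError("expected ';'", self.pos)
        return node, blen

    def _node(self):
        node = Node()
        if self._peek() == "(":
            self.pos += 1
            while True:
                child, blen = self._node()
                child.height = -blen  # placeholder: depth below parent
                node.children.append(child)
                ch = self._peek()
                if ch == ",":
                    self.pos += 1
                    continue
                if ch == ")":
                    self.pos += 1
                    break
                raise NewickError("expected ',' or ')'", self.pos)
            label = self._token()
            if label:
                try:
                    node.support = float(label)
                except ValueError:
                    raise NewickError(f"invalid support label {label!r}", self.pos)
        else:
            name = self._token()
            if not name:
                raise NewickError("expected a leaf name", self.pos)
            node.name = name
        blen = 0.0
        if self._peek() == ":":
            self.pos += 1
            tok = self._token()
            try:
                blen = float(tok)
            except ValueError:
                raise NewickError(f"invalid branch length {tok!r}", self.pos)
            node.blen_repr = tok
        return node, blen

    def _peek(self) -> str:
        return self.text[self.pos] if self.pos < len(self.text) else ""

    def _token(self) -> str:
        start = self.pos
        while self.pos < len(self.text) and self.text[self.pos] not in "(),:;":
            self.pos += 1
        return self.text[start:self.pos]


def _assign_heights(root: Node) -> None:
    """Convert stored child branch lengths (negated) into absolute heights."""

    def depth(node: Node) -> float:
        # distance from node down to any leaf (ultrametric assumption)
        if node.is_leaf:
            return 0.0
        child = node.children[0]
        return (-child.height) + depth(child)

    def assign(node: Node, h: float) -> None:
        if node.is_leaf:
            node.height = 0.0
            return
        for c in node.children:
            blen = -c.height
            assign(c, h - blen)
        node.height = h

    assign(root, depth(root))
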