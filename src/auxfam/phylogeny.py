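"""p-distance + neighbor-joining phylogeny with bootstrap sister pairs.

The tree-building route mirrors a classical family survey: pairwise
p-distances from an externally produced protein alignment (alignment is
an input, not computed here), Saitou-Nei neighbor joining, bootstrap
supports from column resampling, and a sister-pair rule that keeps
cherries whose support exceeds a threshold (default >99%), the usual
proxy for recent gene duplication.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import dendropy
import numpy as np

from .io_core import IoError, SequenceSet

log = logging.getLogger(__name__)

GAP_CHARS = {"-", "."}


# ---------------------------------------------------------------------------
# Distance matrix
# ---------------------------------------------------------------------------

@dataclass
class DistanceMatrix:
    ids: list[str]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.ids), len(self.ids)):
            raise IoError("distance matrix shape does not match ids")
        if not np.all(np.isfinite(m)):
            raise IoError("distance matrix has non-finite entries")
        if np.any(m < 0):
            raise IoError("distance matrix has negative entries")
        if not np.allclose(m, m.T):
            raise IoError("distance matrix not symmetric")
        if not np.allclose(np.diag(m), 0.0):
            raise IoError("distance matrix diagonal not zero")
        self.matrix = m

    def __len__(self) -> int:
        return len(self.ids)


def p_distance(alignment: SequenceSet) -> DistanceMatrix:
    """Pairwise p-distance with pairwise deletion of gapped columns.

    d(i, j) = mismatches / compared columns, where a column is compared
    only if neither sequence has a gap there.  A pair with zero
    comparable columns is a hard error naming the pair.
    """
    ids = alignment.ids
    seqs = [s for _, s in alignment.records]
    lengths = {len(s) for s in seqs}
    if len(lengths) != 1:
        raise IoError("alignment sequences are not equal length")
    arr = np.array([list(s) for s in seqs])
    gap = np.isin(arr, list(GAP_CHARS))
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = ~(gap[i] | gap[j])
            comp = int(ok.sum())
            if comp == 0:
                raise IoError(
                    f"no comparable columns for pair ({ids[i]}, {ids[j]})"
                )
            mism = int((arr[i][ok] != arr[j][ok]).sum())
            d[i, j] = d[j, i] = mism / comp
    return DistanceMatrix(ids, d)


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------

def nj_tree(dm: DistanceMatrix) -> dendropy.Tree:
    """Saitou-Nei neighbor joining with deterministic tie-breaking.

    Agglomerates by the Q criterion; among equal-Q pairs the one with the
    lowest (row, column) index in the current active ordering wins.
    Negative branch-length estimates are clamped to zero (the clamped
    deficit is logged).  The result is an unrooted dendropy tree whose
    seed node is the final trifurcation.
    """
    n = len(dm)
    if n < 3:
        raise IoError("neighbor joining needs at least 3 taxa")
    tns = dendropy.TaxonNamespace(dm.ids)
    size = 2 * n
    D = np.zeros((size, size))
    D[:n, :n] = dm.matrix
    nodes: dict[int, dendropy.Node] = {
        i: dendropy.Node(taxon=tns.get_taxon(t))
        for i, t in enumerate(dm.ids)
    }
    active = list(range(n))
    nxt = n
    deficit = 0.0

    def _clamp(v: float) -> float:
        nonlocal deficit
        if v < 0:
            deficit += -v
            return 0.0
        return v

    while len(active) > 3:
        m = len(active)
        sub = D[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin = lowest (row, column) pair among exact ties
        a, b = np.unravel_index(int(np.argmin(q)), q.shape)
        if a > b:
            a, b = b, a
        i, j = active[a], active[b]
        dij = D[i, j]
        vi = _clamp(0.5 * dij + (r[a] - r[b]) / (2 * (m - 2)))
        vj = _clamp(dij - (0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))))
        u = nxt
        nxt += 1
        parent = dendropy.Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes[i].edge.length = vi
        nodes[j].edge.length = vj
        nodes[u] = parent
        for k in active:
            if k in (i, j):
                continue
            D[u, k] = D[k, u] = 0.5 * (D[i, k] + D[j, k] - dij)
        active = [k for k in active if k not in (i, j)] + [u]

    i, j, k = active
    la = _clamp(0.5 * (D[i, j] + D[i, k] - D[j, k]))
    lb = _clamp(0.5 * (D[i, j] + D[j, k] - D[i, k]))
    lc = _clamp(0.5 * (D[i, k] + D[j, k] - D[i, j]))
    center = dendropy.Node()
    for node, length in ((nodes[i], la), (nodes[j], lb), (nodes[k], lc)):
        center.add_child(node)
        node.edge.length = length
    tree = dendropy.Tree(taxon_namespace=tns, seed_node=center)
    tree.is_rooted = False
    if deficit > 0:
        log.info("clamped negative NJ branch lengths, total deficit %.3g",
                 deficit)
    return tree


def patristic_matrix(tree: dendropy.Tree, ids: list[str]) -> np.ndarray:
    """Leaf-to-leaf path-length matrix in the order of ``ids``."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    n = len(ids)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
            out[i, j] = out[j, i] = d
    return out


# ---------------------------------------------------------------------------
# Bipartitions and bootstrap
# ---------------------------------------------------------------------------

def bipartitions(tree: dendropy.Tree) -> set[frozenset[frozenset[str]]]:
    """Non-trivial bipartitions of the leaf set, as unordered pairs of
    leaf-label sets (representation-independent, so rooted and unrooted
    drawings of the same topology compare equal)."""
    all_leaves = frozenset(
        lf.taxon.label for lf in tree.leaf_node_iter()
    )
    out: set[frozenset[frozenset[str]]] = set()
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(
            lf.taxon.label for lf in node.leaf_iter()
        )
        if 2 <= len(clade) <= len(all_leaves) - 2:
            out.add(frozenset({clade, all_leaves - clade}))
    return out


def same_topology(t1: dendropy.Tree, t2: dendropy.Tree) -> bool:
    """Unrooted topological equality via bipartition sets."""
    return bipartitions(t1) == bipartitions(t2)


def bootstrap_supports(
    alignment: SequenceSet,
    n_reps: int = 1000,
    seed: int = 0,
) -> dendropy.Tree:
    """NJ tree with bootstrap supports on its internal edges.

    Columns are resampled with replacement ``n_reps`` times; the support
    of an internal edge is the percentage of replicate trees containing
    the same bipartition.  Supports are stored on internal nodes as
    ``node.support`` (and as the node label, so they serialize into
    newick output).
    """
    if n_reps < 1:
        raise IoError("n_reps must be >= 1")
    tree = nj_tree(p_distance(alignment))
    ids = alignment.ids
    cols = np.array([list(s) for _, s in alignment.records]).T  # L x n
    length = cols.shape[0]
    rng = np.random.default_rng(seed)
    counts: dict[frozenset[frozenset[str]], int] = {}
    for _ in range(n_reps):
        pick = rng.integers(0, length, size=length)
        resampled = cols[pick].T
        rep = SequenceSet(
            [(ids[i], "".join(resampled[i])) for i in range(len(ids))],
            alphabet=alignment.alphabet,
        )
        for bp in bipartitions(nj_tree(p_distance(rep))):
            counts[bp] = counts.get(bp, 0) + 1
    all_leaves = frozenset(ids)
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        clade = frozenset(lf.taxon.label for lf in node.leaf_iter())
        key = frozenset({clade, all_leaves - clade})
        support = 100.0 * counts.get(key, 0) / n_reps
        node.support = support
        node.label = f"{support:g}"
    return tree


# ---------------------------------------------------------------------------
# Sister pairs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SisterPair:
    taxa: tuple[str, str]
    support: float

    def __post_init__(self) -> None:
        object.__setattr__(self, "taxa", tuple(sorted(self.taxa)))


def cherries(tree: dendropy.Tree) -> list[tuple[tuple[str, str], object]]:
    """All cherries: internal nodes joining exactly two leaves."""
    out = []
    for node in tree.preorder_node_iter():
        if node is tree.seed_node or node.is_leaf():
            continue
        kids = node.child_nodes()
        if len(kids) == 2 and all(k.is_leaf() for k in kids):
            pair = tuple(sorted(k.taxon.label for k in kids))
            out.append((pair, node))
    return out


def sister_pairs(
    tree: dendropy.Tree, threshold: float = 99.0
) -> list[SisterPair]:
    """Cherries with bootstrap support strictly above ``threshold``."""
    out = []
    for pair, node in cherries(tree):
        support = getattr(node, "support", None)
        if support is not None and support > threshold:
            out.append(SisterPair(taxa=pair, support=support))
    return sorted(out, key=lambda p: p.taxa)
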