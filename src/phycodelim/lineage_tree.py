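"""Distance trees with bootstrap support for clustering strains into lineages.

This is deliberately lightweight plumbing: the study-grade trees (ML,
Bayesian) come from external programs, and their support values can be
imported onto bipartitions via a TSV.  In-repo, an uncorrected p-distance +
neighbor-joining tree with nonparametric bootstrap is enough to recover the
strongly separated lineages the delimitation step consumes.

Neighbor joining is implemented here with a documented deterministic
tie-break (smallest ``(i, j)`` index pair on equal Q-values) because the
topology depends on it; trees are carried as :mod:`dendropy` objects so
newick IO and rerooting come from an established library.
"""

from __future__ import annotations

from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .io_formats import UNAMBIGUOUS, SequenceRecord


class TreeError(ValueError):
    pass


@dataclass
class LineageTree:
    """An unrooted strain tree with bootstrap supports on internal edges.

    Supports live on ``edge.support`` (floats, 0..100) of the underlying
    dendropy tree; leaf taxa are strain IDs.
    """

    tree: dendropy.Tree
    taxa: tuple[str, ...]

    def newick(self) -> str:
        """Newick with supports as internal node labels."""
        for nd in self.tree.preorder_node_iter():
            sup = getattr(nd.edge, "support", None)
            if sup is not None and not nd.is_leaf():
                nd.label = f"{sup:g}"
        return self.tree.as_string(schema="newick").strip()

    def bipartitions(self) -> dict[frozenset, float | None]:
        """Internal bipartitions as the leaf-set side not containing the
        reference (first) taxon, mapped to their support (None if unset)."""
        ref = self.taxa[0]
        out = {}
        all_taxa = frozenset(self.taxa)
        for nd in self.tree.preorder_internal_node_iter():
            leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
            if len(leaves) in (0, 1, len(self.taxa)):
                continue
            side = leaves if ref not in leaves else all_taxa - leaves
            if len(side) < 2 or len(side) > len(self.taxa) - 2:
                continue
            out[side] = getattr(nd.edge, "support", None)
        return out


# ---------------------------------------------------------------------------
# Distances

def p_distance_matrix(records: list[SequenceRecord]) -> pd.DataFrame:
    """Uncorrected p-distances over pairwise comparable columns.

    A column is comparable for a pair when both strains carry an
    unambiguous, non-gap base.  A pair with zero comparable columns is an
    error.
    """
    if len(records) < 3:
        raise TreeError("need at least 3 sequences")
    lengths = {len(r.sequence) for r in records}
    if len(lengths) != 1:
        raise TreeError(f"unequal aligned lengths: {sorted(lengths)}")
    ids = [r.id for r in records]
    arr = np.array([list(r.sequence) for r in records])
    ok = np.isin(arr, sorted(UNAMBIGUOUS))
    n = len(records)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            comparable = ok[i] & ok[j]
            m = int(comparable.sum())
            if m == 0:
                raise TreeError(
                    f"no comparable columns between {ids[i]!r} and {ids[j]!r}")
            diffs = int((arr[i][comparable] != arr[j][comparable]).sum())
            d[i, j] = d[j, i] = diffs / m
    return pd.DataFrame(d, index=ids, columns=ids)


# ---------------------------------------------------------------------------
# Neighbor joining

def nj_tree(matrix: pd.DataFrame) -> LineageTree:
    """Standard neighbor-joining agglomeration.

    Deterministic given input order: on equal Q-values the smallest
    ``(i, j)`` pair in current working order is joined.  Negative branch
    length estimates are clamped to zero.  Recovers additive matrices
    exactly (up to the clamp, which additive input never triggers).
    """
    d = np.asarray(matrix, dtype=float)
    ids = list(matrix.index)
    if d.shape[0] != d.shape[1] or not np.allclose(d, d.T):
        raise TreeError("distance matrix must be symmetric")
    if (d < 0).any():
        raise TreeError("distance matrix must be non-negative")
    n = len(ids)
    if n < 3:
        raise TreeError("need at least 3 taxa")

    taxon_ns = dendropy.TaxonNamespace(ids)
    tree = dendropy.Tree(taxon_namespace=taxon_ns)
    nodes = []
    for label in ids:
        nd = dendropy.Node(taxon=taxon_ns.get_taxon(label))
        nodes.append(nd)

    D = d.copy()
    active = list(range(n))

    def join(i_pos, j_pos):
        """Join active entries at positions i_pos < j_pos; return new node."""
        nonlocal D, active, nodes
        m = len(active)
        r = D.sum(axis=0)
        dij = D[i_pos, j_pos]
        li = dij / 2 + (r[i_pos] - r[j_pos]) / (2 * (m - 2))
        lj = dij - li
        li, lj = max(li, 0.0), max(lj, 0.0)
        new = dendropy.Node()
        new.add_child(nodes[active[i_pos]])
        nodes[active[i_pos]].edge.length = li
        new.add_child(nodes[active[j_pos]])
        nodes[active[j_pos]].edge.length = lj
        dnew = 0.5 * (D[i_pos, :] + D[j_pos, :] - dij)
        keep = [k for k in range(m) if k not in (i_pos, j_pos)]
        D2 = np.empty((m - 1, m - 1))
        D2[:-1, :-1] = D[np.ix_(keep, keep)]
        D2[-1, :-1] = D2[:-1, -1] = dnew[keep]
        D2[-1, -1] = 0.0
        nodes.append(new)
        active = [active[k] for k in keep] + [len(nodes) - 1]
        D = D2
        return new

    while len(active) > 3:
        m = len(active)
        r = D.sum(axis=0)
        Q = (m - 2) * D - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        best = None
        for i in range(m):
            for j in range(i + 1, m):
                if best is None or Q[i, j] < Q[best] - 1e-12:
                    best = (i, j)
        join(*best)

    # final star join of the remaining three
    root = dendropy.Node()
    dij, dik, djk = D[0, 1], D[0, 2], D[1, 2]
    lens = [(dij + dik - djk) / 2, (dij + djk - dik) / 2,
            (dik + djk - dij) / 2]
    for pos, ln in zip(range(3), lens):
        root.add_child(nodes[active[pos]])
        nodes[active[pos]].edge.length = max(ln, 0.0)
    tree.seed_node = root
    tree.update_bipartitions(suppress_unifurcations=False)
    return LineageTree(tree, tuple(ids))


# ---------------------------------------------------------------------------
# Bootstrap

def bootstrap_supports(records: list[SequenceRecord], n_replicates: int = 100,
                       seed: int = 0) -> LineageTree:
    """NJ tree with nonparametric bootstrap supports (percent).

    Alignment columns are resampled with replacement ``n_replicates``
    times; the support of each internal bipartition of the original tree
    is the percentage of replicate trees containing it.  Reproducible
    given ``seed``.
    """
    if n_replicates < 1:
        raise TreeError("n_replicates must be >= 1")
    base = nj_tree(p_distance_matrix(records))
    original = {bp: 0 for bp in base.bipartitions()}
    rng = np.random.default_rng(seed)
    ncol = len(records[0].sequence)
    for _ in range(n_replicates):
        cols = rng.integers(0, ncol, size=ncol)
        resampled = [SequenceRecord(r.id, "".join(r.sequence[c] for c in cols))
                     for r in records]
        rep = nj_tree(p_distance_matrix(resampled))
        for bp in rep.bipartitions():
            if bp in original:
                original[bp] += 1
    supports = {bp: 100.0 * k / n_replicates for bp, k in original.items()}
    _attach_supports(base, supports)
    return base


def _attach_supports(ltree: LineageTree, supports: dict[frozenset, float]):
    ref = ltree.taxa[0]
    all_taxa = frozenset(ltree.taxa)
    for nd in ltree.tree.preorder_internal_node_iter():
        leaves = frozenset(l.taxon.label for l in nd.leaf_iter())
        side = leaves if ref not in leaves else all_taxa - leaves
        if side in supports:
            nd.edge.support = supports[side]


def import_supports(ltree: LineageTree, table: pd.DataFrame) -> LineageTree:
    """Attach externally computed supports onto matching bipartitions.

    ``table`` needs columns ``bipartition`` (comma-separated strain IDs of
    one side) and ``support``; this is how support values from external
    ML/Bayesian analyses are plugged in.
    """
    ref = ltree.taxa[0]
    all_taxa = frozenset(ltree.taxa)
    supports = {}
    for row in table.itertuples(index=False):
        side = frozenset(s.strip() for s in str(row.bipartition).split(","))
        if ref in side:
            side = all_taxa - side
        supports[side] = float(row.support)
    _attach_supports(ltree, supports)
    return ltree


# ---------------------------------------------------------------------------
# Supported lineages

def supported_lineages(ltree: LineageTree, min_support: float = 70.0,
                       outgroup: str | None = None) -> list[frozenset]:
    """Partition strains into maximal supported clades.

    The tree is rooted at the declared outgroup, else at the midpoint.
    Walking from the root, every maximal clade whose subtending edge
    carries support >= ``min_support`` becomes one lineage; strains not in
    any supported clade become singletons.  A star tree yields all
    singletons.
    """
    if not 0 <= min_support <= 100:
        raise TreeError("support threshold must be in 0..100")
    # supports are looked up by bipartition side, which is rooting-invariant
    supports = ltree.bipartitions()
    ref = ltree.taxa[0]
    all_taxa = frozenset(ltree.taxa)
    work = dendropy.Tree(ltree.tree)  # clone before rerooting
    if outgroup is not None:
        leaf = work.find_node_with_taxon_label(outgroup)
        if leaf is None:
            raise TreeError(f"outgroup {outgroup!r} not in tree")
        work.reroot_at_edge(leaf.edge, update_bipartitions=False)
    else:
        work.reroot_at_midpoint(update_bipartitions=False)

    lineages: list[frozenset] = []
    assigned: set[str] = set()

    def edge_support(node) -> float | None:
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(leaves) >= len(all_taxa):
            return None
        side = leaves if ref not in leaves else all_taxa - leaves
        return supports.get(side)

    def has_supported_substructure(node) -> bool:
        for nd in node.preorder_internal_node_iter():
            if nd is node:
                continue
            sup = edge_support(nd)
            if sup is not None and sup >= min_support:
                return True
        return False

    def visit(node, at_root):
        if node.is_leaf():
            return
        for child in node.child_nodes():
            if child.is_leaf():
                continue
            sup = edge_support(child)
            if sup is not None and sup >= min_support:
                # a root child's subtending edge is the rooting edge; when
                # the data support finer clades inside it, report those
                if at_root and has_supported_substructure(child):
                    visit(child, False)
                else:
                    leaves = frozenset(
                        l.taxon.label for l in child.leaf_iter())
                    lineages.append(leaves)
                    assigned.update(leaves)
            else:
                visit(child, False)

    visit(work.seed_node, True)

    # A supported split can sit exactly at the root (e.g. a midpoint that
    # lands on a node), in which case neither side is a rooted clade during
    # the traversal.  Promote supported bipartition sides whose strains are
    # all still unassigned, finest first.
    candidates = []
    for side, sup in supports.items():
        if sup is None or sup < min_support:
            continue
        for s in (side, all_taxa - side):
            if 2 <= len(s) <= len(all_taxa) - 2:
                candidates.append(s)
    for s in sorted(set(candidates), key=lambda s: (len(s), sorted(s))):
        if not s & assigned:
            lineages.append(s)
            assigned.update(s)

    for t in ltree.taxa:
        if t not in assigned:
            lineages.append(frozenset([t]))
    return sorted(lineages, key=lambda s: min(s))
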