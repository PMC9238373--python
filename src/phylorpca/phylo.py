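"""Rooted phylogenies: parsing, indexing, node expansion, and control trees.

A :class:`Phylogeny` wraps a :class:`skbio.TreeNode` and adds the bookkeeping
the downstream transforms need: a cached postorder index, unique tip names,
and stable ids for internal nodes (``n<postorder-rank>`` for nodes the newick
left unnamed).  Count tables are expanded Fast-UniFrac style: every internal
node receives a column holding the summed counts of its descendant tips, and
every non-root node carries a branch-length weight.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from skbio import TreeNode

logger = logging.getLogger("phylorpca")

__all__ = [
    "Phylogeny",
    "ExpandedTable",
    "parse_newick",
    "write_newick",
    "expand_table",
    "prune_tree",
    "shuffle_tips",
    "random_tree",
    "tips_under",
]


@dataclass
class ExpandedTable:
    """Samples x nodes count matrix (tips + internal nodes, root excluded).

    ``counts`` columns follow the tree postorder restricted to non-root
    nodes; ``branch_weights`` is aligned to the same columns and holds each
    node's branch length (its distance to its parent).
    """

    counts: pd.DataFrame
    branch_weights: pd.Series

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.branch_weights.index):
            raise ValueError("counts columns and branch_weights index differ")


class Phylogeny:
    """A rooted tree with branch lengths and a stable node index."""

    def __init__(self, root: TreeNode, default_length: float = 1.0):
        self._root = root
        self._validate_and_index(default_length)

    # -- construction helpers -------------------------------------------------
    def _validate_and_index(self, default_length: float) -> None:
        root = self._root
        seen_tips: set[str] = set()
        n_defaulted = 0
        postorder = list(root.postorder(include_self=True))
        for rank, node in enumerate(postorder):
            if node.is_tip():
                if node.name is None or node.name == "":
                    raise ValueError("unnamed tip in tree")
                if node.name in seen_tips:
                    raise ValueError(f"duplicate tip name {node.name}")
                seen_tips.add(node.name)
            elif node.name is None or node.name == "":
                node.name = f"n{rank}"
            if node is root:
                node.length = None
            elif node.length is None:
                node.length = default_length
                n_defaulted += 1
            elif node.length < 0:
                raise ValueError(f"negative branch length at {node.name}")
        if n_defaulted:
            logger.warning(
                "%d branch lengths missing from newick; defaulted to %.3g",
                n_defaulted,
                default_length,
            )
        names = [n.name for n in postorder]
        if len(set(names)) != len(names):
            # internal auto-names may collide with user names; disambiguate
            used: set[str] = set()
            for node in postorder:
                base = node.name
                if base in used and not node.is_tip():
                    k = 1
                    while f"{base}.{k}" in used:
                        k += 1
                    node.name = f"{base}.{k}"
                used.add(node.name)
        self._postorder = postorder
        self._index = {n.name: n for n in postorder}
        self._tips = [n.name for n in postorder if n.is_tip()]

    # -- basic accessors ------------------------------------------------------
    @property
    def root(self) -> TreeNode:
        return self._root

    @property
    def tip_names(self) -> list[str]:
        return list(self._tips)

    @property
    def internal_ids(self) -> list[str]:
        return [n.name for n in self._postorder if not n.is_tip()]

    @property
    def postorder_ids(self) -> list[str]:
        """Names of all nodes in postorder (children before parents)."""
        return [n.name for n in self._postorder]

    def node(self, node_id: str) -> TreeNode:
        try:
            return self._index[node_id]
        except KeyError:
            raise KeyError(f"unknown node id {node_id!r}") from None

    def __contains__(self, node_id: str) -> bool:
        return node_id in self._index

    def __len__(self) -> int:
        return len(self._postorder)

    def copy(self) -> "Phylogeny":
        return Phylogeny(self._root.copy())

    def write_newick(self) -> str:
        buf = io.StringIO()
        self._root.write(buf)
        return buf.getvalue().strip()

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"<Phylogeny: {len(self._tips)} tips, {len(self)} nodes>"


def parse_newick(text: str, default_length: float = 1.0) -> Phylogeny:
    """Parse a rooted newick string into an indexed :class:`Phylogeny`.

    Missing branch lengths default to ``default_length`` (the root keeps no
    length).  Raises ``ValueError`` on empty input, malformed newick or
    duplicate tip names.
    """
    if text is None or not text.strip():
        raise ValueError("empty newick")
    try:
        root = TreeNode.read(io.StringIO(text))
    except Exception as exc:
        raise ValueError(f"malformed newick: {exc}") from exc
    return Phylogeny(root, default_length=default_length)


def write_newick(tree: Phylogeny) -> str:
    return tree.write_newick()


def tips_under(tree: Phylogeny, node_id: str) -> set[str]:
    """Descendant tip names of a node; for a tip, its own singleton set."""
    node = tree.node(node_id)
    if node.is_tip():
        return {node.name}
    return {t.name for t in node.tips()}


def expand_table(
    table: pd.DataFrame, tree: Phylogeny
) -> tuple[ExpandedTable, pd.Series]:
    """Expand a samples x features count table to all non-root tree nodes.

    Every feature must be a tip of ``tree``; the tree is first sheared to the
    table's features.  Each internal node's column is the per-sample sum of
    its descendant tip columns; each column carries the node's branch length
    as weight.  Nodes with zero branch weight are dropped (their weighted
    proportion would be 0, hence log-undefined).

    Returns ``(ExpandedTable, branch_weights)`` with identically ordered
    columns (postorder, root excluded).
    """
    if (table.values < 0).any():
        raise ValueError("negative counts in table")
    features = list(table.columns)
    missing = set(features) - set(tree.tip_names)
    if missing:
        raise ValueError(
            f"table features absent from tree: {sorted(missing)[:5]}"
            + ("..." if len(missing) > 5 else "")
        )
    if set(features) != set(tree.tip_names):
        tree = prune_tree(tree, set(features))

    n_samples = len(table.index)
    col_values: dict[str, np.ndarray] = {}
    weights: dict[str, float] = {}
    # postorder accumulation: child columns are ready before the parent
    node_sums: dict[int, np.ndarray] = {}
    for node in tree.root.postorder(include_self=True):
        if node.is_tip():
            vec = table[node.name].to_numpy(dtype=float)
        else:
            vec = np.zeros(n_samples)
            for child in node.children:
                vec = vec + node_sums[id(child)]
        node_sums[id(node)] = vec
        if node is tree.root:
            continue
        if node.length > 0:
            col_values[node.name] = vec
            weights[node.name] = float(node.length)
    counts = pd.DataFrame(col_values, index=table.index)
    bw = pd.Series(weights, dtype=float).reindex(counts.columns)
    return ExpandedTable(counts, bw), bw


def prune_tree(
    tree: Phylogeny, keep_tips: set[str], min_subtree_tips: int = 1
) -> Phylogeny:
    """Shear a tree to ``keep_tips``, collapsing unary chains.

    Branch lengths along collapsed chains are summed, so tip-to-root path
    lengths are preserved.  Internal nodes whose subtree retains fewer than
    ``min_subtree_tips`` tips are additionally collapsed into their parent
    (children inherit the removed node's branch length), which removes them
    from downstream node expansion without touching the tip set.
    """
    keep_tips = set(keep_tips)
    if not keep_tips:
        raise ValueError("keep_tips is empty")
    missing = keep_tips - set(tree.tip_names)
    if missing:
        raise ValueError(f"keep_tips not in tree: {sorted(missing)[:5]}")
    sheared = tree.root.copy().shear(keep_tips)
    sheared.prune()
    if min_subtree_tips > 1:
        changed = True
        while changed:
            changed = False
            for node in list(sheared.postorder(include_self=False)):
                if node.is_tip() or node.parent is None:
                    continue
                if node.count(tips=True) < min_subtree_tips:
                    parent = node.parent
                    for child in list(node.children):
                        node.remove(child)
                        if child.length is not None and node.length is not None:
                            child.length += node.length
                        parent.append(child)
                    parent.remove(node)
                    changed = True
    return Phylogeny(sheared)


def shuffle_tips(tree: Phylogeny, proportion: float, seed: int) -> Phylogeny:
    """Permute the labels of a seeded random subset of tips.

    ``k = round(proportion * n_tips)`` tips are chosen uniformly and their
    labels permuted uniformly among themselves (fixed points allowed);
    topology and branch lengths are untouched.
    """
    if not 0.0 <= proportion <= 1.0:
        raise ValueError("proportion must be in [0, 1]")
    out = tree.copy()
    if proportion == 0.0:
        return out
    rng = np.random.default_rng(seed)
    tips = [out.node(t) for t in out.tip_names]
    k = int(round(proportion * len(tips)))
    if k < 2:
        return out
    chosen = rng.choice(len(tips), size=k, replace=False)
    perm = rng.permutation(k)
    labels = [tips[i].name for i in chosen]
    for slot, tip_idx in enumerate(chosen):
        tips[tip_idx].name = labels[perm[slot]]
    return Phylogeny(out.root)


def random_tree(tip_ids: list[str], seed: int) -> Phylogeny:
    """Random binary rooted tree over ``tip_ids`` with no phylogenetic signal.

    Built by seeded random sequential joins; every non-root branch length is
    drawn from an exponential with mean 1.  Same seed, same tree.
    """
    if not tip_ids:
        raise ValueError("tip_ids is empty")
    if len(set(tip_ids)) != len(tip_ids):
        raise ValueError("duplicate tip_ids")
    rng = np.random.default_rng(seed)
    nodes = [TreeNode(name=t) for t in tip_ids]
    while len(nodes) > 1:
        i, j = rng.choice(len(nodes), size=2, replace=False)
        a, b = nodes[i], nodes[j]
        parent = TreeNode(children=[a, b])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    root = nodes[0]
    for node in root.postorder(include_self=True):
        if node is not root:
            node.length = float(rng.exponential(1.0))
    return Phylogeny(root)
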