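"""Newick I/O and tree algebra.

A :class:`PhyloTree` wraps a rooted dendropy tree and exposes the quantities
the host-shift test needs: patristic distances between tips, the set of
branches "covered" by a subset of tips (the support of the unweighted
UniFrac index), and distance-preserving pruning.

Conventions
-----------
* Tip labels are normalized on input: surrounding whitespace is trimmed and
  internal spaces are unified to underscores, so ``"Acer mono"`` and
  ``"Acer_mono "`` refer to the same taxon.
* A branch length attached to the root (``...):x;``) is ignored for both
  distances and branch coverage: it lies on no tip-to-tip path, and
  unweighted UniFrac conventionally excludes it.
* Polytomies are accepted and preserved.  Zero-length branches are allowed
  with a warning (patristic distance is then a semimetric).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloTree",
    "BranchSet",
    "NewickParseError",
    "TreeValidationError",
    "parse_newick",
    "patristic_matrix",
    "covered_branches",
    "prune",
]


class NewickParseError(ValueError):
    """Malformed Newick input; message carries the reader's line/column."""


class TreeValidationError(ValueError):
    """Structurally valid Newick that violates a tree invariant."""


def normalize_label(label: str) -> str:
    """Trim surrounding whitespace and unify internal spaces to underscores."""
    return "_".join(str(label).strip().split())


@dataclass(frozen=True)
class BranchSet:
    """Branches of a reference tree covered by a set of tips.

    ``ids`` are indices into the owning tree's internal branch table;
    ``lengths`` are the corresponding branch lengths.
    """

    ids: frozenset[int]
    lengths: dict[int, float] = field(repr=False)

    @property
    def total_length(self) -> float:
        return float(sum(self.lengths[i] for i in self.ids))

    def __len__(self) -> int:
        return len(self.ids)


class PhyloTree:
    """Rooted phylogeny with branch lengths and uniquely labeled tips.

    Parameters
    ----------
    tree:
        A dendropy tree.  Ownership passes to the new object; callers should
        not mutate it afterwards.
    require_lengths:
        If True (default) every non-root branch must carry a length;
        a missing length raises :class:`TreeValidationError` naming the node.
    default_length:
        If not None, branches without an explicit length receive this value
        instead of raising.
    """

    def __init__(
        self,
        tree: dendropy.Tree,
        *,
        require_lengths: bool = True,
        default_length: float | None = None,
    ) -> None:
        self._tree = tree
        self._normalize_and_validate(require_lengths, default_length)
        self._index()

    # -- construction helpers -------------------------------------------------

    def _normalize_and_validate(
        self, require_lengths: bool, default_length: float | None
    ) -> None:
        seen: dict[str, int] = {}
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon is None or not str(leaf.taxon.label).strip():
                raise TreeValidationError("tree has an unlabeled tip")
            leaf.taxon.label = normalize_label(leaf.taxon.label)
            seen[leaf.taxon.label] = seen.get(leaf.taxon.label, 0) + 1
        dups = sorted(k for k, v in seen.items() if v > 1)
        if dups:
            raise TreeValidationError(f"duplicate tip labels: {', '.join(dups)}")

        zero_lengths = 0
        for node in self._tree.preorder_node_iter():
            if node is self._tree.seed_node:
                continue  # root edge ignored by convention
            bl = node.edge.length
            if bl is None:
                if default_length is not None:
                    node.edge.length = bl = float(default_length)
                elif require_lengths:
                    name = node.taxon.label if node.taxon else "an internal node"
                    raise TreeValidationError(
                        f"missing branch length on the branch above {name}"
                    )
                else:
                    node.edge.length = bl = 0.0
            if not np.isfinite(bl) or bl < 0:
                raise TreeValidationError(f"non-finite or negative branch length {bl}")
            if bl == 0:
                zero_lengths += 1
        if zero_lengths:
            warnings.warn(
                f"{zero_lengths} zero-length branch(es); patristic distance is a "
                "semimetric on this tree",
                stacklevel=3,
            )

    def _index(self) -> None:
        # Tips in a stable (leaf-iteration) order; branch table over all
        # non-root nodes, each branch identified with the node below it.
        leaves = list(self._tree.leaf_node_iter())
        self.tip_labels: tuple[str, ...] = tuple(l.taxon.label for l in leaves)
        tip_pos = {id(l): i for i, l in enumerate(leaves)}
        n_tips = len(leaves)

        branch_nodes = [
            nd for nd in self._tree.preorder_node_iter() if nd is not self._tree.seed_node
        ]
        self._branch_lengths = np.array(
            [nd.edge.length for nd in branch_nodes], dtype=float
        )
        # mask[e, t] == True iff tip t descends from (or is) the node below branch e
        mask = np.zeros((len(branch_nodes), n_tips), dtype=bool)
        below: dict[int, np.ndarray] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                row = np.zeros(n_tips, dtype=bool)
                row[tip_pos[id(nd)]] = True
            else:
                row = np.zeros(n_tips, dtype=bool)
                for ch in nd.child_nodes():
                    row |= below[id(ch)]
            below[id(nd)] = row
        for e, nd in enumerate(branch_nodes):
            mask[e] = below[id(nd)]
        self._branch_tip_mask = mask
        self._tip_index = {lab: i for i, lab in enumerate(self.tip_labels)}
        self._patristic_cache: pd.DataFrame | None = None

    # -- basic queries --------------------------------------------------------

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    @property
    def total_branch_length(self) -> float:
        """Sum of all branch lengths, root edge excluded."""
        return float(self._branch_lengths.sum())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def as_newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return f"<PhyloTree with {self.n_tips} tips>"

    # -- patristic distances --------------------------------------------------

    def patristic_matrix(self) -> pd.DataFrame:
        """All-pairs patristic distances as a labeled, symmetric DataFrame.

        d(i, j) is the sum of branch lengths on the unique path between tips
        i and j.  Computed once and cached.
        """
        if self._patristic_cache is not None:
            return self._patristic_cache
        n = self.n_tips
        dist = np.zeros((n, n), dtype=float)
        # depth of each tip below each node is accumulated postorder: at each
        # internal node, tips in different child subtrees meet for the first
        # time, so their path length is the sum of their depths below it.
        depths: dict[int, list[tuple[int, float]]] = {}
        for nd in self._tree.postorder_node_iter():
            if nd.is_leaf():
                depths[id(nd)] = [(self._tip_index[nd.taxon.label], 0.0)]
                continue
            children = nd.child_nodes()
            lists = []
            for ch in children:
                lists.append([(t, d + ch.edge.length) for t, d in depths.pop(id(ch))])
            for a in range(len(lists)):
                for b in range(a + 1, len(lists)):
                    for ti, di in lists[a]:
                        for tj, dj in lists[b]:
                            dist[ti, tj] = dist[tj, ti] = di + dj
            depths[id(nd)] = [pair for lst in lists for pair in lst]
        self._patristic_cache = pd.DataFrame(
            dist, index=list(self.tip_labels), columns=list(self.tip_labels)
        )
        return self._patristic_cache

    # -- branch coverage (UniFrac support) ------------------------------------

    def coverage_vector(self, tips: set[str] | frozenset[str]) -> np.ndarray:
        """Boolean vector over branches: covered by ≥1 member of ``tips``."""
        if not tips:
            raise ValueError("empty tip set has no covered branches")
        idx = []
        for lab in tips:
            lab = normalize_label(lab)
            if lab not in self._tip_index:
                raise KeyError(f"label {lab!r} is not a tip of this tree")
            idx.append(self._tip_index[lab])
        sel = np.zeros(self.n_tips, dtype=bool)
        sel[idx] = True
        return self._branch_tip_mask @ sel  # bool matmul: any shared tip

    def covered_branches(self, tips: set[str] | frozenset[str]) -> BranchSet:
        """Branches with at least one member of ``tips`` among their descendants."""
        cov = self.coverage_vector(tips)
        ids = frozenset(int(i) for i in np.nonzero(cov)[0])
        return BranchSet(ids=ids, lengths={int(i): float(self._branch_lengths[i]) for i in ids})

    @property
    def branch_lengths(self) -> np.ndarray:
        """Lengths of all non-root branches, aligned with coverage vectors."""
        return self._branch_lengths

    # -- pruning ---------------------------------------------------------------

    def prune(self, keep: set[str]) -> "PhyloTree":
        """Induced subtree on ``keep``; patristic distances among kept tips
        are preserved (collapsed unifurcations have their lengths summed)."""
        keep_norm = {normalize_label(k) for k in keep}
        unknown = sorted(keep_norm - set(self.tip_labels))
        if unknown:
            raise KeyError(f"labels not on tree: {', '.join(unknown)}")
        if len(keep_norm) < 2:
            raise ValueError("prune requires at least 2 tips to keep")
        clone = self._tree.clone(depth=1)
        clone.retain_taxa_with_labels(sorted(keep_norm))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return PhyloTree(clone)


# -- module-level functional surface ------------------------------------------


def parse_newick(
    text: str,
    *,
    require_lengths: bool = True,
    default_length: float | None = None,
) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Raises :class:`NewickParseError` on malformed input (the message carries
    the reader's character position) and :class:`TreeValidationError` on
    duplicate tip labels or missing/invalid branch lengths.
    """
    if not text or not text.strip():
        raise NewickParseError("empty Newick string")
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
            preserve_underscores=True,
        )
    except dendropy.utility.error.DataParseError as exc:
        if "Duplicate taxon labels" in str(exc) or "Multiple occurrences" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(str(exc)) from exc
    return PhyloTree(tree, require_lengths=require_lengths, default_length=default_length)


def read_newick(path, **kwargs) -> PhyloTree:
    """Read a Newick file from ``path`` (thin wrapper over parse_newick)."""
    with open(path) as fh:
        return parse_newick(fh.read(), **kwargs)


def patristic_matrix(tree: PhyloTree) -> pd.DataFrame:
    return tree.patristic_matrix()


def covered_branches(tree: PhyloTree, host_set: set[str]) -> BranchSet:
    return tree.covered_branches(host_set)


def prune(tree: PhyloTree, keep: set[str]) -> PhyloTree:
    return tree.prune(keep)
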