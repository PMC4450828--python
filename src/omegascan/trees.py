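"""Phylogenetic trees with codeml-style foreground branch tags.

Trees are read from newick via dendropy.  A branch may carry the codeml
foreground tag ``#1`` (e.g. ``(A#1:0.1,B:0.1)``); since ``#`` starts a
comment in strict newick, tags are extracted before parsing and
re-attached afterwards.  Internally a tree is a flat postorder array
structure tuned for the pruning likelihood: each node owns the branch
above it.

Branch labels: a terminal branch is labelled with its taxon name; an
internal branch with the sorted descendant leaf names joined by ``|``.
These labels are the lineage identifiers used by the rates tables.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

_TAG = re.compile(r"\s*#\s*1")


@dataclass
class PhyloTree:
    """Rooted topology; node 0..n-1 in postorder, root last.

    ``parent[i]`` is -1 for the root. ``lengths[i]`` is the branch above
    node ``i`` (0 for the root).  ``names[i]`` is the taxon name for
    leaves, ``""`` for internal nodes.  ``foreground`` holds the node id
    of the flagged branch, or None.
    """

    parent: np.ndarray
    lengths: np.ndarray
    names: list[str]
    children: list[list[int]]
    foreground: int | None = None
    postorder: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.postorder:
            self.postorder = list(range(self.n_nodes))
        leaves = [n for n in self.names if n]
        if len(set(leaves)) != len(leaves):
            raise ValueError("duplicate leaf names")

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    @property
    def root(self) -> int:
        return int(np.nonzero(self.parent < 0)[0][0])

    @property
    def leaves(self) -> list[int]:
        """Nodes carrying an observed taxon.

        After collapsing a 2-taxon tree's root, the root is a named leaf
        that also has a child, so "has a name" is the defining property.
        """
        return [
            i for i in range(self.n_nodes) if self.names[i] or not self.children[i]
        ]

    @property
    def leaf_names(self) -> list[str]:
        return [self.names[i] for i in self.leaves]

    def descendant_leaves(self, i: int) -> list[str]:
        if not self.children[i]:
            return [self.names[i]]
        out: list[str] = []
        for c in self.children[i]:
            out.extend(self.descendant_leaves(c))
        return out

    def branch_label(self, i: int) -> str:
        if not self.children[i]:
            return self.names[i]
        return "|".join(sorted(self.descendant_leaves(i)))

    def branch_nodes(self) -> list[int]:
        """Nodes owning a real branch (everything but the root), postorder."""
        r = self.root
        return [i for i in self.postorder if i != r]

    def label_to_node(self) -> dict[str, int]:
        return {self.branch_label(i): i for i in self.branch_nodes()}

    def with_foreground(self, label: str) -> "PhyloTree":
        """Return a copy with the branch of the given label flagged."""
        mapping = self.label_to_node()
        if label not in mapping:
            raise KeyError(f"no branch labelled {label!r}; have {sorted(mapping)}")
        return PhyloTree(
            parent=self.parent.copy(),
            lengths=self.lengths.copy(),
            names=list(self.names),
            children=[list(c) for c in self.children],
            foreground=mapping[label],
            postorder=list(self.postorder),
        )

    # ------------------------------------------------------------------
    def unrooted(self) -> "PhyloTree":
        """Collapse a degree-2 root: merge its two child branches.

        Under a reversible model the two root-adjacent branch lengths are
        not separately identifiable, so fitting is done on the collapsed
        tree.  One child becomes the new root; the other is re-attached
        beneath it with the summed length.  Trees whose root already has
        >= 3 children (or a 2-taxon tree, where the root becomes a leaf)
        are handled uniformly.
        """
        r = self.root
        if len(self.children[r]) != 2:
            return self
        c1, c2 = self.children[r]
        # prefer an internal node as the new root
        if not self.children[c1] and self.children[c2]:
            c1, c2 = c2, c1
        keep = [i for i in range(self.n_nodes) if i != r]
        remap = {old: new for new, old in enumerate(keep)}
        parent = np.array(
            [remap[self.parent[i]] if self.parent[i] != r else -1 for i in keep]
        )
        parent[remap[c2]] = remap[c1]
        lengths = self.lengths[keep].copy()
        lengths[remap[c1]] = 0.0
        lengths[remap[c2]] = self.lengths[c1] + self.lengths[c2]
        children = [[remap[c] for c in self.children[i]] for i in keep]
        children[remap[c1]] = children[remap[c1]] + [remap[c2]]
        fg = self.foreground
        if fg is not None:
            fg = remap[fg] if fg != r else None
            if self.foreground in (c1, c2):
                fg = remap[c2]  # merged branch inherits the tag
        order = _postorder(children, remap[c1])
        return PhyloTree(
            parent=parent,
            lengths=lengths,
            names=[self.names[i] for i in keep],
            children=children,
            foreground=fg,
            postorder=order,
        )

    # ------------------------------------------------------------------
    def to_newick(self, include_foreground: bool = True) -> str:
        def rec(i: int) -> str:
            tag = "#1" if include_foreground and i == self.foreground else ""
            if not self.children[i]:
                return f"{self.names[i]}{tag}:{self.lengths[i]:.6g}"
            inner = ",".join(rec(c) for c in self.children[i])
            if self.parent[i] < 0:
                return f"({inner})"
            return f"({inner}){tag}:{self.lengths[i]:.6g}"

        return rec(self.root) + ";"


def _postorder(children: list[list[int]], root: int) -> list[int]:
    order: list[int] = []
    stack = [(root, False)]
    while stack:
        node, done = stack.pop()
        if done:
            order.append(node)
        else:
            stack.append((node, True))
            for c in reversed(children[node]):
                stack.append((c, False))
    return order


def parse_newick(text: str) -> PhyloTree:
    """Parse newick, honouring a single codeml-style ``#1`` foreground tag."""
    n_tags = len(_TAG.findall(text))
    if n_tags > 1:
        raise ValueError("at most one branch may carry the #1 foreground tag")
    marker = "__FG1__"
    clean = _TAG.sub(marker, text)
    try:
        dt = dendropy.Tree.get(data=clean, schema="newick",
                               suppress_internal_node_taxa=False,
                               preserve_underscores=True)
    except Exception as e:  # dendropy raises schema-specific errors
        raise ValueError(f"malformed newick: {e}") from e
    nodes = list(dt.postorder_node_iter())
    index = {id(nd): i for i, nd in enumerate(nodes)}
    n = len(nodes)
    parent = np.full(n, -1, dtype=int)
    lengths = np.zeros(n)
    names: list[str] = [""] * n
    children: list[list[int]] = [[] for _ in range(n)]
    fg = None
    for i, nd in enumerate(nodes):
        label = nd.taxon.label if nd.taxon else (nd.label or "")
        if marker in label:
            fg = i
            label = label.replace(marker, "").strip()
        if nd.is_leaf():
            names[i] = label
        lengths[i] = nd.edge.length or 0.0
        if nd.parent_node is not None:
            parent[i] = index[id(nd.parent_node)]
            children[parent[i]].append(i)
    return PhyloTree(parent=parent, lengths=lengths, names=names,
                     children=children, foreground=fg,
                     postorder=list(range(n)))


def read_tree(path) -> PhyloTree:
    with open(path) as fh:
        return parse_newick(fh.read())


def write_tree(tree: PhyloTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.to_newick() + "\n")
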