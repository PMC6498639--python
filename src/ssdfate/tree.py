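"""Rooted species-tree wrapper used by the family-size reconstruction.

The reconstruction only needs tree topology, stable node labels and
parent/child lookups; branch lengths are carried through but never used
by the parsimony machinery.  Parsing is delegated to dendropy.
"""

from __future__ import annotations

from typing import Dict, Iterator, List, Optional

import dendropy


class SpeciesTree:
    """A rooted, labelled species phylogeny.

    Internal nodes without a Newick label receive deterministic labels
    ``N1, N2, ...`` in preorder (the root is ``N1`` when unlabelled).
    Every non-root node identifies the branch leading to it, so branch
    labels coincide with child-node labels.
    """

    def __init__(self, tree: dendropy.Tree):
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise ValueError(
                "tree root must be bifurcating (got %d children); "
                "supply a rooted Newick tree" % len(root.child_nodes())
            )
        self._tree = tree
        self._label_nodes()
        self._parent: Dict[str, Optional[str]] = {}
        self._children: Dict[str, List[str]] = {}
        self._lengths: Dict[str, Optional[float]] = {}
        for node in tree.preorder_node_iter():
            lab = _label(node)
            self._children[lab] = [_label(c) for c in node.child_nodes()]
            self._parent[lab] = _label(node.parent_node) if node.parent_node else None
            self._lengths[lab] = node.edge.length
        self.root: str = _label(root)

    def _label_nodes(self) -> None:
        counter = 1
        seen = set()
        for node in self._tree.preorder_node_iter():
            lab = _label(node)
            if lab is None:
                while "N%d" % counter in seen:
                    counter += 1
                lab = "N%d" % counter
                counter += 1
                if node.taxon is None:
                    node.label = lab
            if lab in seen:
                raise ValueError("duplicate node label in tree: %r" % lab)
            seen.add(lab)

    # -- construction ------------------------------------------------
    @classmethod
    def from_newick(cls, source: str, *, is_path: bool = True) -> "SpeciesTree":
        kwargs = {"path": source} if is_path else {"data": source}
        tree = dendropy.Tree.get(
            schema="newick", preserve_underscores=True, **kwargs
        )
        return cls(tree)

    # -- queries -----------------------------------------------------
    @property
    def leaves(self) -> List[str]:
        return [lab for lab, ch in self._children.items() if not ch]

    @property
    def nodes(self) -> List[str]:
        return list(self._children)

    @property
    def branches(self) -> List[str]:
        """Branch labels: every node except the root names its stem branch."""
        return [lab for lab in self._children if lab != self.root]

    def children(self, label: str) -> List[str]:
        return self._children[label]

    def parent(self, label: str) -> Optional[str]:
        return self._parent[label]

    def branch_length(self, label: str) -> Optional[float]:
        return self._lengths[label]

    def is_leaf(self, label: str) -> bool:
        return not self._children[label]

    def postorder(self) -> Iterator[str]:
        for node in self._tree.postorder_node_iter():
            yield _label(node)

    def preorder(self) -> Iterator[str]:
        for node in self._tree.preorder_node_iter():
            yield _label(node)

    def validate_leaves(self, species: List[str]) -> None:
        """Check that *species* and the leaf set coincide; list offenders."""
        leaves = set(self.leaves)
        wanted = set(species)
        missing = sorted(leaves - wanted)
        extra = sorted(wanted - leaves)
        if missing or extra:
            raise ValueError(
                "species/leaf mismatch: leaves without counts %s; "
                "counts without leaves %s" % (missing or "-", extra or "-")
            )

    def newick(self) -> str:
        return self._tree.as_string(schema="newick", suppress_rooting=True).strip()

    def __repr__(self) -> str:  # pragma: no cover
        return "SpeciesTree(%d leaves, %d nodes)" % (len(self.leaves), len(self.nodes))


def _label(node: Optional[dendropy.Node]) -> Optional[str]:
    if node is None:
        return None
    if node.taxon is not None and node.taxon.label is not None:
        return node.taxon.label
    return node.label
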