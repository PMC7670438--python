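"""Calibrated (dated) rooted species trees.

Every node carries an absolute age in million years ago (MYA); tips are at
age 0 and every parent is strictly older than its children, so the tree is
ultrametric.  The branch above a node spans the half-open time interval
``(child_age, parent_age)``.  Ages either come from ``[&age=X]`` Newick
comments or, for plain ultrametric Newick, are derived from branch lengths.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, field

import dendropy

_AGE_RE = re.compile(r"&?age\s*=\s*([0-9.eE+-]+)")

_TOL = 1e-6


@dataclass
class TreeNode:
    label: str
    age: float
    parent: "TreeNode | None" = None
    children: list["TreeNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self):
        yield self
        for c in self.children:
            yield from c.preorder()

    def leaves(self) -> list["TreeNode"]:
        return [n for n in self.preorder() if n.is_leaf]


class CalibratedTree:
    """Rooted tree with node ages in MYA; tips at age 0; unique labels."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        for node in root.preorder():
            if node.label:
                if node.label in self._index:
                    raise ValueError(f"duplicate node label {node.label!r}")
                self._index[node.label] = node
        self.validate()

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, source: str) -> "CalibratedTree":
        """Parse Newick from a string or file path.

        Ages are taken from ``[&age=X]`` node comments where present;
        otherwise they are derived from branch lengths assuming an
        ultrametric tree (tips at 0).
        """
        text = source
        if "\n" not in source and not source.strip().endswith(";"):
            with open(source) as fh:
                text = fh.read()
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=False,
            preserve_underscores=True,
            extract_comment_metadata=True,
        )
        # depth of each dendropy node from root
        any_age_comment = False
        ages: dict[int, float] = {}
        depths: dict[int, float] = {}
        maxdepth = 0.0
        anon = 0
        for nd in dtree.preorder_node_iter():
            d = 0.0 if nd.parent_node is None else depths[id(nd.parent_node)] + (
                nd.edge.length or 0.0
            )
            depths[id(nd)] = d
            maxdepth = max(maxdepth, d)
            age = nd.annotations.get_value("age")
            if age is None:
                for comment in nd.comments:
                    m = _AGE_RE.search(comment)
                    if m:
                        age = m.group(1)
                        break
            if age is not None:
                ages[id(nd)] = float(age)
                any_age_comment = True

        def build(nd: dendropy.Node) -> TreeNode:
            nonlocal anon
            label = None
            if nd.taxon is not None:
                label = nd.taxon.label
            elif nd.label:
                label = nd.label
            if not label:
                anon += 1
                label = f"_node{anon}"
            if id(nd) in ages:
                age = ages[id(nd)]
            elif any_age_comment and nd.is_leaf():
                age = 0.0
            elif any_age_comment:
                raise ValueError(
                    f"internal node {label!r} lacks the required [&age=] annotation"
                )
            else:
                age = maxdepth - depths[id(nd)]
            node = TreeNode(label=label, age=age)
            for child in nd.child_nodes():
                node.add_child(build(child))
            return node

        return cls(build(dtree.seed_node))

    # -- validation -------------------------------------------------------

    def validate(self) -> None:
        for node in self.root.preorder():
            if node.is_leaf and abs(node.age) > _TOL:
                raise ValueError(f"tip {node.label!r} has nonzero age {node.age}")
            for child in node.children:
                if node.age <= child.age:
                    raise ValueError(
                        f"node {node.label!r} (age {node.age}) not older than child "
                        f"{child.label!r} (age {child.age})"
                    )

    # -- queries ----------------------------------------------------------

    @property
    def root_age(self) -> float:
        return self.root.age

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"no node labelled {label!r}") from None

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.root.leaves()]

    def mrca(self, labels: list[str]) -> TreeNode:
        """Most recent common ancestor of the named tips (or nodes)."""
        if not labels:
            raise ValueError("mrca of empty label set")
        nodes = [self.node(l) for l in labels]

        def ancestors(n: TreeNode) -> list[TreeNode]:
            path = []
            while n is not None:
                path.append(n)
                n = n.parent
            return path

        common = set(id(a) for a in ancestors(nodes[0]))
        for n in nodes[1:]:
            common &= set(id(a) for a in ancestors(n))
        # deepest (youngest) common ancestor on first node's path
        for a in ancestors(nodes[0]):
            if id(a) in common:
                return a
        raise RuntimeError("disconnected tree")

    def tip_set(self, node: TreeNode) -> frozenset[str]:
        return frozenset(n.label for n in node.leaves())

    def branch_interval(self, label: str) -> tuple[float, float]:
        """(child_age, parent_age) of the branch above the named node."""
        node = self.node(label)
        if node.parent is None:
            raise ValueError(f"node {label!r} is the root; it has no branch above it")
        return (node.age, node.parent.age)

    # -- output -----------------------------------------------------------

    def to_newick(self, *, ages_as_comments: bool = True) -> str:
        def fmt(node: TreeNode) -> str:
            comment = f"[&age={node.age:g}]" if ages_as_comments else ""
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(fmt(c) for c in node.children)
                label = "" if node.label.startswith("_node") else node.label
                body = f"({inner}){label}"
            length = "" if node.parent is None else f":{node.parent.age - node.age:g}"
            return f"{body}{comment}{length}"

        return fmt(self.root) + ";"

    def write(self, path: str) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")
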