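"""Minimal rooted-tree structure shared by the simulator and the phylogeny
stage: newick serialization, leaf/split enumeration.  Heavier tree surgery
(rerooting, Robinson-Foulds) is delegated to dendropy where needed."""

from __future__ import annotations


class Node:
    __slots__ = ("name", "children", "length", "support")

    def __init__(
        self,
        name: str = "",
        children: list["Node"] | None = None,
        length: float = 0.0,
        support: float | None = None,
    ):
        self.name = name
        self.children: list[Node] = children or []
        self.length = length
        self.support = support

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def walk(self):
        """Preorder traversal."""
        yield self
        for c in self.children:
            yield from c.walk()

    def leaves(self) -> list[str]:
        return [n.name for n in self.walk() if n.is_leaf]

    def find(self, name: str) -> "Node | None":
        for n in self.walk():
            if n.name == name:
                return n
        return None

    def to_newick(self, lengths: bool = True, supports: bool = False) -> str:
        return self._newick(lengths, supports) + ";"

    def _newick(self, lengths: bool, supports: bool) -> str:
        if self.is_leaf:
            s = self.name
        else:
            inner = ",".join(c._newick(lengths, supports) for c in self.children)
            if supports and self.support is not None:
                label = f"{self.support:.4g}"
            else:
                label = self.name
            s = f"({inner}){label}"
        if lengths:
            s += f":{self.length:.10g}"
        return s


def splits(root: Node) -> set[frozenset[str]]:
    """Non-trivial bipartitions of the unrooted topology, each encoded as
    the side not containing the lexicographically smallest leaf."""
    all_leaves = frozenset(root.leaves())
    anchor = min(all_leaves)
    out: set[frozenset[str]] = set()
    for node in root.walk():
        if node is root or node.is_leaf:
            continue
        side = frozenset(node.leaves())
        if anchor in side:
            side = all_leaves - side
        if 1 < len(side) < len(all_leaves) - 1:
            out.add(side)
    return out
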