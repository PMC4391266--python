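"""Composite multi-method bootstrap support annotation.

Trees in this pipeline are evaluated by several reconstruction methods
at once; the published figures summarise agreement with a dot code per
internal edge.  With ``m`` methods and ``c`` of them giving >= 95%
bootstrap support:

* ``black``  — c = m (every method strongly supports the edge);
* ``white``  — ceil(2m/3) <= c < m (a qualified majority);
* ``hollow`` — otherwise, if at least one method reaches 75% (the
  values >= 75 are printed, in fixed method order);
* ``none``   — no method reaches 75%.

The white band generalises the legends of the three figure conventions:
m=3 -> exactly 2 methods, m=4 -> 3, m=6 -> 4 or 5.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import ceil

from .tree import Tree

STRONG = 95.0
PRINTABLE = 75.0


@dataclass
class EdgeSupport:
    """Per-method percentages and the composite dot for one internal edge."""

    values: dict[str, float]
    category: str  # black | white | hollow | none
    printable: list[float] = field(default_factory=list)


@dataclass
class SupportedTree:
    """A reference topology with per-edge multi-method support annotation."""

    tree: Tree
    method_order: list[str]
    edges: dict[frozenset, EdgeSupport]

    def newick_with(self, method: str) -> str:
        """Newick with one method's support as internal-node labels."""
        t = self.tree.copy()
        for node, bip in t.edge_bipartitions():
            if bip in self.edges:
                node.label = f"{self.edges[bip].values[method]:g}"
        return t.to_newick()

    def newick_with_dots(self) -> str:
        """Newick with composite dot codes as internal-node labels.

        Labels are B/W for black/white dots and, for hollow circles,
        the printed values (>= 75) joined by '/', mirroring the figure
        convention of listing supports in fixed method order.
        """
        t = self.tree.copy()
        code = {"black": "B", "white": "W"}
        for node, bip in t.edge_bipartitions():
            if bip not in self.edges:
                continue
            e = self.edges[bip]
            if e.category in code:
                node.label = code[e.category]
            elif e.category == "hollow":
                node.label = "/".join(f"{v:g}" for v in e.printable)
            else:
                node.label = None
        return t.to_newick()

    def dot_rows(self) -> list[list[object]]:
        """TSV rows: bipartition, per-method percents, category, printed values."""
        rows: list[list[object]] = []
        for bip in sorted(self.edges, key=lambda b: (len(b), sorted(b))):
            e = self.edges[bip]
            rows.append(
                ["|".join(sorted(bip))]
                + [f"{e.values[m]:.1f}" for m in self.method_order]
                + [e.category, ",".join(f"{v:g}" for v in e.printable)]
            )
        return rows


def dot_category(values: list[float], m: int | None = None) -> tuple[str, list[float]]:
    """Composite dot for one edge given per-method support percentages."""
    if m is None:
        m = len(values)
    if len(values) != m:
        raise ValueError(f"expected {m} method values, got {len(values)}")
    for v in values:
        if not (0.0 <= v <= 100.0):
            raise ValueError(f"support percentage {v} outside [0, 100]")
    c = sum(v >= STRONG for v in values)
    if c == m:
        return "black", []
    if ceil(2 * m / 3) <= c < m:
        return "white", []
    printable = [v for v in values if v >= PRINTABLE]
    if printable:
        return "hollow", printable
    return "none", []


def annotate_support(
    reference: Tree,
    supports: dict[str, dict[frozenset, float]],
    m: int | None = None,
) -> SupportedTree:
    """Annotate every internal edge of ``reference`` with the dot code.

    ``supports`` maps a method label to a complete per-bipartition
    percentage table for the reference tree's internal edges (use
    :func:`guildphylo.trees.bootstrap.supports_for_tree` to fill in 0
    for never-sampled edges).  A method missing an edge is an error.
    """
    method_order = list(supports)
    if m is None:
        m = len(method_order)
    edges: dict[frozenset, EdgeSupport] = {}
    for _node, bip in reference.edge_bipartitions():
        values: dict[str, float] = {}
        for meth in method_order:
            if bip not in supports[meth]:
                raise ValueError(
                    f"method {meth!r} has no support value for edge {sorted(bip)}"
                )
            values[meth] = supports[meth][bip]
        cat, printable = dot_category([values[meth] for meth in method_order], m)
        edges[bip] = EdgeSupport(values=values, category=cat, printable=printable)
    return SupportedTree(tree=reference.copy(), method_order=method_order, edges=edges)
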