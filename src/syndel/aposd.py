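"""Attribute partial-ordered structure diagrams (APOSD).

An APOSD organises a formal context K = (U, M, I) — objects U,
attributes M, binary incidence I — into a layered tree: the attribute
nearest the root covers the most objects (highest universality), and
each object is represented by exactly one root-to-leaf path whose
attributes are exactly the object's intent.  Reading chains of nodes
off the first few layers yields the frequent attribute combinations.

The construction is a recursive greedy partition: among the objects
reaching a node, the not-yet-used attribute with the largest cover
spawns the next child; objects possessing it descend, the rest are
re-partitioned as sibling branches.  Ties between equally covering
attributes are broken by an explicit attribute priority order so the
tree is deterministic.

For the diagnostic pipeline, objects are screened patient records and
attributes are the syndrome elements attaining each record's highest
value order, so root-ward layers name the cohort's most common
elements.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import pandas as pd

from .model import ValidationError
from .evaluate import ValueOrderVector

__all__ = [
    "FormalContext",
    "APOSDNode",
    "APOSDTree",
    "ElementCombination",
    "build_context",
    "generate_aposd",
    "extract_combinations",
    "export_diagram",
    "tree_from_json",
]


@dataclass
class FormalContext:
    """A formal context: objects, attributes, and a binary incidence."""

    objects: tuple[str, ...]
    attributes: tuple[str, ...]
    incidence: frozenset  # of (object, attribute) pairs

    def __post_init__(self) -> None:
        if len(set(self.objects)) != len(self.objects):
            raise ValidationError("duplicate objects in formal context")
        if len(set(self.attributes)) != len(self.attributes):
            raise ValidationError("duplicate attributes in formal context")
        objs, attrs = set(self.objects), set(self.attributes)
        for o, a in self.incidence:
            if o not in objs or a not in attrs:
                raise ValidationError(f"incidence pair ({o!r}, {a!r}) outside U x M")

    def intent(self, obj: str) -> frozenset:
        """Attributes of one object."""
        return frozenset(a for o, a in self.incidence if o == obj)

    def extent(self, attr: str) -> frozenset:
        """Objects possessing one attribute."""
        return frozenset(o for o, a in self.incidence if a == attr)

    def to_frame(self) -> pd.DataFrame:
        """Cross-table as a 0/1 DataFrame (objects x attributes)."""
        df = pd.DataFrame(0, index=list(self.objects), columns=list(self.attributes), dtype=int)
        for o, a in self.incidence:
            df.loc[o, a] = 1
        df.index.name = "object"
        return df

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "FormalContext":
        pairs = frozenset(
            (str(o), str(a)) for o in df.index for a in df.columns if df.loc[o, a]
        )
        return cls(
            objects=tuple(str(o) for o in df.index),
            attributes=tuple(str(a) for a in df.columns),
            incidence=pairs,
        )


@dataclass
class APOSDNode:
    """One attribute node of the diagram.

    ``support`` counts the objects that descend through the node;
    ``objects`` lists those whose intent is exhausted here (the node
    terminates their path).  The virtual root has attribute ``None``
    and layer 0.
    """

    attribute: Optional[str]
    support: int
    layer: int
    children: list = field(default_factory=list)
    objects: list = field(default_factory=list)

    def walk(self):
        yield self
        for child in self.children:
            yield from child.walk()


@dataclass
class APOSDTree:
    """Rooted layered diagram over one formal context."""

    root: APOSDNode
    attributes: tuple[str, ...]

    def n_nodes(self, include_root: bool = False) -> int:
        n = sum(1 for _ in self.root.walk())
        return n if include_root else n - 1

    def leaves(self):
        return [n for n in self.root.walk() if not n.children and n is not self.root]


@dataclass(frozen=True)
class ElementCombination:
    """A frequent attribute chain read off the first layers of the tree."""

    chain: tuple[str, ...]
    support: int

    @property
    def label(self) -> str:
        return "-".join(self.chain)


def _sort_key(label: str):
    # ascending element index for e<N> labels, lexicographic otherwise
    if label.startswith("e") and label[1:].isdigit():
        return (0, int(label[1:]))
    return (1, label)


def build_context(
    cohort_orders: Iterable[tuple[str, "ValueOrderVector | pd.Series"]],
) -> FormalContext:
    """Build the formal context of a diagnosed cohort.

    Objects are record ids; the attributes of a record are the elements
    attaining its highest value order actually present (ties included),
    labelled ``e<index>``.  Records whose orders are all zero carry no
    diagnostic signal and are excluded with a warning.
    """
    objects: list[str] = []
    pairs: set[tuple[str, str]] = set()
    attrs: set[str] = set()
    n_seen = 0
    for record_id, orders in cohort_orders:
        n_seen += 1
        series = orders.orders if isinstance(orders, ValueOrderVector) else orders
        top = int(series.max()) if len(series) else 0
        if top <= 0:
            warnings.warn(f"record {record_id!r} has all-zero orders; excluded", stacklevel=2)
            continue
        objects.append(str(record_id))
        for i in series.index[series == top]:
            label = f"e{int(i)}"
            attrs.add(label)
            pairs.add((str(record_id), label))
    if n_seen == 0:
        raise ValidationError("cannot build a formal context from an empty cohort")
    if not objects:
        raise ValidationError("all records had zero orders; empty formal context")
    return FormalContext(
        objects=tuple(objects),
        attributes=tuple(sorted(attrs, key=_sort_key)),
        incidence=frozenset(pairs),
    )


def generate_aposd(
    context: FormalContext, tie_break: Optional[Sequence[str]] = None
) -> APOSDTree:
    """Generate the layered diagram of a formal context.

    ``tie_break`` is an attribute priority order used when several
    attributes cover equally many objects; it defaults to the context's
    attribute order.
    """
    if not context.objects:
        raise ValidationError("cannot build an APOSD from an empty context")
    order = list(tie_break) if tie_break is not None else list(context.attributes)
    missing = set(context.attributes) - set(order)
    if missing:
        raise ValidationError(f"tie_break omits attributes {sorted(missing)}")
    rank = {a: k for k, a in enumerate(order)}
    intents = {o: context.intent(o) for o in context.objects}

    root = APOSDNode(attribute=None, support=len(context.objects), layer=0)

    def partition(obj_ids: list[str], path: frozenset, node: APOSDNode) -> None:
        pool = []
        for o in obj_ids:
            if intents[o] <= path:
                node.objects.append(o)
            else:
                pool.append(o)
        while pool:
            counts: dict[str, int] = {}
            for o in pool:
                for a in intents[o] - path:
                    counts[a] = counts.get(a, 0) + 1
            best = min(counts, key=lambda a: (-counts[a], rank[a]))
            covered = [o for o in pool if best in intents[o]]
            child = APOSDNode(attribute=best, support=len(covered), layer=node.layer + 1)
            node.children.append(child)
            partition(covered, path | {best}, child)
            pool = [o for o in pool if best not in intents[o]]

    partition(list(context.objects), frozenset(), root)
    return APOSDTree(root=root, attributes=context.attributes)


def extract_combinations(
    tree: APOSDTree, depth: int, min_support: int = 1
) -> list[ElementCombination]:
    """Extract the root-to-layer-``depth`` chains with enough support.

    Returns every path of exactly ``depth`` layers whose terminal node
    covers at least ``min_support`` objects (supports are non-increasing
    along a path, so the whole chain is at least that frequent), in
    tree order.
    """
    if depth < 1:
        raise ValidationError(f"depth must be >= 1, got {depth}")
    out: list[ElementCombination] = []

    def visit(node: APOSDNode, prefix: tuple[str, ...]) -> None:
        for child in node.children:
            chain = prefix + (child.attribute,)
            if child.layer == depth:
                if child.support >= min_support:
                    out.append(ElementCombination(chain=chain, support=child.support))
            else:
                visit(child, chain)

    visit(tree.root, ())
    return out


def _node_to_dict(node: APOSDNode) -> dict:
    return {
        "attribute": node.attribute,
        "support": node.support,
        "layer": node.layer,
        "objects": list(node.objects),
        "children": [_node_to_dict(c) for c in node.children],
    }


def _node_from_dict(d: dict) -> APOSDNode:
    return APOSDNode(
        attribute=d["attribute"],
        support=int(d["support"]),
        layer=int(d["layer"]),
        objects=list(d.get("objects", [])),
        children=[_node_from_dict(c) for c in d.get("children", [])],
    )


def tree_from_json(text: str) -> APOSDTree:
    """Parse a tree previously serialised with ``export_diagram(..., "json")``."""
    payload = json.loads(text)
    root = _node_from_dict(payload["root"])
    return APOSDTree(root=root, attributes=tuple(payload["attributes"]))


def export_diagram(tree: APOSDTree, format: str = "json") -> str:
    """Serialise the tree as deterministic JSON or Graphviz DOT."""
    if format == "json":
        return json.dumps(
            {"attributes": list(tree.attributes), "root": _node_to_dict(tree.root)},
            indent=2,
            sort_keys=True,
        )
    if format == "dot":
        lines = ["digraph aposd {", "  rankdir=TB;", '  node [shape=box];']
        ids: dict[int, str] = {}
        for k, node in enumerate(tree.root.walk()):
            ids[id(node)] = f"n{k}"
            label = node.attribute if node.attribute is not None else "root"
            lines.append(f'  n{k} [label="{label}\\n({node.support})"];')
        for node in tree.root.walk():
            for child in node.children:
                lines.append(f"  {ids[id(node)]} -> {ids[id(child)]};")
        lines.append("}")
        return "\n".join(lines) + "\n"
    raise ValidationError(f"unknown diagram format {format!r}; expected 'json' or 'dot'")
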