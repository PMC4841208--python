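"""GRN data model: nodes, signed links, and the model hierarchy.

Genes are first-class: a gene node is drawn as a wide horizontal bar whose
width depends on its label, while auxiliary node kinds (boxes, bubbles,
intercellular markers, slashes) get a compact square footprint.  Complex
networks are organized as a hierarchy of models in which every child model
may contain only a subset of the network elements present in its parent —
the structural constraint that lets one maintained root network drive many
focused sub-views.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .grid_geometry import GRID_STEP, Rect


class Sign(enum.IntEnum):
    """Regulatory sign of a link.  The integer order (promote < repress <
    neutral) is the tie-break order used by every deterministic sort."""

    PROMOTE = 0
    REPRESS = 1
    NEUTRAL = 2


class NodeKind(enum.Enum):
    GENE = "gene"
    BOX = "box"
    BUBBLE = "bubble"
    INTERCELL = "intercell"
    SLASH = "slash"


#: Footprint constants, in grid units.  Gene bars are 20 tall and at least
#: 80 wide (8 units per label character, snapped up to the grid); other node
#: kinds are 20x20.  Chosen to match the visual proportions of typical GRN
#: drawings; the grid itself is 10 units.
GENE_HEIGHT = 20
GENE_MIN_WIDTH = 80
GENE_WIDTH_PER_CHAR = 8
OTHER_SIZE = 20


def _ceil_to_grid(v: float) -> int:
    return int(math.ceil(v / GRID_STEP)) * GRID_STEP


@dataclass(frozen=True)
class Node:
    id: str
    label: str = ""
    kind: NodeKind = NodeKind.GENE

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("node id must be non-empty")
        if not self.label:
            object.__setattr__(self, "label", self.id)

    @property
    def footprint(self) -> Rect:
        """Footprint rectangle at the origin, corners on grid points."""
        if self.kind is NodeKind.GENE:
            w = max(GENE_MIN_WIDTH,
                    _ceil_to_grid(GENE_WIDTH_PER_CHAR * len(self.label)))
            return Rect(0, 0, w, GENE_HEIGHT)
        return Rect(0, 0, OTHER_SIZE, OTHER_SIZE)


@dataclass(frozen=True)
class Link:
    source: str
    target: str
    sign: Sign = Sign.NEUTRAL

    def sort_key(self) -> tuple:
        return (self.source, self.target, int(self.sign))


class UnknownNodeError(KeyError):
    pass


class SelfLinkError(ValueError):
    pass


class GrnModel:
    """A gene regulatory network: a set of nodes plus signed directed links.

    Self-links are rejected unless ``allow_self_links`` is set; duplicate
    (source, target, sign) triples collapse to one link.
    """

    def __init__(self, name: str = "network", *, allow_self_links: bool = False):
        self.name = name
        self.allow_self_links = allow_self_links
        self.nodes: dict[str, Node] = {}
        self.links: set[Link] = set()

    def add_node(self, node: Node | str, *, kind: NodeKind = NodeKind.GENE,
                 label: str = "") -> Node:
        if isinstance(node, str):
            node = Node(node, label=label, kind=kind)
        existing = self.nodes.get(node.id)
        if existing is not None:
            return existing
        self.nodes[node.id] = node
        return node

    def add_link(self, source: str, target: str,
                 sign: Sign = Sign.NEUTRAL) -> Link:
        for nid in (source, target):
            if nid not in self.nodes:
                raise UnknownNodeError(nid)
        if source == target and not self.allow_self_links:
            raise SelfLinkError(f"self-link on {source!r} not permitted")
        link = Link(source, target, sign)
        self.links.add(link)
        return link

    # -- queries ----------------------------------------------------------
    def sorted_links(self) -> list[Link]:
        return sorted(self.links, key=Link.sort_key)

    def outbound_links(self, node: str) -> list[Link]:
        """All links with ``node`` as source, sorted by (target, sign)."""
        if node not in self.nodes:
            raise UnknownNodeError(node)
        out = [l for l in self.links if l.source == node]
        out.sort(key=lambda l: (l.target, int(l.sign)))
        return out

    def inbound_links(self, node: str) -> list[Link]:
        if node not in self.nodes:
            raise UnknownNodeError(node)
        out = [l for l in self.links if l.target == node]
        out.sort(key=lambda l: (l.source, int(l.sign)))
        return out

    def sources(self) -> list[str]:
        """Node ids with at least one outbound link, in id order."""
        src = {l.source for l in self.links}
        return sorted(src)

    def input_signature(self, node: str) -> tuple[str, ...]:
        """Sorted tuple of distinct source ids feeding ``node``."""
        return tuple(sorted({l.source for l in self.links if l.target == node}))

    def submodel(self, node_subset: Iterable[str],
                 name: Optional[str] = None) -> "GrnModel":
        """Induced sub-network: the given nodes plus every link with both
        endpoints inside the subset."""
        subset = set(node_subset)
        unknown = subset - set(self.nodes)
        if unknown:
            raise UnknownNodeError(sorted(unknown))
        m = GrnModel(name or f"{self.name}:sub",
                     allow_self_links=self.allow_self_links)
        for nid in sorted(subset):
            m.nodes[nid] = self.nodes[nid]
        m.links = {l for l in self.links
                   if l.source in subset and l.target in subset}
        return m

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GrnModel):
            return NotImplemented
        return self.nodes == other.nodes and self.links == other.links

    def __repr__(self) -> str:
        return (f"GrnModel({self.name!r}, {len(self.nodes)} nodes, "
                f"{len(self.links)} links)")


# ---------------------------------------------------------------------------
# Model hierarchy


class HierarchyError(ValueError):
    pass


class SubsetViolationError(HierarchyError):
    def __init__(self, offending: list[str]):
        self.offending = offending
        super().__init__("elements not present in parent model: "
                         + ", ".join(map(str, offending)))


@dataclass
class HierarchyViolation:
    model_id: str
    kind: str  # "node-not-in-parent" | "link-not-in-parent" | "structure"
    detail: str


@dataclass
class _HierarchyEntry:
    model_id: str
    parent_id: Optional[str]
    node_ids: frozenset[str]
    links: frozenset[Link]


class ModelHierarchy:
    """Tree of models, each child restricted to a subset of its parent."""

    def __init__(self, root: GrnModel, root_id: str = "root"):
        self.root_model = root
        self.root_id = root_id
        self.entries: dict[str, _HierarchyEntry] = {
            root_id: _HierarchyEntry(root_id, None,
                                     frozenset(root.nodes),
                                     frozenset(root.links)),
        }
        self._counter = 0

    def add_submodel(self, parent: str, node_subset: Iterable[str],
                     link_subset: Iterable[Link],
                     model_id: Optional[str] = None) -> str:
        """Register a child model.  Improper subsets (child equal to parent)
        and empty link sets are both legal; any element absent from the
        parent raises SubsetViolationError naming every offender."""
        if parent not in self.entries:
            raise HierarchyError(f"unknown parent model {parent!r}")
        pe = self.entries[parent]
        nodes = frozenset(node_subset)
        links = frozenset(link_subset)
        bad = sorted(nodes - pe.node_ids)
        bad += [f"{l.source}->{l.target}" for l in sorted(links - pe.links,
                                                          key=Link.sort_key)]
        # a link whose endpoints are outside the chosen node subset is also
        # a violation: the child model could not resolve it
        bad += [f"{l.source}->{l.target} (endpoint outside subset)"
                for l in sorted(links & pe.links, key=Link.sort_key)
                if l.source not in nodes or l.target not in nodes]
        if bad:
            raise SubsetViolationError(bad)
        if model_id is None:
            self._counter += 1
            model_id = f"model-{self._counter}"
        if model_id in self.entries:
            raise HierarchyError(f"duplicate model id {model_id!r}")
        self.entries[model_id] = _HierarchyEntry(model_id, parent, nodes, links)
        return model_id

    def model(self, model_id: str) -> GrnModel:
        e = self.entries[model_id]
        m = GrnModel(model_id, allow_self_links=self.root_model.allow_self_links)
        for nid in sorted(e.node_ids):
            m.nodes[nid] = self.root_model.nodes[nid]
        m.links = set(e.links)
        return m

    def validate(self) -> list[HierarchyViolation]:
        return validate_hierarchy(self)


def validate_hierarchy(h: ModelHierarchy) -> list[HierarchyViolation]:
    """Audit a hierarchy: single root, acyclic parent pointers, and every
    child's node and link sets contained in its parent's.  Violations are
    returned as data, never raised."""
    out: list[HierarchyViolation] = []
    roots = [e for e in h.entries.values() if e.parent_id is None]
    if len(roots) != 1:
        out.append(HierarchyViolation(
            "<hierarchy>", "structure",
            f"expected exactly one root, found {len(roots)}"))
    for mid in sorted(h.entries):
        e = h.entries[mid]
        # cycle / dangling-parent walk
        seen = {mid}
        cur = e.parent_id
        while cur is not None:
            if cur not in h.entries:
                out.append(HierarchyViolation(mid, "structure",
                                              f"unknown parent {cur!r}"))
                break
            if cur in seen:
                out.append(HierarchyViolation(mid, "structure",
                                              "cycle in parent chain"))
                break
            seen.add(cur)
            cur = h.entries[cur].parent_id
        if e.parent_id is None or e.parent_id not in h.entries:
            continue
        pe = h.entries[e.parent_id]
        for nid in sorted(e.node_ids - pe.node_ids):
            out.append(HierarchyViolation(mid, "node-not-in-parent", nid))
        for l in sorted(e.links - pe.links, key=Link.sort_key):
            out.append(HierarchyViolation(mid, "link-not-in-parent",
                                          f"{l.source}->{l.target}"))
    return out
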