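"""File I/O: SIF networks, overlay documents, and layout documents.

SIF (Cytoscape Simple Interaction Format) is the tab-delimited
``source relation target [target ...]`` format; a line with a single token
declares an isolated node.  Relation tokens map onto link signs through a
configurable dialect (default: ``positive`` -> promote, ``negative`` ->
repress, anything else -> neutral).

Overlay documents are YAML (or JSON, a YAML subset) files describing
network modules and module links; layout documents are JSON files holding a
model together with node placements and link-tree geometry.  Both formats
are defined by this package (documented in docs/schema.md).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from typing import Mapping, Optional

import yaml

from .core_model import GrnModel, Link, Node, NodeKind, Sign
from .grid_geometry import GridPoint, LinkTree, Rect

log = logging.getLogger(__name__)

#: Default relation-token dialect.  Tokens not listed map to neutral.
DEFAULT_RELATION_MAP: dict[str, Sign] = {
    "positive": Sign.PROMOTE,
    "negative": Sign.REPRESS,
}

_SIGN_TO_TOKEN = {
    Sign.PROMOTE: "positive",
    Sign.REPRESS: "negative",
    Sign.NEUTRAL: "neutral",
}


class SifFormatError(ValueError):
    def __init__(self, lineno: int, message: str):
        self.lineno = lineno
        super().__init__(f"line {lineno}: {message}")


@dataclass(frozen=True)
class SifRecord:
    source: str
    relation: Optional[str]
    targets: tuple[str, ...]


def _split_sif_line(line: str) -> list[str]:
    # tab-delimited if any tab present, else any whitespace
    return line.split("\t") if "\t" in line else line.split()


def parse_sif_records(text: str) -> list[tuple[int, SifRecord]]:
    records = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        tokens = [t.strip() for t in _split_sif_line(line) if t.strip()]
        if not tokens:
            continue
        if len(tokens) == 1:
            records.append((lineno, SifRecord(tokens[0], None, ())))
        elif len(tokens) == 2:
            raise SifFormatError(
                lineno, "relation given but no target "
                        "(expected 'source relation target [target ...]')")
        else:
            records.append((lineno,
                            SifRecord(tokens[0], tokens[1], tuple(tokens[2:]))))
    return records


def read_sif(text: str, *, name: str = "network",
             relation_map: Optional[Mapping[str, Sign]] = None,
             strict_relations: bool = False) -> GrnModel:
    """Parse SIF text into a model.

    One node per distinct identifier, one link per (source, target) pair on
    a relation line; duplicate lines collapse with a warning.  With
    ``strict_relations`` a relation token outside ``relation_map`` is an
    error listing the accepted tokens instead of mapping to neutral.
    """
    rmap = dict(DEFAULT_RELATION_MAP if relation_map is None else relation_map)
    model = GrnModel(name)
    seen: set[Link] = set()
    for lineno, rec in parse_sif_records(text):
        model.add_node(rec.source)
        if rec.relation is None:
            continue
        if rec.relation in rmap:
            sign = rmap[rec.relation]
        elif strict_relations:
            raise SifFormatError(
                lineno, f"unknown relation {rec.relation!r}; accepted: "
                        + ", ".join(sorted(rmap)))
        else:
            sign = Sign.NEUTRAL
        for tgt in rec.targets:
            model.add_node(tgt)
            link = Link(rec.source, tgt, sign)
            if link in seen:
                log.warning("duplicate SIF line %d: %s %s %s — deduplicated",
                            lineno, rec.source, rec.relation, tgt)
                continue
            seen.add(link)
            model.add_link(rec.source, tgt, sign)
    return model


def write_sif(model: GrnModel) -> str:
    """Serialize a model to SIF.  ``read_sif(write_sif(m))`` reproduces
    ``m``'s node and link sets exactly."""
    lines = []
    linked: set[str] = set()
    for l in model.sorted_links():
        lines.append(f"{l.source}\t{_SIGN_TO_TOKEN[l.sign]}\t{l.target}")
        linked.add(l.source)
        linked.add(l.target)
    for nid in sorted(set(model.nodes) - linked):
        lines.append(nid)
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# Overlay documents

OVERLAY_SCHEMA_VERSION = 1


class OverlayFormatError(ValueError):
    pass


def read_overlay(text: str):
    """Parse a YAML/JSON overlay document into a NetworkOverlay.

    Membership against a concrete model is checked at use time by
    ``overlay_layout.validate_overlay``, not here.
    """
    from .overlay_layout import ModuleLink, NetworkModule, NetworkOverlay

    try:
        doc = yaml.safe_load(text)
    except yaml.YAMLError as e:
        raise OverlayFormatError(f"unparseable overlay document: {e}") from e
    if not isinstance(doc, dict):
        raise OverlayFormatError("overlay document must be a mapping")
    if doc.get("schema_version", OVERLAY_SCHEMA_VERSION) != OVERLAY_SCHEMA_VERSION:
        raise OverlayFormatError(
            f"unsupported overlay schema_version {doc.get('schema_version')!r}")
    modules = []
    names = set()
    for i, m in enumerate(doc.get("modules") or []):
        if not isinstance(m, dict) or "name" not in m:
            raise OverlayFormatError(f"module #{i}: missing name")
        name = str(m["name"])
        if name in names:
            raise OverlayFormatError(f"duplicate module name {name!r}")
        names.add(name)
        members = m.get("members")
        if not members:
            raise OverlayFormatError(f"module {name!r}: empty member list")
        box = m.get("box")
        if box is not None:
            if (not isinstance(box, (list, tuple)) or len(box) != 4):
                raise OverlayFormatError(f"module {name!r}: box must be "
                                         "[x0, y0, x1, y1]")
            box = Rect(*(int(v) for v in box))
        modules.append(NetworkModule(name=name,
                                     members=frozenset(map(str, members)),
                                     box=box))
    links = []
    for i, l in enumerate(doc.get("module_links") or []):
        if not isinstance(l, dict) or "source" not in l or "target" not in l:
            raise OverlayFormatError(f"module link #{i}: needs source and target")
        src, tgt = str(l["source"]), str(l["target"])
        for end in (src, tgt):
            if end not in names:
                raise OverlayFormatError(
                    f"module link #{i}: unknown module {end!r}")
        wps = tuple(GridPoint(int(p[0]), int(p[1]))
                    for p in (l.get("waypoints") or []))
        links.append(ModuleLink(source=src, target=tgt, waypoints=wps))
    intensity = float(doc.get("intensity", 1.0))
    if not 0.0 <= intensity <= 1.0:
        raise OverlayFormatError("intensity must be in [0, 1]")
    return NetworkOverlay(name=str(doc.get("name", "overlay")),
                          modules=modules, module_links=links,
                          intensity=intensity)


def write_overlay(overlay) -> str:
    doc = {
        "schema_version": OVERLAY_SCHEMA_VERSION,
        "name": overlay.name,
        "intensity": overlay.intensity,
        "modules": [
            {
                "name": m.name,
                "members": sorted(m.members),
                **({"box": [m.box.x0, m.box.y0, m.box.x1, m.box.y1]}
                   if m.box is not None else {}),
            }
            for m in overlay.modules
        ],
        "module_links": [
            {
                "source": l.source,
                "target": l.target,
                "sign": "positive",
                "waypoints": [[p.x, p.y] for p in l.waypoints],
            }
            for l in overlay.module_links
        ],
    }
    return yaml.safe_dump(doc, sort_keys=True)


# ---------------------------------------------------------------------------
# Layout documents

LAYOUT_SCHEMA_VERSION = 1


class LayoutFormatError(ValueError):
    pass


def _tree_to_doc(tree: LinkTree) -> dict:
    return {
        "source": tree.source,
        "root": tree.root_id,
        "points": {str(nid): [p.x, p.y] for nid, p in sorted(tree.points.items())},
        "parent": {str(c): p for c, p in sorted(tree.parent.items())},
        "leaves": [[t, _SIGN_TO_TOKEN[sign], nid]
                   for (t, sign), nid in sorted(tree.leaf_ids.items(),
                                                key=lambda kv: (kv[0][0],
                                                                int(kv[0][1])))],
    }


def _tree_from_doc(doc: dict) -> LinkTree:
    tree = LinkTree.__new__(LinkTree)
    tree.source = doc["source"]
    tree.points = {int(k): GridPoint(int(v[0]), int(v[1]))
                   for k, v in doc["points"].items()}
    tree.parent = {int(k): int(v) for k, v in doc["parent"].items()}
    tree.root_id = int(doc["root"])
    token_to_sign = {v: k for k, v in _SIGN_TO_TOKEN.items()}
    tree.leaf_ids = {(t, token_to_sign[token]): int(nid)
                     for t, token, nid in doc["leaves"]}
    tree._next_id = max(tree.points, default=0) + 1
    tree.validate_structure()
    return tree


def layout_to_json(model: GrnModel, layout) -> str:
    """Serialize (model, layout) to a deterministic JSON document."""
    doc = {
        "schema_version": LAYOUT_SCHEMA_VERSION,
        "model": {
            "name": model.name,
            "nodes": [{"id": n.id, "label": n.label, "kind": n.kind.value}
                      for n in sorted(model.nodes.values(), key=lambda n: n.id)],
            "links": [[l.source, _SIGN_TO_TOKEN[l.sign], l.target]
                      for l in model.sorted_links()],
        },
        "bounds": [layout.bounds.x0, layout.bounds.y0,
                   layout.bounds.x1, layout.bounds.y1],
        "placements": {nid: [r.x0, r.y0, r.x1, r.y1]
                       for nid, r in sorted(layout.placements.items())},
        "trees": {src: _tree_to_doc(t) for src, t in sorted(layout.trees.items())},
    }
    return json.dumps(doc, sort_keys=True, indent=1)


def layout_from_json(text: str):
    from .stacked_layout import Layout

    try:
        doc = json.loads(text)
    except json.JSONDecodeError as e:
        raise LayoutFormatError(f"unparseable layout document: {e}") from e
    if doc.get("schema_version") != LAYOUT_SCHEMA_VERSION:
        raise LayoutFormatError(
            f"unsupported layout schema_version {doc.get('schema_version')!r}")
    token_to_sign = {v: k for k, v in _SIGN_TO_TOKEN.items()}
    model = GrnModel(doc["model"].get("name", "network"))
    for n in doc["model"]["nodes"]:
        model.add_node(Node(n["id"], label=n.get("label", ""),
                            kind=NodeKind(n.get("kind", "gene"))))
    for src, token, tgt in doc["model"]["links"]:
        model.add_link(src, tgt, token_to_sign[token])
    placements = {nid: Rect(*map(int, r))
                  for nid, r in doc["placements"].items()}
    trees = {src: _tree_from_doc(t) for src, t in doc["trees"].items()}
    bounds = Rect(*map(int, doc["bounds"]))
    return model, Layout(placements=placements, trees=trees, bounds=bounds)
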