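"""Mechanistic drug-to-disease path records.

A mechanistic path is a directed chain that starts at a drug node, traverses
intermediate biological entities (genes, proteins, metabolites, processes),
and ends at a disease node.  Each node carries a compact prefixed identifier
(CURIE), a Biolink-style category label, and a display name; each edge carries
a controlled predicate.  Records arrive as YAML or JSON documents: a sequence
of records, each with a graph id, a ``nodes`` list (``id``/``label``/``name``)
and a ``links`` list (``source``/``target``/``key``).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import yaml

__all__ = [
    "PathNode",
    "PathLink",
    "MechPath",
    "PathRecordError",
    "parse_drugmechdb",
    "dump_paths",
]


class PathRecordError(ValueError):
    """A malformed path record; carries the offending path id."""

    def __init__(self, path_id: str, message: str):
        self.path_id = path_id
        super().__init__(f"path {path_id!r}: {message}")


@dataclass(frozen=True)
class PathNode:
    """One entity on a mechanistic path."""

    curie: str
    label: str
    name: str

    def __post_init__(self) -> None:
        if not self.curie or self.curie.count(":") != 1:
            raise ValueError(f"curie must contain exactly one ':': {self.curie!r}")
        if not self.name:
            raise ValueError("node name must be non-empty")

    @property
    def prefix(self) -> str:
        return self.curie.split(":", 1)[0]


@dataclass(frozen=True)
class PathLink:
    """One directed, predicated edge between two path nodes."""

    source_curie: str
    target_curie: str
    predicate: str

    def __post_init__(self) -> None:
        if not self.predicate:
            raise ValueError("predicate must be non-empty")


@dataclass
class MechPath:
    """A drug -> ... -> disease mechanism-of-action path."""

    path_id: str
    nodes: list[PathNode]
    links: list[PathLink]
    drug: PathNode = field(init=False)
    disease: PathNode = field(init=False)

    def __post_init__(self) -> None:
        if not self.nodes:
            raise PathRecordError(self.path_id, "no nodes")
        curies = [n.curie for n in self.nodes]
        if len(set(curies)) != len(curies):
            raise PathRecordError(self.path_id, "duplicate node curies")
        known = set(curies)
        for link in self.links:
            if link.source_curie not in known or link.target_curie not in known:
                raise PathRecordError(
                    self.path_id,
                    f"link {link.source_curie}->{link.target_curie} references an absent node",
                )
        self.drug = self.nodes[0]
        self.disease = self.nodes[-1]
        if not self._connected(self.drug.curie, self.disease.curie):
            raise PathRecordError(self.path_id, "drug is not connected to disease")

    def _connected(self, start: str, goal: str) -> bool:
        adj: dict[str, list[str]] = {}
        for link in self.links:
            adj.setdefault(link.source_curie, []).append(link.target_curie)
        seen = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            if cur == goal:
                return True
            for nxt in adj.get(cur, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return start == goal

    @property
    def internal_nodes(self) -> list[PathNode]:
        """Nodes other than the drug and disease endpoints."""
        ends = {self.drug.curie, self.disease.curie}
        return [n for n in self.nodes if n.curie not in ends]

    def node(self, curie: str) -> PathNode:
        for n in self.nodes:
            if n.curie == curie:
                return n
        raise KeyError(curie)


def _record_id(record: dict) -> str:
    graph = record.get("graph")
    if isinstance(graph, dict) and graph.get("_id"):
        return str(graph["_id"])
    if record.get("id"):
        return str(record["id"])
    return "<missing id>"


def _parse_record(record: dict) -> MechPath:
    path_id = _record_id(record)
    if path_id == "<missing id>":
        raise PathRecordError(path_id, "record has no graph id")
    raw_nodes = record.get("nodes")
    raw_links = record.get("links")
    if not raw_nodes or raw_links is None:
        raise PathRecordError(path_id, "record missing nodes or links")
    try:
        nodes = [
            PathNode(curie=str(n["id"]), label=str(n.get("label", "")), name=str(n.get("name", "")))
            for n in raw_nodes
        ]
        links = [
            PathLink(
                source_curie=str(e["source"]),
                target_curie=str(e["target"]),
                predicate=str(e.get("key", e.get("predicate", ""))),
            )
            for e in raw_links
        ]
    except (KeyError, TypeError, ValueError) as exc:
        raise PathRecordError(path_id, str(exc)) from exc
    return MechPath(path_id=path_id, nodes=nodes, links=links)


def parse_drugmechdb(document: str, *, on_error: str = "fail") -> list[MechPath]:
    """Parse a YAML/JSON document of mechanistic path records.

    Parameters
    ----------
    document:
        Text of a YAML (or JSON, a YAML subset) sequence of path records.
    on_error:
        ``"fail"`` (default) raises :class:`PathRecordError` on the first
        malformed record; ``"skip"`` drops malformed records.

    Returns one :class:`MechPath` per well-formed record, in document order,
    with node labels and curies preserved verbatim.
    """
    if on_error not in ("fail", "skip"):
        raise ValueError("on_error must be 'fail' or 'skip'")
    data = yaml.safe_load(document)
    if data is None:
        return []
    if not isinstance(data, Sequence) or isinstance(data, (str, bytes)):
        raise ValueError("document must deserialize to a sequence of records")
    paths: list[MechPath] = []
    for record in data:
        try:
            paths.append(_parse_record(record))
        except PathRecordError:
            if on_error == "fail":
                raise
    return paths


def dump_paths(paths: Iterable[MechPath]) -> str:
    """Serialize paths back to the YAML record format (inverse of parse)."""
    records = []
    for p in paths:
        records.append(
            {
                "graph": {"_id": p.path_id},
                "nodes": [{"id": n.curie, "label": n.label, "name": n.name} for n in p.nodes],
                "links": [
                    {"source": e.source_curie, "target": e.target_curie, "key": e.predicate}
                    for e in p.links
                ],
            }
        )
    return yaml.safe_dump(records, sort_keys=True, allow_unicode=True)
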