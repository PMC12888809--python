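"""One-hop TRAPI queries, response parsing, and a content-addressed cache.

TRAPI (Translator Reasoner API) is the standard JSON request/response format
for querying federated biomedical knowledge graphs.  A request carries a
*query graph* — here always one pinned node (a concrete CURIE) connected to
one free node constrained only by a Biolink category — and the response
carries a *knowledge graph* of concrete nodes and edges with provenance.

Transports are pluggable: an HTTP POST transport for a live endpoint, or an
offline mock.  Every request is resolved through a file cache keyed by the
SHA-256 of its canonical serialization, so a warmed cache replays a whole
benchmark run byte-identically with no network.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Protocol, runtime_checkable

from ._jsonl import dumps_canonical
from .benchmark import BenchmarkItem

import json

logger = logging.getLogger(__name__)

__all__ = [
    "TrapiQuerySpec",
    "RetrievedGraph",
    "KgEdge",
    "Transport",
    "HttpTransport",
    "ResponseCache",
    "RetrievalConfig",
    "build_trapi_query",
    "canonical_request_bytes",
    "cache_key",
    "parse_trapi_response",
    "specs_for_item",
    "retrieve_for_item",
    "CacheMissError",
]


@dataclass(frozen=True)
class TrapiQuerySpec:
    """One entity -> category retrieval pattern."""

    input_curie: str
    input_category: str
    output_category: str
    predicate: str | None = None

    def __post_init__(self) -> None:
        if not self.input_curie:
            raise ValueError("input_curie must be non-empty")
        for cat in (self.input_category, self.output_category):
            if cat and not cat.startswith("biolink:"):
                raise ValueError(f"category must carry the 'biolink:' prefix: {cat!r}")


@dataclass(frozen=True)
class KgEdge:
    subject: str
    predicate: str
    object: str
    primary_source: str = ""


@dataclass
class RetrievedGraph:
    """A parsed TRAPI knowledge graph: node map plus deduplicated edge list."""

    nodes: dict[str, tuple[str, tuple[str, ...]]] = field(default_factory=dict)
    edges: list[KgEdge] = field(default_factory=list)
    dropped_edges: int = 0

    def node_name(self, curie: str) -> str:
        name, _ = self.nodes.get(curie, ("", ()))
        return name or curie

    def union(self, other: "RetrievedGraph") -> "RetrievedGraph":
        merged = RetrievedGraph(nodes=dict(self.nodes), edges=list(self.edges))
        for curie, info in other.nodes.items():
            merged.nodes.setdefault(curie, info)
        seen = set(merged.edges)
        for edge in other.edges:
            if edge not in seen:
                seen.add(edge)
                merged.edges.append(edge)
        merged.dropped_edges = self.dropped_edges + other.dropped_edges
        return merged


def build_trapi_query(spec: TrapiQuerySpec) -> dict:
    """Build a one-hop TRAPI request document for a query spec.

    The query graph pins ``n0`` to the input CURIE/category, leaves ``n1``
    free under the output category, and joins them with edge ``e0``.  A
    predicate constraint is included only when the spec carries one.
    """
    if not spec.output_category:
        raise ValueError("output_category must be non-empty")
    edge: dict = {"subject": "n0", "object": "n1"}
    if spec.predicate:
        edge["predicates"] = [spec.predicate]
    return {
        "message": {
            "query_graph": {
                "nodes": {
                    "n0": {
                        "ids": [spec.input_curie],
                        "categories": [spec.input_category],
                    },
                    "n1": {"categories": [spec.output_category]},
                },
                "edges": {"e0": edge},
            }
        }
    }


def canonical_request_bytes(request: dict) -> bytes:
    """Canonical UTF-8 bytes of a request (sorted keys, no whitespace)."""
    return dumps_canonical(request).encode("utf-8")


def cache_key(request: dict) -> str:
    """SHA-256 hex digest of the canonical request bytes."""
    return hashlib.sha256(canonical_request_bytes(request)).hexdigest()


def _primary_source(edge: dict) -> str:
    for src in edge.get("sources", ()) or ():
        if src.get("resource_role") == "primary_knowledge_source":
            return str(src.get("resource_id", ""))
    for attr in edge.get("attributes", ()) or ():
        if attr.get("attribute_type_id") == "biolink:primary_knowledge_source":
            return str(attr.get("value", ""))
    return ""


def parse_trapi_response(document: dict) -> RetrievedGraph:
    """Extract the knowledge graph from a TRAPI response document.

    An absent ``knowledge_graph`` yields an empty graph.  Edges whose
    endpoints are missing from the node map are dropped (their count is kept
    on the graph and logged); exact duplicate edges are collapsed.
    """
    message = document.get("message", {}) or {}
    kg = message.get("knowledge_graph") or {}
    graph = RetrievedGraph()
    for curie, node in (kg.get("nodes") or {}).items():
        name = str(node.get("name") or "")
        categories = tuple(node.get("categories") or ())
        graph.nodes[str(curie)] = (name, categories)
    seen: set[KgEdge] = set()
    for edge in (kg.get("edges") or {}).values():
        subj = str(edge.get("subject", ""))
        obj = str(edge.get("object", ""))
        if subj not in graph.nodes or obj not in graph.nodes:
            graph.dropped_edges += 1
            continue
        parsed = KgEdge(
            subject=subj,
            predicate=str(edge.get("predicate", "")),
            object=obj,
            primary_source=_primary_source(edge),
        )
        if parsed not in seen:
            seen.add(parsed)
            graph.edges.append(parsed)
    if graph.dropped_edges:
        logger.warning("dropped %d edges with missing endpoints", graph.dropped_edges)
    return graph


@runtime_checkable
class Transport(Protocol):
    def __call__(self, request: dict) -> dict:
        """Map a TRAPI request document to a TRAPI response document."""
        ...


class HttpTransport:
    """POST transport against a live TRAPI endpoint (optional, online only)."""

    def __init__(self, endpoint: str, timeout: float = 60.0):
        self.endpoint = endpoint
        self.timeout = timeout

    def __call__(self, request: dict) -> dict:
        import urllib.request

        req = urllib.request.Request(
            self.endpoint,
            data=canonical_request_bytes(request),
            headers={"Content-Type": "application/json"},
            method="POST",
        )
        with urllib.request.urlopen(req, timeout=self.timeout) as resp:
            return json.loads(resp.read().decode("utf-8"))


class CacheMissError(KeyError):
    """Raised in offline mode when a request is not in the cache."""


class ResponseCache:
    """File cache: ``<root>/<first two hex>/<digest>.json``, raw responses."""

    def __init__(self, root: str | Path):
        self.root = Path(root)

    def _path(self, key: str) -> Path:
        return self.root / key[:2] / f"{key}.json"

    def get(self, key: str) -> dict | None:
        p = self._path(key)
        if not p.exists():
            return None
        with p.open("r", encoding="utf-8") as fh:
            return json.load(fh)

    def put(self, key: str, response: dict) -> None:
        p = self._path(key)
        p.parent.mkdir(parents=True, exist_ok=True)
        tmp = p.with_suffix(".tmp")
        with tmp.open("w", encoding="utf-8") as fh:
            fh.write(dumps_canonical(response))
        tmp.replace(p)


@dataclass(frozen=True)
class RetrievalConfig:
    """Biolink categories used per benchmark's entity -> category queries.

    The gene benchmark retrieves both Gene and Protein neighbors of the drug
    and the disease; the metabolite benchmark retrieves chemical neighbors of
    the drug and the disease; the drug benchmark retrieves chemical neighbors
    of the disease and the biological process.
    """

    drug_category: str = "biolink:Drug"
    disease_category: str = "biolink:Disease"
    process_category: str = "biolink:BiologicalProcess"
    gene_output_categories: tuple[str, ...] = ("biolink:Gene", "biolink:Protein")
    chemical_output_category: str = "biolink:ChemicalEntity"
    predicate: str | None = None


def specs_for_item(
    item: BenchmarkItem, config: RetrievalConfig = RetrievalConfig()
) -> list[TrapiQuerySpec]:
    """The benchmark-specific set of one-hop query specs for one item."""
    specs: list[TrapiQuerySpec] = []
    if item.benchmark == "gene":
        if not item.drug_curie:
            raise ValueError(f"{item.item_id}: gene item missing drug_curie")
        for out_cat in config.gene_output_categories:
            specs.append(
                TrapiQuerySpec(item.drug_curie, config.drug_category, out_cat, config.predicate)
            )
            specs.append(
                TrapiQuerySpec(
                    item.disease_curie, config.disease_category, out_cat, config.predicate
                )
            )
    elif item.benchmark == "metabolite":
        if not item.drug_curie:
            raise ValueError(f"{item.item_id}: metabolite item missing drug_curie")
        specs.append(
            TrapiQuerySpec(
                item.drug_curie, config.drug_category, config.chemical_output_category,
                config.predicate,
            )
        )
        specs.append(
            TrapiQuerySpec(
                item.disease_curie, config.disease_category, config.chemical_output_category,
                config.predicate,
            )
        )
    elif item.benchmark == "drug":
        if not item.process_curie:
            raise ValueError(f"{item.item_id}: drug item missing process_curie")
        specs.append(
            TrapiQuerySpec(
                item.disease_curie, config.disease_category, config.chemical_output_category,
                config.predicate,
            )
        )
        specs.append(
            TrapiQuerySpec(
                item.process_curie, config.process_category, config.chemical_output_category,
                config.predicate,
            )
        )
    else:
        raise ValueError(f"unknown benchmark kind: {item.benchmark!r}")
    return specs


def retrieve_for_item(
    item: BenchmarkItem,
    transport: Transport | None,
    cache: ResponseCache | None = None,
    config: RetrievalConfig = RetrievalConfig(),
    *,
    offline: bool = False,
) -> RetrievedGraph:
    """Issue the item's query set and return the union of the results.

    Each request is served from the cache when possible; on a cache miss the
    transport is invoked and the raw response stored.  In offline mode
    (``offline=True`` or ``transport is None``) a cache miss raises
    :class:`CacheMissError` naming the spec.
    """
    union = RetrievedGraph()
    for spec in specs_for_item(item, config):
        request = build_trapi_query(spec)
        key = cache_key(request)
        response = cache.get(key) if cache is not None else None
        if response is None:
            if offline or transport is None:
                raise CacheMissError(f"offline cache miss for {spec}")
            try:
                response = transport(request)
            except Exception as exc:  # noqa: BLE001 - annotate with the spec
                raise RuntimeError(f"transport failed for {spec}: {exc}") from exc
            if cache is not None:
                cache.put(key, response)
        union = union.union(parse_trapi_response(response))
    return union
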