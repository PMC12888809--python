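"""Turn knowledge-graph triples into declarative context statements.

Each retrieved edge becomes one short sentence of the form
``"<subject> <predicate> <object> (source: <primary source>)"`` — e.g.
``"DrugX inhibits GeneY (source: ctd)"`` — so structured evidence can be
spliced directly into a language-model prompt while keeping its provenance
visible.
"""

from __future__ import annotations

from dataclasses import dataclass

from .trapi import KgEdge, RetrievedGraph

__all__ = [
    "ContextStatement",
    "humanize_predicate",
    "verbalize_edge",
    "verbalize_graph",
]


@dataclass(frozen=True)
class ContextStatement:
    subject_name: str
    predicate_text: str
    object_name: str
    source: str
    sentence: str


def humanize_predicate(predicate: str) -> str:
    """Strip the ``biolink:`` prefix, replace underscores, lowercase.

    Idempotent: applying it twice equals applying it once.
    """
    text = predicate
    if text.startswith("biolink:"):
        text = text[len("biolink:"):]
    return text.replace("_", " ").lower()


def render_sentence(
    subject_name: str, predicate_text: str, object_name: str, source: str,
    *, include_source: bool = True,
) -> str:
    base = f"{subject_name} {predicate_text} {object_name}"
    if source and include_source:
        return f"{base} (source: {source})"
    return base


def verbalize_edge(
    edge: KgEdge,
    nodes: dict[str, tuple[str, tuple[str, ...]]],
    *,
    include_source: bool = True,
) -> ContextStatement:
    """Render one edge as a declarative sentence with source attribution.

    Node display names come from the graph's node map, falling back to the
    CURIE when the name is absent.  An empty source omits the parenthetical.
    """
    for endpoint in (edge.subject, edge.object):
        if endpoint not in nodes:
            raise KeyError(f"edge endpoint {endpoint!r} absent from node map")

    def display(curie: str) -> str:
        name, _ = nodes[curie]
        return name or curie

    subject_name = display(edge.subject)
    object_name = display(edge.object)
    predicate_text = humanize_predicate(edge.predicate)
    sentence = render_sentence(
        subject_name, predicate_text, object_name, edge.primary_source,
        include_source=include_source,
    )
    return ContextStatement(
        subject_name=subject_name,
        predicate_text=predicate_text,
        object_name=object_name,
        source=edge.primary_source if include_source else "",
        sentence=sentence,
    )


def verbalize_graph(
    graph: RetrievedGraph, *, include_source: bool = True
) -> list[ContextStatement]:
    """One statement per edge, exact-duplicate sentences removed.

    Order follows the edge input order; the first occurrence of a duplicate
    sentence is kept.  Equal graphs therefore yield byte-equal statement
    lists.
    """
    out: list[ContextStatement] = []
    seen: set[str] = set()
    for edge in graph.edges:
        stmt = verbalize_edge(edge, graph.nodes, include_source=include_source)
        if stmt.sentence not in seen:
            seen.add(stmt.sentence)
            out.append(stmt)
    return out
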