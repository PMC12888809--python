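"""Mechanistic question-answer benchmark construction.

Three complementary benchmarks are derived from mechanistic path records,
each probing a different facet of a drug's mechanism of action:

* **gene** — paths with exactly one internal gene/protein node whose
  identifier resolves to exactly one HGNC symbol; the symbol is the gold
  answer.
* **metabolite** — paths with exactly one internal CHEBI-identified
  biochemical entity, after removing purely taxonomic paths and indications
  covered by more than one path record; the metabolite name is the gold.
* **drug** — paths with exactly one BiologicalProcess node and a drug
  identifier from DrugBank or MESH; the drug name is the gold and the
  question supplies the disease and the mediating process.

Each selected path is rendered through a fixed question template, and items
that are identical up to letter case (same drug-or-process, disease, and gold)
are collapsed into one.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

from ._jsonl import read_jsonl, write_jsonl
from .paths import MechPath, PathNode
from .resolve import GeneResolver

__all__ = [
    "BenchmarkItem",
    "QUESTION_TEMPLATES",
    "DEFAULT_GENE_LABELS",
    "DEFAULT_DRUG_ID_PREFIXES",
    "DEFAULT_TAXONOMIC_SUBSTRING",
    "select_gene_paths",
    "select_metabolite_paths",
    "select_drug_paths",
    "render_question",
    "deduplicate_items",
    "build_benchmark",
    "write_benchmark",
    "read_benchmark",
]

BENCHMARK_KINDS = ("gene", "metabolite", "drug")

DEFAULT_GENE_LABELS = frozenset({"Gene", "Protein"})
DEFAULT_DRUG_ID_PREFIXES = frozenset({"DB", "MESH"})
#: a predicate is taxonomic when it contains this substring (case-insensitive)
DEFAULT_TAXONOMIC_SUBSTRING = "subclass"

QUESTION_TEMPLATES = {
    "gene": (
        'Which gene plays the most significant mechanistic role in how '
        'Drug "{drug}" treats or impacts Disease "{disease}"?'
    ),
    "metabolite": (
        'Which biochemical entity is affected by Drug "{drug}" via its '
        'mechanism of action in treating Disease "{disease}"?'
    ),
    "drug": (
        'Which drug can be used in the treatment of Disease "{disease}" by '
        'targeting Biological Process "{process}"?'
    ),
}


@dataclass(frozen=True)
class BenchmarkItem:
    """One templated question with its gold answer and provenance."""

    item_id: str
    benchmark: str
    question: str
    disease_curie: str
    disease_name: str
    gold_answer: str
    gold_curie: str
    drug_curie: str | None = None
    drug_name: str | None = None
    process_curie: str | None = None
    process_name: str | None = None
    source_path_ids: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "benchmark": self.benchmark,
            "question": self.question,
            "drug_curie": self.drug_curie,
            "drug_name": self.drug_name,
            "disease_curie": self.disease_curie,
            "disease_name": self.disease_name,
            "process_curie": self.process_curie,
            "process_name": self.process_name,
            "gold_answer": self.gold_answer,
            "gold_curie": self.gold_curie,
            "source_path_ids": list(self.source_path_ids),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BenchmarkItem":
        return cls(
            item_id=d["item_id"],
            benchmark=d["benchmark"],
            question=d["question"],
            drug_curie=d.get("drug_curie"),
            drug_name=d.get("drug_name"),
            disease_curie=d["disease_curie"],
            disease_name=d["disease_name"],
            process_curie=d.get("process_curie"),
            process_name=d.get("process_name"),
            gold_answer=d["gold_answer"],
            gold_curie=d["gold_curie"],
            source_path_ids=tuple(d.get("source_path_ids", ())),
        )


def render_question(
    benchmark: str,
    drug_name: str | None,
    disease_name: str,
    process_name: str | None = None,
) -> str:
    """Render the fixed question template for one benchmark kind.

    Entity names are substituted verbatim inside double quotes. The drug
    benchmark requires ``process_name`` (and ignores ``drug_name``, which is
    the gold there); the other two require ``drug_name``.
    """
    if benchmark not in BENCHMARK_KINDS:
        raise ValueError(f"unknown benchmark kind: {benchmark!r}")
    if not disease_name:
        raise ValueError("disease_name is required")
    if benchmark == "drug":
        if not process_name:
            raise ValueError("process_name is required for the drug benchmark")
        return QUESTION_TEMPLATES["drug"].format(disease=disease_name, process=process_name)
    if not drug_name:
        raise ValueError(f"drug_name is required for the {benchmark} benchmark")
    return QUESTION_TEMPLATES[benchmark].format(drug=drug_name, disease=disease_name)


def select_gene_paths(
    paths: Sequence[MechPath],
    resolver: GeneResolver,
    gene_labels: frozenset[str] | set[str] = DEFAULT_GENE_LABELS,
) -> list[tuple[MechPath, str]]:
    """Keep paths with exactly one internal gene node resolving to one symbol.

    A path qualifies when its internal (non-drug, non-disease) nodes contain
    exactly one node whose label is in ``gene_labels`` and whose CURIE
    resolves to exactly one HGNC symbol.  Zero resolutions (deprecated
    identifiers) and multiple resolutions (ambiguous identifiers) disqualify
    the path.
    """
    if not gene_labels:
        raise ValueError("gene_labels must be non-empty")
    out: list[tuple[MechPath, str]] = []
    for path in paths:
        gene_nodes = [n for n in path.internal_nodes if n.label in gene_labels]
        if len(gene_nodes) != 1:
            continue
        symbols = resolver.resolve(gene_nodes[0].curie)
        if len(symbols) != 1:
            continue
        out.append((path, symbols[0]))
    return out


def _is_taxonomic_only(path: MechPath, taxonomic_substring: str) -> bool:
    needle = taxonomic_substring.lower()
    return bool(path.links) and all(needle in e.predicate.lower() for e in path.links)


def select_metabolite_paths(
    paths: Sequence[MechPath],
    taxonomic_substring: str = DEFAULT_TAXONOMIC_SUBSTRING,
) -> list[tuple[MechPath, PathNode]]:
    """Keep single-record indications with exactly one internal CHEBI node.

    Stages, in order: (1) drop paths whose every link predicate is taxonomic
    (contains ``taxonomic_substring``); (2) drop indications — (drug curie,
    disease curie) pairs — represented by more than one remaining path
    record; (3) keep paths with exactly one internal node whose CURIE has
    prefix ``CHEBI:`` (case-sensitive), that node being the gold metabolite.
    """
    non_taxonomic = [p for p in paths if not _is_taxonomic_only(p, taxonomic_substring)]
    by_indication: dict[tuple[str, str], list[MechPath]] = {}
    for p in non_taxonomic:
        by_indication.setdefault((p.drug.curie, p.disease.curie), []).append(p)
    out: list[tuple[MechPath, PathNode]] = []
    for p in non_taxonomic:
        if len(by_indication[(p.drug.curie, p.disease.curie)]) != 1:
            continue
        chebi = [n for n in p.internal_nodes if n.curie.startswith("CHEBI:")]
        if len(chebi) != 1:
            continue
        out.append((p, chebi[0]))
    return out


def select_drug_paths(
    paths: Sequence[MechPath],
    drug_id_prefixes: frozenset[str] | set[str] = DEFAULT_DRUG_ID_PREFIXES,
) -> list[tuple[MechPath, PathNode]]:
    """Keep paths with one BiologicalProcess node and a resolvable drug id.

    The drug's CURIE prefix must be in ``drug_id_prefixes`` (DrugBank/MESH by
    default); the path must contain exactly one node labeled
    ``BiologicalProcess``, which becomes the question's process entity.
    """
    if not drug_id_prefixes:
        raise ValueError("drug_id_prefixes must be non-empty")
    out: list[tuple[MechPath, PathNode]] = []
    for p in paths:
        if p.drug.prefix not in drug_id_prefixes:
            continue
        processes = [n for n in p.nodes if n.label == "BiologicalProcess"]
        if len(processes) != 1:
            continue
        out.append((p, processes[0]))
    return out


def _dedup_key(item: BenchmarkItem) -> tuple[str, str, str]:
    first = item.process_name if item.benchmark == "drug" else item.drug_name
    return ((first or "").lower(), item.disease_name.lower(), item.gold_answer.lower())


def deduplicate_items(items: Sequence[BenchmarkItem]) -> list[BenchmarkItem]:
    """Collapse items identical up to case into the first occurrence.

    The key is (drug name — or process name for the drug benchmark —, disease
    name, gold answer), all lowercased.  Source path ids of dropped
    duplicates are merged into the kept item, preserving first-seen order.
    """
    keepers: dict[tuple[str, str, str], BenchmarkItem] = {}
    order: list[tuple[str, str, str]] = []
    for item in items:
        key = _dedup_key(item)
        if key in keepers:
            kept = keepers[key]
            merged = list(kept.source_path_ids)
            for pid in item.source_path_ids:
                if pid not in merged:
                    merged.append(pid)
            keepers[key] = replace(kept, source_path_ids=tuple(merged))
        else:
            keepers[key] = item
            order.append(key)
    return [keepers[k] for k in order]


def _items_from_selection(
    kind: str, selected: Iterable[tuple[MechPath, object]]
) -> list[BenchmarkItem]:
    items: list[BenchmarkItem] = []
    for path, gold in selected:
        if kind == "metabolite":
            node = gold  # the metabolite PathNode
            items.append(
                BenchmarkItem(
                    item_id="",
                    benchmark="metabolite",
                    question=render_question("metabolite", path.drug.name, path.disease.name),
                    drug_curie=path.drug.curie,
                    drug_name=path.drug.name,
                    disease_curie=path.disease.curie,
                    disease_name=path.disease.name,
                    gold_answer=node.name,  # type: ignore[attr-defined]
                    gold_curie=node.curie,  # type: ignore[attr-defined]
                    source_path_ids=(path.path_id,),
                )
            )
        else:  # drug
            process = gold  # the BiologicalProcess PathNode
            items.append(
                BenchmarkItem(
                    item_id="",
                    benchmark="drug",
                    question=render_question(
                        "drug", None, path.disease.name, process.name  # type: ignore[attr-defined]
                    ),
                    drug_curie=path.drug.curie,
                    drug_name=path.drug.name,
                    disease_curie=path.disease.curie,
                    disease_name=path.disease.name,
                    process_curie=process.curie,  # type: ignore[attr-defined]
                    process_name=process.name,  # type: ignore[attr-defined]
                    gold_answer=path.drug.name,
                    gold_curie=path.drug.curie,
                    source_path_ids=(path.path_id,),
                )
            )
    return items


def build_benchmark(
    kind: str,
    paths: Sequence[MechPath],
    resolver: GeneResolver | None = None,
    *,
    gene_labels: frozenset[str] | set[str] = DEFAULT_GENE_LABELS,
    taxonomic_substring: str = DEFAULT_TAXONOMIC_SUBSTRING,
    drug_id_prefixes: frozenset[str] | set[str] = DEFAULT_DRUG_ID_PREFIXES,
) -> list[BenchmarkItem]:
    """Build one benchmark: select paths, render questions, deduplicate.

    Items receive stable ids (``<kind>-<zero-padded ordinal>``) and the output
    is sorted by item id, so identical inputs serialize identically.
    """
    if kind not in BENCHMARK_KINDS:
        raise ValueError(f"unknown benchmark kind: {kind!r}")
    if kind == "gene":
        if resolver is None:
            raise ValueError("gene benchmark requires a resolver")
        selected_g = select_gene_paths(paths, resolver, gene_labels)
        # attach the actual gene node curie as gold_curie
        items = []
        for path, symbol in selected_g:
            gene_node = next(
                n
                for n in path.internal_nodes
                if n.label in gene_labels and len(resolver.resolve(n.curie)) == 1
            )
            items.append(
                BenchmarkItem(
                    item_id="",
                    benchmark="gene",
                    question=render_question("gene", path.drug.name, path.disease.name),
                    drug_curie=path.drug.curie,
                    drug_name=path.drug.name,
                    disease_curie=path.disease.curie,
                    disease_name=path.disease.name,
                    gold_answer=symbol,
                    gold_curie=gene_node.curie,
                    source_path_ids=(path.path_id,),
                )
            )
    elif kind == "metabolite":
        items = _items_from_selection(kind, select_metabolite_paths(paths, taxonomic_substring))
    else:
        items = _items_from_selection(kind, select_drug_paths(paths, drug_id_prefixes))
    deduped = deduplicate_items(items)
    width = max(4, len(str(len(deduped))))
    final = [
        replace(item, item_id=f"{kind}-{i + 1:0{width}d}") for i, item in enumerate(deduped)
    ]
    return sorted(final, key=lambda it: it.item_id)


def write_benchmark(path, items: Sequence[BenchmarkItem]) -> None:
    write_jsonl(path, (it.to_dict() for it in items))


def read_benchmark(path) -> list[BenchmarkItem]:
    return [BenchmarkItem.from_dict(d) for d in read_jsonl(path)]
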