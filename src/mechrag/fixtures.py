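"""Offline synthetic stand-ins for every external dependency.

Real runs of this toolkit depend on a curated mechanistic-path release, a
live federated knowledge-graph endpoint, sentence-embedding models, and
hosted LLM APIs.  This module fabricates deterministic substitutes with
*planted*, known-count structure so every pipeline stage runs offline and
its output can be checked exactly:

* :func:`generate_mini_drugmechdb` — a miniature path database in which
  exactly the configured number of paths satisfy each benchmark filter,
  alongside explicit negatives for every exclusion rule (multi-gene paths,
  ambiguous/deprecated identifiers, taxonomic-only paths, multi-path
  indications, unresolvable drug identifiers, multi-process paths);
* :class:`MockTrapiTransport` — answers TRAPI requests from planted
  entity neighborhoods;
* :class:`HashEmbedder` — a deterministic character-n-gram hashing embedder
  standing in for sentence-transformer models;
* :class:`ScriptedBackend` — an LLM backend that replays scripted responses,
  with helpers to plant exact contingency structure and exact per-item
  similarity targets.

Nothing here aims for statistical realism of biomedical text; the planted
structure is the point.
"""

from __future__ import annotations

import hashlib
import json
import math
import random
from dataclasses import dataclass, field as dc_field
from pathlib import Path
from typing import Sequence

import numpy as np

from .benchmark import BenchmarkItem, render_question
from .inference import SYSTEM_PROMPTS
from .paths import MechPath, PathLink, PathNode, dump_paths
from .resolve import MappingResolver

__all__ = [
    "FixtureConfig",
    "PlantedTruth",
    "generate_mini_drugmechdb",
    "MockTrapiTransport",
    "HashEmbedder",
    "ScriptedBackend",
    "LookupEmbedder",
    "plant_contingency",
    "plant_similarity",
    "script_answers",
]


@dataclass(frozen=True)
class FixtureConfig:
    seed: int = 0
    n_paths: int = 20
    eligible_gene: int = 4
    eligible_metabolite: int = 3
    eligible_drug: int = 4
    n_duplicate_groups: int = 1

    def __post_init__(self) -> None:
        for name in ("n_paths", "eligible_gene", "eligible_metabolite",
                     "eligible_drug", "n_duplicate_groups"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        need = (self.eligible_gene + self.eligible_metabolite
                + self.eligible_drug + self.n_duplicate_groups)
        if need > self.n_paths:
            raise ValueError(
                f"planted paths ({need}) exceed n_paths ({self.n_paths})"
            )
        if self.n_duplicate_groups > self.eligible_gene:
            raise ValueError("duplicate groups require that many gene-eligible paths")


@dataclass
class PlantedTruth:
    """Everything the generator promised about its output."""

    config: FixtureConfig
    expected_counts: dict[str, int]
    resolver_table: dict[str, list[str]]
    #: (input curie, output category) -> list of neighbor edge dicts
    neighborhoods: dict[tuple[str, str], list[dict]] = dc_field(default_factory=dict)
    #: curie -> (display name, biolink categories)
    node_names: dict[str, tuple[str, list[str]]] = dc_field(default_factory=dict)
    #: kind -> list of gold answers, one per eligible path (pre-deduplication)
    golds: dict[str, list[str]] = dc_field(default_factory=dict)

    def resolver(self) -> MappingResolver:
        return MappingResolver(self.resolver_table)

    def to_files(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        with (out / "resolver.json").open("w", encoding="utf-8") as fh:
            json.dump(self.resolver_table, fh, indent=1, sort_keys=True)
        doc = {
            "node_names": {k: [v[0], v[1]] for k, v in self.node_names.items()},
            "neighborhoods": {
                f"{curie}|{cat}": neighbors
                for (curie, cat), neighbors in self.neighborhoods.items()
            },
        }
        with (out / "kg_truth.json").open("w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1, sort_keys=True)


class _Mint:
    """Deterministic entity vocabulary minting."""

    def __init__(self) -> None:
        self.counters: dict[str, int] = {}

    def next(self, kind: str) -> int:
        i = self.counters.get(kind, 0)
        self.counters[kind] = i + 1
        return i

    def drug(self, prefix: str = "MESH") -> PathNode:
        i = self.next("drug")
        local = f"D{i:06d}" if prefix == "MESH" else f"{i:05d}"
        return PathNode(f"{prefix}:{local}", "Drug", f"Drugamycin {i}")

    def disease(self) -> PathNode:
        i = self.next("disease")
        return PathNode(f"MESH:D9{i:05d}", "Disease", f"Malady {i}")

    def gene(self, label: str = "Gene") -> PathNode:
        i = self.next("gene")
        return PathNode(f"NCBIGene:{1000 + i}", label, f"Gene {i}")

    def metabolite(self) -> PathNode:
        i = self.next("metabolite")
        return PathNode(f"CHEBI:{10000 + i}", "ChemicalSubstance", f"Metabolite {i}")

    def process(self) -> PathNode:
        i = self.next("process")
        return PathNode(f"GO:{7000000 + i}", "BiologicalProcess", f"biological process {i}")

    def chemical(self) -> PathNode:
        i = self.next("chemical")
        return PathNode(f"MESH:C{i:06d}", "ChemicalSubstance", f"Compound {i}")


def _chain(path_id: str, nodes: list[PathNode], predicates: list[str]) -> MechPath:
    links = [
        PathLink(nodes[i].curie, nodes[i + 1].curie, predicates[i])
        for i in range(len(nodes) - 1)
    ]
    return MechPath(path_id=path_id, nodes=nodes, links=links)


def _plant_gene_neighborhood(truth: PlantedTruth, drug: PathNode, disease: PathNode,
                             gene: PathNode, symbol: str, mint: _Mint) -> None:
    truth.node_names.setdefault(drug.curie, (drug.name, ["biolink:Drug"]))
    truth.node_names.setdefault(disease.curie, (disease.name, ["biolink:Disease"]))
    truth.node_names.setdefault(gene.curie, (symbol, ["biolink:Gene"]))
    distractor = mint.gene()
    truth.node_names.setdefault(distractor.curie, (distractor.name, ["biolink:Gene"]))
    truth.neighborhoods[(drug.curie, "biolink:Gene")] = [
        {"curie": gene.curie, "predicate": "biolink:affects", "source": "infores:ctd"},
        {"curie": distractor.curie, "predicate": "biolink:interacts_with",
         "source": "infores:biogrid"},
    ]
    truth.neighborhoods[(disease.curie, "biolink:Gene")] = [
        {"curie": gene.curie, "predicate": "biolink:gene_associated_with_condition",
         "source": "infores:disgenet"},
    ]
    truth.neighborhoods.setdefault((drug.curie, "biolink:Protein"), [])
    truth.neighborhoods.setdefault((disease.curie, "biolink:Protein"), [])


def _plant_chemical_neighborhood(truth: PlantedTruth, inputs: list[PathNode],
                                 input_cats: list[str], gold: PathNode,
                                 gold_cat: str, mint: _Mint) -> None:
    truth.node_names.setdefault(gold.curie, (gold.name, [gold_cat]))
    distractor = mint.chemical()
    truth.node_names.setdefault(distractor.curie, (distractor.name, [gold_cat]))
    for node, cat in zip(inputs, input_cats):
        truth.node_names.setdefault(node.curie, (node.name, [cat]))
        truth.neighborhoods[(node.curie, "biolink:ChemicalEntity")] = [
            {"curie": gold.curie, "predicate": "biolink:related_to",
             "source": "infores:drugmechdb"},
            {"curie": distractor.curie, "predicate": "biolink:related_to",
             "source": "infores:chembl"},
        ]


def generate_mini_drugmechdb(config: FixtureConfig) -> tuple[str, PlantedTruth]:
    """Generate a miniature mechanistic-path document with planted structure.

    Exactly ``eligible_gene`` / ``eligible_metabolite`` / ``eligible_drug``
    paths satisfy the respective benchmark filters; ``n_duplicate_groups``
    extra gene-eligible paths duplicate existing items up to letter case (so
    deduplication collapses them); remaining slots are filled with explicit
    negatives, one per exclusion rule, cycling.  The same config yields a
    byte-identical document.
    """
    rng = random.Random(config.seed)
    mint = _Mint()
    truth = PlantedTruth(
        config=config,
        expected_counts={
            "gene": config.eligible_gene,
            "metabolite": config.eligible_metabolite,
            "drug": config.eligible_drug,
        },
        resolver_table={},
        golds={"gene": [], "metabolite": [], "drug": []},
    )
    paths: list[MechPath] = []
    pid = 0

    def next_pid() -> str:
        nonlocal pid
        pid += 1
        return f"path-{pid:04d}"

    gene_eligible: list[tuple[PathNode, PathNode, PathNode, str]] = []
    for i in range(config.eligible_gene):
        drug, disease = mint.drug(), mint.disease()
        label = "Gene" if i % 2 == 0 else "Protein"
        gene = mint.gene(label)
        symbol = f"SG{len(truth.resolver_table) + 1}"
        truth.resolver_table[gene.curie] = [symbol]
        predicates = [rng.choice(["decreases activity of", "increases activity of"]),
                      "causes"]
        paths.append(_chain(next_pid(), [drug, gene, disease], predicates))
        truth.golds["gene"].append(symbol)
        gene_eligible.append((drug, disease, gene, symbol))
        _plant_gene_neighborhood(truth, drug, disease, gene, symbol, mint)

    for _ in range(config.eligible_metabolite):
        drug, disease, metab = mint.drug(), mint.disease(), mint.metabolite()
        predicates = [rng.choice(["increases abundance of", "decreases abundance of"]),
                      "treats"]
        paths.append(_chain(next_pid(), [drug, metab, disease], predicates))
        truth.golds["metabolite"].append(metab.name)
        _plant_chemical_neighborhood(
            truth, [drug, disease], ["biolink:Drug", "biolink:Disease"],
            metab, "biolink:ChemicalEntity", mint,
        )

    for i in range(config.eligible_drug):
        prefix = "DB" if i % 2 == 0 else "MESH"
        drug, disease, proc = mint.drug(prefix), mint.disease(), mint.process()
        predicates = ["positively regulates", "treats"]
        paths.append(_chain(next_pid(), [drug, proc, disease], predicates))
        truth.golds["drug"].append(drug.name)
        _plant_chemical_neighborhood(
            truth, [disease, proc], ["biolink:Disease", "biolink:BiologicalProcess"],
            drug, "biolink:ChemicalEntity", mint,
        )

    # Case-variant duplicates of existing gene items: filters keep them,
    # deduplication must collapse them, leaving the planted counts intact.
    for i in range(config.n_duplicate_groups):
        drug, disease, gene, _symbol = gene_eligible[i]
        dup_drug = PathNode(drug.curie, drug.label, drug.name.upper())
        dup_disease = PathNode(disease.curie, disease.label, disease.name.lower())
        paths.append(_chain(next_pid(), [dup_drug, gene, dup_disease],
                            ["decreases activity of", "causes"]))

    def negative(kind: int) -> list[MechPath]:
        if kind == 0:  # two gene internal nodes
            drug, disease = mint.drug(), mint.disease()
            g1, g2 = mint.gene(), mint.gene("Protein")
            for g in (g1, g2):
                truth.resolver_table[g.curie] = [f"SG{len(truth.resolver_table) + 1}"]
            return [_chain(next_pid(), [drug, g1, g2, disease],
                           ["increases activity of", "interacts with", "causes"])]
        if kind == 1:  # ambiguous gene identifier (resolves to two symbols)
            drug, disease, gene = mint.drug(), mint.disease(), mint.gene()
            base = len(truth.resolver_table)
            truth.resolver_table[gene.curie] = [f"SG{base + 1}", f"SG{base + 2}"]
            return [_chain(next_pid(), [drug, gene, disease],
                           ["decreases activity of", "causes"])]
        if kind == 2:  # deprecated gene identifier (resolves to nothing)
            drug, disease, gene = mint.drug(), mint.disease(), mint.gene()
            return [_chain(next_pid(), [drug, gene, disease],
                           ["decreases activity of", "causes"])]
        if kind == 3:  # taxonomic-only path around a CHEBI node
            drug, disease, metab = mint.drug(), mint.disease(), mint.metabolite()
            return [_chain(next_pid(), [drug, metab, disease],
                           ["subclass of", "subclass of"])]
        if kind == 4:  # an indication covered by two path records
            drug, disease = mint.drug(), mint.disease()
            m1, m2 = mint.metabolite(), mint.metabolite()
            return [
                _chain(next_pid(), [drug, m1, disease],
                       ["increases abundance of", "treats"]),
                _chain(next_pid(), [drug, m2, disease],
                       ["decreases abundance of", "treats"]),
            ]
        if kind == 5:  # drug identifier not resolvable to DrugBank/MESH
            drug = PathNode(f"UNII:X{mint.next('unii'):05d}", "Drug",
                            f"Unresolvable {mint.next('unii_name')}")
            disease, proc = mint.disease(), mint.process()
            return [_chain(next_pid(), [drug, proc, disease],
                           ["positively regulates", "treats"])]
        if kind == 6:  # two BiologicalProcess nodes
            drug, disease = mint.drug(), mint.disease()
            p1, p2 = mint.process(), mint.process()
            return [_chain(next_pid(), [drug, p1, p2, disease],
                           ["positively regulates", "precedes", "treats"])]
        # plain filler: eligible for nothing
        drug, disease, chem = mint.drug(), mint.disease(), mint.chemical()
        return [_chain(next_pid(), [drug, chem, disease],
                       ["increases abundance of", "treats"])]

    kind = 0
    while len(paths) < config.n_paths:
        remaining = config.n_paths - len(paths)
        k = kind % 8
        if k == 4 and remaining < 2:
            k = 7
        paths.extend(negative(k))
        kind += 1

    return dump_paths(paths[: config.n_paths]), truth


class MockTrapiTransport:
    """Answer TRAPI requests from planted (entity, category) neighborhoods."""

    def __init__(self, neighborhoods: dict[tuple[str, str], list[dict]],
                 node_names: dict[str, tuple[str, list[str]]]):
        self.neighborhoods = neighborhoods
        self.node_names = node_names
        self.calls = 0

    @classmethod
    def from_truth(cls, truth: PlantedTruth) -> "MockTrapiTransport":
        return cls(truth.neighborhoods, truth.node_names)

    @classmethod
    def from_file(cls, path: str | Path) -> "MockTrapiTransport":
        with Path(path).open("r", encoding="utf-8") as fh:
            doc = json.load(fh)
        neighborhoods = {}
        for key, neighbors in doc["neighborhoods"].items():
            curie, cat = key.split("|", 1)
            neighborhoods[(curie, cat)] = neighbors
        node_names = {k: (v[0], list(v[1])) for k, v in doc["node_names"].items()}
        return cls(neighborhoods, node_names)

    def __call__(self, request: dict) -> dict:
        self.calls += 1
        try:
            qg = request["message"]["query_graph"]
            pinned = next(n for n in qg["nodes"].values() if n.get("ids"))
            free = next(n for n in qg["nodes"].values() if not n.get("ids"))
            input_curie = pinned["ids"][0]
            output_category = free["categories"][0]
        except (KeyError, StopIteration, IndexError, TypeError) as exc:
            raise ValueError(f"malformed TRAPI request: {exc}") from exc
        neighbors = self.neighborhoods.get((input_curie, output_category), [])
        nodes: dict[str, dict] = {}
        edges: dict[str, dict] = {}

        def add_node(curie: str) -> None:
            name, cats = self.node_names.get(curie, (curie, []))
            nodes[curie] = {"name": name, "categories": list(cats)}

        if neighbors:
            add_node(input_curie)
        for i, nb in enumerate(neighbors):
            add_node(nb["curie"])
            edges[f"e{i}"] = {
                "subject": input_curie,
                "predicate": nb["predicate"],
                "object": nb["curie"],
                "sources": [
                    {"resource_role": "primary_knowledge_source",
                     "resource_id": nb.get("source", "")}
                ],
            }
        return {"message": {"knowledge_graph": {"nodes": nodes, "edges": edges},
                            "results": []}}


class HashEmbedder:
    """Deterministic character-n-gram hashing embedder (test stand-in).

    Each 3-gram of the text is hashed (SHA-256, keyed by the seed) to a
    coordinate and a sign; the accumulated vector is L2-normalized.  Same
    text, same vector — across processes and platforms.
    """

    def __init__(self, dimension: int = 64, seed: int = 0):
        if dimension < 8:
            raise ValueError("dimension must be at least 8")
        self.dimension = dimension
        self.seed = seed

    def _tokens(self, text: str) -> list[str]:
        padded = f"\x02{text}\x03"
        grams = [padded[i : i + 3] for i in range(len(padded) - 2)]
        return grams or [padded]

    def embed(self, text: str) -> np.ndarray:
        vec = np.zeros(self.dimension)
        for gram in self._tokens(text):
            digest = hashlib.sha256(f"{self.seed}|{gram}".encode("utf-8")).digest()
            idx = int.from_bytes(digest[:4], "big") % self.dimension
            sign = 1.0 if digest[4] % 2 == 0 else -1.0
            vec[idx] += sign
        norm = np.linalg.norm(vec)
        if norm == 0.0:
            vec[0] = 1.0
            norm = 1.0
        return vec / norm


class LookupEmbedder:
    """Embedder over a fixed text -> vector table (for planted cosines)."""

    def __init__(self, table: dict[str, np.ndarray]):
        self._table = table

    def embed(self, text: str) -> np.ndarray:
        if text not in self._table:
            raise KeyError(f"no planted vector for text: {text!r}")
        return self._table[text]


class ScriptedBackend:
    """LLM backend replaying scripted responses keyed by (question, mode).

    The question is the last non-empty line of the user text; the mode is
    recovered from the registered system prompt (falling back to whether the
    user text carries a context block).  Unscripted questions raise.
    """

    def __init__(self, scripts: dict[tuple[str, str], str]):
        self.scripts = dict(scripts)
        self._mode_by_system = {text: mode for (_b, mode), text in SYSTEM_PROMPTS.items()}

    def generate(self, system_text: str, user_text: str, *,
                 model: str, temperature: float) -> str:
        lines = [ln for ln in user_text.splitlines() if ln.strip()]
        question = lines[-1] if lines else ""
        mode = self._mode_by_system.get(system_text)
        if mode is None:
            mode = "rag" if user_text.strip() != question else "llm_only"
        key = (question, mode)
        if key not in self.scripts:
            raise KeyError(f"unscripted question/mode: {key!r}")
        return self.scripts[key]

    def to_file(self, path: str | Path) -> None:
        records = [
            {"question": q, "mode": m, "raw": raw}
            for (q, m), raw in sorted(self.scripts.items())
        ]
        with Path(path).open("w", encoding="utf-8") as fh:
            json.dump(records, fh, indent=1, sort_keys=True)

    @classmethod
    def from_file(cls, path: str | Path) -> "ScriptedBackend":
        with Path(path).open("r", encoding="utf-8") as fh:
            records = json.load(fh)
        return cls({(r["question"], r["mode"]): r["raw"] for r in records})


def _answer_json(value: str) -> str:
    return json.dumps({"answer": value})


def script_answers(
    items: Sequence[BenchmarkItem],
    correct_llm: set[str],
    correct_rag: set[str],
    *,
    malformed: set[tuple[str, str]] = frozenset(),
    wrong_prefix: str = "WRONG ",
) -> ScriptedBackend:
    """Build a backend answering the gold for items in the planted sets.

    ``correct_llm`` / ``correct_rag`` are item-id sets answered correctly per
    mode; all others get a planted wrong answer.  ``malformed`` marks
    (item_id, mode) pairs that return non-JSON text (parse failures).
    """
    scripts: dict[tuple[str, str], str] = {}
    for item in items:
        for mode, correct_set in (("llm_only", correct_llm), ("rag", correct_rag)):
            if (item.item_id, mode) in malformed:
                raw = "I cannot answer in the requested format."
            elif item.item_id in correct_set:
                raw = _answer_json(item.gold_answer)
            else:
                raw = _answer_json(wrong_prefix + item.gold_answer)
            scripts[(item.question, mode)] = raw
    return ScriptedBackend(scripts)


def _synthetic_items(n: int, kind: str) -> list[BenchmarkItem]:
    items = []
    width = max(4, len(str(n)))
    for i in range(n):
        drug, disease = f"Drugamycin {i}", f"Malady {i}"
        process = f"biological process {i}"
        gold = {"gene": f"SG{i + 1}", "metabolite": f"Metabolite {i}",
                "drug": drug}[kind]
        items.append(
            BenchmarkItem(
                item_id=f"{kind}-{i + 1:0{width}d}",
                benchmark=kind,
                question=render_question(
                    kind, drug if kind != "drug" else None, disease,
                    process if kind == "drug" else None,
                ),
                drug_curie=f"MESH:D{i:06d}",
                drug_name=drug,
                disease_curie=f"MESH:D9{i:05d}",
                disease_name=disease,
                process_curie=f"GO:{7000000 + i}" if kind == "drug" else None,
                process_name=process if kind == "drug" else None,
                gold_answer=gold,
                gold_curie=f"X:{i}",
                source_path_ids=(f"path-{i + 1:04d}",),
            )
        )
    return items


def plant_contingency(
    n: int, a: int, b: int, c: int, kind: str = "gene"
) -> tuple[list[BenchmarkItem], ScriptedBackend, dict]:
    """Items plus a backend realizing an exact paired contingency table.

    The first ``a`` items are correct under both modes, the next ``b`` only
    under the treatment (rag), the next ``c`` only under the baseline, and
    the remaining ``n - a - b - c`` under neither.
    """
    if a + b + c > n:
        raise ValueError("a + b + c cannot exceed n")
    items = _synthetic_items(n, kind)
    ids = [it.item_id for it in items]
    correct_llm = set(ids[:a]) | set(ids[a + b : a + b + c])
    correct_rag = set(ids[: a + b])
    backend = script_answers(items, correct_llm, correct_rag)
    expected = {"a": a, "b": b, "c": c, "d": n - a - b - c, "n": n}
    return items, backend, expected


def plant_similarity(
    base_scores: Sequence[float],
    diffs: Sequence[float],
    *,
    kind: str = "metabolite",
    dimension: int = 8,
    seed: int = 0,
) -> tuple[list[BenchmarkItem], ScriptedBackend, LookupEmbedder]:
    """Items, backend, and scorer realizing exact per-item cosine targets.

    Item *i*'s baseline answer embeds at cosine ``base_scores[i]`` to the
    gold, its treatment answer at ``base_scores[i] + diffs[i]`` — achieved by
    planting unit vectors ``s*g + sqrt(1-s^2)*w`` in a per-item plane
    ``(g, w)``, so the recovered mean similarity shift equals ``mean(diffs)``
    up to float rounding.
    """
    if len(base_scores) != len(diffs):
        raise ValueError("base_scores and diffs must align")
    n = len(base_scores)
    items = _synthetic_items(n, kind)
    rng = np.random.default_rng(seed)
    table: dict[str, np.ndarray] = {}
    scripts: dict[tuple[str, str], str] = {}
    for i, item in enumerate(items):
        g = rng.standard_normal(dimension)
        g /= np.linalg.norm(g)
        w = rng.standard_normal(dimension)
        w -= w.dot(g) * g
        w /= np.linalg.norm(w)
        s_base = float(base_scores[i])
        s_treat = float(base_scores[i] + diffs[i])
        for s in (s_base, s_treat):
            if not -1 <= s <= 1:
                raise ValueError(f"target cosine out of range: {s}")
        base_text = f"baseline answer {i}"
        treat_text = f"augmented answer {i}"
        table[item.gold_answer] = g
        table[base_text] = s_base * g + math.sqrt(max(0.0, 1 - s_base**2)) * w
        table[treat_text] = s_treat * g + math.sqrt(max(0.0, 1 - s_treat**2)) * w
        scripts[(item.question, "llm_only")] = _answer_json(base_text)
        scripts[(item.question, "rag")] = _answer_json(treat_text)
    return items, ScriptedBackend(scripts), LookupEmbedder(table)
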