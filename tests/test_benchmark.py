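"""Benchmark filters, question templates, deduplication, and build."""

import random

import pytest

from mechrag.benchmark import (
    BenchmarkItem,
    build_benchmark,
    deduplicate_items,
    render_question,
    select_drug_paths,
    select_gene_paths,
    select_metabolite_paths,
    write_benchmark,
)
from mechrag.paths import MechPath, PathLink, PathNode
from mechrag.resolve import MappingResolver


def chain(path_id, nodes, predicates):
    links = [
        PathLink(nodes[i].curie, nodes[i + 1].curie, predicates[i])
        for i in range(len(nodes) - 1)
    ]
    return MechPath(path_id=path_id, nodes=nodes, links=links)


def drug(i=0, prefix="MESH"):
    return PathNode(f"{prefix}:D{i:04d}", "Drug", f"Drug{i}")


def disease(i=0):
    return PathNode(f"MESH:D9{i:03d}", "Disease", f"Disease{i}")


def gene(i=0, label="Gene"):
    return PathNode(f"NCBIGene:{i}", label, f"Gene{i}")


RESOLVER = MappingResolver({
    "NCBIGene:1": ["TNF"],
    "NCBIGene:2": ["IL6"],
    "NCBIGene:3": ["ABC1", "ABC2"],  # ambiguous
})


class TestGeneFilter:
    def test_single_resolvable_gene_retained(self):
        p = chain("p", [drug(), gene(1), disease()], ["inhibits", "causes"])
        assert select_gene_paths([p], RESOLVER) == [(p, "TNF")]

    def test_two_gene_internal_nodes_excluded(self):
        p = chain("p", [drug(), gene(1), gene(2), disease()],
                  ["inhibits", "interacts with", "causes"])
        assert select_gene_paths([p], RESOLVER) == []

    def test_ambiguous_and_deprecated_identifiers_excluded(self):
        amb = chain("a", [drug(0), gene(3), disease(0)], ["inhibits", "causes"])
        dep = chain("d", [drug(1), gene(9), disease(1)], ["inhibits", "causes"])
        assert select_gene_paths([amb, dep], RESOLVER) == []

    def test_protein_label_counts_by_default(self):
        p = chain("p", [drug(), gene(1, "Protein"), disease()], ["inhibits", "causes"])
        assert select_gene_paths([p], RESOLVER) == [(p, "TNF")]
        assert select_gene_paths([p], RESOLVER, gene_labels={"Gene"}) == []

    def test_empty_label_set_rejected(self):
        with pytest.raises(ValueError):
            select_gene_paths([], RESOLVER, gene_labels=set())


def metab(i=0):
    return PathNode(f"CHEBI:{i}", "ChemicalSubstance", f"Metab{i}")


class TestMetaboliteFilter:
    def test_single_chebi_mixed_predicates_retained(self):
        p = chain("p", [drug(), metab(1), disease()], ["increases abundance of", "treats"])
        [(path, node)] = select_metabolite_paths([p])
        assert path is p and node.curie == "CHEBI:1"

    def test_taxonomic_only_excluded(self):
        p = chain("p", [drug(), metab(1), disease()], ["subclass of", "subclass of"])
        assert select_metabolite_paths([p]) == []

    def test_multi_path_indication_excluded(self):
        p1 = chain("p1", [drug(0), metab(1), disease(0)], ["affects", "treats"])
        p2 = chain("p2", [drug(0), metab(2), disease(0)], ["affects", "treats"])
        other = chain("p3", [drug(1), metab(3), disease(1)], ["affects", "treats"])
        selected = select_metabolite_paths([p1, p2, other])
        assert [p.path_id for p, _ in selected] == ["p3"]

    def test_chebi_prefix_is_case_sensitive(self):
        node = PathNode("chebi:1", "ChemicalSubstance", "X")
        p = chain("p", [drug(), node, disease()], ["affects", "treats"])
        assert select_metabolite_paths([p]) == []


def process(i=0):
    return PathNode(f"GO:{i:07d}", "BiologicalProcess", f"process{i}")


class TestDrugFilter:
    def test_one_process_resolvable_drug_retained(self):
        p = chain("p", [drug(1, "DB"), process(1), disease()],
                  ["positively regulates", "treats"])
        [(path, node)] = select_drug_paths([p])
        assert node.name == "process1"

    def test_zero_process_nodes_excluded(self):
        p = chain("p", [drug(1, "DB"), metab(1), disease()], ["affects", "treats"])
        assert select_drug_paths([p]) == []

    def test_unresolvable_drug_prefix_excluded(self):
        p = chain("p", [drug(1, "UNII"), process(1), disease()],
                  ["positively regulates", "treats"])
        assert select_drug_paths([p]) == []


class TestTemplates:
    def test_gene_template(self):
        assert render_question("gene", "Metformin", "Type 2 diabetes") == (
            'Which gene plays the most significant mechanistic role in how '
            'Drug "Metformin" treats or impacts Disease "Type 2 diabetes"?'
        )

    def test_metabolite_template(self):
        assert render_question("metabolite", "Aspirin", "Fever") == (
            'Which biochemical entity is affected by Drug "Aspirin" via its '
            'mechanism of action in treating Disease "Fever"?'
        )

    def test_drug_template(self):
        assert render_question("drug", None, "Asthma", "bronchodilation") == (
            'Which drug can be used in the treatment of Disease "Asthma" by '
            'targeting Biological Process "bronchodilation"?'
        )

    def test_missing_required_name_errors(self):
        with pytest.raises(ValueError):
            render_question("gene", None, "Fever")
        with pytest.raises(ValueError):
            render_question("drug", None, "Asthma", None)
        with pytest.raises(ValueError):
            render_question("nope", "A", "B")


def make_item(i, drug_name, disease_name, gold, kind="gene"):
    return BenchmarkItem(
        item_id=f"{kind}-{i:04d}", benchmark=kind,
        question=render_question(kind, drug_name, disease_name),
        drug_curie=f"MESH:D{i:04d}", drug_name=drug_name,
        disease_curie=f"MESH:D9{i:03d}", disease_name=disease_name,
        gold_answer=gold, gold_curie=f"NCBIGene:{i}",
        source_path_ids=(f"p{i}",),
    )


class TestDedup:
    def test_case_duplicates_merge_sources(self):
        a = make_item(1, "DrugX", "DisY", "TNF")
        b = make_item(2, "DRUGX", "disy", "tnf")
        [kept] = deduplicate_items([a, b])
        assert kept.item_id == a.item_id  # first occurrence wins
        assert kept.source_path_ids == ("p1", "p2")

    def test_distinct_gold_answers_kept(self):
        a = make_item(1, "DrugX", "DisY", "TNF")
        b = make_item(2, "DrugX", "DisY", "IL6")
        assert len(deduplicate_items([a, b])) == 2

    def test_matches_brute_force_distinct_keys(self):
        rng = random.Random(42)
        items = [
            make_item(
                i,
                f"Drug{rng.randrange(5)}".upper() if rng.random() < 0.5 else f"Drug{rng.randrange(5)}",
                f"Dis{rng.randrange(4)}",
                f"G{rng.randrange(6)}",
            )
            for i in range(120)
        ]
        expected_keys = {
            (it.drug_name.lower(), it.disease_name.lower(), it.gold_answer.lower())
            for it in items
        }
        assert len(deduplicate_items(items)) == len(expected_keys)


class TestBuild:
    def test_planted_counts(self, mini_paths, resolver, mini_truth):
        for kind in ("gene", "metabolite", "drug"):
            items = build_benchmark(kind, mini_paths, resolver)
            assert len(items) == mini_truth.expected_counts[kind], kind

    def test_empty_input(self, resolver):
        assert build_benchmark("gene", [], resolver) == []

    def test_deterministic_serialization(self, mini_paths, resolver, tmp_path):
        for i in (1, 2):
            write_benchmark(tmp_path / f"b{i}.jsonl",
                            build_benchmark("gene", mini_paths, resolver))
        assert (tmp_path / "b1.jsonl").read_bytes() == (tmp_path / "b2.jsonl").read_bytes()

    def test_question_regeneration_equality(self, mini_paths, resolver):
        """Every item's stored question round-trips from its stored entities."""
        for kind in ("gene", "metabolite", "drug"):
            for item in build_benchmark(kind, mini_paths, resolver):
                regenerated = render_question(
                    kind, item.drug_name if kind != "drug" else None,
                    item.disease_name, item.process_name,
                )
                assert regenerated == item.question

    def test_gold_invariants(self, mini_paths, resolver):
        for item in build_benchmark("metabolite", mini_paths, resolver):
            assert item.gold_curie.startswith("CHEBI:")
        for item in build_benchmark("drug", mini_paths, resolver):
            assert item.process_curie is not None
            assert item.gold_answer == item.drug_name


class TestFilterProperties:
    def test_idempotence(self, mini_paths, resolver):
        gene_paths = [p for p, _ in select_gene_paths(mini_paths, resolver)]
        assert select_gene_paths(gene_paths, resolver) == select_gene_paths(
            gene_paths, resolver
        )
        assert [p for p, _ in select_gene_paths(gene_paths, resolver)] == gene_paths
        met = [p for p, _ in select_metabolite_paths(mini_paths)]
        assert [p for p, _ in select_metabolite_paths(met)] == met
        drg = [p for p, _ in select_drug_paths(mini_paths)]
        assert [p for p, _ in select_drug_paths(drg)] == drg

    def test_monotonicity_removal_never_adds(self, mini_paths, resolver):
        full = {p.path_id for p, _ in select_gene_paths(mini_paths, resolver)}
        for drop in range(len(mini_paths)):
            subset = mini_paths[:drop] + mini_paths[drop + 1:]
            got = {p.path_id for p, _ in select_gene_paths(subset, resolver)}
            assert got <= full
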