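"""End-to-end orchestration: build -> retrieve -> run -> evaluate.

One declarative :class:`RunConfig` drives the full pipeline and writes a
self-describing run directory: the benchmark file, one answer file per
inference mode, the evaluation report (JSON and text), and a manifest with
content digests of every input and output.  With the scripted backend and a
warm cache, rerunning the same config reproduces every artifact byte for
byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

from ._jsonl import dumps_canonical
from .benchmark import build_benchmark, read_benchmark, write_benchmark
from .evaluation import compare_runs, render_report, score_answers
from .fixtures import HashEmbedder, MockTrapiTransport, ScriptedBackend
from .inference import run_benchmark, write_answers
from .paths import parse_drugmechdb
from .resolve import MappingResolver
from .selection import SelectionConfig, select_context
from .trapi import ResponseCache, RetrievalConfig, retrieve_for_item
from .verbalize import verbalize_graph

__all__ = ["RunConfig", "orchestrate"]

_REGIME_BY_KIND = {"gene": "binary", "metabolite": "score", "drug": "score"}


@dataclass(frozen=True)
class RunConfig:
    kind: str
    paths_file: str
    kg_file: str
    scripts_file: str
    out_dir: str
    cache_dir: str
    resolver_file: str | None = None
    benchmark_file: str | None = None  # reuse a prebuilt benchmark instead
    modes: tuple[str, ...] = ("llm_only", "rag")
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    retrieval: RetrievalConfig = field(default_factory=RetrievalConfig)
    embedder_dimension: int = 64
    seed: int = 0
    model: str = "scripted"
    offline: bool = False

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "paths_file": self.paths_file,
            "kg_file": self.kg_file,
            "scripts_file": self.scripts_file,
            "out_dir": self.out_dir,
            "cache_dir": self.cache_dir,
            "resolver_file": self.resolver_file,
            "benchmark_file": self.benchmark_file,
            "modes": list(self.modes),
            "selection": {
                "mode": self.selection.mode,
                "percentile": self.selection.percentile,
                "token_budget": self.selection.token_budget,
            },
            "embedder_dimension": self.embedder_dimension,
            "seed": self.seed,
            "model": self.model,
            "offline": self.offline,
        }


def _digest_file(path: Path) -> str:
    h = hashlib.sha256()
    with path.open("rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _validate(config: RunConfig) -> None:
    if config.kind not in _REGIME_BY_KIND:
        raise ValueError(f"unknown benchmark kind: {config.kind!r}")
    required = [config.paths_file, config.kg_file, config.scripts_file]
    if config.kind == "gene":
        if config.resolver_file is None:
            raise ValueError("gene benchmark requires resolver_file")
        required.append(config.resolver_file)
    if config.benchmark_file is not None:
        required.append(config.benchmark_file)
    for p in required:
        if not Path(p).exists():
            raise FileNotFoundError(p)
    if config.offline and not Path(config.cache_dir).exists():
        raise FileNotFoundError(f"offline run with missing cache: {config.cache_dir}")


def orchestrate(config: RunConfig, *, clock=None) -> Path:
    """Run the pipeline for one benchmark kind; return the run directory."""
    _validate(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counters: dict[str, int] = {}

    # stage 1: benchmark construction
    if config.benchmark_file is not None:
        items = read_benchmark(config.benchmark_file)
    else:
        document = Path(config.paths_file).read_text(encoding="utf-8")
        paths = parse_drugmechdb(document)
        counters["paths_parsed"] = len(paths)
        resolver = (
            MappingResolver.from_file(config.resolver_file)
            if config.resolver_file
            else None
        )
        items = build_benchmark(config.kind, paths, resolver)
    counters["items_built"] = len(items)
    benchmark_path = out / "benchmark.jsonl"
    write_benchmark(benchmark_path, items)

    # stage 2+3: retrieval, verbalization, context selection
    transport = None if config.offline else MockTrapiTransport.from_file(config.kg_file)
    cache = ResponseCache(config.cache_dir)
    embedder = HashEmbedder(config.embedder_dimension, config.seed)

    def context_provider(item):
        graph = retrieve_for_item(
            item, transport, cache, config.retrieval, offline=config.offline
        )
        statements = verbalize_graph(graph)
        counters["statements_verbalized"] = (
            counters.get("statements_verbalized", 0) + len(statements)
        )
        return select_context(item.question, statements, embedder, config.selection)

    # stage 4: inference per mode
    backend = ScriptedBackend.from_file(config.scripts_file)
    answer_files: dict[str, Path] = {}
    answers_by_mode = {}
    for mode in config.modes:
        answers, record = run_benchmark(
            items,
            backend,
            mode,
            context_provider=context_provider if mode == "rag" else None,
            model=config.model,
            selection_config=config.to_dict()["selection"],
            clock=clock,
        )
        answers_by_mode[mode] = answers
        path = out / f"answers-{mode}.jsonl"
        write_answers(path, answers)
        answer_files[mode] = path
        with (out / f"run-{mode}.json").open("w", encoding="utf-8") as fh:
            fh.write(dumps_canonical(record))

    # stage 5: evaluation
    regime = _REGIME_BY_KIND[config.kind]
    report = None
    if {"llm_only", "rag"} <= set(config.modes):
        scorer = embedder if regime == "score" else None
        baseline = score_answers(items, answers_by_mode["llm_only"], regime, scorer)
        treatment = score_answers(items, answers_by_mode["rag"], regime, scorer)
        report = compare_runs(baseline, treatment, regime, seed=config.seed)
        with (out / "report.json").open("w", encoding="utf-8") as fh:
            fh.write(dumps_canonical(report.to_dict()))
        (out / "report.txt").write_text(render_report(report) + "\n", encoding="utf-8")

    # stage 6: manifest with digests of everything written
    manifest = {
        "config": config.to_dict(),
        "counters": counters,
        "outputs": {
            p.name: _digest_file(p)
            for p in sorted(out.iterdir())
            if p.is_file() and p.name != "manifest.json"
        },
        "inputs": {
            Path(p).name: _digest_file(Path(p))
            for p in [config.paths_file, config.kg_file, config.scripts_file]
            + ([config.resolver_file] if config.resolver_file else [])
        },
    }
    if clock is not None:
        manifest["written_at"] = clock()
    with (out / "manifest.json").open("w", encoding="utf-8") as fh:
        fh.write(dumps_canonical(manifest))
    return out
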