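# mechrag

Knowledge-graph retrieval-augmented generation (RAG) benchmarks for drug
mechanism-of-action question answering — for computational pharmacologists
and LLM evaluators who want to measure, with proper paired statistics,
whether grounding a language model in explicit knowledge-graph evidence
improves its mechanistic answers.

## What it does

Starting from curated mechanistic paths (directed drug → … → disease chains
whose nodes carry Biolink-style categories and CURIEs and whose edges carry
controlled predicates), the package:

1. derives three QA benchmarks — **gene** (gold: the HGNC symbol of the one
   internal gene/protein node), **metabolite** (gold: the one internal
   `CHEBI:` entity), and **drug** (gold: the drug, given disease and
   biological process) — via explicit filtering, identifier-resolution,
   templating, and case-insensitive deduplication rules;
2. retrieves one-hop evidence per question through TRAPI query graphs
   (entity → output category), cached content-addressably for offline,
   byte-reproducible replay;
3. verbalizes retrieved triples into declarative statements
   (`DrugX inhibits GeneY (source: infores:ctd)`);
4. ranks statements by embedding cosine similarity to the question and
   prunes by rank-based percentile rules (`drop_bottom` p%, `keep_top` p%);
5. runs paired LLM-only vs RAG inference at temperature 0 with structured
   JSON answers, and compares the two runs:
   - binary regime: paired 2×2 contingency table (flip counts *b*, *c*),
     exact-binomial and chi-square McNemar tests, net gain
     (b − c)/n × 100 points;
   - score regime: paired mean similarity difference with bootstrap CI,
     Wilcoxon signed-rank, Cliff's δ with CI, threshold-accuracy tables at
     τ ∈ {0.85, 0.90, 0.95}, and score distributions with the
     high-fidelity zone (cosine ≥ 0.90) highlighted.

Every external dependency (path database, knowledge-graph endpoint,
embedders, LLMs) has a deterministic synthetic stand-in with planted,
known-count structure, so the whole pipeline runs and is tested offline.
Live services plug in behind the `Transport` / `Embedder` / `LlmBackend` /
`GeneResolver` contracts.

## Worked example

```sh
mechrag fixtures --seed 1 --out fx                       # synthetic world
mechrag build-benchmarks --input fx/mini_drugmechdb.yaml \
    --kind all --resolver fx/resolver.json --out bench
mechrag run --benchmark bench/benchmark-gene.jsonl --mode llm-only \
    --scripts fx/scripts.json --kg-file fx/kg_truth.json --cache cache --out ans
mechrag run --benchmark bench/benchmark-gene.jsonl --mode rag \
    --scripts fx/scripts.json --kg-file fx/kg_truth.json --cache cache \
    --selection-mode keep_top --percentile 80 --out ans
mechrag evaluate --benchmark bench/benchmark-gene.jsonl \
    --baseline ans/answers-llm_only.jsonl --treatment ans/answers-rag.jsonl \
    --regime binary --out eval
```

prints (fixture defaults: 4/3/4 eligible paths, scripted backend correct on
50% of items alone and 75% with evidence):

```
gene: 4 items
metabolite: 3 items
drug: 4 items
regime: binary
n = 4
contingency  a=2  b=1  c=0  d=1
accuracy     baseline 50.0%  treatment 75.0%
net gain     +25.0 points
McNemar      exact p = 1   chi2 p = 0.317
```

Reading it: of 4 questions, 2 were answered correctly in both modes (*a*),
1 was fixed by retrieval (*b*), none were broken (*c*), 1 stayed wrong (*d*);
accuracy moved 50% → 75%, a net gain of (1−0)/4 × 100 = 25 points; with a
single discordant pair the exact McNemar test rightly finds no significance.
The same commands with `--regime score` on the metabolite or drug benchmark
report mean similarity shift, Wilcoxon, Cliff's δ, and threshold tables.
A single `mechrag pipeline --config run.json` drives all stages and writes a
manifest of content digests; reruns with the scripted backend reproduce
every artifact byte for byte.

## Acceptance script

`scripts/acceptance.py` replays the published paired-analysis inputs through
the full pipeline: it plants the reported contingency flip counts
(245/47 and 119/49 over 798 questions) and high-fidelity-zone counts
(28 → 51 and 30 → 53 of 201; 129 → 144 of 842) into synthetic benchmarks,
runs both inference modes with the scripted backend, and reads the net
accuracy gains, exact McNemar p-value, and relative high-fidelity increases
off the resulting reports:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

## Layout

- `src/mechrag/paths.py` — mechanistic path records (YAML/JSON parsing)
- `src/mechrag/benchmark.py` — filters, templates, dedup, benchmark build
- `src/mechrag/resolve.py` — gene CURIE → HGNC symbol resolution contract
- `src/mechrag/trapi.py` — TRAPI queries, parsing, content-addressed cache
- `src/mechrag/verbalize.py` — triple → declarative statement
- `src/mechrag/selection.py` — cosine ranking, percentile pruning, budgets
- `src/mechrag/inference.py` — prompts, backends, structured-answer parsing
- `src/mechrag/evaluation.py` — metrics, paired statistics, reports, plots
- `src/mechrag/fixtures.py` — planted synthetic world
- `src/mechrag/pipeline.py`, `src/mechrag/cli.py` — orchestration and CLI

See `docs/methods.md` for the statistical definitions, the synthetic-data
model and its limits, and the numerical conventions.
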