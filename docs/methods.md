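# Methods

## Problem and approach

Large language models asked mechanistic pharmacology questions ("which gene
mediates how drug X treats disease Y?") hallucinate freely: their knowledge
is implicit and unsourced.  `mechrag` implements and evaluates the standard
remedy — retrieval-augmented generation grounded in a federated biomedical
knowledge graph — as a reproducible, offline-testable pipeline with a paired
statistical evaluation harness.

The pipeline has five stages:

1. **Benchmark construction.**  Curated mechanistic paths (drug → … →
   disease chains with Biolink-style node categories and controlled edge
   predicates) are filtered into three QA benchmarks.
   *Gene*: exactly one internal (non-endpoint) node labeled `Gene` or
   `Protein` whose CURIE resolves to exactly one HGNC symbol; ambiguous
   (≥ 2 symbols) and deprecated (0 symbols) identifiers disqualify a path.
   *Metabolite*: taxonomic-only paths (every predicate contains "subclass")
   are removed first, then indications — (drug CURIE, disease CURIE) pairs —
   covered by more than one remaining record, then paths kept with exactly
   one internal `CHEBI:`-prefixed node.
   *Drug*: exactly one `BiologicalProcess` node and a drug CURIE prefixed
   `DB` or `MESH`.
   Each selected path is rendered through a fixed question template; items
   identical up to case in (drug-or-process name, disease name, gold) are
   collapsed, first occurrence kept, provenance merged.
2. **Retrieval.**  One-hop TRAPI query graphs (one pinned CURIE, one free
   category-constrained node) are issued per item: gene items query the drug
   and the disease for `Gene` and `Protein` neighbors; metabolite items
   query drug and disease for `ChemicalEntity` neighbors; drug items query
   disease and biological process for `ChemicalEntity` neighbors.  The union
   knowledge graph is kept.  Every request is content-addressed
   (SHA-256 of the canonical serialization) into a file cache so runs replay
   offline, byte-identically.
3. **Verbalization.**  Each edge becomes one declarative sentence,
   `subject predicate object (source: primary_knowledge_source)`, predicate
   de-camel-cased from its `biolink:` form.  Duplicate sentences collapse.
4. **Context selection.**  Sentences and question are embedded; sentences
   are ranked by cosine similarity to the question.  Pruning is rank-based
   (order statistics, not interpolation): `drop_bottom` at percentile *p*
   removes the `floor(p·n/100)` lowest-ranked sentences; `keep_top` retains
   `n − ceil(p·n/100)`.  Ties rank the earlier sentence higher, making the
   retained set unique and reproducible.  An optional token budget
   (4 characters ≈ 1 token) drops further sentences from the low-score end.
5. **Inference and evaluation.**  Prompts instruct a single-key JSON answer;
   generation runs at temperature 0.  Answers that arrive fenced or wrapped
   in prose are repaired by extracting the first balanced JSON object;
   irrecoverable output is scored as wrong (binary regime) or similarity 0
   (score regime) — recorded distinctly (`parse_status`) so the policy is
   auditable.

## Statistical comparison

Two runs over the same items (context-free baseline vs retrieval-augmented)
are compared as paired observations.

*Binary regime* (gene benchmark): answers score by exact case-insensitive
match after trimming whitespace/quotes.  The paired 2×2 table (a, b, c, d) =
(both right, fixed, broken, both wrong) yields accuracies, the net gain
(b − c)/n × 100 in percentage points, and McNemar's test — by default the
exact two-sided binomial min(1, 2·P(X ≤ min(b,c))), X ~ Bin(b+c, ½), because
discordant counts can be small in sub-analyses; the 1-df chi-square without
continuity correction is reported alongside.

*Score regime* (metabolite/drug benchmarks, free-form answers): answers
score by embedding cosine similarity to the gold.  Reported: mean paired
difference with a seeded percentile-bootstrap 95% CI (10,000 reps by
default); the Wilcoxon signed-rank test (zeros dropped; exact distribution
for n ≤ 25 without ties, otherwise normal approximation with tie and
continuity corrections); Cliff's delta between the two score vectors with a
CI from Cliff's consistent variance estimate and normal quantiles, clipped
to [−1, 1]; threshold-accuracy counts at τ ∈ {0.85, 0.90, 0.95} (inclusive:
score ≥ τ); and distribution summaries (rank-ordered scores; histogram over
[0, 1] with 0.05-wide left-closed bins, last bin closed, negatives clamped
into the first bin with a recorded count).  Similarity ≥ 0.90 is the
high-fidelity zone; its count change is also reported as a relative
increase, rounded to an integer percent (fractions to one decimal), matching
conventional reporting precision.

## Synthetic world

The fixtures module fabricates every external dependency:

- **Mini path database**: the generator *plants* exact eligible counts per
  benchmark and emits dedicated negatives for each exclusion clause
  (multi-gene paths, ambiguous/deprecated identifiers, taxonomic-only paths,
  two-record indications, `UNII:` drugs, two-process paths) plus
  case-variant duplicates that deduplication must collapse.  Defaults
  (24 paths, 4/3/4 eligible, one duplicate group) are sized for sub-second
  tests; the planted-count-recovery suite sweeps 100 seeds.
- **Mock TRAPI transport**: planted per-(entity, category) neighborhoods,
  always containing the item's gold entity plus distractors, returned as
  well-formed TRAPI responses with provenance.
- **Hash embedder**: seeded SHA-256 character-trigram hashing into a
  unit-normalized vector (64-d default).  Deterministic across platforms;
  identical texts embed identically and distinct texts essentially never
  reach cosine 1.  It reproduces none of the *semantic* geometry of
  biomedical sentence embedders — a green test establishes pipeline
  correctness (ranking, pruning arithmetic, scoring plumbing), not retrieval
  quality.
- **Scripted backend**: replays planned responses keyed by (question, mode),
  letting tests plant exact contingency structure (which items flip between
  modes) and, via a planted-vector scorer that assigns each answer/gold text
  a unit vector with a prescribed cosine, exact per-item similarity targets.
  Planted effects are recovered to float precision (asserted at 1e-9).

Real-data integration (a DrugMechDB release, a live TRAPI endpoint,
sentence-transformer embedders, hosted LLM APIs) plugs in behind the same
contracts (`Transport`, `Embedder`, `LlmBackend`, `GeneResolver`) but is not
required by any test.

## Numerical and design choices

- Percentile pruning is per-question (each question's own context
  distribution), the natural reading for per-prompt token control; a global
  cutoff across a benchmark would couple unrelated prompts.
- `Protein`-labeled nodes count as gene entities by default (curated paths
  label gene products as proteins while gold answers are HGNC symbols); the
  label set is an argument.
- The metabolite filter applies taxonomic removal before the
  one-record-per-indication rule, following the construction's narrative
  order; indications group by (drug CURIE, disease CURIE).
- Dedup keeps the first occurrence in input order; item ids are zero-padded
  per-benchmark ordinals, and outputs are sorted by id, so rebuilt files are
  byte-stable.
- Cosines are clipped to [−1, 1] against rounding; zero vectors are an
  error, but the hash embedder never produces one (empty text gets a fixed
  basis vector).
- Run records include wall-clock timestamps only when a clock is injected;
  library-default runs are therefore byte-reproducible, which the
  determinism tests exploit.
- McNemar variant and Cliff's-delta CI method are switchable because the
  common conventions differ; defaults are the exact binomial and the
  symmetric normal interval on the consistent variance.

## Known limitations

- The filter monotonicity property ("removing an input path never adds
  items") holds for the gene and drug filters but *cannot* hold for the
  metabolite filter: removing one record of a two-record indication makes
  the survivor eligible.  The property is tested where it is true.
- Exact Wilcoxon p-values are unavailable under tied absolute differences;
  the tie-corrected normal approximation is used there even at small n.
- Token budgeting estimates 4 characters/token; backend-specific tokenizers
  will disagree by small factors.
- Headline accuracies of hosted models and the real benchmark sizes
  (798/201/842) require live services and a pinned database release; this
  package reproduces the evaluation arithmetic and machinery, not the
  hosted-model measurements.
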