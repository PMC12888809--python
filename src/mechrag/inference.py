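"""Prompt assembly, deterministic generation backends, and answer parsing.

Two inference routes are assembled per question: a context-free baseline
(the question alone) and a retrieval-augmented route that prepends the
retained context statements, one per line, before the question.  System
prompts instruct a single-key structured JSON response (``{"answer": ...}``)
so downstream scoring never has to interpret free prose; answers that arrive
wrapped in code fences or surrounded by chatter are repaired by extracting
the first balanced JSON object.  Backends run at temperature 0.
"""

from __future__ import annotations

import hashlib
import json
import re
from dataclasses import dataclass
from typing import Callable, Protocol, Sequence, runtime_checkable

from ._jsonl import read_jsonl, write_jsonl
from .benchmark import BenchmarkItem
from .selection import ScoredStatement

__all__ = [
    "PromptBundle",
    "LlmBackend",
    "ModelAnswer",
    "SYSTEM_PROMPTS",
    "ANSWER_KEY",
    "assemble_qa_prompt",
    "assemble_extraction_prompt",
    "parse_structured_answer",
    "run_benchmark",
    "write_answers",
    "read_answers",
]

ANSWER_KEY = "answer"

_JSON_ONLY = (
    'Respond with a JSON object containing exactly one key, "answer", whose '
    "value is your answer. Output no explanatory text outside the JSON object."
)

#: One system prompt per (benchmark, mode); texts are config-overridable.
SYSTEM_PROMPTS: dict[tuple[str, str], str] = {
    ("gene", "llm_only"): (
        "You are a biomedical expert. Answer with the single official HGNC "
        "gene symbol that plays the most significant mechanistic role in the "
        "drug-disease relationship asked about. " + _JSON_ONLY
    ),
    ("gene", "rag"): (
        "You are a biomedical expert. Mechanistic evidence statements "
        "retrieved from a biomedical knowledge graph precede the question; "
        "use them to identify the single official HGNC gene symbol that "
        "plays the most significant mechanistic role. " + _JSON_ONLY
    ),
    ("metabolite", "llm_only"): (
        "You are a biomedical expert. Name the biochemical entity "
        "(metabolite) affected by the drug's mechanism of action in treating "
        "the disease asked about. " + _JSON_ONLY
    ),
    ("metabolite", "rag"): (
        "You are a biomedical expert. Mechanistic evidence statements "
        "retrieved from a biomedical knowledge graph precede the question; "
        "use them to name the biochemical entity (metabolite) affected by "
        "the drug's mechanism of action. " + _JSON_ONLY
    ),
    ("drug", "llm_only"): (
        "You are a biomedical expert. Name the drug that treats the disease "
        "asked about by targeting the stated biological process. " + _JSON_ONLY
    ),
    ("drug", "rag"): (
        "You are a biomedical expert. Mechanistic evidence statements "
        "retrieved from a biomedical knowledge graph precede the question; "
        "use them to name the drug that treats the disease by targeting the "
        "stated biological process. " + _JSON_ONLY
    ),
}

EXTRACTION_PROMPT = (
    "You are a biomedical named-entity extractor. From the question, extract "
    "the drug, the disease, and the biological process it mentions. Respond "
    'with a JSON object with exactly the keys "drug", "disease", and '
    '"biological_process"; use null for any entity the question does not '
    "mention. Output no text outside the JSON object."
)


@dataclass(frozen=True)
class PromptBundle:
    system_text: str
    user_text: str
    mode: str
    benchmark: str
    context_statement_count: int = 0

    def digest(self) -> str:
        h = hashlib.sha256()
        h.update(self.system_text.encode("utf-8"))
        h.update(b"\x00")
        h.update(self.user_text.encode("utf-8"))
        return h.hexdigest()


@runtime_checkable
class LlmBackend(Protocol):
    def generate(self, system_text: str, user_text: str, *,
                 model: str, temperature: float) -> str:
        """Return raw response text; deterministic at temperature 0."""
        ...


@dataclass(frozen=True)
class ModelAnswer:
    item_id: str
    mode: str
    raw_text: str
    answer: str | None
    parse_status: str  # ok | repaired | failed
    error: str | None = None

    def to_dict(self) -> dict:
        return {
            "item_id": self.item_id,
            "mode": self.mode,
            "raw_text": self.raw_text,
            "answer": self.answer,
            "parse_status": self.parse_status,
            "error": self.error,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelAnswer":
        return cls(
            item_id=d["item_id"],
            mode=d["mode"],
            raw_text=d.get("raw_text", ""),
            answer=d.get("answer"),
            parse_status=d.get("parse_status", "failed"),
            error=d.get("error"),
        )


def assemble_qa_prompt(
    item: BenchmarkItem,
    statements: Sequence[ScoredStatement] | None,
    mode: str,
    *,
    prompts: dict[tuple[str, str], str] = SYSTEM_PROMPTS,
) -> PromptBundle:
    """Build the prompt for one item and inference mode.

    ``rag`` user text is the retained context statements (one per line, in
    retained order), a blank line, then the question; ``llm_only`` is the
    question alone.
    """
    if mode not in ("llm_only", "rag"):
        raise ValueError(f"unknown mode: {mode!r}")
    key = (item.benchmark, mode)
    if key not in prompts:
        raise ValueError(f"no system prompt registered for {key}")
    if mode == "rag":
        retained = [s for s in (statements or []) if s.retained]
        lines = [s.statement.sentence for s in retained]
        user_text = "\n".join(lines) + "\n\n" + item.question if lines else item.question
        count = len(retained)
    else:
        user_text = item.question
        count = 0
    return PromptBundle(
        system_text=prompts[key],
        user_text=user_text,
        mode=mode,
        benchmark=item.benchmark,
        context_statement_count=count,
    )


def assemble_extraction_prompt(free_text_question: str) -> PromptBundle:
    """Zero-shot entity-extraction prompt (drug / disease / process slots)."""
    if not free_text_question:
        raise ValueError("question must be non-empty")
    return PromptBundle(
        system_text=EXTRACTION_PROMPT,
        user_text=free_text_question,
        mode="extraction",
        benchmark="extraction",
        context_statement_count=0,
    )


_FENCE_RE = re.compile(r"```(?:[A-Za-z0-9_+-]*)\n?(.*?)```", re.DOTALL)


def _first_balanced_object(text: str) -> str | None:
    start = text.find("{")
    while start != -1:
        depth = 0
        in_str = False
        escape = False
        for i in range(start, len(text)):
            ch = text[i]
            if in_str:
                if escape:
                    escape = False
                elif ch == "\\":
                    escape = True
                elif ch == '"':
                    in_str = False
            elif ch == '"':
                in_str = True
            elif ch == "{":
                depth += 1
            elif ch == "}":
                depth -= 1
                if depth == 0:
                    return text[start : i + 1]
        start = text.find("{", start + 1)
    return None


def parse_structured_answer(
    raw_text: str, expected_key: str = ANSWER_KEY
) -> tuple[str | None, str]:
    """Extract the structured answer from raw model output.

    Returns ``(answer, parse_status)`` where the status is ``"ok"`` for a
    direct JSON parse, ``"repaired"`` when the object had to be recovered
    from fences or surrounding text, and ``"failed"`` when no object with
    the expected key could be found.  Never raises.
    """

    def _extract(candidate: str) -> str | None:
        try:
            obj = json.loads(candidate)
        except (json.JSONDecodeError, ValueError):
            return None
        if isinstance(obj, dict) and expected_key in obj and obj[expected_key] is not None:
            return str(obj[expected_key]).strip()
        return None

    value = _extract(raw_text.strip())
    if value is not None:
        return value, "ok"
    candidates: list[str] = []
    for m in _FENCE_RE.finditer(raw_text):
        candidates.append(m.group(1).strip())
    stripped = _FENCE_RE.sub(lambda m: m.group(1), raw_text)
    obj_text = _first_balanced_object(stripped)
    if obj_text is not None:
        candidates.append(obj_text)
    for candidate in candidates:
        value = _extract(candidate)
        if value is None and candidate:
            inner = _first_balanced_object(candidate)
            if inner is not None and inner != candidate:
                value = _extract(inner)
        if value is not None:
            return value, "repaired"
    return None, "failed"


def run_benchmark(
    items: Sequence[BenchmarkItem],
    backend: LlmBackend,
    mode: str,
    *,
    context_provider: Callable[[BenchmarkItem], Sequence[ScoredStatement]] | None = None,
    model: str = "scripted",
    temperature: float = 0.0,
    fail_fast: bool = False,
    selection_config: dict | None = None,
    clock: Callable[[], float] | None = None,
) -> tuple[list[ModelAnswer], dict]:
    """Run one inference mode over a benchmark.

    Returns one :class:`ModelAnswer` per item (input order preserved) and a
    run record carrying the model identifier, mode, selection config, and
    per-item prompt digests.  Backend failures mark the item ``failed`` and
    the run continues unless ``fail_fast``.  Timestamps are recorded only
    when a ``clock`` is injected, so default runs are byte-reproducible.
    """
    if mode == "rag" and context_provider is None:
        raise ValueError("rag mode requires a context_provider")
    answers: list[ModelAnswer] = []
    prompt_digests: dict[str, str] = {}
    record: dict = {
        "model": model,
        "mode": mode,
        "temperature": temperature,
        "selection_config": selection_config,
        "n_items": len(items),
        "prompt_digests": prompt_digests,
    }
    if clock is not None:
        record["started_at"] = clock()
    for item in items:
        statements = context_provider(item) if mode == "rag" else None
        bundle = assemble_qa_prompt(item, statements, mode)
        prompt_digests[item.item_id] = bundle.digest()
        try:
            raw = backend.generate(
                bundle.system_text, bundle.user_text, model=model, temperature=temperature
            )
        except Exception as exc:  # noqa: BLE001 - per-item failure policy
            if fail_fast:
                raise
            answers.append(
                ModelAnswer(item.item_id, mode, "", None, "failed", error=str(exc))
            )
            continue
        value, status = parse_structured_answer(raw)
        answers.append(ModelAnswer(item.item_id, mode, raw, value, status))
    if clock is not None:
        record["finished_at"] = clock()
    record["n_failed"] = sum(1 for a in answers if a.parse_status == "failed")
    return answers, record


def write_answers(path, answers: Sequence[ModelAnswer]) -> None:
    write_jsonl(path, (a.to_dict() for a in answers))


def read_answers(path) -> list[ModelAnswer]:
    return [ModelAnswer.from_dict(d) for d in read_jsonl(path)]
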