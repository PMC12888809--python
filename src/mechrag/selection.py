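"""Embedding-similarity ranking and percentile pruning of context.

Context statements are scored by cosine similarity between their sentence
embedding and the question embedding, then pruned by rank-based percentile
rules: ``drop_bottom`` removes the lowest-scoring ``floor(p*n/100)``
statements ("the lowest 10% of similarity scores were removed"), while
``keep_top`` retains only statements strictly above the p-th percentile rank
(a ">80th percentile" cut keeps the top 20%).  Percentiles are order
statistics, not interpolated values, so the retained sets are exact and
tie-stable: at equal scores the earlier statement outranks the later one.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from math import ceil, floor
from typing import Protocol, Sequence, runtime_checkable

import numpy as np

from .verbalize import ContextStatement

__all__ = [
    "Embedder",
    "ScoredStatement",
    "SelectionConfig",
    "cosine_similarity",
    "score_statements",
    "prune",
    "truncate_to_budget",
    "estimate_tokens",
    "select_context",
]


@runtime_checkable
class Embedder(Protocol):
    def embed(self, text: str) -> np.ndarray:
        """Deterministically map a text to a fixed-dimension vector."""
        ...


@dataclass(frozen=True)
class ScoredStatement:
    statement: ContextStatement
    score: float
    retained: bool = True


@dataclass(frozen=True)
class SelectionConfig:
    """mode: full | drop_bottom | keep_top; percentile in [0, 100]."""

    mode: str = "full"
    percentile: float | None = None
    token_budget: int | None = None

    def __post_init__(self) -> None:
        if self.mode not in ("full", "drop_bottom", "keep_top"):
            raise ValueError(f"unknown selection mode: {self.mode!r}")
        if self.mode != "full" and self.percentile is None:
            raise ValueError(f"mode {self.mode!r} requires a percentile")
        if self.percentile is not None and not (0 <= self.percentile <= 100):
            raise ValueError("percentile must be in [0, 100]")
        if self.token_budget is not None and self.token_budget <= 0:
            raise ValueError("token_budget must be positive")


def cosine_similarity(u: np.ndarray, v: np.ndarray) -> float:
    """dot(u, v) / (||u|| * ||v||), clipped to [-1, 1] against rounding."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"dimension mismatch: {u.shape} vs {v.shape}")
    nu = float(np.linalg.norm(u))
    nv = float(np.linalg.norm(v))
    if nu == 0.0 or nv == 0.0:
        raise ValueError("cosine similarity undefined for a zero vector")
    return float(np.clip(float(np.dot(u, v)) / (nu * nv), -1.0, 1.0))


def score_statements(
    question: str,
    statements: Sequence[ContextStatement],
    embedder: Embedder,
) -> list[ScoredStatement]:
    """Score each statement against the question embedding; order preserved."""
    if not statements:
        return []
    q = embedder.embed(question)
    return [
        ScoredStatement(stmt, cosine_similarity(embedder.embed(stmt.sentence), q), True)
        for stmt in statements
    ]


def _rank_order(scored: Sequence[ScoredStatement]) -> list[int]:
    """Indices from lowest- to highest-ranked.

    Rank is by score; at ties the earlier statement outranks the later, so
    among equal scores later indices appear earlier (are dropped first).
    """
    return sorted(range(len(scored)), key=lambda i: (scored[i].score, -i))


def prune(
    scored: Sequence[ScoredStatement], config: SelectionConfig
) -> list[ScoredStatement]:
    """Apply the configured percentile rule; relative order is preserved.

    ``full`` retains everything; ``drop_bottom`` at percentile p marks the
    ``floor(p*n/100)`` lowest-ranked statements unretained; ``keep_top`` at p
    retains the top ``n - ceil(p*n/100)``.
    """
    n = len(scored)
    if config.mode == "full":
        return [replace(s, retained=True) for s in scored]
    p = float(config.percentile)  # type: ignore[arg-type]
    if not (0 <= p <= 100):
        raise ValueError("percentile must be in [0, 100]")
    if config.mode == "drop_bottom":
        n_drop = floor(p * n / 100)
    else:  # keep_top
        n_drop = ceil(p * n / 100)
    dropped = set(_rank_order(scored)[:n_drop])
    return [replace(s, retained=i not in dropped) for i, s in enumerate(scored)]


def estimate_tokens(text: str) -> int:
    """Rough token estimate at 4 characters per token."""
    return ceil(len(text) / 4)


def truncate_to_budget(
    scored: Sequence[ScoredStatement], token_budget: int
) -> list[ScoredStatement]:
    """Unretain statements from the lowest-score end until under budget.

    The budget is compared against the summed token estimates of retained
    statements only; may leave nothing retained.
    """
    if token_budget <= 0:
        raise ValueError("token_budget must be positive")
    out = list(scored)
    total = sum(estimate_tokens(s.statement.sentence) for s in out if s.retained)
    for i in _rank_order(out):
        if total <= token_budget:
            break
        if out[i].retained:
            total -= estimate_tokens(out[i].statement.sentence)
            out[i] = replace(out[i], retained=False)
    return out


def select_context(
    question: str,
    statements: Sequence[ContextStatement],
    embedder: Embedder,
    config: SelectionConfig,
) -> list[ScoredStatement]:
    """Score, prune, and (optionally) budget-truncate in one call."""
    scored = score_statements(question, statements, embedder)
    pruned = prune(scored, config)
    if config.token_budget is not None:
        pruned = truncate_to_budget(pruned, config.token_budget)
    return pruned
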