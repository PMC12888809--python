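"""Scoring and paired statistical comparison of two inference runs.

Two scoring regimes cover the three benchmarks.  The *binary* regime (gene
questions) scores each answer by exact, case-insensitive string match against
the gold symbol; two runs are then compared through the paired 2x2
contingency table — a (both right), b (baseline wrong, treatment right),
c (baseline right, treatment wrong), d (both wrong) — with McNemar's test on
the discordant counts and the net accuracy gain (b - c)/n x 100 in
percentage points.  The *score* regime (metabolite and drug questions, whose
answers are free-form names) scores each answer by embedding cosine
similarity to the gold and compares runs by the paired mean similarity
difference with a bootstrap CI, the Wilcoxon signed-rank test, Cliff's delta
with its consistent-variance CI, threshold-accuracy tables at nearby cutoffs,
and rank-ordered / histogram distribution summaries.  Similarity at or above
0.90 is the high-fidelity zone (near-perfect concordance).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from .benchmark import BenchmarkItem
from .inference import ModelAnswer
from .selection import Embedder, cosine_similarity

__all__ = [
    "ItemResult",
    "PairedBinaryComparison",
    "PairedScoreComparison",
    "ThresholdTable",
    "DistributionSummary",
    "normalize_answer",
    "exact_match",
    "semantic_similarity",
    "threshold_accuracy",
    "paired_contingency",
    "mcnemar_p",
    "net_gain",
    "relative_increase",
    "wilcoxon_signed_rank",
    "cliffs_delta",
    "mean_diff_ci",
    "distribution_summary",
    "score_answers",
    "compare_runs",
    "render_report",
]

HIGH_FIDELITY_THRESHOLD = 0.90
DEFAULT_THRESHOLDS = (0.85, 0.90, 0.95)

_QUOTE_CHARS = "\"'‘’“”`"


@dataclass(frozen=True)
class ItemResult:
    """Per-item outcome under one scoring regime (exactly one field set)."""

    item_id: str
    mode: str
    correct: bool | None = None
    similarity: float | None = None


@dataclass(frozen=True)
class PairedBinaryComparison:
    n: int
    a: int
    b: int
    c: int
    d: int
    acc_baseline: float
    acc_treatment: float
    net_gain_points: float
    p_exact: float
    p_chi2: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "a": self.a, "b": self.b, "c": self.c, "d": self.d,
            "acc_baseline": self.acc_baseline, "acc_treatment": self.acc_treatment,
            "net_gain_points": self.net_gain_points,
            "p_exact": self.p_exact, "p_chi2": self.p_chi2,
        }


@dataclass(frozen=True)
class PairedScoreComparison:
    n: int
    mean_diff: float
    ci_low: float
    ci_high: float
    wilcoxon_p: float
    cliffs_delta: float
    delta_ci_low: float
    delta_ci_high: float

    def to_dict(self) -> dict:
        return {
            "n": self.n, "mean_diff": self.mean_diff,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
            "wilcoxon_p": self.wilcoxon_p, "cliffs_delta": self.cliffs_delta,
            "delta_ci_low": self.delta_ci_low, "delta_ci_high": self.delta_ci_high,
        }


@dataclass(frozen=True)
class ThresholdRow:
    tau: float
    count_baseline: int
    frac_baseline: float
    count_treatment: int
    frac_treatment: float


@dataclass(frozen=True)
class ThresholdTable:
    rows: tuple[ThresholdRow, ...]

    def to_dict(self) -> dict:
        return {
            "rows": [
                {
                    "tau": r.tau,
                    "count_baseline": r.count_baseline,
                    "frac_baseline": r.frac_baseline,
                    "count_treatment": r.count_treatment,
                    "frac_treatment": r.frac_treatment,
                }
                for r in self.rows
            ]
        }


@dataclass(frozen=True)
class DistributionSummary:
    sorted_scores: tuple[float, ...]
    bin_edges: tuple[float, ...]
    counts: tuple[int, ...]
    clamped_negative: int = 0

    def to_dict(self) -> dict:
        return {
            "sorted_scores": list(self.sorted_scores),
            "bin_edges": list(self.bin_edges),
            "counts": list(self.counts),
            "clamped_negative": self.clamped_negative,
        }


def normalize_answer(text: str) -> str:
    """Trim whitespace and surrounding quotes, then case-fold. Idempotent."""
    return text.strip().strip(_QUOTE_CHARS + " \t\r\n").strip().casefold()


def exact_match(pred: str | None, gold: str) -> bool:
    """Case-insensitive exact string match; an absent prediction is wrong."""
    if not gold:
        raise ValueError("gold answer must be non-empty")
    if pred is None:
        return False
    return normalize_answer(pred) == normalize_answer(gold)


def semantic_similarity(pred: str | None, gold: str, scorer: Embedder) -> float:
    """Embedding cosine similarity of prediction and gold; absent pred -> 0."""
    if not gold:
        raise ValueError("gold answer must be non-empty")
    if pred is None or not pred.strip():
        return 0.0
    return cosine_similarity(scorer.embed(pred), scorer.embed(gold))


def threshold_accuracy(scores: Sequence[float], tau: float) -> tuple[int, float]:
    """Count of scores >= tau and its percentage of n (one decimal)."""
    if len(scores) == 0:
        raise ValueError("scores must be non-empty")
    if not (0 <= tau <= 1):
        raise ValueError("tau must be in [0, 1]")
    count = int(sum(1 for s in scores if s >= tau))
    return count, round(count / len(scores) * 100, 1)


def paired_contingency(
    baseline: Sequence[bool], treatment: Sequence[bool]
) -> tuple[int, int, int, int]:
    """(a, b, c, d): both right / fixed / broken / both wrong counts."""
    if len(baseline) != len(treatment):
        raise ValueError(f"length mismatch: {len(baseline)} vs {len(treatment)}")
    a = b = c = d = 0
    for x, y in zip(baseline, treatment):
        if x and y:
            a += 1
        elif not x and y:
            b += 1
        elif x and not y:
            c += 1
        else:
            d += 1
    return a, b, c, d


def mcnemar_p(b: int, c: int, method: str = "exact") -> float:
    """McNemar's test p-value from the discordant counts.

    ``exact``: two-sided binomial, min(1, 2 * P(X <= min(b, c))) with
    X ~ Binomial(b + c, 1/2).  ``chi2``: survival of (b - c)^2 / (b + c) at
    one degree of freedom, no continuity correction.  b + c = 0 gives p = 1.
    """
    if b < 0 or c < 0:
        raise ValueError("counts must be non-negative")
    n_disc = b + c
    if n_disc == 0:
        return 1.0
    if method == "exact":
        return min(1.0, 2.0 * float(stats.binom.cdf(min(b, c), n_disc, 0.5)))
    if method == "chi2":
        return float(stats.chi2.sf((b - c) ** 2 / n_disc, df=1))
    raise ValueError(f"unknown method: {method!r}")


def net_gain(b: int, c: int, n: int) -> float:
    """Net accuracy gain (b - c)/n x 100 in percentage points, one decimal."""
    if n <= 0:
        raise ValueError("n must be positive")
    if b + c > n:
        raise ValueError("b + c cannot exceed n")
    return round((b - c) / n * 100, 1)


def relative_increase(before: int, after: int) -> float:
    """Relative change (after - before)/before x 100, full precision.

    Report-facing numbers round this to the nearest integer percent.
    """
    if before <= 0:
        raise ValueError("before must be positive")
    return (after - before) / before * 100


def wilcoxon_signed_rank(diffs: Sequence[float]) -> float:
    """Two-sided Wilcoxon signed-rank p on paired differences.

    Zero differences are dropped.  The exact distribution is used for
    n <= 25 when the absolute differences are tie-free; otherwise the normal
    approximation with tie and continuity corrections.  All-zero input gives
    p = 1.
    """
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size == 0:
        raise ValueError("diffs must be non-empty")
    nonzero = arr[arr != 0]
    if nonzero.size == 0:
        return 1.0
    has_ties = len(np.unique(np.abs(nonzero))) < nonzero.size
    method = "exact" if (nonzero.size <= 25 and not has_ties) else "approx"
    res = stats.wilcoxon(
        nonzero, zero_method="wilcox", correction=(method == "approx"), method=method
    )
    return float(res.pvalue)


def cliffs_delta(
    x: Sequence[float], y: Sequence[float], level: float = 0.95
) -> tuple[float, float, float]:
    """Cliff's delta of x over y with a consistent-variance normal CI.

    delta = (#{x_i > y_j} - #{x_i < y_j}) / (|x| |y|).  The CI uses Cliff's
    consistent variance estimate with normal quantiles, clipped to [-1, 1].
    Degenerate sizes (|x| < 2 or |y| < 2) give the trivial interval [-1, 1].
    """
    xa = np.asarray(list(x), dtype=float)
    ya = np.asarray(list(y), dtype=float)
    if xa.size == 0 or ya.size == 0:
        raise ValueError("x and y must be non-empty")
    n, m = xa.size, ya.size
    dmat = np.sign(xa[:, None] - ya[None, :])
    delta = float(dmat.mean())
    if n < 2 or m < 2:
        return delta, -1.0, 1.0
    di = dmat.mean(axis=1)
    dj = dmat.mean(axis=0)
    s2 = (
        m**2 * float(((di - delta) ** 2).sum())
        + n**2 * float(((dj - delta) ** 2).sum())
        - float(((dmat - delta) ** 2).sum())
    ) / (n * m * (n - 1) * (m - 1))
    s2 = max(s2, 0.0)
    z = float(stats.norm.ppf(0.5 + level / 2))
    half = z * math.sqrt(s2)
    return delta, max(-1.0, delta - half), min(1.0, delta + half)


def mean_diff_ci(
    diffs: Sequence[float],
    level: float = 0.95,
    reps: int = 10000,
    seed: int = 0,
) -> tuple[float, float, float]:
    """Mean paired difference with a seeded percentile-bootstrap interval."""
    arr = np.asarray(list(diffs), dtype=float)
    if arr.size == 0:
        raise ValueError("diffs must be non-empty")
    if reps < 1000:
        raise ValueError("reps must be at least 1000")
    mean = float(arr.mean())
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, arr.size, size=(reps, arr.size))
    boot_means = arr[idx].mean(axis=1)
    alpha = (1 - level) / 2
    lo, hi = np.quantile(boot_means, [alpha, 1 - alpha])
    return mean, float(lo), float(hi)


def distribution_summary(
    scores: Sequence[float], bin_width: float = 0.05
) -> DistributionSummary:
    """Rank-ordered scores plus a histogram over [0, 1].

    Bins are left-closed with the last bin right-closed; negative scores are
    clamped into the first bin (their count is recorded).
    """
    arr = np.asarray(list(scores), dtype=float)
    nbins = round(1 / bin_width)
    if not math.isclose(nbins * bin_width, 1.0, rel_tol=1e-9):
        raise ValueError("bin_width must divide 1 evenly")
    clamped = int((arr < 0).sum())
    clipped = np.clip(arr, 0.0, 1.0)
    edges = np.linspace(0.0, 1.0, nbins + 1)
    counts, _ = np.histogram(clipped, bins=edges)
    return DistributionSummary(
        sorted_scores=tuple(float(v) for v in np.sort(arr)),
        bin_edges=tuple(float(e) for e in edges),
        counts=tuple(int(cnt) for cnt in counts),
        clamped_negative=clamped,
    )


def score_answers(
    items: Sequence[BenchmarkItem],
    answers: Sequence[ModelAnswer],
    regime: str,
    scorer: Embedder | None = None,
) -> list[ItemResult]:
    """Score one run's answers against the benchmark's golds.

    ``binary`` uses exact match; ``score`` uses embedding similarity (and
    requires a scorer).  Parse failures count as incorrect / similarity 0.
    """
    if regime not in ("binary", "score"):
        raise ValueError(f"unknown regime: {regime!r}")
    if regime == "score" and scorer is None:
        raise ValueError("score regime requires a scorer")
    gold_by_id = {it.item_id: it for it in items}
    missing = [a.item_id for a in answers if a.item_id not in gold_by_id]
    if missing:
        raise ValueError(f"answers for unknown items: {missing}")
    out: list[ItemResult] = []
    for ans in answers:
        gold = gold_by_id[ans.item_id].gold_answer
        if regime == "binary":
            out.append(
                ItemResult(ans.item_id, ans.mode, correct=exact_match(ans.answer, gold))
            )
        else:
            sim = semantic_similarity(ans.answer, gold, scorer)  # type: ignore[arg-type]
            out.append(ItemResult(ans.item_id, ans.mode, similarity=sim))
    return out


@dataclass(frozen=True)
class ComparisonReport:
    regime: str
    binary: PairedBinaryComparison | None = None
    score: PairedScoreComparison | None = None
    thresholds: ThresholdTable | None = None
    distribution_baseline: DistributionSummary | None = None
    distribution_treatment: DistributionSummary | None = None
    high_fidelity: dict | None = None

    def to_dict(self) -> dict:
        out: dict = {"regime": self.regime}
        if self.binary is not None:
            out["binary"] = self.binary.to_dict()
        if self.score is not None:
            out["score"] = self.score.to_dict()
        if self.thresholds is not None:
            out["thresholds"] = self.thresholds.to_dict()
        if self.distribution_baseline is not None:
            out["distribution_baseline"] = self.distribution_baseline.to_dict()
        if self.distribution_treatment is not None:
            out["distribution_treatment"] = self.distribution_treatment.to_dict()
        if self.high_fidelity is not None:
            out["high_fidelity"] = self.high_fidelity
        return out


def _aligned(
    baseline: Sequence[ItemResult], treatment: Sequence[ItemResult]
) -> list[tuple[ItemResult, ItemResult]]:
    base_ids = {r.item_id for r in baseline}
    treat_ids = {r.item_id for r in treatment}
    if base_ids != treat_ids:
        diff = sorted(base_ids.symmetric_difference(treat_ids))
        raise ValueError(f"item_id mismatch between runs: {diff}")
    treat_by_id = {r.item_id: r for r in treatment}
    return [(r, treat_by_id[r.item_id]) for r in baseline]


def compare_runs(
    baseline: Sequence[ItemResult],
    treatment: Sequence[ItemResult],
    regime: str,
    *,
    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
    bootstrap_reps: int = 10000,
    seed: int = 0,
) -> ComparisonReport:
    """Full paired comparison of a baseline run and a treatment run.

    Binary regime: contingency table, both McNemar p-values, accuracies, net
    gain.  Score regime: mean-difference bootstrap CI, Wilcoxon signed-rank,
    Cliff's delta with CI, threshold table, distribution summaries, and
    high-fidelity-zone counts with their relative increase.
    """
    pairs = _aligned(baseline, treatment)
    n = len(pairs)
    if n == 0:
        raise ValueError("no paired items")
    if regime == "binary":
        base_vec = [bool(b.correct) for b, _ in pairs]
        treat_vec = [bool(t.correct) for _, t in pairs]
        a, b_cnt, c_cnt, d = paired_contingency(base_vec, treat_vec)
        return ComparisonReport(
            regime="binary",
            binary=PairedBinaryComparison(
                n=n, a=a, b=b_cnt, c=c_cnt, d=d,
                acc_baseline=round((a + c_cnt) / n * 100, 1),
                acc_treatment=round((a + b_cnt) / n * 100, 1),
                net_gain_points=net_gain(b_cnt, c_cnt, n),
                p_exact=mcnemar_p(b_cnt, c_cnt, "exact"),
                p_chi2=mcnemar_p(b_cnt, c_cnt, "chi2"),
            ),
        )
    if regime != "score":
        raise ValueError(f"unknown regime: {regime!r}")
    base_scores = [float(b.similarity) for b, _ in pairs]
    treat_scores = [float(t.similarity) for _, t in pairs]
    diffs = [t - b for b, t in zip(base_scores, treat_scores)]
    mean, lo, hi = mean_diff_ci(diffs, reps=bootstrap_reps, seed=seed)
    delta, dlo, dhi = cliffs_delta(treat_scores, base_scores)
    rows = []
    for tau in thresholds:
        cb, fb = threshold_accuracy(base_scores, tau)
        ct, ft = threshold_accuracy(treat_scores, tau)
        rows.append(ThresholdRow(tau, cb, fb, ct, ft))
    hf_base, _ = threshold_accuracy(base_scores, HIGH_FIDELITY_THRESHOLD)
    hf_treat, _ = threshold_accuracy(treat_scores, HIGH_FIDELITY_THRESHOLD)
    high_fidelity = {
        "threshold": HIGH_FIDELITY_THRESHOLD,
        "count_baseline": hf_base,
        "count_treatment": hf_treat,
        "relative_increase_pct": (
            round(relative_increase(hf_base, hf_treat)) if hf_base > 0 else None
        ),
    }
    return ComparisonReport(
        regime="score",
        score=PairedScoreComparison(
            n=n, mean_diff=mean, ci_low=lo, ci_high=hi,
            wilcoxon_p=wilcoxon_signed_rank(diffs),
            cliffs_delta=delta, delta_ci_low=dlo, delta_ci_high=dhi,
        ),
        thresholds=ThresholdTable(tuple(rows)),
        distribution_baseline=distribution_summary(base_scores),
        distribution_treatment=distribution_summary(treat_scores),
        high_fidelity=high_fidelity,
    )


def render_report(report: ComparisonReport) -> str:
    """Human-readable text table for a comparison report."""
    lines: list[str] = [f"regime: {report.regime}"]
    if report.binary is not None:
        b = report.binary
        lines += [
            f"n = {b.n}",
            f"contingency  a={b.a}  b={b.b}  c={b.c}  d={b.d}",
            f"accuracy     baseline {b.acc_baseline:.1f}%  treatment {b.acc_treatment:.1f}%",
            f"net gain     {b.net_gain_points:+.1f} points",
            f"McNemar      exact p = {b.p_exact:.3g}   chi2 p = {b.p_chi2:.3g}",
        ]
    if report.score is not None:
        s = report.score
        lines += [
            f"n = {s.n}",
            f"mean diff    {s.mean_diff:+.3f}  (95% CI {s.ci_low:.3f} to {s.ci_high:.3f})",
            f"Wilcoxon     p = {s.wilcoxon_p:.3g}",
            (
                f"Cliff's d    {s.cliffs_delta:+.3f}  "
                f"(95% CI {s.delta_ci_low:.3f} to {s.delta_ci_high:.3f})"
            ),
        ]
    if report.thresholds is not None:
        lines.append("tau    baseline        treatment")
        for r in report.thresholds.rows:
            lines.append(
                f"{r.tau:.2f}   {r.count_baseline:4d} ({r.frac_baseline:5.1f}%)"
                f"   {r.count_treatment:4d} ({r.frac_treatment:5.1f}%)"
            )
    if report.high_fidelity is not None:
        hf = report.high_fidelity
        rel = hf.get("relative_increase_pct")
        rel_txt = f" ({rel:+d}%)" if rel is not None else ""
        lines.append(
            f"high-fidelity (>= {hf['threshold']:.2f}): "
            f"{hf['count_baseline']} -> {hf['count_treatment']}{rel_txt}"
        )
    return "\n".join(lines)


def plot_rank_order(score_sets: dict[str, Sequence[float]], out_path) -> None:
    """Rank-ordered similarity curves (lowest to highest), one per label."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for label, scores in score_sets.items():
        ordered = np.sort(np.asarray(list(scores), dtype=float))
        ax.plot(np.arange(1, ordered.size + 1), ordered, label=label)
    ax.set_xlabel("question rank (lowest to highest similarity)")
    ax.set_ylabel("cosine similarity")
    ax.legend()
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)


def plot_histogram(summary: DistributionSummary, out_path, title: str = "") -> None:
    """Histogram of similarity scores with the high-fidelity bin marked."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    edges = np.asarray(summary.bin_edges)
    counts = np.asarray(summary.counts)
    widths = np.diff(edges)
    colors = [
        "tab:orange" if left >= HIGH_FIDELITY_THRESHOLD - 1e-12 else "tab:blue"
        for left in edges[:-1]
    ]
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(edges[:-1], counts, width=widths, align="edge", color=colors, edgecolor="black")
    ax.set_xlabel("cosine similarity")
    ax.set_ylabel("count")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out_path, dpi=120)
    plt.close(fig)
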