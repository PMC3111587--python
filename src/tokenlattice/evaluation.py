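"""Evaluation statistics for tokenization experiments.

Exact-match accuracy (a unit counts as correct only when its whole predicted
token sequence equals the gold sequence, case-sensitively), the normal
approximation of the binomial confidence interval for a proportion, and
Cohen's kappa with a fixed chance-agreement term.  The kappa convention
models chance agreement between two segmentors as a fair coin toss per unit
(agree/disagree), hence the default ``p_e = 0.5``.

Display rounding follows the reporting convention of the evaluation tables:
percentages to one decimal, kappa to three decimals; raw values are kept
internally.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

__all__ = [
    "EvaluationReport",
    "KeyMismatchError",
    "exact_match_accuracy",
    "binomial_ci",
    "cohens_kappa",
    "pairwise_agreement",
    "report_to_tsv",
    "report_summary",
]

TokenSeq = Sequence[str]


class KeyMismatchError(ValueError):
    """Prediction and gold mappings do not cover the same unit ids."""


@dataclass(frozen=True)
class EvaluationReport:
    """Per-unit exact-match outcomes with accuracy and its 95% CI."""

    n_units: int
    n_correct: int
    accuracy: float
    ci_low: float
    ci_high: float
    per_unit: dict[str, bool] = field(default_factory=dict)
    disagreements: tuple[tuple[str, tuple[str, ...], tuple[str, ...]], ...] = ()

    def __post_init__(self) -> None:
        if not 0 <= self.n_correct <= self.n_units:
            raise ValueError("n_correct out of range")
        if not self.ci_low <= self.accuracy <= self.ci_high:
            raise ValueError("confidence interval does not bracket accuracy")


def _check_keys(a: Mapping[str, TokenSeq], b: Mapping[str, TokenSeq]) -> None:
    if set(a) != set(b):
        missing = sorted(set(b) - set(a))
        extra = sorted(set(a) - set(b))
        raise KeyMismatchError(
            f"mismatched unit ids (missing: {missing[:5]}, extra: {extra[:5]})"
        )


def binomial_ci(p_hat: float, n: int, z: float = 1.96) -> tuple[float, float]:
    """Normal-approximation binomial confidence interval, clamped to [0, 1].

    ``p_hat +/- z * sqrt(p_hat * (1 - p_hat) / n)``; degenerate (zero-width)
    at ``p_hat`` 0 or 1.  Raises ``ValueError`` on ``n < 1`` or a proportion
    outside [0, 1].
    """
    if n < 1:
        raise ValueError(f"n must be >= 1, got {n}")
    if not 0.0 <= p_hat <= 1.0:
        raise ValueError(f"p_hat must be in [0, 1], got {p_hat}")
    half = z * math.sqrt(p_hat * (1.0 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def cohens_kappa(p_o: float, p_e: float = 0.5) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    The default chance term 0.5 is the coin-toss model of per-unit
    agreement.  Raises ``ValueError`` on ``p_e == 1`` or proportions outside
    [0, 1].
    """
    if not 0.0 <= p_o <= 1.0:
        raise ValueError(f"p_o must be in [0, 1], got {p_o}")
    if not 0.0 <= p_e < 1.0:
        raise ValueError(f"p_e must be in [0, 1), got {p_e}")
    return (p_o - p_e) / (1.0 - p_e)


def exact_match_accuracy(
    predictions: Mapping[str, TokenSeq],
    gold: Mapping[str, TokenSeq],
) -> EvaluationReport:
    """Exact-match tokenization accuracy over units keyed by id.

    A unit is correct iff its predicted token sequence equals the gold
    sequence element-wise (case-sensitive); any other tokenization is an
    error.  Raises :class:`KeyMismatchError` on differing key sets.
    """
    _check_keys(predictions, gold)
    if not gold:
        raise ValueError("no units to evaluate")
    per_unit: dict[str, bool] = {}
    disagreements: list[tuple[str, tuple[str, ...], tuple[str, ...]]] = []
    for uid in sorted(gold):
        pred_seq = tuple(predictions[uid])
        gold_seq = tuple(gold[uid])
        ok = pred_seq == gold_seq
        per_unit[uid] = ok
        if not ok:
            disagreements.append((uid, pred_seq, gold_seq))
    n = len(per_unit)
    n_correct = sum(per_unit.values())
    accuracy = n_correct / n
    low, high = binomial_ci(accuracy, n)
    return EvaluationReport(
        n_units=n,
        n_correct=n_correct,
        accuracy=accuracy,
        ci_low=low,
        ci_high=high,
        per_unit=per_unit,
        disagreements=tuple(disagreements),
    )


def pairwise_agreement(
    seg_a: Mapping[str, TokenSeq],
    seg_b: Mapping[str, TokenSeq],
) -> tuple[float, float]:
    """Percent agreement and Cohen's kappa between two segmentations.

    Agreement on a unit means both segmentors produced identical token
    sequences; kappa uses the coin-toss chance term 0.5.
    """
    _check_keys(seg_a, seg_b)
    if not seg_a:
        raise ValueError("no units to compare")
    agree = sum(1 for uid in seg_a if tuple(seg_a[uid]) == tuple(seg_b[uid]))
    p_o = agree / len(seg_a)
    return p_o, cohens_kappa(p_o)


# ---------------------------------------------------------------------------
# Report rendering
# ---------------------------------------------------------------------------

def report_to_tsv(report: EvaluationReport) -> str:
    """Machine-readable TSV: a header block plus one row per unit."""
    lines = [
        "metric\tvalue",
        f"n_units\t{report.n_units}",
        f"n_correct\t{report.n_correct}",
        f"accuracy\t{report.accuracy:.6f}",
        f"ci_low\t{report.ci_low:.6f}",
        f"ci_high\t{report.ci_high:.6f}",
        "",
        "unit_id\tmatch",
    ]
    for uid, ok in sorted(report.per_unit.items()):
        lines.append(f"{uid}\t{int(ok)}")
    return "\n".join(lines) + "\n"


def report_summary(report: EvaluationReport, name: str = "tokenizer") -> str:
    """Human-readable one-line summary in table style.

    Accuracy and CI bounds are shown as percentages rounded to one decimal.
    """
    return (
        f"{name}\tAccuracy (%) {report.accuracy * 100:.1f}\t"
        f"Confidence Interval, 95% {report.ci_low * 100:.1f}, "
        f"{report.ci_high * 100:.1f}\t(n={report.n_units})"
    )
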