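"""Confusion-table metrics and exact reconstruction from rounded marginals.

Besides the usual 2×2 accounting at a chosen cutoff, this module can invert
published summary statistics: given the class sizes and a sensitivity and
specificity printed to one decimal place, it enumerates every integer table
whose exact fractions round (half-up) back to the printed values.  When the
rounding windows admit a single TP and a single TN count, the published 2×2
table — and hence PPV, NPV and accuracy — is recovered exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np

__all__ = [
    "ConfusionTable",
    "ReconstructionResult",
    "table_at_cutoff",
    "reconstruct_table",
    "round_half_up",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Round with ties away from zero at ``ndigits`` decimals (reporting style)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class ConfusionTable:
    """2×2 counts with the derived diagnostic-accuracy metrics."""

    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn", "tn"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer, got {v!r}")

    @property
    def n_pos(self) -> int:
        return self.tp + self.fn

    @property
    def n_neg(self) -> int:
        return self.fp + self.tn

    @property
    def n(self) -> int:
        return self.n_pos + self.n_neg

    @property
    def sensitivity(self) -> float:
        return self.tp / self.n_pos

    @property
    def specificity(self) -> float:
        return self.tn / self.n_neg

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp)

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn)

    @property
    def accuracy(self) -> float:
        return (self.tp + self.tn) / self.n

    @property
    def test_positive_fraction(self) -> float:
        """Fraction of all limbs testing positive (i.e. scoring below cutoff)."""
        return (self.tp + self.fp) / self.n

    def metrics_pct(self, ndigits: int = 1) -> dict:
        """All metrics as percentages, rounded half-up for reporting."""
        return {
            "sensitivity": round_half_up(100.0 * self.sensitivity, ndigits),
            "specificity": round_half_up(100.0 * self.specificity, ndigits),
            "ppv": round_half_up(100.0 * self.ppv, ndigits),
            "npv": round_half_up(100.0 * self.npv, ndigits),
            "accuracy": round_half_up(100.0 * self.accuracy, ndigits),
            "test_positive_fraction": round_half_up(
                100.0 * self.test_positive_fraction, ndigits
            ),
        }


def table_at_cutoff(scores, labels, cutoff: float) -> ConfusionTable:
    """2×2 table under the "score < cutoff ⇒ test positive" rule."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.size == 0:
        raise ValueError("no observations")
    test_pos = scores < cutoff
    return ConfusionTable(
        tp=int(np.sum(test_pos & labels)),
        fp=int(np.sum(test_pos & ~labels)),
        fn=int(np.sum(~test_pos & labels)),
        tn=int(np.sum(~test_pos & ~labels)),
    )


@dataclass(frozen=True)
class ReconstructionResult:
    """Outcome of inverting printed sensitivity/specificity to integer counts."""

    candidates: tuple[ConfusionTable, ...]

    @property
    def unique(self) -> bool:
        return len(self.candidates) == 1

    @property
    def table(self) -> ConfusionTable:
        if not self.unique:
            raise ValueError(
                f"reconstruction is not unique ({len(self.candidates)} candidates)"
            )
        return self.candidates[0]

    @property
    def consistent(self) -> bool:
        return len(self.candidates) > 0


def reconstruct_table(
    n_pos: int,
    n_neg: int,
    sens_printed: float,
    spec_printed: float,
    ndigits: int = 1,
) -> ReconstructionResult:
    """Enumerate the integer 2×2 tables matching printed sens/spec.

    Keeps every tp ∈ [0, n_pos] with round(100·tp/n_pos) == sens_printed and
    every tn ∈ [0, n_neg] with round(100·tn/n_neg) == spec_printed (half-up,
    ``ndigits`` decimals).  An empty candidate set means the printed numbers
    are mutually inconsistent with the stated class sizes.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("n_pos and n_neg must be positive")
    tp_hits = [
        tp
        for tp in range(n_pos + 1)
        if round_half_up(100.0 * tp / n_pos, ndigits) == sens_printed
    ]
    tn_hits = [
        tn
        for tn in range(n_neg + 1)
        if round_half_up(100.0 * tn / n_neg, ndigits) == spec_printed
    ]
    candidates = tuple(
        ConfusionTable(tp=tp, fp=n_neg - tn, fn=n_pos - tp, tn=tn)
        for tp in tp_hits
        for tn in tn_hits
    )
    return ReconstructionResult(candidates=candidates)
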