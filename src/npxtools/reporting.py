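"""Report bookkeeping: integer percentages and exclusion ledgers."""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = ["percent_round_half_up", "ExclusionLedger"]


def percent_round_half_up(numerator: int, denominator: int) -> int:
    """Integer percentage with round-half-up (the convention of printed
    cohort summaries: 85.5% -> 86, not banker's 86/85 ambiguity)."""
    if denominator == 0:
        raise ZeroDivisionError("denominator is zero")
    frac = Decimal(numerator) * 100 / Decimal(denominator)
    return int(frac.quantize(Decimal("1"), rounding=ROUND_HALF_UP))


@dataclass
class ExclusionLedger:
    """Sequential exclusion arithmetic for one participant group.

    Each step subtracts a count for a reason; the ledger keeps the full
    trail so every reported cohort size is re-derivable.
    """

    label: str
    initial: int
    steps: list[dict] = field(default_factory=list)

    def exclude(self, n: int, reason: str) -> "ExclusionLedger":
        if n < 0:
            raise ValueError("exclusion count must be >= 0")
        if n > self.remaining:
            raise ValueError(f"cannot exclude {n} from {self.remaining} remaining")
        self.steps.append({"reason": reason, "n": int(n)})
        return self

    @property
    def remaining(self) -> int:
        return self.initial - sum(s["n"] for s in self.steps)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "initial": self.initial,
            "steps": list(self.steps),
            "remaining": self.remaining,
        }
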