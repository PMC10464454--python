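"""Sequencing-requirement arithmetic for organelle assembly planning."""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP


@dataclass(frozen=True)
class PlanParams:
    """Inputs for the sequencing budget calculation.

    plastome_size in bp, target_coverage in fold coverage, and
    plastid_fraction as the proportion of sequenced bases that are
    plastid-derived.
    """

    plastome_size: int
    target_coverage: float = 50.0
    plastid_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.plastome_size <= 0:
            raise ValueError("plastome_size must be positive")
        if self.target_coverage <= 0:
            raise ValueError("target_coverage must be positive")
        if not (0 < self.plastid_fraction <= 1):
            raise ValueError("plastid_fraction must be in (0, 1]")


def required_total_bp(p: PlanParams) -> int:
    """Total sequencing yield (bp) needed for the target plastid coverage.

    plastome_size * target_coverage / plastid_fraction, rounded half-up
    to whole bases.
    """
    exact = (
        Decimal(p.plastome_size)
        * Decimal(str(p.target_coverage))
        / Decimal(str(p.plastid_fraction))
    )
    return int(exact.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def plastid_read_budget(p: PlanParams) -> int:
    """Plastid bases needed at the target coverage (fraction-independent)."""
    exact = Decimal(p.plastome_size) * Decimal(str(p.target_coverage))
    return int(exact.quantize(Decimal(1), rounding=ROUND_HALF_UP))


def to_gbp_string(bp: int | float) -> str:
    """Render base pairs as Gbp, rounded half-up to two decimals.

    Trailing zeros are dropped ("0.8", not "0.80").
    """
    gbp = (Decimal(bp) / Decimal(10) ** 9).quantize(
        Decimal("0.01"), rounding=ROUND_HALF_UP
    )
    text = str(gbp.normalize())
    # normalize() may produce exponent notation for whole numbers (1E+1)
    if "E" in text:
        text = str(gbp.quantize(Decimal(1)))
    return f"{text} Gbp"


def required_total_gbp(p: PlanParams) -> str:
    return to_gbp_string(required_total_bp(p))


def length_difference(reference_bp: int, assembly_bp: int) -> int:
    """Signed length difference (reference minus assembly) in bp."""
    return reference_bp - assembly_bp
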