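"""X-linked Hardy-Weinberg carrier arithmetic and attribution among myopes.

For an X-linked allele at frequency q, hemizygous males carry it with
probability q, while females carry one copy with probability 2q(1-q) and two
copies with probability q².  Given a per-100 carrier count, a penetrance
(the proportion of carriers who are myopic) and a per-100 myopia prevalence,
the attribution calculation gives the expected number of myopic carriers and
the fraction of all myopes they represent.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import ValidationError

__all__ = [
    "CarrierProbs",
    "AttributionResult",
    "x_linked_carrier_probs",
    "myope_attribution",
    "round_sig",
]


@dataclass(frozen=True)
class CarrierProbs:
    q: float
    male_carrier: float  # = q (hemizygous)
    female_one_copy: float  # = 2q(1-q)
    female_two_copies: float  # = q^2


@dataclass(frozen=True)
class AttributionResult:
    carriers_per_100: float
    penetrance: float
    myopes_per_100: float
    expected_myopic_carriers_per_100: float
    fraction_of_myopes: float


def x_linked_carrier_probs(q: float) -> CarrierProbs:
    """Hardy-Weinberg carrier probabilities for an X-linked allele."""
    if not 0.0 <= q <= 1.0:
        raise ValidationError(f"allele frequency {q} outside [0,1]")
    return CarrierProbs(
        q=q,
        male_carrier=q,
        female_one_copy=2.0 * q * (1.0 - q),
        female_two_copies=q * q,
    )


def myope_attribution(
    carriers_per_100: float, penetrance: float, myopes_per_100: float
) -> AttributionResult:
    """Expected myopic carriers per 100 people and their share of all myopes."""
    if carriers_per_100 < 0 or not 0.0 <= penetrance <= 1.0:
        raise ValidationError("carriers must be >= 0 and penetrance in [0,1]")
    if myopes_per_100 <= 0:
        raise ValidationError("myopes_per_100 must be positive")
    expected = carriers_per_100 * penetrance
    return AttributionResult(
        carriers_per_100=carriers_per_100,
        penetrance=penetrance,
        myopes_per_100=myopes_per_100,
        expected_myopic_carriers_per_100=expected,
        fraction_of_myopes=expected / myopes_per_100,
    )


def round_sig(x: float, sig: int = 2) -> float:
    """Round to ``sig`` significant figures (display convention)."""
    if x == 0:
        return 0.0
    from math import floor, log10

    return round(x, -int(floor(log10(abs(x)))) + (sig - 1))
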