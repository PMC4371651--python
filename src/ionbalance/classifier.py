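"""The one-equation repolarisation/depolarisation-balance classifier.

The score

    Z = (1 + a0*S_CaL + a1*S_Na) / (1 + a2*S_Kr)

pits the remaining depolarising conductance (L-type calcium and sodium
currents, numerator) against the remaining repolarising conductance (hERG,
denominator).  Strong hERG block shrinks the denominator and raises Z
(repolarisation deficit → prolongation direction); strong calcium/sodium
block shrinks the numerator and lowers Z (shortening direction).  With no
drug effect at all (all S = 1) and unit coefficients, Z = 3/2.

Decision rules map Z to endpoint classes: a single cut-off for binary
endpoints (positive iff Z >= t_high) and two cut-offs for ternary
prolong / no-effect / shorten endpoints.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

from .pharmacology import BlockProfile

__all__ = [
    "ClassifierParams",
    "RuleKind",
    "DecisionRule",
    "InvalidRuleError",
    "z_score",
    "classify",
    "POSITIVE",
    "NEGATIVE",
    "PROLONG",
    "NONE",
    "SHORTEN",
]

# Canonical label tokens shared with the io layer.
POSITIVE = "positive"
NEGATIVE = "negative"
PROLONG = "prolong"
NONE = "none"
SHORTEN = "shorten"


class InvalidRuleError(ValueError):
    """A decision rule violates its invariants (e.g. t_low > t_high)."""


@dataclass(frozen=True)
class ClassifierParams:
    """Non-negative channel weights (a0: ICaL, a1: INa, a2: IKr).

    Defaults to unit coefficients (1, 1, 1), the parameter-free form used
    for discriminatory (ROC) analysis; negative weights are rejected as
    they would invert the depolarisation/repolarisation semantics.
    """

    a0: float = 1.0
    a1: float = 1.0
    a2: float = 1.0

    def __post_init__(self) -> None:
        for name in ("a0", "a1", "a2"):
            value = getattr(self, name)
            if value < 0:
                raise InvalidRuleError(f"{name} must be >= 0, got {value!r}")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.a0, self.a1, self.a2)


class RuleKind(str, enum.Enum):
    BINARY = "binary"
    TERNARY = "ternary"


@dataclass(frozen=True)
class DecisionRule:
    """Threshold(s) on Z.

    Binary: positive iff Z >= ``t_high`` (boundary inclusive by
    convention; any fixed convention works for ROC).  Ternary:
    "prolong" iff Z >= ``t_high``, "shorten" iff Z <= ``t_low``,
    "none" otherwise, so each compound receives exactly one label.
    """

    kind: RuleKind
    t_high: float
    t_low: float | None = None

    def __post_init__(self) -> None:
        if self.kind is RuleKind.TERNARY:
            if self.t_low is None:
                raise InvalidRuleError("ternary rule requires t_low")
            if self.t_low > self.t_high:
                raise InvalidRuleError(
                    f"ternary rule requires t_low <= t_high, "
                    f"got t_low={self.t_low!r} > t_high={self.t_high!r}"
                )


def z_score(profile: BlockProfile, params: ClassifierParams | None = None) -> float:
    """Balance score Z = (1 + a0*S_CaL + a1*S_Na) / (1 + a2*S_Kr).

    Larger Z means the repolarisation deficit dominates (prolongation
    direction); smaller Z means the depolarisation deficit dominates.
    The denominator is positive for any valid profile since a2 >= 0 and
    S_Kr >= 0.
    """
    if params is None:
        params = ClassifierParams()
    return (1.0 + params.a0 * profile.s_cal + params.a1 * profile.s_na) / (
        1.0 + params.a2 * profile.s_kr
    )


def classify(z: float, rule: DecisionRule) -> str:
    """Map a Z score to a label token under ``rule``.

    Binary rules return ``"positive"``/``"negative"``; ternary rules
    return ``"prolong"``/``"none"``/``"shorten"``.
    """
    if rule.kind is RuleKind.BINARY:
        return POSITIVE if z >= rule.t_high else NEGATIVE
    if z >= rule.t_high:
        return PROLONG
    assert rule.t_low is not None
    if z <= rule.t_low:
        return SHORTEN
    return NONE
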