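"""Hill-equation pharmacology for multi-channel cardiac safety panels.

Converts per-compound ion-channel potency data (IC50/EC50, Hill coefficient,
Emax) into fractional conductance scalings ``S_x`` at a drug concentration
``[D]``.  Three channels are modelled, matching what routine HTS cardiac
panels measure consistently:

* ``IKr``  — hERG, the rapid delayed-rectifier potassium current
  (repolarising; block delays repolarisation),
* ``ICaL`` — hCav1.2, the L-type calcium current (depolarising),
* ``INa``  — hNav1.5, the cardiac sodium current (depolarising).

For an inhibitor the conductance scaling is

    S = 1 - 1 / (1 + (IC50 / [D])**n)

and for an agonist

    S = 1 + Emax / (1 + (EC50 / [D])**n)

so ``S = 1`` means no effect, ``S = 0`` full block and ``S > 1`` agonism.
Potencies and concentrations must share one unit (canonically µM); only the
ratio ``potency/[D]`` enters the formulas.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import TYPE_CHECKING, Iterable

if TYPE_CHECKING:  # pragma: no cover - import cycle avoidance, typing only
    from .io import CompoundRecord

__all__ = [
    "Channel",
    "Mode",
    "ChannelActivity",
    "BlockProfile",
    "InvalidInputError",
    "fractional_conductance",
    "block_profile",
]


class Channel(str, enum.Enum):
    """The three ion channels consistently measured across HTS panels."""

    IKR = "IKr"
    ICAL = "ICaL"
    INA = "INa"


class Mode(str, enum.Enum):
    INHIBITOR = "inhibitor"
    AGONIST = "agonist"


class InvalidInputError(ValueError):
    """A pharmacology input violates its invariants; names the offending field."""


@dataclass(frozen=True)
class ChannelActivity:
    """One compound's action on one channel.

    Parameters
    ----------
    channel
        Which channel the measurement refers to.
    mode
        ``inhibitor`` (potency read as IC50) or ``agonist`` (potency read
        as EC50; ``emax`` required).
    potency
        IC50 or EC50, in the same concentration unit as the test
        concentration (canonically µM).  Must be positive.
    hill_n
        Hill coefficient (sigmoid steepness); defaults to 1, the standard
        pharmacology convention when a source does not report it.
    emax
        Maximal fractional conductance increase for agonists; ignored for
        inhibitors.
    """

    channel: Channel
    mode: Mode
    potency: float
    hill_n: float = 1.0
    emax: float | None = None

    def __post_init__(self) -> None:
        if not self.potency > 0:
            raise InvalidInputError(f"potency must be > 0, got {self.potency!r}")
        if not self.hill_n > 0:
            raise InvalidInputError(f"hill_n must be > 0, got {self.hill_n!r}")
        if self.mode is Mode.AGONIST:
            if self.emax is None:
                raise InvalidInputError("emax is required for an agonist activity")
            if self.emax < 0:
                raise InvalidInputError(f"emax must be >= 0, got {self.emax!r}")


@dataclass(frozen=True)
class BlockProfile:
    """The triple (S_Kr, S_CaL, S_Na) of conductance scalings at one concentration.

    A channel with no recorded activity scales by exactly 1 (no effect);
    inhibited channels lie in [0, 1], agonised channels in [1, 1 + Emax].
    """

    s_kr: float
    s_cal: float
    s_na: float
    concentration: float = field(default=1.0)

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.s_kr, self.s_cal, self.s_na)


def fractional_conductance(activity: ChannelActivity, concentration: float) -> float:
    """Fractional conductance scaling S of one channel at ``concentration``.

    Evaluates the mode-appropriate Hill equation.  Continuous and monotone
    in concentration: decreasing for inhibitors (1 → 0), increasing for
    agonists (1 → 1 + Emax).  At ``concentration == potency`` an inhibitor
    gives exactly S = 0.5 regardless of the Hill coefficient.
    """
    if not concentration > 0:
        raise InvalidInputError(
            f"concentration must be > 0, got {concentration!r}"
        )
    ratio = (activity.potency / concentration) ** activity.hill_n
    if activity.mode is Mode.INHIBITOR:
        return 1.0 - 1.0 / (1.0 + ratio)
    assert activity.emax is not None  # enforced by ChannelActivity
    return 1.0 + activity.emax / (1.0 + ratio)


def block_profile(record: "CompoundRecord", concentration: float | None = None) -> BlockProfile:
    """Compute the (S_Kr, S_CaL, S_Na) profile for one compound.

    ``concentration`` defaults to the record's own test concentration.
    Channels without a recorded activity are assigned S = 1: an unmeasured
    channel leaves its conductance unscaled, the only neutral choice under
    conductance-scaling semantics.
    """
    if concentration is None:
        concentration = record.concentration
    activities: Iterable[ChannelActivity] = record.activities
    scalings = {channel: 1.0 for channel in Channel}
    for activity in activities:
        scalings[activity.channel] = fractional_conductance(activity, concentration)
    return BlockProfile(
        s_kr=scalings[Channel.IKR],
        s_cal=scalings[Channel.ICAL],
        s_na=scalings[Channel.INA],
        concentration=concentration,
    )
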