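"""Seeded synthetic multi-channel potency panels with Z-linked labels.

Emulates the structure of literature cardiac-safety screening data-sets —
log-spread potencies across hERG/hCav1.2/hNav1.5, occasional unmeasured
channels, rare calcium/sodium agonists — with endpoint labels generated
from the compound's true balance score Z under known coefficients and
thresholds, then corrupted by a configurable label-flip rate.  Because the
generating parameters are known, the generator supports end-to-end testing
(label–Z consistency, parameter recovery, permutation nulls) without any
external data.

Potencies are parameterised relative to the test concentration, which is
fixed at 1: only the ratio potency/[D] enters the conductance scaling, so
the generator is unit-free.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import classifier as _cls
from .classifier import ClassifierParams, DecisionRule, RuleKind, classify, z_score
from .io import LABELS, CompoundRecord, Dataset, Endpoint, positive_label
from .pharmacology import Channel, ChannelActivity, Mode, block_profile

__all__ = ["GeneratorConfig", "generate", "default_thresholds"]


def default_thresholds(
    endpoint: Endpoint, params: ClassifierParams | None = None
) -> DecisionRule:
    """Default true decision rule per endpoint.

    Thresholds are anchored at the drug-free baseline
    Z0 = (1 + a0 + a1)/(1 + a2) of the generating coefficients, so the
    positive class always means "net shift toward repolarisation deficit
    relative to no drug" whatever the coefficients.  Binary endpoints cut
    at Z0 itself (1.5 at unit coefficients); the ternary rule brackets it
    at (0.8·Z0, 1.2·Z0) — (1.2, 1.8) at unit coefficients — so
    moderate-imbalance compounds fall in the no-effect band.
    """
    if params is None:
        params = ClassifierParams()
    baseline = (1.0 + params.a0 + params.a1) / (1.0 + params.a2)
    if endpoint is Endpoint.APD_TERNARY:
        return DecisionRule(kind=RuleKind.TERNARY,
                            t_high=1.2 * baseline, t_low=0.8 * baseline)
    return DecisionRule(kind=RuleKind.BINARY, t_high=baseline)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions for one synthetic panel.

    Defaults emulate a realistic HTS screening panel: potencies log-uniform
    over four decades around the test concentration, 15% of channel
    measurements missing, 5% of calcium/sodium activities agonist rather
    than inhibitor, Hill coefficients in [0.7, 1.5], and a 5% label-flip
    rate standing in for endpoint misclassification.
    """

    n_compounds: int
    seed: int = 0
    endpoint: Endpoint = Endpoint.TDP_BINARY
    true_params: ClassifierParams = field(default_factory=ClassifierParams)
    true_thresholds: DecisionRule | None = None  # None -> default_thresholds
    potency_log10_range: tuple[float, float] = (-2.0, 2.0)
    missing_rate: float = 0.15
    agonist_rate: float = 0.05
    label_noise: float = 0.05
    hill_n_range: tuple[float, float] = (0.7, 1.5)
    emax_range: tuple[float, float] = (0.5, 2.0)
    # optional log-normal measurement error on recorded potencies
    # (labels always derive from the true, unjittered potencies)
    potency_jitter_sigma: float = 0.0

    def __post_init__(self) -> None:
        if self.n_compounds < 3:
            raise ValueError("n_compounds must be >= 3")
        for name in ("missing_rate", "agonist_rate", "label_noise"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {p!r}")
        for name in ("potency_log10_range", "hill_n_range", "emax_range"):
            lo, hi = getattr(self, name)
            if lo > hi:
                raise ValueError(f"{name} must be ordered, got ({lo!r}, {hi!r})")
        if self.potency_jitter_sigma < 0:
            raise ValueError("potency_jitter_sigma must be >= 0")

    def rule(self) -> DecisionRule:
        return self.true_thresholds or default_thresholds(
            self.endpoint, self.true_params
        )


def generate(config: GeneratorConfig) -> Dataset:
    """Draw one synthetic dataset; fully reproducible from ``config.seed``.

    Per compound and channel: presence ~ Bernoulli(1 − missing_rate);
    mode agonist with probability ``agonist_rate`` for ICaL/INa (hERG
    activities are always inhibitory, matching screening practice);
    potency log-uniform; Hill coefficient uniform; Emax uniform for
    agonists.  The label is the true rule applied to the true Z, flipped
    with probability ``label_noise``.

    Panel structure, label noise and potency jitter are drawn from three
    independent child streams of ``seed``, so changing the noise settings
    perturbs only the noise: the underlying compounds stay identical.
    """
    streams = np.random.SeedSequence(config.seed).spawn(3)
    rng_panel, rng_noise, rng_jitter = (np.random.default_rng(s) for s in streams)
    rule = config.rule()
    records = []
    lo, hi = config.potency_log10_range
    for i in range(config.n_compounds):
        true_activities: list[ChannelActivity] = []
        for channel in (Channel.IKR, Channel.ICAL, Channel.INA):
            if rng_panel.random() < config.missing_rate:
                continue
            mode = Mode.INHIBITOR
            if channel is not Channel.IKR and rng_panel.random() < config.agonist_rate:
                mode = Mode.AGONIST
            potency = float(10.0 ** rng_panel.uniform(lo, hi))
            hill_n = float(rng_panel.uniform(*config.hill_n_range))
            emax = (
                float(rng_panel.uniform(*config.emax_range))
                if mode is Mode.AGONIST else None
            )
            true_activities.append(
                ChannelActivity(channel=channel, mode=mode, potency=potency,
                                hill_n=hill_n, emax=emax)
            )

        probe = CompoundRecord(
            compound_id=f"cpd-{i + 1:04d}",
            concentration=1.0,
            activities=tuple(true_activities),
            label=LABELS[config.endpoint][0],  # placeholder, replaced below
        )
        z = z_score(block_profile(probe), config.true_params)
        token = classify(z, rule)
        if config.endpoint is Endpoint.APD_TERNARY:
            label = token
        elif token == _cls.POSITIVE:
            label = positive_label(config.endpoint)
        else:
            label = next(lab for lab in LABELS[config.endpoint]
                         if lab != positive_label(config.endpoint))
        # both noise draws are consumed per compound regardless of outcome,
        # keeping the noise stream aligned across label_noise settings
        flip = rng_noise.random() < config.label_noise
        flip_choice = int(rng_noise.integers(0, 2))
        if flip:
            others = [lab for lab in LABELS[config.endpoint] if lab != label]
            label = others[flip_choice % len(others)]

        activities = tuple(true_activities)
        if config.potency_jitter_sigma > 0:
            activities = tuple(
                ChannelActivity(
                    channel=a.channel, mode=a.mode,
                    potency=float(a.potency * np.exp(
                        rng_jitter.normal(0.0, config.potency_jitter_sigma))),
                    hill_n=a.hill_n, emax=a.emax,
                )
                for a in activities
            )

        records.append(
            CompoundRecord(
                compound_id=probe.compound_id,
                concentration=1.0,
                activities=activities,
                label=label,
            )
        )

    return Dataset(
        name=f"synthetic-{config.endpoint.value}-seed{config.seed}",
        endpoint=config.endpoint,
        species="synthetic",
        records=tuple(records),
    )
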