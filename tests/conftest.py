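import pytest
from hypothesis import HealthCheck, settings

from ionbalance import (
    Channel,
    ChannelActivity,
    CompoundRecord,
    Dataset,
    Endpoint,
    Mode,
)

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


def make_record(cid, label, conc=1.0, ikr=None, ical=None, ina=None):
    """Build a CompoundRecord from per-channel (mode, potency, n[, emax]) tuples."""
    activities = []
    for channel, spec in ((Channel.IKR, ikr), (Channel.ICAL, ical), (Channel.INA, ina)):
        if spec is None:
            continue
        mode, potency, hill_n = spec[0], spec[1], spec[2]
        emax = spec[3] if len(spec) > 3 else None
        activities.append(
            ChannelActivity(channel=channel, mode=Mode(mode), potency=potency,
                            hill_n=hill_n, emax=emax)
        )
    return CompoundRecord(compound_id=cid, concentration=conc,
                          activities=tuple(activities), label=label)


@pytest.fixture
def tdp_dataset():
    """Six compounds whose risk labels follow hERG-vs-CaL/Na balance exactly."""
    records = (
        # strong selective hERG blockers -> repolarisation deficit -> risk
        make_record("herg-strong", "risk", ikr=("inhibitor", 0.01, 1.0)),
        make_record("herg-mid", "risk", ikr=("inhibitor", 0.02, 1.2)),
        make_record("herg-weak", "risk",
                    ikr=("inhibitor", 0.05, 1.0), ina=("inhibitor", 50.0, 1.0)),
        # hERG-sparing depolarisation blockers or inactives -> no risk
        make_record("cal-selective", "no-risk", ical=("inhibitor", 0.1, 1.0)),
        make_record("na-selective", "no-risk", ina=("inhibitor", 0.5, 1.0)),
        make_record("clean", "no-risk"),
    )
    return Dataset(name="tdp-demo", endpoint=Endpoint.TDP_BINARY,
                   species="human", records=records)


@pytest.fixture
def ternary_dataset():
    records = (
        make_record("p1", "prolong", ikr=("inhibitor", 0.05, 1.0)),
        make_record("p2", "prolong", ikr=("inhibitor", 0.1, 1.0)),
        make_record("p3", "prolong", ikr=("inhibitor", 0.2, 1.3)),
        make_record("n1", "none"),
        make_record("n2", "none", ikr=("inhibitor", 1.0, 1.0),
                    ical=("inhibitor", 1.0, 1.0)),
        make_record("n3", "none", ina=("inhibitor", 30.0, 1.0)),
        make_record("n4", "none", ikr=("inhibitor", 5.0, 1.0)),
        make_record("n5", "none", ical=("inhibitor", 8.0, 1.0)),
        make_record("s1", "shorten", ical=("inhibitor", 0.05, 1.0)),
        make_record("s2", "shorten", ical=("inhibitor", 0.1, 1.0),
                    ina=("inhibitor", 0.2, 1.0)),
    )
    return Dataset(name="apd-demo", endpoint=Endpoint.APD_TERNARY,
                   species="dog", records=records)
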