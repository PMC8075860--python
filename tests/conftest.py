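import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from itdcall import (
    ITDSpec,
    MixtureSpec,
    RunConfig,
    SequencingRead,
    default_reference,
    simulate_reads,
)

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def ref():
    return default_reference()


@pytest.fixture()
def cfg():
    return RunConfig()


@pytest.fixture(scope="session")
def as_reads():
    """Convert simulator output into SequencingReads with constant Q37."""

    def convert(simulated):
        return [
            SequencingRead(
                f"r{i}", r.bases, np.full(len(r.bases), 37, dtype=np.int16), r.mate
            )
            for i, r in enumerate(simulated)
        ]

    return convert


@pytest.fixture(scope="session")
def simulate(ref, as_reads):
    """Shortcut: simulate a mixture and return in-memory reads."""

    def run(alleles, **kwargs):
        mix = MixtureSpec(alleles=alleles, **kwargs)
        return as_reads(simulate_reads(ref, mix))

    return run
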