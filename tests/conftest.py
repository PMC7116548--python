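import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")

from aacsia.registry import STANDARD_AAS
from aacsia.types import Injection, SequenceRun, StandardReference


def make_standard_injection(seq, element, values, replicate=1):
    return Injection(
        sequence_index=seq,
        role="standard",
        sample_id="",
        element=element,
        replicate_index=replicate,
        measured=dict(values),
    )


def make_sample_injection(seq, element, sample_id, values, replicate=1):
    return Injection(
        sequence_index=seq,
        role="sample",
        sample_id=sample_id,
        element=element,
        replicate_index=replicate,
        measured=dict(values),
    )


@pytest.fixture
def nitrogen_reference():
    return StandardReference(
        element="N",
        certified={code: float(v) for code, v in zip(
            STANDARD_AAS, [43.25, 30.19, -6.69, 11.2, 0.8, 22.5, 5.3])},
    )


@pytest.fixture
def tiny_nitrogen_run(nitrogen_reference):
    """Two standards bracketing one triplicate sample, Glu and Phe only."""
    values = {"Glu": 10.0, "Phe": 2.0}
    injections = [
        make_standard_injection(1, "N", {"Glu": 22.5, "Phe": 5.3}),
        make_sample_injection(2, "N", "s1", values, replicate=1),
        make_sample_injection(3, "N", "s1", values, replicate=2),
        make_sample_injection(4, "N", "s1", values, replicate=3),
        make_standard_injection(5, "N", {"Glu": 22.5, "Phe": 5.3}),
    ]
    return SequenceRun(
        element="N", injections=injections, standard_ref=nitrogen_reference
    )
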