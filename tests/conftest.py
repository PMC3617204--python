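"""Shared fixtures: the reference network and small closed-form toy models."""

import numpy as np
import pytest

from cd4sim.model import ModelDefinition, RateLaw, Reaction, Species
from cd4sim.reference import build_reference_model


@pytest.fixture(scope="session")
def reference_model():
    return build_reference_model()


def make_decay_toy(k: float = 1.0) -> ModelDefinition:
    """A -> B, mass action; closed form A(t) = e^-kt, B(t) = 1 - e^-kt."""
    return ModelDefinition(
        species=[
            Species("A", "A", "signal_transducer", 1.0),
            Species("B", "B", "signal_transducer", 0.0),
        ],
        reactions=[
            Reaction(
                id="conv",
                substrates=(("A", 1.0),),
                products=(("B", 1.0),),
                rate_law=RateLaw(kind="mass_action", k="k1"),
            )
        ],
        parameters={"k1": k},
        name="decay_toy",
    )


def make_source_sink_toy(k_in: float = 0.7, k_out: float = 0.35) -> ModelDefinition:
    """S(boundary) -> X -> sink; steady state X* = k_in*S/k_out."""
    return ModelDefinition(
        species=[
            Species("S", "source", "external_cytokine", 1.0, True),
            Species("X", "X", "signal_transducer", 0.0),
            Species("sink", "sink", "degradation_product", 0.0, True),
        ],
        reactions=[
            Reaction(
                id="influx",
                substrates=(("S", 1.0),),
                products=(("X", 1.0),),
                rate_law=RateLaw(kind="mass_action", k="k_in"),
            ),
            Reaction(
                id="efflux",
                substrates=(("X", 1.0),),
                products=(("sink", 1.0),),
                rate_law=RateLaw(kind="mass_action", k="k_out"),
            ),
        ],
        parameters={"k_in": k_in, "k_out": k_out},
        name="source_sink_toy",
    )


@pytest.fixture()
def decay_toy():
    return make_decay_toy()


@pytest.fixture()
def source_sink_toy():
    return make_source_sink_toy()
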