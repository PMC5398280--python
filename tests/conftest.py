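import numpy as np
import pytest

from logicmap.genome import CircuitNetwork, GateSpec


@pytest.fixture
def rng():
    return np.random.default_rng(20_26)


@pytest.fixture
def table1_gate():
    """The 2-in/2-out reference gate: 11->01, 01->00, 10->11, 00->01.

    Rows are indexed with the first input as the most significant bit, so
    the truth table reads (row 00, 01, 10, 11) -> (01, 00, 11, 01).
    """
    return GateSpec(
        n_in=2,
        n_out=2,
        input_addrs=(0, 1),
        output_addrs=(4, 5),
        table=(0b01, 0b00, 0b11, 0b01),
    )


@pytest.fixture
def table1_network(table1_gate):
    # two inputs, no hidden nodes; gate writes the first two output nodes
    return CircuitNetwork([table1_gate], n_inputs=2, n_hidden=0)


def random_gate_specs(rng, n_gates, n_inputs, n_hidden):
    """Uniformly random well-formed gate specs for round-trip tests."""
    state_size = n_inputs + n_hidden + 4
    specs = []
    for _ in range(n_gates):
        n_in = int(rng.integers(1, 5))
        n_out = int(rng.integers(1, 5))
        specs.append(
            GateSpec(
                n_in,
                n_out,
                tuple(int(a) for a in rng.integers(0, min(state_size, 256), n_in)),
                tuple(
                    int(a) for a in rng.integers(n_inputs, state_size, n_out)
                ),
                tuple(int(v) for v in rng.integers(0, 2**n_out, 2**n_in)),
            )
        )
    return specs
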