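"""Genome codec, gate execution, and mutation operators."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from logicmap.genome import (
    START_BYTES,
    CircuitNetwork,
    GateSpec,
    Genome,
    MutationRates,
    classify,
    classify_batch,
    compile_circuit,
    decode_genome,
    encode_gates,
    gene_span,
    mutate,
    random_genome,
    read_genomes,
    step_network,
    used_input_bits,
    write_genomes,
)
from conftest import random_gate_specs


class TestDecode:
    def test_all_zero_genome_has_no_gates(self):
        g = Genome(np.zeros(400, dtype=np.uint8))
        net = decode_genome(g, n_inputs=10, n_hidden=4)
        assert net.gates == []

    def test_hand_written_not_gate(self):
        # built by hand against the documented layout: codon, n_in=1,
        # n_out=1, input node 3, output slot 0 (first non-input node),
        # table rows 0 -> 1 and 1 -> 0 (a NOT gate); trailing bytes unused
        raw = [42, 213, 0, 0, 3, 0, 0, 0, 0, 0, 0, 0, 1, 0] + [0] * 14
        net = decode_genome(Genome(np.array(raw, dtype=np.uint8)), 8, 2)
        assert len(net.gates) == 1
        gate = net.gates[0]
        assert gate == GateSpec(1, 1, (3,), (8,), (1, 0))

    def test_codon_inside_gene_body_is_not_rescanned(self, rng):
        spec = GateSpec(1, 1, (42,), (50,), (1, 0))
        # force codon-like bytes into the table region
        g = encode_gates([spec], 50, 2)
        data = g.data.copy()
        data[12] = START_BYTES[0]
        data[13] = START_BYTES[1]
        net = decode_genome(Genome(data), 50, 2)
        assert len(net.gates) == 1

    def test_truncated_tail_gene_is_ignored(self):
        raw = np.array(list(START_BYTES) + [0] * 5, dtype=np.uint8)
        assert decode_genome(Genome(raw), 4, 0).gates == []

    @settings(max_examples=50, deadline=None)
    @given(st.integers(0, 2**32 - 1), st.integers(0, 6))
    def test_encode_decode_round_trip(self, seed, n_gates):
        rng = np.random.default_rng(seed)
        n_inputs, n_hidden = int(rng.integers(1, 200)), int(rng.integers(0, 40))
        specs = random_gate_specs(rng, n_gates, n_inputs, n_hidden)
        genome = encode_gates(specs, n_inputs, n_hidden)
        assert decode_genome(genome, n_inputs, n_hidden).gates == specs

    def test_round_trip_with_two_byte_addresses(self, rng):
        # wide networks need multi-byte addresses to reach nodes >= 256
        specs = [GateSpec(2, 1, (300, 5), (1400,), (1, 0, 1, 1))]
        genome = encode_gates(specs, 1376, 64, address_bytes=2)
        assert decode_genome(genome, 1376, 64, address_bytes=2).gates == specs

    def test_one_byte_address_cannot_reach_wide_nodes(self):
        specs = [GateSpec(1, 1, (300,), (1400,), (1, 0))]
        with pytest.raises(ValueError, match="not representable"):
            encode_gates(specs, 1376, 64, address_bytes=1)


class TestRandomGenome:
    def test_zero_gates_decodes_empty(self, rng):
        g = random_genome(0, rng)
        assert len(g) == 0
        assert decode_genome(g, 5, 2).gates == []

    def test_gate_count_matches_request(self, rng):
        g = random_genome(100, rng)
        assert len(decode_genome(g, 50, 16).gates) == 100

    def test_same_seed_is_byte_identical(self):
        a = random_genome(10, np.random.default_rng(7))
        b = random_genome(10, np.random.default_rng(7))
        assert a == b

    def test_too_many_gates_rejected(self, rng):
        with pytest.raises(ValueError):
            random_genome(10_000, rng, max_length=1_000)


class TestExecution:
    @pytest.mark.parametrize(
        "ab,cd",
        [((1, 1), (0, 1)), ((0, 1), (0, 0)), ((1, 0), (1, 1)), ((0, 0), (0, 1))],
    )
    def test_reference_gate_rows(self, table1_network, ab, cd):
        state = np.array([*ab, 0, 0, 0, 0], dtype=np.uint8)
        new = step_network(table1_network, state)
        assert tuple(new[4:6]) == cd

    def test_same_node_writes_are_ored(self):
        # two constant gates write 0 and 1 into the same node
        g0 = GateSpec(1, 1, (0,), (1,), (0, 0))
        g1 = GateSpec(1, 1, (0,), (1,), (1, 1))
        net = CircuitNetwork([g0, g1], n_inputs=1, n_hidden=0)
        assert step_network(net, [0, 0, 0, 0, 0])[1] == 1

    def test_or_combination_matches_individual_writes(self, rng):
        n_inputs, n_hidden = 6, 2
        state_size = n_inputs + n_hidden + 4
        for _ in range(25):
            specs = random_gate_specs(rng, 2, n_inputs, n_hidden)
            target = int(rng.integers(n_inputs, state_size))
            specs = [
                GateSpec(s.n_in, s.n_out, s.input_addrs,
                         (target,) + s.output_addrs[1:], s.table)
                for s in specs
            ]
            state = np.zeros(state_size, dtype=np.uint8)
            state[:n_inputs] = rng.integers(0, 2, n_inputs)
            joint = step_network(CircuitNetwork(specs, n_inputs, n_hidden), state)
            solo = [
                step_network(CircuitNetwork([s], n_inputs, n_hidden), state)[target]
                for s in specs
            ]
            assert joint[target] == max(solo)

    def test_unwritten_nodes_carry_over(self):
        net = CircuitNetwork([], n_inputs=1, n_hidden=1)
        state = np.array([1, 1, 0, 1, 0, 1], dtype=np.uint8)
        assert np.array_equal(step_network(net, state), state)


class TestClassify:
    def test_empty_network_asserts_nothing(self):
        net = CircuitNetwork([], 4, 2)
        assert classify(net, [1, 0, 1, 0]) == (False, False)

    def test_constant_positive_writer(self):
        # gate writes 1 into pos-primary whatever the input
        net = CircuitNetwork([GateSpec(1, 1, (0,), (4 + 2,), (1, 1))], 2, 2)
        assert classify(net, [0, 0]) == (False, True)
        assert classify(net, [1, 1]) == (False, True)

    def test_veto_suppresses_assertion(self):
        # writes 1 into both pos-primary and pos-veto
        net = CircuitNetwork([GateSpec(1, 2, (0,), (6, 7), (3, 3))], 2, 2)
        assert classify(net, [1, 0]) == (False, False)

    def test_classify_is_deterministic(self, rng):
        net = decode_genome(random_genome(8, rng), 20, 8)
        bits = rng.integers(0, 2, 20)
        first = classify(net, bits, n_steps=2)
        assert all(classify(net, bits, n_steps=2) == first for _ in range(100))

    @pytest.mark.parametrize("n_steps", [1, 2, 3])
    def test_batch_path_matches_scalar_path(self, rng, n_steps):
        for _ in range(10):
            net = decode_genome(random_genome(12, rng), 30, 8)
            X = rng.integers(0, 2, size=(40, 30)).astype(np.uint8)
            bneg, bpos = classify_batch(net, X, n_steps)
            for k in range(40):
                assert (bneg[k], bpos[k]) == classify(net, X[k], n_steps)

    def test_compiled_circuit_matches_decoded_network(self, rng):
        """The array-form evaluator is exact against the reference path."""
        for _ in range(30):
            n_in, n_hid = int(rng.integers(1, 300)), int(rng.integers(0, 80))
            genome = mutate(
                random_genome(int(rng.integers(0, 25)), rng),
                MutationRates(0.05, 0.5, 0.5),
                rng,
            )
            X = rng.integers(0, 2, size=(20, n_in)).astype(np.uint8)
            ref = classify_batch(decode_genome(genome, n_in, n_hid), X, 1)
            fast = classify_batch(compile_circuit(genome, n_in, n_hid), X, 1)
            assert np.array_equal(ref[0], fast[0])
            assert np.array_equal(ref[1], fast[1])

    def test_multi_step_uses_hidden_state(self):
        # input -> hidden -> pos-primary needs two steps to propagate
        relay = GateSpec(1, 1, (0,), (1,), (0, 1))
        emit = GateSpec(1, 1, (1,), (1 + 1 + 2,), (0, 1))
        net = CircuitNetwork([relay, emit], 1, 1)
        assert classify(net, [1], n_steps=1) == (False, False)
        assert classify(net, [1], n_steps=2) == (False, True)


class TestUsedInputBits:
    def test_empty_network(self):
        assert used_input_bits(CircuitNetwork([], 10, 2)) == set()

    def test_single_gate(self):
        net = CircuitNetwork([GateSpec(2, 1, (3, 7), (10,), (0, 0, 0, 1))], 10, 2)
        assert used_input_bits(net) == {3, 7}

    def test_union_over_gates_and_hidden_reads_excluded(self):
        gates = [
            GateSpec(2, 1, (3, 7), (10,), (0, 1, 1, 0)),
            GateSpec(2, 1, (7, 9), (11,), (1, 1, 0, 0)),
            GateSpec(1, 1, (11,), (12,), (0, 1)),  # reads a hidden node
        ]
        assert used_input_bits(CircuitNetwork(gates, 10, 4)) == {3, 7, 9}


class TestMutate:
    def test_zero_rates_copy_parent(self, rng):
        parent = random_genome(10, rng)
        child = mutate(parent, MutationRates(0, 0, 0), rng)
        assert child == parent
        assert child.data is not parent.data

    def test_site_rate_one_resamples_every_byte(self):
        rng = np.random.default_rng(3)
        parent = random_genome(10, rng)
        child = mutate(parent, MutationRates(1.0, 0, 0), rng)
        assert len(child) == len(parent)
        # a uniform resample matches the old byte ~1/256 of the time
        assert (child.data != parent.data).mean() > 0.9

    def test_point_mutation_count_matches_binomial(self, rng):
        parent = random_genome(35, rng)  # ~1,000 bytes at one-byte addresses
        n_bytes = len(parent)
        rates = MutationRates(site_rate=0.001, dup_rate=0, del_rate=0)
        n_off = 10_000
        changed = sum(
            int((mutate(parent, rates, rng).data != parent.data).sum())
            for _ in range(n_off)
        )
        # a resampled byte equals the original w.p. 1/256
        expect = n_bytes * 0.001 * (255 / 256)
        sd = np.sqrt(n_bytes * 0.001 / n_off)  # ~Poisson spread of the mean
        assert abs(changed / n_off - expect) < 3 * sd

    def test_duplication_appends_one_gene_span(self, rng):
        parent = random_genome(5, rng)
        child = mutate(parent, MutationRates(0, 1.0, 0), rng)
        assert len(child) == len(parent) + gene_span()
        assert len(decode_genome(child, 10, 2).gates) == 6

    def test_deletion_removes_one_gene_span(self, rng):
        parent = random_genome(5, rng)
        child = mutate(parent, MutationRates(0, 0, 1.0), rng)
        assert len(child) == len(parent) - gene_span()
        assert len(decode_genome(child, 10, 2).gates) == 4

    def test_duplication_skipped_at_length_cap(self, rng):
        cap = 6 * gene_span() - 1
        parent = random_genome(5, rng, max_length=cap)
        child = mutate(parent, MutationRates(0, 1.0, 0), rng)
        assert len(child) == len(parent)

    @settings(max_examples=40, deadline=None)
    @given(st.integers(0, 2**32 - 1))
    def test_mutants_stay_valid(self, seed):
        rng = np.random.default_rng(seed)
        genome = random_genome(int(rng.integers(0, 20)), rng, max_length=600)
        rates = MutationRates(
            site_rate=float(rng.random()),
            dup_rate=float(rng.random()),
            del_rate=float(rng.random()),
        )
        for _ in range(5):
            genome = mutate(genome, rates, rng)
            assert len(genome) <= genome.max_length
            assert genome.data.dtype == np.uint8


class TestPersistence:
    def test_write_read_round_trip(self, tmp_path, rng):
        genomes = [random_genome(int(n), rng) for n in (0, 3, 7)]
        path = tmp_path / "committee.txt"
        write_genomes(path, genomes, {"n_inputs": 200, "encoding": "split4-2bit"})
        loaded, meta = read_genomes(path)
        assert loaded == genomes
        assert meta["n_inputs"] == "200"
        assert meta["encoding"] == "split4-2bit"
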