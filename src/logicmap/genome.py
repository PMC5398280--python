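"""Byte-string genomes and the deterministic logic-gate networks they encode.

A classifier here is a "Markov network" with deterministic probability
tables, i.e. a plain digital logic circuit.  The circuit is described by a
genome: a bounded string of bytes in which each *gene* encodes one logic
gate.  A gene is located by a two-byte start codon and then specifies, in a
fixed-width layout, the gate's arity, the state nodes it reads and writes,
and its full truth table.

State vector layout: ``[input nodes | hidden nodes | 4 output nodes]``.
The four output nodes are, in order, negative-primary, negative-veto,
positive-primary and positive-veto; a class is asserted when its primary
output is 1 and its veto output is 0, so a second output per class can
evolve to suppress over-eager "yes" answers.

Gene layout (``address_bytes = k``, default 1)::

    [42, 213,                      start codon
     n_in  (1 + byte mod 4),
     n_out (1 + byte mod 4),
     4*k bytes input addresses,    little-endian, only the first n_in used
     4*k bytes output addresses,   only the first n_out used
     16 bytes truth table]         row r -> byte[r] mod 2**n_out

Input addresses resolve modulo the state size; output addresses resolve
modulo (n_hidden + 4) and are offset past the input block, so gates can
never overwrite the clamped input sensors.  Bit order is most-significant
first: the first listed input is the high bit of the truth-table row index,
and the first listed output receives the high bit of the row's output
pattern.
"""

from __future__ import annotations

import dataclasses
from typing import Iterable, Sequence

import numpy as np

START_BYTES = (42, 213)
N_OUTPUT_NODES = 4
#: offsets of the four output roles within the output block
NEG_PRIMARY, NEG_VETO, POS_PRIMARY, POS_VETO = range(4)
DEFAULT_MAX_LENGTH = 40_000
MAX_ARITY = 4


def gene_body_size(address_bytes: int = 1) -> int:
    """Number of bytes in a gene body (everything after the start codon)."""
    return 2 + 2 * MAX_ARITY * address_bytes + 16


def gene_span(address_bytes: int = 1) -> int:
    """Total number of bytes a gene occupies, start codon included."""
    return 2 + gene_body_size(address_bytes)


@dataclasses.dataclass
class Genome:
    """A bounded byte string; the unit of mutation and inheritance.

    Parameters
    ----------
    data
        Sequence of integers, each in [0, 255].
    max_length
        Hard cap on genome length, enforced here and by every mutation.
    """

    data: np.ndarray
    max_length: int = DEFAULT_MAX_LENGTH

    def __post_init__(self) -> None:
        arr = np.asarray(self.data)
        if arr.ndim != 1:
            raise ValueError("genome data must be one-dimensional")
        if arr.size and (arr.min() < 0 or arr.max() > 255):
            raise ValueError("genome bytes must lie in [0, 255]")
        if arr.size > self.max_length:
            raise ValueError(
                f"genome length {arr.size} exceeds max_length {self.max_length}"
            )
        object.__setattr__(self, "data", arr.astype(np.uint8))

    def __len__(self) -> int:
        return int(self.data.size)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Genome):
            return NotImplemented
        return self.max_length == other.max_length and np.array_equal(
            self.data, other.data
        )

    def tobytes(self) -> bytes:
        return self.data.tobytes()

    def copy(self) -> "Genome":
        return Genome(self.data.copy(), self.max_length)


@dataclasses.dataclass(frozen=True)
class GateSpec:
    """One decoded logic gate.

    ``table[r]`` is the n_out-bit output pattern for row index ``r``; the
    first listed input is the most significant bit of ``r`` and the first
    listed output receives the most significant bit of ``table[r]``.
    """

    n_in: int
    n_out: int
    input_addrs: tuple[int, ...]
    output_addrs: tuple[int, ...]
    table: tuple[int, ...]

    def __post_init__(self) -> None:
        if not 1 <= self.n_in <= MAX_ARITY or not 1 <= self.n_out <= MAX_ARITY:
            raise ValueError("gate arity must be in [1, 4]")
        if len(self.input_addrs) != self.n_in or len(self.output_addrs) != self.n_out:
            raise ValueError("address count must match arity")
        if len(self.table) != 2**self.n_in:
            raise ValueError("truth table must have 2**n_in rows")
        if any(not 0 <= v < 2**self.n_out for v in self.table):
            raise ValueError("table entries must be n_out-bit patterns")


class CircuitNetwork:
    """A decoded gate network over ``n_inputs + n_hidden + 4`` state nodes.

    Execution is fully deterministic.  When several gates write into the
    same node in one step, the node receives the OR of all written values.
    """

    def __init__(self, gates: Sequence[GateSpec], n_inputs: int, n_hidden: int):
        self.gates = list(gates)
        self.n_inputs = int(n_inputs)
        self.n_hidden = int(n_hidden)
        self.n_outputs = N_OUTPUT_NODES
        for g in self.gates:
            if any(a >= self.state_size for a in g.input_addrs):
                raise ValueError("gate input address outside state vector")
            if any(
                not self.n_inputs <= a < self.state_size for a in g.output_addrs
            ):
                raise ValueError("gate output address must be a non-input node")
        self._fast: list[tuple] | None = None

    @property
    def state_size(self) -> int:
        return self.n_inputs + self.n_hidden + self.n_outputs

    @property
    def output_base(self) -> int:
        return self.n_inputs + self.n_hidden

    # -- single-step / single-example execution --------------------------

    def _compiled_output_gates(self) -> list[tuple]:
        """Per-gate arrays for the one-step batch path.

        Only gates that write at least one of the four output nodes can
        influence a single-step classification (hidden nodes start at 0 and
        are never read back), so the rest are skipped.
        """
        if self._fast is None:
            fast = []
            base = self.output_base
            for g in self.gates:
                writes = [
                    (g.n_out - 1 - j, a - base)
                    for j, a in enumerate(g.output_addrs)
                    if a >= base
                ]
                if not writes:
                    continue
                cols, weights = [], []
                for pos, a in enumerate(g.input_addrs):
                    if a < self.n_inputs:  # non-input reads are constant 0
                        cols.append(a)
                        weights.append(1 << (g.n_in - 1 - pos))
                fast.append(
                    (
                        np.asarray(cols, dtype=np.intp),
                        np.asarray(weights, dtype=np.int16),
                        np.asarray(g.table, dtype=np.int16),
                        writes,
                    )
                )
            self._fast = fast
        return self._fast


def decode_genome(
    genome: Genome,
    n_inputs: int,
    n_hidden: int,
    address_bytes: int = 1,
) -> CircuitNetwork:
    """Decode every gene found in ``genome`` into a :class:`CircuitNetwork`.

    Scanning moves left to right looking for the start codon; after a gene
    is parsed the scan resumes past its body, so codon-like byte pairs
    inside a gene body do not spawn spurious genes.  A codon too close to
    the end of the genome to fit a full body is ignored.  Zero genes is
    legal and yields a network that never asserts anything.
    """
    data = genome.data
    gates = []
    for start in gene_starts(data, address_bytes):
        gates.append(_decode_gate(data, start, n_inputs, n_hidden, address_bytes))
    return CircuitNetwork(gates, n_inputs, n_hidden)


def gene_starts(data: np.ndarray, address_bytes: int = 1) -> list[int]:
    """Offsets of every decodable gene's start codon, in genome order."""
    span = gene_span(address_bytes)
    if data.size < span:
        return []
    candidates = np.flatnonzero(
        (data[:-1] == START_BYTES[0]) & (data[1:] == START_BYTES[1])
    )
    starts: list[int] = []
    next_free = 0
    for c in candidates:
        if c < next_free:
            continue
        if c + span > data.size:
            break
        starts.append(int(c))
        next_free = int(c) + span
    return starts


def _read_addr(body: np.ndarray, offset: int, k: int) -> int:
    raw = 0
    for i in range(k):
        raw |= int(body[offset + i]) << (8 * i)
    return raw


def _decode_gate(
    data: np.ndarray, start: int, n_inputs: int, n_hidden: int, k: int
) -> GateSpec:
    body = data[start + 2 : start + 2 + gene_body_size(k)]
    n_in = 1 + int(body[0]) % MAX_ARITY
    n_out = 1 + int(body[1]) % MAX_ARITY
    state_size = n_inputs + n_hidden + N_OUTPUT_NODES
    in_off, out_off = 2, 2 + MAX_ARITY * k
    input_addrs = tuple(
        _read_addr(body, in_off + i * k, k) % state_size for i in range(n_in)
    )
    output_addrs = tuple(
        n_inputs + _read_addr(body, out_off + i * k, k) % (n_hidden + N_OUTPUT_NODES)
        for i in range(n_out)
    )
    table_off = 2 + 2 * MAX_ARITY * k
    table = tuple(
        int(body[table_off + r]) % (1 << n_out) for r in range(1 << n_in)
    )
    return GateSpec(n_in, n_out, input_addrs, output_addrs, table)


def encode_gates(
    gates: Iterable[GateSpec],
    n_inputs: int,
    n_hidden: int,
    address_bytes: int = 1,
    max_length: int = DEFAULT_MAX_LENGTH,
) -> Genome:
    """Synthesize a genome that decodes back to exactly ``gates``.

    The inverse of :func:`decode_genome` for well-formed specs; used to
    build hand-designed networks and in round-trip checks.
    """
    k = address_bytes
    state_size = n_inputs + n_hidden + N_OUTPUT_NODES
    out: list[int] = []
    for g in gates:
        body = [g.n_in - 1, g.n_out - 1]
        raws = []
        for a in g.input_addrs:
            if not 0 <= a < state_size:
                raise ValueError("input address outside state vector")
            raws.append(a)
        raws += [0] * (MAX_ARITY - g.n_in)
        for a in g.output_addrs:
            if not n_inputs <= a < state_size:
                raise ValueError("output address must be a non-input node")
            raws.append(a - n_inputs)
        raws += [0] * (MAX_ARITY - g.n_out)
        for raw in raws:
            if raw >= 256**k:
                raise ValueError(
                    f"address {raw} not representable with {k} address byte(s)"
                )
            body.extend((raw >> (8 * i)) & 0xFF for i in range(k))
        body.extend(list(g.table) + [0] * (16 - len(g.table)))
        out.extend(START_BYTES)
        out.extend(body)
    return Genome(np.asarray(out, dtype=np.uint8), max_length)


def random_genome(
    n_gates: int,
    rng: np.random.Generator,
    max_length: int = DEFAULT_MAX_LENGTH,
    address_bytes: int = 1,
) -> Genome:
    """A genome of ``n_gates`` genes with uniformly random gene bodies."""
    if n_gates < 0:
        raise ValueError("n_gates must be non-negative")
    span = gene_span(address_bytes)
    total = n_gates * span
    if total > max_length:
        raise ValueError(
            f"{n_gates} genes need {total} bytes, over the cap of {max_length}"
        )
    data = rng.integers(0, 256, size=total, dtype=np.uint8)
    data[0::span] = START_BYTES[0]
    data[1::span] = START_BYTES[1]
    return Genome(data, max_length)


# ---------------------------------------------------------------------------
# execution


def step_network(network: CircuitNetwork, state: Sequence[int]) -> np.ndarray:
    """Advance the state vector by one synchronous update.

    Every gate reads from the pre-step state.  A node written by one or
    more gates takes the OR of the written values; a node written by no
    gate carries its previous value (input nodes are re-clamped by the
    caller and are unwritable by construction).
    """
    state = np.asarray(state, dtype=np.uint8)
    if state.size != network.state_size:
        raise ValueError("state length must equal the network state size")
    acc = np.zeros(network.state_size, dtype=np.uint8)
    written = np.zeros(network.state_size, dtype=bool)
    for g in network.gates:
        r = 0
        for a in g.input_addrs:
            r = (r << 1) | int(state[a])
        v = g.table[r]
        for j, a in enumerate(g.output_addrs):
            acc[a] |= (v >> (g.n_out - 1 - j)) & 1
            written[a] = True
    new = state.copy()
    new[written] = acc[written]
    return new


def classify(
    network: CircuitNetwork, encoded_bits: Sequence[int], n_steps: int = 1
) -> tuple[bool, bool]:
    """Run the circuit on one encoded example.

    Hidden and output nodes start at 0; the input block is clamped to
    ``encoded_bits`` before every step.  Returns ``(neg_assert,
    pos_assert)`` where a class is asserted iff its primary output is 1
    and its veto output is 0.
    """
    bits = np.asarray(encoded_bits, dtype=np.uint8)
    if bits.size != network.n_inputs:
        raise ValueError("encoded example width must equal n_inputs")
    state = np.zeros(network.state_size, dtype=np.uint8)
    state[: network.n_inputs] = bits
    for _ in range(n_steps):
        state = step_network(network, state)
        state[: network.n_inputs] = bits
    out = state[network.output_base :]
    neg = bool(out[NEG_PRIMARY]) and not bool(out[NEG_VETO])
    pos = bool(out[POS_PRIMARY]) and not bool(out[POS_VETO])
    return neg, pos


def classify_batch(
    network: CircuitNetwork, X: np.ndarray, n_steps: int = 1
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized :func:`classify` over a matrix of encoded examples.

    ``X`` has shape (n_examples, n_inputs) with 0/1 entries.  Returns
    boolean arrays ``(neg_assert, pos_assert)``.  The single-step case
    (the default configuration) uses a reduced evaluation over only the
    gates wired into the output block; multi-step networks fall back to a
    full state-matrix simulation.  Both paths agree with the per-example
    scalar path.
    """
    X = np.ascontiguousarray(X, dtype=np.uint8)
    if X.ndim != 2 or X.shape[1] != network.n_inputs:
        raise ValueError("X must be (n_examples, n_inputs)")
    if isinstance(network, CompiledCircuit):
        if n_steps != 1:
            raise ValueError("a CompiledCircuit only supports single-step runs")
        return network.classify_batch(X)
    n = X.shape[0]
    if n_steps == 1:
        outs = np.zeros((N_OUTPUT_NODES, n), dtype=np.int16)
        for cols, weights, table, writes in network._compiled_output_gates():
            if cols.size:
                idx = X[:, cols].astype(np.int16) @ weights
            else:
                idx = np.zeros(n, dtype=np.int16)
            vals = table[idx]
            for shift, out_col in writes:
                outs[out_col] |= (vals >> shift) & 1
        neg = (outs[NEG_PRIMARY] == 1) & (outs[NEG_VETO] == 0)
        pos = (outs[POS_PRIMARY] == 1) & (outs[POS_VETO] == 0)
        return neg, pos

    state = np.zeros((n, network.state_size), dtype=np.uint8)
    state[:, : network.n_inputs] = X
    for _ in range(n_steps):
        acc = np.zeros_like(state)
        written = np.zeros(network.state_size, dtype=bool)
        for g in network.gates:
            idx = np.zeros(n, dtype=np.int16)
            for pos_, a in enumerate(g.input_addrs):
                idx |= state[:, a].astype(np.int16) << (g.n_in - 1 - pos_)
            vals = np.asarray(g.table, dtype=np.int16)[idx]
            for j, a in enumerate(g.output_addrs):
                acc[:, a] |= ((vals >> (g.n_out - 1 - j)) & 1).astype(np.uint8)
                written[a] = True
        state[:, written] = acc[:, written]
        state[:, : network.n_inputs] = X
    base = network.output_base
    neg = (state[:, base + NEG_PRIMARY] == 1) & (state[:, base + NEG_VETO] == 0)
    pos = (state[:, base + POS_PRIMARY] == 1) & (state[:, base + POS_VETO] == 0)
    return neg, pos


def used_input_bits(network: CircuitNetwork) -> set[int]:
    """Input-node indices wired into any gate's inputs (raw connectivity).

    No reachability pruning is applied: a network "recognizes" a bit as
    soon as some gate reads it, whether or not that gate can influence an
    output.
    """
    used: set[int] = set()
    for g in network.gates:
        for a in g.input_addrs:
            if a < network.n_inputs:
                used.add(int(a))
    return used


class CompiledCircuit:
    """Array-form single-step evaluator for one genome.

    Produced by :func:`compile_circuit` straight from genome bytes without
    building per-gate objects; used in the evolutionary hot loop.  Only
    gates wired into the four output nodes are kept, which is exact for
    single-step execution.  Agrees bit-for-bit with
    :func:`decode_genome` + :func:`classify_batch` (tested property).
    """

    __slots__ = ("n_inputs", "cols", "weights", "flat_tables", "writes")

    def __init__(self, n_inputs, cols, weights, flat_tables, writes):
        self.n_inputs = n_inputs
        self.cols = cols  # (A, 4) intp, col 0 with weight 0 when unused
        self.weights = weights  # (A, 4) int16, MSB-first, 0 past n_in
        self.flat_tables = flat_tables  # (A * 16,) int16
        self.writes = writes  # per output slot: (gate_rows, shifts)

    def classify_batch(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        n = X.shape[0]
        if self.cols.shape[0] == 0:
            zero = np.zeros(n, dtype=bool)
            return zero, zero
        gathered = X[:, self.cols]  # (N, A, 4) uint8
        idx = np.einsum("nak,ak->na", gathered, self.weights, dtype=np.int16)
        vals = self.flat_tables[idx + np.arange(idx.shape[1]) * 16]
        outs = []
        for rows, shifts in self.writes:
            if rows.size == 0:
                outs.append(np.zeros(n, dtype=bool))
            else:
                outs.append((((vals[:, rows] >> shifts) & 1) != 0).any(axis=1))
        neg = outs[NEG_PRIMARY] & ~outs[NEG_VETO]
        pos = outs[POS_PRIMARY] & ~outs[POS_VETO]
        return neg, pos


def compile_circuit(
    genome: Genome, n_inputs: int, n_hidden: int, address_bytes: int = 1
) -> CompiledCircuit:
    """Vectorized decode of a genome into a :class:`CompiledCircuit`."""
    data = genome.data
    k = address_bytes
    state_size = n_inputs + n_hidden + N_OUTPUT_NODES
    base = n_inputs + n_hidden
    starts = np.asarray(gene_starts(data, k), dtype=np.intp)
    empty = CompiledCircuit(
        n_inputs,
        np.empty((0, 4), dtype=np.intp),
        np.empty((0, 4), dtype=np.int16),
        np.empty(0, dtype=np.int16),
        [(np.empty(0, dtype=np.intp), np.empty(0, dtype=np.int16))] * 4,
    )
    if starts.size == 0:
        return empty
    body = data[starts[:, None] + np.arange(2, 2 + gene_body_size(k))].astype(
        np.int64
    )
    n_in = 1 + body[:, 0] % MAX_ARITY
    n_out = 1 + body[:, 1] % MAX_ARITY
    addr_w = (256 ** np.arange(k)).astype(np.int64)
    in_raw = (body[:, 2 : 2 + 4 * k].reshape(-1, 4, k) * addr_w).sum(2)
    out_raw = (body[:, 2 + 4 * k : 2 + 8 * k].reshape(-1, 4, k) * addr_w).sum(2)
    in_addr = in_raw % state_size
    out_addr = base - n_hidden + out_raw % (n_hidden + N_OUTPUT_NODES)

    # keep only gates writing at least one output node
    arity_mask = np.arange(4)[None, :] < n_out[:, None]
    hits = (out_addr >= base) & arity_mask
    keep = hits.any(axis=1)
    if not keep.any():
        return empty
    n_in, n_out = n_in[keep], n_out[keep]
    in_addr, out_addr, hits = in_addr[keep], out_addr[keep], hits[keep]
    body = body[keep]

    in_active = np.arange(4)[None, :] < n_in[:, None]
    cols = np.where(in_active & (in_addr < n_inputs), in_addr, 0).astype(np.intp)
    weights = np.where(
        in_active & (in_addr < n_inputs),
        1 << np.maximum(n_in[:, None] - 1 - np.arange(4)[None, :], 0),
        0,
    ).astype(np.int16)
    tables = (body[:, 2 + 8 * k : 18 + 8 * k] & ((1 << n_out) - 1)[:, None]).astype(
        np.int16
    )
    writes: list[tuple[np.ndarray, np.ndarray]] = []
    gate_rows, slot_pos = np.nonzero(hits)
    shifts_all = (n_out[gate_rows] - 1 - slot_pos).astype(np.int16)
    slots_all = out_addr[gate_rows, slot_pos] - base
    for s in range(N_OUTPUT_NODES):
        sel = slots_all == s
        writes.append((gate_rows[sel].astype(np.intp), shifts_all[sel]))
    return CompiledCircuit(n_inputs, cols, weights, tables.ravel(), writes)


# ---------------------------------------------------------------------------
# mutation


@dataclasses.dataclass(frozen=True)
class MutationRates:
    """Per-offspring mutation probabilities.

    site_rate is per byte; dup_rate / del_rate are per offspring and act
    on one uniformly chosen whole gene (codon plus body).
    """

    site_rate: float = 0.001
    dup_rate: float = 0.05
    del_rate: float = 0.05

    def __post_init__(self) -> None:
        for name in ("site_rate", "dup_rate", "del_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")


def mutate(
    genome: Genome,
    rates: MutationRates,
    rng: np.random.Generator,
    address_bytes: int = 1,
) -> Genome:
    """Produce a mutated offspring genome; the parent is left untouched.

    Point mutations replace each byte independently with a uniform random
    byte at ``site_rate``.  Then, with probability ``dup_rate``, one
    uniformly chosen gene span is copied and appended to the genome end —
    skipped entirely if the copy would exceed ``max_length`` (truncating
    would leave a corrupt half-gene).  Finally, with probability
    ``del_rate``, one uniformly chosen gene span is excised.
    """
    span = gene_span(address_bytes)
    data = genome.data.copy()
    if data.size and rates.site_rate > 0:
        mask = rng.random(data.size) < rates.site_rate
        n_hits = int(mask.sum())
        if n_hits:
            data[mask] = rng.integers(0, 256, size=n_hits, dtype=np.uint8)
    if rates.dup_rate > 0 and rng.random() < rates.dup_rate:
        starts = gene_starts(data, address_bytes)
        if starts:
            s = starts[int(rng.integers(len(starts)))]
            if data.size + span <= genome.max_length:
                data = np.concatenate([data, data[s : s + span]])
    if rates.del_rate > 0 and rng.random() < rates.del_rate:
        starts = gene_starts(data, address_bytes)
        if starts:
            s = starts[int(rng.integers(len(starts)))]
            data = np.concatenate([data[:s], data[s + span :]])
    return Genome(data, genome.max_length)


# ---------------------------------------------------------------------------
# plain-text persistence


def write_genomes(path, genomes: Sequence[Genome], meta: dict | None = None) -> None:
    """Write genomes one per line as space-separated decimal bytes.

    ``meta`` key/value pairs (e.g. n_inputs, n_hidden, encoding name) are
    stored as ``# key=value`` header lines.  An ordered file of genomes is
    the on-disk form of a committee.
    """
    with open(path, "w") as fh:
        for key, value in (meta or {}).items():
            fh.write(f"# {key}={value}\n")
        for g in genomes:
            fh.write(" ".join(str(int(b)) for b in g.data) + "\n")


def read_genomes(path, max_length: int = DEFAULT_MAX_LENGTH):
    """Read a genome file written by :func:`write_genomes`.

    Returns ``(genomes, meta)`` where meta maps header keys to strings.
    """
    genomes: list[Genome] = []
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" in body:
                    key, _, value = body.partition("=")
                    meta[key.strip()] = value.strip()
                continue
            # a blank (non-comment) line is a zero-length genome
            genomes.append(
                Genome(np.asarray([int(t) for t in line.split()], dtype=np.uint8),
                       max_length)
            )
    return genomes, meta
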