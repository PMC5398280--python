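"""Discretization of mixed binary/continuous features into circuit inputs.

Logic circuits take binary input, so every continuous feature is split
into a fixed number of equal-width bins fitted on the *training* range of
that feature; test values outside the training range fall into the lowest
or highest training bin.  Five encodings are supported, named after the
split and the bits spent per feature:

====================  =====  ==========  ================
name                  split  bits/feat.  width on 688 feat.
====================  =====  ==========  ================
``split4``              4        4             2,752
``split10``            10       10             6,880
``split16``            16       16            11,008
``split16-4bit``       16        4 (base-2)    2,752
``split4-2bit``         4        2 (base-2)    1,376
====================  =====  ==========  ================

Uncompressed encodings write the bin as a cumulative-unary (thermometer)
pattern — bin k sets the first k bits — which makes a binary feature's
all-zeros / all-ones representation the natural two-level special case.
A one-hot variant is available via ``EncodingScheme(style="onehot")``.
Compressed encodings write the bin index in base 2, most significant bit
first, so bin 0 is all zeros (ascending order).
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

VALID_SPLITS = (4, 10, 16)
SCHEME_NAMES = {
    "split4": (4, False),
    "split10": (10, False),
    "split16": (16, False),
    "split16-4bit": (16, True),
    "split4-2bit": (4, True),
}


@dataclasses.dataclass(frozen=True)
class FeatureMeta:
    """Per-column metadata: position, type, and fitted training range."""

    index: int
    is_binary: bool
    lo: float = 0.0
    hi: float = 1.0

    def __post_init__(self) -> None:
        if self.lo > self.hi:
            raise ValueError("feature range must satisfy lo <= hi")
        if self.is_binary and not ({self.lo, self.hi} <= {0.0, 1.0}):
            raise ValueError("binary feature range must lie in {0, 1}")


@dataclasses.dataclass(frozen=True)
class EncodingScheme:
    """A split count plus the bit layout used to express it."""

    split: int = 4
    compressed: bool = False
    style: str = "thermometer"  # or "onehot"; uncompressed encodings only

    def __post_init__(self) -> None:
        if self.split not in VALID_SPLITS:
            raise ValueError(f"split must be one of {VALID_SPLITS}")
        if self.compressed and (self.split & (self.split - 1)) != 0:
            raise ValueError("compressed encoding requires a power-of-two split")
        if self.style not in ("thermometer", "onehot"):
            raise ValueError("style must be 'thermometer' or 'onehot'")

    @property
    def bits_per_feature(self) -> int:
        if self.compressed:
            return int(self.split).bit_length() - 1
        return self.split

    @property
    def name(self) -> str:
        for name, (split, compressed) in SCHEME_NAMES.items():
            if (split, compressed) == (self.split, self.compressed):
                return name
        return f"split{self.split}"  # pragma: no cover


def scheme_from_name(name: str) -> EncodingScheme:
    """Look up one of the five named encodings (e.g. ``"split4-2bit"``)."""
    try:
        split, compressed = SCHEME_NAMES[name]
    except KeyError:
        raise ValueError(
            f"unknown scheme {name!r}; choose from {sorted(SCHEME_NAMES)}"
        ) from None
    return EncodingScheme(split=split, compressed=compressed)


def output_width(scheme: EncodingScheme, n_features: int) -> int:
    """Total circuit input width: bits per feature times feature count."""
    return scheme.bits_per_feature * n_features


def infer_metas(X: np.ndarray) -> list[FeatureMeta]:
    """Derive FeatureMeta per column, marking {0,1}-valued columns binary."""
    X = np.asarray(X, dtype=float)
    metas = []
    for j in range(X.shape[1]):
        col = X[:, j]
        is_binary = bool(np.isin(col, (0.0, 1.0)).all())
        metas.append(FeatureMeta(j, is_binary, float(col.min()), float(col.max())))
    return metas


@dataclasses.dataclass
class FittedEncoder:
    """An encoding scheme bound to per-feature training ranges."""

    scheme: EncodingScheme
    metas: list[FeatureMeta]

    @property
    def n_features(self) -> int:
        return len(self.metas)

    @property
    def width(self) -> int:
        return output_width(self.scheme, self.n_features)

    def edges(self, index: int) -> np.ndarray:
        """The split+1 equal-width bin boundaries of one continuous feature."""
        m = self.metas[index]
        return np.linspace(m.lo, m.hi, self.scheme.split + 1)


def fit_encoder(
    X: np.ndarray,
    metas: Sequence[FeatureMeta] | None = None,
    scheme: EncodingScheme | str = "split4-2bit",
) -> FittedEncoder:
    """Fit bin ranges on a training feature matrix.

    Ranges (lo/hi) are always recomputed from ``X``; supplied ``metas``
    only contribute the binary/continuous flag.  A constant column is
    degenerate: it always encodes as bin 0 (all-zero bits).
    """
    if isinstance(scheme, str):
        scheme = scheme_from_name(scheme)
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("training features must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("training features contain non-finite values")
    if metas is None:
        metas = infer_metas(X)
    if len(metas) != X.shape[1]:
        raise ValueError("metas length must match feature count")
    fitted = [
        FeatureMeta(j, m.is_binary, float(X[:, j].min()), float(X[:, j].max()))
        for j, m in enumerate(metas)
    ]
    return FittedEncoder(scheme, fitted)


def bin_index(value: float, meta: FeatureMeta, split: int) -> int:
    """Equal-width bin of ``value`` over the fitted range, clamped.

    Bins are half-open ``[e_k, e_{k+1})`` with the last bin closed at the
    top; out-of-range values use the lowest/highest training bin.
    """
    if meta.hi <= meta.lo:
        return 0
    k = int(np.floor((value - meta.lo) / (meta.hi - meta.lo) * split))
    return min(max(k, 0), split - 1)


def _pattern_table(scheme: EncodingScheme) -> np.ndarray:
    """(split, bits_per_feature) 0/1 array mapping bin index -> bit pattern."""
    split, bpf = scheme.split, scheme.bits_per_feature
    table = np.zeros((split, bpf), dtype=np.uint8)
    for k in range(split):
        if scheme.compressed:
            for i in range(bpf):
                table[k, i] = (k >> (bpf - 1 - i)) & 1
        elif scheme.style == "thermometer":
            table[k, :k] = 1
        else:  # onehot
            table[k, k] = 1
    return table


def encode_example(features: Sequence[float], encoder: FittedEncoder) -> np.ndarray:
    """Encode one raw feature vector into a 0/1 input-bit vector."""
    features = np.asarray(features, dtype=float)
    if features.size != encoder.n_features:
        raise ValueError(
            f"expected {encoder.n_features} features, got {features.size}"
        )
    return encode_matrix(features[None, :], encoder)[0]


def encode_matrix(X: np.ndarray, encoder: FittedEncoder) -> np.ndarray:
    """Encode a feature matrix into a (n_examples, width) uint8 bit matrix.

    Binary features emit all-ones for value 1 and all-zeros otherwise,
    keeping every feature the same width as a continuous one.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != encoder.n_features:
        raise ValueError("X must be (n_examples, n_features)")
    scheme = encoder.scheme
    bpf = scheme.bits_per_feature
    table = _pattern_table(scheme)
    out = np.empty((X.shape[0], encoder.width), dtype=np.uint8)
    for j, m in enumerate(encoder.metas):
        block = slice(j * bpf, (j + 1) * bpf)
        if m.is_binary:
            out[:, block] = (X[:, j] == 1.0).astype(np.uint8)[:, None]
        elif m.hi <= m.lo:
            out[:, block] = 0
        else:
            k = np.floor((X[:, j] - m.lo) / (m.hi - m.lo) * scheme.split)
            k = np.clip(k, 0, scheme.split - 1).astype(np.intp)
            out[:, block] = table[k]
    return out


def decode_bits(bits: Sequence[int], encoder: FittedEncoder) -> np.ndarray:
    """Recover per-feature bin indices from an encoded bit vector.

    The exact inverse of the bin->bits mapping; used in round-trip checks.
    For binary features the recovered "bin" is the feature value (0 or 1).
    """
    bits = np.asarray(bits, dtype=np.uint8)
    scheme = encoder.scheme
    bpf = scheme.bits_per_feature
    if bits.size != encoder.width:
        raise ValueError("bit vector width mismatch")
    bins = np.empty(encoder.n_features, dtype=int)
    for j, m in enumerate(encoder.metas):
        block = bits[j * bpf : (j + 1) * bpf]
        if m.is_binary:
            bins[j] = int(block[0])
        elif scheme.compressed:
            v = 0
            for b in block:
                v = (v << 1) | int(b)
            bins[j] = v
        elif scheme.style == "thermometer":
            bins[j] = int(block.sum())
        else:
            nz = np.flatnonzero(block)
            bins[j] = int(nz[0]) if nz.size else 0
    return bins


# ---------------------------------------------------------------------------
# persistence


def save_encoder(encoder: FittedEncoder, path) -> None:
    """Plain-text encoder file: a scheme header plus one line per feature."""
    with open(path, "w") as fh:
        fh.write(
            f"# scheme split={encoder.scheme.split} "
            f"compressed={int(encoder.scheme.compressed)} "
            f"style={encoder.scheme.style}\n"
        )
        fh.write("# index is_binary lo hi\n")
        for m in encoder.metas:
            fh.write(f"{m.index} {int(m.is_binary)} {m.lo!r} {m.hi!r}\n")


def load_encoder(path) -> FittedEncoder:
    scheme = None
    metas: list[FeatureMeta] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("# scheme"):
                kv = dict(tok.split("=") for tok in line.split()[2:])
                scheme = EncodingScheme(
                    split=int(kv["split"]),
                    compressed=bool(int(kv["compressed"])),
                    style=kv.get("style", "thermometer"),
                )
            elif line.startswith("#"):
                continue
            else:
                idx, isbin, lo, hi = line.split()
                metas.append(
                    FeatureMeta(int(idx), bool(int(isbin)), float(lo), float(hi))
                )
    if scheme is None:
        raise ValueError("encoder file is missing its scheme header")
    return FittedEncoder(scheme, metas)
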