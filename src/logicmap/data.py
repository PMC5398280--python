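"""Labeled contact-pair datasets: text I/O, synthesis, and train schedules.

An example is one candidate residue pair (i, j) from one protein, with a
binary contact label (alpha-carbon distance under 8 angstroms), a sequence
separation |j - i| >= 6, and a numeric feature vector (688 features in the
SVMcon layout this package was designed around, but any width works).

Two plain-text dialects are supported, both gzip-transparent:

dense
    one example per line: ``label protein_id res_i res_j f_1 ... f_F``
sparse
    ``label idx:value ... # protein_id res_i res_j`` with absent indices
    equal to zero; the feature count comes from a ``# F=<n>`` header or
    the ``n_features`` argument.

The synthetic generator stands in for the real feature data: it plants a
chosen set of class-informative features (class-shifted normals for
continuous columns, class-dependent Bernoullis for binary ones) among
class-independent noise columns, at a configurable positive-contact
prevalence, grouped into proteins with realistic separation annotations.
"""

from __future__ import annotations

import dataclasses
import gzip
from typing import Iterator, Sequence

import numpy as np

from .encoding import FeatureMeta

MIN_SEPARATION = 6  # dataset inclusion rule

# SVMcon-style training/testing set compositions, used as defaults for
# prevalence-matched synthesis: 94,110 of 267,702 training pairs positive,
# 10,498 of 377,797 testing pairs positive.
TRAIN_POSITIVE_RATE = 94_110 / 267_702
TEST_POSITIVE_RATE = 10_498 / 377_797


@dataclasses.dataclass(frozen=True)
class PairExample:
    """One labeled residue pair."""

    label: int
    protein_id: str
    res_i: int
    res_j: int
    features: np.ndarray

    @property
    def separation(self) -> int:
        return abs(self.res_j - self.res_i)


class PairDataset:
    """Column-oriented container for contact-pair examples.

    Stored as parallel arrays (labels, ids, residue indices, and an
    (N, F) feature matrix) for fast slicing and encoding; iterate to get
    :class:`PairExample` views.
    """

    def __init__(
        self,
        labels: Sequence[int],
        protein_ids: Sequence[str],
        res_i: Sequence[int],
        res_j: Sequence[int],
        features: np.ndarray,
        feature_metas: list[FeatureMeta] | None = None,
    ):
        self.labels = np.asarray(labels, dtype=np.int8)
        self.protein_ids = np.asarray(protein_ids, dtype=object)
        self.res_i = np.asarray(res_i, dtype=np.int64)
        self.res_j = np.asarray(res_j, dtype=np.int64)
        self.features = np.asarray(features, dtype=float)
        n = self.labels.size
        if self.features.ndim != 2 or self.features.shape[0] != n:
            raise ValueError("features must be an (n_examples, F) matrix")
        if not (self.protein_ids.size == self.res_i.size == self.res_j.size == n):
            raise ValueError("column lengths disagree")
        self.feature_metas = feature_metas

    def __len__(self) -> int:
        return int(self.labels.size)

    @property
    def n_features(self) -> int:
        return int(self.features.shape[1])

    @property
    def separations(self) -> np.ndarray:
        return np.abs(self.res_j - self.res_i)

    def __iter__(self) -> Iterator[PairExample]:
        for k in range(len(self)):
            yield PairExample(
                int(self.labels[k]),
                str(self.protein_ids[k]),
                int(self.res_i[k]),
                int(self.res_j[k]),
                self.features[k],
            )

    def subset(self, indices) -> "PairDataset":
        indices = np.asarray(indices)
        return PairDataset(
            self.labels[indices],
            self.protein_ids[indices],
            self.res_i[indices],
            self.res_j[indices],
            self.features[indices],
            self.feature_metas,
        )


def positive_fraction(dataset: PairDataset) -> float:
    """Fraction of examples labeled as contacts."""
    if len(dataset) == 0:
        raise ValueError("positive fraction of an empty dataset is undefined")
    return float((dataset.labels == 1).mean())


# ---------------------------------------------------------------------------
# text I/O


def _open_text(path, mode: str):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, mode + "t")
    return open(path, mode)


class DatasetFormatError(ValueError):
    """A malformed dataset line, reported with its 1-based line number."""

    def __init__(self, lineno: int, message: str):
        super().__init__(f"line {lineno}: {message}")
        self.lineno = lineno


def read_dataset(path, fmt: str = "dense", n_features: int | None = None) -> PairDataset:
    """Read a labeled contact-pair file in the dense or sparse dialect."""
    if fmt not in ("dense", "sparse"):
        raise ValueError("format must be 'dense' or 'sparse'")
    labels, pids, ris, rjs, rows = [], [], [], [], []
    header_f = n_features
    with _open_text(path, "r") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if body.startswith("F="):
                    header_f = int(body[2:])
                continue
            if fmt == "dense":
                lab, pid, ri, rj, feats = _parse_dense(line, lineno, header_f)
            else:
                lab, pid, ri, rj, feats = _parse_sparse(line, lineno, header_f)
                header_f = feats.size
            labels.append(lab)
            pids.append(pid)
            ris.append(ri)
            rjs.append(rj)
            rows.append(feats)
    if not rows:
        return PairDataset([], [], [], [], np.empty((0, header_f or 0)))
    features = np.vstack(rows)
    return PairDataset(labels, pids, ris, rjs, features)


def _parse_dense(line: str, lineno: int, n_features: int | None):
    toks = line.split()
    if len(toks) < 5:
        raise DatasetFormatError(lineno, "dense line needs label, id, i, j, features")
    try:
        lab = int(toks[0])
        ri, rj = int(toks[2]), int(toks[3])
        feats = np.asarray([float(t) for t in toks[4:]])
    except ValueError as exc:
        raise DatasetFormatError(lineno, f"non-numeric token ({exc})") from None
    if n_features is not None and feats.size != n_features:
        raise DatasetFormatError(
            lineno, f"expected {n_features} feature columns, found {feats.size}"
        )
    return lab, toks[1], ri, rj, feats


def _parse_sparse(line: str, lineno: int, n_features: int | None):
    body, _, comment = line.partition("#")
    toks = body.split()
    if not toks:
        raise DatasetFormatError(lineno, "sparse line is empty")
    if n_features is None:
        raise DatasetFormatError(
            lineno, "sparse dialect needs n_features (argument or '# F=' header)"
        )
    try:
        lab = int(toks[0])
    except ValueError:
        raise DatasetFormatError(lineno, f"bad label {toks[0]!r}") from None
    feats = np.zeros(n_features)
    seen: set[int] = set()
    for tok in toks[1:]:
        idx_s, colon, val_s = tok.partition(":")
        if not colon:
            raise DatasetFormatError(lineno, f"expected index:value, got {tok!r}")
        try:
            idx, val = int(idx_s), float(val_s)
        except ValueError:
            raise DatasetFormatError(lineno, f"non-numeric token {tok!r}") from None
        if idx in seen:
            raise DatasetFormatError(lineno, f"duplicate sparse index {idx}")
        if not 0 <= idx < n_features:
            raise DatasetFormatError(lineno, f"index {idx} out of range")
        seen.add(idx)
        feats[idx] = val
    ctoks = comment.split()
    pid = ctoks[0] if ctoks else "NA"
    ri = int(ctoks[1]) if len(ctoks) > 1 else 0
    rj = int(ctoks[2]) if len(ctoks) > 2 else 0
    return lab, pid, ri, rj, feats


def write_dataset(dataset: PairDataset, path, fmt: str = "dense") -> None:
    """Write a dataset in the chosen dialect (gzip if path ends in .gz)."""
    if fmt not in ("dense", "sparse"):
        raise ValueError("format must be 'dense' or 'sparse'")
    with _open_text(path, "w") as fh:
        fh.write(f"# F={dataset.n_features}\n")
        for ex in dataset:
            if fmt == "dense":
                feats = " ".join(repr(float(v)) for v in ex.features)
                fh.write(f"{ex.label} {ex.protein_id} {ex.res_i} {ex.res_j} {feats}\n")
            else:
                nz = np.flatnonzero(ex.features)
                toks = " ".join(f"{k}:{float(ex.features[k])!r}" for k in nz)
                fh.write(
                    f"{ex.label} {toks} # {ex.protein_id} {ex.res_i} {ex.res_j}\n"
                )


# ---------------------------------------------------------------------------
# synthesis


def generate_synthetic(
    n_proteins: int,
    pairs_per_protein: int,
    n_features: int = 688,
    n_binary: int = 145,
    informative: Sequence[tuple[int, float]] = (),
    positive_rate: float = TRAIN_POSITIVE_RATE,
    seed: int | np.random.Generator = 0,
) -> PairDataset:
    """Synthesize a labeled contact-pair dataset with planted structure.

    Layout: the first ``n_binary`` columns are binary, the rest continuous.
    Labels are Bernoulli(``positive_rate``).  For an informative continuous
    column with effect ``e``, positives are drawn N(e, 1) and negatives
    N(0, 1); for an informative binary column, P(1 | pos) = 0.5 + e/2 and
    P(1 | neg) = 0.5 - e/2 (e in [0, 1]).  All other columns are
    class-independent: N(0, 1) or Bernoulli(0.5).

    Separations mix 70% Uniform{6..24} with 30% Uniform{25..150} so the
    short/medium/long evaluation bands are all populated; a separation is
    shortened when a protein is too short to hold it.
    """
    if not 0 <= n_binary <= n_features:
        raise ValueError("need 0 <= n_binary <= n_features")
    if not 0.0 <= positive_rate <= 1.0:
        raise ValueError("positive_rate must be in [0, 1]")
    effects = dict(informative)
    if any(not np.isfinite(e) for e in effects.values()):
        raise ValueError("informative effects must be finite")
    if any(not 0 <= f < n_features for f in effects):
        raise ValueError("informative feature index out of range")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n = n_proteins * pairs_per_protein
    labels = (rng.random(n) < positive_rate).astype(np.int8)
    X = np.empty((n, n_features))
    for j in range(n_features):
        e = effects.get(j, 0.0)
        if j < n_binary:
            p = np.where(labels == 1, np.clip(0.5 + e / 2, 0, 1),
                         np.clip(0.5 - e / 2, 0, 1))
            X[:, j] = (rng.random(n) < p).astype(float)
        else:
            X[:, j] = rng.normal(0.0, 1.0, size=n) + e * labels

    lengths = rng.integers(100, 200, size=n_proteins, endpoint=True)
    pids = np.repeat([f"SYN{k:04d}" for k in range(n_proteins)], pairs_per_protein)
    plens = np.repeat(lengths, pairs_per_protein)
    short = rng.random(n) < 0.7
    seps = np.where(
        short,
        rng.integers(6, 24, size=n, endpoint=True),
        rng.integers(25, 150, size=n, endpoint=True),
    )
    seps = np.minimum(seps, plens - 2)
    res_i = 1 + rng.integers(0, np.maximum(plens - seps, 1))
    res_j = res_i + seps

    metas = [
        FeatureMeta(j, j < n_binary,
                    float(X[:, j].min()), float(X[:, j].max()))
        for j in range(n_features)
    ]
    return PairDataset(labels, pids, res_i, res_j, X, metas)


# ---------------------------------------------------------------------------
# rotating training subsets


@dataclasses.dataclass
class TrainingSchedule:
    """Disjoint training chunks with their update switch-points.

    Chunk k is active during updates ``[k * rotate_every,
    (k+1) * rotate_every)``; the final chunk stays active through any
    remaining updates.
    """

    chunks: list[np.ndarray]
    rotate_every: int

    @property
    def switch_points(self) -> list[int]:
        return [k * self.rotate_every for k in range(1, len(self.chunks))]

    def chunk_id(self, update: int) -> int:
        return min(update // self.rotate_every, len(self.chunks) - 1)

    def chunk_for_update(self, update: int) -> np.ndarray:
        return self.chunks[self.chunk_id(update)]

    @property
    def n_examples(self) -> int:
        return sum(c.size for c in self.chunks)


def training_schedule(
    dataset: PairDataset,
    chunk_size: int = 50_000,
    rotate_every: int = 25_000,
    total_updates: int = 100_000,
) -> TrainingSchedule:
    """Partition a dataset prefix into rotating training chunks.

    With the full-scale defaults (chunks of 50,000 rotated every 25,000
    updates across 100,000 updates) this yields four disjoint chunks and
    200,000 training examples in total.
    """
    if chunk_size <= 0 or rotate_every <= 0 or total_updates < 0:
        raise ValueError("chunk_size and rotate_every must be positive")
    n_chunks = max(1, -(-max(total_updates, 1) // rotate_every))
    if n_chunks * chunk_size > len(dataset):
        raise ValueError(
            f"need {n_chunks} disjoint chunks of {chunk_size} examples but the "
            f"dataset has only {len(dataset)}"
        )
    chunks = [
        np.arange(k * chunk_size, (k + 1) * chunk_size) for k in range(n_chunks)
    ]
    return TrainingSchedule(chunks, rotate_every)


# ---------------------------------------------------------------------------
# the SVMcon feature layout (for width arithmetic and grouping reports)

#: window geometry: two size-9 windows around the pair plus a size-5
#: central segment = 23 positions; each carries entropy (1), secondary
#: structure (3), solvent accessibility (2) and a 21-symbol profile.
WINDOW_POSITIONS = 9 + 9 + 5
PER_POSITION_FEATURES = {"entropy": 1, "secondary_structure": 3,
                         "solvent_accessibility": 2, "profile": 21}


def svmcon_feature_groups() -> dict[str, tuple[int, bool]]:
    """The 688-feature SVMcon layout as ``group -> (count, is_binary)``.

    Window-position groups are derived from the geometry constants above;
    the remainder are the pairwise/global groups of the original layout.
    """
    per_pos = PER_POSITION_FEATURES
    groups: dict[str, tuple[int, bool]] = {
        "cosine_similarity": (1, False),
        "correlation": (1, False),
        "mutual_information": (1, False),
        "amino_acid_types": (10, True),
        "levitt_potential": (1, False),
        "jernigan_potential": (1, False),
        "braun_potential": (1, False),
        "window_profiles": (WINDOW_POSITIONS * per_pos["profile"], False),
        "window_entropy": (WINDOW_POSITIONS * per_pos["entropy"], False),
        "window_solvent_accessibility": (
            WINDOW_POSITIONS * per_pos["solvent_accessibility"], True),
        "window_secondary_structure": (
            WINDOW_POSITIONS * per_pos["secondary_structure"], True),
        "central_aa_composition": (21, False),
        "central_ss_composition": (3, False),
        "central_sa_composition": (2, False),
        "sequence_separation_bins": (16, True),
        "protein_ss_composition": (3, False),
        "protein_length_bins": (4, True),
        "protein_sa_composition": (2, False),
    }
    return groups


def window_feature_count() -> int:
    """Features tied to window positions: 23 positions x 27 features."""
    return WINDOW_POSITIONS * sum(PER_POSITION_FEATURES.values())


def profile_feature_count() -> int:
    """Alignment-profile features: 23 positions x 21 profile symbols."""
    return WINDOW_POSITIONS * PER_POSITION_FEATURES["profile"]


def total_feature_count() -> int:
    return sum(count for count, _ in svmcon_feature_groups().values())
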