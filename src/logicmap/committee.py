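"""Committee voting, confidence-ranked selection, and evaluation metrics.

A committee is the set of best-evolved circuits, one per independent run
(60 in the full-scale protocol).  Individual circuits answer only yes/no,
so confidence is emulated by the positive vote count: for each example
the positive votes are compared with the negative votes and the larger
sum wins (exact ties are broken uniformly at random).  A member asserting
both channels contributes one vote to each sum; a member asserting
neither contributes nothing.

Evaluation follows the contact-prediction convention in which
*specificity* is precision on the positive class, TP / (TP + FP),
*sensitivity* is recall, TP / P, and the combined score is

    Fmax = specificity * sensitivity / (specificity + sensitivity),

whose maximum is 0.5 (reached only at specificity = sensitivity = 1).
Negative contacts do not enter these measures.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Sequence

import numpy as np

from .data import PairDataset
from .encoding import FittedEncoder, encode_matrix
from .genome import CircuitNetwork, classify_batch

SEPARATION_BANDS = (">=6", ">=12", ">=24", "[6,12]", "(12,24]", ">24")


class Committee:
    """An ordered ensemble of decoded circuits sharing one input width."""

    def __init__(
        self,
        members: Sequence[CircuitNetwork],
        encoder: FittedEncoder | None = None,
        n_steps: int = 1,
    ):
        if not members:
            raise ValueError("a committee needs at least one member")
        widths = {m.n_inputs for m in members}
        if len(widths) != 1:
            raise ValueError("committee members must share one input width")
        if encoder is not None and encoder.width not in widths:
            raise ValueError("encoder width does not match committee members")
        self.members = list(members)
        self.encoder = encoder
        self.n_steps = n_steps

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def input_width(self) -> int:
        return self.members[0].n_inputs

    def vote_batch(self, X_bits: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Per-example (pos_votes, neg_votes) summed over all members."""
        n = X_bits.shape[0]
        pos_votes = np.zeros(n, dtype=np.int32)
        neg_votes = np.zeros(n, dtype=np.int32)
        for member in self.members:
            neg, pos = classify_batch(member, X_bits, self.n_steps)
            pos_votes += pos
            neg_votes += neg
        return pos_votes, neg_votes


@dataclasses.dataclass
class Prediction:
    """One committee decision on one pair, with its vote tallies."""

    protein_id: str
    res_i: int
    res_j: int
    separation: int
    pos_votes: int
    neg_votes: int
    answer: int  # 1 = positive contact, 0 = negative
    label: int | None = None


def committee_vote(
    committee: Committee, encoded_bits: np.ndarray, rng: np.random.Generator
) -> tuple[int, int, int]:
    """Vote on one encoded example: ``(pos_votes, neg_votes, answer)``."""
    bits = np.asarray(encoded_bits, dtype=np.uint8)[None, :]
    pos_votes, neg_votes = committee.vote_batch(bits)
    pv, nv = int(pos_votes[0]), int(neg_votes[0])
    if pv > nv:
        answer = 1
    elif nv > pv:
        answer = 0
    else:
        answer = int(rng.integers(2))
    return pv, nv, answer


def predict_dataset(
    committee: Committee,
    dataset: PairDataset,
    rng: np.random.Generator,
    encoder: FittedEncoder | None = None,
) -> list[Prediction]:
    """Committee predictions for every example of a dataset."""
    encoder = encoder or committee.encoder
    if encoder is None:
        raise ValueError("an encoder is required to encode raw examples")
    X = encode_matrix(dataset.features, encoder)
    pos_votes, neg_votes = committee.vote_batch(X)
    answers = np.where(
        pos_votes > neg_votes,
        1,
        np.where(neg_votes > pos_votes, 0, rng.integers(2, size=len(dataset))),
    )
    seps = dataset.separations
    return [
        Prediction(
            str(dataset.protein_ids[k]),
            int(dataset.res_i[k]),
            int(dataset.res_j[k]),
            int(seps[k]),
            int(pos_votes[k]),
            int(neg_votes[k]),
            int(answers[k]),
            int(dataset.labels[k]),
        )
        for k in range(len(dataset))
    ]


# ---------------------------------------------------------------------------
# metrics


def fmax_score(specificity: float, sensitivity: float) -> float:
    """spec * sens / (spec + sens), with 0/0 defined as 0."""
    denom = specificity + sensitivity
    if denom == 0:
        return 0.0
    return specificity * sensitivity / denom


@dataclasses.dataclass(frozen=True)
class EvaluationReport:
    """Confusion counts with precision-style specificity and Fmax."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def specificity(self) -> float:
        predicted_pos = self.TP + self.FP
        return self.TP / predicted_pos if predicted_pos else 0.0

    @property
    def sensitivity(self) -> float:
        positives = self.TP + self.FN
        return self.TP / positives if positives else 0.0

    @property
    def fmax(self) -> float:
        return fmax_score(self.specificity, self.sensitivity)


def evaluate(
    predictions: Sequence[Prediction] | Sequence[int],
    labels: Sequence[int] | None = None,
) -> EvaluationReport:
    """Confusion counts for a prediction set.

    Accepts either :class:`Prediction` objects (labels taken from the
    objects when ``labels`` is omitted) or raw 0/1 answers plus a label
    sequence of the same length.
    """
    if predictions and isinstance(predictions[0], Prediction):
        answers = np.array([p.answer for p in predictions])
        if labels is None:
            if any(p.label is None for p in predictions):
                raise ValueError("predictions carry no labels; pass labels=")
            labels = np.array([p.label for p in predictions])
    else:
        answers = np.asarray(predictions, dtype=int)
    if labels is None:
        raise ValueError("labels are required")
    labels = np.asarray(labels, dtype=int)
    if answers.size != labels.size:
        raise ValueError("predictions and labels are misaligned")
    tp = int(((answers == 1) & (labels == 1)).sum())
    fp = int(((answers == 1) & (labels == 0)).sum())
    tn = int(((answers == 0) & (labels == 0)).sum())
    fn = int(((answers == 0) & (labels == 1)).sum())
    return EvaluationReport(tp, fp, tn, fn)


def random_baseline_fmax(n_pos: int, n_neg: int, guess_rate: float) -> float:
    """Expected Fmax of label-blind random guessing.

    Guessing positive with probability ``guess_rate`` independently of
    the label gives expected specificity equal to the positive prevalence
    n_pos / (n_pos + n_neg) and expected sensitivity equal to the guess
    rate; the two are combined with the Fmax formula.  On the reference
    testing composition (10,498 positives of 377,797) this is 0.026 at
    guess rates 0.5 and 0.35155 alike.
    """
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("both classes must be present")
    if not 0.0 < guess_rate <= 1.0:
        raise ValueError("guess_rate must be in (0, 1]")
    prevalence = n_pos / (n_pos + n_neg)
    return fmax_score(prevalence, guess_rate)


# ---------------------------------------------------------------------------
# confidence-ranked selection


def _resolve_cutoff_ties(
    ranked: list[Prediction], count: int, rng: np.random.Generator
) -> list[Prediction]:
    """Take the top ``count`` of a vote-sorted list, sampling cutoff ties."""
    if count <= 0:
        return []
    if len(ranked) <= count:
        return list(ranked)
    cut = ranked[count - 1].pos_votes
    above = [p for p in ranked if p.pos_votes > cut]
    tied = [p for p in ranked if p.pos_votes == cut]
    chosen = rng.choice(len(tied), size=count - len(above), replace=False)
    return above + [tied[i] for i in sorted(chosen)]


def top_L_select(
    predictions: Sequence[Prediction], L: int, rng: np.random.Generator
) -> list[Prediction]:
    """Top-L highest-confidence positive guesses for one protein.

    Only majority-positive predictions qualify; they are ordered by the
    positive vote count and the top L kept.  A tie straddling the cutoff
    is resolved by uniform random sampling among the tied items so that
    exactly L are returned; fewer than L qualifiers are returned as-is.
    """
    if L < 0:
        raise ValueError("L must be non-negative")
    qualified = [p for p in predictions if p.answer == 1]
    ranked = sorted(qualified, key=lambda p: -p.pos_votes)
    return _resolve_cutoff_ties(ranked, L, rng)


def top_fraction_select(
    predictions: Sequence[Prediction],
    protein_length: int,
    fraction: float,
    rng: np.random.Generator,
) -> list[Prediction]:
    """Top floor(L * fraction) guesses for one target of length L.

    Follows the CASP-style protocol of a fixed guess quota per target
    (L/2, L/5, L/10): *all* predictions are ranked by positive votes —
    not just majority-positive ones — because the quota must be filled
    even when majority-positive predictions are scarce.
    """
    if protein_length < 0:
        raise ValueError("protein_length must be non-negative")
    count = int(math.floor(protein_length * fraction))
    ranked = sorted(predictions, key=lambda p: -p.pos_votes)
    return _resolve_cutoff_ties(ranked, count, rng)


def filter_separation(items, band: str):
    """Restrict a dataset or prediction list to one separation band.

    Bands follow interval notation exactly: ``">=6"``, ``">=12"``,
    ``">=24"``, short ``"[6,12]"``, medium ``"(12,24]"`` and long
    ``">24"``; the last three partition all separations >= 6.
    """
    predicates = {
        ">=6": lambda s: s >= 6,
        ">=12": lambda s: s >= 12,
        ">=24": lambda s: s >= 24,
        "[6,12]": lambda s: (s >= 6) & (s <= 12),
        "(12,24]": lambda s: (s > 12) & (s <= 24),
        ">24": lambda s: s > 24,
    }
    if band not in predicates:
        raise ValueError(f"unknown separation band {band!r}; use {SEPARATION_BANDS}")
    pred = predicates[band]
    if isinstance(items, PairDataset):
        return items.subset(np.flatnonzero(pred(items.separations)))
    return [p for p in items if pred(p.separation)]


# ---------------------------------------------------------------------------
# prediction files


def write_predictions(predictions: Sequence[Prediction], path) -> None:
    """Tab-separated predictions file, one row per pair."""
    with open(path, "w") as fh:
        fh.write("protein_id\tres_i\tres_j\tseparation\tpos_votes\tneg_votes"
                 "\tanswer\tlabel\n")
        for p in predictions:
            label = "" if p.label is None else p.label
            fh.write(
                f"{p.protein_id}\t{p.res_i}\t{p.res_j}\t{p.separation}"
                f"\t{p.pos_votes}\t{p.neg_votes}\t{p.answer}\t{label}\n"
            )


def read_predictions(path) -> list[Prediction]:
    preds: list[Prediction] = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("protein_id"):
            raise ValueError("not a predictions file")
        for line in fh:
            toks = line.rstrip("\n").split("\t")
            label = int(toks[7]) if len(toks) > 7 and toks[7] != "" else None
            preds.append(
                Prediction(toks[0], int(toks[1]), int(toks[2]), int(toks[3]),
                           int(toks[4]), int(toks[5]), int(toks[6]), label)
            )
    return preds


def to_casp_rr(predictions: Sequence[Prediction], n_members: int) -> list[str]:
    """CASP RR-style contact lines ``i j 0 8 prob``.

    The probability column is the positive vote fraction, the committee's
    confidence proxy.
    """
    return [
        f"{p.res_i} {p.res_j} 0 8 {p.pos_votes / n_members:.4f}"
        for p in predictions
    ]
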