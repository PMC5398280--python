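"""Committee voting, ranked selection, separation bands, and metrics."""

import numpy as np
import pytest

from logicmap.committee import (
    Committee,
    EvaluationReport,
    Prediction,
    committee_vote,
    evaluate,
    filter_separation,
    fmax_score,
    predict_dataset,
    random_baseline_fmax,
    read_predictions,
    to_casp_rr,
    top_fraction_select,
    top_L_select,
    write_predictions,
)
from logicmap.data import PairDataset
from logicmap.genome import (
    CircuitNetwork,
    GateSpec,
    classify,
    decode_genome,
    random_genome,
)

N_IN = 10


def constant_member(neg: bool, pos: bool) -> CircuitNetwork:
    """A network that always gives the same (neg, pos) answer pair."""
    gates = []
    base = N_IN  # no hidden nodes
    if neg:
        gates.append(GateSpec(1, 1, (0,), (base + 0,), (1, 1)))
    if pos:
        gates.append(GateSpec(1, 1, (0,), (base + 2,), (1, 1)))
    return CircuitNetwork(gates, N_IN, 0)


def make_prediction(pos_votes, answer=1, sep=10, pid="p", label=None):
    return Prediction(pid, 1, 1 + sep, sep, pos_votes, 0, answer, label)


class TestCommitteeVote:
    def test_unanimous_positive(self, rng):
        committee = Committee([constant_member(False, True)] * 60)
        pv, nv, answer = committee_vote(committee, np.zeros(N_IN), rng)
        assert (pv, nv, answer) == (60, 0, 1)

    def test_silent_member_ties_are_random(self, rng):
        committee = Committee([constant_member(False, False)])
        answers = {committee_vote(committee, np.zeros(N_IN), rng)[2]
                   for _ in range(50)}
        assert answers == {0, 1}

    def test_crafted_three_member_vote(self, rng):
        committee = Committee([
            constant_member(False, True),
            constant_member(False, True),
            constant_member(True, False),
        ])
        pv, nv, answer = committee_vote(committee, np.zeros(N_IN), rng)
        assert (pv, nv, answer) == (2, 1, 1)

    def test_both_asserting_member_votes_on_both_sums(self, rng):
        committee = Committee([constant_member(True, True)])
        pv, nv, _ = committee_vote(committee, np.zeros(N_IN), rng)
        assert (pv, nv) == (1, 1)

    def test_vote_matches_brute_force_tally(self, rng):
        """Batch vote sums equal a per-member scalar classify tally."""
        n_instances = 0
        for trial in range(10):
            members = [
                decode_genome(random_genome(6, rng), N_IN, 4) for _ in range(7)
            ]
            committee = Committee(members)
            X = rng.integers(0, 2, size=(100, N_IN)).astype(np.uint8)
            pos_votes, neg_votes = committee.vote_batch(X)
            for k in range(X.shape[0]):
                votes = [classify(m, X[k]) for m in members]
                assert pos_votes[k] == sum(p for _, p in votes)
                assert neg_votes[k] == sum(n for n, _ in votes)
                n_instances += 1
        assert n_instances == 1_000

    def test_mixed_width_members_rejected(self, rng):
        with pytest.raises(ValueError):
            Committee([
                decode_genome(random_genome(2, rng), 10, 2),
                decode_genome(random_genome(2, rng), 12, 2),
            ])


class TestEvaluate:
    def test_perfect_predictions_reach_half(self):
        rep = evaluate([1, 1, 0, 0, 0], [1, 1, 0, 0, 0])
        assert rep.specificity == 1.0
        assert rep.sensitivity == 1.0
        assert rep.fmax == 0.5

    def test_published_operating_point(self):
        # specificity 0.14 and sensitivity 0.35 combine to Fmax 0.1
        assert fmax_score(0.14, 0.35) == pytest.approx(0.1, abs=5e-4)

    def test_no_positive_answers_convention(self):
        rep = evaluate([0, 0, 0], [1, 0, 1])
        assert rep.specificity == 0.0
        assert rep.fmax == 0.0

    def test_confusion_counts(self):
        rep = evaluate([1, 1, 0, 0, 1, 0], [1, 0, 1, 0, 1, 0])
        assert (rep.TP, rep.FP, rep.TN, rep.FN) == (2, 1, 2, 1)

    def test_misaligned_inputs_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 0], [1])

    def test_fmax_never_exceeds_half(self, rng):
        for _ in range(200):
            s, n = rng.random(), rng.random()
            assert fmax_score(s, n) <= 0.5 + 1e-12
        assert fmax_score(1.0, 1.0) == 0.5


class TestRandomBaseline:
    N_POS, N_TOTAL = 10_498, 377_797

    def test_half_guess_rate(self):
        v = random_baseline_fmax(self.N_POS, self.N_TOTAL - self.N_POS, 0.5)
        assert round(v, 3) == 0.026

    def test_training_prevalence_guess_rate(self):
        v = random_baseline_fmax(self.N_POS, self.N_TOTAL - self.N_POS, 0.35155)
        assert round(v, 3) == 0.026

    def test_balanced_classes_full_guessing(self):
        assert random_baseline_fmax(100, 100, 1.0) == pytest.approx(1 / 3)

    def test_agrees_with_monte_carlo(self, rng):
        n, p, rate = 100_000, 0.0278, 0.5
        labels = rng.random(n) < p
        guesses = rng.random(n) < rate
        tp = int((labels & guesses).sum())
        emp = fmax_score(tp / guesses.sum(), tp / labels.sum())
        expected = random_baseline_fmax(int(labels.sum()),
                                        int(n - labels.sum()), rate)
        # three standard errors of the empirical Fmax via binomial spread
        se = 3 * np.sqrt(p * (1 - p) / (n * rate))
        assert abs(emp - expected) < 3 * se

    def test_degenerate_counts_rejected(self):
        with pytest.raises(ValueError):
            random_baseline_fmax(0, 100, 0.5)


class TestTopL:
    def test_fewer_qualifiers_than_L_returns_all(self, rng):
        preds = [make_prediction(v) for v in (40, 30, 20)]
        assert len(top_L_select(preds, 10, rng)) == 3

    def test_cutoff_tie_is_sampled_to_exactly_L(self, rng):
        preds = [make_prediction(v) for v in (58, 51, 51, 40, 12)]
        for _ in range(20):
            sel = top_L_select(preds, 2, rng)
            votes = sorted(p.pos_votes for p in sel)
            assert votes == [51, 58]

    def test_both_tied_candidates_eventually_selected(self, rng):
        a, b = make_prediction(51, pid="a"), make_prediction(51, pid="b")
        preds = [make_prediction(58), a, b]
        chosen = {id(sel[1]) for sel in
                  (top_L_select(preds, 2, rng) for _ in range(100))}
        assert chosen == {id(a), id(b)}

    def test_majority_negative_predictions_excluded(self, rng):
        preds = [make_prediction(40), make_prediction(45, answer=0)]
        sel = top_L_select(preds, 5, rng)
        assert [p.pos_votes for p in sel] == [40]

    def test_L_zero_is_empty(self, rng):
        assert top_L_select([make_prediction(9)], 0, rng) == []

    def test_size_is_min_of_L_and_qualifiers(self, rng):
        for L in range(6):
            preds = [make_prediction(v, answer=int(v > 10))
                     for v in (58, 51, 41, 30, 9, 3)]
            n_qual = 4
            assert len(top_L_select(preds, L, rng)) == min(L, n_qual)


class TestTopFraction:
    def test_quota_is_floor_of_fraction(self, rng):
        preds = [make_prediction(v) for v in range(20)]
        assert len(top_fraction_select(preds, 7, 0.5, rng)) == 3
        assert len(top_fraction_select(preds, 100, 0.1, rng)) == 10

    def test_ranks_all_predictions_not_only_positive(self, rng):
        preds = [make_prediction(30, answer=0), make_prediction(2, answer=1)]
        sel = top_fraction_select(preds, 2, 0.5, rng)
        assert sel[0].pos_votes == 30

    def test_matches_brute_force_sort(self, rng):
        votes = rng.integers(0, 60, 30)
        # distinct votes: selection must equal the top slice of a sort
        votes = np.unique(votes)
        preds = [make_prediction(int(v)) for v in votes]
        sel = top_fraction_select(preds, 40, 0.2, rng)
        expected = sorted(votes, reverse=True)[:8]
        assert [p.pos_votes for p in sel] == expected


class TestSeparationBands:
    @pytest.mark.parametrize(
        "sep,band,included",
        [
            (12, "[6,12]", True),
            (12, "(12,24]", False),
            (24, "(12,24]", True),
            (24, ">24", False),
            (25, ">24", True),
            (6, ">=6", True),
            (11, ">=12", False),
        ],
    )
    def test_band_boundaries(self, rng, sep, band, included):
        preds = [make_prediction(1, sep=sep)]
        assert (len(filter_separation(preds, band)) == 1) is included

    def test_three_bands_partition_separations(self, rng):
        seps = rng.integers(6, 200, 500)
        preds = [make_prediction(1, sep=int(s)) for s in seps]
        counts = sum(
            len(filter_separation(preds, band))
            for band in ("[6,12]", "(12,24]", ">24")
        )
        assert counts == len(preds)

    def test_empty_input(self):
        assert filter_separation([], ">24") == []

    def test_unknown_band(self):
        with pytest.raises(ValueError, match="unknown separation band"):
            filter_separation([], "[0,5]")

    def test_dataset_filtering(self, rng):
        ds = PairDataset([0, 1, 1], ["a"] * 3, [1, 1, 1], [10, 20, 40],
                         np.zeros((3, 2)))
        assert len(filter_separation(ds, ">24")) == 1


class TestPredictionFiles:
    def test_vote_batch_over_constant_members(self):
        committee = Committee(
            [constant_member(False, True), constant_member(True, False)]
        )
        X = np.zeros((2, N_IN), dtype=np.uint8)
        pos, neg = committee.vote_batch(X)
        assert list(pos) == [1, 1] and list(neg) == [1, 1]

    def test_round_trip_and_rr_lines(self, tmp_path):
        preds = [
            Prediction("a", 1, 10, 9, 2, 0, 1, 1),
            Prediction("a", 2, 30, 28, 0, 2, 0, 0),
        ]
        path = tmp_path / "preds.tsv"
        write_predictions(preds, path)
        assert read_predictions(path) == preds
        rr = to_casp_rr(preds, n_members=2)
        assert rr[0] == "1 10 0 8 1.0000"
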