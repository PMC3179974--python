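"""Gold standards, totals-based ROC/PR curves and interactor ranking."""

import io

import numpy as np
import pytest

from coevotree import (
    FormatError,
    generate_negatives,
    pr_curve,
    rank_interactors,
    read_gold_standard,
    roc_curve,
    run_experiment,
    write_experiment,
)
from coevotree.evaluation import GoldStandard, normalize_pair


class TestReadGoldStandard:
    def test_unordered_dedup(self):
        pairs = read_gold_standard(io.StringIO("A\tB\nB\tA\n"))
        assert pairs == {("A", "B")}

    def test_self_pair_rejected(self):
        with pytest.raises(FormatError, match="line 2"):
            read_gold_standard(io.StringIO("A\tB\nC\tC\n"))

    def test_simulator_round_trip(self, tmp_path, small_benchmark):
        from coevotree import write_benchmark

        out = write_benchmark(small_benchmark, tmp_path / "bench")
        pairs = read_gold_standard(out / "gold.tsv")
        assert pairs == set(small_benchmark.gold.positives)


class TestGenerateNegatives:
    def test_single_pair_no_negatives(self):
        gold = generate_negatives({("A", "B")})
        assert gold.P == 1 and gold.N == 0

    def test_two_pairs_hand_enumeration(self):
        gold = generate_negatives({("A", "B"), ("C", "D")})
        assert gold.P == 2
        assert gold.N == 4  # C(4,2) = 6 total pairs minus 2 positives
        assert gold.negatives == frozenset(
            {("A", "C"), ("A", "D"), ("B", "C"), ("B", "D")}
        )

    def test_matches_brute_force_count(self):
        rng = np.random.default_rng(0)
        proteins = [f"P{i}" for i in range(12)]
        for _ in range(10):
            pos = set()
            while len(pos) < 10:
                a, b = rng.choice(proteins, 2, replace=False)
                pos.add(normalize_pair(a, b))
            gold = generate_negatives(pos)
            involved = {p for pair in pos for p in pair}
            n = len(involved)
            assert gold.N == n * (n - 1) // 2 - gold.P

    def test_disjoint_sets_enforced(self):
        with pytest.raises(ValueError):
            GoldStandard(
                positives=frozenset({("A", "B")}),
                negatives=frozenset({("A", "B")}),
                P=1,
                N=1,
            )


def naive_roc(scored, gold):
    """Textbook threshold-recount oracle under the fixed-totals convention."""
    pts = [(0.0, 0.0)]
    thresholds = sorted({s for _, s in scored}, reverse=True)
    for thr in thresholds:
        tp = sum(
            1 for p, s in scored if s >= thr and gold.classify(p) == "positive"
        )
        fp = sum(
            1 for p, s in scored if s >= thr and gold.classify(p) == "negative"
        )
        pts.append((fp / gold.N, tp / gold.P))
    return pts


class TestRocCurve:
    def test_perfect_full_coverage(self):
        gold = generate_negatives({("A", "B"), ("C", "D")})
        scored = {("A", "B"): 9.0, ("C", "D"): 8.0}
        scored.update({pair: -i for i, pair in enumerate(sorted(gold.negatives))})
        roc = roc_curve(scored, gold)
        assert roc.auc == pytest.approx(1.0)
        assert roc.coverage == pytest.approx(1.0)
        assert roc.points[-1] == (1.0, 1.0)

    def test_half_coverage_terminates_early(self):
        # 10 positives, 10 negatives; only 5 of each scored, perfectly ranked
        pos = [(f"P{i}", f"Q{i}") for i in range(10)]
        gold_pos = {normalize_pair(*p) for p in pos}
        involved = sorted({x for p in gold_pos for x in p})
        neg = []
        for a in involved:
            for b in involved:
                if a < b and (a, b) not in gold_pos:
                    neg.append((a, b))
        gold = GoldStandard(
            positives=frozenset(gold_pos),
            negatives=frozenset(neg[:10]),
            P=10,
            N=10,
        )
        scored = {p: 100 - i for i, p in enumerate(sorted(gold_pos)[:5])}
        scored.update({p: -i for i, p in enumerate(sorted(gold.negatives)[:5])})
        roc = roc_curve(scored, gold)
        assert roc.points[-1] == (0.5, 0.5)
        assert roc.auc == pytest.approx(0.25)  # 0.5 x 0.5 rectangle
        assert roc.coverage == pytest.approx(0.5)

    def test_hand_enumerated_toy_curve(self):
        gold = GoldStandard(
            positives=frozenset({("a", "b"), ("c", "d")}),
            negatives=frozenset({("a", "c"), ("a", "d"), ("b", "c"), ("b", "d")}),
            P=2,
            N=4,
        )
        scored = {
            ("a", "b"): 0.9,
            ("a", "c"): 0.8,
            ("c", "d"): 0.7,
            ("b", "c"): 0.7,  # tie with the positive: one step
            ("a", "d"): 0.1,
        }
        roc = roc_curve(scored, gold)
        assert roc.points == [
            (0.0, 0.0),
            (0.0, 0.5),     # 0.9: Tp=1
            (0.25, 0.5),    # 0.8: Fp=1
            (0.5, 1.0),     # 0.7: tie adds Tp=1 and Fp=1 together
            (0.75, 1.0),    # 0.1: Fp=3 (one negative never scored)
        ]

    def test_matches_naive_oracle_on_random_lists(self):
        rng = np.random.default_rng(1)
        pos = {normalize_pair(f"X{i}", f"Y{i}") for i in range(10)}
        gold = generate_negatives(pos)
        pairs = sorted(gold.positives | gold.negatives)
        for _ in range(10):
            chosen = [pairs[i] for i in rng.choice(len(pairs), 20, replace=False)]
            scored = [(p, float(rng.integers(0, 8))) for p in chosen]
            roc = roc_curve(scored, gold)
            assert roc.points == pytest.approx(naive_roc(scored, gold))

    def test_full_coverage_reduces_to_standard_roc(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(2)
        pos = {normalize_pair(f"X{i}", f"Y{i}") for i in range(8)}
        gold = generate_negatives(pos)
        scored = {p: float(rng.normal()) for p in gold.positives | gold.negatives}
        y = [1 if gold.classify(p) == "positive" else 0 for p in scored]
        s = [scored[p] for p in scored]
        assert roc_curve(scored, gold).auc == pytest.approx(roc_auc_score(y, s))

    def test_conservation_at_every_threshold(self):
        rng = np.random.default_rng(3)
        pos = {normalize_pair(f"X{i}", f"Y{i}") for i in range(6)}
        gold = generate_negatives(pos)
        pairs = sorted(gold.positives | gold.negatives)
        scored = [(p, float(rng.integers(0, 5))) for p in pairs[: len(pairs) // 2]]
        roc = roc_curve(scored, gold)
        for tp, fp in roc.counts:
            assert 0 <= tp <= gold.P
            assert 0 <= fp <= gold.N

    def test_undefined_without_negatives(self):
        gold = generate_negatives({("A", "B")})
        with pytest.raises(ValueError, match="undefined"):
            roc_curve({("A", "B"): 1.0}, gold)

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(4)
        pos = {normalize_pair(f"A{i}", f"B{i}") for i in range(500)}
        involved = sorted({x for p in pos for x in p})
        neg = set()
        while len(neg) < 500:
            a, b = rng.choice(involved, 2, replace=False)
            p = normalize_pair(a, b)
            if p not in pos:
                neg.add(p)
        gold = GoldStandard(
            positives=frozenset(pos), negatives=frozenset(neg), P=500, N=500
        )
        scored = {p: float(rng.random()) for p in pos | neg}
        assert 0.45 <= roc_curve(scored, gold).auc <= 0.55


class TestPrCurve:
    def test_perfect_classifier_max_f(self):
        gold = generate_negatives({("A", "B"), ("C", "D")})
        scored = {("A", "B"): 2.0, ("C", "D"): 1.5}
        scored.update({p: 0.0 for p in gold.negatives})
        assert pr_curve(scored, gold).max_f == pytest.approx(1.0)

    def test_single_positive_ranked_first(self):
        gold = GoldStandard(
            positives=frozenset({("a", "b")}),
            negatives=frozenset(
                {("a", f"n{i}") for i in range(9)}
            ),
            P=1,
            N=9,
        )
        scored = {("a", "b"): 10.0}
        scored.update({p: float(-i) for i, p in enumerate(sorted(gold.negatives))})
        pr = pr_curve(scored, gold)
        thr, precision, recall, f = pr.points[0]
        assert (precision, recall, f) == (1.0, 1.0, 1.0)

    def test_hand_computed_table(self):
        gold = GoldStandard(
            positives=frozenset({("a", "b"), ("c", "d")}),
            negatives=frozenset({("a", "c"), ("b", "d")}),
            P=2,
            N=2,
        )
        scored = {("a", "b"): 3.0, ("a", "c"): 2.0, ("c", "d"): 1.0}
        pr = pr_curve(scored, gold)
        assert pr.points[0][1:] == pytest.approx((1.0, 0.5, 2 / 3))
        assert pr.points[1][1:] == pytest.approx((0.5, 0.5, 0.5))
        assert pr.points[2][1:] == pytest.approx((2 / 3, 1.0, 0.8))
        assert pr.max_f == pytest.approx(0.8)


def mann_whitney_auc(pos_scores, neg_scores):
    """Explicit double-loop U statistic with ties counted as 1/2."""
    wins = 0.0
    for p in pos_scores:
        for n in neg_scores:
            if p > n:
                wins += 1.0
            elif p == n:
                wins += 0.5
    return wins / (len(pos_scores) * len(neg_scores))


class TestRankInteractors:
    def make_gold(self):
        return GoldStandard(
            positives=frozenset({("X", "p1")}),
            negatives=frozenset({("X", f"n{i}") for i in range(9)}),
            P=1,
            N=9,
        )

    def test_positive_ranked_first(self):
        gold = self.make_gold()
        scored = {("X", "p1"): 5.0}
        scored.update({("X", f"n{i}"): float(-i) for i in range(9)})
        rep = rank_interactors(scored, "X", gold)
        assert rep.local_auc == pytest.approx(1.0)
        assert rep.top_partner == "p1"
        assert rep.n_candidates == 10
        assert rep.n_positives == 1

    def test_positive_ranked_last(self):
        gold = self.make_gold()
        scored = {("X", "p1"): -99.0}
        scored.update({("X", f"n{i}"): float(i) for i in range(9)})
        assert rank_interactors(scored, "X", gold).local_auc == pytest.approx(0.0)

    def test_matches_mann_whitney_oracle(self):
        rng = np.random.default_rng(5)
        gold = GoldStandard(
            positives=frozenset({("X", f"p{i}") for i in range(4)}),
            negatives=frozenset({("X", f"n{i}") for i in range(12)}),
            P=4,
            N=12,
        )
        for _ in range(20):
            scored = {p: float(rng.integers(0, 6)) for p in gold.positives | gold.negatives}
            rep = rank_interactors(scored, "X", gold)
            pos = [scored[p] for p in gold.positives]
            neg = [scored[p] for p in gold.negatives]
            assert rep.local_auc == pytest.approx(mann_whitney_auc(pos, neg))

    def test_unknown_protein(self):
        with pytest.raises(KeyError):
            rank_interactors({("A", "B"): 1.0}, "Z", self.make_gold())


class TestRunExperiment:
    def test_perfect_separation_cell(self, headline_benchmark):
        sets = [("all", headline_benchmark.organisms)]
        result = run_experiment(headline_benchmark, sets, methods=["MT"])
        row = result.summary.iloc[0]
        assert row["auc"] == pytest.approx(1.0)
        assert row["coverage"] == pytest.approx(1.0)

    def test_deterministic_summary(self, small_benchmark):
        sets = [("all", small_benchmark.organisms)]
        r1 = run_experiment(small_benchmark, sets, min_common=8, cm_level=3)
        r2 = run_experiment(small_benchmark, sets, min_common=8, cm_level=3)
        assert r1.summary.equals(r2.summary)

    def test_empty_cells_reported_not_failed(self, small_benchmark):
        # an organism set too small for any pair to be evaluable
        sets = [("tiny", small_benchmark.organisms[:3])]
        result = run_experiment(small_benchmark, sets, methods=["MT"])
        assert np.isnan(result.summary.iloc[0]["auc"])
        assert result.summary.iloc[0]["n_scored"] == 0

    def test_write_experiment(self, tmp_path, small_benchmark):
        sets = [("all", small_benchmark.organisms)]
        result = run_experiment(small_benchmark, sets, min_common=8, cm_level=2)
        out = write_experiment(result, tmp_path / "exp")
        assert (out / "summary.tsv").exists()
        assert (out / "manifest.json").exists()
        assert (out / "curve_all_MT.tsv").exists()
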