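from itertools import permutations

import numpy as np
import pytest

from sigmin import (
    GeneSignature,
    PredictionConfig,
    nearest_neighbors,
    pearson,
    predict_and_score,
    random_baseline,
    random_signature,
)
from sigmin.annotations import TargetAnnotationTable
from sigmin.prediction import ConstantProfileError

from conftest import make_matrix


class TestPearson:
    def test_perfect_and_inverse(self):
        x = np.array([1.0, 2.0, 5.0])
        assert pearson(x, x) == pytest.approx(1.0)
        assert pearson(x, -x) == pytest.approx(-1.0)

    def test_hand_computed_value(self):
        assert pearson([1, 2, 3], [1, 2, 4]) == pytest.approx(9 / np.sqrt(84))

    def test_constant_vector_rejected(self):
        with pytest.raises(ConstantProfileError):
            pearson([1, 1, 1], [1, 2, 3])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            pearson([1, 2], [1, 2])

    def test_shift_and_scale_invariance(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 20))
        assert pearson(2.5 * x + 7, y) == pytest.approx(pearson(x, y), abs=1e-12)


def five_instance_fixture():
    """Hand-computed fixture: query i1 ranks i3 (r=1) > i4 (r=0.5) > i5 (r=-1)."""
    values = np.array(
        [
            [0.0, 1.0, 2.0],  # i1, compound c1
            [0.0, 1.0, 2.0],  # i2, replicate of c1 (self-excluded)
            [0.0, 1.0, 2.0],  # i3, c2: r=1 with i1
            [0.0, 2.0, 1.0],  # i4, c3: r=0.5 with i1
            [2.0, 1.0, 0.0],  # i5, c4: r=-1 with i1
        ]
    )
    m = make_matrix(values, compounds=["c1", "c1", "c2", "c3", "c4"])
    table = TargetAnnotationTable(
        {
            "c1": frozenset({"A", "B"}),
            "c2": frozenset({"B", "C"}),
            "c3": frozenset({"D"}),
            "c4": frozenset({"E"}),
        }
    )
    sig = GeneSignature(("p1", "p2", "p3"))
    return m, table, sig


class TestNearestNeighbors:
    def test_hand_computed_ordering(self):
        m, table, sig = five_instance_fixture()
        nn = nearest_neighbors(m, sig, "i1", PredictionConfig(k_neighbors=3), table)
        assert [n.instance_id for n in nn] == ["i3", "i4", "i5"]
        assert [n.correlation for n in nn] == pytest.approx([1.0, 0.5, -1.0])

    def test_self_compound_excluded_even_when_most_correlated(self):
        values = np.array([[0.0, 1.0, 2.0], [0.0, 1.0, 2.0], [2.0, 0.0, 1.0]])
        m = make_matrix(values, compounds=["c1", "c1", "c2"])
        table = TargetAnnotationTable({"c1": frozenset("a"), "c2": frozenset("b")})
        nn = nearest_neighbors(m, GeneSignature(("p1", "p2", "p3")), "i1",
                               PredictionConfig(1), table)
        assert nn[0].instance_id == "i3"

    def test_exact_duplicate_of_other_compound_ranks_first(self):
        rng = np.random.default_rng(1)
        values = rng.normal(size=(4, 5))
        values[2] = values[0]
        m = make_matrix(values, compounds=["c1", "c2", "c3", "c4"])
        table = TargetAnnotationTable({c: frozenset({c}) for c in ["c1", "c2", "c3", "c4"]})
        nn = nearest_neighbors(m, GeneSignature(tuple(m.probeset_ids)), "i1",
                               PredictionConfig(1), table)
        assert nn[0].instance_id == "i3"
        assert nn[0].correlation == pytest.approx(1.0)

    def test_too_few_candidates_rejected(self):
        m, table, sig = five_instance_fixture()
        with pytest.raises(ValueError, match="eligible"):
            nearest_neighbors(m, sig, "i1", PredictionConfig(k_neighbors=4), table)


class TestPredictAndScore:
    def test_hand_computed_accuracy_and_precision(self):
        m, table, sig = five_instance_fixture()
        report = predict_and_score(m, sig, table, PredictionConfig(1), keep_per_query=True)
        # i1,i2 -> i3 hit {B}; i3 -> i1 (id tie-break) hit {B}; i4 -> i1 miss; i5 -> i4 miss
        assert report.accuracy == pytest.approx(3 / 5)
        assert report.precision == pytest.approx((0.5 + 0.5 + 0.5 + 0 + 0) / 5)
        by_query = {r.query_instance: r for r in report.per_query}
        assert by_query["i3"].neighbors[0].instance_id == "i1"
        assert not by_query["i4"].success

    def test_success_iff_intersection_nonempty(self):
        m, table, sig = five_instance_fixture()
        report = predict_and_score(m, sig, table, PredictionConfig(1), keep_per_query=True)
        for r in report.per_query:
            assert r.success == bool(r.predicted_targets & r.true_targets)

    def test_accuracy_non_decreasing_in_k(self, prepared11):
        m, table = prepared11
        sig = random_signature(m.probeset_ids, 64, seed=0)
        accs = [
            predict_and_score(m, sig, table, PredictionConfig(k)).accuracy for k in (1, 2, 3)
        ]
        assert accs[0] <= accs[1] <= accs[2]

    def test_invariant_to_signature_order_and_affine_transform(self):
        m, table, sig = five_instance_fixture()
        base = predict_and_score(m, sig, table, PredictionConfig(1)).accuracy
        reordered = GeneSignature(("p3", "p1", "p2"))
        assert predict_and_score(m, reordered, table, PredictionConfig(1)).accuracy == base
        scaled = make_matrix(2.0 * m.values + 5.0, compounds=m.compound_ids)
        assert predict_and_score(scaled, sig, table, PredictionConfig(1)).accuracy == base

    def test_planted_signature_beats_shuffled_annotations(self, prepared7, bundle7):
        m, table = prepared7
        sig = GeneSignature(bundle7.truth.informative_probesets, origin="planted")
        informative = predict_and_score(m, sig, table, PredictionConfig(1)).accuracy
        baseline = random_baseline(m, sig, table, PredictionConfig(1), n_shuffles=5, seed=2)
        assert informative > baseline.mean + 3 * max(baseline.sd, 0.01)


class TestRandomBaseline:
    def test_shared_target_set_always_hits(self):
        rng = np.random.default_rng(3)
        m = make_matrix(rng.normal(size=(4, 5)))
        table = TargetAnnotationTable({f"c{i+1}": frozenset({"T"}) for i in range(4)})
        out = random_baseline(m, GeneSignature(tuple(m.probeset_ids)), table,
                              PredictionConfig(1), n_shuffles=5, seed=0)
        assert out.mean == 1.0 and out.sd == 0.0

    def test_disjoint_singletons_two_compounds_never_hit(self):
        rng = np.random.default_rng(4)
        m = make_matrix(rng.normal(size=(2, 4)))
        table = TargetAnnotationTable({"c1": frozenset("a"), "c2": frozenset("b")})
        out = random_baseline(m, GeneSignature(tuple(m.probeset_ids)), table,
                              PredictionConfig(1), n_shuffles=8, seed=0)
        assert out.mean == 0.0

    def test_monte_carlo_matches_exhaustive_permutation_mean(self):
        """4 compounds, disjoint singleton targets: compare with the S4 average."""
        rng = np.random.default_rng(5)
        m = make_matrix(rng.normal(size=(4, 6)))
        sig = GeneSignature(tuple(m.probeset_ids))
        sets = [frozenset({t}) for t in "wxyz"]
        compounds = ["c1", "c2", "c3", "c4"]
        table = TargetAnnotationTable(dict(zip(compounds, sets)))
        cfg = PredictionConfig(1)
        exact = np.mean(
            [
                predict_and_score(
                    m, sig, TargetAnnotationTable(dict(zip(compounds, perm))), cfg
                ).accuracy
                for perm in permutations(sets)
            ]
        )
        n = 120
        mc = random_baseline(m, sig, table, cfg, n_shuffles=n, seed=1)
        sigma = np.std(
            [
                predict_and_score(
                    m, sig, TargetAnnotationTable(dict(zip(compounds, perm))), cfg
                ).accuracy
                for perm in permutations(sets)
            ]
        ) / np.sqrt(n)
        assert abs(mc.mean - exact) <= 3 * max(sigma, 1e-9)

    def test_constant_query_skipped_not_fatal(self):
        values = np.array([[1.0, 1.0, 1.0], [0.0, 1.0, 2.0], [2.0, 1.0, 0.0]])
        m = make_matrix(values)
        table = TargetAnnotationTable({f"c{i+1}": frozenset({"T"}) for i in range(3)})
        report = predict_and_score(m, GeneSignature(("p1", "p2", "p3")), table,
                                   PredictionConfig(1))
        assert report.n_skipped == 1
        assert report.n_queries == 2
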