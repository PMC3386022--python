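import numpy as np
import pytest

from sigmin import GeneSignature, batch_mean_center, load_expression, subset_probesets
from sigmin.expr_data import write_expression, write_metadata
from sigmin.prediction import pearson

from conftest import make_matrix


def write_tsv(path, text):
    path.write_text(text)
    return path


@pytest.fixture
def meta3(tmp_path):
    return write_tsv(
        tmp_path / "meta.tsv",
        "instance_id\tcompound_id\tbatch_id\n"
        "i1\tc1\tb1\ni2\tc2\tb1\ni3\tc3\tb1\n",
    )


class TestLoad:
    def test_tsv_round_trip(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "probeset_id\ti1\ti2\ti3\np1\t1\t2\t3\np2\t4\t5\t6\n",
        )
        m = load_expression(expr, meta3)
        assert m.n_instances == 3 and m.n_probesets == 2
        assert m.instance_ids == ["i1", "i2", "i3"]
        assert not m.centred
        np.testing.assert_allclose(m.values, [[1, 4], [2, 5], [3, 6]])

    def test_instances_in_rows_autodetected(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "id\tp1\tp2\ni1\t1\t4\ni2\t2\t5\ni3\t3\t6\n",
        )
        m = load_expression(expr, meta3)
        assert m.probeset_ids == ["p1", "p2"]
        np.testing.assert_allclose(m.values, [[1, 4], [2, 5], [3, 6]])

    def test_duplicate_probeset_rejected(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "probeset_id\ti1\ti2\ti3\np1\t1\t2\t3\np1\t4\t5\t6\n",
        )
        with pytest.raises(ValueError, match="duplicate probeset"):
            load_expression(expr, meta3)

    def test_instance_without_metadata_rejected(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "probeset_id\ti1\ti2\ti9\np1\t1\t2\t3\np2\t4\t5\t6\n",
        )
        with pytest.raises(ValueError, match="i9"):
            load_expression(expr, meta3)

    def test_non_numeric_cell_rejected(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "probeset_id\ti1\ti2\ti3\np1\t1\tfoo\t3\np2\t4\t5\t6\n",
        )
        with pytest.raises(ValueError, match="non-numeric"):
            load_expression(expr, meta3)

    def test_gct_dimension_mismatch(self, tmp_path, meta3):
        gct = write_tsv(
            tmp_path / "e.gct",
            "#1.2\n4\t5\nName\tDescription\ti1\ti2\ti3\n"
            "p1\tna\t1\t2\t3\np2\tna\t4\t5\t6\n",
        )
        with pytest.raises(ValueError, match="GCT"):
            load_expression(gct, meta3)

    def test_gct_valid(self, tmp_path, meta3):
        gct = write_tsv(
            tmp_path / "e.gct",
            "#1.2\n2\t3\nName\tDescription\ti1\ti2\ti3\n"
            "p1\tna\t1\t2\t3\np2\tna\t4\t5\t6\n",
        )
        m = load_expression(gct, meta3)
        assert m.probeset_ids == ["p1", "p2"]
        np.testing.assert_allclose(m.values, [[1, 4], [2, 5], [3, 6]])

    def test_missing_values_rejected_then_imputed(self, tmp_path, meta3):
        expr = write_tsv(
            tmp_path / "e.tsv",
            "probeset_id\ti1\ti2\ti3\np1\t1\t\t3\np2\t4\t5\t6\n",
        )
        with pytest.raises(ValueError, match="missing"):
            load_expression(expr, meta3)
        m = load_expression(expr, meta3, impute_missing=True)
        assert m.values[1, 0] == 2.0  # probeset median of (1, 3)

    def test_write_read_round_trip(self, tmp_path, prepared7):
        m, _ = prepared7
        write_expression(m, tmp_path / "expr.tsv")
        write_metadata(m.instances, tmp_path / "meta.tsv")
        m2 = load_expression(tmp_path / "expr.tsv", tmp_path / "meta.tsv")
        np.testing.assert_allclose(m2.values, m.values, atol=1e-9)
        assert m2.instance_ids == m.instance_ids


class TestBatchCenter:
    def test_single_batch_centring_identity(self):
        m = make_matrix(np.array([[1, 2, 3, 4, 5, 6]]).T)
        out = batch_mean_center(m)
        np.testing.assert_allclose(out.values[:, 0], [-2.5, -1.5, -0.5, 0.5, 1.5, 2.5])
        assert out.centred

    def test_identical_rows_become_zero(self):
        m = make_matrix(np.ones((6, 3)) * 7.0)
        out = batch_mean_center(m)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_small_batches_are_dropped(self):
        values = np.arange(9 * 2).reshape(9, 2).astype(float)
        batches = ["big"] * 6 + ["small"] * 3
        m = make_matrix(values, batches=batches)
        out = batch_mean_center(m)
        assert out.n_instances == 6
        assert all(i.batch_id == "big" for i in out.instances)
        np.testing.assert_allclose(out.values.mean(axis=0), 0.0, atol=1e-9)

    def test_already_centred_rejected(self):
        m = make_matrix(np.zeros((6, 2)), centred=True)
        with pytest.raises(ValueError, match="already centred"):
            batch_mean_center(m)

    def test_idempotent_in_effect(self, prepared7):
        m, _ = prepared7
        again = batch_mean_center(
            make_matrix(
                m.values,
                compounds=m.compound_ids,
                batches=m.batch_ids,
                probesets=m.probeset_ids,
            )
        )
        np.testing.assert_allclose(again.values, m.values, atol=1e-9)

    def test_centring_removes_only_the_batch_offset(self):
        """When the batch effect is a pure offset, within-batch correlations survive."""
        rng = np.random.default_rng(0)
        base = rng.normal(size=(12, 5))
        base[:6] -= base[:6].mean(axis=0)   # biological signal, zero batch mean
        base[6:] -= base[6:].mean(axis=0)
        values = base + np.array([3.0] * 6 + [-2.0] * 6)[:, None]
        m = make_matrix(values, batches=["A"] * 6 + ["B"] * 6)
        out = batch_mean_center(m)
        # Pearson is shift-invariant per instance, so the observed correlation
        # equals the signal correlation, and centring must preserve it
        r_before = pearson(values[0], values[1])
        r_after = pearson(out.values[0], out.values[1])
        assert r_after == pytest.approx(r_before, abs=1e-9)
        assert r_after == pytest.approx(pearson(base[0], base[1]), abs=1e-9)


class TestSubset:
    def test_identity_and_single_column(self):
        m = make_matrix(np.arange(12).reshape(3, 4).astype(float))
        full = subset_probesets(m, GeneSignature(tuple(m.probeset_ids)))
        np.testing.assert_allclose(full.values, m.values)
        single = subset_probesets(m, GeneSignature(("p3",)))
        np.testing.assert_allclose(single.values[:, 0], m.values[:, 2])

    def test_unknown_probeset_named_in_error(self):
        m = make_matrix(np.zeros((3, 2)))
        with pytest.raises(KeyError, match="pX"):
            subset_probesets(m, GeneSignature(("p1", "pX")))

    def test_subset_composes(self):
        m = make_matrix(np.arange(20).reshape(4, 5).astype(float))
        outer = GeneSignature(("p5", "p2", "p3"))
        inner = GeneSignature(("p3", "p5"))
        once = subset_probesets(m, inner)
        twice = subset_probesets(subset_probesets(m, outer), inner)
        np.testing.assert_allclose(once.values, twice.values)
        assert once.probeset_ids == twice.probeset_ids
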