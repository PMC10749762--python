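import logging

import numpy as np
import pytest

from microgda import data_io
from microgda.data_io import (
    AbundanceMatrix,
    NormalizationStats,
    align_features,
    attach_metadata,
    concat_samples,
    log10_transform,
    read_abundance_table,
    read_metadata,
    write_abundance_table,
    write_metadata,
    zscore_apply,
    zscore_fit,
)


def _matrix(values, sample_ids=None, taxa=None, **kw):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    return AbundanceMatrix(
        sample_ids=sample_ids or [f"s{i}" for i in range(n)],
        taxa=taxa or [f"t{j}" for j in range(p)],
        values=values,
        **kw,
    )


class TestReadWrite:
    def test_round_trip_preserves_everything(self, tmp_path):
        m = _matrix([[0.5, 0.5], [0.2, 0.8]])
        path = tmp_path / "a.tsv"
        write_abundance_table(m, path)
        back = read_abundance_table(path)
        assert back.sample_ids == m.sample_ids
        assert back.taxa == m.taxa
        np.testing.assert_array_equal(back.values, m.values)

    def test_samples_in_columns_matches_manual_transpose(self, tmp_path):
        # hand-written 3 taxa x 2 samples file
        path = tmp_path / "t.tsv"
        path.write_text(
            "taxon\tsA\tsB\n"
            "sp1\t0.1\t0.4\n"
            "sp2\t0.2\t0.5\n"
            "sp3\t0.7\t0.1\n"
        )
        m = read_abundance_table(path, orientation="samples-in-columns")
        assert m.sample_ids == ["sA", "sB"]
        assert m.taxa == ["sp1", "sp2", "sp3"]
        manual = np.array([[0.1, 0.2, 0.7], [0.4, 0.5, 0.1]])
        np.testing.assert_array_equal(m.values, manual)

    @pytest.mark.parametrize(
        "content,match",
        [
            ("id\ta\ta\ns1\t0.1\t0.2\n", "duplicate"),
            ("id\ta\tb\ns1\t0.1\t0.2\ns1\t0.3\t0.4\n", "duplicate"),
            ("id\ta\tb\ns1\t-0.1\t0.2\n", "negative"),
            ("id\ta\tb\ns1\tabc\t0.2\n", "non-numeric"),
        ],
    )
    def test_malformed_tables_rejected(self, tmp_path, content, match):
        path = tmp_path / "bad.tsv"
        path.write_text(content)
        with pytest.raises(ValueError, match=match):
            read_abundance_table(path)

    def test_metadata_round_trip(self, tmp_path):
        m = _matrix(
            [[0.5, 0.5], [0.2, 0.8], [0.3, 0.7]],
            cohort=["c1", "c1", "c2"],
            label=np.array([1.0, 0.0, np.nan]),
        )
        path = tmp_path / "meta.tsv"
        write_metadata(m, path)
        meta = read_metadata(path)
        plain = _matrix(m.values)
        back = attach_metadata(plain, meta)
        assert back.cohort == m.cohort
        np.testing.assert_array_equal(np.isnan(back.label), np.isnan(m.label))
        np.testing.assert_array_equal(back.label[:2], m.label[:2])


class TestInvariants:
    def test_duplicate_ids_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            _matrix([[0.1], [0.2]], sample_ids=["s", "s"])
        with pytest.raises(ValueError, match="duplicate"):
            _matrix([[0.1, 0.2]], taxa=["t", "t"])

    def test_negative_values_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            _matrix([[-0.1, 0.2]])


class TestAlignFeatures:
    def test_union_with_zero_fill(self):
        train = _matrix([[1.0, 2.0]], taxa=["a", "b"])
        test = _matrix([[3.0, 4.0]], taxa=["b", "c"])
        tr, te = align_features(train, test)
        assert tr.taxa == te.taxa == ["a", "b", "c"]
        np.testing.assert_array_equal(tr.values, [[1.0, 2.0, 0.0]])
        np.testing.assert_array_equal(te.values, [[0.0, 3.0, 4.0]])

    def test_identical_taxa_is_reordering_only(self):
        train = _matrix([[1.0, 2.0]], taxa=["b", "a"])
        test = _matrix([[3.0, 4.0]], taxa=["a", "b"])
        tr, te = align_features(train, test)
        np.testing.assert_array_equal(tr.values, [[2.0, 1.0]])
        np.testing.assert_array_equal(te.values, [[3.0, 4.0]])

    def test_idempotent(self):
        train = _matrix([[1.0, 2.0]], taxa=["a", "b"])
        test = _matrix([[3.0, 4.0]], taxa=["b", "c"])
        tr1, te1 = align_features(train, test)
        tr2, te2 = align_features(tr1, te1)
        assert tr2.taxa == tr1.taxa
        np.testing.assert_array_equal(tr2.values, tr1.values)
        np.testing.assert_array_equal(te2.values, te1.values)

    def test_disjoint_taxa_warns_but_unions(self, caplog):
        train = _matrix([[1.0]], taxa=["a"])
        test = _matrix([[2.0]], taxa=["b"])
        with caplog.at_level(logging.WARNING, logger="microgda.data_io"):
            tr, te = align_features(train, test)
        assert tr.taxa == ["a", "b"]
        assert any("no taxa" in r.message for r in caplog.records)


class TestNormalization:
    def test_log10_known_values(self):
        m = _matrix([[0.0, 0.001]])
        out = log10_transform(m, pseudocount=1e-5)
        assert out[0, 0] == pytest.approx(-5.0)
        assert out[0, 1] == pytest.approx(np.log10(0.00101), abs=1e-12)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            log10_transform(_matrix([[1.0]]), pseudocount=0.0)

    def test_fit_population_std(self):
        stats = zscore_fit(np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0]]))
        assert stats.mean[0] == pytest.approx(2.0)
        assert stats.std[0] == pytest.approx(np.sqrt(2.0 / 3.0), abs=1e-12)
        # constant column: mean 5, std 0 — independent per-column stats
        assert stats.mean[1] == pytest.approx(5.0)
        assert stats.std[1] == 0.0

    def test_fit_requires_two_samples(self):
        with pytest.raises(ValueError):
            zscore_fit(np.array([[1.0, 2.0]]))

    def test_apply_closed_form(self):
        x = np.array([[1.0], [2.0], [3.0]])
        out = zscore_apply(x, zscore_fit(x))
        np.testing.assert_allclose(
            out.ravel(), [-1.2247448714, 0.0, 1.2247448714], atol=1e-9
        )

    def test_zero_variance_taxon_maps_to_zero(self):
        x = np.array([[5.0], [5.0], [5.0]])
        out = zscore_apply(x, zscore_fit(x))
        np.testing.assert_array_equal(out, np.zeros((3, 1)))

    def test_value_at_training_mean_maps_to_zero(self):
        x = np.array([[1.0], [3.0]])
        stats = zscore_fit(x)
        assert zscore_apply(np.array([[2.0]]), stats)[0, 0] == 0.0

    def test_dimension_mismatch_rejected(self):
        stats = zscore_fit(np.random.default_rng(0).normal(size=(5, 3)))
        with pytest.raises(ValueError):
            zscore_apply(np.zeros((2, 4)), stats)

    def test_self_normalization_gives_unit_moments(self):
        rng = np.random.default_rng(42)
        x = rng.normal(size=(50, 20)) * rng.uniform(0.5, 3.0, size=20)
        out = zscore_apply(x, zscore_fit(x))
        assert np.abs(out.mean(axis=0)).max() < 1e-10
        assert np.abs(out.std(axis=0, ddof=0) - 1.0).max() < 1e-10

    def test_training_stats_independent_of_test_data(self):
        rng = np.random.default_rng(1)
        train = rng.uniform(size=(10, 4))
        test = rng.uniform(size=(6, 4))
        before = zscore_fit(train)
        out1 = zscore_apply(test, before)
        perm = rng.permutation(6)
        after = zscore_fit(train)  # refit after touching the test set
        np.testing.assert_array_equal(before.mean, after.mean)
        np.testing.assert_array_equal(before.std, after.std)
        np.testing.assert_array_equal(zscore_apply(test[perm], after), out1[perm])

    def test_stats_serialization_round_trip(self, tmp_path):
        stats = zscore_fit(np.random.default_rng(3).normal(size=(7, 5)), 1e-4)
        path = tmp_path / "stats.tsv"
        stats.save(path)
        back = NormalizationStats.load(path)
        np.testing.assert_array_equal(back.mean, stats.mean)
        np.testing.assert_array_equal(back.std, stats.std)
        assert back.pseudocount == stats.pseudocount


def test_concat_requires_shared_taxa():
    a = _matrix([[1.0]], sample_ids=["x"], taxa=["a"])
    b = _matrix([[1.0]], sample_ids=["y"], taxa=["b"])
    with pytest.raises(ValueError, match="align"):
        concat_samples([a, b])
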