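"""Count IO, TMM factors, CPM, the expressed-gene filter and outlier capping."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nutrinet.matrix import ExpressionMatrix, MatrixFormatError
from nutrinet.preprocess import (NormalizationFactors, cap_outliers, cpm,
                                 filter_expressed, read_count_matrix,
                                 tmm_factors)


def _write_dataset(tmp_path, counts, biotypes, groups):
    cpath = tmp_path / "c.tsv"
    counts.rename_axis("gene_id").to_csv(cpath, sep="\t")
    bpath = tmp_path / "b.tsv"
    pd.DataFrame({"gene_id": list(biotypes), "biotype": list(biotypes.values())}
                 ).to_csv(bpath, sep="\t", index=False)
    gpath = tmp_path / "g.tsv"
    pd.DataFrame({"sample_id": list(groups), "group": list(groups.values())}
                 ).to_csv(gpath, sep="\t", index=False)
    return cpath, bpath, gpath


class TestReadCountMatrix:
    def test_well_formed(self, tmp_path):
        counts = pd.DataFrame({"s1": [1, 2, 3], "s2": [4, 5, 6]},
                              index=["g1", "g2", "g3"])
        paths = _write_dataset(tmp_path, counts,
                               {"g1": "mRNA", "g2": "miRNA", "g3": "lincRNA"},
                               {"s1": "a", "s2": "b"})
        m = read_count_matrix(*paths)
        assert m.counts.shape == (3, 2)
        assert list(m.biotype) == ["mRNA", "miRNA", "lincRNA"]

    def test_sample_missing_from_groups(self, tmp_path):
        counts = pd.DataFrame({"s1": [1], "s2": [2]}, index=["g1"])
        paths = _write_dataset(tmp_path, counts, {"g1": "mRNA"}, {"s1": "a"})
        with pytest.raises(MatrixFormatError, match="s2"):
            read_count_matrix(*paths)

    def test_negative_count(self, tmp_path):
        counts = pd.DataFrame({"s1": [1, -3]}, index=["g1", "g2"])
        paths = _write_dataset(tmp_path, counts,
                               {"g1": "mRNA", "g2": "mRNA"}, {"s1": "a"})
        with pytest.raises(MatrixFormatError, match="g2"):
            read_count_matrix(*paths)

    def test_unknown_biotype_rejected(self, tmp_path):
        counts = pd.DataFrame({"s1": [1]}, index=["g1"])
        paths = _write_dataset(tmp_path, counts, {"g1": "rRNA"}, {"s1": "a"})
        with pytest.raises(MatrixFormatError, match="rRNA"):
            read_count_matrix(*paths)


def _matrix(counts: np.ndarray) -> ExpressionMatrix:
    df = pd.DataFrame(counts, index=[f"g{i}" for i in range(counts.shape[0])],
                      columns=[f"s{j}" for j in range(counts.shape[1])])
    return ExpressionMatrix(
        counts=df,
        biotype=pd.Series("mRNA", index=df.index),
        group=pd.Series("a", index=df.columns),
    )


def _tmm_oracle_pair(counts: np.ndarray, s: int, ref: int) -> float:
    """Literal trim-and-weight TMM oracle for one sample vs a reference."""
    lib = counts.sum(axis=0)
    ys, yr = counts[:, s].astype(float), counts[:, ref].astype(float)
    ns, nr = lib[s], lib[ref]
    rows = [(math.log2((ys[g] / ns) / (yr[g] / nr)),
             0.5 * math.log2((ys[g] / ns) * (yr[g] / nr)),
             (ns - ys[g]) / (ns * ys[g]) + (nr - yr[g]) / (nr * yr[g]))
            for g in range(len(ys)) if ys[g] > 0 and yr[g] > 0]
    n = len(rows)
    by_m = sorted(range(n), key=lambda i: rows[i][0])
    by_a = sorted(range(n), key=lambda i: rows[i][1])
    lo_m = int(math.floor(0.30 * n))
    lo_a = int(math.floor(0.05 * n))
    keep = set(by_m[lo_m:n - lo_m]) & set(by_a[lo_a:n - lo_a])
    num = sum(rows[i][0] / rows[i][2] for i in keep)
    den = sum(1.0 / rows[i][2] for i in keep)
    return 2.0 ** (num / den)


class TestTMM:
    def test_identical_columns_unit_factors(self):
        counts = np.tile(np.array([[10], [200], [35], [7], [90], [3]]), (1, 2))
        f = tmm_factors(_matrix(counts))
        np.testing.assert_allclose(f.tmm_factor.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_scale_invariance(self):
        a = np.array([13, 220, 35, 7, 90, 3, 55, 18])
        counts = np.column_stack([a, 3 * a])
        f = tmm_factors(_matrix(counts))
        np.testing.assert_allclose(f.tmm_factor.to_numpy(), [1.0, 1.0], atol=1e-12)

    def test_matches_brute_force_oracle(self):
        # one dominant gene in sample A shifts the trimmed mean
        counts = np.array([[5000, 40], [30, 35], [60, 70], [110, 95],
                           [20, 22], [300, 280], [45, 50], [80, 88],
                           [15, 12], [200, 210]])
        m = _matrix(counts)
        f = tmm_factors(m, reference_sample="s1")
        raw = _tmm_oracle_pair(counts, 0, 1)
        # implementation rescales to geometric mean 1
        expected = np.array([raw, 1.0])
        expected /= np.exp(np.mean(np.log(expected)))
        np.testing.assert_allclose(f.tmm_factor.to_numpy(), expected, rtol=1e-10)

    def test_all_zero_sample_errors(self):
        counts = np.array([[0, 5], [0, 7]])
        with pytest.raises(ValueError, match="zero library"):
            tmm_factors(_matrix(counts))

    def test_geometric_mean_is_one(self):
        rng = np.random.default_rng(3)
        counts = rng.poisson(rng.gamma(2, 50, size=(50, 1)), size=(50, 6))
        f = tmm_factors(_matrix(counts))
        assert abs(np.mean(np.log(f.tmm_factor.to_numpy()))) < 1e-12


class TestCPM:
    def test_direct_arithmetic(self):
        m = _matrix(np.array([[100], [999900]]))
        f = NormalizationFactors(
            library_size=pd.Series([1e6], index=m.sample_ids),
            tmm_factor=pd.Series([1.0], index=m.sample_ids),
        )
        assert cpm(m, f).iloc[0, 0] == pytest.approx(100.0)

    def test_factor_scaling(self):
        m = _matrix(np.array([[5]]))
        f = NormalizationFactors(
            library_size=pd.Series([2e6], index=m.sample_ids),
            tmm_factor=pd.Series([0.5], index=m.sample_ids),
        )
        assert cpm(m, f).iloc[0, 0] == pytest.approx(5.0)

    def test_doubling_counts_leaves_cpm_unchanged(self):
        counts = np.array([[10, 10], [90, 90]])
        m1, m2 = _matrix(counts), _matrix(counts * np.array([2, 1]))
        c1 = cpm(m1, tmm_factors(m1))
        c2 = cpm(m2, tmm_factors(m2))
        np.testing.assert_allclose(c1.to_numpy(), c2.to_numpy(), rtol=1e-12)

    def test_rows_sum_to_million(self):
        m = _matrix(np.array([[10, 1], [90, 9], [900, 90]]))
        f = NormalizationFactors(
            library_size=m.counts.sum(),
            tmm_factor=pd.Series(1.0, index=m.sample_ids),
        )
        np.testing.assert_allclose(cpm(m, f).sum(axis=0), [1e6, 1e6])


class TestFilterExpressed:
    @pytest.fixture
    def cpm23(self):
        # 23 samples: gene passing in 12, gene passing in 11, dead lincRNA
        vals = np.zeros((3, 23))
        vals[0, :12] = 2.0
        vals[1, :11] = 1.5
        return pd.DataFrame(vals, index=["keep", "drop", "linc"],
                            columns=[f"s{i}" for i in range(23)])

    def test_half_of_samples_rule(self, cpm23):
        bio = pd.Series(["mRNA", "mRNA", "lincRNA"], index=cpm23.index)
        kept = filter_expressed(cpm23, bio)
        assert "keep" in kept          # 12 >= ceil(0.5 * 23) = 12
        assert "drop" not in kept      # 11 < 12
        assert "linc" in kept          # lincRNAs exempt

    def test_monotone_in_min_cpm(self, cpm23):
        bio = pd.Series("mRNA", index=cpm23.index)
        low = set(filter_expressed(cpm23, bio, min_cpm=0.5))
        high = set(filter_expressed(cpm23, bio, min_cpm=1.8))
        assert high <= low

    def test_empty_matrix_errors(self):
        with pytest.raises(ValueError):
            filter_expressed(pd.DataFrame(), pd.Series(dtype=object))


def _cap_oracle(x):
    """Independent quantile-rule capping oracle (type-7 quantiles)."""
    x = np.asarray(x, dtype=float)
    q1, q3 = np.quantile(x, [0.25, 0.75])
    iqr = q3 - q1
    if iqr == 0 or len(x) < 4:
        return x.copy()
    inside = x[(x >= q1 - 1.5 * iqr) & (x <= q3 + 1.5 * iqr)]
    p10, p90 = np.quantile(inside, [0.10, 0.90])
    return np.array([p90 if v > q3 + 1.5 * iqr
                     else p10 if v < q1 - 1.5 * iqr else v for v in x])


class TestCapOutliers:
    def test_no_outliers_unchanged(self):
        np.testing.assert_array_equal(cap_outliers(np.arange(1.0, 6.0)),
                                      np.arange(1.0, 6.0))

    def test_zero_iqr_unchanged(self):
        x = np.array([3.0, 3.0, 3.0, 3.0, 50.0])
        np.testing.assert_array_equal(cap_outliers(x), x)

    def test_upper_outlier_capped_to_oracle_value(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 100.0])
        out = cap_outliers(x)
        np.testing.assert_allclose(out, _cap_oracle(x))
        assert out[-1] < 100.0

    def test_short_vector_warns_and_passes_through(self):
        with pytest.warns(UserWarning):
            out = cap_outliers(np.array([1.0, 2.0, 900.0]))
        np.testing.assert_array_equal(out, [1.0, 2.0, 900.0])

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.floats(min_value=0, max_value=1e4, allow_nan=False),
                    min_size=8, max_size=30),
           st.floats(min_value=1e4, max_value=1e6))
    def test_idempotent_on_expression_like_vectors(self, base, spike):
        x = np.array(base + [spike])
        once = cap_outliers(x)
        np.testing.assert_allclose(cap_outliers(once), once, rtol=1e-12)
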