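import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twinconn import (
    TimeSeriesRun,
    average_runs,
    compute_fc_matrix,
    devectorize,
    edge_count,
    edge_index_to_node_pair,
    node_pair_to_edge_index,
    read_fc_matrix,
    read_time_series,
    vectorize_lower_triangle,
)


def _pearson_by_hand(a, b):
    """Covariance-formula oracle, independent of numpy.corrcoef."""
    am, bm = sum(a) / len(a), sum(b) / len(b)
    cov = sum((x - am) * (y - bm) for x, y in zip(a, b))
    va = sum((x - am) ** 2 for x in a)
    vb = sum((y - bm) ** 2 for y in b)
    return cov / (va * vb) ** 0.5


class TestComputeFcMatrix:
    def test_matches_hand_computed_pearson_on_toy_run(self):
        data = np.array(
            [[1.0, 2.0, 0.5], [2.0, 1.5, 1.0], [4.0, 3.0, 0.0], [3.0, 5.0, 2.0]]
        )
        z = compute_fc_matrix(TimeSeriesRun("s", "r1", data))
        for i in range(3):
            for j in range(i):
                r = _pearson_by_hand(data[:, i].tolist(), data[:, j].tolist())
                assert z[i, j] == pytest.approx(np.arctanh(r), abs=1e-12)
        assert np.allclose(z, z.T)
        assert np.all(np.diag(z) == 0)

    def test_perfectly_correlated_columns_clamp_to_large_z(self):
        col = np.array([1.0, 2.0, 3.0, 5.0])
        data = np.column_stack([col, col, -col])
        with pytest.warns(UserWarning, match="clamping"):
            z = compute_fc_matrix(TimeSeriesRun("s", "r1", data))
        assert z[1, 0] > 10  # atanh near 1
        assert z[2, 0] < -10
        assert np.isfinite(z).all()

    def test_zero_variance_column_errors_with_node_index(self):
        data = np.array([[1.0, 7.0], [2.0, 7.0], [3.0, 7.0]])
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_fc_matrix(TimeSeriesRun("s", "r1", data))

    def test_invariant_to_affine_rescaling_of_columns(self, rng):
        data = rng.standard_normal((30, 5))
        z1 = compute_fc_matrix(TimeSeriesRun("s", "r", data))
        scaled = data * np.array([2.0, 0.5, 10.0, 1.0, 3.0]) + np.arange(5)
        z2 = compute_fc_matrix(TimeSeriesRun("s", "r", scaled))
        assert np.allclose(z1, z2, atol=1e-10)

    def test_rejects_too_short_or_nonfinite_series(self):
        with pytest.raises(ValueError):
            TimeSeriesRun("s", "r", np.ones((1, 3)))
        with pytest.raises(ValueError, match="finite"):
            TimeSeriesRun("s", "r", np.array([[1.0, np.nan], [2.0, 3.0]]))


class TestAverageRuns:
    def test_identical_runs_average_to_themselves(self, rng):
        m = rng.standard_normal((4, 4))
        m = (m + m.T) / 2
        assert np.allclose(average_runs([m] * 4), m)

    def test_opposite_runs_cancel(self, rng):
        m = rng.standard_normal((3, 3))
        with pytest.warns(UserWarning, match="2 run"):
            out = average_runs([m, -m])
        assert np.allclose(out, 0)

    def test_two_matrix_mean_matches_per_entry_sums(self):
        a = np.arange(9.0).reshape(3, 3)
        b = np.ones((3, 3))
        with pytest.warns(UserWarning):
            out = average_runs([a, b])
        for i in range(3):
            for j in range(3):
                assert out[i, j] == (a[i, j] + b[i, j]) / 2

    def test_errors_on_empty_or_mismatched(self):
        with pytest.raises(ValueError, match="no matrices"):
            average_runs([])
        with pytest.raises(ValueError, match="mismatched"):
            average_runs([np.zeros((3, 3)), np.zeros((4, 4))])


class TestVectorization:
    def test_explicit_three_node_ordering(self):
        m = np.array([[0, 1, 2], [1, 0, 3], [2, 3, 0.0]])
        assert vectorize_lower_triangle(m).tolist() == [1.0, 2.0, 3.0]

    @pytest.mark.parametrize(
        "r,expected", [(3, 3), (10, 45), (268, 35778)]
    )
    def test_edge_vector_length(self, r, expected):
        assert edge_count(r) == expected
        assert vectorize_lower_triangle(np.zeros((r, r))).size == expected

    def test_round_trip_is_exact(self, rng):
        for r in (3, 8, 20):
            m = rng.standard_normal((r, r))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0.0)
            v = vectorize_lower_triangle(m)
            assert np.array_equal(devectorize(v), m)
            assert np.array_equal(vectorize_lower_triangle(devectorize(v)), v)

    def test_asymmetric_matrix_rejected(self):
        m = np.array([[0, 1.0], [2.0, 0]])
        with pytest.raises(ValueError, match="asymmetric"):
            vectorize_lower_triangle(m)


class TestEdgeIndexMaps:
    def test_first_edge(self):
        assert edge_index_to_node_pair(0, 3) == (1, 0)

    def test_last_edge_matches_enumeration_oracle(self):
        pairs = [(i, j) for i in range(10) for j in range(i)]
        assert edge_index_to_node_pair(44, 10) == pairs[44] == (9, 8)
        for k, (i, j) in enumerate(pairs):
            assert edge_index_to_node_pair(k, 10) == (i, j)

    def test_bijection_round_trip(self):
        r = 8
        seen = set()
        for k in range(edge_count(r)):
            i, j = edge_index_to_node_pair(k, r)
            assert i > j
            assert node_pair_to_edge_index(i, j, r) == k
            assert node_pair_to_edge_index(j, i, r) == k  # unordered
            seen.add((i, j))
        assert len(seen) == edge_count(r)

    def test_out_of_range_and_diagonal_errors(self):
        with pytest.raises(IndexError):
            edge_index_to_node_pair(3, 3)
        with pytest.raises(ValueError):
            node_pair_to_edge_index(2, 2, 5)


@settings(max_examples=25, deadline=None)
@given(st.integers(min_value=3, max_value=12), st.integers(0, 2**31 - 1))
def test_vectorize_devectorize_identity_property(r, seed):
    v = np.random.default_rng(seed).standard_normal(edge_count(r))
    assert np.array_equal(vectorize_lower_triangle(devectorize(v)), v)


def test_delimited_io_round_trip(tmp_path, rng):
    data = rng.standard_normal((20, 4))
    path = tmp_path / "SUBJ01_run2.tsv"
    header = "\t".join(f"roi{i}" for i in range(4))
    np.savetxt(path, data, delimiter="\t", header=header, comments="")
    ts = read_time_series(path)
    assert ts.subject_id == "SUBJ01" and ts.run_id == "run2"
    assert np.allclose(ts.data, data)

    z = compute_fc_matrix(ts)
    mat_path = tmp_path / "fc.csv"
    np.savetxt(mat_path, z, delimiter=",")
    assert np.allclose(read_fc_matrix(mat_path), z)
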