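import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from hic3d import (
    ContactMap,
    ContactMapError,
    filter_empty_bins,
    ice_normalize,
    prefilter_low_if,
    read_contact_map,
    scn_normalize,
    write_contact_map,
)


def _write(tmp_path, text, name="map.txt"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestRead:
    def test_dense_parse(self, tmp_path):
        cm = read_contact_map(_write(tmp_path, "0 2\n2 0\n"))
        assert cm.n_bins == 2
        assert cm.matrix[0, 1] == 2

    def test_dense_symmetrized_by_averaging(self, tmp_path):
        cm = read_contact_map(_write(tmp_path, "0 1\n2 0\n"))
        assert cm.matrix[0, 1] == pytest.approx(1.5)
        assert cm.matrix[1, 0] == pytest.approx(1.5)

    def test_coo_symmetry_fill_and_zeros(self, tmp_path):
        cm = read_contact_map(_write(tmp_path, "0 1 5\n"), format="coo", n_bins=3)
        assert cm.n_bins == 3
        assert cm.matrix[0, 1] == 5 and cm.matrix[1, 0] == 5
        assert cm.matrix[0, 2] == 0 and cm.matrix[2, 2] == 0

    def test_coo_duplicates_summed(self, tmp_path):
        cm = read_contact_map(
            _write(tmp_path, "0 1 5\n0 1 2\n"), format="coo", n_bins=2
        )
        assert cm.matrix[0, 1] == 7

    def test_coo_one_based_dialect(self, tmp_path):
        cm = read_contact_map(
            _write(tmp_path, "1 2 3\n"), format="coo", n_bins=2, one_based=True
        )
        assert cm.matrix[0, 1] == 3

    def test_non_square_dense_rejected(self, tmp_path):
        with pytest.raises(ContactMapError, match="square"):
            read_contact_map(_write(tmp_path, "0 1 2\n1 0 3\n"))

    def test_negative_if_rejected_with_location(self, tmp_path):
        with pytest.raises(ContactMapError, match="row 2"):
            read_contact_map(_write(tmp_path, "0 1\n-1 0\n"))

    def test_coo_out_of_range_names_entry(self, tmp_path):
        with pytest.raises(ContactMapError, match="0..2"):
            read_contact_map(_write(tmp_path, "0 5 1\n"), format="coo", n_bins=3)

    def test_coo_bad_line_number_in_message(self, tmp_path):
        with pytest.raises(ContactMapError, match=":2:"):
            read_contact_map(_write(tmp_path, "0 1 5\n0 x 1\n"), format="coo")

    def test_round_trip_dense_and_coo(self, tmp_path, small_map):
        for fmt in ("dense", "coo"):
            path = tmp_path / f"rt.{fmt}"
            write_contact_map(small_map, path, format=fmt)
            back = read_contact_map(path, format=fmt, n_bins=small_map.n_bins)
            np.testing.assert_allclose(back.matrix, small_map.matrix, rtol=1e-6)


class TestFilterEmptyBins:
    def test_removes_zero_row(self):
        m = np.zeros((3, 3))
        m[0, 2] = m[2, 0] = 1.0
        out = filter_empty_bins(ContactMap(m))
        assert out.n_bins == 2
        assert list(out.active_bins) == [0, 2]

    def test_identity_when_no_empty_rows(self, small_map):
        out = filter_empty_bins(small_map)
        assert out.n_bins == 4
        np.testing.assert_array_equal(out.matrix, small_map.matrix)

    def test_multiple_empty_rows(self):
        m = np.zeros((4, 4))
        m[1, 2] = m[2, 1] = 3.0
        out = filter_empty_bins(ContactMap(m))
        assert list(out.active_bins) == [1, 2]

    def test_diagonal_only_bin_is_empty(self):
        m = np.zeros((3, 3))
        m[0, 0] = 7.0
        m[1, 2] = m[2, 1] = 1.0
        out = filter_empty_bins(ContactMap(m))
        assert list(out.active_bins) == [1, 2]

    def test_idempotent(self, small_map):
        once = filter_empty_bins(small_map)
        twice = filter_empty_bins(once)
        np.testing.assert_array_equal(once.matrix, twice.matrix)
        np.testing.assert_array_equal(once.active_bins, twice.active_bins)

    def test_all_empty_rejected(self):
        with pytest.raises(ContactMapError, match="no informative bins"):
            filter_empty_bins(ContactMap(np.zeros((3, 3))))


def _random_positive_map(rng, n):
    a = rng.uniform(0.5, 5.0, size=(n, n))
    a = (a + a.T) / 2
    np.fill_diagonal(a, 0.0)
    return ContactMap(a)


class TestIce:
    def test_balanced_input_scaled_to_unit_row_sums(self):
        out = ice_normalize(ContactMap([[0.0, 4.0], [4.0, 0.0]]))
        np.testing.assert_allclose(out.matrix.sum(axis=1), 1.0, atol=1e-9)
        assert out.matrix[0, 1] == pytest.approx(1.0)

    def test_row_sums_equalized(self, rng):
        out = ice_normalize(_random_positive_map(rng, 5))
        s = out.matrix.sum(axis=1)
        np.testing.assert_allclose(s, s.mean(), rtol=1e-6)

    def test_scale_invariance(self):
        a = ice_normalize(ContactMap([[0.0, 2.0], [2.0, 0.0]]))
        b = ice_normalize(ContactMap([[0.0, 8.0], [8.0, 0.0]]))
        np.testing.assert_allclose(a.matrix, b.matrix, atol=1e-12)

    def test_fixpoint_under_second_pass(self, rng):
        once = ice_normalize(_random_positive_map(rng, 6))
        twice = ice_normalize(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, rtol=1e-5)

    def test_zeros_preserved(self, small_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = ice_normalize(small_map)
        assert out.matrix[0, 3] == 0.0

    def test_zero_row_precondition(self):
        m = np.zeros((3, 3))
        m[0, 1] = m[1, 0] = 1.0
        with pytest.raises(ContactMapError):
            ice_normalize(ContactMap(m))

    def test_non_convergence_warns(self, rng):
        cm = _random_positive_map(rng, 5)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            out = ice_normalize(cm, max_iters=1, tol=1e-15)
        assert not out.balanced


class TestScn:
    def test_two_bin_unit_norm(self):
        out = scn_normalize(ContactMap([[0.0, 3.0], [3.0, 0.0]]))
        np.testing.assert_allclose(out.matrix, [[0, 1], [1, 0]], atol=1e-9)

    def test_converges_to_symmetric(self, rng):
        out = scn_normalize(_random_positive_map(rng, 6))
        assert out.balanced
        np.testing.assert_allclose(out.matrix, out.matrix.T, atol=1e-6)

    def test_idempotent_at_fixpoint(self, rng):
        once = scn_normalize(_random_positive_map(rng, 5))
        twice = scn_normalize(once)
        np.testing.assert_allclose(once.matrix, twice.matrix, atol=1e-4)

    def test_zeros_preserved(self, small_map):
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            out = scn_normalize(small_map)
        assert out.matrix[0, 3] == 0.0


class TestPrefilter:
    def test_quantile_zero_identity(self, small_map):
        out = prefilter_low_if(small_map, 0.0)
        np.testing.assert_array_equal(out.matrix, small_map.matrix)

    def test_median_rule_on_four_entries(self):
        m = np.zeros((5, 5))
        for k, v in enumerate([1.0, 2.0, 3.0, 4.0]):
            m[k, k + 1] = m[k + 1, k] = v
        out = prefilter_low_if(ContactMap(m), 0.5)
        kept = sorted(out.matrix[out.matrix > 0])
        # median of {1,2,3,4} is 2.5; entries strictly below are zeroed
        assert kept == [3.0, 3.0, 4.0, 4.0]

    def test_quantile_one_keeps_only_max(self, small_map):
        out = prefilter_low_if(small_map, 1.0)
        assert set(out.matrix[out.matrix > 0]) == {5.0}

    def test_bad_quantile_rejected(self, small_map):
        with pytest.raises(ValueError):
            prefilter_low_if(small_map, 1.5)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    arrays(
        np.float64,
        (5, 5),
        elements=st.floats(0.1, 10.0, allow_nan=False),
    )
)
def test_normalizers_preserve_symmetry_and_nonnegativity(a):
    """Every normalization keeps the map symmetric and non-negative."""
    m = (a + a.T) / 2
    np.fill_diagonal(m, 0.0)
    cm = ContactMap(m)
    for fn in (ice_normalize, scn_normalize, lambda c: prefilter_low_if(c, 0.3)):
        out = fn(cm)
        assert np.all(out.matrix >= 0)
        np.testing.assert_allclose(out.matrix, out.matrix.T, atol=1e-9)
        # no nonzero entries created where the input had exact zeros
        assert np.all(out.matrix[m == 0] == 0)
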