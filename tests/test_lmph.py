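import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from lmphmap import (
    ConfigurationError,
    DegenerateTrainingError,
    HistogramSpec,
    apply_conversion,
    build_conversion,
    build_histograms,
    compute_lmph,
    compute_lmph_array,
)


def _table(values, classes, pid="p0"):
    return pd.DataFrame(
        {
            "patient_id": pid,
            "rt1t2": np.asarray(values, dtype=float),
            "met_class": np.asarray(classes),
        }
    )


class TestHistogramSpec:
    def test_default_binning(self):
        spec = HistogramSpec()
        assert spec.n_bins == 50
        assert spec.bin_edges[0] == pytest.approx(0.3)
        assert spec.bin_edges[-1] == pytest.approx(1.3)

    def test_uneven_width_rejected(self):
        with pytest.raises(ConfigurationError):
            HistogramSpec(lo=0.0, hi=1.0, bin_width=0.3)

    def test_interior_edge_goes_right(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.25)
        assert spec.assign_bins(np.array([0.25]))[0] == 1

    def test_top_edge_in_last_bin(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.25)
        assert spec.assign_bins(np.array([1.0]))[0] == 3

    def test_out_of_range_flagged(self):
        spec = HistogramSpec()
        bins = spec.assign_bins(np.array([0.2, 1.4, np.nan, 0.3, 1.3]))
        assert list(bins[:3]) == [-1, -1, -1]
        assert bins[3] == 0 and bins[4] == 49


class TestBuildHistograms:
    def test_counts_by_class(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.5)
        table = _table([0.1, 0.2, 0.3, 0.4, 0.7], ["high"] * 4 + ["low"])
        nH, nL, NH, NL = build_histograms(table, spec)
        assert list(nH) == [4, 0] and list(nL) == [0, 1]
        assert (NH, NL) == (4, 1)

    def test_out_of_range_excluded_from_totals(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.5)
        table = _table([0.1, 1.5, -0.2], ["high", "high", "low"])
        nH, nL, NH, NL = build_histograms(table, spec)
        assert (NH, NL) == (1, 0)

    def test_empty_table_rejected(self):
        with pytest.raises(ConfigurationError):
            build_histograms(_table([], []), HistogramSpec())


class TestComputeLmph:
    @pytest.mark.parametrize(
        "nH_k,nL_k,NH,NL,expected",
        [
            (0, 5, 10, 50, -1.0),
            (5, 0, 10, 50, 1.0),
            (2, 10, 10, 50, 0.0),           # balanced proportions
            (3, 1, 10, 20, 5.0 / 7.0),      # (0.30-0.05)/(0.30+0.05)
            (1, 1, 10, 10, 0.0),
        ],
    )
    def test_known_values(self, nH_k, nL_k, NH, NL, expected):
        assert compute_lmph(nH_k, nL_k, NH, NL) == pytest.approx(expected, abs=1e-12)

    def test_undefined_iff_both_zero(self):
        assert math.isnan(compute_lmph(0, 0, 10, 10))
        assert not math.isnan(compute_lmph(0, 1, 10, 10))

    def test_inconsistent_totals_rejected(self):
        from lmphmap import InconsistencyError

        with pytest.raises(InconsistencyError):
            compute_lmph(3, 0, 0, 10)

    @given(
        nH_k=st.integers(0, 30), nL_k=st.integers(0, 30),
        NH=st.integers(30, 100), NL=st.integers(30, 100),
    )
    @settings(deadline=None)
    def test_bounds_and_endpoint_conditions(self, nH_k, nL_k, NH, NL):
        v = compute_lmph(nH_k, nL_k, NH, NL)
        if nH_k == 0 and nL_k == 0:
            assert math.isnan(v)
        else:
            assert -1.0 <= v <= 1.0
            assert (v == 1.0) == (nL_k == 0 < nH_k)
            assert (v == -1.0) == (nH_k == 0 < nL_k)

    def test_monotone_in_high_proportion(self):
        values = [compute_lmph(k, 5, 50, 50) for k in range(1, 51)]
        assert all(a < b for a, b in zip(values, values[1:]))


class TestConversionProperties:
    @given(st.data())
    @settings(deadline=None, max_examples=50)
    def test_antisymmetry_and_class_scale_invariance(self, data):
        n_bins = data.draw(st.integers(2, 12))
        nH = np.array(data.draw(st.lists(st.integers(0, 20), min_size=n_bins, max_size=n_bins)))
        nL = np.array(data.draw(st.lists(st.integers(0, 20), min_size=n_bins, max_size=n_bins)))
        NH, NL = int(nH.sum()), int(nL.sum())
        if NH == 0 or NL == 0:
            return
        base = compute_lmph_array(nH, nL, NH, NL)
        swapped = compute_lmph_array(nL, nH, NL, NH)
        np.testing.assert_allclose(swapped, -base, atol=1e-12)
        m = data.draw(st.integers(1, 7))
        scaled = compute_lmph_array(m * nH, nL, m * NH, NL)
        np.testing.assert_allclose(scaled, base, atol=1e-12)

    def test_separated_classes_hit_endpoints(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.25)
        table = _table([0.1, 0.15, 0.6, 0.7], ["high", "high", "low", "low"])
        conv = build_conversion(table, spec)
        assert conv.lmph[0] == 1.0
        assert conv.lmph[2] == -1.0
        assert np.isnan(conv.lmph[1]) and np.isnan(conv.lmph[3])

    def test_identical_distributions_give_zero(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.5)
        table = _table([0.1, 0.6, 0.1, 0.6], ["high", "high", "low", "low"])
        conv = build_conversion(table, spec)
        np.testing.assert_allclose(conv.lmph, 0.0, atol=1e-12)

    def test_single_class_training_rejected(self):
        table = _table([0.5, 0.6], ["low", "low"])
        with pytest.raises(DegenerateTrainingError):
            build_conversion(table, HistogramSpec())

    def test_training_voxels_all_scored(self, small_table):
        """Applying a conversion to its own training values defines every retained voxel."""
        spec = HistogramSpec()
        conv = build_conversion(small_table, spec)
        bins = spec.assign_bins(small_table["rt1t2"].to_numpy())
        in_range = bins >= 0
        assert np.isfinite(conv.lmph[bins[in_range]]).all()


class TestApplyConversion:
    def _conv(self):
        spec = HistogramSpec(lo=0.0, hi=1.0, bin_width=0.25)
        table = _table(
            [0.1, 0.1, 0.1, 0.3, 0.1, 0.35, 0.6, 0.6],
            ["high", "high", "high", "high", "low", "low", "low", "low"],
        )
        return build_conversion(table, spec)

    def test_single_bin_lookup(self):
        conv = self._conv()
        expected = compute_lmph(int(conv.nH[1]), int(conv.nL[1]), conv.NH, conv.NL)
        ratio = np.full((3, 3, 3), 0.375)  # center of bin 1
        voi = np.ones_like(ratio, dtype=np.uint8)
        out = apply_conversion(ratio, voi, conv)
        assert np.allclose(out, expected)

    def test_undefined_bin_and_out_of_range_excluded(self):
        conv = self._conv()
        ratio = np.array([[[0.8, -0.5, 0.1, 1.2]]])  # bin3 empty, below lo, bin0, above hi
        voi = np.ones_like(ratio, dtype=np.uint8)
        out = apply_conversion(ratio, voi, conv)
        assert np.isnan(out[0, 0, 0]) and np.isnan(out[0, 0, 1]) and np.isnan(out[0, 0, 3])
        assert np.isfinite(out[0, 0, 2])

    def test_outside_voi_is_nan(self):
        conv = self._conv()
        ratio = np.full((2, 2, 2), 0.1)
        voi = np.zeros_like(ratio, dtype=np.uint8)
        voi[0, 0, 0] = 1
        out = apply_conversion(ratio, voi, conv)
        assert np.isfinite(out[0, 0, 0]) and np.isnan(out[1, 1, 1])


def test_conversion_csv_round_trip(tmp_path, small_table):
    conv = build_conversion(small_table)
    path = tmp_path / "conversion.csv"
    conv.save(path)
    back = type(conv).load(path)
    np.testing.assert_array_equal(back.nH, conv.nH)
    np.testing.assert_array_equal(back.nL, conv.nL)
    np.testing.assert_allclose(back.lmph, conv.lmph, atol=1e-12, equal_nan=True)
    assert (back.NH, back.NL) == (conv.NH, conv.NL)
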