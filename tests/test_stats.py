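"""Cellularity, percent-area immunopositivity and Mann-Whitney comparison."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import mannwhitneyu as scipy_mwu

from conftest import enumeration_two_sided_p, pair_count_u
from tilecyte.datatypes import LINING, SUBLINING, ChannelImage, NucleusSet, RegionMask
from tilecyte.errors import EmptyROIError, TilecyteError
from tilecyte.stats import (
    cellularity,
    compare_compositions,
    mann_whitney_u,
    percent_area_positive,
)


class TestCellularity:
    def test_density_definition(self):
        # 1 mm^2 lining region at 10 µm pixels: 100x100 px
        labels = np.full((100, 100), LINING, dtype=np.int8)
        mask = RegionMask(labels, pixel_size=10.0)
        rng = np.random.default_rng(0)
        pts = rng.choice(100 * 100, size=10, replace=False)
        nuclei = NucleusSet(
            np.column_stack([pts // 100, pts % 100]).astype(float)
        )
        table = cellularity(nuclei, mask).set_index("region")
        assert table.loc["lining", "count"] == 10
        assert table.loc["lining", "area_mm2"] == pytest.approx(1.0)
        assert table.loc["lining", "density_per_mm2"] == pytest.approx(10.0)
        assert np.isnan(table.loc["sub-lining", "density_per_mm2"])

    def test_empty_nucleus_set_counts_zero(self, band_mask):
        table = cellularity(NucleusSet.empty(), band_mask).set_index("region")
        assert (table["count"] == 0).all()

    def test_counts_match_ground_truth_regions(self, small_sample):
        table = cellularity(small_sample.nuclei, small_sample.region_mask)
        truth_counts = small_sample.truth["region"].value_counts()
        t = table.set_index("region")["count"]
        assert t["lining"] == truth_counts.get("lining", 0)
        assert t["sub-lining"] == truth_counts.get("sub-lining", 0)
        assert t["total"] == t["lining"] + t["sub-lining"]


class TestPercentAreaPositive:
    def _mask(self, h, w):
        return RegionMask(np.full((h, w), SUBLINING, dtype=np.int8), pixel_size=2.0)

    def test_all_none_and_half_positive(self):
        mask = self._mask(4, 4)
        high = ChannelImage(np.full((4, 4), 9.0), "DAB")
        low = ChannelImage(np.zeros((4, 4)), "DAB")
        checker = ChannelImage(np.indices((4, 4)).sum(0) % 2 * 10.0, "DAB")
        assert percent_area_positive(high, mask, 1.0).percent_area_positive == 100.0
        assert percent_area_positive(low, mask, 1.0).percent_area_positive == 0.0
        assert percent_area_positive(checker, mask, 5.0).percent_area_positive == 50.0

    def test_normalized_to_nuclei_count(self):
        mask = self._mask(4, 4)  # 2 µm pixels
        res = percent_area_positive(
            ChannelImage(np.full((4, 4), 9.0), "DAB"), mask, 1.0, nuclei_count=8
        )
        assert res.positive_area_per_nucleus == pytest.approx(16 * 4.0 / 8)
        res0 = percent_area_positive(
            ChannelImage(np.full((4, 4), 9.0), "DAB"), mask, 1.0, nuclei_count=0
        )
        assert res0.positive_area_per_nucleus is None

    def test_monotone_in_threshold(self):
        rng = np.random.default_rng(2)
        stain = ChannelImage(rng.random((16, 16)) * 10, "DAB")
        mask = self._mask(16, 16)
        fracs = [
            percent_area_positive(stain, mask, t).percent_area_positive
            for t in np.linspace(0, 10, 11)
        ]
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))

    def test_empty_roi_rejected(self):
        mask = RegionMask(np.zeros((4, 4), dtype=np.int8))
        with pytest.raises(EmptyROIError):
            percent_area_positive(ChannelImage(np.ones((4, 4)), "DAB"), mask, 0.5)


class TestMannWhitney:
    def test_worked_example_u0(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3)
        assert res.method == "exact"

    def test_worked_example_u1(self):
        res = mann_whitney_u([1, 3], [2, 4])
        assert res.u_statistic == 1.0
        assert res.p_value == pytest.approx(2 / 3)

    def test_complete_tie_degenerate_distribution(self):
        res = mann_whitney_u([5], [5])
        assert res.u_statistic == 0.5
        assert res.p_value == 1.0

    def test_empty_sample_rejected(self):
        with pytest.raises(TilecyteError):
            mann_whitney_u([], [1.0])

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.integers(0, 5), min_size=1, max_size=5),
        b=st.lists(st.integers(0, 5), min_size=1, max_size=5),
    )
    def test_exact_path_matches_enumeration_oracle(self, a, b):
        res = mann_whitney_u(a, b)
        assert res.u_statistic == pytest.approx(pair_count_u(a, b))
        assert res.p_value == pytest.approx(enumeration_two_sided_p(a, b))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        a=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6),
        b=st.lists(st.floats(0, 100, allow_nan=False), min_size=1, max_size=6),
    )
    def test_group_swap_symmetry(self, a, b):
        r1 = mann_whitney_u(a, b)
        r2 = mann_whitney_u(b, a)
        assert r1.u_statistic + r2.u_statistic == pytest.approx(len(a) * len(b))
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_u_statistic_agrees_with_scipy(self):
        rng = np.random.default_rng(5)
        for _ in range(10):
            a = rng.normal(size=8)
            b = rng.normal(size=9)
            res = mann_whitney_u(a, b)
            assert res.u_statistic == pytest.approx(
                float(scipy_mwu(a, b, alternative="two-sided").statistic)
            )

    def test_normal_approximation_close_to_exact(self, monkeypatch):
        # tie-free n1 = n2 = 10 through both formulas on the same samples
        from tilecyte import stats as tstats

        rng = np.random.default_rng(8)
        for _ in range(5):
            a = rng.normal(0, 1, size=10)
            b = rng.normal(0.4, 1, size=10)
            exact = mann_whitney_u(a, b)
            assert exact.method == "exact"
            monkeypatch.setattr(tstats, "EXACT_MAX_POOLED_N", 0)
            approx = tstats.mann_whitney_u(a, b)
            monkeypatch.undo()
            assert approx.method == "normal_approximation"
            assert abs(approx.p_value - exact.p_value) <= 0.02


class TestCompareCompositions:
    @staticmethod
    def _composition(values_by_group):
        rows = []
        for group, vals in values_by_group.items():
            for k, v in enumerate(vals, 1):
                rows.append(
                    {
                        "sample": f"{group}_{k}",
                        "group": group,
                        "region": "combined",
                        "type": "DKK3",
                        "proportion_pct": v,
                    }
                )
        return pd.DataFrame(rows)

    def test_identical_groups_give_p_one(self):
        comp = self._composition({"a": [10, 20, 30], "b": [10, 20, 30]})
        res = compare_compositions(comp)
        assert (res["p"] == 1.0).all()

    def test_consistent_with_unit_operation(self):
        comp = self._composition({"a": [65, 66], "b": [50, 51]})
        res = compare_compositions(comp)
        unit = mann_whitney_u([65, 66], [50, 51])
        row = res.iloc[0]
        assert row["U"] == unit.u_statistic
        assert row["p"] == unit.p_value
        assert row["method"] == "exact"

    def test_extra_endpoints_and_bh_column(self):
        comp = self._composition({"a": [65, 66, 70], "b": [50, 51, 52]})
        res = compare_compositions(
            comp, extra_endpoints={"cellularity_total": ([5, 6, 7], [9, 10, 11])},
            adjust=True,
        )
        assert set(res["endpoint"]) == {"composition", "cellularity_total"}
        assert "p_bh" in res.columns
        assert (res["p_bh"] >= res["p"] - 1e-12).all()
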