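"""Lexis decomposition: exact additivity, cause split, elimination."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import tcalkit as tk
from tcalkit.decomposition import (
    cause_contribution_table,
    decompose_gap,
    elimination_gap_change,
    neoplasm_gap_scenarios,
    split_by_cause,
)
from tcalkit.tcal import compute_tcal

from conftest import time_invariant_surface


def random_pair(seed, n_ages=15, n_years=8, scale=0.3):
    rng = np.random.default_rng(seed)
    years = np.arange(2020 - n_years, 2020)
    f = tk.MortalitySurface(
        "female", np.arange(n_ages), years, rng.uniform(0, scale, (n_ages, n_years))
    )
    m = tk.MortalitySurface(
        "male", np.arange(n_ages), years, rng.uniform(0, scale, (n_ages, n_years))
    )
    return f, m


class TestDecomposeGap:
    def test_identical_surfaces_give_zero_everywhere(self):
        f, _ = random_pair(0)
        m = tk.MortalitySurface("male", f.ages, f.years, f.rates)
        d = decompose_gap(f, m, 2020, 2012)
        assert np.all(d.cells == 0)
        assert d.total_gap == 0

    def test_single_cell_perturbation_localised_to_crossing_diagonals(self):
        f, _ = random_pair(1)
        rates_m = f.rates.copy()
        rates_m[5, 3] += 0.1  # age 5, year 2015
        m = tk.MortalitySurface("male", f.ages, f.years, rates_m)
        d = decompose_gap(f, m, 2020, 2012)
        nonzero = np.argwhere(d.cells != 0)
        assert nonzero.tolist() == [[5, 3]]
        gap = compute_tcal(f, 2020, 2012).value - compute_tcal(m, 2020, 2012).value
        assert d.cells.sum() == pytest.approx(gap, abs=1e-12)

    def test_antisymmetry_cellwise(self):
        f, m = random_pair(2)
        d_fm = decompose_gap(f, m, 2020, 2012)
        d_mf = decompose_gap(
            tk.MortalitySurface("female", m.ages, m.years, m.rates),
            tk.MortalitySurface("male", f.ages, f.years, f.rates),
            2020, 2012,
        )
        assert np.allclose(d_fm.cells, -d_mf.cells, atol=1e-15)

    @given(st.integers(0, 2**31 - 1), st.integers(3, 20), st.integers(1, 10))
    def test_exact_additivity_property(self, seed, n_ages, n_years):
        f, m = random_pair(seed, n_ages=n_ages, n_years=n_years)
        d = decompose_gap(f, m, 2020, 2020 - n_years)
        assert d.cells.sum() == pytest.approx(d.total_gap, abs=1e-10)

    def test_cell_sums_equal_independent_tcal_difference(self):
        f, m = random_pair(3, n_ages=5, n_years=5)
        d = decompose_gap(f, m, 2020, 2015)
        gap = compute_tcal(f, 2020, 2015).value - compute_tcal(m, 2020, 2015).value
        assert d.cells.sum() == pytest.approx(gap, abs=1e-12)

    def test_cohort_totals_sum_to_gap(self):
        f, m = random_pair(4)
        d = decompose_gap(f, m, 2020, 2012)
        assert d.cohort_totals().sum() == pytest.approx(d.total_gap, abs=1e-10)


def make_cause_rates(surface, shares):
    """Constant-share split of a surface into cause surfaces."""
    return {
        c: surface.with_rates(surface.rates * s) for c, s in shares.items()
    }


class TestSplitByCause:
    def test_single_cause_carries_whole_cell(self):
        f, m = random_pair(5)
        d = decompose_gap(f, m, 2020, 2012)
        d = split_by_cause(d, {"all": f}, {"all": m})
        assert np.allclose(d.per_cause["all"], d.cells, atol=1e-15)

    def test_opposite_sign_cause_contribution(self):
        # male all-cause higher, but cause 'x' higher in females
        ages, years = np.arange(3), np.array([2019])
        f = tk.MortalitySurface("female", ages, years, np.full((3, 1), 0.10))
        m = tk.MortalitySurface("male", ages, years, np.full((3, 1), 0.15))
        crf = {"x": f.with_rates(np.full((3, 1), 0.08)),
               "y": f.with_rates(np.full((3, 1), 0.02))}
        crm = {"x": m.with_rates(np.full((3, 1), 0.05)),
               "y": m.with_rates(np.full((3, 1), 0.10))}
        d = split_by_cause(decompose_gap(f, m, 2020, 2019), crf, crm)
        assert np.all(d.cells > 0)  # overall female advantage
        assert np.all(d.per_cause["x"] < 0)  # female excess in cause x
        assert np.allclose(
            d.per_cause["x"] + d.per_cause["y"], d.cells, atol=1e-12
        )

    def test_equal_rates_guard_assigns_zero(self):
        f, _ = random_pair(6)
        m = tk.MortalitySurface("male", f.ages, f.years, f.rates)
        d = split_by_cause(
            decompose_gap(f, m, 2020, 2012),
            make_cause_rates(f, {"a": 0.5, "b": 0.5}),
            make_cause_rates(m, {"a": 0.5, "b": 0.5}),
        )
        assert np.all(d.per_cause["a"] == 0)
        assert np.all(d.per_cause["b"] == 0)

    def test_differing_cause_sets_rejected(self):
        f, m = random_pair(7)
        d = decompose_gap(f, m, 2020, 2012)
        with pytest.raises(ValueError, match="differ"):
            split_by_cause(d, {"a": f}, {"b": m})


class TestContributionTable:
    def test_cause_totals_sum_to_gap(self, paper_expected):
        f = paper_expected["female"]["rates"]
        m = paper_expected["male"]["rates"]
        d = split_by_cause(
            decompose_gap(f, m, 2020, 1955),
            paper_expected["female"]["cause_rates"],
            paper_expected["male"]["cause_rates"],
        )
        table = cause_contribution_table(d).set_index("cause")["contribution_years"]
        assert table.drop("total").sum() == pytest.approx(d.total_gap, abs=1e-9)
        # female-only midlife cancers reduce the female advantage
        assert table["breast"] < 0
        assert table["gynecological"] < 0

    def test_identical_cause_rates_contribute_zero(self):
        base_f, base_m = random_pair(8)
        shared_rates = np.full_like(base_f.rates, 0.01)
        f = base_f.with_rates(base_f.rates + shared_rates)
        m = base_m.with_rates(base_m.rates + shared_rates)
        crf = {"same": f.with_rates(shared_rates), "rest": base_f}
        crm = {"same": m.with_rates(shared_rates), "rest": base_m}
        d = split_by_cause(decompose_gap(f, m, 2020, 2012), crf, crm)
        table = cause_contribution_table(d).set_index("cause")["contribution_years"]
        assert table["same"] == pytest.approx(0.0, abs=1e-12)

    def test_missing_split_rejected(self):
        f, m = random_pair(9)
        with pytest.raises(ValueError, match="per-cause"):
            cause_contribution_table(decompose_gap(f, m, 2020, 2012))


class TestElimination:
    def build(self):
        m_vec = np.full(30, 0.02)
        f = time_invariant_surface(m_vec, 20, sex="female")
        m = time_invariant_surface(m_vec * 1.5, 20, sex="male")
        zero_f = f.with_rates(np.zeros_like(f.rates))
        zero_m = m.with_rates(np.zeros_like(m.rates))
        fem_only = f.with_rates(np.full_like(f.rates, 0.005))
        male_only = m.with_rates(np.full_like(m.rates, 0.005))
        crf = {"fem": fem_only, "mal": zero_f,
               "nil": zero_f, "rest": f.with_rates(f.rates - 0.005)}
        crm = {"fem": zero_m, "mal": male_only,
               "nil": zero_m, "rest": m.with_rates(m.rates - 0.005)}
        return f, m, crf, crm

    def test_absent_cause_changes_nothing(self):
        f, m, crf, crm = self.build()
        before, after = elimination_gap_change(f, m, crf, crm, {"nil"}, 2020, 2000)
        assert after == pytest.approx(before, abs=1e-12)

    def test_female_only_cause_deletion_widens_gap(self):
        f, m, crf, crm = self.build()
        before, after = elimination_gap_change(f, m, crf, crm, {"fem"}, 2020, 2000)
        assert after > before

    def test_male_only_cause_deletion_narrows_gap(self):
        f, m, crf, crm = self.build()
        before, after = elimination_gap_change(f, m, crf, crm, {"mal"}, 2020, 2000)
        assert after < before


class TestNeoplasmScenarios:
    def test_scenario_ordering_on_preset(self, paper_expected):
        table = neoplasm_gap_scenarios(
            paper_expected["female"]["rates"],
            paper_expected["male"]["rates"],
            paper_expected["female"]["cause_rates"],
            paper_expected["male"]["cause_rates"],
            2020, 1955,
        ).set_index("scenario")["neoplasm_contribution_years"]
        assert table["minus_both"] >= table["minus_breast"] >= table["observed"]
        assert table["minus_both"] >= table["minus_gynecological"] >= table["observed"]

    def test_no_reproductive_mortality_all_rows_equal(self):
        f, m = random_pair(10)
        zero = f.with_rates(np.zeros_like(f.rates))
        crf = {"breast": zero, "gynecological": zero, "other_cancers": f}
        zm = m.with_rates(np.zeros_like(m.rates))
        crm = {"breast": zm, "gynecological": zm, "other_cancers": m}
        table = neoplasm_gap_scenarios(f, m, crf, crm, 2020, 2012)
        vals = table["neoplasm_contribution_years"]
        assert np.allclose(vals, vals.iloc[0], atol=1e-12)

    def test_each_scenario_respects_additivity(self, paper_expected):
        # spot-check one deletion scenario's internal additivity
        from tcalkit.decomposition import _deleted_cause_rates
        f = paper_expected["female"]["rates"]
        m = paper_expected["male"]["rates"]
        sf, crf = _deleted_cause_rates(
            paper_expected["female"]["cause_rates"], f, ("breast",)
        )
        sm, crm = _deleted_cause_rates(
            paper_expected["male"]["cause_rates"], m, ("breast",)
        )
        d = split_by_cause(decompose_gap(sf, sm, 2020, 1955), crf, crm)
        per_cause_sum = sum(arr.sum() for arr in d.per_cause.values())
        assert per_cause_sum == pytest.approx(d.total_gap, abs=1e-9)
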