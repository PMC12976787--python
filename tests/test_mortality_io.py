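"""IO dialects, ICD harmonisation, age-band expansion, cause rates."""

import numpy as np
import pytest

import tcalkit as tk
from tcalkit import mortality_io as mio
from tcalkit import synthetic_data as synth
from tcalkit.surfaces import CauseDeathSurface


# ----------------------------------------------------------------------
# HMD dialect

HMD_TOY = """Toyland, Death rates (period 1x1)

  Year    Age    Female    Male    Total
  2000    109    0.5       0.6     0.55
  2000    110+   .         0.9     0.9
"""


class TestHmdReader:
    def test_open_interval_and_missing_token(self, tmp_path):
        path = tmp_path / "mx.txt"
        path.write_text(HMD_TOY)
        surf = mio.read_hmd_rates(path, "female")
        assert surf.open_age
        assert surf.ages[-1] == 110
        assert surf.missing[1, 0]  # the "." cell
        assert surf.rates[0, 0] == 0.5
        male = mio.read_hmd_rates(path, "male")
        assert male.missing is None
        assert male.rates[1, 0] == 0.9

    def test_window_1955_2020_gives_66_year_columns(self, tmp_path):
        lines = ["X", "", "  Year  Age  Female  Male  Total"]
        for year in range(1955, 2021):
            lines.append(f"  {year}  0  0.01  0.02  0.015")
            lines.append(f"  {year}  1  0.01  0.02  0.015")
        path = tmp_path / "mx.txt"
        path.write_text("\n".join(lines))
        surf = mio.read_hmd_rates(path, "female")
        assert surf.years.size == 66

    @pytest.mark.parametrize(
        "row,message",
        [
            ("  2000  x9  0.1  0.1  0.1", "age token"),
            ("  2000  109  0.2  0.2  0.2", "duplicate"),
            ("  1999  108  0.1  0.1  0.1", "order"),
        ],
    )
    def test_parse_errors_carry_line_number(self, tmp_path, row, message):
        path = tmp_path / "mx.txt"
        path.write_text(HMD_TOY.rstrip("\n") + "\n" + row + "\n")
        with pytest.raises(ValueError, match=message) as err:
            mio.read_hmd_rates(path, "female")
        assert ":6:" in str(err.value)  # header line 3, toy rows 4-5, bad row 6


# ----------------------------------------------------------------------
# WHO-MDB dialect and mapping

def who_csv(tmp_path, rows, age_cols=("Age50",)):
    path = tmp_path / "who.csv"
    header = "Year,Sex,Revision,Cause," + ",".join(age_cols)
    path.write_text("\n".join([header] + rows) + "\n")
    return path


class TestWhoReader:
    def test_direct_code_mapping(self, tmp_path):
        path = who_csv(tmp_path, ["2000,2,10,C50,7"])
        surf = mio.read_who_mdb(path, mio.default_cause_mapping(), "female")
        assert surf.counts[surf.causes.index("breast"), 0, 0] == 7

    def test_unmapped_codes_conserved_in_residual(self, tmp_path):
        path = who_csv(tmp_path, ["2000,2,10,Z99,5", "2000,2,10,R00,3"])
        surf = mio.read_who_mdb(path, mio.default_cause_mapping(), "female")
        assert surf.counts[surf.causes.index("residual"), 0, 0] == 8
        assert surf.total[0, 0] == 8

    def test_two_revisions_give_contiguous_series(self, tmp_path):
        path = who_csv(tmp_path, ["1978,2,9,174,4", "1979,2,10,C50,6"])
        surf = mio.read_who_mdb(path, mio.default_cause_mapping(), "female")
        k = surf.causes.index("breast")
        assert surf.counts[k, 0, 0] == 4 and surf.counts[k, 0, 1] == 6

    def test_uncovered_revision_rejected(self, tmp_path):
        path = who_csv(tmp_path, ["1960,2,7,174,4"])
        with pytest.raises(ValueError, match="revision 7"):
            mio.read_who_mdb(path, mio.default_cause_mapping(), "female")

    def test_negative_counts_rejected(self, tmp_path):
        path = who_csv(tmp_path, ["2000,2,10,C50,-1"])
        with pytest.raises(ValueError, match="negative"):
            mio.read_who_mdb(path, mio.default_cause_mapping(), "female")


class TestCauseMapping:
    def test_default_gynecological_codes(self):
        mapping = mio.default_cause_mapping()
        assert mapping.category_for(10, "C53") == "gynecological"
        assert mapping.category_for(10, "C509") == "breast"  # 4-char root
        assert mapping.category_for(9, "180") == "gynecological"
        assert mapping.category_for(9, "E950") == "external"

    def test_conflicting_assignment_names_both_rules(self):
        with pytest.raises(ValueError, match="breast.*other_cancers"):
            mio.CauseMapping(
                rules=(
                    mio.MappingRule(10, "C50", "breast"),
                    mio.MappingRule(10, "C50", "other_cancers"),
                )
            )

    def test_empty_config_is_residual_only(self, tmp_path):
        path = tmp_path / "empty.yaml"
        path.write_text("")
        mapping = mio.load_cause_mapping(path)
        assert mapping.category_for(7, "174") == "residual"
        assert mapping.category_for(10, "C50") == "residual"

    def test_yaml_config_round_trip(self, tmp_path):
        path = tmp_path / "map.yaml"
        path.write_text(
            "rules:\n"
            "  - revision: 10\n"
            "    category: breast\n"
            "    codes: [C50]\n"
            "  - revision: 10\n"
            "    category: gynecological\n"
            "    codes: ['C51-C58']\n"
        )
        mapping = mio.load_cause_mapping(path)
        assert mapping.category_for(10, "C56") == "gynecological"
        with pytest.raises(ValueError, match="revision 9"):
            mapping.category_for(9, "174")


# ----------------------------------------------------------------------
# Age-band expansion

def banded(counts, bands, causes=("c",)):
    counts = np.asarray(counts, dtype=float)
    return CauseDeathSurface(
        sex="female", years=np.array([2000]), causes=causes,
        counts=counts.reshape(len(causes), len(bands), 1), bands=bands,
    )


class TestDistributeToSingleAges:
    def test_uniform_fallback_splits_evenly(self):
        surf = banded([10], [(35, 39)])
        out = mio.distribute_to_single_ages(surf)
        assert np.all(out.counts[0, 35:40, 0] == 2)
        assert out.counts.sum() == 10

    def test_largest_remainder_rounding(self):
        surf = banded([10], [(0, 2)])
        weights = tk.MortalitySurface(
            "female", np.arange(3), np.array([2000]),
            np.array([[0.5], [0.3], [0.2]]),
        )
        out = mio.distribute_to_single_ages(surf, weights=weights)
        assert out.counts[0, :, 0].tolist() == [5.0, 3.0, 2.0]

    def test_single_year_input_unchanged(self):
        surf = banded([[3], [4]], [(0, 0), (1, 1)], causes=("c",))
        assert mio.distribute_to_single_ages(surf) is surf

    def test_overlapping_bands_rejected(self):
        surf = banded([[1], [1]], [(0, 5), (3, 9)])
        with pytest.raises(ValueError, match="overlap"):
            mio.distribute_to_single_ages(surf)

    def test_band_totals_conserved_with_weights(self):
        rng = np.random.default_rng(0)
        surf = banded([137], [(60, 64)])
        weights = tk.MortalitySurface(
            "female", np.arange(65), np.array([2000]),
            rng.uniform(0.001, 0.1, (65, 1)),
        )
        out = mio.distribute_to_single_ages(surf, weights=weights)
        assert out.counts.sum() == 137
        assert np.all(out.counts == np.round(out.counts))


# ----------------------------------------------------------------------
# Cause-specific rates

class TestCauseSpecificRates:
    def surface(self, rates):
        rates = np.atleast_2d(np.asarray(rates, dtype=float))
        return tk.MortalitySurface(
            "female", np.arange(rates.shape[0]), np.arange(2000, 2000 + rates.shape[1]),
            rates,
        )

    def test_single_cause_recovers_all_cause(self):
        m = self.surface([[0.01, 0.02]])
        counts = CauseDeathSurface(
            "female", np.array([2000, 2001]), ("only",), np.array([[[5.0, 9.0]]])
        )
        out = mio.cause_specific_rates(m, counts)
        assert np.array_equal(out["only"].rates, m.rates)

    def test_share_arithmetic(self):
        m = self.surface([[0.004]])
        counts = CauseDeathSurface(
            "female", np.array([2000]), ("breast", "rest"),
            np.array([[[25.0]], [[75.0]]]),
        )
        out = mio.cause_specific_rates(m, counts)
        assert out["breast"].rates[0, 0] == pytest.approx(0.001, abs=1e-15)

    def test_empty_cell_gives_zero_everywhere(self):
        m = self.surface([[0.0]])
        counts = CauseDeathSurface(
            "female", np.array([2000]), ("a", "b"), np.zeros((2, 1, 1))
        )
        out = mio.cause_specific_rates(m, counts)
        assert all(np.all(s.rates == 0) for s in out.values())

    def test_discordant_cell_assigned_to_residual(self):
        m = self.surface([[0.01]])
        counts = CauseDeathSurface(
            "female", np.array([2000]), ("a", "residual"), np.zeros((2, 1, 1))
        )
        out = mio.cause_specific_rates(m, counts)
        assert out["residual"].rates[0, 0] == 0.01
        assert out["a"].rates[0, 0] == 0.0

    def test_cause_rates_sum_to_all_cause(self, paper_expected):
        for sex in ("female", "male"):
            total = sum(s.rates for s in paper_expected[sex]["cause_rates"].values())
            assert np.allclose(
                total, paper_expected[sex]["rates"].rates, atol=1e-12
            )

    def test_grid_mismatch_rejected(self):
        m = self.surface([[0.01, 0.02]])
        counts = CauseDeathSurface(
            "female", np.array([1999, 2000]), ("only",), np.array([[[5.0, 9.0]]])
        )
        with pytest.raises(ValueError, match="grid"):
            mio.cause_specific_rates(m, counts)


# ----------------------------------------------------------------------
# Fixture round-trip

def test_fixture_files_round_trip(tmp_path, paper_params):
    import dataclasses
    params = dataclasses.replace(
        paper_params, age_max=50, year_start=2010, year_end=2020
    )
    data = synth.generate_dataset(params, mode="sampled", seed=9)
    paths = synth.write_fixture_files(
        tmp_path,
        {s: d["rates"] for s, d in data.items()},
        {s: d["counts"] for s, d in data.items()},
        {s: d["exposure"] for s, d in data.items()},
    )
    mapping = mio.default_cause_mapping()
    for sex in ("female", "male"):
        rates = mio.read_hmd_rates(paths["rates"], sex)
        assert rates.missing is None
        assert np.max(np.abs(rates.rates - data[sex]["rates"].rates)) < 1e-12
        exp = mio.read_hmd_exposures(paths["exposures"], sex)
        assert np.max(np.abs(exp.person_years - data[sex]["exposure"].person_years)) < 1e-9
        counts = mio.distribute_to_single_ages(
            mio.read_who_mdb(paths["cause_counts"], mapping, sex)
        )
        orig = data[sex]["counts"]
        idx = [counts.causes.index(c) for c in orig.causes]
        assert np.array_equal(counts.counts[idx], orig.counts)


def test_write_empty_grid_rejected(tmp_path):
    with pytest.raises(ValueError, match="empty"):
        synth.write_fixture_files(tmp_path, {}, {}, {})
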