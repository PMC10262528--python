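import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import frailtykit as fk
from frailtykit.errors import ConfigurationError, DataError, EmptySampleError


def _definition(**kwargs):
    base = dict(id="d", label="d", system="s", variant_class="physical")
    return fk.DeficitDefinition(**{**base, **kwargs})


class TestScoreDeficit:
    @pytest.mark.parametrize(
        "kwargs, raw, expected",
        [
            (dict(kind="ordinal", n_levels=5), 1, 0.25),
            (dict(kind="ordinal", n_levels=5), 4, 1.0),
            (dict(kind="ordinal", n_levels=3), 2, 1.0),
            (dict(kind="binary"), 0, 0.0),
            (dict(kind="binary"), 1, 1.0),
            (dict(kind="threshold", threshold=12.0, direction="below"), 11.0, 1.0),
            (dict(kind="threshold", threshold=12.0, direction="below"), 12.0, 1.0),
            (dict(kind="threshold", threshold=12.0, direction="below"), 12.5, 0.0),
            (dict(kind="threshold", threshold=104.0, direction="above"), 130.0, 1.0),
            (dict(kind="threshold", threshold=104.0, direction="above"), 90.0, 0.0),
        ],
    )
    def test_scoring_rules(self, kwargs, raw, expected):
        assert fk.score_deficit(raw, _definition(**kwargs)) == expected

    def test_missing_propagates(self):
        assert np.isnan(fk.score_deficit(None, _definition(kind="binary")))
        assert np.isnan(fk.score_deficit(float("nan"), _definition(kind="ordinal", n_levels=5)))

    def test_ordinal_out_of_range_names_deficit(self):
        with pytest.raises(DataError, match="'d'"):
            fk.score_deficit(5, _definition(kind="ordinal", n_levels=5))

    def test_non_binary_value_rejected(self):
        with pytest.raises(DataError):
            fk.score_deficit(2, _definition(kind="binary"))


class TestComputeFI:
    IDS = [f"d{i}" for i in range(40)]

    def _scores(self, values):
        return dict(zip(self.IDS, values))

    def test_all_zero_gives_zero(self):
        res = fk.compute_fi(self._scores([0.0] * 40), self.IDS)
        assert res.fi == 0.0 and not res.excluded

    def test_ratio_of_deficits_to_considered(self):
        res = fk.compute_fi(self._scores([1.0] * 10 + [0.0] * 30), self.IDS)
        assert res.fi == pytest.approx(0.25)

    def test_missing_removed_from_numerator_and_denominator(self):
        vals = [np.nan] * 2 + [1.0] * 19 + [0.0] * 19
        res = fk.compute_fi(self._scores(vals), self.IDS)
        assert res.n_available == 38
        assert res.fi == pytest.approx(19 / 38)

    def test_exclusion_strictly_above_20_percent(self):
        # 9/40 = 22.5% missing -> excluded; 8/40 = 20% exactly -> retained
        res9 = fk.compute_fi(self._scores([np.nan] * 9 + [0.0] * 31), self.IDS)
        assert res9.excluded and res9.fi is None
        res8 = fk.compute_fi(self._scores([np.nan] * 8 + [1.0] * 32), self.IDS)
        assert not res8.excluded and res8.fi == pytest.approx(1.0)

    def test_empty_variant_set_is_a_configuration_error(self):
        with pytest.raises(ConfigurationError):
            fk.compute_fi({}, [])

    @settings(derandomize=True, max_examples=100)
    @given(
        scores=st.lists(
            st.sampled_from([0.0, 0.25, 0.5, 0.75, 1.0]), min_size=2, max_size=30
        ),
        bump=st.integers(min_value=0, max_value=29),
    )
    def test_monotone_in_any_single_score_and_permutation_invariant(self, scores, bump):
        ids = [f"d{i}" for i in range(len(scores))]
        base = fk.compute_fi(dict(zip(ids, scores)), ids)
        bump = bump % len(scores)
        higher = list(scores)
        higher[bump] = min(1.0, higher[bump] + 0.25)
        res = fk.compute_fi(dict(zip(ids, higher)), ids)
        assert res.fi >= base.fi - 1e-12
        assert 0.0 <= base.fi <= 1.0
        perm = ids[::-1]
        assert fk.compute_fi(dict(zip(ids, scores)), perm).fi == pytest.approx(base.fi)


class TestBuildFITable:
    def test_hand_scored_fixture(self, toy_catalog):
        baseline = pd.DataFrame(
            {
                "participant_id": ["a", "b", "c"],
                "age_years": [70.0, 80.0, 75.0],
                "sex": ["F", "M", "F"],
                "medications": [
                    "antihypertensive;metformin;x1;x2;x3",  # htn, diabetes, 5 meds
                    "statin",                                # htn via statin
                    "",
                ],
                "anaemia": [11.0, 13.0, np.nan],
                "adl": [2, 0, 4],
                "tremor": [0, 1, np.nan],
            }
        )
        table = fk.build_fi_table(baseline, toy_catalog, "physical")
        # a: htn 1, diabetes 1, anaemia 1, adl 0.5, tremor 0, polypharmacy 1 -> 4.5/6
        # b: htn 1, diabetes 0, anaemia 0, adl 0, tremor 1, polypharmacy 0 -> 2/6
        # c: 2 of 6 missing (33%) -> excluded
        assert table.loc[0, "fi"] == pytest.approx(4.5 / 6)
        assert table.loc[1, "fi"] == pytest.approx(2 / 6)
        assert bool(table.loc[2, "excluded"]) and np.isnan(table.loc[2, "fi"])

    def test_all_missing_participant_is_excluded(self, toy_catalog):
        baseline = pd.DataFrame(
            {
                "participant_id": ["a"],
                "medications": [""],
                "anaemia": [np.nan],
                "adl": [np.nan],
                "tremor": [np.nan],
            }
        )
        # med-derived deficits score 0 from an empty list; the three raw columns
        # are all missing, so 3/6 = 50% of deficits are missing -> excluded
        table = fk.build_fi_table(baseline, toy_catalog, "physical")
        assert bool(table.loc[0, "excluded"])
        res = fk.compute_fi(
            {"anaemia": np.nan, "adl": np.nan, "tremor": np.nan},
            ["anaemia", "adl", "tremor"],
        )
        assert res.excluded and res.missing_fraction == 1.0

    def test_variants_differ_only_through_added_cognitive_deficits(self, toy_catalog):
        baseline = pd.DataFrame(
            {
                "participant_id": ["a"],
                "medications": ["antihypertensive"],
                "anaemia": [10.0],
                "adl": [1],
                "tremor": [1],
                "memory": [2],
            }
        )
        phys = fk.build_fi_table(baseline, toy_catalog, "physical")
        comb = fk.build_fi_table(baseline, toy_catalog, "physical_cognitive")
        # physical: (1 + 0 + 1 + 0.25 + 1 + 0)/6; combined adds memory 2/2 = 1.0
        assert phys.loc[0, "fi"] == pytest.approx(3.25 / 6)
        assert comb.loc[0, "fi"] == pytest.approx((3.25 + 1.0) / 7)

    def test_unresolvable_deficit_fails_before_scoring(self, toy_catalog):
        baseline = pd.DataFrame({"participant_id": ["a"], "medications": [""]})
        with pytest.raises(ConfigurationError, match="anaemia"):
            fk.build_fi_table(baseline, toy_catalog, "physical")

    def test_column_order_never_changes_fi(self, toy_catalog):
        baseline = pd.DataFrame(
            {
                "participant_id": ["a", "b"],
                "medications": ["metformin", ""],
                "anaemia": [11.0, 13.0],
                "adl": [3, 1],
                "tremor": [1, 0],
            }
        )
        shuffled = baseline[list(baseline.columns[::-1])]
        t1 = fk.build_fi_table(baseline, toy_catalog, "physical")
        t2 = fk.build_fi_table(shuffled, toy_catalog, "physical")
        assert np.allclose(t1["fi"], t2["fi"])


class TestCategorize:
    @pytest.mark.parametrize(
        "fi, expected",
        [
            (0.10, "robust"),
            (0.12, "robust"),
            (0.121, "mild"),
            (0.24, "mild"),
            (0.30, "moderate"),
            (0.36, "moderate"),
            (0.37, "severe"),
            (0.0, "robust"),
            (1.0, "severe"),
        ],
    )
    def test_efi_half_open_boundaries(self, fi, expected):
        assert fk.categorize(fi) == expected

    def test_domain_error_outside_unit_interval(self):
        with pytest.raises(DataError):
            fk.categorize(1.2)


class TestSummaries:
    def test_symmetric_fixture(self):
        s = fk.summarize_fi([0.1, 0.2, 0.3, 0.4])
        assert s["mean"] == pytest.approx(0.25)
        assert all(v == pytest.approx(25.0) for v in s["prevalence"].values())
        assert sum(s["prevalence"].values()) == pytest.approx(100.0)

    def test_degenerate_constant_sample(self):
        s = fk.summarize_fi([0.14] * 10)
        assert s["sd"] == pytest.approx(0.0, abs=1e-12)
        assert s["p99"] == pytest.approx(0.14)

    def test_all_excluded_raises(self):
        df = pd.DataFrame({"fi": [np.nan], "excluded": [True]})
        with pytest.raises(EmptySampleError):
            fk.summarize_fi(df)

    def test_prevalence_from_printed_category_rows(self):
        row = {"robust": 5.5, "mild": 45.9, "moderate": 41.1, "severe": 7.5}
        assert fk.prevalence_over_threshold(row, 0.24) == pytest.approx(48.6)
        assert fk.prevalence_over_threshold(
            {"robust": 43.2, "mild": 50.0, "moderate": 6.7, "severe": 0.2}, 0.24
        ) == pytest.approx(6.9)

    def test_non_boundary_threshold_demands_raw_values(self):
        with pytest.raises(DataError, match="raw"):
            fk.prevalence_over_threshold({"robust": 100.0}, 0.2)

    def test_all_robust_sample_has_zero_prevalence(self):
        assert fk.prevalence_over_threshold([0.01, 0.05, 0.1]) == 0.0

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(min_value=0, max_value=1), min_size=2, max_size=200))
    def test_threshold_prevalence_equals_moderate_plus_severe(self, vals):
        s = fk.summarize_fi(vals)
        assert fk.prevalence_over_threshold(vals, 0.24) == pytest.approx(
            s["prevalence"]["moderate"] + s["prevalence"]["severe"]
        )
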