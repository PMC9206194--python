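import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from txaccess.roster import (
    chi_square_test,
    classify_affiliation,
    classify_membership,
    deduplicate_roster,
    match_key,
    net_loss,
    normalize_name,
    round_half_up,
    tabulate_characteristics,
)


def mk_roster(specs):
    """specs: list of (id, name, lon, lat) with default attributes."""
    return pd.DataFrame(
        [
            {"id": i, "name": n, "lon": x, "lat": y, "state": "S0", "rucc": 1}
            for i, n, x, y in specs
        ]
    )


class TestDedup:
    def test_identical_name_and_coords_flagged(self):
        r = mk_roster([("a", "Clinic One", 1.0, 2.0), ("b", "clinic one!", 1.00004, 2.0)])
        kept, dups = deduplicate_roster(r)
        assert len(kept) == 1 and len(dups) == 1
        assert kept.iloc[0]["id"] == "a"

    def test_no_repeats_identity(self):
        r = mk_roster([("a", "A", 0, 0), ("b", "B", 1, 1)])
        kept, dups = deduplicate_roster(r)
        assert len(kept) == 2 and dups.empty

    def test_partition_sizes(self):
        r = mk_roster(
            [("a", "X", 0, 0), ("b", "X", 0, 0), ("c", "X", 0, 0), ("d", "Y", 5, 5)]
        )
        kept, dups = deduplicate_roster(r)
        assert len(kept) + len(dups) == len(r)
        assert len(kept) == 2

    def test_coordinates_distinguish_same_name(self):
        r = mk_roster([("a", "Chain Clinic", 0, 0), ("b", "Chain Clinic", 10, 0)])
        kept, _ = deduplicate_roster(r)
        assert len(kept) == 2

    def test_empty_roster(self):
        r = mk_roster([])
        kept, dups = deduplicate_roster(r)
        assert kept.empty and dups.empty


class TestMembership:
    def test_three_way_partition(self):
        r18 = mk_roster([("1", "A", 0, 0), ("2", "B", 1, 0), ("3", "C", 2, 0)])
        r20 = mk_roster([("4", "B", 1, 0), ("5", "C", 2, 0), ("6", "D", 3, 0)])
        lab = classify_membership(r18, r20)
        by = {m: set(lab.loc[lab["membership"] == m, "name"]) for m in ("left", "joined", "stayed")}
        assert by == {"left": {"A"}, "joined": {"D"}, "stayed": {"B", "C"}}
        assert net_loss(lab) == 0

    def test_identical_rosters_no_flux(self):
        r = mk_roster([("1", "A", 0, 0), ("2", "B", 1, 0)])
        lab = classify_membership(r, r)
        assert (lab["membership"] == "stayed").all()
        assert net_loss(lab) == 0

    def test_partition_covers_both_rosters_exactly_once(self):
        rng = np.random.default_rng(0)
        names = [f"N{i}" for i in range(40)]
        r18 = mk_roster([(f"a{i}", names[i], i, 0) for i in range(30)])
        r20 = mk_roster([(f"b{i}", names[i], i, 0) for i in rng.permutation(40)[:25]])
        lab = classify_membership(r18, r20)
        counts = lab["membership"].value_counts()
        assert counts["left"] + counts["stayed"] == len(r18)
        assert counts["joined"] + counts["stayed"] == len(r20)
        assert len(lab) == counts.sum()


class TestAffiliation:
    def test_name_based_planned_parenthood(self):
        assert classify_affiliation("Planned Parenthood of Springfield") == "PlannedParenthood"

    def test_registry_based_fqhc(self):
        assert classify_affiliation("Valley Clinic", "id1", fqhc_registry={"id1"}) == "FQHC"
        assert classify_affiliation("Valley Clinic", fqhc_flag=True) == "FQHC"

    def test_unmatched_is_other(self):
        assert classify_affiliation("Main Street Medical") == "Other"

    def test_precedence_cpc_over_pp_over_fqhc(self):
        # a CPC-registered site named like PP with FQHC designation: CPC wins
        assert (
            classify_affiliation(
                "Planned Parenthood Annex", "x", fqhc_registry={"x"}, cpc_registry={"x"}
            )
            == "CrisisPregnancyCenter"
        )
        assert (
            classify_affiliation("Planned Parenthood Annex", "x", fqhc_registry={"x"})
            == "PlannedParenthood"
        )


class TestTabulate:
    def _labelled(self):
        rows = []
        for i in range(6):
            rows.append({"id": i, "name": f"n{i}", "lon": i, "lat": 0, "state": "S0",
                         "rucc": 1 if i < 4 else 5, "affiliation": "Other",
                         "membership": "stayed"})
        rows[5]["membership"] = "left"
        rows.append({"id": 9, "name": "n9", "lon": 9, "lat": 0, "state": "S1", "rucc": 2,
                     "affiliation": "FQHC", "membership": "joined"})
        return pd.DataFrame(rows)

    def test_single_stratum_is_100_percent(self):
        lab = self._labelled()
        lab["affiliation"] = "Other"
        tab = tabulate_characteristics(lab, "affiliation")
        assert tab.percentages.loc["Other", "pct_2018"] == 100.0

    def test_counts_and_net_change(self):
        tab = tabulate_characteristics(self._labelled(), "urban_rural")
        assert tab.counts.loc["Urban", "n_2018"] == 4
        assert tab.counts.loc["Rural", "n_2018"] == 2
        assert tab.counts.loc["Urban", "n_2020"] == 5
        assert tab.counts.loc["Rural", "n_2020"] == 1
        assert int(tab.counts["net_change"].sum()) == -net_loss(self._labelled())

    def test_percentage_columns_sum_to_100(self):
        for strat in ("affiliation", "urban_rural"):
            tab = tabulate_characteristics(self._labelled(), strat)
            for col in ("pct_2018", "pct_2020"):
                assert tab.percentages[col].sum() == pytest.approx(100.0, abs=0.2)

    def test_unknown_stratifier_rejected(self):
        with pytest.raises(ValueError):
            tabulate_characteristics(self._labelled(), "shoe_size")

    def test_law_status_needs_protective_set(self):
        with pytest.raises(ValueError):
            tabulate_characteristics(self._labelled(), "law_status")


class TestChiSquare:
    def test_identical_proportions_statistic_zero(self):
        stat, df, p = chi_square_test([[10, 20], [10, 20]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_hand_computed_2x2(self):
        # Pearson formula by hand: all expected cells are 15
        stat, df, p = chi_square_test([[10, 20], [20, 10]])
        assert stat == pytest.approx(20.0 / 3.0, abs=1e-9)
        assert df == 1
        assert p == pytest.approx(0.009823, abs=1e-6)

    def test_scaling_property(self):
        s1, _, _ = chi_square_test([[10, 20], [20, 10]])
        s10, _, _ = chi_square_test([[100, 200], [200, 100]])
        assert s10 == pytest.approx(10 * s1, rel=1e-12)

    def test_matches_textbook_formula_on_random_tables(self):
        rng = np.random.default_rng(8)
        for _ in range(50):
            t = rng.integers(1, 60, (rng.integers(2, 4), rng.integers(2, 5))).astype(float)
            stat, df, _ = chi_square_test(t)
            # independent textbook oracle: sum (O-E)^2/E over cells
            exp = t.sum(1, keepdims=True) @ t.sum(0, keepdims=True) / t.sum()
            want = float(((t - exp) ** 2 / exp).sum())
            assert stat == pytest.approx(want, abs=1e-9)
            assert df == (t.shape[0] - 1) * (t.shape[1] - 1)

    def test_zero_expected_cell_named(self):
        with pytest.raises(ValueError, match="cell"):
            chi_square_test([[0, 0], [5, 7]])


@settings(deadline=None, derandomize=True, max_examples=60)
@given(st.text(max_size=30))
def test_normalize_name_idempotent(s):
    assert normalize_name(normalize_name(s)) == normalize_name(s)


def test_match_key_rounding():
    assert match_key("A  Clinic.", 1.00001, 2.0) == match_key("a clinic", 1.0, 2.0)
    assert match_key("A", 1.001, 2.0) != match_key("A", 1.0, 2.0)


def test_round_half_up_matches_printed_tables():
    assert round_half_up(11.15, 1) == 11.2
    assert round_half_up(27.965, 2) == 27.97
    assert round_half_up(0.25, 1) == 0.3
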