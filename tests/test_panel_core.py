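"""Panel data model: I/O, filtering, windowing, lagging, descriptives."""

import io

import numpy as np
import pandas as pd
import pytest

from alepanel import (
    EventCatalog,
    PanelDataset,
    build_household_ids,
    consecutive_window,
    count_summaries,
    drop_all_missing_rows,
    filter_adults,
    impute_missing_as_zero,
    joint_conditional_probs,
    lag_align,
    read_panel,
)
from alepanel.panel import PanelError
from conftest import random_typed_panel


def _write_csv(tmp_path, text):
    path = tmp_path / "panel.csv"
    path.write_text(text)
    return str(path)


class TestReadPanel:
    def test_parses_na_into_mask(self, tmp_path, tiny_catalog):
        path = _write_csv(
            tmp_path,
            "id,hh_id,year,age,a,b,c\n1,10,2000,30,1,NA,0\n2,11,2000,40,0,1,0\n3,12,2000,50,0,0,\n",
        )
        panel = read_panel(path, tiny_catalog)
        assert panel.n_rows == 3
        assert panel.mask.to_numpy().sum() == 2  # "NA" token and empty cell
        assert bool(panel.mask.iloc[0]["b"]) and bool(panel.mask.iloc[2]["c"])

    def test_duplicate_key_is_error(self, tmp_path, tiny_catalog):
        path = _write_csv(
            tmp_path,
            "id,hh_id,year,age,a,b,c\n1,10,2005,30,1,0,0\n1,10,2005,30,0,1,0\n",
        )
        with pytest.raises(PanelError, match="duplicate"):
            read_panel(path, tiny_catalog)

    def test_exclusivity_violation_is_error(self, tmp_path):
        catalog = EventCatalog(events=("a", "b", "c"), exclusivity_groups=(frozenset({"a", "b"}),))
        path = _write_csv(
            tmp_path,
            "id,hh_id,year,age,a,b,c\n1,10,2000,30,1,1,0\n",
        )
        with pytest.raises(PanelError, match="exclusivity"):
            read_panel(path, catalog)

    def test_unknown_column_is_error(self, tmp_path, tiny_catalog):
        path = _write_csv(
            tmp_path,
            "id,hh_id,year,age,a,b,c,zzz\n1,10,2000,30,1,0,0,5\n",
        )
        with pytest.raises(PanelError, match="unknown"):
            read_panel(path, tiny_catalog)


class TestFilters:
    def test_adult_filter_is_boundary_inclusive(self, tiny_panel):
        out = filter_adults(tiny_panel)
        assert sorted(out.data["age"]) == [18, 30, 31, 32]

    def test_adult_filter_identity_when_all_adult(self, tiny_panel):
        adults = filter_adults(tiny_panel)
        assert filter_adults(adults).n_rows == adults.n_rows

    def test_removed_count_matches_generated_minors(self, swiss):
        panel = random_typed_panel(swiss, n=200, years=3, seed=5)
        data = panel.data.copy()
        rng = np.random.default_rng(0)
        minors = rng.random(len(data)) < 0.1
        data.loc[minors, "age"] = 15
        panel = PanelDataset(data=data, catalog=swiss)
        assert filter_adults(panel).n_rows == len(data) - minors.sum()

    def test_drop_all_missing_rows(self, tiny_catalog):
        df = pd.DataFrame(
            {
                "id": [1, 2],
                "hh_id": [1, 2],
                "year": [2000, 2000],
                "age": [30, 40],
                "a": [1.0, np.nan],
                "b": [0.0, np.nan],
                "c": [0.0, np.nan],
            }
        )
        panel = PanelDataset(data=df, catalog=tiny_catalog)
        assert drop_all_missing_rows(panel).n_rows == 1
        # partially observed rows are retained
        assert drop_all_missing_rows(drop_all_missing_rows(panel)).n_rows == 1

    def test_imputation_zeroes_masked_cells_and_keeps_mask(self, tiny_panel):
        out = impute_missing_as_zero(tiny_panel)
        assert out.data["b"].iloc[1] == 0.0
        assert bool(out.mask.iloc[1]["b"])  # audit mask retained
        assert out.yearly_counts().sum() <= tiny_panel.data[["a", "b", "c"]].sum().sum() + 1

    def test_filter_order_commutes(self, swiss):
        from alepanel import inject_missingness

        panel = random_typed_panel(swiss, n=150, years=4, seed=9)
        panel = inject_missingness(panel, 0.02, 0.03, seed=1)
        a = drop_all_missing_rows(filter_adults(panel))
        b = filter_adults(drop_all_missing_rows(panel))
        pd.testing.assert_frame_equal(
            a.data.reset_index(drop=True), b.data.reset_index(drop=True)
        )


class TestHouseholdIds:
    def test_same_members_share_id_across_waves(self):
        waves = [[{"A", "B"}], [{"A", "B"}], [{"A", "B"}]]
        ids = build_household_ids(waves)
        assert ids[0] == ids[1] == ids[2] == [0]

    def test_membership_change_creates_new_id(self):
        ids = build_household_ids([[{"A", "B"}], [{"A", "B", "C"}]])
        assert ids[0][0] != ids[1][0]

    def test_merge_creates_third_id(self):
        ids = build_household_ids([[{"A"}, {"B"}], [{"A", "B"}]])
        assert len({ids[0][0], ids[0][1], ids[1][0]}) == 3

    def test_individual_in_two_households_is_error(self):
        with pytest.raises(PanelError, match="two households"):
            build_household_ids([[{"A", "B"}, {"A"}]])


class TestConsecutiveWindow:
    def _panel(self, years_by_id):
        rows = []
        for i, years in years_by_id.items():
            for y in years:
                rows.append({"id": i, "hh_id": i, "year": y, "age": 30, "count": 0})
        return PanelDataset(data=pd.DataFrame(rows), catalog=None)

    def test_full_run_retained(self):
        panel = self._panel({1: range(2001, 2021)})
        out = consecutive_window(panel, 20)
        assert out.n_rows == 20

    def test_gap_breaks_run(self):
        panel = self._panel({1: list(range(2001, 2011)) + list(range(2012, 2023))})
        assert consecutive_window(panel, 20).n_rows == 0

    def test_earliest_run_kept_and_matches_bruteforce(self):
        rng = np.random.default_rng(3)
        years_by_id = {
            i: sorted(rng.choice(np.arange(2000, 2020), size=rng.integers(3, 18), replace=False))
            for i in range(40)
        }
        panel = self._panel(years_by_id)
        length = 5
        out = consecutive_window(panel, length)
        # brute force: earliest index j with years[j..j+L-1] consecutive
        expected = {}
        for i, years in years_by_id.items():
            years = list(years)
            for j in range(len(years) - length + 1):
                if years[j + length - 1] - years[j] == length - 1 and all(
                    years[j + k] == years[j] + k for k in range(length)
                ):
                    expected[i] = years[j : j + length]
                    break
        got = out.data.groupby("id")["year"].apply(list).to_dict()
        assert got == expected
        assert out.n_rows == length * len(expected)


class TestLagAlign:
    def test_only_adjacent_years_paired(self):
        df = pd.DataFrame(
            {
                "id": [1, 1, 1],
                "hh_id": [5, 5, 6],
                "year": [2001, 2002, 2004],
                "age": [30, 31, 33],
                "count": [1, 2, 0],
            }
        )
        pairs = lag_align(PanelDataset(data=df, catalog=None))
        assert len(pairs) == 1
        assert pairs.iloc[0]["year"] == 2001
        assert pairs.iloc[0]["pred_count"] == 1 and pairs.iloc[0]["out_count"] == 2

    def test_single_year_individual_yields_no_pairs(self):
        df = pd.DataFrame({"id": [1], "hh_id": [1], "year": [2000], "age": [40], "count": [2]})
        assert lag_align(PanelDataset(data=df, catalog=None)).empty

    def test_outcome_year_household_attached(self):
        df = pd.DataFrame(
            {
                "id": [1, 1],
                "hh_id": [5, 9],
                "year": [2000, 2001],
                "age": [30, 31],
                "count": [0, 1],
            }
        )
        pairs = lag_align(PanelDataset(data=df, catalog=None))
        assert pairs.iloc[0]["hh_id"] == 9

    def test_pair_count_matches_adjacency_oracle(self, swiss):
        panel = random_typed_panel(swiss, n=100, years=6, seed=2)
        # drop random rows to create gaps
        keep = np.random.default_rng(0).random(panel.n_rows) > 0.2
        panel = PanelDataset(data=panel.data.loc[keep], catalog=swiss)
        pairs = lag_align(panel)
        expected = 0
        for _, g in panel.data.groupby("id"):
            ys = set(g["year"])
            expected += sum(1 for y in ys if y + 1 in ys)
        assert len(pairs) == expected


class TestSummaries:
    def test_frequencies_and_counts_on_toy_panel(self):
        df = pd.DataFrame(
            {
                "id": [1, 2],
                "hh_id": [1, 2],
                "year": [2000, 2000],
                "age": [30, 40],
                "a": [1.0, 1.0],
                "b": [0.0, 1.0],
            }
        )
        panel = PanelDataset(data=df, catalog=EventCatalog(events=("a", "b")))
        s = count_summaries(panel)
        assert np.allclose(s["event_frequencies"], [2 / 3, 1 / 3])
        assert list(panel.yearly_counts()) == [1, 2]

    def test_all_zero_panel(self):
        df = pd.DataFrame(
            {"id": [1], "hh_id": [1], "year": [2000], "age": [30], "a": [0.0], "b": [0.0]}
        )
        panel = PanelDataset(data=df, catalog=EventCatalog(events=("a", "b")))
        s = count_summaries(panel)
        assert s["event_frequencies"].sum() == 0
        assert (s["cumulative_counts"] == 0).all()

    def test_frequencies_match_bruteforce_tally(self, swiss):
        panel = random_typed_panel(swiss, n=120, years=5, seed=11)
        s = count_summaries(panel)
        tally = {e: panel.data[e].sum() for e in swiss.events}
        total = sum(tally.values())
        for e in swiss.events:
            assert s["event_frequencies"][e] == pytest.approx(tally[e] / total)

    def test_both_dispersion_statistics_reported(self, swiss):
        s = count_summaries(random_typed_panel(swiss, n=50, years=10, seed=1))
        assert s["sd_over_mean"] == pytest.approx(
            np.sqrt(s["cumulative_variance"]) / s["cumulative_mean"]
        )
        assert s["variance_over_mean"] == pytest.approx(
            s["cumulative_variance"] / s["cumulative_mean"]
        )


class TestJointConditional:
    def test_toy_joint_probability(self):
        df = pd.DataFrame(
            {
                "id": [1, 2, 3, 4],
                "hh_id": [1, 2, 3, 4],
                "year": [2000] * 4,
                "age": [30] * 4,
                "a": [1.0, 1.0, 0.0, 0.0],
                "b": [1.0, 0.0, 1.0, 0.0],
            }
        )
        panel = PanelDataset(data=df, catalog=EventCatalog(events=("a", "b")))
        probs = joint_conditional_probs(panel)
        assert probs["joint"].loc["a", "b"] == pytest.approx(0.25)
        assert probs["conditional"].loc["a", "b"] == pytest.approx(0.5)

    def test_exclusive_pair_has_zero_joint(self, swiss):
        panel = random_typed_panel(swiss, n=300, years=4, seed=7)
        probs = joint_conditional_probs(panel)
        group = sorted(swiss.exclusivity_groups[0])
        assert probs["joint"].loc[group[0], group[1]] == 0.0

    def test_bayes_identity_and_bruteforce_agreement(self, swiss):
        panel = random_typed_panel(swiss, n=200, years=4, seed=13)
        probs = joint_conditional_probs(panel)
        block = panel.data[list(swiss.events)].to_numpy()
        n = len(block)
        for i, a in enumerate(swiss.events[:5]):
            for j, b in enumerate(swiss.events[:5]):
                brute = np.mean(block[:, i].astype(bool) & block[:, j].astype(bool))
                assert probs["joint"].loc[a, b] == pytest.approx(brute)
        # P(A|B) P(B) = P(B|A) P(A) where defined
        joint = probs["joint"].to_numpy()
        assert np.allclose(joint, joint.T)
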