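"""Cover sums, cover-weighted indicators and the physical-equivalence arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from resurvey.errors import UndefinedResultError, ValidationError
from resurvey.indicators import (
    belt_fraction,
    community_weighted_indicator,
    cover_by_rank,
    cover_sum_per_plot,
    elevation_equivalent,
    indicator_deltas,
    indicator_series,
    lapse_rate_elevation,
    rank_correlation_check,
    trend_rescale,
)


class TestCoverSums:
    def test_addition_oracle(self, mini_dataset):
        sums = cover_sum_per_plot(mini_dataset, 1994)
        assert sums["p1"] == pytest.approx(16.0)  # 10 + 5 + 1

    def test_empty_plot_sums_to_zero(self, mini_dataset):
        assert cover_sum_per_plot(mini_dataset, 1994)["p3"] == 0.0

    def test_single_species_percent_equals_dm2(self, mini_dataset):
        # 1 m² = 100 dm², so percent cover and dm² coincide numerically
        assert cover_sum_per_plot(mini_dataset, 1994)["p2"] == pytest.approx(2.0)

    def test_rank_totals_partition_grand_total(self, sim_dataset):
        year = sim_dataset.years[0]
        by_rank = cover_by_rank(sim_dataset, year)
        grand = cover_sum_per_plot(sim_dataset, year).sum()
        assert by_rank["total_cover"].sum() == pytest.approx(grand, rel=1e-12)

    def test_mean_per_species_division_oracle(self, mini_dataset):
        by_rank = cover_by_rank(mini_dataset, 1994)
        # rank 1 = species a only: covers 10 + 2 + 4 = 16, one species
        assert by_rank.loc[1, "total_cover"] == pytest.approx(16.0)
        assert by_rank.loc[1, "mean_cover_per_species"] == pytest.approx(16.0)

    def test_absent_rank_mean_is_nan(self, mini_dataset):
        ds = mini_dataset
        sub = ds.records[ds.records.species_id != "d"]
        from resurvey.data_model import assemble_dataset

        ds2 = assemble_dataset(sub, ds.traits, ds.plots, ds.years)
        by_rank = cover_by_rank(ds2, 1994)
        assert by_rank.loc[4, "total_cover"] == 0.0
        assert np.isnan(by_rank.loc[4, "mean_cover_per_species"])


class TestCommunityWeightedIndicator:
    def test_single_species_returns_its_rank(self):
        assert community_weighted_indicator({"x": 7.0}, {"x": 3}) == 3.0

    def test_equal_covers_average_ranks(self):
        assert community_weighted_indicator(
            {"x": 5.0, "y": 5.0}, {"x": 1, "y": 3}
        ) == pytest.approx(2.0)

    def test_hand_computed_weighted_mean(self):
        value = community_weighted_indicator(
            {"x": 10.0, "y": 5.0, "z": 1.0}, {"x": 1, "y": 2, "z": 3}
        )
        assert value == pytest.approx(23 / 16)

    def test_empty_plot_is_undefined_not_zero(self):
        with pytest.raises(UndefinedResultError):
            community_weighted_indicator({}, {})

    def test_nonpositive_cover_rejected(self):
        with pytest.raises(ValidationError):
            community_weighted_indicator({"x": 0.0}, {"x": 1})

    @given(
        covers=st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=8
        ),
        ranks=st.lists(st.integers(min_value=1, max_value=4), min_size=8, max_size=8),
        scale=st.floats(min_value=0.01, max_value=50.0),
    )
    def test_bounds_and_scale_invariance(self, covers, ranks, scale):
        names = [f"s{i}" for i in range(len(covers))]
        cov = dict(zip(names, covers))
        rk = dict(zip(names, ranks))
        value = community_weighted_indicator(cov, rk)
        used = [rk[n] for n in names]
        assert min(used) - 1e-9 <= value <= max(used) + 1e-9
        scaled = community_weighted_indicator(
            {k: v * scale for k, v in cov.items()}, rk
        )
        assert scaled == pytest.approx(value, rel=1e-9)

    @given(
        covers=st.lists(
            st.floats(min_value=0.1, max_value=50.0), min_size=2, max_size=6
        ),
        bump=st.floats(min_value=0.1, max_value=50.0),
    )
    def test_monotone_in_highest_ranked_cover(self, covers, bump):
        names = [f"s{i}" for i in range(len(covers))]
        ranks = {n: (4 if i == 0 else 1 + i % 3) for i, n in enumerate(names)}
        cov = dict(zip(names, covers))
        before = community_weighted_indicator(cov, ranks)
        cov[names[0]] += bump
        after = community_weighted_indicator(cov, ranks)
        if len(set(ranks.values())) > 1:
            assert after > before

    @given(
        covers=st.lists(
            st.floats(min_value=0.01, max_value=100.0), min_size=1, max_size=10
        ),
        ranks=st.lists(st.integers(min_value=1, max_value=4), min_size=10, max_size=10),
    )
    def test_matches_naive_loop_oracle(self, covers, ranks):
        names = [f"s{i}" for i in range(len(covers))]
        cov = dict(zip(names, covers))
        rk = dict(zip(names, ranks))
        num = den = 0.0
        for n in names:
            num += rk[n] * cov[n]
            den += cov[n]
        assert community_weighted_indicator(cov, rk) == pytest.approx(
            num / den, rel=1e-12
        )


class TestIndicatorSeries:
    def test_unchanged_plot_has_zero_delta(self, mini_dataset):
        deltas = indicator_deltas(indicator_series(mini_dataset))
        row = deltas[deltas.plot_id == "p4"].iloc[0]
        assert row.delta_thermic == pytest.approx(0.0)
        assert row.delta_moisture == pytest.approx(0.0)

    def test_cryophile_decline_raises_thermic_indicator(self):
        from resurvey.data_model import assemble_dataset
        from conftest import make_survey_frame

        rows = [
            ("p1", "t1", "A", 1994, "cold", 10.0),
            ("p1", "t1", "A", 1994, "warm", 5.0),
            ("p1", "t1", "A", 2004, "cold", 5.0),
            ("p1", "t1", "A", 2004, "warm", 10.0),
        ]
        traits = pd.DataFrame(
            {
                "species_id": ["cold", "warm"],
                "altitudinal_rank": [1, 2],
                "moisture_rank": [2, 2],
                "is_annual": [False, False],
            }
        ).set_index("species_id")
        attrs = pd.DataFrame(
            {
                "plot_id": ["p1"],
                "transect_id": "t1",
                "block_id": "A",
                "elevation_m": 3000.0,
                "aspect_deg": 180.0,
                "slope_deg": 30.0,
                "rock_pct": 50.0,
                "scree_pct": 30.0,
                "soil_pct": 10.0,
                "veg_pct": 10.0,
                "disturbed_years": [frozenset()],
            }
        ).set_index("plot_id")
        ds = assemble_dataset(
            make_survey_frame(rows), traits, attrs, (1994, 2004)
        )
        deltas = indicator_deltas(indicator_series(ds))
        assert deltas.iloc[0].delta_thermic > 0

    def test_undefined_years_flagged_not_imputed(self, mini_dataset):
        series = indicator_series(mini_dataset)
        p3_94 = series[(series.plot_id == "p3") & (series.year == 1994)].iloc[0]
        assert not p3_94.defined and np.isnan(p3_94.thermic)
        deltas = indicator_deltas(series)
        row = deltas[deltas.plot_id == "p3"].iloc[0]
        assert not row.defined and np.isnan(row.delta_thermic)

    def test_indicator_within_observed_rank_range(self, sim_dataset):
        series = indicator_series(sim_dataset)
        defined = series[series.defined]
        assert (defined.thermic >= 1.0).all() and (defined.thermic <= 4.0).all()
        assert (defined.moisture >= 1.0).all() and (defined.moisture <= 4.0).all()

    def test_rank_scale_correlation_diagnostic_runs(self, sim_dataset):
        rho, p = rank_correlation_check(sim_dataset.traits)
        assert -1.0 <= rho <= 1.0 and 0.0 <= p <= 1.0


class TestEquivalenceArithmetic:
    @pytest.mark.parametrize(
        "delta,expected", [(0.15, 15.0), (0.06, 6.0), (0.09, 9.0), (0.0, 0.0)]
    )
    def test_belt_fraction(self, delta, expected):
        assert belt_fraction(delta) == pytest.approx(expected)

    @pytest.mark.parametrize(
        "delta,extent,expected", [(0.15, 500.0, 75.0), (0.0, 500.0, 0.0), (0.09, 500.0, 45.0)]
    )
    def test_elevation_equivalent(self, delta, extent, expected):
        assert elevation_equivalent(delta, extent) == pytest.approx(expected)

    def test_elevation_equivalent_requires_positive_extent(self):
        with pytest.raises(ValidationError):
            elevation_equivalent(0.1, 0.0)

    def test_lapse_rate_conversion(self):
        assert lapse_rate_elevation(0.53, 0.65, round_to=10) == pytest.approx(80.0)
        assert lapse_rate_elevation(0.0, 0.65) == 0.0
        assert lapse_rate_elevation(0.65, 0.65) == pytest.approx(100.0)

    def test_zero_lapse_rate_rejected(self):
        with pytest.raises(ValidationError):
            lapse_rate_elevation(0.5, 0.0)

    def test_trend_rescale(self):
        assert trend_rescale(0.8, 30, 20, ndigits=2) == pytest.approx(0.53)
        assert trend_rescale(1.7, 30, 30) == pytest.approx(1.7)
        assert trend_rescale(1.2, 30, 10) == pytest.approx(0.4)
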