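"""Model selection ladder, contrasts, compact letters, Δ–Δ correlation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from resurvey.errors import ValidationError
from resurvey.inference import (
    ModelSpec,
    compact_letter_display,
    delta_correlation,
    fit_and_contrast,
    pearson_dispersion,
    select_count_family,
)


class TestPearsonDispersion:
    def test_perfect_fit_scores_zero(self):
        rep = pearson_dispersion([2, 2, 2], [2.0, 2.0, 2.0], 1)
        assert rep.statistic == 0.0 and not rep.overdispersed

    def test_hand_pearson_sum(self):
        rep = pearson_dispersion([0, 4, 2], [2.0, 2.0, 2.0], 1)
        assert rep.statistic == pytest.approx(2.0)
        assert rep.overdispersed

    def test_threshold_is_strict(self):
        rep = pearson_dispersion([0, 4, 2], [2.0, 2.0, 2.0], 1, threshold=2.0)
        assert not rep.overdispersed

    def test_nonpositive_fitted_rejected(self):
        with pytest.raises(ValidationError):
            pearson_dispersion([1, 2], [0.0, 1.0], 1)


def _count_frame(y, groups=2):
    n = len(y)
    return pd.DataFrame({"y": y, "g": np.repeat(list("ab"), n // 2)[:n]})


class TestSelectCountFamily:
    def test_poisson_data_prefers_poisson(self):
        rng = np.random.default_rng(11)
        hits = 0
        for _ in range(20):
            df = _count_frame(rng.poisson(5.0, 400))
            sel = select_count_family(df, ModelSpec(response="y", fixed="g", family="poisson"))
            hits += sel.chosen == "poisson"
        assert hits >= 18

    def test_overdispersed_data_prefers_negative_binomial(self):
        rng = np.random.default_rng(12)
        hits = 0
        for _ in range(20):
            lam = rng.gamma(0.5, 10.0, 400)
            df = _count_frame(rng.poisson(lam))
            sel = select_count_family(df, ModelSpec(response="y", fixed="g", family="poisson"))
            hits += sel.chosen == "negative_binomial"
        assert hits >= 18

    def test_constant_response_degenerates_to_poisson_with_zero_lrt(self):
        df = _count_frame(np.full(100, 3))
        sel = select_count_family(df, ModelSpec(response="y", fixed="g", family="poisson"))
        assert sel.chosen == "poisson" and sel.lrt_statistic == 0.0
        assert "degenerate" in sel.note

    def test_row_permutation_invariance(self):
        rng = np.random.default_rng(13)
        df = _count_frame(rng.poisson(4.0, 300))
        spec = ModelSpec(response="y", fixed="g", family="poisson")
        a = select_count_family(df, spec)
        b = select_count_family(df.sample(frac=1.0, random_state=5), spec)
        assert a.chosen == b.chosen
        assert a.lrt_statistic == pytest.approx(b.lrt_statistic, rel=1e-8)

    def test_non_integer_response_rejected(self):
        df = _count_frame(np.array([1.5] * 10))
        with pytest.raises(ValidationError):
            select_count_family(df, ModelSpec(response="y", fixed="g", family="poisson"))


class TestCompactLetterDisplay:
    def test_no_significant_pairs_share_one_letter(self):
        sig = np.zeros((3, 3), bool)
        assert compact_letter_display(["x", "y", "z"], sig) == {
            "x": "a", "y": "a", "z": "a"
        }

    def test_all_pairs_significant_get_distinct_letters(self):
        sig = ~np.eye(3, dtype=bool)
        out = compact_letter_display(["x", "y", "z"], sig)
        assert out == {"x": "a", "y": "b", "z": "c"}

    def test_chain_pattern_yields_bridging_letter(self):
        sig = np.zeros((3, 3), bool)
        sig[0, 2] = sig[2, 0] = True
        out = compact_letter_display(["1", "2", "3"], sig)
        assert out == {"1": "a", "2": "ab", "3": "b"}

    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_sharing_iff_nonsignificant_exhaustive(self, n):
        """Letter sharing must encode the significance matrix exactly."""
        pairs = list(itertools.combinations(range(n), 2))
        levels = [str(i) for i in range(n)]
        for bits in itertools.product([False, True], repeat=len(pairs)):
            sig = np.zeros((n, n), bool)
            for (i, j), b in zip(pairs, bits):
                sig[i, j] = sig[j, i] = b
            letters = compact_letter_display(levels, sig)
            for i, j in pairs:
                shared = set(letters[levels[i]]) & set(letters[levels[j]])
                assert bool(shared) == (not sig[i, j]), (bits, letters)

    def test_asymmetric_matrix_rejected(self):
        sig = np.zeros((2, 2), bool)
        sig[0, 1] = True
        with pytest.raises(ValidationError):
            compact_letter_display(["a", "b"], sig)


def _grouped_gaussian(rng, means, n_per, sd=1.0):
    k = len(means)
    df = pd.DataFrame(
        {
            "y": np.concatenate(
                [rng.normal(m, sd, n_per) for m in means]
            ),
            "g": np.repeat([f"g{i}" for i in range(k)], n_per),
        }
    )
    return df


class TestFitAndContrast:
    def test_identical_groups_share_a_letter(self):
        rng = np.random.default_rng(2)
        df = _grouped_gaussian(rng, [5.0, 5.0], 300)
        res = fit_and_contrast(
            df, ModelSpec(response="y", fixed="g", random_nesting=()), alpha=0.05
        )
        assert res.letters["g0"] == res.letters["g1"]
        assert abs(res.pairwise.iloc[0]["estimate"]) < 0.2

    def test_three_group_poisson_rate_ratio_pattern(self):
        rng = np.random.default_rng(22)
        n = 300
        df = pd.DataFrame(
            {
                "y": np.concatenate(
                    [rng.poisson(3.0, n), rng.poisson(3.0, n), rng.poisson(6.0, n)]
                ),
                "g": np.repeat(["g0", "g1", "g2"], n),
            }
        )
        res = fit_and_contrast(
            df, ModelSpec(response="y", fixed="g", random_nesting=(), family="poisson")
        )
        assert set(res.letters["g0"]) & set(res.letters["g1"])
        assert not set(res.letters["g0"]) & set(res.letters["g2"])

    def test_no_trend_gaussian_mixed_ci_covers_zero(self, sim_dataset):
        """Frozen responses: year contrast CI must cover 0 under the LMM."""
        from resurvey.turnover import richness_per_plot

        rows = []
        rng = np.random.default_rng(23)
        meta = sim_dataset.plot_meta()
        base = rng.normal(2.0, 0.3, len(meta))
        for year in sim_dataset.years:
            rows.append(
                pd.DataFrame(
                    {
                        "plot_id": meta.index,
                        "year": int(year),
                        "resp": base + rng.normal(0, 0.05, len(meta)),
                    }
                )
            )
        df = pd.concat(rows, ignore_index=True).join(meta, on="plot_id")
        res = fit_and_contrast(df, ModelSpec(response="resp", fixed="year"))
        pair = res.pairwise.iloc[0]
        assert pair["ci_low"] <= 0.0 <= pair["ci_high"]

    def test_zero_variance_mixed_estimates_match_ols_oracle(self):
        """Balanced design without group effects: LMM cell means = OLS cell means."""
        import statsmodels.formula.api as smf

        rng = np.random.default_rng(24)
        n_plot, years = 40, [1, 2, 3]
        df = pd.DataFrame(
            {
                "plot_id": np.repeat([f"p{i}" for i in range(n_plot)], len(years)),
                "block_id": np.repeat(
                    [f"b{i % 4}" for i in range(n_plot)], len(years)
                ),
                "transect_id": np.repeat(
                    [f"t{i % 8}" for i in range(n_plot)], len(years)
                ),
                "year": np.tile(years, n_plot),
            }
        )
        df["resp"] = rng.normal(5.0, 1.0, len(df))
        res = fit_and_contrast(df, ModelSpec(response="resp", fixed="year"))
        ols = smf.ols("resp ~ 0 + C(year)", data=df).fit()
        for est, ref in zip(
            [e.estimate for e in res.level_estimates], ols.params.to_numpy()
        ):
            assert est == pytest.approx(ref, rel=1e-6)

    def test_contrast_needs_two_levels(self):
        df = pd.DataFrame({"y": [1.0, 2.0], "g": ["a", "a"]})
        with pytest.raises(ValidationError):
            fit_and_contrast(df, ModelSpec(response="y", fixed="g", random_nesting=()))


def _delta_frame(rng, m=150, decades=2):
    return pd.DataFrame(
        {
            "plot_id": [f"p{i}" for i in range(m)] * decades,
            "transect_id": [f"t{i % 10}" for i in range(m)] * decades,
            "block_id": [f"b{i % 4}" for i in range(m)] * decades,
            "decade": np.repeat([f"d{k}" for k in range(decades)], m),
            "delta_thermic": rng.normal(0.0, 0.1, m * decades),
        }
    )


class TestDeltaCorrelation:
    def test_exact_negative_relation_recovered(self):
        df = _delta_frame(np.random.default_rng(31))
        df["delta_moisture"] = -df["delta_thermic"]
        res = delta_correlation(df)
        assert res.slope == pytest.approx(-1.0)
        assert res.significant and res.ci_high < 0

    def test_independent_noise_not_significant(self):
        rng = np.random.default_rng(32)
        df = _delta_frame(rng)
        df["delta_moisture"] = rng.normal(0.0, 0.1, len(df))
        res = delta_correlation(df)
        assert res.ci_low <= 0.0 <= res.ci_high

    def test_single_plot_rejected(self):
        rng = np.random.default_rng(33)
        df = _delta_frame(rng, m=1)
        df["delta_moisture"] = rng.normal(0.0, 0.1, len(df))
        with pytest.raises(ValidationError):
            delta_correlation(df)

    def test_all_undefined_rejected(self):
        df = _delta_frame(np.random.default_rng(34))
        df["delta_moisture"] = np.nan
        with pytest.raises(ValidationError):
            delta_correlation(df)
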