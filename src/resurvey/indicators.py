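"""Cover aggregation and cover-weighted community indicators.

The community-weighted *thermic indicator* of a plot is the cover-weighted
mean of the altitudinal ranks of the species present,

    I = Σᵢ rank(speciesᵢ) · cover(speciesᵢ) / Σᵢ cover(speciesᵢ),

and the *soil-moisture indicator* is the same weighted mean over moisture
ranks.  An increase of the thermic indicator over time (thermophilisation)
signals a shift towards more warmth-demanding assemblages; a decrease of the
moisture indicator (aridisation) a shift towards drought-adapted composition.
Plots with zero total cover have no defined indicator and are flagged, never
imputed.

The module also houses the small arithmetic that translates indicator change
into physical equivalents: fractions of a vegetation belt, metres of
elevation via a belt extent, and the lapse-rate / warming-trend conversions.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import AnalysisDataset, cover_matrix
from .errors import UndefinedResultError, ValidationError


def cover_sum_per_plot(ds: AnalysisDataset, year) -> pd.Series:
    """Cumulative cover (percent of plot area) of all species, per plot.

    On a 1-m² plot the value is numerically identical to dm².
    """
    return cover_matrix(ds, year).sum(axis=1).rename("cover_sum")


def cover_by_rank(ds: AnalysisDataset, year) -> pd.DataFrame:
    """Total cover over all plots and mean cover per species, by rank.

    The mean divides the rank total by the number of species of that rank in
    the dataset pool; ranks with no species get total 0 and NaN mean.
    Rank totals partition the grand total exactly.
    """
    cov = cover_matrix(ds, year)
    ranks = ds.traits.loc[ds.species_pool, "altitudinal_rank"]
    rows = []
    for rank in (1, 2, 3, 4):
        species = ranks.index[ranks == rank]
        total = float(cov[species].to_numpy().sum())
        n_sp = len(species)
        rows.append(
            {
                "altitudinal_rank": rank,
                "total_cover": total,
                "n_species": n_sp,
                "mean_cover_per_species": total / n_sp if n_sp else np.nan,
            }
        )
    return pd.DataFrame(rows).set_index("altitudinal_rank")


def community_weighted_indicator(covers, ranks) -> float:
    """Cover-weighted mean rank of one plot.

    Parameters
    ----------
    covers : mapping or Series
        species → cover percent, all strictly positive.
    ranks : mapping or Series
        species → integer rank; must cover every species in ``covers``.
    """
    covers = pd.Series(covers, dtype=float)
    if len(covers) == 0:
        raise UndefinedResultError("indicator undefined for an empty plot")
    if (covers <= 0).any():
        raise ValidationError("all covers must be > 0")
    ranks = pd.Series(ranks)
    missing = covers.index.difference(ranks.index)
    if len(missing):
        raise ValidationError(f"species without rank: {list(missing)[:5]}")
    r = ranks.loc[covers.index].astype(float)
    return float((r * covers).sum() / covers.sum())


def indicator_series(ds: AnalysisDataset) -> pd.DataFrame:
    """Per-plot, per-year thermic and moisture indicators plus raw deltas.

    Returns a tidy frame with one row per (plot, year): columns ``thermic``,
    ``moisture`` and ``defined`` (False for zero-cover plots, where the
    indicator columns hold NaN).  Raw per-plot deltas between consecutive
    surveys are available via :func:`indicator_deltas`; the model-based
    Δ indicator (the year effect size of a mixed model) lives in
    :mod:`resurvey.inference`.
    """
    therm = ds.traits.loc[ds.species_pool, "altitudinal_rank"].to_numpy(float)
    moist = ds.traits.loc[ds.species_pool, "moisture_rank"].to_numpy(float)
    frames = []
    for year in ds.years:
        cov = cover_matrix(ds, year).to_numpy()
        total = cov.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            thermic = (cov * therm).sum(axis=1) / total
            moisture = (cov * moist).sum(axis=1) / total
        defined = total > 0
        frames.append(
            pd.DataFrame(
                {
                    "plot_id": ds.plot_ids,
                    "year": int(year),
                    "thermic": np.where(defined, thermic, np.nan),
                    "moisture": np.where(defined, moisture, np.nan),
                    "defined": defined,
                }
            )
        )
    return pd.concat(frames, ignore_index=True)


def indicator_deltas(series: pd.DataFrame) -> pd.DataFrame:
    """Raw per-plot indicator differences between consecutive survey years.

    A delta is defined only when the indicator is defined in both years;
    undefined deltas hold NaN with ``defined`` False.
    """
    years = sorted(series["year"].unique())
    wide_t = series.pivot(index="plot_id", columns="year", values="thermic")
    wide_m = series.pivot(index="plot_id", columns="year", values="moisture")
    rows = []
    for y0, y1 in zip(years[:-1], years[1:]):
        dt = wide_t[y1] - wide_t[y0]
        dm = wide_m[y1] - wide_m[y0]
        rows.append(
            pd.DataFrame(
                {
                    "plot_id": wide_t.index,
                    "decade": f"{y0}-{y1}",
                    "delta_thermic": dt.to_numpy(),
                    "delta_moisture": dm.to_numpy(),
                    "defined": ~np.isnan(dt.to_numpy()),
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


def rank_correlation_check(traits: pd.DataFrame):
    """Spearman rank correlation between altitudinal and moisture ranks.

    Species-level diagnostic for whether the two indicator scales are
    confounded; midrank ties handled by the standard Spearman statistic.
    Returns (rho, p_value).
    """
    res = stats.spearmanr(
        traits["altitudinal_rank"].to_numpy(), traits["moisture_rank"].to_numpy()
    )
    return float(res.statistic), float(res.pvalue)


# --- physical-equivalence arithmetic -------------------------------------


def belt_fraction(delta_thermic: float) -> float:
    """Express an indicator change as a percentage of one vegetation belt.

    One indicator unit spans roughly one elevational vegetation belt, so the
    fraction is simply delta × 100.
    """
    return delta_thermic * 100.0


def elevation_equivalent(delta_thermic: float, belt_extent: float) -> float:
    """Metres of elevation equivalent to an indicator change.

    ``belt_extent`` is the vertical extent of one vegetation belt in metres.
    """
    if belt_extent <= 0:
        raise ValidationError("belt_extent must be > 0")
    return delta_thermic * belt_extent


def lapse_rate_elevation(
    delta_T: float, lapse_rate: float, round_to: float | None = None
) -> float:
    """Elevation difference equivalent to a temperature change.

    ``lapse_rate`` is in °C per 100 m (sign ignored).  With ``round_to``
    given, the result is rounded to that nearest multiple (e.g. 10 m).
    """
    if lapse_rate == 0:
        raise ValidationError("lapse rate must be nonzero")
    metres = abs(delta_T) / abs(lapse_rate) * 100.0
    if round_to:
        metres = round(metres / round_to) * round_to
    return metres


def trend_rescale(
    trend: float, period_years: float, target_years: float, ndigits: int | None = None
) -> float:
    """Rescale a temperature trend from one period length to another."""
    if period_years <= 0:
        raise ValidationError("period_years must be > 0")
    value = trend * target_years / period_years
    if ndigits is not None:
        value = round(value, ndigits)
    return value
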