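"""Richness and colonisation/disappearance accounting.

A *colonisation* is a species present in a plot at the resurvey that was
absent from that plot at the previous survey; a *disappearance* is the
converse.  Relative rates divide event counts by the number of at-risk
species × plot combinations: plots not yet occupied for colonisation,
previously occupied plots for disappearance.  Every quantity here satisfies
the bookkeeping identity

    richness(t+1) = richness(t) + colonisations − disappearances

per plot, and relative rates equal the mean of the corresponding Bernoulli
trial outcomes exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import AnalysisDataset, occupancy_matrix
from .errors import UndefinedResultError, ValidationError


@dataclass(frozen=True)
class TurnoverTable:
    """Colonisation/disappearance counts for one decade (year_from → year_to).

    ``per_plot`` has one row per plot with columns ``colonisations`` and
    ``disappearances``; ``per_plot_rank`` additionally stratifies by
    altitudinal rank and carries the at-risk denominators
    (``n_unoccupied`` for colonisation, ``n_occupied`` for disappearance).
    """

    year_from: int
    year_to: int
    per_plot: pd.DataFrame
    per_plot_rank: pd.DataFrame


@dataclass(frozen=True)
class RelativeRates:
    """Pooled relative colonisation/disappearance for one rank and decade.

    ``None`` rate means the denominator was zero (undefined, not 0).
    """

    rank: int
    colonisation: float | None
    disappearance: float | None
    n_unoccupied: int
    n_occupied: int
    n_colonised: int
    n_disappeared: int


def richness_per_plot(ds: AnalysisDataset, year) -> pd.Series:
    """Number of species with cover > 0 per plot in one survey year."""
    occ = occupancy_matrix(ds, year)
    return occ.sum(axis=1).astype(int).rename("richness")


def _validate_year_pair(ds, year_from, year_to):
    for y in (year_from, year_to):
        if y not in ds.years:
            raise ValidationError(f"year {y} not in dataset years {ds.years}")
    if year_from == year_to:
        raise ValidationError("year_from and year_to must differ")


def turnover_events(ds: AnalysisDataset, year_from, year_to) -> TurnoverTable:
    """Per-plot (and per-plot-per-rank) colonisation/disappearance counts."""
    _validate_year_pair(ds, year_from, year_to)
    occ_from = occupancy_matrix(ds, year_from).to_numpy(bool)
    occ_to = occupancy_matrix(ds, year_to).to_numpy(bool)
    colon = occ_to & ~occ_from
    disap = occ_from & ~occ_to

    plots = pd.Index(ds.plot_ids, name="plot_id")
    per_plot = pd.DataFrame(
        {
            "colonisations": colon.sum(axis=1),
            "disappearances": disap.sum(axis=1),
        },
        index=plots,
    )

    ranks = ds.traits.loc[ds.species_pool, "altitudinal_rank"].to_numpy()
    rows = []
    for rank in (1, 2, 3, 4):
        sel = ranks == rank
        rows.append(
            pd.DataFrame(
                {
                    "plot_id": plots,
                    "altitudinal_rank": rank,
                    "colonisations": colon[:, sel].sum(axis=1),
                    "disappearances": disap[:, sel].sum(axis=1),
                    "n_unoccupied": (~occ_from[:, sel]).sum(axis=1),
                    "n_occupied": occ_from[:, sel].sum(axis=1),
                }
            )
        )
    per_plot_rank = pd.concat(rows, ignore_index=True)
    return TurnoverTable(
        year_from=int(year_from),
        year_to=int(year_to),
        per_plot=per_plot,
        per_plot_rank=per_plot_rank,
    )


def relative_rates(
    ds: AnalysisDataset, year_from, year_to, rank: int, pool_species: bool = True
):
    """Pooled relative colonisation/disappearance for one altitudinal rank.

    With ``pool_species=True`` (default) events and denominators are pooled
    over all species of the rank; with ``False`` a per-species DataFrame of
    rates is returned instead (diagnostic view).
    """
    if rank not in (1, 2, 3, 4):
        raise ValidationError(f"rank must be in 1..4, got {rank}")
    _validate_year_pair(ds, year_from, year_to)
    species = [
        s for s in ds.species_pool if ds.traits.loc[s, "altitudinal_rank"] == rank
    ]
    if not species:
        raise UndefinedResultError(f"no species of rank {rank} in the dataset")

    occ_from = occupancy_matrix(ds, year_from)[species].to_numpy(bool)
    occ_to = occupancy_matrix(ds, year_to)[species].to_numpy(bool)
    colonised = occ_to & ~occ_from
    disappeared = occ_from & ~occ_to

    if not pool_species:
        out = pd.DataFrame(
            {
                "species_id": species,
                "n_unoccupied": (~occ_from).sum(axis=0),
                "n_occupied": occ_from.sum(axis=0),
                "n_colonised": colonised.sum(axis=0),
                "n_disappeared": disappeared.sum(axis=0),
            }
        )
        out["colonisation"] = np.where(
            out["n_unoccupied"] > 0, out["n_colonised"] / out["n_unoccupied"], np.nan
        )
        out["disappearance"] = np.where(
            out["n_occupied"] > 0, out["n_disappeared"] / out["n_occupied"], np.nan
        )
        return out

    n_unocc = int((~occ_from).sum())
    n_occ = int(occ_from.sum())
    n_col = int(colonised.sum())
    n_dis = int(disappeared.sum())
    return RelativeRates(
        rank=rank,
        colonisation=(n_col / n_unocc) if n_unocc else None,
        disappearance=(n_dis / n_occ) if n_occ else None,
        n_unoccupied=n_unocc,
        n_occupied=n_occ,
        n_colonised=n_col,
        n_disappeared=n_dis,
    )


def bernoulli_table(ds: AnalysisDataset, year_from, year_to) -> pd.DataFrame:
    """Long table of colonisation/disappearance Bernoulli trials.

    One row per (species, plot, trial_type) where the plot is at risk for
    that trial type at ``year_from``: unoccupied plots yield colonisation
    trials, occupied plots disappearance trials.  ``outcome`` is 1 for a
    successful colonisation / an actual disappearance, else 0.  Carries
    species rank and plot grouping labels for downstream mixed models.
    """
    _validate_year_pair(ds, year_from, year_to)
    species = ds.species_pool
    occ_from = occupancy_matrix(ds, year_from).to_numpy(bool)
    occ_to = occupancy_matrix(ds, year_to).to_numpy(bool)

    plots = np.asarray(ds.plot_ids, dtype=object)
    meta = ds.plot_meta()
    ranks = ds.traits.loc[species, "altitudinal_rank"].to_numpy()
    decade = f"{year_from}-{year_to}"

    frames = []
    for trial_type, at_risk, success in (
        ("colonisation", ~occ_from, occ_to & ~occ_from),
        ("disappearance", occ_from, occ_from & ~occ_to),
    ):
        pi, si = np.nonzero(at_risk)
        frames.append(
            pd.DataFrame(
                {
                    "species_id": np.asarray(species, dtype=object)[si],
                    "altitudinal_rank": ranks[si],
                    "plot_id": plots[pi],
                    "trial_type": trial_type,
                    "decade": decade,
                    "outcome": success[pi, si].astype(int),
                }
            )
        )
    out = pd.concat(frames, ignore_index=True)
    out["transect_id"] = meta["transect_id"].reindex(out["plot_id"]).to_numpy()
    out["block_id"] = meta["block_id"].reindex(out["plot_id"]).to_numpy()
    return out
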