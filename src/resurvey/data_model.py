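"""Domain tables, CSV readers/writers, validation, and dataset assembly.

The package is pandas-centric: a *survey table* is a long-format
:class:`pandas.DataFrame` with one row per (plot, year, species) presence and
columns ``plot_id, transect_id, block_id, year, species_id, cover``.  Cover is
the visually estimated percentage of the 1-m² plot area occupied by the
species; absence is encoded by the absence of a row, so every stored cover is
strictly positive.  Because the plots measure 1 m² = 100 dm², a cover
percentage and a cover in dm² are numerically identical.

A *traits table* assigns each species an altitudinal rank (1 = subnival–nival,
2 = alpine–subnival, 3 = alpine, 4 = (montane–)treeline–alpine), a Landolt-type
soil-moisture rank (1 = very dry … 4 = very moist) and an annual flag.  A
*plot-attribute table* carries topography and surface-type covers per plot.

:func:`assemble_dataset` applies the standard resurvey filters — keep only
plots surveyed in every requested campaign, drop plots disturbed (rockfall,
substrate movement) in any requested campaign, drop annual species — and
returns an :class:`AnalysisDataset` with a provenance log of what was removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    ConsistencyError,
    EmptyDatasetError,
    SchemaError,
    ValidationError,
)

logger = logging.getLogger(__name__)

SURVEY_COLUMNS = ["plot_id", "transect_id", "block_id", "year", "species_id", "cover"]

#: Default mapping from canonical field names to on-disk CSV column names.
DEFAULT_SURVEY_SCHEMA = {
    "plot_id": "plot_id",
    "transect_id": "transect_id",
    "block_id": "block_id",
    "year": "year",
    "species_id": "species_id",
    "cover": "cover_pct",
}


@dataclass(frozen=True)
class AnalysisDataset:
    """A validated, filtered plot set restricted to a chosen survey-year set.

    Attributes
    ----------
    records : pandas.DataFrame
        Long survey records (``SURVEY_COLUMNS``) for the included plots/years.
    plots : pandas.DataFrame
        Plot attributes indexed by ``plot_id`` for every included plot.
    years : tuple of int
        The requested survey years, strictly increasing.
    traits : pandas.DataFrame
        Species traits indexed by ``species_id`` covering the species pool.
    provenance : tuple of str
        Human-readable log of each filter applied and the counts removed.
    """

    records: pd.DataFrame
    plots: pd.DataFrame
    years: tuple
    traits: pd.DataFrame
    provenance: tuple = field(default_factory=tuple)

    @property
    def plot_ids(self) -> list:
        return list(self.plots.index)

    @property
    def species_pool(self) -> list:
        """Union of species observed in any included year, sorted."""
        return sorted(self.records["species_id"].unique())

    def records_for_year(self, year) -> pd.DataFrame:
        if year not in self.years:
            raise ValidationError(f"year {year} not in dataset years {self.years}")
        return self.records[self.records["year"] == year]

    def plot_meta(self) -> pd.DataFrame:
        """plot_id → (transect_id, block_id), one row per plot."""
        meta = (
            self.records[["plot_id", "transect_id", "block_id"]]
            .drop_duplicates("plot_id")
            .set_index("plot_id")
        )
        # plots never observed in any record still belong to the dataset;
        # their grouping labels come from the attribute table if present
        missing = [p for p in self.plots.index if p not in meta.index]
        if missing:
            extra = pd.DataFrame(index=pd.Index(missing, name="plot_id"))
            for col in ("transect_id", "block_id"):
                extra[col] = (
                    self.plots.loc[missing, col] if col in self.plots.columns else pd.NA
                )
            meta = pd.concat([meta, extra])
        return meta.loc[self.plots.index]


def _resolve_schema(df: pd.DataFrame, schema: dict | None) -> dict:
    schema = {**DEFAULT_SURVEY_SCHEMA, **(schema or {})}
    missing = [v for v in schema.values() if v not in df.columns]
    if missing:
        raise SchemaError(f"survey CSV missing column(s): {', '.join(missing)}")
    return schema


def validate_survey_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate a canonical-column survey table and drop zero-cover rows.

    Raises on out-of-range covers, duplicate (plot, year, species) rows and
    plots mapped to more than one transect or block.
    """
    df = df.copy()
    df["cover"] = pd.to_numeric(df["cover"], errors="raise")
    df["year"] = df["year"].astype(int)

    bad = df.index[(df["cover"] < 0) | (df["cover"] > 100)]
    if len(bad):
        raise ValidationError(
            f"cover outside [0, 100] at row index {bad[0]} "
            f"(value {df.loc[bad[0], 'cover']!r})"
        )

    n_zero = int((df["cover"] == 0).sum())
    if n_zero:
        logger.warning("dropping %d zero-cover row(s); absence is encoded by no record", n_zero)
        df = df[df["cover"] > 0]

    dup = df.duplicated(subset=["plot_id", "year", "species_id"])
    if dup.any():
        first = df[dup].iloc[0]
        raise ValidationError(
            "duplicate (plot, year, species) row: "
            f"({first['plot_id']}, {first['year']}, {first['species_id']})"
        )

    for col in ("transect_id", "block_id"):
        counts = df.groupby("plot_id", sort=False)[col].nunique()
        conflicted = counts[counts > 1]
        if len(conflicted):
            raise ConsistencyError(
                f"plot {conflicted.index[0]!r} is mapped to "
                f"{conflicted.iloc[0]} different {col} values"
            )
    return df.reset_index(drop=True)[SURVEY_COLUMNS]


def read_survey_csv(path, schema: dict | None = None) -> pd.DataFrame:
    """Read and validate a long-format survey CSV.

    Parameters
    ----------
    path : str or path-like
        CSV with header; UTF-8; '.' decimal separator.
    schema : dict, optional
        Overrides mapping canonical names (``plot_id`` … ``cover``) to the
        file's column names; defaults to :data:`DEFAULT_SURVEY_SCHEMA`.
    """
    raw = pd.read_csv(path, dtype={})
    resolved = _resolve_schema(raw, schema)
    df = raw.rename(columns={v: k for k, v in resolved.items()})
    for col in ("plot_id", "transect_id", "block_id", "species_id"):
        df[col] = df[col].astype(str)
    return validate_survey_table(df[SURVEY_COLUMNS])


def write_survey_csv(df: pd.DataFrame, path, schema: dict | None = None) -> None:
    """Write a survey table back to CSV using the external column names."""
    schema = {**DEFAULT_SURVEY_SCHEMA, **(schema or {})}
    out = df[SURVEY_COLUMNS].rename(columns=schema)
    out.to_csv(path, index=False)


def read_traits_csv(path) -> pd.DataFrame:
    """Read the species-trait CSV (species_id, altitudinal_rank, moisture_rank, is_annual)."""
    df = pd.read_csv(path)
    required = ["species_id", "altitudinal_rank", "moisture_rank", "is_annual"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"traits CSV missing column(s): {', '.join(missing)}")
    df["species_id"] = df["species_id"].astype(str)
    for col in ("altitudinal_rank", "moisture_rank"):
        df[col] = df[col].astype(int)
        bad = df.index[~df[col].isin([1, 2, 3, 4])]
        if len(bad):
            raise ValidationError(
                f"{col} outside {{1..4}} at row index {bad[0]} "
                f"(species {df.loc[bad[0], 'species_id']!r})"
            )
    if df["is_annual"].dtype == object:
        df["is_annual"] = df["is_annual"].astype(str).str.lower().map(
            {"true": True, "false": False}
        )
        if df["is_annual"].isna().any():
            raise ValidationError("is_annual must be true/false")
    df["is_annual"] = df["is_annual"].astype(bool)
    if df["species_id"].duplicated().any():
        raise ValidationError("duplicate species_id in traits CSV")
    return df.set_index("species_id")


def write_traits_csv(traits: pd.DataFrame, path) -> None:
    traits.reset_index().to_csv(path, index=False)


def _parse_year_set(v):
    if pd.isna(v) or str(v).strip() == "":
        return frozenset()
    return frozenset(int(float(y)) for y in str(v).split(";"))


def read_plots_csv(path) -> pd.DataFrame:
    """Read the plot-attribute CSV.

    Columns: plot_id, elevation_m, aspect_deg, slope_deg, rock_pct, scree_pct,
    soil_pct, veg_pct, disturbed_years (semicolon-separated, may be empty);
    optional ruggedness_m, transect_id, block_id, surveyed_years (semicolon
    list of campaigns the plot was actually visited in; absent ⇒ assumed
    visited in every campaign).
    """
    df = pd.read_csv(path)
    required = [
        "plot_id", "elevation_m", "aspect_deg", "slope_deg",
        "rock_pct", "scree_pct", "soil_pct", "veg_pct", "disturbed_years",
    ]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"plots CSV missing column(s): {', '.join(missing)}")
    df["plot_id"] = df["plot_id"].astype(str)
    for col in ("rock_pct", "scree_pct", "soil_pct", "veg_pct"):
        if ((df[col] < 0) | (df[col] > 100)).any():
            raise ValidationError(f"{col} outside [0, 100]")

    df["disturbed_years"] = df["disturbed_years"].map(_parse_year_set)
    if "surveyed_years" in df.columns:
        df["surveyed_years"] = df["surveyed_years"].map(_parse_year_set)
    if df["plot_id"].duplicated().any():
        raise ValidationError("duplicate plot_id in plots CSV")
    for col in ("transect_id", "block_id"):
        if col in df.columns:
            df[col] = df[col].astype(str)
    return df.set_index("plot_id")


def write_plots_csv(plots: pd.DataFrame, path) -> None:
    out = plots.copy()
    for col in ("disturbed_years", "surveyed_years"):
        if col in out.columns:
            out[col] = out[col].map(lambda s: ";".join(str(y) for y in sorted(s)))
    out.reset_index().to_csv(path, index=False)


def assemble_dataset(
    records: pd.DataFrame,
    traits: pd.DataFrame,
    attrs: pd.DataFrame,
    years,
) -> AnalysisDataset:
    """Build the filtered analysis dataset for a chosen survey-year set.

    Filters, in order: restrict to the requested years; keep only plots
    surveyed in *all* requested years; drop plots disturbed in any requested
    year; drop annual species.  Disturbance is evaluated against the requested
    year set only, so a two-survey dataset can legitimately retain more plots
    than the three-survey dataset drawn from the same records.
    """
    years = tuple(int(y) for y in years)
    if list(years) != sorted(set(years)):
        raise ValidationError("years must be strictly increasing")
    present_years = set(records["year"].unique())
    missing = [y for y in years if y not in present_years]
    if missing:
        raise ValidationError(f"requested year(s) not present in records: {missing}")

    provenance = []
    rec = records[records["year"].isin(years)].copy()

    known_plots = set(attrs.index)
    no_attrs = sorted(set(rec["plot_id"].unique()) - known_plots)
    if no_attrs:
        raise ConsistencyError(
            f"{len(no_attrs)} plot(s) lack attribute data, e.g. {no_attrs[0]!r}"
        )

    # Coverage: records are presence-only, so a recordless plot-year is
    # ambiguous (not visited vs. visited but bare).  The attribute table's
    # optional surveyed_years column is the authority; without it every plot
    # in the attribute table is assumed visited in every campaign.
    requested = set(years)
    if "surveyed_years" in attrs.columns:
        covered = {p for p in attrs.index if requested <= attrs.loc[p, "surveyed_years"]}
    else:
        covered = known_plots
    candidate = sorted(covered)
    provenance.append(
        f"kept {len(candidate)} plot(s) surveyed in all of {years}; "
        f"dropped {len(known_plots) - len(candidate)} not covering every year"
    )
    rec = rec[rec["plot_id"].isin(covered)]

    disturbed = [
        p for p in candidate if attrs.loc[p, "disturbed_years"] & set(years)
    ]
    candidate = [p for p in candidate if p not in set(disturbed)]
    provenance.append(
        f"removed {len(disturbed)} plot(s) disturbed within {years}"
    )

    rec = rec[rec["plot_id"].isin(candidate)]

    species_seen = set(rec["species_id"].unique())
    untraited = species_seen - set(traits.index)
    if untraited:
        raise ConsistencyError(
            f"species without traits row: {sorted(untraited)[:5]}"
        )
    annual = [s for s in species_seen if traits.loc[s, "is_annual"]]
    n_annual_rows = int(rec["species_id"].isin(annual).sum())
    rec = rec[~rec["species_id"].isin(annual)]
    provenance.append(
        f"removed {len(annual)} annual species ({n_annual_rows} record(s))"
    )

    if not candidate:
        raise EmptyDatasetError("no plots remain after filtering")

    plots = attrs.loc[candidate]
    pool = sorted(rec["species_id"].unique())
    return AnalysisDataset(
        records=rec.reset_index(drop=True),
        plots=plots,
        years=years,
        traits=traits.loc[pool],
        provenance=tuple(provenance),
    )


def occupancy_matrix(ds: AnalysisDataset, year) -> pd.DataFrame:
    """Binary plot × species matrix for one survey year.

    Rows are all dataset plots (plots without records give all-zero rows);
    columns are the union of species over *all* dataset years, so matrices for
    different years share identical row and column orderings.
    """
    if year not in ds.years:
        raise ValidationError(f"year {year} not in dataset years {ds.years}")
    plots = pd.Index(ds.plot_ids, name="plot_id")
    species = pd.Index(ds.species_pool, name="species_id")
    mat = pd.DataFrame(0, index=plots, columns=species, dtype=np.int8)
    sub = ds.records_for_year(year)
    if len(sub):
        mat.values[
            plots.get_indexer(sub["plot_id"]), species.get_indexer(sub["species_id"])
        ] = 1
    return mat


def cover_matrix(ds: AnalysisDataset, year) -> pd.DataFrame:
    """Plot × species cover matrix (percent; 0 where absent) for one year."""
    if year not in ds.years:
        raise ValidationError(f"year {year} not in dataset years {ds.years}")
    plots = pd.Index(ds.plot_ids, name="plot_id")
    species = pd.Index(ds.species_pool, name="species_id")
    mat = pd.DataFrame(0.0, index=plots, columns=species)
    sub = ds.records_for_year(year)
    if len(sub):
        mat.values[
            plots.get_indexer(sub["plot_id"]), species.get_indexer(sub["species_id"])
        ] = sub["cover"].to_numpy()
    return mat
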