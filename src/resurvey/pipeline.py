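"""End-to-end orchestration: assemble → turnover → cover/indicators → models.

`run_full_analysis` executes the whole chain for one or more survey-year
sets (e.g. all three campaigns, and first + last only), over the entire
study area and per block, and writes tidy CSV report tables: raw-data means
± s.e. with compact letters for richness, turnover counts, cover sums, the
model-based Δ indicators, pooled relative colonisation/disappearance rates
per altitudinal rank, the Δ–Δ correlation, a first-ever-recorded species
summary, and a provenance log.  Every number in the bundle is produced by a
library operation; this layer only arranges calls and writes files.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import turnover as tv
from .data_model import (
    AnalysisDataset,
    assemble_dataset,
    read_plots_csv,
    read_survey_csv,
    read_traits_csv,
)
from .errors import UndefinedResultError, ValidationError
from .indicators import (
    belt_fraction,
    cover_sum_per_plot,
    elevation_equivalent,
    indicator_deltas,
    indicator_series,
    rank_correlation_check,
)
from .inference import (
    ModelSpec,
    delta_correlation,
    fit_and_contrast,
    select_count_family,
)

logger = logging.getLogger(__name__)

FULL_NESTING = ("block_id", "transect_id", "plot_id")
BLOCK_NESTING = ("transect_id", "plot_id")


@dataclass
class PipelineConfig:
    """Inputs, filters, model options and output location for one run."""

    survey_path: str = "survey.csv"
    traits_path: str = "traits.csv"
    plots_path: str = "plots.csv"
    raster_path: str | None = None
    year_sets: tuple = ()  # empty → (all years, (first, last))
    alpha: float = 0.05
    dispersion_threshold: float = 1.2
    belt_extent_m: float = 500.0
    lapse_rate_c_per_100m: float = 0.65
    out_dir: str | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must be in (0, 1)")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {k: v for k, v in raw.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        if cfg.year_sets:
            cfg.year_sets = tuple(tuple(int(y) for y in ys) for ys in cfg.year_sets)
        return cfg


def _scopes(ds: AnalysisDataset):
    """('All', full dataset) plus one restricted dataset per block."""
    yield "All", ds, FULL_NESTING
    meta = ds.plot_meta()
    for block in sorted(meta["block_id"].dropna().unique()):
        plots = meta.index[meta["block_id"] == block]
        sub = AnalysisDataset(
            records=ds.records[ds.records["plot_id"].isin(plots)].reset_index(drop=True),
            plots=ds.plots.loc[plots],
            years=ds.years,
            traits=ds.traits,
            provenance=ds.provenance + (f"restricted to block {block}",),
        )
        yield str(block), sub, BLOCK_NESTING


def _with_meta(df: pd.DataFrame, ds: AnalysisDataset) -> pd.DataFrame:
    return df.join(ds.plot_meta(), on="plot_id")


def _mean_se(values: pd.Series):
    v = values.dropna()
    return float(v.mean()), float(v.sem()) if len(v) > 1 else np.nan, int(len(v))


def summarise_richness(ds: AnalysisDataset, alpha: float, threshold: float):
    """Raw means ± s.e. and model letters for richness per year, per scope."""
    rows, selections = [], []
    for scope, sub, nesting in _scopes(ds):
        long = pd.concat(
            [
                tv.richness_per_plot(sub, y).rename("richness").reset_index().assign(year=int(y))
                for y in sub.years
            ],
            ignore_index=True,
        )
        long = _with_meta(long.set_index("plot_id"), sub).reset_index()
        spec = ModelSpec(
            response="richness", fixed="year", random_nesting=nesting, family="poisson"
        )
        sel = select_count_family(long, spec, alpha=alpha, dispersion_threshold=threshold)
        family = sel.escalated_to or sel.chosen
        fitted = fit_and_contrast(
            long,
            ModelSpec(response="richness", fixed="year", random_nesting=nesting, family=family),
            alpha=alpha,
        )
        selections.append({"scope": scope, "response": "richness", **_sel_row(sel)})
        for y in sub.years:
            mean, se, n = _mean_se(long.loc[long["year"] == y, "richness"])
            rows.append(
                {
                    "scope": scope, "year": int(y), "mean": mean, "se": se, "n": n,
                    "letters": fitted.letters[str(y)], "family": family,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(selections)


def _sel_row(sel):
    return {
        "chosen": sel.chosen,
        "lrt_statistic": sel.lrt_statistic,
        "lrt_p": sel.p_value,
        "dispersion": sel.dispersion.statistic,
        "overdispersed": sel.dispersion.overdispersed,
        "escalated_to": sel.escalated_to or "",
    }


def summarise_turnover(ds: AnalysisDataset, alpha: float, threshold: float):
    """Colonisations/disappearances per decade with decade × type letters."""
    rows, selections = [], []
    decades = list(zip(ds.years[:-1], ds.years[1:]))
    for scope, sub, nesting in _scopes(ds):
        frames = []
        for y0, y1 in decades:
            tt = tv.turnover_events(sub, y0, y1)
            for kind in ("colonisations", "disappearances"):
                frames.append(
                    pd.DataFrame(
                        {
                            "plot_id": tt.per_plot.index,
                            "count": tt.per_plot[kind].to_numpy(),
                            "decade": f"{y0}-{y1}",
                            "type": kind,
                        }
                    )
                )
        long = pd.concat(frames, ignore_index=True)
        long["cell"] = long["decade"] + ":" + long["type"]
        long = _with_meta(long.set_index("plot_id"), sub).reset_index()
        spec = ModelSpec(response="count", fixed="cell", random_nesting=nesting, family="poisson")
        sel = select_count_family(long, spec, alpha=alpha, dispersion_threshold=threshold)
        family = sel.escalated_to or sel.chosen
        fitted = fit_and_contrast(
            long,
            ModelSpec(response="count", fixed="cell", random_nesting=nesting, family=family),
            alpha=alpha,
        )
        selections.append({"scope": scope, "response": "turnover", **_sel_row(sel)})
        for cell in sorted(long["cell"].unique()):
            decade, kind = cell.split(":")
            mean, se, n = _mean_se(long.loc[long["cell"] == cell, "count"])
            rows.append(
                {
                    "scope": scope, "decade": decade, "type": kind,
                    "mean": mean, "se": se, "n": n,
                    "letters": fitted.letters[cell], "family": family,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(selections)


def summarise_cover(ds: AnalysisDataset, alpha: float):
    """Cover sums per plot and year (Gaussian LMM letters)."""
    rows = []
    for scope, sub, nesting in _scopes(ds):
        long = pd.concat(
            [
                cover_sum_per_plot(sub, y).reset_index().assign(year=int(y))
                for y in sub.years
            ],
            ignore_index=True,
        )
        long = _with_meta(long.set_index("plot_id"), sub).reset_index()
        fitted = fit_and_contrast(
            long,
            ModelSpec(response="cover_sum", fixed="year", random_nesting=nesting),
            alpha=alpha,
        )
        for y in sub.years:
            mean, se, n = _mean_se(long.loc[long["year"] == y, "cover_sum"])
            rows.append(
                {
                    "scope": scope, "year": int(y), "mean": mean, "se": se, "n": n,
                    "letters": fitted.letters[str(y)],
                }
            )
    return pd.DataFrame(rows)


def summarise_indicators(ds: AnalysisDataset, alpha: float):
    """Model-based Δ indicators (year-contrast effect sizes) per scope.

    The Δ indicator for a decade is the mixed-model contrast between the
    two survey years; letters compare the decades' Δ values against each
    other via the raw per-plot deltas.
    """
    rows = []
    for scope, sub, nesting in _scopes(ds):
        series = _with_meta(indicator_series(sub).set_index("plot_id"), sub).reset_index()
        series = series[series["defined"]]
        deltas = indicator_deltas(indicator_series(sub))
        deltas = _with_meta(deltas.set_index("plot_id"), sub).reset_index()
        for indicator in ("thermic", "moisture"):
            fitted = fit_and_contrast(
                series,
                ModelSpec(response=indicator, fixed="year", random_nesting=nesting),
                alpha=alpha,
            )
            delta_col = f"delta_{indicator}"
            sub_d = deltas[deltas["defined"]]
            if sub_d["decade"].nunique() >= 2:
                dl = fit_and_contrast(
                    sub_d,
                    ModelSpec(response=delta_col, fixed="decade", random_nesting=nesting),
                    alpha=alpha,
                ).letters
            else:
                dl = {d: "" for d in sub_d["decade"].unique()}
            for y0, y1 in zip(sub.years[:-1], sub.years[1:]):
                pair = fitted.pairwise[fitted.pairwise["term"] == f"{y1} - {y0}"].iloc[0]
                rows.append(
                    {
                        "scope": scope,
                        "indicator": indicator,
                        "decade": f"{y0}-{y1}",
                        "delta": float(pair["estimate"]),
                        "se": float(pair["se"]),
                        "ci_low": float(pair["ci_low"]),
                        "ci_high": float(pair["ci_high"]),
                        "p_adjusted": float(pair["p_adjusted"]),
                        "letters": dl.get(f"{y0}-{y1}", ""),
                    }
                )
    return pd.DataFrame(rows)


def summarise_relative_rates(ds: AnalysisDataset):
    rows = []
    for y0, y1 in zip(ds.years[:-1], ds.years[1:]):
        for rank in (1, 2, 3, 4):
            try:
                rr = tv.relative_rates(ds, y0, y1, rank)
            except UndefinedResultError:
                continue
            rows.append(
                {
                    "decade": f"{y0}-{y1}",
                    "altitudinal_rank": rank,
                    "relative_colonisation": rr.colonisation,
                    "relative_disappearance": rr.disappearance,
                    "n_unoccupied": rr.n_unoccupied,
                    "n_occupied": rr.n_occupied,
                }
            )
    return pd.DataFrame(rows)


def summarise_new_species(ds: AnalysisDataset) -> pd.DataFrame:
    """Per-year counts of first-ever-recorded species, by altitudinal rank.

    A species is new in year y when it is absent from every plot in every
    earlier dataset year; species present from the first year are never
    counted.
    """
    if len(ds.years) < 2:
        raise ValidationError("need ≥ 2 years to define first records")
    first_year = ds.records.groupby("species_id")["year"].min()
    rows = []
    for year in ds.years[1:]:
        new = first_year.index[first_year == year]
        ranks = ds.traits.loc[new, "altitudinal_rank"]
        for rank in (1, 2, 3, 4):
            rows.append(
                {
                    "year": int(year),
                    "altitudinal_rank": rank,
                    "n_new_species": int((ranks == rank).sum()),
                }
            )
        rows.append(
            {"year": int(year), "altitudinal_rank": 0, "n_new_species": int(len(new))}
        )
    out = pd.DataFrame(rows)
    return out


def run_full_analysis(cfg: PipelineConfig) -> dict:
    """Execute the full chain; returns the report bundle as a dict of tables.

    With ``cfg.out_dir`` set, each table is also written as
    ``<out_dir>/<dataset-tag>_<table>.csv`` together with a provenance log.
    """
    records = read_survey_csv(cfg.survey_path)
    traits = read_traits_csv(cfg.traits_path)
    attrs = read_plots_csv(cfg.plots_path)
    all_years = tuple(sorted(records["year"].unique()))
    year_sets = cfg.year_sets or (
        (all_years, (all_years[0], all_years[-1])) if len(all_years) > 2 else (all_years,)
    )

    bundle: dict = {}
    provenance = [f"seed={cfg.seed}", f"alpha={cfg.alpha}"]
    for years in year_sets:
        tag = "-".join(str(y) for y in years)
        stage = f"dataset {tag}"
        try:
            ds = assemble_dataset(records, traits, attrs, years)
            provenance.extend(f"[{tag}] {line}" for line in ds.provenance)
            provenance.append(
                f"[{tag}] {len(ds.plot_ids)} plots, {len(ds.species_pool)} species"
            )

            stage = f"richness models ({tag})"
            richness, sel_r = summarise_richness(ds, cfg.alpha, cfg.dispersion_threshold)
            stage = f"turnover models ({tag})"
            turnover_tbl, sel_t = summarise_turnover(ds, cfg.alpha, cfg.dispersion_threshold)
            stage = f"cover models ({tag})"
            cover = summarise_cover(ds, cfg.alpha)
            stage = f"indicator models ({tag})"
            indicators_tbl = summarise_indicators(ds, cfg.alpha)
            stage = f"relative rates ({tag})"
            rates = summarise_relative_rates(ds)
            new_species = summarise_new_species(ds)

            stage = f"delta correlation ({tag})"
            deltas = indicator_deltas(indicator_series(ds))
            deltas = _with_meta(deltas.set_index("plot_id"), ds).reset_index()
            dc = delta_correlation(deltas, alpha=cfg.alpha)
            dc_tbl = pd.DataFrame([{
                "slope": dc.slope, "se": dc.se, "ci_low": dc.ci_low,
                "ci_high": dc.ci_high, "p_value": dc.p_value,
                "significant": dc.significant,
            }])

            overall = indicators_tbl[
                (indicators_tbl["scope"] == "All")
                & (indicators_tbl["indicator"] == "thermic")
            ]
            total_delta = float(overall["delta"].sum())
            equivalence = pd.DataFrame([{
                "total_delta_thermic": total_delta,
                "belt_fraction_pct": belt_fraction(total_delta),
                "elevation_equivalent_m": elevation_equivalent(
                    total_delta, cfg.belt_extent_m
                ),
            }])

            rho, p_rho = rank_correlation_check(ds.traits)
            trait_diag = pd.DataFrame(
                [{"spearman_rho": rho, "p_value": p_rho}]
            )

            bundle[tag] = {
                "richness": richness,
                "family_selection": pd.concat([sel_r, sel_t], ignore_index=True),
                "turnover": turnover_tbl,
                "cover": cover,
                "indicator_deltas": indicators_tbl,
                "relative_rates": rates,
                "new_species": new_species,
                "delta_correlation": dc_tbl,
                "equivalence": equivalence,
                "trait_diagnostics": trait_diag,
            }
        except Exception as exc:
            raise type(exc)(
                f"pipeline aborted at stage '{stage}': {exc}"
            ) from exc

    bundle["provenance"] = provenance
    if cfg.out_dir:
        out = Path(cfg.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for tag, tables in bundle.items():
            if tag == "provenance":
                continue
            for name, tbl in tables.items():
                tbl.to_csv(out / f"{tag}_{name}.csv", index=False)
        (out / "provenance.log").write_text("\n".join(provenance) + "\n")
    return bundle


def write_truth_json(truth, path) -> None:
    with open(path, "w") as fh:
        json.dump(truth.to_dict(), fh, indent=2, default=float)
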