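"""Synthetic alpine-community generator with a known-truth ledger.

The generator emulates a permanent-plot design at the alpine–nival ecotone:
1-m² plots arranged in transects grouped into topographic blocks along an
elevation gradient, surveyed in three campaigns at decadal spacing.  Each
species belongs to an altitudinal rank (1 = subnival–nival … 4 =
treeline–alpine) and carries a Gaussian occupancy-probability curve along
elevation centred on its optimum.  Baseline occupancy is Bernoulli in that
probability, baseline cover lognormal (truncated at 100%).  Climate warming
is modelled as an upward displacement of the species optima relative to the
plots (the lapse-rate view of warming: +0.53°C ≈ 80 m of elevation), so at
each resurvey warm-adapted low-rank-4 species approach the plots from below
while cryophilic rank-1 species lose suitability.  On top of the occupancy
dynamics, rank-specific multiplicative cover trends impose the cryophile
decline / rank-2 expansion seen in long-term ecotone data.

All randomness flows from the config seed through positionally indexed draw
matrices (one :class:`numpy.random.SeedSequence` spawn per survey step and
draw purpose), so output is bit-reproducible and independent of iteration
order, and the identical simulation kernel serves both the survey generator
and the ≥10⁵-plot Monte-Carlo truth oracle :func:`truth_delta_thermic`.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .errors import ConfigError

# stream purposes (second element of the SeedSequence entropy tuple)
_P_SPECIES = 1
_P_PLOTS = 2
_P_OCC = 3
_P_COVER = 4
_P_COLONISE = 5
_P_DISAPPEAR = 6
_P_NEWCOVER = 7
_P_DISTURB = 8
_P_ANNUAL = 9

_TRUTH_SEED_OFFSET = 1_000_003  # internal MC stream, distinct from data streams


@dataclass
class SimulationConfig:
    """Generating parameters of the synthetic community.

    Defaults are chosen to emulate a ~350-plot, three-campaign ecotone
    dataset: ~50 species in four altitudinal-rank guilds, sparse covers
    (plot vegetation cover roughly 10–25%), per-plot richness around 11–13,
    declining rank-1 cover, expanding rank-2 cover, and a colonisation
    excess in the first decade shifting towards disappearances in the
    second.
    """

    n_blocks: int = 4
    plots_per_block: int = 90
    transects_per_block: int = 6
    years: tuple = (1994, 2004, 2014)
    n_species_per_rank: tuple = (6, 20, 18, 6)
    plot_elevation_range: tuple = (2900.0, 3450.0)
    species_optimum_ranges: tuple = (
        (3150.0, 3500.0),  # rank 1: subnival–nival, highest optima
        (3000.0, 3350.0),  # rank 2: alpine–subnival pioneers
        (2700.0, 3000.0),  # rank 3: alpine grassland, marginal from below
        (2500.0, 2850.0),  # rank 4: treeline–alpine outposts
    )
    niche_breadth: float = 200.0
    max_occupancy_prob: float = 0.42
    cover_lognormal_params: tuple = (0.2, 0.9)
    #: additive shift of the lognormal log-mean per rank: cryophiles dominate
    #: cover at the ecotone, treeline species occur only as small individuals
    rank_cover_mu_offset: tuple = (1.0, 0.3, -0.3, -0.8)
    warming_shift_per_decade: float = 60.0
    rank1_cover_trend: float = 0.80
    rank2_cover_trend: float = 1.20
    colonisation_prob_scale: float = 0.30
    disappearance_prob_scale: float = 0.05
    disappearance_accel_per_decade: float = 3.0
    #: fresh colonisers establish at smaller cover than resident populations
    coloniser_cover_mu_offset: float = -1.0
    disturbed_fraction: float = 0.02
    include_annuals: bool = False
    richness_target_window: tuple = (10.0, 14.0)
    seed: int = 2014

    def validate(self) -> None:
        probs = (
            self.max_occupancy_prob,
            self.colonisation_prob_scale,
            self.disappearance_prob_scale,
            self.disturbed_fraction,
        )
        if any(not (0.0 <= p <= 1.0) for p in probs):
            raise ConfigError("probabilities must lie in [0, 1]")
        if self.niche_breadth <= 0:
            raise ConfigError("niche_breadth must be > 0")
        if list(self.years) != sorted(set(self.years)):
            raise ConfigError("years must be strictly increasing")
        if len(self.years) < 2:
            raise ConfigError("need at least two survey years")
        if len(self.n_species_per_rank) != 4 or len(self.species_optimum_ranges) != 4:
            raise ConfigError("exactly four altitudinal ranks are modelled")
        if len(self.rank_cover_mu_offset) != 4:
            raise ConfigError("rank_cover_mu_offset needs one entry per rank")
        if min(self.n_species_per_rank) < 0 or sum(self.n_species_per_rank) == 0:
            raise ConfigError("species counts must be non-negative, not all zero")
        lo, hi = self.plot_elevation_range
        if not hi > lo:
            raise ConfigError("plot_elevation_range must be increasing")
        if self.n_blocks < 1 or self.plots_per_block < 1 or self.transects_per_block < 1:
            raise ConfigError("design counts must be ≥ 1")
        if self.disappearance_accel_per_decade <= 0:
            raise ConfigError("disappearance_accel_per_decade must be > 0")


@dataclass
class SimTruth:
    """Known generating parameters plus (optionally) the true indicator drift."""

    species_id: list
    altitudinal_rank: list
    moisture_rank: list
    optimum_elevation: list
    baseline_cover_mean: float
    delta_thermic: dict = field(default_factory=dict)  # decade → (mean, mc_se)
    config: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return asdict(self)


def _rng(seed: int, *key) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence((int(seed),) + tuple(int(k) for k in key)))


def _draw_species(cfg: SimulationConfig):
    """Species ranks, optima and moisture ranks (shared by data and truth)."""
    rng = _rng(cfg.seed, _P_SPECIES)
    ranks, optima = [], []
    for rank, (n, (lo, hi)) in enumerate(
        zip(cfg.n_species_per_rank, cfg.species_optimum_ranges), start=1
    ):
        ranks.extend([rank] * n)
        optima.extend(rng.uniform(lo, hi, size=n))
    ranks = np.array(ranks)
    optima = np.array(optima)
    moisture = rng.integers(1, 5, size=len(ranks))
    ids = [f"sp{i + 1:03d}" for i in range(len(ranks))]
    return ids, ranks, optima, moisture


def _occupancy_prob(cfg, elevations, optima, decade_index: int) -> np.ndarray:
    """Gaussian occupancy curve; optima shift upward with warming."""
    shifted = optima[None, :] + cfg.warming_shift_per_decade * decade_index
    z = (elevations[:, None] - shifted) / cfg.niche_breadth
    return cfg.max_occupancy_prob * np.exp(-0.5 * z**2)


def _simulate_ensemble(cfg: SimulationConfig, elevations: np.ndarray, seed: int):
    """Run the occupancy/cover dynamics for a set of plots.

    Returns (occ, cover): boolean and float arrays of shape
    (n_years, n_plots, n_species).
    """
    ids, ranks, optima, _ = _draw_species(cfg)
    n_plots, n_sp = len(elevations), len(ranks)
    n_years = len(cfg.years)
    mu, sigma = cfg.cover_lognormal_params
    mu_sp = mu + np.asarray(cfg.rank_cover_mu_offset)[ranks - 1]
    trend = np.ones(n_sp)
    trend[ranks == 1] = cfg.rank1_cover_trend
    trend[ranks == 2] = cfg.rank2_cover_trend

    occ = np.zeros((n_years, n_plots, n_sp), dtype=bool)
    cover = np.zeros((n_years, n_plots, n_sp))

    p0 = _occupancy_prob(cfg, elevations, optima, 0)
    occ[0] = _rng(seed, _P_OCC, 0).uniform(size=p0.shape) < p0
    cover[0] = np.minimum(
        _rng(seed, _P_COVER, 0).lognormal(0.0, sigma, size=p0.shape)
        * np.exp(mu_sp)[None, :],
        100.0,
    )
    cover[0][~occ[0]] = 0.0

    for t in range(1, n_years):
        p_t = _occupancy_prob(cfg, elevations, optima, t)
        prev_occ, prev_cov = occ[t - 1], cover[t - 1]

        new_cov = np.minimum(prev_cov * trend[None, :], 100.0)

        d_scale = cfg.disappearance_prob_scale * cfg.disappearance_accel_per_decade ** (
            t - 1
        )
        p_dis = np.clip(d_scale * (1.0 - p_t), 0.0, 1.0)
        dis = _rng(seed, _P_DISAPPEAR, t).uniform(size=p_t.shape) < p_dis

        p_col = np.clip(cfg.colonisation_prob_scale * p_t, 0.0, 1.0)
        col = _rng(seed, _P_COLONISE, t).uniform(size=p_t.shape) < p_col

        occ[t] = (prev_occ & ~dis) | (~prev_occ & col)
        cover[t] = np.where(prev_occ & ~dis, new_cov, 0.0)
        colonised = ~prev_occ & col
        fresh = np.minimum(
            _rng(seed, _P_NEWCOVER, t).lognormal(0.0, sigma, size=p_t.shape)
            * np.exp(mu_sp + cfg.coloniser_cover_mu_offset)[None, :],
            100.0,
        )
        cover[t][colonised] = fresh[colonised]
    return occ, cover


def _plot_layout(cfg: SimulationConfig):
    """Plot ids, block/transect labels and elevations for the survey design.

    Blocks tile the elevation range in equal contiguous bands (lowest block
    first), so the marginal plot-elevation distribution is uniform over the
    whole range.
    """
    rng = _rng(cfg.seed, _P_PLOTS)
    lo, hi = cfg.plot_elevation_range
    band = (hi - lo) / cfg.n_blocks
    plot_ids, blocks, transects, elevations = [], [], [], []
    for b in range(cfg.n_blocks):
        label = chr(ord("A") + b)
        elev = np.sort(rng.uniform(lo + b * band, lo + (b + 1) * band, cfg.plots_per_block))
        for i in range(cfg.plots_per_block):
            plot_ids.append(f"{label}{i + 1:03d}")
            blocks.append(label)
            transects.append(f"{label}T{i % cfg.transects_per_block + 1}")
            elevations.append(elev[i])
    return plot_ids, blocks, transects, np.array(elevations)


def simulate_surveys(cfg: SimulationConfig):
    """Generate (survey table, traits, plot attributes, SimTruth).

    The survey table is long-format presence records (cover > 0); traits and
    attributes match the data_model CSV contracts.  Identical (cfg, seed)
    yields identical output.
    """
    cfg.validate()
    ids, ranks, optima, moisture = _draw_species(cfg)
    plot_ids, blocks, transects, elevations = _plot_layout(cfg)
    occ, cover = _simulate_ensemble(cfg, elevations, cfg.seed)

    rows = []
    for t, year in enumerate(cfg.years):
        pi, si = np.nonzero(occ[t])
        rows.append(
            pd.DataFrame(
                {
                    "plot_id": np.asarray(plot_ids, dtype=object)[pi],
                    "transect_id": np.asarray(transects, dtype=object)[pi],
                    "block_id": np.asarray(blocks, dtype=object)[pi],
                    "year": int(year),
                    "species_id": np.asarray(ids, dtype=object)[si],
                    "cover": np.round(cover[t][pi, si], 4),
                }
            )
        )
    records = pd.concat(rows, ignore_index=True)
    records = records[records["cover"] > 0].reset_index(drop=True)

    traits = pd.DataFrame(
        {
            "species_id": ids,
            "altitudinal_rank": ranks,
            "moisture_rank": moisture,
            "is_annual": False,
        }
    ).set_index("species_id")

    if cfg.include_annuals:
        records, traits = _add_annuals(cfg, records, traits, plot_ids, transects, blocks)

    rng = _rng(cfg.seed, _P_PLOTS, 1)
    veg = np.clip(cover.sum(axis=2)[0], 0, 100)
    remainder = 100.0 - veg
    split = rng.dirichlet((2.0, 2.0, 1.0), size=len(plot_ids))
    aspect = np.mod(rng.normal(180.0, 30.0, len(plot_ids)), 360.0)
    slope = rng.uniform(20.0, 40.0, len(plot_ids))
    ruggedness = rng.lognormal(1.0, 0.6, len(plot_ids))

    disturb_rng = _rng(cfg.seed, _P_DISTURB)
    disturbed = disturb_rng.uniform(size=len(plot_ids)) < cfg.disturbed_fraction
    resurvey_years = list(cfg.years[1:])
    disturbed_years = [
        frozenset({int(disturb_rng.choice(resurvey_years))}) if d else frozenset()
        for d in disturbed
    ]

    attrs = pd.DataFrame(
        {
            "plot_id": plot_ids,
            "transect_id": transects,
            "block_id": blocks,
            "elevation_m": np.round(elevations, 1),
            "aspect_deg": np.round(aspect, 1),
            "slope_deg": np.round(slope, 1),
            "rock_pct": np.round(remainder * split[:, 0], 2),
            "scree_pct": np.round(remainder * split[:, 1], 2),
            "soil_pct": np.round(remainder * split[:, 2], 2),
            "veg_pct": np.round(veg, 2),
            "ruggedness_m": np.round(ruggedness, 2),
            "disturbed_years": disturbed_years,
        }
    ).set_index("plot_id")

    truth = SimTruth(
        species_id=list(traits.index),
        altitudinal_rank=[int(r) for r in traits["altitudinal_rank"]],
        moisture_rank=[int(m) for m in traits["moisture_rank"]],
        optimum_elevation=[float(o) for o in optima] + [np.nan] * (len(traits) - len(optima)),
        baseline_cover_mean=float(
            np.exp(cfg.cover_lognormal_params[0] + cfg.cover_lognormal_params[1] ** 2 / 2)
        ),
        config=asdict(cfg),
    )
    return records, traits, attrs, truth


def _add_annuals(cfg, records, traits, plot_ids, transects, blocks):
    """Two optional high-turnover annual species to exercise the is_annual filter."""
    rng = _rng(cfg.seed, _P_ANNUAL)
    frames = [records]
    new_rows = []
    for k, sp in enumerate(("ann001", "ann002")):
        for year in cfg.years:
            present = rng.uniform(size=len(plot_ids)) < 0.15
            idx = np.nonzero(present)[0]
            new_rows.append(
                pd.DataFrame(
                    {
                        "plot_id": np.asarray(plot_ids, dtype=object)[idx],
                        "transect_id": np.asarray(transects, dtype=object)[idx],
                        "block_id": np.asarray(blocks, dtype=object)[idx],
                        "year": int(year),
                        "species_id": sp,
                        "cover": np.round(rng.lognormal(-1.0, 0.5, len(idx)), 4),
                    }
                )
            )
        traits = pd.concat(
            [
                traits,
                pd.DataFrame(
                    {
                        "altitudinal_rank": [3 + k],
                        "moisture_rank": [int(rng.integers(1, 5))],
                        "is_annual": [True],
                    },
                    index=pd.Index([sp], name="species_id"),
                ),
            ]
        )
    records = pd.concat(frames + new_rows, ignore_index=True)
    return records, traits


def truth_delta_thermic(
    cfg: SimulationConfig, n_plots: int = 100_000
) -> dict:
    """Monte-Carlo expectation of the per-decade Δ thermic indicator.

    Integrates the generating process over a large plot ensemble (elevations
    uniform over the plot range, ≥ 10⁵ replicate plots, fixed internal seed)
    conditional on the config's realised species parameters.  For each decade
    the returned dict maps "y0-y1" → (mean Δ, Monte-Carlo s.e., n), where Δ is
    the difference of cover-weighted thermic indicators between consecutive
    surveys over plots with defined indicators in both, and the s.e. is that
    of the paired per-plot differences.
    """
    cfg.validate()
    if n_plots < 1000:
        raise ConfigError("truth oracle needs a large plot ensemble")
    _, ranks, _, _ = _draw_species(cfg)
    lo, hi = cfg.plot_elevation_range
    internal = _rng(cfg.seed, _TRUTH_SEED_OFFSET)
    elevations = internal.uniform(lo, hi, size=n_plots)
    occ, cover = _simulate_ensemble(cfg, elevations, cfg.seed + _TRUTH_SEED_OFFSET)

    rank_vec = ranks.astype(float)
    indicators = []
    for t in range(len(cfg.years)):
        total = cover[t].sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            ind = (cover[t] * rank_vec[None, :]).sum(axis=1) / total
        ind[total == 0] = np.nan
        indicators.append(ind)

    out = {}
    for t in range(1, len(cfg.years)):
        diff = indicators[t] - indicators[t - 1]
        valid = ~np.isnan(diff)
        n = int(valid.sum())
        mean = float(np.mean(diff[valid]))
        se = float(np.std(diff[valid], ddof=1) / np.sqrt(n))
        out[f"{cfg.years[t - 1]}-{cfg.years[t]}"] = (mean, se, n)
    return out
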