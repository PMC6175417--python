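"""Count-model selection, mixed-model fitting contracts and group contrasts.

The survey design is hierarchical — plots nested in transects nested in
blocks, resurveyed at decadal intervals — so every model carries a nested
random-intercept structure.  Model *selection* logic (Poisson vs negative
binomial likelihood-ratio ladder, Pearson overdispersion rule with the
conventional 1.2 threshold, quasi-likelihood escalation), contrast matrices,
Tukey-style single-step adjustment and compact-letter assignment are owned
here; the mixed-model *optimisers* are delegated to statsmodels (MixedLM for
Gaussian responses, GEE with a nested dependence structure for count and
binomial responses, plain GLM/OLS when no random structure survives).

Nesting levels with fewer than two units are collapsed with a warning — the
standard treatment for subsites whose transects contain too few plots.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats

from .errors import ConvergenceError, ValidationError

logger = logging.getLogger(__name__)

FAMILIES = ("poisson", "negative_binomial", "quasi_poisson", "binomial", "gaussian")


@dataclass
class ModelSpec:
    """Declarative description of one model fit.

    ``fixed`` names the factor whose levels are estimated and contrasted
    (a combined cell factor such as decade × type is passed as one column).
    ``random_nesting`` lists grouping columns outermost-first; levels with
    < 2 units in the data are collapsed automatically.
    """

    response: str
    fixed: str
    random_nesting: tuple = ("block_id", "transect_id", "plot_id")
    family: str = "gaussian"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class DispersionReport:
    statistic: float
    df: int
    overdispersed: bool
    threshold: float = 1.2


@dataclass(frozen=True)
class EffectEstimate:
    """One estimated term (a factor level or a pairwise difference)."""

    term: str
    estimate: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float | None = None
    group_letters: str = ""


@dataclass
class ContrastResult:
    """Level estimates, Tukey-adjusted pairwise differences and letters."""

    levels: list
    level_estimates: list
    pairwise: pd.DataFrame
    letters: dict
    metadata: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "term": e.term,
                "estimate": e.estimate,
                "se": e.se,
                "ci_low": e.ci_low,
                "ci_high": e.ci_high,
                "group_letters": e.group_letters,
            }
            for e in self.level_estimates
        ]
        return pd.DataFrame(rows)


def pearson_dispersion(
    observed, fitted, n_params: int, threshold: float = 1.2
) -> DispersionReport:
    """Pearson χ²/df overdispersion statistic.

    statistic = Σ (obs − fit)² / fit over (n_obs − n_params) residual df;
    overdispersed when the statistic strictly exceeds ``threshold``.
    """
    observed = np.asarray(observed, dtype=float)
    fitted = np.asarray(fitted, dtype=float)
    if np.any(fitted <= 0):
        raise ValidationError("fitted means must be strictly positive")
    df = observed.size - n_params
    if df <= 0:
        raise ValidationError("need more observations than parameters")
    statistic = float(((observed - fitted) ** 2 / fitted).sum() / df)
    return DispersionReport(
        statistic=statistic,
        df=int(df),
        overdispersed=statistic > threshold,
        threshold=threshold,
    )


def _collapse_nesting(data: pd.DataFrame, nesting) -> list:
    """Drop nesting levels with < 2 units, outermost-first, with a warning."""
    kept = []
    for level in nesting:
        if level not in data.columns:
            raise ValidationError(f"nesting column {level!r} missing from data")
        if data[level].nunique() < 2:
            logger.warning(
                "random level %r has < 2 units; collapsing it out of the structure",
                level,
            )
            continue
        kept.append(level)
    return kept


@dataclass
class FitResult:
    """Cell means on the model's link scale with their covariance."""

    levels: list
    estimates: np.ndarray
    cov: np.ndarray
    df_resid: float
    backend: dict


def _ordered_levels(col: pd.Series) -> list:
    values = col.unique().tolist()
    try:
        return sorted(values)
    except TypeError:
        return values


def _fit_cell_means(data: pd.DataFrame, spec: ModelSpec) -> FitResult:
    """Estimate per-level means of spec.fixed on the link scale.

    The model is fitted with treatment coding (better conditioned than the
    no-intercept parametrisation for mixed models) and the cell means are
    recovered with a contrast matrix, emmeans-style.
    """
    data = data.reset_index(drop=True)
    levels = _ordered_levels(data[spec.fixed])
    if len(levels) < 2:
        raise ValidationError(f"contrast factor {spec.fixed!r} needs ≥ 2 levels")
    formula = f"{spec.response} ~ C({spec.fixed})"
    nesting = _collapse_nesting(data, spec.random_nesting)
    backend: dict = {"family": spec.family, "random_nesting": tuple(nesting)}

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if spec.family == "gaussian":
                result, df_resid = _fit_gaussian(data, formula, nesting, backend)
            else:
                result, df_resid = _fit_glm_like(data, formula, nesting, spec, backend)
    except ConvergenceError:
        raise
    except Exception as exc:  # backend failure surfaces as convergence error
        raise ConvergenceError(f"backend failed: {exc}", diagnostics=exc) from exc

    names = list(pd.Series(result.params).index)
    prefix = f"C({spec.fixed})[T."
    fe_names = ["Intercept"] + [n for n in names if n.startswith(prefix)]
    params = pd.Series(result.params, index=names)[fe_names].to_numpy(float)
    cov = pd.DataFrame(
        np.asarray(result.cov_params()), index=names, columns=names
    ).loc[fe_names, fe_names].to_numpy(float)

    # L maps (intercept, offsets) to cell means; row order follows `levels`
    offset_levels = [n[len(prefix):-1] for n in fe_names[1:]]
    reference = [lv for lv in levels if str(lv) not in offset_levels]
    if len(reference) != 1:
        raise ConvergenceError(
            f"could not identify reference level among {levels} from {fe_names}"
        )
    L = np.zeros((len(levels), len(fe_names)))
    L[:, 0] = 1.0
    for i, lv in enumerate(levels):
        if lv == reference[0]:
            continue
        L[i, 1 + offset_levels.index(str(lv))] = 1.0
    return FitResult(
        levels=levels,
        estimates=L @ params,
        cov=L @ cov @ L.T,
        df_resid=df_resid,
        backend=backend,
    )


def _fit_gaussian(data, formula, nesting, backend):
    # singular variance structures are collapsed innermost-first, ending at
    # OLS; each fallback is logged
    attempts = [tuple(nesting[:k]) for k in range(len(nesting), -1, -1)]
    last_exc = None
    for attempt in attempts:
        if not attempt:
            backend["backend"] = "statsmodels.OLS"
            backend["random_nesting"] = ()
            if nesting:
                logger.warning("all random levels singular; fell back to OLS")
            res = smf.ols(formula, data=data).fit()
            return res, float(res.df_resid)
        outer, inner = attempt[0], attempt[1:]
        vc = {lvl: f"0 + C({lvl})" for lvl in inner}
        try:
            res = None
            for method in (None, "powell"):
                model = smf.mixedlm(
                    formula,
                    data=data,
                    groups=data[outer],
                    re_formula="1",
                    vc_formula=vc or None,
                )
                kw = {} if method is None else {"method": method}
                res = model.fit(reml=True, **kw)
                if res.converged:
                    break
        except Exception as exc:
            last_exc = exc
            logger.warning("MixedLM with structure %s failed (%s); collapsing", attempt, exc)
            continue
        if not res.converged or not np.all(np.isfinite(np.asarray(res.bse_fe))):
            last_exc = ConvergenceError("MixedLM did not converge", diagnostics=res)
            logger.warning(
                "MixedLM with structure %s did not converge cleanly; "
                "collapsing innermost level",
                attempt,
            )
            continue
        backend["backend"] = "statsmodels.MixedLM(REML)"
        backend["groups"] = outer
        backend["variance_components"] = tuple(inner)
        backend["random_nesting"] = attempt
        # Wald/z inference on fixed effects (large-sample); recorded in metadata
        backend["inference"] = "wald-z"
        return res, np.inf
    raise ConvergenceError(f"Gaussian backends exhausted: {last_exc}", diagnostics=last_exc)


def _glm_family(spec, data):
    if spec.family == "poisson":
        return sm.families.Poisson(), None
    if spec.family == "quasi_poisson":
        return sm.families.Poisson(), "X2"
    if spec.family == "binomial":
        return sm.families.Binomial(), None
    if spec.family == "negative_binomial":
        alpha = _estimate_nb_alpha(data, spec)
        return sm.families.NegativeBinomial(alpha=alpha), None
    raise ValidationError(f"family {spec.family!r} not a GLM family")


def _estimate_nb_alpha(data, spec) -> float:
    """NB dispersion (alpha) by MLE on the fixed-effects model."""
    res = smf.negativebinomial(
        f"{spec.response} ~ 0 + C({spec.fixed})", data=data
    ).fit(disp=0, maxiter=200)
    return float(max(res.params.iloc[-1], 1e-8))


def _fit_glm_like(data, formula, nesting, spec, backend):
    family, scale = _glm_family(spec, data)
    if not nesting:
        backend["backend"] = "statsmodels.GLM"
        res = smf.glm(formula, data=data, family=family).fit(scale=scale)
        backend["scale"] = float(res.scale)
        return res, float(res.df_resid)
    # cluster on the innermost surviving level (the repeated-measures unit);
    # working independence + robust sandwich covariance is the stable path
    cluster = nesting[-1]
    model = smf.gee(
        formula,
        groups=cluster,
        data=data,
        family=family,
        cov_struct=sm.cov_struct.Independence(),
    )
    res = model.fit(maxiter=100)
    if not getattr(res, "converged", True):
        raise ConvergenceError("GEE did not converge", diagnostics=res)
    backend["backend"] = "statsmodels.GEE(Independence, robust)"
    backend["cluster"] = cluster
    if spec.family == "quasi_poisson":
        backend["scale"] = float(res.scale)
    backend["inference"] = "robust-sandwich-z"
    return res, np.inf


@dataclass(frozen=True)
class FamilySelection:
    """Outcome of the Poisson vs negative-binomial selection ladder."""

    chosen: str
    ll_poisson: float
    ll_negbin: float
    lrt_statistic: float
    p_value: float
    nb_alpha: float | None
    dispersion: DispersionReport
    escalated_to: str | None
    note: str = ""


def select_count_family(
    data: pd.DataFrame,
    spec: ModelSpec,
    alpha: float = 0.05,
    dispersion_threshold: float = 1.2,
) -> FamilySelection:
    """Choose Poisson or negative binomial for a count response.

    Both families are fitted as fixed-effects GLMs on the model's design; a
    1-df likelihood-ratio test with P < ``alpha`` selects the negative
    binomial (which accommodates the many zeros of turnover counts), else
    Poisson.  The chosen fit is then screened with the Pearson χ²/df rule;
    an overdispersed Poisson is flagged for quasi-Poisson escalation
    (dispersion-scaled standard errors).  Likelihoods are computed on the
    fixed-effects (marginal) models; the chosen family is what the clustered
    backend then uses.
    """
    y = np.asarray(data[spec.response])
    if np.any(y < 0) or not np.allclose(y, np.round(y)):
        raise ValidationError("count response must be non-negative integers")
    formula = f"{spec.response} ~ 0 + C({spec.fixed})"
    data = data.reset_index(drop=True)

    if np.ptp(y) == 0:
        # constant response: the LRT is vacuous and a log-link fit may not
        # even be evaluable (all zeros); report Poisson with zero LRT
        disp = DispersionReport(
            statistic=0.0,
            df=int(y.size - 1),
            overdispersed=False,
            threshold=dispersion_threshold,
        )
        return FamilySelection(
            chosen="poisson",
            ll_poisson=0.0,
            ll_negbin=0.0,
            lrt_statistic=0.0,
            p_value=1.0,
            nb_alpha=None,
            dispersion=disp,
            escalated_to=None,
            note="degenerate: constant response; Poisson retained with zero LRT",
        )

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        pois = smf.glm(formula, data=data, family=sm.families.Poisson()).fit()

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            nb = smf.negativebinomial(formula, data=data).fit(disp=0, maxiter=200)
        ll_nb = float(nb.llf)
        nb_alpha = float(nb.params.iloc[-1])
    except Exception as exc:
        raise ConvergenceError(
            f"negative-binomial fit failed: {exc}", diagnostics=exc
        ) from exc

    lrt = max(0.0, 2.0 * (ll_nb - float(pois.llf)))
    p = float(stats.chi2.sf(lrt, df=1))
    chosen = "negative_binomial" if p < alpha else "poisson"

    if chosen == "poisson":
        fitted, k = pois.fittedvalues, len(pois.params)
    else:
        fitted, k = nb.predict(), len(nb.params)
    disp = pearson_dispersion(y, fitted, k, dispersion_threshold)
    escalated = (
        "quasi_poisson" if (chosen == "poisson" and disp.overdispersed) else None
    )
    return FamilySelection(
        chosen=chosen,
        ll_poisson=float(pois.llf),
        ll_negbin=ll_nb,
        lrt_statistic=lrt,
        p_value=p,
        nb_alpha=nb_alpha,
        dispersion=disp,
        escalated_to=escalated,
        note="LRT on fixed-effects (marginal) likelihoods",
    )


def _tukey_sf(q: float, k: int, df: float) -> float:
    df = min(df, 1e6) if np.isfinite(df) else 1e6
    return float(stats.studentized_range.sf(q, k, df))


def _tukey_crit(k: int, df: float, alpha: float) -> float:
    df = min(df, 1e6) if np.isfinite(df) else 1e6
    return float(stats.studentized_range.ppf(1 - alpha, k, df))


def fit_and_contrast(
    data: pd.DataFrame, spec: ModelSpec, contrasts: str | None = None,
    alpha: float = 0.05,
) -> ContrastResult:
    """Fit a cell-means model and compare all factor-level pairs.

    Pairwise differences carry family-wise Tukey-style single-step adjusted
    P values (studentized-range distribution on the estimated contrast
    covariance) and the levels receive a compact letter display in which two
    levels share a letter iff their difference is not significant at
    ``alpha``.  Estimates are on the model's link scale.
    """
    if contrasts is not None:
        spec = ModelSpec(
            response=spec.response,
            fixed=contrasts,
            random_nesting=spec.random_nesting,
            family=spec.family,
        )
    y = np.asarray(data[spec.response], dtype=float)
    if np.ptp(y[~np.isnan(y)]) == 0:
        return _constant_response_result(data, spec, alpha)
    fit = _fit_cell_means(data, spec)
    k = len(fit.levels)
    zcrit = stats.norm.ppf(1 - alpha / 2)

    level_estimates = []
    for i, lv in enumerate(fit.levels):
        est = fit.estimates[i]
        se = float(np.sqrt(max(fit.cov[i, i], 0.0)))
        level_estimates.append(
            EffectEstimate(
                term=str(lv),
                estimate=float(est),
                se=se,
                ci_low=float(est - zcrit * se),
                ci_high=float(est + zcrit * se),
            )
        )

    rows = []
    sig = np.zeros((k, k), dtype=bool)
    qcrit = _tukey_crit(k, fit.df_resid, alpha)
    for i in range(k):
        for j in range(i + 1, k):
            diff = float(fit.estimates[j] - fit.estimates[i])
            var = max(fit.cov[i, i] + fit.cov[j, j] - 2 * fit.cov[i, j], 0.0)
            se = float(np.sqrt(var))
            if se == 0:
                # degenerate contrast: identical cells up to float error
                scale = max(abs(fit.estimates[i]), abs(fit.estimates[j]), 1.0)
                p = 1.0 if abs(diff) <= 1e-10 * scale else 0.0
            else:
                p = _tukey_sf(abs(diff) / se * np.sqrt(2), k, fit.df_resid)
            half = qcrit / np.sqrt(2) * se
            sig[i, j] = sig[j, i] = p < alpha
            rows.append(
                {
                    "term": f"{fit.levels[j]} - {fit.levels[i]}",
                    "estimate": diff,
                    "se": se,
                    "ci_low": diff - half,
                    "ci_high": diff + half,
                    "p_adjusted": p,
                    "significant": p < alpha,
                }
            )
    pairwise = pd.DataFrame(rows)
    letters = compact_letter_display([str(lv) for lv in fit.levels], sig)
    level_estimates = [
        EffectEstimate(
            term=e.term,
            estimate=e.estimate,
            se=e.se,
            ci_low=e.ci_low,
            ci_high=e.ci_high,
            group_letters=letters[e.term],
        )
        for e in level_estimates
    ]
    meta = dict(fit.backend)
    meta["alpha"] = alpha
    meta["adjustment"] = "tukey-single-step (studentized range)"
    return ContrastResult(
        levels=[str(lv) for lv in fit.levels],
        level_estimates=level_estimates,
        pairwise=pairwise,
        letters=letters,
        metadata=meta,
    )


def _constant_response_result(data, spec, alpha) -> ContrastResult:
    """Degenerate case: a constant response separates nothing."""
    levels = _ordered_levels(data[spec.fixed])
    value = float(np.asarray(data[spec.response], dtype=float)[0])
    level_estimates = [
        EffectEstimate(
            term=str(lv), estimate=value, se=0.0, ci_low=value, ci_high=value,
            group_letters="a",
        )
        for lv in levels
    ]
    rows = [
        {
            "term": f"{levels[j]} - {levels[i]}",
            "estimate": 0.0, "se": 0.0, "ci_low": 0.0, "ci_high": 0.0,
            "p_adjusted": 1.0, "significant": False,
        }
        for i in range(len(levels))
        for j in range(i + 1, len(levels))
    ]
    return ContrastResult(
        levels=[str(lv) for lv in levels],
        level_estimates=level_estimates,
        pairwise=pd.DataFrame(rows),
        letters={str(lv): "a" for lv in levels},
        metadata={
            "family": spec.family,
            "backend": "degenerate-constant-response",
            "alpha": alpha,
            "note": "response constant on the response scale; no contrasts fitted",
        },
    )


def compact_letter_display(levels, pairwise_significant) -> dict:
    """Insert-and-absorb compact letter display.

    ``pairwise_significant`` is a hollow symmetric boolean matrix in the
    order of ``levels``.  Two levels share at least one letter iff their
    pair is non-significant.  Deterministic given the input ordering.
    """
    sig = np.asarray(pairwise_significant, dtype=bool)
    n = len(levels)
    if sig.shape != (n, n):
        raise ValidationError("significance matrix shape does not match levels")
    if not np.array_equal(sig, sig.T) or sig.diagonal().any():
        raise ValidationError("significance matrix must be symmetric and hollow")

    columns = [set(range(n))]
    for i in range(n):
        for j in range(i + 1, n):
            if not sig[i, j]:
                continue
            for col in [c for c in columns if i in c and j in c]:
                columns.remove(col)
                columns.append(col - {i})
                columns.append(col - {j})
            # absorb: drop columns contained in another
            columns = [
                c
                for idx, c in enumerate(columns)
                if c
                and not any(
                    c < other or (c == other and idx2 < idx)
                    for idx2, other in enumerate(columns)
                    if idx2 != idx
                )
            ]
    columns.sort(key=lambda c: min(c))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {lv: "" for lv in levels}
    for letter, col in zip(alphabet, columns):
        for idx in sorted(col):
            out[levels[idx]] += letter
    return out


@dataclass(frozen=True)
class DeltaCorrelation:
    """Slope of Δ moisture on Δ thermic under the nested random structure."""

    slope: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    significant: bool
    backend: dict


def delta_correlation(
    deltas: pd.DataFrame,
    grouping=("block_id", "transect_id", "plot_id"),
    alpha: float = 0.05,
) -> DeltaCorrelation:
    """Regress Δ soil-moisture indicator on Δ thermic indicator.

    Random intercepts for each grouping factor and for decade (the latter
    only with ≥ 2 decades present) are fitted as crossed variance components
    in a single-group linear mixed model.
    """
    df = deltas.copy()
    if "defined" in df.columns:
        df = df[df["defined"]]
    df = df.dropna(subset=["delta_thermic", "delta_moisture"]).reset_index(drop=True)
    if len(df) == 0:
        raise ValidationError("all deltas undefined; nothing to correlate")
    if df["plot_id"].nunique() < 2:
        raise ValidationError("need ≥ 2 plots for the Δ–Δ correlation model")
    if np.ptp(df["delta_thermic"].to_numpy()) == 0:
        # zero-variance predictor (e.g. frozen dynamics): slope unidentifiable
        return DeltaCorrelation(
            slope=0.0, se=0.0, ci_low=0.0, ci_high=0.0, p_value=1.0,
            significant=False,
            backend={"backend": "degenerate-zero-variance-predictor"},
        )

    vc = {}
    for lvl in grouping:
        if lvl in df.columns and df[lvl].nunique() >= 2:
            vc[lvl] = f"0 + C({lvl})"
    if "decade" in df.columns and df["decade"].nunique() >= 2:
        vc["decade"] = "0 + C(decade)"
    else:
        logger.warning("fewer than 2 decades; random decade intercept dropped")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(
            "delta_moisture ~ delta_thermic",
            data=df,
            groups=np.ones(len(df)),
            vc_formula=vc or None,
        )
        try:
            res = model.fit(reml=True, method=["lbfgs", "cg"])
        except Exception as exc:
            raise ConvergenceError(f"Δ–Δ LMM failed: {exc}", diagnostics=exc) from exc
    slope = float(res.params["delta_thermic"])
    se = float(res.bse["delta_thermic"])
    z = stats.norm.ppf(1 - alpha / 2)
    p = float(res.pvalues["delta_thermic"])
    if np.isnan(se):  # exact linear relation: zero residual variance
        se, p = 0.0, (0.0 if slope != 0 else 1.0)
    return DeltaCorrelation(
        slope=slope,
        se=se,
        ci_low=slope - z * se,
        ci_high=slope + z * se,
        p_value=p,
        significant=p < alpha,
        backend={
            "backend": "statsmodels.MixedLM(REML, crossed VCs)",
            "variance_components": tuple(vc),
            "inference": "wald-z",
        },
    )
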