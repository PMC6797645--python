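"""Marginal (GEE) models for the stimulus-ambiguity effect.

Each outcome measure is regressed on the 0/1 stimulus-ambiguity
indicator with trials as the unit of analysis and subjects as
clusters, using generalized estimating equations with an exchangeable
working correlation and robust (sandwich) inference.  Continuous
outcomes (xdev, area, maxspeed, rt) are standardized first, so their
coefficients read as standard-deviation differences between ambiguous
and unambiguous trials; the x-flips count uses a Poisson log link.

Display idiosyncrasy indicators (``weird_scaling``, ``wts``) enter as
precision covariates together with their full factorial interactions
with the ambiguity indicator.  Terms that are inestimable in a given
sample (e.g. no too-small-window subjects at all) are dropped with a
warning rather than failing the fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as scipy_stats
from statsmodels.genmod.cov_struct import Exchangeable
from statsmodels.tools.sm_exceptions import IterationLimitWarning

from .errors import ModelError

__all__ = [
    "CONTINUOUS_OUTCOMES",
    "OUTCOMES",
    "GEEFit",
    "standardize",
    "fit_ambiguity_model",
    "fit_moderation_model",
    "fit_all_outcomes",
]

CONTINUOUS_OUTCOMES = ("xdev", "area", "maxspeed", "rt")
OUTCOMES = ("xflips",) + CONTINUOUS_OUTCOMES

#: nuisance design: main effects and full factorial with ambiguity
NUISANCE_TERMS = (
    "weird_scaling",
    "wts",
    "ambiguous:weird_scaling",
    "ambiguous:wts",
    "weird_scaling:wts",
    "ambiguous:weird_scaling:wts",
)


@dataclass
class GEEFit:
    """A fitted marginal model.

    ``params`` / ``robust_se`` / ``p_values`` are keyed by term name;
    the headline estimand is the ``ambiguous`` coefficient.
    """

    outcome: str
    link: str
    params: dict[str, float]
    robust_se: dict[str, float]
    p_values: dict[str, float]
    conf_int: dict[str, tuple[float, float]]
    n_clusters: int
    n_observations: int
    converged: bool
    standardized: bool
    cov_type: str = "bias_reduced"
    df: float | None = None
    dropped_terms: list[str] = field(default_factory=list)
    n_dropped_rows: int = 0

    @property
    def ambiguity_estimate(self) -> float:
        return self.params["ambiguous"]

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame({
            "outcome": self.outcome,
            "term": list(self.params),
            "estimate": list(self.params.values()),
            "robust_se": [self.robust_se[t] for t in self.params],
            "p_value": [self.p_values[t] for t in self.params],
            "conf_low": [self.conf_int[t][0] for t in self.params],
            "conf_high": [self.conf_int[t][1] for t in self.params],
            "link": self.link,
        })


def standardize(values) -> np.ndarray:
    """Z-score a trial-level outcome vector (sample SD, ddof = 1).

    Missing values propagate untouched; a vector without at least two
    distinct non-missing values has no scale and raises
    :class:`~mtpipe.errors.ModelError`.
    """
    v = np.asarray(values, dtype=float)
    ok = ~np.isnan(v)
    if ok.sum() < 2:
        raise ModelError("standardize needs >= 2 non-missing values")
    sd = float(np.std(v[ok], ddof=1))
    if sd == 0:
        raise ModelError("outcome has zero dispersion; cannot standardize")
    return (v - float(np.mean(v[ok]))) / sd


def _product_column(df: pd.DataFrame, term: str) -> pd.Series:
    parts = term.split(":")
    col = df[parts[0]].astype(float)
    for p in parts[1:]:
        col = col * df[p].astype(float)
    return col


def _build_design(df: pd.DataFrame, terms: list[str]) -> tuple[pd.DataFrame, list[str]]:
    """Expand interaction terms into columns, dropping inestimable ones.

    A term is inestimable if its column is constant or duplicates an
    earlier column exactly (perfect collinearity of indicators).
    """
    exog = pd.DataFrame({"intercept": np.ones(len(df))}, index=df.index)
    dropped: list[str] = []
    for term in terms:
        col = _product_column(df, term)
        if col.nunique() < 2 or any(col.equals(exog[c]) for c in exog.columns):
            dropped.append(term)
            continue
        exog[term] = col
    return exog, dropped


def _fit_gee_once(endog, exog, groups, family, cov_type):
    model = sm.GEE(endog, exog, groups=groups, family=family,
                   cov_struct=Exchangeable())
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        result = model.fit(cov_type=cov_type)
    for w in caught:
        if issubclass(w.category, IterationLimitWarning):
            converged = False
    return result, converged


def _fit_gee(
    endog: np.ndarray,
    exog: pd.DataFrame,
    groups: np.ndarray,
    family,
    cov_type: str = "bias_reduced",
) -> tuple[dict, dict, dict, dict, bool, list[str], float]:
    """Fit the GEE and assemble small-sample robust inference.

    The sandwich covariance uses the Mancl–DeRouen bias-reduced form by
    default, and p-values / confidence intervals use a t reference with
    ``df = n_clusters - n_params`` — the plain sandwich with a normal
    reference is anticonservative below ~100 clusters.  If any term's
    sandwich variance is invalid (NaN or non-positive — near-collinear
    indicators in sparse cells), those terms are treated as inestimable,
    dropped, and the model refit.
    """
    result, converged = _fit_gee_once(endog, exog, groups, family, cov_type)
    bse = result.bse
    bad = [t for t in exog.columns
           if t not in ("intercept", "ambiguous")
           and not (np.isfinite(bse[t]) and bse[t] > 0)]
    if bad:
        warnings.warn(
            f"dropped terms with invalid robust variance: {bad}",
            stacklevel=3)
        exog = exog.drop(columns=bad)
        result, converged = _fit_gee_once(endog, exog, groups, family,
                                          cov_type)
    n_clusters = len(np.unique(groups))
    df = max(float(n_clusters - exog.shape[1]), 1.0)
    tcrit = float(scipy_stats.t.ppf(0.975, df))
    params, se, pvals, conf = {}, {}, {}, {}
    for t in exog.columns:
        b, s = float(result.params[t]), float(result.bse[t])
        params[t], se[t] = b, s
        pvals[t] = float(2.0 * scipy_stats.t.sf(abs(b / s), df))
        conf[t] = (b - tcrit * s, b + tcrit * s)
    return params, se, pvals, conf, converged, bad, df


def _prepare(table: pd.DataFrame, outcome: str, covars: list[str]):
    if outcome not in table.columns:
        raise ModelError(f"outcome {outcome!r} not in table; "
                         f"valid outcomes: {list(OUTCOMES)}")
    needed = ["subject_id", "ambiguous", outcome] + covars
    missing = [c for c in needed if c not in table.columns]
    if missing:
        raise ModelError(f"measures table is missing columns {missing}")
    df = table[needed].dropna()
    n_dropped = len(table) - len(df)
    if df["subject_id"].nunique() < 2:
        raise ModelError("GEE needs at least 2 subject clusters")
    return df, n_dropped


def fit_ambiguity_model(
    table: pd.DataFrame,
    outcome: str,
    include_nuisance: bool = True,
    standardize_outcome: bool = True,
    cov_type: str = "bias_reduced",
) -> GEEFit:
    """Fit the marginal stimulus-ambiguity model for one outcome.

    Parameters
    ----------
    table
        Long-format measures table (one row per trial) with columns
        ``subject_id``, ``ambiguous``, the outcome, and — when
        ``include_nuisance`` — ``weird_scaling`` and ``wts``.
    outcome
        One of ``xflips``, ``xdev``, ``area``, ``maxspeed``, ``rt``.
    include_nuisance
        Include the display-idiosyncrasy indicators and their full
        factorial interactions with ambiguity.
    standardize_outcome
        Z-score continuous outcomes across all analyzed trials before
        fitting (never applied to the Poisson x-flips model).
    cov_type
        Sandwich flavor: ``bias_reduced`` (Mancl–DeRouen, default),
        ``robust`` (plain sandwich), or ``naive``.

    Rows with a missing outcome or covariate are dropped listwise.
    """
    covars = ["weird_scaling", "wts"] if include_nuisance else []
    df, n_dropped = _prepare(table, outcome, covars)

    if outcome == "xflips":
        family = sm.families.Poisson()
        link, standardized = "log", False
        endog = df[outcome].to_numpy(dtype=float)
    else:
        family = sm.families.Gaussian()
        link = "identity"
        standardized = bool(standardize_outcome)
        endog = (standardize(df[outcome]) if standardized
                 else df[outcome].to_numpy(dtype=float))

    terms = ["ambiguous"] + (list(NUISANCE_TERMS) if include_nuisance else [])
    exog, dropped = _build_design(df, terms)
    if "ambiguous" in dropped:
        raise ModelError("ambiguity indicator is constant; nothing to estimate")
    if dropped:
        warnings.warn(f"dropped inestimable terms for {outcome}: {dropped}",
                      stacklevel=2)

    params, se, pvals, conf, converged, pruned, t_df = _fit_gee(
        endog, exog, df["subject_id"].to_numpy(), family, cov_type)
    return GEEFit(
        outcome=outcome, link=link, params=params, robust_se=se,
        p_values=pvals, conf_int=conf,
        n_clusters=int(df["subject_id"].nunique()),
        n_observations=len(df), converged=converged,
        standardized=standardized, cov_type=cov_type, df=t_df,
        dropped_terms=dropped + pruned, n_dropped_rows=n_dropped,
    )


def fit_moderation_model(
    table: pd.DataFrame,
    outcome: str,
    moderator: str,
    levels: tuple[str, str] | None = None,
    include_nuisance: bool = True,
    standardize_outcome: bool = True,
    cov_type: str = "bias_reduced",
) -> GEEFit:
    """Refit the ambiguity model with a two-level moderator.

    ``moderator`` names a column of subject attributes (browser or
    operating system); ``levels`` selects the reference and contrast
    levels (default: the two most frequent).  Rows from other levels
    are excluded, mirroring the exclusion of rare browsers/systems.
    The reported interaction term ``ambiguous:<moderator>`` estimates
    how the ambiguity effect differs between the two levels.
    """
    if moderator not in table.columns:
        raise ModelError(f"moderator column {moderator!r} not in table")
    if levels is None:
        counts = table[moderator].value_counts()
        if len(counts) < 2:
            raise ModelError(
                f"moderator {moderator!r} has fewer than 2 levels")
        levels = tuple(counts.index[:2])
    sub = table[table[moderator].isin(levels)].copy()
    if sub[moderator].nunique() < 2:
        raise ModelError(
            f"moderator {moderator!r} has fewer than 2 retained levels")
    ind = f"{moderator}_is_{levels[1]}"
    sub[ind] = (sub[moderator] == levels[1]).astype(int)

    covars = (["weird_scaling", "wts"] if include_nuisance else []) + [ind]
    df, n_dropped = _prepare(sub, outcome, covars)

    if outcome == "xflips":
        family = sm.families.Poisson()
        link, standardized = "log", False
        endog = df[outcome].to_numpy(dtype=float)
    else:
        family = sm.families.Gaussian()
        link = "identity"
        standardized = bool(standardize_outcome)
        endog = (standardize(df[outcome]) if standardized
                 else df[outcome].to_numpy(dtype=float))

    terms = (["ambiguous"]
             + (list(NUISANCE_TERMS) if include_nuisance else [])
             + [ind, f"ambiguous:{ind}"])
    exog, dropped = _build_design(df, terms)
    if "ambiguous" in dropped or f"ambiguous:{ind}" in dropped:
        raise ModelError("moderation design is inestimable")
    if dropped:
        warnings.warn(f"dropped inestimable terms for {outcome}: {dropped}",
                      stacklevel=2)

    params, se, pvals, conf, converged, pruned, t_df = _fit_gee(
        endog, exog, df["subject_id"].to_numpy(), family, cov_type)
    if f"ambiguous:{ind}" in pruned:
        raise ModelError("moderation interaction is inestimable")
    fit = GEEFit(
        outcome=outcome, link=link, params=params, robust_se=se,
        p_values=pvals, conf_int=conf,
        n_clusters=int(df["subject_id"].nunique()),
        n_observations=len(df), converged=converged,
        standardized=standardized, cov_type=cov_type, df=t_df,
        dropped_terms=dropped + pruned, n_dropped_rows=n_dropped,
    )
    fit.moderator = moderator          # type: ignore[attr-defined]
    fit.moderator_levels = levels      # type: ignore[attr-defined]
    fit.interaction_term = f"ambiguous:{ind}"  # type: ignore[attr-defined]
    return fit


def fit_all_outcomes(
    table: pd.DataFrame,
    include_nuisance: bool = True,
    standardize_outcome: bool = True,
) -> dict[str, GEEFit]:
    """Fit the ambiguity model for all five outcomes."""
    return {
        outcome: fit_ambiguity_model(
            table, outcome, include_nuisance, standardize_outcome)
        for outcome in OUTCOMES
    }
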