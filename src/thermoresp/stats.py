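"""Treatment-level statistics for the factorial design.

Covers the four analyses run on the fitted thermal traits and the
environment covariates:

* cell and marginal summary tables (mean ± SE, n);
* three-way factorial ANOVA with sequential (Type I) sums of squares
  in a fixed factor order — the design is balanced except for one
  discarded sample, so order matters slightly and is therefore fixed;
* backwards stepwise regression starting from the full three-way
  interaction of MET, water content and carbon, dropping the least
  significant droppable term (marginality respected: an interaction
  is never retained without its constituent main effects, and a main
  effect is never dropped while an interaction contains it);
* a Gaussian random-intercept (transect) model fitted by maximum
  likelihood via a one-dimensional profile over the between/within
  variance ratio, compared against the fixed-effects model by AICc.

ML (not REML) is used for the mixed model so that AICc comparisons
across fixed-effect structures are valid.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy.optimize import minimize_scalar
from scipy.stats import f as f_dist

__all__ = [
    "summarize_treatments",
    "unweighted_marginal_means",
    "AnovaResult",
    "three_way_anova",
    "StepwiseResult",
    "backwards_stepwise",
    "marginal_slope",
    "variance_explained",
    "LMMResult",
    "lmm_random_intercept",
    "RandomInterceptComparison",
    "compare_random_intercept",
    "aicc_from_loglik",
]


# ---------------------------------------------------------------------------
# summaries


def summarize_treatments(
    data: pd.DataFrame,
    variable: str,
    factors: tuple[str, ...] = ("biome", "depth", "distance_m"),
) -> pd.DataFrame:
    """Cell means ± SE (sd/√n) of ``variable`` per factor combination."""
    if variable not in data.columns:
        raise ValueError(f"variable {variable!r} not in data")
    for f_ in factors:
        if f_ not in data.columns:
            raise ValueError(f"grouping factor {f_!r} not in data")
    grouped = data.groupby(list(factors), dropna=True)[variable]
    out = grouped.agg(
        mean="mean",
        se=lambda x: x.std(ddof=1) / math.sqrt(len(x)) if len(x) > 1 else np.nan,
        n="count",
    ).reset_index()
    return out


def unweighted_marginal_means(
    cell_table: pd.DataFrame,
    value: str,
    by: tuple[str, ...] | str,
) -> pd.DataFrame:
    """Marginal means as unweighted means of cell means.

    For a balanced design this equals the grand mean over the pooled
    observations; with mild unbalance it is the estimator that weights
    every design cell equally.  ``cell_table`` holds one row per cell
    (e.g. the output of :func:`summarize_treatments`, or a published
    summary table); ``by`` names the factor(s) to retain.
    """
    if isinstance(by, str):
        by = (by,)
    out = (
        cell_table.groupby(list(by))[value]
        .agg(mean="mean", se=lambda x: x.std(ddof=1) / math.sqrt(len(x)), n_cells="count")
        .reset_index()
    )
    return out


# ---------------------------------------------------------------------------
# three-way ANOVA


@dataclass
class AnovaResult:
    """Sequential-SS ANOVA table plus the model R²."""

    table: pd.DataFrame
    r_squared: float
    formula: str


def three_way_anova(
    data: pd.DataFrame,
    response: str,
    factors: tuple[str, str, str] = ("biome", "depth", "distance_m"),
) -> AnovaResult:
    """Full-factorial three-way ANOVA, Type I SS in the given order.

    Main effects enter in the order given, then the two-way
    interactions, then the three-way term; F statistics are against
    the residual mean square.
    """
    df = data.dropna(subset=[response, *factors]).copy()
    for f_ in factors:
        if df[f_].nunique() < 2:
            raise ValueError(f"factor {f_!r} needs at least 2 levels")
    a, b, c = (f"C(Q('{f_}'))" for f_ in factors)
    formula = (
        f"Q('{response}') ~ {a} + {b} + {c} + {a}:{b} + {a}:{c} + {b}:{c} + {a}:{b}:{c}"
    )
    fit = smf.ols(formula, data=df).fit()
    table = sm.stats.anova_lm(fit, typ=1)
    # readable term labels
    rename = {}
    for term in table.index:
        label = term
        for f_ in factors:
            label = label.replace(f"C(Q('{f_}'))", f_)
        rename[term] = label.replace(":", " x ")
    table = table.rename(index=rename)
    return AnovaResult(table=table, r_squared=float(fit.rsquared), formula=formula)


# ---------------------------------------------------------------------------
# backwards stepwise regression


def _term_label(term: frozenset[str], order: list[str]) -> str:
    return ":".join(sorted(term, key=order.index))


def _formula(response: str, terms: list[frozenset[str]], order: list[str]) -> str:
    if not terms:
        return f"Q('{response}') ~ 1"
    sorted_terms = sorted(terms, key=lambda t: (len(t), [order.index(v) for v in sorted(t, key=order.index)]))
    rhs = " + ".join(_term_label(t, order) for t in sorted_terms)
    return f"Q('{response}') ~ {rhs}"


@dataclass
class StepwiseResult:
    """Final model and elimination trace of a backwards stepwise run."""

    response: str
    retained: list[str]
    params: pd.Series
    bse: pd.Series
    term_pvalues: dict[str, float]
    trace: pd.DataFrame
    model: object = field(repr=False, default=None)

    def has_term(self, name: str) -> bool:
        return name in self.retained

    def involves(self, variable: str) -> bool:
        """True if any retained term contains ``variable``."""
        return any(variable in t.split(":") for t in self.retained)


def backwards_stepwise(
    data: pd.DataFrame,
    response: str,
    covariates: tuple[str, ...] = ("MET_C", "Ws_m3m3", "C_pct"),
    alpha: float = 0.05,
) -> StepwiseResult:
    """Backwards elimination from the full interaction model.

    Starts from the model containing all products of the covariates up
    to the highest-order interaction.  At each step the droppable
    terms (those not nested inside a retained higher-order term) are
    tested by the extra-sum-of-squares F test against the current
    model; the least significant term with p > ``alpha`` is dropped,
    preferring higher-order terms on ties.  Stops when every droppable
    term is significant or only the intercept remains.
    """
    df = data.dropna(subset=[response, *covariates]).copy()
    order = list(covariates)
    terms: list[frozenset[str]] = [
        frozenset(combo)
        for size in range(1, len(covariates) + 1)
        for combo in itertools.combinations(covariates, size)
    ]
    if len(df) <= len(terms) + 1:
        raise ValueError("too few observations for the full model")

    def fit(term_list):
        return smf.ols(_formula(response, term_list, order), data=df).fit()

    current = fit(terms)
    trace_rows = []
    step = 0
    while terms:
        droppable = [
            t for t in terms if not any(t < other for other in terms)
        ]
        # p-value of dropping each droppable term
        candidates = []
        for t in droppable:
            reduced = fit([u for u in terms if u != t])
            df_num = int(current.df_model - reduced.df_model)
            df_den = int(current.df_resid)
            fstat = ((reduced.ssr - current.ssr) / df_num) / (current.ssr / df_den)
            pval = float(f_dist.sf(fstat, df_num, df_den))
            candidates.append((t, fstat, pval))
        worst = max(candidates, key=lambda c: (c[2], len(c[0])))
        term, fstat, pval = worst
        trace_rows.append(
            {
                "step": step,
                "term": _term_label(term, order),
                "F": fstat,
                "p": pval,
                "dropped": pval > alpha,
            }
        )
        if pval <= alpha:
            break
        terms = [u for u in terms if u != term]
        current = fit(terms)
        step += 1

    retained = [_term_label(t, order) for t in sorted(terms, key=len)]
    # final per-term F tests against the final model
    term_p = {}
    for t in terms:
        if any(t < other for other in terms):
            term_p[_term_label(t, order)] = np.nan  # protected by marginality
            continue
        reduced = fit([u for u in terms if u != t])
        df_num = int(current.df_model - reduced.df_model)
        fstat = ((reduced.ssr - current.ssr) / df_num) / (current.ssr / current.df_resid)
        term_p[_term_label(t, order)] = float(f_dist.sf(fstat, df_num, current.df_resid))

    return StepwiseResult(
        response=response,
        retained=retained,
        params=current.params,
        bse=current.bse,
        term_pvalues=term_p,
        trace=pd.DataFrame(trace_rows, columns=["step", "term", "F", "p", "dropped"]),
        model=current,
    )


def marginal_slope(result: StepwiseResult, data: pd.DataFrame, variable: str) -> float | None:
    """Average marginal effect of ``variable`` in a final stepwise model.

    ∂E[y]/∂x averaged over the observed covariate rows.  When the final
    model is additive in the variable this is exactly its coefficient;
    when interactions were retained it is the mean slope over the data,
    which is the only comparable single-number summary (a raw
    coefficient would be the slope with every interacting covariate at
    zero).  Returns ``None`` if no retained term involves the variable.
    """
    if not result.involves(variable):
        return None
    slopes = np.zeros(len(data), dtype=float)
    for label, coef in result.params.items():
        parts = label.split(":")
        if variable not in parts:
            continue
        others = [p for p in parts if p != variable]
        partial = np.full(len(data), coef, dtype=float)
        for other in others:
            partial = partial * data[other].to_numpy(dtype=float)
        slopes += partial
    return float(slopes.mean())


def variance_explained(data: pd.DataFrame, response: str, covariate: str) -> float:
    """R² of the simple regression of ``response`` on one covariate."""
    df = data.dropna(subset=[response, covariate])
    x = df[covariate].to_numpy(dtype=float)
    y = df[response].to_numpy(dtype=float)
    if np.ptp(x) == 0:
        raise ValueError(f"covariate {covariate!r} has zero variance")
    r = np.corrcoef(x, y)[0, 1]
    return float(r**2)


# ---------------------------------------------------------------------------
# random-intercept mixed model (profile maximum likelihood)


def aicc_from_loglik(loglik: float, n: int, k: int) -> float:
    """AICc from a maximised log-likelihood."""
    if not n > k + 1:
        raise ValueError(f"AICc undefined for n={n}, k={k}")
    return -2.0 * loglik + 2 * k + 2 * k * (k + 1) / (n - k - 1)


@dataclass
class LMMResult:
    """Gaussian random-intercept model fitted by profile ML."""

    fe_params: pd.Series
    sigma2_between: float
    sigma2_within: float
    loglik: float
    aicc: float
    n: int
    k: int
    groups: list


def _profile_loglik(lam: float, X: np.ndarray, y: np.ndarray, group_idx: list[np.ndarray]):
    """Profile log-likelihood of the variance ratio λ = σ²_b/σ²_w.

    With V0 = I + λ·ZZᵀ block-diagonal over groups, V0⁻¹ per group is
    I − (λ/(1+λ n_i))·J, so GLS and ln|V0| are closed-form per group.
    """
    n = len(y)
    logdet = 0.0
    XtVX = np.zeros((X.shape[1], X.shape[1]))
    XtVy = np.zeros(X.shape[1])
    for idx in group_idx:
        ni = len(idx)
        Xi, yi = X[idx], y[idx]
        w = lam / (1.0 + lam * ni)
        logdet += math.log1p(lam * ni)
        XtVX += Xi.T @ Xi - w * np.outer(Xi.sum(axis=0), Xi.sum(axis=0))
        XtVy += Xi.T @ yi - w * Xi.sum(axis=0) * yi.sum()
    beta = np.linalg.solve(XtVX, XtVy)
    quad = 0.0
    for idx in group_idx:
        ri = y[idx] - X[idx] @ beta
        w = lam / (1.0 + lam * len(idx))
        quad += ri @ ri - w * ri.sum() ** 2
    sigma2 = quad / n
    loglik = -0.5 * (n * math.log(2 * math.pi * sigma2) + logdet + n)
    return loglik, beta, sigma2


def lmm_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed: str,
    group: str = "transect",
) -> LMMResult:
    """Maximum-likelihood random-intercept model.

    ``fixed`` is a patsy right-hand side (e.g. ``"MET_C*Ws_m3m3*C_pct"``).
    The likelihood is profiled over the between/within variance ratio
    λ ≥ 0 and maximised by bounded one-dimensional search; λ = 0 (no
    between-group variance) is admitted at the boundary.  The AICc
    parameter count is the number of fixed effects plus the two
    variances.
    """
    df = data.dropna(subset=[response, group]).copy()
    groups = sorted(df[group].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 groups for a random intercept")
    import patsy

    y_mat, X_mat = patsy.dmatrices(f"Q('{response}') ~ {fixed}", df, return_type="dataframe")
    X = X_mat.to_numpy(dtype=float)
    y = y_mat.to_numpy(dtype=float).ravel()
    if len(y) <= X.shape[1] + 2:
        raise ValueError("too few observations for the fixed-effects structure")
    codes = df[group].to_numpy()
    group_idx = [np.flatnonzero(codes == g) for g in groups]

    def negll(u: float) -> float:
        lam = math.expm1(u) if u > 0 else u  # identity near 0, exp growth
        lam = max(lam, 0.0)
        return -_profile_loglik(lam, X, y, group_idx)[0]

    # profile on a transformed axis u with λ = e^u − 1 for u>0
    res = minimize_scalar(negll, bounds=(0.0, 12.0), method="bounded", options={"xatol": 1e-12})
    lam = max(math.expm1(res.x), 0.0)
    # always admit the boundary
    ll0, beta0, s20 = _profile_loglik(0.0, X, y, group_idx)
    ll, beta, sigma2 = _profile_loglik(lam, X, y, group_idx)
    if ll0 >= ll:
        lam, ll, beta, sigma2 = 0.0, ll0, beta0, s20
    k = X.shape[1] + 2
    return LMMResult(
        fe_params=pd.Series(beta, index=list(X_mat.columns)),
        sigma2_between=lam * sigma2,
        sigma2_within=sigma2,
        loglik=ll,
        aicc=aicc_from_loglik(ll, len(y), k),
        n=len(y),
        k=k,
        groups=groups,
    )


@dataclass(frozen=True)
class RandomInterceptComparison:
    """AICc comparison of the mixed model against plain OLS."""

    aicc_fixed: float
    aicc_mixed: float

    @property
    def improved(self) -> bool:
        """True if the random intercept lowers AICc."""
        return self.aicc_mixed < self.aicc_fixed


def compare_random_intercept(
    data: pd.DataFrame,
    response: str,
    fixed: str,
    group: str = "transect",
) -> RandomInterceptComparison:
    """Does a transect random intercept improve the full model's AICc?"""
    df = data.dropna(subset=[response, group]).copy()
    ols_fit = smf.ols(f"Q('{response}') ~ {fixed}", data=df).fit()
    k_fixed = int(ols_fit.df_model) + 2  # coefficients (incl. intercept) + variance
    aicc_fixed = aicc_from_loglik(float(ols_fit.llf), int(ols_fit.nobs), k_fixed)
    mixed = lmm_random_intercept(df, response, fixed, group)
    return RandomInterceptComparison(aicc_fixed=aicc_fixed, aicc_mixed=mixed.aicc)
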