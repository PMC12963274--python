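"""Statistical comparison layer for contextualised gait outcomes.

Four families of analyses, mirroring the exploratory design of small
free-living mobility studies (no multiple-testing correction; standardized
effect sizes reported alongside p-values):

* within-cohort Gaussian GLMs of a DMO on location (indoor vs outdoor),
  adjusted for sex, age and height, fitted on participant-level summaries;
* between-cohort GLMs adding cohort and a Cohort x Location interaction;
* Fisher's exact test on mode-count contingency tables — exact
  hypergeometric enumeration for 2 x 2, seeded Monte Carlo over tables with
  fixed margins for larger tables;
* proportional-odds (cumulative-logit) ordinal regression of the mode count
  on clinical predictors with backward elimination of non-significant
  predictors (Wald p > 0.05, age/sex adjusters never removed) and
  Nagelkerke's R-squared for explanatory power.

Continuous predictors are standardized before modeling.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.special import gammaln
from scipy.stats import hypergeom, random_table
from statsmodels.miscmodels.ordinal_model import OrderedModel

from .config import StatsConfig

__all__ = [
    "ModelResult",
    "FisherResult",
    "glm_within_cohort",
    "glm_interaction",
    "fisher_exact",
    "ordinal_backward_elimination",
    "nagelkerke_r2",
]


class ModelFitError(RuntimeError):
    """Raised on singular designs or non-convergence."""


@dataclass
class ModelResult:
    """Fitted-model summary: one row per term plus diagnostics."""

    outcome: str
    model: str
    terms: pd.DataFrame  # term, estimate, se, ci_low, ci_high, p [, odds_ratio...]
    n: int
    loglik: float = np.nan
    loglik_null: float = np.nan
    diagnostics: dict = field(default_factory=dict)
    elimination_trace: list = field(default_factory=list)
    exploratory: bool = True  # no multiplicity correction applied

    def term(self, name: str) -> pd.Series:
        row = self.terms[self.terms["term"] == name]
        if row.empty:
            raise KeyError(f"term {name!r} not in model")
        return row.iloc[0]

    def summary(self) -> pd.DataFrame:
        out = self.terms.copy()
        out.insert(0, "outcome", self.outcome)
        out.insert(1, "model", self.model)
        return out


def _standardize(df: pd.DataFrame, cols) -> pd.DataFrame:
    out = df.copy()
    for c in cols:
        v = out[c].astype(float)
        sd = v.std(ddof=0)
        if not np.isfinite(sd) or sd == 0:
            raise ModelFitError(f"cannot standardize constant predictor {c!r}")
        out[c] = (v - v.mean()) / sd
    return out


def _ols_result(y, X: pd.DataFrame, outcome: str, model: str) -> ModelResult:
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        # name the collinear columns for the error message
        _, r = np.linalg.qr(X.to_numpy())
        bad = [X.columns[i] for i in range(X.shape[1]) if abs(r[i, i]) < 1e-10]
        raise ModelFitError(f"singular design; collinear terms: {bad}")
    fit = sm.OLS(np.asarray(y, dtype=float), X).fit()
    ci = fit.conf_int(alpha=0.05)
    resid_sd = float(np.sqrt(fit.scale))
    terms = pd.DataFrame(
        {
            "term": X.columns,
            "estimate": fit.params.to_numpy(),
            "se": fit.bse.to_numpy(),
            "ci_low": ci[0].to_numpy(),
            "ci_high": ci[1].to_numpy(),
            "p": fit.pvalues.to_numpy(),
            "std_effect": fit.params.to_numpy() / resid_sd,
        }
    )
    return ModelResult(
        outcome=outcome,
        model=model,
        terms=terms,
        n=int(fit.nobs),
        loglik=float(fit.llf),
        diagnostics={
            "resid_sd": resid_sd,
            "condition_number": float(fit.condition_number),
            "r_squared": float(fit.rsquared),
        },
    )


def _long_format(
    participant_dmos: pd.DataFrame, clinical: pd.DataFrame, outcome: str
) -> pd.DataFrame:
    """Paired long format: one row per participant per context stratum."""
    sub = participant_dmos[
        participant_dmos["stratum"].isin(["indoor", "outdoor"])
        & ~participant_dmos.get("excluded", False)
    ][["participant_id", "stratum", outcome]].dropna(subset=[outcome])
    merged = sub.merge(
        clinical[["participant_id", "cohort", "sex", "age_y", "height_m"]],
        on="participant_id",
        how="inner",
    )
    merged["location_outdoor"] = (merged["stratum"] == "outdoor").astype(float)
    merged["sex_male"] = (merged["sex"] == "M").astype(float)
    return merged


def glm_within_cohort(
    participant_dmos: pd.DataFrame,
    clinical: pd.DataFrame,
    cohort: str,
    outcome: str,
    cfg: StatsConfig | None = None,
) -> ModelResult:
    """Gaussian GLM of a DMO on location within one cohort.

    Model: outcome ~ location + sex + age + height on the paired long
    format (one indoor and one outdoor row per participant). The
    ``location_outdoor`` coefficient is the adjusted outdoor-minus-indoor
    difference.
    """
    cfg = (cfg or StatsConfig()).validate()
    long = _long_format(participant_dmos, clinical, outcome)
    long = long[long["cohort"] == cohort]
    n_participants = long["participant_id"].nunique()
    if n_participants < 3:
        raise ModelFitError(
            f"cohort {cohort!r}: need participants with both-context values"
        )
    if n_participants < 10:
        warnings.warn(
            f"cohort {cohort!r}: only {n_participants} participants with "
            "both-context values; estimates will be unstable",
            stacklevel=2,
        )
    if cfg.standardize:
        long = _standardize(long, ["age_y", "height_m"])
    X = sm.add_constant(
        long[["location_outdoor", "sex_male", "age_y", "height_m"]], has_constant="add"
    )
    res = _ols_result(long[outcome], X, outcome, f"within_{cohort}")
    res.diagnostics["n_participants"] = n_participants
    return res


def glm_interaction(
    participant_dmos: pd.DataFrame,
    clinical: pd.DataFrame,
    outcome: str,
    cfg: StatsConfig | None = None,
) -> ModelResult:
    """Between-cohort GLM with a Cohort x Location interaction.

    The ``cohort_pwp:location_outdoor`` coefficient tests whether the
    indoor/outdoor difference differs between cohorts.
    """
    cfg = (cfg or StatsConfig()).validate()
    long = _long_format(participant_dmos, clinical, outcome)
    cohorts = sorted(long["cohort"].unique())
    if len(cohorts) != 2:
        raise ModelFitError(f"need exactly two cohorts, found {cohorts}")
    for c in cohorts:
        strata = set(long.loc[long["cohort"] == c, "stratum"])
        if strata != {"indoor", "outdoor"}:
            raise ModelFitError(f"cohort {c!r} missing a context stratum")
    long["cohort_pwp"] = (long["cohort"] == "pwp").astype(float)
    long["cohort_pwp:location_outdoor"] = (
        long["cohort_pwp"] * long["location_outdoor"]
    )
    if cfg.standardize:
        long = _standardize(long, ["age_y", "height_m"])
    X = sm.add_constant(
        long[
            ["cohort_pwp", "location_outdoor", "cohort_pwp:location_outdoor",
             "sex_male", "age_y", "height_m"]
        ],
        has_constant="add",
    )
    return _ols_result(long[outcome], X, outcome, "cohort_x_location")


# ---------------------------------------------------------------------------
# Fisher's exact test


@dataclass
class FisherResult:
    p: float
    method: str  # "exact" | "mc" | "degenerate"
    n_draws: int = 0


def _log_table_prob(tables: np.ndarray, rows: np.ndarray, cols: np.ndarray):
    """Log multivariate hypergeometric probability of tables given margins."""
    n = rows.sum()
    const = gammaln(rows + 1).sum() + gammaln(cols + 1).sum() - gammaln(n + 1)
    return const - gammaln(tables + 1).sum(axis=(-2, -1))


def fisher_exact(table, cfg: StatsConfig | None = None) -> FisherResult:
    """Fisher's exact test of independence on an r x c contingency table.

    2 x 2 tables use full hypergeometric enumeration with the two-sided
    rule "sum the probabilities of all tables no more probable than the
    observed one". Larger tables use seeded Monte Carlo over tables with
    the observed margins, with the add-one estimator
    p = (1 + #{prob <= observed}) / (draws + 1).
    """
    cfg = (cfg or StatsConfig()).validate()
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or np.any(t < 0):
        raise ValueError("table must be a 2-D array of nonnegative integers")
    rows = t.sum(axis=1)
    cols = t.sum(axis=0)
    n = int(t.sum())
    if n == 0:
        return FisherResult(p=1.0, method="degenerate")
    if t.shape == (2, 2):
        r0, c0 = int(rows[0]), int(cols[0])
        support = np.arange(max(0, r0 + c0 - n), min(r0, c0) + 1)
        pmf = hypergeom(n, r0, c0).pmf(support)
        p_obs = hypergeom(n, r0, c0).pmf(int(t[0, 0]))
        p = float(pmf[pmf <= p_obs * (1.0 + 1e-10)].sum())
        return FisherResult(p=min(1.0, p), method="exact")
    rng = np.random.default_rng(int(cfg.seed) % (2**31))
    draws = random_table(rows, cols).rvs(size=cfg.fisher_mc_draws, random_state=rng)
    logp = _log_table_prob(draws, rows, cols)
    logp_obs = float(_log_table_prob(t[None], rows, cols)[0])
    count = int(np.sum(logp <= logp_obs + 1e-7))
    p = (1.0 + count) / (cfg.fisher_mc_draws + 1.0)
    return FisherResult(p=float(p), method="mc", n_draws=cfg.fisher_mc_draws)


# ---------------------------------------------------------------------------
# proportional-odds ordinal regression


def _ordinal_null_loglik(y: np.ndarray) -> float:
    """Log-likelihood of the intercept-only ordinal model (closed form)."""
    _, counts = np.unique(y, return_counts=True)
    n = counts.sum()
    return float((counts * np.log(counts / n)).sum())


def _fit_ordered(y, X: pd.DataFrame):
    endog = pd.Categorical(y, ordered=True)
    model = OrderedModel(endog, X, distr="logit")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(method="bfgs", disp=0, maxiter=1000, gtol=1e-10)
    # BFGS may stop on precision loss with the gradient already negligible;
    # accept any stationary point (per-observation score ~ 0)
    grad = np.linalg.norm(model.score(fit.params)) / max(model.nobs, 1)
    if not fit.mle_retvals.get("converged", True) and grad > 1e-6:
        raise ModelFitError(f"ordinal fit did not converge; |gradient|/n = {grad:.3g}")
    return model, fit


def ordinal_backward_elimination(
    data: pd.DataFrame,
    outcome: str,
    candidates: list[str],
    cfg: StatsConfig | None = None,
    adjusters: tuple[str, ...] = (),
) -> ModelResult:
    """Proportional-odds model with backward elimination of candidates.

    Fits P(Y <= j | x) = logistic(theta_j - x'beta) by maximum likelihood,
    then iteratively removes the candidate with the largest Wald p-value
    above the elimination threshold, refitting each time. ``adjusters``
    (e.g. age, sex) are never removed. Reports odds ratios exp(beta) with
    95% CIs, the elimination trace, and Nagelkerke's R-squared.
    """
    cfg = (cfg or StatsConfig()).validate()
    df = data.dropna(subset=[outcome] + list(candidates) + list(adjusters)).copy()
    y = df[outcome].to_numpy()
    levels = np.unique(y)
    if len(levels) < 2:
        raise ModelFitError("outcome needs >= 2 observed levels")
    keep = list(candidates)
    if cfg.standardize:
        continuous = [
            c for c in list(candidates) + list(adjusters)
            if df[c].nunique() > 2
        ]
        df = _standardize(df, continuous)
    n = len(df)
    if n <= 10 * len(candidates):
        warnings.warn(
            f"n={n} is small for {len(candidates)} candidate predictors",
            stacklevel=2,
        )
    trace = []
    step = 0
    while True:
        cols = keep + list(adjusters)
        if not cols:
            fit = None
            break
        _, fit = _fit_ordered(y, df[cols])
        pvals = fit.pvalues[cols]
        cand_p = pvals[keep] if keep else pd.Series(dtype=float)
        if cand_p.empty or cand_p.max() <= cfg.elimination_threshold:
            break
        worst = cand_p.idxmax()
        trace.append(
            {"step": step, "dropped": worst, "p": float(cand_p.max()),
             "remaining": [c for c in keep if c != worst]}
        )
        keep.remove(worst)
        step += 1

    ll0 = _ordinal_null_loglik(y)
    if fit is None:
        # nothing retained and no adjusters: null model
        terms = pd.DataFrame(
            columns=["term", "estimate", "se", "ci_low", "ci_high", "p",
                     "odds_ratio", "or_ci_low", "or_ci_high"]
        )
        return ModelResult(
            outcome=outcome, model="proportional_odds", terms=terms, n=n,
            loglik=ll0, loglik_null=ll0, elimination_trace=trace,
            diagnostics={"retained": [], "nagelkerke_r2": 0.0,
                         "thresholds": {}},
        )
    cols = keep + list(adjusters)
    separation = bool(np.any(np.abs(fit.params[cols]) > 15))
    ci = fit.conf_int(alpha=0.05)
    rows = []
    for c in cols:
        est = float(fit.params[c])
        rows.append(
            {
                "term": c,
                "estimate": est,
                "se": float(fit.bse[c]),
                "ci_low": float(ci.loc[c, 0]),
                "ci_high": float(ci.loc[c, 1]),
                "p": float(fit.pvalues[c]),
                "odds_ratio": float(np.exp(est)),
                "or_ci_low": float(np.exp(ci.loc[c, 0])),
                "or_ci_high": float(np.exp(ci.loc[c, 1])),
            }
        )
    ll1 = float(fit.llf)
    thresholds = {
        name: float(v)
        for name, v in fit.params.items()
        if name not in cols
    }
    return ModelResult(
        outcome=outcome,
        model="proportional_odds",
        terms=pd.DataFrame(rows),
        n=n,
        loglik=ll1,
        loglik_null=ll0,
        elimination_trace=trace,
        diagnostics={
            "retained": keep,
            "adjusters": list(adjusters),
            "nagelkerke_r2": nagelkerke_r2(ll1, ll0, n),
            "complete_separation": separation,
            "thresholds": thresholds,
        },
    )


def nagelkerke_r2(loglik_full: float, loglik_null: float, n: int) -> float:
    """Nagelkerke's pseudo R-squared.

    R2 = [1 - exp((2/n)(l0 - l1))] / [1 - exp((2/n) l0)], clamped to [0, 1].
    The null model must nest in the full model (l1 >= l0).
    """
    if not (np.isfinite(loglik_full) and np.isfinite(loglik_null)):
        raise ValueError("log-likelihoods must be finite")
    if loglik_full < loglik_null - 1e-8:
        raise ValueError("null model must nest in the full model (l1 >= l0)")
    cox_snell = 1.0 - np.exp((2.0 / n) * (loglik_null - loglik_full))
    max_cs = 1.0 - np.exp((2.0 / n) * loglik_null)
    if max_cs <= 0:
        return 0.0
    r2 = cox_snell / max_cs
    return float(min(1.0, max(0.0, r2)))
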