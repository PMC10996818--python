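"""Two-part mixed models of 0-100 discrete-emotion ratings.

Negative emotions (anger, disgust, sadness) are reflected and log-transformed,
``t = ln(101 - raw)``, so that the boundary response raw = 100 lands exactly at
t = 0; joy uses ``t = ln(raw + 1)`` so raw = 0 lands at t = 0.  Fear is left
untransformed.  The transform isolates *extreme* responses (t = 0) from
graded ones (t > 0), which a two-part zero-inflated Gaussian mixed model then
handles with:

* a logistic mixed submodel for the indicator "non-extreme response"
  (success = t > 0) with a subject random intercept, fitted by maximum
  likelihood with Gauss-Hermite quadrature over the random effect; and
* a Gaussian linear mixed submodel for t restricted to the non-extreme rows,
  with a subject random intercept, fitted by maximum likelihood.

Both submodels use the fixed effects time + group + time x group.  Reported
alongside the coefficients: odds ratios (exp of the logistic coefficients),
Wald confidence intervals, variance components (sigma^2, tau00), intraclass
correlations (tau00 / (tau00 + sigma^2), with sigma^2 = pi^2/3 on the latent
logistic scale), and marginal/conditional R^2 in the variance-partition form
marginal = var_fixed / (var_fixed + tau00 + sigma^2).

Fear is modeled with a single Gaussian mixed model fitted by REML on the raw
scale.  A Mann-Whitney U test is provided for the intergroup-attitude
outcomes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.special import log_expit
import statsmodels.api as sm
from statsmodels.tools.numdiff import approx_hess1

from .types import DegenerateInputError, InvalidSpecError

__all__ = [
    "transform_ratings",
    "inverse_transform",
    "fit_two_part_zig",
    "fit_gaussian_lmm",
    "icc_gaussian",
    "icc_logistic",
    "r2_nakagawa",
    "mann_whitney_u",
    "TwoPartFit",
    "MixedFit",
]

NEGATIVE_EMOTIONS = ("anger", "disgust", "sadness")
LATENT_LOGISTIC_VAR = np.pi**2 / 3  # residual variance on the log-odds scale
FIXED_TERMS = ("intercept", "time", "group", "time_x_group")


# --------------------------------------------------------------------------
# rating transformations
# --------------------------------------------------------------------------


def transform_ratings(values: np.ndarray | pd.Series, emotion: str) -> pd.DataFrame:
    """Transform raw 0-100 ratings for one emotion.

    Returns a frame with columns ``transformed`` (t >= 0) and ``extreme``
    (t == 0).  Negative emotions: ``t = ln(101 - raw)``; joy:
    ``t = ln(raw + 1)``; fear passes through untransformed with no extremes.
    """
    raw = np.asarray(values, dtype=float)
    if np.any((raw < 0) | (raw > 100)) or not np.all(np.isfinite(raw)):
        raise InvalidSpecError("raw ratings must lie in [0, 100]")
    if emotion in NEGATIVE_EMOTIONS:
        t = np.log(101.0 - raw)
    elif emotion == "joy":
        t = np.log(raw + 1.0)
    elif emotion == "fear":
        t = raw.copy()
    else:
        raise InvalidSpecError(f"unknown emotion {emotion!r}")
    extreme = (t == 0) if emotion != "fear" else np.zeros(raw.shape, dtype=bool)
    return pd.DataFrame({"transformed": t, "extreme": extreme})


def inverse_transform(t: np.ndarray, emotion: str) -> np.ndarray:
    """Inverse of :func:`transform_ratings` (round-trips to ~1e-12)."""
    t = np.asarray(t, dtype=float)
    if emotion in NEGATIVE_EMOTIONS:
        return 101.0 - np.exp(t)
    if emotion == "joy":
        return np.exp(t) - 1.0
    if emotion == "fear":
        return t.copy()
    raise InvalidSpecError(f"unknown emotion {emotion!r}")


# --------------------------------------------------------------------------
# logistic mixed model (Gauss-Hermite quadrature ML)
# --------------------------------------------------------------------------


def _glmm_logit_loglik(
    params: np.ndarray,
    X: np.ndarray,
    y: np.ndarray,
    group_idx: np.ndarray,
    n_groups: int,
    nodes: np.ndarray,
    log_weights: np.ndarray,
) -> float:
    """Marginal log-likelihood of a random-intercept logistic model.

    params = (beta..., log sd_u).  The integral over each subject's random
    intercept is approximated with Gauss-Hermite quadrature:
    int phi(u; 0, sd^2) f(u) du ~ sum_q w_q / sqrt(pi) * f(sqrt(2) sd z_q).
    """
    beta = params[:-1]
    sd = np.exp(params[-1])
    eta = X @ beta  # (n_obs,)
    u = np.sqrt(2.0) * sd * nodes  # (n_quad,)
    # conditional log-lik of each obs at each node: (n_obs, n_quad)
    lin = eta[:, None] + u[None, :]
    ll_obs = np.where(y[:, None] > 0, log_expit(lin), log_expit(-lin))
    # sum within subjects
    ll_group = np.zeros((n_groups, nodes.size))
    np.add.at(ll_group, group_idx, ll_obs)
    # log sum over quadrature nodes
    m = ll_group + log_weights[None, :]
    mx = m.max(axis=1, keepdims=True)
    lse = mx[:, 0] + np.log(np.sum(np.exp(m - mx), axis=1))
    return float(np.sum(lse))


def _fit_logistic_glmm(
    X: np.ndarray,
    y: np.ndarray,
    groups: np.ndarray,
    n_quad: int = 30,
) -> dict:
    """ML fit of a random-intercept logistic model; Wald SEs from the Hessian."""
    uniq, group_idx = np.unique(groups, return_inverse=True)
    n_groups = uniq.size
    nodes, weights = np.polynomial.hermite.hermgauss(n_quad)
    log_weights = np.log(weights) - 0.5 * np.log(np.pi)

    def neg(params: np.ndarray) -> float:
        return -_glmm_logit_loglik(
            params, X, y, group_idx, n_groups, nodes, log_weights
        )

    # start from the marginal GLM and a moderate random-intercept sd
    glm = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    x0 = np.concatenate([glm.params, [np.log(0.5)]])
    res = optimize.minimize(neg, x0, method="BFGS", options={"maxiter": 500})
    if not res.success:
        res2 = optimize.minimize(
            neg, res.x, method="Nelder-Mead", options={"maxiter": 4000, "xatol": 1e-8}
        )
        if res2.fun <= res.fun:
            res = res2
    params = res.x
    H = approx_hess1(params, neg)
    try:
        cov = np.linalg.inv(H)
        se = np.sqrt(np.clip(np.diag(cov), 0, None))
    except np.linalg.LinAlgError:
        se = np.full(params.size, np.nan)
    sd_u = float(np.exp(params[-1]))
    return {
        "coef": params[:-1],
        "se": se[:-1],
        "tau00": sd_u**2,
        "sd_u": sd_u,
        "loglik": -res.fun,
        "converged": bool(res.success or np.all(np.isfinite(se))),
    }


# --------------------------------------------------------------------------
# fit containers
# --------------------------------------------------------------------------


@dataclass
class SubmodelFit:
    """Coefficient table plus variance components for one submodel."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    sigma2: float
    tau00: float
    icc: float
    odds_ratio: np.ndarray | None = None
    or_ci_low: np.ndarray | None = None
    or_ci_high: np.ndarray | None = None
    converged: bool = True

    def to_dict(self) -> dict:
        out = {
            "terms": {
                t: {
                    "estimate": float(self.coef[i]),
                    "se": float(self.se[i]),
                    "ci": [float(self.ci_low[i]), float(self.ci_high[i])],
                    "p": float(self.p[i]),
                    **(
                        {
                            "odds_ratio": float(self.odds_ratio[i]),
                            "or_ci": [
                                float(self.or_ci_low[i]),
                                float(self.or_ci_high[i]),
                            ],
                        }
                        if self.odds_ratio is not None
                        else {}
                    ),
                }
                for i, t in enumerate(self.terms)
            },
            "sigma2": float(self.sigma2),
            "tau00": float(self.tau00),
            "icc": float(self.icc),
            "converged": self.converged,
        }
        return out


@dataclass
class TwoPartFit:
    """Joint result of the logistic + Gaussian two-part model."""

    logistic: SubmodelFit | None
    gaussian: SubmodelFit
    r2_marginal: float
    r2_conditional: float
    n_subjects: int
    n_observations: int
    n_extreme: int
    logistic_skipped: bool = False
    notes: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "logistic": None if self.logistic is None else self.logistic.to_dict(),
            "gaussian": self.gaussian.to_dict(),
            "r2_marginal": float(self.r2_marginal),
            "r2_conditional": float(self.r2_conditional),
            "n_subjects": self.n_subjects,
            "n_observations": self.n_observations,
            "n_extreme": self.n_extreme,
            "logistic_skipped": self.logistic_skipped,
            "notes": self.notes,
        }


@dataclass
class MixedFit:
    """Plain Gaussian linear mixed model result (used for fear)."""

    terms: list[str]
    coef: np.ndarray
    se: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    p: np.ndarray
    sigma2: float
    tau00: float
    icc: float
    r2_marginal: float
    r2_conditional: float
    n_subjects: int
    n_observations: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)


# --------------------------------------------------------------------------
# model fitting
# --------------------------------------------------------------------------


def _design(df: pd.DataFrame) -> np.ndarray:
    X = np.column_stack(
        [
            np.ones(len(df)),
            df["session"].to_numpy(dtype=float),
            df["group"].to_numpy(dtype=float),
            df["session"].to_numpy(dtype=float) * df["group"].to_numpy(dtype=float),
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise InvalidSpecError(
            "design matrix is rank deficient (constant time or group indicator?)"
        )
    return X


def _wald_table(coef, se, alpha=0.05):
    z = stats.norm.ppf(1 - alpha / 2)
    ci_low = coef - z * se
    ci_high = coef + z * se
    with np.errstate(divide="ignore", invalid="ignore"):
        p = 2 * stats.norm.sf(np.abs(coef / se))
    return ci_low, ci_high, p


def _var_fixed(X: np.ndarray, coef: np.ndarray) -> float:
    # variance of the linear predictor (sample variance, n-1 denominator,
    # mirroring the convention of the R implementations of this statistic)
    return float(np.var(X @ coef, ddof=1))


def _fit_gaussian_submodel(
    df: pd.DataFrame, outcome: np.ndarray, reml: bool
) -> SubmodelFit:
    X = _design(df)
    groups = df["subject"].to_numpy()
    model = sm.MixedLM(outcome, X, groups=groups)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            fit = model.fit(reml=reml)
        except np.linalg.LinAlgError:
            fit = model.fit(reml=reml, method="powell")
    coef = np.asarray(fit.fe_params)
    se = np.asarray(fit.bse_fe)
    ci_low, ci_high, p = _wald_table(coef, se)
    sigma2 = float(fit.scale)
    tau00 = float(np.asarray(fit.cov_re)[0, 0])
    return SubmodelFit(
        terms=list(FIXED_TERMS),
        coef=coef,
        se=se,
        ci_low=ci_low,
        ci_high=ci_high,
        p=p,
        sigma2=sigma2,
        tau00=tau00,
        icc=icc_gaussian(tau00, sigma2),
        converged=bool(fit.converged),
    )


def fit_two_part_zig(
    table: pd.DataFrame,
    emotion: str | None = None,
) -> TwoPartFit:
    """Fit the two-part zero-inflated Gaussian mixed model.

    ``table`` is a long-format ratings frame with columns subject, session,
    group, value (raw 0-100) and optionally emotion.  The raw values are
    transformed for the given emotion; the logistic submodel then models the
    indicator of a *non-extreme* response (so an odds ratio below 1 for a term
    means more extreme responding), and the Gaussian submodel models the
    transformed value on the non-extreme rows.
    """
    df = table.copy()
    if emotion is None:
        emotions_present = df["emotion"].unique()
        if len(emotions_present) != 1:
            raise InvalidSpecError("table mixes emotions; pass emotion explicitly")
        emotion = emotions_present[0]
    elif "emotion" in df.columns:
        df = df[df["emotion"] == emotion]
    if emotion == "fear":
        raise InvalidSpecError("fear uses fit_gaussian_lmm (no zero-inflated part)")
    n_missing = int(df["value"].isna().sum())
    if n_missing:
        df = df.dropna(subset=["value"])
    tr = transform_ratings(df["value"].to_numpy(), emotion)
    df = df.assign(transformed=tr["transformed"].to_numpy(), extreme=tr["extreme"].to_numpy())
    if df["subject"].nunique() < 2:
        raise InvalidSpecError("need >= 2 subjects")

    notes = []
    if n_missing:
        notes.append(f"{n_missing} missing rating(s) dropped")
    n_extreme = int(df["extreme"].sum())
    y_nonextreme = (~df["extreme"]).to_numpy(dtype=float)

    logistic_fit = None
    skipped = False
    if n_extreme == 0 or n_extreme == len(df):
        skipped = True
        notes.append(
            "logistic submodel skipped: "
            + ("no extreme responses" if n_extreme == 0 else "all responses extreme")
        )
    else:
        X = _design(df)
        raw = _fit_logistic_glmm(X, y_nonextreme, df["subject"].to_numpy())
        coef, se = raw["coef"], raw["se"]
        ci_low, ci_high, p = _wald_table(coef, se)
        tau00 = raw["tau00"]
        logistic_fit = SubmodelFit(
            terms=list(FIXED_TERMS),
            coef=coef,
            se=se,
            ci_low=ci_low,
            ci_high=ci_high,
            p=p,
            sigma2=LATENT_LOGISTIC_VAR,
            tau00=tau00,
            icc=icc_logistic(tau00),
            odds_ratio=np.exp(coef),
            or_ci_low=np.exp(ci_low),
            or_ci_high=np.exp(ci_high),
            converged=raw["converged"],
        )

    pos = df[~df["extreme"]]
    if len(pos) < 8 or pos["subject"].nunique() < 2:
        raise InvalidSpecError("too few non-extreme rows for the Gaussian submodel")
    gaussian_fit = _fit_gaussian_submodel(
        pos, pos["transformed"].to_numpy(), reml=False
    )
    vf = _var_fixed(_design(pos), gaussian_fit.coef)
    r2m, r2c = r2_nakagawa(vf, gaussian_fit.tau00, gaussian_fit.sigma2)
    return TwoPartFit(
        logistic=logistic_fit,
        gaussian=gaussian_fit,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_subjects=int(df["subject"].nunique()),
        n_observations=len(df),
        n_extreme=n_extreme,
        logistic_skipped=skipped,
        notes=notes,
    )


def fit_gaussian_lmm(table: pd.DataFrame, emotion: str = "fear") -> MixedFit:
    """REML Gaussian mixed model on the untransformed 0-100 scale (fear)."""
    df = table.copy()
    if "emotion" in df.columns:
        df = df[df["emotion"] == emotion]
    df = df.dropna(subset=["value"])
    notes = []
    per_subject = df.groupby("subject").size()
    if per_subject.max() == 1:
        notes.append(
            "single observation per subject: tau00 and sigma2 are not separately identifiable"
        )
    fit = _fit_gaussian_submodel(df, df["value"].to_numpy(dtype=float), reml=True)
    vf = _var_fixed(_design(df), fit.coef)
    r2m, r2c = r2_nakagawa(vf, fit.tau00, fit.sigma2)
    return MixedFit(
        terms=fit.terms,
        coef=fit.coef,
        se=fit.se,
        ci_low=fit.ci_low,
        ci_high=fit.ci_high,
        p=fit.p,
        sigma2=fit.sigma2,
        tau00=fit.tau00,
        icc=fit.icc,
        r2_marginal=r2m,
        r2_conditional=r2c,
        n_subjects=int(df["subject"].nunique()),
        n_observations=len(df),
        converged=fit.converged,
        notes=notes,
    )


# --------------------------------------------------------------------------
# variance-partition statistics
# --------------------------------------------------------------------------


def icc_gaussian(tau00: float, sigma2: float) -> float:
    """Intraclass correlation tau00 / (tau00 + sigma2)."""
    if tau00 < 0:
        raise InvalidSpecError("tau00 must be >= 0")
    if sigma2 <= 0:
        raise InvalidSpecError("sigma2 must be > 0")
    return tau00 / (tau00 + sigma2)


def icc_logistic(tau00: float) -> float:
    """Latent-scale ICC of a logistic mixed model, tau00 / (tau00 + pi^2/3)."""
    if tau00 < 0:
        raise InvalidSpecError("tau00 must be >= 0")
    return tau00 / (tau00 + LATENT_LOGISTIC_VAR)


def r2_nakagawa(
    var_fixed: float, tau00: float, sigma2: float
) -> tuple[float, float]:
    """Marginal and conditional R^2 by variance partitioning.

    marginal = var_fixed / (var_fixed + tau00 + sigma2);
    conditional = (var_fixed + tau00) / (var_fixed + tau00 + sigma2).
    """
    if min(var_fixed, tau00, sigma2) < 0:
        raise InvalidSpecError("variance components must be >= 0")
    total = var_fixed + tau00 + sigma2
    if total <= 0:
        raise InvalidSpecError("total variance must be > 0")
    return var_fixed / total, (var_fixed + tau00) / total


def mann_whitney_u(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney U test; returns (U of sample a, p).

    Exact enumeration when ``n_a * n_b <= 400`` and there are no ties,
    otherwise the normal approximation with tie and continuity corrections.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise InvalidSpecError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size * b.size <= 400 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
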