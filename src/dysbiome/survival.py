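"""Longitudinal, survival, and joint modeling for 60-day outcomes.

The longitudinal submodel is a linear mixed model with a random patient
intercept (statsmodels ``MixedLM``). Survival uses the Kaplan-Meier
product-limit estimator and log-rank test (lifelines) and a Cox
proportional-hazards model maximized by Newton iteration on the partial
likelihood with Efron (default) or Breslow tie handling.

The joint model couples the two through a shared random intercept:

    y_ij = x_ij' beta + b_i + eps_ij,      b_i ~ N(0, sigma_b^2)
    lambda_i(t) = lambda0 * exp(z_i' gamma + nu * b_i)

with a constant (exponential) baseline hazard and administrative censoring
at 60 days. The marginal likelihood integrates b_i out by adaptive
Gauss-Hermite quadrature (15 nodes, centered per subject on the
longitudinal posterior mode of b_i). The association coefficient nu
captures informative censoring: nu > 0 means subjects with higher latent
intercepts die faster. Confidence intervals for nu come from a
subject-level bootstrap.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import optimize, stats
from scipy.special import roots_hermite
from statsmodels.regression.mixed_linear_model import MixedLM


# ---------------------------------------------------------------------------
# linear mixed model
# ---------------------------------------------------------------------------

@dataclass
class LMMFit:
    fixed_effects: pd.Series
    se: pd.Series
    random_intercept_var: float
    residual_var: float
    log_likelihood: float
    converged: bool


def fit_lmm(
    data: pd.DataFrame,
    value: str,
    predictors: list[str],
    subject: str = "subject_id",
    reml: bool = False,
) -> LMMFit:
    """Random-patient-intercept linear mixed model (ML by default)."""
    cols = [value, subject, *predictors]
    frame = data[cols].dropna()
    if frame[subject].nunique() < 2:
        raise ValueError("need at least two subjects")
    exog = np.column_stack([np.ones(len(frame))] + [frame[p].to_numpy(float) for p in predictors])
    names = ["Intercept", *predictors]
    if np.linalg.matrix_rank(exog) < exog.shape[1]:
        raise ValueError("singular fixed-effects design")
    model = MixedLM(frame[value].to_numpy(float), exog, groups=frame[subject].to_numpy())
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=reml, method="lbfgs")
    return LMMFit(
        fixed_effects=pd.Series(fit.fe_params, index=names),
        se=pd.Series(np.asarray(fit.bse_fe), index=names),
        random_intercept_var=float(np.asarray(fit.cov_re)[0, 0]),
        residual_var=float(fit.scale),
        log_likelihood=float(fit.llf),
        converged=bool(fit.converged),
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier / log-rank
# ---------------------------------------------------------------------------

def kaplan_meier(
    records: pd.DataFrame, groups: str | None = None
) -> tuple[dict[str, pd.DataFrame], float | None]:
    """Product-limit survival curves per group plus the log-rank p-value.

    ``records`` needs columns ``time`` and ``event``. With a single group
    (``groups=None``) the log-rank p is None.
    """
    if len(records) == 0:
        raise ValueError("no survival records")
    curves: dict[str, pd.DataFrame] = {}
    if groups is None:
        labels = pd.Series(["all"] * len(records), index=records.index)
    else:
        labels = records[groups].astype(str)
    for g, sub in records.groupby(labels):
        if len(sub) == 0:
            raise ValueError(f"empty group {g!r}")
        km = KaplanMeierFitter()
        km.fit(sub["time"], event_observed=sub["event"])
        curve = km.survival_function_.reset_index()
        curve.columns = ["time", "survival"]
        curves[str(g)] = curve
    p = None
    if groups is not None and labels.nunique() > 1:
        res = multivariate_logrank_test(records["time"], labels, records["event"])
        p = float(res.p_value)
    return curves, p


# ---------------------------------------------------------------------------
# Cox proportional hazards (Newton on the partial likelihood)
# ---------------------------------------------------------------------------

@dataclass
class CoxFit:
    coefficients: pd.Series
    se: pd.Series
    hr: pd.Series
    ci_lower: pd.Series
    ci_upper: pd.Series
    p: pd.Series
    ties: str
    log_likelihood: float
    penalized: bool = False


def _cox_loglik(beta: np.ndarray, X: np.ndarray, time: np.ndarray, event: np.ndarray, ties: str):
    """Partial log-likelihood, gradient and Hessian with Efron/Breslow ties."""
    order = np.argsort(-time, kind="stable")  # decreasing time: cumulative risk sets
    Xs, ts, ds = X[order], time[order], event[order]
    eta = Xs @ beta
    w = np.exp(eta)
    cum_w = np.cumsum(w)
    cum_wx = np.cumsum(w[:, None] * Xs, axis=0)
    cum_wxx = np.cumsum(w[:, None, None] * (Xs[:, :, None] * Xs[:, None, :]), axis=0)
    ll, grad, hess = 0.0, np.zeros(X.shape[1]), np.zeros((X.shape[1], X.shape[1]))
    i = 0
    n = len(ts)
    while i < n:
        j = i
        while j < n and ts[j] == ts[i]:
            j += 1
        # risk set = all with time >= ts[i] = indices 0..j-1 in sorted order
        deaths = [k for k in range(i, j) if ds[k] == 1]
        d = len(deaths)
        if d > 0:
            R_w = cum_w[j - 1]
            R_wx = cum_wx[j - 1]
            R_wxx = cum_wxx[j - 1]
            D_w = w[deaths].sum()
            D_wx = (w[deaths, None] * Xs[deaths]).sum(axis=0)
            D_wxx = (w[deaths, None, None] * (Xs[deaths][:, :, None] * Xs[deaths][:, None, :])).sum(axis=0)
            ll += eta[deaths].sum()
            grad += Xs[deaths].sum(axis=0)
            for l in range(d):
                frac = l / d if ties == "efron" else 0.0
                sw = R_w - frac * D_w
                swx = R_wx - frac * D_wx
                swxx = R_wxx - frac * D_wxx
                ll -= np.log(sw)
                grad -= swx / sw
                hess -= swxx / sw - np.outer(swx, swx) / sw**2
        i = j
    return ll, grad, hess


def fit_cox(
    records: pd.DataFrame,
    covariates: list[str],
    ties: str = "efron",
    ridge: float = 0.0,
    max_iter: int = 50,
    tol: float = 1e-9,
) -> CoxFit:
    """Cox model by Newton iteration with step halving.

    Monotone (separated) likelihoods are detected by runaway coefficients
    and refit with a small ridge penalty, flagged ``penalized``.
    """
    if ties not in ("efron", "breslow"):
        raise ValueError("ties must be 'efron' or 'breslow'")
    frame = records.dropna(subset=["time", "event", *covariates])
    X = frame[covariates].to_numpy(float)
    if X.shape[0] == 0 or frame["event"].sum() == 0:
        raise ValueError("need at least one event")
    sds = X.std(axis=0)
    if np.any(sds == 0):
        bad = [c for c, s in zip(covariates, sds) if s == 0]
        raise ValueError(f"constant covariates: {bad}")
    time = frame["time"].to_numpy(float)
    event = frame["event"].to_numpy(int)
    beta = np.zeros(X.shape[1])
    penalized = ridge > 0
    lam = ridge

    def objective(b):
        ll, g, h = _cox_loglik(b, X, time, event, ties)
        if lam > 0:
            ll -= 0.5 * lam * b @ b
            g -= lam * b
            h -= lam * np.eye(len(b))
        return ll, g, h

    ll, grad, hess = objective(beta)
    for _ in range(max_iter):
        try:
            step = np.linalg.solve(-hess, grad)
        except np.linalg.LinAlgError:
            step = grad * 0.01
        # step halving keeps the concave partial likelihood non-decreasing
        scale = 1.0
        for _ in range(30):
            cand = beta + scale * step
            ll_new, g_new, h_new = objective(cand)
            if ll_new >= ll - 1e-12:
                break
            scale /= 2.0
        beta, ll_prev = cand, ll
        ll, grad, hess = ll_new, g_new, h_new
        if abs(ll - ll_prev) < tol * (1 + abs(ll)):
            break
    if np.max(np.abs(beta)) > 20 and lam == 0:
        warnings.warn(
            "monotone partial likelihood (separation) detected; refitting with ridge 0.1",
            stacklevel=2,
        )
        return fit_cox(records, covariates, ties=ties, ridge=0.1, max_iter=max_iter, tol=tol)
    cov = np.linalg.inv(-hess)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    idx = pd.Index(covariates)
    with np.errstate(over="ignore"):  # a huge SE legitimately gives an inf CI bound
        ci_lo = np.exp(beta - 1.959964 * se)
        ci_hi = np.exp(beta + 1.959964 * se)
    return CoxFit(
        coefficients=pd.Series(beta, index=idx),
        se=pd.Series(se, index=idx),
        hr=pd.Series(np.exp(beta), index=idx),
        ci_lower=pd.Series(ci_lo, index=idx),
        ci_upper=pd.Series(ci_hi, index=idx),
        p=pd.Series(p, index=idx),
        ties=ties,
        log_likelihood=float(ll),
        penalized=penalized,
    )


# ---------------------------------------------------------------------------
# shared-random-intercept joint model
# ---------------------------------------------------------------------------

@dataclass
class JointFit:
    beta: pd.Series  # longitudinal fixed effects
    sigma_b: float
    sigma_e: float
    gamma: pd.Series  # survival covariate log-hazard ratios
    log_lambda0: float
    nu: float
    nu_ci: tuple[float, float] | None
    log_likelihood: float
    converged: bool
    n_boot: int = 0
    n_boot_success: int = 0
    boot_nu: np.ndarray = field(default_factory=lambda: np.array([]))


class _JointData:
    """Pre-grouped arrays for fast marginal-likelihood evaluation."""

    def __init__(
        self,
        long_data: pd.DataFrame,
        value: str,
        predictors: list[str],
        surv_data: pd.DataFrame,
        surv_covariates: list[str],
        subject: str,
    ):
        surv = surv_data.set_index(subject)
        subjects = [s for s in surv.index if s in set(long_data[subject])]
        self.subjects = subjects
        self.y = []
        self.X = []
        grouped = dict(tuple(long_data.groupby(subject)))
        for s in subjects:
            sub = grouped[s]
            self.y.append(sub[value].to_numpy(float))
            self.X.append(
                np.column_stack([np.ones(len(sub))] + [sub[p].to_numpy(float) for p in predictors])
            )
        self.n_obs = np.array([len(v) for v in self.y])
        self.Z = np.column_stack(
            [surv.loc[subjects, c].to_numpy(float) for c in surv_covariates]
        ) if surv_covariates else np.zeros((len(subjects), 0))
        self.time = surv.loc[subjects, "time"].to_numpy(float)
        self.event = surv.loc[subjects, "event"].to_numpy(int)
        self.predictors = ["Intercept", *predictors]
        self.surv_covariates = list(surv_covariates)

    def subset(self, idx: np.ndarray) -> "_JointData":
        out = object.__new__(_JointData)
        out.subjects = [self.subjects[i] for i in idx]
        out.y = [self.y[i] for i in idx]
        out.X = [self.X[i] for i in idx]
        out.n_obs = self.n_obs[idx]
        out.Z = self.Z[idx]
        out.time = self.time[idx]
        out.event = self.event[idx]
        out.predictors = self.predictors
        out.surv_covariates = self.surv_covariates
        return out


def _joint_negloglik(params: np.ndarray, data: _JointData, nodes, weights, fix_nu=None) -> float:
    p_long = len(data.predictors)
    p_surv = data.Z.shape[1]
    beta = params[:p_long]
    log_sb, log_se = params[p_long], params[p_long + 1]
    gamma = params[p_long + 2 : p_long + 2 + p_surv]
    log_lam0 = params[p_long + 2 + p_surv]
    nu = fix_nu if fix_nu is not None else params[p_long + 3 + p_surv]
    sb, se = np.exp(log_sb), np.exp(log_se)
    if not np.isfinite(sb) or not np.isfinite(se) or sb > 1e3 or se > 1e3:
        return 1e10
    n = len(data.subjects)
    resid_sum = np.empty(n)
    resid_ss = np.empty(n)
    for i in range(n):
        r = data.y[i] - data.X[i] @ beta
        resid_sum[i] = r.sum()
        resid_ss[i] = r @ r
    m = data.n_obs
    # longitudinal-only posterior over b_i is Gaussian: center the quadrature there
    post_var = 1.0 / (1.0 / sb**2 + m / se**2)
    post_mean = post_var * resid_sum / se**2
    tau = np.sqrt(post_var)
    b = post_mean[:, None] + np.sqrt(2.0) * tau[:, None] * nodes[None, :]  # (n, Q)
    # log integrand: longitudinal density + survival density + prior, at each node
    ll_long = (
        -0.5 * m[:, None] * np.log(2 * np.pi * se**2)
        - 0.5 * (resid_ss[:, None] - 2 * b * resid_sum[:, None] + m[:, None] * b**2) / se**2
    )
    eta_surv = (data.Z @ gamma)[:, None] + nu * b
    log_haz = log_lam0 + eta_surv
    cum_haz = np.exp(log_lam0 + eta_surv) * data.time[:, None]
    ll_surv = data.event[:, None] * log_haz - cum_haz
    ll_prior = -0.5 * np.log(2 * np.pi * sb**2) - 0.5 * b**2 / sb**2
    log_int = ll_long + ll_surv + ll_prior
    # adaptive GH: integral = sum_q w_q * exp(u_q^2) * sqrt(2)*tau * f(b_q)
    log_w = np.log(weights)[None, :] + nodes[None, :] ** 2 + np.log(np.sqrt(2.0) * tau)[:, None]
    total = log_int + log_w
    mx = total.max(axis=1, keepdims=True)
    ll = (mx.squeeze(1) + np.log(np.exp(total - mx).sum(axis=1))).sum()
    return -ll if np.isfinite(ll) else 1e10


def fit_joint(
    long_data: pd.DataFrame,
    surv_data: pd.DataFrame,
    value: str,
    predictors: list[str],
    surv_covariates: list[str] = ("age",),
    subject: str = "subject_id",
    n_boot: int = 100,
    n_quad: int = 15,
    seed: int = 0,
    bootstrap: bool = True,
) -> JointFit:
    """Fit the shared-random-intercept joint model by marginal ML.

    ``long_data`` has one row per longitudinal measurement; ``surv_data``
    one row per subject with ``time``/``event``. The baseline hazard is
    constant (one-interval piecewise-exponential). The 95% CI for nu is the
    percentile interval of ``n_boot`` subject-level bootstrap refits.
    """
    surv_covariates = list(surv_covariates)
    data = _JointData(long_data, value, predictors, surv_data, surv_covariates, subject)
    if data.event.sum() == 0:
        raise ValueError("need at least one event")
    nodes, weights = roots_hermite(n_quad)

    # starting values from the separate submodels
    lmm = fit_lmm(long_data, value, predictors, subject=subject)
    events, total_time = data.event.sum(), data.time.sum()
    x0 = np.concatenate(
        [
            lmm.fixed_effects.to_numpy(),
            [0.5 * np.log(max(lmm.random_intercept_var, 1e-4)),
             0.5 * np.log(max(lmm.residual_var, 1e-4))],
            np.zeros(len(surv_covariates)),
            [np.log(max(events, 1) / total_time)],
            [0.0],
        ]
    )

    def solve(d: _JointData, start: np.ndarray):
        return optimize.minimize(
            _joint_negloglik, start, args=(d, nodes, weights),
            method="Nelder-Mead",
            options={"maxiter": 4000, "xatol": 1e-5, "fatol": 1e-7},
        )

    res = solve(data, x0)
    # polish with BFGS from the simplex solution
    res2 = optimize.minimize(
        _joint_negloglik, res.x, args=(data, nodes, weights), method="BFGS",
        options={"maxiter": 200},
    )
    if res2.fun <= res.fun:
        res = res2
    p_long = len(data.predictors)
    p_surv = data.Z.shape[1]
    params = res.x
    nu_hat = params[p_long + 3 + p_surv]

    nu_ci = None
    boot_nu = np.array([])
    n_success = 0
    if bootstrap and n_boot > 0:
        rng = np.random.default_rng(seed)
        draws = []
        n = len(data.subjects)
        for _ in range(n_boot):
            idx = rng.integers(0, n, size=n)
            d = data.subset(idx)
            if d.event.sum() == 0:
                continue
            try:
                r = optimize.minimize(
                    _joint_negloglik, params, args=(d, nodes, weights),
                    method="Nelder-Mead",
                    options={"maxiter": 2000, "xatol": 1e-4, "fatol": 1e-6},
                )
                if np.isfinite(r.fun):
                    draws.append(r.x[p_long + 3 + p_surv])
            except Exception:  # pragma: no cover - defensive
                continue
        boot_nu = np.asarray(draws)
        n_success = len(draws)
        if n_success >= max(10, n_boot // 2):
            nu_ci = (float(np.percentile(boot_nu, 2.5)), float(np.percentile(boot_nu, 97.5)))
        else:
            warnings.warn(
                f"only {n_success}/{n_boot} bootstrap refits succeeded; no CI reported",
                stacklevel=2,
            )
    return JointFit(
        beta=pd.Series(params[:p_long], index=data.predictors),
        sigma_b=float(np.exp(params[p_long])),
        sigma_e=float(np.exp(params[p_long + 1])),
        gamma=pd.Series(params[p_long + 2 : p_long + 2 + p_surv], index=surv_covariates),
        log_lambda0=float(params[p_long + 2 + p_surv]),
        nu=float(nu_hat),
        nu_ci=nu_ci,
        log_likelihood=float(-res.fun),
        converged=bool(res.success or res2.success),
        n_boot=n_boot if bootstrap else 0,
        n_boot_success=n_success,
        boot_nu=boot_nu,
    )


def joint_loglik(
    long_data: pd.DataFrame,
    surv_data: pd.DataFrame,
    value: str,
    predictors: list[str],
    surv_covariates: list[str],
    params: np.ndarray,
    subject: str = "subject_id",
    n_quad: int = 15,
    fix_nu: float | None = None,
) -> float:
    """Marginal joint log-likelihood at explicit parameter values."""
    data = _JointData(long_data, value, predictors, surv_data, list(surv_covariates), subject)
    nodes, weights = roots_hermite(n_quad)
    return -_joint_negloglik(np.asarray(params, float), data, nodes, weights, fix_nu=fix_nu)


# ---------------------------------------------------------------------------
# 2x2 association
# ---------------------------------------------------------------------------

@dataclass
class FisherResult:
    odds_ratio: float
    ci: tuple[float, float]
    p: float
    corrected: bool


def fisher_association(table) -> FisherResult:
    """Odds ratio with Woolf CI and two-sided Fisher exact p for a 2×2 table.

    The point estimate is the sample OR (a·d)/(b·c), with a Haldane-Anscombe
    0.5 correction applied to every cell when any cell is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or np.any(t < 0) or np.any(t != np.floor(t)):
        raise ValueError("need a 2×2 table of non-negative integers")
    a, b, c, d = t.ravel()
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    oddsr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    ci = (float(np.exp(np.log(oddsr) - 1.959964 * se)), float(np.exp(np.log(oddsr) + 1.959964 * se)))
    _, p = stats.fisher_exact(np.asarray(table, dtype=int), alternative="two-sided")
    return FisherResult(odds_ratio=float(oddsr), ci=ci, p=float(p), corrected=corrected)
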