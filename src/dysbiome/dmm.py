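"""Dirichlet-multinomial mixture (DMM) community typing.

A DMM models each 16S count vector as multinomial with composition drawn
from one of K Dirichlet components; mixture weights pi_k give the component
prevalences. Fitting is by EM: the E-step computes responsibilities
proportional to pi_k * DirMult(x_i | alpha_k), the M-step sets the weights
to mean responsibilities and updates each alpha_k with Minka's
responsibility-weighted fixed-point iteration (a monotone generalized
M-step, so the observed-data log-likelihood never decreases).

The number of components is chosen by a Laplace approximation to the log
model evidence, combined with a prevalence criterion that rejects any K
whose smallest hard-assigned cluster holds fewer than 10% of samples.
Fitted components are labeled High / Intermediate / Low Diversity by the
mean Shannon index of their member samples.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp, polygamma, psi
from sklearn.cluster import KMeans

from .containers import CountTable
from .ecology import clr_transform

_ALPHA_FLOOR = 1e-10
#: weak Gamma(shape, rate) prior on each Dirichlet parameter, used only in the
#: Laplace evidence: with a flat (improper) prior the evidence has no proper
#: normalization and barely penalizes extra components.
PRIOR_SHAPE = 0.1
PRIOR_RATE = 0.1


@dataclass
class DMMModel:
    K: int
    alpha: np.ndarray  # (K, T) positive Dirichlet parameters
    weights: np.ndarray  # (K,) simplex
    responsibilities: np.ndarray  # (n, K)
    log_likelihood: float
    laplace_log_evidence: float | None = None
    fit_info: dict = field(default_factory=dict)

    def hard_assignments(self) -> np.ndarray:
        """Component index per sample; responsibility ties go to the lowest index."""
        return np.argmax(self.responsibilities, axis=1)


@dataclass
class ClusterLabeling:
    labels: dict[int, str]  # component index -> High/Intermediate/Low
    mean_shannon: dict[int, float]

    def sample_labels(self, model: DMMModel) -> list[str]:
        return [self.labels[int(k)] for k in model.hard_assignments()]


def dirmult_logpmf(counts: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Dirichlet-multinomial log pmf for each sample under each component.

    ``counts`` is (n, T), ``alpha`` is (K, T); returns (n, K). Includes the
    multinomial coefficient, so values are true log probabilities.
    """
    counts = np.asarray(counts, dtype=float)
    alpha = np.atleast_2d(np.asarray(alpha, dtype=float))
    n_reads = counts.sum(axis=1)
    a0 = alpha.sum(axis=1)
    log_coef = gammaln(n_reads + 1) - gammaln(counts + 1).sum(axis=1)
    # (K, n, T) broadcast; desk-scale tables keep this small
    cross = gammaln(counts[None, :, :] + alpha[:, None, :]).sum(axis=2)
    out = (
        log_coef[None, :]
        + gammaln(a0)[:, None]
        - gammaln(n_reads[None, :] + a0[:, None])
        + cross
        - gammaln(alpha).sum(axis=1)[:, None]
    )
    return out.T


def _init_alpha(counts: np.ndarray, assign: np.ndarray, K: int, rng: np.random.Generator) -> np.ndarray:
    """Moment-style initialization: scaled mean composition of each seed cluster."""
    rel = counts / np.maximum(counts.sum(axis=1, keepdims=True), 1)
    T = counts.shape[1]
    alpha = np.empty((K, T))
    for k in range(K):
        members = rel[assign == k]
        mean = members.mean(axis=0) if len(members) else rel.mean(axis=0)
        alpha[k] = np.maximum(mean, 1e-4) * 20.0 * (1 + 0.05 * rng.random(T))
    return alpha


def _m_step_alpha(counts: np.ndarray, alpha_k: np.ndarray, resp_k: np.ndarray, inner: int = 3) -> np.ndarray:
    """Minka fixed-point update of one component's alpha with weights resp_k."""
    n_reads = counts.sum(axis=1)
    w = resp_k
    for _ in range(inner):
        a0 = alpha_k.sum()
        num = (w[:, None] * (psi(counts + alpha_k) - psi(alpha_k))).sum(axis=0)
        den = (w * (psi(n_reads + a0) - psi(a0))).sum()
        if den <= 0:
            break
        alpha_k = np.maximum(alpha_k * num / den, _ALPHA_FLOOR)
    return alpha_k


def _em(
    counts: np.ndarray,
    alpha: np.ndarray,
    weights: np.ndarray,
    tol: float,
    max_iter: int,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float, int, bool]:
    ll_prev = -np.inf
    converged = False
    for iteration in range(1, max_iter + 1):
        logp = dirmult_logpmf(counts, alpha) + np.log(weights)[None, :]
        ll = float(logsumexp(logp, axis=1).sum())
        # EM with a monotone generalized M-step: the likelihood may not drop
        assert ll >= ll_prev - 1e-8 * max(1.0, abs(ll_prev)), "EM log-likelihood decreased"
        if np.isfinite(ll_prev) and abs(ll - ll_prev) <= tol * max(1.0, abs(ll_prev)):
            ll_prev = ll
            converged = True
            break
        ll_prev = ll
        resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
        weights = np.maximum(resp.mean(axis=0), 1e-12)
        weights = weights / weights.sum()
        for k in range(alpha.shape[0]):
            alpha[k] = _m_step_alpha(counts, alpha[k], resp[:, k])
    logp = dirmult_logpmf(counts, alpha) + np.log(weights)[None, :]
    resp = np.exp(logp - logsumexp(logp, axis=1, keepdims=True))
    return alpha, weights, resp, ll_prev, iteration, converged


def fit_dmm(
    table: CountTable | np.ndarray,
    K: int,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> DMMModel:
    """Fit a K-component Dirichlet-multinomial mixture by EM.

    The first restart is seeded by k-means on CLR-transformed counts; the
    remaining restarts use random hard assignments. The best restart by
    final log-likelihood is returned.
    """
    counts = table.counts if isinstance(table, CountTable) else np.asarray(table)
    n = counts.shape[0]
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError(f"K={K} exceeds the number of samples ({n})")
    rng = np.random.default_rng(seed)
    best: tuple | None = None
    for init in range(max(1, n_init)):
        if init == 0 and K > 1:
            clr = clr_transform(counts)
            km = KMeans(n_clusters=K, n_init=3, random_state=int(rng.integers(2**31 - 1)))
            assign = km.fit_predict(clr)
        else:
            assign = rng.integers(K, size=n)
        alpha0 = _init_alpha(counts, assign, K, rng)
        w0 = np.bincount(assign, minlength=K).astype(float) + 1.0
        w0 /= w0.sum()
        result = _em(counts, alpha0.copy(), w0, tol, max_iter)
        if best is None or result[3] > best[3]:
            best = result
    alpha, weights, resp, ll, iters, converged = best
    if not converged:
        warnings.warn(f"DMM EM did not converge in {max_iter} iterations (K={K})", stacklevel=2)
    return DMMModel(
        K=K,
        alpha=alpha,
        weights=weights,
        responsibilities=resp,
        log_likelihood=ll,
        fit_info={"iterations": iters, "converged": converged, "n_init": n_init, "seed": seed},
    )


def _component_neg_hessian_logalpha(
    counts: np.ndarray, alpha_k: np.ndarray, resp_k: np.ndarray
) -> np.ndarray:
    """Hessian of the negative (responsibility-weighted) log-likelihood of one
    component with respect to lambda = log(alpha)."""
    n_reads = counts.sum(axis=1)
    a0 = alpha_k.sum()
    w = resp_k
    # gradient and Hessian w.r.t. alpha
    grad = (w[:, None] * (psi(a0) - psi(n_reads + a0)[:, None]
                          + psi(counts + alpha_k) - psi(alpha_k))).sum(axis=0)
    shared = (w * (polygamma(1, a0) - polygamma(1, n_reads + a0))).sum()
    diag_part = (w[:, None] * (polygamma(1, counts + alpha_k) - polygamma(1, alpha_k))).sum(axis=0)
    hess_alpha = np.full((len(alpha_k), len(alpha_k)), shared)
    hess_alpha[np.diag_indices_from(hess_alpha)] += diag_part
    a = alpha_k
    hess_lambda = hess_alpha * np.outer(a, a)
    hess_lambda[np.diag_indices_from(hess_lambda)] += a * grad
    # gamma-prior curvature in log space: d²/dλ² (rate·e^λ) = rate·alpha
    neg_hess = -hess_lambda
    neg_hess[np.diag_indices_from(neg_hess)] += PRIOR_RATE * a
    return neg_hess


def _log_prior(alpha: np.ndarray, K: int) -> float:
    """Log prior density at the mode, in the log-alpha parameterization.

    Independent Gamma(PRIOR_SHAPE, PRIOR_RATE) on each alpha (Jacobian of the
    log transform included) and a uniform Dirichlet on the mixture weights
    (density Gamma(K) on the simplex).
    """
    a = np.ravel(alpha)
    per_param = (
        PRIOR_SHAPE * np.log(PRIOR_RATE)
        - gammaln(PRIOR_SHAPE)
        + PRIOR_SHAPE * np.log(a)
        - PRIOR_RATE * a
    )
    return float(per_param.sum() + gammaln(K))


def _weights_neg_hessian(counts: np.ndarray, model: DMMModel, eps: float = 1e-5) -> np.ndarray:
    """Numerical Hessian of the negative mixture log-likelihood w.r.t. the
    first K-1 mixture weights (the last weight absorbs the constraint)."""
    K = model.K
    base_logp = dirmult_logpmf(counts, model.alpha)

    def negll(free: np.ndarray) -> float:
        w = np.concatenate([free, [1.0 - free.sum()]])
        if np.any(w <= 0):
            return np.inf
        return -float(logsumexp(base_logp + np.log(w)[None, :], axis=1).sum())

    free0 = model.weights[: K - 1].copy()
    m = K - 1
    hess = np.empty((m, m))
    for i in range(m):
        for j in range(i, m):
            steps = []
            for si, sj in ((1, 1), (1, -1), (-1, 1), (-1, -1)):
                x = free0.copy()
                x[i] += si * eps
                x[j] += sj * eps
                steps.append(negll(x))
            hess[i, j] = hess[j, i] = (steps[0] - steps[1] - steps[2] + steps[3]) / (4 * eps**2)
    return hess


def laplace_log_evidence(model: DMMModel, table: CountTable | np.ndarray) -> float:
    """Laplace approximation to the log model evidence at the fitted mode.

    log evidence ~= log posterior at the mode + (d/2)·ln(2π) − 0.5·ln det H,
    with H the Hessian of the negative log posterior and d = K·T + (K−1)
    free parameters. The posterior combines the mixture likelihood with a
    weak Gamma(0.1, 0.1) prior per Dirichlet parameter (log-alpha scale) and
    a uniform prior on the weights. Dirichlet blocks are analytic
    (responsibility-weighted — exact at K=1); the mixture-weight block is
    computed numerically; cross-component curvature is neglected
    (block-diagonal approximation).
    """
    counts = (table.counts if isinstance(table, CountTable) else np.asarray(table)).astype(float)
    K, T = model.alpha.shape
    d = K * T + (K - 1)
    logdet = 0.0
    for k in range(K):
        block = _component_neg_hessian_logalpha(counts, model.alpha[k], model.responsibilities[:, k])
        sign, ld = np.linalg.slogdet(block)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                f"singular or indefinite Hessian for component {k}; the model is "
                "likely overparameterized — reduce K"
            )
        logdet += ld
    if K > 1:
        wblock = _weights_neg_hessian(counts, model)
        sign, ld = np.linalg.slogdet(wblock)
        if sign <= 0:
            raise np.linalg.LinAlgError(
                "singular weight-block Hessian; a component may be empty — reduce K"
            )
        logdet += ld
    log_post = model.log_likelihood + _log_prior(model.alpha, K)
    return float(log_post + 0.5 * d * np.log(2 * np.pi) - 0.5 * logdet)


def select_k(
    table: CountTable | np.ndarray,
    K_max: int = 5,
    prevalence_min: float = 0.10,
    n_init: int = 5,
    tol: float = 1e-6,
    max_iter: int = 500,
    seed: int = 0,
) -> DMMModel:
    """Fit K = 1..K_max and pick the best Laplace evidence among K values
    whose smallest hard-assigned cluster holds >= ``prevalence_min`` of
    samples. Falls back to K=1 (with a warning) if every K is discarded."""
    counts = table.counts if isinstance(table, CountTable) else np.asarray(table)
    n = counts.shape[0]
    seeds = np.random.SeedSequence(seed).spawn(K_max)
    candidates: list[DMMModel] = []
    fallback: DMMModel | None = None
    for K in range(1, K_max + 1):
        k_seed = int(seeds[K - 1].generate_state(1)[0] % (2**31 - 1))
        model = fit_dmm(table, K, n_init=n_init, tol=tol, max_iter=max_iter, seed=k_seed)
        sizes = np.bincount(model.hard_assignments(), minlength=K)
        if K == 1:
            fallback = model
        if sizes.min() < prevalence_min * n:
            continue
        try:
            model.laplace_log_evidence = laplace_log_evidence(model, counts)
        except np.linalg.LinAlgError:
            continue
        candidates.append(model)
    if not candidates:
        warnings.warn(
            "all K discarded by the prevalence criterion or singular evidence; "
            "falling back to K=1",
            stacklevel=2,
        )
        fallback.laplace_log_evidence = laplace_log_evidence(fallback, counts)
        return fallback
    return max(candidates, key=lambda m: m.laplace_log_evidence)


def label_clusters(model: DMMModel, shannon: np.ndarray) -> ClusterLabeling:
    """Name components High / Intermediate / Low by descending mean member
    Shannon index. For K other than 3 the middle ranks are Intermediate-i."""
    shannon = np.asarray(shannon, dtype=float)
    assign = model.hard_assignments()
    means: dict[int, float] = {}
    for k in range(model.K):
        members = shannon[assign == k]
        means[k] = float(members.mean()) if len(members) else -np.inf
    vals = np.array([means[k] for k in range(model.K)])
    if len(np.unique(np.round(vals, 12))) < model.K:
        warnings.warn("tied mean Shannon between components; breaking by index", stacklevel=2)
    order = sorted(range(model.K), key=lambda k: (-means[k], k))
    if model.K == 1:
        names = ["High"]
    elif model.K == 2:
        names = ["High", "Low"]
    elif model.K == 3:
        names = ["High", "Intermediate", "Low"]
    else:
        names = ["High"] + [f"Intermediate-{i}" for i in range(1, model.K - 1)] + ["Low"]
    labels = {comp: names[rank] for rank, comp in enumerate(order)}
    return ClusterLabeling(labels=labels, mean_shannon=means)
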