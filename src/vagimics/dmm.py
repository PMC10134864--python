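"""Dirichlet multinomial mixture (DMM) community typing.

Samples are modelled as draws from a K-component mixture of
Dirichlet-multinomial distributions: component k has a Dirichlet parameter
vector alpha_k over OTUs, and a sample's counts x (depth n) have marginal

    DM(x; alpha) = n! / prod_j x_j!
                   * Gamma(A) / Gamma(n + A)
                   * prod_j Gamma(x_j + alpha_j) / Gamma(alpha_j),   A = sum alpha.

Fitting is by MAP EM under a weak Gamma prior on the alphas: the E-step
computes posterior responsibilities z_sk ~ pi_k DM(x_s; alpha_k); the M-step
updates the weights and maximizes each component's responsibility-weighted
DM log posterior over log(alpha) by L-BFGS. The number of community types is
chosen by minimizing a Laplace approximation to the negative log model
evidence, and each sample is assigned to the component with maximum
posterior probability.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import gammaln, logsumexp, polygamma, psi

from .otutable import OtuTable

__all__ = [
    "dm_log_likelihood",
    "fit_dmm",
    "select_k",
    "assign_types",
    "rank_contributions",
    "DmmModel",
    "CommunityTypeAssignment",
    "OtuContributionRanking",
]

_ALPHA_FLOOR = 1e-6
_HESS_FLOOR = 1e-8


@dataclass
class DmmModel:
    """A fitted Dirichlet multinomial mixture."""

    K: int
    alpha: np.ndarray  # (K, n_otus), all positive
    pi: np.ndarray  # (K,), sums to 1
    posterior: np.ndarray  # (n_samples, K), rows sum to 1
    log_likelihood: float
    neg_log_evidence_laplace: float
    converged: bool
    n_iterations: int
    sample_ids: list[str] = field(default_factory=list)
    otu_ids: list[str] = field(default_factory=list)
    log_likelihood_trace: list[float] = field(default_factory=list)

    @property
    def component_mean_proportions(self) -> np.ndarray:
        """Per-component expected composition alpha_k / sum(alpha_k)."""
        return self.alpha / self.alpha.sum(axis=1, keepdims=True)


@dataclass
class CommunityTypeAssignment:
    sample_ids: list[str]
    labels: list[int]  # 1-based component index
    max_posterior: np.ndarray


@dataclass
class OtuContributionRanking:
    """Per-OTU contribution to the two-type contrast, descending."""

    otu_ids: list[str]  # in descending contribution order
    scores: np.ndarray  # normalized to sum 1 (or all 0 if degenerate)
    cumulative: np.ndarray
    top_set: list[str]
    threshold: float


def dm_log_likelihood(counts, alpha) -> float:
    """Log Dirichlet-multinomial pmf of one sample (multinomial coefficient included)."""
    x = np.asarray(counts, dtype=float)
    a = np.asarray(alpha, dtype=float)
    if np.any(a <= 0):
        raise ValueError("alpha must be positive elementwise")
    if x.shape != a.shape:
        raise ValueError("counts and alpha must have the same length")
    n = x.sum()
    a0 = a.sum()
    log_coef = gammaln(n + 1) - gammaln(x + 1).sum()
    return float(
        log_coef
        + gammaln(a0)
        - gammaln(n + a0)
        + np.sum(gammaln(x + a) - gammaln(a))
    )


def _dm_loglik_components(X: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """Matrix of log DM(x_s; alpha_k) without the multinomial coefficient."""
    n = X.sum(axis=1)
    out = np.empty((X.shape[0], alpha.shape[0]))
    for k in range(alpha.shape[0]):
        a = alpha[k]
        a0 = a.sum()
        out[:, k] = (
            gammaln(a0)
            - gammaln(n + a0)
            + np.sum(gammaln(X + a[None, :]) - gammaln(a)[None, :], axis=1)
        )
    return out


# Weak Gamma(shape=_PRIOR_NU, rate=_PRIOR_ETA) prior on every alpha: mean 1
# with high variance. It regularizes empty components (no alpha collapses to
# 0 or diverges to infinite precision) and enters the Laplace evidence.
_PRIOR_NU = 0.1
_PRIOR_ETA = 0.1


_PRIOR_LOG_NORM = _PRIOR_NU * np.log(_PRIOR_ETA) - float(gammaln(_PRIOR_NU))


def _log_prior(alpha: np.ndarray) -> float:
    """Log Gamma prior density of one component's alphas, in log-alpha space
    (Jacobian included). The normalization constant matters: it does not
    cancel across models with different K and is what makes extra
    weakly-identified components pay for their prior volume."""
    return float(
        np.sum(_PRIOR_NU * np.log(alpha) - _PRIOR_ETA * alpha + _PRIOR_LOG_NORM)
    )


def _map_update(X: np.ndarray, w: np.ndarray, alpha: np.ndarray, maxiter: int = 15) -> np.ndarray:
    """M-step: maximize the responsibility-weighted DM log-likelihood plus
    the log prior over log(alpha), warm-started L-BFGS."""
    n = X.sum(axis=1)

    def objective(lam: np.ndarray) -> tuple[float, np.ndarray]:
        a = np.exp(np.clip(lam, -30.0, 30.0))
        a0 = a.sum()
        ll = float(
            w @ (gammaln(a0) - gammaln(n + a0))
            + w @ np.sum(gammaln(X + a[None, :]) - gammaln(a)[None, :], axis=1)
        )
        f = -(ll + _log_prior(a))
        grad_a = w @ (psi(X + a[None, :]) - psi(a)[None, :]) + float(
            w @ (psi(a0) - psi(n + a0))
        )
        grad_lam = -(a * grad_a + _PRIOR_NU - _PRIOR_ETA * a)
        return f, grad_lam

    res = minimize(
        objective,
        np.log(np.maximum(alpha, _ALPHA_FLOOR)),
        jac=True,
        method="L-BFGS-B",
        options={"maxiter": maxiter},
    )
    return np.maximum(np.exp(np.clip(res.x, -30.0, 30.0)), _ALPHA_FLOOR)


def _laplace_neg_log_evidence(
    X: np.ndarray, alpha: np.ndarray, pi: np.ndarray, z: np.ndarray, log_lik: float
) -> float:
    """Laplace approximation to -log model evidence at the MAP.

    -log Z ~ -(log L + log prior) - (d/2) log 2pi + (1/2) log det H with
    d = K*n_otus + (K-1) free parameters and H the Hessian of the negative
    log posterior in log-alpha space. Per component the Hessian has a
    diagonal-plus-rank-one structure (the sum-alpha terms couple all
    coordinates), handled with the matrix determinant lemma; a diagonal
    fallback with clamped curvatures guards indefinite corner cases.
    """
    K, J = alpha.shape
    n = X.sum(axis=1)
    d = K * J + (K - 1)
    log_det = 0.0
    log_prior_total = 0.0
    for k in range(K):
        a = alpha[k]
        a0 = a.sum()
        w = z[:, k]
        log_prior_total += _log_prior(a)
        grad_a = w @ (psi(X + a[None, :]) - psi(a)[None, :]) + float(
            w @ (psi(a0) - psi(n + a0))
        )
        diag_curv = -(w @ (polygamma(1, X + a[None, :]) - polygamma(1, a)[None, :]))
        c_sum = float(w @ (polygamma(1, a0) - polygamma(1, n + a0)))  # > 0
        # H_lambda = diag(D) - c_sum * outer(a, a), with
        # D_j = a_j^2 d_j + a_j g_j + eta a_j  (prior curvature included).
        D = a**2 * diag_curv - a * grad_a + _PRIOR_ETA * a
        D = np.maximum(D, _HESS_FLOOR)
        correction = 1.0 - c_sum * float(np.sum(a**2 / D))
        if correction > 1e-8:
            log_det += float(np.sum(np.log(D)) + np.log(correction))
        else:
            log_det += float(np.sum(np.log(D)))
    # Mixture-weight block (logit space, observed-information approximation).
    n_samples = X.shape[0]
    if K > 1:
        h_pi = np.maximum(n_samples * pi[:-1] * (1 - pi[:-1]), _HESS_FLOOR)
        log_det += np.sum(np.log(h_pi))
    return float(
        -(log_lik + log_prior_total) - 0.5 * d * np.log(2 * np.pi) + 0.5 * log_det
    )


def fit_dmm(
    counts: OtuTable | np.ndarray,
    K: int,
    seed: int = 0,
    max_iter: int = 200,
    tol: float = 1e-7,
    warn_unequal_depth: bool = True,
) -> DmmModel:
    """Fit a K-component Dirichlet multinomial mixture by EM.

    Inputs are ideally rarefied counts (a warning is issued otherwise).
    Initialization seeds components from randomly chosen samples; use
    :func:`select_k` for multiple restarts and evidence-based model choice.
    Non-convergence within ``max_iter`` flags the result, it does not raise.
    """
    if isinstance(counts, OtuTable):
        X = counts.counts.astype(float)
        sample_ids = list(counts.sample_ids)
        otu_ids = list(counts.otu_ids)
    else:
        X = np.asarray(counts, dtype=float)
        sample_ids = [f"s{i + 1}" for i in range(X.shape[0])]
        otu_ids = [f"otu{j + 1}" for j in range(X.shape[1])]
    n_samples, n_otus = X.shape
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n_samples:
        raise ValueError(f"K={K} exceeds the number of samples ({n_samples})")
    depths = X.sum(axis=1)
    if warn_unequal_depth and depths.max() > 1.5 * depths.min():
        # Mild inequality is expected after restricting rarefied counts to a
        # top-OTU subset; warn only on clearly unrarefied input.
        warnings.warn("strongly unequal sample depths; rarefy before DMM fitting", stacklevel=2)

    rng = np.random.default_rng(seed)
    rel = X / depths[:, None]

    # Seed each component's alpha from one sample's smoothed composition.
    seeds = rng.choice(n_samples, size=K, replace=False)
    precision = 50.0
    alpha = np.maximum(0.5 * (rel[seeds] + 1.0 / n_otus) * precision, _ALPHA_FLOOR)
    pi = np.full(K, 1.0 / K)

    log_coef = gammaln(depths + 1) - gammaln(X + 1).sum(axis=1)
    trace: list[float] = []
    ll = -np.inf
    obj = -np.inf
    converged = False
    it = 0
    z = np.full((n_samples, K), 1.0 / K)
    for it in range(1, max_iter + 1):
        comp = _dm_loglik_components(X, alpha)  # (S, K)
        joint = comp + np.log(pi)[None, :]
        norm = logsumexp(joint, axis=1)
        z = np.exp(joint - norm[:, None])
        ll = float(np.sum(norm + log_coef))
        new_obj = ll + sum(_log_prior(alpha[k]) for k in range(K))
        trace.append(new_obj)
        if np.isfinite(obj) and abs(new_obj - obj) <= tol * abs(obj):
            obj = new_obj
            converged = True
            break
        obj = new_obj
        # M-step (MAP under the weak Gamma prior)
        pi = np.maximum(z.mean(axis=0), 1e-12)
        pi /= pi.sum()
        for k in range(K):
            alpha[k] = _map_update(X, z[:, k], alpha[k])

    nle = _laplace_neg_log_evidence(X, alpha, pi, z, ll)
    return DmmModel(
        K=K,
        alpha=alpha,
        pi=pi,
        posterior=z,
        log_likelihood=ll,
        neg_log_evidence_laplace=nle,
        converged=converged,
        n_iterations=it,
        sample_ids=sample_ids,
        otu_ids=otu_ids,
        log_likelihood_trace=trace,
    )


def select_k(
    counts: OtuTable | np.ndarray,
    k_candidates: list[int],
    seed: int = 0,
    n_restarts: int = 5,
    **fit_kwargs,
) -> tuple[int, list[tuple[int, float]], dict[int, DmmModel]]:
    """Fit each candidate K (with restarts) and pick the minimal-evidence one.

    Returns ``(best_k, [(K, neg_log_evidence), ...], {K: best model})``.
    """
    if not k_candidates:
        raise ValueError("k_candidates must be non-empty")
    rng = np.random.default_rng(seed)
    evidence: list[tuple[int, float]] = []
    models: dict[int, DmmModel] = {}
    for K in k_candidates:
        best = None
        for _ in range(max(1, n_restarts)):
            sub = int(rng.integers(0, 2**31 - 1))
            model = fit_dmm(counts, K, seed=sub, **fit_kwargs)
            if best is None or model.neg_log_evidence_laplace < best.neg_log_evidence_laplace:
                best = model
        models[K] = best
        evidence.append((K, best.neg_log_evidence_laplace))
    best_k = min(evidence, key=lambda kv: kv[1])[0]
    return best_k, evidence, models


def assign_types(model: DmmModel) -> CommunityTypeAssignment:
    """Maximum-posterior community type per sample (ties -> lowest index)."""
    labels = np.argmax(model.posterior, axis=1)  # argmax takes lowest on ties
    return CommunityTypeAssignment(
        sample_ids=list(model.sample_ids),
        labels=[int(l) + 1 for l in labels],
        max_posterior=model.posterior[np.arange(model.posterior.shape[0]), labels],
    )


def rank_contributions(
    model: DmmModel, cumulative_threshold: float = 0.5
) -> OtuContributionRanking:
    """Rank OTUs by how much they discriminate the two community types.

    The contribution of OTU j is the absolute difference of the fitted
    component mean proportions |alpha_j1/A1 - alpha_j2/A2|, normalized to
    sum 1. Also returns the smallest top set whose cumulative contribution
    exceeds ``cumulative_threshold`` (the study's headline set is the top
    OTUs explaining over half of the two-type contrast).
    """
    if model.K != 2:
        raise ValueError("contribution ranking is defined for K=2 models")
    means = model.component_mean_proportions
    raw = np.abs(means[0] - means[1])
    total = raw.sum()
    if total <= 0:
        warnings.warn("identical components: all contributions are zero", stacklevel=2)
        order = sorted(range(len(model.otu_ids)), key=lambda j: model.otu_ids[j])
        zeros = np.zeros(len(order))
        return OtuContributionRanking(
            otu_ids=[model.otu_ids[j] for j in order],
            scores=zeros,
            cumulative=zeros.copy(),
            top_set=[],
            threshold=cumulative_threshold,
        )
    scores = raw / total
    order = sorted(
        range(len(model.otu_ids)), key=lambda j: (-scores[j], model.otu_ids[j])
    )
    sorted_scores = scores[order]
    cumulative = np.cumsum(sorted_scores)
    n_top = int(np.searchsorted(cumulative, cumulative_threshold, side="right")) + 1
    n_top = min(n_top, len(order))
    ids = [model.otu_ids[j] for j in order]
    return OtuContributionRanking(
        otu_ids=ids,
        scores=sorted_scores,
        cumulative=cumulative,
        top_set=ids[:n_top],
        threshold=cumulative_threshold,
    )
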