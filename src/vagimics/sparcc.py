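"""SparCC compositional correlations and cooccurrence network construction.

Relative abundances carry a unit-sum constraint, so ordinary correlations
between taxa are badly biased. SparCC infers correlations between the latent
(basis) absolute abundances from log-ratio variances

    t_ij = Var_s[ log(f_i / f_j) ] = w_i + w_j - 2 rho_ij sqrt(w_i w_j),

using the sparsity assumption that most true correlations are near zero to
solve a linear system for the basis variances w, then inverting for rho.
Strongly correlated pairs (which violate the sparsity approximation) are
iteratively excluded from the system. Fractions are resampled from a
per-sample Dirichlet posterior over several inner iterations and the median
rho is reported. Significance comes from an empirical null in which every
OTU's counts are permuted independently across samples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .otutable import OtuTable

__all__ = [
    "sparcc",
    "sparcc_bootstrap_p",
    "build_network",
    "SparccResult",
    "EdgeList",
]


@dataclass
class SparccResult:
    otu_ids: list[str]
    rho: np.ndarray  # symmetric, unit diagonal, clamped to [-1, 1]
    omega: np.ndarray  # basis variances (median over inner iterations)
    excluded_pairs: list[tuple[str, str]] = field(default_factory=list)


@dataclass
class EdgeList:
    """Thresholded cooccurrence edges (i < j) with per-node degrees."""

    edges: list[dict]  # keys: source, target, rho, p, sign
    degrees: dict[str, int]
    r_threshold: float
    p_threshold: float


def _log_ratio_variance_matrix(frac: np.ndarray) -> np.ndarray:
    logf = np.log(frac)
    cov = np.cov(logf, rowvar=False)
    var = np.diag(cov)
    return var[:, None] + var[None, :] - 2.0 * cov


def _basis_solve(T: np.ndarray, excluded: set[tuple[int, int]]) -> np.ndarray:
    p = T.shape[0]
    M = np.ones((p, p)) + np.diag(np.full(p, float(p - 2)))
    t = T.copy()
    for i, j in excluded:
        M[i, j] = M[j, i] = 0.0
        M[i, i] -= 1.0
        M[j, j] -= 1.0
        t[i, j] = t[j, i] = 0.0
    t_vec = t.sum(axis=1)
    try:
        omega = np.linalg.solve(M, t_vec)
    except np.linalg.LinAlgError:
        # Heavy exclusion on few OTUs can make the system singular.
        omega = np.linalg.lstsq(M, t_vec, rcond=None)[0]
    return np.maximum(omega, 1e-12)


def _rho_from(T: np.ndarray, omega: np.ndarray) -> np.ndarray:
    denom = 2.0 * np.sqrt(np.outer(omega, omega))
    rho = (omega[:, None] + omega[None, :] - T) / denom
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -1.0, 1.0)


def sparcc(
    counts: OtuTable | np.ndarray,
    inner_iterations: int = 20,
    exclusion_threshold: float = 0.1,
    max_exclusions: int = 10,
    seed: int = 0,
    pseudocount: float = 1.0,
) -> SparccResult:
    """Estimate basis correlations between OTUs from compositional counts.

    ``exclusion_threshold`` is the |rho| above which the strongest pair is
    iteratively removed from the basis-variance system (up to
    ``max_exclusions`` pairs); the final rho is the elementwise median over
    ``inner_iterations`` Dirichlet resamplings of the fractions.
    """
    if isinstance(counts, OtuTable):
        X = counts.counts.astype(float)
        otu_ids = list(counts.otu_ids)
    else:
        X = np.asarray(counts, dtype=float)
        otu_ids = [f"otu{j + 1}" for j in range(X.shape[1])]
    n, p = X.shape
    if p < 4:
        raise ValueError(
            "SparCC needs at least 4 OTUs: the basis-variance system is not "
            "identifiable below that"
        )
    if n < 4:
        raise ValueError("SparCC needs at least 4 samples")
    rng = np.random.default_rng(seed)
    rhos = np.empty((inner_iterations, p, p))
    omegas = np.empty((inner_iterations, p))
    excluded_named: set[tuple[str, str]] = set()
    for it in range(inner_iterations):
        # Per-sample posterior draw of the underlying fractions.
        frac = rng.gamma(X + pseudocount)
        frac /= frac.sum(axis=1, keepdims=True)
        T = _log_ratio_variance_matrix(frac)
        excluded: set[tuple[int, int]] = set()
        omega = _basis_solve(T, excluded)
        rho = _rho_from(T, omega)
        for _ in range(max_exclusions):
            masked = np.abs(rho.copy())
            np.fill_diagonal(masked, 0.0)
            for i, j in excluded:
                masked[i, j] = masked[j, i] = 0.0
            i, j = np.unravel_index(int(np.argmax(masked)), masked.shape)
            if masked[i, j] <= exclusion_threshold:
                break
            excluded.add((min(i, j), max(i, j)))
            omega = _basis_solve(T, excluded)
            rho = _rho_from(T, omega)
        rhos[it] = rho
        omegas[it] = omega
        for i, j in excluded:
            excluded_named.add((otu_ids[i], otu_ids[j]))
    rho_med = np.median(rhos, axis=0)
    rho_med = np.clip((rho_med + rho_med.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho_med, 1.0)
    return SparccResult(
        otu_ids=otu_ids,
        rho=rho_med,
        omega=np.median(omegas, axis=0),
        excluded_pairs=sorted(excluded_named),
    )


def sparcc_bootstrap_p(
    counts: OtuTable | np.ndarray,
    n_bootstrap: int = 100,
    seed: int = 0,
    observed: SparccResult | None = None,
    **sparcc_settings,
) -> np.ndarray:
    """Empirical two-sided p-values from a permutation null.

    Each bootstrap shuffles every OTU's counts independently across samples
    (destroying all pairwise association while preserving marginals) and
    recomputes SparCC; p_ij = (#{|rho_null| >= |rho_obs|} + 1)/(B + 1).
    """
    if n_bootstrap < 1:
        raise ValueError("n_bootstrap must be >= 1")
    X = counts.counts if isinstance(counts, OtuTable) else np.asarray(counts)
    X = X.astype(float)
    rng = np.random.default_rng(seed)
    if observed is None:
        observed = sparcc(X, seed=int(rng.integers(2**31 - 1)), **sparcc_settings)
    abs_obs = np.abs(observed.rho)
    n, p = X.shape
    exceed = np.zeros((p, p))
    for _ in range(n_bootstrap):
        perm = np.empty_like(X)
        for j in range(p):
            perm[:, j] = X[rng.permutation(n), j]
        null = sparcc(perm, seed=int(rng.integers(2**31 - 1)), **sparcc_settings)
        exceed += np.abs(null.rho) >= abs_obs
    pmat = (exceed + 1.0) / (n_bootstrap + 1.0)
    np.fill_diagonal(pmat, 1.0)
    return pmat


def build_network(
    result: SparccResult,
    p: np.ndarray,
    r_threshold: float = 0.3,
    p_threshold: float = 0.05,
) -> EdgeList:
    """Edges where |rho| exceeds ``r_threshold`` and p is below ``p_threshold``.

    The sign of rho is recorded so positive (cooccurrence) and negative
    (exclusion) relationships can be drawn differently.
    """
    ids = result.otu_ids
    k = len(ids)
    if p.shape != (k, k):
        raise ValueError("p matrix shape does not match the rho matrix")
    edges = []
    degrees = {o: 0 for o in ids}
    for i in range(k):
        for j in range(i + 1, k):
            rho = float(result.rho[i, j])
            if abs(rho) > r_threshold and p[i, j] < p_threshold:
                edges.append(
                    {
                        "source": ids[i],
                        "target": ids[j],
                        "rho": rho,
                        "p": float(p[i, j]),
                        "sign": "positive" if rho > 0 else "negative",
                    }
                )
                degrees[ids[i]] += 1
                degrees[ids[j]] += 1
    return EdgeList(edges=edges, degrees=degrees, r_threshold=r_threshold, p_threshold=p_threshold)
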