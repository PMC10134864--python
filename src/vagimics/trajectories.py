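"""Soft clustering of OTU abundance trajectories across the 7 ordered stages.

Each OTU is reduced to its per-stage mean relative abundance, row-standardized
to mean 0 / SD 1 so that only the shape of the trajectory matters, and the
standardized profiles are grouped by fuzzy c-means (the Mfuzz-style soft
clustering used for short time courses). Membership values quantify how well
an OTU follows each cluster's trajectory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .otutable import STAGES, RelativeAbundanceTable

__all__ = [
    "stage_profiles",
    "fuzzy_cmeans",
    "assign_trajectory",
    "StageProfileMatrix",
    "TrajectoryModel",
]


@dataclass
class StageProfileMatrix:
    """Row-standardized per-stage mean abundance profiles (OTUs x stages)."""

    otu_ids: list[str]
    stages: tuple[str, ...]
    values: np.ndarray
    dropped: list[str] = field(default_factory=list)  # zero-variance OTUs


@dataclass
class TrajectoryModel:
    c: int
    m: float
    centers: np.ndarray  # (c, n_stages)
    membership: np.ndarray  # (n_otus, c), rows sum to 1
    objective: float
    n_iterations: int
    converged: bool
    otu_ids: list[str] = field(default_factory=list)
    objective_trace: list[float] = field(default_factory=list)


def stage_profiles(
    table: RelativeAbundanceTable, otu_subset: list[str] | None = None
) -> StageProfileMatrix:
    """Per-OTU per-stage mean abundance, z-standardized across stages.

    OTUs whose stage means are constant carry no trajectory information and
    are dropped (recorded in ``dropped``).
    """
    if otu_subset is None:
        otu_subset = list(table.otu_ids)
    if not otu_subset:
        raise ValueError("empty OTU subset")
    present = sorted(set(table.stages), key=lambda s: STAGES.index(s))
    col = {o: j for j, o in enumerate(table.otu_ids)}
    missing = [o for o in otu_subset if o not in col]
    if missing:
        raise ValueError(f"OTUs not in table: {missing[:5]}")
    stage_means = np.empty((len(otu_subset), len(present)))
    for si, stage in enumerate(present):
        idx = [i for i, s in enumerate(table.stages) if s == stage]
        sub = table.values[idx, :]
        for oi, otu in enumerate(otu_subset):
            stage_means[oi, si] = sub[:, col[otu]].mean()
    sd = stage_means.std(axis=1, ddof=0)
    keep = sd > 0
    dropped = [o for o, k in zip(otu_subset, keep) if not k]
    vals = stage_means[keep]
    vals = (vals - vals.mean(axis=1, keepdims=True)) / sd[keep][:, None]
    return StageProfileMatrix(
        otu_ids=[o for o, k in zip(otu_subset, keep) if k],
        stages=tuple(present),
        values=vals,
        dropped=dropped,
    )


def fuzzy_cmeans(
    profiles: StageProfileMatrix | np.ndarray,
    c: int,
    m: float = 1.25,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 300,
) -> TrajectoryModel:
    """Standard fuzzy c-means on trajectory profiles.

    Memberships follow u_ic = 1 / sum_j (d_ic/d_ij)^(2/(m-1)) with Euclidean
    distances; centers are the u^m-weighted means. Iteration stops when the
    maximum membership change drops below ``tol``. A profile coinciding with
    a center receives hard membership for that cluster. Deterministic given
    ``seed`` (centers are initialized from randomly chosen profiles).
    """
    if isinstance(profiles, StageProfileMatrix):
        X = profiles.values
        otu_ids = list(profiles.otu_ids)
    else:
        X = np.asarray(profiles, dtype=float)
        otu_ids = [f"row{i + 1}" for i in range(X.shape[0])]
    n = X.shape[0]
    if c < 2:
        raise ValueError("c must be >= 2")
    if m <= 1:
        raise ValueError("fuzzifier m must be > 1")
    if c >= n:
        raise ValueError(f"c={c} must be smaller than the number of profiles ({n})")

    rng = np.random.default_rng(seed)
    # Farthest-point initialization: spreads initial centers across the data
    # so duplicated profile groups each attract their own cluster.
    first = int(rng.integers(n))
    chosen = [first]
    d_min = ((X - X[first]) ** 2).sum(axis=1)
    for _ in range(c - 1):
        nxt = int(np.argmax(d_min))
        chosen.append(nxt)
        d_min = np.minimum(d_min, ((X - X[nxt]) ** 2).sum(axis=1))
    centers = X[chosen].copy()
    # Break exact duplicates among initial centers.
    centers += 1e-9 * rng.standard_normal(centers.shape)
    exponent = 2.0 / (m - 1.0)
    u = np.full((n, c), 1.0 / c)
    converged = False
    it = 0
    obj_trace: list[float] = []
    for it in range(1, max_iter + 1):
        d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_u = np.empty_like(u)
        with np.errstate(divide="ignore", over="ignore"):
            inv = d2 ** (-exponent / 2.0)
        # Rows touching a center (zero distance, or close enough that the
        # inverse power overflows) get hard membership for the nearest one.
        hard_rows = ~np.isfinite(inv).all(axis=1)
        soft = ~hard_rows
        new_u[soft] = inv[soft] / inv[soft].sum(axis=1, keepdims=True)
        if hard_rows.any():
            for r in np.flatnonzero(hard_rows):
                new_u[r] = 0.0
                new_u[r, int(np.argmin(d2[r]))] = 1.0  # lowest index on ties
        delta = np.abs(new_u - u).max()
        u = new_u
        um = u**m
        mass = um.sum(axis=0)
        alive = mass > 0
        centers[alive] = (um.T @ X)[alive] / mass[alive, None]
        d2_new = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        obj_trace.append(float(np.sum(um * d2_new)))
        if delta < tol:
            converged = True
            break
    d2 = ((X[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
    objective = float(np.sum((u**m) * d2))
    return TrajectoryModel(
        c=c,
        m=m,
        centers=centers,
        membership=u,
        objective=objective,
        n_iterations=it,
        converged=converged,
        otu_ids=otu_ids,
        objective_trace=obj_trace,
    )


def assign_trajectory(
    model: TrajectoryModel, min_membership: float = 0.0
) -> list[int | None]:
    """Argmax cluster (1-based) per OTU, or ``None`` when the maximum
    membership does not exceed ``min_membership`` (unassigned)."""
    labels: list[int | None] = []
    for row in model.membership:
        k = int(np.argmax(row))  # lowest index on ties
        labels.append(k + 1 if row[k] > min_membership else None)
    return labels
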