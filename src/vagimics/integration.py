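"""Host transcriptome integration: DEGs, coexpression modules, eigengenes,
microbe-module association, and RV concordance.

The pipeline consumes a per-gene differential-expression statistics table
(log2 fold change and BH-adjusted FDR from an upstream DE tool), filters
DEGs at FDR < 0.05 and |log2FC| > 1, builds a Pearson coexpression network
over the DEGs (|r| > 0.9, p < 0.05), partitions it into modules with the
Louvain method, summarizes each module by its first-principal-component
eigengene, and associates OTU abundances with module eigengenes under a
joint Benjamini-Hochberg correction. The RV coefficient quantifies the
concordance of two multivariate views of the same samples (the coinertia
statistic used to compare sequencing methods).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .otutable import RelativeAbundanceTable

__all__ = [
    "filter_degs",
    "benjamini_hochberg",
    "pearson_r_p",
    "coexpression_network",
    "louvain_partition",
    "module_eigengene",
    "compute_eigengenes",
    "associate_microbes",
    "rv_coefficient",
    "CoexpressionNetwork",
    "ModulePartition",
    "EigengeneSet",
    "RvResult",
]

_FDR_FLOOR = 1e-300  # avoids infinite -log10(FDR) in rank values


@dataclass
class CoexpressionNetwork:
    """Genes with at least one retained edge, plus the edge table."""

    genes: list[str]
    edges: pd.DataFrame  # columns gene_i, gene_j, r, p
    r_threshold: float
    p_threshold: float

    def to_graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.genes)
        for row in self.edges.itertuples(index=False):
            g.add_edge(row.gene_i, row.gene_j, weight=abs(row.r), r=row.r, p=row.p)
        return g


@dataclass
class ModulePartition:
    membership: dict[str, int]  # gene -> 1-based module id
    n_modules: int
    modularity: float

    def genes_of(self, module: int) -> list[str]:
        return sorted(g for g, m in self.membership.items() if m == module)


@dataclass
class EigengeneSet:
    """Per-module first-PC eigengene scores (samples x modules)."""

    scores: pd.DataFrame  # index = sample ids, columns = module ids
    variance_explained: dict[int, float] = field(default_factory=dict)


@dataclass
class RvResult:
    rv: float
    p_perm: float
    n_permutations: int


def filter_degs(stats_table: pd.DataFrame) -> pd.DataFrame:
    """Keep genes with FDR < 0.05 and |log2FC| > 1; add direction and rank value.

    ``rank_value = -log10(FDR) * log2FC`` (FDR floored at 1e-300), the score
    used to order top up- and downregulated genes.
    """
    required = {"gene_id", "log2fc", "fdr"}
    missing = required - set(stats_table.columns)
    if missing:
        raise ValueError(f"DEG table missing columns: {sorted(missing)}")
    t = stats_table.copy()
    if ((t["fdr"] < 0) | (t["fdr"] > 1)).any():
        raise ValueError("fdr values must lie in [0, 1]")
    kept = t[(t["fdr"] < 0.05) & (t["log2fc"].abs() > 1.0)].copy()
    kept["direction"] = np.where(kept["log2fc"] > 0, "up", "down")
    kept["rank_value"] = -np.log10(kept["fdr"].clip(lower=_FDR_FLOOR)) * kept["log2fc"]
    return kept.reset_index(drop=True)


def benjamini_hochberg(p_values) -> np.ndarray:
    """Standard BH step-up adjustment, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def pearson_r_p(x, y) -> tuple[float, float]:
    """Pearson r with a two-sided t-test p; (nan, nan) on zero variance."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("need vectors of equal length >= 3")
    if np.std(x) == 0 or np.std(y) == 0:
        return (float("nan"), float("nan"))
    r, p = stats.pearsonr(x, y)
    if abs(r) >= 1.0 - 1e-12:
        p = 0.0
    return float(r), float(p)


def _corr_p_matrix(values: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs Pearson r and two-sided p for rows of ``values``."""
    n = values.shape[1]
    r = np.corrcoef(values)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r**2, 1e-300))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.abs(r) >= 1.0 - 1e-15] = 0.0
    return r, p


def coexpression_network(
    expr: pd.DataFrame,
    r_threshold: float = 0.9,
    p_threshold: float = 0.05,
    signed: bool = False,
) -> CoexpressionNetwork:
    """Pearson coexpression network over genes (rows) x samples (columns).

    Edges require p < ``p_threshold`` and |r| > ``r_threshold`` (or r alone
    when ``signed``). Genes with no retained edge are excluded — the network
    keeps only its "main components". Constant genes are skipped with a
    warning.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    values = expr.to_numpy(dtype=float)
    sd = values.std(axis=1)
    constant = sd == 0
    if constant.any():
        warnings.warn(
            f"skipping {int(constant.sum())} constant-expression genes", stacklevel=2
        )
    genes = expr.index[~constant].to_list()
    values = values[~constant]
    r, p = _corr_p_matrix(values)
    strength = r if signed else np.abs(r)
    iu, ju = np.triu_indices(len(genes), 1)
    mask = (strength[iu, ju] > r_threshold) & (p[iu, ju] < p_threshold)
    edges = pd.DataFrame(
        {
            "gene_i": [genes[i] for i in iu[mask]],
            "gene_j": [genes[j] for j in ju[mask]],
            "r": r[iu[mask], ju[mask]],
            "p": p[iu[mask], ju[mask]],
        }
    )
    connected = sorted(set(edges["gene_i"]) | set(edges["gene_j"]))
    return CoexpressionNetwork(
        genes=connected, edges=edges, r_threshold=r_threshold, p_threshold=p_threshold
    )


def louvain_partition(
    network: CoexpressionNetwork, seed: int = 0, resolution: float = 1.0
) -> ModulePartition:
    """Louvain modularity optimization with |r| edge weights (seeded)."""
    g = network.to_graph()
    if g.number_of_nodes() == 0:
        raise ValueError("empty network")
    communities = nx.community.louvain_communities(
        g, weight="weight", resolution=resolution, seed=seed
    )
    # Deterministic module numbering: largest first, ties by smallest gene id.
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))
    membership = {}
    for mid, comm in enumerate(communities, start=1):
        for gene in comm:
            membership[gene] = mid
    q = nx.community.modularity(g, communities, weight="weight")
    return ModulePartition(membership=membership, n_modules=len(communities), modularity=float(q))


def module_eigengene(
    expr: pd.DataFrame, module_genes: list[str]
) -> tuple[pd.Series, float]:
    """First-PC eigengene of a module (unit variance, mean-profile sign).

    Genes are standardized across samples; the eigengene is the first
    principal component score per sample, sign-fixed to correlate positively
    with the module's mean standardized expression, and scaled to unit
    variance. Also returns the leading eigenvalue's share of variance.
    """
    if len(module_genes) < 2:
        raise ValueError("module must contain at least 2 genes")
    sub = expr.loc[module_genes]
    if sub.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    vals = sub.to_numpy(dtype=float)
    sd = vals.std(axis=1, ddof=0)
    if np.all(sd == 0):
        raise ValueError("module contains only constant genes")
    vals = vals[sd > 0]
    z = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, keepdims=True)
    # samples x genes
    zt = z.T
    u, s, _ = np.linalg.svd(zt - zt.mean(axis=0), full_matrices=False)
    scores = u[:, 0] * s[0]
    mean_profile = z.mean(axis=0)
    if np.corrcoef(scores, mean_profile)[0, 1] < 0:
        scores = -scores
    scores = scores / scores.std(ddof=0)
    var_explained = float(s[0] ** 2 / np.sum(s**2))
    return pd.Series(scores, index=expr.columns, name="eigengene"), var_explained


def compute_eigengenes(expr: pd.DataFrame, partition: ModulePartition) -> EigengeneSet:
    """Eigengene per module of a partition (modules of >= 2 genes)."""
    cols = {}
    ve = {}
    for mid in range(1, partition.n_modules + 1):
        genes = partition.genes_of(mid)
        if len(genes) < 2:
            continue
        scores, v = module_eigengene(expr, genes)
        cols[mid] = scores
        ve[mid] = v
    return EigengeneSet(scores=pd.DataFrame(cols), variance_explained=ve)


def associate_microbes(
    otu_abund: RelativeAbundanceTable, eigengenes: EigengeneSet
) -> pd.DataFrame:
    """Pearson association of every OTU with every module eigengene.

    BH correction is applied jointly across all (OTU x module) pairs;
    significant means FDR < 0.05. The OTU table and eigengene scores must
    cover the same samples.
    """
    eg = eigengenes.scores
    otu_samples = set(otu_abund.sample_ids)
    eg_samples = set(eg.index)
    if otu_samples != eg_samples:
        raise ValueError(
            "sample mismatch between OTU table and eigengenes; "
            f"only in OTU table: {sorted(otu_samples - eg_samples)}, "
            f"only in eigengenes: {sorted(eg_samples - otu_samples)}"
        )
    abund = otu_abund.to_dataframe().loc[eg.index]
    rows = []
    for otu in abund.columns:
        for mid in eg.columns:
            r, p = pearson_r_p(abund[otu].to_numpy(), eg[mid].to_numpy())
            rows.append({"otu_id": otu, "module": int(mid), "r": r, "p": p})
    out = pd.DataFrame(rows)
    valid = out["p"].notna()
    fdr = np.full(len(out), np.nan)
    if valid.any():
        fdr[valid.to_numpy()] = benjamini_hochberg(out.loc[valid, "p"].to_numpy())
    out["fdr"] = fdr
    out["significant"] = out["fdr"] < 0.05
    return out


def rv_coefficient(
    X, Y, n_permutations: int = 999, seed: int = 0
) -> RvResult:
    """RV coefficient between two sample-matched configurations.

    RV = tr(XX'YY') / sqrt(tr((XX')^2) tr((YY')^2)) on column-centered
    matrices; the permutation p shuffles Y's sample rows (add-one rule).
    """
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.ndim != 2 or Y.ndim != 2 or X.shape[0] != Y.shape[0]:
        raise ValueError("X and Y must be 2-D with matching sample rows")
    if X.shape[0] < 3:
        raise ValueError("need at least 3 samples")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)

    def _rv(a: np.ndarray, b: np.ndarray) -> float:
        sa = a @ a.T
        sb = b @ b.T
        denom = np.sqrt(np.sum(sa * sa) * np.sum(sb * sb))
        if denom == 0:
            return float("nan")
        return float(np.sum(sa * sb) / denom)

    rv_obs = _rv(Xc, Yc)
    rng = np.random.default_rng(seed)
    count = 0
    n = X.shape[0]
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        if _rv(Xc, Yc[perm]) >= rv_obs - 1e-12:
            count += 1
    p = (count + 1) / (n_permutations + 1)
    return RvResult(rv=rv_obs, p_perm=float(p), n_permutations=n_permutations)
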