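"""Synthetic study generator with a full ground-truth record.

Generates data with the statistical structure the analysis assumes — two
stage-linked Dirichlet-multinomial community types with a small set of
discriminating OTUs, stage-shaped abundance trajectories, planted basis
correlations between OTUs, and a host expression matrix whose gene modules
are driven by latent factors linearly coupled to selected OTU abundances —
so every pipeline stage can be tested for parameter recovery without the
deposited sequencing data.

The default study mirrors the design of the source experiment: 7 ordered
stages (estrous-cycle day 9 plus pregnancy days 9-35) with 4 samples each
except 2 at P35 (26 swabs), community type 1 spanning C9-P12 and type 2
spanning P16-P35, and a transcriptome of two stages (P9 and P28) with 3
epithelial samples per stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .otutable import RANKS, STAGES, UNANNOTATED, OtuTable, Taxonomy

__all__ = [
    "SimulationConfig",
    "SimulatedStudy",
    "simulate_otu_study",
    "simulate_correlated_counts",
    "simulate_expression",
    "simulate_trajectory_profiles",
    "trajectory_shapes",
]

_PHYLA = (
    "Firmicutes",
    "Proteobacteria",
    "Bacteroidota",
    "Actinobacteriota",
    UNANNOTATED,
)


def trajectory_shapes() -> np.ndarray:
    """Nine canonical stage-shapes over the 7 stages, standardized rows.

    Monotone up/down, early/mid/late peaks and troughs, and a step-up shape —
    the qualitative trajectory families seen in short pregnancy time courses.
    """
    t = np.linspace(0, 1, 7)
    raw = np.stack(
        [
            t,  # monotone up
            -t,  # monotone down
            np.exp(-(((t - 0.1) / 0.22) ** 2)),  # early peak
            np.exp(-(((t - 0.5) / 0.22) ** 2)),  # mid peak
            np.exp(-(((t - 0.9) / 0.22) ** 2)),  # late peak
            -np.exp(-(((t - 0.1) / 0.22) ** 2)),  # early trough
            -np.exp(-(((t - 0.5) / 0.22) ** 2)),  # mid trough
            -np.exp(-(((t - 0.9) / 0.22) ** 2)),  # late trough
            np.where(t >= 0.5, 1.0, -1.0),  # step up
        ]
    )
    raw = raw - raw.mean(axis=1, keepdims=True)
    return raw / raw.std(axis=1, keepdims=True)


@dataclass
class SimulationConfig:
    """Study-design parameters of the synthetic data generator.

    Defaults reproduce the source study's design: 26 swab samples over 7
    stages, two community types split at implantation (P12/P16 boundary),
    5 discriminating OTUs, 9 trajectory shapes, a 200-gene transcriptome
    with 4 coexpression modules (loading 0.95, noise SD 0.3 on the log2
    scale) of which module 1 is coupled to a discriminating OTU, and
    module-coherent differential expression between P9 and P28.
    """

    seed: int = 0
    stages: tuple[str, ...] = STAGES
    samples_per_stage: dict = field(
        default_factory=lambda: {"C9": 4, "P9": 4, "P12": 4, "P16": 4, "P21": 4, "P28": 4, "P35": 2}
    )
    n_otus: int = 50
    # Sequencing depth: ("fixed", depth) or ("lognormal", mean, sigma-of-log).
    depth: tuple = ("lognormal", 20000, 0.3)
    community_type_map: dict = field(
        default_factory=lambda: {"C9": 1, "P9": 1, "P12": 1, "P16": 2, "P21": 2, "P28": 2, "P35": 2}
    )
    n_discriminating: int = 5
    discriminating_alpha_high: float = 8.0
    discriminating_alpha_low: float = 0.3
    background_alpha_total: float = 15.0
    n_trajectory_otus_per_shape: int = 2
    trajectory_amplitude: float = 0.3
    # Expression block
    expression_stages: tuple[str, str] = ("P9", "P28")
    n_expression_per_stage: int = 3
    n_genes: int = 200
    n_modules: int = 4
    genes_per_module: int = 25
    module_loading: float = 0.95
    gene_noise_sd: float = 0.3
    couplings: dict = field(default_factory=lambda: {1: 0})  # module -> disc. OTU index
    coupling_noise_sd: float = 0.33  # gives coupling r ~ 0.95
    de_shift: float = 1.5  # |log2FC|-scale stage shift for module genes
    n_de_up: Optional[int] = None  # default: genes of up modules
    n_de_down: Optional[int] = None

    def otu_id(self, j: int) -> str:
        return f"OTU_{j + 1}"

    def validate(self) -> None:
        for s in self.stages:
            if s not in self.samples_per_stage:
                raise ValueError(f"samples_per_stage missing stage {s!r}")
            if s not in self.community_type_map:
                raise ValueError(f"community_type_map missing stage {s!r}")
        if self.depth[0] not in ("fixed", "lognormal"):
            raise ValueError("depth must be ('fixed', d) or ('lognormal', mean, sigma)")
        if min(self.samples_per_stage.values()) < 1:
            raise ValueError("samples_per_stage entries must be positive")
        if self.n_discriminating >= self.n_otus:
            raise ValueError("n_discriminating must be smaller than n_otus")
        for mod, otu_idx in self.couplings.items():
            if not (1 <= mod <= self.n_modules):
                raise ValueError(f"coupling references unknown module {mod}")
            if not (0 <= otu_idx < self.n_discriminating):
                raise ValueError(f"coupling references unknown discriminating OTU index {otu_idx}")


@dataclass
class SimulatedStudy:
    otu_table: OtuTable
    taxonomy: Taxonomy
    truth: dict
    expression: Optional[pd.DataFrame] = None  # genes x samples
    deg_stats: Optional[pd.DataFrame] = None


def _type_alphas(config: SimulationConfig) -> tuple[np.ndarray, np.ndarray]:
    """Dirichlet parameter vectors of the two community types.

    Both types share a power-law background; the discriminating OTUs are
    dominant in type 1 and nearly absent in type 2, whose mass is
    redistributed over the background so the total precision matches.
    """
    n_disc = config.n_discriminating
    bg = 1.0 / (np.arange(1, config.n_otus - n_disc + 1) ** 0.7)
    bg = bg / bg.sum() * config.background_alpha_total
    a1 = np.empty(config.n_otus)
    a2 = np.empty(config.n_otus)
    a1[:n_disc] = config.discriminating_alpha_high
    a2[:n_disc] = config.discriminating_alpha_low
    a1[n_disc:] = bg
    # Rescale type 2 background so both types have equal precision.
    total1 = a1.sum()
    a2[n_disc:] = bg * (total1 - n_disc * config.discriminating_alpha_low) / bg.sum()
    return a1, a2


def _default_taxonomy(config: SimulationConfig, rng: np.random.Generator) -> Taxonomy:
    assignments = {}
    for j in range(config.n_otus):
        phylum = _PHYLA[rng.integers(0, len(_PHYLA))]
        entry = {rank: UNANNOTATED for rank in RANKS}
        entry["domain"] = "Bacteria"
        entry["phylum"] = phylum
        if phylum != UNANNOTATED:
            entry["genus"] = f"{phylum[:4]}_genus_{j % 7 + 1}"
        assignments[config.otu_id(j)] = entry
    return Taxonomy(assignments)


def simulate_otu_study(config: SimulationConfig) -> SimulatedStudy:
    """Generate the microbiome half of the study from a config.

    Each sample's composition is a Dirichlet draw from its stage's community
    type (trajectory OTUs get a stage-dependent multiplicative modulation of
    their Dirichlet parameter first), and counts are multinomial at the
    sample's sequencing depth. Deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    a_type = _type_alphas(config)
    shapes = trajectory_shapes()
    n_shapes = shapes.shape[0]

    # Trajectory OTUs are drawn from the background block.
    n_traj = n_shapes * config.n_trajectory_otus_per_shape
    first_bg = config.n_discriminating
    if first_bg + n_traj > config.n_otus:
        raise ValueError("not enough background OTUs for the trajectory assignments")
    traj_otus = np.arange(first_bg, first_bg + n_traj)
    traj_shape_of = {int(o): i % n_shapes for i, o in enumerate(traj_otus)}

    sample_ids: list[str] = []
    stage_labels: list[str] = []
    type_labels: list[int] = []
    rows = []
    for stage in config.stages:
        stage_idx = STAGES.index(stage)
        ctype = config.community_type_map[stage]
        alpha = a_type[ctype - 1].copy()
        for otu, shp in traj_shape_of.items():
            alpha[otu] *= np.exp(config.trajectory_amplitude * shapes[shp, stage_idx])
        for r in range(config.samples_per_stage[stage]):
            sid = f"{stage}_{r + 1}"
            sample_ids.append(sid)
            stage_labels.append(stage)
            type_labels.append(ctype)
            comp = rng.dirichlet(alpha)
            if config.depth[0] == "fixed":
                depth = int(config.depth[1])
            else:
                _, mean, sigma = config.depth
                depth = max(100, int(rng.lognormal(np.log(mean), sigma)))
            rows.append(rng.multinomial(depth, comp))
    table = OtuTable(
        sample_ids=sample_ids,
        otu_ids=[config.otu_id(j) for j in range(config.n_otus)],
        counts=np.asarray(rows),
        stages=stage_labels,
    )
    taxonomy = _default_taxonomy(config, rng)
    truth = {
        "type_of_sample": dict(zip(sample_ids, type_labels)),
        "discriminating_otus": [config.otu_id(j) for j in range(config.n_discriminating)],
        "type_alphas": {"1": a_type[0].tolist(), "2": a_type[1].tolist()},
        "trajectory_shape_of": {
            config.otu_id(o): int(s) + 1 for o, s in traj_shape_of.items()
        },
        "trajectory_shapes": shapes.tolist(),
    }
    return SimulatedStudy(otu_table=table, taxonomy=taxonomy, truth=truth)


def simulate_correlated_counts(
    n_samples: int,
    n_otus: int,
    planted_pairs: list[tuple[int, int, float]],
    depth: int,
    seed: int = 0,
    log_sd: float = 1.0,
) -> tuple[OtuTable, dict]:
    """Counts whose latent absolute abundances carry planted correlations.

    Basis abundances are exp of a multivariate normal whose correlation
    matrix is the identity except for the planted pairs; fractions are the
    normalized basis and counts are multinomial at ``depth``. The truth
    record stores the full basis correlation matrix.
    """
    corr = np.eye(n_otus)
    for i, j, rho in planted_pairs:
        if not (-1.0 < rho < 1.0):
            raise ValueError("planted correlations must satisfy |rho| < 1")
        corr[i, j] = corr[j, i] = rho
    try:
        chol = np.linalg.cholesky(corr)
    except np.linalg.LinAlgError as err:
        raise ValueError("requested correlation structure is not positive definite") from err
    rng = np.random.default_rng(seed)
    # Spread of mean log-abundances across OTUs, as in real communities.
    mu = rng.normal(0.0, 1.0, size=n_otus)
    z = rng.standard_normal((n_samples, n_otus)) @ chol.T
    basis = np.exp(mu[None, :] + log_sd * z)
    frac = basis / basis.sum(axis=1, keepdims=True)
    counts = np.vstack([rng.multinomial(depth, f) for f in frac])
    stages = [STAGES[i % len(STAGES)] for i in range(n_samples)]
    table = OtuTable(
        sample_ids=[f"s{i + 1}" for i in range(n_samples)],
        otu_ids=[f"OTU_{j + 1}" for j in range(n_otus)],
        counts=counts,
        stages=stages,
    )
    truth = {
        "basis_correlation": corr,
        "planted_pairs": [(i, j, rho) for i, j, rho in planted_pairs],
        "log_basis": np.log(basis),
    }
    return table, truth


def simulate_expression(
    config: SimulationConfig, otu_table: OtuTable
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Generate the host transcriptome coupled to the microbiome.

    Expression samples are a subset of ``otu_table``'s samples from the two
    designated stages. Each module m has a per-sample latent factor carrying
    the module's stage offset; coupled modules instead take the standardized
    relative abundance of their OTU (already stage-separated) plus Gaussian
    noise. Gene g of module m is

        value = baseline * 2^(loading * factor_m + eps),   eps ~ N(0, noise_sd),

    i.e. log-normal measurement noise around a baseline modulated by the
    factor. Stand-alone DE genes (outside modules) shift directly with the
    stage. The surrogate DEG statistics table is derived from the planted
    shifts: true DE genes get FDR well below 0.05 and |log2FC| above 1,
    null genes fail at least one filter.
    """
    config.validate()
    rng = np.random.default_rng(config.seed + 1)
    s1, s2 = config.expression_stages
    samples = []
    groups = []
    for stage in (s1, s2):
        stage_samples = [
            sid for sid, st in zip(otu_table.sample_ids, otu_table.stages) if st == stage
        ]
        if len(stage_samples) < config.n_expression_per_stage:
            raise ValueError(
                f"stage {stage!r} has {len(stage_samples)} samples, "
                f"fewer than n_expression_per_stage={config.n_expression_per_stage}"
            )
        chosen = stage_samples[: config.n_expression_per_stage]
        samples.extend(chosen)
        groups.extend([stage] * len(chosen))
    n = len(samples)
    group2 = np.array([g == s2 for g in groups], dtype=float)

    # Relative abundances of the coupled OTUs on the expression samples.
    idx = [otu_table.sample_ids.index(s) for s in samples]
    counts = otu_table.counts[idx, :].astype(float)
    rel = counts / counts.sum(axis=1, keepdims=True)
    otu_col = {o: j for j, o in enumerate(otu_table.otu_ids)}

    # Module latent factors. The stage (differential-expression) effect acts
    # through the factor: non-coupled modules get an alternating-sign group
    # offset, coupled modules inherit their stage structure from the coupled
    # OTU's abundance, which already separates the community types.
    factors = np.empty((config.n_modules, n))
    couplings_named = {}
    module_direction = {}
    for m in range(1, config.n_modules + 1):
        if m in config.couplings:
            otu_id = f"OTU_{config.couplings[m] + 1}"
            if otu_id not in otu_col:
                raise ValueError(f"coupling references unknown OTU {otu_id!r}")
            a = rel[:, otu_col[otu_id]]
            a_std = (a - a.mean()) / (a.std() if a.std() > 0 else 1.0)
            f = a_std + rng.normal(0, config.coupling_noise_sd, size=n)
            couplings_named[m] = otu_id
        else:
            direction = 1.0 if m % 2 == 1 else -1.0
            f = rng.standard_normal(n) + direction * config.de_shift * group2
        factors[m - 1] = f
        delta = f[group2 == 1].mean() - f[group2 == 0].mean()
        module_direction[m] = 1.0 if delta >= 0 else -1.0

    n_module_genes = config.n_modules * config.genes_per_module
    if n_module_genes > config.n_genes:
        raise ValueError("module structure exceeds n_genes")
    gene_ids = [f"gene_{g + 1}" for g in range(config.n_genes)]
    module_of: dict[str, int] = {}
    # Module-coherent DE: odd modules up, even modules down between stages.
    shift_of = np.zeros(config.n_genes)
    # Optional extra stand-alone DE genes among the background block so that
    # the planted up/down totals can be set exactly. Module directions are
    # the realized factor stage offsets (a coupled module follows its OTU).
    n_up_mod = sum(
        config.genes_per_module
        for m in range(1, config.n_modules + 1)
        if module_direction[m] > 0
    )
    n_down_mod = n_module_genes - n_up_mod
    extra_up = 0 if config.n_de_up is None else config.n_de_up - n_up_mod
    extra_down = 0 if config.n_de_down is None else config.n_de_down - n_down_mod
    if extra_up < 0 or extra_down < 0:
        raise ValueError("n_de_up/n_de_down smaller than the module DE genes")
    if n_module_genes + extra_up + extra_down > config.n_genes:
        raise ValueError("planted DE genes exceed n_genes")
    for g in range(n_module_genes, n_module_genes + extra_up):
        shift_of[g] = config.de_shift * (1.0 + 0.3 * rng.random())
    for g in range(n_module_genes + extra_up, n_module_genes + extra_up + extra_down):
        shift_of[g] = -config.de_shift * (1.0 + 0.3 * rng.random())
    baseline = rng.uniform(20, 200, size=config.n_genes)
    values = np.empty((config.n_genes, n))
    for g in range(config.n_genes):
        if g < n_module_genes:
            m = g // config.genes_per_module + 1
            module_of[gene_ids[g]] = m
            # Module genes are DE through their factor's stage offset.
            shift_of[g] = module_direction[m] * config.de_shift * (1.0 + 0.3 * rng.random())
            log2 = config.module_loading * factors[m - 1] + rng.normal(
                0, config.gene_noise_sd, size=n
            )
        else:
            log2 = shift_of[g] * group2 + rng.normal(0, config.gene_noise_sd, size=n)
        values[g] = baseline[g] * np.power(2.0, log2)
    expr = pd.DataFrame(values, index=gene_ids, columns=samples)

    # Surrogate per-gene DE statistics derived from the planted shifts.
    de_mask = shift_of != 0
    log2fc = np.where(
        de_mask,
        shift_of,
        np.clip(rng.normal(0, 0.3, size=config.n_genes), -0.95, 0.95),
    )
    fdr = np.where(
        de_mask,
        10.0 ** rng.uniform(-8, -2, size=config.n_genes),
        rng.uniform(0.1, 1.0, size=config.n_genes),
    )
    deg_stats = pd.DataFrame({"gene_id": gene_ids, "log2fc": log2fc, "fdr": fdr})

    truth = {
        "expression_samples": samples,
        "expression_groups": groups,
        "module_of_gene": module_of,
        "factors": factors,
        "couplings": couplings_named,
        "de_up": [g for g, s in zip(gene_ids, shift_of) if s > 0],
        "de_down": [g for g, s in zip(gene_ids, shift_of) if s < 0],
    }
    return expr, deg_stats, truth


def simulate_trajectory_profiles(
    n_per_shape: int = 20, noise_sd: float = 0.15, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Standardized noisy copies of the 9 canonical shapes, with shape labels."""
    rng = np.random.default_rng(seed)
    shapes = trajectory_shapes()
    rows = []
    labels = []
    for s in range(shapes.shape[0]):
        for _ in range(n_per_shape):
            prof = shapes[s] + rng.normal(0, noise_sd, size=shapes.shape[1])
            prof = (prof - prof.mean()) / prof.std()
            rows.append(prof)
            labels.append(s + 1)
    return np.asarray(rows), np.asarray(labels)
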