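"""Seeded end-to-end orchestration of the analysis pipeline.

Order of stages: rarefaction -> top-fraction OTU filtering -> alpha
diversity and stage trend tests -> DMM community typing with evidence-based
K selection and contribution ranking -> trajectory soft clustering ->
per-community SparCC cooccurrence networks -> PERMANOVA stage contrasts ->
DEG filtering -> coexpression network, Louvain modules, eigengenes ->
microbe-module association -> RV concordance. All randomness flows from one
master seed, expanded per stage, so a rerun with the same seed reproduces
every artifact.
"""

from __future__ import annotations

import itertools
import logging
import zlib
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import diversity as dv
from . import io as vio
from .dmm import assign_types, rank_contributions, select_k
from .integration import (
    associate_microbes,
    coexpression_network,
    compute_eigengenes,
    filter_degs,
    louvain_partition,
    rv_coefficient,
)
from .otutable import STAGES, OtuTable, Taxonomy, aggregate_rank, rarefy, select_top_fraction, to_relative
from .sparcc import build_network, sparcc, sparcc_bootstrap_p
from .trajectories import assign_trajectory, fuzzy_cmeans, stage_profiles

logger = logging.getLogger("vagimics")


@dataclass
class PipelineConfig:
    """All pipeline settings; defaults follow the study's stated thresholds."""

    # Inputs (may be left None when run_study is called with objects)
    otu_table_path: str | None = None
    metadata_path: str | None = None
    expression_path: str | None = None
    deg_stats_path: str | None = None
    outdir: str = "results"
    seed: int = 0
    # Microbiome settings
    rarefaction_depth: int | str = "min"
    top_fraction: float = 0.05
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6)
    dmm_restarts: int = 5
    contribution_threshold: float = 0.5
    trajectory_c: int = 9
    trajectory_m: float = 1.25
    trajectory_min_membership: float = 0.3
    sparcc_inner_iterations: int = 20
    sparcc_exclusion_threshold: float = 0.1
    sparcc_max_exclusions: int = 10
    sparcc_bootstraps: int = 100
    network_r_threshold: float = 0.3
    network_p_threshold: float = 0.05
    permanova_permutations: int = 999
    # Integration settings
    coexpr_r_threshold: float = 0.9
    coexpr_p_threshold: float = 0.05
    louvain_resolution: float = 1.0
    association_fdr: float = 0.05
    integration_stage_pair: tuple[str, str] | None = None  # None: choose by PERMANOVA F

    def validate(self) -> None:
        if not (0 < self.top_fraction <= 1):
            raise ValueError("top_fraction must lie in (0, 1]")
        for name in ("network_p_threshold", "coexpr_p_threshold", "association_fdr"):
            v = getattr(self, name)
            if not (0 < v <= 1):
                raise ValueError(f"{name} must lie in (0, 1]")


def _stage_seed(master: int, label: str) -> int:
    mix = zlib.crc32(label.encode())  # stable across processes
    return int(np.random.default_rng([master, mix]).integers(2**31 - 1))


def run_pipeline(config: PipelineConfig):
    """Read inputs from the configured paths and run the full pipeline."""
    config.validate()
    table, taxonomy = vio.read_otu_table(config.otu_table_path, config.metadata_path)
    expression = (
        vio.read_expression(config.expression_path) if config.expression_path else None
    )
    deg_stats = (
        vio.read_deg_stats(config.deg_stats_path) if config.deg_stats_path else None
    )
    return run_study(table, taxonomy, config, expression=expression, deg_stats=deg_stats)


def run_study(
    table: OtuTable,
    taxonomy: Taxonomy,
    config: PipelineConfig,
    expression: pd.DataFrame | None = None,
    deg_stats: pd.DataFrame | None = None,
) -> dict:
    """Run the pipeline on in-memory objects; returns the report dict."""
    config.validate()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "pipeline.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    report: dict = {"seed": config.seed, "settings": {
        k: v for k, v in asdict(config).items() if not k.endswith("_path")
    }}
    try:
        stage = "rarefaction"
        depth = (
            int(table.sample_totals.min())
            if config.rarefaction_depth == "min"
            else int(config.rarefaction_depth)
        )
        logger.info("rarefying %d samples to depth %d", table.n_samples, depth)
        rare = rarefy(table, depth, seed=_stage_seed(config.seed, "rarefy"))
        report["rarefaction_depth"] = depth

        stage = "otu_filtering"
        top, cumulative = select_top_fraction(rare, config.top_fraction)
        report["n_otus_retained"] = top.n_otus
        report["cumulative_abundance"] = cumulative
        logger.info("retained %d/%d OTUs (%.1f%% of reads)",
                    top.n_otus, rare.n_otus, 100 * cumulative)

        stage = "diversity"
        alpha = dv.alpha_diversity(rare)
        alpha.to_csv(outdir / "diversity.tsv", sep="\t", index=False)
        rel_full = to_relative(rare)
        phylum = aggregate_rank(rare, taxonomy, "phylum")
        rel_phylum = to_relative(phylum)
        stages_present = sorted(set(table.stages), key=STAGES.index)
        trend_rows = []
        phylum_totals = phylum.counts.sum(axis=0)
        top_phyla = [
            phylum.otu_ids[j]
            for j in np.argsort(-phylum_totals)[: min(4, len(phylum.otu_ids))]
        ]
        for ph in top_phyla:
            col = phylum.otu_ids.index(ph)
            groups = [
                [
                    rel_phylum.values[i, col]
                    for i in range(rel_phylum.n_samples)
                    if rel_phylum.stages[i] == s
                ]
                for s in stages_present
            ]
            kw = dv.kruskal_wallis(groups)
            trend_rows.append(
                {"test": "kruskal_wallis", "taxon": ph,
                 "statistic": kw.statistic, "z": np.nan, "p": kw.p}
            )
            if len(groups) >= 3:
                jt = dv.jonckheere_terpstra(groups, ordering=tuple(stages_present))
                trend_rows.append(
                    {"test": "jonckheere_terpstra", "taxon": ph,
                     "statistic": jt.J, "z": jt.z, "p": jt.p}
                )
        pd.DataFrame(trend_rows).to_csv(outdir / "trend_tests.tsv", sep="\t", index=False)
        report["trend_tests"] = len(trend_rows)

        stage = "community_typing"
        best_k, evidence, models = select_k(
            top,
            list(config.k_candidates),
            seed=_stage_seed(config.seed, "dmm"),
            n_restarts=config.dmm_restarts,
            # The pipeline rarefied already; the top-OTU subset makes totals
            # unequal by composition, which is expected.
            warn_unequal_depth=False,
        )
        model = models[best_k]
        assignment = assign_types(model)
        vio.write_dmm_model(model, assignment, outdir / "dmm_model.json")
        vio.write_assignments(assignment, outdir / "community_types.tsv")
        report["selected_k"] = best_k
        report["evidence_by_k"] = {str(k): v for k, v in evidence}
        report["samples_by_type"] = {
            str(t): [s for s, l in zip(assignment.sample_ids, assignment.labels) if l == t]
            for t in sorted(set(assignment.labels))
        }
        logger.info("selected K=%d; type sizes %s", best_k,
                    {t: len(v) for t, v in report["samples_by_type"].items()})

        contributions = None
        if best_k == 2:
            stage = "contribution_ranking"
            contributions = rank_contributions(model, config.contribution_threshold)
            vio.write_contributions(contributions, outdir / "contributions.tsv")
            report["top_contribution_set_size"] = len(contributions.top_set)

        stage = "trajectories"
        rel_top = to_relative(top)
        traj_otus = (
            contributions.top_set
            if contributions is not None and len(contributions.top_set) > config.trajectory_c
            else list(top.otu_ids)
        )
        profiles = stage_profiles(rel_top, traj_otus)
        traj_counts: dict[str, int] = {}
        if profiles.values.shape[0] > config.trajectory_c:
            tm = fuzzy_cmeans(
                profiles,
                c=config.trajectory_c,
                m=config.trajectory_m,
                seed=_stage_seed(config.seed, "trajectories"),
            )
            labels = assign_trajectory(tm, config.trajectory_min_membership)
            out = pd.DataFrame(
                {
                    "otu_id": profiles.otu_ids,
                    "cluster": ["unassigned" if l is None else l for l in labels],
                    "membership": tm.membership.max(axis=1),
                }
            )
            for si, s in enumerate(profiles.stages):
                out[f"center_{s}"] = [
                    np.nan if l is None else tm.centers[l - 1, si] for l in labels
                ]
            out.to_csv(outdir / "trajectories.tsv", sep="\t", index=False)
            centers = pd.DataFrame(tm.centers, columns=list(profiles.stages))
            centers.insert(0, "cluster", np.arange(1, tm.c + 1))
            centers.to_csv(outdir / "trajectory_centers.tsv", sep="\t", index=False)
            for l in labels:
                key = "unassigned" if l is None else str(l)
                traj_counts[key] = traj_counts.get(key, 0) + 1
        report["trajectory_counts"] = traj_counts

        stage = "cooccurrence"
        contrib_scores = (
            dict(zip(contributions.otu_ids, contributions.scores))
            if contributions is not None
            else {}
        )
        network_otus = (
            contributions.top_set
            if contributions is not None and len(contributions.top_set) >= 8
            else list(top.otu_ids)
        )
        report["network_edges"] = {}
        for t, sample_list in report["samples_by_type"].items():
            if len(sample_list) < 4:
                logger.info("community type %s has <4 samples; skipping network", t)
                continue
            sub = top.subset_samples(sample_list).subset_otus(network_otus)
            sp_seed = _stage_seed(config.seed, f"sparcc_{t}")
            res = sparcc(
                sub,
                inner_iterations=config.sparcc_inner_iterations,
                exclusion_threshold=config.sparcc_exclusion_threshold,
                max_exclusions=config.sparcc_max_exclusions,
                seed=sp_seed,
            )
            pmat = sparcc_bootstrap_p(
                sub,
                n_bootstrap=config.sparcc_bootstraps,
                seed=sp_seed + 1,
                observed=res,
                inner_iterations=config.sparcc_inner_iterations,
                exclusion_threshold=config.sparcc_exclusion_threshold,
                max_exclusions=config.sparcc_max_exclusions,
            )
            edges = build_network(
                res, pmat, config.network_r_threshold, config.network_p_threshold
            )
            vio.write_edge_list(
                edges,
                outdir / f"network_type{t}_edges.tsv",
                outdir / f"network_type{t}_nodes.tsv",
                contributions=contrib_scores,
            )
            report["network_edges"][str(t)] = len(edges.edges)
            logger.info("type %s cooccurrence network: %d edges", t, len(edges.edges))

        stage = "permanova"
        bc = dv.bray_curtis(rel_full)
        perm_rows = []
        counts_per_stage = {s: table.stages.count(s) for s in stages_present}
        multi = [s for s in stages_present if counts_per_stage[s] >= 2]
        if len(multi) >= 2:
            idx = [i for i, s in enumerate(rel_full.stages) if s in multi]
            sub_d = dv.DistanceMatrix(
                [rel_full.sample_ids[i] for i in idx], bc.values[np.ix_(idx, idx)]
            )
            overall = dv.permanova(
                sub_d,
                [rel_full.stages[i] for i in idx],
                n_permutations=config.permanova_permutations,
                seed=_stage_seed(config.seed, "permanova"),
            )
            perm_rows.append(
                {"contrast": "all_stages", "pseudo_F": overall.pseudo_F,
                 "r_squared": overall.r_squared, "p": overall.p_perm}
            )
            for s1, s2 in itertools.combinations(multi, 2):
                idx = [i for i, s in enumerate(rel_full.stages) if s in (s1, s2)]
                sub_d = dv.DistanceMatrix(
                    [rel_full.sample_ids[i] for i in idx], bc.values[np.ix_(idx, idx)]
                )
                r = dv.permanova(
                    sub_d,
                    [rel_full.stages[i] for i in idx],
                    n_permutations=config.permanova_permutations,
                    seed=_stage_seed(config.seed, f"permanova_{s1}_{s2}"),
                )
                perm_rows.append(
                    {"contrast": f"{s1}_vs_{s2}", "pseudo_F": r.pseudo_F,
                     "r_squared": r.r_squared, "p": r.p_perm}
                )
        perm_df = pd.DataFrame(perm_rows)
        perm_df.to_csv(outdir / "permanova.tsv", sep="\t", index=False)
        if config.integration_stage_pair is not None:
            chosen_pair = tuple(config.integration_stage_pair)
        elif len(perm_rows) > 1:
            pairwise = perm_df[perm_df["contrast"] != "all_stages"]
            best = pairwise.loc[pairwise["pseudo_F"].idxmax(), "contrast"]
            chosen_pair = tuple(best.split("_vs_"))
        else:
            chosen_pair = None
        report["integration_stage_pair"] = list(chosen_pair) if chosen_pair else None

        if expression is not None and deg_stats is not None:
            stage = "deg_filtering"
            degs = filter_degs(deg_stats)
            degs.to_csv(outdir / "degs.tsv", sep="\t", index=False)
            report["n_degs"] = len(degs)
            report["n_degs_up"] = int((degs["direction"] == "up").sum())
            report["n_degs_down"] = int((degs["direction"] == "down").sum())

            stage = "coexpression"
            deg_expr = expression.loc[expression.index.intersection(degs["gene_id"])]
            deg_expr = np.log2(deg_expr + 1.0)  # FPKM-like -> log scale
            net = coexpression_network(
                deg_expr, config.coexpr_r_threshold, config.coexpr_p_threshold
            )
            net.edges.to_csv(outdir / "coexpression_edges.tsv", sep="\t", index=False)
            report["coexpression_edges"] = len(net.edges)

            stage = "modules"
            partition = louvain_partition(
                net,
                seed=_stage_seed(config.seed, "louvain"),
                resolution=config.louvain_resolution,
            )
            pd.DataFrame(
                {
                    "gene_id": list(partition.membership),
                    "module": list(partition.membership.values()),
                }
            ).to_csv(outdir / "modules.tsv", sep="\t", index=False)
            report["n_modules"] = partition.n_modules
            report["module_sizes"] = {
                str(m): len(partition.genes_of(m))
                for m in range(1, partition.n_modules + 1)
            }
            report["modularity"] = partition.modularity

            stage = "eigengenes"
            eigengenes = compute_eigengenes(deg_expr, partition)
            eg = eigengenes.scores.copy()
            eg.index.name = "sample_id"
            eg.to_csv(outdir / "eigengenes.tsv", sep="\t")

            stage = "association"
            expr_samples = [s for s in rel_top.sample_ids if s in set(expression.columns)]
            assoc_otus = (
                contributions.top_set
                if contributions is not None and contributions.top_set
                else list(top.otu_ids)
            )
            matched = rel_top.subset_samples(expr_samples)
            matched_sub = type(matched)(
                sample_ids=matched.sample_ids,
                otu_ids=assoc_otus,
                values=_renorm(matched.to_dataframe()[assoc_otus].to_numpy()),
                stages=matched.stages,
            )
            assoc = associate_microbes(matched_sub, eigengenes)
            assoc.to_csv(outdir / "associations.tsv", sep="\t", index=False)
            sig = assoc[assoc["significant"]]
            report["n_associations_tested"] = len(assoc)
            report["significant_associations"] = [
                {"otu_id": r.otu_id, "module": int(r.module), "r": float(r.r)}
                for r in sig.itertuples(index=False)
            ]

            stage = "rv_concordance"
            x = matched.to_dataframe().to_numpy()
            y = deg_expr[expr_samples].to_numpy().T
            y = np.log2(y + 1.0)
            rv = rv_coefficient(
                x, y, n_permutations=config.permanova_permutations,
                seed=_stage_seed(config.seed, "rv"),
            )
            report["rv"] = rv.rv
            report["rv_p"] = rv.p_perm

        vio.write_json(report, outdir / "report.json")
        logger.info("pipeline complete; report written")
        return report
    except Exception as exc:
        logger.exception("pipeline failed at stage %s", stage)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    finally:
        logger.removeHandler(handler)
        handler.close()


def _renorm(values: np.ndarray) -> np.ndarray:
    sums = values.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return values / sums
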