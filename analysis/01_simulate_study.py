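"""Generate the default synthetic study and write its inputs under results/data/.

The study mirrors the source design: 26 vaginal swabs over 7 ordered stages
(4 per stage, 2 at P35), 50 OTUs with two stage-linked community types and
5 discriminating OTUs, 9 planted abundance trajectories, and a 200-gene
transcriptome (3 samples at P9 and P28 each) with 4 coexpression modules,
one of which is coupled to a discriminating OTU.
"""

from pathlib import Path

from vagimics.io import write_json, write_otu_table
from vagimics.simulate import SimulationConfig, simulate_expression, simulate_otu_study

OUT = Path(__file__).resolve().parent.parent / "results" / "data"
SEED = 20230915


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    cfg = SimulationConfig(seed=SEED)
    study = simulate_otu_study(cfg)
    expr, deg_stats, expr_truth = simulate_expression(cfg, study.otu_table)

    write_otu_table(study.otu_table, study.taxonomy, OUT / "otu_table.tsv", OUT / "metadata.tsv")
    expr.rename_axis("gene_id").to_csv(OUT / "expression.tsv", sep="\t")
    deg_stats.to_csv(OUT / "deg_stats.tsv", sep="\t", index=False)
    truth = dict(study.truth)
    truth.update({k: v for k, v in expr_truth.items() if k != "factors"})
    truth["factors"] = expr_truth["factors"].tolist()
    write_json(truth, OUT / "truth.json")

    t = study.otu_table
    print(f"wrote synthetic study to {OUT}")
    print(f"  {t.n_samples} samples x {t.n_otus} OTUs; depths {t.sample_totals.min()}-{t.sample_totals.max()}")
    print(f"  expression: {expr.shape[0]} genes x {expr.shape[1]} samples "
          f"({len(expr_truth['de_up'])} up / {len(expr_truth['de_down'])} down planted DE)")


if __name__ == "__main__":
    main()
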