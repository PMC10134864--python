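"""Per-community-type SparCC cooccurrence networks.

For each community type found in 03, subsets its samples, estimates SparCC
compositional correlations over the retained OTUs, attaches bootstrap
p-values (100 iterations), and writes the thresholded edge lists
(|rho| > 0.3, P < 0.05) in a Cytoscape/Gephi-ready format.
"""

from pathlib import Path

import pandas as pd

from vagimics.io import read_otu_table, write_edge_list
from vagimics.otutable import rarefy, select_top_fraction
from vagimics.sparcc import build_network, sparcc, sparcc_bootstrap_p

BASE = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    table, _ = read_otu_table(BASE / "data/otu_table.tsv", BASE / "data/metadata.tsv")
    rare = rarefy(table, int(table.sample_totals.min()), seed=6)
    top, _ = select_top_fraction(rare, 0.5)
    types = pd.read_csv(BASE / "community_types.tsv", sep="\t")
    contrib = pd.read_csv(BASE / "contributions.tsv", sep="\t")
    scores = dict(zip(contrib["otu_id"], contrib["contribution"]))

    for t in sorted(types["community_type"].unique()):
        samples = types.loc[types["community_type"] == t, "sample_id"].tolist()
        if len(samples) < 4:
            print(f"type {t}: only {len(samples)} samples, skipping")
            continue
        sub = top.subset_samples(samples)
        res = sparcc(sub, seed=10 + t)
        pmat = sparcc_bootstrap_p(sub, n_bootstrap=100, seed=20 + t, observed=res)
        edges = build_network(res, pmat, r_threshold=0.3, p_threshold=0.05)
        write_edge_list(
            edges,
            BASE / f"network_type{t}_edges.tsv",
            BASE / f"network_type{t}_nodes.tsv",
            contributions=scores,
        )
        pos = sum(e["sign"] == "positive" for e in edges.edges)
        print(f"type {t} ({len(samples)} samples): {len(edges.edges)} edges "
              f"({pos} positive, {len(edges.edges) - pos} negative) over {sub.n_otus} OTUs")


if __name__ == "__main__":
    main()
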