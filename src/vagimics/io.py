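"""Readers and writers for the pipeline's TSV/JSON artifacts.

The OTU table dialect: rows are OTUs, the first column is ``#OTU_ID``, one
column per sample with integer counts, and an optional trailing ``taxonomy``
column with semicolon-separated ranks (QIIME-style ``k__...;p__...`` prefixes
or plain names). Sample metadata is a two-column TSV ``sample_id, stage``.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .dmm import CommunityTypeAssignment, DmmModel, OtuContributionRanking
from .otutable import RANKS, UNANNOTATED, OtuTable, Taxonomy
from .sparcc import EdgeList

_PREFIXES = {"k__": "domain", "d__": "domain", "p__": "phylum", "c__": "class",
             "o__": "order", "f__": "family", "g__": "genus"}


def parse_taxonomy_string(s: str) -> dict[str, str]:
    """Parse ``k__Bacteria;p__Firmicutes;...`` or plain semicolon-joined names."""
    entry = {rank: UNANNOTATED for rank in RANKS}
    parts = [p.strip() for p in str(s).split(";")]
    plain_idx = 0
    for part in parts:
        if not part:
            plain_idx += 1
            continue
        prefix = part[:3].lower()
        if prefix in _PREFIXES:
            name = part[3:].strip()
            if name:
                entry[_PREFIXES[prefix]] = name
            plain_idx += 1
        else:
            if plain_idx < len(RANKS):
                entry[RANKS[plain_idx]] = part
            plain_idx += 1
    return entry


def format_taxonomy_string(entry: dict[str, str]) -> str:
    short = {"domain": "k", "phylum": "p", "class": "c", "order": "o",
             "family": "f", "genus": "g"}
    parts = []
    for rank in RANKS:
        name = entry.get(rank, UNANNOTATED)
        parts.append(f"{short[rank]}__{'' if name == UNANNOTATED else name}")
    return ";".join(parts)


def read_otu_table(path, metadata_path) -> tuple[OtuTable, Taxonomy]:
    """Read and validate an OTU count table plus its sample metadata."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first.lstrip("#").upper() not in ("OTU_ID", "OTUID", "OTU ID"):
        raise ValueError(f"{path}: first column must be '#OTU_ID', got {first!r}")
    otu_ids = df[first].tolist()
    has_tax = "taxonomy" in df.columns
    sample_cols = [c for c in df.columns[1:] if c != "taxonomy"]
    counts = np.empty((len(sample_cols), len(otu_ids)), dtype=np.int64)
    for j, col in enumerate(sample_cols):
        for i, cell in enumerate(df[col]):
            try:
                v = int(cell)
            except (TypeError, ValueError):
                raise ValueError(
                    f"{path}: non-integer count {cell!r} at row {i + 2}, column {col!r}"
                ) from None
            if v < 0:
                raise ValueError(
                    f"{path}: negative count {v} at row {i + 2}, column {col!r}"
                )
            counts[j, i] = v

    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if not {"sample_id", "stage"}.issubset(meta.columns):
        raise ValueError(f"{metadata_path}: need columns sample_id, stage")
    stage_of = dict(zip(meta["sample_id"], meta["stage"]))
    missing = [s for s in sample_cols if s not in stage_of]
    if missing:
        raise ValueError(f"{metadata_path}: no stage for samples {missing}")
    table = OtuTable(
        sample_ids=sample_cols,
        otu_ids=otu_ids,
        counts=counts,
        stages=[stage_of[s] for s in sample_cols],
    )
    if has_tax:
        taxonomy = Taxonomy(
            {o: parse_taxonomy_string(t) for o, t in zip(otu_ids, df["taxonomy"])}
        )
    else:
        warnings.warn("no taxonomy column; all ranks unannotated", stacklevel=2)
        taxonomy = Taxonomy({o: {r: UNANNOTATED for r in RANKS} for o in otu_ids})
    return table, taxonomy


def write_otu_table(table: OtuTable, taxonomy: Taxonomy | None, path, metadata_path) -> None:
    df = pd.DataFrame(table.counts.T, columns=table.sample_ids)
    df.insert(0, "#OTU_ID", table.otu_ids)
    if taxonomy is not None:
        df["taxonomy"] = [
            format_taxonomy_string(taxonomy.ranks_for(o)) for o in table.otu_ids
        ]
    df.to_csv(path, sep="\t", index=False)
    pd.DataFrame({"sample_id": table.sample_ids, "stage": table.stages}).to_csv(
        metadata_path, sep="\t", index=False
    )


def read_expression(path) -> pd.DataFrame:
    """Genes x samples matrix; first column is the gene id."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index(df.columns[0])
    df.index.name = "gene_id"
    if df.index.duplicated().any():
        dupes = df.index[df.index.duplicated()].tolist()[:5]
        raise ValueError(f"{path}: duplicate gene ids {dupes}")
    return df.astype(float)


def read_deg_stats(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = {"gene_id", "log2fc", "fdr"} - set(df.columns)
    if missing:
        raise ValueError(f"{path}: DEG stats missing columns {sorted(missing)}")
    return df


def write_dmm_model(model: DmmModel, assignment: CommunityTypeAssignment, path) -> None:
    doc = {
        "K": model.K,
        "pi": model.pi.tolist(),
        "alpha": model.alpha.tolist(),
        "otu_ids": model.otu_ids,
        "sample_ids": model.sample_ids,
        "log_likelihood": model.log_likelihood,
        "neg_log_evidence_laplace": model.neg_log_evidence_laplace,
        "converged": model.converged,
        "n_iterations": model.n_iterations,
        "assignments": {
            s: {"community_type": t, "max_posterior": float(p)}
            for s, t, p in zip(
                assignment.sample_ids, assignment.labels, assignment.max_posterior
            )
        },
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def write_assignments(assignment: CommunityTypeAssignment, path) -> None:
    pd.DataFrame(
        {
            "sample_id": assignment.sample_ids,
            "community_type": assignment.labels,
            "max_posterior": assignment.max_posterior,
        }
    ).to_csv(path, sep="\t", index=False)


def write_contributions(ranking: OtuContributionRanking, path) -> None:
    pd.DataFrame(
        {
            "otu_id": ranking.otu_ids,
            "contribution": ranking.scores,
            "cumulative": ranking.cumulative,
            "in_top_set": [o in set(ranking.top_set) for o in ranking.otu_ids],
        }
    ).to_csv(path, sep="\t", index=False)


def write_edge_list(edges: EdgeList, edge_path, node_path=None, contributions=None) -> None:
    pd.DataFrame(
        edges.edges, columns=["source", "target", "rho", "p", "sign"]
    ).to_csv(edge_path, sep="\t", index=False)
    if node_path is not None:
        contributions = contributions or {}
        pd.DataFrame(
            {
                "otu_id": list(edges.degrees),
                "degree": list(edges.degrees.values()),
                "contribution": [contributions.get(o, np.nan) for o in edges.degrees],
            }
        ).to_csv(node_path, sep="\t", index=False)


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=1, default=_jsonify))


def _jsonify(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    raise TypeError(f"not JSON serializable: {type(x)}")
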