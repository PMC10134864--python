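"""OTU count tables: validation, rarefaction, normalization, filtering, aggregation.

The count table is the substrate of every microbiome stage of the pipeline.
Samples are labelled with one of seven ordered gestational stages: C9 (day 9
of the estrous cycle, the non-pregnant control) followed by pregnancy days
P9, P12, P16, P21, P28 and P35.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Ordered stage vocabulary: estrous-cycle day 9, then pregnancy days 9-35.
STAGES: tuple[str, ...] = ("C9", "P9", "P12", "P16", "P21", "P28", "P35")
STAGE_ORDER: dict[str, int] = {s: i for i, s in enumerate(STAGES)}

#: Taxonomic ranks carried by :class:`Taxonomy`, coarsest first.
RANKS: tuple[str, ...] = ("domain", "phylum", "class", "order", "family", "genus")
UNANNOTATED = "unannotated"


@dataclass
class OtuTable:
    """Integer OTU count matrix (samples x OTUs) with per-sample stage labels.

    Parameters
    ----------
    sample_ids, otu_ids
        Unique identifiers for rows and columns of ``counts``.
    counts
        Non-negative integer matrix of shape ``(n_samples, n_otus)``.
    stages
        Per-sample stage label drawn from :data:`STAGES`.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    stages: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        n_s, n_o = self.counts.shape
        if n_s != len(self.sample_ids) or n_o != len(self.otu_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs"
            )
        if len(set(self.sample_ids)) != n_s:
            raise ValueError("duplicate sample identifiers")
        if len(set(self.otu_ids)) != n_o:
            raise ValueError("duplicate OTU identifiers")
        if len(self.stages) != n_s:
            raise ValueError("one stage label required per sample")
        unknown = sorted(set(self.stages) - set(STAGES))
        if unknown:
            raise ValueError(f"unknown stage labels: {unknown}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.mod(self.counts, 1) == 0):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(np.int64)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def stage_of(self, sample_id: str) -> str:
        return self.stages[self.sample_ids.index(sample_id)]

    def subset_samples(self, sample_ids: list[str]) -> "OtuTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return OtuTable(
            sample_ids=list(sample_ids),
            otu_ids=list(self.otu_ids),
            counts=self.counts[idx, :].copy(),
            stages=[self.stages[i] for i in idx],
        )

    def subset_otus(self, otu_ids: list[str]) -> "OtuTable":
        idx = [self.otu_ids.index(o) for o in otu_ids]
        return OtuTable(
            sample_ids=list(self.sample_ids),
            otu_ids=list(otu_ids),
            counts=self.counts[:, idx].copy(),
            stages=list(self.stages),
        )

    def to_dataframe(self) -> pd.DataFrame:
        """Counts as a DataFrame indexed by sample id, columns = OTU ids."""
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


@dataclass
class Taxonomy:
    """Mapping OTU id -> rank assignments; missing ranks are ``unannotated``."""

    assignments: dict[str, dict[str, str]] = field(default_factory=dict)

    def ranks_for(self, otu_id: str) -> dict[str, str]:
        raw = self.assignments.get(otu_id, {})
        return {rank: raw.get(rank, UNANNOTATED) or UNANNOTATED for rank in RANKS}

    def at_rank(self, otu_id: str, rank: str) -> str:
        if rank not in RANKS:
            raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
        return self.ranks_for(otu_id)[rank]

    def covers(self, otu_ids: list[str]) -> bool:
        return all(o in self.assignments for o in otu_ids)


@dataclass
class RelativeAbundanceTable:
    """Row-normalized abundance matrix; each sample row sums to one."""

    sample_ids: list[str]
    otu_ids: list[str]
    values: np.ndarray
    stages: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        rowsums = self.values.sum(axis=1)
        if not np.allclose(rowsums, 1.0, atol=1e-9):
            raise ValueError("relative abundance rows must sum to 1")
        if np.any(self.values < 0):
            raise ValueError("relative abundances must be non-negative")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.otu_ids)

    def subset_samples(self, sample_ids: list[str]) -> "RelativeAbundanceTable":
        idx = [self.sample_ids.index(s) for s in sample_ids]
        return RelativeAbundanceTable(
            sample_ids=list(sample_ids),
            otu_ids=list(self.otu_ids),
            values=self.values[idx, :].copy(),
            stages=[self.stages[i] for i in idx],
        )


def rarefy(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """Subsample every sample without replacement to a common read depth.

    Each sample's reads are drawn by multivariate hypergeometric sampling, the
    exact distribution of subsampling ``depth`` reads from the observed pool.
    Deterministic given ``seed``.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    totals = table.sample_totals
    for sid, tot in zip(table.sample_ids, totals):
        if depth > tot:
            raise ValueError(
                f"depth {depth} exceeds total count {tot} of sample {sid!r}"
            )
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if row.sum() == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        counts=out,
        stages=list(table.stages),
    )


def to_relative(table: OtuTable) -> RelativeAbundanceTable:
    """Scale each sample's counts to its total so that rows sum to one."""
    totals = table.sample_totals
    zero = [sid for sid, t in zip(table.sample_ids, totals) if t == 0]
    if zero:
        raise ValueError(f"samples with zero total counts: {zero}")
    values = table.counts / totals[:, None]
    return RelativeAbundanceTable(
        sample_ids=list(table.sample_ids),
        otu_ids=list(table.otu_ids),
        values=values,
        stages=list(table.stages),
    )


def select_top_fraction(
    table: OtuTable, fraction: float
) -> tuple[OtuTable, float]:
    """Keep the most abundant ``fraction`` of OTUs by summed counts.

    OTUs are ranked by total count across samples (descending), ties at the
    cutoff broken lexicographically by OTU id. Returns the restricted table
    and the retained share of the grand total. The default analysis keeps the
    top 5% of OTUs, which in the study data carry over 75% of all reads.
    """
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    if table.n_otus == 0:
        raise ValueError("empty OTU table")
    totals = table.counts.sum(axis=0)
    order = sorted(range(table.n_otus), key=lambda j: (-totals[j], table.otu_ids[j]))
    n_keep = math.ceil(fraction * table.n_otus)
    keep = order[:n_keep]
    grand = totals.sum()
    cumulative = float(totals[keep].sum() / grand) if grand > 0 else 0.0
    kept_ids = [table.otu_ids[j] for j in keep]
    return table.subset_otus(kept_ids), cumulative


def aggregate_rank(table: OtuTable, taxonomy: Taxonomy, rank: str) -> OtuTable:
    """Sum counts over OTUs sharing a taxon at ``rank``; unannotated pooled."""
    if rank not in RANKS:
        raise ValueError(f"unknown rank {rank!r}; expected one of {RANKS}")
    if not taxonomy.covers(table.otu_ids):
        missing = [o for o in table.otu_ids if o not in taxonomy.assignments]
        raise ValueError(f"taxonomy does not cover OTUs: {missing[:5]}")
    taxa = [taxonomy.at_rank(o, rank) for o in table.otu_ids]
    uniq = sorted(set(taxa))
    col = {t: i for i, t in enumerate(uniq)}
    out = np.zeros((table.n_samples, len(uniq)), dtype=table.counts.dtype)
    for j, t in enumerate(taxa):
        out[:, col[t]] += table.counts[:, j]
    return OtuTable(
        sample_ids=list(table.sample_ids),
        otu_ids=uniq,
        counts=out,
        stages=list(table.stages),
    )
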