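import numpy as np
import pytest

from vagimics.otutable import OtuTable, RelativeAbundanceTable, Taxonomy


@pytest.fixture
def small_table() -> OtuTable:
    counts = np.array(
        [
            [5, 0, 3, 2],
            [2, 2, 0, 6],
            [1, 1, 2, 6],
            [0, 4, 4, 2],
        ]
    )
    return OtuTable(
        sample_ids=["s1", "s2", "s3", "s4"],
        otu_ids=["OTU_1", "OTU_2", "OTU_3", "OTU_4"],
        counts=counts,
        stages=["C9", "P9", "P16", "P28"],
    )


@pytest.fixture
def small_taxonomy() -> Taxonomy:
    return Taxonomy(
        {
            "OTU_1": {"domain": "Bacteria", "phylum": "Firmicutes"},
            "OTU_2": {"domain": "Bacteria", "phylum": "Firmicutes"},
            "OTU_3": {"domain": "Bacteria", "phylum": "Proteobacteria"},
            "OTU_4": {"domain": "Bacteria"},  # phylum unannotated
        }
    )


def relative(values, stages=None) -> RelativeAbundanceTable:
    values = np.asarray(values, dtype=float)
    n = values.shape[0]
    return RelativeAbundanceTable(
        sample_ids=[f"s{i + 1}" for i in range(n)],
        otu_ids=[f"OTU_{j + 1}" for j in range(values.shape[1])],
        values=values,
        stages=stages or ["C9"] * n,
    )
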