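import numpy as np
import pytest

from oralmark.otu_preprocess import OtuTable


@pytest.fixture
def toy_table() -> OtuTable:
    """3 taxa x 2 samples with parseable lineages."""
    return OtuTable(
        taxon_ids=["OTU_a", "OTU_b", "OTU_c"],
        lineages=[
            "k__Bacteria; p__Firmicutes; c__Bacilli; o__Lactobacillales; "
            "f__Streptococcaceae; g__Streptococcus; s__salivarius",
            "k__Bacteria; p__Firmicutes; c__Negativicutes; o__Veillonellales; "
            "f__Veillonellaceae; g__Veillonella; s__parvula",
            "k__Bacteria; p__Bacteroidetes; c__Bacteroidia; o__Bacteroidales; "
            "f__Bacteroidaceae; g__Bacteroides; s__fragilis",
        ],
        sample_ids=["s1", "s2"],
        counts=np.array([[5, 0], [3, 7], [2, 13]]),
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260928)
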