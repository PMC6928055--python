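import numpy as np
import pandas as pd
import pytest

from microcompare import AbundanceTable


@pytest.fixture
def counts_table() -> AbundanceTable:
    """Small handmade counts table with taxonomy, 5 features x 6 samples."""
    data = pd.DataFrame(
        {
            "S1": [120, 30, 0, 5, 845],
            "S2": [200, 10, 2, 0, 988],
            "S3": [90, 55, 1, 9, 1245],
            "S4": [310, 0, 0, 4, 686],
            "S5": [150, 22, 3, 1, 1024],
            "S6": [95, 61, 0, 0, 944],
        },
        index=["OTU_1", "OTU_2", "OTU_3", "OTU_4", "OTU_5"],
    )
    taxonomy = {
        "OTU_1": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
        "OTU_2": ("Bacteria", "Bacteroidetes", "Bacteroidia", "Bacteroidales", "Prevotellaceae", "Prevotella"),
        "OTU_3": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Lachnospiraceae", "Roseburia"),
        "OTU_4": ("Bacteria", "Firmicutes", "Clostridia", "Clostridiales", "Ruminococcaceae", "Faecalibacterium"),
        "OTU_5": ("Bacteria", "Proteobacteria", "Gammaproteobacteria", "Aeromonadales", "Succinivibrionaceae", "Succinivibrio"),
    }
    return AbundanceTable(data=data, kind="counts", taxonomy=taxonomy)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
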