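import numpy as np
import pandas as pd
import pytest

from pioneerdep.genomic_io import SampleSheet, SignalMatrix
from pioneerdep.synthetic import SyntheticConfig, regression_fixture, simulate


@pytest.fixture(scope="session")
def fixture_bundle():
    """Small deterministic bundle (20 elements / 20 genes)."""
    return regression_fixture()


@pytest.fixture(scope="session")
def standard_bundle():
    """The standard study-conditions bundle: 40 elements per category, 4v4."""
    return simulate(SyntheticConfig(seed=0))


@pytest.fixture()
def small_sheet():
    rows = []
    for geno in ("WT", "KO_A"):
        for r in (1, 2, 3, 4):
            rows.append(
                {
                    "sample_id": f"ATAC_{geno}_r{r}",
                    "assay": "ATAC",
                    "genotype": geno,
                    "replicate": r,
                    "library_size": 10_000_000,
                }
            )
    return SampleSheet(pd.DataFrame(rows))


def make_matrix(counts, sheet, length=1000):
    counts = np.asarray(counts)
    return SignalMatrix(
        [f"p{i}" for i in range(counts.shape[0])],
        sheet.sample_ids,
        counts,
        np.full(counts.shape[0], length, dtype=np.int64),
    )
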