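import numpy as np
import pandas as pd
import pytest

from latgc.io_formats import CohortClinical, ExpressionMatrix, MutationTable


@pytest.fixture
def toy_expression() -> ExpressionMatrix:
    """6 genes x 4 samples, distinct values, log2 layout."""
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.normal(5, 2, size=(6, 4)),
        index=[f"g{i}" for i in range(6)],
        columns=[f"s{i}" for i in range(4)],
    )
    return ExpressionMatrix(data, "log2")


@pytest.fixture
def toy_mutations() -> MutationTable:
    records = pd.DataFrame(
        {
            "sample_id": ["p1", "p1", "p1", "p2", "p2"],
            "gene": ["TP53", "KRAS", "TP53", "TP53", "ARID1A"],
            "variant_classification": [
                "Missense_Mutation",
                "Silent",
                "Nonsense_Mutation",
                "Missense_Mutation",
                "Silent",
            ],
            "chrom": ["17", "12", "17", "17", "1"],
            "position": [100, 200, 300, 100, 400],
            "ref_count": [60, 50, 70, 55, 45],
            "alt_count": [40, 50, 30, 45, 55],
        }
    )
    return MutationTable(records)


@pytest.fixture
def toy_clinical() -> CohortClinical:
    table = pd.DataFrame(
        {
            "os_time": [100.0, 250.0, 400.0, 80.0],
            "os_event": [1, 0, 1, 1],
            "latitude": [30.0, 45.0, 46.0, 60.0],
            "stage": ["I-II", "III-IV", "III-IV", "I-II"],
        },
        index=pd.Index(["p1", "p2", "p3", "p4"], name="sample_id"),
    )
    return CohortClinical(table)
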