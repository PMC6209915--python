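import numpy as np
import pandas as pd
import pytest

from pathcombo import ExpressionMatrix, Pathway, PathwayDB


@pytest.fixture
def ras_db() -> PathwayDB:
    """Three small pathways sharing gene A."""
    return PathwayDB(
        [
            Pathway("RAS", {"HRAS": 1, "NF1": -1, "PIK3CA": 0.5}),
            Pathway("P2", {"HRAS": 1, "GENEC": 1}),
            Pathway("P3", {"HRAS": 0.5}),
        ]
    )


def make_matrix(values: dict, genes, control_samples, cell_line="SKOV-3"):
    """ExpressionMatrix from a dict sample -> list of intensities."""
    df = pd.DataFrame(values, index=list(genes), dtype=float)
    meta = pd.DataFrame(
        {
            "cell_line": cell_line,
            "drug": [
                "none" if s in control_samples else "DRUG-A"
                for s in df.columns
            ],
            "timepoint_weeks": 4,
            "is_control": [s in control_samples for s in df.columns],
        },
        index=df.columns,
    )
    return ExpressionMatrix(df, meta)


@pytest.fixture
def four_sample_matrix():
    rng = np.random.default_rng(11)
    vals = {
        "ctrl1": rng.uniform(10, 100, 5),
        "ctrl2": rng.uniform(10, 100, 5),
        "ctrl3": rng.uniform(10, 100, 5),
        "case1": rng.uniform(10, 100, 5),
    }
    genes = [f"G{i}" for i in range(5)]
    return make_matrix(vals, genes, control_samples={"ctrl1", "ctrl2", "ctrl3"})
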