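import numpy as np
import pandas as pd
import pytest

from agescreen.io import ComparisonDesign, ExpressionMatrix, ProbeGeneMap


@pytest.fixture
def tiny_matrix():
    """4 probes x 4 samples with hand-pickable ratios."""
    df = pd.DataFrame(
        {
            "ctrl_a": [10.0, 10.0, 10.0, 5.0],
            "trt_a": [15.0, 10.0, 4.0, 20.0],
            "ctrl_b": [10.0, 8.0, 9.0, 1.0],
            "trt_b": [5.0, 8.0, 27.0, 1.0],
        },
        index=["p1", "p2", "p3", "p4"],
    )
    df.index.name = "probe_id"
    return ExpressionMatrix(df)


@pytest.fixture
def tiny_design():
    return ComparisonDesign(
        pd.DataFrame(
            {
                "comparison_id": ["c1", "c2"],
                "group": ["EG1", "EG2"],
                "treated": ["trt_a", "trt_b"],
                "control": ["ctrl_a", "ctrl_b"],
                "model": ["HUVEC", "HUVEC"],
            }
        )
    )


@pytest.fixture
def tiny_map():
    return ProbeGeneMap(
        pd.DataFrame(
            {
                "probe_id": ["p1", "p2", "p3", "p4"],
                "gene_symbol": ["gA", "gA", "gB", "gC"],
            }
        )
    )


def make_design(n_eg1: int, n_eg2: int) -> ComparisonDesign:
    rows = []
    for g, n in (("EG1", n_eg1), ("EG2", n_eg2)):
        for i in range(n):
            cid = f"{g}_{i + 1:02d}"
            rows.append((cid, g, f"T_{cid}", f"C_{cid}", "M"))
    return ComparisonDesign(
        pd.DataFrame(rows, columns=["comparison_id", "group", "treated", "control", "model"])
    )
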