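import numpy as np
import pandas as pd
import pytest

from arecamir.io import ExpressionMatrix, load_panel_table


@pytest.fixture(scope="session")
def oncomir_table():
    return load_panel_table("oncomir")


@pytest.fixture(scope="session")
def tsmir_table():
    return load_panel_table("tsmir")


@pytest.fixture
def toy_paired_matrix():
    """3-miRNA, 2-line paired experiment with hand-computable ratios.

    Per line, one parental and one exposed chip.  mirA doubles in both
    lines, mirB halves in both, mirC is unchanged.
    """
    values = pd.DataFrame(
        {
            "L1_parental_0": [100.0, 200.0, 50.0],
            "L1_exposed_0": [200.0, 100.0, 50.0],
            "L2_parental_0": [80.0, 400.0, 10.0],
            "L2_exposed_0": [160.0, 200.0, 10.0],
        },
        index=["mirA", "mirB", "mirC"],
    )
    ann = pd.DataFrame(
        {
            "cell_line": ["L1", "L1", "L2", "L2"],
            "condition": ["parental", "exposed", "parental", "exposed"],
        },
        index=values.columns,
    )
    return ExpressionMatrix(values, ann)


@pytest.fixture
def small_cohort_matrix():
    """4 tumors + 3 normals, 2 miRNAs; mir1 doubled in tumors."""
    rng = np.random.default_rng(7)
    normal_profile = np.array([100.0, 300.0])
    cols, data, ann = [], [], []
    for j in range(4):
        cols.append(f"tumor_{j}")
        data.append(normal_profile * np.array([2.0, 1.0]) * np.exp(rng.normal(0, 0.05, 2)))
        ann.append({"sample": cols[-1], "tissue": "tumor"})
    for j in range(3):
        cols.append(f"normal_{j}")
        data.append(normal_profile * np.exp(rng.normal(0, 0.05, 2)))
        ann.append({"sample": cols[-1], "tissue": "normal"})
    values = pd.DataFrame(np.column_stack(data), index=["mir1", "mir2"], columns=cols)
    return ExpressionMatrix(values, pd.DataFrame(ann).set_index("sample"))
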