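import numpy as np
import pandas as pd
import pytest

from wntcrd import (
    LIPID_PROTEIN,
    PROTEIN_PROTEIN,
    DescriptorMatrix,
    builtin_models,
    fixture_frame,
    fixture_table2,
)


@pytest.fixture(scope="session")
def table2():
    """Packaged experimental comparison table as printed (23 rows)."""
    return fixture_frame()


@pytest.fixture(scope="session")
def table2_data():
    """(measurements, published predictions) for the 23 complexes."""
    return fixture_table2()


@pytest.fixture(scope="session")
def models():
    return builtin_models()


@pytest.fixture
def small_matrix():
    """5 complexes x (4 protein + 2 lipid) deterministic descriptor matrix."""
    rng = np.random.default_rng(42)
    names_pp = ["a_pp", "b_pp", "c_pp", "d_pp"]
    names_lp = ["x_lp", "y_lp"]
    data = pd.DataFrame(
        {n: rng.normal(0, 5, 5) for n in names_pp}
        | {n: rng.lognormal(3.0, 0.3, 5) for n in names_lp},
        index=[f"cpx{i}" for i in range(5)],
    )
    classes = {n: PROTEIN_PROTEIN for n in names_pp} | {n: LIPID_PROTEIN for n in names_lp}
    return DescriptorMatrix(data=data, classes=classes)
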