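import numpy as np
import pytest

import stemomics as st


@pytest.fixture(scope="session")
def demo_dataset():
    """Small paired dataset with planted structure (seed fixed)."""
    cfg = st.SimulationConfig(seed=17, glucose=("plus",))
    dataset, truth = st.simulate_dataset(cfg)
    return dataset, truth


@pytest.fixture()
def toy_sheet():
    return st.SampleSheet(
        ["p1", "p2", "p3", "s1", "s2", "s3"],
        ["P", "P", "P", "S", "S", "S"],
        ["plus"] * 6,
        [1.0, 1.0, 1.0, 1.0, 1.0, 1.0],
    )


@pytest.fixture()
def toy_conc(toy_sheet):
    rng = np.random.default_rng(5)
    vals = rng.lognormal(3.0, 0.2, size=(4, 6))
    return st.FeatureMatrix(
        ["NAAD+", "NAADP+", "lactate", "alanine"],
        list(toy_sheet.sample_id),
        vals,
        st.MatrixKind.metabolite_conc,
    )
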