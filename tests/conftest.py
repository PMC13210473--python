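import numpy as np
import pandas as pd
import pytest

from discordia import OmicsMatrix, SynthConfig, generate_multiomics


@pytest.fixture
def design_3x2() -> pd.Series:
    samples = ["CK_1", "CK_2", "DT_1", "DT_2", "DTR_1", "DTR_2"]
    return pd.Series(["CK", "CK", "DT", "DT", "DTR", "DTR"], index=samples)


@pytest.fixture
def design_2x3() -> pd.Series:
    samples = ["A_1", "A_2", "A_3", "B_1", "B_2", "B_3"]
    return pd.Series(["A", "A", "A", "B", "B", "B"], index=samples)


def make_matrix(rows: dict, design: pd.Series, layer: str = "protein") -> OmicsMatrix:
    df = pd.DataFrame.from_dict(rows, orient="index", columns=list(design.index), dtype=float)
    return OmicsMatrix(values=df, layer=layer, design=design)


@pytest.fixture(scope="session")
def noiseless_config() -> SynthConfig:
    # beta1 = 0.3 keeps every structured protein delta clear of the 1.2
    # fold-change threshold, so threshold sets are unambiguous without noise
    return SynthConfig(
        n_genes=600,
        seed=42,
        beta1=0.3,
        sigma_rna=0.0,
        sigma_prot=0.0,
        sigma_ptm=0.0,
        gamma_phos=0.0,
        gamma_acet=0.0,
        missing_mcar_rate=0.0,
        mnar_logistic_slope=0.0,
    )


@pytest.fixture(scope="session")
def noiseless_dataset(noiseless_config):
    return generate_multiomics(noiseless_config)


@pytest.fixture(scope="session")
def noisy_dataset():
    return generate_multiomics(SynthConfig(n_genes=500, seed=9))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
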