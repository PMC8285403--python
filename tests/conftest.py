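import numpy as np
import pandas as pd
import pytest

from cardiomr.summary_stats import harmonize
from cardiomr.synthetic import GeneratorConfig, generate_dataset


def make_config(seed: int, **overrides) -> GeneratorConfig:
    """Strong-instrument baseline scenario used across tests."""
    params = dict(
        n_variants=50,
        n_exposure=300_000,
        n_outcome=50_000,
        true_beta=0.2,
        instrument_r2_total=0.1,
        seed=seed,
        palindromic_fraction=0.0,
        allele_swap_fraction=0.3,
    )
    params.update(overrides)
    return GeneratorConfig(**params)


@pytest.fixture
def harmonized_set():
    """One harmonized generator dataset with strong instruments."""
    exposure, outcome, _ld, _truth = generate_dataset(make_config(seed=7))
    return harmonize(exposure, outcome)


@pytest.fixture
def assoc_frame():
    """Tiny hand-built association table."""
    return pd.DataFrame(
        {
            "variant_id": ["rs1", "rs2", "rs3"],
            "effect_allele": ["A", "C", "G"],
            "other_allele": ["G", "T", "A"],
            "eaf": [0.2, 0.3, 0.4],
            "beta": [0.10, 0.08, -0.05],
            "se": [0.01, 0.01, 0.02],
            "p_value": [1e-10, 1e-9, 1e-3],
            "n": [1000.0, 1000.0, 1000.0],
        }
    )


def write_tsv(path, df):
    df.to_csv(path, sep="\t", index=False)
    return path
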