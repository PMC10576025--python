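import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from splicebalance.model import ModelParams
from splicebalance.sequences import wobble_vector
from splicebalance.synthetic import build_synthetic_assay


def assay_to_dataset(assay) -> pd.DataFrame:
    """Truth sidecar + counts -> model-ready dataset table (test helper)."""
    counts = assay.counts.groupby("barcode", sort=False, as_index=False)[
        ["n_inclusion", "n_skipping", "n_other"]
    ].sum()
    df = assay.truth.merge(counts, on="barcode").rename(columns={"barcode": "id"})
    df["psi"] = df["n_inclusion"] / (df["n_inclusion"] + df["n_skipping"])
    df["wobble"] = [
        "".join(str(int(v)) for v in wobble_vector(s, st))
        for s, st in zip(df["sequence"], df["structure"])
    ]
    return df


@pytest.fixture(scope="session")
def small_assay():
    return build_synthetic_assay(n_exons=300, depth=200, seed=11)


@pytest.fixture(scope="session")
def small_dataset(small_assay) -> pd.DataFrame:
    return assay_to_dataset(small_assay)


@pytest.fixture(scope="session")
def random_model() -> ModelParams:
    return ModelParams.default(seed=7)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
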