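import numpy as np
import pandas as pd
import pytest

from retrolib.simulate import (
    default_chassis_catalog,
    default_ground_truth,
    make_editing_site,
    synthetic_annotation,
)


@pytest.fixture(scope="session")
def ann():
    return synthetic_annotation(seed=0)


@pytest.fixture(scope="session")
def ground_truth(ann):
    return default_ground_truth(ann)


@pytest.fixture(scope="session")
def site():
    return make_editing_site(seed=1)


@pytest.fixture(scope="session")
def chassis(ann):
    return default_chassis_catalog(ann, n=25, seed=0)


def make_count_table(rng, n_variants, kind):
    """Random CountTable (one replicate) for oracle-equivalence tests."""
    from retrolib.quantify import CountTable

    ids = [f"v{i}" for i in range(n_variants)]
    if kind == "msdna":
        roles = ["plasmid_pre", "plasmid_post", "msdna"]
    else:
        roles = ["plasmid_t0", "plasmid_t24", "plasmid_t48", "genome_t48"]
    counts = {}
    samples = {}
    for role in roles:
        counts[role] = rng.integers(0, 200, size=n_variants)
        samples[role] = {"role": role, "replicate": "rep1", "site": "s1"}
    counts_df = pd.DataFrame(counts, index=pd.Index(ids, name="variant_id"))
    # keep the wild type covered so msdna normalization is defined
    counts_df.iloc[0] = np.maximum(counts_df.iloc[0], 1)
    return CountTable(counts=counts_df, samples=pd.DataFrame(samples).T.rename_axis("sample"))
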