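import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from dualtarget import DiseaseMeta, SimConfig

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


#: Compact disease layout spanning all four AAD classes plus NAADs, for
#: tests that do not need the full 33-disease study geometry.
SMALL_DISEASES = (
    DiseaseMeta("aad_neuro", "AAD", "neurological", 5),
    DiseaseMeta("aad_metab", "AAD", "metabolic", 5),
    DiseaseMeta("aad_inflam", "AAD", "inflammatory", 4),
    DiseaseMeta("aad_fibro", "AAD", "fibrotic", 4),
    DiseaseMeta("naad_neuro", "NAAD", "neurological", 4),
    DiseaseMeta("naad_infect", "NAAD", "infectious", 3),
    DiseaseMeta("naad_inflam", "NAAD", "inflammatory", 5),
)


@pytest.fixture
def small_config():
    return SimConfig(
        seed=11,
        n_genes=300,
        diseases=SMALL_DISEASES,
        n_planted_aad=8,
        n_planted_common=4,
        list_length=40,
    )


def make_records(rows):
    """Comparison-record DataFrame from (gene, comparison_id, disease, logfc,
    category, disease_class) tuples."""
    return pd.DataFrame(
        rows,
        columns=["gene", "comparison_id", "disease", "logfc", "category", "disease_class"],
    )


def aad_records(gene, logfcs, disease_class="neurological", start=0):
    """AAD records for one gene/class from a vector of logFC values."""
    return [
        (gene, f"{disease_class}|c{start + i}", f"dis_{disease_class}", x, "AAD", disease_class)
        for i, x in enumerate(logfcs)
    ]


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
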