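import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from icibench.simulate import SimulationConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


#: compact configuration for machinery tests (not the study conditions)
SMALL_CONFIG = SimulationConfig(
    n_mut=12,
    n_wt=48,
    n_genes=60,
    background_mutation_rate_mut=30.0,
    background_mutation_rate_wt=15.0,
    seed=2024,
)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(SMALL_CONFIG)


@pytest.fixture(scope="session")
def default_cohort():
    """One cohort at the study conditions (63 mutant / 599 wildtype)."""
    return generate_cohort(SimulationConfig(seed=7))


@pytest.fixture()
def toy_maf(tmp_path):
    df = pd.DataFrame(
        {
            "Tumor_Sample_Barcode": ["S1", "S1", "S2", "S3", "S3"],
            "Hugo_Symbol": ["NOTCH4", "TP53", "KRAS", "NOTCH4", "NOTCH4"],
            "Variant_Classification": [
                "Missense_Mutation", "Silent", "Nonsense_Mutation",
                "Frame_Shift_Del", "Splice_Site",
            ],
            "assay_id": ["WES"] * 5,
        }
    )
    path = tmp_path / "toy.maf.tsv"
    df.to_csv(path, sep="\t", index=False)
    return path


def survival_frame(times, events, covariate=None):
    df = pd.DataFrame({"time": np.asarray(times, float), "event": np.asarray(events, int)})
    if covariate is not None:
        df["x"] = np.asarray(covariate, float)
    return df
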