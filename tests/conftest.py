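import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

import methdeconv as md

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def four_type_reference():
    """Planted-marker reference over the four main compartments.

    6 replicates/type, 40 markers/type with a 0.8 beta contrast and 0.02
    replicate noise — the regime where one-vs-all selection at the panel
    thresholds must recover the planted sets exactly.
    """
    return md.generate_synthetic_reference(
        cell_types=("TC", "Epi", "Fib", "IC"),
        replicates_per_type=6,
        n_probes=1500,
        n_informative_per_type=40,
        informative_delta=0.8,
        replicate_noise_sd=0.02,
        seed=7,
        shared_blocks=None,
    )


@pytest.fixture(scope="session")
def noiseless_reference():
    """Replicate-noise-free 10-type reference (exact planted profiles)."""
    return md.generate_synthetic_reference(
        replicates_per_type=2,
        n_probes=1000,
        n_informative_per_type=40,
        replicate_noise_sd=0.0,
        seed=3,
    )


@pytest.fixture(scope="session")
def exact_mixtures(noiseless_reference):
    """A full-rank signature with 60 noiseless mixtures of its own columns."""
    types = list(md.DEFAULT_CELL_TYPES)
    profiles = md.build_profile_matrix(
        noiseless_reference, {t: 2 for t in types}, seed=1
    )
    signature = md.SignatureMatrix(profiles.values.copy(), aggregator="mean")
    comps = md.sample_compositions(60, types, seed=11)
    return signature, md.mix(profiles, comps)


@pytest.fixture(scope="session")
def nine_type_reference():
    """Tumor-free 9-type reference for the immune-cap scenario sweep."""
    return md.generate_synthetic_reference(
        cell_types=("Epi", "Fib") + md.IMMUNE_SUBTYPES,
        replicates_per_type=12,
        n_probes=3000,
        n_informative_per_type=50,
        informative_delta=0.8,
        replicate_noise_sd=0.02,
        seed=5,
    )


@pytest.fixture()
def tiny_labeled_reference():
    """Hand-built 2-type reference with known betas for arithmetic checks."""
    values = pd.DataFrame(
        {
            "s1": [0.2, 0.9, 0.5],
            "s2": [0.4, 0.7, 0.5],
            "t1": [0.8, 0.1, 0.5],
            "t2": [0.6, 0.3, 0.5],
        },
        index=["cg1", "cg2", "cg3"],
    )
    labels = pd.Series(
        {"s1": "alpha", "s2": "alpha", "t1": "beta", "t2": "beta"}
    )
    return md.LabeledReference(md.BetaMatrix(values), labels)


def composition_from_array(arr, cell_types=None, sample_ids=None):
    arr = np.asarray(arr, dtype=float)
    cell_types = cell_types or [f"ct{i}" for i in range(arr.shape[0])]
    sample_ids = sample_ids or [f"s{j}" for j in range(arr.shape[1])]
    return md.CompositionMatrix(
        pd.DataFrame(arr, index=cell_types, columns=sample_ids)
    )
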