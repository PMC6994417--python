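import pytest

from somatic_screen import generate_cohort, load_reference_profile
from somatic_screen.io_model import CohortProfile
from somatic_screen.pipeline import run_targeted_cascade, run_wes_cascade

REFERENCE_SEED = 42


@pytest.fixture(scope="session")
def profile():
    return load_reference_profile()


@pytest.fixture(scope="session")
def bundle(profile):
    return generate_cohort(profile, REFERENCE_SEED)


@pytest.fixture(scope="session")
def wes_result(bundle):
    return run_wes_cascade(bundle)


@pytest.fixture(scope="session")
def targeted_result(bundle):
    return run_targeted_cascade(bundle)


SMALL_PROFILE_DICT = {
    "name": "small",
    "seed": 7,
    "n_discovery": 4,
    "n_extension": 6,
    "n_matched_pairs": 2,
    "n_matched_discovery": 1,
    "n_pon": 3,
    "n_hyperplastic": 2,
    "n_rna": 3,
    "exome_mb": 10.0,
    "titv_ratio": 2.0,
    "gc_bias": 0.6,
    "germline_per_tumor": 8,
    "artifacts_per_tumor": 4,
    "germline_pool": 30,
    "artifact_pool": 10,
    "n_context_duplicated": 2,
    "gene_freqs": {"GENEA": 3, "GENEB": 2, "GENEC": 1},
    "literature_genes": ["GENEX", "GENEY"],
    "per_sample_burden": [8, 6, 5, 4],
    "stability_plan": {"GENEA": {"missense": 2, "destabilizing": 1}},
    "survival": None,
}


@pytest.fixture()
def small_profile():
    return CohortProfile.from_dict(dict(SMALL_PROFILE_DICT))
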