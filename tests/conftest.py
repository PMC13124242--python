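import numpy as np
import pytest
from hypothesis import settings

from karyokit.db import build_feature_db
from karyokit.simulate import ToyGenomeSpec, make_diploid, make_reference

settings.register_profile("ci", deadline=None, derandomize=True)
settings.load_profile("ci")


# A miniature genome (chromosomes ~9 kbp) for exhaustive brute-force oracles.
SMALL_SPEC = ToyGenomeSpec(
    seed=11,
    n_chrom=2,
    arm_len=(2_000, 2_600),
    telomere_copies=100,
    centromere_copies=20,
)

# Full-scale toy genome matching the classifier's default thresholds
# (12 kbp telomeres, ~68 kbp centromeres, 45-55 kbp arms).
TOY_SPEC = ToyGenomeSpec(seed=1, n_chrom=3)


@pytest.fixture(scope="session")
def small_ref():
    return make_reference(SMALL_SPEC)


@pytest.fixture(scope="session")
def small_db(small_ref):
    return build_feature_db(small_ref.sequences, small_ref.annotation, 31)


@pytest.fixture(scope="session")
def toy_ref():
    return make_reference(TOY_SPEC)


@pytest.fixture(scope="session")
def toy_db(toy_ref):
    return build_feature_db(toy_ref.sequences, toy_ref.annotation, 31)


@pytest.fixture(scope="session")
def toy_diploid(toy_ref):
    return make_diploid(toy_ref, het_rate=1e-3, seed=3)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
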