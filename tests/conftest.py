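import numpy as np
import pytest

from chromx.genodata import MISSING, GenotypeDataset, SampleRecord, VariantInfo
from chromx.simulate import SimConfig, simulate_cohort


def random_dataset(rng, n_samples=10, n_variants=7, allow_invalid_male=False):
    """Random valid X dataset; males hemizygous 0/1 unless invalid allowed."""
    variants = [
        VariantInfo(f"rs{j + 1}", "X", 1000 + 10 * j, "A", "C") for j in range(n_variants)
    ]
    samples = []
    calls = np.empty((n_samples, n_variants), dtype=np.int8)
    for i in range(n_samples):
        male = bool(rng.integers(0, 2))
        samples.append(
            SampleRecord(
                iid=f"I{i + 1}",
                sex="male" if male else "female",
                group="case" if rng.integers(0, 2) else "control",
            )
        )
        if male:
            opts = [0, 1, MISSING] + ([2] if allow_invalid_male else [])
        else:
            opts = [0, 1, 2, MISSING]
        calls[i] = rng.choice(opts, n_variants)
    return GenotypeDataset(samples=samples, variants=variants, calls=calls)


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (915 children, 7 SNPs), seed 0."""
    return simulate_cohort(SimConfig(seed=0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
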