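import numpy as np
import pytest

from deshkit.phantom import PhantomSpec, PhenotypeFlags, render_phantom, sample_cohort

DESH_FLAGS = PhenotypeFlags(desh=True, vd=True, thc=True, sfd=True)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def desh_subject():
    spec = PhantomSpec(phenotype=DESH_FLAGS, contrast="T2_like", seed=7)
    return render_phantom(spec, age_years=78.0, sex="male", subject_id="desh-7")


@pytest.fixture(scope="session")
def normal_subject():
    spec = PhantomSpec(phenotype=PhenotypeFlags(), contrast="T2_like", seed=11)
    return render_phantom(spec, age_years=48.0, sex="female", subject_id="normal-11")


@pytest.fixture(scope="session")
def small_cohort():
    """Balanced 12-phantom cohort shared across tests (order shuffled)."""
    subjects, manifest = sample_cohort(12, 0.5, "T2_like", seed=21)
    order = np.random.default_rng(0).permutation(len(subjects))
    return [subjects[i] for i in order], manifest
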