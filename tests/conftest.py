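import numpy as np
import pytest

from t1bh import phantom as ph


def small_config(**overrides) -> ph.PhantomConfig:
    """A desk-scale phantom: small grid, few lesions, fast to rasterize."""
    base = dict(
        grid_shape=(72, 72, 72),
        n_patients=4,
        bh_count=(6.0, 3.0),
        pure_flair_count=(5.0, 3.0),
        ce_fraction=0.5,
        seed=123,
    )
    base.update(overrides)
    return ph.PhantomConfig(**base)


@pytest.fixture
def small_cfg():
    return small_config()


@pytest.fixture(scope="session")
def small_patient():
    """One rasterized phantom patient shared by read-only tests."""
    cfg = small_config()
    return cfg, ph.generate_patient(cfg, ph.patient_seed_for(cfg.seed, 0), "P000")


@pytest.fixture(scope="session")
def cohort_dir(tmp_path_factory):
    """A 5-patient phantom cohort written to disk, shared by pipeline tests."""
    cfg = small_config(n_patients=5, seed=77)
    cohort = ph.generate_cohort(cfg)
    out = tmp_path_factory.mktemp("cohort")
    manifest = ph.write_cohort(cohort, out)
    return out, manifest, cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
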