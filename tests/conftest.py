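import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import airrshare as a

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture
def single_path_model():
    """Degenerate model: every sample is CASSF from V1/J1 with pgen 1."""
    return a.ToyGenerativeModel(
        v_segments=(("V1", "CASS", 1.0),),
        j_segments=(("J1", "F", 1.0),),
        junction_length_dist={0: 1.0},
        residue_dist={"A": 1.0},
    )


@pytest.fixture
def four_receptor_model():
    """2 equiprobable V, 1 J, middle length 1, residues uniform over {A, G}:
    exactly 4 generatable receptors, each with probability 0.25."""
    return a.ToyGenerativeModel(
        v_segments=(("V1", "CASS", 0.5), ("V2", "CASR", 0.5)),
        j_segments=(("J1", "F", 1.0),),
        junction_length_dist={1: 1.0},
        residue_dist={"A": 0.5, "G": 0.5},
    )


@pytest.fixture(scope="session")
def default_model():
    return a.default_toy_model()


@pytest.fixture(scope="session")
def signal_model():
    return a.default_signal_model()


@pytest.fixture(scope="session")
def public_model():
    return a.default_public_model()


@pytest.fixture(scope="session")
def low_pgen_pool(default_model):
    """25 rare sequences (pgen <= 1e-12) drawn once from a reference pool."""
    pool = a.build_reference_pool(a.ToyEngine(default_model), 30_000, 999)
    picked = [r for r in pool if r.pgen <= 1e-12][:25]
    assert len(picked) == 25
    return picked


@pytest.fixture(scope="session")
def corrected_cohort():
    """A moderate incidence-corrected cohort reused across invariant tests."""
    cfg = a.SimConfig(n_repertoires=200, depth=1000, positive_fraction=0.5, seed=7)
    return cfg, a.correct_public_component(cfg)


def make_dataset(spec, manifest=()):
    """Tiny labeled dataset from {rep_id: (label, [receptors])}."""
    reps = [
        a.Repertoire(rid, label, set(recs)) for rid, (label, recs) in spec.items()
    ]
    return a.RepertoireDataset(reps, list(manifest))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
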