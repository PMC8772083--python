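import numpy as np
import pytest

from cfplasma.simulate import FragmentLengthModel, SimConfig, simulate_study


@pytest.fixture(scope="session")
def study_uniform100():
    """Matched study at uniform 100x depth, tf = 0.30 (caller's easy regime)."""
    cfg = SimConfig(seed=11, depth_germline=100.0, depth_tumour=100.0,
                    depth_plasma=100.0)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_lowtf():
    """Same design at tf = 0.005 — the sub-percent tumour-fraction regime."""
    cfg = SimConfig(seed=12, plasma_tumour_fraction=0.005,
                    depth_germline=100.0, depth_tumour=100.0,
                    depth_plasma=100.0, n_plasma_fragments=2000)
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_equal_lengths():
    """Tumour-derived and background fragments share one length model."""
    model = dict(mono_weight=0.85, di_weight=0.15)
    cfg = SimConfig(seed=13,
                    background_fragment_model=FragmentLengthModel(**model),
                    tumour_fragment_model=FragmentLengthModel(**model))
    return simulate_study(cfg)


@pytest.fixture(scope="session")
def study_clean():
    """Error-free study (base_error_rate = 0) at default depths."""
    cfg = SimConfig(seed=14, base_error_rate=0.0, n_plasma_fragments=2000)
    return simulate_study(cfg)


@pytest.fixture
def small_config():
    """A fast, fully-featured configuration for functional tests."""
    return SimConfig(seed=5, genome_length=100_000, n_chromosomes=1,
                     n_germline_variants=40, n_tumour_mutations=60,
                     n_background_mutations=60, n_error_sites=40,
                     n_plasma_fragments=20_000)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
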