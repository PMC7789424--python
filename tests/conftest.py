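import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import crisprbf as cbf

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def default_screen():
    """The default study-condition screen (1000 genes x 4 guides, 2 reps)."""
    return cbf.generate_screen(cbf.ScreenConfig(seed=1))


@pytest.fixture(scope="session")
def default_fc(default_screen):
    return cbf.compute_fold_change(default_screen.counts,
                                   default_screen.control_sample)


@pytest.fixture(scope="session")
def default_cv_results(default_screen, default_fc):
    """Cross-validation fit with multi-target correction on the default screen."""
    return cbf.run_classifier(
        default_fc, default_screen.essential_ref,
        default_screen.nonessential_ref, method="cv", seed=1,
        target_map=default_screen.target_map,
    )


@pytest.fixture(scope="session")
def small_screen():
    """A quick 150-gene screen for unit-level pipeline tests.

    The per-locus BF increments are milder than the default because a
    150-gene screen cannot realise the full-size targets (the required
    depletion would outrun the BF response; the generator refuses).
    """
    return cbf.generate_screen(cbf.ScreenConfig(
        n_genes=150, bf_per_perfect=2.0, bf_per_1bp=0.8, seed=3))


@pytest.fixture(scope="session")
def small_fc(small_screen):
    return cbf.compute_fold_change(small_screen.counts,
                                   small_screen.control_sample)


@pytest.fixture
def rng():
    return np.random.default_rng(2026)
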