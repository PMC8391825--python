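import warnings

import pytest

from ordinoise import regressor as R

# analyses at mismatched lengths are exercised deliberately in several tests
warnings.filterwarnings("ignore", message="series length .* differs from the model")


@pytest.fixture(scope="session")
def tiny_model():
    """Small, fast regressor for plumbing tests (not for accuracy claims)."""
    ts = R.build_training_set(
        alpha_grid=[0.0, 0.75, 1.5, 2.25, 3.0],
        series_per_alpha=6,
        series_length=4096,
        seed=11,
    )
    return R.train(ts, seed=11)


@pytest.fixture(scope="session")
def default_model():
    """Full-scale regressor: alpha in [0,3] step 0.05, 20 series/alpha, N=2**14."""
    ts = R.build_training_set(seed=1)
    return R.train(ts, seed=1)
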