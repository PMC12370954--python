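import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import selfthin as st

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def small_dataset():
    """12-plot synthetic study at default truth (stand-level only)."""
    cfg = st.GeneratorConfig(n_plots=12, n_control=6)
    return st.gen_dataset(cfg, seed=1, tree_level=False)


@pytest.fixture(scope="session")
def tree_dataset():
    """6-plot synthetic study with tree-level records for pipeline tests."""
    cfg = st.GeneratorConfig(n_plots=6, n_control=3)
    return st.gen_dataset(cfg, seed=2, tree_level=True)


@pytest.fixture(scope="session")
def composite_fit():
    """One composite-variant mortality fit at the reference truth (shared)."""
    truth = st.TruthParams.composite()
    ds = st.gen_dataset(st.GeneratorConfig(), truth=truth, seed=7, tree_level=False)
    model = st.MortalityModel.from_dataframe(
        ds.model_frame(), variant="eq_composite", mat_center=truth.mat_center)
    return ds, model.fit(seed=0, n_draws=1000)


def make_static_sim(seed, n_plots=40, n_obs=8, alpha0=12.29, alpha1=-1.67, alpha2=-0.09,
                    sigma_a0=0.12, sigma=0.06):
    """Data simulated directly from the static allometry (known truth)."""
    rng = np.random.default_rng(seed)
    plot = np.repeat(np.arange(n_plots), n_obs)
    mat = rng.uniform(9.5, 12.5, n_plots)
    a0j = alpha0 + rng.normal(0, sigma_a0, n_plots)
    logd = np.log(rng.uniform(15, 80, n_plots * n_obs))
    logn = (a0j[plot] + alpha1 * logd + alpha2 * (mat[plot] - mat.mean())
            + rng.normal(0, sigma, n_plots * n_obs))
    return logn, logd, mat[plot], plot, mat.mean()
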