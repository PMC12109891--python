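import numpy as np
import pytest

from pglogit import (
    ModelSpec,
    PanelDataset,
    SimConfig,
    apply_filters,
    build_design,
    generate_panel,
)
from pglogit.variables import simple_scheme


def make_simple_panel(
    n_respondents=200,
    k=10,
    seed=7,
    beta_seed=123,
    beta_scale=0.5,
    sigma_alpha=1.0,
    ensure_nonconstant=True,
    degenerate_fractions=None,
):
    """Synthetic panel with k Gaussian covariates plus its true beta."""
    rng = np.random.default_rng(beta_seed)
    beta = rng.normal(0.0, beta_scale, k)
    kwargs = dict(
        n_respondents=n_respondents,
        true_beta={f"x{j + 1}": b for j, b in enumerate(beta)},
        true_sigma_alpha=sigma_alpha,
        covariate_scheme=simple_scheme(k),
        seed=seed,
        ensure_nonconstant=ensure_nonconstant,
    )
    if degenerate_fractions is not None:
        kwargs["degenerate_fractions"] = degenerate_fractions
    return generate_panel(SimConfig(**kwargs)), beta


def simple_design(table, k):
    spec = ModelSpec(model_id="custom", covariate_names=[f"x{j + 1}" for j in range(k)])
    return build_design(table, spec, simple_scheme(k))


@pytest.fixture(scope="session")
def small_fitted_draws():
    """A converged small fit shared by summary-level tests."""
    from pglogit import SamplerConfig, run_gibbs

    table, beta = make_simple_panel(n_respondents=60, k=3, seed=11)
    data = simple_design(table, 3)
    draws = run_gibbs(data, config=SamplerConfig(n_iter=1200, n_burn=400, n_chains=2, seed=5))
    return data, draws


@pytest.fixture
def tiny_dataset():
    """3 respondents x 5 waves, 1 covariate; deterministic fixture."""
    rng = np.random.default_rng(77)
    x = rng.normal(size=15)
    ridx = np.repeat(np.arange(3), 5)
    y = np.array([1, 0, 1, 1, 0, 0, 0, 1, 0, 1, 1, 1, 0, 1, 0], dtype=float)
    return PanelDataset(y, x[:, None], ridx, np.array(["a", "b", "c"]))
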