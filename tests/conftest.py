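import numpy as np
import pandas as pd
import pytest

from covrn.data import TraitDataset
from covrn.inference import MCMCConfig, fit
from covrn.modelspec import CRNModelSpec, FamilySpec, build_model, spec_for_dataset
from covrn.simulate import (
    SimConfig,
    simulate_intergenerational,
    simulate_intraindividual,
    simulate_marmot_like,
    simulate_sheep_like,
)


@pytest.fixture(scope="session")
def small_cfg():
    return SimConfig(n_years=6, recruits_per_year=8, seed=3)


@pytest.fixture(scope="session")
def interg_small(small_cfg):
    return simulate_intergenerational(small_cfg)


@pytest.fixture(scope="session")
def intra_small(small_cfg):
    return simulate_intraindividual(small_cfg)


@pytest.fixture(scope="session")
def sheep_small(small_cfg):
    return simulate_sheep_like(small_cfg)


@pytest.fixture(scope="session")
def marmot_small(small_cfg):
    return simulate_marmot_like(small_cfg)


def make_full_dataset(seed=1, n_ctx=5, n_ind=12, n_rep=3):
    """Paired repeated measurements of two Gaussian traits, with both an
    among-individual and a within-individual context-dependent correlation."""
    rng = np.random.default_rng(seed)
    rows1, rows2, ctx_rows = [], [], []
    for c in range(n_ctx):
        clim = rng.standard_normal()
        ctx_rows.append((f"c{c}", clim))
        r_a = np.tanh(0.3 + 0.5 * clim)
        r_e = np.tanh(-0.4)
        for i in range(n_ind):
            z = rng.standard_normal(2)
            a1 = 0.4 * z[0]
            a2 = 0.3 * (r_a * z[0] + np.sqrt(1 - r_a**2) * z[1])
            for _ in range(n_rep):
                z = rng.standard_normal(2)
                e1 = 0.5 * z[0]
                e2 = 0.4 * (r_e * z[0] + np.sqrt(1 - r_e**2) * z[1])
                rows1.append((f"i{i}", f"c{c}", 0.2 * clim + a1 + e1, clim))
                rows2.append((f"i{i}", f"c{c}", -0.1 * clim + a2 + e2, clim))
    cols = ["individual", "context", "value", "climate"]
    return TraitDataset(
        pd.DataFrame(rows1, columns=cols),
        pd.DataFrame(rows2, columns=cols),
        pd.DataFrame(ctx_rows, columns=["context", "climate"]),
        design="full",
        families=("gaussian", "gaussian"),
    )


@pytest.fixture(scope="session")
def full_dataset():
    return make_full_dataset()


@pytest.fixture(scope="session")
def full_spec():
    return CRNModelSpec(
        "full",
        FamilySpec("gaussian"),
        FamilySpec("gaussian"),
        covariates1=["climate"],
        covariates2=["climate"],
        corr_covariates=["climate"],
    )


@pytest.fixture(scope="session")
def tiny_fit():
    """A small but real posterior used by inference/postprocess tests."""
    cfg = SimConfig(n_years=8, recruits_per_year=15, seed=7)
    ds, gt = simulate_intraindividual(cfg)
    model = build_model(spec_for_dataset(ds), ds)
    result = fit(model, MCMCConfig(n_chains=2, n_warmup=300, n_samples=300, max_treedepth=7, seed=2))
    return ds, gt, model, result
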