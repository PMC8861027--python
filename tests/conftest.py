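import numpy as np
import pandas as pd
import pytest

from fluxdry.pipeline import RunConfig, prepare_site
from fluxdry.synthetic import TruthParams, simulate_site


@pytest.fixture(scope="session")
def default_params() -> TruthParams:
    return TruthParams()


@pytest.fixture(scope="session")
def one_year_site():
    """One simulated site-year at default parameters."""
    return simulate_site(TruthParams(n_days=365, seed=0), 0)


@pytest.fixture(scope="session")
def clean_site():
    """Zero-noise, gap-free site (closure tests)."""
    params = TruthParams(n_days=120, seed=0, noise_sd_rel=0.0,
                         qc_bad_frac=0.0, missing_frac=0.0)
    return simulate_site(params, 0)


@pytest.fixture(scope="session")
def prepped_three_year():
    """A fully prepped 3-year site (selection, z-scores, bin labels)."""
    params = TruthParams(n_days=1095, seed=0)
    series = simulate_site(params, 1)
    prep = prepare_site(series, RunConfig())
    assert prep is not None
    return params, prep


def make_linear_days(n, coeffs, sigma, rng, corr=-0.5):
    """Standardized daily table whose response is linear in the drivers."""
    L = np.linalg.cholesky(np.array([[1.0, corr], [corr, 1.0]]))
    sv = rng.standard_normal((n, 2)) @ L.T
    ta = rng.standard_normal(n)
    rg = rng.standard_normal(n)
    gpp = (coeffs.get("swc", 0.0) * sv[:, 0] + coeffs.get("vpd", 0.0) * sv[:, 1]
           + coeffs.get("ta", 0.0) * ta + coeffs.get("rg", 0.0) * rg
           + sigma * rng.standard_normal(n))
    idx = pd.date_range("2015-06-01", periods=n, freq="D")
    return pd.DataFrame({"swc": sv[:, 0], "vpd": sv[:, 1], "ta": ta, "rg": rg,
                         "gpp_nt": gpp}, index=idx)
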