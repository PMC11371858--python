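"""Shared fixtures: canonical parameter sets and small simulated studies.

The "pooled" parameter set is the canonical moderately-heritable,
shared-environment-heavy configuration used throughout: A = (0.47,
0.28), C = (0.34, 0.51) for (RSI, CI), factor correlations rA = 0.74,
rC = 0.47, rE = 0.48, thresholds at the normal quantiles of 33.2% and
29.5% lifetime prevalence.
"""

import numpy as np
import pytest

from twinace import BivariateACEParams, margin_threshold, simulate_pairs


POOLED = dict(a=(0.47, 0.28), c=(0.34, 0.51), r_a=0.74, r_c=0.47, r_e=0.48)
POOLED_PREV = (0.332, 0.295)


@pytest.fixture(scope="session")
def pooled_params() -> BivariateACEParams:
    return BivariateACEParams.from_components(
        tau=(margin_threshold(POOLED_PREV[0]),
             margin_threshold(POOLED_PREV[1])),
        **POOLED)


@pytest.fixture(scope="session")
def e_only_params() -> BivariateACEParams:
    """Independent liabilities: E = 1 per trait, no cross-covariance."""
    return BivariateACEParams(
        tau_rsi=0.0, tau_ci=0.0,
        a_rsi=0.0, c_rsi=0.0, e_rsi=1.0,
        a_ci=0.0, c_ci=0.0, e_ci=1.0,
        cov_a=0.0, cov_c=0.0, cov_e=0.0)


@pytest.fixture(scope="session")
def small_study(pooled_params):
    """2,000 pairs from the pooled configuration (fast, reused)."""
    return simulate_pairs(pooled_params, n_mz=1000, n_dz_ss=1000, seed=202)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def csv_writer(tmp_path):
    """Write raw CSV text to a temp file and return its path."""
    def _write(text, name="pairs.csv"):
        p = tmp_path / name
        p.write_text(text, encoding="utf-8")
        return p
    return _write
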