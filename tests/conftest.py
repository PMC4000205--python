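import numpy as np
import pytest
from scipy.special import gammaln, logsumexp

from accmeta.study_table import FactorSet, encode_design, outcomes_array
from accmeta.synthetic_data import (
    SyntheticConfig,
    generate_study_table,
    make_synthetic_benchmark_table,
)


@pytest.fixture(scope="session")
def benchmark_records():
    """The deterministic synthetic benchmark study table (48 studies, 61 rows)."""
    return make_synthetic_benchmark_table()


@pytest.fixture(scope="session")
def small_corpus():
    """A 12-study corpus with one real factor effect and moderate variance."""
    cfg = SyntheticConfig(
        n_studies=12,
        beta={"intercept": 1.2, "cv_technique[nested]": 0.6},
        sigma2=0.4,
        seed=101,
    )
    return generate_study_table(cfg)


@pytest.fixture(scope="session")
def cluster_fixture():
    """Small clustered design + outcomes for quadrature oracle checks."""
    cfg = SyntheticConfig(
        n_studies=5,
        models_per_study={2: 1.0},
        n_eval_range=(20, 20),
        beta={"intercept": 1.0, "cv_technique[nested]": 0.5},
        sigma2=0.7,
        seed=7,
    )
    records = generate_study_table(cfg)
    design = encode_design(
        records,
        FactorSet(("cv_technique",)),
        reference_levels={"cv_technique": "single"},
    )
    return design, outcomes_array(records)


def brute_force_marginal_loglik(design, outcomes, beta, sigma2,
                                nodes=20001, width=8.0):
    """Dense-trapezoid integration of each cluster's marginal likelihood.

    Independent oracle for the adaptive Gauss-Hermite implementation: the
    integrand is evaluated on a fixed grid over b in [-width*sd, width*sd]
    and integrated in log space with trapezoid weights.
    """
    y, n = (np.asarray(a, dtype=float) for a in outcomes)
    eta = design.X @ np.asarray(beta, dtype=float)
    sd = np.sqrt(sigma2)
    b = np.linspace(-width * sd, width * sd, nodes)
    logc = gammaln(n + 1) - gammaln(y + 1) - gammaln(n - y + 1)
    w = np.full(nodes, b[1] - b[0])
    w[0] /= 2.0
    w[-1] /= 2.0
    ll = 0.0
    for c in range(design.n_clusters):
        m = design.cluster_index == c
        integrand = -0.5 * b**2 / sigma2 - 0.5 * np.log(2 * np.pi * sigma2)
        for yi, ni, ei, lci in zip(y[m], n[m], eta[m], logc[m]):
            etab = ei + b
            integrand = integrand + yi * etab - ni * np.logaddexp(0, etab) + lci
        ll += logsumexp(integrand + np.log(w))
    return float(ll)


@pytest.fixture(scope="session")
def brute_force_oracle():
    return brute_force_marginal_loglik
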