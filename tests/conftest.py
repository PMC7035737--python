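import numpy as np
import pandas as pd
import pytest

import heteroseq as h


@pytest.fixture(scope="session")
def small_config():
    return h.SimConfig(
        n_genes=300,
        n_chromosomes=3,
        chrom_length=5_000_000,
        tissues=("0-L", "0-S"),
        hybrids=("H1xH8",),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_catalog(small_config):
    return h.simulate_annotation(small_config)


@pytest.fixture(scope="session")
def small_experiment(small_config, small_catalog):
    counts, sheet, truth = h.simulate_trio_counts(small_catalog, small_config)
    return counts, sheet, truth


def nb_conditional_oracle(k_a, k_b, n_a, n_b, alpha):
    """Brute-force enumeration oracle for the exact conditional NB test.

    Enumerates every split (a, T-a) of the conditional distribution using
    scipy's nbinom/binom pmf directly (independent of the implementation's
    log-gamma route) and sums the probabilities of all splits whose
    probability does not exceed the observed one (same 1e-8 relative tie
    tolerance, which is part of the test's definition).
    """
    from scipy import stats

    T = k_a + k_b
    if T == 0:
        return 1.0
    a = np.arange(T + 1)
    if alpha > 0:
        # sum of n iid NB(mu, alpha) with common success prob q: NB(r = n/alpha, q)
        r_a, r_b = n_a / alpha, n_b / alpha
        q = 0.5  # arbitrary: cancels after conditioning
        w = stats.nbinom.pmf(a, r_a, q) * stats.nbinom.pmf(T - a, r_b, q)
    else:
        w = stats.binom.pmf(a, T, n_a / (n_a + n_b))
    w = w / w.sum()
    return float(w[w <= w[k_a] * (1 + 1e-8)].sum())
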