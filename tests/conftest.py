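import numpy as np
import pandas as pd
import pytest

from bevmod import GeneratorConfig, generate_dataset, load_reference, load_rules


@pytest.fixture(scope="session")
def reference():
    return load_reference()


@pytest.fixture(scope="session")
def rules():
    return load_rules()


@pytest.fixture(scope="session")
def small_dataset(reference):
    """A modest synthetic survey reused across tests (seeded)."""
    config = GeneratorConfig(n_per_age=300)
    return generate_dataset(config, seed=7, reference=reference)


def _jackknife_ratio_se(x, w, strata, psu):
    """Delete-one-PSU jackknife SE of the weighted ratio mean Σwx/Σw.

    Independent oracle for the Taylor-linearized SE: drop each PSU in turn,
    reweight its stratum's remaining PSUs by n_h/(n_h−1), recompute the
    ratio, and accumulate (n_h−1)/n_h · (θ₍hj₎ − θ)².
    """
    x = np.asarray(x, float)
    w = np.asarray(w, float)
    strata = np.asarray(strata)
    psu = np.asarray(psu)
    theta = np.dot(w, x) / w.sum()
    var = 0.0
    for s in pd.unique(strata):
        in_s = strata == s
        psus = pd.unique(psu[in_s])
        n_h = len(psus)
        for j in psus:
            drop = in_s & (psu == j)
            wj = np.where(drop, 0.0, w)
            wj = np.where(in_s & ~drop, wj * n_h / (n_h - 1), wj)
            th = np.dot(wj, x) / wj.sum()
            var += (n_h - 1) / n_h * (th - theta) ** 2
    return float(np.sqrt(var))


@pytest.fixture(scope="session")
def jackknife_ratio_se():
    return _jackknife_ratio_se


def _random_design(rng, n_strata=None, psus=None, per_psu=None):
    """A small random stratified design with gamma outcome data."""
    n_strata = n_strata or int(rng.integers(3, 8))
    psus = psus or int(rng.integers(2, 4))
    per_psu = per_psu or int(rng.integers(4, 10))
    n = n_strata * psus * per_psu
    strata = np.repeat(np.arange(n_strata), psus * per_psu)
    psu = np.tile(np.repeat(np.arange(psus), per_psu), n_strata)
    w = rng.lognormal(0.0, 0.5, n)
    x = rng.gamma(2.0, 50.0, n)
    return x, w, strata, psu


@pytest.fixture(scope="session")
def random_design():
    return _random_design
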