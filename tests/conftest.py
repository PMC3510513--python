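import numpy as np
import pytest

from rnpkinetics import RateSet
from rnpkinetics.synthetic_data import default_fcs_truth


@pytest.fixture(scope="session")
def slow_complex_rates():
    """Rates of the slowly reacting substrate-enzyme complex scenario."""
    return RateSet(koff_S=0.45e-3, kcat=0.19e-3, koff_P=6.4e-3, Kd_P=0.32e-6)


@pytest.fixture(scope="session")
def fcs_truth():
    """(free, bound) single-species FCS parameters used across tests."""
    return default_fcs_truth()


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def bisect_bound_concentration(C_ligand, C_enzyme, Kd):
    """Independent mass-action oracle: bound complex concentration by bisection.

    Solves (C_ligand - x)(C_enzyme - x) = Kd * x for x in
    [0, min(C_ligand, C_enzyme)], iterated to float resolution.
    """
    lo, hi = 0.0, min(C_ligand, C_enzyme)

    def f(x):
        return (C_ligand - x) * (C_enzyme - x) - Kd * x

    if f(hi) >= 0:
        return hi
    for _ in range(300):
        mid = 0.5 * (lo + hi)
        if mid == lo or mid == hi:
            break
        if f(mid) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)
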