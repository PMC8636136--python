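import numpy as np
import pytest

import picmelt as pm


@pytest.fixture(scope="session")
def bdna20():
    """20-bp idealized duplex with the calibrated DNA model."""
    topo, coords = pm.build_bdna("ACGTACGTACGTACGTACGT")
    return topo, coords


@pytest.fixture(scope="session")
def bdna10():
    topo, coords = pm.build_bdna("ACGTACGTAC")
    return topo, coords


@pytest.fixture(scope="session")
def toy_pic():
    """Session toy PIC (seed 0)."""
    return pm.build_toy_pic(seed=0)


@pytest.fixture(scope="session")
def toy_pic_seed1():
    return pm.build_toy_pic(seed=1)


def numerical_forces(system, x, h=1.0e-5):
    """Central-difference gradient of the total energy."""
    num = np.zeros_like(x)
    for i in range(x.shape[0]):
        for k in range(3):
            xp = x.copy(); xp[i, k] += h
            xm = x.copy(); xm[i, k] -= h
            num[i, k] = -(system.energy(xp).total
                          - system.energy(xm).total) / (2 * h)
    return num
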