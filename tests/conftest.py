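import math
import warnings

import numpy as np
import pytest

from springwing.kernel import DSAKernel, rates_from_t0
from springwing.mechanics import hawkmoth_plant, hawkmoth_forcing_defaults


@pytest.fixture(scope="session")
def plant():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hawkmoth_plant()


@pytest.fixture(scope="session")
def forcing_defaults():
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return hawkmoth_forcing_defaults()


@pytest.fixture(scope="session")
def reference_kernel():
    """Reduced kernel at the fitted M. sexta rates."""
    return DSAKernel(36.39, 22.80)


@pytest.fixture(scope="session")
def tuned_gains(plant, forcing_defaults, reference_kernel):
    """Session-wide tuned forcing gains (mu at Kr=0, Fs at Kr=1).

    Tuning simulates repeatedly; computed once and shared.
    """
    from springwing.sweep import tune_Fs, tune_mu

    target = forcing_defaults["phi0_target"]
    mu = tune_mu(plant, reference_kernel, forcing_defaults["Fa"],
                 target=target, fs=forcing_defaults["fs"])
    Fs = tune_Fs(plant, forcing_defaults["fs"], target=target)
    return {"mu": mu, "Fs": Fs, "target": target}
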