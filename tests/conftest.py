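import numpy as np
import pytest

from dfescan import dfe
from dfescan.spectra import SpectrumSet


@pytest.fixture(scope="session")
def gammaexpo_truth():
    """The generator's default fly-like Gamma-Exponential DFE."""
    return dfe.DFEParams("GammaExpo", shape=0.3, mean_del=2000.0,
                         p_b=0.009, mean_ben=10.0)


@pytest.fixture(scope="session")
def big_spectrum(gammaexpo_truth):
    """One genome-scale spectrum simulated from the default DFE (seed 0)."""
    n, Ls, Ln, theta, dr = 20, 2e6, 6e6, 0.01, 0.15
    rng = np.random.default_rng(0)
    i = np.arange(1, n)
    w = dfe.omega_expected(gammaexpo_truth)
    return SpectrumSet(
        n=n, Ls=Ls, Ln=Ln,
        sfs_syn=rng.poisson(theta * Ls / i),
        sfs_nonsyn=rng.poisson(theta * Ln * dfe._nonsyn_integral(gammaexpo_truth, n)),
        Ds=float(rng.poisson(dr * Ls)),
        Dn=float(rng.poisson(dr * Ln * w)),
        name="sim_genome",
    )
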