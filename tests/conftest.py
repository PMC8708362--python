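import numpy as np
import pytest

from ferroheat.materials import MaterialModel, anchor_table
from ferroheat.reports import printed_reference

#: Compositions with the full (K, Ms, rho) property set.
ANCHOR_X = (0.0, 0.05, 0.1, 0.2, 0.4, 0.67, 0.8, 1.0)


@pytest.fixture(scope="session")
def anchors():
    return anchor_table()


@pytest.fixture(scope="session")
def model():
    return MaterialModel.default()


@pytest.fixture(scope="session")
def printed_345():
    return printed_reference("tables345")


@pytest.fixture(scope="session")
def printed_6():
    return printed_reference("table6")


@pytest.fixture(scope="session")
def printed_7():
    return printed_reference("table7")


def brute_force_peak(x, H, f, step_nm=5e-4, lo_nm=1.0, hi_nm=20.0,
                     epsilon=0.1, tau0=1e-9, T=300.0):
    """Independent dense-grid argmax of the loss power over diameter.

    Evaluates the loss-power expressions directly (not through the package's
    optimizer) on a uniform diameter grid; serves as the optimizer oracle.
    """
    from ferroheat.materials import anisotropy_constant, density, spontaneous_magnetization

    mu0, kB = 4e-7 * np.pi, 1.380649e-23
    K = anisotropy_constant(x)
    Ms = spontaneous_magnetization(x)
    rho = density(x)
    D = np.arange(lo_nm, hi_nm + step_nm / 2, step_nm) * 1e-9
    xi = np.pi * mu0 * Ms * D**3 * H / (6 * kB * T)
    L = 1 / np.tanh(xi) - 1 / xi
    chi_i = epsilon * np.pi * mu0 * Ms**2 * D**3 / (18 * kB * T)
    tau = tau0 * np.exp(np.pi * K * D**3 / (6 * kB * T))
    u = 2 * np.pi * f * tau
    chi_imag = 3 * chi_i * L / xi / (u + 1 / u)
    Ps = np.pi * mu0 * chi_imag * f * H**2 / rho
    i = int(np.argmax(Ps))
    return D[i], Ps[i]
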