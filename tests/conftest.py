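import numpy as np
import pytest

from petaloptics import KMParams, build_flower_stack
from petaloptics.flower_model import FlowerConfig
from petaloptics.synthetic_data import (
    default_grid,
    make_pigment_kstar,
    make_scatter_sstar,
    simulate_measurement,
)


def two_flux_bvp_rt(K_star: float, S_star: float):
    """Independent oracle: solve the two-flux boundary-value problem numerically.

    Downward flux I and upward flux J inside a slab of unit optical depth obey
        dI/dx = -(K* + S*) I + S* J
        dJ/dx =  (K* + S*) J - S* I
    with I(0) = 1 (diffuse light entering the top) and J(1) = 0 (nothing
    entering from below).  Reflectance = J(0), transmittance = I(1).
    """
    from scipy.integrate import solve_bvp

    k = K_star + S_star

    def odes(x, y):
        I, J = y
        return np.vstack([-k * I + S_star * J, k * J - S_star * I])

    def bc(ya, yb):
        return np.array([ya[0] - 1.0, yb[1]])

    x = np.linspace(0.0, 1.0, 41)
    y0 = np.vstack([np.exp(-k * x), np.zeros_like(x)])
    sol = solve_bvp(odes, bc, x, y0, tol=1e-10, max_nodes=20000)
    assert sol.success, f"BVP solver failed for K*={K_star}, S*={S_star}"
    r = float(sol.sol(0.0)[1])
    t = float(sol.sol(1.0)[0])
    return r, t


@pytest.fixture(scope="session")
def grid():
    return default_grid()


@pytest.fixture(scope="session")
def default_config():
    return FlowerConfig(r_surface=0.03, S_u_star=0.1)


@pytest.fixture(scope="session")
def pigment_truth(grid):
    """Ground-truth (K_p*, S_p*) spectra of the default synthetic pigment."""
    K = make_pigment_kstar(grid=grid)
    S = make_scatter_sstar(0.5, grid)
    return K, S


@pytest.fixture(scope="session")
def noiseless_measurement(grid, default_config, pigment_truth):
    """Exact four-layer model spectra for the default synthetic petal."""
    K, S = pigment_truth
    stack = build_flower_stack(default_config, KMParams(K.values, S.values), grid)
    return simulate_measurement(stack, noise_sd=0.0)
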