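import numpy as np
import pytest

import natzkit.reaction_transport as rt
from natzkit import synthetic_data as sd


def no_reaction_network():
    """A network whose kinetics are numerically switched off, for transport
    oracles (constants must stay positive by contract)."""
    return rt.ReactionNetwork(k_TOC=1e-30, k_nit=1e-30, k_mnox=1e-30, k_amx=1e-30)


def single_solute_bcs(top_uM, bottom):
    """Boundary set with only O2 active; every other species pinned to zero
    or zero flux."""
    bcs = []
    for s in rt.SPECIES:
        if s == "O2":
            bcs.append(rt.BoundaryCondition("O2", "top", "fixed_concentration", top_uM))
            kind, value = bottom
            bcs.append(rt.BoundaryCondition("O2", "bottom", kind, value))
        elif s in rt.SOLIDS:
            bcs.append(rt.BoundaryCondition(s, "top", "fixed_flux", 0.0))
            bcs.append(rt.BoundaryCondition(s, "bottom", "zero_gradient"))
        else:
            bcs.append(rt.BoundaryCondition(s, "top", "fixed_concentration", 0.0))
            bcs.append(rt.BoundaryCondition(s, "bottom", "zero_gradient"))
    return bcs


def uniform_grid(L=100.0, n=100, phi=0.8, w=0.0):
    return rt.build_grid(L, n_cells=n, porosity_surface=phi, porosity_deep=phi,
                         attenuation=50.0, w=w, Db0=0.0)


def cubic_oracle_case(n, L=100.0, phi=0.8, beta=4e-5):
    """Single solute with a linearly increasing volumetric sink: the exact
    steady state is cubic, giving a genuine O(dz^2) truncation error.

    0 = phi*Ds*1e-3 * C'' - beta*z, Dirichlet top C0, zero-gradient bottom:
    C(z) = C0 + gamma*z^3/6 - gamma*L^2*z/2 with gamma = beta/(phi*Ds*1e-3).
    """
    grid = uniform_grid(L=L, n=n, phi=phi)
    species = rt.default_species()
    ds = rt.tortuosity_corrected_diffusivity(
        species["O2"].free_solution_diffusivity, phi
    )
    sink = -beta * grid.depths
    sol = rt.solve_steady_state(
        grid, species, no_reaction_network(),
        single_solute_bcs(100.0, ("zero_gradient", 0.0)),
        extra_sources={"O2": sink},
    )
    gamma = beta / (phi * ds * 1e-3)
    z = grid.depths
    exact = 100.0 + gamma * z**3 / 6.0 - gamma * L**2 * z / 2.0
    return sol, exact


@pytest.fixture(scope="session")
def reference_core():
    """The default synthetic core: spec, noisy observations and truth."""
    spec = sd.SyntheticCoreSpec(seed=42)
    profile, truth = sd.make_core(spec)
    return spec, profile, truth


@pytest.fixture(scope="session")
def reference_solution(reference_core):
    return reference_core[2].solution


@pytest.fixture(scope="session")
def noiseless_core():
    spec = sd.SyntheticCoreSpec(noise_sd=0.0)
    profile, truth = sd.make_core(spec)
    return spec, profile, truth
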