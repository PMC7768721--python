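"""Grid closures, kinetics, stoichiometry and the steady-state solver."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import natzkit.reaction_transport as rt
from conftest import (
    cubic_oracle_case,
    no_reaction_network,
    single_solute_bcs,
    uniform_grid,
)


# ---------------------------------------------------------------------------
# grid and closures
# ---------------------------------------------------------------------------


class TestBuildGrid:
    def test_constant_porosity_limit(self):
        grid = uniform_grid(phi=0.8)
        assert np.allclose(grid.porosity, 0.8)

    def test_no_compaction_limit(self):
        grid = rt.build_grid(100.0, 50, 0.9, 0.7, attenuation=1e9)
        assert np.allclose(grid.porosity, 0.9, atol=1e-6)

    def test_exponential_closure_value(self):
        # cell center at exactly 100 cm: phi = 0.7 + 0.2 * exp(-2)
        grid = rt.build_grid(400.0, 10, 0.9, 0.7, attenuation=50.0)
        assert grid.depths[2] == 100.0
        assert grid.porosity[2] == pytest.approx(0.7 + 0.2 * math.exp(-2.0), rel=1e-12)

    def test_bioturbation_cutoff(self):
        grid = rt.build_grid(300.0, 200, Db0=0.3, zbio=10.0)
        assert np.all(grid.bioturbation_coeff[grid.depths <= 10.0] == 0.3)
        assert np.all(grid.bioturbation_coeff[grid.depths > 10.0] == 0.0)

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(porosity_surface=1.2),
            dict(porosity_surface=0.5, porosity_deep=0.8),
            dict(domain_length=-5.0),
            dict(n_cells=5),
        ],
    )
    def test_invalid_configuration(self, kwargs):
        base = dict(domain_length=100.0, n_cells=50)
        base.update(kwargs)
        with pytest.raises(rt.ConfigurationError):
            rt.build_grid(**base)


class TestTortuosity:
    def test_unit_porosity_limit(self):
        assert rt.tortuosity_corrected_diffusivity(300.0, 0.999999) == pytest.approx(
            300.0, rel=1e-5
        )

    def test_log_identity(self):
        # ln(e^-1) = -1 forces the denominator to 3 exactly
        assert rt.tortuosity_corrected_diffusivity(300.0, math.exp(-1)) == pytest.approx(
            100.0, rel=1e-12
        )

    def test_direct_evaluation(self):
        expected = 350.0 / (1.0 - 2.0 * math.log(0.8))
        assert rt.tortuosity_corrected_diffusivity(350.0, 0.8) == pytest.approx(
            expected, rel=1e-12
        )

    @pytest.mark.parametrize("phi", [0.0, 1.0, 1.2, -0.1])
    def test_unphysical_porosity(self, phi):
        with pytest.raises(rt.ConfigurationError):
            rt.tortuosity_corrected_diffusivity(300.0, phi)


# ---------------------------------------------------------------------------
# kinetics and stoichiometry
# ---------------------------------------------------------------------------


def _state(**overrides):
    base = {"O2": 0.0, "NO3": 0.0, "NH4": 0.0, "Mn2": 0.0, "DIC": 2000.0,
            "TOC": 1.0, "MnO2": 20.0}
    base.update(overrides)
    return base


class TestReactionRates:
    net = rt.ReactionNetwork()

    def test_substrate_absence(self):
        rates = rt.reaction_rates(_state(O2=100.0, NH4=0.0), self.net, 0.8)
        assert rates["R4"] == 0.0 and rates["R6"] == 0.0

    def test_oxygen_inhibition_limit(self):
        rates = rt.reaction_rates(
            _state(O2=1e7, NO3=10.0, NH4=10.0), self.net, 0.8
        )
        # anammox is fully inhibited at high oxygen
        assert rates["R6"] < 1e-6 * self.net.k_amx * 100.0

    def test_half_saturation_identity(self):
        rates = rt.reaction_rates(_state(O2=self.net.K_O2), self.net, 0.8)
        toc_bulk = 1.0 * 1e4 / 12.011 * self.net.rho_dry * 0.2
        assert rates["R1"] == pytest.approx(self.net.k_TOC * toc_bulk / 2.0, rel=1e-12)

    def test_r6_monotone_decreasing_in_oxygen(self):
        o2 = np.linspace(0.0, 200.0, 50)
        rates = rt.reaction_rates(
            {k: np.full(50, v) for k, v in _state(NO3=10.0, NH4=10.0).items()}
            | {"O2": o2},
            self.net,
            0.8,
        )
        assert np.all(np.diff(rates["R6"]) < 0)

    def test_negative_concentration_raises(self):
        with pytest.raises(ValueError):
            rt.reaction_rates(_state(O2=-1.0), self.net, 0.8)

    @settings(deadline=None, max_examples=50, derandomize=True)
    @given(
        o2=st.floats(0, 500), no3=st.floats(0, 50), nh4=st.floats(0, 200),
        mn2=st.floats(0, 100), toc=st.floats(0, 5), mno2=st.floats(0, 100),
    )
    def test_rates_nonnegative(self, o2, no3, nh4, mn2, toc, mno2):
        rates = rt.reaction_rates(
            _state(O2=o2, NO3=no3, NH4=nh4, Mn2=mn2, TOC=toc, MnO2=mno2),
            self.net, 0.8,
        )
        assert all(v >= 0 for v in rates.values())


class TestStoichiometry:
    def test_nitrate_coupled_atoms_balance(self):
        # normalized per mol NH4+: N in = 1 + 0.6, N out = 2 * 0.8
        s = rt.anammox_stoichiometry("nitrate_coupled")
        assert s["NH4+"] + s["NO3-"] + 2 * s["N2"] == pytest.approx(0.0, abs=1e-12)

    def test_nitrate_coupled_charge_balance(self):
        s = rt.anammox_stoichiometry("nitrate_coupled")
        charge = s["NH4+"] * (+1) + s["NO3-"] * (-1) + s["H+"] * (+1)
        assert charge == pytest.approx(0.0, abs=1e-12)

    def test_canonical_one_to_one(self):
        s = rt.anammox_stoichiometry("nitrite_canonical")
        assert s["NH4+"] == s["NO2-"] == -1.0

    def test_unknown_mode(self):
        with pytest.raises(rt.ConfigurationError):
            rt.anammox_stoichiometry("nitrous_oxide")

    def test_network_conserves_atoms_at_construction(self):
        net = rt.ReactionNetwork()
        S = net.stoich
        n = S.loc["NO3"] + S.loc["NH4"] + 2 * S.loc["N2"] + S.loc["OrgN"]
        mn = S.loc["Mn2"] + S.loc["MnO2"]
        assert np.allclose(n, 0.0, atol=1e-12)
        assert np.allclose(mn, 0.0, atol=1e-12)

    @pytest.mark.parametrize("kwargs", [dict(k_TOC=-1.0), dict(r_NC=1.5), dict(K_O2=0.0)])
    def test_invalid_network(self, kwargs):
        with pytest.raises(rt.ConfigurationError):
            rt.ReactionNetwork(**kwargs)


# ---------------------------------------------------------------------------
# solver oracles
# ---------------------------------------------------------------------------


class TestSolverOracles:
    species = rt.default_species()

    def solve_linear(self, n=100):
        grid = uniform_grid(n=n)
        bcs = single_solute_bcs(100.0, ("fixed_concentration", 0.0))
        return grid, rt.solve_steady_state(grid, self.species, no_reaction_network(), bcs)

    def test_laplace_linear_profile(self):
        grid, sol = self.solve_linear()
        exact = 100.0 * (1.0 - grid.depths / 100.0)
        assert np.abs(sol.concentrations["O2"] - exact).max() < 1e-7
        assert sol.converged

    def parabola(self, n):
        """Zero-order consumption k0 (uM yr-1 of porewater), Dirichlet top,
        zero-gradient bottom; closed form solved independently."""
        k0, phi, L = 5.0, 0.8, 100.0
        grid = uniform_grid(L=L, n=n, phi=phi)
        bcs = single_solute_bcs(100.0, ("zero_gradient", 0.0))
        sink = {"O2": np.full(n, -k0 * 1e-3 * phi)}
        sol = rt.solve_steady_state(
            grid, self.species, no_reaction_network(), bcs, extra_sources=sink
        )
        ds = rt.tortuosity_corrected_diffusivity(
            self.species["O2"].free_solution_diffusivity, phi
        )
        z = grid.depths
        exact = 100.0 - (k0 / ds) * (L * z - z**2 / 2.0)
        return sol, exact, k0, phi, L

    def test_parabolic_closed_form(self):
        sol, exact, *_ = self.parabola(100)
        rel = np.abs(sol.concentrations["O2"] - exact) / 100.0
        assert rel.max() < 1e-3  # < 0.1 % node-wise

    def test_second_order_grid_convergence(self):
        errors = []
        for n in (50, 100, 200):
            sol, exact = cubic_oracle_case(n)
            errors.append(np.abs(sol.concentrations["O2"] - exact).max())
        assert errors[0] / errors[1] == pytest.approx(4.0, rel=0.15)
        assert errors[1] / errors[2] == pytest.approx(4.0, rel=0.15)

    def test_zero_order_boundary_flux(self):
        sol, _, k0, phi, L = self.parabola(100)
        # all consumed oxygen enters from the top: influx = k0 * phi * L (bulk)
        assert sol.boundary_fluxes["O2"][0] == pytest.approx(k0 * 1e-3 * phi * L, rel=1e-8)
        assert sol.boundary_fluxes["O2"][1] == pytest.approx(0.0, abs=1e-10)

    def test_bioturbated_decay_matches_piecewise_closed_form(self):
        """Organic matter with burial, first-order decay and a 10-cm mixed
        layer has a piecewise-exponential steady state; the solver matches
        the closed form through the mixing discontinuity."""
        phi, w, db, k, zb, L, flux = 0.8, 2e-3, 0.1, 1.2e-4, 10.0, 300.0, 2.8
        rho = 2.5
        sf = (1 - phi) * rho
        disc = math.sqrt(w * w + 4 * db * k)
        lam_p, lam_m = (w + disc) / (2 * db), (w - disc) / (2 * db)
        # S1' vanishes at the mixed-layer base (flux continuity), top flux fixed
        M = np.array(
            [[sf * (-db * lam_p + w), sf * (-db * lam_m + w)],
             [lam_p * math.exp(lam_p * zb), lam_m * math.exp(lam_m * zb)]]
        )
        a, b = np.linalg.solve(M, [flux, 0.0])

        def s_exact(z):
            s1 = a * np.exp(lam_p * z) + b * np.exp(lam_m * z)
            s10 = a * math.exp(lam_p * zb) + b * math.exp(lam_m * zb)
            return np.where(z <= zb, s1, s10 * np.exp(-k * (z - zb) / w))

        # make organic decay unconditional: no oxidant limitation/inhibition
        net = rt.ReactionNetwork(
            k_TOC=k, K_O2=1e-6, k_nit=1e-30, k_mnox=1e-30, k_amx=1e-30,
            Kin_O2=1e9, Kin_NO3=1e-9, K_NO3=1e9, K_MnO2=1e9,
        )
        errors = {}
        for n in (150, 300):
            grid = rt.build_grid(L, n, phi, phi, 50.0, w=w, Db0=db, zbio=zb)
            bcs = []
            for s in rt.SPECIES:
                if s == "O2":
                    bcs += [rt.BoundaryCondition("O2", "top", "fixed_concentration", 1e6),
                            rt.BoundaryCondition("O2", "bottom", "zero_gradient")]
                elif s in rt.SOLIDS:
                    top_flux = flux if s == "TOC" else 0.0
                    bcs += [rt.BoundaryCondition(s, "top", "fixed_flux", top_flux),
                            rt.BoundaryCondition(s, "bottom", "zero_gradient")]
                else:
                    bcs += [rt.BoundaryCondition(s, "top", "fixed_concentration", 0.0),
                            rt.BoundaryCondition(s, "bottom", "zero_gradient")]
            sol = rt.solve_steady_state(grid, self.species, net, bcs)
            toc_umol_g = sol.concentrations["TOC"] * 1e4 / 12.011
            exact = s_exact(grid.depths)
            errors[n] = np.abs(toc_umol_g - exact).max() / exact.max()
        assert errors[300] < 5e-4
        assert errors[150] / errors[300] == pytest.approx(4.0, rel=0.2)

    def test_nonconvergence_raises_with_history(self):
        # a zero-order sink keeps the initial guess away from the solution
        grid = uniform_grid(n=20)
        bcs = single_solute_bcs(100.0, ("zero_gradient", 0.0))
        with pytest.raises(rt.ConvergenceError) as err:
            rt.solve_steady_state(
                grid, self.species, no_reaction_network(), bcs, max_iter=0,
                extra_sources={"O2": np.full(20, -4e-3)},
            )
        assert len(err.value.residual_history) >= 1


class TestFullNetwork:
    def test_anammox_confined_to_overlap(self, reference_solution):
        """R6 is appreciable only where modeled NO3 and NH4 coexist at low O2."""
        sol = reference_solution
        r6 = sol.reaction_rates["R6"]
        c = sol.concentrations
        cum = np.cumsum(r6) / r6.sum()
        active = (cum > 0.05) & (cum < 0.95)
        assert np.all(c["O2"][active] < 10.0)
        assert np.all(c["NO3"][active] > 0.1)
        assert np.all(c["NH4"][active] > 0.1)
        # the rate peak sits where both substrates are appreciable
        peak = np.argmax(r6)
        assert c["NO3"][peak] > 2.0 and c["NH4"][peak] > 2.0 and c["O2"][peak] < 2.0

    def test_mass_balance_closes(self, reference_solution):
        report = rt.mass_balance_report(reference_solution)
        assert report["relative_closure"].max() < 5e-3
        budget = report.attrs["nitrogen_budget"]
        lhs = budget["boundary_N_influx"] + budget["organic_N_release"]
        assert lhs == pytest.approx(budget["N2_production"], rel=5e-3)

    def test_flux_reaction_balance_within_solver_tolerance(self, reference_solution):
        # steady state: boundary-flux difference equals integrated net reaction
        assert rt.mass_balance_report(reference_solution)["relative_closure"].max() < 1e-8

    def test_r6_peak_stable_under_grid_refinement(self, reference_core):
        spec, _, truth = reference_core
        coarse = truth.solution
        import dataclasses

        spec2 = dataclasses.replace(spec, n_cells=2 * spec.n_cells)
        from natzkit import synthetic_data as sd

        _, truth2 = sd.make_core(spec2)
        fine = truth2.solution
        r6c, r6f = coarse.reaction_rates["R6"], fine.reaction_rates["R6"]
        z_coarse = coarse.grid.depths[np.argmax(r6c)]
        z_fine = fine.grid.depths[np.argmax(r6f)]
        assert abs(z_coarse - z_fine) <= coarse.grid.cell_thickness
        centroid_c = np.average(coarse.grid.depths, weights=r6c)
        centroid_f = np.average(fine.grid.depths, weights=r6f)
        assert abs(centroid_c - centroid_f) <= coarse.grid.cell_thickness


class TestRmse:
    def _profile(self, depths, values):
        from natzkit.profile_analysis import PorewaterProfile

        return PorewaterProfile(
            site_id="t", depths=np.asarray(depths),
            concentrations={"NO3": np.asarray(values)},
        )

    def test_perfect_match_is_zero(self, reference_solution):
        sol = reference_solution
        z = sol.grid.depths[::10]
        prof = self._profile(z, sol.concentrations["NO3"][::10])
        assert rt.rmse_model_vs_data(sol, prof, "NO3") == pytest.approx(0.0, abs=1e-12)

    def test_constant_offset_identity(self, reference_solution):
        sol = reference_solution
        z = sol.grid.depths[::10]
        prof = self._profile(z, sol.concentrations["NO3"][::10] + 3.0)
        assert rt.rmse_model_vs_data(sol, prof, "NO3") == pytest.approx(3.0, rel=1e-9)

    def test_hand_computed_residuals(self, reference_solution):
        sol = reference_solution
        z = sol.grid.depths[[10, 50, 90]]
        model = sol.concentrations["NO3"][[10, 50, 90]]
        prof = self._profile(z, np.clip(model + np.array([-1.0, 2.0, -2.0]), 0, None))
        clipped = np.clip(model + np.array([-1.0, 2.0, -2.0]), 0, None) - model
        expected = math.sqrt(np.mean(clipped**2))
        assert rt.rmse_model_vs_data(sol, prof, "NO3") == pytest.approx(expected, rel=1e-12)

    def test_empty_profile_raises(self, reference_solution):
        prof = self._profile([], [])
        with pytest.raises(ValueError):
            rt.rmse_model_vs_data(reference_solution, prof, "NO3")
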