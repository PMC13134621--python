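"""Unit and property tests of the swelling model: binding equilibria,
osmotic pressure components, equilibrium and transient solvers, fitting."""

import math
from dataclasses import replace

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import brentq

from sononeedle.chemo_mechanics import (
    DEFAULT_TISSUE_STIFFNESS,
    R_GAS,
    BathCondition,
    BindingState,
    CalibratedModel,
    HydrogelComposition,
    MechanicalEnvironment,
    _pressure_residual,
    charged_fraction,
    constrained_equilibrium,
    equilibrium_sr_curve,
    equilibrium_swelling,
    fit_parameters,
    j_from_length_sr,
    length_sr_from_J,
    osmotic_elastic,
    osmotic_ionic,
    osmotic_mixing,
    relaxation_fraction,
    solve_axial_profile,
    transient_sr,
)
from sononeedle.errors import (
    InvalidInputError,
    NoEquilibriumError,
    UnderdeterminedError,
)


# ---------------------------------------------------------------------------
# charged fraction
# ---------------------------------------------------------------------------

class TestChargedFraction:
    def test_no_binding_reduces_to_acid_base(self):
        Ka, h = 1e-9, 10.0**-7.4
        for g in (0.0, 5.0, 40.0):
            f = charged_fraction(BathCondition(glucose=g), Ka, Kb=1e-12)
            assert f == pytest.approx(Ka / (Ka + h), rel=1e-6)

    def test_saturation_limit(self):
        f = charged_fraction(BathCondition(glucose=1e9), 1e-9, 100.0)
        assert f == pytest.approx(1.0, abs=1e-6)

    def test_monotone_in_glucose(self):
        vals = [charged_fraction(BathCondition(glucose=g), 1e-9, 100.0)
                for g in np.linspace(0, 40, 20)]
        assert np.all(np.diff(vals) > 0)

    def test_mass_action_oracle(self):
        # explicit species solve of the two coupled equilibria: per unit
        # neutral acid HA, [A-] = Ka/[H+], [A-G] = Kb c_g [A-]
        Ka, Kb, pH, glucose = 1e-9, 100.0, 7.4, 10.0
        h = 10.0**-pH
        Am = Ka / h
        AG = Kb * glucose * 1e-3 * Am
        f_oracle = (Am + AG) / (1.0 + Am + AG)
        f = charged_fraction(BathCondition(glucose=glucose, pH=pH), Ka, Kb)
        assert f == pytest.approx(f_oracle, rel=1e-14)

    def test_invalid_inputs(self):
        with pytest.raises(InvalidInputError):
            BathCondition(glucose=-1.0)
        with pytest.raises(InvalidInputError):
            charged_fraction(BathCondition(), Ka=-1.0, Kb=10.0)


# ---------------------------------------------------------------------------
# osmotic pressures
# ---------------------------------------------------------------------------

class TestOsmoticComponents:
    def test_ionic_zero_charge(self):
        assert osmotic_ionic(0.0, 150.0) == 0.0

    def test_ionic_counterion_limit(self):
        # vanishing salt: ideal-gas pressure of the counterions, RT c_f
        cf, T = 10.0, 310.0
        pi = osmotic_ionic(cf, 1e-8, T)
        assert pi == pytest.approx(R_GAS * T * cf, rel=1e-6)

    def test_ionic_decreasing_in_salt(self):
        vals = [osmotic_ionic(10.0, s) for s in (50.0, 100.0, 200.0, 400.0)]
        assert np.all(np.diff(vals) < 0)

    def test_ionic_electroneutrality_oracle(self):
        # brute force: anion content c- in the gel from c-(c- + c_f) = c_s^2
        # (equal salt chemical potential), pressure = RT (c+ + c- - 2 c_s)
        cf, cs, T = 10.0, 150.0, 310.0
        cm = brentq(lambda x: x * (x + cf) - cs * cs, 0.0, 2 * cs, xtol=1e-14)
        oracle = R_GAS * T * (2 * cm + cf - 2 * cs)
        assert osmotic_ionic(cf, cs, T) == pytest.approx(oracle, rel=1e-10)

    def test_ionic_invalid_salt(self):
        with pytest.raises(InvalidInputError):
            osmotic_ionic(10.0, 0.0)

    def test_mixing_pure_solvent_limit(self):
        assert osmotic_mixing(1e-9, 0.45) == pytest.approx(0.0, abs=1.0)

    def test_mixing_theta_solvent_bound(self):
        # chi = 1/2 kills the phi^2 term; remainder is O(phi^3)
        T, V1 = 310.0, 1.8e-5
        for phi in (0.01, 0.05, 0.1):
            pi = osmotic_mixing(phi, 0.5, V1, T)
            assert abs(pi) <= (R_GAS * T / V1) * phi**3

    def test_mixing_high_precision_oracle(self):
        # independent evaluation in extended precision
        phi, chi, V1, T = 0.2, 0.45, 1.8e-5, 310.0
        ld = np.longdouble
        oracle = -ld(R_GAS) * ld(T) / ld(V1) * (
            np.log1p(-ld(phi)) + ld(phi) + ld(chi) * ld(phi) ** 2)
        assert osmotic_mixing(phi, chi, V1, T) == pytest.approx(float(oracle), rel=1e-13)

    def test_mixing_invalid_phi(self):
        for phi in (0.0, 1.0, -0.2, 1.5):
            with pytest.raises(InvalidInputError):
                osmotic_mixing(phi, 0.45)

    def test_elastic_reference_state(self):
        nu, T = 120.0, 310.0
        pi = osmotic_elastic(0.2, 0.2, nu, T, 1.0)
        assert pi == pytest.approx(-R_GAS * T * nu * 0.5, rel=1e-12)

    def test_elastic_linear_stiffening(self):
        base = osmotic_elastic(0.1, 0.2, 120.0, 310.0, 1.0)
        assert osmotic_elastic(0.1, 0.2, 120.0, 310.0, 2.0) == pytest.approx(2 * base)

    def test_silica_stiffening_lowers_swelling(self, model):
        # silica-loaded gel swells less at high glucose than pristine gel
        stiffer = replace(model, composition=replace(model.composition,
                                                     silica_stiffening=1.3))
        bath = BathCondition(glucose=40.0)
        sr_plain = constrained_equilibrium(model, bath, 0.0).sr_length
        sr_silica = constrained_equilibrium(stiffer, bath, 0.0).sr_length
        assert sr_silica < sr_plain


# ---------------------------------------------------------------------------
# equilibrium solver
# ---------------------------------------------------------------------------

class TestEquilibrium:
    def test_no_boronate_gives_flat_curve(self, model):
        comp = replace(model.composition, boronate_density=1e-12)
        sols = [equilibrium_swelling(comp, BathCondition(glucose=g),
                                     binding=model.binding)
                for g in (0.0, 10.0, 40.0)]
        js = [s.J for s in sols]
        assert np.ptp(js) < 1e-6

    def test_sr_strictly_increasing_in_glucose(self, model):
        sr = model.sr_percent([0.0, 10.0, 20.0, 30.0, 40.0])
        assert np.all(np.diff(sr) > 0)

    def test_residual_below_tolerance(self, model):
        sol = equilibrium_swelling(model.composition, BathCondition(glucose=10.0),
                                   binding=model.binding, baseline_J=model.baseline_J)
        tol = 1e-6 * R_GAS * 310.0 / model.composition.solvent_molar_volume
        assert abs(sol.residual) < tol
        assert sol.phi == pytest.approx(model.composition.phi0 / sol.J, rel=1e-12)

    def test_dense_grid_oracle(self, model):
        # scan J in steps of 1e-4: the sign change must bracket the root
        bath = BathCondition(glucose=10.0)
        sol = equilibrium_swelling(model.composition, bath, binding=model.binding,
                                   baseline_J=model.baseline_J)
        f = charged_fraction(bath, model.binding.Ka, model.binding.Kb)
        Js = np.arange(1.0 + 1e-4, 30.0, 1e-4)
        res = _pressure_residual(Js, model.composition, bath, f,
                                 MechanicalEnvironment.free(), model.baseline_J)
        idx = np.nonzero(np.sign(res[:-1]) != np.sign(res[1:]))[0]
        assert idx.size == 1
        assert Js[idx[0]] <= sol.J <= Js[idx[0] + 1]

    def test_dense_grid_oracle_random_draws(self, rng):
        # bracketing solver equals the grid sign change for random valid gels
        for _ in range(10):
            comp = HydrogelComposition(
                boronate_density=rng.uniform(100, 1500),
                crosslink_density=rng.uniform(30, 400),
                chi=rng.uniform(0.3, 0.52),
                phi0=rng.uniform(0.1, 0.3),
            )
            binding = BindingState(Kb=10 ** rng.uniform(1, 3.5))
            bath = BathCondition(glucose=rng.uniform(0, 40))
            try:
                sol = equilibrium_swelling(comp, bath, binding=binding)
            except NoEquilibriumError:
                continue
            f = charged_fraction(bath, binding.Ka, binding.Kb)
            Js = np.arange(1.0 + 1e-4, 30.0, 1e-4)
            res = _pressure_residual(Js, comp, bath, f,
                                     MechanicalEnvironment.free(), 1.0)
            idx = np.nonzero(np.sign(res[:-1]) != np.sign(res[1:]))[0]
            assert any(Js[i] <= sol.J <= Js[i + 1] for i in idx)

    def test_vectorised_curve_matches_scalar_solver(self, model):
        g = np.array([0.0, 7.5, 23.0, 40.0])
        curve = equilibrium_sr_curve(model, g)
        for gi, sri in zip(g, curve):
            sol = equilibrium_swelling(model.composition, BathCondition(glucose=gi),
                                       binding=model.binding,
                                       baseline_J=model.baseline_J)
            assert sri == pytest.approx(100 * sol.sr_length, abs=1e-6)

    def test_no_equilibrium_diagnostics(self):
        # an absurdly stiff network cannot swell: residual never positive
        comp = HydrogelComposition(boronate_density=1e-9, crosslink_density=500.0,
                                   chi=0.58, phi0=0.01)
        with pytest.raises(NoEquilibriumError) as err:
            equilibrium_swelling(comp, BathCondition())
        assert "residual_at_J1" in err.value.diagnostics

    def test_saturating_sensitivity(self, model):
        # slope over [20, 40] is smaller than over [0, 20]
        sr = model.sr_percent([0.0, 20.0, 40.0])
        assert (sr[2] - sr[1]) < (sr[1] - sr[0])


class TestLengthMapping:
    def test_identity(self):
        assert length_sr_from_J(2.0, 2.0) == 0.0

    def test_cube_law(self):
        assert length_sr_from_J(1.331, 1.0) == pytest.approx(0.10, rel=1e-12)

    def test_roundtrip(self):
        for J in (1.0, 1.7, 5.0, 12.0):
            sr = length_sr_from_J(J, 1.3)
            assert j_from_length_sr(sr, 1.3) == pytest.approx(J, rel=1e-12)

    def test_invalid(self):
        with pytest.raises(InvalidInputError):
            length_sr_from_J(-1.0, 1.0)


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

class TestTransient:
    def test_initial_condition(self, model):
        sr = transient_sr(model, [(0.0, 10.0)], [0.0], initial_sr=5.0)
        assert sr[0] == pytest.approx(5.0, abs=1e-9)

    def test_asymptote(self, model):
        sr_inf = transient_sr(model, [(0.0, 10.0)], [5000.0])[0]
        assert sr_inf == pytest.approx(model.sr_percent(10.0)[0], abs=1e-6)

    def test_monotone_after_step(self, model):
        sr = transient_sr(model, [(0.0, 15.0)], np.linspace(0, 180, 50))
        assert np.all(np.diff(sr) >= -1e-12)

    def test_half_time_single_mode_oracle(self, model):
        m1 = replace(model, kinetics=replace(model.kinetics, n_modes=1))
        tau1 = m1.kinetics.tau1_minutes
        t = np.linspace(0.0, 300.0, 6001)
        sr = transient_sr(m1, [(0.0, 10.0)], t)
        sr_eq = m1.sr_percent(10.0)[0]
        # fit a single exponential: log(1 - sr/sr_eq) should be -t/tau
        mask = (t > 0) & (sr / sr_eq < 0.99)
        slope = np.polyfit(t[mask], np.log(1.0 - sr[mask] / sr_eq), 1)[0]
        assert -1.0 / slope == pytest.approx(tau1, rel=1e-3)
        half_t = float(np.interp(0.5 * sr_eq, sr, t))
        assert half_t == pytest.approx(tau1 * math.log(2), rel=0.01)

    def test_sixty_minute_fraction(self, model):
        assert relaxation_fraction(60.0, model.kinetics) >= 0.90

    def test_curves_ordered_by_glucose_at_thirty_minutes(self, model):
        vals = [transient_sr(model, [(0.0, g)], [30.0])[0] for g in (0, 5, 10, 15)]
        assert np.all(np.diff(vals) > 0)

    def test_unordered_times_rejected(self, model):
        with pytest.raises(InvalidInputError):
            transient_sr(model, [(0.0, 10.0)], [10.0, 5.0])

    def test_step_down_relaxes_back(self, model):
        # glucose removed after equilibration: SR decays toward the 0 mM value
        sched = [(0.0, 12.0), (300.0, 0.0)]
        sr = transient_sr(model, sched, [300.0, 360.0, 2000.0])
        assert sr[1] < sr[0]
        assert sr[2] == pytest.approx(model.sr_percent(0.0)[0], abs=1e-3)


# ---------------------------------------------------------------------------
# confinement
# ---------------------------------------------------------------------------

class TestConfinement:
    def test_zero_stiffness_is_free(self, model):
        bath = BathCondition(glucose=15.0)
        a = constrained_equilibrium(model, bath, 0.0)
        b = equilibrium_swelling(model.composition, bath, binding=model.binding,
                                 baseline_J=model.baseline_J)
        assert a.J == pytest.approx(b.J, rel=1e-10)

    def test_rigid_cage_limit(self, model):
        sol = constrained_equilibrium(model, BathCondition(glucose=40.0), 1e12)
        assert sol.J == pytest.approx(model.baseline_J, rel=1e-4)

    def test_constrained_below_free_pointwise(self, model):
        g = np.arange(0.0, 41.0, 5.0)
        free = model.sr_percent(g)
        con = model.sr_percent(g, confinement_stiffness=DEFAULT_TISSUE_STIFFNESS)
        assert np.all(con <= free + 1e-12)

    def test_slope_preserved_within_five_percent(self, model):
        g = np.arange(5.0, 41.0, 5.0)
        free = np.polyfit(g, model.sr_percent(g), 1)[0]
        con = np.polyfit(g, model.sr_percent(
            g, confinement_stiffness=DEFAULT_TISSUE_STIFFNESS), 1)[0]
        assert abs(con / free - 1.0) < 0.05


class TestAxialProfile:
    def test_uniform_free_matches_homogeneous(self, model):
        bath = BathCondition(glucose=10.0)
        hom = constrained_equilibrium(model, bath, 0.0)
        sols = solve_axial_profile(model, bath, lambda x: 0.0, 16)
        assert all(s.J == pytest.approx(hom.J, rel=1e-10) for s in sols)

    def test_monotone_confinement_gives_monotone_sr(self, model):
        bath = BathCondition(glucose=20.0)
        sols = solve_axial_profile(model, bath, lambda x: 3e4 * x, 64)
        sr = [s.sr_length for s in sols]
        assert np.all(np.diff(sr) <= 1e-12)  # decreasing toward the base

    def test_mesh_convergence(self, model):
        bath = BathCondition(glucose=20.0)
        tip64 = solve_axial_profile(model, bath, lambda x: 3e4 * x, 64)[0].sr_length
        tip128 = solve_axial_profile(model, bath, lambda x: 3e4 * x, 128)[0].sr_length
        assert abs(tip64 / tip128 - 1.0) < 1e-3

    def test_profile_length_mismatch(self, model):
        with pytest.raises(InvalidInputError):
            solve_axial_profile(model, BathCondition(), [0.0, 0.0], 3)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

class TestFitting:
    def test_underdetermined(self):
        with pytest.raises(UnderdeterminedError):
            fit_parameters([(10.0, 20.0)])
        with pytest.raises(UnderdeterminedError):
            fit_parameters([(10.0, 20.0), (10.0, 21.0), (10.0, 22.0)])

    def test_zero_noise_parameter_recovery(self, model):
        # observations generated from known parameters; fit with the
        # degenerate directions (chi, baseline) pinned recovers Kb and the
        # crosslink density to better than 1 %
        g = np.array([0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0])
        obs = np.column_stack([g, model.sr_percent(g)])
        fixed = {"chi": model.composition.chi, "baseline_J": model.baseline_J}
        fit = fit_parameters(obs, fixed=fixed, seed=7, n_starts=4)
        assert fit.binding.Kb == pytest.approx(model.binding.Kb, rel=0.01)
        assert fit.composition.crosslink_density == pytest.approx(
            model.composition.crosslink_density, rel=0.01)
        assert fit.fit_residual_rms < 1e-3

    def test_sensitivity_recovery_under_noise(self, model):
        # Gaussian SR noise sigma = 0.3 points at 8 levels: the fitted
        # 0-20 mM sensitivity lands within 10 % in >= 90 % of replicates
        g = np.array([0.0, 2.5, 5.0, 10.0, 15.0, 20.0, 30.0, 40.0])
        truth = model.sr_percent(g)
        gg = np.linspace(0.0, 20.0, 9)
        gen_slope = np.polyfit(gg, model.sr_percent(gg), 1)[0]
        fixed = {"chi": model.composition.chi, "baseline_J": model.baseline_J}
        rng = np.random.default_rng(2024)
        hits = 0
        n_rep = 40
        for _ in range(n_rep):
            obs = np.column_stack([g, truth + rng.normal(0.0, 0.3, g.size)])
            fit = fit_parameters(obs, fixed=fixed, seed=11, n_starts=2)
            slope = np.polyfit(gg, fit.sr_percent(gg), 1)[0]
            hits += abs(slope / gen_slope - 1.0) <= 0.10
        assert hits >= 0.9 * n_rep


# ---------------------------------------------------------------------------
# property tests
# ---------------------------------------------------------------------------

@settings(max_examples=25, deadline=None, derandomize=True)
@given(
    nu=st.floats(30.0, 300.0),
    chi=st.floats(0.30, 0.50),
    cb=st.floats(100.0, 1200.0),
    log_kb=st.floats(1.0, 3.5),
    g1=st.floats(0.0, 20.0),
    dg=st.floats(0.5, 20.0),
)
def test_equilibrium_sr_monotone_property(nu, chi, cb, log_kb, g1, dg):
    """For any valid calibration, equilibrium SR strictly increases with
    glucose and the pressure balance holds at the returned root."""
    comp = HydrogelComposition(boronate_density=cb, crosslink_density=nu, chi=chi)
    binding = BindingState(Kb=10.0**log_kb)
    model = CalibratedModel(composition=comp, binding=binding)
    try:
        sr = equilibrium_sr_curve(model, np.array([g1, g1 + dg]))
    except NoEquilibriumError:
        return
    assert sr[1] > sr[0]
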