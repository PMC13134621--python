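"""Chemo-mechanical swelling model of glucose-responsive hydrogel microneedles.

The hydrogel is a polyacrylamide network functionalised with phenylboronic
acid (PBA) groups.  Boronate groups ionise (acid constant ``Ka``) and bind
glucose 1:1 (association constant ``Kb``); the bound, charged boronate acts
as fixed charge on the network, which sets up a Donnan ion imbalance with
the bath and hence an ionic osmotic pressure that swells the gel.  Swelling
is resisted by polymer-solvent mixing (Flory-Huggins) and Gaussian network
elasticity; in tissue an additional confinement pressure from the
surrounding medium opposes swelling.  Equilibrium is the volumetric ratio
``J`` at which the pressures balance:

    Pi_mix(phi) + Pi_el(phi) + Pi_ion(c_f) = P_confinement(J),   phi = phi0/J

The observable is the length swelling ratio SR = (J/J_baseline)^(1/3) - 1
(isotropic swelling), reported in percent.  Swelling kinetics follow a
collective-diffusion (Tanaka-type) relaxation with time constant
``tau1 = L^2 / (pi^2 D)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Sequence

import numpy as np
from scipy.optimize import brentq, least_squares

from .errors import (
    FitConvergenceError,
    InvalidInputError,
    NoEquilibriumError,
    UnderdeterminedError,
)
from ._seeding import rng_for

__all__ = [
    "R_GAS",
    "DEFAULT_TISSUE_STIFFNESS",
    "HydrogelComposition",
    "BathCondition",
    "BindingState",
    "MechanicalEnvironment",
    "SwellingSolution",
    "KineticsParams",
    "CalibratedModel",
    "charged_fraction",
    "osmotic_ionic",
    "osmotic_mixing",
    "osmotic_elastic",
    "equilibrium_swelling",
    "equilibrium_sr_curve",
    "length_sr_from_J",
    "j_from_length_sr",
    "transient_sr",
    "relaxation_fraction",
    "constrained_equilibrium",
    "solve_axial_profile",
    "fit_parameters",
    "load_default_model",
]

R_GAS = 8.314462618  # J / (mol K)

#: Tissue spring stiffness (Pa) calibrated so that the constrained-to-free
#: sensitivity ratio over 5-40 mM matches the measured 0.252/0.255 %/mM.
DEFAULT_TISSUE_STIFFNESS = 5.0e3

_J_BRACKET = (1.0 + 1e-9, 30.0)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class HydrogelComposition:
    """Material parameters of the gel, per unit reference (as-prepared) volume.

    Parameters
    ----------
    boronate_density : float
        PBA group concentration in the reference state, mol/m^3.
    crosslink_density : float
        Effective elastic chain density, mol/m^3.
    chi : float
        Flory-Huggins polymer-solvent interaction parameter.
    solvent_molar_volume : float
        Molar volume of water, m^3/mol.
    phi0 : float
        Polymer volume fraction in the reference state.
    silica_fraction : float
        Volume fraction of embedded silica microspheres (acoustic contrast
        agent; mechanically inert filler here).
    silica_stiffening : float
        Multiplicative stiffening of the elastic pressure caused by the
        rigid filler (>= 1; 1 = no stiffening).
    """

    boronate_density: float = 800.0
    crosslink_density: float = 100.0
    chi: float = 0.45
    solvent_molar_volume: float = 1.8e-5
    phi0: float = 0.2
    silica_fraction: float = 0.05
    silica_stiffening: float = 1.0

    def __post_init__(self):
        if self.boronate_density < 0:
            raise InvalidInputError("boronate_density must be >= 0")
        if self.crosslink_density <= 0:
            raise InvalidInputError("crosslink_density must be > 0")
        if not 0 < self.phi0 < 1:
            raise InvalidInputError("phi0 must lie in (0, 1)")
        if not 0 <= self.silica_fraction <= 0.2:
            raise InvalidInputError("silica_fraction must lie in [0, 0.2]")
        if self.silica_stiffening < 1:
            raise InvalidInputError("silica_stiffening must be >= 1")
        if self.solvent_molar_volume <= 0:
            raise InvalidInputError("solvent_molar_volume must be > 0")


@dataclass(frozen=True)
class BathCondition:
    """External solution: glucose (mM), pH, 1:1 salt (mM), temperature (K).

    Defaults are PBS at body temperature. Note mM == mol/m^3.
    """

    glucose: float = 0.0
    pH: float = 7.4
    salt: float = 150.0
    temperature: float = 310.0

    def __post_init__(self):
        if self.glucose < 0:
            raise InvalidInputError("glucose concentration must be >= 0")
        if not 0 < self.pH < 14:
            raise InvalidInputError("pH must lie in (0, 14)")
        if self.salt <= 0:
            raise InvalidInputError("salt concentration must be > 0")
        if self.temperature <= 0:
            raise InvalidInputError("temperature must be > 0")


@dataclass(frozen=True)
class BindingState:
    """Boronate ionisation/binding equilibria.

    ``Ka`` is the acid ionisation constant (M), ``Kb`` the 1:1
    glucose-boronate association constant (1/M).  ``charged_fraction``
    caches the fraction of boronate groups carrying net negative charge for
    a particular bath (filled in by solvers; 0 when not yet evaluated).
    """

    Ka: float = 10 ** -8.9
    Kb: float = 100.0
    charged_fraction: float = 0.0

    def __post_init__(self):
        if self.Ka <= 0 or self.Kb <= 0:
            raise InvalidInputError("Ka and Kb must be > 0")
        if not 0 <= self.charged_fraction <= 1:
            raise InvalidInputError("charged_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class MechanicalEnvironment:
    """Free swelling or linear tissue confinement.

    The confined gel feels a spring pressure
    ``P = k * max(J - J_baseline, 0) / J_baseline`` opposing swelling
    beyond the insertion state.
    """

    mode: str = "free"
    confinement_stiffness: float = 0.0

    def __post_init__(self):
        if self.mode not in ("free", "constrained"):
            raise InvalidInputError("mode must be 'free' or 'constrained'")
        if self.confinement_stiffness < 0:
            raise InvalidInputError("confinement_stiffness must be >= 0")
        if self.mode == "free" and self.confinement_stiffness != 0:
            raise InvalidInputError("free mode requires zero confinement")

    @classmethod
    def free(cls) -> "MechanicalEnvironment":
        return cls("free", 0.0)

    @classmethod
    def constrained(cls, stiffness: float = DEFAULT_TISSUE_STIFFNESS):
        return cls("constrained", stiffness)


@dataclass(frozen=True)
class SwellingSolution:
    """Equilibrium state: J, phi = phi0/J, length SR, pressure components (Pa)."""

    J: float
    phi: float
    sr_length: float
    pi_mix: float
    pi_elastic: float
    pi_ionic: float
    confinement_pressure: float = 0.0

    @property
    def residual(self) -> float:
        return self.pi_mix + self.pi_elastic + self.pi_ionic - self.confinement_pressure


@dataclass(frozen=True)
class KineticsParams:
    """Collective-diffusion swelling kinetics.

    ``tau1 = length_scale^2 / (pi^2 * collective_diffusivity)`` is the
    slowest relaxation time; defaults give tau1 ~ 20 min for a 1.2 mm
    needle, which puts the 60-min reading above 95 % of equilibrium.
    """

    collective_diffusivity: float = 1.2e-10  # m^2/s
    length_scale: float = 1.2e-3  # m, needle height
    n_modes: int = 10

    def __post_init__(self):
        if self.collective_diffusivity <= 0:
            raise InvalidInputError("collective_diffusivity must be > 0")
        if self.length_scale <= 0:
            raise InvalidInputError("length_scale must be > 0")
        if self.n_modes < 1:
            raise InvalidInputError("n_modes must be >= 1")

    @property
    def tau1_minutes(self) -> float:
        tau1_s = self.length_scale**2 / (math.pi**2 * self.collective_diffusivity)
        return tau1_s / 60.0


@dataclass(frozen=True)
class CalibratedModel:
    """A composition + binding + kinetics set tied to observed SR data."""

    composition: HydrogelComposition
    binding: BindingState
    kinetics: KineticsParams = field(default_factory=KineticsParams)
    baseline_J: float = 1.0
    fit_residual_rms: float = 0.0
    provenance: str = "unfitted"

    def __post_init__(self):
        if self.baseline_J < 1:
            raise InvalidInputError("baseline_J must be >= 1")
        if self.fit_residual_rms < 0:
            raise InvalidInputError("fit_residual_rms must be >= 0")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema": "sononeedle/calibrated-model/1",
            "composition": vars(self.composition).copy(),
            "binding": {"Ka": self.binding.Ka, "Kb": self.binding.Kb},
            "kinetics": vars(self.kinetics).copy(),
            "baseline_J": self.baseline_J,
            "fit_residual_rms": self.fit_residual_rms,
            "provenance": self.provenance,
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "CalibratedModel":
        return cls(
            composition=HydrogelComposition(**d["composition"]),
            binding=BindingState(**d["binding"]),
            kinetics=KineticsParams(**d["kinetics"]),
            baseline_J=d["baseline_J"],
            fit_residual_rms=d["fit_residual_rms"],
            provenance=d.get("provenance", "json"),
        )

    @classmethod
    def from_json(cls, path) -> "CalibratedModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))

    # -- convenience --------------------------------------------------------
    def sr_percent(self, glucose_mM, confinement_stiffness: float = 0.0,
                   time_min: float | None = None) -> np.ndarray:
        """Equilibrium SR (%) at one or more glucose levels; optionally the
        value reached ``time_min`` minutes after a step from the baseline."""
        sr = equilibrium_sr_curve(self, np.atleast_1d(np.asarray(glucose_mM, float)),
                                  confinement_stiffness=confinement_stiffness)
        if time_min is not None:
            sr = sr * relaxation_fraction(time_min, self.kinetics)
        return sr


def load_default_model() -> CalibratedModel:
    """The shipped calibration, fitted to the printed quasi-free SR table."""
    text = resources.files("sononeedle.data").joinpath("default_model.json").read_text()
    return CalibratedModel.from_dict(json.loads(text))


# ---------------------------------------------------------------------------
# pressure components
# ---------------------------------------------------------------------------

def charged_fraction(bath: BathCondition, Ka: float, Kb: float) -> float:
    """Fraction of boronate groups carrying net negative charge.

    Two coupled fast equilibria -- acid ionisation (Ka) and 1:1
    glucose-boronate association (Kb, binding shifts ionisation towards the
    charged form) -- give

        f = Ka (1 + Kb c_g) / ([H+] + Ka (1 + Kb c_g))

    with glucose ``c_g`` in M.  Monotone increasing in glucose and
    saturating at 1.
    """
    if Ka <= 0 or Kb <= 0:
        raise InvalidInputError("Ka and Kb must be > 0")
    h = 10.0 ** (-bath.pH)
    c_g = bath.glucose * 1e-3
    a = Ka * (1.0 + Kb * c_g)
    return a / (h + a)


def osmotic_ionic(fixed_charge: float, salt: float, temperature: float = 310.0) -> float:
    """Ideal-Donnan ionic pressure (Pa) for a 1:1 salt bath.

    ``Pi_ion = RT (sqrt(c_f^2 + 4 c_s^2) - 2 c_s)`` with the fixed-charge
    density ``c_f`` and bath salt ``c_s`` both in mol/m^3.  Zero iff the gel
    carries no fixed charge; decreasing in salt (screening).
    """
    if salt <= 0:
        raise InvalidInputError("salt concentration must be > 0")
    if fixed_charge < 0:
        raise InvalidInputError("fixed_charge must be >= 0")
    return R_GAS * temperature * (math.hypot(fixed_charge, 2.0 * salt) - 2.0 * salt)


def osmotic_mixing(phi: float, chi: float, solvent_molar_volume: float = 1.8e-5,
                   temperature: float = 310.0) -> float:
    """Flory-Huggins mixing pressure (Pa):
    ``-(RT/V1) [ln(1 - phi) + phi + chi phi^2]``."""
    if not 0 < phi < 1:
        raise InvalidInputError("phi must lie in (0, 1)")
    rt_v = R_GAS * temperature / solvent_molar_volume
    return -rt_v * (math.log1p(-phi) + phi + chi * phi * phi)


def osmotic_elastic(phi: float, phi0: float, crosslink_density: float,
                    temperature: float = 310.0, silica_stiffening: float = 1.0) -> float:
    """Affine Gaussian network pressure (Pa):
    ``-RT nu_c s [(phi/phi0)^(1/3) - phi/(2 phi0)]``.

    Negative (opposing swelling) whenever phi < phi0; the silica filler
    enters as a multiplicative stiffening factor ``s``.
    """
    if crosslink_density <= 0:
        raise InvalidInputError("crosslink_density must be > 0")
    if silica_stiffening < 1:
        raise InvalidInputError("silica_stiffening must be >= 1")
    x = phi / phi0
    return -R_GAS * temperature * crosslink_density * silica_stiffening * (
        x ** (1.0 / 3.0) - 0.5 * x
    )


# ---------------------------------------------------------------------------
# equilibrium
# ---------------------------------------------------------------------------

def length_sr_from_J(J, J_baseline):
    """Length swelling ratio from volumetric ratios, isotropic mapping
    ``sr = (J / J_baseline)^(1/3) - 1`` (dimensionless, not percent)."""
    J = np.asarray(J, dtype=float)
    if np.any(J <= 0) or J_baseline <= 0:
        raise InvalidInputError("J and J_baseline must be > 0")
    out = (J / J_baseline) ** (1.0 / 3.0) - 1.0
    return float(out) if out.ndim == 0 else out

def j_from_length_sr(sr, J_baseline):
    """Inverse of :func:`length_sr_from_J`."""
    sr = np.asarray(sr, dtype=float)
    if np.any(sr <= -1) or J_baseline <= 0:
        raise InvalidInputError("sr must be > -1 and J_baseline > 0")
    out = J_baseline * (1.0 + sr) ** 3
    return float(out) if out.ndim == 0 else out


def _confinement_pressure(J, env: MechanicalEnvironment, baseline_J: float):
    """Clamped linear spring: no pull below the insertion state."""
    return env.confinement_stiffness * np.maximum(J - baseline_J, 0.0) / baseline_J


def _pressure_residual(J, comp: HydrogelComposition, bath: BathCondition,
                       f: float, env: MechanicalEnvironment, baseline_J: float):
    """Net swelling pressure at volumetric ratio J (vectorised over J)."""
    J = np.asarray(J, dtype=float)
    phi = comp.phi0 / J
    rt = R_GAS * bath.temperature
    rt_v = rt / comp.solvent_molar_volume
    pi_mix = -rt_v * (np.log1p(-phi) + phi + comp.chi * phi * phi)
    x = phi / comp.phi0
    pi_el = -rt * comp.crosslink_density * comp.silica_stiffening * (
        x ** (1.0 / 3.0) - 0.5 * x
    )
    c_f = f * comp.boronate_density / J
    pi_ion = rt * (np.hypot(c_f, 2.0 * bath.salt) - 2.0 * bath.salt)
    return pi_mix + pi_el + pi_ion - _confinement_pressure(J, env, baseline_J)


def equilibrium_swelling(comp: HydrogelComposition, bath: BathCondition,
                         env: MechanicalEnvironment | None = None,
                         binding: BindingState | None = None,
                         baseline_J: float = 1.0) -> SwellingSolution:
    """Solve the pressure balance for the equilibrium volumetric ratio J.

    Brent root-finding on log J over [1, 30]; raises
    :class:`NoEquilibriumError` with the bracket-end pressure components if
    the residual does not change sign.  The returned state satisfies
    ``|Pi_mix + Pi_el + Pi_ion - P_conf| < 1e-6 RT/V1``.
    """
    env = env or MechanicalEnvironment.free()
    binding = binding or BindingState()
    f = charged_fraction(bath, binding.Ka, binding.Kb)

    lo, hi = _J_BRACKET
    def g(logJ):
        return float(_pressure_residual(math.exp(logJ), comp, bath, f, env, baseline_J))

    glo, ghi = g(math.log(lo)), g(math.log(hi))
    if glo * ghi > 0:
        raise NoEquilibriumError(
            "swelling-pressure residual has no sign change on J in [1, 30]",
            diagnostics={"residual_at_J1": glo, "residual_at_J30": ghi,
                         "charged_fraction": f},
        )
    logJ = brentq(g, math.log(lo), math.log(hi), xtol=1e-13, rtol=8.9e-16)
    J = math.exp(logJ)
    phi = comp.phi0 / J
    sol = SwellingSolution(
        J=J,
        phi=phi,
        sr_length=length_sr_from_J(J, baseline_J),
        pi_mix=osmotic_mixing(phi, comp.chi, comp.solvent_molar_volume, bath.temperature),
        pi_elastic=osmotic_elastic(phi, comp.phi0, comp.crosslink_density,
                                   bath.temperature, comp.silica_stiffening),
        pi_ionic=osmotic_ionic(f * comp.boronate_density / J, bath.salt, bath.temperature),
        confinement_pressure=float(_confinement_pressure(J, env, baseline_J)),
    )
    tol = 1e-6 * R_GAS * bath.temperature / comp.solvent_molar_volume
    assert abs(sol.residual) < tol, "equilibrium residual above tolerance"
    return sol


def equilibrium_sr_curve(model: CalibratedModel, glucose_mM: np.ndarray,
                         confinement_stiffness: float = 0.0,
                         bath: BathCondition | None = None,
                         n_bisect: int = 80) -> np.ndarray:
    """Vectorised equilibrium SR (%) over an array of glucose levels.

    Bisection on log J, fixed iteration count; used by the fitting loop
    where thousands of equilibria are evaluated.  Agrees with
    :func:`equilibrium_swelling` to well below solver tolerance.
    """
    bath = bath or BathCondition()
    comp, binding = model.composition, model.binding
    env = (MechanicalEnvironment.constrained(confinement_stiffness)
           if confinement_stiffness > 0 else MechanicalEnvironment.free())
    glucose = np.asarray(glucose_mM, dtype=float)
    if np.any(glucose < 0):
        raise InvalidInputError("glucose must be >= 0")
    h = 10.0 ** (-bath.pH)
    a = binding.Ka * (1.0 + binding.Kb * glucose * 1e-3)
    f = a / (h + a)

    lo = np.full(glucose.shape, math.log(_J_BRACKET[0]))
    hi = np.full(glucose.shape, math.log(_J_BRACKET[1]))

    def res(logJ):
        J = np.exp(logJ)
        phi = comp.phi0 / J
        rt = R_GAS * bath.temperature
        pi_mix = -(rt / comp.solvent_molar_volume) * (
            np.log1p(-phi) + phi + comp.chi * phi * phi)
        x = phi / comp.phi0
        pi_el = -rt * comp.crosslink_density * comp.silica_stiffening * (
            x ** (1.0 / 3.0) - 0.5 * x)
        c_f = f * comp.boronate_density / J
        pi_ion = rt * (np.hypot(c_f, 2.0 * bath.salt) - 2.0 * bath.salt)
        p_conf = confinement_stiffness * np.maximum(J - model.baseline_J, 0.0) / model.baseline_J
        return pi_mix + pi_el + pi_ion - p_conf

    rlo, rhi = res(lo), res(hi)
    if np.any(rlo * rhi > 0):
        raise NoEquilibriumError("no sign change in bracket for some glucose levels")
    for _ in range(n_bisect):
        mid = 0.5 * (lo + hi)
        rmid = res(mid)
        take_hi = rlo * rmid <= 0
        hi = np.where(take_hi, mid, hi)
        lo = np.where(take_hi, lo, mid)
        rlo = np.where(take_hi, rlo, rmid)
    J = np.exp(0.5 * (lo + hi))
    return 100.0 * ((J / model.baseline_J) ** (1.0 / 3.0) - 1.0)


def constrained_equilibrium(model: CalibratedModel, bath: BathCondition,
                            confinement_stiffness: float = DEFAULT_TISSUE_STIFFNESS
                            ) -> SwellingSolution:
    """Equilibrium under linear tissue confinement; zero stiffness reduces
    to the free solution, infinite stiffness pins J at the baseline."""
    if confinement_stiffness < 0:
        raise InvalidInputError("confinement_stiffness must be >= 0")
    env = (MechanicalEnvironment.constrained(confinement_stiffness)
           if confinement_stiffness > 0 else MechanicalEnvironment.free())
    return equilibrium_swelling(model.composition, bath, env, model.binding,
                                baseline_J=model.baseline_J)


def solve_axial_profile(model: CalibratedModel, bath: BathCondition,
                        confinement_profile, n_elements: int) -> list[SwellingSolution]:
    """Per-element equilibrium along the needle axis (tip = coordinate 0).

    ``confinement_profile`` is either a callable of the normalised axial
    coordinate x in [0, 1] returning a stiffness (Pa), or a sequence of
    per-element stiffnesses.  Each element is in local equilibrium with the
    bath -- a 1-D reduction of the full continuum problem.
    """
    if n_elements < 1:
        raise InvalidInputError("n_elements must be >= 1")
    centers = (np.arange(n_elements) + 0.5) / n_elements
    if callable(confinement_profile):
        stiffness = np.asarray([confinement_profile(x) for x in centers], float)
    else:
        stiffness = np.asarray(confinement_profile, dtype=float)
        if stiffness.shape != (n_elements,):
            raise InvalidInputError(
                f"confinement profile length {stiffness.size} != n_elements {n_elements}")
    return [constrained_equilibrium(model, bath, float(k)) for k in stiffness]


# ---------------------------------------------------------------------------
# kinetics
# ---------------------------------------------------------------------------

def _mode_spectrum(kinetics: KineticsParams):
    """Relaxation rates (1/min) and weights of the slab diffusion series.

    Weights 8/((2k-1)^2 pi^2) are renormalised to sum to 1 so that the
    truncated series starts exactly at the pre-step value.
    """
    k = np.arange(1, kinetics.n_modes + 1)
    odd = 2 * k - 1
    rates = odd**2 / kinetics.tau1_minutes
    weights = 8.0 / (odd**2 * math.pi**2)
    return rates, weights / weights.sum()


def relaxation_fraction(t_minutes, kinetics: KineticsParams) -> np.ndarray | float:
    """Fraction of a step change in equilibrium SR completed after t minutes."""
    t = np.asarray(t_minutes, dtype=float)
    if np.any(t < 0):
        raise InvalidInputError("time must be >= 0")
    rates, weights = _mode_spectrum(kinetics)
    g = 1.0 - np.sum(weights * np.exp(-np.outer(t, rates)), axis=1)
    return float(g[0]) if np.ndim(t_minutes) == 0 else g


def transient_sr(model: CalibratedModel, bath_schedule: Sequence[tuple],
                 times, initial_sr: float = 0.0,
                 confinement_stiffness: float = 0.0) -> np.ndarray:
    """SR (%) time series under a piecewise-constant bath schedule.

    ``bath_schedule`` is a sequence of ``(start_minute, bath)`` pairs with
    the first start at 0; ``bath`` may be a :class:`BathCondition` or a bare
    glucose level in mM.  The relaxation is the superposition of diffusion
    modes, each mode tracking its segment-wise equilibrium target -- exact
    for piecewise-constant forcing.
    """
    times = np.asarray(times, dtype=float)
    if times.size and (np.any(np.diff(times) < 0) or times[0] < 0):
        raise InvalidInputError("times must be nonnegative and nondecreasing")
    starts = [float(s) for s, _ in bath_schedule]
    if starts != sorted(starts) or (starts and starts[0] != 0.0):
        raise InvalidInputError("schedule starts must be sorted and begin at 0")

    def as_bath(b):
        return b if isinstance(b, BathCondition) else BathCondition(glucose=float(b))

    sr_eq = np.array([
        model.sr_percent(as_bath(b).glucose, confinement_stiffness)[0]
        for _, b in bath_schedule
    ])
    rates, weights = _mode_spectrum(model.kinetics)
    # per-mode deficit amplitudes at segment entry
    b_modes = weights * (sr_eq[0] - initial_sr)
    out = np.empty_like(times)
    seg = 0
    t_entry = 0.0
    for i, t in enumerate(times):
        while seg + 1 < len(starts) and t >= starts[seg + 1]:
            # roll modes forward to the boundary, then retarget
            dt = starts[seg + 1] - t_entry
            b_modes = b_modes * np.exp(-rates * dt)
            b_modes = b_modes + weights * (sr_eq[seg + 1] - sr_eq[seg])
            t_entry = starts[seg + 1]
            seg += 1
        out[i] = sr_eq[seg] - np.sum(b_modes * np.exp(-rates * (t - t_entry)))
    return out


# ---------------------------------------------------------------------------
# parameter fitting
# ---------------------------------------------------------------------------

_FIT_BOUNDS = {
    "log10_Kb": (0.0, 4.5),       # glucose-boronate association, 1 .. 3e4 1/M
    "crosslink_density": (1.0, 500.0),
    "chi": (0.30, 0.58),
    "baseline_J": (1.0, 10.0),
}
_FIT_ORDER = tuple(_FIT_BOUNDS)


def _model_from_params(params: dict, template: CalibratedModel) -> CalibratedModel:
    comp = replace(template.composition,
                   crosslink_density=params["crosslink_density"],
                   chi=params["chi"])
    binding = BindingState(Ka=template.binding.Ka, Kb=10.0 ** params["log10_Kb"])
    return replace(template, composition=comp, binding=binding,
                   baseline_J=params["baseline_J"])


def fit_parameters(observations, fixed: dict | None = None, seed: int = 0,
                   template: CalibratedModel | None = None, n_starts: int = 8,
                   provenance: str = "fit") -> CalibratedModel:
    """Fit model parameters to observed (glucose mM, SR %) pairs.

    Free parameters are ``log10_Kb``, ``crosslink_density``, ``chi`` and
    ``baseline_J`` unless pinned through ``fixed`` (name -> value).  Bounded
    trust-region least squares from ``n_starts`` seeded multistart points;
    the best run is returned as a :class:`CalibratedModel` with the SR
    percentage-point RMS of the fit recorded.
    """
    obs = np.asarray(observations, dtype=float)
    if obs.ndim != 2 or obs.shape[1] < 2:
        raise InvalidInputError("observations must be (n, 2) of (glucose, SR%)")
    glucose, sr_obs = obs[:, 0], obs[:, 1]
    if np.unique(glucose).size < 3:
        raise UnderdeterminedError("need >= 3 distinct glucose levels to fit")
    if np.any(sr_obs <= -100.0):
        raise InvalidInputError("SR values must exceed -100 %")

    fixed = dict(fixed or {})
    template = template or CalibratedModel(
        composition=HydrogelComposition(), binding=BindingState())
    free_names = [n for n in _FIT_ORDER if n not in fixed]
    if not free_names:
        raise InvalidInputError("at least one parameter must remain free")
    lb = np.array([_FIT_BOUNDS[n][0] for n in free_names])
    ub = np.array([_FIT_BOUNDS[n][1] for n in free_names])

    def unpack(x):
        params = dict(fixed)
        params.update(zip(free_names, x))
        params.setdefault("log10_Kb", math.log10(template.binding.Kb))
        params.setdefault("crosslink_density", template.composition.crosslink_density)
        params.setdefault("chi", template.composition.chi)
        params.setdefault("baseline_J", template.baseline_J)
        return params

    def cost(x):
        model = _model_from_params(unpack(x), template)
        try:
            return equilibrium_sr_curve(model, glucose) - sr_obs
        except (NoEquilibriumError, InvalidInputError):
            return np.full(glucose.size, 1e3)

    rng = rng_for(seed, "fit-multistart")
    best = None
    for _ in range(n_starts):
        x0 = lb + (ub - lb) * rng.uniform(0.05, 0.95, size=lb.size)
        try:
            res = least_squares(cost, x0, bounds=(lb, ub), method="trf",
                                xtol=1e-12, ftol=1e-12, max_nfev=400)
        except Exception:  # pragma: no cover - scipy internal failure
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None or not np.all(np.isfinite(best.x)):
        raise FitConvergenceError("optimiser failed on every start", best=best)
    model = _model_from_params(unpack(best.x), template)
    rms = float(np.sqrt(np.mean(cost(best.x) ** 2)))
    if rms >= 1e3:
        raise FitConvergenceError("no feasible equilibrium at best parameters",
                                  best=model)
    return replace(model, fit_residual_rms=rms, provenance=provenance)
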