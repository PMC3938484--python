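"""Chemiosmotic model of the proton motive force (PMF) under acid stress.

The proton motive force across the bacterial inner membrane combines an
electrical term (the membrane potential, Δψ, inside minus outside) and a
chemical term from the transmembrane pH gradient:

    Δp = Δψ − Z·ΔpH,   ΔpH = pH_i − pH_e,   Z = ln(10)·R·T/F  (mV per pH unit)

Negative Δp drives protons into the cell; a positive Δp (an *inverted* PMF)
drives them out. Weak carboxylic acids such as octanoic acid (C8, pKa 4.89)
cross the membrane in their protonated form and deprotonate in the cytoplasm,
so a C8 shock at neutral media pH acidifies the cell interior, inverts ΔpH and
— transiently — the PMF itself. A strong mineral acid like HCl delivers equal
amounts of protons and counter-anions to the medium and so perturbs pH without
an immediate membrane-potential change.

This module provides the Nernst/Mitchell primitives, Henderson–Hasselbalch
acid speciation, and a three-phase scenario solver (normal → shock → adapted)
that finds the membrane-potential adjustment — cation accumulation for
inorganic acids, anion accumulation for carboxylic acids — required to bring
the PMF back into the physiological range (−140 to −180 mV for E. coli, with
−160 mV as the normal-state average).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace

import yaml
from scipy.optimize import brentq

from .errors import InvalidInputError, SolverError

__all__ = [
    "ThermoContext",
    "IonPool",
    "CompartmentState",
    "AcidSpecies",
    "Scenario",
    "ScenarioResult",
    "OCTANOIC_ACID",
    "zeta_factor",
    "ph_gradient_force",
    "nernst_potential",
    "pmf_total",
    "protonated_fraction",
    "equimolar_pH",
    "normal_scenario",
    "apply_shock",
    "solve_adaptation",
    "load_scenario",
]

#: Physiological PMF band for E. coli K-12, mV.
PHYSIOLOGICAL_PMF_RANGE = (-180.0, -140.0)
#: Normal-state average PMF, mV.
NORMAL_PMF_MV = -160.0


@dataclass(frozen=True)
class ThermoContext:
    """Physical constants and temperature for electrochemical calculations.

    Parameters
    ----------
    temperature_K
        Absolute temperature in kelvin. Default 310.15 K (37 °C, the growth
        temperature); use 303.15 K for plate-reader measurements at 30 °C.
    gas_constant
        R in J·mol⁻¹·K⁻¹.
    faraday
        F in C·mol⁻¹.
    """

    temperature_K: float = 310.15
    gas_constant: float = 8.314
    faraday: float = 96485.0

    def __post_init__(self) -> None:
        if not (self.temperature_K > 0):
            raise InvalidInputError(
                f"temperature must be positive, got {self.temperature_K} K"
            )


@dataclass(frozen=True)
class IonPool:
    """One ion species with its charge and transmembrane abundances (mM)."""

    species: str
    z: int
    ions_i: float
    ions_e: float

    def __post_init__(self) -> None:
        if self.z == 0 or self.z != int(self.z):
            raise InvalidInputError(f"charge z must be a nonzero integer, got {self.z}")
        if self.ions_i <= 0 or self.ions_e <= 0:
            raise InvalidInputError("ion abundances must be positive")


def _check_ph(value: float, name: str = "pH") -> float:
    if not (0.0 <= value <= 14.0) or not math.isfinite(value):
        raise InvalidInputError(f"{name} must lie in [0, 14], got {value}")
    return float(value)


@dataclass(frozen=True)
class CompartmentState:
    """Intra/extracellular pH, membrane potential and optional ion pools.

    ``delta_psi`` is the membrane potential Δψ in mV, inside minus outside.
    """

    pH_i: float
    pH_e: float
    delta_psi: float
    ion_pools: tuple[IonPool, ...] = ()

    def __post_init__(self) -> None:
        _check_ph(self.pH_i, "pH_i")
        _check_ph(self.pH_e, "pH_e")


@dataclass(frozen=True)
class AcidSpecies:
    """A weak acid characterized by its pKa.

    ``membrane_permeant_when_protonated`` marks carboxylic acids whose neutral
    protonated form diffuses through the lipid bilayer and releases its proton
    in the cytoplasm — the mechanism behind intracellular acidification at
    neutral media pH.
    """

    name: str
    pKa: float
    membrane_permeant_when_protonated: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.pKa < 14.0):
            raise InvalidInputError(f"pKa must lie in (0, 14), got {self.pKa}")


#: Octanoic acid (C8), pKa 4.89.
OCTANOIC_ACID = AcidSpecies("octanoic acid", pKa=4.89)


@dataclass(frozen=True)
class Scenario:
    """A named acid-challenge configuration.

    ``acid`` is an :class:`AcidSpecies` for weak/carboxylic acids or a plain
    string tag (e.g. ``"HCl"``) for strong inorganic acids, which are treated
    as fully dissociated. ``target_pmf_mean``/``target_pmf_range`` define the
    physiological band the adaptation solver aims for.
    """

    label: str
    acid: AcidSpecies | str
    dose_mM: float
    thermo: ThermoContext
    state: CompartmentState
    target_pmf_mean: float = NORMAL_PMF_MV
    target_pmf_range: tuple[float, float] = PHYSIOLOGICAL_PMF_RANGE

    def __post_init__(self) -> None:
        lo, hi = self.target_pmf_range
        if not (lo <= self.target_pmf_mean <= hi):
            raise InvalidInputError(
                "target_pmf_mean must lie inside target_pmf_range"
            )

    @property
    def is_carboxylic(self) -> bool:
        return isinstance(self.acid, AcidSpecies)


@dataclass(frozen=True)
class ScenarioResult:
    """PMF decomposition for one scenario phase.

    ``psi_force`` is the Δψ electrical term and ``ph_force`` the −Z·ΔpH
    chemical term, so ``pmf = psi_force + ph_force`` exactly. For adapted
    states, ``delta_psi_required`` is the membrane potential the cell must
    reach and ``ion_fold_change`` the Nernst-equivalent molar fold-change of a
    monovalent carrier ion relative to the pre-adaptation state.
    """

    label: str
    pH_i: float
    pH_e: float
    delta_psi: float
    ph_force: float
    pmf: float
    inverted: bool
    delta_psi_required: float | None = None
    ion_fold_change: float | None = None

    @property
    def psi_force(self) -> float:
        return self.delta_psi


def zeta_factor(thermo: ThermoContext) -> float:
    """Nernstian slope Z = ln(10)·R·T/F in mV per pH unit.

    ≈61.5 mV at 37 °C; strictly positive and linear in T.
    """
    return (
        math.log(10.0)
        * thermo.gas_constant
        * thermo.temperature_K
        / thermo.faraday
        * 1000.0
    )


def ph_gradient_force(pH_i: float, pH_e: float, thermo: ThermoContext) -> float:
    """ΔpH-associated electrochemical force, −Z·(pH_i − pH_e), in mV.

    Negative when the cytoplasm is more alkaline than the medium (the normal
    state, where the pH term pulls protons inward); positive when the gradient
    is inverted by intracellular acidification.
    """
    _check_ph(pH_i, "pH_i")
    _check_ph(pH_e, "pH_e")
    return -zeta_factor(thermo) * (pH_i - pH_e)


def nernst_potential(
    ions_i: float, ions_e: float, z: int, thermo: ThermoContext
) -> float:
    """Equilibrium (Nernst) potential for an ion gradient, in mV.

    (R·T/(z·F))·ln(ions_e/ions_i); antisymmetric under swapping the two
    pools and invariant to scaling both by a common factor.
    """
    if z == 0 or z != int(z):
        raise InvalidInputError(f"charge z must be a nonzero integer, got {z}")
    if ions_i <= 0 or ions_e <= 0:
        raise InvalidInputError("ion abundances must be positive")
    rt_zf = thermo.gas_constant * thermo.temperature_K / (z * thermo.faraday)
    return rt_zf * math.log(ions_e / ions_i) * 1000.0


def pmf_total(
    delta_psi: float, pH_i: float, pH_e: float, thermo: ThermoContext
) -> float:
    """Total proton motive force Δp = Δψ − Z·ΔpH, in mV."""
    return delta_psi + ph_gradient_force(pH_i, pH_e, thermo)


def protonated_fraction(pH: float, acid: AcidSpecies) -> float:
    """Henderson–Hasselbalch fraction of the acid in its protonated form.

    1/(1 + 10^(pH − pKa)): 0.5 at pH = pKa, ≈0.0077 for C8 at pH 7.0 — the
    membrane-permeant neutral species is a small minority in neutral media,
    yet suffices to shuttle protons inward.
    """
    _check_ph(pH)
    return 1.0 / (1.0 + 10.0 ** (pH - acid.pKa))


def equimolar_pH(acid: AcidSpecies) -> float:
    """pH at which protonated and deprotonated forms are equimolar.

    Solved by numerically inverting :func:`protonated_fraction` rather than
    returning the pKa directly; agreement with the pKa to ≤1e−9 is a
    consistency check on the speciation model.
    """
    return float(brentq(lambda ph: protonated_fraction(ph, acid) - 0.5,
                        1e-9, 14.0 - 1e-9, xtol=1e-12))


def normal_scenario(
    pH_i: float = 7.6,
    pH_e: float = 7.0,
    thermo: ThermoContext | None = None,
    target_pmf_mean: float = NORMAL_PMF_MV,
    target_pmf_range: tuple[float, float] = PHYSIOLOGICAL_PMF_RANGE,
    acid: AcidSpecies | str = OCTANOIC_ACID,
    dose_mM: float = 0.0,
) -> Scenario:
    """Unstressed reference scenario with Δψ closed from the target PMF.

    E. coli growing at neutral media pH holds its cytoplasm near pH 7.6 and a
    PMF near −160 mV; Δψ is solved from Δp = Δψ − Z·ΔpH (≈ −123.1 mV at
    37 °C) rather than specified independently.
    """
    thermo = thermo or ThermoContext()
    delta_psi = target_pmf_mean - ph_gradient_force(pH_i, pH_e, thermo)
    state = CompartmentState(pH_i=pH_i, pH_e=pH_e, delta_psi=delta_psi)
    return Scenario(
        label="normal",
        acid=acid,
        dose_mM=dose_mM,
        thermo=thermo,
        state=state,
        target_pmf_mean=target_pmf_mean,
        target_pmf_range=target_pmf_range,
    )


def _result_from_state(
    label: str, state: CompartmentState, thermo: ThermoContext, **extra
) -> ScenarioResult:
    ph_force = ph_gradient_force(state.pH_i, state.pH_e, thermo)
    pmf = state.delta_psi + ph_force
    return ScenarioResult(
        label=label,
        pH_i=state.pH_i,
        pH_e=state.pH_e,
        delta_psi=state.delta_psi,
        ph_force=ph_force,
        pmf=pmf,
        inverted=pmf > 0,
        **extra,
    )


def apply_shock(
    normal: Scenario,
    acid: AcidSpecies | str | None = None,
    dose_mM: float | None = None,
    measured_pH_i: float | None = None,
    pH_e_after: float | None = None,
) -> ScenarioResult:
    """Instantaneous PMF outcome of an acid shock, before any cell response.

    Two branches:

    * **Inorganic** (strong mineral acid, e.g. HCl): protons arrive with an
      equal number of counter-anions, so Δψ is unchanged. The measured
      intracellular pH and — for unadjusted media — the new extracellular pH
      are taken as inputs, never predicted. ``pH_e_after`` must be supplied
      when the medium was not readjusted; ``None`` keeps the normal pH_e
      (readjusted media).
    * **Carboxylic**: the protonated acid partitions into the membrane and
      deprotonates inside, an irreversible intracellular proton load with no
      accompanying anion entry. The uncompensated positive charge shifts Δψ
      by +Z·(pH_i,normal − pH_i,shock), the Nernst equivalent of the proton
      pool fold-increase, which together with the inverted ΔpH produces a
      positive (inverted) PMF.

    A zero dose returns the normal state unchanged.
    """
    acid = normal.acid if acid is None else acid
    dose = normal.dose_mM if dose_mM is None else dose_mM
    thermo = normal.thermo
    base = normal.state

    if dose == 0:
        return _result_from_state("normal", base, thermo)
    if measured_pH_i is None:
        raise InvalidInputError("apply_shock requires measured_pH_i for a nonzero dose")
    _check_ph(measured_pH_i, "measured_pH_i")

    carboxylic = isinstance(acid, AcidSpecies)
    pH_e = base.pH_e if pH_e_after is None else _check_ph(pH_e_after, "pH_e_after")

    if carboxylic:
        if measured_pH_i >= base.pH_i:
            warnings.warn(
                "carboxylic shock without intracellular proton load "
                f"(pH_i {measured_pH_i} >= normal {base.pH_i})",
                stacklevel=2,
            )
            delta_psi = base.delta_psi
        else:
            delta_psi = base.delta_psi + zeta_factor(thermo) * (
                base.pH_i - measured_pH_i
            )
    else:
        delta_psi = base.delta_psi

    state = replace(base, pH_i=measured_pH_i, pH_e=pH_e, delta_psi=delta_psi)
    return _result_from_state("shock", state, thermo)


def solve_adaptation(shock: ScenarioResult, scenario: Scenario) -> ScenarioResult:
    """Membrane-potential adjustment restoring the PMF to its target.

    With pH values pinned at their shocked levels, the only lever left is Δψ:
    cation accumulation (inorganic challenge) or anion accumulation
    (carboxylic challenge, where the required shift is strongly negative)
    moves Δψ to ``target − ph_force``. The closed-form solution is verified by
    bisection to 0.1 mV; ``ion_fold_change`` converts the Δψ shift into the
    molar fold-change of a single monovalent carrier ion via
    exp(|ΔΔψ|·F/(R·T)).
    """
    thermo = scenario.thermo
    target = scenario.target_pmf_mean
    ph_force = shock.ph_force

    delta_psi_required = target - ph_force
    if not math.isfinite(delta_psi_required):
        raise SolverError("adaptation target unreachable: non-finite delta_psi")

    # bisection fallback cross-checks the algebra on the same residual
    def residual(dpsi: float) -> float:
        return pmf_total(dpsi, shock.pH_i, shock.pH_e, thermo) - target

    lo, hi = delta_psi_required - 500.0, delta_psi_required + 500.0
    if residual(lo) * residual(hi) <= 0:
        bisected = brentq(residual, lo, hi, xtol=1e-9, maxiter=200)
        if abs(bisected - delta_psi_required) > 1e-6:
            raise SolverError("bisection disagrees with closed-form delta_psi")

    pmf = pmf_total(delta_psi_required, shock.pH_i, shock.pH_e, thermo)
    if abs(pmf - target) > 0.1:
        raise SolverError(
            f"adapted PMF {pmf:.3f} mV missed target {target:.3f} mV"
        )

    shift = delta_psi_required - shock.delta_psi
    fold = math.exp(
        abs(shift) / 1000.0 * thermo.faraday
        / (thermo.gas_constant * thermo.temperature_K)
    )
    state = CompartmentState(
        pH_i=shock.pH_i, pH_e=shock.pH_e, delta_psi=delta_psi_required
    )
    return _result_from_state(
        "adapted",
        state,
        thermo,
        delta_psi_required=delta_psi_required,
        ion_fold_change=fold,
    )


def run_scenario(
    scenario: Scenario,
    measured_pH_i: float,
    pH_e_after: float | None = None,
) -> dict[str, ScenarioResult]:
    """All three phases — normal, shock, adapted — for one challenge."""
    normal = _result_from_state("normal", scenario.state, scenario.thermo)
    shock = apply_shock(
        scenario, measured_pH_i=measured_pH_i, pH_e_after=pH_e_after
    )
    adapted = solve_adaptation(shock, scenario)
    return {"normal": normal, "shock": shock, "adapted": adapted}


def load_scenario(path) -> tuple[Scenario, float, float | None]:
    """Read a scenario config file.

    YAML keys: acid, pKa (omit for a strong inorganic acid), dose_mM, pH_i
    (the *measured* shocked intracellular pH), pH_e (media pH after challenge;
    omit if readjusted to the normal 7.0), temperature_K, target_pmf_mV,
    target_range_mV. Returns (normal scenario, measured_pH_i, pH_e_after).
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    thermo = ThermoContext(temperature_K=float(cfg.get("temperature_K", 310.15)))
    acid_name = str(cfg["acid"])
    if cfg.get("pKa") is not None:
        acid: AcidSpecies | str = AcidSpecies(acid_name, pKa=float(cfg["pKa"]))
    else:
        acid = acid_name  # inorganic tag
    target = float(cfg.get("target_pmf_mV", NORMAL_PMF_MV))
    rng = cfg.get("target_range_mV", list(PHYSIOLOGICAL_PMF_RANGE))
    scenario = normal_scenario(
        thermo=thermo,
        target_pmf_mean=target,
        target_pmf_range=(float(rng[0]), float(rng[1])),
        acid=acid,
        dose_mM=float(cfg.get("dose_mM", 0.0)),
    )
    measured_pH_i = float(cfg["pH_i"])
    pH_e_after = None if cfg.get("pH_e") is None else float(cfg["pH_e"])
    return scenario, measured_pH_i, pH_e_after
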