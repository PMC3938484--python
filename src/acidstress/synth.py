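"""Seeded generators for every pipeline input, with physiological presets.

Each generator draws from the statistical model the corresponding analysis
assumes — expression as connectivity × activity plus log-scale Gaussian
noise, exponential growth with multiplicative (lognormal) read noise,
fluorescence from the monotone reporter calibration curve, lipid mol%
profiles as tight Dirichlet perturbations of strain/dose-dependent means —
and returns the ground truth alongside the data so parameter-recovery tests
can close the loop. Identical seeds give identical output.

The named presets embed the physiological values reported for E. coli under
octanoic-acid (C8) challenge: 23% growth inhibition at 10 mM C8 (pH 7.0),
intracellular pH 5.32 after an unadjusted 20 mM HCl shock, acidification to
(at or below) the pH 5.5 reporter floor during long-term C8 exposure,
intracellular pH above 6.5 in producing strains, >32 mol% cyclopropane
lipids in cfa-overexpressing membranes versus <11 mol% in wildtype, and zero
cyclopropanes in the Δcfa knockout.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .errors import InvalidInputError
from .expression import ExpressionStudy
from .nca import RegulatoryTopology, check_identifiability
from .physiology import (
    CYCLOPROPANE,
    LIPID_SPECIES,
    GabaMeasurement,
    GrowthSeries,
    LipidProfile,
)
from .reporter import CalibrationStandard

__all__ = [
    "GROWTH_PRESETS",
    "FLUOR_PRESETS",
    "LIPID_BASE_PROFILES",
    "GABA_ARM_MEANS",
    "gen_expression",
    "gen_de_study",
    "gen_growth_curves",
    "gen_fluorescence",
    "gen_lipid_profiles",
    "gen_gaba",
    "demo_topology",
]

# ---------------------------------------------------------------------------
# Preset registry. Every embedded constant is a physiological value for the
# E. coli C8-challenge system (see docs/methods.md for units and rationale).
# ---------------------------------------------------------------------------

GROWTH_PRESETS: dict[str, dict[str, float]] = {
    # 10 mM C8 at media pH 7.0 inhibits growth by 23%
    "c8_10mM": {"mu_control": 0.50, "inhibition_pct": 23.0},
    "no_stress": {"mu_control": 0.50, "inhibition_pct": 0.0},
}

FLUOR_PRESETS: dict[str, dict[str, float]] = {
    # 20 mM HCl without media readjustment drops intracellular pH to 5.32
    "hcl_20mM_unadjusted": {"true_ph": 5.32},
    # long-term C8 challenge acidifies to (at or below) the pH 5.5 floor
    "c8_longterm": {"true_ph": 5.20},
    # carboxylic-acid producing strains stay above pH 6.5
    "production": {"true_ph": 6.80},
    "unstressed": {"true_ph": 7.60},
}

#: Reporter calibration truth: fluorescence = slope·pH + intercept (a.u.).
#: Standards reach to pH 5.25, just under the 5.5 reliable detection limit,
#: so that sharp shocks (pH 5.32) are resolvable while deeper acidification
#: censors at the limit.
_FLUOR_SLOPE = 120.0
_FLUOR_INTERCEPT = -560.0
_CAL_PH_GRID = (5.25, 5.5, 6.0, 6.5, 7.0, 7.5, 8.0)

#: Baseline mol% by strain at zero dose. Wildtype carries ~9 mol%
#: cyclopropanes (below the 11 mol% ceiling observed for unstressed WT),
#: the cfa overexpresser 35 mol% (above the 32 mol% floor), the knockout none.
LIPID_BASE_PROFILES: dict[str, dict[str, float]] = {
    "WT": {
        "C12:0": 2.0, "C14:0": 4.0, "C16:0": 35.0, "C16:1": 27.0,
        "C17cyc": 7.5, "C18:0": 2.0, "C18:1": 21.0, "C19cyc": 1.5,
    },
    "cfa++": {
        "C12:0": 2.0, "C14:0": 3.0, "C16:0": 30.0, "C16:1": 12.0,
        "C17cyc": 20.0, "C18:0": 2.0, "C18:1": 16.0, "C19cyc": 15.0,
    },
    "dcfa": {
        "C12:0": 2.0, "C14:0": 4.0, "C16:0": 35.0, "C16:1": 33.0,
        "C17cyc": 0.0, "C18:0": 2.0, "C18:1": 24.0, "C19cyc": 0.0,
    },
}

#: (intracellular, extracellular) GABA means per experimental arm, µmol/gDW.
#: Control pools are near-equal; glutamate boosts export at constant total;
#: C8 lowers every pool (the AR2 system fails under membrane damage).
GABA_ARM_MEANS: dict[str, tuple[float, float]] = {
    "control": (5.0, 5.0),
    "glutamate": (2.5, 7.5),
    "c8": (2.0, 2.5),
    "c8_glutamate": (1.5, 3.0),
}


@dataclass
class GroundTruth:
    """What the generator actually used, for recovery tests."""

    params: dict[str, Any] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Expression
# ---------------------------------------------------------------------------

def demo_topology(n_tf: int = 3, targets_per_tf: int = 4, shared: int = 2,
                  signed: bool = True) -> RegulatoryTopology:
    """Small identifiable topology: each TF gets private targets plus a chain
    of shared ones, mimicking the overlap structure of real regulons."""
    pairs, signs = [], []
    gene = 0
    for j in range(n_tf):
        for _ in range(targets_per_tf):
            pairs.append((f"TF{j + 1}", f"g{gene:03d}"))
            signs.append(1 if (gene % 3) else -1)
            gene += 1
    for j in range(n_tf - 1):  # shared targets chain adjacent TFs
        for s in range(shared):
            g = f"gs{j}_{s}"
            pairs.append((f"TF{j + 1}", g))
            signs.append(1)
            pairs.append((f"TF{j + 2}", g))
            signs.append(-1)
    return RegulatoryTopology.from_edges(pairs, signs if signed else None)


def gen_expression(
    topology: RegulatoryTopology,
    true_P: pd.DataFrame,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Expression study drawn from the NCA model E = A·P + noise.

    ``true_P`` is TFs × conditions with condition names ``control``/
    ``treated`` (each condition is replicated ``n_replicates`` times with
    fresh Gaussian noise in log2 space). A is drawn on the topology support
    with magnitudes in [0.5, 1.5] and the edge signs.
    """
    if noise_sd < 0:
        raise InvalidInputError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    sup = topology.support()
    # replicate columns are distinct samples, so they count toward P's width
    report = check_identifiability(
        topology, n_conditions=true_P.shape[1] * n_replicates
    )

    mask = sup.to_numpy() != 0
    signs = np.where(sup.to_numpy() < 0, -1.0, 1.0)
    A = np.where(mask, signs * rng.uniform(0.5, 1.5, size=mask.shape), 0.0)
    P = true_P.reindex(sup.columns).to_numpy(dtype=float)
    base = A @ P

    cols, mats, conds = [], [], []
    for c, cond in enumerate(true_P.columns):
        for r in range(n_replicates):
            cols.append(f"{cond}_{r + 1}")
            conds.append(str(cond))
            mats.append(base[:, c] + rng.normal(0.0, noise_sd, size=base.shape[0]))
    matrix = pd.DataFrame(np.column_stack(mats), index=sup.index, columns=cols)
    study = ExpressionStudy(
        matrix=matrix, conditions=pd.Series(conds, index=cols)
    )
    truth = GroundTruth(
        params={
            "A": pd.DataFrame(A, index=sup.index, columns=sup.columns),
            "P": true_P.copy(),
            "noise_sd": noise_sd,
            "identifiable": report.passed,
            "identifiability_issues": report.issues,
        }
    )
    return study, truth


def gen_de_study(
    n_genes: int = 500,
    n_spiked: int = 10,
    effect_log2: float = 2.0,
    noise_sd: float = 0.25,
    n_replicates: int = 3,
    seed: int | None = None,
) -> tuple[ExpressionStudy, GroundTruth]:
    """Two-condition study with a known spike set: ``n_spiked`` genes shifted
    by ``effect_log2`` (4-fold at the default 2.0) among null genes."""
    rng = np.random.default_rng(seed)
    genes = [f"gene{i:04d}" for i in range(n_genes)]
    baseline = rng.uniform(4.0, 12.0, size=n_genes)
    spiked = genes[:n_spiked]
    effect = np.zeros(n_genes)
    effect[:n_spiked] = effect_log2

    cols, data, conds = [], [], []
    for cond, shift in (("control", 0.0), ("treated", 1.0)):
        for r in range(n_replicates):
            cols.append(f"{cond}_{r + 1}")
            conds.append(cond)
            data.append(
                baseline + shift * effect + rng.normal(0, noise_sd, n_genes)
            )
    matrix = pd.DataFrame(np.column_stack(data), index=genes, columns=cols)
    study = ExpressionStudy(matrix=matrix, conditions=pd.Series(conds, index=cols))
    truth = GroundTruth(
        params={"spiked_genes": spiked, "effect_log2": effect_log2,
                "noise_sd": noise_sd}
    )
    return study, truth


# ---------------------------------------------------------------------------
# Growth
# ---------------------------------------------------------------------------

def gen_growth_curves(
    preset: str = "c8_10mM",
    seed: int | None = None,
    noise_cv: float = 0.02,
    times: tuple[float, ...] = tuple(np.round(np.arange(0.0, 5.01, 0.25), 2)),
    od0: float = 0.05,
) -> tuple[GrowthSeries, GrowthSeries, GroundTruth]:
    """Paired control/treated OD550 series with multiplicative read noise."""
    if preset not in GROWTH_PRESETS:
        raise InvalidInputError(f"unknown growth preset {preset!r}")
    p = GROWTH_PRESETS[preset]
    mu_c = p["mu_control"]
    mu_t = mu_c * (1.0 - p["inhibition_pct"] / 100.0)
    rng = np.random.default_rng(seed)
    t = np.asarray(times, dtype=float)

    def series(mu: float, label: str) -> GrowthSeries:
        od = od0 * np.exp(mu * t)
        if noise_cv > 0:
            od = od * rng.lognormal(0.0, noise_cv, size=od.size)
        return GrowthSeries(times=tuple(t), od=tuple(od),
                            window=(float(t[0]), float(t[-1])), label=label)

    ctrl = series(mu_c, "control")
    trt = series(mu_t, "treated")
    truth = GroundTruth(params={"mu_control": mu_c, "mu_treated": mu_t,
                                "inhibition_pct": p["inhibition_pct"],
                                "noise_cv": noise_cv})
    return ctrl, trt, truth


# ---------------------------------------------------------------------------
# Fluorescence
# ---------------------------------------------------------------------------

def _true_fluorescence(ph: float) -> float:
    return _FLUOR_SLOPE * ph + _FLUOR_INTERCEPT


def gen_fluorescence(
    preset: str = "hcl_20mM_unadjusted",
    seed: int | None = None,
    noise_cv: float = 0.02,
    n_replicates: int = 4,
) -> tuple[list[CalibrationStandard], dict[str, Any], GroundTruth]:
    """Benzoate-style calibration standards plus sample readings.

    Standards cover pH 5.5–8.0; the sample's readings come from the same
    monotone curve at the preset's true intracellular pH, with multiplicative
    noise. Returns (standards, sample dict with ``readings``, ground truth).
    """
    if preset not in FLUOR_PRESETS:
        raise InvalidInputError(f"unknown fluorescence preset {preset!r}")
    true_ph = FLUOR_PRESETS[preset]["true_ph"]
    rng = np.random.default_rng(seed)

    def noisy(value: float, n: int) -> np.ndarray:
        out = np.full(n, value)
        if noise_cv > 0:
            out = out * rng.lognormal(0.0, noise_cv, size=n)
        return out

    standards = [
        CalibrationStandard(
            pH=ph, fluorescence=tuple(noisy(_true_fluorescence(ph), n_replicates))
        )
        for ph in _CAL_PH_GRID
    ]
    sample = {
        "sample_id": preset,
        "readings": [float(v) for v in noisy(_true_fluorescence(true_ph), n_replicates)],
    }
    truth = GroundTruth(params={"true_ph": true_ph, "noise_cv": noise_cv,
                                "slope": _FLUOR_SLOPE, "intercept": _FLUOR_INTERCEPT})
    return standards, sample, truth


# ---------------------------------------------------------------------------
# Lipids
# ---------------------------------------------------------------------------

#: Dirichlet concentration scale; ~0.5 mol% jitter on major species,
#: matching GC-FAME measurement precision.
_LIPID_CONCENTRATION = 2000.0
#: Maximum dose-driven mol% transfer for the wildtype response (at 30 mM C8).
_WT_DOSE_SHIFT = 8.0


def _dose_adjusted_means(strain: str, dose_mM: float) -> dict[str, float]:
    base = dict(LIPID_BASE_PROFILES[strain])
    if dose_mM < 0:
        raise InvalidInputError("dose must be >= 0")
    t = min(dose_mM, 30.0) / 30.0
    if strain in ("WT", "dcfa"):
        # dose response: saturated C16:0 falls, long unsaturated C18:1 rises,
        # so S:U decreases and average length increases with dose
        shift = _WT_DOSE_SHIFT * t
        base["C16:0"] -= shift
        base["C18:1"] += shift
    else:  # cfa++ resists the S:U drop; mild shortening instead
        shift = 4.0 * t
        base["C18:1"] -= shift
        base["C16:1"] += shift
    return base


def gen_lipid_profiles(
    strain: str = "WT",
    dose_mM: float = 0.0,
    seed: int | None = None,
) -> tuple[LipidProfile, GroundTruth]:
    """Membrane mol% profile for a strain at a given C8 dose.

    Strains: ``WT`` (wildtype), ``dcfa`` (Δcfa knockout: zero cyclopropanes),
    ``cfa++`` (overexpresser: ~35 mol% cyclopropanes). The profile is a
    Dirichlet draw around the strain/dose mean and sums to 100.
    """
    if strain not in LIPID_BASE_PROFILES:
        raise InvalidInputError(f"unknown strain {strain!r}")
    means = _dose_adjusted_means(strain, dose_mM)
    rng = np.random.default_rng(seed)
    species = [s for s in LIPID_SPECIES if means.get(s, 0.0) > 0]
    alpha = np.array([means[s] for s in species]) / 100.0 * _LIPID_CONCENTRATION
    draw = rng.dirichlet(alpha) * 100.0
    profile = {s: float(v) for s, v in zip(species, draw)}
    for s in LIPID_SPECIES:
        profile.setdefault(s, 0.0)
    if strain == "dcfa":
        assert all(profile[s] == 0.0 for s in CYCLOPROPANE)
    truth = GroundTruth(params={"means": means, "strain": strain,
                                "dose_mM": dose_mM})
    return LipidProfile(mol_percent=profile, label=f"{strain}_{dose_mM:g}mM"), truth


# ---------------------------------------------------------------------------
# GABA
# ---------------------------------------------------------------------------

def gen_gaba(
    condition: str = "control",
    seed: int | None = None,
    noise_cv: float = 0.10,
) -> tuple[GabaMeasurement, GroundTruth]:
    """Intra/extracellular GABA for one experimental arm (lognormal noise)."""
    if condition not in GABA_ARM_MEANS:
        raise InvalidInputError(f"unknown GABA condition {condition!r}")
    mi, me = GABA_ARM_MEANS[condition]
    rng = np.random.default_rng(seed)
    intra = mi * rng.lognormal(0.0, noise_cv)
    extra = me * rng.lognormal(0.0, noise_cv)
    truth = GroundTruth(params={"mean_intracellular": mi, "mean_extracellular": me})
    return GabaMeasurement(intracellular=float(intra), extracellular=float(extra),
                           condition=condition), truth
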