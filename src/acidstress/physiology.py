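"""Scalar physiology metrics: growth, membrane lipids, GABA, Bonferroni.

Specific growth rate μ is the slope of ln(OD550) versus time over the
exponential window; percent inhibition compares a treated culture's μ to its
control. Membrane composition is summarized from mol% fatty-acid profiles as
the saturated:unsaturated ratio (cyclopropane species count as unsaturated,
since they derive from unsaturated precursors), the mol%-weighted average
chain length, and total cyclopropane content. GABA accounting treats each
glutamate decarboxylation as a one-proton sink, so total GABA produced is a
lower bound on protons consumed (some GABA is further converted to
succinate). The Bonferroni utility reproduces the α/m cutoff used for
amino-acid supplementation surveys (0.05/20 = 0.0025).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy import stats

from .errors import InvalidInputError

__all__ = [
    "GrowthSeries",
    "LipidProfile",
    "LipidMetrics",
    "GabaMeasurement",
    "fit_growth_rate",
    "percent_inhibition",
    "lipid_metrics",
    "gaba_balance",
    "bonferroni_threshold",
    "LIPID_SPECIES",
    "SATURATED",
    "UNSATURATED",
    "CYCLOPROPANE",
]

LIPID_SPECIES = (
    "C12:0", "C14:0", "C16:0", "C16:1", "C17cyc", "C18:0", "C18:1", "C19cyc",
)
SATURATED = ("C12:0", "C14:0", "C16:0", "C18:0")
UNSATURATED = ("C16:1", "C18:1", "C17cyc", "C19cyc")  # cyclopropanes included
CYCLOPROPANE = ("C17cyc", "C19cyc")

#: Carbon counts per species under the two chain-length conventions.
_CHAIN_LENGTH = {
    "actual": {
        "C12:0": 12, "C14:0": 14, "C16:0": 16, "C16:1": 16,
        "C17cyc": 17, "C18:0": 18, "C18:1": 18, "C19cyc": 19,
    },
    # cyclopropane ring carbon not counted: C17cyc/C19cyc grouped with their
    # 16- and 18-carbon precursors
    "precursor": {
        "C12:0": 12, "C14:0": 14, "C16:0": 16, "C16:1": 16,
        "C17cyc": 16, "C18:0": 18, "C18:1": 18, "C19cyc": 18,
    },
}


@dataclass(frozen=True)
class GrowthSeries:
    """OD550 time series with an exponential-phase fitting window (hours)."""

    times: tuple[float, ...]
    od: tuple[float, ...]
    window: tuple[float, float] | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if len(self.times) != len(self.od):
            raise InvalidInputError("times and OD must have equal length")
        if any(v <= 0 for v in self.od):
            raise InvalidInputError("OD readings must be positive")

    def in_window(self) -> tuple[np.ndarray, np.ndarray]:
        t = np.asarray(self.times, dtype=float)
        y = np.asarray(self.od, dtype=float)
        if self.window is not None:
            lo, hi = self.window
            keep = (t >= lo) & (t <= hi)
            t, y = t[keep], y[keep]
        if t.size < 3:
            raise InvalidInputError("need >=3 points in the exponential window")
        return t, y


@dataclass(frozen=True)
class LipidProfile:
    """mol% per membrane fatty-acid species; must total 100 ± 0.5."""

    mol_percent: Mapping[str, float]
    label: str = ""

    def __post_init__(self) -> None:
        unknown = set(self.mol_percent) - set(LIPID_SPECIES)
        if unknown:
            raise InvalidInputError(f"unknown lipid species: {sorted(unknown)}")
        if any(v < 0 for v in self.mol_percent.values()):
            raise InvalidInputError("mol% entries must be >= 0")
        total = sum(self.mol_percent.values())
        if abs(total - 100.0) > 0.5:
            raise InvalidInputError(f"mol% must total 100 +/- 0.5, got {total:.2f}")

    def get(self, species: str) -> float:
        return float(self.mol_percent.get(species, 0.0))


@dataclass(frozen=True)
class LipidMetrics:
    su_ratio: float
    average_length: float
    cyclopropane_molpct: float


@dataclass(frozen=True)
class GabaMeasurement:
    """Intra/extracellular GABA concentrations for one condition."""

    intracellular: float
    extracellular: float
    condition: str = ""

    def __post_init__(self) -> None:
        if self.intracellular < 0 or self.extracellular < 0:
            raise InvalidInputError("GABA concentrations must be >= 0")


def fit_growth_rate(series: GrowthSeries) -> float:
    """Specific growth rate μ (h⁻¹): least-squares slope of ln(OD) vs time."""
    t, y = series.in_window()
    slope = stats.linregress(t, np.log(y)).slope
    return float(slope)


def percent_inhibition(mu_control: float, mu_treated: float) -> float:
    """Growth inhibition in percent, 100·(1 − μ_treated/μ_control)."""
    if mu_control <= 0:
        raise InvalidInputError("control growth rate must be positive")
    return 100.0 * (1.0 - mu_treated / mu_control)


def lipid_metrics(
    profile: LipidProfile, length_convention: str = "actual"
) -> LipidMetrics:
    """S:U ratio, average chain length and cyclopropane content of a profile.

    ``length_convention`` is ``"actual"`` (cyclopropane ring carbon counted:
    C17cyc→17, C19cyc→19; the default) or ``"precursor"`` (grouped with the
    16-/18-carbon parents). Metrics are invariant to rescaling the profile.
    """
    if length_convention not in _CHAIN_LENGTH:
        raise InvalidInputError(f"unknown length convention {length_convention!r}")
    sat = sum(profile.get(s) for s in SATURATED)
    unsat = sum(profile.get(s) for s in UNSATURATED)
    if unsat == 0:
        raise InvalidInputError("undefined S:U ratio: no unsaturated lipids")
    total = sat + unsat
    lengths = _CHAIN_LENGTH[length_convention]
    avg_len = sum(profile.get(s) * lengths[s] for s in LIPID_SPECIES) / total
    cyclo = sum(profile.get(s) for s in CYCLOPROPANE)
    return LipidMetrics(
        su_ratio=sat / unsat, average_length=avg_len, cyclopropane_molpct=cyclo
    )


def gaba_balance(m: GabaMeasurement) -> tuple[float, float]:
    """(total GABA, protons sunk): 1:1 glutamate-decarboxylation
    stoichiometry; the proton count is a lower bound because GABA can be
    further converted to succinate."""
    total = m.intracellular + m.extracellular
    return total, total


def bonferroni_threshold(alpha: float, m_tests: int) -> float:
    """Bonferroni-adjusted per-test cutoff α/m."""
    if not (0.0 < alpha < 1.0):
        raise InvalidInputError("alpha must lie in (0, 1)")
    if m_tests < 1 or m_tests != int(m_tests):
        raise InvalidInputError("m_tests must be a positive integer")
    return alpha / m_tests
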