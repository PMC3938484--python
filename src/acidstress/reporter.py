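"""Intracellular pH inference from a pH-sensitive fluorescent reporter.

A cytoplasmic pH-dependent GFP reports intracellular pH through its emission
intensity. Calibration standards are prepared by collapsing the transmembrane
pH gradient with a permeant weak acid (sodium benzoate) so that intracellular
pH equals the buffer pH; a monotone curve fitted to (pH, fluorescence) pairs
is then inverted to convert sample readings into pH estimates.

The method has a reliable lower detection limit of pH 5.5. Calibration can
extend slightly below that limit (standards down to pH 5.25), and estimates
resolved inside the calibrated span are reported numerically even between
5.25 and 5.5 — mirroring how sharp acid shocks are quantified at pH 5.32.
Readings that map *below* the calibrated span, however, are unreliable and
are reported censored at the 5.5 detection limit, to be read as upper bounds
("the intracellular pH may be lower"). No upper censoring is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import PchipInterpolator

from .errors import CalibrationError, InvalidInputError

__all__ = [
    "CalibrationStandard",
    "CalibrationCurve",
    "PhEstimate",
    "fit_calibration",
    "estimate_ph",
    "read_standards_csv",
    "read_samples_csv",
]

#: Detection floor of the GFP method, pH units.
DETECTION_LIMIT_PH = 5.5


@dataclass(frozen=True)
class CalibrationStandard:
    """One calibration point: buffer pH with replicate fluorescence readings."""

    pH: float
    fluorescence: tuple[float, ...]

    def __post_init__(self) -> None:
        if not self.fluorescence:
            raise InvalidInputError("standard needs at least one reading")
        if any(f <= 0 or not np.isfinite(f) for f in self.fluorescence):
            raise InvalidInputError("fluorescence readings must be positive finite")

    @property
    def mean(self) -> float:
        return float(np.mean(self.fluorescence))


class CalibrationCurve:
    """Monotone pH → fluorescence mapping over a stated span.

    ``censor_lo`` is the lower edge of the span: inversions landing below it
    are censored. The censored *reported* value is ``censor_value``, the
    method's stated detection limit when the span reaches below it (so a
    censored estimate is always "≤ 5.5"), else the span edge itself.
    """

    def __init__(self, predict, invert, span, residual_rms, form,
                 detection_limit: float = DETECTION_LIMIT_PH):
        self._predict = predict
        self._invert = invert
        self.span = (float(span[0]), float(span[1]))
        self.residual_rms = float(residual_rms)
        self.form = form
        self.detection_limit = float(detection_limit)

    @property
    def censor_lo(self) -> float:
        return self.span[0]

    @property
    def censor_value(self) -> float:
        return max(self.censor_lo, self.detection_limit)

    def predict(self, pH: float) -> float:
        return float(self._predict(pH))

    def invert(self, fluorescence: float) -> float:
        return float(self._invert(fluorescence))

    def __call__(self, pH: float) -> float:
        return self.predict(pH)


@dataclass(frozen=True)
class PhEstimate:
    """A pH estimate; when ``censored`` the value is the detection floor and
    is an upper bound on the true pH."""

    value: float
    censored: bool
    interval: tuple[float, float] | None = None


def fit_calibration(
    standards: Sequence[CalibrationStandard], form: str = "linear"
) -> CalibrationCurve:
    """Fit a monotone calibration curve to benzoate-collapsed standards.

    Requires ≥3 standards at distinct pH spanning ≥1 pH unit with strictly
    increasing mean fluorescence (the reporter brightens with pH). ``form`` is
    ``"linear"`` (least squares, the default) or ``"spline"`` (monotone PCHIP
    through the means).
    """
    if len(standards) < 3:
        raise InvalidInputError("need at least 3 calibration standards")
    pts = sorted(standards, key=lambda s: s.pH)
    ph = np.array([s.pH for s in pts])
    mean_f = np.array([s.mean for s in pts])
    if len(np.unique(ph)) < 3:
        raise InvalidInputError("standards must cover at least 3 distinct pH values")
    if ph[-1] - ph[0] < 1.0:
        raise InvalidInputError("standards must span at least 1 pH unit")
    if not np.all(np.diff(mean_f) > 0):
        raise CalibrationError(
            "standard means are not strictly increasing in pH; "
            "cannot fit a monotone calibration"
        )

    span = (ph[0], ph[-1])
    if form == "linear":
        # fit on all replicate points, not just the means
        xs = np.concatenate([[s.pH] * len(s.fluorescence) for s in pts])
        ys = np.concatenate([list(s.fluorescence) for s in pts])
        slope, intercept, *_ = stats.linregress(xs, ys)
        if slope <= 0:
            raise CalibrationError("fitted slope is non-positive")
        resid = ys - (intercept + slope * xs)
        rms = float(np.sqrt(np.mean(resid**2)))
        predict = lambda p: intercept + slope * p
        invert = lambda f: (f - intercept) / slope
        return CalibrationCurve(predict, invert, span, rms, "linear")
    if form == "spline":
        interp = PchipInterpolator(ph, mean_f)
        fine = np.linspace(ph[0], ph[-1], 1001)
        vals = interp(fine)

        def invert(f, fine=fine, vals=vals):
            return float(np.interp(f, vals, fine))

        return CalibrationCurve(interp, invert, span, 0.0, "spline")
    raise InvalidInputError(f"unknown calibration form {form!r}")


def estimate_ph(
    fluorescence: float | Sequence[float], curve: CalibrationCurve
) -> PhEstimate:
    """Invert a fluorescence reading (or replicate readings) to a pH estimate.

    Replicates are summarized by their mean; with ≥3 replicates a t-based 95%
    interval on the inverted values is attached. Readings mapping below the
    calibrated span return the detection floor with ``censored=True``.
    """
    readings = np.atleast_1d(np.asarray(fluorescence, dtype=float))
    if readings.size == 0 or not np.all(np.isfinite(readings)):
        raise InvalidInputError("fluorescence readings must be finite")

    value = curve.invert(float(readings.mean()))
    interval = None
    if readings.size >= 3:
        inv = np.array([curve.invert(f) for f in readings])
        sem = inv.std(ddof=1) / np.sqrt(inv.size)
        half = stats.t.ppf(0.975, inv.size - 1) * sem
        interval = (float(inv.mean() - half), float(inv.mean() + half))

    if value < curve.censor_lo:
        return PhEstimate(value=curve.censor_value, censored=True, interval=None)
    return PhEstimate(value=value, censored=False, interval=interval)


def read_standards_csv(path) -> list[CalibrationStandard]:
    """Read standards from CSV with columns pH, fluorescence[, replicate]."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "ph" not in cols or "fluorescence" not in cols:
        raise InvalidInputError("standards CSV needs columns pH, fluorescence")
    out = []
    for ph_val, grp in df.groupby(cols["ph"], sort=True):
        out.append(
            CalibrationStandard(
                pH=float(ph_val),
                fluorescence=tuple(grp[cols["fluorescence"]].astype(float)),
            )
        )
    return out


def read_samples_csv(path) -> dict[str, list[float]]:
    """Read sample readings from CSV with columns sample_id, fluorescence."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    if "sample_id" not in cols or "fluorescence" not in cols:
        raise InvalidInputError("samples CSV needs columns sample_id, fluorescence")
    return {
        str(sid): list(grp[cols["fluorescence"]].astype(float))
        for sid, grp in df.groupby(cols["sample_id"], sort=True)
    }
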