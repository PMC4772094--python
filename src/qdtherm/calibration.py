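"""Photobleach correction, temperature calibration and resolution.

Under continuous illumination the band ratio of a single quantum dot
decays exponentially toward an equilibrium value,

    R(t) = (R0 - Req) * exp(-lambda * t) + Req,

with decay constant ``lambda`` (about 0.00635 1/s under the acquisition
conditions emulated by the synthetic generator).  All subsequent ratio
measurements are detrended by this fitted curve.

Calibration proceeds per particle: the corrected ratio is regressed on
stage temperature, giving one line per quantum dot.  Individual dots
differ mostly in their intercepts, so the ensemble slope is the mean of
the per-particle slopes rather than a pooled regression — pooling mixes
the intercept heterogeneity into the correlation and weakens it.

Measurement resolution is reported as a normal-quantile interval
half-width ``z * s`` of repeated calibrated measurements at constant
temperature: the smallest ratio change treated as detectable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import CorrectionError, FitError, InsufficientDataError

__all__ = [
    "RatioTrace",
    "BleachModel",
    "CalibrationLine",
    "SlopeAggregate",
    "ResolutionEstimate",
    "ReversibilityResult",
    "fit_bleach",
    "correct_bleach",
    "fit_calibration_line",
    "aggregate_slopes",
    "ratio_resolution",
    "reversibility_check",
]


@dataclass(frozen=True)
class RatioTrace:
    """Time-stamped ratio measurements of one spot at known temperatures."""

    t_s: np.ndarray
    temp_degC: np.ndarray
    R_raw: np.ndarray
    R_cal: np.ndarray | None = None
    particle_id: str | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.t_s, dtype=float)
        temp = np.asarray(self.temp_degC, dtype=float)
        if temp.ndim == 0:
            temp = np.full(t.size, float(temp))
        r = np.asarray(self.R_raw, dtype=float)
        if t.ndim != 1 or t.size != temp.size or t.size != r.size:
            raise ValueError("t_s, temp_degC and R_raw must be 1-D, equal length")
        if not np.all(np.diff(t) > 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "t_s", t)
        object.__setattr__(self, "temp_degC", temp)
        object.__setattr__(self, "R_raw", r)
        if self.R_cal is not None:
            rc = np.asarray(self.R_cal, dtype=float)
            if rc.size != t.size:
                raise ValueError("R_cal length mismatch")
            object.__setattr__(self, "R_cal", rc)

    def __len__(self) -> int:
        return self.t_s.size

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            {"t_s": self.t_s, "temp_degC": self.temp_degC, "R_raw": self.R_raw}
        )
        if self.R_cal is not None:
            df["R_cal"] = self.R_cal
        return df

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, particle_id: str | None = None) -> "RatioTrace":
        df = pd.read_csv(path)
        return cls(
            t_s=df["t_s"].to_numpy(),
            temp_degC=df["temp_degC"].to_numpy(),
            R_raw=df["R_raw"].to_numpy(),
            R_cal=df["R_cal"].to_numpy() if "R_cal" in df else None,
            particle_id=particle_id,
        )


@dataclass(frozen=True)
class BleachModel:
    """Exponential photobleach model of the ratio."""

    R0: float
    Req: float
    decay_per_s: float
    fit_rms: float = 0.0

    def __post_init__(self) -> None:
        if self.decay_per_s < 0:
            raise ValueError("decay constant must be non-negative")

    def predict(self, t_s: np.ndarray | float) -> np.ndarray | float:
        t = np.asarray(t_s, dtype=float)
        out = (self.R0 - self.Req) * np.exp(-self.decay_per_s * t) + self.Req
        return out if out.ndim else float(out)


@dataclass(frozen=True)
class CalibrationLine:
    """Per-particle linear model R = intercept + slope * T."""

    slope_per_degC: float
    intercept: float
    pearson_r: float
    n: int
    particle_id: str | None = None
    # raw points kept for pooled-correlation aggregation
    points: tuple[np.ndarray, np.ndarray] | None = field(
        default=None, repr=False, compare=False
    )

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("a calibration line needs n >= 2")
        if not -1.0 <= self.pearson_r <= 1.0 + 1e-12:
            raise ValueError("pearson_r outside [-1, 1]")


@dataclass(frozen=True)
class SlopeAggregate:
    mean_slope_per_degC: float
    sd_slope_per_degC: float
    per_line_r: tuple[float, ...]
    pooled_r: float
    n_lines: int


@dataclass(frozen=True)
class ResolutionEstimate:
    """Confidence-interval half-width of repeated ratio measurements."""

    half_width: float
    confidence: float
    source: str = "temporal_single_particle"

    def __post_init__(self) -> None:
        if self.half_width < 0:
            raise ValueError("half_width must be non-negative")
        if not 0 < self.confidence < 1:
            raise ValueError("confidence must lie in (0, 1)")


@dataclass(frozen=True)
class ReversibilityResult:
    passed: bool
    drift: float
    per_temp_cycle_means: dict


def fit_bleach(trace: RatioTrace) -> BleachModel:
    """Fit R(t) = (R0 - Req) exp(-lambda t) + Req by nonlinear least squares.

    Requires >= 10 samples acquired at constant temperature.  The decay
    constant is constrained non-negative.  A constant trace leaves
    lambda unidentifiable and raises :class:`FitError`.
    """
    if len(trace) < 10:
        raise InsufficientDataError("bleach fit needs at least 10 samples")
    if np.ptp(trace.temp_degC) > 0.5:
        raise ValueError("bleach fit expects a constant-temperature trace")
    t, r = trace.t_s, trace.R_raw
    if np.ptp(r) == 0:
        raise FitError("constant trace: decay constant is unidentifiable")

    span = t[-1] - t[0]
    p0 = [float(r[0]), float(r[-1]), 2.0 / span]

    def model(x, R0, Req, lam):
        return (R0 - Req) * np.exp(-lam * x) + Req

    try:
        popt, _ = optimize.curve_fit(
            model,
            t,
            r,
            p0=p0,
            bounds=([-np.inf, -np.inf, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:
        raise FitError(f"bleach fit did not converge: {exc}") from exc
    resid = r - model(t, *popt)
    return BleachModel(
        R0=float(popt[0]),
        Req=float(popt[1]),
        decay_per_s=float(popt[2]),
        fit_rms=float(np.sqrt(np.mean(resid**2))),
    )


def correct_bleach(trace: RatioTrace, model: BleachModel) -> RatioTrace:
    """Detrend a raw ratio trace by the fitted bleach curve.

    The correction is multiplicative to the t=0 level,
    ``R_cal(t) = R_raw(t) * R_model(0) / R_model(t)``, because the ratio
    is a scale-like quantity.  A trace that follows the model exactly
    becomes constant at R0; a lambda = 0 model leaves the trace
    unchanged.
    """
    pred = np.asarray(model.predict(trace.t_s), dtype=float)
    if np.any(pred <= 0):
        raise CorrectionError("bleach model predicts non-positive ratio")
    r_cal = trace.R_raw * (model.predict(0.0) / pred)
    return replace(trace, R_cal=r_cal)


def fit_calibration_line(
    temps_degC: Sequence[float],
    R: Sequence[float],
    particle_id: str | None = None,
) -> CalibrationLine:
    """OLS of the (bleach-corrected) ratio on stage temperature.

    Temperature is the controlled variable, so R is regressed on T.
    Requires at least 3 points spanning at least 2 degC.
    """
    t = np.asarray(list(temps_degC), dtype=float)
    r = np.asarray(list(R), dtype=float)
    if t.size != r.size:
        raise ValueError("temperature and ratio arrays differ in length")
    if t.size < 3:
        raise InsufficientDataError("calibration line needs >= 3 points")
    if np.ptp(t) < 2.0:
        raise InsufficientDataError("calibration temperatures must span >= 2 degC")
    res = stats.linregress(t, r)
    return CalibrationLine(
        slope_per_degC=float(res.slope),
        intercept=float(res.intercept),
        pearson_r=float(res.rvalue),
        n=int(t.size),
        particle_id=particle_id,
        points=(t, r),
    )


def aggregate_slopes(lines: Sequence[CalibrationLine]) -> SlopeAggregate:
    """Ensemble summary of per-particle calibration lines.

    The mean slope (arithmetic mean over particles) is the sensitivity
    used for ratio-to-temperature conversion.  The pooled correlation is
    computed on all points merged; with heterogeneous intercepts it is
    systematically weaker than the per-particle correlations.
    """
    if len(lines) < 1:
        raise InsufficientDataError("need at least one calibration line")
    slopes = np.array([ln.slope_per_degC for ln in lines])
    per_r = tuple(float(ln.pearson_r) for ln in lines)
    if all(ln.points is not None for ln in lines):
        all_t = np.concatenate([ln.points[0] for ln in lines])
        all_r = np.concatenate([ln.points[1] for ln in lines])
        pooled_r = float(stats.pearsonr(all_t, all_r).statistic)
    else:
        pooled_r = float("nan")
    sd = float(np.std(slopes, ddof=1)) if slopes.size > 1 else 0.0
    return SlopeAggregate(
        mean_slope_per_degC=float(slopes.mean()),
        sd_slope_per_degC=sd,
        per_line_r=per_r,
        pooled_r=pooled_r,
        n_lines=len(lines),
    )


def ratio_resolution(
    values: Sequence[float],
    confidence: float = 0.95,
    source: str = "temporal_single_particle",
) -> ResolutionEstimate:
    """Resolution of the ratio from repeated measurements at fixed T.

    half_width = z_(1-(1-confidence)/2) * sample s.d.  This is a
    population interval on single measurements (not an SEM): it answers
    "how large must a ratio change be to exceed measurement scatter".
    """
    v = np.asarray(list(values), dtype=float)
    if v.size < 10:
        raise InsufficientDataError("resolution estimate needs >= 10 values")
    z = stats.norm.ppf(1 - (1 - confidence) / 2)
    return ResolutionEstimate(
        half_width=float(z * np.std(v, ddof=1)),
        confidence=confidence,
        source=source,
    )


def reversibility_check(
    measurements: Sequence[tuple[float, float]],
    resolution_half_width: float,
) -> ReversibilityResult:
    """Check that cycling between two temperatures leaves R unchanged.

    ``measurements`` alternates (temperature, R) pairs between two set
    points, e.g. 40/30/40/30 degC.  For each temperature the per-cycle
    values are compared with their overall mean; the check passes when
    the largest deviation does not exceed the resolution half-width.
    Requires at least two full cycles (each temperature visited twice).
    """
    temps = np.array([m[0] for m in measurements], dtype=float)
    rs = np.array([m[1] for m in measurements], dtype=float)
    uniq = np.unique(temps)
    if uniq.size != 2:
        raise ValueError(f"expected exactly 2 set-point temperatures, got {uniq.size}")
    per_temp: dict[float, np.ndarray] = {
        float(u): rs[temps == u] for u in uniq
    }
    if any(v.size < 2 for v in per_temp.values()):
        raise InsufficientDataError("reversibility check needs >= 2 full cycles")
    drift = 0.0
    cycle_means: dict[float, list[float]] = {}
    for temp, vals in per_temp.items():
        overall = vals.mean()
        cycle_means[temp] = [float(v) for v in vals]
        drift = max(drift, float(np.max(np.abs(vals - overall))))
    return ReversibilityResult(
        passed=drift <= resolution_half_width,
        drift=drift,
        per_temp_cycle_means=cycle_means,
    )
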