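"""Ratio-to-temperature conversion and group comparison.

Absolute temperature cannot be read from a single quantum dot because
per-particle calibration intercepts vary; what the calibration slope
supports is converting ratio *differences* into temperature
*differences*:

    delta_T = delta_R / slope        (slope in ratio units per degC).

A ratio change only counts as a detected temperature change when it
exceeds the measurement resolution (the confidence-interval half-width
of repeated measurements), which is how stimulus responses are
classified into increase / within-resolution / decrease.

Compartment comparisons (cell body vs neurite) report group means, the
mean ratio difference, its Welch t-test p-value and the converted
temperature difference.  A permutation test is available as a
distribution-free cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .calibration import RatioTrace, ResolutionEstimate

__all__ = [
    "TemperatureEstimate",
    "ResponseClass",
    "GroupComparison",
    "delta_ratio_to_delta_T",
    "temperature_estimate",
    "classify_response",
    "timecourse_temperature",
    "compare_groups",
]


@dataclass(frozen=True)
class TemperatureEstimate:
    delta_T_degC: float
    delta_R: float
    slope_used_per_degC: float
    resolution_half_width: float
    significant: bool


@dataclass(frozen=True)
class ResponseClass:
    """Classification of a stimulus response against the resolution."""

    label: str  # increase | within_resolution | decrease
    delta_R: float


@dataclass(frozen=True)
class GroupComparison:
    mean_a: float
    mean_b: float
    mean_diff: float
    p_value: float
    n_a: int
    n_b: int
    delta_T_degC: float
    test: str = "welch"


def delta_ratio_to_delta_T(delta_R: float, slope_per_degC: float) -> float:
    """Convert a ratio difference into a temperature difference."""
    if slope_per_degC == 0:
        raise ValueError("calibration slope must be non-zero")
    return delta_R / slope_per_degC


def temperature_estimate(
    delta_R: float,
    slope_per_degC: float,
    resolution: ResolutionEstimate,
) -> TemperatureEstimate:
    """Temperature difference plus a significance call vs the resolution."""
    return TemperatureEstimate(
        delta_T_degC=delta_ratio_to_delta_T(delta_R, slope_per_degC),
        delta_R=delta_R,
        slope_used_per_degC=slope_per_degC,
        resolution_half_width=resolution.half_width,
        significant=abs(delta_R) > resolution.half_width,
    )


def classify_response(
    R_before: Sequence[float],
    R_after: Sequence[float],
    resolution: ResolutionEstimate,
) -> ResponseClass:
    """Label a before/after response as increase, decrease, or within
    the measurement resolution.

    Uses bleach-corrected ratios; delta_R = mean(after) - mean(before).
    """
    before = np.asarray(list(R_before), dtype=float)
    after = np.asarray(list(R_after), dtype=float)
    if before.size == 0 or after.size == 0:
        raise ValueError("before and after samples must be non-empty")
    delta = float(after.mean() - before.mean())
    if delta > resolution.half_width:
        label = "increase"
    elif delta < -resolution.half_width:
        label = "decrease"
    else:
        label = "within_resolution"
    return ResponseClass(label=label, delta_R=delta)


def timecourse_temperature(
    trace: RatioTrace,
    baseline_window_s: tuple[float, float],
    slope_per_degC: float,
) -> np.ndarray:
    """Per-frame temperature change relative to a baseline window.

    delta_T(t) = (R_cal(t) - mean over baseline) / slope.  Uses the
    bleach-corrected ratio when present, the raw ratio otherwise.
    """
    r = trace.R_cal if trace.R_cal is not None else trace.R_raw
    lo, hi = baseline_window_s
    mask = (trace.t_s >= lo) & (trace.t_s <= hi)
    if not mask.any():
        raise ValueError("baseline window contains no samples")
    baseline = float(r[mask].mean())
    return (r - baseline) / slope_per_degC


def _welch_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate: no within-group variance; equal means are maximally
        # compatible, unequal means maximally incompatible
        return 1.0 if a.mean() == b.mean() else 0.0
    return float(stats.ttest_ind(a, b, equal_var=False).pvalue)


def compare_groups(
    R_a: Sequence[float],
    R_b: Sequence[float],
    slope_per_degC: float,
    resolution: ResolutionEstimate | None = None,
    test: str = "welch",
    n_permutations: int = 100_000,
    seed: int = 0,
) -> GroupComparison:
    """Compare ratio samples from two compartments.

    Reports group means, the mean difference (a minus b), a two-sided
    p-value and the converted temperature difference.  ``test`` is
    ``"welch"`` (default; unequal-variance t-test) or ``"permutation"``
    (difference of means, label reshuffling).
    """
    a = np.asarray(list(R_a), dtype=float)
    b = np.asarray(list(R_b), dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 samples")
    diff = float(a.mean() - b.mean())
    if test == "welch":
        p = _welch_p(a, b)
    elif test == "permutation":
        res = stats.permutation_test(
            (a, b),
            lambda x, y: np.mean(x) - np.mean(y),
            permutation_type="independent",
            alternative="two-sided",
            n_resamples=n_permutations,
            rng=np.random.default_rng(seed),
        )
        p = float(res.pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")
    return GroupComparison(
        mean_a=float(a.mean()),
        mean_b=float(b.mean()),
        mean_diff=diff,
        p_value=p,
        n_a=int(a.size),
        n_b=int(b.size),
        delta_T_degC=delta_ratio_to_delta_T(diff, slope_per_degC),
        test=test,
    )
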