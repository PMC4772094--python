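"""Single-spot detection, Gaussian fitting, ratio extraction and QC.

Works on pairs of simultaneously acquired images: the low spectral band
(630-650 nm) and the high band (650-670 nm).  Candidate quantum dots
are local maxima of the channel-summed image; each is fitted with an
isotropic 2D Gaussian plus constant background, its diameter is taken
as the FWHM of that fit (the standard single-particle convention), and
channel intensities come from background-subtracted aperture
photometry.  Quality gates:

* ``non_gaussian`` — the window does not fit a Gaussian (aggregates or
  background structure);
* ``overlapping`` — another candidate sits within the minimum
  separation;
* diameter outside mean +/- s.d. of the cohort (aggregates and
  sub-resolution outliers), applied by :func:`diameter_filter`;
* axial gate — only planes within +/-0.25 um of the intensity peak are
  trusted, where the ratio is empirically flat (:func:`z_gate`).

Pixel coordinates are 0-based with the pixel-center convention;
physical positions are in micrometres via the pixel size.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize
from skimage.feature import peak_local_max

from .errors import DegenerateSignalError, FitError, GatingError
from .spectral import band_ratio

__all__ = [
    "SpotCandidate",
    "SpotFit",
    "SpotRecord",
    "DiameterFilter",
    "DiameterFilterReport",
    "ZGateResult",
    "detect_spots",
    "fit_spot",
    "estimate_diameter",
    "extract_ratio",
    "diameter_filter",
    "z_gate",
    "measure_spots",
    "records_to_frame",
]

_FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


@dataclass(frozen=True)
class SpotCandidate:
    x_um: float
    y_um: float
    peak_value: float
    overlapping: bool = False


@dataclass(frozen=True)
class SpotFit:
    x_um: float
    y_um: float
    sigma_um: float
    amplitude: float
    background: float
    fit_rms: float


@dataclass(frozen=True)
class SpotRecord:
    """One measured quantum dot."""

    x_um: float
    y_um: float
    diameter_um: float
    I_low: float
    I_high: float
    ratio: float
    gaussian_fit_rms: float
    z_um: float | None = None
    qc_flags: frozenset[str] = frozenset()
    compartment: str | None = None


@dataclass(frozen=True)
class DiameterFilter:
    """Diameter gate: cohort mean +/- s.d., or explicit bounds."""

    derivation: str = "mean_pm_sd"
    lower_um: float | None = None
    upper_um: float | None = None

    def __post_init__(self) -> None:
        if self.derivation not in {"mean_pm_sd", "explicit"}:
            raise ValueError("derivation must be 'mean_pm_sd' or 'explicit'")
        if self.derivation == "explicit":
            if self.lower_um is None or self.upper_um is None:
                raise ValueError("explicit filter needs lower_um and upper_um")
            if self.lower_um >= self.upper_um:
                raise ValueError("lower_um must be below upper_um")


@dataclass(frozen=True)
class DiameterFilterReport:
    lower_um: float
    upper_um: float
    n_input: int
    n_retained: int
    excluded: tuple[SpotRecord, ...]
    degenerate: bool = False  # s.d. collapsed to zero; gate is the mean only


@dataclass(frozen=True)
class ZGateResult:
    peak_z_um: float
    accepted: np.ndarray
    tolerance_um: float


def detect_spots(
    image_low: np.ndarray,
    image_high: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float = 0.5,
    threshold_policy: str | float = "auto",
) -> list[SpotCandidate]:
    """Detect candidate spots as local maxima of the summed image.

    ``threshold_policy`` is either an absolute intensity or ``"auto"``
    (median + 8 robust sigma of the summed image, with sigma from the
    median absolute deviation).  Candidates closer together than
    ``min_separation_um`` are non-maximum suppressed: the brighter one
    is kept and flagged overlapping.  Results are ordered row-major by
    position and are deterministic.
    """
    low = np.asarray(image_low, dtype=float)
    high = np.asarray(image_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("channel images must have identical shape")
    img = low + high
    if img.size == 0:
        return []
    if threshold_policy == "auto":
        med = float(np.median(img))
        sigma = 1.4826 * float(np.median(np.abs(img - med)))
        thr = med + 8.0 * sigma
    else:
        thr = float(threshold_policy)
    peaks = peak_local_max(img, min_distance=1, threshold_abs=thr, exclude_border=False)
    peaks = [p for p in peaks if img[tuple(p)] > thr]
    if not peaks:
        return []
    values = np.array([img[tuple(p)] for p in peaks])
    order = np.argsort(-values)
    min_sep_px = min_separation_um / pixel_size_um
    # intensity plateaus of a symmetric spot yield adjacent tied maxima;
    # those merge silently, only distinct candidates count as overlap
    merge_px = 2.0
    kept: list[tuple[np.ndarray, float, bool]] = []
    for idx in order:
        p, v = np.asarray(peaks[idx], dtype=float), float(values[idx])
        clash = False
        for i, (q, _, _) in enumerate(kept):
            d = float(np.hypot(*(p - q)))
            if d < min_sep_px:
                if d > merge_px:
                    kept[i] = (q, kept[i][1], True)
                clash = True
        if not clash:
            kept.append((p, v, False))
    out = [
        SpotCandidate(
            x_um=(p[1] + 0.5) * pixel_size_um,
            y_um=(p[0] + 0.5) * pixel_size_um,
            peak_value=v,
            overlapping=flag,
        )
        for p, v, flag in kept
    ]
    out.sort(key=lambda c: (c.y_um, c.x_um))
    return out


def fit_spot(
    image_sum: np.ndarray,
    position_um: tuple[float, float],
    pixel_size_um: float,
    window_px: int = 15,
) -> SpotFit:
    """Fit an isotropic 2D Gaussian + constant background in a window.

    ``position_um`` is the (x, y) candidate position.  Raises
    :class:`FitError` when the window holds no Gaussian peak (flat
    background, or amplitude indistinguishable from the residuals) —
    callers translate this into the ``non_gaussian`` QC flag.
    """
    img = np.asarray(image_sum, dtype=float)
    cx = int(round(position_um[0] / pixel_size_um - 0.5))
    cy = int(round(position_um[1] / pixel_size_um - 0.5))
    h = window_px // 2
    if cy - h < 0 or cx - h < 0 or cy + h >= img.shape[0] or cx + h >= img.shape[1]:
        raise ValueError("fit window extends beyond the image")
    win = img[cy - h : cy + h + 1, cx - h : cx + h + 1]
    if np.ptp(win) == 0:
        raise FitError("flat window: no spot to fit")
    ys = (np.arange(cy - h, cy + h + 1) + 0.5) * pixel_size_um
    xs = (np.arange(cx - h, cx + h + 1) + 0.5) * pixel_size_um
    Y, X = np.meshgrid(ys, xs, indexing="ij")

    def model(coords, a, x0, y0, sig, b):
        xx, yy = coords
        return b + a * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2 * sig**2))

    b0 = float(win.min())
    a0 = float(win.max() - win.min())
    p0 = [a0, position_um[0], position_um[1], 2.0 * pixel_size_um, b0]
    try:
        popt, _ = optimize.curve_fit(
            model,
            (X.ravel(), Y.ravel()),
            win.ravel(),
            p0=p0,
            maxfev=10000,
        )
    except RuntimeError as exc:
        raise FitError(f"spot fit did not converge: {exc}") from exc
    a, x0, y0, sig, b = popt
    sig = abs(float(sig))
    resid = win.ravel() - model((X.ravel(), Y.ravel()), *popt)
    rms = float(np.sqrt(np.mean(resid**2)))
    if a <= 0 or sig <= 0 or (rms > 0 and a < 3.0 * rms):
        raise FitError(
            f"no credible Gaussian peak (amplitude {a:.3g}, residual rms {rms:.3g})"
        )
    return SpotFit(
        x_um=float(x0),
        y_um=float(y0),
        sigma_um=sig,
        amplitude=float(a),
        background=float(b),
        fit_rms=rms,
    )


def estimate_diameter(sigma_xy_um: float) -> float:
    """Spot diameter as the FWHM of the fitted Gaussian, 2.3548 sigma."""
    if sigma_xy_um <= 0:
        raise ValueError("sigma must be positive")
    return _FWHM_PER_SIGMA * sigma_xy_um


def extract_ratio(
    image_low: np.ndarray,
    image_high: np.ndarray,
    x_um: float,
    y_um: float,
    aperture_radius_um: float,
    pixel_size_um: float,
    background_policy: str = "annulus",
) -> tuple[float, float, float]:
    """Background-subtracted aperture photometry and the band ratio.

    Integrates each channel over pixels whose centers fall within the
    circular aperture.  Background per pixel is the median of an
    annulus (inner 2x, outer 3x the aperture radius) unless
    ``background_policy`` is ``"none"``.  Raises
    :class:`DegenerateSignalError` when the low band carries no signal
    after subtraction (e.g. the aperture missed the spot).
    """
    low = np.asarray(image_low, dtype=float)
    high = np.asarray(image_high, dtype=float)
    if low.shape != high.shape:
        raise ValueError("channel images must have identical shape")
    ny, nx = low.shape
    ys = (np.arange(ny) + 0.5) * pixel_size_um
    xs = (np.arange(nx) + 0.5) * pixel_size_um
    dist = np.hypot(ys[:, None] - y_um, xs[None, :] - x_um)
    ap = dist <= aperture_radius_um
    if not ap.any():
        raise DegenerateSignalError("aperture contains no pixel")
    if background_policy == "annulus":
        ann = (dist > 2.0 * aperture_radius_um) & (dist <= 3.0 * aperture_radius_um)
        bg_low = float(np.median(low[ann])) if ann.any() else 0.0
        bg_high = float(np.median(high[ann])) if ann.any() else 0.0
    elif background_policy == "none":
        bg_low = bg_high = 0.0
    else:
        raise ValueError(f"unknown background policy {background_policy!r}")
    n_ap = int(ap.sum())
    I_low = float(low[ap].sum() - n_ap * bg_low)
    I_high = float(high[ap].sum() - n_ap * bg_high)
    if I_low <= 0:
        raise DegenerateSignalError(
            f"low-band aperture signal is {I_low:.3g} after background subtraction"
        )
    return I_low, I_high, band_ratio(I_low, I_high)


def diameter_filter(
    records: Sequence[SpotRecord], policy: DiameterFilter = DiameterFilter()
) -> tuple[list[SpotRecord], DiameterFilterReport]:
    """Retain spots whose diameter lies strictly between the thresholds.

    With the ``mean_pm_sd`` policy the thresholds are the sample mean
    +/- sample standard deviation (ddof=1) of the input diameters —
    spots much larger (aggregates) or smaller than the cohort are
    excluded.  Ties on a threshold are excluded (strict inequality).
    If all diameters are equal the band collapses; every record is then
    retained and the report is flagged degenerate.  Input records are
    never mutated and the retained set is independent of input order.
    """
    recs = list(records)
    if policy.derivation == "mean_pm_sd":
        if len(recs) < 2:
            raise ValueError("mean_pm_sd derivation needs at least 2 records")
        d = np.array([r.diameter_um for r in recs])
        sd = float(np.std(d, ddof=1))
        lo, hi = float(d.mean() - sd), float(d.mean() + sd)
        if sd == 0:
            return list(recs), DiameterFilterReport(
                lower_um=lo,
                upper_um=hi,
                n_input=len(recs),
                n_retained=len(recs),
                excluded=(),
                degenerate=True,
            )
    else:
        lo, hi = float(policy.lower_um), float(policy.upper_um)
    retained = [r for r in recs if lo < r.diameter_um < hi]
    excluded = tuple(
        replace(r, qc_flags=r.qc_flags | {"diameter_out_of_range"})
        for r in recs
        if not lo < r.diameter_um < hi
    )
    return retained, DiameterFilterReport(
        lower_um=lo,
        upper_um=hi,
        n_input=len(recs),
        n_retained=len(retained),
        excluded=excluded,
    )


def z_gate(
    z_profile: pd.DataFrame, tolerance_um: float = 0.25
) -> ZGateResult:
    """Accept only focal planes within +/-tolerance of the intensity peak.

    The intensity column is smoothed with a 3-point moving average
    before locating the peak; the peak must be interior (a monotone
    profile has no focus and raises :class:`GatingError`).  Within the
    default +/-0.25 um the ratio is empirically flat, so those planes
    are trusted for ratiometry.
    """
    z = z_profile["z_um"].to_numpy(dtype=float)
    inten = z_profile["intensity"].to_numpy(dtype=float)
    if z.size < 3:
        raise GatingError("profile too short to locate a peak")
    kernel = np.ones(3) / 3.0
    smooth = np.convolve(inten, kernel, mode="same")
    # moving-average edges use fewer samples; rescale to stay comparable
    smooth[0] = inten[:2].mean()
    smooth[-1] = inten[-2:].mean()
    peak_idx = int(np.argmax(smooth))
    if peak_idx in (0, z.size - 1):
        raise GatingError("profile is monotone: no interior intensity peak")
    peak_z = float(z[peak_idx])
    accepted = np.abs(z - peak_z) <= tolerance_um + 1e-9
    return ZGateResult(peak_z_um=peak_z, accepted=accepted, tolerance_um=tolerance_um)


def measure_spots(
    image_low: np.ndarray,
    image_high: np.ndarray,
    pixel_size_um: float,
    min_separation_um: float = 0.5,
    aperture_radius_um: float = 0.4,
    threshold_policy: str | float = "auto",
    window_px: int = 15,
    max_relative_fit_rms: float = 0.2,
) -> list[SpotRecord]:
    """End-to-end photometry: detect, fit, size and ratio every spot.

    Spots whose Gaussian fit fails, or whose residual rms exceeds
    ``max_relative_fit_rms`` of the fitted amplitude, carry the
    ``non_gaussian`` flag; candidates that collided during detection
    carry ``overlapping``.  Diameter gating is a separate, explicit
    step (:func:`diameter_filter`) so the cohort statistics are formed
    from the full detection set.
    """
    cands = detect_spots(
        image_low, image_high, pixel_size_um, min_separation_um, threshold_policy
    )
    img_sum = np.asarray(image_low, dtype=float) + np.asarray(image_high, dtype=float)
    records: list[SpotRecord] = []
    for c in cands:
        flags: set[str] = {"overlapping"} if c.overlapping else set()
        try:
            fit = fit_spot(img_sum, (c.x_um, c.y_um), pixel_size_um, window_px)
        except (FitError, ValueError):
            flags.add("non_gaussian")
            records.append(
                SpotRecord(
                    x_um=c.x_um,
                    y_um=c.y_um,
                    diameter_um=float("nan"),
                    I_low=float("nan"),
                    I_high=float("nan"),
                    ratio=float("nan"),
                    gaussian_fit_rms=float("nan"),
                    qc_flags=frozenset(flags),
                )
            )
            continue
        if fit.amplitude > 0 and fit.fit_rms / fit.amplitude > max_relative_fit_rms:
            flags.add("non_gaussian")
        diameter = estimate_diameter(fit.sigma_um)
        try:
            I_low, I_high, ratio = extract_ratio(
                image_low,
                image_high,
                fit.x_um,
                fit.y_um,
                aperture_radius_um,
                pixel_size_um,
            )
        except DegenerateSignalError:
            I_low = I_high = ratio = float("nan")
            flags.add("non_gaussian")
        records.append(
            SpotRecord(
                x_um=fit.x_um,
                y_um=fit.y_um,
                diameter_um=diameter,
                I_low=I_low,
                I_high=I_high,
                ratio=ratio,
                gaussian_fit_rms=fit.fit_rms,
                qc_flags=frozenset(flags),
            )
        )
    return records


def records_to_frame(records: Sequence[SpotRecord]) -> pd.DataFrame:
    """Tabulate spot records with documented column names."""
    return pd.DataFrame(
        {
            "x_um": [r.x_um for r in records],
            "y_um": [r.y_um for r in records],
            "z_um": [r.z_um for r in records],
            "diameter_um": [r.diameter_um for r in records],
            "I_low": [r.I_low for r in records],
            "I_high": [r.I_high for r in records],
            "ratio": [r.ratio for r in records],
            "gaussian_fit_rms": [r.gaussian_fit_rms for r in records],
            "qc_flags": [";".join(sorted(r.qc_flags)) for r in records],
            "compartment": [r.compartment for r in records],
        }
    )
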