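"""FRAP trace processing: photobleaching correction, normalization, fitting.

The pipeline takes the three ROI traces (bleach, control, background) and

1. corrects each time point for acquisition photobleaching,

       corrected(n) = (bleach(n) - background(n)) * control(pre) / control(n)

   where ``control(pre)`` is the mean control signal over the pre-bleach
   frames — a multiplicative correction that cancels any exponential decay
   shared by the bleach and control ROIs;

2. normalizes the corrected trace to the bleach depth,

       normalized(n) = (corrected(n) - corrected(t0))
                       / (corrected(pre) - corrected(t0))

   so the first post-bleach frame maps to 0 and the pre-bleach level to 1;

3. fits a one-phase association F(t) = P * (1 - exp(-k t)) over a fixed
   post-bleach window (default 0-14 s) and reports the recovery half-life
   ln(2)/k from the fitted rate.

The one-phase association is the standard single-component FRAP recovery
model; it is a configurable choice, not the only possible regression.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.optimize import curve_fit

from .datatypes import FRAPSeries, ParameterizationError, UndefinedResultError

__all__ = [
    "RecoveryFit",
    "FitConvergenceError",
    "correct_photobleach",
    "normalize_recovery",
    "fit_recovery",
    "process_series",
]


class FitConvergenceError(RuntimeError):
    """Recovery fit failed; carries the initial values and residuals."""

    def __init__(self, message: str, init: dict[str, float], residuals=None):
        super().__init__(message)
        self.init = init
        self.residuals = residuals


@dataclasses.dataclass
class RecoveryFit:
    """One-phase association fit of a normalized recovery trace."""

    plateau: float  # normalized intensity
    k: float  # 1/s
    half_life: float  # s, ln(2)/k
    window: tuple[float, float]
    residual_rms: float
    n_points: int

    def __post_init__(self) -> None:
        if self.k <= 0:
            raise ParameterizationError("fitted rate k must be > 0")


def correct_photobleach(series: FRAPSeries) -> np.ndarray:
    """Acquisition-photobleaching-corrected bleach-ROI trace."""
    bad = np.flatnonzero(series.control <= series.background)
    if bad.size:
        raise ParameterizationError(
            f"control ROI does not exceed background at frame {bad[0]}"
        )
    pre_control = series.pre_bleach_mean("control")
    return (series.bleach - series.background) * (pre_control / series.control)


def normalize_recovery(
    corrected: np.ndarray, pre_bleach_value: float, t0_value: float
) -> np.ndarray:
    """Map the corrected trace to [bleach depth -> 0, pre-bleach -> 1]."""
    depth = pre_bleach_value - t0_value
    if depth == 0:
        raise UndefinedResultError("no bleach depth: pre-bleach equals t0 value")
    return (np.asarray(corrected, dtype=float) - t0_value) / depth


def fit_recovery(
    time_s: np.ndarray,
    normalized: np.ndarray,
    window: tuple[float, float] = (0.0, 14.0),
) -> RecoveryFit:
    """Least-squares one-phase association fit over the analysis window.

    Initialization: plateau = max in window; k = 1 / (first time the trace
    exceeds half the plateau). k is bounded in (1e-4, 1e3) 1/s.
    """
    time_s = np.asarray(time_s, dtype=float)
    normalized = np.asarray(normalized, dtype=float)
    sel = (time_s >= window[0]) & (time_s <= window[1]) & (time_s >= 0)
    t = time_s[sel]
    f = normalized[sel]
    if t.size < 5:
        raise ParameterizationError(
            f"need >= 5 samples in the fit window, got {t.size}"
        )
    p_max = float(f.max())
    if p_max <= 0 or np.ptp(f) == 0:
        raise FitConvergenceError(
            "degenerate trace: no recovery signal in the window",
            init={"plateau": p_max, "k": np.nan},
            residuals=f,
        )
    above = np.flatnonzero(f > p_max / 2)
    t_half = t[above[0]] if above.size and t[above[0]] > 0 else np.median(t[t > 0])
    k0 = float(np.clip(1.0 / t_half, 1e-3, 1e2))
    init = {"plateau": p_max, "k": k0}

    def model(tt, p, k):
        return p * (1.0 - np.exp(-k * tt))

    try:
        popt, _ = curve_fit(
            model,
            t,
            f,
            p0=[p_max, k0],
            bounds=([1e-6, 1e-4], [10.0, 1e3]),
            maxfev=10000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(
            f"recovery fit did not converge: {exc}",
            init=init,
            residuals=f - model(t, p_max, k0),
        ) from exc
    plateau, k = float(popt[0]), float(popt[1])
    resid = f - model(t, plateau, k)
    return RecoveryFit(
        plateau=plateau,
        k=k,
        half_life=float(np.log(2.0) / k),
        window=window,
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        n_points=int(t.size),
    )


def process_series(
    series: FRAPSeries, window: tuple[float, float] = (0.0, 14.0)
) -> dict:
    """Full pipeline: correct, normalize, fit. Returns all intermediates."""
    corrected = correct_photobleach(series)
    pre_value = float(np.mean(corrected[: series.n_pre]))
    t0_value = float(corrected[series.t0_index])
    normalized = normalize_recovery(corrected, pre_value, t0_value)
    fit = fit_recovery(series.time_s, normalized, window)
    return {
        "corrected": corrected,
        "normalized": normalized,
        "pre_bleach_corrected": pre_value,
        "t0_corrected": t0_value,
        "fit": fit,
    }
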