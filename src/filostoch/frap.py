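"""FRAP (fluorescence recovery after photobleaching) normalization and fitting.

A FRAP experiment on an FLS tip records four regions of interest: the
bleached structure, an unbleached structure nearby, and one local background
for each.  Normalization (i) subtracts the paired background from each
structure ROI, (ii) divides the bleached series by the unbleached series
relative to its own prebleach mean, correcting the gradual fluorescence loss
caused by postbleach acquisition, (iii) scales the prebleach mean to 1 and
(iv) shifts/scales affinely so the bleach frame sits at 0.  The normalized
recovery is then fitted with A*(1 - exp(-k*t)): ``percent_recovery`` is
100*A (the mobile fraction) and the half-time is ln2/k.

Sampling may be nonuniform (e.g. 0.5-s frames early in the recovery, 1-s
frames later); all fitting is done in real time units, never frame indices.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from sklearn.base import BaseEstimator

__all__ = [
    "FrapTrace",
    "FrapFit",
    "detect_bleach_frame",
    "normalize_frap",
    "FrapRecoveryFit",
    "fit_recovery",
    "analyze_frap",
]


@dataclass
class FrapTrace:
    """Four-ROI photobleaching time series; times in seconds."""

    time_s: np.ndarray
    bleached: np.ndarray
    unbleached: np.ndarray
    background_bleached: np.ndarray
    background_unbleached: np.ndarray
    bleach_frame: int | None = None

    def __post_init__(self) -> None:
        arrs = [self.time_s, self.bleached, self.unbleached,
                self.background_bleached, self.background_unbleached]
        arrs = [np.asarray(a, dtype=float) for a in arrs]
        if len({a.shape for a in arrs}) != 1:
            raise ValueError("all four ROI series and time must have equal length")
        (self.time_s, self.bleached, self.unbleached,
         self.background_bleached, self.background_unbleached) = arrs
        if self.bleach_frame is not None and self.bleach_frame < 1:
            raise ValueError("bleach frame must follow at least one prebleach frame")


@dataclass(frozen=True)
class FrapFit:
    """Single-exponential recovery fit; half_time = ln2/rate."""

    rate: float  # k, 1/s
    plateau: float  # A, fraction of bleached pool that recovers
    half_time_s: float
    percent_recovery: float
    residual_rms: float
    flagged: bool = False


def detect_bleach_frame(series) -> int:
    """Index of the frame after the largest frame-to-frame intensity drop.

    Ties break to the earliest frame.  A series with no drop anywhere has no
    bleach event and is rejected.
    """
    x = np.asarray(series, dtype=float)
    if x.size < 3:
        raise ValueError("need >= 3 frames")
    drops = x[:-1] - x[1:]
    if np.all(drops <= 0):
        raise ValueError("series is non-decreasing: no bleach event found")
    return int(np.argmax(drops)) + 1


def normalize_frap(trace: FrapTrace) -> dict:
    """Background-subtract, acquisition-bleach-correct and rescale a trace.

    Returns the normalized series (prebleach mean 1, bleach frame 0), the
    time from bleach (seconds, 0 at the bleach frame) and the detected
    bleach frame.
    """
    ib = detect_bleach_frame(trace.bleached) if trace.bleach_frame is None else trace.bleach_frame
    b = trace.bleached - trace.background_bleached
    u = trace.unbleached - trace.background_unbleached
    if np.any(u <= 0):
        raise ValueError("unbleached ROI non-positive after background subtraction")
    pre = slice(0, ib)
    # acquisition-bleach correction: ratio to the unbleached ROI's same-frame
    # value relative to its prebleach mean
    corr = b / (u / u[pre].mean())
    norm = corr / corr[pre].mean()  # prebleach mean -> 1
    v0 = norm[ib]
    if v0 >= 1.0:
        raise ValueError("bleach frame not below prebleach level after normalization")
    norm = (norm - v0) / (1.0 - v0)  # bleach frame -> 0, prebleach -> 1
    return {
        "normalized": norm,
        "time_from_bleach_s": trace.time_s - trace.time_s[ib],
        "bleach_frame": ib,
    }


class FrapRecoveryFit(BaseEstimator):
    """Least-squares fit of A*(1 - exp(-k*t)) to a normalized recovery.

    ``fit(t, y)`` takes postbleach times (seconds from the bleach frame) and
    normalized intensities.  Fitted attributes: ``rate_``, ``plateau_``,
    ``half_time_s_``, ``percent_recovery_``.  A flat (A ~ 0) series is
    flagged with an undefined half-time rather than an error.
    """

    def __init__(self, max_nfev: int = 10_000):
        self.max_nfev = max_nfev

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        keep = t >= 0
        t, v = t[keep], v[keep]
        if t.size < 5:
            raise ValueError("need >= 5 postbleach frames")
        a0 = max(float(v[-5:].mean()), 1e-3)
        above = v > 0.5 * a0
        t_half_guess = t[int(np.argmax(above))] if above.any() else t[-1] / 2
        k0 = np.log(2.0) / max(t_half_guess, t[1] - t[0] if t.size > 1 else 1.0)
        model = lambda tt, A, k: A * (1.0 - np.exp(-k * tt))
        try:
            (A, k), _ = optimize.curve_fit(
                model, t, v, p0=(a0, k0), maxfev=self.max_nfev,
                bounds=((0.0, 0.0), (np.inf, np.inf)),
            )
        except RuntimeError as err:
            raise RuntimeError(f"recovery fit did not converge: {err}") from err
        resid = v - model(t, A, k)
        self.rate_ = float(k)
        self.plateau_ = float(A)
        self.flagged_ = A < 1e-3 or k <= 0
        self.half_time_s_ = float(np.log(2.0) / k) if not self.flagged_ else np.nan
        self.percent_recovery_ = float(100.0 * A)
        self.residual_rms_ = float(np.sqrt(np.mean(resid**2)))
        return self

    def result_(self) -> FrapFit:
        return FrapFit(
            rate=self.rate_,
            plateau=self.plateau_,
            half_time_s=self.half_time_s_,
            percent_recovery=self.percent_recovery_,
            residual_rms=self.residual_rms_,
            flagged=self.flagged_,
        )


def fit_recovery(time_from_bleach_s, normalized) -> FrapFit:
    """Fit a normalized recovery curve; see :class:`FrapRecoveryFit`."""
    return FrapRecoveryFit().fit(time_from_bleach_s, normalized).result_()


def analyze_frap(trace: FrapTrace) -> FrapFit:
    """Normalize a raw four-ROI trace and fit its recovery."""
    norm = normalize_frap(trace)
    return fit_recovery(norm["time_from_bleach_s"], norm["normalized"])
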