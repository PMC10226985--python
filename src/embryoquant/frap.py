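"""FRAP trace normalization and exponential recovery fitting.

The raw ROI intensity is background-corrected and divided by a
non-photobleached reference (which removes acquisition photofade), then
double-normalized so the pre-bleach mean maps to 1 and the first post-bleach
frame to 0.  The normalized recovery is fitted with a single exponential
``y(t) = I∞ (1 − exp(−(t − t0)/τ))`` on the post-bleach frames (the bleach
frame itself is included as the y = 0 anchor), and the immobile fraction —
the pool of molecules that never exchanges on the experiment's timescale —
is ``1 − I∞``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .io_formats import FrapTrace

__all__ = ["FrapFitResult", "normalize_trace", "fit_recovery", "analyze_trace"]


@dataclass
class FrapFitResult:
    """Fitted recovery parameters of one FRAP trace."""

    i_inf: float  # normalized plateau I∞
    tau: float  # recovery time constant, s
    immobile_fraction: float  # 1 − I∞
    fit_rmse: float  # RMSE on the normalized scale
    n_pre: int
    n_post: int
    flags: tuple[str, ...] = ()  # e.g. "i_inf_above_1", "tau_at_bound"


def normalize_trace(trace: FrapTrace) -> tuple[np.ndarray, np.ndarray]:
    """Background-correct, reference-normalize and double-normalize a trace.

    Returns ``(t, y)`` where the mean pre-bleach ``y`` is exactly 1 and
    ``y[bleach_index]`` is exactly 0.  Raises if the reference does not
    exceed background everywhere or if no bleach depth exists.
    """
    bg = trace.background
    ref = trace.reference - bg
    if np.any(ref <= 0):
        raise ValueError("reference must exceed background at every frame")
    r = (trace.roi - bg) / ref
    r_pre = r[: trace.bleach_index].mean()
    r0 = r[trace.bleach_index]
    if r_pre == r0:
        raise ValueError("no bleach detected: pre-bleach level equals post-bleach level")
    y = (r - r0) / (r_pre - r0)
    return trace.t.copy(), y


def fit_recovery(
    t: np.ndarray,
    y: np.ndarray,
    bleach_index: int,
    max_tau_factor: float = 100.0,
) -> FrapFitResult:
    """Least-squares single-exponential fit of a normalized recovery.

    Deterministic initialization: I∞ starts at the mean of the last 10% of
    frames and τ at the time to reach half of that plateau.  τ is bounded by
    ``max_tau_factor`` times the post-bleach duration; hitting the bound is
    flagged rather than silently accepted.
    """
    t = np.asarray(t, float)
    y = np.asarray(y, float)
    post = slice(bleach_index, None)
    tp = t[post] - t[bleach_index]
    yp = y[post]
    if len(tp) < 5:
        raise ValueError("need at least 5 post-bleach frames")

    n_tail = max(1, int(round(0.1 * len(yp))))
    i0 = float(np.clip(yp[-n_tail:].mean(), 1e-6, 2.0))
    half = np.nonzero(yp >= 0.5 * i0)[0]
    tau0 = float(tp[half[0]]) if len(half) and tp[half[0]] > 0 else float(tp[-1] / 5.0)
    tau_hi = max_tau_factor * float(tp[-1])

    def model(tt, i_inf, tau):
        return i_inf * (1.0 - np.exp(-tt / tau))

    try:
        popt, _ = curve_fit(
            model,
            tp,
            yp,
            p0=(i0, max(tau0, tp[1] if len(tp) > 1 else 1.0)),
            bounds=([0.0, 1e-9], [5.0, tau_hi]),
            maxfev=10000,
        )
    except RuntimeError as e:
        raise RuntimeError(f"FRAP fit did not converge: {e}") from e
    i_inf, tau = float(popt[0]), float(popt[1])
    rmse = float(np.sqrt(np.mean((model(tp, i_inf, tau) - yp) ** 2)))
    flags = []
    if i_inf > 1.0:
        flags.append("i_inf_above_1")
    if tau >= 0.99 * tau_hi:
        flags.append("tau_at_bound")
    return FrapFitResult(
        i_inf=i_inf,
        tau=tau,
        immobile_fraction=1.0 - i_inf,
        fit_rmse=rmse,
        n_pre=bleach_index,
        n_post=len(tp),
        flags=tuple(flags),
    )


def analyze_trace(trace: FrapTrace) -> FrapFitResult:
    """Normalize and fit one raw trace in a single call."""
    t, y = normalize_trace(trace)
    return fit_recovery(t, y, trace.bleach_index)
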