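"""Non-compartmental analysis of drug concentration–time data.

Terminal half-life by log-linear regression on the last points of the mean
profile, and AUC by the linear trapezoid with single-exponential tail
extrapolation.  Note that under flip-flop kinetics the NCA terminal slope
reflects the absorption rate constant, not elimination.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .model import NCAError, SchemaError

__all__ = ["terminal_half_life", "terminal_slope", "auc_to_last_and_inf", "nca_summary"]


def _clean(times, concs):
    times = np.asarray(times, dtype=float)
    concs = np.asarray(concs, dtype=float)
    if times.shape != concs.shape or times.ndim != 1:
        raise SchemaError("times and concs must be 1-D arrays of equal length")
    if np.any(np.diff(times) <= 0):
        raise SchemaError("times must be strictly increasing")
    if np.any(concs < 0):
        raise SchemaError("concentrations must be >= 0")
    return times, concs


def terminal_slope(times, concs, n_terminal: int = 3) -> float:
    """λz: negative slope of the log-linear regression on the last points.

    Only strictly positive concentrations are usable; with ``n_terminal=None``
    the tail length (3 up to all-but-one points) maximizing adjusted R² of the
    log-linear fit is chosen automatically.
    """
    times, concs = _clean(times, concs)
    positive = concs > 0
    t = times[positive]
    c = concs[positive]
    if t.size < 3:
        raise NCAError(f"need >= 3 positive concentrations, got {t.size}")

    def slope_for(n):
        reg = stats.linregress(t[-n:], np.log(c[-n:]))
        return reg

    if n_terminal is None:
        best = None
        for n in range(3, t.size + 1):
            reg = slope_for(n)
            r2_adj = 1.0 - (1.0 - reg.rvalue ** 2) * (n - 1) / (n - 2)
            if best is None or r2_adj > best[0]:
                best = (r2_adj, reg)
        reg = best[1]
    else:
        if n_terminal < 3:
            raise NCAError(f"n_terminal must be >= 3, got {n_terminal}")
        if n_terminal > t.size:
            raise NCAError(f"n_terminal={n_terminal} exceeds {t.size} usable points")
        reg = slope_for(n_terminal)
    lam = -reg.slope
    if not (lam > 0):
        raise NCAError(f"nonpositive terminal slope (lambda_z={lam:.4g})")
    return float(lam)


def terminal_half_life(times, concs, n_terminal: int = 3) -> float:
    """Terminal half-life ln 2 / λz from the log-linear terminal phase."""
    return math.log(2.0) / terminal_slope(times, concs, n_terminal)


def auc_to_last_and_inf(times, concs, lambda_z: float | None = None) -> tuple[float, float]:
    """(AUC_0–t, AUC_0–∞) by the linear trapezoid plus C_last/λz tail.

    With ``lambda_z=None`` the terminal slope is estimated from the data
    (last 3 positive points); if that fails, AUC_0–∞ is returned as NaN.
    """
    times, concs = _clean(times, concs)
    auc_last = float(np.trapezoid(concs, times))
    c_last = concs[-1]
    if c_last <= 0:
        return auc_last, auc_last
    if lambda_z is None:
        try:
            lambda_z = terminal_slope(times, concs, 3)
        except NCAError:
            return auc_last, float("nan")
    if not (lambda_z > 0):
        raise NCAError(f"lambda_z must be > 0, got {lambda_z!r}")
    return auc_last, auc_last + float(c_last) / lambda_z


@dataclass(frozen=True)
class NCAResult:
    lambda_z: float
    half_life: float
    auc_last: float
    auc_inf: float
    cmax: float
    tmax: float
    n: int


def nca_summary(times, concs, n_terminal: int = 3) -> NCAResult:
    """Standard NCA battery for one mean concentration–time profile."""
    times, concs = _clean(times, concs)
    lam = terminal_slope(times, concs, n_terminal)
    auc_last, auc_inf = auc_to_last_and_inf(times, concs, lam)
    i = int(np.argmax(concs))
    return NCAResult(
        lambda_z=lam, half_life=math.log(2.0) / lam,
        auc_last=auc_last, auc_inf=auc_inf,
        cmax=float(concs[i]), tmax=float(times[i]), n=int(times.size),
    )
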