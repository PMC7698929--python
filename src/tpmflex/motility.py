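"""Functional-assay curve fits.

* :func:`fit_hill` — calcium dependence of thin-filament sliding velocity,
  v = vmax / (1 + 10^(n (pCa - pCa50))): vmax is the saturating velocity,
  pCa50 the calcium sensitivity and n the Hill (cooperativity) coefficient.
* :func:`fit_load_line` — sliding velocity vs fraction of NEM-modified
  myosin (a non-cycling, load-bearing crossbridge); linear extrapolation to
  zero velocity gives the load that stops movement, a relative force measure.
* :func:`fit_saturation` — co-sedimentation binding curve; K50 is the
  concentration at which the filament lattice is half-saturated.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .synthetic import hill_velocity

__all__ = ["HillFit", "LoadFit", "SaturationFit", "fit_hill",
           "velocity_ratio", "fit_load_line", "fit_saturation"]


@dataclass
class HillFit:
    vmax: float        # um/s
    pCa50: float
    n: float
    se: dict = field(default_factory=dict)   # parameter standard errors
    residual_norm: float = 0.0

    def predict(self, pCa):
        return hill_velocity(pCa, self.vmax, self.pCa50, self.n)

    def to_dict(self) -> dict:
        return {"vmax_um_s": self.vmax, "pCa50": self.pCa50, "n": self.n,
                "se": self.se, "residual_norm": self.residual_norm}


@dataclass
class LoadFit:
    v0: float              # um/s, unloaded velocity (y-intercept)
    stop_fraction: float   # % NEM-myosin at zero velocity (x-intercept)
    slope: float
    n_points_used: int

    def to_dict(self) -> dict:
        return {"v0_um_s": self.v0, "stop_fraction_percent": self.stop_fraction,
                "slope": self.slope, "n_points_used": self.n_points_used}


@dataclass
class SaturationFit:
    K50: float       # uM
    h: float         # Hill slope of the binding curve
    plateau: float
    se: dict = field(default_factory=dict)
    warning: str | None = None

    def to_dict(self) -> dict:
        return {"K50_uM": self.K50, "hill_slope": self.h,
                "plateau": self.plateau, "se": self.se,
                "warning": self.warning}


def fit_hill(data: pd.DataFrame, weights=None) -> HillFit:
    """Fit the Hill pCa-velocity relation to (pCa, velocity) data.

    Requires >= 4 distinct pCa values spanning the transition; flat data
    (no velocity transition) is rejected as non-identifiable. ``weights``
    are optional per-point standard deviations (as in curve_fit ``sigma``);
    the default fit is unweighted.
    """
    pCa = np.asarray(data["pCa"], dtype=float)
    v = np.asarray(data["velocity"], dtype=float)
    if len(np.unique(pCa)) < 4:
        raise ValueError("need >= 4 distinct pCa values")
    vmax0 = float(np.max(v))
    if vmax0 <= 0 or (np.max(v) - np.min(v)) < 0.05 * max(vmax0, 1e-12):
        raise ValueError("no velocity transition in range; "
                         "Hill parameters are not identifiable")
    half_idx = int(np.argmin(np.abs(v - vmax0 / 2.0)))
    p0 = [vmax0, float(pCa[half_idx]), 2.0]
    popt, pcov = curve_fit(hill_velocity, pCa, v, p0=p0, sigma=weights,
                           bounds=([1e-9, 0.0, 1e-9], [np.inf, 14.0, np.inf]),
                           maxfev=20000)
    perr = np.sqrt(np.diag(pcov))
    rnorm = float(np.linalg.norm(hill_velocity(pCa, *popt) - v))
    return HillFit(vmax=float(popt[0]), pCa50=float(popt[1]), n=float(popt[2]),
                   se={"vmax": float(perr[0]), "pCa50": float(perr[1]),
                       "n": float(perr[2])},
                   residual_norm=rnorm)


def velocity_ratio(fit_a: HillFit, fit_b: HillFit) -> float:
    """Ratio of saturating velocities vmax_a / vmax_b, to one decimal."""
    if fit_b.vmax == 0:
        raise ZeroDivisionError("denominator fit has vmax = 0")
    return round(fit_a.vmax / fit_b.vmax, 1)


def fit_load_line(data: pd.DataFrame) -> LoadFit:
    """Linear extrapolation of velocity vs %NEM-myosin to zero velocity.

    Only moving points (v > 0) enter the ordinary least-squares line —
    stopped filaments carry no extrapolation information. The x-intercept
    is the NEM-myosin fraction required to stop movement.
    """
    x = np.asarray(data["percent_nem"], dtype=float)
    v = np.asarray(data["velocity"], dtype=float)
    keep = v > 0
    if keep.sum() < 3:
        raise ValueError("need >= 3 points with positive velocity")
    slope, intercept = np.polyfit(x[keep], v[keep], 1)
    if slope >= 0:
        raise ValueError("velocity does not decrease with load; "
                         "no stopping fraction exists")
    return LoadFit(v0=float(intercept), stop_fraction=float(-intercept / slope),
                   slope=float(slope), n_points_used=int(keep.sum()))


def _saturation_model(c, plateau, K50, h):
    c = np.asarray(c, dtype=float)
    return plateau * c**h / (K50**h + c**h)


def fit_saturation(data: pd.DataFrame, fix_h: float | None = None) -> SaturationFit:
    """Fit a (Hill-form) binding curve to (concentration, bound fraction).

    ``fix_h`` constrains the binding Hill slope (e.g. 1 for hyperbolic
    binding); by default it is fitted. Non-saturating data (fitted K50
    beyond the sampled range) is flagged with a warning string rather than
    rejected.
    """
    c = np.asarray(data["concentration"], dtype=float)
    f = np.asarray(data["bound"], dtype=float)
    if len(np.unique(c)) < 4:
        raise ValueError("need >= 4 distinct concentrations")
    plateau0 = float(np.max(f))
    K0 = float(c[np.argmin(np.abs(f - plateau0 / 2.0))]) or float(np.median(c))
    if fix_h is None:
        popt, pcov = curve_fit(_saturation_model, c, f,
                               p0=[plateau0, K0, 1.0],
                               bounds=([1e-9, 1e-9, 0.1], [np.inf, np.inf, 10.0]),
                               maxfev=20000)
        plateau, K50, h = (float(p) for p in popt)
        perr = np.sqrt(np.diag(pcov))
        se = {"plateau": float(perr[0]), "K50": float(perr[1]), "h": float(perr[2])}
    else:
        def model(cc, plateau, K50):
            return _saturation_model(cc, plateau, K50, fix_h)
        popt, pcov = curve_fit(model, c, f, p0=[plateau0, K0],
                               bounds=([1e-9, 1e-9], [np.inf, np.inf]),
                               maxfev=20000)
        plateau, K50, h = float(popt[0]), float(popt[1]), float(fix_h)
        perr = np.sqrt(np.diag(pcov))
        se = {"plateau": float(perr[0]), "K50": float(perr[1])}
    warning = None
    if K50 > c.max():
        warning = ("fitted K50 exceeds the sampled concentration range; "
                   "the binding curve does not saturate and the estimate "
                   "has a wide confidence bound")
    return SaturationFit(K50=K50, h=h, plateau=plateau, se=se, warning=warning)
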