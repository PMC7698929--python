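"""Thermal-denaturation fits.

Two fits live here:

* :func:`fit_dsc` — deconvolution of a baseline-corrected DSC excess heat
  capacity curve into a sum of non-two-state transitions (calorimetric
  domains), each with its own melting temperature Tm, calorimetric enthalpy
  dH_cal and van't Hoff enthalpy dH_vH. "Non-two-state" means dH_vH is fitted
  independently of dH_cal; their ratio measures cooperativity.
* :func:`fit_dissociation` — a four-parameter decreasing Boltzmann sigmoid
  for normalized light-scattering melts of filament complexes; the midpoint
  temperature (Tdiss) is the temperature of half-dissociation.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit, least_squares
from scipy.signal import argrelmax

from .synthetic import (TransitionSpec, boltzmann_sigmoid,
                        dsc_excess_heat_capacity)

__all__ = ["DSCFitResult", "DissociationFit", "fit_dsc", "domain_percentages",
           "fit_dissociation"]

#: identifiability bounds on the van't Hoff / calorimetric enthalpy ratio
VH_RATIO_BOUNDS = (0.2, 5.0)


@dataclass
class DSCFitResult:
    """Fitted non-two-state deconvolution, domains sorted by Tm."""

    transitions: list            # of TransitionSpec
    total_dH_cal: float          # kJ/mol
    percentages: list            # per-domain % of total
    residual_norm: float
    converged: bool = True

    def to_dict(self) -> dict:
        return {
            "domains": [
                {"Tm_C": t.Tm, "dH_cal_kJ_mol": t.dH_cal,
                 "dH_vH_kJ_mol": t.dH_vH, "percent_of_total": p}
                for t, p in zip(self.transitions, self.percentages)
            ],
            "total_dH_cal_kJ_mol": self.total_dH_cal,
            "residual_norm": self.residual_norm,
            "converged": self.converged,
        }


@dataclass
class DissociationFit:
    """Fitted Boltzmann sigmoid decay of normalized light scattering."""

    Tdiss: float      # deg C, half-decrease temperature
    width: float      # deg C
    upper: float
    lower: float
    residual_norm: float

    def to_dict(self) -> dict:
        return {"Tdiss_C": self.Tdiss, "width_C": self.width,
                "upper_plateau": self.upper, "lower_plateau": self.lower,
                "residual_norm": self.residual_norm}


def _auto_init(T: np.ndarray, cp: np.ndarray, n_domains: int) -> list:
    """Initial transitions: Tm at the n largest local maxima (padded by the
    global maximum / spread when fewer are distinguishable), dH_cal by equal
    split of the integral, dH_vH = dH_cal."""
    total = float(np.trapezoid(cp, T))
    if total <= 0:
        raise ValueError("curve has non-positive integral; not a melt")
    idx = argrelmax(cp, order=max(2, len(T) // 100))[0]
    if len(idx) < n_domains:
        warnings.warn(
            f"only {len(idx)} local maxima found for {n_domains} domains; "
            "initial Tm values spread over the grid", stacklevel=2)
        qs = np.linspace(0.25, 0.75, n_domains)
        tms = np.quantile(T, qs)
    else:
        top = idx[np.argsort(cp[idx])[::-1][:n_domains]]
        tms = np.sort(T[top])
    dh = total / n_domains
    return [TransitionSpec(Tm=float(tm), dH_cal=dh, dH_vH=dh) for tm in tms]


def fit_dsc(curve: pd.DataFrame, n_domains: int,
            init="auto") -> DSCFitResult:
    """Nonlinear least-squares deconvolution of a DSC thermogram.

    ``curve`` has columns ``T_C`` and ``Cp_excess`` (baseline-corrected
    excess heat capacity, kJ mol^-1 K^-1). Each domain is parameterized as
    (Tm, dH_cal, r) with dH_vH = r * dH_cal and r bounded in [0.2, 5] to
    keep the deconvolution identifiable. ``init`` is "auto" or a list of
    :class:`~tpmflex.synthetic.TransitionSpec`.
    """
    if n_domains < 1:
        raise ValueError("n_domains must be >= 1")
    T = np.asarray(curve["T_C"], dtype=float)
    cp = np.asarray(curve["Cp_excess"], dtype=float)
    if init == "auto":
        init = _auto_init(T, cp, n_domains)
    if len(init) != n_domains:
        raise ValueError("init must supply one transition per domain")

    rlo, rhi = VH_RATIO_BOUNDS
    x0, lo, hi = [], [], []
    for tr in init:
        r0 = np.clip(tr.dH_vH / tr.dH_cal, rlo, rhi)
        x0 += [tr.Tm, tr.dH_cal, r0]
        lo += [T.min() - 20.0, 1e-6, rlo]
        hi += [T.max() + 20.0, np.inf, rhi]

    def unpack(x):
        return [TransitionSpec(Tm=x[3 * i], dH_cal=x[3 * i + 1],
                               dH_vH=x[3 * i + 1] * x[3 * i + 2])
                for i in range(n_domains)]

    def resid(x):
        return dsc_excess_heat_capacity(T, unpack(x)) - cp

    res = least_squares(resid, x0, bounds=(lo, hi), method="trf",
                        xtol=1e-12, ftol=1e-12)
    if not res.success:
        warnings.warn(
            f"DSC deconvolution did not converge cleanly "
            f"(status {res.status}, final residual {np.linalg.norm(res.fun):.4g})",
            stacklevel=2)
    transitions = sorted(unpack(res.x), key=lambda t: (t.Tm, t.dH_cal))
    total = float(sum(t.dH_cal for t in transitions))
    pct = [100.0 * t.dH_cal / total for t in transitions]
    return DSCFitResult(transitions=transitions, total_dH_cal=total,
                        percentages=pct,
                        residual_norm=float(np.linalg.norm(res.fun)),
                        converged=bool(res.success))


def domain_percentages(result: DSCFitResult) -> list:
    """Per-domain share of the total calorimetric enthalpy, in percent."""
    total = sum(t.dH_cal for t in result.transitions)
    if total <= 0:
        raise ValueError("total enthalpy is zero")
    return [100.0 * t.dH_cal / total for t in result.transitions]


def fit_dissociation(curve: pd.DataFrame) -> DissociationFit:
    """Four-parameter Boltzmann sigmoid fit of a light-scattering melt.

    ``curve`` has columns ``T_C`` and ``scattering``; the data must decay
    with temperature (monotone-increasing data is rejected as wrong-signed).
    The reported Tdiss is the temperature of the half-decrease between the
    fitted plateaus.
    """
    T = np.asarray(curve["T_C"], dtype=float)
    y = np.asarray(curve["scattering"], dtype=float)
    n3 = max(3, len(y) // 5)
    if np.mean(y[:n3]) <= np.mean(y[-n3:]):
        raise ValueError("scattering increases with temperature; "
                         "expected a dissociation (decay) curve")
    upper0, lower0 = float(np.max(y)), float(np.min(y))
    mid = 0.5 * (upper0 + lower0)
    Td0 = float(T[np.argmin(np.abs(y - mid))])
    p0 = [upper0, lower0, Td0, 1.0]
    popt, _ = curve_fit(boltzmann_sigmoid, T, y, p0=p0,
                        bounds=([-np.inf, -np.inf, T.min(), 1e-6],
                                [np.inf, np.inf, T.max(), np.inf]),
                        maxfev=20000)
    upper, lower, Td, width = (float(v) for v in popt)
    if lower >= upper:
        raise ValueError("fitted lower plateau above upper plateau")
    rnorm = float(np.linalg.norm(boltzmann_sigmoid(T, *popt) - y))
    return DissociationFit(Tdiss=Td, width=width, upper=upper, lower=lower,
                           residual_norm=rnorm)
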