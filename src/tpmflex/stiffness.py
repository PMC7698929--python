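"""Secant persistence length and bending stiffness from skeleton ensembles.

The estimator follows the tangent-correlation construction for a semi-rigid
rod of a priori unknown intrinsically bent shape: the first segments of all
skeletons are superimposed, the time-average unit tangent field ``t0(s)`` is
formed, and the correlation ``C(s) = <t(s) . t0(s)>`` is fitted as
``exp(-s / L_p)``; the bending stiffness follows from ``K = L_p * kB T``.

Because superposing only the first *segment* leaves the torsion about that
segment undefined, two modes are provided: a least-squares superposition of
the three leading nodes onto the ensemble-mean leading triad (default,
removes the spin ambiguity) and the literal minimal rotation taking the first
tangent onto the mean first-tangent direction.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .skeleton import SkeletonFrame, WindowingScheme, skeletonize_trajectory

__all__ = ["TangentField", "PersistenceFit", "superpose_first_segments",
           "tangent_correlation", "fit_persistence", "estimate_stiffness",
           "estimate_stiffness_from_skeletons", "nearest_neighbor_persistence",
           "KBT_DEFAULT"]

#: Thermal energy in pN nm at ~297 K.
KBT_DEFAULT = 4.1


@dataclass
class TangentField:
    """Per-frame unit tangents and their time-average reference field."""

    s: np.ndarray          # (n_seg,) arc midpoints, nm (ensemble mean)
    tangents: np.ndarray   # (n_frames, n_seg, 3), unit norm
    t0: np.ndarray         # (n_seg, 3), renormalized time average

    @property
    def n_frames(self) -> int:
        return self.tangents.shape[0]


@dataclass
class PersistenceFit:
    """Result of the log-linear fit of the tangent correlation profile."""

    s: np.ndarray
    C: np.ndarray
    lnC: np.ndarray
    slope: float
    intercept: float
    L_p: float             # nm; inf when the profile does not decay
    K: float               # pN nm^2
    kBT: float
    fit_range: tuple
    r_squared: float
    infinite: bool = False
    n_excluded: int = 0

    def to_dict(self) -> dict:
        return {
            "L_p_nm": self.L_p, "K_pN_nm2": self.K, "kBT_pN_nm": self.kBT,
            "slope_per_nm": self.slope, "intercept": self.intercept,
            "fit_range_nm": list(self.fit_range), "r_squared": self.r_squared,
            "infinite_persistence": self.infinite,
            "n_points_excluded": self.n_excluded,
        }


def _as_node_array(skeletons) -> np.ndarray:
    nodes = np.asarray([s.nodes for s in skeletons], dtype=float)
    if nodes.ndim != 3:
        raise ValueError("skeletons must share a common node count")
    return nodes


def _wahba_batch(P: np.ndarray, Q: np.ndarray) -> np.ndarray:
    """Per-frame rotations R_f minimizing sum_m |R_f P_fm - Q_fm|^2
    (rotation about the origin; P, Q have shape (F, m, 3))."""
    H = np.einsum("fmi,fmj->fij", P, Q)
    U, _, Vt = np.linalg.svd(H)
    V = np.swapaxes(Vt, -1, -2)
    Ut = np.swapaxes(U, -1, -2)
    d = np.sign(np.linalg.det(V @ Ut))
    D = np.tile(np.eye(3), (len(P), 1, 1))
    D[:, 2, 2] = d
    return V @ D @ Ut


def _minimal_rotations(t_from: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Per-frame geodesic rotation taking unit vector t_from[f] onto ref."""
    v = np.cross(t_from, ref)
    s2 = np.einsum("fi,fi->f", v, v)
    c = t_from @ ref
    K = np.zeros((len(v), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -v[:, 2], v[:, 1]
    K[:, 1, 0], K[:, 1, 2] = v[:, 2], -v[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -v[:, 1], v[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(s2 > 1e-24, (1.0 - c) / np.where(s2 > 0, s2, 1.0), 0.5)
    return np.eye(3)[None] + K + fac[:, None, None] * (K @ K)


def superpose_first_segments(skeletons, mode: str = "first-two-segments"):
    """Align all skeleton frames on their leading geometry.

    Every frame is translated so node 0 sits at the origin, then rotated:

    * ``"first-two-segments"`` (default): least-squares rotation of nodes
      {0, 1, 2} onto the ensemble-mean leading triad (fixes the spin about
      the first tangent); the reference triad is refined once.
    * ``"first-segment"``: minimal geodesic rotation taking the first
      tangent onto the ensemble-mean first-tangent direction.
    """
    if mode not in ("first-two-segments", "first-segment"):
        raise ValueError(f"unknown superposition mode {mode!r}")
    nodes = _as_node_array(skeletons)
    if len(nodes) < 1:
        raise ValueError("need at least one frame")
    if nodes.shape[1] < 3 and mode == "first-two-segments":
        raise ValueError("first-two-segments mode needs >= 3 nodes per frame")
    nodes = nodes - nodes[:, :1, :]  # node 0 -> origin

    if mode == "first-segment":
        t1 = nodes[:, 1, :] - nodes[:, 0, :]
        t1 /= np.linalg.norm(t1, axis=1, keepdims=True)
        ref = t1.mean(axis=0)
        ref /= np.linalg.norm(ref)
        R = _minimal_rotations(t1, ref)
        nodes = np.einsum("fij,fnj->fni", R, nodes)
    else:
        # node 0 is at the origin, so only nodes 1 and 2 constrain the fit
        ref = nodes[:, 1:3, :].mean(axis=0)
        for _ in range(2):  # refine the mean triad once
            R = _wahba_batch(nodes[:, 1:3, :], np.broadcast_to(ref, (len(nodes), 2, 3)))
            nodes = np.einsum("fij,fnj->fni", R, nodes)
            ref = nodes[:, 1:3, :].mean(axis=0)

    out = []
    for f, sk in enumerate(skeletons):
        out.append(SkeletonFrame(nodes=nodes[f], arc_s=sk.arc_s.copy(),
                                 frame_time=sk.frame_time))
    return out


def tangent_correlation(aligned_skeletons, renormalize_t0: bool = True):
    """Unit tangents, reference field and the correlation profile C(s).

    Returns ``(TangentField, profile)`` where profile is a DataFrame with
    columns ``s`` (ensemble-mean segment arc midpoint, nm), ``C`` and
    ``lnC`` (NaN where C <= 0).
    """
    nodes = _as_node_array(aligned_skeletons)
    diffs = np.diff(nodes, axis=1)
    seg_len = np.linalg.norm(diffs, axis=2)
    bad = np.argwhere(seg_len <= 0)
    if len(bad):
        f, k = bad[0]
        raise ValueError(f"zero-length segment {k} in frame {f}")
    tangents = diffs / seg_len[..., None]
    arcs = np.asarray([s.arc_s for s in aligned_skeletons])
    s_mid = 0.5 * (arcs[:, :-1] + arcs[:, 1:]).mean(axis=0)
    t0 = tangents.mean(axis=0)
    if renormalize_t0:
        t0 = t0 / np.linalg.norm(t0, axis=1, keepdims=True)
    C = np.einsum("fkj,kj->k", tangents, t0) / len(tangents)
    with np.errstate(divide="ignore", invalid="ignore"):
        lnC = np.where(C > 0, np.log(np.maximum(C, 1e-300)), np.nan)
    field = TangentField(s=s_mid, tangents=tangents, t0=t0)
    profile = pd.DataFrame({"s": s_mid, "C": C, "lnC": lnC})
    return field, profile


def fit_persistence(profile, fit_range: tuple | None = None,
                    kBT: float = KBT_DEFAULT,
                    through_origin: bool = True) -> PersistenceFit:
    """Fit ln C(s) = -s / L_p (optionally with a free intercept).

    ``profile`` is a DataFrame with columns ``s`` and ``C`` (or ``lnC``).
    Points with C <= 0 inside the range are excluded and counted. When
    ``fit_range`` is None the fit runs from the first midpoint to
    ``min(total length, L_p/2)``, iterated once from an initial full-range
    fit. A non-negative slope yields an infinite-persistence flag rather
    than an exception.
    """
    s = np.asarray(profile["s"], dtype=float)
    C = np.asarray(profile["C"], dtype=float) if "C" in profile else np.exp(
        np.asarray(profile["lnC"], dtype=float))

    def _fit(lo, hi):
        in_range = (s >= lo) & (s <= hi)
        ok = in_range & (C > 0)
        n_excl = int(in_range.sum() - ok.sum())
        ss, yy = s[ok], np.log(C[ok])
        if len(ss) < 3:
            raise ValueError("fewer than 3 usable points in fit range")
        if through_origin:
            slope = float(ss @ yy / (ss @ ss))
            inter = 0.0
        else:
            slope, inter = np.polyfit(ss, yy, 1)
            slope, inter = float(slope), float(inter)
        pred = slope * ss + inter
        sst = float(((yy - yy.mean()) ** 2).sum())
        ssr = float(((yy - pred) ** 2).sum())
        r2 = 1.0 - ssr / sst if sst > 0 else 1.0
        return slope, inter, r2, n_excl, (float(lo), float(hi))

    if fit_range is not None:
        slope, inter, r2, n_excl, rng = _fit(*fit_range)
    else:
        slope, *_ = _fit(s.min(), s.max())
        if slope < 0:
            hi = min(s.max(), (-1.0 / slope) / 2.0)
            if hi < s.min():
                hi = s.max()
        else:
            hi = s.max()
        slope, inter, r2, n_excl, rng = _fit(s.min(), hi)

    if slope >= 0:
        return PersistenceFit(s=s, C=C, lnC=np.log(np.maximum(C, 1e-300)),
                              slope=slope, intercept=inter, L_p=np.inf,
                              K=np.inf, kBT=kBT, fit_range=rng,
                              r_squared=r2, infinite=True, n_excluded=n_excl)
    L_p = -1.0 / slope
    return PersistenceFit(s=s, C=C, lnC=np.log(np.maximum(C, 1e-300)),
                          slope=slope, intercept=inter, L_p=L_p,
                          K=L_p * kBT, kBT=kBT, fit_range=rng,
                          r_squared=r2, infinite=False, n_excluded=n_excl)


def nearest_neighbor_persistence(skeletons) -> float:
    """Auxiliary estimator from the mean nearest-neighbour tangent dot
    product: L_p = -b / ln<t_k . t_{k+1}> with b the mean segment length."""
    nodes = _as_node_array(skeletons)
    diffs = np.diff(nodes, axis=1)
    seg_len = np.linalg.norm(diffs, axis=2)
    t = diffs / seg_len[..., None]
    m = float(np.einsum("fkj,fkj->", t[:, :-1], t[:, 1:])
              / (t.shape[0] * (t.shape[1] - 1)))
    b = float(seg_len.mean())
    if m >= 1.0:
        return np.inf
    if m <= 0.0:
        return np.nan
    return -b / np.log(m)


def estimate_stiffness_from_skeletons(skeletons, mode: str = "first-two-segments",
                                      kBT: float = KBT_DEFAULT,
                                      fit_range: tuple | None = None,
                                      through_origin: bool = True):
    """Superpose, correlate and fit; returns (PersistenceFit, report dict).

    The report records the profile, the alternative superposition mode's
    persistence length (the torsion ambiguity of single-segment alignment
    makes the two modes legitimately different) and the auxiliary
    nearest-neighbour estimate.
    """
    if len(skeletons) < 2:
        raise ValueError("need >= 2 frames to estimate stiffness")
    aligned = superpose_first_segments(skeletons, mode=mode)
    field, profile = tangent_correlation(aligned)
    fit = fit_persistence(profile, fit_range=fit_range, kBT=kBT,
                          through_origin=through_origin)
    other_mode = ("first-segment" if mode == "first-two-segments"
                  else "first-two-segments")
    try:
        aligned2 = superpose_first_segments(skeletons, mode=other_mode)
        _, profile2 = tangent_correlation(aligned2)
        fit2 = fit_persistence(profile2, fit_range=fit_range, kBT=kBT,
                               through_origin=through_origin)
        L_other = fit2.L_p
    except ValueError:
        L_other = None
    report = {
        "n_frames": len(skeletons),
        "n_nodes": skeletons[0].n_nodes,
        "superposition_mode": mode,
        "fit": fit.to_dict(),
        "profile": profile.to_dict(orient="list"),
        "L_p_alternative_mode_nm": L_other,
        "L_p_nearest_neighbor_nm": nearest_neighbor_persistence(skeletons),
    }
    return fit, report


def estimate_stiffness(trajectory, scheme: WindowingScheme | None = None,
                       stride_ps: float = 100.0, chain_ids=None,
                       mode: str = "first-two-segments",
                       kBT: float = KBT_DEFAULT,
                       fit_range: tuple | None = None,
                       through_origin: bool = True):
    """End-to-end pipeline: skeletonize -> superpose -> correlate -> fit."""
    scheme = scheme or WindowingScheme()
    skeletons = skeletonize_trajectory(trajectory, scheme, stride_ps=stride_ps,
                                       chain_ids=chain_ids)
    fit, report = estimate_stiffness_from_skeletons(
        skeletons, mode=mode, kBT=kBT, fit_range=fit_range,
        through_origin=through_origin)
    report["windowing"] = {"window": scheme.window, "step": scheme.step,
                           "end_weight": scheme.end_weight,
                           "chain_mode": scheme.chain_mode,
                           "stride_ps": stride_ps}
    return fit, report
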