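"""Synthetic inputs for every stage of the pipeline.

The generators here define the statistical structure the downstream analyses
assume:

* a discrete worm-like chain (WLC) whose joint bends follow a von Mises-Fisher
  distribution with concentration ``kappa = L_p / b`` -- the exact Boltzmann
  distribution for a bending energy linear in ``cos(theta)``, giving the
  closed-form joint mean ``<cos theta> = coth(kappa) - 1/kappa`` and tangent
  correlations ``<t(0) . t(k b)> = (coth kappa - 1/kappa)^k``;
* an idealized two-chain coiled-coil backbone (Crick-style: alpha-helices
  wound on a common superhelical axis) for skeleton and hydrogen-bond
  fixtures;
* sums of non-two-state thermal transitions (DSC excess heat capacity);
* Hill-shaped pCa-velocity curves, Boltzmann sigmoid dissociation curves and
  linear velocity-vs-load data for the functional-assay fits.

All generators are deterministic given a seed.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import ChainAtoms, Frame

__all__ = [
    "WLCParams",
    "CoiledCoilParams",
    "TransitionSpec",
    "vmf_mean_cos",
    "sample_vmf_cos",
    "gen_wlc_ensemble",
    "gen_coiled_coil",
    "gen_dsc_curve",
    "dsc_excess_heat_capacity",
    "gen_motility_curve",
    "hill_velocity",
    "gen_dissociation_curve",
    "boltzmann_sigmoid",
    "gen_nem_line",
]

#: Gas constant in kJ mol^-1 K^-1 (DSC enthalpies are in kJ/mol).
R_GAS = 8.314462618e-3


# --------------------------------------------------------------------------
# parameter containers
# --------------------------------------------------------------------------

@dataclass
class WLCParams:
    """Discrete worm-like-chain ensemble parameters.

    ``persistence_length`` is the generator ground truth recovered later by
    the tangent-correlation estimator; ``intrinsic_curvature`` adds a
    deterministic bend (radians per joint) in a fixed material plane, on top
    of the random thermal bend, emulating an intrinsically bent rod.
    """

    n_chains: int = 3000
    n_segments: int = 30
    segment_length: float = 1.4  # nm
    persistence_length: float = 161.0  # nm
    intrinsic_curvature: float = 0.0  # rad per joint
    seed: int = 0

    def __post_init__(self):
        if self.segment_length <= 0:
            raise ValueError("segment_length must be > 0")
        if self.persistence_length <= 0:
            raise ValueError("persistence_length must be > 0")
        if self.n_segments < 2:
            raise ValueError("n_segments must be >= 2")
        if self.n_chains < 1:
            raise ValueError("n_chains must be >= 1")

    @property
    def kappa(self) -> float:
        """vMF concentration of the joint bend distribution, L_p / b."""
        return self.persistence_length / self.segment_length


@dataclass
class CoiledCoilParams:
    """Idealized two-chain coiled-coil geometry (lengths in angstrom).

    Defaults are literature-standard values for a parallel dimeric coiled
    coil; they are fixture geometry, not a structural claim about any
    particular protein. ``superhelix_radius = 0`` degenerates to two straight
    ideal alpha-helices with axes on z.
    """

    n_residues: int = 284
    superhelix_radius: float = 4.9  # A
    superhelix_pitch: float = 140.0  # A
    helix_radius: float = 2.28  # A, C-alpha radius
    rise_per_residue: float = 1.56  # A
    residues_per_turn: float = 3.62

    def __post_init__(self):
        for name in ("superhelix_pitch", "helix_radius", "rise_per_residue",
                     "residues_per_turn"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if self.superhelix_radius < 0:
            raise ValueError("superhelix_radius must be >= 0")
        if self.n_residues < 2:
            raise ValueError("n_residues must be >= 2")


@dataclass
class TransitionSpec:
    """One non-two-state thermal transition.

    ``Tm`` in deg C; ``dH_cal`` (calorimetric) and ``dH_vH`` (van't Hoff)
    enthalpies in kJ/mol. The two enthalpies are independent: their ratio
    measures the deviation of the transition from two-state behaviour.
    """

    Tm: float
    dH_cal: float
    dH_vH: float

    def __post_init__(self):
        if self.dH_cal <= 0 or self.dH_vH <= 0:
            raise ValueError("enthalpies must be > 0")


# --------------------------------------------------------------------------
# worm-like chain
# --------------------------------------------------------------------------

def vmf_mean_cos(kappa: float) -> float:
    """Closed-form mean of cos(theta) under vMF(kappa): coth(kappa) - 1/kappa."""
    if kappa > 350:
        # coth(k) -> 1 to double precision
        return 1.0 - 1.0 / kappa
    return 1.0 / np.tanh(kappa) - 1.0 / kappa


def sample_vmf_cos(kappa: float, size, rng: np.random.Generator) -> np.ndarray:
    """Sample cos(theta) with density ~ exp(kappa cos theta) on [-1, 1].

    Inverse-CDF sampling: F^-1(u) = 1 + log(u + (1-u) e^{-2 kappa}) / kappa.
    """
    if kappa <= 0:
        raise ValueError("kappa must be > 0")
    u = rng.random(size)
    if kappa > 350:
        # e^{-2 kappa} underflows; the second term is negligible
        c = 1.0 + np.log(u) / kappa
    else:
        c = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
    return np.clip(c, -1.0, 1.0)


def _rotate_frames(mats: np.ndarray, t_old: np.ndarray, t_new: np.ndarray) -> np.ndarray:
    """Apply, per chain, the minimal rotation taking t_old onto t_new (parallel
    transport of the material frame; no spurious twist)."""
    v = np.cross(t_old, t_new)
    s2 = np.einsum("ij,ij->i", v, v)
    c = np.einsum("ij,ij->i", t_old, t_new)
    # Rodrigues: R = I + [v]_x + [v]_x^2 (1-c)/s^2 ; stable unless c ~ -1
    K = np.zeros((len(v), 3, 3))
    K[:, 0, 1], K[:, 0, 2] = -v[:, 2], v[:, 1]
    K[:, 1, 0], K[:, 1, 2] = v[:, 2], -v[:, 0]
    K[:, 2, 0], K[:, 2, 1] = -v[:, 1], v[:, 0]
    with np.errstate(invalid="ignore", divide="ignore"):
        fac = np.where(s2 > 1e-24, (1.0 - c) / np.where(s2 > 0, s2, 1.0), 0.5)
    R = np.eye(3)[None] + K + fac[:, None, None] * (K @ K)
    return R @ mats


def gen_wlc_ensemble(params: WLCParams) -> np.ndarray:
    """Generate an ensemble of discrete worm-like chains.

    Returns an array of node coordinates, shape ``(n_chains, n_segments + 1,
    3)``, in nm. Every chain starts at the origin with its first tangent
    along +z; each subsequent joint composes an optional deterministic bend of
    ``intrinsic_curvature`` radians (in the chain's material x-z plane) with a
    random vMF bend of concentration ``kappa = L_p / b`` and uniform azimuth.
    """
    rng = np.random.default_rng(params.seed)
    nc, ns, b = params.n_chains, params.n_segments, params.segment_length
    kappa = params.kappa
    c_int = params.intrinsic_curvature

    # material frames: columns of M are the local x, y, z axes in world coords
    M = np.tile(np.eye(3), (nc, 1, 1))
    tangents = np.empty((nc, ns, 3))
    tangents[:, 0] = [0.0, 0.0, 1.0]

    if c_int != 0.0:
        cb, sb = np.cos(c_int), np.sin(c_int)
        # bend about the local y axis: rotates local z toward local x
        R_int = np.array([[cb, 0.0, sb], [0.0, 1.0, 0.0], [-sb, 0.0, cb]])

    for k in range(1, ns):
        if c_int != 0.0:
            M = M @ R_int
        t_pre = M[:, :, 2].copy()
        cth = sample_vmf_cos(kappa, nc, rng)
        sth = np.sqrt(np.maximum(0.0, 1.0 - cth * cth))
        phi = rng.uniform(0.0, 2.0 * np.pi, nc)
        d_local = np.stack([sth * np.cos(phi), sth * np.sin(phi), cth], axis=1)
        t_new = np.einsum("nij,nj->ni", M, d_local)
        t_new /= np.linalg.norm(t_new, axis=1, keepdims=True)
        M = _rotate_frames(M, t_pre, t_new)
        tangents[:, k] = t_new

    nodes = np.zeros((nc, ns + 1, 3))
    nodes[:, 1:] = np.cumsum(b * tangents, axis=1)
    return nodes


# --------------------------------------------------------------------------
# coiled-coil fixture
# --------------------------------------------------------------------------

# ideal backbone internal coordinates (angstrom / degrees)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O, _B_N_H = 1.458, 1.525, 1.329, 1.231, 1.01
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA = 111.2, 116.2, 121.7
_PHI, _PSI, _OMEGA = -57.0, -47.0, 180.0


def _place_atom(a, b, c, bond, angle_deg, dihedral_deg):
    """NeRF placement of atom d given chain a-b-c and internal coordinates."""
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array([
        -bond * np.cos(ang),
        bond * np.sin(ang) * np.cos(dih),
        bond * np.sin(ang) * np.sin(dih),
    ])
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _build_straight_helix(n_res: int):
    """Ideal alpha-helix backbone (phi=-57, psi=-47) via NeRF chain building.

    Returns dict of (n_res, 3) arrays for N, CA, C, O, H in angstrom, in an
    arbitrary orientation (axis not yet aligned).
    """
    N = np.empty((n_res, 3))
    CA = np.empty((n_res, 3))
    C = np.empty((n_res, 3))
    N[0] = [0.0, 0.0, 0.0]
    CA[0] = [_B_N_CA, 0.0, 0.0]
    ang = np.deg2rad(_A_N_CA_C)
    C[0] = CA[0] + _B_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])
    for i in range(1, n_res):
        N[i] = _place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, _PSI)
        CA[i] = _place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, _OMEGA)
        C[i] = _place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, _PHI)
    # carbonyl O: in the peptide plane, opposing the CA/N(+1) bisector
    O = np.empty((n_res, 3))
    for i in range(n_res - 1):
        u1 = C[i] - CA[i]
        u2 = C[i] - N[i + 1]
        d = u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2)
        O[i] = C[i] + _B_C_O * d / np.linalg.norm(d)
    O[-1] = _place_atom(N[-1], CA[-1], C[-1], _B_C_O, 120.8, _PSI + 180.0)
    # amide H: opposing the bisector of C(i-1)-N and CA(i)-N; none on residue 1
    H = np.full((n_res, 3), np.nan)
    for i in range(1, n_res):
        u1 = C[i - 1] - N[i]
        u2 = CA[i] - N[i]
        d = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
        H[i] = N[i] + _B_N_H * d / np.linalg.norm(d)
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}


def _align_helix_to_z(atoms: dict) -> dict:
    """Rigidly move a straight ideal helix so its screw axis is +z through the
    origin, with CA of residue 1 on the +x side."""
    CA = atoms["CA"]
    # screw transform between consecutive residues (identical for all i in an
    # ideal helix): Kabsch on (N, CA, C) triads of residues 1 and 2
    P = np.stack([atoms["N"][0], CA[0], atoms["C"][0]])
    Q = np.stack([atoms["N"][1], CA[1], atoms["C"][1]])
    Pc, Qc = P - P.mean(0), Q - Q.mean(0)
    U, _, Vt = np.linalg.svd(Qc.T @ Pc)
    d = np.sign(np.linalg.det(U @ Vt))
    Rm = U @ np.diag([1.0, 1.0, d]) @ Vt
    t = Q.mean(0) - Rm @ P.mean(0)
    # rotation axis of Rm
    w, v = np.linalg.eig(Rm)
    axis = np.real(v[:, np.argmin(np.abs(w - 1.0))])
    axis /= np.linalg.norm(axis)
    if axis @ (CA[-1] - CA[0]) < 0:
        axis = -axis
    # a point p on the screw axis satisfies (I - Rm) p = t - (t.axis) axis
    t_perp = t - (t @ axis) * axis
    p, *_ = np.linalg.lstsq(np.eye(3) - Rm, t_perp, rcond=None)
    # rotate axis -> z
    zhat = np.array([0.0, 0.0, 1.0])
    vv = np.cross(axis, zhat)
    s = np.linalg.norm(vv)
    c = axis @ zhat
    if s < 1e-12:
        Rz = np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    else:
        K = np.array([[0, -vv[2], vv[1]], [vv[2], 0, -vv[0]], [-vv[1], vv[0], 0]])
        Rz = np.eye(3) + K + K @ K * ((1 - c) / s**2)
    out = {}
    for name, xyz in atoms.items():
        out[name] = (xyz - p) @ Rz.T
    # zero the phase of CA_1 and drop its axial offset
    ca0 = out["CA"][0]
    phase = np.arctan2(ca0[1], ca0[0])
    cph, sph = np.cos(-phase), np.sin(-phase)
    Rp = np.array([[cph, -sph, 0.0], [sph, cph, 0.0], [0.0, 0.0, 1.0]])
    for name in out:
        out[name] = out[name] @ Rp.T
    z0 = out["CA"][0, 2]
    for name in out:
        out[name][..., 2] -= z0
    return out


def _rescale_helix(atoms: dict, params: CoiledCoilParams) -> dict:
    """Scale an axis-aligned helix to the requested radius, rise and twist.

    The per-residue twist adjustment is applied as an extra rotation of each
    residue's atoms about the axis, so intra-residue geometry is preserved up
    to the (small, for near-default parameters) radial/axial scaling.
    """
    CA = atoms["CA"]
    n = len(CA)
    phi_ca = np.unwrap(np.arctan2(CA[:, 1], CA[:, 0]))
    r0 = np.hypot(CA[:, 0], CA[:, 1]).mean()
    dz0 = (CA[-1, 2] - CA[0, 2]) / (n - 1)
    dphi0 = (phi_ca[-1] - phi_ca[0]) / (n - 1)
    r_scale = params.helix_radius / r0
    z_scale = params.rise_per_residue / dz0
    dphi_new = np.sign(dphi0) * 2.0 * np.pi / params.residues_per_turn
    extra = (dphi_new - dphi0) * np.arange(n)
    out = {}
    for name, xyz in atoms.items():
        r = np.hypot(xyz[:, 0], xyz[:, 1]) * r_scale
        phi = np.arctan2(xyz[:, 1], xyz[:, 0]) + extra
        out[name] = np.stack(
            [r * np.cos(phi), r * np.sin(phi), xyz[:, 2] * z_scale], axis=-1
        )
    return out


def _wrap_on_superhelix(atoms: dict, radius: float, pitch: float, phase: float) -> dict:
    """Map a straight (z-axis) helix onto a superhelical axis.

    The straight-chain z coordinate is treated as arclength along the
    superhelical curve a(h) = (R cos(2 pi h / P + phase), R sin(...), h);
    the atom's (x, y) offsets are carried in the curve's normal/binormal
    frame. ``radius = 0`` reduces to a rigid rotation of the input.
    """
    alpha = 2.0 * np.pi / pitch
    gamma = np.sqrt(1.0 + (radius * alpha) ** 2)
    out = {}
    for name, xyz in atoms.items():
        s = xyz[..., 2]
        h = s / gamma
        ang = alpha * h + phase
        ca, sa = np.cos(ang), np.sin(ang)
        a_pt = np.stack([radius * ca, radius * sa, h], axis=-1)
        T = np.stack([-radius * alpha * sa, radius * alpha * ca,
                      np.ones_like(sa)], axis=-1) / gamma
        Nv = np.stack([-ca, -sa, np.zeros_like(sa)], axis=-1)
        Bv = np.cross(T, Nv)
        out[name] = a_pt + xyz[..., 0, None] * Nv + xyz[..., 1, None] * Bv
    return out


def gen_coiled_coil(params: CoiledCoilParams | None = None) -> Frame:
    """Build an idealized parallel two-chain coiled-coil backbone.

    Returns a :class:`~tpmflex.structures.Frame` with chains ``A`` and ``B``
    (coordinates in nm; atoms N, H, CA, C, O per residue; residue 1 has no
    amide H). Deterministic.
    """
    params = params or CoiledCoilParams()
    straight = _align_helix_to_z(_build_straight_helix(params.n_residues))
    straight = _rescale_helix(straight, params)
    resids = np.arange(1, params.n_residues + 1)
    chains = {}
    for chain_id, phase in (("A", 0.0), ("B", np.pi)):
        wrapped = _wrap_on_superhelix(
            straight, params.superhelix_radius, params.superhelix_pitch, phase
        )
        chains[chain_id] = ChainAtoms(
            resids=resids.copy(),
            coords={name: xyz * 0.1 for name, xyz in wrapped.items()},  # A -> nm
        )
    return Frame(chains=chains, time_ps=0.0)


# --------------------------------------------------------------------------
# DSC thermograms
# --------------------------------------------------------------------------

def dsc_excess_heat_capacity(T_celsius: np.ndarray, transitions) -> np.ndarray:
    """Excess heat capacity (kJ mol^-1 K^-1) of a sum of non-two-state
    transitions evaluated on a temperature grid in deg C.

    Each transition contributes
    ``dH_cal * dH_vH / (R T^2) * K / (1 + K)^2`` with
    ``K = exp[-(dH_vH / R)(1/T - 1/Tm)]``, temperatures in kelvin. The
    integral over T of each term equals dH_cal regardless of dH_vH.
    """
    T = np.asarray(T_celsius, dtype=float) + 273.15
    cp = np.zeros_like(T)
    for tr in transitions:
        tm = tr.Tm + 273.15
        K = np.exp(-(tr.dH_vH / R_GAS) * (1.0 / T - 1.0 / tm))
        cp += tr.dH_cal * tr.dH_vH / (R_GAS * T**2) * K / (1.0 + K) ** 2
    return cp


def gen_dsc_curve(transitions, T_grid, noise_sd: float = 0.0,
                  seed: int | None = None) -> pd.DataFrame:
    """Synthetic baseline-corrected DSC thermogram: columns T_C, Cp_excess."""
    T_grid = np.asarray(T_grid, dtype=float)
    if len(T_grid) < 2 or np.any(np.diff(T_grid) <= 0):
        raise ValueError("T_grid must be strictly increasing")
    for tr in transitions:
        if tr.Tm - 15.0 < T_grid[0] or tr.Tm + 15.0 > T_grid[-1]:
            warnings.warn(
                f"T_grid does not span Tm={tr.Tm} +/- 15 C; "
                "the transition is truncated", stacklevel=2)
    cp = dsc_excess_heat_capacity(T_grid, transitions)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sd, size=cp.shape)
    return pd.DataFrame({"T_C": T_grid, "Cp_excess": cp})


# --------------------------------------------------------------------------
# functional-assay curves
# --------------------------------------------------------------------------

def hill_velocity(pCa, vmax: float, pCa50: float, n: float):
    """Hill pCa-velocity relation v = vmax / (1 + 10^(n (pCa - pCa50)))."""
    return vmax / (1.0 + 10.0 ** (n * (np.asarray(pCa, dtype=float) - pCa50)))


def gen_motility_curve(vmax: float, pCa50: float, n: float, pCa_grid,
                       noise_sd: float = 0.0, replicates: int = 1,
                       seed: int | None = None) -> pd.DataFrame:
    """Synthetic sliding-velocity data on a pCa grid (columns pCa, velocity).

    Gaussian noise of sd ``noise_sd`` (um/s) is added per replicate and the
    result clipped at zero (velocities are non-negative).
    """
    if vmax <= 0 or n <= 0:
        raise ValueError("vmax and n must be > 0")
    pCa = np.asarray(pCa_grid, dtype=float)
    rng = np.random.default_rng(seed)
    rows = []
    for _ in range(replicates):
        v = hill_velocity(pCa, vmax, pCa50, n)
        if noise_sd > 0:
            v = v + rng.normal(0.0, noise_sd, size=v.shape)
        rows.append(pd.DataFrame({"pCa": pCa, "velocity": np.clip(v, 0.0, None)}))
    return pd.concat(rows, ignore_index=True)


def boltzmann_sigmoid(T, upper: float, lower: float, Tdiss: float, width: float):
    """Decreasing Boltzmann sigmoid: lower + (upper-lower)/(1+exp((T-Tdiss)/width))."""
    return lower + (upper - lower) / (1.0 + np.exp((np.asarray(T, dtype=float) - Tdiss) / width))


def gen_dissociation_curve(Tdiss: float, width: float, T_grid,
                           noise_sd: float = 0.0,
                           seed: int | None = None) -> pd.DataFrame:
    """Normalized light-scattering decay vs temperature (columns T_C, scattering).

    y(T) = 1 / (1 + exp((T - Tdiss)/width)); y(Tdiss) = 0.5 marks
    half-dissociation of the complex.
    """
    if width <= 0:
        raise ValueError("width must be > 0")
    T = np.asarray(T_grid, dtype=float)
    y = boltzmann_sigmoid(T, 1.0, 0.0, Tdiss, width)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=y.shape)
    return pd.DataFrame({"T_C": T, "scattering": y})


def gen_nem_line(v0: float, stop_fraction: float, nem_grid,
                 noise_sd: float = 0.0, seed: int | None = None) -> pd.DataFrame:
    """Sliding velocity vs %NEM-myosin load (columns percent_nem, velocity).

    v(x) = max(0, v0 (1 - x / stop_fraction)) + noise; the x-intercept is the
    NEM-myosin fraction that stops filament movement.
    """
    if stop_fraction <= 0:
        raise ValueError("stop_fraction must be > 0")
    x = np.asarray(nem_grid, dtype=float)
    v = np.maximum(0.0, v0 * (1.0 - x / stop_fraction))
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        v = v + rng.normal(0.0, noise_sd, size=v.shape)
    return pd.DataFrame({"percent_nem": x, "velocity": v})
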