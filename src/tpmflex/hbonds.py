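"""Backbone hydrogen-bond detection and per-residue occupancy profiles.

A bond is recorded between a backbone amide donor (N-H) and a backbone
carbonyl acceptor (C=O) when the donor-acceptor (N...O) distance and the
hydrogen-donor-acceptor (H-N...O) angle both fall inside a geometric
criterion — the de-facto standard 0.35 nm / 30 degrees used by common MD
analysis tools. Occupancy of a residue is the fraction of frames in which
its amide donates a detected bond, averaged over the two chains.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structures import Frame

__all__ = ["HBondCriterion", "OccupancyProfile", "reconstruct_amide_hydrogens",
           "detect_backbone_hbonds", "occupancy_profile"]


@dataclass
class HBondCriterion:
    """Geometric hydrogen-bond criterion.

    ``angle_convention``: ``"hda"`` (default) tests the angle at the donor
    nitrogen between N->H and N->O; ``"dha"`` tests the deviation from
    linearity of the N-H...O arrangement at the hydrogen. Both use
    ``max_angle_deg`` as the cutoff.
    """

    max_distance_nm: float = 0.35
    max_angle_deg: float = 30.0
    min_sequence_separation: int = 3  # |i - j| within one chain
    angle_convention: str = "hda"

    def __post_init__(self):
        if self.max_distance_nm <= 0:
            raise ValueError("max_distance_nm must be > 0")
        if not (0.0 < self.max_angle_deg < 90.0):
            raise ValueError("max_angle_deg must be in (0, 90)")
        if self.angle_convention not in ("hda", "dha"):
            raise ValueError(f"unknown angle_convention {self.angle_convention!r}")


@dataclass
class OccupancyProfile:
    """Per-residue h-bond occupancy, per chain and chain-averaged."""

    table: pd.DataFrame  # residue + occupancy_<chain> columns + occupancy_mean
    n_frames: int
    criterion: HBondCriterion
    role: str = "donor"

    def occupancy(self, residue: int) -> float:
        row = self.table[self.table["residue"] == residue]
        if row.empty:
            raise KeyError(f"residue {residue} not in profile")
        return float(row["occupancy_mean"].iloc[0])


def reconstruct_amide_hydrogens(frame: Frame) -> Frame:
    """Return a copy of the frame with amide hydrogens placed geometrically.

    H sits 0.101 nm from N, opposing the bisector of the C(i-1)-N and
    CA(i)-N bonds. Residues that already carry an H are left untouched; the
    first residue of each chain gets none (no preceding carbonyl carbon).
    """
    out = frame.copy()
    for cid, chain in out.chains.items():
        for name in ("N", "CA", "C"):
            if name not in chain.coords:
                raise ValueError(f"chain {cid}: backbone atom {name} missing")
        n_res = chain.n_residues
        N, CA, C = chain.coords["N"], chain.coords["CA"], chain.coords["C"]
        H = chain.coords.get("H")
        if H is None:
            H = np.full((n_res, 3), np.nan)
        else:
            H = H.copy()
        for i in range(1, n_res):
            if not np.isnan(H[i]).any():
                continue
            u1 = C[i - 1] - N[i]
            u2 = CA[i] - N[i]
            d = -(u1 / np.linalg.norm(u1) + u2 / np.linalg.norm(u2))
            H[i] = N[i] + 0.101 * d / np.linalg.norm(d)
        chain.coords["H"] = H
    return out


def detect_backbone_hbonds(frame: Frame, criterion: HBondCriterion | None = None):
    """Detect backbone N-H...O=C hydrogen bonds in one frame.

    Missing amide hydrogens are reconstructed first. Returns a sorted list of
    ``((donor_chain, donor_resid), (acceptor_chain, acceptor_resid))`` pairs.
    Within one chain a sequence separation of at least
    ``criterion.min_sequence_separation`` is required; inter-chain bonds have
    no separation constraint.
    """
    criterion = criterion or HBondCriterion()
    frame = reconstruct_amide_hydrogens(frame)

    donors, acceptors = [], []
    for cid, chain in frame.chains.items():
        N, H = chain.coords["N"], chain.coords["H"]
        if "O" not in chain.coords or "C" not in chain.coords:
            raise ValueError(f"chain {cid}: carbonyl atoms missing")
        O = chain.coords["O"]
        for i, resid in enumerate(chain.resids):
            if not np.isnan(H[i]).any():
                if np.isnan(N[i]).any():
                    raise ValueError(f"chain {cid} residue {resid}: N missing")
                donors.append((cid, int(resid), N[i], H[i]))
            if not np.isnan(O[i]).any():
                acceptors.append((cid, int(resid), O[i]))
    if not donors or not acceptors:
        return []

    d_N = np.array([d[2] for d in donors])
    d_H = np.array([d[3] for d in donors])
    a_O = np.array([a[2] for a in acceptors])

    dist = np.linalg.norm(d_N[:, None, :] - a_O[None, :, :], axis=2)
    within = dist <= criterion.max_distance_nm
    # sequence-separation / self exclusion within a chain
    cid_index = {cid: k for k, cid in enumerate(frame.chains)}
    d_c = np.array([cid_index[d[0]] for d in donors])
    a_c = np.array([cid_index[a[0]] for a in acceptors])
    d_r = np.array([d[1] for d in donors])
    a_r = np.array([a[1] for a in acceptors])
    same_chain = d_c[:, None] == a_c[None, :]
    too_close = np.abs(d_r[:, None] - a_r[None, :]) < criterion.min_sequence_separation
    within &= ~(same_chain & too_close)

    bonds = []
    cos_cut = np.cos(np.deg2rad(criterion.max_angle_deg))
    for di, ai in zip(*np.nonzero(within)):
        if criterion.angle_convention == "hda":
            v1 = d_H[di] - d_N[di]
            v2 = a_O[ai] - d_N[di]
        else:  # deviation from linearity at the hydrogen
            v1 = d_H[di] - d_N[di]
            v2 = a_O[ai] - d_H[di]
        c = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
        if c >= cos_cut:
            bonds.append(((donors[di][0], donors[di][1]),
                          (acceptors[ai][0], acceptors[ai][1])))
    return sorted(bonds)


def occupancy_profile(frames, criterion: HBondCriterion | None = None,
                      role: str = "donor") -> OccupancyProfile:
    """Per-residue occupancy over a trajectory, averaged over the chains.

    ``role`` attributes a bond to its donor residue (default) or to the
    acceptor (``role="acceptor"``).
    """
    criterion = criterion or HBondCriterion()
    if role not in ("donor", "acceptor"):
        raise ValueError(f"unknown role {role!r}")
    frames = list(frames)
    if not frames:
        raise ValueError("no frames supplied")

    chain_ids = frames[0].chain_ids()
    counts = {cid: {} for cid in chain_ids}
    for frame in frames:
        bonds = detect_backbone_hbonds(frame, criterion)
        seen = set()
        for (dcid, dres), (acid, ares) in bonds:
            key = (dcid, dres) if role == "donor" else (acid, ares)
            seen.add(key)
        for cid, resid in seen:
            counts[cid][resid] = counts[cid].get(resid, 0) + 1

    residues = sorted({int(r) for cid in chain_ids
                       for r in frames[0].chains[cid].resids})
    n = len(frames)
    data = {"residue": residues}
    for cid in chain_ids:
        data[f"occupancy_{cid}"] = [counts[cid].get(r, 0) / n for r in residues]
    occ_cols = [f"occupancy_{cid}" for cid in chain_ids]
    table = pd.DataFrame(data)
    table["occupancy_mean"] = table[occ_cols].mean(axis=1)
    return OccupancyProfile(table=table, n_frames=n, criterion=criterion,
                            role=role)
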