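"""Reduce coiled-coil frames to a polygonal axis ("skeleton").

Each trajectory frame is collapsed to an ordered list of nodes: weighted
centroids of the C-alpha atoms of sliding windows of (by default) 11
consecutive residues, with the first and last residue of each window given
half weight. With the default step of 10 residues, consecutive windows share
one boundary residue which then contributes a total weight of 1 across the
two windows. Arc-length coordinates ``s`` are cumulative Euclidean distances
along the polyline.
"""
from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .structures import Frame

logger = logging.getLogger(__name__)

__all__ = ["SkeletonFrame", "WindowingScheme", "window_centroid",
           "skeletonize_frame", "skeletonize_trajectory"]


@dataclass
class SkeletonFrame:
    """Polygonal axis of one frame: node coordinates (nm) and arc positions."""

    nodes: np.ndarray  # (n_nodes, 3), nm
    arc_s: np.ndarray  # (n_nodes,), nm, arc_s[0] = 0, strictly increasing
    frame_time: float = 0.0  # ps

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        self.arc_s = np.asarray(self.arc_s, dtype=float)
        if len(self.nodes) != len(self.arc_s):
            raise ValueError("nodes and arc_s must have equal length")
        if len(self.arc_s) and self.arc_s[0] != 0.0:
            raise ValueError("arc_s must start at 0")
        if np.any(np.diff(self.arc_s) <= 0):
            raise ValueError("arc_s must be strictly increasing")

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @classmethod
    def from_nodes(cls, nodes: np.ndarray, frame_time: float = 0.0) -> "SkeletonFrame":
        nodes = np.asarray(nodes, dtype=float)
        seg = np.linalg.norm(np.diff(nodes, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        return cls(nodes=nodes, arc_s=arc, frame_time=frame_time)


@dataclass
class WindowingScheme:
    """Sliding-window scheme for skeletonization.

    ``chain_mode`` selects whether one axis is built from the pooled C-alpha
    atoms of both chains (default) or per-chain axes are averaged.
    """

    window: int = 11
    step: int = 10
    end_weight: float = 0.5
    chain_mode: str = "pooled-both-chains"  # or "per-chain-averaged"

    def __post_init__(self):
        if self.window < 3:
            raise ValueError("window must be >= 3")
        if not (1 <= self.step <= self.window):
            raise ValueError("step must satisfy 1 <= step <= window")
        if not (0.0 < self.end_weight <= 1.0):
            raise ValueError("end_weight must be in (0, 1]")
        if self.chain_mode not in ("pooled-both-chains", "per-chain-averaged"):
            raise ValueError(f"unknown chain_mode {self.chain_mode!r}")

    @property
    def weights(self) -> np.ndarray:
        w = np.ones(self.window)
        w[0] = w[-1] = self.end_weight
        return w

    def n_nodes(self, n_residues: int) -> int:
        """Number of windows that fit; independent of coordinates."""
        if n_residues < self.window:
            return 0
        return (n_residues - self.window) // self.step + 1

    def n_dropped(self, n_residues: int) -> int:
        """Trailing residues not covered by any full window."""
        k = self.n_nodes(n_residues)
        if k == 0:
            return n_residues
        return n_residues - ((k - 1) * self.step + self.window)


def window_centroid(points: np.ndarray, end_weight: float = 0.5) -> np.ndarray:
    """Weighted centroid of one window of ordered points.

    Weights are (end_weight, 1, ..., 1, end_weight); the normalizer is
    ``len(points) - 2 + 2 * end_weight`` (10 for the defaults).
    """
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] != 3 or len(points) < 3:
        raise ValueError("expected an (n >= 3, 3) array of window points")
    w = np.ones(len(points))
    w[0] = w[-1] = end_weight
    return (w[:, None] * points).sum(axis=0) / w.sum()


def _chain_window_centroids(ca_list, scheme: WindowingScheme) -> np.ndarray:
    """Nodes from windows pooled over the given chains' C-alpha arrays."""
    n_res = len(ca_list[0])
    k = scheme.n_nodes(n_res)
    w = scheme.weights
    nodes = np.empty((k, 3))
    for i in range(k):
        lo = i * scheme.step
        sl = slice(lo, lo + scheme.window)
        num = np.zeros(3)
        for ca in ca_list:
            num += (w[:, None] * ca[sl]).sum(axis=0)
        nodes[i] = num / (w.sum() * len(ca_list))
    return nodes


def skeletonize_frame(chains, scheme: WindowingScheme | None = None,
                      frame_time: float = 0.0) -> SkeletonFrame:
    """Skeletonize one frame given per-chain C-alpha coordinates (nm).

    ``chains`` is a sequence of (n_res, 3) arrays (one per chain, equal
    lengths). In pooled mode each node is the weighted centroid over all
    chains' window atoms; in per-chain mode chain skeletons are averaged
    node-wise. Trailing residues that do not fill a window are dropped (the
    count is logged at DEBUG).
    """
    scheme = scheme or WindowingScheme()
    chains = [np.asarray(c, dtype=float) for c in chains]
    if not chains:
        raise ValueError("at least one chain required")
    n_res = len(chains[0])
    if any(len(c) != n_res for c in chains):
        raise ValueError("all chains must have equal residue counts")
    if n_res < scheme.window:
        raise ValueError(
            f"{n_res} residues < one window of {scheme.window}")
    dropped = scheme.n_dropped(n_res)
    if dropped:
        logger.debug("skeletonize_frame: %d trailing residues dropped", dropped)
    if scheme.chain_mode == "pooled-both-chains":
        nodes = _chain_window_centroids(chains, scheme)
    else:
        nodes = np.mean(
            [_chain_window_centroids([c], scheme) for c in chains], axis=0)
    if len(nodes) == 1:
        return SkeletonFrame(nodes=nodes, arc_s=np.zeros(1), frame_time=frame_time)
    return SkeletonFrame.from_nodes(nodes, frame_time=frame_time)


def skeletonize_trajectory(frames, scheme: WindowingScheme | None = None,
                           stride_ps: float = 100.0,
                           chain_ids=None) -> list:
    """Skeletonize a trajectory, retaining one snapshot per ``stride_ps``.

    ``frames`` is an iterable of :class:`~tpmflex.structures.Frame` (or of
    sequences of per-chain C-alpha arrays). Frames are retained when their
    time stamp advances by at least ``stride_ps`` since the last retained
    snapshot (time 0 is always retained); frames with missing C-alpha atoms
    are skipped with a warning.
    """
    scheme = scheme or WindowingScheme()
    skeletons = []
    next_t = None
    for i, fr in enumerate(frames):
        if isinstance(fr, Frame):
            t = fr.time_ps
            ids = chain_ids if chain_ids is not None else fr.chain_ids()
            try:
                cas = []
                for cid in ids:
                    ca = fr.chains[cid].coords["CA"]
                    if np.isnan(ca).any():
                        raise KeyError("CA has NaN entries")
                    cas.append(ca)
            except KeyError as exc:
                warnings.warn(f"frame {i}: missing C-alpha atoms ({exc}); skipped",
                              stacklevel=2)
                continue
        else:
            t = float(i)
            cas = fr
        if next_t is None or t >= next_t - 1e-9:
            skeletons.append(skeletonize_frame(cas, scheme, frame_time=t))
            next_t = t + (stride_ps if isinstance(fr, Frame) else 1.0)
    counts = {s.n_nodes for s in skeletons}
    if len(counts) > 1:
        raise ValueError(f"inconsistent node counts across frames: {sorted(counts)}")
    return skeletons
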