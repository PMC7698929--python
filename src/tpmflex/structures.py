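"""Lightweight in-memory containers for multi-frame backbone structures.

Coordinates are stored in nanometres throughout the package; file readers
convert from ångström on input (see :mod:`tpmflex.io`).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Backbone atom names the package knows about, in canonical order.
BACKBONE_ATOMS = ("N", "H", "CA", "C", "O")


@dataclass
class ChainAtoms:
    """Backbone coordinates for one chain of one frame.

    Parameters
    ----------
    resids : array of int
        Residue numbers, strictly increasing.
    coords : dict mapping atom name -> (n_res, 3) float array, nm
        Missing atoms (e.g. amide H before reconstruction) are simply
        absent from the dict or contain NaN rows.
    """

    resids: np.ndarray
    coords: dict = field(default_factory=dict)

    @property
    def n_residues(self) -> int:
        return len(self.resids)

    def has_atom(self, name: str) -> bool:
        return name in self.coords and not np.isnan(self.coords[name]).all()

    def copy(self) -> "ChainAtoms":
        return ChainAtoms(
            resids=self.resids.copy(),
            coords={k: v.copy() for k, v in self.coords.items()},
        )


@dataclass
class Frame:
    """One snapshot: a mapping of chain id -> :class:`ChainAtoms`."""

    chains: dict
    time_ps: float = 0.0

    def chain_ids(self):
        return list(self.chains)

    def ca_coords(self, chain_id: str) -> np.ndarray:
        return self.chains[chain_id].coords["CA"]

    def copy(self) -> "Frame":
        return Frame({k: v.copy() for k, v in self.chains.items()}, self.time_ps)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Frame":
        """Return a rigidly moved copy (x -> R x + t)."""
        out = self.copy()
        for chain in out.chains.values():
            for name, xyz in chain.coords.items():
                chain.coords[name] = xyz @ np.asarray(rotation).T + translation
        return out
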