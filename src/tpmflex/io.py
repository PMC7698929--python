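"""Readers and writers.

Multi-model PDB is the canonical interchange format for frame ensembles:
one MODEL per snapshot, chains A/B. PDB coordinates are in angstrom and are
converted to nm on read (and back on write); all curve tables are 2-column
CSV with a header row. JSON reports are schema-versioned and embed the seed
and a hash of the configuration for provenance.
"""
from __future__ import annotations

import hashlib
import json
from pathlib import Path

import biotite.structure as struc
import numpy as np
import pandas as pd
from biotite.structure.io.pdb import PDBFile

from .structures import BACKBONE_ATOMS, ChainAtoms, Frame

__all__ = ["read_structure_ensemble", "write_structure_ensemble",
           "read_curve", "write_curve", "write_report", "SCHEMA_VERSION"]

SCHEMA_VERSION = "1.0"
A_PER_NM = 10.0


def read_structure_ensemble(path, chains=None, dt_ps: float = 100.0):
    """Read a multi-model PDB into a list of :class:`Frame` (coords in nm).

    ``chains`` optionally restricts/orders the chains; a requested chain
    absent from the file is an error. Frames are time-stamped 0, dt_ps,
    2*dt_ps, ... in file order. Backbone atoms (N, H, CA, C, O) are kept;
    atoms missing from a residue are NaN.
    """
    path = Path(path)
    pdb = PDBFile.read(str(path))
    stack = pdb.get_structure(model=None)
    if stack.array_length() == 0:
        raise ValueError(f"{path}: no atoms")
    present = sorted(set(stack.chain_id))
    if chains is None:
        chains = present
    else:
        for cid in chains:
            if cid not in present:
                raise ValueError(
                    f"{path}: chain {cid!r} not present (found {present})")
    frames = []
    for m in range(stack.stack_depth()):
        model = stack[m]
        chain_map = {}
        for cid in chains:
            sel = model[model.chain_id == cid]
            resids = np.unique(sel.res_id)
            coords = {}
            for name in BACKBONE_ATOMS:
                xyz = np.full((len(resids), 3), np.nan)
                atom_sel = sel[sel.atom_name == name]
                idx = np.searchsorted(resids, atom_sel.res_id)
                xyz[idx] = atom_sel.coord / A_PER_NM
                if not np.isnan(xyz).all():
                    coords[name] = xyz
            chain_map[cid] = ChainAtoms(resids=resids.astype(int), coords=coords)
        frames.append(Frame(chains=chain_map, time_ps=m * dt_ps))
    counts = {tuple((cid, c.n_residues) for cid, c in f.chains.items())
              for f in frames}
    if len(counts) > 1:
        raise ValueError(f"{path}: inconsistent atom counts across models")
    return frames


def _frame_to_atom_array(frame: Frame) -> struc.AtomArray:
    rows = []
    for cid, chain in frame.chains.items():
        for i, resid in enumerate(chain.resids):
            for name in BACKBONE_ATOMS:
                if name in chain.coords and not np.isnan(chain.coords[name][i]).any():
                    rows.append((cid, int(resid), name, chain.coords[name][i]))
    arr = struc.AtomArray(len(rows))
    arr.chain_id = np.array([r[0] for r in rows])
    arr.res_id = np.array([r[1] for r in rows])
    arr.res_name = np.full(len(rows), "ALA")  # placeholder residue type
    arr.atom_name = np.array([r[2] for r in rows])
    arr.element = np.array([r[2][0] for r in rows])
    arr.coord = np.array([r[3] for r in rows]) * A_PER_NM
    arr.hetero = np.zeros(len(rows), dtype=bool)
    return arr


def write_structure_ensemble(frames, path) -> None:
    """Write frames as a multi-model PDB (one MODEL per frame), coords in A."""
    arrays = [_frame_to_atom_array(f) for f in frames]
    stack = struc.stack(arrays)
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def read_curve(path) -> pd.DataFrame:
    """Read a 2+-column CSV curve (comma separated, header row, '.' decimal)."""
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected at least two columns")
    return df


def write_curve(df: pd.DataFrame, path) -> None:
    """Write a curve table as CSV (full float precision, reproducible)."""
    df.to_csv(path, index=False)


def _config_hash(config) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if hasattr(obj, "to_dict"):
        return obj.to_dict()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_report(results: dict, path, seed=None, config=None,
                 warnings_list=None) -> dict:
    """Write a schema-versioned JSON report embedding seed and config hash.

    Returns the report dict that was written.
    """
    config = config if config is not None else {}
    report = {
        "schema_version": SCHEMA_VERSION,
        "seed": seed,
        "config": config,
        "config_hash": _config_hash({"seed": seed, **config}),
        "warnings": warnings_list or [],
        "results": results,
    }
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, default=_jsonable)
        fh.write("\n")
    return report
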