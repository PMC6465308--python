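"""PDB reading and writing (biotite-backed).

Structures are exposed as :class:`~tpshoot.frames.Frame` objects plus a
pandas table of per-atom metadata (chain, residue, atom name) that drives
selection patterns.  Multi-model files map to one frame per model.

Fixture frames are written with one chain per component: dimerization
domain CA pseudo-atoms (chain A), transporter domain CA (chain B), the
probe atom (chain P, an aspartate OD1 stand-in) and water oxygens
(chain W, resname HOH).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import biotite.structure as struc
import biotite.structure.io.pdb as pdb

from ..errors import ValidationError
from ..frames import AtomSelection, Frame
from ..synthetic.fixtures import FixtureResult


def read_structure(path) -> tuple[list[Frame], pd.DataFrame]:
    """Read a (possibly multi-model) PDB file.

    Returns one Frame per model and a per-atom metadata table with columns
    chain_id, res_id, res_name, atom_name, element and the 0-based index.
    """
    path = Path(path)
    try:
        pdb_file = pdb.PDBFile.read(str(path))
        stack = pdb_file.get_structure(model=None)
    except Exception as exc:  # biotite raises various parse errors
        raise ValidationError(f"cannot parse PDB file {path}: {exc}") from exc
    if stack.array_length() == 0:
        raise ValidationError(f"PDB file {path} contains no atoms")
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    box = None
    if stack.box is not None:
        lengths = np.diagonal(stack.box[0])
        if np.all(lengths > 0):
            box = lengths.copy()
    frames = [
        Frame(coordinates=np.asarray(stack.coord[i], dtype=float), box=box, time=float(i))
        for i in range(stack.stack_depth())
    ]
    meta = pd.DataFrame(
        {
            "index": np.arange(stack.array_length()),
            "chain_id": stack.chain_id,
            "res_id": stack.res_id,
            "res_name": stack.res_name,
            "atom_name": stack.atom_name,
            "element": stack.element,
        }
    )
    return frames, meta


def select(meta: pd.DataFrame, name: str, **patterns) -> AtomSelection:
    """Build an AtomSelection from metadata column filters, e.g.
    ``select(meta, 'waters', chain_id='W', atom_name='O')``.  Values may be
    scalars or lists."""
    mask = np.ones(len(meta), dtype=bool)
    for col, value in patterns.items():
        if col not in meta.columns:
            raise ValidationError(f"unknown metadata column {col!r}")
        values = value if isinstance(value, (list, tuple, set)) else [value]
        mask &= meta[col].isin(list(values)).to_numpy()
    return AtomSelection(name, meta.loc[mask, "index"].to_numpy())


def _atom_array(frame: Frame, meta: pd.DataFrame) -> struc.AtomArray:
    n = frame.n_atoms
    if len(meta) != n:
        raise ValidationError("metadata length does not match frame size")
    arr = struc.AtomArray(n)
    arr.coord = frame.coordinates.astype(np.float32)
    arr.chain_id = meta["chain_id"].to_numpy(dtype="U4")
    arr.res_id = meta["res_id"].to_numpy(dtype=int)
    arr.res_name = meta["res_name"].to_numpy(dtype="U5")
    arr.atom_name = meta["atom_name"].to_numpy(dtype="U6")
    arr.element = meta["element"].to_numpy(dtype="U2")
    arr.hetero = np.asarray(meta["res_name"].isin(["HOH"]), dtype=bool)
    if frame.box is not None:
        arr.box = np.diag(frame.box).astype(np.float32)
    return arr


def write_structure(path, frames: Frame | list[Frame], meta: pd.DataFrame) -> None:
    """Write one or more frames as a (multi-model) PDB file."""
    if isinstance(frames, Frame):
        frames = [frames]
    if not frames:
        raise ValidationError("no frames to write")
    arrays = [_atom_array(f, meta) for f in frames]
    stack = struc.stack(arrays) if len(arrays) > 1 else arrays[0]
    pdb_file = pdb.PDBFile()
    pdb_file.set_structure(stack)
    pdb.PDBFile.write(pdb_file, str(path))


def fixture_metadata(fixture: FixtureResult) -> pd.DataFrame:
    """Per-atom metadata for a synthetic fixture frame."""
    sel = fixture.selections
    n = fixture.frame.n_atoms
    chain = np.empty(n, dtype="U4")
    res_name = np.empty(n, dtype="U5")
    atom_name = np.empty(n, dtype="U6")
    element = np.empty(n, dtype="U2")
    for key, ch, rn, an, el in (
        ("dimer", "A", "GLY", "CA", "C"),
        ("transporter", "B", "GLY", "CA", "C"),
        ("probe", "P", "ASP", "OD1", "O"),
        ("waters", "W", "HOH", "O", "O"),
    ):
        idx = sel[key].indices
        chain[idx] = ch
        res_name[idx] = rn
        atom_name[idx] = an
        element[idx] = el
    res_id = np.zeros(n, dtype=int)
    for key in ("dimer", "transporter", "probe", "waters"):
        idx = sel[key].indices
        res_id[idx] = np.arange(1, idx.size + 1)
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "chain_id": chain,
            "res_id": res_id,
            "res_name": res_name,
            "atom_name": atom_name,
            "element": element,
        }
    )


def write_fixture(path, fixture: FixtureResult, reference_path=None) -> None:
    """Write a fixture frame (and optionally its inward reference) as PDB."""
    meta = fixture_metadata(fixture)
    write_structure(path, fixture.frame, meta)
    if reference_path is not None:
        write_structure(reference_path, fixture.ref_in, meta)
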