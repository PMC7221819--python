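"""Shared fixtures: residue builders, PDB-line formatter, rigid motions."""

import numpy as np
import pytest

from bsmm import PCPoint, PCSite, Residue, TypingTable
from bsmm.io_structures import AtomRecord


@pytest.fixture(scope="session")
def default_table():
    return TypingTable.default()


def make_residue(name, atoms, chain="A", resnum=1, icode=""):
    """Build a Residue from {atom_name: (x, y, z)} with inferred elements."""
    rid = (chain, resnum, icode)
    res = Residue(name=name, residue_id=rid)
    for atom_name, pos in atoms.items():
        element = atom_name[0] if atom_name[0] in "CNOS" else "C"
        res.atoms.append(AtomRecord(name=atom_name, element=element,
                                    pos=tuple(float(v) for v in pos),
                                    residue_name=name, residue_id=rid))
    return res


def pdb_line(record, serial, name, resname, chain, resnum, pos, element,
             altloc=" ", occ=1.0):
    """Independent wwPDB v3.3 ATOM/HETATM formatter for fixtures."""
    x, y, z = pos
    name_field = f" {name:<3}" if len(name) < 4 else name[:4]
    return (f"{record:<6}{serial:>5} {name_field}{altloc}{resname:>3} "
            f"{chain}{resnum:>4}    {x:8.3f}{y:8.3f}{z:8.3f}"
            f"{occ:6.2f}{0.0:6.2f}          {element:>2}")


def random_rotation(rng):
    """Uniform proper rotation from a random quaternion."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])


def point(pos, ptype, resnum=1, name="UNK", source="fx"):
    return PCPoint(pos=np.asarray(pos, dtype=float), ptype=ptype,
                   residue_id=("A", resnum, ""), residue_name=name,
                   source=source)


def site_from(coords, ptypes, site_id="fixture"):
    pts = [point(c, t, resnum=i + 1) for i, (c, t) in
           enumerate(zip(coords, ptypes))]
    return PCSite(site_id=site_id, points=pts)
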