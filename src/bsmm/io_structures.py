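"""Structure input/output: PDB reading, ligand selection, match-report writers.

A protein–ligand complex is read into a flat heavy-atom model
(:class:`ComplexRecord`).  Hydrogens and deuteriums never survive parsing;
alternate conformations are resolved to the highest-occupancy atom (ties go
to altloc ``A``).  Only the first MODEL of multi-model files is used.

The report writers emit a versioned JSON document, a CSV pair table and a
PDB-format pseudo-atom file of the matched ("similar") site for visual
inspection in a molecular viewer.
"""

from __future__ import annotations

import csv
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np

from .errors import AmbiguousLigandError, LigandNotFoundError, ParseError

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = "bsmm-report-1"

#: residue names treated as water and never selectable as a ligand
WATER_NAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass(frozen=True)
class AtomRecord:
    """One heavy atom of a parsed structure."""

    name: str
    element: str
    pos: tuple  # (x, y, z) in Angstrom
    residue_name: str
    residue_id: tuple  # (chain id, residue number, insertion code)
    is_hetero: bool = False

    @property
    def xyz(self) -> np.ndarray:
        return np.asarray(self.pos, dtype=float)


@dataclass
class Residue:
    """A group of atoms sharing one residue identity."""

    name: str
    residue_id: tuple
    atoms: list = field(default_factory=list)

    def atom(self, name: str) -> Optional[AtomRecord]:
        for a in self.atoms:
            if a.name == name:
                return a
        return None

    def coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.atoms], dtype=float)


@dataclass
class ComplexRecord:
    """A parsed complex: protein heavy atoms plus the selected ligand."""

    structure_id: str
    protein_atoms: list
    ligand_atoms: list
    ligand_code: str

    def ligand_coords(self) -> np.ndarray:
        return np.array([a.pos for a in self.ligand_atoms], dtype=float)


def group_residues(atoms: Sequence[AtomRecord]) -> list:
    """Group a flat atom list into residues, preserving first-seen order."""
    out: dict = {}
    for a in atoms:
        key = (a.residue_id, a.residue_name)
        if key not in out:
            out[key] = Residue(name=a.residue_name, residue_id=a.residue_id)
        out[key].atoms.append(a)
    return list(out.values())


def _resolve_altlocs(residue: gemmi.Residue) -> list:
    """Pick one atom per name: highest occupancy, ties broken toward altloc 'A'."""
    by_name: dict = {}
    for atom in residue:
        by_name.setdefault(atom.name, []).append(atom)
    chosen = []
    for name, group in by_name.items():
        if len(group) == 1:
            chosen.append(group[0])
        else:
            group = sorted(group, key=lambda a: (-a.occ, a.altloc or "A"))
            chosen.append(group[0])
    return chosen


def _is_hydrogen(atom: gemmi.Atom) -> bool:
    return atom.element.name in ("H", "D")


def read_complex(path, ligand_selector) -> ComplexRecord:
    """Read a PDB file and select the bound ligand.

    Parameters
    ----------
    path
        PDB file (wwPDB v3.3 columns). Only the first MODEL is read.
    ligand_selector
        ``(code,)``, ``(code, chain)`` or ``(code, chain, resnum)``.
        ``chain``/``resnum`` may be None.  When chain/resnum are omitted the
        code must identify exactly one HET group; otherwise an
        :class:`AmbiguousLigandError` lists the candidates.

    Returns
    -------
    ComplexRecord
        Heavy-atom protein model plus the ligand's heavy atoms.
    """
    path = Path(path)
    code, chain_sel, resnum_sel = _normalize_selector(ligand_selector)
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise ParseError(f"cannot parse {path}: {exc}") from exc
    if len(st) == 0:
        raise ParseError(f"{path} contains no models")
    model = st[0]

    protein_atoms: list = []
    het_groups: list = []  # (chain, resnum, icode, residue)
    for chain in model:
        for residue in chain:
            rid = (chain.name, residue.seqid.num, residue.seqid.icode.strip())
            is_het = residue.het_flag == "H"
            if is_het:
                if residue.name in WATER_NAMES:
                    continue
                if residue.name == code:
                    het_groups.append((chain.name, residue.seqid.num,
                                       residue.seqid.icode.strip(), residue))
                continue
            for atom in _resolve_altlocs(residue):
                if _is_hydrogen(atom):
                    continue
                protein_atoms.append(AtomRecord(
                    name=atom.name,
                    element=atom.element.name,
                    pos=(atom.pos.x, atom.pos.y, atom.pos.z),
                    residue_name=residue.name,
                    residue_id=rid,
                    is_hetero=False,
                ))

    candidates = [g for g in het_groups
                  if (chain_sel is None or g[0] == chain_sel)
                  and (resnum_sel is None or g[1] == resnum_sel)]
    if not candidates:
        raise LigandNotFoundError(
            f"ligand not found: no HET group {code!r} "
            f"(chain={chain_sel}, resnum={resnum_sel}) in {path.name}")
    if len(candidates) > 1:
        raise AmbiguousLigandError(code, [(c[0], c[1], c[2]) for c in candidates])

    lig_chain, lig_num, lig_icode, lig_res = candidates[0]
    ligand_atoms = []
    for atom in _resolve_altlocs(lig_res):
        if _is_hydrogen(atom):
            continue
        ligand_atoms.append(AtomRecord(
            name=atom.name,
            element=atom.element.name,
            pos=(atom.pos.x, atom.pos.y, atom.pos.z),
            residue_name=lig_res.name,
            residue_id=(lig_chain, lig_num, lig_icode),
            is_hetero=True,
        ))
    if not ligand_atoms:
        raise LigandNotFoundError(f"ligand {code!r} has no heavy atoms")

    return ComplexRecord(
        structure_id=st.name or path.stem,
        protein_atoms=protein_atoms,
        ligand_atoms=ligand_atoms,
        ligand_code=code,
    )


def _normalize_selector(sel):
    if isinstance(sel, str):
        parts = sel.split(":")
        sel = tuple(parts)
    sel = tuple(sel) + (None,) * (3 - len(sel))
    code, chain, resnum = sel[:3]
    if not code:
        raise ValueError("ligand selector needs a chemical-component code")
    if chain in ("", None):
        chain = None
    if resnum in ("", None):
        resnum = None
    else:
        resnum = int(resnum)
    return str(code).upper(), chain, resnum


# ---------------------------------------------------------------------------
# report writers


def _pair_records(result) -> list:
    recs = []
    ref_site, qry_site = result.ref_site, result.qry_site
    for ref_idx, qry_idx, dist in result.pairs:
        rp = ref_site.points[ref_idx]
        qp = qry_site.points[qry_idx]
        recs.append({
            "ref_index": int(ref_idx),
            "ref_residue": list(rp.residue_id),
            "ref_residue_name": rp.residue_name,
            "ref_ptype": str(rp.ptype.value),
            "qry_index": int(qry_idx),
            "qry_residue": list(qp.residue_id),
            "qry_residue_name": qp.residue_name,
            "qry_ptype": str(qp.ptype.value),
            "distance": round(float(dist), 6),
        })
    return recs


def write_match_report(result, out_dir, ref: ComplexRecord | None = None,
                       qry: ComplexRecord | None = None,
                       timestamp: str | None = None) -> dict:
    """Write JSON report, CSV pair table and pseudo-atom PDB of the similar site.

    Returns a dict of the paths written.  The pseudo-atom file is omitted for
    an empty match.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    pairs = _pair_records(result)
    doc = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "ref_site_id": result.ref_site_id,
        "qry_site_id": result.qry_site_id,
        "ref_structure": ref.structure_id if ref else None,
        "qry_structure": qry.structure_id if qry else None,
        "votes": int(result.votes),
        "match_num": int(result.match_num),
        "r_p_num": int(result.r_p_num),
        "q_p_num": int(result.q_p_num),
        "mscore": float(result.mscore),
        "l_match_num": int(result.l_match_num),
        "lr_p_num": int(result.lr_p_num),
        "lq_p_num": int(result.lq_p_num),
        "lscore": float(result.lscore),
        "rmsd": None if result.rmsd is None else float(result.rmsd),
        "transform": None if result.rotation is None else {
            "rotation": np.asarray(result.rotation).tolist(),
            "translation": np.asarray(result.translation).tolist(),
        },
        "pairs": pairs,
    }
    if timestamp is not None:
        doc["created"] = timestamp

    json_path = out_dir / "match_report.json"
    json_path.write_text(json.dumps(doc, indent=1) + "\n")

    csv_path = out_dir / "match_pairs.csv"
    fieldnames = ["ref_index", "ref_residue", "ref_residue_name", "ref_ptype",
                  "qry_index", "qry_residue", "qry_residue_name", "qry_ptype",
                  "distance"]
    with open(csv_path, "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=fieldnames)
        writer.writeheader()
        for rec in pairs:
            row = dict(rec)
            row["ref_residue"] = ":".join(str(x) for x in rec["ref_residue"])
            row["qry_residue"] = ":".join(str(x) for x in rec["qry_residue"])
            writer.writerow(row)

    written = {"json": json_path, "csv": csv_path}
    if pairs:
        pdb_path = out_dir / "similar_site.pdb"
        pdb_path.write_text(_pseudo_atom_pdb(result))
        written["pseudo_pdb"] = pdb_path
    return written


def _pseudo_atom_pdb(result) -> str:
    """One HETATM per matched reference PC point; property encoded in resname."""
    lines = []
    for serial, (ref_idx, _qry_idx, _d) in enumerate(result.pairs, start=1):
        p = result.ref_site.points[ref_idx]
        x, y, z = np.asarray(p.pos, dtype=float)
        resname = str(p.ptype.value)[:3]
        lines.append(
            f"HETATM{serial:>5}  PC  {resname:>3} P{serial:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{'C':>2}"
        )
    lines.append("END")
    return "\n".join(lines) + "\n"


def read_match_report(path) -> dict:
    """Load a JSON match report written by :func:`write_match_report`."""
    doc = json.loads(Path(path).read_text())
    if doc.get("schema_version") != REPORT_SCHEMA_VERSION:
        raise ParseError(f"unknown report schema: {doc.get('schema_version')!r}")
    return doc
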