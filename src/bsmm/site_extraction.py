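"""Binding-site and PC-site extraction relative to the bound ligand.

The binding site is the set of protein residues having at least one heavy
atom within a distance cutoff (default 6.0 Å, inclusive) of any ligand heavy
atom.  The PC-site is the set of physicochemical points generated from those
residues whose *point position* also lies within the cutoff of the ligand.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist

from .errors import EmptySiteError, SiteTooSmallError
from .io_structures import ComplexRecord, group_residues
from .pc_typing import PCPoint, PCType, TypingTable, assign_pc_points

logger = logging.getLogger(__name__)

DEFAULT_CUTOFF = 6.0
MIN_HASHABLE_POINTS = 3

SITE_SCHEMA_VERSION = "bsmm-site-1"


@dataclass
class PCSite:
    """A labeled point cloud: the matching currency of the whole pipeline."""

    site_id: str
    points: list
    cutoff_used: Optional[float] = None
    source_id: Optional[str] = None

    @property
    def n_points(self) -> int:
        return len(self.points)

    def coords(self) -> np.ndarray:
        return np.array([p.pos for p in self.points], dtype=float).reshape(-1, 3)

    def ptypes(self) -> list:
        return [p.ptype for p in self.points]

    def transformed(self, rotation, translation, site_id=None) -> "PCSite":
        """Return a rigidly moved copy (labels and provenance preserved)."""
        return PCSite(
            site_id=site_id or self.site_id,
            points=[p.moved(rotation, translation) for p in self.points],
            cutoff_used=self.cutoff_used,
            source_id=self.source_id,
        )

    # -- serialization ------------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "schema_version": SITE_SCHEMA_VERSION,
            "site_id": self.site_id,
            "cutoff_used": self.cutoff_used,
            "source_id": self.source_id,
            "points": [
                {
                    "pos": [float(x) for x in p.pos],
                    "ptype": p.ptype.value,
                    "residue_id": list(p.residue_id),
                    "residue_name": p.residue_name,
                    "source": p.source,
                }
                for p in self.points
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCSite":
        points = [
            PCPoint(pos=np.array(rec["pos"], dtype=float),
                    ptype=PCType(rec["ptype"]),
                    residue_id=tuple(rec["residue_id"]),
                    residue_name=rec.get("residue_name", "UNK"),
                    source=rec.get("source", ""))
            for rec in d["points"]
        ]
        return cls(site_id=d["site_id"], points=points,
                   cutoff_used=d.get("cutoff_used"),
                   source_id=d.get("source_id"))

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def load(cls, path) -> "PCSite":
        return cls.from_dict(json.loads(Path(path).read_text()))


def extract_binding_site(cplx: ComplexRecord, cutoff: float = DEFAULT_CUTOFF) -> list:
    """Residues with any heavy atom within ``cutoff`` (inclusive) of the ligand."""
    ligand = cplx.ligand_coords()
    residues = group_residues(cplx.protein_atoms)
    selected = []
    for res in residues:
        d = cdist(res.coords(), ligand)
        if d.min() <= cutoff:
            selected.append(res)
    if not selected:
        raise EmptySiteError(
            f"no residues within {cutoff} A of ligand {cplx.ligand_code} "
            f"in {cplx.structure_id}")
    return selected


def build_pc_site(cplx: ComplexRecord, table: TypingTable | None = None,
                  cutoff: float = DEFAULT_CUTOFF, site_id: str | None = None) -> PCSite:
    """Extract the binding site, type it, and keep points near the ligand.

    A point survives iff its own position is within ``cutoff`` (inclusive)
    of any ligand heavy atom; group pseudocenters are filtered by their
    centroid position, not by their contributing atoms.
    """
    residues = extract_binding_site(cplx, cutoff=cutoff)
    all_points = assign_pc_points(residues, table)
    ligand = cplx.ligand_coords()
    kept = []
    for p in all_points:
        if cdist(p.pos.reshape(1, 3), ligand).min() <= cutoff:
            kept.append(p)
    if len(kept) < MIN_HASHABLE_POINTS:
        raise SiteTooSmallError(
            f"site too small to hash: {len(kept)} PC points survive the "
            f"{cutoff} A filter for {cplx.structure_id}/{cplx.ligand_code}")
    sid = site_id or f"{cplx.structure_id}:{cplx.ligand_code}"
    logger.info("PC-site %s: %d residues -> %d points (cutoff %.1f A)",
                sid, len(residues), len(kept), cutoff)
    return PCSite(site_id=sid, points=kept, cutoff_used=cutoff,
                  source_id=cplx.structure_id)
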