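"""Physicochemical typing: residues -> labeled pseudocenter points.

Binding-site residues are abstracted into five point classes:

* ``HA``  — hydrogen-bond acceptor (e.g. Asp OD1/OD2, backbone O)
* ``HD``  — hydrogen-bond donor (e.g. Lys NZ, backbone N)
* ``HAD`` — mixed acceptor/donor (e.g. Ser OG, His ring nitrogens)
* ``ALI`` — aliphatic hydrophobic group, one point per contiguous
  side-chain carbon group at its centroid
* ``ARO`` — aromatic ring, one point at the ring centroid

The mapping is a configurable, versioned :class:`TypingTable` shipped as a
YAML file; users may supply an alternative table to test other conventions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from enum import Enum
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

logger = logging.getLogger(__name__)


class PCType(str, Enum):
    """Closed five-member vocabulary of physicochemical point labels."""

    HA = "HA"
    HD = "HD"
    HAD = "HAD"
    ALI = "ALI"
    ARO = "ARO"


#: deterministic rank used for tie-breaking in canonical triangle ordering
PTYPE_RANK = {PCType.HA: 0, PCType.HD: 1, PCType.HAD: 2,
              PCType.ALI: 3, PCType.ARO: 4}


@dataclass
class PCPoint:
    """A labeled 3-D point with provenance."""

    pos: np.ndarray
    ptype: PCType
    residue_id: tuple = ("", 0, "")
    residue_name: str = "UNK"
    source: str = ""

    def __post_init__(self):
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError("PCPoint position must be a finite 3-vector")
        self.ptype = PCType(self.ptype)

    def moved(self, rotation: np.ndarray, translation: np.ndarray) -> "PCPoint":
        return PCPoint(pos=np.asarray(rotation) @ self.pos + np.asarray(translation),
                       ptype=self.ptype, residue_id=self.residue_id,
                       residue_name=self.residue_name, source=self.source)


@dataclass
class TypingTable:
    """Residue/atom -> PC type mapping, loadable from a YAML config."""

    version: str
    backbone: dict
    backbone_no_donor: list
    residues: dict

    @classmethod
    def default(cls) -> "TypingTable":
        with resources.files("bsmm.data").joinpath("typing_default.yaml").open() as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_file(cls, path) -> "TypingTable":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def from_dict(cls, d: dict) -> "TypingTable":
        return cls(
            version=str(d["version"]),
            backbone={str(k): str(v) for k, v in (d.get("backbone") or {}).items()},
            backbone_no_donor=[str(x) for x in (d.get("backbone_no_donor") or [])],
            residues={str(k): (v or {}) for k, v in (d.get("residues") or {}).items()},
        )

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "backbone": dict(self.backbone),
            "backbone_no_donor": list(self.backbone_no_donor),
            "residues": {k: dict(v) for k, v in self.residues.items()},
        }

    def to_file(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def knows(self, residue_name: str) -> bool:
        return residue_name in self.residues


#: maximum pseudocenter-to-contributing-atom distance (sanity bound)
MAX_CENTROID_SPREAD = 3.0


def _centroid_point(residue, group: Sequence[str], ptype: PCType) -> Optional[PCPoint]:
    """Pseudocenter at the centroid of the group atoms that are present."""
    atoms = [residue.atom(n) for n in group]
    atoms = [a for a in atoms if a is not None]
    if not atoms:
        return None
    if len(atoms) < len(group):
        logger.debug("residue %s %s: %d/%d atoms for %s group",
                     residue.name, residue.residue_id, len(atoms), len(group),
                     ptype.value)
    coords = np.array([a.pos for a in atoms], dtype=float)
    centroid = coords.mean(axis=0)
    spread = np.linalg.norm(coords - centroid, axis=1).max()
    if spread > MAX_CENTROID_SPREAD:
        logger.warning("residue %s %s: %s pseudocenter spread %.2f A exceeds %.1f A",
                       residue.name, residue.residue_id, ptype.value, spread,
                       MAX_CENTROID_SPREAD)
    source = "centroid(" + "+".join(a.name for a in atoms) + ")"
    return PCPoint(pos=centroid, ptype=ptype, residue_id=residue.residue_id,
                   residue_name=residue.name, source=source)


def assign_pc_points(residues: Sequence, table: TypingTable | None = None) -> list:
    """Convert residues (heavy atoms) into a deterministic list of PC points.

    Unknown residue names are skipped with a logged warning.  Missing
    side-chain atoms are tolerated: a group pseudocenter is emitted from the
    atoms actually present.
    """
    if table is None:
        table = TypingTable.default()
    points: list = []
    for residue in residues:
        known = table.knows(residue.name)
        if not known:
            logger.warning("unknown residue %r at %s: skipped by typing table %s",
                           residue.name, residue.residue_id, table.version)
            continue
        # backbone
        for atom_name, label in table.backbone.items():
            if label == "HD" and residue.name in table.backbone_no_donor:
                continue
            atom = residue.atom(atom_name)
            if atom is not None:
                points.append(PCPoint(pos=atom.xyz, ptype=PCType(label),
                                      residue_id=residue.residue_id,
                                      residue_name=residue.name,
                                      source=atom.name))
        entry = table.residues[residue.name]
        for key, ptype in (("ha", PCType.HA), ("hd", PCType.HD),
                           ("had", PCType.HAD)):
            for atom_name in entry.get(key, []):
                atom = residue.atom(atom_name)
                if atom is not None:
                    points.append(PCPoint(pos=atom.xyz, ptype=ptype,
                                          residue_id=residue.residue_id,
                                          residue_name=residue.name,
                                          source=atom.name))
        for key, ptype in (("aro", PCType.ARO), ("ali", PCType.ALI)):
            for group in entry.get(key, []):
                pt = _centroid_point(residue, group, ptype)
                if pt is not None:
                    points.append(pt)
    return points
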