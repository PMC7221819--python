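"""Synthetic PC-sites and complexes with known ground truth.

The generator emulates the geometry of real PC-sites — a few dozen labeled
points spread over a pocket-sized box with a physical minimum separation —
without pretending to be protein structure.  Defaults: 20 points in a 15 Å
box with 2.0 Å minimum separation and a uniform label distribution, roughly
the size and density of a ligand-binding pocket's pseudocenter set.

`make_pair` produces a matched site pair under a known rigid motion with
optional Gaussian jitter and label-preserving partial overlap; decoy points
are kept at least ``decoy_clearance`` away from every true point so exact
tests have clean ground truth.  `make_complex` realizes a site as a minimal
but syntactically valid PDB file (one single-atom residue per point plus a
central HET ligand), which lets every file-based stage run end-to-end
without any real structure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

from .errors import BsmmError
from .pc_typing import PCPoint, PCType
from .site_extraction import PCSite

#: single-atom residue realization for each PC type: (resname, atom, element)
_TYPE_REALIZATION = {
    PCType.HA: ("ASP", "OD1", "O"),
    PCType.HD: ("LYS", "NZ", "N"),
    PCType.HAD: ("SER", "OG", "O"),
    PCType.ALI: ("LEU", "CD1", "C"),
    PCType.ARO: ("PHE", "CG", "C"),
}

_TYPES = (PCType.HA, PCType.HD, PCType.HAD, PCType.ALI, PCType.ARO)


@dataclass
class SyntheticSpec:
    """Parameters of one synthetic PC-site."""

    n_points: int = 20
    extent: float = 15.0          # box edge, Angstrom
    min_separation: float = 2.0   # hard pairwise floor, Angstrom
    label_weights: Optional[dict] = None  # PCType -> weight; uniform if None
    jitter_sigma: float = 0.0     # per-coordinate Gaussian noise, Angstrom
    overlap_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_points < 3:
            raise ValueError("need at least 3 points")
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if not 0.0 <= self.overlap_fraction <= 1.0:
            raise ValueError("overlap_fraction must lie in [0, 1]")


def _place_points(rng, n, extent, min_sep, avoid=None, avoid_dist=0.0,
                  max_tries_per_point=2000):
    """Rejection-sample n points in [0, extent]^3 with a pairwise floor."""
    placed: list = []
    tries = 0
    limit = max_tries_per_point * n
    while len(placed) < n:
        if tries > limit:
            raise BsmmError(
                f"could not place {n} points with separation {min_sep} A "
                f"in a {extent} A box after {limit} draws: spec too dense")
        tries += 1
        cand = rng.uniform(0.0, extent, size=3)
        if placed and cdist(cand[None], np.array(placed)).min() < min_sep:
            continue
        if avoid is not None and len(avoid) and \
                cdist(cand[None], avoid).min() < avoid_dist:
            continue
        placed.append(cand)
    return np.array(placed)


def _draw_labels(rng, n, label_weights):
    if label_weights is None:
        probs = np.full(len(_TYPES), 1.0 / len(_TYPES))
    else:
        probs = np.array([float(label_weights.get(t, 0.0)) for t in _TYPES])
        if probs.sum() <= 0:
            raise ValueError("label weights must have positive total")
        probs = probs / probs.sum()
    return [_TYPES[i] for i in rng.choice(len(_TYPES), size=n, p=probs)]


def _make_points(coords, labels, tag="synthetic"):
    pts = []
    for i, (pos, label) in enumerate(zip(coords, labels)):
        resname = _TYPE_REALIZATION[label][0]
        pts.append(PCPoint(pos=pos, ptype=label,
                           residue_id=("A", i + 1, ""),
                           residue_name=resname, source=tag))
    return pts


def make_site(spec: SyntheticSpec, site_id: str | None = None) -> PCSite:
    """Deterministic labeled point cloud per the spec's seed."""
    rng = np.random.default_rng(spec.seed)
    coords = _place_points(rng, spec.n_points, spec.extent,
                           spec.min_separation)
    labels = _draw_labels(rng, spec.n_points, spec.label_weights)
    return PCSite(site_id=site_id or f"synthetic-{spec.seed}",
                  points=_make_points(coords, labels),
                  cutoff_used=None, source_id="synthetic")


def random_rigid_motion(rng):
    """A uniformly random proper rotation plus a translation in [-20, 20]^3."""
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)],
    ])
    t = rng.uniform(-20.0, 20.0, size=3)
    return R, t


@dataclass
class PairGroundTruth:
    """What `make_pair` knows: the rigid motion A→B and the correspondence."""

    rotation: np.ndarray      # maps site A coords into site B coords
    translation: np.ndarray
    correspondence: list      # (index in A, index in B) for shared points

    def inverse(self):
        """The B→A motion (what matching with ref=A, qry=B must recover)."""
        Rinv = self.rotation.T
        return Rinv, -(Rinv @ self.translation)


#: decoys stay at least this far from every transformed true point, so that
#: with the default 3.0 A extension cutoff they can never absorb a true match
DECOY_CLEARANCE = 3.5


def make_pair(spec: SyntheticSpec, transform_seed: int = 0):
    """Site A plus a rigidly moved, jittered, partially overlapping copy B.

    Returns ``(site_a, site_b, ground_truth)``.  B carries
    ``round(overlap_fraction * n)`` moved copies of A's points (labels
    preserved) and decoys for the remainder; B's point order is shuffled.
    """
    site_a = make_site(spec, site_id=f"synthA-{spec.seed}")
    rng = np.random.default_rng((int(transform_seed), int(spec.seed), 7919))
    R, t = random_rigid_motion(rng)
    n = spec.n_points
    k = int(round(spec.overlap_fraction * n))
    chosen = sorted(rng.choice(n, size=k, replace=False)) if k else []
    coords_a = site_a.coords()
    true_b = coords_a[chosen] @ R.T + t
    if spec.jitter_sigma > 0:
        true_b = true_b + rng.normal(0.0, spec.jitter_sigma, size=true_b.shape)
    labels_b = [site_a.points[i].ptype for i in chosen]

    n_decoy = n - k
    if n_decoy:
        lo = true_b.min(axis=0) - 5.0 if k else np.zeros(3)
        span = (true_b.max(axis=0) - true_b.min(axis=0) + 10.0) if k \
            else np.full(3, spec.extent)
        extent = float(span.max())
        decoys = _place_points(rng, n_decoy, extent, spec.min_separation,
                               avoid=true_b - lo if k else None,
                               avoid_dist=DECOY_CLEARANCE) + lo
        decoy_labels = _draw_labels(rng, n_decoy, spec.label_weights)
        coords_b = np.vstack([true_b, decoys])
        labels_full = labels_b + decoy_labels
    else:
        coords_b = true_b
        labels_full = labels_b

    order = rng.permutation(len(coords_b))
    coords_b = coords_b[order]
    labels_full = [labels_full[i] for i in order]
    # position of A-point chosen[j] inside B after the shuffle
    where = {old: new for new, old in enumerate(order)}
    correspondence = [(int(chosen[j]), int(where[j])) for j in range(k)]

    site_b = PCSite(site_id=f"synthB-{spec.seed}-{transform_seed}",
                    points=_make_points(coords_b, labels_full),
                    cutoff_used=None, source_id="synthetic")
    gt = PairGroundTruth(rotation=R, translation=t,
                         correspondence=sorted(correspondence))
    return site_a, site_b, gt


# ---------------------------------------------------------------------------
# synthetic PDB complexes


def _pdb_line(record, serial, name, resname, chain, resseq, pos, element):
    x, y, z = (float(v) for v in pos)
    name_field = f" {name:<3}" if len(name) < 4 else name[:4]
    return (f"{record:<6}{serial:>5} {name_field}{'':1}{resname:>3} "
            f"{chain:1}{resseq:>4}{'':1}   "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.00:6.2f}{0.00:6.2f}"
            f"          {element:>2}")


def ligand_positions_for(site: PCSite, max_reach: float = 5.0) -> np.ndarray:
    """Greedy cover: ligand atom positions such that every site point lies
    within ``max_reach`` of at least one of them."""
    coords = site.coords()
    centroid = coords.mean(axis=0)
    placed = [centroid]
    for pos in coords:
        if cdist(pos[None], np.array(placed)).min() > max_reach:
            # nudge toward the centroid so the atom sits inside the pocket
            direction = centroid - pos
            norm = np.linalg.norm(direction)
            step = direction / norm if norm > 1e-9 else np.zeros(3)
            placed.append(pos + 1.0 * step)
    return np.array(placed)


def make_complex(site: PCSite, ligand_atoms: int = 8,
                 structure_id: str = "SYNTH") -> str:
    """Render a site as minimal PDB text with a covering HET ligand.

    Each PC point becomes a single-atom residue whose (residue, atom) entry
    in the default typing table reproduces exactly that point; the ligand is
    ``ligand_atoms`` carbon HETATM records placed so that every point is
    within 6 Å of the ligand.
    """
    cover = ligand_positions_for(site)
    if ligand_atoms < len(cover):
        raise BsmmError(
            f"need at least {len(cover)} ligand atoms to cover this site")
    lig_pos = list(cover)
    coords = site.coords()
    centroid = coords.mean(axis=0)
    # pad toward site points so the whole complex stays rigid-covariant:
    # transforming the site transforms the written ligand identically
    i = 0
    while len(lig_pos) < ligand_atoms:
        direction = coords[i % len(coords)] - centroid
        norm = np.linalg.norm(direction)
        unit = direction / norm if norm > 1e-9 else np.zeros(3)
        lig_pos.append(centroid + unit * (0.5 + 0.37 * i))
        i += 1

    lines = [f"HEADER    SYNTHETIC COMPLEX                       {structure_id:<10}"]
    serial = 1
    for resseq, point in enumerate(site.points, start=1):
        resname, atom_name, element = _TYPE_REALIZATION[point.ptype]
        lines.append(_pdb_line("ATOM", serial, atom_name, resname, "A",
                               resseq, point.pos, element))
        serial += 1
    for i, pos in enumerate(lig_pos, start=1):
        lines.append(_pdb_line("HETATM", serial, f"C{i}", "LIG", "L", 1,
                               pos, "C"))
        serial += 1
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_complex(site: PCSite, path, ligand_atoms: int = 8,
                  structure_id: str = "SYNTH") -> Path:
    path = Path(path)
    path.write_text(make_complex(site, ligand_atoms=ligand_atoms,
                                 structure_id=structure_id))
    return path
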