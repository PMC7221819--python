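"""Geometric hashing of PC-sites over canonical reference triangles.

Every non-collinear point triple whose side lengths fall inside
``[d_min, d_max]`` defines a reference triangle.  Its vertices are named by
the length of the side they face: P1 faces the shortest side, P3 the
longest.  The triangle fixes a local right-handed frame (P1 at the origin,
P2 on +x, P3 in the z=0 half-plane with y>0); expressing the whole site in
that frame yields a *model*.  Because the frame rides with the site, the
model coordinates are invariant to any rigid motion of the input — the core
property geometric hashing trades on.

Models are indexed by the vertex property triple and the binned side
lengths, so that candidate model pairs between two sites can be found by key
lookup instead of an all-against-all scan.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .errors import DegenerateGeometryError, HashingError
from .pc_typing import PCPoint, PCType, PTYPE_RANK
from .site_extraction import PCSite

HASH_SCHEMA_VERSION = "bsmm-hash-1"

#: side-length near-tie quantum for deterministic vertex ordering
TIE_TOL = 1e-6


@dataclass(frozen=True)
class HashParams:
    """Triangle admissibility and indexing parameters."""

    d_min: float = 2.0    # shortest admissible triangle side, Angstrom
    d_max: float = 13.0   # longest admissible triangle side, Angstrom
    bin_width: float = 1.0  # side-length bin for the index key, Angstrom
    min_area: float = 0.1   # collinearity rejection threshold, Angstrom^2

    def to_dict(self) -> dict:
        return {"d_min": self.d_min, "d_max": self.d_max,
                "bin_width": self.bin_width, "min_area": self.min_area}

    @classmethod
    def from_dict(cls, d: dict) -> "HashParams":
        return cls(**{k: float(v) for k, v in d.items()})


@dataclass(frozen=True)
class CanonicalTriangle:
    """A point triple in canonical vertex order.

    ``indices`` are positions in the source site's point list, ordered
    (P1, P2, P3); ``sides`` are (s1, s2, s3) with s1 = |P2P3| <= s2 = |P1P3|
    <= s3 = |P1P2|.
    """

    indices: tuple
    sides: tuple


def _tri_area(a: np.ndarray, b: np.ndarray, c: np.ndarray) -> float:
    return 0.5 * float(np.linalg.norm(np.cross(b - a, c - a)))


def canonical_order(points: Sequence[PCPoint], indices=(0, 1, 2),
                    min_area: float = 0.1) -> CanonicalTriangle:
    """Order a triangle's vertices by the length of the side each one faces.

    P1 faces the shortest side, P3 the longest.  Near-ties in side length
    (within 1e-6 Å) are broken by property rank (HA<HD<HAD<ALI<ARO) and then
    by lexicographically rounded coordinates, so the order is stable under
    permutation of the input.

    Raises
    ------
    DegenerateGeometryError
        for (near-)collinear triples.
    """
    a, b, c = (np.asarray(p.pos, dtype=float) for p in points)
    if _tri_area(a, b, c) < min_area:
        raise DegenerateGeometryError("collinear or near-degenerate triangle")
    pos = [a, b, c]
    opp = [float(np.linalg.norm(pos[(i + 1) % 3] - pos[(i + 2) % 3]))
           for i in range(3)]  # opp[i] = side length facing vertex i

    def sort_key(i: int):
        p = points[i]
        return (round(opp[i] / TIE_TOL),
                PTYPE_RANK[PCType(p.ptype)],
                tuple(np.round(pos[i], 3)))

    order = sorted(range(3), key=sort_key)
    return CanonicalTriangle(
        indices=tuple(indices[i] for i in order),
        sides=tuple(opp[i] for i in order),
    )


def triangle_frame(p1: np.ndarray, p2: np.ndarray, p3: np.ndarray):
    """Rigid map into the triangle's canonical frame.

    Returns ``(R, origin)`` such that ``x' = R @ (x - origin)`` sends
    P1 to (0,0,0), P2 to (|P1P2|, 0, 0) and P3 into the z=0 plane with y>0.
    R is a proper rotation (det +1).
    """
    p1, p2, p3 = (np.asarray(p, dtype=float) for p in (p1, p2, p3))
    u = p2 - p1
    v = p3 - p1
    n = np.cross(u, v)
    n_norm = np.linalg.norm(n)
    u_norm = np.linalg.norm(u)
    if u_norm < 1e-12 or n_norm < 1e-12:
        raise DegenerateGeometryError("degenerate triangle frame")
    x = u / u_norm
    z = n / n_norm
    y = np.cross(z, x)
    R = np.vstack([x, y, z])  # rows are the new axes
    return R, p1


def enumerate_triangles(site: PCSite, d_min: float = 2.0, d_max: float = 13.0,
                        min_area: float = 0.1) -> list:
    """All canonical triangles whose three sides lie in [d_min, d_max].

    Side bounds are inclusive; collinear triples are skipped.
    """
    coords = site.coords()
    n = len(coords)
    if n < 3:
        return []
    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff ** 2).sum(axis=2))
    in_range = (dist >= d_min) & (dist <= d_max)
    out = []
    pts = site.points
    for i, j, k in combinations(range(n), 3):
        if not (in_range[i, j] and in_range[i, k] and in_range[j, k]):
            continue
        try:
            tri = canonical_order((pts[i], pts[j], pts[k]), indices=(i, j, k),
                                  min_area=min_area)
        except DegenerateGeometryError:
            continue
        out.append(tri)
    return out


@dataclass
class HashModel:
    """The whole site expressed in one reference triangle's frame."""

    triangle: CanonicalTriangle
    key: tuple  # (ptype1, ptype2, ptype3, bin_s1, bin_s2, bin_s3)
    coords: np.ndarray  # (n_points, 3) in the triangle frame
    site_id: str
    _cells: Optional[dict] = field(default=None, repr=False, compare=False)

    def cell_index(self, bin_width: float) -> dict:
        """Map grid cell -> point indices (cached for the last bin width)."""
        if self._cells is None or self._cells[0] != bin_width:
            cells = np.floor(self.coords / bin_width).astype(int)
            table: dict = {}
            for idx, cell in enumerate(map(tuple, cells)):
                table.setdefault(cell, []).append(idx)
            self._cells = (bin_width, table)
        return self._cells[1]


def model_key(site: PCSite, tri: CanonicalTriangle, bin_width: float) -> tuple:
    t1, t2, t3 = (site.points[i].ptype.value for i in tri.indices)
    b1, b2, b3 = (int(np.floor(s / bin_width)) for s in tri.sides)
    return (t1, t2, t3, b1, b2, b3)


def build_model(site: PCSite, tri: CanonicalTriangle,
                params: HashParams) -> HashModel:
    coords = site.coords()
    i1, i2, i3 = tri.indices
    R, origin = triangle_frame(coords[i1], coords[i2], coords[i3])
    local = (coords - origin) @ R.T
    return HashModel(triangle=tri, key=model_key(site, tri, params.bin_width),
                     coords=local, site_id=site.site_id)


@dataclass
class HashFile:
    """All models of one site plus the parameters that produced them."""

    site: PCSite
    params: HashParams
    models: list

    @property
    def n_models(self) -> int:
        return len(self.models)

    def index(self) -> dict:
        """key -> list of model positions, in deterministic order."""
        idx: dict = {}
        for m_i, model in enumerate(self.models):
            idx.setdefault(model.key, []).append(m_i)
        return idx

    # -- persistence: JSON-lines (header line, then one model per line) ----
    def save(self, path) -> None:
        with open(path, "w") as fh:
            header = {
                "schema_version": HASH_SCHEMA_VERSION,
                "params": self.params.to_dict(),
                "site": self.site.to_dict(),
                "n_models": self.n_models,
            }
            fh.write(json.dumps(header) + "\n")
            for m in self.models:
                fh.write(json.dumps({
                    "indices": list(m.triangle.indices),
                    "sides": [float(s) for s in m.triangle.sides],
                    "key": list(m.key),
                    "coords": np.round(m.coords, 9).tolist(),
                }) + "\n")

    @classmethod
    def load(cls, path) -> "HashFile":
        with open(path) as fh:
            header = json.loads(fh.readline())
            if header.get("schema_version") != HASH_SCHEMA_VERSION:
                raise HashingError(
                    f"unknown hash schema {header.get('schema_version')!r}")
            site = PCSite.from_dict(header["site"])
            params = HashParams.from_dict(header["params"])
            models = []
            for line in fh:
                rec = json.loads(line)
                tri = CanonicalTriangle(indices=tuple(rec["indices"]),
                                        sides=tuple(rec["sides"]))
                models.append(HashModel(
                    triangle=tri,
                    key=tuple(rec["key"]),
                    coords=np.array(rec["coords"], dtype=float),
                    site_id=site.site_id,
                ))
        return cls(site=site, params=params, models=models)


def build_hash(site: PCSite, params: HashParams | None = None) -> HashFile:
    """Hash a site: one model per admissible reference triangle."""
    params = params or HashParams()
    triangles = enumerate_triangles(site, d_min=params.d_min,
                                    d_max=params.d_max,
                                    min_area=params.min_area)
    if not triangles:
        coords = site.coords()
        n = len(coords)
        diff = coords[:, None, :] - coords[None, :, :]
        dists = np.sqrt((diff ** 2).sum(axis=2))
        iu = np.triu_indices(n, 1)
        hist, edges = np.histogram(dists[iu], bins=8)
        diag = ", ".join(f"[{edges[i]:.1f},{edges[i+1]:.1f}):{hist[i]}"
                         for i in range(len(hist)))
        raise HashingError(
            f"no admissible triangle for site {site.site_id!r}: {n} points, "
            f"d_min={params.d_min}, d_max={params.d_max}; "
            f"pair-distance histogram {diag}")
    models = [build_model(site, tri, params) for tri in triangles]
    return HashFile(site=site, params=params, models=models)
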