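"""Site matching: grid voting, superposition, extension, scoring, clustering.

Two hashed sites are compared model-against-model.  Candidate model pairs
are pre-filtered by index key (pairwise-compatible vertex properties, side
bins within one bin).  Each candidate pair is scored by grid voting: points
of the two models that fall into the same 1.0 Å grid cell and carry
compatible properties contribute one vote each, one-to-one.  Pairs passing
the vote threshold are refined: a least-squares rigid superposition (Kabsch)
of the voted points yields a query→reference transform, correspondences are
extended to all compatible point pairs closer than D_cutoff, the fit is
repeated once on the extended set, and the match is scored.

Scores
------
* ``M_score = Match_num / min(R_p_num, Q_p_num)`` — Simpson coefficient over
  the whole site ("similar site").
* ``L_score = L_Match_num / (LR_p_num + LQ_p_num − L_Match_num)`` — Tanimoto
  coefficient over the largest single-linkage cluster of matched points
  ("similar subsite").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import product
from typing import Optional, Sequence

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import cdist, pdist

from .errors import DegenerateGeometryError
from .geohash import HashFile, HashModel
from .pc_typing import PCType
from .site_extraction import PCSite

logger = logging.getLogger(__name__)

DEFAULT_GRID = 1.0
DEFAULT_VOTE_THRESHOLD = 7  # passes iff votes >= 7, i.e. "vote > 6"
DEFAULT_D_CUTOFF = 3.0      # strict <
DEFAULT_LINKAGE_CUTOFF = 5.0


class MatchRules:
    """Symmetric property-compatibility relation between PC types.

    The default relation: HA↔{HA,HAD}, HD↔{HD,HAD}, HAD↔{HA,HD,HAD},
    ALI↔{ALI,ARO}, ARO↔{ALI,ARO}.  Donors never pair with acceptors;
    hydrophobic classes pair with each other only.
    """

    DEFAULT = {
        PCType.HA: frozenset({PCType.HA, PCType.HAD}),
        PCType.HD: frozenset({PCType.HD, PCType.HAD}),
        PCType.HAD: frozenset({PCType.HA, PCType.HD, PCType.HAD}),
        PCType.ALI: frozenset({PCType.ALI, PCType.ARO}),
        PCType.ARO: frozenset({PCType.ALI, PCType.ARO}),
    }

    def __init__(self, relation: dict | None = None):
        rel = {PCType(k): frozenset(PCType(x) for x in v)
               for k, v in (relation or self.DEFAULT).items()}
        for a, partners in rel.items():
            for b in partners:
                if a not in rel.get(b, frozenset()):
                    raise ValueError(f"asymmetric rule: {a.value}->{b.value}")
        self.relation = rel

    def compatible(self, a: PCType, b: PCType) -> bool:
        return PCType(b) in self.relation[PCType(a)]

    def compatible_with(self, a: PCType) -> frozenset:
        return self.relation[PCType(a)]


def property_compatible(a: PCType, b: PCType,
                        rules: MatchRules | None = None) -> bool:
    """Symmetric lookup in the matching-rule table."""
    return (rules or MatchRules()).compatible(a, b)


@dataclass
class GridBox:
    """Axis-aligned cubic grid; a point's cell is floor(coord / bin_width)."""

    bin_width: float = DEFAULT_GRID

    def __post_init__(self):
        if self.bin_width <= 0:
            raise ValueError("grid bin width must be positive")

    def cell(self, pos: np.ndarray) -> tuple:
        return tuple(np.floor(np.asarray(pos) / self.bin_width).astype(int))


def _greedy_one_to_one(cands: list) -> list:
    """Resolve (dist, ref, qry) candidates greedily by ascending distance.

    Ties are broken by ref then qry index so the result is deterministic.
    """
    cands = sorted(cands, key=lambda t: (t[0], t[1], t[2]))
    used_r: set = set()
    used_q: set = set()
    out = []
    for d, r, q in cands:
        if r in used_r or q in used_q:
            continue
        used_r.add(r)
        used_q.add(q)
        out.append((r, q, d))
    return out


def vote_models(ref_model: HashModel, qry_model: HashModel,
                grid: GridBox | float = DEFAULT_GRID,
                rules: MatchRules | None = None,
                ref_ptypes: Sequence | None = None,
                qry_ptypes: Sequence | None = None):
    """Count grid votes between two models in their canonical frames.

    A vote is a one-to-one pairing of a reference and a query point that
    share a grid cell and carry compatible properties; within a cell,
    pairings are resolved greedily by ascending Euclidean distance.

    Returns ``(votes, voted_pairs)`` where voted pairs are
    ``(ref point index, qry point index, distance)`` in site numbering.
    """
    if not isinstance(grid, GridBox):
        grid = GridBox(float(grid))
    rules = rules or MatchRules()
    if ref_ptypes is None or qry_ptypes is None:
        raise ValueError("vote_models needs the point types of both sites")
    ref_cells = ref_model.cell_index(grid.bin_width)
    qry_cells = qry_model.cell_index(grid.bin_width)
    cands = []
    for cell, q_idxs in qry_cells.items():
        r_idxs = ref_cells.get(cell)
        if not r_idxs:
            continue
        for r in r_idxs:
            rc = ref_model.coords[r]
            rt = ref_ptypes[r]
            for q in q_idxs:
                if rules.compatible(rt, qry_ptypes[q]):
                    d = float(np.linalg.norm(rc - qry_model.coords[q]))
                    cands.append((d, r, q))
    pairs = _greedy_one_to_one(cands)
    return len(pairs), pairs


def superpose(ref_coords: np.ndarray, qry_coords: np.ndarray):
    """Least-squares rigid superposition (Kabsch) of paired points.

    Finds the proper rotation R (det +1) and translation t minimizing
    ``sum ||R q_i + t - p_i||^2`` over the pairs, mapping query onto
    reference.  Returns ``(R, t, rmsd)``.
    """
    P = np.asarray(ref_coords, dtype=float)
    Q = np.asarray(qry_coords, dtype=float)
    if P.shape != Q.shape or P.ndim != 2 or P.shape[1] != 3:
        raise ValueError("superpose needs matched (n,3) arrays")
    n = P.shape[0]
    if n < 3:
        raise DegenerateGeometryError("need at least 3 pairs to superpose")
    pc = P.mean(axis=0)
    qc = Q.mean(axis=0)
    P0 = P - pc
    Q0 = Q - qc
    # collinearity check: second singular value of either cloud near zero
    if min(np.linalg.svd(P0, compute_uv=False)[1],
           np.linalg.svd(Q0, compute_uv=False)[1]) < 1e-8:
        raise DegenerateGeometryError("collinear point pairs; fit is ill-posed")
    H = Q0.T @ P0
    U, _S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = pc - R @ qc
    resid = (Q @ R.T + t) - P
    rmsd = float(np.sqrt((resid ** 2).sum() / n))
    return R, t, rmsd


def extend_matches(ref_site: PCSite, qry_site: PCSite, rotation, translation,
                   d_cutoff: float = DEFAULT_D_CUTOFF,
                   rules: MatchRules | None = None) -> list:
    """One-to-one pairs of compatible points closer than ``d_cutoff`` (strict)
    after mapping the query into the reference frame; greedy by distance."""
    rules = rules or MatchRules()
    ref_c = ref_site.coords()
    qry_c = qry_site.coords() @ np.asarray(rotation).T + np.asarray(translation)
    dists = cdist(ref_c, qry_c)
    ref_t = ref_site.ptypes()
    qry_t = qry_site.ptypes()
    cands = []
    for r, q in zip(*np.nonzero(dists < d_cutoff)):
        if rules.compatible(ref_t[r], qry_t[q]):
            cands.append((float(dists[r, q]), int(r), int(q)))
    return _greedy_one_to_one(cands)


def mscore(match_num: int, r_p_num: int, q_p_num: int) -> float:
    """Simpson overlap: matched points over the smaller site's point count."""
    if r_p_num < 1 or q_p_num < 1:
        raise ValueError("site point counts must be >= 1")
    if not 0 <= match_num <= min(r_p_num, q_p_num):
        raise ValueError("match_num must lie in [0, min(R_p_num, Q_p_num)]")
    return match_num / min(r_p_num, q_p_num)


def lscore(l_match_num: int, lr_p_num: int, lq_p_num: int) -> float:
    """Tanimoto coefficient over the largest-cluster (subsite) counts."""
    if min(l_match_num, lr_p_num, lq_p_num) < 0:
        raise ValueError("counts must be non-negative")
    if l_match_num > min(lr_p_num, lq_p_num):
        raise ValueError("l_match_num exceeds a subsite point count")
    denom = lr_p_num + lq_p_num - l_match_num
    if denom == 0:
        raise ValueError("empty subsite: zero denominator")
    return l_match_num / denom


def cluster_matches(pairs: Sequence, ref_site: PCSite,
                    linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF):
    """Single-linkage clusters of the matched reference points.

    Returns ``(clusters, largest)`` where clusters are lists of indices into
    ``pairs``.  The largest family wins ties by larger spatial extent
    (maximum pairwise distance), then by lowest member reference index.
    """
    if not pairs:
        raise ValueError("cluster_matches needs a non-empty pair list")
    coords = np.array([ref_site.points[r].pos for r, _q, _d in pairs])
    n = len(pairs)
    if n == 1:
        return [[0]], [0]
    Z = linkage(pdist(coords), method="single")
    labels = fcluster(Z, t=linkage_cutoff, criterion="distance")
    clusters: dict = {}
    for i, lab in enumerate(labels):
        clusters.setdefault(lab, []).append(i)
    groups = list(clusters.values())

    def extent(members):
        if len(members) == 1:
            return 0.0
        return float(pdist(coords[members]).max())

    def rank(members):
        return (-len(members), -extent(members),
                min(pairs[i][0] for i in members))

    groups.sort(key=rank)
    return groups, groups[0]


def _subsite_counts(pairs, cluster, ref_site, qry_site, linkage_cutoff):
    """Counts for the L_score: points of each site inside the space the
    largest family encloses — the union of balls of radius ``linkage_cutoff``
    around the cluster's matched points, per site in its own coordinates."""
    ref_members = np.array([ref_site.points[pairs[i][0]].pos for i in cluster])
    qry_members = np.array([qry_site.points[pairs[i][1]].pos for i in cluster])
    lr = int((cdist(ref_site.coords(), ref_members).min(axis=1)
              <= linkage_cutoff).sum())
    lq = int((cdist(qry_site.coords(), qry_members).min(axis=1)
              <= linkage_cutoff).sum())
    return len(cluster), lr, lq


@dataclass
class MatchResult:
    """Correspondences, transform and scores for one site-vs-site match."""

    ref_site_id: str
    qry_site_id: str
    pairs: list = field(default_factory=list)  # (ref idx, qry idx, distance)
    votes: int = 0
    rotation: Optional[np.ndarray] = None   # query -> reference original coords
    translation: Optional[np.ndarray] = None
    match_num: int = 0
    r_p_num: int = 0
    q_p_num: int = 0
    mscore: float = 0.0
    largest_cluster: list = field(default_factory=list)  # indices into pairs
    l_match_num: int = 0
    lr_p_num: int = 0
    lq_p_num: int = 0
    lscore: float = 0.0
    rmsd: Optional[float] = None
    ref_site: Optional[PCSite] = None
    qry_site: Optional[PCSite] = None
    alternatives: list = field(default_factory=list)

    @property
    def is_empty(self) -> bool:
        return not self.pairs

    def transform_point(self, pos: np.ndarray) -> np.ndarray:
        if self.rotation is None:
            raise ValueError("empty match has no transform")
        return self.rotation @ np.asarray(pos, dtype=float) + self.translation


def _empty_result(ref_site: PCSite, qry_site: PCSite) -> MatchResult:
    return MatchResult(ref_site_id=ref_site.site_id,
                       qry_site_id=qry_site.site_id,
                       r_p_num=ref_site.n_points, q_p_num=qry_site.n_points,
                       ref_site=ref_site, qry_site=qry_site)


def _refine(ref_site, qry_site, voted_pairs, votes, d_cutoff, linkage_cutoff,
            rules) -> Optional[MatchResult]:
    """Superpose voted pairs, extend, refit once, score and cluster."""
    ref_c = ref_site.coords()
    qry_c = qry_site.coords()
    idx_r = [p[0] for p in voted_pairs]
    idx_q = [p[1] for p in voted_pairs]
    try:
        R, t, _ = superpose(ref_c[idx_r], qry_c[idx_q])
    except DegenerateGeometryError:
        return None
    pairs = extend_matches(ref_site, qry_site, R, t, d_cutoff, rules)
    if len(pairs) >= 3:
        try:
            R, t, _ = superpose(ref_c[[p[0] for p in pairs]],
                                qry_c[[p[1] for p in pairs]])
            pairs = extend_matches(ref_site, qry_site, R, t, d_cutoff, rules)
        except DegenerateGeometryError:
            pass
    if not pairs:
        return None
    fit_resid = np.array([p[2] for p in pairs])
    rmsd = float(np.sqrt((fit_resid ** 2).mean()))
    res = MatchResult(
        ref_site_id=ref_site.site_id, qry_site_id=qry_site.site_id,
        pairs=pairs, votes=votes, rotation=R, translation=t,
        match_num=len(pairs), r_p_num=ref_site.n_points,
        q_p_num=qry_site.n_points,
        mscore=mscore(len(pairs), ref_site.n_points, qry_site.n_points),
        rmsd=rmsd, ref_site=ref_site, qry_site=qry_site,
    )
    _clusters, largest = cluster_matches(pairs, ref_site, linkage_cutoff)
    res.largest_cluster = largest
    res.l_match_num, res.lr_p_num, res.lq_p_num = _subsite_counts(
        pairs, largest, ref_site, qry_site, linkage_cutoff)
    res.lscore = lscore(res.l_match_num, res.lr_p_num, res.lq_p_num)
    return res


def _compatible_keys(key: tuple, rules: MatchRules):
    """Query-index keys a reference model key may pair with: property triple
    compatible position-wise, side bins within +/- 1."""
    t1, t2, t3, b1, b2, b3 = key
    type_opts = [sorted(x.value for x in rules.compatible_with(PCType(t)))
                 for t in (t1, t2, t3)]
    bin_opts = [(b - 1, b, b + 1) for b in (b1, b2, b3)]
    for u1, u2, u3 in product(*type_opts):
        for c1, c2, c3 in product(*bin_opts):
            yield (u1, u2, u3, c1, c2, c3)


def match_sites(ref_hash: HashFile, qry_hash: HashFile,
                vote_threshold: int = DEFAULT_VOTE_THRESHOLD,
                grid: GridBox | float = DEFAULT_GRID,
                rules: MatchRules | None = None,
                d_cutoff: float = DEFAULT_D_CUTOFF,
                linkage_cutoff: float = DEFAULT_LINKAGE_CUTOFF,
                prefilter: bool = True,
                top_k: int = 5) -> MatchResult:
    """Match two hashed sites and return the best-scoring result.

    Model pairs are iterated in deterministic sorted-key order.  A pair
    whose grid vote reaches ``vote_threshold`` is refined and scored; the
    result maximizing (mscore, match_num, −rmsd) wins.  Iteration stops
    early once every point of the smaller site is matched, since no later
    round can improve the score.  ``result.alternatives`` holds up to
    ``top_k − 1`` next-best distinct results.

    An empty :class:`MatchResult` (mscore 0) is returned when no model pair
    passes the threshold; that is a result, not an error.
    """
    if not isinstance(grid, GridBox):
        grid = GridBox(float(grid))
    rules = rules or MatchRules()
    ref_site, qry_site = ref_hash.site, qry_hash.site
    ref_t, qry_t = ref_site.ptypes(), qry_site.ptypes()
    best_possible = min(ref_site.n_points, qry_site.n_points)

    qry_index = qry_hash.index()
    ref_index = ref_hash.index()

    best: Optional[MatchResult] = None
    kept: dict = {}  # frozenset(pair indices) -> MatchResult

    def better(a: MatchResult, b: Optional[MatchResult]) -> bool:
        if b is None:
            return True
        ka = (a.mscore, a.match_num, -(a.rmsd or 0.0))
        kb = (b.mscore, b.match_num, -(b.rmsd or 0.0))
        return ka > kb

    done = False
    for ref_key in sorted(ref_index):
        if done:
            break
        if prefilter:
            qry_model_ids: list = []
            seen: set = set()
            for cand in _compatible_keys(ref_key, rules):
                for q_i in qry_index.get(cand, ()):
                    if q_i not in seen:
                        seen.add(q_i)
                        qry_model_ids.append(q_i)
            qry_model_ids.sort()
        else:
            qry_model_ids = list(range(qry_hash.n_models))
        if not qry_model_ids:
            continue
        for r_i in ref_index[ref_key]:
            ref_model = ref_hash.models[r_i]
            for q_i in qry_model_ids:
                qry_model = qry_hash.models[q_i]
                votes, voted = vote_models(ref_model, qry_model, grid, rules,
                                           ref_ptypes=ref_t, qry_ptypes=qry_t)
                if votes < vote_threshold or len(voted) < 3:
                    continue
                res = _refine(ref_site, qry_site, voted, votes, d_cutoff,
                              linkage_cutoff, rules)
                if res is None:
                    continue
                sig = frozenset((p[0], p[1]) for p in res.pairs)
                prev = kept.get(sig)
                if prev is None or better(res, prev):
                    kept[sig] = res
                if better(res, best):
                    best = res
                if res.match_num >= best_possible:
                    done = True
                    break
            if done:
                break

    if best is None:
        logger.info("no model pair of %s vs %s reached vote threshold %d",
                    ref_site.site_id, qry_site.site_id, vote_threshold)
        return _empty_result(ref_site, qry_site)
    ranked = sorted(kept.values(),
                    key=lambda r: (-r.mscore, -r.match_num, r.rmsd or 0.0))
    best.alternatives = [r for r in ranked if r is not best][:max(0, top_k - 1)]
    return best
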