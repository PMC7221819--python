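"""Matching: rules, voting, superposition, extension, scoring, end-to-end."""

from itertools import combinations

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment

from bsmm import (DegenerateGeometryError, GridBox, MatchRules, PCType,
                  build_hash, cluster_matches, extend_matches, lscore,
                  match_sites, mscore, property_compatible, superpose,
                  vote_models)
from bsmm.geohash import HashParams, build_model, enumerate_triangles
from bsmm.synthetic import SyntheticSpec, make_pair, make_site

from conftest import random_rotation, site_from

TYPES = [PCType.HA, PCType.HD, PCType.HAD, PCType.ALI, PCType.ARO]

TRUTH = {  # the full compatibility relation
    (PCType.HA, PCType.HA): True, (PCType.HA, PCType.HD): False,
    (PCType.HA, PCType.HAD): True, (PCType.HA, PCType.ALI): False,
    (PCType.HA, PCType.ARO): False,
    (PCType.HD, PCType.HD): True, (PCType.HD, PCType.HAD): True,
    (PCType.HD, PCType.ALI): False, (PCType.HD, PCType.ARO): False,
    (PCType.HAD, PCType.HAD): True, (PCType.HAD, PCType.ALI): False,
    (PCType.HAD, PCType.ARO): False,
    (PCType.ALI, PCType.ALI): True, (PCType.ALI, PCType.ARO): True,
    (PCType.ARO, PCType.ARO): True,
}


def test_compatibility_relation_exact():
    rules = MatchRules()
    for a in TYPES:
        for b in TYPES:
            expected = TRUTH.get((a, b), TRUTH.get((b, a)))
            assert property_compatible(a, b, rules) is expected, (a, b)
            assert rules.compatible(a, b) == rules.compatible(b, a)


def test_asymmetric_rules_rejected():
    with pytest.raises(ValueError, match="asymmetric"):
        MatchRules({PCType.HA: {PCType.HD}, PCType.HD: set(),
                    PCType.HAD: set(), PCType.ALI: set(), PCType.ARO: set()})


# ---------------------------------------------------------------------------
# voting


def _first_model(site):
    return build_model(site, enumerate_triangles(site)[0], HashParams())


def test_self_vote_counts_every_point():
    site = make_site(SyntheticSpec(n_points=12, seed=0))
    model = _first_model(site)
    votes, pairs = vote_models(model, model, 1.0, MatchRules(),
                               ref_ptypes=site.ptypes(),
                               qry_ptypes=site.ptypes())
    assert votes == 12
    assert all(r == q for r, q, _ in pairs)


def test_vote_lost_at_bin_boundary():
    """A point crossing a 1.0 A cell boundary stops voting."""
    coords = [(0.4, 0.5, 0.5), (4.5, 0.5, 0.5), (0.5, 4.5, 0.5),
              (0.5, 0.5, 4.5)]
    site_a = site_from(coords, [PCType.HA] * 4, "a")
    moved = [(1.1, 0.5, 0.5)] + coords[1:]  # cell x: 0 -> 1
    site_b = site_from(moved, [PCType.HA] * 4, "b")
    grid = GridBox(1.0)
    rules = MatchRules()
    ca = np.floor(np.array(coords) / 1.0)
    cb = np.floor(np.array(moved) / 1.0)
    assert not np.array_equal(ca[0], cb[0])
    # vote directly on identity-frame models
    from bsmm.geohash import HashModel, CanonicalTriangle
    ma = HashModel(CanonicalTriangle((0, 1, 2), (1, 1, 1)), ("x",) * 6,
                   np.array(coords, dtype=float), "a")
    mb = HashModel(CanonicalTriangle((0, 1, 2), (1, 1, 1)), ("x",) * 6,
                   np.array(moved, dtype=float), "b")
    votes, pairs = vote_models(ma, mb, grid, rules,
                               ref_ptypes=site_a.ptypes(),
                               qry_ptypes=site_b.ptypes())
    assert votes == 3
    assert all(r != 0 for r, _, _ in pairs)


def _oracle_votes(ref_coords, ref_types, qry_coords, qry_types, bw, rules):
    """Independent restatement: per-cell greedy one-to-one pairing."""
    cells = {}
    for i, c in enumerate(np.floor(np.asarray(ref_coords) / bw).astype(int)):
        cells.setdefault(tuple(c), []).append(i)
    cands = []
    for j, c in enumerate(np.floor(np.asarray(qry_coords) / bw).astype(int)):
        for i in cells.get(tuple(c), []):
            if rules.compatible(ref_types[i], qry_types[j]):
                d = float(np.linalg.norm(np.asarray(ref_coords[i])
                                         - np.asarray(qry_coords[j])))
                cands.append((d, i, j))
    cands.sort()
    used_i, used_j, n = set(), set(), 0
    for d, i, j in cands:
        if i not in used_i and j not in used_j:
            used_i.add(i); used_j.add(j); n += 1
    return n


@pytest.mark.parametrize("seed", range(10))
def test_votes_match_brute_force(seed):
    from bsmm.geohash import HashModel, CanonicalTriangle
    rng = np.random.default_rng(seed)
    n, m = rng.integers(4, 12), rng.integers(4, 12)
    rc = rng.uniform(0, 6, (n, 3))
    qc = rng.uniform(0, 6, (m, 3))
    rt = [TYPES[i] for i in rng.integers(0, 5, n)]
    qt = [TYPES[i] for i in rng.integers(0, 5, m)]
    ma = HashModel(CanonicalTriangle((0, 1, 2), (1, 1, 1)), ("x",) * 6, rc, "a")
    mb = HashModel(CanonicalTriangle((0, 1, 2), (1, 1, 1)), ("x",) * 6, qc, "b")
    rules = MatchRules()
    votes, _ = vote_models(ma, mb, 1.0, rules, ref_ptypes=rt, qry_ptypes=qt)
    assert votes == _oracle_votes(rc, rt, qc, qt, 1.0, rules)


# ---------------------------------------------------------------------------
# superposition


def _horn_quaternion(P, Q):
    """Oracle: Horn's closed-form quaternion absolute orientation."""
    P = np.asarray(P, float); Q = np.asarray(Q, float)
    pc, qc = P.mean(0), Q.mean(0)
    A = (Q - qc).T @ (P - pc)
    Sxx, Sxy, Sxz = A[0]
    Syx, Syy, Syz = A[1]
    Szx, Szy, Szz = A[2]
    N = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    vals, vecs = np.linalg.eigh(N)
    w, x, y, z = vecs[:, np.argmax(vals)]
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - w * z), 2 * (x * z + w * y)],
        [2 * (x * y + w * z), 1 - 2 * (x * x + z * z), 2 * (y * z - w * x)],
        [2 * (x * z - w * y), 2 * (y * z + w * x), 1 - 2 * (x * x + y * y)]])
    t = pc - R @ qc
    resid = Q @ R.T + t - P
    return R, t, float(np.sqrt((resid ** 2).sum() / len(P)))


def test_superpose_identity():
    P = np.random.default_rng(0).uniform(0, 10, (6, 3))
    R, t, rmsd = superpose(P, P)
    assert np.allclose(R, np.eye(3), atol=1e-12)
    assert np.allclose(t, 0, atol=1e-10)
    assert rmsd < 1e-12


def test_superpose_recovers_90_degree_rotation():
    P = np.random.default_rng(1).uniform(0, 10, (8, 3))
    Rz = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1]])
    Q = P @ Rz.T  # Q = Rz P; fitting Q onto P must recover Rz^-1
    R, t, rmsd = superpose(P, Q)
    assert np.allclose(R, Rz.T, atol=1e-10)
    assert rmsd < 1e-9


@pytest.mark.parametrize("seed", range(10))
def test_superpose_agrees_with_quaternion_oracle(seed):
    rng = np.random.default_rng(seed)
    P = rng.uniform(0, 10, (10, 3))
    Rm = random_rotation(rng)
    Q = (P - P.mean(0)) @ Rm.T + rng.uniform(-5, 5, 3)
    Q = Q + rng.normal(0, 0.2, Q.shape)
    R1, t1, rmsd1 = superpose(P, Q)
    R2, t2, rmsd2 = _horn_quaternion(P, Q)
    assert abs(rmsd1 - rmsd2) < 1e-9
    assert np.allclose(R1, R2, atol=1e-7)
    assert np.allclose(t1, t2, atol=1e-6)
    assert np.isclose(np.linalg.det(R1), 1.0)


def test_superpose_rejects_degenerate():
    with pytest.raises(DegenerateGeometryError):
        superpose(np.zeros((2, 3)), np.zeros((2, 3)))
    line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
    with pytest.raises(DegenerateGeometryError):
        superpose(line, line)


def test_superpose_corrects_reflection():
    """A mirrored cloud must still yield a proper rotation (det +1)."""
    rng = np.random.default_rng(5)
    P = rng.uniform(0, 10, (10, 3))
    Q = P.copy()
    Q[:, 0] *= -1
    R, t, rmsd = superpose(P, Q)
    assert np.isclose(np.linalg.det(R), 1.0)
    assert rmsd > 0.1  # mirror image cannot be fit rigidly


# ---------------------------------------------------------------------------
# extension


def test_extend_identity_pairs_everything():
    site = make_site(SyntheticSpec(n_points=10, seed=3))
    pairs = extend_matches(site, site, np.eye(3), np.zeros(3))
    assert len(pairs) == 10
    assert all(d == 0.0 and r == q for r, q, d in pairs)


def test_extend_strict_cutoff():
    a = site_from([(0, 0, 0), (10, 0, 0), (0, 10, 0)], [PCType.HA] * 3, "a")
    b = site_from([(3.2, 0, 0), (10, 0, 0), (0, 10, 0)], [PCType.HA] * 3, "b")
    pairs = extend_matches(a, b, np.eye(3), np.zeros(3), d_cutoff=3.0)
    assert {(r, q) for r, q, _ in pairs} == {(1, 1), (2, 2)}  # 3.2 A excluded


@pytest.mark.parametrize("seed", range(20))
def test_greedy_extension_vs_hungarian(seed):
    """Greedy size equals optimal assignment size on 8-point fixtures."""
    rng = np.random.default_rng(seed)
    a = site_from(rng.uniform(0, 10, (8, 3)),
                  [TYPES[i] for i in rng.integers(0, 5, 8)], "a")
    b = site_from(rng.uniform(0, 10, (8, 3)),
                  [TYPES[i] for i in rng.integers(0, 5, 8)], "b")
    pairs = extend_matches(a, b, np.eye(3), np.zeros(3), d_cutoff=3.0)
    # oracle: maximum-cardinality assignment over admissible pairs
    rules = MatchRules()
    BIG = 1e6
    cost = np.full((8, 8), BIG)
    for i in range(8):
        for j in range(8):
            d = np.linalg.norm(a.coords()[i] - b.coords()[j])
            if d < 3.0 and rules.compatible(a.ptypes()[i], b.ptypes()[j]):
                cost[i, j] = d
    ri, ci = linear_sum_assignment(cost)
    optimal = int(sum(cost[r, c] < BIG for r, c in zip(ri, ci)))
    assert len(pairs) == optimal


# ---------------------------------------------------------------------------
# scores


@pytest.mark.parametrize("args,expected", [
    ((8, 10, 16), 0.8), ((5, 5, 5), 1.0), ((0, 5, 7), 0.0),
    ((7, 7, 20), 1.0),
])
def test_mscore_formula(args, expected):
    assert mscore(*args) == pytest.approx(expected)


@pytest.mark.parametrize("args", [(11, 10, 16), (1, 0, 5), (-1, 3, 3)])
def test_mscore_preconditions(args):
    with pytest.raises(ValueError):
        mscore(*args)


@pytest.mark.parametrize("args,expected", [
    ((5, 7, 8), 0.5), ((4, 4, 4), 1.0), ((0, 3, 4), 0.0),
])
def test_lscore_formula(args, expected):
    assert lscore(*args) == pytest.approx(expected)


def test_lscore_zero_denominator():
    with pytest.raises(ValueError):
        lscore(0, 0, 0)


# ---------------------------------------------------------------------------
# clustering


def _pairs_at(coords):
    return [(i, i, 0.0) for i in range(len(coords))]


def test_two_separated_groups():
    coords = [(0, 0, 0), (1, 0, 0), (0, 1, 0), (1, 1, 0),
              (20, 0, 0), (21, 0, 0), (20, 1, 0), (21, 1, 0)]
    site = site_from(coords, [PCType.HA] * 8)
    clusters, largest = cluster_matches(_pairs_at(coords), site,
                                        linkage_cutoff=5.0)
    assert sorted(len(c) for c in clusters) == [4, 4]
    assert len(largest) == 4


def test_chain_is_one_cluster():
    coords = [(i * 4.0, 0, 0) for i in range(6)]  # consecutive links at 4 A
    site = site_from(coords, [PCType.HA] * 6)
    clusters, largest = cluster_matches(_pairs_at(coords), site, 5.0)
    assert len(clusters) == 1 and len(largest) == 6


def _oracle_components(coords, cutoff):
    n = len(coords)
    adj = {i: set() for i in range(n)}
    for i, j in combinations(range(n), 2):
        if np.linalg.norm(np.asarray(coords[i]) - coords[j]) <= cutoff:
            adj[i].add(j); adj[j].add(i)
    seen, comps = set(), []
    for s in range(n):
        if s in seen:
            continue
        stack, comp = [s], set()
        while stack:
            v = stack.pop()
            if v in comp:
                continue
            comp.add(v); stack.extend(adj[v] - comp)
        seen |= comp; comps.append(frozenset(comp))
    return set(comps)


@pytest.mark.parametrize("seed", range(10))
def test_clustering_matches_connected_components(seed):
    rng = np.random.default_rng(seed)
    coords = rng.uniform(0, 25, (12, 3))
    site = site_from(coords, [PCType.HA] * 12)
    clusters, _ = cluster_matches(_pairs_at(coords), site, 5.0)
    assert {frozenset(c) for c in clusters} == _oracle_components(coords, 5.0)


# ---------------------------------------------------------------------------
# end-to-end matching


def test_self_match_perfect():
    site = make_site(SyntheticSpec(n_points=15, seed=6))
    h = build_hash(site)
    res = match_sites(h, h)
    assert res.mscore == 1.0
    assert res.match_num == 15
    assert res.lscore == 1.0
    assert np.allclose(res.rotation, np.eye(3), atol=1e-9)


def test_rigid_copy_recovers_ground_truth():
    spec = SyntheticSpec(n_points=15, seed=7)
    A, B, gt = make_pair(spec, transform_seed=2)
    res = match_sites(build_hash(A), build_hash(B))
    assert res.mscore == 1.0
    Rinv, tinv = gt.inverse()
    moved = B.coords() @ res.rotation.T + res.translation
    truth = B.coords() @ Rinv.T + tinv
    assert np.abs(moved - truth).max() < 1e-3


def test_jittered_match_state():
    spec = SyntheticSpec(n_points=20, seed=8, jitter_sigma=0.3)
    A, B, _ = make_pair(spec, transform_seed=1)
    res = match_sites(build_hash(A), build_hash(B))
    assert res.mscore >= 0.9
    # every reported pair is compatible and inside the cutoff
    rules = MatchRules()
    for r, q, d in res.pairs:
        assert d < 3.0
        assert rules.compatible(A.points[r].ptype, B.points[q].ptype)
    # pairs are one-to-one in both directions
    assert len({r for r, _, _ in res.pairs}) == len(res.pairs)
    assert len({q for _, q, _ in res.pairs}) == len(res.pairs)


def test_mscore_rigid_motion_invariant():
    spec = SyntheticSpec(n_points=12, seed=9, jitter_sigma=0.2)
    A, B, _ = make_pair(spec, transform_seed=3)
    base = match_sites(build_hash(A), build_hash(B)).mscore
    rng = np.random.default_rng(42)
    R = random_rotation(rng)
    t = rng.uniform(-30, 30, 3)
    moved = match_sites(build_hash(A.transformed(R, t)), build_hash(B)).mscore
    assert moved == pytest.approx(base, abs=1e-9)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_swap_symmetry_within_tolerance(seed):
    spec = SyntheticSpec(n_points=14, seed=seed, jitter_sigma=0.3,
                         overlap_fraction=0.8)
    A, B, _ = make_pair(spec, transform_seed=seed + 10)
    hA, hB = build_hash(A), build_hash(B)
    ab = match_sites(hA, hB).mscore
    ba = match_sites(hB, hA).mscore
    assert abs(ab - ba) <= 0.05


def test_unreachable_threshold_returns_empty_result():
    site = make_site(SyntheticSpec(n_points=10, seed=11))
    h = build_hash(site)
    res = match_sites(h, h, vote_threshold=999)
    assert res.is_empty and res.mscore == 0.0 and res.pairs == []


def test_prefilter_agrees_with_exhaustive_loop():
    spec = SyntheticSpec(n_points=10, seed=12, jitter_sigma=0.2)
    A, B, _ = make_pair(spec, transform_seed=5)
    hA, hB = build_hash(A), build_hash(B)
    fast = match_sites(hA, hB, prefilter=True)
    slow = match_sites(hA, hB, prefilter=False)
    assert fast.mscore == pytest.approx(slow.mscore, abs=1e-12)
    assert fast.match_num == slow.match_num


def test_alternatives_ranked():
    spec = SyntheticSpec(n_points=14, seed=13, jitter_sigma=0.4,
                         overlap_fraction=0.8)
    A, B, _ = make_pair(spec, transform_seed=4)
    res = match_sites(build_hash(A), build_hash(B), top_k=5)
    scores = [res.mscore] + [alt.mscore for alt in res.alternatives]
    assert scores == sorted(scores, reverse=True)
    assert len(res.alternatives) <= 4
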