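import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.optimize import minimize
from scipy.spatial.transform import Rotation

from polydom.core import AssemblyModel, RigidPose
from polydom.fixtures import make_toy_domain
from polydom.metrics import (
    AlignmentMap,
    harmonic_tm_score,
    kabsch,
    r_tm_score,
    structural_align,
    tm_d0,
    tm_score,
)


def _random_cloud(n, seed, scale=5.0):
    return np.random.default_rng(seed).normal(0, scale, (n, 3))


# ---------------------------------------------------------------------------
# Kabsch


def test_kabsch_exact_recovery():
    q = _random_cloud(15, 0)
    rm = Rotation.from_euler("zyx", [0.7, -0.3, 1.2]).as_matrix()
    r = q @ rm.T + np.array([3.0, -1.0, 2.0])
    sup = kabsch(q, r, AlignmentMap.identity(15))
    assert sup.rmsd < 1e-6
    assert np.allclose(sup.apply(q), r, atol=1e-6)


def test_kabsch_vs_rotation_grid_oracle():
    """The Kabsch RMSD must match an independent optimizer over rotation
    space (multi-start trust-region on the rotation vector) to 1e-3."""
    rng = np.random.default_rng(7)
    q = _random_cloud(12, 1)
    rm = Rotation.from_rotvec([0.4, -0.9, 0.3]).as_matrix()
    r = q @ rm.T + 2.0 + rng.normal(0, 0.5, (12, 3))  # noisy copy

    qc, rc = q - q.mean(0), r - r.mean(0)

    def rmsd_of(rotvec):
        rot = Rotation.from_rotvec(rotvec).as_matrix()
        return float(np.sqrt(np.mean(np.sum((qc @ rot.T - rc) ** 2, axis=1))))

    best = np.inf
    for k in range(20):
        x0 = np.random.default_rng(k).uniform(-np.pi, np.pi, 3)
        res = minimize(rmsd_of, x0, method="Nelder-Mead",
                       options={"xatol": 1e-8, "fatol": 1e-12, "maxiter": 2000})
        best = min(best, float(res.fun))

    sup = kabsch(q, r, AlignmentMap.identity(12))
    assert sup.rmsd <= best + 1e-3
    assert abs(sup.rmsd - best) < 1e-3


def test_kabsch_rejects_degenerate_inputs():
    line = np.column_stack([np.arange(5.0), np.zeros(5), np.zeros(5)])
    with pytest.raises(ValueError, match="degenerate"):
        kabsch(line, line, AlignmentMap.identity(5))
    q = _random_cloud(5, 2)
    with pytest.raises(ValueError, match="pairs"):
        kabsch(q, q, AlignmentMap(np.array([[0, 0], [1, 1]])))


def test_alignment_map_must_increase():
    with pytest.raises(ValueError):
        AlignmentMap(np.array([[0, 1], [1, 1]]))


# ---------------------------------------------------------------------------
# TM-score


def test_tm_d0_values():
    assert tm_d0(10) == 0.5          # short-length floor
    assert tm_d0(15) == 0.5
    expect = 1.24 * np.cbrt(100 - 15) - 1.8
    assert abs(tm_d0(100) - expect) < 1e-12


def test_tm_score_self_is_exactly_one():
    d = make_toy_domain(30, seed=3)
    n = len(d.ca)
    tm = tm_score(d.ca, d.ca, AlignmentMap.identity(n), n)
    assert tm == 1.0


def test_tm_score_matches_brute_force_oracle():
    """On <=20-residue toys, the fragment-seeded TM search must match a
    multi-start 6-parameter optimization of the kernel sum to 1e-3."""
    for seed in range(3):
        d = make_toy_domain(20, fold="compact-walk", seed=seed)
        rng = np.random.default_rng(seed + 50)
        # distorted copy: rigid motion plus noise on half the residues
        rm = Rotation.random(rng=rng).as_matrix()
        ref = d.ca @ rm.T + rng.uniform(-5, 5, 3)
        ref[10:] += rng.normal(0, 2.0, (10, 3))
        n = 20
        d0 = tm_d0(n)

        def neg_kernel(x):
            rot = Rotation.from_rotvec(x[:3]).as_matrix()
            moved = d.ca @ rot.T + x[3:]
            d2 = np.sum((moved - ref) ** 2, axis=1)
            return -np.sum(1.0 / (1.0 + d2 / d0**2)) / n

        best = -np.inf
        for k in range(60):
            r0 = np.random.default_rng(1000 * seed + k)
            x0 = np.concatenate([
                Rotation.random(rng=r0).as_rotvec(),
                ref.mean(0) - d.ca.mean(0) + r0.normal(0, 2, 3),
            ])
            res = minimize(neg_kernel, x0, method="Nelder-Mead",
                           options={"maxiter": 4000, "xatol": 1e-7,
                                    "fatol": 1e-10})
            best = max(best, -float(res.fun))

        tm = tm_score(d.ca, ref, AlignmentMap.identity(n), n)
        assert tm >= best - 1e-3, f"seed {seed}: tm {tm} < oracle {best}"
        assert abs(tm - best) < 1e-3, f"seed {seed}: tm {tm} vs oracle {best}"


def test_tm_score_shrinks_with_noise():
    d = make_toy_domain(40, seed=4)
    rng = np.random.default_rng(0)
    noisy = d.ca + rng.normal(0, 2.0, d.ca.shape)
    n = len(d.ca)
    tm = tm_score(noisy, d.ca, AlignmentMap.identity(n), n)
    assert 0.3 < tm < 1.0


# ---------------------------------------------------------------------------
# harmonic TM-score


def test_harmonic_worked_example():
    # per-domain 0.94 and 0.88 combine to 2/(1/0.94 + 1/0.88)
    direct = 2.0 / (1.0 / 0.94 + 1.0 / 0.88)
    assert abs(harmonic_tm_score([0.94, 0.88]) - direct) < 1e-12
    assert round(harmonic_tm_score([0.94, 0.88]), 4) == 0.9090


def test_harmonic_errors():
    with pytest.raises(ValueError):
        harmonic_tm_score([])
    with pytest.raises(ValueError):
        harmonic_tm_score([0.5, 0.0])


@settings(max_examples=50, deadline=None, derandomize=True)
@given(st.lists(st.floats(0.001, 1.0), min_size=1, max_size=6))
def test_harmonic_properties(scores):
    h = harmonic_tm_score(scores)
    assert min(scores) - 1e-12 <= h <= max(scores) + 1e-12
    assert h <= np.mean(scores) + 1e-12          # harmonic <= arithmetic
    assert abs(harmonic_tm_score(scores[::-1]) - h) < 1e-12  # symmetric


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.floats(0.001, 1.0))
def test_harmonic_of_equal_scores(x):
    assert abs(harmonic_tm_score([x, x, x]) - x) < 1e-12


def test_harmonic_dominated_by_worst_domain():
    assert harmonic_tm_score([0.95, 0.1]) < 0.2


# ---------------------------------------------------------------------------
# structural alignment


def test_structural_align_exact_substructure():
    d = make_toy_domain(40, seed=5)
    amap, tm = structural_align(d.ca[5:25], d.ca)
    assert tm > 0.999
    assert len(amap) == 20


def test_structural_align_mirror_is_not_a_match():
    for seed in range(3):
        d = make_toy_domain(30, fold="compact-walk", seed=seed)
        mirror = d.ca * np.array([1.0, 1.0, -1.0])
        _, tm = structural_align(d.ca, mirror)
        assert tm < 0.5


def test_structural_align_unrelated_low():
    a = make_toy_domain(30, fold="compact-walk", seed=10)
    b = make_toy_domain(30, fold="compact-walk", seed=11)
    _, tm = structural_align(a.ca, b.ca)
    assert tm < 0.6


def test_structural_align_requires_min_length():
    with pytest.raises(ValueError):
        structural_align(np.zeros((3, 3)), np.zeros((10, 3)))


# ---------------------------------------------------------------------------
# rTM-score


def _model_from(coords, ids, dom_of):
    return AssemblyModel(poses=[RigidPose.identity()], residue_ids=ids,
                         domain_of_residue=dom_of, coords=coords)


def test_rtm_identity_is_one():
    d = make_toy_domain(30, seed=6)
    ids = d.residue_ids
    m = _model_from(d.ca.copy(), ids, np.zeros(len(ids), int))
    assert r_tm_score(m, d.ca, ids) > 0.9999


def test_rtm_penalizes_domain_reorientation():
    """Rotating one domain must hurt rTM more than TM (which refits)."""
    from conftest import sorted_domains, toy_problem
    from polydom.core import model_from_domains
    from polydom.fixtures import ToySpec

    native, domains, layout, _, problem = toy_problem(ToySpec(seed=3))
    doms = sorted_domains(domains)
    poses = [RigidPose.identity() for _ in doms]
    poses[1] = RigidPose(rot=[np.pi / 2, 0, 0], trans=[0, 0, 0])
    m = model_from_domains(doms, poses)
    rtm = r_tm_score(m, native, problem.residue_ids)
    n = len(native)
    tm = tm_score(m.coords, native, AlignmentMap.identity(n), n)
    assert rtm < tm  # the fixed-superposition score is the stricter one
    assert rtm < 0.8


@settings(max_examples=10, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_rtm_never_exceeds_tm(seed):
    rng = np.random.default_rng(seed)
    d = make_toy_domain(25, fold="compact-walk", seed=seed % 100)
    ids = d.residue_ids
    coords = d.ca + rng.normal(0, 1.5, d.ca.shape)
    m = _model_from(coords, ids, np.zeros(len(ids), int))
    rtm = r_tm_score(m, d.ca, ids)
    n = len(ids)
    tm = tm_score(coords, d.ca, AlignmentMap.identity(n), n)
    assert rtm <= tm + 1e-9
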