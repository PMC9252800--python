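"""Synthetic multi-domain structures with known native poses.

The generators build idealized CA traces — packed helix bundles or compact
self-avoiding walks — place two or more of them as domains of one chain with
realistic inter-domain interfaces and linker geometry, and produce scrambled
starting configurations for pose-recovery experiments.  Everything is
deterministic per seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.spatial.distance import cdist, pdist
from scipy.spatial.transform import Rotation

from .core import (
    ChainLayout,
    DomainModel,
    RigidPose,
    Segment,
    infer_layout,
)

__all__ = ["ToySpec", "make_toy_domain", "make_toy_multidomain", "scramble"]

CA_STEP = 3.8
MIN_SEP = 3.5  # hard lower bound for non-consecutive CA pairs


@dataclass
class ToySpec:
    """Parameters of one synthetic multi-domain target."""

    n_domains: int = 2
    residues_per_domain: tuple[int, ...] = (60, 60)
    topology: str = "continuous"      # or "discontinuous"
    fold: str = "helix-bundle"        # or "compact-walk"
    linker_gap: int = 2               # missing residues between consecutive domains
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.residues_per_domain, int):
            self.residues_per_domain = (self.residues_per_domain,) * self.n_domains
        if len(self.residues_per_domain) != self.n_domains:
            raise ValueError("residues_per_domain length must equal n_domains")
        if min(self.residues_per_domain) < 20:
            raise ValueError("domains must have >= 20 residues")
        if self.topology == "discontinuous" and self.n_domains < 2:
            raise ValueError("discontinuous topology needs >= 2 domains")


# ---------------------------------------------------------------------------
# single-domain folds

_HELIX_RISE = 1.5
_HELIX_RADIUS = 2.3
_HELIX_TWIST = np.deg2rad(100.0)


def _helix(n: int, origin: np.ndarray, direction: float, phase: float) -> np.ndarray:
    i = np.arange(n)
    ang = phase + i * _HELIX_TWIST
    return np.column_stack([
        origin[0] + _HELIX_RADIUS * np.cos(ang),
        origin[1] + _HELIX_RADIUS * np.sin(ang),
        origin[2] + direction * _HELIX_RISE * i,
    ])


def _relax_turn(p: np.ndarray, q: np.ndarray, k: int, context: np.ndarray,
                bulge_dir: np.ndarray) -> np.ndarray:
    """Place k CA atoms between p and q with ~3.8 A steps, avoiding context."""
    t = np.linspace(0, 1, k + 2)[1:-1]
    init = p + np.outer(t, q - p) + np.outer(np.sin(np.pi * t), bulge_dir * 3.0)

    def cost(x: np.ndarray) -> float:
        pts = x.reshape(k, 3)
        chain = np.vstack([p, pts, q])
        steps = np.linalg.norm(np.diff(chain, axis=0), axis=1)
        c = ((steps - CA_STEP) ** 2).sum()
        d = cdist(pts, context)
        c += 10.0 * (np.maximum(0.0, 3.8 - d) ** 2).sum()
        if k > 1:
            dd = pdist(pts)
            c += 10.0 * (np.maximum(0.0, 3.8 - dd) ** 2).sum()
        return float(c)

    res = minimize(cost, init.ravel(), method="L-BFGS-B")
    return res.x.reshape(k, 3)


def _helix_bundle(n: int, rng: np.random.Generator) -> np.ndarray:
    n_h = 2 if n < 75 else 3
    turn = 3
    per = (n - turn * (n_h - 1)) // n_h
    extra = n - turn * (n_h - 1) - per * n_h
    lengths = [per + (1 if i < extra else 0) for i in range(n_h)]

    sep = rng.uniform(9.0, 10.5)
    coords: list[np.ndarray] = []
    helices: list[np.ndarray] = []
    if n_h == 2:
        origins = [np.zeros(3), np.array([sep, 0.0, 0.0])]
    else:
        spread = rng.uniform(np.deg2rad(50), np.deg2rad(70))
        origins = [np.zeros(3),
                   np.array([sep, 0.0, 0.0]),
                   np.array([sep * np.cos(spread), sep * np.sin(spread), 0.0])]
    for h in range(n_h):
        direction = 1.0 if h % 2 == 0 else -1.0
        # odd helices run downward, starting from the top, so the chain flows
        start_z = 0.0 if direction > 0 else _HELIX_RISE * (lengths[h] - 1)
        origin = np.array([origins[h][0], origins[h][1], start_z])
        helices.append(_helix(lengths[h], origin, direction, rng.uniform(0, 2 * np.pi)))
    for h, hel in enumerate(helices):
        if h > 0:
            context = np.vstack(coords + helices[h:])
            p, q = coords_last(coords), hel[0]
            centroid = np.vstack(coords).mean(axis=0)
            mid = 0.5 * (p + q)
            out = mid - centroid
            nrm = np.linalg.norm(out)
            bulge = out / nrm if nrm > 1e-6 else np.array([0.0, 0.0, 1.0])
            coords.append(_relax_turn(p, q, turn, context, bulge))
        coords.append(hel)
    xyz = np.vstack(coords)
    # small seeded jitter so decoys of equal size differ
    xyz = xyz + rng.normal(0.0, 0.05, xyz.shape)
    return xyz - xyz.mean(axis=0)


def coords_last(blocks: list[np.ndarray]) -> np.ndarray:
    return blocks[-1][-1]


def _compact_walk(n: int, rng: np.random.Generator) -> np.ndarray | None:
    pts = [np.zeros(3)]
    direction = _random_unit(rng)
    for _ in range(n - 1):
        placed = False
        for _attempt in range(60):
            cur = pts[-1]
            centroid = np.mean(pts, axis=0)
            bias = centroid - cur
            nb = np.linalg.norm(bias)
            bias = bias / nb if nb > 1e-6 else np.zeros(3)
            cand_dir = _random_unit(rng) + 0.7 * bias + 0.3 * direction
            cand_dir /= np.linalg.norm(cand_dir)
            cand = cur + CA_STEP * cand_dir
            if len(pts) >= 2:
                d = np.linalg.norm(np.asarray(pts[:-1]) - cand, axis=1)
                if d.min() < MIN_SEP:
                    continue
            pts.append(cand)
            direction = cand_dir
            placed = True
            break
        if not placed:
            return None
    xyz = np.asarray(pts)
    rg = np.sqrt(((xyz - xyz.mean(axis=0)) ** 2).sum(axis=1).mean())
    if rg > 0.8 * (CA_STEP * n ** 0.6):
        return None
    return xyz - xyz.mean(axis=0)


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _check_trace(xyz: np.ndarray) -> bool:
    steps = np.linalg.norm(np.diff(xyz, axis=0), axis=1)
    if not ((steps > CA_STEP - 0.2) & (steps < CA_STEP + 0.2)).all():
        return False
    d = cdist(xyz, xyz)
    n = len(xyz)
    mask = ~np.eye(n, dtype=bool) & ~np.eye(n, k=1, dtype=bool) & ~np.eye(n, k=-1, dtype=bool)
    return bool(d[mask].min() >= MIN_SEP)


def make_toy_domain(n: int, fold: str = "helix-bundle", seed: int = 0,
                    domain_id: int = 1, start_id: int = 1) -> DomainModel:
    """Generate one compact toy domain of ``n`` residues as a CA trace.

    helix-bundle: 2-3 ideal, packed alpha-helices joined by short relaxed
    turns.  compact-walk: a self-avoiding 3.8 A-step random walk biased
    toward its running centroid.  Consecutive CA distances are 3.8 +/- 0.2 A
    and no non-consecutive pair comes closer than 3.5 A.
    """
    if n < 20:
        raise ValueError("toy domains need >= 20 residues")
    rng = np.random.default_rng(seed)
    for _ in range(1000):
        if fold == "helix-bundle":
            xyz = _helix_bundle(n, rng)
        elif fold == "compact-walk":
            xyz = _compact_walk(n, rng)
        else:
            raise ValueError(f"unknown fold {fold!r}")
        if xyz is not None and _check_trace(xyz):
            # random global orientation, still seed-deterministic
            xyz = xyz @ Rotation.random(random_state=np.random.default_rng(seed + 7)).as_matrix().T
            ids = np.arange(start_id, start_id + n)
            return DomainModel(
                domain_id=domain_id,
                segments=[Segment(start_id, start_id + n - 1)],
                residue_ids=ids,
                residue_names=["ALA"] * n,
                ca=xyz,
            )
    raise RuntimeError(f"could not generate a valid {fold} of {n} residues")


# ---------------------------------------------------------------------------
# multi-domain targets


def _interface_ok(a: np.ndarray, b: np.ndarray, min_pairs: int = 10) -> bool:
    d = cdist(a, b)
    if d.min() < 4.0:
        return False
    return int((d < 8.0).sum()) >= min_pairs


def _place_next(prev_ca: np.ndarray, anchor: np.ndarray, dom: DomainModel,
                attach_atom: int, gap: int, rng: np.random.Generator,
                max_tries: int = 1000) -> np.ndarray | None:
    """Place dom so its attach_atom CA sits near anchor, interface-forming."""
    limit = CA_STEP * (gap + 1)
    lo = 4.2
    hi = max(lo + 0.2, limit - 0.2)
    for _ in range(max_tries):
        rot = Rotation.random(random_state=rng).as_matrix()
        xyz = (dom.ca - dom.ca.mean(axis=0)) @ rot.T
        v = _random_unit(rng) * rng.uniform(lo, hi)
        shift = anchor + v - xyz[attach_atom]
        cand = xyz + shift
        if _interface_ok(prev_ca, cand):
            return cand
    return None


def make_toy_multidomain(spec: ToySpec):
    """Build a synthetic multi-domain native and its split domain models.

    Returns ``(native_coords, domains, layout)`` where ``native_coords`` is
    the full-chain CA array in residue-id order and each returned
    :class:`DomainModel` stores its native placement (identity poses
    reproduce the native).  Consecutive domains share at least 10 CA pairs
    within 8 A, all inter-domain pairs are at least ~4 A apart, and the
    flanking CA atoms across every linker satisfy the 3.8 * (gap + 1) A
    connectivity bound, so every assembly penalty term vanishes at the
    native.
    """
    rng = np.random.default_rng(spec.seed)
    g = spec.linker_gap
    sizes = spec.residues_per_domain

    if spec.topology == "continuous":
        domains: list[DomainModel] = []
        start = 1
        raw = []
        for d in range(spec.n_domains):
            raw.append(make_toy_domain(sizes[d], spec.fold,
                                       seed=spec.seed * 1000 + 17 * d,
                                       domain_id=d + 1, start_id=start))
            start += sizes[d] + g
        placed = [raw[0].ca]
        for d in range(1, spec.n_domains):
            prev_all = np.vstack(placed)
            anchor = placed[d - 1][-1]  # C-terminal CA of the previous domain
            ok = _place_next(prev_all, anchor, raw[d], attach_atom=0, gap=g, rng=rng)
            if ok is None:
                raise RuntimeError("domain placement failed after 1000 attempts")
            placed.append(ok)
        for d in range(spec.n_domains):
            raw[d].ca = placed[d]
            domains.append(raw[d])
    elif spec.topology == "discontinuous":
        # domain 1 is the host (two segments); domain 2 is inserted into it
        n_host, n_ins = sizes[0], sizes[1]
        host_xyz = None
        for attempt in range(1000):
            host_raw = make_toy_domain(n_host, spec.fold,
                                       seed=spec.seed * 1000 + attempt,
                                       domain_id=1)
            split = n_host // 2
            p_left, p_right = host_raw.ca[split - 1], host_raw.ca[split]
            ins_raw = make_toy_domain(n_ins, spec.fold,
                                      seed=spec.seed * 1000 + 500 + attempt,
                                      domain_id=2)
            # both insert termini must reach the host split point
            anchor = 0.5 * (p_left + p_right)
            limit = CA_STEP * (g + 1)
            placed_ins = None
            for _ in range(400):
                rot = Rotation.random(random_state=rng).as_matrix()
                xyz = (ins_raw.ca - ins_raw.ca.mean(axis=0)) @ rot.T
                mid_term = 0.5 * (xyz[0] + xyz[-1])
                out = anchor - host_raw.ca.mean(axis=0)
                out /= np.linalg.norm(out)
                offset = rng.uniform(5.0, 9.0)
                cand = xyz + (anchor + out * offset - mid_term)
                if (np.linalg.norm(cand[0] - p_left) <= limit - 0.2
                        and np.linalg.norm(cand[-1] - p_right) <= limit - 0.2
                        and _interface_ok(host_raw.ca, cand)):
                    placed_ins = cand
                    break
            if placed_ins is None:
                continue
            host_xyz, ins_xyz, split_at = host_raw.ca, placed_ins, split
            host_names = host_raw.residue_names
            break
        if host_xyz is None:
            raise RuntimeError("discontinuous placement failed after 1000 attempts")

        a = split_at
        seg1 = Segment(1, a)
        ins_start = a + g + 1
        ins_seg = Segment(ins_start, ins_start + n_ins - 1)
        seg2_start = ins_seg.end + g + 1
        seg2 = Segment(seg2_start, seg2_start + (n_host - a) - 1)
        host_ids = np.concatenate([np.arange(1, a + 1),
                                   np.arange(seg2_start, seg2.end + 1)])
        host = DomainModel(domain_id=1, segments=[seg1, seg2],
                           residue_ids=host_ids,
                           residue_names=["ALA"] * n_host, ca=host_xyz)
        insert = DomainModel(domain_id=2, segments=[ins_seg],
                             residue_ids=np.arange(ins_seg.start, ins_seg.end + 1),
                             residue_names=["ALA"] * n_ins, ca=ins_xyz)
        domains = [host, insert]
    else:
        raise ValueError(f"unknown topology {spec.topology!r}")

    layout = infer_layout(domains)
    ids = np.concatenate([d.residue_ids for d in domains])
    coords = np.vstack([d.ca for d in domains])
    order = np.argsort(ids)
    return coords[order], domains, layout


def scramble(domains, max_rot_deg: float, max_trans: float, seed: int) -> list[RigidPose]:
    """Seeded random rigid perturbation of every domain (about its centroid)."""
    rng = np.random.default_rng(seed)
    poses = []
    for _ in domains:
        if max_rot_deg <= 0 and max_trans <= 0:
            poses.append(RigidPose.identity())
            continue
        angle = np.deg2rad(rng.uniform(0, max(max_rot_deg, 0)))
        axis = _random_unit(rng)
        rotm = Rotation.from_rotvec(angle * axis).as_matrix()
        trans = _random_unit(rng) * rng.uniform(0, max(max_trans, 0))
        poses.append(RigidPose.from_matrix(rotm, trans))
    return poses
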