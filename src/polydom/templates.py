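"""Global/local template identification and initial-model construction.

Templates are library structures that contain analogues of several of the
query's domains.  Each template is scored by the harmonic mean of the
per-domain TM-scores (TM-score_h): a *local* evaluation aligns every domain
independently (alignment overlap on the template is allowed), and the
top-scoring templates are re-scored by a *global* evaluation in which the
template residues claimed by earlier domains are masked before aligning the
next domain, run both N-to-C and C-to-N with the better direction kept.
If even the best global template fails to cover some domain (per-domain
TM-score < 0.5), templates for the broken parts are detected independently
and merged.  Top templates yield initial full-length models by applying
each domain's alignment superposition, with a sliding-window translation
step to pull apart domains that land on top of each other.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .core import ChainLayout, DomainModel, RigidPose, read_domain_pdb
from .metrics import AlignmentMap, Superposition, harmonic_tm_score, structural_align

__all__ = [
    "TemplateHit",
    "InitialModel",
    "load_library",
    "local_evaluate",
    "global_evaluate",
    "rank_library",
    "build_initial_models",
]

SCORE_FLOOR = 1e-3   # keeps the harmonic mean defined when an alignment fails
COVER_TM = 0.5       # a domain with TM-score_d below this is not covered
HARD_CLASH = 3.0     # CA pairs closer than this trigger the sliding step


@dataclass
class TemplateHit:
    template_id: str
    template_coords: np.ndarray
    # entry per query domain (same order as the domain list); None = not evaluated
    per_domain: list[Optional[tuple[AlignmentMap, float, Optional[Superposition]]]]
    tm_h: float
    mode: str = "local-eval"          # or "global-eval"
    direction: str = "N-C"            # or "C-N"
    covered_domains: set[int] = field(default_factory=set)


@dataclass
class InitialModel:
    poses: list[RigidPose]
    source: str                        # template id or "random"
    clash_count: int = 0


def load_library(path: str | Path) -> list[tuple[str, np.ndarray]]:
    """Load a template library: a directory of single-chain PDB files with an
    optional plain-text index (one ``id path`` per line)."""
    path = Path(path)
    entries: list[tuple[str, Path]] = []
    if path.is_dir():
        index = path / "index.txt"
        if index.exists():
            for line in index.read_text().splitlines():
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                tid, rel = line.split()[:2]
                entries.append((tid, path / rel))
        else:
            entries = [(p.stem, p) for p in sorted(path.glob("*.pdb"))]
    else:
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, rel = line.split()[:2]
            entries.append((tid, path.parent / rel))
    return [(tid, read_domain_pdb(p, domain_id=0).ca) for tid, p in entries]


# ---------------------------------------------------------------------------
# evaluation


def _eval_domain(domain: DomainModel, tmpl_coords: np.ndarray):
    amap, tm = structural_align(domain.ca, tmpl_coords)
    sup = None
    if len(amap) >= 3:
        from .metrics import kabsch

        try:
            sup = kabsch(domain.ca, tmpl_coords, amap)
        except ValueError:
            sup = None
    return amap, tm, sup


def local_evaluate(domains: Sequence[DomainModel], template_id: str,
                   template_coords: np.ndarray) -> TemplateHit:
    """Score a template by aligning each domain independently (overlap of
    different domains' alignments on the template is allowed)."""
    per_domain = []
    scores = []
    covered = set()
    for d in domains:
        amap, tm, sup = _eval_domain(d, template_coords)
        per_domain.append((amap, tm, sup))
        scores.append(max(tm, SCORE_FLOOR))
        if tm >= COVER_TM:
            covered.add(d.domain_id)
    return TemplateHit(
        template_id=template_id,
        template_coords=np.asarray(template_coords, float),
        per_domain=per_domain,
        tm_h=harmonic_tm_score(scores),
        mode="local-eval",
        covered_domains=covered,
    )


def global_evaluate(domains: Sequence[DomainModel], template_id: str,
                    template_coords: np.ndarray, direction: str = "N-C",
                    chain_order: Optional[Sequence[int]] = None,
                    local_scores: Optional[Sequence[float]] = None) -> TemplateHit:
    """Score a template with alignment overlap forbidden: domains are
    aligned in chain order (or reversed), and template residues claimed by
    earlier domains are masked before aligning the next.

    Each domain's score is capped at its unconstrained full-template
    (local) score: the alignment search is heuristic, and a search on a
    masked subset of the template occasionally lands in a better local
    optimum than the full-template search did.  The constrained threading
    must never outrank the local evaluation on search noise alone, so the
    full-template value (``local_scores`` when supplied, recomputed
    otherwise) is an upper bound on the reported per-domain score."""
    tmpl = np.asarray(template_coords, float)
    n_t = len(tmpl)
    order = list(chain_order) if chain_order is not None else list(range(len(domains)))
    if direction == "C-N":
        order = order[::-1]
    elif direction != "N-C":
        raise ValueError(f"unknown direction {direction!r}")

    available = np.ones(n_t, bool)
    per_domain: list = [None] * len(domains)
    scores = [SCORE_FLOOR] * len(domains)
    covered = set()
    for k in order:
        d = domains[k]
        idx_avail = np.flatnonzero(available)
        if len(idx_avail) < 5:
            per_domain[k] = (AlignmentMap(np.zeros((0, 2), int)), 0.0, None)
            continue
        sub = tmpl[idx_avail]
        amap, tm, sup = _eval_domain(d, sub)
        if len(idx_avail) < n_t:
            cap = (local_scores[k] if local_scores is not None
                   else _eval_domain(d, tmpl)[1])
            tm = min(tm, cap)
        # map alignment reference indices back into the full template
        if len(amap):
            full_pairs = np.column_stack([amap.pairs[:, 0], idx_avail[amap.pairs[:, 1]]])
            amap = AlignmentMap(full_pairs)
            available[full_pairs[:, 1]] = False
        per_domain[k] = (amap, tm, sup)
        scores[k] = max(tm, SCORE_FLOOR)
        if tm >= COVER_TM:
            covered.add(d.domain_id)
    return TemplateHit(
        template_id=template_id,
        template_coords=tmpl,
        per_domain=per_domain,
        tm_h=harmonic_tm_score(scores),
        mode="global-eval",
        direction=direction,
        covered_domains=covered,
    )


def _sorted_hits(hits: list[TemplateHit]) -> list[TemplateHit]:
    return sorted(hits, key=lambda h: (-round(h.tm_h, 9), h.template_id))


def rank_library(
    domains: Sequence[DomainModel],
    layout: ChainLayout,
    library: Sequence[tuple[str, np.ndarray]],
    top_global: int = 10,
    top_local: int = 10,
    stage1_keep: int = 500,
    _depth: int = 0,
):
    """Two-stage template ranking.

    Stage 1 scores every library entry by local evaluation and keeps the
    top ``stage1_keep``; stage 2 re-scores those globally (both directions,
    better one kept).  If the best global hit leaves a domain uncovered
    (TM-score_d < 0.5) the two broken parts are ranked independently and
    their hits merged.  Local hits for every consecutive domain pair are
    returned when there are at least three domains.  Ties break on the
    template id, so results are deterministic given the library.

    Returns ``(global_hits, local_pair_hits)`` where ``local_pair_hits``
    maps a (domain_id, domain_id) pair to its hit list.
    """
    if not library:
        return [], {}
    did_to_idx = {d.domain_id: k for k, d in enumerate(domains)}
    chain_order = [did_to_idx[i] for i in layout.domain_order if i in did_to_idx]

    local_hits = _sorted_hits(
        [local_evaluate(domains, tid, coords) for tid, coords in library]
    )
    stage2 = local_hits[:stage1_keep]
    global_hits = []
    for lh in stage2:
        best = None
        for direction in ("N-C", "C-N"):
            gh = global_evaluate(domains, lh.template_id, lh.template_coords,
                                 direction=direction, chain_order=chain_order,
                                 local_scores=[t[1] for t in lh.per_domain])
            if best is None or gh.tm_h > best.tm_h:
                best = gh
        global_hits.append(best)
    global_hits = _sorted_hits(global_hits)

    # broken-template recursion: detect templates for uncovered parts
    if global_hits and len(domains) >= 2 and _depth < len(domains):
        best = global_hits[0]
        uncovered = [d for d in domains if d.domain_id not in best.covered_domains]
        covered = [d for d in domains if d.domain_id in best.covered_domains]
        if uncovered and covered:
            for part in (covered, uncovered):
                sub_global, _ = rank_library(
                    part, layout, library, top_global=top_global,
                    top_local=top_local, stage1_keep=stage1_keep,
                    _depth=_depth + 1,
                )
                for sh in sub_global[:top_global]:
                    merged = [None] * len(domains)
                    for k, d in enumerate(part):
                        merged[did_to_idx[d.domain_id]] = sh.per_domain[k]
                    global_hits.append(
                        TemplateHit(
                            template_id=sh.template_id,
                            template_coords=sh.template_coords,
                            per_domain=merged,
                            tm_h=sh.tm_h,
                            mode=sh.mode,
                            direction=sh.direction,
                            covered_domains=sh.covered_domains,
                        )
                    )

    local_pair_hits: dict[tuple[int, int], list[TemplateHit]] = {}
    if len(domains) >= 3 and _depth == 0:
        for a, b in zip(layout.domain_order, layout.domain_order[1:]):
            pair = [domains[did_to_idx[a]], domains[did_to_idx[b]]]
            hits = _sorted_hits(
                [local_evaluate(pair, tid, coords) for tid, coords in library]
            )[:top_local]
            remapped = []
            for h in hits:
                merged = [None] * len(domains)
                merged[did_to_idx[a]] = h.per_domain[0]
                merged[did_to_idx[b]] = h.per_domain[1]
                remapped.append(
                    TemplateHit(template_id=h.template_id,
                                template_coords=h.template_coords,
                                per_domain=merged, tm_h=h.tm_h,
                                mode="local-eval",
                                covered_domains=h.covered_domains)
                )
            local_pair_hits[(a, b)] = remapped

    return global_hits[:top_global] if _depth == 0 else global_hits, local_pair_hits


# ---------------------------------------------------------------------------
# initial models


def _pose_from_superposition(domain: DomainModel, sup: Superposition) -> RigidPose:
    c = domain.centroid
    trans = sup.rotation @ c + sup.translation - c
    return RigidPose.from_matrix(sup.rotation, trans)


def _slide_apart(coords: list[np.ndarray], chain_rank: list[int],
                 max_steps: int = 30) -> tuple[list[np.ndarray], list[np.ndarray], int]:
    """Translate chain-later domains along the inter-centroid vector in 1 A
    steps until no hard clash remains (or the step budget is exhausted)."""
    shifts = [np.zeros(3) for _ in coords]
    for _ in range(max_steps):
        worst = None
        for a in range(len(coords)):
            for b in range(a + 1, len(coords)):
                dmin = cdist(coords[a], coords[b]).min()
                if dmin < HARD_CLASH and (worst is None or dmin < worst[0]):
                    worst = (dmin, a, b)
        if worst is None:
            break
        _, a, b = worst
        later = b if chain_rank[b] > chain_rank[a] else a
        other = a if later == b else b
        v = coords[later].mean(axis=0) - coords[other].mean(axis=0)
        nrm = np.linalg.norm(v)
        v = v / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
        coords[later] = coords[later] + v
        shifts[later] = shifts[later] + v
    clashes = 0
    for a in range(len(coords)):
        for b in range(a + 1, len(coords)):
            clashes += int((cdist(coords[a], coords[b]) < HARD_CLASH).sum())
    return coords, shifts, clashes


def _random_tandem_starts(domains, layout, seed: int, n: int) -> list[InitialModel]:
    """Chain-like fallback: domains along +x at centroid spacing equal to the
    sum of their radii of gyration plus 5 A, with seeded perturbations."""
    rng = np.random.default_rng(seed)
    did_to_idx = {d.domain_id: k for k, d in enumerate(domains)}
    rank = {did: r for r, did in enumerate(layout.domain_order)}
    out = []
    for m in range(n):
        poses = [RigidPose.identity() for _ in domains]
        x = 0.0
        prev_rg = None
        for did in layout.domain_order:
            k = did_to_idx[did]
            d = domains[k]
            if prev_rg is not None:
                x += prev_rg + d.radius_of_gyration + 5.0
            target = np.array([x, 0.0, 0.0])
            if m == 0:
                rotm = np.eye(3)
                jitter = np.zeros(3)
            else:
                angle = rng.uniform(0, np.deg2rad(180))
                axis = rng.normal(size=3)
                axis /= np.linalg.norm(axis)
                rotm = Rotation.from_rotvec(angle * axis).as_matrix()
                jitter = rng.normal(0, 2.0, 3)
            poses[k] = RigidPose.from_matrix(rotm, target - d.centroid + jitter)
            prev_rg = d.radius_of_gyration
        out.append(InitialModel(poses=poses, source="random"))
    return out


def build_initial_models(
    hits: Sequence[TemplateHit],
    domains: Sequence[DomainModel],
    layout: ChainLayout,
    seed: int = 0,
    n_max: int = 20,
) -> list[InitialModel]:
    """Initial full-length models from template hits (or random fallback).

    Covered domains are placed by their alignment superpositions; uncovered
    domains go next to their nearest covered sequence neighbor along the
    neighbor's centroid-to-terminus direction.  Domains that land closer
    than 3 A are pulled apart by 1 A sliding steps along the inter-centroid
    vector (at most 30), and the residual hard-clash count is recorded.
    """
    did_to_idx = {d.domain_id: k for k, d in enumerate(domains)}
    rank_of_idx = [0] * len(domains)
    for r, did in enumerate(layout.domain_order):
        rank_of_idx[did_to_idx[did]] = r

    models: list[InitialModel] = []
    for hit in hits:
        poses: list[Optional[RigidPose]] = [None] * len(domains)
        for k, d in enumerate(domains):
            entry = hit.per_domain[k] if hit.per_domain else None
            if entry is None:
                continue
            amap, tm, sup = entry
            if sup is not None and len(amap) >= 3 and tm >= COVER_TM:
                poses[k] = _pose_from_superposition(d, sup)
        if not any(p is not None for p in poses):
            continue
        # place uncovered domains next to their nearest covered chain neighbor
        order = sorted(range(len(domains)), key=lambda k: rank_of_idx[k])
        for k in order:
            if poses[k] is not None:
                continue
            d = domains[k]
            neighbor = None
            for j in sorted(range(len(domains)),
                            key=lambda j: abs(rank_of_idx[j] - rank_of_idx[k])):
                if j != k and poses[j] is not None:
                    neighbor = j
                    break
            if neighbor is None:
                poses[k] = RigidPose.identity()
                continue
            nd = domains[neighbor]
            placed = transform_coords_of(nd, poses[neighbor])
            cen = placed.mean(axis=0)
            term = placed[-1] if rank_of_idx[k] > rank_of_idx[neighbor] else placed[0]
            v = term - cen
            nrm = np.linalg.norm(v)
            v = v / nrm if nrm > 1e-6 else np.array([1.0, 0.0, 0.0])
            target = term + v * (d.radius_of_gyration + 5.0)
            poses[k] = RigidPose(trans=target - d.centroid)
        coords = [transform_coords_of(d, p) for d, p in zip(domains, poses)]
        coords, shifts, clashes = _slide_apart(coords, rank_of_idx)
        for k in range(len(domains)):
            poses[k] = RigidPose(rot=poses[k].rot, trans=poses[k].trans + shifts[k])
        models.append(InitialModel(poses=list(poses), source=hit.template_id,
                                   clash_count=clashes))
        if len(models) >= n_max:
            break

    if not models:
        models = _random_tandem_starts(domains, layout, seed, n_max)
    return models[:n_max]


def transform_coords_of(domain: DomainModel, pose: RigidPose) -> np.ndarray:
    from .core import apply_pose

    return apply_pose(domain, pose)
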