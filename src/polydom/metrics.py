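"""Superposition and structural similarity metrics.

Provides least-squares (Kabsch) superposition, the TM-score under a fixed
residue correspondence (maximized over superpositions by a fragment-seeded
iterative search), a simplified structural aligner in the TM-align spirit,
the harmonic mean of per-domain TM-scores used for template ranking, and the
rTM-score, a single-superposition TM-score that fully penalizes errors in
relative domain orientation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .core import AssemblyModel

__all__ = [
    "Superposition",
    "AlignmentMap",
    "kabsch",
    "tm_d0",
    "tm_score",
    "structural_align",
    "harmonic_tm_score",
    "r_tm_score",
]


@dataclass
class Superposition:
    rotation: np.ndarray   # (3,3), proper
    translation: np.ndarray
    rmsd: float

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


@dataclass
class AlignmentMap:
    """Residue correspondences (query position, reference position).

    Positions are 0-based indices into the coordinate arrays; pairs must be
    strictly increasing in both coordinates (sequential alignment).
    """

    pairs: np.ndarray  # (n, 2) int

    def __post_init__(self) -> None:
        self.pairs = np.asarray(self.pairs, dtype=int).reshape(-1, 2)
        if len(self.pairs) > 1:
            d = np.diff(self.pairs, axis=0)
            if not (d > 0).all():
                raise ValueError("alignment must be strictly increasing in both coordinates")

    def __len__(self) -> int:
        return len(self.pairs)

    @classmethod
    def identity(cls, n: int) -> "AlignmentMap":
        idx = np.arange(n)
        return cls(np.column_stack([idx, idx]))


def kabsch(
    query_coords: np.ndarray, ref_coords: np.ndarray, pairs: AlignmentMap
) -> Superposition:
    """Least-squares rigid superposition of the paired atoms (query -> ref)."""
    if len(pairs) < 3:
        raise ValueError(f"need >= 3 pairs for superposition, got {len(pairs)}")
    q = np.asarray(query_coords, float)[pairs.pairs[:, 0]]
    r = np.asarray(ref_coords, float)[pairs.pairs[:, 1]]
    qc, rc = q.mean(axis=0), r.mean(axis=0)
    cov = (q - qc).T @ (r - rc)
    if np.linalg.matrix_rank(cov, tol=1e-9) < 2:
        raise ValueError("degenerate (collinear) point sets: superposition is not unique")
    rot_obj, rssd = Rotation.align_vectors(r - rc, q - qc)
    rotation = rot_obj.as_matrix()
    translation = rc - rotation @ qc
    rmsd = float(rssd / np.sqrt(len(pairs)))
    return Superposition(rotation=rotation, translation=translation, rmsd=rmsd)


def tm_d0(l_norm: int) -> float:
    """Length-dependent normalization distance of the TM-score kernel."""
    return max(0.5, 1.24 * np.cbrt(max(l_norm - 15, 0)) - 1.8) if l_norm > 15 else 0.5


def _kernel_sum(q: np.ndarray, r: np.ndarray, d0: float) -> float:
    d2 = ((q - r) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / d0 ** 2)).sum())


def _refine_superposition(
    q: np.ndarray, r: np.ndarray, sup: Superposition, d0: float, max_iter: int = 30
) -> tuple[Superposition, float]:
    """Iteratively re-superpose on the well-fitting subset until a fixed point."""
    n = len(q)
    best_sup, best_sum = sup, _kernel_sum(sup.apply(q), r, d0)
    cutoff = max(d0, 3.5)
    prev_sel: np.ndarray | None = None
    cur = sup
    for _ in range(max_iter):
        d = np.linalg.norm(cur.apply(q) - r, axis=1)
        sel = d < cutoff
        if sel.sum() < 3:
            cutoff += 0.5
            continue
        if prev_sel is not None and np.array_equal(sel, prev_sel):
            break
        prev_sel = sel
        idx = np.flatnonzero(sel)
        try:
            cur = kabsch(q, r, AlignmentMap(np.column_stack([idx, idx])))
        except ValueError:
            break
        s = _kernel_sum(cur.apply(q), r, d0)
        if s > best_sum:
            best_sum, best_sup = s, cur
    return best_sup, best_sum


def tm_score(
    query: np.ndarray,
    ref: np.ndarray,
    pairs: AlignmentMap,
    l_norm: int,
    return_superposition: bool = False,
):
    """TM-score of a fixed correspondence, maximized over superpositions.

    Seeds are all gapless windows of the pair list at lengths
    {L_ali, L_ali // 2, 4}; each seed superposition is refined by re-fitting
    on the residues currently within a distance cutoff until a fixed point.
    """
    if len(pairs) == 0:
        raise ValueError("empty alignment")
    if l_norm < 1:
        raise ValueError("l_norm must be >= 1")
    q = np.asarray(query, float)[pairs.pairs[:, 0]]
    r = np.asarray(ref, float)[pairs.pairs[:, 1]]
    n = len(q)
    d0 = tm_d0(l_norm)

    lengths = sorted({n, max(n // 2, 3), min(4, n)}, reverse=True)
    best_sum, best_sup = -1.0, None
    for lw in lengths:
        if lw < 3:
            continue
        for start in range(0, n - lw + 1):
            idx = np.arange(start, start + lw)
            try:
                seed = kabsch(q, r, AlignmentMap(np.column_stack([idx, idx])))
            except ValueError:
                continue
            sup, s = _refine_superposition(q, r, seed, d0)
            if s > best_sum:
                best_sum, best_sup = s, sup
    if best_sup is None:
        raise ValueError("no non-degenerate seed window found")
    score = best_sum / l_norm
    if return_superposition:
        return score, best_sup
    return score


def harmonic_tm_score(per_domain_scores) -> float:
    """Harmonic mean of per-domain TM-scores (the template-ranking score)."""
    scores = np.asarray(per_domain_scores, float)
    if scores.size == 0:
        raise ValueError("no scores given")
    if (scores <= 0).any():
        raise ValueError("all TM-scores must be positive")
    return float(len(scores) / (1.0 / scores).sum())


# ---------------------------------------------------------------------------
# Simplified structural alignment (TM-align-style: DP over a TM-score kernel
# similarity matrix alternated with superposition refits, from gapless seeds)

_GAP_PENALTY = -0.6


def _dp_align(sim: np.ndarray) -> np.ndarray:
    """Global alignment with linear gap penalty; returns (n,2) pair indices."""
    lq, lr = sim.shape
    f = np.zeros((lq + 1, lr + 1))
    g = _GAP_PENALTY
    j = np.arange(lr + 1)
    for i in range(1, lq + 1):
        diag = f[i - 1, :-1] + sim[i - 1]
        up = f[i - 1, 1:] + g
        row = np.maximum(diag, up)
        # horizontal moves: f[i,j] = max(row[j-1], f[i,j-1] + g)
        h = np.maximum.accumulate(np.concatenate([[f[i, 0]], row]) - j * g)
        f[i, 1:] = (h + j * g)[1:]
    # traceback
    pairs = []
    i, jj = lq, lr
    while i > 0 and jj > 0:
        if np.isclose(f[i, jj], f[i - 1, jj - 1] + sim[i - 1, jj - 1]):
            pairs.append((i - 1, jj - 1))
            i -= 1
            jj -= 1
        elif np.isclose(f[i, jj], f[i - 1, jj] + g):
            i -= 1
        else:
            jj -= 1
    return np.array(pairs[::-1], dtype=int).reshape(-1, 2)


def _seed_superpositions(q: np.ndarray, r: np.ndarray, d0_sq: float,
                         n_keep: int = 10) -> list[Superposition]:
    """Score gapless diagonal seeds (full overlap + short fragments) cheaply
    and keep the most promising superpositions for DP refinement."""
    lq, lr = len(q), len(r)
    min_ov = 5
    scored: list[tuple[float, Superposition]] = []
    for offset in range(-(lq - min_ov), lr - min_ov + 1):
        qi0, ri0 = max(0, -offset), max(0, offset)
        ov = min(lq - qi0, lr - ri0)
        if ov < min_ov:
            continue
        qi = np.arange(qi0, qi0 + ov)
        ri = np.arange(ri0, ri0 + ov)
        lf = min(20, ov)
        starts = {0, (ov - lf) // 2, ov - lf}
        windows = [np.arange(s, s + lf) for s in starts]
        windows.append(np.arange(ov))  # full overlap
        for w in windows:
            try:
                sup = kabsch(q, r, AlignmentMap(np.column_stack([qi[w], ri[w]])))
            except ValueError:
                continue
            d2 = ((sup.apply(q[qi]) - r[ri]) ** 2).sum(axis=1)
            s = float((1.0 / (1.0 + d2 / d0_sq)).sum())
            scored.append((s, sup))
    scored.sort(key=lambda t: -t[0])
    return [sup for _, sup in scored[:n_keep]]


def structural_align(query_coords: np.ndarray, ref_coords: np.ndarray,
                     max_iter: int = 30, n_seeds: int = 10):
    """Sequence-order structural alignment of two CA traces.

    Gapless diagonal seeds are scored under fragment superpositions; the
    best seeds are refined by alternating dynamic programming over a
    TM-score-kernel similarity matrix with superposition refits until the
    alignment stops changing.  Returns ``(AlignmentMap, tm)`` with the
    TM-score normalized by the query length; an empty alignment with
    tm = 0 when no seed yields at least 4 aligned pairs.
    """
    q = np.asarray(query_coords, float)
    r = np.asarray(ref_coords, float)
    lq, lr = len(q), len(r)
    if lq < 5 or lr < 5:
        raise ValueError("structures must have at least 5 residues")
    d0 = tm_d0(lq)
    d0_sq = d0 * d0

    def align_score(pair_arr: np.ndarray, sup: Superposition) -> float:
        d2 = ((sup.apply(q[pair_arr[:, 0]]) - r[pair_arr[:, 1]]) ** 2).sum(axis=1)
        return float((1.0 / (1.0 + d2 / d0_sq)).sum()) / lq

    best_pairs, best_score, best_sup = None, 0.0, None
    for sup in _seed_superpositions(q, r, d0_sq, n_keep=n_seeds):
        pair_arr = np.zeros((0, 2), dtype=int)
        for _ in range(max_iter):
            qt = sup.apply(q)
            d2 = ((qt[:, None, :] - r[None, :, :]) ** 2).sum(axis=2)
            sim = 1.0 / (1.0 + d2 / d0_sq)
            new_pairs = _dp_align(sim)
            if len(new_pairs) < 4:
                break
            # keep only pairs contributing meaningful similarity
            qt_d2 = ((qt[new_pairs[:, 0]] - r[new_pairs[:, 1]]) ** 2).sum(axis=1)
            keep = qt_d2 < (3 * d0 + 4.0) ** 2
            if keep.sum() >= 4:
                new_pairs = new_pairs[keep]
            if pair_arr.shape == new_pairs.shape and np.array_equal(pair_arr, new_pairs):
                break
            pair_arr = new_pairs
            try:
                sup = kabsch(q, r, AlignmentMap(pair_arr))
            except ValueError:
                break
        if len(pair_arr) >= 4:
            s = align_score(pair_arr, sup)
            if s > best_score:
                best_pairs, best_score, best_sup = pair_arr, s, sup

    if best_pairs is None:
        return AlignmentMap(np.zeros((0, 2), dtype=int)), 0.0
    amap = AlignmentMap(best_pairs)
    tm = tm_score(q, r, amap, l_norm=lq)
    return amap, tm


# ---------------------------------------------------------------------------
# rTM-score


def r_tm_score(model: AssemblyModel, native_coords: np.ndarray,
               native_ids: np.ndarray) -> float:
    """TM-score under a single fixed superposition (no per-region refit).

    The model is superposed on the native once, using the Kabsch transform
    fitted on the residues of the single domain whose individual TM-score to
    the native is highest; with that transform fixed, the TM-score kernel is
    summed over all residues and normalized by the full length.  Because the
    relative orientation between domains cannot be absorbed by refitting,
    domain-orientation errors are fully penalized.
    """
    native_ids = np.asarray(native_ids, dtype=int)
    if model.coords.shape[0] != len(native_ids) or not np.array_equal(
        np.asarray(model.residue_ids, dtype=int), native_ids
    ):
        raise ValueError("model and native must cover the same residue set")
    nat = np.asarray(native_coords, float)
    n = len(nat)
    d0 = tm_d0(n)

    best_dom, best_tm = None, -1.0
    for dom in np.unique(model.domain_of_residue):
        mask = model.domain_of_residue == dom
        if mask.sum() < 3:
            continue
        amap = AlignmentMap.identity(int(mask.sum()))
        s = tm_score(model.coords[mask], nat[mask], amap, l_norm=int(mask.sum()))
        if s > best_tm:
            best_tm, best_dom = s, dom
    if best_dom is None:
        raise ValueError("no domain with >= 3 residues")

    mask = model.domain_of_residue == best_dom
    idx = np.flatnonzero(mask)
    sup = kabsch(model.coords, nat, AlignmentMap(np.column_stack([idx, idx])))
    d2 = ((sup.apply(model.coords) - nat) ** 2).sum(axis=1)
    return float((1.0 / (1.0 + d2 / d0 ** 2)).sum() / n)
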