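"""Cryo-EM density support: map simulation, real-space correlation,
per-domain map fitting, and two-stage density-guided assembly.

Model density is simulated as a sum of spherical Gaussians at CA positions
with sigma = 0.425 * resolution (so the kernel FWHM equals the nominal
resolution).  The fitting score is the Pearson correlation between the
experimental and model-simulated maps over voxels where either map carries
signal.  The assembly pipeline ends after the rigid-body stage: atomic-level
flexible refinement is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy import ndimage
from scipy.spatial.transform import Rotation

from .core import DomainModel, RigidPose, transform_coords

__all__ = [
    "DensityGrid",
    "simulate_map",
    "density_correlation",
    "read_map",
    "write_map",
    "fit_domain_to_map",
    "density_guided_assemble",
]

SIGMA_PER_RESOLUTION = 0.425  # FWHM = resolution
MAP_PADDING = 10.0            # Angstrom beyond the atom bounding box
SIGNAL_FLOOR = 1e-6           # voxel mask threshold, relative to each map's max


@dataclass
class DensityGrid:
    origin: np.ndarray        # (3,) Angstrom
    voxel: float              # isotropic voxel size, Angstrom
    values: np.ndarray        # (nx, ny, nz)

    def __post_init__(self) -> None:
        self.origin = np.asarray(self.origin, float)
        self.values = np.asarray(self.values, float)
        if self.voxel <= 0:
            raise ValueError("voxel size must be positive")
        if min(self.values.shape) < 2:
            raise ValueError("grid must have >= 2 voxels per axis")

    @property
    def dims(self) -> tuple[int, int, int]:
        return self.values.shape

    def voxel_centers_to_xyz(self, ijk: np.ndarray) -> np.ndarray:
        return self.origin + np.asarray(ijk, float) * self.voxel


def _splat_gaussians(coords: np.ndarray, origin: np.ndarray, voxel: float,
                     dims: tuple[int, int, int], sigma: float) -> np.ndarray:
    """Sum of spherical Gaussians accumulated on local patches (4 sigma cut)."""
    out = np.zeros(dims)
    half = int(np.ceil(4.0 * sigma / voxel))
    rel = np.arange(-half, half + 1)
    n_atoms = len(coords)
    base = np.round((coords - origin) / voxel).astype(int)          # (n, 3)
    # per-axis indices and Gaussian factors for every atom at once
    idx = base[:, None, :] + rel[None, :, None]                      # (n, k, 3)
    dist = idx * voxel + origin[None, None, :] - coords[:, None, :]
    gauss = np.exp(-dist ** 2 / (2 * sigma ** 2))
    valid = (idx >= 0) & (idx < np.array(dims)[None, None, :])
    gauss = np.where(valid, gauss, 0.0)
    idx = np.clip(idx, 0, np.array(dims)[None, None, :] - 1)
    k = len(rel)
    # outer product over the three axes -> (n, k, k, k) patch values
    patch = (gauss[:, :, None, None, 0]
             * gauss[:, None, :, None, 1]
             * gauss[:, None, None, :, 2])
    flat = (idx[:, :, None, None, 0] * dims[1] * dims[2]
            + idx[:, None, :, None, 1] * dims[2]
            + idx[:, None, None, :, 2]).reshape(n_atoms, -1)
    np.add.at(out.reshape(-1), flat.ravel(), patch.reshape(n_atoms, -1).ravel())
    return out


def simulate_map(coords: np.ndarray, resolution: float, voxel: float = 2.0) -> DensityGrid:
    """Simulate a density map from CA coordinates.

    Sum of spherical Gaussians (sigma = 0.425 * resolution), on a grid
    padded 10 A beyond the coordinate bounding box.
    """
    coords = np.asarray(coords, float)
    if coords.size == 0:
        raise ValueError("no coordinates to simulate a map from")
    if resolution < 2.0 * voxel:
        raise ValueError("resolution must be at least twice the voxel size")
    lo = coords.min(axis=0) - MAP_PADDING
    hi = coords.max(axis=0) + MAP_PADDING
    dims = tuple(int(np.ceil((hi[a] - lo[a]) / voxel)) + 1 for a in range(3))
    sigma = SIGMA_PER_RESOLUTION * resolution
    values = _splat_gaussians(coords, lo, voxel, dims, sigma)
    return DensityGrid(origin=lo, voxel=voxel, values=values)


def simulate_onto_grid(coords: np.ndarray, grid: DensityGrid,
                       resolution: float) -> np.ndarray:
    """Simulate model density on an existing grid's geometry."""
    sigma = SIGMA_PER_RESOLUTION * resolution
    return _splat_gaussians(np.asarray(coords, float), grid.origin, grid.voxel,
                            grid.dims, sigma)


def pearson_on_grid(map_values: np.ndarray, model_values: np.ndarray) -> float:
    """Masked Pearson correlation between two scalar fields on one grid."""
    a = np.asarray(map_values, float).ravel()
    b = np.asarray(model_values, float).ravel()
    amax = np.abs(a).max()
    bmax = np.abs(b).max()
    mask = np.zeros(a.shape, bool)
    if amax > 0:
        mask |= np.abs(a) > SIGNAL_FLOOR * amax
    if bmax > 0:
        mask |= np.abs(b) > SIGNAL_FLOOR * bmax
    if mask.sum() < 2:
        warnings.warn("no signal voxels; correlation undefined, returning 0")
        return 0.0
    av, bv = a[mask], b[mask]
    sa, sb = av.std(), bv.std()
    if sa < 1e-12 or sb < 1e-12:
        warnings.warn("zero-variance map under mask; returning 0")
        return 0.0
    return float(np.corrcoef(av, bv)[0, 1])


def density_correlation(coords: np.ndarray, grid: DensityGrid,
                        resolution: float) -> float:
    """Real-space correlation between a model and an experimental map."""
    model = simulate_onto_grid(coords, grid, resolution)
    return pearson_on_grid(grid.values, model)


# ---------------------------------------------------------------------------
# CCP4/MRC I/O (mode 2, orthogonal axes)


def write_map(grid: DensityGrid, path: str | Path) -> None:
    g = gemmi.FloatGrid(*grid.dims)
    np.asarray(g.array)[:] = grid.values.astype(np.float32)
    n = grid.dims
    g.set_unit_cell(gemmi.UnitCell(n[0] * grid.voxel, n[1] * grid.voxel,
                                   n[2] * grid.voxel, 90, 90, 90))
    m = gemmi.Ccp4Map()
    m.grid = g
    m.update_ccp4_header()
    for w, v in zip((50, 51, 52), grid.origin):
        m.set_header_float(w, float(v))
    m.write_ccp4_map(str(path))


def read_map(path: str | Path) -> DensityGrid:
    m = gemmi.read_ccp4_map(str(path))
    cell = m.grid.unit_cell
    if not (abs(cell.alpha - 90) < 1e-3 and abs(cell.beta - 90) < 1e-3
            and abs(cell.gamma - 90) < 1e-3):
        raise ValueError("only orthogonal map axes are supported")
    values = np.array(m.grid.array, dtype=float)
    voxel = cell.a / m.grid.nu
    vb = cell.b / m.grid.nv
    vc = cell.c / m.grid.nw
    if abs(vb - voxel) > 1e-3 or abs(vc - voxel) > 1e-3:
        raise ValueError("only isotropic voxels are supported")
    origin = np.array([m.header_float(w) for w in (50, 51, 52)])
    return DensityGrid(origin=origin, voxel=voxel, values=values)


# ---------------------------------------------------------------------------
# per-domain map fitting


def _map_local_maxima(grid: DensityGrid, n_peaks: int = 8) -> np.ndarray:
    """Positions (A) of the strongest local maxima of the low-pass map."""
    smooth = ndimage.gaussian_filter(grid.values, sigma=2.0)
    footprint = ndimage.maximum_filter(smooth, size=5)
    peaks = (smooth == footprint) & (smooth > 0.2 * smooth.max())
    ijk = np.argwhere(peaks)
    if len(ijk) == 0:
        ijk = np.array([np.unravel_index(np.argmax(smooth), smooth.shape)])
    vals = smooth[tuple(ijk.T)]
    top = ijk[np.argsort(-vals)][:n_peaks]
    return grid.voxel_centers_to_xyz(top)


def local_correlation(coords: np.ndarray, grid: DensityGrid,
                      resolution: float) -> float:
    """Correlation between map and model over the MODEL's support only.

    Used when fitting a part (one domain) into a map of the whole: the
    global mask of :func:`density_correlation` penalizes density the part
    cannot explain and rewards smearing it between blobs, whereas masking
    on the model support scores how well the part matches the density it
    actually occupies.
    """
    model = simulate_onto_grid(coords, grid, resolution)
    m = model.ravel()
    mmax = np.abs(m).max()
    if mmax <= 0:
        warnings.warn("model has no density on the grid; returning 0")
        return 0.0
    mask = np.abs(m) > SIGNAL_FLOOR * mmax
    if mask.sum() < 2:
        warnings.warn("model support below 2 voxels; returning 0")
        return 0.0
    a, b = grid.values.ravel()[mask], m[mask]
    sa, sb = a.std(), b.std()
    if sa < 1e-12 or sb < 1e-12:
        warnings.warn("zero-variance map under model mask; returning 0")
        return 0.0
    return float(np.corrcoef(a, b)[0, 1])


def _fit_coords_to_map(
    coords: np.ndarray,
    grid: DensityGrid,
    resolution: float,
    seed: int,
    n_orientations: int,
    n_starts: int,
    max_steps: int,
) -> list[tuple[RigidPose, float]]:
    """Multi-start rigid fit of a coordinate set, maximizing the
    model-masked local correlation; poses are about the centroid of
    ``coords`` and ranked by that correlation."""
    from scipy.optimize import minimize

    coords = np.asarray(coords, float)
    centroid = coords.mean(axis=0)
    peaks = _map_local_maxima(grid)
    rng = np.random.default_rng(seed)
    rots = [np.eye(3)] + [
        Rotation.random(rng=rng).as_matrix() for _ in range(n_orientations - 1)
    ]

    starts = []
    for peak in peaks:
        for rm in rots:
            pose = RigidPose.from_matrix(rm, peak - centroid)
            c = local_correlation(
                transform_coords(coords, pose, centroid), grid, resolution
            )
            starts.append((c, pose))
    starts.sort(key=lambda t: -t[0])
    starts = starts[:n_starts]

    def neg_corr(x: np.ndarray) -> float:
        pose = RigidPose.from_vector(x)
        return 1.0 - local_correlation(
            transform_coords(coords, pose, centroid), grid, resolution
        )

    def grad(x: np.ndarray, step: float = 1e-3) -> np.ndarray:
        g = np.empty_like(x)
        for k in range(len(x)):
            xp = x.copy(); xp[k] += step
            xm = x.copy(); xm[k] -= step
            g[k] = (neg_corr(xp) - neg_corr(xm)) / (2 * step)
        return g

    results = []
    for _c0, pose in starts:
        res = minimize(neg_corr, pose.as_vector(), jac=grad, method="L-BFGS-B",
                       options={"maxiter": max_steps, "maxcor": 10})
        results.append((RigidPose.from_vector(res.x), 1.0 - float(res.fun)))
    results.sort(key=lambda t: -t[1])
    # collapse refined poses that landed on the same placement AND orientation
    kept: list[tuple[RigidPose, float]] = []
    for pose, corr in results:
        cen = transform_coords(coords, pose, centroid).mean(axis=0)
        distinct = True
        for kp, _ in kept:
            kcen = transform_coords(coords, kp, centroid).mean(axis=0)
            rel_ang = np.linalg.norm(
                Rotation.from_matrix(pose.matrix @ kp.matrix.T).as_rotvec()
            )
            if np.linalg.norm(cen - kcen) <= 3.0 and rel_ang <= np.deg2rad(30):
                distinct = False
                break
        if distinct:
            kept.append((pose, corr))
    return kept


def fit_domain_to_map(
    domain: DomainModel,
    grid: DensityGrid,
    resolution: float = 8.0,
    seed: int = 0,
    n_orientations: int = 8,
    n_starts: int = 5,
    max_steps: int = 50,
) -> list[tuple[RigidPose, float]]:
    """Rigidly fit one domain into a density map, guided purely by the
    density correlation.

    Starts place the domain centroid at the strongest local maxima of the
    low-pass map under seeded random orientations; the most correlated
    starts are refined by L-BFGS on 1 - correlation.  Returns distinct
    poses ranked by correlation (best first).
    """
    return _fit_coords_to_map(domain.ca, grid, resolution, seed,
                              n_orientations, n_starts, max_steps)


def _compose_global(pose: RigidPose, c_k: np.ndarray, r_g: np.ndarray,
                    c_g: np.ndarray, t_g: np.ndarray) -> RigidPose:
    """Compose a domain pose (about centroid ``c_k``) with a global rigid
    motion (rotation ``r_g`` about ``c_g`` plus translation ``t_g``),
    returning the equivalent single pose about ``c_k``."""
    r_new = r_g @ pose.matrix
    t_new = r_g @ (c_k + pose.trans - c_g) + c_g + t_g - c_k
    return RigidPose.from_matrix(r_new, t_new)


MAX_COMBOS = 16


def _prealign_starts(starts, problem, max_steps: int = 60):
    """Pull each start into the capture basin of the capped hybrid energy by
    minimizing the UNCAPPED Gaussian distance residuals plus chain
    connectivity.

    The capped wells of the assembly energy are flat far from the native
    distances, so a start with a flipped domain cannot be rotated out by
    stage 2; the uncapped objective keeps a global gradient.  Starts are
    returned unchanged when there are no Gaussian distance restraints.
    """
    from scipy.optimize import minimize

    cd = problem.distance
    if len(cd.g_i) == 0:
        return list(starts)
    bnd = problem.boundaries

    def obj(x: np.ndarray) -> float:
        poses = problem.poses_from_vector(x)
        coords = problem.full_coords(problem.coords_by_domain(poses))
        d = np.linalg.norm(coords[cd.g_i] - coords[cd.g_j], axis=1)
        e = float(np.sum(cd.g_w * ((d - cd.g_mean) / cd.g_sd) ** 2))
        if len(bnd):
            i, j = bnd[:, 0].astype(int), bnd[:, 1].astype(int)
            span = np.linalg.norm(coords[i] - coords[j], axis=1)
            e += float(np.sum(np.maximum(0.0, span - 3.8 * (bnd[:, 2] + 1)) ** 2))
        return e

    def grad(x: np.ndarray, step: float = 1e-4) -> np.ndarray:
        g = np.empty_like(x)
        for k in range(len(x)):
            xp = x.copy(); xp[k] += step
            xm = x.copy(); xm[k] -= step
            g[k] = (obj(xp) - obj(xm)) / (2 * step)
        return g

    out = []
    for poses in starts:
        x0 = np.concatenate([p.as_vector() for p in poses])
        res = minimize(obj, x0, jac=grad, method="L-BFGS-B",
                       options={"maxiter": max_steps, "maxcor": 10})
        out.append(problem.poses_from_vector(res.x))
    return out


def density_guided_assemble(problem, config):
    """Density-guided rigid-body assembly.

    Stage 1 fits every domain into the map independently (correlation
    only); initial models combine the top-2 poses of each domain, dropping
    combinations whose domains collapse onto the same density blob (clash
    test).  The start budget (16) is then filled with orientation-resampled
    copies of those combinations — at low resolution the per-domain fits
    constrain placement but barely constrain orientation — and every start
    is pre-aligned against the uncapped distance restraints (see
    :func:`_prealign_starts`).  Stage 2 re-optimizes each start under the
    full hybrid energy plus the density term.  Stage 3 docks each assembled
    model back into the map as a single rigid body (all non-density energy
    terms are invariant under a global rigid motion), and the results are
    ranked by full-model correlation, ties broken by energy.
    """
    from itertools import product

    from .assemble import AssemblyResult, lbfgs_minimize
    from .core import model_from_domains

    if problem.density is None:
        raise ValueError("problem has no density map attached")
    grid, resolution = problem.density, problem.resolution

    per_domain = []
    for k, d in enumerate(problem.domains):
        fits = fit_domain_to_map(d, grid, resolution=resolution,
                                 seed=config.seed + 101 * k,
                                 max_steps=min(config.max_steps, 60))
        per_domain.append(fits[:2] if len(fits) >= 2 else fits)

    combos = list(product(*[range(len(f)) for f in per_domain]))[:MAX_COMBOS]
    starts, fallback = [], None
    for combo in combos:
        poses = [per_domain[k][c][0] for k, c in enumerate(combo)]
        corr = sum(per_domain[k][c][1] for k, c in enumerate(combo))
        cbd = problem.coords_by_domain(poses)
        min_d = min(
            np.linalg.norm(cbd[a][:, None, :] - cbd[b][None, :, :], axis=2).min()
            for a in range(len(cbd)) for b in range(a + 1, len(cbd))
        ) if len(cbd) > 1 else np.inf
        if fallback is None or corr > fallback[0]:
            fallback = (corr, poses)
        if min_d >= 3.8:
            starts.append(poses)
    if not starts:
        starts = [fallback[1]]

    # orientation resampling: keep each domain's fitted placement (the moved
    # centroid is independent of the rotation about the input centroid) but
    # redraw its orientation, until the start budget is full
    rng = np.random.default_rng(config.seed + 555)
    base = list(starts)
    k = 0
    while len(starts) < MAX_COMBOS:
        tmpl = base[k % len(base)]
        starts.append([
            RigidPose.from_matrix(Rotation.random(rng=rng).as_matrix(), p.trans)
            for p in tmpl
        ])
        k += 1

    starts = _prealign_starts(starts, problem)

    # collapse starts that pre-aligned onto the same relative arrangement
    # (the global frame is re-docked in stage 3, so it adds no diversity)
    from .metrics import r_tm_score

    distinct_starts, seen_models = [], []
    for poses in starts:
        m = model_from_domains(problem.domains, poses)
        if any(r_tm_score(m, sm.coords, problem.residue_ids) > 0.98
               for sm in seen_models):
            continue
        distinct_starts.append(poses)
        seen_models.append(m)
    starts = distinct_starts

    models = []
    for si, poses in enumerate(starts):
        model = lbfgs_minimize(poses, problem, config,
                               provenance=f"density-start-{si}")
        full = model_from_domains(problem.domains, model.poses,
                                  provenance=model.provenance)
        full.energy_breakdown = model.energy_breakdown
        corr = density_correlation(full.coords, grid, resolution)
        models.append((corr, full))
    models.sort(key=lambda t: (-round(t[0], 6), t[1].total_energy))

    # stage 3: rigid re-dock of the top assembled models into the map.
    # Candidate global motions map one domain of the model onto one of its
    # stage-1 fitted placements; the best candidate by whole-model
    # correlation is refined by L-BFGS.
    from .energy import EnergyEvaluator

    ev = EnergyEvaluator(problem, config.weights)
    docked = []
    for corr, full in models[: config.keep_top]:
        g_corr, g_pose = _dock_model(full, problem, grid, resolution,
                                     per_domain)
        if g_corr > corr + 1e-6:
            c_g = full.coords.mean(axis=0)
            best_poses = [
                _compose_global(p, d.centroid, g_pose.matrix, c_g, g_pose.trans)
                for p, d in zip(full.poses, problem.domains)
            ]
            best_corr = g_corr
        else:
            best_poses, best_corr = full.poses, corr
        redone = model_from_domains(problem.domains, best_poses,
                                    provenance=full.provenance)
        xvec = np.concatenate([p.as_vector() for p in best_poses])
        redone.energy_breakdown = ev.breakdown(xvec).as_dict()
        redone.confidence["density_correlation"] = float(best_corr)
        docked.append((best_corr, redone))
    docked.sort(key=lambda t: (-round(t[0], 6), t[1].total_energy))
    ranked = [m for _c, m in docked][:config.keep_top]
    return AssemblyResult(models=ranked)


def _dock_model(full, problem, grid: DensityGrid, resolution: float,
                per_domain_fits) -> tuple[float, RigidPose]:
    """Best global rigid motion (about the model centroid) docking a whole
    assembled model into the map.

    Candidates: identity, plus for every domain and every stage-1 fit of
    that domain, the unique global motion that carries the model's copy of
    the domain onto the fitted placement.  The top candidates by
    whole-model correlation are refined by L-BFGS on 1 - correlation.
    """
    from scipy.optimize import minimize

    coords = full.coords
    c_g = coords.mean(axis=0)
    cands = [RigidPose.identity()]
    for k, fits in enumerate(per_domain_fits):
        d = problem.domains[k]
        p_k = full.poses[k]
        for f, _c in fits:
            r_g = f.matrix @ p_k.matrix.T
            t_g = (f.trans + d.centroid - c_g
                   - r_g @ (d.centroid + p_k.trans - c_g))
            cands.append(RigidPose.from_matrix(r_g, t_g))

    def corr_of(pose: RigidPose) -> float:
        return density_correlation(
            transform_coords(coords, pose, c_g), grid, resolution
        )

    scored = sorted(((corr_of(g), g) for g in cands), key=lambda t: -t[0])
    best_corr, best_pose = scored[0]

    def neg_corr(x: np.ndarray) -> float:
        return 1.0 - corr_of(RigidPose.from_vector(x))

    def grad(x: np.ndarray, step: float = 1e-3) -> np.ndarray:
        g = np.empty_like(x)
        for k in range(len(x)):
            xp = x.copy(); xp[k] += step
            xm = x.copy(); xm[k] -= step
            g[k] = (neg_corr(xp) - neg_corr(xm)) / (2 * step)
        return g

    for _c0, g0 in scored[:3]:
        res = minimize(neg_corr, g0.as_vector(), jac=grad, method="L-BFGS-B",
                       options={"maxiter": 40, "maxcor": 10})
        c = 1.0 - float(res.fun)
        if c > best_corr:
            best_corr, best_pose = c, RigidPose.from_vector(res.x)
    return best_corr, best_pose
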