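"""Inter-residue spatial restraints: containers, file I/O, and synthesis.

Restraints are keyed by full-chain residue-index pairs and come in four
channels: binned distance distributions (distograms), Gaussian distance
restraints (a compact dialect convenient for native-derived synthetic
restraints), interface contact probabilities, and inter-residue orientation
angles in the trRosetta convention.  Hydrogen-bond-network records are
parsed and stored but carry no energy.

File dialect (whitespace-delimited, one record per line, '#' comments):

    #BINS e0 e1 ... eK          bin edges in Angstrom for DGRAM records
    DIST  i j atom mean sd weight
    DGRAM i j atom p1 ... pK
    CON   i j prob
    ORI   i j omega theta_ij theta_ji phi_ij phi_ji weight
    HBNET i j value...          stored verbatim, no energy
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
from scipy.spatial.distance import cdist

__all__ = [
    "DistogramRestraint",
    "GaussianRestraint",
    "ContactRestraint",
    "OrientationRestraint",
    "RestraintSet",
    "default_bin_edges",
    "contacts_from_distograms",
    "synth_restraints_from_native",
    "read_restraints",
    "write_restraints",
]


def default_bin_edges(n_bins: int = 36, first: float = 2.0, last: float = 20.0) -> np.ndarray:
    return np.linspace(first, last, n_bins + 1)


@dataclass
class DistogramRestraint:
    i: int
    j: int
    atom: str                 # "CA" or "CB"
    bin_edges: np.ndarray     # (K+1,) ascending, Angstrom
    probs: np.ndarray         # (K,) sums to 1

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, float)
        self.probs = np.asarray(self.probs, float)
        if self.i >= self.j:
            raise ValueError("restraint requires i < j")
        if (self.probs < 0).any() or abs(self.probs.sum() - 1.0) > 1e-6:
            raise ValueError(
                f"distogram ({self.i},{self.j}): probabilities must be "
                f"non-negative and sum to 1 (got {self.probs.sum():.4f})"
            )
        if len(self.probs) != len(self.bin_edges) - 1:
            raise ValueError("bin count mismatch")


@dataclass
class GaussianRestraint:
    i: int
    j: int
    atom: str
    mean: float
    sd: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.i >= self.j:
            raise ValueError("restraint requires i < j")
        if self.sd <= 0:
            raise ValueError("sd must be positive")
        if self.weight < 0:
            raise ValueError("weight must be non-negative")


@dataclass
class ContactRestraint:
    i: int
    j: int
    prob: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.prob <= 1.0:
            raise ValueError("contact probability must be in [0, 1]")


@dataclass
class OrientationRestraint:
    i: int
    j: int
    omega: float
    theta_ij: float
    theta_ji: float
    phi_ij: float
    phi_ji: float
    weight: float = 1.0

    def __post_init__(self) -> None:
        pi = np.pi + 1e-9
        for name in ("omega", "theta_ij", "theta_ji"):
            v = getattr(self, name)
            if not -pi < v <= pi:
                raise ValueError(f"{name} out of (-pi, pi]: {v}")
        for name in ("phi_ij", "phi_ji"):
            v = getattr(self, name)
            if not 0.0 <= v <= np.pi + 1e-9:
                raise ValueError(f"{name} out of [0, pi]: {v}")


@dataclass
class RestraintSet:
    distograms: list[DistogramRestraint] = field(default_factory=list)
    gaussians: list[GaussianRestraint] = field(default_factory=list)
    contacts: list[ContactRestraint] = field(default_factory=list)
    orientations: list[OrientationRestraint] = field(default_factory=list)
    hbnets: list[str] = field(default_factory=list)
    note: str = ""

    def __post_init__(self) -> None:
        seen = set()
        for r in self.distograms + self.gaussians:
            key = (r.i, r.j, r.atom, type(r).__name__)
            if key in seen:
                raise ValueError(f"duplicate restraint for pair {key}")
            seen.add(key)

    @property
    def n_distance(self) -> int:
        return len(self.distograms) + len(self.gaussians)

    def __len__(self) -> int:
        return self.n_distance + len(self.contacts) + len(self.orientations)


# ---------------------------------------------------------------------------
# derived contacts


def contacts_from_distograms(rset: RestraintSet, cutoff: float = 18.0) -> list[ContactRestraint]:
    """Interface contact probabilities from CA distograms.

    The contact probability is the cumulative distogram probability below
    the cutoff: full bins below the cutoff plus the linear fraction of the
    bin the cutoff falls in.
    """
    out = []
    for dg in rset.distograms:
        if dg.atom != "CA":
            continue
        edges, probs = dg.bin_edges, dg.probs
        p = 0.0
        for k in range(len(probs)):
            lo, hi = edges[k], edges[k + 1]
            if hi <= cutoff:
                p += probs[k]
            elif lo < cutoff:
                p += probs[k] * (cutoff - lo) / (hi - lo)
        out.append(ContactRestraint(dg.i, dg.j, min(1.0, float(p))))
    if not out and rset.distograms:
        warnings.warn("no CA distograms present; no contacts derived")
    return out


# ---------------------------------------------------------------------------
# synthetic restraints from a native structure


def synth_restraints_from_native(
    native_coords: np.ndarray,
    residue_ids: np.ndarray,
    domain_of_residue: np.ndarray,
    mode: str = "exact",
    sd: float = 1.0,
    subsample: float = 1.0,
    seed: int = 0,
) -> RestraintSet:
    """Gaussian CA distance restraints measured on a native structure.

    Only inter-domain pairs are restrained — the domains themselves are
    rigid, so intra-domain distances carry no information for assembly.
    In ``noisy`` mode Normal(0, sd) noise is added to each measured
    distance; ``subsample`` keeps a seeded random fraction of the eligible
    pairs (count rounded to the nearest integer).
    """
    if mode not in ("exact", "noisy"):
        raise ValueError(f"unknown mode {mode!r}")
    if sd <= 0:
        raise ValueError("sd must be positive")
    coords = np.asarray(native_coords, float)
    ids = np.asarray(residue_ids, int)
    doms = np.asarray(domain_of_residue, int)
    iu, ju = np.triu_indices(len(ids), k=1)
    inter = doms[iu] != doms[ju]
    iu, ju = iu[inter], ju[inter]
    rng = np.random.default_rng(seed)
    if subsample < 1.0:
        n_keep = int(round(subsample * len(iu)))
        pick = rng.choice(len(iu), size=n_keep, replace=False)
        pick.sort()
        iu, ju = iu[pick], ju[pick]
    d = np.linalg.norm(coords[iu] - coords[ju], axis=1)
    if mode == "noisy":
        d = d + rng.normal(0.0, sd, size=len(d))
    gaussians = [
        GaussianRestraint(int(min(ids[a], ids[b])), int(max(ids[a], ids[b])),
                          "CA", float(max(m, 0.1)), sd, 1.0)
        for a, b, m in zip(iu, ju, d)
    ]
    return RestraintSet(gaussians=gaussians,
                        note=f"synthetic native-derived ({mode}, sd={sd}, "
                             f"subsample={subsample}, seed={seed})")


# ---------------------------------------------------------------------------
# file I/O


def write_restraints(rset: RestraintSet, path: str | Path) -> None:
    path = Path(path)
    lines = ["# polydom restraint file"]
    if rset.note:
        lines.append(f"# {rset.note}")
    edges_written = None
    for dg in rset.distograms:
        if edges_written is None or not np.array_equal(edges_written, dg.bin_edges):
            lines.append("#BINS " + " ".join(f"{e:g}" for e in dg.bin_edges))
            edges_written = dg.bin_edges
        lines.append(f"DGRAM {dg.i} {dg.j} {dg.atom} "
                     + " ".join(f"{p:.6g}" for p in dg.probs))
    for g in rset.gaussians:
        lines.append(f"DIST {g.i} {g.j} {g.atom} {g.mean:.4f} {g.sd:.4f} {g.weight:.4f}")
    for c in rset.contacts:
        lines.append(f"CON {c.i} {c.j} {c.prob:.6f}")
    for o in rset.orientations:
        lines.append(f"ORI {o.i} {o.j} {o.omega:.6f} {o.theta_ij:.6f} "
                     f"{o.theta_ji:.6f} {o.phi_ij:.6f} {o.phi_ji:.6f} {o.weight:.4f}")
    for h in rset.hbnets:
        lines.append(f"HBNET {h}")
    path.write_text("\n".join(lines) + "\n")


def read_restraints(path: str | Path) -> RestraintSet:
    path = Path(path)
    edges: Optional[np.ndarray] = None
    rset = RestraintSet()
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            if line.upper().startswith("#BINS"):
                edges = np.array([float(x) for x in line.split()[1:]])
                if len(edges) < 2 or (np.diff(edges) <= 0).any():
                    raise ValueError(f"{path}:{ln}: bin edges must be ascending")
            continue
        fields = line.split()
        kind = fields[0].upper()
        try:
            if kind == "DIST":
                i, j, atom = int(fields[1]), int(fields[2]), fields[3]
                mean, sd, w = map(float, fields[4:7])
                rset.gaussians.append(GaussianRestraint(i, j, atom, mean, sd, w))
            elif kind == "DGRAM":
                if edges is None:
                    raise ValueError("DGRAM record before any #BINS header")
                i, j, atom = int(fields[1]), int(fields[2]), fields[3]
                probs = np.array([float(x) for x in fields[4:]])
                rset.distograms.append(DistogramRestraint(i, j, atom, edges, probs))
            elif kind == "CON":
                rset.contacts.append(
                    ContactRestraint(int(fields[1]), int(fields[2]), float(fields[3]))
                )
            elif kind == "ORI":
                i, j = int(fields[1]), int(fields[2])
                vals = list(map(float, fields[3:9]))
                rset.orientations.append(OrientationRestraint(i, j, *vals))
            elif kind == "HBNET":
                rset.hbnets.append(" ".join(fields[1:]))
            else:
                warnings.warn(f"{path}:{ln}: unknown record type {kind!r}; skipped")
        except (ValueError, IndexError) as exc:
            raise ValueError(f"{path}:{ln}: malformed {kind} record: {exc}") from exc
    return rset
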