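"""Domain/chain data model, PDB I/O and rigid-pose bookkeeping.

A multi-domain protein is handled as a set of rigid folding units
(:class:`DomainModel`) that live in a common full-chain residue numbering.
A domain may be *continuous* (one sequence segment) or *discontinuous*
(several segments, e.g. when another domain is inserted into it).  The
placement of each domain is a 6-parameter rigid pose applied about the
centroid of its input coordinates.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import gemmi
import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Segment",
    "DomainModel",
    "ChainLayout",
    "Boundary",
    "RigidPose",
    "AssemblyModel",
    "read_domain_pdb",
    "infer_layout",
    "apply_pose",
    "write_model_pdb",
]

BACKBONE_ATOMS = ("N", "C", "O", "CB")


@dataclass(frozen=True)
class Segment:
    """A contiguous residue range in full-chain numbering (1-based, inclusive)."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValueError(f"segment start must be >= 1, got {self.start}")
        if self.end < self.start:
            raise ValueError(f"segment end {self.end} < start {self.start}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __contains__(self, idx: int) -> bool:
        return self.start <= idx <= self.end


@dataclass
class DomainModel:
    """One rigid folding unit: segments plus CA (and optional backbone) coordinates.

    Residue indices are in the full-chain frame and must exactly cover the
    union of the segments, sorted ascending.
    """

    domain_id: int
    segments: list[Segment]
    residue_ids: np.ndarray          # (n,) int, ascending
    residue_names: list[str]         # 3-letter codes
    ca: np.ndarray                   # (n, 3) float, Angstrom
    backbone: dict[str, np.ndarray] = field(default_factory=dict)  # name -> (n,3), NaN where absent

    def __post_init__(self) -> None:
        self.residue_ids = np.asarray(self.residue_ids, dtype=int)
        self.ca = np.asarray(self.ca, dtype=float)
        covered = sorted(i for s in self.segments for i in range(s.start, s.end + 1))
        if covered != list(self.residue_ids):
            raise ValueError(
                f"domain {self.domain_id}: residue ids do not cover the segment union"
            )
        if self.ca.shape != (len(self.residue_ids), 3):
            raise ValueError("CA coordinate array shape mismatch")

    @property
    def n_residues(self) -> int:
        return len(self.residue_ids)

    @property
    def centroid(self) -> np.ndarray:
        return self.ca.mean(axis=0)

    @property
    def radius_of_gyration(self) -> float:
        d = self.ca - self.centroid
        return float(np.sqrt((d * d).sum(axis=1).mean()))

    def has_backbone(self) -> bool:
        need = {"N", "C"}
        return need.issubset(self.backbone) and not (
            np.isnan(self.backbone["N"]).any() or np.isnan(self.backbone["C"]).any()
        )


@dataclass(frozen=True)
class Boundary:
    """An adjacency of two segments in full-chain order (a potential linker)."""

    left_domain: int
    right_domain: int
    left_end: int      # residue id of the upstream flanking CA
    right_start: int   # residue id of the downstream flanking CA
    gap: int           # full-chain residues between them (>= 0)


@dataclass
class ChainLayout:
    """Full-chain bookkeeping: domain order, segment adjacencies, linker gaps."""

    domain_order: list[int]
    boundaries: list[Boundary]
    full_sequence: Optional[str] = None

    @property
    def linker_gaps(self) -> list[int]:
        return [b.gap for b in self.boundaries]


@dataclass
class RigidPose:
    """Rotation (intrinsic Z-Y-X Euler angles, radians) about the domain's
    input centroid, followed by a translation in Angstrom."""

    rot: np.ndarray = field(default_factory=lambda: np.zeros(3))
    trans: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.rot = np.asarray(self.rot, dtype=float)
        self.trans = np.asarray(self.trans, dtype=float)

    @classmethod
    def identity(cls) -> "RigidPose":
        return cls()

    @classmethod
    def from_vector(cls, v: np.ndarray) -> "RigidPose":
        v = np.asarray(v, dtype=float)
        return cls(rot=v[:3].copy(), trans=v[3:6].copy())

    def as_vector(self) -> np.ndarray:
        return np.concatenate([self.rot, self.trans])

    @property
    def matrix(self) -> np.ndarray:
        return Rotation.from_euler("ZYX", self.rot).as_matrix()

    @classmethod
    def from_matrix(cls, rotation: np.ndarray, translation: np.ndarray) -> "RigidPose":
        rot = Rotation.from_matrix(rotation).as_euler("ZYX")
        return cls(rot=rot, trans=np.asarray(translation, dtype=float))

    def copy(self) -> "RigidPose":
        return RigidPose(rot=self.rot.copy(), trans=self.trans.copy())


@dataclass
class AssemblyModel:
    """A posed full-length model with its energy breakdown and provenance."""

    poses: list[RigidPose]
    residue_ids: np.ndarray          # full-chain ids of domain residues, ascending
    domain_of_residue: np.ndarray    # parallel array of domain ids
    coords: np.ndarray               # (n, 3) transformed CA
    residue_names: list[str] = field(default_factory=list)
    backbone: dict[str, np.ndarray] = field(default_factory=dict)
    linker_ids: np.ndarray = field(default_factory=lambda: np.zeros(0, dtype=int))
    linker_coords: np.ndarray = field(default_factory=lambda: np.zeros((0, 3)))
    linker_stretched: bool = False
    energy_breakdown: dict[str, float] = field(default_factory=dict)
    provenance: str = ""
    confidence: dict[str, float] = field(default_factory=dict)

    @property
    def total_energy(self) -> float:
        return self.energy_breakdown.get("total", float("nan"))


# ---------------------------------------------------------------------------
# PDB reading


def _split_segments(ids: Sequence[int]) -> list[Segment]:
    """Split a sorted residue-id list into segments at numbering gaps >= 2."""
    segs: list[Segment] = []
    start = prev = ids[0]
    for i in ids[1:]:
        if i - prev >= 2:
            segs.append(Segment(start, prev))
            start = i
        prev = i
    segs.append(Segment(start, prev))
    return segs


def read_domain_pdb(path: str | Path, domain_id: int) -> DomainModel:
    """Read one domain model from a PDB file (CA required per residue).

    Residues are sorted by residue number; insertion codes are rejected;
    for alternate locations only blank or 'A' is kept; the chain id is
    recorded in provenance terms only and ignored for numbering.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    if len(st) == 0:
        raise ValueError(f"{path}: no model in PDB file")
    model = st[0]

    entries: dict[int, dict] = {}
    for chain in model:
        for res in chain:
            if res.het_flag == "H" and gemmi.find_tabulated_residue(res.name) is None:
                continue  # ligands/waters
            if res.seqid.icode not in (" ", "\0", ""):
                raise ValueError(
                    f"{path}: insertion code '{res.seqid.icode}' at residue "
                    f"{res.seqid.num} is not supported"
                )
            idx = res.seqid.num
            rec = entries.setdefault(idx, {"name": res.name, "atoms": {}})
            for atom in res:
                if atom.altloc not in ("", "A", "\0"):
                    continue
                if atom.name in ("CA",) + BACKBONE_ATOMS and atom.name not in rec["atoms"]:
                    rec["atoms"][atom.name] = np.array(
                        [atom.pos.x, atom.pos.y, atom.pos.z]
                    )
    if not entries:
        raise ValueError(f"{path}: no ATOM records with coordinates found")

    ids = sorted(entries)
    for idx in ids:
        if "CA" not in entries[idx]["atoms"]:
            raise ValueError(
                f"{path}: residue {entries[idx]['name']} {idx} has no CA atom"
            )

    ca = np.array([entries[i]["atoms"]["CA"] for i in ids])
    names = [entries[i]["name"] for i in ids]
    backbone: dict[str, np.ndarray] = {}
    for atom_name in BACKBONE_ATOMS:
        if any(atom_name in entries[i]["atoms"] for i in ids):
            arr = np.full((len(ids), 3), np.nan)
            for k, i in enumerate(ids):
                if atom_name in entries[i]["atoms"]:
                    arr[k] = entries[i]["atoms"][atom_name]
            backbone[atom_name] = arr

    return DomainModel(
        domain_id=domain_id,
        segments=_split_segments(ids),
        residue_ids=np.array(ids),
        residue_names=names,
        ca=ca,
        backbone=backbone,
    )


# ---------------------------------------------------------------------------
# Layout inference

_THREE_TO_ONE = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C", "GLN": "Q",
    "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I", "LEU": "L", "LYS": "K",
    "MET": "M", "PHE": "F", "PRO": "P", "SER": "S", "THR": "T", "TRP": "W",
    "TYR": "Y", "VAL": "V", "MSE": "M", "UNK": "X",
}


def infer_layout(
    domains: Sequence[DomainModel], full_sequence: Optional[str] = None
) -> ChainLayout:
    """Derive the chain layout (domain order, segment adjacencies, linker gaps).

    Domains must carry mutually disjoint full-chain numbering; overlapping
    numbering is a hard error.  When a full sequence is supplied the residue
    names of every domain are validated against it.
    """
    if not domains:
        raise ValueError("no domains given")

    owner: dict[int, int] = {}
    overlaps = []
    for d in domains:
        for i in d.residue_ids:
            i = int(i)
            if i in owner:
                overlaps.append((i, owner[i], d.domain_id))
            owner[i] = d.domain_id
    if overlaps:
        desc = ", ".join(f"residue {i} in domains {a} and {b}" for i, a, b in overlaps[:5])
        raise ValueError(f"overlapping residue numbering: {desc}")

    if full_sequence is not None:
        for d in domains:
            for idx, name in zip(d.residue_ids, d.residue_names):
                idx = int(idx)
                if idx > len(full_sequence):
                    raise ValueError(
                        f"residue {idx} beyond sequence length {len(full_sequence)}"
                    )
                one = _THREE_TO_ONE.get(name, "X")
                if one != "X" and full_sequence[idx - 1].upper() != one:
                    raise ValueError(
                        f"sequence mismatch at residue {idx}: structure has "
                        f"{name} ({one}), sequence has {full_sequence[idx - 1]}"
                    )

    seg_list = sorted(
        ((s, d.domain_id) for d in domains for s in d.segments),
        key=lambda t: t[0].start,
    )
    boundaries = [
        Boundary(
            left_domain=a_dom,
            right_domain=b_dom,
            left_end=a.end,
            right_start=b.start,
            gap=b.start - a.end - 1,
        )
        for (a, a_dom), (b, b_dom) in zip(seg_list, seg_list[1:])
    ]
    order = sorted(
        {d.domain_id: min(s.start for s in d.segments) for d in domains},
        key=lambda did: min(
            s.start for d in domains if d.domain_id == did for s in d.segments
        ),
    )
    return ChainLayout(domain_order=order, boundaries=boundaries,
                       full_sequence=full_sequence)


# ---------------------------------------------------------------------------
# Pose application


def apply_pose(domain: DomainModel, pose: RigidPose) -> np.ndarray:
    """Rigidly transform a domain's CA coordinates: R (x - c) + c + t."""
    return transform_coords(domain.ca, pose, domain.centroid)


def transform_coords(
    coords: np.ndarray, pose: RigidPose, centroid: np.ndarray
) -> np.ndarray:
    if np.all(pose.rot == 0.0) and np.all(pose.trans == 0.0):
        return coords.copy()
    r = pose.matrix
    return (coords - centroid) @ r.T + centroid + pose.trans


# ---------------------------------------------------------------------------
# PDB writing


def write_model_pdb(model: AssemblyModel, path: str | Path) -> None:
    """Write an assembled model as a single-chain PDB file.

    Residues are emitted in full-chain index order (rebuilt linker residues,
    if any, are interleaved as GLY); the owning domain id is stored in the
    B-factor column, which is noted in a REMARK.
    """
    path = Path(path)
    if model.coords.shape[0] != len(model.residue_ids):
        raise ValueError("model has no consistent coordinates")

    rows = []  # (residue id, name, domain id, {atom: coord})
    names = model.residue_names or ["ALA"] * len(model.residue_ids)
    for k, rid in enumerate(model.residue_ids):
        atoms = {"CA": model.coords[k]}
        for an, arr in model.backbone.items():
            if not np.isnan(arr[k]).any():
                atoms[an] = arr[k]
        rows.append((int(rid), names[k], int(model.domain_of_residue[k]), atoms))
    for k, rid in enumerate(model.linker_ids):
        rows.append((int(rid), "GLY", 0, {"CA": model.linker_coords[k]}))
    rows.sort(key=lambda r: r[0])

    st = gemmi.Structure()
    st.name = "polydom model"
    remarks = ["REMARK   3 POLYDOM ASSEMBLED MODEL",
               "REMARK   3 B-FACTOR COLUMN HOLDS THE DOMAIN ID (0 = REBUILT LINKER)"]
    for key, val in model.confidence.items():
        remarks.append(f"REMARK   3 {key.upper()} {val:.4f}")
    if model.provenance:
        remarks.append(f"REMARK   3 PROVENANCE {model.provenance[:60].upper()}")
    st.raw_remarks = remarks
    gmodel = gemmi.Model("1")
    chain = gemmi.Chain("A")
    element = {"N": "N", "C": "C", "O": "O", "CB": "C", "CA": "C"}
    for rid, name, dom, atoms in rows:
        res = gemmi.Residue()
        res.name = name
        res.seqid = gemmi.SeqId(rid, " ")
        res.het_flag = "A"
        for an in ("N", "CA", "C", "O", "CB"):
            if an in atoms:
                at = gemmi.Atom()
                at.name = an
                at.element = gemmi.Element(element[an])
                x, y, z = atoms[an]
                at.pos = gemmi.Position(round(x, 3), round(y, 3), round(z, 3))
                at.occ = 1.0
                at.b_iso = float(dom)
                res.add_atom(at)
        chain.add_residue(res)
    gmodel.add_chain(chain)
    st.add_model(gmodel)
    st.setup_entities()
    st.write_pdb(str(path))


def model_from_domains(
    domains: Sequence[DomainModel],
    poses: Sequence[RigidPose],
    provenance: str = "",
) -> AssemblyModel:
    """Assemble the full-chain coordinate set from per-domain poses."""
    ids, doms, coords, names = [], [], [], []
    bb_names = set()
    for d in domains:
        bb_names.update(d.backbone)
    bb: dict[str, list] = {an: [] for an in bb_names}
    for d, p in zip(domains, poses):
        ids.append(d.residue_ids)
        doms.append(np.full(d.n_residues, d.domain_id))
        coords.append(apply_pose(d, p))
        names.extend(d.residue_names)
        for an in bb_names:
            if an in d.backbone:
                bb[an].append(transform_coords(d.backbone[an], p, d.centroid))
            else:
                bb[an].append(np.full((d.n_residues, 3), np.nan))
    ids = np.concatenate(ids)
    order = np.argsort(ids, kind="stable")
    return AssemblyModel(
        poses=[p.copy() for p in poses],
        residue_ids=ids[order],
        domain_of_residue=np.concatenate(doms)[order],
        coords=np.concatenate(coords)[order],
        residue_names=[names[i] for i in order],
        backbone={an: np.concatenate(v)[order] for an, v in bb.items()},
        provenance=provenance,
    )
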