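import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

from polydom.core import (
    AssemblyModel,
    DomainModel,
    RigidPose,
    Segment,
    apply_pose,
    infer_layout,
    model_from_domains,
    read_domain_pdb,
    transform_coords,
    write_model_pdb,
)
from polydom.fixtures import ToySpec, make_toy_domain, make_toy_multidomain

from conftest import sorted_domains


def test_segment_validation():
    s = Segment(3, 7)
    assert len(s) == 5 and 3 in s and 7 in s and 8 not in s
    with pytest.raises(ValueError):
        Segment(0, 5)
    with pytest.raises(ValueError):
        Segment(5, 4)


def test_domain_model_requires_consistent_ids():
    with pytest.raises(ValueError):
        DomainModel(domain_id=0, segments=[Segment(1, 4)],
                    residue_ids=np.array([1, 2, 3]),
                    residue_names=["ALA"] * 3, ca=np.zeros((3, 3)))


def test_pose_vector_round_trip():
    p = RigidPose(rot=[0.3, -0.2, 1.1], trans=[1.0, -2.0, 3.0])
    q = RigidPose.from_vector(p.as_vector())
    assert np.allclose(p.rot, q.rot) and np.allclose(p.trans, q.trans)
    assert np.allclose(p.matrix @ p.matrix.T, np.eye(3), atol=1e-12)


def test_pose_from_matrix_round_trip():
    rm = Rotation.from_euler("zyx", [0.4, -0.7, 0.2]).as_matrix()
    p = RigidPose.from_matrix(rm, np.array([1.0, 2.0, 3.0]))
    assert np.allclose(p.matrix, rm, atol=1e-12)


def test_identity_pose_is_noop():
    d = make_toy_domain(25, seed=1)
    assert np.array_equal(apply_pose(d, RigidPose.identity()), d.ca)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_pose_preserves_internal_geometry(seed):
    rng = np.random.default_rng(seed)
    coords = rng.normal(0, 5, (12, 3))
    pose = RigidPose(rot=rng.uniform(-np.pi, np.pi, 3),
                     trans=rng.uniform(-10, 10, 3))
    moved = transform_coords(coords, pose, coords.mean(axis=0))
    d_before = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
    d_after = np.linalg.norm(moved[:, None] - moved[None, :], axis=2)
    assert np.allclose(d_before, d_after, atol=1e-9)


def test_pose_rotates_about_input_centroid():
    d = make_toy_domain(25, seed=2)
    pose = RigidPose(rot=[0.5, 0.2, -0.3], trans=[0, 0, 0])
    moved = apply_pose(d, pose)
    # pure rotation about the centroid leaves the centroid fixed
    assert np.allclose(moved.mean(axis=0), d.centroid, atol=1e-9)


def test_infer_layout_continuous():
    _, domains, layout = make_toy_multidomain(ToySpec(seed=0))
    assert layout.domain_order == [d.domain_id for d in sorted_domains(domains)]
    assert all(b.gap == 2 for b in layout.boundaries)


def test_infer_layout_discontinuous():
    _, domains, layout = make_toy_multidomain(
        ToySpec(topology="discontinuous", seed=0))
    doms = {d.domain_id: d for d in domains}
    # one domain is split into two segments around the other
    assert sorted(len(d.segments) for d in doms.values()) == [1, 2]


def test_infer_layout_rejects_overlap():
    d = make_toy_domain(25, seed=3)
    d2 = DomainModel(domain_id=1, segments=d.segments,
                     residue_ids=d.residue_ids, residue_names=d.residue_names,
                     ca=d.ca + 30.0)
    with pytest.raises(ValueError, match="overlap"):
        infer_layout([d, d2])


def test_infer_layout_sequence_mismatch():
    d = make_toy_domain(25, seed=3)
    seq = "W" * (int(d.residue_ids.max()) + 5)
    with pytest.raises(ValueError, match="mismatch"):
        infer_layout([d], full_sequence=seq)


def test_pdb_round_trip(tmp_path):
    _, domains, layout = make_toy_multidomain(ToySpec(seed=1))
    doms = sorted_domains(domains)
    model = model_from_domains(doms, [RigidPose.identity()] * len(doms))
    path = tmp_path / "m.pdb"
    write_model_pdb(model, path)
    back = read_domain_pdb(path, domain_id=0)
    assert np.array_equal(back.residue_ids, model.residue_ids)
    # coordinates are written at 3-decimal PDB precision
    assert np.allclose(back.ca, model.coords, atol=2e-3)


def test_pdb_written_as_atom_records(tmp_path):
    d = make_toy_domain(25, seed=4)
    model = model_from_domains([d], [RigidPose.identity()])
    path = tmp_path / "m.pdb"
    write_model_pdb(model, path)
    text = path.read_text()
    assert "ATOM" in text and "HETATM" not in text
    assert "DOMAIN ID" in text  # B-factor remark


def test_read_rejects_insertion_codes(tmp_path):
    path = tmp_path / "ins.pdb"
    path.write_text(
        "ATOM      1  CA  ALA A   1      0.000   0.000   0.000  1.00  0.00           C\n"
        "ATOM      2  CA  ALA A   1A     3.800   0.000   0.000  1.00  0.00           C\n"
        "END\n"
    )
    with pytest.raises(ValueError, match="insertion code"):
        read_domain_pdb(path, domain_id=0)


def test_read_requires_ca(tmp_path):
    path = tmp_path / "noca.pdb"
    path.write_text(
        "ATOM      1  N   ALA A   1      0.000   0.000   0.000  1.00  0.00           N\n"
        "END\n"
    )
    with pytest.raises(ValueError, match="no CA"):
        read_domain_pdb(path, domain_id=0)


def test_read_missing_file():
    with pytest.raises(FileNotFoundError):
        read_domain_pdb("/nonexistent/file.pdb", domain_id=0)


def test_model_from_domains_sorts_by_residue_id():
    _, domains, _ = make_toy_multidomain(ToySpec(seed=2))
    doms = sorted_domains(domains)
    model = model_from_domains(doms, [RigidPose.identity()] * len(doms))
    assert np.all(np.diff(model.residue_ids) > 0)
    native = np.concatenate([d.ca for d in doms])
    order = np.argsort(np.concatenate([d.residue_ids for d in doms]), kind="stable")
    assert np.allclose(model.coords, native[order])


def test_linkers_written_as_gly(tmp_path):
    from polydom.assemble import rebuild_linkers

    _, domains, layout = make_toy_multidomain(ToySpec(seed=1))
    doms = sorted_domains(domains)
    model = model_from_domains(doms, [RigidPose.identity()] * len(doms))
    rebuild_linkers(model, layout)
    assert len(model.linker_ids) == 2 * len(layout.boundaries)
    path = tmp_path / "m.pdb"
    write_model_pdb(model, path)
    text = path.read_text()
    assert "GLY" in text
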