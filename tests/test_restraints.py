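import numpy as np
import pytest

from polydom.fixtures import ToySpec, make_toy_multidomain
from polydom.restraints import (
    ContactRestraint,
    DistogramRestraint,
    GaussianRestraint,
    OrientationRestraint,
    RestraintSet,
    contacts_from_distograms,
    default_bin_edges,
    read_restraints,
    synth_restraints_from_native,
    write_restraints,
)

from conftest import native_ids_and_membership


def uniform_distogram(i, j, edges=None):
    edges = default_bin_edges() if edges is None else edges
    k = len(edges) - 1
    return DistogramRestraint(i, j, "CA", edges, np.full(k, 1.0 / k))


# ---------------------------------------------------------------------------
# validation


def test_distogram_validation():
    edges = default_bin_edges()
    with pytest.raises(ValueError, match="i < j"):
        uniform_distogram(5, 5)
    with pytest.raises(ValueError, match="sum to 1"):
        DistogramRestraint(1, 2, "CA", edges, np.full(36, 0.5))
    with pytest.raises(ValueError, match="bin count"):
        DistogramRestraint(1, 2, "CA", edges, np.full(35, 1 / 35))


def test_gaussian_validation():
    with pytest.raises(ValueError):
        GaussianRestraint(1, 2, "CA", 10.0, 0.0)
    with pytest.raises(ValueError):
        GaussianRestraint(2, 1, "CA", 10.0, 1.0)


def test_contact_orientation_validation():
    with pytest.raises(ValueError):
        ContactRestraint(1, 2, 1.5)
    with pytest.raises(ValueError):
        OrientationRestraint(1, 2, omega=4.0, theta_ij=0, theta_ji=0,
                             phi_ij=0, phi_ji=0)


def test_restraint_set_rejects_duplicates():
    g = GaussianRestraint(1, 5, "CA", 8.0, 1.0)
    with pytest.raises(ValueError, match="duplicate"):
        RestraintSet(gaussians=[g, GaussianRestraint(1, 5, "CA", 9.0, 1.0)])


# ---------------------------------------------------------------------------
# contacts from distograms (criterion 5, analytic cases)


def test_contacts_all_mass_below_cutoff():
    edges = np.linspace(2.0, 16.0, 15)  # all bins end below 18
    dg = DistogramRestraint(1, 9, "CA", edges, np.full(14, 1 / 14))
    (c,) = contacts_from_distograms(RestraintSet(distograms=[dg]))
    assert c.prob == pytest.approx(1.0, abs=1e-12)


def test_contacts_all_mass_above_cutoff():
    edges = np.linspace(20.0, 40.0, 11)
    dg = DistogramRestraint(1, 9, "CA", edges, np.full(10, 0.1))
    (c,) = contacts_from_distograms(RestraintSet(distograms=[dg]))
    assert c.prob == pytest.approx(0.0, abs=1e-12)


def test_contacts_uniform_distogram_is_16_over_18():
    # uniform over [2, 20]: mass below 18 A is (18-2)/(20-2) = 16/18
    dg = uniform_distogram(1, 9)
    (c,) = contacts_from_distograms(RestraintSet(distograms=[dg]))
    assert c.prob == pytest.approx(16.0 / 18.0, abs=1e-12)


def test_contacts_fractional_bin():
    # one bin [16, 20]: cutoff 18 takes half the bin
    dg = DistogramRestraint(1, 9, "CA", np.array([16.0, 20.0]), np.array([1.0]))
    (c,) = contacts_from_distograms(RestraintSet(distograms=[dg]))
    assert c.prob == pytest.approx(0.5, abs=1e-12)


def test_contacts_skip_non_ca(recwarn):
    dg = DistogramRestraint(1, 9, "CB", default_bin_edges(),
                            np.full(36, 1 / 36))
    out = contacts_from_distograms(RestraintSet(distograms=[dg]))
    assert out == []


# ---------------------------------------------------------------------------
# synthetic restraints


def test_synth_restraints_inter_domain_only():
    native, domains, _ = make_toy_multidomain(ToySpec(seed=4))
    ids, dom_of = native_ids_and_membership(domains)
    rset = synth_restraints_from_native(native, ids, dom_of, subsample=1.0)
    pos = {int(i): k for k, i in enumerate(ids)}
    assert rset.n_distance > 0
    for g in rset.gaussians:
        assert dom_of[pos[g.i]] != dom_of[pos[g.j]]
        d = np.linalg.norm(native[pos[g.i]] - native[pos[g.j]])
        assert abs(d - g.mean) < 1e-9  # exact mode


def test_synth_restraints_subsample_count():
    native, domains, _ = make_toy_multidomain(ToySpec(seed=4))
    ids, dom_of = native_ids_and_membership(domains)
    full = synth_restraints_from_native(native, ids, dom_of, subsample=1.0)
    quarter = synth_restraints_from_native(native, ids, dom_of, subsample=0.25,
                                           seed=9)
    assert len(quarter.gaussians) == round(0.25 * len(full.gaussians))


def test_synth_restraints_noisy_mode_changes_means():
    native, domains, _ = make_toy_multidomain(ToySpec(seed=4))
    ids, dom_of = native_ids_and_membership(domains)
    exact = synth_restraints_from_native(native, ids, dom_of, subsample=0.2,
                                         seed=1)
    noisy = synth_restraints_from_native(native, ids, dom_of, mode="noisy",
                                         sd=1.0, subsample=0.2, seed=1)
    d_exact = np.array([g.mean for g in exact.gaussians])
    d_noisy = np.array([g.mean for g in noisy.gaussians])
    resid = d_noisy - d_exact
    assert resid.std() > 0.3  # noise actually applied
    assert abs(resid.mean()) < 0.5  # and unbiased at this sample size


def test_synth_restraints_bad_mode():
    native, domains, _ = make_toy_multidomain(ToySpec(seed=4))
    ids, dom_of = native_ids_and_membership(domains)
    with pytest.raises(ValueError, match="mode"):
        synth_restraints_from_native(native, ids, dom_of, mode="gaussian")


# ---------------------------------------------------------------------------
# file dialect


def test_round_trip(tmp_path):
    native, domains, _ = make_toy_multidomain(ToySpec(seed=5))
    ids, dom_of = native_ids_and_membership(domains)
    rset = synth_restraints_from_native(native, ids, dom_of, subsample=0.3,
                                        seed=2)
    rset.distograms.append(uniform_distogram(1, 70))
    rset.contacts.append(ContactRestraint(2, 71, 0.9))
    path = tmp_path / "r.txt"
    write_restraints(rset, path)
    back = read_restraints(path)
    assert len(back.gaussians) == len(rset.gaussians)
    assert len(back.distograms) == 1
    assert len(back.contacts) == 1
    for a, b in zip(rset.gaussians, back.gaussians):
        assert (a.i, a.j) == (b.i, b.j)
        assert abs(a.mean - b.mean) < 1e-3
    assert np.allclose(back.distograms[0].probs, rset.distograms[0].probs,
                       atol=1e-6)


def test_read_malformed_line_reports_position(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("DIST 1 5 CA 8.0 1.0 1.0\nDIST 2 banana\n")
    with pytest.raises(ValueError, match=r"bad.txt:2"):
        read_restraints(path)


def test_read_unknown_record_warns_and_skips(tmp_path):
    path = tmp_path / "bad.txt"
    path.write_text("FROB 1 2 3\nDIST 1 5 CA 8.0 1.0 1.0\n")
    with pytest.warns(UserWarning, match="unknown record"):
        rset = read_restraints(path)
    assert len(rset.gaussians) == 1
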