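"""Shared helpers for the test suite."""

from __future__ import annotations

import numpy as np

from polydom.energy import AssemblyProblem
from polydom.fixtures import ToySpec, make_toy_multidomain
from polydom.restraints import synth_restraints_from_native


def sorted_domains(domains):
    return sorted(domains, key=lambda d: d.domain_id)


def native_ids_and_membership(domains):
    doms = sorted_domains(domains)
    ids = np.concatenate([d.residue_ids for d in doms])
    dom_of = np.concatenate(
        [np.full(d.n_residues, d.domain_id) for d in doms]
    )
    # id-sorted so the arrays align with the id-sorted native coordinates
    # (domain order != id order for discontinuous topologies)
    order = np.argsort(ids, kind="stable")
    return ids[order], dom_of[order]


def toy_problem(spec: ToySpec, sd: float = 1.0, subsample: float = 0.25,
                restraint_seed: int = 0, density=None, resolution: float = 8.0):
    """Build a fixture: (native coords, domains, layout, restraints, problem).

    The restraints are exact native inter-domain Gaussian distances at the
    given subsampling; the domains are at their native placement, so the
    identity poses reproduce the native.
    """
    native, domains, layout = make_toy_multidomain(spec)
    ids, dom_of = native_ids_and_membership(domains)
    rset = synth_restraints_from_native(
        native, ids, dom_of, mode="exact", sd=sd, subsample=subsample,
        seed=restraint_seed,
    )
    problem = AssemblyProblem(domains, layout, rset, density=density,
                              resolution=resolution)
    return native, domains, layout, rset, problem
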