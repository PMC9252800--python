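"""Model confidence: estimated TM-score (eTM-score) and RMSD (eRMSD).

The confidence of an assembled model is estimated without knowing the
native structure, from four signals: the significance of the best template
(its TM-score_h), the consistency between the predicted inter-domain
distance restraints and the model, the convergence of the multi-start
assembly (pairwise rTM-score agreement of the top models), and the supplied
accuracy of the individual domain models.  The combination is a documented
linear stand-in with fixed weights; the eRMSD is obtained by inverting the
TM-score distance kernel at the estimated score, which is a heuristic and
is flagged as such in reports.  Models with eTM-score above 0.5 are
conventionally taken to have a correct global fold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .metrics import r_tm_score, tm_d0
from .restraints import RestraintSet

__all__ = ["ConfidenceReport", "restraint_satisfaction", "convergence_score",
           "estimate_quality"]

ETM_WEIGHTS = {"template": 0.25, "restraint": 0.25, "convergence": 0.20,
               "domain": 0.30}
ETM_FOLD_CUTOFF = 0.5


@dataclass
class ConfidenceReport:
    etm: float
    ermsd: float
    components: dict[str, float]

    def __post_init__(self) -> None:
        assert 0.0 <= self.etm <= 1.0
        assert self.ermsd >= 0.0


def restraint_satisfaction(model, rset: RestraintSet) -> float:
    """Fraction of distance restraints the model satisfies.

    Gaussian dialect: the model distance is within 2 sd of the mean.
    Distogram dialect: the model distance falls in the smallest set of bins
    holding 90% of the probability mass.
    """
    if rset.n_distance == 0:
        raise ValueError("no distance restraints to check")
    pos = {int(i): k for k, i in enumerate(model.residue_ids)}
    n_ok = n_tot = 0
    for g in rset.gaussians:
        if g.i not in pos or g.j not in pos:
            continue
        d = np.linalg.norm(model.coords[pos[g.i]] - model.coords[pos[g.j]])
        n_tot += 1
        n_ok += int(abs(d - g.mean) <= 2.0 * g.sd)
    for dg in rset.distograms:
        if dg.i not in pos or dg.j not in pos:
            continue
        d = np.linalg.norm(model.coords[pos[dg.i]] - model.coords[pos[dg.j]])
        order = np.argsort(-dg.probs)
        mass = np.cumsum(dg.probs[order])
        n_keep = int(np.searchsorted(mass, 0.9) + 1)
        hdb = set(order[:n_keep].tolist())
        k = int(np.searchsorted(dg.bin_edges, d, side="right") - 1)
        n_tot += 1
        n_ok += int(0 <= k < len(dg.probs) and k in hdb)
    if n_tot == 0:
        raise ValueError("no restraint references residues present in the model")
    return n_ok / n_tot


def convergence_score(models) -> float:
    """Mean pairwise rTM-score between the top (up to five) final models.

    Multi-start runs that collapse onto one pose score near 1; scattered
    outcomes score low.  A single model returns 0.5 with a warning.
    """
    models = list(models)[:5]
    if len(models) < 2:
        warnings.warn("only one model; convergence undefined, returning 0.5")
        return 0.5
    vals = []
    for a in range(len(models)):
        for b in range(a + 1, len(models)):
            vals.append(
                r_tm_score(models[a], models[b].coords, models[b].residue_ids)
            )
    return float(np.mean(vals))


def estimate_quality(result, hits=(), rset: RestraintSet | None = None,
                     domain_conf=None) -> ConfidenceReport:
    """Composite confidence of the top assembled model.

    etm = 0.25 * best TM-score_h + 0.25 * restraint satisfaction
        + 0.20 * convergence + 0.30 * mean per-domain confidence,
    clamped to [0, 1]; ermsd = d0(L) * sqrt(max(0, 1/etm - 1)).
    """
    if not result.models:
        raise ValueError("empty assembly result")
    best = result.models[0]

    template = max((h.tm_h for h in hits), default=0.0)
    if rset is not None and rset.n_distance > 0:
        restraint = restraint_satisfaction(best, rset)
    else:
        restraint = 0.0
    pool = result.all_models if len(result.all_models) >= 2 else result.models
    convergence = convergence_score(pool) if len(pool) >= 2 else 0.5
    n_dom = len(np.unique(best.domain_of_residue))
    if domain_conf is None:
        domain_conf = [0.8] * n_dom
    components = {
        "template": float(np.clip(template, 0, 1)),
        "restraint": float(restraint),
        "convergence": float(np.clip(convergence, 0, 1)),
        "domain": float(np.clip(np.mean(domain_conf), 0, 1)),
    }
    etm = float(np.clip(sum(ETM_WEIGHTS[k] * v for k, v in components.items()), 0, 1))
    length = len(best.residue_ids) + len(best.linker_ids)
    ermsd = 0.0 if etm >= 1.0 else float(
        tm_d0(length) * np.sqrt(max(0.0, 1.0 / max(etm, 1e-6) - 1.0))
    )
    return ConfidenceReport(etm=etm, ermsd=ermsd, components=components)
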