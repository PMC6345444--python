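"""Knockout analysis: MOMA projection, concentrations, fold-change bins.

A single-reaction knockout is simulated constraint-based by projecting
the wild-type reference flux onto the mutant flux space (minimization
of metabolic adjustment, a strictly convex QP).  The mutant flux then
yields predicted concentrations for every SCC metabolite through the
certificate identity, and predicted-vs-simulated fold changes are
compared on a common binning of log2 fold change.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import minimize

from .bounds import point_concentration, sigma_pair
from .coupling import CouplingRelation
from .network import FluxSpace, MetabolicNetwork
from .scc import SCCCertificate

logger = logging.getLogger(__name__)

__all__ = [
    "KnockoutResult",
    "moma",
    "knockout_concentrations",
    "fold_change_bins",
    "default_log2_edges",
]


def default_log2_edges() -> np.ndarray:
    """Inner edges of the 12-bin log2 fold-change scheme.

    Bins: (-inf, -2.5], (-2.5, -2], ..., (2, 2.5], (2.5, inf) — eleven
    inner edges, symmetric around zero so up- and down-regulation are
    treated alike.
    """
    return np.arange(-2.5, 2.51, 0.5)


@dataclass
class KnockoutResult:
    knocked_out: Tuple[str, ...]
    feasible: bool
    v_mut: Optional[Dict[str, float]]
    distance: float = float("nan")
    predicted: Dict[str, Optional[float]] = field(default_factory=dict)
    fold_changes: Dict[str, Optional[float]] = field(default_factory=dict)
    bins: Dict[str, Optional[int]] = field(default_factory=dict)


def moma(
    net: MetabolicNetwork,
    v_ref: Mapping[str, float],
    ko,
    fs: Optional[FluxSpace] = None,
    split_map: Optional[Mapping[str, Tuple[str, str]]] = None,
    tol: float = 1e-8,
) -> Tuple[Optional[np.ndarray], float, bool]:
    """Project the reference flux onto the knockout flux space.

    Minimizes ``||v - v_ref||^2`` subject to ``Nv = 0``, the flux
    bounds, and ``v = 0`` for the knocked-out reaction (both halves when
    ``ko`` names an unsplit reversible reaction present in
    ``split_map``).  Returns (flux vector or None, distance, feasible).
    """
    fs = fs or net.flux_space()
    if isinstance(ko, str):
        ko_ids = [ko]
    else:
        ko_ids = list(ko)
    expanded: List[str] = []
    for rid in ko_ids:
        if split_map and rid in split_map:
            expanded.extend(split_map[rid])
        else:
            expanded.append(rid)
    for rid in expanded:
        if rid not in net.rxn_index:
            raise KeyError(f"unknown reaction {rid!r}")

    n = net.n_reactions
    ref = np.array([float(v_ref[r.id]) for r in net.reactions])
    lb, ub = fs.lb.copy(), fs.ub.copy()
    for rid in expanded:
        j = net.rxn_index[rid]
        if lb[j] > 0:
            return None, float("nan"), False
        lb[j] = ub[j] = 0.0

    N = net.stoichiometry
    x0 = np.clip(ref, lb, ub)
    for rid in expanded:
        x0[net.rxn_index[rid]] = 0.0

    res = minimize(
        lambda v: float(np.sum((v - ref) ** 2)),
        x0,
        jac=lambda v: 2.0 * (v - ref),
        bounds=list(zip(lb, ub)),
        constraints=[{"type": "eq", "fun": lambda v: N @ v, "jac": lambda v: N}],
        method="SLSQP",
        options={"ftol": tol * 1e-4, "maxiter": 1000},
    )
    if not res.success:
        logger.info("MOMA infeasible or failed for %s: %s", expanded, res.message)
        return None, float("nan"), False
    v = res.x
    if np.max(np.abs(N @ v)) > 1e-6 * max(1.0, np.max(np.abs(v))):
        return None, float("nan"), False
    return v, float(np.linalg.norm(v - ref)), True


def knockout_concentrations(
    certs: Sequence[SCCCertificate],
    theta: Mapping[str, float],
    cr: CouplingRelation,
    net: MetabolicNetwork,
    v_mut: Mapping[str, float],
) -> Dict[str, Optional[float]]:
    """SCC concentrations implied by a mutant flux distribution.

    Each certificate contributes one point estimate; a metabolite with
    several certificates gets the median of the defined estimates (an
    LP- or QP-derived flux need not be exactly mass-action consistent,
    so the per-certificate values can disagree slightly).  ``None``
    marks metabolites whose relevant fluxes vanish in the mutant.
    """
    per_met: Dict[str, List[float]] = {}
    seen = set()
    for cert in certs:
        seen.add(cert.target)
        try:
            sigma = sigma_pair(cert, theta, cr, net)
            value = point_concentration(cert, sigma, v_mut)
        except (ValueError, KeyError):
            continue
        per_met.setdefault(cert.target, []).append(value)
    return {
        met: (float(np.median(per_met[met])) if met in per_met else None)
        for met in sorted(seen)
    }


def fold_change_bins(
    x_mut: Mapping[str, Optional[float]],
    x_ref: Mapping[str, float],
    edges: Optional[np.ndarray] = None,
) -> Tuple[Dict[str, Optional[int]], np.ndarray, int]:
    """Assign fold changes ``x_mut / x_ref`` to log2 bins.

    Returns (per-metabolite bin index or None, histogram over the bins,
    number of undefined fold changes).  Undefined concentrations are
    excluded from the histogram.
    """
    edges = default_log2_edges() if edges is None else np.asarray(edges, dtype=float)
    n_bins = len(edges) + 1
    hist = np.zeros(n_bins, dtype=int)
    assignment: Dict[str, Optional[int]] = {}
    undefined = 0
    for met, ref in x_ref.items():
        if ref <= 0:
            raise ValueError(f"reference concentration for {met} must be positive")
        mut = x_mut.get(met)
        if mut is None or mut <= 0:
            assignment[met] = None
            undefined += 1
            continue
        idx = int(np.searchsorted(edges, np.log2(mut / ref), side="left"))
        assignment[met] = idx
        hist[idx] += 1
    return assignment, hist, undefined
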