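"""Constraint-based estimation of relevant flux-ratio ranges.

When no kinetic information is available, the relevant flux ratio
``v_num / v_den`` of a certificate is estimated in two steps:

1. maximize a weighted combination of ATP synthesis and (negated) total
   flux over the condition-constrained flux space, giving an optimal
   value ``z*``;
2. compute the exact range of the ratio on the optimal face with a
   Charnes-Cooper transformed linear-fractional program in which the
   flux vector is scaled by an auxiliary variable ``t``.

In the transformed program the objective-fixing constraint must scale
with ``t`` to stay consistent with the change of variables; ``mode=
"scaled"`` (default) does that, ``mode="literal"`` keeps the constraint
un-scaled as sometimes written, for replication purposes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional, Tuple

import numpy as np
from scipy.optimize import linprog

from .coupling import InfeasibleFluxSpace
from .network import FluxSpace, MetabolicNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "ConditionConstraints",
    "RatioLPResult",
    "optimize_weighted_objective",
    "ratio_range_at_optimum",
]

#: weight presets (w_atp, w_flux) used in the experiments this package reproduces
WEIGHT_PRESETS = {
    "kinetic": (1.0, 0.01),
    "ishii": (0.1, 1.0),
    "gerosa": (0.001, 1000.0),
}


@dataclass
class ConditionConstraints:
    """Measured-condition constraints on exchange reactions.

    ``fixed`` pins reactions to measured rates (growth, O2/glucose
    uptake, CO2 release; mmol/gDW/hr, growth 1/hr); ``intervals``
    constrains reactions to [min, max] windows (e.g. simulated exchange
    ranges).  ``epsilon`` is the minimal-flux floor applied to every
    lower bound when ``apply_floor`` is set, forcing a strictly positive
    flux distribution.
    """

    fixed: Dict[str, float] = field(default_factory=dict)
    intervals: Dict[str, Tuple[float, float]] = field(default_factory=dict)
    epsilon: float = 1e-7
    apply_floor: bool = True

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")

    def effective_bounds(self, net: MetabolicNetwork, fs: Optional[FluxSpace] = None):
        fs = fs or net.flux_space()
        lb, ub = fs.lb.copy(), fs.ub.copy()
        if self.apply_floor:
            lb = np.maximum(lb, self.epsilon)
        for rid, (lo, hi) in self.intervals.items():
            j = net.rxn_index[rid]
            lb[j] = max(lb[j], lo)
            ub[j] = min(ub[j], hi)
        for rid, val in self.fixed.items():
            j = net.rxn_index[rid]
            lb[j] = ub[j] = val
        if np.any(lb > ub):
            bad = [net.reactions[j].id for j in np.where(lb > ub)[0]]
            raise InfeasibleFluxSpace(
                f"condition constraints contradict flux bounds for: {', '.join(bad)}"
            )
        return lb, ub


@dataclass
class RatioLPResult:
    z_star: float
    ratio_min: float
    ratio_max: float
    t_min: float
    t_max: float
    bounded: bool

    @property
    def interval(self) -> Tuple[float, float]:
        return (self.ratio_min, self.ratio_max)


def _objective_row(net: MetabolicNetwork, atp_reaction: str, w_atp: float, w_flux: float):
    c = np.full(net.n_reactions, -w_flux)
    c[net.rxn_index[atp_reaction]] += w_atp
    return c  # objective value = c @ v (to be maximized)


def optimize_weighted_objective(
    net: MetabolicNetwork,
    fs: Optional[FluxSpace],
    cond: ConditionConstraints,
    w_atp: float = 1.0,
    w_flux: float = 0.01,
    atp_reaction: str = "ATP",
) -> Tuple[float, np.ndarray]:
    """max  w_atp * v_atp - w_flux * sum_i v_i  over the constrained space.

    The total-flux sum runs over all reactions.  Returns the optimum
    ``z*`` and one optimal flux vector.
    """
    if atp_reaction not in net.rxn_index:
        raise KeyError(f"ATP-synthesis reaction {atp_reaction!r} not in network")
    lb, ub = cond.effective_bounds(net, fs)
    c = _objective_row(net, atp_reaction, w_atp, w_flux)
    res = linprog(
        -c,
        A_eq=net.stoichiometry,
        b_eq=np.zeros(net.n_metabolites),
        bounds=list(zip(lb, ub)),
        method="highs",
    )
    if res.status == 2:
        raise InfeasibleFluxSpace("no feasible flux under the given conditions")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return -res.fun, res.x


def ratio_range_at_optimum(
    net: MetabolicNetwork,
    cond: ConditionConstraints,
    z_star: float,
    pair: Tuple[str, str],
    mode: str = "scaled",
    w_atp: float = 1.0,
    w_flux: float = 0.01,
    atp_reaction: str = "ATP",
    t_lower: float = 0.0,
    fs: Optional[FluxSpace] = None,
    z_tol: float = 1e-6,
) -> RatioLPResult:
    """Range of ``v_p / v_s`` over the optimal face of the weighted LP.

    Solves min/max ``v_p`` subject to ``Nv = 0``, ``v_s = 1``, the
    t-scaled bounds ``t*lb <= v <= t*ub`` and the objective pinned to
    its optimum: ``c@v = t*z*`` (``mode="scaled"``) or ``c@v = z*``
    (``mode="literal"``).  Degeneracy is absorbed by a small relative
    tolerance on the pinning constraint.  Unbounded directions are
    reported with ``bounded=False``.
    """
    if mode not in {"scaled", "literal"}:
        raise ValueError(f"unknown mode {mode!r}")
    p, s = pair
    if p == s:
        return RatioLPResult(z_star, 1.0, 1.0, np.nan, np.nan, True)
    lb, ub = cond.effective_bounds(net, fs)
    n = net.n_reactions
    ip, is_ = net.rxn_index[p], net.rxn_index[s]
    c_obj = _objective_row(net, atp_reaction, w_atp, w_flux)
    slack = z_tol * max(1.0, abs(z_star))

    # variables: v (n), t
    A_eq = np.zeros((net.n_metabolites + 1, n + 1))
    A_eq[: net.n_metabolites, :n] = net.stoichiometry
    A_eq[-1, is_] = 1.0
    b_eq = np.zeros(net.n_metabolites + 1)
    b_eq[-1] = 1.0

    rows = []
    rhs = []
    # t-scaled box: v - t*ub <= 0 and t*lb - v <= 0
    for j in range(n):
        row = np.zeros(n + 1)
        row[j] = 1.0
        row[n] = -ub[j]
        rows.append(row)
        rhs.append(0.0)
        row = np.zeros(n + 1)
        row[j] = -1.0
        row[n] = lb[j]
        rows.append(row)
        rhs.append(0.0)
    # objective pinned within tolerance
    obj_row = np.zeros(n + 1)
    obj_row[:n] = c_obj
    if mode == "scaled":
        obj_row[n] = -z_star
        target = 0.0
    else:
        target = z_star
    rows.append(obj_row.copy())
    rhs.append(target + slack)
    rows.append(-obj_row.copy())
    rhs.append(-(target - slack))

    A_ub = np.vstack(rows)
    b_ub = np.array(rhs)
    bounds = [(None, None)] * n + [(t_lower, None)]

    out = {}
    for label, sign in (("min", 1.0), ("max", -1.0)):
        c = np.zeros(n + 1)
        c[ip] = sign
        res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
        if res.status == 2:
            raise InfeasibleFluxSpace(
                f"no feasible flux with v[{s}] > 0 at the objective optimum"
            )
        if res.status == 3:
            out[label] = (np.inf if sign < 0 else -np.inf, np.nan)
            continue
        if not res.success:
            raise RuntimeError(f"LP failed: {res.message}")
        out[label] = (sign * res.fun if sign > 0 else -res.fun, res.x[n])
    r_min, t_min = out["min"]
    r_max, t_max = out["max"]
    return RatioLPResult(
        z_star=z_star,
        ratio_min=r_min,
        ratio_max=r_max,
        t_min=t_min,
        t_max=t_max,
        bounded=bool(np.isfinite(r_min) and np.isfinite(r_max)),
    )
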