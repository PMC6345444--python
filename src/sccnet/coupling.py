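"""Blocked reactions and full coupling of fluxes.

Two reactions are *fully coupled* when their flux ratio is one and the
same constant in every admissible state.  This happens for two distinct
reasons:

* **structural** coupling — the ratio is fixed by ``Nv = 0`` over the
  bounded flux space, detected with the Charnes-Cooper transformed
  linear-fractional program (equal minimum and maximum of ``v_i/v_j``);
* **kinetic** coupling — the reactions have identical substrate columns
  in ``N-``, so under mass action ``v_l / v_k = theta_l / theta_k`` at
  *any* state, steady or not.

Both kinds are combined transitively into a single
:class:`CouplingRelation`, which is the input the detection of
structurally constrained concentrations needs.
"""

from __future__ import annotations

import itertools
import logging
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
from scipy.optimize import linprog

from .network import FluxSpace, MetabolicNetwork
from .ratios import RatioCoeff

logger = logging.getLogger(__name__)

__all__ = [
    "CouplingRelation",
    "CouplingInconsistency",
    "InfeasibleFluxSpace",
    "find_blocked",
    "ratio_range",
    "structural_couplings",
    "kinetic_couplings",
    "merge_couplings",
]

BLOCKED_TOL = 1e-9
REL_TOL = 1e-6
ABS_TOL = 1e-9


class InfeasibleFluxSpace(RuntimeError):
    """The flux space {Nv=0, lb<=v<=ub} (plus side constraints) is empty."""


class CouplingInconsistency(ValueError):
    """Numerically contradictory coupling coefficients along a cycle."""


def _compatible(c1: RatioCoeff, c2: RatioCoeff, theta=None) -> bool:
    try:
        return abs(c1.value(theta) - c2.value(theta)) <= REL_TOL * max(
            abs(c1.value(theta)), abs(c2.value(theta))
        )
    except KeyError:
        pass
    if dict(c1.powers) == dict(c2.powers):
        return c1.agrees_with(c2, REL_TOL)
    # one structural (numeric), one kinetic (symbolic): cannot be refuted
    return True


class CouplingRelation:
    """Partition of reactions into fully-coupled classes with coefficients.

    Coefficients follow the convention ``v_l = lam(k, l) * v_k``.  They
    are :class:`~sccnet.ratios.RatioCoeff` objects: numeric for
    structural couplings, monomials in the rate constants for kinetic
    ones, products of both along transitive chains.
    """

    def __init__(self, reactions: Iterable[str]):
        self.reactions: List[str] = list(reactions)
        self._parent: Dict[str, str] = {r: r for r in self.reactions}
        # coefficient such that v_r = coeff * v_parent[r]
        self._coeff: Dict[str, RatioCoeff] = {r: RatioCoeff.number(1.0) for r in self.reactions}
        self._provenance: Dict[FrozenSet[str], str] = {}

    # -- union-find ----------------------------------------------------
    def _find(self, r: str) -> Tuple[str, RatioCoeff]:
        path = []
        coeff = RatioCoeff.number(1.0)
        while self._parent[r] != r:
            path.append((r, self._coeff[r]))
            coeff = coeff * self._coeff[r]
            r = self._parent[r]
        # path compression
        acc = RatioCoeff.number(1.0)
        for node, c in reversed(path):
            acc = c * acc
            self._parent[node] = r
            self._coeff[node] = acc
        return r, coeff

    def add_pair(self, k: str, l: str, lam: RatioCoeff, provenance: str, theta=None):
        """Record full coupling ``v_l = lam * v_k``."""
        if k == l:
            return
        rk, ck = self._find(k)  # v_k = ck * v_rk
        rl, cl = self._find(l)  # v_l = cl * v_rl
        if rk == rl:
            implied = cl / ck  # v_l = implied * v_k
            if not _compatible(implied, lam, theta):
                raise CouplingInconsistency(
                    f"coupling cycle through {k},{l}: existing ratio {implied!r} "
                    f"conflicts with {lam!r}"
                )
        else:
            # v_rl = (lam * ck / cl) * v_rk
            self._parent[rl] = rk
            self._coeff[rl] = lam * ck / cl
        self._provenance[frozenset((k, l))] = provenance

    # -- queries -------------------------------------------------------
    def same_class(self, k: str, l: str) -> bool:
        return self._find(k)[0] == self._find(l)[0]

    def mutually_coupled(self, ids: Sequence[str]) -> bool:
        ids = list(ids)
        if len(ids) <= 1:
            return True
        root0 = self._find(ids[0])[0]
        return all(self._find(r)[0] == root0 for r in ids[1:])

    def lam(self, k: str, l: str) -> RatioCoeff:
        """Coefficient with ``v_l = lam * v_k``; reactions must be coupled."""
        rk, ck = self._find(k)
        rl, cl = self._find(l)
        if rk != rl:
            raise KeyError(f"reactions {k} and {l} are not fully coupled")
        return cl / ck

    def provenance(self, k: str, l: str) -> str:
        key = frozenset((k, l))
        if key in self._provenance:
            return self._provenance[key]
        if self.same_class(k, l):
            return "transitive"
        raise KeyError(f"reactions {k} and {l} are not fully coupled")

    def classes(self) -> List[Set[str]]:
        groups: Dict[str, Set[str]] = {}
        for r in self.reactions:
            groups.setdefault(self._find(r)[0], set()).add(r)
        return sorted(groups.values(), key=lambda s: sorted(s)[0])

    def nontrivial_classes(self) -> List[Set[str]]:
        return [c for c in self.classes() if len(c) > 1]

    def explicit_pairs(self) -> List[Tuple[str, str, RatioCoeff, str]]:
        out = []
        for key, prov in self._provenance.items():
            k, l = sorted(key)
            out.append((k, l, self.lam(k, l), prov))
        return out

    def to_frame(self):
        import pandas as pd

        rows = []
        for cls in self.nontrivial_classes():
            ordered = sorted(cls)
            for k, l in itertools.combinations(ordered, 2):
                lam = self.lam(k, l)
                rows.append(
                    {
                        "reaction_a": k,
                        "reaction_b": l,
                        "lambda": lam.value() if lam.is_numeric else repr(lam),
                        "provenance": self.provenance(k, l),
                    }
                )
        return pd.DataFrame(rows, columns=["reaction_a", "reaction_b", "lambda", "provenance"])


# ---------------------------------------------------------------------------
# linear programming primitives
# ---------------------------------------------------------------------------

def _solve_lp(c, A_eq, b_eq, bounds, A_ub=None, b_ub=None):
    res = linprog(c, A_ub=A_ub, b_ub=b_ub, A_eq=A_eq, b_eq=b_eq, bounds=bounds, method="highs")
    return res


def _max_flux(net: MetabolicNetwork, fs: FluxSpace, j: int) -> float:
    n = net.n_reactions
    c = np.zeros(n)
    c[j] = -1.0  # maximize v_j
    res = _solve_lp(c, net.stoichiometry, np.zeros(net.n_metabolites), list(zip(fs.lb, fs.ub)))
    if res.status == 2:
        raise InfeasibleFluxSpace("flux bounds admit no steady-state flux")
    if not res.success:
        raise RuntimeError(f"LP failed: {res.message}")
    return -res.fun


def find_blocked(net: MetabolicNetwork, fs: Optional[FluxSpace] = None, tol: float = BLOCKED_TOL) -> Set[str]:
    """Reactions with ``v_i = 0`` in every feasible steady-state flux.

    Assumes a split network (``lb >= 0``), so maximizing each flux is
    enough to decide.
    """
    fs = fs or net.flux_space()
    blocked = set()
    for j, rxn in enumerate(net.reactions):
        if _max_flux(net, fs, j) <= tol:
            blocked.add(rxn.id)
    return blocked


def ratio_range(
    net: MetabolicNetwork,
    fs: Optional[FluxSpace],
    i: str,
    j: str,
    t_lower: float = 0.0,
) -> Tuple[float, float]:
    """Exact range of ``v_i / v_j`` over F minus {v_j = 0}.

    Uses the Charnes-Cooper change of variables: optimize ``v_i`` subject
    to ``Nv = 0``, ``v_j = 1``, ``t*lb <= v <= t*ub``, ``t >= t_lower``.
    Unbounded directions are reported as ``inf``.
    """
    fs = fs or net.flux_space()
    if i == j:
        return (1.0, 1.0)
    n = net.n_reactions
    ii, jj = net.rxn_index[i], net.rxn_index[j]
    # variables: v (n), t
    A_eq = np.zeros((net.n_metabolites + 1, n + 1))
    A_eq[: net.n_metabolites, :n] = net.stoichiometry
    b_eq = np.zeros(net.n_metabolites + 1)
    A_eq[-1, jj] = 1.0
    b_eq[-1] = 1.0
    # v - t*ub <= 0 ; t*lb - v <= 0
    A_ub = np.zeros((2 * n, n + 1))
    A_ub[:n, :n] = np.eye(n)
    A_ub[:n, n] = -fs.ub
    A_ub[n:, :n] = -np.eye(n)
    A_ub[n:, n] = fs.lb
    b_ub = np.zeros(2 * n)
    bounds = [(None, None)] * n + [(t_lower, None)]
    out = []
    for sign in (1.0, -1.0):
        c = np.zeros(n + 1)
        c[ii] = sign
        res = _solve_lp(c, A_eq, b_eq, bounds, A_ub, b_ub)
        if res.status == 2:
            raise InfeasibleFluxSpace(f"no feasible flux with v[{j}] > 0")
        if res.status == 3:
            out.append(np.inf if sign < 0 else -np.inf)
            continue
        if not res.success:
            raise RuntimeError(f"LP failed: {res.message}")
        out.append(sign * res.fun if sign > 0 else -res.fun)
    r_min, r_max = out[0], out[1]
    return (r_min, r_max)


def _sample_vertices(net: MetabolicNetwork, fs: FluxSpace, n_samples: int, seed: int) -> np.ndarray:
    rng = np.random.default_rng(seed)
    n = net.n_reactions
    rows = []
    objectives = [np.ones(n), -np.ones(n)]
    objectives += [rng.standard_normal(n) for _ in range(n_samples)]
    for c in objectives:
        res = _solve_lp(-c, net.stoichiometry, np.zeros(net.n_metabolites), list(zip(fs.lb, fs.ub)))
        if res.status == 2:
            raise InfeasibleFluxSpace("flux bounds admit no steady-state flux")
        if res.success:
            rows.append(res.x)
    return np.array(rows)


def structural_couplings(
    net: MetabolicNetwork,
    fs: Optional[FluxSpace] = None,
    n_samples: int = 12,
    seed: int = 0,
) -> CouplingRelation:
    """Full couplings implied by stoichiometry and bounds alone.

    Candidate pairs are pre-filtered on a handful of vertex samples of F
    (a constant ratio on every sample is necessary for coupling), then
    certified by the exact fractional program.  Blocked reactions must
    have been removed.
    """
    fs = fs or net.flux_space()
    rel = CouplingRelation(net.reaction_ids())
    n = net.n_reactions
    if n < 2:
        return rel
    V = _sample_vertices(net, fs, n_samples, seed)
    ids = net.reaction_ids()
    for a, b in itertools.combinations(range(n), 2):
        va, vb = V[:, a], V[:, b]
        active = (np.abs(va) > ABS_TOL) | (np.abs(vb) > ABS_TOL)
        if not active.any():
            continue  # both zero everywhere sampled; blocked reactions are a precondition
        if np.any((np.abs(va) > ABS_TOL) != (np.abs(vb) > ABS_TOL)):
            continue
        ratios = va[active] / vb[active]
        if np.ptp(ratios) > REL_TOL * max(1.0, np.abs(ratios).max()):
            continue
        if rel.same_class(ids[a], ids[b]):
            continue  # already implied transitively by certified pairs
        r_min, r_max = ratio_range(net, fs, ids[a], ids[b])
        if not np.isfinite(r_min) or not np.isfinite(r_max):
            continue
        if abs(r_max - r_min) <= max(REL_TOL * max(abs(r_min), abs(r_max)), ABS_TOL):
            lam_ab = 0.5 * (r_min + r_max)  # v_a = lam_ab * v_b
            rel.add_pair(ids[a], ids[b], RatioCoeff.number(1.0 / lam_ab), "structural")
    return rel


def kinetic_couplings(net: MetabolicNetwork, theta=None) -> CouplingRelation:
    """Couplings from identical substrate columns under mass action.

    ``v_l / v_k = theta_l / theta_k`` holds at any (not only steady)
    state; coefficients are symbolic rate-constant ratios and resolve to
    numbers whenever the rate constants are supplied.
    """
    rel = CouplingRelation(net.reaction_ids())
    groups: Dict[tuple, List[str]] = {}
    for rxn in net.reactions:
        groups.setdefault(rxn.substrate_signature(), []).append(rxn.id)
    for members in groups.values():
        for k, l in zip(members, members[1:]):
            rel.add_pair(k, l, RatioCoeff.theta_ratio(l, k), "kinetic", theta)
    return rel


def merge_couplings(a: CouplingRelation, b: CouplingRelation, theta=None) -> CouplingRelation:
    """Transitive closure of two coupling relations.

    Coefficients compose multiplicatively; a numeric contradiction along
    a cycle raises :class:`CouplingInconsistency`.  Idempotent and
    commutative in the relation it induces.
    """
    reactions = list(dict.fromkeys(list(a.reactions) + list(b.reactions)))
    merged = CouplingRelation(reactions)
    for rel in (a, b):
        for k, l, lam, prov in rel.explicit_pairs():
            merged.add_pair(k, l, lam, prov, theta)
    return merged
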