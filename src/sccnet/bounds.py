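"""Sigma constants, point concentrations and concentration ranges.

Given a certificate for a metabolite ``x_i`` (witness ``x_j``), the two
sides of the witness ODE collapse into constants at steady state:

    sigma_num = sum over the coupled side of  coeff * v_k / v_num,
    sigma_den = sum over the lack side of     coeff * (theta_l / theta_q) * v_q / v_den,

where ``q`` is the lack partner of ``l`` chosen from the representative
set Q, ``v_num``/``v_den`` are the representative fluxes, and all the
flux ratios are coupling coefficients, hence constants.  Then

    x_i = (sigma_num / sigma_den) * (v_num / v_den)

and a concentration range over a set of flux distributions is obtained
by optimizing that expression over the flux set and over the admissible
choices of Q.  Intersecting the ranges of several witness ODEs gives the
final bounds; an empty intersection certifies that the network has no
positive steady state.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np

from .coupling import CouplingRelation
from .network import MetabolicNetwork, RateConstants
from .ratios import MissingRateConstant, RatioCoeff
from .scc import DEFAULT_Q_CAP, SCCCertificate

logger = logging.getLogger(__name__)

__all__ = [
    "SigmaConstants",
    "ConcentrationRange",
    "sigma_pair",
    "point_concentration",
    "range_over_fluxes",
    "intersect_ranges",
    "substitute_missing_ratios",
]

#: orders of magnitude between numerator and denominator flux beyond
#: which a prediction is flagged numerically unstable
INSTABILITY_DECADES = 6.0


@dataclass(frozen=True)
class SigmaConstants:
    """The pair of ODE-side constants for one representative set Q."""

    sigma_num: float
    sigma_den: float
    num_rep: str
    den_rep: str
    q_choice: Tuple[Tuple[str, str], ...]  # lack-side reaction -> chosen partner
    substituted: Tuple[Tuple[str, str], ...] = ()

    def __post_init__(self):
        if self.sigma_num <= 0 or self.sigma_den <= 0:
            raise ValueError("sigma constants must be strictly positive")

    @property
    def ratio(self) -> float:
        """sigma_num / sigma_den."""
        return self.sigma_num / self.sigma_den


@dataclass
class ConcentrationRange:
    """Per-ODE intervals and their intersection (units mmol/gDW)."""

    per_ode: Dict[object, Tuple[float, float]]
    lower: float
    upper: float
    feasible: bool
    unstable: bool = False


def _side_coeffs(net: MetabolicNetwork, cert: SCCCertificate):
    """Stoichiometric coefficients of the witness row for both sides."""
    j = cert.witness
    if cert.case == "II":
        num_matrix, den_matrix = net.nplus, net.nminus
    else:
        num_matrix, den_matrix = net.nminus, net.nplus
    jrow = net.met_index[j]
    num = {k: float(num_matrix[jrow, net.rxn_index[k]]) for k in cert.coupled_side}
    den = {l: float(den_matrix[jrow, net.rxn_index[l]]) for l in cert.lack_side}
    return num, den


def substitute_missing_ratios(
    cert: SCCCertificate,
    theta_partial: Mapping[str, float],
    scheme: str,
    cr: CouplingRelation,
    net: MetabolicNetwork,
    q_choice: Optional[Mapping[str, str]] = None,
) -> Tuple[Dict[Tuple[str, str], float], List[Tuple[str, str]]]:
    """Complete the rate-constant ratios a certificate's sigma_den needs.

    For every lack-side reaction ``l`` and its chosen partner ``q`` the
    required quantity is the rate-constant part of
    ``(theta_l / theta_q) * lam(den_rep -> q)``.  Ratios whose constants
    are all known keep their value; missing ones are substituted by
    ``one`` (all constants equal), or the ``mean`` / ``median`` of the
    ratios known in this certificate's equation, falling back to one
    when nothing is known.

    Returns the completed map ``(l, partner) -> theta-ratio value`` and
    the list of substituted pairs.
    """
    if scheme not in {"one", "mean", "median"}:
        raise ValueError(f"unknown substitution scheme {scheme!r}")
    if q_choice is None:
        q_choice = cert.q_choices(cap=1)[0]
    den_rep = min(q_choice.values())
    known: Dict[Tuple[str, str], float] = {}
    missing: List[Tuple[str, str]] = []
    monos: Dict[Tuple[str, str], RatioCoeff] = {}
    for l, partner in q_choice.items():
        mono = RatioCoeff.theta_ratio(l, partner) * cr.lam(den_rep, partner)
        theta_part = RatioCoeff(1.0, mono.powers)
        monos[(l, partner)] = theta_part
        try:
            known[(l, partner)] = theta_part.value(theta_partial)
        except MissingRateConstant:
            missing.append((l, partner))
    if missing:
        values = list(known.values())
        if scheme == "one" or not values:
            if scheme != "one" and not values:
                logger.info(
                    "certificate %s/%s: no known ratios for scheme %s; falling back to one",
                    cert.target,
                    cert.witness,
                    scheme,
                )
            fill = 1.0
        elif scheme == "mean":
            fill = float(np.mean(values))
        else:
            fill = float(np.median(values))
        for key in missing:
            known[key] = fill
    return known, missing


def sigma_pair(
    cert: SCCCertificate,
    theta: Optional[Mapping[str, float]],
    cr: CouplingRelation,
    net: MetabolicNetwork,
    q_choice: Optional[Mapping[str, str]] = None,
    scheme: Optional[str] = None,
) -> SigmaConstants:
    """Evaluate sigma_num and sigma_den for one representative set Q.

    All coupling coefficients and rate-constant ratios must resolve to
    numbers; with a partial ``theta`` a substitution ``scheme`` must be
    supplied, otherwise the missing constants are reported.
    """
    theta = theta or {}
    if q_choice is None:
        q_choice = cert.q_choices(cap=1)[0]
    num_coeffs, den_coeffs = _side_coeffs(net, cert)
    num_rep = cert.num_rep
    den_rep = min(q_choice.values())

    sigma_num = 0.0
    for k, coeff in num_coeffs.items():
        lam = cr.lam(num_rep, k)  # v_k / v_num_rep
        sigma_num += coeff * lam.value(theta)

    substituted: List[Tuple[str, str]] = []
    if scheme is not None:
        ratios, substituted = substitute_missing_ratios(
            cert, theta, scheme, cr, net, q_choice
        )
    else:
        ratios = None

    sigma_den = 0.0
    for l, partner in q_choice.items():
        coeff = den_coeffs[l]
        mono = RatioCoeff.theta_ratio(l, partner) * cr.lam(den_rep, partner)
        if ratios is not None:
            sigma_den += coeff * mono.coeff * ratios[(l, partner)]
        else:
            try:
                sigma_den += coeff * mono.value(theta)
            except MissingRateConstant as exc:
                raise MissingRateConstant(exc.missing) from exc

    return SigmaConstants(
        sigma_num=sigma_num,
        sigma_den=sigma_den,
        num_rep=num_rep,
        den_rep=den_rep,
        q_choice=tuple(sorted(q_choice.items())),
        substituted=tuple(substituted),
    )


def ratio_unstable(v_num: float, v_den: float, decades: float = INSTABILITY_DECADES) -> bool:
    return abs(math.log10(v_num / v_den)) > decades


def point_concentration(
    cert: SCCCertificate,
    sigma: SigmaConstants,
    v: Mapping[str, float],
) -> float:
    """x_i = (sigma_num / sigma_den) * (v_num / v_den) for one flux vector."""
    v_num = float(v[sigma.num_rep])
    v_den = float(v[sigma.den_rep])
    if v_den <= 0 or v_num <= 0:
        raise ValueError(
            f"certificate {cert.target}/{cert.witness}: relevant fluxes must be "
            f"positive (v[{sigma.num_rep}]={v_num}, v[{sigma.den_rep}]={v_den})"
        )
    if ratio_unstable(v_num, v_den):
        logger.warning(
            "certificate %s/%s: flux ratio spans more than %g decades; "
            "prediction may be numerically unstable",
            cert.target,
            cert.witness,
            INSTABILITY_DECADES,
        )
    return sigma.ratio * (v_num / v_den)


def range_over_fluxes(
    cert: SCCCertificate,
    theta: Optional[Mapping[str, float]],
    cr: CouplingRelation,
    net: MetabolicNetwork,
    flux_set: Union[Sequence[Mapping[str, float]], Tuple[float, float]],
    scheme: Optional[str] = None,
    q_cap: int = DEFAULT_Q_CAP,
    instability_decades: float = INSTABILITY_DECADES,
) -> Tuple[float, float]:
    """Concentration interval [L, U] from one witness ODE.

    ``flux_set`` is either a sequence of flux vectors (maps reaction id
    -> flux) or a pre-computed interval ``(r_min, r_max)`` for the
    relevant flux ratio ``v_num / v_den``.  The optimization runs
    jointly over the flux set and the representative-set choices Q.
    Members with non-positive or unstable relevant fluxes are skipped;
    if nothing remains, a ``ValueError`` is raised.
    """
    sigmas = [
        sigma_pair(cert, theta, cr, net, q_choice=q, scheme=scheme)
        for q in cert.q_choices(cap=q_cap)
    ]
    if isinstance(flux_set, tuple) and len(flux_set) == 2 and np.isscalar(flux_set[0]):
        r_min, r_max = float(flux_set[0]), float(flux_set[1])
        if r_min <= 0:
            raise ValueError("ratio interval must be strictly positive")
        lo = min(s.ratio for s in sigmas) * r_min
        hi = max(s.ratio for s in sigmas) * r_max
        return (lo, hi)

    values: List[float] = []
    for sigma in sigmas:
        for v in flux_set:
            v_num = float(v.get(sigma.num_rep, 0.0))
            v_den = float(v.get(sigma.den_rep, 0.0))
            if v_num <= 0 or v_den <= 0:
                continue
            if abs(math.log10(v_num / v_den)) > instability_decades:
                continue
            values.append(sigma.ratio * v_num / v_den)
    if not values:
        raise ValueError(
            f"certificate {cert.target}/{cert.witness}: no usable flux vector "
            "(all relevant fluxes zero or unstable)"
        )
    return (min(values), max(values))


def intersect_ranges(per_ode: Mapping[object, Tuple[float, float]]) -> ConcentrationRange:
    """Intersection of the per-ODE intervals (lower = max L, upper = min U).

    An empty intersection is retained with ``feasible=False``: it means
    no positive steady state is compatible with all witness ODEs.
    """
    if not per_ode:
        raise ValueError("at least one per-ODE interval is required")
    lower = max(lo for lo, _ in per_ode.values())
    upper = min(hi for _, hi in per_ode.values())
    return ConcentrationRange(
        per_ode=dict(per_ode),
        lower=lower,
        upper=upper,
        feasible=lower <= upper,
    )
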