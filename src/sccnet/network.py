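"""Stoichiometric network data model and preprocessing.

A metabolic network is held as an ordered list of metabolites and
reactions.  Each reaction stores its substrate and product stoichiometry
separately, so the split ``N = N+ - N-`` that the mass-action rate law
``v_i = theta_i * prod_j x_j ** Nminus[j, i]`` relies on is available
without sign games.  Preprocessing (splitting reversible reactions,
removing blocked reactions) always returns a new network.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Set, Tuple

import numpy as np

logger = logging.getLogger(__name__)

__all__ = [
    "Metabolite",
    "Reaction",
    "MetabolicNetwork",
    "FluxSpace",
    "RateConstants",
    "NetworkValidationError",
    "split_reversible",
    "remove_blocked",
]

#: tolerance for comparing stoichiometric coefficients
STOICH_TOL = 1e-9


class NetworkValidationError(ValueError):
    """Raised when a network refers to undeclared metabolites or is inconsistent."""


@dataclass(frozen=True)
class Metabolite:
    id: str
    name: str = ""
    compartment: str = ""


@dataclass(frozen=True)
class Reaction:
    """An irreversible-or-reversible reaction with non-negative stoichiometry.

    ``substrates`` and ``products`` map metabolite ids to coefficients
    (columns of N- and N+).  ``lb < 0`` marks the reaction reversible
    until :func:`split_reversible` is applied.  Flux bounds are in
    mmol/gDW/hr.
    """

    id: str
    substrates: Mapping[str, float] = field(default_factory=dict)
    products: Mapping[str, float] = field(default_factory=dict)
    lb: float = 0.0
    ub: float = 1000.0

    def __post_init__(self):
        for side in (self.substrates, self.products):
            for met, coeff in side.items():
                if coeff < 0:
                    raise NetworkValidationError(
                        f"reaction {self.id}: negative coefficient for {met}"
                    )
        object.__setattr__(self, "substrates", dict(self.substrates))
        object.__setattr__(self, "products", dict(self.products))

    @property
    def reversible(self) -> bool:
        return self.lb < 0

    @property
    def exchange(self) -> bool:
        """Boundary pseudo-reaction: no substrates (import) or no products (export)."""
        return not self.substrates or not self.products

    def substrate_signature(self) -> Tuple[Tuple[str, float], ...]:
        """Canonical form of the substrate column, for kinetic-coupling tests."""
        return tuple(sorted((m, float(c)) for m, c in self.substrates.items()))


class MetabolicNetwork:
    """Ordered collection of metabolites and reactions with derived matrices."""

    def __init__(
        self,
        metabolites: Sequence[Metabolite],
        reactions: Sequence[Reaction],
        id: str = "",
    ):
        self.id = id
        self.metabolites: List[Metabolite] = list(metabolites)
        self.reactions: List[Reaction] = list(reactions)
        self.met_index: Dict[str, int] = {m.id: i for i, m in enumerate(self.metabolites)}
        self.rxn_index: Dict[str, int] = {r.id: i for i, r in enumerate(self.reactions)}
        if len(self.met_index) != len(self.metabolites):
            raise NetworkValidationError("duplicate metabolite ids")
        if len(self.rxn_index) != len(self.reactions):
            raise NetworkValidationError("duplicate reaction ids")
        for rxn in self.reactions:
            for met in list(rxn.substrates) + list(rxn.products):
                if met not in self.met_index:
                    raise NetworkValidationError(
                        f"reaction {rxn.id} references undeclared metabolite {met}"
                    )
        self._nminus: Optional[np.ndarray] = None
        self._nplus: Optional[np.ndarray] = None

    # -- sizes ---------------------------------------------------------
    @property
    def n_metabolites(self) -> int:
        return len(self.metabolites)

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    # -- matrices ------------------------------------------------------
    def _build(self):
        m, n = self.n_metabolites, self.n_reactions
        nminus = np.zeros((m, n))
        nplus = np.zeros((m, n))
        for j, rxn in enumerate(self.reactions):
            for met, coeff in rxn.substrates.items():
                nminus[self.met_index[met], j] = coeff
            for met, coeff in rxn.products.items():
                nplus[self.met_index[met], j] = coeff
        self._nminus, self._nplus = nminus, nplus

    @property
    def nminus(self) -> np.ndarray:
        """Substrate stoichiometry N- (m x n, non-negative)."""
        if self._nminus is None:
            self._build()
        return self._nminus

    @property
    def nplus(self) -> np.ndarray:
        """Product stoichiometry N+ (m x n, non-negative)."""
        if self._nplus is None:
            self._build()
        return self._nplus

    @property
    def stoichiometry(self) -> np.ndarray:
        """Net stoichiometric matrix N = N+ - N-."""
        return self.nplus - self.nminus

    # -- lookups -------------------------------------------------------
    def reaction(self, rid: str) -> Reaction:
        return self.reactions[self.rxn_index[rid]]

    def reaction_ids(self) -> List[str]:
        return [r.id for r in self.reactions]

    def metabolite_ids(self) -> List[str]:
        return [m.id for m in self.metabolites]

    def producers(self, met: str) -> List[str]:
        """Reactions with ``met`` among the products (P_j)."""
        return [r.id for r in self.reactions if met in r.products]

    def consumers(self, met: str) -> List[str]:
        """Reactions with ``met`` among the substrates (S_j)."""
        return [r.id for r in self.reactions if met in r.substrates]

    def flux_space(self) -> "FluxSpace":
        return FluxSpace(
            lb=np.array([r.lb for r in self.reactions], dtype=float),
            ub=np.array([r.ub for r in self.reactions], dtype=float),
        )

    def copy_with(self, reactions=None, metabolites=None) -> "MetabolicNetwork":
        return MetabolicNetwork(
            metabolites if metabolites is not None else self.metabolites,
            reactions if reactions is not None else self.reactions,
            id=self.id,
        )

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"<MetabolicNetwork {self.id or '?'}: "
            f"{self.n_metabolites} metabolites, {self.n_reactions} reactions>"
        )


@dataclass
class FluxSpace:
    """The polyhedron F = {v : Nv = 0, lb <= v <= ub}; bounds only."""

    lb: np.ndarray
    ub: np.ndarray

    def __post_init__(self):
        self.lb = np.asarray(self.lb, dtype=float)
        self.ub = np.asarray(self.ub, dtype=float)
        if np.any(self.lb > self.ub + STOICH_TOL):
            raise NetworkValidationError("flux space with lb > ub")

    def restrict(self, index: int, lb: float = None, ub: float = None) -> "FluxSpace":
        lo, hi = self.lb.copy(), self.ub.copy()
        if lb is not None:
            lo[index] = lb
        if ub is not None:
            hi[index] = ub
        return FluxSpace(lo, hi)


class RateConstants(dict):
    """Partial map reaction id -> mass-action rate constant theta > 0.

    Units are order-dependent; downstream code only ever consumes
    ratios, so no unit bookkeeping is done.
    """

    def __init__(self, values: Optional[Mapping[str, float]] = None):
        values = dict(values or {})
        for rid, theta in values.items():
            if theta <= 0:
                raise ValueError(f"rate constant for {rid} must be > 0, got {theta}")
        super().__init__(values)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def split_reversible(net: MetabolicNetwork) -> Tuple[MetabolicNetwork, Dict[str, Tuple[str, str]]]:
    """Replace each reversible reaction by irreversible forward/backward copies.

    Returns the new network and a map original id -> (forward id, backward id).
    Irreversible reactions are kept as-is; the map is empty when nothing
    was split.
    """
    reactions: List[Reaction] = []
    mapping: Dict[str, Tuple[str, str]] = {}
    for rxn in net.reactions:
        if not rxn.reversible:
            reactions.append(rxn)
            continue
        fwd = replace(rxn, id=rxn.id + "_f", lb=0.0, ub=max(rxn.ub, 0.0))
        bwd = Reaction(
            id=rxn.id + "_b",
            substrates=dict(rxn.products),
            products=dict(rxn.substrates),
            lb=0.0,
            ub=-rxn.lb,
        )
        reactions.extend([fwd, bwd])
        mapping[rxn.id] = (fwd.id, bwd.id)
    return net.copy_with(reactions=reactions), mapping


def remove_blocked(
    net: MetabolicNetwork,
    blocked: Iterable[str],
) -> Tuple[MetabolicNetwork, List[str]]:
    """Drop blocked reactions and any metabolites orphaned by the removal.

    Orphaned metabolites cannot take part in a positive steady state, so
    keeping them would defeat the preprocessing goal.  Returns the new
    network and the list of dropped metabolite ids.
    """
    blocked = set(blocked)
    reactions = [r for r in net.reactions if r.id not in blocked]
    used: Set[str] = set()
    for rxn in reactions:
        used.update(rxn.substrates)
        used.update(rxn.products)
    orphans = [m.id for m in net.metabolites if m.id not in used]
    if blocked:
        logger.info("removed %d blocked reactions", len(blocked))
    if orphans:
        logger.info("dropped orphaned metabolites: %s", ", ".join(orphans))
    if not reactions:
        logger.warning("all reactions blocked; returning empty network")
    metabolites = [m for m in net.metabolites if m.id in used]
    return net.copy_with(reactions=reactions, metabolites=metabolites), orphans
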