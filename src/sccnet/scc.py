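"""Detection of metabolites with structurally constrained concentrations.

A metabolite ``x_i`` has a structurally constrained concentration (SCC)
when, for some witness metabolite ``x_j`` (possibly ``i`` itself), the
steady-state balance of ``x_j`` pins ``x_i`` down to

    x_i = (sigma_num / sigma_den) * (v_num / v_den),

a product of a structure-and-rate-constant constant and a single flux
ratio.  This requires three conditions on the witness ODE:

(i)   every reaction on one side of the ODE has at least one partner
      reaction *lacking one substrate molecule* of ``x_i`` (identical
      substrate column except one fewer ``x_i``);
(ii)  all those partner reactions are mutually fully coupled;
(iii) all reactions on the other side of the ODE are mutually fully
      coupled.

Case II applies the lack condition to the consumers ``S_j`` of the
witness, Case I to its producers ``P_j``.  Coupling means the merged
structural + kinetic relation from :mod:`sccnet.coupling`.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .coupling import CouplingRelation
from .network import MetabolicNetwork
from .ratios import RatioCoeff

logger = logging.getLogger(__name__)

__all__ = ["SCCCertificate", "lacks_one_substrate", "find_scc", "certificate_summary"]

#: default cap on enumerated representative-set (Q) combinations
DEFAULT_Q_CAP = 64


def lacks_one_substrate(net: MetabolicNetwork, k: str, l: str, i: str, tol: float = 1e-9) -> bool:
    """True iff reaction ``k`` lacks one substrate molecule of ``i`` vs ``l``.

    That is, ``N-[i, l] - N-[i, k] == 1`` and the substrate columns agree
    on every other metabolite row.
    """
    nminus = net.nminus
    ck = nminus[:, net.rxn_index[k]]
    cl = nminus[:, net.rxn_index[l]]
    row = net.met_index[i]
    if abs((cl[row] - ck[row]) - 1.0) > tol:
        return False
    diff = np.abs(cl - ck)
    diff[row] = 0.0
    return bool(np.all(diff <= tol))


@dataclass(frozen=True)
class SCCCertificate:
    """Everything needed to evaluate one witness ODE for one SCC metabolite.

    ``coupled_side`` carries the ODE side whose internal flux ratios are
    fixed directly by coupling (P_j in Case II, S_j in Case I); its
    stoichiometric coefficients define ``sigma_num``.  ``lack_side``
    carries the side rewritten through the lack relation (S_j in Case
    II, P_j in Case I); together with the chosen representative set Q it
    defines ``sigma_den``.  The relevant flux ratio is
    ``v[num_rep] / v[den_rep]``.
    """

    target: str
    witness: str
    case: str  # "I" or "II"
    producers: Tuple[str, ...]  # P_j
    consumers: Tuple[str, ...]  # S_j
    lack_sets: Tuple[Tuple[str, Tuple[str, ...]], ...]  # l -> Q_l^{-i}
    union_set: Tuple[str, ...]  # union of the lack sets
    num_rep: str
    den_rep: str
    relevant_thetas: Tuple[str, ...]

    @property
    def coupled_side(self) -> Tuple[str, ...]:
        return self.producers if self.case == "II" else self.consumers

    @property
    def lack_side(self) -> Tuple[str, ...]:
        return self.consumers if self.case == "II" else self.producers

    @property
    def ratio_pair(self) -> Tuple[str, str]:
        """(numerator, denominator) of the relevant flux ratio."""
        return (self.num_rep, self.den_rep)

    def lack_map(self) -> Dict[str, Tuple[str, ...]]:
        return dict(self.lack_sets)

    def q_choices(self, cap: int = DEFAULT_Q_CAP) -> List[Dict[str, str]]:
        """Representative sets Q: one lack partner per lack-side reaction.

        Enumerated as maps ``l -> chosen partner``, capped at ``cap``
        combinations (with a warning when truncated).
        """
        keys = [l for l, _ in self.lack_sets]
        pools = [q for _, q in self.lack_sets]
        total = 1
        for pool in pools:
            total *= len(pool)
        out = []
        for combo in itertools.product(*pools):
            out.append(dict(zip(keys, combo)))
            if len(out) >= cap:
                if total > cap > 1:
                    logger.warning(
                        "certificate %s/%s: %d representative sets truncated at %d",
                        self.target,
                        self.witness,
                        total,
                        cap,
                    )
                break
        return out

    def to_dict(self) -> dict:
        return {
            "target": self.target,
            "witness": self.witness,
            "case": self.case,
            "producers": list(self.producers),
            "consumers": list(self.consumers),
            "lack_sets": {l: list(q) for l, q in self.lack_sets},
            "union_set": list(self.union_set),
            "ratio_pair": list(self.ratio_pair),
            "relevant_thetas": list(self.relevant_thetas),
        }


def _stoich_coeff(net: MetabolicNetwork, matrix: np.ndarray, met: str, rxn: str) -> float:
    return float(matrix[net.met_index[met], net.rxn_index[rxn]])


def _relevant_thetas(
    net: MetabolicNetwork,
    cr: CouplingRelation,
    case: str,
    witness: str,
    coupled_side: Sequence[str],
    lack_sets: Dict[str, Sequence[str]],
    num_rep: str,
    q_cap: int,
) -> Tuple[str, ...]:
    """Rate constants appearing in sigma_num or sigma_den for any Q."""
    thetas = set()
    for k in coupled_side:
        thetas |= cr.lam(num_rep, k).theta_ids  # v_k / v_num_rep
    pools = [list(q) for q in lack_sets.values()]
    keys = list(lack_sets.keys())
    for n_done, combo in enumerate(itertools.product(*pools)):
        if n_done >= q_cap:
            break
        q = dict(zip(keys, combo))
        den_rep = min(combo)
        for l, partner in q.items():
            term = RatioCoeff.theta_ratio(l, partner) * cr.lam(den_rep, partner)
            thetas |= term.theta_ids
    return tuple(sorted(thetas))


def find_scc(
    net: MetabolicNetwork,
    cr: CouplingRelation,
    q_cap: int = DEFAULT_Q_CAP,
) -> List[SCCCertificate]:
    """Scan every metabolite for SCC certificates.

    ``net`` must be split and free of blocked reactions; ``cr`` is the
    merged structural + kinetic coupling relation.  For each metabolite
    ``x_i`` the witnesses scanned are the products (Case I) and the
    substrates (Case II) of the reactions consuming ``x_i`` — the only
    ODEs in which the lack relation can eliminate ``x_i``.  One
    certificate is emitted per (target, witness, case) triple that
    satisfies conditions (i)-(iii).
    """
    nminus, nplus = net.nminus, net.nplus
    # precompute lack partners: partners[l][i] = reactions lacking one i vs l
    certificates: List[SCCCertificate] = []

    def lack_partners(l: str, i: str) -> List[str]:
        return [q.id for q in net.reactions if lacks_one_substrate(net, q.id, l, i)]

    for i in net.metabolite_ids():
        s_i = net.consumers(i)
        if not s_i:
            logger.debug("metabolite %s is never consumed; skipped", i)
            continue
        witnesses_p: List[str] = []
        witnesses_s: List[str] = []
        for rid in s_i:
            rxn = net.reaction(rid)
            witnesses_p.extend(m for m in rxn.products if m not in witnesses_p)
            witnesses_s.extend(m for m in rxn.substrates if m not in witnesses_s)

        for case, pool in (("I", witnesses_p), ("II", witnesses_s)):
            for j in pool:
                p_j = net.producers(j)
                s_j = net.consumers(j)
                if not p_j or not s_j:
                    continue
                lack_side = p_j if case == "I" else s_j
                coupled_side = s_j if case == "I" else p_j
                lack_sets = {}
                ok = True
                for l in lack_side:
                    partners = lack_partners(l, i)
                    if not partners:
                        ok = False
                        break
                    lack_sets[l] = tuple(sorted(partners))
                if not ok:
                    continue
                union = sorted(set(itertools.chain.from_iterable(lack_sets.values())))
                if not cr.mutually_coupled(union):
                    continue
                if not cr.mutually_coupled(coupled_side):
                    continue
                num_rep = min(coupled_side)
                den_rep = min(union)
                thetas = _relevant_thetas(
                    net, cr, case, j, coupled_side, lack_sets, num_rep, q_cap
                )
                certificates.append(
                    SCCCertificate(
                        target=i,
                        witness=j,
                        case=case,
                        producers=tuple(sorted(p_j)),
                        consumers=tuple(sorted(s_j)),
                        lack_sets=tuple(sorted(lack_sets.items())),
                        union_set=tuple(union),
                        num_rep=num_rep,
                        den_rep=den_rep,
                        relevant_thetas=thetas,
                    )
                )
    certificates.sort(key=lambda c: (c.target, c.witness, c.case))
    return certificates


def certificate_summary(certs: Sequence[SCCCertificate], net: Optional[MetabolicNetwork] = None):
    """One row per SCC metabolite: certificates, witnesses, ratios, degrees."""
    import pandas as pd

    rows = []
    by_target: Dict[str, List[SCCCertificate]] = {}
    for cert in certs:
        by_target.setdefault(cert.target, []).append(cert)
    for target in sorted(by_target):
        group = by_target[target]
        thetas = sorted(set(itertools.chain.from_iterable(c.relevant_thetas for c in group)))
        row = {
            "metabolite": target,
            "n_certificates": len(group),
            "witnesses": ";".join(sorted({c.witness for c in group})),
            "n_relevant_thetas": len(thetas),
            "ratio_pairs": ";".join(sorted({f"{c.num_rep}/{c.den_rep}" for c in group})),
        }
        if net is not None:
            row["in_degree"] = len(net.producers(target))
            row["out_degree"] = len(net.consumers(target))
        rows.append(row)
    columns = ["metabolite", "n_certificates", "witnesses", "n_relevant_thetas", "ratio_pairs"]
    if net is not None:
        columns += ["in_degree", "out_degree"]
    return pd.DataFrame(rows, columns=columns)
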