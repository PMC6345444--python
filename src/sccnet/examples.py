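"""Small built-in example networks.

These fixtures are used throughout the documentation and tests:

* :func:`chain_network` — the three-reaction linear pathway
  import -> A -> B -> export, whose steady state is available in closed
  form (``x_A = theta_1/theta_2``, ``x_B = theta_1/theta_3``).
* :func:`demo_network` — the seven-reaction, three-metabolite
  demonstration network in which the hub metabolite B is the sole SCC
  metabolite, derivable from the ODEs of both arm products A and C.
* :func:`diamond_network` — two parallel branches between a source and
  a sink, used for projection (knockout) tests.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .network import Metabolite, MetabolicNetwork, RateConstants, Reaction

__all__ = ["chain_network", "demo_network", "diamond_network"]


def chain_network(ub: float = 1000.0) -> MetabolicNetwork:
    """Linear chain: R1: 0 -> A, R2: A -> B, R3: B -> 0."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("R1", {}, {"A": 1}, 0.0, ub),
        Reaction("R2", {"A": 1}, {"B": 1}, 0.0, ub),
        Reaction("R3", {"B": 1}, {}, 0.0, ub),
    ]
    return MetabolicNetwork(mets, rxns, id="chain")


def demo_network(ub: float = 1000.0) -> MetabolicNetwork:
    """Seven-reaction network whose hub B is the sole SCC metabolite.

    B is fed by the import R1 and drained four ways: a second-order
    export R2, the second-order arm reactions R3 (to A) and R5 (to C),
    and a first-order export R7.  A and C are cleared by second-order
    exports R4 and R6.  R3 and R5 share their substrate column (kinetic
    coupling, ``v3/v5 = theta3/theta5``); R3-R4 and R5-R6 are fully
    coupled through the balances of A and C; and R7 lacks one substrate
    molecule of B in comparison to R2 (and to R3, R5).  The ODEs of A
    and C then pin B down via the ratios ``v4/v7`` and ``v6/v7``:

        x_B = (2 theta7 / theta3) (v4 / v7) = (2 theta7 / theta5) (v6 / v7).

    Varying the import rate theta1 moves the network through different
    positive steady states while those two identities keep holding.
    """
    mets = [Metabolite("A"), Metabolite("B"), Metabolite("C")]
    rxns = [
        Reaction("R1", {}, {"B": 1}, 0.0, ub),
        Reaction("R2", {"B": 2}, {}, 0.0, ub),
        Reaction("R3", {"B": 2}, {"A": 1}, 0.0, ub),
        Reaction("R4", {"A": 2}, {}, 0.0, ub),
        Reaction("R5", {"B": 2}, {"C": 1}, 0.0, ub),
        Reaction("R6", {"C": 2}, {}, 0.0, ub),
        Reaction("R7", {"B": 1}, {}, 0.0, ub),
    ]
    return MetabolicNetwork(mets, rxns, id="demo")


def demo_theta(theta1: float = 1.0) -> RateConstants:
    """A convenient parameterization of :func:`demo_network`."""
    return RateConstants(
        {"R1": theta1, "R2": 0.4, "R3": 0.7, "R4": 0.9, "R5": 1.3, "R6": 0.6, "R7": 0.5}
    )


def diamond_network(ub: float = 1000.0) -> MetabolicNetwork:
    """R1: 0 -> A; R2, R3: A -> B in parallel; R4: B -> 0."""
    mets = [Metabolite("A"), Metabolite("B")]
    rxns = [
        Reaction("R1", {}, {"A": 1}, 0.0, ub),
        Reaction("R2", {"A": 1}, {"B": 1}, 0.0, ub),
        Reaction("R3", {"A": 1}, {"B": 1}, 0.0, ub),
        Reaction("R4", {"B": 1}, {}, 0.0, ub),
    ]
    return MetabolicNetwork(mets, rxns, id="diamond")
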