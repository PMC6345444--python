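"""Independent brute-force oracles used by the test suite.

These deliberately avoid the package's LP machinery: the flux cone is
enumerated combinatorially and couplings are read off the rays, so that
the production implementations can be checked against something that
cannot share their bugs.
"""

from __future__ import annotations

import itertools
from typing import Dict, List, Optional, Set, Tuple

import numpy as np
from scipy.linalg import null_space

TOL = 1e-9


def cone_rays(N: np.ndarray) -> List[np.ndarray]:
    """Generating rays of {v : Nv = 0, v >= 0}, sum-normalized.

    Enumerates every support subset whose restricted stoichiometry has a
    one-dimensional null space with single-signed entries.  Includes all
    extreme rays (possibly plus redundant ones, which is harmless for
    hull-based queries).  Only for small n.
    """
    n = N.shape[1]
    rays: List[np.ndarray] = []
    seen: Set[Tuple[int, ...]] = set()
    for size in range(1, n + 1):
        for support in itertools.combinations(range(n), size):
            ns = null_space(N[:, support])
            if ns.shape[1] != 1:
                continue
            d = ns[:, 0]
            if np.all(d <= TOL):
                d = -d
            if np.any(d < -TOL) or np.all(np.abs(d) <= TOL):
                continue
            v = np.zeros(n)
            v[list(support)] = np.clip(d, 0.0, None)
            v = v / v.sum()
            key = tuple(np.round(v * 1e9).astype(np.int64))
            if key not in seen:
                seen.add(key)
                rays.append(v)
    return rays


def blocked_oracle(N: np.ndarray) -> Set[int]:
    rays = cone_rays(N)
    if not rays:
        return set(range(N.shape[1]))
    V = np.array(rays)
    return {j for j in range(N.shape[1]) if np.all(V[:, j] <= TOL)}


def coupled_oracle(N: np.ndarray, i: int, j: int) -> Optional[float]:
    """lambda with v_i = lambda * v_j over the whole cone, else None."""
    rays = cone_rays(N)
    lam = None
    for v in rays:
        ai, aj = v[i] > TOL, v[j] > TOL
        if ai != aj:
            return None
        if ai and aj:
            r = v[i] / v[j]
            if lam is None:
                lam = r
            elif abs(r - lam) > 1e-6 * max(1.0, abs(lam)):
                return None
    return lam


def structural_classes_oracle(N: np.ndarray, unblocked: List[int]) -> List[Set[int]]:
    """Partition of unblocked reaction indices into fully-coupled classes."""
    parent = {j: j for j in unblocked}

    def find(a):
        while parent[a] != a:
            parent[a] = parent[parent[a]]
            a = parent[a]
        return a

    for a, b in itertools.combinations(unblocked, 2):
        if find(a) != find(b) and coupled_oracle(N, a, b) is not None:
            parent[find(a)] = find(b)
    groups: Dict[int, Set[int]] = {}
    for j in unblocked:
        groups.setdefault(find(j), set()).add(j)
    return sorted(groups.values(), key=min)


def scc_triples_oracle(net, cr) -> Set[Tuple[str, str, str]]:
    """Literal check of conditions (i)-(iii) over all (target, witness, case).

    Scans every metabolite pair without the adjacency restriction of the
    production scan, so it doubles as a proof that the restriction loses
    nothing.
    """
    from sccnet.scc import lacks_one_substrate

    triples = set()
    for i in net.metabolite_ids():
        for j in net.metabolite_ids():
            p_j = net.producers(j)
            s_j = net.consumers(j)
            if not p_j or not s_j:
                continue
            for case, lack_side, coupled_side in (
                ("I", p_j, s_j),
                ("II", s_j, p_j),
            ):
                lack_union = set()
                ok = True
                for l in lack_side:
                    q = {
                        r.id
                        for r in net.reactions
                        if lacks_one_substrate(net, r.id, l, i)
                    }
                    if not q:
                        ok = False
                        break
                    lack_union |= q
                if not ok:
                    continue
                if not cr.mutually_coupled(sorted(lack_union)):
                    continue
                if not cr.mutually_coupled(coupled_side):
                    continue
                triples.add((i, j, case))
    return triples


def steady_ensemble(sn, n_initials: int, seed: int):
    """Converged steady states from perturbed initials of a synthetic network."""
    from sccnet.simulate import integrate_to_steady_state, perturb_initials

    states = []
    for x0 in perturb_initials(sn.x0, n=n_initials, seed=seed):
        ss = integrate_to_steady_state(sn.network, sn.theta, x0)
        if ss.converged:
            states.append(ss)
    return states
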