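"""Comparison metrics and robustness experiments.

Predicted concentration ranges are compared against simulated ones by
rank and linear correlation of the bound vectors, three Euclidean
distance variants (raw, log10-transformed, and max-normalized — the
latter two compensate for concentrations spanning decades), and an
interval classification (predicted inside simulated / overlapping /
disjoint).  Two experiment drivers reproduce the robustness protocols:
random removal of relevant rate constants with ratio substitution, and
replacement of the true flux ratios by LP-derived ranges.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .bounds import intersect_ranges, range_over_fluxes
from .coupling import CouplingRelation
from .network import MetabolicNetwork
from .ratio_lp import ConditionConstraints, optimize_weighted_objective, ratio_range_at_optimum
from .scc import SCCCertificate

logger = logging.getLogger(__name__)

__all__ = [
    "ComparisonRecord",
    "compare_bounds",
    "predict_ranges",
    "rate_constant_robustness",
    "flux_ratio_robustness",
]

Interval = Tuple[float, float]


@dataclass
class ComparisonRecord:
    metabolites: Tuple[str, ...]
    predicted: Dict[str, Interval]
    simulated: Dict[str, Interval]
    pearson_lower: float
    pearson_upper: float
    pearson_range: float  # on the concatenated (lower, upper) vectors
    spearman_lower: float
    spearman_upper: float
    dist_raw: Dict[str, float]
    dist_log: Dict[str, float]
    dist_maxnorm: Dict[str, float]
    n_inside: int
    n_overlap: int
    n_disjoint: int
    cv_simulated: Optional[Dict[str, float]] = None


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if len(a) < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")  # undefined, not zero
    if method == "pearson":
        return float(stats.pearsonr(a, b)[0])
    return float(stats.spearmanr(a, b)[0])


def _distances(a: np.ndarray, b: np.ndarray) -> Tuple[float, float, float]:
    raw = float(np.linalg.norm(a - b))
    log = float(np.linalg.norm(np.log10(a) - np.log10(b)))
    maxnorm = float(np.linalg.norm(a / a.max() - b / b.max()))
    return raw, log, maxnorm


def compare_bounds(
    predicted: Mapping[str, Interval],
    simulated: Mapping[str, Interval],
    simulated_concentrations: Optional[Mapping[str, Sequence[float]]] = None,
) -> ComparisonRecord:
    """Correlations, distances and containment between two range maps."""
    mets = tuple(sorted(set(predicted) & set(simulated)))
    if not mets:
        raise ValueError("no common metabolites to compare")
    p_lo = np.array([predicted[m][0] for m in mets])
    p_hi = np.array([predicted[m][1] for m in mets])
    s_lo = np.array([simulated[m][0] for m in mets])
    s_hi = np.array([simulated[m][1] for m in mets])

    inside = overlap = disjoint = 0
    for m in mets:
        plo, phi = predicted[m]
        slo, shi = simulated[m]
        if plo >= slo and phi <= shi:
            inside += 1
        elif phi < slo or plo > shi:
            disjoint += 1
        else:
            overlap += 1

    d_lo = _distances(p_lo, s_lo)
    d_hi = _distances(p_hi, s_hi)
    cv = None
    if simulated_concentrations is not None:
        cv = {
            m: float(np.std(simulated_concentrations[m]) / np.mean(simulated_concentrations[m]))
            for m in mets
            if m in simulated_concentrations
        }
    cat = np.concatenate
    return ComparisonRecord(
        metabolites=mets,
        predicted={m: predicted[m] for m in mets},
        simulated={m: simulated[m] for m in mets},
        pearson_lower=_corr(p_lo, s_lo, "pearson"),
        pearson_upper=_corr(p_hi, s_hi, "pearson"),
        pearson_range=_corr(cat([p_lo, p_hi]), cat([s_lo, s_hi]), "pearson"),
        spearman_lower=_corr(p_lo, s_lo, "spearman"),
        spearman_upper=_corr(p_hi, s_hi, "spearman"),
        dist_raw={"lower": d_lo[0], "upper": d_hi[0]},
        dist_log={"lower": d_lo[1], "upper": d_hi[1]},
        dist_maxnorm={"lower": d_lo[2], "upper": d_hi[2]},
        n_inside=inside,
        n_overlap=overlap,
        n_disjoint=disjoint,
        cv_simulated=cv,
    )


def predict_ranges(
    net: MetabolicNetwork,
    certs: Sequence[SCCCertificate],
    theta: Optional[Mapping[str, float]],
    cr: CouplingRelation,
    flux_set: Sequence[Mapping[str, float]],
    scheme: Optional[str] = None,
) -> Dict[str, Interval]:
    """Intersected per-metabolite concentration ranges over a flux set.

    Certificates whose relevant fluxes vanish in every member are
    skipped; the per-ODE intervals of the remaining certificates are
    intersected (crossed intervals are kept as-is so that downstream
    comparisons can still see the bound values).
    """
    per_met: Dict[str, Dict[object, Interval]] = {}
    for idx, cert in enumerate(certs):
        try:
            interval = range_over_fluxes(cert, theta, cr, net, flux_set, scheme=scheme)
        except (ValueError, KeyError):
            continue
        per_met.setdefault(cert.target, {})[(cert.witness, cert.case, idx)] = interval
    out = {}
    for met, per_ode in per_met.items():
        rng = intersect_ranges(per_ode)
        out[met] = (rng.lower, rng.upper)
    return out


def rate_constant_robustness(
    net: MetabolicNetwork,
    theta: Mapping[str, float],
    certs: Sequence[SCCCertificate],
    cr: CouplingRelation,
    flux_set: Sequence[Mapping[str, float]],
    simulated: Mapping[str, Interval],
    fractions: Sequence[float] = (10, 30, 50, 70, 90),
    schemes: Sequence[str] = ("one", "mean", "median"),
    reps: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Remove relevant rate constants at random and re-predict.

    For each removal fraction (percent), substitution scheme and
    repetition, the stated share of the *relevant* rate constants (the
    union over certificates — removing irrelevant constants cannot
    change anything) is deleted, missing ratios are substituted, ranges
    recomputed and compared against the simulated ranges.  Returns a
    long-format table (fraction, scheme, rep, metric, value);
    reproducible for a fixed seed.
    """
    pool = sorted(set().union(*(c.relevant_thetas for c in certs)) & set(theta))
    rng = np.random.default_rng(seed)
    rows = []
    for fraction in fractions:
        n_remove = int(round(len(pool) * fraction / 100.0))
        for rep in range(reps):
            removed = set(rng.choice(pool, size=n_remove, replace=False)) if n_remove else set()
            partial = {k: v for k, v in theta.items() if k not in removed}
            for scheme in schemes:
                predicted = predict_ranges(net, certs, partial, cr, flux_set, scheme=scheme)
                rec = compare_bounds(predicted, simulated)
                for metric, value in (
                    ("pearson_lower", rec.pearson_lower),
                    ("pearson_upper", rec.pearson_upper),
                    ("pearson_range", rec.pearson_range),
                    ("spearman_lower", rec.spearman_lower),
                    ("spearman_upper", rec.spearman_upper),
                    ("dist_log_lower", rec.dist_log["lower"]),
                    ("dist_log_upper", rec.dist_log["upper"]),
                    ("dist_maxnorm_lower", rec.dist_maxnorm["lower"]),
                    ("dist_maxnorm_upper", rec.dist_maxnorm["upper"]),
                ):
                    rows.append(
                        {
                            "fraction": fraction,
                            "scheme": scheme,
                            "rep": rep,
                            "metric": metric,
                            "value": value,
                        }
                    )
    return pd.DataFrame(rows)


def flux_ratio_robustness(
    net: MetabolicNetwork,
    certs: Sequence[SCCCertificate],
    theta: Mapping[str, float],
    cr: CouplingRelation,
    cond: ConditionConstraints,
    simulated: Mapping[str, Interval],
    w_atp: float = 1.0,
    w_flux: float = 0.01,
    atp_reaction: str = "ATP",
    mode: str = "scaled",
) -> ComparisonRecord:
    """Predict ranges from LP flux-ratio ranges at the weighted optimum.

    Full rate-constant knowledge is kept; only the relevant flux ratios
    are replaced by their constraint-based ranges, mirroring the
    situation where fluxes are unknown but exchange rates are measured.
    """
    z_star, _ = optimize_weighted_objective(
        net, None, cond, w_atp=w_atp, w_flux=w_flux, atp_reaction=atp_reaction
    )
    per_met: Dict[str, Dict[object, Interval]] = {}
    for idx, cert in enumerate(certs):
        result = ratio_range_at_optimum(
            net,
            cond,
            z_star,
            cert.ratio_pair,
            mode=mode,
            w_atp=w_atp,
            w_flux=w_flux,
            atp_reaction=atp_reaction,
        )
        if not result.bounded or result.ratio_min <= 0:
            logger.info(
                "certificate %s/%s: unbounded or degenerate LP ratio range", cert.target, cert.witness
            )
            continue
        interval = range_over_fluxes(cert, theta, cr, net, result.interval)
        per_met.setdefault(cert.target, {})[(cert.witness, cert.case, idx)] = interval
    predicted = {}
    for met, per_ode in per_met.items():
        rng = intersect_ranges(per_ode)
        predicted[met] = (rng.lower, rng.upper)
    return compare_bounds(predicted, simulated)
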