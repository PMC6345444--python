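"""Calibrating sigma ratios from measured concentrations.

The ratio ``sigma_num / sigma_den`` of a certificate is, by
construction, invariant across growth conditions (as long as the
relevant fluxes stay positive).  Given a measured concentration in a
reference condition and an LP-derived range for the relevant flux
ratio, interval division yields an estimate of the sigma ratio; that
estimate, multiplied by the flux-ratio range of an unseen condition,
predicts the concentration range there.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Sequence, Tuple

__all__ = [
    "CalibrationResult",
    "estimate_sigma_ratio",
    "combine_replicates",
    "predict_new_condition",
    "volumetric_to_specific",
    "CELL_VOLUME_PER_GDW",
]

#: aqueous cell volume per gram dry weight (L/gDW) used to convert
#: volumetric concentrations (mM) into specific ones (mmol/gDW)
CELL_VOLUME_PER_GDW = 0.0023


def volumetric_to_specific(conc_mM: float, volume_per_gdw: float = CELL_VOLUME_PER_GDW) -> float:
    """mM -> mmol/gDW via the cell-volume-to-dry-weight ratio."""
    return conc_mM * volume_per_gdw


Interval = Tuple[float, float]


@dataclass
class CalibrationResult:
    metabolite: str
    ratio_pair: Tuple[str, str]
    per_replicate: Dict[str, Interval]
    combined: Interval
    replicates_overlap: bool


def estimate_sigma_ratio(x_meas: float, ratio_range: Interval) -> Interval:
    """Interval for sigma_num/sigma_den from x = (sigma ratio) * (flux ratio).

    With the flux ratio in ``[r_min, r_max]`` and measured concentration
    ``x``, the sigma ratio lies in ``[x / r_max, x / r_min]``.
    """
    r_min, r_max = ratio_range
    if x_meas <= 0:
        raise ValueError("measured concentration must be positive")
    if r_min <= 0:
        raise ValueError("flux-ratio range touching zero gives an unbounded estimate")
    if r_min > r_max:
        raise ValueError("invalid ratio range (min > max)")
    return (x_meas / r_max, x_meas / r_min)


def combine_replicates(
    intervals: Sequence[Interval], mode: str = "envelope"
) -> Tuple[Interval, bool]:
    """Combine per-replicate sigma-ratio intervals.

    ``envelope`` (default) takes [min of lowers, max of uppers], the
    across-replicates prediction; ``intersection`` is the optimistic
    alternative.  Also returns whether all replicate intervals mutually
    overlap — disagreement flags poor reproducibility of the reference
    measurements.
    """
    if not intervals:
        raise ValueError("at least one replicate interval is required")
    if mode not in {"envelope", "intersection"}:
        raise ValueError(f"unknown combination mode {mode!r}")
    lows = [lo for lo, _ in intervals]
    highs = [hi for _, hi in intervals]
    overlap = max(lows) <= min(highs)
    if mode == "envelope":
        return (min(lows), max(highs)), overlap
    return (max(lows), min(highs)), overlap


def predict_new_condition(sigma_interval: Interval, new_ratio_range: Interval) -> Interval:
    """Concentration interval for an unseen condition.

    With both factors positive, the product interval is
    ``[sigma_min * r_min, sigma_max * r_max]``.  Feed the result to
    :func:`sccnet.bounds.intersect_ranges` when a metabolite carries
    several certificates.
    """
    s_min, s_max = sigma_interval
    r_min, r_max = new_ratio_range
    if s_min <= 0 or r_min <= 0:
        raise ValueError("both intervals must be strictly positive")
    return (s_min * r_min, s_max * r_max)
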