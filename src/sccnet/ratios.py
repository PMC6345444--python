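"""Symbolic monomials in rate constants.

Flux-ratio coefficients produced by reaction coupling are either plain
numbers (structural coupling, fixed by stoichiometry alone) or monomials
in the mass-action rate constants ``theta`` (kinetic coupling, e.g.
``theta_l / theta_k`` for two reactions sharing a substrate column).
:class:`RatioCoeff` represents both uniformly: a positive numeric factor
times a product of rate constants raised to integer powers.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Optional

__all__ = ["RatioCoeff", "MissingRateConstant"]


class MissingRateConstant(KeyError):
    """A numeric value was requested but some rate constants are unknown."""

    def __init__(self, missing):
        self.missing = sorted(missing)
        super().__init__(
            "rate constants required but not provided: " + ", ".join(self.missing)
        )


@dataclass(frozen=True)
class RatioCoeff:
    """A positive coefficient of the form ``c * prod_r theta_r ** e_r``.

    Parameters
    ----------
    coeff:
        Strictly positive numeric factor.
    powers:
        Map reaction id -> integer exponent of its rate constant.
        Zero exponents are dropped on construction.
    """

    coeff: float = 1.0
    powers: Mapping[str, int] = field(default_factory=dict)

    def __post_init__(self):
        if self.coeff <= 0:
            raise ValueError("ratio coefficients must be strictly positive")
        cleaned = {r: int(e) for r, e in self.powers.items() if e != 0}
        object.__setattr__(self, "powers", cleaned)

    # -- constructors -------------------------------------------------
    @classmethod
    def number(cls, value: float) -> "RatioCoeff":
        return cls(float(value), {})

    @classmethod
    def theta_ratio(cls, numerator: str, denominator: str) -> "RatioCoeff":
        """The ratio ``theta_numerator / theta_denominator``."""
        if numerator == denominator:
            return cls.number(1.0)
        return cls(1.0, {numerator: 1, denominator: -1})

    # -- algebra ------------------------------------------------------
    def __mul__(self, other: "RatioCoeff") -> "RatioCoeff":
        if isinstance(other, (int, float)):
            other = RatioCoeff.number(other)
        powers: Dict[str, int] = dict(self.powers)
        for r, e in other.powers.items():
            powers[r] = powers.get(r, 0) + e
        return RatioCoeff(self.coeff * other.coeff, powers)

    __rmul__ = __mul__

    def __truediv__(self, other: "RatioCoeff") -> "RatioCoeff":
        return self * other.inverse()

    def inverse(self) -> "RatioCoeff":
        return RatioCoeff(1.0 / self.coeff, {r: -e for r, e in self.powers.items()})

    # -- queries ------------------------------------------------------
    @property
    def is_numeric(self) -> bool:
        return not self.powers

    @property
    def theta_ids(self):
        """Rate constants appearing with non-zero exponent."""
        return frozenset(self.powers)

    def value(self, theta: Optional[Mapping[str, float]] = None) -> float:
        """Evaluate numerically, raising if rate constants are missing."""
        if self.is_numeric:
            return self.coeff
        theta = theta or {}
        missing = [r for r in self.powers if r not in theta]
        if missing:
            raise MissingRateConstant(missing)
        out = self.coeff
        for r, e in self.powers.items():
            out *= theta[r] ** e
        return out

    def agrees_with(self, other: "RatioCoeff", rtol: float = 1e-6) -> bool:
        """Consistency of two coefficients (used for cycle checks).

        Symbolic parts must match exactly; numeric parts to relative
        tolerance.
        """
        if dict(self.powers) != dict(other.powers):
            return False
        return abs(self.coeff - other.coeff) <= rtol * max(
            abs(self.coeff), abs(other.coeff), 1e-12
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        if self.is_numeric:
            return f"{self.coeff:g}"
        sym = "*".join(
            f"theta[{r}]^{e}" if e != 1 else f"theta[{r}]"
            for r, e in sorted(self.powers.items())
        )
        return f"{self.coeff:g}*{sym}" if self.coeff != 1.0 else sym
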