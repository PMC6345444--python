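"""Readers and writers for networks, rate constants and measurements.

Three network formats are supported:

``tsv``
    The package's own plain-text dialect, one reaction per row::

        R1\t\tA\t0\t1000
        R2\tA\t2 B + C\t0\t1000
        @metabolite\tA\talpha-thing\tc

    Columns: reaction id, substrate list (``2 A + B``), product list,
    lower bound, upper bound.  Rows starting ``@metabolite`` declare
    metabolites (id, name, compartment); when at least one declaration
    is present, referencing an undeclared metabolite is an error,
    otherwise metabolites are inferred from the reactions.  ``#`` lines
    are comments.

``sbml`` / ``bigg-json``
    Read through :mod:`cobra`.
"""

from __future__ import annotations

import re
from pathlib import Path
from typing import Dict, List, Tuple

import pandas as pd

from .network import (
    Metabolite,
    MetabolicNetwork,
    NetworkValidationError,
    RateConstants,
    Reaction,
)

__all__ = [
    "read_network",
    "write_network",
    "read_rate_constants",
    "write_rate_constants",
    "network_from_cobra",
    "ParseError",
]


class ParseError(ValueError):
    """A file does not parse under the declared format."""


_TERM_RE = re.compile(r"^\s*(?:(\d+(?:\.\d+)?)\s+)?(\S+)\s*$")


def _parse_side(text: str, rxn_id: str) -> Dict[str, float]:
    text = text.strip()
    if not text:
        return {}
    side: Dict[str, float] = {}
    for term in text.split("+"):
        match = _TERM_RE.match(term)
        if match is None:
            raise ParseError(f"reaction {rxn_id}: cannot parse term {term!r}")
        coeff = float(match.group(1)) if match.group(1) else 1.0
        met = match.group(2)
        side[met] = side.get(met, 0.0) + coeff
    return side


def _format_side(side: Dict[str, float]) -> str:
    parts = []
    for met in sorted(side):
        coeff = side[met]
        if coeff == int(coeff):
            coeff = int(coeff)
        parts.append(f"{coeff} {met}" if coeff != 1 else met)
    return " + ".join(parts)


def _read_tsv(path: Path) -> MetabolicNetwork:
    declared: List[Metabolite] = []
    reactions: List[Reaction] = []
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.rstrip("\n")
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        fields = line.split("\t")
        if fields[0] == "@metabolite":
            if len(fields) < 2:
                raise ParseError(f"{path}:{lineno}: metabolite row without id")
            declared.append(
                Metabolite(
                    id=fields[1],
                    name=fields[2] if len(fields) > 2 else "",
                    compartment=fields[3] if len(fields) > 3 else "",
                )
            )
            continue
        if len(fields) != 5:
            raise ParseError(
                f"{path}:{lineno}: expected 5 tab-separated fields, got {len(fields)}"
            )
        rid, subs, prods, lb, ub = fields
        try:
            reactions.append(
                Reaction(
                    id=rid,
                    substrates=_parse_side(subs, rid),
                    products=_parse_side(prods, rid),
                    lb=float(lb),
                    ub=float(ub),
                )
            )
        except ValueError as exc:
            raise ParseError(f"{path}:{lineno}: reaction {rid}: {exc}") from exc
    if declared:
        metabolites = declared
        ids = {m.id for m in declared}
        for rxn in reactions:
            for met in list(rxn.substrates) + list(rxn.products):
                if met not in ids:
                    raise NetworkValidationError(
                        f"reaction {rxn.id} references undeclared metabolite {met}"
                    )
    else:
        seen: Dict[str, None] = {}
        for rxn in reactions:
            for met in list(rxn.substrates) + list(rxn.products):
                seen.setdefault(met, None)
        metabolites = [Metabolite(id=m) for m in seen]
    return MetabolicNetwork(metabolites, reactions, id=path.stem)


def network_from_cobra(model) -> MetabolicNetwork:
    """Convert a :class:`cobra.Model` into a :class:`MetabolicNetwork`."""
    metabolites = [
        Metabolite(id=m.id, name=m.name or "", compartment=m.compartment or "")
        for m in model.metabolites
    ]
    reactions = []
    for rxn in model.reactions:
        substrates: Dict[str, float] = {}
        products: Dict[str, float] = {}
        for met, coeff in rxn.metabolites.items():
            if coeff < 0:
                substrates[met.id] = -float(coeff)
            elif coeff > 0:
                products[met.id] = float(coeff)
        reactions.append(
            Reaction(
                id=rxn.id,
                substrates=substrates,
                products=products,
                lb=float(rxn.lower_bound),
                ub=float(rxn.upper_bound),
            )
        )
    return MetabolicNetwork(metabolites, reactions, id=model.id or "")


def read_network(path, format: str = "tsv") -> MetabolicNetwork:
    """Read a network from ``path`` in the named format.

    ``format`` is one of ``tsv``, ``sbml``, ``bigg-json``.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "tsv":
        return _read_tsv(path)
    if format in {"sbml", "bigg-json"}:
        import cobra.io

        try:
            if format == "sbml":
                model = cobra.io.read_sbml_model(str(path))
            else:
                model = cobra.io.load_json_model(str(path))
        except Exception as exc:  # cobra raises a zoo of types
            raise ParseError(f"{path}: {exc}") from exc
        return network_from_cobra(model)
    raise ValueError(f"unknown format {format!r}")


def write_network(net: MetabolicNetwork, path) -> None:
    """Write the TSV dialect; round-trips bit-for-bit through read_network."""
    path = Path(path)
    lines = []
    for met in net.metabolites:
        lines.append(f"@metabolite\t{met.id}\t{met.name}\t{met.compartment}")
    for rxn in net.reactions:
        lines.append(
            "\t".join(
                [
                    rxn.id,
                    _format_side(rxn.substrates),
                    _format_side(rxn.products),
                    repr(rxn.lb),
                    repr(rxn.ub),
                ]
            )
        )
    path.write_text("\n".join(lines) + "\n")


def read_rate_constants(path) -> RateConstants:
    """Two-column TSV: reaction id, theta."""
    frame = pd.read_csv(path, sep="\t", header=None, comment="#")
    if frame.shape[1] < 2:
        raise ParseError(f"{path}: expected two columns (reaction id, theta)")
    return RateConstants(dict(zip(frame[0].astype(str), frame[1].astype(float))))


def write_rate_constants(theta: RateConstants, path) -> None:
    pd.DataFrame(sorted(theta.items())).to_csv(path, sep="\t", header=False, index=False)
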