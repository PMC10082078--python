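"""Model reading/writing and classification reports.

Models come in three forms: a small JSON document (the package's native
format), an equivalent TSV table, and SBML Level 3 (with FBC flux bounds
when present).  The equation grammar is

    term ("+" term)* ("->" | "<->" | "<=>") term ("+" term)*

where a term is an optional positive rational coefficient followed by a
species identifier, and an empty side is written "∅" or "0".  Bounds left
unspecified default to the canonical unbounded regime: ub = +inf for all
reactions, lb = 0 for irreversible ones and -inf for reversible ones.
Infinite bounds serialize as the strings "-inf"/"inf"; SBML bound values
pass through verbatim (no clamping), because the type-II classification is
sensitive to the exact bound values.
"""

from __future__ import annotations

import csv
import json
import logging
import re
import warnings
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np

from .crn import (
    CRN,
    EMPTY_COMPLEX_SYMBOL,
    FluxBounds,
    Multiset,
    build_crn,
    format_complex,
)
from .factorize import (
    CLASS_LABELS,
    NOT_BALANCED,
    STOICHIOMETRIC,
    STRICTLY_STOICHIOMETRIC,
)
from .lp import BalanceResult

logger = logging.getLogger("balcom")

_ARROWS = ("<->", "<=>", "->")
_COEFF_RE = re.compile(r"^(\d+(?:\.\d+)?(?:/\d+)?)\s*(.*)$")
_EMPTY_TOKENS = {EMPTY_COMPLEX_SYMBOL, "0"}


@dataclass
class ReactionEntry:
    id: str
    equation: str
    reversible: bool
    lb: float
    ub: float


@dataclass
class ModelDocument:
    """A parsed model file: reaction equations plus flux bounds."""

    model_id: str
    reactions: list[ReactionEntry] = field(default_factory=list)
    annotations: dict = field(default_factory=dict)

    def __post_init__(self):
        seen = set()
        for entry in self.reactions:
            if entry.id in seen:
                raise ValueError(f"duplicate reaction id {entry.id!r}")
            seen.add(entry.id)


def parse_reaction_equation(text: str) -> tuple[Multiset, Multiset, bool]:
    """Parse one reaction equation into (substrates, products, reversible)."""
    arrow = next((a for a in _ARROWS if a in text), None)
    if arrow is None:
        raise ValueError(f"no reaction arrow in {text!r}")
    left, right = text.split(arrow, 1)
    if any(a in right for a in _ARROWS):
        raise ValueError(f"multiple arrows in {text!r}")
    reversible = arrow in ("<->", "<=>")
    return _parse_side(left, text), _parse_side(right, text), reversible


def _parse_side(side: str, context: str) -> Multiset:
    side = side.strip()
    if side in _EMPTY_TOKENS:
        return {}
    if not side:
        raise ValueError(f"empty reaction side in {context!r} (write ∅ or 0)")
    out: Multiset = {}
    for term in side.split("+"):
        term = term.strip()
        if not term:
            raise ValueError(f"dangling '+' in {context!r}")
        coeff = Fraction(1)
        match = _COEFF_RE.match(term)
        if match and match.group(2):
            coeff = Fraction(match.group(1))
            term = match.group(2).strip()
        if not term or not re.fullmatch(r"[^\s+<>-]+", term):
            raise ValueError(f"malformed term in {context!r}")
        if coeff <= 0:
            raise ValueError(f"non-positive coefficient in {context!r}")
        if term in out:
            warnings.warn(
                f"species {term!r} repeated on one side of {context!r}; merging",
                stacklevel=2,
            )
        out[term] = out.get(term, Fraction(0)) + coeff
    return out


def format_equation(sub: Multiset, prod: Multiset, reversible: bool) -> str:
    arrow = "<->" if reversible else "->"
    return f"{format_complex(sub)} {arrow} {format_complex(prod)}"


# ---------------------------------------------------------------------------
# document <-> network
# ---------------------------------------------------------------------------


def document_to_network(doc: ModelDocument) -> tuple[CRN, FluxBounds]:
    triples = []
    for entry in doc.reactions:
        sub, prod, rev_from_eq = parse_reaction_equation(entry.equation)
        reversible = entry.reversible if entry.reversible is not None else rev_from_eq
        triples.append((sub, prod, reversible))
    crn = build_crn(triples)
    bounds = FluxBounds(
        tuple(e.lb for e in doc.reactions), tuple(e.ub for e in doc.reactions)
    )
    return crn, bounds


def network_to_document(
    crn: CRN, bounds: FluxBounds, model_id: str = "model"
) -> ModelDocument:
    entries = []
    for k, ((sub, prod), rev) in enumerate(zip(crn.reactions, bounds.reversible_flags)):
        entries.append(
            ReactionEntry(
                id=f"R{k+1}",
                equation=format_equation(crn.complexes[sub], crn.complexes[prod], rev),
                reversible=rev,
                lb=bounds.lb[k],
                ub=bounds.ub[k],
            )
        )
    return ModelDocument(model_id, entries)


def _default_bounds(reversible: bool) -> tuple[float, float]:
    return (-np.inf if reversible else 0.0, np.inf)


def _parse_bound(value, default: float) -> float:
    if value is None or value == "":
        return default
    if isinstance(value, str):
        return float(value)  # handles "inf"/"-inf"
    return float(value)


def _bound_str(x: float) -> Union[str, float]:
    if np.isinf(x):
        return "inf" if x > 0 else "-inf"
    return x


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def read_model(
    path: Union[str, Path], format: str = "auto"
) -> tuple[CRN, FluxBounds]:
    """Read a model file (JSON / TSV / SBML) into (CRN, FluxBounds)."""
    path = Path(path)
    if format == "auto":
        suffix = path.suffix.lower()
        format = {
            ".json": "json",
            ".tsv": "tsv",
            ".txt": "tsv",
            ".xml": "sbml",
            ".sbml": "sbml",
        }.get(suffix)
        if format is None:
            raise ValueError(f"cannot infer model format from {path.name!r}")
    doc = read_document(path, format)
    logger.info("read model %s: %d reactions", doc.model_id, len(doc.reactions))
    return document_to_network(doc)


def read_document(path: Union[str, Path], format: str) -> ModelDocument:
    path = Path(path)
    if format == "json":
        return _read_json(path)
    if format == "tsv":
        return _read_tsv(path)
    if format == "sbml":
        return _read_sbml(path)
    raise ValueError(f"unknown model format {format!r}")


def _entry_from_fields(rid, equation, reversible, lb, ub) -> ReactionEntry:
    _, _, rev_from_eq = parse_reaction_equation(equation)
    if reversible is None:
        reversible = rev_from_eq
    else:
        reversible = bool(reversible) if not isinstance(reversible, str) else (
            reversible.strip().lower() in ("1", "true", "yes")
        )
    d_lb, d_ub = _default_bounds(reversible)
    lb = _parse_bound(lb, d_lb)
    ub = _parse_bound(ub, d_ub)
    if lb > ub:
        raise ValueError(f"reaction {rid!r}: lb {lb} > ub {ub}")
    return ReactionEntry(str(rid), equation, reversible, lb, ub)


def _read_json(path: Path) -> ModelDocument:
    data = json.loads(path.read_text())
    entries = [
        _entry_from_fields(
            rx.get("id", f"R{k+1}"),
            rx["equation"],
            rx.get("reversible"),
            rx.get("lb"),
            rx.get("ub"),
        )
        for k, rx in enumerate(data["reactions"])
    ]
    return ModelDocument(data.get("id", path.stem), entries,
                         data.get("annotations", {}))


def _read_tsv(path: Path) -> ModelDocument:
    with path.open() as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        entries = [
            _entry_from_fields(
                row.get("id", f"R{k+1}"),
                row["equation"],
                row.get("reversible") or None,
                row.get("lb") or None,
                row.get("ub") or None,
            )
            for k, row in enumerate(reader)
        ]
    return ModelDocument(path.stem, entries)


def _read_sbml(path: Path) -> ModelDocument:
    import libsbml

    doc = libsbml.readSBMLFromString(Path(path).read_text())
    if doc.getNumErrors(libsbml.LIBSBML_SEV_ERROR):
        raise ValueError(f"unreadable SBML file {path}")
    model = doc.getModel()
    if model is None:
        raise ValueError(f"no model in SBML file {path}")
    entries = []
    for rx in model.getListOfReactions():
        if not rx.isSetReversible():
            raise ValueError(f"SBML reaction {rx.getId()!r} lacks reversibility")
        reversible = rx.getReversible()
        sub = _sbml_side(rx.getListOfReactants())
        prod = _sbml_side(rx.getListOfProducts())
        lb = ub = None
        fbc = rx.getPlugin("fbc")
        if fbc is not None:
            lb = _sbml_bound(model, fbc.getLowerFluxBound())
            ub = _sbml_bound(model, fbc.getUpperFluxBound())
        equation = format_equation(sub, prod, reversible)
        entries.append(_entry_from_fields(rx.getId(), equation, reversible, lb, ub))
    return ModelDocument(model.getId() or path.stem, entries)


def _sbml_side(refs) -> Multiset:
    out: Multiset = {}
    for ref in refs:
        c = Fraction(ref.getStoichiometry()).limit_denominator(10**6)
        out[ref.getSpecies()] = out.get(ref.getSpecies(), Fraction(0)) + c
    return {sp: c for sp, c in out.items() if c != 0}


def _sbml_bound(model, param_id: Optional[str]):
    if not param_id:
        return None
    param = model.getParameter(param_id)
    return param.getValue() if param is not None else None


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_model(
    crn: CRN,
    bounds: FluxBounds,
    path: Union[str, Path],
    model_id: str = "model",
) -> None:
    """Write the native JSON model document."""
    Path(path).write_text(render_model(crn, bounds, model_id))


def render_model(crn: CRN, bounds: FluxBounds, model_id: str = "model") -> str:
    doc = network_to_document(crn, bounds, model_id)
    payload = {
        "id": doc.model_id,
        "reactions": [
            {
                "id": e.id,
                "equation": e.equation,
                "reversible": e.reversible,
                "lb": _bound_str(e.lb),
                "ub": _bound_str(e.ub),
            }
            for e in doc.reactions
        ],
    }
    return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"


_REPORT_COLUMNS = (
    "complex_index",
    "complex_formula",
    "balanced",
    "class",
    "min_net_flux",
    "max_net_flux",
    "certificate",
)


def summarize(results: Sequence[BalanceResult]) -> dict:
    """Per-class counts and percentages among balanced complexes.

    Percentages are reported in both conventions: classes disjoint with the
    strictly stoichiometric group broken out, and stoichiometric including
    its strict subclass.
    """
    counts = {label: 0 for label in CLASS_LABELS}
    for res in results:
        counts[res.class_label or NOT_BALANCED] += 1
    n_balanced = sum(1 for res in results if res.balanced)
    pct = {
        label: (100.0 * counts[label] / n_balanced if n_balanced else 0.0)
        for label in CLASS_LABELS
        if label != NOT_BALANCED
    }
    pct_inclusive = dict(pct)
    pct_inclusive[STOICHIOMETRIC] = (
        pct[STOICHIOMETRIC] + pct[STRICTLY_STOICHIOMETRIC]
    )
    return {
        "n_complexes": len(results),
        "n_balanced": n_balanced,
        "counts": counts,
        "percent_of_balanced": pct,
        "percent_of_balanced_stoichiometric_including_strict": pct_inclusive,
    }


def write_report(
    results: Sequence[BalanceResult],
    path: Union[str, Path],
    format: str = "tsv",
    header: Optional[dict] = None,
) -> None:
    """Write the per-complex classification report (TSV or JSON).

    Complex indices are reported 1-based.  The TSV embeds the per-class
    summary as '#'-prefixed header lines; the JSON embeds certificates and
    the summary object.  ``header`` carries provenance metadata (e.g. the
    bounds source) verbatim.
    """
    Path(path).write_text(render_report(results, format, header))


def render_report(
    results: Sequence[BalanceResult],
    format: str = "tsv",
    header: Optional[dict] = None,
) -> str:
    summary = summarize(results)
    if format == "json":
        payload = {
            "header": header or {},
            "summary": summary,
            "results": [
                {
                    "complex_index": res.complex_index + 1,
                    "complex_formula": res.formula,
                    "balanced": res.balanced,
                    "class": res.class_label,
                    "min_net_flux": res.min_opt,
                    "max_net_flux": res.max_opt,
                    "flags": res.flags,
                    "certificate": res.certificate,
                }
                for res in results
            ],
        }
        return json.dumps(payload, indent=2, ensure_ascii=False) + "\n"
    if format != "tsv":
        raise ValueError(f"unknown report format {format!r}")
    lines = []
    for key, val in (header or {}).items():
        lines.append(f"# {key}: {val}")
    lines.append(f"# balanced: {summary['n_balanced']} / {summary['n_complexes']}")
    for label, p in summary["percent_of_balanced"].items():
        lines.append(f"# percent_{label}: {p:.1f}")
    lines.append("\t".join(_REPORT_COLUMNS))
    for res in results:
        cert = "embedded:json" if res.certificate else ""
        lines.append(
            "\t".join(
                [
                    str(res.complex_index + 1),
                    res.formula,
                    str(res.balanced).lower(),
                    res.class_label or "",
                    "" if res.min_opt is None else f"{res.min_opt + 0.0:.6g}",
                    "" if res.max_opt is None else f"{res.max_opt + 0.0:.6g}",
                    cert,
                ]
            )
        )
    return "\n".join(lines) + "\n"
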