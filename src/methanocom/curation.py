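"""Curation diagnostics and physiological constraints for methanotroph models.

Two concerns live here. First, elemental/charge balance auditing: every
internal reaction with fully specified metabolite formulas is checked
for net element and charge imbalance, and imbalances repairable by
adding protons to one side are flagged as such. Second, the
study-specific physiological constraints applied after reconstruction:

* a fixed non-growth-associated ATP maintenance (NGAM) flux,
  21.6 mmol/gDCW/hr by default;
* formaldehyde assimilation restricted to the RuMP cycle and the
  tetrahydrofolate-associated pathways — the direct formaldehyde entry
  into the serine cycle is shut off while the rest of the cycle stays
  usable from other inputs;
* fixed oxygen stoichiometry in the methane-oxidation electron-transfer
  reactions (1 O2 per pyrroloquinoline quinone in the direct-coupling
  mode, 0.5 O2 per cytochrome c at the oxidase);
* replacement of the biomass reaction coefficients with a configured
  biomass composition (mmol per gDCW).

Reactions are matched to these roles through an explicit tag map in the
configuration; nothing is pattern-guessed, because reaction identifiers
differ between reconstructions.
"""

from __future__ import annotations

import csv
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import cobra

PROTON_FORMULA = {"H": 1}

#: Default NGAM flux (mmol/gDCW/hr), from measured maintenance in a
#: closely related alkaliphilic methanotroph.
DEFAULT_NGAM = 21.6


class CurationWarning(UserWarning):
    """A curation step matched nothing or was skipped."""


@dataclass(frozen=True)
class BalanceReport:
    """Balance audit result for one reaction.

    ``auditable`` is False when a participating metabolite lacks a
    formula; such reactions are reported but never counted imbalanced.
    ``proton_fixable`` means adding k protons to one side zeroes the
    hydrogen and charge imbalance simultaneously.
    """

    reaction_id: str
    element_imbalance: dict[str, float]
    charge_imbalance: float
    proton_fixable: bool
    auditable: bool = True

    @property
    def balanced(self) -> bool:
        return (
            self.auditable
            and not self.element_imbalance
            and self.charge_imbalance == 0
        )


@dataclass
class CurationConfig:
    """Parameters and reaction-tag map for :func:`apply_curation`.

    ``tags`` maps role names to reaction ids in the target model:
    ``ngam``, ``serine_entry`` (direct formaldehyde entries into the
    serine cycle), ``pqq_oxidation``, ``cytc_oxidation`` and
    ``biomass``. Roles absent from the map are skipped with a warning
    only when configured values depend on them.
    """

    ngam_flux: float = DEFAULT_NGAM
    o2_per_pqq: float = 1.0
    o2_per_cytc: float = 0.5
    allowed_c1_assimilation_routes: frozenset[str] = frozenset({"RuMP", "THF"})
    biomass_coefficients: dict[str, float] = field(default_factory=dict)
    tags: dict[str, list[str]] = field(default_factory=dict)
    auto_fix_protons: bool = False
    proton_metabolite_id: str | None = None

    def __post_init__(self) -> None:
        if self.ngam_flux < 0:
            raise ValueError("ngam_flux must be >= 0")
        if self.o2_per_pqq <= 0 or self.o2_per_cytc <= 0:
            raise ValueError("oxygen ratios must be > 0")
        if any(v <= 0 for v in self.biomass_coefficients.values()):
            raise ValueError("biomass coefficients must be > 0")


def _imbalance(rxn: cobra.Reaction) -> tuple[dict[str, float], float, bool]:
    """Net (products - reactants) element and charge imbalance."""
    elements: dict[str, float] = {}
    charge = 0.0
    auditable = True
    for met, coef in rxn.metabolites.items():
        if not met.formula:
            auditable = False
            continue
        for element, count in met.elements.items():
            elements[element] = elements.get(element, 0.0) + coef * count
        charge += coef * (met.charge or 0)
    elements = {e: c for e, c in elements.items() if abs(c) > 1e-9}
    return elements, charge, auditable


def audit_balance(model: cobra.Model) -> list[BalanceReport]:
    """Audit every non-exchange reaction for element/charge balance.

    Exchange (boundary) reactions are exempt — they are unbalanced by
    design. A reaction touching a formula-less metabolite is reported
    with ``auditable=False``.
    """
    boundary = {r.id for r in model.boundary}
    reports = []
    for rxn in model.reactions:
        if rxn.id in boundary:
            continue
        elements, charge, auditable = _imbalance(rxn)
        if not auditable:
            reports.append(BalanceReport(rxn.id, {}, 0.0, False, auditable=False))
            continue
        h = elements.get("H", 0.0)
        proton_fixable = (
            h != 0
            and abs(h - charge) < 1e-9
            and all(e == "H" for e in elements)
        )
        reports.append(
            BalanceReport(rxn.id, elements, charge, proton_fixable)
        )
    return reports


def _find_oxygen(rxn: cobra.Reaction) -> cobra.Metabolite | None:
    for met in rxn.metabolites:
        if met.elements == {"O": 2}:
            return met
    return None


def _set_coefficient(rxn: cobra.Reaction, met: cobra.Metabolite, coef: float) -> None:
    current = rxn.metabolites.get(met, 0.0)
    rxn.add_metabolites({met: coef - current})


def apply_curation(model: cobra.Model, config: CurationConfig) -> cobra.Model:
    """Return a curated copy of ``model``.

    Applies, in order: the NGAM equality bound, the serine-cycle
    formaldehyde-entry shutoff, the oxygen stoichiometry rewrites, the
    biomass coefficient replacement, and (optionally) automatic proton
    repair of proton-fixable reactions. Idempotent: applying the same
    config twice equals applying it once. Tags matching no reaction
    raise a :class:`CurationWarning` naming the tag.
    """
    curated = model.copy()
    tags = config.tags

    def _resolve(tag: str) -> list[cobra.Reaction]:
        rxns = []
        for rid in tags.get(tag, []):
            if curated.reactions.has_id(rid):
                rxns.append(curated.reactions.get_by_id(rid))
            else:
                warnings.warn(
                    f"curation tag {tag!r}: no reaction {rid!r} in model "
                    f"{curated.id}", CurationWarning, stacklevel=3,
                )
        if tag in tags and tags[tag] and not rxns:
            warnings.warn(
                f"curation tag {tag!r} matched zero reactions",
                CurationWarning, stacklevel=3,
            )
        return rxns

    for rxn in _resolve("ngam"):
        rxn.bounds = (config.ngam_flux, config.ngam_flux)

    if "serine" not in {r.lower() for r in config.allowed_c1_assimilation_routes}:
        for rxn in _resolve("serine_entry"):
            rxn.bounds = (0.0, 0.0)

    for tag, ratio in (("pqq_oxidation", config.o2_per_pqq),
                       ("cytc_oxidation", config.o2_per_cytc)):
        for rxn in _resolve(tag):
            o2 = _find_oxygen(rxn)
            if o2 is None:
                warnings.warn(
                    f"curation tag {tag!r}: reaction {rxn.id} has no O2 "
                    "metabolite; skipped", CurationWarning, stacklevel=2,
                )
                continue
            _set_coefficient(rxn, o2, -abs(ratio))

    if config.biomass_coefficients:
        for rxn in _resolve("biomass"):
            rxn.subtract_metabolites(dict(rxn.metabolites))
            rxn.add_metabolites({
                curated.metabolites.get_by_id(mid): -coef
                for mid, coef in config.biomass_coefficients.items()
            })

    if config.auto_fix_protons:
        _repair_protons(curated, config.proton_metabolite_id)

    return curated


def _repair_protons(model: cobra.Model, proton_id: str | None) -> None:
    if proton_id is None:
        candidates = [m for m in model.metabolites
                      if m.elements == PROTON_FORMULA and (m.charge or 0) == 1]
        if not candidates:
            warnings.warn("no proton metabolite found; proton repair skipped",
                          CurationWarning, stacklevel=3)
            return
        proton = candidates[0]
    else:
        proton = model.metabolites.get_by_id(proton_id)
    for report in audit_balance(model):
        if report.proton_fixable:
            rxn = model.reactions.get_by_id(report.reaction_id)
            rxn.add_metabolites({proton: -report.element_imbalance["H"]})


def load_biomass_table(path: str | Path) -> dict[str, float]:
    """Read a two-column biomass composition table.

    Expects tab- or comma-separated rows ``metabolite_id<sep>mmol/gDCW``;
    a header row is skipped if its second field is not numeric.
    """
    path = Path(path)
    coefficients: dict[str, float] = {}
    with path.open() as handle:
        dialect = "excel-tab" if "\t" in handle.readline() else "excel"
        handle.seek(0)
        for row in csv.reader(handle, dialect=dialect):
            if len(row) < 2 or not row[0].strip():
                continue
            try:
                value = float(row[1])
            except ValueError:
                continue  # header
            coefficients[row[0].strip()] = value
    return coefficients


def config_from_file(path: str | Path) -> CurationConfig:
    """Load a :class:`CurationConfig` from YAML or JSON."""
    path = Path(path)
    text = path.read_text()
    if path.suffix in (".yaml", ".yml"):
        import yaml

        raw = yaml.safe_load(text)
    else:
        raw = json.loads(text)
    if "allowed_c1_assimilation_routes" in raw:
        raw["allowed_c1_assimilation_routes"] = frozenset(
            raw["allowed_c1_assimilation_routes"]
        )
    return CurationConfig(**raw)
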