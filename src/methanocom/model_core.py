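"""Model I/O and bookkeeping for genome-scale metabolic models.

The in-memory container is :class:`cobra.Model`; this module wraps the
SBML reader/writer so that models arrive with finite default bounds
(+/- 1000 mmol/gDCW/hr), an identified biomass reaction, and flagged
exchange reactions, and it computes the per-model statistics table
(genes, reactions, metabolites, blocked reactions).
"""

from __future__ import annotations

import json
import re
import warnings
from dataclasses import asdict, dataclass
from pathlib import Path

import cobra
from cobra.io import read_sbml_model, write_sbml_model

#: Conventional magnitude used when a model file leaves a flux unbounded.
DEFAULT_BOUND = 1000.0

_BIOMASS_RE = re.compile(r"biomass|growth|bio\d*$", re.IGNORECASE)


class BiomassNotFoundWarning(UserWarning):
    """Raised as a warning when no biomass reaction can be identified."""


@dataclass(frozen=True)
class ModelStats:
    """Headline counts for one member model.

    ``n_blocked`` counts reactions unable to carry flux in the reference
    medium (see :func:`methanocom.fluxcalc.find_blocked_reactions`).
    """

    n_genes: int
    n_reactions: int
    n_metabolites: int
    n_blocked: int

    def __post_init__(self) -> None:
        for field, value in asdict(self).items():
            if value < 0:
                raise ValueError(f"{field} must be >= 0, got {value}")
        if self.n_blocked > self.n_reactions:
            raise ValueError("n_blocked cannot exceed n_reactions")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)


def find_biomass_reaction(model: cobra.Model) -> cobra.Reaction | None:
    """Return the model's biomass reaction, or None.

    Preference order: the reaction(s) carrying the current objective, then
    any reaction whose id or name matches a biomass/growth pattern.
    """
    from cobra.util.solver import linear_reaction_coefficients

    objective = linear_reaction_coefficients(model)
    for rxn in objective:
        return rxn
    for rxn in model.reactions:
        if _BIOMASS_RE.search(rxn.id) or _BIOMASS_RE.search(rxn.name or ""):
            return rxn
    return None


def _clamp_bounds(model: cobra.Model, magnitude: float = DEFAULT_BOUND) -> None:
    for rxn in model.reactions:
        lb, ub = rxn.bounds
        if lb < -magnitude or lb != lb:  # -inf or NaN
            lb = -magnitude
        if ub > magnitude or ub != ub:
            ub = magnitude
        rxn.bounds = (lb, ub)


def load_sbml(path: str | Path) -> cobra.Model:
    """Read an SBML Level 2 or Level 3 model file.

    Bounds absent from the file (or infinite) are clamped to
    +/- :data:`DEFAULT_BOUND`. Exchange reactions are the boundary
    reactions reported by ``model.boundary`` (single-metabolite
    stoichiometry across the system boundary). A missing biomass
    reaction produces a :class:`BiomassNotFoundWarning`, and the
    objective is left as the file declares it.

    Raises
    ------
    IOError
        If ``path`` does not exist.
    cobra.io.sbml.CobraSBMLError
        On malformed XML; the message carries libSBML's line-numbered
        diagnostics.
    """
    path = Path(path)
    if not path.exists():
        raise IOError(f"SBML file not found: {path}")
    model = read_sbml_model(str(path))
    _clamp_bounds(model)
    if find_biomass_reaction(model) is None:
        warnings.warn(
            f"no biomass reaction identified in {path.name}; "
            "objective left unset",
            BiomassNotFoundWarning,
            stacklevel=2,
        )
    return model


def write_sbml(model: cobra.Model, path: str | Path) -> Path:
    """Write ``model`` as SBML Level 3 (fbc); round-trips stoichiometry,
    bounds and identifiers through :func:`load_sbml`."""
    path = Path(path)
    write_sbml_model(model, str(path))
    return path


def model_stats(model: cobra.Model, blocked: set[str] | None = None) -> ModelStats:
    """Compute the statistics row for one model.

    ``blocked`` is the set of blocked reaction ids (computed separately,
    e.g. by :func:`methanocom.fluxcalc.find_blocked_reactions`); it must
    be a subset of the model's reaction ids. Genes are counted as
    distinct gene identifiers across all gene-reaction rules.
    """
    blocked = set(blocked or ())
    known = {r.id for r in model.reactions}
    unknown = blocked - known
    if unknown:
        raise ValueError(
            f"blocked ids not in model: {sorted(unknown)[:5]}"
        )
    return ModelStats(
        n_genes=len(model.genes),
        n_reactions=len(model.reactions),
        n_metabolites=len(model.metabolites),
        n_blocked=len(blocked),
    )
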