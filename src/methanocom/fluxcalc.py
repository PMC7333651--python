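"""Flux balance analysis, flux variability analysis, and network diagnostics.

FBA maximizes an objective flux subject to steady-state mass balance
``S v = 0`` and bounds ``LB <= v <= UB``. FVA minimizes and maximizes
each reaction flux under the same constraints with the objective flux
pinned at a threshold. Two diagnostics build on FVA:

* blocked reactions — reactions whose flux range is [0, 0] with every
  exchange reaction opened to the default bounds;
* thermodynamically infeasible cycles — internal loops that can carry
  circulation with *all* exchange reactions closed; such flux has no net
  metabolite turnover and hence no thermodynamic driving force. They
  are located by closing every exchange, running FVA at objective
  threshold zero, collecting reactions whose flux reaches the default
  bounds, and grouping those into connected components of the
  reaction-metabolite bipartite graph.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import cobra
import networkx as nx
from cobra.exceptions import OptimizationError

from methanocom.model_core import DEFAULT_BOUND

#: LP feasibility tolerance requested from the solver.
FEASIBILITY_TOL = 1e-9
#: Fluxes with magnitude below this are treated as zero.
ZERO_TOL = 1e-6
#: A flux counts as "at the default bound" above this fraction of it.
BOUND_HIT_FRACTION = 0.999


@dataclass
class FluxState:
    """One solution of the FBA problem.

    ``fluxes`` maps reaction id to flux (mmol/gDCW/hr). When ``status``
    is not ``"optimal"`` the flux map is empty and ``objective_value``
    is NaN.
    """

    fluxes: dict[str, float]
    objective_value: float
    status: str  # optimal | infeasible | unbounded

    def residuals(self, model: cobra.Model) -> dict[str, float]:
        """Mass-balance residual per metabolite, Σ_j S_ij v_j."""
        res: dict[str, float] = {m.id: 0.0 for m in model.metabolites}
        for rxn in model.reactions:
            v = self.fluxes.get(rxn.id, 0.0)
            for met, coef in rxn.metabolites.items():
                res[met.id] += coef * v
        return res


@dataclass
class FvaSpec:
    """FVA configuration.

    ``objective_threshold`` pins the objective flux: as an equality when
    ``fix_mode="equality"`` (the threshold is a flux value), or as a
    lower bound at a fraction of the optimum when
    ``fix_mode="fraction-of-optimum"`` (the threshold is a fraction in
    [0, 1]). ``reactions`` restricts which ranges are computed.
    """

    objective_threshold: float = 0.0
    fix_mode: str = "equality"  # equality | fraction-of-optimum
    reactions: list[str] | None = None

    def __post_init__(self) -> None:
        if self.objective_threshold < 0:
            raise ValueError("objective_threshold must be >= 0")
        if self.fix_mode not in ("equality", "fraction-of-optimum"):
            raise ValueError(f"unknown fix_mode {self.fix_mode!r}")


@dataclass(frozen=True)
class FvaRange:
    reaction_id: str
    min_flux: float
    max_flux: float

    def __post_init__(self) -> None:
        if self.min_flux > self.max_flux + ZERO_TOL:
            raise ValueError(
                f"{self.reaction_id}: min {self.min_flux} > max {self.max_flux}"
            )


@dataclass(frozen=True)
class CycleGroup:
    """A group of reactions forming (part of) an infeasible cycle."""

    reaction_ids: frozenset[str]
    signature: str

    def __len__(self) -> int:
        return len(self.reaction_ids)


def _status(sol_status: str) -> str:
    if sol_status == "optimal":
        return "optimal"
    if "unbounded" in (sol_status or ""):
        return "unbounded"
    return "infeasible"


def solve_fba(
    model: cobra.Model,
    objective_id: str | None = None,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    maximize: bool = True,
) -> FluxState:
    """Solve the FBA linear program.

    ``objective_id`` defaults to the model's current objective.
    ``extra_bounds`` temporarily overrides reaction bounds (useful for
    nutrient caps). Returns a :class:`FluxState` whose status is
    ``infeasible``/``unbounded`` (with empty fluxes) when the LP is.
    """
    with model:
        model.tolerance = FEASIBILITY_TOL
        if objective_id is not None:
            model.objective = model.reactions.get_by_id(objective_id)
        model.objective_direction = "max" if maximize else "min"
        for rid, bounds in (extra_bounds or {}).items():
            model.reactions.get_by_id(rid).bounds = bounds
        try:
            sol = model.optimize()
            status = _status(sol.status)
        except OptimizationError as exc:  # e.g. unbounded objective
            status = _status(str(exc))
        if status != "optimal":
            return FluxState({}, float("nan"), status)
        return FluxState(dict(sol.fluxes), float(sol.objective_value), "optimal")


def run_fva(model: cobra.Model, spec: FvaSpec | None = None) -> list[FvaRange]:
    """Min/max flux envelope per reaction at a pinned objective.

    Solves two LPs per requested reaction. Raises ``ValueError`` naming
    the threshold if the pinned problem is infeasible.
    """
    spec = spec or FvaSpec()
    rids = spec.reactions or [r.id for r in model.reactions]
    with model:
        model.tolerance = FEASIBILITY_TOL
        obj_rxns = list(cobra.util.solver.linear_reaction_coefficients(model))
        if obj_rxns:
            obj = obj_rxns[0]
            if spec.fix_mode == "equality":
                obj.bounds = (spec.objective_threshold, spec.objective_threshold)
            else:
                opt = model.slim_optimize(error_value=None)
                obj.lower_bound = spec.objective_threshold * opt
        # feasibility probe before the per-reaction loop
        model.objective = model.problem.Objective(0)
        if _status(model.optimize().status) != "optimal":
            raise ValueError(
                "FVA infeasible at objective threshold "
                f"{spec.objective_threshold}"
            )
        ranges = []
        for rid in rids:
            rxn = model.reactions.get_by_id(rid)
            model.objective = rxn
            model.objective_direction = "min"
            lo = model.slim_optimize()
            model.objective_direction = "max"
            hi = model.slim_optimize()
            # guard against solver round-off inverting a degenerate range
            if lo > hi:
                lo, hi = hi, lo
            ranges.append(FvaRange(rid, float(lo), float(hi)))
        return ranges


def find_blocked_reactions(model: cobra.Model) -> set[str]:
    """Reactions unable to carry flux with all exchanges open.

    The medium is the most permissive one: every exchange reaction is
    opened to [-DEFAULT_BOUND, DEFAULT_BOUND] before the variability
    scan. A reaction is blocked when its flux range is [0, 0] within
    :data:`ZERO_TOL`.
    """
    with model:
        for rxn in model.boundary:
            rxn.bounds = (-DEFAULT_BOUND, DEFAULT_BOUND)
        model.objective = model.problem.Objective(0)  # no biomass forcing
        ranges = run_fva(model, FvaSpec(objective_threshold=0.0))
    return {
        r.reaction_id
        for r in ranges
        if abs(r.min_flux) < ZERO_TOL and abs(r.max_flux) < ZERO_TOL
    }


def detect_infeasible_cycles(model: cobra.Model) -> list[CycleGroup]:
    """Locate thermodynamically infeasible cycles.

    All exchange reactions are closed (bounds [0, 0]); FVA is run at
    objective threshold zero; reactions whose flux attains
    +/- ``BOUND_HIT_FRACTION * DEFAULT_BOUND`` are collected and grouped
    into connected components via shared metabolites.
    """
    with model:
        for rxn in model.boundary:
            rxn.bounds = (0.0, 0.0)
        model.objective = model.problem.Objective(0)
        ranges = run_fva(model, FvaSpec(objective_threshold=0.0))
    limit = BOUND_HIT_FRACTION * DEFAULT_BOUND
    unbounded = [
        r.reaction_id
        for r in ranges
        if r.max_flux >= limit or r.min_flux <= -limit
    ]
    if not unbounded:
        return []
    graph = nx.Graph()
    for rid in unbounded:
        rxn = model.reactions.get_by_id(rid)
        graph.add_node(("r", rid))
        for met in rxn.metabolites:
            graph.add_edge(("r", rid), ("m", met.id))
    groups = []
    for component in nx.connected_components(graph):
        rids = frozenset(rid for kind, rid in component if kind == "r")
        sig = "; ".join(
            f"{rid}: {model.reactions.get_by_id(rid).build_reaction_string()}"
            for rid in sorted(rids)
        )
        groups.append(CycleGroup(rids, sig))
    return sorted(groups, key=lambda g: sorted(g.reaction_ids))


def fva_to_tsv(ranges: list[FvaRange]) -> str:
    """Flux-envelope report (reaction_id, min, max, blocked flag)."""
    lines = ["reaction_id\tmin_flux\tmax_flux\tblocked"]
    for r in sorted(ranges, key=lambda x: x.reaction_id):
        blocked = abs(r.min_flux) < ZERO_TOL and abs(r.max_flux) < ZERO_TOL
        lines.append(f"{r.reaction_id}\t{r.min_flux:.9g}\t{r.max_flux:.9g}\t{int(blocked)}")
    return "\n".join(lines) + "\n"
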