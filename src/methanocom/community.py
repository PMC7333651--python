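"""Two-level community model with a shared extracellular metabolite pool.

Each member k keeps its own steady-state FBA problem (mass balance and
bounds over its namespaced reactions). For every shared metabolite i the
member's exchange reaction is split into a non-negative uptake link
r_uptake(k,i) (pool -> member) and export link r_export(k,i)
(member -> pool). The pool itself is balanced by community supply
u_c(i) >= 0 and community export e_c(i) >= 0:

    sum_k r_uptake(k,i) + e_c(i) = sum_k r_export(k,i) + u_c(i)

which is enforced as the steady-state constraint of a pool
pseudo-metabolite. The community objective is the weighted sum of the
member biomass fluxes.

Because the outer objective is exactly the (weighted) sum of the inner
objectives, the two-level program is solved as the single joint LP
followed by a polish step that, with member biomasses pinned at their
solved values, minimizes total uptake-link flux — removing slack
substrate allocations that would make a member's allocation look
wasteful — and a certification step (:func:`verify_inner_optimality`)
that re-maximizes each member's biomass at the solved link values and
checks no member could have grown more. The certificate is what makes
the two-level contract checkable regardless of the solution route.

Formaldehyde inhibition: extracellular formaldehyde inhibits growth of
the consuming member. With v_max the member's uninhibited biomass
optimum in the same environment and R the inhibition slope,

    v_biomass <= v_max * (1 - R * v_formaldehyde_uptake)

is added as a linear constraint; growth hits zero when
R * uptake = 1. R derives from the inhibitory concentration window
(growth inhibition sets in at 1 mM and is total at 7 mM): R = 1/c_max
in the zero-offset reading of the inequality, or R = 1/(c_max - c_min)
with the constraint shifted by the onset in the onset-offset reading.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import cobra

from methanocom.fluxcalc import FEASIBILITY_TOL, FluxState, _status
from methanocom.model_core import DEFAULT_BOUND, find_biomass_reaction

INNER_TOL = 1e-6
POOL_TOL = 1e-6

#: Formulas used to recognize the capped nutrients among shared metabolites.
_NUTRIENT_FORMULAS = {"methane": "CH4", "oxygen": "O2", "nitrogen": "N2"}
_HCHO_FORMULA = "CH2O"


@dataclass(frozen=True)
class NutrientCondition:
    """Community-level supply caps (mmol/gDCW/hr) on u_c."""

    name: str
    methane_cap: float
    oxygen_cap: float
    nitrogen_cap: float

    def __post_init__(self) -> None:
        if min(self.methane_cap, self.oxygen_cap, self.nitrogen_cap) < 0:
            raise ValueError("caps must be >= 0")


@dataclass
class InhibitionParams:
    """Formaldehyde growth-inhibition parameters.

    ``c_min``/``c_max`` are the inhibition onset and total-inhibition
    concentrations (mM); the uptake flux (mmol/gDCW/hr) stands in
    numerically for concentration in the inequality. ``R`` defaults to
    the value derived from ``mode``; ``v_maxbiomass`` is normally
    recomputed per environment ("auto") as the member's optimum with
    formaldehyde uptake shut off.
    """

    c_min: float = 1.0
    c_max: float = 7.0
    mode: str = "zero-offset"  # zero-offset | onset-offset
    R: float | None = None
    v_maxbiomass: float | str | None = "auto"

    def __post_init__(self) -> None:
        if not 0 < self.c_min < self.c_max:
            raise ValueError("need 0 < c_min < c_max")
        if self.mode not in ("zero-offset", "onset-offset"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.R is None:
            self.R = compute_inhibition_R(self.c_min, self.c_max, self.mode)
        if self.R <= 0:
            raise ValueError("R must be > 0")


@dataclass
class CommunitySolution:
    """Solved community state.

    ``link_values`` holds the realized non-negative link variables:
    ``uptake``/``export`` keyed by (member, shared id), ``supply`` and
    ``pool_export`` keyed by shared id. ``inner_optimality_certified``
    marks, per member, whether re-maximizing that member's biomass at
    the fixed link values could not improve on the reported biomass.
    """

    status: str
    member_biomass: dict[str, float] = field(default_factory=dict)
    member_flux_states: dict[str, FluxState] = field(default_factory=dict)
    link_values: dict[str, dict] = field(default_factory=dict)
    total_biomass: float = float("nan")
    inner_optimality_certified: dict[str, bool] = field(default_factory=dict)
    joint_fluxes: dict[str, float] = field(default_factory=dict)
    inhibition_vmax: dict[str, float] = field(default_factory=dict)


@dataclass
class CommunityModel:
    """Joint LP plus the bookkeeping to address members and links."""

    model: cobra.Model
    members: dict[str, cobra.Model]
    shared_ids: list[str]
    weights: dict[str, float]
    biomass_ids: dict[str, str]  # member -> prefixed biomass reaction id
    member_exchange_ids: dict[tuple[str, str], str]  # (member, shared) -> original id
    nutrient_ids: dict[str, str]  # methane/oxygen/nitrogen -> shared id
    hcho_id: str | None

    def uptake_link(self, member: str, shared_id: str) -> str:
        return f"r_up__{member}__{shared_id}"

    def export_link(self, member: str, shared_id: str) -> str:
        return f"r_ex__{member}__{shared_id}"

    def supply_id(self, shared_id: str) -> str:
        return f"U__{shared_id}"

    def pool_export_id(self, shared_id: str) -> str:
        return f"E__{shared_id}"

    # registered inhibition constraints, materialized per solve
    inhibitions: dict[str, InhibitionParams] = field(default_factory=dict)


def compute_inhibition_R(c_min: float, c_max: float, mode: str = "zero-offset") -> float:
    """Inhibition slope per unit formaldehyde uptake flux.

    zero-offset: solve 1 - R*c_max = 0, i.e. R = 1/c_max (growth is zero
    exactly at the total-inhibition concentration, measured from zero).
    onset-offset: R = 1/(c_max - c_min), used with the constraint
    shifted so inhibition starts at c_min.
    """
    if not 0 < c_min < c_max:
        raise ValueError(f"need 0 < c_min < c_max, got ({c_min}, {c_max})")
    if mode == "zero-offset":
        return 1.0 / c_max
    if mode == "onset-offset":
        return 1.0 / (c_max - c_min)
    raise ValueError(f"unknown mode {mode!r}")


def _prefixed_copy(member: cobra.Model, prefix: str) -> cobra.Model:
    clone = member.copy()
    for met in clone.metabolites:
        met.id = prefix + met.id
    for rxn in clone.reactions:
        rxn.id = prefix + rxn.id
    clone.repair()
    return clone


def build_community(
    members: list[cobra.Model],
    shared_ids: set[str],
    weights: dict[str, float] | None = None,
) -> CommunityModel:
    """Assemble the joint community LP.

    ``shared_ids`` are extracellular metabolite ids; each must have an
    exchange reaction in at least one member (error naming the id
    otherwise). Member namespaces are kept disjoint by prefixing with
    the member id. Link variables are created for every member/shared
    pair; where a member's exchange disallowed a direction, the
    corresponding link gets an upper bound of zero. Supply variables
    start closed (cap 0) and are opened by the nutrient condition at
    solve time.
    """
    member_ids = [m.id for m in members]
    if len(set(member_ids)) != len(member_ids):
        raise ValueError(f"member ids must be unique: {member_ids}")
    weights = dict(weights or {mid: 1.0 for mid in member_ids})
    for mid in member_ids:
        weights.setdefault(mid, 1.0)

    joint = cobra.Model("community")
    shared = sorted(shared_ids)
    pool_mets: dict[str, cobra.Metabolite] = {}
    seen: dict[str, int] = {sid: 0 for sid in shared}
    biomass_ids: dict[str, str] = {}
    member_exchange_ids: dict[tuple[str, str], str] = {}
    originals: dict[str, cobra.Model] = {}

    for member in members:
        mid = member.id
        originals[mid] = member
        biomass = find_biomass_reaction(member)
        if biomass is None:
            raise ValueError(f"member {mid} has no identifiable biomass reaction")
        prefix = f"{mid}__"
        clone = _prefixed_copy(member, prefix)
        biomass_ids[mid] = prefix + biomass.id

        links: list[cobra.Reaction] = []
        for sid in shared:
            pmet_id = prefix + sid
            if pmet_id not in clone.metabolites:
                continue
            met = clone.metabolites.get_by_id(pmet_id)
            exchanges = [
                r for r in clone.reactions
                if len(r.metabolites) == 1 and met in r.metabolites
            ]
            if not exchanges:
                continue
            if len(exchanges) > 1:
                warnings.warn(
                    f"member {mid}: multiple exchanges for {sid}; using "
                    f"{exchanges[0].id}", UserWarning, stacklevel=2,
                )
            exch = exchanges[0]
            member_exchange_ids[(mid, sid)] = exch.id[len(prefix):]
            lb, ub = exch.bounds
            clone.remove_reactions([exch])
            seen[sid] += 1
            if sid not in pool_mets:
                pool_mets[sid] = cobra.Metabolite(
                    f"{sid}_pool",
                    formula=met.formula,
                    compartment="pool",
                    charge=met.charge,
                )
            up = cobra.Reaction(
                f"r_up__{mid}__{sid}", lower_bound=0.0,
                upper_bound=max(0.0, -lb),
            )
            up.add_metabolites({pool_mets[sid]: -1, met: 1})
            ex = cobra.Reaction(
                f"r_ex__{mid}__{sid}", lower_bound=0.0,
                upper_bound=max(0.0, ub),
            )
            ex.add_metabolites({met: -1, pool_mets[sid]: 1})
            links.extend([up, ex])
        joint.add_reactions(list(clone.reactions))
        joint.add_reactions(links)

    missing = [sid for sid in shared if seen[sid] == 0]
    if missing:
        raise ValueError(
            f"shared metabolites with no exchange in any member: {missing}"
        )

    pool_cap = DEFAULT_BOUND * max(1, len(members))
    for sid in shared:
        if sid not in pool_mets:
            continue
        supply = cobra.Reaction(f"U__{sid}", lower_bound=0.0, upper_bound=0.0)
        supply.add_metabolites({pool_mets[sid]: 1})
        export = cobra.Reaction(f"E__{sid}", lower_bound=0.0, upper_bound=pool_cap)
        export.add_metabolites({pool_mets[sid]: -1})
        joint.add_reactions([supply, export])

    joint.objective = {
        joint.reactions.get_by_id(biomass_ids[mid]): weights[mid]
        for mid in member_ids
    }

    nutrient_ids: dict[str, str] = {}
    hcho_id = None
    for sid, met in pool_mets.items():
        for nutrient, formula in _NUTRIENT_FORMULAS.items():
            if (met.formula or "") == formula:
                nutrient_ids[nutrient] = sid
        if (met.formula or "") == _HCHO_FORMULA:
            hcho_id = sid

    return CommunityModel(
        model=joint,
        members=originals,
        shared_ids=shared,
        weights=weights,
        biomass_ids=biomass_ids,
        member_exchange_ids=member_exchange_ids,
        nutrient_ids=nutrient_ids,
        hcho_id=hcho_id,
    )


def apply_formaldehyde_inhibition(
    community: CommunityModel,
    member: str,
    params: InhibitionParams,
    v_maxbiomass: float | str | None = None,
) -> CommunityModel:
    """Register (or add) the formaldehyde inhibition constraint.

    With ``v_maxbiomass="auto"`` (the default carried by ``params``) the
    constraint is materialized inside every solve, using the member's
    uninhibited optimum in that environment. A numeric value adds a
    static constraint immediately. ``None`` in both places raises,
    instructing to compute the uninhibited optimum first.
    """
    if member not in community.members:
        raise KeyError(f"unknown member {member!r}")
    if community.hcho_id is None or (
        member, community.hcho_id
    ) not in community.member_exchange_ids:
        raise ValueError(f"member {member!r} has no formaldehyde uptake link")
    up = community.model.reactions.get_by_id(
        community.uptake_link(member, community.hcho_id)
    )
    if up.upper_bound <= 0:
        raise ValueError(
            f"member {member!r} has no formaldehyde uptake capacity "
            "(uptake link bound is zero)"
        )
    if v_maxbiomass is not None:
        params.v_maxbiomass = v_maxbiomass
    if params.v_maxbiomass is None:
        raise ValueError(
            "v_maxbiomass is unset: run the uninhibited community solve "
            'first, or pass v_maxbiomass="auto" to recompute it per solve'
        )
    if params.v_maxbiomass == "auto":
        community.inhibitions[member] = params
        return community
    _add_inhibition_constraints(
        community, member, params, float(params.v_maxbiomass)
    )
    return community


def _add_inhibition_constraints(
    community: CommunityModel,
    member: str,
    params: InhibitionParams,
    v_max: float,
) -> list:
    m = community.model
    bio = m.reactions.get_by_id(community.biomass_ids[member])
    up = m.reactions.get_by_id(community.uptake_link(member, community.hcho_id))
    added = []
    if params.mode == "zero-offset":
        # bio + vmax*R*up <= vmax
        cons = m.problem.Constraint(
            bio.flux_expression + v_max * params.R * up.flux_expression,
            ub=v_max, name=f"hcho_inhibition__{member}",
        )
        added.append(cons)
    else:
        # bio <= vmax for up <= c_min; shifted slope above the onset
        cons_cap = m.problem.Constraint(
            bio.flux_expression, ub=v_max,
            name=f"hcho_inhibition_cap__{member}",
        )
        cons = m.problem.Constraint(
            bio.flux_expression + v_max * params.R * up.flux_expression,
            ub=v_max * (1.0 + params.R * params.c_min),
            name=f"hcho_inhibition__{member}",
        )
        added.extend([cons_cap, cons])
    m.add_cons_vars(added)
    return added


def _apply_condition(community: CommunityModel, condition: NutrientCondition) -> None:
    caps = {
        "methane": condition.methane_cap,
        "oxygen": condition.oxygen_cap,
        "nitrogen": condition.nitrogen_cap,
    }
    for nutrient, cap in caps.items():
        sid = community.nutrient_ids.get(nutrient)
        if sid is None:
            raise ValueError(
                f"community has no shared metabolite for {nutrient}"
            )
        supply = community.model.reactions.get_by_id(community.supply_id(sid))
        supply.bounds = (0.0, cap)


def _extract_solution(
    community: CommunityModel, fluxes: dict[str, float]
) -> CommunitySolution:
    member_biomass = {}
    member_flux_states = {}
    for mid in community.members:
        prefix = f"{mid}__"
        mem_fluxes = {
            rid[len(prefix):]: v for rid, v in fluxes.items()
            if rid.startswith(prefix)
        }
        bio = fluxes[community.biomass_ids[mid]]
        member_biomass[mid] = bio
        member_flux_states[mid] = FluxState(mem_fluxes, bio, "optimal")
    link_values = {"uptake": {}, "export": {}, "supply": {}, "pool_export": {}}
    for mid in community.members:
        for sid in community.shared_ids:
            up = community.uptake_link(mid, sid)
            ex = community.export_link(mid, sid)
            if up in fluxes:
                link_values["uptake"][(mid, sid)] = fluxes[up]
                link_values["export"][(mid, sid)] = fluxes[ex]
    for sid in community.shared_ids:
        uid = community.supply_id(sid)
        if uid in fluxes:
            link_values["supply"][sid] = fluxes[uid]
            link_values["pool_export"][sid] = fluxes[community.pool_export_id(sid)]
    total = sum(
        community.weights[mid] * member_biomass[mid] for mid in community.members
    )
    return CommunitySolution(
        status="optimal",
        member_biomass=member_biomass,
        member_flux_states=member_flux_states,
        link_values=link_values,
        total_biomass=total,
        joint_fluxes=dict(fluxes),
    )


def solve_optcom(
    community: CommunityModel,
    condition: NutrientCondition,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
    polish: bool = True,
    certify: bool = True,
    tol: float = INNER_TOL,
    _ratio_constraint: tuple[str, str, float] | None = None,
) -> CommunitySolution:
    """Solve the community problem under a nutrient condition.

    Steps: apply the supply caps (and ``extra_bounds``), materialize any
    registered formaldehyde-inhibition constraints (computing each
    member's uninhibited optimum in this environment first), maximize
    weighted community biomass, then polish (minimize total uptake-link
    flux at pinned member biomasses) and certify inner optimality. A
    member failing certification is flagged in the returned solution,
    never silently accepted.

    ``_ratio_constraint`` is the fixed-abundance hook used by
    :func:`solve_fixed_ratio`; it is imposed *after* the uninhibited
    optima are computed, so v_max reflects the environment, not the
    imposed composition.
    """
    m = community.model
    with m:
        m.tolerance = FEASIBILITY_TOL
        _apply_condition(community, condition)
        for rid, bounds in (extra_bounds or {}).items():
            m.reactions.get_by_id(rid).bounds = bounds

        vmax_used: dict[str, float] = {}
        for member, params in community.inhibitions.items():
            up_id = community.uptake_link(member, community.hcho_id)
            with m:
                m.reactions.get_by_id(up_id).bounds = (0.0, 0.0)
                sol0 = m.optimize()
                if _status(sol0.status) != "optimal":
                    return CommunitySolution(status=_status(sol0.status))
                v_max = float(sol0.fluxes[community.biomass_ids[member]])
            vmax_used[member] = v_max
            _add_inhibition_constraints(community, member, params, v_max)

        if _ratio_constraint is not None:
            member_a, member_b, ratio = _ratio_constraint
            bio_a = m.reactions.get_by_id(community.biomass_ids[member_a])
            bio_b = m.reactions.get_by_id(community.biomass_ids[member_b])
            m.add_cons_vars([
                m.problem.Constraint(
                    bio_a.flux_expression - ratio * bio_b.flux_expression,
                    lb=0.0, ub=0.0, name="fixed_abundance_ratio",
                )
            ])

        sol = m.optimize()
        status = _status(sol.status)
        if status != "optimal":
            return CommunitySolution(status=status)
        fluxes = dict(sol.fluxes)

        if polish:
            with m:
                uptake_sum = 0
                for mid in community.members:
                    bio = m.reactions.get_by_id(community.biomass_ids[mid])
                    bio.lower_bound = max(
                        bio.lower_bound, fluxes[bio.id] - 1e-9
                    )
                    for sid in community.shared_ids:
                        up_id = community.uptake_link(mid, sid)
                        if m.reactions.has_id(up_id):
                            up = m.reactions.get_by_id(up_id)
                            uptake_sum = uptake_sum + up.flux_expression
                m.objective = m.problem.Objective(uptake_sum, direction="min")
                polished = m.optimize()
                if _status(polished.status) == "optimal":
                    new_fluxes = dict(polished.fluxes)
                    for mid in community.members:
                        new_fluxes[community.biomass_ids[mid]] = fluxes[
                            community.biomass_ids[mid]
                        ]
                    fluxes = new_fluxes

    solution = _extract_solution(community, fluxes)
    solution.inhibition_vmax = vmax_used
    if certify:
        solution.inner_optimality_certified = verify_inner_optimality(
            community, solution, tol=tol
        )
    return solution


def verify_inner_optimality(
    community: CommunityModel,
    solution: CommunitySolution,
    tol: float = INNER_TOL,
) -> dict[str, bool]:
    """Certify the two-level contract member by member.

    For each member, the shared-metabolite exchange fluxes are fixed at
    the solution's net link values (export - uptake, the SBML sign
    convention) in the member's standalone model, its biomass is
    re-maximized, and the certificate is true iff the re-solved optimum
    does not exceed the reported biomass by more than ``tol``. Any
    member-specific inhibition constraint is honored with the
    formaldehyde uptake fixed, so it reduces to a biomass cap.
    """
    out: dict[str, bool] = {}
    for mid, member in community.members.items():
        with member:
            member.tolerance = FEASIBILITY_TOL
            for sid in community.shared_ids:
                key = (mid, sid)
                if key not in community.member_exchange_ids:
                    continue
                up = solution.link_values["uptake"].get(key, 0.0)
                ex = solution.link_values["export"].get(key, 0.0)
                net = ex - up
                exch = member.reactions.get_by_id(
                    community.member_exchange_ids[key]
                )
                exch.bounds = (net - 1e-7, net + 1e-7)
            bio = find_biomass_reaction(member)
            member.objective = bio
            member.objective_direction = "max"
            inner_opt = member.slim_optimize(error_value=None)
        if inner_opt is None:
            out[mid] = False
            continue
        cap = _inhibited_cap(community, mid, solution)
        if cap is not None:
            inner_opt = min(inner_opt, cap)
        out[mid] = inner_opt <= solution.member_biomass[mid] + tol
    return out


def _inhibited_cap(
    community: CommunityModel, member: str, solution: CommunitySolution
) -> float | None:
    """Biomass cap implied by a registered inhibition at fixed uptake.

    With the formaldehyde uptake fixed at the link value, the
    inhibition inequality reduces to a plain biomass upper bound the
    inner problem must honor; it uses the environment-specific
    uninhibited optimum recorded in the solution.
    """
    params = community.inhibitions.get(member)
    if params is None or community.hcho_id is None:
        return None
    v_max = solution.inhibition_vmax.get(member)
    if v_max is None:
        return None
    uptake = solution.link_values["uptake"].get((member, community.hcho_id), 0.0)
    if params.mode == "zero-offset":
        return v_max * (1.0 - params.R * uptake)
    return min(
        v_max,
        v_max * (1.0 + params.R * params.c_min) - v_max * params.R * uptake,
    )


def pool_balance_residuals(
    community: CommunityModel, solution: CommunitySolution
) -> dict[str, float]:
    """Residual of the pool balance per shared metabolite (should be ~0)."""
    res = {}
    for sid in community.shared_ids:
        if sid not in solution.link_values["supply"]:
            continue
        up = sum(
            v for (mid, s), v in solution.link_values["uptake"].items() if s == sid
        )
        ex = sum(
            v for (mid, s), v in solution.link_values["export"].items() if s == sid
        )
        res[sid] = (
            up + solution.link_values["pool_export"][sid]
            - ex - solution.link_values["supply"][sid]
        )
    return res


def solve_fixed_ratio(
    community: CommunityModel,
    condition: NutrientCondition,
    ratio: float,
    member_a: str | None = None,
    member_b: str | None = None,
    **kwargs,
) -> CommunitySolution:
    """Solve with the abundance constraint bio_a = ratio * bio_b.

    ``ratio`` is the biomass ratio of ``member_a`` to ``member_b``
    (defaults: the first two members in insertion order). All other
    machinery (inhibition, polish, certification) is as in
    :func:`solve_optcom`.
    """
    if ratio <= 0:
        raise ValueError("ratio must be > 0")
    mids = list(community.members)
    member_a = member_a or mids[0]
    member_b = member_b or mids[1]
    return solve_optcom(
        community, condition,
        _ratio_constraint=(member_a, member_b, ratio), **kwargs,
    )


def biomass_split_envelope(
    community: CommunityModel,
    condition: NutrientCondition,
    total_biomass: float,
    extra_bounds: dict[str, tuple[float, float]] | None = None,
) -> dict[str, tuple[float, float]]:
    """Min/max of each member's biomass with the community total pinned.

    Quantifies the degeneracy of the member-level split: alternative
    optima can distribute the same community biomass differently, and
    comparisons of member fractions should be read against this
    envelope.
    """
    m = community.model
    out: dict[str, tuple[float, float]] = {}
    with m:
        m.tolerance = FEASIBILITY_TOL
        _apply_condition(community, condition)
        for rid, bounds in (extra_bounds or {}).items():
            m.reactions.get_by_id(rid).bounds = bounds
        total_expr = 0
        for mid in community.members:
            bio = m.reactions.get_by_id(community.biomass_ids[mid])
            total_expr = total_expr + community.weights[mid] * bio.flux_expression
        cons = m.problem.Constraint(
            total_expr, lb=total_biomass - 1e-7, ub=total_biomass + 1e-7,
            name="pinned_total_biomass",
        )
        m.add_cons_vars([cons])
        for mid in community.members:
            bio = m.reactions.get_by_id(community.biomass_ids[mid])
            m.objective = bio
            m.objective_direction = "min"
            lo = m.slim_optimize(error_value=float("nan"))
            m.objective_direction = "max"
            hi = m.slim_optimize(error_value=float("nan"))
            out[mid] = (float(lo), float(hi))
    return out
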