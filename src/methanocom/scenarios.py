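"""Simulation suite on top of the community model.

* the four nutrient-condition panels (nutrient-rich A, oxygen-limited
  B, nitrogen-limited C, methane-limited D) with per-member nutrient
  shares and exchange fluxes;
* a methane x oxygen supply gradient reporting community biomass and
  member composition per grid point (degenerate splits are read off the
  envelope midpoint of each member's biomass range at pinned total);
* fixed-abundance-ratio runs (sediment-incubated 9.3:1, synthetic
  co-culture 0.05:1) with a per-reaction flux-difference table and the
  inter-member formaldehyde transfer flux;
* pathway-level flux summaries from named reaction groups.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from methanocom.community import (
    CommunityModel,
    CommunitySolution,
    NutrientCondition,
    biomass_split_envelope,
    solve_fixed_ratio,
    solve_optcom,
)
from methanocom.fluxcalc import FluxState, ZERO_TOL

#: The four nutrient panels: caps on community supply (mmol/gDCW/hr).
TABLE2_CONDITIONS = (
    NutrientCondition("A", methane_cap=100, oxygen_cap=100, nitrogen_cap=100),
    NutrientCondition("B", methane_cap=100, oxygen_cap=50, nitrogen_cap=100),
    NutrientCondition("C", methane_cap=100, oxygen_cap=100, nitrogen_cap=40),
    NutrientCondition("D", methane_cap=20, oxygen_cap=100, nitrogen_cap=100),
)

#: Default fixed-abundance scenarios (biomass ratio of first to second member).
ABUNDANCE_RATIOS = {"sediment": 9.3, "synthetic": 0.05}


@dataclass(frozen=True)
class PathwayDefinition:
    """A named reaction group summarized by one reporter reaction."""

    name: str
    reaction_ids: tuple[str, ...]
    reporter_reaction: str

    def __post_init__(self) -> None:
        if self.reporter_reaction not in self.reaction_ids:
            raise ValueError(
                f"{self.name}: reporter {self.reporter_reaction!r} not in group"
            )


#: Pathway groups for the toy methanotrophs of :mod:`methanocom.synthetic`.
TOY_PATHWAYS = (
    PathwayDefinition("methane-oxidation", ("TCH4", "MMO", "MDH"), "MMO"),
    PathwayDefinition("assimilation", ("ASSIM",), "ASSIM"),
    PathwayDefinition("dissimilation", ("DISSIM",), "DISSIM"),
)


@dataclass
class ConditionResult:
    """Community solution plus the derived per-member summaries.

    ``nutrient_shares[member][nutrient]`` is the member's fraction of
    the community's *realized* uptake of that nutrient (NaN when the
    community consumed none); realized uptake can fall short of the cap
    when another nutrient limits. ``formaldehyde_exchange`` is
    export - uptake per member (positive = net secretion).
    """

    condition: NutrientCondition
    solution: CommunitySolution
    nutrient_shares: dict[str, dict[str, float]] = field(default_factory=dict)
    co2_export: dict[str, float] = field(default_factory=dict)
    formaldehyde_exchange: dict[str, float] = field(default_factory=dict)
    pathway_summaries: dict[str, dict] = field(default_factory=dict)


def _shares(community: CommunityModel, solution: CommunitySolution):
    shares: dict[str, dict[str, float]] = {mid: {} for mid in community.members}
    for nutrient, sid in community.nutrient_ids.items():
        total = sum(
            solution.link_values["uptake"].get((mid, sid), 0.0)
            for mid in community.members
        )
        for mid in community.members:
            up = solution.link_values["uptake"].get((mid, sid), 0.0)
            shares[mid][nutrient] = up / total if total > ZERO_TOL else float("nan")
    return shares


def summarize_condition(
    community: CommunityModel,
    condition: NutrientCondition,
    solution: CommunitySolution,
    pathways: tuple[PathwayDefinition, ...] | None = None,
) -> ConditionResult:
    """Derive shares, exchange fluxes and pathway summaries from a solution."""
    result = ConditionResult(condition=condition, solution=solution)
    if solution.status != "optimal":
        return result
    result.nutrient_shares = _shares(community, solution)
    co2_sid = next(
        (
            sid for sid in community.shared_ids
            if sid in {s for (_, s) in community.member_exchange_ids}
            and (community.model.metabolites.get_by_id(f"{sid}_pool").formula or "")
            == "CO2"
        ),
        None,
    )
    for mid in community.members:
        if co2_sid is not None:
            result.co2_export[mid] = solution.link_values["export"].get(
                (mid, co2_sid), 0.0
            )
        if community.hcho_id is not None:
            key = (mid, community.hcho_id)
            result.formaldehyde_exchange[mid] = solution.link_values[
                "export"
            ].get(key, 0.0) - solution.link_values["uptake"].get(key, 0.0)
        if pathways:
            result.pathway_summaries[mid] = pathway_summary(
                solution.member_flux_states[mid], list(pathways)
            )
    return result


def run_condition_suite(
    community: CommunityModel,
    conditions: tuple[NutrientCondition, ...] | None = None,
    pathways: tuple[PathwayDefinition, ...] | None = None,
    **solve_kwargs,
) -> list[ConditionResult]:
    """Solve each nutrient condition (defaults: panels A-D) and summarize."""
    conditions = conditions or TABLE2_CONDITIONS
    results = []
    for condition in conditions:
        solution = solve_optcom(community, condition, **solve_kwargs)
        results.append(
            summarize_condition(community, condition, solution, pathways)
        )
    return results


def run_gradient(
    community: CommunityModel,
    methane_levels: tuple[float, ...] = tuple(range(10, 101, 10)),
    oxygen_levels: tuple[float, ...] = tuple(range(10, 101, 10)),
    nitrogen_cap: float = 100.0,
    **solve_kwargs,
) -> pd.DataFrame:
    """Community biomass and composition over a methane x oxygen grid.

    Returns one row per grid point with the total biomass, each
    member's point-estimate fraction, and each member's fraction at the
    midpoint of its biomass envelope (the degeneracy-aware estimate
    used for composition statements).
    """
    if list(methane_levels) != sorted(methane_levels) or min(methane_levels) <= 0:
        raise ValueError("methane_levels must be positive and ascending")
    if list(oxygen_levels) != sorted(oxygen_levels) or min(oxygen_levels) <= 0:
        raise ValueError("oxygen_levels must be positive and ascending")
    rows = []
    for ch4 in methane_levels:
        for o2 in oxygen_levels:
            condition = NutrientCondition(f"ch4={ch4},o2={o2}", ch4, o2, nitrogen_cap)
            solution = solve_optcom(community, condition, **solve_kwargs)
            row: dict[str, float] = {
                "methane_cap": ch4,
                "oxygen_cap": o2,
                "total_biomass": solution.total_biomass,
            }
            if solution.status == "optimal" and solution.total_biomass > ZERO_TOL:
                envelope = biomass_split_envelope(
                    community, condition, solution.total_biomass
                )
                for mid in community.members:
                    row[f"fraction_{mid}"] = (
                        solution.member_biomass[mid] / solution.total_biomass
                    )
                    lo, hi = envelope[mid]
                    row[f"fraction_mid_{mid}"] = (
                        0.5 * (lo + hi) / solution.total_biomass
                    )
            else:
                for mid in community.members:
                    row[f"fraction_{mid}"] = float("nan")
                    row[f"fraction_mid_{mid}"] = float("nan")
                if solution.status != "optimal":
                    row["total_biomass"] = float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def run_abundance_scenarios(
    community: CommunityModel,
    condition: NutrientCondition,
    ratios: dict[str, float] | None = None,
    member_a: str | None = None,
    member_b: str | None = None,
    pathways: tuple[PathwayDefinition, ...] | None = None,
    **solve_kwargs,
) -> tuple[dict[str, ConditionResult], pd.DataFrame]:
    """Fixed-abundance-ratio runs plus a per-reaction flux delta table.

    ``ratios`` maps scenario name to the biomass ratio of ``member_a``
    to ``member_b`` (defaults: sediment 9.3, synthetic 0.05). The delta
    table subtracts the second scenario's joint fluxes from the
    first's, and includes the formaldehyde transfer flux (the amount of
    pool formaldehyde taken up by ``member_a``) per scenario.
    """
    ratios = dict(ratios or ABUNDANCE_RATIOS)
    if any(r <= 0 for r in ratios.values()):
        raise ValueError("ratios must be > 0")
    mids = list(community.members)
    member_a = member_a or mids[0]
    results: dict[str, ConditionResult] = {}
    for name, ratio in ratios.items():
        solution = solve_fixed_ratio(
            community, condition, ratio, member_a=member_a, member_b=member_b,
            **solve_kwargs,
        )
        results[name] = summarize_condition(community, condition, solution, pathways)
    names = list(ratios)
    first, second = results[names[0]], results[names[-1]]
    all_rids = sorted(
        set(first.solution.joint_fluxes) | set(second.solution.joint_fluxes)
    )
    table = pd.DataFrame(
        {
            names[0]: [first.solution.joint_fluxes.get(r, 0.0) for r in all_rids],
            names[-1]: [second.solution.joint_fluxes.get(r, 0.0) for r in all_rids],
        },
        index=pd.Index(all_rids, name="reaction_id"),
    )
    table["difference"] = table[names[0]] - table[names[-1]]
    return results, table


def formaldehyde_transfer(
    community: CommunityModel, solution: CommunitySolution, member: str
) -> float:
    """Pool formaldehyde taken up by ``member`` (mmol/gDCW/hr)."""
    if community.hcho_id is None:
        return 0.0
    return solution.link_values["uptake"].get((member, community.hcho_id), 0.0)


def pathway_summary(
    flux_state: FluxState, definitions: list[PathwayDefinition]
) -> dict[str, dict]:
    """Reporter flux and per-reaction fractions for each pathway group.

    Fractions are each reaction's |flux| relative to the reporter's
    |flux| (NaN when the reporter carries none), which is how e.g. a
    minor dehydrogenase's activity is expressed as a percentage of its
    cycle's flux. Raises ``KeyError`` naming any missing reaction.
    """
    out: dict[str, dict] = {}
    for definition in definitions:
        fluxes = {}
        for rid in definition.reaction_ids:
            if rid not in flux_state.fluxes:
                raise KeyError(
                    f"pathway {definition.name!r}: reaction {rid!r} not in flux state"
                )
            fluxes[rid] = flux_state.fluxes[rid]
        reporter = fluxes[definition.reporter_reaction]
        fractions = {
            rid: abs(v) / abs(reporter) if abs(reporter) > ZERO_TOL else float("nan")
            for rid, v in fluxes.items()
        }
        out[definition.name] = {
            "reporter_flux": reporter,
            "fluxes": fluxes,
            "fractions": fractions,
        }
    return out


def toy_carbon_residual(
    community: CommunityModel, solution: CommunitySolution
) -> float:
    """Community carbon balance residual for toy communities.

    carbon in (supply) - carbon out (pool export) - carbon fixed in
    biomass, using the pool metabolite formulas for carbon counts and
    one carbon per biomass unit (the toy convention). Zero within
    tolerance for any feasible toy solution.
    """
    carbon_in = carbon_out = 0.0
    for sid in community.shared_ids:
        if sid not in solution.link_values["supply"]:
            continue
        met = community.model.metabolites.get_by_id(f"{sid}_pool")
        n_carbon = met.elements.get("C", 0)
        carbon_in += n_carbon * solution.link_values["supply"][sid]
        carbon_out += n_carbon * solution.link_values["pool_export"][sid]
    fixed = sum(solution.member_biomass.values())
    return carbon_in - carbon_out - fixed


def plot_gradient_heatmap(gradient: pd.DataFrame, path: str) -> None:
    """Write a heat map of total biomass over the methane x oxygen grid."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    pivot = gradient.pivot(
        index="oxygen_cap", columns="methane_cap", values="total_biomass"
    )
    fig, ax = plt.subplots(figsize=(6, 5))
    im = ax.imshow(pivot.values, origin="lower", aspect="auto", cmap="viridis")
    ax.set_xticks(range(len(pivot.columns)), pivot.columns)
    ax.set_yticks(range(len(pivot.index)), pivot.index)
    ax.set_xlabel("methane supply cap (mmol/gDCW/hr)")
    ax.set_ylabel("oxygen supply cap (mmol/gDCW/hr)")
    fig.colorbar(im, ax=ax, label="community biomass flux")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
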