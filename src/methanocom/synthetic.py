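"""Methanotroph-like toy models with analytically known optima.

The toys mirror the structure of an obligate aerobic methanotroph:
methane is taken up and oxidized through the linear chain
CH4 -> CH3OH -> HCHO; formaldehyde then branches into assimilation
(yielding a one-carbon biomass precursor plus respired CO2) and
dissimilation (full oxidation to CO2, generating ATP for maintenance).
Biomass production consumes the precursor and fixed di-nitrogen.
Exchange reactions exist for CH4, O2, N2, CO2 and HCHO, so the toys
drop straight into the community builder with the standard shared
metabolite set.

Carbon bookkeeping is exact by construction: the biomass precursor
``x_c`` carries one carbon per unit and the assimilation reaction
respires the (1 - yield) excess as CO2, so for any feasible flux state

    CH4 in = CO2 out + HCHO out + biomass flux   (carbon units).

For a toy with no planted defects, no formaldehyde import and caps
(mCH4, mO2, mN) the FBA optimum has the closed form implemented in
:func:`analytic_optimum`; with zero maintenance it reduces to
``min(mCH4*y*(1-f), (mO2/o2_per_ch4)*y*(1-f), mN/n_per_biomass)`` where
``y`` is the biomass yield per assimilated carbon and ``f`` the forced
formaldehyde secretion fraction.

Defects can be planted for the curation/diagnostic detectors:
``futile-loop`` and ``duplicate-reaction`` create closed circulations
(found by cycle detection), ``proton-imbalance`` a proton-repairable
imbalanced reaction (found by the balance audit), and
``orphan-metabolite`` a reaction consuming an unproducible metabolite
(found by blocked-reaction detection).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from cobra import Metabolite, Model, Reaction

from methanocom.model_core import DEFAULT_BOUND

DEFECT_KINDS = frozenset(
    {"futile-loop", "duplicate-reaction", "proton-imbalance", "orphan-metabolite"}
)

#: Shared extracellular metabolites of the two-member methanotroph community.
SHARED_METABOLITES = ("ch4_e", "o2_e", "n2_e", "co2_e", "hcho_e")

#: Reaction ids planted by each defect kind.
DEFECT_REACTIONS = {
    "futile-loop": ("FUT1", "FUT2"),
    "duplicate-reaction": ("DUP1", "DUP2"),
    "proton-imbalance": ("PIMB",),
    "orphan-metabolite": ("ORPH",),
}

DEFAULT_SWEEP_SEED = 20200630


@dataclass(frozen=True)
class ToySpec:
    """Parameters of one toy methanotroph.

    biomass_yield_per_ch4
        Biomass units per assimilated formaldehyde carbon, in (0, 1].
    o2_per_ch4
        O2 consumed per CH4 oxidized (all charged at the monooxygenase
        step).
    n_per_biomass
        N2 consumed per biomass unit.
    formaldehyde_secretion_fraction
        Fraction of oxidized carbon forced out as extracellular
        formaldehyde at the methanol-dehydrogenase step.
    formaldehyde_uptake_enabled
        Whether the member can import extracellular formaldehyde and
        assimilate it at its own yield.
    ngam
        Non-growth ATP maintenance flux; each unit requires one
        dissimilated formaldehyde.
    """

    biomass_yield_per_ch4: float = 0.5
    o2_per_ch4: float = 1.5
    n_per_biomass: float = 0.25
    formaldehyde_secretion_fraction: float = 0.0
    formaldehyde_uptake_enabled: bool = False
    ngam: float = 0.0
    planted_defects: frozenset[str] = frozenset()

    def __post_init__(self) -> None:
        if not 0 < self.biomass_yield_per_ch4 <= 1:
            raise ValueError("biomass_yield_per_ch4 must be in (0, 1]")
        if self.o2_per_ch4 <= 0 or self.n_per_biomass <= 0:
            raise ValueError("yields/ratios must be > 0")
        if not 0 <= self.formaldehyde_secretion_fraction <= 1:
            raise ValueError("secretion fraction must be in [0, 1]")
        if self.ngam < 0:
            raise ValueError("ngam must be >= 0")
        unknown = set(self.planted_defects) - DEFECT_KINDS
        if unknown:
            raise ValueError(f"unknown defects: {sorted(unknown)}")
        if (
            self.formaldehyde_uptake_enabled
            and self.formaldehyde_secretion_fraction > 0
        ):
            raise ValueError(
                "forced secretion with uptake enabled is contradictory: "
                "the member would re-import its own secreted formaldehyde"
            )


def _met(mid: str, formula: str | None, compartment: str, charge: int = 0) -> Metabolite:
    met = Metabolite(mid, formula=formula, compartment=compartment, charge=charge)
    return met


def _rxn(model: Model, rid: str, stoich: dict[Metabolite, float],
         lb: float = 0.0, ub: float = DEFAULT_BOUND) -> Reaction:
    rxn = Reaction(rid, lower_bound=lb, upper_bound=ub)
    model.add_reactions([rxn])
    rxn.add_metabolites(stoich)
    return rxn


def make_toy_methanotroph(spec: ToySpec, model_id: str = "toy") -> Model:
    """Build the toy model; see the module docstring for its layout.

    Exchange reactions are open at the default bounds; nutrient caps are
    applied at solve time (or by the community supply variables). The
    model objective is the biomass reaction ``BIOMASS``.
    """
    f = spec.formaldehyde_secretion_fraction
    # snap to the endpoints: coefficients many orders of magnitude below
    # the rest of the matrix destroy LP solver scaling without changing
    # the physics
    if f < 1e-9:
        f = 0.0
    elif f > 1 - 1e-9:
        f = 1.0
    y = spec.biomass_yield_per_ch4
    model = Model(model_id)

    ch4_e = _met("ch4_e", "CH4", "e")
    ch4_c = _met("ch4_c", "CH4", "c")
    o2_e = _met("o2_e", "O2", "e")
    o2_c = _met("o2_c", "O2", "c")
    n2_e = _met("n2_e", "N2", "e")
    n2_c = _met("n2_c", "N2", "c")
    co2_e = _met("co2_e", "CO2", "e")
    co2_c = _met("co2_c", "CO2", "c")
    hcho_e = _met("hcho_e", "CH2O", "e")
    hcho_c = _met("hcho_c", "CH2O", "c")
    # methanol carries no formula: the lumped oxidation steps are not
    # elementally balanced (no cofactors in the toy), so they must be
    # unauditable rather than imbalanced for the balance audit
    ch3oh_c = _met("ch3oh_c", None, "c")
    x_c = _met("x_c", None, "c")  # biomass precursor, 1 C per unit
    atp_c = _met("atp_c", None, "c")
    adp_c = _met("adp_c", None, "c")

    _rxn(model, "EX_ch4_e", {ch4_e: -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
    _rxn(model, "EX_o2_e", {o2_e: -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
    _rxn(model, "EX_n2_e", {n2_e: -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
    _rxn(model, "EX_co2_e", {co2_e: -1}, 0.0, DEFAULT_BOUND)
    hcho_lb = -DEFAULT_BOUND if spec.formaldehyde_uptake_enabled else 0.0
    _rxn(model, "EX_hcho_e", {hcho_e: -1}, hcho_lb, DEFAULT_BOUND)

    _rxn(model, "TCH4", {ch4_e: -1, ch4_c: 1})
    _rxn(model, "TO2", {o2_e: -1, o2_c: 1})
    _rxn(model, "TN2", {n2_e: -1, n2_c: 1})
    _rxn(model, "TCO2", {co2_c: -1, co2_e: 1})
    _rxn(model, "THCHO_sec", {hcho_c: -1, hcho_e: 1})
    if spec.formaldehyde_uptake_enabled:
        _rxn(model, "THCHO_upt", {hcho_e: -1, hcho_c: 1})

    # oxidation chain: all O2 charged at the monooxygenase
    _rxn(model, "MMO", {ch4_c: -1, o2_c: -spec.o2_per_ch4, ch3oh_c: 1})
    mdh_products = {ch3oh_c: -1.0}
    if f < 1:
        mdh_products[hcho_c] = 1 - f
    if f > 0:
        mdh_products[hcho_e] = f
    _rxn(model, "MDH", mdh_products)

    # assimilation respires the excess carbon so biomass carries 1 C/unit
    assim = {hcho_c: -1.0, x_c: y}
    if y < 1:
        assim[co2_c] = 1 - y
    _rxn(model, "ASSIM", assim)
    _rxn(model, "DISSIM", {hcho_c: -1, adp_c: -1, co2_c: 1, atp_c: 1})
    _rxn(model, "ATPM", {atp_c: -1, adp_c: 1}, spec.ngam, DEFAULT_BOUND)
    _rxn(model, "BIOMASS", {x_c: -1, n2_c: -spec.n_per_biomass})

    _plant_defects(model, spec.planted_defects)
    model.objective = "BIOMASS"
    return model


def _plant_defects(model: Model, defects: frozenset[str]) -> None:
    if "futile-loop" in defects:
        m1 = _met("fut1_c", None, "c")
        m2 = _met("fut2_c", None, "c")
        _rxn(model, "FUT1", {m1: -1, m2: 1})
        _rxn(model, "FUT2", {m2: -1, m1: 1})
    if "duplicate-reaction" in defects:
        d1 = _met("dup1_c", None, "c")
        d2 = _met("dup2_c", None, "c")
        _rxn(model, "DUP1", {d1: -1, d2: 1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "DUP2", {d1: -1, d2: 1}, -DEFAULT_BOUND, DEFAULT_BOUND)
    if "proton-imbalance" in defects:
        # deprotonated product written without the proton: fixable
        ga = _met("glca_e", "C6H12O6", "e", charge=0)
        gb = _met("glcb_e", "C6H11O6", "e", charge=-1)
        _rxn(model, "EX_glca_e", {ga: -1}, -DEFAULT_BOUND, DEFAULT_BOUND)
        _rxn(model, "EX_glcb_e", {gb: -1}, 0.0, DEFAULT_BOUND)
        _rxn(model, "PIMB", {ga: -1, gb: 1})
    if "orphan-metabolite" in defects:
        orphan = _met("orphan_c", None, "c")
        co2 = model.metabolites.get_by_id("co2_c")
        _rxn(model, "ORPH", {orphan: -1, co2: 1})


def analytic_optimum(
    spec: ToySpec,
    methane_cap: float,
    oxygen_cap: float,
    nitrogen_cap: float,
) -> float | None:
    """Closed-form FBA optimum of the defect-free toy under caps.

    Assumes no extracellular formaldehyde is available for import.
    Returns None when the maintenance demand cannot be met (infeasible).
    """
    f = spec.formaldehyde_secretion_fraction
    oxidizable = min(methane_cap, oxygen_cap / spec.o2_per_ch4)
    intracellular_c = oxidizable * (1 - f)
    assimilable = intracellular_c - spec.ngam
    if assimilable < -1e-12:
        return None
    biomass_c = assimilable * spec.biomass_yield_per_ch4
    biomass_n = nitrogen_cap / spec.n_per_biomass
    return max(0.0, min(biomass_c, biomass_n))


def cap_bounds(
    methane_cap: float, oxygen_cap: float, nitrogen_cap: float
) -> dict[str, tuple[float, float]]:
    """Exchange-bound overrides implementing standalone nutrient caps."""
    return {
        "EX_ch4_e": (-methane_cap, DEFAULT_BOUND),
        "EX_o2_e": (-oxygen_cap, DEFAULT_BOUND),
        "EX_n2_e": (-nitrogen_cap, DEFAULT_BOUND),
    }


def make_toy_community(
    spec_a: ToySpec,
    spec_b: ToySpec,
    ids: tuple[str, str] = ("A", "B"),
    weights: dict[str, float] | None = None,
):
    """Two-member toy community sharing CH4/O2/N2/CO2/HCHO.

    Member ``ids[0]`` gets ``spec_a``. Cross-feeding arises when one
    member secretes formaldehyde and the other has uptake enabled.
    """
    from methanocom.community import build_community

    member_a = make_toy_methanotroph(spec_a, ids[0])
    member_b = make_toy_methanotroph(spec_b, ids[1])
    return build_community(
        [member_a, member_b], set(SHARED_METABOLITES), weights=weights
    )


def random_spec_sweep(
    n: int = 100, seed: int = DEFAULT_SWEEP_SEED
) -> list[tuple[ToySpec, tuple[float, float, float]]]:
    """Randomized defect-free specs + caps for closed-form sweeps."""
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n):
        spec = ToySpec(
            biomass_yield_per_ch4=float(rng.uniform(0.2, 1.0)),
            o2_per_ch4=float(rng.uniform(1.0, 3.0)),
            n_per_biomass=float(rng.uniform(0.05, 0.5)),
            formaldehyde_secretion_fraction=float(
                rng.choice([0.0, rng.uniform(0.0, 0.8)])
            ),
            ngam=float(rng.choice([0.0, rng.uniform(0.0, 2.0)])),
        )
        caps = tuple(float(c) for c in rng.uniform(1.0, 50.0, size=3))
        out.append((spec, caps))
    return out


def study_pair(
    inhibit: bool = True,
    mb_methane_transport_cap: float | None = 28.0,
) -> "methanocom.community.CommunityModel":  # noqa: F821
    """The package's reference two-member methanotroph community.

    Member ``MB`` (Methylobacter-like) converts methane to biomass more
    efficiently and can take up extracellular formaldehyde, which
    inhibits its growth; member ``ML`` (Methylomonas-like) secretes a
    small fraction of its oxidized carbon as formaldehyde.

    ``mb_methane_transport_cap`` limits MB's own methane import
    capacity, which keeps both members active at the community optimum
    under oxygen limitation (otherwise the more efficient member simply
    monopolizes the substrate). Yields, the secretion fraction and the
    transport cap are fixture choices documented in the package's
    methods note, not fitted quantities.
    """
    from methanocom.community import (
        InhibitionParams,
        apply_formaldehyde_inhibition,
        build_community,
    )

    spec_mb = ToySpec(
        biomass_yield_per_ch4=0.6,
        o2_per_ch4=1.5,
        n_per_biomass=0.25,
        formaldehyde_uptake_enabled=True,
        ngam=0.5,
    )
    spec_ml = ToySpec(
        biomass_yield_per_ch4=0.5,
        o2_per_ch4=1.5,
        n_per_biomass=0.25,
        formaldehyde_secretion_fraction=0.05,
        ngam=0.5,
    )
    member_mb = make_toy_methanotroph(spec_mb, "MB")
    if mb_methane_transport_cap is not None:
        member_mb.reactions.EX_ch4_e.lower_bound = -mb_methane_transport_cap
    member_ml = make_toy_methanotroph(spec_ml, "ML")
    community = build_community(
        [member_mb, member_ml], set(SHARED_METABOLITES)
    )
    if inhibit:
        apply_formaldehyde_inhibition(
            community, "MB", InhibitionParams(), v_maxbiomass="auto"
        )
    return community
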