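# Methods

## Constraint-based models

A member model is a stoichiometric network over metabolites *i* and
reactions *j* with coefficients S<sub>ij</sub>, flux bounds
LB<sub>j</sub> ≤ v<sub>j</sub> ≤ UB<sub>j</sub> (mmol/gDCW/hr
throughout), and a biomass reaction. Flux balance analysis (FBA)
maximizes the biomass flux subject to steady state, Σ<sub>j</sub>
S<sub>ij</sub>·v<sub>j</sub> = 0 for every metabolite, and the bounds.
Flux variability analysis (FVA) minimizes and maximizes each reaction
flux with the objective pinned — either as an equality at a stated
flux, or as a lower bound at a fraction of the optimum. Models arrive
through the SBML reader of COBRApy (Level 2 legacy encodings and Level
3/fbc are both accepted); bounds absent from a file are set to the
conventional ±1000 mmol/gDCW/hr.

Two FVA-based diagnostics:

* **Blocked reactions** are reactions whose flux range is [0, 0] with
  every exchange reaction opened to the default bounds (the most
  permissive medium; a different medium can be imposed by editing the
  exchange bounds before the scan).
* **Thermodynamically infeasible cycles** are internal loops that can
  circulate with *all* exchange reactions closed; with no net
  metabolite turnover such flux has no thermodynamic driving force.
  They are found by closing all exchanges, running FVA at objective
  zero, collecting reactions whose range reaches the default bound
  (within a factor 0.999, robust to solver round-off), and grouping
  these into connected components of the reaction–metabolite bipartite
  graph. Grouping by connectivity is a deliberate, simple choice; a
  component may in principle contain several elementary loops.

## Curation

The balance audit computes, per internal reaction, the net element and
charge imbalance from metabolite formulas and charges. Reactions
touching a formula-less metabolite are reported as unauditable rather
than imbalanced; exchange reactions are exempt by design. An imbalance
confined to hydrogen with equal charge imbalance is flagged
proton-fixable; automatic proton repair is off by default because
silent model edits are dangerous.

Physiological constraints applied by `apply_curation` (all through an
explicit reaction-tag map, never pattern guessing):

* non-growth-associated ATP maintenance (NGAM) fixed as an equality
  bound, default 21.6 mmol/gDCW/hr (measured in a closely related
  alkaliphilic methanotroph);
* the direct formaldehyde entry into the serine cycle shut off,
  restricting C1 assimilation to the RuMP cycle and
  tetrahydrofolate-associated routes, while the rest of the serine
  cycle stays usable from other inputs;
* oxygen stoichiometry of the methane-oxidation electron-transfer
  reactions fixed at 1 O₂ per pyrroloquinoline quinone
  (direct-coupling mode) and 0.5 O₂ per cytochrome c (oxidase);
* biomass coefficients replaced from a two-column composition table
  (metabolite id, mmol/gDCW).

## Community model

Members keep disjoint namespaces inside one joint LP. For each shared
metabolite *i* (methane, oxygen, di-nitrogen, CO₂, formaldehyde) a
member's exchange reaction is split into non-negative uptake and
export links r<sub>uptake,i</sub><sup>k</sup>, r<sub>export,i</sub><sup>k</sup>;
the extracellular pool is balanced by non-negative community supply
u<sub>i</sub><sup>c</sup> and export e<sub>i</sub><sup>c</sup>:

Σ<sub>k</sub> r<sub>uptake,i</sub><sup>k</sup> + e<sub>i</sub><sup>c</sup> =
Σ<sub>k</sub> r<sub>export,i</sub><sup>k</sup> + u<sub>i</sub><sup>c</sup>.

Nutrient conditions cap the supply variables; the panels used
throughout are A (100/100/100), B (100/50/100), C (100/100/40) and
D (20/100/100) for methane/oxygen/nitrogen. Link directionality is
inherited from each member's exchange bounds, so e.g. CO₂ is
export-only where the member model says so. Nitrogen is shared as N₂
(the members fix di-nitrogen); ammonium sharing is not modeled.

**Solution strategy.** The underlying program is two-level: each member
maximizes its own biomass given its link values, while the community
objective (weighted sum of member biomasses) is maximized over the
links. Because the outer objective is exactly the weighted sum of the
inner objectives, the joint single-level LP attains the same optimum;
the general KKT reformulation of such programs is nonconvex and
needless here. The solver therefore (1) solves the joint LP, (2)
*polishes*: pins each member's biomass at its solved value and
minimizes total uptake-link flux, removing slack substrate allocations
that alternative optima permit, and (3) *certifies*: for each member,
fixes the net shared-metabolite exchange at the solved link values in
the member's standalone model, re-maximizes its biomass, and checks the
re-solved optimum does not exceed the reported biomass by more than
1e-6. A failing member is flagged in the returned solution, never
silently accepted. Member-level splits can remain degenerate; the
envelope of each member's biomass at pinned community total is exposed
(`biomass_split_envelope`) and composition statements use its midpoint.

**Formaldehyde inhibition.** Extracellular formaldehyde inhibits the
consuming member (the Methylobacter-like partner):

v<sub>biomass</sub> ≤ v<sub>max</sub> · (1 − R · v<sub>HCHO-uptake</sub>)

with v<sub>max</sub> the member's uninhibited optimum recomputed per
environment (same condition, formaldehyde uptake fixed to zero) before
any fixed-abundance constraint is imposed — v_max characterizes the
environment, not an imposed composition. R derives from the inhibitory
concentration window (onset 1 mM, total inhibition 7 mM). The uptake
flux (mmol/gDCW/hr) stands in numerically for concentration, as no
volume/time conversion is available; two readings are exposed:
zero-offset (default) R = 1/c_max = 1/7, and onset-offset
R = 1/(c_max − c_min) = 1/6 with the constraint shifted by the onset
(implemented as two linear inequalities). Growth hits zero exactly at
R·uptake = 1.

**Fixed abundance ratios** add v<sub>biomass</sub><sup>A</sup> =
ratio · v<sub>biomass</sub><sup>B</sup> to the outer problem (sediment
9.3:1, synthetic co-culture 0.05:1 by default).

## Synthetic toy models

The toy generator is the download-free test surface. Each toy mirrors
an obligate aerobic methanotroph: exchanges for CH₄/O₂/N₂/CO₂/HCHO,
the oxidation chain CH₄ → CH₃OH → HCHO (all O₂ charged at the
monooxygenase, `o2_per_ch4` per CH₄), a branch into assimilation and
dissimilation, ATP from dissimilation feeding an NGAM drain, and a
biomass reaction consuming a one-carbon precursor plus N₂. The
assimilation step respires the (1 − yield) excess carbon, so one unit
of biomass carries exactly one carbon and community carbon balance is
exact by construction. The defect-free FBA optimum has the closed form

min( (min(m_CH₄, m_O₂/o2_per_ch4)·(1 − f) − NGAM) · yield,
m_N / n_per_biomass ),

with f the forced formaldehyde-secretion fraction; at NGAM = 0 this is
the plain three-way minimum of the carbon-, oxygen- and
nitrogen-limited yields. Forced secretion together with uptake enabled
is rejected (the member would re-import its own secretion); a secretion
fraction of 1 with uptake disabled is valid and yields optimum zero.
Defects can be planted for the detectors: an opposed irreversible pair
(futile loop) and a reversible duplicate pair for cycle detection, a
proton-repairable imbalanced reaction for the audit, and an
orphan-metabolite reaction for blocked detection; the chain
intermediates deliberately carry no formulas so only planted
imbalances are auditable.

The default two-member community (`study_pair`) emulates the modeled
system: MB (Methylobacter-like; yield 0.6 per assimilated carbon,
formaldehyde consumer, inhibited) and ML (Methylomonas-like; yield
0.5, secretes 5% of oxidized carbon as formaldehyde), both with
o2_per_ch4 = 1.5, n_per_biomass = 0.25 and a small maintenance of 0.5.
MB's methane import is capped at 28 mmol/gDCW/hr, which keeps both
members active at the community optimum under oxygen limitation;
without it the more efficient member simply monopolizes the substrate.
These are fixture choices pitched at methanotroph-like magnitudes, not
fitted quantities. With them the fixed-ratio scenarios reproduce the
qualitative cross-feeding switch: under the sediment composition
(9.3:1) MB sits at its uninhibited maximum and declines formaldehyde;
under the synthetic composition (0.05:1) MB covers its small carbon
need partly from ML's secreted formaldehyde, bypassing the
oxygen-intensive oxidation of methane.

What the toys do **not** emulate: genome-scale size (≈1,400 reactions),
cofactor and redox bookkeeping, realistic biomass composition, multiple
electron-transfer modes, or measured uptake kinetics. Passing tests
demonstrate the correctness of the optimization machinery and the
conservation/certification contracts, not quantitative fluxes of the
real organisms; the genome-scale models can be run through the same
pipeline via the CLI when their SBML files are available.

## Numerical choices

* LP feasibility tolerance 1e-9; flux-zero threshold 1e-6; a flux
  "reaches" a default bound above 0.999 of it.
* Certification tolerance 1e-6; pinned values are relaxed by 1e-9
  (biomass) or 1e-7 (exchange fixing, total pinning) to absorb solver
  round-off.
* Toy secretion fractions within 1e-9 of 0 or 1 are snapped to the
  endpoint: coefficients dozens of orders of magnitude below the rest
  of the matrix wreck LP scaling without changing the physics.
* Solver: GLPK through optlang/COBRApy; all problems are pure LPs, so
  results are deterministic for a fixed model ordering.
* Degenerate member splits are reported alongside their FVA envelope;
  the gradient's composition fractions use the envelope midpoint.

## Known limitations

* Blocked-reaction counts depend on the medium convention (all
  exchanges open at ±1000); genome-scale reproductions may need the
  deposited files' own embedded bounds.
* The cycle grouping is connectivity-based and does not separate
  elementary flux modes within one component.
* The inner-optimality certificate checks *net* exchange fixing per
  shared metabolite, which is equivalent to fixing uptake and export
  separately whenever the member has a single exchange reaction per
  shared metabolite (true for the toys and the deposited models).
* No dynamic or spatial extension; no loopless-FBA solver variants —
  infeasible cycles are meant to be removed by curation.
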