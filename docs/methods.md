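# Methods

## Model representation and preparation

A model is an ordered list of species and reactions. Reversible reactions are
split into a forward copy (keeping the original id) and a backward copy with
the `_reverse` suffix and swapped sides, so every downstream stage works on
non-negative directional fluxes. From the split model two dense matrices are
built: the signed stoichiometric matrix `S` (products positive, reactants
negative) and the reactant-order matrix `A` holding reactant-side
coefficients, which serve directly as the kinetic orders of the mass-action
law. Non-integer coefficients (biomass-style pseudo-reactions) are accepted
and used literally as orders.

SBML Level 2/3 input is parsed with libsbml: species with a boundary-condition
flag are clamped, and species in an external compartment (or with a boundary
flag) are marked non-internal. The tabular dialect (`reaction_id <TAB>
equation`, with `<->` marking reversibility) carries no species metadata;
clamped species are supplied separately as a one-id-per-line file, matching
how the CLI wires the two together. Initial concentrations come from a
`species_id <TAB> concentration` table; species without a listed value receive
the mean of the listed values, computed once per load. Concentrations are
treated as mM and times as seconds throughout; rate constants then have the
units that make `k_i ∏ x_w^{A_wi}` a mM/s flux for each reaction's order.

## Sampling

Each parametrization draws one rate constant per directional reaction from a
uniform law on `[low, high)`, default `[0, 100)`. Forward and backward
constants of a split pair are sampled independently — the framework imposes no
thermodynamic coupling between the two directions. Reproducibility uses a
counter-based scheme: parametrization `p` gets
`SeedSequence(master_seed, spawn_key=(p,))`, so vector `p` is identical
regardless of ensemble size and vectors can be regenerated in isolation or in
parallel. A log-uniform prior is a natural extension but is deliberately not
the default; the uniform prior is the framework's stated sampling condition.

## Dynamics and the steady-state criterion

Rates are evaluated as `exp(Σ_{w: A_wi>0} A_wi ln x_w)` with an exact zero
whenever a required reactant is absent; this one code path is robust for
high-order (many-reactant) columns that would under/overflow as a literal
product, and costs nothing for small models. Clamped species have their
derivative forced to zero and their trajectory rows set bit-exactly to the
initial value. Integration uses LSODA (stiff-capable, automatic method
switching) on a fixed output grid of 1001 points over `[0, 100]` s with
rtol 1e-6 and atol 1e-9; reported concentrations are clipped at zero. Solver
failures raise an error carrying the parametrization id and are counted by the
driver as discarded samples, indistinguishable in the bookkeeping from
non-steady runs.

A trajectory is accepted as a metabolic steady state when the mean, over
non-excluded species, of the per-species standard deviation across the final
`window_fraction` (default 10 %) of the horizon falls below `theta`
(default 1e-3). Design choices worth stating:

* `sigma` is the absolute standard deviation; the criterion as written has no
  normalization by the window mean. A relative mode (sigma divided by the
  window mean, skipping near-zero means) is available via `relative=True` for
  users who prefer a scale-free criterion.
* The denominator is `M − S` with `M` the total species count and `S` the
  number of excluded species. Excluded means clamped **or** flagged
  non-internal: accumulating species (exported products, biomass) never
  settle, and counting them would make every simulation fail; they contribute
  exactly zero to the numerator either way.
* The window must contain at least three grid points; with the default grid
  the 10 % window holds 101.

The flux-balance residual `max_w |Σ_i S_wi v_i(x(t_e))|` over internal
unclamped species shrinks as `theta` is tightened — this monotonicity is a
tested property and the practical justification for reading fluxes off the
final state.

## Fluxes and the zero threshold

Fluxes are evaluated at the final time point of a certified run (not averaged
over the window — the window dispersion is already certified small, and a
single state keeps the flux/concentration correspondence exact). Values
strictly below `1e-10` are snapped to zero before any filter is evaluated;
the strict inequality means a flux of exactly `1e-10` survives. Thresholding
first makes the `= 0` predicate of the anaerobic filter numerically
meaningful and is idempotent.

## FBA and filter derivation

The reference flux distributions maximize a biomass reaction over
`{v : S_internal v = 0, 0 ≤ v ≤ ub}` with scipy's HiGHS backend. Condition
bounds open exactly one carbon uptake at 10 flux units (a conventional
mmol·gDW⁻¹·h⁻¹ scale), close the others, and cap oxygen uptake at zero for
the anaerobic condition; a rich-medium `exp0` opens every carbon source.
Infeasible/unbounded programs are reported through a status field rather than
raised. `derive_filter_targets` reconstructs the condition-discriminating
table: class A reactions carry flux (after the 1e-10 threshold) in exactly
one condition, class B are the configured condition-defining exchanges.
Because LP vertices can be degenerate in non-objective coordinates, an
optional flux-variability check re-solves min/max of each class-A reaction at
the fixed optimum and flags calls whose single-condition status is not
unique.

## Phenotype filters and membership

A phenotype is a conjunction of `(reaction, > 0)` / `(reaction, = 0)`
predicates evaluated on thresholded fluxes; a record belongs to every
phenotype whose conjunction it satisfies, so zero, one, or several
memberships are all possible. The five built-in filters encode aerobic
growth on glucose, anaerobic growth on glucose (the only filter with an
equal-zero predicate, on oxygen uptake), and aerobic growth on acetate,
succinate, and glycerol. Filters are also serializable as JSON for
user-defined phenotypes.

Intersection cardinalities are reported in two deliberately distinct views,
because "a parametrization in two ensembles" is ambiguous:

* **per record** — each simulation record counted by its exact membership
  set; marginals count records, and co-membership of the anaerobic phenotype
  with any aerobic one is structurally impossible on a single record;
* **per parametrization (matched)** — phenotype `e` holds for parametrization
  `p` iff `p`'s simulation under condition `e` satisfies filter `e`; this is
  the view in which "works for all aerobic conditions but not the anaerobic
  one" is a meaningful intersection.

In both views the exact-combination counts partition the entities with
non-empty membership (a tested invariant).

## Ensemble characterization

Summaries report per-reaction medians and population standard deviations of
kinetic constants or steady-state fluxes, grouped either by simulated
condition (`sC`) or by filter satisfaction regardless of condition (`fC`).
Empty ensembles are flagged, never raised. The relevant-flux procedure runs a
two-sample Kolmogorov–Smirnov test for each reaction and each of the 10
condition pairs; a reaction is *relevant* iff `p < alpha` (default 0.05) for
every pair. The exact small-sample null distribution is used when both
samples have ≤ 50 points, the asymptotic law otherwise. No multiple-testing
correction is applied by default — the relevance call is a plain
per-comparison 0.05 — but Benjamini–Hochberg across all tests is available
behind a flag. Records belonging to several ensembles are used as-is; the
induced dependence between groups is a known property of the design, not
corrected for.

## Storage

Runs are persisted in an HDF5 container (h5py) with one group per condition
holding appendable final-state, flux, and steady-report tables keyed by
parametrization id, plus groups for model metadata, the sampled constants,
and the membership table. Full trajectories are not stored by default — the
criterion needs only the final window, and storing every trajectory of a
large ensemble is the multi-gigabyte regime this layout exists to avoid.
Dataset creation disables HDF5 timestamp tracking, so identical inputs and
master seed produce byte-identical files; end-to-end byte determinism is a
tested property.

## Synthetic fixtures: what they emulate and what they do not

* **Linear chains** `X0 (clamped) → X1 → … → Xn → ∅` have closed-form steady
  states (`J = k_1 X0`, `[X_i] = J / k_{i+1}`), giving an independent oracle
  for the ODE, criterion, and flux stages to relative 1e-4. A chain with a
  dead outflow step accumulates linearly and must fail the criterion — the
  planted "discard".
* **The marker network** (24 species, 30 directional reactions after
  splitting the reversible oxygen exchange) carries the five filters' marker
  reactions, wired so each condition's FBA optimum satisfies exactly its own
  filter (hand-derived optima 20, 10, 10, 10, 10). Overflow export valves
  give every internal species a linear sink so mass-action steady states
  exist for generic positive rates; the reversible oxygen exchange lets
  excess oxygen leave, which is what makes aerobic steady states reachable
  when supply and consumption do not match. Feeds are clamped at 10 mM for
  the condition's nutrient (and oxygen when aerobic), 0 otherwise; internal
  species start at 1 mM.
* **Planted flux tables** and **planted KS samples** provide ground truth for
  membership assignment (including multi-membership, empty membership, and
  the refusal of structurally impossible anaerobic∧aerobic plants) and for
  relevant-flux detection (all-pairs separation at a chosen effect size in
  sigma units, a partially separated decoy, and identically distributed
  nulls).

What passing these tests shows: the sampling, integration, criterion, flux,
filtering, storage, and analysis machinery is correct on networks whose truth
is known. What it does not show: behavior on a real core reconstruction —
the marker network's topology is minimal by construction, its assignments
under its own growth conditions are nearly deterministic, and its discard
rate (a few percent at ensemble scale) reflects its own kinetics, not those
of any published model. Quantities tied to a specific published
reconstruction (its reaction counts, growth rates, discard rate, ensemble
sizes) require that model file as input; the loaders accept it directly.

## Problem sizes and numerical defaults

Default experiment sizes used by the acceptance script: 200 parametrizations
× 5 conditions on the marker network (~1000 ODE integrations, well under a
minute), 10 replicates of the KS fixture at n = 200 per condition, and five
random chains for the closed-form oracle. Tolerances: solver rtol 1e-6 /
atol 1e-9 (tightened to 1e-10/1e-12 where tests compare against closed
forms at relative 1e-6); steady-state theta 1e-3; zero-flux epsilon 1e-10;
KS alpha 0.05. Ties and degenerate inputs: empty reactant side means rate
`k`; zero concentrations give exact zero rates for reactions that need the
species; empty ensembles are flagged; LP degeneracy is surfaced via the
optional variability check rather than hidden.
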