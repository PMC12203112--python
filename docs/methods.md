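# Methods

## Model and assumptions

The community is modelled as a compartmentalised stoichiometric matrix at
steady state (S·v = 0): each member's metabolites and reactions live in a
private namespace, extracellular species with the same identifier are
merged into shared rows, and community-level exchange reactions are
deduplicated to one per species. The formulation assumes mutualistic or
resource-competing communities; inhibitory interactions (toxicity) are not
representable. Growth is the flux of each member's biomass reaction, and
the community objective is the *unweighted* sum of member growth rates —
abundance weighting is deliberately absent, since the whole point of the
method is to predict growth without abundance data.

All analysis runs on the irreversible form of the model: a reversible
reaction (lb < 0) becomes a forward and a reverse column, both inheriting
the reaction's GPR, with net flux fwd − rev. A reaction with a strictly
positive lower bound (forced flux) is kept as-is with a warning, since the
nonnegative-flux convention cannot apply to it.

Expression enters via GPR rules evaluated on TPM values: AND → min (a
complex is limited by its scarcest subunit), OR → sum (isozymes add
capacity). The per-reaction score f(g̃) is rescaled by the community-wide
maximum M, computed **per sample**: constraints are built per time point,
so the temporal scope of M follows the sample while the community scope
spans all members. Genes present in a GPR but absent from the expression
table score 0 — metatranscriptomes are sparse, and the relaxation
mechanism below exists precisely to rescue reactions silenced by dropout;
treating absence as missing-at-random would erase the method's signal.
The forward and reverse columns of a split reversible reaction share one
factor (one enzyme catalyses both directions) but carry independent
relaxation pairs, because the bound being relaxed is per column.

The growth LP maximises Σμ − λΣ(β⁺+β⁻) subject to the expression-scaled
bounds 0 ≤ v ≤ v_max·(f/M + β⁺ − β⁻), the plain capacity bounds, the
factor box 0 ≤ f/M + β⁺ − β⁻ ≤ 1 and the relaxation box 0 ≤ β ≤ 1000.
TPM is used on the linear scale. Useful analytic facts, all verified by
the test suite: z*(λ) is non-increasing, convex and piecewise linear; as
λ → 0⁺ the LP approaches plain FBA (every factor relaxed to its cap of
1); at large λ it becomes the hard-bound (pure E-flux) problem with
Σβ = 0; and β⁻ is redundant at the optimum — tightening a bound can never
help while costing λ > 0 — so it is carried only for fidelity to the
formulation and checked, not needed.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| λ (balancing factor) | auto-selected | — | growth vs relaxation trade-off |
| λ grid | 0.1, 0.5, 1, 2, …, 50 | — | scanned by both selection modes |
| β box | 1000 | — | relaxation bound (matches default v_max) |
| default v_max | 1000 | mmol·gDW⁻¹·h⁻¹ | substituted for non-finite bounds |
| essentiality threshold | 1e-5 | mmol·gDW⁻¹·h⁻¹ | Φ_min above it ⇒ essential |
| key-reaction cutoffs | ρ > 0.7, BH p < 0.05 | — | per sample |
| min_sample_fraction | 0.5 (strict majority) | — | samples a key reaction must pass in |
| solver tolerances | 1e-9 (clamped to HiGHS' 1e-10 floor) | — | feasibility/optimality |

## λ selection

*Sensitivity (no abundance data).* The grid is solved per sample and z*
averaged; both λ and z* are min–max normalised to [0, 1]; the selected λ
is the grid point with the largest discrete curvature (second divided
difference, correct for the non-uniform grid head). Ties break toward the
smaller λ, a flat curve returns the smallest grid value with a warning,
and monotonicity of z*(λ) is checked as a solver-sanity assertion. The
detector is intentionally simple; on a convex piecewise-linear curve the
curvature maximum is the transition point where growth and relaxation
balance.

*Cross-validation (with abundance data).* Samples are partitioned into k
seeded random folds. For every grid λ the Spearman correlation between
predicted μ and relative abundance is computed per sample; each fold's
best λ is the argmax of the mean correlation over its **held-out**
samples (ties toward smaller λ), and the returned λ is the mean of the
per-fold bests. Scoring on held-out rather than training samples is the
design choice here: it is the reading that makes the fold structure do
any work. Samples with a constant abundance vector are excluded with a
warning (correlation undefined).

## Fixed-optimum analyses

Variability and flux-sum analyses pin the incumbent objective. Exact
equality is numerically brittle with simplex/interior solvers, so the
pin is two-sided for variability (z* − ε ≤ Σμ − λΣβ ≤ z*) and one-sided
(≥ z* − ε) for flux sums, with ε = 1e-6·max(1, |z*|). Growth variability
reports (μ_min, μ_max, (μ_max − μ_min)/μ_max), defined as 0 when
μ_max = 0; precision claims should be made through these ranges, never
through the raw point solution, which is an arbitrary optimal vertex.

The flux sum Φ_m = ½ Σ_i |S_mi| v_i is linear on the irreversible model,
so Φ_min is one LP per metabolite. "Import reaction" means a member
column consuming an extracellular species; the analysed metabolite is the
extracellular species itself (its row spans all members' transporters).
Candidate sets are either the metabolites imported by *every* member
(common imports) or all extracellular species. Classification across
samples: essential everywhere → time-independent; essential somewhere but
not everywhere → time-dependent; otherwise never essential. A metabolite
with no incident reactions returns Φ_min = 0 with a warning.

Key reactions: Spearman ρ across members between net flux and relative
abundance, per (sample, reaction); Benjamini–Hochberg correction is
applied within each sample's family of reactions (the conservative
per-time-point reading); a reaction is key when it passes both cutoffs in
a strict majority of samples. At least 4 members are required — with 3
the exact permutation null cannot reach p < 0.05. Constant flux vectors
are skipped with a note. Knockouts zero the v_max of every column of the
reaction in every member (key reactions are common by construction) and
re-solve at the same λ, restoring the model afterwards.

## Synthetic data generator

The generator emulates the data situation the method is built for, at
oracle-tractable scale (≤ ~40 reactions). Each member runs a linear
pathway: shared substrate → transport (capacity ≈ 10 mmol·gDW⁻¹·h⁻¹, the
standard FBA uptake scale) → `pathway_depth` conversions (capacity 1000)
→ biomass. Member j's first conversion secretes a byproduct that member
j+1's biomass requires at 0.1 units per unit growth, so byproducts are
obligate cross-feeding links; unconsumed medium decoys serve as negative
controls. Transport capacities are staggered by 0.1% across members to
keep the optimal vertex unique. Designed activities default to a
geometric ladder (1, 3, 9, 27), reflecting the orders-of-magnitude
activity spans of real communities; they double as ground-truth relative
abundances.

Expression: TPM = activity × pathway-position weight × lognormal(0,
noise_sd), then an exact fraction of gene entries is zeroed
(`expression_sparsity`), then the profile is renormalised to 10⁶. The
transporter carries an OR-family of 5 isozymes so that dropout attenuates
rather than erases a member's uptake signal — with a single transporter
gene, one zeroed entry would silence the member and the test would probe
the relaxation mechanism instead of expression integration.

What the fixture does *not* emulate: genome-scale network redundancy,
branched pathways with alternative routes, realistic media, gene
multi-functionality, compositional coupling between members' TPM totals.
Passing tests therefore demonstrate correctness of the optimisation
machinery and the direction of the method's effects, not field
performance on real metatranscriptomes.

A behaviour worth knowing when designing experiments on the fixture: at
moderate λ the LP will rescue a transcriptionally silent *mid-chain*
member, because relaxing its transport bound also unlocks its downstream
consumer's growth (the cascade gain exceeds λ). Only the terminal member,
with no consumer, stays silent when λ exceeds its transport capacity.
This is the relaxation mechanism working as intended — essential routes
are protected from expression dropout — but it means "silencing" a member
in the middle of the chain does not zero its growth.

## Numerical choices

- LPs are solved with HiGHS via `scipy.optimize.linprog` on sparse
  blocks; the independent oracle in the tests uses optlang/GLPK with a
  naive dense formulation. Agreement to 1e-6 on random toys is part of
  the test suite; results are required to be solver-stable at 1e-5.
- Problem sizes: random oracle toys ≤ 8 reactions; the standard community
  fixture has 4 members, 30 columns (32 after splitting), 8 genes per
  member; grid scans solve 52 LPs per sample. The whole test suite runs
  in well under a minute on one CPU.
- Exchange reactions duplicated across member files keep the first
  occurrence's bounds (with a warning on conflict). Extracellular merging
  is by metabolite id only; no formula reconciliation is attempted (ids
  are assumed namespace-harmonised, e.g. MNXref).
- Biomass detection is a case-insensitive regex (default "biomass");
  multiple matches are fatal rather than guessed.
- The growth medium is whatever the exchange bounds of the input SBML say,
  optionally overridden by a per-exchange max-uptake table; no gap-filling
  is performed. A per-sample medium override is possible by rebuilding the
  bundle; the default is a fixed medium across time points.
- All stochastic steps (CV folds, fixture generation) require an explicit
  seed; there is no silent default.

## Known limitations

- The β box of 1000 is generous by design; on models whose v_max exceeds
  it the relaxation cap, not the factor box, may bind first.
- The knee detector assumes the convex piecewise-linear shape the LP
  guarantees; it is not meant for curves averaged over wildly
  heterogeneous samples, where the knee may smear across grid points.
- Top-k selection for exchanged-metabolite reporting is exposed as a user
  parameter (`FluxSumResult.ranked(top=k)`) without an endorsed default.
- Point flux distributions at the optimum are degenerate in general; all
  conclusions should be drawn from the pinned-optimum analyses
  (variability, Φ_min) rather than from a single flux vector.
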