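# imic — expression-constrained community metabolic modelling

`imic` integrates metatranscriptomic data into compartmentalised microbial
community genome-scale metabolic models (GEMs) to predict the growth rate
of each community member and to quantify the metabolite exchanges that
sustain the community. It is aimed at microbiome and systems-biology
researchers who have (i) one metabolic reconstruction per community member
(e.g. per MAG) and (ii) per-sample gene expression (TPM, or counts plus
gene lengths), and who want condition-specific growth and interaction
predictions *without* relying on species-abundance data.

## The model

Member GEMs are merged into one stoichiometric matrix **S**: each member
keeps a private compartment, extracellular species are shared, and all
reactions are put in irreversible form (0 ≤ *v*). Expression enters
through gene–protein–reaction (GPR) rules: each reaction's TPM values are
folded with AND → min (enzyme complexes) and OR → sum (isozymes) into a
score *f*(g̃), rescaled by the community-wide maximum *M* so that *f/M* ∈
[0, 1] multiplies the reaction's flux capacity, E-flux style.
Metatranscriptomes are sparse, so each expression-bounded reaction also
gets relaxation variables β⁺, β⁻ that can loosen or tighten the bound at a
price. Growth is predicted by a single linear program

```
max  Σ_j μ_j − λ Σ_{i,j} (β⁺_ij + β⁻_ij)
s.t. S·v = 0
     0 ≤ v_ij ≤ v_max,ij · (f_ij/M + β⁺_ij − β⁻_ij)   (reactions with GPR)
     0 ≤ v_ij ≤ v_max,ij
     0 ≤ f_ij/M + β⁺_ij − β⁻_ij ≤ 1
     0 ≤ β⁺, β⁻ ≤ 1000
```

where μ_j is member *j*'s biomass flux. The one free parameter λ trades
growth maximisation against relaxation of the expression bounds. It is
chosen automatically: the value function z\*(λ) is convex, piecewise
linear and non-increasing, and λ is taken at the inflection (knee) of the
normalised curve; with relative abundances available, k-fold
cross-validation against held-out Spearman correlation is offered instead.
Downstream analyses re-solve the LP with the optimum pinned: growth-rate
variability ranges (how determined each μ_j is), minimum flux sums
Φ_m = ½ Σ_i |S_mi| v_i per metabolite (essential imports are those with
Φ_min > 10⁻⁵), key reactions (common reactions whose fluxes track member
abundances, Spearman ρ > 0.7 and BH-adjusted p < 0.05), and community-wide
knockouts.

## Worked example

```sh
python examples/01_growth_prediction.py
```

builds a deterministic 4-member cross-feeding community whose designed
activities are 1 : 3 : 9 : 27, generates a sparse noisy expression sample,
auto-selects λ and prints:

```
lambda selected at the objective-curve knee: 10
community objective z* = 14.9194 (sum mu = 15.0882, sum beta = 0.0169)
member   activity  mu [1/h]            mu range  rel var
m1              1    0.3732 [  0.3732,   0.3782]  0.01315
m2              3    1.2704 [  1.2703,   1.2778]  0.00584
m3              9    3.4447 [  3.4447,   3.4454]  0.00021
m4             27   10.0000 [ 10.0000,  10.0000]  0.00000
```

The predicted growth rates rank the members exactly by their designed
activities (Spearman ρ = 1), and the variability ranges show the
predictions are tightly determined at the optimum. The other examples
cover λ selection with and without abundance data (`02`), minimum
flux-sum analysis and time-dependence classification (`03`), and key
reactions plus knockouts (`04`).

A thin CLI mirrors the library for shell pipelines:

```sh
imic make-fixture --seed 3 --n-samples 2 -o fixture/
imic build fixture/ -o bundle/
imic run bundle/ fixture/expression.tsv --lambda auto-sens -o out/
imic fluxsum bundle/ fixture/expression.tsv --lambda-value 12 -o fluxsum.tsv
```

Inputs are SBML Level 3 (fbc) member models and long-format TSV tables;
outputs are TSV tables plus a JSON run manifest.

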