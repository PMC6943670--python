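# Methods

This note records the models implemented in `fieldqsar`, the conventions
and numerical choices behind them, and what the bundled data and synthetic
experiments can and cannot establish.

## Data model and units

Activities are IC50 values in µM, modelled as pIC50 = −log₁₀(IC50·10⁻⁶).
The unit convention is fixed by the bundled table itself (0.121 µM ↔ 6.917).
A train/test partition is considered legal when the test-set pIC50 range is
contained in the training range (external prediction should interpolate,
not extrapolate) and the test fraction is 20–25 % of the series; the
bundled 41-compound set uses 32 training and 9 test compounds (22 %).

Two defects of the bundled reference table are carried as printed and
flagged at run time rather than silently corrected:

* **Compound 33**: the printed IC50 (1.93 µM) corresponds to pIC50 5.714,
  but the printed pIC50 is 5.888 (≡ 1.294 µM), and the printed residual
  columns are consistent with 5.888. The pIC50 is therefore treated as
  authoritative and the IC50 flagged as a misprint
  (`datasets.KNOWN_IC50_MISPRINTS`).
* **CoMSIA external-validation row**: evaluating the validation equations
  directly on the printed CoMSIA test-set predictions gives R² ≈ 0.904,
  k ≈ 0.991, rm² ≈ 0.868 — internally consistent, but different from the
  published row (R² 0.861, k 0.983, rm² 0.804). The published CoMFA row
  *is* exactly recoverable from the same table (to the ±0.005 that
  3-decimal predictions allow), so the implementation is checked against
  CoMFA and reports the CoMSIA difference as a documented discrepancy.
  r²pred is reproducible for both models (0.856 / 0.899).

## Alignment

Conformers are superposed on a shared scaffold by the Kabsch SVD
construction with a reflection guard (the sign-corrected determinant keeps
the rotation proper even for near-mirror point sets). All scaffold atoms
are weighted equally, non-scaffold atoms do not influence the fit, and the
atom correspondence is supplied explicitly (matched skeleton index lists or
a two-column map) — no maximum-common-substructure search, so the step is
deterministic and testable. Degenerate anchor sets (fewer than three
pairs, collinear or coincident points) are rejected because they leave a
rotation axis undetermined.

## Field computation

Lattice: axis-aligned cubic grid, spacing 2.0 Å, extended 4.0 Å beyond the
union bounding box of the input conformers, origin snapped down to a
multiple of the spacing, closed bounds (an atom exactly on a node is
inside).

CoMFA probe: sp³ carbon, r_vdw = 1.52 Å, charge +1 e, Lennard-Jones well
depth 0.107 kcal/mol. Atomic well depths default to 0.107 kcal/mol and are
combined geometrically; contact radii are additive (R = rᵢ + r_probe).
With the 6-12 form `ε[(R/r)¹² − 2(R/r)⁶]` the minimum is exactly −ε at
r = R. Energies are truncated at ±30 kcal/mol; a node inside (or on) an
atom takes the +30 clamp. Electrostatics use 332.0636 kcal·Å·mol⁻¹·e⁻² and
the distance-dependent dielectric ε(r) = r by default (a constant
dielectric is selectable). At sterically buried nodes (steric value at the
clamp) the electrostatic entry is replaced at assembly time by the mean of
the unburied training compounds in that column, so the arbitrary clamp
value never enters the regression.

CoMSIA similarity indices use α = 0.3 Å⁻² and no cutoff. Probe weights are
+1 for every property. Atomic weights are an explicit parameterisation
choice: steric — (r_vdw/r_C)³ (cube of the radius, carbon-normalised);
electrostatic — the partial charge; hydrophobic — Crippen atom-based logP
increments; donor/acceptor — {0,1} flags from element/valence rules (O–H
and N–H donors; O or N with an available lone pair acceptors).

Descriptor assembly flattens the per-compound fields with the lattice z
index fastest, then y, then x, then field kind. Columns whose standard
deviation across the training compounds falls below a minimum-sigma
threshold are masked: default 2.0 kcal/mol for CoMFA energy fields;
similarity fields are O(1), so similarity-only assemblies (including the
synthetic experiments) use 0.02 on the same relative footing. Optional
block scaling divides each field-kind block by its RMS column standard
deviation so that every kind enters with equal total variance (the
CoMFA-STD convention); no per-column autoscaling is ever applied.

## PLS modelling

`FieldPLS` / `FieldPLSResults` follow the model/results idiom. The latent
decomposition is NIPALS (scikit-learn `PLSRegression`, `scale=False`): X
and y are mean-centred on the training data and never variance-scaled.
Conventions:

* q² — leave-one-out, `1 − PRESS_LOO/Σ(y−ȳ)²` with ȳ the full training
  mean; each compound is predicted by a model refit without it (verified
  in the tests against an explicit refit oracle).
* ONC — the component count (1..max, default max 10, capped at the centred
  design rank and at n−2) maximising q²; exact ties go to the smaller
  count.
* r² = 1 − RSS/TSS on the training data (0 by convention for a constant
  response); SEE = √(RSS/(n−c−1)); F = (r²/c)/((1−r²)/(n−c−1)).
* Field contributions — the per-kind share of Σⱼ|βⱼ|·σⱼ over retained
  columns, normalised to 1.

StDev\*Coeff contours: each retained column scores σ(column)·β. Within a
field kind the columns are ranked by signed value and placed on a
cumulative |σβ| contribution scale from the most disfavouring to the most
favouring column. Columns above the 80 % contribution level with positive
values form the favoured set; columns below the 20 % level with negative
values form the disfavoured set. The two sets are disjoint whenever the
disfavoured level is below the favoured one; an all-zero coefficient field
yields empty sets with a warning.

## External validation

On test-set pairs (Y_obs, Y_pred): R² is the squared Pearson correlation;
k = ΣY_obs·Y_pred/ΣY_pred² and k′ = ΣY_obs·Y_pred/ΣY_obs² are the
least-squares through-origin slopes; R₀² = 1 − Σ(Y_obs − k·Y_pred)²/
Σ(Y_obs − Ȳ_obs)² and R′₀² analogously with k′ and roles swapped.
rm² is computed as R²(1 − √(R² − R₀²)) — the square-root form; the
radical-free rendering sometimes seen in print does not reproduce the
reference CoMFA value (0.799) while this form does. Since k is the
least-squares through-origin slope, R₀² ≤ R² holds for any non-degenerate
input; a negative radicand can only arise as floating-point dust and is
clamped at 10⁻¹², with anything beyond reported as undefined plus a
diagnostic. Threshold battery: R² > 0.6; (R²−R₀²)/R² < 0.1 or
(R²−R′₀²)/R² < 0.1 (operationalising "R₀² close to R²"); 0.85 < k < 1.15
or 0.85 < k′ < 1.15; |R₀² − R′₀²| < 0.3; rm² > 0.5.

Y-randomization permutes the activity vector with a dedicated seeded
generator (default 10 iterations), refits, and records (q², r²) per
shuffle next to the original statistics; per-iteration fit failures (e.g.
a degenerate shuffle) are recorded, not fatal.

## MM/GBSA bookkeeping

The package does not run MD or GB solvation; it audits reported
components: ΔE_gas = ΔE_vdw + ΔE_ele, ΔG_sol = ΔG_GB + ΔG_SA, ΔG_bind =
ΔE_gas + ΔG_sol − TΔS with TΔS taken as zero when absent (the usual
omission for congeneric ranking). When per-species totals are supplied the
thermodynamic-cycle identity is enforced to 10⁻³ kcal/mol. Rank agreement
orders complexes by ascending ΔG_bind and descending pIC50 (ties broken by
complex id) and reports exact concordance plus Spearman ρ. All four
bundled complexes satisfy the sum identities to 10⁻³ kcal/mol and rank
exactly as their activities.

## Synthetic data: what it emulates, and what it does not

The generator builds compound sets with the statistical structure the
analysis assumes: a rigid 8-atom chiral skeleton shared by all compounds
(the alignment anchor), one decoration atom near each of k planted spatial
regions whose per-compound cubed-radius steric weight varies the local
Gaussian field summary, further decoration atoms at random positions with
charges in [−0.5, 0.5] e and radii in [1.2, 1.9] Å (field variation
carrying no signal), and random rigid poses (up to 180°, 5 Å) for every
compound but the first. Activity = intercept + Σ_r w_r·s_r + N(0, σ) where
s_r is exactly the (negated) Gaussian similarity summary at region r, so
PLS-on-fields is the correct model class and planted-weight recovery is a
meaningful end-to-end test. Defaults: 40 compounds, σ = 0.1 pIC50 units,
weights |w| ∈ [0.6, 1.4] with random signs, regions 2.5–4.5 Å from the
skeleton centroid and ≥3.5 Å apart.

Recovered weights are estimated by a probe construction: the fitted
model's predicted activity change from adding one unit-weight decoration
atom's Gaussian footprint at each planted centre. This deconvolves the
smearing of PLS coefficients across correlated neighbouring columns, which
depresses a naive coefficient-map correlation (~0.8) even when the model
ranks the regions perfectly.

What the synthetic suite does **not** emulate: real chemistry (valence,
conformational flexibility, tautomers), correlated substituent patterns,
experimental activity error structure, or alignment ambiguity beyond rigid
poses. Passing these tests therefore demonstrates that the pipeline's
machinery is correct under its own model assumptions — not that any
particular real-world series is well described by it.

## Problem sizes and determinism

The test suite and the acceptance script use 16–40 synthetic compounds on
~10³-node lattices, 10-iteration Y-randomization, and the 41-compound
bundled table; the full suite runs in well under a minute on one CPU. All
stochastic stages draw from explicit seeds (`numpy` Generators); the
pipeline writes a manifest of input hashes, parameters and outputs, and a
rerun with the same configuration is bit-identical for deterministic
stages.

## Known limitations

* The internal statistics of the original study's models (q², r², SEE, F,
  ONC, field contributions) depend on the commercial modelling stack's
  exact field implementation, column handling and scaling, plus 3D
  structures defined only in figures; they are not reproducible at desk
  scale and are deliberately not numeric targets. The machinery is instead
  pinned by exact oracles (LOO refit, brute-force field sums, Kabsch
  recovery) and planted-signal recovery.
* Scaffold correspondence must be supplied; there is no MCS search,
  flexible alignment or conformer generation.
* H-bond fields use point flags, not lone-pair/extension-point geometry;
  charges beyond input files are limited to Gasteiger.
* The printed-table defects noted above are flagged, not repaired.
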