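# Methods

This note records the scientific and numerical choices behind `gridqsar`:
what each stage computes, which parameters matter, what the synthetic data
emulate, and where the design was genuinely open.

## Molecules, charges and alignment

Structures enter as SMILES (embedded in 3D with ETKDG under a fixed seed,
then relaxed with MMFF94 for at most 500 iterations) or as SDF V2000 with
existing conformers. A single conformer per molecule is used throughout:
field-based QSAR on a congeneric series assumes one bioactive-like pose per
compound, fixed by the common-template alignment; conformational search is
deliberately out of scope.

Partial charges are Gasteiger–Marsili PEOE values (6 damped iterations by
default, geometric damping ½ⁿ), computed with explicit hydrogens; all atoms
including hydrogens contribute to the fields. PEOE charges are topological,
hence invariant to conformer geometry and atom ordering — both properties
are asserted by tests.

Alignment superposes each molecule's template-substructure atoms onto those
of a reference (by default the most active compound) with the Kabsch
least-squares rotation; when the template matches in several ways the
lowest-RMSD match is kept. Congener selection retains molecules whose
template RMSD is at most 1.0 Å by default; the cutoff is a free parameter
because what counts as "well aligned" depends on the flexibility of the
series.

## Field descriptors

A rectangular grid covers the aligned set's bounding box extended by a
5 Å margin at 2 Å spacing (roughly 10²–10³ points per field for drug-sized
ligands). At every point three probe energies are computed against an
sp³-carbon probe of charge +1 e:

- **Steric** — Lennard-Jones 6-12 with per-element well depths and radii
  (Tripos-style table in `fields.VDW_PARAMS`; combination rules:
  arithmetic radii, geometric well depths).
- **Electrostatic** — Coulomb with the 332.063 kcal·Å/(mol·e²) constant and
  a constant dielectric of 1.0.
- **Hydrophobic** — Crippen per-atom logP contributions damped by a
  Gaussian of width σ = 1.5 Å. The functional form is a design choice: the
  field needs to be local (an atom's hydrophobicity should not be felt
  10 Å away), smooth, and proportional to an accepted atomic hydrophobicity
  scale; a Gaussian-damped sum is the simplest function with those
  properties.

Steric and electrostatic values are truncated to ±30 kcal/mol so grid
points inside atoms remain finite; distances are floored at 10⁻⁶ Å.
Columns are named `S_i`/`E_i`/`H_i` by linear grid index (x slowest,
z fastest) and ordered steric, electrostatic, hydrophobic. Columns with
sample variance below 0.1 (kcal/mol)² are removed before modelling.

## Model building

**Splitting.** The external test set may be given explicitly (mirroring
manual selection) or chosen by `split_interpolative`, which picks test
compounds at interior activity quantiles so the test range lies strictly
inside the training range — the unicolumn-statistics requirement
(max(train) > max(test), min(test) > min(train)). A sphere-exclusion
splitter in descriptor space is provided as an alternative.

**Stepwise-forward selection.** Greedy forward addition scored by
leave-one-out q² of a full-rank linear fit (computed exactly via the PRESS
identity e_loo = e/(1−h)), stopping at `max_descriptors` (default 4) or
when no addition improves q²; exact ties keep the lower column index. A
replacement pass follows: every selected descriptor is tentatively swapped
against every remaining candidate and the best strictly improving swap is
applied until stable. The refinement matters on grid fields, whose columns
are strongly collinear — plain greedy selection can land on a proxy subset
that no single swap escapes only rarely, but measurably often at n ≈ 23.
`refine=False` restores plain greedy selection.

LOO q² was chosen as the selection criterion because cross-validated
performance is the quantity the final model is judged by; an F-to-enter
rule is the main alternative and would couple selection to a significance
threshold instead.

**PLS.** Partial least squares on mean-centered, *not* autoscaled,
descriptors: all columns share kcal/mol units, so column variance is
physically meaningful and autoscaling would up-weight near-invariant
points. The latent-component count is chosen to maximize LOO q² over
1..min(k, n−1) unless pinned. The fitted model is exported as an
equivalent linear equation on the original descriptor scale; with as many
components as descriptors PLS reproduces ordinary least squares, which the
tests assert against a normal-equations oracle. A constant activity vector
yields zero coefficients with the constant as intercept.

**Contributions.** Descriptor i's contribution is
100·bᵢ·rangeᵢ / Σⱼ|bⱼ·rangeⱼ| with the range taken over the training set;
signed by the coefficient, absolute values summing to 100. This
coefficient-times-range normalization is one of several possible
conventions; it was chosen because it measures each term's share of the
achievable spread in predicted activity.

## Validation

- **q² (LOO)** — each training compound is held out, the model refitted on
  the rest with the descriptor set frozen (coefficients only) and the same
  component count, and the held-out activity predicted;
  q² = 1 − Σ(y−ŷ)²/Σ(y−ȳ_train)². Freezing the selection during LOO
  matches common practice when a single reported descriptor set defines
  "the model"; a strict mode (`reselect_per_fold=True`) reruns selection in
  every fold.
- **pred_r²** — same formula on the test set, with the denominator summing
  test deviations *from the training mean*. This is deliberate: it makes
  pred_r² = 0 mean "no better than predicting the training mean", the
  natural null for an external prediction. Some tools use the test mean
  instead; that variant is not implemented.
- **Fit statistics** — r², standard error √(SSE/(n−k−1)) and
  F = (SSR/k)/(SSE/(n−k−1)); a perfect fit reports F = +∞.
- **Y-randomization** — training activities are permuted (seeded), the
  entire selection + fit is rerun per permutation, and the true statistic h
  is summarized as Z = (h−μ)/σ against the permutation distribution, with
  the Z-score convertible to a standard-normal curve area (100·Φ(Z)).
  Defaults: 100 permutations, seed 42. The per-permutation q² (and the
  actual-data q² used as h for that comparison) is computed in *nested*
  mode, reselecting descriptors inside every LOO fold. This is essential:
  the frozen-selection LOO q² is the very quantity selection maximized, so
  on permuted activities it measures selection bias (it stabilizes around
  0.4–0.5 at n ≈ 23 with dozens of candidate columns) rather than chance
  correlation. The nested estimate is selection-bias-free — on permuted
  activities it scatters around or below zero. It is also the expensive
  path: n_train selection reruns per permutation, so randomization on a
  full grid matrix is many times slower than on a reduced candidate pool.
  The report also includes the best random r²/q² and the empirical
  one-sided p-value (#random ≥ h + 1)/(n_perm + 1).

## Pharmacophore model

Features are perceived by rules: donors (N/O/S–H, direction along the mean
H vector), acceptors (carbonyl-type and ether O, pyridine-type and imine N,
non-amide tertiary amines; amide and quaternary N excluded), negative and
positive ionisable groups (SMARTS table `pharmacophore.FEATURE_SMARTS`,
editable), aromatic rings (centroid, normal from the ring plane's SVD), and
hydrophobes (connected groups of ≥ 2 aliphatic carbons with only C/H
neighbours, at their centroid).

Hypotheses are all k-site feature combinations (k = 5 by default, 3..7
allowed) keyed by sorted type letters plus intersite distances binned at
1.0 Å; the canonical key minimizes the binned-distance vector over
permutations of same-letter sites, so it is independent of enumeration
order. Keys recurring in at least ⌈0.9·n_actives⌉ actives become common
hypotheses, numbered `<letters>.<variant>` by decreasing match count.

Scoring against the active set: site score = mean of
max(0, 1 − RMSD/tolerance) with a 2.0 Å tolerance; vector score = mean
cosine between matched direction vectors (absolute value for ring normals,
whose sign is arbitrary); volume score = shared/union volume of hard-sphere
models (1.7 Å heavy-atom spheres, deterministic 0.4 Å lattice sampling)
against the source ligand; selectivity = −log₁₀ of the fraction of all
k-site combinations in the set sharing the hypothesis key (floored at
10⁻⁶). Survival is the exact weighted sum of these terms; the strain (ΔE)
and reference-activity terms default to weight 0 (single-conformer inputs
have no meaningful strain), and the reversed term W_rev^m is disabled by
default because its intended semantics are not well defined — it is kept
configurable rather than guessed. Ranking is by survival, then selectivity,
then id.

## Screening

A library molecule matches a hypothesis if a type-respecting injective
assignment of its features onto the hypothesis sites superposes within the
site tolerance; the minimizing assignment gives the align score (site
RMSD). Fitness = w₁(1 − align/tol) + w₂·vector + w₃·volume with default
weights (1, 1, 1) — a simple convention, stated in the report header, not a
reproduction of any proprietary fitness. Matched molecules are carried into
the training frame by the match transform, their model descriptors
evaluated on the training grid, and activities predicted with the QSAR
equation directly (no rescaling). Docking is out of scope: externally
computed scores are merged from CSV and can re-rank the report
(ascending, docking convention).

## Synthetic data: what it emulates and what it does not

`generate_congeneric_series` emulates the input of a real study: a
thiosemicarbazone-like scaffold substituted at ring positions with a pool
of common substituents, 28 compounds by default, activities in a realistic
potency window (intercept 6.5, planted spread 0.65 pIC50 units ≈ a 5.3–7.6
range, matching a typical congeneric inhibitor series; test-set size 5).

The activity is planted as a *linear function of actual computed grid
descriptors* plus Gaussian noise, so the generator exercises the identical
code path as real data while providing exact ground truth. Planted columns
are chosen to be identifiable: spatially isolated (smallest maximum
correlation with any other column), free of single-compound leverage
(within-column |z| ≤ 2.5), mutually weakly correlated (|r| < 0.3), and
above the 0.1 variance cutoff. Relative contributions follow a
hierarchical profile (1, 0.55, −0.3, 0.18) — echoing how real grid-QSAR
equations distribute contributions across a dominant site, smaller sites
and a negative site — and coefficients are rescaled so the planted
activity spread hits the target. Without the identifiability constraints a
signal planted on near-collinear grid columns is unrecoverable even at
zero noise, and the ground truth would be useless as a test oracle.

What the synthetic series does *not* emulate: measurement error structure
beyond i.i.d. Gaussian noise, activity cliffs, multiple binding modes,
conformational flexibility, tautomers/protonation states, or deviations
from linearity. Passing tests therefore demonstrate that the machinery is
correct and recovers planted truth under the stated conditions — not that
any real series satisfies those conditions.

`replant_activities` redraws only the activity noise on an existing series
(same structures and fields), which is how repeated-seed robustness checks
stay affordable.

## Numerical choices and degenerate inputs

- LOO shortcuts use the PRESS identity with a guard on 1−h < 10⁻¹⁰
  (a leave-one-out singularity reports q² = −∞ for that candidate).
- Grid/atom coincidences are floored at r = 10⁻⁶ Å and capped by the
  ±30 kcal/mol truncation.
- Ties in selection (exact q² equality) keep the lower column index; swap
  refinement requires strict improvement (> 10⁻⁹), so duplicated columns
  do not oscillate.
- Zero-variance activities: PLS returns zero coefficients; q² and r² raise
  (undefined denominator).
- Z-scores with zero permutation spread are reported as +∞ with a warning.
- All randomness (embedding, substituent sampling, noise, permutations,
  tie-breaks) flows from explicit integer seeds; reruns are byte-identical
  and the pipeline manifest hashes the numeric outputs to prove it.

## Problem sizes

Default test and validation runs use 28-compound series on ~1300-column
filtered matrices, 20×5 random PLS problems, 50-column selection pools and
100-permutation randomizations — sizes at which every check completes in
seconds to a couple of minutes on one CPU while remaining comfortably
non-trivial (n ≪ p selection, collinear fields, nested cross-validation).

## Known limitations

- Absolute field values depend on the LJ parameter table and charge model;
  models are comparable within one parameterization only.
- The grid is axis-aligned in the frame of the alignment reference;
  rotating the reference rotates the grid (fields are covariant, the
  descriptor *names* are not).
- Feature perception is rule-based and does not handle tautomers or pH.
- Hypothesis enumeration is combinatorial in the per-molecule feature
  count; it is intended for small active sets (tens of molecules, ≤ ~15
  features each).
- The survival weights are conventions; only the site/vector/volume
  components are grounded in geometry.
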