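# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `fabqsar`. It is the package's own account of its
science; every number quoted here is computed by the test suite or by
`scripts/acceptance.py`.

## Substructure annotation

Variable domains are numbered with an anchor-plus-gap-rule algorithm
rather than a profile alignment. The four conserved residues of the
IMGT unique numbering — Cys23, Trp41, Cys104, Phe/Trp118 — are located
by scanning windows around their expected offsets (Cys23 in sequence
positions 19–26; Trp41 at 6–19 residues past Cys23; Cys104 at 48–65
past Trp41; the J anchor by the `[FW]G.G` motif downstream of Cys104).
Framework stretches are then mapped onto their fixed IMGT position
ranges (FR1 1–26, FR2 39–55, FR3 66–104, FR4 118–128) and loop residues
(CDR1 27–38, CDR2 56–65, CDR3 105–117 with 111.x/112.x insertions) are
gapped middle-out, the standard IMGT loop rule.

Two simplifications follow from the anchor-scan design:

- FR1 is end-aligned so Cys always lands at position 23; when FR1 has
  fewer than 26 residues the gaps sit at the start of the domain (IMGT
  proper places them near position 10). Region boundaries — the only
  thing downstream descriptors consume — are unaffected.
- FR3 is assumed indel-free (all 39 positions occupied), so the CDR2
  length is the anchor-to-anchor stretch minus 39. This is exact for
  the packaged germline-like frameworks and for most IgG1-Kappa
  domains; sequences with FR3 indels will mis-split CDR2/FR3 and are a
  documented limitation.

Constant domains (IGHG1\*01 CH1, kappa CL) are annotated with a packaged
strand-boundary table: 7 ordered, non-overlapping ranges per domain
approximating the IMGT C-domain strand layout. Because every sample
shares the same constant alleles, a length check against the allele
template guards the table's validity.

Sequences containing ambiguity codes (B, Z, X) are rejected outright:
every packaged property table is defined only for the 20 canonical
residues.

## Sequence descriptors (Seq2D)

Per-region descriptors are sums of per-residue values, so they are
additive over residues and invariant to residue order within a region —
a deliberate, documented limitation of sequence-level descriptors for a
surface-driven property like HIC binding (two sequences with the same
composition but different surface placement get identical Seq2D rows).
Only the 14 variable-domain regions are emitted: constant-domain
sequences are identical across samples and would produce static
columns.

The amino-acid scales ship as packaged constants: the 5-component
extended Z-scale (Sandberg et al. 1998), the 5-component topological
T-scale (Tian et al. 2007) and the 3-component MS-WHIM scale (Zaliani &
Gancia 1999). The scalar per-residue registry ships Kyte–Doolittle
hydropathy plus three thermodynamic-style tables — side-chain
conformational entropy (`Gc`, Pickett–Sternberg), hydration potential
(`dGw`, Wolfenden) and an estimated first-shell water count (`W`,
MaxASA / 9.65 Å² per water). The registry is pluggable
(`fabqsar.tables.register_residue_table`), so users can substitute
tables exported from any external descriptor tool; numerical parity
with any particular tool's output is explicitly not a goal.

Pepstats-like properties use average residue masses plus one water for
MW; net charge is the Henderson–Hasselbalch sum with EMBOSS pKa
defaults (N-term 8.6, C-term 3.6, C 8.5, D 3.9, E 4.1, H 6.5, K 10.8,
R 12.5, Y 10.1); pI is solved by bisection on the net-charge function
to 1e-4 pH. Empty regions (possible when a CDR numbers to zero
residues) contribute zeros with a warning, keeping the matrix
rectangular.

## Structural descriptors (Hom3D / MD3D)

SASA is computed by the Shrake–Rupley algorithm with a deterministic
Fibonacci-lattice point set (default 960 points, probe 1.4 Å; element
radii C 1.70, N 1.55, O 1.52, S 1.80, H 1.20 Å, hydrogens included when
present). The lattice is expressed in a canonical frame built from the
structure's principal axes, with axis signs fixed by the third central
moment of the coordinate projections. Attaching the lattice to this
frame makes SASA exactly invariant under rigid motion of the input
(verified to 1e-6 relative) for geometries with non-degenerate
principal axes; for nearly symmetric point clouds the frame — and
therefore the ~0.1% lattice discretisation residual — can flip
orientation. Descriptor values at 960 points agree with 3840 points
within 1% on the test fixtures; an isolated atom reproduces the
closed-form sphere area 4π(r+probe)² within 1%, and a biotite SASA run
with identical radii serves as an independent cross-check in the test
suite.

Relative solvent accessibility divides per-residue SASA by the
theoretical Gly-X-Gly maximum (Tien et al. 2013) and is clamped to
[0, 1] with a warning on raw ratios above 1 (real and toy structures
occasionally exceed the theoretical maximum). Surface-property
descriptors weight RSA with Kyte–Doolittle hydropathy over the
non-polar group NPR = {A,G,I,L,M,F,P,W,V} and polar group
PLR = {R,N,D,C,Q,E,H,K,S,T,Y}; raw cumulative region SASA
(total/polar/non-polar) is emitted alongside because the weighted and
unweighted variants carry different information. All 28 regions
contribute (constant-domain structural descriptors vary with
conformation even though their sequences do not).

Descriptor generation uses one structure per sample (e.g. the final MD
frame); multi-frame averaging is deliberately out of the default path.

## Trajectory analytics

Superposition is the Kabsch SVD solution with a proper-rotation
correction; collinear selections are rejected. RMSF aligns frames to
their mean structure (two passes) with an optional separate alignment
selection — aligning on static atoms lets a programmed single-atom
oscillation of ±d be recovered exactly as RMSF = d. Essential-motion
analysis diagonalises the unweighted 3N coordinate covariance (1/N
normalisation) of superposed frames via SVD of the frame matrix; the
first mode's magnitude is the square root of the leading eigenvalue,
and the eigenvalue sum equals the total coordinate variance (trace
identity, asserted in tests). Mass weighting is not applied; this
matters only when comparing against mass-weighted covariance tools.

The SASA interval difference |mean(0–5 ns) − mean(5–50 ns)| uses a
5 ns split by default, separating the initial relaxation phase from
the stabilised remainder of a 50 ns trajectory. SASA time series may
subsample frames (`frame_stride`) to bound cost on long trajectories.

## Chemometrics

- **Autoscaling** (mean 0, sd 1 per column) is fitted on calibration
  samples only and reused for test samples; distances, V-WSP, PLS and
  SVM all operate on autoscaled data. Scaling-free splitting would make
  Kennard–Stone depend on descriptor units.
- **Kennard–Stone** starts from the two most distant samples and
  repeatedly adds the sample maximising its minimum Euclidean distance
  to the selected set; ties break to the lowest sample index, making
  the split fully deterministic (verified against a brute-force
  max–min oracle on small sets). The calibration fraction is 0.8;
  stratified mode applies the procedure per label group to retain the
  class ratio.
- **V-WSP** seeds with the descriptor most correlated to the first
  principal axis, discards everything correlated above the threshold
  (default |r| ≤ 0.95) with the last-retained descriptor, and recurses
  on the survivors; every retained pair ends below the threshold.
- **PLS** is NIPALS PLS1 (closed-form per component for a single
  response). Regression coefficients for every nested component count
  come from one fit via the R-weight recursion, which makes the
  CV-over-components selection inside the GA fitness a single fit per
  fold. At full rank the PLS predictor equals ordinary least squares
  (asserted against a normal-equations oracle).
- **GA-PLS**: binary chromosomes (gene = descriptor inclusion),
  population 64, ≤100 generations, per-gene mutation 0.005, double
  crossover, binary-tournament parents, elitism of the best
  chromosome, initial inclusion probability 0.30, convergence when
  ≥50% of the population shares the best fitness. Fitness is the
  5-fold CV RMSE of PLS with the latent-variable count (≤10) chosen by
  the same CV; fold assignment is fixed per run so fitnesses are
  comparable, and chromosome fitnesses are cached. The selection is
  repeated over 10 seeded runs; the consensus keeps descriptors present
  in ≥⌈50%⌉ of the runs' best chromosomes (threshold configurable).
  A `window_width` field is carried in the config for fidelity to the
  standard GA-PLS parameterisation but is a no-op at width 1.
- **SVM**: linear-kernel ε-SVR (scikit-learn's libsvm binding) over
  the 90-pair grid C ∈ {10⁻⁵…10⁴}, ε ∈ {10⁻³…10¹ at half-decade
  steps}, each pair scored by repeated random 5-fold × 20 CV RMSE
  (classification: C grid scored by CV MCC); the winner is refit on the
  calibration set. A libsvm iteration cap (default 20 000) bounds the
  pathological large-C/small-ε cells, which would otherwise take
  seconds per fit; capped cells produce poor CV scores and are never
  selected, and results remain deterministic.
- **Metrics**: R² = 1 − SS_res/SS_tot and is allowed to go negative —
  an overfit model predicting worse than the response mean on an
  external test set is a meaningful diagnostic. Multiclass MCC uses
  the generalised (Gorodkin) covariance formula, which reduces to the
  textbook binary MCC (both asserted against independent formula
  evaluations and scikit-learn).
- **Validation**: Y-randomisation permutes the calibration response
  (seeded), retrains with the already-selected descriptors and chosen
  hyperparameters, and averages CV R²/RMSE over repeats (default 50;
  the test suite and acceptance script use 10 repeats with 5 CV
  repeats as their problem size). The learning curve grows calibration
  subsets in Kennard–Stone selection order, reusing the full model's
  (C, ε) at every size, with 5-fold × 5 CV per size. The 95% prediction
  interval is the Student-t predictive form
  t(0.975, n−1) · sd(residuals) · √(1 + 1/n).
- **Exploration**: complete-linkage (farthest-neighbour) HCA on
  Euclidean distances via scipy; PCA by SVD of the centred matrix with
  orthonormal loadings and descending explained variances.

Leakage isolation is a workflow invariant: the variance-filter
threshold, V-WSP, GA-PLS and the grid search see calibration data only.
The test suite asserts this by corrupting test-set rows and checking
that every selection output is unchanged.

## Synthetic fixtures: what they emulate, and what they do not

The generators define the study conditions under which the workflow is
validated:

- **Fab sequences**: germline-like frameworks carrying the conserved
  anchors, randomised CDRs with H3 length 6–20, a fixed 3-residue L2,
  and H1/H2/L1/L3 in 5–12 — the length ranges typical of an IgG1-Kappa
  panel. CDR alphabets exclude C/W/F so random loops cannot spoof the
  anchor scan. Real repertoire features not emulated: framework
  mutations, FR3 indels, allelic variation.
- **Toy structures**: C-alpha traces with 2.0 Å pseudo-radii in
  extended/helix/shell/ellipsoid/globule geometries — geometrically
  valid, chemically naive. They exercise the SASA machinery, not
  protein energetics; RSA against the (real-protein) Tien maxima can
  exceed 1 and is clamped. Tests that need an exact RSA = 1 reference
  build their MaxASA table from the generating geometry itself.
- **Trajectories**: base coordinates plus isotropic Gaussian noise,
  with an optional linear or step drift of a leading atom block —
  enough to program RMSD plateaus (noise sd 1.2 Å gives the 2–5 Å
  plateau band typical of relaxed Fab simulations), monotone
  conformational transitions and two-level SASA series with a known
  step. No physical kinetics, solvent or force field.
- **Regression matrices**: standard-normal descriptors with a sparse
  linear signal (defaults n = 80, p = 50, 5 informative coefficients,
  noise sd 0.1), optional near-duplicate collinear columns (r ≈ 0.98),
  an optional class-correlated confounder block (3 species, strong
  between-class separation, no relation to the response) and an
  optional right-skewed response transform. Passing the planted-signal
  acceptance checks therefore demonstrates that the selection and
  modelling machinery recovers known structure under realistic noise —
  not that any particular real antibody panel is predictable.

## Numerical choices

- Fibonacci sphere lattice: deterministic; 960 points default, floor 92.
- pI bisection tolerance 1e-4 pH; NIPALS deflation tolerance 1e-12;
  PLS components capped at matrix rank with a warning.
- Kennard–Stone and V-WSP tie-breaks: lowest column/sample index.
- GA convergence tolerance: exact fitness equality within 1e-12.
- libsvm iteration cap 20 000 (configurable); SVR/SVC tolerance at
  scikit-learn defaults.
- Degenerate inputs: constant response → error; empty consensus → best
  single run's chromosome; empty CDRs → zero-width regions and zero
  descriptors; coincident atoms → symmetric SASA split.

## Known limitations

- The annotation algorithm targets IgG1-Kappa Fabs; lambda chains,
  other isotypes and heavily gapped frameworks are out of scope.
- Seq2D descriptors cannot represent residue order or surface
  placement; this is intrinsic to summed sequence descriptors.
- SASA absolute values depend on the radii set and probe; no attempt
  is made to match any specific external tool's absolute numbers.
- Trajectory PCA is unweighted; mass-weighted covariance tools will
  report different eigenvalues for heterogeneous atom masses.
- The pipeline consumes trajectories and structures; it never produces
  them (no homology modelling, no MD).
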