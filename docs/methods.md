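# Methods

## Scope and model

`femorph` implements a high-density 3D geometric-morphometrics workflow for
long-bone shape, organised around the analysis of archosauriform femora:
template-guided sliding-semilandmark registration, generalized Procrustes
superimposition, principal-component morphospace construction, phylogenetic
comparative statistics (multivariate K, PGLS, ancestral states), landmark-
derived angle and circumference metrics, and k-nearest-neighbour prediction of
locomotor mode (bipedal B vs quadrupedal Q). Because 3D scan archives cannot
ship with a software package, a synthetic-shape generator with known ground
truth stands in for digitized specimens; the published specimen table and the
input-vs-predicted locomotor-mode table are packaged as plain-text
transcriptions so their arithmetic is reproducible.

## Thin-plate splines and bending energy

The 3D interpolant uses the biharmonic kernel U(r) = r with affine side
conditions. With those side conditions enforced, the kernel quadratic form
w^T K w is negative semidefinite, so bending energy is defined as
−tr(W^T K W) ≥ 0, zero exactly for affine targets. The equivalent
bending-energy matrix B (the negated upper-left block of the inverse bordered
system) gives the energy of any target as a quadratic form y^T B y per
coordinate; B annihilates affine targets and is what the sliding step
minimizes. The linear system is solved exactly (no smoothing; a ridge
parameter exists, default 0) and rejected above condition number 1e12.

## Sliding semilandmarks

Registration follows the standard three-step protocol:

1. **Patch projection.** A TPS map fitted on anatomical + curve landmarks
   warps the template's surface semilandmarks onto each specimen; warped
   points are replaced by their exact nearest point on the specimen mesh.
2. **Template relaxation** (default 5 iterations). Per iteration, curve
   points may slide along their chain tangent (central differences, one-sided
   at endpoints) and surface points within their tangent plane (from the
   nearest mesh-face normal, or a local plane fit over the 8 nearest patch
   points when no mesh is available); the closed-form GLS step minimizes the
   bending energy of the template-to-specimen deformation; slid points are
   re-projected to their polyline/mesh every iteration so they never leave
   their geometry. Displacements are clamped at 10% of centroid size per
   iteration to prevent runaway sliding on coarse meshes. Anatomical
   landmarks never move.
3. **Consensus sliding** (default 2 iterations). The partial-Procrustes
   consensus is recomputed each iteration and every specimen relaxed one step
   against it. Bending energy is affine-invariant, so the unit-size consensus
   is a valid reference for raw-size specimens.

Whether curve points slide during step 2 is configurable (`slide_curves`,
default true). The two shaft delimitation rings are flagged `delimitation`
landmarks, slide like curves, and are stripped before all shape statistics.

## Superimposition and shape space

GPA is partial Procrustes: translate to the centroid, scale to unit centroid
size, and iteratively rotate (proper rotations only; left femora must be
mirrored first) to the evolving consensus until its RMS change is below
1e-10 (max 100 iterations). Centroid sizes are retained in millimetres.
PCA is computed on the raw vectorized residuals (covariance PCA, no tangent
projection by default — shape variation at this scale makes the difference
negligible, and a flag exposes the choice). Axis signs follow a deterministic
convention: axes whose scores correlate with log centroid size (|r| > 0.1)
point toward larger specimens, others toward their largest loading. All
min(n−1, 3k) axes are retained for the comparative statistics; plots and the
classifier use the leading pair.

`identify_mode_axis` formalises the analyst's step of picking the axis "linked
to locomotor mode": it returns the leading axis whose scores have the largest
absolute point-biserial correlation with the known B/Q labels. The pipeline's
default classification axis remains PC2, the configuration the published
protocol states.

## Comparative statistics

Branch lengths default to 1 (topology-only convention). The Brownian
covariance C has entries equal to shared root-to-MRCA path lengths.

* **K statistic (multivariate).** K = [Σ‖yᵢ−â‖² / tr((Y−1â)ᵀC⁻¹(Y−1â))] ÷
  [(tr C − n/(1ᵀC⁻¹1))/(n−1)] with â the GLS phylogenetic mean. K equals 1
  identically on star trees; significance comes from permuting tip rows
  (default 999 permutations; the observed case counts in numerator and
  denominator, so p ≥ 1/(n_perm+1)).
* **PGLS.** Data and design are whitened by the symmetric eigen-based
  C^(−1/2) (eigenvalues clipped at 1e-12); sums of squares are sequential
  (size, then mode, then size×mode); per-term r² = SS_term/SS_total;
  significance by residual randomization of the reduced model (RRPP). With
  C = I this reproduces OLS exactly. Indeterminate specimens enter the design
  with k-NN-estimated modes.
* **Continuous ancestral states.** Squared-change parsimony: internal values
  solve the sparse stationarity system of Σ_edges ‖x_parent−x_child‖²/length,
  which equals the Brownian-motion ML states.
* **Discrete ancestral states.** Minimal-change sets for the B/Q character
  are computed by a two-state min-change dynamic program (down- and up-pass),
  which reproduces the classic intersection/union two-pass on binary trees
  and remains exactly minimal on polytomies, where the naive union rule
  undercounts. Nodes whose optimal set contains both states are "ambiguous".
  Specimen-level statistics on a species-level tree attach conspecific
  femora as unit-length terminal polytomies (`expand_tree_to_specimens`);
  collapsing to species means is the alternative the user can choose.

## Angles, circumference, allometry

Angles between two landmark-pair axes are measured after projecting both
directions onto the plane orthogonal to the configuration's first principal
axis — the reproducible surrogate for on-screen protractor measurements in a
fixed view; folding to [0°, 90°] is the default and the 180° range is a flag.
The group comparison runs the published two-step procedure (F-test for equal
variances at 0.05, then pooled-variance Student or Welch t), with a flag to
force Welch, which is otherwise statistically preferable.

Minimum diaphyseal circumference sweeps cross-section planes orthogonal to
the shaft axis (default the mesh's first principal axis) across the central
60% of the bone at 100 stations; each station contributes the perimeter of
its longest closed intersection loop, and the minimum over stations is
reported with its position.

Allometry is assessed two ways: per-group OLS of axis scores on log centroid
size (with 95% slope CIs), and the multivariate allometric regression of the
full vectorized shape on centered log centroid size. The latter's slope
magnitude is the norm of the coefficient vector; its bootstrap CI resamples
specimens and projects each resampled coefficient vector onto the full-sample
direction — a percentile CI of the raw norm is biased upward under
resampling, while the projection CI attains nominal coverage in simulation.

## Classifier

Distances along one PCA axis are absolute score differences, which is the
full-shape Procrustes distance restricted to that axis under the orthonormal
basis; a full-shape distance mode exists for comparison. k defaults to 5 and
must be odd (no vote ties with two classes); distance ties break
lexicographically on specimen id. Evaluation reports both resubstitution-free
leave-one-out over known-mode specimens and the agreement convention in which
only contradictions (known input ≠ prediction) count against the whole
sample; both denominators (knowns, all rows) are always reported.

## Synthetic generator

Tip shapes are composed in vectorized shape space as template + allometric
term β(log CS − mean)·v_size + group offset δ·1[B]·v_mode + Brownian values
on extra modes (rate σ_phy on the tree) + iid coordinate noise σ_e, then
scaled to centroid size and randomly rotated/translated. Mode vectors are
random orthonormal directions constructed orthogonal to the template's
translation, rotation and scale directions, so every effect is a pure shape
deformation that survives superimposition, and effects compose additively and
recoverably. Defaults (chosen once as the study conditions): 36 taxa; log
sizes uniform on [log 40, log 800] mm, spanning the study sample's femoral
lengths; β = 0.05 per unit log size, δ = 0.06, σ_phy = 0.008, σ_e = 0.003,
σ_d = 0.002 (all in unit-centroid-size shape units) — these place the
allometric axis above the group axis in variance, with Brownian modes and
noise below both, mirroring the morphospace structure the analysis assumes.
The default template is a "bent tube" (two swollen ellipsoidal ends, bowed
shaft) on a 5/20/30 scheme for speed; the full 20/176/229 scheme is available.
The generator emulates the covariance structure only: it does not produce
realistic femoral anatomy, taphonomic distortion, correlated digitization
error, or unbalanced group sizes, so passing recovery tests demonstrates the
estimators work under the model's assumptions, not that real bones satisfy
them.

## Problem sizes and numerical choices

Test and acceptance runs use the small scheme with 36-80 taxa, 99-199
permutations/bootstrap draws, and 100-400 simulation replicates — sizes at
which every calibration (K mean under BM, permutation type-I error, PGLS
power, CI coverage, classifier accuracy) is measured stably in seconds.
Convergence tolerances: GPA 1e-10 on consensus RMS change; TPS condition
limit 1e12; PCA sign convention as above; permutation p-values include the
observed case. All stochastic routines take explicit seeds and results carry
them.

## Known limitations

Missing landmarks are a hard error (the analysis assumes complete femora).
The anatomical placement of the published 425-landmark scheme is not
reproduced (only its counts, roles and chain structure); angle landmark pairs
must be supplied by the user for real data. Mesh nearest-point queries use an
exact but O(points × faces) search, adequate for package-scale meshes but not
for million-face scans. The species-vs-specimen level of the comparative
analyses is a user choice, as is the success-rate denominator; defaults
follow the conventions stated above.
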