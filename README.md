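# femorph

High-density 3D geometric morphometrics of archosauriform femora: sliding-
semilandmark registration, Procrustes shape space, phylogenetic comparative
statistics, and k-nearest-neighbour locomotor-mode prediction.

## The problem

Early archosauriforms (the bird-line Avemetatarsalia, the crocodile-line
Pseudosuchia, and their closest relatives) span an exceptional range of
locomotor habits — obligate bipeds, quadrupeds, and everything between — and
of body sizes. The femur records both signals: head rotation, shaft
curvature, fourth-trochanter shape and the crista tibiofibularis–lateral
condyle angle track locomotor mode, while epiphyseal robusticity tracks size.
`femorph` provides the full quantitative toolchain for asking how femoral
shape covaries with locomotor mode, size and phylogeny from 3D landmark data:

1. **Registration.** A 425-landmark scheme (20 anatomical, 176 curve
   semilandmarks, 229 surface semilandmarks; two delimitation rings bound the
   shaft) is transferred from a template to every specimen by thin-plate-
   spline (TPS) patch projection, then relaxed by sliding semilandmarks to
   minimize TPS bending energy — five iterations against the template, two
   against the Procrustes consensus.
2. **Shape space.** Partial generalized Procrustes analysis (translate,
   scale to unit centroid size CS, rotate) followed by PCA of the residuals.
   Theoretical shapes at axis extremes and landmark displacement fields
   visualise what each axis means.
3. **Statistics.** Multivariate phylogenetic signal
   K_mult (expectation 1 under Brownian motion; >1 = variation between
   clades) with permutation tests; PGLS of shape on log CS and locomotor
   mode with residual randomization; squared-change-parsimony
   phylomorphospaces; minimal-change (Fitch/Hartigan) ancestral locomotor
   states; angle metrics; minimum diaphyseal circumference (MDC) from mesh
   cross-sections; allometric regressions.
4. **Prediction.** k-NN (k = 5) along the locomotor axis of the morphospace
   (PC2 in the femoral analysis): each indeterminate specimen receives the
   majority vote of its five nearest known-mode neighbours; known specimens
   are scored by leave-one-out.

Because 3D scan archives cannot ship with a package, a synthetic-shape
generator with known ground truth (allometric mode, group-offset mode,
Brownian covariance on a tree, digitization noise) stands in for scan data,
and the published specimen and prediction tables are packaged as plain-text
transcriptions.

## Worked example

```python
import numpy as np
from femorph import (default_truth, simulate_sample, gpa_align, fit_pca,
                     loo_evaluate, kmult_test)

truth = default_truth(n_tips=36, seed=7)          # study-condition sample
configs, records = simulate_sample(truth)         # 36 landmark configurations
aligned = gpa_align(configs)                      # partial Procrustes
space = fit_pca(aligned)                          # morphospace
print(f"PC1 variance: {100*space.variance_fractions[0]:.1f}%")
print(f"PC2 variance: {100*space.variance_fractions[1]:.1f}%")

scores = {sid: float(space.scores[i, 1]) for i, sid in enumerate(space.specimen_ids)}
known = {r.specimen_id: r.input_mode for r in records}
loo = loo_evaluate(scores, known, k=5)
print(f"LOO success over knowns: {100*loo['success_rate_known']:.1f}%")

res = kmult_test(aligned.residuals(), truth.tree, aligned.specimen_ids,
                 n_perm=999, seed=7)
print(f"K_mult = {res.k_mult:.2f} (p = {res.p_value:.3f})")
```

prints

```
PC1 variance: 41.4%
PC2 variance: 22.0%
LOO success over knowns: 100.0%
K_mult = 0.26 (p = 0.296)
```

PC1 is the allometric (size) axis and PC2 the locomotor axis, so the k-NN
along PC2 separates the bipedal and quadrupedal groups perfectly at these
noise levels. The low, non-significant K_mult says shape variation in this
draw is structured within rather than between clades — the generator's
Brownian rate is small relative to the group and size effects.

The same stages are scriptable from the shell:

```sh
femorph simulate --n-tips 36 --seed 7 --out run/
femorph pca --landmarks run/landmarks --out run/scores.csv
femorph classify --scores run/scores.csv --metadata run/metadata.csv \
        --axis PC2 --k 5 --out run/predictions.csv
femorph physignal --scores run/scores.csv --tree run/tree.nwk \
        --n-perm 999 --seed 7 --out run/kmult.json
```

Mode-table agreement uses the packaged transcription:

```python
from femorph import load_packaged_table2, evaluate_against_inputs
report = evaluate_against_inputs(load_packaged_table2())
print(report["pct_correct_all"])       # 93.05 -> 93.1% correct over 72 femora
print(report["pct_indeterminate"])     # 22.2% indeterminate inputs
```

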