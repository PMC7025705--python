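# florasym

Geometric morphometrics of biradial (four-fold) flower symmetry.

Many actinomorphic flowers — the tetrameric corolla of the common spindle
tree (*Euonymus europaeus*) is the motivating case — are symmetric under two
perpendicular reflections, forming the Klein four-group. `florasym`
implements the landmark-based analysis that separates corolla shape
variation into three orthogonal parts:

* **symmetric** variation — coordinated shape change of all four petals
  (differences *among* flowers),
* **lateral asymmetry** — contrasts between adjacent petal pairs
  (two merged patterns, since the two axes cannot be told apart),
* **transversal asymmetry** — contrasts between opposite petal pairs,

and tests whether sexually differentiated flowers (e.g. female vs
hermaphrodite flowers of a gynodioecious species) differ in size, mean
shape, and the amount of within-flower asymmetry.

## The method

Each corolla is digitised as 4 petals × 50 outline points (200 landmarks,
the two basal corner points of each petal fixed, the 48 interior points
treated as sliding semilandmarks). The pipeline:

1. **Symmetry-group expansion.** Every configuration is joined by its three
   reflected and re-labelled copies (reflection across each nominal axis and
   across both), giving a symmetry-closed dataset — for a study of
   169 flowers × 2 photographs × 2 digitisations, 676 × 4 = 2,704
   configurations.
2. **Generalized Procrustes analysis** (centring, unit centroid-size
   scaling, rotation-only fitting) with **bending-energy sliding**: interior
   outline points slide along their tangents to minimise the thin-plate-spline
   bending energy of the deformation from the grand consensus. Centroid size
   CS = √Σ‖xᵢ − x̄‖² is recorded from the raw digitised coordinates.
3. **Subspace decomposition.** PCA of the aligned expanded data; each
   component is classified by the characters s_V = v·T_V(v), s_H = v·T_H(v)
   of the two relabelling reflections — (+,+) symmetric, (−,−) transversal,
   mixed signs lateral — using exact group-averaging projectors so the
   labels are pure even for close eigenvalues. Subspace variance fractions
   and per-flower asymmetry scores (the Euclidean distance from the
   symmetric consensus within each asymmetric subspace) follow.
4. **Inference.** Nested permutation ANOVA (sex / tree / flower / imaging /
   digitisation) for centroid size and symmetrised shape; Goodall's-F
   multivariate regression of per-flower symmetrised shape on sex; the
   Levene-analogue test for homogeneity of multivariate dispersions in each
   subspace (distances to group centroids, permutation p-values, flower-level
   exchangeable units); 2-D non-metric multidimensional scaling with Kruskal
   stress-1 for visualisation.

A **synthetic corolla generator** emulates the full study design — nested
sampling, coordinated symmetric variation, the two lateral and one
transversal contrast patterns, petal-level noise, photograph- and
digitisation-level measurement error, a ~15.5 % smaller female corolla and
elevated female asymmetry — so every stage is testable without the original
images.

## Worked example

Simulate a small population (2 trees per sex, 4 flowers per tree, 2
photographs × 2 digitisations) and analyse it:

```bash
cat > demo.yaml <<EOF
n_trees_per_sex: 2
flowers_per_tree: 4
n_imaging: 2
n_digitisation: 2
EOF
florasym simulate --config demo.yaml --seed 7 --out demo_data
florasym analyze --tps demo_data/landmarks.tps --meta demo_data/metadata.csv \
    --out demo_out --seed 7 --n-perm-anova 199 --n-perm-disp 999
```

The analysis report (abridged) prints:

```
"n_configurations_raw": 64,
"n_configurations_expanded": 256,
"anova_size_df": [1, 2, 12, 16, 32, 63],
"female_cs_reduction_pct": 15.494120691365843,
"variance_fractions": {
  "symmetric": 55.08252708198578,
  "lateral": 32.15652838767787,
  "transversal": 12.760944530336367
},
```

Reading this: the 64 digitised corollas were expanded to 256 symmetry
copies; the nested size ANOVA has the degrees of freedom implied by the
design (1 for sex, 2 for trees within sexes, 12 for flowers within trees, 16
for repeat photographs, 32 for repeat digitisations); female corollas came
out 15.5 % smaller than hermaphrodite ones (the generator's default size
dimorphism); and at this small sample 55 % of shape variance is symmetric,
32 % lateral and 13 % transversal. `demo_out/` holds the ANOVA tables,
the eigenvalue table with subspace labels, per-flower asymmetry scores,
dispersion-test JSONs and NMDS coordinates, plus the exact config for a
bit-for-bit re-run.

The same `florasym analyze` command works on real TPS landmark files (with a
metadata CSV: `object_id, flower, tree, sex, imaging, digitisation`);
`florasym validate-labeling` checks a file's point ordering against the
canonical petal layout, and `florasym benchmark` estimates the dispersion
test's type-I error or power by simulation.

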