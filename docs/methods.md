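# Methods

This note documents the models, numerical choices and known limitations of
`florasym`. It is written for users who want to understand what the pipeline
computes and what passing tests do and do not establish.

## Landmark model and symmetry group

A corolla is an ordered configuration of 4 petal blocks × 50 outline points.
Petals are indexed P1–P4 counterclockwise starting in the (+x, +y) quadrant,
with points within each petal ordered counterclockwise from one basal corner
to the other; the two nominal symmetry axes are the coordinate axes in this
canonical frame. The first and last point of each petal block are fixed
anatomical landmarks (basal corners); the 48 interior points are
semilandmarks.

The object's symmetry group is the Klein four-group {identity, reflectV,
reflectH, reflectHV}. A reflection must be accompanied by landmark
re-labelling to preserve homology: reflectV (negate x) swaps P1↔P2 and
P3↔P4 and reverses within-petal order; reflectH (negate y) swaps P1↔P4 and
P2↔P3 and reverses within-petal order; reflectHV (the half-turn) swaps
P1↔P3 and P2↔P4 with order preserved. Reflections act in each
configuration's own centred coordinates; no symmetry-axis estimation is ever
performed, because the subsequent GPA aligns all copies regardless of the
frame in which they were reflected.

**Labeling ambiguity.** The sixteen block relabelings of a file (petal roll ×
petal direction × within-petal reversal) all normalise the Klein group, so
every downstream quantity — the expanded dataset, the GPA consensus, the PCA
subspaces and their variance fractions — is mathematically invariant under
them (the two lateral characters may swap, and they are merged anyway). This
mirrors the biological fact that the two axes of a truly actinomorphic
tetramer cannot be distinguished. `validate_labeling` therefore reports these
candidates as score-equivalent and tie-breaks to the identity; what it *can*
detect, and checks explicitly, is a within-petal cyclic start-point shift,
which breaks fixed-landmark homology and is a real digitisation error mode.

## Superimposition

Full-Procrustes GPA: configurations are centred, scaled to unit centroid
size, and iteratively rotated onto the evolving consensus until the
consensus RMS change drops below `tol` (default 1e-6, `max_iter` 50).
Rotation fitting is closed-form in 2-D; **reflections are never allowed**,
because the reflected copies are explicit data points and allowing
reflection in the fit would collapse the asymmetric subspaces onto the
symmetric one. Centroid size is recorded from the raw digitised coordinates
before any scaling, since size is analysed in original units.

**Sliding semilandmarks.** After each converged superimposition pass, every
semilandmark may slide along its tangent — the chord between its two
within-petal outline neighbours — by the amount minimising the thin-plate-
spline bending energy of the deformation from the grand consensus to the
configuration (kernel U(r) = r²·log r; the bending-energy matrix is the
upper-left block of the inverted TPS system, whose null space is the affine
maps). With all sliders moving jointly this is a single positive-definite
linear solve per configuration (192 × 192 in the study layout); because zero
displacement is always admissible, bending energy cannot increase. Points
are projected onto the tangent *line*, not back onto a curve. Five outer
GPA–slide rounds are run by default, re-centring and re-scaling after each
slide; the sliding target is the grand consensus of the entire expanded
dataset. Singular sliding systems (theoretically possible for degenerate
geometry) fall back to a ridge-regularised solve with a warning.

## Subspace decomposition

After GPA, the aligned dataset is rotated so that the consensus symmetry
axes coincide with the coordinate axes (the half-angle of the rotation
fitting the reflected consensus onto itself; the 90°/sign branch is chosen
by symmetry residual). In that frame the relabelling reflections are exact
linear involutions T_V, T_H on the 400-dimensional coordinate space.

PCA uses the covariance of the aligned coordinates about the grand mean
(divisor n − 1). Because the covariance of a symmetry-closed sample commutes
with the group action, shape space splits into four orthogonal character
subspaces; classification projects the centred data onto each subspace with
the exact group-averaging projectors P = (I ± T_V)(I ± T_H)/4 and re-solves
the PCA within each, so every component is pure by construction even where
the global spectrum is (near-)degenerate — the situation in which raw PCA
axes mix characters. Characters s_V = v·T_V(v), s_H = v·T_H(v) are
recomputed on the final eigenvectors as verification (threshold 0.9; no
tangent-space projection is applied, since the aligned data are centred and
rotation-fitted and the unit-size sphere's radial direction is itself
symmetric-character). An independent classifier from the score geometry of
the four copies (equal scores ⇒ symmetric; mirror patterns (1, s_V, s_H,
s_V·s_H) ⇒ asymmetric) is kept as a cross-check oracle.

Variance fractions are sums of eigenvalues per label over the total, ×100.
Asymmetry scores are, per configuration, the Euclidean norm of its score
vector within each asymmetric subspace — its distance from the ideally
symmetric consensus in that subspace; a per-PC absolute-value sum is
available behind `score_kind="abs_sum"`. The four symmetry copies of one
configuration share the same subspace norm (asserted in tests), so the
per-flower mode simply averages over copies and imaging/digitisation
replicates.

## Inference

**Nested permutation ANOVA** (type-I, sequential): SS at each level of
sex / tree(sex) / flower(tree) / imaging / digitisation is the summed
squared deviation of that level's group means from their parent means,
summed over coordinates for shape; the decomposition is exact. Each F uses
the immediately nested effect's MS as denominator. p-values come from
restricted permutations of the exchangeable units of that nested level:
whole trees across sexes; whole flowers across trees within their sex;
photographs across flowers within their tree; digitisation rows across
photographs within their flower (999 permutations by default; the observed
statistic is included in the reference set). A free row-permutation scheme
is available behind `scheme="rows"`. The shape ANOVA consumes the
symmetrised configurations — the average of each object's four aligned
copies.

**Goodall's F regression**: for the binary sex contrast,
F = (SS_between/1)/(SS_within/(n − 2)) on Procrustes coordinates, identical
to the sex row of a two-level Procrustes ANOVA (asserted to 1e-8). The
pipeline feeds one symmetrised mean shape per *flower* (n = 169 in the study
design): the printed effect size (percent variance) and F are then mutually
consistent, and flowers are the independent units for label permutation.

**Dispersion test** (Levene analogue): each point's Euclidean distance to
its own group centroid in the given subspace's PC scores; the statistic is
the one-way ANOVA F on those distances; p by permuting group assignments of
the exchangeable unit — `flower` by default (the four mirror copies and the
replicate digitisations of one flower travel together; copies of one flower
are not exchangeable between sexes), with `configuration` available to mimic
row-level permutation. The 95 % CI of the difference in mean distances is
the pooled two-sample t interval. Monte-Carlo calibration at α = 0.05 puts
the null rejection rate in [0.03, 0.07] and power at ~100 % when one group's
scores are doubled at n = 80/80 (`florasym benchmark`).

**NMDS**: non-metric SMACOF (scikit-learn) from a classical-scaling start
plus random starts, best Kruskal stress-1 reported; the chunked optimisation
records a non-increasing stress trajectory and is deterministic given a
seed. The pipeline subsamples to 350 points per subspace for the ordination.

## Synthetic data generator

The generator emulates the study's sampling design: 8 + 8 trees with the
per-tree flower counts of the original sample (169 flowers), each flower
photographed `n_imaging = 2` times and each photograph digitised
`n_digitisation = 2` times. Shape variation enters as petal-template
perturbations organised by symmetry character:

| component | pattern over petals | default SD | what it emulates |
|---|---|---|---|
| `sigma_sym` | same on all four petals | 0.153 | inter-flower symmetric variation |
| `tree_effect_sd` | same, drawn per tree | 0.088 | inter-tree mean shape differences |
| `sigma_lat` | (+,+,−,−) and (+,−,−,+) | 0.063 | lateral asymmetry (two patterns) |
| `sigma_trans` | (+,−,+,−) | 0.0382 | transversal asymmetry |
| `sigma_petal` | independent per petal | 0.004 | unstructured petal noise |

SDs are relative: a draw with SD s offsets petal length by s·length, width
by s·width and tip shape by 0.3·s. Symmetric and tree-level draws are
*size-neutral* (an elongation pattern — length up, width down — plus a tip
component), and each noise-free flower is normalised to the template's
centroid size, so `female_size_factor` (default 0.845, a 15.5 % smaller
female corolla) is the only systematic size signal. Contrast draws touch
only mirror-symmetric template parameters; the chiral `skew` parameter is
driven solely by the per-petal noise, because its character changes under
reflection. `female_asym_factor` (default 1.27) multiplies the female
lateral and transversal SDs.

Measurement error is nested: per photograph, a random rigid motion plus
isotropic point jitter (`sigma_imaging` = 0.8 digitiser units) shared by the
photograph's digitisations; per digitisation, tangential point jitter
(`sigma_digit` = 0.8) along the outline — the error mode that sliding
semilandmarks absorb.

The defaults were calibrated once so that the generated populations
reproduce the study-scale quantities (subspace variance fractions near
45/43/12 %, group mean distances at the reported magnitudes, a ~24 % female
excess in asymmetric dispersion) and then frozen. At the study's design
size, the subspace fractions carry sampling noise of ±2–4 percentage points
per seed — dominated by the 16 tree-level draws — so study-scale checks and
the acceptance script average a small number of replicate populations.
Second-order effects of the nonlinear petal geometry leak a small amount of
squared-asymmetry variation into the symmetric subspace (and couple the two
lateral patterns into the transversal subspace); at the calibrated SDs these
leakages are well below a percent of total variance.

**What the generator does not emulate:** systematic size variation among
trees and flowers (Table-style size ANOVAs on synthetic data have near-zero
tree and flower effects by construction); any mean-shape difference between
the sexes (the sex regression on synthetic data estimates null-scale
values); directional vs fluctuating asymmetry (the decomposition does not
separate them); petal numbers other than four (the code is generic in the
petal count, but only tetramers are exercised); correlated within-flower
noise beyond the character patterns (residual petal noise is independent
across petals — a modelling choice, not an empirical claim). Passing tests
on synthetic data therefore demonstrate correctness of the algorithms and
calibration of the tests under these assumptions, not biological claims
about real corollas.

## Numerical choices and degenerate inputs

* GPA tolerance 1e-6 on consensus RMS change; 5 outer slide rounds;
  convergence failure warns and returns the last iterate.
* PCA drops eigenvalues below 1e-12 of the leading one.
* Zero-centroid-size configurations raise; all-coincident point sets give
  CS 0 with a degeneracy warning.
* Outline resampling interpolates linearly within polyline segments;
  endpoints are preserved exactly.
* TPS records are written with full float precision (round-trips to 1e-9 and
  beyond); `SCALE=` multiplies coordinates on read; 3-D records (`LM3=`) are
  rejected with a clear message.
* Permutation p-values are computed as (1 + #{F* ≥ F}) / (n_perm + 1), so
  they are bounded below by 1/(n_perm + 1) and reproducible under a fixed
  seed; the pipeline splits one global seed into per-stage seeds with
  SeedSequence spawning so stages can be re-run in isolation.
* Problem sizes in the shipped checks: the study-scale runs use the full
  676-configuration design (2,704 after expansion); unit tests use
  populations of 12–64 configurations; the dispersion calibration uses
  1,000 simulated datasets of 2 × 20 points with 199 permutations each.

## Known limitations

* The dispersion CI is a pooled two-sample t interval on distances; a
  bootstrap interval might behave better for strongly skewed distance
  distributions.
* Sliding projects onto tangent lines, so extremely large slides could
  distort point spacing; at the study-scale noise levels the observed slides
  are a small fraction of the inter-point spacing.
* The NMDS stress depends on the subsample size; values are comparable only
  at a fixed subsample.
* Visualisation (deformation grids, score scatter plots) is out of scope;
  the CSV/JSON outputs feed any standard plotting tool.
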