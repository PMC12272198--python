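# Methods

This note documents the models implemented in `intalign`, the numerical
choices behind them, the synthetic test bed, and the limitations of both.

## Data model and conventions

Functional images are `vertices × timepoints` matrices (rows are vertices;
readers transpose formats stored the other way round, e.g. CIFTI-2
dtseries). A parcellation assigns each vertex one integer label; label 0
(medial wall / unassigned) is carried through every transform unchanged by
an implicit identity, so outputs always keep the full vertex count.
Vertices containing NaN are zero-filled at load time and recorded in a
per-image exclusion list that ISC averaging honours; this keeps matrix
shapes fixed across participants, which every solver requires. Vertex
indexing is 0-based; 1-based file formats are converted at the I/O
boundary.

## Source-to-target solvers

All solvers act within one parcel, estimating a square map `R` such that
`R F_X ≈ F_Y`. Whole-cortex transforms are block-diagonal: off-diagonal
blocks are never materialized, and signal cannot cross parcel boundaries.

**Procrustes.** `R = s·M` with `MᵀM = I`, `s > 0`, via SVD of `F_Y F_Xᵀ`:
`M = U Vᵀ`, `s = (Σ singular values)/‖F_X‖²_F` (`s = 1` with scaling off).
Reflections are allowed (orthonormal, not rotation-proper; no determinant
correction). SVD sign ambiguity is resolved by flipping each singular-vector
pair so the largest-magnitude entry of the left vector is positive, making
output deterministic across BLAS builds. Rank-deficient input is accepted
(the formula remains a minimizer); a warning is raised when timepoints <
parcel size, where the fit is underdetermined, and an all-zero source block
returns the identity with a warning (the scale is undefined there).

**Entropic optimal transport.** Cost `C_ij` is the Euclidean distance
between the functional profiles of source vertex `i` and target vertex `j`;
the objective is the standard entropic OT one, `min ⟨R, C⟩ − ε H(R)` with
`H(R) = −Σ R_ij (log R_ij − 1)` and `⟨·,·⟩` the elementwise (Frobenius)
inner product. It is solved by log-domain Sinkhorn iterations on uniform
marginals `1/v` (total mass 1, numerically stable for small ε), and the
converged plan is rescaled by `v` so every row and column sums to 1 — all
vertices weighted equally. Two details matter in practice:

- *Convergence.* Iterations stop when the marginal violation (on the
  unit-sum scale) drops below `tol` (default 1e-9). Strongly peaked plans
  (small ε, well-separated costs) can stagnate at a float64 floor above
  that; stagnation is detected, plans within 1e-4 are accepted, and the
  result is projected onto exact uniform marginals by a rank-one rounding
  step (scale overfull rows/columns down, distribute the mass deficit), so
  the returned plan satisfies the sum-to-1 invariant to machine precision.
  Genuine non-convergence raises, reporting the final violation.
- *Cost scale.* Timeseries are z-scored per vertex before the cost
  computation by default for OT only (off for Procrustes/ridge); ε trades
  off against the cost scale, and z-scoring keeps ε=1 meaningful across
  datasets. Both choices are configurable.
- *Orientation.* The plan is computed with rows indexing source vertices,
  but an aligner must satisfy `R F_X ≈ F_Y`; the stored matrix is therefore
  the transposed plan (target rows drawing from source vertices). Applying
  it to a contrast map is a convex re-weighting per target vertex.

Defaults ε = 1 and (ridge) α = 1000 follow values tuned on held-out human
data in the literature; they are defaults, not constants, since their
optimal values depend on data scale.

**Ridge.** Closed form `R = F_Y F_Xᵀ (F_X F_Xᵀ + αI)⁻¹` via a linear solve.
`α = 0` is allowed only for invertible Gram matrices. Note that ridge
shrinks even on self-alignment: `fit(X, X)` is *not* the identity (unlike
Procrustes and, in the small-ε limit, OT). This is a property of the
estimator, not a bug.

**ProMises.** Orthonormal `M` maximizing `trace(Mᵀ(F_Y F_Xᵀ + k·Q))` with
location prior `Q = exp(−D)` (elementwise; entries in (0, 1], unit
diagonal), `D` the inter-vertex distance matrix. `k = 0` reduces
bit-identically to unscaled Procrustes (same SVD code path, same sign
convention). The exp(−D) kernel form follows the originating literature;
synthetic geometries use Euclidean distances, and a precomputed (e.g.
geodesic) matrix can be supplied instead. ProMises is Procrustes-only; it
has no analogue for OT or ridge.

## Templates

- **GPA** — initial template is the Euclidean mean of the cohort; each
  iteration re-aligns everyone to the current template and averages the
  aligned images. Default 2 iterations (enough for the fixed-point and
  convergence behaviour; the mean-then-align loop makes the summed squared
  residual non-increasing). No per-iteration rescaling of the template: the
  plain mean of aligned images is used as-is.
- **Hyperalignment** — level 1 seeds the template with the first
  participant in the supplied order and folds each next participant in
  (template ← mean of template and newly aligned image); level 2 re-aligns
  everyone to the mean of level-1 aligned images and averages. The result
  is order-dependent by construction; the order is recorded in provenance.
- **PCA** — per parcel, cohort submatrices are stacked along the vertex
  axis; timepoint columns are mean-centered across stacked vertices;
  the top `n_components` (default: parcel size, preserving solver shapes)
  principal component timecourses form the raw template, with component
  signs fixed (largest-magnitude loading positive). The raw template is
  then rotated by unscaled Procrustes toward the cohort's elementwise-mean
  image so it lives near the anatomical orientation. The rotation target is
  a design choice of this package (the primary sources leave it to
  supplementary material); `rotation="none"` disables it.
- **Pairwise** — one participant's data is the target; the target maps by
  identity, and rotating the target role across participants supports
  averaged pairwise evaluation.

## Integrated alignment

The blended target is `F'_T = γ F_X + (1 − γ) F_T` with global γ (one value
for all parcels). Blending is done row-wise in the shared vertex space,
which presupposes anatomical pre-alignment — the method regularizes an
existing registration, it cannot replace one. Endpoints are exact: γ=0
returns the template bitwise and γ=1 the participant's data bitwise. At
γ=1 the mathematical optimum for Procrustes and OT is the identity
transform and it is returned exactly; for OT this is special-cased, since
the entropic solver at finite ε only approaches the identity in the small-ε
limit. Ridge at γ=1 is solved normally and remains shrunk (see above).

γ is selected over the default grid {0, 0.02, 0.05, 0.1, 0.2, 0.5, 1}
(approximately logarithmic) by cross-validated inter-participant decoding
(or ISC) on a parameter-optimization cohort. The template is fixed during
the search (it is not rebuilt per γ). Exact score ties break toward the
*smaller* γ — more functional alignment only when strictly better. The
search refuses cohorts overlapping the template-generation cohort unless
the overlap is declared (`in_sample=True`): in-sample templates bias
transforms toward the identity (a participant's own noise correlates with
the template at matching vertices), inflating apparent alignment quality,
most strongly for small template cohorts.

## Evaluation

- **Decoding** — folds partition *participants* (seeded, recorded); a
  linear SVM (default regularization, one-vs-rest, no feature selection)
  is trained on training-fold participants' labelled task maps and scored
  on held-out participants. Chance is 1/n_labels.
- **Parcel-mean augmentation** — appended per-parcel means are computed
  from the *pre-alignment* map (solvers that remix a parcel can reset its
  mean; the pre-alignment reference restores that information;
  configurable to post-alignment).
- **ISC** — per vertex, the mean of pairwise Pearson correlations with all
  other participants, then averaged over usable vertices (mean-of-pairwise,
  not correlation-with-average). Zero-variance or excluded vertices are
  skipped in the average, never NaN-propagated.
- **Bump probes** — binary maps of vertices within `radius` (default 1 mm)
  of randomly drawn centers; the spatial constraint ratio
  `S = ‖T on original support‖_F / ‖T‖_F ∈ [0, 1]` measures how local a
  transform is (1 = perfectly local) and is invariant to global rescaling.

## Synthetic test bed

`make_cohort` draws, per parcel, latent vertex-level movie timecourses and
one latent activation pattern per task label (all i.i.d. normal with
`signal_sigma`), shared by the whole cohort; participant *i* observes both
through a single topographic transform `G_i` (identity, per-parcel
permutation, random orthogonal, or smooth displacement — jittered positions
with a row-normalized `exp(−d²/2τ²)` kernel) plus i.i.d. Gaussian noise.
Using the same `G_i` for movie and task data encodes the core
generalization assumption: a map estimated from one stimulus transfers to
another. Task patterns shared in latent space make decoding transfer across
participants exactly when topography is unmixed. Desk-scale defaults
(20 participants, 300 vertices in 10 parcels, 600 movie timepoints, 18 task
labels, `noise_sigma=0.5`, `signal_sigma=1`) run in minutes on one CPU;
identical config and seed give bitwise-identical cohorts.

Under the identity topography the generator is the classic shared-signal
model: expected vertex ISC is `σ_s²/(σ_s²+σ_n²)`, which the ISC tests
check in closed form.

What the generator does **not** emulate: hemodynamics, temporal
autocorrelation (i.i.d. noise only; an extension hook exists), realistic
cortical meshes or geodesic distances (a flat 1-mm grid stands in),
between-parcel functional correlation, and site/session effects. A green
test therefore establishes the *logic* of the methods (recovery, bias,
endpoint and blending behaviour), not performance on human data.

### Regimes used in the experiment suite

The gamma-curve experiments fix the Procrustes scale to 1 (unscaled). With
the scale free, a fit toward a noisy or blended target shrinks the
transformed vertex features, which acts as an accidental feature-scaling
regularizer for the SVM and can manufacture interior γ optima even when the
functional data are pure noise; the unscaled solver removes that confound
so the curve reflects alignment quality alone.

- *Intermediate noise* (interior γ optimum): smooth-displacement topography
  (`displacement_sigma=1.5`, `τ=1`), `noise_sigma=0.5`, 3 parcels of 20
  vertices, 25 movie timepoints. Few timepoints relative to parcel size are
  essential: they make the per-parcel fit genuinely underdetermined, the
  regime where blending in the anatomical prior pays off.
- *Zero noise* (flat ceiling): same, with `noise_sigma=0` and 10 parcels —
  at γ=1 (no alignment) only the parcel-mean features are comparable
  across participants, and 10 of them are needed to separate 18 task
  classes.
- *Pure-noise functional data* (γ=1 wins): identity topography,
  `noise_sigma=1.5`, movie timeseries replaced by white noise, so the
  functional fit can only hurt.

## Known limitations

- Transforms require matched vertex counts between source and target
  spaces; unbalanced alignment and individualized parcellations are out of
  scope.
- γ is global; per-parcel γ is not implemented.
- The Sinkhorn solver is dense (O(v²) per parcel) — appropriate for
  parcel-sized problems, not whole-cortex single-block alignment.
- Grid search only; no continuous γ optimization.
- The OT plan orientation assumes symmetric uniform marginals; searchlight
  and overlapping parcels are not supported.
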