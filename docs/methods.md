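# Methods

## Problem and scope

`prepscore` scores preclinical Class II cavity preparations (lower first
molar, one occlusal and one mesial lesion) from 3D surface scans against
a 9-item, 20-point examiner rubric, and quantifies agreement between the
model and examiner references with the standard method-comparison suite.
The package covers the full pipeline — mesh input, deterministic point
sampling, pose normalization, a bounded point-cloud regression network,
block-wise training with best-epoch restore, and the agreement
statistics — plus a synthetic-preparation generator that stands in for
clinical scan data, which is not publicly deposited.

## Preprocessing

**Sampling.** "Uniform down-sampling" of a triangle mesh is realized as
area-weighted face selection followed by uniform barycentric placement
(square-folding). The generator is a PCG64 stream seeded from the
configured seed together with a SHA-256 hash of the mesh's source id, so
(a) identical (mesh, config) inputs give bit-identical clouds, and (b) a
batch of files yields the same clouds regardless of processing order.
Poisson-disk sampling was considered and rejected as under-determined
and harder to make reproducible. Default cloud size is 100,000 points at
inference; the worked examples and tests use 2,048 points, which keeps a
full training run on one CPU core in minutes while leaving every
contract (determinism, invariance, bounds) unchanged.

**Normalization.** Clouds are centred on their centroid and divided by
the maximum centroid-to-point distance (unit-sphere convention). This
makes downstream scores invariant to rigid translation and positive
uniform rescaling of the input mesh — asserted to 1e-5 in tests — and
gives the network scale-free inputs. Degenerate inputs (all points
coincident) raise a named error.

**OBJ dialect.** `v`/`f` records; `vn`/`vt`/material/group records
ignored; polygons fan-triangulated; negative indices resolved relative
to the vertices read so far; zero-area faces dropped with a logged
count. Missing file, out-of-range face index, and no-faces-after-cleanup
each raise a distinct error type.

## Rubric arithmetic

Criterion values live in fixed ranges (caries 0–9; three clearances 0–2;
inter-cavity preservation 0–2; occlusal preservation 0–1; undermined
enamel 0–2; adjacent-tooth damage stored as a value in [−4, 0] rather
than a separate magnitude + band). The total is the plain sum (the
deduction enters with its sign), zeroed by pulp exposure and clamped
below at 0 — a mark, not a signed quantity. Examiner-average sheets are
validated to half-point granularity (averaging two integer marks is the
only stated source of halves); model sheets are unconstrained reals
within bounds. JSON label files store case id, the eight criterion
fields under their snake_case keys (the schema of record), the pulp
flag, and the total, which is re-verified on read.

One published per-case table contains a value above the occlusal
criterion's 1-point maximum; the package keeps the [0, 1] bound and
preserves the table verbatim in `prepscore.datasets` with the
inconsistency documented rather than silently reconciled.

## Synthetic preparations

Meshes are built as radially displaced subdivided icospheres (height
field in the radial direction; no CSG booleans), which guarantees
watertight, self-intersection-checked, dependency-light and fully
deterministic geometry. Cusps are four smooth bumps at polar angle 0.65
rad; the occlusal cavity is a quartic-profile depression (flat-ish floor,
soft walls); the mesial box is a smoothstep-edged depression around the
mesial direction whose lateral and gingival extents widen with the
clearance parameters; adjacent teeth are separate spheres at near-contact
(0.35 mm) with damage as a depression on the facing surface.

Residual caries is modelled as the cavity not being cut to full depth: a
lobe of the floor is raised back by `residual_fraction × cavity_depth`,
plus small bumps for carious texture. The lobe is azimuthally
asymmetric, which is what the learnability probe measures (below).
Undermined enamel appears as a flared rim at the cavity margin; pulp
exposure as a deep narrow pit at the cavity centre; a thin isthmus as
erosion of the ridge between the two cavities.

**Geometry → score map.** The rubric states point values, not the metric
criteria examiners applied, so the cutoffs are this package's own
clinically plausible conventions, exposed as module constants: clearance
2 points at ≥ 0.5 mm, 1 at ≥ 0.25 mm; inter-cavity preservation 2 at
isthmus ≥ 1.0 mm, 1 at ≥ 0.5 mm; caries score = 9·(1 − residual
fraction) rounded to the nearest half point; undermined-enamel score =
2·(1 − extent) likewise; damage deduction linear, −2·depth below 1 mm
and −2 − 2·(depth − 1) for 1–2 mm (so exactly −2 at the 1 mm band edge
and −4 at 2 mm); occlusal preservation 1 iff the cavity footprint stays
0.15 rad clear of the cusp ring. The map is a pure function of the
parameters: regenerating a case recovers its score sheet exactly.

**Cohorts.** The default cohort mirrors the study design: n = 30 with a
seeded 20/10 train/test split. Cases are drawn from three strata with
fixed counts — 20% ideal (full marks), 15% deliberately poor (failing),
65% varied — reflecting the stated practice of preparing some teeth
deliberately less conservatively to create scoring variation, and
guaranteeing for every seed that cohort totals span at least [8, 20].
Scanner noise is not simulated (a Gaussian vertex-jitter flag exists,
default off); anatomically accurate molar morphology is out of scope.
Consequences: passing tests show the pipeline can learn geometric
determinants of rubric scores under clean geometry; they do not show
robustness to scan artifacts, soft-tissue remnants, or real anatomical
variation.

## Network

Canonical PointNet classification trunk: shared per-point MLP (default
widths 64-64-128-1024), symmetric max-pool to a global feature
(permutation invariance is exact by construction), fully connected head
(512-256), nine outputs. Each output passes through a sigmoid affinely
rescaled to its rubric range — chosen over linear output + clamping
because every output then respects its bounds for any parameters while
keeping gradients alive at the bounds. The ninth output is a jointly
trained total head, separate from the sum of the predicted criteria;
both are always reported (published per-case tables show totals that are
not the sum of the printed criteria, so the two-route structure is
real). A learned input transform (T-Net) is not implemented: inputs are
pose-normalized upstream; the config flag is reserved.

The network, its reverse-mode gradients, and the Adam update are written
directly in NumPy (float32 by default; float64 for gradient tests, which
agree with central differences to 1e-7). The desk-scale architecture
used in examples and tests is trunk 32-64-128-256 with head 128-64.

Two architecture variants are implemented and config-exposed but off by
default, having underperformed the canonical form on the synthetic
task: a hybrid max+mean pooling (concatenating the per-feature mean —
still symmetric, and in principle sensitive to concave regions that
never attain a per-point maximum) and a shrunken final-layer
initialization (`out_init_scale`).

## Training

Loss is the mean absolute error in rubric points, averaged over the nine
outputs with uniform weights (one output off by 1.8 on one case
contributes 0.2). Epochs run in blocks — default (50, 50) — with a fresh
Adam state per block; per epoch: seeded shuffle, mini-batch gradient
steps, then the full-training-set MAE is recomputed and recorded as that
epoch's training loss (not the running mini-batch average). A checkpoint
(`epoch_%04d.npz`: parameters, epoch, training MAE, RNG state) is
written every epoch; after training the argmin-MAE epoch (ties →
earliest) is restored and also saved as `best.npz`, with the curve as
CSV. There is no validation split — best-epoch selection uses training
MAE, matching the original workflow, which kept all 20 cases for
training. A leakage guard refuses to train if any offered case carries a
test split tag.

Training defaults are learning rate 3e-3, batch size 2, and a ×1/3
learning-rate reduction at the second block, chosen from convergence
behaviour at the package's working scale: with 20 cases, 100 epochs at
batch 4 and rate 1e-3 is only 500 Adam updates and stalls near the
predict-the-mean plateau, while flat rates of 5e-3 and above saturate
the bounded outputs (sign-gradient MAE pushes the pre-sigmoid
activations hard, after which gradients vanish). Batch 2 doubles the
update count; the lower second-block rate settles the curve instead of
oscillating around the optimum. Optimizer (Adam), batch size, rate,
per-block decay and an optional global-norm gradient clip are all
config-exposed since the original report states none of them.

Determinism is a platform contract: fixed seeds give identical curves on
a fixed platform/BLAS build (asserted to 1e-6 in tests), not a
cross-platform bit-exactness guarantee.

## Agreement statistics

Difference direction is predicted − reference throughout. Lin's ρc uses
population (1/n) moments (the original convention); Cb = ρc / r.
Bland–Altman limits are bias ± 1.96·SD with the n−1 denominator.
Spearman uses mid-rank tie correction (required: score totals tie).
ICC(2,1) is the two-way random-effects, absolute-agreement, single-rater
form computed from the ANOVA mean squares. Within-threshold accuracy
uses an inclusive comparison with a 1e-9 absolute guard. Degenerate
inputs (zero variance) raise a named error; the aggregate report instead
records correlation-type fields as null so a perfect-prediction stub
still yields MAE/bias/accuracy.

The shipped reference tables are rounded to one decimal, so statistics
recomputed from them legitimately differ from the originally reported
unrounded-data values (e.g. test bias +0.23 from the table vs +0.52
reported); tests assert only table-derived values, at 1e-3, against
brute-force oracles. The original headline training metrics depend on
the non-deposited scans and unstated hyperparameters and are treated as
non-reproducible narrative; the corresponding end-to-end check is
property-based (training MAE halves from epoch 1; held-out rank
correlation positive; median over 3 seeds) on the default synthetic
cohort at desk scale (2,048 points, 100 epochs).

## Known limitations

- Synthetic geometry is schematic: displaced spheres, not molar anatomy;
  no scan noise, holes, or cropping artifacts.
- The geometry→score cutoffs are conventions, not calibrated clinical
  standards; real examiner criteria may weight geometry differently.
- The desk-scale network underfits relative to what the full-width
  architecture at 100,000 points could achieve; the package asserts
  learning-signal properties, not clinical-grade accuracy, on synthetic
  cohorts.
- Per-criterion predictions are descriptive; only total-score agreement
  is property-tested end to end.
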