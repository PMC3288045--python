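# Methods

This note documents the statistical models behind `g1screen`, the default
parameter choices and why they were made, and what the synthetic-data tests
do and do not establish about instrument data.

## Assay model

The pipeline starts from per-cell intensity tables (one row per segmented
cell) and a plate map assigning each well a reagent role (library target,
non-targeting siRNA, mock/lipid, p21-siRNA positive control), an IR dose and
a replicate index. Image acquisition and segmentation are upstream of this
package and out of scope.

A well's marker signal is treated as a two-component mixture: a
"responder" population (for the RB1 phospho-S780 readout: cells that lost
the phospho-signal, i.e. checkpoint-active) and a non-responder population.
The science of the screen lives entirely in the mixing weight — the
percentage of responder cells — not in the component locations. All POS
metrics are therefore threshold counts.

## Gating

Gates are derived **per plate** from in-plate controls, never globally: the
threshold is placed where the kernel-density estimates of the negative
(non-targeting) and positive (p21 siRNA) control log-intensity distributions
cross. Two implementation details matter:

* Both KDEs share a common absolute bandwidth. Two mixtures of the same two
  components cross exactly at the component-density equality point
  regardless of their mixing weights, but only if both densities are
  smoothed equally; per-sample bandwidths would smooth the broader control
  more and bias the crossing.
* The crossing is searched first between the control medians (the natural
  interval for well-separated unimodal controls); if none is found there —
  the generic case when both controls are mixtures, whose medians can both
  sit inside the non-responder component — the search widens to the central
  99% of the pooled data before falling back to the midpoint of the
  log-medians. Control pairs whose log-medians differ by less than a
  configurable minimum (default 0.1) raise a "no separation" error.

Gate provenance (control cell counts, medians, method) is recorded on every
`GateSpec` and written to the audit JSON.

Unirradiated counterscreen plates cannot anchor their own gate: without IR
the non-targeting and p21 control wells have the same responder fraction and
the histogram difference vanishes. Each 0 Gy plate therefore inherits the
gate of its paired irradiated plate (same replicate, same plate index). This
assumes a common intensity scale within a replicate batch; it is the
package's design choice for a case the assay itself leaves undefined.

Wells below the minimum cell count (default 1500) are reported and flagged,
not dropped; the flag propagates through the well-summary tables.

The G1 reporter metric counts cells with nuclear:cytoplasmic fluorescence
ratio ≥ 2 (inclusive). The source descriptions of this assay disagree on the
ratio's orientation; the nuclear/cytoplasmic reading matches the reporter's
biology (nuclear accumulation in G1) and is the default, with both the
threshold and the direction configurable. Cells with non-positive
cytoplasmic signal are dropped and counted separately.

## Plate QC

Z′ = 1 − 3(σ_p + σ_n)/|μ_p − μ_n| from the well-level POS values of the
plate-internal p21 (positive) and mock (negative) control wells, with sample
(n−1) standard deviations. The absolute mean difference keeps the statistic
meaningful for inverted assays. A triplicate plate set is rejected when any
plate scores Z′ strictly below 0.2 (boundary accepted; both convention and
threshold configurable). QC decisions are made on the irradiated plates
only: the 0 Gy plates have no assay window by construction (see above).

## Hit calling

* **z-scores.** z_i = (x̄_i − μ_pop)/s_pop, where x̄_i is target i's mean
  POS over triplicates and μ_pop, s_pop are the mean and sample SD of *all*
  library target means in the same run. The per-target-SE alternative
  (s/√3) would inflate |z| roughly threefold and is inconsistent with a
  ~52/779 expected null tail below −1.5; the population reading makes the
  z-distribution standard normal under the null, which the Monte-Carlo
  tests confirm. A degenerate library in which every mean coincides gets
  z = 0 everywhere (the limit), rather than an error.
* **Fold grading.** fold = baseline / target mean, with the baseline the
  pooled mean of the plate-internal mock (lipid) wells of the irradiated
  run (configurable to NT- or population-based). Grades: strong ≥ 2.0,
  average [1.6, 2.0), weak [1.4, 1.6), each conditional on z < −1.5;
  boundaries closed on the left ("2-fold or greater" is inclusive; the
  interior assignment is a documented convention). Grading is a partition:
  every target gets exactly one class.
* **Counterscreen.** Hits with unirradiated-run z < −1.3 are flagged
  nonspecific and excluded from the candidate list; hits absent from the
  counterscreen are flagged untested but retained — the counterscreen is a
  specificity check, not a gate.
* **Deconvolution.** An oligo is active when it meets the weak-or-better
  pool criteria (z < −1.5 and fold ≥ 1.4); a target validates with ≥ 2
  active oligos; fewer than 2 tested oligos yields an
  insufficient-deconvolution flag instead of a verdict.

No multiple-testing correction is applied in the primary screen and no
plate-position (B-score/loess) normalization is performed; a
Benjamini–Hochberg helper exists but is off by default.

## Interaction statistics

With Cc, Rc, C_IR, R_IR the mock/knockdown readouts without/with IR, the
expected multiplicative combined response is (Rc/Cc)·(C_IR/Cc) and the
interaction index is that expectation minus the observed R_IR/Cc. The index
is invariant under common rescaling and identically zero for multiplicative
(independent) effects. Classification compares the relative treatment effect
in the knockdown arm against the mock arm in the assay's response direction:
for a viability readout (IR decreases signal) a positive index is
synergistic sensitization; for an IR-induced readout such as p21 positivity
a positive index is antagonism of the induction. Indices within a tolerance
of zero (default |index| < 0.02, configurable — no significance procedure is
defined for this statistic) classify as "none".

Paired t-tests are computed across biological replicates only; technical
replicates are averaged first so degrees of freedom are not overstated
(df = n_bio − 1). Zero-variance differences are handled explicitly: identical
vectors give t = 0, p = 1; a constant nonzero difference reports the limit
p = 0.

## Profile clustering

Per-target phenotype profiles (normalized assay means; identical column
order enforced, missing cells are errors naming the gap) are clustered
agglomeratively with Euclidean distance and complete linkage after row
standardization (mean 0, sample SD 1 per target) — the defaults of the
standard heatmap routine — and cut into k = 2 groups. All three choices are
configurable since only the routine, not its parameters, is canonical.
Constant rows are rejected before standardization. Output group labels are
renumbered by first appearance, making the assignment invariant to row
permutation and to affine rescaling of any single row.

## Synthetic screen generator

Defaults encode the study conditions end to end:

| parameter | default | rationale |
|---|---|---|
| library size | 779 targets | screened kinome set |
| plate format | 96-well, 87 library wells + 3 pos/3 mock/3 NT controls | triplicate in-plate controls |
| replicates | 3 plates per run | triplicate screening |
| cells per well | Poisson(2500) | high-content acquisition scale; Poisson lets wells dip under the 1500-cell QC floor |
| responder fraction | 5% baseline → 45% after IR | strong but sub-saturating checkpoint response |
| intensity components | log-normal, medians 40 (responder) and 100, σ_log = ln(2.5)/6 | positive right-skewed fluorescence; each component sits 3σ from the gate midpoint, i.e. ~0.13% intrinsic misclassification |
| positive control effect | 1.0 (full suppression) | p21 knockdown abolishes the shift |
| planted hits | effect e suppresses the IR shift by the fraction e | knockdown acts on the mixture weight, not component locations |
| G1 reporter | independent log-normal nuclear/cytoplasmic channels, median ratio 4 (G1) vs 0.5, σ_log 0.15 | simplest model producing a gateable ratio |
| viability | expected luminescence per (arm, dose ∈ {0,2,5} Gy) × log-normal noise (σ 0.05) | multiplicative ATP-readout noise |
| profile noise | iid Gaussian, SD 0.08 on normalized means | matches the spread of triplicate-mean error bars in this assay class |

`effect_for_fold` inverts the gated (misclassification-aware) expectation, so
a planted "2.5-fold" hit shows a 2.5-fold reduction of the *measured* POS.
A fixed seed gives byte-identical output; per-plate tables are drawn from
seeds spawned deterministically off the master seed so plates regenerate
lazily without holding the screen in memory.

The default profile patterns encode the two phenotype groups the panel
assays distinguish: group I (TP53-axis: suppressed IR-induced p21
positivity, partially suppressed baseline positivity) versus group II
(p21-independent: positivity preserved), both with suppressed checkpoint
readouts and IR sensitization.

A fast well-level route (`simulate_well_level_screen`) samples gated well
fractions directly as Binomial(n, p(1−ε)+(1−p)ε) with the closed-form gate
misclassification ε, skipping per-cell draws; it exists for many-screen
Monte Carlo and is cross-checked against the per-cell + KDE route in the
test suite.

### What the generator does not emulate

No spatial plate effects (edge/row/column gradients), no transfection
efficiency variation, no batch drift of the intensity scale, no correlation
between a target's counterscreen behaviour and its IR-specific effect, no
segmentation errors, and component separations are free parameters rather
than estimates of any instrument's point-spread. Passing tests therefore
demonstrate the correctness and calibration of the *statistics* under the
assumed generative model, not robustness to instrument artefacts — on real
screens the plate-QC and counterscreen stages carry correspondingly more
weight. One visible consequence of the independence assumption: about 10%
of targets (planted hits included) fall below the −1.3 counterscreen floor
by chance, so a few true hits are flagged nonspecific in synthetic runs.

## Numerical choices and problem sizes

Gate KDEs subsample each control group to at most 5000 cells (deterministic
order statistics, preserving reproducibility) and evaluate on a 512-point
grid with linear root interpolation. Threshold counting uses strict `<` on
the responder side of "below" gates and `>=` for "above", so the two
directions partition a well exactly. The test suite exercises screen-scale
recovery on 20 full per-cell screens (779 targets × 3 replicates × ~2500
cells/well) plus 50 analytic null screens, calibration of the paired t-test
on 10⁴ null triples, gate recovery on 100 wells of 2·10⁴ cells, and
cluster recovery on 100 noise realizations; these sizes make the whole
suite run in a couple of minutes while keeping Monte-Carlo standard errors
well inside the asserted tolerances.

## Known limitations

* The gate-crossing estimator carries a small residual bias (fractions of a
  percentage point) when control mixtures are strongly asymmetric, from
  KDE smoothing; it is far inside the 1-percentage-point recovery tolerance
  at the default separation but would grow for poorly separated assays.
* The counterscreen filter assumes the unirradiated run shares the
  irradiated run's intensity scale (inherited gates).
* The interaction classification threshold (0.02) is a reporting
  convention, not an inference procedure; no error model is attached to the
  index.
* DNA content is used for object identification only; no cell-cycle gating
  on DNA intensity is implemented.
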