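# Methods

## Problem setting

Exosomes exported by tumor cells carry miRNA whose abundance can be read from
body fluids, making them candidates for non-invasive PDAC detection. The
package covers the two computational halves of assembling such a diagnostic:
(1) choosing a small set of miRNA genes whose copy-number alterations jointly
cover as many patients as possible, and (2) quantifying the corresponding
mature miRs from RT-qPCR of exosomal RNA, where the dominant data problem is
censoring — many wells never cross the calling threshold.

## Panel selection model

The input is a binary patients × genes matrix; "altered" collapses
amplification and deletion because the coverage criterion only asks whether a
patient's tumor is flagged by a gene, not in which direction. A panel's merit
is its patient coverage — the fraction of patients altered in at least one
member — i.e. maximum-coverage set cover with unit weights.

- **Frequency filter**: genes altered in ≥ `min_fraction` of patients
  (default 0.10, inclusive: 11/109 passes, 10/109 does not).
- **Optimization**: exhaustive enumeration of all k-subsets while
  C(n, k) ≤ `exhaustive_limit` (default 100 000); otherwise greedy set cover,
  each step adding the gene covering the most uncovered patients. Greedy
  attains ≥ (1 − 1/e) of the optimum; the suite verifies both paths against a
  brute-force oracle on small random instances. All ties (both paths) break
  by lexicographic gene symbol, so output is a pure function of input.
- **Stage stratification**: per-stage sets of panel genes altered in ≥ 1
  patient of that stage. Patients with unknown stage count toward overall
  coverage but toward no stage set: a cohort may be incompletely staged, and
  an unknown label is evidence for no particular stage.

## Annotation model

Live database lookups (exosome catalogues, disease expression resources) are
replaced by flat per-gene tables so runs are reproducible offline. Expression
direction in each contrast is four-valued: `up`, `down`, `none` (evaluated,
no signal), `unknown` (never evaluated). The differential filter accepts any
known direction in either contrast and never lets `unknown` pass — absence of
evidence is not evidence of absence — but logs the distinction. Mature
expansion emits 5p before 3p within a gene and tolerates single-arm families
(miR-429, miR-1208).

The shipped annotation table (`data/panel_annotations.tsv`) records the
published evidence for the 18-gene reference panel. Under it, 11 of the 18
genes carry some differential signal; the published final panel kept 10,
selected "systematically using a combination" of criteria that is not fully
derivable, so the package does not claim to re-derive the 10-gene identity
from evidence. The funnel fixture used in tests marks exactly the published
final 10 as differential — a synthetic assignment, labelled as such in its
docstring, whose purpose is to exercise the cascade at the published stage
sizes (383 → 72 → 50 → 18 → 10 → 18 mature).

## Censored ΔΔCq quantification

Parameters (units are PCR cycles unless noted):

| parameter | default | meaning |
|---|---|---|
| `ceiling` | 35 | Cq above which a well is background noise |
| `imputed` | 36 | value assigned to censored wells |
| `min_detected_fraction` | 0.20 | detection rate required per (cell line, assay) |
| `alpha` | 0.05 | significance level for collation and arm preference |

Censoring replaces non-detect wells and wells with Cq > 35 by 36 and flags
them; the boundary is strict (a well at exactly 35.0 is kept) so the
replacement rule and the detection rule (Cq ≤ 35) partition wells
consistently. Censored values participate in all downstream means — dropping
them would delete precisely the "absent in this line" signal. The instrument
fluorescence threshold (0.1 by default) is carried as metadata only; Cq
calling happens upstream of this package.

Normalization averages the technical-replicate means of the endogenous
(miR-16-5p) and exogenous spike-in (cel-miR-2-3p) controls into one control
value per sample. Any additive per-sample shift (pipetting, extraction
efficiency) cancels exactly in ΔCq; the suite asserts this invariance. A
sample whose control assay is entirely non-detect is excluded with a logged
reason rather than silently normalized against an imputed constant.

Statistical unit: the biological replicate. Technical replicates are averaged
first; t-tests run on per-sample ΔCq (equivalent, up to sign and shift, to
testing ΔΔCq or log2 FC replicates). The test is two-sided Student's t with
pooled variance — Welch is a switch (`equal_var=False`) — and degenerate
zero-variance groups get the exact limit (p = 1 for equal means, p = 0
otherwise). Outlier handling follows a deterministic, distribution-free rule:
within each (cell line, miR) ΔCq group, values outside median ± 1.5·IQR are
removed farthest-first, never reducing a group below 2 values; it can be
disabled (`remove_outliers=False`). No multiplicity correction is applied by
default (raw p-values with star tiers are the convention in this assay
design); Benjamini–Hochberg is available via
`QuantResults.with_adjusted_pvalues`.

A miR undetectable in both the target and reference line is reported
`detectable=False` with NaN estimates. Detectable on exactly one side, it is
quantified against the censored values (36) of the silent side and flagged
`one_sided_detection`; such fold changes are floors, not estimates — the true
effect is at least as extreme as reported (visible in `examples/03`, where an
injected −6 is recovered as ≈ −1.7 against a fully censored side).

Arm preference is unpaired by default, matching the main contrast's test
flavor; a paired mode exists (`paired=True`) since both arms are measured on
the same samples. The preferred arm is the one with lower mean ΔCq, called
only at p ≤ alpha.

## Synthetic-data generator

A well's true Cq for miR m in line L is
`base_cq[m] − log2_fc[L, m] + sample_effect + N(0, noise_sd)`; the per-sample
effect is N(0, 0.2) applied to every assay of that sample, controls included,
which is exactly the nuisance the dual controls exist to remove. Dropout is
deterministic in the true Cq (wells above `detection_limit` read non-detect)
because that is the simplest mechanism reproducing the "high Cq ⇒ non-detect"
structure; an independent Bernoulli dropout can be layered on
(`dropout_rate`). Defaults mirror the reference design: 3 biological × 3
technical replicates, noise sd 0.3 cycles, detection limit 35, control means
20 and 22.

What the generator does *not* emulate: amplification-efficiency differences
between assays, probe cross-hybridization, plate/batch effects, and
non-normal noise. Passing recovery tests therefore demonstrates correctness
of the estimator under the stated measurement model, not robustness to every
real-world artifact.

Deterministic fixtures: `table1_matrix()` encodes the reference cohort's
stage-wise alteration incidence exactly (round-robin assignment of each
stage's altered genes to that stage's patients, which is the minimal matrix
consistent with the published per-stage sets and counts);
`funnel_fixture(seed)` is described above.

## Verification strategy and problem sizes

The suite checks, at sizes chosen to keep the default run fast: brute-force
equivalence of panel optimization on 200 random instances (≤ 12 genes, ≤ 30
patients); coverage monotonicity; normalization invariance and antisymmetry
of log2 FC under swapping target and reference; censoring idempotence;
t-statistics against the textbook pooled formula to 1e-10; exact noiseless
recovery of injected fold changes; noisy recovery (σ = 0.3, 3×3 replicates,
effects 0, ±2, ±5) with mean absolute error < 0.5 log2 units over 200 seeds;
and empirical type-I error at the nominal 5% over 1200 null simulations. The
type-I property is computed with outlier removal disabled: it is a property
of the t-test under the null, and median ± 1.5·IQR trimming at n = 3 distorts
the level of any test it precedes (a known cost of the robustness rule,
which is why every report carries the flag and the rule can be disabled).

## Known limitations

- Coverage optimization ignores alteration direction and any redundancy
  beyond patient overlap; it does not jointly optimize the
  disease-differential criterion (applied as a candidate pre-filter).
- Censored fold changes are biased toward zero whenever one side sits at the
  imputed value; they are reported with flags rather than corrected (no
  tobit-style likelihood is attempted).
- No amplification-efficiency (standard-curve/Pfaffl) correction, absolute
  quantification, or melt-curve QC.
- The 20% detectability rule operates on wells within a (cell line, assay)
  group; other readings of "samples" (biological replicates) are possible and
  configurable upstream of the rule's fraction.
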