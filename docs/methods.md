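# Methods

## Model and procedure

`arecamir` chains five analyses, each behind its own module surface.

**Fold-regulation algebra.** All expression changes are linear ratios
r > 0. Two printed dialects coexist in published panels: the ratio itself
and the signed fold-regulation (r for r ≥ 1, −1/r otherwise). Panel
averages are arithmetic means on the linear ratio scale, re-expressed in
the output dialect. This rule is not stated in the source tables; it was
reverse-engineered and verified row-by-row against both packaged tables
(84 rows, all within ±0.02 of the printed averages — inputs are
themselves rounded to 2 decimals, so exact parity is not attainable for
every row). Signed entries with magnitude below 1 (−0.88 and similar) are
decoded as ratio = 1/|v|; this quirk is accepted on input only and never
produced on output. Report rendering uses half-up rounding via decimal
arithmetic; all internal computation keeps full precision.

**Paired-line exposure screen.** Group summaries are geometric means
(microarray intensities are approximately log-normal); singleton groups
(one chip per condition, the historical screening design) are allowed and
flagged. Normalization equalizes per-sample median log-intensity, which
removes per-chip scale factors exactly and leaves within-sample ratios
untouched; zeros are floored at 1e-6 × the global positive median before
logs. Calls are inclusive at the threshold (ratio ≥ t is up, ≤ 1/t is
down; default t = 1.2). The joint classification of two lines is the 3×3
call grid minus the concordant-null centre, labelled R1–R8 with R2/R6 the
concordant up/down cells; this is the unique natural scheme in which
"up in at least one line" = R1+R2+R3 and "down in at least one line" =
R5+R6+R7 while discordant miRNAs (R4, R8) belong to neither. Numbering of
the remaining regions is a labelling convention.

**Cohort screen with purity calibration.** Bulk tumor expression is
modelled as a two-compartment mixture,
observed = p·tumor + (1 − p)·normal, with p the malignant-cell fraction.
De-mixing inverts this linearly per sample, flooring at zero. Purity
comes either from the annotation table (preferred — used as-is) or from a
simplified admixture estimate: single-sample rank running-sum enrichment
of stromal and immune marker sets (invariant to monotone transforms of
expression), summed and rank-calibrated across the cohort to a purity
range of (0.05, 1]. Cohort rank calibration identifies purity only up to
a monotone map; the tests show it lands within ±0.1 of truth on an
admixture grid. Differential calls use a two-sided unpaired t-test on
log2 intensities — Welch's form by default because cohorts of interest
are strongly unbalanced (hundreds of tumors vs tens of normals); the
pooled-variance form is behind a flag. Selection is |FR| ≥ 1.2 (ratio of
group geometric means, signed dialect) with raw p < 0.05, matching the
published criteria; Benjamini–Hochberg q-values can be reported alongside
but do not gate selection by default.

**Integration and signatures.** OncomiRs = (up in ≥1 line) ∩
(tumor-overexpressed); TSmiRs mirrored. Signature selection requires
absolute fold-regulation above 2 on both axes, with a *strict*
inequality: on the packaged tables a non-strict ≥ would admit an eleventh
OncomiR sitting exactly at T/N = 2.00, contradicting the published count
of ten. Whether that exclusion reflects strict inequality or an unrounded
value just below 2 is indistinguishable from printed data; strict `>` is
the default and the non-strict variant is retained behind a flag.

**Targets and enrichment.** Target assertions are supplied as TSV
snapshots rather than fetched live: database versions drift, so published
target counts are not reproducible against current releases and the
analysis must be testable offline. Every source counts one vote;
interactions with ≥ 4 votes are kept (a validated-evidence override is
available, off by default). Over-representation uses the upper-tail
hypergeometric probability with the GMT union as the default universe
(background choice is population-dependent; overridable), omitting
zero-overlap pathways; the conservative EASE variant (overlap decremented
by one) is behind a flag. Enriched pathways roll up into phenotype
modules via a packaged map: adherens junction and focal adhesion →
motility; EGFR-TKI resistance, p53 signaling, cellular senescence, cell
cycle → survival; PI3K-Akt, Rap1, MAPK and Ras signaling → both.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| exposure fold threshold | 1.2 (inclusive) | per-line dysregulation call |
| cohort fold threshold | 1.2 (inclusive) | tumor/normal screen |
| alpha | 0.05 | raw p cutoff, Welch test on log2 |
| signature threshold | 2.0 (strict >) | both-axis signature call |
| min_votes | 4 of 11 | target consensus |
| purity range | (0.05, 1] | rank-calibration clip |
| zero floor | 1e-6 × global median | log-safety epsilon |

## Synthetic data: what it emulates and what it does not

Generators plant known effects and return the truth, so every stage's
recovery is scored exactly. Defaults encode the study conditions: a
500-miRNA two-line paired experiment with 40 common-up, 40 common-down
and 10 discordant miRNAs at 2-fold effects, σ = 0.1 multiplicative
log-normal noise, 3 replicates and per-chip scale factors
(exp N(0, 0.3²)); a 40-tumor / 10-normal cohort (preserving the ~10:1
imbalance of public HNC cohorts at desk scale) with 30 + 30 planted
2-fold effects and Beta(8, 2) purity; 11 target sources (3 validated,
8 predicted) with a 50-edge consensus core and 150 sub-threshold noise
edges; 20 pathways of 40 genes over a 1,000-gene universe with one
pathway enriched at odds 20. Not emulated: probe-level artefacts, dye or
batch structure beyond a per-chip scale, copy-number/methylation
confounding, miRNA family cross-hybridisation, and real database biases —
so passing tests demonstrate correctness of the algebra and the
screening logic under the stated noise model, not robustness to every
real-data pathology.

The calibrated-vs-uncalibrated comparison runs on a deliberately admixed
stress cohort (1.4-fold effects, Beta(5, 5) purity) where dilution pulls
the raw fold below the 1.2 threshold; sensitivity is compared along each
method's p-value ranking truncated at 10% empirical FDR. At fixed
thresholds in extreme low-purity regimes, naive per-sample de-mixing
amplifies noise by 1/p and can inflate the false-discovery rate — a known
limitation of linear de-mixing, which is why the matched-FDR comparison
is the honest one and why supplied purity is preferred over estimated.

## Numerical choices and degenerate inputs

Ties in rank statistics use average ranks with a stable ordering.
Zero-variance t-test inputs return p = 1 (equal means) or 0. All-zero
samples are rejected before normalization. Empty fold lists, empty query
miRNA sets and empty universes raise domain errors rather than returning
sentinels. Simulation problem sizes in the test suite (hundreds of
features, tens of samples, ≤ 2,000 Monte-Carlo replicates, 100 enrichment
seeds) were chosen as the smallest scales at which the statistical
assertions are stable across seeds.

## Known limitations

- The region scheme assumes exactly two cell lines define the joint
  classification; further lines contribute fold columns only.
- Purity estimation is relative (rank-calibrated); absolute accuracy
  depends on the cohort spanning a contamination range.
- No multiple-testing correction gates the default cohort screen (by
  design, matching the published criteria); expect ~5% false positives
  among null features at α = 0.05.
- Consensus voting treats sources as independent and equally reliable;
  correlated prediction databases can inflate votes.
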