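# arecamir

Screening pipeline for miRNA panels associated with chronic areca nut
exposure in head and neck cancer (HNC). Habitual areca (betel) nut chewing
is the dominant oral-cancer carcinogen in Southeast Asia; `arecamir`
implements, as an offline and fully testable Python package, the
integrative analysis that derives oncogenic (OncomiR) and
tumor-suppressive (TSmiR) miRNA panels from two complementary screens and
follows them through to target genes and oncogenic pathways.

## What it computes

1. **Exposure panel** — paired isogenic cell lines (parental vs a subline
   chronically exposed to areca nut extract) are compared per miRNA by the
   ratio of group geometric means. Calls at an inclusive fold threshold
   (default 1.2) in two cell lines place each miRNA in one of eight joint
   regions R1–R8 (a 3×3 up/none/down grid minus the concordant-null
   centre): R2/R6 are common-up/common-down, R4/R8 discordant, and the
   derived sets *up in ≥1 line* = R1+R2+R3, *down in ≥1 line* = R5+R6+R7.
2. **Cohort panel** — tumor vs adjacent-normal screening with tumor-purity
   calibration. Observed bulk tumor signal is modelled as
   `purity · tumor-intrinsic + (1 − purity) · normal`; profiles are
   linearly de-mixed with supplied or rank-calibrated purity, then
   screened at |fold-regulation| ≥ 1.2 and Welch-test p < 0.05.
3. **Integration** — OncomiRs = up-in-exposure ∩ tumor-overexpressed,
   TSmiRs = the mirrored set. *Signature* members exceed absolute
   fold-regulation 2 on **both** axes (strict `>`, which reproduces the
   published 10-OncomiR / 8-TSmiR lists; `--no-strict` documents the
   boundary case at T/N = 2.00).
4. **Targets** — miRNA→gene assertions from up to eleven databases are
   consensus-voted: keep interactions asserted by ≥ 4 sources.
5. **Enrichment** — hypergeometric over-representation of the target union
   against a GMT collection with BH adjustment, and a rollup of enriched
   pathways into phenotype modules (cell motility / cell survival / both).

### Fold-regulation algebra

Expression changes are linear ratios r (treated/reference); panels print
either the ratio itself or the signed *fold-regulation*

```
FR(r) = r        if r ≥ 1
FR(r) = −1/r     if r < 1
```

Panel averages ("Average FC") are arithmetic means **on the ratio scale**,
re-expressed in the printed dialect — for concordant negatives this is a
harmonic mean of magnitudes: averaging −5.68 and −4.08 gives
−2/(1/5.68 + 1/4.08) = −4.75. Legacy signed entries with magnitude < 1
(e.g. −0.88) are read by the same reciprocal convention (ratio = 1/0.88),
the only interpretation consistent with the published averages.

## Worked example

The packaged published-format panel tables ship with the package; the
`integrate` subcommand recomputes every ratio-scale average and applies
strict two-axis signature selection:

```
$ arecamir integrate
OncomiR signatures (10): miR-513a-5p, miR-615-3p, miR-589-3p, miR-135b-5p, miR-508-3p, miR-518c-5p, miR-9-5p, miR-663a, miR-506-3p, miR-509-3p
TSmiR signatures (8): miR-499a-5p, miR-190a-5p, miR-1-3p, miR-154-5p, miR-410-3p, miR-378a-5p, miR-376c-3p, miR-432-5p
```

The ten OncomiRs are miRNAs more than 2-fold up in both the exposure and
tumor axes; the eight TSmiRs are the mirrored down-regulated signatures,
headed by miR-499a-5p (average exposure fold −4.75, tumor/normal −7.97).

A fully synthetic end-to-end run (planted 2-fold effects, σ = 0.1 noise,
40 tumors / 10 normals with Beta(8, 2) purity):

```
$ arecamir run --seed 7 --out out/demo
OncomiRs=30 TSmiRs=30 edges=18 genes=18 pathways=9
```

All 30 planted concordant-up and 30 concordant-down miRNAs are recovered
as OncomiRs/TSmiRs; consensus voting keeps the planted 4-of-11 core edges
for the signature miRNAs, and the planted pathway leads the enrichment
report (`out/demo/enrichment.tsv`, with the resolved thresholds logged in
`out/demo/run_config.yaml`).

## Layout

- `src/arecamir/foldreg.py` — fold-regulation dialects and averaging
- `src/arecamir/ane.py` — paired-line screen and joint regions
- `src/arecamir/cohort.py` — purity estimation, de-mixing, t-test screen
- `src/arecamir/integrate.py` — concordance integration and signatures
- `src/arecamir/targets.py` — consensus voting and network export
- `src/arecamir/enrich.py` — over-representation and module rollup
- `src/arecamir/simulate.py` — generators with planted ground truth
- `src/arecamir/data/` — packaged published-format panel tables
- `docs/methods.md` — modelling assumptions and design choices
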