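# Methods

## Scope and model

`pdburden` re-implements, as a reusable pipeline, a cohort-genetics analysis
of early-onset Parkinsonism (EOPD; onset 25–50 years): rare-damaging variant
selection over a 127-gene neurodegeneration panel, a four-way classification
of each patient's genetic architecture, a per-subject variant-burden
comparison across diagnostic groups, an onset-age ANOVA against the number
of co-occurring variants, and carrier-based case–control odds ratios. The
design it mirrors genotyped 142 patients (all by Sanger + MLPA over
*LRRK2*/*PRKN*/*PINK1*; 54 of them additionally by panel NGS or exome
sequencing), 106 non-PD neurodegenerative patients and 124 NGS controls for
the burden comparison, and 137 exome controls for the carrier associations.

### Rare-damaging filters A–D

A variant's consequence is mapped onto {LoF, missense, other}, where LoF is
{stop gained/lost, frameshift, canonical splice, start lost}. Rarity is
`max_pop_maf < 1%` over **every** annotated reference population, strict
inequality (a variant at exactly 1% fails; the comparison operator is
configurable because the two natural readings, "< 1%" and "did not exceed
1%", differ only at this boundary). A variant with no frequency annotation
is treated as rare — an allele never observed in any reference population
cannot exceed the ceiling. The nested levels:

* **A**: rare ∧ (LoF ∨ missense)
* **B**: A, missense additionally damaging by the predictor rule
* **C**: A ∧ gene in the 17-gene core Parkinsonism list
* **D**: C ∧ the predictor rule

"Multiple lines of computational evidence" has no canonical quantification;
we require ≥ 2 damaging predictor calls **and** ≥ 50% of the non-missing
calls damaging, both configurable. LoF variants pass B/D unconditionally.

Separately, the *discovery* rule used for reporting individual variants is
filter B plus absence from the control cohort (zero control carriers). The
burden statistic deliberately does not condition on control carriers; the
two operations are distinct in the API.

### Qualifying variants and architecture groups

Per patient, qualifying variants are the de-duplicated union of (i)
discovery-selected rare damaging variants they carry, (ii) registry risk
variants carried at the registry's required zygosity, and (iii) CNV events
classified P/LP. The registry ships nine published susceptibility variants
(five in *GBA*, two in *LRRK2*, two in *PINK1*); *LRRK2* S1647T requires
homozygosity, the rest count from heterozygosity up. Registry variants are
exempt from the rarity filter when counted as co-occurrence hits: a common
susceptibility allele (S1647T, population frequency 0.31) still contributes
a hit in the oligogenic model.

Classification precedence: ≥ 2 qualifying variants → `multi_hit` (the
co-occurrence is variant-level, so two risk alleles in one gene count);
exactly one → `monogenic` for pathogenic CNVs, dominant-gene (or, by
default, candidate-gene) rare damaging variants and homozygous
recessive-gene variants; `risk_only` for registry variants and rare
damaging variants in pure risk genes (*GBA*); `single_het_ar` for a single
heterozygous rare damaging variant in a recessive gene; zero → `unresolved`.

On the reference cohort this yields 87 / 45 / 9 / 1 patients with 0 / 1 /
2 / 3 co-occurring variants. One patient (P1) carries two registry variants
(S1647T homozygous + G411S) and is therefore classified `multi_hit` by the
precedence rule, although the source tables list only nine oligogenic
patients; the stated rule is applied uniformly and the divergence is
surfaced rather than special-cased.

### Burden and group tests

Burden per subject = Σ hits over panel genes for filter-passing calls, 1
per heterozygous and 2 per homozygous call; hemizygous (haploid) genotypes
count as homozygous by default (configurable). Burden is defined only for
NGS-assayed subjects — the panel was not interrogated in Sanger-only
subjects, and those are excluded with a logged count rather than imputed
as zero. Groups (pooled controls, non-PD neurodegenerative, PD) are
compared with the ties-corrected Kruskal–Wallis H (burdens are small
integers; ties dominate, so the correction is always applied; an
all-constant pooled sample is returned as H = 0, p = 1). The onset-age
test is a classical one-way fixed-effects ANOVA over co-occurrence counts
0/1/2; patients with ≥ 3 counts are excluded and reported (a singleton
group contributes no within-group information). The count used by the
ANOVA includes registry risk variants by default; a rare-damaging-only
count is available (`include_risk=False`) because "filtered variants" is
ambiguous between the two readings.

### Carrier odds ratios

Tables are carrier-based (subjects with ≥ 1 qualifying allele), never
allele-based, with per-scope denominators: a Sanger-covered gene has
denominator 142, an NGS-only gene 54, and the control denominator is 137
(or 117 for the novel-variant scope) — the manifest carries a named
(case N, control N) pair per scope instead of a single cohort N. For a
variant whose registry risk requires homozygosity, only homozygous carriers
count. OR = ad/bc with SE(ln OR) = √(1/a+1/b+1/c+1/d), Wald 95% CI, and a
two-sided normal p from z = ln(OR)/SE. When any cell is zero the
Haldane–Anscombe correction adds 0.5 to **all four** cells before every
downstream quantity; this convention (rather than correcting only zero
cells, or always) is what reproduces the reference values 7.7, 8.9 and 2.9
from their printed counts. Report rounding is half-up: OR to 1 decimal,
p and percentages to 2.

Two p-values printed alongside zero-cell rows in the source tables (0.15
for the 4/142 vs 0/137 table and 0.65 for 1/142 vs 0/137) are not
derivable from their own counts under this or any standard formulation we
tried (we obtain 0.14 and 0.51); all eleven other OR/p pairs reproduce
exactly at the printed rounding. The package reports the values its formula
computes.

## Reference (fixture) cohort

Per-subject genotypes for the original cohort are not publicly deposited,
so cohort-wide discovery results are not reproducible from raw data. The
package instead ships a fully synthetic reference cohort
(`pdburden.fixture`) constructed to be exactly consistent with every
published count: each reported variant planted in its named carriers at the
reported zygosity, control carrier counts, sporadic/familial and sex
margins (61/48 sporadic and 17/16 familial male/female), assay assignments
(patients P1–P54 NGS-tested), and the five pathogenic CNVs. Ages at onset
of patients never listed individually were solved from the published
row-level mean-onset columns (e.g. the five T408M carriers must sum to 168
years); unnamed patients' ages are filled deterministically inside the
25–50 window so the cohort mean is 40.1. Statistics whose patient-level
inputs are neither printed nor implied by a row mean (for example the
sporadic single-risk-variant onset summary) are under-determined by the
published record and are not asserted anywhere.

## Synthetic cohort generator

`pdburden.simulate` draws seeded cohorts at the design's group sizes
(54 + 88 patients, 106 neurodegenerative, 21 + 45 + 58 controls). Defaults:

* **Planted risk variants** — the nine registry variants at carrier
  fractions equal to the published counts over their denominators,
  independent Bernoulli per eligible subject (Sanger-covered genes are
  visible in all patients, others only in the NGS subset).
* **Background** — per panel gene, Poisson(2) neutral sites; annotated
  frequencies log-uniform on [1e-5, 0.5] so both rare and common strata
  exercise the filters; ~30% of background missense sites are
  damaging-voted; carriers i.i.d. across all panel-covered subjects at a
  frequency set by `background_rate` (default 0.02 expected carriers per
  subject per gene), identical across groups — the exchangeable null for
  the burden test. Carrier frequency is deliberately decoupled from the
  annotated population frequency; the annotation exercises the filters,
  the carrier draw fixes the group structure.
* **Onset age** — `clamp(Normal(41 − |δ|·hits, 6.9), 25, 50)` with
  δ = −2 years/hit by default. Clamping (not rejection sampling) keeps
  group sizes exact; at extreme δ it inflates mass at the window edges,
  which slightly attenuates the measurable shift.
* **Familial label** — Bernoulli with logistic probability in hits
  (baseline ≈ 0.20, matching 33/142 familial).

Variant positions live on a synthetic one-contig-per-gene layout (cDNA
coordinate as position); no genome build is implied. Identical config and
seed give byte-identical output files.

What the generator does **not** emulate: linkage disequilibrium, realistic
site-frequency spectra, relatedness, annotation error, or assay-specific
missingness. Passing recovery tests therefore demonstrate correctness of
the bookkeeping and statistics under the stated sampling model, not
robustness to real-data artefacts.

## Calibration and recovery results computed by the test suite

* Type-I error of the burden Kruskal–Wallis under the null generator
  (no planted differences): 500 replicates, rejection rate asserted within
  a ±3.3 σ binomial band around 5%.
* Power of the onset-age ANOVA at δ = −5 years/hit, design sizes, 200
  seeds: estimated power printed with a binomial CI and asserted > 0.5.
* Planted carrier-frequency recovery: aggregate carriers over 200
  replicates inside exact binomial 99.9% bounds per variant.
* Planted odds recovery: the OR point estimate is strongly right-skewed at
  these counts (arithmetic mean ≈ 1.5× the truth), so recovery is checked
  on the log scale — the geometric-mean OR over 1000 replicates is within
  10% of the closed form implied by the planted fractions.

## Numerical choices and degenerate inputs

* Multi-allelic VCF records are split per alternate allele; a 1/2 genotype
  yields one heterozygous call per involved allele; `0/0` and `./.` are
  dropped, so a stored call always carries ≥ 1 hit.
* VCF floats are 32-bit; frequencies are renormalized to 6 significant
  digits at ingest so a value written as 0.01 compares exactly at the
  ceiling.
* `mean_sd` uses the n−1 sample SD and reports SD as missing for n < 2.
* Kruskal–Wallis with an all-constant pooled sample short-circuits to
  H = 0, p = 1 rather than erroring.
* Unknown consequence terms map to `other`; unknown gene symbols resolve to
  a non-panel candidate entry — both lookups are total.

## Known limitations

* The reference cohort is a reconstruction: statistics beyond those pinned
  by published counts (full burden distributions, the burden-test p-values
  of the original figure) are not reproducible and are not claimed.
* No covariate-adjusted burden regression, no exact (Fisher) test, no
  multiple-testing correction — mirroring the analysis re-implemented here,
  which applied none.
* ACMG classes and predictor calls are consumed as input annotations; the
  package computes neither.
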