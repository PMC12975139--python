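# Methods

This note documents the models, conventions and numerical choices behind
`osccohort`, and what the synthetic cohort does and does not emulate.

## The analysis model

The unit of identity throughout is the normalized variant key
(chrom, pos, ref, alt): shared trailing then leading bases are trimmed,
keeping at least one base on each side as the indel anchor, and the
position is adjusted. Normalization is idempotent, multi-allelic records
are split into per-allele keys before normalization, and all cross-sample
matching uses keys only — rsids are carried for reporting but never used
for identity, since they can be absent or merged. Only records whose FILTER
is PASS or "." enter the analysis, and only non-reference genotypes emit
calls; cohort prevalence uses presence/absence per patient, not dosage.

**Triage.** Clinical-significance strings are tokenized (split on `|` and
`,`, lowercased, spaces to underscores, slash-joined combinations expanded
to both tokens, unknown tokens preserved). The default allowlist is
`pathogenic, likely_pathogenic, risk_factor, risk_allele,
uncertain_risk_allele, likely_risk_allele, drug_response, association,
likely_association, protective, affects`. This is the union of the
classifier classes named for downstream analysis in this kind of study and
the label spellings that actually occur in curated ClinVar exports next to
them; whether the narrower seven-class reading was intended is ambiguous in
the source material, so the set is fully configurable and `likely_association`
is kept as an alias companion of `association`. Any-label matching is the
default: a multi-label record qualifies if any label qualifies.

**Origin.** Germline = key present in the matched normal; somatic = matched
normal exists but lacks the key; unclassified = no matched normal. The
cohort germline fraction is the unweighted across-patient mean of
g = germline/(germline+somatic) over paired patients, with the *population*
SD (divide by n). The SD convention is not derivable from the reference
values and is fixed here for reproducibility.

**Tumor-exclusive variants** must be somatic in ≥ 1 patient, germline in
none, and absent from every normal sample in the cohort — including
unpaired normals. The stricter absence-from-all-normals reading is
implemented because it is what "exclusively tumor specific" describes; the
frequency denominator defaults to the number of paired patients but is a
configuration knob (`paired` | `tumor`), since published percentages of
this kind are often consistent with either.

**Recurrence.** Prevalence thresholds are inclusive (≥). The denominator is
the number of patients with a tumor sample and is printed in every table,
because studies of this design quote several denominators (pairs, tumor
samples, recruited patients) and transparency beats guessing. Variants
without a gene annotation aggregate under a reserved `(intergenic)` unit
that is excluded from gene-level prevalence by default. The consequence
distribution is computed per patient first (proportions summing to 1), then
averaged across patients with the population SD.

**Staging.** Pathological TNM tokens are parsed case-insensitively with a
small alias table for data-entry variants (`Nb2 → N2b`, `AN → aN` case
folds); unknown tokens raise rather than guess. The stage rule order —
T4\* or N2+/N3\* → IV; N1 or T3N0 → III; T2N0 → II; T1N0 → I; Nx treated as
N0 with an audit warning; M ignored — was reverse-engineered from the
printed per-row TNM→stage pairs of the reference cohort and reproduces all
24 of them. Every assignment records which rule fired.

**Burden tests.** Two groups: two-sided Wilcoxon rank-sum, exact by full
enumeration of rank allocations (tie-averaged ranks, doubled smaller tail,
capped at 1) when the pooled size is ≤ 20, otherwise the normal
approximation with tie correction and no continuity correction. More
groups: tie-corrected Kruskal–Wallis (scipy), with Dunn's post-hoc
z-statistics on mean ranks using the tie-corrected pooled variance.
Dunn p-values are Bonferroni-adjusted by default (capped at 1; Holm
available); Bonferroni reproduces the all-adjusted-p-equal-1 shape that
degenerate small-cohort comparisons produce. Per-gene association across a
binary stratum uses Fisher's exact test with the point-probability
two-sided convention (sum of outcome probabilities ≤ the observed table's),
then Benjamini–Hochberg across genes; degenerate margins give p = 1.

**PRS.** Base summary statistics need SNP/A1/A2/P and BETA or OR (natural
log applied); the inclusion p-threshold defaults to 1.0 (all SNPs) and no
LD clumping is performed — an LD reference panel is outside desk scope, so
the scoring reproduces additive semantics only. When target allele codings
are supplied, swapped A1/A2 pairs are dosage-flipped (d → 2−d), complement
pairs are strand-folded first, and palindromic A/T / C/G SNPs are excluded
with a logged count. Missing dosages are imputed with twice the cohort
effect-allele frequency; an individual with no observed dosage at any
shared SNP gets a missing score. Quartiles are contiguous score-ordered
blocks with sizes as equal as possible, remainder individuals allocated to
the lowest quartiles first (configurable), ties broken by stable
individual-id order, Q1 the reference. Case enrichment per quartile uses
the Pearson chi-square without continuity correction on the 2×2 table,
1 df. The published Q1-vs-Q2 and Q1-vs-Q3 statistics (2.04, 4.15) are
reproduced exactly by equal quartiles of 56 with the printed case
distribution (0/2/4 cases); the printed Q1-vs-Q4 value (17.6) is not
consistent with any single quartile-size split that also reproduces the
other two, so it is not asserted anywhere.

## The synthetic cohort

The generator emulates the *post-annotation statistical structure* of an
FFPE matched-pair exome study; its defaults are the study conditions:

| parameter | default | source/rationale |
|---|---|---|
| pairs / tumor-only / normal-only | 14 / 5 / 2 | study design (19 tumor, 16 normal samples) |
| relevant variants per patient | truncated Normal(171, 14) on [150, 197], rounded | printed mean and range; SD chosen to fit the range (no distribution is published; the outlying printed low count of 132 conflicts with the printed range, so the bounds stay configurable) |
| germline fraction per patient | Normal(0.933, 0.039) truncated to [0, 1] | printed cohort mean ± SD across patients |
| consequence mixture | intron 0.56, missense 0.12, non-coding transcript 0.10, regulatory 0.08, synonymous 0.06, splice region 0.05, frameshift 0.025, stop-gained 0.005 | printed leading proportions; remainder split over the categories the study names, stop-gained < 1 % |
| core genes | the 21 genes reported mutated in every patient | planted with one qualifying variant in every tumor patient |
| gene prevalence spectrum | PERM1/ITPKB 0.95, XRCC1 0.80, TP53 0.24, CDKN2A 0.14, EGFR 0.05 | reported catalogue/driver gene frequencies; carriers planted as exact rounded counts so recovery is exact |
| exclusive variants | 10 planted at fractions 1.0, 0.46×2, 0.31×2, 0.23×5 with their published identities and annotations | the published tumor-exclusive table |
| PRS | 5,341 SNPs, 21 cases + 204 controls, β ~ N(0, 0.02), base allele frequencies U(0.1, 0.9), case shift 0.0067 | the study's merged-panel dimensions; see below |

Origins are per-variant Bernoulli draws at the patient's germline fraction,
except planted exclusives, which are forced somatic and never written to
any normal VCF. Two consistency mechanisms keep truth recovery exact:

* the Bernoulli probability for non-exclusive variants is conditioned
  upward (g′ = g·n/(n−n_excl), capped at 1) so the forced-somatic
  exclusives do not bias the patient-level germline fraction below its
  drawn value;
* after all origins are drawn, any *non-planted* variant that happens to be
  somatic in every carrier and absent from every normal — which would be
  indistinguishable from a planted exclusive — has one carrier flipped to
  germline (and added to that normal VCF), so the exclusive set recovered
  at any threshold is exactly the planted one.

The PRS case shift was set analytically, once, from the distribution shape
implied by the published quartile case counts (0/2/4/15 of 21): the score
SD under the defaults is ≈ √(m·σ_β²·E[2p(1−p)]) ≈ 0.92 and the case–control
mean separation is 2·shift·Σ|β| ≈ 170·shift, so shift = 0.0067 targets a
≈ 1.24 SD separation, which places ≈ 71 % of cases above the 75th
percentile. With 21 cases the realized top-quartile count varies by
several patients across seeds; tests therefore assert the ordering
properties (positive separation, non-decreasing case proportion with
quartile), not the exact count.

Clinical covariates are sampled from the packaged 24-row reference table's
empirical pools (TNM strings with their Mx/Nx and data-entry quirks, age
≈ Normal(54.8, 10.1), 2:1 male:female, site pool). Variants live on a
fictitious chr1–chr22 coordinate system with per-contig positions drawn
without replacement and alleles drawn from ACGT (indels 1–3 bp); no
reference FASTA is needed, and left-alignment beyond parsimony trimming is
therefore out of scope. One seeded generator drives named sub-streams
(universe, patients, clinical, PRS), so identical seeds give byte-identical
bundles.

**What the generator does not emulate** — and hence what passing tests do
not show about real data: read-level error processes and FFPE artifact
chemistry (C>T deamination), copy-number and structural variation, LD
between PRS SNPs, transcript-level annotation multiplicity (one consequence
per variant), and any correlation between clinical covariates and the
mutation profile (covariates are drawn independently, which is also why
null burden tests are the calibrated expectation on synthetic data).

## Problem sizes and determinism

The default test suite generates one study-scale bundle (14 pairs, ~171
variants/patient, 5,341-SNP PRS over 225 individuals; ~2 s to generate and
analyze) and one small bundle (4 pairs, ~40 variants/patient) shared across
tests, plus 20 small replicate cohorts for the mixture-recovery check.
Exact rank-sum enumeration is limited to pooled n ≤ 20 (C(20,10) ≈ 1.8×10⁵
allocations); beyond that the tie-corrected normal approximation is used.
All stochastic tests run under fixed seeds; hypothesis properties are
derandomized.

## Known limitations

* Origin classification is presence-based; no allele-frequency (VAF)
  thresholds, tumor-purity correction or FFPE artifact filtering.
* One tumor and at most one normal sample per patient.
* The reported germline SD convention (population SD) and the exclusivity
  denominator are choices where the reference material is silent; both are
  documented and the latter is configurable.
* PRS scoring has no ancestry correction and no best-fit threshold search.
* Nuclear-receptor percentage columns in the source tables are internally
  inconsistent with their counts; only counts are computed here, with the
  unknown flag ("-") folded to "no".
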