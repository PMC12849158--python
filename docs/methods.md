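# Methods

## Setting and scope

The package analyses a small, deeply sequenced, case-only cohort after
variant calling and annotation are done: every input sample is an affected
individual; there are no controls. Upstream steps — alignment, joint calling,
contamination estimation, VEP-style annotation, and posterior shrinkage of
GWAS effect sizes into a score weights table — are consumed as inputs, never
recomputed. Downstream clinical judgment (ACMG classification, read-level
phasing of compound heterozygotes) is deliberately left to manual review:
candidates are emitted with their complete evidence tuple instead.

## Data model

A cohort is a list of biallelic `VariantRecord`s (multiallelic sites are
decomposed on read; alleles of a different alt are counted as reference, and
inputs are assumed left-normalized upstream). Each record holds per-sample
`GenotypeCall`s (GT state, DP, AD) and one `AnnotationSet` per overlapped
gene — mirroring a single most-relevant consequence per (allele, gene).
Coordinates are 1-based inclusive throughout; half-open interval inputs are
converted at the reader boundary. The annotation sub-field order is parsed
from the VCF header, not hard-coded, and unknown sub-fields are ignored.

Missing annotation scores stay *absent* (`None`), never 0: a filter that
needs a score fails when the score is absent. The one exception is the
reference-population allele frequency, where absence means the variant was
never observed — i.e. it is maximally rare — and is treated as 0.

## Sample QC

**Sex check.** Over non-PAR X sites (GRCh38 PAR1/PAR2 by default,
configurable), the inbreeding coefficient per sample is
`F = (O_hom − E_hom) / (L − E_hom)` with `E_hom = Σ_l (1 − 2 p_l (1 − p_l))`
over that sample's called sites; hemizygous calls count as homozygous.
Allele frequencies `p_l` are estimated from female-reported samples only,
because male hemizygosity would bias `p` on X (if no females are present,
all samples are used). Inference: male iff `F > 0.8`; female iff
`−0.2 ≤ F < 0.2`; everything else — including an anomalous `F < −0.2`, which
signals excess heterozygosity rather than either sex — is undetermined.
Mismatch flags: a reported female with `F` outside `[−0.2, 0.2]`; a reported
male with `F ≤ 0.2` (female-consistent or anomalous territory). A reported
male with intermediate `F` in `(0.2, 0.8]` is left undetermined for review
without a mismatch flag. A floor of 50 informative sites (configurable)
guards the estimate.

**Kinship.** The KING-robust between-family estimator
`φ = (N_het,het − 2·N_opp_hom) / (N_het(i) + N_het(j))` over shared
non-missing autosomal diploid sites (floor 200, configurable); `φ ≥ 0.044`
flags a pair as related. Duplicates sit at φ ≈ 0.5 exactly (no opposite
homozygotes), first-degree pairs near 0.25. Flagged pairs are reported, not
auto-dropped (a config switch exists): in the modelled setting no sample was
excluded for relatedness. At desk scale the estimator is noisy — with
~2,500 sites sd(φ) ≈ 0.017 for unrelated pairs, so a handful of unrelated
pairs in a 110-sample cohort will exceed 0.044 by chance; planted duplicate
and parent-offspring pairs remain separated from that noise by an order of
magnitude. At 5,000 sites with allele frequencies uniform on (0.1, 0.9) the
dispersion is sd(φ) ≈ 0.0126 (per-site numerator variance `12p²q²`), so
about 91% of unrelated pairs fall within ±0.02 — a useful calibration figure
when reading the dispersion checks.

**Call rate.** Non-missing calls / total variants; pass at ≥ 98% (boundary
inclusive).

## Ancestry

Variants with alternate-allele frequency below 0.1 are excluded before
pruning and PCA. This is the rule as specified for the modelled workflow —
on the *alternate* allele, not the folded minor allele — and it is unusually
aggressive; the cutoff is a parameter (`af_filter(min_af=...)`) for users who
want a conventional MAF filter instead.

LD pruning is the classic sliding-window VIF scheme: windows of 50 variants
advancing by 5; within a window, greedily remove the variant with the largest
VIF (`1/(1−R²)` from regressing its genotype on the other live window
variants) until all VIF ≤ 1.5 (r² ≈ 0.33). Ties and exact duplicates resolve
toward the later position. The original tool's removal order is unspecified;
greedy largest-first is this package's documented dialect. Note that with
n ≈ 110 samples and 50-variant windows, chance multicollinearity alone
produces VIFs above 1.5, so roughly half of even independent variants are
pruned — a property of the VIF criterion at this n/window ratio, shared with
the modelled workflow, not a defect.

Cohort and reference genotypes are combined and decomposed jointly (not
projected; a projection mode exists but is non-default), each variant
standardized by mean `2p̂` and scale `√(2p̂(1−p̂))` from the combined data;
monomorphic variants are dropped with a log entry; missing genotypes are
mean-imputed before standardization. The top 20 components feed a
500-tree random forest (seed 1914 by default) trained on the reference
samples' scores with super-population labels as outcomes; each cohort sample
receives its highest-vote class and vote fraction. No abstention threshold is
applied by default (the rule is plain highest-vote); one can be enabled.
The EUR subset is exactly the set of samples whose highest-vote class is EUR.

## Polygenic score

Weights are matched to cohort variants by exact (chrom, pos, ref, alt) key —
no strand-flip or ambiguous-allele resolution; mismatches are dropped and
counted. Entries on variants with call rate ≤ 98% (strict) or whose effect
allele is neither ref nor alt are dropped likewise. The score is the
weighted sum of effect-allele dosages (0/1/2 diploid, 0/1 hemizygous);
missing genotypes are imputed at `2·p̂` cohort effect-allele frequency
(sum mode with imputation is the default, mirroring the referenced scoring
tool's default family; average and no-imputation modes are switches).

## Prioritization cascade

Gates run in a fixed order; each candidate records the full evidence tuple
and re-running the decision on that tuple reproduces it (tested):

1. **Region** — keep variants inside any panel gene region (regions are
   expected pre-extended ±200 bp beyond the UTRs); a variant overlapping two
   panel genes is evaluated once per gene.
2. **Cohort AF** — drop variants at ≥ 10% within-cohort frequency
   (hemizygous calls contribute one allele), or with undefined AF.
3. **Functional class** — first match wins: HIGH impact → pLoF; missense
   consequence with CADD > 20 → missense; SpliceAI max Δ > 0.5 → splice.
   All comparisons strict.
4. **Population AF** — gnomAD-style AF < 1e-3 (recessive) or < 1e-4
   (dominant), strict; absent AF passes both.
5. **ClinVar rescue** — Pathogenic / Likely pathogenic / combined assertions
   (case-normalized) bypass gates 3–4 regardless of allele frequency. They do
   *not* bypass genotype QC or zygosity retention: the final variant sets the
   rescue feeds into are zygosity-defined.
6. **Genotype QC** — allelic balance > 95% for hom/hemi calls; 25–75% for het
   calls with ≥ 4 reads supporting each allele (the read-count rule binds to
   heterozygotes only, as in the sentence that defines it); undefined balance
   fails. Diploid het calls for males on non-PAR X are inconsistent and are
   excluded with a log entry.
7. **Retention** — dominant: heterozygotes only. Recessive: homozygotes and
   hemizygotes, plus every member of a (sample, gene) group with ≥ 2
   qualifying heterozygotes, labelled `compound_het_member` and
   `phase_unknown` (cis/trans adjudication is manual downstream). The
   group threshold is read as ≥ 2 — compound heterozygosity needs exactly
   two hits — and is configurable. On X, female homozygotes are retained and
   female het pairs count toward compound candidates (standard practice).

The **clinical approach** evaluates established-IEI panel genes under their
reported inheritance (AD → dominant, AR → recessive, AD/AR → both,
XLR → recessive); genes lacking a label are skipped with a log entry. The
**research approach** evaluates every panel gene under both models, so its
candidate set is a superset of the clinical one on shared genes (tested).

## Deletion screen

Within a target region (default the TLR7 locus, chrX:12,760,551–12,980,636),
male samples are scanned across region variant sites in position order for
maximal runs of consecutive sites with missing genotype or zero depth. Runs
of ≥ 5 sites (configurable; the source analysis was qualitative/visual, so
the floor is this package's operational choice) are reported with run
coordinates and the fraction of region sites covered.

## Association

Case-only logistic regressions: outcome age < 40 years (boundary age 40
falls in the older group) or rare-candidate carrier status; primary predictor
the PRS, z-standardized within each analyzed subset by default (affects the
coefficient scale, not the p-value; a switch disables it), adjusting for sex
and ten PCs; secondary models add BMI, then BMI + smoking, with listwise
deletion and `n_used` reported. Every model runs on the full cohort and the
EUR subset. Fitting is Newton/IRLS (tol 1e-8, ≤ 100 iterations) with
observed-information standard errors; `p = 2(1 − Φ(|β/se|))`; 95% CI is Wald
with z = 1.96 (profile likelihood out of scope). Perfect separation, a
degenerate outcome, or fewer than 5 events refuse the model with a message
rather than reporting an unstable fit. Cohort summaries use the printed
category definitions (age decades; BMI 18.5–24.9 / 25–29.9 / 30–39.9; WHO
10 = dead, 6–9 = severe, 4–5 = moderate; NA as its own category) with
percentages rounded half-up to one decimal — the convention that reproduces
all checkable published-style percentages exactly.

## Synthetic cohorts

The generator emulates exactly the structure the pipeline assumes, under
fixed default conditions chosen to mirror the modelled study: 110 samples,
82 male, 85 of the EUR-like population (two cohort populations at
Balding–Nichols F_ST = 0.15 against a shared ancestral frequency uniform on
(0.05, 0.95); a three-population reference panel of 100 samples each,
standing in for a public reference panel); 2,500 autosomal background
variants plus ~120 non-PAR X sites, 30 common sites in the TLR7 region, and
a handful of benign common panel variants (~3,000 sites total); depths
`DP ~ max(10, Poisson(30))` echoing 30× genomes; heterozygous allelic
balance ~ Beta(50, 50) clamped into the QC window, homozygous error ~ 1% of
reads capped below the 95% threshold — so every non-planted call passes
genotype QC by construction, and planted bad-balance/low-depth controls
violate it deliberately.

Planted content, each with a truth row: one retention instance per cascade
class (dominant pLoF, dominant missense, splice, recessive hom, recessive
hemi in an X-linked gene, a two-site compound-het pair, a common ClinVar
rescue, a dominant het in a recessive-labelled gene) and near-miss controls
placed just outside one boundary each (CADD 19.9; SpliceAI 0.49; population
AF exactly at the dominant cutoff; het balance 0.96; 3 reference reads;
cohort AF exactly 10%); eleven further plain dominant-pass variants bring
the distinct carrier count to the study's 19 of 110. Compound-het members
planted at the class's reference AF (1e-5) legitimately also qualify as
dominant heterozygotes, and the truth table records both expectations. One
duplicate pair, one parent-offspring pair (one transmitted allele), one
reported-female genetic male, and one 8-site missing/DP=0 run in a male's
TLR7 region are planted for the QC and CNV stages.

The weights file (1,000 entries, a desk-scale stand-in for a genome-wide
predictor; 10% with the effect on the reference allele; five entries on
low-call-rate variants and five unmatched keys to exercise scoring QC) is
coupled to age by construction: ages are assigned from each sample's raw
score through a logistic model with log-OR −2.0 per score SD for being under
40 (intercept set to the study's 42/110 young fraction), giving the
association stage a planted signal of known direction. Carrier samples are
drawn from the low-score half in randomized order, so the carrier group's
score distribution is shifted down without being perfectly separable — a
separable carrier set would make the carrier model unfittable, which is a
property of logistic regression, not of the biology being emulated.
Phenotype categories (BMI, smoking, vaccination, WHO) are quota-assigned to
the study's printed frequencies with independent shuffles per block, so
missingness patterns are unlinked across covariates.

**What the generator does not emulate** — and therefore what passing tests
do not establish about real data: linkage disequilibrium (variants are
independent within population, so pruning behaviour on really correlated
markers is only exercised by constructed unit fixtures), sequence content
and alignment artefacts, genotyping error correlated with context,
population substructure beyond two/three discrete clusters, age-genotype
confounding other than the planted score coupling, and any realistic effect
sizes: planted effects are strong by design so that direction recovery at
n = 110 is a sharp test of the machinery, not of statistical power.

## Numerical and degenerate-input choices

Fixed seed ⇒ bit-identical outputs, including written files (no timestamps;
run manifests carry a config hash and the seed instead). VIF computation
inverts the window correlation matrix and falls back to per-variant
least-squares with an explicit ∞ for exact collinearity; the later-positioned
duplicate is removed first. PCA uses full SVD on the standardized matrix
(cohorts of this scale need no randomized solver) and reports scores `U·S`.
All-missing records, zero-read balance, empty regions, empty weight tables,
zero-sample configs, and single-class reference panels all have explicit,
tested behaviours (logged exclusion, failure of the QC gate, warning plus
empty result, zero scores, empty bundles, and a hard error respectively).

## Known limitations

Decomposition assumes upstream normalization and does not left-align.
Kinship at a few thousand sites is indicative, not confirmatory (see the
dispersion figures above). The case-only design cannot estimate absolute
risk, and no multiple-testing correction is applied across the exploratory
association battery — nominal p-values are reported, as in the modelled
analysis. Gene-burden testing is out of scope by design.
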