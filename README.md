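# covrare

Post-variant-calling analysis for small, deeply sequenced case-only cohorts
of severe COVID-19 — or any rare-disease-style cohort where the questions
are: *is a monogenic cause hiding in a candidate gene panel, and does common
polygenic background modulate who gets severely ill?*

The package implements, as a tested and reusable library + CLI:

- **Sample QC** — sex concordance via the X-chromosome inbreeding coefficient
  `F = (O_hom − E_hom)/(L − E_hom)` (males `F > 0.8`, females `F < 0.2`,
  mismatch window ±0.2), pairwise relatedness with the KING-robust estimator
  `φ = (N_het,het − 2·N_opp_hom)/(N_het(i) + N_het(j))` (related at
  `φ ≥ 0.044`), and per-sample call rate (pass at ≥ 98%).
- **Ancestry inference** — alt-AF ≥ 0.1 retention, sliding-window VIF pruning
  (window 50, step 5, VIF ≤ 1.5, i.e. r² ≈ 0.33), joint PCA with a labelled
  reference panel (variants standardized by mean `2p̂`, scale `√(2p̂(1−p̂))`),
  and a 500-tree random-forest vote over the top 20 PCs assigning each sample
  its highest-vote super-population; the EUR subset is defined from that label.
- **Polygenic risk scoring** — `PRS_s = Σ_v w_v d_{s,v}` over a weights table,
  with exact-key matching, per-variant call-rate QC (> 98%), effect-allele
  orientation on ref or alt, and `2p̂` imputation of missing genotypes.
- **Rare-variant prioritization** — the two-model cascade over a gene panel:
  region subsetting (regions pre-extended ±200 bp), cohort AF < 10%,
  functional class (pLoF by HIGH impact, else missense with CADD > 20, else
  SpliceAI Δ > 0.5), model-specific gnomAD AF gates (recessive < 1e-3,
  dominant < 1e-4), ClinVar pathogenic/likely-pathogenic rescue regardless of
  AF, allelic-balance genotype QC (hom/hemi > 95%; het 25–75% with ≥ 4 reads
  per allele), and zygosity retention (dominant: het; recessive: hom/hemi plus
  ≥ 2-het compound candidates per sample and gene, emitted phase-unknown).
  A *clinical* mode honours each gene's reported inheritance; a *research*
  mode evaluates every gene under both models.
- **Deletion screen** — runs of consecutive sites with missing genotypes or
  zero depth across the TLR7 locus (chrX:12,760,551–12,980,636) in males,
  the coverage signature of a hemizygous deletion.
- **Case-only association** — logistic models of age group (< 40 vs ≥ 40) and
  rare-candidate carrier status on standardized PRS, adjusted for sex and ten
  PCs (secondary models add BMI and smoking), with Wald tests, on the full
  cohort and the EUR subset; plus Table-1-style cohort summaries with
  half-up percentage rounding.
- **Synthetic cohorts** — a generator (`covrare.cohortsim`) that emulates the
  statistical structure all of the above assumes (two-population
  Balding–Nichols ancestry, sex-consistent X genotypes, QC-calibrated
  read depths, planted candidates of every retention class with near-miss
  controls, planted deletions, duplicates, parent-offspring pairs, sex swaps,
  and an age-coupled score distribution), with machine-readable truth tables.
  Real patient genomes in this setting are access-controlled; the generator
  is the test substrate.

## Worked example

```python
from covrare.cohortsim import SimConfig, simulate_cohort
from covrare.rarevar import run_research_approach
from covrare.assoc import run_pipeline

sim = simulate_cohort(SimConfig(seed=1))
sexes = dict(zip(sim.truth.samples.sample_id, sim.truth.samples.true_sex))
cands = run_research_approach(sim.records, sim.panel, sexes)
print(len(cands), "candidates;",
      sum(c.model == "dominant" for c in cands), "dominant")
run_pipeline({"seed": 1}, "out")
```

prints `22 candidates; 18 dominant` — the 22 planted retentions (and nothing
else) recovered from ~3,000 variants in 110 samples, and writes the full
output bundle (`qc.tsv`, `pcs.tsv`, `labels.tsv`, `prs.tsv`,
`candidates.tsv`, `cnv.tsv`, `assoc.tsv`, `summary.tsv`, ...) to `out/`.
The association table there includes, for the default cohort,

```
outcome    subset  model    or      p_wald  n_used
age_lt_40  full    primary  0.0671  0.0000  110
carrier    full    primary  0.3036  0.0016  110
```

— the planted inverse PRS–age and PRS–carrier effects, recovered with the
expected direction (odds ratios are per standard deviation of score).

The same stages are available as CLI subcommands:

```sh
covrare simulate --seed 1 --out-dir data
covrare sampleqc --vcf data/cohort.vcf --samples data/samples.tsv --out qc.tsv
covrare prioritize --vcf data/cohort.vcf --panel data/panel.tsv \
    --samples data/samples.tsv --approach research --out candidates.tsv
covrare cnv-screen --vcf data/cohort.vcf --samples data/samples.tsv --out cnv.tsv
covrare run --config pipeline.yaml --out-dir results
```

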