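"""Synthetic severe-COVID-19 cohort generator with machine-readable truth tables.

Emulates the statistical structure the downstream pipeline assumes, at desk
scale: two-population ancestry structure (Balding–Nichols allele-frequency
divergence, Hardy–Weinberg genotypes within population), sex-consistent X
genotypes (males hemizygous outside the PARs), read-depth/allele-depth fields
tuned to the genotype-QC thresholds, planted rare candidate variants of every
zygosity class (including near-miss controls sitting just outside each filter
boundary), planted multi-site deletions, planted duplicate / parent-offspring /
sex-mismatch samples, and a polygenic-score weights file whose score
distribution is coupled to age group by construction.

Everything is deterministic for a fixed seed.  The generator does not emulate
linkage disequilibrium, sequence content or read-level error; what passing
tests show about real data is discussed in the methods note.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .variantio import (
    AnnotationSet,
    GenePanelEntry,
    GenotypeCall,
    SampleRecord,
    VariantRecord,
    WeightEntry,
    compute_cohort_af,
    write_cohort_vcf,
    write_gene_panel,
    write_sample_sheet,
    write_weights,
)

__all__ = [
    "SimConfig",
    "PlantedSpec",
    "TruthTable",
    "SimResult",
    "default_panel",
    "default_planted_specs",
    "simulate_cohort",
    "plant_deletion",
]

#: TLR7 locus screened for hemizygous deletions (GRCh38, gene ±200 bp).
TLR7_REGION = ("chrX", 12_760_551, 12_980_636)

_CHROM_ORDER = {f"chr{i}": i for i in range(1, 23)} | {"chrX": 23, "chrY": 24}


def default_panel() -> list[GenePanelEntry]:
    """Candidate-gene panel: type-I-IFN IEI genes with reported inheritance,
    GWAS-prioritized severity genes, and the two genes shared by both sets.
    Regions are synthetic desk-scale stand-ins near the real GRCh38 loci,
    already extended ±200 bp beyond the UTRs."""
    e = GenePanelEntry
    return [
        e("TICAM1", "chr19", 4_815_736, 4_831_704, "AD", "IEI"),
        e("NFKB2", "chr10", 102_394_110, 102_402_529, "AD", "IEI"),
        e("AIRE", "chr21", 44_285_638, 44_298_648, "AD_AR", "IEI"),
        e("IRF7", "chr11", 612_355, 615_900, "AR", "IEI"),
        e("UNC93B1", "chr11", 67_991_900, 68_005_100, "AR", "IEI"),
        e("IKBKG", "chrX", 154_541_000, 154_565_000, "XLR", "IEI"),
        e("TLR7", "chrX", TLR7_REGION[1], TLR7_REGION[2], "XLR", "IEI"),
        e("TYK2", "chr19", 10_350_327, 10_380_676, "AR", "BOTH"),
        e("IFNAR2", "chr21", 33_229_902, 33_265_261, "AR", "BOTH"),
        e("THBS3", "chr1", 155_195_531, 155_210_330, "AD_AR", "GWAS"),
        e("SLC22A31", "chr16", 89_193_600, 89_203_900, "AD_AR", "GWAS"),
        e("MTX1", "chr1", 155_213_000, 155_222_000, "AD_AR", "GWAS"),
    ]


@dataclass(frozen=True)
class PlantedSpec:
    """One planted rare-variant scenario with its expected cascade outcome."""

    name: str
    gene: str
    zygosity: str  # het | hom | hemi | compound_het (two het sites)
    consequence: str = "missense_variant"
    impact: str = "MODERATE"
    cadd: float | None = None
    spliceai: float | None = None
    pop_af: float | None = 1e-5
    clinvar: str | None = None
    model: str = "dominant"  # model under which expected_retained is stated
    expected_retained: bool = True
    expected_reason: str = ""
    # genotype-QC overrides: (ref_depth, alt_depth); None → QC-clean draw
    depths: tuple[int, int] | None = None
    n_carriers: int = 1  # het carriers planted (cohort-AF control uses many)


def default_planted_specs() -> list[PlantedSpec]:
    """One planted instance per retention class plus near-miss controls.

    Controls sit just outside one filter boundary each: CADD 19.9 vs the
    strict >20 rule; SpliceAI 0.49 vs >0.5; population AF exactly at the
    dominant 1e-4 cutoff (strict <); heterozygous allelic balance 0.96 vs the
    25–75% window; alt-supporting reads present but reference reads below the
    minimum of 4; within-cohort AF exactly at the 10% exclusion boundary.
    """
    P = PlantedSpec
    return [
        P("dominant_plof", "TICAM1", "het", consequence="stop_gained",
          impact="HIGH", cadd=35.0, pop_af=1e-6, model="dominant",
          expected_reason="pLoF"),
        P("dominant_missense", "THBS3", "het", cadd=33.0, pop_af=2.478e-6,
          model="dominant", expected_reason="missense_cadd"),
        P("splice_pass", "SLC22A31", "het", consequence="intron_variant",
          impact="MODIFIER", spliceai=0.62, pop_af=1e-5, model="dominant",
          expected_reason="splice_ai"),
        P("recessive_hom", "IRF7", "hom", cadd=24.0, pop_af=5e-4,
          model="recessive", expected_reason="missense_cadd"),
        P("recessive_hemi", "IKBKG", "hemi", cadd=25.4, pop_af=2.751e-5,
          model="recessive", expected_reason="missense_cadd"),
        P("compound_het", "UNC93B1", "compound_het", cadd=25.0, pop_af=1e-5,
          model="recessive", expected_reason="missense_cadd"),
        P("clinvar_rescue", "NFKB2", "het", cadd=12.0, pop_af=5e-3,
          clinvar="Pathogenic", model="dominant",
          expected_reason="clinvar_rescue"),
        P("dominant_in_ar_gene", "IRF7", "het", cadd=26.0, pop_af=5e-5,
          model="dominant", expected_reason="missense_cadd"),
        P("near_miss_cadd", "AIRE", "het", cadd=19.9, pop_af=1e-5,
          model="dominant", expected_retained=False),
        P("near_miss_spliceai", "MTX1", "het", consequence="intron_variant",
          impact="MODIFIER", spliceai=0.49, pop_af=1e-5, model="dominant",
          expected_retained=False),
        P("near_miss_popaf", "TYK2", "het", cadd=25.0, pop_af=1e-4,
          model="dominant", expected_retained=False),
        P("near_miss_ab_het", "IFNAR2", "het", cadd=25.0, pop_af=1e-5,
          depths=(1, 24), model="dominant", expected_retained=False),
        P("near_miss_depth", "AIRE", "het", cadd=25.0, pop_af=1e-5,
          depths=(3, 20), model="dominant", expected_retained=False),
        P("near_miss_ab_hom", "IRF7", "hom", cadd=24.0, pop_af=5e-4,
          depths=(3, 27), model="recessive", expected_retained=False),
        P("recessive_single_het", "UNC93B1", "het", cadd=25.0, pop_af=5e-4,
          model="recessive", expected_retained=False),
        P("cohort_af_control", "NFKB2", "het", cadd=25.0, pop_af=1e-5,
          n_carriers=22, model="dominant", expected_retained=False),
    ]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults mirror the modelled study: 110 hospitalized cases, 82 male,
    roughly 85 of European-like ancestry, WHO severity 4–10, whole-genome
    depth averaging 30x, and a weights file of 1,000 entries (a desk-scale
    stand-in for a genome-wide predictor)."""

    seed: int
    n_samples: int = 110
    male_fraction: float = 82 / 110
    young_fraction: float = 42 / 110  # age < 40 years
    n_background_variants: int = 2500
    n_x_sites: int = 120
    n_region_sites: int = 30
    fst: float = 0.15
    ancestry_fractions: dict[str, float] = field(
        default_factory=lambda: {"EUR": 85 / 110, "SAS": 25 / 110}
    )
    ref_pops: tuple[str, ...] = ("EUR", "SAS", "AFR")
    n_ref_per_pop: int = 100
    planted: list[PlantedSpec] = field(default_factory=default_planted_specs)
    n_benign_panel_variants: int = 10
    deletion_run: int = 8
    n_deletion_samples: int = 1
    n_duplicate_pairs: int = 1
    n_parent_offspring_pairs: int = 1
    n_sex_mismatch: int = 1
    # additional straightforward dominant-pass carriers so the cohort reaches
    # the study's 19 rare-candidate carriers of 110
    n_extra_carrier_variants: int = 11
    n_weights: int = 1000
    weight_scale: float = 0.1
    ref_effect_fraction: float = 0.1  # weights whose effect allele is REF
    age_log_or: float = -2.0  # log-odds of age<40 per SD of score
    n_lowcall_weight_variants: int = 5
    n_unmatched_weights: int = 5
    carrier_low_prs: bool = True
    mean_depth: float = 30.0
    min_depth: int = 10

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        for name, frac in [
            ("male_fraction", self.male_fraction),
            ("young_fraction", self.young_fraction),
            *[(f"ancestry_fractions[{k}]", v) for k, v in self.ancestry_fractions.items()],
        ]:
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if not 0.0 <= self.fst < 1.0:
            raise ValueError("fst must be in [0, 1)")
        if abs(sum(self.ancestry_fractions.values()) - 1.0) > 1e-9:
            raise ValueError("ancestry_fractions must sum to 1")


@dataclass
class TruthTable:
    """Machine-readable ground truth for every planted feature."""

    samples: pd.DataFrame  # sample_id, true_sex, true_pop, true_age_group
    variants: pd.DataFrame  # planted candidates with expected cascade outcome
    related_pairs: pd.DataFrame  # sample_i, sample_j, relationship
    sex_mismatches: pd.DataFrame  # sample_id, true_sex, reported_sex
    deletions: pd.DataFrame  # sample_id, run_start, run_end, n_sites


@dataclass
class SimResult:
    """In-memory bundle from :func:`simulate_cohort`."""

    config: SimConfig
    sample_ids: list[str]
    records: list[VariantRecord]
    samples: list[SampleRecord]
    panel: list[GenePanelEntry]
    weights: list[WeightEntry]
    ref_genotypes: pd.DataFrame  # variants × reference samples, dosage 0/1/2
    ref_labels: pd.Series  # super-population label per reference sample
    truth: TruthTable
    lowcall_weight_keys: list[tuple]

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {
            "vcf": out / "cohort.vcf",
            "samples": out / "samples.tsv",
            "panel": out / "panel.tsv",
            "weights": out / "weights.tsv",
            "ref_genotypes": out / "ref_genotypes.tsv",
            "ref_labels": out / "ref_labels.tsv",
            "truth_samples": out / "truth_samples.tsv",
            "truth_variants": out / "truth_variants.tsv",
            "truth_related": out / "truth_related_pairs.tsv",
            "truth_sex_mismatch": out / "truth_sex_mismatches.tsv",
            "truth_deletions": out / "truth_deletions.tsv",
        }
        write_cohort_vcf(self.records, self.sample_ids, paths["vcf"])
        write_sample_sheet(self.samples, paths["samples"])
        write_gene_panel(self.panel, paths["panel"])
        write_weights(self.weights, paths["weights"])
        self.ref_genotypes.to_csv(paths["ref_genotypes"], sep="\t")
        self.ref_labels.rename("pop").to_csv(paths["ref_labels"], sep="\t")
        self.truth.samples.to_csv(paths["truth_samples"], sep="\t", index=False)
        self.truth.variants.to_csv(paths["truth_variants"], sep="\t", index=False)
        self.truth.related_pairs.to_csv(paths["truth_related"], sep="\t", index=False)
        self.truth.sex_mismatches.to_csv(paths["truth_sex_mismatch"], sep="\t", index=False)
        self.truth.deletions.to_csv(paths["truth_deletions"], sep="\t", index=False)
        return paths


# ---------------------------------------------------------------------------
# low-level draws


def _quota_counts(n: int, fractions: Sequence[float]) -> list[int]:
    """Largest-remainder apportionment of n into len(fractions) bins."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(x)) for x in raw]
    short = n - sum(counts)
    order = np.argsort([-(x - math.floor(x)) for x in raw], kind="stable")
    for i in range(short):
        counts[order[i]] += 1
    return counts


def _balding_nichols_freqs(rng, n_variants: int, pops: Sequence[str], fst: float):
    """Per-population allele frequencies under a two-level Balding–Nichols
    model: ancestral p ~ U(0.05, 0.95); each population draws
    Beta(p(1-F)/F, (1-p)(1-F)/F)."""
    p_anc = rng.uniform(0.05, 0.95, n_variants)
    freqs = {}
    for pop in pops:
        if fst == 0.0:
            freqs[pop] = p_anc.copy()
        else:
            a = p_anc * (1 - fst) / fst
            b = (1 - p_anc) * (1 - fst) / fst
            freqs[pop] = rng.beta(a, b)
    return p_anc, freqs


def _draw_depth(rng, n: int, mean: float, floor: int) -> np.ndarray:
    return np.maximum(rng.poisson(mean, n), floor)


def _ad_arrays(rng, gts: Sequence[str], depths: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized (ref_depth, alt_depth) draws that satisfy the genotype-QC
    thresholds for each genotype state: heterozygotes get allelic balance
    within 25–75% with ≥4 reads on each allele; homozygous/hemizygous calls
    get >95% support for the called allele; missing calls get zero reads."""
    nloc = len(gts)
    ab = rng.beta(50, 50, nloc)
    err = rng.binomial(depths, 0.01)
    err = np.minimum(err, np.maximum((0.04 * depths).astype(int), 0))
    ref = np.zeros(nloc, dtype=int)
    alt = np.zeros(nloc, dtype=int)
    states = np.asarray(gts)
    het = states == "het"
    alt[het] = np.clip(np.round(depths[het] * ab[het]).astype(int), 4, depths[het] - 4)
    ref[het] = depths[het] - alt[het]
    hom_a = (states == "hom_alt") | (states == "hemi_alt")
    ref[hom_a] = err[hom_a]
    alt[hom_a] = depths[hom_a] - err[hom_a]
    hom_r = (states == "hom_ref") | (states == "hemi_ref")
    alt[hom_r] = err[hom_r]
    ref[hom_r] = depths[hom_r] - err[hom_r]
    return ref, alt


_BASES = np.array(list("ACGT"))


def _random_alleles(rng, n: int) -> list[tuple[str, str]]:
    i = rng.integers(0, 4, n)
    j = (i + rng.integers(1, 4, n)) % 4
    return list(zip(_BASES[i], _BASES[j]))


def _make_record(chrom, pos, ref, alt, sample_ids, gts, rng, cfg,
                 annotations=(), depth_overrides=None):
    """Assemble a VariantRecord from per-sample genotype states."""
    depths = _draw_depth(rng, len(sample_ids), cfg.mean_depth, cfg.min_depth)
    depths[np.asarray(gts) == "missing"] = 0
    rdep, adep = _ad_arrays(rng, gts, depths)
    calls = []
    for i, (sid, gt) in enumerate(zip(sample_ids, gts)):
        dp, rd, ad = int(depths[i]), int(rdep[i]), int(adep[i])
        if depth_overrides and sid in depth_overrides:
            rd, ad = depth_overrides[sid]
            dp = rd + ad
        calls.append(GenotypeCall(sid, gt, depth=dp, ref_depth=rd, alt_depth=ad))
    rec = VariantRecord(chrom, int(pos), ref, alt, calls, list(annotations))
    rec.cohort_af = compute_cohort_af(rec)
    return rec


def _diploid_states(dosages: np.ndarray) -> list[str]:
    return [("hom_ref", "het", "hom_alt")[int(d)] for d in dosages]


def _haploid_states(dosages: np.ndarray) -> list[str]:
    return [("hemi_ref", "hemi_alt")[int(d)] for d in dosages]


# ---------------------------------------------------------------------------
# generator


def plant_deletion(
    records: list[VariantRecord],
    region: tuple[str, int, int],
    sample_ids: Sequence[str],
    sample_sexes: dict[str, str],
    run_length: int,
    start_index: int = 5,
) -> pd.DataFrame:
    """Plant a contiguous run of missing-GT / DP=0 sites in ``region`` for the
    listed male samples; returns the truth rows.  The screen is defined on
    males only, so non-male samples are rejected."""
    rows = []
    region_recs = sorted(
        (r for r in records if r.chrom == region[0] and region[1] <= r.pos <= region[2]),
        key=lambda r: r.pos,
    )
    if run_length == 0 or not sample_ids:
        return pd.DataFrame(columns=["sample_id", "run_start", "run_end", "n_sites"])
    if len(region_recs) < run_length + start_index:
        raise ValueError("region does not contain enough variant sites for the run")
    for sid in sample_ids:
        if sample_sexes.get(sid) != "male":
            raise ValueError(f"deletion screen is defined on males; {sid} is not male")
        run = region_recs[start_index : start_index + run_length]
        for rec in run:
            for c in rec.calls:
                if c.sample_id == sid:
                    c.gt, c.depth, c.ref_depth, c.alt_depth = "missing", 0, 0, 0
        rows.append(
            {"sample_id": sid, "run_start": run[0].pos, "run_end": run[-1].pos,
             "n_sites": run_length}
        )
    return pd.DataFrame(rows)


def simulate_cohort(config: SimConfig, out_dir: str | Path | None = None) -> SimResult:
    """Generate the full synthetic cohort bundle (and optionally write it).

    Returns records sorted by (chrom, pos); with a fixed seed the result is
    bit-identical across runs.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    panel = default_panel()
    panel_genes = {g.gene: g for g in panel}
    for spec in cfg.planted:
        if spec.gene not in panel_genes:
            raise ValueError(f"planted spec {spec.name} references unknown gene {spec.gene}")

    n = cfg.n_samples
    sample_ids = [f"S{i + 1:03d}" for i in range(n)]
    if n == 0:
        empty = pd.DataFrame()
        return SimResult(cfg, [], [], [], panel, [], pd.DataFrame(), pd.Series(dtype=object),
                         TruthTable(empty, empty, empty, empty, empty), [])

    # --- sample frame: sex, ancestry --------------------------------------
    n_male = _quota_counts(n, [cfg.male_fraction, 1 - cfg.male_fraction])[0]
    true_sex = np.array(["male"] * n_male + ["female"] * (n - n_male))
    rng.shuffle(true_sex)
    pops = list(cfg.ancestry_fractions)
    pop_counts = _quota_counts(n, list(cfg.ancestry_fractions.values()))
    true_pop = np.array(sum(([p] * c for p, c in zip(pops, pop_counts)), []))
    rng.shuffle(true_pop)

    # --- background autosomal variants ------------------------------------
    m = cfg.n_background_variants
    all_pops = list(dict.fromkeys(pops + list(cfg.ref_pops)))
    p_anc, pop_freqs = _balding_nichols_freqs(rng, m, all_pops, cfg.fst)
    chroms = np.sort(rng.integers(1, 23, m))
    positions = rng.integers(1_000_000, 100_000_000, m)
    # keep background clear of the panel regions
    for g in panel:
        if g.chrom.startswith("chr") and g.chrom not in ("chrX", "chrY"):
            ci = int(g.chrom[3:])
            mask = (chroms == ci) & (positions >= g.start) & (positions <= g.end)
            positions[mask] += g.end - g.start + 1000
    alleles = _random_alleles(rng, m)

    geno = np.empty((n, m), dtype=np.int8)
    for pop in pops:
        idx = np.where(true_pop == pop)[0]
        f = pop_freqs[pop]
        geno[idx] = rng.binomial(2, f[None, :], (len(idx), m))

    # --- relatedness plants (autosomes copied/transmitted) -----------------
    related_rows = []
    used: set[int] = set()

    def _pick(pred) -> int:
        for i in range(n - 1, -1, -1):
            if i not in used and pred(i):
                used.add(i)
                return i
        raise ValueError("not enough samples for planted features")

    for _ in range(cfg.n_duplicate_pairs):
        a = _pick(lambda i: True)
        b = _pick(lambda i, a=a: true_sex[i] == true_sex[a])
        geno[b] = geno[a]
        related_rows.append({"sample_i": sample_ids[min(a, b)],
                             "sample_j": sample_ids[max(a, b)],
                             "relationship": "duplicate"})
    for _ in range(cfg.n_parent_offspring_pairs):
        a = _pick(lambda i: True)  # parent
        b = _pick(lambda i, a=a: true_pop[i] == true_pop[a])  # offspring
        transmitted = rng.binomial(1, geno[a] / 2.0)
        other = rng.binomial(1, pop_freqs[true_pop[b]])
        geno[b] = (transmitted + other).astype(np.int8)
        related_rows.append({"sample_i": sample_ids[min(a, b)],
                             "sample_j": sample_ids[max(a, b)],
                             "relationship": "parent_offspring"})

    # --- sex mismatches -----------------------------------------------------
    reported_sex = true_sex.copy()
    mismatch_rows = []
    for _ in range(cfg.n_sex_mismatch):
        i = _pick(lambda i: true_sex[i] == "male")
        reported_sex[i] = "female"
        mismatch_rows.append({"sample_id": sample_ids[i], "true_sex": "male",
                              "reported_sex": "female"})

    # --- weights and score-coupled age -------------------------------------
    w_idx = rng.choice(m, size=min(cfg.n_weights, m), replace=False)
    w_idx.sort()
    eff_ref = rng.random(len(w_idx)) < cfg.ref_effect_fraction
    w_vals = rng.normal(0.0, cfg.weight_scale, len(w_idx))
    dos_eff = np.where(eff_ref[None, :], 2 - geno[:, w_idx], geno[:, w_idx])
    raw_score = dos_eff @ w_vals
    z = (raw_score - raw_score.mean()) / (raw_score.std() or 1.0)
    b0 = math.log(cfg.young_fraction / (1 - cfg.young_fraction))
    p_young = 1.0 / (1.0 + np.exp(-(b0 + cfg.age_log_or * z)))
    young = rng.random(n) < p_young
    age = np.where(young, rng.integers(18, 40, n), rng.integers(40, 60, n))

    lowcall_idx = rng.choice(w_idx, size=min(cfg.n_lowcall_weight_variants, len(w_idx)),
                             replace=False)
    lowcall_set = set(int(i) for i in lowcall_idx)
    n_drop = max(int(math.floor(n * 0.02)) + 1, 1)  # push call rate ≤ 0.98

    # --- assemble autosomal background records ------------------------------
    records: list[VariantRecord] = []
    lowcall_keys = []
    for j in range(m):
        chrom = f"chr{chroms[j]}"
        gts = _diploid_states(geno[:, j])
        if j in lowcall_set:
            for i in rng.choice(n, n_drop, replace=False):
                gts[int(i)] = "missing"
        rec = _make_record(chrom, positions[j], alleles[j][0], alleles[j][1],
                           sample_ids, gts, rng, cfg)
        records.append(rec)
        if j in lowcall_set:
            lowcall_keys.append(rec.key)

    weights = [
        WeightEntry(records[j].chrom, records[j].pos, records[j].ref, records[j].alt,
                    records[j].ref if r else records[j].alt, float(w))
        for j, r, w in zip(w_idx, eff_ref, w_vals)
    ]
    for k in range(cfg.n_unmatched_weights):
        weights.append(WeightEntry("chr1", 999_000_000 + k, "A", "C", "C",
                                   float(rng.normal(0, cfg.weight_scale))))

    # --- X-chromosome background sites (sex check) --------------------------
    male_mask = true_sex == "male"
    x_pos = np.sort(rng.integers(20_000_000, 120_000_000, cfg.n_x_sites))
    x_pos = x_pos[(x_pos < TLR7_REGION[1] - 10_000) | (x_pos > TLR7_REGION[2] + 10_000)]
    x_alleles = _random_alleles(rng, len(x_pos))
    x_freq = rng.uniform(0.2, 0.8, len(x_pos))
    for j, pos in enumerate(x_pos):
        gts = []
        dip = rng.binomial(2, x_freq[j], n)
        hap = rng.binomial(1, x_freq[j], n)
        for i in range(n):
            if male_mask[i]:
                gts.append(("hemi_ref", "hemi_alt")[hap[i]])
            else:
                gts.append(("hom_ref", "het", "hom_alt")[dip[i]])
        records.append(_make_record("chrX", pos, x_alleles[j][0], x_alleles[j][1],
                                    sample_ids, gts, rng, cfg))

    # --- TLR7-region common sites (deletion screen substrate) ---------------
    r0, r1 = TLR7_REGION[1] + 500, TLR7_REGION[2] - 500
    reg_pos = np.sort(rng.choice(np.arange(r0, r1, 50), cfg.n_region_sites, replace=False))
    reg_alleles = _random_alleles(rng, cfg.n_region_sites)
    reg_freq = rng.uniform(0.3, 0.7, cfg.n_region_sites)
    for j, pos in enumerate(reg_pos):
        gts = []
        dip = rng.binomial(2, reg_freq[j], n)
        hap = rng.binomial(1, reg_freq[j], n)
        for i in range(n):
            if male_mask[i]:
                gts.append(("hemi_ref", "hemi_alt")[hap[i]])
            else:
                gts.append(("hom_ref", "het", "hom_alt")[dip[i]])
        ann = AnnotationSet(gene="TLR7", consequence="intron_variant",
                            impact="MODIFIER", pop_af=round(float(reg_freq[j]), 4))
        records.append(_make_record("chrX", pos, reg_alleles[j][0], reg_alleles[j][1],
                                    sample_ids, gts, rng, cfg, annotations=[ann]))

    # --- benign common variants inside autosomal panel genes ----------------
    auto_genes = [g for g in panel if g.chrom not in ("chrX", "chrY")]
    for k in range(cfg.n_benign_panel_variants):
        g = auto_genes[k % len(auto_genes)]
        # stay clear of the window where planted candidates are placed
        pos = int(rng.integers(g.start + 2000, g.end + 1))
        ref, alt = _random_alleles(rng, 1)[0]
        f = rng.uniform(0.2, 0.5)
        gts = _diploid_states(rng.binomial(2, f, n))
        ann = AnnotationSet(gene=g.gene, consequence="synonymous_variant",
                            impact="LOW", cadd_phred=round(float(rng.uniform(0.1, 5.0)), 3),
                            pop_af=round(f, 4))
        records.append(_make_record(g.chrom, pos, ref, alt, sample_ids, gts, rng, cfg,
                                    annotations=[ann]))

    # --- planted candidates --------------------------------------------------
    score_order = np.argsort(raw_score)  # ascending: low-score first
    # carriers come from the low-score half, in random order within it, so the
    # carrier group is shifted downward without being perfectly separable
    low_half = [int(i) for i in rng.permutation(score_order[: max(n // 2, 1)])]
    planted_cursor = 0

    def _next_carrier(need_sex: str | None) -> int:
        nonlocal planted_cursor
        pool = low_half if cfg.carrier_low_prs else list(range(n))
        for _ in range(len(pool)):
            i = pool[planted_cursor % len(pool)]
            planted_cursor += 1
            if i in used:
                continue
            if need_sex and true_sex[i] != need_sex:
                continue
            return i
        raise ValueError("no eligible carrier sample for planted spec")

    extra_genes = [g.gene for g in panel if g.chrom not in ("chrX", "chrY")]
    extra_specs = [
        PlantedSpec(f"extra_carrier_{k + 1}", extra_genes[k % len(extra_genes)],
                    "het", consequence="stop_gained", impact="HIGH", cadd=38.0,
                    pop_af=1e-6, model="dominant", expected_reason="pLoF")
        for k in range(cfg.n_extra_carrier_variants)
    ]

    truth_var_rows = []
    gene_offsets: dict[str, int] = {}
    for spec in list(cfg.planted) + extra_specs:
        g = panel_genes[spec.gene]
        off = gene_offsets.get(spec.gene, 0)
        gene_offsets[spec.gene] = off + 1
        need_sex = None
        if spec.zygosity == "hemi" or (g.chrom == "chrX" and spec.zygosity == "hom"):
            need_sex = "male" if spec.zygosity == "hemi" else "female"
        carrier = _next_carrier(need_sex)
        n_sites = 2 if spec.zygosity == "compound_het" else 1
        for site_k in range(n_sites):
            pos = g.start + 100 + 37 * (2 * off + site_k)
            ref, alt = _random_alleles(rng, 1)[0]
            gts = ["hom_ref"] * n
            if g.chrom == "chrX":
                for i in range(n):
                    if male_mask[i]:
                        gts[i] = "hemi_ref"
            zyg = spec.zygosity if spec.zygosity != "compound_het" else "het"
            carrier_ids = [carrier]
            if spec.n_carriers > 1:
                extra = [int(i) for i in score_order if int(i) != carrier][: spec.n_carriers - 1]
                carrier_ids += extra
            for ci in carrier_ids:
                gts[ci] = {"het": "het", "hom": "hom_alt", "hemi": "hemi_alt"}[zyg]
            overrides = None
            if spec.depths is not None:
                overrides = {sample_ids[carrier]: spec.depths}
            ann = AnnotationSet(
                gene=spec.gene, consequence=spec.consequence, impact=spec.impact,
                cadd_phred=spec.cadd, spliceai_max_ds=spec.spliceai,
                pop_af=spec.pop_af, clinvar_sig=spec.clinvar,
            )
            rec = _make_record(g.chrom, pos, ref, alt, sample_ids, gts, rng, cfg,
                               annotations=[ann], depth_overrides=overrides)
            records.append(rec)
            models = {"AD": ("dominant",), "AR": ("recessive",),
                      "AD_AR": ("dominant", "recessive"), "XLR": ("recessive",)}

            def _truth_row(model, zygosity, retained, reason):
                truth_var_rows.append({
                    "class": spec.name, "sample_id": sample_ids[carrier],
                    "gene": spec.gene, "chrom": g.chrom, "pos": rec.pos,
                    "ref": ref, "alt": alt, "model": model,
                    "zygosity": zygosity,
                    "expected_retained": retained,
                    "expected_reason": reason,
                    "expected_in_clinical": bool(
                        retained and g.panel in ("IEI", "BOTH")
                        and model in models[g.inheritance]
                    ),
                })

            _truth_row(spec.model,
                       "compound_het_member" if spec.zygosity == "compound_het" else zyg,
                       spec.expected_retained, spec.expected_reason)
            if spec.zygosity == "compound_het" and spec.expected_retained:
                # each member is rare and deleterious enough to qualify on
                # its own as a heterozygous dominant-model candidate too
                dom_gate = (spec.clinvar is not None) or (
                    (spec.pop_af or 0.0) < 1e-4
                )
                if dom_gate:
                    _truth_row("dominant", "het", True, spec.expected_reason)

    # --- sort, deletion plant, reference panel -------------------------------
    records.sort(key=lambda r: (_CHROM_ORDER.get(r.chrom, 99), r.pos, r.alt))
    sexes = dict(zip(sample_ids, true_sex))
    del_samples = []
    for _ in range(cfg.n_deletion_samples):
        i = _pick(lambda i: true_sex[i] == "male")
        del_samples.append(sample_ids[i])
    deletions = plant_deletion(records, TLR7_REGION, del_samples, sexes,
                               cfg.deletion_run)

    ref_ids, ref_labels, ref_geno = [], [], []
    for pop in cfg.ref_pops:
        f = pop_freqs[pop]
        gmat = rng.binomial(2, f[None, :], (cfg.n_ref_per_pop, m))
        for k in range(cfg.n_ref_per_pop):
            ref_ids.append(f"REF_{pop}_{k + 1:03d}")
            ref_labels.append(pop)
            ref_geno.append(gmat[k])
    bg_keys = [f"chr{c}:{p}:{a}:{b}" for c, p, (a, b) in zip(chroms, positions, alleles)]
    ref_df = pd.DataFrame(np.array(ref_geno).T, index=pd.Index(bg_keys, name="variant"),
                          columns=ref_ids)
    ref_lab = pd.Series(ref_labels, index=ref_ids, name="pop")

    # --- phenotypes (quota-assigned to the study's category frequencies,
    # independently shuffled per block so missingness patterns are unlinked) --
    def _assign(vals: list) -> list:
        order = rng.permutation(n)
        out = [None] * n
        for k, i in enumerate(order):
            out[i] = vals[k]
        return out

    bmi_counts = _quota_counts(n, [27 / 110, 43 / 110, 23 / 110, 17 / 110])
    bmi_vals: list[float | None] = []
    for cat, cnt in zip(["healthy", "over", "obese", "na"], bmi_counts):
        lo, hi = {"healthy": (18.5, 24.9), "over": (25.0, 29.9),
                  "obese": (30.0, 39.9), "na": (0, 0)}[cat]
        for _ in range(cnt):
            bmi_vals.append(None if cat == "na" else round(float(rng.uniform(lo, hi)), 1))
    smoking_counts = _quota_counts(n, [95 / 110, 5 / 110, 10 / 110])
    smoking_vals = ["no"] * smoking_counts[0] + ["yes"] * smoking_counts[1] + [None] * smoking_counts[2]
    vacc_counts = _quota_counts(n, [91 / 110, 10 / 110, 9 / 110])
    vacc_vals = ["no"] * vacc_counts[0] + ["yes"] * vacc_counts[1] + [None] * vacc_counts[2]
    who_counts = _quota_counts(n, [1 / 110, 23 / 110, 86 / 110])
    who_vals = ([10] * who_counts[0]
                + [int(x) for x in rng.integers(6, 10, who_counts[1])]
                + [int(x) for x in rng.integers(4, 6, who_counts[2])])
    bmi_by, smok_by, vacc_by, who_by = (
        _assign(bmi_vals), _assign(smoking_vals), _assign(vacc_vals), _assign(who_vals)
    )

    samples = []
    for i in range(n):
        samples.append(SampleRecord(
            sample_id=sample_ids[i], reported_sex=str(reported_sex[i]),
            age=float(age[i]), bmi=bmi_by[i], smoking=smok_by[i],
            vaccinated=vacc_by[i], who_score=who_by[i],
            contamination_flag=False,
        ))

    truth = TruthTable(
        samples=pd.DataFrame({
            "sample_id": sample_ids, "true_sex": true_sex, "true_pop": true_pop,
            "age_lt_40": young,
        }),
        variants=pd.DataFrame(truth_var_rows),
        related_pairs=pd.DataFrame(related_rows),
        sex_mismatches=pd.DataFrame(mismatch_rows),
        deletions=deletions,
    )
    result = SimResult(cfg, sample_ids, records, samples, panel, weights,
                       ref_df, ref_lab, truth, lowcall_keys)
    if out_dir is not None:
        result.write(out_dir)
    return result
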