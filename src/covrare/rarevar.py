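"""Rare-variant prioritization cascade and the locus deletion screen.

The cascade, applied per annotated variant and candidate gene:

1. region subsetting — keep variants inside a panel gene region (regions are
   already extended ±200 bp beyond the UTRs);
2. within-cohort frequency — exclude variants with cohort AF ≥ 10%;
3. functional class — pLoF (HIGH impact), else missense with CADD > 20, else
   SpliceAI max delta score > 0.5 (evaluation order fixed, one primary
   reason per variant);
4. model-specific population-AF gate — gnomAD AF < 1e-3 for the recessive
   model, < 1e-4 for the dominant model (strict; absent AF counts as 0);
5. ClinVar rescue — Pathogenic / Likely pathogenic assertions bypass steps
   3–4 regardless of allele frequency, but not the genotype QC or the
   zygosity retention;
6. genotype QC — allelic balance > 95% for homozygous/hemizygous calls,
   25–75% for heterozygous calls with ≥ 4 reads on each allele;
7. zygosity retention — dominant: heterozygous only; recessive: homozygous
   or hemizygous, plus all members of (sample, gene) groups with ≥ 2
   qualifying heterozygous variants (potential compound heterozygotes,
   emitted phase-unknown for manual review).

The clinical approach evaluates established IEI genes under their reported
inheritance only (AD→dominant, AR→recessive, AD/AR→both, XLR→recessive);
the research approach evaluates every panel gene under both models.

The deletion screen reports, per male sample, maximal runs of consecutive
region variant sites with missing genotype or zero read depth — the
coverage signature of a hemizygous deletion.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, asdict

import pandas as pd
from intervaltree import IntervalTree

from .variantio import (
    AnnotationSet,
    GenePanelEntry,
    GenotypeCall,
    VariantRecord,
    allelic_balance,
    assign_zygosity,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CandidateVariant",
    "CnvCandidate",
    "Evidence",
    "COHORT_AF_MAX",
    "MODEL_AF_CUTOFFS",
    "subset_to_panel",
    "cohort_af_exclusion",
    "functional_class",
    "model_af_gate",
    "clinvar_rescue",
    "genotype_qc",
    "retain_by_model",
    "run_research_approach",
    "run_clinical_approach",
    "deletion_screen",
    "evidence_consistent",
    "candidates_to_frame",
    "INHERITANCE_MODELS",
]

COHORT_AF_MAX = 0.10
CADD_MIN = 20.0
SPLICEAI_MIN = 0.5
MODEL_AF_CUTOFFS = {"recessive": 1e-3, "dominant": 1e-4}
AB_HOM_MIN = 0.95
AB_HET_RANGE = (0.25, 0.75)
MIN_ALLELE_READS = 4
RESCUE_LABELS = {"pathogenic", "likely_pathogenic", "pathogenic/likely_pathogenic"}
INHERITANCE_MODELS = {
    "AD": ("dominant",),
    "AR": ("recessive",),
    "AD_AR": ("dominant", "recessive"),
    "XLR": ("recessive",),
}


@dataclass
class Evidence:
    """The complete input tuple behind one retention decision."""

    impact: str
    consequence: str
    cadd_phred: float | None
    spliceai_max_ds: float | None
    pop_af: float | None
    clinvar_sig: str | None
    cohort_af: float | None
    allelic_balance: float | None
    ref_depth: int
    alt_depth: int
    depth: int


@dataclass
class CandidateVariant:
    sample_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    gene: str
    panel: str
    model: str  # dominant | recessive
    zygosity_class: str  # het | hom | hemi | compound_het_member
    reason: str  # pLoF | missense_cadd | splice_ai | clinvar_rescue
    evidence: Evidence
    phase: str = ""  # "phase_unknown" for compound-het members


@dataclass
class CnvCandidate:
    sample_id: str
    region: str
    run_start: int
    run_end: int
    n_sites_in_run: int
    fraction_of_region_sites: float


# ---------------------------------------------------------------------------
# cascade gates


def subset_to_panel(
    records: list[VariantRecord], panel: list[GenePanelEntry]
) -> list[VariantRecord]:
    """Keep records inside ≥1 panel region, annotations restricted to panel
    genes.  A variant overlapping two panel genes keeps one annotation per
    gene and is evaluated once per gene downstream."""
    trees: dict[str, IntervalTree] = {}
    for g in panel:
        # IntervalTree is half-open; +1 makes the 1-based inclusive end hit
        trees.setdefault(g.chrom, IntervalTree()).addi(g.start, g.end + 1, g)
    panel_genes = {g.gene for g in panel}
    out = []
    for r in records:
        tree = trees.get(r.chrom)
        if tree is None or not tree.overlaps(r.pos):
            continue
        anns = [a for a in r.annotations if a.gene in panel_genes]
        out.append(
            VariantRecord(r.chrom, r.pos, r.ref, r.alt, r.calls, anns, r.cohort_af)
        )
    return out


def cohort_af_exclusion(
    records: list[VariantRecord], max_af: float = COHORT_AF_MAX
) -> list[VariantRecord]:
    """Drop records with cohort AF ≥ max_af (strict keep below) or with
    undefined AF (all calls missing; logged)."""
    kept = []
    for r in records:
        if r.cohort_af is None:
            logger.info("excluding %s:%d %s>%s: undefined cohort AF", r.chrom,
                        r.pos, r.ref, r.alt)
            continue
        if r.cohort_af < max_af:
            kept.append(r)
    return kept


def functional_class(ann: AnnotationSet) -> str | None:
    """Primary functional reason: pLoF → missense_cadd → splice_ai, in that
    fixed order; None if no criterion is met.  Absent scores fail their
    criterion."""
    if ann.impact == "HIGH":
        return "pLoF"
    if "missense" in ann.consequence and ann.cadd_phred is not None \
            and ann.cadd_phred > CADD_MIN:
        return "missense_cadd"
    if ann.spliceai_max_ds is not None and ann.spliceai_max_ds > SPLICEAI_MIN:
        return "splice_ai"
    return None


def model_af_gate(ann: AnnotationSet, model: str) -> bool:
    """Strict population-AF cutoff per inheritance model; an absent AF means
    the variant is unobserved in the reference population (treated as 0)."""
    af = ann.pop_af if ann.pop_af is not None else 0.0
    return af < MODEL_AF_CUTOFFS[model]


def clinvar_rescue(ann: AnnotationSet) -> bool:
    """Pathogenic / likely-pathogenic ClinVar assertion, case-normalized."""
    if not ann.clinvar_sig:
        return False
    return ann.clinvar_sig.strip().lower().replace(" ", "_") in RESCUE_LABELS


def genotype_qc(call: GenotypeCall, zygosity: str) -> bool:
    """Allelic-balance genotype QC.

    hom/hemi: AB > 95%.  het: AB within 25–75% and ≥ 4 reads supporting each
    allele.  Undefined AB (zero informative reads) fails.
    """
    ab = allelic_balance(call)
    if ab is None:
        return False
    if zygosity in ("hom", "hemi"):
        return ab > AB_HOM_MIN
    if zygosity == "het":
        return (
            AB_HET_RANGE[0] <= ab <= AB_HET_RANGE[1]
            and call.ref_depth >= MIN_ALLELE_READS
            and call.alt_depth >= MIN_ALLELE_READS
        )
    return False


# ---------------------------------------------------------------------------
# retention


@dataclass
class _Qualifying:
    sample_id: str
    record: VariantRecord
    gene_entry: GenePanelEntry
    zygosity: str  # het | hom | hemi
    reason: str
    evidence: Evidence


def _qualifying_triples(
    records: list[VariantRecord],
    panel: list[GenePanelEntry],
    sample_sexes: dict[str, str],
    model: str,
    genes: set[str] | None = None,
) -> list[_Qualifying]:
    by_gene = {g.gene: g for g in panel}
    recs = cohort_af_exclusion(subset_to_panel(records, panel))
    out: list[_Qualifying] = []
    for rec in recs:
        for ann in rec.annotations:
            if genes is not None and ann.gene not in genes:
                continue
            gene_entry = by_gene.get(ann.gene)
            if gene_entry is None:
                continue
            reason = functional_class(ann)
            passes_main = reason is not None and model_af_gate(ann, model)
            rescued = clinvar_rescue(ann)
            if not (passes_main or rescued):
                continue
            primary = reason if passes_main else "clinvar_rescue"
            for call in rec.calls:
                sex = sample_sexes.get(call.sample_id, "unknown")
                zyg = assign_zygosity(call, sex, rec.chrom, rec.pos)
                if zyg in ("ref", "missing"):
                    continue
                if zyg == "inconsistent":
                    logger.info(
                        "excluding inconsistent call %s at %s:%d",
                        call.sample_id, rec.chrom, rec.pos,
                    )
                    continue
                if not genotype_qc(call, zyg):
                    continue
                ev = Evidence(
                    impact=ann.impact, consequence=ann.consequence,
                    cadd_phred=ann.cadd_phred,
                    spliceai_max_ds=ann.spliceai_max_ds, pop_af=ann.pop_af,
                    clinvar_sig=ann.clinvar_sig, cohort_af=rec.cohort_af,
                    allelic_balance=allelic_balance(call),
                    ref_depth=call.ref_depth, alt_depth=call.alt_depth,
                    depth=call.depth,
                )
                out.append(_Qualifying(call.sample_id, rec, gene_entry, zyg,
                                       primary, ev))
    return out


def retain_by_model(
    triples: list[_Qualifying], model: str, compound_het_min: int = 2
) -> list[CandidateVariant]:
    """Zygosity retention: dominant keeps heterozygotes; recessive keeps
    homozygous/hemizygous plus (sample, gene) groups of ≥ compound_het_min
    qualifying heterozygotes as phase-unknown compound-het members."""
    candidates: list[CandidateVariant] = []

    def _emit(t: _Qualifying, zclass: str, phase: str = "") -> None:
        r = t.record
        candidates.append(CandidateVariant(
            t.sample_id, r.chrom, r.pos, r.ref, r.alt, t.gene_entry.gene,
            t.gene_entry.panel, model, zclass, t.reason, t.evidence, phase,
        ))

    if model == "dominant":
        for t in triples:
            if t.zygosity == "het":
                _emit(t, "het")
    elif model == "recessive":
        het_groups: dict[tuple[str, str], list[_Qualifying]] = {}
        for t in triples:
            if t.zygosity in ("hom", "hemi"):
                _emit(t, t.zygosity)
            elif t.zygosity == "het":
                het_groups.setdefault((t.sample_id, t.gene_entry.gene), []).append(t)
        for (_, _), group in sorted(het_groups.items()):
            if len(group) >= compound_het_min:
                for t in group:
                    _emit(t, "compound_het_member", phase="phase_unknown")
    else:
        raise ValueError(f"unknown model {model!r}")
    return candidates


def run_research_approach(
    records: list[VariantRecord],
    panel: list[GenePanelEntry],
    sample_sexes: dict[str, str],
    compound_het_min: int = 2,
) -> list[CandidateVariant]:
    """Evaluate every panel gene under both inheritance models."""
    out = []
    for model in ("dominant", "recessive"):
        triples = _qualifying_triples(records, panel, sample_sexes, model)
        out.extend(retain_by_model(triples, model, compound_het_min))
    return out


def run_clinical_approach(
    records: list[VariantRecord],
    panel: list[GenePanelEntry],
    sample_sexes: dict[str, str],
    compound_het_min: int = 2,
) -> list[CandidateVariant]:
    """Evaluate established IEI genes under their reported inheritance only.

    Genes without an inheritance label are skipped (logged).  Candidates are
    emitted with their full evidence trail for manual (ACMG-style) review —
    no classification is computed here.
    """
    iei = [g for g in panel if g.panel in ("IEI", "BOTH")]
    out = []
    for model in ("dominant", "recessive"):
        genes = set()
        for g in iei:
            if g.inheritance not in INHERITANCE_MODELS:
                logger.info("skipping %s: missing/unknown inheritance label", g.gene)
                continue
            if model in INHERITANCE_MODELS[g.inheritance]:
                genes.add(g.gene)
        if not genes:
            continue
        triples = _qualifying_triples(records, iei, sample_sexes, model, genes=genes)
        out.extend(retain_by_model(triples, model, compound_het_min))
    return out


# ---------------------------------------------------------------------------
# deletion screen


def deletion_screen(
    records: list[VariantRecord],
    region: tuple[str, int, int],
    male_samples: list[str],
    min_run: int = 5,
) -> list[CnvCandidate]:
    """Coverage-based hemizygous-deletion screen on male samples.

    Scans region variant sites in position order and reports, per sample,
    maximal runs of ≥ min_run consecutive sites with missing genotype or
    zero read depth.
    """
    chrom, start, end = region
    sites = sorted(
        (r for r in records if r.chrom == chrom and start <= r.pos <= end),
        key=lambda r: r.pos,
    )
    if not sites:
        logger.warning("deletion screen: no variant sites in %s:%d-%d",
                       chrom, start, end)
        return []
    region_label = f"{chrom}:{start}-{end}"
    out = []
    for sid in male_samples:
        flags = []
        for rec in sites:
            call = next(c for c in rec.calls if c.sample_id == sid)
            flags.append(call.gt == "missing" or call.depth == 0)
        i = 0
        while i < len(flags):
            if not flags[i]:
                i += 1
                continue
            j = i
            while j < len(flags) and flags[j]:
                j += 1
            if j - i >= min_run:
                out.append(CnvCandidate(
                    sid, region_label, sites[i].pos, sites[j - 1].pos,
                    j - i, (j - i) / len(sites),
                ))
            i = j
    return out


# ---------------------------------------------------------------------------
# evidence self-consistency and output


def evidence_consistent(c: CandidateVariant) -> bool:
    """Re-run the cascade's decisions on the candidate's own evidence tuple."""
    ev = c.evidence
    if ev.cohort_af is None or ev.cohort_af >= COHORT_AF_MAX:
        return False
    ann = AnnotationSet(
        gene=c.gene, consequence=ev.consequence, impact=ev.impact,
        cadd_phred=ev.cadd_phred, spliceai_max_ds=ev.spliceai_max_ds,
        pop_af=ev.pop_af, clinvar_sig=ev.clinvar_sig,
    )
    passes_main = (
        functional_class(ann) is not None and model_af_gate(ann, c.model)
    )
    if not (passes_main or clinvar_rescue(ann)):
        return False
    call = GenotypeCall(c.sample_id, "het", depth=ev.depth,
                        ref_depth=ev.ref_depth, alt_depth=ev.alt_depth)
    zyg = {"het": "het", "hom": "hom", "hemi": "hemi",
           "compound_het_member": "het"}[c.zygosity_class]
    if not genotype_qc(call, zyg):
        return False
    if c.model == "dominant" and c.zygosity_class != "het":
        return False
    if c.model == "recessive" and c.zygosity_class == "het":
        return False
    return True


def candidates_to_frame(candidates: list[CandidateVariant]) -> pd.DataFrame:
    """Flatten candidates (evidence fields inlined) for TSV output."""
    rows = []
    for c in candidates:
        row = asdict(c)
        row.update({f"ev_{k}": v for k, v in row.pop("evidence").items()})
        rows.append(row)
    cols = ["sample_id", "chrom", "pos", "ref", "alt", "gene", "panel",
            "model", "zygosity_class", "reason", "phase",
            "ev_impact", "ev_consequence", "ev_cadd_phred",
            "ev_spliceai_max_ds", "ev_pop_af", "ev_clinvar_sig",
            "ev_cohort_af", "ev_allelic_balance", "ev_ref_depth",
            "ev_alt_depth", "ev_depth"]
    df = pd.DataFrame(rows, columns=cols)
    return df.sort_values(["model", "chrom", "pos", "sample_id"]).reset_index(drop=True)
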