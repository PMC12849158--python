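"""Domain types and readers/writers for annotated cohort VCFs and sidecar tables.

The in-memory model is deliberately simple: a cohort is a list of
:class:`VariantRecord`, each holding one alternate allele (multiallelic sites
are decomposed on read), the per-sample :class:`GenotypeCall` list in file
sample order, and one parsed :class:`AnnotationSet` per overlapped gene
(mirroring a single most-relevant consequence per gene, as produced by VEP's
``pick_allele_gene``).

Coordinates are 1-based inclusive everywhere.  BED-style half-open inputs are
converted at the reader boundary.  Annotation sub-field order is taken from the
``##INFO=<ID=CSQ,...>`` header line, never hard-coded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from cyvcf2 import VCF

__all__ = [
    "GenotypeCall",
    "AnnotationSet",
    "VariantRecord",
    "GenePanelEntry",
    "SampleRecord",
    "WeightEntry",
    "PAR_GRCH38",
    "in_par",
    "read_cohort_vcf",
    "write_cohort_vcf",
    "compute_cohort_af",
    "allelic_balance",
    "assign_zygosity",
    "read_gene_panel",
    "write_gene_panel",
    "read_weights",
    "write_weights",
    "read_sample_sheet",
    "write_sample_sheet",
]

# GRCh38 pseudoautosomal regions, 1-based inclusive.  Diploid in males.
PAR_GRCH38: dict[str, list[tuple[int, int]]] = {
    "chrX": [(10_001, 2_781_479), (155_701_383, 156_030_895)],
    "chrY": [(10_001, 2_781_479), (56_887_903, 57_217_415)],
}

#: Canonical annotation sub-field order for VCFs written by this package.
CSQ_FIELDS = (
    "Allele",
    "SYMBOL",
    "Consequence",
    "IMPACT",
    "CADD_PHRED",
    "REVEL",
    "AlphaMissense",
    "SpliceAI_max_DS",
    "gnomAD_AF",
    "ClinVar_CLNSIG",
)

GT_STATES = ("hom_ref", "het", "hom_alt", "hemi_ref", "hemi_alt", "missing")


class VcfFormatError(ValueError):
    """Raised when a cohort VCF lacks a required header or FORMAT field."""


@dataclass
class GenotypeCall:
    """One genotype call: GT state plus the DP/AD read-support fields."""

    sample_id: str
    gt: str  # one of GT_STATES
    depth: int = 0
    ref_depth: int = 0
    alt_depth: int = 0

    def __post_init__(self) -> None:
        if self.gt not in GT_STATES:
            raise ValueError(f"unknown genotype state {self.gt!r}")

    @property
    def n_alt(self) -> int | None:
        """Alt-allele count (0/1/2 diploid, 0/1 hemizygous); None if missing."""
        return {
            "hom_ref": 0, "het": 1, "hom_alt": 2,
            "hemi_ref": 0, "hemi_alt": 1, "missing": None,
        }[self.gt]

    @property
    def ploidy(self) -> int | None:
        if self.gt == "missing":
            return None
        return 1 if self.gt.startswith("hemi") else 2


@dataclass
class AnnotationSet:
    """Parsed per-(allele, gene) annotation; score fields are None when absent.

    Absent scores are never coerced to 0 — filters treat an absent score as
    failing that score criterion, except the reference-population AF where
    absent means the variant was unobserved, i.e. maximally rare.
    """

    gene: str
    consequence: str = ""
    impact: str = ""
    cadd_phred: float | None = None
    revel: float | None = None
    alphamissense_class: str | None = None
    spliceai_max_ds: float | None = None
    pop_af: float | None = None
    clinvar_sig: str | None = None


@dataclass
class VariantRecord:
    """One biallelic variant (single alt after decomposition)."""

    chrom: str
    pos: int
    ref: str
    alt: str
    calls: list[GenotypeCall] = field(default_factory=list)
    annotations: list[AnnotationSet] = field(default_factory=list)
    cohort_af: float | None = None

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass(frozen=True)
class GenePanelEntry:
    """Gene region (already extended ±200 bp beyond the UTRs) with its
    reported inheritance label and panel membership."""

    gene: str
    chrom: str
    start: int  # 1-based inclusive
    end: int
    inheritance: str  # AD | AR | AD_AR | XLR
    panel: str  # IEI | GWAS | BOTH

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"{self.gene}: start > end")
        if self.inheritance == "XLR" and self.chrom not in ("chrX", "X"):
            raise ValueError(f"{self.gene}: XLR inheritance off chrX")


@dataclass
class SampleRecord:
    """Per-sample phenotypes and downstream QC/analysis annotations."""

    sample_id: str
    reported_sex: str = "unknown"  # male | female | unknown
    age: float | None = None
    bmi: float | None = None
    smoking: str | None = None  # yes | no | None
    vaccinated: str | None = None
    who_score: int | None = None
    contamination_flag: bool = False
    call_rate: float | None = None
    inferred_sex: str | None = None
    related_flag: bool = False
    ancestry_label: str | None = None
    pcs: list[float] | None = None
    prs: float | None = None
    carrier: bool | None = None


@dataclass(frozen=True)
class WeightEntry:
    """One polygenic-score weight: variant key, effect allele, weight."""

    chrom: str
    pos: int
    ref: str
    alt: str
    effect_allele: str
    weight: float

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)


# ---------------------------------------------------------------------------
# call-level helpers


def in_par(chrom: str, pos: int, par_regions: dict | None = None) -> bool:
    """True if (chrom, pos) lies in a pseudoautosomal region."""
    table = par_regions or PAR_GRCH38
    regions = table.get(chrom) or table.get("chr" + chrom) or []
    return any(s <= pos <= e for s, e in regions)


def allelic_balance(call: GenotypeCall) -> float | None:
    """Alt-read fraction alt/(ref+alt); None when there are no informative reads."""
    tot = call.ref_depth + call.alt_depth
    if tot == 0:
        return None
    return call.alt_depth / tot


def compute_cohort_af(record: VariantRecord) -> float | None:
    """Within-cohort alternate-allele frequency.

    Diploid calls contribute two alleles, hemizygous calls one, missing calls
    none.  Returns None when every call is missing (undefined AF; such records
    are excluded downstream with a logged reason).
    """
    alt = 0
    total = 0
    for c in record.calls:
        n = c.n_alt
        if n is None:
            continue
        alt += n
        total += c.ploidy  # type: ignore[operator]
    if total == 0:
        return None
    return alt / total


def assign_zygosity(
    call: GenotypeCall,
    sample_sex: str,
    chrom: str,
    pos: int | None = None,
    par_regions: dict | None = None,
) -> str:
    """Zygosity class for candidate filtering: het/hom/hemi/ref/missing.

    Males on non-PAR X (or Y) are hemizygous: any alt allele yields ``hemi``
    (a haploid call, or a diploid hom-alt collapsed to single copy).  A
    diploid heterozygous call for a male on non-PAR X is biologically
    inconsistent and returns ``inconsistent`` so callers can exclude and log
    it; likewise a haploid call for a female.  When ``pos`` is given, PAR
    coordinates are treated as diploid for males.
    """
    is_sex_chrom = chrom in ("chrX", "X", "chrY", "Y")
    par = in_par(chrom, pos, par_regions) if (is_sex_chrom and pos is not None) else False
    male_hemi_context = sample_sex == "male" and is_sex_chrom and not par
    if call.gt == "missing":
        return "missing"
    if call.gt in ("hemi_ref", "hemi_alt"):
        if sample_sex == "female":
            return "inconsistent"
        return "hemi" if call.gt == "hemi_alt" else "ref"
    if male_hemi_context:
        if call.gt == "het":
            return "inconsistent"
        return "hemi" if call.gt == "hom_alt" else "ref"
    return {"hom_ref": "ref", "het": "het", "hom_alt": "hom"}[call.gt]


# ---------------------------------------------------------------------------
# VCF reading


def _parse_csq_format(raw_header: str) -> list[str]:
    for line in raw_header.splitlines():
        if line.startswith("##INFO=<ID=CSQ"):
            if "Format:" not in line:
                raise VcfFormatError(
                    "INFO/CSQ header present but declares no 'Format:' sub-field order"
                )
            fmt = line.split("Format:", 1)[1]
            fmt = fmt.strip().strip('">').strip()
            return fmt.split("|")
    raise VcfFormatError(
        "cohort VCF lacks the required ##INFO=<ID=CSQ,...> annotation header"
    )


def _maybe_float(s: str) -> float | None:
    if s is None or s == "":
        return None
    try:
        return float(s)
    except ValueError:
        return None


def _annotation_from_csq(entry: str, fields: Sequence[str]) -> tuple[str, AnnotationSet]:
    parts = entry.split("|")
    d = {f: (parts[i] if i < len(parts) else "") for i, f in enumerate(fields)}
    ann = AnnotationSet(
        gene=d.get("SYMBOL", ""),
        consequence=d.get("Consequence", ""),
        impact=d.get("IMPACT", ""),
        cadd_phred=_maybe_float(d.get("CADD_PHRED", "")),
        revel=_maybe_float(d.get("REVEL", "")),
        alphamissense_class=d.get("AlphaMissense") or None,
        spliceai_max_ds=_maybe_float(d.get("SpliceAI_max_DS", "")),
        pop_af=_maybe_float(d.get("gnomAD_AF", "")),
        clinvar_sig=d.get("ClinVar_CLNSIG") or None,
    )
    return d.get("Allele", ""), ann


def read_cohort_vcf(path: str | Path) -> list[VariantRecord]:
    """Read an annotated multi-sample VCF into decomposed VariantRecords.

    Multiallelic sites become one record per alt allele; AD is re-indexed to
    the kept alt; CSQ entries are routed to the matching alt allele.  Alleles
    belonging to a different alt are counted as reference after decomposition
    (inputs are assumed normalized upstream).
    """
    vcf = VCF(str(path))
    csq_fields = _parse_csq_format(vcf.raw_header)
    fmt_ids = set()
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            fmt_ids.add(line.split("ID=", 1)[1].split(",", 1)[0])
    missing_fmt = {"GT", "AD", "DP"} - fmt_ids
    if missing_fmt:
        raise VcfFormatError(
            f"cohort VCF FORMAT lacks required field(s): {sorted(missing_fmt)} "
            f"for samples {list(vcf.samples)}"
        )
    samples = list(vcf.samples)
    records: list[VariantRecord] = []
    for var in vcf:
        ad = var.format("AD")
        dp = var.format("DP")
        csq = var.INFO.get("CSQ") or ""
        parsed = [_annotation_from_csq(e, csq_fields) for e in csq.split(",") if e]
        for alt_idx, alt in enumerate(var.ALT, start=1):
            calls = []
            for si, sid in enumerate(samples):
                g = var.genotypes[si]
                alleles = [a for a in g[:-1]]
                d = int(dp[si][0]) if dp is not None and dp[si][0] >= 0 else 0
                rd = int(ad[si][0]) if ad is not None and ad[si][0] >= 0 else 0
                adep = (
                    int(ad[si][alt_idx])
                    if ad is not None and len(ad[si]) > alt_idx and ad[si][alt_idx] >= 0
                    else 0
                )
                if all(a < 0 for a in alleles):
                    gt = "missing"
                elif len(alleles) == 1:
                    gt = "hemi_alt" if alleles[0] == alt_idx else "hemi_ref"
                else:
                    n = sum(1 for a in alleles if a == alt_idx)
                    gt = {0: "hom_ref", 1: "het", 2: "hom_alt"}[n]
                calls.append(GenotypeCall(sid, gt, depth=d, ref_depth=rd, alt_depth=adep))
            anns = [a for allele, a in parsed if allele == alt]
            rec = VariantRecord(var.CHROM, var.POS, var.REF, alt, calls, anns)
            rec.cohort_af = compute_cohort_af(rec)
            records.append(rec)
    return records


# ---------------------------------------------------------------------------
# VCF writing (canonical dialect; write→read→write is byte-stable)

_GT_STR = {
    "hom_ref": "0/0", "het": "0/1", "hom_alt": "1/1",
    "hemi_ref": "0", "hemi_alt": "1", "missing": "./.",
}


def _fmt_score(x: float | None) -> str:
    if x is None:
        return ""
    return format(x, ".6g")


def _csq_entry(alt: str, a: AnnotationSet) -> str:
    return "|".join(
        [
            alt,
            a.gene,
            a.consequence,
            a.impact,
            _fmt_score(a.cadd_phred),
            _fmt_score(a.revel),
            a.alphamissense_class or "",
            _fmt_score(a.spliceai_max_ds),
            _fmt_score(a.pop_af),
            a.clinvar_sig or "",
        ]
    )


def write_cohort_vcf(
    records: Iterable[VariantRecord],
    samples: Sequence[str],
    path: str | Path,
    contigs: Sequence[tuple[str, int]] | None = None,
) -> None:
    """Write records in the package's canonical VCF 4.2 dialect."""
    records = list(records)
    if contigs is None:
        seen: dict[str, int] = {}
        for r in records:
            seen[r.chrom] = max(seen.get(r.chrom, 0), r.pos + 1000)
        contigs = list(seen.items())
    lines = ["##fileformat=VCFv4.2"]
    for name, length in contigs:
        lines.append(f"##contig=<ID={name},length={length}>")
    lines.append(
        '##INFO=<ID=CSQ,Number=.,Type=String,Description="Consequence annotations. '
        'Format: ' + "|".join(CSQ_FIELDS) + '">'
    )
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    lines.append('##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">')
    lines.append('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))
    for r in records:
        csq = ",".join(_csq_entry(r.alt, a) for a in r.annotations)
        info = f"CSQ={csq}" if csq else "."
        cells = []
        for c in r.calls:
            cells.append(f"{_GT_STR[c.gt]}:{c.ref_depth},{c.alt_depth}:{c.depth}")
        lines.append(
            f"{r.chrom}\t{r.pos}\t.\t{r.ref}\t{r.alt}\t.\tPASS\t{info}\tGT:AD:DP\t"
            + "\t".join(cells)
        )
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# sidecar tables


def read_gene_panel(path: str | Path) -> list[GenePanelEntry]:
    df = pd.read_csv(path, sep="\t")
    return [
        GenePanelEntry(
            gene=row.gene, chrom=row.chrom, start=int(row.start), end=int(row.end),
            inheritance=row.inheritance, panel=row.panel,
        )
        for row in df.itertuples()
    ]


def write_gene_panel(panel: Iterable[GenePanelEntry], path: str | Path) -> None:
    pd.DataFrame(
        [(g.gene, g.chrom, g.start, g.end, g.inheritance, g.panel) for g in panel],
        columns=["gene", "chrom", "start", "end", "inheritance", "panel"],
    ).to_csv(path, sep="\t", index=False)


def read_weights(path: str | Path) -> list[WeightEntry]:
    df = pd.read_csv(path, sep="\t")
    return [
        WeightEntry(row.chrom, int(row.pos), row.ref, row.alt, row.effect_allele, float(row.weight))
        for row in df.itertuples()
    ]


def write_weights(weights: Iterable[WeightEntry], path: str | Path) -> None:
    pd.DataFrame(
        [(w.chrom, w.pos, w.ref, w.alt, w.effect_allele, w.weight) for w in weights],
        columns=["chrom", "pos", "ref", "alt", "effect_allele", "weight"],
    ).to_csv(path, sep="\t", index=False)


_SHEET_COLS = [
    "sample_id", "reported_sex", "age", "bmi", "smoking", "vaccinated",
    "who_score", "contamination_flag",
]


def read_sample_sheet(path: str | Path) -> list[SampleRecord]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        d = row._asdict()

        def get(col, cast=None):
            v = d.get(col)
            if v is None or (isinstance(v, float) and math.isnan(v)):
                return None
            return cast(v) if cast else v

        out.append(
            SampleRecord(
                sample_id=str(d["sample_id"]),
                reported_sex=get("reported_sex") or "unknown",
                age=get("age", float),
                bmi=get("bmi", float),
                smoking=get("smoking"),
                vaccinated=get("vaccinated"),
                who_score=get("who_score", int),
                contamination_flag=bool(get("contamination_flag") or False),
            )
        )
    return out


def write_sample_sheet(samples: Iterable[SampleRecord], path: str | Path) -> None:
    rows = []
    for s in samples:
        rows.append(
            {
                "sample_id": s.sample_id,
                "reported_sex": s.reported_sex,
                "age": s.age,
                "bmi": s.bmi,
                "smoking": s.smoking,
                "vaccinated": s.vaccinated,
                "who_score": s.who_score,
                "contamination_flag": s.contamination_flag,
            }
        )
    pd.DataFrame(rows, columns=_SHEET_COLS).to_csv(path, sep="\t", index=False)
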