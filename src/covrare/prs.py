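"""Polygenic risk scoring: per-variant QC of the weights table, then
effect-allele dosage scoring.

The score for sample s is  PRS_s = Σ_v w_v · d_{s,v}  over usable weight
entries, where d is the effect-allele dosage (0/1/2 diploid, 0/1 hemizygous).
Weight entries are matched to cohort variants by exact (chrom, pos, ref, alt)
key; entries on variants with per-variant call rate ≤ 98%, entries whose
effect allele is neither ref nor alt, and unmatched entries are dropped with
counts logged.  Missing genotypes are imputed at 2·p̂ (cohort effect-allele
frequency) by default; sum scoring is the default, with average and
no-imputation modes available.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .variantio import VariantRecord, WeightEntry, compute_cohort_af

logger = logging.getLogger(__name__)

__all__ = ["ScoreResult", "ScoringQc", "variant_qc_for_scoring", "score_samples"]

VARIANT_CALL_RATE_MIN = 0.98  # strict: call rate must exceed this


@dataclass
class ScoreResult:
    sample_id: str
    score: float
    n_weights_total: int
    n_weights_used: int
    n_missing_imputed: int


@dataclass
class ScoringQc:
    """Usable weights plus an audit of what was dropped and why."""

    usable: list[tuple[WeightEntry, VariantRecord]]
    n_total: int
    n_unmatched: int
    n_low_call_rate: int
    n_bad_effect_allele: int
    dropped_keys: dict[str, list[tuple]] = field(default_factory=dict)


def variant_qc_for_scoring(
    records: list[VariantRecord],
    weights: list[WeightEntry],
    call_rate_min: float = VARIANT_CALL_RATE_MIN,
) -> ScoringQc:
    """Match weights to records and drop entries failing variant-level QC."""
    by_key = {r.key: r for r in records}
    usable: list[tuple[WeightEntry, VariantRecord]] = []
    dropped: dict[str, list[tuple]] = {"unmatched": [], "low_call_rate": [], "bad_effect_allele": []}
    for w in weights:
        rec = by_key.get(w.key)
        if rec is None:
            dropped["unmatched"].append(w.key)
            continue
        if w.effect_allele not in (rec.ref, rec.alt):
            dropped["bad_effect_allele"].append(w.key)
            continue
        called = sum(1 for c in rec.calls if c.gt != "missing")
        if rec.calls and called / len(rec.calls) <= call_rate_min:
            dropped["low_call_rate"].append(w.key)
            continue
        usable.append((w, rec))
    qc = ScoringQc(
        usable=usable,
        n_total=len(weights),
        n_unmatched=len(dropped["unmatched"]),
        n_low_call_rate=len(dropped["low_call_rate"]),
        n_bad_effect_allele=len(dropped["bad_effect_allele"]),
        dropped_keys=dropped,
    )
    logger.info(
        "scoring QC: %d/%d weights usable (%d unmatched, %d low call rate, "
        "%d bad effect allele)",
        len(usable), len(weights), qc.n_unmatched, qc.n_low_call_rate,
        qc.n_bad_effect_allele,
    )
    return qc


def score_samples(
    records_or_qc: ScoringQc | list[tuple[WeightEntry, VariantRecord]],
    sample_ids: list[str] | None = None,
    mode: str = "sum",
    impute_missing: bool = True,
) -> list[ScoreResult]:
    """Score samples over the usable weight set.

    ``mode``: "sum" (default) or "average" (sum divided by the number of
    weights used).  With ``impute_missing`` a missing genotype contributes
    2·p̂ effect-allele dosage, where p̂ is the cohort effect-allele frequency
    at that variant; without it, missing genotypes contribute 0.
    """
    usable = records_or_qc.usable if isinstance(records_or_qc, ScoringQc) else records_or_qc
    if sample_ids is None:
        if not usable:
            return []
        sample_ids = [c.sample_id for c in usable[0][1].calls]
    n_total = (
        records_or_qc.n_total if isinstance(records_or_qc, ScoringQc) else len(usable)
    )
    idx = {s: i for i, s in enumerate(sample_ids)}
    score = np.zeros(len(sample_ids))
    imputed = np.zeros(len(sample_ids), dtype=int)
    for w, rec in usable:
        af_alt = compute_cohort_af(rec)
        p_eff = af_alt if w.effect_allele == rec.alt else (
            None if af_alt is None else 1.0 - af_alt
        )
        for c in rec.calls:
            i = idx[c.sample_id]
            n = c.n_alt
            if n is None:
                if impute_missing and p_eff is not None:
                    score[i] += w.weight * 2.0 * p_eff
                    imputed[i] += 1
                continue
            d = n if w.effect_allele == rec.alt else (c.ploidy - n)
            score[i] += w.weight * d
    if mode == "average" and usable:
        score = score / len(usable)
    elif mode not in ("sum", "average"):
        raise ValueError(f"unknown scoring mode {mode!r}")
    return [
        ScoreResult(s, float(score[i]), n_total, len(usable), int(imputed[i]))
        for s, i in idx.items()
    ]
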