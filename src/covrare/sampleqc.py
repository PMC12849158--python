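"""Sample-level QC: X-inbreeding sex check, KING-robust kinship, call rate.

Sex concordance uses the X-chromosome inbreeding coefficient
F = (O_hom − E_hom) / (L − E_hom) over non-PAR X sites, with the expected
homozygosity E_hom = Σ_l (1 − 2 p_l (1 − p_l)).  Genetic males (hemizygous,
counted as homozygous) sit near F = 1; genetic females near F = 0.  Inference
thresholds are F > 0.8 for males and F < 0.2 for females, with samples outside
the −0.2 to 0.2 window flagged as potential mismatches against reported sex.

Relatedness uses the KING between-family ("robust") estimator
phi = (N_het,het − 2 N_opp_hom) / (N_het(i) + N_het(j)) over shared autosomal
diploid sites; phi ≥ 0.044 flags a related pair (≈ 0.5 duplicates,
≈ 0.25 first degree).  Flagged pairs are reported, not auto-dropped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .variantio import GenotypeCall, VariantRecord, in_par

__all__ = [
    "SexCheckResult",
    "KinshipEstimate",
    "x_inbreeding",
    "infer_sex",
    "king_kinship",
    "king_kinship_matrix",
    "sample_call_rate",
    "x_dosage_matrix",
    "autosomal_dosage_matrix",
    "run_sample_qc",
]

KINSHIP_RELATED_THRESHOLD = 0.044
MALE_F_THRESHOLD = 0.8
FEMALE_F_THRESHOLD = 0.2
MISMATCH_WINDOW = (-0.2, 0.2)
CALL_RATE_MIN = 0.98


@dataclass
class SexCheckResult:
    sample_id: str
    f_x: float | None
    inferred_sex: str  # male | female | undetermined
    concordant: bool
    mismatch: bool


@dataclass
class KinshipEstimate:
    sample_i: str
    sample_j: str
    phi: float | None
    n_informative_sites: int
    related: bool


class InsufficientSitesError(ValueError):
    """Raised when fewer informative sites are available than the floor."""


# ---------------------------------------------------------------------------
# dosage matrices


def autosomal_dosage_matrix(
    records: list[VariantRecord], sample_ids: list[str]
) -> tuple[np.ndarray, list[tuple]]:
    """Samples × variants alt-dosage matrix over autosomal diploid sites
    (NaN where missing).  Returns the matrix and the variant keys kept."""
    idx = {s: i for i, s in enumerate(sample_ids)}
    cols, keys = [], []
    for r in records:
        if r.chrom in ("chrX", "X", "chrY", "Y"):
            continue
        col = np.full(len(sample_ids), np.nan)
        for c in r.calls:
            n = c.n_alt
            if n is not None and c.ploidy == 2:
                col[idx[c.sample_id]] = n
        cols.append(col)
        keys.append(r.key)
    if not cols:
        return np.empty((len(sample_ids), 0)), []
    return np.column_stack(cols), keys


def x_dosage_matrix(
    records: list[VariantRecord], sample_ids: list[str]
) -> tuple[np.ndarray, np.ndarray, list[tuple]]:
    """Non-PAR X dosages (samples × sites) plus a haploid-call indicator.

    Hemizygous calls are coded on the homozygous scale (0 or 2) so that the
    inbreeding calculation counts them as homozygous.
    """
    idx = {s: i for i, s in enumerate(sample_ids)}
    cols, haps, keys = [], [], []
    for r in records:
        if r.chrom not in ("chrX", "X") or in_par(r.chrom, r.pos):
            continue
        col = np.full(len(sample_ids), np.nan)
        hap = np.zeros(len(sample_ids), dtype=bool)
        for c in r.calls:
            n = c.n_alt
            if n is None:
                continue
            if c.ploidy == 1:
                col[idx[c.sample_id]] = 2 * n
                hap[idx[c.sample_id]] = True
            else:
                col[idx[c.sample_id]] = n
        cols.append(col)
        haps.append(hap)
        keys.append(r.key)
    if not cols:
        return np.empty((len(sample_ids), 0)), np.empty((len(sample_ids), 0), bool), []
    return np.column_stack(cols), np.column_stack(haps), keys


# ---------------------------------------------------------------------------
# sex check


def x_inbreeding(
    dosages: np.ndarray,
    allele_freqs: np.ndarray,
    min_sites: int = 50,
) -> np.ndarray:
    """Per-sample X inbreeding coefficient F.

    ``dosages``: samples × sites, values 0/1/2 (hemizygous pre-coded 0/2),
    NaN missing.  ``allele_freqs``: per-site alt frequency p_l used for the
    expected homozygosity.  Sites with p outside (0, 1) are uninformative and
    ignored.  Samples with fewer than ``min_sites`` informative sites, or with
    L − E_hom ≤ 0, get NaN (flagged undefined).
    """
    p = np.asarray(allele_freqs, float)
    informative = (p > 0) & (p < 1)
    d = np.asarray(dosages, float)[:, informative]
    p = p[informative]
    e_site = 1.0 - 2.0 * p * (1.0 - p)  # per-site expected homozygosity
    called = ~np.isnan(d)
    o_hom = ((d == 0) | (d == 2)).sum(axis=1)
    L = called.sum(axis=1)
    e_hom = np.where(called, e_site[None, :], 0.0).sum(axis=1)
    denom = L - e_hom
    with np.errstate(invalid="ignore", divide="ignore"):
        f = (o_hom - e_hom) / denom
    f = np.where((denom <= 0) | (L < min_sites), np.nan, f)
    return f


def infer_sex(f_x: float | None, reported_sex: str | None = None) -> tuple[str, bool]:
    """Infer sex from F and flag mismatches against the reported sex.

    Inference: F > 0.8 → male; −0.2 ≤ F < 0.2 → female; anything else
    (including anomalous F < −0.2) → undetermined.  Mismatch flags: a reported
    female with F outside the −0.2..0.2 window; a reported male with F at or
    below the window's upper edge (i.e. in female-consistent or anomalous
    territory).  A reported male with intermediate F (0.2 < F ≤ 0.8) is left
    undetermined for review without a mismatch flag.
    """
    if f_x is None or np.isnan(f_x):
        return "undetermined", False
    if f_x > MALE_F_THRESHOLD:
        inferred = "male"
    elif MISMATCH_WINDOW[0] <= f_x < FEMALE_F_THRESHOLD:
        inferred = "female"
    else:
        inferred = "undetermined"
    mismatch = False
    if reported_sex == "female":
        mismatch = not (MISMATCH_WINDOW[0] <= f_x <= MISMATCH_WINDOW[1])
    elif reported_sex == "male":
        mismatch = f_x <= FEMALE_F_THRESHOLD
    return inferred, mismatch


# ---------------------------------------------------------------------------
# kinship


def king_kinship(
    geno_i: np.ndarray, geno_j: np.ndarray, min_sites: int = 200
) -> KinshipEstimate:
    """KING-robust kinship for one pair of dosage vectors (0/1/2, NaN missing)."""
    gi = np.asarray(geno_i, float)
    gj = np.asarray(geno_j, float)
    shared = ~np.isnan(gi) & ~np.isnan(gj)
    n_shared = int(shared.sum())
    if n_shared < min_sites:
        raise InsufficientSitesError(
            f"only {n_shared} shared non-missing sites (< {min_sites})"
        )
    gi, gj = gi[shared], gj[shared]
    het_i, het_j = gi == 1, gj == 1
    n_hethet = int((het_i & het_j).sum())
    n_opp = int((((gi == 0) & (gj == 2)) | ((gi == 2) & (gj == 0))).sum())
    denom = int(het_i.sum() + het_j.sum())
    if denom == 0:
        return KinshipEstimate("i", "j", None, n_shared, False)
    phi = (n_hethet - 2.0 * n_opp) / denom
    return KinshipEstimate("i", "j", phi, n_shared,
                           phi >= KINSHIP_RELATED_THRESHOLD)


def king_kinship_matrix(dosages: np.ndarray) -> np.ndarray:
    """All-pairs KING-robust phi for a samples × sites dosage matrix.

    Vectorized over pairs; entries with a zero denominator are NaN.
    """
    d = np.asarray(dosages, float)
    valid = ~np.isnan(d)
    het = np.where(valid & (d == 1), 1.0, 0.0)
    hom0 = np.where(valid & (d == 0), 1.0, 0.0)
    hom2 = np.where(valid & (d == 2), 1.0, 0.0)
    v = valid.astype(float)
    n_hethet = het @ het.T
    n_opp = hom0 @ hom2.T + hom2 @ hom0.T
    het_on_shared = het @ v.T  # het count of row sample on sites shared with col
    denom = het_on_shared + het_on_shared.T
    with np.errstate(invalid="ignore", divide="ignore"):
        phi = (n_hethet - 2.0 * n_opp) / denom
    phi[denom == 0] = np.nan
    return phi


# ---------------------------------------------------------------------------
# call rate


def sample_call_rate(calls: list[GenotypeCall] | np.ndarray) -> float:
    """Fraction of non-missing calls; raises on zero variants."""
    if isinstance(calls, np.ndarray):
        total = calls.size
        called = int((~np.isnan(calls)).sum())
    else:
        total = len(calls)
        called = sum(1 for c in calls if c.gt != "missing")
    if total == 0:
        raise ValueError("call rate undefined for zero variants")
    return called / total


def call_rates(records: list[VariantRecord], sample_ids: list[str]) -> pd.Series:
    """Per-sample call rate across all records."""
    if not records:
        raise ValueError("call rate undefined for zero variants")
    idx = {s: i for i, s in enumerate(sample_ids)}
    missing = np.zeros(len(sample_ids), dtype=int)
    for r in records:
        for c in r.calls:
            if c.gt == "missing":
                missing[idx[c.sample_id]] += 1
    return pd.Series(1.0 - missing / len(records), index=sample_ids, name="call_rate")


# ---------------------------------------------------------------------------
# orchestration


def run_sample_qc(
    records: list[VariantRecord],
    sample_ids: list[str],
    reported_sex: dict[str, str],
    min_x_sites: int = 50,
    min_kinship_sites: int = 200,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full sample QC: returns (per-sample table, flagged-pair table).

    Allele frequencies for the sex check are estimated from female-reported
    samples only, since male hemizygosity would bias p on X; if no females are
    reported, all samples are used.
    """
    xd, xh, _ = x_dosage_matrix(records, sample_ids)
    females = [i for i, s in enumerate(sample_ids) if reported_sex.get(s) == "female"]
    freq_rows = xd[females] if females else xd
    with np.errstate(invalid="ignore"):
        p = np.nanmean(freq_rows, axis=0) / 2.0
    p = np.nan_to_num(p, nan=0.0)
    f = x_inbreeding(xd, p, min_sites=min_x_sites)

    ad, _ = autosomal_dosage_matrix(records, sample_ids)
    phi = king_kinship_matrix(ad)
    cr = call_rates(records, sample_ids)

    rows = []
    for i, s in enumerate(sample_ids):
        fx = None if np.isnan(f[i]) else float(f[i])
        inferred, mismatch = infer_sex(fx, reported_sex.get(s))
        rows.append({
            "sample_id": s,
            "f_x": fx,
            "inferred_sex": inferred,
            "sex_concordant": inferred == reported_sex.get(s),
            "sex_mismatch": mismatch,
            "call_rate": cr[s],
            "call_rate_pass": cr[s] >= CALL_RATE_MIN,
        })
    qc = pd.DataFrame(rows)

    shared = (~np.isnan(ad)).astype(float)
    n_shared = shared @ shared.T
    pair_rows = []
    for i in range(len(sample_ids)):
        for j in range(i + 1, len(sample_ids)):
            if n_shared[i, j] < min_kinship_sites or np.isnan(phi[i, j]):
                continue
            if phi[i, j] >= KINSHIP_RELATED_THRESHOLD:
                pair_rows.append({
                    "sample_i": sample_ids[i], "sample_j": sample_ids[j],
                    "phi": float(phi[i, j]),
                    "n_informative_sites": int(n_shared[i, j]),
                })
    related = pd.DataFrame(pair_rows,
                           columns=["sample_i", "sample_j", "phi", "n_informative_sites"])
    qc["related_flag"] = qc["sample_id"].isin(
        set(related["sample_i"]) | set(related["sample_j"])
    )
    return qc, related
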