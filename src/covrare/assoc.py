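"""Case-only association analyses, cohort summary, and pipeline orchestration.

The design is case-only: every individual is a hospitalized case, and the
polygenic score is tested against within-case strata — age group (< 40 vs
≥ 40 years) and rare-variant carrier status — by logistic regression with the
stratum indicator as outcome and the (standardized) PRS as primary predictor,
adjusting for sex and ten ancestry principal components.  Secondary models
add BMI, then BMI + smoking, on the subset with those covariates available
(listwise deletion).  Every model is fitted on the full cohort and on the
PCA-defined European-ancestry subset.  P-values are Wald tests.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .variantio import SampleRecord

logger = logging.getLogger(__name__)

__all__ = [
    "AssocResult",
    "CohortSummary",
    "SeparationError",
    "fit_logistic",
    "run_prs_models",
    "summarize_cohort",
    "run_pipeline",
]

Z95 = 1.96


class SeparationError(RuntimeError):
    """Perfect or quasi-perfect separation: the model is not reportable."""


class ConfigError(ValueError):
    """Pipeline configuration is missing or inconsistent."""


@dataclass
class AssocResult:
    outcome: str  # age_lt_40 | carrier
    subset: str  # full | eur
    model: str  # primary | bmi | bmi_smoking
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    p_wald: float
    covariates: list[str]
    n_used: int


@dataclass
class CohortSummary:
    """Per-category counts and percentages, Table-1 style."""

    n: int
    blocks: dict[str, list[tuple[str, int, float]]]  # block -> (category, count, pct)


# ---------------------------------------------------------------------------
# logistic fitting


def fit_logistic(y: np.ndarray, X: np.ndarray, names: list[str] | None = None):
    """Maximum-likelihood logistic fit (Newton/IRLS, tol 1e-8, ≤100 iters).

    Returns (beta, se, p_wald) arrays over the columns of X (X must already
    include the intercept).  Raises :class:`SeparationError` on perfect
    separation or a degenerate outcome, and ValueError for a constant
    non-intercept column.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    if len(np.unique(y)) < 2:
        raise SeparationError("degenerate outcome: all responses identical")
    const_cols = np.where(X.std(axis=0) == 0)[0]
    if len(const_cols) > 1:
        raise ValueError("design has a constant non-intercept column")
    import warnings as _w

    try:
        with _w.catch_warnings(), np.errstate(all="ignore"):
            _w.simplefilter("ignore", RuntimeWarning)
            _w.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, X).fit(method="newton", maxiter=100, tol=1e-8, disp=0)
    except (PerfectSeparationError, PerfectSeparationWarning) as e:
        raise SeparationError(str(e)) from e
    except np.linalg.LinAlgError as e:
        raise SeparationError(f"singular information matrix: {e}") from e
    beta = np.asarray(res.params, float)
    if not res.mle_retvals.get("converged", True) and np.any(np.abs(beta) > 15):
        raise SeparationError("non-convergence with diverging coefficients")
    se = np.asarray(res.bse, float)
    z = np.abs(beta / se)
    p = 2.0 * (1.0 - stats.norm.cdf(z))
    return beta, se, p


def _fit_one(df: pd.DataFrame, outcome: str, covars: list[str],
             subset: str, model: str, min_events: int) -> AssocResult:
    cols = [outcome, "prs_z"] + covars
    d = df.dropna(subset=cols)
    y = d[outcome].astype(float).to_numpy()
    events = int(y.sum())
    if min(events, len(y) - events) < min_events:
        raise SeparationError(
            f"{outcome}/{subset}/{model}: only {min(events, len(y) - events)} "
            f"events (< {min_events}); refusing to fit"
        )
    X = np.column_stack([np.ones(len(d)), d["prs_z"].to_numpy()]
                        + [d[c].to_numpy(float) for c in covars])
    beta, se, p = fit_logistic(y, X)
    b, s = float(beta[1]), float(se[1])
    return AssocResult(
        outcome=outcome, subset=subset, model=model, beta=b, se=s,
        or_=math.exp(b), ci95=(math.exp(b - Z95 * s), math.exp(b + Z95 * s)),
        p_wald=float(p[1]), covariates=covars, n_used=len(d),
    )


def run_prs_models(
    samples: pd.DataFrame,
    n_pcs: int = 10,
    standardize_prs: bool = True,
    min_events: int = 5,
    models: tuple[str, ...] = ("primary", "bmi", "bmi_smoking"),
) -> tuple[list[AssocResult], list[str]]:
    """Fit the case-only PRS association battery.

    ``samples`` needs columns: prs, age, carrier, reported_sex, PC1..PCn,
    bmi, smoking, eur (bool).  Returns (results, skipped-model messages).
    PRS is z-standardized within each analyzed subset (so the odds ratio is
    per standard deviation of score); permutation of sample rows does not
    change any fitted value.
    """
    df = samples.copy()
    df["age_lt_40"] = (df["age"] < 40).astype(float)
    df["carrier"] = df["carrier"].astype(float)
    df["sex_male"] = (df["reported_sex"] == "male").astype(float)
    if "smoking" in df.columns:
        df["smoking_yes"] = df["smoking"].map({"yes": 1.0, "no": 0.0})
    pcs = [f"PC{i}" for i in range(1, n_pcs + 1) if f"PC{i}" in df.columns]
    base = ["sex_male"] + pcs
    model_covars = {
        "primary": base,
        "bmi": base + ["bmi"],
        "bmi_smoking": base + ["bmi", "smoking_yes"],
    }
    subsets = {"full": np.ones(len(df), bool)}
    if "eur" in df.columns:
        subsets["eur"] = df["eur"].astype(bool).to_numpy()
    results, skipped = [], []
    for subset, mask in subsets.items():
        sub = df.loc[mask].copy()
        if standardize_prs:
            mu, sd = sub["prs"].mean(), sub["prs"].std(ddof=0)
            sub["prs_z"] = (sub["prs"] - mu) / (sd if sd > 0 else 1.0)
        else:
            sub["prs_z"] = sub["prs"]
        for outcome in ("age_lt_40", "carrier"):
            for model in models:
                try:
                    results.append(
                        _fit_one(sub, outcome, model_covars[model], subset,
                                 model, min_events)
                    )
                except (SeparationError, ValueError) as e:
                    skipped.append(f"{outcome}/{subset}/{model}: {e}")
                    logger.warning("model skipped: %s", e)
    return results, skipped


def assoc_to_frame(results: list[AssocResult]) -> pd.DataFrame:
    return pd.DataFrame([
        {
            "outcome": r.outcome, "subset": r.subset, "model": r.model,
            "beta": r.beta, "se": r.se, "or": r.or_,
            "ci95_low": r.ci95[0], "ci95_high": r.ci95[1],
            "p_wald": r.p_wald, "n_used": r.n_used,
            "covariates": ",".join(r.covariates),
        }
        for r in results
    ])


# ---------------------------------------------------------------------------
# cohort summary


def _round1(count: int, n: int) -> float:
    """100·count/n rounded half-up to one decimal, in exact decimal arithmetic."""
    return float((Decimal(100 * count) / Decimal(n)).quantize(
        Decimal("0.1"), rounding=ROUND_HALF_UP))


AGE_BINS = [("18-29", 18, 29), ("30-39", 30, 39), ("40-49", 40, 49), ("50-59", 50, 59)]
BMI_BINS = [("healthy_weight", 18.5, 24.9), ("overweight", 25.0, 29.9),
            ("obese", 30.0, 39.9)]


def summarize_cohort(samples: list[SampleRecord] | pd.DataFrame) -> CohortSummary:
    """Table-1-style counts and percentages of N per category block.

    Percentages are round-half-up to one decimal.  Missing values form their
    own "NA" category.  A WHO score below 4 triggers a warning (the modelled
    study's inclusion floor is 4).
    """
    if isinstance(samples, pd.DataFrame):
        df = samples
    else:
        df = pd.DataFrame([{
            "reported_sex": s.reported_sex, "age": s.age, "bmi": s.bmi,
            "smoking": s.smoking, "vaccinated": s.vaccinated,
            "who_score": s.who_score,
        } for s in samples])
    n = len(df)
    if n == 0:
        raise ValueError("empty sample sheet")
    if (df["who_score"].dropna() < 4).any():
        import warnings
        warnings.warn("WHO score < 4 present (below the inclusion floor)",
                      stacklevel=2)
    blocks: dict[str, list[tuple[str, int, float]]] = {}

    def block(name, pairs):
        blocks[name] = [(cat, cnt, _round1(cnt, n)) for cat, cnt in pairs]

    sex = df["reported_sex"]
    block("sex", [("male", int((sex == "male").sum())),
                  ("female", int((sex == "female").sum()))])
    age = df["age"]
    block("age_group", [(lab, int(((age >= lo) & (age <= hi)).sum()))
                        for lab, lo, hi in AGE_BINS])
    bmi = df["bmi"]
    bmi_pairs = [(lab, int(((bmi >= lo) & (bmi <= hi)).sum()))
                 for lab, lo, hi in BMI_BINS]
    bmi_pairs.append(("NA", int(bmi.isna().sum())))
    block("bmi_category", bmi_pairs)
    if "smoking" in df.columns:
        sm_ = df["smoking"]
        block("smoking", [("no", int((sm_ == "no").sum())),
                          ("yes", int((sm_ == "yes").sum())),
                          ("NA", int(sm_.isna().sum()))])
    if "vaccinated" in df.columns:
        v = df["vaccinated"]
        block("vaccination", [("no", int((v == "no").sum())),
                              ("yes", int((v == "yes").sum())),
                              ("NA", int(v.isna().sum()))])
    who = df["who_score"]
    block("who_category", [
        ("dead", int((who == 10).sum())),
        ("severe", int(((who >= 6) & (who <= 9)).sum())),
        ("moderate", int(((who >= 4) & (who <= 5)).sum())),
    ])
    return CohortSummary(n=n, blocks=blocks)


def summary_to_frame(s: CohortSummary) -> pd.DataFrame:
    rows = []
    for blk, items in s.blocks.items():
        for cat, cnt, pct in items:
            rows.append({"block": blk, "category": cat, "count": cnt, "pct": pct})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# pipeline orchestration


def _config_hash(config: dict) -> str:
    return hashlib.sha256(
        json.dumps(config, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def run_pipeline(config: dict, out_dir: str | Path) -> dict:
    """Run every stage in dependency order and write the output bundle.

    ``config`` requires a ``seed`` and either a ``simulate`` section (synthetic
    cohort) or an ``inputs`` section with paths (vcf, samples, panel, weights,
    ref_genotypes, ref_labels).  Outputs: qc.tsv, related_pairs.tsv, pcs.tsv,
    labels.tsv, prs.tsv, candidates.tsv, candidates_clinical.tsv, cnv.tsv,
    assoc.tsv, summary.tsv and a run_manifest.json stamped with the config
    hash and seed.  Reruns on identical inputs are byte-identical.
    """
    from . import ancestry as anc
    from . import cohortsim, prs as prsmod, rarevar, sampleqc
    from . import variantio as vio

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config_hash": _config_hash(config), "seed": config.get("seed"),
                "status": "incomplete", "stage": None, "outputs": []}

    def _write_manifest():
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")

    if "seed" not in config:
        raise ConfigError("missing config key: seed")
    stage = "load"
    try:
        if "inputs" in config:
            req = ["vcf", "samples", "panel", "weights", "ref_genotypes", "ref_labels"]
            for k in req:
                if k not in config["inputs"]:
                    raise ConfigError(f"missing config key: inputs.{k}")
            inp = config["inputs"]
            records = vio.read_cohort_vcf(inp["vcf"])
            sheet = vio.read_sample_sheet(inp["samples"])
            panel = vio.read_gene_panel(inp["panel"])
            weights = vio.read_weights(inp["weights"])
            ref_geno = pd.read_csv(inp["ref_genotypes"], sep="\t", index_col=0)
            ref_labels = pd.read_csv(inp["ref_labels"], sep="\t", index_col=0)["pop"]
            sample_ids = [c.sample_id for c in records[0].calls] if records else []
        else:
            sim_cfg = cohortsim.SimConfig(
                seed=int(config["seed"]), **config.get("simulate", {})
            )
            sim = cohortsim.simulate_cohort(sim_cfg)
            records, sheet, panel, weights = sim.records, sim.samples, sim.panel, sim.weights
            ref_geno, ref_labels = sim.ref_genotypes, sim.ref_labels
            sample_ids = sim.sample_ids

        sexes = {s.sample_id: s.reported_sex for s in sheet}

        stage = "sampleqc"
        qc, related = sampleqc.run_sample_qc(records, sample_ids, sexes)
        qc.to_csv(out / "qc.tsv", sep="\t", index=False)
        related.to_csv(out / "related_pairs.tsv", sep="\t", index=False)

        stage = "ancestry"
        G, keys = sampleqc.autosomal_dosage_matrix(records, sample_ids)
        key_strs = [f"{c}:{p}:{r}:{a}" for c, p, r, a in keys]
        shared = [i for i, k in enumerate(key_strs) if k in set(ref_geno.index)]
        Gc = G[:, shared]
        Gr = ref_geno.loc[[key_strs[i] for i in shared]].to_numpy().T
        keep = anc.af_filter(Gc)
        Gc, Gr = Gc[:, keep], Gr[:, keep]
        pruned = anc.ld_prune(Gc)
        Gc, Gr = Gc[:, pruned.kept_indices], Gr[:, pruned.kept_indices]
        pca = anc.joint_pca(Gc, Gr)
        labels, votes = anc.classify_ancestry(
            pca.scores_ref, ref_labels.to_numpy(), pca.scores_cohort,
            seed=config.get("rf_seed", anc.DEFAULT_RF_SEED),
        )
        n_pcs = pca.scores_cohort.shape[1]
        pcs_df = pd.DataFrame(
            pca.scores_cohort, index=sample_ids,
            columns=[f"PC{i}" for i in range(1, n_pcs + 1)],
        )
        pcs_df.round(10).to_csv(out / "pcs.tsv", sep="\t", index_label="sample_id")
        lab_df = pd.DataFrame({"sample_id": sample_ids, "ancestry": labels,
                               "vote_fraction": votes})
        lab_df.to_csv(out / "labels.tsv", sep="\t", index=False)

        stage = "prs"
        qc_w = prsmod.variant_qc_for_scoring(records, weights)
        scores = prsmod.score_samples(qc_w, sample_ids)
        prs_df = pd.DataFrame([{
            "sample_id": r.sample_id, "prs": r.score,
            "n_weights_total": r.n_weights_total,
            "n_weights_used": r.n_weights_used,
            "n_missing_imputed": r.n_missing_imputed,
        } for r in scores])
        prs_df.to_csv(out / "prs.tsv", sep="\t", index=False)

        stage = "rarevar"
        research = rarevar.run_research_approach(records, panel, sexes)
        clinical = rarevar.run_clinical_approach(records, panel, sexes)
        rarevar.candidates_to_frame(research).to_csv(
            out / "candidates.tsv", sep="\t", index=False)
        rarevar.candidates_to_frame(clinical).to_csv(
            out / "candidates_clinical.tsv", sep="\t", index=False)
        carriers = {c.sample_id for c in research}

        stage = "cnv"
        region = tuple(config.get("cnv_region", cohortsim.TLR7_REGION))
        males = [s for s in sample_ids if sexes.get(s) == "male"]
        cnv = rarevar.deletion_screen(records, region, males,
                                      min_run=config.get("min_run", 5))
        pd.DataFrame([{
            "sample_id": c.sample_id, "region": c.region,
            "run_start": c.run_start, "run_end": c.run_end,
            "n_sites_in_run": c.n_sites_in_run,
            "fraction_of_region_sites": c.fraction_of_region_sites,
        } for c in cnv]).to_csv(out / "cnv.tsv", sep="\t", index=False)

        stage = "assoc"
        tbl = pd.DataFrame([{
            "sample_id": s.sample_id, "reported_sex": s.reported_sex,
            "age": s.age, "bmi": s.bmi, "smoking": s.smoking,
        } for s in sheet]).set_index("sample_id")
        tbl = tbl.join(prs_df.set_index("sample_id")["prs"])
        tbl = tbl.join(pcs_df)
        tbl["carrier"] = tbl.index.isin(carriers)
        tbl["eur"] = tbl.index.map(dict(zip(lab_df["sample_id"], lab_df["ancestry"]))) == "EUR"
        results, skipped = run_prs_models(tbl.reset_index(),
                                          n_pcs=config.get("n_pcs_assoc", 10))
        assoc_to_frame(results).to_csv(out / "assoc.tsv", sep="\t", index=False)
        manifest["skipped_models"] = skipped

        stage = "summary"
        summary_to_frame(summarize_cohort(sheet)).to_csv(
            out / "summary.tsv", sep="\t", index=False)

        manifest["status"] = "complete"
        manifest["stage"] = None
        manifest["outputs"] = sorted(p.name for p in out.glob("*.tsv"))
        _write_manifest()
        return {"out_dir": out, "manifest": manifest}
    except Exception:
        manifest["stage"] = stage
        _write_manifest()
        logger.error("pipeline failed at stage %s", stage)
        raise
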