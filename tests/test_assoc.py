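"""Logistic association battery, cohort summary, and the pipeline."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from covrare.assoc import (
    ConfigError,
    SeparationError,
    fit_logistic,
    run_pipeline,
    run_prs_models,
    summarize_cohort,
)

from conftest import subseed


def or_from_2x2(a, b, c, d):
    """Fit intercept + binary predictor on a 2×2 table and return exp(beta)."""
    y = np.array([1] * a + [0] * b + [1] * c + [0] * d, float)
    x = np.array([1] * (a + b) + [0] * (c + d), float)
    X = np.column_stack([np.ones_like(x), x])
    beta, se, p = fit_logistic(y, X)
    return np.exp(beta[1])


class TestFitLogistic:
    def test_two_by_two_equals_cross_product_ratio(self):
        assert or_from_2x2(20, 30, 10, 40) == pytest.approx((20 * 40) / (30 * 10),
                                                            abs=1e-6)

    def test_cross_product_identity_over_random_tables(self):
        rng = np.random.default_rng(subseed(31, 0))
        for _ in range(25):
            a, b, c, d = rng.integers(3, 60, 4)
            assert or_from_2x2(a, b, c, d) == pytest.approx((a * d) / (b * c),
                                                            rel=1e-6)

    def test_degenerate_outcome_raises(self):
        y = np.ones(30)
        X = np.column_stack([np.ones(30), np.arange(30.0)])
        with pytest.raises(SeparationError):
            fit_logistic(y, X)

    def test_perfect_separation_raises(self):
        x = np.linspace(-2, 2, 40)
        y = (x > 0).astype(float)
        with pytest.raises(SeparationError):
            fit_logistic(y, np.column_stack([np.ones(40), x]))

    def test_constant_non_intercept_column_rejected(self):
        y = np.array([0, 1] * 15, float)
        X = np.column_stack([np.ones(30), np.full(30, 3.0)])
        with pytest.raises(ValueError, match="constant"):
            fit_logistic(y, X)

    def test_wald_type1_error_near_nominal(self):
        """Null simulations: rejection rate at alpha=0.05 lands in a tight
        window around nominal (smaller replicate in the acceptance suite)."""
        rng = np.random.default_rng(subseed(31, 1))
        rejections = 0
        reps = 100
        for _ in range(reps):
            x = rng.normal(0, 1, 500)
            y = rng.binomial(1, 0.4, 500).astype(float)
            _, _, p = fit_logistic(y, np.column_stack([np.ones(500), x]))
            rejections += p[1] < 0.05
        assert 0.01 <= rejections / reps <= 0.10


class TestRunPrsModels:
    def _frame(self, seed, n=120, effect=-1.5):
        rng = np.random.default_rng(seed)
        prs = rng.normal(0, 1, n)
        logit = np.log(0.6) + effect * prs
        young = rng.random(n) < 1 / (1 + np.exp(-logit))
        df = pd.DataFrame({
            "sample_id": [f"S{i}" for i in range(n)],
            "prs": prs, "age": np.where(young, 30, 50),
            "carrier": rng.random(n) < 0.2,
            "reported_sex": rng.choice(["male", "female"], n),
            "bmi": rng.normal(27, 4, n), "smoking": rng.choice(["yes", "no"], n),
        })
        for i in range(1, 11):
            df[f"PC{i}"] = rng.normal(0, 1, n)
        return df

    def test_planted_effect_direction_recovered(self):
        res, _ = run_prs_models(self._frame(subseed(32, 0)), models=("primary",))
        r = next(x for x in res if x.outcome == "age_lt_40" and x.subset == "full")
        assert r.or_ < 1 and r.p_wald < 0.05
        assert r.ci95[0] < r.or_ < r.ci95[1]

    def test_null_effect_log_or_near_zero(self):
        betas = []
        for k in range(10):
            res, _ = run_prs_models(self._frame(subseed(32, 1 + k), effect=0.0),
                                    models=("primary",))
            r = next(x for x in res if x.outcome == "age_lt_40" and x.subset == "full")
            betas.append(r.beta)
        assert abs(np.median(betas)) < 0.2

    def test_row_permutation_invariance(self):
        df = self._frame(subseed(32, 99))
        res1, _ = run_prs_models(df, models=("primary",))
        perm = df.sample(frac=1.0, random_state=3).reset_index(drop=True)
        res2, _ = run_prs_models(perm, models=("primary",))
        for a, b in zip(res1, res2):
            assert a.beta == pytest.approx(b.beta, rel=1e-9)
            assert a.n_used == b.n_used

    def test_too_few_events_refused_with_message(self):
        df = self._frame(subseed(32, 100))
        df["carrier"] = False
        df.loc[:2, "carrier"] = True  # 3 events only
        res, skipped = run_prs_models(df, models=("primary",))
        assert not any(r.outcome == "carrier" for r in res)
        assert any("carrier" in s and "events" in s for s in skipped)


class TestSummarizeCohort:
    def test_reproduces_printed_percentages(self, printed_counts_sheet):
        s = summarize_cohort(printed_counts_sheet)
        b = {k: {cat: (cnt, pct) for cat, cnt, pct in v} for k, v in s.blocks.items()}
        assert b["sex"]["male"] == (82, 74.5)
        assert b["sex"]["female"] == (28, 25.5)
        assert b["age_group"]["18-29"] == (17, 15.5)
        assert b["age_group"]["30-39"] == (25, 22.7)
        assert b["age_group"]["40-49"] == (38, 34.5)
        assert b["age_group"]["50-59"] == (30, 27.3)
        assert b["bmi_category"]["healthy_weight"] == (27, 24.5)
        assert b["bmi_category"]["overweight"] == (43, 39.1)
        assert b["bmi_category"]["obese"] == (23, 20.9)
        assert b["bmi_category"]["NA"] == (17, 15.5)
        assert b["smoking"]["no"] == (95, 86.4)
        assert b["smoking"]["yes"] == (5, 4.5)
        assert b["smoking"]["NA"] == (10, 9.1)
        assert b["vaccination"]["no"] == (91, 82.7)
        assert b["vaccination"]["yes"] == (10, 9.1)
        assert b["vaccination"]["NA"] == (9, 8.2)
        assert b["who_category"]["dead"] == (1, 0.9)
        assert b["who_category"]["severe"] == (23, 20.9)
        assert b["who_category"]["moderate"] == (86, 78.2)

    def test_percentages_sum_to_hundred_within_rounding(self):
        rng = np.random.default_rng(subseed(33, 0))
        for _ in range(10):
            n = int(rng.integers(20, 200))
            df = pd.DataFrame({
                "reported_sex": rng.choice(["male", "female"], n),
                "age": rng.integers(18, 60, n),
                "bmi": np.where(rng.random(n) < 0.2, np.nan,
                                np.round(rng.uniform(18.5, 39.9, n), 1)),
                "smoking": rng.choice(["yes", "no", None], n),
                "vaccinated": rng.choice(["yes", "no", None], n),
                "who_score": rng.integers(4, 11, n),
            })
            s = summarize_cohort(df)
            for blk in ("sex", "bmi_category", "smoking", "who_category"):
                total = sum(p for _, _, p in s.blocks[blk])
                if blk == "sex":  # no NA category: counts may not exhaust n
                    continue
                assert abs(total - 100.0) <= 0.2

    def test_low_who_score_warns(self):
        df = pd.DataFrame({"reported_sex": ["male"], "age": [30], "bmi": [25.0],
                           "smoking": ["no"], "vaccinated": ["no"],
                           "who_score": [2]})
        with pytest.warns(UserWarning, match="WHO"):
            summarize_cohort(df)

    def test_empty_sheet_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            summarize_cohort(pd.DataFrame(columns=["reported_sex", "age", "bmi",
                                                   "smoking", "who_score"]))


class TestPipeline:
    def test_end_to_end_on_default_cohort(self, tmp_path, sim):
        """Master integration: the full pipeline on the default synthetic
        cohort recovers every truth-table label."""
        out = run_pipeline({"seed": 1}, tmp_path / "run")
        assert out["manifest"]["status"] == "complete"
        # candidates match planted truth
        cand = pd.read_csv(tmp_path / "run/candidates.tsv", sep="\t")
        got = set(map(tuple, cand[["sample_id", "chrom", "pos", "model"]].to_numpy()))
        tv = sim.truth.variants
        exp = set(map(tuple, tv[tv.expected_retained][
            ["sample_id", "chrom", "pos", "model"]].to_numpy()))
        assert got == exp
        # planted relatives flagged
        rel = pd.read_csv(tmp_path / "run/related_pairs.tsv", sep="\t")
        pairs = set(map(tuple, rel[["sample_i", "sample_j"]].to_numpy()))
        for row in sim.truth.related_pairs.itertuples():
            assert (row.sample_i, row.sample_j) in pairs
        # planted sex mismatch flagged
        qc = pd.read_csv(tmp_path / "run/qc.tsv", sep="\t")
        assert set(sim.truth.sex_mismatches.sample_id) <= set(
            qc[qc.sex_mismatch].sample_id)
        # deletion recovered
        cnv = pd.read_csv(tmp_path / "run/cnv.tsv", sep="\t")
        truth_del = sim.truth.deletions.iloc[0]
        assert len(cnv) == 1
        assert cnv.iloc[0].run_start == truth_del.run_start
        # association battery ran with both outcomes
        assoc = pd.read_csv(tmp_path / "run/assoc.tsv", sep="\t")
        assert {"age_lt_40", "carrier"} <= set(assoc.outcome)

    def test_rerun_is_byte_identical(self, tmp_path):
        cfg = {"seed": 6, "simulate": {"n_samples": 40,
                                       "n_background_variants": 400,
                                       "n_weights": 100,
                                       "n_extra_carrier_variants": 3}}
        run_pipeline(cfg, tmp_path / "a")
        run_pipeline(cfg, tmp_path / "b")
        for f in sorted((tmp_path / "a").iterdir()):
            assert f.read_bytes() == (tmp_path / "b" / f.name).read_bytes(), f.name

    def test_missing_config_key_named(self, tmp_path):
        with pytest.raises(ConfigError, match="seed"):
            run_pipeline({}, tmp_path / "x")
        with pytest.raises(ConfigError, match="inputs.vcf"):
            run_pipeline({"seed": 1, "inputs": {}}, tmp_path / "y")

    def test_file_inputs_match_in_memory_run(self, tmp_path, sim):
        """Writing the bundle to disk and running from files reproduces the
        in-memory candidates (reader/writer consistency end to end)."""
        paths = sim.write(tmp_path / "bundle")
        cfg = {"seed": 1, "inputs": {
            "vcf": str(paths["vcf"]), "samples": str(paths["samples"]),
            "panel": str(paths["panel"]), "weights": str(paths["weights"]),
            "ref_genotypes": str(paths["ref_genotypes"]),
            "ref_labels": str(paths["ref_labels"]),
        }}
        run_pipeline(cfg, tmp_path / "fromfiles")
        run_pipeline({"seed": 1}, tmp_path / "insim")
        a = pd.read_csv(tmp_path / "fromfiles/candidates.tsv", sep="\t")
        b = pd.read_csv(tmp_path / "insim/candidates.tsv", sep="\t")
        pd.testing.assert_frame_equal(a, b)
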