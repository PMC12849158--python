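"""The prioritization cascade: every gate, retention rule, both approaches,
and the deletion screen."""

from __future__ import annotations

import numpy as np
import pytest

from covrare.rarevar import (
    clinvar_rescue,
    cohort_af_exclusion,
    deletion_screen,
    evidence_consistent,
    functional_class,
    genotype_qc,
    model_af_gate,
    run_clinical_approach,
    run_research_approach,
    subset_to_panel,
)
from covrare.variantio import (
    AnnotationSet,
    GenePanelEntry,
    GenotypeCall,
    VariantRecord,
)


def ann(**kw):
    return AnnotationSet(gene=kw.pop("gene", "G1"), **kw)


def rec(pos, gts_by_sample, annotations, chrom="chr1", cohort_af=None,
        depths=None, pad_to=24):
    """Build a record; pads with hom-ref background samples so that a single
    carrier stays under the 10% cohort-AF exclusion."""
    gts_by_sample = dict(gts_by_sample)
    for k in range(pad_to - len(gts_by_sample)):
        gts_by_sample.setdefault(f"BG{k:02d}", "hom_ref")
    calls = []
    for sid, g in gts_by_sample.items():
        rd, ad = (depths or {}).get(sid, (15, 15) if g == "het" else
                                    ((30, 0) if g in ("hom_ref", "hemi_ref")
                                     else (0, 30)))
        dp = rd + ad
        calls.append(GenotypeCall(sid, g, depth=dp, ref_depth=rd, alt_depth=ad))
    r = VariantRecord(chrom, pos, "A", "G", calls, annotations)
    from covrare.variantio import compute_cohort_af
    r.cohort_af = cohort_af if cohort_af is not None else compute_cohort_af(r)
    return r


PANEL = [
    GenePanelEntry("G1", "chr1", 1000, 2000, "AD", "IEI"),
    GenePanelEntry("G2", "chr1", 1990, 3000, "AR", "IEI"),
    GenePanelEntry("GX", "chrX", 50_000_000, 50_010_000, "XLR", "IEI"),
    GenePanelEntry("G3", "chr2", 500, 900, "AD_AR", "GWAS"),
]


class TestRegionAndCohortAf:
    def test_boundary_inside_kept_outside_dropped(self):
        inside = rec(1000, {"S": "het"}, [ann()])
        outside = rec(999, {"S": "het"}, [ann()])
        kept = subset_to_panel([inside, outside], PANEL)
        assert [r.pos for r in kept] == [1000]

    def test_overlapping_genes_give_one_evaluation_per_gene(self):
        r = rec(1995, {"S": "het"}, [ann(gene="G1"), ann(gene="G2")])
        (kept,) = subset_to_panel([r], PANEL)
        assert {a.gene for a in kept.annotations} == {"G1", "G2"}
        # interval-overlap oracle
        assert sum(1 for g in PANEL if g.chrom == "chr1"
                   and g.start <= 1995 <= g.end) == 2

    @pytest.mark.parametrize("af,kept", [(0.10, False), (0.0999, True), (0.0, True)])
    def test_cohort_af_strict_boundary(self, af, kept):
        r = rec(1500, {"S": "het"}, [ann()], cohort_af=af)
        assert bool(cohort_af_exclusion([r])) is kept

    def test_undefined_af_dropped(self):
        r = rec(1500, {"S": "missing"}, [ann()], pad_to=1)
        assert cohort_af_exclusion([r]) == []


class TestFunctionalClassAndGates:
    @pytest.mark.parametrize("a,expected", [
        (dict(consequence="stop_gained", impact="HIGH"), "pLoF"),
        (dict(consequence="missense_variant", impact="MODERATE", cadd_phred=25.4),
         "missense_cadd"),
        (dict(consequence="missense_variant", impact="MODERATE", cadd_phred=20.0),
         None),  # strict inequality
        (dict(consequence="intron_variant", impact="MODIFIER", spliceai_max_ds=0.62),
         "splice_ai"),
        (dict(consequence="intron_variant", impact="MODIFIER", spliceai_max_ds=0.49),
         None),
        (dict(consequence="missense_variant", impact="MODERATE"), None),  # no score
        # evaluation order: HIGH impact wins over a qualifying CADD
        (dict(consequence="stop_gained", impact="HIGH", cadd_phred=35.0), "pLoF"),
    ])
    def test_functional_class(self, a, expected):
        assert functional_class(ann(**a)) == expected

    @pytest.mark.parametrize("pop_af,model,ok", [
        (2.751e-5, "recessive", True),
        (2.478e-6, "dominant", True),
        (1e-3, "recessive", False),  # strict boundary
        (1e-4, "dominant", False),
        (9.99e-5, "dominant", True),
        (None, "dominant", True),  # absent = unobserved = maximally rare
        (None, "recessive", True),
    ])
    def test_model_af_gate(self, pop_af, model, ok):
        assert model_af_gate(ann(pop_af=pop_af), model) is ok

    @pytest.mark.parametrize("sig,rescued", [
        ("Pathogenic", True), ("Likely_pathogenic", True),
        ("Pathogenic/Likely_pathogenic", True), ("likely pathogenic", True),
        ("Uncertain_significance", False), ("Benign", False), (None, False),
    ])
    def test_clinvar_rescue_labels(self, sig, rescued):
        assert clinvar_rescue(ann(clinvar_sig=sig)) is rescued


class TestGenotypeQc:
    @pytest.mark.parametrize("rd,ad,zyg,ok", [
        (10, 12, "het", True),   # AB 0.545, both ≥ 4
        (3, 20, "het", False),   # ref reads < 4 and AB 0.87
        (1, 30, "hemi", True),   # AB 0.968 > 0.95
        (1, 24, "het", False),   # AB 0.96 outside het window
        (3, 27, "hom", False),   # AB 0.90 ≤ 0.95
        (0, 30, "hom", True),
        (0, 0, "het", False),    # undefined AB
        (4, 4, "het", True),     # minimum reads boundary
    ])
    def test_allelic_balance_rules(self, rd, ad, zyg, ok):
        call = GenotypeCall("s", "het", depth=rd + ad, ref_depth=rd, alt_depth=ad)
        assert genotype_qc(call, zyg) is ok


class TestRetention:
    def _cands(self, records, panel=None, sexes=None, approach="research", **kw):
        run = run_research_approach if approach == "research" else run_clinical_approach
        return run(records, panel or PANEL, sexes or {"S": "female"}, **kw)

    def test_recessive_single_het_not_retained(self):
        r = rec(2500, {"S": "het"}, [ann(gene="G2", consequence="missense_variant",
                                         impact="MODERATE", cadd_phred=25, pop_af=5e-4)])
        # dominant AF gate fails at 5e-4; recessive passes but a lone het is
        # never retained — so nothing comes out at all
        assert self._cands([r]) == []

    def test_two_hets_same_gene_sample_both_compound_members(self):
        anns = [ann(gene="G2", consequence="missense_variant", impact="MODERATE",
                    cadd_phred=25, pop_af=5e-4)]
        r1 = rec(2500, {"S": "het", "T": "hom_ref"}, anns)
        r2 = rec(2600, {"S": "het", "T": "hom_ref"}, anns)
        cands = [c for c in self._cands([r1, r2]) if c.model == "recessive"]
        assert len(cands) == 2
        assert all(c.zygosity_class == "compound_het_member" for c in cands)
        assert all(c.phase == "phase_unknown" for c in cands)

    def test_compound_het_threshold_configurable(self):
        anns = [ann(gene="G2", consequence="missense_variant", impact="MODERATE",
                    cadd_phred=25, pop_af=5e-4)]
        recs = [rec(2500, {"S": "het"}, anns), rec(2600, {"S": "het"}, anns)]
        assert self._cands(recs, compound_het_min=3) == []

    def test_dominant_excludes_homozygotes(self):
        r = rec(1500, {"S": "hom_alt"}, [ann(gene="G1", consequence="missense_variant",
                                             impact="MODERATE", cadd_phred=25, pop_af=1e-5)])
        cands = self._cands([r])
        assert not any(c.model == "dominant" for c in cands)
        # but the recessive model retains the homozygote
        assert any(c.model == "recessive" and c.zygosity_class == "hom" for c in cands)

    def test_clinvar_rescue_bypasses_af_but_not_zygosity(self):
        # common pathogenic variant: rescued for dominant het, but a single
        # het still fails recessive retention
        r = rec(1500, {"S": "het"}, [ann(gene="G1", consequence="missense_variant",
                                         impact="MODERATE", cadd_phred=10,
                                         pop_af=5e-3, clinvar_sig="Pathogenic")])
        cands = self._cands([r])
        assert [c.model for c in cands] == ["dominant"]
        assert cands[0].reason == "clinvar_rescue"

    def test_xlr_male_hemizygote_is_clinical_candidate(self):
        r = rec(50_005_000, {"M": "hemi_alt"}, [ann(gene="GX",
                consequence="missense_variant", impact="MODERATE",
                cadd_phred=25.4, pop_af=2.751e-5)], chrom="chrX")
        cands = self._cands([r], sexes={"M": "male"}, approach="clinical")
        assert len(cands) == 1
        assert (cands[0].model, cands[0].zygosity_class) == ("recessive", "hemi")

    def test_clinical_respects_reported_inheritance(self):
        # qualifying hom in an AD gene is not retained clinically
        r = rec(1500, {"S": "hom_alt"}, [ann(gene="G1", consequence="missense_variant",
                                             impact="MODERATE", cadd_phred=25, pop_af=1e-5)])
        assert self._cands([r], approach="clinical") == []
        # AR gene, single het: nothing either
        r2 = rec(2500, {"S": "het"}, [ann(gene="G2", consequence="missense_variant",
                                          impact="MODERATE", cadd_phred=25, pop_af=5e-4)])
        assert self._cands([r2], approach="clinical") == []

    def test_research_finds_dominant_het_in_ar_gene(self):
        r = rec(2500, {"S": "het"}, [ann(gene="G2", consequence="missense_variant",
                                         impact="MODERATE", cadd_phred=26, pop_af=5e-5)])
        cands = self._cands([r])
        assert any(c.model == "dominant" and c.gene == "G2" for c in cands)
        # the same variant is not a clinical candidate (G2 is recessive-only)
        assert self._cands([r], approach="clinical") == []

    def test_inconsistent_male_x_het_excluded(self):
        r = rec(50_005_000, {"M": "het"}, [ann(gene="GX",
                consequence="missense_variant", impact="MODERATE",
                cadd_phred=25, pop_af=1e-5)], chrom="chrX")
        assert self._cands([r], sexes={"M": "male"}) == []


class TestCascadeOnGenerator:
    def test_truth_table_exact_recovery_research(self, sim, sexes):
        cands = run_research_approach(sim.records, sim.panel, sexes)
        got = {(c.sample_id, c.chrom, c.pos, c.model, c.zygosity_class)
               for c in cands}
        tv = sim.truth.variants
        exp = {(r.sample_id, r.chrom, r.pos, r.model, r.zygosity)
               for r in tv[tv.expected_retained].itertuples()}
        assert got == exp  # every planted retention, zero extras

    def test_truth_table_exact_recovery_clinical(self, sim, sexes):
        cands = run_clinical_approach(sim.records, sim.panel, sexes)
        got = {(c.sample_id, c.chrom, c.pos, c.model, c.zygosity_class)
               for c in cands}
        tv = sim.truth.variants
        exp = {(r.sample_id, r.chrom, r.pos, r.model, r.zygosity)
               for r in tv[tv.expected_in_clinical].itertuples()}
        assert got == exp

    def test_clinical_subset_of_research_on_shared_genes(self, sim, sexes):
        res = {(c.sample_id, c.chrom, c.pos, c.model)
               for c in run_research_approach(sim.records, sim.panel, sexes)}
        clin = {(c.sample_id, c.chrom, c.pos, c.model)
                for c in run_clinical_approach(sim.records, sim.panel, sexes)}
        assert clin <= res

    def test_every_candidate_evidence_self_consistent(self, sim, sexes):
        cands = run_research_approach(sim.records, sim.panel, sexes)
        assert cands and all(evidence_consistent(c) for c in cands)

    def test_no_planted_variants_means_no_candidates(self, sexes):
        from covrare.cohortsim import SimConfig, simulate_cohort
        clean = simulate_cohort(SimConfig(seed=2, planted=[],
                                          n_extra_carrier_variants=0))
        sx = dict(zip(clean.truth.samples.sample_id, clean.truth.samples.true_sex))
        assert run_research_approach(clean.records, clean.panel, sx) == []

    def test_tightening_cohort_af_never_adds_candidates(self, sim):
        recs = subset_to_panel(sim.records, sim.panel)
        loose = {r.key for r in cohort_af_exclusion(recs, 0.10)}
        tight = {r.key for r in cohort_af_exclusion(recs, 0.05)}
        assert tight <= loose


class TestDeletionScreen:
    REGION = ("chrX", 12_760_551, 12_980_636)

    def test_planted_run_detected_with_exact_coordinates(self, sim, sexes):
        males = [s for s, x in sexes.items() if x == "male"]
        out = deletion_screen(sim.records, self.REGION, males, min_run=5)
        truth = sim.truth.deletions.iloc[0]
        assert len(out) == 1
        c = out[0]
        assert (c.sample_id, c.run_start, c.run_end, c.n_sites_in_run) == (
            truth.sample_id, truth.run_start, truth.run_end, truth.n_sites)
        assert c.fraction_of_region_sites == pytest.approx(8 / 30)

    def test_isolated_missing_site_not_flagged(self):
        sites = []
        for k in range(10):
            gt = "missing" if k == 4 else "hemi_ref"
            dp = 0 if k == 4 else 30
            sites.append(VariantRecord("chrX", 12_760_600 + k * 100, "A", "G",
                                       [GenotypeCall("M", gt, depth=dp,
                                                     ref_depth=dp, alt_depth=0)]))
        assert deletion_screen(sites, self.REGION, ["M"], min_run=5) == []

    def test_longest_of_two_runs_reported(self):
        flags = [False, True, True, True, False, True, True, True, True, True, True, False]
        sites = []
        for k, f in enumerate(flags):
            gt, dp = ("missing", 0) if f else ("hemi_ref", 30)
            sites.append(VariantRecord("chrX", 12_760_600 + k * 10, "A", "G",
                                       [GenotypeCall("M", gt, depth=dp,
                                                     ref_depth=dp, alt_depth=0)]))
        out = deletion_screen(sites, self.REGION, ["M"], min_run=5)
        assert [(c.n_sites_in_run,) for c in out] == [(6,)]

    def test_empty_region_warns_and_returns_empty(self, caplog):
        import logging
        with caplog.at_level(logging.WARNING, logger="covrare.rarevar"):
            out = deletion_screen([], self.REGION, ["M"])
        assert out == [] and "no variant sites" in caplog.text
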