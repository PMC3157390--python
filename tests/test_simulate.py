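"""Synthetic-data generator: determinism, self-labelling fixtures, and
parameter recovery."""

import math

import numpy as np
import pandas as pd
import pytest

from replix.catalog import curate
from replix.io import read_catalog
from replix.simulate import (
    AssociationSpec,
    SimConfig,
    default_config,
    gen_catalog,
    gen_cohort,
    gen_surveys,
    solve_haplotype_freqs,
)


def small_config(seed=0, n=4000, **over):
    specs = (
        AssociationSpec("rs1000", "disease_a", raf=0.3, effect=1.5, prevalence=0.1, class_label="a"),
        AssociationSpec("rs1001", "disease_b", raf=0.2, effect=1.2, prevalence=0.05, class_label="b"),
        AssociationSpec("rs1002", "trait_q", raf=0.4, effect=0.2, trait_type="quantitative", class_label="q"),
    )
    kwargs = dict(seed=seed, n_subjects=n, associations=specs)
    kwargs.update(over)
    return SimConfig(**kwargs)


class TestDeterminism:
    def test_catalog_identical_across_runs(self):
        a = gen_catalog(default_config(seed=11))
        b = gen_catalog(default_config(seed=11))
        for key in a:
            pd.testing.assert_frame_equal(a[key], b[key])

    def test_cohort_identical_across_runs_and_seed_sensitive(self):
        a = gen_cohort(small_config(seed=5))
        b = gen_cohort(small_config(seed=5))
        c = gen_cohort(small_config(seed=6))
        pd.testing.assert_frame_equal(a["genotypes"], b["genotypes"])
        assert not a["genotypes"].drop(columns="subject_id").equals(c["genotypes"].drop(columns="subject_id"))

    def test_surveys_identical_across_runs(self):
        cfg = small_config(seed=5)
        ph = gen_cohort(cfg)["phenotypes"]
        pd.testing.assert_frame_equal(gen_surveys(cfg, ph), gen_surveys(cfg, ph))


class TestCatalogFixturesSelfVerify:
    def test_every_row_receives_its_intended_curation_outcome(self, tmp_path):
        cfg = default_config(seed=3)
        tables = gen_catalog(cfg)
        cat = tables["catalog"]
        cat.drop(columns="expected_outcome").to_csv(tmp_path / "cat.tsv", sep="\t", index=False, na_rep=".")
        entries = read_catalog(tmp_path / "cat.tsv")

        from replix.io import read_ld, read_platform

        tables["ld"].to_csv(tmp_path / "ld.tsv", sep="\t", index=False)
        tables["platform"].to_csv(tmp_path / "plat.tsv", sep="\t", index=False)
        refs = dict(zip(tables["reference"]["snp_id"], tables["reference"]["ref_freq"]))
        report = curate(entries, read_ld(tmp_path / "ld.tsv"), read_platform(tmp_path / "plat.tsv"), refs)

        curated = {(c.source.snp_id, c.source.study_id): c for c in report.curated}
        dropped = {(e.snp_id, e.study_id): r for e, r in report.dropped}
        review = {(c.source.snp_id, c.source.study_id) for c in report.review}
        for _, row in cat.iterrows():
            key = (row["snp_id"], row["study_id"])
            expect = row["expected_outcome"]
            if expect == "curated":
                assert key in curated and curated[key].proxy_r2 == 1.0, key
            elif expect == "curated_proxy":
                assert key in curated and curated[key].test_snp != row["snp_id"], key
            elif expect == "review":
                assert key in review, key
            elif expect == "duplicate":
                assert dropped.get(key) == "duplicate", key
            elif expect == "ld_pruned":
                assert dropped.get(key) == "ld_pruned", key
            elif expect == "no_proxy":
                assert dropped.get(key) == "no_proxy", key
            elif expect == "filtered":
                assert dropped.get(key) == "filtered", key
            else:  # pragma: no cover - generator emits a fixed label set
                raise AssertionError(f"unknown label {expect}")


class TestHaplotypeProxy:
    def test_haplotype_frequencies_reproduce_target_r2(self):
        for pa, pb, r2 in [(0.3, 0.3, 0.6), (0.2, 0.4, 0.3), (0.5, 0.5, 1.0)]:
            h = solve_haplotype_freqs(pa, pb, r2)
            assert h.sum() == pytest.approx(1.0, abs=1e-12)
            d = h[0] - pa * pb
            assert d**2 / (pa * (1 - pa) * pb * (1 - pb)) == pytest.approx(r2, abs=1e-12)

    def test_infeasible_r2_names_feasible_range(self):
        with pytest.raises(ValueError, match="feasible range"):
            solve_haplotype_freqs(0.05, 0.5, 0.9)

    def test_empirical_proxy_r2_near_target(self):
        cfg = small_config(seed=9, n=50_000, proxy_r2=(0.6,))
        geno = gen_cohort(cfg)["genotypes"]
        r = np.corrcoef(geno["rs1000"], geno["rs1000_proxy"])[0, 1]
        assert r**2 == pytest.approx(0.6, abs=0.02)


class TestParameterRecovery:
    def test_null_association_recovers_or_one(self):
        from replix.assoc import or_with_ci

        cfg = SimConfig(
            seed=21,
            n_subjects=10_000,
            associations=(AssociationSpec("rsN", "dnull", raf=0.3, effect=1.0, prevalence=0.2),),
            e_case=0.0,
            e_control=0.0,
        )
        cohort = gen_cohort(cfg)
        y = cohort["phenotypes"]["dnull"].to_numpy(float)
        g = cohort["genotypes"]["rsN"].to_numpy(float)
        or_hat, (lo, hi), _, _ = or_with_ci(g, y)
        assert lo < 1.0 < hi

    def test_effect_prevalence_recovered(self):
        from replix.assoc import or_with_ci

        cfg = SimConfig(
            seed=22,
            n_subjects=20_000,
            associations=(AssociationSpec("rsE", "deff", raf=0.3, effect=1.5, prevalence=0.1),),
            e_case=0.0,
            e_control=0.0,
        )
        cohort = gen_cohort(cfg)
        y = cohort["phenotypes"]["deff"].to_numpy(float)
        g = cohort["genotypes"]["rsE"].to_numpy(float)
        assert abs(y.mean() - 0.1) < 2 * math.sqrt(0.1 * 0.9 / len(y))
        or_hat, (lo, hi), _, _ = or_with_ci(g, y)
        assert lo < 1.5 < hi

    def test_misreport_rates_realized(self):
        cfg = small_config(seed=23, n=30_000, e_case=0.10, e_control=0.02)
        ph = gen_cohort(cfg)["phenotypes"]
        true = ph["disease_a__true"].to_numpy()
        rep = ph["disease_a"].to_numpy()
        case_flip = (~rep[true]).mean()
        ctrl_flip = (rep[~true]).mean()
        assert case_flip == pytest.approx(0.10, abs=0.02)
        assert ctrl_flip == pytest.approx(0.02, abs=0.005)

    def test_quantitative_trait_slope(self):
        from replix.assoc import wald_linear_test

        cohort = gen_cohort(small_config(seed=24, n=20_000))
        res = wald_linear_test(
            cohort["genotypes"]["rs1002"].to_numpy(float),
            cohort["phenotypes"]["trait_q"].to_numpy(float),
            "+",
        )
        assert res.effect_estimate == pytest.approx(0.2, abs=0.03)


class TestSurveys:
    def test_answer_patterns_match_reported_status(self):
        from replix.phenotyping import PhenotypeDefinition, assign_case_control
        from replix.simulate import gen_surveys

        cfg = small_config(seed=31, n=5000, p_uncertain=0.0, p_inconsistent=0.0)
        cohort = gen_cohort(cfg)
        responses = gen_surveys(cfg, cohort["phenotypes"])
        from replix.phenotyping import SurveyResponse

        rs = [
            SurveyResponse(r.subject_id, r.question_id, r.answer, None if pd.isna(r.onset_age) else r.onset_age)
            for r in responses.itertuples()
        ]
        defn = PhenotypeDefinition("disease_a", ("q_disease_a_1", "q_disease_a_2"))
        out = {a.subject_id: a.status for a in assign_case_control(rs, defn)}
        rep = dict(zip(cohort["phenotypes"]["subject_id"], cohort["phenotypes"]["disease_a"]))
        assert all(out[s] == ("case" if rep[s] else "control") for s in out)

    def test_uncertainty_fraction_realized(self):
        cfg = small_config(seed=32, n=10_000, p_uncertain=0.1, p_inconsistent=0.0)
        cohort = gen_cohort(cfg)
        responses = gen_surveys(cfg, cohort["phenotypes"])
        per_pheno = responses[responses["question_id"] == "q_disease_a_1"]
        frac = (per_pheno["answer"] == "uncertain").mean()
        assert abs(frac - 0.1) < 2 * math.sqrt(0.1 * 0.9 / 10_000) + 0.005

    def test_zero_inconsistency_means_no_inconsistent_exclusions(self):
        from replix.phenotyping import PhenotypeDefinition, SurveyResponse, assign_case_control

        cfg = small_config(seed=33, n=2000, p_uncertain=0.05, p_inconsistent=0.0)
        cohort = gen_cohort(cfg)
        responses = gen_surveys(cfg, cohort["phenotypes"])
        rs = [SurveyResponse(r.subject_id, r.question_id, r.answer, None) for r in responses.itertuples()]
        defn = PhenotypeDefinition("disease_b", ("q_disease_b_1", "q_disease_b_2"))
        out = assign_case_control(rs, defn)
        assert not any(a.reason == "inconsistent" for a in out)
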