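"""Synthetic-cohort generators: determinism, structural validity, moment
checks against liability-threshold theory, and the exact calibration."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from famdep.meta import cohort_prevalence, pool_random_effects
from famdep.pedigree import RelationshipStructure
from famdep.scoring import score_responses
from famdep.simulate import (
    FamilyTemplate,
    GenerativeConfig,
    calibrate_liability_h2,
    expected_observed_h2,
    simulate_bivariate_binary,
    simulate_cohort_prevalences,
    simulate_continuous,
    simulate_liability_binary,
    simulate_pedigrees,
    simulate_prs_cohort,
    simulate_responses,
)
from famdep.varcomp import liability_to_observed_h2


class TestPedigreeGeneration:
    def test_deterministic_given_seed(self, tmp_path):
        cfg = GenerativeConfig(n_families=50, seed=9)
        p1, r1 = simulate_pedigrees(cfg)
        p2, r2 = simulate_pedigrees(cfg)
        pd.testing.assert_frame_equal(r1, r2)
        f1, f2 = tmp_path / "a.fam", tmp_path / "b.fam"
        p1.to_fam(f1)
        p2.to_fam(f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_counts_for_minimal_template(self):
        tpl = FamilyTemplate(p_extra_sib=0.0, p_twin_offspring=0.0)
        cfg = GenerativeConfig(n_families=10, template=tpl, seed=1)
        ped, roster = simulate_pedigrees(cfg)
        assert ped.n_individuals == 40  # 2 parents + twin pair each

    def test_mz_fraction_extremes(self):
        for frac, zyg in ((1.0, {"MZ"}), (0.0, {"DZ"})):
            tpl = FamilyTemplate(mz_fraction=frac)
            cfg = GenerativeConfig(n_families=30, template=tpl, seed=2)
            ped, _ = simulate_pedigrees(cfg)
            seen = set(ped.table.loc[ped.table["zygosity"] != "NA",
                                     "zygosity"])
            assert seen == zyg

    def test_generated_pedigrees_validate_and_build(self):
        cfg = GenerativeConfig(n_families=100, seed=3)
        ped, _ = simulate_pedigrees(cfg)  # Pedigree() validates on build
        rs = RelationshipStructure.from_pedigree(ped)
        assert len(rs.members) == 100


class TestLiabilityPhenotypes:
    def test_prevalence_matches_k(self):
        cfg = GenerativeConfig(n_families=8000, h2_liab=0.4,
                               prevalence=0.227, seed=4)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_liability_binary(ped, roster, cfg)
        assert ph["mdd"].mean() == pytest.approx(0.227, abs=0.01)

    def test_no_genetics_means_no_twin_concordance_excess(self):
        cfg = GenerativeConfig(n_families=6000, h2_liab=0.0, c2_liab=0.0,
                               prevalence=0.2, seed=5)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_liability_binary(ped, roster, cfg)
        r = twin_phenotype_correlation(ped, ph, "mdd")
        assert abs(r["MZ"]) < 0.04 and abs(r["DZ"]) < 0.04

    def test_mz_exceed_dz_similarity_under_heritability(self):
        cfg = GenerativeConfig(n_families=6000, h2_liab=0.7, c2_liab=0.0,
                               prevalence=0.3, seed=6)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_liability_binary(ped, roster, cfg)
        r = twin_phenotype_correlation(ped, ph, "mdd")
        assert r["MZ"] > r["DZ"] + 0.05

    def test_sex_shift_raises_female_prevalence(self):
        cfg = GenerativeConfig(n_families=6000, h2_liab=0.4,
                               prevalence=0.2, sex_threshold_shift=0.3,
                               seed=7)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_liability_binary(ped, roster, cfg)
        by_sex = ph.groupby("sex")["mdd"].mean()
        assert by_sex[2] > by_sex[1] + 0.03

    def test_infeasible_partition_rejected(self):
        with pytest.raises(ValueError):
            GenerativeConfig(h2_liab=0.8, c2_liab=0.3)


class TestContinuousPhenotypes:
    def test_mz_twins_identical_at_full_heritability(self):
        cfg = GenerativeConfig(n_families=500,
                               template=FamilyTemplate(mz_fraction=1.0),
                               seed=8)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_continuous(ped, roster, h2=1.0, seed=8)
        r = twin_phenotype_correlation(ped, ph, "y")
        assert r["MZ"] == pytest.approx(1.0, abs=1e-9)

    def test_unit_variance_and_parent_offspring_regression(self):
        cfg = GenerativeConfig(
            n_families=20000,
            template=FamilyTemplate(p_parents_phenotyped=1.0), seed=9)
        ped, roster = simulate_pedigrees(cfg)
        h2 = 0.6
        ph = simulate_continuous(ped, roster, h2=h2, seed=9)
        assert ph["y"].var() == pytest.approx(1.0, abs=0.02)
        t = ped.table
        twins = t[t["twin_group"] != "0"]
        fathers = ph.set_index("individual_id").loc[
            twins["father_id"], "y"].to_numpy()
        kids = ph.set_index("individual_id").loc[
            twins["individual_id"], "y"].to_numpy()
        cov = np.cov(fathers, kids)[0, 1]
        assert cov == pytest.approx(h2 / 2, abs=0.02)


class TestBivariate:
    def test_marginal_prevalences(self):
        cfg = GenerativeConfig(n_families=8000, h2_liab=0.4, rg=0.7,
                               prevalence=0.11, prevalence2=0.04, seed=10)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_bivariate_binary(ped, roster, cfg)
        assert ph["trait1"].mean() == pytest.approx(0.11, abs=0.01)
        assert ph["trait2"].mean() == pytest.approx(0.04, abs=0.006)

    def test_rg_zero_kills_cross_trait_cotwin_covariance(self):
        cfg = GenerativeConfig(n_families=8000, h2_liab=0.6, rg=0.0,
                               prevalence=0.3, prevalence2=0.3, seed=11)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_bivariate_binary(ped, roster, cfg)
        t = ped.table
        mz = t[t["zygosity"] == "MZ"]
        d = ph.set_index("individual_id")
        t1 = d.loc[mz["individual_id"], "trait1"].to_numpy()
        grp = mz.groupby(["family_id", "twin_group"]).cumcount().to_numpy()
        a, b = t1[grp == 0], d.loc[mz["individual_id"], "trait2"].to_numpy()[grp == 1]
        m = min(len(a), len(b))
        r = np.corrcoef(a[:m], b[:m])[0, 1]
        assert abs(r) < 0.04

    def test_missing_masks(self):
        cfg = GenerativeConfig(n_families=500, seed=12)
        ped, roster = simulate_pedigrees(cfg)
        ph = simulate_bivariate_binary(ped, roster, cfg, p_obs1=0.6,
                                       p_obs2=0.3)
        assert 0.4 < ph["trait1"].isna().mean() < 0.6
        assert 0.6 < ph["trait2"].isna().mean() < 0.8


class TestPrsCohort:
    def test_null_score_gives_or_near_one(self):
        from famdep.prs import gee_logistic

        cfg = GenerativeConfig(r2_prs_liab=0.0, prevalence=0.25, seed=13)
        pheno, _, _ = simulate_prs_cohort(8000, cfg)
        X = np.column_stack([np.ones(len(pheno)), pheno["prs"]])
        fit = gee_logistic(pheno["mdd"].to_numpy(dtype=float), X,
                           pheno["family_id"].to_numpy())
        assert fit.or_ci[0] < 1.0 < fit.or_ci[1]

    def test_dosage_expansion_reconstitutes_score(self):
        from famdep.prs import compute_prs

        cfg = GenerativeConfig(r2_prs_liab=0.05, prevalence=0.25, seed=14)
        pheno, dosages, weights = simulate_prs_cohort(500, cfg,
                                                      n_variants=1000)
        prof = compute_prs(dosages, weights)
        r = np.corrcoef(prof["z_score"], pheno["prs"])[0, 1]
        assert r > 0.95

    def test_within_family_score_correlation(self):
        cfg = GenerativeConfig(seed=15)
        pheno, _, _ = simulate_prs_cohort(40000, cfg, family_size=2)
        wide = pheno.assign(k=pheno.groupby("family_id").cumcount()).pivot(
            index="family_id", columns="k", values="prs")
        r = np.corrcoef(wide[0], wide[1])[0, 1]
        assert r == pytest.approx(0.5, abs=0.03)


class TestCohortTables:
    def test_zero_tau2_gives_small_i2(self):
        cfg = GenerativeConfig(tau2=0.0, mu_logit=-1.5, seed=16)
        i2 = []
        for rep in range(10):
            df = simulate_cohort_prevalences(cfg, k=8, seed=100 + rep)
            per = df.groupby("cohort_id")[["cases", "n"]].sum()
            ests = [cohort_prevalence(int(r.cases), int(r.n), cohort_id=i)
                    for i, r in per.iterrows()]
            i2.append(pool_random_effects(ests).I2)
        assert np.mean(i2) < 30

    def test_large_tau2_gives_i2_near_100(self):
        cfg = GenerativeConfig(tau2=0.5, mu_logit=-1.5, seed=17)
        i2 = []
        for rep in range(10):
            df = simulate_cohort_prevalences(cfg, k=8, seed=200 + rep)
            per = df.groupby("cohort_id")[["cases", "n"]].sum()
            ests = [cohort_prevalence(int(r.cases), int(r.n), cohort_id=i)
                    for i, r in per.iterrows()]
            i2.append(pool_random_effects(ests).I2)
        assert np.mean(i2) > 90

    def test_pooled_tracks_mean_logit(self):
        cfg = GenerativeConfig(tau2=0.0, mu_logit=-2.0, seed=18)
        df = simulate_cohort_prevalences(cfg, k=10, n_range=(4000, 6000))
        per = df.groupby("cohort_id")[["cases", "n"]].sum()
        ests = [cohort_prevalence(int(r.cases), int(r.n), cohort_id=i)
                for i, r in per.iterrows()]
        res = pool_random_effects(ests)
        assert res.pooled_p == pytest.approx(1 / (1 + np.exp(2.0)),
                                             abs=0.012)


class TestResponses:
    def test_round_trip_small(self):
        rng = np.random.default_rng(19)
        n = 500
        status = pd.DataFrame({
            "respondent_id": [f"R{i}" for i in range(n)],
            "status_lifetime": rng.choice(["case", "control"], n),
        })
        status["status_current"] = np.where(
            (status["status_lifetime"] == "case") & (rng.random(n) < 0.5),
            "case", "control")
        resp = simulate_responses(status, seed=20)
        scored = score_responses(resp)
        assert (scored["status_lifetime"].to_numpy()
                == status["status_lifetime"].to_numpy()).all()
        assert (scored["status_current"].to_numpy()
                == status["status_current"].to_numpy()).all()

    def test_screen_negative_controls_have_structural_missingness(self):
        status = pd.DataFrame({"respondent_id": range(300),
                               "status_lifetime": ["control"] * 300})
        resp = simulate_responses(status, seed=21)
        neg = (resp["scr_mood"] == 0) & (resp["scr_interest"] == 0)
        assert neg.any()
        assert resp.loc[neg, "sym_sleep"].isna().all()
        assert resp.loc[neg, "interference"].isna().all()

    def test_inconsistent_current_status_rejected(self):
        status = pd.DataFrame({"respondent_id": [0],
                               "status_lifetime": ["control"],
                               "status_current": ["case"]})
        with pytest.raises(ValueError, match="lifetime"):
            simulate_responses(status)


class TestExactCalibration:
    def test_matches_linear_bridge_at_small_heritability(self):
        """For weak liability heritability the orthant probabilities are in
        their linear regime, so the exact estimand matches the classical
        z^2/(K(1-K)) bridge."""
        tpl = FamilyTemplate()
        got = expected_observed_h2(0.1, 0.0, 0.227, tpl)
        lin = liability_to_observed_h2(0.1, 0.227)
        assert got == pytest.approx(lin, abs=0.004)

    def test_calibration_inverts_forward_map(self):
        tpl = FamilyTemplate()
        h2l = calibrate_liability_h2(0.25, 0.227, tpl)
        assert expected_observed_h2(h2l, 0.0, 0.227, tpl) == pytest.approx(
            0.25, abs=1e-3)

    def test_exact_exceeds_linear_at_high_heritability(self):
        # orthant covariances are convex in the liability correlation, so
        # the exact observed-scale estimand dominates the linear bridge
        tpl = FamilyTemplate()
        got = expected_observed_h2(0.8, 0.0, 0.10, tpl)
        lin = liability_to_observed_h2(0.8, 0.10)
        assert got > lin

    def test_infeasible_target_raises(self):
        with pytest.raises(ValueError, match="infeasible"):
            calibrate_liability_h2(0.9, 0.05)


def twin_phenotype_correlation(ped, pheno, trait):
    t = ped.table
    twins = t[t["twin_group"] != "0"]
    d = pheno.set_index("individual_id")[trait]
    out = {}
    for zyg in ("MZ", "DZ"):
        grp = twins[twins["zygosity"] == zyg]
        if grp.empty:
            continue
        k = grp.groupby(["family_id", "twin_group"]).cumcount().to_numpy()
        vals = d.loc[grp["individual_id"]].to_numpy()
        a, b = vals[k == 0], vals[k == 1]
        m = min(len(a), len(b))
        out[zyg] = float(np.corrcoef(a[:m], b[:m])[0, 1])
    return out
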