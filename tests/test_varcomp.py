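"""REML variance components: closed-form twin oracles, grid-search
verification, invariances and the liability-scale bridge."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from famdep.pedigree import Pedigree, RelationshipStructure
from famdep.simulate import (
    GenerativeConfig,
    simulate_continuous,
    simulate_pedigrees,
)
from famdep.varcomp import (
    AceModel,
    BivariateAceModel,
    LiabilityScale,
    _reml_neg2ll,
    filter_outliers_sd,
    liability_to_observed_h2,
    observed_to_liability_h2,
)

from conftest import simulate_twin_pairs


def fit_df(df, structure, trait="y", model="ACE"):
    return AceModel.from_dataframe(df, trait, ["age", "sex"], structure,
                                   model=model).fit()


class TestUnivariateRecovery:
    def test_null_model_recovery(self, twin_pair_pedigree):
        """Pure-noise data: h2 ~ 0 and sigma2_E ~ 1."""
        df = simulate_twin_pairs(twin_pair_pedigree, 0.0, 0.0, seed=10)
        res = fit_df(df, RelationshipStructure.from_pedigree(twin_pair_pedigree))
        assert res.h2 == pytest.approx(0.0, abs=0.05)
        assert res.params["sigma2_E"] == pytest.approx(1.0, abs=0.06)

    def test_falconer_closed_form_on_twin_pairs(self, twin_pair_pedigree):
        """Twin-pairs-only data at MZ/DZ correlations 0.6/0.3: REML h2
        matches Falconer's 2(rMZ - rDZ) computed from the same sample."""
        df = simulate_twin_pairs(twin_pair_pedigree, 0.6, 0.3, seed=11)
        struct = RelationshipStructure.from_pedigree(twin_pair_pedigree)
        res = fit_df(df, struct)
        # empirical within-pair correlations
        wide = df.assign(k=df.groupby("family_id").cumcount()).pivot(
            index="family_id", columns="k", values="y")
        zyg = twin_pair_pedigree.table.groupby("family_id")["zygosity"].agg(
            lambda s: [z for z in s if z != "NA"][0])
        r = {z: np.corrcoef(wide.loc[zyg == z, 0], wide.loc[zyg == z, 1])[0, 1]
             for z in ("MZ", "DZ")}
        falconer = 2 * (r["MZ"] - r["DZ"])
        assert res.h2 == pytest.approx(0.6, abs=0.07)
        assert res.h2 == pytest.approx(falconer, abs=0.08)
        assert res.c2 == pytest.approx(0.0, abs=0.06)

    def test_shared_environment_recovered(self, twin_pair_pedigree):
        """MZ = DZ correlation = 0.4 implies pure C, no A."""
        df = simulate_twin_pairs(twin_pair_pedigree, 0.4, 0.4, seed=12)
        res = fit_df(df, RelationshipStructure.from_pedigree(twin_pair_pedigree))
        assert res.h2 == pytest.approx(0.0, abs=0.06)
        assert res.c2 == pytest.approx(0.4, abs=0.06)

    def test_reml_optimum_beats_dense_grid_on_toy(self):
        """On a tiny 2-family dataset the optimizer's restricted likelihood
        is at least the best over a dense parameter grid."""
        rows = []
        for f in ("a", "b"):
            rows += [
                (f, f"{f}fa", "0", "0", "1", "0", "NA"),
                (f, f"{f}mo", "0", "0", "2", "0", "NA"),
                (f, f"{f}t1", f"{f}fa", f"{f}mo", "1", "1",
                 "MZ" if f == "a" else "DZ"),
                (f, f"{f}t2", f"{f}fa", f"{f}mo", "1", "1",
                 "MZ" if f == "a" else "DZ"),
            ]
        ped = Pedigree(pd.DataFrame(rows, columns=[
            "family_id", "individual_id", "father_id", "mother_id", "sex",
            "twin_group", "zygosity"]))
        struct = RelationshipStructure.from_pedigree(ped)
        rng = np.random.default_rng(3)
        ids = ped.table["individual_id"]
        y = rng.standard_normal(len(ids))
        X = np.ones((len(ids), 1))
        model = AceModel(y, X, ids, struct)
        res = model.fit()
        best_grid = np.inf
        grid = np.linspace(0.0, 2.5, 26)
        for a in grid:
            for c in grid:
                for e in np.linspace(0.05, 2.5, 25):
                    val = _reml_neg2ll(np.array([a, c, e]), model.groups, 1)
                    best_grid = min(best_grid, val)
        opt = _reml_neg2ll(res.params.to_numpy(), model.groups, 1)
        assert opt <= best_grid + 1e-4

    def test_duplicated_families_leave_estimates_unchanged(
            self, twin_pair_pedigree):
        df = simulate_twin_pairs(twin_pair_pedigree, 0.5, 0.25, seed=13)
        struct = RelationshipStructure.from_pedigree(twin_pair_pedigree)
        res1 = fit_df(df, struct)
        # duplicate every family under new ids
        t = twin_pair_pedigree.table.copy()
        t2 = t.copy()
        for c in ("family_id", "individual_id", "father_id", "mother_id"):
            t2[c] = np.where(t2[c] != "0", "dup" + t2[c], "0")
        ped2 = Pedigree(pd.concat([t, t2], ignore_index=True))
        df2 = pd.concat([df, df.assign(
            individual_id="dup" + df["individual_id"],
            family_id="dup" + df["family_id"])], ignore_index=True)
        res2 = fit_df(df2, RelationshipStructure.from_pedigree(ped2))
        assert res2.params.to_numpy() == pytest.approx(
            res1.params.to_numpy(), abs=2e-3)

    def test_h2_se_shrinks_with_sample_size(self):
        ses = []
        for n_fam in (400, 1600):
            cfg = GenerativeConfig(n_families=n_fam, seed=21)
            ped, roster = simulate_pedigrees(cfg, seed=21)
            df = simulate_continuous(ped, roster, h2=0.5, seed=22)
            res = fit_df(df, RelationshipStructure.from_pedigree(ped))
            ses.append(res.h2_se)
        ratio = ses[0] / ses[1]
        assert ratio == pytest.approx(2.0, abs=0.45)  # ~ sqrt(1600/400)

    def test_model_restriction_ae(self, twin_pair_pedigree):
        df = simulate_twin_pairs(twin_pair_pedigree, 0.6, 0.3, seed=14)
        res = fit_df(df, RelationshipStructure.from_pedigree(twin_pair_pedigree),
                     model="AE")
        assert res.params["sigma2_C"] == 0.0
        assert res.h2 == pytest.approx(0.6, abs=0.07)

    def test_boundary_flagged(self, twin_pair_pedigree):
        df = simulate_twin_pairs(twin_pair_pedigree, 0.6, 0.3, seed=15)
        res = fit_df(df, RelationshipStructure.from_pedigree(twin_pair_pedigree))
        if res.params["sigma2_C"] < 1e-6:
            assert res.on_boundary["sigma2_C"]


class TestBivariate:
    def make_data(self, rg, seed, n_fam=1200):
        cfg = GenerativeConfig(n_families=n_fam, h2_liab=0.5, rg=rg,
                               seed=seed)
        ped, roster = simulate_pedigrees(cfg, seed=seed)
        rng = np.random.default_rng(seed + 1)
        from famdep.simulate import _breeding_values
        cov = np.array([[0.5, rg * 0.5], [rg * 0.5, 0.5]])
        bv = _breeding_values(ped, cov, rng)
        e = rng.standard_normal((len(roster), 2)) * np.sqrt(0.5)
        y = bv + e
        df = roster[["individual_id", "family_id"]].copy()
        df["age"], df["sex"] = 40.0, 1.0
        df["y1"], df["y2"] = y[:, 0], y[:, 1]
        return ped, df

    def fit(self, ped, df):
        struct = RelationshipStructure.from_pedigree(ped)
        X = np.ones((len(df), 1))
        return BivariateAceModel(df["y1"], df["y2"], X, df["individual_id"],
                                 struct).fit()

    def test_near_identical_traits_have_rg_one(self, twin_pair_pedigree):
        """A re-measurement of the same trait (tiny independent error)
        carries the same genetic factor: rg ~ 1.  (An *exact* duplicate is
        degenerate: the within-person difference has zero variance and the
        restricted likelihood is unbounded.)"""
        df = simulate_twin_pairs(twin_pair_pedigree, 0.6, 0.3, seed=16)
        struct = RelationshipStructure.from_pedigree(twin_pair_pedigree)
        X = np.ones((len(df), 1))
        rng = np.random.default_rng(5)
        y2 = df["y"].to_numpy() + 0.15 * rng.standard_normal(len(df))
        res = BivariateAceModel(df["y"], y2, X,
                                df["individual_id"], struct).fit()
        assert res.rg == pytest.approx(1.0, abs=0.03)

    def test_independent_genetic_factors_give_rg_zero(self):
        ped, df = self.make_data(rg=0.0, seed=30)
        res = self.fit(ped, df)
        assert res.rg == pytest.approx(0.0, abs=0.12)

    def test_generating_rg_recovered(self):
        ped, df = self.make_data(rg=0.6, seed=31)
        res = self.fit(ped, df)
        assert res.rg == pytest.approx(0.6, abs=0.1)
        assert abs(res.rg) <= 1.0 + 1e-9

    def test_missing_by_trait_supported(self):
        ped, df = self.make_data(rg=0.5, seed=32, n_fam=800)
        rng = np.random.default_rng(7)
        df.loc[rng.random(len(df)) < 0.3, "y1"] = np.nan
        df.loc[rng.random(len(df)) < 0.3, "y2"] = np.nan
        res = self.fit(ped, df)
        assert res.converged
        assert res.rg == pytest.approx(0.5, abs=0.2)

    def test_constant_trait_rejected(self, twin_pair_pedigree):
        df = simulate_twin_pairs(twin_pair_pedigree, 0.5, 0.25, seed=17)
        struct = RelationshipStructure.from_pedigree(twin_pair_pedigree)
        with pytest.raises(ValueError, match="constant"):
            BivariateAceModel(df["y"], np.ones(len(df)), np.ones((len(df), 1)),
                              df["individual_id"], struct)


class TestOutlierFilter:
    def test_normal_sample_keeps_everything(self):
        x = np.random.default_rng(0).standard_normal(10000)
        assert filter_outliers_sd(x, k=5).all()

    def test_gross_outlier_removed(self):
        x = np.concatenate([np.random.default_rng(1).normal(0, 1, 500),
                            [40.0]])
        keep = filter_outliers_sd(x, k=5)
        assert not keep[-1] and keep[:-1].all()

    def test_k_zero_keeps_only_the_mean(self):
        x = np.array([1.0, 1.0, 2.0])
        keep = filter_outliers_sd(x, k=0)
        assert list(keep) == [False, False, False]
        x = np.array([1.0, 1.0, 1.0, 3.0])
        # mean 1.5; no value at the mean
        assert not filter_outliers_sd(x, k=0).any()

    def test_zero_variance_keeps_all(self):
        assert filter_outliers_sd(np.ones(5)).all()

    def test_moments_not_reiterated(self):
        # after removing the big outlier the small one would fall outside a
        # recomputed 5-sd band; single-pass filtering keeps it
        x = np.concatenate([np.zeros(200), [1.0], [1000.0]])
        keep = filter_outliers_sd(x, k=5)
        assert keep[-2] and not keep[-1]

    def test_needs_two_values(self):
        with pytest.raises(ValueError):
            filter_outliers_sd([1.0])


class TestLiabilityBridge:
    def test_zero_maps_to_zero(self):
        assert observed_to_liability_h2(0.0, 0.3)[0] == 0.0

    def test_half_prevalence_factor(self):
        h2l, ok = observed_to_liability_h2(1.0, 0.5)
        assert h2l == pytest.approx(0.25 / norm.pdf(0.0) ** 2, rel=1e-12)
        assert h2l == pytest.approx(np.pi / 2, rel=1e-12)

    def test_round_trip_identity(self):
        h2l, ok = observed_to_liability_h2(0.3, 0.227)
        assert ok
        assert liability_to_observed_h2(h2l, 0.227) == pytest.approx(
            0.3, abs=1e-12)

    def test_infeasible_target_flagged(self):
        h2l, ok = observed_to_liability_h2(0.9, 0.05)
        assert h2l > 1.0 and not ok

    def test_liability_scale_geometry(self):
        ls = LiabilityScale.from_prevalence(0.10)
        assert ls.t == pytest.approx(norm.ppf(0.9), rel=1e-12)
        assert ls.z == pytest.approx(norm.pdf(ls.t), rel=1e-12)
        with pytest.raises(ValueError):
            LiabilityScale.from_prevalence(1.5)
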