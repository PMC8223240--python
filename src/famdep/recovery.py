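"""Parameter-recovery experiments on synthetic cohorts.

Each experiment generates replicate twin-family cohorts at a known
configuration, runs the corresponding estimator end to end, and reports the
replicate estimates — the package's own check that its estimators recover
the parameters its generators embed.  Binary-trait configurations are
specified on the observed scale and converted to generating liability-scale
values by the exact threshold-model calibration
(:func:`famdep.simulate.calibrate_liability_h2`), so the estimand of the
observed-scale fit equals the requested target.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .pedigree import RelationshipStructure
from .prs import gee_logistic
from .simulate import (
    GenerativeConfig,
    calibrate_liability_h2,
    calibrate_liability_rg,
    simulate_bivariate_binary,
    simulate_liability_binary,
    simulate_pedigrees,
    simulate_prs_cohort,
)
from .varcomp import AceModel, BivariateAceModel

__all__ = [
    "recover_h2_binary",
    "recover_h2_continuous",
    "recover_prs_or",
    "recover_rg_binary",
]


def _child_seeds(seed, n):
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(n)]


def _fit_h2(ped, roster, pheno, trait):
    struct = RelationshipStructure.from_pedigree(ped)
    res = AceModel.from_dataframe(pheno, trait, ["age", "sex"], struct).fit()
    return res


def recover_h2_binary(target_h2_obs: float, K: float, n_families=4000,
                      n_reps=20, seed=0) -> dict:
    """Replicated observed-scale heritability recovery for a binary trait.

    The generating liability h2 is set by exact threshold-model inversion
    so the pseudo-true observed-scale estimand equals ``target_h2_obs`` at
    prevalence ``K``; each replicate simulates a fresh cohort and fits the
    linear ACE model on the 0/1 phenotype with age and sex covariates.
    """
    h2_liab = calibrate_liability_h2(target_h2_obs, K)
    seeds = _child_seeds(seed, 2 * n_reps)
    values, ns = [], []
    for rep in range(n_reps):
        cfg = GenerativeConfig(n_families=n_families, h2_liab=h2_liab,
                               c2_liab=0.0, prevalence=K,
                               seed=seeds[2 * rep])
        ped, roster = simulate_pedigrees(cfg)
        pheno = simulate_liability_binary(ped, roster, cfg,
                                          seed=seeds[2 * rep + 1])
        res = _fit_h2(ped, roster, pheno, "mdd")
        values.append(res.h2)
        ns.append(res.n_used)
    return {"mean_h2": float(np.mean(values)), "values": values,
            "h2_liab_generating": h2_liab, "n_individuals": int(np.mean(ns))}


def recover_h2_continuous(h2: float, n_families=4000, n_reps=20,
                          seed=0) -> dict:
    """Replicated heritability recovery for a continuous unit-variance
    trait generated at additive proportion ``h2`` (no thresholding, so the
    generating and target values coincide)."""
    from .simulate import simulate_continuous

    seeds = _child_seeds(seed, 2 * n_reps)
    values, ns = [], []
    for rep in range(n_reps):
        cfg = GenerativeConfig(n_families=n_families, seed=seeds[2 * rep])
        ped, roster = simulate_pedigrees(cfg)
        pheno = simulate_continuous(ped, roster, h2=h2, c2=0.0,
                                    seed=seeds[2 * rep + 1], trait="y")
        res = _fit_h2(ped, roster, pheno, "y")
        values.append(res.h2)
        ns.append(res.n_used)
    return {"mean_h2": float(np.mean(values)), "values": values,
            "n_individuals": int(np.mean(ns))}


def recover_prs_or(r2_liab: float, case_fraction: float, n=50000,
                   n_reps=20, seed=0) -> dict:
    """Replicated odds ratio per SD of a polygenic score from
    family-clustered GEE logistic regression.

    Each replicate simulates ``n`` individuals in sibships where the score
    explains ``r2_liab`` of a unit liability (plus shared familial
    variance), thresholds at the requested case fraction, and fits the GEE
    with age and sex covariates.
    """
    seeds = _child_seeds(seed, n_reps)
    ors = []
    for rep in range(n_reps):
        cfg = GenerativeConfig(r2_prs_liab=r2_liab,
                               prevalence=case_fraction, seed=seeds[rep])
        pheno, _, _ = simulate_prs_cohort(n, cfg)
        age = pheno["age"].to_numpy()
        X = np.column_stack([
            np.ones(n), pheno["prs"].to_numpy(),
            age - age.mean(),
            np.where(pheno["sex"].to_numpy() == 2, 1.0, -1.0)])
        fit = gee_logistic(pheno["mdd"].to_numpy(dtype=float), X,
                           pheno["family_id"].to_numpy(),
                           exog_names=["intercept", "prs", "age", "sex"])
        ors.append(fit.or_per_sd)
    return {"mean_or": float(np.mean(ors)), "values": ors, "n": int(n)}


def recover_rg_binary(target_rg_obs: float, h2_liab: float, K1: float,
                      K2: float, n_families=5000, n_reps=20,
                      seed=0) -> dict:
    """Replicated genetic-correlation recovery for two binary traits.

    The generating liability-scale correlation is calibrated by exact
    threshold-model inversion so the observed-scale bivariate estimand
    equals ``target_rg_obs``; each replicate fits the bivariate ACE model
    on fresh simulated families.
    """
    rg_liab = calibrate_liability_rg(target_rg_obs, h2_liab, h2_liab,
                                     K1, K2)
    seeds = _child_seeds(seed, 2 * n_reps)
    values, ns = [], []
    for rep in range(n_reps):
        cfg = GenerativeConfig(n_families=n_families, h2_liab=h2_liab,
                               c2_liab=0.0, rg=rg_liab, prevalence=K1,
                               prevalence2=K2, seed=seeds[2 * rep])
        ped, roster = simulate_pedigrees(cfg)
        pheno = simulate_bivariate_binary(ped, roster, cfg,
                                         seed=seeds[2 * rep + 1])
        struct = RelationshipStructure.from_pedigree(ped)
        age = pheno["age"].to_numpy()
        X = np.column_stack([
            np.ones(len(pheno)), age - age.mean(),
            np.where(pheno["sex"].to_numpy() == 2, 1.0, -1.0)])
        res = BivariateAceModel(pheno["trait1"], pheno["trait2"], X,
                                pheno["individual_id"], struct,
                                exog_names=["intercept", "age", "sex"]).fit()
        values.append(res.rg)
        ns.append(res.n_used)
    return {"mean_rg": float(np.mean(values)), "values": values,
            "rg_liab_generating": rg_liab, "n_individuals": int(np.mean(ns))}
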