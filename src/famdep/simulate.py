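"""Synthetic twin-family cohorts under a liability-threshold model.

Every input the pipeline consumes can be generated here with known
parameters: extended twin-family pedigrees (MZ/DZ twin pairs with parents,
extra siblings and twin offspring), binary phenotypes arising from a latent
normal liability exceeding the prevalence threshold, continuous benchmark
traits, bivariate traits with a chosen genetic correlation, polygenic-score
cohorts, cohort-level prevalence tables with between-cohort heterogeneity,
and questionnaire responses whose symptom patterns score back to an
intended case/control status.

The generative genetic model is classical: founder breeding values are
N(0, h2_liab); an offspring receives the parental midpoint plus an
independent Mendelian-sampling deviation N(0, h2_liab/2); MZ co-twins share
one breeding value; co-twins (MZ and DZ alike) share a common-environment
deviate with variance c2_liab; the residual makes the liability variance 1.
Assortative mating, age effects on liability and participation bias are
deliberately absent — the generator realises exactly the assumptions of the
variance-component estimator it feeds.

Because a binary trait is a thresholded liability, the estimator operates
on the observed 0/1 scale while the generator operates on the liability
scale.  The classical linear bridge (``observed_to_liability_h2``) is a
small-correlation approximation that fails badly at common prevalences;
``calibrate_liability_h2`` and ``calibrate_liability_rg`` therefore invert
the *exact* threshold model: they compute, from bivariate-normal orthant
probabilities, the exact observed-scale family covariance matrices implied
by a liability parameter, locate the pseudo-true value of the
variance-component estimator on those covariances, and bisect the liability
parameter until the estimand equals the requested observed-scale target.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import multivariate_normal, norm

from .pedigree import Pedigree, RelationshipStructure, _family_a_matrix, \
    _family_c_matrix
from .varcomp import fit_components_to_covariances

__all__ = [
    "FamilyTemplate",
    "GenerativeConfig",
    "simulate_pedigrees",
    "simulate_liability_binary",
    "simulate_continuous",
    "simulate_bivariate_binary",
    "simulate_prs_cohort",
    "simulate_cohort_prevalences",
    "simulate_responses",
    "expected_observed_h2",
    "expected_observed_rg",
    "calibrate_liability_h2",
    "calibrate_liability_rg",
]


# ----------------------------------------------------------------------
# configuration


@dataclass(frozen=True)
class FamilyTemplate:
    """Composition of the simulated families.

    Defaults approximate an extended twin register: every family has two
    founders and a twin pair (45% MZ, matching a 2345:2882 MZ:DZ pair mix),
    parents are phenotyped in half of the families, a quarter have an
    additional full sibling and a quarter attach a spouse and one child to
    the first twin.
    """

    mz_fraction: float = 2345 / (2345 + 2882)
    p_parents_phenotyped: float = 0.5
    p_extra_sib: float = 0.25
    p_twin_offspring: float = 0.25

    def __post_init__(self):
        if not 0.0 <= self.mz_fraction <= 1.0:
            raise ValueError("mz_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class GenerativeConfig:
    """Generating parameters for the synthetic cohorts.

    All variance parameters are on the liability scale; ``h2_liab +
    c2_liab <= 1`` must hold.  ``sex_threshold_shift`` moves the liability
    of females up by the given amount (in liability SD units), producing a
    higher female prevalence as in depression.  Cohort-level prevalence
    heterogeneity is parameterised by the mean logit ``mu_logit`` and
    between-cohort variance ``tau2``.
    """

    n_families: int = 4000
    template: FamilyTemplate = field(default_factory=FamilyTemplate)
    h2_liab: float = 0.45
    c2_liab: float = 0.0
    prevalence: float = 0.227
    sex_threshold_shift: float = 0.0
    r2_prs_liab: float = 0.0147
    rg: float = 0.70
    prevalence2: float = 68 / 1682
    mu_logit: float = -1.5
    tau2: float = 0.3
    seed: int = 0

    def __post_init__(self):
        if self.h2_liab + self.c2_liab > 1.0 + 1e-12:
            raise ValueError("h2_liab + c2_liab must not exceed 1")
        for name in ("prevalence", "prevalence2"):
            v = getattr(self, name)
            if not 0.0 < v < 1.0:
                raise ValueError(f"{name} must lie in (0, 1)")
        if abs(self.rg) > 1.0:
            raise ValueError("|rg| must not exceed 1")


def _rng(seed_or_rng):
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


# ----------------------------------------------------------------------
# pedigrees


def _family_rows(fam_idx, mz, extra_sib, twin_offspring, rng):
    """Rows (PED columns + role) for one family realisation."""
    fid = f"F{fam_idx}"
    mk = lambda tag: f"{fid}_{tag}"
    rows = []
    rows.append((fid, mk("fa"), "0", "0", 1, "0", "NA", "parent"))
    rows.append((fid, mk("mo"), "0", "0", 2, "0", "NA", "parent"))
    zyg = "MZ" if mz else "DZ"
    if mz:
        s = int(rng.integers(1, 3))
        sexes = (s, s)
    else:
        sexes = (int(rng.integers(1, 3)), int(rng.integers(1, 3)))
    rows.append((fid, mk("t1"), mk("fa"), mk("mo"), sexes[0], "1", zyg, "twin"))
    rows.append((fid, mk("t2"), mk("fa"), mk("mo"), sexes[1], "1", zyg, "twin"))
    if extra_sib:
        rows.append((fid, mk("s1"), mk("fa"), mk("mo"),
                     int(rng.integers(1, 3)), "0", "NA", "sib"))
    if twin_offspring:
        sp_sex = 1 if sexes[0] == 2 else 2
        rows.append((fid, mk("sp"), "0", "0", sp_sex, "0", "NA", "spouse"))
        fa = mk("t1") if sexes[0] == 1 else mk("sp")
        mo = mk("sp") if sexes[0] == 1 else mk("t1")
        rows.append((fid, mk("c1"), fa, mo, int(rng.integers(1, 3)),
                     "0", "NA", "twin_child"))
    return rows


def simulate_pedigrees(config: GenerativeConfig, seed=None):
    """Draw a forest of twin families.

    Returns ``(Pedigree, roster)`` where the roster adds ``role`` and a
    boolean ``phenotyped`` column (parents are study members in a random
    half of families; everyone else is phenotyped).
    """
    rng = _rng(config.seed if seed is None else seed)
    tpl = config.template
    rows, phenotyped = [], []
    for f in range(config.n_families):
        mz = rng.random() < tpl.mz_fraction
        sib = rng.random() < tpl.p_extra_sib
        off = rng.random() < tpl.p_twin_offspring
        parents_ph = rng.random() < tpl.p_parents_phenotyped
        fam_rows = _family_rows(f, mz, sib, off, rng)
        rows.extend(fam_rows)
        for r in fam_rows:
            phenotyped.append(parents_ph if r[7] == "parent" else True)
    roster = pd.DataFrame(rows, columns=[
        "family_id", "individual_id", "father_id", "mother_id", "sex",
        "twin_group", "zygosity", "role"])
    roster["phenotyped"] = phenotyped
    ped = Pedigree(roster.drop(columns=["role", "phenotyped"]))
    return ped, roster


# ----------------------------------------------------------------------
# liability machinery


def _breeding_values(ped: Pedigree, cov_a: np.ndarray, rng) -> np.ndarray:
    """Breeding-value matrix (n_individuals, dim) aligned with ped.table.

    Founders draw N(0, cov_a); offspring get the parental midpoint plus a
    Mendelian deviation N(0, cov_a / 2); MZ co-twins share one vector.
    Vectorized by generation: at each pass every individual whose parents
    are already realised is drawn in one batch.
    """
    t = ped.table
    n = len(t)
    d = cov_a.shape[0]
    L = np.linalg.cholesky(cov_a + 1e-14 * np.eye(d)) \
        if np.any(cov_a) else np.zeros((d, d))
    Lm = L / np.sqrt(2.0)
    pos = {i: k for k, i in enumerate(t["individual_id"])}
    fa = np.array([pos.get(p, -1) if p != "0" else -1
                   for p in t["father_id"]])
    mo = np.array([pos.get(p, -1) if p != "0" else -1
                   for p in t["mother_id"]])
    # MZ co-twins collapse onto the group's first member
    leader = np.arange(n)
    mz = t["zygosity"].to_numpy() == "MZ"
    if mz.any():
        key = pd.Series(t["family_id"].to_numpy() + "\x00"
                        + t["twin_group"].to_numpy())
        first = key[mz].groupby(key[mz]).transform(lambda s: s.index[0])
        leader[np.flatnonzero(mz)] = first.to_numpy()
    bv = np.full((n, d), np.nan)
    done = np.zeros(n, dtype=bool)
    while not done.all():
        ready = ~done & \
            ((fa < 0) | done[np.clip(fa, 0, None)]) & \
            ((mo < 0) | done[np.clip(mo, 0, None)])
        ready &= leader == np.arange(n)  # followers copy later
        idx = np.flatnonzero(ready)
        if idx.size == 0:
            idx = np.flatnonzero(~done & (leader != np.arange(n))
                                 & done[leader])
            bv[idx] = bv[leader[idx]]
            done[idx] = True
            continue
        founders = idx[(fa[idx] < 0) & (mo[idx] < 0)]
        children = idx[(fa[idx] >= 0) | (mo[idx] >= 0)]
        if founders.size:
            bv[founders] = rng.standard_normal((founders.size, d)) @ L.T
        if children.size:
            mid = 0.5 * (np.where(fa[children, None] >= 0,
                                  bv[np.clip(fa[children], 0, None)], 0.0)
                         + np.where(mo[children, None] >= 0,
                                    bv[np.clip(mo[children], 0, None)], 0.0))
            bv[children] = mid + rng.standard_normal((children.size, d)) @ Lm.T
        done[idx] = True
        followers = np.flatnonzero(~done & (leader != np.arange(n))
                                   & done[leader])
        if followers.size:
            bv[followers] = bv[leader[followers]]
            done[followers] = True
    return bv


def _twin_shared_deviates(ped: Pedigree, c_sd: float, rng) -> np.ndarray:
    """Per-individual twin-shared deviate, aligned with ped.table."""
    t = ped.table
    out = np.zeros(len(t))
    if c_sd == 0.0:
        return out
    istwin = (t["twin_group"] != "0").to_numpy()
    if not istwin.any():
        return out
    key = (t["family_id"].to_numpy() + "\x00" + t["twin_group"].to_numpy())
    codes, uniques = pd.factorize(pd.Series(key[istwin]))
    vals = c_sd * rng.standard_normal(len(uniques))
    out[istwin] = vals[codes]
    return out


def _ages_by_role(roster: pd.DataFrame, rng) -> np.ndarray:
    """Adult ages structured by family role (twins share an age)."""
    fam_codes, fams = pd.factorize(roster["family_id"])
    base = rng.uniform(25.0, 60.0, len(fams))[fam_codes]
    role = roster["role"].to_numpy()
    n = len(roster)
    age = base + rng.uniform(-2.0, 2.0, n)
    age[role == "twin"] = base[role == "twin"]
    age[role == "parent"] = base[role == "parent"] + \
        rng.uniform(25.0, 35.0, int((role == "parent").sum()))
    off = role == "twin_child"
    age[off] = np.maximum(18.0, base[off] - rng.uniform(25.0, 35.0,
                                                        int(off.sum())))
    return np.round(age, 1)


def _liabilities(ped, roster, h2, c2, rng):
    bv = _breeding_values(ped, np.array([[h2]]), rng)[:, 0]
    cdev = _twin_shared_deviates(ped, np.sqrt(c2), rng)
    e_sd = np.sqrt(max(1.0 - h2 - c2, 0.0))
    e = e_sd * rng.standard_normal(len(roster))
    return bv + cdev + e


def _phenotype_frame(roster, rng):
    df = roster[["individual_id", "family_id", "sex", "phenotyped"]].copy()
    df["sex"] = df["sex"].astype(int)
    df["age"] = _ages_by_role(roster, rng)
    return df


def simulate_liability_binary(ped: Pedigree, roster: pd.DataFrame,
                              config: GenerativeConfig, seed=None,
                              trait="mdd") -> pd.DataFrame:
    """Binary liability-threshold phenotype for a simulated pedigree.

    Liability = breeding value + twin-shared deviate + residual
    (+ sex_threshold_shift for females); the trait is 1 when liability
    exceeds the threshold of the configured prevalence.  Non-phenotyped
    individuals get a missing trait value.
    """
    rng = _rng(config.seed if seed is None else seed)
    df = _phenotype_frame(roster, rng)
    liab = _liabilities(ped, roster, config.h2_liab, config.c2_liab, rng)
    liab = liab + config.sex_threshold_shift * (df["sex"].to_numpy() == 2)
    t = norm.ppf(1.0 - config.prevalence)
    y = (liab > t).astype(float)
    y[~df["phenotyped"].to_numpy()] = np.nan
    df[trait] = y
    return df.drop(columns=["phenotyped"])


def simulate_continuous(ped: Pedigree, roster: pd.DataFrame, h2: float,
                        c2: float = 0.0, seed=0,
                        trait="y") -> pd.DataFrame:
    """Continuous unit-variance trait with the same genetic machinery."""
    if h2 + c2 > 1.0 + 1e-12:
        raise ValueError("h2 + c2 must not exceed 1")
    rng = _rng(seed)
    df = _phenotype_frame(roster, rng)
    y = _liabilities(ped, roster, h2, c2, rng)
    y[~df["phenotyped"].to_numpy()] = np.nan
    df[trait] = y
    return df.drop(columns=["phenotyped"])


def simulate_bivariate_binary(ped: Pedigree, roster: pd.DataFrame,
                              config: GenerativeConfig, seed=None,
                              h2_2=None, p_obs1=1.0, p_obs2=1.0
                              ) -> pd.DataFrame:
    """Two binary traits whose breeding values correlate at ``config.rg``.

    Residuals are independent across traits; thresholds sit at
    ``config.prevalence`` and ``config.prevalence2``.  ``p_obs1/p_obs2``
    randomly mask each trait to mimic partial measurement overlap.
    """
    rng = _rng(config.seed if seed is None else seed)
    h1 = config.h2_liab
    h2_ = h1 if h2_2 is None else h2_2
    cov_a = np.array([
        [h1, config.rg * np.sqrt(h1 * h2_)],
        [config.rg * np.sqrt(h1 * h2_), h2_],
    ])
    df = _phenotype_frame(roster, rng)
    A = _breeding_values(ped, cov_a, rng)
    ids = roster["individual_id"]
    c_sd = np.sqrt(config.c2_liab)
    c1 = _twin_shared_deviates(ped, c_sd, rng)
    c2col = _twin_shared_deviates(ped, c_sd, rng)
    e1 = np.sqrt(max(1 - h1 - config.c2_liab, 0)) * rng.standard_normal(len(ids))
    e2 = np.sqrt(max(1 - h2_ - config.c2_liab, 0)) * rng.standard_normal(len(ids))
    l1 = A[:, 0] + c1 + e1
    l2 = A[:, 1] + c2col + e2
    y1 = (l1 > norm.ppf(1 - config.prevalence)).astype(float)
    y2 = (l2 > norm.ppf(1 - config.prevalence2)).astype(float)
    ph = df["phenotyped"].to_numpy()
    m1 = ph & (rng.random(len(ids)) < p_obs1)
    m2 = ph & (rng.random(len(ids)) < p_obs2)
    y1[~m1] = np.nan
    y2[~m2] = np.nan
    df["trait1"] = y1
    df["trait2"] = y2
    return df.drop(columns=["phenotyped"])


# ----------------------------------------------------------------------
# polygenic-score cohorts


def simulate_prs_cohort(n_individuals: int, config: GenerativeConfig,
                        seed=None, family_size: int = 4,
                        familial_var: float = 0.30, n_variants: int = 0,
                        maf_range=(0.05, 0.5)):
    """Cohort of sibships with a polygenic score explaining part of a
    liability.

    The true score ``s`` is standard normal with within-family correlation
    1/2 (it is transmitted like a breeding value across siblings); the
    liability is sqrt(r2)*s + shared familial deviate + residual with unit
    total variance, thresholded at the configured prevalence.  With
    ``n_variants > 0`` the score is expanded into Hardy-Weinberg dosages
    plus a weight table whose oriented weighted sum reconstitutes ``s``;
    half the emitted weight rows are randomly allele-swapped relative to
    the dosage orientation to exercise scoring-time allele matching.

    Returns ``(phenotypes, dosages, weights)``; the latter two are ``None``
    in direct-score mode.
    """
    rng = _rng(config.seed if seed is None else seed)
    r2 = config.r2_prs_liab
    if r2 + familial_var >= 1.0:
        raise ValueError("r2_prs_liab + familial_var must be below 1")
    n_fam = int(np.ceil(n_individuals / family_size))
    fam = np.repeat(np.arange(n_fam), family_size)[:n_individuals]
    dosages = weights = None
    if n_variants:
        maf = rng.uniform(*maf_range, size=n_variants)
        w = rng.standard_normal(n_variants) / np.sqrt(n_variants)
        # family-shared component of each dosage: draw parental mean dose
        shared = np.vstack([rng.binomial(1, maf, size=n_variants) +
                            rng.binomial(1, maf, size=n_variants)
                            for _ in range(n_fam)]) / 2.0
        doses = np.empty((n_individuals, n_variants), dtype=np.int16)
        for i in range(n_individuals):
            pmean = shared[fam[i]]
            doses[i] = rng.binomial(1, pmean) + rng.binomial(1, maf)
        raw = doses @ w
        s = (raw - raw.mean()) / raw.std()
        alleles = np.array(["A", "C", "G", "T"])
        eff = alleles[rng.integers(0, 4, n_variants)]
        oth = np.array([alleles[(list(alleles).index(a) + 1) % 4] for a in eff])
        vids = [f"rs{100000 + j}" for j in range(n_variants)]
        swap = rng.random(n_variants) < 0.5
        col_allele = np.where(swap, oth, eff)
        col_dose = np.where(swap[None, :], 2 - doses, doses)
        dosages = pd.DataFrame(
            col_dose, columns=[f"{v}:{a}" for v, a in zip(vids, col_allele)])
        dosages.insert(0, "individual_id", [f"I{i}" for i in range(n_individuals)])
        weights = pd.DataFrame({"variant_id": vids, "effect_allele": eff,
                                "other_allele": oth, "weight": w})
    else:
        f_part = rng.standard_normal(n_fam)[fam]
        s = np.sqrt(0.5) * f_part + np.sqrt(0.5) * rng.standard_normal(n_individuals)
    fam_dev = np.sqrt(familial_var) * rng.standard_normal(n_fam)[fam]
    resid_sd = np.sqrt(1.0 - r2 - familial_var)
    liab = np.sqrt(r2) * s + fam_dev + resid_sd * rng.standard_normal(n_individuals)
    t = norm.ppf(1.0 - config.prevalence)
    pheno = pd.DataFrame({
        "individual_id": [f"I{i}" for i in range(n_individuals)],
        "family_id": [f"F{f}" for f in fam],
        "sex": rng.integers(1, 3, n_individuals),
        "age": np.round(rng.uniform(18, 80, n_individuals), 1),
        "prs": s,
        "mdd": (liab > t).astype(int),
    })
    return pheno, dosages, weights


# ----------------------------------------------------------------------
# cohort prevalence tables

_AGE_BANDS = ("18-39", "40-59", "60+")


def simulate_cohort_prevalences(config: GenerativeConfig, k: int = 8,
                                n_range=(800, 6000), seed=None,
                                sex_logit_shift: float = 0.0,
                                age_logit_shift=(0.0, 0.0, 0.0)
                                ) -> pd.DataFrame:
    """Stratified per-cohort case counts with between-cohort heterogeneity.

    True cohort logits are N(mu_logit, tau2); sex and age-band offsets are
    added on the logit scale; counts are binomial.  Returns one row per
    cohort x sex x age band with ``cases`` and ``n``.
    """
    rng = _rng(config.seed if seed is None else seed)
    rows = []
    for c in range(k):
        base = config.mu_logit + np.sqrt(config.tau2) * rng.standard_normal()
        n_total = int(rng.integers(*n_range))
        sex_split = rng.uniform(0.4, 0.6)
        age_split = rng.dirichlet([3, 4, 3])
        for sex, s_off, s_frac in (("male", -sex_logit_shift / 2, sex_split),
                                   ("female", sex_logit_shift / 2, 1 - sex_split)):
            for band, a_off, a_frac in zip(_AGE_BANDS, age_logit_shift,
                                           age_split):
                n = max(int(round(n_total * s_frac * a_frac)), 1)
                p = 1.0 / (1.0 + np.exp(-(base + s_off + a_off)))
                rows.append({"cohort_id": f"C{c}", "sex": sex,
                             "age_band": band,
                             "cases": int(rng.binomial(n, p)), "n": n})
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# questionnaire responses

_SYMPTOM_COLS = ["sym_energy", "sym_sleep", "sym_guilt", "sym_concentration",
                 "sym_psychomotor", "sym_appetite", "sym_suicidal"]
_CORE_COLS = ["scr_mood", "scr_interest"]


def _pattern_sets():
    """All complete (2 core, 7 other, interference) patterns split into the
    case-rule set and its complement."""
    case, control = [], []
    for bits in itertools.product((0, 1), repeat=10):
        core = bits[0] + bits[1]
        total = core + sum(bits[2:9])
        intf = bits[9]
        if core >= 1 and total >= 5 and intf == 1:
            case.append(bits)
        else:
            control.append(bits)
    return np.array(case, dtype=int), np.array(control, dtype=int)


_CASE_PATTERNS, _CONTROL_PATTERNS = _pattern_sets()


def simulate_responses(status: pd.DataFrame, seed=0,
                       cohort_id="SYN") -> pd.DataFrame:
    """Questionnaire rows whose DSM scoring reproduces intended statuses.

    ``status`` has columns ``respondent_id``, ``status_lifetime`` and
    optionally ``status_current`` (each ``case`` or ``control``; a current
    case must also be a lifetime case).  Lifetime cases draw a symptom
    pattern uniformly from the set satisfying the case rule (>=1 core
    symptom, >=5 of 9 criteria, interference); controls draw uniformly from
    the complement.  Screen-negative controls get structurally missing
    symptom and interference items (skip logic).  Demographics are filled
    from simple adult distributions.
    """
    rng = _rng(seed)
    n = len(status)
    lifetime = status["status_lifetime"].to_numpy()
    current = (status["status_current"].to_numpy()
               if "status_current" in status else np.array(["control"] * n))
    bad = (current == "case") & (lifetime != "case")
    if bad.any():
        raise ValueError("a current case must be a lifetime case")
    rows = np.empty((n, 10), dtype=float)
    for i, st in enumerate(lifetime):
        pool = _CASE_PATTERNS if st == "case" else _CONTROL_PATTERNS
        rows[i] = pool[rng.integers(len(pool))]
    screen_neg = (rows[:, 0] + rows[:, 1]) == 0
    rows[screen_neg, 2:] = np.nan  # skip logic: section not asked
    last_year = np.where(lifetime != "case", np.nan,
                         np.where(current == "case", 1.0, 0.0))
    height = rng.normal(175, 9, n).round(1)
    weight = (22.5 * (height / 100) ** 2 + rng.normal(0, 8, n)).round(1)
    df = pd.DataFrame(rows, columns=_CORE_COLS + _SYMPTOM_COLS + ["interference"])
    df.insert(0, "respondent_id", status["respondent_id"].to_numpy())
    df.insert(1, "cohort_id", cohort_id)
    if "family_id" in status:
        df["family_id"] = status["family_id"].to_numpy()
    df["last_year_episode"] = last_year
    df["other_dx"] = rng.binomial(1, 0.1, n).astype(float)
    df["sex"] = rng.integers(1, 3, n)
    df["age"] = rng.integers(18, 90, n)
    df["education"] = rng.choice(["low", "medium", "high"], n,
                                 p=[0.25, 0.4, 0.35])
    df["education_diploma"] = rng.binomial(1, 0.9, n)
    df["smoking"] = rng.integers(1, 4, n)
    df["activity"] = rng.integers(1, 4, n)
    df["height_cm"] = height
    df["weight_kg"] = weight
    return df


# ----------------------------------------------------------------------
# exact threshold-model calibration


def _orthant(t1, t2, rho) -> float:
    """P(X > t1, Y > t2) for standard bivariate normal with correlation rho."""
    if rho >= 1.0 - 1e-12:
        return float(norm.cdf(-max(t1, t2)))
    return float(multivariate_normal.cdf(
        [-t1, -t2], mean=[0.0, 0.0],
        cov=[[1.0, rho], [rho, 1.0]], abseps=1e-10, releps=0.0))


def _template_patterns(template: FamilyTemplate):
    """Enumerate phenotyped-member configurations with probabilities.

    Yields ``(weight, A, C)`` over the 16 template realisations (zygosity x
    parents-phenotyped x extra sibling x twin offspring), with A and C
    restricted to phenotyped members.
    """
    out = []
    for mz, p_mz in ((True, template.mz_fraction),
                     (False, 1 - template.mz_fraction)):
        for par, p_par in ((True, template.p_parents_phenotyped),
                           (False, 1 - template.p_parents_phenotyped)):
            for sib, p_sib in ((True, template.p_extra_sib),
                               (False, 1 - template.p_extra_sib)):
                for off, p_off in ((True, template.p_twin_offspring),
                                   (False, 1 - template.p_twin_offspring)):
                    w = p_mz * p_par * p_sib * p_off
                    if w <= 0:
                        continue
                    rng = np.random.default_rng(0)
                    rows = _family_rows(0, mz, sib, off, rng)
                    g = pd.DataFrame(rows, columns=[
                        "family_id", "individual_id", "father_id",
                        "mother_id", "sex", "twin_group", "zygosity",
                        "role"]).astype({"sex": str})
                    A = _family_a_matrix(g)
                    C = _family_c_matrix(g)
                    keep = [k for k, r in enumerate(g.itertuples(index=False))
                            if par or r.role != "parent"]
                    out.append((w, A[np.ix_(keep, keep)],
                                C[np.ix_(keep, keep)]))
    return out


def _observed_sigma(A, C, h2l, c2l, t1, t2, K1, K2, rg=None, h2l2=None):
    """Exact observed-scale covariance of thresholded family liabilities."""
    n = A.shape[0]
    if rg is None:
        S = np.empty((n, n))
        cache = {}
        for i in range(n):
            S[i, i] = K1 * (1 - K1)
            for j in range(i):
                rho = h2l * A[i, j] + c2l * C[i, j]
                if rho not in cache:
                    cache[rho] = _orthant(t1, t1, rho) - K1 * K1
                S[i, j] = S[j, i] = cache[rho]
        return S
    # bivariate: stacked (trait1 rows, trait2 rows)
    S = np.empty((2 * n, 2 * n))
    cross = rg * np.sqrt(h2l * h2l2)
    for i in range(n):
        for j in range(n):
            r11 = h2l * A[i, j] + c2l * C[i, j]
            r22 = h2l2 * A[i, j] + c2l * C[i, j]
            rx = cross * A[i, j]
            S[i, j] = (K1 * (1 - K1) if i == j
                       else _orthant(t1, t1, r11) - K1 ** 2)
            S[n + i, n + j] = (K2 * (1 - K2) if i == j
                              else _orthant(t2, t2, r22) - K2 ** 2)
            S[i, n + j] = S[n + j, i] = _orthant(t1, t2, rx) - K1 * K2
    return S


def expected_observed_h2(h2l: float, c2l: float, K: float,
                         template: FamilyTemplate) -> float:
    """Pseudo-true observed-scale h2 of the linear ACE estimator applied to
    a binary trait generated at liability (h2l, c2l) and prevalence K."""
    t = norm.ppf(1 - K)
    patterns = []
    for w, A, C in _template_patterns(template):
        S = _observed_sigma(A, C, h2l, c2l, t, t, K, K)
        patterns.append((w, [A, C, np.eye(A.shape[0])], S))
    v = K * (1 - K)
    theta = fit_components_to_covariances(
        patterns, 3, [(0, None), (0, None), (1e-12, None)],
        np.array([v / 3, v / 6, v / 2]))
    return float(theta[0] / theta.sum())


def expected_observed_rg(rg_l: float, h2l1: float, h2l2: float, c2l: float,
                         K1: float, K2: float,
                         template: FamilyTemplate) -> float:
    """Pseudo-true observed-scale genetic correlation of the bivariate
    estimator at generating liability correlation ``rg_l``."""
    t1, t2 = norm.ppf(1 - K1), norm.ppf(1 - K2)
    patterns = []
    for w, A, C in _template_patterns(template):
        n = A.shape[0]
        S = _observed_sigma(A, C, h2l1, c2l, t1, t2, K1, K2,
                            rg=rg_l, h2l2=h2l2)
        Z = np.zeros((n, n))
        I = np.eye(n)
        blk = lambda M11, M22, M12: np.block([[M11, M12], [M12.T, M22]])
        G = [blk(A, Z, Z), blk(Z, A, Z), blk(Z, Z, A),
             blk(C, Z, Z), blk(Z, C, Z),
             blk(I, Z, Z), blk(Z, I, Z), blk(Z, Z, I)]
        patterns.append((w, G, S))
    v1, v2 = K1 * (1 - K1), K2 * (1 - K2)
    theta = fit_components_to_covariances(
        patterns, 8,
        [(0, None), (0, None), (None, None), (0, None), (0, None),
         (1e-12, None), (1e-12, None), (None, None)],
        np.array([v1 / 3, v2 / 3, np.sqrt(v1 * v2) / 10,
                  v1 / 10, v2 / 10, v1 / 2, v2 / 2, 0.0]))
    return float(theta[2] / np.sqrt(theta[0] * theta[1]))


def calibrate_liability_h2(target_h2_obs: float, K: float,
                           template: FamilyTemplate | None = None,
                           c2l: float = 0.0) -> float:
    """Liability h2 whose exact observed-scale estimand equals the target.

    Deterministic bisection on the liability heritability; the forward map
    goes through exact orthant-probability family covariances and the
    pseudo-true REML estimand (no simulation involved).
    """
    template = template or FamilyTemplate()
    f = lambda h: expected_observed_h2(h, c2l, K, template) - target_h2_obs
    lo, hi = 1e-3, 1.0 - c2l - 1e-6
    if f(hi) < 0:
        raise ValueError("target observed-scale h2 infeasible at this K")
    return float(optimize.brentq(f, lo, hi, xtol=1e-5))


def calibrate_liability_rg(target_rg_obs: float, h2l1: float, h2l2: float,
                           K1: float, K2: float,
                           template: FamilyTemplate | None = None,
                           c2l: float = 0.0) -> float:
    """Generating liability-scale rg whose observed-scale estimand equals
    the target (exact threshold-model inversion, cf.
    :func:`calibrate_liability_h2`)."""
    template = template or FamilyTemplate()
    f = lambda r: expected_observed_rg(r, h2l1, h2l2, c2l, K1, K2,
                                       template) - target_rg_obs
    if f(1.0 - 1e-9) < 0:
        raise ValueError("target observed-scale rg infeasible")
    return float(optimize.brentq(f, 0.0, 1.0 - 1e-9, xtol=1e-4))
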