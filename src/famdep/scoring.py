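"""DSM major-depression scoring of self-report questionnaire tables.

The instrument screens with the two core symptoms (depressed mood, loss of
interest); respondents negative on both skip the remaining symptom section
(structural missingness), which by itself classifies them as controls.  A
case requires at least five of the nine DSM criteria including a core
symptom, plus serious interference with work, household or self-care; a
control is anyone failing any of those three conditions.  Partially missing
symptom sections are resolved by completion logic: a respondent is
``unknown`` only when both a case-yielding and a control-yielding
completion of the missing items exist — if every completion agrees, that
status is assigned.

Current (last-year) status is the lifetime status gated by the last-year
episode item: a current case is a lifetime case with an episode in the
last year, so a current case is always also a lifetime case.

Ternary items are coded 1 (yes), 0 (no), blank (missing) in the input CSV.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORE_COLS = ["scr_mood", "scr_interest"]
SYMPTOM_COLS = ["sym_energy", "sym_sleep", "sym_guilt", "sym_concentration",
                "sym_psychomotor", "sym_appetite", "sym_suicidal"]
TERNARY_COLS = CORE_COLS + SYMPTOM_COLS + ["interference",
                                           "last_year_episode", "other_dx"]

#: default raw-code mapping for the bundled synthetic dialect
DEFAULT_MAPPING = {
    "education": {"low": "low", "medium": "medium", "high": "high"},
    "smoking": {"1": "never", "2": "former", "3": "current"},
    "activity": {"1": "none", "2": "1-2/wk", "3": "3+/wk"},
}


class ValidationError(ValueError):
    pass


class ConfigurationError(ValueError):
    pass


# ----------------------------------------------------------------------
# symptom profiles and classification


@dataclass
class SymptomProfile:
    """Counted DSM criteria for one respondent and timeframe.

    ``core_count``/``criterion_count`` count affirmative answers;
    ``*_max`` add the items that are respondent-missing (their value under
    the most case-favourable completion).  ``determinable`` is False when
    both a case and a control completion of the missing items exist.
    """

    timeframe: str
    core_count: int
    criterion_count: int
    core_max: int
    criterion_max: int
    interference: float  # 1 / 0 / nan
    last_year: float
    determinable: bool


@dataclass
class MdsClassification:
    respondent_id: object
    status_current: str
    status_lifetime: str
    strict_control_current: bool = False
    strict_control_lifetime: bool = False
    flags: list = field(default_factory=list)


def _tern(value, where=""):
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    if isinstance(value, str):
        s = value.strip()
        if s == "":
            return np.nan
        value = s
    try:
        v = float(value)
    except (TypeError, ValueError):
        raise ValidationError(f"malformed ternary value {value!r} {where}")
    if v not in (0.0, 1.0):
        raise ValidationError(f"malformed ternary value {value!r} {where}")
    return v


def derive_symptom_profile(response, timeframe="lifetime") -> SymptomProfile:
    """Count core and total DSM criteria for one respondent row.

    ``response`` is a mapping with the ternary item columns.  Skip logic:
    when both screeners are answered "no" the symptom section was not
    asked; its items count as structurally absent (no), not missing.
    """
    if timeframe not in ("current", "lifetime"):
        raise ValueError(f"unknown timeframe {timeframe!r}")
    core = [_tern(response.get(c), f"(column {c})") for c in CORE_COLS]
    syms = [_tern(response.get(c), f"(column {c})") for c in SYMPTOM_COLS]
    intf = _tern(response.get("interference"), "(column interference)")
    last_year = _tern(response.get("last_year_episode"),
                      "(column last_year_episode)")
    screen_negative = core[0] == 0.0 and core[1] == 0.0
    if screen_negative:
        syms = [0.0] * len(syms)
        intf = 0.0
    core_yes = int(sum(v == 1.0 for v in core))
    core_mis = int(sum(np.isnan(v) for v in core))
    sym_yes = int(sum(v == 1.0 for v in syms))
    sym_mis = int(sum(np.isnan(v) for v in syms))
    crit_yes = core_yes + sym_yes
    crit_max = core_yes + core_mis + sym_yes + sym_mis
    prof = SymptomProfile(
        timeframe=timeframe,
        core_count=core_yes,
        criterion_count=crit_yes,
        core_max=core_yes + core_mis,
        criterion_max=crit_max,
        interference=intf,
        last_year=last_year,
        determinable=True,
    )
    prof.determinable = classify_mdd(prof) != "unknown"
    return prof


def classify_mdd(profile: SymptomProfile) -> str:
    """Case / control / unknown from a symptom profile.

    Case: >=1 core symptom, >=5 of the 9 criteria, interference affirmed —
    all certain under every completion of missing items.  Control: no
    completion can satisfy the case rule.  Unknown otherwise.
    """
    case_certain = (profile.core_count >= 1
                    and profile.criterion_count >= 5
                    and profile.interference == 1.0)
    case_possible = (profile.core_max >= 1
                     and profile.criterion_max >= 5
                     and (profile.interference == 1.0
                          or np.isnan(profile.interference)))
    lifetime = ("case" if case_certain
                else "control" if not case_possible else "unknown")
    if profile.timeframe == "lifetime":
        return lifetime
    # current: gate the lifetime status on a last-year episode
    if lifetime == "control" or profile.last_year == 0.0:
        return "control"
    if lifetime == "case" and profile.last_year == 1.0:
        return "case"
    return "unknown"


def apply_strict_control_filter(classification: MdsClassification,
                                response) -> MdsClassification:
    """Exclude controls with self-reported other psychiatric diagnosis or
    treatment; missing is treated as no (exclusion needs an affirmative
    report) but flagged."""
    other = _tern(response.get("other_dx"), "(column other_dx)")
    c = classification
    if other == 1.0:
        if c.status_current == "control":
            c.status_current = "excluded"
        if c.status_lifetime == "control":
            c.status_lifetime = "excluded"
    elif np.isnan(other):
        if "control" in (c.status_current, c.status_lifetime):
            c.flags.append("other_dx_missing")
    c.strict_control_current = c.status_current == "control"
    c.strict_control_lifetime = c.status_lifetime == "control"
    return c


# ----------------------------------------------------------------------
# vectorized scoring of a respondent table


def _read_ternary_frame(df: pd.DataFrame, cols) -> np.ndarray:
    out = np.empty((len(df), len(cols)))
    for j, c in enumerate(cols):
        if c not in df.columns:
            raise ValidationError(f"missing column {c!r}")
        v = pd.to_numeric(df[c].replace("", np.nan), errors="coerce")
        raw_missing = df[c].isna() | (df[c].astype(str).str.strip() == "") \
            if df[c].dtype == object else df[c].isna()
        bad = v.isna() & ~raw_missing
        bad |= v.notna() & ~v.isin([0.0, 1.0])
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise ValidationError(
                f"malformed ternary value {df[c].iloc[row]!r} "
                f"(row {row}, column {c})")
        out[:, j] = v.to_numpy(dtype=float)
    return out


def score_responses(df: pd.DataFrame, strict=False) -> pd.DataFrame:
    """Score a respondent table into current and lifetime MDD status.

    Returns a frame indexed like ``df`` with ``status_current``,
    ``status_lifetime``, strict-control booleans and scoring flags.  With
    ``strict=True`` controls reporting another psychiatric diagnosis or
    treatment become ``excluded``.
    """
    core = _read_ternary_frame(df, CORE_COLS)
    syms = _read_ternary_frame(df, SYMPTOM_COLS)
    intf = _read_ternary_frame(df, ["interference"])[:, 0]
    last_year = _read_ternary_frame(df, ["last_year_episode"])[:, 0]

    screen_neg = (core[:, 0] == 0.0) & (core[:, 1] == 0.0)
    syms = np.where(screen_neg[:, None], 0.0, syms)
    intf = np.where(screen_neg, 0.0, intf)

    core_yes = np.nansum(core == 1.0, axis=1)
    core_mis = np.isnan(core).sum(axis=1)
    sym_yes = np.nansum(syms == 1.0, axis=1)
    sym_mis = np.isnan(syms).sum(axis=1)
    crit_yes = core_yes + sym_yes
    crit_max = crit_yes + core_mis + sym_mis

    case = (core_yes >= 1) & (crit_yes >= 5) & (intf == 1.0)
    possible = ((core_yes + core_mis >= 1) & (crit_max >= 5)
                & ((intf == 1.0) | np.isnan(intf)))
    lifetime = np.where(case, "case",
                        np.where(~possible, "control", "unknown"))
    current = np.where((lifetime == "control") | (last_year == 0.0),
                       "control",
                       np.where((lifetime == "case") & (last_year == 1.0),
                                "case", "unknown"))

    out = pd.DataFrame({
        "respondent_id": df["respondent_id"].to_numpy()
        if "respondent_id" in df else np.arange(len(df)),
        "status_current": current,
        "status_lifetime": lifetime,
    }, index=df.index)
    flags = np.where(screen_neg, "screen_negative", "")
    if strict:
        other = _read_ternary_frame(df, ["other_dx"])[:, 0]
        excl = other == 1.0
        out.loc[excl & (out["status_current"] == "control"),
                "status_current"] = "excluded"
        out.loc[excl & (out["status_lifetime"] == "control"),
                "status_lifetime"] = "excluded"
        miss = np.isnan(other) & ((out["status_current"] == "control")
                                  | (out["status_lifetime"] == "control"))
        flags = np.where(miss, np.char.add(
            np.char.add(flags.astype("<U40"), ";"), "other_dx_missing"),
            flags)
    out["strict_control_current"] = out["status_current"] == "control"
    out["strict_control_lifetime"] = out["status_lifetime"] == "control"
    out["flags"] = flags
    return out


# ----------------------------------------------------------------------
# covariates and QC


@dataclass
class CovariateRecord:
    sex: object
    age_band: str
    education: str
    smoking: str
    activity: str
    bmi: float
    bmi_class: str
    qc_flags: frozenset = frozenset()


def _band_age(age):
    age = pd.to_numeric(age, errors="coerce")
    return pd.cut(age, bins=[18, 40, 60, np.inf], right=False,
                  labels=["18-39", "40-59", "60+"]).astype(object) \
        .where(age >= 18, other=np.nan)


def _band_bmi(bmi):
    return pd.cut(bmi, bins=[-np.inf, 18.5, 25.0, 30.0, np.inf], right=False,
                  labels=["underweight", "normal", "overweight", "obese"]
                  ).astype(object)


def _apply_map(series: pd.Series, mapping: dict, what: str) -> pd.Series:
    s = series.astype(object).where(series.notna(), np.nan)
    out = []
    for v in s:
        if v is np.nan or (isinstance(v, float) and np.isnan(v)):
            out.append(np.nan)
            continue
        key = str(v).strip()
        if key.endswith(".0"):
            key = key[:-2]
        if key == "":
            out.append(np.nan)
        elif key in mapping:
            out.append(mapping[key])
        else:
            raise ConfigurationError(
                f"unmapped {what} code {v!r}")
    return pd.Series(out, index=series.index, dtype=object)


def derive_covariates(df: pd.DataFrame, mapping_config=None) -> pd.DataFrame:
    """Demographic covariates: sex, age band, education (high without a
    diploma is downgraded to medium), smoking, activity, BMI and its class.

    ``mapping_config`` maps cohort-specific raw codes to the harmonised
    levels; unmapped codes raise :class:`ConfigurationError`.
    """
    cfg = mapping_config or DEFAULT_MAPPING
    out = pd.DataFrame(index=df.index)
    out["sex"] = df.get("sex")
    out["age"] = pd.to_numeric(df.get("age"), errors="coerce")
    out["age_band"] = _band_age(out["age"])
    edu = _apply_map(df["education"], cfg["education"], "education")
    if "education_diploma" in df:
        dip = pd.to_numeric(df["education_diploma"], errors="coerce")
        edu = edu.mask((edu == "high") & (dip == 0), "medium")
    out["education"] = edu.fillna("missing")
    out["smoking"] = _apply_map(df["smoking"], cfg["smoking"], "smoking")
    out["activity"] = _apply_map(df["activity"], cfg["activity"], "activity")
    h = pd.to_numeric(df.get("height_cm"), errors="coerce")
    w = pd.to_numeric(df.get("weight_kg"), errors="coerce")
    out["height_cm"] = h
    out["weight_kg"] = w
    out["bmi"] = w / (h / 100.0) ** 2
    out["bmi_class"] = _band_bmi(out["bmi"])
    return out


#: QC rules in fixed application order; first hit wins, and the BMI bound is
#: evaluated only on survivors of the height/weight rules.
QC_RULES = (
    ("age", lambda d: d["age"] > 110),
    ("height", lambda d: (d["height_cm"] < 150) | (d["height_cm"] > 220)),
    ("weight", lambda d: (d["weight_kg"] < 45) | (d["weight_kg"] > 200)),
    ("bmi", lambda d: (d["bmi"] < 15) | (d["bmi"] > 50)),
)


def apply_qc_exclusions(records: pd.DataFrame, for_pedigree=False):
    """Drop out-of-range records; returns (kept, exclusion log).

    Bounds are strict inequalities (a height of exactly 150 cm is kept).
    The log counts each dropped record once, under the first rule it hits
    in the fixed order age, height, weight, BMI; the BMI rule is applied
    after the height and weight exclusions.  With ``for_pedigree=True``,
    records with missing or non-binary sex, or missing age, are also
    dropped (required for relatedness analyses).
    """
    d = records.copy()
    if "bmi" not in d and {"height_cm", "weight_kg"} <= set(d.columns):
        d["bmi"] = pd.to_numeric(d["weight_kg"], errors="coerce") / \
            (pd.to_numeric(d["height_cm"], errors="coerce") / 100.0) ** 2
    log = {}
    hit = pd.Series(False, index=d.index)
    for name, rule in QC_RULES:
        if name == "bmi":
            mask = rule(d) & ~hit
        else:
            mask = rule(d).fillna(False) & ~hit
        mask = mask.fillna(False)
        log[name] = int(mask.sum())
        hit |= mask
    if for_pedigree:
        sex = pd.to_numeric(d.get("sex"), errors="coerce")
        mask = (~sex.isin([1, 2]) | d.get("age").isna()) & ~hit
        log["sex_or_age"] = int(mask.sum())
        hit |= mask
    return d.loc[~hit], log


def select_unrelated(records: pd.DataFrame, family_col="family_id",
                     seed=0) -> pd.DataFrame:
    """One randomly sampled record per family (uniform, seed-deterministic)."""
    rng = np.random.default_rng(seed)
    keep = []
    for fam, g in records.groupby(family_col, sort=True):
        if len(g) == 0:
            continue
        keep.append(g.index[rng.integers(len(g))])
    return records.loc[keep]
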