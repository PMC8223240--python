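import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")

from famdep.scoring import CORE_COLS, SYMPTOM_COLS  # noqa: E402


def all_complete_patterns() -> pd.DataFrame:
    """Every complete assignment of 2 core + 7 other symptoms +
    interference (2^10 rows), with a last-year item set to yes."""
    rows = list(itertools.product((0, 1), repeat=10))
    df = pd.DataFrame(rows, columns=CORE_COLS + SYMPTOM_COLS
                      + ["interference"])
    df["last_year_episode"] = 1
    df["other_dx"] = 0
    df.insert(0, "respondent_id", [f"P{i}" for i in range(len(df))])
    return df


@pytest.fixture(scope="session")
def complete_patterns():
    return all_complete_patterns()


def rule_oracle(row) -> str:
    """Independently coded DSM case rule for complete symptom patterns."""
    core = row["scr_mood"] + row["scr_interest"]
    total = core + sum(row[c] for c in SYMPTOM_COLS)
    if core >= 1 and total >= 5 and row["interference"] == 1:
        return "case"
    return "control"


@pytest.fixture(scope="session")
def twin_pair_pedigree():
    """2000 families of one twin pair + parents (half MZ), phenotypes on
    twins only — the classical twin design."""
    from famdep.pedigree import Pedigree

    rows = []
    for f in range(2000):
        zyg = "MZ" if f % 2 == 0 else "DZ"
        fid = f"F{f}"
        rows += [
            (fid, f"{fid}_fa", "0", "0", 1, "0", "NA"),
            (fid, f"{fid}_mo", "0", "0", 2, "0", "NA"),
            (fid, f"{fid}_t1", f"{fid}_fa", f"{fid}_mo", 1, "1", zyg),
            (fid, f"{fid}_t2", f"{fid}_fa", f"{fid}_mo", 1, "1", zyg),
        ]
    table = pd.DataFrame(rows, columns=[
        "family_id", "individual_id", "father_id", "mother_id", "sex",
        "twin_group", "zygosity"])
    return Pedigree(table)


def simulate_twin_pairs(pedigree, rho_mz, rho_dz, seed):
    """Bivariate-normal twin phenotypes at fixed MZ/DZ correlations."""
    rng = np.random.default_rng(seed)
    t = pedigree.table
    twins = t[t["twin_group"] != "0"]
    recs = []
    for (fam, _), grp in twins.groupby(["family_id", "twin_group"]):
        rho = rho_mz if grp["zygosity"].iloc[0] == "MZ" else rho_dz
        L = np.linalg.cholesky([[1.0, rho], [rho, 1.0]])
        y = L @ rng.standard_normal(2)
        age = rng.uniform(20.0, 60.0)
        for iid, v in zip(grp["individual_id"], y):
            recs.append({"individual_id": iid, "family_id": fam,
                         "sex": int(rng.integers(1, 3)), "age": age,
                         "y": v})
    return pd.DataFrame(recs)
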