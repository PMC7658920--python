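"""Sample sheets: group labels and clinical covariates.

The comparison driving the pipeline is between desmoid-type fibromatosis
tumors carrying the CTNNB1 S45F mutation and those carrying T41A.  A sample
sheet maps sample id -> mutation group plus the covariates used by the
downstream clustering and size-contrast analyses: sex, tumor site, largest
tumor size (mm, may be missing) and age at diagnosis.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["GROUPS", "validate_sample_sheet", "simulate_sample_sheet"]

GROUPS = ("S45F", "T41A")
TUMOR_SITES = ("extra-abdominal", "abdominal wall", "intra-abdominal")
REQUIRED_COLUMNS = ["sample_id", "group", "sex", "tumor_site", "size_mm", "age_years"]

# Cohort marginals the simulator reproduces: per mutation group, the
# sex split, tumor-site distribution and median (IQR) of size and age
# reported for the 29-tumor desmoid study cohort.
_COHORT = {
    "S45F": {
        "n": 14,
        "p_female": 8 / 14,
        "p_site": (13 / 14, 1 / 14, 0.0),
        "size_median": 68.0,
        "size_sigma": 0.536,  # log-normal sigma from IQR 50-103
        "age_median": 31.0,
        "age_iqr": (20.0, 45.0),
    },
    "T41A": {
        "n": 15,
        "p_female": 11 / 15,
        "p_site": (7 / 15, 5 / 15, 3 / 15),
        "size_median": 53.0,
        "size_sigma": 0.527,  # log-normal sigma from IQR 29-59
        "age_median": 38.0,
        "age_iqr": (33.0, 48.0),
    },
}


def validate_sample_sheet(sheet: pd.DataFrame) -> pd.DataFrame:
    """Validate and normalize a sample sheet DataFrame.

    Raises ``ValueError`` on missing columns, duplicate sample ids, unknown
    group labels, or non-positive sizes.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet missing columns: {missing}")
    dup = sheet["sample_id"][sheet["sample_id"].duplicated()]
    if len(dup):
        raise ValueError(f"duplicate sample ids: {sorted(dup.unique())}")
    bad = set(sheet["group"]) - set(GROUPS)
    if bad:
        raise ValueError(f"unknown group labels {sorted(bad)}; expected {GROUPS}")
    sizes = sheet["size_mm"].dropna()
    if (sizes <= 0).any():
        raise ValueError("size_mm must be positive where present")
    return sheet.reset_index(drop=True)


def simulate_sample_sheet(
    n_s45f: int = 14,
    n_t41a: int = 15,
    n_missing_size: int = 3,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate a clinical sample sheet matching the study cohort's marginals.

    Sizes are log-normal around each group's reported median with sigma
    derived from the reported interquartile range; ages likewise.  A few
    sizes are blanked to mirror the missing imaging measurements.
    """
    rng = np.random.default_rng(seed)
    rows = []
    for group, n in (("S45F", n_s45f), ("T41A", n_t41a)):
        c = _COHORT[group]
        for i in range(n):
            sex = "F" if rng.random() < c["p_female"] else "M"
            site = TUMOR_SITES[rng.choice(3, p=c["p_site"])]
            size = float(np.round(c["size_median"] * np.exp(rng.normal(0.0, c["size_sigma"]))))
            lo, hi = c["age_iqr"]
            age_sigma = (hi - lo) / 1.349
            age = float(np.clip(np.round(rng.normal(c["age_median"], age_sigma)), 16, 85))
            rows.append(
                {
                    "sample_id": f"{group}_{i + 1:02d}",
                    "group": group,
                    "sex": sex,
                    "tumor_site": site,
                    "size_mm": max(size, 5.0),
                    "age_years": age,
                }
            )
    sheet = pd.DataFrame(rows)
    if n_missing_size:
        blank = rng.choice(len(sheet), size=min(n_missing_size, len(sheet)), replace=False)
        sheet.loc[blank, "size_mm"] = np.nan
    return validate_sample_sheet(sheet)
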