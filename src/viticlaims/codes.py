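"""Shared vocabularies: treatment classes, ICD code predicates, age bands.

RAMQ-style claims redact exact age into bands; matching and reporting use a
coarser five-band grouping. Diagnosis columns may be plain strings or pandas
Categoricals; the mask helpers below evaluate prefix predicates on the
category set when possible, which keeps them cheap on multi-million-row
claim tables.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

# The nine treatment classes tracked by the pipeline. Phototherapy is billed
# as a medical service (procedure), not dispensed at a pharmacy.
TREATMENT_CLASSES: tuple[str, ...] = (
    "TCS",
    "tacrolimus",
    "pimecrolimus",
    "phototherapy",
    "prednisone",
    "dexamethasone",
    "methotrexate",
    "cyclosporine",
    "calcipotriene",
)

# Treatments that qualify a 709.x-coded person as a vitiligo case.
QUALIFYING_TREATMENTS: tuple[str, ...] = ("tacrolimus", "pimecrolimus", "phototherapy")

PHOTOTHERAPY_FLAG = "phototherapy"

VITILIGO_ICD9_PREFIX = "709"
VITILIGO_ICD10_PREFIX = "L80"

# ---------------------------------------------------------------------------
# Age bands

FINE_AGE_BANDS: tuple[str, ...] = (
    "<1", "1-4", "5-9", "10-14", "15-19", "20-24", "25-29", "30-34",
    "35-39", "40-44", "45-49", "50-54", "55-59", "60-64", "65-69",
    "70-74", "75-79", "80-84", "85+",
)

COARSE_AGE_BANDS: tuple[str, ...] = ("<20", "20-34", "35-49", "50-64", "65+")

_FINE_LOWER = {
    "<1": 0, "1-4": 1, "5-9": 5, "10-14": 10, "15-19": 15, "20-24": 20,
    "25-29": 25, "30-34": 30, "35-39": 35, "40-44": 40, "45-49": 45,
    "50-54": 50, "55-59": 55, "60-64": 60, "65-69": 65, "70-74": 70,
    "75-79": 75, "80-84": 80, "85+": 85,
}

_FINE_UPPER = {
    "<1": 0, "1-4": 4, "5-9": 9, "10-14": 14, "15-19": 19, "20-24": 24,
    "25-29": 29, "30-34": 34, "35-39": 39, "40-44": 44, "45-49": 49,
    "50-54": 54, "55-59": 59, "60-64": 64, "65-69": 69, "70-74": 74,
    "75-79": 79, "80-84": 84, "85+": 90,  # open band; see band_midpoint
}


def fine_to_coarse(band: str) -> str:
    """Map a fine (5-year) age band into the coarse matching band."""
    lo = _FINE_LOWER[band]
    if lo < 20:
        return "<20"
    if lo < 35:
        return "20-34"
    if lo < 50:
        return "35-49"
    if lo < 65:
        return "50-64"
    return "65+"


_FINE_TO_COARSE = {b: fine_to_coarse(b) for b in FINE_AGE_BANDS}


def coarse_band_series(age_group: pd.Series) -> pd.Series:
    """Vectorized fine→coarse band mapping."""
    return age_group.map(_FINE_TO_COARSE)


def band_midpoint(band: str) -> float:
    """Age estimate for a band: the middle of the group.

    The open-ended 85+ band has no upper bound; 87.5 is used by convention.
    """
    if band == "85+":
        return 87.5
    if band == "<1":
        return 0.5
    return (_FINE_LOWER[band] + _FINE_UPPER[band]) / 2.0


# ---------------------------------------------------------------------------
# Diagnosis-code predicates


def startswith_mask(series: pd.Series, prefixes) -> np.ndarray:
    """Boolean mask of entries starting with any of ``prefixes``.

    Evaluates on the category set when ``series`` is Categorical. Missing
    values are False.
    """
    prefixes = tuple(prefixes)
    if isinstance(series.dtype, pd.CategoricalDtype):
        cats = series.cat.categories.astype(str)
        lut = np.array([c.startswith(prefixes) for c in cats] + [False], dtype=bool)
        return lut[series.cat.codes.to_numpy()]
    return (
        series.astype("string").str.startswith(prefixes).fillna(False).to_numpy(dtype=bool)
    )


def _icd9_head(code: str) -> int:
    head = code.split(".")[0][:3]
    return int(head) if head.isdigit() else -1


def icd9_range_mask(series: pd.Series, lo: int, hi: int) -> np.ndarray:
    """Mask of ICD-9 codes whose three-digit head lies in [lo, hi].

    Non-numeric heads (V/E codes, ICD-10 strings, blanks) are False.
    """
    if isinstance(series.dtype, pd.CategoricalDtype):
        cats = series.cat.categories.astype(str)
        heads = np.array([_icd9_head(c) for c in cats] + [-1])
        lut = (heads >= lo) & (heads <= hi)
        return lut[series.cat.codes.to_numpy()]
    heads = np.array([_icd9_head(str(c)) if pd.notna(c) else -1 for c in series])
    return (heads >= lo) & (heads <= hi)


def vitiligo_dx_mask(dx_code: pd.Series) -> np.ndarray:
    """709.x (ICD-9 other skin disorders) or L80.x (ICD-10 vitiligo)."""
    return startswith_mask(dx_code, (VITILIGO_ICD9_PREFIX, VITILIGO_ICD10_PREFIX))


def mental_health_mask(dx_code: pd.Series, dx_system: pd.Series) -> np.ndarray:
    """ICD-9 290-319 or ICD-10 F00-F99."""
    icd9 = (dx_system == "icd9").to_numpy()
    icd10 = (dx_system == "icd10").to_numpy()
    return (icd9 & icd9_range_mask(dx_code, 290, 319)) | (
        icd10 & startswith_mask(dx_code, ("F",))
    )
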