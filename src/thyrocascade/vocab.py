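"""Closed category vocabularies and the synonym table.

Three classification axes are used throughout:

* preoperative fine-needle aspiration (FNA) cytology, graded with the
  Bethesda system (ordinal categories I..VI, VI most suspicious);
* intraoperative frozen section (FS) histology, four levels
  (malignancy / suspicious for malignancy / benign / indeterminate);
* final postoperative pathology, the binary gold standard.

Row orders are fixed (most- to least-malignant) so that every table the
package emits is diffable.  The synonym table is the single place where
alternative spellings (roman or arabic Bethesda numerals, long frozen-
section phrases) are mapped onto the canonical tokens.
"""

from __future__ import annotations

# Canonical tokens, in fixed display order (most suspicious first).
FNA_CATEGORIES: tuple[str, ...] = ("VI", "V", "IV", "III", "II", "I")
FS_CATEGORIES: tuple[str, ...] = ("MALIGNANCY", "SUSPICIOUS", "BENIGN", "INDETERMINATE")
OUTCOMES: tuple[str, ...] = ("MALIGNANT", "BENIGN")

# Ordinal order of Bethesda categories, least to most suspicious.
FNA_ORDINAL: tuple[str, ...] = ("I", "II", "III", "IV", "V", "VI")

_FNA_SYNONYMS = {
    "i": "I", "1": "I", "bethesda i": "I", "bethesda 1": "I",
    "nondiagnostic": "I", "nondiagnostic/unsatisfactory": "I", "unsatisfactory": "I",
    "ii": "II", "2": "II", "bethesda ii": "II", "bethesda 2": "II", "benign": "II",
    "iii": "III", "3": "III", "bethesda iii": "III", "bethesda 3": "III",
    "aus": "III", "aus/flus": "III", "flus": "III",
    "atypia of undetermined significance": "III",
    "follicular lesion of undetermined significance": "III",
    "iv": "IV", "4": "IV", "bethesda iv": "IV", "bethesda 4": "IV",
    "fn": "IV", "sfn": "IV", "fn/sfn": "IV", "follicular neoplasm": "IV",
    "suspicious for follicular neoplasm": "IV",
    "v": "V", "5": "V", "bethesda v": "V", "bethesda 5": "V",
    "sfm": "V", "suspicious for malignancy": "V",
    "vi": "VI", "6": "VI", "bethesda vi": "VI", "bethesda 6": "VI", "malignant": "VI",
}

_FS_SYNONYMS = {
    "malignancy": "MALIGNANCY", "malignant": "MALIGNANCY",
    "suspicious": "SUSPICIOUS", "suspicious for malignancy": "SUSPICIOUS",
    "sfm": "SUSPICIOUS",
    "benign": "BENIGN",
    "indeterminate": "INDETERMINATE", "undetermined": "INDETERMINATE",
}

_OUTCOME_SYNONYMS = {
    "malignant": "MALIGNANT", "malignancy": "MALIGNANT", "cancer": "MALIGNANT",
    "positive": "MALIGNANT",
    "benign": "BENIGN", "negative": "BENIGN",
}

_SEX_SYNONYMS = {"f": "F", "female": "F", "m": "M", "male": "M"}


def _normalize(token: str, table: dict[str, str], canonical: tuple[str, ...]) -> str:
    key = token.strip().lower()
    if key.upper() in canonical:
        return key.upper()
    if key in table:
        return table[key]
    raise KeyError(token)


def normalize_fna(token: str) -> str:
    """Map an FNA category token (roman/arabic numeral or long name) to I..VI."""
    return _normalize(token, _FNA_SYNONYMS, FNA_CATEGORIES)


def normalize_fs(token: str) -> str:
    """Map a frozen-section category token to its canonical four-level form."""
    return _normalize(token, _FS_SYNONYMS, FS_CATEGORIES)


def normalize_outcome(token: str) -> str:
    """Map a final-pathology token to MALIGNANT / BENIGN."""
    return _normalize(token, _OUTCOME_SYNONYMS, OUTCOMES)


def normalize_sex(token: str) -> str:
    return _normalize(token, _SEX_SYNONYMS, ("F", "M"))
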