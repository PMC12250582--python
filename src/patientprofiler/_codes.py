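"""Default clinical code sets.

ICD-10-CM prefixes identify CKD (N18, ICD-9 585) and AKI (N17, ICD-9 584)
events; inpatient hospitalizations are flagged by an editable CPT set
covering hospital observation/inpatient E&M ranges. The diagnosis and
procedure pools supply realistic codes to the synthetic generator.
"""

from __future__ import annotations

CKD_CODE_PREFIXES: tuple[str, ...] = ("N18", "585")
AKI_CODE_PREFIXES: tuple[str, ...] = ("N17", "584")

CKD_EVENT_CODE = "N18.9"
AKI_EVENT_CODE = "N17.9"
DIALYSIS_EVENT_CODE = "90935"  # CPT hemodialysis, single evaluation


def _cpt_range(lo: int, hi: int) -> list[str]:
    return [str(c) for c in range(lo, hi + 1)]


# Hospital inpatient/observation E&M codes used to flag inpatient encounters.
# The two long numeric identifiers are TriNetX-style internal encounter codes
# seen in EHR extracts; G0378 is hospital observation per hour. The set is a
# default, not ground truth — pass your own to assign_cohorts for other data.
INPATIENT_CPT_DEFAULT: frozenset[str] = frozenset(
    _cpt_range(99218, 99239)
    + _cpt_range(99251, 99255)
    + ["99291"]
    + _cpt_range(99304, 99307)
    + ["94002", "G0378", "1013699", "1013659"]
)

# ICD-10-CM diagnosis codes common in pre-CKD comorbidity profiles
# (diabetes, cardiovascular, respiratory, electrolyte, long-term drug use...).
DIAGNOSIS_CODE_POOL: tuple[str, ...] = (
    "E11.9", "E11.65", "I25.10", "I25.2", "I34.0", "I36.1", "I48.91",
    "I50.9", "I10", "I11.0", "J44.9", "J98.11", "J90", "E66.9", "E78.5",
    "E87.1", "E87.2", "E87.5", "E87.6", "G89.29", "M19.90", "M54.5",
    "F32.9", "F41.9", "K59.00", "N39.0", "R00.0", "R05", "R10.9", "R42",
    "R53.1", "R53.83", "D64.9", "D72.829", "Z79.01", "Z79.4", "Z79.891",
    "Z79.899", "Z82.49", "Z90.49", "Z98.890", "Z00.00", "Z09", "Z23",
)

# CPT procedure codes: chemistry/hematology panels, imaging, office services.
PROCEDURE_CODE_POOL: tuple[str, ...] = (
    "80048", "80053", "80061", "82607", "82947", "83605", "83615", "84132",
    "84295", "84443", "84520", "84540", "85018", "85025", "85610", "86900",
    "86923", "87040", "87070", "87086", "88304", "93000", "93306", "71045",
    "71250", "74176", "76700", "36415", "96372", "99213", "99214", "97110",
    "94760", "83036",
)
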