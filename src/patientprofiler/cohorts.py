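"""Cohort classification, binary feature matrices, and baseline statistics.

Cohort rules: the CKD index is a patient's first CKD-coded diagnosis event;
the first AKI is the earliest AKI-coded event inside the 3-year lookback
window before index. A patient is HA-AKI when an inpatient encounter falls
within the 90 days up to and including the first AKI, CA-AKI for any other
qualifying AKI, No-AKI otherwise. Dialysis strictly before the first AKI
(or, for never-AKI patients, before index) and age under 18 at index are
exclusions; under-18 takes precedence when both apply.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from ._codes import AKI_CODE_PREFIXES, CKD_CODE_PREFIXES, INPATIENT_CPT_DEFAULT

logger = logging.getLogger(__name__)

COHORTS = ("HA_AKI", "CA_AKI", "NO_AKI")

ASSIGNMENT_COLUMNS = ["patient_id", "label", "ckd_index_date",
                      "first_aki_date", "exclusion_reason"]


def age_at(on_date: pd.Series, birth_date: pd.Series) -> pd.Series:
    """Completed calendar years between birth_date and on_date (floor).

    Missing birth dates yield NaN (such patients have no recorded age)."""
    on_date = pd.to_datetime(on_date)
    birth_date = pd.to_datetime(birth_date)
    years = on_date.dt.year - birth_date.dt.year
    before_bday = ((on_date.dt.month < birth_date.dt.month)
                   | ((on_date.dt.month == birth_date.dt.month)
                      & (on_date.dt.day < birth_date.dt.day)))
    return years - before_bday.astype(int)


def _has_prefix(codes: pd.Series, prefixes: tuple[str, ...]) -> pd.Series:
    return codes.str.startswith(prefixes)


def assign_cohorts(events: pd.DataFrame, patients: pd.DataFrame, *,
                   lookback_years: int = 3, ha_window_days: int = 90,
                   inpatient_cpt_set: frozenset[str] | set[str] = INPATIENT_CPT_DEFAULT,
                   ckd_prefixes: tuple[str, ...] = CKD_CODE_PREFIXES,
                   aki_prefixes: tuple[str, ...] = AKI_CODE_PREFIXES,
                   ha_direction: str = "encounter_before",
                   min_age: int = 18) -> pd.DataFrame:
    """Classify every patient into HA_AKI / CA_AKI / NO_AKI / EXCLUDED.

    Returns one row per patient with a CKD event (columns
    ``ASSIGNMENT_COLUMNS``); patients without any CKD event are dropped and
    counted in ``result.attrs['n_dropped_no_ckd']``.
    """
    if ha_direction not in ("encounter_before", "encounter_after", "either"):
        raise ValueError("ha_direction must be encounter_before|encounter_after|either")
    events = events.copy()
    events["date"] = pd.to_datetime(events["date"])

    diag = events[events["kind"] == "diagnosis"]
    ckd = diag[_has_prefix(diag["code"], tuple(ckd_prefixes))]
    index_date = ckd.groupby("patient_id")["date"].min().rename("ckd_index_date")

    n_dropped = int((~patients["patient_id"].isin(index_date.index)).sum())
    if n_dropped:
        logger.warning("dropping %d patients without any CKD event", n_dropped)

    base = patients.merge(index_date, left_on="patient_id", right_index=True,
                          how="inner").copy()
    base["age_at_index"] = age_at(base["ckd_index_date"], base["birth_date"])
    window_start = base["ckd_index_date"] - pd.DateOffset(years=lookback_years)
    base["window_start"] = window_start

    # first qualifying AKI inside [index - lookback, index)
    aki = diag[_has_prefix(diag["code"], tuple(aki_prefixes))]
    aki = aki.merge(base[["patient_id", "ckd_index_date", "window_start"]],
                    on="patient_id")
    aki = aki[(aki["date"] >= aki["window_start"])
              & (aki["date"] < aki["ckd_index_date"])]
    first_aki = aki.groupby("patient_id")["date"].min().rename("first_aki_date")
    base = base.merge(first_aki, left_on="patient_id", right_index=True, how="left")

    # inpatient encounters relative to the first AKI
    inp = events[(events["kind"] == "inpatient_encounter")
                 | ((events["kind"] == "procedure")
                    & events["code"].isin(set(inpatient_cpt_set)))]
    inp = inp.merge(base.loc[base["first_aki_date"].notna(),
                             ["patient_id", "first_aki_date"]], on="patient_id")
    w = pd.Timedelta(days=ha_window_days)
    before = (inp["date"] >= inp["first_aki_date"] - w) & \
             (inp["date"] <= inp["first_aki_date"])
    after = (inp["date"] >= inp["first_aki_date"]) & \
            (inp["date"] <= inp["first_aki_date"] + w)
    if ha_direction == "encounter_before":
        hit = before
    elif ha_direction == "encounter_after":
        hit = after
    else:
        hit = before | after
    ha_patients = set(inp.loc[hit, "patient_id"])

    # dialysis strictly before first AKI, or before index for never-AKI
    dial = events[events["kind"] == "dialysis"].merge(
        base[["patient_id", "ckd_index_date", "first_aki_date"]], on="patient_id")
    cutoff = dial["first_aki_date"].fillna(dial["ckd_index_date"])
    dialysis_excluded = set(dial.loc[dial["date"] < cutoff, "patient_id"])

    label = np.where(base["first_aki_date"].notna(),
                     np.where(base["patient_id"].isin(ha_patients),
                              "HA_AKI", "CA_AKI"),
                     "NO_AKI").astype(object)
    reason = np.full(len(base), "none", dtype=object)
    is_dial = base["patient_id"].isin(dialysis_excluded).to_numpy()
    reason[is_dial] = "pre_aki_dialysis"
    is_minor = (base["age_at_index"] < min_age).to_numpy()
    reason[is_minor] = "under_18"
    label[is_dial | is_minor] = "EXCLUDED"

    out = base[["patient_id", "ckd_index_date", "first_aki_date"]].copy()
    out.insert(1, "label", label)
    out["exclusion_reason"] = reason
    out = out[ASSIGNMENT_COLUMNS].reset_index(drop=True)
    out.attrs["n_dropped_no_ckd"] = n_dropped
    return out


# --- feature matrices ------------------------------------------------------

@dataclass
class FeatureMatrix:
    """Patients x binary code indicators for one cohort and one domain."""

    data: pd.DataFrame                  # index: patient_id; columns: codes; 0/1
    domain: str
    cohort: str | None = None

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def counts(self) -> pd.Series:
        return self.data.sum(axis=0)

    @property
    def prevalence(self) -> pd.Series:
        return self.data.mean(axis=0)


def read_crosswalk(path: str | Path) -> dict[str, str]:
    """Read a user-supplied ICD-9 -> ICD-10 crosswalk CSV (icd9,icd10)."""
    df = pd.read_csv(path, dtype=str)
    return dict(zip(df["icd9"], df["icd10"]))


def _apply_crosswalk(codes: pd.Series, crosswalk: dict[str, str] | None,
                     on_unmapped: str) -> pd.Series:
    is_icd9 = codes.str.match(r"^\d")
    if not is_icd9.any():
        return codes
    mapped = codes.where(~is_icd9, codes.map(crosswalk or {}))
    missing = mapped.isna()
    if missing.any():
        offenders = sorted(codes[missing].unique())
        if on_unmapped == "error":
            raise ValueError(f"unmapped ICD-9 codes: {offenders}")
        logger.warning("dropping %d events with unmapped ICD-9 codes: %s",
                       int(missing.sum()), offenders)
    return mapped


def build_feature_matrix(events: pd.DataFrame, assignments: pd.DataFrame,
                         domain: str, *, crosswalk: dict[str, str] | None = None,
                         on_unmapped: str = "warn",
                         procedure_lookback_years: int = 3,
                         truncate: int | None = None,
                         exclude_prefixes: tuple[str, ...] =
                         CKD_CODE_PREFIXES + AKI_CODE_PREFIXES
                         ) -> dict[str, FeatureMatrix]:
    """Binary presence/absence matrices per cohort.

    Diagnoses count any event strictly before the CKD index; procedures only
    events within ``procedure_lookback_years`` before index. The CKD/AKI
    definition codes themselves are excluded from the feature universe.
    """
    if domain not in ("diagnosis", "procedure"):
        raise ValueError("domain must be 'diagnosis' or 'procedure'")
    included = assignments[assignments["label"].isin(COHORTS)]
    ev = events[events["kind"] == domain].merge(
        included[["patient_id", "label", "ckd_index_date"]], on="patient_id")
    ev = ev.copy()
    ev["date"] = pd.to_datetime(ev["date"])
    ev = ev[ev["date"] < ev["ckd_index_date"]]
    if domain == "procedure":
        start = ev["ckd_index_date"] - pd.DateOffset(years=procedure_lookback_years)
        ev = ev[ev["date"] >= start]
    else:
        ev["code"] = _apply_crosswalk(ev["code"], crosswalk, on_unmapped)
        ev = ev[ev["code"].notna()]
        ev = ev[~_has_prefix(ev["code"], tuple(exclude_prefixes))]
    if truncate is not None:
        ev["code"] = ev["code"].str[:truncate]

    out: dict[str, FeatureMatrix] = {}
    for cohort in COHORTS:
        pids = included.loc[included["label"] == cohort, "patient_id"]
        sub = ev[ev["label"] == cohort]
        mat = (pd.crosstab(sub["patient_id"], sub["code"]) > 0).astype(np.int8)
        mat = mat.reindex(index=pids, fill_value=0)
        mat = mat[sorted(mat.columns)]
        mat.columns.name = None
        mat.index.name = "patient_id"
        out[cohort] = FeatureMatrix(data=mat, domain=domain, cohort=cohort)
    return out


def filter_rare_features(matrices: dict[str, FeatureMatrix],
                         min_prevalence: float = 0.01
                         ) -> tuple[dict[str, FeatureMatrix], pd.DataFrame]:
    """Drop features below ``min_prevalence`` in *every* cohort.

    A feature is retained when its prevalence reaches the threshold in at
    least one cohort; per-cohort matrices additionally drop features absent
    from that cohort, so retained feature counts may differ across cohorts.
    Returns the filtered matrices and a retention report.
    """
    universe = sorted(set().union(*(m.data.columns for m in matrices.values())))
    prev = pd.DataFrame(
        {c: m.prevalence.reindex(universe, fill_value=0.0)
         for c, m in matrices.items()})
    keep = prev.ge(min_prevalence).any(axis=1)
    report = prev.copy()
    report["retained"] = keep
    if not keep.any():
        raise ValueError(
            f"no features reach prevalence {min_prevalence:g} in any cohort; "
            "lower min_prevalence or check the input data")
    logger.info("rare-feature filter: retained %d / %d features",
                int(keep.sum()), len(universe))
    out = {}
    for cohort, m in matrices.items():
        cols = [c for c in universe
                if keep[c] and c in m.data.columns and m.counts.get(c, 0) > 0]
        out[cohort] = FeatureMatrix(m.data[cols].copy(), m.domain, cohort)
    return out, report


# --- baseline descriptive table --------------------------------------------

def _pct(count: float, denom: float) -> float:
    return round(100.0 * count / denom, 1) if denom else float("nan")


@dataclass
class BaselineTable:
    """Per-cohort descriptive statistics with pairwise tests."""

    table: pd.DataFrame
    reference: str = "NO_AKI"

    def to_tsv(self, path: str | Path) -> None:
        self.table.to_csv(path, sep="\t")


def baseline_table(assignments: pd.DataFrame, patients: pd.DataFrame, *,
                   comorbidity: dict[str, FeatureMatrix] | None = None,
                   reference: str = "NO_AKI",
                   comparisons: tuple[str, ...] = ("HA_AKI", "CA_AKI"),
                   age_breaks: tuple[int, int] = (44, 64)) -> BaselineTable:
    """Baseline characteristics per cohort.

    Percentages for sex/race/ethnicity/comorbidities use the full cohort N
    as denominator; age-group percentages use the number of patients with a
    recorded age group. Categorical variables are compared with Pearson
    chi-square, continuous ones with independent-samples t-tests (reference
    cohort vs each comparison cohort); degenerate tests yield NaN.
    """
    cohorts = (reference,) + tuple(comparisons)
    inc = assignments[assignments["label"].isin(cohorts)].merge(
        patients, on="patient_id")
    inc["age"] = age_at(inc["ckd_index_date"], inc["birth_date"])
    lo, hi = age_breaks
    inc["age_group"] = pd.cut(inc["age"], [-np.inf, lo, hi, np.inf],
                              labels=[f"< {lo}", f"{lo + 1}-{hi}", f"> {hi}"])
    groups = {c: inc[inc["label"] == c] for c in cohorts}
    ns = {c: len(groups[c]) for c in cohorts}
    if sum(n > 0 for n in ns.values()) < 2:
        raise ValueError("baseline_table needs at least two non-empty cohorts")

    rows: list[dict] = []

    def _continuous(section: str, values: dict[str, pd.Series]) -> None:
        row = {"section": section, "level": "mean (sd)"}
        for c in cohorts:
            v = values[c]
            row[f"{c}_mean"] = round(float(v.mean()), 2) if len(v) else np.nan
            row[f"{c}_sd"] = round(float(v.std(ddof=1)), 2) if len(v) > 1 else np.nan
        for c in comparisons:
            a, b = values[reference], values[c]
            if len(a) > 1 and len(b) > 1 and (a.std(ddof=1) > 0 or b.std(ddof=1) > 0):
                row[f"pvalue_{c}"] = float(stats.ttest_ind(a, b).pvalue)
            else:
                row[f"pvalue_{c}"] = np.nan
        rows.append(row)

    def _categorical(section: str, column: str, denom_recorded: bool) -> None:
        counts = {c: groups[c][column].value_counts() for c in cohorts}
        levels = sorted(set().union(*(ct.index for ct in counts.values())), key=str)
        pvals = {}
        for c in comparisons:
            tab = np.array([[counts[reference].get(lv, 0) for lv in levels],
                            [counts[c].get(lv, 0) for lv in levels]])
            tab = tab[:, tab.sum(axis=0) > 0]
            if tab.shape[1] > 1 and tab.sum(axis=1).min() > 0:
                pvals[c] = float(stats.chi2_contingency(tab).pvalue)
            else:
                pvals[c] = np.nan
        for lv in levels:
            row = {"section": section, "level": str(lv)}
            for c in cohorts:
                cnt = int(counts[c].get(lv, 0))
                denom = int(counts[c].sum()) if denom_recorded else ns[c]
                row[f"{c}_count"] = cnt
                row[f"{c}_pct"] = _pct(cnt, denom)
            for c in comparisons:       # one omnibus test, echoed per level
                row[f"pvalue_{c}"] = pvals[c]
            rows.append(row)

    rows.append({"section": "N", "level": "",
                 **{f"{c}_count": ns[c] for c in cohorts}})
    _continuous("Age", {c: groups[c]["age"] for c in cohorts})
    _categorical("Age group", "age_group", denom_recorded=True)
    for section, col in (("Sex", "sex"), ("Race", "race"),
                         ("Ethnicity", "ethnicity")):
        if col in inc.columns:
            _categorical(section, col, denom_recorded=False)

    if comorbidity is not None:
        burden = {}
        for c in cohorts:
            m = comorbidity.get(c)
            burden[c] = (m.data.sum(axis=1) if m is not None
                         else pd.Series(dtype=float))
        _continuous("Comorbidity count", burden)
        all_codes = sorted(set().union(
            *(m.data.columns for m in comorbidity.values())))
        for code in all_codes:
            row = {"section": "Comorbidities", "level": code}
            vals = {}
            for c in cohorts:
                m = comorbidity.get(c)
                col = (m.data[code] if m is not None and code in m.data.columns
                       else pd.Series(0, index=range(ns[c])))
                vals[c] = col
                row[f"{c}_count"] = int(col.sum())
                row[f"{c}_pct"] = _pct(int(col.sum()), ns[c])
            for c in comparisons:
                tab = np.array(
                    [[ns[reference] - int(vals[reference].sum()),
                      int(vals[reference].sum())],
                     [ns[c] - int(vals[c].sum()), int(vals[c].sum())]])
                if tab.sum(axis=0).min() > 0:
                    row[f"pvalue_{c}"] = float(stats.chi2_contingency(tab).pvalue)
                else:
                    row[f"pvalue_{c}"] = np.nan
            rows.append(row)

    table = pd.DataFrame(rows).set_index(["section", "level"])
    return BaselineTable(table=table, reference=reference)
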