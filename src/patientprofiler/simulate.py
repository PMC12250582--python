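"""Synthetic longitudinal EHR generator.

Emulates a pre-CKD event extract: every patient carries one index CKD
diagnosis; intended HA-AKI patients get an AKI event 0-90 days after an
inpatient encounter within the 3-year lookback; intended CA-AKI patients an
AKI event in the lookback with no inpatient encounter in the preceding 90
days; intended No-AKI patients none (a fraction carry a *stale* AKI more
than 3 years before index to exercise the window). A configurable fraction
receive a dialysis event before their first AKI (or before index) and are
intended EXCLUDED, as are a fraction of under-18 patients.

Comorbidity indicators use a shared latent Bernoulli per planted block: a
patient "carries" a block with probability q, in which case member features
fire with probability min(0.95, multiplier * baseline), baseline otherwise.
Multiplier 1 recovers full independence (pairwise OER -> 1); larger
multipliers inflate within-block co-occurrence while cross-block pairs stay
independent. Everything is drawn from one numpy Generator, so a fixed seed
yields byte-identical outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from ._codes import (AKI_EVENT_CODE, CKD_EVENT_CODE, DIAGNOSIS_CODE_POOL,
                     DIALYSIS_EVENT_CODE, PROCEDURE_CODE_POOL)
from .config import Block, SimulationConfig

_INPATIENT_EVENT_CODES = ("99221", "99223", "99232", "99291")

EVENT_COLUMNS = ["patient_id", "kind", "code", "date"]
PATIENT_COLUMNS = ["patient_id", "birth_date", "sex", "race", "ethnicity"]


@dataclass
class GroundTruth:
    """Intended labels and planted structure carried by the generator."""

    labels: pd.DataFrame                  # patient_id, label, reason, index_date, first_aki_date
    diagnosis_blocks: dict[str, int]      # code -> planted block id
    procedure_blocks: dict[str, int]
    X_diagnosis: pd.DataFrame             # patients x codes binary indicators
    X_procedure: pd.DataFrame

    def block_labels(self, domain: str) -> pd.Series:
        m = self.diagnosis_blocks if domain == "diagnosis" else self.procedure_blocks
        return pd.Series(m, name="block")

    def to_json(self, path: str | Path) -> None:
        payload = {
            "patients": {
                row.patient_id: {"label": row.label, "reason": row.reason}
                for row in self.labels.itertuples()
            },
            "diagnosis_blocks": self.diagnosis_blocks,
            "procedure_blocks": self.procedure_blocks,
        }
        Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def _draw_block_indicators(rng: np.random.Generator, n: int, prev: np.ndarray,
                           blocks: Sequence[Block], q: float) -> np.ndarray:
    """Latent-carrier block model; returns an (n, n_features) 0/1 array."""
    p = np.tile(np.asarray(prev, float), (n, 1))
    for b in blocks:
        carriers = rng.random(n) < q
        members = list(b.members)
        p_hi = np.minimum(0.95, b.multiplier * np.asarray(prev, float)[members])
        p[np.ix_(carriers, members)] = p_hi
    return (rng.random(p.shape) < p).astype(np.int8)


def _truncated_normal(rng: np.random.Generator, n: int, mean: float, sd: float,
                      lo: float, hi: float) -> np.ndarray:
    out = rng.normal(mean, sd, n)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, bad.sum())
        bad = (out < lo) | (out > hi)
    return out


def _categorical(rng: np.random.Generator, levels_p: dict[str, float],
                 idx: np.ndarray, out: np.ndarray) -> None:
    levels = list(levels_p)
    p = np.array([levels_p[k] for k in levels])
    out[idx] = rng.choice(np.array(levels, dtype=object), size=idx.size, p=p / p.sum())


def generate_cohort_events(config: SimulationConfig
                           ) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Draw one synthetic cohort; returns (patients, events, ground_truth)."""
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = np.array([f"P{i:06d}" for i in range(n)], dtype=object)

    base = rng.choice(3, size=n, p=np.asarray(config.cohort_fractions))
    base_label = np.array(["HA_AKI", "CA_AKI", "NO_AKI"], dtype=object)[base]
    under18 = rng.random(n) < config.under18_fraction
    dialysis = rng.random(n) < config.dialysis_fraction

    label = base_label.copy()
    reason = np.full(n, "none", dtype=object)
    reason[dialysis] = "pre_aki_dialysis"
    reason[under18] = "under_18"
    label[dialysis | under18] = "EXCLUDED"

    start = np.datetime64(config.index_start)
    span = int((np.datetime64(config.index_end) - start).astype(int))
    index_date = start + rng.integers(0, span + 1, n).astype("timedelta64[D]")

    # ages: cohort-specific truncated normals; minors overridden to 10-17
    age = np.empty(n)
    for k, lab in enumerate(("HA_AKI", "CA_AKI", "NO_AKI")):
        spec = config.demographics[lab]
        sel = base == k
        age[sel] = _truncated_normal(rng, int(sel.sum()), spec.age_mean,
                                     spec.age_sd, 19, 100)
    age = np.floor(age)
    age[under18] = rng.integers(10, 18, int(under18.sum()))
    jitter = rng.integers(0, 181, n)
    birth_date = index_date - (np.round(365.25 * age).astype(int)
                               - jitter).astype("timedelta64[D]")

    sex = np.empty(n, dtype=object)
    race = np.empty(n, dtype=object)
    ethnicity = np.empty(n, dtype=object)
    for k, lab in enumerate(("HA_AKI", "CA_AKI", "NO_AKI")):
        spec = config.demographics[lab]
        sel = np.flatnonzero(base == k)
        _categorical(rng, spec.sex, sel, sex)
        _categorical(rng, spec.race, sel, race)
        _categorical(rng, spec.ethnicity, sel, ethnicity)

    patients = pd.DataFrame({
        "patient_id": pids, "birth_date": birth_date.astype("datetime64[s]"),
        "sex": sex, "race": race, "ethnicity": ethnicity,
    })

    # --- clinical timeline -------------------------------------------------
    ev_pid: list[np.ndarray] = []
    ev_kind: list[np.ndarray] = []
    ev_code: list[np.ndarray] = []
    ev_date: list[np.ndarray] = []

    def emit(idx: np.ndarray, kind: str, codes, dates: np.ndarray) -> None:
        if len(idx) == 0:
            return
        ev_pid.append(pids[idx])
        ev_kind.append(np.full(len(idx), kind, dtype=object))
        if isinstance(codes, str):
            codes = np.full(len(idx), codes, dtype=object)
        ev_code.append(np.asarray(codes, dtype=object))
        ev_date.append(dates)

    all_idx = np.arange(n)
    emit(all_idx, "diagnosis", CKD_EVENT_CODE, index_date)
    follow = np.flatnonzero(rng.random(n) < 0.3)
    emit(follow, "diagnosis", CKD_EVENT_CODE,
         index_date[follow] + rng.integers(30, 301, follow.size).astype("timedelta64[D]"))

    has_aki = base != 2
    aki_offset = rng.integers(30, 1051, n)
    aki_date = index_date - aki_offset.astype("timedelta64[D]")
    aki_idx = np.flatnonzero(has_aki)
    emit(aki_idx, "diagnosis", AKI_EVENT_CODE, aki_date[aki_idx])

    ha_idx = np.flatnonzero(base == 0)
    enc_date = aki_date[ha_idx] - rng.integers(0, 91, ha_idx.size).astype("timedelta64[D]")
    emit(ha_idx, "inpatient_encounter",
         rng.choice(np.array(_INPATIENT_EVENT_CODES, dtype=object), ha_idx.size),
         enc_date)

    # benign inpatient encounters for some No-AKI patients (no AKI nearby)
    noaki_idx = np.flatnonzero(base == 2)
    benign = noaki_idx[rng.random(noaki_idx.size) < 0.15]
    emit(benign, "inpatient_encounter",
         rng.choice(np.array(_INPATIENT_EVENT_CODES, dtype=object), benign.size),
         index_date[benign] - rng.integers(0, 1001, benign.size).astype("timedelta64[D]"))

    # stale AKI (> 3 years before index) for some No-AKI patients
    stale = noaki_idx[rng.random(noaki_idx.size) < config.stale_aki_fraction]
    emit(stale, "diagnosis", AKI_EVENT_CODE,
         index_date[stale] - rng.integers(1100, 1801, stale.size).astype("timedelta64[D]"))

    dial_aki = np.flatnonzero(dialysis & has_aki)
    emit(dial_aki, "dialysis", DIALYSIS_EVENT_CODE,
         aki_date[dial_aki] - rng.integers(5, 26, dial_aki.size).astype("timedelta64[D]"))
    dial_no = np.flatnonzero(dialysis & ~has_aki)
    emit(dial_no, "dialysis", DIALYSIS_EVENT_CODE,
         index_date[dial_no] - rng.integers(10, 401, dial_no.size).astype("timedelta64[D]"))

    # --- planted comorbidity indicators ------------------------------------
    diag_codes = np.array(DIAGNOSIS_CODE_POOL[: config.n_diagnoses], dtype=object)
    proc_codes = np.array(PROCEDURE_CODE_POOL[: config.n_procedures], dtype=object)
    X_diag = _draw_block_indicators(rng, n, config.diagnosis_prevalences,
                                    config.diagnosis_blocks, config.block_carrier_prob)
    X_proc = _draw_block_indicators(rng, n, config.procedure_prevalences,
                                    config.procedure_blocks, config.block_carrier_prob)

    for X, codes, kind in ((X_diag, diag_codes, "diagnosis"),
                           (X_proc, proc_codes, "procedure")):
        pi, fi = np.nonzero(X)
        offs = rng.integers(1, 1051, pi.size).astype("timedelta64[D]")
        emit(pi, kind, codes[fi], index_date[pi] - offs)
        if kind == "diagnosis":
            dup = rng.random(pi.size) < config.duplicate_diagnosis_prob
            offs2 = rng.integers(1, 1051, int(dup.sum())).astype("timedelta64[D]")
            emit(pi[dup], kind, codes[fi[dup]], index_date[pi[dup]] - offs2)

    # out-of-window procedure events: must not flip the feature matrix
    stale_proc = np.flatnonzero(rng.random(n) < config.stale_procedure_prob)
    emit(stale_proc, "procedure",
         proc_codes[rng.integers(0, len(proc_codes), stale_proc.size)],
         index_date[stale_proc] - rng.integers(1150, 1701, stale_proc.size
                                               ).astype("timedelta64[D]"))

    events = pd.DataFrame({
        "patient_id": np.concatenate(ev_pid),
        "kind": np.concatenate(ev_kind),
        "code": np.concatenate(ev_code),
        "date": np.concatenate(ev_date).astype("datetime64[s]"),
    })
    events = events.sort_values(EVENT_COLUMNS, kind="mergesort").reset_index(drop=True)

    first_aki = np.full(n, np.datetime64("NaT", "s"))
    first_aki[has_aki] = aki_date[has_aki]
    truth = GroundTruth(
        labels=pd.DataFrame({
            "patient_id": pids, "label": label, "reason": reason,
            "base_cohort": base_label,
            "index_date": index_date.astype("datetime64[s]"),
            "first_aki_date": first_aki,
        }),
        diagnosis_blocks=_block_map(diag_codes, config.diagnosis_blocks),
        procedure_blocks=_block_map(proc_codes, config.procedure_blocks),
        X_diagnosis=pd.DataFrame(X_diag, index=pids, columns=diag_codes),
        X_procedure=pd.DataFrame(X_proc, index=pids, columns=proc_codes),
    )
    return patients, events, truth


def _block_map(codes: np.ndarray, blocks: Sequence[Block]) -> dict[str, int]:
    return {str(codes[m]): b for b, blk in enumerate(blocks) for m in blk.members}


# --- I/O -------------------------------------------------------------------

def write_event_tables(patients: pd.DataFrame, events: pd.DataFrame,
                       outdir: str | Path,
                       truth: GroundTruth | None = None) -> dict[str, Path]:
    """Write patients.csv / events.csv (ISO-8601 dates) and, if given,
    ground_truth.json. Returns the written paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {"patients": outdir / "patients.csv", "events": outdir / "events.csv"}
    p = patients.copy()
    p["birth_date"] = pd.to_datetime(p["birth_date"]).dt.strftime("%Y-%m-%d")
    p.to_csv(paths["patients"], index=False)
    e = events.copy()
    e["date"] = pd.to_datetime(e["date"]).dt.strftime("%Y-%m-%d")
    e.to_csv(paths["events"], index=False)
    if truth is not None:
        paths["ground_truth"] = outdir / "ground_truth.json"
        truth.to_json(paths["ground_truth"])
    return paths


def read_event_tables(events_path: str | Path, patients_path: str | Path
                      ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read the delimited tables written by :func:`write_event_tables`."""
    events = pd.read_csv(events_path, dtype={"patient_id": str, "code": str,
                                             "kind": str})
    events["date"] = pd.to_datetime(events["date"], format="ISO8601")
    patients = pd.read_csv(patients_path, dtype=str)
    patients["birth_date"] = pd.to_datetime(patients["birth_date"], format="ISO8601")
    return events, patients
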