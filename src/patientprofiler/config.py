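"""Configuration objects for the simulator and the pipeline."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from ._codes import DIAGNOSIS_CODE_POOL, PROCEDURE_CODE_POOL

COHORT_LABELS = ("HA_AKI", "CA_AKI", "NO_AKI")


@dataclass(frozen=True)
class Block:
    """A planted comorbidity block: member feature indices and the
    within-block co-occurrence odds multiplier (>= 1; 1 = independence)."""

    members: tuple[int, ...]
    multiplier: float = 6.0


@dataclass(frozen=True)
class DemographicsSpec:
    """Per-cohort categorical level probabilities and age moments."""

    age_mean: float
    age_sd: float
    sex: dict[str, float]
    race: dict[str, float]
    ethnicity: dict[str, float]


def _norm(d: dict[str, float]) -> dict[str, float]:
    tot = sum(d.values())
    return {k: v / tot for k, v in d.items()}


# Cohort-level demographics emulating the source population's baseline table.
DEFAULT_DEMOGRAPHICS: dict[str, DemographicsSpec] = {
    "NO_AKI": DemographicsSpec(
        age_mean=68.6, age_sd=13.4,
        sex=_norm({"Female": 0.530, "Male": 0.4697, "Unknown": 0.0003}),
        race=_norm({"White": 0.827, "Black": 0.034, "Other": 0.002, "Unknown": 0.137}),
        ethnicity=_norm({"Hispanic or Latino": 0.0038,
                         "Not Hispanic or Latino": 0.809, "Unknown": 0.187}),
    ),
    "HA_AKI": DemographicsSpec(
        age_mean=65.1, age_sd=13.6,
        sex=_norm({"Female": 0.485, "Male": 0.5145, "Unknown": 0.0005}),
        race=_norm({"White": 0.890, "Black": 0.034, "Other": 0.002, "Unknown": 0.074}),
        ethnicity=_norm({"Hispanic or Latino": 0.0028,
                         "Not Hispanic or Latino": 0.894, "Unknown": 0.103}),
    ),
    "CA_AKI": DemographicsSpec(
        age_mean=66.4, age_sd=13.2,
        sex=_norm({"Female": 0.486, "Male": 0.5136, "Unknown": 0.0004}),
        race=_norm({"White": 0.884, "Black": 0.042, "Other": 0.002, "Unknown": 0.072}),
        ethnicity=_norm({"Hispanic or Latino": 0.0034,
                         "Not Hispanic or Latino": 0.906, "Unknown": 0.0904}),
    ),
}


def default_blocks(n_features: int, n_blocks: int = 3, block_size: int = 10,
                   multiplier: float = 6.0) -> tuple[Block, ...]:
    blocks = []
    for b in range(n_blocks):
        members = tuple(range(b * block_size, (b + 1) * block_size))
        if members[-1] >= n_features:
            raise ValueError("blocks exceed the number of features")
        blocks.append(Block(members=members, multiplier=multiplier))
    return tuple(blocks)


def default_prevalences(n_features: int, blocks: Sequence[Block],
                        common: float = 0.05, rare: float = 0.004) -> np.ndarray:
    """Baseline per-feature prevalence: `common` for block members, `rare`
    for the unplanted tail (exercises the 1% prevalence filter)."""
    p = np.full(n_features, rare, dtype=float)
    for b in blocks:
        if min(b.members) < 0 or max(b.members) >= n_features:
            raise ValueError("block indices out of range")
        p[list(b.members)] = common
    return p


@dataclass
class SimulationConfig:
    """Conditions for one synthetic EHR draw.

    Cohort fractions are (HA-AKI, CA-AKI, No-AKI) intended-label shares;
    blocks plant elevated within-block co-occurrence via a shared latent
    Bernoulli carrier per block (probability ``block_carrier_prob``).
    """

    n_patients: int = 5000
    cohort_fractions: tuple[float, float, float] = (0.102, 0.115, 0.783)
    n_diagnoses: int = 34
    n_procedures: int = 34
    diagnosis_blocks: tuple[Block, ...] = field(default_factory=lambda: default_blocks(34))
    procedure_blocks: tuple[Block, ...] = field(default_factory=lambda: default_blocks(34))
    diagnosis_prevalences: np.ndarray | None = None
    procedure_prevalences: np.ndarray | None = None
    block_carrier_prob: float = 0.2
    dialysis_fraction: float = 0.02
    under18_fraction: float = 0.01
    stale_aki_fraction: float = 0.05      # No-AKI patients with an AKI > 3y before index
    stale_procedure_prob: float = 0.03    # out-of-window procedure events
    duplicate_diagnosis_prob: float = 0.2
    index_start: str = "2013-06-01"
    index_end: str = "2022-06-01"
    demographics: dict[str, DemographicsSpec] = field(
        default_factory=lambda: dict(DEFAULT_DEMOGRAPHICS))
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.cohort_fractions) - 1.0) > 1e-12:
            raise ValueError("cohort_fractions must sum to 1")
        if self.diagnosis_prevalences is None:
            self.diagnosis_prevalences = default_prevalences(
                self.n_diagnoses, self.diagnosis_blocks)
        if self.procedure_prevalences is None:
            self.procedure_prevalences = default_prevalences(
                self.n_procedures, self.procedure_blocks)
        for name, n, blocks, prev, pool in (
            ("diagnosis", self.n_diagnoses, self.diagnosis_blocks,
             self.diagnosis_prevalences, DIAGNOSIS_CODE_POOL),
            ("procedure", self.n_procedures, self.procedure_blocks,
             self.procedure_prevalences, PROCEDURE_CODE_POOL),
        ):
            if n > len(pool):
                raise ValueError(f"n_{name}s exceeds the {name} code pool "
                                 f"({len(pool)})")
            prev = np.asarray(prev, dtype=float)
            if prev.shape != (n,):
                raise ValueError(f"{name}_prevalences must have length {n}")
            if ((prev < 0) | (prev > 1)).any():
                raise ValueError(f"{name} prevalences must lie in [0, 1]")
            seen: set[int] = set()
            for b in blocks:
                if b.multiplier < 1:
                    raise ValueError("block multiplier must be >= 1")
                if min(b.members) < 0 or max(b.members) >= n:
                    raise ValueError(f"{name} block indices out of range")
                if seen & set(b.members):
                    raise ValueError(f"{name} blocks must be disjoint")
                seen.update(b.members)


@dataclass
class RunConfig:
    """End-to-end pipeline settings; serialized into every run directory."""

    output_dir: str = "ppa_run"
    events_path: str | None = None
    patients_path: str | None = None
    simulate: bool = False
    seed: int = 0
    lookback_years: int = 3
    ha_window_days: int = 90
    min_prevalence: float = 0.01
    oer_percentile: float = 0.90
    viz_percentile: float = 0.50
    resolution: float = 1.0
    community_seed: int = 20220901
    n_clusters: int = 3
    edge_mode: str = "analysis"
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        for name, v in (("min_prevalence", self.min_prevalence),
                        ("oer_percentile", self.oer_percentile),
                        ("viz_percentile", self.viz_percentile)):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.lookback_years <= 0 or self.ha_window_days < 0:
            raise ValueError("invalid cohort window parameters")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.edge_mode not in ("analysis", "prominent"):
            raise ValueError("edge_mode must be 'analysis' or 'prominent'")

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        def conv(obj):
            if isinstance(obj, np.ndarray):
                return obj.tolist()
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: conv(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, dict):
                return {k: conv(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [conv(v) for v in obj]
            return obj

        return conv(self)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        """Hash of the analysis settings (I/O paths excluded)."""
        d = self.to_dict()
        for key in ("output_dir", "events_path", "patients_path"):
            d.pop(key, None)
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", None)
        cfg_kwargs = {k: v for k, v in d.items()
                      if k in {f.name for f in dataclasses.fields(cls)}}
        if sim is not None:
            sim = dict(sim)
            for key in ("diagnosis_blocks", "procedure_blocks"):
                if key in sim and sim[key] is not None:
                    sim[key] = tuple(
                        Block(members=tuple(b["members"]),
                              multiplier=float(b.get("multiplier", 6.0)))
                        for b in sim[key])
            if "demographics" in sim and sim["demographics"] is not None:
                sim["demographics"] = {
                    k: DemographicsSpec(**v) if not isinstance(v, DemographicsSpec) else v
                    for k, v in sim["demographics"].items()}
            for key in ("diagnosis_prevalences", "procedure_prevalences"):
                if sim.get(key) is not None:
                    sim[key] = np.asarray(sim[key], dtype=float)
            if "cohort_fractions" in sim:
                sim["cohort_fractions"] = tuple(sim["cohort_fractions"])
            cfg_kwargs["simulation"] = SimulationConfig(**sim)
        return cls(**cfg_kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
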