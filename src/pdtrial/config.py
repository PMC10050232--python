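"""Scenario configuration: the full generative and analytic specification of
one simulated prediction-driven trial.

All times are months.  Event times are exponential with subgroup-specific
medians, one median per (biomarker, treatment) cell; censoring is purely
administrative at a fixed calendar analysis time, with optional uniform
accrual.  A scenario also fixes the design, its randomization probabilities,
the physician-choice behaviour, the evaluation horizon for survival-difference
and restricted-mean summaries, the significance level and the replication
count.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from types import MappingProxyType
from typing import Mapping

import yaml

from .designs import DESIGNS, DesignSpec

TREATMENTS = ("A", "B")

#: Serialization keys for the four (marker, treatment) cells.
_MEDIAN_KEYS = {"pos_A": (1, "A"), "pos_B": (1, "B"), "neg_A": (0, "A"), "neg_B": (0, "B")}
_MEDIAN_NAMES = {v: k for k, v in _MEDIAN_KEYS.items()}


@dataclass(frozen=True)
class PhysicianModel:
    """Treatment-assignment law of the physician's-choice arm.

    ``ideal`` means the physician always prescribes according to the
    biomarker-directed strategy (B to positives, A to negatives) without
    seeing the assay — the scenario in which the biomarker has exactly zero
    clinical utility.  ``bernoulli`` prescribes B with marker-conditional
    probabilities; ``ideal`` is the special case (1, 0).
    """

    kind: str = "ideal"
    p_B_given_pos: float = 1.0
    p_B_given_neg: float = 0.0

    def __post_init__(self):
        if self.kind not in ("ideal", "bernoulli"):
            raise ValueError(f"unknown physician model kind {self.kind!r}")
        if self.kind == "ideal":
            object.__setattr__(self, "p_B_given_pos", 1.0)
            object.__setattr__(self, "p_B_given_neg", 0.0)
        for name in ("p_B_given_pos", "p_B_given_neg"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")

    def prob_B(self, marker) -> float:
        return self.p_B_given_pos if marker else self.p_B_given_neg

    @property
    def is_ideal(self) -> bool:
        return self.p_B_given_pos == 1.0 and self.p_B_given_neg == 0.0


def _default_medians():
    # base grid of the null-utility study: positives do equally well on
    # either treatment (9 months), negatives do better on A (12 vs 9)
    return MappingProxyType({(1, "A"): 9.0, (1, "B"): 9.0, (0, "A"): 12.0, (0, "B"): 9.0})


@dataclass(frozen=True)
class ScenarioConfig:
    """Generative plus analytic specification of one simulation scenario.

    Parameters
    ----------
    prevalence : float
        P(M = 1), the biomarker-positive fraction of the screened population.
    medians : mapping ``(marker, treatment) -> months``
        Median survival for each of the four cells; exponential event times.
    n_per_arm : int
        Patients per arm; total enrolment is ``2 * n_per_arm``.
    design : str
        One of ``enrichment``, ``stratified``, ``strategy``,
        ``modified_strategy``.
    r_strat, r_pos1, r_neg1, r_pos2, r_neg2 : float
        Randomization probabilities, see :class:`~pdtrial.designs.DesignSpec`.
    physician_model : PhysicianModel
    accrual_duration : float
        Uniform accrual window in months (0 = instantaneous enrolment).
    admin_censor_time : float
        Calendar time of analysis; follow-up is censored there.
    horizon_t : float
        Evaluation time for survival-difference and restricted-mean-survival
        summaries; must not exceed the maximum possible follow-up.
    alpha : float
        Two-sided significance level.
    n_reps : int
        Monte-Carlo replicates.
    seed : int
        Root seed; replicate streams are spawned from it.
    """

    prevalence: float = 0.25
    medians: Mapping = field(default_factory=_default_medians)
    n_per_arm: int = 500
    design: str = "strategy"
    test_marker_in_randomized_arm: bool = True
    r_strat: float = 0.5
    r_pos1: float = 0.5
    r_neg1: float = 0.5
    r_pos2: float = 0.5
    r_neg2: float = 0.5
    physician_model: PhysicianModel = field(default_factory=PhysicianModel)
    accrual_duration: float = 0.0
    admin_censor_time: float = 60.0
    horizon_t: float = 36.0
    alpha: float = 0.05
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError(f"prevalence={self.prevalence} outside [0, 1]")
        if self.design not in DESIGNS:
            raise ValueError(f"unknown design {self.design!r}; expected one of {DESIGNS}")
        medians = {}
        for key, m in dict(self.medians).items():
            if isinstance(key, str):
                if key not in _MEDIAN_KEYS:
                    raise ValueError(f"unknown median cell {key!r}; expected {sorted(_MEDIAN_KEYS)}")
                key = _MEDIAN_KEYS[key]
            medians[(int(key[0]), str(key[1]))] = float(m)
        missing = set(_MEDIAN_NAMES) - set(medians)
        if missing:
            raise ValueError(f"medians missing cells: {sorted(_MEDIAN_NAMES[c] for c in missing)}")
        for cell, m in medians.items():
            if not m > 0:
                raise ValueError(f"median for cell {cell} must be > 0, got {m}")
        object.__setattr__(self, "medians", MappingProxyType(medians))
        if self.n_per_arm < 2:
            raise ValueError("n_per_arm must be at least 2")
        for name in ("r_strat", "r_pos1", "r_neg1", "r_pos2", "r_neg2", "alpha"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie strictly inside (0, 1)")
        if self.accrual_duration < 0:
            raise ValueError("accrual_duration must be >= 0")
        if self.admin_censor_time <= 0:
            raise ValueError("admin_censor_time must be > 0")
        if self.accrual_duration >= self.admin_censor_time:
            raise ValueError("accrual must finish before the analysis time")
        if not 0.0 < self.horizon_t <= self.admin_censor_time:
            raise ValueError("horizon_t must lie in (0, admin_censor_time]")
        if self.n_reps < 1:
            raise ValueError("n_reps must be positive")

    # -- derived quantities -------------------------------------------------

    def median(self, marker, treatment) -> float:
        return self.medians[(int(marker), str(treatment))]

    def rate(self, marker, treatment) -> float:
        """Exponential hazard rate lambda = ln 2 / median for one cell."""
        return math.log(2.0) / self.median(marker, treatment)

    def design_spec(self) -> DesignSpec:
        return DesignSpec(
            kind=self.design,
            r_pos1=self.r_pos1,
            r_neg1=self.r_neg1,
            r_strat=self.r_strat,
            r_pos2=self.r_pos2,
            r_neg2=self.r_neg2,
            test_marker_in_randomized_arm=self.test_marker_in_randomized_arm,
        )

    def replace(self, **changes) -> "ScenarioConfig":
        changes.setdefault("medians", dict(self.medians))
        return dataclasses.replace(self, **changes)

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = {f.name: getattr(self, f.name) for f in dataclasses.fields(self)}
        d["medians"] = {_MEDIAN_NAMES[cell]: float(m) for cell, m in self.medians.items()}
        d["physician_model"] = dataclasses.asdict(self.physician_model)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        if "medians" in d:
            medians = {}
            for key, m in dict(d["medians"]).items():
                if key not in _MEDIAN_KEYS:
                    raise ValueError(f"unknown median cell {key!r}; expected {sorted(_MEDIAN_KEYS)}")
                medians[_MEDIAN_KEYS[key]] = float(m)
            d["medians"] = medians
        if "physician_model" in d and not isinstance(d["physician_model"], PhysicianModel):
            d["physician_model"] = PhysicianModel(**dict(d["physician_model"]))
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**d)


def load_scenario(path):
    """Read a scenario file (YAML or JSON by extension).

    The file holds the :class:`ScenarioConfig` keys at top level, plus an
    optional ``requests`` list of contrast-request blocks which is returned
    untouched for the caller (see :mod:`pdtrial.contrasts`).

    Returns ``(config, request_dicts)``.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        raw = json.loads(text)
    else:
        raw = yaml.safe_load(text)
    if not isinstance(raw, Mapping):
        raise ValueError(f"{path}: scenario file must contain a mapping at top level")
    raw = dict(raw)
    requests = raw.pop("requests", [])
    return ScenarioConfig.from_dict(raw), list(requests)


def save_scenario(config: ScenarioConfig, path, requests=None):
    """Write a scenario (and optional request blocks) as YAML or JSON."""
    path = Path(path)
    d = config.to_dict()
    if requests:
        d["requests"] = list(requests)
    if path.suffix.lower() == ".json":
        path.write_text(json.dumps(d, indent=2, sort_keys=True) + "\n")
    else:
        path.write_text(yaml.safe_dump(d, sort_keys=True))
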