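"""Patient-level data generation for simulated prediction-driven trials.

Event times are exponential with a separate median per (biomarker, treatment)
cell and independent of everything else.  Patients accrue uniformly over an
accrual window and are administratively censored at a fixed calendar analysis
time, so censoring depends only on entry time — completely independent
censoring, as required for the pseudo-observation estimators downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .config import PhysicianModel, ScenarioConfig
from .designs import DesignSpec, assign_cohort

#: Column order of the cohort CSV dialect.
CSV_COLUMNS = ["id", "arm", "marker", "treatment", "entry_time", "time", "event"]


def median_to_rate(median):
    """Hazard rate of an exponential distribution with the given median.

    The median of Exponential(lambda) is ln 2 / lambda, so
    ``rate = ln 2 / median``.
    """
    median = float(median)
    if not median > 0:
        raise ValueError(f"median must be > 0, got {median}")
    return math.log(2.0) / median


def draw_survival_time(marker, treatment, config: ScenarioConfig, rng, size=None):
    """Draw exponential event time(s) for one (marker, treatment) cell."""
    try:
        median = config.median(marker, treatment)
    except KeyError:
        raise ValueError(f"no median configured for cell ({marker}, {treatment})") from None
    return rng.exponential(scale=1.0 / median_to_rate(median), size=size)


def physician_choice(marker, model: PhysicianModel, rng):
    """Treatment a biomarker-blinded physician prescribes to one patient.

    The ideal physician reproduces the directed strategy exactly (B iff
    positive); the bernoulli physician prescribes B with a marker-conditional
    probability.
    """
    return "B" if rng.random() < model.prob_B(marker) else "A"


def apply_censoring(event_time, entry_time, admin_censor_time):
    """Administrative censoring at the calendar analysis time.

    Returns ``(observed_time, event)`` with
    ``observed_time = min(event_time, admin_censor_time - entry_time)``.
    Accepts scalars or arrays.
    """
    event_time = np.asarray(event_time, dtype=float)
    entry_time = np.asarray(entry_time, dtype=float)
    follow_up = admin_censor_time - entry_time
    if np.any(follow_up <= 0):
        raise ValueError("entry at or after the analysis time yields no follow-up")
    observed = np.minimum(event_time, follow_up)
    event = (event_time <= follow_up).astype(int)
    if observed.ndim == 0:
        return float(observed), int(event)
    return observed, event


@dataclass
class CohortData:
    """One simulated trial cohort: a patient table plus provenance.

    ``records`` has columns id, arm, marker, marker_measured, treatment,
    entry_time, event_time (latent), time (observed) and event.  The latent
    ``event_time`` and the marker of unmeasured patients are available in
    memory for oracle computations but are masked on export.
    """

    records: pd.DataFrame
    design: str
    config: Optional[ScenarioConfig] = None

    def __len__(self):
        return len(self.records)

    def to_csv(self, path):
        """Export as the cohort CSV dialect; unmeasured markers are blanked
        and the latent event time is dropped."""
        df = self.records.copy()
        marker = df["marker"].astype("object")
        marker[~df["marker_measured"].astype(bool)] = ""
        df["marker"] = marker
        df[CSV_COLUMNS].to_csv(path, index=False, float_format="%.10g")

    @classmethod
    def from_csv(cls, path, design=None, config=None):
        df = pd.read_csv(path, dtype={"marker": "Int64"})
        df["marker_measured"] = df["marker"].notna()
        df["marker"] = df["marker"].fillna(-1).astype(int)
        df["event_time"] = np.where(df["event"] == 1, df["time"], np.nan)
        return cls(records=df, design=design or "unknown", config=config)


def _draw_markers(config: ScenarioConfig, rng, n_total):
    """Marker statuses of the enrolled cohort.

    Enrichment screens Bernoulli(prevalence) candidates and enrolls positives
    only, so the screening cost is governed by prevalence; other designs
    enroll every screened patient.
    """
    if config.design != "enrichment":
        return (rng.random(n_total) < config.prevalence).astype(int)
    if config.prevalence == 0:
        raise ValueError("enrichment design with zero prevalence cannot enroll anyone")
    enrolled = 0
    while enrolled < n_total:
        batch = max(64, int(1.5 * (n_total - enrolled) / config.prevalence))
        enrolled += int(np.sum(rng.random(batch) < config.prevalence))
    # only positives enter the cohort; their count is fixed at n_total
    return np.ones(n_total, dtype=int)


def generate_cohort(config: ScenarioConfig, rng) -> CohortData:
    """Generate one complete trial cohort under the scenario's design.

    All randomness flows from ``rng``; identical (config, rng state) yields a
    bit-identical patient table.
    """
    n_total = 2 * config.n_per_arm
    marker = _draw_markers(config, rng, n_total)
    arm, treatment, measured = assign_cohort(
        marker, config.design_spec(), rng, physician_model=config.physician_model
    )

    # subgroup-specific exponential event times
    event_time = np.empty(n_total, dtype=float)
    for m in (0, 1):
        for x in ("A", "B"):
            mask = (marker == m) & (treatment == x)
            k = int(mask.sum())
            if k:
                event_time[mask] = draw_survival_time(m, x, config, rng, size=k)

    if config.accrual_duration > 0:
        entry_time = rng.uniform(0.0, config.accrual_duration, size=n_total)
    else:
        entry_time = np.zeros(n_total)
    observed, event = apply_censoring(event_time, entry_time, config.admin_censor_time)

    records = pd.DataFrame(
        {
            "id": np.arange(n_total),
            "arm": arm,
            "marker": marker,
            "marker_measured": measured,
            "treatment": treatment,
            "entry_time": entry_time,
            "event_time": event_time,
            "time": observed,
            "event": event,
        }
    )
    return CohortData(records=records, design=config.design, config=config)
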