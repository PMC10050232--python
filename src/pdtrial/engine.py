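"""Monte-Carlo engine: replicate trials and aggregate operating
characteristics.

A replicate simulates one trial per design needed by the requested contrasts
(the comparative clinical-utility contrast needs a biomarker-strategy trial,
the experimental one a modified biomarker-strategy trial, subgroup and
differential contrasts a stratified trial if the scenario's own design does
not already identify them), shares the scenario parameters between those
trials, and computes every requested estimand on each.  Replicate random
streams are spawned hierarchically from the scenario seed, so replicate ``k``
is reproducible in isolation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import ScenarioConfig
from .contrasts import ContrastRequest, estimate, true_contrast_value
from .datagen import generate_cohort
from .designs import ContrastKind, identifiable_contrasts
from .estimators import FitError

#: Design used to realize each contrast when the scenario's own design does
#: not identify it (the canonical trial for that contrast).
_CANONICAL_DESIGN = {
    ContrastKind.SUBGROUP_EFFECT: "stratified",
    ContrastKind.DIFFERENTIAL_EFFECT: "stratified",
    ContrastKind.CLINICAL_UTILITY_COMPARATIVE: "strategy",
    ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL: "modified_strategy",
}


def replicate_rng(seed, replicate_index):
    """Independent random stream for one replicate, spawned from the root
    seed; reproducible regardless of execution order."""
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(int(replicate_index),)))


def _design_for(config: ScenarioConfig, request: ContrastRequest) -> str:
    if request.contrast in identifiable_contrasts(config.design_spec()):
        return config.design
    return _CANONICAL_DESIGN[request.contrast]


def run_replicate(config: ScenarioConfig, replicate_index, requests):
    """Simulate one replicate and estimate every request.

    Returns a list of row dicts (one per request) with the fit results; a
    request whose fit fails (separation, no events) yields a row with
    ``estimable = False`` rather than raising.
    """
    rng = replicate_rng(config.seed, replicate_index)
    designs_needed = []
    for req in requests:
        d = _design_for(config, req)
        if d not in designs_needed:
            designs_needed.append(d)
    cohorts = {}
    for d in designs_needed:  # fixed order => deterministic stream consumption
        cohorts[d] = generate_cohort(config.replace(design=d), rng)

    rows = []
    for req in requests:
        cohort = cohorts[_design_for(config, req)]
        row = {
            "replicate": replicate_index,
            "contrast": req.contrast.value,
            "estimand": req.estimand,
            "design": cohort.design,
        }
        try:
            res = estimate(cohort, req, rng=rng)
        except FitError as exc:
            row.update(
                {"estimable": False, "estimate": np.nan, "se": np.nan, "statistic": np.nan,
                 "p_value": np.nan, "hr_reciprocal": np.nan, "note": str(exc)}
            )
        else:
            row.update(
                {
                    "estimable": True,
                    "estimate": res.estimate,
                    "se": res.se,
                    "statistic": res.statistic,
                    "p_value": res.p_value,
                    "hr_reciprocal": res.extra.get("hr_reciprocal", np.nan),
                    "note": "",
                }
            )
        rows.append(row)
    return rows


@dataclass
class OperatingCharacteristics:
    """Aggregated frequentist properties per (contrast, estimand).

    ``summary`` has one row per request with columns: rejection_rate,
    mean_estimate, empirical_se, true_value, bias, n_estimable, n_reps and
    Monte-Carlo standard errors of the rejection rate and the mean.
    """

    summary: pd.DataFrame
    replicates: pd.DataFrame
    config: ScenarioConfig

    def to_csv(self, path):
        self.summary.to_csv(path, index=False, float_format="%.6g")


def operating_characteristics(config: ScenarioConfig, requests, keep_replicates=True):
    """Run ``config.n_reps`` replicates and aggregate.

    Rejection rate is the fraction of estimable replicates with two-sided
    p < alpha; bias is relative to :func:`true_contrast_value` where a truth
    exists (HR truths for non-proportional mixtures, and LR, have none).
    """
    if config.n_reps < 2:
        raise ValueError("operating characteristics need at least 2 replicates")
    requests = [r if isinstance(r, ContrastRequest) else ContrastRequest.from_dict(r) for r in requests]
    all_rows = []
    for k in range(config.n_reps):
        all_rows.extend(run_replicate(config, k, requests))
    reps = pd.DataFrame(all_rows)

    summaries = []
    for req in requests:
        sub = reps[(reps["contrast"] == req.contrast.value) & (reps["estimand"] == req.estimand)]
        ok = sub[sub["estimable"]]
        n_est = len(ok)
        if n_est == 0:
            raise FitError(
                f"no estimable replicates for {req.contrast.value}/{req.estimand}"
            )
        reject = float((ok["p_value"] < config.alpha).mean())
        mean_est = float(ok["estimate"].mean()) if req.estimand != "LR" else np.nan
        emp_se = float(ok["estimate"].std(ddof=1)) if req.estimand != "LR" else np.nan
        try:
            truth = true_contrast_value(config, req)
        except ValueError:
            truth = np.nan
        summaries.append(
            {
                "contrast": req.contrast.value,
                "estimand": req.estimand,
                "rejection_rate": reject,
                "mc_se_rejection": float(np.sqrt(reject * (1 - reject) / n_est)),
                "mean_estimate": mean_est,
                "mean_hr_reciprocal": float(ok["hr_reciprocal"].mean()) if req.estimand == "HR" else np.nan,
                "empirical_se": emp_se,
                "mc_se_mean": emp_se / np.sqrt(n_est) if np.isfinite(emp_se) else np.nan,
                "true_value": truth,
                "bias": mean_est - truth if np.isfinite(truth) else np.nan,
                "n_estimable": n_est,
                "n_reps": config.n_reps,
            }
        )
    summary = pd.DataFrame(summaries)
    return OperatingCharacteristics(
        summary=summary, replicates=reps if keep_replicates else reps.iloc[0:0], config=config
    )


# ---------------------------------------------------------------------------
# The six-scenario null-utility experiment
# ---------------------------------------------------------------------------

#: (median of positives on B, biomarker prevalence) grid of the
#: null-clinical-utility study.
GRID_MEDIANS_POS_B = (9.0, 12.0, 21.0)
GRID_PREVALENCES = (0.25, 0.50)

_UTILITY_REQUESTS = [
    ContrastRequest(contrast=c, estimand=e)
    for c in (ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL, ContrastKind.CLINICAL_UTILITY_COMPARATIVE)
    for e in ("LR", "HR", "RMST", "SD")
]

#: Column blocks mirroring the published layout: LR reject, HR reject,
#: HR mean, RMST reject, RMST mean, SD reject, SD mean, each Exp. then Comp.
_TABLE_CELLS = [
    ("lr_reject", "LR", "rejection_rate"),
    ("hr_reject", "HR", "rejection_rate"),
    ("hr_mean", "HR", "mean_estimate"),
    ("rmst_reject", "RMST", "rejection_rate"),
    ("rmst_mean", "RMST", "mean_estimate"),
    ("sd_reject", "SD", "rejection_rate"),
    ("sd_mean", "SD", "mean_estimate"),
]
_SUFFIX = {
    ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL.value: "exp",
    ContrastKind.CLINICAL_UTILITY_COMPARATIVE.value: "comp",
}


def scenario_grid(base_config: ScenarioConfig):
    """The six scenario configs: median(T | M=1, X=B) in {9, 12, 21} months
    by prevalence in {0.25, 0.50}; all other cells fixed at 9 (pos on A),
    9 (neg on B) and 12 (neg on A) months."""
    scenarios = []
    for med_pos_b in GRID_MEDIANS_POS_B:
        for prev in GRID_PREVALENCES:
            medians = dict(base_config.medians)
            medians[(1, "B")] = med_pos_b
            scenarios.append(base_config.replace(medians=medians, prevalence=prev))
    return scenarios


def table2_experiment(base_config: ScenarioConfig, progress=False):
    """Operating characteristics of both clinical-utility contrasts over the
    six-scenario grid, under the ideal-physician null (zero true utility).

    Returns a DataFrame with one row per scenario: the scenario columns
    (median_pos_B, prevalence), the seven cells for each contrast
    (``*_exp`` / ``*_comp``), the reciprocal-orientation HR means, and the
    Monte-Carlo SE of every cell.
    """
    rows = []
    for config in scenario_grid(base_config):
        oc = operating_characteristics(config, _UTILITY_REQUESTS, keep_replicates=False)
        row = {
            "median_pos_B": config.median(1, "B"),
            "prevalence": config.prevalence,
        }
        for _, s in oc.summary.iterrows():
            suffix = _SUFFIX[s["contrast"]]
            for cell, estimand, col in _TABLE_CELLS:
                if s["estimand"] == estimand:
                    row[f"{cell}_{suffix}"] = s[col]
                    mc = s["mc_se_rejection"] if col == "rejection_rate" else s["mc_se_mean"]
                    row[f"{cell}_{suffix}_mc_se"] = mc
            if s["estimand"] == "HR":
                row[f"hr_mean_recip_{suffix}"] = s["mean_hr_reciprocal"]
        rows.append(row)
        if progress:
            print(
                f"scenario median_pos_B={row['median_pos_B']:g} "
                f"prevalence={row['prevalence']:g} done",
                flush=True,
            )
    ordered = ["median_pos_B", "prevalence"]
    for cell, _, _ in _TABLE_CELLS:
        for suffix in ("exp", "comp"):
            ordered.append(f"{cell}_{suffix}")
    extra = [c for c in rows[0] if c not in ordered]
    return pd.DataFrame(rows)[ordered + extra]
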