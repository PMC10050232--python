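"""Mapping (design, contrast, estimand) requests onto the right estimator.

A :class:`ContrastRequest` names what to estimate — treatment effect within a
biomarker subgroup, differential treatment effect between subgroups, or
clinical utility in its comparative (directed vs physician's choice) or
experimental (directed vs randomized) form — and on which scale: logrank
test (LR), hazard ratio (HR), survival-probability difference (SD) or
restricted-mean difference (RMST).

:func:`estimate` enforces identifiability (a contrast a design cannot
identify raises :class:`IdentifiabilityError`) and dispatches to the Cox or
pseudo-observation regression layouts; :func:`true_contrast_value` returns
the generative truth under the exponential scenario for bias computation.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import ScenarioConfig
from .datagen import CohortData
from .designs import (
    ARM_DIRECTED,
    ARM_PHYSICIAN,
    ARM_RANDOMIZED,
    ContrastKind,
    identifiable_contrasts,
    strategy_rule,
)
from .estimators import FitResult, cox_fit, glm_identity, logrank, pseudo_observations

ESTIMANDS = ("LR", "HR", "SD", "RMST")


class IdentifiabilityError(ValueError):
    """The requested contrast is not identified by the cohort's design
    without additional distributional assumptions."""


@dataclass(frozen=True)
class ContrastRequest:
    """One estimation request: contrast, estimand scale and settings."""

    contrast: ContrastKind
    estimand: str = "HR"
    subgroup: Optional[int] = None  # subgroup_effect only
    horizon: Optional[float] = None  # SD/RMST; falls back to config.horizon_t

    def __post_init__(self):
        object.__setattr__(self, "contrast", ContrastKind(self.contrast))
        if self.estimand not in ESTIMANDS:
            raise ValueError(f"estimand must be one of {ESTIMANDS}")
        if self.estimand == "LR" and self.contrast is ContrastKind.DIFFERENTIAL_EFFECT:
            raise ValueError(
                "the logrank test cannot target a differential treatment "
                "effect: it tests equality of all four subgroup survival "
                "distributions, not equality of the two treatment effects"
            )
        if self.contrast is ContrastKind.SUBGROUP_EFFECT:
            if self.subgroup not in (0, 1):
                raise ValueError("subgroup_effect requests need subgroup 0 or 1")

    @classmethod
    def from_dict(cls, d):
        d = dict(d)
        return cls(
            contrast=ContrastKind(d.pop("contrast")),
            estimand=d.pop("estimand", "HR"),
            subgroup=d.pop("subgroup", None),
            horizon=d.pop("horizon", None),
        )


def _horizon(request: ContrastRequest, cohort: CohortData) -> float:
    if request.horizon is not None:
        return float(request.horizon)
    if cohort.config is not None:
        return float(cohort.config.horizon_t)
    return 36.0


def _two_sample(request, times, events, indicator, horizon, cox_model, glm_model):
    """Shared two-group estimation: logrank, Cox, or pseudo-value GLM on a
    single 0/1 indicator."""
    if request.estimand == "LR":
        res = logrank(times, events, indicator)
    elif request.estimand == "HR":
        res = cox_fit(times, events, indicator[:, None], model=cox_model)
    else:
        functional = "survival" if request.estimand == "SD" else "rmst"
        pseudo = pseudo_observations(times, events, functional, horizon)
        Z = np.column_stack([np.ones(times.shape[0]), indicator])
        res = glm_identity(pseudo, Z, model=glm_model)
    res.contrast = request.contrast.value
    return res


def estimate(cohort: CohortData, request: ContrastRequest, rng=None) -> FitResult:
    """Estimate a contrast on a cohort, enforcing design identifiability.

    For the experimental clinical-utility contrast on a *stratified* cohort
    (identified, but with no trial arms to compare) an independent random
    half-split builds disjoint evaluation pools: each patient is sent to a
    "directed" pool — kept only if the randomized treatment agrees with the
    strategy rule — or to a "randomized" pool, kept always.  The split is
    independent of outcomes, so the pools are unbiased samples of the two
    counterfactual arms; pass ``rng`` to control it (defaults to a fixed
    stream).
    """
    design = cohort.config.design_spec() if cohort.config is not None else None
    if design is None:
        raise ValueError("cohort has no config attached; cannot check identifiability")
    allowed = identifiable_contrasts(design)
    if request.contrast not in allowed:
        raise IdentifiabilityError(
            f"the {design.kind} design does not identify "
            f"{request.contrast.value}; identifiable contrasts are "
            f"{sorted(c.value for c in allowed)}"
        )

    df = cohort.records
    times = df["time"].to_numpy(dtype=float)
    events = df["event"].to_numpy(dtype=int)
    horizon = _horizon(request, cohort)

    if request.contrast is ContrastKind.SUBGROUP_EFFECT:
        if design.kind == "enrichment" and request.subgroup == 0:
            raise IdentifiabilityError(
                "enrichment designs enroll biomarker-positive patients only; "
                "the negative-subgroup effect is not identified"
            )
        measured = df["marker_measured"].to_numpy(dtype=bool)
        mask = measured & (df["marker"].to_numpy() == request.subgroup)
        if mask.sum() < 2:
            raise IdentifiabilityError("subgroup has fewer than 2 measured patients")
        x = (df["treatment"].to_numpy() == "B").astype(float)[mask]
        return _two_sample(request, times[mask], events[mask], x, horizon, 5, 8)

    if request.contrast is ContrastKind.DIFFERENTIAL_EFFECT:
        measured = df["marker_measured"].to_numpy(dtype=bool)
        t_, e_ = times[measured], events[measured]
        x = (df["treatment"].to_numpy() == "B").astype(float)[measured]
        m = df["marker"].to_numpy(dtype=float)[measured]
        if request.estimand == "HR":
            X = np.column_stack([x, m, x * m])
            res = cox_fit(t_, e_, X, model=6)
        else:
            functional = "survival" if request.estimand == "SD" else "rmst"
            pseudo = pseudo_observations(t_, e_, functional, horizon)
            Z = np.column_stack([np.ones(t_.shape[0]), x, m, x * m])
            res = glm_identity(pseudo, Z, model=9)
        res.contrast = request.contrast.value
        return res

    if request.contrast is ContrastKind.CLINICAL_UTILITY_COMPARATIVE:
        arm = df["arm"].to_numpy()
        mask = np.isin(arm, [ARM_DIRECTED, ARM_PHYSICIAN])
        indicator = (arm[mask] == ARM_DIRECTED).astype(float)
        return _two_sample(request, times[mask], events[mask], indicator, horizon, 7, 10)

    # experimental clinical utility
    arm = df["arm"].to_numpy()
    if design.kind == "modified_strategy":
        mask = np.isin(arm, [ARM_DIRECTED, ARM_RANDOMIZED])
        indicator = (arm[mask] == ARM_DIRECTED).astype(float)
        return _two_sample(request, times[mask], events[mask], indicator, horizon, 7, 10)

    # stratified design: build disjoint directed/randomized evaluation pools
    if rng is None:
        rng = np.random.default_rng(0)
    to_directed = rng.random(len(df)) < 0.5
    concordant = df["treatment"].to_numpy() == strategy_rule(df["marker"].to_numpy())
    keep = np.where(to_directed, concordant, True)
    indicator = to_directed[keep].astype(float)
    if indicator.sum() < 2 or (1 - indicator).sum() < 2:
        raise IdentifiabilityError("evaluation pools too small for the experimental contrast")
    return _two_sample(request, times[keep], events[keep], indicator, horizon, 7, 10)


# ---------------------------------------------------------------------------
# Analytic truths under the exponential generative model
# ---------------------------------------------------------------------------


def _exp_surv(rate, t):
    return math.exp(-rate * t)


def _exp_rmst(rate, t):
    return (1.0 - math.exp(-rate * t)) / rate


def _mixture(config: ScenarioConfig, weights_by_cell):
    """(weights, rates) of a mixture over the four (marker, treatment) cells."""
    cells = [(m, x) for m in (0, 1) for x in ("A", "B")]
    w = np.array([weights_by_cell.get(c, 0.0) for c in cells])
    rates = np.array([config.rate(*c) for c in cells])
    return w, rates


def _arm_laws(config: ScenarioConfig, contrast: ContrastKind):
    """Mixture laws of the two compared populations for the utility
    contrasts (treated arm first)."""
    p = config.prevalence
    directed = {(1, "B"): p, (0, "A"): 1 - p}
    if contrast is ContrastKind.CLINICAL_UTILITY_COMPARATIVE:
        phys = config.physician_model
        other = {
            (1, "B"): p * phys.p_B_given_pos,
            (1, "A"): p * (1 - phys.p_B_given_pos),
            (0, "B"): (1 - p) * phys.p_B_given_neg,
            (0, "A"): (1 - p) * (1 - phys.p_B_given_neg),
        }
    else:
        other = {
            (1, "B"): p * config.r_pos2,
            (1, "A"): p * (1 - config.r_pos2),
            (0, "B"): (1 - p) * config.r_neg2,
            (0, "A"): (1 - p) * (1 - config.r_neg2),
        }
    return _mixture(config, directed), _mixture(config, other)


def true_contrast_value(config: ScenarioConfig, request: ContrastRequest) -> float:
    """Generative truth of a contrast under the exponential scenario.

    HR truths exist when the compared hazards are proportional: always for
    subgroup and differential contrasts (single exponentials), and for the
    utility contrasts exactly when the two mixture distributions coincide
    (then HR = 1, e.g. under the ideal physician).  Non-proportional mixture
    comparisons raise ``ValueError`` on the HR scale, as does LR, which has
    no magnitude.
    """
    if request.estimand == "LR":
        raise ValueError("the logrank test has no magnitude; no true value is defined")
    t = request.horizon if request.horizon is not None else config.horizon_t

    if request.contrast is ContrastKind.SUBGROUP_EFFECT:
        m = request.subgroup
        lam_b, lam_a = config.rate(m, "B"), config.rate(m, "A")
        if request.estimand == "HR":
            return lam_b / lam_a
        if request.estimand == "SD":
            return _exp_surv(lam_b, t) - _exp_surv(lam_a, t)
        return _exp_rmst(lam_b, t) - _exp_rmst(lam_a, t)

    if request.contrast is ContrastKind.DIFFERENTIAL_EFFECT:
        rates = {(m, x): config.rate(m, x) for m in (0, 1) for x in ("A", "B")}
        if request.estimand == "HR":
            return (rates[(1, "B")] / rates[(1, "A")]) / (rates[(0, "B")] / rates[(0, "A")])
        f = _exp_surv if request.estimand == "SD" else _exp_rmst
        return (f(rates[(1, "B")], t) - f(rates[(1, "A")], t)) - (
            f(rates[(0, "B")], t) - f(rates[(0, "A")], t)
        )

    (w1, r1), (w2, r2) = _arm_laws(config, request.contrast)
    if request.estimand == "HR":
        # identical mixtures <=> identical survival functions (checked on a
        # grid; mixtures of exponentials are analytic, so agreement on any
        # infinite set implies identity)
        ts = np.linspace(0.5, config.admin_censor_time, 25)
        s1 = (w1[None, :] * np.exp(-np.outer(ts, r1))).sum(axis=1)
        s2 = (w2[None, :] * np.exp(-np.outer(ts, r2))).sum(axis=1)
        if np.allclose(s1, s2, atol=1e-12):
            return 1.0
        raise ValueError(
            "the compared mixture distributions differ and their hazards are "
            "not proportional; no scalar HR truth exists"
        )
    if request.estimand == "SD":
        return float((w1 * np.exp(-r1 * t)).sum() - (w2 * np.exp(-r2 * t)).sum())
    return float(
        (w1 * (1.0 - np.exp(-r1 * t)) / r1).sum() - (w2 * (1.0 - np.exp(-r2 * t)) / r2).sum()
    )
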