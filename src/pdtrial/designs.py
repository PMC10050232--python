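"""Trial designs for prediction-driven RCTs and their identifiability logic.

Four designs are supported, all for two approved treatments ``A``/``B`` and a
binary biomarker ``M`` whose directed strategy is "positives get B, negatives
get A":

``enrichment``
    Only biomarker-positive patients are enrolled and randomized between A
    and B.
``stratified``
    All patients are enrolled; randomization between A and B is performed
    within each biomarker stratum (possibly with stratum-specific
    probabilities).
``strategy``
    Patients are randomized between a biomarker-directed arm (treated by the
    strategy rule) and a physician's-choice arm (treated by a physician who
    does not see the biomarker).
``modified_strategy``
    Patients are randomized between a biomarker-directed arm and a fully
    randomized arm; the biomarker may or may not be assayed in the randomized
    arm.

Each design identifies a different subset of the contrasts of interest; see
:func:`identifiable_contrasts`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np

DESIGNS = ("enrichment", "stratified", "strategy", "modified_strategy")

#: Fixed arm labels used in cohort tables and exported CSV files.
ARM_DIRECTED = "directed"
ARM_PHYSICIAN = "physician"
ARM_RANDOMIZED = "randomized"


class ContrastKind(str, Enum):
    """The estimable contrasts in the comparative-effectiveness setting."""

    SUBGROUP_EFFECT = "subgroup_effect"
    DIFFERENTIAL_EFFECT = "differential_effect"
    CLINICAL_UTILITY_COMPARATIVE = "clinical_utility_comparative"
    CLINICAL_UTILITY_EXPERIMENTAL = "clinical_utility_experimental"


def strategy_rule(marker):
    """Biomarker-directed treatment: B for positives, A for negatives."""
    return np.where(np.asarray(marker).astype(bool), "B", "A")


@dataclass(frozen=True)
class DesignSpec:
    """Randomization structure of one prediction-driven design.

    Parameters
    ----------
    kind : str
        One of ``enrichment``, ``stratified``, ``strategy``,
        ``modified_strategy``.
    r_pos1, r_neg1 : float
        Probability of treatment B for positives / negatives in the
        enrichment and stratified designs.
    r_strat : float
        Probability of the biomarker-directed arm in the strategy and
        modified-strategy designs.
    r_pos2, r_neg2 : float
        Probability of treatment B within the randomized arm of the
        modified-strategy design.
    test_marker_in_randomized_arm : bool
        Whether the biomarker is assayed in the randomized arm of the
        modified-strategy design (drives identifiability).
    """

    kind: str = "strategy"
    r_pos1: float = 0.5
    r_neg1: float = 0.5
    r_strat: float = 0.5
    r_pos2: float = 0.5
    r_neg2: float = 0.5
    test_marker_in_randomized_arm: bool = True

    def __post_init__(self):
        if self.kind not in DESIGNS:
            raise ValueError(f"unknown design kind {self.kind!r}; expected one of {DESIGNS}")
        for name in ("r_pos1", "r_neg1", "r_strat", "r_pos2", "r_neg2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name}={p} outside [0, 1]")


class AssignmentError(ValueError):
    """Raised when a patient cannot be assigned under a design (e.g. a
    biomarker-negative patient in an enrichment trial)."""


def matched_stratified_probability(r_strat, r_pos2):
    """Stratified-design randomization probability matching a modified design.

    In the modified biomarker-strategy design a positive patient receives B
    either by landing in the directed arm (probability ``r_strat``) or by
    being further randomized to B in the randomized arm (probability
    ``(1 - r_strat) * r_pos2``).  Setting the stratified design's ``r_pos1``
    to the total makes the two designs' joint (marker, treatment) laws equal::

        r_pos1 = r_strat + (1 - r_strat) * r_pos2

    For the negative stratum the directed arm assigns treatment A, so the
    matching probability of *A* obeys the same formula; equivalently
    ``r_neg1 = 1 - matched_stratified_probability(r_strat, 1 - r_neg2)``
    (see :func:`matched_stratified_design`).
    """
    r_strat = float(r_strat)
    r_pos2 = float(r_pos2)
    if not (0.0 <= r_strat <= 1.0 and 0.0 <= r_pos2 <= 1.0):
        raise ValueError("randomization probabilities must lie in [0, 1]")
    return r_strat + (1.0 - r_strat) * r_pos2


def matched_stratified_design(modified: DesignSpec) -> DesignSpec:
    """The stratified design whose joint (marker, treatment) law equals that
    of a modified biomarker-strategy design with biomarker testing."""
    if modified.kind != "modified_strategy":
        raise ValueError("matching is defined for the modified_strategy design")
    return DesignSpec(
        kind="stratified",
        r_pos1=matched_stratified_probability(modified.r_strat, modified.r_pos2),
        r_neg1=1.0 - matched_stratified_probability(modified.r_strat, 1.0 - modified.r_neg2),
    )


def assignment_probability_table(design: DesignSpec, prevalence: float):
    """Exact joint probability table P(marker, treatment) under a design.

    Returns a dict ``{(marker, treatment): probability}``.  For the strategy
    design the physician arm's treatment law depends on the physician model
    and is excluded here; only designs with fully specified randomization
    (enrichment, stratified, modified_strategy) are supported.
    """
    p = float(prevalence)
    if design.kind == "enrichment":
        return {(1, "B"): design.r_pos1, (1, "A"): 1 - design.r_pos1}
    if design.kind == "stratified":
        return {
            (1, "B"): p * design.r_pos1,
            (1, "A"): p * (1 - design.r_pos1),
            (0, "B"): (1 - p) * design.r_neg1,
            (0, "A"): (1 - p) * (1 - design.r_neg1),
        }
    if design.kind == "modified_strategy":
        pb_pos = design.r_strat + (1 - design.r_strat) * design.r_pos2
        pb_neg = (1 - design.r_strat) * design.r_neg2
        return {
            (1, "B"): p * pb_pos,
            (1, "A"): p * (1 - pb_pos),
            (0, "B"): (1 - p) * pb_neg,
            (0, "A"): (1 - p) * (1 - pb_neg),
        }
    raise ValueError(
        "joint (marker, treatment) law of the strategy design depends on the "
        "physician model; no closed table is exposed"
    )


def assign_cohort(marker, design: DesignSpec, rng, physician_model=None):
    """Vectorized arm/treatment assignment for a cohort.

    Parameters
    ----------
    marker : array of {0, 1}
    design : DesignSpec
    rng : numpy.random.Generator
    physician_model : PhysicianModel, optional
        Required for the strategy design (physician arm treatment law).

    Returns
    -------
    arm : array of str
        ``"A"``/``"B"`` for enrichment and stratified designs (arm equals
        treatment), ``"directed"``/``"physician"`` or
        ``"directed"``/``"randomized"`` for the strategy designs.
    treatment : array of {"A", "B"}
    marker_measured : bool array
        False where the trial would not have assayed the biomarker
        (physician arm; randomized arm without testing).
    """
    marker = np.asarray(marker, dtype=int)
    n = marker.shape[0]
    measured = np.ones(n, dtype=bool)

    if design.kind == "enrichment":
        if np.any(marker == 0):
            raise AssignmentError("biomarker-negative patients are not enrolled in an enrichment design")
        treatment = np.where(rng.random(n) < design.r_pos1, "B", "A")
        return treatment.copy(), treatment, measured

    if design.kind == "stratified":
        p_b = np.where(marker == 1, design.r_pos1, design.r_neg1)
        treatment = np.where(rng.random(n) < p_b, "B", "A")
        return treatment.copy(), treatment, measured

    if design.kind == "strategy":
        if physician_model is None:
            raise ValueError("strategy design requires a physician_model")
        directed = rng.random(n) < design.r_strat
        arm = np.where(directed, ARM_DIRECTED, ARM_PHYSICIAN)
        p_b_phys = np.where(marker == 1, physician_model.p_B_given_pos, physician_model.p_B_given_neg)
        physician_treat = np.where(rng.random(n) < p_b_phys, "B", "A")
        treatment = np.where(directed, strategy_rule(marker), physician_treat)
        measured = directed.copy()  # the biomarker is never assayed in the physician arm
        return arm, treatment, measured

    # modified_strategy
    directed = rng.random(n) < design.r_strat
    arm = np.where(directed, ARM_DIRECTED, ARM_RANDOMIZED)
    p_b = np.where(marker == 1, design.r_pos2, design.r_neg2)
    randomized_treat = np.where(rng.random(n) < p_b, "B", "A")
    treatment = np.where(directed, strategy_rule(marker), randomized_treat)
    if not design.test_marker_in_randomized_arm:
        measured = directed.copy()
    return arm, treatment, measured


def assign(marker, design: DesignSpec, rng, physician_model=None):
    """Assign a single patient; scalar convenience wrapper over
    :func:`assign_cohort`.

    Returns ``(arm, treatment, marker_measured)``.
    """
    arm, treatment, measured = assign_cohort(
        np.asarray([marker]), design, rng, physician_model=physician_model
    )
    return str(arm[0]), str(treatment[0]), bool(measured[0])


def identifiable_contrasts(design: DesignSpec) -> frozenset:
    """Contrasts a design identifies without extra distributional assumptions.

    Follows the identifiability of the subgroup-conditional counterfactual
    summaries g(T_x | M = m): randomization within a stratum identifies the
    stratum's treatment effect; only the strategy design observes a
    physician's-choice arm and hence the comparative clinical-utility
    contrast; designs with a directed arm and a randomized arm observe the
    experimental clinical-utility contrast directly.
    """
    if design.kind == "enrichment":
        return frozenset({ContrastKind.SUBGROUP_EFFECT})
    if design.kind == "stratified":
        return frozenset(
            {
                ContrastKind.SUBGROUP_EFFECT,
                ContrastKind.DIFFERENTIAL_EFFECT,
                ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL,
            }
        )
    if design.kind == "strategy":
        return frozenset({ContrastKind.CLINICAL_UTILITY_COMPARATIVE})
    # modified_strategy
    if design.test_marker_in_randomized_arm:
        return frozenset(
            {
                ContrastKind.SUBGROUP_EFFECT,
                ContrastKind.DIFFERENTIAL_EFFECT,
                ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL,
            }
        )
    warnings.warn(
        "modified biomarker-strategy design without biomarker testing in the "
        "randomized arm: the subgroup-conditional summaries are not "
        "identified; the directed-vs-randomized (experimental clinical "
        "utility) comparison is still directly observed and is exposed here",
        stacklevel=2,
    )
    return frozenset({ContrastKind.CLINICAL_UTILITY_EXPERIMENTAL})
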