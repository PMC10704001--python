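"""Headphone-use and hearing-status screening rules, and the two-Gaussian ROC.

The hearing screen applies per-SNR cutoffs to word-recognition-in-babble
scores, an engagement filter on browser "blur" events, and survey gates.
Cutoff derivation starts at the 65th percentile of a cohort's scores at each
SNR and relaxes all cutoffs simultaneously in 2-percentile-point steps until
the joint exclusion first reaches the target.

The theoretical ROC treats normal-hearing (NH) and hearing-loss (HL) scores
as Gaussians separated by a standardized effect size ``g`` (pooled-SD units)
with HL scores ``r`` times more dispersed:

    NH ~ Normal(mu, sigma),  HL ~ Normal(mu - g * s_p, r * sigma),
    s_p = sigma * sqrt((1 + r^2) / 2)   (equal-weight pooling).

Placing the cutoff at the NH ``q``-quantile excludes a fraction ``q`` of NH
listeners and ``Phi((Phi^-1(q) + g * s_p / sigma) / r)`` of HL listeners.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

# ---------------------------------------------------------------------------
# Headphone-use check
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class HeadphoneRule:
    """Pass rule for the two 6-trial headphone checks (conjunctive)."""

    n_trials_per_task: int = 6
    min_correct: int = 5

    def __post_init__(self):
        if not 0 <= self.min_correct <= self.n_trials_per_task:
            raise ValueError("min_correct must lie in [0, n_trials]")


STANDARD_HEADPHONE_RULE = HeadphoneRule(6, 5)
#: Relaxed rule used for cohorts recruited for diagnosed hearing loss.
RELAXED_HEADPHONE_RULE = HeadphoneRule(6, 4)


def score_headphone_check(
    task1_correct: int,
    task2_correct: int,
    rule: HeadphoneRule = STANDARD_HEADPHONE_RULE,
) -> bool:
    """True iff both checks meet the rule (e.g. 5-of-6 in *each* task)."""
    for c in (task1_correct, task2_correct):
        if not 0 <= c <= rule.n_trials_per_task:
            raise ValueError(f"correct count {c} outside [0, {rule.n_trials_per_task}]")
    return task1_correct >= rule.min_correct and task2_correct >= rule.min_correct


# ---------------------------------------------------------------------------
# Hearing screen
# ---------------------------------------------------------------------------

#: Survey items a participant must deny to pass screening.
SURVEY_DENIALS = ("hearing_loss", "neurological_disorder", "persistent_tinnitus")


@dataclass(frozen=True)
class ScreeningRule:
    """Per-SNR percent-correct cutoffs plus engagement and survey gates.

    Scores gate with >= at each SNR listed in ``cutoffs``; the -5 dB block is
    recorded but never gates.  More than ``max_blur`` focus-loss events fails
    the engagement gate.
    """

    cutoffs: tuple = ((10.0, 100.0), (5.0, 83.0), (0.0, 75.0))
    max_blur: int = 2
    required_denials: tuple = SURVEY_DENIALS

    def __post_init__(self):
        for snr, cut in self.cutoffs:
            if not 0 <= cut <= 100:
                raise ValueError(f"cutoff {cut} at {snr} dB outside [0, 100]")

    @property
    def cutoff_dict(self) -> dict:
        return dict(self.cutoffs)


DEFAULT_SCREENING_RULE = ScreeningRule()


@dataclass(frozen=True)
class ScreeningOutcome:
    passed: bool
    reasons: tuple

    def __post_init__(self):
        if self.passed != (len(self.reasons) == 0):
            raise ValueError("passed must hold exactly when no gate failed")


def classify_hearing(
    scores_by_snr: dict,
    blur_count: int = 0,
    survey: dict | None = None,
    rule: ScreeningRule = DEFAULT_SCREENING_RULE,
) -> ScreeningOutcome:
    """Classify a participant's hearing status from screening data.

    ``scores_by_snr`` maps SNR (dB) to percent correct and must cover every
    gating SNR in the rule.  ``survey`` maps each required item to True when
    the participant denied it; missing items count as failures.  Reasons
    enumerate every failed gate.
    """
    survey = survey or {}
    reasons = []
    for snr, cutoff in rule.cutoffs:
        if snr not in scores_by_snr:
            raise ValueError(f"missing score for gating SNR {snr} dB")
        if scores_by_snr[snr] < cutoff:
            reasons.append(f"{snr:g} dB SNR cutoff")
    if blur_count > rule.max_blur:
        reasons.append("engagement")
    for item in rule.required_denials:
        if not survey.get(item, False):
            reasons.append(f"survey: {item}")
    return ScreeningOutcome(passed=not reasons, reasons=tuple(reasons))


# ---------------------------------------------------------------------------
# Cutoff derivation from a cohort
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CutoffDerivation:
    rule: ScreeningRule
    achieved_exclusion: float
    trace: tuple  # (percentile, cutoffs dict, joint exclusion) per step


def _scores_wide(cohort_scores) -> pd.DataFrame:
    """Accept a long (participant_id, snr_db, percent_correct) frame or a
    mapping snr -> score array; return a wide participants x SNR frame."""
    if isinstance(cohort_scores, pd.DataFrame):
        return cohort_scores.pivot_table(
            index="participant_id", columns="snr_db", values="percent_correct"
        )
    return pd.DataFrame({float(k): np.asarray(v, float) for k, v in cohort_scores.items()})


def derive_cutoffs(
    cohort_scores,
    target_exclusion: float,
    gate_snrs: tuple = (10.0, 5.0, 0.0),
    start_percentile: float = 65.0,
    step: float = 2.0,
    rule_template: ScreeningRule = DEFAULT_SCREENING_RULE,
) -> CutoffDerivation:
    """Derive per-SNR cutoffs achieving at most ``target_exclusion`` jointly.

    Initial cutoffs sit at the cohort's ``start_percentile`` at each gating
    SNR; all cutoffs are then relaxed together in ``step``-percentile-point
    decrements until the joint exclusion (failing any SNR gate, comparisons
    with >=) first reaches the target.  Percentiles use linear interpolation.
    """
    if not 0 < target_exclusion < 1:
        raise ValueError("target_exclusion must lie in (0, 1)")
    wide = _scores_wide(cohort_scores)
    missing = [s for s in gate_snrs if s not in wide.columns]
    if missing:
        raise ValueError(f"cohort lacks scores at SNRs {missing}")
    wide = wide[list(gate_snrs)].dropna()
    if len(wide) < 20:
        raise ValueError("cohort too small (need >= 20 complete participants)")
    scores = wide.to_numpy()

    trace = []
    pct = start_percentile
    best = None
    while pct >= 0:
        cuts = np.percentile(scores, pct, axis=0)
        excluded = np.any(scores < cuts[None, :], axis=1).mean()
        trace.append((pct, dict(zip(gate_snrs, cuts)), float(excluded)))
        best = trace[-1]
        if excluded <= target_exclusion:
            rule = ScreeningRule(
                cutoffs=tuple(zip(gate_snrs, (float(c) for c in cuts))),
                max_blur=rule_template.max_blur,
                required_denials=rule_template.required_denials,
            )
            return CutoffDerivation(rule, float(excluded), tuple(trace))
        pct -= step
    raise ValueError(
        f"target exclusion {target_exclusion:.2f} unattainable; best achievable "
        f"{best[2]:.3f} at percentile {best[0]:g}"
    )


# ---------------------------------------------------------------------------
# Two-Gaussian population model and theoretical ROC
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PopulationModel:
    """NH/HL score populations: effect size ``g`` (pooled-SD units), SD ratio ``r``."""

    g: float = 2.05
    sd_ratio: float = 3.0
    nh_mean: float = 0.0
    nh_sd: float = 1.0

    def __post_init__(self):
        if self.sd_ratio <= 0:
            raise ValueError("sd_ratio must be positive")
        if self.nh_sd <= 0:
            raise ValueError("nh_sd must be positive")

    @property
    def pooled_sd(self) -> float:
        """Equal-weight pooled SD, sqrt((sigma_NH^2 + sigma_HL^2) / 2)."""
        return self.nh_sd * math.sqrt((1.0 + self.sd_ratio**2) / 2.0)

    @property
    def hl_mean(self) -> float:
        return self.nh_mean - self.g * self.pooled_sd

    @property
    def hl_sd(self) -> float:
        return self.sd_ratio * self.nh_sd


def expected_hl_exclusion(model: PopulationModel, nh_exclusion: float) -> float:
    """Fraction of HL listeners below the cutoff at the NH ``nh_exclusion`` quantile."""
    if not 0 < nh_exclusion < 1:
        raise ValueError("nh_exclusion must lie in (0, 1)")
    cutoff = norm.ppf(nh_exclusion, loc=model.nh_mean, scale=model.nh_sd)
    return float(norm.cdf(cutoff, loc=model.hl_mean, scale=model.hl_sd))


@dataclass(frozen=True)
class ROCCurve:
    """Exclusion trade-off: (NH excluded, HL excluded) pairs on [0, 1]^2."""

    nh_exclusion: tuple
    hl_exclusion: tuple

    def __post_init__(self):
        nh = np.asarray(self.nh_exclusion, float)
        hl = np.asarray(self.hl_exclusion, float)
        if nh.shape != hl.shape or nh.ndim != 1 or len(nh) < 2:
            raise ValueError("need matched 1-d exclusion arrays")
        if np.any(nh < 0) or np.any(nh > 1) or np.any(hl < -1e-9) or np.any(hl > 1 + 1e-9):
            raise ValueError("exclusion fractions must lie in [0, 1]")
        if np.any(np.diff(nh) < 0) or np.any(np.diff(hl) < -1e-9):
            raise ValueError("ROC must be non-decreasing in both coordinates")

    @property
    def points(self) -> np.ndarray:
        return np.column_stack([self.nh_exclusion, self.hl_exclusion])

    def interpolate(self, nh_exclusion) -> np.ndarray:
        return np.interp(nh_exclusion, self.nh_exclusion, self.hl_exclusion)


def theoretical_roc(model: PopulationModel, grid) -> ROCCurve:
    """Analytic exclusion trade-off over a grid of NH-exclusion fractions.

    Endpoints (0, 0) and (1, 1) are appended so the curve satisfies the
    ROC invariants.
    """
    grid = np.asarray(list(grid), float)
    if grid.size == 0:
        raise ValueError("empty grid")
    if np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    grid = np.sort(grid)
    hl = [expected_hl_exclusion(model, q) for q in grid]
    nh = np.concatenate([[0.0], grid, [1.0]])
    hl = np.concatenate([[0.0], hl, [1.0]])
    return ROCCurve(tuple(nh), tuple(hl))
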