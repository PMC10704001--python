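"""Synthetic observers and cohorts for end-to-end, download-free testing.

Observers are parametric response models, not signal-processing listeners: a
psychometric observer answers forced-choice trials with probability
``gamma + (1 - gamma - lambda) * S(log level)``; cohort members carry a
latent word-recognition score drawn from the two-Gaussian normal-hearing /
hearing-loss population model, mapped to per-SNR scores by a fixed monotone
offset; headphone-check sessions draw per-task Bernoulli outcomes from a
listening-mode accuracy model (stereo headphones easy on both checks, mono
earphone near chance on the dichotic chirp, free-field degraded on the triad
by foil cancellation and near chance on the chirp).

Everything is reproducible under a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .psychometrics import PsychometricData, performance
from .screening import PopulationModel, ROCCurve

# ---------------------------------------------------------------------------
# Psychometric observers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ObserverModel:
    """Stationary forced-choice observer with lapses and a guess floor."""

    threshold: float          # sigmoid midpoint, stimulus units
    width: float              # 5-95% rise width on the log axis
    lapse: float = 0.0
    guess: float = 1.0 / 3.0
    blur_propensity: float = 0.0   # mean blur events per task run

    def __post_init__(self):
        if not 0 < self.guess < 1 or not 0 <= self.lapse < 1 - self.guess:
            raise ValueError("invalid guess/lapse probabilities")
        if self.threshold <= 0 or self.width <= 0:
            raise ValueError("threshold and width must be positive")

    def p_correct(self, levels) -> np.ndarray:
        x = np.log(np.asarray(levels, float))
        return performance(x, np.log(self.threshold), self.width, self.guess, self.lapse)


def simulate_psychometric_responses(
    observer: ObserverModel,
    levels,
    trials_per_level: int,
    seed: int = 0,
) -> PsychometricData:
    """Binomial draws from the observer's performance curve, per level."""
    levels = np.asarray(levels, float)
    if np.any(levels <= 0):
        raise ValueError("levels must be positive")
    if trials_per_level < 1:
        raise ValueError("need at least one trial per level")
    rng = np.random.default_rng(seed)
    p = observer.p_correct(levels)
    k = rng.binomial(trials_per_level, p)
    return PsychometricData(
        levels=tuple(levels),
        n_trials=tuple([trials_per_level] * len(levels)),
        n_correct=tuple(int(v) for v in k),
        chance=observer.guess,
    )


# ---------------------------------------------------------------------------
# Cohorts of word-recognition scores
# ---------------------------------------------------------------------------

#: Latent-score population defaults: percent-correct at 0 dB SNR.
DEFAULT_SCORE_POPULATION = PopulationModel(g=2.05, sd_ratio=3.0, nh_mean=85.0, nh_sd=8.0)

#: Monotone SNR-to-score offsets (percent points) applied to the latent score.
DEFAULT_SNR_OFFSETS = {10.0: 8.0, 5.0: 4.0, 0.0: 0.0, -5.0: -18.0}


@dataclass(frozen=True)
class CohortSpec:
    """Synthetic cohort: size, hearing mix, population model, mode mix."""

    n: int = 1000
    hl_fraction: float = 0.0
    population: PopulationModel = DEFAULT_SCORE_POPULATION
    mode_mix: tuple = (("stereo-headphones", 1.0),)
    seed: int = 0

    def __post_init__(self):
        if not 0 <= self.hl_fraction <= 1:
            raise ValueError("hl_fraction must lie in [0, 1]")
        total = sum(f for _, f in self.mode_mix)
        if abs(total - 1.0) > 1e-9 or any(f < 0 for _, f in self.mode_mix):
            raise ValueError("mode fractions must be non-negative and sum to 1")


def _latent_scores(spec: CohortSpec, rng: np.random.Generator):
    n_hl = int(round(spec.n * spec.hl_fraction))
    n_nh = spec.n - n_hl
    pop = spec.population
    nh = rng.normal(pop.nh_mean, pop.nh_sd, n_nh)
    hl = rng.normal(pop.hl_mean, pop.hl_sd, n_hl)
    groups = np.array(["NH"] * n_nh + ["HL"] * n_hl)
    return np.concatenate([nh, hl]), groups


def simulate_cohort_scores(
    spec: CohortSpec,
    snr_offsets: dict | None = None,
    clip: bool = True,
) -> pd.DataFrame:
    """Per-participant MRT percent-correct scores by SNR (long format).

    Each participant carries one latent score from the population model;
    per-SNR scores add the monotone SNR offset and are clipped to [0, 100].
    Columns: participant_id, group (NH/HL), snr_db, percent_correct,
    latent_score.
    """
    offsets = DEFAULT_SNR_OFFSETS if snr_offsets is None else snr_offsets
    rng = np.random.default_rng(spec.seed)
    latent, groups = _latent_scores(spec, rng)
    rows = []
    for snr, off in sorted(offsets.items(), reverse=True):
        scores = latent + off
        if clip:
            scores = np.clip(scores, 0.0, 100.0)
        rows.append(
            pd.DataFrame(
                {
                    "participant_id": [f"p{i:06d}" for i in range(spec.n)],
                    "group": groups,
                    "snr_db": snr,
                    "percent_correct": scores,
                    "latent_score": latent,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# Headphone-check sessions by listening mode
# ---------------------------------------------------------------------------

#: Per-mode (triad accuracy, chirp accuracy).  Stereo headphones make both
#: checks easy; a mono earphone removes the dichotic chirp cue (chance 1/3);
#: free-field playback degrades the triad via foil cancellation and also
#: leaves the chirp at chance.
MODE_ACCURACIES = {
    "stereo-headphones": (0.98, 0.95),
    "mono-earphone": (0.98, 1.0 / 3.0),
    "freefield-stereo": (0.40, 1.0 / 3.0),
}


@dataclass(frozen=True)
class ListeningMode:
    name: str
    triad_accuracy: float
    chirp_accuracy: float

    @classmethod
    def named(cls, name: str) -> "ListeningMode":
        if name not in MODE_ACCURACIES:
            raise KeyError(f"unknown listening mode {name!r}")
        t, c = MODE_ACCURACIES[name]
        return cls(name, t, c)


def simulate_headphone_session(
    mode: ListeningMode | str,
    seed: int = 0,
    n_trials: int = 6,
) -> dict:
    """Draw one participant's 6 + 6 headphone-check trial outcomes."""
    if isinstance(mode, str):
        mode = ListeningMode.named(mode)
    rng = np.random.default_rng(seed)
    triad = rng.random(n_trials) < mode.triad_accuracy
    chirp = rng.random(n_trials) < mode.chirp_accuracy
    return {
        "mode": mode.name,
        "triad_outcomes": tuple(bool(b) for b in triad),
        "chirp_outcomes": tuple(bool(b) for b in chirp),
        "triad_correct": int(triad.sum()),
        "chirp_correct": int(chirp.sum()),
    }


# ---------------------------------------------------------------------------
# Empirical ROC
# ---------------------------------------------------------------------------


def empirical_roc(spec: CohortSpec, grid, snr_db: float = 0.0) -> ROCCurve:
    """Monte-Carlo exclusion trade-off from a simulated mixed cohort.

    Sweeps score cutoffs placed at the NH group's empirical quantiles over
    ``grid`` and tallies the NH and HL fractions falling below each cutoff.
    Requires both hearing groups in the cohort.
    """
    if not 0 < spec.hl_fraction < 1:
        raise ValueError("empirical ROC needs both NH and HL participants")
    grid = np.sort(np.asarray(list(grid), float))
    if grid.size == 0 or np.any((grid <= 0) | (grid >= 1)):
        raise ValueError("grid values must lie strictly inside (0, 1)")
    scores = simulate_cohort_scores(spec)
    at_snr = scores[scores["snr_db"] == snr_db]
    nh = at_snr.loc[at_snr["group"] == "NH", "percent_correct"].to_numpy()
    hl = at_snr.loc[at_snr["group"] == "HL", "percent_correct"].to_numpy()
    cutoffs = np.quantile(nh, grid)
    nh_frac = [float(np.mean(nh < c)) for c in cutoffs]
    hl_frac = [float(np.mean(hl < c)) for c in cutoffs]
    nh_frac = np.concatenate([[0.0], np.maximum.accumulate(nh_frac), [1.0]])
    hl_frac = np.concatenate([[0.0], np.maximum.accumulate(hl_frac), [1.0]])
    return ROCCurve(tuple(nh_frac), tuple(hl_frac))
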