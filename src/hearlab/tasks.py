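"""Trial-list construction, response scoring, and conditional study flow.

Tasks are classic n-alternative forced-choice designs run by the method of
constant stimuli.  A :class:`TaskConfig` names a registered task, its
condition ladder and the trial count per condition; :func:`build_trial_list`
expands it into a seeded, shuffled sequence of :class:`TrialSpec` records.
Responses come back as tabular records and are scored per condition; study
flow ("present task 2 if the score in condition c of task 1 exceeds X%") is
evaluated as a pure function of rules and score tables.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

# ---------------------------------------------------------------------------
# Registered task designs
# ---------------------------------------------------------------------------


def _geometric_ladder(lo: float, hi: float, n: int) -> tuple:
    return tuple(float(v) for v in np.geomspace(lo, hi, n))


#: Default condition ladders and response sets for the registered tasks.
TASK_REGISTRY = {
    "mrt": {
        "conditions": [{"snr_db": s} for s in (10.0, 5.0, 0.0, -5.0)],
        "choices": tuple(f"word{i}" for i in range(1, 7)),  # corpus placeholders
        "condition_key": "snr_db",
    },
    "f0dl": {
        "conditions": [{"delta_f0": v} for v in _geometric_ladder(0.05, 3.2, 7)],
        "choices": ("1", "2", "3"),
        "condition_key": "delta_f0",
    },
    "gap": {
        "conditions": [{"gap_ms": v} for v in _geometric_ladder(1.0, 32.0, 6)],
        "choices": ("1", "2", "3"),
        "condition_key": "gap_ms",
    },
    "itd": {
        "conditions": [{"itd_us": v} for v in _geometric_ladder(2.0, 128.0, 7)],
        "choices": ("LR", "RL"),
        "condition_key": "itd_us",
    },
    "ild": {
        "conditions": [{"ild_db": v} for v in _geometric_ladder(0.125, 8.0, 7)],
        "choices": ("LR", "RL"),
        "condition_key": "ild_db",
    },
    "cmr": {
        "conditions": [
            {"cmr_condition": c, "snr_db": s}
            for c in ("REF", "CORR", "ACORR")
            for s in (-25.0, -20.0, -15.0, -10.0, -5.0)
        ],
        "choices": ("1", "2", "3"),
        "condition_key": "cmr_condition",
    },
    "triad": {
        "conditions": [{}],
        "choices": ("1", "2", "3"),
        "condition_key": None,
    },
    "bmld_chirp": {
        "conditions": [{}],
        "choices": ("rising", "falling", "flat"),
        "condition_key": None,
    },
}


@dataclass(frozen=True)
class TaskConfig:
    """A task run: which task, how many trials per condition, which seed."""

    task_id: str
    trials_per_condition: int = 5
    seed: int = 0
    conditions: tuple | None = None   # override the registry ladder
    choices: tuple | None = None

    def resolve(self) -> dict:
        if self.task_id not in TASK_REGISTRY:
            raise KeyError(
                f"unknown task {self.task_id!r}; registered: {sorted(TASK_REGISTRY)}"
            )
        entry = TASK_REGISTRY[self.task_id]
        return {
            "conditions": list(self.conditions) if self.conditions else entry["conditions"],
            "choices": tuple(self.choices) if self.choices else entry["choices"],
            "condition_key": entry["condition_key"],
        }


@dataclass(frozen=True)
class TrialSpec:
    """One forced-choice trial: stimulus condition, alternatives, answer."""

    trial_id: str
    task_id: str
    condition: str
    choices: tuple
    correct_choice: str
    condition_fields: tuple = ()   # (key, value) pairs
    stimulus_ref: str = ""

    def __post_init__(self):
        if self.correct_choice not in self.choices:
            raise ValueError("correct_choice must be one of the choices")

    @property
    def n_alternatives(self) -> int:
        return len(self.choices)


def _condition_label(fields: dict, key: str | None) -> str:
    if not fields:
        return "default"
    if key is not None and key in fields:
        v = fields[key]
        rest = {k: w for k, w in fields.items() if k != key}
        label = f"{key}={v:g}" if isinstance(v, float) else f"{key}={v}"
        if rest:
            label += "," + ",".join(f"{k}={w:g}" for k, w in sorted(rest.items()))
        return label
    return ",".join(f"{k}={v}" for k, v in sorted(fields.items()))


def build_trial_list(config: TaskConfig) -> list:
    """Expand a task config into a shuffled, seeded trial sequence.

    Condition counts match the config exactly; the correct alternative is
    drawn uniformly per trial; the same seed reproduces the same order.
    """
    spec = config.resolve()
    rng = np.random.default_rng(config.seed)
    trials = []
    for cond_fields in spec["conditions"]:
        for _ in range(config.trials_per_condition):
            trials.append(dict(cond_fields))
    order = rng.permutation(len(trials))
    out = []
    for i, idx in enumerate(order):
        fields = trials[idx]
        correct = spec["choices"][rng.integers(len(spec["choices"]))]
        out.append(
            TrialSpec(
                trial_id=f"{config.task_id}-{i:04d}",
                task_id=config.task_id,
                condition=_condition_label(fields, spec["condition_key"]),
                choices=spec["choices"],
                correct_choice=correct,
                condition_fields=tuple(sorted(fields.items())),
                stimulus_ref=f"{config.task_id}-{i:04d}.wav",
            )
        )
    return out


def trial_list_to_json(trials, path=None) -> str:
    payload = json.dumps([asdict(t) for t in trials], ensure_ascii=False, indent=1)
    if path is not None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(payload)
    return payload


def trial_list_from_json(source) -> list:
    data = json.loads(source) if isinstance(source, str) else json.load(source)
    out = []
    for d in data:
        d["choices"] = tuple(d["choices"])
        d["condition_fields"] = tuple(tuple(p) for p in d["condition_fields"])
        out.append(TrialSpec(**d))
    return out


# ---------------------------------------------------------------------------
# Response scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ResponseRecord:
    participant_id: str
    trial_id: str
    response: str
    blur_count_running: int = 0


RESPONSE_COLUMNS = ("participant_id", "trial_id", "response", "blur_count_running")


def read_responses(path_or_df) -> pd.DataFrame:
    """Load a response CSV, validating the required headers."""
    df = path_or_df if isinstance(path_or_df, pd.DataFrame) else pd.read_csv(path_or_df)
    missing = [c for c in RESPONSE_COLUMNS[:3] if c not in df.columns]
    if missing:
        raise ValueError(f"response table lacks columns {missing}")
    if "blur_count_running" not in df.columns:
        df = df.assign(blur_count_running=0)
    return df


def score_responses(trials, records) -> pd.DataFrame:
    """Per-participant, per-condition accuracy table.

    ``records`` is a DataFrame (or list of :class:`ResponseRecord`) carrying
    participant_id, trial_id, response.  Missing trials are reported in the
    ``n_missing`` column, never imputed; duplicate responses to one trial by
    one participant raise with the offending ids.
    """
    by_id = {t.trial_id: t for t in trials}
    if isinstance(records, pd.DataFrame):
        df = read_responses(records)
    else:
        df = pd.DataFrame([asdict(r) for r in records])
        df = read_responses(df)
    unknown = sorted(set(df["trial_id"]) - set(by_id))
    if unknown:
        raise ValueError(f"responses reference unknown trials: {unknown[:5]}")
    dup = df.duplicated(subset=["participant_id", "trial_id"], keep=False)
    if dup.any():
        ids = df.loc[dup, ["participant_id", "trial_id"]].drop_duplicates()
        raise ValueError(f"duplicate responses: {ids.to_dict('records')[:5]}")
    df = df.assign(
        condition=[by_id[t].condition for t in df["trial_id"]],
        correct=[r == by_id[t].correct_choice for t, r in zip(df["trial_id"], df["response"])],
    )
    n_by_cond = pd.Series(
        [t.condition for t in trials], name="condition"
    ).value_counts()
    rows = []
    for (pid, cond), grp in df.groupby(["participant_id", "condition"], sort=True):
        n_answered = len(grp)
        n_correct = int(grp["correct"].sum())
        rows.append(
            {
                "participant_id": pid,
                "condition": cond,
                "n_trials": int(n_by_cond[cond]),
                "n_answered": n_answered,
                "n_correct": n_correct,
                "n_missing": int(n_by_cond[cond]) - n_answered,
                "percent_correct": 100.0 * n_correct / n_answered,
            }
        )
    return pd.DataFrame(rows).sort_values(["participant_id", "condition"]).reset_index(drop=True)


# ---------------------------------------------------------------------------
# Conditional study flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowRule:
    """Gate between tasks: continue iff the source score exceeds a threshold.

    The gate uses a strict "more than" comparison; a score exactly at the
    threshold does not open the gate.
    """

    source_task: str
    condition: str
    threshold_percent: float
    next_task: str | None   # None means "conclude"

    def __post_init__(self):
        if not 0 <= self.threshold_percent <= 100:
            raise ValueError("threshold must lie in [0, 100]")


def evaluate_flow(rules, score_tables: dict) -> list:
    """Walk an acyclic chain of flow rules against observed scores.

    ``score_tables`` maps (task_id, condition) to percent correct.  Returns
    an ordered decision trace; a failed gate appends a concluding decision
    flagged ``partial=True``.
    """
    by_source = {}
    for r in rules:
        if r.source_task in by_source:
            raise ValueError(f"multiple rules out of task {r.source_task!r}")
        by_source[r.source_task] = r
    # cycle check over the successor graph
    seen: set = set()
    for start in by_source:
        chain, node = set(), start
        while node in by_source:
            if node in chain:
                raise ValueError(f"cyclic flow rules through {node!r}")
            chain.add(node)
            node = by_source[node].next_task
    trace = []
    if not rules:
        return trace
    task = rules[0].source_task
    while task in by_source:
        rule = by_source[task]
        key = (rule.source_task, rule.condition)
        if key not in score_tables:
            raise ValueError(f"no score for {key}")
        score = score_tables[key]
        taken = score > rule.threshold_percent
        trace.append(
            {
                "source_task": rule.source_task,
                "condition": rule.condition,
                "score_percent": float(score),
                "threshold_percent": rule.threshold_percent,
                "gate_taken": bool(taken),
                "next": rule.next_task if taken else "conclude",
                "partial": not taken,
            }
        )
        if not taken:
            break
        task = rule.next_task
    return trace
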