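"""Paradigm runner, scoring and recovery-pattern classification.

Each simulated day presents six blocks in a fixed order — picture naming in
L1, word repetition in L1, translation from L1 (into L2), picture naming in
L2, word repetition in L2, translation from L2 (into L1) — with five items
per block drawn without replacement from the twelve concepts.  A control
subject (precision intact, ω = 1 every day) and a lesioned subject (a
precision schedule) are run on identical random streams, so the pair forms a
matched-seed counterfactual: any behavioural divergence is caused by the
lesion alone.

Scoring counts positive-feedback trials per (task, stimulus-language) cell
per day.  The classifier operationalises two clinical recovery patterns:

* *alternate antagonism* — the language accessible for picture naming (able
  in one language, unable in the other) switches between consecutive days;
* *paradoxical translation* — on a given day the subject cannot translate
  into the language she can name in, yet can translate into the language she
  cannot name in, with repetition preserved in both.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .engine import (
    GenerativeModel,
    InvalidInputError,
    ObservationSet,
    PolicyEvaluation,
    evaluate_policies,
    infer_states,
    select_action,
)
from .lesion import PrecisionSchedule, lesion_model
from .taskmodel import (
    CONCEPTS,
    LANGUAGES,
    TrialSetup,
    Vocabulary,
    observations_for_trial,
    required_language,
)

__all__ = [
    "BLOCK_ORDER",
    "ITEMS_PER_BLOCK",
    "ABLE_THRESHOLD",
    "UNABLE_THRESHOLD",
    "TrialRecord",
    "DayResult",
    "StudyResult",
    "PatternReport",
    "run_trial",
    "run_day",
    "run_study",
    "score_study",
    "classify_pattern",
    "export_belief_traces",
]

# (task, stimulus language); translation blocks are named by the language
# translated FROM (the heard language).
BLOCK_ORDER: tuple[tuple[str, str], ...] = (
    ("naming", "L1"),
    ("repetition", "L1"),
    ("translation", "L1"),
    ("naming", "L2"),
    ("repetition", "L2"),
    ("translation", "L2"),
)
ITEMS_PER_BLOCK = 5
ABLE_THRESHOLD = 4
UNABLE_THRESHOLD = 1


@dataclass
class TrialRecord:
    """Everything one trial produced, including full belief traces."""

    day: int
    block: int
    trial: int
    setup: TrialSetup
    observations: dict[int, dict[str, int]]
    belief_trace: dict[str, np.ndarray]       # factor -> (epochs, levels), post-epoch marginals
    policy_evaluation: PolicyEvaluation
    chosen_language: str
    feedback: str
    correct: bool
    converged: bool

    def __post_init__(self):
        if self.correct != (self.feedback == "positive"):
            raise InvalidInputError("correct flag inconsistent with feedback level")


@dataclass
class DayResult:
    """Correct counts per (task, stimulus-language) cell for one day."""

    day: int
    counts: dict[tuple[str, str], int]
    items_per_block: int = ITEMS_PER_BLOCK

    def __post_init__(self):
        for cell, c in self.counts.items():
            if not (0 <= c <= self.items_per_block):
                raise InvalidInputError(f"cell {cell}: count {c} outside [0, {self.items_per_block}]")

    def total(self) -> int:
        return sum(self.counts.values())


@dataclass
class StudyResult:
    """Per-day results for one subject."""

    subject: str
    days: list[DayResult]
    base_seed: int
    items_per_block: int = ITEMS_PER_BLOCK

    def n_trials(self) -> int:
        return sum(len(d.counts) * d.items_per_block for d in self.days)

    def n_correct(self) -> int:
        return sum(d.total() for d in self.days)

    def percent_correct(self) -> float:
        n = self.n_trials()
        return 100.0 * self.n_correct() / n if n else 0.0


@dataclass
class PatternReport:
    """Recovery-pattern flags derived from a scored study."""

    accessible_naming_language: dict[int, str]   # day -> "L1"/"L2"/"both"/"neither"
    alternate_antagonism: bool
    alternation_days: list[tuple[int, int]]
    paradoxical_translation: bool
    paradoxical_days: list[int]
    repetition_intact: bool


def _trial_seed(base_seed: int, day: int, trial: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(day, trial)))


def run_trial(
    agent_model: GenerativeModel,
    setup: TrialSetup,
    seed: np.random.Generator | int | None = None,
    *,
    action_mode: str = "deterministic",
    policy_precision: float | None = None,
    vocabulary: Vocabulary | None = None,
    trial_index: int = 0,
) -> TrialRecord:
    """Run one two-epoch trial of the agent against the intact environment.

    Epoch 1: the environment presents the stimulus; the agent infers states
    under each policy and scores them.  The agent then acts (choosing the
    reply language); epoch 2: the environment emits the response outcomes and
    evaluates feedback from true states.  The agent's post-response beliefs
    are recorded for trace export.
    """
    from .engine import DEFAULT_POLICY_PRECISION

    gamma = DEFAULT_POLICY_PRECISION if policy_precision is None else policy_precision
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    obs1 = observations_for_trial(agent_model, setup, upto_epoch=0, vocabulary=vocabulary)
    evaluation, beliefs = evaluate_policies(agent_model, obs1, policy_precision=gamma)
    policy = select_action(
        evaluation.policy_posterior, agent_model.policies, mode=action_mode, rng=rng
    )
    chosen = LANGUAGES[policy["target"]]

    obs2 = observations_for_trial(
        agent_model, setup, upto_epoch=1, agent_action=chosen, vocabulary=vocabulary
    )
    post = infer_states(agent_model, obs2, policy)
    feedback_level = obs2.get(1, "feedback")
    feedback = agent_model.modality("feedback").levels[feedback_level]

    return TrialRecord(
        day=setup.day,
        block=setup.block,
        trial=trial_index,
        setup=setup,
        observations=obs2.as_dict(),
        belief_trace={name: arr.copy() for name, arr in post.posteriors.items()},
        policy_evaluation=evaluation,
        chosen_language=chosen,
        feedback=feedback,
        correct=feedback == "positive",
        converged=post.converged,
    )


def run_day(
    model: GenerativeModel,
    schedule: PrecisionSchedule,
    day: int,
    base_seed: int,
    *,
    blocks: Sequence[tuple[str, str]] = BLOCK_ORDER,
    items_per_block: int = ITEMS_PER_BLOCK,
    action_mode: str = "deterministic",
    policy_precision: float | None = None,
    vocabulary: Vocabulary | None = None,
) -> tuple[DayResult, list[TrialRecord]]:
    """Run one day's blocks with the day's lesion applied to the agent.

    Items are drawn uniformly without replacement from the twelve concepts
    per block, using a per-day stream derived from ``base_seed`` (identical
    across subjects, realising the matched-seed counterfactual).
    """
    if items_per_block > len(CONCEPTS):
        raise InvalidInputError("items per block cannot exceed the 12-concept corpus")
    day_model = lesion_model(model, schedule, day)
    item_rng = np.random.default_rng(np.random.SeedSequence(base_seed, spawn_key=(day,)))
    counts: dict[tuple[str, str], int] = {}
    records: list[TrialRecord] = []
    trial_no = 0
    for b, (task, language) in enumerate(blocks):
        items = item_rng.choice(len(CONCEPTS), size=items_per_block, replace=False)
        cell = 0
        for concept_idx in items:
            setup = TrialSetup(
                context=task,
                heard_language=language,
                concept=CONCEPTS[int(concept_idx)],
                block=b,
                day=day,
            )
            rec = run_trial(
                day_model,
                setup,
                _trial_seed(base_seed, day, trial_no),
                action_mode=action_mode,
                policy_precision=policy_precision,
                vocabulary=vocabulary,
                trial_index=trial_no,
            )
            records.append(rec)
            cell += int(rec.correct)
            trial_no += 1
        counts[(task, language)] = cell
    return DayResult(day=day, counts=counts, items_per_block=items_per_block), records


def run_study(
    model: GenerativeModel,
    schedule_control: PrecisionSchedule,
    schedule_lesioned: PrecisionSchedule,
    days: int | None = None,
    base_seed: int = 0,
    *,
    keep_records: bool = False,
    **day_kwargs,
) -> tuple[StudyResult, StudyResult, dict[str, list[list[TrialRecord]]]]:
    """Run control and lesioned subjects over the same days and seeds."""
    n_days = schedule_lesioned.n_days if days is None else days
    results: dict[str, StudyResult] = {}
    all_records: dict[str, list[list[TrialRecord]]] = {"control": [], "lesioned": []}
    for label, sched in (("control", schedule_control), ("lesioned", schedule_lesioned)):
        day_results = []
        for day in range(1, n_days + 1):
            dr, recs = run_day(model, sched, day, base_seed, **day_kwargs)
            day_results.append(dr)
            if keep_records:
                all_records[label].append(recs)
        results[label] = StudyResult(
            subject=label,
            days=day_results,
            base_seed=base_seed,
            items_per_block=day_kwargs.get("items_per_block", ITEMS_PER_BLOCK),
        )
    return results["control"], results["lesioned"], all_records


def score_study(results: Iterable[StudyResult]) -> pd.DataFrame:
    """Long-format score table: one row per subject x day x task x language."""
    rows = []
    for study in results:
        for dr in study.days:
            for (task, language), count in dr.counts.items():
                rows.append(
                    {
                        "subject": study.subject,
                        "day": dr.day,
                        "task": task,
                        "language": language,
                        "correct": count,
                        "items": dr.items_per_block,
                    }
                )
    df = pd.DataFrame(rows, columns=["subject", "day", "task", "language", "correct", "items"])
    if len(df):
        df["percent"] = 100.0 * df["correct"] / df["items"]
    else:
        df["percent"] = pd.Series(dtype=float)
    return df


def _cell(day: DayResult, task: str, language: str) -> int:
    return day.counts.get((task, language), 0)


def classify_pattern(
    study: StudyResult,
    able_threshold: int = ABLE_THRESHOLD,
    unable_threshold: int = UNABLE_THRESHOLD,
) -> PatternReport:
    """Flag alternate antagonism and paradoxical translation in a study.

    A language is *able* for a task when its cell count is at or above
    ``able_threshold`` and *unable* at or below ``unable_threshold``.  The
    naming-accessible language on a day is the language able for naming while
    the other is unable.  Alternate antagonism holds when the accessible
    language switches between at least one pair of consecutive days.
    Paradoxical translation holds on a day when translation into the
    accessible language is unable, translation into the inaccessible language
    is able, and repetition is able in both languages.  Translation INTO a
    language is the block translating FROM the other language.
    """
    if able_threshold <= unable_threshold:
        raise InvalidInputError("able threshold must exceed unable threshold")
    other = {"L1": "L2", "L2": "L1"}
    accessible: dict[int, str] = {}
    paradox_days: list[int] = []
    repetition_ok = True
    for dr in study.days:
        able = {l: _cell(dr, "naming", l) >= able_threshold for l in LANGUAGES}
        unable = {l: _cell(dr, "naming", l) <= unable_threshold for l in LANGUAGES}
        if able["L1"] and unable["L2"]:
            acc = "L1"
        elif able["L2"] and unable["L1"]:
            acc = "L2"
        elif able["L1"] and able["L2"]:
            acc = "both"
        else:
            acc = "neither"
        accessible[dr.day] = acc
        rep_able = all(_cell(dr, "repetition", l) >= able_threshold for l in LANGUAGES)
        repetition_ok = repetition_ok and rep_able
        if acc in LANGUAGES:
            into_acc = _cell(dr, "translation", other[acc])   # from the other language
            into_inacc = _cell(dr, "translation", acc)
            if into_acc <= unable_threshold and into_inacc >= able_threshold and rep_able:
                paradox_days.append(dr.day)

    alternations = [
        (d, d + 1)
        for d in sorted(accessible)
        if d + 1 in accessible
        and accessible[d] in LANGUAGES
        and accessible[d + 1] in LANGUAGES
        and accessible[d] != accessible[d + 1]
    ]
    return PatternReport(
        accessible_naming_language=accessible,
        alternate_antagonism=bool(alternations),
        alternation_days=alternations,
        paradoxical_translation=bool(paradox_days),
        paradoxical_days=paradox_days,
        repetition_intact=repetition_ok,
    )


def export_belief_traces(
    records: Iterable[TrialRecord],
    selection: Iterable[tuple[int, int]] | None = None,
    factors: Sequence[str] = ("heard", "target"),
) -> pd.DataFrame:
    """Tabulate posterior expectations per epoch for chosen trials.

    ``selection`` filters on (day, trial index); None keeps everything.
    One row per trial x factor x level x epoch, mirroring a states-by-epochs
    belief raster.
    """
    wanted = set(selection) if selection is not None else None
    rows = []
    for rec in records:
        if wanted is not None and (rec.day, rec.trial) not in wanted:
            continue
        for fac in factors:
            arr = rec.belief_trace[fac]
            for epoch in range(arr.shape[0]):
                for li, level in enumerate(LANGUAGES if fac in ("heard", "target") else range(arr.shape[1])):
                    rows.append(
                        {
                            "day": rec.day,
                            "trial": rec.trial,
                            "task": rec.setup.context,
                            "stimulus_language": rec.setup.heard_language,
                            "factor": fac,
                            "level": level if isinstance(level, str) else str(level),
                            "epoch": epoch + 1,
                            "expectation": float(arr[epoch, li]),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "day", "trial", "task", "stimulus_language",
            "factor", "level", "epoch", "expectation",
        ],
    )
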