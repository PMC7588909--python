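"""Generative model of picture naming, word repetition and word translation.

The model is a two-epoch categorical POMDP for a bilingual speaker tested on
three tasks.  Five hidden-state factors:

* ``context`` — the task in play (naming, repetition, translation);
* ``heard`` — the stimulus language (L1 or L2);
* ``target`` — the language the reply should be (and ends up being) in; the
  single controllable factor;
* ``concept`` — twelve concepts, language-independent;
* ``epoch`` — trial phase (1: stimulus presentation, 2: response + feedback).

Five outcome modalities: ``task`` (what task this is), ``language`` (language
of what is currently heard or spoken), ``audition`` (the heard/spoken word, or
N/A), ``visual`` (the picture, or N/A) and ``feedback`` (neutral / positive /
negative evaluation).

Likelihood structure
--------------------
``task`` reports the context.  ``language`` reports the heard language at
epoch 1 and the spoken (target) language at epoch 2.  ``audition`` maps
(heard language, concept) to the heard word at epoch 1 — N/A during picture
naming, where nothing is spoken — and (target language, concept) to the
produced word at epoch 2.  ``visual`` shows the concept's picture at epoch 1
and N/A at epoch 2.  ``feedback`` is neutral at epoch 1; at epoch 2 it is
positive when heard and target language match for naming or repetition,
positive when they differ for translation, and negative otherwise.

Columns of the auditory-stream and evaluative modalities carry calibrated
sensory noise (a per-modality probability floor): the language-identity
channel is deliberately coarse — a prosodic cue, not a transcript — while
audition discriminates words sharply and vision identifies the concept.
These floors are free parameters of the model (the published account of this
paradigm specifies the mapping rules but not likelihood sharpness); the
defaults here are the committed calibration under which an intact agent is at
ceiling and a precision-lesioned agent reproduces the alternate-antagonism /
paradoxical-translation recovery pattern.

The environment (generative process) is the deterministic, un-noised,
un-lesioned counterpart of the same rules: it emits true outcomes and
evaluates feedback from true states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .engine import (
    Factor,
    GenerativeModel,
    InvalidInputError,
    Modality,
    ObservationSet,
    floor_distribution,
)

__all__ = [
    "CONTEXTS",
    "LANGUAGES",
    "CONCEPTS",
    "DEFAULT_VOCABULARY",
    "DEFAULT_SENSORY_NOISE",
    "DEFAULT_PREFERENCES",
    "Vocabulary",
    "TrialSetup",
    "word_for",
    "build_specs",
    "build_likelihood",
    "build_transitions",
    "build_priors_and_preferences",
    "build_policies",
    "build_task_model",
    "required_language",
    "true_feedback",
    "environment_step",
]

CONTEXTS = ("naming", "repetition", "translation")
LANGUAGES = ("L1", "L2")
CONCEPTS = (
    "man", "girl", "baby", "ring", "scarf", "hat",
    "cat", "dog", "parrot", "leaflet", "book", "newspaper",
)
NA = "N/A"
FEEDBACK_LEVELS = ("neutral", "positive", "negative")

# Default word forms: L1 French, L2 English (L1 'man' -> 'homme').
_FRENCH = (
    "homme", "fille", "l'enfant", "bague", "écharpe", "chapeau",
    "chatte", "chienne", "perroquet", "brochure", "livre", "la feuille",
)
_ENGLISH = CONCEPTS

DEFAULT_VOCABULARY: dict[tuple[str, str], str] = {}
for _c, _f, _e in zip(CONCEPTS, _FRENCH, _ENGLISH):
    DEFAULT_VOCABULARY[(_c, "L1")] = _f
    DEFAULT_VOCABULARY[(_c, "L2")] = _e

# Calibrated per-modality sensory-noise floors (see module docstring and the
# methods note).  Values are the floor applied to every likelihood column of
# that modality before renormalisation.
DEFAULT_SENSORY_NOISE: dict[str, float] = {
    "task": 1e-8,
    "language": 0.60,
    "audition": 0.12,
    "visual": 1e-8,
    "feedback": 0.10,
}

# Log-preferences over feedback outcomes (neutral, positive, negative), nats.
# Success is preferred, failure strongly avoided, and an uninformative
# (neutral) evaluation sits close to success: the agent fears being wrong far
# more than it fears learning nothing.
DEFAULT_PREFERENCES: tuple[float, float, float] = (2.0, 3.0, -6.0)


class Vocabulary:
    """Bijective mapping (concept, language) -> word, 12 x 2 entries."""

    def __init__(self, words: Mapping[tuple[str, str], str] | None = None):
        words = dict(DEFAULT_VOCABULARY if words is None else words)
        expected = {(c, l) for c in CONCEPTS for l in LANGUAGES}
        if set(words) != expected:
            raise InvalidInputError("vocabulary must cover every (concept, language) pair")
        if len(set(words.values())) != len(words):
            raise InvalidInputError("vocabulary words must be distinct")
        self._words = words
        # word level order: concept-major, language-minor; N/A last
        self.word_levels: tuple[str, ...] = tuple(
            words[(c, l)] for c in CONCEPTS for l in LANGUAGES
        ) + (NA,)

    def word(self, concept: str, language: str) -> str:
        try:
            return self._words[(concept, language)]
        except KeyError:
            raise InvalidInputError(f"unknown (concept, language) pair ({concept!r}, {language!r})") from None

    def items(self):
        return self._words.items()


def word_for(concept: str, language: str, vocabulary: Vocabulary | None = None) -> str:
    """The word naming ``concept`` in ``language`` under ``vocabulary``."""
    vocab = vocabulary or Vocabulary()
    return vocab.word(concept, language)


@dataclass(frozen=True)
class TrialSetup:
    """The environment's true trial states plus bookkeeping indices."""

    context: str
    heard_language: str
    concept: str
    block: int = 0
    day: int = 1

    def __post_init__(self):
        if self.context not in CONTEXTS:
            raise InvalidInputError(f"unknown context {self.context!r}")
        if self.heard_language not in LANGUAGES:
            raise InvalidInputError(f"unknown language {self.heard_language!r}")
        if self.concept not in CONCEPTS:
            raise InvalidInputError(f"unknown concept {self.concept!r}")


# ---------------------------------------------------------------------------
# Model construction
# ---------------------------------------------------------------------------

def build_specs(vocabulary: Vocabulary | None = None) -> tuple[tuple[Factor, ...], tuple[Modality, ...]]:
    """Factor and modality specifications (five of each)."""
    vocab = vocabulary or Vocabulary()
    factors = (
        Factor("context", CONTEXTS),
        Factor("heard", LANGUAGES),
        Factor("target", LANGUAGES),
        Factor("concept", CONCEPTS),
        Factor("epoch", ("1", "2")),
    )
    modalities = (
        Modality("task", CONTEXTS),
        Modality("language", LANGUAGES),
        Modality("audition", vocab.word_levels),          # 24 words + N/A
        Modality("visual", CONCEPTS + (NA,)),             # 12 pictures + N/A
        Modality("feedback", FEEDBACK_LEVELS),
    )
    return factors, modalities


def _deterministic_outcome(
    modality: str,
    vocab: Vocabulary,
    context: str,
    heard: str,
    target: str,
    concept: str,
    epoch: int,
) -> str:
    """The single outcome the intact rules emit for one joint state.

    ``epoch`` is 0-based (0 = stimulus, 1 = response/feedback).
    """
    if modality == "task":
        return context
    if modality == "language":
        return heard if epoch == 0 else target
    if modality == "audition":
        if epoch == 0:
            return NA if context == "naming" else vocab.word(concept, heard)
        return vocab.word(concept, target)
    if modality == "visual":
        return concept if epoch == 0 else NA
    if modality == "feedback":
        if epoch == 0:
            return "neutral"
        if context == "translation":
            return "positive" if heard != target else "negative"
        return "positive" if heard == target else "negative"
    raise InvalidInputError(f"unknown modality {modality!r}")


def build_likelihood(
    factors: tuple[Factor, ...],
    modalities: tuple[Modality, ...],
    vocabulary: Vocabulary | None = None,
    sensory_noise: Mapping[str, float] | None = None,
) -> dict[str, np.ndarray]:
    """Per-modality likelihood tensors implementing the task rules.

    Each column is the deterministic rule outcome floored at that modality's
    sensory-noise level and renormalised.
    """
    vocab = vocabulary or Vocabulary()
    noise = dict(DEFAULT_SENSORY_NOISE)
    if sensory_noise:
        noise.update(sensory_noise)
    state_shape = tuple(f.n for f in factors)
    likelihoods: dict[str, np.ndarray] = {}
    for m in modalities:
        A = np.zeros((m.n, *state_shape))
        for ci, context in enumerate(CONTEXTS):
            for hi, heard in enumerate(LANGUAGES):
                for ti, target in enumerate(LANGUAGES):
                    for ki, concept in enumerate(CONCEPTS):
                        for ei in range(2):
                            out = _deterministic_outcome(
                                m.name, vocab, context, heard, target, concept, ei
                            )
                            A[m.index(out), ci, hi, ti, ki, ei] = 1.0
        likelihoods[m.name] = floor_distribution(A, floor=noise[m.name], axis=0)
    return likelihoods


def build_transitions(factors: tuple[Factor, ...]) -> dict[str, np.ndarray]:
    """Per-factor transition tensors.

    Context, heard language and concept persist (identity).  The target
    language has two actions, each mapping every previous level to the chosen
    language.  The epoch advances 1 -> 2 with 2 absorbing.
    """
    B: dict[str, np.ndarray] = {}
    for f in factors:
        if f.name == "target":
            T = np.zeros((f.n, f.n, f.n))
            for a in range(f.n):
                T[a, :, a] = 1.0
            B[f.name] = T
        elif f.name == "epoch":
            T = np.zeros((2, 2, 1))
            T[1, 0, 0] = 1.0
            T[1, 1, 0] = 1.0
            B[f.name] = T
        else:
            B[f.name] = np.eye(f.n)[:, :, None]
    return B


def build_priors_and_preferences(
    factors: tuple[Factor, ...],
    modalities: tuple[Modality, ...],
    preference_config: tuple[float, float, float] | None = None,
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    """Initial-state priors D and outcome log-preferences C.

    The agent starts each trial certain it is at epoch 1 and uninformed about
    everything else.  Preferences are non-zero only on the feedback modality:
    (neutral, positive, negative) log-preferences in nats.
    """
    prefs = DEFAULT_PREFERENCES if preference_config is None else tuple(preference_config)
    D: dict[str, np.ndarray] = {}
    for f in factors:
        if f.name == "epoch":
            D[f.name] = floor_distribution(np.array([1.0, 0.0]))
        else:
            D[f.name] = np.full(f.n, 1.0 / f.n)
    C: dict[str, np.ndarray] = {m.name: np.zeros(m.n) for m in modalities}
    C["feedback"] = np.asarray(prefs, dtype=float)
    return D, C


def build_policies() -> tuple[Mapping[str, int], ...]:
    """The two one-step policies: speak L1, speak L2."""
    return ({"target": 0}, {"target": 1})


def build_task_model(
    vocabulary: Vocabulary | None = None,
    sensory_noise: Mapping[str, float] | None = None,
    preferences: tuple[float, float, float] | None = None,
) -> GenerativeModel:
    """Assemble the complete agent-side generative model."""
    vocab = vocabulary or Vocabulary()
    factors, modalities = build_specs(vocab)
    return GenerativeModel(
        factors=factors,
        modalities=modalities,
        likelihoods=build_likelihood(factors, modalities, vocab, sensory_noise),
        transitions=build_transitions(factors),
        initial_priors=build_priors_and_preferences(factors, modalities, preferences)[0],
        preferences=build_priors_and_preferences(factors, modalities, preferences)[1],
        policies=build_policies(),
        horizon=2,
    )


# ---------------------------------------------------------------------------
# Environment (generative process)
# ---------------------------------------------------------------------------

def required_language(context: str, heard_language: str) -> str:
    """The response language the task demands."""
    if context == "translation":
        return "L2" if heard_language == "L1" else "L1"
    return heard_language


def true_feedback(context: str, heard_language: str, spoken_language: str) -> str:
    """Evaluation of a response, from true states (the four feedback rules)."""
    if context == "translation":
        return "positive" if spoken_language != heard_language else "negative"
    return "positive" if spoken_language == heard_language else "negative"


def environment_step(
    setup: TrialSetup,
    epoch: int,
    agent_action: str | None = None,
    vocabulary: Vocabulary | None = None,
) -> dict[str, str]:
    """Outcomes the environment emits at ``epoch`` (0-based).

    Emission follows the intact deterministic rules applied to the true
    states; the lesion never touches the environment.  At epoch 1 the true
    target language is the language of the agent's chosen action
    (``agent_action``, "L1" or "L2").
    """
    vocab = vocabulary or Vocabulary()
    if epoch == 0:
        obs = {
            "task": setup.context,
            "language": setup.heard_language,
            "visual": setup.concept,
            "feedback": "neutral",
        }
        if setup.context == "naming":
            obs["audition"] = NA
        else:
            obs["audition"] = vocab.word(setup.concept, setup.heard_language)
        return obs
    if agent_action not in LANGUAGES:
        raise InvalidInputError("epoch 2 requires the agent's chosen language")
    return {
        "task": setup.context,
        "language": agent_action,
        "audition": vocab.word(setup.concept, agent_action),
        "visual": NA,
        "feedback": true_feedback(setup.context, setup.heard_language, agent_action),
    }


def observations_for_trial(
    model: GenerativeModel,
    setup: TrialSetup,
    *,
    upto_epoch: int,
    agent_action: str | None = None,
    vocabulary: Vocabulary | None = None,
) -> ObservationSet:
    """Bundle environment emissions up to ``upto_epoch`` (inclusive, 0-based)."""
    obs = ObservationSet(model)
    for t in range(upto_epoch + 1):
        emitted = environment_step(setup, t, agent_action, vocabulary)
        for mod, level in emitted.items():
            obs.observe(t, mod, level)
    return obs
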