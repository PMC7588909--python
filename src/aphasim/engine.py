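"""Generic discrete active-inference machinery.

This module implements belief updating and policy selection for categorical
POMDP generative models of the kind used throughout the discrete
active-inference literature.  A model consists of

* hidden-state *factors* (independent latent dimensions, each categorical),
* outcome *modalities* (independent observation channels, each categorical),
* a likelihood tensor ``A`` per modality mapping the joint hidden state to a
  distribution over that modality's outcome levels,
* an action-conditioned transition tensor ``B`` per factor,
* an initial-state prior ``D`` per factor,
* a log-preference vector ``C`` per modality, and
* a set of policies (one action per controllable factor per step).

Perception is variational: posteriors over factor states at each epoch are
obtained by coordinate-wise mean-field updates that monotonically decrease
variational free energy ``F = complexity - accuracy``.  Action is selected by
scoring each policy's expected free energy ``G = risk + ambiguity`` for the
predicted future and passing ``-(F + G)`` through a precision-weighted
softmax.

Exhaustive-enumeration oracles (:func:`enumerate_exact_posterior`,
:func:`efe_bruteforce`) are provided for testing only; they compute exact
posteriors and expected free energies by summing over the full joint state
space.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "PROB_FLOOR",
    "MAX_ITERATIONS",
    "CONVERGENCE_TOL",
    "DEFAULT_POLICY_PRECISION",
    "InvalidInputError",
    "Factor",
    "Modality",
    "GenerativeModel",
    "ObservationSet",
    "BeliefState",
    "PolicyEvaluation",
    "softmax",
    "kl_divergence",
    "free_energy",
    "infer_states",
    "expected_free_energy",
    "policy_posterior",
    "select_action",
    "enumerate_exact_posterior",
    "efe_bruteforce",
]

# Numerical defaults.  The probability floor is applied to every stored
# distribution before a logarithm is ever taken; it also makes the
# unit-precision lesion an exact identity on the stored representation.
PROB_FLOOR = 1e-8
MAX_ITERATIONS = 16
CONVERGENCE_TOL = 1e-4
DESCENT_TOL = 1e-6
DEFAULT_POLICY_PRECISION = 16.0

NOT_OBSERVED = -1


class InvalidInputError(ValueError):
    """Raised when an operation receives malformed probabilistic input."""


def _as_prob_vector(x, name: str) -> np.ndarray:
    v = np.asarray(x, dtype=float)
    if v.ndim != 1 or v.size == 0:
        raise InvalidInputError(f"{name} must be a non-empty 1-D vector")
    if not np.all(np.isfinite(v)):
        raise InvalidInputError(f"{name} contains non-finite values")
    return v


def floor_distribution(p: np.ndarray, floor: float = PROB_FLOOR, axis: int = 0) -> np.ndarray:
    """Floor entries of a (column-)stochastic array at ``floor`` and renormalise."""
    q = np.maximum(np.asarray(p, dtype=float), floor)
    return q / q.sum(axis=axis, keepdims=True)


def softmax(values, temperature_scale: float = 1.0) -> np.ndarray:
    """Convert real values into probabilities that sum to one.

    ``temperature_scale`` multiplies the inputs before exponentiation (an
    inverse temperature); the output is invariant to adding a constant to all
    inputs.
    """
    v = _as_prob_vector(values, "softmax input")
    if not (np.isfinite(temperature_scale) and temperature_scale > 0):
        raise InvalidInputError("temperature_scale must be a positive real")
    x = temperature_scale * v
    x = x - x.max()
    e = np.exp(x)
    return e / e.sum()


def kl_divergence(q, p) -> float:
    """Kullback-Leibler divergence ``KL(q || p)`` in nats.

    Zeros in either argument are floored (at :data:`PROB_FLOOR`) and the
    vectors renormalised, so the divergence is always finite.
    """
    qv = _as_prob_vector(q, "q")
    pv = _as_prob_vector(p, "p")
    if qv.shape != pv.shape:
        raise InvalidInputError("q and p must have the same length")
    for v, name in ((qv, "q"), (pv, "p")):
        if abs(v.sum() - 1.0) > 1e-6:
            raise InvalidInputError(f"{name} must sum to 1")
    qf = floor_distribution(qv)
    pf = floor_distribution(pv)
    return float(np.sum(qf * (np.log(qf) - np.log(pf))))


@dataclass(frozen=True)
class Factor:
    """A named hidden-state factor with ordered, named levels."""

    name: str
    levels: tuple[str, ...]

    def __post_init__(self):
        if len(set(self.levels)) != len(self.levels):
            raise InvalidInputError(f"factor {self.name}: level names must be unique")

    @property
    def n(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise InvalidInputError(f"factor {self.name}: unknown level {level!r}") from None


@dataclass(frozen=True)
class Modality:
    """A named outcome modality with ordered, named levels."""

    name: str
    levels: tuple[str, ...]

    @property
    def n(self) -> int:
        return len(self.levels)

    def index(self, level: str) -> int:
        try:
            return self.levels.index(level)
        except ValueError:
            raise InvalidInputError(f"modality {self.name}: unknown level {level!r}") from None


@dataclass
class GenerativeModel:
    """A categorical POMDP generative model.

    Attributes
    ----------
    factors, modalities
        Ordered specifications of the hidden-state factors and outcome
        modalities.
    likelihoods
        One tensor per modality, shape ``(n_outcomes, *state_shape)``; each
        column (fixed joint state) is a distribution over outcome levels.
    transitions
        One tensor per factor, shape ``(n_next, n_prev, n_actions)``; factors
        without actions have a single implicit action.
    initial_priors
        One probability vector per factor (beliefs about the initial state).
    preferences
        One log-preference vector per modality over outcome levels.
    policies
        Each policy maps controllable factor names to an action index; one
        action per step (one-step policies repeat their action if the horizon
        exceeds two epochs).
    horizon
        Number of epochs per trial.
    """

    factors: tuple[Factor, ...]
    modalities: tuple[Modality, ...]
    likelihoods: dict[str, np.ndarray]
    transitions: dict[str, np.ndarray]
    initial_priors: dict[str, np.ndarray]
    preferences: dict[str, np.ndarray]
    policies: tuple[Mapping[str, int], ...]
    horizon: int = 2

    def __post_init__(self):
        self.validate()

    # -- structure helpers -------------------------------------------------
    @property
    def state_shape(self) -> tuple[int, ...]:
        return tuple(f.n for f in self.factors)

    @property
    def n_joint_states(self) -> int:
        return int(np.prod(self.state_shape))

    def factor(self, name: str) -> Factor:
        for f in self.factors:
            if f.name == name:
                return f
        raise InvalidInputError(f"unknown factor {name!r}")

    def modality(self, name: str) -> Modality:
        for m in self.modalities:
            if m.name == name:
                return m
        raise InvalidInputError(f"unknown modality {name!r}")

    def factor_index(self, name: str) -> int:
        return [f.name for f in self.factors].index(name)

    def action_for(self, policy: Mapping[str, int], factor: Factor) -> int:
        """Action index this policy assigns to ``factor`` (0 if uncontrolled)."""
        return int(policy.get(factor.name, 0))

    def validate(self, tol: float = 1e-10) -> None:
        if not self.policies:
            raise InvalidInputError("policy list is empty")
        for m in self.modalities:
            A = self.likelihoods[m.name]
            if A.shape != (m.n, *self.state_shape):
                raise InvalidInputError(f"likelihood {m.name}: bad shape {A.shape}")
            if not np.allclose(A.sum(axis=0), 1.0, atol=tol):
                raise InvalidInputError(f"likelihood {m.name}: columns must sum to 1")
        for f in self.factors:
            B = self.transitions[f.name]
            if B.ndim != 3 or B.shape[0] != f.n or B.shape[1] != f.n:
                raise InvalidInputError(f"transition {f.name}: bad shape {B.shape}")
            if not np.allclose(B.sum(axis=0), 1.0, atol=tol):
                raise InvalidInputError(f"transition {f.name}: columns must sum to 1")
            D = self.initial_priors[f.name]
            if D.shape != (f.n,) or abs(D.sum() - 1.0) > tol:
                raise InvalidInputError(f"initial prior {f.name}: must sum to 1")
        for p in self.policies:
            for fname, a in p.items():
                B = self.transitions[fname]
                if not (0 <= a < B.shape[2]):
                    raise InvalidInputError(f"policy action {a} invalid for factor {fname}")

    def copy(self) -> "GenerativeModel":
        return GenerativeModel(
            factors=self.factors,
            modalities=self.modalities,
            likelihoods={k: v.copy() for k, v in self.likelihoods.items()},
            transitions={k: v.copy() for k, v in self.transitions.items()},
            initial_priors={k: v.copy() for k, v in self.initial_priors.items()},
            preferences={k: v.copy() for k, v in self.preferences.items()},
            policies=self.policies,
            horizon=self.horizon,
        )

    def equals(self, other: "GenerativeModel") -> bool:
        return (
            self.factors == other.factors
            and self.modalities == other.modalities
            and all(np.array_equal(self.likelihoods[m.name], other.likelihoods[m.name]) for m in self.modalities)
            and all(np.array_equal(self.transitions[f.name], other.transitions[f.name]) for f in self.factors)
            and all(np.array_equal(self.initial_priors[f.name], other.initial_priors[f.name]) for f in self.factors)
        )


class ObservationSet:
    """Observed outcome levels per modality per epoch.

    Unobserved (future, or genuinely absent) entries hold the distinguished
    marker :data:`NOT_OBSERVED`.
    """

    def __init__(self, model: GenerativeModel, horizon: int | None = None):
        self._model = model
        T = model.horizon if horizon is None else horizon
        self.horizon = T
        self._obs = np.full((T, len(model.modalities)), NOT_OBSERVED, dtype=int)

    def observe(self, epoch: int, modality: str, level: str | int) -> "ObservationSet":
        m = self._model.modality(modality)
        idx = m.index(level) if isinstance(level, str) else int(level)
        if not (0 <= idx < m.n):
            raise InvalidInputError(f"observation {idx} invalid for modality {modality}")
        mi = [mm.name for mm in self._model.modalities].index(modality)
        self._obs[epoch, mi] = idx
        return self

    def get(self, epoch: int, modality: str) -> int:
        mi = [mm.name for mm in self._model.modalities].index(modality)
        return int(self._obs[epoch, mi])

    def is_observed(self, epoch: int, modality: str) -> bool:
        return self.get(epoch, modality) != NOT_OBSERVED

    def observed_epochs(self) -> list[int]:
        return [t for t in range(self.horizon) if np.any(self._obs[t] != NOT_OBSERVED)]

    def as_dict(self) -> dict[int, dict[str, int]]:
        out: dict[int, dict[str, int]] = {}
        for t in range(self.horizon):
            row = {
                m.name: int(self._obs[t, i])
                for i, m in enumerate(self._model.modalities)
                if self._obs[t, i] != NOT_OBSERVED
            }
            if row:
                out[t] = row
        return out


@dataclass
class BeliefState:
    """Mean-field posterior expectations for one policy.

    ``posteriors[factor][epoch]`` is a probability vector over that factor's
    levels.  ``iteration_trace`` holds the variational free energy after each
    sweep of coordinate updates; it is non-increasing.
    """

    posteriors: dict[str, np.ndarray]  # factor -> (T, n_levels)
    iteration_trace: list[float]
    converged: bool

    def marginal(self, factor: str, epoch: int) -> np.ndarray:
        return self.posteriors[factor][epoch]


@dataclass
class PolicyEvaluation:
    """Free energies and the resulting posterior over policies."""

    free_energy_per_policy: np.ndarray
    expected_free_energy_per_policy: np.ndarray
    risk_per_policy: np.ndarray
    ambiguity_per_policy: np.ndarray
    policy_posterior: np.ndarray


# ---------------------------------------------------------------------------
# Free energy (joint-state form, used directly in tests and by the oracles)
# ---------------------------------------------------------------------------

def free_energy(q, prior, likelihood_for_observation) -> float:
    """Variational free energy of a joint-state posterior (Eq. ``F = complexity - accuracy``).

    Parameters are flat vectors over the same joint state space: a posterior
    ``q``, a prior, and the likelihood column ``P(o | s)`` of the observed
    outcome evaluated at every joint state.  Returns ``KL(q || prior) -
    E_q[ln P(o | s)]`` in nats, an upper bound on ``-ln P(o)``.
    """
    qv = _as_prob_vector(q, "q")
    pv = _as_prob_vector(prior, "prior")
    lv = np.asarray(likelihood_for_observation, dtype=float)
    if qv.shape != pv.shape or qv.shape != lv.shape:
        raise InvalidInputError("q, prior and likelihood must share one joint state space")
    for v, name in ((qv, "q"), (pv, "prior")):
        if abs(v.sum() - 1.0) > 1e-6:
            raise InvalidInputError(f"{name} must be normalised")
    complexity = kl_divergence(qv, pv)
    accuracy = float(np.sum(floor_distribution(qv) * np.log(np.maximum(lv, PROB_FLOOR))))
    return complexity - accuracy


# ---------------------------------------------------------------------------
# Mean-field state inference
# ---------------------------------------------------------------------------

def _ln(a: np.ndarray) -> np.ndarray:
    return np.log(np.maximum(a, PROB_FLOOR))


def _outcome_message(lnA_o: np.ndarray, qs: list[np.ndarray], target: int) -> np.ndarray:
    """Contract ``ln A[o]`` with every factor's posterior except ``target``."""
    letters = "abcdefghij"[: lnA_o.ndim]
    operands: list[np.ndarray] = [lnA_o]
    subs = [letters]
    for i, q in enumerate(qs):
        if i != target:
            operands.append(q)
            subs.append(letters[i])
    return np.einsum(",".join(subs) + "->" + letters[target], *operands)


def _expect_all(tensor: np.ndarray, qs: list[np.ndarray]) -> float:
    letters = "abcdefghij"[: tensor.ndim]
    subs = [letters] + [letters[i] for i in range(len(qs))]
    return float(np.einsum(",".join(subs) + "->", tensor, *qs))


def _model_free_energy(
    model: GenerativeModel,
    obs: ObservationSet,
    policy: Mapping[str, int],
    q: dict[str, np.ndarray],
    T_inf: int,
) -> float:
    """Variational free energy of a factorised posterior over the inferred epochs."""
    F = 0.0
    names = [f.name for f in model.factors]
    for f in model.factors:
        for t in range(T_inf):
            qt = q[f.name][t]
            F += float(np.sum(qt * _ln(qt)))  # negative entropy
        F -= float(np.sum(q[f.name][0] * _ln(model.initial_priors[f.name])))
        B = model.transitions[f.name]
        a = model.action_for(policy, f)
        lnB = _ln(floor_distribution(B[:, :, a], axis=0))
        for t in range(1, T_inf):
            F -= float(q[f.name][t] @ lnB @ q[f.name][t - 1])
    for t in range(T_inf):
        for m in model.modalities:
            if obs.is_observed(t, m.name):
                o = obs.get(t, m.name)
                lnA_o = _ln(model.likelihoods[m.name][o])
                F -= _expect_all(lnA_o, [q[n][t] for n in names])
    return F


def infer_states(
    model: GenerativeModel,
    observations: ObservationSet,
    policy: Mapping[str, int],
    *,
    max_iterations: int = MAX_ITERATIONS,
    tol: float = CONVERGENCE_TOL,
) -> BeliefState:
    """Mean-field variational inference of hidden states under one policy.

    Posteriors are factorised over factors and epochs.  Inference runs over
    the epochs carrying observed evidence: each sweep performs sequential
    coordinate updates (softmax of summed log-messages from observed
    outcomes, the forward transition message and — between inferred epochs —
    the backward transition message), which cannot increase the free energy
    recorded in ``iteration_trace``.  Epochs beyond the last observation hold
    no evidence and are filled in afterwards as forward predictions under the
    policy (exact smoothing assigns them no backward influence).  Iteration
    stops when the largest absolute belief change falls below ``tol`` or
    after ``max_iterations`` sweeps; failure to converge is flagged, never
    fatal.
    """
    T = observations.horizon
    names = [f.name for f in model.factors]
    observed = observations.observed_epochs()
    T_inf = (max(observed) + 1) if observed else 1

    q: dict[str, np.ndarray] = {}
    for f in model.factors:
        q[f.name] = np.tile(np.full(f.n, 1.0 / f.n), (T, 1))

    lnD = {f.name: _ln(model.initial_priors[f.name]) for f in model.factors}
    B_act = {}
    lnB = {}
    for f in model.factors:
        a = model.action_for(policy, f)
        B_act[f.name] = floor_distribution(model.transitions[f.name][:, :, a], axis=0)
        lnB[f.name] = _ln(B_act[f.name])
    lnA_obs: dict[tuple[int, str], np.ndarray] = {}
    for t in range(T_inf):
        for m in model.modalities:
            if observations.is_observed(t, m.name):
                o = observations.get(t, m.name)
                lnA_obs[(t, m.name)] = _ln(model.likelihoods[m.name][o])

    trace: list[float] = [_model_free_energy(model, observations, policy, q, T_inf)]
    converged = False
    for _ in range(max_iterations):
        delta = 0.0
        for t in range(T_inf):
            for fi, f in enumerate(model.factors):
                v = np.zeros(f.n)
                if t == 0:
                    v += lnD[f.name]
                else:
                    v += lnB[f.name] @ q[f.name][t - 1]
                if t + 1 < T_inf:
                    v += q[f.name][t + 1] @ lnB[f.name]
                for m in model.modalities:
                    key = (t, m.name)
                    if key in lnA_obs:
                        v += _outcome_message(lnA_obs[key], [q[n][t] for n in names], fi)
                new = softmax(v)
                delta = max(delta, float(np.max(np.abs(new - q[f.name][t]))))
                q[f.name][t] = new
        trace.append(_model_free_energy(model, observations, policy, q, T_inf))
        if delta < tol:
            converged = True
            break

    # forward predictions for epochs with no evidence yet
    for t in range(T_inf, T):
        for f in model.factors:
            q[f.name][t] = B_act[f.name] @ q[f.name][t - 1]

    return BeliefState(posteriors=q, iteration_trace=trace, converged=converged)


# ---------------------------------------------------------------------------
# Expected free energy and policy selection
# ---------------------------------------------------------------------------

def _predicted_outcomes(model: GenerativeModel, modality: str, qs: list[np.ndarray]) -> np.ndarray:
    A = model.likelihoods[modality]
    letters = "abcdefghij"[: A.ndim - 1]
    subs = ["z" + letters] + [letters[i] for i in range(len(qs))]
    return np.einsum(",".join(subs) + "->z", A, *qs)


def expected_free_energy(
    model: GenerativeModel,
    belief: BeliefState,
    policy: Mapping[str, int],
    future_epoch: int = 1,
    *,
    risk_over_states: bool = False,
) -> tuple[float, float, float]:
    """Expected free energy ``G = risk + ambiguity`` of one policy's future.

    Ambiguity is the expected conditional entropy of outcomes given states,
    summed over modalities.  Risk, by default, is the divergence between each
    modality's predicted outcome distribution and the preference distribution
    (softmax of that modality's log-preferences), summed over modalities.  A
    literal state-space risk variant — the divergence between the predicted
    state distribution and the policy-averaged prior propagated from the
    initial-state beliefs — is available via ``risk_over_states``.
    """
    names = [f.name for f in model.factors]
    qs = [belief.posteriors[n][future_epoch] for n in names]

    ambiguity = 0.0
    risk = 0.0
    for m in model.modalities:
        A = model.likelihoods[m.name]
        H_cols = -np.sum(A * _ln(A), axis=0)  # conditional entropy per joint state
        ambiguity += _expect_all(H_cols, qs)
        if not risk_over_states:
            qo = _predicted_outcomes(model, m.name, qs)
            risk += kl_divergence(qo, softmax(model.preferences[m.name]))
    if risk_over_states:
        for f in model.factors:
            B = model.transitions[f.name]
            Bavg = B.mean(axis=2)
            prior_t = model.initial_priors[f.name]
            for _ in range(future_epoch):
                prior_t = Bavg @ prior_t
            risk += kl_divergence(belief.posteriors[f.name][future_epoch], prior_t)
    return risk + ambiguity, risk, ambiguity


def policy_posterior(F, G, policy_precision: float = DEFAULT_POLICY_PRECISION) -> np.ndarray:
    """Posterior over policies: softmax of ``-γ (F + G)``."""
    Fv = _as_prob_vector(F, "F")
    Gv = _as_prob_vector(G, "G")
    if Fv.shape != Gv.shape:
        raise InvalidInputError("F and G must have one entry per policy")
    return softmax(-(Fv + Gv), temperature_scale=policy_precision)


def evaluate_policies(
    model: GenerativeModel,
    observations: ObservationSet,
    *,
    policy_precision: float = DEFAULT_POLICY_PRECISION,
    future_epoch: int = 1,
    risk_over_states: bool = False,
) -> tuple[PolicyEvaluation, list[BeliefState]]:
    """Infer states under each policy and score the policy set."""
    beliefs: list[BeliefState] = []
    F = np.zeros(len(model.policies))
    G = np.zeros(len(model.policies))
    risk = np.zeros(len(model.policies))
    amb = np.zeros(len(model.policies))
    for i, pol in enumerate(model.policies):
        b = infer_states(model, observations, pol)
        beliefs.append(b)
        F[i] = b.iteration_trace[-1]
        G[i], risk[i], amb[i] = expected_free_energy(
            model, b, pol, future_epoch, risk_over_states=risk_over_states
        )
    post = policy_posterior(F, G, policy_precision)
    return PolicyEvaluation(F, G, risk, amb, post), beliefs


def select_action(
    posterior,
    policies: Sequence[Mapping[str, int]],
    epoch: int = 0,
    *,
    mode: str = "deterministic",
    rng: np.random.Generator | None = None,
) -> Mapping[str, int]:
    """Pick a policy (and hence an action per controllable factor).

    Deterministic mode takes the maximum-probability policy, breaking ties by
    lowest policy index; sampling mode draws from the posterior using the
    supplied seeded generator.
    """
    post = _as_prob_vector(posterior, "policy posterior")
    if abs(post.sum() - 1.0) > 1e-6:
        raise InvalidInputError("policy posterior must sum to 1")
    if mode == "deterministic":
        idx = int(np.argmax(post))  # argmax returns the lowest index on ties
    elif mode == "sampling":
        if rng is None:
            raise InvalidInputError("sampling mode requires a random generator")
        idx = int(rng.choice(len(post), p=post / post.sum()))
    else:
        raise InvalidInputError(f"unknown action-selection mode {mode!r}")
    return policies[idx]


# ---------------------------------------------------------------------------
# Exhaustive-enumeration test oracles
# ---------------------------------------------------------------------------

MAX_ORACLE_STATES = 10_000


def enumerate_exact_posterior(
    model: GenerativeModel,
    observations: ObservationSet,
    action_sequence: Sequence[Mapping[str, int]] | Mapping[str, int],
):
    """Exact joint posterior over state trajectories by full enumeration.

    Sums the complete joint distribution of the generative model over every
    state trajectory, conditioned on the observed outcomes.  Returns a dict
    with the flattened joint posterior over trajectories, per-factor marginals
    at every epoch, and the exact log evidence.  Refuses joint state spaces
    larger than ``10**4`` per epoch.
    """
    if model.n_joint_states > MAX_ORACLE_STATES:
        raise InvalidInputError("joint state space too large for enumeration")
    T = observations.horizon
    if isinstance(action_sequence, Mapping):
        action_sequence = [action_sequence] * (T - 1)
    names = [f.name for f in model.factors]
    shape = model.state_shape

    # log-likelihood of the observed outcomes at each epoch, per joint state
    logL = [np.zeros(shape) for _ in range(T)]
    for t in range(T):
        for m in model.modalities:
            if observations.is_observed(t, m.name):
                o = observations.get(t, m.name)
                logL[t] += _ln(model.likelihoods[m.name][o])

    n = model.n_joint_states
    logD = np.zeros(shape)
    for i, f in enumerate(model.factors):
        logD = logD + _ln(model.initial_priors[f.name]).reshape(
            [f.n if j == i else 1 for j in range(len(shape))]
        )

    # joint over trajectories, built epoch by epoch (log domain, flattened);
    # log_traj has shape (n,) * t after processing epoch t-1
    log_traj = (logD + logL[0]).reshape(n)
    for t in range(1, T):
        pol = action_sequence[t - 1]
        # joint transition = Kronecker product of per-factor transitions
        mats = []
        for f in model.factors:
            a = model.action_for(pol, f)
            mats.append(floor_distribution(model.transitions[f.name][:, :, a], axis=0))
        Bjoint = mats[0]
        for M in mats[1:]:
            Bjoint = np.kron(Bjoint, M)
        # new[(s_0..s_{t-1}, s_t)] = old[(s_0..s_{t-1})] + ln B[s_t, s_{t-1}] + ln L_t[s_t]
        log_step = np.log(np.maximum(Bjoint, PROB_FLOOR)) + logL[t].reshape(n)[:, None]
        log_traj = log_traj[..., None] + np.moveaxis(log_step, 0, -1)

    mx = log_traj.max()
    traj = np.exp(log_traj - mx)
    Z = traj.sum()
    log_evidence = float(mx + np.log(Z))
    traj = traj / Z

    marginals: dict[str, np.ndarray] = {f.name: np.zeros((T, f.n)) for f in model.factors}
    for t in range(T):
        axes = tuple(i for i in range(T) if i != t)
        epoch_marg = traj.sum(axis=axes) if axes else traj
        epoch_marg = epoch_marg.reshape(shape)
        for i, f in enumerate(model.factors):
            other = tuple(j for j in range(len(shape)) if j != i)
            marginals[f.name][t] = epoch_marg.sum(axis=other)
    return {
        "joint": traj,
        "marginals": marginals,
        "log_evidence": log_evidence,
    }


def efe_bruteforce(model: GenerativeModel, state_posterior: Mapping[str, np.ndarray], preferences=None):
    """Expected free energy by explicit enumeration of state-outcome pairs.

    ``state_posterior`` maps factor names to probability vectors for the
    future epoch.  Returns ``(G, risk, ambiguity)`` computed with plain Python
    loops; intended only as a test oracle on small models.
    """
    prefs = preferences if preferences is not None else model.preferences
    names = [f.name for f in model.factors]
    joints = []
    for combo in itertools.product(*[range(f.n) for f in model.factors]):
        p = 1.0
        for i, f in enumerate(model.factors):
            p *= float(state_posterior[f.name][combo[i]])
        joints.append((combo, p))

    ambiguity = 0.0
    risk = 0.0
    for m in model.modalities:
        A = model.likelihoods[m.name]
        qo = np.zeros(m.n)
        for combo, p in joints:
            col = A[(slice(None), *combo)]
            h = 0.0
            for po in col:
                h -= po * math.log(max(po, PROB_FLOOR))
            ambiguity += p * h
            qo += p * col
        pref = softmax(np.asarray(prefs[m.name], dtype=float))
        risk += kl_divergence(qo / qo.sum(), pref)
    return risk + ambiguity, risk, ambiguity
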