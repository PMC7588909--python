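# Methods

## The generative model

The subject's model of a testing session is a two-epoch categorical POMDP.
Epoch 1 is stimulus presentation; epoch 2 is response and evaluation, and is
absorbing. Hidden states factorise into task context (naming / repetition /
translation), heard language (L1/L2), target language (L1/L2), concept (12
items) and epoch. Outcomes factorise into five channels: task identity,
language identity of the current auditory stream, the heard/spoken word
(24 words + N/A), the picture (12 + N/A) and evaluative feedback
(neutral / positive / negative).

The likelihood rules are deterministic at core: the task channel reports the
context; the language channel reports the heard language at epoch 1 and the
spoken language at epoch 2; audition maps (heard language, concept) to the
heard word at epoch 1 — N/A during naming, where nothing is spoken — and
(target language, concept) to the produced word at epoch 2; vision shows the
concept's picture at epoch 1 and N/A afterwards; feedback is neutral at
epoch 1 and, at epoch 2, positive when heard and target language match for
naming/repetition, positive when they differ for translation, and negative
otherwise. Context, heard language and concept persist (identity
transitions); the epoch advances 1 → 2; the target language is the one
controllable factor, with two actions that each force it to a specific
language regardless of its previous state. The policy set contains exactly
the two corresponding one-step policies.

Each deterministic likelihood column is floored at a per-modality sensory
noise level and renormalised. These floors are free parameters — the mapping
rules say nothing about channel sharpness — and they are scientifically
meaningful: vision and task instructions are treated as essentially
noiseless (floor 1e-8), word identity is sharp but not perfect
(audition 0.12), and the *language-identity* channel is deliberately coarse
(0.60): it stands for prosodic/phonotactic cues to which language is being
spoken, not a transcript. Feedback carries floor 0.10.

The environment (generative process) applies the same rules, un-noised and
never lesioned, to the true trial states, and evaluates feedback from true
states and the agent's chosen reply language. With deterministic action
selection the environment is fully deterministic given the item sequence;
seeds enter only through item sampling (and through action sampling if the
stochastic selection mode is chosen).

## Inference and action

Perception is mean-field variational inference: posteriors factorise over
factors and epochs, and sequential coordinate updates (softmax of summed
log-messages from observed outcomes plus forward and backward transition
messages) monotonically decrease the variational free energy
F = complexity − accuracy. Updates run to convergence (max-abs belief change
< 1e-4) or 16 sweeps; non-convergence is flagged, never fatal. All stored
distributions are floored at 1e-8 before logarithms.

One numerical point deserves emphasis. Epochs that carry no observed
evidence are excluded from the variational sweep and filled in as forward
predictions under the policy. Exact smoothing assigns an unobserved future
no backward influence, but a naive mean-field backward message through a
floored identity transition is strongly self-reinforcing (the floor turns
ln B into ±18 logits) and drives posteriors to saturation. Restricting
inference to observed epochs removes the artifact, keeps epoch-1 marginals
within ~1e-9 total variation of exhaustive enumeration on the 288-state
task model, and makes per-policy F identical at epoch 1, as it should be —
policies differ only in their predicted futures.

Policies are scored by expected free energy G = risk + ambiguity at the
future epoch. Risk is, by default, the divergence between predicted outcomes
and the preference distribution σ(C) summed over modalities (outcome-risk);
a literal state-space risk variant is available behind a switch
(`risk_over_states`), using the policy-averaged propagated prior as the
reference, but the task defines preferences only over outcomes, so the
outcome form is the committed default. The policy posterior is
σ(−γ(F + G)) with policy precision γ = 16; the default action rule is the
posterior mode with lowest-index tie-breaking (a sampling mode exists for
stochastic experiments). Log-preferences live on feedback alone:
(neutral, positive, negative) = (2, 3, −6) nats. Success is preferred,
failure is strongly avoided, and a *neutral or uninformative* evaluation is
nearly as acceptable as success — the agent fears being wrong far more than
it fears learning nothing. This asymmetry is load-bearing (below).

## The lesion

A lesion is the pair (ω, target). For every targeted likelihood column c,
the agent's model is rebuilt with normalise(exp(ω·ln c)): a temperature-like
flattening that preserves within-column ordering, leaves ω = 1 bitwise
intact, and tends to the uniform distribution as ω → 0. Columns are
targeted by the affected language: epoch-1 columns through their
heard-language index (processing what is heard), epoch-2 columns through
their target-language index (predicting the consequences of speaking). The
committed targeted modalities are audition, language and feedback — the
full auditory-evaluative stream for one language. Narrower loci (audition
only, language only, audition+language) are selectable; with feedback
excluded the paradoxical-translation component of the pattern does not
arise under any noise/preference setting we explored, because outcome risk
then always favours the objectively correct reply whenever heard-language
beliefs lean the right way, and ambiguity only ever pushes *away* from the
affected language.

The default nine-day schedule alternates the affected language daily (odd
days L1, even days L2) and steps ω through 0.1, 0.1, 0.1, 0.1, 0.25, 0.25,
0.5, 0.5, 1 — saturation to full precision on the final day. A "slow"
preset stretches the same staircase over three-day plateaus, emulating the
same recovery at a slower timescale. Only the agent's model is lesioned;
the environment, and hence every emitted outcome under matched seeds, is
identical across subjects.

## Why the pattern emerges

Three forces, all consequences of the single precision manipulation,
produce the clinical pattern on a strongly lesioned day (affected language
ℓ, ω = 0.1):

1. **Degraded but truthful word evidence.** Hearing a word in ℓ still
   favours "heard = ℓ" (words are mutually exclusive across languages), but
   the flattened columns reduce the posterior to roughly 0.55–0.65 —
   genuine uncertainty rather than misbelief.
2. **Silence inverts.** In naming trials nothing is heard (audition N/A).
   The N/A outcome is far better explained by the *intact* ear than by the
   flattened one, so the posterior flips toward "heard = the other
   language". The agent concludes the trial is in the unaffected language
   and replies there: naming in ℓ fails, naming in the other language is
   untouched.
3. **Blunted evaluation makes the affected language the safe bet.**
   Flattened feedback columns for *speaking* ℓ make that reply's predicted
   evaluation nearly flat (~⅓ negative), while the intact alternative is a
   sharp gamble whose negative mass is the heard-language uncertainty
   (~0.4 from force 1). Under preferences that punish failure far more than
   uncertainty, the blunted option wins. For repetition the blunted option
   *is* the correct reply (repeat in ℓ): repetition stays intact. For
   translation out of ℓ the blunted option is the wrong reply: the subject
   answers in ℓ and fails — exactly translation into the accessible
   language. Translation into ℓ is driven by near-certain evidence from the
   intact stimulus language and succeeds.

Jointly: the accessible naming language alternates with the lesion side
(alternate antagonism), translation fails exactly into the accessible
language with repetition spared (paradoxical translation), and the ω = 1
day is bit-identical to control.

## Calibration

The free parameters — per-modality noise floors and feedback preferences —
were calibrated jointly by grid search against qualitative constraints
only: intact agent correct on all 72 (task, language, concept) cases;
at ω = 0.1 the failing cells are exactly naming-in-ℓ and translation-from-ℓ
for either ℓ; repetition correct at every ω; no failures at ω = 1. The
committed point (audition 0.12, language 0.60, feedback 0.10, preferences
(2, 3, −6), γ = 16) maximises the minimum decision margin across all cells,
ω levels and lesion sides (min |ΔG| ≈ 0.42 nats); 44 of 54 neighbouring
grid points satisfy all constraints, so the configuration is a region, not
a knife-edge. No per-day score was targeted during calibration.

## What the simulation does and does not emulate

The paradigm generator emulates a fixed clinical testing routine: six
blocks per day in a fixed order (naming L1, repetition L1, translation from
L1, then the L2 mirror), five items per block drawn uniformly without
replacement from the twelve-concept corpus, per-day seeded streams shared
between subjects. It does not emulate: lexical frequency or
concept-difficulty effects (feedback scores language choice only, not word
retrieval); phonological or acoustic word structure; more than two
languages; within-day fatigue or order effects; or learning between trials
(the model has no parameter updating by design — each trial starts from the
same priors). Passing tests therefore demonstrate the control-theoretic
account of the recovery pattern under these idealised conditions, not a fit
to any individual patient's trajectory; the real case reports evolve over
weeks with graded scores, which the deterministic default reproduces only
at the level of the qualitative pattern flags.

## Numerical choices and degenerate inputs

Probability floor 1e-8 on every stored distribution (also what makes the
ω = 1 lesion an exact identity); convergence tolerance 1e-4 on beliefs,
descent asserted to 1e-6 per sweep; KL and free-energy helpers floor and
renormalise their arguments, so zeros are handled without infinities;
policy ties break to the lowest index for reproducibility; empty block
lists yield empty (zero-trial) results; an items-per-block above twelve,
non-positive ω, inconsistent able/unable thresholds and unknown
configuration keys raise validation errors naming the offending field. The
exhaustive-enumeration oracles refuse joint state spaces above 10⁴ states
per epoch (the task model has 288).

## Known limitations

Mean-field inference over two fully-observed epochs shows the usual
winner-take-all tendency of factorised posteriors with near-deterministic
couplings; two-epoch marginals agree with exact enumeration to ~0.007 total
variation on the task model, comfortably within the 0.05 envelope asserted
by the tests but not exact. The deterministic action rule makes per-cell
scores 0 or 5; graded day-by-day trajectories require the sampling mode
with a finite policy precision. The lesion schedule is imposed, not
emergent: precision recovery is modelled as an exogenous staircase rather
than inferred by a higher hierarchical level.
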