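# aphasim

Active-inference simulation of recovery patterns in bilingual aphasia.

Bilingual speakers recovering from brain injury sometimes show a striking
pattern: on one day they can name pictures only in one language (say L1), the
next day only in the other (*alternate antagonism*), and on any given day
they cannot translate **into** the language they can name in, yet translate
fluently into the language they cannot use (*paradoxical translation*) —
while word repetition stays intact in both languages. Such a pattern rules
out destruction of either language network and points instead at a failure
of *control* over intact networks.

`aphasim` reproduces this phenomenology in silico. A synthetic subject
performs picture naming, word repetition and word translation under a
discrete (categorical POMDP) generative model, with perception implemented
as variational free-energy minimisation and action selection by expected
free energy. A "lesion" is a drop in the sensory precision hyperparameter ω
applied to the likelihood mapping **A** — the agent's sensory channels are
left structurally intact but become unreliable for one language at a time.
A matched-seed control subject runs on identical random streams, so every
behavioural difference is attributable to the lesion alone.

The package is for computational neuropsychologists and active-inference
researchers who want a compact, fully-tested discrete active-inference
engine together with a worked, calibrated lesion study.

## Model

The generative model factorises over hidden-state factors and outcome
modalities:

    P(o, s, π) = P(π) Π_τ  Π_m P(o_τ^m | s_τ)  Π_f P(s_τ^f | s_{τ-1}^f, π)

* five factors: task context (3), heard language (2), target language (2,
  the single controllable factor), concept (12), trial epoch (2);
* five modalities: task (3), language (2), audition (24 words + N/A),
  visual (12 pictures + N/A), feedback (neutral/positive/negative);
* likelihood tensors **A** (one per modality), action-conditioned
  transitions **B** (one per factor), initial priors **D**, log-preferences
  **C** (non-zero only on feedback), and two one-step policies — *speak L1*,
  *speak L2*.

Perception minimises variational free energy

    F = KL[Q(s) || P(s)] − E_Q[ln P(o | s)]        (complexity − accuracy)

by mean-field coordinate updates; policies are scored by expected free
energy

    G(π) = risk(π) + ambiguity(π)

(risk: divergence of predicted outcomes from the preference distribution
σ(**C**); ambiguity: expected conditional entropy of outcomes), and actions
follow σ(−γ(F + G)). The in-silico lesion raises targeted likelihood
columns to the power ω < 1 and renormalises, flattening the mapping from
causes to sensations for the affected language; ω = 1 is an exact identity.

## Worked example

Run the default nine-day study (six blocks × five items per day; precision
staircase 0.1, 0.1, 0.1, 0.1, 0.25, 0.25, 0.5, 0.5, 1 with the affected
language alternating daily) and summarise it:

```
$ aphasim run --seed 1 --out results
$ aphasim report results
subject control: 100% correct overall
...
subject lesioned: 78% correct overall
task     naming    repetition    translation
language     L1 L2         L1 L2          L1 L2
day
1             0  5          5  5           0  5
2             5  0          5  5           5  0
3             0  5          5  5           0  5
4             5  0          5  5           5  0
5             0  5          5  5           5  5
...
9             5  5          5  5           5  5
```

Reading day 1 (L1-side lesion): naming in L1 fails outright while naming in
L2 is perfect; repetition is at ceiling in both languages; translation
*from* L1 (i.e. **into** the accessible language L2) fails while translation
into the inaccessible L1 is perfect. Day 2 mirrors the pattern. The
classifier makes the clinical reading explicit:

```
$ aphasim classify results
  "lesioned": { "alternate_antagonism": true,
                "paradoxical_translation": true,
                "paradoxical_days": [1, 2, 3, 4],
                "repetition_intact": true, ... }
```

The control subject's flags are false/false, its score 100%, and the
lesioned subject's final (recovered, ω = 1) day equals the control day
cell-for-cell. `aphasim trace results --day 1` shows the per-epoch belief
rasters behind any trial. The same functionality is available in-process
via `aphasim.build_task_model`, `aphasim.run_study`,
`aphasim.classify_pattern` and friends.

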