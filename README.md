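# inquiryflow

Multi-level process mining for event logs from simulation-based
scientific-inquiry tasks.

Structured inquiry simulations — here, a *Hydroelectric Power Plant* task in
which students manipulate a gate position (Low/Medium/High) and an inlet
diameter (40/80/120 cm) to find the fastest rotation speed under a 400 rpm
safety limit — log every interface action with a timestamp. `inquiryflow`
turns those raw logs into a multi-level account of how students inquire and
how that relates to performance. It is written for researchers in
educational measurement and learning analytics who want the whole chain —
from raw events to publishable statistics — as reusable, tested library
code, with a built-in agent simulator so every stage can be exercised (and
validated against known ground truth) without access to classroom data.

## What it computes

**Coding.** Raw events are recoded into eight micro-level behaviors
(Adjust Gate, Adjust Diameter, Run Trial, Initial Answer, Revise Answer,
Remove Record, Start Task, End Task); contiguous answer-element edits
collapse into single answer episodes, the first coded Initial Answer and
later ones Revise Answer. Micro codes aggregate many-to-one into six
macro-level inquiry phases (START, DESIGN, CONDUCT, ANSWER, MANAGE, END).
Cohen's κ is provided for validating alternative coders.

**Performance subgroups.** Effectiveness is dichotomous task correctness
(submitting the unique constrained-optimum triple). Efficiency is latent:
univariate Gaussian mixtures with K = 1..4 components are EM-fitted to
completion time within each effectiveness group, the minimum-BIC model is
selected, and the smaller-mean component is the Efficient profile. A
behavioral proxy — PDR, the share of Adjust Diameter → Run Trial
transitions — plus median/tertile sensitivity splits check the robustness
of the split.

**Macro analytics.** Per-behavior Poisson GLMs with a log link, a group
indicator and log sequence length as exposure offset yield incidence rate
ratios (IRR = e^β) with HC3-robust Wald CIs and Benjamini–Hochberg
adjustment; positionwise state distributions (BLANK-padded) give the
classic sequence-distribution plot; and a SPADE-style miner enumerates
gap-tolerant subsequences of length 2–4 with support ≥ 0.30 in at least
one group, Wilson 95% CIs, and two-proportion z tests.

**Micro dynamics.** Per-student normalized Shannon entropy
H = −Σᵢ pᵢ log₂ pᵢ / log₂ 8 summarizes behavioral diversity (bootstrap CIs,
two-way ANOVA with partial η²). First-order Markov process models estimate
P(t|s) = count(s,t)/Σ count(s,·), shrunk toward a pooled global prior by a
hierarchical Dirichlet–multinomial posterior mean with concentration
α = 0.5. Efficiency contrasts are *delta probability maps* (Efficient minus
Inefficient) with 1000-resample bootstrap CIs; process graphs keep edges
with Pr ≥ 0.30 and export to DOT/JSON.

**Simulation.** Agents are stationary first-order Markov chains over the
eight micro behaviors, with task-grammar-aware sampling (no deleting from
an empty Data Panel, no ending with a blank answer) and per-student
completion times drawn from profile-level log-normal distributions. Four
built-in profiles realize the 2×2 effectiveness × efficiency design with
labeled ground truth.

## Worked example

```python
import numpy as np
from inquiryflow import agent, coding, profiles, macro, micro
from inquiryflow.events import group_by_student

presets = agent.builtin_profiles()
spec = agent.CohortSpec(
    profiles=[(presets["effective_efficient"], 72),
              (presets["effective_inefficient"], 14),
              (presets["ineffective_efficient"], 151),
              (presets["ineffective_inefficient"], 22)],
    seed=0,
)
events, labels = agent.generate_cohort(spec)
per_student = list(group_by_student(events))
coded = coding.code_cohort(per_student)

answers = {sid: coding.extract_final_answer(log) for sid, log in per_student}
assignments, fits = profiles.assign_subgroups(coded, answers, seed=0)

eff_map = dict(zip(assignments.student_id, assignments.effectiveness))
rates = macro.rate_comparison([s.macro for s in coded],
                              [eff_map[s.student_id] for s in coded],
                              reference="Ineffective")
```

Output of the session above (formatted prints):

```
259 students, 3456 events, 32.4% correct
Effective group: K=2 by BIC, component means [ 78.6 178.2] s, mean max posterior 0.95
DESIGN rate, Effective vs Ineffective: IRR=1.15 [1.03, 1.28], p_fdr=0.013
<DESIGN, CONDUCT>: support 1.00 vs 0.77, p_fdr=3.3e-06
Effective group delta map: 9 significant cells; largest |delta| = 0.49
```

Reading the numbers: about a third of the simulated cohort finds the
optimal condition; within the correct solvers the completion-time mixture
resolves into a fast (~79 s) and a slow (~178 s) profile with high
assignment certainty; effective students design experiments at a higher
per-step rate (IRR > 1); the design→conduct subsequence is near-universal
among effective students; and the efficiency profiles differ significantly
in how they route transitions around the experimentation backbone.

The same chain runs from the shell:

```bash
inquiryflow all --seed 0 --out out/demo      # simulate → code → profile → macro → micro
inquiryflow simulate --seed 0 --out out/logs # just the synthetic cohort
```

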