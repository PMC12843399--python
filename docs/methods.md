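# Methods

This note documents the models, parameter choices, and numerical decisions
behind `inquiryflow`, and what its synthetic-data generator does and does
not emulate.

## Task model

The simulated task is a two-factor optimization: gate position
(Low < Medium < High) × inlet diameter (40 < 80 < 120 cm), each trial
returning a rotation speed from a fixed 3×3 outcome table, with a safety
limit of 400 rpm. Three cells anchor the problem structure: the unique
constrained optimum Medium/120 = 309 rpm, the over-limit cell
High/120 = 438 rpm, and the next-best safe cell High/80 = 292 rpm. The
remaining six cells (76, 124, 208 / 118, 196 / 163 for Low/Medium/High at
40–120 cm) were chosen to satisfy two structural constraints: rpm strictly
increases along both factor orderings (the qualitative priors the task
states), and every non-optimal safe cell stays below 309 rpm so the
optimum is unique and the decisive comparison involves exactly the three
anchor cells. `validate_table` re-checks both constraints for any
user-supplied table. An answer scores 1 only if gate, diameter and the
exact integer rpm of the optimum cell are all given; rpm is compared
exactly because the interface displays exact trial values.

## Behavior coding

Raw events map 1:1 onto micro codes except answer-element edits: a
*maximal run of consecutive edit events* is one answer episode, the first
per student coded Initial Answer and all later ones Revise Answer.
Contiguity is the episode boundary — an edit run interrupted by any
non-answer event starts a new episode; a pause alone does not. A later
episode counts as Revise Answer whether or not the stored value actually
changed, since logs need not carry old values. Completion time is
t(end) − t(start). The implications: coded sequences begin with Start Task
and end with End Task exactly once, macro sequences are the deterministic
image of micro sequences, and recoding a coded sequence's reconstructed
event stream is idempotent (all tested).

Cohen's κ (via scikit-learn, with percent agreement) is included as a
utility for validating alternative coder implementations against fixtures,
not as a re-run of any human coding study.

## Agent simulator

Each agent follows a stationary first-order Markov chain over the eight
micro behaviors; a profile is (transition matrix, dwell parameters, answer
policy, max steps). Sampling masks contextually invalid moves and
renormalizes the row: Remove Record is unavailable while the Data Panel is
empty, answer codes are positional (an Initial Answer proposed after an
answer exists is emitted as Revise Answer, and vice versa; two answer
episodes never abut, since the coder would merge them), and a proposed End
Task before any answer forces an answer episode first — the interface
prompt that blocks incomplete submissions. Trial payloads carry the true
outcome-table rpm at the agent's current settings; deletions target
existing rows; the first answer episode edits all three elements. The
final episode submits the optimum triple with probability `answer_policy`,
otherwise a uniformly chosen non-optimal safe cell, which makes
effectiveness rates controllable (the default cohort realizes ≈33%
correct). A walk exceeding `max_steps` raises a generation error naming
the profile.

**Completion-time model.** Each student's total completion time is drawn
from a profile-level log-normal; per-event log-normal dwells (with
per-behavior relative scales — trials slow, answer edits fast) are then
rescaled to sum to that draw, so timestamps remain cumulative sums of
sampled dwells. The student-level draw exists because free-running i.i.d.
dwell sums inherit the geometric tail of the chain's path length,
producing completion-time spreads several times wider than behavioral data
show and defeating mixture-based efficiency profiling; treating overall
pace as a student trait separates time-on-task from step count and yields
per-profile time distributions with realistic means *and* spreads
(efficient ≈ 81 s and 62 s, inefficient ≈ 197 s and 144 s within the
effective/ineffective levels respectively).

**Built-in profiles.** The four presets realize the 2×2 design
qualitatively: effective profiles cycle design→conduct iteratively before
committing (mean coded length ≈ 12 for the efficient, ≈ 21 for the
inefficient variant) and submit the optimum with probability ≥ 0.95; the
ineffective-efficient profile opens with an immediate answer (its Start
Task row is dominated by Initial Answer) and stays short (≈ 8); the
ineffective-inefficient profile explores in a poorly structured way with
heavy diameter cycling. The effective-efficient preset is deliberately
*repair-free* — its structure (answer at step one, revision/end mass only
afterwards, Remove Record reachable only after Run Trial) guarantees the
grammar masks never fire, so coded transition frequencies converge to the
profile matrix and ground-truth parameter recovery is testable (sup-norm
error ≈ 0.03 at 200 students). Profiles that emulate answer-late behavior
(e.g. the effective-inefficient preset starting with a default trial) do
trigger positional relabeling, so their coded frequencies are close to but
not identical with the raw matrix; quantitative recovery tests therefore
use repair-free matrices.

**What the generator does not emulate.** Agents do not learn or adapt
(stationarity is by design, matching the first-order analysis model);
dwell times are exchangeable within student rather than autocorrelated;
answer content before the final episode is a simple current-settings
guess. Passing tests therefore certify the analysis chain under the
assumed data-generating model, not the behavior of real students.

## Efficiency profiling

Gaussian mixtures are fitted to raw completion seconds (not log seconds)
within each effectiveness group, K = 1..4, using scikit-learn's EM with a
deterministic initialization: quantile-based means, pooled variance, equal
weights. For K > 1 a second, *nested* initialization (the (K−1)-component
solution plus a 2%-weight component at the 98th percentile) is also run
and the higher-likelihood fit kept; this keeps log-likelihood non-
decreasing in K, which quantile-only initialization does not guarantee.
Degenerate EM runs are retried up to three times with jittered means. The
regularization floor scales with the sample variance (1e-6 · var), making
labels invariant to the time unit. BIC = −2 logL + (3K−1) ln n selects K;
students are assigned by maximum posterior; the smaller-mean component is
Efficient. With the subgroup-like mixture 0.84·N(81, 28²) + 0.16·N(183, 55²)
at n = 86, the dominant fast component is recovered within ±15 s, but the
14-student slow component's MLE has a sampling SD near 34 s (measured by
replicate simulation), so tests bound it accordingly — a genuine
small-sample property of the estimator, not an implementation artifact.

PDR uses all consecutive pairs as its denominator (the plainest reading of
"proportion of Adjust Diameter → Run Trial transitions"); the alternative
denominator (pairs leaving Adjust Diameter only) was considered and
rejected as a less direct reading. The validation regression puts PDR on
z-scored log time plus a correctness indicator via OLS. Quantile
sensitivity splits assign cut-point ties to the faster side,
deterministically.

## Macro analytics

Rate comparison fits one Poisson GLM per behavior: count ~ group with
offset log(sequence length), HC3 sandwich covariance for Wald CIs, and
Benjamini–Hochberg adjustment across the modeled behaviors. Behaviors with
zero count variance (START and END, structurally constant at 1) are
skipped; a behavior absent in exactly one group is fitted but flagged as a
boundary estimate. In the saturated two-group case the IRR equals the
ratio of pooled rates, which the tests exploit as a closed-form oracle.

The miner enumerates order-preserving, gap-tolerant subsequences (no
maxgap/mingap constraints, single-event items) level-wise over the
6-symbol alphabet up to length 4, pruning by the anti-monotone maximum
group support; a pattern counts at most once per student (student-level
Bernoulli support). This direct enumeration is exact — with 6 states and
max length 4 there are only 1,554 possible patterns, so no ID-list or
lattice machinery is warranted. Each candidate gets Wilson 95% score
intervals per group (clamped to bracket the point estimate against ~1e-17
floating spill), a pooled two-proportion z test, and BH adjustment over
the candidate set; retention requires the support threshold and adjusted
p < 0.05. A support threshold of zero is refused outright. Reported
supports round half-up to two decimals in the CSV artifacts.

State distributions right-pad sequences with a BLANK filler to the cohort
maximum length; each position's proportions sum to one and render as a
stacked-area plot.

## Micro dynamics

Entropy is computed over the fixed 8-code alphabet with 0·log 0 = 0 and
normalized by log₂ 8 = 3 bits. Subgroup means carry percentile bootstrap
CIs (2000 resamples, students resampled within subgroup); the two-way
ANOVA uses Type II sums of squares — appropriate for the unbalanced 2×2 —
with partial η² = SS_effect/(SS_effect + SS_error). An empty or singleton
cell refuses the ANOVA but still reports means.

Transition estimation excludes End Task as a source and Start Task as a
target (structural zeros from the grammar). The smoothed estimate is the
Dirichlet–multinomial posterior mean with total per-row prior mass
α = 0.5 split proportionally to the pooled global row,
(count + α·prior)/(rowsum + α); α → 0 recovers the plain conditional
frequencies and α → ∞ the prior (both tested numerically). α is read as
per-row total mass rather than a per-cell pseudo-count — with a per-cell
reading the effective shrinkage would grow with the alphabet size, which
is not what a single concentration parameter suggests. Rows with no data
and no prior are undefined (NaN) and flagged.

The bootstrap resamples students with replacement independently within
each subgroup (1000 resamples), holding the global prior fixed so the
intervals isolate subgroup sampling variability; percentile 95% intervals
(not BCa) are used, the minimal reading of "bootstrap confidence
interval". Cells whose delta CI excludes zero are flagged significant;
with a +0.3 planted cell at n = 150 per group the flag fires with the
correct sign, and identical subgroups yield exactly zero deltas and no
flags. Process graphs keep edges with Pr ≥ 0.30 by default and serialize
to a minimal DOT dialect and JSON that round-trip to the same edge set.

## Pipeline

One seed drives everything: `numpy.random.SeedSequence(seed).spawn`
derives stable child seeds for simulation, GMM fitting, the entropy
bootstrap, and the transition bootstrap, so stages are reproducible both
in-pipeline and standalone, and identical configs produce byte-identical
text artifacts (fixed column orders, fixed float formatting). The default
configuration mirrors the analysis constants above — support ≥ 0.30,
pattern length ≤ 4, α = 0.5, 2000/1000 bootstrap replicates, edge
threshold 0.30, FDR level 0.05, K ≤ 4, seed 0 — and a 259-student cohort
in the 72/14/151/22 profile mix. Test and demonstration runs use smaller
cohorts (50–60 students) and reduced replicate counts; the acceptance
script uses a 50-student cohort, whose reported quantity is
replicate-independent.

## Known limitations

* First-order stationarity is assumed everywhere — no learning curves,
  higher-order dependence, or semi-Markov dwell modeling.
* The efficiency GMM is univariate by design; no covariance-structured or
  multivariate profiles.
* Small inefficient subgroups (n ≈ 14–22 in the emulated design) make the
  slow mixture component and its delta-map cells intrinsically noisy; the
  bootstrap CIs surface this rather than remove it.
* The miner's exhaustive strategy is exact but exponential in pattern
  length; it is intended for short patterns over small phase alphabets,
  not for event-level mining with large vocabularies.
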