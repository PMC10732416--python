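# Methods

## The task and what the package models

The orthogonalized go/no-go task decouples action from valence: four
fractal cues require either a button press ("go") or withholding
("no-go"), and pay either in the win domain (+1 vs 0) or the avoid domain
(0 vs -1). Feedback is probabilistic — the better outcome follows a
correct response with probability 0.8 and an incorrect response with
probability 0.2. Each task run has 30 trials of each cue type (120 total)
in two 60-trial blocks, with cue order uniformly shuffled over the run and
the cue-to-meaning assignment randomized per subject. In the
working-memory load condition (WMGNG) the same task runs with a concurrent
2-back stream: every trial additionally asks whether the current cue
matches the cue two trials back. The package generates these task
structures, labels the 2-back ground truth (the first two trials of a run
have none), simulates cohorts, fits the model family, and runs the
behavioral and model-derived analyses.

The 2-back stream is generated as ground-truth labels only; 2-back
*responses* are not modeled. The load manipulation enters the models
purely through condition-split parameters, mirroring how this model family
treats dual-task load.

## Generative model

Per cue s, instrumental action values Q(a, s) follow Rescorla-Wagner
updating of the taken action only,

    Q_t(a_t, s_t) = Q_{t-1}(a_t, s_t) + eps * (rho * r_t - Q_{t-1}(a_t, s_t)),

and a Pavlovian stimulus value V(s) follows the same rule on every
presentation of s regardless of the action. Outcomes r in {-1, 0, +1} are
scaled by a valence-specific sensitivity (rho_rew for r = +1, rho_pun for
r = -1; at r = 0 the scaled outcome is zero under either, and by design
win cues never lose and avoid cues never win, so outcome-sign and
cue-valence selection coincide). Action weights add a go bias and the
Pavlovian value weighted by pi to the go side only:

    W(go)   = Q(go, s) + b + pi * V(s),      W(nogo) = Q(nogo, s),

and choice follows a squashed softmax with irreducible noise xi:

    P(go) = logistic(W(go) - W(nogo)) * (1 - xi) + xi / 2.

Q and V start at zero for every cue at the start of each task run. The
tasks use disjoint cue sets, so no latent state carries over between runs;
zero initialization also makes the first trial of a run an analytic
check: P(go) = logistic(b) * (1 - xi) + xi / 2. The sensitivities play
the role of an inverse temperature, so none is included separately. pi
and b are unconstrained reals (negative pi — an anti-Pavlovian coupling —
is allowed); rho_rew and rho_pun are strictly positive; eps and xi live in
[0, 1].

Eight nested variants differ only in which of {pi, eps, xi} get a
free-standing second copy (pi_wm, eps_wm, xi_wm) governing the WMGNG
condition: model 1 none (6 parameters); models 2, 3, 4 split pi, eps, xi
respectively (7); models 5 (pi, eps), 6 (pi, xi), 7 (eps, xi) (8); model 8
all three (9). rho_rew, rho_pun and b are always shared across
conditions. The _wm copies are free-standing values with their own
group-level distributions, not additive offsets.

## Hierarchical estimation

Each parameter is sampled on an unconstrained scale: probit
(standard-normal CDF) for eps and xi, log for the positive sensitivities,
identity for b and pi. Subject-level unconstrained values are exchangeable
draws from group-level normal distributions, written non-centered
(u = mu + sigma * raw with raw ~ N(0,1)) to decorrelate the group
hyperparameters from the subject deviations. Priors are weakly
informative and overridable: group means N(0, 1); group SDs half-normal
with scale 1 for location-type parameters and 0.2 for probit-scale
parameters, whose unconstrained axis spans only a few units.

The sampler is an adaptive Metropolis-within-Gibbs scheme. One iteration
performs two full sweeps; each sweep updates, in turn, every group mean
(Gaussian random walk, full-cohort likelihood), every group SD on the log
scale (half-normal prior plus the log-scale Jacobian), and every
subject-level deviation column (proposals for all subjects at once,
accepted subject-by-subject — valid because subjects are conditionally
independent given the group). Each sweep ends with an
ancillarity-sufficiency interweaving step: holding the subject-level
unconstrained values fixed, the group mean is re-drawn from its conjugate
normal conditional and log sigma gets two Metropolis updates against the
centered conditional, after which the raw deviations are recomputed. The
interweaving costs no likelihood evaluations and removes most of the
autocorrelation in the group hyperparameters that a pure non-centered
random walk leaves behind. Proposal scales adapt toward a 0.44 acceptance
rate in batches of 25 iterations during warm-up only, so retained draws
come from a fixed transition kernel. Chains initialize from moderately
dispersed draws near the prior center, re-drawn (up to 20 times) if the
starting likelihood is non-finite.

The default configuration is four independent chains of 4000 iterations
with 2000 warm-up; the recovery experiments and tests run reduced configs
(typically 4 x 1000 with 500 warm-up, where the full model on a 20-subject
cohort converges with max split R-hat around 1.03-1.07 in about 40 s on
one CPU). Convergence is monitored with the rank-normalized split-chain
R-hat (computed via arviz) for every group mean, group SD, and
subject-level unconstrained parameter; identical constant chains return
1.0 with a warning by convention. The trial-replay likelihood kernel is
JIT-compiled with numba; a scalar pure-Python replay serves as an
independent oracle in the test suite (agreement to 1e-10).

Group-level posteriors are summarized by the median and the 95%
highest-density interval of the transformed group mean; a condition-split
pair is called credibly different when the two 95% HDIs do not overlap.

## Model comparison

Models are compared by LOOIC = -2 * elpd from Pareto-smoothed importance
sampling (arviz), with the **subject** as the pointwise unit: each entry
of the log-likelihood matrix is one subject's total choice log-likelihood
at one retained draw, so LOO approximates leave-one-subject-out
prediction — the natural exchangeable unit of the hierarchy. The standard
error is 2 * sqrt(n * var(elpd_i)); units with Pareto k above 0.7 flag the
estimate as unreliable without suppressing it. Draws are pooled across
chains, with the relative efficiency of importance ratios taken as 1.
Ties in LOOIC break by smaller parameter count, then model id. A
brute-force check in the test suite refits a 3-subject cohort leaving one
subject out at a time and integrates the held-out subject's likelihood
over the group posterior by Monte Carlo; PSIS-LOO agrees within twice its
standard error.

## Behavioral analyses

Correctness is action == required action. Pavlovian-congruent cue types
are go-to-win and no-go-to-avoid; incongruent are no-go-to-win and
go-to-avoid. The Pavlovian bias index is the pooled congruent accuracy
minus the pooled incongruent accuracy, range [-1, 1]. (Summing the two
cue-type accuracies instead of averaging them gives an index on [-2, 2]
that is exactly twice this one at equal trial counts; group values near
0.15 here correspond to ~0.3 on that doubled scale.)

Learning curves index trials by cue presentation (1..30), average
correctness over the four cue types, and smooth with a centered moving
average whose window shrinks symmetrically at the series edges (window 5;
the temporal bias series uses window 3 and additionally reports the
presentation index of the group-mean peak). With the window exceeding the
series, the curve collapses to the global mean. A `trial` x-axis variant
is available as an option.

The choice-randomness analyses replay each subject's observed history at
point parameters (posterior medians of the fitted model; full-posterior
averaging is deliberately not the default, matching the use of posterior
medians as point summaries) to obtain per-trial action weights, then bin
each subject's trials per task into deciles of W_go - W_nogo (go ratio
per bin) and of |W_go - W_nogo| (accuracy per bin). Bins are formed by
stable-sorted position, so counts differ by at most one and tied values
resolve to the lower bin in trial order; edges are computed per subject
per task from that task's own trials, since the tasks are plotted
separately and uncertainty is across subjects. Per-bin GNG-vs-WMGNG
comparisons use classical paired t-tests (Cohen's d = mean/sd of
differences; all-zero differences give t = 0 by convention, constant
nonzero differences are flagged undefined), uncorrected for multiple
comparisons as in the per-quantile analyses this mirrors. The 2x2
repeated-measures ANOVA (action x valence) is computed via pingouin with
generalized eta-squared; zero-variance effects report F = 0.

One-step-ahead prediction conditions each trial's predicted go
probability on the subject's actual history up to the previous trial
(observed actions and outcomes drive the updates) at posterior-median
parameters; predicted accuracy is the predicted probability of the
required action.

## Synthetic cohorts: what they emulate and what they do not

The generator reproduces the study's design — 49 subjects x 2 tasks x 120
trials, 30 per cue type, 80/20 feedback — with choices from the model
itself under heterogeneous subject parameters. Group distributions
(`DEFAULT_GROUP_DISTS`) were calibrated once so a simulated cohort
matches the study's group-level behavior: overall accuracy ~0.80
(control) vs ~0.74 (load), every cue-type accuracy above chance,
congruent well above incongruent, and the load effect carried by a lower
learning rate (~0.27 vs ~0.14) and more irreducible noise (~0.03 vs
~0.12) with the Pavlovian bias unchanged — the study's central pattern.
On the unconstrained scale: eps (-0.6, 0.25), eps_wm (-1.1, 0.25),
rho_rew and rho_pun (1.8, 0.25), b (0.15, 0.25), pi and pi_wm (0.4,
0.25), xi (-1.9, 0.2), xi_wm (-1.2, 0.2).

Because the data are generated by the very model being fitted, passing
recovery and comparison checks demonstrates the pipeline's internal
consistency, not that human behavior follows the model: real data carry
sequential dependencies (fatigue, attention drift), response-time
structure, 2-back engagement varying across subjects, and model
misspecification, none of which the generator emulates. Counterbalanced
task order and the practice block are likewise not modeled; the two task
runs are generated independently per subject.

## Validation experiments and fixed expectations

Parameter recovery simulates a cohort, refits it, and reports Spearman
rank correlation, bias, and RMSE between true and posterior-median
subject-level parameters. Acceptance floors for the rank correlations of
eps, xi, and pi were fixed from three pilot runs (20 subjects, 240 trials
each, 4 chains x 1000/500; seeds and per-seed results recorded in
`config/recovery_expectations.json`) as the observed minimum minus a
noise margin; single-replicate recovery of weakly identified parameters
(notably eps_wm at a low learning rate, and the sensitivities, which
shrink toward the group) fluctuates substantially across seeds, which the
margins absorb. Model recovery simulates from the baseline and the full
model under the default (separated) group distributions, fits both
candidates, and requires the LOOIC winner to match the generator in the
majority of replicates.

Desk-scale problem sizes used throughout (20-subject cohorts, 4 x 1000
iteration chains, 5 recovery replicates) were chosen so the entire
validation suite runs in minutes on a single CPU while leaving the
protocol-scale configuration one argument away.

## Known limitations

* Random-walk MCMC needs the interweaving step and moderate dimension
  (~200 here) to mix well; much larger cohorts would warrant a
  gradient-based sampler.
* PSIS-LOO with subjects as units has only n_subjects pointwise terms, so
  LOOIC standard errors are coarse for small cohorts, and leaving out a
  whole 240-trial subject strains the importance weights — high Pareto-k
  flags are common and reported rather than suppressed. Model rankings in
  the recovery experiments are nevertheless stable, with LOOIC gaps far
  exceeding their standard errors.
* The 2-back accuracy exclusion screen used in the original study (cutoff
  0.575) is an analysis of 2-back responses, which are not modeled; the
  cutoff derivation is ambiguous (a one-sided binomial test at n = 120
  does not land exactly there), so no exclusion logic is implemented and
  any cutoff would enter as configuration.
* Uniform cue shuffling is unconstrained (no maximum run length), as no
  constraint is documented for the task.
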