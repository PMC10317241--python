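# Methods

## Model

The agent performs exact Bayesian inference in a switching observation model.
Contexts are a finite, fixed set; the agent assumes a Markov chain over them
with self-transition probability `p_self` and uniform off-diagonal mass
`(1 - p_self)/(N - 1)`. Contextual cues, when the task provides them, are
categorical symbols that match the true context with probability `1 - η` and
any other symbol with probability `η/(N - 1)`; the agent's cue model uses the
same symmetric parameterization, and by default the environment's and agent's
η are matched (a single "cue uncertainty" knob). An absent cue is equivalent
to a maximally uncertain one: the cue factor becomes uniform.

Each context `j` carries a Normal-Gamma belief `(μ_j, ν_j, α_j, β_j)` over
its scalar adaptation state. The quantity `β_j/α_j` is treated throughout as
the belief's expected observation standard deviation. The per-trial loop is:

1. cue → cue factor `p(ζ|q)`;
2. predictive context distribution
   `normalize(p(ζ|q) ⊙ Kᵀ · posterior_{t-1})` with `K` the transition matrix;
3. action `u_t = Σ_j p_j μ_j` under the *predictive* probabilities, executed
   with motor noise `σ_u`;
4. observed error `e_t` scored per context as a Gaussian with mean
   `μ_j − u_t` and standard deviation
   `σ_pred = sqrt(σ_r² + σ_u² + σ_x²)`;
5. posterior (responsibilities) ∝ predictive ⊙ likelihood, computed in log
   space;
6. every belief absorbs `s_t = e_t + u_t` with fractional weight equal to its
   responsibility (the four conjugate update lines in the README).

This ordering — action before same-trial feedback — is what produces the
one-trial switching lag in uncued designs, while a reliable cue (step 1)
switches the predictive distribution, and hence the action, on the switch
trial itself.

### The state-uncertainty term σ_x

`σ_x` is the uncertainty of the state *estimate*, not of single
observations. The default convention shrinks the observation scale by the
belief's pseudo-count, `σ_x = (β/α)/√ν`, so a well-practised context makes
sharp predictions while a fresh one is forgiving. The un-shrunk alternative
`σ_x = β/α` is exposed as `AgentConfig.sigma_x_mode = "expected-sd"`; it
makes adaptation contexts permanently tolerant and weakens switch detection.

### Learning weights vs action weights

Action selection uses the predictive probabilities (feedback of trial `t`
cannot influence `u_t`); belief updates use the full posterior after the
trial's feedback. The pooled predicted error `Σ_j p_j (μ_j − u_t)` is
available from the trace as a diagnostic, but inference is driven by the
per-context likelihoods.

### Degenerate posteriors

If the observed error is so far from every context's prediction that all log
densities are `-inf`, the posterior falls back to the predictive vector and a
warning is logged with the trial index. A cue that assigns zero probability
to every context with prior support raises an error instead — that is a
mis-specified model, not an unlucky observation.

## Environment simulator

The environment is the experiment script, not a second inference model: the
true context sequence is fixed by the block design (the Markov chain is the
agent's assumption only, since all simulated studies use fixed block
structures). Per trial the observed error is
`x*_ζ + ε_a − u_exec + ν_obs`, with trial-to-trial adaptation noise
`ε_a ~ N(0, σ_a)` and true observation noise `ν_obs ~ N(0, σ*_r)`; the sign
convention (error = adaptation − compensation) makes a fully adapted agent
produce zero-mean errors. Error-clamp trials return exactly 0 regardless of
the command; inside adaptation blocks a clamp fraction `f` converts exactly
`round(f·n)` trials (round half away from zero) at uniformly sampled
positions. Clamp trials keep the block's true context for bookkeeping.

What the simulator does *not* emulate: movement kinematics (only a scalar
per-trial error), error compounding across movements (the compounding term is
zero in all shipped paradigms), within-trial corrections, and reward
feedback. Passing tests therefore speak to trial-level error dynamics, not to
trajectory-level phenomena.

## Randomness and reproducibility

One root seed per batch; each run draws a child seed, and each run derives
four independent streams (clamp placement, cue emission, environment noise,
motor noise), so ablating one noise source leaves the other streams' draws
unchanged. Environment noise draws are consumed even on clamp trials so that
flipping a clamp flag does not shift later draws. Trace CSVs are written with
17 significant digits and re-read with round-trip float parsing, making
write → read → aggregate bit-exact.

## Shipped study configurations

Task and agent parameter values follow those used in prior simulation work
on these experimental designs; where a value is ambiguous or a design detail
is unreported, the choice below was made once and is exposed as an ordinary
config field:

- **Adaptation noise σ_a per study**: Kim = 0.01, Oh = 0.5 (the
  rotation-noise SD those designs used), Davidson = 1, Vaswani = 0.1 — the
  assignment consistent with each task's units.
- **fig2_grid** uses the curl-force (Davidson) column with two contexts
  (0, 4), a naive adaptation prior, blocks 20 + 10 (switch back to baseline
  at trial 20), 50 runs, η ∈ {0, 0.33}, agent σ_r ∈ {0.5, 2}.
- **kim2015**: three contexts (0, +40, −40) deg, deterministic cues; prior
  means (0, +1, −1) seed learning toward the respective rotation signs;
  twelve 50-trial blocks cycling O–A–O–B (exact block lengths for this study
  are unreported; regular alternation matches the original design).
- **oh2019_exp1/exp2**: two contexts (0, 20) or (0, 10) deg, no cues,
  p_self = 0.98, blocks O20–A60–O20–A20–O20–A20, 11 runs. Switch metrics are
  taken over the switches after the initial 60-trial learning block.
- **davidson2004**: pre-adapted three-context curl-force groups
  (0, 4, −4) vs (0, 4, 12), blocks A60–B60–A60, 32 runs/group. Pre-adaptation
  sets the prior means to the true values (with the default pseudo-counts;
  belief mass then consolidates during the first two blocks). Variants:
  (0, 4, −8) vs (0, 4, 16) (doubled separation) and two-context
  no-baseline versions — dropping the baseline from the agent also drops it
  from the task list, which is behaviourally identical since the baseline is
  never scheduled in this design.
- **vaswani2013**: p_self = 0.8, pre-adapted groups
  (A)–E, O–(A)–E, (−A/2)–(A)–E, (−A)–E with 100-trial adaptation blocks
  (20% interleaved clamp trials) and 100 clamp trials; 6 runs/group
  (block lengths are estimates; the original study's exact counts were not
  used).

## Metric conventions

- `switch_lag`: trials after a true switch until `u_t` crosses half (by
  default) of the old→new adaptation distance; a never-crossing trace yields
  a `"no-switch"` sentinel distinct from any integer.
- `trials_to_plateau`: first trial (1-based within the block) at which the
  inferred state enters and *remains* within a 10% band of the true value
  through block end. Runs whose state exits the band near block end count as
  not plateaued and are excluded from the mean (they are reported separately);
  with the grid's σ_a = 1 this affects roughly a tenth of runs.
- `trials_to_posterior_threshold`: trials after a switch until the true
  context's posterior exceeds 0.9; censored at block length when averaging.
- Cross-run SEM is the sample standard deviation (ddof = 1) over runs divided
  by √n; a single run reports SEM 0 by convention.

## Known limitations

- The number of contexts is fixed; there is no online creation of new
  contexts, and no inference of `p_self` or of the cue matrix.
- No intrinsic memory decay: all decay-like behaviour is produced by context
  inference, which is the point of the model — but it means phenomena that
  require genuine forgetting are out of reach.
- Group-level predictions with 6-run groups are noisy: individual runs can
  de-adapt abruptly when the baseline context takes over early in a clamp
  block, so group comparisons in the tests average over several replications
  of the whole experiment rather than a single 6-run batch.
- The between-group gap in the doubled-separation variant of the post-switch
  asymmetry is small in expectation: the transient contribution of the
  now-distant context disappears, but the transition prior keeps a
  `(1 - p_self)/(N - 1)` floor on it during action averaging, which grows
  with the context's magnitude and offsets part of the shrink. The tests
  therefore assert the expected ordering over ten replications.
- Model parameters are hand-chosen to emulate the experimental designs rather
  than fit to participant data; comparisons to human behaviour are
  qualitative.
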