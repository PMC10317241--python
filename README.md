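# scoin

Trial-level simulation of **context-dependent motor adaptation** with exact
Bayesian context inference — a simplified contextual-inference (sCOIN) model,
together with the task environments needed to reproduce classical adaptation
experiments (curl-force fields, visuomotor rotations, probabilistic cues,
error-clamp trials).

The package is for computational/sensorimotor neuroscientists who want to
simulate how *context inference under uncertainty* shapes switching behaviour,
savings, anterograde interference and the slow decay of adaptation during
error-clamp blocks — without positing a separate mechanism for each
phenomenon.

## The model

A latent context $\zeta_t \in \{1,\dots,N_\zeta\}$ (e.g. "no force",
"clockwise curl force") evolves as a Markov chain with self-transition
probability $p_\zeta$ and uniform off-diagonal transitions
$(1-p_\zeta)/(N_\zeta-1)$. Each context $j$ owns a scalar adaptation state
$x_j$ (force magnitude or rotation angle) over which the agent keeps a
Normal-Gamma belief $(\mu_j,\nu_j,\alpha_j,\beta_j)$; $\beta_j/\alpha_j$ is
the belief's expected observation standard deviation.

Per trial, in order:

1. **Cue → predictive context.** An optional cue $q_t$ contributes
   $p(\zeta_t{=}i \mid q_t{=}i) = 1-\eta$ (others $\eta/(N_\zeta-1)$); combined
   with the transition prior this gives the predictive distribution
   $p(\zeta_t \mid q_t, \zeta_{t-1})$.
2. **Action.** The motor command is the probability-weighted mean
   $u_t = \sum_j p(\zeta_{j,t}\mid q_t,\dots)\,\mu_j$, executed with Gaussian
   motor noise $\sigma_u$.
3. **Feedback → posterior.** The observed error $e_t$ is scored per context
   against the predicted error $\mu_j - u_t$ with composite noise
   $\sigma_\text{pred} = \sqrt{\sigma_r^2 + \sigma_u^2 + \sigma_x^2}$;
   multiplying by the predictive distribution gives the posterior
   (the contexts' *responsibilities*).
4. **Learning.** Every context absorbs the reconstructed state observation
   $s_t = e_t + u_t$ with fractional weight $w_j$ equal to its responsibility:

   $$\mu \leftarrow \frac{\nu\mu + w s_t}{\nu + w},\quad
     \nu \leftarrow \nu + w,\quad
     \alpha \leftarrow \alpha + \tfrac{w}{2},\quad
     \beta \leftarrow \beta + \frac{w\,\nu}{\nu+w}\frac{(s_t-\mu)^2}{2}.$$

Error-clamp trials force $e_t = 0$ while the agent's output is still
recorded; because each context *expects* a spread of errors, continued exact
zeros gradually favour the (tighter) baseline context, producing the
characteristic slow de-adaptation without any intrinsic memory decay.

The environment is simulated alongside the agent: block designs are laid out
trial by trial, cues are emitted from the true context with matched
uncertainty, and per-trial errors are
$x^*_{\zeta_t} + \varepsilon_a - u^\text{exec}_t + \nu_\text{obs}$.

## Worked example

Simulate the uncued 20° visuomotor-rotation switching design (11 agents, six
blocks alternating no-rotation and rotation), then measure the lag between a
true context switch and the agent's half-way response:

```bash
$ scoin run --study oh2019_exp1 --seed 0 --out oh.csv
wrote 1760 trial rows (11 runs x 160 trials) to oh.csv

$ scoin metrics --in oh.csv --metric switch_lag --switch-trial 100
{
  "metric": "switch_lag",
  "per_run": [
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1,
    1
  ],
  "n_no_switch": 0,
  "mean": 1.0
}
```

Every one of the 11 simulated agents crosses half of the 0°→20° distance
exactly one trial after the switch at trial 100: without cues, the switch can
only be detected from the first post-switch error, so the correction appears
on the following trial (the "one-trial lag"). The same library calls are
available from Python (`scoin.make_config`, `scoin.run_batch`,
`scoin.all_switch_lags`, …), and the trace CSV carries per-trial commands,
errors, context posteriors and per-context Normal-Gamma beliefs, with a JSON
manifest sidecar that reproduces the batch bit-for-bit.

Other shipped studies: `fig2_grid` (2×2 cue-uncertainty × observation-noise
grid), `kim2015` (cued three-context rotation), `oh2019_exp2` (10° variant),
`davidson2004` (post-switch error asymmetry, with larger-separation and
no-baseline variants), `vaswani2013` (error-clamp decay with 20% interleaved
clamp trials). `scoin run --study … --group …` lists the groups on a wrong
id.

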