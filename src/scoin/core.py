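"""Context-dependent motor adaptation with exact Bayesian context inference (sCOIN).

The model treats motor adaptation as inference in a switching generative model.
A latent context ``ζ_t`` (e.g. "no force", "clockwise curl force") evolves as a
Markov chain with self-transition probability ``p_ζ``; each context ``j`` owns a
scalar adaptation state ``x_j`` (force magnitude or rotation angle) over which
the agent holds a Normal-Gamma belief ``(μ, ν, α, β)``.  On every trial the
agent

1. observes an optional contextual cue and combines it with the transition
   prior to form a *predictive* context distribution,
2. issues the probability-weighted motor command ``u_t = Σ_j p_j · μ_j``
   (executed with Gaussian motor noise ``σ_u``),
3. observes the scalar motor error, evaluates each context's Gaussian
   likelihood of that error, and forms the context *posterior*
   (the "responsibility" of each context), and
4. updates every context's Normal-Gamma belief with a fractional,
   responsibility-weighted conjugate update.

The companion environment simulator produces the block designs used in
classical adaptation studies (curl-force fields and visuomotor rotations),
including probabilistic cue emission and error-clamp trials in which the
observed error is forced to zero while the agent's output is still recorded.

Everything is deterministic given a root seed: the environment noise, cue
emission, clamp placement and motor noise each draw from an independent,
deterministically derived stream.

The module is laid out in the order the method runs: environment simulation,
agent inference, shipped experiment configurations and behavioural metrics,
then serialization and config loading.
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass
from datetime import datetime, timezone
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    # environment
    "Block",
    "TrialSchedule",
    "TaskConfig",
    "build_schedule",
    "emit_cue",
    "sample_trial_error",
    # agent
    "NormalGammaBelief",
    "ContextBelief",
    "AgentConfig",
    "TrialRecord",
    "ScoinAgent",
    "transition_kernel",
    "cue_likelihood",
    "predict_context",
    "prediction_sd",
    "observation_likelihood",
    "posterior_context",
    "select_action",
    "learning_datum",
    "update_beliefs",
    "simulate_run",
    # experiments
    "StudyConfig",
    "BatchResult",
    "STUDY_IDS",
    "make_config",
    "available_configs",
    "run_batch",
    "switch_lag",
    "context_switch_trials",
    "all_switch_lags",
    "trials_to_plateau",
    "trials_to_posterior_threshold",
    "error_after_switch",
    "ec_decay_curve",
    "NO_SWITCH",
    # io
    "RunManifest",
    "load_config",
    "config_to_dict",
    "config_from_dict",
    "write_traces",
    "read_traces",
    "aggregate_runs",
]

logger = logging.getLogger("scoin")

#: Sentinel returned by threshold metrics when the trace never crosses.
NO_SWITCH = "no-switch"

_LOG_SQRT_2PI = 0.5 * math.log(2.0 * math.pi)

#: Probability vectors must sum to one within this tolerance.
PROB_ATOL = 1e-12

__version__ = "0.1.0"


class ValidationError(ValueError):
    """A configuration or input value violates a model invariant."""


class DegeneratePosteriorError(RuntimeError):
    """Raised when a cue rules out every context with prior support."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ValidationError(msg)


def _as_prob_vector(p: Sequence[float], name: str) -> np.ndarray:
    v = np.asarray(p, dtype=float)
    _check(v.ndim == 1, f"{name} must be a 1-d probability vector")
    _check(np.all(v >= 0.0), f"{name} has negative entries")
    _check(abs(v.sum() - 1.0) <= 1e-9, f"{name} does not sum to 1 (sum={v.sum()!r})")
    return v


# =====================================================================
# 1. Generative environment: block designs, cues, trial errors
# =====================================================================


@dataclass(frozen=True)
class Block:
    """One block of trials under a single true context.

    ``clamp_fraction`` is the fraction of trials inside an *adaptation* block
    that are converted into interleaved error-clamp trials; it is ignored when
    the whole block is an error-clamp block (``is_error_clamp=True``).
    """

    context_id: int
    n_trials: int
    is_error_clamp: bool = False
    clamp_fraction: float = 0.0

    def __post_init__(self) -> None:
        _check(int(self.n_trials) >= 1, f"Block.n_trials must be >= 1, got {self.n_trials}")
        _check(
            0.0 <= self.clamp_fraction <= 1.0,
            f"Block.clamp_fraction must lie in [0, 1], got {self.clamp_fraction}",
        )
        _check(int(self.context_id) >= 0, "Block.context_id must be a non-negative index")


@dataclass(frozen=True)
class TrialSchedule:
    """Materialized per-trial design: true context and clamp flag per trial."""

    trial: np.ndarray  # contiguous 0-based trial index
    block: np.ndarray  # index of the generating block
    context_id: np.ndarray
    clamp: np.ndarray  # boolean

    @property
    def n_trials(self) -> int:
        return int(self.trial.size)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "trial": self.trial,
                "block": self.block,
                "context_id": self.context_id,
                "clamp": self.clamp.astype(int),
            }
        )

    def to_csv(self, path: str | os.PathLike) -> None:
        self.to_frame().to_csv(path, index=False)


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5)) if x >= 0 else -int(math.floor(-x + 0.5))


def build_schedule(blocks: Sequence[Block], rng_seed: int | np.random.Generator) -> TrialSchedule:
    """Lay out blocks into a per-trial schedule, placing interleaved clamp trials.

    Within an adaptation block with clamp fraction ``f`` and ``n`` trials,
    exactly ``round(f·n)`` trials (half away from zero) are flagged as clamp
    trials, at positions drawn uniformly without replacement from the seeded
    generator.  Clamp trials keep the block's true context; only their feedback
    is clamped.
    """
    if len(blocks) == 0:
        raise ValidationError("cannot build a schedule from an empty block list")
    rng = rng_seed if isinstance(rng_seed, np.random.Generator) else np.random.default_rng(rng_seed)
    trial_ids: list[int] = []
    block_ids: list[int] = []
    ctx_ids: list[int] = []
    clamp_flags: list[bool] = []
    t = 0
    for b_idx, blk in enumerate(blocks):
        n = int(blk.n_trials)
        if blk.is_error_clamp:
            flags = np.ones(n, dtype=bool)
        else:
            flags = np.zeros(n, dtype=bool)
            n_clamp = _round_half_away(blk.clamp_fraction * n)
            if n_clamp > 0:
                pos = rng.choice(n, size=n_clamp, replace=False)
                flags[pos] = True
        for i in range(n):
            trial_ids.append(t)
            block_ids.append(b_idx)
            ctx_ids.append(blk.context_id)
            clamp_flags.append(bool(flags[i]))
            t += 1
    return TrialSchedule(
        trial=np.asarray(trial_ids, dtype=int),
        block=np.asarray(block_ids, dtype=int),
        context_id=np.asarray(ctx_ids, dtype=int),
        clamp=np.asarray(clamp_flags, dtype=bool),
    )


@dataclass
class TaskConfig:
    """Ground truth of the simulated task.

    ``context_adaptations`` holds the true adaptation ``x*_j`` per context, in
    task units (degrees for visuomotor rotations, normalized force units for
    curl fields).  ``adaptation_noise`` (σ_a) is trial-to-trial Gaussian noise
    on the true adaptation; ``observation_noise`` (σ*_r) is the true noise on
    the observed error.  ``cue_uncertainty`` (η) is the probability that the
    emitted cue does not match the true context, split evenly over the other
    symbols.
    """

    context_adaptations: tuple[float, ...]
    adaptation_noise: float
    observation_noise: float
    blocks: tuple[Block, ...] = ()
    cues_present: bool = False
    cue_uncertainty: float = 0.0

    def __post_init__(self) -> None:
        self.context_adaptations = tuple(float(x) for x in self.context_adaptations)
        self.blocks = tuple(self.blocks)
        _check(len(self.context_adaptations) >= 1, "need at least one context")
        _check(self.adaptation_noise >= 0.0, "adaptation_noise (sigma_a) must be >= 0")
        _check(self.observation_noise >= 0.0, "observation_noise (sigma_r*) must be >= 0")
        n = self.n_contexts
        hi = (n - 1) / n
        _check(
            0.0 <= self.cue_uncertainty <= hi + 1e-12,
            f"cue_uncertainty must lie in [0, {(n - 1)}/{n}], got {self.cue_uncertainty}",
        )
        for blk in self.blocks:
            _check(
                blk.context_id < n,
                f"block references context {blk.context_id} but only {n} contexts exist",
            )

    @property
    def n_contexts(self) -> int:
        return len(self.context_adaptations)


def emit_cue(
    true_context: int, eta_env: float, n_contexts: int, rng: np.random.Generator
) -> int:
    """Emit a cue symbol: the true context's symbol w.p. ``1−η``, any other
    symbol w.p. ``η/(N−1)``."""
    _check(0 <= true_context < n_contexts, f"unknown context id {true_context}")
    hi = (n_contexts - 1) / n_contexts
    _check(0.0 <= eta_env <= hi + 1e-12, f"cue uncertainty {eta_env} outside [0, {hi:.4g}]")
    if n_contexts == 1 or eta_env == 0.0:
        return int(true_context)
    probs = np.full(n_contexts, eta_env / (n_contexts - 1))
    probs[true_context] = 1.0 - eta_env
    return int(rng.choice(n_contexts, p=probs))


def sample_trial_error(
    u_exec: float,
    true_context: int,
    task: TaskConfig,
    clamp: bool,
    rng: np.random.Generator,
) -> float:
    """Observed scalar error of one trial.

    Error-clamp trials return exactly 0 regardless of the executed command.
    Otherwise the error is ``x*_ζ + ε_a − u_exec + ν_obs`` with
    ``ε_a ~ N(0, σ_a)`` and ``ν_obs ~ N(0, σ*_r)``: positive error means
    under-compensation of a positive adaptation.

    Note: the two noise draws are consumed from ``rng`` even on clamp trials,
    so that flipping a trial's clamp flag does not shift every later draw.
    """
    _check(math.isfinite(u_exec), "executed command must be finite")
    _check(0 <= true_context < task.n_contexts, f"unknown context id {true_context}")
    eps_a = rng.normal(0.0, task.adaptation_noise) if task.adaptation_noise > 0 else 0.0
    nu_obs = rng.normal(0.0, task.observation_noise) if task.observation_noise > 0 else 0.0
    if clamp:
        return 0.0
    x_true = task.context_adaptations[true_context]
    return float(x_true + eps_a - u_exec + nu_obs)


# =====================================================================
# 2. The sCOIN agent: context inference and Normal-Gamma adaptation
# =====================================================================


@dataclass
class NormalGammaBelief:
    """Normal-Gamma belief ``(μ, ν, α, β)`` over one context's adaptation state.

    ``mu`` is the current point estimate of the adaptation, ``nu`` the
    pseudo-count of evidence behind it, and ``beta/alpha`` is the belief's
    expected observation standard deviation.  ``param_sd`` is the uncertainty
    σ_x of the state estimate itself that enters the composite prediction
    noise; by default it is the observation scale shrunk by the pseudo-count,
    ``(β/α)/√ν`` (mode "shrunk"), with the un-shrunk alternative ``β/α``
    available as mode "expected-sd".
    """

    mu: float
    nu: float
    alpha: float
    beta: float

    def __post_init__(self) -> None:
        _check(self.nu > 0, f"NormalGamma nu must be > 0, got {self.nu}")
        _check(self.alpha > 0, f"NormalGamma alpha must be > 0, got {self.alpha}")
        _check(self.beta > 0, f"NormalGamma beta must be > 0, got {self.beta}")
        _check(
            all(math.isfinite(v) for v in (self.mu, self.nu, self.alpha, self.beta)),
            "NormalGamma parameters must be finite",
        )

    @property
    def obs_sd(self) -> float:
        return self.beta / self.alpha

    def param_sd(self, mode: str = "shrunk") -> float:
        if mode == "shrunk":
            return self.obs_sd / math.sqrt(self.nu)
        if mode == "expected-sd":
            return self.obs_sd
        raise ValidationError(f"unknown sigma_x mode {mode!r}")


@dataclass
class ContextBelief:
    """Predictive (pre-feedback) and posterior (post-feedback) context vectors."""

    predictive: np.ndarray
    posterior: np.ndarray

    def __post_init__(self) -> None:
        self.predictive = _as_prob_vector(self.predictive, "predictive")
        self.posterior = _as_prob_vector(self.posterior, "posterior")


@dataclass
class AgentConfig:
    """The agent's assumptions about the task.

    ``p_self`` is the assumed context self-transition probability, ``sigma_r``
    the assumed observation noise, ``sigma_u`` the motor noise, and ``eta`` the
    assumed cue uncertainty.  ``hyperpriors`` holds one Normal-Gamma prior
    ``(μ0, ν0, α0, β0)`` per context.  ``include_baseline`` flags whether the
    baseline (zero-adaptation) context is part of the agent's context set;
    configs that drop it must also drop its hyper-prior entry.
    """

    p_self: float
    sigma_r: float
    sigma_u: float
    hyperpriors: tuple[tuple[float, float, float, float], ...]
    eta: float = 0.0
    include_baseline: bool = True
    sigma_x_mode: str = "shrunk"

    def __post_init__(self) -> None:
        self.hyperpriors = tuple(tuple(float(v) for v in h) for h in self.hyperpriors)
        _check(0.0 < self.p_self <= 1.0, f"p_self must lie in (0, 1], got {self.p_self}")
        _check(self.sigma_r > 0.0, f"sigma_r must be > 0, got {self.sigma_r}")
        _check(self.sigma_u >= 0.0, f"sigma_u must be >= 0, got {self.sigma_u}")
        n = self.n_contexts
        _check(n >= 1, "need at least one context hyper-prior")
        hi = (n - 1) / n if n > 1 else 0.0
        _check(0.0 <= self.eta <= hi + 1e-12, f"eta must lie in [0, {hi:.4g}], got {self.eta}")
        _check(self.sigma_x_mode in ("shrunk", "expected-sd"), "sigma_x_mode must be 'shrunk' or 'expected-sd'")
        for j, h in enumerate(self.hyperpriors):
            _check(len(h) == 4, f"hyperprior {j} must be (mu0, nu0, alpha0, beta0)")
            NormalGammaBelief(*h)  # validates positivity invariants

    @property
    def n_contexts(self) -> int:
        return len(self.hyperpriors)

    def initial_beliefs(self) -> list[NormalGammaBelief]:
        return [NormalGammaBelief(*h) for h in self.hyperpriors]


def transition_kernel(p_self: float, n_contexts: int) -> np.ndarray:
    """Row-stochastic context transition matrix: ``p_self`` on the diagonal and
    ``(1−p_self)/(N−1)`` off it."""
    _check(n_contexts >= 1, "n_contexts must be >= 1")
    _check(0.0 < p_self <= 1.0, f"p_self must lie in (0, 1], got {p_self}")
    if n_contexts == 1:
        _check(p_self == 1.0, "a single context cannot transition away (p_self < 1 with N=1)")
        return np.ones((1, 1))
    off = (1.0 - p_self) / (n_contexts - 1)
    kernel = np.full((n_contexts, n_contexts), off)
    np.fill_diagonal(kernel, p_self)
    return kernel


def cue_likelihood(cue: int | None, eta: float, n_contexts: int) -> np.ndarray:
    """Per-context cue evidence ``p(ζ|q)``: the cued context gets ``1−η``, the
    others ``η/(N−1)``.  An absent cue is uninformative (uniform vector)."""
    if cue is None:
        return np.full(n_contexts, 1.0 / n_contexts)
    _check(0 <= int(cue) < n_contexts, f"unknown cue symbol {cue}")
    if n_contexts == 1:
        return np.ones(1)
    hi = (n_contexts - 1) / n_contexts
    _check(0.0 <= eta <= hi + 1e-12, f"eta {eta} outside [0, {hi:.4g}]")
    v = np.full(n_contexts, eta / (n_contexts - 1))
    v[int(cue)] = 1.0 - eta
    return v


def predict_context(
    prev_posterior: np.ndarray, kernel: np.ndarray, cue_lik: np.ndarray
) -> np.ndarray:
    """Predictive context distribution: cue evidence times the transition prior,
    normalized.  Raises if the cue rules out every context with prior support."""
    prev = _as_prob_vector(prev_posterior, "prev_posterior")
    prior = kernel.T @ prev
    unnorm = np.asarray(cue_lik, dtype=float) * prior
    z = unnorm.sum()
    if z <= 0.0:
        raise DegeneratePosteriorError("cue likelihood rules out all contexts with prior support")
    return unnorm / z


def prediction_sd(belief: NormalGammaBelief, sigma_r: float, sigma_u: float,
                  sigma_x_mode: str = "shrunk") -> float:
    """Composite prediction noise ``σ_pred = √(σ_r² + σ_u² + σ_x²)`` with σ_x
    taken from the belief (see :class:`NormalGammaBelief.param_sd`)."""
    _check(sigma_r >= 0.0 and sigma_u >= 0.0, "noise parameters must be >= 0")
    sx = belief.param_sd(sigma_x_mode)
    return math.sqrt(sigma_r * sigma_r + sigma_u * sigma_u + sx * sx)


def _log_normal_pdf(x: float, mean: float, sd: float) -> float:
    z = (x - mean) / sd
    return -0.5 * z * z - math.log(sd) - _LOG_SQRT_2PI


def observation_likelihood(
    e_t: float,
    u_t: float,
    beliefs: Sequence[NormalGammaBelief],
    cfg: AgentConfig,
    log: bool = False,
) -> np.ndarray:
    """Per-context Gaussian likelihood of the observed error.

    Context ``i`` predicts the error ``μ_i − u_t`` (its estimated adaptation
    minus the issued compensation; the compounding error term is zero in all
    simulated paradigms) with standard deviation ``prediction_sd(belief_i)``.
    Returns densities, or log densities with ``log=True``.
    """
    _check(math.isfinite(e_t) and math.isfinite(u_t), "error and command must be finite")
    out = np.empty(len(beliefs))
    for i, b in enumerate(beliefs):
        sd = prediction_sd(b, cfg.sigma_r, cfg.sigma_u, cfg.sigma_x_mode)
        out[i] = _log_normal_pdf(e_t, b.mu - u_t, sd)
    return out if log else np.exp(out)


def posterior_context(
    predictive: np.ndarray,
    densities: np.ndarray,
    log: bool = False,
    trial: int | None = None,
) -> np.ndarray:
    """Posterior context probabilities (responsibilities): predictive times the
    observation likelihood, renormalized in log space.

    If every product underflows to zero (the error is many σ from every
    context's prediction), the predictive vector is returned unchanged and a
    warning is logged, rather than crashing mid-run.
    """
    pred = _as_prob_vector(predictive, "predictive")
    dens = np.asarray(densities, dtype=float)
    with np.errstate(divide="ignore"):
        log_pred = np.log(pred)
    log_dens = dens if log else np.log(np.maximum(dens, 0.0), where=dens > 0,
                                       out=np.full_like(dens, -np.inf))
    log_post = log_pred + log_dens
    m = np.max(log_post)
    if not np.isfinite(m):
        where = f" at trial {trial}" if trial is not None else ""
        logger.warning("degenerate context posterior%s; falling back to predictive", where)
        return pred
    w = np.exp(log_post - m)
    return w / w.sum()


def select_action(
    context_probs: np.ndarray,
    beliefs: Sequence[NormalGammaBelief],
    sigma_u: float,
    rng: np.random.Generator,
) -> tuple[float, float]:
    """Probability-weighted motor command and its noisy execution.

    The intended command is the mean adaptation under the *predictive* context
    distribution, ``u_t = Σ_j p_j μ_j``; the executed command adds Gaussian
    motor noise of scale ``σ_u``.
    """
    p = _as_prob_vector(context_probs, "context_probs")
    _check(len(beliefs) == p.size, "probability vector and belief list disagree in length")
    u_t = float(np.dot(p, [b.mu for b in beliefs]))
    u_exec = u_t + (rng.normal(0.0, sigma_u) if sigma_u > 0 else 0.0)
    return u_t, float(u_exec)


def learning_datum(e_t: float, u_t: float) -> float:
    """Reconstructed state observation ``s_t = e_t + u_t``: the observed error
    plus the issued compensation, which is what each context's belief models.
    On clamp trials (``e_t = 0``) this equals the issued command itself, which
    is how continued zero error gradually favours the baseline context."""
    _check(math.isfinite(e_t) and math.isfinite(u_t), "inputs must be finite")
    return e_t + u_t


def update_beliefs(
    beliefs: Sequence[NormalGammaBelief],
    s_t: float,
    responsibilities: np.ndarray,
) -> list[NormalGammaBelief]:
    """Responsibility-weighted Normal-Gamma conjugate update.

    Each context ``i`` absorbs the datum ``s_t`` with fractional weight
    ``w = p(ζ_i | …)``::

        μ ← (ν μ + w s) / (ν + w)
        ν ← ν + w
        α ← α + w / 2
        β ← β + w ν / (ν + w) · (s − μ)² / 2     (ν, μ pre-update)

    A context with weight exactly zero is returned unchanged (bitwise), so
    contexts ruled out by the posterior are frozen.
    """
    w = np.asarray(responsibilities, dtype=float)
    _check(w.ndim == 1 and w.size == len(beliefs), "responsibilities must match beliefs")
    _check(np.all(w >= 0.0), "responsibilities must be non-negative")
    _check(abs(w.sum() - 1.0) <= 1e-9, f"responsibilities must sum to 1, got {w.sum()!r}")
    out: list[NormalGammaBelief] = []
    for b, wi in zip(beliefs, w):
        if wi == 0.0:
            out.append(b)
            continue
        denom = b.nu + wi
        mu_new = (b.nu * b.mu + wi * s_t) / denom
        beta_new = b.beta + wi * b.nu / denom * (s_t - b.mu) ** 2 / 2.0
        out.append(NormalGammaBelief(mu=mu_new, nu=denom, alpha=b.alpha + wi / 2.0, beta=beta_new))
    return out


@dataclass
class TrialRecord:
    """Full state of one trial, sufficient to replay the belief update."""

    trial: int
    true_context: int
    cue: int | None
    clamp: bool
    u: float
    u_exec: float
    error: float
    s: float
    predictive: np.ndarray
    posterior: np.ndarray
    beliefs: tuple[tuple[float, float, float, float], ...]  # post-update (mu, nu, alpha, beta)


class ScoinAgent:
    """Stateful per-trial inference loop.

    Per-trial ordering: cue → predictive context → action → feedback →
    posterior (responsibilities) → belief update.  This is the unique ordering
    that yields cue-driven immediate switches in cued designs and a one-trial
    lag in uncued ones.
    """

    def __init__(self, cfg: AgentConfig):
        self.cfg = cfg
        self.n_contexts = cfg.n_contexts
        self.kernel = transition_kernel(cfg.p_self, cfg.n_contexts)
        self.beliefs: list[NormalGammaBelief] = cfg.initial_beliefs()
        # Cold start: uniform over contexts before any evidence.
        self.posterior = np.full(cfg.n_contexts, 1.0 / cfg.n_contexts)
        self._trial = 0

    def step(
        self,
        cue: int | None,
        env_feedback: Callable[[float], tuple[float, bool, int]],
        rng_motor: np.random.Generator,
    ) -> TrialRecord:
        """Run one trial.  ``env_feedback(u_exec)`` must return the observed
        error, the clamp flag and the true context id for this trial."""
        cfg = self.cfg
        try:
            cue_lik = cue_likelihood(cue, cfg.eta, self.n_contexts)
            predictive = predict_context(self.posterior, self.kernel, cue_lik)
            u_t, u_exec = select_action(predictive, self.beliefs, cfg.sigma_u, rng_motor)
            e_t, clamp, true_ctx = env_feedback(u_exec)
            log_dens = observation_likelihood(e_t, u_t, self.beliefs, cfg, log=True)
            posterior = posterior_context(predictive, log_dens, log=True, trial=self._trial)
            s_t = learning_datum(e_t, u_t)
            self.beliefs = update_beliefs(self.beliefs, s_t, posterior)
        except (ValidationError, DegeneratePosteriorError) as err:
            raise type(err)(f"trial {self._trial}: {err}") from err
        self.posterior = posterior
        rec = TrialRecord(
            trial=self._trial,
            true_context=int(true_ctx),
            cue=cue,
            clamp=bool(clamp),
            u=u_t,
            u_exec=u_exec,
            error=e_t,
            s=s_t,
            predictive=predictive,
            posterior=posterior,
            beliefs=tuple((b.mu, b.nu, b.alpha, b.beta) for b in self.beliefs),
        )
        self._trial += 1
        return rec


def _records_to_frame(records: Sequence[TrialRecord], n_contexts: int,
                      schedule: TrialSchedule) -> pd.DataFrame:
    cols: dict[str, list] = {
        "trial": [r.trial for r in records],
        "block": list(schedule.block[: len(records)]),
        "true_context": [r.true_context for r in records],
        "cue": [(-1 if r.cue is None else r.cue) for r in records],
        "clamp": [int(r.clamp) for r in records],
        "u": [r.u for r in records],
        "u_exec": [r.u_exec for r in records],
        "error": [r.error for r in records],
        "s": [r.s for r in records],
    }
    for j in range(n_contexts):
        cols[f"p_pred_{j}"] = [r.predictive[j] for r in records]
        cols[f"p_ctx_{j}"] = [r.posterior[j] for r in records]
    for j in range(n_contexts):
        cols[f"mu_{j}"] = [r.beliefs[j][0] for r in records]
        cols[f"nu_{j}"] = [r.beliefs[j][1] for r in records]
        cols[f"alpha_{j}"] = [r.beliefs[j][2] for r in records]
        cols[f"beta_{j}"] = [r.beliefs[j][3] for r in records]
    return pd.DataFrame(cols)


def simulate_run(
    task: TaskConfig,
    agent_cfg: AgentConfig,
    seed: int | np.random.SeedSequence,
    schedule: TrialSchedule | None = None,
) -> pd.DataFrame:
    """Simulate one agent through the task's block schedule.

    Four independent random streams are derived deterministically from the
    seed — clamp placement, cue emission, environment noise, motor noise — so
    ablating one source leaves the others' draws unchanged.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    ss_clamp, ss_cue, ss_env, ss_motor = ss.spawn(4)
    if schedule is None:
        schedule = build_schedule(task.blocks, np.random.default_rng(ss_clamp))
    rng_cue = np.random.default_rng(ss_cue)
    rng_env = np.random.default_rng(ss_env)
    rng_motor = np.random.default_rng(ss_motor)
    _check(
        agent_cfg.n_contexts == task.n_contexts,
        f"agent has {agent_cfg.n_contexts} contexts but task defines {task.n_contexts}",
    )
    agent = ScoinAgent(agent_cfg)
    records: list[TrialRecord] = []
    for t in range(schedule.n_trials):
        true_ctx = int(schedule.context_id[t])
        clamp = bool(schedule.clamp[t])
        cue = (
            emit_cue(true_ctx, task.cue_uncertainty, task.n_contexts, rng_cue)
            if task.cues_present
            else None
        )

        def feedback(u_exec: float, _ctx=true_ctx, _clamp=clamp) -> tuple[float, bool, int]:
            e = sample_trial_error(u_exec, _ctx, task, _clamp, rng_env)
            return e, _clamp, _ctx

        records.append(agent.step(cue, feedback, rng_motor))
    return _records_to_frame(records, task.n_contexts, schedule)


# =====================================================================
# 3. Shipped experiments: study configurations, batch runner, metrics
# =====================================================================


@dataclass
class StudyConfig:
    """A fully resolved simulated study: task + agent + batch settings."""

    study_id: str
    group_id: str
    task: TaskConfig
    agent: AgentConfig
    n_runs: int
    root_seed: int = 0

    def __post_init__(self) -> None:
        _check(int(self.n_runs) >= 1, f"n_runs must be >= 1, got {self.n_runs}")
        _check(
            self.task.n_contexts == self.agent.n_contexts,
            "task and agent disagree on the number of contexts",
        )

    @property
    def n_trials(self) -> int:
        return int(sum(b.n_trials for b in self.task.blocks))


# Curl-force studies use normalized force units; rotation studies use degrees.
# Hyper-priors are (mu0, nu0, alpha0, beta0) per context, baseline first.
_DAVIDSON_TASK = dict(adaptation_noise=1.0, observation_noise=0.1)
_DAVIDSON_AGENT = dict(p_self=0.9, sigma_r=2.5, sigma_u=0.17)
_DAVIDSON_HYPER_SCALE = dict(nu0=(1e4, 1.0, 1.0), alpha0=(33e3, 4e2, 4e2), beta0=(1e5, 23e2, 23e2))

STUDY_IDS = ("fig2_grid", "kim2015", "oh2019_exp1", "oh2019_exp2", "davidson2004", "vaswani2013")

_FIG2_CELLS = {
    # (cue uncertainty eta, agent observation noise sigma_r)
    "low_cue_low_obs": (0.0, 0.5),
    "low_cue_high_obs": (0.0, 2.0),
    "high_cue_low_obs": (0.33, 0.5),
    "high_cue_high_obs": (0.33, 2.0),
}

_DAVIDSON_GROUPS = {
    # group -> (adaptations, include_baseline); index 1 is A, index 2 the other context
    "group_minusA": ((0.0, 4.0, -4.0), True),
    "group_3A": ((0.0, 4.0, 12.0), True),
    "group_minus2A": ((0.0, 4.0, -8.0), True),
    "group_4A": ((0.0, 4.0, 16.0), True),
    "group_minusA_no_baseline": ((4.0, -4.0), False),
    "group_3A_no_baseline": ((4.0, 12.0), False),
}


def _hyper_tuple(mu0: Sequence[float], nu0: Sequence[float], alpha0: Sequence[float],
                 beta0: Sequence[float]) -> tuple[tuple[float, float, float, float], ...]:
    return tuple(zip(mu0, nu0, alpha0, beta0))


def available_configs() -> dict[str, tuple[str, ...]]:
    """Mapping from study id to its known group ids."""
    return {
        "fig2_grid": tuple(_FIG2_CELLS),
        "kim2015": ("exp1",),
        "oh2019_exp1": ("default",),
        "oh2019_exp2": ("default",),
        "davidson2004": tuple(_DAVIDSON_GROUPS),
        "vaswani2013": ("grp1", "grp2", "grp3", "grp4"),
    }


def make_config(study_id: str, group_id: str | None = None, root_seed: int = 0) -> StudyConfig:
    """Return the shipped configuration for one simulated study group.

    Studies: a 2x2 cue-uncertainty x observation-noise grid on a generic
    curl-force switching task (``fig2_grid``); a cued three-context visuomotor
    rotation study (``kim2015``); uncued visuomotor rotation switching at 20
    and 10 degrees (``oh2019_exp1``/``exp2``); the curl-force action-selection
    asymmetry design with its larger-separation and no-baseline variants
    (``davidson2004``); and the error-clamp decay design with interleaved
    clamp trials (``vaswani2013``).
    """
    groups = available_configs()
    if study_id not in groups:
        raise ValidationError(
            f"unknown study {study_id!r}; available: {', '.join(groups)}"
        )
    if group_id is None:
        group_id = groups[study_id][0]
    if group_id not in groups[study_id]:
        raise ValidationError(
            f"unknown group {group_id!r} for study {study_id!r}; "
            f"available: {', '.join(groups[study_id])}"
        )

    if study_id == "fig2_grid":
        eta, sigma_r = _FIG2_CELLS[group_id]
        task = TaskConfig(
            context_adaptations=(0.0, 4.0),
            blocks=(Block(1, 20), Block(0, 10)),
            cues_present=True,
            cue_uncertainty=eta,
            **_DAVIDSON_TASK,
        )
        agent = AgentConfig(
            p_self=0.9,
            sigma_r=sigma_r,
            sigma_u=0.17,
            eta=eta,
            hyperpriors=((0.0, 1e4, 33e3, 1e5), (0.0, 1.0, 4e2, 23e2)),
        )
        return StudyConfig(study_id, group_id, task, agent, n_runs=50, root_seed=root_seed)

    if study_id == "kim2015":
        # Contexts (0, 40, -40) deg; the +40 context's prior mean is +1 and the
        # -40 context's is -1, seeding learning in the right direction.
        cycle = (Block(0, 50), Block(1, 50), Block(0, 50), Block(2, 50))
        task = TaskConfig(
            context_adaptations=(0.0, 40.0, -40.0),
            adaptation_noise=0.01,
            observation_noise=3.0,
            blocks=cycle * 3,  # 600 trials
            cues_present=True,
            cue_uncertainty=0.0,
        )
        agent = AgentConfig(
            p_self=0.9,
            sigma_r=3.0,
            sigma_u=1.0,
            eta=0.0,
            hyperpriors=_hyper_tuple(
                mu0=(0.0, 1.0, -1.0),
                nu0=(1e4, 1.0, 1.0),
                alpha0=(25e3, 0.25, 0.25),
                beta0=(1e5, 2.0, 2.0),
            ),
        )
        return StudyConfig(study_id, group_id, task, agent, n_runs=20, root_seed=root_seed)

    if study_id in ("oh2019_exp1", "oh2019_exp2"):
        rot = 20.0 if study_id == "oh2019_exp1" else 10.0
        task = TaskConfig(
            context_adaptations=(0.0, rot),
            adaptation_noise=0.5,
            observation_noise=2.5,
            blocks=(
                Block(0, 20), Block(1, 60), Block(0, 20),
                Block(1, 20), Block(0, 20), Block(1, 20),
            ),
            cues_present=False,
        )
        agent = AgentConfig(
            p_self=0.98,
            sigma_r=2.5,
            sigma_u=2.0,
            hyperpriors=_hyper_tuple(
                mu0=(0.0, 0.0), nu0=(1e4, 1.0), alpha0=(22e3, 2.2), beta0=(1e5, 20.0)
            ),
        )
        return StudyConfig(study_id, group_id, task, agent, n_runs=11, root_seed=root_seed)

    if study_id == "davidson2004":
        adaptations, with_baseline = _DAVIDSON_GROUPS[group_id]
        n = len(adaptations)
        scale = {k: v[-n:] for k, v in _DAVIDSON_HYPER_SCALE.items()} if not with_baseline \
            else _DAVIDSON_HYPER_SCALE
        a_idx, b_idx = (1, 2) if with_baseline else (0, 1)
        task = TaskConfig(
            context_adaptations=adaptations,
            blocks=(Block(a_idx, 60), Block(b_idx, 60), Block(a_idx, 60)),
            cues_present=False,
            **_DAVIDSON_TASK,
        )
        agent = AgentConfig(
            hyperpriors=_hyper_tuple(mu0=adaptations, **scale),  # pre-adapted: mu0 at truth
            include_baseline=with_baseline,
            **_DAVIDSON_AGENT,
        )
        return StudyConfig(study_id, group_id, task, agent, n_runs=32, root_seed=root_seed)

    # vaswani2013: error-clamp decay; adaptation blocks carry 20% interleaved clamps.
    A, E = 100, 100
    f = 0.2
    vas_agent = dict(p_self=0.8, sigma_r=0.1, sigma_u=0.17)
    vas_task = dict(adaptation_noise=0.1, observation_noise=0.1, cues_present=False)
    if group_id == "grp1":
        adaptations = (0.0, 1.0)
        blocks = (Block(1, A, clamp_fraction=f), Block(0, E, is_error_clamp=True))
    elif group_id == "grp2":
        adaptations = (0.0, 1.0)
        blocks = (Block(0, 50), Block(1, A, clamp_fraction=f), Block(0, E, is_error_clamp=True))
    elif group_id == "grp3":
        adaptations = (0.0, -0.5, 1.0)
        blocks = (
            Block(1, A, clamp_fraction=f),
            Block(2, A, clamp_fraction=f),
            Block(0, E, is_error_clamp=True),
        )
    else:  # grp4: sign-flipped twin of grp1
        adaptations = (0.0, -1.0)
        blocks = (Block(1, A, clamp_fraction=f), Block(0, E, is_error_clamp=True))
    n = len(adaptations)
    alpha0 = (15e4,) + (5.0,) * (n - 1) if n == 3 else (5e4,) + (5.0,) * (n - 1)
    agent = AgentConfig(
        hyperpriors=_hyper_tuple(
            mu0=adaptations,  # pre-adapted
            nu0=(1e4,) + (1.0,) * (n - 1),
            alpha0=alpha0,
            beta0=(1e5,) + (2.0,) * (n - 1),
        ),
        **vas_agent,
    )
    task = TaskConfig(context_adaptations=adaptations, blocks=blocks, **vas_task)
    return StudyConfig(study_id, group_id, task, agent, n_runs=6, root_seed=root_seed)


def aggregate_runs(runs: Sequence[pd.DataFrame]) -> pd.DataFrame:
    """Cross-run per-trial mean and SEM of command, error, context posteriors
    and inferred states.  SEM uses the sample standard deviation over runs
    (ddof=1) divided by sqrt(n_runs); a single run yields SEM 0 by convention."""
    _check(len(runs) >= 1, "cannot aggregate an empty batch")
    n = len(runs)
    stacked = pd.concat(runs, keys=range(n), names=["run"])
    g = stacked.groupby("trial", sort=True)
    out = pd.DataFrame({"trial": sorted(stacked["trial"].unique())}).set_index("trial")
    for col in ("u", "error"):
        out[f"mean_{col}"] = g[col].mean()
        out[f"sem_{col}"] = g[col].std(ddof=1) / math.sqrt(n) if n > 1 else 0.0
    prob_cols = [c for c in runs[0].columns if c.startswith(("p_ctx_", "p_pred_", "mu_"))]
    for col in prob_cols:
        out[f"mean_{col}"] = g[col].mean()
    return out.reset_index()


@dataclass
class BatchResult:
    """Seeded batch of runs for one study group plus cross-run aggregates."""

    config: StudyConfig
    runs: list[pd.DataFrame]
    aggregate: pd.DataFrame

    @property
    def n_runs(self) -> int:
        return len(self.runs)

    @property
    def n_contexts(self) -> int:
        return self.config.task.n_contexts


def run_batch(cfg: StudyConfig) -> BatchResult:
    """Run ``cfg.n_runs`` independent seeded simulations; deterministic given
    ``cfg.root_seed``."""
    root = np.random.SeedSequence(cfg.root_seed)
    run_seeds = root.spawn(cfg.n_runs)
    runs: list[pd.DataFrame] = []
    for i, ss in enumerate(run_seeds):
        logger.info("run %d/%d study=%s group=%s", i + 1, cfg.n_runs, cfg.study_id, cfg.group_id)
        try:
            runs.append(simulate_run(cfg.task, cfg.agent, ss))
        except Exception as err:
            raise RuntimeError(f"run {i} of {cfg.study_id}/{cfg.group_id} failed: {err}") from err
    return BatchResult(config=cfg, runs=runs, aggregate=aggregate_runs(runs))


# --- behavioural metrics -------------------------------------------------


def switch_lag(
    u: Sequence[float],
    switch_trial: int,
    old_value: float,
    new_value: float,
    threshold_fraction: float = 0.5,
):
    """Trials after a true context switch until the intended command first
    crosses ``threshold_fraction`` of the distance from the old context's
    adaptation to the new one.  Returns the ``NO_SWITCH`` sentinel if the
    command never crosses."""
    u = np.asarray(u, dtype=float)
    _check(0 <= switch_trial < u.size, "switch_trial outside trace")
    _check(0.0 < threshold_fraction < 1.0, "threshold_fraction must lie in (0, 1)")
    _check(new_value != old_value, "old and new adaptation values must differ")
    frac = (u[switch_trial:] - old_value) / (new_value - old_value)
    hits = np.nonzero(frac >= threshold_fraction)[0]
    return int(hits[0]) if hits.size else NO_SWITCH


def context_switch_trials(run: pd.DataFrame) -> list[int]:
    """Trial indices at which the true context changes (clamp trials excluded
    from defining switches so interleaved clamps do not count)."""
    ctx = run["true_context"].to_numpy()
    return [int(t) for t in np.nonzero(np.diff(ctx) != 0)[0] + 1]


def all_switch_lags(
    batch: BatchResult, threshold_fraction: float = 0.5, from_trial: int = 0
) -> list:
    """Switch lags for every true context switch at or after ``from_trial``,
    across all runs of a batch."""
    adapt = batch.config.task.context_adaptations
    lags = []
    for run in batch.runs:
        ctx = run["true_context"].to_numpy()
        for t in context_switch_trials(run):
            if t < from_trial:
                continue
            old_v, new_v = adapt[int(ctx[t - 1])], adapt[int(ctx[t])]
            lags.append(switch_lag(run["u"].to_numpy(), t, old_v, new_v, threshold_fraction))
    return lags


def trials_to_plateau(
    mu: Sequence[float],
    true_value: float,
    block_start: int,
    block_end: int,
    band_fraction: float = 0.1,
):
    """First trial (1-based from block start) at which the inferred state
    enters and remains within ``band_fraction`` of the true value for the rest
    of the block; ``NO_SWITCH`` if it never does."""
    _check(true_value != 0.0, "plateau band is relative; true value must be nonzero")
    mu = np.asarray(mu, dtype=float)[block_start:block_end]
    inside = np.abs(mu - true_value) <= band_fraction * abs(true_value)
    # last index from which the trace stays inside through block end
    ok = np.flip(np.cumprod(np.flip(inside))).astype(bool)
    hits = np.nonzero(ok)[0]
    return int(hits[0]) + 1 if hits.size else NO_SWITCH


def trials_to_posterior_threshold(
    p_context: Sequence[float], switch_trial: int, threshold: float = 0.9
):
    """Trials after a switch until the posterior probability of the (new) true
    context first exceeds ``threshold``; ``NO_SWITCH`` if it never does."""
    p = np.asarray(p_context, dtype=float)
    _check(0 <= switch_trial < p.size, "switch_trial outside trace")
    hits = np.nonzero(p[switch_trial:] > threshold)[0]
    return int(hits[0]) if hits.size else NO_SWITCH


def error_after_switch(
    batch: BatchResult, switch_trial: int, horizon: int | None = None
) -> pd.DataFrame:
    """Cross-run mean ± SEM of the observed error indexed by trials since the
    switch."""
    n = batch.n_runs
    errs = np.stack([run["error"].to_numpy()[switch_trial:] for run in batch.runs])
    if horizon is not None:
        errs = errs[:, :horizon]
    mean = errs.mean(axis=0)
    sem = errs.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    return pd.DataFrame(
        {"trials_since_switch": np.arange(errs.shape[1]), "mean_error": mean, "sem_error": sem}
    )


def ec_decay_curve(
    batch: BatchResult, clamp_start_trial: int
) -> tuple[pd.DataFrame, np.ndarray]:
    """Adaptation (intended command) during an error-clamp block.

    Returns the cross-run mean ± SEM curve indexed from clamp onset, plus the
    per-run traces (n_runs x n_clamp_trials) for lag visualization."""
    n = batch.n_runs
    traces = np.stack([run["u"].to_numpy()[clamp_start_trial:] for run in batch.runs])
    mean = traces.mean(axis=0)
    sem = traces.std(axis=0, ddof=1) / math.sqrt(n) if n > 1 else np.zeros_like(mean)
    curve = pd.DataFrame(
        {"trials_since_clamp": np.arange(traces.shape[1]), "mean_u": mean, "sem_u": sem}
    )
    return curve, traces


# =====================================================================
# 4. Serialization: configs, trace CSVs, run manifests
# =====================================================================

_TASK_KEYS = {
    "context_adaptations": "true adaptation sizes x*_j",
    "adaptation_noise": "trial-to-trial adaptation noise sigma_a",
    "observation_noise": "true observation noise sigma_r*",
    "cues_present": "whether contextual cues are shown",
    "cue_uncertainty": "environment cue uncertainty eta",
    "blocks": "block schedule",
}
_AGENT_KEYS = {
    "p_self": "context self-transition p_zeta",
    "sigma_r": "assumed observation noise sigma_r",
    "sigma_u": "motor noise sigma_u",
    "eta": "assumed cue uncertainty eta",
    "hyperpriors": "per-context Normal-Gamma hyper-priors (mu0, nu0, alpha0, beta0)",
    "include_baseline": "whether the baseline context is modelled",
    "sigma_x_mode": "state-uncertainty convention for the prediction noise",
}
_BLOCK_KEYS = ("context_id", "n_trials", "is_error_clamp", "clamp_fraction")
_TOP_KEYS = ("study", "group", "n_runs", "root_seed", "task", "agent")


def _reject_unknown(d: Mapping, allowed: Iterable[str], where: str) -> None:
    unknown = [k for k in d if k not in set(allowed)]
    if unknown:
        known = ", ".join(allowed)
        raise ValidationError(f"unknown key(s) {unknown} in {where}; known keys: {known}")


def config_to_dict(cfg: StudyConfig) -> dict:
    """Plain-dict snapshot of a study config (YAML/JSON serializable)."""
    return {
        "study": cfg.study_id,
        "group": cfg.group_id,
        "n_runs": cfg.n_runs,
        "root_seed": cfg.root_seed,
        "task": {
            "context_adaptations": list(cfg.task.context_adaptations),
            "adaptation_noise": cfg.task.adaptation_noise,
            "observation_noise": cfg.task.observation_noise,
            "cues_present": cfg.task.cues_present,
            "cue_uncertainty": cfg.task.cue_uncertainty,
            "blocks": [
                {
                    "context_id": b.context_id,
                    "n_trials": b.n_trials,
                    "is_error_clamp": b.is_error_clamp,
                    "clamp_fraction": b.clamp_fraction,
                }
                for b in cfg.task.blocks
            ],
        },
        "agent": {
            "p_self": cfg.agent.p_self,
            "sigma_r": cfg.agent.sigma_r,
            "sigma_u": cfg.agent.sigma_u,
            "eta": cfg.agent.eta,
            "include_baseline": cfg.agent.include_baseline,
            "sigma_x_mode": cfg.agent.sigma_x_mode,
            "hyperpriors": [list(h) for h in cfg.agent.hyperpriors],
        },
    }


def config_from_dict(d: Mapping) -> StudyConfig:
    """Validated StudyConfig from a plain dict; unknown keys are rejected with
    a message naming the offending key and the model quantity it maps to."""
    _reject_unknown(d, _TOP_KEYS, "study config")
    for part, keys in (("task", _TASK_KEYS), ("agent", _AGENT_KEYS)):
        if part not in d:
            raise ValidationError(f"study config is missing the {part!r} section")
        _reject_unknown(d[part], keys, f"'{part}' section ({'; '.join(f'{k}: {v}' for k, v in keys.items())})")
    td = dict(d["task"])
    blocks = []
    for i, bd in enumerate(td.get("blocks", [])):
        _reject_unknown(bd, _BLOCK_KEYS, f"task.blocks[{i}]")
        blocks.append(Block(**{k: bd[k] for k in _BLOCK_KEYS if k in bd}))
    td["blocks"] = tuple(blocks)
    ad = dict(d["agent"])
    ad["hyperpriors"] = tuple(tuple(h) for h in ad.get("hyperpriors", ()))
    try:
        task = TaskConfig(**td)
        agent = AgentConfig(**ad)
    except ValidationError as err:
        raise ValidationError(f"invalid study config: {err}") from err
    return StudyConfig(
        study_id=str(d.get("study", "custom")),
        group_id=str(d.get("group", "custom")),
        task=task,
        agent=agent,
        n_runs=int(d.get("n_runs", 1)),
        root_seed=int(d.get("root_seed", 0)),
    )


def _deep_merge(base: dict, override: Mapping) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, Mapping) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out


def load_config(path: str | os.PathLike) -> StudyConfig:
    """Load a YAML or JSON study config.

    A file naming a shipped study (``study: oh2019_exp1``) starts from that
    study's full defaults; any other keys are merged over them, so a minimal
    file resolves every field.  Files without a ``study`` key must specify the
    full config.  Unknown keys are rejected.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, Mapping):
        raise ValidationError(f"config file {path} does not contain a mapping")
    _reject_unknown(raw, _TOP_KEYS, "study config")
    study = raw.get("study")
    if study in STUDY_IDS:
        base = make_config(study, raw.get("group"), root_seed=int(raw.get("root_seed", 0)))
        merged = _deep_merge(config_to_dict(base), raw)
        return config_from_dict(merged)
    if study is not None and "task" not in raw:
        raise ValidationError(
            f"unknown study {study!r}; available: {', '.join(STUDY_IDS)}"
        )
    return config_from_dict(raw)


@dataclass
class RunManifest:
    """Provenance sidecar: the config snapshot alone reproduces the batch."""

    study_id: str
    group_id: str
    root_seed: int
    version: str
    config: dict
    outputs: list[str]
    timestamp: str

    def to_json(self) -> str:
        return json.dumps(self.__dict__, indent=2, sort_keys=True)


_TRACE_FLOAT_FMT = "%.17g"  # 17 significant digits preserve bitwise replay


def _atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write via a temp file + rename so a failure leaves no partial file."""
    directory = os.path.dirname(os.fspath(path)) or "."
    fd, tmp = tempfile.mkstemp(dir=directory, suffix=".tmp")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_traces(batch: BatchResult, path: str | os.PathLike) -> RunManifest:
    """Write a batch as one CSV row per (run, trial) plus a JSON manifest
    sidecar at ``<path>.manifest.json``.  Floats are written at 17 significant
    digits so re-reading the CSV reconstructs the aggregates exactly."""
    directory = os.path.dirname(os.fspath(path)) or "."
    if not os.path.isdir(directory):
        raise IOError(f"output directory {directory!r} does not exist")
    if batch.runs:
        frames = [run.assign(run=i) for i, run in enumerate(batch.runs)]
        combined = pd.concat(frames, ignore_index=True)
        combined = combined[["run"] + [c for c in combined.columns if c != "run"]]
    else:
        combined = pd.DataFrame(columns=["run", "trial"])
    _atomic_write_text(path, combined.to_csv(index=False, float_format=_TRACE_FLOAT_FMT))
    manifest = RunManifest(
        study_id=batch.config.study_id,
        group_id=batch.config.group_id,
        root_seed=batch.config.root_seed,
        version=__version__,
        config=config_to_dict(batch.config),
        outputs=[os.fspath(path)],
        timestamp=datetime.now(timezone.utc).isoformat(),
    )
    _atomic_write_text(os.fspath(path) + ".manifest.json", manifest.to_json())
    return manifest


def read_traces(path: str | os.PathLike) -> list[pd.DataFrame]:
    """Read a trace CSV back into per-run DataFrames (inverse of
    :func:`write_traces` up to the added ``run`` column)."""
    combined = pd.read_csv(path, float_precision="round_trip")
    if combined.empty:
        return []
    return [
        g.drop(columns="run").reset_index(drop=True)
        for _, g in combined.groupby("run", sort=True)
    ]
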