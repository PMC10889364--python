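"""Learning rules, choice policy, working-memory comparator and simulation loop.

Two learning rules share the radial-basis value representation:

* traditional RL — each element's weight moves toward the obtained reward
  in proportion to its eligibility and the learning rate:

      w_b <- w_b + e_b(t) * alpha * [reward - w_b]

* information-compressing RL with selective maintenance — the same update
  plus decay of low-eligibility (spatiotemporally distant, nonpreferred)
  elements toward a prior h:

      w_b <- w_b + e_b(t) * alpha * [reward - w_b] - gamma * (1 - e_b(t)) * (w_b - h)

  With gamma = 0 the rule reduces exactly to traditional RL.  The decay
  compresses the information content (entropy) of the value map as
  preferred options are selectively maintained.

Choices are sampled from a softmax over the discretized response interval,
p(j) proportional to exp(V_j / beta); higher temperature beta yields more
stochastic, less value-sensitive choices.

The working-memory comparator stores the last k response times as a sum of
unit-height Gaussians on the same representational substrate (selection
history), plus a buffer of reward/omission outcomes; its information
content is the joint entropy of the two normalized buffers.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .basis import (
    BasisConfig,
    ValueState,
    _SQRT_2PI,
    eligibility,
    eligibility_matrix,
    basis_matrix,
    entropy,
    value_function,
    rt_vmax,
)

__all__ = [
    "AgentParams",
    "TrialRecord",
    "WMState",
    "update_traditional",
    "update_selective",
    "choice_probabilities",
    "softmax_policy",
    "wm_update",
    "wm_entropy",
    "run_agent",
    "replay",
    "LOG_COLUMNS",
]

LOG_COLUMNS = [
    "subject", "run", "trial", "contingency", "rt", "rt_bin", "reward",
    "rewarded", "entropy", "entropy_change", "rt_vmax", "v_max", "v_chosen",
    "pe",
]


@dataclass(frozen=True)
class AgentParams:
    """Free parameters of the learning agent.

    alpha : learning rate in (0, 1)
    beta  : softmax temperature > 0 (higher = more stochastic choice)
    gamma : selective-maintenance (decay) parameter in [0, 1]
    h     : decay target in points (0 by default)
    """

    alpha: float
    beta: float
    gamma: float = 0.0
    h: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.beta <= 0.0:
            raise ValueError("beta must be positive")
        if not 0.0 <= self.gamma <= 1.0:
            raise ValueError("gamma must lie in [0, 1]")


@dataclass(frozen=True)
class TrialRecord:
    """One choice/outcome event."""

    subject_id: int
    run_index: int
    trial_index: int
    contingency_label: str
    rt: float
    reward: float
    rewarded: bool
    rt_bin: int

    def __post_init__(self) -> None:
        if self.rt < 0 or self.reward < 0:
            raise ValueError("rt and reward must be nonnegative")


def _updated_weights(cfg: BasisConfig, state: ValueState, params: AgentParams,
                     rt: float, reward: float, gamma: float,
                     elig: np.ndarray | None = None) -> np.ndarray:
    e = eligibility(cfg, rt) if elig is None else elig
    w = state.weights
    w_new = w + e * params.alpha * (reward - w)
    if gamma != 0.0:
        w_new = w_new - gamma * (1.0 - e) * (w - params.h)
    return w_new


def update_traditional(cfg: BasisConfig, state: ValueState,
                       params: AgentParams, trial: TrialRecord,
                       elig: np.ndarray | None = None) -> ValueState:
    """Eligibility-weighted delta-rule update toward the obtained reward."""
    w = _updated_weights(cfg, state, params, trial.rt, trial.reward, 0.0, elig)
    return ValueState(w, trial.trial_index + 1)


def update_selective(cfg: BasisConfig, state: ValueState,
                     params: AgentParams, trial: TrialRecord,
                     elig: np.ndarray | None = None) -> ValueState:
    """Traditional update plus decay of low-eligibility weights toward h."""
    w = _updated_weights(cfg, state, params, trial.rt, trial.reward,
                         params.gamma, elig)
    return ValueState(w, trial.trial_index + 1)


_RULES = {"traditional": update_traditional, "selective": update_selective}


def softmax_policy(v, beta: float) -> np.ndarray:
    """Softmax over a value vector, p_j ~ exp(v_j / beta), computed with
    max-subtraction so it is numerically stable and exactly invariant to
    adding a constant to v."""
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("value function contains nonfinite entries")
    if beta <= 0:
        raise ValueError("beta must be positive")
    z = v / beta
    z = z - z.max()
    ez = np.exp(z)
    return ez / ez.sum()


def choice_probabilities(cfg: BasisConfig, state: ValueState,
                         params: AgentParams) -> np.ndarray:
    """Softmax choice distribution over the response bins, p_j ~ exp(V_j/beta)."""
    return softmax_policy(value_function(cfg, state), params.beta)


# ---------------------------------------------------------------------------
# Working-memory comparator
# ---------------------------------------------------------------------------

@dataclass
class WMState:
    """Buffer of the last k choices (selection history) and outcomes."""

    k: int = 4
    rt_buffer: list = field(default_factory=list)
    outcome_buffer: list = field(default_factory=list)
    wm_weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("buffer length k must be >= 1")


def selection_history(cfg: BasisConfig, rts, x) -> np.ndarray:
    """s(x) = sum of unit-height Gaussians (variance s_g^2) at buffered RTs."""
    x = np.asarray(x, dtype=float)
    s = np.zeros_like(x)
    for t in rts:
        s += np.exp(-0.5 * (x - t) ** 2 / cfg.gen_width_sq)
    return s


def wm_update(cfg: BasisConfig, wm: WMState, trial: TrialRecord) -> WMState:
    """Push the trial into the buffers and rebuild the WM basis weights.

    wm_weights_b = integral s(tau) phi_b~(tau) dtau with phi density-
    normalized, so each buffered choice contributes at most 1 per element.
    """
    rts = (wm.rt_buffer + [trial.rt])[-wm.k:]
    outcomes = (wm.outcome_buffer + [1 if trial.rewarded else 0])[-wm.k:]
    tau = cfg.quad_grid()
    s = selection_history(cfg, rts, tau)
    phi = (np.exp(-0.5 * (tau[:, None] - cfg.centers[None, :]) ** 2
                  / cfg.basis_width_sq) / (cfg.basis_sd * _SQRT_2PI))
    w = np.trapezoid(s[:, None] * phi, tau, axis=0)
    return WMState(wm.k, rts, outcomes, w)


def wm_entropy(wm: WMState) -> float:
    """Joint information content: H(normalized wm weights) + H(normalized outcomes).

    All-zero buffers contribute 0 (an empty buffer carries no information,
    unlike the value map where zero evidence means maximal uncertainty).
    """
    h_w = 0.0
    if wm.wm_weights is not None:
        h_w = entropy(wm.wm_weights, empty="zero")
    h_o = entropy(np.asarray(wm.outcome_buffer, dtype=float), empty="zero") \
        if wm.outcome_buffer else 0.0
    return h_w + h_o


# ---------------------------------------------------------------------------
# Closed simulation loop and forced-choice replay
# ---------------------------------------------------------------------------

def _as_contingency_sequence(env, n_trials: int):
    if hasattr(env, "p") and callable(getattr(env, "p")):
        return [env] * n_trials
    env = list(env)
    if len(env) != n_trials:
        raise ValueError("contingency sequence length must equal n_trials")
    return env


def run_agent(cfg: BasisConfig, params: AgentParams, env, n_trials: int,
              rule: str = "selective", seed=None, rng=None,
              init: str = "random", w0: float = 1.0,
              subject_id: int = 0, run_index: int = 0,
              track_wm: bool = False):
    """Simulate a closed loop of choices and outcomes.

    Per trial: the pre-choice value function defines the softmax policy; a
    response bin is sampled and mapped to its bin-center time; the outcome
    is drawn from the contingency (rewarded ~ Bernoulli(p(rt)), reward =
    m(rt) on reward else 0, both evaluated at the continuous RT); weights
    update under ``rule``.  Entropy H is recorded before the update
    (decision-aligned) and the entropy change dH = H_after - H_before is
    feedback-aligned.

    Returns (log DataFrame, weight trajectory of shape (n_trials+1, B)).
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}")
    if rng is None:
        rng = np.random.default_rng(seed)
    envs = _as_contingency_sequence(env, n_trials)

    if init == "random":
        state = ValueState.random_uniform(cfg, rng, w0)
    elif init == "zeros":
        state = ValueState.zeros(cfg)
    else:
        raise ValueError("init must be 'random' or 'zeros'")

    wm = WMState() if track_wm else None
    update = _RULES[rule]
    traj = np.empty((n_trials + 1, cfg.n_elements))
    traj[0] = state.weights
    rows = []
    for i in range(n_trials):
        con = envs[i]
        v = value_function(cfg, state)
        h_pre = entropy(state.weights)
        p = choice_probabilities(cfg, state, params)
        j = int(rng.choice(cfg.n_bins, p=p))
        rt = float(cfg.bin_centers[j])
        rewarded = bool(rng.random() < con.p(rt))
        reward = float(con.m(rt)) if rewarded else 0.0
        trial = TrialRecord(subject_id, run_index, i, con.label, rt, reward,
                            rewarded, j)
        state = update(cfg, state, params, trial)
        traj[i + 1] = state.weights
        h_post = entropy(state.weights)
        row = {
            "subject": subject_id, "run": run_index, "trial": i,
            "contingency": con.label, "rt": rt, "rt_bin": j,
            "reward": reward, "rewarded": int(rewarded),
            "entropy": h_pre, "entropy_change": h_post - h_pre,
            "rt_vmax": float(cfg.bin_centers[int(np.argmax(v))]),
            "v_max": float(v.max()), "v_chosen": float(v[j]),
            "pe": reward - float(v[j]),
        }
        if track_wm:
            wm = wm_update(cfg, wm, trial)
            row["wm_entropy"] = wm_entropy(wm)
        rows.append(row)
    return pd.DataFrame(rows), traj


def replay(cfg: BasisConfig, params: AgentParams, rule: str, rts, rewards,
           w_init: np.ndarray | None = None, elig: np.ndarray | None = None):
    """Deterministically rebuild latent states from a forced choice/outcome
    sequence.

    Returns a dict with the weight trajectory ``weights`` (n+1, B), the
    pre-choice value functions ``V`` (n, n_bins) and per-trial series
    ``entropy`` (pre-update), ``entropy_change``, ``rt_vmax``, ``v_max``,
    ``v_chosen`` and scalar ``pe``.
    """
    if rule not in _RULES:
        raise ValueError(f"unknown rule {rule!r}")
    rts = np.asarray(rts, dtype=float)
    rewards = np.asarray(rewards, dtype=float)
    n = rts.size
    if rewards.size != n:
        raise ValueError("rts and rewards must have equal length")
    if elig is None:
        elig = eligibility_matrix(cfg, rts)
    gamma = params.gamma if rule == "selective" else 0.0
    phi_bins = basis_matrix(cfg)
    w = np.zeros(cfg.n_elements) if w_init is None else np.asarray(w_init, float).copy()

    weights = np.empty((n + 1, cfg.n_elements))
    weights[0] = w
    V = np.empty((n, cfg.n_bins))
    H = np.empty(n)
    dH = np.empty(n)
    rtv = np.empty(n)
    vmax = np.empty(n)
    vch = np.empty(n)
    pe = np.empty(n)
    state = ValueState(w)
    for i in range(n):
        v = phi_bins @ state.weights
        V[i] = v
        H[i] = entropy(state.weights)
        k = int(np.argmax(v))
        rtv[i] = cfg.bin_centers[k]
        vmax[i] = v[k]
        j = cfg.rt_to_bin(rts[i])
        vch[i] = v[j]
        pe[i] = rewards[i] - v[j]
        w_new = state.weights + elig[i] * params.alpha * (rewards[i] - state.weights)
        if gamma != 0.0:
            w_new = w_new - gamma * (1.0 - elig[i]) * (state.weights - params.h)
        state = ValueState(w_new, i + 1)
        weights[i + 1] = state.weights
        dH[i] = entropy(state.weights) - H[i]
    return {"weights": weights, "V": V, "entropy": H, "entropy_change": dH,
            "rt_vmax": rtv, "v_max": vmax, "v_chosen": vch, "pe": pe}
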