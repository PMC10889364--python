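"""Hierarchical fitting of the learning models to trial logs.

The softmax choice rule defines the likelihood of each observed response
bin given the deterministically replayed latent value function, so the
per-subject negative log-likelihood is

    NLL = - sum_i log p(rt_bin_i | V_i, beta)

with V_i rebuilt from the subject's own choices and outcomes (zero initial
weights, re-initialized at run boundaries by default).

Subject-level estimation is MAP with a Gaussian prior on transformed
parameters (logit alpha, log beta, logit gamma) and a Laplace (inverse
Hessian) posterior SD — a deliberate, fully specified approximation to the
variational scheme this family of models is usually fitted with.  The
population loop is empirical Bayes: it alternates subject MAP fits with
moment updates of the parent Gaussian (mean of posterior modes; variance =
mean of posterior variances + variance of modes), shrinking individual
estimates toward the group.

Model comparison uses AIC = 2k - 2 logL summed over subjects, with the
traditional-RL model carrying two free parameters (alpha, beta) and the
selective-maintenance model three (alpha, beta, gamma).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit, logit

from .agents import AgentParams, replay
from .basis import BasisConfig, basis_matrix, eligibility_matrix
from .task import CohortSpec, SessionDesign, generate_cohort

__all__ = [
    "ParamTransform",
    "FitResult",
    "SubjectFit",
    "negative_log_likelihood",
    "fit_subject",
    "fit_population",
    "refit_at_group_means",
    "compare_models",
    "recover_parameters",
    "PARAM_NAMES",
]

PARAM_NAMES = {"traditional": ("alpha", "beta"),
               "selective": ("alpha", "beta", "gamma")}


class ParamTransform:
    """Bijections between the unconstrained fitting scale and native bounds:
    logistic for alpha and gamma, log for beta."""

    _FORWARD = {"alpha": logit, "beta": np.log, "gamma": logit}
    _INVERSE = {"alpha": expit, "beta": np.exp, "gamma": expit}

    def __init__(self, rule: str):
        if rule not in PARAM_NAMES:
            raise ValueError(f"unknown rule {rule!r}")
        self.rule = rule
        self.names = PARAM_NAMES[rule]

    def to_unconstrained(self, native: dict) -> np.ndarray:
        return np.array([float(self._FORWARD[n](native[n])) for n in self.names])

    def to_native(self, u: np.ndarray) -> dict:
        out = {}
        for n, ui in zip(self.names, u):
            v = float(self._INVERSE[n](np.clip(ui, -60.0, 60.0)))
            if n in ("alpha", "gamma"):
                # keep strictly inside (0, 1) under float saturation
                v = float(np.clip(v, 1e-12, 1.0 - 1e-12))
            out[n] = v
        return out

    def agent_params(self, u: np.ndarray) -> AgentParams:
        d = self.to_native(u)
        return AgentParams(alpha=d["alpha"], beta=d["beta"],
                           gamma=d.get("gamma", 0.0))


# ---------------------------------------------------------------------------
# Likelihood
# ---------------------------------------------------------------------------

def _prepare_log(cfg: BasisConfig, log: pd.DataFrame, reinit_per_run: bool):
    """Split a subject log into run segments with precomputed eligibility.

    Eligibility depends only on the basis geometry and the observed RTs, so
    it is computed once per log and reused across optimizer iterations.
    Trials with a missing RT (no response) are dropped from the likelihood.
    """
    log = log.dropna(subset=["rt"]).sort_values(["run", "trial"])
    segments = []
    groups = log.groupby("run", sort=True) if reinit_per_run else [(0, log)]
    for _, seg in groups:
        rts = seg["rt"].to_numpy(dtype=float)
        rewards = seg["reward"].to_numpy(dtype=float)
        bins = np.array([cfg.rt_to_bin(t) for t in rts])
        if np.any((bins < 0) | (bins >= cfg.n_bins)):
            raise ValueError("rt_bin out of range")
        elig = eligibility_matrix(cfg, rts)
        segments.append((rts, rewards, bins, elig))
    return segments


def _segment_nll(cfg, phi_bins, params: AgentParams, gamma, rewards, bins, elig):
    w = np.zeros(cfg.n_elements)
    alpha = params.alpha
    inv_beta = 1.0 / params.beta
    nll = 0.0
    for i in range(rewards.size):
        z = (phi_bins @ w) * inv_beta
        zmax = z.max()
        nll -= z[bins[i]] - zmax - np.log(np.exp(z - zmax).sum())
        e = elig[i]
        w_new = w + e * alpha * (rewards[i] - w)
        if gamma != 0.0:
            w_new = w_new - gamma * (1.0 - e) * w
        w = w_new
    return nll


def negative_log_likelihood(cfg: BasisConfig, params: AgentParams, rule: str,
                            log: pd.DataFrame, reinit_per_run: bool = True,
                            _segments=None) -> float:
    """NLL of the observed response bins under the replayed value function."""
    if rule not in PARAM_NAMES:
        raise ValueError(f"unknown rule {rule!r}")
    segments = _segments if _segments is not None \
        else _prepare_log(cfg, log, reinit_per_run)
    phi_bins = basis_matrix(cfg)
    gamma = params.gamma if rule == "selective" else 0.0
    nll = sum(_segment_nll(cfg, phi_bins, params, gamma, rewards, bins, elig)
              for _, rewards, bins, elig in segments)
    if not np.isfinite(nll):
        raise FloatingPointError("nonfinite negative log-likelihood")
    return float(nll)


# ---------------------------------------------------------------------------
# Subject-level MAP + Laplace
# ---------------------------------------------------------------------------

@dataclass
class SubjectFit:
    subject: int
    rule: str
    mode: np.ndarray            # transformed scale
    sd: np.ndarray              # Laplace SD, transformed scale
    native: dict
    nll: float                  # data NLL at the mode (no prior)
    converged: bool
    n_trials: int


def _fd_hessian(f, x, step: float = 1e-3) -> np.ndarray:
    d = x.size
    h = step * (1.0 + np.abs(x))
    H = np.empty((d, d))
    f0 = f(x)
    for i in range(d):
        ei = np.zeros(d); ei[i] = h[i]
        H[i, i] = (f(x + ei) - 2.0 * f0 + f(x - ei)) / h[i] ** 2
        for j in range(i + 1, d):
            ej = np.zeros(d); ej[j] = h[j]
            H[i, j] = H[j, i] = (
                f(x + ei + ej) - f(x + ei - ej) - f(x - ei + ej)
                + f(x - ei - ej)) / (4.0 * h[i] * h[j])
    return H


def _laplace_sd(f, mode: np.ndarray, prior_sd: np.ndarray) -> np.ndarray:
    H = _fd_hessian(f, mode)
    try:
        cov = np.linalg.inv(H)
        sd = np.sqrt(np.diag(cov))
        if np.all(np.isfinite(sd)) and np.all(sd > 0):
            return sd
    except np.linalg.LinAlgError:
        pass
    # non-PD curvature at a boundary-ish mode: fall back to the prior scale
    return prior_sd.copy()


def fit_subject(cfg: BasisConfig, rule: str, log: pd.DataFrame,
                prior_mean: np.ndarray, prior_sd: np.ndarray, seed=None,
                n_starts: int = 5, x0: np.ndarray | None = None,
                reinit_per_run: bool = True) -> SubjectFit:
    """MAP estimate (multistart quasi-Newton) with Laplace posterior SDs.

    The objective is NLL + Gaussian negative log-prior on the transformed
    scale.  Starts are drawn around the prior mean; an explicit ``x0``
    (e.g. a warm start from a previous empirical-Bayes iteration) is used
    as an additional start.
    """
    tf = ParamTransform(rule)
    prior_mean = np.asarray(prior_mean, dtype=float)
    prior_sd = np.asarray(prior_sd, dtype=float)
    if np.any(prior_sd <= 0):
        raise ValueError("prior SDs must be positive")
    segments = _prepare_log(cfg, log, reinit_per_run)
    n_trials = int(sum(s[0].size for s in segments))
    rng = np.random.default_rng(seed)

    def objective(u):
        params = tf.agent_params(u)
        nll = negative_log_likelihood(cfg, params, rule, log,
                                      _segments=segments)
        return nll + 0.5 * np.sum(((u - prior_mean) / prior_sd) ** 2)

    starts = [prior_mean] + [prior_mean + prior_sd * rng.standard_normal(prior_mean.size)
                             for _ in range(max(0, n_starts - 1))]
    if x0 is not None:
        starts.insert(0, np.asarray(x0, dtype=float))
    best = None
    any_ok = False
    for s in starts:
        res = minimize(objective, np.clip(s, -19.0, 19.0), method="L-BFGS-B",
                       bounds=[(-20.0, 20.0)] * prior_mean.size,
                       options={"maxiter": 200, "ftol": 1e-9})
        any_ok = any_ok or res.success
        if best is None or res.fun < best.fun:
            best = res
    mode = best.x
    sd = _laplace_sd(objective, mode, prior_sd)
    params = tf.agent_params(mode)
    nll = negative_log_likelihood(cfg, params, rule, log, _segments=segments)
    return SubjectFit(subject=int(log["subject"].iloc[0]), rule=rule,
                      mode=mode, sd=sd, native=tf.to_native(mode), nll=nll,
                      converged=bool(any_ok), n_trials=n_trials)


# ---------------------------------------------------------------------------
# Empirical-Bayes population loop
# ---------------------------------------------------------------------------

@dataclass
class FitResult:
    rule: str
    subjects: pd.DataFrame       # one row per subject: modes, SDs, NLL, AIC
    pop_mean: np.ndarray         # transformed scale
    pop_sd: np.ndarray
    n_params: int
    total_nll: float
    total_aic: float
    trace: list
    converged: bool
    data_fingerprint: str = ""

    @property
    def param_names(self):
        return PARAM_NAMES[self.rule]


def _fingerprint(logs: pd.DataFrame) -> str:
    cols = ["subject", "run", "trial", "rt", "reward"]
    raw = logs[cols].round(9).to_csv(index=False).encode()
    return hashlib.sha1(raw).hexdigest()


def fit_population(cfg: BasisConfig, rule: str, logs: pd.DataFrame,
                   init: dict | None = None, tol: float = 0.01,
                   max_iter: int = 50, seed=0, n_starts: int = 5,
                   reinit_per_run: bool = True) -> FitResult:
    """Alternate subject MAP fits and population-moment updates until the
    population means move less than ``tol`` on the transformed scale.

    After the first iteration each subject fit is warm-started from its
    previous mode with a single additional start.
    """
    tf = ParamTransform(rule)
    names = tf.names
    subjects = sorted(logs["subject"].unique())
    if len(subjects) < 2:
        raise ValueError("population fit needs at least 2 subjects")
    if init is None:
        init = {"alpha": (-2.0, 1.0), "beta": (2.0, 1.0), "gamma": (-1.0, 1.0)}
    mu = np.array([init[n][0] for n in names])
    sd = np.array([init[n][1] for n in names])

    by_subject = {s: logs[logs["subject"] == s] for s in subjects}
    fits: dict[int, SubjectFit] = {}
    trace = []
    converged = False
    for it in range(max_iter):
        for s in subjects:
            warm = fits[s].mode if s in fits else None
            fits[s] = fit_subject(
                cfg, rule, by_subject[s], mu, sd,
                seed=np.random.default_rng([seed, it, int(s)]).integers(2**31),
                n_starts=n_starts if it == 0 else 1, x0=warm,
                reinit_per_run=reinit_per_run)
        modes = np.array([fits[s].mode for s in subjects])
        variances = np.array([fits[s].sd ** 2 for s in subjects])
        new_mu = modes.mean(axis=0)
        new_var = variances.mean(axis=0) + modes.var(axis=0)
        shift = float(np.max(np.abs(new_mu - mu)))
        trace.append({"iteration": it, "pop_mean": new_mu.copy(),
                      "pop_sd": np.sqrt(new_var), "max_shift": shift})
        mu = new_mu
        sd = np.sqrt(np.maximum(new_var, 1e-8))
        if shift < tol:
            converged = True
            break

    k = len(names)
    rows = []
    for s in subjects:
        f = fits[s]
        row = {"subject": s, "nll": f.nll, "aic": 2 * k + 2 * f.nll,
               "converged": f.converged, "n_trials": f.n_trials}
        for i, n in enumerate(names):
            row[f"{n}_mode"] = f.mode[i]
            row[f"{n}_sd"] = f.sd[i]
            row[n] = f.native[n]
        rows.append(row)
    subj_df = pd.DataFrame(rows)
    total_nll = float(subj_df["nll"].sum())
    return FitResult(rule=rule, subjects=subj_df, pop_mean=mu, pop_sd=sd,
                     n_params=k, total_nll=total_nll,
                     total_aic=float(subj_df["aic"].sum()), trace=trace,
                     converged=converged, data_fingerprint=_fingerprint(logs))


def refit_at_group_means(cfg: BasisConfig, rule: str, logs: pd.DataFrame,
                         group_means: dict, reinit_per_run: bool = True) -> pd.DataFrame:
    """Recompute latent trajectories for every subject with parameters fixed
    at the group means (no optimization).

    Only the latent states (weights, entropy, entropy change, RT_Vmax,
    prediction errors) are recomputed from each subject's own choices and
    outcomes, so regression coefficients on these signals are comparable
    across subjects.
    """
    params = AgentParams(alpha=group_means["alpha"], beta=group_means["beta"],
                         gamma=group_means.get("gamma", 0.0))
    out = []
    keys = ["subject", "run"] if reinit_per_run else ["subject"]
    for _, seg in logs.dropna(subset=["rt"]).groupby(keys, sort=True):
        seg = seg.sort_values("trial")
        lat = replay(cfg, params, rule, seg["rt"].to_numpy(),
                     seg["reward"].to_numpy())
        block = seg.copy()
        for col in ("entropy", "entropy_change", "rt_vmax", "v_max",
                    "v_chosen", "pe"):
            block[col] = lat[col]
        out.append(block)
    return pd.concat(out, ignore_index=True)


def compare_models(results: dict) -> pd.DataFrame:
    """Summed-AIC comparison table across fitted models on identical data.

    ``delta_aic`` is AIC_model - min AIC, so the best model has 0 and lower
    AIC is better.
    """
    prints = {name: r.data_fingerprint for name, r in results.items()}
    if len(set(prints.values())) > 1:
        raise ValueError("models were fitted to different data; refusing to "
                         "compare AICs")
    rows = [{"model": name, "n_params": r.n_params, "nll": r.total_nll,
             "aic": r.total_aic} for name, r in results.items()]
    df = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df


def recover_parameters(spec: CohortSpec, design: SessionDesign,
                       rule: str = "selective", seed: int = 0,
                       cfg: BasisConfig | None = None, out=None,
                       n_starts: int = 5, tol: float = 0.01,
                       max_iter: int = 50):
    """Full generate -> fit -> compare loop.

    Simulates a cohort from ``spec``, fits it with the empirical-Bayes
    loop, and reports truth-estimate correlation, bias and RMSE per
    parameter.  Returns (report DataFrame, truth-vs-estimate DataFrame,
    FitResult); writes the report to ``out`` when given.
    """
    spec = CohortSpec(spec.n_subjects, spec.mu, spec.sd, seed)
    cfg = cfg or design.basis_config()
    logs, truth = generate_cohort(spec, design, rule=rule, cfg=cfg)
    fit = fit_population(cfg, rule, logs, seed=seed, n_starts=n_starts,
                         tol=tol, max_iter=max_iter)
    merged = truth.merge(fit.subjects, on="subject",
                         suffixes=("_true", "_hat"))
    rows = []
    for n in PARAM_NAMES[rule]:
        t = merged[f"{n}_true"].to_numpy()
        e = merged[f"{n}_hat"].to_numpy()
        r = float(np.corrcoef(t, e)[0, 1]) if np.std(t) > 0 and np.std(e) > 0 else np.nan
        rows.append({"param": n, "correlation": r,
                     "bias": float(np.mean(e - t)),
                     "rmse": float(np.sqrt(np.mean((e - t) ** 2)))})
    report = pd.DataFrame(rows)
    if out is not None:
        report.to_csv(out, sep="\t", index=False)
    return report, merged, fit
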