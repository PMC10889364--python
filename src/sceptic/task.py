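"""Clock-task environments, session designs, cohorts and synthetic neural data.

The clock task asks *when* to respond within a trial interval (4 s, or 5 s
in the replication design).  Reward probability p(t) and magnitude m(t)
vary monotonically with the chosen response time under four contingencies:

* IEV — increasing expected value (learnable; later is better),
* DEV — decreasing expected value (learnable; earlier is better),
* CEV — constant expected value (unlearnable),
* CEVR — constant expected value with the probability/magnitude trade-off
  reversed relative to CEV (probability rises where CEV's falls).

The exact p/m functional forms used in the original experiments are not
part of this package's contract; the default family below (linear monotone
magnitudes, affine expected value, p = ev/m clipped to [0.05, 0.95])
preserves the four qualitative regimes and is fully overridable.

Session designs ship as presets: ``fmri_original`` (8 runs x 50 trials,
4 s), ``meg_original`` (8 x 63, 4 s) and ``replication`` (240 trials, 5 s,
unsignaled contingency reversal every 40 trials, alternating IEV/DEV).

``synth_neural`` emulates trial x time deconvolved neural responses as a
linear combination of trial-level model signals with known effect curves,
subject random intercepts and Gaussian noise, for testing the design and
analysis modules.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .agents import AgentParams, run_agent
from .basis import BasisConfig

__all__ = [
    "Contingency",
    "SessionDesign",
    "CohortSpec",
    "make_contingency",
    "design_preset",
    "reversal_trials",
    "generate_session",
    "generate_cohort",
    "synth_neural",
    "DEFAULT_POPULATION",
]

CONTINGENCY_LABELS = ("IEV", "DEV", "CEV", "CEVR")

P_CLIP = (0.05, 0.95)


@dataclass(frozen=True)
class Contingency:
    """A reward environment: probability and magnitude schedules over time."""

    label: str
    p: callable
    m: callable

    def ev(self, t):
        return self.p(t) * self.m(t)


def _affine(lo: float, hi: float, T: float):
    def f(t):
        return lo + (hi - lo) * np.asarray(t, dtype=float) / T
    return f


# Endpoint values of m(t) and ev(t) on [0, T]; chosen to keep expected value
# in the tens of points and p(t) inside [0.05, 0.95] without clipping.
_DEFAULT_EV_PARAMS = {
    "CEV": {"m": (50.0, 150.0), "ev": (40.0, 40.0)},
    "CEVR": {"m": (150.0, 50.0), "ev": (40.0, 40.0)},
    "IEV": {"m": (50.0, 150.0), "ev": (25.0, 65.0)},
    "DEV": {"m": (150.0, 50.0), "ev": (65.0, 25.0)},
}


def make_contingency(label: str, T: float = 4.0, ev_params: dict | None = None) -> Contingency:
    """Build one of the four clock-task contingencies on the interval [0, T].

    ``ev_params`` may override the endpoint values ``{"m": (m0, mT),
    "ev": (ev0, evT)}``.  Raises if the implied p = ev/m leaves [0, 1]
    anywhere on the interval (silent clipping is only applied within
    [0.05, 0.95]).
    """
    if label not in CONTINGENCY_LABELS:
        raise ValueError(f"unknown contingency {label!r}")
    params = dict(_DEFAULT_EV_PARAMS[label])
    if ev_params:
        params.update(ev_params)
    m_fn = _affine(*params["m"], T)
    ev_fn = _affine(*params["ev"], T)

    grid = np.linspace(0.0, T, 401)
    with np.errstate(divide="ignore", invalid="ignore"):
        p_raw = ev_fn(grid) / m_fn(grid)
    if np.any(p_raw < 0) or np.any(p_raw > 1) or not np.all(np.isfinite(p_raw)):
        raise ValueError(
            f"{label}: ev/m leaves [0, 1] on the interval; adjust ev_params")

    def p_fn(t):
        return np.clip(ev_fn(t) / m_fn(t), *P_CLIP)

    return Contingency(label, p_fn, m_fn)


@dataclass(frozen=True)
class SessionDesign:
    """Run/trial structure of one experimental session."""

    name: str
    n_runs: int
    trials_per_run: int
    trial_length: float = 4.0
    contingencies: tuple = ("IEV",)  # per-run labels, cycled over runs
    reversal_every: int | None = None
    feedback_duration: float = 0.9
    iti_mean: float = 2.0
    iti_max: float = 8.0

    @property
    def n_trials(self) -> int:
        return self.n_runs * self.trials_per_run

    def basis_config(self, **overrides) -> BasisConfig:
        return BasisConfig(interval_length=self.trial_length, **overrides)

    def run_schedule(self, run: int) -> list:
        """Per-trial contingency labels for one (0-based) run."""
        labels = self.contingencies
        if self.reversal_every is None:
            return [labels[run % len(labels)]] * self.trials_per_run
        out = []
        for i in range(self.trials_per_run):
            block = (run * self.trials_per_run + i) // self.reversal_every
            out.append(labels[block % len(labels)])
        return out


_PRESETS = {
    "fmri_original": SessionDesign(
        "fmri_original", n_runs=8, trials_per_run=50, trial_length=4.0,
        contingencies=("IEV", "DEV", "CEV", "CEVR")),
    "meg_original": SessionDesign(
        "meg_original", n_runs=8, trials_per_run=63, trial_length=4.0,
        contingencies=("IEV", "DEV", "CEV", "CEVR")),
    "replication": SessionDesign(
        "replication", n_runs=1, trials_per_run=240, trial_length=5.0,
        contingencies=("IEV", "DEV"), reversal_every=40),
}


def design_preset(name: str) -> SessionDesign:
    try:
        return _PRESETS[name]
    except KeyError:
        raise ValueError(f"unknown design preset {name!r}; "
                         f"choose from {sorted(_PRESETS)}") from None


def reversal_trials(design: SessionDesign) -> list:
    """1-based trial indices (within the session) at which the contingency
    switches; the first block has no preceding reversal."""
    if design.reversal_every is None:
        return []
    return list(range(design.reversal_every + 1, design.n_trials + 1,
                      design.reversal_every))


def generate_session(design: SessionDesign, agent: AgentParams,
                     rule: str = "selective", seed=None, rng=None,
                     cfg: BasisConfig | None = None, subject_id: int = 0,
                     init: str = "random") -> pd.DataFrame:
    """Simulate a full session: one ``run_agent`` call per run, reversals
    applied silently at block boundaries, ITIs drawn (exponential,
    truncated) and event onsets recorded for the design module.

    The agent's state is never reset at a reversal (the manipulation is
    unsignaled); weights re-initialize at run boundaries, which are
    separate blocks in the original designs.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    cfg = cfg or design.basis_config()
    cons = {lab: make_contingency(lab, design.trial_length)
            for lab in set(l for r in range(design.n_runs)
                           for l in design.run_schedule(r))}
    logs = []
    for r in range(design.n_runs):
        schedule = [cons[lab] for lab in design.run_schedule(r)]
        log, traj = run_agent(cfg, agent, schedule, design.trials_per_run,
                              rule=rule, rng=rng, init=init,
                              subject_id=subject_id, run_index=r)
        itis = np.minimum(rng.exponential(design.iti_mean, len(log)),
                          design.iti_max)
        onsets = np.empty(len(log))
        t0 = 0.0
        for i, (rt, iti) in enumerate(zip(log["rt"], itis)):
            onsets[i] = t0
            t0 += rt + design.feedback_duration + iti
        log["iti"] = itis
        log["trial_onset"] = onsets
        log["feedback_onset"] = onsets + log["rt"].to_numpy()
        log["block"] = ((log["run"] * design.trials_per_run + log["trial"])
                        // (design.reversal_every or design.n_trials))
        logs.append(log)
    out = pd.concat(logs, ignore_index=True)
    out["session_trial"] = np.arange(len(out))
    return out


DEFAULT_POPULATION = {
    # transformed-scale (logit alpha, log beta, logit gamma) moments
    "alpha": (-2.2, 0.4),
    "beta": (2.1, 0.35),
    "gamma": (-0.85, 0.5),
}


@dataclass(frozen=True)
class CohortSpec:
    """Population distribution of agent parameters on transformed scales.

    ``mu``/``sd`` map parameter name -> mean/SD of (logit alpha, log beta,
    logit gamma); inverse transforms keep draws inside the native bounds.
    """

    n_subjects: int
    mu: dict = field(default_factory=lambda: {k: v[0] for k, v in DEFAULT_POPULATION.items()})
    sd: dict = field(default_factory=lambda: {k: v[1] for k, v in DEFAULT_POPULATION.items()})
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("a cohort needs at least 2 subjects")
        if any(s < 0 for s in self.sd.values()):
            raise ValueError("population SDs must be nonnegative")


def _expit(x):
    return 1.0 / (1.0 + np.exp(-x))


def draw_cohort_params(spec: CohortSpec, rng=None) -> pd.DataFrame:
    rng = rng or np.random.default_rng(spec.seed)
    rows = []
    for s in range(spec.n_subjects):
        a = _expit(rng.normal(spec.mu["alpha"], spec.sd["alpha"]))
        b = float(np.exp(rng.normal(spec.mu["beta"], spec.sd["beta"])))
        g = _expit(rng.normal(spec.mu["gamma"], spec.sd["gamma"]))
        rows.append({"subject": s, "alpha": float(a), "beta": b,
                     "gamma": float(g)})
    return pd.DataFrame(rows)


def generate_cohort(spec: CohortSpec, design: SessionDesign,
                    rule: str = "selective", cfg: BasisConfig | None = None,
                    init: str = "random"):
    """Simulate every subject of a cohort.

    Returns (concatenated trial log, truth table of generating parameters).
    """
    rng = np.random.default_rng(spec.seed)
    truth = draw_cohort_params(spec, rng)
    cfg = cfg or design.basis_config()
    logs = []
    for row in truth.itertuples(index=False):
        agent = AgentParams(alpha=row.alpha, beta=row.beta, gamma=row.gamma)
        log = generate_session(design, agent, rule=rule, rng=rng, cfg=cfg,
                               subject_id=int(row.subject), init=init)
        logs.append(log)
    return pd.concat(logs, ignore_index=True), truth


def synth_neural(logs: pd.DataFrame, effect_map: dict, noise_sd: float = 0.5,
                 seed=None, time_step: float = 1.0, window=(-4.0, 4.0),
                 subject_intercept_sd: float = 0.5, regions=("DAN",)):
    """Trial x time synthetic neural responses around feedback.

    response(trial, time) = sum_signals effect_map[signal](time) * signal(trial)
                            + subject intercept + N(0, noise_sd)

    ``effect_map`` maps a log column name (e.g. ``entropy_change``) to a
    callable of peri-feedback time or an array over the grid.  Returns
    (long DataFrame with subject/trial/region/time/response, ground-truth
    effect-curve DataFrame).
    """
    required = set(effect_map)
    missing = required - set(logs.columns)
    if missing:
        raise ValueError(f"log is missing signal columns {sorted(missing)}")
    rng = np.random.default_rng(seed)
    grid = np.arange(window[0], window[1] + time_step / 2, time_step)
    curves = {}
    for name, eff in effect_map.items():
        curves[name] = np.asarray([eff(t) for t in grid], dtype=float) \
            if callable(eff) else np.asarray(eff, dtype=float)
        if curves[name].shape != grid.shape:
            raise ValueError(f"effect curve for {name!r} does not match grid")
    subjects = logs["subject"].unique()
    intercepts = {s: rng.normal(0.0, subject_intercept_sd) for s in subjects}
    rows = []
    for region in regions:
        for rec in logs.itertuples(index=False):
            signal = np.zeros_like(grid)
            for name, curve in curves.items():
                signal = signal + curve * getattr(rec, name)
            resp = signal + intercepts[rec.subject] \
                + rng.normal(0.0, noise_sd, grid.size)
            for t, y in zip(grid, resp):
                rows.append({"subject": rec.subject, "run": rec.run,
                             "trial": rec.trial, "region": region,
                             "time": float(t), "response": float(y)})
    truth = pd.DataFrame(
        [{"signal": n, "time": float(t), "effect": float(v)}
         for n, c in curves.items() for t, v in zip(grid, c)])
    return pd.DataFrame(rows), truth
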