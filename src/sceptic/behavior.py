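"""Model-free and model-derived behavioral statistics and dataset builders.

* RT swings — absolute trial-to-trial change in response time, the
  model-free index of exploration.
* A Kullback-Leibler divergence statistic quantifying shifts in the local
  distribution of recent response times (selection history), with the
  three window recipes used for behavioral, MEG and fMRI analyses.
* The working-memory buffer regression dataset: current RT against k
  lagged RTs, lagged reward/omission flags and their interactions, plus
  the model-derived RT_Vmax — the design used to test whether the learned
  value map explains choice beyond a finite choice/outcome buffer.
* The within-trial survival dataset: discrete 100-ms risk bins from 1.0 to
  3.5 s with the time-varying learned value as a covariate, ready for an
  external mixed-effects Cox engine.

All builders are deterministic, idempotent, pure functions of the log (and
basis geometry where densities are involved).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import BasisConfig

__all__ = [
    "WindowSpec",
    "KLD_PRESETS",
    "rt_swings",
    "kld_rt_history",
    "buffer_regression_dataset",
    "survival_dataset",
]


def rt_swings(log: pd.DataFrame) -> pd.Series:
    """Per-trial |RT_t - RT_{t-1}| in seconds; the first trial of each
    (subject, run) is missing."""
    ordered = log.sort_values(["subject", "run", "trial"])
    sw = ordered.groupby(["subject", "run"])["rt"].diff().abs()
    return sw.reindex(log.index)


@dataclass(frozen=True)
class WindowSpec:
    """Trial-lag windows for the KLD selection-history statistic.

    ``source_lags``/``reference_lags`` are positive-or-zero lags relative
    to the current trial t (lag 0 = trial t itself); the statistic is the
    divergence of the source window's RT density from the reference
    window's.
    """

    source_lags: tuple
    reference_lags: tuple
    log_transform: bool = False


KLD_PRESETS = {
    # shift of trials {t-4, t-3, t-2} away from the three trials before them
    "behavioral": WindowSpec((4, 3, 2), (7, 6, 5), log_transform=False),
    # divergence of RT_{t-3, t-2} from RT_{t-1}
    "meg": WindowSpec((3, 2), (1,), log_transform=False),
    # log KLD between the last RT and the three preceding it
    "fmri": WindowSpec((0,), (3, 2, 1), log_transform=True),
}


def _rt_density(cfg: BasisConfig, rts: np.ndarray, bandwidth_sq: float,
                floor: float) -> np.ndarray:
    """Normalized mixture of unit-height Gaussians at the window's RTs on
    the response-bin grid, floored and renormalized."""
    grid = cfg.bin_centers
    dens = np.zeros_like(grid)
    for t in rts:
        dens += np.exp(-0.5 * (grid - t) ** 2 / bandwidth_sq)
    dens /= dens.sum()
    dens = np.maximum(dens, floor)
    return dens / dens.sum()


def kld_rt_history(log: pd.DataFrame, cfg: BasisConfig,
                   window_spec="behavioral", bandwidth_sq: float | None = None,
                   floor: float = 1e-6) -> pd.Series:
    """Per-trial KLD of the source RT window from the reference RT window.

    Each window is converted to a density over the response bins as a
    normalized Gaussian-mixture (variance ``bandwidth_sq``, defaulting to
    the generalization width s_g^2), floored at ``floor`` and
    renormalized; the statistic is the discrete KLD (natural log) summed
    over bins, optionally log-transformed per the window preset.  Trials
    without enough history are missing.
    """
    spec = KLD_PRESETS[window_spec] if isinstance(window_spec, str) else window_spec
    if not spec.source_lags or not spec.reference_lags:
        raise ValueError("both windows must contain at least one lag")
    bw = cfg.gen_width_sq if bandwidth_sq is None else float(bandwidth_sq)
    max_lag = max(max(spec.source_lags), max(spec.reference_lags))

    out = pd.Series(np.nan, index=log.index, name="kld")
    ordered = log.sort_values(["subject", "run", "trial"])
    for _, seg in ordered.groupby(["subject", "run"]):
        rts = seg["rt"].to_numpy(dtype=float)
        for i in range(max_lag, len(rts)):
            src = rts[[i - l for l in spec.source_lags]]
            ref = rts[[i - l for l in spec.reference_lags]]
            p = _rt_density(cfg, src, bw, floor)
            q = _rt_density(cfg, ref, bw, floor)
            kld = float(np.sum(p * np.log(p / q)))
            kld = max(kld, 0.0)
            if spec.log_transform:
                kld = float(np.log(max(kld, floor)))
            out.loc[seg.index[i]] = kld
    return out


def buffer_regression_dataset(log: pd.DataFrame, k: int = 5,
                              include_rt_vmax: bool = True,
                              drop_first: int = 0) -> pd.DataFrame:
    """Design table predicting RT_t from a k-trial choice/outcome buffer.

    Columns: ``rt`` (response), ``rt_lag1..k``, ``reward_lag1..k``
    (reward/omission flags), their products ``rt_lagj_x_reward_lagj``,
    the inverse-transformed trial number ``inv_trial`` = 1/(trial+1), the
    previous reward magnitude and optionally ``rt_vmax``.  Rows with
    incomplete lags are dropped; ``drop_first`` additionally removes the
    first N trials of each block (or run, when no block column exists) as
    an analysis-stage novelty filter.
    """
    if k < 1:
        raise ValueError("buffer length k must be >= 1")
    ordered = log.sort_values(["subject", "run", "trial"])
    parts = []
    for keys, seg in ordered.groupby(["subject", "run"]):
        seg = seg.reset_index(drop=True)
        d = pd.DataFrame({
            "subject": seg["subject"], "run": seg["run"],
            "trial": seg["trial"], "rt": seg["rt"],
            "inv_trial": 1.0 / (seg["trial"].to_numpy(dtype=float) + 1.0),
        })
        for j in range(1, k + 1):
            d[f"rt_lag{j}"] = seg["rt"].shift(j)
            d[f"reward_lag{j}"] = seg["rewarded"].shift(j)
            d[f"rt_lag{j}_x_reward_lag{j}"] = d[f"rt_lag{j}"] * d[f"reward_lag{j}"]
        d["prev_reward"] = seg["reward"].shift(1)
        if include_rt_vmax:
            d["rt_vmax"] = seg["rt_vmax"]
        if drop_first > 0:
            blocks = seg["block"] if "block" in seg else pd.Series(0, index=seg.index)
            within = seg.groupby(blocks).cumcount()
            d = d[within.to_numpy() >= drop_first]
        parts.append(d)
    out = pd.concat(parts, ignore_index=True)
    return out.dropna().reset_index(drop=True)


def survival_dataset(log: pd.DataFrame, value_trajectories: np.ndarray,
                     cfg: BasisConfig, window=(1.0, 3.5), step: float = 0.1,
                     front_censor: float = 0.0, back_censor: float = 0.0,
                     moderators: pd.DataFrame | None = None) -> pd.DataFrame:
    """Long-format discrete-time risk set for within-trial survival models.

    Per trial, one record per ``step``-second bin from the window start
    until the response (or the window end).  Bins are contiguous half-open
    [start, stop) intervals in milliseconds, 0-based; a response landing
    exactly on a bin edge is assigned to the earlier bin.  ``event`` = 1
    in the bin containing the RT when it falls inside the (possibly
    censored) window; responses before the window contribute no records;
    responses after it leave every record censored.  The time-varying
    covariate ``value`` is the pre-choice value function sampled at the
    bin's location on the response grid; ``value_trajectories`` must be a
    (n_trials, n_bins) array aligned with the rows of ``log``.
    """
    V = np.asarray(value_trajectories, dtype=float)
    if V.shape != (len(log), cfg.n_bins):
        raise ValueError(
            f"value_trajectories shape {V.shape} does not match "
            f"({len(log)}, {cfg.n_bins})")
    w0 = window[0] + front_censor
    w1 = window[1] - back_censor
    if w1 <= w0:
        raise ValueError("censoring leaves an empty window")
    n_full = int(round((w1 - w0) / step))
    rows = []
    for idx, (pos, rec) in enumerate(log.iterrows()):
        rt = float(rec["rt"])
        if rt < w0:
            continue
        if rt >= w1:
            n_rec, event_bin = n_full, None
        else:
            # tolerance guards float noise; an RT exactly on a bin edge
            # belongs to the earlier bin
            n_rec = int(np.ceil((rt - w0) / step - 1e-9))
            n_rec = max(n_rec, 1)
            event_bin = n_rec - 1
        for b in range(n_rec):
            start = w0 + b * step
            mid_bin = min(int((start + step / 2) / cfg.bin_width), cfg.n_bins - 1)
            row = {
                "subject": rec["subject"], "run": rec["run"],
                "trial": rec["trial"], "bin": b,
                "start_ms": int(round(start * 1000)),
                "stop_ms": int(round((start + step) * 1000)),
                "event": int(event_bin == b),
                "value": float(V[idx, mid_bin]),
            }
            rows.append(row)
    out = pd.DataFrame(rows)
    if moderators is not None and len(out):
        out = out.merge(moderators, on="subject", how="left")
    return out
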