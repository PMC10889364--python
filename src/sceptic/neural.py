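"""Model-based fMRI regressor construction and trial-aligned analysis plumbing.

Covers the standard steps between a fitted behavioral model and a neural
engine: the canonical double-gamma hemodynamic response function (HRF),
duration-modulated boxcar regressors, the peak-renormalized parametric
regressor that decouples event duration from parametric amplitude,
FSL-style Gaussian running-line high-pass filtering (identical operator
for data and design), feedback-aligned epoching with adjacent-trial
masking, and assembly of the per-timepoint model-comparison dataset with
AIC bookkeeping and Benjamini-Yekutieli correction.

Voxelwise estimation, prewhitening, group mixed-effects and deconvolution
itself are out of scope; the module produces engine-agnostic tables.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import signal as sps
from scipy.stats import gamma as gamma_dist
from statsmodels.stats.multitest import multipletests

__all__ = [
    "HRFParams",
    "EpochedSignal",
    "hrf",
    "event_regressor",
    "peak_renormalized_regressor",
    "highpass",
    "epoch_feedback",
    "model_comparison_dataset",
    "by_adjust",
    "neural_model_aic",
]

TR_PRESETS = {"fmri_original": 1.0, "replication": 0.6}


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF shape: response peaking near ``peak_delay`` s with an
    undershoot near ``undershoot_delay`` s scaled by ``undershoot_ratio``.
    Implementation defaults, exposed for configuration."""

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    undershoot_ratio: float = 1.0 / 6.0
    length: float = 32.0


@functools.lru_cache(maxsize=16)
def _hrf_peak(params: HRFParams) -> float:
    t = np.linspace(0, params.length, 4001)
    return float(np.max(_hrf_raw(t, params)))


def _hrf_raw(t, params: HRFParams):
    # gamma pdfs with unit scale peak at (shape - 1)
    pos = gamma_dist.pdf(t, params.peak_delay + 1.0)
    neg = gamma_dist.pdf(t, params.undershoot_delay + 1.0)
    return pos - params.undershoot_ratio * neg


def hrf(t, params: HRFParams = HRFParams()):
    """Canonical double-gamma HRF, peak-normalized to 1; zero for t <= 0."""
    t = np.asarray(t, dtype=float)
    out = np.where(t > 0, _hrf_raw(np.maximum(t, 0.0), params), 0.0)
    out = out / _hrf_peak(params)
    return out if out.ndim else float(out)


def _fine_convolved(onsets, durations, grid, params, dt):
    """Per-event boxcar * HRF curves on a fine internal grid.

    Returns (fine time grid, list of per-event convolved curves)."""
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if onsets.size != durations.size:
        raise ValueError("onsets and durations must have equal length")
    order = np.argsort(onsets)
    ends = onsets[order] + durations[order]
    if np.any(ends[:-1] > onsets[order][1:] + 1e-12):
        raise ValueError("overlapping events; the task design forbids them")
    t_end = float(max(np.max(grid), np.max(onsets + durations)) + params.length)
    fine = np.arange(0.0, t_end + dt, dt)
    kernel = hrf(fine[fine <= params.length], params)
    curves = []
    for on, dur in zip(onsets, durations):
        box = ((fine >= on) & (fine < on + dur)).astype(float)
        curves.append(np.convolve(box, kernel)[: fine.size] * dt)
    return fine, curves


def event_regressor(onsets, durations, values, grid, convolve: bool = True,
                    mean_center: bool = True, params: HRFParams = HRFParams(),
                    dt: float = 0.05) -> np.ndarray:
    """Duration-modulated unit-height boxcar regressor sampled on ``grid``.

    Each event's boxcar is scaled by its (optionally mean-centered)
    parametric value and, when ``convolve`` is set, convolved with the
    canonical HRF.
    """
    values = np.asarray(values, dtype=float)
    if mean_center:
        values = values - values.mean()
    onsets = np.asarray(onsets, dtype=float)
    durations = np.asarray(durations, dtype=float)
    if convolve:
        fine, curves = _fine_convolved(onsets, durations, grid, params, dt)
        col = np.zeros_like(fine)
        for v, c in zip(values, curves):
            col += v * c
        return np.interp(grid, fine, col)
    col = np.zeros(len(grid))
    grid = np.asarray(grid, dtype=float)
    for on, dur, v in zip(onsets, durations, values):
        col += v * ((grid >= on) & (grid < on + dur))
    return col


def peak_renormalized_regressor(onsets, durations, values, grid,
                                params: HRFParams = HRFParams(),
                                mean_center: bool = True,
                                dt: float = 0.05) -> np.ndarray:
    """Parametric regressor with per-trial peak renormalization.

    Each trial's duration-modulated boxcar is convolved with the HRF,
    rescaled so its peak is exactly 1, multiplied by that trial's signal
    value and summed across trials — so trials of very different durations
    contribute equal peak height per unit signal, decoupling decision time
    from the parametric amplitude.
    """
    values = np.asarray(values, dtype=float)
    if mean_center:
        values = values - values.mean()
    fine, curves = _fine_convolved(onsets, durations, grid, params, dt)
    col = np.zeros_like(fine)
    for v, c in zip(values, curves):
        peak = np.max(np.abs(c))
        if peak <= 0:
            raise ValueError("degenerate event with zero-peak response")
        col += v * (c / peak)
    return np.interp(grid, fine, col)


def highpass(series, tr: float, cutoff_hz: float = 0.008,
             method: str = "gaussian_line") -> np.ndarray:
    """Temporal high-pass filter with sigma = 1/(2*cutoff) seconds.

    ``gaussian_line`` removes a Gaussian-weighted running-line fit (the
    FSL-style local linear detrend: a constant or linear trend maps to ~0
    and the operator is linear); ``butterworth`` applies a zero-phase
    second-order Butterworth high-pass instead.
    """
    y = np.asarray(series, dtype=float)
    if y.ndim != 1:
        raise ValueError("series must be 1-D")
    sigma_s = 1.0 / (2.0 * cutoff_hz)
    if y.size * tr < 2.0 * sigma_s:
        raise ValueError(
            f"series of {y.size * tr:.0f} s is shorter than the "
            f"{2 * sigma_s:.0f}-s filter window")
    if method == "butterworth":
        b, a = sps.butter(2, cutoff_hz, btype="highpass", fs=1.0 / tr)
        return sps.filtfilt(b, a, y)
    if method != "gaussian_line":
        raise ValueError("method must be 'gaussian_line' or 'butterworth'")
    n = y.size
    t = np.arange(n) * tr
    # Gaussian-weighted running-line fit evaluated at each sample
    w = np.exp(-0.5 * ((t[:, None] - t[None, :]) / sigma_s) ** 2)
    s0 = w.sum(axis=1)
    s1 = (w * t[None, :]).sum(axis=1)
    s2 = (w * t[None, :] ** 2).sum(axis=1)
    sy = w @ y
    sxy = w @ (t * y)
    det = s0 * s2 - s1 ** 2
    intercept = (s2 * sy - s1 * sxy) / det
    slope = (s0 * sxy - s1 * sy) / det
    fitted = intercept + slope * t
    return y - fitted


@dataclass
class EpochedSignal:
    """Trials x time matrix aligned to feedback onset with a validity mask
    (True where the cell belongs to the current trial)."""

    values: np.ndarray
    mask: np.ndarray
    offsets: np.ndarray
    trial_index: np.ndarray

    def to_frame(self, subject=0) -> pd.DataFrame:
        rows = []
        for i, tr_idx in enumerate(self.trial_index):
            for j, off in enumerate(self.offsets):
                rows.append({"subject": subject, "trial": int(tr_idx),
                             "time": float(off),
                             "value": float(self.values[i, j]),
                             "valid": bool(self.mask[i, j])})
        return pd.DataFrame(rows)


def epoch_feedback(times, series, feedback_onsets, trial_starts, trial_ends,
                   tr: float, window=(-4.0, 4.0)) -> EpochedSignal:
    """Linear-interpolation epoching of a run's signal around feedback.

    The grid is anchored at each feedback onset (offsets ``window[0]`` to
    ``window[1]`` in steps of ``tr``); cells whose absolute time falls
    outside the trial's own span [trial_start, trial_end) — i.e. overlap
    the previous or next trial — are masked invalid, as are cells outside
    the recorded series.
    """
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    feedback_onsets = np.asarray(feedback_onsets, dtype=float)
    trial_starts = np.asarray(trial_starts, dtype=float)
    trial_ends = np.asarray(trial_ends, dtype=float)
    if np.any(feedback_onsets < times[0]) or np.any(feedback_onsets > times[-1]):
        raise ValueError("feedback onset outside the recorded series")
    offsets = np.arange(window[0], window[1] + tr / 2.0, tr)
    n = feedback_onsets.size
    values = np.empty((n, offsets.size))
    mask = np.zeros((n, offsets.size), dtype=bool)
    for i in range(n):
        abs_t = feedback_onsets[i] + offsets
        values[i] = np.interp(abs_t, times, series)
        mask[i] = ((abs_t >= trial_starts[i]) & (abs_t < trial_ends[i])
                   & (abs_t >= times[0]) & (abs_t <= times[-1]))
    return EpochedSignal(values, mask, offsets, np.arange(n))


def by_adjust(pvalues) -> np.ndarray:
    """Benjamini-Yekutieli FDR adjustment (valid under arbitrary dependence)."""
    p = np.asarray(pvalues, dtype=float)
    return multipletests(p, method="fdr_by")[1]


def model_comparison_dataset(epoch: EpochedSignal, log: pd.DataFrame,
                             model_signals: dict, covariates=()) -> pd.DataFrame:
    """Stacked per-timepoint modeling table for neural model comparison.

    ``model_signals`` maps a candidate-model name to a DataFrame (aligned
    with ``log`` rows) holding that model's ``entropy`` and
    ``entropy_change`` columns.  The output has one block per (model,
    time) with the masked neural response, the candidate's model-derived
    columns and the shared covariates — identical across candidates except
    for the model-derived columns.
    """
    if len(log) != epoch.values.shape[0]:
        raise ValueError("epoch and log have different trial counts")
    rows = []
    cov = list(covariates)
    for name, sig in model_signals.items():
        if len(sig) != len(log):
            raise ValueError(f"signals for {name!r} do not align with the log")
        for j, off in enumerate(epoch.offsets):
            valid = epoch.mask[:, j]
            for i in np.flatnonzero(valid):
                row = {"model": name, "time": float(off),
                       "subject": log["subject"].iloc[i],
                       "trial": log["trial"].iloc[i],
                       "response": float(epoch.values[i, j]),
                       "entropy": float(sig["entropy"].iloc[i]),
                       "entropy_change": float(sig["entropy_change"].iloc[i])}
                for c in cov:
                    row[c] = log[c].iloc[i]
                rows.append(row)
    return pd.DataFrame(rows)


def neural_model_aic(dataset: pd.DataFrame, predictors=("entropy_change",),
                     covariates=()) -> pd.DataFrame:
    """Summed-AIC bookkeeping across candidate models.

    Fits, per candidate model and time point, an OLS regression of the
    neural response on the model-derived predictors plus shared
    covariates, and sums AIC over time points.  This is the light-weight
    stand-in for the external mixed-effects engine: lower summed AIC
    favors that candidate's account of the neural signal.
    """
    out = []
    for name, block in dataset.groupby("model", sort=False):
        total = 0.0
        for _, sub in block.groupby("time"):
            X = sm.add_constant(sub[list(predictors) + list(covariates)])
            res = sm.OLS(sub["response"], X).fit()
            total += float(res.aic)
        out.append({"model": name, "aic": total})
    df = pd.DataFrame(out).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].min()
    return df
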