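"""Gaussian radial-basis representation of the clock-task response interval.

The agent's value function over a continuous one-dimensional response
interval [0, T] is carried by B evenly spaced Gaussian radial basis
functions (RBFs).  Each element b has a temporal receptive field

    phi_b(x) = exp[-(x - mu_b)^2 / (2 s_b^2)]

whose weight w_b stores the locally learned expected reward.  The module
provides

* element evaluation in unit-height ("height") and density-normalized form,
* the value function V(x) = sum_b w_b phi_b(x) on the discrete response grid,
* the eligibility (temporal generalization) integral that gates learning,
* Shannon entropy (log10) of the normalized weights, and
* RT_Vmax, the response time at the global maximum of V.

Eligibility of element b for an update after a response at time t is the
shared area between two probability densities: the generalization curve g
centered on t and the element's receptive field,

    e_b(t) = integral min[g~(tau), phi_b~(tau)] dtau   in [0, 1].

Both curves are density-normalized only inside this integral; value
evaluation uses the unit-height form.  The integral is evaluated by
fixed-grid trapezoid quadrature on a dense grid over the untruncated
support (extended several widths beyond [0, T]) so that e_b = 1 is reached
exactly when t coincides with a center, including at boundary elements.
"""

from __future__ import annotations

import functools
from dataclasses import dataclass, field, replace

import numpy as np
import yaml
from scipy.optimize import brentq

__all__ = [
    "BasisConfig",
    "ValueState",
    "evaluate_element",
    "basis_matrix",
    "value_function",
    "eligibility",
    "entropy",
    "rt_vmax",
    "gaussian_min_overlap",
    "solve_basis_width",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


def gaussian_min_overlap(delta: float, sd: float, n_quad: int = 60001,
                         pad_sd: float = 8.0) -> float:
    """Shared area of two equal-width normal densities with centers ``delta`` apart.

    Computed by dense trapezoid quadrature of the pointwise minimum; the
    closed form is 2*Phi(-delta/(2*sd)).
    """
    if sd <= 0:
        raise ValueError("sd must be positive")
    delta = abs(float(delta))
    lo = -pad_sd * sd
    hi = delta + pad_sd * sd
    x = np.linspace(lo, hi, n_quad)
    a = np.exp(-0.5 * (x / sd) ** 2)
    b = np.exp(-0.5 * ((x - delta) / sd) ** 2)
    dens = 1.0 / (sd * _SQRT_2PI)
    return float(np.trapezoid(np.minimum(a, b) * dens, x))


def solve_basis_width(spacing: float, overlap_target: float = 0.5) -> float:
    """Return the SD s_b at which adjacent density-normalized elements share
    ``overlap_target`` of their area, found by 1-D root-finding."""
    if not 0 < overlap_target < 1:
        raise ValueError("overlap_target must lie in (0, 1)")

    def f(sd: float) -> float:
        return gaussian_min_overlap(spacing, sd, n_quad=20001) - overlap_target

    return float(brentq(f, spacing * 1e-3, spacing * 50.0, xtol=1e-12))


@dataclass(frozen=True)
class BasisConfig:
    """Geometry of the radial-basis representation.

    Parameters
    ----------
    n_elements
        Number of basis elements B (default 24).
    interval_length
        Length T of the response interval in seconds (default 4.0).
    bin_width
        Width of the discrete response bins in seconds (default 0.1,
        giving 40 bins on the default interval).
    overlap_target
        Shared-area criterion for adjacent density-normalized elements used
        to choose the default basis width (default 0.5).
    basis_width_sq
        Variance s_b^2 of each element in s^2.  When None it is solved from
        ``overlap_target``.
    gen_width_sq
        Variance s_g^2 of the generalization function; defaults to
        ``basis_width_sq``.
    value_normalized
        If True the value function uses density-normalized elements instead
        of the default unit-height form.
    n_quad
        Number of quadrature points for eligibility/overlap integrals.
    support_pad_sd
        Quadrature support extension beyond [0, T] in units of s_b.
    """

    n_elements: int = 24
    interval_length: float = 4.0
    bin_width: float = 0.1
    overlap_target: float = 0.5
    basis_width_sq: float | None = None
    gen_width_sq: float | None = None
    value_normalized: bool = False
    n_quad: int = 60001
    support_pad_sd: float = 6.0

    def __post_init__(self) -> None:
        if self.n_elements < 2:
            raise ValueError("need at least two basis elements")
        if self.interval_length <= 0 or self.bin_width <= 0:
            raise ValueError("interval_length and bin_width must be positive")
        if self.basis_width_sq is None:
            sb = solve_basis_width(self.spacing, self.overlap_target)
            object.__setattr__(self, "basis_width_sq", sb * sb)
        if self.basis_width_sq <= 0:
            raise ValueError("basis_width_sq must be positive")
        if self.gen_width_sq is None:
            object.__setattr__(self, "gen_width_sq", self.basis_width_sq)
        if self.gen_width_sq <= 0:
            raise ValueError("gen_width_sq must be positive")

    # -- derived geometry ---------------------------------------------------
    @property
    def spacing(self) -> float:
        return self.interval_length / (self.n_elements - 1)

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(0.0, self.interval_length, self.n_elements)

    @property
    def n_bins(self) -> int:
        return int(round(self.interval_length / self.bin_width))

    @property
    def bin_centers(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width

    @property
    def basis_sd(self) -> float:
        return float(np.sqrt(self.basis_width_sq))

    @property
    def gen_sd(self) -> float:
        return float(np.sqrt(self.gen_width_sq))

    def quad_grid(self) -> np.ndarray:
        pad = self.support_pad_sd * self.basis_sd
        return np.linspace(-pad, self.interval_length + pad, self.n_quad)

    def rt_to_bin(self, rt: float) -> int:
        """Map a continuous response time to its 0-based bin index."""
        j = int(np.floor(rt / self.bin_width))
        return min(max(j, 0), self.n_bins - 1)

    # -- flat key/value config IO -------------------------------------------
    def to_file(self, path) -> None:
        keys = ("n_elements", "interval_length", "bin_width", "overlap_target",
                "basis_width_sq", "gen_width_sq", "value_normalized", "n_quad",
                "support_pad_sd")
        with open(path, "w") as fh:
            yaml.safe_dump({k: getattr(self, k) for k in keys}, fh,
                           sort_keys=False)

    @classmethod
    def from_file(cls, path) -> "BasisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)


@dataclass
class ValueState:
    """Per-trial basis weights."""

    weights: np.ndarray
    trial_index: int = 0

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.ndim != 1:
            raise ValueError("weights must be a 1-D vector")
        if not np.all(np.isfinite(self.weights)):
            raise ValueError("weights must be finite")

    @classmethod
    def zeros(cls, cfg: BasisConfig) -> "ValueState":
        return cls(np.zeros(cfg.n_elements))

    @classmethod
    def random_uniform(cls, cfg: BasisConfig, rng: np.random.Generator,
                       high: float = 1.0) -> "ValueState":
        return cls(rng.uniform(0.0, high, cfg.n_elements))


def _check_state(cfg: BasisConfig, state: ValueState) -> None:
    if state.weights.shape[0] != cfg.n_elements:
        raise ValueError(
            f"state has {state.weights.shape[0]} weights, config expects "
            f"{cfg.n_elements}")


def evaluate_element(cfg: BasisConfig, b: int, x, normalized: bool = False):
    """Evaluate element ``b`` at time(s) ``x``.

    Unit-height form peaks at 1 at the center; normalized form is the
    corresponding probability density (area 1 over the real line).
    """
    if not 0 <= b < cfg.n_elements:
        raise IndexError(f"element index {b} out of range [0, {cfg.n_elements})")
    x = np.asarray(x, dtype=float)
    val = np.exp(-0.5 * (x - cfg.centers[b]) ** 2 / cfg.basis_width_sq)
    if normalized:
        val = val / (cfg.basis_sd * _SQRT_2PI)
    return val if val.ndim else float(val)


def basis_matrix(cfg: BasisConfig, x=None, normalized: bool | None = None) -> np.ndarray:
    """(len(x), B) matrix of element evaluations; x defaults to the bin centers."""
    if x is None:
        x = cfg.bin_centers
    if normalized is None:
        normalized = cfg.value_normalized
    x = np.atleast_1d(np.asarray(x, dtype=float))
    m = np.exp(-0.5 * (x[:, None] - cfg.centers[None, :]) ** 2 / cfg.basis_width_sq)
    if normalized:
        m = m / (cfg.basis_sd * _SQRT_2PI)
    return m


@functools.lru_cache(maxsize=64)
def _bin_basis_matrix(cfg: BasisConfig) -> np.ndarray:
    return basis_matrix(cfg)


def value_function(cfg: BasisConfig, state: ValueState) -> np.ndarray:
    """Expected value V(x_j) = sum_b w_b phi_b(x_j) over the n_bins grid."""
    _check_state(cfg, state)
    return _bin_basis_matrix(cfg) @ state.weights


@functools.lru_cache(maxsize=32)
def _quad_phi(cfg: BasisConfig):
    """Density-normalized element evaluations on the quadrature grid."""
    tau = cfg.quad_grid()
    phi = (np.exp(-0.5 * (tau[:, None] - cfg.centers[None, :]) ** 2
                  / cfg.basis_width_sq) / (cfg.basis_sd * _SQRT_2PI))
    return tau, phi


@functools.lru_cache(maxsize=100_000)
def _eligibility_cached(cfg: BasisConfig, t: float) -> tuple:
    tau, phi = _quad_phi(cfg)
    g = np.exp(-0.5 * (tau - t) ** 2 / cfg.gen_width_sq) / (cfg.gen_sd * _SQRT_2PI)
    e = np.trapezoid(np.minimum(g[:, None], phi), tau, axis=0)
    return tuple(np.clip(e, 0.0, 1.0))


def eligibility(cfg: BasisConfig, t: float) -> np.ndarray:
    """Eligibility e_b(t) of every element for an update after a response at t."""
    t = float(t)
    if not 0.0 <= t <= cfg.interval_length:
        raise ValueError(f"response time {t} outside [0, {cfg.interval_length}]")
    return np.array(_eligibility_cached(cfg, t))


def eligibility_matrix(cfg: BasisConfig, rts) -> np.ndarray:
    """Stack eligibility vectors for a sequence of response times (cached)."""
    return np.vstack([eligibility(cfg, rt) for rt in np.asarray(rts, dtype=float)])


def entropy(weights, empty: str = "max") -> float:
    """Shannon entropy (log10) of the normalized weight vector.

    Weights are normalized to sum to one for this computation only;
    0*log10(0) is taken as 0.  An all-zero vector returns log10(B) under
    ``empty='max'`` (zero evidence = maximal uncertainty) or 0 under
    ``empty='zero'`` (the working-memory buffer convention).
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0):
        raise ValueError("entropy requires nonnegative weights")
    total = w.sum()
    if total == 0:
        if empty == "max":
            return float(np.log10(w.size))
        if empty == "zero":
            return 0.0
        raise ValueError("empty must be 'max' or 'zero'")
    p = w / total
    nz = p > 0
    return float(-(p[nz] * np.log10(p[nz])).sum())


def rt_vmax(cfg: BasisConfig, state: ValueState) -> float:
    """Response time (bin center, seconds) at the global maximum of the value
    function; ties break toward the earliest bin."""
    v = value_function(cfg, state)
    return float(cfg.bin_centers[int(np.argmax(v))])
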