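"""Noise schedules and the DDPM forward/reverse primitives.

The forward chain perturbs both Cartesian coordinates and continuous
relaxations of the one-hot atom-type rows with Gaussian noise under a
variance-preserving schedule,

    q(x_t | x_{t-1}) = N(x_t; sqrt(1 - beta_t) x_{t-1}, beta_t I),

and the reverse chain is epsilon-parameterized with fixed variance
Sigma = beta_t I.  Two schedules are provided: the linear schedule with
beta rising from 1e-4 to 0.02, and a squared-polynomial alpha-bar schedule
alpha_bar_t = (1 - (t/T)^p)^2 used for the R-group stage.

Indexing convention: ``beta[t-1]`` is beta_t for t in 1..T; ``alpha_bar``
has length T+1 with ``alpha_bar[0] = 1`` so that ``forward_marginal`` at
t = 0 is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ParameterError

__all__ = [
    "NoiseSchedule",
    "NoisePrediction",
    "make_schedule",
    "forward_step",
    "forward_marginal",
    "posterior_step",
    "diffusion_loss",
]


@dataclass
class NoiseSchedule:
    """Per-step variances beta_t with derived alpha and alpha-bar arrays."""

    kind: str
    T: int
    beta: np.ndarray
    alpha: np.ndarray = field(init=False)
    alpha_bar: np.ndarray = field(init=False)

    def __post_init__(self):
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (self.T,):
            raise ParameterError("beta must have length T")
        if np.any(self.beta <= 0) or np.any(self.beta >= 1):
            raise ParameterError("beta values must lie in (0, 1)")
        self.alpha = 1.0 - self.beta
        self.alpha_bar = np.concatenate([[1.0], np.cumprod(self.alpha)])

    def to_dict(self) -> dict:
        return {"kind": self.kind, "T": int(self.T),
                "beta": self.beta.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NoiseSchedule":
        return cls(d["kind"], int(d["T"]), np.asarray(d["beta"]))


def make_schedule(kind: str, T: int, params: dict | None = None
                  ) -> NoiseSchedule:
    """Build a noise schedule.

    ``linear``: beta_t equally spaced from 1e-4 to 0.02 inclusive.
    ``polynomial``: alpha_bar_t = (1 - (t/T)^p)^2 (default p = 2), betas
    derived from successive alpha-bar ratios and clipped to [1e-5, 0.999].
    """
    params = params or {}
    if T < 2:
        raise ParameterError("T must be at least 2")
    if kind == "linear":
        beta_start = float(params.get("beta_start", 1e-4))
        beta_end = float(params.get("beta_end", 0.02))
        beta = np.linspace(beta_start, beta_end, T)
    elif kind == "polynomial":
        p = float(params.get("p", 2.0))
        t = np.arange(T + 1, dtype=float)
        alpha_bar = (1.0 - (t / T) ** p) ** 2
        # tiny offset keeps alpha_bar_T > 0 so beta_T < 1
        alpha_bar = np.clip(alpha_bar, 1e-8, 1.0)
        beta = 1.0 - alpha_bar[1:] / alpha_bar[:-1]
        beta = np.clip(beta, 1e-5, 0.999)
    else:
        raise ParameterError(f"unknown schedule kind {kind!r}")
    return NoiseSchedule(kind, T, beta)


@dataclass
class NoisePrediction:
    """Predicted noise for the generated atoms: coordinates and features."""

    eps_coords: np.ndarray
    eps_features: np.ndarray

    def __post_init__(self):
        self.eps_coords = np.asarray(self.eps_coords, dtype=float)
        self.eps_features = np.asarray(self.eps_features, dtype=float)
        if self.eps_coords.shape[0] != self.eps_features.shape[0]:
            raise ParameterError("coordinate/feature row mismatch")
        if not (
            np.isfinite(self.eps_coords).all()
            and np.isfinite(self.eps_features).all()
        ):
            raise ParameterError("non-finite noise prediction")


def _check_t(t: int, schedule: NoiseSchedule, allow_zero: bool = False):
    lo = 0 if allow_zero else 1
    if not (lo <= t <= schedule.T):
        raise ParameterError(f"t={t} outside [{lo}, {schedule.T}]")


def forward_step(x_prev: np.ndarray, t: int, schedule: NoiseSchedule,
                 noise: np.ndarray) -> np.ndarray:
    """One forward noising step: sqrt(1-beta_t) x_{t-1} + sqrt(beta_t) z."""
    _check_t(t, schedule)
    x_prev = np.asarray(x_prev, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x_prev.shape:
        raise ParameterError("noise shape mismatch")
    b = schedule.beta[t - 1]
    return np.sqrt(1.0 - b) * x_prev + np.sqrt(b) * noise


def forward_marginal(x0: np.ndarray, t: int, schedule: NoiseSchedule,
                     noise: np.ndarray) -> np.ndarray:
    """Closed-form marginal: sqrt(abar_t) x0 + sqrt(1-abar_t) z."""
    _check_t(t, schedule, allow_zero=True)
    x0 = np.asarray(x0, dtype=float)
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x0.shape:
        raise ParameterError("noise shape mismatch")
    if t == 0:
        return x0.copy()
    ab = schedule.alpha_bar[t]
    return np.sqrt(ab) * x0 + np.sqrt(1.0 - ab) * noise


def posterior_step(x_t: np.ndarray, eps_hat: np.ndarray, t: int,
                   schedule: NoiseSchedule,
                   noise: np.ndarray | None = None) -> np.ndarray:
    """One epsilon-parameterized reverse step with fixed variance beta_t.

    mu = (x_t - beta_t / sqrt(1 - abar_t) * eps_hat) / sqrt(alpha_t);
    at t = 1 the mean is returned with no added noise.
    """
    _check_t(t, schedule)
    x_t = np.asarray(x_t, dtype=float)
    eps_hat = np.asarray(eps_hat, dtype=float)
    if eps_hat.shape != x_t.shape:
        raise ParameterError("eps_hat shape mismatch")
    b = schedule.beta[t - 1]
    a = schedule.alpha[t - 1]
    ab = schedule.alpha_bar[t]
    mu = (x_t - (b / np.sqrt(1.0 - ab)) * eps_hat) / np.sqrt(a)
    if t == 1 or noise is None:
        return mu
    noise = np.asarray(noise, dtype=float)
    if noise.shape != x_t.shape:
        raise ParameterError("noise shape mismatch")
    return mu + np.sqrt(b) * noise


def diffusion_loss(eps, eps_hat) -> float:
    """Mean squared difference over all coordinate and feature entries."""

    def flat(e):
        if isinstance(e, NoisePrediction):
            return np.concatenate(
                [e.eps_coords.ravel(), e.eps_features.ravel()]
            )
        return np.asarray(e, dtype=float).ravel()

    a, b = flat(eps), flat(eps_hat)
    if a.shape != b.shape:
        raise ParameterError("shape mismatch in diffusion loss")
    return float(np.mean((a - b) ** 2))
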