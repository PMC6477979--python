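"""Reaction networks with distributed-delay hazards.

The state of a biochemical reaction network is a Markov jump process
``X(t)`` driven by reaction hazards.  Here a subset of the reactions may
depend on the *past* of the process through a kernel-weighted integral

    u(t) = int_{t-tau_m}^{t} X(s) K(t-s) ds,

where ``K`` is a (truncated) delay density on ``[0, tau_m]``.  This module
provides the generic network container split into delayed and non-delayed
reaction sets, discretized delay kernels on a regular lag lattice, the Hill
repression function, and the concrete one-species transcriptional negative
feedback loop (TTFL) used to model circadian mRNA dynamics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, fields, replace
from typing import Callable, Sequence

import numpy as np
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteDelayKernel",
    "GammaDelay",
    "PointMassDelay",
    "HillFunction",
    "ParameterSet",
    "Hazard",
    "DelayedReactionNetwork",
    "hill_transcription",
    "make_gamma_kernel",
    "ttfl_network",
    "birth_death_network",
    "deterministic_fixed_point",
]


# --------------------------------------------------------------------------
# Delay kernels
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class DiscreteDelayKernel:
    """A delay density discretized on a regular lag lattice.

    ``weights[j]`` is the probability mass assigned to lag ``j * grid_step``
    for ``j = 0 .. max_lag/grid_step``; weights sum to one after truncation
    at ``max_lag``.
    """

    grid_step: float
    max_lag: float
    weights: np.ndarray
    mean: float
    sd: float

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        object.__setattr__(self, "weights", w)
        if np.any(w < 0):
            raise ValueError("kernel weights must be non-negative")
        if not np.isclose(w.sum(), 1.0, atol=1e-9):
            raise ValueError("kernel weights must sum to 1")
        n_expected = int(round(self.max_lag / self.grid_step)) + 1
        if len(w) != n_expected:
            raise ValueError(
                f"expected {n_expected} weights on [0, {self.max_lag}] "
                f"at step {self.grid_step}, got {len(w)}"
            )

    @property
    def lags(self) -> np.ndarray:
        return np.arange(len(self.weights)) * self.grid_step

    def discrete_mean(self) -> float:
        return float(np.dot(self.lags, self.weights))


def _check_divisible(max_lag: float, grid_step: float) -> int:
    n = max_lag / grid_step
    if abs(n - round(n)) > 1e-9:
        raise ValueError(
            f"grid_step {grid_step} does not divide max_lag {max_lag}"
        )
    return int(round(n))


def make_gamma_kernel(
    mean: float, sd: float, max_lag: float = 30.0, grid_step: float = 0.1
) -> DiscreteDelayKernel:
    """Discretize a Gamma delay density on the lag lattice.

    The Gamma is parameterized by its mean and standard deviation
    (shape = mean^2/sd^2, scale = sd^2/mean), evaluated at the lattice
    points ``0, grid_step, ..., max_lag``, truncated there and renormalized
    so the weights sum to one.  A degenerate sd (all lattice density
    underflowing) collapses to a point mass at the lattice point nearest
    ``mean``.
    """
    if mean <= 0 or sd <= 0:
        raise ValueError("mean and sd must be positive")
    if mean >= max_lag:
        warnings.warn(
            f"delay mean {mean} >= max_lag {max_lag}: "
            "most of the kernel mass is truncated",
            stacklevel=2,
        )
    m = _check_divisible(max_lag, grid_step)
    lags = np.arange(m + 1) * grid_step
    shape = mean**2 / sd**2
    scale = sd**2 / mean
    w = stats.gamma.pdf(lags, a=shape, scale=scale)
    total = w.sum()
    if not np.isfinite(total) or total <= 1e-300:
        # density too narrow for the lattice: point mass at the nearest bin
        w = np.zeros(m + 1)
        w[int(round(min(mean, max_lag) / grid_step))] = 1.0
    else:
        w = w / total
    return DiscreteDelayKernel(
        grid_step=grid_step, max_lag=max_lag, weights=w, mean=mean, sd=sd
    )


@dataclass(frozen=True)
class GammaDelay:
    """Descriptor for a Gamma-distributed delay, truncated at ``max_lag``."""

    mean: float
    sd: float
    max_lag: float = 30.0

    def discretize(self, grid_step: float) -> DiscreteDelayKernel:
        return make_gamma_kernel(self.mean, self.sd, self.max_lag, grid_step)


@dataclass(frozen=True)
class PointMassDelay:
    """Degenerate (no-delay) kernel: all mass at lag zero.

    Species without delay dependence carry this descriptor, making the
    non-delayed case a degenerate instance of the delayed machinery.
    """

    def discretize(self, grid_step: float) -> DiscreteDelayKernel:
        return DiscreteDelayKernel(
            grid_step=grid_step,
            max_lag=0.0,
            weights=np.array([1.0]),
            mean=0.0,
            sd=0.0,
        )


# --------------------------------------------------------------------------
# Hill repression
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HillFunction:
    """Repressive Hill function ``R_max / (1 + (u/K_pc)^n)``.

    ``r_max`` is the maximum transcription rate (molecules/hour),
    ``threshold`` (K_pc, molecules) the repressor level halving the output,
    and ``coefficient`` (n) the cooperativity.
    """

    r_max: float
    threshold: float
    coefficient: float

    def __post_init__(self) -> None:
        if self.r_max <= 0 or self.threshold <= 0 or self.coefficient <= 0:
            raise ValueError("Hill parameters must be strictly positive")

    def __call__(self, u: float) -> float:
        return hill_transcription(u, self)

    def derivative(self, u: float) -> float:
        """d nu / d u, always <= 0."""
        if u < 0:
            raise ValueError(f"repressor level must be non-negative, got {u}")
        if u == 0.0:
            return 0.0 if self.coefficient > 1 else -np.inf
        ratio = (u / self.threshold) ** self.coefficient
        return (
            -self.r_max
            * self.coefficient
            * ratio
            / (u * (1.0 + ratio) ** 2)
        )


def hill_transcription(u: float, h: HillFunction) -> float:
    """Transcription rate under Hill repression by ``u`` molecules."""
    if u < 0:
        raise ValueError(f"repressor level must be non-negative, got {u}")
    return h.r_max / (1.0 + (u / h.threshold) ** h.coefficient)


# --------------------------------------------------------------------------
# Parameters
# --------------------------------------------------------------------------

@dataclass
class ParameterSet:
    """All inferable quantities of the delayed TTFL state-space model.

    Units: rates in molecules/hour or 1/hour, delays in hours, ``kappa``
    in intensity per molecule-hour, ``sigma_eps`` in intensity units.
    ``init_rate`` and ``mu0`` govern the birth--death model used on the
    initialization window ``[0, tau_max]``; ``beta`` (dimensionless) and
    ``var_x0`` (molecules^2) parameterize the dispersion of the state at
    time zero (variance ``beta * mean`` unless ``var_x0`` is given).
    """

    r_max: float = 100.0
    k_pc: float = 100.0
    n: float = 5.0
    mu: float = 0.58
    delay_mean: float = 9.67
    delay_sd: float = 3.56
    kappa: float = 1.0
    sigma_eps: float = 0.05
    init_rate: float = 55.0
    mu0: float = 0.58
    beta: float = 1.0
    var_x0: float | None = None
    tau_max: float = 30.0

    def __post_init__(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if f.name == "var_x0":
                if v is not None and v <= 0:
                    raise ValueError("var_x0 must be positive when given")
                continue
            if not (v > 0):
                raise ValueError(f"{f.name} must be strictly positive, got {v}")
        if self.delay_mean >= self.tau_max:
            raise ValueError(
                f"delay_mean {self.delay_mean} must be below tau_max {self.tau_max}"
            )
        if self.n < 1:
            raise ValueError(f"Hill coefficient must be >= 1, got {self.n}")

    def hill(self) -> HillFunction:
        return HillFunction(self.r_max, self.k_pc, self.n)

    def replace(self, **kwargs) -> "ParameterSet":
        return replace(self, **kwargs)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        known = {f.name for f in cls.__dataclass_fields__.values()}
        return cls(**{k: v for k, v in d.items() if k in known})


# --------------------------------------------------------------------------
# Networks
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class Hazard:
    """A reaction hazard with an optional analytic gradient.

    The callable receives the current state (for non-delayed reactions) or
    the kernel-weighted past state (for delayed reactions), as a length-p
    vector.  Without an analytic ``grad`` a central finite difference is
    used for the linearization.
    """

    fn: Callable[[np.ndarray], float]
    grad: Callable[[np.ndarray], np.ndarray] | None = None

    def __call__(self, x: np.ndarray) -> float:
        return float(self.fn(np.asarray(x, dtype=float)))

    def gradient(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if self.grad is not None:
            return np.atleast_1d(np.asarray(self.grad(x), dtype=float))
        # central differences, step scaled to the state magnitude
        g = np.empty(x.size)
        for i in range(x.size):
            h = 1e-6 * max(1.0, abs(x[i]))
            xp, xm = x.copy(), x.copy()
            xp[i] += h
            xm[i] = max(xm[i] - h, 0.0)
            g[i] = (self.fn(xp) - self.fn(xm)) / (xp[i] - xm[i])
        return g


class DelayedReactionNetwork:
    """Reaction network split into delayed and plain reaction sets.

    The stoichiometry is ``S = [S_d | S_plain]`` (p x (w + z)).  Delayed
    hazards are functions of the kernel-weighted past state ``u``; plain
    hazards are functions of the current state.  ``kernels`` holds one
    delay descriptor per species (``PointMassDelay`` for species without
    delay dependence).
    """

    def __init__(
        self,
        n_species: int,
        stoich_delayed: np.ndarray,
        stoich_plain: np.ndarray,
        hazards_delayed: Sequence[Hazard],
        hazards_plain: Sequence[Hazard],
        kernels: Sequence[GammaDelay | PointMassDelay],
    ) -> None:
        self.n_species = int(n_species)
        self.stoich_delayed = np.atleast_2d(np.asarray(stoich_delayed, dtype=float))
        self.stoich_plain = np.atleast_2d(np.asarray(stoich_plain, dtype=float))
        self.hazards_delayed = list(hazards_delayed)
        self.hazards_plain = list(hazards_plain)
        self.kernels = list(kernels)
        p = self.n_species
        if self.stoich_delayed.shape != (p, len(self.hazards_delayed)):
            raise ValueError("stoich_delayed shape mismatch with delayed hazards")
        if self.stoich_plain.shape != (p, len(self.hazards_plain)):
            raise ValueError("stoich_plain shape mismatch with plain hazards")
        if len(self.kernels) != p:
            raise ValueError("one delay kernel descriptor required per species")

    # ---- reaction counts ------------------------------------------------
    @property
    def n_delayed(self) -> int:
        return len(self.hazards_delayed)

    @property
    def n_plain(self) -> int:
        return len(self.hazards_plain)

    @property
    def stoichiometry(self) -> np.ndarray:
        """Full p x r stoichiometry, delayed columns first."""
        return np.hstack([self.stoich_delayed, self.stoich_plain])

    @property
    def max_lag(self) -> float:
        lags = [k.max_lag for k in self.kernels if isinstance(k, GammaDelay)]
        return max(lags) if lags else 0.0

    # ---- hazards --------------------------------------------------------
    def _eval(self, hazards: Sequence[Hazard], x: np.ndarray) -> np.ndarray:
        vals = np.array([h(x) for h in hazards], dtype=float)
        if np.any(vals < -1e-12):
            bad = vals.min()
            raise ValueError(f"hazard evaluated negative ({bad}) at state {x}")
        return np.maximum(vals, 0.0)

    def hazards_plain_at(self, x: np.ndarray) -> np.ndarray:
        return self._eval(self.hazards_plain, x)

    def hazards_delayed_at(self, u: np.ndarray) -> np.ndarray:
        return self._eval(self.hazards_delayed, u)

    # ---- drift / diffusion / Jacobians (for the LNA) --------------------
    def drift_plain(self, x: np.ndarray) -> np.ndarray:
        """g(x) = S_plain h_plain(x)."""
        return self.stoich_plain @ self._floored(self.hazards_plain, x)

    def drift_delayed(self, u: np.ndarray) -> np.ndarray:
        """f(u) = S_d h_d(u)."""
        return self.stoich_delayed @ self._floored(self.hazards_delayed, u)

    def jac_plain(self, x: np.ndarray) -> np.ndarray:
        G = np.array([h.gradient(x) for h in self.hazards_plain])
        G = G.reshape(self.n_plain, self.n_species)
        return self.stoich_plain @ G

    def jac_delayed(self, u: np.ndarray) -> np.ndarray:
        G = np.array([h.gradient(u) for h in self.hazards_delayed])
        G = G.reshape(self.n_delayed, self.n_species)
        return self.stoich_delayed @ G

    def diffusion(self, x: np.ndarray, u: np.ndarray) -> np.ndarray:
        """l(x) + q(u) = S_plain diag(h_plain) S_plain' + S_d diag(h_d) S_d'."""
        hp = self._floored(self.hazards_plain, x)
        hd = self._floored(self.hazards_delayed, u)
        return (self.stoich_plain * hp) @ self.stoich_plain.T + (
            self.stoich_delayed * hd
        ) @ self.stoich_delayed.T

    def _floored(self, hazards: Sequence[Hazard], x: np.ndarray) -> np.ndarray:
        """Hazards at a (possibly negative-mean) argument, floored at zero.

        The LNA mean path is real-valued and may dip negative for extreme
        states; hazards are evaluated at the clipped argument and floored,
        with a debug log entry.
        """
        x = np.asarray(x, dtype=float)
        xc = np.maximum(x, 0.0)
        vals = np.array([h(xc) for h in hazards], dtype=float)
        if np.any(vals < 0):
            logger.debug("hazard floored at 0 for state %s", x)
        return np.maximum(vals, 0.0)


# --------------------------------------------------------------------------
# Concrete models
# --------------------------------------------------------------------------

def ttfl_network(params: ParameterSet) -> DelayedReactionNetwork:
    """The one-species delayed transcriptional feedback loop.

    Reactions: delayed transcription  0 -> X  with hazard
    ``nu(u) = R_max / (1 + (u/K_pc)^n)`` where ``u`` is the Gamma-kernel
    weighted past mRNA level, and first-order degradation  X -> 0  with
    hazard ``mu * x``.
    """
    hill = params.hill()
    transcription = Hazard(
        fn=lambda u: hill(max(u[0], 0.0)),
        grad=lambda u: np.array([hill.derivative(max(u[0], 0.0))]),
    )
    mu = params.mu
    degradation = Hazard(
        fn=lambda x: mu * x[0],
        grad=lambda x: np.array([mu]),
    )
    return DelayedReactionNetwork(
        n_species=1,
        stoich_delayed=np.array([[1.0]]),
        stoich_plain=np.array([[-1.0]]),
        hazards_delayed=[transcription],
        hazards_plain=[degradation],
        kernels=[GammaDelay(params.delay_mean, params.delay_sd, params.tau_max)],
    )


def birth_death_network(birth_rate: float, death_rate: float) -> DelayedReactionNetwork:
    """Linear immigration--death network (no delay): 0 -> X at constant
    rate, X -> 0 at rate ``death_rate * x``.  Used for the initialization
    window and as an analytically solvable test model."""
    if birth_rate < 0 or death_rate < 0:
        raise ValueError("rates must be non-negative")
    birth = Hazard(fn=lambda u: birth_rate, grad=lambda u: np.array([0.0]))
    death = Hazard(
        fn=lambda x: death_rate * x[0], grad=lambda x: np.array([death_rate])
    )
    return DelayedReactionNetwork(
        n_species=1,
        stoich_delayed=np.array([[1.0]]),
        stoich_plain=np.array([[-1.0]]),
        hazards_delayed=[birth],
        hazards_plain=[death],
        kernels=[PointMassDelay()],
    )


def deterministic_fixed_point(params: ParameterSet) -> float:
    """Positive root of ``nu(x) = mu x`` for the TTFL drift.

    The Hill repression is strictly decreasing and ``mu x`` strictly
    increasing, so the intersection is unique; located by bisection.
    """
    hill = params.hill()

    def balance(x: float) -> float:
        return hill(x) - params.mu * x

    hi = params.r_max / params.mu  # above this, mu*x exceeds nu's maximum
    return float(optimize.brentq(balance, 0.0, hi * 1.001, xtol=1e-10))
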