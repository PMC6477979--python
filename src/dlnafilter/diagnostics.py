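"""Model-checking instruments for the delayed-LNA filter.

Covers the evaluation battery used for this class of state-space models:
empirical coverage of predictive and partial-smoothing intervals against
known simulation truths, posterior-predictive simulation from thinned MCMC
draws, standardized one-step innovations, and a periodogram check for
residual periodicity (the circadian application looks for leftover power
near 24 h and 12 h).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .inference import ChainResult
from .model import ParameterSet
from .simulate import ObservedSeries, simulate_observations
from .window import FilterResult, filter_loglik

__all__ = [
    "CoverageReport",
    "coverage",
    "posterior_predictive",
    "standardized_residuals",
    "periodicity_check",
    "PeriodicityReport",
]


@dataclass
class CoverageReport:
    """Empirical coverage of central Gaussian intervals at one level."""

    nominal: float
    predictive: float
    smoothing: float
    n_intervals: int
    dt: float

    @property
    def pooled(self) -> float:
        """Coverage pooled over predictive and smoothing intervals."""
        return 0.5 * (self.predictive + self.smoothing)


def coverage(
    series_list: list[ObservedSeries],
    params_true: ParameterSet,
    level: float = 0.95,
    dt: float = 0.1,
    use_meta_scales: bool = True,
) -> CoverageReport:
    """Coverage of filter intervals against the noise-free binned signal.

    Runs the filter at the true parameters on each replicate and counts
    how often the noise-free integrated signal (stored by the simulator in
    ``series.meta['truth']``) falls inside the central ``level`` Gaussian
    interval of the one-step predictive and of the partial-smoothing
    density.  Observations in the initialization window are excluded.
    With ``use_meta_scales`` the replicate's realized ``kappa`` and
    ``sigma_eps`` (simulator metadata) override those in ``params_true``.
    """
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    z = np.inf if level == 1 else stats.norm.ppf(0.5 * (1 + level))
    hits_pred = hits_smooth = total = 0
    for series in series_list:
        if "truth" not in series.meta:
            raise ValueError("series lacks the noise-free truth in meta")
        params = params_true
        if use_meta_scales:
            params = params_true.replace(
                kappa=series.meta.get("kappa", params_true.kappa),
                sigma_eps=series.meta.get("sigma_eps", params_true.sigma_eps),
            )
        res = filter_loglik(series, params, dt=dt, smoothing=True)
        truth = np.asarray(series.meta["truth"], dtype=float)
        sl = slice(res.n_head, len(series))
        lo = res.pred_mean[sl] - z * np.sqrt(res.pred_var_signal[sl])
        hi = res.pred_mean[sl] + z * np.sqrt(res.pred_var_signal[sl])
        hits_pred += int(np.sum((truth[sl] >= lo) & (truth[sl] <= hi)))
        lo_s = res.smooth_mean[sl] - z * np.sqrt(res.smooth_var_signal[sl])
        hi_s = res.smooth_mean[sl] + z * np.sqrt(res.smooth_var_signal[sl])
        hits_smooth += int(np.sum((truth[sl] >= lo_s) & (truth[sl] <= hi_s)))
        total += truth[sl].size
    if total == 0:
        raise ValueError("no intervals outside the initialization window")
    return CoverageReport(
        nominal=level,
        predictive=hits_pred / total,
        smoothing=hits_smooth / total,
        n_intervals=total,
        dt=dt,
    )


def posterior_predictive(
    series: ObservedSeries,
    chain: ChainResult,
    n_draws: int,
    seed: int,
    burn_in: float = 0.5,
    level: float = 0.95,
) -> dict:
    """Simulate the observation process from thinned posterior draws.

    For each thinned parameter draw the delayed SSA is run over the span
    of ``series`` and converted to observations with the draw's kappa and
    sigma_eps.  Returns the simulated matrix and pointwise envelopes.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    post = chain.samples[int(burn_in * len(chain.samples)) :]
    idx = np.linspace(0, len(post) - 1, n_draws).astype(int)
    rng = np.random.default_rng(seed)
    horizon = float(series.times[-1] - series.times[0] + series.exposure)
    sims = []
    for k, i in enumerate(idx):
        values = dict(zip(chain.names, post[i]))
        params = ParameterSet.from_dict({**ParameterSet().to_dict(), **values})
        sim = simulate_observations(
            params, horizon, seed=int(rng.integers(2**31 - 1)),
            exposure=series.exposure, burn_in=2 * params.tau_max,
        )
        sims.append(sim.values[: len(series)])
    sims = np.vstack(sims)
    alpha = 0.5 * (1 - level)
    return {
        "times": series.times.copy(),
        "simulations": sims,
        "lo": np.quantile(sims, alpha, axis=0),
        "hi": np.quantile(sims, 1 - alpha, axis=0),
        "median": np.median(sims, axis=0),
    }


def standardized_residuals(
    series: ObservedSeries, result: FilterResult
) -> np.ndarray:
    """One-step innovations standardized by their predictive SD.

    ``(y - F rho) / sqrt(F P F' + sigma_eps^2)`` per observation, with the
    initialization window excluded (its moments come from the instrumental
    birth--death model, not the feedback loop).
    """
    if len(series) != result.pred_mean.size:
        raise ValueError("series and predictive moments length mismatch")
    sl = slice(result.n_head, len(series))
    return (series.values[sl] - result.pred_mean[sl]) / np.sqrt(
        result.pred_var_obs[sl]
    )


@dataclass
class PeriodicityReport:
    periods: np.ndarray  # top peak periods, hours
    power: np.ndarray  # normalized periodogram power at the peaks
    significant: np.ndarray  # bool per peak (white-noise null, Bonferroni)
    flag_24h: bool
    flag_12h: bool


def periodicity_check(
    residuals: np.ndarray,
    exposure: float,
    n_peaks: int = 3,
    alpha: float = 0.05,
) -> PeriodicityReport:
    """Periodogram scan of the residual series.

    Reports the top peaks with their normalized power and flags those
    exceeding a white-noise null threshold (periodogram ordinates of
    Gaussian noise are exponential; the threshold is Bonferroni-corrected
    over the number of Fourier frequencies).  Peaks near 24 h (+-2 h) and
    12 h (+-1.5 h) are flagged separately.
    """
    residuals = np.asarray(residuals, dtype=float)
    if residuals.size * exposure < 48.0:
        raise ValueError("need at least two full days of residuals")
    freqs, power = signal.periodogram(
        residuals - residuals.mean(), fs=1.0 / exposure
    )
    freqs, power = freqs[1:], power[1:]
    order = np.argsort(power)[::-1][:n_peaks]
    periods = 1.0 / freqs[order]
    mean_power = power.mean()
    threshold = mean_power * np.log(len(power) / alpha)
    significant = power[order] > threshold
    sig_periods = periods[significant]
    return PeriodicityReport(
        periods=periods,
        power=power[order] / mean_power,
        significant=significant,
        flag_24h=bool(np.any(np.abs(sig_periods - 24.0) <= 2.0)),
        flag_12h=bool(np.any(np.abs(sig_periods - 12.0) <= 1.5)),
    )
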