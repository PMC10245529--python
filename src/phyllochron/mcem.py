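"""Monte Carlo EM estimation of phyllochron parameters.

The observed data of a plant are censoring boxes on its latent appearance
times.  The E-step samples the latent Gaussian chain given the boxes with a
systematic-scan Gibbs sampler (each H_f has a truncated-Gaussian full
conditional by the bridge formula); the M-step is the closed-form Gaussian
MLE on the sampled increments.  The Monte Carlo sample size grows over
iterations and the final estimate averages the last iterates to smooth
residual Monte Carlo noise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from . import _engine
from .data_model import CensoringIntervals, LeafRangeWindow
from .likelihood import PhyllochronParams

__all__ = ["McemSettings", "McemTrace", "gibbs_sample_latent", "m_step", "fit_mcem"]


@dataclass(frozen=True)
class McemSettings:
    """Tuning knobs of the MCEM run.

    n_mc_start draws at iteration 1, growing by n_mc_growth_factor per
    iteration up to n_mc_max.  burn_in Gibbs sweeps are discarded at the
    first iteration only: chains persist across EM iterations and need just
    ``reburn`` sweeps after each parameter update.  Convergence: max
    relative parameter change < rel_tol over 3 consecutive iterations; the
    estimate averages the last n_avg_final iterates.
    """

    n_mc_start: int = 50
    n_mc_growth_factor: float = 1.2
    n_mc_max: int = 600
    burn_in: int = 100
    reburn: int = 10
    thinning: int = 5
    max_iter: int = 80
    rel_tol: float = 1e-3
    n_avg_final: int = 5
    seed: int | None = None
    sigma_floor: float = 1e-2
    init_sigma_floor: float = 1.0
    trace_nodes: int = 48
    final_nodes: int = 128

    def __post_init__(self):
        if min(self.n_mc_start, self.burn_in + 1, self.thinning, self.max_iter,
               self.n_avg_final) < 1 or self.rel_tol <= 0:
            raise ValueError("all MCEM settings must be positive")


@dataclass
class McemTrace:
    """Per-iteration parameter vectors, estimated log-likelihoods and Monte
    Carlo sample sizes of one MCEM run."""

    params: list
    loglik: list
    n_mc: list
    converged: bool
    seed: object
    final_loglik: float = float("nan")

    @classmethod
    def from_engine(cls, tr: _engine.FitTrace, seed) -> "McemTrace":
        return cls(params=tr.params, loglik=tr.loglik, n_mc=tr.n_mc,
                   converged=tr.converged, seed=seed)

    @property
    def n_iter(self) -> int:
        return len(self.params)


def _rng_from(settings: McemSettings, rng=None) -> np.random.Generator:
    if rng is not None:
        return rng
    return np.random.default_rng(settings.seed)


def gibbs_sample_latent(
    params: PhyllochronParams,
    intervals: Sequence[CensoringIntervals],
    n_samples: int,
    settings: McemSettings = McemSettings(),
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Sample latent appearance-time chains given the boxes.

    Returns an array (n_samples, n_plants, n_ranks); entries beyond a
    plant's active prefix are NaN.  burn_in sweeps are discarded and
    ``thinning`` sweeps separate retained draws; every retained sample
    satisfies all box constraints.
    """
    rng = _rng_from(settings, rng)
    pk = _engine.pack_intervals(list(intervals), params.window)
    N, R = pk.L.shape
    muC = np.full(N, params.mu_C)
    sgC = np.full(N, params.sigma_C)
    mu = np.broadcast_to(params.mu, (N, R - 1)) if R > 1 else np.zeros((N, 0))
    sg = np.broadcast_to(params.sigma, (N, R - 1)) if R > 1 else np.ones((N, 0))
    H = _engine.init_state(pk, muC, sgC, mu, sg)
    for _ in range(settings.burn_in):
        _engine.gibbs_sweep(H, pk, muC, sgC, mu, sg, rng)
    out = np.full((n_samples, N, R), np.nan)
    mask = pk.mask
    for k in range(n_samples):
        for _ in range(settings.thinning):
            _engine.gibbs_sweep(H, pk, muC, sgC, mu, sg, rng)
        out[k][mask] = H[mask]
    return out


def m_step(
    latent: np.ndarray,
    window: LeafRangeWindow,
    key: object = None,
) -> PhyllochronParams:
    """Gaussian MLE from latent samples (NaN = rank not modeled for plant).

    mu_f is the mean of the sampled increments Y_f = H_f - H_{f-1} over all
    (plant, sample) pairs where rank f is modeled; sigma_f^2 the MLE
    (divide-by-N) variance; (mu_C, sigma_C) likewise from H_{f_min}.
    """
    latent = np.asarray(latent, dtype=float)
    if latent.ndim == 2:
        latent = latent[None, :, :]
    S, N, R = latent.shape
    if R != window.n_ranks:
        raise ValueError("latent width does not match window")
    h0 = latent[:, :, 0]
    v0 = ~np.isnan(h0)
    if v0.any(axis=0).sum() < 2:
        raise ValueError("cumulated rank has fewer than 2 contributing plants")
    mu_C = float(np.nanmean(h0))
    sigma_C = float(np.nanstd(h0))  # MLE (ddof=0)
    mu = np.empty(R - 1)
    sigma = np.empty(R - 1)
    for r in range(1, R):
        y = latent[:, :, r] - latent[:, :, r - 1]
        valid = ~np.isnan(y)
        if valid.any(axis=0).sum() < 2:
            raise ValueError(
                f"rank {window.f_min + r} has fewer than 2 contributing plants")
        mu[r - 1] = np.nanmean(y)
        sigma[r - 1] = np.nanstd(y)
    if sigma_C == 0 or np.any(sigma == 0):
        raise ValueError("degenerate latent samples: zero variance estimate")
    return PhyllochronParams(key=key, window=window, mu_C=mu_C, sigma_C=sigma_C,
                             mu=mu, sigma=sigma)


def fit_mcem(
    data: Sequence[CensoringIntervals],
    window: LeafRangeWindow,
    settings: McemSettings = McemSettings(),
    rng: np.random.Generator | None = None,
    key: object = None,
    init: PhyllochronParams | None = None,
) -> tuple[PhyllochronParams, McemTrace]:
    """Fit one parameter set to a pooled dataset by MCEM.

    Returns (params, trace); ``trace.loglik`` carries the per-iteration
    observed-data log-likelihood (quadrature) and the final value is
    recomputed at higher quadrature order.  A non-converged run returns the
    averaged last iterates with a warning.
    """
    rng = _rng_from(settings, rng)
    pk = _engine.pack_intervals(list(data), window)
    n = pk.n_plants
    init_gp = None
    if init is not None:
        init_gp = _engine.GroupParams(
            muC=np.array([init.mu_C]), sgC=np.array([init.sigma_C]),
            mu=init.mu[None, :].copy(), sg=init.sigma[None, :].copy())
    fit = _engine.fit_groups(
        pk, cum_idx=np.zeros(n, dtype=int), n_cum=1,
        inst_idx=np.zeros(n, dtype=int), n_inst=1,
        settings=settings, rng=rng, init=init_gp)
    params = PhyllochronParams(
        key=key, window=window,
        mu_C=float(fit.params.muC[0]), sigma_C=float(fit.params.sgC[0]),
        mu=fit.params.mu[0], sigma=fit.params.sg[0])
    trace = McemTrace.from_engine(fit.trace, settings.seed)
    trace.final_loglik = fit.loglik
    return params, trace
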