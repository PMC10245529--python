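"""Parametric structures for the instant phyllochron vs leaf rank.

Within a genotype-year, the vector (mu_f) of mean intervals between leaf
appearances can be left free ("complete") or summarized by a parametric
trend: constant, constant-rate (linear in rank), piecewise-constant (one
jump at a breakpoint kappa) or continuous piecewise-linear (two slopes
joined at kappa).  Fitting uses MCEM with a constrained M-step (the
unconstrained mean update is projected onto the family by weighted least
squares; variances stay free per rank).  Model choice: candidates beating
the constant model in a chi-square LRT at p < alpha are admissible, and the
admissible model with the lowest AIC wins.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np

from . import _engine
from .data_model import CensoringIntervals, LeafRangeWindow
from .group_tests import chi2_pvalue
from .likelihood import PhyllochronParams
from .mcem import McemSettings, McemTrace

__all__ = [
    "FAMILIES",
    "SubmodelSpec",
    "SubmodelFit",
    "SelectionResult",
    "mu_from_submodel",
    "fit_submodel",
    "select_submodel",
]

FAMILIES = ("constant", "constant-rate", "piecewise-constant",
            "piecewise-linear", "complete")
_PIECEWISE = ("piecewise-constant", "piecewise-linear")


@dataclass
class SubmodelSpec:
    """A parametric family with its coefficients.

    ``kappa`` (piecewise families only) is a leaf rank strictly inside
    (f_min + 1, f_max).  theta: constant (a,); constant-rate (a, b);
    piecewise-constant (a1, a2); piecewise-linear (a, b1, b2) continuous at
    kappa; complete = the full mu vector.
    """

    family: str
    theta: np.ndarray
    kappa: int | None = None

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        self.theta = np.asarray(self.theta, dtype=float)
        if self.family in _PIECEWISE and self.kappa is None:
            raise ValueError(f"{self.family} requires a breakpoint kappa")

    def n_free(self, window: LeafRangeWindow) -> int:
        """Mean-structure parameter count; kappa counts as one estimated
        parameter in the piecewise families."""
        base = {"constant": 1, "constant-rate": 2, "piecewise-constant": 2,
                "piecewise-linear": 3, "complete": window.n_instant}[self.family]
        return base + (1 if self.family in _PIECEWISE else 0)


def _check_kappa(kappa: int, window: LeafRangeWindow) -> None:
    if not (window.f_min + 1 < kappa < window.f_max):
        raise ValueError(
            f"kappa={kappa} must lie strictly inside "
            f"({window.f_min + 1}, {window.f_max})")


def admissible_kappas(window: LeafRangeWindow) -> list[int]:
    return list(range(window.f_min + 2, window.f_max))


def _design(family: str, window: LeafRangeWindow, kappa: int | None) -> np.ndarray:
    """Design matrix mapping theta -> mu over ranks (f_min, f_max].

    The rank covariate is centered at f_min + 1 for slope stability.
    """
    ranks = window.instant_ranks()
    x = (ranks - (window.f_min + 1)).astype(float)
    if family == "constant":
        return np.ones((len(ranks), 1))
    if family == "constant-rate":
        return np.column_stack([np.ones_like(x), x])
    if family == "piecewise-constant":
        _check_kappa(kappa, window)
        return np.column_stack([(ranks <= kappa).astype(float),
                                (ranks > kappa).astype(float)])
    if family == "piecewise-linear":
        _check_kappa(kappa, window)
        # continuous at kappa: slope b1 up to kappa, b2 after
        x1 = np.minimum(x, kappa - (window.f_min + 1))
        x2 = np.maximum(x - (kappa - (window.f_min + 1)), 0.0)
        return np.column_stack([np.ones_like(x), x1, x2])
    if family == "complete":
        return np.eye(len(ranks))
    raise ValueError(family)


def mu_from_submodel(spec: SubmodelSpec, window: LeafRangeWindow) -> np.ndarray:
    """Instant-phyllochron vector implied by a parametric spec."""
    X = _design(spec.family, window, spec.kappa)
    if X.shape[1] != len(spec.theta):
        raise ValueError(
            f"{spec.family} expects {X.shape[1]} coefficients, got {len(spec.theta)}")
    return X @ spec.theta


def _wls_project(mu_hat: np.ndarray, wts: np.ndarray, X: np.ndarray):
    """Weighted least squares of mu_hat on the family design; returns
    (projected mu, theta)."""
    w = np.maximum(wts, 0.0)
    Xw = X * w[:, None]
    theta, *_ = np.linalg.lstsq(Xw.T @ X, Xw.T @ mu_hat, rcond=None)
    return X @ theta, theta


@dataclass
class SubmodelFit:
    spec: SubmodelSpec
    params: PhyllochronParams
    loglik: float
    trace: McemTrace
    window: LeafRangeWindow
    kappa_logliks: dict | None = None

    @property
    def k(self) -> int:
        """Total free parameters: (mu_C, sigma_C) + free per-rank sigmas +
        the family's mean-structure parameters."""
        return 2 + self.window.n_instant + self.spec.n_free(self.window)

    @property
    def aic(self) -> float:
        return 2.0 * self.k - 2.0 * self.loglik


def _run_constrained(data_pk, window, family, kappa, settings, rng, init=None):
    n = data_pk.n_plants
    zeros = np.zeros(n, dtype=int)
    if family == "complete":
        projector = None
    else:
        X = _design(family, window, kappa)
        last_theta = {}

        def projector(mu_hat, counts):
            proj, theta = _wls_project(mu_hat[0], counts[0], X)
            last_theta["theta"] = theta
            return proj[None, :]
    fit = _engine.fit_groups(data_pk, zeros, 1, zeros, 1, settings, rng,
                             init=init, mu_projector=projector)
    theta = None
    if family != "complete":
        X = _design(family, window, kappa)
        # recover theta from the averaged final mu (exact: mu lies in span(X))
        theta, *_ = np.linalg.lstsq(X, fit.params.mu[0], rcond=None)
    return fit, theta


def fit_submodel(
    data: Sequence[CensoringIntervals],
    window: LeafRangeWindow,
    family: str,
    settings: McemSettings = McemSettings(),
    rng: np.random.Generator | None = None,
    kappa: int | None = None,
    key: object = None,
) -> SubmodelFit:
    """MCEM fit of one parametric family on a genotype-year dataset.

    The M-step projects the unconstrained mean update onto the family by
    least squares weighted by per-rank contributing-sample counts; sigma_f,
    mu_C and sigma_C stay free.  For piecewise families with ``kappa`` not
    given, every admissible breakpoint is fitted (warm-started from the
    complete-model moments) and the one maximizing the observed-data
    (quadrature) likelihood is kept.
    """
    if family not in FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    pk = _engine.pack_intervals(list(data), window)
    min_ranks = {"constant": 1, "constant-rate": 2, "piecewise-constant": 3,
                 "piecewise-linear": 4, "complete": 1}[family]
    if window.n_instant < min_ranks:
        raise ValueError(
            f"window has {window.n_instant} instant ranks; {family} needs "
            f">= {min_ranks}")

    def finalize(fit, theta, kap, kappa_lls=None):
        spec = SubmodelSpec(family=family, theta=theta if theta is not None
                            else fit.params.mu[0].copy(), kappa=kap)
        params = PhyllochronParams(
            key=key, window=window, mu_C=float(fit.params.muC[0]),
            sigma_C=float(fit.params.sgC[0]), mu=fit.params.mu[0],
            sigma=fit.params.sg[0])
        return SubmodelFit(spec=spec, params=params, loglik=fit.loglik,
                           trace=McemTrace.from_engine(fit.trace, settings.seed),
                           window=window, kappa_logliks=kappa_lls)

    if family not in _PIECEWISE:
        fit, theta = _run_constrained(pk, window, family, None, settings, rng)
        return finalize(fit, theta, None)

    if kappa is not None:
        _check_kappa(kappa, window)
        fit, theta = _run_constrained(pk, window, family, kappa, settings, rng)
        return finalize(fit, theta, kappa)

    # breakpoint search: one full run for the first candidate, short
    # warm-started runs for the rest, argmax of the observed-data loglik;
    # the winner is then refit at the full budget so its reported
    # log-likelihood does not carry the selection's optimistic noise
    cands = admissible_kappas(window)
    if not cands:
        raise ValueError("window too short for a breakpoint family")
    best = None
    kappa_lls = {}
    warm = None
    refine = replace(settings, burn_in=settings.reburn,
                     max_iter=max(3, settings.max_iter // 3))
    for i, kap in enumerate(cands):
        st = settings if i == 0 else refine
        fit, theta = _run_constrained(pk, window, family, kap, st, rng, init=warm)
        kappa_lls[kap] = fit.loglik
        if warm is None:
            warm = fit.params
        if best is None or fit.loglik > best[0].loglik:
            best = (fit, theta, kap)
    kap = best[2]
    fit, theta = _run_constrained(pk, window, family, kap, settings, rng,
                                  init=best[0].params)
    kappa_lls[kap] = fit.loglik
    return finalize(fit, theta, kap, kappa_lls)


@dataclass
class SelectionResult:
    selected: SubmodelFit
    best_parametric: SubmodelFit | None
    table: dict
    alpha: float


def select_submodel(fits: dict, alpha: float = 0.01) -> SelectionResult:
    """LRT + AIC selection among fitted families.

    Candidates significantly better than the constant model (chi-square LRT
    at level ``alpha``) are admissible; among them the lowest AIC wins; if
    none is admissible the constant model is selected.  When the winner is
    the complete model, the best admissible strictly-parametric family is
    reported alongside.
    """
    if "constant" not in fits:
        raise ValueError("selection requires the constant-model fit")
    const = fits["constant"]
    table = {}
    admissible = []
    for name, fit in fits.items():
        row = {"loglik": fit.loglik, "k": fit.k, "aic": fit.aic,
               "p_vs_constant": float("nan")}
        if name != "constant":
            stat = 2.0 * (fit.loglik - const.loglik)
            df = fit.k - const.k
            row["p_vs_constant"] = chi2_pvalue(stat, df)
            if row["p_vs_constant"] < alpha:
                admissible.append((fit.aic, name, fit))
        table[name] = row
    if not admissible:
        selected = const
        best_param = None
    else:
        admissible.sort(key=lambda t: (t[0], t[1]))
        selected = admissible[0][2]
        best_param = None
        if selected.spec.family == "complete":
            non_complete = [t for t in admissible if t[1] != "complete"]
            if non_complete:
                best_param = non_complete[0][2]
    return SelectionResult(selected=selected, best_parametric=best_param,
                           table=table, alpha=alpha)
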