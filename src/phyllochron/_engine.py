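"""Vectorized numerical core for box-censored Gaussian chains.

The latent appearance times of one plant form a Gaussian Markov chain
H_{f_min} ~ N(mu_C, sigma_C^2), H_f = H_{f-1} + Y_f with independent
Y_f ~ N(mu_f, sigma_f^2); the data constrain each H_f to a box (L_f, U_f].
Everything here is vectorized across plants so that many plants (and, for
permutation tests, many relabelled copies of the dataset) are processed in
single array operations:

* ``pack_intervals``   : censoring intervals -> rectangular (L, U) arrays;
* ``gibbs_sweep``      : one systematic-scan update of all chains;
* ``chain_box_loglik`` : exact log P(L < H <= U) by forward Gauss-Legendre
                         quadrature on the chain;
* ``fit_groups``       : MCEM with arbitrary parameter-sharing groups for
                         the cumulated (mu_C, sigma_C) and instant
                         (mu_f, sigma_f) parameters.

Plants contribute their prefix of doubly-bounded ranks; ranks beyond a
plant's last finite upper bound (dissected plants) are excluded.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr, ndtri

_SQRT_2PI = math.sqrt(2.0 * math.pi)
_GL_CACHE: dict[int, tuple[np.ndarray, np.ndarray]] = {}


class EngineError(RuntimeError):
    pass


def _gl_nodes(n: int) -> tuple[np.ndarray, np.ndarray]:
    if n not in _GL_CACHE:
        _GL_CACHE[n] = leggauss(n)
    return _GL_CACHE[n]


# ---------------------------------------------------------------------------
# packing


@dataclass
class PackedData:
    """Rectangular view of a dataset on a fixed leaf-rank window.

    L, U have shape (n_plants, n_ranks); rank index r corresponds to leaf
    f_min + r.  ``n_active[p]`` is the length of plant p's prefix of
    doubly-bounded ranks (0 means the plant carries no modeled information).
    """

    L: np.ndarray
    U: np.ndarray
    n_active: np.ndarray
    plant_ids: list
    row_ids: list
    keys: list

    @property
    def n_plants(self) -> int:
        return self.L.shape[0]

    @property
    def n_ranks(self) -> int:
        return self.L.shape[1]

    @property
    def mask(self) -> np.ndarray:
        return np.arange(self.n_ranks)[None, :] < self.n_active[:, None]

    def subset(self, idx) -> "PackedData":
        idx = np.asarray(idx)
        return PackedData(
            L=self.L[idx], U=self.U[idx], n_active=self.n_active[idx],
            plant_ids=[self.plant_ids[i] for i in idx],
            row_ids=[self.row_ids[i] for i in idx],
            keys=[self.keys[i] for i in idx],
        )

    def tile(self, k: int) -> "PackedData":
        """k stacked copies (used to fit many relabellings jointly)."""
        return PackedData(
            L=np.tile(self.L, (k, 1)), U=np.tile(self.U, (k, 1)),
            n_active=np.tile(self.n_active, k),
            plant_ids=self.plant_ids * k, row_ids=self.row_ids * k,
            keys=self.keys * k,
        )


def pack_intervals(intervals: Sequence, window) -> PackedData:
    """Build rectangular arrays from CensoringIntervals on a window.

    A plant's active prefix stops at the first rank whose upper bound is
    infinite (right-censored) or that the plant does not model.
    """
    R = window.n_ranks
    n = len(intervals)
    L = np.zeros((n, R))
    U = np.full((n, R), np.inf)
    n_active = np.zeros(n, dtype=int)
    for p, ci in enumerate(intervals):
        for r in range(R):
            lo, hi = ci.interval(window.f_min + r)
            if not math.isfinite(hi):
                break
            if lo >= hi:
                raise EngineError(
                    f"plant {ci.plant_id}: empty box at rank {window.f_min + r}"
                )
            L[p, r], U[p, r] = lo, hi
            n_active[p] = r + 1
    return PackedData(
        L=L, U=U, n_active=n_active,
        plant_ids=[ci.plant_id for ci in intervals],
        row_ids=[ci.row_id for ci in intervals],
        keys=[ci.key for ci in intervals],
    )


# ---------------------------------------------------------------------------
# truncated-normal sampling and Gibbs sweep


def sample_truncnorm(m, s, lo, hi, rng) -> np.ndarray:
    """Inverse-CDF draws from N(m, s^2) restricted to (lo, hi]."""
    a = ndtr((lo - m) / s)
    b = ndtr((hi - m) / s)
    u = a + rng.random(np.shape(m)) * (b - a)
    x = m + s * ndtri(np.clip(u, 1e-15, 1.0 - 1e-16))
    # guard against tail underflow: stay inside the box
    return np.clip(x, np.nextafter(lo, np.inf), hi)


def gibbs_sweep(H, pk: PackedData, muC, sgC, mu, sg, rng) -> None:
    """One red-black (even/odd rank) scan of the full conditionals.

    muC, sgC: per-plant (n_plants,) arrays; mu, sg: per-plant
    (n_plants, n_ranks - 1) arrays of instant parameters.  The full
    conditional of H_r given its neighbours is Gaussian (bridge formula)
    truncated to the plant's box; ranks of one parity only neighbour the
    other parity, so each parity class is updated in a single vectorized
    draw.  Updates H in place.
    """
    N, R = pk.L.shape
    mask = pk.mask
    for parity in (0, 1):
        rs = np.arange(parity, R, 2)
        if len(rs) == 0:
            continue
        sub = mask[:, rs]
        if not sub.any():
            continue
        # left neighbour term: prior for r = 0, H_{r-1} + mu_r otherwise
        lm = np.empty((N, len(rs)))
        lv = np.empty((N, len(rs)))
        if parity == 0:
            lm[:, 0] = muC
            lv[:, 0] = sgC ** 2
            inner = rs[1:]
        else:
            inner = rs
        if len(inner):
            j0 = 1 if parity == 0 else 0
            lm[:, j0:] = H[:, inner - 1] + mu[:, inner - 1]
            lv[:, j0:] = sg[:, inner - 1] ** 2
        prec = 1.0 / lv
        num = lm / lv
        # right neighbour term where rank r+1 is active
        has_right = np.zeros((N, len(rs)), dtype=bool)
        rgt = rs[rs + 1 < R]
        if len(rgt):
            jj = np.nonzero(rs + 1 < R)[0]
            hr = mask[:, rgt + 1]
            rv = sg[:, rgt] ** 2
            rm = H[:, rgt + 1] - mu[:, rgt]
            prec[:, jj] += np.where(hr, 1.0 / rv, 0.0)
            num[:, jj] += np.where(hr, rm / rv, 0.0)
        m = num / prec
        s = np.sqrt(1.0 / prec)
        act = sub
        draw = sample_truncnorm(m[act], s[act], pk.L[:, rs][act],
                                pk.U[:, rs][act], rng)
        cols = H[:, rs]
        cols[act] = draw
        H[:, rs] = cols


def init_state(pk: PackedData, muC=None, sgC=None, mu=None, sg=None) -> np.ndarray:
    """Feasible starting chain.

    Boxes are axis-aligned, so any per-coordinate interior point is jointly
    feasible.  With parameters given, start at the marginal means clipped
    into the boxes (fast mixing even for near-unconstrained boxes);
    otherwise use box midpoints (bounded below by the lower edge).
    """
    N, R = pk.L.shape
    H = np.zeros_like(pk.L)
    mask = pk.mask
    if muC is not None:
        m = np.empty((N, R))
        m[:, 0] = np.asarray(muC, dtype=float)
        for r in range(1, R):
            m[:, r] = m[:, r - 1] + mu[:, r - 1]
        span = np.minimum(pk.U - pk.L, 1e6)
        lo = pk.L + 1e-6 * span
        hi = np.where(np.isfinite(pk.U), pk.U, pk.L + span)
        start = np.clip(m, lo, hi)
    else:
        start = 0.5 * (pk.L + np.minimum(pk.U, pk.L + 1e6))
    H[mask] = start[mask]
    return H


# ---------------------------------------------------------------------------
# exact observed-data log-likelihood (forward quadrature on the chain)


def chain_box_loglik(pk: PackedData, muC, sgC, mu, sg, n_nodes: int = 96,
                     tail: float = 10.0) -> np.ndarray:
    """log P(L_r < H_r <= U_r, r < n_active) per plant.

    Forward pass: the density of H_r restricted to its box is carried on
    Gauss-Legendre nodes and propagated through the Gaussian increment
    kernel.  Integration ranges are the boxes intersected with marginal
    mean +/- ``tail`` sd; plants whose box lies wholly outside that range
    get -inf.  Plants with no active rank contribute 0.
    """
    N, R = pk.L.shape
    muC = np.broadcast_to(np.asarray(muC, dtype=float), (N,))
    sgC = np.broadcast_to(np.asarray(sgC, dtype=float), (N,))
    if R > 1:
        mu = np.broadcast_to(np.asarray(mu, dtype=float), (N, R - 1))
        sg = np.broadcast_to(np.asarray(sg, dtype=float), (N, R - 1))
    # marginal moments of H_r per plant
    marg_m = np.empty((N, R))
    marg_v = np.empty((N, R))
    marg_m[:, 0] = muC
    marg_v[:, 0] = sgC ** 2
    for r in range(1, R):
        marg_m[:, r] = marg_m[:, r - 1] + mu[:, r - 1]
        marg_v[:, r] = marg_v[:, r - 1] + sg[:, r - 1] ** 2
    marg_s = np.sqrt(marg_v)

    x, w = _gl_nodes(n_nodes)
    logp = np.zeros(N)
    lognorm = np.zeros(N)
    dead = pk.n_active == 0  # finished (or failed) plants
    p = None
    nodes_prev = None
    wts_prev = None
    for r in range(R):
        live = ~dead & (pk.n_active > r)
        if not live.any():
            break
        lo = np.maximum(pk.L[:, r], marg_m[:, r] - tail * marg_s[:, r])
        hi = np.minimum(pk.U[:, r], marg_m[:, r] + tail * marg_s[:, r])
        bad = live & (hi <= lo)
        if bad.any():
            warnings.warn("box with negligible probability: returning -inf")
            logp[bad] = -np.inf
            dead |= bad
            live &= ~bad
        half = 0.5 * (hi - lo)
        nodes = (0.5 * (hi + lo))[:, None] + half[:, None] * x[None, :]
        wts = half[:, None] * w[None, :]
        if r == 0:
            z = (nodes - muC[:, None]) / sgC[:, None]
            p = np.exp(-0.5 * z * z) / (sgC[:, None] * _SQRT_2PI)
        else:
            s_r = sg[:, r - 1]
            wp = wts_prev * p
            p = np.empty_like(nodes)
            # chunk plants: keeps the (chunk, G, G) kernel in cache and
            # avoids gigabyte-scale temporaries for batched fits
            step = max(1, int(4e6 // (n_nodes * n_nodes)))
            for a in range(0, N, step):
                b = min(a + step, N)
                z = nodes[a:b, :, None] - nodes_prev[a:b, None, :]
                z -= mu[a:b, r - 1][:, None, None]
                z /= s_r[a:b, None, None]
                z *= z
                z *= -0.5
                np.exp(z, out=z)
                z /= s_r[a:b, None, None] * _SQRT_2PI
                np.einsum("nij,nj->ni", z, wp[a:b], out=p[a:b])
        # rescale to avoid underflow over long chains
        c = p.max(axis=1)
        ok = live & (c > 0)
        under = live & (c <= 0)
        if under.any():
            logp[under] = -np.inf
            dead |= under
        c_safe = np.where(c > 0, c, 1.0)
        p = p / c_safe[:, None]
        lognorm = lognorm + np.where(ok, np.log(c_safe), 0.0)
        finish = ok & (pk.n_active == r + 1)
        if finish.any():
            tot = np.einsum("ni,ni->n", wts, p)
            good = finish & (tot > 0)
            logp[good] = lognorm[good] + np.log(tot[good])
            logp[finish & ~good] = -np.inf
            dead |= finish
        nodes_prev, wts_prev = nodes, wts
    return logp


# ---------------------------------------------------------------------------
# MCEM


@dataclass
class GroupParams:
    """Parameter state for a sharing structure: cumulated parameters per
    cumulated-group, instant parameters per instant-group."""

    muC: np.ndarray      # (n_cum,)
    sgC: np.ndarray      # (n_cum,)
    mu: np.ndarray       # (n_inst, R-1)
    sg: np.ndarray       # (n_inst, R-1)

    def flat(self) -> np.ndarray:
        return np.concatenate([self.muC, self.sgC, self.mu.ravel(), self.sg.ravel()])

    def copy(self) -> "GroupParams":
        return GroupParams(self.muC.copy(), self.sgC.copy(),
                           self.mu.copy(), self.sg.copy())


@dataclass
class FitTrace:
    params: list = field(default_factory=list)
    loglik: list = field(default_factory=list)
    n_mc: list = field(default_factory=list)
    converged: bool = False
    seed: object = None

    @property
    def n_iter(self) -> int:
        return len(self.params)


@dataclass
class GroupFit:
    params: GroupParams
    loglik: float
    logp_plant: np.ndarray
    trace: FitTrace


def _per_plant(params: GroupParams, cum_idx, inst_idx):
    return (params.muC[cum_idx], params.sgC[cum_idx],
            params.mu[inst_idx], params.sg[inst_idx])


def moment_init(pk: PackedData, cum_idx, n_cum, inst_idx, n_inst,
                sigma_floor: float = 1.0) -> GroupParams:
    """Method-of-moments start: interval midpoints stand in for the latent
    appearance times; sigma starts at half the mean interval width (floored).
    """
    N, R = pk.L.shape
    mask = pk.mask
    mid = np.where(mask, 0.5 * (pk.L + np.where(np.isfinite(pk.U), pk.U, pk.L)), np.nan)
    width = np.where(mask, np.minimum(pk.U - pk.L, 1e6), np.nan)

    def group_mean(values, valid, idx, n_groups):
        tot = np.bincount(idx[valid], weights=values[valid], minlength=n_groups)
        cnt = np.bincount(idx[valid], minlength=n_groups)
        overall = values[valid].mean() if valid.any() else 0.0
        return np.where(cnt > 0, tot / np.maximum(cnt, 1), overall)

    v0 = mask[:, 0] & np.isfinite(mid[:, 0])
    muC = group_mean(mid[:, 0], v0, cum_idx, n_cum)
    sgC = np.maximum(group_mean(width[:, 0], v0, cum_idx, n_cum) / 2.0, sigma_floor)
    mu = np.zeros((n_inst, max(R - 1, 0)))
    sg = np.ones((n_inst, max(R - 1, 0)))
    for r in range(1, R):
        d = mid[:, r] - mid[:, r - 1]
        v = mask[:, r] & np.isfinite(d)
        mu[:, r - 1] = group_mean(d, v, inst_idx, n_inst)
        sg[:, r - 1] = np.maximum(group_mean(width[:, r], v, inst_idx, n_inst) / 2.0,
                                  sigma_floor)
    return GroupParams(muC, sgC, mu, sg)


def fit_groups(
    pk: PackedData,
    cum_idx: np.ndarray,
    n_cum: int,
    inst_idx: np.ndarray,
    n_inst: int,
    settings,
    rng: np.random.Generator,
    init: GroupParams | None = None,
    mu_projector: Callable | None = None,
    trace_loglik: bool = True,
) -> GroupFit:
    """Monte Carlo EM on a packed dataset with parameter-sharing groups.

    E-step: Gibbs sampling of the latent chains given current parameters
    (chains persist across iterations; full burn-in only once).  M-step:
    closed-form Gaussian MLE per group; ``mu_projector(mu_hat, counts)`` may
    constrain the instant-mean update (parametric sub-models).  Stops when
    the max relative parameter change stays below rel_tol for 3 consecutive
    iterations; the final estimate averages the last n_avg_final iterates.
    """
    N, R = pk.L.shape
    cum_idx = np.asarray(cum_idx, dtype=int)
    inst_idx = np.asarray(inst_idx, dtype=int)
    if cum_idx.shape != (N,) or inst_idx.shape != (N,):
        raise EngineError("group index arrays must have one entry per plant")
    for name, idx, n_groups in (("cumulated", cum_idx, n_cum),
                                ("instant", inst_idx, n_inst)):
        cnt = np.bincount(idx[pk.n_active > 0], minlength=n_groups)
        if (cnt == 0).any():
            raise EngineError(f"empty {name} sharing cell(s): {np.nonzero(cnt == 0)[0]}")

    params = init.copy() if init is not None else moment_init(
        pk, cum_idx, n_cum, inst_idx, n_inst, sigma_floor=settings.init_sigma_floor)
    muC_p, sgC_p, mu_p, sg_p = _per_plant(params, cum_idx, inst_idx)
    H = init_state(pk, muC_p, sgC_p, mu_p, sg_p)
    mask = pk.mask
    trace = FitTrace(seed=None)
    prev_flat = params.flat()
    rel_hist: list[float] = []

    for it in range(settings.max_iter):
        n_mc = int(min(round(settings.n_mc_start * settings.n_mc_growth_factor ** it),
                       settings.n_mc_max))
        muC_p, sgC_p, mu_p, sg_p = _per_plant(params, cum_idx, inst_idx)
        burn = settings.burn_in if it == 0 else settings.reburn
        for _ in range(burn):
            gibbs_sweep(H, pk, muC_p, sgC_p, mu_p, sg_p, rng)
        # accumulate sufficient statistics over retained draws
        sC = np.zeros(n_cum); sC2 = np.zeros(n_cum); nC = np.zeros(n_cum)
        sI = np.zeros((n_inst, max(R - 1, 0)))
        sI2 = np.zeros_like(sI)
        nI = np.zeros_like(sI)
        act0 = mask[:, 0]
        for _ in range(n_mc):
            for _ in range(settings.thinning):
                gibbs_sweep(H, pk, muC_p, sgC_p, mu_p, sg_p, rng)
            h0 = H[act0, 0]
            sC += np.bincount(cum_idx[act0], weights=h0, minlength=n_cum)
            sC2 += np.bincount(cum_idx[act0], weights=h0 * h0, minlength=n_cum)
            nC += np.bincount(cum_idx[act0], minlength=n_cum)
            for r in range(1, R):
                a = mask[:, r]
                if not a.any():
                    break
                y = H[a, r] - H[a, r - 1]
                gi = inst_idx[a]
                sI[:, r - 1] += np.bincount(gi, weights=y, minlength=n_inst)
                sI2[:, r - 1] += np.bincount(gi, weights=y * y, minlength=n_inst)
                nI[:, r - 1] += np.bincount(gi, minlength=n_inst)
        # M-step (MLE: variance divided by N)
        n_plants_I = nI / max(n_mc, 1)
        low = np.argwhere(n_plants_I < 2)
        if low.size:
            g, r = low[0]
            raise EngineError(
                f"instant rank index {int(r) + 1} (group {int(g)}) has "
                f"fewer than 2 contributing plants")
        muC_new = sC / np.maximum(nC, 1)
        varC = sC2 / np.maximum(nC, 1) - muC_new ** 2
        mu_new = sI / np.maximum(nI, 1)
        varI = sI2 / np.maximum(nI, 1) - mu_new ** 2
        if np.any(varC <= 0) or (varI.size and np.any(varI[nI > 0] <= 0)):
            raise EngineError("degenerate latent samples: zero variance estimate")
        if mu_projector is not None and R > 1:
            mu_new = mu_projector(mu_new, n_plants_I)
            # sigma stays free per rank: re-center second moment on projection
            varI = sI2 / np.maximum(nI, 1) - 2 * mu_new * sI / np.maximum(nI, 1) \
                + mu_new ** 2
        params = GroupParams(
            muC=muC_new,
            sgC=np.maximum(np.sqrt(varC), settings.sigma_floor),
            mu=mu_new,
            sg=np.maximum(np.sqrt(np.maximum(varI, 0.0)), settings.sigma_floor),
        )
        trace.params.append(params.copy())
        trace.n_mc.append(n_mc)
        if trace_loglik:
            muC_p, sgC_p, mu_p, sg_p = _per_plant(params, cum_idx, inst_idx)
            lp = chain_box_loglik(pk, muC_p, sgC_p, mu_p, sg_p,
                                  n_nodes=settings.trace_nodes)
            trace.loglik.append(float(lp.sum()))
        else:
            trace.loglik.append(np.nan)
        # convergence is judged on the smoothed estimate (mean of the last
        # n_avg_final iterates) — the quantity actually reported — which
        # filters the Monte Carlo jitter of individual iterations
        tail_flat = [q.flat() for q in trace.params[-settings.n_avg_final:]]
        flat = np.mean(tail_flat, axis=0)
        denom = np.abs(prev_flat) + 1e-8
        rel_hist.append(float(np.max(np.abs(flat - prev_flat) / denom)))
        prev_flat = flat
        if len(rel_hist) >= 3 and max(rel_hist[-3:]) < settings.rel_tol:
            trace.converged = True
            break
    if not trace.converged:
        warnings.warn("MCEM did not converge within max_iter; returning last iterates")
    # final estimate: average of the last n_avg_final iterates
    tail_iters = trace.params[-settings.n_avg_final:]
    params = GroupParams(
        muC=np.mean([p.muC for p in tail_iters], axis=0),
        sgC=np.mean([p.sgC for p in tail_iters], axis=0),
        mu=np.mean([p.mu for p in tail_iters], axis=0),
        sg=np.mean([p.sg for p in tail_iters], axis=0),
    )
    muC_p, sgC_p, mu_p, sg_p = _per_plant(params, cum_idx, inst_idx)
    logp = chain_box_loglik(pk, muC_p, sgC_p, mu_p, sg_p,
                            n_nodes=settings.final_nodes)
    return GroupFit(params=params, loglik=float(logp.sum()),
                    logp_plant=logp, trace=trace)
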