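"""Nested genotype-group models and row-permutation likelihood-ratio tests.

The plant material is hierarchical: ancestral line > selection population
(Early/Late) > genotype.  Seven nested models M_ij tie the cumulated
(index i) and instant (index j) phyllochron parameters at increasing depth
(0 identical, 1 line, 2 selection, 3 genotype).  Model pairs are compared
with the LRT statistic; because plants within a field row are correlated,
the null distribution is built by permuting whole rows between groups
rather than relying on the chi-square asymptotics (also reported).
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

from . import _engine
from .data_model import CensoringIntervals, GenotypeKey, LeafRangeWindow
from .likelihood import PhyllochronParams
from .mcem import McemSettings, McemTrace

__all__ = [
    "SharingSpec",
    "SharedFit",
    "PermutationResult",
    "fit_shared",
    "lrt",
    "chi2_pvalue",
    "permutation_test",
]

_VALID_SPECS = {(0, 0), (1, 0), (1, 1), (2, 1), (2, 2), (3, 2), (3, 3)}
_LEVEL_ATTRS = ("line", "selection", "genotype")
_MIN_PERMS = 20


@dataclass(frozen=True)
class SharingSpec:
    """Sharing depths (i = cumulated, j = instant) of a model M_ij."""

    cumulated_level: int
    instant_level: int

    def __post_init__(self):
        if (self.cumulated_level, self.instant_level) not in _VALID_SPECS:
            raise ValueError(
                f"M_{self.cumulated_level}{self.instant_level} is not one of "
                f"the seven nested models {sorted(_VALID_SPECS)}")

    @property
    def name(self) -> str:
        return f"M{self.cumulated_level}{self.instant_level}"

    @property
    def max_level(self) -> int:
        return max(self.cumulated_level, self.instant_level)

    def nests(self, other: "SharingSpec") -> bool:
        """True if ``other`` (reduced) is nested in self (full)."""
        return (self.cumulated_level >= other.cumulated_level
                and self.instant_level >= other.instant_level
                and self != other)

    @classmethod
    def parse(cls, name: str) -> "SharingSpec":
        digits = [ch for ch in name if ch.isdigit()]
        if len(digits) != 2:
            raise ValueError(f"cannot parse sharing spec {name!r}")
        return cls(int(digits[0]), int(digits[1]))


def _level_label(key: GenotypeKey, level: int) -> tuple:
    """Grouping label at a hierarchy depth.  Analyses are per-year, so the
    year is always part of the label."""
    return (key.year,) + tuple(getattr(key, a) for a in _LEVEL_ATTRS[:level])


@dataclass
class SharedFit:
    spec: SharingSpec
    window: LeafRangeWindow
    cum_cells: list
    inst_cells: list
    params: _engine.GroupParams
    loglik: float
    trace: McemTrace
    n_plants: int

    @property
    def n_params(self) -> int:
        """Free parameters: each cumulated cell carries (mu_C, sigma_C) and
        each instant cell (mu_f, sigma_f) per modeled instant rank."""
        return 2 * len(self.cum_cells) + 2 * self.window.n_instant * len(self.inst_cells)

    def param_map(self) -> dict:
        """(cum_cell, inst_cell) -> PhyllochronParams."""
        out = {}
        for ci, cc in enumerate(self.cum_cells):
            for ii, ic in enumerate(self.inst_cells):
                out[(cc, ic)] = PhyllochronParams(
                    key=(cc, ic), window=self.window,
                    mu_C=float(self.params.muC[ci]),
                    sigma_C=float(self.params.sgC[ci]),
                    mu=self.params.mu[ii], sigma=self.params.sg[ii])
        return out

    def params_for(self, key: GenotypeKey) -> PhyllochronParams:
        cc = _level_label(key, self.spec.cumulated_level)
        ic = _level_label(key, self.spec.instant_level)
        return self.param_map()[(cc, ic)]


def _cells_and_idx(keys: Sequence[GenotypeKey], level: int):
    labels = [_level_label(k, level) for k in keys]
    cells = sorted(set(labels))
    pos = {c: i for i, c in enumerate(cells)}
    return cells, np.array([pos[l] for l in labels], dtype=int)


def fit_shared(
    data: Sequence[CensoringIntervals],
    spec: SharingSpec,
    window: LeafRangeWindow,
    settings: McemSettings = McemSettings(),
    rng: np.random.Generator | None = None,
    init: _engine.GroupParams | None = None,
) -> SharedFit:
    """Joint MCEM fit of a sharing model: cumulated parameters pooled at
    depth i, instant parameters pooled at depth j, in one fit."""
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    data = list(data)
    pk = _engine.pack_intervals(data, window)
    cum_cells, cum_idx = _cells_and_idx(pk.keys, spec.cumulated_level)
    inst_cells, inst_idx = _cells_and_idx(pk.keys, spec.instant_level)
    fit = _engine.fit_groups(pk, cum_idx, len(cum_cells), inst_idx,
                             len(inst_cells), settings, rng, init=init)
    return SharedFit(spec=spec, window=window, cum_cells=cum_cells,
                     inst_cells=inst_cells, params=fit.params,
                     loglik=fit.loglik,
                     trace=McemTrace.from_engine(fit.trace, settings.seed),
                     n_plants=pk.n_plants)


def lrt(full_fit: SharedFit, reduced_fit: SharedFit, eps: float = 0.5) -> float:
    """LRT statistic 2 (ll_full - ll_reduced) for nested sharing models.

    Slightly negative values (within the combined quadrature/MCEM tolerance
    ``eps``) can arise from Monte Carlo noise; values below -eps warn.
    """
    if not full_fit.spec.nests(reduced_fit.spec):
        raise ValueError(
            f"{full_fit.spec.name} does not nest {reduced_fit.spec.name}")
    stat = 2.0 * (full_fit.loglik - reduced_fit.loglik)
    if stat < -eps:
        warnings.warn(f"LRT statistic {stat:.3g} < -{eps}: MCEM fits may "
                      "not have converged")
    return stat


def chi2_pvalue(statistic: float, df: int) -> float:
    """Upper-tail chi-square probability of the LRT statistic."""
    if df <= 0:
        raise ValueError("df must be >= 1")
    return float(_chi2.sf(max(statistic, 0.0), df))


@dataclass
class PermutationResult:
    observed_lrt: float
    null_lrts: np.ndarray
    n_permutations: int
    exhaustive: bool
    p_value: float
    df: int = 0
    chi2_p: float = float("nan")
    full_fit: SharedFit | None = None
    reduced_fit: SharedFit | None = None


def _multiset_orderings(labels: tuple):
    """Distinct orderings of a label multiset, lexicographic."""
    uniq = sorted(set(labels))
    counts = {u: labels.count(u) for u in uniq}

    def rec(remaining):
        if remaining == 0:
            yield ()
            return
        for u in uniq:
            if counts[u] > 0:
                counts[u] -= 1
                for tail in rec(remaining - 1):
                    yield (u,) + tail
                counts[u] += 1

    yield from rec(len(labels))


def _n_multiset_orderings(labels: tuple) -> int:
    n = math.factorial(len(labels))
    for u in set(labels):
        n //= math.factorial(labels.count(u))
    return n


def _default_perm_settings(settings: McemSettings) -> McemSettings:
    return replace(settings,
                   n_mc_start=max(15, settings.n_mc_start // 2),
                   n_mc_max=min(settings.n_mc_max, 120),
                   burn_in=min(settings.burn_in, 40),
                   reburn=min(settings.reburn, 5),
                   thinning=min(settings.thinning, 2),
                   max_iter=min(settings.max_iter, 6),
                   n_avg_final=min(settings.n_avg_final, 2),
                   trace_nodes=min(settings.trace_nodes, 40),
                   final_nodes=min(settings.final_nodes, 48))


def _batched_loglik(pk, keys, row_of_plant, assignments, spec, level,
                    warm: SharedFit, settings, rng, chunk: int):
    """Observed-data log-likelihood of ``spec`` refitted under each row-label
    assignment, all assignments fitted jointly through the engine.

    ``assignments`` is an (n_assign, n_rows) array of label codes.  Returns
    an (n_assign,) array of log-likelihoods.
    """
    n_assign, n_rows = assignments.shape
    N = pk.n_plants

    depends = spec.max_level >= level
    base_cum = [_level_label(k, spec.cumulated_level) for k in keys]
    base_inst = [_level_label(k, spec.instant_level) for k in keys]
    cum_cells = sorted(set(base_cum))
    inst_cells = sorted(set(base_inst))
    cum_pos = {c: i for i, c in enumerate(cum_cells)}
    inst_pos = {c: i for i, c in enumerate(inst_cells)}

    def idx_for(assign_row):
        def lab(base, lvl):
            if lvl == level:
                return [b[:-1] + (assign_row[row_of_plant[p]],)
                        for p, b in enumerate(base)]
            return base
        cum = np.array([cum_pos[l] for l in lab(base_cum, spec.cumulated_level)])
        inst = np.array([inst_pos[l] for l in lab(base_inst, spec.instant_level)])
        return cum, inst

    if not depends:
        # the permuted attribute is invisible to this spec: one fit serves all
        cum, inst = idx_for(assignments[0])
        fit = _engine.fit_groups(pk, cum, len(cum_cells), inst, len(inst_cells),
                                 settings, rng, init=warm.params,
                                 trace_loglik=False)
        return np.full(n_assign, fit.loglik)

    lls = np.empty(n_assign)
    n_cum, n_inst = len(cum_cells), len(inst_cells)
    for start in range(0, n_assign, chunk):
        block = assignments[start:start + chunk]
        k = len(block)
        pk_big = pk.tile(k)
        cum_big = np.empty(k * N, dtype=int)
        inst_big = np.empty(k * N, dtype=int)
        for a, assign_row in enumerate(block):
            cum, inst = idx_for(assign_row)
            cum_big[a * N:(a + 1) * N] = cum + a * n_cum
            inst_big[a * N:(a + 1) * N] = inst + a * n_inst
        init = _engine.GroupParams(
            muC=np.tile(warm.params.muC, k), sgC=np.tile(warm.params.sgC, k),
            mu=np.tile(warm.params.mu, (k, 1)), sg=np.tile(warm.params.sg, (k, 1)))
        fit = _engine.fit_groups(pk_big, cum_big, k * n_cum, inst_big, k * n_inst,
                                 settings, rng, init=init, trace_loglik=False)
        lls[start:start + k] = fit.logp_plant.reshape(k, N).sum(axis=1)
    return lls


def permutation_test(
    data: Sequence[CensoringIntervals],
    spec_full: SharingSpec,
    spec_reduced: SharingSpec,
    window: LeafRangeWindow,
    max_perms: int = 200,
    settings: McemSettings = McemSettings(),
    rng: np.random.Generator | None = None,
    perm_settings: McemSettings | None = None,
    chunk: int = 256,
) -> PermutationResult:
    """Row-permutation LRT between two nested sharing models.

    The permutation unit is the field row.  The permuted attribute is the
    deepest hierarchy level the full model distinguishes, shuffled between
    rows within strata defined by the next level up (and the year), which
    preserves per-group row counts and within-row correlation.  All distinct
    assignments are enumerated when there are at most ``max_perms``;
    otherwise ``max_perms`` distinct non-identity assignments are sampled
    without replacement and the add-one convention gives the p-value.  Null
    and observed statistics are computed with the same reduced MCEM budget,
    warm-started from the full-budget observed fits, so that they are
    exchangeable under the null.
    """
    if not spec_full.nests(spec_reduced):
        raise ValueError(f"{spec_full.name} does not nest {spec_reduced.name}")
    level = spec_full.max_level
    if level < 1:
        raise ValueError("full model distinguishes no groups: nothing to permute")
    rng = rng if rng is not None else np.random.default_rng(settings.seed)
    data = list(data)
    pk = _engine.pack_intervals(data, window)
    keys = pk.keys

    # rows with their stratum and permuted-attribute label
    row_ids = sorted(set(pk.row_ids))
    row_pos = {r: i for i, r in enumerate(row_ids)}
    row_of_plant = np.array([row_pos[r] for r in pk.row_ids], dtype=int)
    row_stratum: dict = {}
    row_label: dict = {}
    attr = _LEVEL_ATTRS[level - 1]
    for k, r in zip(keys, pk.row_ids):
        lab = getattr(k, attr)
        strat = _level_label(k, level - 1)
        if r in row_label and (row_label[r] != lab or row_stratum[r] != strat):
            raise ValueError(f"row {r} spans several {attr} groups")
        row_label[r], row_stratum[r] = lab, strat

    strata: dict = {}
    for r in row_ids:
        strata.setdefault(row_stratum[r], []).append(r)
    for s, rows in strata.items():
        if len(set(row_label[r] for r in rows)) < 2 and len(strata) == 1:
            raise ValueError(f"stratum {s}: all rows in one group (degenerate)")

    n_assign_total = 1
    for s, rows in strata.items():
        n_assign_total *= _n_multiset_orderings(tuple(row_label[r] for r in rows))
    if n_assign_total <= _MIN_PERMS:
        raise ValueError(
            f"only {n_assign_total} distinct row assignments (<= {_MIN_PERMS}); "
            "the permutation test is not advisable here")

    identity = tuple(row_label[r] for r in row_ids)
    stratum_rows = {s: [row_pos[r] for r in rows] for s, rows in strata.items()}

    exhaustive = n_assign_total <= max_perms
    assignments: list[tuple] = []
    if exhaustive:
        per_stratum = {s: list(_multiset_orderings(
            tuple(row_label[row_ids[i]] for i in idxs)))
            for s, idxs in stratum_rows.items()}
        s_keys = list(per_stratum)
        for combo in itertools.product(*(per_stratum[s] for s in s_keys)):
            assign = list(identity)
            for s, ordering in zip(s_keys, combo):
                for i, lab in zip(stratum_rows[s], ordering):
                    assign[i] = lab
            assignments.append(tuple(assign))
    else:
        seen = {identity}
        guard = 0
        while len(assignments) < max_perms:
            assign = list(identity)
            for s, idxs in stratum_rows.items():
                labs = [identity[i] for i in idxs]
                perm = rng.permutation(len(labs))
                for i, j in zip(idxs, perm):
                    assign[i] = labs[j]
            t = tuple(assign)
            guard += 1
            if guard > 100 * max_perms:
                raise RuntimeError("failed to sample distinct assignments")
            if t in seen:
                continue
            seen.add(t)
            assignments.append(t)

    # full-budget observed fits (reported; warm starts for the batch)
    full_fit = fit_shared(data, spec_full, window, settings, rng)
    reduced_fit = fit_shared(data, spec_reduced, window, settings, rng)
    df = full_fit.n_params - reduced_fit.n_params

    ps = perm_settings if perm_settings is not None else _default_perm_settings(settings)
    todo = assignments if exhaustive else [identity] + assignments
    arr = np.array(todo, dtype=object)
    ll_full = _batched_loglik(pk, keys, row_of_plant, arr, spec_full, level,
                              full_fit, ps, rng, chunk)
    ll_red = _batched_loglik(pk, keys, row_of_plant, arr, spec_reduced, level,
                             reduced_fit, ps, rng, chunk)
    lrts = 2.0 * (ll_full - ll_red)

    if exhaustive:
        obs = float(lrts[todo.index(identity)])
        null_lrts = lrts
        p = float(np.mean(null_lrts >= obs))
    else:
        obs = float(lrts[0])
        null_lrts = lrts[1:]
        p = (1.0 + float(np.sum(null_lrts >= obs))) / (1.0 + len(null_lrts))
    return PermutationResult(
        observed_lrt=obs, null_lrts=np.asarray(null_lrts, dtype=float),
        n_permutations=len(null_lrts), exhaustive=exhaustive, p_value=p,
        df=df, chi2_p=chi2_pvalue(obs, df) if df > 0 else float("nan"),
        full_fit=full_fit, reduced_fit=reduced_fit)
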