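"""Windowed-climate regression of the phyllochron and the false-climate test.

The estimated mean interval between leaf appearances, expressed in calendar
days, is regressed on cumulative climate sums over short backward windows
(1, 2, 3, 5, 10, 20 days by default) preceding the mean appearance day of
each leaf, with unpenalized year-line and genotype effects and L1-penalized
climate coefficients gamma_{y,l,c,w}.  The penalty is tuned by grouped
cross-validation keeping each genotype-year combination together.  Whether
climate explains anything beyond chance is assessed by re-running the whole
cross-validated pipeline on "false" climates (daily records from other
years/periods): the proportion of false climates achieving a smaller
weighted MSE than the true one acts as a p-value.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Lasso, lasso_path

from .data_model import CensoringIntervals, GenotypeKey, LeafRangeWindow
from .likelihood import PhyllochronParams, aggregate_cumulated
from .thermal_time import att_at_day, calendar_from_att

__all__ = [
    "DEFAULT_W0",
    "ClimateSeries",
    "ClimateCandidate",
    "ClimateFeatureTable",
    "ClimateLassoFit",
    "compute_weights",
    "build_features",
    "fit_climate_lasso",
    "cv_predict_mse",
    "false_climate_test",
    "make_pool",
]

DEFAULT_W0 = (1, 2, 3, 5, 10, 20)


@dataclass
class ClimateSeries:
    """Daily values of one climate variable for one experimental year,
    indexed by integer day offset since sowing (negative offsets = pre-
    sowing lookback)."""

    year: str
    variable: str
    values: pd.Series

    def __post_init__(self):
        self.values = self.values.sort_index()
        idx = self.values.index.to_numpy()
        if len(idx) and np.any(np.diff(idx) != 1):
            raise ValueError(
                f"climate {self.variable}/{self.year}: days not contiguous")

    def at(self, days: np.ndarray) -> np.ndarray:
        vals = self.values.to_numpy(dtype=float)
        first = int(self.values.index[0]) if len(vals) else 0
        idx = np.asarray(days, dtype=int) - first
        bad = (idx < 0) | (idx >= len(vals))
        if bad.any():
            raise ValueError(
                f"climate variable {self.variable!r} year {self.year} does "
                f"not cover day offset(s) {np.asarray(days)[bad]}")
        return vals[idx]


@dataclass(frozen=True)
class ClimateCandidate:
    """A pool entry for the false-climate test: a full set of daily series
    (variable -> day-offset-indexed values) under one label."""

    label: object
    series: Mapping[str, pd.Series] = field(hash=False)


# ---------------------------------------------------------------------------
# weights


def compute_weights(data: Sequence[CensoringIntervals],
                    window: LeafRangeWindow) -> pd.DataFrame:
    """omega_{y,lsg,f}: number of plants of each genotype-year with at least
    one observation before and one after the appearance of leaf f."""
    rows: dict = {}
    for ci in data:
        k = ci.key
        for f in window.instant_ranks():
            cell = (k.year, k.line, k.selection, k.genotype, int(f))
            rows.setdefault(cell, 0)
            if ci.observed(f):
                rows[cell] += 1
    return pd.DataFrame(
        [{"year": y, "line": l, "selection": s, "genotype": g,
          "leaf_rank": f, "weight": w}
         for (y, l, s, g, f), w in sorted(rows.items())])


# ---------------------------------------------------------------------------
# feature construction


@dataclass
class ClimateFeatureTable:
    """(year, genotype, leaf) rows with the response in calendar days, the
    windowed cumulative-climate features, the unpenalized design labels and
    the weights; carries what is needed to convert predictions back to
    degree-days."""

    df: pd.DataFrame
    feature_cols: list
    W0: tuple
    att_by_year: Mapping

    @property
    def groups(self) -> pd.Series:
        return self.df["year"].str.cat(self.df["genotype"], sep="|")


def build_features(
    params_by_group: Mapping[GenotypeKey, PhyllochronParams],
    att_by_year: Mapping[str, pd.Series],
    climate: Sequence[ClimateSeries],
    W0: Sequence[int] = DEFAULT_W0,
    weights: pd.DataFrame | None = None,
) -> ClimateFeatureTable:
    """Assemble the regression table.

    For each genotype-year and instant rank f, the response is the mean
    interval in calendar days mu_cal = cal(H mean at f) - cal(H mean at
    f-1); the feature for (variable c, window w) is the sum of c over the w
    days preceding the anchor day = floor(calendar mean appearance day of
    leaf f).
    """
    W0 = tuple(int(w) for w in W0)
    clim: dict[tuple, ClimateSeries] = {}
    for cs in climate:
        clim[(cs.year, cs.variable)] = cs
    variables = sorted({v for (_, v) in clim})
    wmap = None
    if weights is not None:
        wmap = {(r.year, r.genotype, int(r.leaf_rank)): float(r.weight)
                for r in weights.itertuples()}
    rows = []
    for key in sorted(params_by_group, key=lambda k: k.genotype_key):
        p = params_by_group[key]
        att = att_by_year[key.year]
        w = p.window
        for i, f in enumerate(w.instant_ranks()):
            m_prev, _ = aggregate_cumulated(p, int(f) - 1)
            m_f, _ = aggregate_cumulated(p, int(f))
            cal_prev = calendar_from_att(att, m_prev)
            cal_f = calendar_from_att(att, m_f)
            anchor = math.floor(cal_f)
            row = {
                "year": key.year, "line": key.line, "selection": key.selection,
                "genotype": key.genotype, "leaf_rank": int(f),
                "mu_cal": cal_f - cal_prev, "mu_dd": float(p.mu[i]),
                "cal_prev": cal_prev,
                "weight": 1.0 if wmap is None else
                          wmap.get((key.year, key.genotype, int(f)), 0.0),
            }
            for c in variables:
                cs = clim.get((key.year, c))
                if cs is None:
                    raise ValueError(f"no climate series for variable {c!r} "
                                     f"year {key.year}")
                days = anchor - np.arange(1, max(W0) + 1)
                vals = cs.at(days)
                csum = np.cumsum(vals)
                for wdw in W0:
                    row[f"{c}_w{wdw}"] = float(csum[wdw - 1])
            rows.append(row)
    feature_cols = [f"{c}_w{w}" for c in variables for w in W0]
    return ClimateFeatureTable(df=pd.DataFrame(rows), feature_cols=feature_cols,
                               W0=W0, att_by_year=att_by_year)


# ---------------------------------------------------------------------------
# lasso with unpenalized year-line / genotype blocks


def _unpenalized_design(df: pd.DataFrame):
    """Intercept + reference-coded year-line and genotype indicator blocks
    (full-rank unpenalized design).  Returns (Z, year-line column indices,
    year-line levels beyond the reference)."""
    yl = df["year"].str.cat(df["line"], sep="|")
    g = df["genotype"]
    cols = [np.ones(len(df))]
    yl_cols: list[int] = []
    yl_levels: list[str] = []
    for series, track in ((yl, True), (g, False)):
        levels = sorted(series.unique())
        for lev in levels[1:]:
            if track:
                yl_cols.append(len(cols))
                yl_levels.append(lev)
            cols.append((series == lev).to_numpy(dtype=float))
    return np.column_stack(cols), yl_cols, yl_levels


def _penalized_design(table: ClimateFeatureTable, gamma_per_year_line: bool):
    df = table.df
    X = df[table.feature_cols].to_numpy(dtype=float)
    names = list(table.feature_cols)
    if not gamma_per_year_line:
        return X, names
    yl = df["year"].str.cat(df["line"], sep="|")
    levels = sorted(yl.unique())
    if len(levels) == 1:
        return X, [f"{levels[0]}|{n}" for n in names]
    blocks, out = [], []
    for lev in levels:
        ind = (yl == lev).to_numpy(dtype=float)[:, None]
        blocks.append(X * ind)
        out.extend(f"{lev}|{n}" for n in names)
    return np.hstack(blocks), out


def _wls(Z: np.ndarray, y: np.ndarray, w: np.ndarray) -> np.ndarray:
    Zw = Z * w[:, None]
    beta, *_ = np.linalg.lstsq(Zw.T @ Z, Zw.T @ y, rcond=None)
    return beta


@dataclass
class ClimateLassoFit:
    lambda_: float
    gamma: pd.Series            # penalized coefficients, original scale
    unpenalized: np.ndarray     # coefficients of the alpha/beta block
    cv_error: pd.Series         # grouped-CV error per candidate lambda
    weighted: bool
    gamma_per_year_line: bool

    def support(self) -> pd.Series:
        """Non-zero climate coefficients.  Correlated climate variables make
        this selection non-robust; interpret with caution."""
        return self.gamma[self.gamma != 0.0]


def _prepare(table: ClimateFeatureTable, weighted: bool, gamma_per_year_line: bool):
    df = table.df
    y = df["mu_cal"].to_numpy(dtype=float)
    w = df["weight"].to_numpy(dtype=float) if weighted else np.ones(len(df))
    if w.sum() <= 0:
        raise ValueError("all weights are zero")
    Z, yl_cols, yl_levels = _unpenalized_design(df)
    X, names = _penalized_design(table, gamma_per_year_line)
    sd = np.sqrt(np.average((X - np.average(X, axis=0, weights=w)) ** 2,
                            axis=0, weights=w))
    sd[sd == 0] = 1.0
    return y, w, Z, X, names, sd, yl_cols, yl_levels


def _lasso_path_fit(Z, Xs, y, w, lam):
    """Partialled-out lasso at one penalty: residualize y and Xs on Z by
    WLS, run the L1 solver, then refit the unpenalized block."""
    bz = _wls(Z, y, w)
    ry = y - Z @ bz
    RX = Xs - Z @ _wls(Z, Xs, w)
    model = Lasso(alpha=lam, fit_intercept=False, max_iter=20000, tol=1e-6)
    model.fit(RX, ry, sample_weight=w / w.mean())
    gamma = model.coef_
    bz_final = _wls(Z, y - Xs @ gamma, w)
    return gamma, bz_final


def _gamma_path(Z, Xs, y, w, lams):
    """Penalized coefficients along a whole penalty path in one solver call.

    Weights enter by row-scaling with sqrt(w / mean w), which reproduces
    the weighted coordinate-descent objective exactly; y and Xs are first
    residualized on the unpenalized block by WLS."""
    ry = y - Z @ _wls(Z, y, w)
    RX = Xs - Z @ _wls(Z, Xs, w)
    s = np.sqrt(w / w.mean())
    order = np.argsort(lams)[::-1]
    _, coefs, _ = lasso_path(RX * s[:, None], ry * s,
                             alphas=lams[order], max_iter=20000, tol=1e-6)
    out = np.empty_like(coefs)
    out[:, order] = coefs
    return out


def _lambda_grid(RX, ry, w, n_lambda):
    lam_max = np.max(np.abs(RX.T @ (w * ry))) / w.sum()
    lam_max = max(lam_max, 1e-10)
    return np.geomspace(lam_max * 1.001, lam_max * 1e-3, n_lambda)


def fit_climate_lasso(
    table: ClimateFeatureTable,
    weighted: bool = True,
    gamma_per_year_line: bool = True,
    n_lambda: int = 25,
    lambda_: float | None = None,
) -> ClimateLassoFit:
    """L1-penalized fit of the climate model.

    alpha (year-line) and beta (genotype) are unpenalized; gamma
    coefficients are penalized on internally standardized features and
    reported on the original scale.  The penalty minimizing the grouped
    (weighted, if ``weighted``) cross-validation squared error is selected,
    with one fold per genotype-year combination.
    """
    y, w, Z, X, names, sd, _, _ = _prepare(table, weighted, gamma_per_year_line)
    groups = table.groups.to_numpy()
    uniq = np.unique(groups)
    if len(uniq) < 3:
        raise ValueError("grouped cross-validation needs >= 3 genotype-year "
                         "combinations")
    Xs = X / sd
    bz = _wls(Z, y, w)
    RX = Xs - Z @ _wls(Z, Xs, w)
    lams = np.array([lambda_]) if lambda_ is not None else _lambda_grid(
        RX, y - Z @ bz, w, n_lambda)
    cv = np.zeros(len(lams))
    for g in uniq:
        hold = groups == g
        tr = ~hold
        G = _gamma_path(Z[tr], Xs[tr], y[tr], w[tr], lams)  # (p, n_lams)
        # refit the unpenalized block per lambda (matrix RHS WLS)
        resid = y[tr][:, None] - Xs[tr] @ G
        Zw = Z[tr] * w[tr][:, None]
        B = np.linalg.lstsq(Zw.T @ Z[tr], Zw.T @ resid, rcond=None)[0]
        pred = Z[hold] @ B + Xs[hold] @ G
        cv += np.sum(w[hold][:, None] * (y[hold][:, None] - pred) ** 2, axis=0)
    best = int(np.argmin(cv))
    lam = float(lams[best])
    gam, bzf = _lasso_path_fit(Z, Xs, y, w, lam)
    return ClimateLassoFit(
        lambda_=lam, gamma=pd.Series(gam / sd, index=names),
        unpenalized=bzf, cv_error=pd.Series(cv, index=lams),
        weighted=weighted, gamma_per_year_line=gamma_per_year_line)


def cv_predict_mse(
    table: ClimateFeatureTable,
    weighted: bool = True,
    gamma_per_year_line: bool = True,
    lambda_: float | None = None,
    n_lambda: int = 25,
) -> tuple[pd.DataFrame, float]:
    """Leave-one-genotype-year-out predictions and the weighted MSE.

    Each genotype-year is predicted from a model fit on all other
    combinations (at the penalty selected on the full table unless
    ``lambda_`` is given).  Predictions are converted from calendar days to
    degree-days through the held-out year's thermal-time series before the
    squared error is computed: MSE = sum (mu_pred_dd - mu_hat_dd)^2 omega,
    with omega = 1 when ``weighted`` is false.
    """
    if lambda_ is None:
        lambda_ = fit_climate_lasso(table, weighted=weighted,
                                    gamma_per_year_line=gamma_per_year_line,
                                    n_lambda=n_lambda).lambda_
    y, w, Z, X, names, sd, yl_cols, yl_levels = _prepare(
        table, weighted, gamma_per_year_line)
    Xs = X / sd
    df = table.df
    groups = table.groups.to_numpy()
    uniq = np.unique(groups)
    pred_cal = np.full(len(df), np.nan)
    yl = df["year"].str.cat(df["line"], sep="|").to_numpy()
    for g in uniq:
        hold = groups == g
        tr = ~hold
        gam, bzf = _lasso_path_fit(Z[tr], Xs[tr], y[tr], w[tr], lambda_)
        pred = Z[hold] @ bzf + Xs[hold] @ gam
        # a year-line absent from training cannot identify its alpha: its
        # indicator column is all-zero there (lstsq gives it coefficient 0);
        # replace by the mean alpha deviation over training year-lines
        missing_yl = set(np.unique(yl[hold])) - set(np.unique(yl[tr]))
        if missing_yl:
            train_devs = [0.0]  # reference level
            for col, lev in zip(yl_cols, yl_levels):
                if lev in set(yl[tr]):
                    train_devs.append(float(bzf[col]))
            adjust = float(np.mean(train_devs))
            rows_missing = hold & np.isin(yl, list(missing_yl))
            pred = pred + adjust * rows_missing[hold].astype(float)
        pred_cal[hold] = pred
    # convert calendar-day predictions to degree-days in the held-out year
    pred_dd = np.empty(len(df))
    for i, row in enumerate(df.itertuples()):
        att = table.att_by_year[row.year]
        t0 = row.cal_prev
        t1 = t0 + max(pred_cal[i], 0.0)
        n_days = len(att) - 1
        t1 = min(t1, n_days)
        pred_dd[i] = float(att_at_day(att, t1) - att_at_day(att, t0))
    out = df[["year", "line", "selection", "genotype", "leaf_rank",
              "mu_dd", "weight"]].copy()
    out["mu_cal"] = y
    out["pred_cal"] = pred_cal
    out["pred_dd"] = pred_dd
    omega = w if weighted else np.ones(len(df))
    mse = float(np.sum((pred_dd - df["mu_dd"].to_numpy()) ** 2 * omega))
    return out, mse


# ---------------------------------------------------------------------------
# false-climate test


def make_pool(series_by_label: Mapping[object, Mapping[str, pd.Series]]):
    """Build ClimateCandidate pool entries from {label: {variable: series}}."""
    return [ClimateCandidate(label=lab, series=dict(s))
            for lab, s in sorted(series_by_label.items(), key=lambda kv: str(kv[0]))]


@dataclass
class FalseClimateResult:
    p_value: float
    mse_true: float
    mse_false: np.ndarray
    assignments: list


def false_climate_test(
    params_by_group: Mapping[GenotypeKey, PhyllochronParams],
    att_by_year: Mapping[str, pd.Series],
    true_climate: Sequence[ClimateSeries],
    pool: Sequence[ClimateCandidate],
    W0: Sequence[int] = DEFAULT_W0,
    weights: pd.DataFrame | None = None,
    weighted: bool = True,
    gamma_per_year_line: bool = True,
    n_false: int | None = None,
    rng: np.random.Generator | None = None,
    n_lambda: int = 25,
) -> FalseClimateResult:
    """Permutation-like significance test of the climate model.

    Every false climate assigns one pool candidate to each experimental
    year; the cross-validated weighted MSE is recomputed with the features
    rebuilt from that assignment.  p = proportion of false climates whose
    MSE is strictly smaller than the true-climate MSE (ties count as not
    smaller); a small p indicates the true climate explains phyllochron
    variation beyond chance.
    """
    rng = rng if rng is not None else np.random.default_rng()
    years = sorted({k.year for k in params_by_group})
    labels = [c.label for c in pool]
    by_label = {c.label: c for c in pool}
    n_total = len(pool) ** len(years)
    if n_false is None:
        n_false = min(n_total - 1, 200)
    all_small = n_total - 1 <= n_false
    assignments: list[tuple] = []
    if all_small:
        assignments = list(itertools.product(labels, repeat=len(years)))
    else:
        seen = set()
        guard = 0
        while len(assignments) < n_false:
            t = tuple(labels[i] for i in rng.integers(0, len(labels), len(years)))
            guard += 1
            if guard > 1000 * n_false:
                break
            if t in seen:
                continue
            seen.add(t)
            assignments.append(t)
    if len(assignments) < 20:
        raise ValueError(
            f"false-climate pool yields only {len(assignments)} assignments "
            "(< 20): enlarge the pool")

    table_true = build_features(params_by_group, att_by_year, true_climate,
                                W0=W0, weights=weights)
    _, mse_true = cv_predict_mse(table_true, weighted=weighted,
                                 gamma_per_year_line=gamma_per_year_line,
                                 n_lambda=n_lambda)
    mses = np.empty(len(assignments))
    for a, assign in enumerate(assignments):
        false_series = []
        for yr, lab in zip(years, assign):
            cand = by_label[lab]
            for var, s in cand.series.items():
                false_series.append(ClimateSeries(year=yr, variable=var,
                                                  values=s))
        tab = build_features(params_by_group, att_by_year, false_series,
                             W0=W0, weights=weights)
        _, mses[a] = cv_predict_mse(tab, weighted=weighted,
                                    gamma_per_year_line=gamma_per_year_line,
                                    n_lambda=n_lambda)
    p = float(np.mean(mses < mse_true))
    return FalseClimateResult(p_value=p, mse_true=mse_true, mse_false=mses,
                              assignments=assignments)
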