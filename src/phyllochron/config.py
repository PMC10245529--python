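"""Run configuration and pipeline orchestration.

A YAML config drives the whole analysis (clean -> censor -> window -> fit ->
compare -> select -> climate -> validate); every stochastic stage derives
its generator from the single config seed, so re-running a config
reproduces all numeric outputs bit for bit.  Analyses are per-year: each
stage partitions the data by year before fitting, and permutations never
cross years.  Every output file carries the config hash and the package
version.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data_model import (clean_observations, extract_intervals,
                         load_observations, select_leaf_range)
from .group_tests import SharingSpec, permutation_test
from .mcem import McemSettings, fit_mcem
from .likelihood import validation_tables
from .submodels import FAMILIES, fit_submodel, select_submodel
from .thermal_time import ThermalTimeResponse, att_series

_KNOWN_KEYS = {
    "seed", "observations", "min_plants", "n_top_trim", "mcem",
    "comparisons", "max_perms", "submodel_families", "climate",
    "validation_breaks",
}
_KNOWN_CLIMATE = {"temperatures", "climate_csv", "sowing", "base_temp", "w0",
                  "weighted", "false_pool"}
_MCEM_FIELDS = set(McemSettings.__dataclass_fields__)


class ConfigError(ValueError):
    pass


@dataclass
class RunConfig:
    seed: int
    observations: str
    min_plants: int = 10
    n_top_trim: int = 2
    mcem: McemSettings = field(default_factory=McemSettings)
    comparisons: list = field(default_factory=list)
    max_perms: int = 200
    submodel_families: list = field(default_factory=list)
    climate: dict | None = None
    validation_breaks: list | None = None
    raw: dict = field(default_factory=dict)

    @property
    def config_hash(self) -> str:
        canon = json.dumps(self.raw, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_config(path) -> RunConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    return parse_config(raw, base_dir=Path(path).parent)


def parse_config(raw: dict, base_dir: Path | None = None) -> RunConfig:
    if not isinstance(raw, dict):
        raise ConfigError("config must be a mapping")
    offending = sorted(set(raw) - _KNOWN_KEYS)
    missing = sorted(k for k in ("seed", "observations") if k not in raw)
    problems = []
    if offending:
        problems.append(f"unknown keys: {offending}")
    if missing:
        problems.append(f"missing keys: {missing}")
    if "mcem" in raw:
        bad = sorted(set(raw["mcem"]) - _MCEM_FIELDS)
        if bad:
            problems.append(f"unknown mcem keys: {bad}")
    climate = raw.get("climate")
    if climate is not None:
        badc = sorted(set(climate) - _KNOWN_CLIMATE)
        if badc:
            problems.append(f"unknown climate keys: {badc}")
        for req in ("temperatures", "climate_csv", "sowing"):
            if req not in climate:
                problems.append(f"climate stage enabled but missing key: {req}")
    for c in raw.get("comparisons", []):
        if not (isinstance(c, (list, tuple)) and len(c) == 2):
            problems.append(f"comparison {c!r} must be a [full, reduced] pair")
    for fam in raw.get("submodel_families", []):
        if fam not in FAMILIES:
            problems.append(f"unknown submodel family {fam!r}")
    if problems:
        raise ConfigError("invalid config: " + "; ".join(problems))

    def respath(p):
        p = Path(p)
        return str(p if p.is_absolute() or base_dir is None else base_dir / p)

    climate_cfg = None
    if climate is not None:
        climate_cfg = dict(climate)
        climate_cfg["temperatures"] = respath(climate["temperatures"])
        climate_cfg["climate_csv"] = respath(climate["climate_csv"])
    return RunConfig(
        seed=int(raw["seed"]),
        observations=respath(raw["observations"]),
        min_plants=int(raw.get("min_plants", 10)),
        n_top_trim=int(raw.get("n_top_trim", 2)),
        mcem=McemSettings(**raw.get("mcem", {})),
        comparisons=[tuple(c) for c in raw.get("comparisons", [])],
        max_perms=int(raw.get("max_perms", 200)),
        submodel_families=list(raw.get("submodel_families", [])),
        climate=climate_cfg,
        validation_breaks=raw.get("validation_breaks"),
        raw=raw,
    )


def _meta(cfg: RunConfig) -> dict:
    return {"config_hash": cfg.config_hash, "version": __version__}


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} version={__version__}\n")
        df.to_csv(fh, index=False)


def _write_json(obj, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        json.dump({"meta": _meta(cfg), "result": obj}, fh, indent=2, default=str)


def _stage_rng(cfg: RunConfig, *key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(cfg.seed, spawn_key=key))


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Execute the configured stages; returns the run directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log = logging.getLogger("phyllochron.pipeline")
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    t0 = time.time()
    try:
        _run(config, out, log)
    finally:
        log.info("total runtime %.1f s", time.time() - t0)
        log.removeHandler(handler)
        handler.close()
    return out


def _check_inputs(cfg: RunConfig) -> None:
    missing = []
    if not Path(cfg.observations).exists():
        missing.append(f"observations: {cfg.observations}")
    if cfg.climate is not None:
        for k in ("temperatures", "climate_csv"):
            if not Path(cfg.climate[k]).exists():
                missing.append(f"climate.{k}: {cfg.climate[k]}")
    if missing:
        raise ConfigError("input file(s) not found: " + "; ".join(missing))


def _run(cfg: RunConfig, out: Path, log) -> None:
    _check_inputs(cfg)
    raw = load_observations(cfg.observations)
    kept, discarded = clean_observations(raw, n_top_trim=cfg.n_top_trim)
    log.info("cleaning: kept %d plants, discarded %d", len(kept), len(discarded))
    intervals = [extract_intervals(s) for s in kept]

    years = sorted({ci.key.year for ci in intervals})
    params_rows = []
    tests: dict = {}
    selections: dict = {}
    fitted_params: dict = {}
    for yi, year in enumerate(years):
        ydata = [ci for ci in intervals if ci.key.year == year]
        groups: dict = {}
        for ci in ydata:
            groups.setdefault(ci.key, []).append(ci)
        windows, common = select_leaf_range(groups, min_plants=cfg.min_plants)
        log.info("year %s: %d genotypes, common window [%d, %d]",
                 year, len(groups), common.f_min, common.f_max)

        for gi, (key, plants) in enumerate(sorted(groups.items(),
                                                  key=lambda kv: kv[0].genotype_key)):
            rng = _stage_rng(cfg, 1, yi, gi)
            params, trace = fit_mcem(plants, windows[key], cfg.mcem, rng=rng,
                                     key=key)
            fitted_params[key] = params
            w = params.window
            params_rows.append(dict(year=key.year, line=key.line,
                                    selection=key.selection, genotype=key.genotype,
                                    f_min=w.f_min, f_max=w.f_max,
                                    param_name="mu_C", leaf_rank=w.f_min,
                                    estimate=params.mu_C))
            params_rows.append(dict(year=key.year, line=key.line,
                                    selection=key.selection, genotype=key.genotype,
                                    f_min=w.f_min, f_max=w.f_max,
                                    param_name="sigma_C", leaf_rank=w.f_min,
                                    estimate=params.sigma_C))
            for i, f in enumerate(w.instant_ranks()):
                for name, v in (("mu", params.mu[i]), ("sigma", params.sigma[i])):
                    params_rows.append(dict(
                        year=key.year, line=key.line, selection=key.selection,
                        genotype=key.genotype, f_min=w.f_min, f_max=w.f_max,
                        param_name=name, leaf_rank=int(f), estimate=float(v)))

        for pi, (full_name, red_name) in enumerate(cfg.comparisons):
            rng = _stage_rng(cfg, 2, yi, pi)
            try:
                res = permutation_test(
                    ydata, SharingSpec.parse(full_name),
                    SharingSpec.parse(red_name), common,
                    max_perms=cfg.max_perms, settings=cfg.mcem, rng=rng)
                tests[f"{year}:{full_name}/{red_name}"] = {
                    "p_value": res.p_value, "observed_lrt": res.observed_lrt,
                    "n_permutations": res.n_permutations,
                    "exhaustive": res.exhaustive, "df": res.df,
                    "chi2_p": res.chi2_p,
                }
            except ValueError as exc:
                tests[f"{year}:{full_name}/{red_name}"] = {"error": str(exc)}
                log.warning("comparison %s/%s year %s: %s", full_name,
                            red_name, year, exc)

        if cfg.submodel_families:
            for gi, (key, plants) in enumerate(sorted(
                    groups.items(), key=lambda kv: kv[0].genotype_key)):
                rng = _stage_rng(cfg, 3, yi, gi)
                fits = {}
                for fam in cfg.submodel_families:
                    try:
                        fits[fam] = fit_submodel(plants, windows[key], fam,
                                                 cfg.mcem, rng=rng, key=key)
                    except ValueError as exc:
                        log.warning("submodel %s for %s: %s", fam, key, exc)
                if "constant" in fits:
                    sel = select_submodel(fits)
                    selections["|".join(key.genotype_key)] = {
                        "winner": sel.selected.spec.family,
                        "best_parametric": (sel.best_parametric.spec.family
                                            if sel.best_parametric else None),
                        "table": sel.table,
                        "kappa": sel.selected.spec.kappa,
                    }

        if cfg.validation_breaks:
            vt, qt = validation_tables(
                {k: fitted_params[k] for k in groups},
                [s for s in kept if s.key.year == year],
                cfg.validation_breaks)
            _write_csv(vt, out / f"validation_{year}.csv", cfg)
            _write_csv(qt, out / f"validation_quantiles_{year}.csv", cfg)

    _write_csv(pd.DataFrame(params_rows), out / "params.csv", cfg)
    _write_json(tests, out / "tests.json", cfg)
    if selections:
        _write_json(selections, out / "selection.json", cfg)
    _write_json({"discarded_plants": discarded}, out / "cleaning.json", cfg)

    if cfg.climate is not None:
        _run_climate(cfg, out, fitted_params, intervals, log)


def _run_climate(cfg: RunConfig, out: Path, fitted_params, intervals, log) -> None:
    from .climate import (ClimateSeries, build_features, compute_weights,
                          cv_predict_mse, fit_climate_lasso)

    ccfg = cfg.climate
    temps = pd.read_csv(ccfg["temperatures"], comment="#", parse_dates=["date"])
    clim = pd.read_csv(ccfg["climate_csv"], comment="#", parse_dates=["date"])
    response = ThermalTimeResponse(base_temp=float(ccfg.get("base_temp", 6.0)))
    sowing = {str(k): pd.Timestamp(v) for k, v in ccfg["sowing"].items()}
    att_by_year = {}
    series = []
    for year, sow in sowing.items():
        tsub = temps.set_index("date")["value"]
        att_by_year[year] = att_series(tsub, sow, response)
        for var, sub in clim.groupby("variable"):
            sub = sub.set_index("date")["value"].sort_index()
            offs = (sub.index - sow).days
            series.append(ClimateSeries(
                year=year, variable=str(var),
                values=pd.Series(sub.to_numpy(), index=offs)))
    window = next(iter(fitted_params.values())).window
    weights = compute_weights(intervals, window)
    table = build_features(fitted_params, att_by_year, series,
                           W0=tuple(ccfg.get("w0", (1, 2, 3, 5, 10, 20))),
                           weights=weights)
    weighted = bool(ccfg.get("weighted", True))
    fit = fit_climate_lasso(table, weighted=weighted)
    preds, mse = cv_predict_mse(table, weighted=weighted, lambda_=fit.lambda_)
    _write_csv(preds, out / "climate_predictions.csv", cfg)
    _write_json({"lambda": fit.lambda_, "mse": mse, "weighted": weighted,
                 "n_nonzero_gamma": int((fit.gamma != 0).sum())},
                out / "climate_result.json", cfg)
    log.info("climate stage: lambda=%.4g weighted MSE=%.4g", fit.lambda_, mse)
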