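"""End-to-end benchmark orchestration: simulate replicates, fit the
requested predictors on the training cohort only, predict the held-out
cohort, and aggregate mean predictive correlation, its SD, and power
(share of replicates significant at P < 0.05) per scenario x method.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from itertools import product
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import baselines, stmgp
from .assoc import gwas_scan, clump
from .evaluation import partial_correlation, pcc, power_summary
from .synthetic_data import (SimulationConfig, simulate_replicate,
                             standardize_dosages, substream)

KNOWN_METHODS = ("stmgp", "prs", "gblup", "sblup", "ridge")


@dataclass
class BenchmarkConfig:
    """One or more simulation scenarios plus the methods to benchmark."""

    scenarios: list
    methods: tuple = ("stmgp",)
    covariate_mode: str = "none"   # none | partial | regress_out
    out_dir: str | None = None
    shuffle_test_phenotype: bool = False

    def __post_init__(self) -> None:
        if not self.scenarios or not self.methods:
            raise ValueError("need at least one scenario and one method")
        for mth in self.methods:
            if mth not in KNOWN_METHODS:
                raise ValueError(f"unknown method {mth!r}")
        if self.covariate_mode not in ("none", "partial", "regress_out"):
            raise ValueError(f"unknown covariate mode {self.covariate_mode!r}")

    @classmethod
    def grid(cls, base: SimulationConfig, k_values=None, effect_dists=None,
             neg_shapes=None, h2_values=None, **kwargs) -> "BenchmarkConfig":
        """Expand a scenario grid (k x effect distribution x shape x h2)
        around a base configuration."""
        ks = k_values or [base.k]
        dists = effect_dists or [base.effect_dist]
        h2s = h2_values or [base.h2]
        scen = []
        for k, dist, h2 in product(ks, dists, h2s):
            shapes = (neg_shapes or [base.neg_shape]) if dist == "neg" else [base.neg_shape]
            for shape in shapes:
                scen.append(SimulationConfig(
                    n_train=base.n_train, n_test=base.n_test, m=base.m,
                    maf_low=base.maf_low, maf_high=base.maf_high, k=k,
                    effect_dist=dist, neg_shape=shape, h2=h2,
                    r2_max=base.r2_max, n_reps=base.n_reps, seed=base.seed))
        return cls(scenarios=scen, **kwargs)

    @classmethod
    def from_yaml(cls, path) -> "BenchmarkConfig":
        raw = yaml.safe_load(Path(path).read_text())
        base = SimulationConfig(**raw.get("simulation", {}))
        return cls.grid(
            base,
            k_values=raw.get("k_values"),
            effect_dists=raw.get("effect_dists"),
            neg_shapes=raw.get("neg_shapes"),
            h2_values=raw.get("h2_values"),
            methods=tuple(raw.get("methods", ("stmgp",))),
            covariate_mode=raw.get("covariate_mode", "none"),
            out_dir=raw.get("out_dir"),
        )

    def memory_estimate_bytes(self) -> int:
        """Rough peak working-set estimate for the largest scenario."""
        worst = max(self.scenarios, key=lambda s: s.n_total * s.m)
        return worst.n_total * worst.m * 5  # int8 dosages + float32 W

    @property
    def desk_feasible(self) -> bool:
        return self.memory_estimate_bytes() < 6 * 2**30


def covariate_mode_apply(mode: str, y, C, pred):
    """Evaluate a prediction under one of the covariate-handling modes:
    plain correlation, partial correlation, or correlation against the
    covariate-regressed-out phenotype residuals."""
    y = np.asarray(y, dtype=np.float64)
    pred = np.asarray(pred, dtype=np.float64)
    empty_C = C is None or np.size(C) == 0
    if mode == "none" or (empty_C and mode in ("partial", "regress_out")):
        return pcc(pred, y)
    if mode == "partial":
        return partial_correlation(pred, y, C)
    if mode == "regress_out":
        Cm = np.asarray(C, dtype=np.float64)
        if Cm.ndim == 1:
            Cm = Cm[:, None]
        X = np.column_stack([np.ones(len(y)), Cm])
        resid = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        return pcc(pred, resid)
    raise ValueError(f"unknown covariate mode {mode!r}")


# ---------------------------------------------------------------------------
# per-method fit/predict wrappers (training objects only)

def _fit_predict(method: str, dos_train, dos_test, y_train, ws: dict,
                 cache: dict):
    n_tr, m = dos_train.shape
    if method == "stmgp":
        model = stmgp.stmgp_fit(dos_train, y_train, _W=ws.get("W"))
        return (stmgp.stmgp_predict(model, dos_train),
                stmgp.stmgp_predict(model, dos_test))
    if method == "prs":
        gw = _gwas(dos_train, y_train, ws, cache)
        model = baselines.prs_fit(gw, dos_train, y_train)
        return (baselines.prs_predict(model, dos_train),
                baselines.prs_predict(model, dos_test))
    if method in ("gblup", "sblup"):
        vc, Wtr, p_tr = _greml(dos_train, y_train, ws, cache)
        if method == "gblup":
            K_tt = cache["K_tt"]
            Wte = standardize_dosages(dos_test, p_tr, dtype=np.float32)
            K_xt = (Wte @ Wtr.T).astype(np.float64) / m
            pred_tr = baselines.gblup_predict(vc, K_tt, K_tt, y_train)
            pred_te = baselines.gblup_predict(vc, K_tt, K_xt, y_train)
            return pred_tr, pred_te
        gw = _gwas(dos_train, y_train, ws, cache)
        h2 = max(vc.h2, 0.01)
        beta = _sblup_blockwise(gw.beta, Wtr, n_tr, m, h2)
        Wte = standardize_dosages(dos_test, p_tr, dtype=np.float32)
        return ((Wtr @ beta.astype(np.float32)).astype(np.float64),
                (Wte @ beta.astype(np.float32)).astype(np.float64))
    if method == "ridge":
        gw = _gwas(dos_train, y_train, ws, cache)
        kept = clump(gw, dos_train)
        model = baselines.ridge_clumped(dos_train, y_train, variants=kept)
        return (baselines.ridge_predict(model, dos_train),
                baselines.ridge_predict(model, dos_test))
    raise ValueError(f"unknown method {method!r}")


def _train_freq(dos_train):
    miss = dos_train == -1
    n = dos_train.shape[0]
    p = np.where(miss, 0, dos_train).sum(axis=0) / np.maximum(
        1, 2 * (n - miss.sum(axis=0)))
    return np.clip(p, 1e-6, 1 - 1e-6)


def _gwas(dos_train, y_train, ws, cache):
    if "gwas" not in cache:
        p = _train_freq(dos_train)
        W = standardize_dosages(dos_train, p, out=ws.get("W"),
                                dtype=np.float32)
        cache["gwas"] = gwas_scan(W, y_train)
        cache["p_train"] = p
    return cache["gwas"]


def _greml(dos_train, y_train, ws, cache):
    if "greml" not in cache:
        p = _train_freq(dos_train)
        Wtr = standardize_dosages(dos_train, p, dtype=np.float32)
        K = baselines.make_grm(Wtr)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            vc = baselines.greml(y_train, K)
        cache.update(greml=vc, W_train=Wtr, p_train2=p, K_tt=K)
    return cache["greml"], cache["W_train"], cache["p_train2"]


def _sblup_blockwise(beta_marginal, Wtr, n, m, h2, block: int = 2000):
    """SBLUP solve in block-diagonal chunks of the LD matrix (exact when
    between-block LD is negligible, as for the generator's SNPs)."""
    out = np.empty_like(beta_marginal, dtype=np.float64)
    for lo in range(0, m, block):
        hi = min(lo + block, m)
        Wb = Wtr[:, lo:hi].astype(np.float64)
        R = (Wb.T @ Wb) / n
        out[lo:hi] = baselines.sblup_coefficients(
            beta_marginal[lo:hi], R, n, m, h2)
    return out


# ---------------------------------------------------------------------------
# benchmark loop

def run_scenario(cfg: SimulationConfig, methods=("stmgp",),
                 covariate_mode: str = "none", out_dir=None,
                 scenario_id: str | None = None,
                 shuffle_test_phenotype: bool = False) -> pd.DataFrame:
    """Run all replicates of one scenario; returns one row per
    method x replicate with train/test correlations and P values.

    When ``out_dir`` is given each completed replicate is written as a JSON
    line file and the run is resumable.
    """
    if scenario_id is None:
        scenario_id = (f"k{cfg.k}_{cfg.effect_dist}"
                       + (f"{cfg.neg_shape:g}" if cfg.effect_dist == "neg" else "")
                       + f"_h{cfg.h2:g}")
    out_dir = Path(out_dir) if out_dir else None
    if out_dir:
        out_dir.mkdir(parents=True, exist_ok=True)
    n_tot = cfg.n_total
    ws = {
        "dos": np.empty((n_tot, cfg.m), dtype=np.int8),
        "W": np.empty((cfg.n_train, cfg.m), dtype=np.float32),
    }
    rows = []
    for rep in range(cfg.n_reps):
        rep_file = (out_dir / f"{scenario_id}_rep{rep}.json") if out_dir else None
        if rep_file is not None and rep_file.exists():
            rows.extend(json.loads(rep_file.read_text()))
            continue
        rep_data = simulate_replicate(cfg, rep, genotype_out=ws["dos"])
        y = rep_data.phenotype.y
        dos_train = ws["dos"][:cfg.n_train]
        dos_test = ws["dos"][cfg.n_train:]
        y_train = y[:cfg.n_train]
        y_test = y[cfg.n_train:].copy()
        if shuffle_test_phenotype:
            perm = substream(cfg.seed, rep, 99).permutation(len(y_test))
            y_test = y_test[perm]
        cache: dict = {}
        rep_rows = []
        for method in methods:
            try:
                pred_tr, pred_te = _fit_predict(method, dos_train, dos_test,
                                                y_train, ws, cache)
                r_tr, p_tr = covariate_mode_apply(covariate_mode, y_train,
                                                  None, pred_tr)
                r_te, p_te = covariate_mode_apply(covariate_mode, y_test,
                                                  None, pred_te)
                rep_rows.append(dict(
                    scenario=scenario_id, rep=rep, method=method,
                    r_train=r_tr, p_train=p_tr, r_test=r_te, p_test=p_te,
                    gap=r_tr - r_te, realized_h2=rep_data.phenotype.realized_h2,
                    error=""))
            except Exception as exc:  # failures recorded, scenario continues
                rep_rows.append(dict(
                    scenario=scenario_id, rep=rep, method=method,
                    r_train=np.nan, p_train=np.nan, r_test=np.nan,
                    p_test=np.nan, gap=np.nan,
                    realized_h2=rep_data.phenotype.realized_h2,
                    error=f"{type(exc).__name__}: {exc}"))
        if rep_file is not None:
            rep_file.write_text(json.dumps(rep_rows))
        rows.extend(rep_rows)
    return pd.DataFrame(rows)


def summarize(replicates: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Aggregate replicate rows into the scenario x method summary table
    (mean PCC, SD, power, mean train PCC, mean overfitting gap)."""
    out = []
    for (scen, method), grp in replicates.groupby(["scenario", "method"],
                                                  sort=True):
        ok = grp[grp["error"] == ""] if "error" in grp else grp
        if len(ok) == 0:
            out.append(dict(scenario=scen, method=method, n_reps=0,
                            mean_pcc=np.nan, sd_pcc=np.nan, power=np.nan,
                            mean_train_pcc=np.nan, mean_gap=np.nan))
            continue
        s = power_summary(ok[["r_test", "p_test"]].to_numpy(), alpha=alpha)
        out.append(dict(
            scenario=scen, method=method, n_reps=s.n_reps,
            mean_pcc=s.mean_r, sd_pcc=s.sd_r, power=s.power,
            mean_train_pcc=float(ok["r_train"].mean()),
            mean_gap=float(ok["gap"].mean()),
        ))
    return pd.DataFrame(out)


def run_benchmark(config: BenchmarkConfig):
    """Run every scenario and aggregate.  Returns (summary, replicates)."""
    if not config.desk_feasible:
        warnings.warn("largest scenario exceeds the desk-scale memory budget")
    all_rows = []
    for cfg in config.scenarios:
        all_rows.append(run_scenario(
            cfg, methods=config.methods,
            covariate_mode=config.covariate_mode,
            out_dir=config.out_dir,
            shuffle_test_phenotype=config.shuffle_test_phenotype))
    replicates = pd.concat(all_rows, ignore_index=True)
    summary = summarize(replicates)
    if config.out_dir:
        out = Path(config.out_dir)
        summary.to_csv(out / "summary.tsv", sep="\t", index=False,
                       float_format="%.6g")
        replicates.to_csv(out / "replicates.tsv", sep="\t", index=False,
                          float_format="%.6g")
    return summary, replicates
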