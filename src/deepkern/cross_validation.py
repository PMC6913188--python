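"""CV2 sparse-testing cross-validation and the method benchmark harness.

CV2 mimics the prediction problem of incomplete field trials: within each
replicate, lines are partitioned into k folds independently in every
environment, so a line held out in one environment is typically observed in
the others (sparse testing).  Every method (GB, GK, AK, DL) is evaluated on
exactly the same masks, and accuracy is summarised as the mean squared error
of prediction (MSEP) over masked cells, per environment, averaged over the
k × replicates partitions.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from . import dl as dl_mod
from .io import MarkerMatrix, PhenotypeTable
from .kernels import ak_series, gaussian_kernel, linear_kernel, squared_distances
from .mixed_model import (
    build_incidence,
    expand_main_kernel,
    fit_multi_kernel,
    fit_single_kernel,
    gxe_kernel,
    predict_cells,
)


@dataclass
class CVPlan:
    """Reproducible cell-level fold assignments for CV2."""

    folds: int
    replicates: int
    seed: int
    assignments: pd.DataFrame  # columns: replicate, env, line, fold

    def fold_map(self, replicate: int) -> dict[tuple[str, str], int]:
        sub = self.assignments[self.assignments["replicate"] == replicate]
        return {(l, e): int(f) for l, e, f in zip(sub["line"], sub["env"], sub["fold"])}

    def test_cells(self, replicate: int, fold: int) -> list[tuple[str, str]]:
        sub = self.assignments
        sel = (sub["replicate"] == replicate) & (sub["fold"] == fold)
        return list(zip(sub.loc[sel, "line"], sub.loc[sel, "env"]))


def make_cv2_plan(
    lines: Sequence[str], envs: Sequence[str], k: int = 5, replicates: int = 10, seed: int = 0
) -> CVPlan:
    """Partition lines into k folds independently per environment and replicate."""
    lines, envs = list(lines), list(envs)
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > len(lines):
        raise ValueError(f"k={k} exceeds the number of lines ({len(lines)})")
    rng = np.random.default_rng(seed)
    rows = []
    for rep in range(replicates):
        for env in envs:
            perm = rng.permutation(len(lines))
            for f, chunk in enumerate(np.array_split(perm, k)):
                rows.extend((rep, env, lines[i], f) for i in chunk)
    return CVPlan(
        folds=k, replicates=replicates, seed=seed,
        assignments=pd.DataFrame(rows, columns=["replicate", "env", "line", "fold"]),
    )


def msep(y_obs, y_pred) -> float:
    """Mean squared error of prediction."""
    y_obs = np.asarray(y_obs, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_obs.size == 0:
        raise ValueError("msep of empty vectors")
    if y_obs.size != y_pred.size:
        raise ValueError("length mismatch")
    return float(np.mean((y_obs - y_pred) ** 2))


@dataclass
class CVResult:
    """Per-partition MSEP records with Tables-style aggregation."""

    records: pd.DataFrame  # method, model, env, replicate, fold, msep, n_test, param

    def summary(self) -> pd.DataFrame:
        """Mean and SD of MSEP across partitions per (method, model, environment)."""
        g = self.records.groupby(["method", "model", "env"])["msep"]
        out = g.agg(["mean", "std"]).reset_index()
        return out.rename(columns={"mean": "msep_mean", "std": "msep_sd"})


def _select_single(y, G_candidates, labels):
    """Fit a single-kernel model per candidate line-level kernel; return (best fit, label)."""
    best = None
    for K, lab in zip(G_candidates, labels):
        fit = fit_single_kernel(y, K, compute_se=False)
        if best is None or fit.logml > best[0].logml + 1e-9:
            best = (fit, lab, K)
    return best


def run_benchmark(
    pheno: PhenotypeTable,
    X: MarkerMatrix,
    methods: Sequence[str] = ("GB", "GK", "AK"),
    models: Sequence[str] = ("G", "E+G+GE"),
    plan: CVPlan | None = None,
    h_grid: Sequence[float] = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.5, 5.0),
    l_max: int = 8,
    dl_grid=None,
    dl_seed: int = 0,
    n_starts: int = 2,
) -> CVResult:
    """Run the full method × model benchmark on one CV plan.

    Line-level kernels are built once from all genotyped lines (marker data
    are never masked; only phenotypes are).  For every partition, bandwidth /
    layer selection is rerun on the training portion by maximum marginal
    likelihood; all methods see identical masks.
    """
    if plan is None:
        plan = make_cv2_plan(pheno.lines, pheno.envs, k=5, replicates=10, seed=0)
    pheno.check_lines_in(X)
    line_order = list(X.line_ids)
    env_order = list(pheno.envs)
    values = {(l, e): v for l, e, v in zip(
        pheno.records["line"], pheno.records["env"], pheno.records["value"])}

    # kernels from all genotyped lines, built once
    line_kernels: dict[str, list] = {}
    if "GB" in methods:
        line_kernels["GB"] = [(linear_kernel(X), None)]
    if "GK" in methods:
        D2 = squared_distances(X)
        line_kernels["GK"] = [(gaussian_kernel(D2, h, line_ids=line_order), h) for h in sorted(h_grid)]
    if "AK" in methods:
        line_kernels["AK"] = [(K, K.layer) for K in ak_series(X, l_max)]
    if "DL" in methods and dl_grid is None:
        dl_grid = [dl_mod.DLConfig(n_hidden_layers=1, units_per_layer=80, dropout=0.0, epochs=50)]

    rows = []
    for rep in range(plan.replicates):
        fmap = plan.fold_map(rep)
        for fold in range(plan.folds):
            test_cells = [c for c in values if fmap[c] == fold]
            train_cells = [c for c in values if fmap[c] != fold]
            test_by_env = {e: [c for c in test_cells if c[1] == e] for e in env_order}

            for model in models:
                preds: dict[str, dict[tuple, float]] = {m: {} for m in methods}
                params: dict[str, object] = {}
                if model == "G":
                    for env in env_order:
                        tr = [c for c in train_cells if c[1] == env]
                        te = test_by_env[env]
                        if not te or not tr:
                            continue
                        y_tr = np.array([values[c] for c in tr])
                        li = {l: i for i, l in enumerate(line_order)}
                        tr_idx = np.array([li[l] for l, _ in tr])
                        for method in methods:
                            if method == "DL":
                                Ftr = dl_mod.build_feature_matrix(X, tr, env_order, "g")
                                Fte = dl_mod.build_feature_matrix(X, te, env_order, "g")
                                tuned = dl_mod.tune_grid(Ftr, y_tr, dl_grid, seed=dl_seed + rep)
                                yhat = dl_mod.fit_predict(Ftr, y_tr, Fte, tuned.best, seed=dl_seed + rep)
                                params[(method, env)] = tuned.best
                            else:
                                cands = [(Kfull.K[np.ix_(tr_idx, tr_idx)], lab)
                                         for Kfull, lab in line_kernels[method]]
                                fit, lab, _ = _select_single(y_tr, [c[0] for c in cands], [c[1] for c in cands])
                                Kfull = next(Kf for Kf, l2 in line_kernels[method] if l2 == lab)
                                ps = predict_cells(fit, Kfull, line_order, [env], tr, y_tr, te)
                                yhat = ps.y_hat
                                params[(method, env)] = lab
                            for c, v in zip(te, yhat):
                                preds[method][c] = v
                else:  # E+G+GE
                    tr_df = pd.DataFrame(train_cells, columns=["line", "env"])
                    tr_df["value"] = [values[c] for c in train_cells]
                    pheno_tr = PhenotypeTable(records=tr_df, envs=env_order)
                    inc = build_incidence(pheno_tr, line_order, env_order)
                    y_tr = pheno_tr.y
                    for method in methods:
                        if method == "DL":
                            Ftr = dl_mod.build_feature_matrix(X, train_cells, env_order, "e-g-ge")
                            Fte = dl_mod.build_feature_matrix(X, test_cells, env_order, "e-g-ge")
                            tuned = dl_mod.tune_grid(Ftr, y_tr, dl_grid, seed=dl_seed + rep)
                            yhat = dl_mod.fit_predict(Ftr, y_tr, Fte, tuned.best, seed=dl_seed + rep)
                            for c, v in zip(test_cells, yhat):
                                preds[method][c] = v
                            params[method] = tuned.best
                            continue
                        best = None
                        for Kfull, lab in line_kernels[method]:
                            K1 = expand_main_kernel(Kfull, inc)
                            K2 = gxe_kernel(K1, inc)
                            fit = fit_multi_kernel(y_tr, inc.ZE, [K1, K2],
                                                   compute_se=False, n_starts=n_starts)
                            if best is None or fit.logml > best[0].logml + 1e-9:
                                best = (fit, lab, Kfull)
                        fit, lab, Kfull = best
                        ps = predict_cells(fit, Kfull, line_order, env_order,
                                           train_cells, y_tr, test_cells)
                        for c, v in zip(test_cells, ps.y_hat):
                            preds[method][c] = v
                        params[method] = lab

                for method in methods:
                    for env in env_order:
                        te = test_by_env[env]
                        if not te or any(c not in preds[method] for c in te):
                            continue
                        err = msep([values[c] for c in te], [preds[method][c] for c in te])
                        rows.append({
                            "method": method, "model": model, "env": env,
                            "replicate": rep, "fold": fold, "msep": err,
                            "n_test": len(te),
                            "param": params.get((method, env), params.get(method)),
                        })
    return CVResult(records=pd.DataFrame(rows))
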