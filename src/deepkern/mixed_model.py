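"""Kernel mixed models for single- and multi-environment genomic prediction.

The single-environment model is

    y = μ1 + u + ε,        u ~ N(0, σu² K),   ε ~ N(0, σε² I),

with K an observation-level genomic kernel.  The multi-environment G×E model
adds environment intercepts and an interaction term,

    y = Z_E β_E + u1 + u2 + ε,
    u1 ~ N(0, σu1² K1),  K1 = Zg G Zg',
    u2 ~ N(0, σu2² K2),  K2 = (Zg G Zg') ∘ (Z_E Z_E'),

where G is a line-level kernel (GB, GK or AK), Zg maps observations to lines
and ∘ is the Hadamard product, so u2 correlates observations of related lines
only within the same environment.  μ1 + Z_E β_E is rank deficient, so the
fixed part is parameterised as one intercept per environment (cell means); μ
is reported as their mean.

Estimation is by maximum marginal likelihood.  Fixed effects and the residual
variance are profiled out in closed form; the remaining variance ratios
λ_r = σ_r²/σε² are optimised on the log scale — a bounded 1-D search via the
eigendecomposition of K when there is a single kernel, multi-start
Nelder–Mead with Cholesky likelihood evaluations otherwise.  The returned
log marginal likelihood is exact at the fitted parameters.

Follows the Model/Results convention: ``KernelMixedModel(...).fit()`` returns
a ``KernelMixedModelResults`` carrying estimates, approximate standard
errors, BLUPs and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_solve, solve_triangular
from scipy.optimize import minimize, minimize_scalar

from .io import PhenotypeTable
from .kernels import KernelMatrix

VAR_FLOOR = 1e-10
_LOG_LAM_BOUND = 25.0


@dataclass
class IncidenceMatrices:
    """0/1 designs relating observations to lines (Zg) and environments (ZE)."""

    Zg: np.ndarray
    ZE: np.ndarray
    line_order: list[str]
    env_order: list[str]

    def __post_init__(self) -> None:
        for M, what in ((self.Zg, "Zg"), (self.ZE, "ZE")):
            if not np.array_equal(M.sum(axis=1), np.ones(M.shape[0])):
                raise ValueError(f"every row of {what} must contain exactly one 1")

    @property
    def line_index(self) -> np.ndarray:
        return self.Zg.argmax(axis=1)

    @property
    def env_index(self) -> np.ndarray:
        return self.ZE.argmax(axis=1)


def build_incidence(pheno: PhenotypeTable, line_order: list[str], env_order: list[str]) -> IncidenceMatrices:
    """Build Zg and ZE for the records of ``pheno`` under the given orders."""
    line_pos = {l: i for i, l in enumerate(line_order)}
    env_pos = {e: i for i, e in enumerate(env_order)}
    n = len(pheno.records)
    Zg = np.zeros((n, len(line_order)))
    ZE = np.zeros((n, len(env_order)))
    for i, (line, env) in enumerate(zip(pheno.records["line"], pheno.records["env"])):
        if line not in line_pos:
            raise ValueError(f"unknown line {line!r}")
        if env not in env_pos:
            raise ValueError(f"unknown environment {env!r}")
        Zg[i, line_pos[line]] = 1.0
        ZE[i, env_pos[env]] = 1.0
    return IncidenceMatrices(Zg=Zg, ZE=ZE, line_order=list(line_order), env_order=list(env_order))


def expand_main_kernel(G: KernelMatrix | np.ndarray, inc: IncidenceMatrices) -> np.ndarray:
    """Observation-level main-effect kernel K1 = Zg G Zg'."""
    Gm = G.K if isinstance(G, KernelMatrix) else np.asarray(G, dtype=float)
    if Gm.shape[0] != inc.Zg.shape[1]:
        raise ValueError(f"G is {Gm.shape[0]}x{Gm.shape[0]} but Zg has {inc.Zg.shape[1]} columns")
    li = inc.line_index
    return Gm[np.ix_(li, li)]


def gxe_kernel(K1: np.ndarray, inc: IncidenceMatrices) -> np.ndarray:
    """Interaction kernel K2 = K1 ∘ (ZE ZE'): K1 within environments, 0 across."""
    if K1.shape[0] != inc.ZE.shape[0]:
        raise ValueError("K1 and ZE have inconsistent numbers of observations")
    ei = inc.env_index
    same_env = (ei[:, None] == ei[None, :]).astype(float)
    return K1 * same_env


def _as_matrix(K) -> np.ndarray:
    return K.K if isinstance(K, KernelMatrix) else np.asarray(K, dtype=float)


class KernelMixedModel:
    """Gaussian mixed model y ~ N(Fβ, Σ_r σ_r² K_r + σε² I).

    Parameters
    ----------
    y : array
        Observation vector.
    kernels : dict[str, array]
        Named observation-level covariance kernels (e.g. ``{"genomic": K1,
        "gxe": K2}``).  Each must be symmetric PSD and n×n.
    fixed : array, optional
        Fixed-effect design matrix; defaults to a single intercept column.
    fe_names : list of str, optional
        Column labels for the fixed design.
    """

    def __init__(self, y, kernels, fixed=None, fe_names=None):
        self.y = np.asarray(y, dtype=float).ravel()
        if not np.isfinite(self.y).all():
            raise ValueError("y contains non-finite values")
        n = self.y.size
        if isinstance(kernels, dict):
            self.kernel_names = list(kernels)
            self.kernels = [_as_matrix(K) for K in kernels.values()]
        else:
            self.kernels = [_as_matrix(K) for K in kernels]
            self.kernel_names = [f"k{r+1}" for r in range(len(self.kernels))]
        if not self.kernels:
            raise ValueError("at least one kernel is required")
        # 1-D kernels are diagonal covariances (e.g. jointly rotated balanced
        # designs); they enable O(n) likelihood evaluations
        self.diagonal = all(K.ndim == 1 for K in self.kernels)
        if any(K.ndim == 1 for K in self.kernels) and not self.diagonal:
            raise ValueError("kernels must be all dense or all diagonal (1-D)")
        for name, K in zip(self.kernel_names, self.kernels):
            expected = (n,) if self.diagonal else (n, n)
            if K.shape != expected:
                raise ValueError(f"kernel {name!r} has shape {K.shape}, expected {expected}")
            if self.diagonal and (K < 0).any():
                raise ValueError(f"diagonal kernel {name!r} has negative entries")
        self.fixed = np.ones((n, 1)) if fixed is None else np.asarray(fixed, dtype=float)
        if self.fixed.ndim == 1:
            self.fixed = self.fixed[:, None]
        if np.linalg.matrix_rank(self.fixed) < self.fixed.shape[1]:
            raise ValueError("fixed-effect design is singular")
        self.fe_names = list(fe_names) if fe_names else [f"b{j}" for j in range(self.fixed.shape[1])]

    # -- likelihood machinery -------------------------------------------------

    def _profile_given_whitened(self, yw, Fw, logdet_w):
        """GLS for β and closed-form σε² given whitened data; returns (logml, beta, sig2e, resid_w)."""
        n = yw.size
        beta, *_ = np.linalg.lstsq(Fw, yw, rcond=None)
        r = yw - Fw @ beta
        sig2e = max(float(r @ r) / n, VAR_FLOOR)
        logml = -0.5 * (n * np.log(2 * np.pi * sig2e) + logdet_w + n)
        return logml, beta, sig2e, r

    def _eval_chol(self, log_lams):
        lams = np.exp(np.clip(log_lams, -_LOG_LAM_BOUND, _LOG_LAM_BOUND))
        n = self.y.size
        if self.diagonal:
            w = np.ones(n)
            for lam, dk in zip(lams, self.kernels):
                w = w + lam * dk
            sw = np.sqrt(w)
            logml, beta, sig2e, r = self._profile_given_whitened(
                self.y / sw, self.fixed / sw[:, None], float(np.log(w).sum())
            )
            return {"logml": logml, "beta": beta, "sig2e": sig2e, "lams": lams, "w": w}
        W = np.eye(n)
        for lam, K in zip(lams, self.kernels):
            W += lam * K
        try:
            L = np.linalg.cholesky(W)
        except np.linalg.LinAlgError:
            return None
        yw = solve_triangular(L, self.y, lower=True)
        Fw = solve_triangular(L, self.fixed, lower=True)
        logdet_w = 2.0 * float(np.log(np.diag(L)).sum())
        logml, beta, sig2e, r = self._profile_given_whitened(yw, Fw, logdet_w)
        return {"logml": logml, "beta": beta, "sig2e": sig2e, "lams": lams, "L": L}

    def loglike(self, var_components: dict[str, float], beta=None) -> float:
        """Exact Gaussian log marginal likelihood at given variances (and β).

        β defaults to its GLS value at those variances.
        """
        n = self.y.size
        sig2e = float(var_components["residual"])
        if self.diagonal:
            v = np.full(n, sig2e)
            for name, dk in zip(self.kernel_names, self.kernels):
                v = v + float(var_components[name]) * dk
            sv = np.sqrt(v)
            yw, Fw = self.y / sv, self.fixed / sv[:, None]
            logdet = float(np.log(v).sum())
        else:
            V = sig2e * np.eye(n)
            for name, K in zip(self.kernel_names, self.kernels):
                V += float(var_components[name]) * K
            L = np.linalg.cholesky(V)
            yw = solve_triangular(L, self.y, lower=True)
            Fw = solve_triangular(L, self.fixed, lower=True)
            logdet = 2.0 * float(np.log(np.diag(L)).sum())
        if beta is None:
            beta, *_ = np.linalg.lstsq(Fw, yw, rcond=None)
        r = yw - Fw @ np.asarray(beta)
        return -0.5 * (n * np.log(2 * np.pi) + logdet + float(r @ r))

    # -- fitting --------------------------------------------------------------

    def _fit_eigen(self):
        """Single-kernel path: eigendecompose K once, 1-D search over log λ."""
        K = self.kernels[0]
        d, U = np.linalg.eigh(K)
        d = np.maximum(d, 0.0)
        yr = U.T @ self.y
        Fr = U.T @ self.fixed

        def neg_logml(log_lam):
            lam = np.exp(log_lam)
            w = lam * d + 1.0
            sw = np.sqrt(w)
            logml, *_ = self._profile_given_whitened(yr / sw, Fr / sw[:, None], float(np.log(w).sum()))
            return -logml

        res = minimize_scalar(
            neg_logml, bounds=(-_LOG_LAM_BOUND, _LOG_LAM_BOUND), method="bounded",
            options={"xatol": 1e-8},
        )
        lam = float(np.exp(res.x))
        w = lam * d + 1.0
        sw = np.sqrt(w)
        logml, beta, sig2e, _ = self._profile_given_whitened(
            yr / sw, Fr / sw[:, None], float(np.log(w).sum())
        )
        # BLUP: u_hat = lam*K W^{-1} (y - F beta), W = I + lam K, in the eigenbasis
        resid_r = yr - Fr @ beta
        u_hat = U @ (lam * d / w * resid_r)
        return {
            "lams": np.array([lam]), "beta": beta, "sig2e": sig2e, "logml": logml,
            "blups": [u_hat], "n_iter": int(res.nfev), "converged": bool(res.success),
        }

    def _neg_logml_and_grad(self, log_lams):
        """Profiled −logML and its gradient w.r.t. log λ (envelope theorem).

        With β and σε² profiled out, ∂logML/∂λ_r =
        (1/2σ̂ε²) rᵀW⁻¹K_rW⁻¹r − ½ tr(W⁻¹K_r); the log-scale gradient
        multiplies by λ_r.
        """
        out = self._eval_chol(log_lams)
        if out is None:
            return np.inf, np.zeros_like(log_lams)
        n = self.y.size
        resid = self.y - self.fixed @ out["beta"]
        if self.diagonal:
            w = out["w"]
            Winv_r = resid / w
            grad = np.empty(len(self.kernels))
            for r, dk in enumerate(self.kernels):
                quad = float(np.sum(dk * Winv_r**2))
                tr = float(np.sum(dk / w))
                grad[r] = -(0.5 * quad / out["sig2e"] - 0.5 * tr) * out["lams"][r]
            return -out["logml"], grad
        L = out["L"]
        Winv_r = cho_solve((L, True), resid)
        Winv = cho_solve((L, True), np.eye(n))
        grad = np.empty(len(self.kernels))
        for r, K in enumerate(self.kernels):
            quad = float(Winv_r @ (K @ Winv_r))
            tr = float(np.sum(Winv * K))
            dl_dlam = 0.5 * quad / out["sig2e"] - 0.5 * tr
            grad[r] = -dl_dlam * out["lams"][r]  # chain rule to log scale, negated
        return -out["logml"], grad

    def _fit_nm(self, n_starts=3, seed=0):
        """Multi-kernel path: gradient-based search over log variance ratios.

        L-BFGS-B with the analytic profiled gradient, multi-start; falls back
        to Nelder–Mead from the best point if the gradient path fails.
        """
        R = len(self.kernels)
        rng = np.random.default_rng(seed)
        starts = [np.zeros(R), np.full(R, np.log(0.1)), np.full(R, np.log(5.0))]
        while len(starts) < n_starts:
            starts.append(rng.normal(scale=2.0, size=R))
        starts = starts[:max(n_starts, 1)]
        bounds = [(-_LOG_LAM_BOUND, _LOG_LAM_BOUND)] * R

        best = None
        nfev = 0
        converged = False
        for x0 in starts:
            res = minimize(
                self._neg_logml_and_grad, x0, jac=True, method="L-BFGS-B",
                bounds=bounds, options={"ftol": 1e-12, "gtol": 1e-7, "maxiter": 200},
            )
            nfev += res.nfev
            if best is None or res.fun < best.fun - 1e-12:
                best = res
            converged = converged or bool(res.success)
        if best is None or not np.isfinite(best.fun):
            res = minimize(
                lambda t: self._neg_logml_and_grad(t)[0], np.zeros(R),
                method="Nelder-Mead",
                options={"xatol": 1e-5, "fatol": 1e-9, "maxfev": 400 * R},
            )
            nfev += res.nfev
            best, converged = res, bool(res.success)
        out = self._eval_chol(best.x)
        # BLUPs: u_r = sig2_r K_r V^{-1}(y - F beta) = lam_r K_r W^{-1} resid
        resid = self.y - self.fixed @ out["beta"]
        if self.diagonal:
            Winv_resid = resid / out["w"]
            blups = [lam * dk * Winv_resid for lam, dk in zip(out["lams"], self.kernels)]
        else:
            Winv_resid = cho_solve((out["L"], True), resid)
            blups = [lam * K @ Winv_resid for lam, K in zip(out["lams"], self.kernels)]
        return {
            "lams": out["lams"], "beta": out["beta"], "sig2e": out["sig2e"],
            "logml": out["logml"], "blups": blups, "n_iter": nfev, "converged": converged,
        }

    def fit(self, method: str = "auto", n_starts: int = 3, compute_se: bool = True) -> "KernelMixedModelResults":
        """Maximise the marginal likelihood and return a results object.

        ``method`` is ``"eigen"`` (single kernel only), ``"nm"`` or ``"auto"``.
        """
        if method == "auto":
            method = "eigen" if len(self.kernels) == 1 and not self.diagonal else "nm"
        if method == "eigen":
            if len(self.kernels) != 1 or self.diagonal:
                raise ValueError("eigen path requires exactly one dense kernel")
            raw = self._fit_eigen()
        elif method == "nm":
            raw = self._fit_nm(n_starts=n_starts)
        else:
            raise ValueError(f"unknown method {method!r}")

        vc = {name: max(float(lam * raw["sig2e"]), VAR_FLOOR)
              for name, lam in zip(self.kernel_names, raw["lams"])}
        vc["residual"] = raw["sig2e"]
        se = self._varcomp_se(vc) if compute_se else None
        return KernelMixedModelResults(
            model=self, params=np.asarray(raw["beta"]), var_components=vc, var_se=se,
            logml=float(raw["logml"]),
            blups={n: b for n, b in zip(self.kernel_names, raw["blups"])},
            converged=raw["converged"], n_iter=raw["n_iter"],
        )

    def _varcomp_se(self, vc: dict[str, float]) -> dict[str, float] | None:
        """Approximate SEs from the numerical observed information of the profile likelihood."""
        names = self.kernel_names + ["residual"]
        theta = np.array([vc[n] for n in names])

        def ll(t):
            if (t <= 0).any():
                return -np.inf
            return self.loglike(dict(zip(names, t)))

        k = theta.size
        H = np.zeros((k, k))
        h = 1e-3 * np.maximum(theta, 1e-4)
        try:
            f0 = ll(theta)
            for i in range(k):
                for j in range(i, k):
                    ei = np.eye(k)[i] * h[i]
                    ej = np.eye(k)[j] * h[j]
                    fpp = ll(theta + ei + ej)
                    fpm = ll(theta + ei - ej)
                    fmp = ll(theta - ei + ej)
                    fmm = ll(theta - ei - ej)
                    if not np.isfinite([fpp, fpm, fmp, fmm]).all():
                        return None
                    H[i, j] = H[j, i] = (fpp - fpm - fmp + fmm) / (4 * h[i] * h[j])
            cov = np.linalg.inv(-H)
            d = np.diag(cov)
            if (d <= 0).any():
                return None
            return dict(zip(names, np.sqrt(d)))
        except (np.linalg.LinAlgError, FloatingPointError):
            return None


@dataclass
class KernelMixedModelResults:
    """Fitted kernel mixed model: estimates, uncertainties, BLUPs, diagnostics."""

    model: KernelMixedModel
    params: np.ndarray
    var_components: dict[str, float]
    var_se: dict[str, float] | None
    logml: float
    blups: dict[str, np.ndarray]
    converged: bool
    n_iter: int

    @property
    def mu(self) -> float:
        """Overall intercept (mean of the fixed-effect coefficients)."""
        return float(np.mean(self.params))

    @property
    def beta_E(self) -> np.ndarray:
        return np.asarray(self.params)

    @property
    def fittedvalues(self) -> np.ndarray:
        yhat = self.model.fixed @ self.params
        for b in self.blups.values():
            yhat = yhat + b
        return yhat

    def heritability(self) -> float:
        """Narrow-sense heritability: genomic main-effect share of total variance.

        σu1²/(σu1²+σu2²+σε²) for the G×E model; σu²/(σu²+σε²) with one kernel.
        """
        total = sum(self.var_components.values())
        if total <= 0:
            raise ValueError("zero total variance")
        main = self.var_components[self.model.kernel_names[0]]
        return main / total

    def summary(self) -> str:
        lines = [
            "Kernel mixed model (maximum marginal likelihood)",
            f"  n obs: {self.model.y.size}   kernels: {', '.join(self.model.kernel_names)}",
            f"  log marginal likelihood: {self.logml:.4f}",
            f"  converged: {self.converged}   function evals: {self.n_iter}",
            "  Fixed effects:",
        ]
        for name, b in zip(self.model.fe_names, np.atleast_1d(self.params)):
            lines.append(f"    {name:>12s}  {b: .5f}")
        lines.append("  Variance components:")
        for name, v in self.var_components.items():
            se = self.var_se.get(name) if self.var_se else None
            se_s = f"  (SE {se:.4f})" if se is not None else ""
            lines.append(f"    {name:>12s}  {v: .5f}{se_s}")
        lines.append(f"  Narrow-sense heritability: {self.heritability():.4f}")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"component": k, "variance": v,
                 "se": (self.var_se or {}).get(k, np.nan)} for k, v in self.var_components.items()]
        return pd.DataFrame(rows)


# -- spec-surface convenience functions --------------------------------------


def fit_single_kernel(y, K, fixed=None, **fit_kw) -> KernelMixedModelResults:
    """Fit y = μ1 + u + ε with u ~ N(0, σu² K)."""
    return KernelMixedModel(y, {"genomic": K}, fixed=fixed).fit(**fit_kw)


def fit_multi_kernel(y, ZE, kernels, **fit_kw) -> KernelMixedModelResults:
    """Fit the G×E model with environment intercepts and the given kernels.

    ``kernels`` is typically ``[K1, K2]`` (main + interaction); with a single
    entry the model nests the single-kernel model with per-environment means.
    """
    names = ["genomic", "gxe", *[f"k{r}" for r in range(3, len(kernels) + 1)]][: len(kernels)]
    env_names = [f"env{j}" for j in range(np.asarray(ZE).shape[1])]
    return KernelMixedModel(
        y, dict(zip(names, kernels)), fixed=ZE, fe_names=env_names
    ).fit(method="nm" if len(kernels) > 1 else "auto", **fit_kw)


def heritability(fit: KernelMixedModelResults) -> float:
    return fit.heritability()


def fit_complete_gxe(Y, G, **fit_kw) -> KernelMixedModelResults:
    """Fast exact ML fit of the G×E model for a complete lines × envs table.

    For a balanced trial (every line observed in every environment, sorted
    environment-major) the observation-level kernels have Kronecker form
    K1 = J_m ⊗ G and K2 = I_m ⊗ G, which are simultaneously diagonalized by
    Q ⊗ U with G = U D U' and Q an orthonormal basis whose first column is
    constant.  After that one rotation every likelihood evaluation is O(nm),
    so large replicate studies are cheap.  Returns the same estimates and
    log marginal likelihood as ``fit_multi_kernel`` on the dense kernels.
    """
    Y = np.asarray(Y, dtype=float)
    n, m = Y.shape
    Gm = _as_matrix(G)
    if Gm.shape != (n, n):
        raise ValueError(f"G must be {n}x{n} to match the {n}x{m} response table")
    d, U = np.linalg.eigh(Gm)
    d = np.maximum(d, 0.0)
    # orthonormal basis of R^m with constant first column (eigenbasis of J_m)
    Q, _ = np.linalg.qr(np.hstack([np.full((m, 1), 1.0 / np.sqrt(m)), np.eye(m)[:, : m - 1]]))
    if Q[0, 0] < 0:
        Q = -Q
    ytil = (U.T @ Y @ Q).ravel(order="F")
    d1 = np.concatenate([(m if q == 0 else 0.0) * d for q in range(m)])
    d2 = np.tile(d, m)
    u1 = U.T @ np.ones(n)
    # rotated environment design: column j of ZE is e_j (x) 1_n
    F = np.zeros((n * m, m))
    for q in range(m):
        for j in range(m):
            F[q * n:(q + 1) * n, j] = Q[j, q] * u1
    model = KernelMixedModel(ytil, {"genomic": d1, "gxe": d2}, fixed=F,
                             fe_names=[f"env{j}" for j in range(m)])
    return model.fit(method="nm", **fit_kw)


@dataclass
class PredictionSet:
    cells: list[tuple[str, str]]
    y_hat: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"line": [c[0] for c in self.cells], "env": [c[1] for c in self.cells],
             "y_hat": self.y_hat}
        )


def predict_cells(
    fit: KernelMixedModelResults,
    G: KernelMatrix | np.ndarray,
    line_order: list[str],
    env_order: list[str],
    train_cells: list[tuple[str, str]],
    y_train,
    target_cells: list[tuple[str, str]],
) -> PredictionSet:
    """BLUP prediction of unobserved line×environment cells.

    Uses the conditional-Gaussian formula under the fitted variance
    components: ŷ_U = f_U + C_UT (C_TT + σε² I)⁻¹ (y_T − f_T), where C is the
    genetic covariance implied by G (main effect, plus the within-environment
    G×E block when the fit contains a ``gxe`` component) and f the fixed part.
    """
    Gm = _as_matrix(G)
    line_pos = {l: i for i, l in enumerate(line_order)}
    env_pos = {e: i for i, e in enumerate(env_order)}
    for line, _ in target_cells:
        if line not in line_pos:
            raise ValueError(f"target line {line!r} absent from G")

    def indices(cells):
        li = np.array([line_pos[l] for l, _ in cells])
        ei = np.array([env_pos[e] for _, e in cells])
        return li, ei

    li_T, ei_T = indices(train_cells)
    li_U, ei_U = indices(target_cells)
    vc = fit.var_components
    sig_main = vc[fit.model.kernel_names[0]]
    sig_gxe = vc.get("gxe", 0.0)

    def cov(li_a, ei_a, li_b, ei_b):
        C = sig_main * Gm[np.ix_(li_a, li_b)]
        if sig_gxe > 0:
            same = (ei_a[:, None] == ei_b[None, :])
            C = C + sig_gxe * Gm[np.ix_(li_a, li_b)] * same
        return C

    def fixed_part(cells, ei):
        if fit.params.size == len(env_order):
            return fit.params[ei]
        return np.full(len(cells), fit.mu)

    C_TT = cov(li_T, ei_T, li_T, ei_T)
    C_UT = cov(li_U, ei_U, li_T, ei_T)
    y_T = np.asarray(y_train, dtype=float)
    f_T = fixed_part(train_cells, ei_T)
    f_U = fixed_part(target_cells, ei_U)
    A = C_TT + vc["residual"] * np.eye(len(train_cells))
    y_hat = f_U + C_UT @ np.linalg.solve(A, y_T - f_T)
    return PredictionSet(cells=list(target_cells), y_hat=y_hat)
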