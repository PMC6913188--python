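"""Marginal-likelihood selection of the AK layer count and the GK bandwidth.

Each candidate kernel (AK at layer l = 1..l_max, or GK at each bandwidth h in
a standardized grid) is plugged into the requested mixed model; the candidate
maximising the log marginal likelihood is chosen, with ties broken toward the
simpler candidate (smaller l, smaller h).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MarkerMatrix, PhenotypeTable
from .kernels import KernelMatrix, ak_series, gaussian_kernel
from .mixed_model import (
    build_incidence,
    expand_main_kernel,
    fit_multi_kernel,
    fit_single_kernel,
    gxe_kernel,
)

DEFAULT_L_MAX = 8
DEFAULT_H_GRID = (0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.5, 5.0)

#: logML differences below this are treated as ties (resolved toward simplicity)
TIE_TOL = 1e-9


@dataclass
class SelectionTrace:
    """Per-candidate log marginal likelihoods and the chosen candidate."""

    candidates: list
    logml: list[float]
    chosen: object = field(init=False)
    failures: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.candidates) != len(self.logml):
            raise ValueError("candidates and logml lengths differ")
        finite = [(c, v) for c, v in zip(self.candidates, self.logml) if np.isfinite(v)]
        if not finite:
            raise ValueError("no candidate produced a finite log marginal likelihood")
        best = max(v for _, v in finite)
        # first (i.e. simplest, in grid order) candidate within TIE_TOL of the max
        self.chosen = next(c for c, v in finite if v >= best - TIE_TOL)

    @classmethod
    def from_values(cls, candidates, logml) -> "SelectionTrace":
        return cls(candidates=list(candidates), logml=[float(v) for v in logml])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"candidate": self.candidates, "logml": self.logml,
             "chosen": [c == self.chosen for c in self.candidates]}
        )


def _fit_model(y, G: KernelMatrix, model: str, pheno: PhenotypeTable | None, line_order):
    """Fit model {g, e-g-ge} with line-level kernel G; returns the results object."""
    if model == "g":
        if pheno is None:
            K = G.K
        else:
            inc = build_incidence(pheno, line_order, pheno.envs)
            K = expand_main_kernel(G, inc)
        return fit_single_kernel(y, K, compute_se=False)
    if model == "e-g-ge":
        if pheno is None:
            raise ValueError("model 'e-g-ge' requires a phenotype table")
        inc = build_incidence(pheno, line_order, pheno.envs)
        K1 = expand_main_kernel(G, inc)
        K2 = gxe_kernel(K1, inc)
        return fit_multi_kernel(y, inc.ZE, [K1, K2], compute_se=False, n_starts=2)
    raise ValueError(f"unknown model {model!r}")


def select_ak_layers(
    y,
    X: MarkerMatrix,
    model: str = "g",
    l_max: int = DEFAULT_L_MAX,
    pheno: PhenotypeTable | None = None,
    series: list[KernelMatrix] | None = None,
) -> SelectionTrace:
    """Choose the arc-cosine kernel depth by maximum marginal likelihood.

    ``series`` may supply precomputed AK kernels (layers 1..l_max) to avoid
    rebuilding them across cross-validation folds.
    """
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    kernels = series[:l_max] if series is not None else ak_series(X, l_max)
    logml, failures = [], {}
    for K in kernels:
        try:
            logml.append(_fit_model(y, K, model, pheno, list(X.line_ids)).logml)
        except Exception as exc:  # noqa: BLE001 - selection proceeds over survivors
            logml.append(-np.inf)
            failures[K.layer] = repr(exc)
    trace = SelectionTrace(candidates=[K.layer for K in kernels], logml=logml)
    trace.failures = failures
    return trace


def select_gk_bandwidth(
    y,
    D2,
    model: str = "g",
    grid=DEFAULT_H_GRID,
    pheno: PhenotypeTable | None = None,
    line_ids: list[str] | None = None,
) -> SelectionTrace:
    """Choose the Gaussian-kernel bandwidth h over a standardized grid."""
    grid = list(grid)
    if not grid or any(h <= 0 for h in grid):
        raise ValueError("grid must be non-empty with all h > 0")
    order = sorted(grid)
    logml, failures = [], {}
    ids = line_ids or [str(i) for i in range(D2.D2.shape[0])]
    for h in order:
        try:
            G = gaussian_kernel(D2, h, line_ids=ids)
            logml.append(_fit_model(y, G, model, pheno, ids).logml)
        except Exception as exc:  # noqa: BLE001
            logml.append(-np.inf)
            failures[h] = repr(exc)
    trace = SelectionTrace(candidates=order, logml=logml)
    trace.failures = failures
    return trace
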