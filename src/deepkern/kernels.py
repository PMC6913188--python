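"""Genomic similarity kernels: linear GBLUP (GB), Gaussian (GK), arc-cosine (AK).

GB is the genomic relationship matrix G = XX'/p built from the scaled marker
matrix.  GK is the Gaussian kernel exp(-h d²/q) with d² the squared Euclidean
marker distance and q the median off-diagonal squared distance, so a single
standardized bandwidth grid works across data sets.  AK is the arc-cosine
kernel of order one,

    AK1(x, x') = (1/π) ||x|| ||x'|| J(θ),   J(θ) = sin θ + (π − θ) cos θ,

which equals (up to a factor 2) the expected product of ramp (ReLU) unit
activations with standard-normal weights — i.e. the covariance function of an
infinitely wide single-hidden-layer network.  A recursion on the kernel
emulates additional hidden layers:

    AK^{l+1}(x, x') = (1/π) sqrt(AK^l(x,x) AK^l(x',x')) J(θ^l),

with θ^l the angle implied by the layer-l kernel.  The diagonal is invariant
under this recursion and, unlike GK, heterogeneous across lines.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import MarkerMatrix

logger = logging.getLogger(__name__)

#: arccos arguments may overshoot [-1, 1] by at most this before it is an error
CLIP_TOL = 1e-12
SYM_TOL = 1e-10
PSD_RTOL = 1e-8


@dataclass
class DistanceMatrix:
    """Pairwise squared Euclidean distances with their median normalizer q."""

    D2: np.ndarray
    q: float = field(init=False)

    def __post_init__(self) -> None:
        D2 = np.asarray(self.D2, dtype=float)
        if D2.ndim != 2 or D2.shape[0] != D2.shape[1]:
            raise ValueError("D2 must be square")
        if np.abs(D2 - D2.T).max(initial=0.0) > SYM_TOL:
            raise ValueError("D2 must be symmetric")
        if np.diag(D2).any():
            raise ValueError("D2 diagonal must be exactly zero")
        if (D2 < 0).any():
            raise ValueError("squared distances must be non-negative")
        self.D2 = D2
        n = D2.shape[0]
        off = D2[np.triu_indices(n, k=1)]
        self.q = float(np.median(off)) if off.size else 0.0


@dataclass
class AngleMatrix:
    """Pairwise angles θ between marker vectors, in radians, in [0, π]."""

    Theta: np.ndarray

    def __post_init__(self) -> None:
        T = np.asarray(self.Theta, dtype=float)
        if (T < -1e-12).any() or (T > np.pi + 1e-12).any():
            raise ValueError("angles must lie in [0, pi]")
        self.Theta = np.clip(T, 0.0, np.pi)


@dataclass
class KernelMatrix:
    """Labeled symmetric PSD similarity matrix among lines.

    ``kind`` is one of GB, GK, AK; AK carries its layer l, GK its bandwidth h.
    Construction validates symmetry and (approximate) positive
    semidefiniteness; eigenvalues more negative than the tolerance but still
    tiny are repaired by adding εI, which is logged.
    """

    K: np.ndarray
    kind: str
    line_ids: list[str] | None = None
    layer: int | None = None
    bandwidth: float | None = None

    def __post_init__(self) -> None:
        K = np.asarray(self.K, dtype=float)
        if K.ndim != 2 or K.shape[0] != K.shape[1]:
            raise ValueError("kernel must be square")
        if self.kind not in ("GB", "GK", "AK"):
            raise ValueError(f"unknown kernel kind {self.kind!r}")
        asym = np.abs(K - K.T).max(initial=0.0)
        if asym > SYM_TOL:
            raise ValueError(f"kernel not symmetric (max |K-K'| = {asym:g})")
        K = 0.5 * (K + K.T)
        w = np.linalg.eigvalsh(K)
        lam_min, lam_max = float(w[0]), float(w[-1])
        tol = PSD_RTOL * max(1.0, lam_max)
        if lam_min < -tol:
            raise ValueError(f"kernel not PSD: lambda_min = {lam_min:g}")
        if lam_min < 0:
            eps = abs(lam_min) + 1e-10
            K = K + eps * np.eye(K.shape[0])
            logger.info("repaired tiny PSD violation by adding %.3g I", eps)
        self.K = K
        if self.line_ids is not None and len(self.line_ids) != K.shape[0]:
            raise ValueError("line_ids length does not match kernel size")

    @property
    def n(self) -> int:
        return self.K.shape[0]

    def to_csv(self, path) -> None:
        ids = self.line_ids or [str(i) for i in range(self.n)]
        pd.DataFrame(self.K, index=ids, columns=ids).to_csv(path)

    @classmethod
    def from_csv(cls, path, kind: str, **kw) -> "KernelMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(K=df.to_numpy(dtype=float), kind=kind, line_ids=[str(i) for i in df.index], **kw)


def linear_kernel(X: MarkerMatrix) -> KernelMatrix:
    """GBLUP genomic relationship matrix G = XX'/p."""
    if X.n < 2:
        raise ValueError("need at least 2 lines")
    if X.p < 1:
        raise ValueError("need at least 1 marker")
    K = X.X @ X.X.T / X.p
    return KernelMatrix(K=K, kind="GB", line_ids=list(X.line_ids))


def squared_distances(X: MarkerMatrix) -> DistanceMatrix:
    """Pairwise squared Euclidean distances d²(i,i') = Σ_k (x_ik − x_i'k)²."""
    D2 = squareform(pdist(X.X, metric="sqeuclidean"))
    np.fill_diagonal(D2, 0.0)
    return DistanceMatrix(D2=D2)


def gaussian_kernel(d: DistanceMatrix, h: float, line_ids: list[str] | None = None) -> KernelMatrix:
    """Gaussian kernel K(i,i') = exp(−h d²(i,i') / q)."""
    if h <= 0:
        raise ValueError("bandwidth h must be > 0")
    if d.q <= 0:
        raise ValueError("median squared distance q must be > 0 (lines all identical?)")
    K = np.exp(-h * d.D2 / d.q)
    np.fill_diagonal(K, 1.0)
    return KernelMatrix(K=K, kind="GK", bandwidth=float(h), line_ids=line_ids)


def _J(theta: np.ndarray) -> np.ndarray:
    return np.sin(theta) + (np.pi - theta) * np.cos(theta)


def _safe_arccos(c: np.ndarray, what: str) -> np.ndarray:
    over = np.abs(c) - 1.0
    worst = over.max(initial=-np.inf)
    if worst > CLIP_TOL:
        raise ValueError(f"{what}: cosine argument exceeds [-1,1] by {worst:g}")
    return np.arccos(np.clip(c, -1.0, 1.0))


def ak_layer1(X: MarkerMatrix) -> tuple[KernelMatrix, AngleMatrix]:
    """First-layer arc-cosine kernel and the pairwise angle matrix."""
    S = X.X @ X.X.T
    norms = np.sqrt(np.diag(S))
    zero = np.flatnonzero(norms == 0)
    if zero.size:
        who = X.line_ids[int(zero[0])] if X.line_ids else str(int(zero[0]))
        raise ValueError(f"zero-norm marker vector for line {who!r}")
    outer = np.outer(norms, norms)
    theta = _safe_arccos(S / outer, "ak_layer1")
    np.fill_diagonal(theta, 0.0)
    K = outer * _J(theta) / np.pi
    K = 0.5 * (K + K.T)
    return (
        KernelMatrix(K=K, kind="AK", layer=1, line_ids=list(X.line_ids)),
        AngleMatrix(Theta=theta),
    )


def ak_recurse(K_l: KernelMatrix) -> KernelMatrix:
    """One step of the arc-cosine layer recursion, AK^(l) -> AK^(l+1)."""
    if K_l.kind != "AK":
        raise ValueError("ak_recurse requires an AK kernel")
    d = np.diag(K_l.K)
    if (d <= 0).any():
        raise ValueError("AK recursion requires a strictly positive diagonal")
    scale = np.sqrt(np.outer(d, d))
    theta = _safe_arccos(K_l.K / scale, f"ak_recurse(layer={K_l.layer})")
    np.fill_diagonal(theta, 0.0)
    K = scale * _J(theta) / np.pi
    K = 0.5 * (K + K.T)
    return KernelMatrix(K=K, kind="AK", layer=(K_l.layer or 1) + 1, line_ids=K_l.line_ids)


def ak_series(X: MarkerMatrix, l_max: int) -> list[KernelMatrix]:
    """Arc-cosine kernels for layers 1..l_max, each built from the previous."""
    if l_max < 1:
        raise ValueError("l_max must be >= 1")
    out, _ = ak_layer1(X)
    series = [out]
    for _ in range(l_max - 1):
        series.append(ak_recurse(series[-1]))
    return series
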