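"""Synthetic genotypes and multi-environment phenotypes.

Emulates the structure of a multi-environment elite yield trial: several
hundred inbred lines genotyped at thousands of biallelic markers (with a
configurable missing-call rate, as in GBS data), phenotyped in a handful of
managed environments.  Phenotypes decompose exactly as

    y(line, env) = env_mean + u1(line) + u2(line, env) + ε,

where u1 is a genomic main effect with an additive part (linear in marker
dosages) and an optional epistatic part built from products of random marker
pairs, u2 is a G×E deviation drawn with covariance proportional to the
genomic relationship matrix independently in each environment, and ε is iid
noise.  Every component is recorded in ``SimTruth`` so recovery can be
checked exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import PhenotypeTable, RawGenotypes, impute_and_scale


@dataclass
class SimConfig:
    """Study-scale defaults: 500 lines, 2,000 markers, 4 environments.

    With the default variances (additive 0.75, G×E 0.25, error 0.5) the
    per-environment narrow-sense heritability is 0.75/1.5 = 0.5, inside the
    0.45–0.75 range typical of well-replicated yield BLUEs.  ``env_means``
    default to grain-yield-like intercepts (ton/ha) with irrigated
    environments out-yielding droughted ones.
    """

    n_lines: int = 500
    n_markers: int = 2000
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    n_envs: int = 4
    env_means: tuple[float, ...] | None = None
    var_additive: float = 0.75     # total genomic main-effect variance σu1²
    var_epistatic: float = 0.0     # fraction of σu1² from pairwise marker products
    var_gxe: float = 0.25          # σu2²
    var_error: float = 0.5         # σε²
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not (0 <= self.missing_rate <= 1):
            raise ValueError("missing_rate must lie in [0, 1]")
        for v in (self.var_additive, self.var_gxe, self.var_error):
            if v < 0:
                raise ValueError("variances must be non-negative")
        if not (0 <= self.var_epistatic <= 1):
            raise ValueError("var_epistatic is a fraction in [0, 1]")
        if self.env_means is None:
            base = (6.0, 5.6, 3.2, 3.6, 5.0, 4.2, 3.0, 5.8)
            self.env_means = tuple(base[i % len(base)] for i in range(self.n_envs))
        if len(self.env_means) != self.n_envs:
            raise ValueError("env_means length must equal n_envs")

    @property
    def env_labels(self) -> list[str]:
        return [f"E{j+1}" for j in range(self.n_envs)]


@dataclass
class SimTruth:
    """Exact per-cell decomposition of the simulated phenotypes."""

    u1: pd.Series                 # per line
    u2: pd.DataFrame              # line x env
    noise: pd.DataFrame           # line x env
    env_means: dict[str, float]
    realized_var: dict[str, float]
    heritability: dict[str, float]  # per environment, Var(u1)/Var(y_env)


def simulate_genotypes(cfg: SimConfig) -> RawGenotypes:
    """Draw 0/1/2 genotypes with per-marker allele frequency uniform in maf_range."""
    rng = np.random.default_rng(cfg.seed)
    freq = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=cfg.n_markers)
    calls = rng.binomial(2, freq, size=(cfg.n_lines, cfg.n_markers)).astype(float)
    if cfg.missing_rate > 0:
        mask = rng.random(calls.shape) < cfg.missing_rate
        calls[mask] = np.nan
    return RawGenotypes(
        line_ids=[f"L{i+1:04d}" for i in range(cfg.n_lines)],
        calls=calls,
        marker_ids=[f"M{j+1:05d}" for j in range(cfg.n_markers)],
    )


def _unit_scale(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return v - v.mean() if sd == 0 else (v - v.mean()) / sd


def simulate_phenotypes(g: RawGenotypes, cfg: SimConfig) -> tuple[PhenotypeTable, SimTruth]:
    """Simulate multi-environment phenotypes on top of the given genotypes."""
    rng = np.random.default_rng(cfg.seed + 1)
    X = impute_and_scale(g, scaling="standardized").X
    n, p = X.shape

    # genomic main effect: additive + optional pairwise-epistatic part,
    # each standardized empirically so the variance split is exact in-sample
    b = rng.normal(size=p)
    u_add = _unit_scale(X @ b)
    f = cfg.var_epistatic
    if f > 0:
        n_pairs = min(2 * p, 5000)
        j1 = rng.integers(0, p, size=n_pairs)
        j2 = rng.integers(0, p, size=n_pairs)
        E = X[:, j1] * X[:, j2]
        u_epi = _unit_scale(E @ rng.normal(size=n_pairs))
        u1 = np.sqrt(cfg.var_additive) * (np.sqrt(1 - f) * u_add + np.sqrt(f) * u_epi)
    else:
        u1 = np.sqrt(cfg.var_additive) * u_add

    # GxE deviations: N(0, var_gxe * G) independently per environment
    G = X @ X.T / p
    d, U = np.linalg.eigh(G)
    d = np.maximum(d, 0.0)
    sqrtG = U * np.sqrt(d)
    envs = cfg.env_labels
    u2 = np.zeros((n, cfg.n_envs))
    if cfg.var_gxe > 0:
        z = rng.normal(size=(n, cfg.n_envs))
        u2 = np.sqrt(cfg.var_gxe) * (sqrtG @ z) / max(np.sqrt(np.mean(d)), 1e-12)

    noise = rng.normal(scale=np.sqrt(cfg.var_error), size=(n, cfg.n_envs)) if cfg.var_error > 0 else np.zeros((n, cfg.n_envs))

    records = []
    for j, env in enumerate(envs):
        for i, line in enumerate(g.line_ids):
            records.append((line, env, cfg.env_means[j] + u1[i] + u2[i, j] + noise[i, j]))
    pheno = PhenotypeTable(
        records=pd.DataFrame(records, columns=["line", "env", "value"]), envs=envs
    )

    h2 = {}
    for j, env in enumerate(envs):
        y_env = cfg.env_means[j] + u1 + u2[:, j] + noise[:, j]
        h2[env] = float(np.var(u1) / np.var(y_env)) if np.var(y_env) > 0 else np.nan
    truth = SimTruth(
        u1=pd.Series(u1, index=g.line_ids),
        u2=pd.DataFrame(u2, index=g.line_ids, columns=envs),
        noise=pd.DataFrame(noise, index=g.line_ids, columns=envs),
        env_means=dict(zip(envs, cfg.env_means)),
        realized_var={
            "genomic": float(np.var(u1)),
            "gxe": float(np.var(u2)),
            "residual": float(np.var(noise)),
        },
        heritability=h2,
    )
    return pheno, truth
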