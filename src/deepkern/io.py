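"""Marker and phenotype table I/O, quality control, imputation and scaling.

Genotypes are biallelic marker calls coded as minor-allele counts 0/1/2 with
missing values allowed (GBS-style data routinely has very high uncalling
rates).  Quality control mirrors the standard genomic-selection pipeline:
drop low-MAF markers, drop markers with excessive missingness, then drop
lines with too few called markers.  Missing calls are mean-imputed per
marker and the matrix is centered/standardized before kernel construction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DEFAULT_MISSING_TOKENS = ("NA", "", "-9")


class GenotypeParseError(ValueError):
    """Raised when a genotype file cannot be parsed."""


class GenotypeValidationError(ValueError):
    """Raised when parsed genotype values violate the 0/1/2 coding."""


@dataclass
class RawGenotypes:
    """Lines x markers calls in {0,1,2,NaN}; NaN marks a missing call."""

    line_ids: list[str]
    calls: np.ndarray  # float array, n x p, NaN = missing
    marker_ids: list[str]

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype=float)
        if self.calls.ndim != 2:
            raise GenotypeValidationError("calls must be a 2-D matrix")
        n, p = self.calls.shape
        if len(self.line_ids) != n or len(self.marker_ids) != p:
            raise GenotypeValidationError("id lengths do not match call matrix shape")
        if len(set(self.line_ids)) != n:
            raise GenotypeValidationError("duplicate line ids")
        if len(set(self.marker_ids)) != p:
            raise GenotypeValidationError("duplicate marker ids")
        observed = self.calls[~np.isnan(self.calls)]
        bad = ~np.isin(observed, (0.0, 1.0, 2.0))
        if bad.any():
            raise GenotypeValidationError(
                f"calls outside {{0,1,2}}: e.g. value {observed[bad][0]!r}"
            )

    @property
    def n_lines(self) -> int:
        return self.calls.shape[0]

    @property
    def n_markers(self) -> int:
        return self.calls.shape[1]

    def n_missing(self) -> int:
        return int(np.isnan(self.calls).sum())


@dataclass
class MarkerMatrix:
    """Complete (imputed) real-valued marker matrix X with its scaling state."""

    X: np.ndarray
    line_ids: list[str]
    marker_ids: list[str] | None = None
    scaling: str = "raw"  # raw | centered | standardized

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        if np.isnan(self.X).any():
            raise GenotypeValidationError("MarkerMatrix may not contain missing values")
        if self.scaling not in ("raw", "centered", "standardized"):
            raise ValueError(f"unknown scaling {self.scaling!r}")

    @property
    def p(self) -> int:
        return self.X.shape[1]

    @property
    def n(self) -> int:
        return self.X.shape[0]


@dataclass
class PhenotypeTable:
    """Long-format (line, env, value) trait records, e.g. grain yield BLUEs in ton/ha."""

    records: pd.DataFrame  # columns: line, env, value
    envs: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        needed = {"line", "env", "value"}
        if not needed.issubset(self.records.columns):
            raise ValueError(f"phenotype table needs columns {sorted(needed)}")
        self.records = self.records.reset_index(drop=True)
        dup = self.records.duplicated(subset=["line", "env"])
        if dup.any():
            pair = self.records.loc[dup.idxmax(), ["line", "env"]].tolist()
            raise ValueError(f"duplicate (line, env) pair: {pair}")
        if not self.envs:
            self.envs = list(pd.unique(self.records["env"]))
        unknown = set(self.records["env"]) - set(self.envs)
        if unknown:
            raise ValueError(f"records mention envs not in env order: {sorted(unknown)}")

    @property
    def lines(self) -> list[str]:
        return list(pd.unique(self.records["line"]))

    @property
    def y(self) -> np.ndarray:
        return self.records["value"].to_numpy(dtype=float)

    def check_lines_in(self, markers: MarkerMatrix) -> None:
        missing = set(self.records["line"]) - set(markers.line_ids)
        if missing:
            raise ValueError(f"phenotyped lines absent from marker matrix: {sorted(missing)[:5]}")


def _sep_for(path: str, dialect: dict | None) -> str:
    if dialect and "sep" in dialect:
        return dialect["sep"]
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_genotypes(path, dialect: dict | None = None) -> RawGenotypes:
    """Read a lines x markers genotype table (header of marker ids, first column line ids).

    ``dialect`` may override ``sep`` and the set of ``missing_tokens``
    (default ``{"NA", "", "-9"}``).
    """
    missing = list((dialect or {}).get("missing_tokens", DEFAULT_MISSING_TOKENS))
    try:
        df = pd.read_csv(
            path,
            sep=_sep_for(path, dialect),
            index_col=0,
            dtype=str,
            na_values=missing,
            keep_default_na=False,
            skip_blank_lines=True,
        )
    except pd.errors.EmptyDataError as exc:
        raise GenotypeParseError(f"empty genotype file: {path}") from exc
    if df.shape[1] == 0 or df.shape[0] == 0:
        raise GenotypeParseError(f"genotype file {path} has no data rows/columns")
    line_ids = [str(i) for i in df.index]
    if len(set(line_ids)) != len(line_ids):
        raise GenotypeValidationError(f"duplicate line id in {path}")
    calls = np.full(df.shape, np.nan)
    for j, col in enumerate(df.columns):
        raw = df[col].to_numpy()
        for i, cell in enumerate(raw):
            if cell is np.nan or (isinstance(cell, float) and np.isnan(cell)):
                continue
            try:
                calls[i, j] = float(cell)
            except (TypeError, ValueError) as exc:
                raise GenotypeParseError(
                    f"malformed cell at line {line_ids[i]!r}, marker {col!r}: {cell!r}"
                ) from exc
    return RawGenotypes(line_ids=line_ids, calls=calls, marker_ids=[str(c) for c in df.columns])


def write_genotypes(g: RawGenotypes, path, missing_token: str = "NA") -> None:
    df = pd.DataFrame(g.calls, index=g.line_ids, columns=g.marker_ids)
    out = df.map(lambda v: missing_token if np.isnan(v) else str(int(v)))
    out.to_csv(path, sep=_sep_for(path, None))


def read_phenotypes(path, env_order: list[str] | None = None) -> PhenotypeTable:
    """Read a long-format phenotype CSV with columns line, env, value."""
    df = pd.read_csv(path, dtype={"line": str, "env": str})
    df["value"] = df["value"].astype(float)
    return PhenotypeTable(records=df[["line", "env", "value"]], envs=list(env_order or []))


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pheno.records[["line", "env", "value"]].to_csv(path, index=False)


def qc_filter(
    g: RawGenotypes,
    maf_min: float = 0.05,
    max_missing_marker: float = 0.60,
    min_called_per_line: int = 0,
) -> RawGenotypes:
    """Apply marker-level then line-level quality control.

    Markers with minor allele frequency strictly below ``maf_min`` or with a
    missing fraction strictly above ``max_missing_marker`` are removed first;
    then lines with fewer than ``min_called_per_line`` called markers (counted
    on the surviving markers) are removed.  Row/column order is preserved.
    """
    if not (0 <= maf_min <= 1) or not (0 <= max_missing_marker <= 1):
        raise ValueError("maf_min and max_missing_marker must lie in [0, 1]")
    if min_called_per_line < 0:
        raise ValueError("min_called_per_line must be >= 0")

    calls = g.calls
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-missing columns
        freq = np.nanmean(calls, axis=0) / 2.0
    all_missing = np.isnan(freq)
    freq = np.where(all_missing, 0.0, freq)
    maf = np.minimum(freq, 1.0 - freq)
    miss_frac = np.isnan(calls).mean(axis=0)
    keep_marker = (maf >= maf_min) & (miss_frac <= max_missing_marker) & ~all_missing
    n_dropped_maf = int((maf < maf_min).sum())
    n_dropped_miss = int((miss_frac > max_missing_marker).sum())
    if not keep_marker.any():
        raise ValueError("empty after QC: all markers removed")

    calls = calls[:, keep_marker]
    called_per_line = (~np.isnan(calls)).sum(axis=1)
    keep_line = called_per_line >= min_called_per_line
    if not keep_line.any():
        raise ValueError("empty after QC: all lines removed")
    logger.info(
        "QC: dropped %d markers (MAF < %g), %d markers (missing > %g), %d lines (< %d called)",
        n_dropped_maf, maf_min, n_dropped_miss, max_missing_marker,
        int((~keep_line).sum()), min_called_per_line,
    )
    return RawGenotypes(
        line_ids=[lid for lid, k in zip(g.line_ids, keep_line) if k],
        calls=calls[keep_line],
        marker_ids=[m for m, k in zip(g.marker_ids, keep_marker) if k],
    )


def impute_and_scale(g: RawGenotypes, scaling: str = "standardized") -> MarkerMatrix:
    """Mean-impute missing calls per marker, then center/standardize.

    ``scaling='raw'`` only imputes; ``'centered'`` subtracts each column mean;
    ``'standardized'`` additionally divides by the column standard deviation
    (population, ddof=0).  Constant columns are centered to zero and left
    unscaled.
    """
    X = g.calls.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        col_mean = np.nanmean(X, axis=0)
    if np.isnan(col_mean).any():
        j = int(np.flatnonzero(np.isnan(col_mean))[0])
        raise ValueError(f"marker {g.marker_ids[j]!r} is entirely missing; run qc_filter first")
    idx = np.where(np.isnan(X))
    X[idx] = np.take(col_mean, idx[1])
    if scaling in ("centered", "standardized"):
        X = X - X.mean(axis=0)
        if scaling == "standardized":
            sd = X.std(axis=0, ddof=0)
            nonconst = sd > 0
            X[:, nonconst] = X[:, nonconst] / sd[nonconst]
    elif scaling != "raw":
        raise ValueError(f"unknown scaling {scaling!r}")
    return MarkerMatrix(X=X, line_ids=list(g.line_ids), marker_ids=list(g.marker_ids), scaling=scaling)
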