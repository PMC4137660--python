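"""Trimmed-mean-of-M-values (TMM) normalization of count matrices.

TMM estimates one scaling factor per sample from doubly trimmed,
precision-weighted log ratios against a reference sample, under the
assumption that most proteins are not differentially abundant between
samples.  For sample y with library size N against reference y_r, N_r,
over proteins with positive counts in both:

    M = log2( (y/N) / (y_r/N_r) )          (log fold change)
    A = 1/2 * log2( (y/N) * (y_r/N_r) )    (mean abundance)
    v = (N - y)/(N y) + (N_r - y_r)/(N_r y_r)   (delta-method variance of M)

The upper and lower ``trim_m`` fraction by M and ``trim_a`` fraction by A are
discarded and the factor is 2**(Σ M/v / Σ 1/v) over the intersection of
survivors (precision weighting by the inverse asymptotic variance).
Factors are geometric-mean standardized to multiply to one.
Normalization is intended to be computed once for the entire data set and
reused by every downstream analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .evidence_io import CountMatrix

__all__ = ["TMMConfig", "NormalizationFactors", "tmm_factors", "apply_normalization"]


@dataclass(frozen=True)
class TMMConfig:
    trim_m: float = 0.30
    trim_a: float = 0.05
    #: "auto" picks the sample whose 75th-percentile count fraction is closest
    #: to the across-sample mean; otherwise a sample_id.
    reference_selection: str = "auto"
    standardize_geomean: bool = True

    def __post_init__(self) -> None:
        if not (0 <= self.trim_m < 0.5 and 0 <= self.trim_a < 0.5):
            raise ValueError("trim fractions must lie in [0, 0.5)")


@dataclass
class NormalizationFactors:
    """Per-sample TMM factors and library sizes (column sums)."""

    factors: pd.Series  # index: sample_id, positive floats
    library_sizes: pd.Series
    reference_sample: str = ""

    def __post_init__(self) -> None:
        if (self.factors <= 0).any():
            raise ValueError("normalization factors must be positive")

    def factor(self, sample_id: str) -> float:
        if sample_id not in self.factors.index:
            raise KeyError(f"no normalization factor for sample {sample_id!r}")
        return float(self.factors[sample_id])

    def log_effective_sizes(self) -> pd.Series:
        """log(N * factor) per sample, for use as a model offset."""
        return np.log(self.library_sizes * self.factors)


def _tmm_pair(
    y: np.ndarray, y_r: np.ndarray, N: float, N_r: float, trim_m: float, trim_a: float
) -> float:
    """TMM log2 factor of one sample against the reference."""
    ok = (y > 0) & (y_r > 0)
    y, y_r = y[ok], y_r[ok]
    if y.size == 0:
        warnings.warn("no proteins shared with the reference; factor set to 1")
        return 0.0
    M = np.log2((y / N) / (y_r / N_r))
    A = 0.5 * np.log2((y / N) * (y_r / N_r))
    w = 1.0 / ((N - y) / (N * y) + (N_r - y_r) / (N_r * y_r))  # inverse variance
    if np.max(np.abs(M)) < 1e-6:  # identical relative profiles
        return 0.0
    n = M.size
    lo_m = np.floor(n * trim_m) + 1
    hi_m = n + 1 - lo_m
    lo_a = np.floor(n * trim_a) + 1
    hi_a = n + 1 - lo_a
    rM = rankdata(M)
    rA = rankdata(A)
    keep = (rM >= lo_m) & (rM <= hi_m) & (rA >= lo_a) & (rA <= hi_a)
    if not keep.any():
        warnings.warn("no proteins survive TMM trimming; factor set to 1")
        return 0.0
    f = float(np.sum(w[keep] * M[keep]) / np.sum(w[keep]))
    return 0.0 if not np.isfinite(f) else f


def tmm_factors(matrix: CountMatrix, cfg: TMMConfig | None = None) -> NormalizationFactors:
    """Compute TMM normalization factors for every sample of a count matrix."""
    cfg = cfg or TMMConfig()
    values = matrix.values
    sample_ids = matrix.sample_ids
    if len(sample_ids) < 2:
        raise ValueError("TMM needs at least 2 samples")
    lib = values.sum(axis=0)
    if (lib <= 0).any():
        bad = [s for s, n in zip(sample_ids, lib) if n <= 0]
        raise ValueError(f"sample(s) with non-positive library size: {bad}")

    if cfg.reference_selection == "auto":
        f75 = np.array(
            [np.quantile(values[:, k], 0.75) / lib[k] for k in range(len(sample_ids))]
        )
        ref_idx = int(np.argmin(np.abs(f75 - f75.mean())))
    else:
        if cfg.reference_selection not in sample_ids:
            raise KeyError(f"reference sample {cfg.reference_selection!r} not in matrix")
        ref_idx = sample_ids.index(cfg.reference_selection)

    log2f = np.array(
        [
            0.0
            if k == ref_idx
            else _tmm_pair(
                values[:, k], values[:, ref_idx], lib[k], lib[ref_idx], cfg.trim_m, cfg.trim_a
            )
            for k in range(len(sample_ids))
        ]
    )
    factors = 2.0 ** log2f
    if cfg.standardize_geomean:
        factors = factors / np.exp(np.mean(np.log(factors)))
    return NormalizationFactors(
        factors=pd.Series(factors, index=sample_ids),
        library_sizes=pd.Series(lib, index=sample_ids),
        reference_sample=sample_ids[ref_idx],
    )


def apply_normalization(
    matrix: CountMatrix,
    factors: NormalizationFactors,
    mode: str = "divide",
    effective_library_size: bool = False,
) -> CountMatrix | pd.Series:
    """Apply TMM factors to a count matrix.

    ``divide`` returns counts divided per column by the factor (optionally by
    factor × relative library size when ``effective_library_size``);
    ``offset`` returns the per-sample log effective sizes for use as a model
    offset, leaving counts untouched.
    """
    for s in matrix.sample_ids:
        factors.factor(s)  # raises on missing sample
    if mode == "offset":
        return factors.log_effective_sizes()[matrix.sample_ids]
    if mode != "divide":
        raise ValueError(f"unknown normalization mode: {mode}")
    div = factors.factors[matrix.sample_ids]
    if effective_library_size:
        lib = factors.library_sizes[matrix.sample_ids]
        div = div * lib / np.exp(np.mean(np.log(lib)))
    return CountMatrix(matrix.frame / div)
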