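"""Pairwise differential abundance and distinguishability of hair profiles.

For each quantifiable protein, a count model is fitted across samples and
all pairwise contrasts of one metadata factor (subject, ethnic group, body
site, or total-hair vs cuticle fraction) are tested.  The per-pair counts of
significantly different proteins form a symmetric *distinguishability
matrix* — the number of proteins separating each pair of subjects / groups /
sites — which doubles as a relatedness distance for complete-linkage
hierarchical clustering (more shared profile ⇒ fewer differing proteins ⇒
closer).

Model-to-comparison mapping mirrors the profiling study design:

=========================  ==================  =========================
comparison                 factor              model / multiplicity
=========================  ==================  =========================
subjects within ethnicity  subject             od_glm (subject fixed), none
between ethnic groups      group               od_glmm, none
body sites                 site                od_glmm + Tukey HSD
total hair vs cuticle      fraction            lognormal_poisson, none
=========================  ==================  =========================
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .evidence_io import CountMatrix, SampleTable, ValidationError
from .models import (
    FitError,
    fit_lognormal_poisson_glmm,
    fit_od_poisson_glm,
    fit_od_poisson_glmm,
    make_design,
    pairwise_contrasts,
    tukey_adjust,
)

__all__ = [
    "ComparisonConfig",
    "DifferentialResults",
    "DistinguishabilityMatrix",
    "select_quantifiable_proteins",
    "pairwise_differential",
    "distinguishability_matrix",
    "cluster_relatedness",
    "linkage_to_newick",
]


@dataclass(frozen=True)
class ComparisonConfig:
    """How one pairwise analysis is run.

    ``factor`` is the compared metadata column; ``covariates`` are additional
    fixed-effect adjustments (e.g. ethnicity when comparing fractions across
    donors).  ``multiplicity`` adjusts within a protein's pairwise family:
    ``tukey`` (studentized range), ``none``, or ``bh``
    (Benjamini–Hochberg across the whole protein × pair table).
    """

    factor: str
    model: str = "od_glm"
    alpha: float = 0.05
    multiplicity: str = "none"
    covariates: tuple[str, ...] = ()
    min_mean: float = 5.0
    min_nonzero_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")
        if self.model not in {"od_glm", "od_glmm", "lognormal_poisson"}:
            raise ValueError(f"unknown model: {self.model}")
        if self.multiplicity not in {"tukey", "none", "bh"}:
            raise ValueError(f"unknown multiplicity rule: {self.multiplicity}")


@dataclass
class DifferentialResults:
    """Per-protein, per-pair contrast table plus fit failures."""

    factor: str
    levels: list[str]
    table: pd.DataFrame  # protein, level_a, level_b, estimate, se, statistic,
    #                      p_raw, p_adjusted, ci_low, ci_high
    failed: list[tuple[str, str]] = field(default_factory=list)
    alpha: float = 0.05

    @property
    def proteins(self) -> list[str]:
        return list(dict.fromkeys(self.table["protein"]))

    def pairs(self) -> list[tuple[str, str]]:
        return list(combinations(self.levels, 2))


@dataclass
class DistinguishabilityMatrix:
    """Symmetric entity × entity counts of significantly different proteins."""

    frame: pd.DataFrame  # square, integer, zero diagonal
    alpha: float = 0.05
    n_proteins_tested: int = 0

    def __post_init__(self) -> None:
        values = self.frame.to_numpy()
        if values.shape[0] != values.shape[1] or not np.array_equal(values, values.T):
            raise ValidationError("distinguishability matrix must be symmetric")
        if np.any(np.diag(values) != 0):
            raise ValidationError("distinguishability matrix must have a zero diagonal")
        if (values < 0).any():
            raise ValidationError("distinguishability counts must be non-negative")

    @property
    def entity_ids(self) -> list[str]:
        return list(self.frame.index)


def select_quantifiable_proteins(
    matrix: CountMatrix,
    min_mean: float = 5.0,
    min_nonzero_fraction: float = 0.5,
) -> tuple[CountMatrix, dict]:
    """Retain proteins "present in sufficient amounts".

    Default rule: mean weighted count >= ``min_mean`` across samples and a
    nonzero count in at least ``min_nonzero_fraction`` of samples.  Returns
    the subset and a census dict.
    """
    values = matrix.values
    means = values.mean(axis=1)
    nonzero = (values > 0).mean(axis=1)
    keep = (means >= min_mean) & (nonzero >= min_nonzero_fraction)
    kept_ids = [p for p, k in zip(matrix.protein_ids, keep) if k]
    census = {
        "n_input": len(matrix.protein_ids),
        "n_retained": len(kept_ids),
        "min_mean": min_mean,
        "min_nonzero_fraction": min_nonzero_fraction,
    }
    if not kept_ids:
        raise ValidationError(
            "no protein passes the presence rule; relax min_mean/min_nonzero_fraction"
        )
    return matrix.subset_proteins(kept_ids), census


_FITTERS = {
    "od_glm": fit_od_poisson_glm,
    "od_glmm": fit_od_poisson_glmm,
    "lognormal_poisson": fit_lognormal_poisson_glmm,
}


def pairwise_differential(
    matrix: CountMatrix,
    metadata: SampleTable,
    cfg: ComparisonConfig,
    offset: pd.Series | None = None,
    select: bool = True,
) -> DifferentialResults:
    """Fit the configured model per protein and test all factor-level pairs.

    Levels represented by a single sample cannot support the within-level
    replication the models need and are excluded with a warning.  Failed
    per-protein fits are recorded in ``results.failed``, not raised.
    """
    sample_ids = [s for s in matrix.sample_ids]
    metadata.require_samples(sample_ids)
    labels = metadata.column(cfg.factor).loc[sample_ids]
    counts_per_level = labels.value_counts()
    usable_levels = sorted(counts_per_level[counts_per_level >= 2].index)
    dropped = sorted(set(labels.unique()) - set(usable_levels))
    if dropped:
        warnings.warn(f"excluding single-sample level(s) of {cfg.factor!r}: {dropped}")
    if len(usable_levels) < 2:
        raise FitError(f"factor {cfg.factor!r} has fewer than 2 usable levels")
    use = [s for s in sample_ids if labels[s] in usable_levels]
    matrix = matrix.subset_samples(use)
    if select:
        matrix, _ = select_quantifiable_proteins(matrix, cfg.min_mean, cfg.min_nonzero_fraction)

    fixed = [cfg.factor, *cfg.covariates]
    random_subject = cfg.model in {"od_glmm", "lognormal_poisson"}
    design = make_design(
        metadata,
        use,
        fixed=fixed,
        random_subject=random_subject,
        offset=offset.loc[use] if offset is not None else None,
    )
    fitter = _FITTERS[cfg.model]
    k = len(usable_levels)

    rows = []
    failed: list[tuple[str, str]] = []
    for protein in matrix.protein_ids:
        y = matrix.frame.loc[protein].to_numpy(dtype=float)
        try:
            fit = fitter(y, design)
            contrasts = pairwise_contrasts(fit, cfg.factor)
            if cfg.multiplicity == "tukey":
                contrasts = tukey_adjust(contrasts, k=k)
            else:
                contrasts = [c for c in contrasts]
                for c in contrasts:
                    c.p_adjusted = c.p_raw
        except (FitError, np.linalg.LinAlgError, ValueError) as exc:
            failed.append((protein, str(exc)))
            continue
        for (a, b), c in zip(combinations(usable_levels, 2), contrasts):
            rows.append(
                {
                    "protein": protein,
                    "level_a": a,
                    "level_b": b,
                    "estimate": c.estimate,
                    "se": c.se,
                    "statistic": c.statistic,
                    "p_raw": c.p_raw,
                    "p_adjusted": c.p_adjusted,
                    "ci_low": c.ci_low,
                    "ci_high": c.ci_high,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "protein",
            "level_a",
            "level_b",
            "estimate",
            "se",
            "statistic",
            "p_raw",
            "p_adjusted",
            "ci_low",
            "ci_high",
        ],
    )
    if cfg.multiplicity == "bh" and len(table):
        table["p_adjusted"] = _benjamini_hochberg(table["p_raw"].to_numpy())
    return DifferentialResults(
        factor=cfg.factor, levels=usable_levels, table=table, failed=failed, alpha=cfg.alpha
    )


def _benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    order = np.argsort(p)
    m = len(p)
    adj = np.empty(m)
    prev = 1.0
    for rank_from_end, idx in enumerate(order[::-1]):
        rank = m - rank_from_end
        prev = min(prev, p[idx] * m / rank)
        adj[idx] = prev
    return adj


def distinguishability_matrix(
    results: DifferentialResults, alpha: float | None = None
) -> DistinguishabilityMatrix:
    """Count, per level pair, the proteins with adjusted p below alpha."""
    alpha = results.alpha if alpha is None else alpha
    levels = results.levels
    frame = pd.DataFrame(0, index=levels, columns=levels, dtype=int)
    if len(results.table):
        sig = results.table[results.table["p_adjusted"] < alpha]
        for (a, b), group in sig.groupby(["level_a", "level_b"], observed=True):
            frame.loc[a, b] += len(group)
            frame.loc[b, a] += len(group)
    return DistinguishabilityMatrix(
        frame=frame, alpha=alpha, n_proteins_tested=len(results.proteins)
    )


def cluster_relatedness(matrix: DistinguishabilityMatrix) -> tuple[np.ndarray, str]:
    """Complete-linkage clustering treating the counts directly as distances.

    Two entities separated by few significantly different proteins are
    "related" and merge early.  Returns the SciPy linkage matrix and a Newick
    string with merge heights as node depths.
    """
    frame = matrix.frame
    if len(frame) < 2:
        raise ValidationError("need at least 2 entities to cluster")
    condensed = squareform(frame.to_numpy(dtype=float), checks=True)
    Z = hierarchy.linkage(condensed, method="complete")
    newick = linkage_to_newick(Z, list(frame.index))
    return Z, newick


def linkage_to_newick(Z: np.ndarray, labels: Sequence[str]) -> str:
    """Serialize a SciPy linkage matrix to Newick with branch lengths."""
    tree = hierarchy.to_tree(Z)

    def render(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{labels[node.id]}:{length:g}"
        left = render(node.left, node.dist)
        right = render(node.right, node.dist)
        return f"({left},{right}):{length:g}"

    return render(tree, tree.dist) + ";"
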