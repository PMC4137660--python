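"""End-to-end orchestration: quantify → normalize (once) → compare → cluster.

A single YAML/ dict run configuration drives the four profiling analyses
(subjects within ethnicity, between ethnic groups, body sites, total hair vs
cuticle).  TMM normalization is computed once for the entire data set and
reused by every analysis that asks for normalized counts.  Each run writes a
JSON manifest recording the package version, a hash of the effective
configuration (defaults included), the seed, and per-stage censuses, so a
run is auditable and reproducible.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .compare import (
    ComparisonConfig,
    cluster_relatedness,
    distinguishability_matrix,
    pairwise_differential,
)
from .evidence_io import (
    read_count_matrix,
    read_evidence,
    read_sample_metadata,
    write_count_matrix,
)
from .normalize import TMMConfig, apply_normalization, tmm_factors
from .quantify import FilterConfig, quantify_evidence

__all__ = ["AnalysisSpec", "RunConfig", "run_pipeline", "load_run_config"]


@dataclass(frozen=True)
class AnalysisSpec:
    """One named pairwise analysis of the run."""

    name: str
    factor: str
    model: str = "od_glm"
    alpha: float = 0.05
    multiplicity: str = "none"
    covariates: tuple[str, ...] = ()
    #: fit on TMM-divided counts (the low-abundance-protein route)
    normalized: bool = False
    #: include log effective library size (TMM factor × column sum) as a
    #: model offset; corrects for per-sample depth differences
    offset: bool = False
    min_mean: float = 5.0
    min_nonzero_fraction: float = 0.5
    #: restrict to samples whose metadata column equals a value, e.g. {"group": "CA"}
    subset: tuple[tuple[str, str], ...] = ()

    def comparison_config(self) -> ComparisonConfig:
        return ComparisonConfig(
            factor=self.factor,
            model=self.model,
            alpha=self.alpha,
            multiplicity=self.multiplicity,
            covariates=self.covariates,
            min_mean=self.min_mean,
            min_nonzero_fraction=self.min_nonzero_fraction,
        )


@dataclass
class RunConfig:
    """Inputs, thresholds and the list of analyses for one pipeline run."""

    metadata: str
    evidence: str | None = None
    counts: str | None = None
    out_dir: str = "folliprof_run"
    seed: int = 0
    filter: FilterConfig = field(default_factory=FilterConfig)
    tmm: TMMConfig = field(default_factory=TMMConfig)
    analyses: tuple[AnalysisSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.evidence is None and self.counts is None:
            raise ValueError("config needs an evidence table or a count matrix")

    def config_hash(self) -> str:
        payload = {
            "metadata": self.metadata,
            "evidence": self.evidence,
            "counts": self.counts,
            "seed": self.seed,
            "filter": asdict(self.filter),
            "tmm": asdict(self.tmm),
            "analyses": [asdict(a) for a in self.analyses],
        }
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def load_run_config(path: str | Path) -> RunConfig:
    """Load a RunConfig from YAML; unknown keys are rejected."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    analyses = tuple(
        AnalysisSpec(
            **{
                **a,
                "covariates": tuple(a.get("covariates", ())),
                "subset": tuple((k, str(v)) for k, v in (a.get("subset") or {}).items()),
            }
        )
        for a in raw.pop("analyses", [])
    )
    filt = FilterConfig(**raw.pop("filter", {}))
    tmm = TMMConfig(**raw.pop("tmm", {}))
    return RunConfig(analyses=analyses, filter=filt, tmm=tmm, **raw)


def _preflight(cfg: RunConfig, metadata) -> None:
    for a in cfg.analyses:
        for col in (a.factor, *a.covariates, *(k for k, _ in a.subset)):
            metadata.column(col)  # raises KeyError on unknown column


def run_pipeline(cfg: RunConfig, force: bool = False) -> dict:
    """Execute every stage and return (and write) the run manifest.

    A completed run directory (one holding a manifest) is never silently
    overwritten; pass ``force`` to redo it.  A stage failure writes a FAILED
    marker naming the stage and re-raises, keeping partial outputs.
    """
    out = Path(cfg.out_dir)
    manifest_path = out / "manifest.json"
    if manifest_path.exists() and not force:
        raise FileExistsError(f"{out} already holds a completed run (use force)")
    out.mkdir(parents=True, exist_ok=True)

    manifest: dict = {
        "version": __version__,
        "config_hash": cfg.config_hash(),
        "seed": cfg.seed,
        "defaults": {"filter": asdict(cfg.filter), "tmm": asdict(cfg.tmm)},
        "stages": {},
        "analyses": {},
    }
    stage = "load"
    try:
        metadata = read_sample_metadata(cfg.metadata)
        _preflight(cfg, metadata)

        stage = "quantify"
        if cfg.evidence is not None:
            evidence = read_evidence(cfg.evidence)
            matrix, groups, report = quantify_evidence(evidence, metadata, cfg.filter)
            write_count_matrix(matrix, out / "counts.tsv")
            manifest["stages"]["quantify"] = report.to_dict()
        else:
            matrix = read_count_matrix(cfg.counts)
            manifest["stages"]["quantify"] = {"skipped": "precomputed counts supplied"}
        manifest["stages"]["counts"] = {
            "n_proteins": len(matrix.protein_ids),
            "n_samples": len(matrix.sample_ids),
        }

        stage = "normalize"  # computed once for the entire data set
        factors = tmm_factors(matrix, cfg.tmm)
        factors.factors.rename("tmm_factor").to_frame().assign(
            library_size=factors.library_sizes
        ).to_csv(out / "factors.tsv", sep="\t")
        normalized = apply_normalization(matrix, factors, mode="divide")
        write_count_matrix(normalized, out / "normalized_counts.tsv")
        manifest["stages"]["normalize"] = {
            "reference_sample": factors.reference_sample,
            "factors_range": [float(factors.factors.min()), float(factors.factors.max())],
        }

        for analysis in cfg.analyses:
            stage = f"compare:{analysis.name}"
            source = normalized if analysis.normalized else matrix
            use = source
            meta_frame = metadata.frame
            keep = pd.Series(True, index=meta_frame.index)
            for col, value in analysis.subset:
                keep &= metadata.column(col) == value
            sample_subset = [s for s in source.sample_ids if keep.get(s, False)]
            use = source.subset_samples(sample_subset)
            offset = factors.log_effective_sizes() if analysis.offset else None
            results = pairwise_differential(
                use, metadata, analysis.comparison_config(), offset=offset
            )
            dmat = distinguishability_matrix(results)
            results.table.to_csv(out / f"results_{analysis.name}.tsv", sep="\t", index=False)
            dmat.frame.to_csv(out / f"distinguishability_{analysis.name}.tsv", sep="\t")
            entry = {
                "factor": analysis.factor,
                "model": analysis.model,
                "alpha": analysis.alpha,
                "n_proteins_tested": dmat.n_proteins_tested,
                "n_failed_fits": len(results.failed),
                "n_significant": int((results.table["p_adjusted"] < analysis.alpha).sum()),
            }
            if len(dmat.frame) >= 2:
                _, newick = cluster_relatedness(dmat)
                (out / f"dendrogram_{analysis.name}.nwk").write_text(newick + "\n")
                entry["dendrogram"] = f"dendrogram_{analysis.name}.nwk"
            manifest["analyses"][analysis.name] = entry

        stage = "manifest"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    except Exception as exc:
        (out / "FAILED").write_text(f"stage {stage}: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
    failed_marker = out / "FAILED"
    if failed_marker.exists():
        failed_marker.unlink()
    return manifest
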