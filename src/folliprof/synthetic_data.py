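"""Synthetic hair-shaft cohorts with known ground truth.

The generator emulates the statistical structure of a multi-subject hair
proteomics study so every pipeline stage is testable without the original
mass-spectrometry deposit: a cohort of subjects in ethnicity-like groups
with triplicate samples, ~90 quantifiable proteins whose baseline
abundances span about two orders of magnitude, protein-specific subject
random effects, extra-Poisson (lognormal) observation noise, keratin-like
families sharing tryptic peptides, and planted group/site/fraction/subject
effects.

The count layer draws, for protein j in sample k of subject s,

    y_jk ~ Poisson( depth_k · λ_j · exp(u_js + δ_j(k) + ε_jk) )

with u_js ~ N(0, σ_subject²), ε_jk ~ N(0, σ_obs²) and δ the planted
log-fold-changes.  The lognormal ε makes the marginal dispersion
φ ≈ 1 + μ·(e^{σ_obs²} − 1), so the generator matches the lognormal-Poisson
model class; a gamma-mixing alternative with the same variance is available
to probe robustness to misspecification.

The evidence layer explodes each protein's count into peptide-spectrum
matches assigned multinomially to the protein's peptides.  Within a family
block, a fraction ρ of each member's peptides comes from a pool shared by
the family, so weighted-count distribution has real work to do.  Decoy PSMs
are injected at a configurable rate with uniform probabilities so the
acceptance filters and FDR estimates are exercised.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .evidence_io import CountMatrix, EvidenceRecord, EvidenceSet, SampleTable

__all__ = ["PlantedEffect", "SyntheticConfig", "GroundTruth", "simulate_count_matrix", "simulate_cohort"]

GROUP_LABELS = ("CA", "AA", "KE", "KO")
SCALP_REPLICATES = ("left", "center", "right")


@dataclass(frozen=True)
class PlantedEffect:
    """A log-fold-change planted on one protein between two factor levels.

    Samples at ``level_a`` of ``factor`` get ``log_fc`` added to the linear
    predictor of ``protein``; ``level_b`` is the unchanged comparator.
    """

    protein: str
    factor: str  # subject | group | site | fraction
    level_a: str
    level_b: str
    log_fc: float


@dataclass(frozen=True)
class SyntheticConfig:
    """Study conditions for a synthetic cohort.

    Defaults mirror a realistic profiling study: 4 ethnic-like groups of 5
    subjects with scalp triplicates, 90 proteins spanning ~2 decades of
    abundance, subject SD 0.3 on the log scale, observation SD 0.17 (φ ≈ 2
    at the typical count of ~35), sample depth 3000 spectra with 20% CV.
    """

    n_groups: int = 4
    subjects_per_group: int = 5
    replicates_per_subject: int = 3
    site_levels: tuple[str, ...] = ("scalp",)
    fraction_levels: tuple[str, ...] = ("total",)
    n_proteins: int = 90
    n_family_blocks: int = 6
    block_size: int = 3
    shared_peptide_fraction: float = 0.3
    peptides_per_protein: tuple[int, int] = (4, 12)
    baseline_log10_sd: float = 0.5
    sigma_subject: float = 0.3
    sigma_obs: float = 0.17
    obs_noise: str = "lognormal"  # or "gamma" (same variance, misspecified shape)
    depth: float = 3000.0
    depth_cv: float = 0.2
    planted_effects: tuple[PlantedEffect, ...] = ()
    #: subject pairs forced to share identical true profiles (null pairs)
    identical_subject_pairs: tuple[tuple[str, str], ...] = ()
    #: families of subjects sharing a block effect (relatedness structure)
    subject_blocks: tuple[tuple[str, ...], ...] = ()
    sigma_block: float = 0.0
    prob_beta_a: float = 40.0
    prob_beta_b: float = 1.0
    min_peptide_probability: float = 0.9
    decoy_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.sigma_subject, self.sigma_obs, self.sigma_block) < 0:
            raise ValueError("variance components must be non-negative")
        if not (0 <= self.shared_peptide_fraction < 1):
            raise ValueError("shared_peptide_fraction must be in [0, 1)")
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if self.peptides_per_protein[0] < 2:
            raise ValueError("proteins need at least 2 peptides to pass acceptance filters")

    def implied_dispersion(self, mean_count: float | None = None) -> float:
        """Marginal quasi-Poisson dispersion at a given mean count."""
        mu = mean_count if mean_count is not None else self.depth / self.n_proteins
        return 1.0 + mu * (np.exp(self.sigma_obs**2) - 1.0)


@dataclass
class GroundTruth:
    """Everything the generator knows that the pipeline must recover."""

    baseline: pd.Series  # per-protein relative abundance λ
    subject_effects: pd.DataFrame  # protein × subject, log scale
    depths: pd.Series  # per-sample realized expected depth
    planted: tuple[PlantedEffect, ...]
    latent_counts: pd.DataFrame | None = None  # protein × sample Poisson draws

    @property
    def de_proteins(self) -> set[str]:
        return {e.protein for e in self.planted}


def _group_names(n: int) -> list[str]:
    if n <= len(GROUP_LABELS):
        return list(GROUP_LABELS[:n])
    return [f"G{i + 1}" for i in range(n)]


def _protein_ids(cfg: SyntheticConfig) -> list[str]:
    """Family-block members get keratin-family-style ids, the rest plain ids."""
    ids = []
    n_family = min(cfg.n_family_blocks * cfg.block_size, cfg.n_proteins)
    for j in range(cfg.n_proteins):
        if j < n_family:
            ids.append(f"KFAM{j // cfg.block_size + 1}_{j % cfg.block_size + 1}")
        else:
            ids.append(f"P{j + 1:03d}")
    return ids


def _build_metadata(cfg: SyntheticConfig) -> SampleTable:
    rows = []
    groups = _group_names(cfg.n_groups)
    for gi, grp in enumerate(groups):
        for si in range(cfg.subjects_per_group):
            subject = f"{grp}{si + 1}"
            for site in cfg.site_levels:
                for fraction in cfg.fraction_levels:
                    for r in range(cfg.replicates_per_subject):
                        rep = (
                            SCALP_REPLICATES[r % 3]
                            if site == "scalp" and cfg.replicates_per_subject <= 3
                            else f"r{r + 1}"
                        )
                        rows.append(
                            {
                                "sample_id": f"{subject}_{site[:2]}_{fraction[:3]}_{r + 1}",
                                "subject_id": subject,
                                "group": grp,
                                "site": site,
                                "fraction": fraction,
                                "replicate": rep,
                            }
                        )
    frame = pd.DataFrame(rows).set_index("sample_id")
    return SampleTable(frame)


def simulate_count_matrix(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[CountMatrix, SampleTable, GroundTruth]:
    """Draw the latent protein × sample count layer with ground truth."""
    rng = rng or np.random.default_rng(cfg.seed)
    metadata = _build_metadata(cfg)
    proteins = _protein_ids(cfg)
    samples = metadata.sample_ids
    subjects = sorted(set(metadata.frame["subject_id"]))
    n_p, n_s = len(proteins), len(samples)

    # baseline relative abundances spanning ~2·baseline_log10_sd decades (95%)
    lam = 10.0 ** rng.normal(0.0, cfg.baseline_log10_sd, size=n_p)
    lam = lam / lam.sum()
    baseline = pd.Series(lam, index=proteins)

    u = rng.normal(0.0, cfg.sigma_subject, size=(n_p, len(subjects)))
    subject_effects = pd.DataFrame(u, index=proteins, columns=subjects)
    if cfg.sigma_block:
        for block in cfg.subject_blocks:
            b = rng.normal(0.0, cfg.sigma_block, size=n_p)
            for s in block:
                subject_effects[s] = subject_effects[s] + b
    for a, b in cfg.identical_subject_pairs:
        subject_effects[b] = subject_effects[a]

    s_depth = np.sqrt(np.log1p(cfg.depth_cv**2))
    depths = cfg.depth * np.exp(rng.normal(0.0, s_depth, size=n_s) - s_depth**2 / 2)
    depth_series = pd.Series(depths, index=samples)

    delta = np.zeros((n_p, n_s))
    meta = metadata.frame
    for eff in cfg.planted_effects:
        if eff.protein not in baseline.index:
            raise ValueError(f"planted effect on unknown protein {eff.protein!r}")
        j = proteins.index(eff.protein)
        col = "subject_id" if eff.factor == "subject" else eff.factor
        mask = (meta[col].astype(str) == eff.level_a).to_numpy()
        delta[j, mask] += eff.log_fc

    log_mu = (
        np.log(lam)[:, None]
        + np.log(depths)[None, :]
        + subject_effects[meta["subject_id"]].to_numpy()
        + delta
    )
    if cfg.sigma_obs > 0:
        if cfg.obs_noise == "lognormal":
            eps = rng.normal(-cfg.sigma_obs**2 / 2, cfg.sigma_obs, size=(n_p, n_s))
            mu = np.exp(log_mu + eps)
        elif cfg.obs_noise == "gamma":
            v = np.exp(cfg.sigma_obs**2) - 1.0  # match lognormal variance
            shape = 1.0 / v
            mu = np.exp(log_mu) * rng.gamma(shape, v, size=(n_p, n_s))
        else:
            raise ValueError(f"unknown obs_noise: {cfg.obs_noise}")
    else:
        mu = np.exp(log_mu)
    y = rng.poisson(mu).astype(float)

    matrix = CountMatrix(pd.DataFrame(y, index=proteins, columns=samples))
    truth = GroundTruth(
        baseline=baseline,
        subject_effects=subject_effects,
        depths=depth_series,
        planted=cfg.planted_effects,
        latent_counts=matrix.frame.copy(),
    )
    return matrix, metadata, truth


def _build_peptide_map(cfg: SyntheticConfig, proteins: list[str], rng: np.random.Generator):
    """Assign each protein its peptide keys; family members share a pool."""
    peptides_of: dict[str, list[str]] = {}
    counter = 0
    n_family = min(cfg.n_family_blocks * cfg.block_size, cfg.n_proteins)
    lo, hi = cfg.peptides_per_protein
    block_pools: dict[int, list[str]] = {}
    for j, prot in enumerate(proteins):
        n_pep = int(rng.integers(lo, hi + 1))
        n_shared = 0
        shared: list[str] = []
        if j < n_family and cfg.shared_peptide_fraction > 0:
            block = j // cfg.block_size
            pool = block_pools.setdefault(block, [])
            n_shared = int(round(cfg.shared_peptide_fraction * n_pep))
            n_shared = min(n_shared, n_pep - 2)  # keep >=2 private ⇒ unique peptides survive
            n_shared = max(n_shared, 0)
            while len(pool) < n_shared:
                pool.append(f"sh{block + 1}_{len(pool) + 1}")
            shared = list(rng.choice(pool, size=n_shared, replace=False)) if n_shared else []
        private = [f"pep{counter + i + 1}" for i in range(n_pep - n_shared)]
        counter += n_pep - n_shared
        peptides_of[prot] = shared + private
    return peptides_of


def _peptide_probabilities(n: int, cfg: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Beta(a, b) draws truncated above the acceptance threshold."""
    out = rng.beta(cfg.prob_beta_a, cfg.prob_beta_b, size=n)
    bad = out <= cfg.min_peptide_probability
    while bad.any():
        out[bad] = rng.beta(cfg.prob_beta_a, cfg.prob_beta_b, size=int(bad.sum()))
        bad = out <= cfg.min_peptide_probability
    return out


def simulate_cohort(
    cfg: SyntheticConfig, rng: np.random.Generator | None = None
) -> tuple[EvidenceSet, SampleTable, GroundTruth]:
    """Draw the count layer, then explode counts into PSM-level evidence.

    Per-sample target spectra equal the summed latent counts exactly; decoy
    records are extra.  With no peptide sharing, quantification recovers the
    latent counts of every retained protein exactly.
    """
    rng = rng or np.random.default_rng(cfg.seed)
    matrix, metadata, truth = simulate_count_matrix(cfg, rng)
    proteins = matrix.protein_ids
    peptides_of = _build_peptide_map(cfg, proteins, rng)
    accessions_of_peptide: dict[str, list[str]] = {}
    for prot, peps in peptides_of.items():
        for pep in peps:
            accessions_of_peptide.setdefault(pep, []).append(prot)

    records: list[EvidenceRecord] = []
    counts = matrix.frame
    for sample in matrix.sample_ids:
        spec_no = 0
        col = counts[sample]
        for prot in proteins:
            y = int(col[prot])
            if y == 0:
                continue
            peps = peptides_of[prot]
            pick = rng.integers(0, len(peps), size=y)
            probs = _peptide_probabilities(y, cfg, rng)
            for idx, prob in zip(pick, probs):
                pep = peps[idx]
                spec_no += 1
                records.append(
                    EvidenceRecord(
                        sample_id=sample,
                        spectrum_id=f"sp{spec_no:06d}",
                        peptide=pep,
                        peptide_probability=float(prob),
                        proteins=frozenset(accessions_of_peptide[pep]),
                        is_decoy=False,
                    )
                )
        n_decoy = rng.poisson(cfg.decoy_rate * max(spec_no, 1))
        for d in range(n_decoy):
            j = int(rng.integers(0, len(proteins)))
            records.append(
                EvidenceRecord(
                    sample_id=sample,
                    spectrum_id=f"dec{d + 1:04d}",
                    peptide=f"dpep{rng.integers(1, 10_000)}",
                    peptide_probability=float(rng.uniform(0.0, 1.0)),
                    proteins=frozenset({f"REV_{proteins[j]}"}),
                    is_decoy=True,
                )
            )
    return EvidenceSet(records), metadata, truth
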