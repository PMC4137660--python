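"""Experiment-wide protein grouping and shared-peptide weighted spectral counting.

Shotgun identification of hair-shaft proteins is dominated by keratins and
keratin-associated proteins, families whose members share many tryptic
peptides.  A naive spectral count would therefore double-count shared
spectra.  The distributed ("weighted") spectral count instead apportions each
spectrum of a shared peptide among the protein groups containing it,
proportionally to each group's summed peptide probabilities (PPS):

    share(peptide i → group j) = PPS(j) / Σ_{k ∈ n(i)} PPS(k)

where n(i) is the set of groups containing peptide i and PPS(j) is the sum of
peptide probabilities over group j's distinct accepted peptides.  A group's
weighted count in a sample is the sum of its shares over that sample's
accepted spectra, so per-sample totals are conserved.

Grouping is experiment-wide: evidence from every sample is pooled before
accessions with identical accepted-peptide sets are collapsed into groups.
Acceptance filtering follows the standard probability-based workflow:
peptides above a probability threshold (default >0.90, strict), protein
groups above a protein-probability threshold (default >0.99) with at least
two peptides and at least one unique peptide.  Decoy matches from a
reversed-sequence database estimate the false discovery rate.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .evidence_io import CountMatrix, EvidenceSet, SampleTable, ValidationError

__all__ = [
    "FilterConfig",
    "ProteinGroup",
    "QuantifyReport",
    "filter_peptides",
    "build_protein_groups",
    "filter_groups",
    "compute_pps",
    "distribute_counts",
    "decoy_fdr",
    "quantify_evidence",
]


@dataclass(frozen=True)
class FilterConfig:
    """Acceptance thresholds for peptides and protein groups.

    Probability thresholds are strict (">"): a peptide at exactly the
    threshold is rejected.
    """

    min_peptide_probability: float = 0.90
    min_protein_probability: float = 0.99
    min_peptides: int = 2
    require_unique_peptide: bool = True
    #: "distinct": each peptide contributes its best probability once (default);
    #: "per_spectrum": every accepted spectrum's probability is summed.
    pps_mode: str = "distinct"

    def __post_init__(self) -> None:
        for name in ("min_peptide_probability", "min_protein_probability"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.min_peptides < 1:
            raise ValueError("min_peptides must be >= 1")
        if self.pps_mode not in {"distinct", "per_spectrum"}:
            raise ValueError(f"unknown pps_mode: {self.pps_mode}")


@dataclass
class ProteinGroup:
    """Protein accessions indistinguishable by their accepted peptide set."""

    group_id: str
    member_accessions: frozenset[str]
    peptide_keys: frozenset[str]
    unique_peptide_keys: frozenset[str] = frozenset()
    pps: float = 0.0
    protein_probability: float = 1.0
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not self.unique_peptide_keys <= self.peptide_keys:
            raise ValueError("unique peptides must be a subset of the peptide set")


@dataclass
class QuantifyReport:
    """Census of a quantification run: what was kept, dropped and estimated."""

    n_spectra_input: int = 0
    n_spectra_accepted: int = 0
    n_spectra_assigned: int = 0
    n_spectra_unmapped: int = 0
    n_groups_built: int = 0
    n_groups_retained: int = 0
    peptide_fdr: float | None = None
    group_fdr: float | None = None

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def filter_peptides(evidence: EvidenceSet, cfg: FilterConfig | None = None) -> EvidenceSet:
    """Keep PSMs with probability strictly above the threshold.

    Decoy records passing the threshold are retained (still flagged) so the
    decoy FDR can be computed on the accepted set.
    """
    cfg = cfg or FilterConfig()
    thr = cfg.min_peptide_probability
    return EvidenceSet([r for r in evidence if r.peptide_probability > thr])


def build_protein_groups(
    evidence: EvidenceSet,
    protein_probabilities: Mapping[str, float] | None = None,
) -> list[ProteinGroup]:
    """Collapse accessions with identical accepted-peptide sets into groups.

    Evidence must be pooled across all samples (experiment-wide grouping).
    Group ids and ordering are deterministic: groups are sorted by their
    lexicographically smallest member accession, which also names the group.
    ``protein_probabilities`` supplies the upstream per-accession protein
    probability; a group takes the maximum over its members (default 1.0).
    """
    peptides_of: dict[str, set[str]] = {}
    decoy_accession: dict[str, bool] = {}
    for rec in evidence:
        for acc in rec.proteins:
            peptides_of.setdefault(acc, set()).add(rec.peptide)
            decoy_accession[acc] = decoy_accession.get(acc, True) and rec.is_decoy

    by_pepset: dict[frozenset[str], set[str]] = {}
    for acc, peps in peptides_of.items():
        by_pepset.setdefault(frozenset(peps), set()).add(acc)

    groups = [
        ProteinGroup(
            group_id=min(accs),
            member_accessions=frozenset(accs),
            peptide_keys=pepset,
            protein_probability=(
                max(protein_probabilities.get(a, 1.0) for a in accs)
                if protein_probabilities
                else 1.0
            ),
            is_decoy=all(decoy_accession[a] for a in accs),
        )
        for pepset, accs in by_pepset.items()
    ]
    groups.sort(key=lambda g: g.group_id)
    return _assign_unique_peptides(groups)


def _assign_unique_peptides(groups: list[ProteinGroup]) -> list[ProteinGroup]:
    """Recompute each group's unique-peptide set against the others."""
    owners: dict[str, int] = {}
    for i, g in enumerate(groups):
        for p in g.peptide_keys:
            owners[p] = -1 if p in owners else i
    return [
        replace(g, unique_peptide_keys=frozenset(p for p in g.peptide_keys if owners[p] == i))
        for i, g in enumerate(groups)
    ]


def filter_groups(groups: Iterable[ProteinGroup], cfg: FilterConfig | None = None) -> list[ProteinGroup]:
    """Apply the protein-level acceptance rules, then refresh shared-peptide sets.

    A group survives if its protein probability is strictly above the
    threshold, it has at least ``min_peptides`` peptides, and (when required)
    at least one unique peptide.  Uniqueness is evaluated against the groups
    present at entry; after removal the surviving groups' unique sets are
    recomputed, since a peptide shared only with removed groups becomes
    unique.
    """
    cfg = cfg or FilterConfig()
    kept = [
        g
        for g in groups
        if g.protein_probability > cfg.min_protein_probability
        and len(g.peptide_keys) >= cfg.min_peptides
        and (not cfg.require_unique_peptide or len(g.unique_peptide_keys) >= 1)
    ]
    return _assign_unique_peptides(kept)


def compute_pps(group: ProteinGroup, evidence: EvidenceSet, mode: str = "distinct") -> float:
    """Summed peptide probabilities (PPS) for a group.

    In ``distinct`` mode each of the group's peptides contributes once, at the
    best (maximum) probability observed for it across all spectra; in
    ``per_spectrum`` mode every accepted spectrum contributes its probability.
    """
    if mode == "distinct":
        best: dict[str, float] = {}
        for rec in evidence:
            if rec.peptide in group.peptide_keys:
                best[rec.peptide] = max(best.get(rec.peptide, 0.0), rec.peptide_probability)
        return float(sum(best.values()))
    if mode == "per_spectrum":
        return float(
            sum(r.peptide_probability for r in evidence if r.peptide in group.peptide_keys)
        )
    raise ValueError(f"unknown PPS mode: {mode}")


def distribute_counts(
    evidence: EvidenceSet,
    groups: list[ProteinGroup],
    metadata: SampleTable | None = None,
    report: QuantifyReport | None = None,
) -> CountMatrix:
    """Distribute accepted spectra into weighted counts per group and sample.

    Each spectrum of peptide i contributes share PPS(j)/Σ_{k∈n(i)} PPS(k) to
    every group j containing i, so shares sum to one per spectrum and column
    sums equal the number of assigned spectra.  Decoy records never receive
    counts.  Spectra whose peptide maps to no surviving group are dropped and
    tallied in ``report``.
    """
    groups = [replace(g) for g in groups]
    for g in groups:
        if g.pps <= 0:
            g.pps = compute_pps(g, evidence)

    containing: dict[str, list[int]] = {}
    for j, g in enumerate(groups):
        for p in g.peptide_keys:
            containing.setdefault(p, []).append(j)

    target = evidence.targets()
    sample_ids = metadata.sample_ids if metadata is not None else target.sample_ids
    if metadata is not None:
        metadata.require_samples(target.sample_ids)
    col_of = {s: k for k, s in enumerate(sample_ids)}
    values = np.zeros((len(groups), len(sample_ids)))

    n_assigned = 0
    n_unmapped = 0
    for rec in target:
        js = containing.get(rec.peptide)
        if not js:
            n_unmapped += 1
            continue
        total = sum(groups[j].pps for j in js)
        if total <= 0:
            raise ValidationError(
                f"all PPS zero for groups sharing peptide {rec.peptide!r}; share undefined"
            )
        k = col_of[rec.sample_id]
        for j in js:
            values[j, k] += groups[j].pps / total
        n_assigned += 1

    if report is not None:
        report.n_spectra_assigned = n_assigned
        report.n_spectra_unmapped = n_unmapped
    frame = pd.DataFrame(values, index=[g.group_id for g in groups], columns=sample_ids)
    return CountMatrix(frame)


def decoy_fdr(items: Iterable, level: str = "peptide") -> float:
    """Decoy-based FDR: accepted decoys / accepted targets.

    ``items`` is an accepted (already filtered) collection of evidence records
    or protein groups, each carrying ``is_decoy``.  Raises if no targets were
    accepted (the ratio is undefined).
    """
    n_decoy = n_target = 0
    for it in items:
        if it.is_decoy:
            n_decoy += 1
        else:
            n_target += 1
    if n_target == 0:
        raise ValidationError(f"no accepted target {level}s; FDR undefined")
    return n_decoy / n_target


def quantify_evidence(
    evidence: EvidenceSet,
    metadata: SampleTable | None = None,
    cfg: FilterConfig | None = None,
    protein_probabilities: Mapping[str, float] | None = None,
) -> tuple[CountMatrix, list[ProteinGroup], QuantifyReport]:
    """Full quantification: filter PSMs, group, filter groups, distribute.

    Decoy groups are used for the group-level FDR estimate and then removed
    before count distribution.
    """
    cfg = cfg or FilterConfig()
    report = QuantifyReport(n_spectra_input=len(evidence))
    accepted = filter_peptides(evidence, cfg)
    report.n_spectra_accepted = len(accepted.targets())
    try:
        report.peptide_fdr = decoy_fdr(accepted, level="peptide")
    except ValidationError:
        report.peptide_fdr = None

    groups = build_protein_groups(accepted, protein_probabilities)
    report.n_groups_built = len(groups)
    kept = filter_groups(groups, cfg)
    try:
        report.group_fdr = decoy_fdr(kept, level="group")
    except ValidationError:
        report.group_fdr = None
    kept = _assign_unique_peptides([g for g in kept if not g.is_decoy])
    report.n_groups_retained = len(kept)

    for g in kept:
        g.pps = compute_pps(g, accepted, cfg.pps_mode)
    matrix = distribute_counts(accepted, kept, metadata, report)
    return matrix, kept, report
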