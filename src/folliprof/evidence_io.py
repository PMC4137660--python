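"""Tabular input/output for PSM evidence, sample metadata and count matrices.

The normative interchange formats are UTF-8 TSV files with a header row:

``evidence``
    columns ``sample_id, spectrum_id, peptide, peptide_probability, proteins``
    and optionally ``is_decoy``; ``proteins`` is a separator-delimited list of
    candidate accessions (default separator ``;``).  Without an ``is_decoy``
    column, decoy status is inferred from an accession prefix (default
    ``REV_``, mirroring a reversed-sequence decoy database).
``metadata``
    columns ``sample_id, subject_id, group, site, fraction, replicate``.
``counts``
    proteins as rows, samples as columns, first column ``protein_id``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EvidenceRecord",
    "EvidenceSet",
    "SampleTable",
    "CountMatrix",
    "FormatError",
    "ValidationError",
    "read_evidence",
    "write_evidence",
    "read_sample_metadata",
    "write_sample_metadata",
    "read_count_matrix",
    "write_count_matrix",
]

VALID_SITES = frozenset({"scalp", "axillary", "facial", "pubic"})
VALID_FRACTIONS = frozenset({"total", "cuticle"})

EVIDENCE_COLUMNS = ("sample_id", "spectrum_id", "peptide", "peptide_probability", "proteins")
METADATA_COLUMNS = ("sample_id", "subject_id", "group", "site", "fraction", "replicate")


class FormatError(ValueError):
    """A file does not have the expected columns or layout."""


class ValidationError(ValueError):
    """Rows violate the declared invariants; offending rows are listed."""


@dataclass(frozen=True)
class EvidenceRecord:
    """One peptide-spectrum match: a spectrum identified as a peptide.

    ``peptide`` is an opaque equality-comparable key (sequence plus
    modification string); ``proteins`` are the candidate accessions the
    search engine offered for the peptide.
    """

    sample_id: str
    spectrum_id: str
    peptide: str
    peptide_probability: float
    proteins: frozenset[str]
    is_decoy: bool = False

    def __post_init__(self) -> None:
        if not (0.0 <= self.peptide_probability <= 1.0):
            raise ValidationError(
                f"peptide_probability {self.peptide_probability} outside [0, 1]"
            )
        if not self.proteins:
            raise ValidationError("candidate protein set must be nonempty")


@dataclass
class EvidenceSet:
    """A validated collection of PSM records, pooled across samples."""

    records: list[EvidenceRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        dups = []
        for i, r in enumerate(self.records):
            key = (r.sample_id, r.spectrum_id)
            if key in seen:
                dups.append((i, key))
            seen.add(key)
        if dups:
            detail = ", ".join(f"record {i}: {k}" for i, k in dups[:10])
            raise ValidationError(f"duplicate (sample_id, spectrum_id) pairs: {detail}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[EvidenceRecord]:
        return iter(self.records)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EvidenceSet):
            return NotImplemented
        return self.records == other.records

    @property
    def sample_ids(self) -> list[str]:
        out: list[str] = []
        for r in self.records:
            if r.sample_id not in out:
                out.append(r.sample_id)
        return out

    def targets(self) -> "EvidenceSet":
        """Records from the target (non-decoy) database only."""
        return EvidenceSet([r for r in self.records if not r.is_decoy])

    def to_frame(self, accession_sep: str = ";") -> pd.DataFrame:
        rows = [
            {
                "sample_id": r.sample_id,
                "spectrum_id": r.spectrum_id,
                "peptide": r.peptide,
                "peptide_probability": r.peptide_probability,
                "proteins": accession_sep.join(sorted(r.proteins)),
                "is_decoy": r.is_decoy,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows, columns=list(EVIDENCE_COLUMNS) + ["is_decoy"])


@dataclass
class SampleTable:
    """Sample metadata keyed by sample_id.

    ``frame`` is indexed by ``sample_id`` with columns ``subject_id``,
    ``group`` (ethnicity label), ``site``, ``fraction`` and ``replicate``.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in METADATA_COLUMNS[1:] if c not in self.frame.columns]
        if missing:
            raise FormatError(f"metadata missing columns: {missing}")
        if self.frame.index.has_duplicates:
            dups = self.frame.index[self.frame.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample_id values: {dups}")
        frame = self.frame.copy()
        for col, vocab in (("site", VALID_SITES), ("fraction", VALID_FRACTIONS)):
            frame[col] = frame[col].astype(str).str.lower()
            bad = sorted(set(frame[col]) - vocab)
            if bad:
                raise ValidationError(f"unknown {col} label(s): {bad}")
        self.frame = frame

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def require_samples(self, sample_ids: Iterable[str]) -> None:
        unknown = [s for s in sample_ids if s not in self.frame.index]
        if unknown:
            raise ValidationError(f"sample_id(s) absent from metadata: {unknown[:10]}")

    def levels(self, factor: str) -> list[str]:
        if factor == "subject":
            factor = "subject_id"
        if factor not in self.frame.columns:
            raise KeyError(f"unknown metadata column: {factor}")
        return sorted(self.frame[factor].astype(str).unique())

    def column(self, factor: str) -> pd.Series:
        if factor == "subject":
            factor = "subject_id"
        return self.frame[factor].astype(str)


@dataclass
class CountMatrix:
    """Protein-group × sample matrix of non-negative weighted spectral counts."""

    frame: pd.DataFrame  # index: protein ids, columns: sample ids, float values

    def __post_init__(self) -> None:
        values = self.frame.to_numpy(dtype=float, copy=False)
        if values.size and not np.all(np.isfinite(values)):
            raise ValidationError("count matrix contains non-finite values")
        if values.size and (values < 0).any():
            raise ValidationError("count matrix contains negative values")
        self.frame = self.frame.astype(float)

    @property
    def protein_ids(self) -> list[str]:
        return list(self.frame.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.columns)

    @property
    def values(self) -> np.ndarray:
        return self.frame.to_numpy(dtype=float)

    def subset_proteins(self, protein_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.frame.loc[list(protein_ids)].copy())

    def subset_samples(self, sample_ids: Sequence[str]) -> "CountMatrix":
        return CountMatrix(self.frame[list(sample_ids)].copy())


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    except FileNotFoundError:
        raise FileNotFoundError(f"no such file: {path}") from None
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty (no header row)") from None


def read_evidence(
    path: str | Path,
    accession_sep: str = ";",
    decoy_prefix: str = "REV_",
) -> EvidenceSet:
    """Read a PSM evidence TSV into a validated :class:`EvidenceSet`.

    Rows with out-of-range probabilities or empty accession lists raise
    :class:`ValidationError` naming the offending 1-based data row numbers.
    Decoy status comes from an ``is_decoy`` column when present, otherwise
    from ``decoy_prefix`` on every candidate accession.
    """
    frame = _read_tsv(path)
    missing = [c for c in EVIDENCE_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing evidence column(s) {missing}")
    has_decoy_col = "is_decoy" in frame.columns

    records: list[EvidenceRecord] = []
    bad_rows: list[tuple[int, str]] = []
    for i, row in enumerate(frame.itertuples(index=False), start=1):
        try:
            prob = float(getattr(row, "peptide_probability"))
        except ValueError:
            bad_rows.append((i, f"non-numeric probability {row.peptide_probability!r}"))
            continue
        accs = frozenset(a for a in str(row.proteins).split(accession_sep) if a)
        if has_decoy_col:
            is_decoy = str(row.is_decoy).strip().lower() in {"1", "true", "yes"}
        else:
            is_decoy = bool(accs) and all(a.startswith(decoy_prefix) for a in accs)
        try:
            records.append(
                EvidenceRecord(
                    sample_id=str(row.sample_id),
                    spectrum_id=str(row.spectrum_id),
                    peptide=str(row.peptide),
                    peptide_probability=prob,
                    proteins=accs,
                    is_decoy=is_decoy,
                )
            )
        except ValidationError as exc:
            bad_rows.append((i, str(exc)))
    if bad_rows:
        detail = "; ".join(f"row {i}: {msg}" for i, msg in bad_rows[:20])
        raise ValidationError(f"{path}: {len(bad_rows)} invalid row(s): {detail}")
    return EvidenceSet(records)


def write_evidence(evidence: EvidenceSet, path: str | Path, accession_sep: str = ";") -> None:
    evidence.to_frame(accession_sep).to_csv(path, sep="\t", index=False)


def read_sample_metadata(path: str | Path) -> SampleTable:
    """Read the sample-metadata TSV; site/fraction labels are case-folded."""
    frame = _read_tsv(path)
    missing = [c for c in METADATA_COLUMNS if c not in frame.columns]
    if missing:
        raise FormatError(f"{path}: missing metadata column(s) {missing}")
    return SampleTable(frame.set_index("sample_id"))


def write_sample_metadata(table: SampleTable, path: str | Path) -> None:
    table.frame.reset_index().rename(columns={"index": "sample_id"}).to_csv(
        path, sep="\t", index=False
    )


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read a protein × sample count TSV (first column ``protein_id``)."""
    path = Path(path)
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except FileNotFoundError:
        raise FileNotFoundError(f"no such file: {path}") from None
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    frame.index = frame.index.astype(str)
    frame.index.name = None
    frame.columns = frame.columns.astype(str)
    return CountMatrix(frame.astype(float))


def write_count_matrix(matrix: CountMatrix, path: str | Path) -> None:
    """Write at full float precision so read(write(m)) == m to 1e-12."""
    frame = matrix.frame.copy()
    frame.index.name = "protein_id"
    frame.to_csv(path, sep="\t", float_format="%.17g")
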