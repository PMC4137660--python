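import numpy as np
import pandas as pd
import pytest

from folliprof.evidence_io import EvidenceRecord, EvidenceSet, SampleTable


@pytest.fixture
def rng():
    return np.random.default_rng(20140805)


def make_metadata(layout):
    """Build a SampleTable from (subject, group, site, fraction, n_reps) tuples."""
    rows = []
    for subject, group, site, fraction, n_reps in layout:
        for r in range(n_reps):
            rows.append(
                {
                    "sample_id": f"{subject}_{site[:2]}_{fraction[:3]}_{r + 1}",
                    "subject_id": subject,
                    "group": group,
                    "site": site,
                    "fraction": fraction,
                    "replicate": str(r + 1),
                }
            )
    return SampleTable(pd.DataFrame(rows).set_index("sample_id"))


def random_evidence(rng, n_records=50, n_samples=3, n_peptides=20, n_proteins=8, decoy_rate=0.1):
    """Random but valid PSM records for round-trip and filter oracles."""
    records = []
    for i in range(n_records):
        k = int(rng.integers(1, 4))
        accs = rng.choice([f"PROT{j}" for j in range(n_proteins)], size=k, replace=False)
        is_decoy = bool(rng.random() < decoy_rate)
        if is_decoy:
            accs = [f"REV_{a}" for a in accs]
        records.append(
            EvidenceRecord(
                sample_id=f"S{int(rng.integers(0, n_samples))}",
                spectrum_id=f"sp{i:05d}",
                peptide=f"pep{int(rng.integers(0, n_peptides))}",
                peptide_probability=float(rng.uniform(0.5, 1.0)),
                proteins=frozenset(accs),
                is_decoy=is_decoy,
            )
        )
    return EvidenceSet(records)
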