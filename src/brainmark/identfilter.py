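"""Peptide-spectrum-match acceptance rules and per-sample spectral counting.

Search-engine output (one scored peptide-spectrum match per row) is reduced to
per-protein evidence: a PSM is accepted when its identification probability,
Mowse score and precursor charge clear the configured thresholds; accepted
PSMs are then grouped by protein, spectral counts are tallied per sample, and
peptide support is summarised.  A peptide is "confirmed" when at least two
accepted spectra match it (across all samples); proteins supported only by a
single unconfirmed peptide are retained but flagged for manual spectrum
validation, mirroring the curation pathway used for single-peptide hits.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import pandas as pd

__all__ = [
    "PSM",
    "psms_from_frame",
    "ProteinEvidence",
    "read_psm_table",
    "accept_psm",
    "filter_psms",
    "assemble_proteins",
    "evidence_to_frame",
]

#: amino-acid alphabet accepted in peptide strings (X = unknown residue)
_PEPTIDE_RE = re.compile(r"^[ACDEFGHIKLMNPQRSTVWYX]+$")

PSM_COLUMNS = [
    "sample_id",
    "accession",
    "peptide",
    "charge",
    "probability",
    "mowse",
    "spectrum_id",
]


@dataclass(frozen=True)
class PSM:
    """One scored peptide-spectrum match in one sample."""

    sample_id: str
    accession: str
    peptide: str
    charge: int
    probability: float
    mowse: float
    spectrum_id: str

    def __post_init__(self) -> None:
        if not _PEPTIDE_RE.match(self.peptide):
            raise ValueError(
                f"peptide {self.peptide!r} is not an amino-acid string"
            )
        if not 0.0 <= self.probability <= 1.0:
            raise ValueError(f"probability {self.probability} outside [0, 1]")
        if self.charge < 1:
            raise ValueError(f"charge {self.charge} must be positive")


@dataclass
class ProteinEvidence:
    """Per-protein spectral counts by sample, with peptide support."""

    accession: str
    sc_by_sample: dict[str, int] = field(default_factory=dict)
    peptides: set[str] = field(default_factory=set)
    single_peptide_flag: bool = False
    manually_validated: bool = False

    @property
    def n_peptides(self) -> int:
        return len(self.peptides)

    @property
    def total_sc(self) -> int:
        return sum(self.sc_by_sample.values())


def read_psm_table(path) -> list[PSM]:
    """Read a tab-separated PSM table into typed records.

    The file must carry a header naming the columns ``sample_id, accession,
    peptide, charge, probability, mowse, spectrum_id``.  Malformed rows raise
    with the offending line number.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    return psms_from_frame(df, source=str(path))


def psms_from_frame(df: pd.DataFrame, source: str = "<frame>") -> list[PSM]:
    """Convert an in-memory PSM table (e.g. a generator's output) to records."""
    missing = [c for c in PSM_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"PSM table {source} is missing column(s): {missing}")
    psms: list[PSM] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            psms.append(
                PSM(
                    sample_id=str(row.sample_id),
                    accession=str(row.accession),
                    peptide=str(row.peptide),
                    charge=int(row.charge),
                    probability=float(row.probability),
                    mowse=float(row.mowse),
                    spectrum_id=str(row.spectrum_id),
                )
            )
        except (ValueError, TypeError) as exc:
            raise ValueError(f"{source}: malformed PSM at line {i}: {exc}") from exc
    return psms


def accept_psm(
    psm: PSM,
    min_probability: float = 0.95,
    min_mowse: float = 35.0,
    min_charge: int = 2,
) -> bool:
    """Acceptance rule for a single PSM.

    Probability and Mowse thresholds are strict (``>``), matching the
    "greater than" phrasing of the acceptance criteria; the charge threshold
    is inclusive (``>=``), the default of 2 keeping doubly charged tryptic
    peptides, which dominate real identifications.
    """
    return (
        psm.probability > min_probability
        and psm.mowse > min_mowse
        and psm.charge >= min_charge
    )


def filter_psms(
    psms: list[PSM],
    min_probability: float = 0.95,
    min_mowse: float = 35.0,
    min_charge: int = 2,
) -> list[PSM]:
    """Return the accepted subset, preserving input order."""
    return [
        p
        for p in psms
        if accept_psm(p, min_probability, min_mowse, min_charge)
    ]


def assemble_proteins(
    accepted_psms: list[PSM],
    min_spectra_per_peptide: int = 2,
    require_manual_validation: bool = True,
    validated_accessions: set[str] | None = None,
) -> list[ProteinEvidence]:
    """Group accepted PSMs into per-protein evidence with spectral counts.

    The spectral count of a protein in a sample is the number of accepted
    PSMs for that (protein, sample) pair.  A peptide is confirmed when
    matched by at least ``min_spectra_per_peptide`` spectra over all samples.
    A protein whose only support is a single peptide seen in a single
    spectrum gets ``single_peptide_flag``; with ``require_manual_validation``
    such proteins are dropped unless listed in ``validated_accessions``
    (standing in for manual spectrum review).  Output is sorted by accession.
    """
    validated = validated_accessions or set()
    by_acc: dict[str, ProteinEvidence] = {}
    peptide_spectra: dict[str, set[str]] = {}
    for psm in accepted_psms:
        ev = by_acc.setdefault(psm.accession, ProteinEvidence(psm.accession))
        ev.sc_by_sample[psm.sample_id] = ev.sc_by_sample.get(psm.sample_id, 0) + 1
        ev.peptides.add(psm.peptide)
        peptide_spectra.setdefault(psm.peptide, set()).add(psm.spectrum_id)

    out: list[ProteinEvidence] = []
    for acc in sorted(by_acc):
        ev = by_acc[acc]
        confirmed = {
            pep
            for pep in ev.peptides
            if len(peptide_spectra[pep]) >= min_spectra_per_peptide
        }
        ev.single_peptide_flag = ev.n_peptides == 1
        ev.manually_validated = acc in validated
        if not confirmed and ev.single_peptide_flag:
            # single peptide, never seen in >=2 spectra: manual-review path
            if require_manual_validation and not ev.manually_validated:
                continue
        out.append(ev)
    return out


def evidence_to_frame(
    evidence: list[ProteinEvidence], sample_ids: list[str] | None = None
) -> pd.DataFrame:
    """Wide accession x sample spectral-count matrix with support flags."""
    if sample_ids is None:
        seen: set[str] = set()
        for ev in evidence:
            seen.update(ev.sc_by_sample)
        sample_ids = sorted(seen)
    rows = []
    for ev in evidence:
        row: dict[str, object] = {"accession": ev.accession}
        for s in sample_ids:
            row[s] = ev.sc_by_sample.get(s, 0)
        row["n_peptides"] = ev.n_peptides
        row["single_peptide_flag"] = ev.single_peptide_flag
        row["manually_validated"] = ev.manually_validated
        rows.append(row)
    cols = ["accession", *sample_ids, "n_peptides", "single_peptide_flag", "manually_validated"]
    return pd.DataFrame(rows, columns=cols)
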