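"""Greedy redundancy clustering of protein sequences at an identity threshold.

Protein-name redundancy in search output (same protein under several database
accessions, isoforms, fragments) is collapsed CD-HIT style: sequences are
sorted by descending length, each sequence joins the first existing cluster
whose representative it matches at or above the identity threshold (default
0.90), otherwise it founds a new cluster.  Identity is computed from an
optimal global alignment (match 1, mismatch 0, linear gap -1) as the number
of identical aligned residue pairs divided by the length of the shorter
sequence — the normalisation CD-HIT uses.  The representative of a cluster is
its longest member (founded first by the sort order), ties broken by
lexicographically smallest accession.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from Bio import SeqIO

from .identfilter import ProteinEvidence

__all__ = [
    "SequenceRecord",
    "Cluster",
    "sequence_identity",
    "cluster_sequences",
    "collapse_evidence",
    "read_fasta",
    "write_clstr",
]

_VALID = set("ACDEFGHIKLMNPQRSTVWYX")


@dataclass(frozen=True)
class SequenceRecord:
    accession: str
    sequence: str

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        bad = set(self.sequence) - _VALID
        if bad:
            raise ValueError(
                f"{self.accession}: invalid residues {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class Cluster:
    representative: str
    members: list[str] = field(default_factory=list)
    identity_to_rep: dict[str, float] = field(default_factory=dict)


def _optimal_matches(a: str, b: str) -> int:
    """Maximum number of identical aligned pairs over all optimal-score
    global alignments (match 1, mismatch 0, linear gap -1).

    With a zero mismatch score the optimal alignment is highly degenerate;
    picking one arbitrary traceback would make the identity depend on
    argument order.  Maximising matches among score-optimal alignments is a
    well-defined, symmetric quantity.  The DP packs (score, matches) into a
    single integer score*K + matches with K > max attainable matches, so the
    lexicographic maximum is an ordinary maximum; rows vectorise with a
    prefix-maximum for the in-row (gap-in-a) transition.
    """
    n, m = len(a), len(b)
    K = min(n, m) + 1
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b.encode(), dtype=np.uint8)
    j_idx = np.arange(m + 1, dtype=np.int64)
    prev = -K * j_idx  # top row: j leading gaps, 0 matches
    for i in range(1, n + 1):
        eq = (b_arr == a_arr[i - 1]).astype(np.int64)
        diag = prev[:-1] + eq * (K + 1)
        up = prev[1:] - K
        cand = np.empty(m + 1, dtype=np.int64)
        cand[0] = -K * i
        np.maximum(diag, up, out=cand[1:])
        # left transition cur[j] = max(cand[j], cur[j-1] - K) via prefix max
        w = np.maximum.accumulate(cand + K * j_idx)
        prev = w - K * j_idx
    return int(prev[m] % K)


def sequence_identity(a: SequenceRecord, b: SequenceRecord) -> float:
    """Fraction of identical residue pairs in the optimal global alignment,
    normalised by the shorter sequence length.  Symmetric, in [0, 1]."""
    return _optimal_matches(a.sequence, b.sequence) / min(len(a), len(b))


def cluster_sequences(
    records: list[SequenceRecord], threshold: float = 0.90
) -> list[Cluster]:
    """Greedy incremental clustering: a partition of the input accessions.

    Join order (descending length, ties by accession) is deterministic, so
    identical inputs always produce identical clusterings.
    """
    if not 0.5 < threshold <= 1.0:
        raise ValueError(f"threshold {threshold} outside (0.5, 1.0]")
    accs = [r.accession for r in records]
    if len(set(accs)) != len(accs):
        dupes = sorted({a for a in accs if accs.count(a) > 1})
        raise ValueError(f"duplicate accessions: {dupes}")

    by_acc = {r.accession: r for r in records}
    order = sorted(records, key=lambda r: (-len(r), r.accession))
    clusters: list[Cluster] = []
    for rec in order:
        for cl in clusters:
            ident = sequence_identity(rec, by_acc[cl.representative])
            if ident >= threshold:
                cl.members.append(rec.accession)
                cl.identity_to_rep[rec.accession] = ident
                break
        else:
            clusters.append(
                Cluster(
                    representative=rec.accession,
                    members=[rec.accession],
                    identity_to_rep={rec.accession: 1.0},
                )
            )
    return clusters


def collapse_evidence(
    evidence: list[ProteinEvidence], clusters: list[Cluster]
) -> list[ProteinEvidence]:
    """Merge evidence over cluster members under the representative accession.

    Per-sample spectral counts are summed over members (total SC is conserved)
    and peptide sets are unioned.  Accessions with no cluster assignment pass
    through unchanged.  Output sorted by accession.
    """
    rep_of: dict[str, str] = {}
    for cl in clusters:
        for m in cl.members:
            rep_of[m] = cl.representative

    merged: dict[str, ProteinEvidence] = {}
    for ev in evidence:
        rep = rep_of.get(ev.accession, ev.accession)
        tgt = merged.setdefault(rep, ProteinEvidence(rep))
        for s, sc in ev.sc_by_sample.items():
            tgt.sc_by_sample[s] = tgt.sc_by_sample.get(s, 0) + sc
        tgt.peptides.update(ev.peptides)
        tgt.manually_validated = tgt.manually_validated or ev.manually_validated
    out = []
    for acc in sorted(merged):
        ev = merged[acc]
        ev.single_peptide_flag = ev.n_peptides == 1
        out.append(ev)
    return out


def read_fasta(path) -> list[SequenceRecord]:
    return [
        SequenceRecord(rec.id, str(rec.seq).upper())
        for rec in SeqIO.parse(str(path), "fasta")
    ]


def write_clstr(clusters: list[Cluster], path) -> None:
    """Write clusters in the CD-HIT ``.clstr`` text layout."""
    with open(path, "w") as fh:
        for i, cl in enumerate(clusters):
            fh.write(f">Cluster {i}\n")
            for j, m in enumerate(cl.members):
                ident = cl.identity_to_rep[m]
                if m == cl.representative:
                    fh.write(f"{j}\t{m} *\n")
                else:
                    fh.write(f"{j}\t{m} at {100 * ident:.2f}%\n")
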