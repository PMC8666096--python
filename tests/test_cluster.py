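"""Sequence identity and greedy redundancy clustering, checked against an
independent brute-force oracle."""

import numpy as np
import pytest

from brainmark.cluster import (
    Cluster,
    SequenceRecord,
    cluster_sequences,
    collapse_evidence,
    read_fasta,
    sequence_identity,
    write_clstr,
)
from brainmark.identfilter import ProteinEvidence
from brainmark.synthetic import generate_sequences


# -------------------------------------------------------------- oracle

def nw_identity(a: str, b: str) -> float:
    """Independent Needleman-Wunsch (match 1, mismatch 0, linear gap -1):
    dynamic programme over (score, identities), maximising identities among
    optimal-score alignments, normalised by the shorter length."""
    n, m = len(a), len(b)
    # cell = (best score, most identities at that score)
    dp = [[(0, 0)] * (m + 1) for _ in range(n + 1)]
    for i in range(1, n + 1):
        dp[i][0] = (-i, 0)
    for j in range(1, m + 1):
        dp[0][j] = (-j, 0)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            eq = a[i - 1] == b[j - 1]
            ds, di = dp[i - 1][j - 1]
            diag = (ds + (1 if eq else 0), di + (1 if eq else 0))
            us, ui = dp[i - 1][j]
            up = (us - 1, ui)
            ls, li = dp[i][j - 1]
            left = (ls - 1, li)
            dp[i][j] = max(diag, up, left)
    return dp[n][m][1] / min(n, m)


def greedy_oracle(records, threshold):
    """Replay the greedy rule from the full pairwise identity matrix."""
    order = sorted(records, key=lambda r: (-len(r.sequence), r.accession))
    clusters: list[list[str]] = []
    reps: list[SequenceRecord] = []
    for rec in order:
        for k, rep in enumerate(reps):
            if nw_identity(rec.sequence, rep.sequence) >= threshold:
                clusters[k].append(rec.accession)
                break
        else:
            reps.append(rec)
            clusters.append([rec.accession])
    return [set(c) for c in clusters]


# ------------------------------------------------------------- identity

class TestIdentity:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACDEFGHIKLMNPQRSTVWY", "ACDEFGHIKLMNPQRSTVWY", 1.0),
            ("AAAA", "CCCC", 0.0),
            ("ACDEFGHIKL", "ACDEFGHIKV", 0.9),  # 9/10 positions match
        ],
    )
    def test_known_values(self, a, b, expected):
        ra, rb = SequenceRecord("A1", a), SequenceRecord("B1", b)
        assert sequence_identity(ra, rb) == pytest.approx(expected)

    def test_symmetry_and_oracle_agreement(self, rng):
        aas = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
        for _ in range(10):
            a = "".join(rng.choice(aas, size=int(rng.integers(20, 40))))
            b = "".join(rng.choice(aas, size=int(rng.integers(20, 40))))
            ra, rb = SequenceRecord("A1", a), SequenceRecord("B1", b)
            ident = sequence_identity(ra, rb)
            assert ident == pytest.approx(sequence_identity(rb, ra))
            # both maximise identities over optimal-score alignments
            assert ident == pytest.approx(nw_identity(a, b))

    def test_substitution_variants_lower_bound(self, rng):
        """k substitutions in a length-L sequence leave identity >= (L-k)/L."""
        base = "".join(rng.choice(np.array(list("ACDEFGHIKLMNPQRSTVWY")), size=100))
        for k in (1, 2, 5, 9):
            seq = list(base)
            for pos in rng.choice(100, size=k, replace=False):
                seq[pos] = "W" if seq[pos] != "W" else "Y"
            ident = sequence_identity(
                SequenceRecord("A1", base), SequenceRecord("B1", "".join(seq))
            )
            assert ident >= (100 - k) / 100 - 1e-12

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("X1", "")


# ------------------------------------------------------------ clustering

class TestClustering:
    def test_identical_pair_merges(self):
        recs = [SequenceRecord("B1", "ACDEFGHIKLMNPQRSTVWY"),
                SequenceRecord("A1", "ACDEFGHIKLMNPQRSTVWY")]
        (cl,) = cluster_sequences(recs)
        assert set(cl.members) == {"A1", "B1"}
        assert cl.representative == "A1"  # length tie -> lexicographic

    def test_dissimilar_sequences_stay_apart(self, rng):
        recs, _ = generate_sequences(6, 1, (50, 80), seed=5)
        clusters = cluster_sequences(recs)
        assert len(clusters) == 6

    def test_partition_property(self, rng):
        recs, _ = generate_sequences(4, 3, (40, 80), seed=9)
        clusters = cluster_sequences(recs)
        members = [m for cl in clusters for m in cl.members]
        assert sorted(members) == sorted(r.accession for r in recs)
        for cl in clusters:
            assert cl.representative in cl.members
            for m in cl.members:
                if m != cl.representative:
                    assert cl.identity_to_rep[m] >= 0.90

    def test_planted_clusters_recovered(self):
        recs, labels = generate_sequences(10, 2, (60, 120), 0.95, seed=21)
        clusters = cluster_sequences(recs, 0.90)
        recovered = {frozenset(cl.members) for cl in clusters}
        planted = {
            frozenset(acc for acc, lab in labels.items() if lab == c)
            for c in set(labels.values())
        }
        assert recovered == planted

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_brute_force_oracle(self, seed):
        """Greedy result equals the oracle's replay for small inputs mixing
        near-duplicates and unrelated sequences."""
        recs, _ = generate_sequences(4, 3, (30, 60), 0.95, seed=seed)
        assert len(recs) == 12
        got = {frozenset(cl.members) for cl in cluster_sequences(recs, 0.90)}
        want = {frozenset(c) for c in greedy_oracle(recs, 0.90)}
        assert got == want

    def test_threshold_monotonicity(self):
        recs, _ = generate_sequences(5, 3, (40, 80), 0.92, seed=13)
        n_low = len(cluster_sequences(recs, 0.90))
        n_high = len(cluster_sequences(recs, 0.99))
        assert n_high >= n_low

    def test_duplicate_accessions_rejected(self):
        recs = [SequenceRecord("A1", "ACDEFGHIKLMNPQRSTVWY")] * 2
        with pytest.raises(ValueError, match="duplicate"):
            cluster_sequences(recs)


# -------------------------------------------------------------- collapse

class TestCollapse:
    def test_member_counts_summed(self):
        ev = [
            ProteinEvidence("P1", {"A": 3}, {"PEPAK"}),
            ProteinEvidence("P2", {"A": 2}, {"PEPBK"}),
        ]
        clusters = [Cluster("P1", ["P1", "P2"], {"P1": 1.0, "P2": 0.95})]
        (merged,) = collapse_evidence(ev, clusters)
        assert merged.accession == "P1"
        assert merged.sc_by_sample == {"A": 5}
        assert merged.n_peptides == 2

    def test_singleton_unchanged(self):
        ev = [ProteinEvidence("P1", {"A": 3, "B": 1}, {"PEPAK"})]
        clusters = [Cluster("P1", ["P1"], {"P1": 1.0})]
        (merged,) = collapse_evidence(ev, clusters)
        assert merged.sc_by_sample == ev[0].sc_by_sample

    def test_total_sc_conserved(self, rng):
        accs = [f"P{i}" for i in range(20)]
        ev = [
            ProteinEvidence(
                a,
                {f"S{j}": int(rng.integers(0, 20)) for j in range(5)},
                {f"PEP{a}K"},
            )
            for a in accs
        ]
        clusters = [
            Cluster(accs[i], accs[i : i + 4], {a: 0.95 for a in accs[i : i + 4]})
            for i in range(0, 20, 4)
        ]
        merged = collapse_evidence(ev, clusters)
        assert sum(e.total_sc for e in merged) == sum(e.total_sc for e in ev)

    def test_unclustered_passthrough(self):
        ev = [ProteinEvidence("ORPHAN", {"A": 2}, {"PEPK"})]
        (merged,) = collapse_evidence(ev, [])
        assert merged.accession == "ORPHAN"


def test_fasta_and_clstr_round_trip(tmp_path):
    recs, _ = generate_sequences(3, 2, (30, 50), seed=3)
    fasta = tmp_path / "seqs.fasta"
    with open(fasta, "w") as fh:
        for r in recs:
            fh.write(f">{r.accession}\n{r.sequence}\n")
    loaded = read_fasta(fasta)
    assert loaded == recs
    clusters = cluster_sequences(loaded)
    out = tmp_path / "clusters.clstr"
    write_clstr(clusters, out)
    text = out.read_text()
    assert text.count(">Cluster") == len(clusters)
    assert text.count("*") == len(clusters)  # one representative each
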