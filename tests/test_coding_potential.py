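"""ORF detection, protein homology search, motif matching, Filter 3."""

import numpy as np
import pytest

from equilnc.coding_potential import (apply_filter3, find_orfs, match_motifs,
                                      prosite_to_regex, search_protein_db)
from equilnc.io_model import TranscriptRecord

from oracles import brute_force_orfs, prosite_match

AA = list("ACDEFGHIKLMNPQRSTVWY")


def _random_peptide(rng, n):
    return "M" + "".join(rng.choice(AA, size=n - 1))


def _rec(tid, seq):
    return TranscriptRecord(transcript_id=tid, chrom="c", strand="+",
                            exons=((1, len(seq)),), sequence=seq)


class TestFindOrfs:
    def test_100_codon_orf_found_at_threshold(self):
        seq = "ATG" + "GCT" * 99 + "TAA"
        (orf,) = find_orfs(seq, min_aa=100, both_strands=False)
        assert orf.peptide == "M" + "A" * 99
        assert orf.length_aa == 100 and not orf.partial
        assert (orf.start, orf.end) == (1, 303)

    def test_99_codon_orf_below_threshold(self):
        seq = "ATG" + "GCT" * 98 + "TAA"
        assert find_orfs(seq, min_aa=100, both_strands=False) == []

    def test_partial_orf_without_stop_flagged(self):
        seq = "ATG" + "GCT" * 10
        (orf,) = find_orfs(seq, min_aa=5, both_strands=False)
        assert orf.partial and orf.length_aa == 11
        assert (orf.start, orf.end) == (1, 33)

    def test_ambiguous_codon_breaks_orf(self):
        seq = "ATG" + "GCT" * 5 + "GNT" + "GCT" * 10 + "TAA"
        assert find_orfs(seq, min_aa=10, both_strands=False) == []

    def test_antisense_orf_reported_in_sense_coordinates(self):
        sense_orf = "ATG" + "GCT" * 9 + "TAA"
        seq_rc = sense_orf.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        seq = "CC" + seq_rc + "CC"
        (orf,) = find_orfs(seq, min_aa=10)
        assert orf.strand_of_transcript == "antisense"
        assert (orf.start, orf.end) == (3, 35)

    def test_matches_brute_force_scanner_on_random_sequences(self):
        """Exact equivalence with an independent six-frame scan, 500 draws."""
        rng = np.random.default_rng(29)
        bases = np.array(list("ACGTN"))
        for i in range(500):
            n = int(rng.integers(60, 400))
            p = [0.24, 0.24, 0.24, 0.24, 0.04]
            seq = "".join(rng.choice(bases, size=n, p=p))
            min_aa = int(rng.integers(1, 25))
            ours = {(o.strand_of_transcript, o.frame, o.start, o.end, o.peptide,
                     o.partial) for o in find_orfs(seq, min_aa=min_aa)}
            assert ours == brute_force_orfs(seq, min_aa), f"seq {i}"


class TestProteinSearch:
    def test_self_hit_is_significant(self):
        rng = np.random.default_rng(31)
        pep = _random_peptide(rng, 100)
        hits = search_protein_db(pep, {"self": pep, "other": _random_peptide(rng, 100)})
        assert hits[0].subject_id == "self"
        assert hits[0].evalue < 1e-3
        assert hits[0].percent_identity == 100.0

    def test_db_proteins_retrieve_themselves(self):
        rng = np.random.default_rng(37)
        db = {f"p{i}": _random_peptide(rng, int(rng.integers(50, 200)))
              for i in range(10)}
        for pid, pep in db.items():
            best = search_protein_db(pep, db)[0]
            assert best.subject_id == pid and best.percent_identity == 100.0

    def test_random_peptides_rarely_hit_unrelated_db(self):
        """<= 1% false-positive rate at e < 1e-3 over 100 seeded trials."""
        rng = np.random.default_rng(41)
        db = {f"p{i}": _random_peptide(rng, 100) for i in range(100)}
        false_hits = sum(
            bool(search_protein_db(_random_peptide(rng, 100), db, evalue_max=1e-3))
            for _ in range(100))
        assert false_hits <= 1

    def test_empty_peptide_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            search_protein_db("", {"p": "MKL"})

    def test_empty_db_warns_and_returns_nothing(self, caplog):
        with caplog.at_level("WARNING", logger="equilnc"):
            assert search_protein_db("MKLMKL", {}) == []
        assert "empty protein database" in caplog.text


class TestMotifs:
    def test_literal_pattern_matches(self):
        assert match_motifs("AAACGHCAAA", [("zn", "C-G-H-C")])

    def test_empty_motif_set(self):
        assert match_motifs("ACDEFG", []) == []

    def test_malformed_pattern_named_in_error(self):
        with pytest.raises(ValueError, match="C-%-H"):
            match_motifs("ACH", [("bad", "C-%-H")])

    def test_patterns_match_like_independent_matcher(self):
        """Regex compilation agrees with a direct recursive matcher."""
        rng = np.random.default_rng(43)
        patterns = ["C-x(2)-[HK]-C", "M-x-{P}-L", "<M-A-x(1,3)-G", "W-W->",
                    "[ST]-x-[RK]", "A-x(2,4)-C-H"]
        for _ in range(300):
            pep = "".join(rng.choice(AA, size=int(rng.integers(3, 30))))
            for pat in patterns:
                ours = bool(match_motifs(pep, [("m", pat)]))
                assert ours == prosite_match(pat, pep), (pat, pep)

    def test_regex_translation_of_wildcards(self):
        assert prosite_to_regex("C-x(2)-H") == "C.{2}H"
        assert prosite_to_regex("<M-[AG]-{C}-x>") == "^M[AG][^C].$"


class TestFilter3:
    def _db_and_transcript(self, rng, n_aa=150):
        pep = _random_peptide(rng, n_aa)
        codons = {"A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
                  "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTT",
                  "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
                  "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT"}
        orf = "".join(codons[a] for a in pep) + "TAA"
        seq = "CCATTC" + orf + "GGATCC"
        return {"ref": pep}, _rec("t1", seq)

    def test_long_orf_with_db_hit_removed(self):
        rng = np.random.default_rng(47)
        db, rec = self._db_and_transcript(rng, 150)
        retained, removed = apply_filter3([rec], db, None)
        assert not retained and len(removed) == 1

    def test_long_orf_without_evidence_retained(self):
        rng = np.random.default_rng(53)
        _, rec = self._db_and_transcript(rng, 150)
        unrelated = {"u": _random_peptide(rng, 120)}
        retained, removed = apply_filter3([rec], unrelated, None)
        assert len(retained) == 1 and not removed

    def test_short_orf_with_hit_retained(self):
        rng = np.random.default_rng(59)
        db, rec = self._db_and_transcript(rng, 80)
        retained, removed = apply_filter3([rec], db, None, min_aa=100)
        assert len(retained) == 1 and not removed

    def test_motif_evidence_triggers_removal(self):
        rng = np.random.default_rng(61)
        _, rec = self._db_and_transcript(rng, 150)
        pep = find_orfs(rec.sequence, min_aa=100)[0].peptide
        motif = "-".join(pep[10:16])
        retained, removed = apply_filter3([rec], None, [("m", motif)])
        assert not retained and len(removed) == 1

    def test_missing_sequence_retained_with_warning(self, caplog):
        rec = TranscriptRecord(transcript_id="t", chrom="c", strand="+",
                               exons=((1, 300),), sequence_missing=True)
        with caplog.at_level("WARNING", logger="equilnc"):
            retained, removed = apply_filter3([rec], {"p": "M" + "A" * 120}, None)
        assert len(retained) == 1 and "cannot assess" in caplog.text

    def test_shrinking_db_never_increases_removals(self):
        rng = np.random.default_rng(67)
        recs, dbs = [], {}
        for i in range(6):
            db, rec = self._db_and_transcript(rng, 120)
            dbs[f"ref{i}"] = db["ref"]
            recs.append(_rec(f"t{i}", rec.sequence))
        _, removed_full = apply_filter3(recs, dbs, None)
        small = {k: dbs[k] for k in list(dbs)[:3]}
        _, removed_small = apply_filter3(recs, small, None)
        assert {r.transcript_id for r in removed_small} <= \
            {r.transcript_id for r in removed_full}
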