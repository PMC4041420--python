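"""Wobble decoding rules, species classification, parsing and the
presence/absence matrix."""

import itertools

import numpy as np
import pytest

from trnadyn.genetic_code import (SENSE_CODONS, STOP_ANTICODONS,
                                  VALID_ANTICODONS)
from trnadyn.repertoire import (AnticodonSpecies, GenomeRepertoire,
                                PresenceMatrix, all_species,
                                build_presence_matrix,
                                check_decoding_completeness, classify_species,
                                decoded_codons, filter_genomes, is_arg_box,
                                parse_trna_table)


class TestDecodedCodons:
    @pytest.mark.parametrize("anticodon,expected", [
        ("GAA", {"UUC": "watson_crick", "UUU": "wobble"}),        # Phe
        ("CCA", {"UGG": "watson_crick"}),                          # Trp, C34 only G3
        ("ACG", {"CGU", "CGC", "CGA"}),                            # Arg, inosine
        ("UGC", {"GCA", "GCG", "GCU", "GCC"}),                     # Ala family box, superwobble
        ("UUC", {"GAA", "GAG"}),                                   # Glu split box: no superwobble
    ])
    def test_known_decoding_ranges(self, anticodon, expected):
        got = decoded_codons(anticodon)
        if isinstance(expected, dict):
            assert got == expected
        else:
            assert set(got) == expected

    def test_superwobble_flag_widens_split_boxes_never(self):
        # even with the flag off restriction removed, a split-box U34 species
        # cannot decode pyrimidine-ending codons of another amino acid
        got = decoded_codons("UUC", superwobble_family_only=False)
        assert all(c.startswith("GA") for c in got)

    def test_every_sense_codon_covered_with_watson_crick_edge(self):
        coverage = {}
        for ac in VALID_ANTICODONS:
            for codon, kind in decoded_codons(ac).items():
                coverage.setdefault(codon, set()).add(kind)
        assert set(coverage) == set(SENSE_CODONS)
        assert all("watson_crick" in kinds for kinds in coverage.values())

    def test_stop_pairing_anticodons_rejected(self):
        for ac in STOP_ANTICODONS:
            with pytest.raises(ValueError):
                decoded_codons(ac)


class TestClassification:
    def test_partition_of_the_61_species(self):
        species = all_species()
        counts = {}
        for s in species:
            counts[s.status] = counts.get(s.status, 0) + 1
        assert counts == {"mandatory": 23, "auxiliary": 22,
                          "avoided": 15, "special": 1}

    @pytest.mark.parametrize("anticodon,status", [
        ("CAU", "mandatory"),   # sole decoder of Met
        ("CCA", "mandatory"),   # sole decoder of Trp
        ("UAU", "special"),     # rarely seen Ile decoder
        ("GGC", "auxiliary"),   # G34 in the Ala family box
        ("GAA", "mandatory"),   # G34 in the 2-fold Phe box
        ("CUC", "auxiliary"),   # C34 Glu
        ("AAA", "avoided"),     # A34
        ("ACG", "mandatory"),   # the one regularly used A34 species (Arg)
        ("UCG", "auxiliary"),   # Arg box special case
    ])
    def test_examples(self, anticodon, status):
        assert classify_species(anticodon) == status

    def test_sole_decoder_rule_marks_exactly_met_and_trp(self):
        singles = [s for s in all_species()
                   if s.status == "mandatory" and s.box_degeneracy == 1]
        assert sorted(s.amino_acid for s in singles) == ["M", "W"]

    def test_arg_box_flag(self):
        assert {ac for ac in VALID_ANTICODONS if is_arg_box(ac)} == \
            {"ACG", "GCG", "UCG", "CCG"}

    def test_dna_alphabet_accepted(self):
        sp = AnticodonSpecies.from_anticodon("cat")
        assert sp.anticodon == "CAU" and sp.amino_acid == "M"


SCAN_TABLE = """Sequence\t\ttRNA\tBounds\ttRNA\tAnti\tIntron Bounds\tInf
Name\ttRNA #\tBegin\tEnd\tType\tCodon\tBegin\tEnd\tScore
--------\t------\t-----\t----\t----\t-----\t-----\t---\t-----
O1\t1\t100\t175\tPhe\tGAA\t0\t0\t85.4
O1\t2\t300\t375\tGlu\tttc\t0\t0\t77.0
O1\t3\t500\t575\tSer\tTGA\t0\t0\t60.0\tpossible pseudogene
O1\t4\t700\t775\tSeC\tUCA\t0\t0\t90.0
O1\t5\t900\t975\tUndet\tNNN\t0\t0\t30.0
O2\t1\t100\t175\tSer\tUCA\t0\t0\t70.0
O2\t2\t200\t275\tLeu\tCAA\t0\t0\t70.0
"""


class TestParsing:
    def test_trnascan_dialect(self, tmp_path):
        path = tmp_path / "scan.tsv"
        path.write_text(SCAN_TABLE)
        with pytest.warns(UserWarning, match="stop codon"):
            reps = parse_trna_table(path)
        by_org = {r.organism_id: r for r in reps}
        # pseudo, SeC, NNN and the stop-pairing UCA rows are dropped
        assert by_org["O1"].species == ("GAA", "UUC")
        assert by_org["O2"].species == ("CAA",)

    def test_simple_tsv_with_sequences(self, tmp_path):
        path = tmp_path / "genes.tsv"
        path.write_text("organism\tgene_id\tanticodon\tsequence\n"
                        "OX\tg1\tgaa\tACGTACGT\n"
                        "OX\tg2\tGAA\t\n")
        reps = parse_trna_table(path)
        assert reps[0].species_copy_number == {"GAA": 2}
        assert reps[0].genes[0][2] == "ACGUACGU"

    def test_malformed_row_names_line(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("O1\tg1\tGAA\nO1\tg2\n")
        with pytest.raises(ValueError, match="line 2"):
            parse_trna_table(path)


class TestFilterGenomes:
    def _rep(self, org, n_species):
        rep = GenomeRepertoire(org)
        for ac in VALID_ANTICODONS[:n_species]:
            rep.add_gene(f"{org}.{ac}", ac)
        return rep

    def test_boundaries(self):
        reps = [self._rep("small_rep", 30), self._rep("ok", 31),
                self._rep("tiny_genome", 45)]
        sizes = {"small_rep": 3e6, "ok": 2e6, "tiny_genome": 9e5}
        kept, log = filter_genomes(reps, sizes)
        assert [r.organism_id for r in kept] == ["ok"]
        assert len(log) == 2

    def test_missing_size_names_organism(self):
        with pytest.raises(KeyError, match="mystery"):
            filter_genomes([self._rep("mystery", 35)], {})


class TestPresenceMatrix:
    def test_binarization_and_union_of_species(self):
        a = GenomeRepertoire("A")
        for _ in range(4):
            a.add_gene(f"g{_}", "GAA")
        b = GenomeRepertoire("B")
        b.add_gene("h1", "CAU")
        m = build_presence_matrix([a, b])
        assert m.species == ["CAU", "GAA"]          # alphabetical
        assert m.organisms == ["A", "B"]            # input order
        assert m.values.tolist() == [[0, 1], [1, 0]]

    def test_row_shuffle_idempotence(self, tmp_path, rng):
        rows = []
        for org, acs in [("O1", ["GAA", "CAU"]), ("O2", ["GAA"]),
                         ("O3", ["CUC", "CAU"])]:
            for k, ac in enumerate(acs):
                rows.append(f"{org}\t{org}g{k}\t{ac}")
        ref = None
        perms = list(itertools.permutations(rows))
        for perm in [perms[i] for i in rng.choice(len(perms), 8, replace=False)]:
            path = tmp_path / "t.tsv"
            path.write_text("\n".join(perm) + "\n")
            m = build_presence_matrix(sorted(parse_trna_table(path),
                                             key=lambda r: r.organism_id))
            frame = m.to_frame()
            if ref is None:
                ref = frame
            else:
                assert frame.equals(ref)

    def test_tsv_round_trip(self, tmp_path):
        m = PresenceMatrix(["A", "B"], ["CAU", "GAA"],
                           np.array([[0, 1], [1, 0]]))
        m.to_tsv(tmp_path / "m.tsv")
        back = PresenceMatrix.from_tsv(tmp_path / "m.tsv")
        assert back.organisms == m.organisms
        assert back.species == m.species
        assert (back.values == m.values).all()

    def test_rejects_non_binary(self):
        with pytest.raises(ValueError):
            PresenceMatrix(["A"], ["GAA"], np.array([[2]]))


class TestDecodingCompleteness:
    def _full_rep(self, exclude=()):
        rep = GenomeRepertoire("O")
        for ac in VALID_ANTICODONS:
            if ac not in exclude:
                rep.add_gene("g" + ac, ac)
        return rep

    def test_all_species_leaves_nothing_uncovered(self):
        assert check_decoding_completeness(self._full_rep()) == []

    def test_missing_arg_box_reports_cg_codons(self):
        rep = self._full_rep(exclude=("ACG", "GCG", "UCG", "CCG"))
        assert check_decoding_completeness(rep) == ["CGA", "CGC", "CGG", "CGU"]

    def test_inosine_arg_alone_misses_cgg(self):
        rep = self._full_rep(exclude=("UCG", "CCG", "GCG"))
        assert check_decoding_completeness(rep) == ["CGG"]
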