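"""Progressive alignment of marked proteins and presence/absence calls."""

import itertools

import pytest

from introgain.errors import ConsistencyError, NotFoundError
from introgain.gene_model import IntronMark, MarkedProtein, intron_marks, mark_protein
from introgain.marker_alignment import (ABSENT, PRESENT, UNCOVERED, AlignedRow,
                                        MarkedAlignment, build_msa,
                                        import_alignment, presence_matrix)
from introgain.synthetic_data import (SimulationConfig, simulate_gene_family,
                                      simulate_taxonomy)


def mp(accession, marked, species=None):
    """MarkedProtein from a marked string (phase-0 marks at each X)."""
    raw = marked.replace("X", "")
    marks = []
    for k, i in enumerate(i for i, ch in enumerate(marked) if ch == "X"):
        c = 3 * (i - len(marks))
        marks.append(IntronMark(ordinal=k + 1, coding_offset=c,
                                protein_index=c // 3 + 1, phase=0,
                                intron_length=90, genomic_interval=(0, 90)))
    return MarkedProtein(species=species or accession, accession=accession,
                         raw=raw, marked=marked, marks=marks)


class TestBuildMsa:
    def test_identical_sequences_share_the_x_column(self):
        aln = build_msa([mp("a", "MKXVLQW"), mp("b", "MKXVLQW")])
        assert aln.rows[0].aligned == aln.rows[1].aligned == "MKXVLQW"

    def test_x_aligns_against_gap_when_partner_lacks_the_intron(self):
        aln = build_msa([mp("a", "MKXVLQ"), mp("b", "MKVLQ")])
        assert aln.rows[0].aligned == "MKXVLQ"
        assert aln.rows[1].aligned == "MK-VLQ"

    def test_input_order_permutation_invariant_for_clean_sequences(self):
        seqs = ["MKVLQWERTYAASDF", "MKVLQWERTYAASDF", "MKXVLQWERTYAASDF",
                "MKVLQWERTYAASDF"]
        reference = None
        for perm in itertools.permutations(range(4)):
            rows = build_msa([mp(f"s{i}", seqs[i]) for i in perm]).rows
            snapshot = sorted((r.accession, r.aligned) for r in rows)
            if reference is None:
                reference = snapshot
            assert snapshot == reference

    def test_single_sequence_returned_trivially(self):
        aln = build_msa([mp("a", "MKXVLQ")])
        assert aln.rows[0].aligned == "MKXVLQ"

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            build_msa([])

    def test_ungapping_any_row_recovers_its_marked_sequence(self, clean_family):
        family, _ = clean_family
        marked = [
            mark_protein(g.protein, intron_marks(g.model), species=g.species,
                         accession=g.accession)
            for g in family.genes
        ]
        aln = build_msa(marked)
        for protein, row in zip(marked, aln.rows):
            assert row.aligned.replace("-", "") == protein.marked


class TestImportAlignment:
    def test_well_formed_round_trip(self, tmp_path):
        proteins = [mp("a", "MKXVLQ"), mp("b", "MKVLQ")]
        path = tmp_path / "aln.faa"
        path.write_text(">a\nMKXVLQ\n>b\nMK-VLQ\n")
        aln = import_alignment(path, proteins)
        assert [r.aligned for r in aln.rows] == ["MKXVLQ", "MK-VLQ"]

    def test_row_ungapping_to_wrong_sequence_names_accession(self, tmp_path):
        path = tmp_path / "aln.faa"
        path.write_text(">a\nMKXVLQ\n>b\nMK-VAQ\n")
        with pytest.raises(ConsistencyError, match="b"):
            import_alignment(path, [mp("a", "MKXVLQ"), mp("b", "MKVLQ")])

    def test_missing_accession_is_an_error(self, tmp_path):
        path = tmp_path / "aln.faa"
        path.write_text(">a\nMKXVLQ\n")
        with pytest.raises(ConsistencyError, match="b"):
            import_alignment(path, [mp("a", "MKXVLQ"), mp("b", "MKVLQ")])


class TestPresenceMatrix:
    def test_identical_ortholog_is_present_everywhere(self):
        aln = build_msa([mp("hum", "MKXVLQW"), mp("oth", "MKXVLQW")])
        matrix = presence_matrix(aln, "hum")
        assert matrix.status(1, "oth") == PRESENT
        assert matrix.status(1, "hum") == PRESENT

    def test_truncated_ortholog_is_uncovered(self):
        rows = [AlignedRow("hum", "hum", "MKXVLQW"),
                AlignedRow("oth", "oth", "-----QW")]
        matrix = presence_matrix(MarkedAlignment(rows), "hum")
        assert matrix.status(1, "oth") == UNCOVERED

    def test_three_orthologs_one_sharing_the_column(self):
        rows = [
            AlignedRow("hum", "hum", "MKXVLQW"),
            AlignedRow("s1", "s1", "MKXVLQW"),
            AlignedRow("s2", "s2", "MK-VLQW"),
            AlignedRow("s3", "s3", "MK-VLQW"),
        ]
        matrix = presence_matrix(MarkedAlignment(rows), "hum")
        assert [matrix.status(1, s) for s in ("s1", "s2", "s3")] == [
            PRESENT, ABSENT, ABSENT
        ]

    def test_row_order_invariance(self):
        rows = [
            AlignedRow("hum", "hum", "MKXVLQW"),
            AlignedRow("s1", "s1", "MKXVLQW"),
            AlignedRow("s2", "s2", "MK-VLQW"),
        ]
        a = presence_matrix(MarkedAlignment(rows), "hum")
        b = presence_matrix(MarkedAlignment([rows[0], rows[2], rows[1]]), "hum")
        assert a.cells == b.cells

    def test_focal_accession_missing_raises(self):
        aln = build_msa([mp("a", "MKXVLQ"), mp("b", "MKVLQ")])
        with pytest.raises(NotFoundError):
            presence_matrix(aln, "nope")


def _family_matrix(config):
    tree = simulate_taxonomy(config)
    family, truth = simulate_gene_family(tree, config)
    focal = family.focal_gene()
    marked = [
        mark_protein(g.protein, intron_marks(g.model), species=g.species,
                     accession=g.accession)
        for g in family.genes if not g.is_paralog
    ]
    aln = build_msa(marked)
    return presence_matrix(aln, focal.accession), truth


class TestAgreementWithSimulatorTruth:
    def test_no_noise_families_agree_exactly(self):
        """With zero divergence the matrix equals the simulator truth."""
        for seed in range(5):
            config = SimulationConfig(n_species=8, seed=seed, loss_rate=0.2,
                                      substitution_rate=0.0)
            matrix, truth = _family_matrix(config)
            for ordinal, iid in truth.focal_ordinals.items():
                for species in matrix.species:
                    expected = PRESENT if truth.presence[species][iid] else ABSENT
                    assert matrix.status(ordinal, species) == expected

    def test_cell_agreement_above_98pct_under_divergence(self):
        """substitution 0.1, no losses: >= 98% of cells match truth (50 families)."""
        agree = total = 0
        for seed in range(50):
            config = SimulationConfig(n_species=8, seed=1000 + seed, loss_rate=0.0,
                                      substitution_rate=0.1)
            matrix, truth = _family_matrix(config)
            for ordinal, iid in truth.focal_ordinals.items():
                for species in matrix.species:
                    expected = PRESENT if truth.presence[species][iid] else ABSENT
                    total += 1
                    agree += matrix.status(ordinal, species) == expected
        assert agree / total >= 0.98
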