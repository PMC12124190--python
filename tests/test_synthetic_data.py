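"""The family simulator: taxonomies, planted events, fixtures."""

import pytest

from introgain.errors import InvalidConfigError
from introgain.gene_model import intron_marks
from introgain.intronization import translate_intron_frames
from introgain.synthetic_data import (GainSpec, SimulationConfig,
                                      load_fixtures, simulate_gene_family,
                                      simulate_taxonomy, write_fixtures)


class TestSimulateTaxonomy:
    def test_smallest_tree_is_a_cherry_with_positive_lengths(self):
        tree = simulate_taxonomy(SimulationConfig(n_species=2, seed=1))
        leaves = list(tree.leaf_node_iter())
        assert len(leaves) == 2
        assert all(l.edge.length > 0 for l in leaves)
        assert {l.taxon.label for l in leaves} >= {"human"}

    def test_fixed_topology_returned_verbatim(self):
        config = SimulationConfig(
            n_species=6, birth_model="fixed-topology",
            topology="((A,B),(C,(D,(E,F))));", focal_species="F",
        )
        tree = simulate_taxonomy(config)
        newick = tree.as_string(schema="newick", suppress_internal_node_labels=True,
                                suppress_edge_lengths=True, suppress_rooting=True)
        assert newick.strip() == "((A,B),(C,(D,(E,F))));"

    def test_same_seed_gives_identical_newick(self):
        config = SimulationConfig(n_species=7, seed=42)
        a = simulate_taxonomy(config).as_string(schema="newick")
        b = simulate_taxonomy(config).as_string(schema="newick")
        assert a == b

    def test_fewer_than_two_species_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(n_species=1)

    def test_node_ages_recorded_and_nonnegative(self):
        tree = simulate_taxonomy(SimulationConfig(n_species=6, seed=2))
        assert tree.seed_node.age > 0
        assert all(n.age >= 0 for n in tree.preorder_node_iter())


class TestSimulateGeneFamily:
    def test_no_noise_generic_gain_adds_one_intron_in_clade_only(self, clean_family):
        family, truth = clean_family
        counts = {
            g.species: len(intron_marks(g.model))
            for g in family.genes if not g.is_paralog
        }
        clade = truth.events[0].clade_leaves
        baseline = counts[next(s for s in counts if s not in clade)]
        for species, n in counts.items():
            assert n == baseline + (1 if species in clade else 0)
        proteins = {g.protein for g in family.genes}
        assert len(proteins) == 1  # substitution rate 0: all proteins identical

    def test_intronization_shortens_protein_by_one_third_of_length(
            self, intronization_clean):
        family, truth = intronization_clean
        event = truth.events[0]
        focal = family.focal_gene()
        outgroup = next(g for g in family.genes if g.species == "out1")
        assert len(outgroup.protein) - len(focal.protein) == event.intron_length // 3

    def test_intron_translated_in_planted_frame_equals_outgroup_segment(
            self, intronization_clean):
        family, truth = intronization_clean
        event = truth.events[0]
        focal = family.focal_gene()
        mark = intron_marks(focal.model)[event.ordinal - 1]
        s, e = mark.genomic_interval
        intron_dna = family.genomes[focal.species][s:e]
        peptide = translate_intron_frames(intron_dna)[event.frame]
        outgroup = next(g for g in family.genes if g.species == "out1")
        idx = mark.protein_index - 1
        extra = event.intron_length // 3
        assert peptide == outgroup.protein[idx:idx + extra]

    def test_translation_consistency_for_every_species(self):
        config = SimulationConfig(n_species=6, seed=9, substitution_rate=0.2,
                                  loss_rate=0.1, paralog_rate=0.5)
        tree = simulate_taxonomy(config)
        family, _ = simulate_gene_family(tree, config)
        for gene in family.genes:
            assert gene.model.translate_cds(family.genomes[gene.species]) == gene.protein

    def test_every_intron_has_canonical_gt_ag_ends(self):
        config = SimulationConfig(
            n_species=5, seed=11, substitution_rate=0.3, loss_rate=0.0,
            gain_events=[
                GainSpec(clade=("human",), coding_offset=200, mechanism="generic",
                         intron_length=77),
                GainSpec(clade=("human",), coding_offset=601, mechanism="intronization",
                         intron_length=90),
            ],
        )
        tree = simulate_taxonomy(config)
        family, _ = simulate_gene_family(tree, config)
        for gene in family.genes:
            genome = family.genomes[gene.species]
            for mark in intron_marks(gene.model):
                s, e = mark.genomic_interval
                assert genome[s:s + 2] == "GT" and genome[e - 2:e] == "AG"

    def test_seed_determinism_of_written_fixtures(self, tmp_path):
        config = SimulationConfig(n_species=4, seed=21, substitution_rate=0.1)
        outputs = []
        for run in ("a", "b"):
            tree = simulate_taxonomy(config)
            family, truth = simulate_gene_family(tree, config)
            d = tmp_path / run
            paths = write_fixtures(family, truth, d)
            outputs.append({p.name: p.read_bytes() for p in sorted(d.iterdir())})
        assert outputs[0] == outputs[1]

    def test_insertion_point_outside_protein_rejected(self):
        with pytest.raises(InvalidConfigError):
            SimulationConfig(
                gain_events=[GainSpec(clade=("human",), coding_offset=10_000)]
            )

    def test_unknown_clade_label_rejected(self):
        config = SimulationConfig(
            n_species=4, seed=1,
            gain_events=[GainSpec(clade="atlantis", coding_offset=300)],
        )
        tree = simulate_taxonomy(config)
        with pytest.raises(InvalidConfigError):
            simulate_gene_family(tree, config)

    def test_focal_ordinals_cover_each_focal_intron_exactly_once(self, clean_family):
        family, truth = clean_family
        marks = intron_marks(family.focal_gene().model)
        assert sorted(truth.focal_ordinals) == list(range(1, len(marks) + 1))

    def test_paralog_registry_records_planted_intron_carriage(self):
        config = SimulationConfig(
            n_species=6, seed=13, paralog_rate=1.0, loss_rate=0.0,
            gain_events=[GainSpec(clade="human", coding_offset=450,
                                  mechanism="generic", intron_length=120)],
        )
        tree = simulate_taxonomy(config)
        family, truth = simulate_gene_family(tree, config)
        paralogs = [g for g in family.genes if g.is_paralog]
        assert paralogs and set(truth.paralogs) == {g.species for g in paralogs}
        # carriage flags match the paralog's actual gene structure
        planted = truth.events[0]
        for gene in paralogs:
            lengths = [m.intron_length for m in intron_marks(gene.model)]
            carries = planted.intron_length in lengths
            assert truth.paralogs[gene.species][planted.intron_id] == carries


class TestWriteFixtures:
    def test_gff_files_have_gene_mrna_exon_cds_records(self, clean_family, tmp_path):
        family, truth = clean_family
        write_fixtures(family, truth, tmp_path)
        for species in family.genomes:
            text = (tmp_path / f"{species}.gff3").read_text()
            for feature in ("\tgene\t", "\tmRNA\t", "\texon\t", "\tCDS\t"):
                assert feature in text

    def test_round_trip_preserves_models_and_proteins(self, clean_family, tmp_path):
        family, truth = clean_family
        write_fixtures(family, truth, tmp_path)
        reloaded = load_fixtures(tmp_path)
        assert reloaded.focal_species == family.focal_species
        original = {g.accession: (g.model.exons, g.model.cds, g.protein)
                    for g in family.genes}
        recovered = {g.accession: (g.model.exons, g.model.cds, g.protein)
                     for g in reloaded.genes}
        assert recovered == original

    def test_empty_family_writes_nothing(self, tmp_path):
        from introgain.synthetic_data import GeneFamily

        family = GeneFamily(focal_species="human", tree=None, genes=[], genomes={})
        target = tmp_path / "out"
        with pytest.raises(InvalidConfigError):
            write_fixtures(family, None, target)
        assert not target.exists() or not any(target.iterdir())
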