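"""Clade scoring, candidate filters, and the end-to-end pipeline."""

import random

import dendropy
import pytest

from introgain.errors import NotFoundError
from introgain.gain_inference import (PipelineConfig, apply_70pct_filter,
                                      apply_boundary_filter, best_gain_clade,
                                      check_intron_retention,
                                      exhaustive_best_clade, paralog_rescue,
                                      run_gain_pipeline)
from introgain.marker_alignment import ABSENT, PRESENT, UNCOVERED
from introgain.studies import random_status_vector
from introgain.synthetic_data import (GainSpec, SimulationConfig,
                                      annotate_node_ages,
                                      random_multifurcating_tree,
                                      simulate_gene_family, simulate_taxonomy)


def _tree(newick="((A,B),(C,(D,(E,F))));"):
    tree = dendropy.Tree.get(data=newick, schema="newick")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = 1.0
    annotate_node_ages(tree)
    return tree


class TestBestGainClade:
    def test_nested_gain_clade_worked_example(self):
        statuses = {sp: PRESENT for sp in "DEF"} | {sp: ABSENT for sp in "ABC"}
        event = best_gain_clade(_tree(), statuses, "F")
        assert event.clade_leaves == frozenset("DEF")
        assert (event.R, event.B, event.score) == (3, 0, 3)
        # agrees with brute-force enumeration of all focal-containing clades
        label, leaves, score = exhaustive_best_clade(_tree(), statuses, "F")
        assert (leaves, score) == (event.clade_leaves, event.score)

    def test_all_present_selects_root(self):
        statuses = {sp: PRESENT for sp in "ABCDEF"}
        event = best_gain_clade(_tree(), statuses, "F")
        assert event.clade_leaves == frozenset("ABCDEF")
        assert (event.R, event.B) == (6, 0)

    def test_only_focal_present_picks_the_leaf_clade(self):
        statuses = {"F": PRESENT} | {sp: ABSENT for sp in "ABCDE"}
        event = best_gain_clade(_tree(), statuses, "F")
        assert event.clade_leaves == frozenset("F")
        assert (event.R, event.B) == (1, 0)

    def test_uncovered_species_count_in_neither_r_nor_b(self):
        statuses = {"F": PRESENT, "E": UNCOVERED, "D": PRESENT} | {
            sp: ABSENT for sp in "ABC"
        }
        event = best_gain_clade(_tree(), statuses, "F")
        assert event.clade_leaves == frozenset("DEF")
        assert (event.R, event.B) == (2, 0)

    def test_focal_absent_from_vector_raises(self):
        with pytest.raises(NotFoundError):
            best_gain_clade(_tree(), {"A": ABSENT}, "F")

    def test_matches_exhaustive_enumeration_on_random_trees(self):
        rng = random.Random(99)
        for i in range(50):
            tree = random_multifurcating_tree(rng.randint(2, 12), 7000 + i)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            focal = rng.choice(leaves)
            statuses = random_status_vector(tree, focal, rng)
            fast = best_gain_clade(tree, statuses, focal)
            label, leaf_set, score = exhaustive_best_clade(tree, statuses, focal)
            assert fast.score == score and fast.clade_leaves == leaf_set

    def test_flipping_absent_to_present_inside_clade_never_lowers_score(self):
        rng = random.Random(5)
        for i in range(25):
            tree = random_multifurcating_tree(rng.randint(3, 10), 8000 + i)
            leaves = [l.taxon.label for l in tree.leaf_node_iter()]
            focal = rng.choice(leaves)
            statuses = random_status_vector(tree, focal, rng)
            event = best_gain_clade(tree, statuses, focal)
            for sp in event.clade_leaves:
                if statuses.get(sp) == ABSENT:
                    flipped = dict(statuses) | {sp: PRESENT}
                    assert best_gain_clade(tree, flipped, focal).score >= event.score


class TestSeventyPercentFilter:
    @staticmethod
    def _vector(n_absent, n_total=10):
        species = [f"s{i}" for i in range(n_total)]
        statuses = {"F": PRESENT}
        for i, sp in enumerate(species):
            statuses[sp] = ABSENT if i < n_absent else PRESENT
        return statuses

    def test_seven_of_ten_passes_at_least_70pct(self):
        statuses = self._vector(7)
        tree = random_multifurcating_tree(4, 1)
        event = best_gain_clade(tree, {"sp01": PRESENT}, "sp01")
        updated = apply_70pct_filter(event, statuses, "F")
        assert updated.passed_70pct and updated.fraction_unaligned == 0.7

    def test_six_of_ten_fails(self):
        tree = random_multifurcating_tree(4, 1)
        event = best_gain_clade(tree, {"sp01": PRESENT}, "sp01")
        updated = apply_70pct_filter(event, self._vector(6), "F")
        assert not updated.passed_70pct

    def test_uncovered_in_denominator_not_numerator(self):
        statuses = {"F": PRESENT} | {f"s{i}": ABSENT for i in range(7)} | {
            f"u{i}": UNCOVERED for i in range(3)
        }
        tree = random_multifurcating_tree(4, 1)
        event = best_gain_clade(tree, {"sp01": PRESENT}, "sp01")
        updated = apply_70pct_filter(event, statuses, "F")
        assert updated.fraction_unaligned == 0.7 and updated.passed_70pct

    def test_zero_orthologs_rejected_with_reason(self):
        tree = random_multifurcating_tree(4, 1)
        event = best_gain_clade(tree, {"sp01": PRESENT}, "sp01")
        updated = apply_70pct_filter(event, {"F": PRESENT}, "F")
        assert updated.rejected_reason and not updated.high_confidence


class TestBoundaryFilter:
    def _event(self):
        tree = _tree()
        return best_gain_clade(tree, {"F": PRESENT} | {s: ABSENT for s in "ABCDE"}, "F")

    def test_all_nonclade_uncovered_excludes(self):
        statuses = {"F": PRESENT} | {s: UNCOVERED for s in "ABCDE"}
        assert apply_boundary_filter(self._event(), statuses).boundary_excluded

    def test_no_uncovered_retains(self):
        statuses = {"F": PRESENT} | {s: ABSENT for s in "ABCDE"}
        assert not apply_boundary_filter(self._event(), statuses).boundary_excluded

    def test_exactly_at_cutoff_retained(self):
        # 2 of 4 non-clade species uncovered == 0.50 cutoff: strict inequality
        statuses = {"F": PRESENT, "A": UNCOVERED, "B": UNCOVERED,
                    "C": ABSENT, "D": ABSENT}
        event = best_gain_clade(_tree(), statuses | {"E": PRESENT}, "F")
        updated = apply_boundary_filter(event, statuses)
        assert not updated.boundary_excluded


class TestParalogRescue:
    def _setup(self):
        # multifurcating clade {D,E,F,G}; member E lost the intron
        tree = _tree("(A,B,H,I,(C,(D,E,F,G)));")
        statuses = {"F": PRESENT, "D": PRESENT, "G": PRESENT, "E": ABSENT} | {
            s: ABSENT for s in "ABHIC"
        }
        event = best_gain_clade(tree, statuses, "F")
        event = apply_70pct_filter(event, statuses, "F")
        return tree, statuses, event

    def test_rescue_inside_clade_moves_b_to_r(self):
        tree, statuses, event = self._setup()
        assert (event.R, event.B) == (3, 1)
        rescued, updated = paralog_rescue(event, statuses, {"E": "has"}, tree, "F")
        assert (rescued.R, rescued.B) == (4, 0)
        assert rescued.rescued_species == ("E",)

    def test_rescue_can_push_event_below_70pct(self):
        tree = _tree()
        statuses = {"F": PRESENT, "E": ABSENT, "D": ABSENT, "C": ABSENT,
                    "B": ABSENT, "A": PRESENT}
        event = apply_70pct_filter(best_gain_clade(tree, statuses, "F"), statuses, "F")
        assert event.passed_70pct  # 4/5 absent passes
        rescued, _ = paralog_rescue(event, statuses, {"E": "has"}, tree, "F")
        assert not rescued.passed_70pct  # 3/5 after rescue fails

    def test_no_paralogs_leaves_event_unchanged(self):
        tree, statuses, event = self._setup()
        unchanged, _ = paralog_rescue(event, statuses, {}, tree, "F")
        assert unchanged == event

    def test_rescue_is_idempotent(self):
        tree, statuses, event = self._setup()
        lookup = {"E": "has"}
        once, statuses1 = paralog_rescue(event, statuses, lookup, tree, "F")
        twice, statuses2 = paralog_rescue(once, statuses1, lookup, tree, "F")
        assert (twice.R, twice.B, statuses2) == (once.R, once.B, statuses1)


class TestIntronRetention:
    def test_spanning_exon_in_second_transcript_detected(self):
        transcripts = [[(0, 100), (200, 300)], [(0, 300)]]
        assert check_intron_retention(transcripts, (100, 200))

    def test_all_transcripts_splice_the_intron(self):
        transcripts = [[(0, 100), (200, 300)], [(0, 100), (200, 250)]]
        assert not check_intron_retention(transcripts, (100, 200))

    def test_single_transcript_gene(self):
        assert not check_intron_retention([[(0, 100), (200, 300)]], (100, 200))


class TestPipeline:
    def test_no_noise_fixture_reports_exactly_the_planted_event(self, clean_family):
        family, truth = clean_family
        result = run_gain_pipeline(family, PipelineConfig())
        events = result.high_confidence
        assert len(events) == 1
        assert events[0].ordinal == truth.events[0].ordinal
        assert events[0].clade_leaves == truth.events[0].clade_leaves

    def test_widespread_intron_filtered_by_70pct_rule(self):
        # intron present in 60% of species: absent fraction 0.44 < 0.70
        config = SimulationConfig(
            n_species=10, seed=17, loss_rate=0.0, substitution_rate=0.0,
            birth_model="fixed-topology",
            topology="(((((human,s1),s2),(s3,s4)),(s5,s6)),(s7,(s8,s9)));",
            focal_species="human",
            gain_events=[GainSpec(clade=("human", "s1", "s2", "s3", "s4", "s5"),
                                  coding_offset=300, intron_length=100)],
        )
        tree = simulate_taxonomy(config)
        family, _ = simulate_gene_family(tree, config)
        result = run_gain_pipeline(family, PipelineConfig())
        assert result.high_confidence == []
        assert any("70%" in line for line in result.log)

    def test_imported_alignment_reproduces_internal_result(self, clean_family, tmp_path):
        """Running from an externally supplied aligned FASTA gives the same
        events as the internal progressive aligner."""
        from introgain.gene_model import intron_marks, mark_protein
        from introgain.marker_alignment import build_msa
        from introgain.ortholog_search import best_hit_per_species

        family, _ = clean_family
        focal = family.focal_gene()
        subjects = [(g.accession, g.species, g.protein) for g in family.orthologs()]
        orthologs = best_hit_per_species(focal.protein, subjects,
                                         query=focal.accession)
        by_acc = {g.accession: g for g in family.genes}
        rows = [mark_protein(focal.protein, intron_marks(focal.model),
                             species=focal.species, accession=focal.accession)]
        for species in orthologs.species():
            gene = by_acc[orthologs.by_species[species].subject]
            rows.append(mark_protein(gene.protein, intron_marks(gene.model),
                                     species=species, accession=gene.accession))
        aln_path = tmp_path / "external.faa"
        build_msa(rows).write_fasta(aln_path)
        internal = run_gain_pipeline(family, PipelineConfig())
        imported = run_gain_pipeline(
            family, PipelineConfig(alignment_file=str(aln_path))
        )
        assert imported.events == internal.events

    def test_paralog_rescue_runs_in_pipeline(self):
        """A species whose ortholog lost the intron but whose paralog kept it
        is flipped to present when the clade is inferred."""
        config = SimulationConfig(
            n_species=6, seed=29, loss_rate=0.0, substitution_rate=0.0,
            paralog_rate=1.0, paralog_flip_prob=1.0,
            gain_events=[GainSpec(clade="human", coding_offset=303,
                                  mechanism="generic", intron_length=120)],
        )
        tree = simulate_taxonomy(config)
        family, truth = simulate_gene_family(tree, config)
        result = run_gain_pipeline(family, PipelineConfig())
        planted = truth.events[0]
        rescued_species = {
            sp for sp, flags in truth.paralogs.items()
            if flags[planted.intron_id] and sp != "human"
        }
        event = next(e for e in result.events if e.ordinal == planted.ordinal)
        assert set(event.rescued_species) == rescued_species
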