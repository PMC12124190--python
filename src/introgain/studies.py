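"""Canned study conditions: seeded simulation studies used by the analysis
drivers and by the validation checks.

Each study fixes the generator's conditions once (sample sizes, rates,
clade-sampling rules) and measures one property of the pipeline:

* clade-scoring agreement with a brute-force oracle,
* end-to-end recovery of a planted gain clade,
* intronization detection power / specificity and frame recovery,
* intron mark/unmark round-trip and planted (position, phase) recovery.

Planted gain clades in the recovery study are sampled among focal-containing
clades covering at most 30% of species: the discovery method only reports
gains absent in at least 70% of orthologs, so broader clades are
undetectable by design, and detectable gains are recent — as observed in
real data, where all discovered gains are recent.
"""

from __future__ import annotations

import random as _pyrandom
from dataclasses import dataclass

import dendropy

from .gain_inference import (PipelineConfig, best_gain_clade, exhaustive_best_clade,
                             run_gain_pipeline)
from .gene_model import intron_marks, mark_protein
from .intronization import scan_with_similarity
from .marker_alignment import ABSENT, PRESENT, UNCOVERED
from .synthetic_data import (GENERIC, INTRONIZATION, GainSpec, GeneFamily,
                             SimulationConfig, SimulationTruth,
                             random_multifurcating_tree, simulate_gene_family,
                             simulate_taxonomy)

# ---------------------------------------------------------------------------
# Clade-scoring oracle study


def random_status_vector(tree: dendropy.Tree, focal: str,
                         rng: _pyrandom.Random) -> dict[str, str]:
    """Random presence vector; focal forced present, some leaves missing."""
    statuses = {focal: PRESENT}
    for leaf in tree.leaf_node_iter():
        sp = leaf.taxon.label
        if sp == focal:
            continue
        u = rng.random()
        if u < 0.35:
            statuses[sp] = PRESENT
        elif u < 0.75:
            statuses[sp] = ABSENT
        elif u < 0.88:
            statuses[sp] = UNCOVERED
        # else: no ortholog found — species not in the vector
    return statuses


def clade_oracle_study(seed: int, n_trees: int = 200,
                       max_leaves: int = 12) -> tuple[int, int]:
    """Compare best_gain_clade with brute-force enumeration on random trees.

    Alternates binary pure-birth and multifurcating topologies. Returns
    (agreements, total); agreement requires identical score AND clade leaf
    set under the smallest-clade tie-break.
    """
    rng = _pyrandom.Random(seed)
    agree = 0
    for i in range(n_trees):
        n = rng.randint(2, max_leaves)
        sub_seed = seed * 1000 + i
        if i % 2 == 0:
            tree = random_multifurcating_tree(n, sub_seed)
        else:
            tree = simulate_taxonomy(
                SimulationConfig(n_species=max(n, 2), seed=sub_seed)
            )
        leaves = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        focal = rng.choice(leaves)
        statuses = random_status_vector(tree, focal, rng)
        fast = best_gain_clade(tree, statuses, focal)
        label, leaf_set, score = exhaustive_best_clade(tree, statuses, focal)
        if fast.score == score and fast.clade_leaves == leaf_set:
            agree += 1
    return agree, n_trees


# ---------------------------------------------------------------------------
# End-to-end recovery study


def sample_recent_clade(tree: dendropy.Tree, focal: str, rng: _pyrandom.Random,
                        max_frac: float = 0.30) -> tuple[str, frozenset[str]]:
    """Pick a focal-containing clade covering <= max_frac of the species."""
    n = sum(1 for _ in tree.leaf_node_iter())
    limit = max(1, int(max_frac * n))
    focal_leaf = next(
        leaf for leaf in tree.leaf_node_iter() if leaf.taxon.label == focal
    )
    eligible = []
    node = focal_leaf
    while node is not None:
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if len(leaves) <= limit:
            label = node.taxon.label if node.is_leaf() else node.label
            eligible.append((label, leaves))
        node = node.parent_node
    label, leaves = eligible[rng.randrange(len(eligible))]
    return label, leaves


def recovery_family(seed: int, n_species: int = 20, loss_rate: float = 0.05,
                    substitution_rate: float = 0.1) -> tuple[GeneFamily, SimulationTruth]:
    """One family with a single planted generic gain in a recent clade."""
    rng = _pyrandom.Random(seed)
    base = SimulationConfig(n_species=n_species, seed=seed)
    tree = simulate_taxonomy(base)
    clade_label, _ = sample_recent_clade(tree, base.focal_species, rng)
    offset = rng.randrange(60, 3 * base.protein_length - 60)
    config = SimulationConfig(
        n_species=n_species,
        seed=seed,
        loss_rate=loss_rate,
        substitution_rate=substitution_rate,
        gain_events=[
            GainSpec(clade=clade_label, coding_offset=offset, mechanism=GENERIC,
                     intron_length=rng.randrange(80, 300)),
        ],
    )
    return simulate_gene_family(tree, config)


@dataclass
class RecoveryResult:
    n_families: int
    n_exact: int
    n_disjoint: int
    n_no_event: int

    @property
    def exact_fraction(self) -> float:
        return self.n_exact / self.n_families


def recovery_study(seed: int, n_families: int = 50, n_species: int = 20,
                   loss_rate: float = 0.05,
                   substitution_rate: float = 0.1) -> RecoveryResult:
    """Recover planted gain clades end to end over seeded families."""
    exact = disjoint = no_event = 0
    for i in range(n_families):
        family, truth = recovery_family(
            seed * 1000 + i, n_species=n_species, loss_rate=loss_rate,
            substitution_rate=substitution_rate,
        )
        planted = truth.events[0]
        result = run_gain_pipeline(family, PipelineConfig())
        hits = [e for e in result.high_confidence if e.ordinal == planted.ordinal]
        if not hits:
            no_event += 1
            continue
        event = hits[0]
        if event.clade_leaves == planted.clade_leaves:
            exact += 1
        elif not (event.clade_leaves & planted.clade_leaves):
            disjoint += 1
    return RecoveryResult(n_families, exact, disjoint, no_event)


# ---------------------------------------------------------------------------
# Intronization studies

_INTRONIZATION_TOPOLOGY = (
    "((human:1,sister:1)ingroup:1,((out1:1,out2:1)n2:1,out3:2)n3:1)root;"
)


def intronization_family(seed: int, segment_sub_p: float = 0.3,
                         mechanism: str = INTRONIZATION,
                         substitution_rate: float = 0.05,
                         ) -> tuple[GeneFamily, SimulationTruth]:
    """A 5-species family with one gain in the (human, sister) cherry.

    The gain sits on the stem of the cherry, so the focal terminal branch
    (length 1) applies exactly ``segment_sub_p`` per-site substitution
    probability to the new intron's interior. Protein-level divergence stays
    at the generator default so the flanking exons remain conserved, as they
    are in real intronization cases.
    """
    rng = _pyrandom.Random(seed)
    length = 3 * rng.randrange(20, 50)  # 60-147 nt, multiple of 3
    if mechanism == GENERIC:
        length += rng.randrange(3)  # generic gains need no length constraint
    offset = rng.randrange(90, 3 * 300 - 90 - length)
    config = SimulationConfig(
        n_species=5,
        birth_model="fixed-topology",
        topology=_INTRONIZATION_TOPOLOGY,
        focal_species="human",
        seed=seed,
        loss_rate=0.0,
        substitution_rate=substitution_rate,
        intron_substitution_rate=segment_sub_p,
        gain_events=[
            GainSpec(clade="ingroup", coding_offset=offset, mechanism=mechanism,
                     intron_length=length),
        ],
    )
    tree = simulate_taxonomy(config)
    return simulate_gene_family(tree, config)


def intron_dna_of(family: GeneFamily, ordinal: int) -> str:
    """Extract the focal gene's intron DNA for one ordinal from its genome."""
    focal = family.focal_gene()
    mark = intron_marks(focal.model)[ordinal - 1]
    s, e = mark.genomic_interval
    return family.genomes[focal.species][s:e]


@dataclass
class IntronizationStudyResult:
    n_families: int
    n_detected: int  #: at least one candidate with length_match
    n_frame_checked: int  #: candidates with similarity significance <= 1e-6
    n_frame_correct: int

    @property
    def detection_fraction(self) -> float:
        return self.n_detected / self.n_families


def intronization_power_study(seed: int, n_families: int = 100,
                              segment_sub_p: float = 0.3) -> IntronizationStudyResult:
    """Scan orthologs lacking a planted intronization intron for signatures."""
    detected = frame_checked = frame_correct = 0
    for i in range(n_families):
        family, truth = intronization_family(seed * 1000 + i, segment_sub_p)
        planted = truth.events[0]
        focal = family.focal_gene()
        marked = mark_protein(focal.protein, intron_marks(focal.model),
                              species=focal.species, accession=focal.accession)
        lacking = [
            (g.accession, g.species, g.protein)
            for g in family.orthologs()
            if not truth.presence[g.species][planted.intron_id]
        ]
        candidates = scan_with_similarity(
            marked, planted.ordinal, lacking, intron_dna_of(family, planted.ordinal)
        )
        if any(c.length_match for c in candidates):
            detected += 1
        for c in candidates:
            if c.similarity and not c.similarity.no_similarity \
                    and c.similarity.evalue <= 1e-6:
                frame_checked += 1
                if c.similarity.frame == planted.frame:
                    frame_correct += 1
    return IntronizationStudyResult(n_families, detected, frame_checked, frame_correct)


def intronization_specificity_study(seed: int,
                                    n_families: int = 100) -> tuple[int, int]:
    """False length_match rate on families whose gain is generic (inserted).

    Returns (families with a spurious length_match candidate, total).
    """
    false_hits = 0
    for i in range(n_families):
        family, truth = intronization_family(seed * 1000 + i, 0.3, mechanism=GENERIC)
        planted = truth.events[0]
        focal = family.focal_gene()
        marked = mark_protein(focal.protein, intron_marks(focal.model),
                              species=focal.species, accession=focal.accession)
        lacking = [
            (g.accession, g.species, g.protein)
            for g in family.orthologs()
            if not truth.presence[g.species][planted.intron_id]
        ]
        candidates = scan_with_similarity(
            marked, planted.ordinal, lacking, intron_dna_of(family, planted.ordinal)
        )
        if any(c.length_match for c in candidates):
            false_hits += 1
    return false_hits, n_families


# ---------------------------------------------------------------------------
# Marking study


@dataclass
class MarkingStudyResult:
    n_models: int
    n_roundtrip_ok: int
    n_marks_match: int  #: models whose (position, phase, length) marks all match truth


def marking_study(seed: int, n_models: int = 1000) -> MarkingStudyResult:
    """Mark/unmark round-trip and planted (position, phase) recovery.

    Models come from seeded 8-species families with random intron phases,
    substitution and loss, until ``n_models`` gene models are collected.
    """
    roundtrip_ok = marks_match = total = 0
    i = 0
    while total < n_models:
        config = SimulationConfig(
            n_species=8, seed=seed * 1000 + i, n_ancestral_introns=4,
            substitution_rate=0.1, loss_rate=0.1,
        )
        tree = simulate_taxonomy(config)
        family, truth = simulate_gene_family(tree, config)
        for gene in family.genes:
            if total >= n_models:
                break
            total += 1
            marks = intron_marks(gene.model)
            marked = mark_protein(gene.protein, marks, species=gene.species,
                                  accession=gene.accession)
            if marked.marked.replace("X", "") == gene.protein \
                    and marked.marked.count("X") == len(marks):
                roundtrip_ok += 1
            expected = truth.marks[gene.accession]
            observed = [(m.coding_offset, m.phase, m.intron_length) for m in marks]
            if observed == expected:
                marks_match += 1
        i += 1
    return MarkingStudyResult(total, roundtrip_ok, marks_match)


# ---------------------------------------------------------------------------
# Nested-clade fixture

_NESTED_TOPOLOGY = (
    "(((human,chimp,gorilla)hominines,((mouse,rat)rodents,(dog,cow)carnivora)boreo)"
    "placentals,((opossum,wombat)marsupials,(chicken,(frog,(zebrafish,"
    "(shark,skate)fishes)anamniotes)nonavian)outgroups)rest)root;"
)


def nested_clade_family(seed: int = 0) -> tuple[GeneFamily, SimulationTruth]:
    """A 14-species, 12-intron focal gene with one gain in a nested subclade.

    Mirrors the structure of a well-known real case: the focal gene has 12
    introns, 11 ancestral plus one gained in the (human, chimp, gorilla)
    multifurcation, where it lands as intron ordinal 8. All other species
    lack intron 8; the pipeline should report exactly that one event.
    """
    config = SimulationConfig(
        n_species=14,
        birth_model="fixed-topology",
        topology=_NESTED_TOPOLOGY,
        focal_species="human",
        seed=seed,
        protein_length=400,
        n_ancestral_introns=11,
        ancestral_intron_offsets=[90 * k for k in range(1, 12)],
        loss_rate=0.0,
        substitution_rate=0.05,
        gain_events=[
            GainSpec(clade="hominines", coding_offset=675, mechanism=GENERIC,
                     intron_length=200),
        ],
    )
    tree = simulate_taxonomy(config)
    return simulate_gene_family(tree, config)
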