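"""Mapping intron presence/absence onto the taxonomy and inferring gain clades.

For one focal intron, every species with an ortholog is *present* (carries
the intron at the aligned position), *absent* (spans the position but lacks
the intron) or *uncovered* (the ortholog does not span the position). The
gain clade is the focal-containing subtree maximizing ``R - B``, where R
counts present leaves and B absent leaves inside the clade; uncovered
leaves and species without an ortholog count in neither. Ties go to the
smallest clade (the most recent origin consistent with the data).

Candidate filters:

* **70% rule** — the intron must be absent in at least 70% of species with
  an ortholog (uncovered species count in the denominator only).
* **Boundary rule** — events are dropped when more than half of the
  non-clade species are uncovered (the intron position falls beyond the
  annotated start or end of most orthologs).
* **Paralog rescue** — a species whose ortholog lacks the intron but that
  has an intron-bearing paralog is flipped to present, and the clade search
  and 70% rule are recomputed.
* **Intron retention** — an advisory flag set when any alternative
  transcript of the focal gene has an exon spanning the intron.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import dendropy

from . import marker_alignment as ma
from .errors import NotFoundError
from .gene_model import intron_marks, mark_protein
from .marker_alignment import ABSENT, PRESENT, UNCOVERED, build_msa, presence_matrix
from .ortholog_search import best_hit_per_species, find_paralogs
from .synthetic_data import GeneFamily

logger = logging.getLogger(__name__)

Statuses = dict[str, str]  # species -> present/absent/uncovered


@dataclass
class PipelineConfig:
    evalue: float = 1e-6
    tolerance: int = 0  #: alignment-column tolerance for "same position"
    min_unaligned_frac: float = 0.70
    uncovered_cutoff: float = 0.50
    #: externally produced aligned FASTA (e.g. MUSCLE output) to use instead
    #: of the internal progressive aligner; validated against the marked rows
    alignment_file: str | None = None


@dataclass
class GainEvent:
    """One focal intron with its inferred gain clade and filter state."""

    gene: str
    ordinal: int
    clade_node: str
    clade_leaves: frozenset[str]
    R: int
    B: int
    score: int
    fraction_unaligned: float = 0.0
    passed_70pct: bool = False
    boundary_excluded: bool = False
    rescued_species: tuple[str, ...] = ()
    retention_flag: bool = False
    rejected_reason: str | None = None
    clade_age: float | None = None
    intron_length: int | None = None
    protein_index: int | None = None
    protein_length: int | None = None

    def __post_init__(self) -> None:
        if self.score != self.R - self.B:
            raise ValueError("score must equal R - B")

    @property
    def high_confidence(self) -> bool:
        return (
            self.passed_70pct
            and not self.boundary_excluded
            and self.rejected_reason is None
        )


def _node_label(node) -> str:
    return node.taxon.label if node.is_leaf() else (node.label or "<unlabeled>")


def best_gain_clade(tree: dendropy.Tree, statuses: Statuses, focal_species: str,
                    *, gene: str = "", ordinal: int = 0) -> GainEvent:
    """Find the focal-containing clade maximizing R - B in one postorder pass.

    ``statuses`` may cover any subset of leaves; leaves not covered (and
    uncovered ones) count in neither R nor B. Ties prefer the clade closest
    to the focal leaf (fewest leaves).
    """
    if statuses.get(focal_species) != PRESENT:
        raise NotFoundError(
            f"focal species {focal_species!r} must be present in the status vector"
        )
    focal_leaf = None
    for leaf in tree.leaf_node_iter():
        if leaf.taxon.label == focal_species:
            focal_leaf = leaf
            break
    if focal_leaf is None:
        raise NotFoundError(f"focal species {focal_species!r} is not a leaf of the tree")
    counts: dict[int, tuple[int, int]] = {}
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            status = statuses.get(node.taxon.label)
            counts[id(node)] = (
                1 if status == PRESENT else 0,
                1 if status == ABSENT else 0,
            )
        else:
            r = b = 0
            for child in node.child_nodes():
                cr, cb = counts[id(child)]
                r += cr
                b += cb
            counts[id(node)] = (r, b)
    # clades containing the focal leaf == ancestors of the focal leaf;
    # walking rootward and replacing only on strict improvement implements
    # the smallest-clade tie-break.
    best_node = focal_leaf
    best = counts[id(focal_leaf)]
    node = focal_leaf.parent_node
    while node is not None:
        r, b = counts[id(node)]
        if r - b > best[0] - best[1]:
            best_node, best = node, (r, b)
        node = node.parent_node
    leaves = frozenset(l.taxon.label for l in best_node.leaf_iter())
    return GainEvent(
        gene=gene, ordinal=ordinal, clade_node=_node_label(best_node),
        clade_leaves=leaves, R=best[0], B=best[1], score=best[0] - best[1],
        clade_age=getattr(best_node, "age", None),
    )


def exhaustive_best_clade(tree: dendropy.Tree, statuses: Statuses,
                          focal_species: str) -> tuple[str, frozenset[str], int]:
    """Brute-force clade search, independent of :func:`best_gain_clade`.

    Enumerates every node, rebuilds its leaf set explicitly, and scores it by
    counting statuses; used as an oracle in tests and acceptance checks.
    Returns ``(node_label, leaf_set, score)`` applying the same tie-break
    (fewest leaves, then closest to focal).
    """
    candidates = []
    for node in tree.preorder_node_iter():
        leaves = frozenset(l.taxon.label for l in node.leaf_iter())
        if focal_species not in leaves:
            continue
        r = sum(1 for sp in leaves if statuses.get(sp) == PRESENT)
        b = sum(1 for sp in leaves if statuses.get(sp) == ABSENT)
        # distance (#edges) from the focal leaf up to this node
        depth = 0
        probe = node
        while probe is not None:
            depth += 1
            probe = probe.parent_node
        candidates.append((r - b, -len(leaves), depth, _node_label(node), leaves))
    if not candidates:
        raise NotFoundError(f"{focal_species!r} not in tree")
    score, _, _, label, leaves = max(candidates, key=lambda c: (c[0], c[1], c[2]))
    return label, leaves, score


def apply_70pct_filter(event: GainEvent, statuses: Statuses,
                       focal_species: str, min_frac: float = 0.70) -> GainEvent:
    """Require the intron to be unaligned in >= 70% of orthologous species.

    The denominator is every species with a found ortholog (excluding the
    focal species); uncovered species count in the denominator but not the
    numerator. With zero orthologs the event is rejected outright.
    """
    others = [sp for sp in statuses if sp != focal_species]
    if not others:
        logger.info("%s intron %s: no orthologs found; rejected", event.gene, event.ordinal)
        return replace(event, passed_70pct=False, fraction_unaligned=0.0,
                       rejected_reason="no orthologs found")
    absent = sum(1 for sp in others if statuses[sp] == ABSENT)
    frac = absent / len(others)
    return replace(event, fraction_unaligned=frac, passed_70pct=frac >= min_frac)


def apply_boundary_filter(event: GainEvent, statuses: Statuses,
                          uncovered_cutoff: float = 0.50) -> GainEvent:
    """Exclude events whose position lies beyond most non-clade orthologs.

    The event is excluded when the fraction of uncovered species among
    non-clade species *strictly exceeds* the cutoff.
    """
    outside = [sp for sp, st in statuses.items() if sp not in event.clade_leaves]
    if not outside:
        return replace(event, boundary_excluded=False)
    uncovered = sum(1 for sp in outside if statuses[sp] == UNCOVERED)
    return replace(event, boundary_excluded=(uncovered / len(outside)) > uncovered_cutoff)


def paralog_rescue(event: GainEvent, statuses: Statuses, paralog_lookup: dict[str, str],
                   tree: dendropy.Tree, focal_species: str,
                   config: PipelineConfig | None = None) -> tuple[GainEvent, Statuses]:
    """Flip absent species with an intron-bearing paralog to present and redo.

    ``paralog_lookup`` maps species to ``"has"``/``"lacks"``/``"unknown"``.
    The clade search, 70% rule and boundary rule are recomputed on the
    updated statuses. Idempotent: rescuing twice changes nothing.
    """
    config = config or PipelineConfig()
    rescued = tuple(
        sorted(
            sp for sp, st in statuses.items()
            if st == ABSENT and paralog_lookup.get(sp) == "has"
        )
    )
    if not rescued:
        return event, statuses
    updated = dict(statuses)
    for sp in rescued:
        updated[sp] = PRESENT
    redone = best_gain_clade(tree, updated, focal_species,
                             gene=event.gene, ordinal=event.ordinal)
    redone = apply_70pct_filter(redone, updated, focal_species, config.min_unaligned_frac)
    redone = apply_boundary_filter(redone, updated, config.uncovered_cutoff)
    redone = replace(redone, rescued_species=rescued,
                     retention_flag=event.retention_flag,
                     intron_length=event.intron_length,
                     protein_index=event.protein_index,
                     protein_length=event.protein_length)
    return redone, updated


def check_intron_retention(transcript_exons: list[list[tuple[int, int]]],
                           intron_interval: tuple[int, int]) -> bool:
    """True iff any transcript has an exon fully containing the intron."""
    s, e = intron_interval
    return any(
        es <= s and e <= ee for exons in transcript_exons for es, ee in exons
    )


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class PipelineResult:
    events: list[GainEvent]
    matrix: ma.PresenceMatrix | None
    ortholog_species: list[str]
    log: list[str] = field(default_factory=list)

    @property
    def high_confidence(self) -> list[GainEvent]:
        return [e for e in self.events if e.high_confidence]


def _paralog_has_intron(focal_marked, ordinal: int, paralog_marked,
                        tolerance: int) -> bool:
    pair = build_msa([focal_marked, paralog_marked])
    matrix = presence_matrix(pair, focal_marked.accession, tolerance)
    return matrix.status(ordinal, paralog_marked.species) == PRESENT


def run_gain_pipeline(family: GeneFamily,
                      config: PipelineConfig | None = None) -> PipelineResult:
    """Run marks → orthologs → MSA → matrix → clade → filters for one family.

    Deterministic for a fixed family. Every rejection is recorded in
    ``result.log`` with the rule that caused it.
    """
    config = config or PipelineConfig()
    log: list[str] = []
    focal = family.focal_gene()
    focal_marks = intron_marks(focal.model)
    focal_marked = mark_protein(focal.protein, focal_marks,
                                species=focal.species, accession=focal.accession)
    if not focal_marks:
        return PipelineResult([], None, [], [f"{focal.accession}: no introns"])

    subjects = [
        (g.accession, g.species, g.protein) for g in family.orthologs()
    ]
    orthologs = best_hit_per_species(
        focal.protein, subjects, query=focal.accession, threshold=config.evalue
    )
    by_accession = {g.accession: g for g in family.genes}
    marked_rows = [focal_marked]
    for species in orthologs.species():
        hit = orthologs.by_species[species]
        gene = by_accession[hit.subject]
        marked_rows.append(
            mark_protein(gene.protein, intron_marks(gene.model),
                         species=species, accession=gene.accession)
        )
    if len(marked_rows) == 1:
        log.append(f"{focal.accession}: no orthologs passed the E-value threshold")
    if config.alignment_file:
        from .marker_alignment import import_alignment

        alignment = import_alignment(config.alignment_file, marked_rows)
    else:
        alignment = build_msa(marked_rows)
    matrix = presence_matrix(alignment, focal.accession, config.tolerance)

    alt_exons = family.alt_transcripts.get(focal.model.gene_id, [])
    events: list[GainEvent] = []
    for ordinal, mark in enumerate(focal_marks, start=1):
        statuses = matrix.vector(ordinal)
        event = best_gain_clade(family.tree, statuses, family.focal_species,
                                gene=focal.accession, ordinal=ordinal)
        event = replace(
            event,
            intron_length=mark.intron_length,
            protein_index=mark.protein_index,
            protein_length=len(focal.protein),
            retention_flag=check_intron_retention(alt_exons, mark.genomic_interval),
        )
        event = apply_70pct_filter(event, statuses, family.focal_species,
                                   config.min_unaligned_frac)
        event = apply_boundary_filter(event, statuses, config.uncovered_cutoff)

        # paralog rescue for species whose ortholog lacks the intron
        lookup: dict[str, str] = {}
        for species, status in statuses.items():
            if status != ABSENT or species == family.focal_species:
                continue
            chosen = orthologs.by_species[species].subject
            species_subjects = [
                (g.accession, g.species, g.protein)
                for g in family.genes if g.species == species
            ]
            paralogs = find_paralogs(
                focal.protein, species_subjects, exclude=chosen,
                query=focal.accession, threshold=config.evalue,
            )
            has = "unknown" if not paralogs else "lacks"
            for para in paralogs:
                pgene = by_accession[para.subject]
                pmarked = mark_protein(pgene.protein, intron_marks(pgene.model),
                                       species=species, accession=pgene.accession)
                if _paralog_has_intron(focal_marked, ordinal, pmarked, config.tolerance):
                    has = "has"
                    break
            lookup[species] = has
        event, statuses = paralog_rescue(event, statuses, lookup, family.tree,
                                         family.focal_species, config)
        if not event.passed_70pct and event.rejected_reason is None:
            log.append(
                f"{focal.accession} intron {ordinal}: unaligned fraction "
                f"{event.fraction_unaligned:.2f} < {config.min_unaligned_frac} (70% rule)"
            )
        if event.boundary_excluded:
            log.append(
                f"{focal.accession} intron {ordinal}: excluded, position beyond "
                f"the annotated extent of most non-clade orthologs"
            )
        if event.rejected_reason:
            log.append(f"{focal.accession} intron {ordinal}: {event.rejected_reason}")
        events.append(event)
    return PipelineResult(events, matrix, orthologs.species(), log)


def events_to_frame(events: list[GainEvent]):
    """Events as a DataFrame matching the events.tsv layout."""
    import pandas as pd

    rows = []
    for e in events:
        rows.append(
            {
                "gene": e.gene,
                "intron_ordinal": e.ordinal,
                "clade_node": e.clade_node,
                "clade_leaves": ",".join(sorted(e.clade_leaves)),
                "R": e.R,
                "B": e.B,
                "score": e.score,
                "fraction_unaligned": round(e.fraction_unaligned, 4),
                "passed_70pct": e.passed_70pct,
                "boundary_excluded": e.boundary_excluded,
                "rescued_species": ",".join(e.rescued_species),
                "retention_flag": e.retention_flag,
                "high_confidence": e.high_confidence,
                "clade_age": e.clade_age,
                "intron_length": e.intron_length,
                "protein_index": e.protein_index,
            }
        )
    return pd.DataFrame(rows)
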