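#!/usr/bin/env python
"""Scan the intronized fixture family for intronization signatures.

For the high-confidence gained intron, the two flanking exon stretches of
the focal protein are searched separately in every ortholog that lacks the
intron; a split match with a gap close to intron_length/3 residues, plus
three-frame translation similarity of the intron DNA against the gap
segment, is the intronization signature. Writes results/candidates.tsv.
"""

from pathlib import Path

from introgain.gain_inference import PipelineConfig, run_gain_pipeline
from introgain.gene_model import intron_marks, mark_protein
from introgain.intronization import candidates_to_frame, scan_with_similarity
from introgain.marker_alignment import ABSENT
from introgain.synthetic_data import load_fixtures

RESULTS = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    family = load_fixtures(RESULTS / "fixtures" / "intronized")
    result = run_gain_pipeline(family, PipelineConfig())
    focal = family.focal_gene()
    marks = intron_marks(focal.model)
    marked = mark_protein(focal.protein, marks, species=focal.species,
                          accession=focal.accession)
    by_species = {g.species: g for g in family.genes if not g.is_paralog}
    candidates = []
    for event in result.high_confidence:
        statuses = result.matrix.vector(event.ordinal)
        lacking = [
            (by_species[sp].accession, sp, by_species[sp].protein)
            for sp, status in statuses.items() if status == ABSENT
        ]
        s, e = marks[event.ordinal - 1].genomic_interval
        intron_dna = family.genomes[focal.species][s:e]
        found = scan_with_similarity(marked, event.ordinal, lacking, intron_dna)
        candidates.extend(found)
        print(f"intron {event.ordinal} ({marks[event.ordinal - 1].intron_length} nt, "
              f"expected gap {found[0].expected_gap if found else '?'} residues):")
        for cand in found:
            sim = cand.similarity
            print(f"  {cand.species}: gap {cand.gap} residues, "
                  f"length_match={cand.length_match}, "
                  f"frame={None if sim is None else sim.frame}, "
                  f"significance={None if sim is None else f'{sim.evalue:.2e}'}")
    candidates_to_frame(candidates).to_csv(RESULTS / "candidates.tsv", sep="\t",
                                           index=False)
    print(f"wrote {RESULTS / 'candidates.tsv'}")


if __name__ == "__main__":
    main()
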