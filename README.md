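# introgain

Discovery of intron gain events in a focal lineage by large-scale
comparison of intron positions across orthologous proteins.

Spliceosomal introns are mostly ancient, but new introns do appear. Given a
focal species' gene models, a collection of orthologous proteins labelled by
species, and a species taxonomy, this package finds introns that exist in
the focal gene but are missing from most orthologs, places each gain on the
taxonomy, and tests whether the gain looks like *intronization* — a stretch
of exon that became an intron, leaving the ancestral coding sequence behind
in species that never gained the intron. It is aimed at comparative
genomicists studying intron evolution, and ships a fully ground-truthed
family simulator so every stage can be validated at desk scale.

## Method

1. **Marking.** For each transcript, an intron interrupting the coding
   sequence after *c* coding nucleotides has phase *c* mod 3 and is
   projected into protein space by inserting an `X` immediately left of
   residue ⌊*c*/3⌋ + 1. Removing the `X`s recovers the protein exactly.
2. **Orthologs.** Each focal protein is searched against all subject
   proteins (internal Smith–Waterman, BLOSUM62, gaps 11/1, `X` scored 0
   against everything), keeping the single best hit per species with
   significance E ≤ 10⁻⁶, where E = *K·m·n·e^(−λS)* with ungapped
   Karlin–Altschul constants. Tables from an external BLASTP run
   (outfmt 6) can be imported instead.
3. **Alignment.** Marked proteins are multiply aligned (progressive
   aligner over a UPGMA guide tree; externally aligned FASTA can be
   imported). `X` markers that land in the same column witness a shared
   intron position.
4. **Presence matrix.** Per focal intron and species: *present* (X in the
   same column), *uncovered* (the ortholog does not span the column), else
   *absent*.
5. **Gain clade.** Among clades containing the focal species, the gain is
   assigned to the clade maximizing **R − B**, where R counts present and
   B absent species inside the clade (uncovered count in neither); ties go
   to the smallest clade.
6. **Filters.** A candidate must be absent in ≥ 70% of species with an
   ortholog; events whose position falls beyond the annotated extent of
   most non-clade orthologs are excluded; a species whose *paralog* carries
   the intron is flipped to present and everything is recomputed; intron
   retention by alternative transcripts is flagged.
7. **Intronization.** For each candidate, the two focal exon flanks are
   searched separately in each intron-lacking ortholog. A split match with
   a gap of ≈ intron_length/3 residues (tolerance max(5, 20%)), plus
   local similarity between the intron DNA translated in all three frames
   and the ortholog's gap segment, is the intronization signature.

## Worked example

The numbered scripts under `analysis/` run the whole study on simulated
families with known ground truth:

```sh
python analysis/01_simulate_families.py   # writes results/fixtures/
python analysis/02_infer_gains.py         # events.tsv + matrix.tsv per family
python analysis/03_detect_intronization.py
python analysis/04_report_figures.py      # presence-matrix SVG + histograms
```

The second script prints, for the 14-species family whose 12-intron focal
gene carries a gain planted in the (human, chimp, gorilla) multifurcation:

```
nested: 12 focal introns, 1 high-confidence gain event(s)
  intron 8: clade ['chimp', 'gorilla', 'human'] R=3 B=0 unaligned=0.85
```

— exactly the planted event: all three clade members carry intron 8 (R=3)
with no absences inside the clade (B=0), and 85% of ortholog species lack
the intron, clearing the 70% filter. The other 11 (ancestral) introns are
rejected by that filter with unaligned fraction 0. The third script, on a
family where a 117-nt exonic segment was intronized in a (human, sister)
cherry, prints:

```
intron 1 (117 nt, expected gap 39 residues):
  out1: gap 39 residues, length_match=True, frame=0, significance=5.72e-19
```

— each outgroup retains a 39-residue insert exactly where the focal intron
sits (117/3 = 39), and the intron translated in its original reading frame
still matches that insert.

The same stages are available as a CLI (`introgain simulate | infer |
intronization | report`) and as library functions (`introgain.run_gain_pipeline`
and friends) for externally supplied GFF3/FASTA/Newick inputs.

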