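# Methods

This note documents the models and procedures implemented in `introgain`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the simulation studies do and do not demonstrate.

## Intron coordinates and marking

Internally all coordinates are 0-based half-open; GFF3 is read and written
1-based inclusive. An intron's *coding offset* c counts the coding
nucleotides preceding it (UTR-only introns are ignored — the analysis lives
in protein space); its phase is c mod 3. The marker `X` is inserted
immediately left of residue ⌊c/3⌋ + 1, which unifies the phase-0 placement
("between residues c/3 and c/3+1") and the mid-codon placement ("just left
of the interrupted residue") into a single rule. Stop codons are excluded
from protein coordinates; a mark landing at or beyond the stop is rejected
as out of range rather than silently clamped, because such introns cannot
be compared in protein space at all. Raw proteins containing literal `X`
(unknown residues) are rejected at marking time: markers would become
ambiguous.

## Alignment and significance

All protein alignment uses BLOSUM62 with gap costs 11 (first gap residue)
plus 1 per additional residue, and with the `X` row and column set to 0 so
intron markers neither attract nor repel an alignment — coincident introns
co-align because their flanking residues do.

*Pairwise:* local (Smith–Waterman) alignment scores each query/subject
pair. Significance is E = K·m·n·e^(−λS) with the ungapped Karlin–Altschul
constants λ = 0.3176, K = 0.134 (configurable). Because gaps are allowed
but the constants are ungapped, E is a ranking and thresholding device,
not a calibrated statistic; the default acceptance threshold is E ≤ 10⁻⁶.
Identical 100-residue proteins score E ≪ 10⁻⁶ while unrelated length-50
sequences essentially never pass, which is all the ortholog screen needs.
For full-scale runs, 12-column BLAST tabular output can be imported
instead, with an accession→species map.

*Multiple:* the progressive aligner computes pairwise distances as
1 − fractional identity (from a fast global edit-distance alignment — a
guide-tree heuristic, not a scoring-sensitive step), clusters them with
UPGMA (ties resolved by input order, so output is deterministic for a
fixed input order), and merges profiles with an affine-gap Gotoh
profile–profile alignment whose column score is the count-weighted average
BLOSUM62 score. Terminal gaps are charged like internal ones. Iterative
refinement is deliberately out of scope; at the divergences the pipeline
targets (≲ 20% amino-acid distance) the progressive pass aligns flanks
reliably, which is what the presence calls depend on.

## Presence calls

For each focal `X` column and each ortholog row: *present* if the row has
an `X` within ±`tolerance` columns (default 0 — the strictest reading of
"same position"; the knob exists for diverged data), *uncovered* if the row
has no residues both before and after the column (the ortholog does not
span the position — the operational form of "beyond the annotated start or
end"), else *absent*. Uncovered is a third state precisely so that missing
coverage is never counted as evidence of absence.

## Gain-clade assignment

Clades containing the focal species are exactly the ancestors of the focal
leaf, so the R − B optimum is found in one postorder counting pass plus a
walk to the root (O(nodes)). R counts present, B absent leaves inside the
clade; uncovered leaves and species without an ortholog count in neither.
Ties keep the node closest to the focal leaf — the smallest clade, i.e. the
most recent origin consistent with the data, the conservative choice.
Multifurcations are handled natively (no arbitrary resolution); a
brute-force enumerator over all focal-containing clades is kept alongside
as an independent oracle and agrees exactly on hundreds of random trees.

## Filters

* **70% rule** — absent species / species with a found ortholog ≥ 0.70
  ("at least": 7 of 10 passes). Uncovered species sit in the denominator
  only. The denominator is orthologous species, not all species in the
  database. The rule is applied after clade selection, on the full
  ortholog set; the alternative order is not distinguishable from the
  published procedure, and applying it afterwards keeps the clade estimate
  independent of the candidacy decision.
* **Boundary rule** — an event is excluded when the fraction of uncovered
  species among non-clade species strictly exceeds 0.50 (configurable).
  The source procedure states only that such events were excluded; the
  0.50 cutoff is this package's operationalization and is exposed in the
  configuration.
* **Paralog rescue** — for each absent species, every passing same-species
  hit other than the chosen ortholog is marked and pairwise-aligned to the
  focal marked protein; if any paralog shows an `X` at the focal column the
  species is flipped to present and the clade search and 70% rule are
  recomputed. The operation is idempotent.
* **Intron retention** — advisory flag: any alternative transcript with an
  exon fully containing the intron interval. It annotates rather than
  rejects, since retention indicates the "gain" may be an alternative
  splicing artifact but the published procedure reports rather than drops
  such cases.

## Intronization detection

Flanks of `flank_len` = 50 residues on each side of the intron (truncated
at protein ends) are aligned separately against each intron-lacking
ortholog. Fifty residues is long enough for an unambiguous local hit at
the significance threshold yet short enough to stay inside the conserved
flanking exons. A candidate requires both flanks at E ≤ 10⁻⁶, in order,
with gap g > 0 between the matches; `length_match` holds when
|g − round(intron_length/3)| ≤ max(5, 0.2·expected), an explicit tolerance
for the indel drift behind "closely matching" lengths. The intron DNA is
translated in frames 0–2, each to its first stop; the best-scoring frame
against the ortholog's gap segment is reported (ties to the lowest frame).
Generic inserted introns leave no gap in orthologs (g = 0), so they produce
no candidates — the basis of the specificity study. Intronization into
pre-existing introns is out of scope.

## The family simulator

The generator emulates the study's inputs at desk scale, with truth tables.

* **Taxonomy**: pure-birth (Yule) trees scaled to unit root depth (branch
  lengths floored at 10⁻³ so every branch is positive), or a fixed Newick
  topology with multifurcations; node ages = distance to the deepest
  descendant leaf.
* **Sequences**: a 300-residue ancestral protein (typical vertebrate
  length) back-encoded into codons. Substitutions are amino-acid level:
  per branch, each residue substitutes with probability
  `substitution_rate × branch_length` (default rate 0.05 per site per unit
  depth — modest vertebrate-scale divergence), the replacement drawn with
  probability ∝ exp(BLOSUM62/2), then re-encoded. Intron interiors evolve
  at `intron_substitution_rate` (default 2× the protein rate;
  unconstrained sequence evolves faster), ends fixed at GT..AG.
* **Gains** are planted on the stem of a named clade. Generic gains insert
  a random GT..AG intron. Intronization gains convert a segment of the
  ancestral coding sequence (length a multiple of 3; ends overwritten to
  GT/AG at setup, with any stop codons this creates repaired) into an
  intron: the gaining clade's protein is shorter by length/3 residues and
  the intron's in-frame translation initially equals the outgroup's extra
  residues. For mid-codon (phase 1/2) events the flanking partial codons
  form a hybrid codon in the gaining lineage; those nucleotides are held
  fixed during evolution so the hybrid can never become a stop.
* **Losses** are Dollo-style per-branch Bernoulli draws (default 0.02;
  vertebrate intron loss rates are not well pinned down, so this is a
  calibration choice kept ≤ 0.05). Branches on the root-to-focal path never
  lose a *planted* intron: the discovery method queries focal introns, so
  planted events are defined conditional on surviving in the focal lineage.
* **Paralogs** (off by default) duplicate a species' gene with extra
  divergence (0.3) and flip carriage of planted generic gains with
  probability 0.5, providing positive and negative rescue fixtures.

What the generator does **not** emulate: insertions/deletions in coding
sequence (alignments of real orthologs are gappier), rate heterogeneity
across sites and lineages, codon-usage bias, splice-site evolution beyond
the GT/AG dinucleotides, transposable-element–derived introns, and
assembly/annotation error. Passing the studies therefore demonstrates the
*logic* of the pipeline — coordinates, alignment of markers, clade scoring,
filter semantics — under calibrated noise, not its robustness to every
artifact of real annotation sets.

## Study conditions

The validation studies fix these conditions once:

* *Clade-scoring oracle*: 200 random trees of ≤ 12 leaves (alternating
  binary and multifurcating), random status vectors including uncovered and
  missing species.
* *Recovery*: 50 families, 20 species, one planted generic gain,
  loss 0.05/branch, substitution 0.1. Planted clades are sampled uniformly
  among focal-containing clades covering ≤ 30% of species: gains broader
  than that are undetectable by construction (the 70% rule would always
  reject them), matching the empirical observation that discoverable gains
  are recent. Exact-recovery failures in this study are loss-erasures —
  peripheral clade members that genuinely lost the intron, making the
  smaller clade the optimum given the surviving data.
* *Intronization power/specificity*: 100 five-species families with the
  gain in a (human, sister) cherry on a unit stem branch, so the segment's
  per-site substitution probability equals `intron_substitution_rate`
  directly (0.3 for the power study, 0 for the no-noise control); protein
  divergence stays at 0.05 so flanks remain conserved, as in real cases.
* *Marking*: 1,000 gene models from 8-species families with 4 ancestral
  introns of random phase, substitution 0.1, loss 0.1.

These sizes keep the whole validation suite and the acceptance script
within tens of seconds on one CPU while leaving every rate at its study
value.

## Numerical and degenerate-input choices

Determinism everywhere: a single integer seed drives tree simulation,
sequence evolution and study sampling; alignments, guide trees and SVG
output are deterministic for fixed inputs (fixed matplotlib `svg.hashsalt`,
no timestamps). Degenerate inputs fail loudly: empty sequences, empty
families, missing accessions/ordinals/species raise typed errors naming the
offender; a transcript without CDS is skipped with a warning; zero found
orthologs rejects the event with a logged reason rather than a division by
zero. `expected_gap_residues` rounds non-multiples of 3 to the nearest
residue (ties to even); the length-match tolerance absorbs the remainder.

## Known limitations

The E-value emulation is not numerically comparable to BLAST's (different
search space and gapped statistics); imported BLAST tables should be used
when published E-values must be reproduced. The progressive aligner has no
refinement pass, so at divergences well beyond 20% presence calls will
degrade before the rest of the pipeline does. Divergence-time binning
reads node ages off the supplied tree and does no dating of its own.
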