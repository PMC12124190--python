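#!/usr/bin/env python
"""Simulate the demonstration ortholog families and write them as fixtures.

Three families are generated under results/fixtures/:

* ``clean``   — six species, no divergence, one human-specific generic gain;
  the smallest end-to-end demonstration.
* ``nested``  — fourteen species, a 12-intron focal gene with one gain
  planted in the (human, chimp, gorilla) multifurcation, mirroring the
  structure of a real nested-clade gain.
* ``intronized`` — five species where a 90-nt exonic segment became an
  intron in the (human, sister) cherry; outgroups keep it as coding
  sequence.
"""

from pathlib import Path

from introgain.studies import nested_clade_family, intronization_family
from introgain.synthetic_data import (GainSpec, SimulationConfig,
                                      simulate_gene_family, simulate_taxonomy,
                                      write_fixtures)

RESULTS = Path(__file__).resolve().parent.parent / "results" / "fixtures"


def main() -> None:
    config = SimulationConfig(
        n_species=6, seed=3, loss_rate=0.0, substitution_rate=0.0,
        gain_events=[GainSpec(clade=("human",), coding_offset=301,
                              mechanism="generic", intron_length=100)],
    )
    tree = simulate_taxonomy(config)
    family, truth = simulate_gene_family(tree, config)
    write_fixtures(family, truth, RESULTS / "clean")
    print(f"clean: {len(family.genes)} genes, "
          f"planted gain at focal intron {truth.events[0].ordinal} "
          f"in clade {sorted(truth.events[0].clade_leaves)}")

    family, truth = nested_clade_family(seed=0)
    write_fixtures(family, truth, RESULTS / "nested")
    print(f"nested: 12-intron focal gene, gain planted at ordinal "
          f"{truth.events[0].ordinal} in {sorted(truth.events[0].clade_leaves)}")

    family, truth = intronization_family(seed=5, segment_sub_p=0.1)
    write_fixtures(family, truth, RESULTS / "intronized")
    event = truth.events[0]
    print(f"intronized: {event.intron_length}-nt segment intronized at ordinal "
          f"{event.ordinal} (in-frame translation frame {event.frame}); "
          f"outgroups keep {event.intron_length // 3} extra residues")


if __name__ == "__main__":
    main()
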