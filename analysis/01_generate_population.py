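#!/usr/bin/env python
"""Generate the synthetic study population.

Two planted architecture types per sex (20 subjects each, 100-node fine
parcellation nested in 7 systems), calibrated so system-level similarity
matches the empirical regime: within-type Pearson r ~ 0.94, across-type
~ 0.91.  Writes matrix TSVs, manifest and ground-truth labels under
results/population/ and prints the realized similarity levels.
"""

from pathlib import Path

import connectotype as ct
from connectotype.synth import similarity_levels, write_population

OUT = Path(__file__).resolve().parents[1] / "results" / "population"
SEED = 7


def main():
    spec = ct.PopulationSpec(n_per_group=20, seed=SEED)
    subjects, labels = ct.generate_population(spec)
    manifest = write_population(subjects, labels, OUT)
    within, across = similarity_levels(spec)
    print(f"wrote {len(subjects)} subjects -> {manifest}")
    print(f"system-level similarity: within-type r = {within:.3f}, "
          f"across-type r = {across:.3f}")
    print("(anchors: 0.942 within, 0.906 across)")


if __name__ == "__main__":
    main()
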