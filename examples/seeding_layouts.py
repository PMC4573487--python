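"""Inspect the initial-condition generators.

Seeds the three densities and several abundance ratios in both modes and
prints the exact species counts; the well-mixed mode alternates species on
the seeding sub-grid, the random mode permutes the same exact label
multiset.
"""

import numpy as np

from socolony import seed_random, seed_wellmixed
from socolony.mechanics import Species

for density in ("high", "medium", "low"):
    for ratio in ((1, 1), (3, 1), (1, 7)):
        cells = seed_wellmixed(density, ratio, np.random.default_rng(0))
        greens = sum(1 for c in cells if c.species == Species.GREEN)
        print(f"{density:>6} {ratio[0]}:{ratio[1]}  ->  {len(cells):3d} cells, "
              f"{greens:3d} green / {len(cells) - greens:3d} red")

print("\nwell-mixed 1:1 layout is a checkerboard (first 4 rows of 16):")
cells = seed_wellmixed("high", (1, 1), np.random.default_rng(0))
for row in range(4):
    labels = ["G" if cells[row * 16 + col].species == Species.GREEN else "r"
              for col in range(16)]
    print("  " + " ".join(labels))

rng = np.random.default_rng(7)
randomized = seed_random("high", (1, 1), rng)
greens = sum(1 for c in randomized if c.species == Species.GREEN)
print(f"\nrandom mode keeps exact counts: {greens} green of {len(randomized)}")
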