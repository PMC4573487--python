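"""Verify the structure metrics on colonies of known geometry.

Builds deterministic fixture colonies (a disc of known radius, two
half-discs, twelve species stripes) and shows that the roughness/radius,
moment-of-inertia radius, and sector-counting metrics recover the
constructed ground truth.
"""

from socolony import make_fixture_colony
from socolony.metrics import (
    colony_edge,
    count_sectors,
    occupancy_lattice,
    radius_from_inertia,
    roughness_and_radius,
)

disc = make_fixture_colony("disc", n_cells=0, radius=100.0).to_cells()
lattice = occupancy_lattice(disc)
rough, r_edge = roughness_and_radius(colony_edge(lattice), disc)
r_inertia = radius_from_inertia(disc)
print(f"disc of radius 100 um ({len(disc)} cells):")
print(f"  edge-mean radius   {r_edge:.1f} um")
print(f"  inertia radius     {r_inertia:.1f} um")
print(f"  roughness          {rough:.2f} lattice units (discretization floor)")

halves = make_fixture_colony("half_discs", n_cells=3000).to_cells()
print(f"\ntwo half-discs ({len(halves)} cells): "
      f"{count_sectors(halves)} sectors (expected 2)")

stripes = make_fixture_colony("stripes", n_cells=4800, n_stripes=12).to_cells()
print(f"12 alternating stripes ({len(stripes)} cells): "
      f"{count_sectors(stripes)} sectors (expected 12)")

for n in (100, 101):
    got = count_sectors(make_fixture_colony("disc", n_cells=n).to_cells())
    print(f"single {n}-cell cluster: {got} sectors "
          f"(threshold requires MORE than 100 cells)")
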