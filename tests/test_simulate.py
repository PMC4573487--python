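"""Seeding, interaction wiring, snapshot I/O, and whole-run behavior."""

import dataclasses
import math

import numpy as np
import pandas as pd
import pytest

import socolony as sc
from socolony.config import DENSITY_COUNTS, SEED_BOX_SIZE, build_interaction, config_from_yaml, config_to_yaml
from socolony.fields import ChemicalParams
from socolony.io import Snapshot, cells_to_frame, read_snapshot, write_snapshot
from socolony.mechanics import MechParams, Species
from socolony.seeding import make_fixture_colony, seed_random, seed_wellmixed, species_counts

RATIOS = [(1, 7), (1, 3), (1, 1), (3, 1), (7, 1)]


class TestSeeding:
    @pytest.mark.parametrize("density", ["high", "medium", "low"])
    @pytest.mark.parametrize("ratio", RATIOS)
    @pytest.mark.parametrize("mode", ["wellmixed", "random"])
    def test_exact_counts_inside_seeding_square(self, density, ratio, mode, rng):
        fn = seed_wellmixed if mode == "wellmixed" else seed_random
        cells = fn(density, ratio, rng)
        assert len(cells) == DENSITY_COUNTS[density]
        greens = sum(1 for c in cells if c.species == Species.GREEN)
        expect_g, expect_r = species_counts(density, ratio)
        assert greens == expect_g
        assert len(cells) - greens == expect_r
        half = SEED_BOX_SIZE / 2
        for c in cells:
            assert -half <= c.center[0] <= half
            assert -half <= c.center[1] <= half

    @pytest.mark.parametrize(
        "density,ratio,expected",
        [("high", (1, 1), (128, 128)), ("low", (1, 1), (8, 8)), ("high", (3, 1), (192, 64))],
    )
    def test_reference_count_splits(self, density, ratio, expected):
        assert species_counts(density, ratio) == expected

    def test_wellmixed_one_to_one_is_a_checkerboard(self, rng):
        cells = seed_wellmixed("high", (1, 1), rng)
        m = 16
        for idx, c in enumerate(cells):
            i, j = divmod(idx, m)
            assert int(c.species) == (i + j) % 2

    def test_same_seed_reproduces_layout_and_seeds_differ(self):
        a = seed_random("medium", (1, 3), np.random.default_rng(5))
        b = seed_random("medium", (1, 3), np.random.default_rng(5))
        c = seed_random("medium", (1, 3), np.random.default_rng(6))
        assert cells_to_frame(a).equals(cells_to_frame(b))
        assert not cells_to_frame(a).equals(cells_to_frame(c))


class TestInteractionWiring:
    def test_control_has_no_chemicals(self):
        spec = build_interaction("control")
        assert not spec.produces_green and not spec.produces_red
        assert spec.xi_green == spec.xi_red == 0.0

    @pytest.mark.parametrize("kind,sign", [("competition", +1), ("mutualism", -1)])
    def test_symmetric_types(self, kind, sign):
        spec = build_interaction(kind, strength=1.5)
        assert spec.produces_green and spec.produces_red
        assert spec.xi_green == spec.xi_red == sign * 1.5

    def test_commensalism_and_amensalism_have_red_as_producer(self):
        com = build_interaction("commensalism", 1.0)
        am = build_interaction("amensalism", 1.0)
        for spec in (com, am):
            assert spec.produces_red and not spec.produces_green
            assert spec.xi_red == 0.0
        assert com.xi_green == -1.0
        assert am.xi_green == +1.0

    def test_parasitism_benefits_green_and_harms_red(self):
        spec = build_interaction("parasitism", 1.0)
        assert spec.produces_green and spec.produces_red
        assert spec.xi_green == -1.0 and spec.xi_red == +1.0
        single = build_interaction("parasitism", 1.0, parasitism_one_chemical=True)
        assert single.produces_green and not single.produces_red
        assert single.xi_red == +1.0

    def test_unknown_type_rejected(self):
        with pytest.raises(ValueError, match="unknown"):
            build_interaction("predation")


class TestSnapshotIO:
    def test_round_trip_identity(self, tmp_path, rng):
        cells = seed_random("medium", (1, 1), rng)
        snap = Snapshot(time=1.25, cells=cells_to_frame(cells))
        path = tmp_path / "snap.csv"
        write_snapshot(snap, path)
        back = read_snapshot(path)
        assert back.time == 1.25
        pd.testing.assert_frame_equal(back.cells, snap.cells)

    def test_empty_colony_is_header_only(self, tmp_path):
        snap = Snapshot(time=0.0, cells=cells_to_frame([]))
        path = tmp_path / "empty.csv"
        write_snapshot(snap, path)
        assert len(path.read_text().strip().splitlines()) == 2
        assert read_snapshot(path).n_cells == 0

    def test_large_table_round_trips(self, tmp_path, rng):
        n = 30_000
        frame = pd.DataFrame(
            {
                "id": np.arange(n),
                "species": np.where(rng.uniform(size=n) < 0.5, "green", "red"),
                "lineage": rng.integers(0, 256, n),
                "x": rng.normal(0, 200, n),
                "y": rng.normal(0, 200, n),
                "angle": rng.uniform(0, 2 * math.pi, n),
                "rod_length": rng.uniform(0, 3.9, n),
                "diameter": np.ones(n),
                "division_length": rng.uniform(3.1, 4.9, n),
                "growth_rate_last": rng.uniform(0, 2, n),
            }
        )
        snap = Snapshot(time=7.5, cells=frame)
        path = tmp_path / "big.csv"
        write_snapshot(snap, path)
        back = read_snapshot(path)
        pd.testing.assert_frame_equal(back.cells, frame)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.csv"
        good = Snapshot(time=0.0, cells=cells_to_frame(
            seed_wellmixed("low", (1, 1), np.random.default_rng(0))))
        write_snapshot(good, path)
        lines = path.read_text().splitlines()
        lines[5] = lines[5].rsplit(",", 1)[0]  # drop a field on data line 5
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="line 6"):
            read_snapshot(path)

    def test_missing_header_rejected(self, tmp_path):
        path = tmp_path / "noheader.csv"
        path.write_text("id,species\n")
        with pytest.raises(ValueError, match="line 1"):
            read_snapshot(path)


class TestFixtures:
    def test_disc_centers_lie_within_radius(self):
        snap = make_fixture_colony("disc", n_cells=0, radius=40.0, pitch=1.5)
        r = np.hypot(snap.cells.x, snap.cells.y)
        assert r.max() <= 40.0 + 1.5 * math.sqrt(2)
        assert snap.n_cells == pytest.approx(math.pi * 40**2 / 1.5**2, rel=0.05)

    def test_half_discs_split_species_by_side(self):
        snap = make_fixture_colony("half_discs", n_cells=400)
        left = snap.cells[snap.cells.x < 0]
        right = snap.cells[snap.cells.x > 0]
        assert set(left.species) == {"green"}
        assert set(right.species) == {"red"}

    def test_stripes_alternate_species_bands(self):
        snap = make_fixture_colony("stripes", n_cells=1200, n_stripes=6)
        assert snap.n_cells == 1200
        # x-sorted bands alternate species
        xs = sorted(set(np.round(snap.cells.x, 6)))
        assert (snap.cells.species == "green").sum() == 600


class TestConfigYaml:
    def test_full_round_trip(self, tmp_path):
        cfg = sc.SimulationConfig(
            interaction=build_interaction("mutualism", 1.2),
            density="medium",
            ratio=(3, 1),
            seed=11,
        )
        text = config_to_yaml(cfg)
        back = config_from_yaml(text)
        assert back == cfg
        path = tmp_path / "cfg.yaml"
        config_to_yaml(cfg, path)
        assert config_from_yaml(str(path)) == cfg


def _fast_config(**kw):
    base = dict(
        interaction=build_interaction("control"),
        seeding_mode="wellmixed",
        density="low",
        ratio=(1, 1),
        mech=MechParams(timestep=1e-3, mobility=2e3),
        nutrient=ChemicalParams(D=3e4, alpha_n=0.0, kappa=0.3, beta=0.0),
        domain_size=300.0,
        max_cells=120,
        seed=3,
        snapshot_every=0.5,
        density_every=4,
    )
    base.update(kw)
    return sc.SimulationConfig(**base)


class TestRun:
    def test_unlimited_nutrient_growth_is_exponential(self):
        """With nutrient consumption off (n = 1 everywhere) and a sharp
        division threshold at 4 um, the population doubling time matches the
        closed form ln((3+pi/4)/(1+pi/4)) / (g * n/(kappa+n))."""
        from socolony.growth import DivisionRule

        cfg = _fast_config(max_cells=128, division=DivisionRule(sd=1e-9))
        snaps, met = sc.run(cfg, with_metrics=False)
        times = np.array([s.time for s in snaps])
        counts = np.array([s.n_cells for s in snaps])
        window = (counts >= 32) & (counts <= 128)
        slope = np.polyfit(times[window], np.log(counts[window]), 1)[0]
        doubling = math.log(2) / slope
        monod = 1.0 / (1.0 + 0.3)
        expected = math.log((3 + math.pi / 4) / (1 + math.pi / 4)) / (0.5 * monod)
        assert doubling == pytest.approx(expected, rel=0.10)

    def test_exit_rule_and_monotone_growth(self):
        snaps, met = sc.run(_fast_config(max_cells=100), with_metrics=True)
        counts = [s.n_cells for s in snaps]
        assert all(b >= a for a, b in zip(counts, counts[1:]))
        assert 100 <= counts[-1] < 200  # at most one step's divisions over the exit
        assert met.lineages.max() <= 16

    def test_identical_config_and_seed_are_bit_identical(self):
        s1, _ = sc.run(_fast_config(), with_metrics=False)
        s2, _ = sc.run(_fast_config(), with_metrics=False)
        pd.testing.assert_frame_equal(s1[-1].cells, s2[-1].cells)

    def test_different_seeds_diverge(self):
        s1, _ = sc.run(_fast_config(seed=3), with_metrics=False)
        s2, _ = sc.run(_fast_config(seed=4), with_metrics=False)
        assert not s1[-1].cells.equals(s2[-1].cells)

    def test_quasi_steady_chemistry_satisfies_the_stationary_equation(self):
        """With the quasi-steady option the nutrient field solves the
        discrete steady balance D lap(n) = alpha rho n/(kappa+n)."""
        cfg = _fast_config(
            nutrient=ChemicalParams(D=3e4, alpha_n=60.0, kappa=0.3, beta=0.0),
            domain_size=100.0,
            max_cells=10_000,  # exit on max_steps instead
            quasi_steady_chem=True,
        )
        cfg = dataclasses.replace(cfg, max_steps=25)
        snaps, _ = sc.run(cfg, with_metrics=False)
        nut = snaps[-1].fields["nutrient"]
        rho = snaps[-1].fields["density"]
        g, h = nut.grid, nut.spacing
        lap = (g[2:, 1:-1] + g[:-2, 1:-1] + g[1:-1, 2:] + g[1:-1, :-2] - 4 * g[1:-1, 1:-1]) / h**2
        uptake = 60.0 * rho.grid[1:-1, 1:-1] * g[1:-1, 1:-1] / (0.3 + g[1:-1, 1:-1])
        residual = np.abs(3e4 * lap - uptake).max()
        assert residual < 0.05 * uptake.max()

    def test_color_symmetry_mirrors_trajectory_exactly(self):
        """Swapping species labels and the interaction wiring yields the
        mirrored colony, cell for cell."""
        inter = build_interaction("amensalism", 1.0)
        mirrored = sc.InteractionSpec(
            type=inter.type,
            produces_green=inter.produces_red,
            produces_red=inter.produces_green,
            xi_green=inter.xi_red,
            xi_red=inter.xi_green,
        )
        cfg_a = _fast_config(
            interaction=inter,
            nutrient=ChemicalParams(D=3e4, alpha_n=60.0, kappa=0.3, beta=0.0),
            max_cells=200,
        )
        cfg_b = dataclasses.replace(cfg_a, interaction=mirrored, swap_species=True)
        sa, _ = sc.run(cfg_a, with_metrics=False)
        sb, _ = sc.run(cfg_b, with_metrics=False)
        fa, fb = sa[-1].cells, sb[-1].cells
        swapped = fb.assign(species=fb.species.map({"green": "red", "red": "green"}))
        pd.testing.assert_frame_equal(fa, swapped)
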