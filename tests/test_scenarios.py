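"""Inoculum generation, experiment presets, VTK/CSV output, colony structure."""

import numpy as np
import pytest
from click.testing import CliRunner

import qsbiofilm as qb
from qsbiofilm.cli import main as cli_main
from qsbiofilm.inoculum import InoculumSpec, generate_inoculum, resolve_pockets
from qsbiofilm.params import ConfigError
from qsbiofilm.presets import (PRESET_GROUPS, preset_constant_dispersal,
                               preset_hollowing, preset_k5_sweep,
                               preset_reattachment_corners, preset_tau_sweep)
from qsbiofilm.structure import hollowness_profile
from qsbiofilm.vtkio import read_fields, snapshot_filename, write_fields


class TestInoculum:
    def test_seeded_determinism(self, params):
        grid = qb.Grid(nx=64, ny=32, L=params.L, H=params.H)
        spec = InoculumSpec(n_colonies=6, seed=123)
        a = generate_inoculum(spec, grid, params)
        b = generate_inoculum(spec, grid, params)
        assert np.array_equal(a.M, b.M)

    def test_different_seeds_differ(self, params):
        grid = qb.Grid(nx=64, ny=32, L=params.L, H=params.H)
        a = generate_inoculum(InoculumSpec(seed=1), grid, params)
        b = generate_inoculum(InoculumSpec(seed=2), grid, params)
        assert not np.array_equal(a.M, b.M)

    def test_colonies_sit_on_substratum_with_uniform_density(self, params):
        from scipy import ndimage
        grid = qb.Grid(nx=128, ny=64, L=params.L, H=params.H)
        st = generate_inoculum(InoculumSpec(n_colonies=6, density=0.3, seed=11),
                               grid, params)
        nz = st.M[st.M > 0]
        assert nz.size > 0 and np.all(nz == 0.3)
        labels, n = ndimage.label(st.M > 0)
        for cid in range(1, n + 1):
            rows = np.nonzero(labels == cid)[0]
            assert rows.min() == 0  # every component touches the bottom row
        # initial fields: bulk nutrient, no dispersed cells, no signal
        assert np.all(st.C == params.C_inf)
        assert np.all(st.N == 0) and np.all(st.A == 0)

    def test_inoculated_area_is_small(self, params):
        grid = qb.Grid(nx=128, ny=64, L=params.L, H=params.H)
        st = generate_inoculum(InoculumSpec(n_colonies=6, seed=11), grid, params)
        assert (st.M > 0).mean() < 0.05

    def test_empty_spec_gives_sterile_domain(self, params, small_grid):
        st = generate_inoculum(InoculumSpec(n_colonies=0, seed=1), small_grid, params)
        assert np.all(st.M == 0)

    def test_explicit_pockets_and_overlap_union(self, params, small_grid):
        spec = InoculumSpec(pockets=[(1e-3, 4e-4, 2e-4, 0.3),
                                     (1.1e-3, 4e-4, 2e-4, 0.5)])
        st = generate_inoculum(spec, small_grid, params)
        assert set(np.unique(st.M)) <= {0.0, 0.3, 0.5}
        assert st.M.max() == 0.5  # overlap takes the max density

    def test_pocket_outside_domain_rejected(self, params, small_grid):
        spec = InoculumSpec(pockets=[(params.L, 4e-4, 2e-4, 0.3)])
        with pytest.raises(ConfigError, match="pocket"):
            generate_inoculum(spec, small_grid, params)

    def test_resolved_pockets_deterministic(self, params):
        a = resolve_pockets(InoculumSpec(seed=5), params)
        b = resolve_pockets(InoculumSpec(seed=5), params)
        assert a == b


class TestPresets:
    def test_tau_sweep_has_seven_thresholds_plus_control(self):
        presets = preset_tau_sweep(seed=1)
        assert len(presets) == 8
        taus = [p.overrides.get("tau") for p in presets[:-1]]
        assert taus == [10.0, 20.0, 30.0, 40.0, 50.0, 60.0, 70.0]
        control = presets[-1].parameters()
        assert control.alpha == 0.0 and control.beta == 0.0

    def test_constant_dispersal_pair(self):
        presets = preset_constant_dispersal(seed=1)
        assert len(presets) == 2
        p0, p50 = (p.parameters() for p in presets)
        assert p0.tau == 0.0 and p50.tau == 50.0
        assert p0.eta1 == p50.eta1 == 2.4

    def test_reattachment_corners_exactly_four(self):
        presets = preset_reattachment_corners(seed=1)
        combos = {(p.parameters().tau, p.parameters().eta1) for p in presets}
        assert combos == {(70.0, 4.2), (70.0, 0.6), (10.0, 4.2), (10.0, 0.6)}

    def test_k5_sweep_values(self):
        k5s = [p.parameters().k5 for p in preset_k5_sweep(seed=1)]
        assert k5s == pytest.approx([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7])

    def test_hollowing_pair_shares_inoculum(self):
        lo, hi = preset_hollowing(seed=3)
        assert lo.parameters().tau == 20.0 and hi.parameters().tau == 60.0
        assert lo.inoculum is hi.inoculum

    def test_eta2_follows_eta1_in_overrides(self):
        for preset in PRESET_GROUPS["reattachment_corners"](seed=1):
            p = preset.parameters()
            assert p.eta2 == pytest.approx(0.5 * p.eta1)

    def test_materialize_is_seed_deterministic(self):
        preset = preset_tau_sweep(seed=None)[0]
        _, _, _, st1 = preset.materialize(seed=7, nx=32, ny=16)
        _, _, _, st2 = preset.materialize(seed=7, nx=32, ny=16)
        assert np.array_equal(st1.M, st2.M)


class TestVTKOutput:
    def test_round_trip(self, params, small_grid, seeded_state, tmp_path):
        seeded_state.t = 1.25
        path = tmp_path / "snap.vtk"
        write_fields(seeded_state, small_grid, path)
        back, grid2 = read_fields(path)
        assert back.t == 1.25
        assert grid2.shape == small_grid.shape
        for name in ("M", "N", "C", "A"):
            assert np.array_equal(getattr(back, name), getattr(seeded_state, name)), name

    def test_header_is_legacy_rectilinear(self, params, small_grid, seeded_state, tmp_path):
        path = tmp_path / "snap.vtk"
        write_fields(seeded_state, small_grid, path)
        lines = path.read_text().splitlines()
        assert lines[0].startswith("# vtk DataFile")
        assert "DATASET RECTILINEAR_GRID" in lines
        assert f"CELL_DATA {small_grid.n_cells}" in lines

    def test_snapshot_names_sort_temporally(self):
        names = [snapshot_filename(i) for i in (0, 2, 10, 100000)]
        assert names == sorted(names)


class TestHollowness:
    def test_uniform_disc_not_hollow(self, params):
        grid = qb.Grid(nx=64, ny=32, L=params.L, H=params.H)
        X, Y = grid.meshgrid()
        M = np.where((X - params.L / 2)**2 + Y**2 < (0.5e-3)**2, 0.6, 0.0)
        prof = hollowness_profile(M, grid)
        assert len(prof) == 1
        assert prof[0].hollow is False
        assert prof[0].core_mean == pytest.approx(prof[0].rim_mean)

    def test_annulus_flagged_hollow(self, params):
        grid = qb.Grid(nx=64, ny=32, L=params.L, H=params.H)
        X, Y = grid.meshgrid()
        r2 = (X - params.L / 2)**2 + Y**2
        M = np.where(r2 < (0.6e-3)**2, 0.9, 0.0)
        M = np.where(r2 < (0.35e-3)**2, 0.1, M)
        prof = hollowness_profile(M, grid)
        assert prof[0].hollow is True
        assert prof[0].core_mean < prof[0].rim_mean

    def test_too_small_colony_gives_marker(self, params, small_grid):
        M = np.zeros(small_grid.shape)
        M[0:2, 0:2] = 0.5
        prof = hollowness_profile(M, small_grid)
        assert np.isnan(prof[0].core_mean)
        assert prof[0].hollow is None


class TestCLI:
    def test_run_command_produces_outputs(self, tmp_path):
        cfg = tmp_path / "tiny.yaml"
        cfg.write_text(
            "model:\n  tau: 20.0\nnumerics:\n"
            "  nx: 16\n  ny: 8\n  t_end: 0.004\n  dt: 0.001\n  output_every: 0.002\n"
            "inoculum:\n  n_colonies: 2\n  seed: 3\n"
        )
        outdir = tmp_path / "out"
        runner = CliRunner()
        result = runner.invoke(cli_main, ["--quiet", "run", "--config", str(cfg),
                                          "--outdir", str(outdir)])
        assert result.exit_code == 0, result.output
        assert (outdir / "timeseries.csv").exists()
        assert (outdir / "run.json").exists()
        snaps = sorted(outdir.glob("fields_*.vtk"))
        assert len(snaps) >= 2
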