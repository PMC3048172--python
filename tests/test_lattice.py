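import numpy as np
import pytest

import nephrosim as ns
from nephrosim.cytokinetics import StepLedger
from nephrosim.lattice import _connected, rebalance, scan_update


class TestInitialization:
    def test_volume_to_gc_arithmetic(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=1.0)
        assert mesh.gc_count == 1000
        assert mesh.nbc == pytest.approx(1e6)
        totals = [gc.total() for gc in mesh.cells.values()]
        np.testing.assert_allclose(totals, 1e6, rtol=1e-9)

    def test_initial_growth_fraction_matches_equilibrium(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.01)
        counts = mesh.aggregate_counts()
        gf = 100 * counts["proliferating"] / counts["total"]
        comp, _ = ns.equilibrium_composition(ref_params)
        assert gf == pytest.approx(comp.proliferating, abs=1e-6)
        assert gf == pytest.approx(14, abs=4)

    def test_no_composition_transient_in_free_growth(self, ref_params):
        result = ns.run_simulation(ref_params, horizon_h=48)
        c0 = ns.composition_at(result, 0).as_dict()
        c48 = ns.composition_at(result, 48).as_dict()
        for key in c0:
            assert abs(c48[key] - c0[key]) < 1.0, key

    def test_mask_initialization(self, ref_params):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, :] = True
        mesh = ns.initialize_mesh(ref_params, mask=mask)
        assert mesh.gc_count == 3

    def test_disconnected_mask_rejected(self, ref_params):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[0, 0, 0] = mask[2, 2, 2] = True
        with pytest.raises(ValueError, match="connected"):
            ns.initialize_mesh(ref_params, mask=mask)

    def test_invalid_volume_rejected(self, ref_params):
        with pytest.raises(ValueError):
            ns.initialize_mesh(ref_params, initial_volume_cm3=-1.0)

    def test_connectivity_helper(self):
        assert _connected({(0, 0, 0), (0, 0, 1)})
        assert not _connected({(0, 0, 0), (0, 0, 2)})


class TestScanUpdate:
    def test_identical_gcs_stay_identical(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.008)
        scan_update(mesh)
        cores = [gc.core for gc in mesh.cells.values()]
        for c in cores[1:]:
            np.testing.assert_array_equal(c, cores[0])

    def test_aggregate_ledger_matches_wellmixed_step(self, ref_params):
        # linearity: stepping GCs independently and summing equals one
        # step of the summed (well-mixed) state
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.008)
        for i, coord in enumerate(sorted(mesh.cells)):
            mesh.cells[coord] = mesh.cells[coord] * (1.0 + 0.1 * i)
        summed = mesh.aggregate_state()
        expected, expected_led = ns.step_state(summed, ref_params)
        led = scan_update(mesh)
        np.testing.assert_allclose(mesh.aggregate_state().core, expected.core, rtol=1e-9)
        assert led.births == pytest.approx(expected_led.births, rel=1e-9)
        assert led.clearances == pytest.approx(expected_led.clearances, rel=1e-9)

    def test_empty_mesh_noop(self, ref_params):
        mesh = ns.TumorMesh(
            cells={}, params=ref_params, layout=ns.StateLayout(ref_params)
        )
        assert isinstance(scan_update(mesh), StepLedger)
        assert mesh.gc_count == 0

    def test_per_region_override_applied(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.002)
        coords = sorted(mesh.cells)
        mesh.set_override(coords[0], ref_params.replace(R_A=0.5))
        scan_update(mesh)
        # the high-apoptosis region loses cells faster
        assert mesh.cells[coords[0]].total() < mesh.cells[coords[1]].total()

    def test_override_cannot_change_layout(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.002)
        with pytest.raises(ValueError, match="durations"):
            mesh.set_override(sorted(mesh.cells)[0], ref_params.replace(Tc=40.0))


class TestRebalance:
    def test_idempotent_within_thresholds(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.008)
        before = {c: gc.core.copy() for c, gc in mesh.cells.items()}
        assert rebalance(mesh) == []
        assert set(mesh.cells) == set(before)
        for c in before:
            np.testing.assert_array_equal(mesh.cells[c].core, before[c])

    def test_overfull_gc_splits_conserving_cells(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.001)
        (coord,) = mesh.cells
        mesh.cells[coord] = mesh.cells[coord] * 2.0  # 2 x nbc > 1.5 x nbc
        events = rebalance(mesh)
        assert mesh.gc_count == 2
        assert any(e[0] == "create" for e in events)
        assert mesh.total() == pytest.approx(2 * mesh.nbc, rel=1e-12)

    def test_underfull_gc_dissolves_into_neighbor(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.002)
        c0, c1 = sorted(mesh.cells)
        mesh.cells[c0] = mesh.cells[c0] * 0.3  # below 0.5 x nbc
        total_before = mesh.total()
        events = rebalance(mesh)
        assert mesh.gc_count == 1
        assert any(e[0] == "delete" for e in events)
        assert mesh.total() == pytest.approx(total_before, rel=1e-12)

    def test_rebalance_conserves_every_compartment(self, ref_params):
        mesh = ns.initialize_mesh(ref_params, initial_volume_cm3=0.008)
        rng = np.random.default_rng(0)
        for coord in sorted(mesh.cells):
            mesh.cells[coord] = mesh.cells[coord] * rng.uniform(0.2, 2.5)
        before = mesh.aggregate_state()
        rebalance(mesh)
        after = mesh.aggregate_state()
        np.testing.assert_allclose(after.core, before.core, rtol=1e-12)
        for gc in mesh.cells.values():
            assert 0.5 * mesh.nbc <= gc.total() <= 1.5 * mesh.nbc

    def test_population_and_mesh_volume_agree_without_rebalancing(self, ref_params):
        # over a short free-growth window no GC crosses the thresholds, so
        # mesh volume and population-derived volume agree within one GC
        result = ns.run_simulation(
            ref_params, initial_volume_cm3=0.008, mode="lattice", horizon_h=100
        )
        vol_pop = result.data["volume_cm3"]
        vol_mesh = result.data["gc_count"] * result.gc_volume
        assert (np.abs(vol_mesh - vol_pop) <= result.gc_volume).all()


class TestModes:
    def test_lattice_matches_wellmixed_under_therapy(self, ref_params):
        sched = ns.default_siop_schedule(params=ref_params)
        kwargs = dict(schedule=sched, initial_volume_cm3=0.027, horizon_h=648)
        wm = ns.run_simulation(ref_params, mode="wellmixed", **kwargs)
        lat = ns.run_simulation(ref_params, mode="lattice", **kwargs)
        days = np.arange(0, 649, 24)
        wmx = wm.data.set_index("hour").loc[days, "total"].to_numpy()
        ltx = lat.data.set_index("hour").loc[days, "total"].to_numpy()
        np.testing.assert_allclose(ltx, wmx, rtol=0.01)

    def test_shrinking_tumor_loses_gcs(self, ref_params):
        sched = ns.default_siop_schedule(params=ref_params)
        lat = ns.run_simulation(
            ref_params, schedule=sched, initial_volume_cm3=0.027,
            mode="lattice", horizon_h=648,
        )
        gcs = lat.data["gc_count"].to_numpy()
        assert gcs[-1] < gcs[0]
        after_first_dose = gcs[72:]
        assert (np.diff(after_first_dose) <= 0).all()

    def test_free_growth_volume_monotone(self, ref_params):
        result = ns.run_simulation(ref_params, horizon_h=500)
        totals = result.data["total"].to_numpy()
        assert (np.diff(totals) >= 0).all()

    def test_horizon_before_last_dose_rejected(self, ref_params):
        sched = ns.default_siop_schedule(params=ref_params)
        with pytest.raises(ValueError, match="horizon"):
            ns.run_simulation(ref_params, schedule=sched, horizon_h=100)
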