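import numpy as np
import pytest

import nephrosim as ns
from nephrosim.parameters import PHASES

from conftest import random_state


def uniform_cycling_state(layout, lineage="stem", mass=1000.0):
    """mass cells spread uniformly over the cycling bins of one lineage."""
    state = ns.CellStateVector.zeros(layout)
    key0 = (lineage, PHASES[0]) if lineage == "stem" else (lineage, 1, PHASES[0])
    bins = [
        sl for k, sl in layout.slices.items()
        if isinstance(k, tuple) and k[0] == lineage and k[-1] in PHASES
        and (lineage == "stem" or k[1] == 1)
    ]
    n = sum(sl.stop - sl.start for sl in bins)
    for sl in bins:
        state.core[sl] = mass / n
    assert key0 in layout.slices
    return state


class TestSchedule:
    def test_default_regimen_timing(self):
        sched = ns.default_siop_schedule()
        assert len(sched.administrations) == 4
        assert [a.time_h / 24 for a in sched.administrations] == [3, 10, 17, 24]
        assert sched.horizon_h == 28 * 24

    def test_default_regimen_drug_pattern(self):
        # vincristine weekly; actinomycin-D in weeks 1 and 3 only
        sched = ns.default_siop_schedule()
        assert [a.ckr_vcr for a in sched.administrations] == [0.3] * 4
        assert [a.ckr_act for a in sched.administrations] == [0.2, 0.0, 0.2, 0.0]

    def test_schedule_validation(self):
        with pytest.raises(ValueError):
            ns.TreatmentSchedule(
                administrations=(
                    ns.DrugAdministration(10.0),
                    ns.DrugAdministration(10.0),
                )
            )
        with pytest.raises(ValueError):
            ns.TreatmentSchedule(
                administrations=(ns.DrugAdministration(10_000.0),), horizon_h=672
            )
        with pytest.raises(ValueError):
            ns.DrugAdministration(10.0, ckr_vcr=1.5)


class TestMarking:
    def test_combined_marking_splits_by_drug(self, ref_layout):
        state = uniform_cycling_state(ref_layout)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.3, ckr_act=0.2)
        new, marked = ns.apply_administration(state, dose)
        assert marked["vcr"] == pytest.approx(300.0)
        assert marked["act"] == pytest.approx(200.0)
        assert new.hit_total() == pytest.approx(500.0)
        assert new.core.sum() == pytest.approx(500.0)

    def test_additive_effect_capped_at_one(self, ref_layout):
        state = uniform_cycling_state(ref_layout)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.7, ckr_act=0.6)
        new, _ = ns.apply_administration(state, dose)
        assert new.hit_total() == pytest.approx(1000.0)
        assert new.core.sum() == pytest.approx(0.0, abs=1e-9)

    def test_dormant_cells_only_hit_by_actinomycin(self, ref_layout):
        state = ns.CellStateVector.zeros(ref_layout)
        g0 = ref_layout.slices[("stem", "G0")]
        state.core[g0] = 1000.0 / (g0.stop - g0.start)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.3, ckr_act=0.2)
        new, marked = ns.apply_administration(state, dose)
        assert marked["act_g0"] == pytest.approx(200.0)
        assert new.core[g0].sum() == pytest.approx(800.0)

    def test_vincristine_alone_never_marks_dormant(self, ref_layout):
        state = random_state(ref_layout, 2)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.5, ckr_act=0.0)
        new, marked = ns.apply_administration(state, dose)
        assert marked["act_g0"] == 0.0
        np.testing.assert_array_equal(
            new.core[ref_layout.stem_g0], state.core[ref_layout.stem_g0]
        )
        np.testing.assert_array_equal(
            new.core[ref_layout.limp_g0], state.core[ref_layout.limp_g0]
        )

    def test_null_dose_is_identity(self, ref_layout):
        state = random_state(ref_layout, 4)
        new, marked = ns.apply_administration(state, ns.DrugAdministration(0.0))
        np.testing.assert_array_equal(new.core, state.core)
        assert new.hit_total() == 0.0
        assert all(v == 0.0 for v in marked.values())

    def test_marking_conserves_total_count(self, ref_layout):
        state = random_state(ref_layout, 9)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.36, ckr_act=0.34)
        new, _ = ns.apply_administration(state, dose)
        assert new.total() == pytest.approx(state.total(), rel=1e-12)

    def test_differentiated_and_dead_unaffected(self, ref_layout):
        state = random_state(ref_layout, 12)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.3, ckr_act=0.2)
        new, _ = ns.apply_administration(state, dose)
        assert new.core[ref_layout.diff_index] == state.core[ref_layout.diff_index]
        np.testing.assert_array_equal(new.core[ref_layout.apo], state.core[ref_layout.apo])
        np.testing.assert_array_equal(new.core[ref_layout.nec], state.core[ref_layout.nec])


class TestHitCellFate:
    def test_vcr_hit_at_end_of_m_dies_next_step(self, ref_params, ref_layout):
        state = ns.CellStateVector.zeros(ref_layout)
        state.hit[("stem", "vcr")]["M"][-1] = 100.0
        new, died = ns.step_hit_cells(state)
        assert died == pytest.approx(100.0)
        assert new.core[ref_layout.apo.start] == pytest.approx(100.0)
        assert new.hit_total() == 0.0

    def test_act_hit_dies_at_end_of_s(self, ref_params, ref_layout):
        state = ns.CellStateVector.zeros(ref_layout)
        state.hit[("limp", "act")]["S"][-1] = 50.0
        new, died = ns.step_hit_cells(state)
        assert died == pytest.approx(50.0)

    def test_act_hit_dormant_traverses_rudimentary_g1_s(self, ref_params, ref_layout):
        # a marked dormant cohort leaves G0 on the next step and dies at
        # the end of the rudimentary G1 + S
        state = ns.CellStateVector.zeros(ref_layout)
        state.hit_g0["stem"] = 100.0
        d = ref_layout.dur
        total_deaths = 0.0
        for _ in range(1 + d["G1"] + d["S"]):
            state, died = ns.step_hit_cells(state)
            total_deaths += died
        assert total_deaths == pytest.approx(100.0)
        assert state.hit_total() == pytest.approx(0.0)

    def test_vcr_hit_traverses_remaining_cycle(self, ref_params, ref_layout):
        state = ns.CellStateVector.zeros(ref_layout)
        state.hit[("stem", "vcr")]["G1"][0] = 10.0
        d = ref_layout.dur
        remaining = sum(d.values())  # from G1 age 0 to end of M
        for i in range(remaining):
            state, died = ns.step_hit_cells(state)
        assert died == pytest.approx(10.0)

    def test_hit_aging_conserves_count(self, ref_params, ref_layout):
        state = random_state(ref_layout, 21)
        dose = ns.DrugAdministration(0.0, ckr_vcr=0.3, ckr_act=0.2)
        state, _ = ns.apply_administration(state, dose)
        before = state.total()
        new, _ = ns.step_hit_cells(state)
        # deaths move cells to the apoptotic pool; nothing leaves the tumor
        assert new.total() == pytest.approx(before, rel=1e-12)


class TestTreatmentTrajectories:
    def test_zero_ckr_schedule_identical_to_free_growth(self, ref_params):
        sched = ns.default_siop_schedule(ckr_vcr=0.0, ckr_act=0.0)
        treated = ns.run_simulation(ref_params, schedule=sched, horizon_h=672)
        free = ns.run_simulation(ref_params, horizon_h=672)
        np.testing.assert_array_equal(
            treated.data["total"].to_numpy(), free.data["total"].to_numpy()
        )

    def test_reduction_nondecreasing_in_ckr_total(self, ref_params):
        reductions = []
        for scale in (0.5, 1.0, 1.4):
            sched = ns.default_siop_schedule(ckr_vcr=0.3 * scale, ckr_act=0.2 * scale)
            res = ns.run_simulation(ref_params, schedule=sched, horizon_h=648)
            reductions.append(
                ns.volume_reduction(res.volume_at(0), res.volume_at(648))
            )
        assert reductions == sorted(reductions)
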