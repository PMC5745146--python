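"""Coupled well simulations: conservation, equilibria, dosing modes."""

import numpy as np
import pytest

from biokin import fixtures as fx
from biokin.engine import (
    ExposureConfig,
    SimulationContext,
    TableSet,
    core_model,
    mass_balance,
    simulate_repeated_exposure,
    simulate_single_exposure,
)
from biokin.fate import FateConfig

NEC, KT = 5e-5, 500.0
N0 = 1e5


class TestCoreModel:
    def test_zero_concentration_full_viability(self, inert_context):
        res = core_model(0.0, 0.0, N0, NEC, KT, inert_context)
        assert res.viability_end == 1.0

    def test_zero_kt_full_viability(self, inert_context):
        res = core_model(1e-6, 0.0, N0, NEC, 0.0, inert_context)
        assert res.viability_end == pytest.approx(1.0, abs=1e-7)

    def test_equilibrium_mode_matches_two_pool_partition(self):
        """Non-volatile, non-degrading, non-sorbing chemical in
        instantaneous-equilibrium mode: the end-state medium/cell split
        equals the algebraic two-pool solution."""
        ctx = fx.make_context(equilibrium_uptake=True)
        ctx.coeffs = ctx.coeffs.__class__(
            kaw=0.0, d_water=ctx.coeffs.d_water, d_air=ctx.coeffs.d_air,
            k_vol=0.0, k_plastic_on=0.0, k_plastic_off=0.0,
            k_cell_water=ctx.coeffs.k_cell_water)
        c0 = 5e-7
        res = core_model(c0, 0.0, N0, NEC, 0.0, ctx)
        last = res.frame.iloc[-1]
        a_total = c0 * ctx.assay_volume
        v_cells_eff = (last["n_total"] * ctx.cell.cell_volume
                       * ctx.coeffs.k_cell_water)
        expected_dissolved = a_total * ctx.assay_volume / (
            ctx.assay_volume + v_cells_eff)
        assert last["a_dissolved"] == pytest.approx(expected_dissolved,
                                                    rel=1e-9)
        assert last["a_cells"] == pytest.approx(a_total - expected_dissolved,
                                                rel=1e-9)

    def test_kinetic_uptake_conserves_medium_cell_exchange(self,
                                                           inert_context):
        """Intracellular gain equals medium loss for an inert chemical
        below NEC (no degradation, volatilization or death release)."""
        res = core_model(5e-8, 0.0, N0, 1.0, KT, inert_context)
        f = res.frame
        gain = f["a_cells"].iloc[-1] - f["a_cells"].iloc[0]
        loss = f["a_dissolved"].iloc[0] - f["a_dissolved"].iloc[-1]
        assert gain == pytest.approx(loss, rel=1e-9)

    def test_fast_path_matches_full_trajectory(self, inert_context):
        full = core_model(2.8e-7, 0.0, N0, NEC, KT, inert_context)
        fast = core_model(2.8e-7, 0.0, N0, NEC, KT, inert_context,
                          end_only=True)
        assert fast.viability_end == pytest.approx(full.viability_end,
                                                   rel=1e-7)

    def test_negative_parameters_rejected(self, inert_context):
        with pytest.raises(ValueError):
            core_model(1e-7, 0.0, N0, -1.0, KT, inert_context)

    def test_control_doubles_on_schedule(self):
        """The chemical-free population doubles in one nominal doubling
        time, within 1%."""
        ctx = fx.make_context(total_time=24.0)
        res = core_model(0.0, 0.0, N0, 0.0, 0.0, ctx)
        assert res.n_total_end == pytest.approx(2 * N0, rel=0.01)


class TestRhsComposition:
    def test_fused_rhs_equals_module_composition(self, inert_context):
        """The engine's fused derivative equals fate_derivatives +
        uptake + cycle_derivatives composed by hand."""
        from biokin import cells as cd
        from biokin.engine import _rhs_factory
        from biokin.fate import fate_derivatives

        ctx = fx.make_context(kind="volatile")
        chem = ctx.chem.model_copy(update={"k_deg_water": 0.05})
        ctx = SimulationContext(chem=chem, cell=ctx.cell, plate=fx.make_plate(),
                                assay_volume=0.2, total_time=48.0)
        rhs = _rhs_factory(ctx, NEC, KT)
        y = np.array([4e-8, 1e-9, 2e-10, 3e-9, 0.0, 0.0,
                      4e4, 3e4, 2e4, 1e4])
        got = rhs(0.0, y)

        n = y[6:10]
        n_total = n.sum()
        c_cell = cd.intracellular_concentration(y[3], n_total, ctx.cell,
                                                ctx.chem)
        dd, dh, dp, dg = fate_derivatives(y[0], y[1], y[2], ctx.coeffs,
                                          ctx.chem, ctx.plate, 0.2,
                                          ctx.fate_config)
        k_tox = cd.toxic_rate(c_cell, fx.make_toxicity("c", "l", NEC, KT))
        upt = cd.uptake_flux(y[0] / 0.2, c_cell, ctx.chem, ctx.cell,
                             ctx.coeffs, n_total, ctx.fate_config.k_up)
        deaths = float(((np.asarray(ctx.cell.stage_mortality) + k_tox) * n).sum())
        release = deaths * y[3] / n_total
        dn = cd.cycle_derivatives(n, ctx.cell, k_tox)
        expected = np.array([dd - upt + release, dh, dp, upt - release,
                             dg, 0.0, *dn])
        np.testing.assert_allclose(got, expected, rtol=1e-12, atol=1e-30)


class TestMassBalance:
    @pytest.mark.parametrize("i_chem", range(8))
    def test_conservation_across_scenario_matrix(self, scenario_matrix,
                                                 i_chem, cell_line, plate):
        """Drift stays below 1e-6 for every volatile/sorbing/degrading
        toggle combination over 72 h."""
        chem = scenario_matrix[i_chem]
        ctx = SimulationContext(chem=chem, cell=cell_line, plate=plate,
                                assay_volume=0.2, total_time=72.0,
                                output_grid=2.0)
        res = core_model(5e-7, 0.0, N0, NEC, KT, ctx)
        assert mass_balance(res) <= 1e-6

    def test_zero_dose_run_has_zero_drift(self, inert_context):
        res = core_model(0.0, 0.0, N0, NEC, KT, inert_context)
        assert mass_balance(res) == 0.0

    def test_degradation_only_drift_matches_closed_form(self, cell_line,
                                                        plate):
        """Excluding the degradation sink from the inventory, the loss
        after time t equals 1 - exp(-k_deg t)."""
        k_deg = 0.05
        chem = fx.make_chemical("inert").model_copy(
            update={"k_deg_water": k_deg, "log_kow": -30.0})
        cell = cell_line.model_copy(
            update={"f_water": 1.0, "f_lipid": 0.0, "f_protein": 0.0})
        ctx = SimulationContext(chem=chem, cell=cell, plate=plate,
                                assay_volume=0.2, total_time=48.0,
                                output_grid=1.0,
                                fate_config=FateConfig(k_up=1e-12))
        res = core_model(1e-7, 0.0, 1.0, 1.0, 0.0, ctx)
        f = res.frame
        live = (f["a_dissolved"] + f["a_headspace"] + f["a_plastic"]
                + f["a_cells"] + f["a_debris"])
        drift_no_sink = abs(live.iloc[-1] - live.iloc[0]) / live.iloc[0]
        assert drift_no_sink == pytest.approx(1 - np.exp(-k_deg * 48.0),
                                              rel=1e-5)

    def test_debris_sink_still_conserves(self, cell_line, plate):
        ctx = SimulationContext(chem=fx.make_chemical("inert"),
                                cell=cell_line, plate=plate,
                                assay_volume=0.2, total_time=48.0,
                                output_grid=2.0,
                                fate_config=FateConfig(debris_sink=True))
        res = core_model(5e-7, 0.0, N0, NEC, KT, ctx)
        assert mass_balance(res) <= 1e-6
        assert res.frame["a_debris"].iloc[-1] > 0


class TestSingleExposure:
    def _config(self, concentrations, tables, **kw):
        chem = next(iter(tables.chemicals))
        line = next(iter(tables.cell_lines))
        plate = next(iter(tables.plates))
        defaults = dict(mode="single", concentrations=concentrations,
                        total_time=48.0, n_cells_initial=N0,
                        assay_volume=0.2, chemical=chem, cell_line=line,
                        plate=plate, output_grid=2.0)
        defaults.update(kw)
        return ExposureConfig(**defaults)

    def test_zero_concentration_run(self, default_tables):
        results = simulate_single_exposure(
            self._config((0.0,), default_tables), default_tables)
        assert len(results) == 1
        assert results[0].viability_end == 1.0

    def test_runs_reset_between_concentrations(self, default_tables):
        """Identical concentrations give bitwise-identical results."""
        r1, r2 = simulate_single_exposure(
            self._config((3e-7, 3e-7), default_tables), default_tables)
        assert r1.viability_end == r2.viability_end
        assert (r1.frame.to_numpy() == r2.frame.to_numpy()).all()

    def test_viability_non_increasing_in_concentration(self, default_tables):
        concs = tuple(np.geomspace(1e-8, 2e-6, 10))
        results = simulate_single_exposure(
            self._config(concs, default_tables), default_tables)
        v = [r.viability_end for r in results]
        assert all(a >= b - 1e-9 for a, b in zip(v, v[1:]))

    def test_unknown_key_named_in_error(self, default_tables):
        cfg = self._config((1e-7,), default_tables, chemical="nope")
        with pytest.raises(KeyError, match="nope"):
            simulate_single_exposure(cfg, default_tables)

    def test_grid_invariance_of_endpoint(self, default_tables):
        coarse = simulate_single_exposure(
            self._config((3e-7,), default_tables, output_grid=2.0),
            default_tables)[0]
        fine = simulate_single_exposure(
            self._config((3e-7,), default_tables, output_grid=1.0),
            default_tables)[0]
        assert abs(coarse.viability_end - fine.viability_end) < 1e-6

    def test_headspace_fraction_monotone_in_kaw(self, cell_line, plate):
        """More volatile chemicals park a larger share of the inventory
        in the headspace at the end of the run."""
        fractions = []
        for kaw in (0.01, 0.1, 0.5, 2.0):
            chem = fx.make_chemical("inert").model_copy(
                update={"henry_kaw": kaw})
            ctx = SimulationContext(chem=chem, cell=cell_line, plate=plate,
                                    assay_volume=0.2, total_time=48.0,
                                    output_grid=4.0)
            res = core_model(5e-7, 0.0, N0, 1.0, 0.0, ctx)
            last = res.frame.iloc[-1]
            fractions.append(last["a_headspace"] / last["mass_expected"])
        assert all(a <= b + 1e-12 for a, b in zip(fractions, fractions[1:]))


class TestRepeatedExposure:
    def _config(self, tables, conc=3e-7, n_doses=3, interval=12.0,
                total=48.0):
        chem = next(iter(tables.chemicals))
        line = next(iter(tables.cell_lines))
        plate = next(iter(tables.plates))
        return ExposureConfig(mode="repeated", concentration=conc,
                              dose_interval=interval, n_doses=n_doses,
                              total_time=total, n_cells_initial=N0,
                              assay_volume=0.2, chemical=chem,
                              cell_line=line, plate=plate, output_grid=2.0)

    def test_single_dose_degenerates_to_single_exposure(self, default_tables):
        rep = simulate_repeated_exposure(
            self._config(default_tables, n_doses=1), default_tables)
        single = simulate_single_exposure(
            ExposureConfig(mode="single", concentrations=(3e-7,),
                           total_time=48.0, n_cells_initial=N0,
                           assay_volume=0.2,
                           chemical=next(iter(default_tables.chemicals)),
                           cell_line=next(iter(default_tables.cell_lines)),
                           plate=next(iter(default_tables.plates)),
                           output_grid=2.0),
            default_tables)[0]
        assert rep.viability_end == pytest.approx(single.viability_end,
                                                  abs=1e-10)

    def test_chaining_equivalence(self):
        """Three doses equal three manual state-carryover single runs.

        Uses a non-volatile, non-sorbing chemical so the five-parameter
        core-model contract (medium conc., cell conc., cell count, NEC,
        kt) captures the whole carryover state.
        """
        chem = fx.make_chemical("inert").model_copy(
            update={"log_kow": -30.0})
        cell = fx.make_cell_line()
        plate = fx.make_plate()
        tox = fx.make_toxicity(chem.name, cell.name, nec=1e-5, kt=500.0)
        tables = TableSet.from_records([chem], [cell], [plate], [tox])
        cfg = ExposureConfig(mode="repeated", concentration=3e-7,
                             dose_interval=12.0, n_doses=3, total_time=36.0,
                             n_cells_initial=N0, assay_volume=0.2,
                             chemical=chem.name, cell_line=cell.name,
                             plate=plate.name, output_grid=2.0)
        rep = simulate_repeated_exposure(cfg, tables)

        c_cell, n_total = 0.0, N0
        for _ in range(3):
            ctx = SimulationContext(chem=chem, cell=cell, plate=plate,
                                    assay_volume=0.2, total_time=12.0,
                                    output_grid=2.0)
            seg = core_model(3e-7, c_cell, n_total, tox.nec, tox.kt, ctx)
            last = seg.frame.iloc[-1]
            c_cell, n_total = float(last["c_cell"]), float(last["n_total"])
        from biokin.cells import stable_stage_distribution, stage_transition_matrix
        from scipy.linalg import expm

        n0 = stable_stage_distribution(cell) * N0
        control = float((expm(stage_transition_matrix(cell) * 36.0) @ n0).sum())
        manual_viability = n_total / control
        assert rep.viability_end == pytest.approx(manual_viability, abs=1e-8)

    def test_zero_concentration_any_doses(self, default_tables):
        rep = simulate_repeated_exposure(
            self._config(default_tables, conc=0.0), default_tables)
        assert rep.viability_end == 1.0

    def test_time_strictly_increasing_and_conserved(self, default_tables):
        rep = simulate_repeated_exposure(self._config(default_tables),
                                         default_tables)
        t = rep.frame["time"].to_numpy()
        assert np.all(np.diff(t) > 0)
        assert mass_balance(rep) <= 1e-6

    def test_repeated_dosing_lowers_viability(self, default_tables):
        one = simulate_repeated_exposure(
            self._config(default_tables, conc=2e-7, n_doses=1),
            default_tables)
        three = simulate_repeated_exposure(
            self._config(default_tables, conc=2e-7, n_doses=3),
            default_tables)
        assert three.viability_end <= one.viability_end + 1e-9
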