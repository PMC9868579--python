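import dataclasses as dc

import numpy as np
import pytest

from purinesim import calcium, cytokine, gq_ip3, ligand_pool, migration, p2x
from purinesim.engine import (
    EXPRESSION_PRESETS,
    IDX,
    Protocol,
    ReceptorExpression,
    assemble_rhs,
    run,
    scenario_matrix,
)


class TestTypes:
    def test_negative_expression_rejected(self):
        with pytest.raises(ValueError):
            ReceptorExpression(rho_p2x4=-0.1)

    def test_presets_match_reported_expression_ratios(self):
        bv2 = EXPRESSION_PRESETS["bv2"]
        assert (bv2.rho_p2x4, bv2.rho_p2x7, bv2.rho_p2y2, bv2.rho_p2y12) == (
            0.18, 0.65, 1.02, 0.030)

    def test_protocol_validation(self):
        with pytest.raises(ValueError):
            Protocol(dose_uM=-5.0)
        with pytest.raises(ValueError):
            Protocol(horizon_s=100.0, duration_s=200.0)
        with pytest.raises(ValueError):
            Protocol(agonist="GTP")


class TestAssembly:
    def test_zero_dose_resting_state_is_fixed_point(self, params):
        y0 = params.resting_state()
        dy = assemble_rhs(y0, 0.0, Protocol(dose_uM=0.0), params)
        assert np.max(np.abs(dy)) < 1e-9

    def test_rhs_equals_module_concatenation(self, params):
        """The assembled derivative vector is exactly the per-module RHS
        outputs stitched together with the shared couplings."""
        proto = Protocol(dose_uM=100.0)
        y = params.resting_state()
        y[IDX["atp"]] = 100.0
        y[IDX["x4_open"]], y[IDX["x7_open"]] = 0.2, 0.05
        y[IDX["ip3"]] = 150.0
        y[IDX["pi3k_recruit"]] = 0.1
        y[IDX["p_akt"]] = 1.0
        dy = assemble_rhs(y, 0.0, proto, params)

        pool_d = ligand_pool.hydrolysis_rhs(y[0:4], params.cd39)
        assert np.allclose(dy[0:4], pool_d)
        gate_d = p2x.p2x_rhs(y[4:7], y[IDX["atp"]], params.p2x)
        assert np.allclose(dy[4:7], gate_d)
        _, _, flux = p2x.p2x_current(y[4:7], 1.0, 1.0, params.p2x)
        gq_d = gq_ip3.gq_rhs(y[7:12], y[IDX["atp"]], 0.0, y[IDX["ca_cyt"]],
                             params.gq)
        assert np.allclose(dy[7:12], gq_d)
        ca_d = calcium.calcium_rhs(y[12:15], y[IDX["ip3"]], flux, params.ca)
        assert np.allclose(dy[12:15], ca_d)
        drive, _, _ = migration.pi3k_drive(
            y[IDX["adp"]], y[IDX["ca_cyt"]], 1.0, params.mig,
            recruitment=y[IDX["pi3k_recruit"]])
        assert dy[IDX["p_akt"]] == pytest.approx(
            migration.akt_rhs(y[IDX["p_akt"]], drive, params.mig))
        nfat_d = cytokine.nfat_rhs(y[18:20], y[IDX["cam_bound"]], params.cyt)
        assert np.allclose(dy[18:20], nfat_d)

    def test_gating_blocks_conserve_probability_along_run(self, wt50_run):
        y = wt50_run.y
        x4 = y[:, IDX["x4_open"]] + y[:, IDX["x4_desens"]]
        assert np.all(x4 >= -1e-8) and np.all(x4 <= 1 + 1e-8)
        assert np.all(y[:, IDX["x7_open"]] >= -1e-8)
        assert np.all(y[:, IDX["x7_open"]] <= 1 + 1e-8)


class TestRun:
    def test_deterministic_bitwise(self, params):
        proto = Protocol(dose_uM=100.0, horizon_s=120.0)
        a = run(proto, params)
        b = run(proto, params)
        assert np.array_equal(a.y, b.y)

    def test_storage_grid_matches_cadence(self, wt50_run):
        assert np.allclose(np.diff(wt50_run.t), 1.0)

    def test_custom_cadence(self, params):
        tr = run(Protocol(dose_uM=50.0, horizon_s=60.0, dt_store=2.0), params)
        assert np.allclose(np.diff(tr.t), 2.0)

    def test_tolerance_convergence(self, params):
        proto = Protocol(dose_uM=1000.0, horizon_s=300.0)
        coarse = run(proto, params, rtol=1e-6, atol=1e-9)
        fine = run(proto, params, rtol=5e-7, atol=5e-10)
        assert np.max(np.abs(coarse.ca_cyt - fine.ca_cyt)) < 0.1

    def test_fine_step_mode_agrees_on_short_horizon(self, params):
        proto = Protocol(dose_uM=100.0, horizon_s=2.0)
        a = run(proto, params)
        b = run(proto, params, fine_step=True)
        assert np.max(np.abs(a.ca_cyt - b.ca_cyt)) < 0.05

    def test_control_run_returns_to_baseline_with_cd39(self, params):
        """1 mM, 10 min, CD39 on: Ca decays back toward rest by the end."""
        tr = run(Protocol(dose_uM=1000.0, horizon_s=600.0), params)
        assert tr.ca_cyt[-1] < 120.0

    def test_washout_empties_pool(self, params):
        tr = run(Protocol(dose_uM=100.0, horizon_s=300.0, duration_s=60.0,
                          washout=True), params)
        assert tr.series("atp")[65:].max() < 1e-9
        assert tr.series("adp")[65:].max() < 1e-9

    def test_delayed_onset(self, params):
        tr = run(Protocol(dose_uM=100.0, horizon_s=120.0, onset_s=60.0), params)
        assert np.allclose(tr.ca_cyt[:59], 100.0, atol=1e-6)
        assert tr.ca_cyt[90] > 110.0

    def test_utp_activates_only_p2y2(self, params):
        """UTP drives the Gq/IP3 branch; ionotropic receptors and the
        ADP/P2Y12 axis stay silent."""
        tr = run(Protocol(agonist="UTP", dose_uM=200.0, horizon_s=600.0), params)
        cur = tr.currents()
        assert cur.ca_influx.max() < 1e-12
        assert tr.series("adp").max() < 1e-12
        assert tr.series("ip3").max() > 50.0
        assert tr.ca_cyt.max() > 110.0

    def test_bv2_preset_reduces_ca_transient(self, params):
        pri = run(Protocol(dose_uM=500.0, horizon_s=120.0), params)
        bv2 = run(Protocol(dose_uM=500.0, horizon_s=120.0, expression="bv2"),
                  params)
        assert bv2.ca_cyt.max() < pri.ca_cyt.max()
        # reduced P2X expression trims the transient at low dose too
        pri50 = run(Protocol(dose_uM=50.0, horizon_s=120.0), params)
        bv250 = run(Protocol(dose_uM=50.0, horizon_s=120.0, expression="bv2"),
                    params)
        assert bv250.ca_cyt.max() < pri50.ca_cyt.max()


class TestScenarioMatrix:
    def test_empty_scenarios_gives_control_row(self, params):
        base = Protocol(dose_uM=50.0, horizon_s=60.0)
        table = scenario_matrix(base, {}, params)
        assert list(table.scenario) == ["control"]

    def test_knockout_rows_reduce_pakt(self, params):
        base = Protocol(dose_uM=50.0, horizon_s=300.0)
        table = scenario_matrix(
            base,
            {"p2y12_ko": {"expression": ReceptorExpression(1, 1, 1, 0)}},
            params,
        ).set_index("scenario")
        assert table.loc["p2y12_ko", "peak_pakt_norm"] < \
            0.2 * table.loc["control", "peak_pakt_norm"]
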