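import json

import numpy as np
import pytest

import memchrom as mc
from memchrom.pore_model import discretize_psd
from memchrom.workflows import (
    PoreDispersionModel,
    compare_models,
    flowrate_sweep,
    psd_to_dispersion,
    rmax_sensitivity,
)


@pytest.fixture(scope="module")
def base_config(disc_column):
    return mc.SimulationConfig(
        column=disc_column, conditions=mc.OperatingConditions.ml_per_min(1.0)
    )


class TestDispersionPipeline:
    def test_narrow_distribution_dispersion(self, base_config, psd_narrow):
        s = psd_to_dispersion(base_config.with_(psd=psd_narrow))
        assert s.dispersion == pytest.approx(1.38e-6, rel=0.10)
        assert not s.epsilon_in_eq6

    def test_monodisperse_dispersion_vanishes(self, base_config, disc_column):
        psd = discretize_psd(1.5e-4, 1e-8, r_min=0.5e-4, r_max=6.5e-4)
        res = PoreDispersionModel(
            disc_column, base_config.conditions, psd
        ).fit()
        assert res.dispersion < 1e-9

    def test_results_are_deterministic(self, base_config, psd_narrow):
        model = PoreDispersionModel.from_config(base_config.with_(psd=psd_narrow))
        r1, r2 = model.fit(), model.fit()
        assert r1.dispersion == r2.dispersion
        assert r1.fit.ssr == r2.fit.ssr

    def test_unregularized_route_matches_exact_moments(self, base_config, psd_narrow):
        res = PoreDispersionModel.from_config(
            base_config.with_(psd=psd_narrow), regularize=False
        ).fit()
        assert res.dispersion == pytest.approx(res.oracle_dispersion, rel=5e-3)

    def test_summary_reports_key_quantities(self, base_config, psd_narrow):
        res = PoreDispersionModel.from_config(base_config.with_(psd=psd_narrow)).fit()
        text = res.summary()
        assert "dispersivity" in text and "t_lag" in text
        assert f"{res.t_lag:.4g}" in text


class TestRmaxSensitivity:
    def test_identical_bounds_give_zero(self, base_config, make_psd):
        cfg = base_config.with_(psd=make_psd(0.35))
        assert rmax_sensitivity(cfg, 6.5, 6.5) == 0.0

    def test_narrow_distribution_is_insensitive(self, base_config, make_psd):
        """At sigma = 0.10 the Gaussian mass beyond 2.5 um is ~1e-23: widening
        the truncation cannot move the estimate the way it does at 0.35."""
        broad = rmax_sensitivity(base_config.with_(psd=make_psd(0.35)), 2.5, 6.5)
        narrow = rmax_sensitivity(base_config.with_(psd=make_psd(0.10)), 2.5, 6.5)
        assert narrow < broad
        assert narrow < 1e-6

    def test_reversed_bounds_rejected(self, base_config, make_psd):
        with pytest.raises(ValueError):
            rmax_sensitivity(base_config.with_(psd=make_psd(0.35)), 6.5, 2.5)


class TestFlowrateSweep:
    @pytest.fixture(scope="class")
    def report(self, base_config, psd_narrow):
        return flowrate_sweep(
            base_config.with_(psd=psd_narrow), [1.0, 2.0, 5.0, 10.0], [0.10]
        )

    def test_alpha_velocity_product_is_exact_per_row(self, report, disc_column):
        for row in report.rows:
            cond = mc.OperatingConditions.ml_per_min(row.flowrate_ml_min)
            v = cond.interstitial_velocity(disc_column)
            assert row.dispersivity * v == pytest.approx(row.dispersion, rel=1e-12)

    def test_exact_route_dispersivity_is_flowrate_invariant(self, report):
        assert report.oracle_alpha_spread[0.10] == pytest.approx(1.0, abs=1e-10)

    def test_fitted_alpha_at_one_ml_per_min(self, report):
        row = next(r for r in report.rows if r.flowrate_ml_min == 1.0)
        assert row.dispersivity == pytest.approx(2.518e-4, rel=0.10)

    def test_frame_has_one_row_per_cell(self, report):
        df = report.to_frame()
        assert len(df) == 4
        assert set(df["flowrate_ml_min"]) == {1.0, 2.0, 5.0, 10.0}

    def test_single_flowrate_rejected(self, base_config, psd_narrow):
        with pytest.raises(ValueError):
            flowrate_sweep(base_config.with_(psd=psd_narrow), [1.0], [0.10])

    def test_fixed_absolute_grid_perturbs_fitted_alpha(self, base_config, psd_narrow):
        """Freezing one absolute time step across flowrates degrades the
        per-flowrate sampling and moves the fitted dispersivity around more
        than the per-flowrate grid does."""
        adaptive = flowrate_sweep(
            base_config.with_(psd=psd_narrow), [1.0, 10.0], [0.10]
        )
        frozen = flowrate_sweep(
            base_config.with_(psd=psd_narrow), [1.0, 10.0], [0.10],
            fixed_time_grid=0.05,
        )
        assert frozen.fitted_alpha_spread[0.10] > adaptive.fitted_alpha_spread[0.10]


class TestModelComparison:
    @pytest.fixture(scope="class")
    def reports(self, base_config, make_psd):
        return {
            s: compare_models(base_config.with_(psd=make_psd(s)))
            for s in (0.10, 0.35)
        }

    def test_discrepancies_nonnegative_and_finite(self, reports):
        for rep in reports.values():
            assert 0 <= rep.linf < 0.2
            assert 0 <= rep.l2 < 0.2

    def test_both_models_share_the_plug_flow_first_moment(self, reports, disc_column):
        cond = mc.OperatingConditions.ml_per_min(1.0)
        t_plug = disc_column.thickness / cond.interstitial_velocity(disc_column)
        for rep in reports.values():
            for curve in (rep.bundle_curve, rep.pde_curve):
                c = curve.values / curve.values[-1]
                mean_rt = np.trapezoid(1.0 - c, curve.times)
                assert mean_rt == pytest.approx(t_plug, rel=0.02)

    def test_dispersion_used_comes_from_the_bundle(self, reports):
        assert reports[0.10].dispersion_used == pytest.approx(1.38e-6, rel=0.10)


class TestCLI:
    CONFIG = """
schema_version: 1
column: {thickness_um: 275, diameter_cm: 2.2, void_fraction: 0.8}
conditions: {flowrate_ml_min: 1.0}
psd: {mu_um: 1.5, sigma_um: 0.10, rmin_um: 0.5, rmax_um: 6.5}
"""

    def test_psd2dl_and_moments_round_trip(self, tmp_path):
        from click.testing import CliRunner

        from memchrom.cli import main

        cfg = tmp_path / "run.yaml"
        cfg.write_text(self.CONFIG)
        out = tmp_path / "dl.json"
        curve = tmp_path / "curve.csv"
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["psd2dl", "--config", str(cfg), "--out", str(out), "--curve-out", str(curve)],
        )
        assert result.exit_code == 0, result.output
        payload = json.loads(out.read_text())
        assert payload["dispersion_cm2_s"] == pytest.approx(1.38e-6, rel=0.10)
        assert curve.exists()

    def test_sweep_writes_table_and_audit(self, tmp_path):
        from click.testing import CliRunner

        from memchrom.cli import main

        cfg = tmp_path / "run.yaml"
        cfg.write_text(self.CONFIG)
        out = tmp_path / "sweep.csv"
        runner = CliRunner()
        result = runner.invoke(
            main,
            ["sweep", "--config", str(cfg), "--out", str(out),
             "--flowrates", "1,2", "--sigmas", "0.10"],
        )
        assert result.exit_code == 0, result.output
        audit = json.loads((tmp_path / "sweep.csv.audit.json").read_text())
        assert audit["oracle_alpha_spread"]["0.1"] == pytest.approx(1.0, abs=1e-10)
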