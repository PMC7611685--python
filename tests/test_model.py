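"""Global weighted fitting: recovery, weighting, diagnostics."""

import numpy as np
import pandas as pd
import pytest

from plasmidkinetics import (
    ExposureAxis,
    GelDataset,
    InitialState,
    PlasmidKineticsModel,
    generate_proportion_dataset,
    preset_config,
)
from plasmidkinetics.dataset import GEL_TABLE_COLUMNS
from conftest import EBRT_GRID, RATE_PAIRS, TIME_GRID, make_noiseless_dataset


def lane_rows(x, s, r, lin, replicate=1, axis="dose", condition="t"):
    return {
        "condition": condition,
        "axis_kind": axis,
        "x": x,
        "replicate": replicate,
        "pct_supercoiled": s,
        "pct_relaxed": r,
        "pct_linear": lin,
    }


class TestSummarizeReplicates:
    def test_identical_replicates_have_zero_sd(self):
        rows = [lane_rows(1.0, 50, 40, 10, rep) for rep in (1, 2, 3)]
        data = GelDataset(pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS))
        summ = data.summarize_replicates()
        assert summ.loc[0, "mean_supercoiled"] == 50
        assert summ.loc[0, "sd_supercoiled"] == 0
        assert summ.loc[0, "n"] == 3

    def test_sample_sd_uses_n_minus_one(self):
        rows = [lane_rows(1.0, s, 100 - s, 0, rep) for rep, s in enumerate((40, 50, 60), 1)]
        data = GelDataset(pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS))
        summ = data.summarize_replicates()
        assert summ.loc[0, "mean_supercoiled"] == pytest.approx(50)
        assert summ.loc[0, "sd_supercoiled"] == pytest.approx(10)

    def test_empty_dataset_rejected(self):
        data = GelDataset(pd.DataFrame(columns=GEL_TABLE_COLUMNS))
        with pytest.raises(ValueError, match="empty"):
            data.summarize_replicates()

    def test_pooled_sd_matches_generating_noise(self):
        # renormalizing each lane to the true total projects the iid noise
        # onto the simplex, so the per-species scatter is the nominal SD
        # times sqrt(1 - 2 p_i + 3 p_i^2); checked at a mid-simplex point
        # (0.40, 0.45, 0.15) where boundary clipping is negligible
        from plasmidkinetics import GenerationConfig, species_proportions

        cfg = GenerationConfig(
            ksr=0.9163, krl=0.5, s0=1.0, grid=[0.0, 1.0],
            n_replicates=2000, sd_pct=5.0, seed=7,
        )
        data = generate_proportion_dataset(cfg)
        summ = data.summarize_replicates().set_index("x")
        s, r, lin = species_proportions([1.0], 0.9163, 0.5, InitialState(1.0))
        for sp, pi in zip(("supercoiled", "relaxed", "linear"), (s[0], r[0], lin[0])):
            expected = 5.0 * np.sqrt(1 - 2 * pi + 3 * pi**2)
            assert summ.loc[1.0, f"sd_{sp}"] == pytest.approx(expected, rel=0.10)


class TestNoiselessRecovery:
    @pytest.mark.parametrize("ksr,krl", RATE_PAIRS)
    def test_exact_recovery_of_generating_parameters(self, ksr, krl):
        grid = EBRT_GRID if ksr > 0.3 else TIME_GRID
        data = make_noiseless_dataset(ksr, krl, s0=0.97, grid=grid)
        res = PlasmidKineticsModel(data).fit()
        assert res.converged
        assert res.params["ksr"] == pytest.approx(ksr, rel=1e-6)
        assert res.params["krl"] == pytest.approx(krl, rel=1e-6, abs=1e-12)
        assert res.s0 == pytest.approx(0.97, rel=1e-6)

    def test_frozen_second_step_sits_at_the_boundary(self):
        data = make_noiseless_dataset(0.585, 0.0, s0=1.0)
        res = PlasmidKineticsModel(data).fit()
        assert res.params["krl"] == pytest.approx(0.0, abs=1e-8)
        assert "krl" in res.at_bound
        # linear-band residuals vanish identically
        pred = res.predict(np.array(EBRT_GRID))
        assert np.allclose(pred["linear"], 0.0, atol=1e-7)

    def test_fixed_s0_option(self):
        data = make_noiseless_dataset(1.21, 0.017, s0=0.97)
        res = PlasmidKineticsModel(
            data, fit_s0=False, init_state=InitialState(0.97)
        ).fit()
        assert "s0" not in res.params.index
        assert res.s0 == 0.97
        assert res.params["ksr"] == pytest.approx(1.21, rel=1e-6)

    def test_refit_of_predictions_is_a_fixed_point(self, ebrt_noiseless):
        res1 = PlasmidKineticsModel(ebrt_noiseless).fit()
        pred = res1.predict(np.array(EBRT_GRID))
        rows = [
            lane_rows(x, 100 * s, 100 * r, 100 * lin)
            for x, s, r, lin in pred.itertuples(index=False)
        ]
        data2 = GelDataset(pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS))
        res2 = PlasmidKineticsModel(data2).fit()
        assert res2.params.to_numpy() == pytest.approx(
            res1.params.to_numpy(), rel=1e-6
        )


class TestWeighting:
    def test_scaling_all_sds_leaves_point_estimates_unchanged(self):
        # common SD rescaling only changes the weights by a constant, so the
        # WLS optimum is untouched; without reduced-chi^2 rescaling the
        # reported SEs scale linearly with it
        cfg = preset_config("ebrt-1.25", seed=13, n_replicates=6)
        data = generate_proportion_dataset(cfg)
        m1 = PlasmidKineticsModel(data, scale_cov=False)
        m2 = PlasmidKineticsModel(data, scale_cov=False)
        m2._obs = m1._obs.copy()
        m2._obs["sd"] *= 3.0
        res1, res2 = m1.fit(), m2.fit()
        assert res2.params.to_numpy() == pytest.approx(
            res1.params.to_numpy(), rel=1e-6
        )
        assert res2.bse.to_numpy() == pytest.approx(
            3.0 * res1.bse.to_numpy(), rel=1e-4
        )

    def test_sd_floor_prevents_infinite_weights(self, ebrt_noiseless):
        # single replicates have SD 0; the floor keeps the objective finite
        model = PlasmidKineticsModel(ebrt_noiseless, sd_floor_pct=1.0)
        assert np.all(model._obs["sd"] >= 0.01 - 1e-15)

    def test_lanes_mode_fits_raw_lanes_with_unit_weights(self):
        cfg = preset_config("ebrt-1.25", seed=11, n_replicates=3)
        data = generate_proportion_dataset(cfg)
        res = PlasmidKineticsModel(data, mode="lanes").fit()
        assert res.converged
        assert abs(res.params["ksr"] - 1.21) < 5 * res.bse["ksr"] + 0.2

    def test_mask_drops_high_dose_linear_observations(self, ebrt_noiseless):
        full = PlasmidKineticsModel(ebrt_noiseless)
        masked = PlasmidKineticsModel(ebrt_noiseless, mask_linear_above=10.0)
        dropped = ((full._obs["species"] == "linear") & (full._obs["x"] > 10)).sum()
        assert dropped > 0
        assert len(masked._obs) == len(full._obs) - dropped


class TestInitialGuess:
    def test_log_linear_slope_recovers_rate_exactly(self):
        data = make_noiseless_dataset(0.59, 0.0, s0=1.0, grid=[0, 1, 2, 3, 4])
        guess = PlasmidKineticsModel(data).initial_guess()
        assert guess[0] == pytest.approx(0.59, rel=1e-6)

    def test_zero_supercoiled_points_are_excluded(self):
        rows = [
            lane_rows(0.0, 95, 5, 0),
            lane_rows(1.0, 40, 55, 5),
            lane_rows(30.0, 0, 60, 40),
        ]
        data = GelDataset(pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS))
        guess = PlasmidKineticsModel(data).initial_guess()
        assert np.all(np.isfinite(guess))
        assert guess[0] > 0

    def test_optimum_is_reached_from_perturbed_starts(self):
        # basin-of-attraction: the same optimum from the data-driven start
        # and from starts perturbed by up to 3x in either direction
        hits = 0
        n_data, n_starts = 10, 10
        for i in range(n_data):
            cfg = preset_config("ebrt-1.25", seed=500 + i, n_replicates=6)
            data = generate_proportion_dataset(cfg)
            model = PlasmidKineticsModel(data)
            ref = model.fit()
            rng = np.random.default_rng(i)
            agree = True
            for _ in range(n_starts):
                factors = 3.0 ** rng.uniform(-1, 1, size=len(ref.params))
                alt = model.fit(start=ref.model.initial_guess() * factors)
                if not np.allclose(
                    alt.params.to_numpy(), ref.params.to_numpy(), rtol=1e-4, atol=1e-8
                ):
                    agree = False
            hits += agree
        assert hits >= 0.95 * n_data - 1e-9


class TestDiagnostics:
    def test_standard_errors_withheld_without_degrees_of_freedom(self, ebrt_noiseless):
        model = PlasmidKineticsModel(ebrt_noiseless)
        cov, bse = model._covariance(np.eye(3), wrss=1.0, dof=0)
        assert np.all(np.isnan(cov)) and np.all(np.isnan(bse))

    def test_covariance_diagonal_matches_reported_ses(self):
        cfg = preset_config("ebrt-1.25", seed=21, n_replicates=6)
        res = PlasmidKineticsModel(generate_proportion_dataset(cfg)).fit()
        assert res.bse.to_numpy() == pytest.approx(
            np.sqrt(np.diag(res.cov.to_numpy())), rel=1e-12
        )
        # symmetry + PSD
        c = res.cov.to_numpy()
        assert np.allclose(c, c.T)
        assert np.all(np.linalg.eigvalsh(c) > -1e-18)

    def test_covariance_scaling_convention_is_switchable(self):
        cfg = preset_config("ebrt-1.25", seed=22, n_replicates=6)
        data = generate_proportion_dataset(cfg)
        scaled = PlasmidKineticsModel(data, scale_cov=True).fit()
        raw = PlasmidKineticsModel(data, scale_cov=False).fit()
        ratio = scaled.cov.to_numpy() / raw.cov.to_numpy()
        assert np.allclose(ratio, scaled.redchi, rtol=1e-8)

    def test_summary_mentions_key_quantities(self, ebrt_noiseless):
        res = PlasmidKineticsModel(ebrt_noiseless).fit()
        text = res.summary()
        for token in ("ksr", "krl", "s0", "dose", "converged"):
            assert token in text

    def test_report_round_trips_through_json(self, tmp_path, ebrt_noiseless):
        from plasmidkinetics import read_fit_report

        res = PlasmidKineticsModel(ebrt_noiseless).fit()
        path = tmp_path / "fit.json"
        res.to_json(path)
        rep = read_fit_report(path)
        assert rep["ksr_estimate"].value == pytest.approx(res.params["ksr"])
        assert rep["kinetic_params"].axis is ExposureAxis.DOSE


class TestValidation:
    def test_single_exposure_dataset_rejected(self):
        rows = [lane_rows(1.0, 50, 40, 10, rep) for rep in (1, 2)]
        data = GelDataset(pd.DataFrame(rows, columns=GEL_TABLE_COLUMNS))
        with pytest.raises(ValueError, match="distinct exposure"):
            PlasmidKineticsModel(data)

    def test_unknown_variant_rejected(self, ebrt_noiseless):
        with pytest.raises(ValueError, match="variant"):
            PlasmidKineticsModel(ebrt_noiseless, variant="fancy")

    def test_direct_break_variant_adds_a_parameter(self, ebrt_noiseless):
        model = PlasmidKineticsModel(ebrt_noiseless, variant="direct_break")
        assert model.param_names == ["ksr", "krl", "s0", "ksl"]
        res = model.fit()
        assert res.converged
        # on data generated without a direct S->L flux, ksl stays negligible
        assert res.params["ksl"] < 1e-6
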