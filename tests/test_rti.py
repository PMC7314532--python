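"""Inverse-problem and cohort-analysis tests."""

import numpy as np
import pandas as pd
import pytest

from ecsdiff.core import (
    CalibrationTable,
    DiffusionCurve,
    ECSParameters,
    generate_curve,
)
from ecsdiff.rti import (
    TissueFit,
    assign_layer,
    average_repeats,
    calibrate_electrode,
    compare_groups,
    fit_agar,
    fit_tissue,
    two_way_anova,
)
from ecsdiff.synth import make_calibration, make_curve

from conftest import FREE_MEDIUM


class TestCalibration:
    def test_exact_nernstian_recovery(self):
        table = make_calibration(slope=58.0, offset=0.0, noise_mV=0.0)
        cal = calibrate_electrode(table)
        assert cal.slope == pytest.approx(58.0, abs=1e-10)
        assert cal.offset == pytest.approx(0.0, abs=1e-10)
        assert cal.residual_rms < 1e-10
        assert cal.monotone

    def test_round_trip_identity(self):
        table = make_calibration(slope=58.0, offset=5.0)
        cal = calibrate_electrode(table)
        back = cal.voltage_to_concentration(
            cal.concentration_to_voltage(table.concentrations)
        )
        assert np.allclose(back, table.concentrations, rtol=1e-9)

    def test_requires_three_points(self):
        table = CalibrationTable(
            concentrations=np.array([1.0, 2.0]), voltages=np.array([0.0, 17.0])
        )
        with pytest.raises(ValueError):
            calibrate_electrode(table)

    def test_noisy_slope_recovery(self):
        """0.5 mV noise on the 7-point series leaves the slope within 2%."""
        table = make_calibration(slope=58.0, offset=0.0, noise_mV=0.5, seed=7)
        cal = calibrate_electrode(table)
        assert cal.slope == pytest.approx(58.0, rel=0.02)


class TestAgarFit:
    def test_noiseless_recovery(self, agar_fit):
        assert agar_fit.transport_number == pytest.approx(0.3, rel=1e-6)
        assert agar_fit.free_D == pytest.approx(1.24e-5, rel=1e-6)

    def test_noisy_recovery(self, source, times):
        curve, _ = make_curve(
            FREE_MEDIUM, source, 120.0, noise_fraction=0.02, seed=11, medium="agar"
        )
        fit = fit_agar(curve, source)
        assert fit.converged
        assert fit.transport_number == pytest.approx(0.3, rel=0.03)
        assert fit.free_D == pytest.approx(1.24e-5, rel=0.03)

    def test_all_zero_curve_flagged(self, times):
        curve = DiffusionCurve(
            distance=120.0,
            times=times,
            concentration=np.zeros_like(times),
            medium="agar",
        )
        fit = fit_agar(curve)
        assert not fit.converged

    def test_rejects_tissue_curve(self, source, times):
        curve = generate_curve(source, FREE_MEDIUM, 120.0, times, medium="tissue")
        with pytest.raises(ValueError):
            fit_agar(curve, source)


class TestTissueFit:
    @pytest.mark.parametrize("alpha", [0.1, 0.2, 0.3])
    @pytest.mark.parametrize("lam", [1.2, 1.5, 1.8])
    @pytest.mark.parametrize("kprime", [0.0, 0.004, 0.01])
    def test_self_inverse_on_noiseless_curves(
        self, source, times, agar_fit, alpha, lam, kprime
    ):
        """fit(generate(theta)) = theta within 1e-3 relative across the
        parameter grid."""
        truth = ECSParameters(alpha, lam, kprime)
        curve = generate_curve(source, truth, 120.0, times, medium="tissue")
        fit = fit_tissue(curve, agar_fit, source=source)
        assert fit.converged
        assert fit.params.alpha == pytest.approx(alpha, rel=1e-3)
        assert fit.params.lam == pytest.approx(lam, rel=1e-3)
        assert fit.params.kprime == pytest.approx(kprime, rel=1e-3, abs=1e-5)

    def test_free_diffusion_identity(self, source, times, agar_fit):
        """A free-diffusion curve fitted as tissue returns alpha = 1,
        lam = 1, k' = 0: the defining property of the agar reference."""
        curve = generate_curve(source, FREE_MEDIUM, 120.0, times, medium="tissue")
        fit = fit_tissue(curve, agar_fit, source=source)
        assert fit.params.alpha == pytest.approx(1.0, abs=1e-3)
        assert fit.params.lam == pytest.approx(1.0, abs=1e-3)
        assert fit.params.kprime == pytest.approx(0.0, abs=1e-3)

    def test_requires_converged_agar(self, source, times):
        from ecsdiff.rti import AgarFit

        curve = generate_curve(
            source, ECSParameters(0.2, 1.5, 0.004), 120.0, times, medium="tissue"
        )
        with pytest.raises(ValueError):
            fit_tissue(curve, AgarFit(0.3, 1.24e-5, np.inf, False))


class TestAverageRepeats:
    @staticmethod
    def _fit(alpha, lam, kprime, converged=True):
        return TissueFit(ECSParameters(alpha, lam, kprime), 0.0, converged)

    def test_identical_triplet(self):
        fits = [self._fit(0.2, 1.5, 0.004)] * 3
        mean = average_repeats(fits)
        assert (mean.alpha, mean.lam, mean.kprime) == pytest.approx((0.2, 1.5, 0.004))

    def test_arithmetic_mean(self):
        fits = [self._fit(a, 1.5, 0.004) for a in (0.18, 0.20, 0.22)]
        assert average_repeats(fits).alpha == pytest.approx(0.20)

    def test_drops_non_converged(self):
        fits = [
            self._fit(0.18, 1.4, 0.004),
            self._fit(0.22, 1.6, 0.004),
            self._fit(0.9, 2.9, 0.09, converged=False),
        ]
        mean = average_repeats(fits)
        assert mean.alpha == pytest.approx(0.20)
        assert mean.lam == pytest.approx(1.5)

    def test_all_failed_raises(self):
        with pytest.raises(ValueError):
            average_repeats([self._fit(0.2, 1.5, 0.0, converged=False)])


class TestAssignLayer:
    @pytest.mark.parametrize(
        "depth, layer",
        [
            (400, "III"),
            (600, "III"),
            (800, "IV"),
            (1000, "V"),
            (1200, "V"),
            (1400, "V"),
            (1600, "VI"),
            (1800, "VI"),
            (2000, "WM"),
        ],
    )
    def test_depth_mapping(self, depth, layer):
        assert assign_layer(depth) == layer

    @pytest.mark.parametrize("depth", [500, 0, 2200, 400.5])
    def test_unsampled_depth_rejected(self, depth):
        with pytest.raises(ValueError):
            assign_layer(depth)


def brute_force_two_way_anova(table: pd.DataFrame, value: str):
    """Textbook balanced two-way ANOVA from raw sums of squares.

    Independent of statsmodels: cell/marginal means and explicit SS
    partitioning for a balanced layout with replication.
    """
    y = table[value].to_numpy()
    a_lv = sorted(table["group"].unique())
    b_lv = sorted(table["layer"].unique())
    n_rep = len(table) // (len(a_lv) * len(b_lv))
    grand = y.mean()
    ss_a = sum(
        len(table[table["group"] == a]) * (table[table["group"] == a][value].mean() - grand) ** 2
        for a in a_lv
    )
    ss_b = sum(
        len(table[table["layer"] == b]) * (table[table["layer"] == b][value].mean() - grand) ** 2
        for b in b_lv
    )
    ss_cells = 0.0
    ss_err = 0.0
    for a in a_lv:
        for b in b_lv:
            cell = table[(table["group"] == a) & (table["layer"] == b)][value]
            ss_cells += len(cell) * (cell.mean() - grand) ** 2
            ss_err += ((cell - cell.mean()) ** 2).sum()
    ss_ab = ss_cells - ss_a - ss_b
    df_a, df_b = len(a_lv) - 1, len(b_lv) - 1
    df_ab = df_a * df_b
    df_err = len(a_lv) * len(b_lv) * (n_rep - 1)
    ms_err = ss_err / df_err
    ss_tot = ((y - grand) ** 2).sum()
    return {
        "F_group": (ss_a / df_a) / ms_err,
        "F_layer": (ss_b / df_b) / ms_err,
        "F_interaction": (ss_ab / df_ab) / ms_err,
        "ss_total": ss_tot,
        "ss_parts": ss_a + ss_b + ss_ab + ss_err,
    }


def _toy_table():
    rng = np.random.default_rng(3)
    rows = []
    for g, base in (("control", 0.20), ("etoh", 0.17)):
        for layer, shift in (("III", 0.0), ("IV", 0.01)):
            for i in range(3):
                rows.append(
                    {
                        "group": g,
                        "layer": layer,
                        "animal_id": f"{g}{layer}{i}",
                        "alpha": base + shift + rng.normal(0, 0.01),
                    }
                )
    return pd.DataFrame(rows)


class TestCompareGroups:
    def test_anova_matches_brute_force_sums_of_squares(self):
        """F statistics on a balanced 2x2 toy table equal the hand
        sums-of-squares computation, and the SS partition is conserved."""
        table = _toy_table()
        ref = brute_force_two_way_anova(table, "alpha")
        aov = two_way_anova(table, "alpha")
        assert aov.loc["group", "F"] == pytest.approx(ref["F_group"], rel=1e-9)
        assert aov.loc["layer", "F"] == pytest.approx(ref["F_layer"], rel=1e-9)
        assert aov.loc["group:layer", "F"] == pytest.approx(
            ref["F_interaction"], rel=1e-9
        )
        assert ref["ss_total"] == pytest.approx(ref["ss_parts"], rel=1e-12)
        assert aov["sum_sq"].sum() == pytest.approx(ref["ss_total"], rel=1e-9)

    @staticmethod
    def _depth_style_table(offset_lam=0.0, seed=0, sd=0.02):
        rng = np.random.default_rng(seed)
        rows = []
        depths_by_layer = {"III": [400, 600], "IV": [800], "V": [1000, 1200, 1400], "VI": [1600, 1800]}
        for g, lam0 in (("control", 1.5), ("etoh", 1.5 - offset_lam)):
            for i in range(6):
                for layer, depths in depths_by_layer.items():
                    for d in depths:
                        rows.append(
                            {
                                "group": g,
                                "animal_id": f"{g}_{i}",
                                "depth": d,
                                "layer": layer,
                                "alpha": 0.2 + rng.normal(0, 0.01),
                                "lam": lam0 + rng.normal(0, sd),
                                "kprime": 0.004,
                            }
                        )
        return pd.DataFrame(rows)

    def test_strong_group_offset_detected(self):
        """Groups 5 SD apart in tortuosity give a decisive group effect."""
        table = self._depth_style_table(offset_lam=0.1, seed=1)
        res = compare_groups(table)
        assert res.anova["lam"].loc["group", "PR(>F)"] < 1e-3
        assert res.pooled["lam"]["p"] < 1e-3
        assert res.pooled["lam"]["mean_difference"] > 0

    def test_null_cohort_pools_layers(self):
        table = self._depth_style_table(offset_lam=0.0, seed=2)
        res = compare_groups(table)
        assert res.pooled_applied["lam"] in (True, False)  # decision exists
        # no layer structure was generated, so pooling should be typical
        assert res.anova["lam"].loc["layer", "PR(>F)"] > 0.001

    def test_missing_cell_raises(self):
        table = self._depth_style_table(seed=3)
        table = table[~((table.group == "etoh") & (table.layer == "IV"))]
        with pytest.raises(ValueError, match="etoh"):
            compare_groups(table)
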