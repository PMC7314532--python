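"""Inverse problem and cohort analysis for real-time iontophoresis.

Workflow mirrors the experimental protocol: the ion-selective electrode
is first calibrated against a concentration series (log-linear, Nernstian
response); a curve recorded in dilute agar — where by definition
alpha = 1, lam = 1, k' = 0 — is fitted to yield the electrode transport
number and the free diffusion coefficient; tissue curves are then fitted
for (alpha, lam, kprime) with those two quantities held fixed.  Repeats
at each depth are averaged, depths map onto cortical layers, and groups
are compared by two-way ANOVA (group x layer) with the layer factor
pooled when it shows no effect.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .core import (
    CalibrationTable,
    DiffusionCurve,
    ECSParameters,
    IontophoreticSource,
    point_source_concentration,
)

__all__ = [
    "ElectrodeCalibration",
    "AgarFit",
    "TissueFit",
    "CohortResult",
    "calibrate_electrode",
    "fit_agar",
    "fit_tissue",
    "average_repeats",
    "assign_layer",
    "fit_cohort",
    "group_means",
    "compare_groups",
    "LAYER_OF_DEPTH",
    "CORTICAL_LAYERS",
]

# Depth (um below surface) -> cortical layer.
LAYER_OF_DEPTH: dict[int, str] = {
    400: "III",
    600: "III",
    800: "IV",
    1000: "V",
    1200: "V",
    1400: "V",
    1600: "VI",
    1800: "VI",
    2000: "WM",
}
#: Layers entering the group x layer ANOVA (white matter is excluded).
CORTICAL_LAYERS: tuple[str, ...] = ("III", "IV", "V", "VI")

# Fit bounds.  lam may drop to 0.9 so noise on free-medium curves does not
# pin the estimate at the physical bound lam = 1.
_TISSUE_BOUNDS = ((0.01, 0.9, 0.0), (1.0, 3.0, 0.1))
_TISSUE_STARTS = [
    (a, l, k)
    for a in (0.1, 0.2, 0.3)
    for l in (1.2, 1.5, 1.8)
    for k in (0.0, 0.005)
]


@dataclass
class ElectrodeCalibration:
    """Log-linear electrode response V = offset + slope * log10(C)."""

    slope: float  # mV per decade
    offset: float  # mV
    residual_rms: float  # mV
    monotone: bool = True

    def voltage_to_concentration(self, voltage: float | np.ndarray) -> np.ndarray:
        return 10.0 ** ((np.asarray(voltage, dtype=float) - self.offset) / self.slope)

    def concentration_to_voltage(self, conc: float | np.ndarray) -> np.ndarray:
        return self.offset + self.slope * np.log10(np.asarray(conc, dtype=float))


@dataclass
class AgarFit:
    """Free-medium fit yielding electrode transport number and free D."""

    transport_number: float
    free_D: float  # cm^2/s
    ssr: float  # uM^2
    converged: bool


@dataclass
class TissueFit:
    """Tissue fit for the three ECS diffusion parameters."""

    params: ECSParameters
    ssr: float  # uM^2
    converged: bool
    n_starts_used: int = 0
    at_bound: bool = False


@dataclass
class CohortResult:
    """Group comparison output for one synthetic or measured cohort."""

    table: pd.DataFrame  # one row per animal x layer cell
    anova: dict[str, pd.DataFrame]  # parameter -> ANOVA table
    pooled: dict[str, dict]  # parameter -> pooled two-sample contrast
    pooled_applied: dict[str, bool]
    group_summary: pd.DataFrame  # mean +/- SE per group and parameter


def calibrate_electrode(table: CalibrationTable) -> ElectrodeCalibration:
    """Least-squares log-linear calibration of the ion-selective electrode."""
    if table.concentrations.size < 3:
        raise ValueError("calibration requires at least 3 points")
    x = np.log10(table.concentrations)
    slope, offset = np.polyfit(x, table.voltages, 1)
    resid = table.voltages - (offset + slope * x)
    monotone = bool(np.all(np.diff(table.voltages) > 0))
    return ElectrodeCalibration(
        slope=float(slope),
        offset=float(offset),
        residual_rms=float(np.sqrt(np.mean(resid**2))),
        monotone=monotone,
    )


def _curve_model(
    curve: DiffusionCurve,
    transport_number: float,
    free_D: float,
    ecs: ECSParameters,
    template: IontophoreticSource,
) -> np.ndarray:
    src = IontophoreticSource(
        bias_current=template.bias_current,
        step_current=template.step_current,
        pulse_duration=template.pulse_duration,
        transport_number=transport_number,
        free_D=free_D,
        valence=template.valence,
    )
    return np.asarray(point_source_concentration(curve.distance, curve.times, src, ecs))


def fit_agar(
    curve: DiffusionCurve, source: IontophoreticSource | None = None
) -> AgarFit:
    """Fit (transport_number, free_D) to a free-diffusion reference curve.

    alpha = 1, lam = 1, k' = 0 are held fixed; the current protocol
    (bias, step, duration) is taken from ``source`` or the defaults.
    """
    if curve.medium != "agar":
        raise ValueError("fit_agar expects a curve recorded in agar")
    template = source or IontophoreticSource()
    free = ECSParameters(alpha=1.0, lam=1.0, kprime=0.0)
    if curve.peak <= 0:
        return AgarFit(np.nan, np.nan, float(np.sum(curve.concentration**2)), False)

    def residuals(theta: np.ndarray) -> np.ndarray:
        n_t, logD = theta
        model = _curve_model(curve, n_t, 10.0**logD, free, template)
        return model - curve.concentration

    best = None
    for n0, d0 in itertools.product((0.1, 0.3, 0.6), (6e-6, 1.24e-5, 2.4e-5)):
        try:
            res = optimize.least_squares(
                residuals,
                x0=[n0, np.log10(d0)],
                bounds=([1e-4, -7.0], [1.0, -3.5]),
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        return AgarFit(np.nan, np.nan, np.inf, False)
    ssr = float(2 * best.cost)
    rel = ssr / float(np.sum(curve.concentration**2))
    return AgarFit(
        transport_number=float(best.x[0]),
        free_D=float(10.0 ** best.x[1]),
        ssr=ssr,
        converged=bool(best.success and rel < 0.5),
    )


def fit_tissue(
    curve: DiffusionCurve,
    agar: AgarFit,
    source: IontophoreticSource | None = None,
    starts: Sequence[tuple[float, float, float]] | None = None,
) -> TissueFit:
    """Fit (alpha, lam, kprime) with the agar-derived (n_t, D) held fixed.

    Bounded least squares from a multi-start grid; the lowest-SSR
    converged solution wins, ties broken by fewest function evaluations.
    """
    if not agar.converged:
        raise ValueError("agar fit must have converged before fitting tissue")
    template = source or IontophoreticSource()
    starts = starts if starts is not None else _TISSUE_STARTS

    def residuals(theta: np.ndarray) -> np.ndarray:
        ecs = ECSParameters(alpha=theta[0], lam=theta[1], kprime=theta[2])
        model = _curve_model(
            curve, agar.transport_number, agar.free_D, ecs, template
        )
        return model - curve.concentration

    lo, hi = _TISSUE_BOUNDS
    best = None
    best_key = None
    n_used = 0
    for x0 in starts:
        n_used += 1
        try:
            res = optimize.least_squares(
                residuals,
                x0=np.asarray(x0, dtype=float),
                bounds=(np.asarray(lo), np.asarray(hi)),
                x_scale=[0.1, 0.5, 0.01],
                xtol=1e-12,
                ftol=1e-12,
            )
        except Exception:
            continue
        key = (res.cost, res.nfev)
        if best is None or key < best_key:
            best, best_key = res, key
        # A start that already explains the curve essentially exactly
        # cannot be improved upon; skip the rest of the grid.
        if res.success and 2 * res.cost < 1e-16 * max(curve.peak, 1.0) ** 2:
            break
    if best is None:
        return TissueFit(ECSParameters(0.5, 1.5, 0.0), np.inf, False, n_used)
    params = ECSParameters(
        alpha=float(best.x[0]), lam=float(best.x[1]), kprime=float(best.x[2])
    )
    atol = 1e-8
    at_bound = bool(
        np.any(np.abs(best.x - np.asarray(lo)) < atol)
        or np.any(np.abs(best.x - np.asarray(hi)) < atol)
    )
    return TissueFit(
        params=params,
        ssr=float(2 * best.cost),
        converged=bool(best.success),
        n_starts_used=n_used,
        at_bound=at_bound,
    )


def average_repeats(fits: Iterable[TissueFit]) -> ECSParameters:
    """Arithmetic mean of the ECS parameters over converged repeat fits."""
    good = [f for f in fits if f.converged]
    if not good:
        raise ValueError("no converged fits to average")
    return ECSParameters(
        alpha=float(np.mean([f.params.alpha for f in good])),
        lam=float(np.mean([f.params.lam for f in good])),
        kprime=float(np.mean([f.params.kprime for f in good])),
    )


def assign_layer(depth: float) -> str:
    """Map a recording depth (um) onto its cortical layer label."""
    key = int(depth)
    if key != depth or key not in LAYER_OF_DEPTH:
        raise ValueError(
            f"depth {depth} um is not one of the sampled depths "
            f"{sorted(LAYER_OF_DEPTH)}"
        )
    return LAYER_OF_DEPTH[key]


def fit_cohort(
    curves: Sequence[DiffusionCurve],
    agar: AgarFit,
    source: IontophoreticSource | None = None,
) -> pd.DataFrame:
    """Fit every tissue curve, average repeats per depth, assign layers.

    Returns one row per (group, animal, depth) with the averaged ECS
    parameters and the layer label.
    """
    rows = []
    keyfunc = lambda c: (c.group, c.animal_id, c.depth)
    curves = sorted(curves, key=keyfunc)
    for (group, animal, depth), reps in itertools.groupby(curves, key=keyfunc):
        fits = [fit_tissue(c, agar, source=source) for c in reps]
        mean = average_repeats(fits)
        rows.append(
            {
                "group": group,
                "animal_id": animal,
                "depth": depth,
                "layer": assign_layer(depth),
                "alpha": mean.alpha,
                "lam": mean.lam,
                "kprime": mean.kprime,
                "n_converged": sum(f.converged for f in fits),
                "n_repeats": len(fits),
            }
        )
    return pd.DataFrame(rows)


def group_means(depth_table: pd.DataFrame) -> pd.DataFrame:
    """Per-group mean +/- SE of each parameter, averaging depths within animal.

    Each animal contributes a single value per parameter (the mean of its
    per-depth values); the group mean and SE are taken across animals.
    """
    per_animal = (
        depth_table.groupby(["group", "animal_id"])[["alpha", "lam", "kprime"]]
        .mean()
        .reset_index()
    )
    agg = per_animal.groupby("group")[["alpha", "lam", "kprime"]].agg(["mean", "sem"])
    agg.columns = [f"{p}_{s}" for p, s in agg.columns]
    return agg.reset_index()


def _layer_table(depth_table: pd.DataFrame) -> pd.DataFrame:
    """Average per-depth values within each animal x layer cell."""
    return (
        depth_table[depth_table["layer"].isin(CORTICAL_LAYERS)]
        .groupby(["group", "animal_id", "layer"])[["alpha", "lam", "kprime"]]
        .mean()
        .reset_index()
    )


def two_way_anova(
    table: pd.DataFrame, value: str, factor_a: str = "group", factor_b: str = "layer"
) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA with interaction (type II sums of squares)."""
    import statsmodels.api as sm
    from statsmodels.formula.api import ols

    data = table.rename(columns={value: "y", factor_a: "A", factor_b: "B"})
    model = ols("y ~ C(A) * C(B)", data=data).fit()
    aov = sm.stats.anova_lm(model, typ=2)
    aov.index = [factor_a, factor_b, f"{factor_a}:{factor_b}", "Residual"]
    return aov


def compare_groups(
    depth_table: pd.DataFrame,
    parameters: Sequence[str] = ("alpha", "lam"),
    pool_threshold: float = 0.05,
) -> CohortResult:
    """Two-way group x cortical-layer ANOVA per parameter, with layer pooling.

    When neither the layer main effect nor the interaction reaches
    ``pool_threshold``, the layers are pooled and a two-sample Welch
    contrast between groups (one value per animal) is reported; this
    pooled contrast is an interpretation of the pooling step, reported
    alongside the ANOVA group effect rather than replacing it.
    """
    cells = _layer_table(depth_table)
    groups = sorted(cells["group"].unique())
    layers = [l for l in CORTICAL_LAYERS if l in set(cells["layer"])]
    if len(groups) < 2 or len(layers) < 2:
        raise ValueError("need >= 2 groups and >= 2 cortical layers")
    missing = [
        (g, l)
        for g in groups
        for l in layers
        if ((cells["group"] == g) & (cells["layer"] == l)).sum() < 2
    ]
    if missing:
        raise ValueError(f"cells with < 2 observations: {missing}")

    anova: dict[str, pd.DataFrame] = {}
    pooled: dict[str, dict] = {}
    pooled_applied: dict[str, bool] = {}
    for p in parameters:
        aov = two_way_anova(cells, p)
        anova[p] = aov
        pool = bool(
            aov.loc["layer", "PR(>F)"] >= pool_threshold
            and aov.loc["group:layer", "PR(>F)"] >= pool_threshold
        )
        pooled_applied[p] = pool
        per_animal = cells.groupby(["group", "animal_id"])[p].mean().reset_index()
        a = per_animal.loc[per_animal["group"] == groups[0], p].to_numpy()
        b = per_animal.loc[per_animal["group"] == groups[1], p].to_numpy()
        t, pval = stats.ttest_ind(a, b, equal_var=False)
        pooled[p] = {
            "groups": (groups[0], groups[1]),
            "mean_difference": float(np.mean(a) - np.mean(b)),
            "t": float(t),
            "p": float(pval),
        }
    return CohortResult(
        table=cells,
        anova=anova,
        pooled=pooled,
        pooled_applied=pooled_applied,
        group_summary=group_means(depth_table),
    )
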