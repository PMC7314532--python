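"""Seeded synthetic-data generators.

Everything the analysis pipeline consumes can be synthesised here with
known ground truth: single noisy tracer curves, full two-group cohorts
mirroring the in-vivo design (animals x depths x repeats), electrode
calibration tables, and random neurite skeletons for the morphometry
index.  All randomness flows from explicit seeds; a cohort is a pure
function of its spec and master seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core import (
    DiffusionCurve,
    ECSParameters,
    IontophoreticSource,
    default_times,
    generate_curve,
)
from .morphometry import NeuriteSkeletonSummary

__all__ = [
    "CohortSpec",
    "CONTROL_TRUTH",
    "ETOH_TRUTH",
    "make_curve",
    "make_cohort",
    "make_calibration",
    "make_microglia_trees",
    "SyntheticTree",
]

#: Group-level generating truths: cortical estimates for naive and
#: alcohol-drinking animals.  Nonspecific uptake is not reported per
#: group; 0.004 1/s is a typical cortical value and is shared.
CONTROL_TRUTH = ECSParameters(alpha=0.196, lam=1.503, kprime=0.004)
ETOH_TRUTH = ECSParameters(alpha=0.176, lam=1.403, kprime=0.004)

#: Between-animal SDs calibrated so group-mean standard errors at
#: n = 6 animals/group approximate the reported +/-0.007 (alpha) and
#: +/-0.015 (lam): SD = SE * sqrt(6).
DEFAULT_BETWEEN_ANIMAL_SD = {"alpha": 0.017, "lam": 0.037, "kprime": 0.001}

_PARAM_BOUNDS = {"alpha": (0.01, 1.0), "lam": (1.0, 3.0), "kprime": (0.0, 0.1)}


@dataclass
class CohortSpec:
    """Design of a synthetic two-group iontophoresis cohort."""

    groups: Mapping[str, ECSParameters] = field(
        default_factory=lambda: {"control": CONTROL_TRUTH, "etoh": ETOH_TRUTH}
    )
    n_animals: int = 6
    depths: Sequence[float] = tuple(range(400, 2001, 200))
    repeats: int = 3
    between_animal_sd: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_BETWEEN_ANIMAL_SD)
    )
    noise_fraction: float = 0.02
    spacing_range: tuple[float, float] = (100.0, 150.0)
    master_seed: int = 0
    source: IontophoreticSource = field(default_factory=IontophoreticSource)

    def __post_init__(self) -> None:
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.repeats < 1:
            raise ValueError("repeats must be >= 1")
        lo, hi = self.spacing_range
        if not (100.0 <= lo <= hi <= 150.0):
            raise ValueError("electrode spacing must lie within [100, 150] um")


def make_curve(
    true_params: ECSParameters,
    source: IontophoreticSource,
    r: float,
    noise_fraction: float = 0.02,
    seed: int | np.random.Generator = 0,
    times: np.ndarray | None = None,
    **curve_meta,
) -> tuple[DiffusionCurve, dict]:
    """One noisy tracer curve plus its ground-truth record.

    Noise is additive Gaussian with SD equal to ``noise_fraction`` times
    the noiseless curve peak (measurement noise referenced to signal
    amplitude).
    """
    if noise_fraction < 0:
        raise ValueError("noise_fraction must be >= 0")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if times is None:
        times = default_times(source.pulse_duration)
    clean = generate_curve(source, true_params, r, times, **curve_meta)
    sd = noise_fraction * clean.peak
    noisy = clean.concentration + rng.normal(0.0, sd, size=clean.concentration.shape) if sd > 0 else clean.concentration
    curve = DiffusionCurve(
        distance=r,
        times=times,
        concentration=noisy,
        medium=clean.medium,
        depth=clean.depth,
        animal_id=clean.animal_id,
        group=clean.group,
    )
    truth = {
        "alpha": true_params.alpha,
        "lam": true_params.lam,
        "kprime": true_params.kprime,
        "distance": r,
        "noise_sd": sd,
    }
    return curve, truth


def _draw_truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, bounds: tuple[float, float]
) -> float:
    if sd == 0:
        return mean
    lo, hi = bounds
    for _ in range(1000):
        x = rng.normal(mean, sd)
        if lo <= x <= hi:
            return float(x)
    raise RuntimeError(
        f"truncated-normal rejection failed for mean={mean}, sd={sd}, bounds={bounds}"
    )


def make_cohort(spec: CohortSpec) -> tuple[list[DiffusionCurve], pd.DataFrame]:
    """Generate every curve of a two-group cohort plus its truth table.

    Per animal the three ECS parameters are drawn from truncated normals
    around the group truth; per depth, ``repeats`` noisy curves are
    generated at an electrode spacing drawn once per animal.  The whole
    cohort is a deterministic function of the master seed.
    """
    root = np.random.SeedSequence(spec.master_seed)
    group_seqs = root.spawn(len(spec.groups))
    curves: list[DiffusionCurve] = []
    rows = []
    for (gname, gtruth), gseq in zip(spec.groups.items(), group_seqs):
        animal_seqs = gseq.spawn(spec.n_animals)
        for i, aseq in enumerate(animal_seqs):
            rng = np.random.default_rng(aseq)
            animal_id = f"{gname}_{i + 1:02d}"
            truth = ECSParameters(
                alpha=_draw_truncated_normal(
                    rng,
                    gtruth.alpha,
                    spec.between_animal_sd.get("alpha", 0.0),
                    _PARAM_BOUNDS["alpha"],
                ),
                lam=_draw_truncated_normal(
                    rng,
                    gtruth.lam,
                    spec.between_animal_sd.get("lam", 0.0),
                    _PARAM_BOUNDS["lam"],
                ),
                kprime=_draw_truncated_normal(
                    rng,
                    gtruth.kprime,
                    spec.between_animal_sd.get("kprime", 0.0),
                    _PARAM_BOUNDS["kprime"],
                ),
            )
            spacing = rng.uniform(*spec.spacing_range)
            for depth in spec.depths:
                for rep in range(spec.repeats):
                    curve, _ = make_curve(
                        truth,
                        spec.source,
                        spacing,
                        noise_fraction=spec.noise_fraction,
                        seed=rng,
                        medium="tissue",
                        depth=float(depth),
                        animal_id=animal_id,
                        group=gname,
                    )
                    curves.append(curve)
                    rows.append(
                        {
                            "group": gname,
                            "animal_id": animal_id,
                            "depth": float(depth),
                            "repeat": rep,
                            "distance": spacing,
                            "true_alpha": truth.alpha,
                            "true_lam": truth.lam,
                            "true_kprime": truth.kprime,
                            "group_alpha": gtruth.alpha,
                            "group_lam": gtruth.lam,
                            "group_kprime": gtruth.kprime,
                        }
                    )
    return curves, pd.DataFrame(rows)


def make_calibration(
    slope: float = 58.0,
    offset: float = 0.0,
    noise_mV: float = 0.0,
    seed: int = 0,
    concentrations: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0, 16.0),
):
    """Synthetic electrode calibration table (log-linear + optional noise)."""
    from .core import CalibrationTable

    if slope <= 0:
        raise ValueError("slope must be > 0")
    conc = np.asarray(concentrations, dtype=float)
    rng = np.random.default_rng(seed)
    v = offset + slope * np.log10(conc)
    if noise_mV > 0:
        v = v + rng.normal(0.0, noise_mV, size=conc.shape)
    return CalibrationTable(concentrations=conc, voltages=v)


@dataclass
class SyntheticTree:
    """A random neurite tree: segments plus the exact summary they imply.

    ``segments`` is a list of (node_id, parent_id, branch_order, length);
    the root soma is parent -1.  ``summary`` is computed from the segment
    list by direct traversal, so tests can recompute it independently.
    """

    segments: list[tuple[int, int, int, float]]
    summary: NeuriteSkeletonSummary


def make_microglia_trees(
    n: int,
    seed: int = 0,
    n_primary_range: tuple[int, int] = (2, 5),
    branch_prob: float = 0.5,
    max_order: int = 5,
    segment_length_range: tuple[float, float] = (5.0, 25.0),
) -> list[SyntheticTree]:
    """Random rooted process trees emulating microglial ramification.

    Primary processes leave the soma at order 1; each segment bifurcates
    with probability ``branch_prob`` until ``max_order``.  Terminal
    orders, counts and total length are computed exactly from the
    generated segments.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    trees = []
    for _ in range(n):
        n_primary = int(rng.integers(n_primary_range[0], n_primary_range[1] + 1))
        segments: list[tuple[int, int, int, float]] = []
        next_id = 0
        frontier: list[tuple[int, int]] = []  # (node_id, order)
        for _p in range(n_primary):
            length = float(rng.uniform(*segment_length_range))
            segments.append((next_id, -1, 1, length))
            frontier.append((next_id, 1))
            next_id += 1
        terminal_orders: list[int] = []
        while frontier:
            node, order = frontier.pop()
            if order < max_order and rng.random() < branch_prob:
                for _c in range(2):
                    length = float(rng.uniform(*segment_length_range))
                    segments.append((next_id, node, order + 1, length))
                    frontier.append((next_id, order + 1))
                    next_id += 1
            else:
                terminal_orders.append(order)
        summary = NeuriteSkeletonSummary(
            terminal_orders=sorted(terminal_orders),
            n_terminals=len(terminal_orders),
            total_length=float(sum(s[3] for s in segments)),
            n_primary=n_primary,
        )
        trees.append(SyntheticTree(segments=segments, summary=summary))
    return trees
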