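"""Dopamine volume transmission: reaction-diffusion with saturable uptake.

Dopamine released from a small spherical source spreads through the
extracellular space and is cleared by the dopamine transporter, whose
kinetics saturate (Michaelis-Menten).  With spherical symmetry the ECS
concentration C(r, t) obeys

    dC/dt = D* (d2C/dr2 + (2/r) dC/dr) - Vm C / (Km + C),

where D* = D_free / lam**2 is the effective diffusion coefficient.  The
source is represented as a prescribed flux through the sphere surface at
r = a:

    -D* dC/dr |_(r=a) = Q(t) / (4 pi a^2 alpha),

with Q(t) the molar release rate derived from the source current, so that
a smaller volume fraction alpha concentrates the same release into less
ECS volume.

The solver is a conservative finite-volume discretisation on a radially
stretched grid (method of lines) integrated with a stiff adaptive ODE
integrator; with Vm = 0 the scheme conserves ECS mass to the time
integrator's tolerance by construction.  Release waveforms (constant
"tonic" vs 20-Hz burst "phasic") enter as piecewise-constant currents and
the integration is restarted at each current discontinuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.integrate import solve_ivp
from scipy.sparse import diags

from .core import CM2_TO_UM2, FARADAY, MOL_PER_UM3_TO_UM

__all__ = [
    "ECSGeometry",
    "UptakeKinetics",
    "ReleaseProtocol",
    "SimulationGrid",
    "ConcentrationField",
    "CONTROL_GEOMETRY",
    "ETOH_GEOMETRY",
    "DEFAULT_KINETICS",
    "release_waveform",
    "solve_dopamine",
    "field_difference",
    "integrate_space",
    "integrate_time",
    "vm_scan",
]

DOPAMINE_FREE_D = 6.9e-6  # cm^2/s


@dataclass(frozen=True)
class ECSGeometry:
    """ECS volume fraction and tortuosity defining one tissue substrate."""

    alpha: float
    lam: float

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha <= 1.0:
            raise ValueError("alpha must be in (0, 1]")
        if self.lam < 1.0:
            raise ValueError("lam must be >= 1")

    @property
    def effective_D(self) -> float:
        """D* = D_free / lam**2 in um^2/s."""
        return DOPAMINE_FREE_D * CM2_TO_UM2 / self.lam**2


#: Substrates measured by real-time iontophoresis: naive and alcohol-exposed.
CONTROL_GEOMETRY = ECSGeometry(alpha=0.20, lam=1.54)
ETOH_GEOMETRY = ECSGeometry(alpha=0.19, lam=1.39)


@dataclass(frozen=True)
class UptakeKinetics:
    """Michaelis-Menten transporter kinetics: rate = Vm * C / (Km + C)."""

    Vm: float = 0.2  # uM/s
    Km: float = 0.15  # uM

    def __post_init__(self) -> None:
        if self.Vm < 0:
            raise ValueError("Vm must be >= 0")
        if self.Km <= 0:
            raise ValueError("Km must be > 0")


@dataclass(frozen=True)
class ReleaseProtocol:
    """Source waveform: constant (tonic) or 20-Hz bursts (phasic).

    The phasic amplitude is by default normalised so that the total
    delivered charge equals the tonic protocol's (current * duration);
    set ``normalization='amplitude'`` to use the nominal current in each
    burst instead.
    """

    pattern: Literal["tonic", "phasic"] = "tonic"
    total_duration: float = 1.0  # s
    current: float = 100.0  # nA
    burst_width: float = 0.004  # s
    burst_frequency: float = 20.0  # Hz
    source_radius: float = 2.0  # um
    transport_number: float = 1.0
    normalization: Literal["charge", "amplitude"] = "charge"

    def __post_init__(self) -> None:
        if self.source_radius <= 0:
            raise ValueError("source_radius must be > 0")
        if self.total_duration <= 0 or self.current < 0:
            raise ValueError("total_duration must be > 0 and current >= 0")
        if self.pattern == "phasic":
            if self.burst_width * self.burst_frequency > 1.0:
                raise ValueError("burst duty cycle exceeds 1")

    @property
    def n_bursts(self) -> int:
        return int(np.floor(self.burst_frequency * self.total_duration - 1e-12)) + 1

    @property
    def burst_amplitude(self) -> float:
        """Current during each burst (nA)."""
        on_time = self.n_bursts * self.burst_width
        if self.normalization == "charge":
            return self.current * self.total_duration / on_time
        return self.current

    def breakpoints(self, t_max: float) -> np.ndarray:
        """Times where the source current is discontinuous, within [0, t_max]."""
        if self.pattern == "tonic":
            pts = [0.0, self.total_duration]
        else:
            pts = [0.0]
            for k in range(self.n_bursts):
                start = k / self.burst_frequency
                pts += [start, start + self.burst_width]
            pts.append(self.total_duration)
        pts = sorted({p for p in pts if 0.0 <= p <= t_max} | {0.0, t_max})
        return np.asarray(pts)

    def total_moles(self) -> float:
        """Total moles released over the protocol."""
        if self.pattern == "tonic":
            charge = self.current * 1e-9 * self.total_duration
        else:
            charge = (
                self.burst_amplitude * 1e-9 * self.burst_width * self.n_bursts
            )
        return charge * self.transport_number / FARADAY


def release_waveform(
    protocol: ReleaseProtocol, t: float | np.ndarray
) -> float | np.ndarray:
    """Source current (nA) at time(s) t."""
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("t must be >= 0")
    if protocol.pattern == "tonic":
        out = np.where(t_arr <= protocol.total_duration, protocol.current, 0.0)
    else:
        phase = t_arr * protocol.burst_frequency
        in_burst = (phase - np.floor(phase)) < (
            protocol.burst_width * protocol.burst_frequency
        )
        out = np.where(
            (t_arr <= protocol.total_duration) & in_burst,
            protocol.burst_amplitude,
            0.0,
        )
    return out if np.ndim(t) else float(out[0])


@dataclass
class SimulationGrid:
    """Radial/time grid: fine near the source, stretched toward the far field.

    The solver domain extends to ``r_pad`` (well beyond the reported
    window) so the zero-concentration outer boundary does not influence
    the solution; cell widths grow geometrically from ``dr`` near the
    source to ``dr_far``.
    """

    r_max_report: float = 100.0  # um
    t_max: float = 3.0  # s
    r_pad: float = 300.0  # um
    dr: float = 0.25  # um, near-source cell width
    dr_far: float = 2.0  # um, far-field cell width
    fine_radius: float = 10.0  # um, extent of the uniform fine region
    stretch: float = 1.05
    n_times: int = 121

    def __post_init__(self) -> None:
        if self.r_pad < 2 * self.r_max_report:
            raise ValueError("r_pad must be >= 2 * r_max_report")
        if self.dr > 1.0:
            raise ValueError("dr must be <= 1 um near the source")

    @property
    def output_times(self) -> np.ndarray:
        return np.linspace(0.0, self.t_max, self.n_times)

    def cell_edges(self, a: float) -> np.ndarray:
        """Cell edges from the source surface r = a out to r_pad."""
        edges = [a]
        h = self.dr
        while edges[-1] < self.r_pad:
            if edges[-1] >= self.fine_radius and h < self.dr_far:
                h = min(h * self.stretch, self.dr_far)
            edges.append(edges[-1] + h)
        edges[-1] = self.r_pad
        return np.asarray(edges)


@dataclass
class ConcentrationField:
    """C(r, t) on a radial/time grid, with provenance."""

    r: np.ndarray  # um, cell centres
    t: np.ndarray  # s
    C: np.ndarray  # uM, shape (len(t), len(r))
    geometry: ECSGeometry
    kinetics: UptakeKinetics
    protocol: ReleaseProtocol
    cell_volumes: np.ndarray | None = None  # um^3, matching r

    def __post_init__(self) -> None:
        if self.C.shape != (self.t.size, self.r.size):
            raise ValueError("C must have shape (len(t), len(r))")


def _fv_operator(edges: np.ndarray, D_star: float):
    """Conservative finite-volume diffusion operator on spherical shells.

    Returns (centres, volumes, apply) where apply(C, flux_in) gives dC/dt
    from diffusion alone; flux_in is the molar-equivalent inflow rate
    (uM um^3/s per unit ECS, i.e. already divided by alpha) through the
    inner surface.
    """
    centres = 0.5 * (edges[:-1] + edges[1:])
    volumes = 4.0 * np.pi / 3.0 * (edges[1:] ** 3 - edges[:-1] ** 3)
    areas = 4.0 * np.pi * edges**2  # faces, len = n+1
    dcent = np.diff(centres)
    # transmissibility of interior faces: D* A / distance between centres
    trans = D_star * areas[1:-1] / dcent
    # outer Dirichlet C = 0 enforced through the last face
    trans_out = D_star * areas[-1] / (edges[-1] - centres[-1])
    n = centres.size

    def apply(C: np.ndarray, inflow: float) -> np.ndarray:
        dC = np.zeros(n)
        f = trans * (C[1:] - C[:-1])  # flux from i+1 into i, uM um^3/s
        dC[:-1] += f
        dC[1:] -= f
        dC[0] += inflow
        dC[-1] -= trans_out * C[-1]
        return dC / volumes

    def jacobian_diags(inv_vol: np.ndarray):
        lower = trans * inv_vol[1:]
        upper = trans * inv_vol[:-1]
        main = np.zeros(n)
        main[:-1] -= trans * inv_vol[:-1]
        main[1:] -= trans * inv_vol[1:]
        main[-1] -= trans_out * inv_vol[-1]
        return lower, main, upper

    return centres, volumes, apply, jacobian_diags


def solve_dopamine(
    geometry: ECSGeometry,
    kinetics: UptakeKinetics,
    protocol: ReleaseProtocol,
    grid: SimulationGrid | None = None,
    full_domain: bool = False,
    rtol: float = 1e-6,
    atol: float = 1e-8,
) -> ConcentrationField:
    """Solve the spherically symmetric dopamine diffusion-uptake equation.

    Method of lines: conservative finite volumes in r, BDF in t, with the
    integration restarted at every source-current discontinuity so the
    stiff integrator never steps across a jump.  The field is reported on
    the (r <= r_max_report, t <= t_max) window unless ``full_domain``.
    """
    grid = grid or SimulationGrid()
    D_star = geometry.effective_D
    a = protocol.source_radius
    edges = grid.cell_edges(a)
    centres, volumes, apply_diff, jac_diags = _fv_operator(edges, D_star)
    n = centres.size
    inv_vol = 1.0 / volumes

    Vm, Km = kinetics.Vm, kinetics.Km

    def inflow_at(current_nA: float) -> float:
        # molar rate -> uM um^3 / s, divided by alpha (flux into ECS concentration)
        Q = current_nA * 1e-9 * protocol.transport_number / FARADAY
        return Q * MOL_PER_UM3_TO_UM / geometry.alpha

    def rhs_factory(inflow: float):
        def rhs(t: float, C: np.ndarray) -> np.ndarray:
            dC = apply_diff(C, inflow)
            if Vm > 0:
                dC -= Vm * C / (Km + C)
            return dC

        return rhs

    lower, main, upper = jac_diags(inv_vol)

    def jac_factory():
        def jac(t: float, C: np.ndarray):
            d_main = main.copy()
            if Vm > 0:
                d_main = d_main - Vm * Km / (Km + C) ** 2
            return diags(
                [lower, d_main, upper], offsets=[-1, 0, 1], format="csc"
            )

        return jac

    out_times = grid.output_times
    breaks = protocol.breakpoints(grid.t_max)
    C = np.zeros(n)
    fields = np.zeros((out_times.size, n))
    written = np.zeros(out_times.size, dtype=bool)
    fields[out_times == 0.0] = 0.0
    written[out_times == 0.0] = True

    for t0, t1 in zip(breaks[:-1], breaks[1:]):
        if t1 <= t0:
            continue
        mid = 0.5 * (t0 + t1)
        current = float(np.atleast_1d(release_waveform(protocol, mid))[0])
        inflow = inflow_at(current)
        mask = (out_times > t0 + 1e-12) & (out_times <= t1 + 1e-12)
        t_eval = np.clip(out_times[mask], t0, t1)
        # always evaluate at the segment end so the state carries over exactly
        if t_eval.size == 0 or t_eval[-1] < t1 - 1e-12:
            t_eval_run = np.append(t_eval, t1)
        else:
            t_eval_run = t_eval
        sol = solve_ivp(
            rhs_factory(inflow),
            (t0, t1),
            C,
            method="BDF",
            t_eval=t_eval_run,
            jac=jac_factory(),
            rtol=rtol,
            atol=atol,
            first_step=min(1e-6, (t1 - t0) / 10),
        )
        if not sol.success:
            raise RuntimeError(
                f"stiff integration failed on [{t0}, {t1}]: {sol.message}"
            )
        if t_eval.size:
            fields[mask] = sol.y[:, : t_eval.size].T
            written[mask] = True
        C = sol.y[:, -1]

    neg = fields.min()
    tol_neg = 1e-6 * max(fields.max(), 1.0)
    if neg < -tol_neg:
        raise RuntimeError(f"negative concentrations beyond tolerance: {neg}")
    np.clip(fields, 0.0, None, out=fields)

    if full_domain:
        keep = slice(None)
    else:
        keep = centres <= grid.r_max_report
    return ConcentrationField(
        r=centres[keep],
        t=out_times,
        C=fields[:, keep],
        geometry=geometry,
        kinetics=kinetics,
        protocol=protocol,
        cell_volumes=volumes[keep],
    )


def field_difference(
    f_a: ConcentrationField, f_b: ConcentrationField
) -> ConcentrationField:
    """Elementwise signed difference f_a - f_b on identical grids."""
    if f_a.r.shape != f_b.r.shape or f_a.t.shape != f_b.t.shape:
        raise ValueError("fields are on different grids")
    if not (np.allclose(f_a.r, f_b.r) and np.allclose(f_a.t, f_b.t)):
        raise ValueError("fields are on different grids")
    out = ConcentrationField(
        r=f_a.r,
        t=f_a.t,
        C=f_a.C - f_b.C,
        geometry=f_a.geometry,
        kinetics=f_a.kinetics,
        protocol=f_a.protocol,
        cell_volumes=f_a.cell_volumes,
    )
    return out


def integrate_space(
    field: ConcentrationField,
    weighting: Literal["volume", "spatial", "plain"] = "volume",
) -> np.ndarray:
    """Space-integrated concentration for each time.

    ``volume`` weighting returns the moles of dopamine present in the ECS,
    M(t) = integral of C alpha 4 pi r^2 dr (mol); ``spatial`` omits the
    volume fraction, integral of C 4 pi r^2 dr (uM um^3) — the total
    concentration integrated across space, which differs between two
    geometries holding the same ECS mass; ``plain`` is the unweighted
    radial integral of C (uM um).
    """
    if weighting in ("volume", "spatial"):
        if field.cell_volumes is not None:
            tot = field.C @ field.cell_volumes  # uM um^3
        else:
            tot = np.trapezoid(field.C * 4 * np.pi * field.r**2, field.r, axis=1)
        if weighting == "spatial":
            return tot
        return tot * field.geometry.alpha / MOL_PER_UM3_TO_UM
    if weighting == "plain":
        return np.trapezoid(field.C, field.r, axis=1)
    raise ValueError(f"unknown weighting {weighting!r}")


def integrate_time(field: ConcentrationField) -> np.ndarray:
    """Time-integrated concentration S(r) = integral of C dt, uM s."""
    return np.trapezoid(field.C, field.t, axis=0)


def vm_scan(
    base: UptakeKinetics,
    multipliers: Sequence[float] = (-0.6, -0.3, 0.3, 0.6),
    geometry: ECSGeometry = CONTROL_GEOMETRY,
    protocol: ReleaseProtocol | None = None,
    grid: SimulationGrid | None = None,
) -> dict[float, ConcentrationField]:
    """Solve the field for Vm scaled by (1 + m) for each multiplier m."""
    protocol = protocol or ReleaseProtocol()
    out: dict[float, ConcentrationField] = {}
    for m in multipliers:
        vm = base.Vm * (1.0 + m)
        if vm < 0:
            raise ValueError(f"multiplier {m} yields negative Vm")
        out[m] = solve_dopamine(
            geometry, UptakeKinetics(Vm=vm, Km=base.Km), protocol, grid
        )
    return out


DEFAULT_KINETICS = UptakeKinetics()
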