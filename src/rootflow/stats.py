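"""Phase-averaged ensemble statistics and derived flow metrics.

Implements the post-processing chain applied to phase-locked velocity
ensembles: the phase average over N replicate cycles, the Reynolds
decomposition U = <U> + u with the pooled fluctuation magnitude
u_rms = <u . u>^(1/2), the rate-of-strain tensor S = (G + G^T)/2 and its
eigenvalue spread gamma_3D = eps_max - eps_min (with the 2D in-plane
analogue gamma_2D), cross-sectional net and retrograde flow rates,
domain-integrated mean/fluctuating kinetic energies, time-window means of
those series, and the dimensionless numbers of the experiment (Reynolds,
Womersley, Stokes).
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from rootflow.geometry import DomainMask, Grid
from rootflow.synth import PhaseEnsemble, VelocityField

__all__ = [
    "MeanField",
    "RmsField",
    "StrainField",
    "MetricsReport",
    "DimensionlessNumbers",
    "METRIC_WINDOWS",
    "phase_average",
    "u_rms",
    "phase_statistics",
    "velocity_gradient",
    "rate_of_strain",
    "gamma_3d",
    "gamma_2d",
    "net_flow_rate",
    "rf_flow_rate",
    "kinetic_energies",
    "window_metrics",
    "dimensionless_numbers",
]

#: Averaging windows [s] for the scalar comparison metrics: turbulence
#: intensity past the jet (fluctuating energy in Omega2), mid-systolic
#: retrograde flow rate, and sinus washout activity (mean energy in
#: OmegaS).
METRIC_WINDOWS: dict[str, tuple[float, float]] = {
    "E_TJ": (0.18, 0.36),
    "Q_RF": (0.15, 0.30),
    "E_MKS": (0.12, 0.27),
}


@dataclass
class MeanField:
    """Phase-averaged velocity <U> at one phase time."""

    grid: Grid
    u: np.ndarray  # (3, nx, ny, nz) [m/s]
    mask: np.ndarray
    t: float
    n: int
    flow_origin_y: float | None = None  # geometry-y of the flow coordinate Y=0

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=0))


@dataclass
class RmsField:
    """Pooled RMS velocity fluctuation u_rms at one phase time."""

    grid: Grid
    urms: np.ndarray  # (nx, ny, nz) [m/s]
    mask: np.ndarray
    t: float
    n: int


def phase_average(ensemble: PhaseEnsemble, j: int) -> MeanField:
    """Voxelwise arithmetic mean over the N replicates of phase ``j``."""
    n = ensemble.n_replicates
    if n < 1:
        raise ValueError("empty ensemble")
    acc = None
    for fld in ensemble.iter_phase(j):
        acc = fld.u.copy() if acc is None else acc + fld.u
    return MeanField(
        grid=ensemble.grid, u=acc / n, mask=ensemble.mask,
        t=float(ensemble.phase_times[j]), n=n,
    )


def u_rms(ensemble: PhaseEnsemble, mean_field: MeanField, j: int) -> RmsField:
    """u_rms = sqrt(mean_k |U_k - <U>|^2), the three component variances
    summed inside the mean, divisor N (population convention — required
    for the exact mean/fluctuating kinetic-energy decomposition)."""
    n = ensemble.n_replicates
    if n < 2:
        raise ValueError("u_rms undefined for N < 2 replicates")
    acc = np.zeros(ensemble.grid.shape)
    for fld in ensemble.iter_phase(j):
        acc += ((fld.u - mean_field.u) ** 2).sum(axis=0)
    return RmsField(
        grid=ensemble.grid, urms=np.sqrt(acc / n), mask=ensemble.mask,
        t=float(ensemble.phase_times[j]), n=n,
    )


def phase_statistics(ensemble: PhaseEnsemble, j: int) -> tuple[MeanField, RmsField]:
    """One-pass mean and RMS for phase ``j`` (sum and sum-of-squares);
    identical to :func:`phase_average` + :func:`u_rms` up to rounding."""
    n = ensemble.n_replicates
    if n < 2:
        raise ValueError("need N >= 2 replicates")
    s = np.zeros((3, *ensemble.grid.shape))
    s2 = np.zeros(ensemble.grid.shape)
    for fld in ensemble.iter_phase(j):
        s += fld.u
        s2 += (fld.u**2).sum(axis=0)
    mean_u = s / n
    var = np.maximum(s2 / n - (mean_u**2).sum(axis=0), 0.0)
    t = float(ensemble.phase_times[j])
    mean = MeanField(ensemble.grid, mean_u, ensemble.mask, t, n)
    rms = RmsField(ensemble.grid, np.sqrt(var), ensemble.mask, t, n)
    return mean, rms


# ---------------------------------------------------------------------------
# Differential operators
# ---------------------------------------------------------------------------


def _masked_derivative(f: np.ndarray, mask: np.ndarray, axis: int, h: float) -> np.ndarray:
    """Finite-difference derivative respecting a validity mask.

    Second-order central differences where both neighbours are valid,
    first-order one-sided at mask boundaries, NaN where no valid
    neighbour pair exists.  ``h`` is the grid spacing in metres (SI
    derivative of an m/s field -> 1/s).
    """
    if f.shape[axis] < 3:
        raise ValueError("need at least 3 voxels along each axis")

    def shift(a: np.ndarray, off: int) -> np.ndarray:
        out = np.full_like(a, np.nan if a.dtype.kind == "f" else False)
        src = [slice(None)] * a.ndim
        dst = [slice(None)] * a.ndim
        if off > 0:
            src[axis] = slice(off, None)
            dst[axis] = slice(None, -off)
        else:
            src[axis] = slice(None, off)
            dst[axis] = slice(-off, None)
        out[tuple(dst)] = a[tuple(src)]
        return out

    fp, fm = shift(f, +1), shift(f, -1)
    vp = shift(mask.astype(bool), +1) & True
    vm = shift(mask.astype(bool), -1) & True
    vp &= np.isfinite(fp)
    vm &= np.isfinite(fm)

    d = np.full(f.shape, np.nan)
    central = mask & vp & vm
    fwd = mask & vp & ~vm
    bwd = mask & ~vp & vm
    d[central] = (fp[central] - fm[central]) / (2.0 * h)
    d[fwd] = (fp[fwd] - f[fwd]) / h
    d[bwd] = (f[bwd] - fm[bwd]) / h
    return d


def velocity_gradient(field: VelocityField | MeanField) -> np.ndarray:
    """Velocity-gradient tensor G[i, j] = dU_i/dX_j, shape (3, 3, nx, ny,
    nz), in 1/s (grid spacing converted mm -> m).  NaN marks voxels where
    the derivative is undefined (outside the mask or isolated)."""
    grid, mask = field.grid, field.mask
    g = np.full((3, 3, *grid.shape), np.nan)
    for i in range(3):
        for j_ax in range(3):
            h_m = grid.spacing[j_ax] * 1.0e-3
            g[i, j_ax] = _masked_derivative(field.u[i], mask, j_ax, h_m)
    return g


def rate_of_strain(grad: np.ndarray) -> np.ndarray:
    """Symmetric part S = (G + G^T)/2 of a velocity-gradient tensor."""
    return 0.5 * (grad + np.swapaxes(grad, 0, 1))


@dataclass
class StrainField:
    """Rate-of-strain tensor and derived shear-rate scalars [1/s]."""

    grid: Grid
    S: np.ndarray  # (3, 3, nx, ny, nz)
    gamma3d: np.ndarray  # (nx, ny, nz)


def gamma_3d(strain: np.ndarray) -> np.ndarray:
    """Shear-rate scalar: spread between the extreme eigenvalues of the
    rate-of-strain tensor, per voxel.  ``strain`` has shape (3, 3, ...);
    NaN tensors propagate to NaN output."""
    s = np.moveaxis(strain, (0, 1), (-2, -1))
    flat = s.reshape(-1, 3, 3)
    valid = np.isfinite(flat).all(axis=(1, 2))
    out = np.full(flat.shape[0], np.nan)
    if valid.any():
        w = np.linalg.eigvalsh(flat[valid])
        out[valid] = w[:, -1] - w[:, 0]
    return out.reshape(s.shape[:-2])


def gamma_2d(
    field: VelocityField | MeanField, x_index: int | None = None
) -> np.ndarray:
    """In-plane shear rate on a grid-aligned Y-Z slice (default: the
    central slice at X = 0): eigenvalue spread of the 2x2 symmetrized
    gradient of the in-plane components (U_y, U_z).

    Underestimates :func:`gamma_3d` wherever out-of-plane gradients are
    present (Cauchy interlacing of principal submatrices).
    """
    grid, mask = field.grid, field.mask
    if x_index is None:
        x_index = int(np.argmin(np.abs(grid.coords(0))))
    if not (0 <= x_index < grid.counts[0]):
        raise ValueError("slice outside grid")
    uy = field.u[1][x_index]
    uz = field.u[2][x_index]
    m2 = mask[x_index]
    h_y = grid.spacing[1] * 1.0e-3
    h_z = grid.spacing[2] * 1.0e-3
    dyy = _masked_derivative(uy, m2, 0, h_y)
    dyz = _masked_derivative(uy, m2, 1, h_z)
    dzy = _masked_derivative(uz, m2, 0, h_y)
    dzz = _masked_derivative(uz, m2, 1, h_z)
    s12 = 0.5 * (dyz + dzy)
    # closed-form eigenvalue spread of [[a, c], [c, b]]
    return np.sqrt((dyy - dzz) ** 2 + 4.0 * s12**2)


# ---------------------------------------------------------------------------
# Integral quantities
# ---------------------------------------------------------------------------


def _section_index(field: MeanField, Y0: float) -> int:
    grid = field.grid
    origin = field.flow_origin_y if field.flow_origin_y is not None else 0.0
    y_geom = origin + Y0
    ys = grid.coords(1)
    if y_geom < ys[0] - 1e-9 or y_geom > ys[-1] + 1e-9:
        raise ValueError("cross-section outside grid")
    idx = int(np.argmin(np.abs(ys - y_geom)))
    if idx in (0, len(ys) - 1):
        raise ValueError("cross-section intersects grid edge")
    return idx


def net_flow_rate(field: MeanField, Y0: float = 0.0) -> float:
    """Net flow rate [m^3/s]: midpoint-rule integral of <U_y> over the
    lumen pixels of the cross-section at flow coordinate ``Y0``."""
    idx = _section_index(field, Y0)
    da_m2 = field.grid.spacing[0] * field.grid.spacing[2] * 1.0e-6
    uy = field.u[1][:, idx, :]
    m = field.mask[:, idx, :]
    return float(uy[m].sum() * da_m2)


def rf_flow_rate(field: MeanField, Y0: float = 0.0) -> float:
    """Retrograde flow rate [m^3/s, positive]: only negative <U_y> pixels
    integrated over the cross-section at ``Y0``."""
    idx = _section_index(field, Y0)
    da_m2 = field.grid.spacing[0] * field.grid.spacing[2] * 1.0e-6
    uy = field.u[1][:, idx, :]
    m = field.mask[:, idx, :]
    return float(-np.minimum(uy[m], 0.0).sum() * da_m2)


def kinetic_energies(
    mean_field: MeanField,
    rms_field: RmsField,
    mask: DomainMask | np.ndarray,
    rho: float = 1200.0,
) -> tuple[float, float]:
    """Domain-integrated mean and fluctuating kinetic energy [J]:

        E_MK = rho/2 * sum |<U>|^2 dV,   E_FK = rho/2 * sum u_rms^2 dV

    over the domain voxels (dV converted from mm^3 to m^3)."""
    m = mask.mask if isinstance(mask, DomainMask) else mask
    m = m & mean_field.mask
    if not m.any():
        warnings.warn("empty domain mask: zero energies", stacklevel=2)
        return 0.0, 0.0
    dv_m3 = mean_field.grid.voxel_volume * 1.0e-9
    e_mk = 0.5 * rho * float(((mean_field.u**2).sum(axis=0)[m]).sum()) * dv_m3
    e_fk = 0.5 * rho * float((rms_field.urms[m] ** 2).sum()) * dv_m3
    return e_mk, e_fk


def window_metrics(
    times: np.ndarray, series: np.ndarray, t_a: float, t_b: float
) -> float:
    """Time-window mean 1/(t_b - t_a) * integral(series dt) by the
    trapezoid rule over the phase samples inside [t_a, t_b] (the standard
    windows land exactly on phase samples)."""
    times = np.asarray(times, dtype=float)
    series = np.asarray(series, dtype=float)
    if t_a < times[0] - 1e-9 or t_b > times[-1] + 1e-9 or t_b <= t_a:
        raise ValueError("window not covered by the sampled series")
    sel = (times >= t_a - 1e-9) & (times <= t_b + 1e-9)
    ts, vs = times[sel], series[sel]
    return float(np.trapezoid(vs, ts) / (ts[-1] - ts[0]))


@dataclass(frozen=True)
class DimensionlessNumbers:
    Re: float
    alpha: float
    St: float
    d_jet_mm: float
    tau_s: float


def dimensionless_numbers(
    Q_max_lmin: float = 20.0,
    d_jet_mm: float | None = None,
    A_poa_mm2: float | None = None,
    nu_mm2s: float = 4.7,
    r_a_mm: float = 11.0,
    T_s: float = 60.0 / 72.0,
    U_ms: float = 2.0,
    rho: float = 1200.0,
    rho_p: float = 1180.0,
    d_p_um: float = 42.0,
) -> DimensionlessNumbers:
    """Dimensionless numbers of the pulse-duplicator experiment.

        Re = 4 Q_max / (pi d_jet nu)        jet Reynolds number
        alpha = r_a sqrt(2 pi / (T nu))     Womersley number
        St = tau U / d_p                    tracer Stokes number
        tau = rho_p d_p^2 / (18 rho nu)     particle relaxation time

    ``d_jet`` may be given directly or derived from the mean systolic
    projected orifice area as d_jet = sqrt(4 A_POA / pi).
    """
    if d_jet_mm is None:
        if A_poa_mm2 is None:
            raise ValueError("provide d_jet_mm or A_poa_mm2")
        if A_poa_mm2 <= 0:
            raise ValueError("A_POA must be positive")
        d_jet_mm = float(np.sqrt(4.0 * A_poa_mm2 / np.pi))
    for name, v in [
        ("Q_max_lmin", Q_max_lmin), ("d_jet_mm", d_jet_mm),
        ("nu_mm2s", nu_mm2s), ("r_a_mm", r_a_mm), ("T_s", T_s),
        ("U_ms", U_ms), ("rho", rho), ("rho_p", rho_p), ("d_p_um", d_p_um),
    ]:
        if v <= 0:
            raise ValueError(f"{name} must be positive")
    q = Q_max_lmin * 1.0e-3 / 60.0  # m^3/s
    nu = nu_mm2s * 1.0e-6  # m^2/s
    d_jet = d_jet_mm * 1.0e-3  # m
    d_p = d_p_um * 1.0e-6  # m
    re = 4.0 * q / (np.pi * d_jet * nu)
    alpha = r_a_mm * 1.0e-3 * np.sqrt(2.0 * np.pi / (T_s * nu))
    tau = rho_p * d_p**2 / (18.0 * rho * nu)
    st = tau * U_ms / d_p
    return DimensionlessNumbers(
        Re=float(re), alpha=float(alpha), St=float(st),
        d_jet_mm=float(d_jet_mm), tau_s=float(tau),
    )


# ---------------------------------------------------------------------------
# Report
# ---------------------------------------------------------------------------


@dataclass
class MetricsReport:
    """Scalar metrics and per-phase series for one phantom run.

    Energies are reported in millijoule, flow rates in m^3/s (and l/min
    in the JSON), diameters in mm.
    """

    label: str
    times: np.ndarray
    series: dict[str, np.ndarray]  # Q_net, Q_RF, E_MK_O1, E_FK_O1, ...
    E_TJ_mJ: float
    Q_RF_m3s: float
    E_MKS_mJ: float
    delta_SOV: float | None
    delta_AAo: float
    d_jet_mm: float
    Re: float
    alpha: float
    St: float
    degenerate_sinus: bool = False
    notes: dict = dc_field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "label": self.label,
            "E_TJ_mJ": self.E_TJ_mJ,
            "Q_RF_m3s": self.Q_RF_m3s,
            "Q_RF_lmin": self.Q_RF_m3s / (1.0e-3 / 60.0),
            "E_MKS_mJ": self.E_MKS_mJ,
            "delta_SOV": self.delta_SOV,
            "delta_AAo": self.delta_AAo,
            "d_jet_mm": self.d_jet_mm,
            "Re": self.Re,
            "alpha": self.alpha,
            "St": self.St,
            "degenerate_sinus": self.degenerate_sinus,
            "times_s": np.asarray(self.times).tolist(),
            "series": {k: np.asarray(v).tolist() for k, v in self.series.items()},
            "notes": self.notes,
        }

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def series_frame(self):
        """Per-phase series as a pandas DataFrame (t_j plus all series)."""
        import pandas as pd

        data = {"t_j": np.asarray(self.times)}
        data.update({k: np.asarray(v) for k, v in self.series.items()})
        return pd.DataFrame(data)
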