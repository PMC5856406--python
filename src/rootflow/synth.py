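"""Synthetic phase-resolved velocity ensembles.

Generates instantaneous 3D velocity fields on a uniform Cartesian grid,
masked to the aortic-root lumen, with the kinematic structure observed
downstream of a bio-prosthetic aortic valve:

* a pulsatile jet with a flat (potential-core) axial profile and a
  tanh shear layer, flux-matched to a prescribed pump waveform via an
  axisymmetric Stokes stream function;
* near-wall retrograde flow during mid/late systole, azimuthally
  weighted toward the back sinus portion;
* a starting vortex ring released at valve opening and advected
  downstream;
* weak circumferential flow inside the sinus of Valsalva;
* seeded Gaussian velocity fluctuations localized to the shear layer,
  plus pulse-to-pulse amplitude jitter.

These ensembles stand in for phase-locked tomographic PIV measurements
and carry full provenance (parameters and seeds) for reproducibility.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field as dc_field

import numpy as np
from scipy.ndimage import gaussian_filter

from rootflow.geometry import (
    Grid,
    RootParameters,
    _baseline_radius,
    derive_radii,
    lumen_mask,
)

__all__ = [
    "PulseWaveform",
    "JetFlowParams",
    "VelocityField",
    "PhaseEnsemble",
    "DEFAULT_POA_MM2",
    "flow_rate",
    "base_field",
    "add_fluctuations",
    "generate_ensemble",
    "analytic_field",
]

#: Mid-systolic projected orifice areas [mm^2] assigned per phantom preset
#: (measured range 170-185 mm^2; the sinus-less phantom has the smallest
#: orifice, the large phantom the largest).
DEFAULT_POA_MM2: dict[str, float] = {"NS": 170.0, "S": 175.0, "M": 180.0, "L": 185.0}

_LMIN_TO_M3S = 1.0e-3 / 60.0


@dataclass(frozen=True)
class PulseWaveform:
    """Pump flow waveform: T-periodic, zero in diastole.

    Parameters
    ----------
    T : cycle period [s] (default 60/72 s, i.e. 72 beats per minute).
    Q_max_lmin : peak flow rate [l/min].
    f_sys : systolic fraction of the cycle (systole duration / T).
    shape : "trapezoid" (rise, plateau at Q_max, fall) or "halfsine".
    f_ramp : rise/fall fraction of the systole (trapezoid only).  The
        default 0.27 gives a stroke volume of Q_max * f_sys * T * (1 -
        f_ramp) = 67.6 ml, matching the measured 68 ml at 20 l/min peak.
    t_open : valve-opening delay with respect to the pump trigger [s].
    """

    T: float = 60.0 / 72.0
    Q_max_lmin: float = 20.0
    f_sys: float = 1.0 / 3.0
    shape: str = "trapezoid"
    f_ramp: float = 0.27
    t_open: float = 0.06

    def __post_init__(self) -> None:
        if self.T <= 0:
            raise ValueError("period T must be positive")
        if not (0.0 < self.f_sys < 1.0):
            raise ValueError("systolic fraction must be in (0, 1)")
        if self.shape not in ("trapezoid", "halfsine"):
            raise ValueError(f"unknown waveform shape {self.shape!r}")
        if self.shape == "trapezoid" and not (0.0 < self.f_ramp < 0.5):
            raise ValueError("f_ramp must be in (0, 0.5)")

    @property
    def Q_max(self) -> float:
        """Peak flow rate [m^3/s]."""
        return self.Q_max_lmin * _LMIN_TO_M3S

    @property
    def t_sys(self) -> float:
        """Systole duration [s]."""
        return self.f_sys * self.T

    @property
    def stroke_volume(self) -> float:
        """Per-cycle ejected volume [m^3]."""
        if self.shape == "trapezoid":
            return self.Q_max * self.t_sys * (1.0 - self.f_ramp)
        return self.Q_max * self.t_sys * 2.0 / np.pi

    @property
    def cardiac_output_lmin(self) -> float:
        """Stroke volume times heart rate [l/min]."""
        return self.stroke_volume / self.T / _LMIN_TO_M3S

    def __call__(self, t: float | np.ndarray) -> float | np.ndarray:
        return flow_rate(self, t)


def flow_rate(waveform: PulseWaveform, t: float | np.ndarray) -> float | np.ndarray:
    """Instantaneous flow rate [m^3/s] at time ``t`` (wrapped into the
    cycle).  Zero during diastole, peak ``Q_max`` at mid-systole."""
    t_arr = np.mod(np.asarray(t, dtype=float), waveform.T)
    s = (t_arr - waveform.t_open) / waveform.t_sys  # systole phase in [0,1)
    q = np.zeros_like(t_arr)
    in_sys = (s >= 0.0) & (s < 1.0)
    if waveform.shape == "halfsine":
        q[in_sys] = np.sin(np.pi * s[in_sys])
    else:
        fr = waveform.f_ramp
        sv = s[in_sys]
        q[in_sys] = np.minimum(1.0, np.minimum(sv / fr, (1.0 - sv) / fr))
    q *= waveform.Q_max
    return float(q) if np.ndim(t) == 0 else q


@dataclass(frozen=True)
class JetFlowParams:
    """Kinematic parameters of the synthetic jet field.

    Lengths in mm, speeds in m/s, fractions dimensionless in [0, 1].
    """

    r_jet: float = 7.57  # jet radius d_jet/2 [mm]
    layer_thickness: float = 1.8  # tanh shear-layer thickness [mm]
    core_length: float = 44.0  # potential-core length scale (~2*d_a) [mm]
    rf_amp: float = 0.15  # peak RF speed / jet speed
    rf_asym: float = 0.6  # fraction of RF weighted to the back (-Z)
    swirl_amp: float = 0.10  # sinus circumferential speed / jet speed
    ring_circulation: float = 8000.0  # vortex-ring circulation [mm^2/s]
    ring_core_radius: float = 2.2  # Gaussian core radius [mm]
    ring_release_time: float = 0.075  # release at valve opening [s]
    ring_advection_speed: float = 0.45  # ring advection speed [m/s]
    sigma_u: float = 0.12  # shear-layer fluctuation rms per component [m/s]
    jitter: float = 0.02  # pulse-to-pulse amplitude jitter fraction
    smooth_voxels: float = 2.0  # fluctuation smoothing kernel sd [voxels]

    def __post_init__(self) -> None:
        for name in ("r_jet", "layer_thickness", "core_length", "ring_core_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("rf_amp", "rf_asym", "swirl_amp", "jitter"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.sigma_u < 0:
            raise ValueError("sigma_u must be >= 0")

    @classmethod
    def for_phantom(
        cls,
        geom: RootParameters,
        A_poa_mm2: float | None = None,
        **overrides,
    ) -> "JetFlowParams":
        """Defaults scaled to one phantom: jet radius from the projected
        orifice area, retrograde amplitude proportional to the annular
        (wall-to-jet) area fraction and fluctuation amplitude growing with
        the free shear-layer gap — both increase with the normalized
        ascending-aorta diameter."""
        if A_poa_mm2 is None:
            A_poa_mm2 = DEFAULT_POA_MM2.get(geom.label, 180.0)
        r_jet = float(np.sqrt(A_poa_mm2 / np.pi))
        a_jet = np.pi * r_jet**2
        a_wall = np.pi * geom.r_stj**2
        defaults = dict(
            r_jet=r_jet,
            rf_amp=min(1.0, 0.08 * (a_wall - a_jet) / a_jet),
            sigma_u=0.15 * (geom.r_stj - r_jet) / r_jet,
            core_length=2.0 * geom.d_a,
        )
        defaults.update(overrides)
        return cls(**defaults)


@dataclass
class VelocityField:
    """One instantaneous 3-component velocity field on a uniform grid.

    ``u`` has shape (3, nx, ny, nz) with components (U_x, U_y, U_z) in
    m/s; ``mask`` marks lumen (valid) voxels; ``t`` is the phase time [s].
    """

    grid: Grid
    u: np.ndarray
    mask: np.ndarray
    t: float = 0.0
    replicate: int = 0

    def __post_init__(self) -> None:
        if self.u.shape != (3, *self.grid.shape):
            raise ValueError("velocity array shape does not match grid")
        if self.mask.shape != self.grid.shape:
            raise ValueError("mask shape does not match grid")
        vals = self.u[:, self.mask]
        if vals.size and (~np.isfinite(vals)).any():
            raise ValueError("non-finite velocities on masked voxels")
        if vals.size and np.abs(vals).max() > 10.0:
            raise ValueError("velocity magnitude exceeds 10 m/s sanity bound")

    @property
    def speed(self) -> np.ndarray:
        return np.sqrt((self.u**2).sum(axis=0))


def _radial_profiles(
    geom: RootParameters,
    jet: JetFlowParams,
    waveform: PulseWaveform,
    t: float,
    ys: np.ndarray,
    amplitude: float,
    n_r: int = 257,
):
    """Axisymmetric construction on a fine (r, y) mesh.

    Returns (r_fine, u_y, u_r, u_rf) with u_y/u_r the stream-function
    velocities [m/s] and u_rf the retrograde component alone (for the
    azimuthal asymmetry weighting).
    """
    Q = amplitude * flow_rate(waveform, t)  # m^3/s
    r_wall = _baseline_radius(geom, ys)  # mm
    r_max = float(r_wall.max())
    r = np.linspace(0.0, r_max, n_r)  # mm

    # retrograde-flow time envelope: grows from early mid-systole to valve
    # closure (observed maximum at the closing phase)
    tau = np.mod(t, waveform.T)
    env_rf = np.clip((tau - 0.12) / 0.18, 0.0, 1.0) if Q > 0 else 0.0
    a_jet_mm2 = np.pi * jet.r_jet**2
    u_jet = Q / (a_jet_mm2 * 1e-6)  # nominal jet speed [m/s]
    u_rf_peak = jet.rf_amp * u_jet * env_rf

    u_y = np.zeros((n_r, ys.size))
    u_rf = np.zeros((n_r, ys.size))
    psi = np.zeros((n_r, ys.size))  # Stokes stream function [m/s * mm^2]
    y_tip = geom.h_sov  # shear layer spreads past the STJ
    for i, y in enumerate(ys):
        rw = r_wall[i]
        grow = 1.0 + max(0.0, (y - y_tip)) / jet.core_length
        delta = jet.layer_thickness * grow
        f = 0.5 * (1.0 - np.tanh(2.5 * (r - jet.r_jet) / delta))
        # smooth wall cutoff: velocity vanishes at the lumen boundary so
        # that Cartesian voxel sums of the flux converge quickly
        cut = 0.5 * (1.0 - np.tanh((r - (rw - 0.6)) / 0.3))
        f = f * cut
        g = -np.exp(-(((r - (rw - 1.6 * jet.layer_thickness)) / jet.layer_thickness) ** 2))
        g = g * cut
        flux_f = 2.0 * np.pi * np.trapezoid(f * r, r)  # mm^2
        flux_g = 2.0 * np.pi * np.trapezoid(g * r, r)
        if Q > 0 and flux_f > 0:
            a_amp = (Q / 1e-6 - u_rf_peak * flux_g) / flux_f
        else:
            a_amp = 0.0
        u_rf[:, i] = u_rf_peak * g
        u_y[:, i] = a_amp * f + u_rf[:, i]
        # cumulative flux / 2 pi
        psi[:, i] = np.concatenate(
            [[0.0], np.cumsum(0.5 * (u_y[1:, i] * r[1:] + u_y[:-1, i] * r[:-1]) * np.diff(r))]
        )

    # starting vortex ring (Gaussian core) superposed in the stream function
    tau_rel = tau - jet.ring_release_time
    if Q > 0 and tau_rel >= 0.0 and jet.ring_circulation != 0.0:
        y_ring = geom.h_sov + jet.ring_advection_speed * 1e3 * tau_rel  # mm
        if y_ring < ys.max() + 4.0 * jet.ring_core_radius:
            rr, yy = np.meshgrid(r, ys, indexing="ij")
            sigma = jet.ring_core_radius
            d2 = (rr - jet.r_jet) ** 2 + (yy - y_ring) ** 2
            # peak in-plane ring speed ~ 0.6 * Gamma / (2 pi sigma);
            # 1e-3 converts mm/s to m/s so psi is in m/s * mm^2
            amp = 1.0e-3 * jet.ring_circulation / (2.0 * np.pi)
            psi_ring = amp * (rr / jet.r_jet) * np.exp(-d2 / (2.0 * sigma**2))
            psi = psi + psi_ring
            dpsi_dr = np.gradient(psi_ring, r, axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                uy_ring = np.where(rr > 1e-9, dpsi_dr / np.maximum(rr, 1e-9), 0.0)
            uy_ring[0, :] = uy_ring[1, :]
            u_y = u_y + uy_ring
    # radial velocity from axial variation of the stream function
    dpsi_dy = np.gradient(psi, ys, axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        u_r = np.where(r[:, None] > 1e-9, -dpsi_dy / np.maximum(r[:, None], 1e-9), 0.0)
    u_r[0, :] = 0.0
    return r, u_y, u_r, u_rf, u_jet


def base_field(
    geom: RootParameters,
    jet: JetFlowParams,
    waveform: PulseWaveform,
    t: float,
    grid: Grid,
    mask: np.ndarray | None = None,
    amplitude: float = 1.0,
) -> VelocityField:
    """Deterministic (fluctuation-free) velocity field at phase time ``t``.

    The axisymmetric jet + retrograde-flow part is built from a Stokes
    stream function, so the through-plane flux at every cross-section
    equals the waveform flow rate; the vortex ring and sinus swirl are
    flux-free to within the Gaussian tails.
    """
    if mask is None:
        mask = lumen_mask(geom, grid).mask
    ys = grid.coords(1)
    if ys[0] < -1e-9 or ys[-1] > geom.domain_top + 1e-9:
        raise ValueError("grid does not lie inside the lumen domain")
    r_fine, u_y_f, u_r_f, u_rf_f, u_jet = _radial_profiles(
        geom, jet, waveform, t, ys, amplitude
    )

    x2d, z2d = np.meshgrid(grid.coords(0), grid.coords(2), indexing="ij")
    r2d = np.hypot(x2d, z2d)
    theta2d = np.arctan2(x2d, z2d)  # 0 at +Z (front sinus bisector)
    cos_back = np.cos(theta2d - np.pi)  # 1 at the back (-Z)
    sin_t, cos_t = np.sin(theta2d), np.cos(theta2d)

    u = np.zeros((3, *grid.shape))
    # sinus swirl support (front/back weighting left uniform: the
    # circumferential flow fills the sinus ring)
    if geom.has_sinus:
        radii = derive_radii(geom)
        r_mid = 0.5 * (radii.r_co + radii.r_s)
        w_sin = 0.5 * (radii.r_s - radii.r_co)
    else:
        r_mid = 0.5 * (geom.r_a + geom.r_stj)
        w_sin = 0.5 * (geom.r_stj - geom.r_a)
    w_sin = max(w_sin, 0.5)
    h = geom.h_sov

    for i, y in enumerate(ys):
        uy = np.interp(r2d, r_fine, u_y_f[:, i])
        ur = np.interp(r2d, r_fine, u_r_f[:, i])
        urf = np.interp(r2d, r_fine, u_rf_f[:, i])
        uy = uy + jet.rf_asym * cos_back * urf
        ut = 0.0
        if 0.0 <= y <= h and jet.swirl_amp > 0.0:
            ut = (
                jet.swirl_amp
                * u_jet
                * np.sin(np.pi * y / h)
                * np.exp(-(((r2d - r_mid) / w_sin) ** 2))
            )
        u[0, :, i, :] = ur * sin_t + ut * cos_t
        u[1, :, i, :] = uy
        u[2, :, i, :] = ur * cos_t - ut * sin_t

    u[:, ~mask] = 0.0
    return VelocityField(grid=grid, u=u, mask=mask, t=float(t))


def _kernel_norm(sigma: float, shape: tuple[int, ...]) -> float:
    """L2 norm of the (circulant) Gaussian smoothing kernel actually
    applied, used to restore the target pointwise standard deviation
    after smoothing.  With periodic boundaries the smoothed white field
    is stationary, so the renormalization is exact everywhere."""
    impulse = np.zeros(shape)
    impulse[tuple(s // 2 for s in shape)] = 1.0
    k = gaussian_filter(impulse, sigma, mode="wrap")
    return float(np.sqrt((k**2).sum()))


def add_fluctuations(
    field: VelocityField,
    sigma_u: float,
    localization: np.ndarray | None = None,
    seed: int | np.random.SeedSequence = 0,
    smooth_voxels: float = 2.0,
) -> VelocityField:
    """Add zero-mean Gaussian velocity perturbations.

    Per-component standard deviation ``sigma_u`` [m/s], spatially smoothed
    with a Gaussian kernel of ``smooth_voxels`` voxels (the amplitude is
    renormalized so the pointwise sd stays ``sigma_u``), windowed by the
    ``localization`` weight array (1 everywhere if None) and by the lumen
    mask.  Deterministic for a given seed.
    """
    if sigma_u < 0:
        raise ValueError("sigma_u must be >= 0")
    if sigma_u == 0.0:
        return field
    rng = np.random.default_rng(seed)
    noise = rng.standard_normal((3, *field.grid.shape))
    if smooth_voxels > 0:
        norm = _kernel_norm(smooth_voxels, field.grid.shape)
        for c in range(3):
            noise[c] = gaussian_filter(noise[c], smooth_voxels, mode="wrap") / norm
    pert = sigma_u * noise
    if localization is not None:
        pert = pert * localization[None]
    u = field.u.copy()
    u[:, field.mask] += pert[:, field.mask]
    return dataclasses.replace(field, u=u)


def shear_layer_weight(
    geom: RootParameters, jet: JetFlowParams, grid: Grid
) -> np.ndarray:
    """Fluctuation localization: a Gaussian annulus around the jet edge
    whose width grows downstream of the STJ (transitional shear layer
    becoming turbulent), with reduced amplitude near the valve."""
    x, y, z = grid.meshgrid()
    r = np.hypot(x, z)
    down = np.clip((y - geom.h_sov) / jet.core_length, 0.0, 1.5)
    width = 1.5 * jet.layer_thickness * (1.0 + down)
    w = np.exp(-(((r - jet.r_jet) / width) ** 2))
    return w * (0.5 + 0.5 * np.clip(down, 0.0, 1.0))


@dataclass
class PhaseEnsemble:
    """Phase-locked ensemble: N replicate fields at each phase time
    ``t_j = j * dt``.  Fields are generated lazily and deterministically
    from ``(master_seed, j, k)``; ``materialize`` caches them."""

    geom: RootParameters
    jet: JetFlowParams
    waveform: PulseWaveform
    grid: Grid
    n_replicates: int = 16
    n_phases: int = 13
    dt: float = 0.03
    master_seed: int = 0
    materialize: bool = False
    _cache: dict = dc_field(default_factory=dict, repr=False)
    _mask: np.ndarray | None = dc_field(default=None, repr=False)
    _weight: np.ndarray | None = dc_field(default=None, repr=False)

    def __post_init__(self) -> None:
        if self.n_replicates < 2:
            raise ValueError("need N >= 2 replicates for statistics")
        if self.n_phases * self.dt > self.waveform.T:
            raise ValueError("phase samples exceed one cycle")

    @property
    def phase_times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_phases)

    @property
    def mask(self) -> np.ndarray:
        if self._mask is None:
            self._mask = lumen_mask(self.geom, self.grid).mask
        return self._mask

    @property
    def provenance(self) -> dict:
        return {
            "geometry": dataclasses.asdict(self.geom),
            "jet": dataclasses.asdict(self.jet),
            "waveform": dataclasses.asdict(self.waveform),
            "protocol": {
                "n_phases": self.n_phases,
                "n_replicates": self.n_replicates,
                "dt_s": self.dt,
            },
            "master_seed": self.master_seed,
        }

    def field(self, j: int, k: int) -> VelocityField:
        """Instantaneous field for phase ``j``, replicate ``k``."""
        if not (0 <= j < self.n_phases and 0 <= k < self.n_replicates):
            raise IndexError("phase or replicate index out of range")
        key = (j, k)
        if key in self._cache:
            return self._cache[key]
        if self._weight is None:
            self._weight = shear_layer_weight(self.geom, self.jet, self.grid)
        ss = np.random.SeedSequence(
            entropy=int(self.master_seed) & 0x7FFFFFFF, spawn_key=(j, k)
        )
        rng = np.random.default_rng(ss)
        eta = rng.standard_normal()
        amplitude = 1.0 + self.jet.jitter * eta
        t = self.dt * j
        fld = base_field(
            self.geom, self.jet, self.waveform, t, self.grid,
            mask=self.mask, amplitude=amplitude,
        )
        q_frac = flow_rate(self.waveform, t) / self.waveform.Q_max
        if self.jet.sigma_u > 0 and q_frac > 0:
            fld = add_fluctuations(
                fld,
                self.jet.sigma_u * q_frac,
                localization=self._weight,
                seed=np.random.SeedSequence(
                    entropy=int(self.master_seed) & 0x7FFFFFFF,
                    spawn_key=(j, k, 1),
                ),
                smooth_voxels=self.jet.smooth_voxels,
            )
        fld.replicate = k
        if self.materialize:
            self._cache[key] = fld
        return fld

    def iter_phase(self, j: int):
        for k in range(self.n_replicates):
            yield self.field(j, k)

    def __len__(self) -> int:
        return self.n_phases * self.n_replicates


def generate_ensemble(
    geom: RootParameters,
    jet: JetFlowParams,
    waveform: PulseWaveform,
    grid: Grid,
    n_replicates: int = 16,
    master_seed: int = 0,
    n_phases: int = 13,
    dt: float = 0.03,
    materialize: bool = False,
) -> PhaseEnsemble:
    """Phase-locked synthetic ensemble (13 phases x N replicates by
    default, the full measurement protocol)."""
    return PhaseEnsemble(
        geom=geom,
        jet=jet,
        waveform=waveform,
        grid=grid,
        n_replicates=n_replicates,
        n_phases=n_phases,
        dt=dt,
        master_seed=master_seed,
        materialize=materialize,
    )


def analytic_field(kind: str, rate: float, grid: Grid) -> VelocityField:
    """Closed-form fields for differential-operator verification.

    * ``pure-shear``: U_y = rate * z
    * ``uniaxial-strain``: (-rate/2 * x, rate * y, -rate/2 * z)
    * ``rigid-rotation``: omega x r with omega = rate * e_y

    ``rate`` in 1/s with coordinates in mm: velocities are scaled by 1e-3
    so that gradients (per mm, differentiated in SI) return ``rate``.
    """
    if not np.isfinite(rate):
        raise ValueError("rate must be finite")
    x, y, z = grid.meshgrid()
    u = np.zeros((3, *grid.shape))
    s = rate * 1.0e-3  # m/s per mm
    if kind == "pure-shear":
        u[1] = s * z
    elif kind == "uniaxial-strain":
        u[0] = -0.5 * s * x
        u[1] = s * y
        u[2] = -0.5 * s * z
    elif kind == "rigid-rotation":
        u[0] = s * z
        u[2] = -s * x
    else:
        raise ValueError(f"unknown analytic field kind {kind!r}")
    mask = np.ones(grid.shape, dtype=bool)
    return VelocityField(grid=grid, u=u, mask=mask, t=0.0)
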