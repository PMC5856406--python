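"""Parametric aortic-root lumen geometry.

The aortic root is modelled as a straight vessel whose lumen is defined by
the annulus radius ``r_a`` and five dimensionless scale factors: the sinus
parameter ``alpha_s`` (sinus radius ``r_s = alpha_s * r_a``), the commissure
parameter ``alpha_co`` (``r_co = alpha_co * r_a``), the sino-tubular junction
(STJ) parameter ``alpha_stj`` (``r_stj = alpha_stj * r_a``) and two height
factors ``beta1``/``beta2`` placing the widest sinus cross-section at
``beta1 * r_a`` above the annulus and the STJ at ``(beta1 + beta2) * r_a``.

The widest cross-section of the sinus of Valsalva (SOV) is a three-lobed
profile built from three circles of radius ``r_sp`` whose centres sit at a
distance ``r_mc`` from the vessel axis on bisectors 120 degrees apart; the
lobes meet at the commissure points at radius ``r_co``.  The two auxiliary
radii follow from the constraints ``r_sp + r_mc = alpha_s * r_a`` and
``r_sp^2 = r_co^2 + r_mc^2 - r_co * r_mc``:

    r_mc = r_a * (alpha_co^2 - alpha_s^2) / (alpha_co - 2 * alpha_s)
    r_sp = r_a * (alpha_co * alpha_s - alpha_s^2 - alpha_co^2)
                / (alpha_co - 2 * alpha_s)

Axis convention: the second Cartesian axis (Y) is the vessel axis, X-Z span
cross-sections, and the front-facing sinus bisector is aligned with +Z.
The internal axial coordinate ``y`` measures height above the annulus plane
in millimetres.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RootParameters",
    "DerivedRootRadii",
    "Grid",
    "DomainMask",
    "PRESETS",
    "derive_radii",
    "lumen_boundary_radius",
    "point_in_lumen",
    "cross_section_area",
    "lumen_volume",
    "tip_to_stj_distance",
    "make_domain_masks",
    "normalized_diameters",
    "lumen_surface_mesh",
    "NoSinusError",
]


class NoSinusError(ValueError):
    """Raised when a sinus-specific quantity is requested for a phantom
    without a sinus bulge."""


@dataclass(frozen=True)
class RootParameters:
    """One aortic-root phantom parameter set.

    All lengths are in millimetres; the alpha/beta factors are
    dimensionless multiples of the annulus radius ``r_a``.
    """

    label: str
    r_a: float
    alpha_stj: float
    beta1: float
    beta2: float
    alpha_s: float | None = None
    alpha_co: float | None = None
    has_sinus: bool = True

    def __post_init__(self) -> None:
        if self.r_a <= 0:
            raise ValueError("annulus radius r_a must be positive")
        if self.beta1 <= 0 or self.beta2 <= 0:
            raise ValueError("height factors beta1, beta2 must be positive")
        if self.alpha_stj <= 0:
            raise ValueError("alpha_stj must be positive")
        if self.has_sinus:
            if self.alpha_s is None or self.alpha_co is None:
                raise ValueError("sinus phantom needs alpha_s and alpha_co")
            if not (self.alpha_s > self.alpha_co >= 1.0):
                raise ValueError("require alpha_s > alpha_co >= 1")
            if self.alpha_co >= 2.0 * self.alpha_s:
                raise ValueError(
                    "alpha_co < 2*alpha_s required (degenerate denominator)"
                )

    @property
    def d_a(self) -> float:
        """Annulus diameter [mm]."""
        return 2.0 * self.r_a

    @property
    def r_stj(self) -> float:
        """Radius at the sino-tubular junction [mm]."""
        return self.alpha_stj * self.r_a

    @property
    def h_sov(self) -> float:
        """Sinus height: axial position of the STJ above the annulus [mm]."""
        return (self.beta1 + self.beta2) * self.r_a

    @property
    def y_max_sov(self) -> float:
        """Axial position of the widest sinus cross-section [mm]."""
        return self.beta1 * self.r_a

    @property
    def domain_top(self) -> float:
        """Top of the analysis domain: two annulus diameters past the STJ."""
        return self.h_sov + 2.0 * self.d_a


#: Built-in phantom presets (annulus radius 11 mm for all sizes).
PRESETS: dict[str, RootParameters] = {
    "NS": RootParameters("NS", 11.0, alpha_stj=1.25, beta1=0.70, beta2=0.80,
                         has_sinus=False),
    "S": RootParameters("S", 11.0, alpha_s=1.40, alpha_co=1.13,
                        alpha_stj=1.13, beta1=0.63, beta2=0.72),
    "M": RootParameters("M", 11.0, alpha_s=1.55, alpha_co=1.25,
                        alpha_stj=1.25, beta1=0.70, beta2=0.80),
    "L": RootParameters("L", 11.0, alpha_s=1.70, alpha_co=1.38,
                        alpha_stj=1.38, beta1=0.77, beta2=0.88),
}


@dataclass(frozen=True)
class DerivedRootRadii:
    """Radii derived from a :class:`RootParameters` set [mm]."""

    r_mc: float
    r_sp: float
    r_co: float
    r_s: float
    r_stj: float
    h_sov: float
    y_max_sov: float


def derive_radii(params: RootParameters) -> DerivedRootRadii:
    """Derive the sinus construction radii from the scale factors.

    Raises
    ------
    NoSinusError
        For a phantom without sinus bulge (r_mc/r_sp undefined).
    """
    if not params.has_sinus:
        raise NoSinusError(f"phantom {params.label!r} has no sinus geometry")
    a_s, a_co, r_a = params.alpha_s, params.alpha_co, params.r_a
    denom = a_co - 2.0 * a_s
    if denom == 0.0:
        raise ValueError("alpha_co == 2*alpha_s: degenerate denominator")
    r_mc = r_a * (a_co**2 - a_s**2) / denom
    r_sp = r_a * (a_co * a_s - a_s**2 - a_co**2) / denom
    radii = DerivedRootRadii(
        r_mc=r_mc,
        r_sp=r_sp,
        r_co=a_co * r_a,
        r_s=a_s * r_a,
        r_stj=params.r_stj,
        h_sov=params.h_sov,
        y_max_sov=params.y_max_sov,
    )
    if r_mc <= 0 or r_sp <= 0:
        raise ValueError("derived radii must be positive")
    return radii


def _baseline_radius(params: RootParameters, y: np.ndarray) -> np.ndarray:
    """Circular baseline radius: cosine taper r_a -> r_stj over the sinus
    height, constant r_stj above."""
    y = np.asarray(y, dtype=float)
    frac = np.clip(y / params.h_sov, 0.0, 1.0)
    taper = 0.5 * (1.0 - np.cos(np.pi * frac))
    return params.r_a + (params.r_stj - params.r_a) * taper


def _lobe_profile(radii: DerivedRootRadii, theta: np.ndarray) -> np.ndarray:
    """Boundary radius of the three-lobed widest cross-section.

    ``theta`` is measured from the front lobe bisector (+Z).  Within each
    120-degree sector the boundary is the arc of the sinus circle (radius
    r_sp, centre at r_mc on the bisector); adjacent arcs meet at the
    commissure points at radius r_co.
    """
    theta = np.asarray(theta, dtype=float)
    # angular offset from the nearest lobe bisector, in [-pi/3, pi/3]
    period = 2.0 * np.pi / 3.0
    phi = np.mod(theta + period / 2.0, period) - period / 2.0
    r_mc, r_sp = radii.r_mc, radii.r_sp
    return r_mc * np.cos(phi) + np.sqrt(r_sp**2 - (r_mc * np.sin(phi)) ** 2)


def _bump(params: RootParameters, y: np.ndarray) -> np.ndarray:
    """Axial modulation of the sinus bulge: 0 at the annulus, 1 at the
    widest cross-section, 0 at the STJ (C1-continuous cosine-squared)."""
    y = np.asarray(y, dtype=float)
    y1 = params.y_max_sov
    y2 = params.h_sov
    out = np.zeros_like(y)
    rising = (y >= 0.0) & (y < y1)
    falling = (y >= y1) & (y <= y2)
    out[rising] = np.sin(0.5 * np.pi * y[rising] / y1) ** 2
    out[falling] = np.cos(0.5 * np.pi * (y[falling] - y1) / (y2 - y1)) ** 2
    return out


def lumen_boundary_radius(
    params: RootParameters,
    y: float | np.ndarray,
    theta: float | np.ndarray = 0.0,
) -> float | np.ndarray:
    """Lumen boundary radius [mm] at height ``y`` above the annulus and
    azimuth ``theta`` [rad] measured from the front lobe bisector (+Z).

    At ``y = 0`` this is ``r_a`` for all azimuths; at and above the STJ it
    is ``r_stj``.  For sinus phantoms the three-lobed profile appears at
    ``beta1 * r_a``, blended smoothly in between.
    """
    y_arr = np.asarray(y, dtype=float)
    scalar = y_arr.ndim == 0 and np.ndim(theta) == 0
    if np.any(y_arr < -1e-12) or np.any(y_arr > params.domain_top + 1e-12):
        raise ValueError("axial position outside the lumen domain")
    y_arr = np.clip(y_arr, 0.0, params.domain_top)
    base = _baseline_radius(params, y_arr)
    if not params.has_sinus:
        r = np.broadcast_arrays(base, np.asarray(theta, dtype=float))[0]
        return float(r) if scalar else r
    radii = derive_radii(params)
    base_at_max = _baseline_radius(params, np.asarray(params.y_max_sov))
    excess = _lobe_profile(radii, np.asarray(theta, dtype=float)) - base_at_max
    r = base + _bump(params, y_arr) * excess
    return float(r) if scalar else r


def point_in_lumen(
    params: RootParameters, point: np.ndarray | list | tuple
) -> bool | np.ndarray:
    """True where a point (x, y, z) [mm] lies strictly inside the lumen.

    Accepts a single point or an (..., 3) array.  Points outside the axial
    domain [0, domain_top] are outside the lumen.
    """
    pts = np.asarray(point, dtype=float)
    scalar = pts.ndim == 1
    pts = np.atleast_2d(pts)
    x, y, z = pts[..., 0], pts[..., 1], pts[..., 2]
    in_y = (y >= 0.0) & (y <= params.domain_top)
    r = np.hypot(x, z)
    theta = np.arctan2(x, z)  # 0 on the +Z front-lobe bisector
    rb = np.empty_like(r)
    yc = np.clip(y, 0.0, params.domain_top)
    rb = lumen_boundary_radius(params, yc, theta)
    inside = in_y & (r < rb)
    return bool(inside[0]) if scalar else inside


def cross_section_area(
    params: RootParameters, y: float, n_theta: int = 720
) -> float:
    """Cross-section area [mm^2] at height ``y`` by polar quadrature of
    ``0.5 * integral of r_b(theta)^2 dtheta``."""
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    rb = lumen_boundary_radius(params, float(y), theta)
    return float(0.5 * np.sum(np.asarray(rb) ** 2) * (2.0 * np.pi / n_theta))


def lumen_volume(
    params: RootParameters,
    y0: float,
    y1: float,
    n_y: int = 200,
    n_theta: int = 720,
) -> float:
    """Lumen volume [mm^3] between heights ``y0`` and ``y1`` by composite
    trapezoid integration of the cross-section area."""
    if not (0.0 <= y0 < y1 <= params.domain_top):
        raise ValueError("invalid axial range")
    ys = np.linspace(y0, y1, n_y)
    areas = np.array([cross_section_area(params, y, n_theta) for y in ys])
    return float(np.trapezoid(areas, ys))


def tip_to_stj_distance(params: RootParameters, valve_height: float) -> float:
    """Axial distance [mm] from the leaflet trailing edge (at
    ``valve_height`` above the annulus) to the sino-tubular junction."""
    if valve_height <= 0:
        raise ValueError("valve height must be positive")
    return params.h_sov - valve_height


def normalized_diameters(
    params: RootParameters, d_jet: float
) -> tuple[float | None, float]:
    """Normalized diameters (delta_SOV, delta_AAo) for jet diameter
    ``d_jet`` [mm]:

        delta_SOV = (r_co + r_s) / d_jet      (None for sinus-less phantoms)
        delta_AAo = 2 * r_stj / d_jet
    """
    if d_jet <= 0:
        raise ValueError("d_jet must be positive")
    delta_aao = 2.0 * params.r_stj / d_jet
    if not params.has_sinus:
        return None, delta_aao
    radii = derive_radii(params)
    return (radii.r_co + radii.r_s) / d_jet, delta_aao


# ---------------------------------------------------------------------------
# Grids and domain masks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Grid:
    """Uniform Cartesian grid.  Y (axis 1) is the vessel axis; X-Z span
    cross-sections; the front sinus bisector is +Z.  Lengths in mm."""

    origin: tuple[float, float, float]
    spacing: tuple[float, float, float]
    counts: tuple[int, int, int]

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.spacing):
            raise ValueError("grid spacing must be positive")
        if any(c < 2 for c in self.counts):
            raise ValueError("need at least 2 grid points per axis")

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(self.counts)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume [mm^3]."""
        return float(np.prod(self.spacing))

    def coords(self, axis: int) -> np.ndarray:
        """Grid-point coordinates along one axis [mm]."""
        return self.origin[axis] + self.spacing[axis] * np.arange(
            self.counts[axis], dtype=float
        )

    def meshgrid(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(X, Y, Z) coordinate arrays of shape ``counts`` [mm]."""
        return np.meshgrid(
            self.coords(0), self.coords(1), self.coords(2), indexing="ij"
        )

    @classmethod
    def for_root(
        cls,
        params: RootParameters,
        spacing: float,
        y0: float = 0.0,
        y1: float | None = None,
        pad: float = 1.0,
    ) -> "Grid":
        """Grid covering the lumen between heights ``y0`` and ``y1``
        (default: whole domain) with uniform ``spacing`` [mm]."""
        if y1 is None:
            y1 = params.domain_top
        r_max = params.alpha_s * params.r_a if params.has_sinus else params.r_stj
        half = r_max + pad
        n_xy = int(np.ceil(2.0 * half / spacing)) + 1
        n_y = int(np.floor((y1 - y0) / spacing + 1e-9)) + 1
        return cls(
            origin=(-half, y0, -half),
            spacing=(spacing, spacing, spacing),
            counts=(n_xy, n_y, n_xy),
        )


@dataclass(frozen=True)
class DomainMask:
    """Boolean voxel occupancy of one analysis domain over a grid."""

    grid: Grid
    mask: np.ndarray = field(repr=False)
    label: str

    def __post_init__(self) -> None:
        if tuple(self.mask.shape) != self.grid.shape:
            raise ValueError("mask shape does not match grid counts")

    @property
    def volume(self) -> float:
        """Occupied volume [mm^3]."""
        return float(np.count_nonzero(self.mask) * self.grid.voxel_volume)


def lumen_mask(params: RootParameters, grid: Grid) -> DomainMask:
    """Voxelized lumen occupancy (voxel centres strictly inside)."""
    x, y, z = grid.meshgrid()
    pts = np.stack([x, y, z], axis=-1)
    inside = point_in_lumen(params, pts.reshape(-1, 3)).reshape(grid.shape)
    return DomainMask(grid=grid, mask=inside, label="lumen")


def make_domain_masks(
    params: RootParameters, grid: Grid, valve_tip_y: float
) -> dict[str, DomainMask]:
    """Analysis domains over ``grid``:

    * ``Omega1`` — lumen voxels with ``valve_tip_y <= y < valve_tip_y + d_a``
    * ``Omega2`` — lumen voxels with the next annulus diameter of height
    * ``OmegaS`` — front-facing sinus lobe: azimuth within 60 degrees of
      +Z, radius beyond the commissure circle, between annulus and STJ

    For a sinus-less phantom ``OmegaS`` degenerates to the same wedge
    bounded inward by the annulus cylinder (a warning is issued).
    """
    d_a = params.d_a
    if grid.coords(1)[0] > valve_tip_y or grid.coords(1)[-1] < valve_tip_y + 2 * d_a:
        raise ValueError("grid does not cover valve tip to tip + 2*d_a")
    x, y, z = grid.meshgrid()
    pts = np.stack([x, y, z], axis=-1)
    lumen = point_in_lumen(params, pts.reshape(-1, 3)).reshape(grid.shape)

    in_o1 = lumen & (y >= valve_tip_y) & (y < valve_tip_y + d_a)
    in_o2 = lumen & (y >= valve_tip_y + d_a) & (y < valve_tip_y + 2 * d_a)

    r = np.hypot(x, z)
    theta = np.arctan2(x, z)
    wedge = (np.abs(theta) <= np.pi / 3.0) & (y >= 0.0) & (y <= params.h_sov)
    if params.has_sinus:
        r_inner = derive_radii(params).r_co
    else:
        warnings.warn(
            "sinus-less phantom: OmegaS is the degenerate wedge bounded "
            "inward by the annulus cylinder",
            stacklevel=2,
        )
        r_inner = params.r_a
    in_os = lumen & wedge & (r > r_inner)

    return {
        "Omega1": DomainMask(grid, in_o1, "Omega1"),
        "Omega2": DomainMask(grid, in_o2, "Omega2"),
        "OmegaS": DomainMask(grid, in_os, "OmegaS"),
        "lumen": DomainMask(grid, lumen, "lumen"),
    }


def lumen_surface_mesh(
    params: RootParameters, n_theta: int = 180, n_y: int = 120
):
    """Triangulated lumen surface as a :class:`trimesh.Trimesh` (for STL
    export).  The lateral surface is sampled on a (y, theta) lattice; the
    annulus and outlet discs close the tube."""
    import trimesh

    ys = np.linspace(0.0, params.domain_top, n_y)
    thetas = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    tt, yy = np.meshgrid(thetas, ys)
    rr = lumen_boundary_radius(params, yy, tt)
    verts = np.stack(
        [rr * np.sin(tt), yy, rr * np.cos(tt)], axis=-1
    ).reshape(-1, 3)
    faces = []
    for i in range(n_y - 1):
        for j in range(n_theta):
            a = i * n_theta + j
            b = i * n_theta + (j + 1) % n_theta
            c = (i + 1) * n_theta + j
            d = (i + 1) * n_theta + (j + 1) % n_theta
            faces.append([a, b, d])
            faces.append([a, d, c])
    # cap centres
    base_centre = len(verts)
    top_centre = base_centre + 1
    verts = np.vstack([verts, [[0.0, 0.0, 0.0], [0.0, params.domain_top, 0.0]]])
    for j in range(n_theta):
        faces.append([base_centre, (j + 1) % n_theta, j])
        off = (n_y - 1) * n_theta
        faces.append([top_centre, off + j, off + (j + 1) % n_theta])
    return trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)
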