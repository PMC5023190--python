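"""Digital tube phantoms and synthetic measurement cohorts.

Contrast-enhanced MR angiograms of the central pulmonary arteries are
emulated as bright tubes on a darker background: an indicator function of a
tube around a parametric centerline (straight segment, circular arc, or
helix; constant or linearly tapered radius) is rasterized with partial-volume
accuracy by supersampled occupancy, scaled to ``[a0, a1]``, blurred with an
isotropic Gaussian point-spread function, and corrupted with additive
Gaussian noise.  Every phantom carries analytic ground truth (centerline,
radius profile, volume over any arclength window), so segmentation accuracy
can be measured exactly.

The cohort simulator stands in for the study population: per-subject true
indexed volumes and BSA-corrected diameters are drawn from per-group normal
distributions, and repeated reads add independent reader noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .volume_io import ImageVolume

__all__ = [
    "TubeSpec",
    "TubeTruth",
    "GridSpec",
    "render_tube",
    "render_bifurcation",
    "voxel_count_volume",
    "simulate_cohort",
    "COHORT_DEFAULTS",
    "BSA_DEFAULTS",
]

# default acquisition grid: coronal contrast-enhanced MRA voxel geometry
DEFAULT_SPACING = (1.04, 1.04, 1.6)
DEFAULT_PSF_SIGMA = 1.0  # mm


def _unit(v) -> np.ndarray:
    v = np.asarray(v, dtype=np.float64)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero-length direction vector")
    return v / n


def _orthonormal_frame(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two unit vectors spanning the plane orthogonal to t."""
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = _unit(np.cross(t, ref))
    v = np.cross(t, u)
    return u, v


@dataclass
class TubeSpec:
    """One tube: parametric centerline, radius profile, contrast and noise.

    Use the classmethods :meth:`straight`, :meth:`arc` and :meth:`helix`;
    the raw constructor takes an internal frame representation.

    ``radius`` is a constant (mm) or a ``(r_start, r_end)`` pair for a linear
    taper over arclength.  ``a1 > a0`` encodes a contrast-enhanced vessel on
    darker background.
    """

    kind: str
    length: float
    radius: float | tuple[float, float]
    a0: float = 10.0
    a1: float = 100.0
    psf_sigma: float = DEFAULT_PSF_SIGMA
    noise_sd: float = 0.0
    supersample: int = 4
    seed: int = 0
    # geometry (kind-dependent)
    start: np.ndarray = field(default_factory=lambda: np.zeros(3))
    direction: np.ndarray = field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))
    curvature_radius: float | None = None  # arc / helix radius rho_c
    binormal: np.ndarray | None = None  # arc plane normal / helix axis
    pitch: float = 0.0  # helix rise per radian

    def __post_init__(self) -> None:
        if self.kind not in ("straight", "arc", "helix"):
            raise ValueError(f"unknown centerline kind {self.kind!r}")
        if self.length <= 0:
            raise ValueError("tube length must be positive")
        r0, r1 = self.radius_endpoints
        if r0 <= 0 or r1 <= 0:
            raise ValueError("tube radius must be positive everywhere")
        if self.a1 <= self.a0:
            raise ValueError("vessel intensity a1 must exceed background a0")
        if self.psf_sigma < 0:
            raise ValueError("psf_sigma must be >= 0")
        if self.supersample < 1:
            raise ValueError("supersample must be >= 1")
        if self.kind in ("arc", "helix"):
            if self.curvature_radius is None or self.curvature_radius <= 0:
                raise ValueError("arc/helix requires a positive curvature_radius")
            if self.kind == "arc" and max(r0, r1) >= self.curvature_radius:
                raise ValueError("tube radius must stay below the arc curvature radius")
        self.start = np.asarray(self.start, dtype=np.float64)
        self.direction = _unit(self.direction)
        if self.binormal is not None:
            self.binormal = _unit(self.binormal)

    # ---------------------------------------------------------------- builders

    @classmethod
    def straight(cls, start, direction, length, radius, **kw) -> "TubeSpec":
        return cls(kind="straight", start=start, direction=direction, length=length, radius=radius, **kw)

    @classmethod
    def arc(cls, start, direction, binormal, curvature_radius, length, radius, **kw) -> "TubeSpec":
        """Circular arc starting at ``start`` with tangent ``direction``.

        The arc lies in the plane orthogonal to ``binormal`` and bends toward
        ``binormal x direction``; ``length`` is arclength (rho_c * angle).
        """
        return cls(
            kind="arc", start=start, direction=direction, binormal=binormal,
            curvature_radius=curvature_radius, length=length, radius=radius, **kw,
        )

    @classmethod
    def helix(cls, start, direction, binormal, curvature_radius, pitch, length, radius, **kw) -> "TubeSpec":
        """Helix with axis ``binormal``, helical radius ``curvature_radius``
        and ``pitch`` = axial rise per radian of turn."""
        return cls(
            kind="helix", start=start, direction=direction, binormal=binormal,
            curvature_radius=curvature_radius, pitch=pitch, length=length, radius=radius, **kw,
        )

    # ---------------------------------------------------------------- geometry

    @property
    def radius_endpoints(self) -> tuple[float, float]:
        if np.isscalar(self.radius):
            return float(self.radius), float(self.radius)  # type: ignore[arg-type]
        r0, r1 = self.radius  # type: ignore[misc]
        return float(r0), float(r1)

    def radius_at(self, s) -> np.ndarray:
        r0, r1 = self.radius_endpoints
        s = np.asarray(s, dtype=np.float64)
        return r0 + (r1 - r0) * np.clip(s / self.length, 0.0, 1.0)

    def _arc_frame(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(center, e_r, t0): start = center - rho*e_r... see centerline()."""
        b = self.binormal
        t0 = self.direction
        if abs(float(np.dot(b, t0))) > 1e-9:
            raise ValueError("binormal must be orthogonal to the initial direction")
        e_r = np.cross(t0, b)  # points from arc center to start
        center = self.start - self.curvature_radius * e_r
        return center, e_r, t0

    def centerline(self, s) -> np.ndarray:
        """World position at arclength(s); s may be an array."""
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        if self.kind == "straight":
            pts = self.start[None, :] + s[:, None] * self.direction[None, :]
        elif self.kind == "arc":
            center, e_r, t0 = self._arc_frame()
            theta = s / self.curvature_radius
            pts = (
                center[None, :]
                + self.curvature_radius * np.cos(theta)[:, None] * e_r[None, :]
                + self.curvature_radius * np.sin(theta)[:, None] * t0[None, :]
            )
        else:  # helix
            rho, h = self.curvature_radius, self.pitch
            speed = np.hypot(rho, h)
            t = s / speed
            b = self.binormal
            t0 = self.direction - float(np.dot(self.direction, b)) * b
            t0 = _unit(t0)
            e_r = np.cross(t0, b)
            center = self.start - rho * e_r
            pts = (
                center[None, :]
                + rho * np.cos(t)[:, None] * e_r[None, :]
                + rho * np.sin(t)[:, None] * t0[None, :]
                + (h * t)[:, None] * b[None, :]
            )
        return pts

    def tangent(self, s) -> np.ndarray:
        s = np.atleast_1d(np.asarray(s, dtype=np.float64))
        eps = 1e-4
        lo = np.clip(s - eps, 0, self.length)
        hi = np.clip(s + eps, 0, self.length)
        d = self.centerline(hi) - self.centerline(lo)
        return d / np.linalg.norm(d, axis=1, keepdims=True)

    @property
    def end(self) -> np.ndarray:
        return self.centerline(self.length)[0]

    # ------------------------------------------------------------ membership

    def project(self, points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """For world points, return (inside, s): tube membership under
        flat normal-plane end caps, and the arclength of the foot point.

        Closed form for straight and arc; for a helix the nearest point on a
        densely sampled centerline (0.05 mm) with an end-plane test.
        """
        x = np.atleast_2d(np.asarray(points, dtype=np.float64))
        if self.kind == "straight":
            rel = x - self.start[None, :]
            t = rel @ self.direction
            perp = rel - t[:, None] * self.direction[None, :]
            d = np.linalg.norm(perp, axis=1)
            s = t
            inside = (t >= 0) & (t <= self.length) & (d < self.radius_at(np.clip(t, 0, self.length)))
            return inside, s
        if self.kind == "arc":
            center, e_r, t0 = self._arc_frame()
            rel = x - center[None, :]
            xi = rel @ e_r
            eta = rel @ t0
            zeta = rel @ self.binormal
            theta = np.arctan2(eta, xi)  # in (-pi, pi], 0 at the start
            theta_max = self.length / self.curvature_radius
            s = theta * self.curvature_radius
            rad = np.hypot(xi, eta)
            d = np.hypot(rad - self.curvature_radius, zeta)
            inside = (theta >= 0) & (theta <= theta_max) & (d < self.radius_at(np.clip(s, 0, self.length)))
            return inside, s
        # helix: dense polyline nearest point
        ds = 0.05
        n = int(np.ceil(self.length / ds)) + 1
        s_grid = np.linspace(0.0, self.length, n)
        cl = self.centerline(s_grid)
        from scipy.spatial import cKDTree

        tree = cKDTree(cl)
        d, i = tree.query(x, k=1)
        s = s_grid[i]
        inside = d < self.radius_at(s)
        # flat end caps: reject points past the end normal planes
        for s_end, sign in ((0.0, -1.0), (self.length, 1.0)):
            tan = self.tangent(s_end)[0]
            p = self.centerline(s_end)[0]
            beyond = sign * ((x - p[None, :]) @ tan) > 0
            at_end = np.abs(s - s_end) < 2 * ds
            inside &= ~(beyond & at_end)
        return inside, s

    # --------------------------------------------------------------- analytics

    def analytic_volume_ul(self, s1: float = 0.0, s2: float | None = None) -> float:
        """pi * integral of r(s)^2 ds over [s1, s2], in mm^3 == microlitres.

        Exact for straight tubes, and exact for arcs by the Pappus centroid
        theorem (the disk centroid lies on the centerline); for a gentle helix
        (curvature * r << 1) it matches the tube volume to the same order.
        """
        s2 = self.length if s2 is None else s2
        if not 0.0 <= s1 < s2 <= self.length + 1e-9:
            raise ValueError(f"invalid arclength window [{s1}, {s2}]")
        r0, r1 = self.radius_endpoints
        slope = (r1 - r0) / self.length
        # integral of (r0 + slope*s)^2 ds
        def antideriv(s: float) -> float:
            return r0**2 * s + r0 * slope * s**2 + slope**2 * s**3 / 3.0
        return float(np.pi * (antideriv(s2) - antideriv(s1)))

    def truth(self, station_mm: float = 1.0) -> "TubeTruth":
        n = int(np.floor(self.length / station_mm))
        s = np.arange(n + 1) * station_mm
        if s[-1] < self.length - 1e-9:
            s = np.append(s, self.length)
        return TubeTruth(
            spec=self,
            s=s,
            points=self.centerline(s),
            radii=self.radius_at(s),
        )


@dataclass
class TubeTruth:
    """Analytic ground truth of a rendered tube: centerline samples at 1 mm
    stations, the radius profile, and exact volume/length over any window."""

    spec: TubeSpec
    s: np.ndarray
    points: np.ndarray
    radii: np.ndarray
    exclusive_volume_ul: float | None = None  # set for bifurcation children

    def volume_ul(self, s1: float = 0.0, s2: float | None = None) -> float:
        return self.spec.analytic_volume_ul(s1, s2)

    @property
    def length_cm(self) -> float:
        return self.spec.length / 10.0

    def to_segmentation(self):
        """Adapt the analytic truth into a :class:`~pavol.segmentation.
        VesselSegmentation` (centerline at the 1 mm stations, diameter
        2*r(s)), for validating the volumetry estimators against exact
        geometry without running the tracker."""
        from .intensity_model import CylinderParams, FitResult
        from .segmentation import VesselSegmentation

        tangents = self.spec.tangent(self.s)
        fits = [
            FitResult(
                params=CylinderParams(center=self.points[i], tangent=tangents[i],
                                      R=float(self.radii[i]), a0=self.spec.a0,
                                      a1=self.spec.a1, sigma=max(self.spec.psf_sigma, 0.2)),
                rms_residual=0.0, n_samples=0, converged=True,
            )
            for i in range(len(self.s))
        ]
        seg = VesselSegmentation(fits=fits, centers=self.points.copy(), tangents=tangents)
        seg.diameters = 2.0 * self.radii.copy()
        return seg

    def to_json(self, path) -> None:
        payload = {
            "kind": self.spec.kind,
            "length_mm": self.spec.length,
            "s_mm": self.s.tolist(),
            "centerline_mm": self.points.tolist(),
            "radius_mm": self.radii.tolist(),
            "volume_ul": self.volume_ul(),
            "length_cm": self.length_cm,
        }
        if self.exclusive_volume_ul is not None:
            payload["exclusive_volume_ul"] = self.exclusive_volume_ul
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)


@dataclass
class GridSpec:
    """Raster geometry for rendering: voxel spacing, array shape, origin."""

    shape: tuple[int, int, int]
    spacing: tuple[float, float, float] = DEFAULT_SPACING
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    @classmethod
    def around(cls, specs: Sequence[TubeSpec], spacing=DEFAULT_SPACING, margin_mm: float = 6.0) -> "GridSpec":
        """Smallest grid containing all tubes with ``margin_mm`` on each face."""
        los, his = [], []
        for spec in specs:
            s = np.linspace(0, spec.length, 200)
            cl = spec.centerline(s)
            r = spec.radius_at(s)[:, None]
            pad = r + margin_mm + 3.0 * spec.psf_sigma
            los.append((cl - pad).min(axis=0))
            his.append((cl + pad).max(axis=0))
        lo = np.min(los, axis=0)
        hi = np.max(his, axis=0)
        spacing = np.asarray(spacing, dtype=np.float64)
        shape = tuple(int(np.ceil((hi[i] - lo[i]) / spacing[i])) + 1 for i in range(3))
        return cls(shape=shape, spacing=tuple(spacing), origin=tuple(lo))


def _subvoxel_offsets(m: int) -> np.ndarray:
    """m^3 offsets (voxel units) of a regular subdivision of one voxel."""
    o = (np.arange(m) + 0.5) / m - 0.5
    return np.stack(np.meshgrid(o, o, o, indexing="ij"), axis=-1).reshape(-1, 3)


def _occupancy(specs: Sequence[TubeSpec], grid: GridSpec, supersample: int) -> np.ndarray:
    """Union occupancy fraction of several tubes on the grid (partial-volume
    via supersampled indicator; union so overlapping branches do not sum)."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)

    # restrict work to the dilated bounding box of the tubes
    los, his = [], []
    for spec in specs:
        s = np.linspace(0, spec.length, 200)
        cl = spec.centerline(s)
        rmax = spec.radius_at(s).max()
        los.append((cl.min(axis=0) - rmax - 1.0 - origin) / spacing)
        his.append((cl.max(axis=0) + rmax + 1.0 - origin) / spacing)
    lo = np.clip(np.floor(np.min(los, axis=0)).astype(int), 0, shape - 1)
    hi = np.clip(np.ceil(np.max(his, axis=0)).astype(int), 0, shape - 1)

    ii, jj, kk = np.meshgrid(
        np.arange(lo[0], hi[0] + 1), np.arange(lo[1], hi[1] + 1), np.arange(lo[2], hi[2] + 1),
        indexing="ij",
    )
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)

    acc = np.zeros(len(idx))
    for off in _subvoxel_offsets(supersample):
        pts = (idx + off) * spacing + origin
        inside = np.zeros(len(pts), dtype=bool)
        for spec in specs:
            ins, _ = spec.project(pts)
            inside |= ins
        acc += inside
    acc /= supersample**3

    occ = np.zeros(tuple(shape))
    occ[lo[0] : hi[0] + 1, lo[1] : hi[1] + 1, lo[2] : hi[2] + 1] = acc.reshape(
        hi[0] - lo[0] + 1, hi[1] - lo[1] + 1, hi[2] - lo[2] + 1
    )
    return occ


def _check_fits(spec: TubeSpec, grid: GridSpec) -> None:
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    extent_hi = origin + (np.asarray(grid.shape) - 1) * spacing
    s = np.linspace(0, spec.length, 200)
    cl = spec.centerline(s)
    pad = spec.radius_at(s)[:, None] + 3.0 * spec.psf_sigma
    if np.any(cl - pad < origin) or np.any(cl + pad > extent_hi):
        raise ValueError("tube exits the rendering grid (needs >= 3*sigma_psf margin)")


def _finish_render(occ: np.ndarray, spec: TubeSpec, grid: GridSpec) -> ImageVolume:
    img = spec.a0 + (spec.a1 - spec.a0) * occ
    if spec.psf_sigma > 0:
        img = gaussian_filter(img, sigma=spec.psf_sigma / np.asarray(grid.spacing))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    return ImageVolume(data=img, spacing=grid.spacing, origin=grid.origin)


def render_tube(spec: TubeSpec, grid: GridSpec | None = None) -> tuple[ImageVolume, TubeTruth]:
    """Rasterize one tube with partial-volume accuracy, blur and noise.

    Returns the image volume together with its analytic ground truth.
    Rendering is deterministic for a fixed spec (noise uses ``spec.seed``).
    """
    if grid is None:
        grid = GridSpec.around([spec])
    _check_fits(spec, grid)
    occ = _occupancy([spec], grid, spec.supersample)
    return _finish_render(occ, spec, grid), spec.truth()


def render_bifurcation(
    parent: TubeSpec, children: Sequence[TubeSpec], grid: GridSpec | None = None
) -> tuple[ImageVolume, dict[str, TubeTruth], dict[str, np.ndarray]]:
    """Render a Y-shaped union of a parent tube and two children.

    Children must start at the parent's end (the junction).  Occupancy is the
    union of the three indicators, so the overlap region has single-tube
    intensity.  Returned landmarks: ``valve`` = parent start, ``bifurcation``
    = junction, ``takeoff_right``/``takeoff_left`` = child ends.  Child truth
    volumes count only the region distal to the junction (child minus
    parent), from the supersampled indicator.
    """
    if len(children) != 2:
        raise ValueError("expected exactly two child tubes")
    junction = parent.end
    r_junction = parent.radius_endpoints[1]
    for ch in children:
        gap = float(np.linalg.norm(ch.start - junction))
        if gap > r_junction + ch.radius_endpoints[0]:
            raise ValueError(f"child tube disconnected from the junction (gap {gap:.1f} mm)")
    specs = [parent, *children]
    if grid is None:
        grid = GridSpec.around(specs)
    for spec in specs:
        _check_fits(spec, grid)
    occ = _occupancy(specs, grid, parent.supersample)
    vol = _finish_render(occ, parent, grid)

    truths = {"parent": parent.truth()}
    for name, ch in zip(("right", "left"), children):
        t = ch.truth()
        t.exclusive_volume_ul = _exclusive_volume(ch, parent, grid, ch.supersample)
        truths[name] = t
    landmarks = {
        "valve": parent.start.copy(),
        "bifurcation": junction,
        "takeoff_right": children[0].end,
        "takeoff_left": children[1].end,
    }
    return vol, truths, landmarks


def _exclusive_volume(child: TubeSpec, parent: TubeSpec, grid: GridSpec, supersample: int) -> float:
    """Supersampled volume of child minus its overlap with the parent (ul)."""
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    s = np.linspace(0, child.length, 200)
    cl = child.centerline(s)
    rmax = child.radius_at(s).max()
    lo = np.floor((cl.min(axis=0) - rmax - 1 - origin) / spacing).astype(int)
    hi = np.ceil((cl.max(axis=0) + rmax + 1 - origin) / spacing).astype(int)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    subvol = np.prod(spacing) / supersample**3
    count = 0
    for off in _subvoxel_offsets(supersample):
        pts = (idx + off) * spacing + origin
        in_child, _ = child.project(pts)
        in_parent, _ = parent.project(pts)
        count += int(np.sum(in_child & ~in_parent))
    return count * subvol


def voxel_count_volume(
    spec: TubeSpec, window: tuple[float, float], spacing=DEFAULT_SPACING, supersample: int = 8
) -> float:
    """Independent volume oracle: supersampled voxel count of the true tube
    restricted to arclength window [s1, s2], in microlitres."""
    s1, s2 = window
    grid = GridSpec.around([spec], spacing=spacing)
    spacing = np.asarray(grid.spacing)
    origin = np.asarray(grid.origin)
    shape = np.asarray(grid.shape)
    ii, jj, kk = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3).astype(np.float64)
    subvol = np.prod(spacing) / supersample**3
    count = 0
    for off in _subvoxel_offsets(supersample):
        pts = (idx + off) * spacing + origin
        inside, s = spec.project(pts)
        count += int(np.sum(inside & (s >= s1) & (s <= s2)))
    return count * subvol


# --------------------------------------------------------------------------
# cohort simulation
# --------------------------------------------------------------------------

# (vessel, method) -> (patient mean, patient SD, control mean, control SD)
# indexed volumes in ul/(cm*m^2); diameters in mm/m^2 (all BSA-corrected)
COHORT_DEFAULTS: dict[tuple[str, str], tuple[float, float, float, float]] = {
    ("MPA", "vol3d"): (5508, 1236, 3438, 749),
    ("RPA", "vol3d"): (3522, 934, 1664, 468),
    ("LPA", "vol3d"): (3093, 692, 1812, 474),
    ("MPA", "d3d_mean"): (19.7, 2.2, 15.4, 1.3),
    ("MPA", "d3d_min"): (18.1, 2.0, 14.8, 1.2),
    ("MPA", "d3d_max"): (21.1, 2.6, 16.4, 1.5),
    ("MPA", "manual_axial"): (19.7, 2.6, 14.4, 1.5),
    ("MPA", "manual_mpr"): (20.1, 2.6, 15.0, 1.5),
    ("RPA", "d3d_mean"): (15.7, 2.0, 10.6, 1.6),
    ("RPA", "d3d_min"): (15.0, 1.9, 10.0, 1.4),
    ("RPA", "d3d_max"): (16.9, 2.4, 12.0, 2.0),
    ("RPA", "manual_axial"): (15.6, 2.0, 10.2, 1.5),
    ("RPA", "manual_mpr"): (16.1, 2.0, 10.6, 1.5),
    ("LPA", "d3d_mean"): (14.8, 1.5, 11.1, 1.5),
    ("LPA", "d3d_min"): (14.1, 1.6, 10.0, 1.3),
    ("LPA", "d3d_max"): (15.6, 1.7, 12.5, 1.7),
    ("LPA", "manual_axial"): (15.0, 1.5, 10.9, 1.6),
    ("LPA", "manual_mpr"): (15.7, 1.6, 11.3, 1.7),
}

#: group BSA (m^2): (patient mean, patient SD, control mean, control SD)
BSA_DEFAULTS = (1.79, 0.20, 1.84, 0.18)

#: default reader error, as a fraction of the control-group mean per method;
#: automated reads repeat much more tightly than manual caliper placement
READER_ERROR_FRAC = {
    "vol3d": 0.015,
    "d3d_mean": 0.015,
    "d3d_min": 0.02,
    "d3d_max": 0.02,
    "manual_axial": 0.04,
    "manual_mpr": 0.04,
}

#: reads per method: reader 1 twice (6 months apart), reader 2 once;
#: the oblique-reformation read was performed by reader 1 only
READS = {
    "vol3d": ("r1a", "r1b", "r2"),
    "d3d_mean": ("r1a", "r1b", "r2"),
    "d3d_min": ("r1a", "r1b", "r2"),
    "d3d_max": ("r1a", "r1b", "r2"),
    "manual_axial": ("r1a", "r1b", "r2"),
    "manual_mpr": ("r1a",),
}


def simulate_cohort(
    n_patients: int = 20,
    n_controls: int = 21,
    group_params: dict | None = None,
    reader_error_sd: dict | float | None = None,
    seed: int = 0,
    methods: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Simulate a measurement cohort in tidy long format.

    Per subject, a true (BSA-indexed) value for each (vessel, method) is
    drawn from the normal distribution of the subject's group; each read adds
    independent reader noise.  Columns: ``subject, group, height_cm,
    weight_kg, bsa_m2, vessel, method, read, value``.

    ``reader_error_sd`` may be a mapping ``method -> absolute SD``, a single
    scalar applied to every method, or None for the per-method defaults.
    ``methods`` restricts the simulated measurement methods (default: all).
    """
    if n_patients < 2 or n_controls < 2:
        raise ValueError("need at least 2 subjects per group")
    params = dict(COHORT_DEFAULTS)
    if group_params:
        params.update(group_params)
    if methods is not None:
        params = {k: v for k, v in params.items() if k[1] in methods}
        if not params:
            raise ValueError(f"no known methods among {methods}")
    for key, (m1, s1, m0, s0) in params.items():
        if s1 < 0 or s0 < 0:
            raise ValueError(f"negative SD for {key}")

    active = {m for (_, m) in params}
    if reader_error_sd is None:
        noise = {m: READER_ERROR_FRAC[m] * np.mean([p[2] for (v, mm), p in params.items() if mm == m])
                 for m in active}
    elif np.isscalar(reader_error_sd):
        noise = {m: float(reader_error_sd) for m in READER_ERROR_FRAC}  # type: ignore[arg-type]
    else:
        noise = {m: float(reader_error_sd.get(m, 0.0)) for m in READER_ERROR_FRAC}  # type: ignore[union-attr]

    rng = np.random.default_rng(seed)
    from .cohort_stats import du_bois_bsa

    rows = []
    groups = ["patient"] * n_patients + ["control"] * n_controls
    for i, group in enumerate(groups):
        subject = f"{'P' if group == 'patient' else 'C'}{i + 1:03d}"
        # anthropometrics chosen to land near the reported group BSA
        height = rng.normal(168.0 if group == "patient" else 172.0, 8.0)
        weight = rng.normal(69.0 if group == "patient" else 73.0, 11.0)
        height = max(height, 120.0)
        weight = max(weight, 35.0)
        bsa = du_bois_bsa(weight, height)
        for (vessel, method), (m1, s1, m0, s0) in params.items():
            mu, sd = (m1, s1) if group == "patient" else (m0, s0)
            truth = rng.normal(mu, sd)
            for read in READS[method]:
                rows.append(
                    (subject, group, height, weight, bsa, vessel, method, read,
                     truth + rng.normal(0.0, noise[method]))
                )
    return pd.DataFrame(
        rows,
        columns=["subject", "group", "height_cm", "weight_kg", "bsa_m2", "vessel", "method", "read", "value"],
    )
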