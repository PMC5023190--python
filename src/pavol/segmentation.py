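"""Seed-initiated vessel tracking, refinement and centerline extraction.

One seed point inside a vessel is enough: a local cylinder fit is
initialized from the intensity statistics around the seed, and the vessel is
then traversed both proximally and distally in 1 mm steps, each step's fit
initialized by extrapolating the previous one along its tangent.  Tracking
stops on loss of contrast, fit failure, implausible radius, sharp bends, or
the volume boundary.  A two-step refinement follows: the chain of fitted
centers is smoothed with a cubic smoothing spline over arclength, and every
segment is refit with its tangent frozen to the spline tangent.  The
centerline runs along the geometric centroid of each cross-section, and the
average diameter perpendicular to it is computed at every 1 mm station by
casting equiangular rays to the half-contrast boundary.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .intensity_model import CylinderParams, FitResult, fit_segment, radial_profile
from .volume_io import ImageVolume

__all__ = [
    "VesselSegmentation",
    "init_from_seed",
    "track",
    "refine",
    "centroid_centerline",
    "diameter_profile",
    "flag_blowouts",
]

STEP_MM = 1.0  # one fit per 1 mm reporting station
CONTRAST_STOP_FRAC = 0.15  # stop when contrast falls below this x seed contrast
MAX_BEND_DEG = 60.0  # per-step bend limit
MAX_LENGTH_MM = 200.0  # per-vessel length cap


@dataclass
class VesselSegmentation:
    """Ordered chain of fitted tube segments with a centerline.

    Stations are ~1 mm apart; ``s`` is cumulative chord arclength (mm, 0 at
    the first vertex).  ``flags[i]`` collects QC labels for station i
    (``"suspect-merge"``, ``"unresolved"``, ``"interpolated"``); flagged
    stations are excluded from downstream measurement.
    """

    fits: list[FitResult]
    centers: np.ndarray
    tangents: np.ndarray
    s: np.ndarray = field(default=None)  # type: ignore[assignment]
    diameters: np.ndarray | None = None
    flags: list[set] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    seed_index: int | None = None  # station nearest the user's seed point

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=np.float64)
        self.tangents = np.asarray(self.tangents, dtype=np.float64)
        if self.s is None:
            self.s = _cum_chord(self.centers)
        if not self.flags:
            self.flags = [set() for _ in range(len(self.centers))]

    def __len__(self) -> int:
        return len(self.centers)

    @property
    def length_mm(self) -> float:
        return float(self.s[-1] - self.s[0])

    def flagged(self) -> np.ndarray:
        return np.array([len(f) > 0 for f in self.flags])

    def resample(self, ds: float = 0.1) -> tuple[np.ndarray, np.ndarray]:
        """Dense (s, xyz) resampling of the centerline by linear interpolation."""
        s_fine = np.arange(self.s[0], self.s[-1] + ds / 2, ds)
        pts = np.column_stack([np.interp(s_fine, self.s, self.centers[:, k]) for k in range(3)])
        return s_fine, pts

    def diameter_at(self, s_query) -> np.ndarray:
        """Diameter interpolated over unflagged stations."""
        if self.diameters is None:
            raise ValueError("diameter profile not computed")
        ok = ~self.flagged() & np.isfinite(self.diameters)
        if ok.sum() < 2:
            raise ValueError("too few unflagged stations for interpolation")
        return np.interp(np.asarray(s_query, dtype=np.float64), self.s[ok], self.diameters[ok])

    # ------------------------------------------------------------------ export

    def to_json(self, path) -> None:
        payload = {
            "s_mm": self.s.tolist(),
            "centerline_mm": self.centers.tolist(),
            "tangents": self.tangents.tolist(),
            "diameter_mm": None if self.diameters is None else self.diameters.tolist(),
            "flags": [sorted(f) for f in self.flags],
            "warnings": self.warnings,
            "segments": [f.to_dict() for f in self.fits],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=2)

    def centerline_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["s_mm", "x_mm", "y_mm", "z_mm", "diameter_mm", "flags"])
            for i in range(len(self)):
                d = "" if self.diameters is None or not np.isfinite(self.diameters[i]) else f"{self.diameters[i]:.4f}"
                w.writerow([f"{self.s[i]:.3f}", *(f"{c:.4f}" for c in self.centers[i]), d, ";".join(sorted(self.flags[i]))])


def _cum_chord(pts: np.ndarray) -> np.ndarray:
    d = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(d)])


def _normal_basis(t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0]) if abs(t[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    u = np.cross(t, ref)
    u /= np.linalg.norm(u)
    return u, np.cross(t, u)


# --------------------------------------------------------------------------
# seed initialization
# --------------------------------------------------------------------------

def init_from_seed(vol: ImageVolume, seed, sphere_radius: float = 10.0) -> CylinderParams:
    """Initial cylinder parameters from intensity statistics around the seed.

    Tangent: principal eigenvector of the intensity-weighted second-moment
    matrix in a sphere around the seed.  Radius: median half-contrast
    distance along rays in the normal plane.  a0/a1: robust low/high
    percentiles in the sphere.  If the sphere lies entirely inside a large
    vessel (no background, hence no contrast), it is grown up to 3x before
    the seed is rejected as "not in vessel".
    """
    last_err: Exception | None = None
    for radius in (sphere_radius, 1.5 * sphere_radius, 2.2 * sphere_radius, 3.0 * sphere_radius):
        try:
            return _init_from_seed_sphere(vol, seed, radius)
        except ValueError as err:
            if "seed not in vessel" not in str(err):
                raise
            last_err = err
    raise last_err  # type: ignore[misc]


def _init_from_seed_sphere(vol: ImageVolume, seed, sphere_radius: float) -> CylinderParams:
    seed = np.asarray(seed, dtype=np.float64)
    if not vol.contains_world(seed):
        raise ValueError("seed point outside the volume")

    # voxel centers inside the sphere
    lo = vol.voxel_from_world(seed - sphere_radius)
    hi = vol.voxel_from_world(seed + sphere_radius)
    lo = np.clip(np.floor(np.minimum(lo, hi)).astype(int), 0, np.array(vol.shape) - 1)
    hi = np.clip(np.ceil(np.maximum(vol.voxel_from_world(seed - sphere_radius), vol.voxel_from_world(seed + sphere_radius))).astype(int), 0, np.array(vol.shape) - 1)
    ii, jj, kk = np.meshgrid(*[np.arange(lo[a], hi[a] + 1) for a in range(3)], indexing="ij")
    idx = np.stack([ii, jj, kk], axis=-1).reshape(-1, 3)
    pts = vol.world_from_voxel(idx)
    inside = np.linalg.norm(pts - seed, axis=1) <= sphere_radius
    pts = pts[inside]
    vals = vol.data[idx[inside, 0], idx[inside, 1], idx[inside, 2]]

    a0 = float(np.percentile(vals, 10))
    a1 = float(np.percentile(vals, 95))
    scale = max(abs(np.percentile(vals, 99)), abs(np.percentile(vals, 1)), 1.0)
    # noise level of the bright compartment; a sphere entirely inside a
    # large vessel shows only noise "contrast" and must trigger growth
    hi = vals[vals >= np.median(vals)]
    sigma_n = 1.4826 * float(np.median(np.abs(hi - np.median(hi))))
    if a1 - a0 <= max(0.05 * scale, 6.0 * sigma_n):
        raise ValueError("seed not in vessel: local contrast below threshold")

    half = 0.5 * (a0 + a1)
    w = np.clip(vals - half, 0.0, None)
    if w.sum() <= 0:
        raise ValueError("seed not in vessel: no bright voxels near seed")
    centroid = (w[:, None] * pts).sum(axis=0) / w.sum()
    rel = pts - centroid
    cov = (w[:, None, None] * rel[:, :, None] * rel[:, None, :]).sum(axis=0) / w.sum()
    evals, evecs = np.linalg.eigh(cov)
    tangent = evecs[:, np.argmax(evals)]

    # half-contrast radius along normal-plane rays
    u, v = _normal_basis(tangent)
    radii = []
    for theta in np.linspace(0, 2 * np.pi, 16, endpoint=False):
        ray = np.cos(theta) * u + np.sin(theta) * v
        rr = np.arange(0.0, sphere_radius, 0.2)
        prof = vol.sample_world(centroid[None, :] + rr[:, None] * ray[None, :])
        below = np.where(prof < half)[0]
        if len(below) and below[0] > 0:
            i = below[0]
            f = (half - prof[i - 1]) / (prof[i] - prof[i - 1])
            radii.append(rr[i - 1] + f * 0.2)
    if len(radii) < 4:
        raise ValueError("seed not in vessel: no half-contrast boundary found")
    R = float(np.median(radii))
    R = max(R, 0.5 * float(np.min(vol.spacing)))
    return CylinderParams(center=centroid, tangent=tangent, R=R, a0=a0, a1=a1, sigma=1.0)


# --------------------------------------------------------------------------
# tracking
# --------------------------------------------------------------------------

def track(
    vol: ImageVolume,
    seed,
    step: float = STEP_MM,
    contrast_stop_frac: float = CONTRAST_STOP_FRAC,
    max_bend_deg: float = MAX_BEND_DEG,
    max_length_mm: float = MAX_LENGTH_MM,
    min_center_level: float = 0.5,
) -> VesselSegmentation:
    """Bidirectional model-based tracking from a single seed point.

    Deterministic for a fixed volume and seed.  Returns the merged
    proximal-to-distal chain; raises if fewer than 3 segments survive.
    ``min_center_level`` is the fraction of the seed contrast (above seed
    background) the image must retain at a fitted center — the rule that
    stops the march at the vessel's end, where the on-axis intensity
    collapses within about one blur width.
    """
    init = init_from_seed(vol, seed)
    fit0 = fit_segment(vol, init)
    if not fit0.converged:
        raise ValueError("seed fit did not converge")
    contrast0 = fit0.params.contrast
    a0_seed = fit0.params.a0
    cos_limit = np.cos(np.deg2rad(max_bend_deg))

    def march(direction_sign: float) -> list[FitResult]:
        out: list[FitResult] = []
        prev = fit0.params
        prev_dir = direction_sign * fit0.params.tangent
        travelled = 0.0
        while travelled < max_length_mm / 2:
            nxt_center = prev.center + step * prev_dir
            if not vol.contains_world(nxt_center):
                break
            init_p = replace(prev, center=nxt_center, tangent=prev_dir)
            try:
                fit = fit_segment(vol, init_p)
            except ValueError:  # ROI fell outside the volume
                break
            p = fit.params
            if not fit.converged:
                break
            if p.contrast < contrast_stop_frac * contrast0:
                break
            level = vol.sample_world(p.center)
            if not np.isfinite(level) or level < a0_seed + min_center_level * contrast0:
                break
            if float(np.dot(p.tangent, prev_dir)) < cos_limit:
                break
            advance = float(np.dot(p.center - prev.center, prev_dir))
            if advance < 0.2 * step:
                break
            out.append(fit)
            travelled += advance
            prev = p
            prev_dir = p.tangent if float(np.dot(p.tangent, prev_dir)) > 0 else -p.tangent
        return out

    distal = march(+1.0)
    proximal = march(-1.0)
    fits = list(reversed(proximal)) + [fit0] + distal
    if len(fits) < 3:
        raise ValueError("vessel too short: fewer than 3 segments tracked")

    centers = np.array([f.params.center for f in fits])
    tangents = np.array([f.params.tangent for f in fits])
    # orient all tangents proximal -> distal
    for i in range(1, len(tangents)):
        if float(np.dot(tangents[i], tangents[i - 1])) < 0:
            tangents[i] = -tangents[i]
    return VesselSegmentation(
        fits=fits, centers=centers, tangents=tangents, seed_index=len(proximal)
    )


# --------------------------------------------------------------------------
# two-step refinement
# --------------------------------------------------------------------------

def refine(vol: ImageVolume, seg: VesselSegmentation) -> VesselSegmentation:
    """Two-step refinement: spline-smooth the chain of centers, then refit
    every segment with the tangent frozen to the spline tangent.

    A per-station fallback keeps the previous fit whenever the constrained
    refit increases the residual, so refinement cannot degrade the chain.
    """
    if len(seg) < 4:
        raise ValueError("refine requires at least 4 segments")
    u = seg.s
    try:
        splines = [make_smoothing_spline(u, seg.centers[:, k]) for k in range(3)]
        smooth = np.column_stack([sp(u) for sp in splines])
        deriv = np.column_stack([sp.derivative()(u) for sp in splines])
    except Exception:
        out = replace_seg(seg)
        out.warnings.append("spline smoothing failed; segmentation unchanged")
        return out
    norms = np.linalg.norm(deriv, axis=1)
    if np.any(norms < 1e-9) or not np.all(np.isfinite(smooth)):
        out = replace_seg(seg)
        out.warnings.append("degenerate spline geometry; segmentation unchanged")
        return out
    tangents = deriv / norms[:, None]

    fits: list[FitResult] = []
    for i in range(len(seg)):
        old = seg.fits[i]
        init = replace(old.params, center=smooth[i], tangent=tangents[i])
        try:
            # in-plane motion capped at 1 mm: the spline is already close,
            # and an end station truncated by the vessel tip must not slide
            new = fit_segment(vol, init, fixed_tangent=True, inplane_bound=1.0)
        except ValueError:
            new = old
        if not new.converged or new.rms_residual > old.rms_residual * (1 + 1e-9) + 1e-12:
            new = old
        fits.append(new)

    centers = np.array([f.params.center for f in fits])
    tangs = np.array([f.params.tangent for f in fits])
    for i in range(1, len(tangs)):
        if float(np.dot(tangs[i], tangs[i - 1])) < 0:
            tangs[i] = -tangs[i]
    return VesselSegmentation(fits=fits, centers=centers, tangents=tangs,
                              warnings=list(seg.warnings), seed_index=seg.seed_index)


def replace_seg(seg: VesselSegmentation) -> VesselSegmentation:
    return VesselSegmentation(
        fits=list(seg.fits), centers=seg.centers.copy(), tangents=seg.tangents.copy(),
        s=seg.s.copy(), diameters=None if seg.diameters is None else seg.diameters.copy(),
        flags=[set(f) for f in seg.flags], warnings=list(seg.warnings),
        seed_index=seg.seed_index,
    )


# --------------------------------------------------------------------------
# centroid centerline
# --------------------------------------------------------------------------

def centroid_centerline(
    vol: ImageVolume, seg: VesselSegmentation, mode: str = "model",
    n_angles: int = 24, n_radii: int = 12,
) -> VesselSegmentation:
    """Replace each station center by the geometric centroid of its
    cross-section: the in-plane region where occupancy >= 0.5, sampled on a
    polar grid.  ``mode="model"`` uses the fitted cylinder occupancy (for
    which the centroid coincides with the fitted center); ``mode="image"``
    uses contrast-normalized image intensity.  Arclength is recomputed as
    cumulative chord length; empty cross-sections are flagged and
    interpolated from their neighbours.
    """
    out = replace_seg(seg)
    new_centers = out.centers.copy()
    for i in range(len(seg)):
        p = seg.fits[i].params
        t = seg.tangents[i]
        u, v = _normal_basis(t)
        rr = np.linspace(p.R / n_radii, 1.6 * p.R, n_radii)
        th = np.linspace(0, 2 * np.pi, n_angles, endpoint=False)
        R_, T_ = np.meshgrid(rr, th, indexing="ij")
        xy = np.stack([R_ * np.cos(T_), R_ * np.sin(T_)], axis=-1).reshape(-1, 2)
        pts = p.center[None, :] + xy[:, :1] * u[None, :] + xy[:, 1:] * v[None, :]
        if mode == "model":
            d = np.linalg.norm(xy, axis=1)
            occ = radial_profile(d, p.R, max(p.sigma, 1e-6))
        else:
            img = vol.sample_world(pts)
            occ = (img - p.a0) / max(p.contrast, 1e-9)
        w = (occ >= 0.5) * R_.reshape(-1)  # polar area element rho drho dphi
        if w.sum() <= 0:
            out.flags[i].add("interpolated")
            continue
        new_centers[i] = (w[:, None] * pts).sum(axis=0) / w.sum()
    # interpolate flagged stations from neighbours (over the old arclength)
    bad = np.array(["interpolated" in f for f in out.flags])
    if bad.any() and (~bad).sum() >= 2:
        for k in range(3):
            new_centers[bad, k] = np.interp(seg.s[bad], seg.s[~bad], new_centers[~bad, k])
    out.centers = new_centers
    out.s = _cum_chord(new_centers)
    return out


# --------------------------------------------------------------------------
# diameter profile
# --------------------------------------------------------------------------

def diameter_profile(
    seg: VesselSegmentation,
    n_rays: int = 36,
    mode: str = "model",
    vol: ImageVolume | None = None,
    max_unresolved_frac: float = 0.25,
) -> VesselSegmentation:
    """Average diameter perpendicular to the centerline at every station.

    Casts ``n_rays`` equiangular rays in the normal plane, finds the
    half-occupancy boundary crossing on each by linear interpolation, and
    averages the ``n_rays/2`` opposing-ray diameters.  For an ideal circular
    cross-section this equals ``2R``.  Stations where more than
    ``max_unresolved_frac`` of rays have no resolvable boundary are flagged
    ``"unresolved"``.
    """
    if mode == "image" and vol is None:
        raise ValueError("image mode requires the volume")
    if n_rays % 2:
        raise ValueError("n_rays must be even (opposing-ray pairing)")
    out = replace_seg(seg)
    diams = np.full(len(seg), np.nan)
    for i in range(len(seg)):
        p = seg.fits[i].params
        t = seg.tangents[i]
        u, v = _normal_basis(t)
        rmax = 2.5 * p.R
        rr = np.arange(0.0, rmax, 0.1)
        bounds = np.full(n_rays, np.nan)
        for j, theta in enumerate(np.linspace(0, 2 * np.pi, n_rays, endpoint=False)):
            ray = np.cos(theta) * u + np.sin(theta) * v
            pts = seg.centers[i][None, :] + rr[:, None] * ray[None, :]
            if mode == "model":
                # deblurred vessel boundary: the model's indicator at sigma=0,
                # so each ray crosses half-occupancy exactly at the fitted R
                d = np.linalg.norm(pts - p.center[None, :] - ((pts - p.center[None, :]) @ p.tangent)[:, None] * p.tangent[None, :], axis=1)
                occ = radial_profile(d, p.R, 0.0)
            else:
                img = vol.sample_world(pts)  # type: ignore[union-attr]
                occ = (img - p.a0) / max(p.contrast, 1e-9)
            below = np.where(occ < 0.5)[0]
            if len(below) == 0 or below[0] == 0:
                continue
            k = below[0]
            if not np.isfinite(occ[k]) or not np.isfinite(occ[k - 1]) or occ[k] == occ[k - 1]:
                continue
            f = (occ[k - 1] - 0.5) / (occ[k - 1] - occ[k])
            bounds[j] = rr[k - 1] + f * 0.1
        half = n_rays // 2
        pair_d = bounds[:half] + bounds[half:]
        ok = np.isfinite(bounds).sum()
        if n_rays - ok > max_unresolved_frac * n_rays or not np.any(np.isfinite(pair_d)):
            out.flags[i].add("unresolved")
            continue
        diams[i] = np.nanmean(pair_d)
    out.diameters = diams
    return out


# --------------------------------------------------------------------------
# blow-out QC
# --------------------------------------------------------------------------

def flag_blowouts(
    seg: VesselSegmentation, jump_factor: float = 1.5, window: int = 5, gap: int = 5
) -> VesselSegmentation:
    """Flag stations whose diameter exceeds ``jump_factor`` times the
    running median of preceding unflagged stations — the signature of a
    segmentation leaking into an adjacent larger vessel (e.g. the ascending
    aorta).  The reference median lags ``gap`` stations behind, because the
    local fit smears a merge into a ramp several stations wide that would
    otherwise contaminate its own reference.  The chain is scanned outward
    from the seed station when known — the seed's caliber defines the
    vessel of interest, so a blow-out at either chain end is caught while a
    legitimately larger parent is never flagged just because the march
    exited into a smaller branch.  Flagged stations are excluded downstream.
    """
    if seg.diameters is None:
        raise ValueError("diameter profile required before blow-out flagging")
    out = replace_seg(seg)
    out.diameters = seg.diameters.copy()
    if not np.isfinite(jump_factor):
        return out
    d = out.diameters

    def scan(order: np.ndarray) -> np.ndarray:
        flagged = np.zeros(len(d), dtype=bool)
        recent: list[float] = []
        for i in order:
            if not np.isfinite(d[i]):
                continue
            if len(recent) >= window + gap:
                ref = float(np.median(recent[-(window + gap) : -gap]))
                if d[i] > jump_factor * ref:
                    flagged[i] = True
                    continue
            recent.append(d[i])
        return flagged

    n = len(d)
    if seg.seed_index is not None and 0 <= seg.seed_index < n:
        k = seg.seed_index
        orders = (np.arange(k, n), np.arange(0, k + 1)[::-1])
    else:
        orders = (np.arange(n), np.arange(n)[::-1])
    bad = scan(orders[0]) | scan(orders[1])
    for i in np.where(bad)[0]:
        out.flags[i].add("suspect-merge")
    return out
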