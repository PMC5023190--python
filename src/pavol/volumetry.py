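"""Landmark-bounded vessel volume, length and diameter summaries.

Anatomical landmarks (pulmonary valve level, MPA bifurcation, upper-lobe
take-offs) are projected onto the centerline's arclength.  The MPA is
measured between a level 5 mm distal to the valve and 5 mm proximal to the
bifurcation; the RPA/LPA between the bifurcation and the respective
upper-lobe take-off.  Volume integrates the cross-sectional area implied by
the per-station average diameter, pi*(d/2)^2, with the trapezoidal rule over
the 1 mm stations (mm^3 == microlitres); length is arclength along the
centerline.  Stations flagged by QC are excluded; a vessel with more than
20% flagged stations inside its window is excluded outright.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .segmentation import VesselSegmentation

__all__ = [
    "LandmarkSet",
    "VesselMeasurement",
    "MeasurementExcluded",
    "project_landmark",
    "measurement_window",
    "vessel_volume",
    "vessel_length",
    "diameter_summary",
    "measure_vessel",
]

MPA_OFFSET_MM = 5.0  # window inset from valve and bifurcation for the MPA
MAX_LANDMARK_DIST_MM = 20.0
MAX_FLAGGED_FRAC = 0.20
VESSELS = ("MPA", "RPA", "LPA")


class MeasurementExcluded(RuntimeError):
    """Raised when a vessel fails QC and must be excluded from analysis."""


@dataclass
class LandmarkSet:
    """World-mm landmark points; per vessel only a subset is required."""

    valve: np.ndarray | None = None
    bifurcation: np.ndarray | None = None
    takeoff_right: np.ndarray | None = None
    takeoff_left: np.ndarray | None = None

    def required_for(self, vessel: str) -> dict[str, np.ndarray]:
        if vessel == "MPA":
            need = {"valve": self.valve, "bifurcation": self.bifurcation}
        elif vessel == "RPA":
            need = {"bifurcation": self.bifurcation, "takeoff": self.takeoff_right}
        elif vessel == "LPA":
            need = {"bifurcation": self.bifurcation, "takeoff": self.takeoff_left}
        else:
            raise ValueError(f"unknown vessel {vessel!r}")
        missing = [k for k, p in need.items() if p is None]
        if missing:
            raise ValueError(f"{vessel}: missing landmarks {missing}")
        return {k: np.asarray(p, dtype=np.float64) for k, p in need.items()}


@dataclass
class VesselMeasurement:
    """One vessel's measurements (pre-indexing): volume in microlitres,
    centerline length in cm, and the mean/min/max of the per-station average
    diameter in mm over the measurement window."""

    vessel: str
    volume_ul: float = np.nan
    length_cm: float = np.nan
    mean_d: float = np.nan
    min_d: float = np.nan
    max_d: float = np.nan
    window: tuple[float, float] | None = None
    excluded: bool = False
    reason: str = ""


def project_landmark(seg: VesselSegmentation, p) -> float:
    """Arclength s (mm) of the centerline point nearest to p.

    The centerline is resampled at 0.1 mm; ties break toward smaller s.
    A landmark further than 20 mm from the vessel is an error.
    """
    p = np.asarray(p, dtype=np.float64)
    s_fine, pts = seg.resample(ds=0.1)
    d = np.linalg.norm(pts - p[None, :], axis=1)
    i = int(np.argmin(d))
    if d[i] > MAX_LANDMARK_DIST_MM:
        raise ValueError(f"landmark far from vessel ({d[i]:.1f} mm > {MAX_LANDMARK_DIST_MM} mm)")
    return float(s_fine[i])


def measurement_window(vessel: str, landmarks_s: dict[str, float]) -> tuple[float, float]:
    """Arclength window [s1, s2] for one vessel from projected landmarks.

    MPA: [s_valve + 5, s_bif - 5]; RPA/LPA: [s_bif, s_takeoff].  Landmark
    order along the chain is normalized first (tracking may have run in
    either direction), so s1 < s2 or the window is an error.
    """
    if vessel == "MPA":
        lo, hi = sorted((landmarks_s["valve"], landmarks_s["bifurcation"]))
        s1, s2 = lo + MPA_OFFSET_MM, hi - MPA_OFFSET_MM
    elif vessel in ("RPA", "LPA"):
        s1, s2 = sorted((landmarks_s["bifurcation"], landmarks_s["takeoff"]))
    else:
        raise ValueError(f"unknown vessel {vessel!r}")
    if s2 <= s1:
        raise ValueError(f"degenerate window [{s1:.1f}, {s2:.1f}] mm for {vessel}")
    return float(s1), float(s2)


def _window_profile(seg: VesselSegmentation, window: tuple[float, float]):
    """Station grid covering the window (fractional ends included) with the
    per-station area; flagged stations are bridged by linear interpolation,
    and too many flags raise :class:`MeasurementExcluded`."""
    if seg.diameters is None:
        raise ValueError("diameter profile not computed")
    s1, s2 = window
    if s1 < seg.s[0] - 1e-6 or s2 > seg.s[-1] + 1e-6:
        raise ValueError(f"window [{s1:.1f}, {s2:.1f}] not covered by the profile "
                         f"[{seg.s[0]:.1f}, {seg.s[-1]:.1f}]")
    in_win = (seg.s >= s1 - 1e-9) & (seg.s <= s2 + 1e-9)
    flagged = seg.flagged() | ~np.isfinite(seg.diameters)
    n_win = int(in_win.sum())
    if n_win == 0:
        raise ValueError("empty measurement window")
    if int((in_win & flagged).sum()) > MAX_FLAGGED_FRAC * n_win:
        raise MeasurementExcluded(
            f"{int((in_win & flagged).sum())}/{n_win} stations flagged inside the window"
        )
    ok = ~flagged
    if ok.sum() < 2:
        raise MeasurementExcluded("fewer than 2 unflagged stations")
    area = np.pi * (seg.diameters[ok] / 2.0) ** 2
    s_ok = seg.s[ok]
    # grid: window ends plus interior unflagged stations; linear area interp
    s_grid = np.concatenate([[s1], s_ok[(s_ok > s1) & (s_ok < s2)], [s2]])
    a_grid = np.interp(s_grid, s_ok, area)
    return s_grid, a_grid


def vessel_volume(seg: VesselSegmentation, window: tuple[float, float]) -> float:
    """Volume over the window in microlitres: trapezoid of pi*(d/2)^2 over
    arclength on the 1 mm stations, partial end intervals included."""
    s_grid, a_grid = _window_profile(seg, window)
    return float(np.trapezoid(a_grid, s_grid))


def vessel_length(seg: VesselSegmentation, window: tuple[float, float]) -> float:
    """Centerline length inside the window, in cm (chord length of the
    0.1 mm-resampled centerline)."""
    _window_profile(seg, window)  # shared QC / coverage checks
    s1, s2 = window
    s_fine, pts = seg.resample(ds=0.1)
    sel = (s_fine >= s1 - 1e-9) & (s_fine <= s2 + 1e-9)
    d = np.linalg.norm(np.diff(pts[sel], axis=0), axis=1)
    return float(d.sum()) / 10.0


def diameter_summary(seg: VesselSegmentation, window: tuple[float, float]) -> tuple[float, float, float]:
    """(mean, min, max) of the average diameter over unflagged stations in
    the window."""
    if seg.diameters is None:
        raise ValueError("diameter profile not computed")
    _window_profile(seg, window)
    s1, s2 = window
    ok = (~seg.flagged()) & np.isfinite(seg.diameters) & (seg.s >= s1 - 1e-9) & (seg.s <= s2 + 1e-9)
    d = seg.diameters[ok]
    if len(d) == 0:
        raise MeasurementExcluded("no unflagged stations in window")
    return float(d.mean()), float(d.min()), float(d.max())


def measure_vessel(seg: VesselSegmentation, vessel: str, landmarks: LandmarkSet) -> VesselMeasurement:
    """Project landmarks, derive the window, and assemble the full
    measurement; QC failures yield an excluded record instead of raising."""
    try:
        pts = landmarks.required_for(vessel)
        s_proj = {name: project_landmark(seg, p) for name, p in pts.items()}
        window = measurement_window(vessel, s_proj)
        vol = vessel_volume(seg, window)
        length = vessel_length(seg, window)
        mean_d, min_d, max_d = diameter_summary(seg, window)
    except (MeasurementExcluded, ValueError) as exc:
        return VesselMeasurement(vessel=vessel, excluded=True, reason=str(exc))
    return VesselMeasurement(
        vessel=vessel, volume_ul=vol, length_cm=length,
        mean_d=mean_d, min_d=min_d, max_d=max_d, window=window,
    )
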