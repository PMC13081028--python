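"""Hemodynamic and intramural wall-metric post-processing.

Turns a per-vertex time series of wall shear stress vectors tau(t) over one
cardiac cycle of duration T into the standard shear-derived fields:

    TAWSS = (1/T) int_0^T |tau| dt
    OSI   = 1/2 (1 - |int_0^T tau dt| / int_0^T |tau| dt)
    ECAP  = OSI / TAWSS
    RRT   = 1 / ((1 - 2 OSI) TAWSS)

plus the von Mises intramural stress of a symmetric stress tensor field,
the Robin (elastic-support) traction of the perivascular tissue, and
area-weighted regional means.  Time integrals use the trapezoid rule with
periodic closure.  Vertices where a denominator falls below a small floor
(flow stagnation for ECAP, the OSI -> 0.5 singularity for RRT) are returned
as NaN and excluded from regional means.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh

__all__ = [
    "WSSTimeSeries",
    "TissueSupportParams",
    "tawss",
    "osi",
    "ecap",
    "rrt",
    "von_mises",
    "robin_traction",
    "regional_mean",
    "vertex_areas",
    "compute_metric_fields",
]

TAWSS_FLOOR = 1e-6  # Pa; below this a vertex is treated as stagnant


@dataclass
class WSSTimeSeries:
    """Wall shear stress vectors (Pa) per vertex per frame over one cycle.

    times : (F,) frame times in [0, T]; vectors : (F, V, 3).
    If the last frame time is short of the period the series is closed
    periodically (frame 0 repeated at t = T) before integration.
    """

    times: np.ndarray
    vectors: np.ndarray
    period_T: float
    mesh: trimesh.Trimesh | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.vectors = np.asarray(self.vectors, dtype=float)
        if self.vectors.ndim != 3 or self.vectors.shape[2] != 3:
            raise ValueError("vectors must have shape (n_frames, n_vertices, 3)")
        if len(self.times) != self.vectors.shape[0]:
            raise ValueError("times length must match frame count")
        if len(self.times) < 2:
            raise ValueError("need at least 2 frames")
        if np.any(self.times < 0) or np.any(self.times > self.period_T):
            raise ValueError("frame times must lie within [0, period_T]")

    def closed(self) -> tuple[np.ndarray, np.ndarray]:
        """(times, vectors) with the periodic wrap frame appended if needed."""
        if np.isclose(self.times[-1], self.period_T):
            return self.times, self.vectors
        t = np.append(self.times, self.period_T)
        v = np.concatenate([self.vectors, self.vectors[:1]], axis=0)
        return t, v


def tawss(series: WSSTimeSeries) -> np.ndarray:
    """Time-averaged wall shear stress magnitude per vertex (Pa)."""
    t, v = series.closed()
    mag = np.linalg.norm(v, axis=2)
    return np.trapezoid(mag, t, axis=0) / series.period_T


def osi(series: WSSTimeSeries) -> np.ndarray:
    """Oscillatory shear index per vertex, in [0, 0.5].

    Vertices with a vanishing magnitude integral (no shear at all) are
    assigned 0 by convention.
    """
    t, v = series.closed()
    vec_int = np.trapezoid(v, t, axis=0)  # (V, 3)
    mag_int = np.trapezoid(np.linalg.norm(v, axis=2), t, axis=0)  # (V,)
    num = np.linalg.norm(vec_int, axis=1)
    out = np.zeros_like(mag_int)
    nz = mag_int > TAWSS_FLOOR * series.period_T
    out[nz] = 0.5 * (1.0 - num[nz] / mag_int[nz])
    return np.clip(out, 0.0, 0.5)


def ecap(tawss_field: np.ndarray, osi_field: np.ndarray, floor: float = TAWSS_FLOOR) -> np.ndarray:
    """Endothelial cell activation potential OSI/TAWSS (1/Pa); NaN where stagnant."""
    tw = np.asarray(tawss_field, dtype=float)
    os_ = np.asarray(osi_field, dtype=float)
    if tw.shape != os_.shape:
        raise ValueError("tawss and osi fields must be aligned")
    out = np.full_like(tw, np.nan)
    ok = tw > floor
    out[ok] = os_[ok] / tw[ok]
    return out


def rrt(tawss_field: np.ndarray, osi_field: np.ndarray, floor: float = TAWSS_FLOOR) -> np.ndarray:
    """Relative residence time 1/((1-2 OSI) TAWSS) (1/Pa); NaN where singular."""
    tw = np.asarray(tawss_field, dtype=float)
    os_ = np.asarray(osi_field, dtype=float)
    if tw.shape != os_.shape:
        raise ValueError("tawss and osi fields must be aligned")
    denom = (1.0 - 2.0 * os_) * tw
    out = np.full_like(tw, np.nan)
    ok = denom > floor
    out[ok] = 1.0 / denom[ok]
    return out


def von_mises(tensors: np.ndarray) -> np.ndarray:
    """Von Mises stress of symmetric tensors given as (..., 6) Voigt rows.

    Component order: (s11, s22, s33, s12, s23, s31).
    """
    s = np.asarray(tensors, dtype=float)
    if s.shape[-1] != 6:
        raise ValueError("expected 6 Voigt components (s11, s22, s33, s12, s23, s31)")
    s11, s22, s33, s12, s23, s31 = (s[..., i] for i in range(6))
    return np.sqrt(
        0.5 * ((s11 - s22) ** 2 + (s22 - s33) ** 2 + (s33 - s11) ** 2)
        + 3.0 * (s12 ** 2 + s23 ** 2 + s31 ** 2)
    )


@dataclass(frozen=True)
class TissueSupportParams:
    """Perivascular elastic-support (Robin) coefficients.

    ks : Pa/mm stiffness; cs : Pa*s/mm damping; p0 : Pa external pressure.
    Defaults are the values used for the mouse aorta simulations
    (ks = 1e3 Pa/mm, cs = 0.1 Pa*s/mm, zero cavity pressure).
    """

    ks: float = 1.0e3
    cs: float = 0.1
    p0: float = 0.0

    def __post_init__(self) -> None:
        if self.ks < 0 or self.cs < 0:
            raise ValueError("ks and cs must be non-negative")


def robin_traction(u, dudt, normal, params: TissueSupportParams) -> np.ndarray:
    """Support traction t = -ks u - cs du/dt - p0 n (Pa).

    ``u`` (mm), ``dudt`` (mm/s) and unit ``normal`` may be single vectors or
    (V, 3) arrays.
    """
    single = np.asarray(u).ndim == 1
    u = np.atleast_2d(np.asarray(u, dtype=float))
    dudt = np.atleast_2d(np.asarray(dudt, dtype=float))
    n = np.atleast_2d(np.asarray(normal, dtype=float))
    norms = np.linalg.norm(n, axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-8):
        raise ValueError("normals must be unit vectors (|n| = 1 within 1e-8)")
    t = -params.ks * u - params.cs * dudt - params.p0 * n
    return t[0] if single else t


def vertex_areas(mesh: trimesh.Trimesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident triangle."""
    areas = np.zeros(len(mesh.vertices))
    np.add.at(areas, mesh.faces.ravel(), np.repeat(mesh.area_faces / 3.0, 3))
    return areas


def regional_mean(
    values: np.ndarray,
    labels: np.ndarray,
    region: str,
    mesh: trimesh.Trimesh | None = None,
    weighting: str = "area",
) -> float:
    """Mean of a per-vertex field over one region, excluding NaN vertices.

    ``weighting="area"`` (default) weights by barycentric vertex area and
    requires ``mesh``; ``weighting="uniform"`` is a plain vertex average.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels)
    mask = labels == region
    if not np.any(mask):
        raise ValueError(f"region {region!r} not present in labels")
    defined = mask & np.isfinite(values)
    if not np.any(defined):
        raise ValueError(f"no defined values in region {region!r}")
    if weighting == "uniform":
        return float(np.mean(values[defined]))
    if weighting != "area":
        raise ValueError("weighting must be 'area' or 'uniform'")
    if mesh is None:
        raise ValueError("area weighting requires the mesh")
    w = vertex_areas(mesh)[defined]
    return float(np.sum(values[defined] * w) / np.sum(w))


def compute_metric_fields(series: WSSTimeSeries) -> dict[str, np.ndarray]:
    """Convenience bundle: TAWSS, OSI, ECAP and RRT for one series."""
    tw = tawss(series)
    os_ = osi(series)
    return {"tawss": tw, "osi": os_, "ecap": ecap(tw, os_), "rrt": rrt(tw, os_)}
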