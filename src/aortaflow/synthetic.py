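"""Synthetic fixtures with known ground truth for the full pipeline.

Every input the analysis consumes can be generated here: pulsatile
mouse-aortic inflow waveforms, idealized fusiform/arched vessel meshes with
ordered centerlines, tangent wall-shear-stress time series with
controllable oscillatory content, noisy biaxial stress-stretch data from a
known HGO truth, binarizable en-face porosity images, and right-censored
longitudinal cohort tables with a prescribed metric-lifespan slope.  All
generators take explicit integer seeds and are byte-deterministic.

Mouse-scale defaults: cardiac period ~0.12 s sampled at 15 frames/cycle,
millimeter geometry, month-resolved ages 1-4 with administrative censoring
at 120 days.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import trimesh
from scipy.ndimage import gaussian_filter

from .constitutive import BiaxialDataset, HGOParams, hgo_cauchy_stress
from .geometry import Centerline
from .microstructure import GrayImage
from .wall_metrics import WSSTimeSeries
from .windkessel import FlowWaveform

__all__ = [
    "WaveformSpec",
    "TubeSpec",
    "CohortSpec",
    "generate_inlet_waveform",
    "generate_tube_mesh",
    "generate_wss_field",
    "generate_biaxial_data",
    "generate_cohort",
    "generate_enface_image",
]


# ------------------------------------------------------------- waveforms


@dataclass(frozen=True)
class WaveformSpec:
    """Inlet waveform parameters.

    The shape is a half-sinusoid systolic ejection over the first third of
    the cycle on a low diastolic plateau, fully determined by the period,
    mean flow and pulsatility (peak/mean ratio); a seeded smooth jitter adds
    beat-shape variability before the mean is rescaled exactly.
    """

    period_s: float = 0.12
    mean_flow: float = 100.0  # uL/s
    pulsatility: float = 3.0
    n_samples: int = 15
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.period_s > 0):
            raise ValueError(f"period_s must be positive, got {self.period_s}")
        if self.n_samples < 4:
            raise ValueError(f"n_samples must be >= 4, got {self.n_samples}")
        if not (self.mean_flow > 0):
            raise ValueError(f"mean_flow must be positive, got {self.mean_flow}")
        if not (1.0 <= self.pulsatility < 4.5):
            raise ValueError(
                f"pulsatility must be in [1, 4.5) for a non-negative waveform, "
                f"got {self.pulsatility}"
            )


def generate_inlet_waveform(spec: WaveformSpec) -> FlowWaveform:
    """Pulsatile inflow samples over one cycle with exact trapezoid mean."""
    T, n = spec.period_s, spec.n_samples
    t = np.linspace(0.0, T, n, endpoint=False)
    ts = T / 3.0  # systolic ejection window
    c = 2.0 * ts / (np.pi * T)  # mean contribution of the half-sine lobe
    qp = spec.pulsatility * spec.mean_flow
    qd = spec.mean_flow * (1.0 - c * spec.pulsatility) / (1.0 - c)
    q = np.where(t < ts, qd + (qp - qd) * np.sin(np.pi * t / ts), qd)

    if spec.pulsatility > 1.0:
        rng = np.random.default_rng(spec.seed)
        # smooth low-order multiplicative jitter (beat-shape variability)
        jitter = np.zeros(n)
        for k in (1, 2):
            jitter += rng.normal(0, 0.02) * np.sin(
                2 * np.pi * k * t / T + rng.uniform(0, 2 * np.pi)
            )
        q = np.clip(q * (1.0 + jitter), 0.0, None)

    # rescale the periodic trapezoid mean exactly to spec.mean_flow
    wf = FlowWaveform(times=t, flows=q, period_T=T)
    q *= spec.mean_flow / wf.mean_flow()
    return FlowWaveform(times=t, flows=q, period_T=T)


# ----------------------------------------------------------------- meshes


@dataclass(frozen=True)
class TubeSpec:
    """Idealized (optionally arched) fusiform tube geometry, millimeters.

    Cross-section radius at arc length s is
    ``base_radius_mm + bulge_amplitude_mm * exp(-(s - s0)^2 / (2 w^2))``
    with ``s0 = bulge_center_frac * length`` and ``w = bulge_width_mm``.
    ``arch_radius_mm`` bends the centerline into a circular arc of that
    radius (arc angle = length / radius); None keeps it straight.
    """

    length_mm: float = 20.0
    base_radius_mm: float = 0.6
    arch_radius_mm: float | None = None
    bulge_amplitude_mm: float = 0.0
    bulge_center_frac: float = 0.5
    bulge_width_mm: float = 1.0
    n_axial: int = 120
    n_circ: int = 48

    def __post_init__(self) -> None:
        if not (self.base_radius_mm > 0):
            raise ValueError("base_radius_mm must be positive")
        if not (0 <= self.bulge_center_frac <= 1):
            raise ValueError("bulge_center_frac must be in [0, 1]")
        if self.n_circ < 3:
            raise ValueError(f"n_circ must be >= 3, got {self.n_circ}")
        if self.n_axial < 2:
            raise ValueError(f"n_axial must be >= 2, got {self.n_axial}")

    def radius_at(self, s) -> np.ndarray:
        """Closed-form radius profile at arc length s (mm)."""
        s = np.asarray(s, dtype=float)
        s0 = self.bulge_center_frac * self.length_mm
        return self.base_radius_mm + self.bulge_amplitude_mm * np.exp(
            -((s - s0) ** 2) / (2.0 * self.bulge_width_mm ** 2)
        )


def generate_tube_mesh(spec: TubeSpec) -> tuple[trimesh.Trimesh, Centerline]:
    """Triangulated tube surface (open ends, outward normals) + centerline."""
    s = np.linspace(0.0, spec.length_mm, spec.n_axial)
    if spec.arch_radius_mm is None:
        centers = np.column_stack([np.zeros_like(s), np.zeros_like(s), s])
        tangents = np.tile([0.0, 0.0, 1.0], (spec.n_axial, 1))
        normals1 = np.tile([1.0, 0.0, 0.0], (spec.n_axial, 1))
    else:
        r_arch = spec.arch_radius_mm
        phi = s / r_arch  # arc angle traversed; pi for a semicircle
        centers = np.column_stack(
            [r_arch * (1.0 - np.cos(phi)), np.zeros_like(s), r_arch * np.sin(phi)]
        )
        tangents = np.column_stack([np.sin(phi), np.zeros_like(s), np.cos(phi)])
        # in-plane normal pointing away from the arc center
        normals1 = np.column_stack([-np.cos(phi), np.zeros_like(s), np.sin(phi)])
    normals2 = np.cross(tangents, normals1)

    radii = spec.radius_at(s)
    theta = np.linspace(0.0, 2.0 * np.pi, spec.n_circ, endpoint=False)
    ct, st = np.cos(theta), np.sin(theta)
    # rings: (n_axial, n_circ, 3)
    rings = (
        centers[:, None, :]
        + radii[:, None, None] * (ct[None, :, None] * normals1[:, None, :]
                                  + st[None, :, None] * normals2[:, None, :])
    )
    verts = rings.reshape(-1, 3)

    nc = spec.n_circ
    faces = []
    for i in range(spec.n_axial - 1):
        for j in range(nc):
            a = i * nc + j
            b = i * nc + (j + 1) % nc
            cidx = (i + 1) * nc + j
            d = (i + 1) * nc + (j + 1) % nc
            faces.append([a, b, d])
            faces.append([a, d, cidx])
    mesh = trimesh.Trimesh(vertices=verts, faces=np.asarray(faces), process=False)

    # enforce outward orientation: face normals should point away from the axis
    ring_idx = np.repeat(np.arange(spec.n_axial - 1), 2 * nc)
    radial = mesh.triangles_center - centers[ring_idx]
    if np.mean(np.einsum("ij,ij->i", mesh.face_normals, radial)) < 0:
        mesh.invert()

    centerline = Centerline(points=centers)
    return mesh, centerline


# -------------------------------------------------------------- WSS fields


def generate_wss_field(
    mesh: trimesh.Trimesh,
    steady_mag: float = 1.5,
    reversal_frac: float = 0.0,
    n_frames: int = 15,
    seed: int = 0,
    period_s: float = 0.12,
) -> WSSTimeSeries:
    """Tangent wall-shear vectors with controllable oscillatory content.

    Each vertex carries ``tau(t) = m_v * steady_mag * [(1 - f) e1 +
    f sin(2 pi t / T + phi_v) e2]`` in its local tangent plane (e1, e2),
    with seeded per-vertex magnitude and phase jitter.  ``reversal_frac``
    f = 0 gives time-constant vectors (OSI 0); f = 1 gives a zero vector
    time integral at every vertex (OSI 0.5).
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if not (0.0 <= reversal_frac <= 1.0):
        raise ValueError("reversal_frac must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vn = np.asarray(mesh.vertex_normals, dtype=float)
    nv = len(vn)
    # tangent frame per vertex
    ref = np.tile([0.0, 0.0, 1.0], (nv, 1))
    degenerate = np.abs(vn[:, 2]) > 0.9
    ref[degenerate] = [1.0, 0.0, 0.0]
    e1 = np.cross(vn, ref)
    e1 /= np.linalg.norm(e1, axis=1, keepdims=True)
    e2 = np.cross(vn, e1)

    mag = steady_mag * rng.uniform(0.8, 1.2, nv)
    phase = rng.uniform(0.0, 2.0 * np.pi, nv)
    times = np.linspace(0.0, period_s, n_frames, endpoint=False)
    vecs = np.empty((n_frames, nv, 3))
    for i, t in enumerate(times):
        osc = np.sin(2.0 * np.pi * t / period_s + phase)
        comp = (1.0 - reversal_frac) * e1 + reversal_frac * osc[:, None] * e2
        vecs[i] = mag[:, None] * comp
    return WSSTimeSeries(times=times, vectors=vecs, period_T=period_s, mesh=mesh)


# ------------------------------------------------------------- biaxial data


def generate_biaxial_data(
    truth: HGOParams,
    stretch_grid,
    noise_sd: float = 0.0,
    seed: int = 0,
    region: str = "ASC",
) -> BiaxialDataset:
    """Forward-model biaxial stresses plus i.i.d. Gaussian noise (kPa)."""
    grid = np.asarray(stretch_grid, dtype=float)
    if grid.ndim != 2 or grid.shape[1] != 2:
        raise ValueError("stretch_grid must be (n, 2) pairs of stretches")
    if np.any(grid <= 0):
        raise ValueError("stretches must be positive")
    lc, la = grid[:, 0], grid[:, 1]
    sc, sa = hgo_cauchy_stress(lc, la, truth)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        sc = sc + rng.normal(0.0, noise_sd, len(lc))
        sa = sa + rng.normal(0.0, noise_sd, len(la))
    return BiaxialDataset(lc, la, sc, sa, region=region)


def default_stretch_grid(n_per_protocol: int = 12) -> np.ndarray:
    """Equibiaxial plus two constant-axial protocols spanning 1.0-1.4."""
    lam = np.linspace(1.0, 1.4, n_per_protocol)
    grids = [np.column_stack([lam, lam])]
    for la_fixed in (1.1, 1.3):
        grids.append(np.column_stack([lam, np.full_like(lam, la_fixed)]))
    return np.vstack(grids)


# ------------------------------------------------------------- cohort table


@dataclass(frozen=True)
class CohortSpec:
    """Longitudinal cohort design with a metric-lifespan link.

    ``metric_effect`` is the drop in lifespan (days) per unit excess of the
    WT-normalized driver metric above 1; ``noise_sd`` the Gaussian residual
    lifespan spread.  WT mice always survive to (and are censored at) the
    administrative bound.  Defaults mirror a small two-set murine study:
    ages 1-4 months, censoring at 120 days.
    """

    n_per_group: int = 6
    ages_mo: tuple = (1, 2, 3, 4)
    metric_effect: float = 60.0  # days per normalized unit
    noise_sd: float = 15.0  # days
    censor_age_days: float = 120.0
    seed: int = 0
    metric_col: str = "max_diameter_mm"
    baseline_lifespan_days: float = 150.0

    def __post_init__(self) -> None:
        if not (self.censor_age_days > 0):
            raise ValueError("censor_age_days must be positive")
        if self.n_per_group < 1:
            raise ValueError("n_per_group must be >= 1")


_DAYS_PER_MONTH = 30.0

# WT reference trajectories (value at age a months = a0 + a1 * a), chosen to
# sit in the reported physiologic range for young mice
_WT_TRAJ = {
    "max_diameter_mm": (1.10, 0.08),
    "aer": (1.04, 0.012),
    "mean_osi": (0.045, 0.003),
    "mean_ecap": (0.030, 0.002),
}
_SEX_SHIFT = {"M": 1.05, "F": 0.95}  # males slightly larger
_METRIC_NOISE_CV = 0.03


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Per-mouse longitudinal rows with right-censored lifespans.

    MU severity is a per-mouse latent normalized excess of the driver
    metric; lifespan = baseline - metric_effect * severity + Gaussian
    noise, censored at ``censor_age_days``.  Rows exist only for ages the
    mouse survived to.  The metric excess is held constant across ages (a
    per-mouse severity level, not a progressive one) so that selecting the
    last available measurement does not couple the measured metric to the
    death age when ``metric_effect`` is zero.
    """
    rng = np.random.default_rng(spec.seed)
    rows = []
    mouse_counter = 0
    for sex in ("M", "F"):
        for genotype in ("WT", "MU"):
            for _ in range(spec.n_per_group):
                mouse_counter += 1
                mid = f"{genotype}{sex}{mouse_counter:03d}"
                if genotype == "MU":
                    severity = abs(rng.normal(0.5, 0.25))  # normalized excess at endpoint
                    lifespan = (
                        spec.baseline_lifespan_days
                        - spec.metric_effect * severity
                        + rng.normal(0.0, spec.noise_sd)
                    )
                    lifespan = max(lifespan, _DAYS_PER_MONTH * min(spec.ages_mo) + 5.0)
                else:
                    severity = 0.0
                    lifespan = 730.0  # WT natural lifespan far beyond the study
                censored = lifespan >= spec.censor_age_days
                rec_lifespan = min(lifespan, spec.censor_age_days)
                for age in spec.ages_mo:
                    if age * _DAYS_PER_MONTH > lifespan:
                        break  # no measurements after death
                    row = {
                        "mouse_id": mid,
                        "sex": sex,
                        "genotype": genotype,
                        "age_mo": age,
                        "lifespan_days": rec_lifespan,
                        "censored": int(censored),
                    }
                    for metric, (a0, a1) in _WT_TRAJ.items():
                        wt_val = (a0 + a1 * age) * _SEX_SHIFT[sex]
                        excess = severity if metric == spec.metric_col else 0.5 * severity
                        val = wt_val * (1.0 + excess)
                        val *= 1.0 + rng.normal(0.0, _METRIC_NOISE_CV)
                        row[metric] = val
                    rows.append(row)
    return pd.DataFrame(rows)


# ------------------------------------------------------------ en-face image


def generate_enface_image(
    size_px: tuple[int, int] = (256, 256),
    white_fraction: float = 0.35,
    blob_scale_px: float = 8.0,
    seed: int = 0,
) -> GrayImage:
    """Synthetic pore-highlighted en-face image with known white fraction.

    A Gaussian random field is thresholded at the quantile that leaves
    ``white_fraction`` of pixels above it, then mapped through a steep
    sigmoid centered on that cut, so thresholding the returned image at the
    generator's known cut of 0.5 recovers the requested area fraction to
    within quantile granularity.
    """
    if not (0.0 <= white_fraction <= 1.0):
        raise ValueError("white_fraction must be in [0, 1]")
    h, w = size_px
    if white_fraction == 0.0:
        return GrayImage(data=np.zeros((h, w)))
    if white_fraction == 1.0:
        return GrayImage(data=np.ones((h, w)))
    rng = np.random.default_rng(seed)
    raw = gaussian_filter(rng.normal(size=(h, w)), sigma=blob_scale_px)
    cut = np.quantile(raw, 1.0 - white_fraction)
    spread = max(np.std(raw) * 0.15, 1e-9)
    img = 1.0 / (1.0 + np.exp(-(raw - cut) / spread))
    # nudge exact-cut pixels off the 0.5 boundary so > is unambiguous
    img = np.clip(img, 1e-6, 1.0 - 1e-6)
    return GrayImage(data=img)
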