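"""Two-fiber-family Holzapfel-Gasser-Ogden (HGO) model with dispersion.

Implements the generalized-structure-tensor arterial wall model: an
incompressible neo-Hookean ground matrix of stiffness ``c`` reinforced by
two symmetric collagen fiber families at +/- ``alpha`` degrees from the
circumferential axis, with rotationally symmetric dispersion ``kappa``
(0 = perfectly aligned, 1/3 = isotropic).  The strain energy per unit
reference volume is

    Psi = c/2 (I1 - 3) + sum_{i=4,6} k1/(2 k2) [exp(k2 E_i^2) - 1],
    E_i = kappa (I1 - 3) + (1 - 3 kappa) (I_i - 1),

with the fiber term active only in tension (E_i > 0).  Planar biaxial
kinematics are used throughout: principal stretches (lambda_circ,
lambda_axial) with exact incompressibility lambda_r = 1/(lambda_circ *
lambda_axial) and plane stress through the thickness, so the Cauchy
stresses reduce to sigma_i = lambda_i * dPsi/dlambda_i.

Fitting to biaxial stress-stretch data uses bounded trust-region least
squares with seeded multi-start, since k2 and alpha are weakly
identifiable from planar protocols.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

__all__ = [
    "HGOParams",
    "BiaxialDataset",
    "hgo_cauchy_stress",
    "strain_energy",
    "incremental_modulus",
    "fit_hgo",
    "FitDiagnostics",
    "FitError",
    "REGIONS",
]

REGIONS = ("ASC", "DSC", "SAB", "IAB")


@dataclass(frozen=True)
class HGOParams:
    """HGO material parameters.

    c : kPa, isotropic matrix stiffness (shear modulus).
    k1 : kPa, fiber stiffness.
    k2 : dimensionless fiber exponent.
    kappa : dispersion, in [0, 1/3].
    alpha_deg : fiber angle from the circumferential axis, degrees in [0, 90].
    nu : Poisson ratio metadata for 3D solver hand-off; planar fitting uses
        exact incompressibility regardless.
    """

    c: float
    k1: float
    k2: float
    kappa: float
    alpha_deg: float
    nu: float = 0.49

    def __post_init__(self) -> None:
        if self.c < 0 or self.k1 < 0:
            raise ValueError("c and k1 must be non-negative")
        if not (self.k2 > 0):
            raise ValueError(f"k2 must be positive, got {self.k2}")
        if not (0 <= self.kappa <= 1 / 3 + 1e-12):
            raise ValueError(f"kappa must be in [0, 1/3], got {self.kappa}")
        if not (0 <= self.alpha_deg <= 90):
            raise ValueError(f"alpha_deg must be in [0, 90], got {self.alpha_deg}")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "HGOParams":
        return cls(**d)


@dataclass
class BiaxialDataset:
    """Planar biaxial stress-stretch records for one aortic region."""

    lambda_circ: np.ndarray
    lambda_axial: np.ndarray
    sigma_circ: np.ndarray  # kPa
    sigma_axial: np.ndarray  # kPa
    region: str = "ASC"

    def __post_init__(self) -> None:
        self.lambda_circ = np.asarray(self.lambda_circ, dtype=float)
        self.lambda_axial = np.asarray(self.lambda_axial, dtype=float)
        self.sigma_circ = np.asarray(self.sigma_circ, dtype=float)
        self.sigma_axial = np.asarray(self.sigma_axial, dtype=float)
        n = len(self.lambda_circ)
        if not (
            len(self.lambda_axial) == len(self.sigma_circ) == len(self.sigma_axial) == n
        ):
            raise ValueError("all columns must have equal length")
        if np.any(self.lambda_circ <= 0) or np.any(self.lambda_axial <= 0):
            raise ValueError("stretches must be positive")
        if not (np.all(np.isfinite(self.sigma_circ)) and np.all(np.isfinite(self.sigma_axial))):
            raise ValueError("stresses must be finite")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")

    def __len__(self) -> int:
        return len(self.lambda_circ)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "lambda_circ": self.lambda_circ,
                "lambda_axial": self.lambda_axial,
                "sigma_circ_kPa": self.sigma_circ,
                "sigma_axial_kPa": self.sigma_axial,
                "region": self.region,
            }
        )

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "BiaxialDataset":
        df = pd.read_csv(path)
        region = df["region"].iloc[0] if "region" in df else "ASC"
        return cls(
            df["lambda_circ"].to_numpy(),
            df["lambda_axial"].to_numpy(),
            df["sigma_circ_kPa"].to_numpy(),
            df["sigma_axial_kPa"].to_numpy(),
            region=str(region),
        )


def _invariants(lc, la, alpha_rad):
    """I1 and the (shared) fiber invariant I4 for planar biaxial kinematics."""
    lr2 = 1.0 / (lc * lc * la * la)
    i1 = lc * lc + la * la + lr2
    ca2 = np.cos(alpha_rad) ** 2
    sa2 = np.sin(alpha_rad) ** 2
    i4 = lc * lc * ca2 + la * la * sa2
    return i1, i4


def strain_energy(lambda_circ, lambda_axial, params: HGOParams):
    """Strain energy density (kPa) at the given biaxial state."""
    lc = np.asarray(lambda_circ, dtype=float)
    la = np.asarray(lambda_axial, dtype=float)
    alpha = np.deg2rad(params.alpha_deg)
    i1, i4 = _invariants(lc, la, alpha)
    psi = 0.5 * params.c * (i1 - 3.0)
    e = params.kappa * (i1 - 3.0) + (1.0 - 3.0 * params.kappa) * (i4 - 1.0)
    active = e > 0.0
    # two symmetric families at +/-alpha share the same invariant here
    psi_fib = np.where(
        active,
        2.0 * params.k1 / (2.0 * params.k2) * (np.exp(params.k2 * e * e) - 1.0),
        0.0,
    )
    return psi + psi_fib


def hgo_cauchy_stress(lambda_circ, lambda_axial, params: HGOParams):
    """Plane-stress Cauchy stresses (sigma_circ, sigma_axial) in kPa.

    Vectorized over stretch arrays.  The radial direction is stress-free and
    incompressibility is enforced exactly, so
    ``sigma_i = lambda_i * dPsi/dlambda_i`` with Psi expressed in the two
    in-plane stretches.
    """
    lc = np.asarray(lambda_circ, dtype=float)
    la = np.asarray(lambda_axial, dtype=float)
    if np.any(lc <= 0) or np.any(la <= 0):
        raise ValueError("stretches must be positive")
    alpha = np.deg2rad(params.alpha_deg)
    ca2 = np.cos(alpha) ** 2
    sa2 = np.sin(alpha) ** 2
    i1, i4 = _invariants(lc, la, alpha)

    di1_dlc = 2.0 * lc - 2.0 * lc ** -3 * la ** -2
    di1_dla = 2.0 * la - 2.0 * lc ** -2 * la ** -3
    di4_dlc = 2.0 * lc * ca2
    di4_dla = 2.0 * la * sa2

    e = params.kappa * (i1 - 3.0) + (1.0 - 3.0 * params.kappa) * (i4 - 1.0)
    active = e > 0.0
    # d(psi_fib)/dE summed over both families, tension-only
    g = np.where(active, 2.0 * params.k1 * e * np.exp(params.k2 * e * e), 0.0)
    de_dlc = params.kappa * di1_dlc + (1.0 - 3.0 * params.kappa) * di4_dlc
    de_dla = params.kappa * di1_dla + (1.0 - 3.0 * params.kappa) * di4_dla

    sc = lc * (0.5 * params.c * di1_dlc + g * de_dlc)
    sa = la * (0.5 * params.c * di1_dla + g * de_dla)
    if not (np.all(np.isfinite(sc)) and np.all(np.isfinite(sa))):
        bad = np.argmax(~(np.isfinite(sc) & np.isfinite(sa)))
        raise FloatingPointError(
            f"non-finite stress at stretch pair ({np.ravel(lc)[bad]}, {np.ravel(la)[bad]})"
        )
    if np.isscalar(lambda_circ) and np.isscalar(lambda_axial):
        return float(sc), float(sa)
    return sc, sa


def incremental_modulus(params: HGOParams, lambda_circ, lambda_axial):
    """Circumferential tangent modulus d(sigma_circ)/d(lambda_circ) in kPa.

    Analytic derivative of the plane-stress Cauchy stress with the axial
    stretch held fixed; this is the stiffness linearization used to
    initialize mesh elasticity at the diastolic operating point.
    """
    lc = np.asarray(lambda_circ, dtype=float)
    la = np.asarray(lambda_axial, dtype=float)
    if np.any(lc <= 0) or np.any(la <= 0):
        raise ValueError("stretches must be positive")
    alpha = np.deg2rad(params.alpha_deg)
    ca2 = np.cos(alpha) ** 2
    i1, i4 = _invariants(lc, la, alpha)

    di1 = 2.0 * lc - 2.0 * lc ** -3 * la ** -2
    d2i1 = 2.0 + 6.0 * lc ** -4 * la ** -2
    di4 = 2.0 * lc * ca2
    d2i4 = 2.0 * ca2

    k, ok = params.kappa, 1.0 - 3.0 * params.kappa
    e = k * (i1 - 3.0) + ok * (i4 - 1.0)
    de = k * di1 + ok * di4
    d2e = k * d2i1 + ok * d2i4
    active = e > 0.0
    ek = np.exp(params.k2 * e * e)
    g = np.where(active, 2.0 * params.k1 * e * ek, 0.0)
    dg_de = np.where(active, 2.0 * params.k1 * ek * (1.0 + 2.0 * params.k2 * e * e), 0.0)

    f = 0.5 * params.c * di1 + g * de
    df = 0.5 * params.c * d2i1 + dg_de * de * de + g * d2e
    mod = f + lc * df
    if np.isscalar(lambda_circ) and np.isscalar(lambda_axial):
        return float(mod)
    return mod


@dataclass
class FitDiagnostics:
    residual_norm: float
    r2_circ: float
    r2_axial: float
    n_iterations: int
    n_starts: int
    success: bool
    cost_per_start: list = field(default_factory=list)


class FitError(RuntimeError):
    """Fit failed to converge; carries the best iterate found."""

    def __init__(self, message: str, best_params: HGOParams, diagnostics: FitDiagnostics):
        super().__init__(message)
        self.best_params = best_params
        self.diagnostics = diagnostics


_DEFAULT_BOUNDS = {
    "c": (1e-6, 1e4),
    "k1": (0.0, 1e5),
    "k2": (1e-3, 500.0),
    "kappa": (0.0, 1 / 3),
    "alpha_deg": (0.0, 90.0),
}


def _r2(obs, pred):
    ss_res = float(np.sum((obs - pred) ** 2))
    ss_tot = float(np.sum((obs - np.mean(obs)) ** 2))
    if ss_tot == 0:
        return 1.0 if ss_res == 0 else 0.0
    return 1.0 - ss_res / ss_tot


def fit_hgo(
    data: BiaxialDataset,
    init: HGOParams | None = None,
    bounds: dict | None = None,
    n_starts: int = 5,
    seed: int = 0,
) -> tuple[HGOParams, FitDiagnostics]:
    """Least-squares HGO fit to biaxial Cauchy stress data.

    Minimizes the summed squared residuals of both stress directions with
    bounded trust-region least squares.  ``n_starts`` seeded random restarts
    guard against local minima in (k2, alpha).  Returns the best parameter
    set and diagnostics (residual norm, per-direction R^2).
    """
    if len(data) < 10:
        raise ValueError("need at least 10 data rows")
    if len(np.unique(np.round(data.lambda_axial, 9))) < 2:
        raise ValueError("data must span at least 2 distinct axial stretches")
    b = dict(_DEFAULT_BOUNDS)
    if bounds:
        b.update(bounds)
    keys = ("c", "k1", "k2", "kappa", "alpha_deg")
    lo = np.array([b[k][0] for k in keys])
    hi = np.array([b[k][1] for k in keys])

    obs = np.concatenate([data.sigma_circ, data.sigma_axial])
    scale = max(float(np.max(np.abs(obs))), 1.0)

    def residuals(x):
        p = HGOParams(c=x[0], k1=x[1], k2=x[2], kappa=min(x[3], 1 / 3), alpha_deg=x[4])
        sc, sa = hgo_cauchy_stress(data.lambda_circ, data.lambda_axial, p)
        return np.concatenate([sc, sa]) - obs

    rng = np.random.default_rng(seed)
    starts = []
    if init is not None:
        starts.append(
            np.array([init.c, init.k1, init.k2, init.kappa, init.alpha_deg], dtype=float)
        )
    else:
        starts.append(np.array([0.1 * scale, 0.1 * scale, 1.0, 0.1, 45.0]))
    while len(starts) < n_starts:
        starts.append(
            np.array(
                [
                    10 ** rng.uniform(-1, 2) * scale / 100,
                    10 ** rng.uniform(-1, 2) * scale / 100,
                    10 ** rng.uniform(-1, 1.5),
                    rng.uniform(0, 1 / 3),
                    rng.uniform(5, 85),
                ]
            )
        )

    best = None
    costs = []
    total_nfev = 0
    for x0 in starts:
        x0c = np.clip(x0, lo + 1e-12, hi - 1e-12)
        try:
            res = least_squares(
                residuals, x0c, bounds=(lo, hi), method="trf",
                xtol=1e-14, ftol=1e-14, gtol=1e-14, max_nfev=2000,
            )
        except FloatingPointError:
            continue
        costs.append(float(res.cost))
        total_nfev += int(res.nfev)
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitError(
            "all starts failed",
            HGOParams(c=1.0, k1=1.0, k2=1.0, kappa=0.0, alpha_deg=45.0),
            FitDiagnostics(np.inf, 0.0, 0.0, total_nfev, len(starts), False, costs),
        )

    x = best.x
    params = HGOParams(c=x[0], k1=x[1], k2=x[2], kappa=min(x[3], 1 / 3), alpha_deg=x[4])
    sc, sa = hgo_cauchy_stress(data.lambda_circ, data.lambda_axial, params)
    diag = FitDiagnostics(
        residual_norm=float(np.sqrt(2.0 * best.cost)),
        r2_circ=_r2(data.sigma_circ, sc),
        r2_axial=_r2(data.sigma_axial, sa),
        n_iterations=total_nfev,
        n_starts=len(starts),
        success=bool(best.success),
        cost_per_start=costs,
    )
    if not best.success:
        raise FitError("least_squares did not converge", params, diag)
    return params, diag


def save_params(params_by_key: dict[str, HGOParams], path: str | Path) -> None:
    """Serialize fitted parameter sets keyed by e.g. 'age/sex/genotype/region'."""
    Path(path).write_text(
        json.dumps({k: p.to_dict() for k, p in params_by_key.items()}, indent=2)
    )


def load_params(path: str | Path) -> dict[str, HGOParams]:
    raw = json.loads(Path(path).read_text())
    return {k: HGOParams.from_dict(v) for k, v in raw.items()}
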