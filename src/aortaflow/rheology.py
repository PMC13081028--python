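"""Shear-thinning blood rheology (Carreau-Yasuda model).

Blood is modeled as a generalized Newtonian fluid whose apparent viscosity
falls from a zero-shear plateau ``eta_0`` to an infinite-shear plateau
``eta_inf`` through a power-law transition::

    eta(gdot) = eta_inf + (eta_0 - eta_inf) * [1 + (lam*gdot)**a]**((n-1)/a)

with time constant ``lam`` (s), Yasuda transition exponent ``a`` and
power-law index ``n``.  Viscosities are carried in centipoise (cP), the unit
blood rheometry is reported in; conversion helpers to SI are provided.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np

__all__ = [
    "CarreauYasudaParams",
    "BLOOD",
    "apparent_viscosity",
    "cp_to_pa_s",
    "pa_s_to_cp",
]


@dataclass(frozen=True)
class CarreauYasudaParams:
    """Carreau-Yasuda parameter set.

    Parameters
    ----------
    eta_inf : float
        Infinite-shear viscosity plateau (cP).
    eta_0 : float
        Zero-shear viscosity plateau (cP).
    lam : float
        Relaxation time constant (s); makes ``lam * shear_rate`` dimensionless.
    a : float
        Yasuda exponent controlling the sharpness of the transition.
    n : float
        Power-law index, ``0 < n <= 1`` for shear thinning.
    """

    eta_inf: float
    eta_0: float
    lam: float
    a: float
    n: float

    def __post_init__(self) -> None:
        if not (self.eta_inf > 0):
            raise ValueError(f"eta_inf must be positive, got {self.eta_inf}")
        if self.eta_0 < self.eta_inf:
            raise ValueError(
                f"eta_0 ({self.eta_0}) must be >= eta_inf ({self.eta_inf})"
            )
        if not (self.lam > 0):
            raise ValueError(f"lam must be positive, got {self.lam}")
        if not (self.a > 0):
            raise ValueError(f"a must be positive, got {self.a}")
        if not (0 < self.n <= 1):
            raise ValueError(f"n must be in (0, 1], got {self.n}")

    @classmethod
    def from_dict(cls, d: dict) -> "CarreauYasudaParams":
        return cls(**{k: float(d[k]) for k in ("eta_inf", "eta_0", "lam", "a", "n")})

    @classmethod
    def from_json(cls, path: str | Path) -> "CarreauYasudaParams":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def to_dict(self) -> dict:
        return asdict(self)


#: Healthy-blood parameter set (eta_inf=2 cP, eta_0=11 cP, lam=1.5 s,
#: a=0.2, n=0.71), the default used throughout the package.
BLOOD = CarreauYasudaParams(eta_inf=2.0, eta_0=11.0, lam=1.5, a=0.2, n=0.71)


def apparent_viscosity(shear_rate, params: CarreauYasudaParams = BLOOD):
    """Apparent viscosity (cP) at the given shear rate(s) (1/s).

    Accepts scalars or arrays; shear rates must be non-negative.  The result
    is monotone non-increasing in shear rate and bounded in
    ``[eta_inf, eta_0]``.
    """
    gdot = np.asarray(shear_rate, dtype=float)
    if np.any(gdot < 0):
        raise ValueError("shear_rate must be non-negative")
    bracket = 1.0 + (params.lam * gdot) ** params.a
    eta = params.eta_inf + (params.eta_0 - params.eta_inf) * bracket ** (
        (params.n - 1.0) / params.a
    )
    if np.isscalar(shear_rate):
        return float(eta)
    return eta


def cp_to_pa_s(eta_cp):
    """Convert centipoise to Pa*s (1 cP = 1e-3 Pa*s)."""
    return np.asarray(eta_cp, dtype=float) * 1e-3


def pa_s_to_cp(eta_pa_s):
    """Convert Pa*s to centipoise."""
    return np.asarray(eta_pa_s, dtype=float) * 1e3
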