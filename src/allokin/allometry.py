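"""Deterministic allometric scaling relations for microbial uptake kinetics.

The chain of relations implemented here links cell volume ``V_cell`` (um^3)
to the Michaelis-Menten uptake parameters:

* ``V_max = a * V_cell**b``           (cell-specific maximum uptake rate)
* ``K_m   = c * V_max**d``            (half-saturation / affinity trade-off)
* ``w     = alpha * V_cell**beta``    (dry weight per cell, empirical)

Dividing ``V_max`` by ``w`` gives the dry-weight-specific rate

* ``V_maxDW = (a/alpha) * V_cell**(b-beta)``

and, folding the weight factor into a compound prefactor ``c_bar = c*w**d``,

* ``K_m = c_bar * V_maxDW**d = c_bar * ((a/alpha) * V_cell**(b-beta))**d``

All quantities use canonical units: mol, g dry weight (DW), litres, hours
and um^3.  ``a`` is stored in mol S cell^-1 h^-1 per um^(3b).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "AllometryConstants",
    "ScalingParams",
    "TransporterModel",
    "DegenerateMapError",
    "michaelis_menten_rate",
    "transporter_kinetics",
    "weight_from_volume",
    "volume_from_weight",
    "vmaxdw_from_volume",
    "km_from_volume",
    "volume_from_vmaxdw",
    "volume_from_km",
    "expected_vmaxdw_exponent",
    "MECHANISTIC_B",
    "MECHANISTIC_D",
    "LITCHMAN_B",
    "LITCHMAN_D",
]

# Reference exponents from the phototroph literature: the transporter-limited
# mechanistic expectation (b = 2/3 from surface-area scaling, d = 1/2) and the
# empirical phytoplankton nitrate-uptake fits (b = 0.67, d = 0.357).
MECHANISTIC_B = 2.0 / 3.0
MECHANISTIC_D = 0.5
LITCHMAN_B = 0.67
LITCHMAN_D = 0.357


class DegenerateMapError(ValueError):
    """Raised when a scaling map has no inverse (b == beta) or collapses."""


@dataclass(frozen=True)
class AllometryConstants:
    """Empirical dry weight-volume constants: ``w = alpha * V_cell**beta``.

    Defaults are the cross-taxa fit ``alpha = 10**-12.244`` g per um^(3*beta)
    and ``beta = 0.920``.
    """

    alpha: float = 10.0 ** -12.244
    beta: float = 0.920

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ValueError(f"alpha must be positive, got {self.alpha}")
        if not 0 < self.beta <= 1.5:
            raise ValueError(f"beta must be in (0, 1.5], got {self.beta}")

    @property
    def log_alpha(self) -> float:
        return math.log(self.alpha)


@dataclass(frozen=True)
class ScalingParams:
    """The inferred quadruple (a, b, c_bar, d).

    a      : prefactor of V_max = a * V_cell**b  [mol S cell^-1 h^-1 um^-3b]
    b      : volume exponent of V_max (dimensionless)
    c_bar  : compound prefactor c*w**d of the K_m relation [mol S L^-1]
    d      : trade-off exponent of K_m vs V_maxDW (dimensionless)
    """

    a: float
    b: float
    c_bar: float
    d: float

    def __post_init__(self) -> None:
        if not self.a > 0:
            raise ValueError(f"prefactor a must be positive, got {self.a}")
        if not self.c_bar > 0:
            raise ValueError(f"prefactor c_bar must be positive, got {self.c_bar}")

    def as_array(self) -> np.ndarray:
        return np.array([self.a, self.b, self.c_bar, self.d], dtype=float)

    @classmethod
    def from_array(cls, arr) -> "ScalingParams":
        a, b, c_bar, d = (float(v) for v in arr)
        return cls(a=a, b=b, c_bar=c_bar, d=d)

    names = ("a", "b", "c_bar", "d")


#: Posterior-mean estimates for the chemotroph compilation, used as the
#: default truth in synthetic-data experiments.
POSTERIOR_MEAN_PARAMS = ScalingParams(a=4.64e-15, b=2.70, c_bar=1.83e-2, d=1.254)


@dataclass(frozen=True)
class TransporterModel:
    """Transporter-limited uptake for a spherical cell.

    h  : handling time per ion (h)
    n0 : transporter site density (sites um^-2)
    r  : cell radius (um)
    A  : area of one uptake site (um^2)
    D  : molecular diffusion coefficient (um^2 h^-1)
    """

    h: float
    n0: float
    r: float
    A: float
    D: float

    def __post_init__(self) -> None:
        for name in ("h", "n0", "r", "A", "D"):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")

    @property
    def cell_volume(self) -> float:
        """Spherical cell volume 4*pi*r^3/3 in um^3."""
        return 4.0 * math.pi * self.r ** 3 / 3.0


def michaelis_menten_rate(vmax, km, s):
    """Michaelis-Menten uptake rate ``vmax * s / (km + s)``.

    Parameters are broadcast; `s` may be an array.  The rate is bounded in
    [0, vmax), equals vmax/2 at s = km, and is 0 at s = 0.
    """
    vmax = np.asarray(vmax, dtype=float)
    km = np.asarray(km, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(vmax <= 0):
        raise ValueError("vmax must be positive")
    if np.any(km <= 0):
        raise ValueError("km must be positive")
    if np.any(s < 0):
        raise ValueError("substrate concentration s must be non-negative")
    out = vmax * s / (km + s)
    return out if out.ndim else float(out)


def transporter_kinetics(tm: TransporterModel) -> tuple[float, float]:
    """Cell-specific (V_max, K_m) of the transporter-limited model.

    V_max = n0 * 4*pi*r^2 / h   (mol S cell^-1 h^-1, up to the site->mol map)
    K_m   = A * r / (h * D)     (concentration up to the boundary unit map)

    Doubling the radius quadruples V_max (surface area) and doubles K_m.
    """
    vmax = tm.n0 * 4.0 * math.pi * tm.r ** 2 / tm.h
    km = tm.A * tm.r / (tm.h * tm.D)
    return vmax, km


def _require_positive(x, name: str):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or not np.all(np.isfinite(x)):
        raise ValueError(f"{name} must be positive and finite")
    return x


def weight_from_volume(vcell, constants: AllometryConstants = AllometryConstants()):
    """Dry weight per cell (g) from cell volume (um^3): ``w = alpha*V**beta``."""
    vcell = _require_positive(vcell, "vcell")
    out = constants.alpha * vcell ** constants.beta
    return out if out.ndim else float(out)


def volume_from_weight(w, constants: AllometryConstants = AllometryConstants()):
    """Cell volume (um^3) from dry weight per cell (g); exact inverse."""
    w = _require_positive(w, "w")
    out = (w / constants.alpha) ** (1.0 / constants.beta)
    return out if out.ndim else float(out)


def vmaxdw_from_volume(
    vcell,
    params: ScalingParams,
    constants: AllometryConstants = AllometryConstants(),
):
    """Dry-weight-specific maximum uptake rate (mol S g^-1 DW h^-1).

    ``V_maxDW = (a/alpha) * V_cell**(b - beta)``
    """
    vcell = _require_positive(vcell, "vcell")
    out = (params.a / constants.alpha) * vcell ** (params.b - constants.beta)
    return out if out.ndim else float(out)


def km_from_volume(
    vcell,
    params: ScalingParams,
    constants: AllometryConstants = AllometryConstants(),
):
    """Half-saturation constant (mol S L^-1) from cell volume.

    ``K_m = c_bar * V_maxDW**d`` with V_maxDW given by its volume scaling,
    so exactly the composition km = c_bar * vmaxdw_from_volume(v)**d.
    """
    v = vmaxdw_from_volume(vcell, params, constants)
    out = params.c_bar * np.asarray(v, dtype=float) ** params.d
    return out if np.ndim(out) else float(out)


def volume_from_vmaxdw(
    vmax_dw,
    params: ScalingParams,
    constants: AllometryConstants = AllometryConstants(),
):
    """Back-predict cell volume (um^3) from V_maxDW; inverse power law.

    Raises :class:`DegenerateMapError` when b == beta (the map is constant).
    """
    vmax_dw = _require_positive(vmax_dw, "vmax_dw")
    if params.b == constants.beta:
        raise DegenerateMapError(
            "b equals beta: V_maxDW does not depend on cell volume, no inverse"
        )
    out = (vmax_dw * constants.alpha / params.a) ** (1.0 / (params.b - constants.beta))
    return out if out.ndim else float(out)


def volume_from_km(
    km,
    params: ScalingParams,
    constants: AllometryConstants = AllometryConstants(),
):
    """Back-predict cell volume (um^3) from K_m via the composed power law."""
    km = _require_positive(km, "km")
    if params.d == 0:
        raise DegenerateMapError("d == 0: K_m does not depend on V_maxDW, no inverse")
    vmax_dw = (km / params.c_bar) ** (1.0 / params.d)
    return volume_from_vmaxdw(vmax_dw, params, constants)


def expected_vmaxdw_exponent(
    constants: AllometryConstants = AllometryConstants(),
) -> float:
    """Mechanistic expectation for the exponent of V_maxDW vs V_cell.

    Transporter-limited uptake on a spherical cell gives V_max ~ V_cell^(2/3);
    dividing by w ~ V_cell^beta gives exponent 2/3 - beta (about -0.25 at the
    default beta = 0.920).
    """
    return MECHANISTIC_B - constants.beta
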