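"""Blood constitutive model: Carreau shear-thinning viscosity.

Blood is modeled as an incompressible generalized-Newtonian fluid whose
apparent viscosity decreases with shear rate following the Carreau law

    eta(gamma) = eta_inf + (eta_0 - eta_inf) * [1 + (gamma*lambda)^2]^((n-1)/2)

with zero-shear viscosity ``eta_0``, infinite-shear viscosity ``eta_inf``,
relaxation time ``lambda`` and power index ``n``.  Setting
``eta_0 == eta_inf`` recovers a Newtonian fluid of that viscosity, which
every downstream solve honors bit-for-bit in the viscosity field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DimensionError, InvalidInputError

#: Default blood constants (SI units).
DEFAULT_DENSITY = 1060.0  # kg/m^3
DEFAULT_ETA0 = 0.033  # Pa s, zero-shear viscosity
DEFAULT_ETA_INF = 0.006109  # Pa s, infinite-shear viscosity
DEFAULT_LAMBDA = 3.34  # s, Carreau time constant
DEFAULT_N = 0.3035  # dimensionless power index


@dataclass(frozen=True)
class CarreauParams:
    """Carreau parameters plus density for one blood analogue.

    Invariants: ``eta0 > eta_inf > 0``, ``lam > 0``, ``0 < n < 1``,
    ``density > 0``.  A Newtonian fluid is expressed with
    :meth:`newtonian`, which relaxes the strict ``eta0 > eta_inf``
    ordering to equality.
    """

    eta0: float = DEFAULT_ETA0
    eta_inf: float = DEFAULT_ETA_INF
    lam: float = DEFAULT_LAMBDA
    n: float = DEFAULT_N
    density: float = DEFAULT_DENSITY

    def __post_init__(self) -> None:
        if not all(np.isfinite([self.eta0, self.eta_inf, self.lam, self.n, self.density])):
            raise InvalidInputError("Carreau parameters must be finite")
        if self.eta_inf <= 0 or self.eta0 < self.eta_inf:
            raise InvalidInputError(
                f"require eta0 >= eta_inf > 0, got eta0={self.eta0}, eta_inf={self.eta_inf}"
            )
        if self.lam <= 0:
            raise InvalidInputError(f"time constant must be positive, got {self.lam}")
        if not 0 < self.n < 1:
            raise InvalidInputError(f"power index must lie in (0, 1), got {self.n}")
        if self.density <= 0:
            raise InvalidInputError(f"density must be positive, got {self.density}")

    @property
    def is_newtonian(self) -> bool:
        return self.eta0 == self.eta_inf

    @classmethod
    def newtonian(cls, viscosity: float, density: float = DEFAULT_DENSITY) -> "CarreauParams":
        """Constant-viscosity fluid expressed in the same parameter set."""
        if viscosity <= 0:
            raise InvalidInputError(f"viscosity must be positive, got {viscosity}")
        return cls(eta0=viscosity, eta_inf=viscosity, lam=DEFAULT_LAMBDA, n=DEFAULT_N,
                   density=density)


def carreau_viscosity(shear_rate, params: CarreauParams):
    """Apparent viscosity eta(gamma) in Pa s.

    ``shear_rate`` is a nonnegative scalar or array of shear-rate
    magnitudes in 1/s; callers pass ``abs(gamma)``.  The result is
    continuous, bounded in ``(eta_inf, eta0]`` and monotone
    non-increasing in gamma.
    """
    gamma = np.asarray(shear_rate, dtype=float)
    if not np.all(np.isfinite(gamma)):
        raise InvalidInputError("shear rate must be finite")
    if np.any(gamma < 0):
        raise InvalidInputError("shear rate magnitude must be nonnegative")
    eta = params.eta_inf + (params.eta0 - params.eta_inf) * (
        1.0 + (gamma * params.lam) ** 2
    ) ** ((params.n - 1.0) / 2.0)
    if np.isscalar(shear_rate):
        return float(eta)
    return eta


def shear_rate_magnitude(u, v, w, dx: float):
    """Second-invariant shear-rate magnitude gamma = sqrt(2 D:D) at cell centers.

    ``u, v, w`` are MAC face-velocity arrays of shapes
    ``(nx+1,ny,nz)``, ``(nx,ny+1,nz)``, ``(nx,ny,nz+1)``; the strain-rate
    tensor D is evaluated with central differences, off-diagonal
    components averaged from cell edges to centers.
    """
    u = np.asarray(u, float)
    v = np.asarray(v, float)
    w = np.asarray(w, float)
    nx, ny, nz = u.shape[0] - 1, v.shape[1] - 1, w.shape[2] - 1
    if v.shape != (nx, ny + 1, nz) or w.shape != (nx, ny, nz + 1):
        raise DimensionError(
            f"inconsistent MAC shapes: u{u.shape} v{v.shape} w{w.shape}"
        )

    # diagonal components at centers
    dudx = (u[1:, :, :] - u[:-1, :, :]) / dx
    dvdy = (v[:, 1:, :] - v[:, :-1, :]) / dx
    dwdz = (w[:, :, 1:] - w[:, :, :-1]) / dx

    def _edge_to_center(arr, axis):
        # average an (n+1)-sized axis down to n
        sl_lo = [slice(None)] * 3
        sl_hi = [slice(None)] * 3
        sl_lo[axis] = slice(None, -1)
        sl_hi[axis] = slice(1, None)
        return 0.5 * (arr[tuple(sl_lo)] + arr[tuple(sl_hi)])

    def _center(arr, axes):
        for ax in axes:
            arr = _edge_to_center(arr, ax)
        return arr

    # off-diagonal: gradients live on cell edges; average back to centers.
    dudy = np.gradient(u, dx, axis=1)
    dudz = np.gradient(u, dx, axis=2)
    dvdx = np.gradient(v, dx, axis=0)
    dvdz = np.gradient(v, dx, axis=2)
    dwdx = np.gradient(w, dx, axis=0)
    dwdy = np.gradient(w, dx, axis=1)

    dudy = _center(dudy, (0,))
    dudz = _center(dudz, (0,))
    dvdx = _center(dvdx, (1,))
    dvdz = _center(dvdz, (1,))
    dwdx = _center(dwdx, (2,))
    dwdy = _center(dwdy, (2,))

    dxy = 0.5 * (dudy + dvdx)
    dxz = 0.5 * (dudz + dwdx)
    dyz = 0.5 * (dvdz + dwdy)

    dd = (dudx**2 + dvdy**2 + dwdz**2 + 2.0 * (dxy**2 + dxz**2 + dyz**2))
    return np.sqrt(2.0 * dd)


def effective_viscosity_field(u, v, w, dx: float, params: CarreauParams,
                              fluid_mask=None):
    """Per-cell apparent viscosity from the local shear-rate magnitude.

    Applies the Carreau law to ``sqrt(2 D:D)`` of the discrete
    strain-rate tensor.  Cells outside ``fluid_mask`` (if given) are set
    to ``eta0`` (value is irrelevant there; walls enforce no-slip).
    """
    if params.is_newtonian:
        nx, ny, nz = np.asarray(u).shape[0] - 1, np.asarray(v).shape[1] - 1, \
            np.asarray(w).shape[2] - 1
        return np.full((nx, ny, nz), params.eta0)
    gamma = shear_rate_magnitude(u, v, w, dx)
    eta = carreau_viscosity(gamma, params)
    if fluid_mask is not None:
        if fluid_mask.shape != eta.shape:
            raise DimensionError(
                f"mask shape {fluid_mask.shape} != field shape {eta.shape}"
            )
        eta = np.where(fluid_mask, eta, params.eta0)
    return eta
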