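"""Numerical steady-state solver for the surface-driven diffusion problem.

The continuum model is Laplace's equation D∇²c = 0 in a 2D rectangle
(x across the light-dark border, z into the gel), with all of the chemistry
living on the cell layer at z = 0:

    −D ∂c/∂z |_{z=0} = r·ρ_α·production(x) − Ω·ρ_A·uptake(x)·c(x, 0)

i.e. a flux (Robin) boundary condition combining surface production and
surface uptake, plus an optional Dirichlet clamp c = 0 where a perfect sink
(saturating Bar1 degradation) is active. The remaining three sides are
no-flux walls, which mirrors the finite experimental chamber and reproduces
the reflective-border artifacts seen near the domain edges.

The discretization is a 5-point Laplacian on a node-centered grid with
ghost-node elimination for the flux boundaries; the resulting sparse linear
system is solved directly. This solver is the brute-force oracle for the
closed-form infinite-domain surface profiles and the only route to
finite-size and z > 0 behavior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import spsolve

from .profiles import PhysicalParams

__all__ = [
    "DomainGeometry",
    "SurfaceMasks",
    "ConcentrationField",
    "solve_steady",
    "surface_slice",
    "transition_sharpness",
    "flux_balance",
]

MaskFn = Callable[[np.ndarray], np.ndarray]


@dataclass(frozen=True)
class DomainGeometry:
    """Finite rectangular domain: stripe length L_x, gel thickness L_z, grid
    spacings dx, dz (all μm). x spans [−L_x/2, +L_x/2] with the border at 0;
    z spans [0, L_z] with the cell layer at z = 0.

    The default gel thickness ~2,600 μm corresponds to 0.5 cm³ of agarose
    spread over a 1.554-cm-diameter well.
    """

    L_x: float
    L_z: float = 2600.0
    dx: float = 10.0
    dz: float = 10.0

    def __post_init__(self) -> None:
        for name in ("L_x", "L_z", "dx", "dz"):
            if not getattr(self, name) > 0:
                raise ValueError(f"DomainGeometry.{name} must be strictly positive")
        if self.nx < 16 or self.nz < 16:
            raise ValueError("grid must have at least 16 nodes per dimension")

    @property
    def nx(self) -> int:
        return max(int(round(self.L_x / self.dx)), 1)

    @property
    def nz(self) -> int:
        return int(round(self.L_z / self.dz)) + 1

    @property
    def x(self) -> np.ndarray:
        # cell-centered in x: a half-domain indicator mask then changes value
        # exactly at x = 0 (the cell edge), matching the continuum border
        return -self.L_x / 2.0 + self.dx * (np.arange(self.nx) + 0.5)

    @property
    def z(self) -> np.ndarray:
        # node-centered in z: the cell layer z = 0 is the first grid row
        return np.linspace(0.0, self.L_z, self.nz)


def _indicator(fn: MaskFn, x: np.ndarray) -> np.ndarray:
    out = np.asarray(fn(x), dtype=float)
    if out.shape != x.shape:
        raise ValueError("mask function must return one value per x node")
    if not np.all((out == 0.0) | (out == 1.0)):
        raise ValueError("mask functions must be {0,1}-valued indicators")
    return out


@dataclass(frozen=True)
class SurfaceMasks:
    """Indicator functions of x selecting where each surface process acts.

    ``production`` marks where emitters inject flux (rate r·ρ_α),
    ``uptake`` where receivers absorb (rate Ω·ρ_A·c), and ``dirichlet_sink``
    where the concentration is clamped to zero (perfect-sink mode). The sink
    overrides the other two wherever active.

    The perfect-sink clamp acts through the full gel depth above the marked
    surface region, i.e. the concentration vanishes on the whole boundary of
    the sink domain. This is the idealization behind the closed-form sink
    profile (the odd reflection of the source solution, g = 2f − 1): nothing
    escapes over the top of a perfect sink. Clamping only the z = 0 line
    would let pheromone diffuse across the border through the bulk and gives
    a measurably different (≈15% higher) surface profile.
    """

    production: MaskFn
    uptake: MaskFn
    dirichlet_sink: MaskFn = field(default=lambda x: np.zeros_like(x))

    @classmethod
    def homogeneous(cls) -> "SurfaceMasks":
        """Production and uptake everywhere — flux balance gives a constant."""
        ones = lambda x: np.ones_like(x)
        return cls(production=ones, uptake=ones)

    @classmethod
    def half_source(cls) -> "SurfaceMasks":
        """Production on x < 0, uptake everywhere (source geometry)."""
        return cls(
            production=lambda x: (x < 0).astype(float),
            uptake=lambda x: np.ones_like(x),
        )

    @classmethod
    def half_sink(cls) -> "SurfaceMasks":
        """Production everywhere, perfect sink on x > 0 (Bar1 geometry)."""
        return cls(
            production=lambda x: np.ones_like(x),
            uptake=lambda x: np.ones_like(x),
            dirichlet_sink=lambda x: (x > 0).astype(float),
        )


@dataclass(frozen=True)
class ConcentrationField:
    """Steady-state concentration on the (z, x) grid, plus its geometry.

    ``c[j, i]`` is the concentration at z = geometry.z[j], x = geometry.x[i],
    in the amplitude units of the physical parameters (r·ρ_α/(Ω·ρ_A) sets
    the natural scale).
    """

    c: np.ndarray
    geometry: DomainGeometry

    def __post_init__(self) -> None:
        if self.c.shape != (self.geometry.nz, self.geometry.nx):
            raise ValueError("field shape does not match geometry grid")

    def to_table(self):
        """Long-format (x, z, c) table of the full field."""
        import pandas as pd

        xx, zz = np.meshgrid(self.geometry.x, self.geometry.z)
        return pd.DataFrame(
            {"x_um": xx.ravel(), "z_um": zz.ravel(), "c": self.c.ravel()}
        )


def solve_steady(
    geometry: DomainGeometry,
    phys: PhysicalParams,
    masks: SurfaceMasks,
    tol: float = 1e-10,
) -> ConcentrationField:
    """Solve the discrete steady state and return the concentration field.

    Raises ``RuntimeError`` with the residual if the direct solve does not
    meet ``tol`` on the relative residual; warns if the x-resolution is
    coarser than λ/5.
    """
    lam = phys.decay_length
    if geometry.dx > lam / 5.0:
        warnings.warn(
            f"dx = {geometry.dx:g} μm is coarse relative to the decay length "
            f"λ = {lam:g} μm (recommend dx <= λ/5)",
            stacklevel=2,
        )

    nx, nz = geometry.nx, geometry.nz
    dx2, dz2 = geometry.dx ** 2, geometry.dz ** 2
    x = geometry.x
    prod = _indicator(masks.production, x)
    upt = _indicator(masks.uptake, x)
    sink = _indicator(masks.dirichlet_sink, x).astype(bool)

    S = phys.r * phys.rho_alpha * prod          # injected flux density
    k = phys.Omega * phys.rho_A * upt           # uptake rate density

    n_unknown = nx * nz
    rows, cols, vals = [], [], []
    b = np.zeros(n_unknown)

    def idx(j: int, i: int) -> int:
        return j * nx + i

    def add(j, i, jj, ii, v):
        rows.append(idx(j, i))
        cols.append(idx(jj, ii))
        vals.append(v)

    for j in range(nz):
        for i in range(nx):
            if sink[i]:
                add(j, i, j, i, 1.0)            # Dirichlet clamp c = 0
                continue

            diag = 0.0
            # x-direction; cell-centered no-flux walls reflect the boundary
            # cell onto itself (zero flux through the wall face)
            if i > 0:
                add(j, i, j, i - 1, 1.0 / dx2)
                diag -= 1.0 / dx2
            if i < nx - 1:
                add(j, i, j, i + 1, 1.0 / dx2)
                diag -= 1.0 / dx2

            # z-direction
            if j == 0:
                # Robin boundary via ghost elimination:
                # c_ghost = c_1 + (2 dz / D) (S_i − k_i c_0)
                add(j, i, j + 1, i, 2.0 / dz2)
                diag -= 2.0 / dz2
                diag -= 2.0 * k[i] / (phys.D * geometry.dz)
                b[idx(j, i)] = -2.0 * S[i] / (phys.D * geometry.dz)
            elif j == nz - 1:
                add(j, i, j - 1, i, 2.0 / dz2)  # mirror ghost (no-flux top)
                diag -= 2.0 / dz2
            else:
                add(j, i, j - 1, i, 1.0 / dz2)
                add(j, i, j + 1, i, 1.0 / dz2)
                diag -= 2.0 / dz2
            add(j, i, j, i, diag)

    A = sp.csr_matrix((vals, (rows, cols)), shape=(n_unknown, n_unknown))
    c_flat = spsolve(A, b)

    b_norm = np.linalg.norm(b)
    if b_norm > 0:
        residual = np.linalg.norm(A @ c_flat - b) / b_norm
        if not np.isfinite(residual) or residual > tol:
            raise RuntimeError(
                f"steady-state solve did not converge: relative residual "
                f"{residual:.3e} exceeds tolerance {tol:.1e}"
            )

    return ConcentrationField(c=c_flat.reshape(nz, nx), geometry=geometry)


def surface_slice(field: ConcentrationField) -> np.ndarray:
    """Concentration along the cell layer c(x, z = 0)."""
    return field.c[0].copy()


def transition_sharpness(field: ConcentrationField, z_values) -> np.ndarray:
    """Magnitude of the border slope |∂c/∂x| at x = 0 for each requested z.

    Uses a centered difference at the grid node nearest x = 0. The sequence
    decreases with z: the transition is sharpest at the cell layer and
    smooths out into the gel.
    """
    geo = field.geometry
    z_arr = np.atleast_1d(np.asarray(z_values, dtype=float))
    if np.any(z_arr < 0) or np.any(z_arr > geo.L_z):
        raise ValueError("z values must lie within [0, L_z]")
    ir = int(np.searchsorted(geo.x, 0.0))
    il = ir - 1
    if il < 0 or ir > geo.nx - 1:
        raise ValueError("x = 0 is too close to the domain edge for a centered slope")
    slopes = np.empty_like(z_arr)
    for m, z in enumerate(z_arr):
        j = int(np.argmin(np.abs(geo.z - z)))
        slopes[m] = abs(field.c[j, ir] - field.c[j, il]) / (geo.x[ir] - geo.x[il])
    return slopes


def flux_balance(field: ConcentrationField, phys: PhysicalParams,
                 masks: SurfaceMasks) -> dict:
    """Steady-state surface flux bookkeeping (per unit stripe width).

    Returns production, uptake and sink fluxes; at steady state production
    balances uptake + sink. Production on perfect-sink columns never enters
    the solved system (it is degraded on the spot) and is excluded.
    """
    geo = field.geometry
    x = geo.x
    prod = _indicator(masks.production, x)
    upt = _indicator(masks.uptake, x)
    sink = _indicator(masks.dirichlet_sink, x).astype(bool)
    c0 = field.c[0]

    production = float(np.sum(phys.r * phys.rho_alpha * prod[~sink]) * geo.dx)
    uptake = float(
        np.sum(phys.Omega * phys.rho_A * upt[~sink] * c0[~sink]) * geo.dx
    )
    # flux into the sink through the vertical absorbing interface(s):
    # D ∂c/∂x integrated over z (trapezoid in z), summed over every
    # non-sink column adjacent to a sink column
    sink_flux = 0.0
    wz = np.full(geo.nz, geo.dz)
    wz[0] = wz[-1] = geo.dz / 2.0
    for i in np.flatnonzero(~sink):
        for ii in (i - 1, i + 1):
            if 0 <= ii < geo.nx and sink[ii]:
                sink_flux += float(
                    np.sum(phys.D * field.c[:, i] / geo.dx * wz)
                )
    return {"production": production, "uptake": uptake, "sink": sink_flux}
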