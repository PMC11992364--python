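"""Closed-form steady-state pheromone gradient profiles and response functions.

A monolayer of surface-attached yeast cells sits under a thick hydrogel.
Pheromone (α-factor) is produced at rate ``r`` per emitter cell on part of the
surface, diffuses with coefficient ``D`` through the gel, and is removed at
the surface by receiver-cell uptake with per-cell rate parameter ``Omega``.
At steady state the surface concentration depends on a single length scale

    λ = D / (Ω · ρ_A)          (decay length, μm)

and a single amplitude

    c_far = r · ρ_α / (Ω · ρ_A)   (far-field concentration in the
                                   production domain)

Two geometries are covered:

* **source** — production restricted to the half plane x < 0, uptake
  everywhere. The normalized surface profile ``f(x)`` interpolates from 1
  (deep in the production domain) to 0 with a heavy ~λ/(πx) tail, crossing
  exactly 1/2 at the light-dark border x = 0.
* **sink** — production everywhere, but the half plane x > 0 degrades the
  ligand perfectly (concentration clamped to zero there, e.g. by the Bar1
  protease). For x < 0 the profile is ``g(x) = 2 f(x) − 1``.

Both closed forms are combinations of the sine and cosine integrals Si/Ci.
Downstream, cellular readouts are modeled as a Hill function of the local
concentration expressed in EC50 units (the concentration giving the
half-maximal gene-expression response), scaled by an amplitude ``A`` and
offset by a baseline ``b``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import sici

__all__ = [
    "PhysicalParams",
    "GradientShape",
    "ResponseParams",
    "si_ci",
    "source_profile",
    "sink_profile",
    "concentration",
    "hill_response",
    "observed_response",
    "normalize_max",
    "border_gradient",
]

# |x|/λ below this uses the analytic border limits (f = 1/2, g = 0):
# sin(u)·Ci(u) has a removable singularity at u = 0 that the direct
# expression cannot evaluate.
_NEAR_ZERO = 1e-8


# ---------------------------------------------------------------------------
# parameter containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PhysicalParams:
    """Microscopic rates and surface densities of the reaction-diffusion model.

    Parameters
    ----------
    D : float
        Pheromone diffusion coefficient in the gel (μm²/s).
    r : float
        Production rate per emitter cell (molecules/s).
    rho_alpha : float
        Emitter (MATα) surface density (cells/μm²).
    rho_A : float
        Receiver (MATa) surface density (cells/μm²).
    Omega : float
        Per-cell degradation parameter (μm³/s — a rate times a length cubed).
    """

    D: float
    r: float
    rho_alpha: float
    rho_A: float
    Omega: float

    def __post_init__(self) -> None:
        for name in ("D", "r", "rho_alpha", "rho_A", "Omega"):
            if not getattr(self, name) > 0:
                raise ValueError(f"PhysicalParams.{name} must be strictly positive")

    @property
    def decay_length(self) -> float:
        """Gradient decay length λ = D/(Ω·ρ_A) in μm."""
        return self.D / (self.Omega * self.rho_A)

    @property
    def c_far(self) -> float:
        """Far-field concentration r·ρ_α/(Ω·ρ_A) in the production domain."""
        return self.r * self.rho_alpha / (self.Omega * self.rho_A)


@dataclass(frozen=True)
class GradientShape:
    """The two effective parameters the data constrain.

    ``lambda_`` is the decay length in μm; ``C`` the far-field concentration
    in EC50 units (dimensionless). ``C`` equals twice the border
    concentration: c(0) = C/2.
    """

    lambda_: float
    C: float

    def __post_init__(self) -> None:
        if not self.lambda_ > 0:
            raise ValueError("GradientShape.lambda_ must be strictly positive")
        if not self.C > 0:
            raise ValueError("GradientShape.C must be strictly positive")

    @classmethod
    def from_physical(cls, phys: PhysicalParams, ec50: float) -> "GradientShape":
        """Build the effective shape from microscopic parameters and an EC50.

        ``ec50`` must be in the same concentration units as ``phys.c_far``.
        """
        if not ec50 > 0:
            raise ValueError("ec50 must be strictly positive")
        return cls(lambda_=phys.decay_length, C=phys.c_far / ec50)


@dataclass(frozen=True)
class ResponseParams:
    """Hill dose-response parameters for one readout channel.

    ``n`` is the Hill coefficient (integer, 1–7), ``A`` the response
    amplitude and ``b`` the baseline, both in readout units (fluorescence
    a.u. for gene expression, μm for cell length).
    """

    n: int
    A: float
    b: float

    def __post_init__(self) -> None:
        if int(self.n) != self.n or not 1 <= int(self.n) <= 7:
            raise ValueError("ResponseParams.n must be an integer in 1..7")
        if not self.A >= 0:
            raise ValueError("ResponseParams.A must be nonnegative")


# ---------------------------------------------------------------------------
# special functions and profiles
# ---------------------------------------------------------------------------

def si_ci(u):
    """Sine and cosine integrals Si(u), Ci(u).

    ``u = 0`` is allowed for Si (Si(0) = 0) but not for Ci, which diverges
    logarithmically at the origin; callers evaluating products such as
    sin(u)·Ci(u) near zero must take the analytic limit themselves.
    """
    u_arr = np.asarray(u, dtype=float)
    if np.any(u_arr < 0):
        raise ValueError("si_ci requires u >= 0")
    si, ci = sici(u_arr)
    if np.ndim(u) == 0:
        return float(si), float(ci)
    return si, ci


def _profile_term(u: np.ndarray) -> np.ndarray:
    """The Si/Ci combination shared by the source and sink closed forms.

    For u ≠ 0 this is cos(u)·sign(u)·(π/2 − Si(|u|))/π + sin(u)·Ci(|u|)/π.
    """
    au = np.abs(u)
    safe = np.where(au < _NEAR_ZERO, 1.0, au)
    si, ci = sici(safe)
    term = (
        np.cos(u) * np.sign(u) * (np.pi / 2 - si) + np.sin(u) * ci
    ) / np.pi
    return np.where(au < _NEAR_ZERO, 0.0, term)


def source_profile(x, lambda_: float):
    """Normalized surface concentration for half-domain production.

    Production occupies x < 0, uptake acts everywhere. Returns
    ``f(x) ∈ [0, 1]`` with f(−∞) = 1, f(0) = 1/2 and the heavy tail
    f(x) ≈ λ/(πx) for x ≫ λ. The physical concentration is
    ``c(x) = c_far · f(x)``.
    """
    if not lambda_ > 0:
        raise ValueError("lambda_ must be strictly positive")
    x_arr = np.asarray(x, dtype=float)
    u = x_arr / lambda_
    step = np.where(u < 0, 1.0, 0.0)
    f = np.where(np.abs(u) < _NEAR_ZERO, 0.5, step + _profile_term(u))
    if np.ndim(x) == 0:
        return float(f)
    return f


def sink_profile(x, lambda_: float):
    """Normalized surface concentration for the perfect-sink geometry.

    Production occupies the whole surface but the domain x > 0 is a perfect
    sink (concentration identically zero there). On the diffusion side the
    profile obeys ``g(x) = 2 f(x) − 1`` with ``f`` the source profile, so
    g(−∞) = 1 and g rises from exactly 0 at the border.
    """
    if not lambda_ > 0:
        raise ValueError("lambda_ must be strictly positive")
    x_arr = np.asarray(x, dtype=float)
    f = np.asarray(source_profile(x_arr, lambda_))
    g = np.where(x_arr < 0, 2.0 * f - 1.0, 0.0)
    if np.ndim(x) == 0:
        return float(g)
    return g


def concentration(x, shape: GradientShape, geometry: str = "source"):
    """Surface concentration in EC50 units for either geometry.

    ``geometry`` is "source" (half-domain production) or "sink" (perfect-sink
    degradation on x > 0). The far-field value in the production/diffusion
    domain is ``shape.C``.
    """
    if geometry == "source":
        prof = source_profile(x, shape.lambda_)
    elif geometry == "sink":
        prof = sink_profile(x, shape.lambda_)
    else:
        raise ValueError(f"unknown geometry {geometry!r}; expected 'source' or 'sink'")
    return shape.C * np.asarray(prof) if np.ndim(x) else shape.C * prof


def hill_response(c, n: int):
    """Fractional pathway activation θ = cⁿ/(1 + cⁿ) for c in EC50 units.

    θ(1) = 1/2 by definition of the EC50; n = 1 is the Michaelian
    gene-expression channel, larger n the switch-like morphology channel.
    """
    if not n >= 1:
        raise ValueError("Hill coefficient n must be >= 1")
    c_arr = np.asarray(c, dtype=float)
    if np.any(c_arr < 0):
        raise ValueError("concentration must be nonnegative")
    cn = c_arr ** n
    theta = cn / (1.0 + cn)
    if np.ndim(c) == 0:
        return float(theta)
    return theta


def observed_response(x, shape: GradientShape, resp: ResponseParams,
                      geometry: str = "source"):
    """Readout-space response  θ̂(x) = A·θ(c(x)) + b."""
    c = concentration(x, shape, geometry)
    return resp.A * hill_response(c, resp.n) + resp.b


def normalize_max(theta_hat, resp: ResponseParams, C: float, n: int | None = None):
    """Map a readout to [0, 1] of its theoretical plateau.

    Baseline-subtracts and rescales: ((θ̂ − b)/A) / (Cⁿ/(1+Cⁿ)). The
    far-field production plateau maps to exactly 1.
    """
    if not resp.A > 0:
        raise ValueError("normalize_max requires amplitude A > 0")
    if n is None:
        n = resp.n
    plateau = C ** n / (1.0 + C ** n)
    return ((np.asarray(theta_hat, dtype=float) - resp.b) / resp.A) / plateau


def border_gradient(shape: GradientShape, delta: float = 5.0) -> float:
    """Finite-difference gradient magnitude at the light-dark border.

    The true derivative of the source profile diverges logarithmically at
    x = 0, so the steepness is quantified over a finite scale ``delta``
    (default 5 μm, one cell diameter) as the centered difference
    [c(−δ/2) − c(+δ/2)] / δ, in EC50 units per μm.
    """
    if not delta > 0:
        raise ValueError("delta must be strictly positive")
    c_lo = concentration(-delta / 2.0, shape, "source")
    c_hi = concentration(+delta / 2.0, shape, "source")
    return (c_lo - c_hi) / delta
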