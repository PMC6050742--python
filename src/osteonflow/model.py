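"""Domain types and layer-level constitutive quantities.

A single osteon is idealized as a hollow, axisymmetric, transversely
isotropic poroelastic cylinder of ``n`` concentric lamellae, each a
homogeneous layer with its own lacunar-canalicular intrinsic permeability.
Under harmonic axial strain ``eps_z = eps_z0 * exp(i*omega*t)`` every field
reduces to a complex radial amplitude; the pressure amplitude in layer *i*
obeys a modified-Bessel equation whose complex wavenumber ``C_i`` is computed
here, together with the drained plane-stiffness constants of the skeleton.

All quantities are strictly SI (m, Pa, s, m^2); unit conversion happens at
the configuration boundary (:mod:`osteonflow.config`).
"""

from __future__ import annotations

import cmath
import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "MaterialConstants",
    "PlaneStiffness",
    "LayerStack",
    "Loading",
    "LayerSolution",
    "FieldProfile",
    "ValidationError",
    "compute_stiffness",
    "layer_wavenumber",
]


class ValidationError(ValueError):
    """Raised when a physical invariant of the input data is violated."""


@dataclass(frozen=True)
class MaterialConstants:
    """Drained elastic, Biot, and fluid constants shared by all lamellae.

    Parameters
    ----------
    E_r, E_z:
        Drained Young's moduli in the isotropic (r-theta) plane and along
        the symmetry (z) axis, in Pa.
    nu_r, nu_z:
        Drained Poisson's ratios in the isotropic plane and along the axis.
    alpha, alpha_prime:
        Biot effective stress coefficients in the isotropic plane and in
        the z-direction (dimensionless, in [0, 1]).
    N_biot:
        Biot's modulus coupling fluid-content change to pore pressure, Pa.
    mu_fluid:
        Pore-fluid dynamic viscosity, Pa*s.
    """

    E_r: float
    E_z: float
    nu_r: float
    nu_z: float
    alpha: float
    alpha_prime: float
    N_biot: float
    mu_fluid: float

    def __post_init__(self) -> None:
        for name in ("E_r", "E_z", "N_biot", "mu_fluid"):
            if not getattr(self, name) > 0:
                raise ValidationError(f"{name} must be > 0, got {getattr(self, name)!r}")
        if not (0 < self.nu_r < 0.5):
            raise ValidationError(f"nu_r must lie in (0, 0.5), got {self.nu_r!r}")
        for name in ("alpha", "alpha_prime"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {v!r}")
        if self.thermo_denominator <= 0:
            raise ValidationError(
                "non-physical constants: E_z - E_z*nu_r - 2*E_r*nu_z^2 = "
                f"{self.thermo_denominator:.6g} <= 0 (drained stiffness would "
                "not be positive definite)"
            )

    @property
    def thermo_denominator(self) -> float:
        """Common denominator of the drained stiffness; must be positive."""
        return self.E_z - self.E_z * self.nu_r - 2.0 * self.E_r * self.nu_z**2


@dataclass(frozen=True)
class PlaneStiffness:
    """Drained stiffness constants of the skeleton in the r-theta plane (Pa)."""

    M11: float
    M12: float
    M13: float

    def __post_init__(self) -> None:
        for name in ("M11", "M12", "M13"):
            if not math.isfinite(getattr(self, name)):
                raise ValidationError(f"{name} is not finite")
        if not self.M11 > abs(self.M12):
            raise ValidationError(
                f"stiffness not positive definite in-plane: M11={self.M11:.6g} "
                f"<= |M12|={abs(self.M12):.6g}"
            )


@dataclass(frozen=True)
class LayerStack:
    """Geometry of the lamellar stack and per-layer intrinsic permeability.

    ``radii`` holds the ordered interface radii ``r_0 = a < r_1 < ... <
    r_n = b`` in metres; ``k`` the intrinsic permeability of each of the
    ``n`` layers in m^2.  The inner radius must be strictly positive: the
    cylindrical 1/r terms are singular at the axis.
    """

    radii: np.ndarray
    k: np.ndarray

    def __post_init__(self) -> None:
        radii = np.asarray(self.radii, dtype=float)
        k = np.asarray(self.k, dtype=float)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "k", k)
        if radii.ndim != 1 or radii.size < 2:
            raise ValidationError("radii must be a 1-D array of at least two radii")
        if not radii[0] > 0:
            raise ValidationError(f"inner radius a must be > 0, got {radii[0]!r}")
        if not np.all(np.diff(radii) > 0):
            raise ValidationError("interface radii must be strictly increasing")
        if k.ndim != 1 or k.size != radii.size - 1:
            raise ValidationError(
                f"permeability list has length {k.size}, expected n = "
                f"{radii.size - 1} (one value per layer)"
            )
        if not np.all(k > 0):
            raise ValidationError("all permeabilities must be > 0")

    @property
    def a(self) -> float:
        """Inner radius (Haversian canal wall), m."""
        return float(self.radii[0])

    @property
    def b(self) -> float:
        """Outer radius (cement line), m."""
        return float(self.radii[-1])

    @property
    def n(self) -> int:
        """Number of lamellae."""
        return self.radii.size - 1

    @property
    def widths(self) -> np.ndarray:
        return np.diff(self.radii)

    @classmethod
    def equal_width(cls, a: float, b: float, k: np.ndarray | list[float]) -> "LayerStack":
        """Build a stack of ``len(k)`` equal-width layers spanning [a, b]."""
        k = np.asarray(k, dtype=float)
        return cls(radii=np.linspace(a, b, k.size + 1), k=k)


@dataclass(frozen=True)
class Loading:
    """Harmonic axial loading: strain amplitude and angular frequency."""

    eps_z0: float
    omega: float

    def __post_init__(self) -> None:
        if self.eps_z0 < 0:
            raise ValidationError(f"eps_z0 must be >= 0, got {self.eps_z0!r}")
        if not self.omega > 0:
            raise ValidationError(f"omega must be > 0, got {self.omega!r}")


@dataclass(frozen=True)
class LayerSolution:
    """Per-layer complex coefficients of the analytic solution.

    Pressure in layer *i* is ``P_i + A_i I0(C_i r) + B_i K0(C_i r)`` with
    ``P_i`` the constant particular term; displacement carries the
    homogeneous constants ``c_i`` (dimensionless strain) and ``s_i`` (m^2).
    """

    A: np.ndarray
    B: np.ndarray
    c: np.ndarray
    s: np.ndarray
    C: np.ndarray

    def __post_init__(self) -> None:
        n = self.A.size
        for name in ("B", "c", "s", "C"):
            if getattr(self, name).size != n:
                raise ValidationError("coefficient arrays must share one length")
        if not np.all(self.C.real >= 0):
            raise ValidationError("wavenumbers must be on the principal branch (Re >= 0)")

    @property
    def n(self) -> int:
        return self.A.size


@dataclass(frozen=True)
class FieldProfile:
    """Radial profiles of the complex field amplitudes.

    Interface radii appear twice (once per owning layer) so that continuity
    is directly assertable from the sampled arrays.
    """

    r: np.ndarray
    layer_index: np.ndarray
    p0: np.ndarray
    u0: np.ndarray
    q0: np.ndarray
    sigma_rr0: np.ndarray
    # loading carried along so a time realization needs no extra context
    omega: float = field(default=float("nan"))

    def __post_init__(self) -> None:
        m = self.r.size
        for name in ("layer_index", "p0", "u0", "q0", "sigma_rr0"):
            if getattr(self, name).size != m:
                raise ValidationError("profile arrays must be aligned in length")


def compute_stiffness(mat: MaterialConstants) -> PlaneStiffness:
    """Drained plane stiffness of the transversely isotropic skeleton.

    With ``D = E_z - E_z*nu_r - 2*E_r*nu_z^2``:

    .. math::

        M_{11} = E_r (E_z - E_r \\nu_z^2) / ((1+\\nu_r) D),\\quad
        M_{12} = E_r (E_z \\nu_r + E_r \\nu_z^2) / ((1+\\nu_r) D),\\quad
        M_{13} = E_r E_z \\nu_z / D.

    The cross-modulus sign is fixed by the isotropic limit: with
    ``E_r = E_z`` and ``nu_r = nu_z`` these collapse to the Lame constants
    ``M11 = lambda + 2 mu`` and ``M12 = M13 = lambda``.

    Raises
    ------
    ValidationError
        If ``D <= 0`` (non-physical constants).
    """
    D = mat.thermo_denominator
    if D <= 0:
        raise ValidationError("stiffness denominator <= 0")
    one_plus = 1.0 + mat.nu_r
    if one_plus == 0:
        raise ValidationError("1 + nu_r must not vanish")
    M11 = mat.E_r * (mat.E_z - mat.E_r * mat.nu_z**2) / (one_plus * D)
    M12 = mat.E_r * (mat.E_z * mat.nu_r + mat.E_r * mat.nu_z**2) / (one_plus * D)
    M13 = mat.E_r * mat.E_z * mat.nu_z / D
    return PlaneStiffness(M11=M11, M12=M12, M13=M13)


def layer_wavenumber(
    mat: MaterialConstants, stiff: PlaneStiffness, k_i: float, omega: float
) -> complex:
    """Complex wavenumber of the pressure-diffusion operator in one layer.

    ``C_i = sqrt(i*omega*mu*(M11 + N*alpha^2) / (k_i * N * M11))`` on the
    principal square-root branch, so ``Re(C_i) >= 0`` and, the radicand
    being purely imaginary with positive imaginary part, ``arg(C_i) = pi/4``
    exactly.  ``1/|C_i|`` is the radial penetration depth of the pore
    pressure at frequency ``omega``.
    """
    if not k_i > 0:
        raise ValidationError(f"permeability must be > 0, got {k_i!r}")
    if not omega > 0:
        raise ValidationError(f"omega must be > 0, got {omega!r}")
    radicand = (
        1j
        * omega
        * mat.mu_fluid
        * (stiff.M11 + mat.N_biot * mat.alpha**2)
        / (k_i * mat.N_biot * stiff.M11)
    )
    return cmath.sqrt(radicand)
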