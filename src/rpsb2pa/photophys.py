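"""Rotational averaging of two-photon tensors and the δ→σ conversion.

The microscopic observable is the second-order (two-photon) transition
moment tensor S for the |0>→|f> transition at degenerate photon energy
ω_f/2. For an isotropic sample and two identical, parallel linearly
polarized photons, the orientation-averaged two-photon transition strength
is the standard isotropic fourth-rank contraction

    δ = (1/15) [ Tr(L) Tr(R) + Σ_ab L_ab R_ab + Σ_ab L_ab R_ba ]

where L and R are the left and right second-order moments. Hermitian
response theories (TD-DFT) give L = Rᵀ; coupled-cluster response (CC2) does
not, which is why both routes exist. A Monte-Carlo orientation average over
uniform SO(3) rotations serves as an independent numerical cross-check.

The macroscopic peak cross section for a Lorentzian band of lifetime
broadening Γ is

    σ = N π³ α a₀⁵ / c · ω² · g_peak(Γ) · δ,    g_peak = 1/(π Γ)

with ω = ΔE/2 the photon energy, reported in GM (10⁻⁵⁰ cm⁴ s/photon).
The prefactor convention was fixed by requiring the packaged reference
table's (δ, ΔE) → σ triples to be reproduced; see docs/methods.md.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.spatial.transform import Rotation

from .constants import CODATA, convert_units
from .errors import InputError, InvariantViolation

logger = logging.getLogger(__name__)

__all__ = [
    "DipoleVector",
    "TwoPhotonTensor",
    "LineShapeParams",
    "delta_mu",
    "average_hermitian",
    "average_nonhermitian",
    "average_numerical",
    "cross_section",
    "convert_units",
]

#: relative Frobenius asymmetry tolerated by the Hermitian route
HERMITIAN_TOL = 1e-8


@dataclass(frozen=True)
class DipoleVector:
    """A Cartesian electric dipole vector with an explicit unit tag."""

    x: float
    y: float
    z: float
    unit: str = "au"  # "au" or "D"

    @classmethod
    def from_array(cls, a, unit: str = "au") -> "DipoleVector":
        a = np.asarray(a, dtype=float)
        if a.shape != (3,):
            raise InputError(f"dipole vector needs 3 components, got shape {a.shape}")
        return cls(float(a[0]), float(a[1]), float(a[2]), unit)

    @property
    def components(self) -> np.ndarray:
        return np.array([self.x, self.y, self.z])

    @property
    def magnitude(self) -> float:
        return float(np.linalg.norm(self.components))

    def to(self, unit: str) -> "DipoleVector":
        if unit == self.unit:
            return self
        f = convert_units(1.0, self.unit, unit)
        return DipoleVector(self.x * f, self.y * f, self.z * f, unit)


def delta_mu(mu00: DipoleVector, mu11: DipoleVector) -> float:
    """|Δμ|: Euclidean norm of the componentwise dipole difference.

    Both vectors must carry the same unit tag; the result is in that unit.
    """
    if mu00.unit != mu11.unit:
        raise InputError(
            f"unit mismatch: mu00 in {mu00.unit!r}, mu11 in {mu11.unit!r}"
        )
    return float(np.linalg.norm(mu11.components - mu00.components))


@dataclass(frozen=True)
class TwoPhotonTensor:
    """Left and right 3x3 second-order transition moments [au].

    For Hermitian sources ``left`` equals ``right`` transposed.
    """

    left: np.ndarray
    right: np.ndarray

    def __post_init__(self) -> None:
        for name in ("left", "right"):
            a = np.asarray(getattr(self, name), dtype=float)
            if a.shape != (3, 3):
                raise InputError(f"{name} moment must be 3x3, got {a.shape}")
            object.__setattr__(self, name, a)

    @classmethod
    def hermitian(cls, S) -> "TwoPhotonTensor":
        """Build from a single (symmetric) moment, left = rightᵀ."""
        S = np.asarray(S, dtype=float)
        return cls(left=S.T.copy(), right=S.copy())

    def asymmetry(self) -> float:
        """Relative Frobenius deviation of left from rightᵀ."""
        scale = max(np.linalg.norm(self.left), np.linalg.norm(self.right))
        if scale == 0.0:
            return 0.0
        return float(np.linalg.norm(self.left - self.right.T) / scale)

    @property
    def is_hermitian(self) -> bool:
        return self.asymmetry() <= HERMITIAN_TOL


@dataclass(frozen=True)
class LineShapeParams:
    """Lorentzian broadening Γ [eV] and the integer prefactor N."""

    gamma: float = 0.1
    n_factor: int = 4
    shape: str = "lorentzian"

    def __post_init__(self) -> None:
        if not self.gamma > 0:
            raise InputError(f"gamma must be > 0, got {self.gamma}")
        if self.n_factor < 1:
            raise InputError(f"n_factor must be >= 1, got {self.n_factor}")
        if self.shape != "lorentzian":
            raise InputError(f"unsupported lineshape {self.shape!r}")


def _contract(left: np.ndarray, right: np.ndarray) -> float:
    # isotropic average of (e·L·e)(e·R·e) for parallel linear polarization
    return float(
        (np.trace(left) * np.trace(right)
         + np.sum(left * right)
         + np.sum(left * right.T)) / 15.0
    )


def average_hermitian(S: TwoPhotonTensor | np.ndarray) -> float:
    """Rotationally averaged δ [au] for a Hermitian (TD-DFT-like) moment.

    Accepts a :class:`TwoPhotonTensor` with left = rightᵀ (within tolerance)
    or a bare 3x3 array. Non-symmetric input raises, directing the caller to
    :func:`average_nonhermitian`.
    """
    if not isinstance(S, TwoPhotonTensor):
        S = TwoPhotonTensor.hermitian(np.asarray(S, dtype=float))
    if S.asymmetry() > HERMITIAN_TOL:
        raise InvariantViolation(
            "tensor is not Hermitian (left != right^T beyond tolerance "
            f"{HERMITIAN_TOL:g}; asymmetry {S.asymmetry():.3e}); "
            "use average_nonhermitian for left/right-asymmetric moments"
        )
    return _contract(S.left, S.right)


def average_nonhermitian(S: TwoPhotonTensor) -> float:
    """Rotationally averaged δ [au] from distinct left/right moments.

    Reduces exactly to :func:`average_hermitian` when left = rightᵀ. Negative
    values (possible for pathological left/right pairs in non-Hermitian
    response) are returned as-is with a logged warning.
    """
    val = _contract(S.left, S.right)
    if val < 0:
        logger.warning("negative rotationally averaged delta2pa: %g au", val)
    return val


def average_numerical(
    S: TwoPhotonTensor,
    n_orientations: int = 20000,
    seed: int = 0,
    return_stderr: bool = False,
):
    """Monte-Carlo orientation average of the polarization-contracted product.

    Samples uniform SO(3) rotations, co-rotates left and right moments and
    averages (e·L·e)(e·R·e) for a fixed linear polarization axis e. Serves as
    the independent oracle for the closed forms.
    """
    if n_orientations < 1000:
        raise InputError("n_orientations must be >= 1000 for a meaningful average")
    rot = Rotation.random(n_orientations, random_state=np.random.default_rng(seed))
    M = rot.as_matrix()          # (n, 3, 3)
    e_rows = M[:, 2, :]          # lab z-axis expressed in the molecular frame
    a = np.einsum("ni,ij,nj->n", e_rows, S.left, e_rows)
    b = np.einsum("ni,ij,nj->n", e_rows, S.right, e_rows)
    prod = a * b
    est = float(np.mean(prod))
    if return_stderr:
        se = float(np.std(prod, ddof=1) / np.sqrt(n_orientations))
        return est, se
    return est


def cross_section(
    delta2pa: float, dE: float, params: LineShapeParams | None = None
) -> float:
    """Peak 2PA cross section σ [GM] from δ [au] and excitation energy ΔE [eV].

    Evaluated at the two-photon resonance peak of a Lorentzian band:
    photon energy ω = ΔE/2, lineshape peak value g = 1/(πΓ). Linear in δ;
    scales as ω² and 1/Γ.
    """
    params = params or LineShapeParams()
    if not dE > 0:
        raise InputError(f"excitation energy must be > 0, got {dE}")
    if delta2pa < 0:
        warnings.warn(
            f"negative delta2pa ({delta2pa} au): returning signed cross section",
            stacklevel=2,
        )
    c = CODATA
    omega_au = convert_units(dE, "eV", "hartree") / 2.0
    gamma_au = convert_units(params.gamma, "eV", "hartree")
    g_peak = 1.0 / (np.pi * gamma_au)
    prefactor = params.n_factor * np.pi**3 * c.alpha * c.a0_cm**5 / c.c_cm_per_s
    sigma_cm4s = prefactor * omega_au**2 * g_peak * delta2pa
    return convert_units(sigma_cm4s, "cm4s", "GM")
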