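"""Few-state sum-over-states (SOS) two-photon moments and the two-state model.

The second-order transition moment for the degenerate |0>→|f> transition is
expanded over the electronic manifold with energy denominators ω_n − ω_f/2,
symmetrized over the two photon orderings. Dipole operators enter in
fluctuation form (the ground-state permanent dipole is subtracted from every
diagonal element), which makes the n = 0 term vanish and the result
independent of the coordinate origin — and is what lets the celebrated
two-state model emerge on a ground+final manifold.

Two-state closed form (parallel linear polarization, degenerate photons),
derived by specializing the isotropic averaging contraction of
:mod:`rpsb2pa.photophys` to the two-state tensor
S_ab = 2(Δμ_a μ01_b + Δμ_b μ01_a)/ω_f:

    δ = 16/(15 ω_f²) · [ |μ01|²|Δμ|² + 2 (μ01·Δμ)² ]

so δ ∝ |μ01|² |Δμ|² / ω_f² with an angle factor of 3 at collinearity.

Intermediate states close to the photon energy ω_f/2 make the SOS diverge
(resonance enhancement); such manifolds are rejected by a configurable
resonance guard rather than silently amplified.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InputError, InvariantViolation
from .photophys import DipoleVector, TwoPhotonTensor, average_nonhermitian

__all__ = [
    "DEFAULT_RESONANCE_GUARD",
    "ElectronicManifold",
    "SosResult",
    "sos_moment",
    "sos_result",
    "two_state_delta",
    "resonance_check",
]

#: default resonance guard [au] (≈ 0.26 eV)
DEFAULT_RESONANCE_GUARD = 0.0095


@dataclass
class ElectronicManifold:
    """Ground + excited states: excitation energies and the full dipole matrix.

    ``energies`` are excitation energies ω_n [au] with ω_0 = 0, strictly
    increasing. ``dipoles`` has shape (n, n, 3) [au] with permanent dipoles on
    the diagonal and transition dipoles off-diagonal; it must be symmetric in
    the two state indices (real-wavefunction convention).
    """

    energies: np.ndarray
    dipoles: np.ndarray
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.energies = np.asarray(self.energies, dtype=float)
        self.dipoles = np.asarray(self.dipoles, dtype=float)
        n = self.energies.shape[0]
        if n < 2:
            raise InputError("manifold needs at least ground + one excited state")
        if self.energies[0] != 0.0:
            raise InputError(f"ground-state energy must be 0, got {self.energies[0]}")
        if np.any(np.diff(self.energies) <= 0):
            raise InputError("excitation energies must be strictly increasing")
        if self.dipoles.shape != (n, n, 3):
            raise InputError(
                f"dipole matrix must have shape ({n}, {n}, 3), got {self.dipoles.shape}"
            )
        if not np.allclose(self.dipoles, np.swapaxes(self.dipoles, 0, 1),
                           rtol=0.0, atol=1e-10):
            raise InvariantViolation(
                "dipole matrix must be symmetric in the state indices"
            )

    @property
    def n_states(self) -> int:
        return int(self.energies.shape[0])

    def dipole(self, n: int, m: int) -> DipoleVector:
        return DipoleVector.from_array(self.dipoles[n, m], unit="au")

    # --- JSON schema: {"energies_au": [...], "dipoles_au": [n][m][3], "labels": [...]}
    def to_json(self, path: str | Path | None = None) -> str:
        obj = {
            "energies_au": self.energies.tolist(),
            "dipoles_au": self.dipoles.tolist(),
        }
        if self.labels:
            obj["labels"] = self.labels
        text = json.dumps(obj, indent=1) + "\n"
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "ElectronicManifold":
        p = Path(source)
        try:
            text = p.read_text() if p.exists() else str(source)
        except OSError:  # e.g. raw JSON string too long for a path
            text = str(source)
        try:
            obj = json.loads(text)
        except json.JSONDecodeError as exc:
            raise InputError(f"invalid manifold JSON: {exc}") from None
        for key in ("energies_au", "dipoles_au"):
            if key not in obj:
                raise InputError(f"manifold JSON missing key {key!r}")
        return cls(
            energies=np.asarray(obj["energies_au"], dtype=float),
            dipoles=np.asarray(obj["dipoles_au"], dtype=float),
            labels=list(obj.get("labels", [])),
        )


@dataclass(frozen=True)
class SosResult:
    """A computed SOS moment with its averaged strength and resonance audit."""

    tensor: TwoPhotonTensor
    delta2pa: float
    resonance_flags: list[tuple[int, float]]


def resonance_check(
    m: ElectronicManifold, f: int, guard: float = DEFAULT_RESONANCE_GUARD
) -> list[tuple[int, float]]:
    """Flag every state whose energy lies within ``guard`` of the photon energy.

    Returns (state index, detuning |ω_n − ω_f/2| [au]) pairs; an empty list
    means the SOS for final state ``f`` is well-conditioned.
    """
    if not guard > 0:
        raise InputError(f"resonance guard must be > 0, got {guard}")
    _check_final(m, f)
    omega = m.energies[f] / 2.0
    detunings = np.abs(m.energies - omega)
    return [(int(n), float(d)) for n, d in enumerate(detunings) if d < guard]


def _check_final(m: ElectronicManifold, f: int) -> None:
    if not 1 <= f < m.n_states:
        raise InputError(
            f"final state index {f} out of range [1, {m.n_states - 1}]"
        )


def sos_moment(
    m: ElectronicManifold, f: int, guard: float = DEFAULT_RESONANCE_GUARD
) -> TwoPhotonTensor:
    """Left/right second-order moments for |0>→|f| at photon energy ω_f/2.

    Each αβ component sums over all states n the dipole products divided by
    (ω_n − ω_f/2), symmetrized over the photon orderings, with dipoles in
    fluctuation form. For the symmetric dipole matrices enforced by
    :class:`ElectronicManifold` the result is Hermitian (left = rightᵀ).
    """
    _check_final(m, f)
    flags = resonance_check(m, f, guard)
    if flags:
        raise InvariantViolation(
            f"SOS for final state {f} is resonance-enhanced; states within "
            f"guard {guard} au of the photon energy: {flags}"
        )
    omega = m.energies[f] / 2.0
    # fluctuation dipoles: subtract mu00 from every diagonal element
    d = m.dipoles.copy()
    mu00 = m.dipoles[0, 0]
    idx = np.arange(m.n_states)
    d[idx, idx, :] -= mu00
    w = 1.0 / (m.energies - omega)            # (n,)
    A = d[f, :, :]                            # <f|mu|n>, (n, 3)
    B = d[:, 0, :]                            # <n|mu|0>, (n, 3)
    C = np.einsum("n,na,nb->ab", w, A, B)
    right = C + C.T
    Al = d[0, :, :]                           # <0|mu|n>
    Bl = d[:, f, :]                           # <n|mu|f>
    Cl = np.einsum("n,na,nb->ab", w, Al, Bl)
    left = Cl + Cl.T
    return TwoPhotonTensor(left=left, right=right)


def sos_result(
    m: ElectronicManifold, f: int, guard: float = DEFAULT_RESONANCE_GUARD
) -> SosResult:
    """SOS moment plus its rotationally averaged strength and resonance audit."""
    tensor = sos_moment(m, f, guard)
    return SosResult(
        tensor=tensor,
        delta2pa=average_nonhermitian(tensor),
        resonance_flags=resonance_check(m, f, guard),
    )


def two_state_delta(
    mu01: DipoleVector | np.ndarray,
    dmu: DipoleVector | np.ndarray,
    omega_f: float,
) -> float:
    """Closed-form two-state δ [au] for parallel linearly polarized photons.

    ``mu01`` and ``dmu`` are the transition dipole and the permanent-dipole
    change in au; ``omega_f`` the excitation energy in au. Exactly equals
    SOS + rotational averaging on a ground+final manifold (defining contract).
    """
    if not omega_f > 0:
        raise InputError(f"omega_f must be > 0, got {omega_f}")
    t = mu01.components if isinstance(mu01, DipoleVector) else np.asarray(mu01, float)
    dm = dmu.components if isinstance(dmu, DipoleVector) else np.asarray(dmu, float)
    t2 = float(t @ t)
    d2 = float(dm @ dm)
    dot = float(t @ dm)
    return 16.0 / (15.0 * omega_f**2) * (t2 * d2 + 2.0 * dot**2)
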