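"""Hyperelastic constitutive models for the aneurysm wall.

Two incompressible strain-energy models:

* an anisotropic two-fiber-family model (neo-Hookean matrix plus two
  exponentially stiffening collagen-fiber families arranged in a double helix
  at +/- theta from the circumferential direction),

      W = c10 (I1b - 3) + k1/(2 k2) [exp(k2 (I4b - 1)^2) - 1]
                        + k3/(2 k4) [exp(k4 (I6b - 1)^2) - 1]

* a softer isotropic polynomial model,

      W = C10 (I1b - 3) + C20 (I1b - 3)^2

where I1b is the first deviatoric invariant of the right Cauchy-Green tensor
and I4b, I6b are the squared (isochoric) fiber stretches.  The module works
in kPa internally; the isotropic constants are entered in MPa and converted.

Local frame convention: e1 = circumferential, e2 = axial, e3 = radial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq

from .errors import ConstraintError, KinematicsError, SaturationError

#: Largest admissible argument of the fiber exponential before a
#: :class:`SaturationError` is raised (exp(700) is near the double limit).
EXP_CAP = 700.0


@dataclass(frozen=True)
class AnisotropicModel:
    """Two-fiber-family arterial wall model (constants in kPa)."""

    c10: float = 110.0  # kPa, matrix stiffness
    k1: float = 210.0   # kPa, fiber family 1 stiffness
    k2: float = 1700.0  # -, fiber family 1 stiffening exponent
    k3: float = 210.0   # kPa, fiber family 2 stiffness
    k4: float = 1700.0  # -, fiber family 2 stiffening exponent
    theta_deg: float = 43.0  # fiber angle from the circumferential direction

    def __post_init__(self):
        if min(self.c10, self.k1, self.k3) <= 0 or min(self.k2, self.k4) <= 0:
            raise ValueError("stiffness-like parameters must be positive")

    def fiber_directions(self) -> tuple[np.ndarray, np.ndarray]:
        """Reference unit vectors n0, m0 at +/- theta in the (circ, axial) plane."""
        th = np.deg2rad(self.theta_deg)
        n0 = np.array([np.cos(th), np.sin(th), 0.0])
        m0 = np.array([np.cos(th), -np.sin(th), 0.0])
        return n0, m0


@dataclass(frozen=True)
class IsotropicModel:
    """Two-term polynomial model (constants entered in MPa)."""

    C10: float = 0.174  # MPa
    C20: float = 1.881  # MPa

    @property
    def c10_kpa(self) -> float:
        return self.C10 * 1000.0

    @property
    def c20_kpa(self) -> float:
        return self.C20 * 1000.0


Model = AnisotropicModel | IsotropicModel


@dataclass(frozen=True)
class DeformationState:
    """Kinematic state derived from a deformation gradient F (3x3)."""

    F: np.ndarray

    def __post_init__(self):
        F = np.asarray(self.F, dtype=float)
        if F.shape != (3, 3):
            raise KinematicsError("F must be a 3x3 tensor")
        if np.linalg.det(F) <= 0:
            raise KinematicsError("det F must be positive")
        object.__setattr__(self, "F", F)

    @property
    def J(self) -> float:
        return float(np.linalg.det(self.F))

    @property
    def C_bar(self) -> np.ndarray:
        """Isochoric right Cauchy-Green tensor J^(-2/3) F^T F."""
        return self.J ** (-2.0 / 3.0) * (self.F.T @ self.F)

    @property
    def I1_bar(self) -> float:
        return float(np.trace(self.C_bar))

    @classmethod
    def identity(cls) -> "DeformationState":
        return cls(np.eye(3))


def invariants_of(state: DeformationState, fibers: tuple[np.ndarray, np.ndarray] | None = None
                  ) -> tuple[float, float, float, float]:
    """(I1b, I4b, I6b, J) for a state and a pair of unit fiber directions.

    The pseudo-invariants are the squared isochoric fiber stretches
    I4b = n0 . C_bar . n0 and I6b = m0 . C_bar . m0.
    """
    if fibers is None:
        n0, m0 = AnisotropicModel().fiber_directions()
    else:
        n0, m0 = (np.asarray(v, dtype=float) for v in fibers)
        for v in (n0, m0):
            if not np.isclose(np.linalg.norm(v), 1.0, atol=1e-9):
                raise KinematicsError("fiber directions must be unit vectors")
    Cb = state.C_bar
    return (float(np.trace(Cb)), float(n0 @ Cb @ n0), float(m0 @ Cb @ m0), state.J)


def _fiber_psi(k_a: float, k_b: float, I: float, clip: bool = False) -> float:
    """dW/dI for one fiber family, with overflow guard."""
    e = I - 1.0
    arg = k_b * e * e
    if arg > EXP_CAP:
        if not clip:
            raise SaturationError(
                f"fiber exponential saturated (k*(I-1)^2 = {arg:.3g} > {EXP_CAP}) at I = {I:.6g}",
                invariant=I)
        arg = EXP_CAP
    return k_a * e * np.exp(arg)


def strain_energy(model: Model, state: DeformationState,
                  fibers: tuple[np.ndarray, np.ndarray] | None = None) -> float:
    """Strain energy density W in kPa."""
    if isinstance(model, IsotropicModel):
        q = state.I1_bar - 3.0
        return model.c10_kpa * q + model.c20_kpa * q * q
    if fibers is None:
        fibers = model.fiber_directions()
    I1b, I4b, I6b, _ = invariants_of(state, fibers)
    W = model.c10 * (I1b - 3.0)
    for k_a, k_b, I in ((model.k1, model.k2, I4b), (model.k3, model.k4, I6b)):
        e = I - 1.0
        arg = k_b * e * e
        if arg > EXP_CAP:
            raise SaturationError(
                f"fiber exponential saturated (k*(I-1)^2 = {arg:.3g} > {EXP_CAP}) at I = {I:.6g}",
                invariant=I)
        W += k_a / (2.0 * k_b) * (np.exp(arg) - 1.0)
    return float(W)


def cauchy_stress(model: Model, state: DeformationState,
                  traction_free: np.ndarray | None = None,
                  fibers: tuple[np.ndarray, np.ndarray] | None = None,
                  clip_saturation: bool = False) -> np.ndarray:
    """Cauchy stress (kPa) of the incompressible material.

    The incompressibility pressure is fixed by requiring zero normal stress
    along the declared ``traction_free`` unit direction (current
    configuration); the membrane use-case declares the radial direction.
    """
    if traction_free is None:
        raise ConstraintError("a traction-free direction is required to fix the pressure")
    d = np.asarray(traction_free, dtype=float)
    d = d / np.linalg.norm(d)

    F, J = state.F, state.J
    Bb = J ** (-2.0 / 3.0) * (F @ F.T)

    if isinstance(model, IsotropicModel):
        I1b = float(np.trace(Bb))
        W1 = model.c10_kpa + 2.0 * model.c20_kpa * (I1b - 3.0)
        sig = 2.0 / J * W1 * Bb
    else:
        if fibers is None:
            fibers = model.fiber_directions()
        I1b, I4b, I6b, _ = invariants_of(state, fibers)
        n0, m0 = fibers
        a = J ** (-1.0 / 3.0) * (F @ n0)
        b = J ** (-1.0 / 3.0) * (F @ m0)
        W4 = _fiber_psi(model.k1, model.k2, I4b, clip=clip_saturation)
        W6 = _fiber_psi(model.k3, model.k4, I6b, clip=clip_saturation)
        sig = 2.0 / J * (model.c10 * Bb + W4 * np.outer(a, a) + W6 * np.outer(b, b))

    sig = sig - np.trace(sig) / 3.0 * np.eye(3)  # deviatoric part
    p = float(d @ sig @ d)
    return sig - p * np.eye(3)


def membrane_stress(model: Model, lam_theta, lam_z=1.0):
    """Closed-form in-plane Cauchy stresses of an incompressible membrane.

    For F = diag(lam_theta, lam_z, 1/(lam_theta*lam_z)) with the radial
    direction traction-free.  Vectorized over ``lam_theta``.  Returns
    (sigma_theta, sigma_z) in kPa.
    """
    lt = np.asarray(lam_theta, dtype=float)
    lz = np.asarray(lam_z, dtype=float)
    if np.any(lt <= 0) or np.any(lz <= 0):
        raise KinematicsError("stretches must be positive")
    lr2 = 1.0 / (lt * lz) ** 2
    lt2, lz2 = lt * lt, lz * lz
    I1 = lt2 + lz2 + lr2

    if isinstance(model, IsotropicModel):
        W1 = model.c10_kpa + 2.0 * model.c20_kpa * (I1 - 3.0)
        return 2.0 * W1 * (lt2 - lr2), 2.0 * W1 * (lz2 - lr2)

    th = np.deg2rad(model.theta_deg)
    c2, s2 = np.cos(th) ** 2, np.sin(th) ** 2
    I4 = lt2 * c2 + lz2 * s2  # both families see the same stretch here
    e = I4 - 1.0
    arg = model.k2 * e * e
    if np.any(arg > EXP_CAP):
        bad = float(np.asarray(I4).ravel()[int(np.argmax(np.asarray(arg)))])
        raise SaturationError(
            f"fiber exponential saturated in membrane state at I4 = {bad:.6g}", invariant=bad)
    W4 = model.k1 * e * np.exp(arg)
    W6 = model.k3 * e * np.exp(model.k4 * e * e)
    sig_t = 2.0 * model.c10 * (lt2 - lr2) + 2.0 * (W4 + W6) * lt2 * c2
    sig_z = 2.0 * model.c10 * (lz2 - lr2) + 2.0 * (W4 + W6) * lz2 * s2
    return sig_t, sig_z


def uniaxial_response(model: Model, stretches, direction: str = "circumferential"
                      ) -> np.ndarray:
    """Uniaxial Cauchy stress (kPa) at each stretch, transverse faces free.

    Solves for the transverse stretch ratio so that both transverse normal
    stresses vanish (they differ for the anisotropic model).
    """
    stretches = np.asarray(stretches, dtype=float)
    if np.any(stretches <= 0.5) or np.any(stretches >= 1.5):
        raise KinematicsError("stretches must lie in (0.5, 1.5)")
    axis = {"circumferential": 0, "axial": 1}[direction]
    other = 1 - axis

    out = np.empty_like(stretches)
    for i, lam in enumerate(stretches):
        def transverse_residual(l2: float) -> float:
            diag = [0.0, 0.0, 0.0]
            diag[axis] = lam
            diag[other] = l2
            diag[2] = 1.0 / (lam * l2)
            st = DeformationState(np.diag(diag))
            # clipped fiber term: bracketing may probe saturated stretches
            sig = cauchy_stress(model, st, traction_free=np.eye(3)[2],
                                clip_saturation=True)
            return float(sig[other, other])

        l2 = brentq(transverse_residual, 0.4, 2.5, xtol=1e-12)
        diag = [0.0, 0.0, 0.0]
        diag[axis] = lam
        diag[other] = l2
        diag[2] = 1.0 / (lam * l2)
        st = DeformationState(np.diag(diag))
        sig = cauchy_stress(model, st, traction_free=np.eye(3)[2])
        out[i] = sig[axis, axis]
    return out


def small_strain_modulus(model: Model) -> float:
    """Small-strain shear modulus in MPa (matrix contribution only for the
    anisotropic model): 2*C10 resp. 2*c10."""
    if isinstance(model, IsotropicModel):
        return 2.0 * model.C10
    return 2.0 * model.c10 / 1000.0


def export_stress_stretch_csv(model: Model, path, stretches=None,
                              direction: str = "circumferential") -> None:
    """CSV of the uniaxial stress-stretch curve (stress in kPa)."""
    import pandas as pd

    if stretches is None:
        stretches = np.linspace(0.9, 1.2, 31)
    stress = uniaxial_response(model, stretches, direction)
    pd.DataFrame({"stretch": stretches, "cauchy_stress_kpa": stress}).to_csv(path, index=False)
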