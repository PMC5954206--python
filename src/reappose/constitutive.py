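"""Gasser–Ogden–Holzapfel (GOH) anisotropic hyperelasticity for aortic tissue.

The strain-energy density combines an isotropic neo-Hookean ground matrix with
two symmetric, dispersed collagen-fiber families at +/- ``alpha`` degrees from
the circumferential axis::

    Psi = C10 (I1 - 3) + k1/(2 k2) * sum_{+-alpha} [exp(k2 E^2) - 1]
    E   = kappa (I1 - 3) + (1 - 3 kappa) (I4 - 1)

``kappa`` in [0, 1/3] measures in-plane fiber dispersion (1/3 = isotropic), and
the exponential fiber term is active only in tension (E > 0).  Both fiber
families share I4 = lambda_c^2 cos^2(alpha) + lambda_a^2 sin^2(alpha) under the
circumferential/axial loadings considered here, so they are evaluated jointly.

Three evaluation paths are provided:

* :func:`goh_energy` — scalar energy density for a biaxial deformation state;
* :func:`biaxial_cauchy_stress` — incompressible plane-stress Cauchy stresses,
  the quantity measured in planar biaxial testing;
* :func:`plane_strain_stress_tangent` / :func:`pk1_stress_tangent` — the
  nearly-incompressible plane-strain point kernel (stress + consistent
  tangent) used by the cross-section finite-element solver.

All stresses and moduli are in Pa; lengths in mm; angles in degrees at the
interface (radians internally).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

MMHG_TO_PA = 133.322
"""1 mmHg in Pa."""

PA_TO_MMHG = 1.0 / MMHG_TO_PA

# exp(k2 E^2) beyond this argument signals a run-away stretch state
_EXP_ARG_MAX = 200.0


class ConstitutiveError(ValueError):
    """Invalid material parameters or deformation state."""


class OverflowStateError(ConstitutiveError):
    """exp(k2 E^2) argument out of range — check the stretch range of the input."""


class InvertedElementError(RuntimeError):
    """Non-positive deformation-gradient determinant."""

    def __init__(self, element_ids):
        self.element_ids = np.atleast_1d(element_ids)
        super().__init__(f"inverted element(s): {self.element_ids.tolist()}")


@dataclass(frozen=True)
class GOHParameters:
    """One tissue layer's GOH material parameters.

    Parameters
    ----------
    c10 : float
        Ground-matrix stiffness (Pa); the initial shear modulus is ``2*c10``.
    k1 : float
        Fiber stiffness (Pa).
    k2 : float
        Dimensionless fiber exponent.
    alpha_deg : float
        Fiber angle from the circumferential axis, degrees, in [0, 90].
    kappa : float
        Fiber dispersion, in [0, 1/3].
    thickness_mm : float
        Layer thickness (mm).
    label : str
        Layer / specimen identifier.
    """

    c10: float
    k1: float
    k2: float
    alpha_deg: float
    kappa: float
    thickness_mm: float
    label: str = ""

    def __post_init__(self):
        checks = [
            (self.c10 > 0, "c10 must be > 0"),
            (self.k1 >= 0, "k1 must be >= 0"),
            (self.k2 > 0, "k2 must be > 0"),
            (0.0 <= self.alpha_deg <= 90.0, "alpha_deg must be in [0, 90]"),
            (0.0 <= self.kappa <= 1.0 / 3.0 + 1e-12, "kappa must be in [0, 1/3]"),
            (self.thickness_mm > 0, "thickness_mm must be > 0"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ConstitutiveError(f"{msg} (got {self})")

    @property
    def alpha_rad(self) -> float:
        return np.deg2rad(self.alpha_deg)

    @property
    def mu(self) -> float:
        """Initial shear modulus 2*c10 (Pa)."""
        return 2.0 * self.c10

    def replace(self, **kw) -> "GOHParameters":
        d = dict(
            c10=self.c10, k1=self.k1, k2=self.k2, alpha_deg=self.alpha_deg,
            kappa=self.kappa, thickness_mm=self.thickness_mm, label=self.label,
        )
        d.update(kw)
        return GOHParameters(**d)


@dataclass(frozen=True)
class DeformationState:
    """Principal biaxial deformation state (circumferential/axial/radial).

    Incompressibility ties the radial stretch to the in-plane pair,
    ``lambda_r = 1/(lambda_c*lambda_a)``; the invariants I1, I4 and the
    dispersion-weighted fiber strain E are stored alongside.
    """

    lambda_c: float
    lambda_a: float
    lambda_r: float
    i1: float
    i4: float
    e_fiber: float

    def __post_init__(self):
        if min(self.lambda_c, self.lambda_a, self.lambda_r) <= 0:
            raise ConstitutiveError("stretches must be positive")
        if abs(self.lambda_c * self.lambda_a * self.lambda_r - 1.0) > 1e-10:
            raise ConstitutiveError("lambda_c*lambda_a*lambda_r must equal 1")
        if self.i1 < 3.0 - 1e-10:
            raise ConstitutiveError("i1 must be >= 3")
        if self.i4 <= 0:
            raise ConstitutiveError("i4 must be positive")

    @classmethod
    def biaxial(cls, params: GOHParameters, lambda_c: float, lambda_a: float) -> "DeformationState":
        """State for an incompressible biaxial stretch under ``params``' fiber angle."""
        if lambda_c <= 0 or lambda_a <= 0:
            raise ConstitutiveError("stretches must be positive")
        lr = 1.0 / (lambda_c * lambda_a)
        i1 = lambda_c**2 + lambda_a**2 + lr**2
        ca, sa = np.cos(params.alpha_rad), np.sin(params.alpha_rad)
        i4 = lambda_c**2 * ca**2 + lambda_a**2 * sa**2
        e = params.kappa * (i1 - 3.0) + (1.0 - 3.0 * params.kappa) * (i4 - 1.0)
        return cls(lambda_c, lambda_a, lr, i1, i4, e)


# ---------------------------------------------------------------------------
# fiber-term scalar responses (shared by every evaluation path)
# ---------------------------------------------------------------------------

def _fiber_psi_g_h(params: GOHParameters, e):
    """(psi_f, dpsi_f/dE, d2psi_f/dE2) for both families combined, tension-only."""
    e = np.asarray(e, dtype=float)
    active = (e > 0.0) & (params.k1 > 0.0)
    arg = params.k2 * e**2
    if np.any(arg[active] > _EXP_ARG_MAX):
        raise OverflowStateError(
            "exp(k2*E^2) argument exceeds bound — check the stretch range of the input"
        )
    ex = np.exp(np.where(active, np.minimum(arg, _EXP_ARG_MAX), 0.0))
    psi = np.where(active, (params.k1 / params.k2) * (ex - 1.0), 0.0)
    g = np.where(active, 2.0 * params.k1 * e * ex, 0.0)
    h = np.where(active, 2.0 * params.k1 * ex * (1.0 + 2.0 * params.k2 * e**2), 0.0)
    return psi, g, h


def goh_energy(params: GOHParameters, state: DeformationState) -> float:
    """Strain-energy density Psi (Pa) at a biaxial deformation state."""
    psi_f, _, _ = _fiber_psi_g_h(params, state.e_fiber)
    return float(params.c10 * (state.i1 - 3.0) + psi_f)


def biaxial_cauchy_stress(params: GOHParameters, lambda_c, lambda_a):
    """In-plane Cauchy stresses (sigma_cc, sigma_aa) in Pa under incompressible
    plane stress (sigma_rr = 0), the planar-biaxial testing condition.

    Accepts scalars or broadcasting arrays of stretches.
    """
    lc = np.asarray(lambda_c, dtype=float)
    la = np.asarray(lambda_a, dtype=float)
    if np.any(lc <= 0) or np.any(la <= 0):
        raise ConstitutiveError("stretches must be positive")
    lr2 = 1.0 / (lc * la) ** 2
    i1 = lc**2 + la**2 + lr2
    ca2 = np.cos(params.alpha_rad) ** 2
    sa2 = 1.0 - ca2
    i4 = lc**2 * ca2 + la**2 * sa2
    e = params.kappa * (i1 - 3.0) + (1.0 - 3.0 * params.kappa) * (i4 - 1.0)
    _, g, _ = _fiber_psi_g_h(params, e)
    kap, okap = params.kappa, 1.0 - 3.0 * params.kappa
    scc = 2.0 * params.c10 * (lc**2 - lr2) + g * (2.0 * kap * (lc**2 - lr2) + 2.0 * okap * lc**2 * ca2)
    saa = 2.0 * params.c10 * (la**2 - lr2) + g * (2.0 * kap * (la**2 - lr2) + 2.0 * okap * la**2 * sa2)
    if np.ndim(lambda_c) == 0 and np.ndim(lambda_a) == 0:
        return float(scc), float(saa)
    return scc, saa


# ---------------------------------------------------------------------------
# plane-strain point kernel (vectorized over leading axes of F)
# ---------------------------------------------------------------------------

def _plane_strain_core(params: GOHParameters, F, circ_dir, kvol, element_ids=None,
                       want_tangent: bool = True):
    """PK1 stress and tangent dP/dF for in-plane F (..., 2, 2).

    The fiber lies at ``alpha`` to the circumferential direction in the
    circumferential-axial plane; its in-plane component follows ``circ_dir``
    (reference circumferential unit vector, (..., 2)) and its out-of-plane
    component rides at the fixed plane-strain stretch of 1, so
    I4 = cos^2(a) * |F t|^2 + sin^2(a).

    Returns (P_iso + P_vol, A_iso + A_vol, J, E).
    """
    F = np.asarray(F, dtype=float)
    t = np.broadcast_to(np.asarray(circ_dir, dtype=float), F.shape[:-2] + (2,))
    J = F[..., 0, 0] * F[..., 1, 1] - F[..., 0, 1] * F[..., 1, 0]
    if np.any(J <= 0):
        bad = np.nonzero(J <= 0)
        ids = element_ids[bad[0]] if element_ids is not None and len(bad) else bad
        raise InvertedElementError(ids if element_ids is not None else np.atleast_1d(bad[0]))

    C11 = np.einsum("...ki,...kj->...ij", F, F)  # in-plane C
    i1 = C11[..., 0, 0] + C11[..., 1, 1] + 1.0
    Ft = np.einsum("...ij,...j->...i", F, t)
    tCt = np.einsum("...i,...i->...", Ft, Ft)
    ca2 = np.cos(params.alpha_rad) ** 2
    sa2 = 1.0 - ca2
    i4 = ca2 * tCt + sa2
    e = params.kappa * (i1 - 3.0) + (1.0 - 3.0 * params.kappa) * (i4 - 1.0)
    _, g, h = _fiber_psi_g_h(params, e)

    kap, okap = params.kappa, 1.0 - 3.0 * params.kappa
    # dE/dF = 2 kap F + 2 (1-3 kap) cos^2(a) (F t) x t
    Ftt = np.einsum("...i,...j->...ij", Ft, t)
    dE = 2.0 * kap * F + 2.0 * okap * ca2 * Ftt

    P = 2.0 * params.c10 * F + g[..., None, None] * dE

    # compressible neo-Hookean correction -2 c10 ln J (stress-free reference)
    # plus volumetric penalty U = kvol/2 (J-1)^2 ; in 2D, G = dJ/dF is linear in F
    G = np.empty_like(F)
    G[..., 0, 0] = F[..., 1, 1]
    G[..., 1, 1] = F[..., 0, 0]
    G[..., 0, 1] = -F[..., 1, 0]
    G[..., 1, 0] = -F[..., 0, 1]
    Jb = J[..., None, None]
    P = P - 2.0 * params.c10 * G / Jb
    if kvol != 0.0:
        P = P + kvol * (Jb - 1.0) * G

    if not want_tangent:
        return P, None, J, e

    I2 = np.eye(2)
    dd = np.einsum("ik,jl->ijkl", I2, I2)
    # d2E/dF2 = 2 kap (dik djl) + 2 (1-3 kap) cos^2(a) dik t_j t_l
    t_outer = np.einsum("...j,...l->...jl", t, t)
    d2E = 2.0 * kap * dd + 2.0 * okap * ca2 * np.einsum("ik,...jl->...ijkl", I2, t_outer)
    A = (
        2.0 * params.c10 * dd
        + g[..., None, None, None, None] * d2E
        + h[..., None, None, None, None] * np.einsum("...ij,...kl->...ijkl", dE, dE)
    )
    D = np.zeros((2, 2, 2, 2))
    D[0, 0, 1, 1] = D[1, 1, 0, 0] = 1.0
    D[0, 1, 1, 0] = D[1, 0, 0, 1] = -1.0
    GG = np.einsum("...ij,...kl->...ijkl", G, G)
    Jb4 = J[..., None, None, None, None]
    A = A - 2.0 * params.c10 * (D / Jb4 - GG / Jb4**2)
    if kvol != 0.0:
        A = A + kvol * (GG + (Jb4 - 1.0) * D)
    return P, A, J, e


def pk1_stress_tangent(params: GOHParameters, F, kvol: float, circ_dir=(1.0, 0.0),
                       element_ids=None):
    """First Piola-Kirchhoff stress and consistent tangent dP/dF (vectorized)."""
    P, A, J, _ = _plane_strain_core(params, F, circ_dir, kvol, element_ids)
    return P, A


def plane_strain_stress_tangent(params: GOHParameters, F, kvol: float,
                                circ_dir=(1.0, 0.0)):
    """Cauchy stress (2x2, symmetric) and consistent tangent dP/dF at one point.

    ``F`` is the in-plane deformation gradient (out-of-plane stretch fixed at
    1); near-incompressibility enters through the volumetric penalty modulus
    ``kvol`` (Pa).  The tangent is returned as the 2x2x2x2 derivative of the
    PK1 stress with respect to F (what a total-Lagrangian Newton solver
    assembles).
    """
    F = np.asarray(F, dtype=float)
    P, A, J, _ = _plane_strain_core(params, F, circ_dir, kvol)
    sigma = np.einsum("...ij,...kj->...ik", P, F) / J[..., None, None]
    sigma = 0.5 * (sigma + np.swapaxes(sigma, -1, -2))
    return sigma, A


# ---------------------------------------------------------------------------
# parameter-table I/O
# ---------------------------------------------------------------------------

_REQUIRED_COLS = ["label", "c10_pa", "k1_pa", "k2", "alpha_deg", "kappa", "thickness_mm"]


def _params_from_row(row) -> GOHParameters:
    return GOHParameters(
        c10=float(row["c10_pa"]), k1=float(row["k1_pa"]), k2=float(row["k2"]),
        alpha_deg=float(row["alpha_deg"]), kappa=float(row["kappa"]),
        thickness_mm=float(row["thickness_mm"]), label=str(row["label"]),
    )


def read_parameter_csv(path) -> dict[str, GOHParameters]:
    """Read a material-parameter CSV (columns label, c10_pa, k1_pa, k2,
    alpha_deg, kappa, thickness_mm) into {label: GOHParameters}."""
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ConstitutiveError(f"parameter CSV missing columns {missing}")
    return {str(r["label"]): _params_from_row(r) for _, r in df.iterrows()}


def write_parameter_csv(path, params_list) -> None:
    rows = [
        dict(label=p.label, c10_pa=p.c10, k1_pa=p.k1, k2=p.k2, alpha_deg=p.alpha_deg,
             kappa=p.kappa, thickness_mm=p.thickness_mm)
        for p in params_list
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def _bundled(name: str) -> Path:
    return Path(resources.files("reappose.data") / name)


def load_flap_parameters() -> dict[str, GOHParameters]:
    """Per-pig flap parameter sets (labels mid_1..mid_5, distal_1..distal_4)."""
    return read_parameter_csv(_bundled("flap_goh_parameters.csv"))


def load_wall_parameters() -> dict[str, GOHParameters]:
    """TL-wall and FL-wall parameter sets (tl_wall, mid_fl_wall, distal_fl_wall)."""
    return read_parameter_csv(_bundled("wall_goh_parameters.csv"))
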