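"""Wing structural model: cantilever beam finite elements and modal basis.

The wing is idealized as a uniform Euler--Bernoulli cantilever of constant
chord, clamped at the root where it meets the wing hinge.  Its out-of-plane
bending is expanded in mass-normalized vibration modes; the dynamics modules
only ever see the modal data assembled here:

* natural frequencies ``omega_k`` (rad/s),
* mode shapes ``phi_k(y)`` normalized so the modal mass is one
  (units kg^-1/2, hence modal stiffness equals ``omega_k**2``),
* the modal coupling constant ``lambda_k = int mu y phi_k dy`` linking wing
  bending to thorax motion through the hinge,
* the aerodynamic surface integrals ``J3 = int_S y^3 dS``,
  ``J2_k = int_S y^2 phi_k dS`` and ``J1_kr = int_S y phi_k phi_r dS`` that
  appear in the quasi-steady blade-element drag.

The discretization uses two-node beam elements with cubic Hermite
interpolation and a consistent mass matrix, validated against the closed-form
uniform cantilever (``(beta_k L)^2 sqrt(EI/(mu L^4))`` with
``beta_1 L = 1.875104...``).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from numpy.polynomial.legendre import leggauss
from scipy.linalg import eigh

__all__ = [
    "WingGeometry",
    "WingModalBasis",
    "CANTILEVER_BETA_L",
    "assemble_beam_fem",
    "solve_modes",
    "tune_stiffness",
    "retain_modes",
    "modal_integrals",
    "build_modal_basis",
    "youngs_modulus",
    "cantilever_frequency",
]

#: Roots of cosh(bL)cos(bL) = -1, the clamped-free beam eigenvalue equation.
CANTILEVER_BETA_L = (1.875104068711961, 4.694091132974175, 7.854757438237613)


class ParameterError(ValueError):
    """A physical parameter is outside its admissible range."""


@dataclass(frozen=True)
class WingGeometry:
    """Uniform rectangular-planform wing.

    Parameters
    ----------
    length : float
        Span ``L`` from root to tip (m).
    chord : float
        Constant chord width ``w`` (m).
    thickness : float
        Membrane thickness ``t_w`` (m).
    mass : float
        Total wing mass ``m_w`` (kg), assumed uniformly distributed.
    """

    length: float
    chord: float
    thickness: float
    mass: float

    def __post_init__(self) -> None:
        for name in ("length", "chord", "thickness", "mass"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"wing {name} must be strictly positive")

    @property
    def mu(self) -> float:
        """Mass per unit span (kg/m)."""
        return self.mass / self.length

    @property
    def inertia(self) -> float:
        """Rotational inertia about the root, ``I_O = m_w L^2 / 3`` (kg m^2)."""
        return self.mass * self.length**2 / 3.0


@dataclass(frozen=True)
class WingModalBasis:
    """Retained mass-normalized bending modes of one wing.

    ``n_modes == 0`` encodes a rigid wing.  Mode shapes are stored as nodal
    (deflection, slope) pairs of the Hermite discretization and evaluated by
    cubic interpolation; the sign convention is ``phi_k(L) > 0``.
    """

    geometry: WingGeometry
    bending_rigidity: float                 # EI, N m^2
    omega: np.ndarray                       # (K,) rad/s, ascending
    nodes: np.ndarray                       # (n_nodes,) nodal y coordinates, m
    shapes: np.ndarray                      # (K, n_nodes) nodal deflections, kg^-1/2
    slopes: np.ndarray                      # (K, n_nodes) nodal slopes, kg^-1/2 m^-1
    lam: np.ndarray = field(default=None)   # (K,) modal coupling, kg^1/2 m
    J3: float = field(default=None)         # m^5
    J2: np.ndarray = field(default=None)    # (K,) kg^-1/2 m^4
    J1: np.ndarray = field(default=None)    # (K, K) kg^-1 m^3

    @property
    def n_modes(self) -> int:
        return len(self.omega)

    @property
    def frequencies_hz(self) -> np.ndarray:
        return np.asarray(self.omega) / (2.0 * np.pi)

    def phi(self, y, k: int):
        """Evaluate mode ``k`` at spanwise positions ``y`` (Hermite cubic)."""
        y = np.asarray(y, dtype=float)
        if np.any(y < -1e-12) or np.any(y > self.geometry.length * (1 + 1e-12)):
            raise ParameterError("y outside [0, L]")
        le = self.nodes[1] - self.nodes[0]
        idx = np.clip((y / le).astype(int), 0, len(self.nodes) - 2)
        xi = (y - self.nodes[idx]) / le
        h1, h2, h3, h4 = _hermite_shape_functions(xi, le)
        return (h1 * self.shapes[k, idx] + h2 * self.slopes[k, idx]
                + h3 * self.shapes[k, idx + 1] + h4 * self.slopes[k, idx + 1])

    def tip_values(self) -> np.ndarray:
        """``phi_k(L)`` for every retained mode."""
        return self.shapes[:, -1].copy()

    # -- CSV round trip -----------------------------------------------------

    def to_csv(self, summary_path, shapes_path) -> None:
        """Write frequencies/coupling constants and nodal shape samples."""
        k = np.arange(1, self.n_modes + 1)
        summary = pd.DataFrame(
            {
                "mode": k,
                "frequency_hz": self.frequencies_hz,
                "lambda_kg05_m": self.lam,
                "J2_kg-05_m4": self.J2,
            }
        )
        summary.attrs["EI"] = self.bending_rigidity
        header = (
            f"# L_m={float(self.geometry.length)!r},w_m={float(self.geometry.chord)!r},"
            f"t_m={float(self.geometry.thickness)!r},m_kg={float(self.geometry.mass)!r},"
            f"EI_N_m2={float(self.bending_rigidity)!r},J3_m5={float(self.J3)!r}\n"
        )
        with open(summary_path, "w") as fh:
            fh.write(header)
            summary.to_csv(fh, index=False)
        cols = {"y_m": self.nodes}
        for i in range(self.n_modes):
            cols[f"phi_{i + 1}"] = self.shapes[i]
            cols[f"dphi_{i + 1}"] = self.slopes[i]
        pd.DataFrame(cols).to_csv(shapes_path, index=False)

    @classmethod
    def from_csv(cls, summary_path, shapes_path) -> "WingModalBasis":
        with open(summary_path) as fh:
            meta_line = fh.readline().lstrip("# ").strip()
            summary = pd.read_csv(fh, float_precision="round_trip")
        meta = dict(item.split("=") for item in meta_line.split(","))
        geom = WingGeometry(
            length=float(meta["L_m"]), chord=float(meta["w_m"]),
            thickness=float(meta["t_m"]), mass=float(meta["m_kg"]),
        )
        nodal = pd.read_csv(shapes_path, float_precision="round_trip")
        n_modes = len(summary)
        shapes = np.array([nodal[f"phi_{i + 1}"].to_numpy() for i in range(n_modes)])
        slopes = np.array([nodal[f"dphi_{i + 1}"].to_numpy() for i in range(n_modes)])
        basis = cls(
            geometry=geom,
            bending_rigidity=float(meta["EI_N_m2"]),
            omega=2 * np.pi * summary["frequency_hz"].to_numpy(),
            nodes=nodal["y_m"].to_numpy(),
            shapes=shapes,
            slopes=slopes,
        )
        return modal_integrals(basis)


# ---------------------------------------------------------------------------
# Finite element assembly
# ---------------------------------------------------------------------------

def _element_matrices(EI: float, mu: float, le: float):
    """Stiffness and consistent mass matrix of one Hermite beam element."""
    l2, l3 = le**2, le**3
    Ke = EI / l3 * np.array(
        [
            [12.0, 6 * le, -12.0, 6 * le],
            [6 * le, 4 * l2, -6 * le, 2 * l2],
            [-12.0, -6 * le, 12.0, -6 * le],
            [6 * le, 2 * l2, -6 * le, 4 * l2],
        ]
    )
    Me = mu * le / 420.0 * np.array(
        [
            [156.0, 22 * le, 54.0, -13 * le],
            [22 * le, 4 * l2, 13 * le, -3 * l2],
            [54.0, 13 * le, 156.0, -22 * le],
            [-13 * le, -3 * l2, -22 * le, 4 * l2],
        ]
    )
    return Ke, Me


def assemble_beam_fem(
    geometry: WingGeometry,
    bending_rigidity: float,
    n_elements: int = 50,
    clamped: bool = True,
):
    """Assemble mass and stiffness matrices of the spanwise beam.

    Two degrees of freedom per node (transverse deflection, slope).  With
    ``clamped=True`` the two root DOFs are eliminated, yielding the
    clamped-free wing; ``clamped=False`` returns the free-free matrices
    (useful for rigid-body checks).
    """
    if bending_rigidity <= 0:
        raise ParameterError("bending rigidity EI must be strictly positive")
    if n_elements < 4:
        raise ParameterError("n_elements must be >= 4")
    le = geometry.length / n_elements
    ndof = 2 * (n_elements + 1)
    K = np.zeros((ndof, ndof))
    M = np.zeros((ndof, ndof))
    Ke, Me = _element_matrices(bending_rigidity, geometry.mu, le)
    for e in range(n_elements):
        sl = slice(2 * e, 2 * e + 4)
        K[sl, sl] += Ke
        M[sl, sl] += Me
    if clamped:
        K = K[2:, 2:]
        M = M[2:, 2:]
    if np.linalg.cond(M) > 1e14:
        raise RuntimeError("assembled mass matrix is numerically singular")
    return M, K


def _hermite_shape_functions(xi, le):
    """Cubic Hermite shape functions on [0, 1] (slope DOFs scaled by le)."""
    h1 = 1 - 3 * xi**2 + 2 * xi**3
    h2 = le * (xi - 2 * xi**2 + xi**3)
    h3 = 3 * xi**2 - 2 * xi**3
    h4 = le * (xi**3 - xi**2)
    return h1, h2, h3, h4


def solve_modes(
    mass_matrix: np.ndarray,
    stiffness_matrix: np.ndarray,
    geometry: WingGeometry,
    bending_rigidity: float,
    n_modes: int = 6,
) -> WingModalBasis:
    """Solve the clamped-beam eigenproblem and mass-normalize the shapes.

    The symmetric generalized eigensolver returns eigenvectors with unit
    modal mass (``v.T M v = 1``), which for the consistent mass matrix equals
    ``int mu phi^2 dy = 1`` exactly on the Hermite interpolants.
    """
    n = mass_matrix.shape[0]
    if n_modes > n:
        raise ParameterError("n_modes exceeds the number of free DOFs")
    try:
        vals, vecs = eigh(stiffness_matrix, mass_matrix)
    except np.linalg.LinAlgError as exc:  # pragma: no cover - defensive
        raise RuntimeError(
            "eigensolver failed; cond(M)="
            f"{np.linalg.cond(mass_matrix):.3e}, cond(K)="
            f"{np.linalg.cond(stiffness_matrix):.3e}"
        ) from exc
    vals = vals[:n_modes]
    vecs = vecs[:, :n_modes]
    omega = np.sqrt(np.clip(vals, 0.0, None))
    n_nodes = n // 2 + 1
    shapes = np.zeros((n_modes, n_nodes))
    slopes = np.zeros((n_modes, n_nodes))
    shapes[:, 1:] = vecs[0::2].T
    slopes[:, 1:] = vecs[1::2].T
    # sign convention: positive tip deflection
    flip = np.sign(shapes[:, -1])
    flip[flip == 0] = 1.0
    shapes *= flip[:, None]
    slopes *= flip[:, None]
    nodes = np.linspace(0.0, geometry.length, n_nodes)
    return WingModalBasis(
        geometry=geometry,
        bending_rigidity=bending_rigidity,
        omega=omega,
        nodes=nodes,
        shapes=shapes,
        slopes=slopes,
    )


def cantilever_frequency(geometry: WingGeometry, bending_rigidity: float,
                         mode: int = 1) -> float:
    """Closed-form uniform clamped-free beam frequency (Hz)."""
    bL = CANTILEVER_BETA_L[mode - 1]
    omega = bL**2 * np.sqrt(
        bending_rigidity / (geometry.mu * geometry.length**4)
    )
    return omega / (2 * np.pi)


def tune_stiffness(
    geometry: WingGeometry, target_f1_hz: float, n_elements: int = 50
) -> float:
    """Bending rigidity EI that places the FEM first frequency at the target.

    Frequency scales as sqrt(EI), so one reference eigensolve at EI = 1
    determines EI in closed form.
    """
    if not target_f1_hz > 0:
        raise ParameterError("target first frequency must be positive")
    M, K = assemble_beam_fem(geometry, 1.0, n_elements)
    basis = solve_modes(M, K, geometry, 1.0, n_modes=1)
    f1_ref = basis.frequencies_hz[0]
    return (target_f1_hz / f1_ref) ** 2


def retain_modes(basis: WingModalBasis, flap_frequency_hz: float) -> WingModalBasis:
    """Keep modes with natural frequency below 10x the flapping frequency.

    Higher modes are not excited appreciably by the drive.  The result may
    retain zero modes, which degenerates to the rigid wing.
    """
    keep = basis.frequencies_hz < 10.0 * flap_frequency_hz
    out = replace(
        basis,
        omega=basis.omega[keep],
        shapes=basis.shapes[keep],
        slopes=basis.slopes[keep],
    )
    if basis.lam is not None:
        out = replace(
            out,
            lam=basis.lam[keep],
            J2=basis.J2[keep],
            J1=basis.J1[np.ix_(keep, keep)],
        )
    return out


def modal_integrals(basis: WingModalBasis, n_gauss: int = 4) -> WingModalBasis:
    """Fill lambda_k, J3, J2_k, J1_kr by element-wise Gauss quadrature.

    The quadrature acts on the Hermite interpolants; with four points per
    element every integrand (degree <= y * cubic * cubic = 7) is integrated
    exactly.  J3 has the constant-chord closed form w L^4 / 4 and is stored
    analytically.
    """
    geom = basis.geometry
    le = basis.nodes[1] - basis.nodes[0]
    gp, gw = leggauss(n_gauss)
    xi = 0.5 * (gp + 1.0)          # quadrature points on [0, 1]
    wq = 0.5 * gw * le             # weights on the physical element
    h1, h2, h3, h4 = _hermite_shape_functions(xi, le)
    K = basis.n_modes
    n_el = len(basis.nodes) - 1
    # phi values at all quadrature points: (K, n_el, n_gauss)
    phi = (
        h1 * basis.shapes[:, :-1, None] + h2 * basis.slopes[:, :-1, None]
        + h3 * basis.shapes[:, 1:, None] + h4 * basis.slopes[:, 1:, None]
    ) if K else np.zeros((0, n_el, n_gauss))
    y = basis.nodes[:-1, None] + xi * le   # (n_el, n_gauss)
    lam = np.array([np.sum(wq * geom.mu * y * phi[k]) for k in range(K)])
    J2 = np.array([np.sum(wq * geom.chord * y**2 * phi[k]) for k in range(K)])
    J1 = np.array(
        [
            [np.sum(wq * geom.chord * y * phi[k] * phi[r]) for r in range(K)]
            for k in range(K)
        ]
    ).reshape(K, K)
    J3 = geom.chord * geom.length**4 / 4.0
    return replace(basis, lam=lam, J3=J3, J2=J2, J1=J1)


def build_modal_basis(
    geometry: WingGeometry,
    f1_hz: float = 60.0,
    n_elements: int = 50,
    n_modes: int = 4,
    flap_frequency_hz: float | None = None,
) -> WingModalBasis:
    """Convenience pipeline: tune EI, solve modes, fill integrals, retain.

    ``flap_frequency_hz`` applies the mode-retention rule; ``None`` keeps all
    ``n_modes`` computed modes.
    """
    EI = tune_stiffness(geometry, f1_hz, n_elements)
    M, K = assemble_beam_fem(geometry, EI, n_elements)
    basis = solve_modes(M, K, geometry, EI, n_modes=n_modes)
    basis = modal_integrals(basis)
    if flap_frequency_hz is not None:
        basis = retain_modes(basis, flap_frequency_hz)
    return basis


def youngs_modulus(geometry: WingGeometry, bending_rigidity: float) -> float:
    """Young's modulus implied by EI for the rectangular section (reporting only)."""
    second_moment = geometry.chord * geometry.thickness**3 / 12.0
    return bending_rigidity / second_moment
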