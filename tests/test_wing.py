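"""Wing beam model: FEM validity, mode normalization, integrals, retention."""

import numpy as np
import pytest
from numpy.polynomial.legendre import leggauss

import flapsim as fs
from flapsim.wing import (
    CANTILEVER_BETA_L,
    ParameterError,
    WingModalBasis,
    assemble_beam_fem,
    cantilever_frequency,
    modal_integrals,
    solve_modes,
)

SIGMA_1 = 0.7340955139420148  # (sinh - sin)/(cosh + cos) at beta_1 L


def analytic_mode_1(y, geometry):
    """Mass-normalized first clamped-free mode of the uniform beam."""
    b = CANTILEVER_BETA_L[0] / geometry.length
    shape = (
        np.cosh(b * y) - np.cos(b * y)
        - SIGMA_1 * (np.sinh(b * y) - np.sin(b * y))
    )
    grid = np.linspace(0.0, geometry.length, 200001)
    ref = (
        np.cosh(b * grid) - np.cos(b * grid)
        - SIGMA_1 * (np.sinh(b * grid) - np.sin(b * grid))
    )
    norm = np.sqrt(np.trapezoid(geometry.mu * ref**2, grid))
    return shape / norm


def gauss_orthonormality(basis):
    """Element-wise Gauss quadrature of int mu phi_k phi_r dy."""
    geom = basis.geometry
    le = basis.nodes[1] - basis.nodes[0]
    gp, gw = leggauss(4)
    out = np.zeros((basis.n_modes, basis.n_modes))
    for e in range(len(basis.nodes) - 1):
        y = basis.nodes[e] + 0.5 * (gp + 1.0) * le
        w = 0.5 * gw * le
        vals = np.array([basis.phi(y, k) for k in range(basis.n_modes)])
        out += geom.mu * (vals * w) @ vals.T
    return out


def test_geometry_derived_quantities(geometry):
    assert geometry.mu * geometry.length == pytest.approx(geometry.mass, rel=1e-14)
    assert geometry.inertia == pytest.approx(
        geometry.mass * geometry.length**2 / 3.0, rel=1e-14
    )
    # hawkmoth-like value: 0.42 g cm^2 (printed to two figures)
    assert geometry.inertia == pytest.approx(0.42e-3 * 1e-4, rel=1e-2)


def test_geometry_rejects_nonpositive():
    with pytest.raises(ParameterError):
        fs.WingGeometry(length=-0.05, chord=0.018, thickness=50e-6, mass=50e-6)


def test_consistent_mass_matrix_preserves_total_mass(geometry):
    M, _ = assemble_beam_fem(geometry, 1e-4, n_elements=12, clamped=False)
    u = np.zeros(M.shape[0])
    u[0::2] = 1.0  # rigid translation: unit deflection, zero slope
    assert u @ M @ u == pytest.approx(geometry.mass, rel=1e-10)


def test_rigid_motion_stores_no_strain_energy(geometry):
    _, K = assemble_beam_fem(geometry, 3.7e-5, n_elements=12, clamped=False)
    n_nodes = K.shape[0] // 2
    y = np.linspace(0, geometry.length, n_nodes)
    scale = K.max()
    for u in (np.tile([1.0, 0.0], n_nodes),          # translation
              np.ravel(np.column_stack([y, np.ones(n_nodes)]))):  # rotation
        assert abs(u @ K @ u) < 1e-10 * scale


@pytest.mark.parametrize("n_elements", [10, 20, 50])
def test_fem_frequency_converges_to_closed_form(geometry, n_elements):
    EI = 7.2e-5
    M, K = assemble_beam_fem(geometry, EI, n_elements)
    basis = solve_modes(M, K, geometry, EI, n_modes=2)
    f_exact = cantilever_frequency(geometry, EI, mode=1)
    rel = abs(basis.frequencies_hz[0] - f_exact) / f_exact
    assert rel < 1e-3
    if n_elements == 50:
        assert rel < 1e-5


def test_fem_convergence_is_monotone(geometry):
    EI = 7.2e-5
    f_exact = cantilever_frequency(geometry, EI, mode=1)
    errors = []
    for n in (10, 20, 50):
        M, K = assemble_beam_fem(geometry, EI, n)
        basis = solve_modes(M, K, geometry, EI, n_modes=1)
        errors.append(abs(basis.frequencies_hz[0] - f_exact))
    assert errors[0] > errors[1] > errors[2]


def test_mode_shapes_are_orthonormal(default_cfg):
    basis = fs.build_modal_basis(default_cfg.wing, n_modes=3)
    gram = gauss_orthonormality(basis)
    assert np.allclose(gram, np.eye(3), atol=1e-8)


def test_frequency_ratio_matches_cantilever_eigenvalues(geometry):
    basis = fs.build_modal_basis(geometry, f1_hz=60.0, n_modes=2)
    ratio = basis.frequencies_hz[1] / basis.frequencies_hz[0]
    expected = (CANTILEVER_BETA_L[1] / CANTILEVER_BETA_L[0]) ** 2
    assert ratio == pytest.approx(expected, rel=2e-3)
    assert basis.frequencies_hz[1] == pytest.approx(6.2669 * 60.0, rel=2e-3)


def test_tune_stiffness_fixed_point_and_scaling(geometry):
    M, K = assemble_beam_fem(geometry, 1.0, 50)
    f_at_unity = solve_modes(M, K, geometry, 1.0, n_modes=1).frequencies_hz[0]
    assert fs.tune_stiffness(geometry, f_at_unity) == pytest.approx(1.0, rel=1e-12)
    EI_60 = fs.tune_stiffness(geometry, 60.0)
    EI_120 = fs.tune_stiffness(geometry, 120.0)
    assert EI_120 == pytest.approx(4.0 * EI_60, rel=1e-10)
    # closed-form check and round trip through the eigensolver
    EI_expected = (
        2 * np.pi * 60.0 / CANTILEVER_BETA_L[0] ** 2
    ) ** 2 * geometry.mu * geometry.length**4
    assert EI_60 == pytest.approx(EI_expected, rel=1e-4)
    M, K = assemble_beam_fem(geometry, EI_60, 50)
    f1 = solve_modes(M, K, geometry, EI_60, n_modes=1).frequencies_hz[0]
    assert f1 == pytest.approx(60.0, rel=1e-6)


@pytest.mark.parametrize(
    "flap_hz, expected_k",
    [(25.0, 1), (40.0, 2), (5.0, 0)],
)
def test_mode_retention_rule(geometry, flap_hz, expected_k):
    basis = fs.build_modal_basis(geometry, f1_hz=60.0, n_modes=4)
    assert fs.retain_modes(basis, flap_hz).n_modes == expected_k


def test_j3_constant_chord_closed_form(default_cfg):
    expected = 0.018 * 0.05**4 / 4.0
    assert default_cfg.basis.J3 == pytest.approx(expected, rel=1e-14)


def test_lambda_matches_analytic_mode_quadrature(default_cfg):
    geom = default_cfg.wing
    y = np.linspace(0, geom.length, 200001)
    lam_exact = np.trapezoid(geom.mu * y * analytic_mode_1(y, geom), y)
    assert default_cfg.basis.lam[0] == pytest.approx(lam_exact, rel=1e-3)
    assert default_cfg.basis.lam[0] > 0  # sign convention phi(L) > 0


def test_constant_shape_gives_half_span_coupling(geometry):
    """A flat test shape phi = 1/sqrt(m_w) has lambda = sqrt(m_w) L / 2."""
    n_nodes = 51
    basis = WingModalBasis(
        geometry=geometry,
        bending_rigidity=1.0,
        omega=np.array([1.0]),
        nodes=np.linspace(0, geometry.length, n_nodes),
        shapes=np.full((1, n_nodes), 1.0 / np.sqrt(geometry.mass)),
        slopes=np.zeros((1, n_nodes)),
    )
    filled = modal_integrals(basis)
    expected = np.sqrt(geometry.mass) * geometry.length / 2.0
    assert filled.lam[0] == pytest.approx(expected, rel=1e-12)


def test_integral_scaling_with_wing_mass(geometry):
    heavy = fs.WingGeometry(
        length=geometry.length, chord=geometry.chord,
        thickness=geometry.thickness, mass=4.0 * geometry.mass,
    )
    b1 = fs.build_modal_basis(geometry, f1_hz=60.0, n_modes=2)
    b4 = fs.build_modal_basis(heavy, f1_hz=60.0, n_modes=2)
    # mass normalization: phi ~ 1/sqrt(m_w), so lambda = mu int y phi dy
    # scales as sqrt(m_w) while the surface integrals J2 = w int y^2 phi dy
    # and J1 = w int y phi phi dy scale as 1/sqrt(m_w) and 1/m_w
    assert np.allclose(b4.lam, 2.0 * b1.lam, rtol=1e-8)
    assert np.allclose(b4.J2, 0.5 * b1.J2, rtol=1e-8)
    assert np.allclose(b4.J1, 0.25 * b1.J1, rtol=1e-8)


def test_integrals_stable_under_mesh_refinement(geometry):
    b50 = fs.build_modal_basis(geometry, f1_hz=60.0, n_elements=50, n_modes=2)
    b100 = fs.build_modal_basis(geometry, f1_hz=60.0, n_elements=100, n_modes=2)
    assert np.allclose(b100.lam, b50.lam, rtol=1e-3)
    assert np.allclose(b100.J2, b50.J2, rtol=1e-3)
    assert np.allclose(b100.J1, b50.J1, rtol=1e-3)
    assert np.allclose(b100.omega, b50.omega, rtol=1e-3)


def test_modal_basis_csv_round_trip(tmp_path, default_cfg):
    basis = fs.build_modal_basis(default_cfg.wing, n_modes=2)
    basis.to_csv(tmp_path / "summary.csv", tmp_path / "shapes.csv")
    back = WingModalBasis.from_csv(tmp_path / "summary.csv", tmp_path / "shapes.csv")
    assert np.allclose(back.omega, basis.omega, rtol=1e-12)
    assert np.allclose(back.lam, basis.lam, rtol=1e-10)
    assert np.allclose(back.J1, basis.J1, rtol=1e-10)
    assert back.geometry.mass == pytest.approx(basis.geometry.mass, rel=1e-12)


def test_assembly_rejects_bad_parameters(geometry):
    with pytest.raises(ParameterError):
        assemble_beam_fem(geometry, -1.0, 50)
    with pytest.raises(ParameterError):
        assemble_beam_fem(geometry, 1.0, 3)
    with pytest.raises(ParameterError):
        fs.tune_stiffness(geometry, -5.0)
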