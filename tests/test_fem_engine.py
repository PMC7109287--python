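"""Mesh construction, P1 assembly and norms, checked against brute-force oracles."""

import numpy as np
import pytest
import scipy.sparse as sp

from knpemi.fem_engine import (
    BlockSystem,
    InterfaceOperators,
    assemble_interface_coupling,
    assemble_mass,
    assemble_weighted_stiffness,
    build_structured_mesh,
    count_system_size,
    error_norms,
    solve_block_system,
)

UM = 1e-6


# ---------------------------------------------------------------------------
# mesh construction
# ---------------------------------------------------------------------------

def test_unit_square_minimal_mesh():
    m = build_structured_mesh((1.0, 1.0), (1.0, 1.0))
    assert len(m.cells) == 2
    assert len(m.points) == 4


def test_model_a_vertex_bookkeeping(model_a_mesh):
    """31x31 grid; the axon box holds 104 vertices, its membrane 56."""
    m = model_a_mesh
    assert len(m.points) == 961
    assert m.n_region_vertices(1) == 104
    assert m.interface.n_vertices == 56
    # interface vertices are duplicated: present in both subdomain maps
    iv = m.interface.vertices
    assert np.all(m.region_local[0][iv] >= 0)
    assert np.all(m.region_local[1][iv] >= 0)


def test_model_d_membrane_vertex_count():
    """Each 3D axon surface (313x3x3 vertex block) carries 2,506 vertices."""
    cells = [
        ((5 * UM, 395 * UM), (y0 * UM, (y0 + 0.2) * UM), (z0 * UM, (z0 + 0.2) * UM))
        for y0 in (0.3, 0.6, 0.9) for z0 in (0.3, 0.6, 0.9)
    ]
    m = build_structured_mesh((400 * UM, 1.4 * UM, 1.4 * UM),
                              (1.25 * UM, 0.1 * UM, 0.1 * UM), cells)
    counts = [(m.interface.vertex_cell == c).sum() for c in range(1, 10)]
    assert counts == [2506] * 9
    assert count_system_size(m, 3) == 401671


@pytest.mark.parametrize("dx_um, expected", [(2.0, 4125), (1.0, 15445)])
def test_system_size_model_a(dx_um, expected):
    m = build_structured_mesh(
        (60 * UM, 60 * UM), (dx_um * UM, dx_um * UM),
        [((6 * UM, 56 * UM), (28 * UM, 34 * UM))],
    )
    assert count_system_size(m, 3) == expected


def test_geometry_validation_errors():
    with pytest.raises(ValueError, match="not grid-aligned"):
        build_structured_mesh((10.0, 10.0), (1.0, 1.0), [((2.5, 4.0), (2.0, 4.0))])
    with pytest.raises(ValueError, match="boundary"):
        build_structured_mesh((10.0, 10.0), (1.0, 1.0), [((0.0, 4.0), (2.0, 4.0))])
    with pytest.raises(ValueError, match="overlap"):
        build_structured_mesh((10.0, 10.0), (1.0, 1.0),
                              [((2.0, 5.0), (2.0, 5.0)), ((4.0, 7.0), (4.0, 7.0))])


def test_interface_facets_pair_intra_extra(small_cell_mesh):
    m = small_cell_mesh
    iface = m.interface
    assert np.all(m.cell_labels[iface.facet_intra_simplex] == iface.facet_cell)
    assert np.all(m.cell_labels[iface.facet_extra_simplex] == 0)
    # membrane measure = box perimeter 2*(8+4) um
    assert iface.measure(1) == pytest.approx(24 * UM, rel=1e-12)


# ---------------------------------------------------------------------------
# assembly vs analytic values and a dense brute-force oracle
# ---------------------------------------------------------------------------

def test_mass_matrix_sums_to_subdomain_measure(model_a_mesh):
    M_i = assemble_mass(model_a_mesh, 1)
    assert M_i.sum() == pytest.approx(50 * UM * 6 * UM, rel=1e-12)
    M_e = assemble_mass(model_a_mesh, 0)
    assert M_e.sum() == pytest.approx(60 * UM * 60 * UM - 50 * UM * 6 * UM, rel=1e-12)


def test_reference_triangle_mass_matrix():
    m = build_structured_mesh((1.0, 1.0), (1.0, 1.0))
    M = assemble_mass(m, 0).toarray()
    # two reference triangles of area 1/2: check global row sums (1/3 per hat
    # on its support) and symmetry
    assert M.sum() == pytest.approx(1.0, abs=1e-15)
    assert np.allclose(M, M.T)
    # edge (0,1) belongs to one triangle of area 1/2: entry = area/12
    assert M[0, 1] == pytest.approx(0.5 / 12, abs=1e-15)
    # the diagonal edge (0,3) is shared by both triangles: entry = 2*area/12
    assert M[0, 3] == pytest.approx(2 * 0.5 / 12, abs=1e-15)
    # diagonal entries: 2*area/12 per incident triangle
    assert M[1, 1] == pytest.approx(2 * 0.5 / 12, abs=1e-15)


def test_stiffness_annihilates_constants(model_a_mesh):
    for lab in (0, 1):
        K = assemble_weighted_stiffness(model_a_mesh, lab)
        one = np.ones(K.shape[0])
        assert np.abs(K @ one).max() <= 1e-12 * np.abs(K.data).max()


def test_stiffness_dirichlet_energy_of_linear_field(plain_square_mesh):
    space = plain_square_mesh.space(0)
    u = space.coords[:, 0]
    K1 = space.stiffness_matrix()
    assert u @ (K1 @ u) == pytest.approx(1.0, rel=1e-12)     # int |grad x|^2 = 1
    Kx = space.stiffness_matrix(u)                            # weight c = x
    assert u @ (Kx @ u) == pytest.approx(0.5, rel=1e-12)      # int x dx = 1/2


def test_assembly_matches_dense_quadrature_oracle(tiny_cell_mesh):
    """Element-loop assembly with an independent quadrature reproduces the
    vectorized operators to near machine precision."""
    rng = np.random.default_rng(7)
    for lab in (0, 1):
        space = tiny_cell_mesh.space(lab)
        w = rng.uniform(0.5, 2.0, space.n)
        M = space.mass_matrix().toarray()
        K = space.stiffness_matrix(w).toarray()
        Mref = np.zeros_like(M)
        Kref = np.zeros_like(K)
        # degree-2 edge-midpoint rule, exact for the P1 x P1 mass integrand
        mid_bary = np.array([[0.5, 0.5, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5]])
        for tri in space.cells:
            X = space.coords[tri]
            area = 0.5 * abs(np.linalg.det(np.column_stack([X[1] - X[0], X[2] - X[0]])))
            # P1 basis gradients via the vertex-interpolation linear system
            V = np.column_stack([np.ones(3), X])
            C = np.linalg.inv(V)          # basis coefficients a + bx + cy
            grads = C[1:, :].T            # (3, 2)
            for a in range(3):
                for b in range(3):
                    Mref[tri[a], tri[b]] += area / 3 * np.sum(
                        mid_bary[:, a] * mid_bary[:, b])
                    cbar = w[tri].mean()
                    Kref[tri[a], tri[b]] += cbar * area * grads[a] @ grads[b]
        assert np.abs(M - Mref).max() < 1e-12 * np.abs(Mref).max()
        assert np.abs(K - Kref).max() < 1e-12 * np.abs(Kref).max()


# ---------------------------------------------------------------------------
# interface operators
# ---------------------------------------------------------------------------

def test_interface_mass_total_is_membrane_measure(model_a_mesh):
    MG, traces = assemble_interface_coupling(model_a_mesh)
    assert MG.sum() == pytest.approx(112 * UM, rel=1e-12)


def test_trace_of_constant_and_jump(model_a_mesh):
    MG, traces = assemble_interface_coupling(model_a_mesh)
    nv = model_a_mesh.interface.n_vertices
    one_i = np.ones(model_a_mesh.n_region_vertices(1))
    one_e = np.ones(model_a_mesh.n_region_vertices(0))
    assert np.allclose(traces[1] @ one_i, np.ones(nv))
    assert np.allclose(traces[0] @ one_e, np.ones(nv))
    jump = traces[1] @ (3.7 * one_i) - traces[0] @ (3.7 * one_e)
    assert np.abs(MG @ jump).max() < 1e-18


def test_interface_normals_point_out_of_cell(small_cell_mesh):
    iface = small_cell_mesh.interface
    pts = small_cell_mesh.points
    center = np.array([10 * UM, 10 * UM])
    fc = pts[iface.vertices][iface.facets].mean(axis=1)
    outward = np.einsum("ij,ij->i", iface.facet_normal, fc - center)
    assert np.all(outward > 0)


# ---------------------------------------------------------------------------
# block solve
# ---------------------------------------------------------------------------

def test_solve_identity_and_diagonal():
    A = sp.identity(5, format="csr")
    b = np.arange(5.0)
    assert np.allclose(solve_block_system((A, b)), b)
    A2 = sp.csr_matrix(np.diag([2.0, 4.0]))
    assert np.allclose(solve_block_system((A2, np.array([2.0, 8.0]))), [1.0, 2.0])


def test_solve_matches_dense_oracle():
    rng = np.random.default_rng(11)
    n = 50
    A = sp.random(n, n, density=0.2, random_state=rng.integers(2**31)).tocsr()
    A = A + sp.identity(n) * n       # well conditioned
    b = rng.standard_normal(n)
    x = solve_block_system((A, b))
    x_ref = np.linalg.solve(A.toarray(), b)
    assert np.abs(x - x_ref).max() <= 1e-10 * np.abs(x_ref).max()


def test_singular_system_raises(model_a_mesh):
    K = assemble_weighted_stiffness(model_a_mesh, 1)     # pure Neumann, singular
    b = np.zeros(K.shape[0])
    b[0] = 1.0
    with pytest.raises(RuntimeError):
        solve_block_system((K.tocsc(), b))


def test_block_system_layout(model_a_mesh):
    n = model_a_mesh.n_region_vertices(1)
    sys_ = BlockSystem([("a", n), ("b", 2)],
                       sp.identity(n + 2, format="csr"), np.zeros(n + 2))
    assert sys_.offsets["b"] == (n, n + 2)
    with pytest.raises(ValueError):
        BlockSystem([("a", n)], sp.identity(n + 1, format="csr"), np.zeros(n + 1))


# ---------------------------------------------------------------------------
# norms
# ---------------------------------------------------------------------------

def test_interpolant_of_linear_field_has_zero_error(plain_square_mesh):
    space = plain_square_mesh.space(0)
    u = 2.0 * space.coords[:, 0] - space.coords[:, 1]
    err = error_norms(space, u, lambda x, y: 2.0 * x - y, "L2")
    assert err < 1e-14


def test_l2_norm_of_sine_product(plain_square_mesh):
    space = plain_square_mesh.space(0)
    err = error_norms(space, np.zeros(space.n),
                      lambda x, y: np.sin(2 * np.pi * x) * np.sin(2 * np.pi * y), "L2")
    assert err == pytest.approx(0.5, rel=1e-4)


def test_broken_l2_of_constant_on_interface(model_a_mesh):
    ops = InterfaceOperators(model_a_mesh)
    err = error_norms(ops, np.ones(ops.nv), lambda x, y: 0.0, "brokenL2_interface")
    assert err == pytest.approx(np.sqrt(112 * UM), rel=1e-12)


def test_h1_requested_on_interface_errors(model_a_mesh):
    ops = InterfaceOperators(model_a_mesh)
    with pytest.raises(ValueError, match="interface"):
        error_norms(ops, np.ones(ops.nv), lambda x, y: 0.0, "H1")
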