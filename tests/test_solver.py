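import numpy as np
import pytest
import sympy

from bidomainuq.mesh import Mesh, _lateral_axis, _z_axis
from bidomainuq.solver import (
    SolverConfig,
    SourceParams,
    assemble,
    consistent_load,
    extract_epd,
    solve,
    solve_model,
)
from bidomainuq.features import extract_features
from bidomainuq.parameters import CONDUCTIVITY_NAMES, default_ranges


def _mean_params():
    r = default_ranges()
    return {n: r.mean[r.index(n)] for n in ("ROT", "g_b") + CONDUCTIVITY_NAMES}


class TestAssembly:
    def test_constant_transmembrane_field_gives_zero_rhs(self, tiny_mesh, mean_cset):
        sys_ = assemble(
            tiny_mesh, mean_cset, 100.0, SourceParams(depth=0.3),
            phi_m=np.ones(tiny_mesh.shape),
        )
        assert np.max(np.abs(sys_.rhs)) < 1e-10

    def test_matrix_symmetric(self, tiny_mesh, mean_cset):
        sys_ = assemble(tiny_mesh, mean_cset, 100.0, SourceParams(depth=0.3))
        diff = sys_.matrix - sys_.matrix.T
        assert np.max(np.abs(diff.data)) if diff.nnz else 0.0 < 1e-12

    def test_discrete_conservation_interior_rows(self, tiny_mesh, mean_cset):
        # applying the operator to a constant leaves only rows coupled to
        # the eliminated Dirichlet plane non-zero (flux telescoping)
        sys_ = assemble(tiny_mesh, mean_cset, 100.0, SourceParams(depth=0.3))
        nx, ny, nz = tiny_mesh.shape
        r = (sys_.matrix @ np.ones(nx * ny * (nz - 1))).reshape(nx, ny, nz - 1)
        scale = np.abs(sys_.matrix.data).max()
        assert np.max(np.abs(r[:, :, : nz - 3])) < 1e-10 * scale


class TestSolve:
    def test_zero_source_gives_zero_potential(self, tiny_mesh, mean_cset):
        sys_ = assemble(tiny_mesh, mean_cset, 100.0, SourceParams(depth=0.3, delta_phi=0.0))
        sol = solve(sys_)
        assert np.max(np.abs(sol.phi)) < 1e-10

    def test_pcg_matches_direct_factorization(self, tiny_mesh, mean_cset):
        sys_ = assemble(tiny_mesh, mean_cset, 100.0, SourceParams(depth=0.3))
        a = solve(sys_, SolverConfig(method="pcg"))
        b = solve(sys_, SolverConfig(method="direct"))
        assert np.max(np.abs(a.phi - b.phi)) < 1e-6
        assert a.residual < 1e-6

    def test_epd_point_symmetry_at_mean_inputs(self, mean_epd_depth30):
        v = mean_epd_depth30.values
        assert np.max(np.abs(v - v[::-1, ::-1])) < 1e-5 * np.max(np.abs(v))

    def test_extract_epd_dimensions(self, tiny_mesh, mean_cset):
        epd = solve_model(tiny_mesh, mean_cset, 100.0, 0.3)
        assert epd.values.shape == (len(tiny_mesh.x), len(tiny_mesh.y))


def _uniform_box_mesh(n: int) -> Mesh:
    axis = np.linspace(-8.0, 8.0, n + 1)
    return Mesh(x=axis, y=axis.copy(), z=np.linspace(0.0, 26.0, n + 1),
                n_tissue_layers=1)


def _mms_error(n: int, tensor: tuple[float, float, float, float]) -> float:
    """Relative L2 error of the scheme against a manufactured solution."""
    axx, ayy, azz, axy = tensor
    x, y, z = sympy.symbols("x y z")
    sigma = 1.5
    phi = sympy.exp(-(x**2 + y**2) / (2 * sigma**2)) * sympy.cos(sympy.pi * z / 52)
    f = -(
        axx * phi.diff(x, 2)
        + ayy * phi.diff(y, 2)
        + azz * phi.diff(z, 2)
        + 2 * axy * phi.diff(x, 1, y, 1)
    )
    mesh = _uniform_box_mesh(n)
    gx, gy, gz = np.meshgrid(mesh.x, mesh.y, mesh.z, indexing="ij")
    f_nodal = sympy.lambdify((x, y, z), f, "numpy")(gx, gy, gz)
    exact = sympy.lambdify((x, y, z), phi, "numpy")(gx, gy, gz)

    layers = np.ones(len(mesh.z) - 1)
    coeff = {"bulk_xx": axx * layers, "bulk_yy": ayy * layers,
             "bulk_zz": azz * layers, "bulk_xy": axy * layers}
    sys_ = assemble(mesh, None, 0.0, None, coeff=coeff,
                    rhs=consistent_load(mesh, f_nodal))
    sol = solve(sys_, SolverConfig(tolerance=1e-10))
    err = sol.phi - exact
    return float(np.linalg.norm(err) / np.linalg.norm(exact))


class TestManufacturedSolution:
    def test_second_order_convergence_full_tensor(self):
        """The scheme converges at order ~2 with mixed-derivative fluxes."""
        tensor = (3.0, 2.0, 1.5, 0.8)
        errors = [_mms_error(n, tensor) for n in (8, 16, 32)]
        rates = np.log2(np.array(errors[:-1]) / np.array(errors[1:]))
        assert np.all(np.array(errors) == sorted(errors, reverse=True))
        assert np.all(rates > 1.6) and np.all(rates < 2.6)


class TestQualitativeBehaviour:
    """One-at-a-time solver runs reproduce the published sign relations."""

    def test_depth_walk_through_pattern_classes(self, tiny_simulator):
        params = _mean_params()
        types = [
            extract_features(tiny_simulator(params, d)).epd_type
            for d in (0.1, 0.3, 0.6)
        ]
        assert types == ["depression_type1", "depression_type2", "elevation"]

    def test_increasing_g_in_deepens_central_minimum(self, tiny_simulator):
        lo, hi = dict(_mean_params(), g_in=0.05), dict(_mean_params(), g_in=0.15)
        f_lo = extract_features(tiny_simulator(lo, 0.3))
        f_hi = extract_features(tiny_simulator(hi, 0.3))
        assert f_hi.cminV < f_lo.cminV

    def test_increasing_g_en_raises_central_minimum(self, tiny_simulator):
        lo, hi = dict(_mean_params(), g_en=0.5), dict(_mean_params(), g_en=1.5)
        f_lo = extract_features(tiny_simulator(lo, 0.3))
        f_hi = extract_features(tiny_simulator(hi, 0.3))
        assert f_hi.cminV > f_lo.cminV

    def test_increasing_rotation_rotates_minimum_anticlockwise(self, tiny_simulator):
        lo, hi = dict(_mean_params(), ROT=60.0), dict(_mean_params(), ROT=140.0)
        f_lo = extract_features(tiny_simulator(lo, 0.3))
        f_hi = extract_features(tiny_simulator(hi, 0.3))
        assert f_hi.angmin > f_lo.angmin


class TestMeshConvergence:
    def test_feature_differences_shrink_under_refinement(self, mean_cset):
        """cminV/cmaxV/ominV approach a fine-mesh reference as the mesh refines."""
        def features_for(n_xy, n_t, n_b):
            axis = _lateral_axis(n_xy, 1.25)
            mesh = Mesh(x=axis, y=axis.copy(), z=_z_axis(n_t, n_b),
                        n_tissue_layers=n_t)
            return extract_features(solve_model(mesh, mean_cset, 100.0, 0.3))

        seq = [features_for(16, 8, 6), features_for(24, 12, 8),
               features_for(32, 20, 12)]
        ref = features_for(44, 28, 14)
        for name in ("cminV", "cmaxV", "ominV"):
            errs = [abs(getattr(f, name) - getattr(ref, name)) for f in seq]
            assert errs[2] < errs[0]
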