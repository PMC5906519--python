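"""Assembly and solution of the passive bidomain / blood volume-conductor problem.

The ST-segment extracellular potential solves the elliptic problem

    div( (M_i + M_e) grad phi_e ) = -div( M_i grad phi_m )   (tissue)
    g_b lap phi_b = 0                                        (blood)

with the potential and total normal current continuous across the
endocardium, insulated lateral walls and epicardium, and phi_b = 0 on the
bottom of the blood.  A single potential unknown per node covers both
regions, with the conductivity tensor switching from M_i + M_e to g_b I
across the interface and the intracellular (source) operator vanishing in
the blood, so the source current is confined to the tissue side.

Discretization is a vertex-centred control-volume/trilinear-element scheme
on the tensor-product mesh.  Because the tensors vary with z only (fibre
rotation about the z-axis), every term of the weak form factorizes into
Kronecker products of 1-D matrices; this makes assembly exact and cheap and
the mixed x-y fluxes introduced by fibre rotation fall out of the same
factorization.  The bottom Dirichlet plane is eliminated from the system,
leaving a symmetric positive-definite operator.

The default linear solver is conjugate gradients preconditioned by an exact
fast-diagonalization solve of the separable (cross-term-free) part of the
operator: generalized eigenbases of the 1-D stiffness/mass pencils in x and
y reduce it to independent tridiagonal systems in z, so each preconditioner
application costs O(n).  Only the fibre-rotation coupling is left to CG,
which converges in a few dozen iterations regardless of mesh size.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.linalg as sla
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mesh import Mesh
from .parameters import ConductivitySet
from .tissue import SourceParams, tensor_profiles, transmembrane_field

__all__ = [
    "SolverConfig",
    "LinearSystem",
    "PotentialSolution",
    "EPD",
    "assemble",
    "solve",
    "extract_epd",
    "solve_model",
]


class SolverError(RuntimeError):
    """Raised when the linear solver fails to converge."""


@dataclass(frozen=True)
class SolverConfig:
    """Linear-solver settings."""

    tolerance: float = 1e-8
    max_iterations: int = 400
    method: str = "pcg"  # 'pcg' (fast-diagonalization preconditioner) or 'direct'

    def __post_init__(self) -> None:
        if not 0.0 < self.tolerance < 1.0:
            raise ValueError("tolerance must lie in (0, 1)")


@dataclass
class EPD:
    """Epicardial potential distribution: the z = 0 node slice [mV]."""

    values: np.ndarray  # (nx, ny)
    x: np.ndarray
    y: np.ndarray
    footprint: float = 2.0

    @property
    def central_mask(self) -> np.ndarray:
        fx = np.abs(self.x) <= self.footprint + 1e-9
        fy = np.abs(self.y) <= self.footprint + 1e-9
        return fx[:, None] & fy[None, :]


@dataclass
class PotentialSolution:
    """Solved potential on all nodes, shape (nx, ny, nz)."""

    phi: np.ndarray
    residual: float
    iterations: int
    mesh: Mesh


def _mass_1d(coords: np.ndarray, weights: np.ndarray | None = None) -> sp.csr_matrix:
    h = np.diff(coords)
    w = h if weights is None else h * weights
    n = len(coords)
    main = np.zeros(n)
    main[:-1] += w / 3.0
    main[1:] += w / 3.0
    off = w / 6.0
    return sp.diags([off, main, off], [-1, 0, 1], format="csr")


def _stiffness_1d(coords: np.ndarray, weights: np.ndarray | None = None) -> sp.csr_matrix:
    h = np.diff(coords)
    w = 1.0 / h if weights is None else weights / h
    n = len(coords)
    main = np.zeros(n)
    main[:-1] += w
    main[1:] += w
    return sp.diags([-w, main, -w], [-1, 0, 1], format="csr")


def _gradient_1d(coords: np.ndarray) -> sp.csr_matrix:
    """C[i, j] = integral N_i N_j' dx (element matrix [[-1/2, 1/2], [-1/2, 1/2]])."""
    n = len(coords)
    main = np.zeros(n)
    main[:-1] += -0.5
    main[1:] += 0.5
    lower = np.full(n - 1, -0.5)
    upper = np.full(n - 1, 0.5)
    return sp.diags([lower, main, upper], [-1, 0, 1], format="csr")


@dataclass
class LinearSystem:
    """Assembled sparse system over the free (non-Dirichlet) nodes."""

    matrix: sp.csr_matrix
    rhs: np.ndarray
    mesh: Mesh
    z_parts: dict  # 1-D z matrices (Dirichlet-trimmed) for the preconditioner


# per-mesh cache of the lateral generalized eigenbases (mesh geometry only)
_EIG_CACHE: dict[bytes, dict] = {}


def _lateral_eigendata(mesh: Mesh) -> dict:
    key = mesh.x.tobytes() + mesh.y.tobytes()
    if key not in _EIG_CACHE:
        data = {}
        for name, coords in (("x", mesh.x), ("y", mesh.y)):
            s = _stiffness_1d(coords).toarray()
            m = _mass_1d(coords).toarray()
            lam, vec = sla.eigh(s, m)  # vec.T @ m @ vec = I
            data[name] = (lam, vec)
        if len(_EIG_CACHE) > 32:
            _EIG_CACHE.clear()
        _EIG_CACHE[key] = data
    return _EIG_CACHE[key]


def assemble(
    mesh: Mesh,
    cset: ConductivitySet | None,
    rot: float,
    src: SourceParams | None,
    phi_m: np.ndarray | None = None,
    coeff: dict[str, np.ndarray] | None = None,
    rhs: np.ndarray | None = None,
) -> LinearSystem:
    """Assemble the coupled tissue-blood system for one parameter set.

    The right-hand side is the weak divergence of the intracellular source
    current, -A_intra phi_m, built with the same flux discretization as the
    diffusion operator; insulated boundaries carry zero flux through the
    natural boundary conditions of the weak form.  The bottom blood plane
    (phi = 0) is eliminated, so the unknowns are nx * ny * (nz - 1).

    `coeff` overrides the per-layer tensor components (keys as produced by
    :func:`bidomainuq.tissue.tensor_profiles`) and `rhs` supplies a custom
    load vector on the free nodes; both serve verification problems such as
    manufactured solutions.
    """
    if coeff is None:
        coeff = tensor_profiles(mesh, cset, rot)
    x, y, z = mesh.x, mesh.y, mesh.z
    sx, sy = _stiffness_1d(x), _stiffness_1d(y)
    mx, my = _mass_1d(x), _mass_1d(y)
    cx, cy = _gradient_1d(x), _gradient_1d(y)

    def zmats(op: str) -> dict[str, sp.csr_matrix]:
        return {
            "xx": _mass_1d(z, coeff[f"{op}_xx"]),
            "yy": _mass_1d(z, coeff[f"{op}_yy"]),
            "zz": _stiffness_1d(z, coeff[f"{op}_zz"]),
            "xy": _mass_1d(z, coeff[f"{op}_xy"]),
        }

    def operator(zm: dict[str, sp.csr_matrix], trim: bool) -> sp.csr_matrix:
        sl = slice(None, -1) if trim else slice(None)
        zxx, zyy = zm["xx"][sl, sl], zm["yy"][sl, sl]
        zzz, zxy = zm["zz"][sl, sl], zm["xy"][sl, sl]
        a = (
            sp.kron(sx, sp.kron(my, zxx))
            + sp.kron(mx, sp.kron(sy, zyy))
            + sp.kron(mx, sp.kron(my, zzz))
        )
        if zxy.nnz and np.any(zxy.data):
            a = a + sp.kron(cx.T, sp.kron(cy, zxy)) + sp.kron(cx, sp.kron(cy.T, zxy))
        return a.tocsr()

    nx, ny, nz = mesh.shape
    if rhs is not None:
        b = np.asarray(rhs, float).copy()
    else:
        if phi_m is None:
            phi_m = transmembrane_field(mesh, src)
        b_full = -(operator(zmats("intra"), trim=False) @ phi_m.ravel())
        b = b_full.reshape(nx, ny, nz)[:, :, :-1].ravel()

    bulk = zmats("bulk")
    a = operator(bulk, trim=True)
    z_parts = {k: m[:-1, :-1].toarray() for k, m in bulk.items()}
    return LinearSystem(matrix=a, rhs=b, mesh=mesh, z_parts=z_parts)


def consistent_load(mesh: Mesh, f_nodal: np.ndarray) -> np.ndarray:
    """Load vector int N_i f dV on the free nodes, for verification problems."""
    mx, my, mz = _mass_1d(mesh.x), _mass_1d(mesh.y), _mass_1d(mesh.z)
    b = sp.kron(mx, sp.kron(my, mz)) @ np.asarray(f_nodal, float).ravel()
    nx, ny, nz = mesh.shape
    return b.reshape(nx, ny, nz)[:, :, :-1].ravel()


class _SeparablePreconditioner:
    """Exact inverse of the cross-term-free part of the assembled operator.

    In the generalized eigenbases of (S_x, M_x) and (S_y, M_y) the
    separable part becomes, for each lateral mode (i, j), the tridiagonal
    z-matrix  lam_x[i] * Mz[a_xx] + lam_y[j] * Mz[a_yy] + Sz[a_zz]; all
    mode systems are factorized once and solved in a vectorized Thomas
    sweep.
    """

    def __init__(self, system: LinearSystem):
        mesh = system.mesh
        eig = _lateral_eigendata(mesh)
        self.lam_x, self.ux = eig["x"]
        self.lam_y, self.uy = eig["y"]
        zp = system.z_parts
        nzr = zp["xx"].shape[0]
        self.shape3 = (len(self.lam_x), len(self.lam_y), nzr)

        lx = self.lam_x[:, None, None]
        ly = self.lam_y[None, :, None]

        def diagonals(m: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
            return np.diag(m).copy(), np.diag(m, 1).copy()

        dxx, oxx = diagonals(zp["xx"])
        dyy, oyy = diagonals(zp["yy"])
        dzz, ozz = diagonals(zp["zz"])
        diag = lx * dxx + ly * dyy + dzz  # (nx, ny, nzr)
        off = lx * oxx + ly * oyy + ozz  # (nx, ny, nzr-1)
        diag = np.broadcast_to(diag, self.shape3).copy()
        off = np.broadcast_to(off, self.shape3[:2] + (nzr - 1,)).copy()

        # vectorized LDL^T factorization of all tridiagonal mode systems
        self.d = diag
        self.e = off
        self.w = np.zeros_like(off)
        for k in range(1, nzr):
            self.w[:, :, k - 1] = off[:, :, k - 1] / self.d[:, :, k - 1]
            self.d[:, :, k] = diag[:, :, k] - self.w[:, :, k - 1] * off[:, :, k - 1]

    def solve(self, r: np.ndarray) -> np.ndarray:
        nx, ny, nzr = self.shape3
        rhat = np.einsum("ia,ajk->ijk", self.ux.T, r.reshape(nx, ny, nzr))
        rhat = np.einsum("jb,ibk->ijk", self.uy.T, rhat)
        # forward/backward Thomas sweeps across all modes at once
        for k in range(1, nzr):
            rhat[:, :, k] -= self.w[:, :, k - 1] * rhat[:, :, k - 1]
        rhat[:, :, -1] /= self.d[:, :, -1]
        for k in range(nzr - 2, -1, -1):
            rhat[:, :, k] = (rhat[:, :, k] - self.e[:, :, k] * rhat[:, :, k + 1]) / self.d[:, :, k]
        out = np.einsum("ia,ajk->ijk", self.ux, rhat)
        out = np.einsum("jb,ibk->ijk", self.uy, out)
        return out.ravel()


def solve(system: LinearSystem, config: SolverConfig = SolverConfig()) -> PotentialSolution:
    """Solve the assembled system and return the padded nodal potential."""
    a, b = system.matrix, system.rhs
    if config.method == "direct":
        lu = spla.splu(a.tocsc(), permc_spec="MMD_AT_PLUS_A")
        phi = lu.solve(b)
        iters = 1
    elif config.method == "pcg":
        prec = _SeparablePreconditioner(system)
        m = spla.LinearOperator(a.shape, prec.solve)
        count = {"n": 0}

        def cb(_):
            count["n"] += 1

        phi, info = spla.cg(
            a, b, rtol=config.tolerance, atol=0.0, maxiter=config.max_iterations,
            M=m, callback=cb,
        )
        iters = count["n"]
        if info != 0:
            raise SolverError(f"CG failed to converge (info={info}, iters={iters})")
    else:
        raise ValueError(f"unknown solver method {config.method!r}")

    bnorm = np.linalg.norm(b)
    residual = float(np.linalg.norm(a @ phi - b) / (bnorm if bnorm > 0 else 1.0))
    nx, ny, nz = system.mesh.shape
    full = np.zeros((nx, ny, nz))
    full[:, :, :-1] = phi.reshape(nx, ny, nz - 1)
    return PotentialSolution(phi=full, residual=residual, iterations=iters,
                             mesh=system.mesh)


def extract_epd(solution: PotentialSolution) -> EPD:
    """Slice the solved potential at the epicardium z = 0."""
    mesh = solution.mesh
    return EPD(values=solution.phi[:, :, 0].copy(), x=mesh.x, y=mesh.y,
               footprint=mesh.geometry.footprint)


def solve_model(
    mesh: Mesh,
    cset: ConductivitySet,
    rot: float,
    depth: float,
    config: SolverConfig = SolverConfig(),
) -> EPD:
    """Convenience wrapper: assemble, solve and return the epicardial slice."""
    src = SourceParams(depth=depth)
    system = assemble(mesh, cset, rot, src)
    return extract_epd(solve(system, config))
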