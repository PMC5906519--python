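"""Fibre field, rotated anisotropic conductivity tensors and the ischaemic source.

The transmembrane potential during the ST segment is prescribed analytically
as a separable product phi_m(x, y, z) = dphi_p * Psi(x) Psi(y) Psi(1 - z):
a plateau offset dphi_p (default -30 mV) inside a 4 cm x 4 cm ischaemic
region reaching from the endocardium (z = 1 cm) down to a fractional depth
of the wall, with a sharp exponential border zone of width lambda.

Cardiac fibres lie in planes parallel to the epicardium, aligned with the
x-axis at z = 0 and rotating linearly through the wall by a total angle ROT.
Conductivity tensors are M_p = A G_p A^T with G_p = diag(g_pl, g_pt, g_pn)
and A the rotation about the z-axis by the local fibre angle.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .mesh import Mesh
from .parameters import ConductivitySet

__all__ = [
    "SourceParams",
    "psi",
    "transmembrane_field",
    "fibre_angle",
    "conductivity_tensor",
    "tensor_profiles",
]


@dataclass(frozen=True)
class SourceParams:
    """Analytic ischaemic-source parameters.

    depth is the ischaemic fraction of the wall (0-1), measured from the
    endocardium; the half-maximum transition of the z-factor then sits at
    z = 1 - depth (in cm for a 1 cm wall).
    """

    depth: float
    delta_phi: float = -30.0  # plateau potential difference [mV]
    half_width: float = 2.0  # ischaemic footprint half-width a_x = a_y [cm]
    lam: float = 0.01  # border-zone steepness lambda [cm]
    wall: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.depth < 1.0:
            raise ValueError("ischaemic depth must lie strictly between 0 and 1")
        if self.lam <= 0 or self.half_width <= 0:
            raise ValueError("half-widths and lambda must be positive")

    @property
    def a_z(self) -> float:
        return self.depth * self.wall


def psi(t: np.ndarray | float, a: float, lam: float) -> np.ndarray | float:
    """Smoothed indicator of the interval |t| <= a with border width lam.

    Equals 1 at t = 0, 1/2 at |t| = a and decays exponentially outside;
    both branches are evaluated in an overflow-safe form.
    """
    if a <= 0 or lam <= 0:
        raise ValueError("psi requires a > 0 and lam > 0")
    t = np.abs(np.asarray(t, dtype=float))
    denom = 1.0 - np.exp(-a / lam)
    # inside: 1 - exp(-a/lam) cosh(t/lam) = 1 - [exp((t-a)/lam) + exp(-(t+a)/lam)] / 2
    inside = 1.0 - 0.5 * (np.exp(np.minimum(t - a, 0.0) / lam) + np.exp(-(t + a) / lam))
    # outside: exp(-t/lam) sinh(a/lam) = [exp((a-t)/lam) - exp(-(a+t)/lam)] / 2
    outside = 0.5 * (np.exp(np.minimum(a - t, 0.0) / lam) - np.exp(-(a + t) / lam))
    out = np.where(t <= a, inside, outside) / denom
    return float(out) if np.isscalar(out) or out.ndim == 0 else out


def transmembrane_field(mesh: Mesh, src: SourceParams) -> np.ndarray:
    """Nodal transmembrane potential [mV], shape (nx, ny, nz); zero in the blood."""
    px = psi(mesh.x, src.half_width, src.lam)
    py = psi(mesh.y, src.half_width, src.lam)
    pz = np.where(
        mesh.z <= src.wall + 1e-12,
        psi(src.wall - mesh.z, src.a_z, src.lam),
        0.0,
    )
    return src.delta_phi * px[:, None, None] * py[None, :, None] * pz[None, None, :]


def fibre_angle(z: np.ndarray | float, rot: float, wall: float = 1.0):
    """Fibre angle [deg] at depth z [cm]: linear from 0 (epicardium) to ROT."""
    z = np.asarray(z, dtype=float)
    if np.any(z < -1e-12) or np.any(z > wall + 1e-12):
        raise ValueError("z must lie within the tissue wall")
    return rot * z / wall


def conductivity_tensor(cset: ConductivitySet, theta_deg: float, space: str) -> np.ndarray:
    """3x3 conductivity tensor M_p = A G_p A^T for fibre angle theta about z."""
    th = np.deg2rad(theta_deg)
    c, s = np.cos(th), np.sin(th)
    a = np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])
    g = np.diag(cset.diag(space))
    return a @ g @ a.T


def tensor_profiles(mesh: Mesh, cset: ConductivitySet, rot: float) -> dict[str, np.ndarray]:
    """Per-z-layer tensor components for the assembled operators.

    Because fibres rotate about z only, both M_i and M_i + M_e have the
    block form [[m_xx, m_xy, 0], [m_xy, m_yy, 0], [0, 0, m_zz]], with
    components depending on z alone (evaluated at layer midpoints).  Blood
    layers carry the isotropic blood conductivity in the bulk operator and
    zero in the intracellular (source) operator.

    Returns arrays of length n_layers for keys '{op}_{comp}' with op in
    {'bulk', 'intra'} and comp in {'xx', 'yy', 'zz', 'xy'}.
    """
    zmid = mesh.z_layer_mid
    tissue = mesh.tissue_layers
    theta = np.deg2rad(rot * np.clip(zmid, 0.0, mesh.geometry.wall) / mesh.geometry.wall)
    c2, s2 = np.cos(theta) ** 2, np.sin(theta) ** 2
    cs = np.cos(theta) * np.sin(theta)

    out: dict[str, np.ndarray] = {}
    for op, gl, gt, gn in (
        ("intra", cset.g_il, cset.g_it, cset.g_in),
        ("bulk", cset.g_il + cset.g_el, cset.g_it + cset.g_et, cset.g_in + cset.g_en),
    ):
        xx = np.where(tissue, gl * c2 + gt * s2, 0.0)
        yy = np.where(tissue, gl * s2 + gt * c2, 0.0)
        zz = np.where(tissue, gn, 0.0)
        xy = np.where(tissue, (gl - gt) * cs, 0.0)
        if op == "bulk":
            xx = np.where(tissue, xx, cset.g_b)
            yy = np.where(tissue, yy, cset.g_b)
            zz = np.where(tissue, zz, cset.g_b)
        out[f"{op}_xx"], out[f"{op}_yy"] = xx, yy
        out[f"{op}_zz"], out[f"{op}_xy"] = zz, xy
    return out
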