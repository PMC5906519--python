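"""Scalar features and pattern classification of epicardial potential maps.

An EPD is reduced to the potentials cminV/cmaxV (min/max over the central
4 cm x 4 cm footprint above the ischaemic region), ominV (minimum outside
that footprint), the orientation of the ST-depression "ellipse", and the
angles angmin/angmax from the origin to the minimum/maximum located in the
y > 0 half-plane.  Patterns are classified as:

* ST depression type 1: cminV < ominV < 0 (global minimum central)
* ST depression type 2: ominV < cminV < 0 (tripole, global minimum outside)
* ST elevation: cmaxV > 0
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .solver import EPD

__all__ = [
    "FeatureSet",
    "extract_features",
    "classify",
    "classify_values",
    "extremum_angle",
    "ellipse_angle",
]

TYPE1 = "depression_type1"
TYPE2 = "depression_type2"
ELEVATION = "elevation"


@dataclass
class FeatureSet:
    cminV: float
    cmaxV: float
    ominV: float
    ellipse_angle: float | None = None
    ellipse_axis_ratio: float | None = None
    angmin: float | None = None
    angmax: float | None = None
    epd_type: str = ""

    def as_dict(self) -> dict:
        return {
            "cminV": self.cminV,
            "cmaxV": self.cmaxV,
            "ominV": self.ominV,
            "ellipse_angle": self.ellipse_angle,
            "angmin": self.angmin,
            "angmax": self.angmax,
            "epd_type": self.epd_type,
        }


def classify_values(cminV: float, ominV: float, cmaxV: float) -> str:
    """Partition of EPD patterns by the three potential extrema."""
    if cmaxV > 0:
        return ELEVATION
    if ominV < cminV:
        return TYPE2
    return TYPE1


def classify(features: FeatureSet) -> str:
    return classify_values(features.cminV, features.ominV, features.cmaxV)


def _local_extrema_mask(v: np.ndarray, kind: str) -> np.ndarray:
    """Strict 8-neighbour local minima (or maxima) of a 2-D field, interior only."""
    w = v if kind == "min" else -v
    mask = np.zeros_like(w, dtype=bool)
    core = w[1:-1, 1:-1]
    strict = np.ones_like(core, dtype=bool)
    for di in (-1, 0, 1):
        for dj in (-1, 0, 1):
            if di == 0 and dj == 0:
                continue
            strict &= core < w[1 + di : w.shape[0] - 1 + di, 1 + dj : w.shape[1] - 1 + dj]
    mask[1:-1, 1:-1] = strict
    return mask


def _refine_quadratic(epd: EPD, i: int, j: int) -> tuple[float, float]:
    """Sub-grid extremum location via a least-squares quadratic on the 3x3 patch."""
    xs = epd.x[i - 1 : i + 2] - epd.x[i]
    ys = epd.y[j - 1 : j + 2] - epd.y[j]
    gx, gy = np.meshgrid(xs, ys, indexing="ij")
    vals = epd.values[i - 1 : i + 2, j - 1 : j + 2].ravel()
    gx, gy = gx.ravel(), gy.ravel()
    basis = np.column_stack([np.ones_like(gx), gx, gy, gx * gy, gx**2, gy**2])
    c, *_ = np.linalg.lstsq(basis, vals, rcond=None)
    # stationary point of c1 x + c2 y + c3 xy + c4 x^2 + c5 y^2
    hess = np.array([[2 * c[4], c[3]], [c[3], 2 * c[5]]])
    grad = np.array([c[1], c[2]])
    try:
        shift = np.linalg.solve(hess, -grad)
    except np.linalg.LinAlgError:
        shift = np.zeros(2)
    # keep refinement within the local cell to avoid runaway fits
    shift = np.clip(shift, [xs[0], ys[0]], [xs[-1], ys[-1]])
    return epd.x[i] + shift[0], epd.y[j] + shift[1]


def _angle_deg(x: float, y: float) -> float:
    ang = np.degrees(np.arctan2(y, x)) % 180.0
    return float(ang)


def extremum_angle(epd: EPD, which: str = "min", region: str = "outside") -> float | None:
    """Angle [deg, in [0, 180)] from the origin to the requested extremum.

    The extremum must be a strict 8-neighbour local extremum with y > 0 in
    the requested region ('outside' the central footprint, 'central', or
    'anywhere'); its location is refined to sub-grid accuracy before the
    angle is taken.  Returns None if no qualifying extremum exists.
    """
    if which not in ("min", "max"):
        raise ValueError("which must be 'min' or 'max'")
    mask = _local_extrema_mask(epd.values, which)
    central = epd.central_mask
    if region == "outside":
        mask &= ~central
    elif region == "central":
        mask &= central
    elif region != "anywhere":
        raise ValueError("region must be 'outside', 'central' or 'anywhere'")
    mask &= (epd.y[None, :] > 1e-9)
    if not mask.any():
        return None
    ii, jj = np.nonzero(mask)
    vals = epd.values[ii, jj]
    order = vals if which == "min" else -vals
    # deepest extremum; ties broken by smallest angle
    angles = np.array([_angle_deg(epd.x[i], epd.y[j]) for i, j in zip(ii, jj)])
    best = np.lexsort((angles, order))[0]
    xr, yr = _refine_quadratic(epd, ii[best], jj[best])
    return _angle_deg(xr, yr)


def _dual_areas(coords: np.ndarray) -> np.ndarray:
    h = np.diff(coords)
    w = np.zeros(len(coords))
    w[:-1] += h / 2
    w[1:] += h / 2
    return w


def ellipse_angle(epd: EPD, level: float = 0.2) -> tuple[float, float] | None:
    """Orientation of the ST-depression pattern.

    Fits the second moments of the depression contour region: the connected
    component of {phi <= level * cminV} containing the central minimum
    (area-weighted on the graded grid), and reports the principal-axis
    angle in [0, 180) together with the axis ratio sqrt(l1/l2); a ratio
    near 1 means the orientation is degenerate.  Returns None when
    cminV >= 0.  The default level 0.2 tracks the closed contour drawn
    around the depression in potential maps, which is markedly more
    elongated (hence better conditioned) than the deep core.
    """
    central = epd.central_mask
    cmin = epd.values[central].min()
    if cmin >= 0:
        return None
    sel = epd.values <= level * cmin
    if not sel.any():
        return None
    labels, _ = ndimage.label(sel)
    ci, cj = np.unravel_index(
        np.argmin(np.where(central, epd.values, np.inf)), epd.values.shape
    )
    sel = labels == labels[ci, cj]
    wx, wy = _dual_areas(epd.x), _dual_areas(epd.y)
    weights = (wx[:, None] * wy[None, :])[sel]
    xs = np.broadcast_to(epd.x[:, None], epd.values.shape)[sel]
    ys = np.broadcast_to(epd.y[None, :], epd.values.shape)[sel]
    wsum = weights.sum()
    mx, my = (weights * xs).sum() / wsum, (weights * ys).sum() / wsum
    dx, dy = xs - mx, ys - my
    cov = np.array(
        [
            [(weights * dx * dx).sum(), (weights * dx * dy).sum()],
            [(weights * dx * dy).sum(), (weights * dy * dy).sum()],
        ]
    ) / wsum
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, np.argmax(evals)]
    ratio = float(np.sqrt(max(evals) / max(min(evals), 1e-30)))
    return _angle_deg(major[0], major[1]), ratio


def extract_features(epd: EPD, ellipse_level: float = 0.2) -> FeatureSet:
    """Reduce an EPD to its scalar outputs and pattern class."""
    central = epd.central_mask
    if not central.any() or central.all():
        raise ValueError("central footprint mask is empty or covers the whole grid")
    v = epd.values
    cminV = float(v[central].min())
    cmaxV = float(v[central].max())
    ominV = float(v[~central].min())
    ell = ellipse_angle(epd, level=ellipse_level)
    fs = FeatureSet(
        cminV=cminV,
        cmaxV=cmaxV,
        ominV=ominV,
        ellipse_angle=None if ell is None else ell[0],
        ellipse_axis_ratio=None if ell is None else ell[1],
        angmin=extremum_angle(epd, "min", "outside"),
        angmax=extremum_angle(epd, "max", "anywhere"),
    )
    fs.epd_type = classify(fs)
    return fs
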