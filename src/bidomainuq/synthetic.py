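"""Synthetic inputs for exercising every analysis stage without the PDE solver.

Three generators are provided:

* surrogate response functions on [0, 1]^d with analytically known
  main-effect sensitivity indices (for the emulator and PLS stages);
* synthetic epicardial potential maps built from anisotropic Gaussian
  wells/peaks with brute-force ground-truth features (for the feature
  stage);
* a fast mock simulator with the qualitative behaviour of the physical
  model: the pattern walks depression-type-1 -> type-2 -> elevation as the
  ischaemic depth grows, the pattern rotates anticlockwise with fibre
  rotation, and the central potential deepens with g_in and shallows with
  g_en.  It is not calibrated to physical magnitudes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .features import FeatureSet, classify
from .parameters import INPUT_NAMES
from .solver import EPD

__all__ = [
    "SurrogateSpec",
    "Surrogate",
    "make_surrogate",
    "GaussianBlob",
    "make_synthetic_epd",
    "mock_simulator",
]


# ---------------------------------------------------------------------------
# surrogate response functions with analytic sensitivity indices


@dataclass(frozen=True)
class SurrogateSpec:
    """f(x) = sum_d [c_d x_d + s_d sin(2 pi x_d + p_d)] + sum c_de x_d x_e + noise."""

    linear: tuple[float, ...]
    sine: tuple[float, ...] = ()
    sine_phase: tuple[float, ...] = ()
    interactions: tuple[tuple[int, int, float], ...] = ()
    noise_sd: float = 0.0
    seed: int = 0

    @property
    def dim(self) -> int:
        return len(self.linear)


@dataclass
class Surrogate:
    spec: SurrogateSpec
    indices: np.ndarray  # analytic main-effect indices
    total_variance: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        x = np.atleast_2d(np.asarray(x, float))
        s = self.spec
        out = x @ np.asarray(s.linear)
        for d, (amp, ph) in enumerate(zip(s.sine, s.sine_phase)):
            out = out + amp * np.sin(2 * np.pi * x[:, d] + ph)
        for i, j, c in s.interactions:
            out = out + c * x[:, i] * x[:, j]
        if s.noise_sd > 0:
            rng = np.random.default_rng(s.seed)
            out = out + rng.normal(0.0, s.noise_sd, size=len(out))
        return out if out.shape[0] > 1 else float(out[0])


def _sine_moments(amp: float, ph: float, mu: float, var: float):
    """Mean, variance and Cov(x, .) of amp*sin(2 pi x + ph) for x ~ N(mu, var)."""
    a = 2.0 * np.pi
    damp = np.exp(-0.5 * a**2 * var)
    mean = amp * np.sin(a * mu + ph) * damp
    second = 0.5 * amp**2 * (1.0 - np.exp(-2.0 * a**2 * var) * np.cos(2 * (a * mu + ph)))
    cov_x = amp * a * var * np.cos(a * mu + ph) * damp  # Stein's identity
    return mean, second - (mean / 1.0) ** 2, cov_x


def make_surrogate(
    spec: SurrogateSpec, input_mean: float = 0.5, input_variance: float = 0.02
) -> Surrogate:
    """Build the surrogate and its analytic main-effect index vector.

    Indices are defined for independent N(input_mean, input_variance)
    inputs, matching the distribution used by the emulator's sensitivity
    stage.  All-zero coefficients give zero variance and raise ValueError.
    """
    mu, v = input_mean, input_variance
    d = spec.dim
    lin = np.asarray(spec.linear, float)
    sine = np.zeros(d)
    phase = np.zeros(d)
    sine[: len(spec.sine)] = spec.sine
    phase[: len(spec.sine_phase)] = spec.sine_phase

    # per-dimension additive terms g_d(x) = c_d x + s_d sin(2 pi x + p_d)
    add_var = np.empty(d)
    for k in range(d):
        _, sv, cov_x = _sine_moments(sine[k], phase[k], mu, v)
        add_var[k] = lin[k] ** 2 * v + sv + 2.0 * lin[k] * cov_x

    inter = np.zeros((d, d))
    for i, j, c in spec.interactions:
        inter[i, j] += c
        inter[j, i] += c

    # main-effect variance per dim: Var[g_w(x_w) + x_w * sum_e c_we mu]
    main_var = np.empty(d)
    for w in range(d):
        extra = inter[w].sum() * mu  # interactions enter via their mean partner
        _, sv, cov_x = _sine_moments(sine[w], phase[w], mu, v)
        cw = lin[w] + extra
        main_var[w] = cw**2 * v + sv + 2.0 * cw * cov_x

    # total variance: additive terms plus interaction remainders
    total = main_var.sum()
    for i, j, c in spec.interactions:
        # Var[c x_i x_j] beyond the two conditional-mean (linear) parts:
        # c^2 (mu_i^2 v + mu_j^2 v + v^2) - c^2 mu_j^2 v - c^2 mu_i^2 v = c^2 v^2
        total += c**2 * v * v
    if total <= 0:
        raise ValueError("surrogate has zero output variance; indices undefined")
    return Surrogate(spec=spec, indices=main_var / total, total_variance=total)


# ---------------------------------------------------------------------------
# synthetic EPD fields with brute-force ground truth


@dataclass(frozen=True)
class GaussianBlob:
    """Anisotropic Gaussian well (amplitude < 0) or peak (amplitude > 0)."""

    x0: float
    y0: float
    amplitude: float  # mV
    sx: float = 1.0  # principal std devs [cm]
    sy: float = 1.0
    angle: float = 0.0  # orientation of the sx axis [deg]


def _blob_field(blobs, x: np.ndarray, y: np.ndarray) -> np.ndarray:
    gx, gy = np.meshgrid(x, y, indexing="ij")
    out = np.zeros_like(gx)
    for b in blobs:
        th = np.deg2rad(b.angle)
        dx, dy = gx - b.x0, gy - b.y0
        u = np.cos(th) * dx + np.sin(th) * dy
        w = -np.sin(th) * dx + np.cos(th) * dy
        out += b.amplitude * np.exp(-0.5 * ((u / b.sx) ** 2 + (w / b.sy) ** 2))
    return out


def make_synthetic_epd(
    blobs: "list[GaussianBlob] | tuple[GaussianBlob, ...]",
    n: int = 81,
    extent: float = 8.0,
    oracle_resolution: float = 0.05,
) -> tuple[EPD, FeatureSet]:
    """Synthetic EPD on a uniform grid plus brute-force ground-truth features.

    Ground truth is evaluated on a dense oracle grid (default 0.05 cm): the
    central/outside extrema come from direct search and the extremum angles
    from the dense argmin/argmax in the y > 0 half-plane.
    """
    axis = np.linspace(-extent, extent, n)
    epd = EPD(values=_blob_field(blobs, axis, axis), x=axis, y=axis.copy())

    dense = np.arange(-extent, extent + oracle_resolution / 2, oracle_resolution)
    f = _blob_field(blobs, dense, dense)
    cm = (np.abs(dense)[:, None] <= 2.0 + 1e-12) & (np.abs(dense)[None, :] <= 2.0 + 1e-12)
    cmin, cmax = float(f[cm].min()), float(f[cm].max())
    omin = float(f[~cm].min())

    def dense_angle(values: np.ndarray, region: np.ndarray, minimum: bool) -> float | None:
        half = dense[None, :] > 1e-9
        sel = region & half
        if not sel.any():
            return None
        v = np.where(sel, values, np.inf if minimum else -np.inf)
        idx = np.unravel_index(np.argmin(v) if minimum else np.argmax(v), v.shape)
        return float(np.degrees(np.arctan2(dense[idx[1]], dense[idx[0]])) % 180.0)

    truth = FeatureSet(
        cminV=cmin,
        cmaxV=cmax,
        ominV=omin,
        angmin=dense_angle(f, ~cm, minimum=True),
        angmax=dense_angle(f, np.ones_like(cm, bool), minimum=False),
    )
    truth.epd_type = classify(truth)
    return epd, truth


# ---------------------------------------------------------------------------
# fast mock simulator


def mock_simulator(params: dict | np.ndarray, depth: float, n: int = 61) -> EPD:
    """Analytic stand-in for the PDE simulator, for pipeline tests.

    Accepts the eight physical inputs (dict keyed by input name, or a vector
    in canonical input order) plus the ischaemic depth fraction.  The
    constructed pattern reproduces the model's qualitative hooks: class
    transitions with depth, anticlockwise rotation of the flank minima with
    ROT (0.5 deg per deg), and a deeper centre for larger g_in / smaller
    g_en.
    """
    if not isinstance(params, dict):
        params = dict(zip(INPUT_NAMES, np.asarray(params, float)))
    rot = params["ROT"]
    c_amp = (
        -1.5
        + 3.2 * depth
        - 6.0 * (params["g_in"] - 0.1)
        + 0.5 * (params["g_en"] - 1.0)
        + 0.05 * (params["g_il"] - 2.4)
    )
    o_amp = -0.3 - 1.8 * depth - 0.02 * (params["g_el"] - 2.4)
    flank = np.deg2rad(30.0 + 0.5 * rot)
    r = 3.2
    blobs = [
        GaussianBlob(0.0, 0.0, c_amp, sx=1.6, sy=1.1, angle=0.3 * rot),
        GaussianBlob(r * np.cos(flank), r * np.sin(flank), o_amp, sx=0.9, sy=0.9),
        GaussianBlob(-r * np.cos(flank), -r * np.sin(flank), o_amp, sx=0.9, sy=0.9),
    ]
    axis = np.linspace(-8.0, 8.0, n)
    return EPD(values=_blob_field(blobs, axis, axis), x=axis, y=axis.copy())
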