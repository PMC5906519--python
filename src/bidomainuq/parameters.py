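"""Model parameters, uncertainty ranges, sampling designs and derived conductivity statistics.

The bidomain description of ventricular tissue carries six conductivities
``g_pq`` (``p`` in ``{i, e}`` for intra-/extracellular space, ``q`` in
``{l, t, n}`` for the fibre-longitudinal, in-sheet transverse and
sheet-normal directions), plus a blood conductivity ``g_b`` and a total
transmural fibre-rotation angle ``ROT``.  All conductivities are in mS/cm,
angles in degrees.

Uncertainty in the eight varied inputs is described by uniform ranges of
the form ``mean +/- 50%`` for conductivities and ``100 +/- 40`` degrees for
fibre rotation.  Sampling designs live on the unit cube ``[0, 1]^d`` and are
mapped to physical units by an affine transform per input.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CONDUCTIVITY_NAMES",
    "INPUT_NAMES",
    "ConductivitySet",
    "ParameterRanges",
    "DesignMatrix",
    "default_ranges",
    "mean_conductivities",
    "literature_table",
    "literature_summary",
    "latin_hypercube",
    "denormalize",
    "normalize",
    "bulk_conductivity_ratio",
    "velocity_ratio",
]

CONDUCTIVITY_NAMES = ("g_il", "g_el", "g_it", "g_et", "g_in", "g_en")
#: The eight varied model inputs, in canonical order.
INPUT_NAMES = ("ROT", "g_b") + CONDUCTIVITY_NAMES


class InvalidDesignError(ValueError):
    """Raised for unusable sampling-design requests."""


@dataclass(frozen=True)
class ConductivitySet:
    """The six bidomain conductivities plus blood conductivity, in mS/cm."""

    g_il: float
    g_el: float
    g_it: float
    g_et: float
    g_in: float
    g_en: float
    g_b: float = 6.5

    def __post_init__(self) -> None:
        for name in CONDUCTIVITY_NAMES + ("g_b",):
            if not getattr(self, name) > 0:
                raise ValueError(f"conductivity {name} must be strictly positive")

    def g(self, space: str, direction: str) -> float:
        """Return ``g_pq`` for ``space`` p in {i, e} and ``direction`` q in {l, t, n}."""
        return getattr(self, f"g_{space}{direction}")

    def diag(self, space: str) -> np.ndarray:
        """Principal-axis conductivities ``(g_pl, g_pt, g_pn)`` for one space."""
        return np.array([self.g(space, q) for q in "ltn"])


@dataclass(frozen=True)
class ParameterRanges:
    """Uniform (min, mean, max) ranges for the varied inputs.

    ``names`` fixes the ordering used by designs and normalization.
    """

    names: tuple[str, ...]
    minimum: np.ndarray
    mean: np.ndarray
    maximum: np.ndarray

    def __post_init__(self) -> None:
        lo, mid, hi = self.minimum, self.mean, self.maximum
        if not (np.all(lo < mid) and np.all(mid < hi)):
            raise ValueError("ranges must satisfy min < mean < max")

    def index(self, name: str) -> int:
        return self.names.index(name)

    def subset(self, names: "list[str] | tuple[str, ...]") -> "ParameterRanges":
        idx = [self.index(n) for n in names]
        return ParameterRanges(
            tuple(names), self.minimum[idx], self.mean[idx], self.maximum[idx]
        )

    @property
    def span(self) -> np.ndarray:
        return self.maximum - self.minimum

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"min": self.minimum, "mean": self.mean, "max": self.maximum},
            index=list(self.names),
        )


@dataclass(frozen=True)
class DesignMatrix:
    """A sampling design on the unit cube, with its physical ranges attached."""

    points: np.ndarray  # (n, d), all entries in [0, 1]
    ranges: ParameterRanges
    seed: int
    labels: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 2:
            raise InvalidDesignError("design points must form an n x d array")
        if np.any(pts < 0) or np.any(pts > 1):
            raise InvalidDesignError("design points must lie in [0, 1]")
        object.__setattr__(self, "points", pts)
        if not self.labels:
            object.__setattr__(self, "labels", self.ranges.names)

    @property
    def n(self) -> int:
        return self.points.shape[0]

    @property
    def physical(self) -> np.ndarray:
        """Design points mapped onto the physical ranges."""
        return denormalize(self.points, self.ranges)

    def physical_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.physical, columns=list(self.labels))


def _data_frame(resource: str) -> pd.DataFrame:
    ref = importlib.resources.files("bidomainuq.data").joinpath(resource)
    with ref.open("r") as fh:
        return pd.read_csv(fh)


def default_ranges() -> ParameterRanges:
    """The study's uniform ranges for the eight varied inputs.

    Conductivity ranges are ``mean +/- 50%`` around the adopted means
    (g_il = g_el = 2.4, g_it = 0.24, g_et = 1.6, g_in = 0.1, g_en = 1.0,
    g_b = 6.5 mS/cm); fibre rotation spans 60-140 degrees around 100.
    """
    df = _data_frame("parameter_ranges.csv")
    return ParameterRanges(
        tuple(df["name"]),
        df["min"].to_numpy(float),
        df["mean"].to_numpy(float),
        df["max"].to_numpy(float),
    )


def mean_conductivities() -> ConductivitySet:
    """ConductivitySet at the range means (the study's baseline tissue)."""
    r = default_ranges()
    vals = {n: r.mean[r.index(n)] for n in CONDUCTIVITY_NAMES + ("g_b",)}
    return ConductivitySet(**vals)


def literature_table() -> pd.DataFrame:
    """Published bidomain conductivity sets (mS/cm); missing entries are NaN."""
    return _data_frame("literature_conductivities.csv")


def literature_summary(table: pd.DataFrame | None = None, ddof: int = 1) -> pd.DataFrame:
    """Column-wise mean and standard deviation of the literature conductivities.

    The sample convention (``ddof=1``) reproduces the published summary row
    to one decimal place.  Columns with no data raise ``ValueError``.
    """
    if table is None:
        table = literature_table()
    cols = [c for c in CONDUCTIVITY_NAMES if c in table.columns]
    sub = table[cols]
    if sub.notna().sum().min() == 0:
        empty = sub.columns[sub.notna().sum() == 0].tolist()
        raise ValueError(f"no data in columns {empty}")
    out = pd.DataFrame({"mean": sub.mean(), "std": sub.std(ddof=ddof)})
    out["n"] = sub.notna().sum()
    return out


def latin_hypercube(
    n: int, ranges: ParameterRanges | None = None, seed: int = 0
) -> DesignMatrix:
    """Seeded Latin-hypercube design: one point per equal-width stratum per dimension."""
    if n < 2:
        raise InvalidDesignError("a Latin hypercube needs at least 2 points")
    if ranges is None:
        ranges = default_ranges()
    d = len(ranges.names)
    rng = np.random.default_rng(seed)
    u = np.empty((n, d))
    for j in range(d):
        perm = rng.permutation(n)
        u[:, j] = (perm + rng.random(n)) / n
    return DesignMatrix(points=u, ranges=ranges, seed=seed)


def denormalize(points: np.ndarray, ranges: ParameterRanges) -> np.ndarray:
    """Map unit-cube coordinates linearly onto the physical ranges."""
    pts = np.asarray(points, dtype=float)
    if np.any(pts < 0) or np.any(pts > 1):
        raise ValueError("normalized coordinates must lie in [0, 1]")
    return ranges.minimum + pts * ranges.span


def normalize(values: np.ndarray, ranges: ParameterRanges) -> np.ndarray:
    """Inverse of :func:`denormalize`."""
    return (np.asarray(values, dtype=float) - ranges.minimum) / ranges.span


def _bulk(cset: ConductivitySet, q: str) -> float:
    return cset.g("i", q) + cset.g("e", q)


def _check_direction(*dirs: str) -> None:
    for q in dirs:
        if q not in ("l", "t", "n"):
            raise ValueError(f"direction must be one of l, t, n; got {q!r}")


def bulk_conductivity_ratio(cset: ConductivitySet, a: str, b: str) -> float:
    """Bulk-conductivity ratio g_A/g_B = (g_iA + g_eA) / (g_iB + g_eB)."""
    _check_direction(a, b)
    denom = _bulk(cset, b)
    if denom == 0:
        raise ZeroDivisionError("degenerate bulk conductivity in denominator")
    return _bulk(cset, a) / denom


def velocity_ratio(cset: ConductivitySet, a: str, b: str) -> float:
    """Conduction-velocity ratio c_A/c_B.

    Equals the square root of the ratio of harmonic means of the
    intra-/extracellular conductivities in the two directions:
    sqrt( [(g_iB+g_eB)/(g_iB g_eB)] * [(g_iA g_eA)/(g_iA+g_eA)] ).
    """
    _check_direction(a, b)
    gia, gea = cset.g("i", a), cset.g("e", a)
    gib, geb = cset.g("i", b), cset.g("e", b)
    return float(np.sqrt((gib + geb) / (gib * geb) * (gia * gea) / (gia + gea)))
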