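"""End-to-end studies: polynomial-chaos sweeps, emulation scenarios and the
fibre-rotation/ischaemic-depth study of the outside-minimum position.

Every study draws its inputs from the canonical parameter ranges, runs the
finite-volume simulator (or the fast mock backend) for each design point,
reduces the epicardial maps to scalar features, and hands the resulting
tables to the polynomial-chaos, Gaussian-process and partial-least-squares
stages.  Solver runs are cached by parameter set within a study, which the
nested sparse-grid levels and repeated emulator passes exploit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import gp
from .chaos import FieldStats, SparseGrid, compare_fields, pc_field_stats, smolyak_grid
from .features import ELEVATION, TYPE1, TYPE2, FeatureSet, extract_features
from .mesh import Mesh, build_mesh
from .parameters import (
    CONDUCTIVITY_NAMES,
    INPUT_NAMES,
    ConductivitySet,
    ParameterRanges,
    default_ranges,
    latin_hypercube,
    mean_conductivities,
    normalize,
)
from .pls import PLSModel, fit_nipals, ratio_features
from .solver import EPD, SolverConfig, solve_model
from .synthetic import mock_simulator

__all__ = [
    "Simulator",
    "PCSweepRecord",
    "ScenarioReport",
    "AngminReport",
    "run_pc_sweep",
    "run_scenario",
    "run_angmin_study",
    "run_level_compare",
    "SCENARIOS",
]

#: scenario name -> (ischaemic depth fraction, target pattern class, outputs)
SCENARIOS: dict[str, tuple[float, str, tuple[str, ...]]] = {
    "type1": (0.10, TYPE1, ("cminV", "cmaxV", "ominV", "ellipse_angle")),
    "type2": (0.30, TYPE2, ("ominV", "cminV", "cmaxV", "angmin")),
    "elevation": (0.60, ELEVATION, ("cmaxV", "ominV", "angmax", "angmin")),
}


class Simulator:
    """Cached EPD simulator over the eight physical inputs plus depth."""

    def __init__(
        self,
        backend: str = "fv",
        mesh_preset: str = "coarse",
        solver_config: SolverConfig = SolverConfig(),
    ):
        if backend not in ("fv", "mock"):
            raise ValueError("backend must be 'fv' or 'mock'")
        self.backend = backend
        self.mesh: Mesh | None = build_mesh(mesh_preset) if backend == "fv" else None
        self.config = solver_config
        self._cache: dict[tuple, EPD] = {}
        self.n_solves = 0

    def __call__(self, params: dict, depth: float) -> EPD:
        key = (round(depth, 9),) + tuple(round(float(params[k]), 9) for k in INPUT_NAMES)
        if key not in self._cache:
            if self.backend == "mock":
                epd = mock_simulator(params, depth)
            else:
                cset = ConductivitySet(
                    **{k: float(params[k]) for k in CONDUCTIVITY_NAMES},
                    g_b=float(params["g_b"]),
                )
                epd = solve_model(self.mesh, cset, float(params["ROT"]), depth,
                                  self.config)
            self.n_solves += 1
            self._cache[key] = epd
        return self._cache[key]


def _conductivity_params(cond_values: np.ndarray, g_b: float, rot: float) -> dict:
    params = dict(zip(CONDUCTIVITY_NAMES, cond_values))
    params["g_b"] = g_b
    params["ROT"] = rot
    return params


# ---------------------------------------------------------------------------
# polynomial-chaos sweeps


@dataclass
class PCSweepRecord:
    depth: float
    stats: FieldStats
    mean_epd: EPD
    features: FeatureSet


def run_pc_sweep(
    depths,
    g_b: float = 6.5,
    rot: float = 100.0,
    level: int = 2,
    simulator: Simulator | None = None,
    ranges: ParameterRanges | None = None,
) -> list[PCSweepRecord]:
    """Mean/std EPDs over the conductivity box for a list of ischaemic depths.

    Fibre rotation and blood conductivity are held fixed while the six
    bidomain conductivities vary uniformly over their ranges on a Smolyak
    sparse grid (85 nodes at level 2).
    """
    sim = simulator or Simulator()
    ranges = (ranges or default_ranges()).subset(list(CONDUCTIVITY_NAMES))
    grid = smolyak_grid(len(CONDUCTIVITY_NAMES), level)
    records = []
    for depth in depths:
        def evaluate(phys):
            return sim(_conductivity_params(phys, g_b, rot), depth).values

        stats = pc_field_stats(evaluate, grid, ranges)
        template = sim(_conductivity_params(ranges.mean, g_b, rot), depth)
        mean_epd = EPD(values=stats.mean, x=template.x, y=template.y,
                       footprint=template.footprint)
        records.append(
            PCSweepRecord(depth=depth, stats=stats, mean_epd=mean_epd,
                          features=extract_features(mean_epd))
        )
    return records


def run_level_compare(
    depth: float = 0.5,
    rot: float = 120.0,
    g_b: float = 6.7,
    levels: tuple[int, int] = (2, 3),
    simulator: Simulator | None = None,
) -> dict:
    """Correlation and relative error between two sparse-grid-level mean EPDs.

    The nested grids share nodes, so the cached simulator only runs the
    higher level's new points.
    """
    sim = simulator or Simulator()
    records = {
        lvl: run_pc_sweep([depth], g_b=g_b, rot=rot, level=lvl, simulator=sim)[0]
        for lvl in levels
    }
    corr, rel = compare_fields(
        records[levels[1]].mean_epd.values, records[levels[0]].mean_epd.values
    )
    return {
        "correlation": corr,
        "relative_error": rel,
        "records": records,
        "n_solves": sim.n_solves,
    }


# ---------------------------------------------------------------------------
# emulation scenarios


@dataclass
class ScenarioReport:
    scenario: str
    depth: float
    design: pd.DataFrame  # physical inputs + features + class for every run
    class_counts: dict
    class_fractions: dict
    used: pd.DataFrame  # the rows analysed (target class, truncated)
    sensitivity: pd.DataFrame  # outputs x inputs GP main-effect indices
    index_sums: pd.Series
    validation: dict  # output -> gp.ValidationReport
    gp_models: dict
    main_effects: dict  # (output, input name) -> gp.MainEffectCurve
    pls_coefficients: pd.DataFrame  # inputs x outputs, standardized
    pls_ratio_coefficients: pd.DataFrame  # conductivity ratios x voltage outputs
    shortfall: bool = False


def _feature_table(sim: Simulator, design_phys: pd.DataFrame, depth) -> pd.DataFrame:
    rows = []
    depths = depth if np.ndim(depth) else np.full(len(design_phys), depth)
    for (_, row), dep in zip(design_phys.iterrows(), depths):
        epd = sim(row.to_dict(), float(dep))
        rows.append(extract_features(epd).as_dict())
    feats = pd.DataFrame(rows, index=design_phys.index)
    return pd.concat([design_phys, feats], axis=1)


def run_scenario(
    scenario: str,
    n: int = 250,
    seed: int = 0,
    simulator: Simulator | None = None,
    max_used: int | None = None,
    min_used: int = 40,
    compute_main_effects: bool = False,
    emulate: bool = True,
) -> ScenarioReport:
    """One pattern-class scenario: design, simulate, filter, emulate, regress.

    A Latin-hypercube design over the eight inputs is simulated at the
    scenario's fixed depth; runs of the target class are kept in generation
    order and truncated to a multiple of ten (so the 90/10 train/validation
    split is integral), then each scalar output gets a GP emulator
    (main-effect indices with input variance 0.02) and all outputs a joint
    PLS regression on standardized inputs.
    """
    if scenario not in SCENARIOS:
        raise KeyError(f"unknown scenario {scenario!r}")
    depth, target, outputs = SCENARIOS[scenario]
    sim = simulator or Simulator()
    design = latin_hypercube(n, seed=seed)
    table = _feature_table(sim, design.physical_frame(), depth)

    counts = table["epd_type"].value_counts().to_dict()
    fractions = {k: v / len(table) for k, v in counts.items()}
    selected = table[table["epd_type"] == target]
    k = (len(selected) // 10) * 10
    if max_used is not None:
        k = min(k, max_used)
    shortfall = k < min_used
    used = selected.iloc[:k]

    ranges = default_ranges()
    sens = {}
    sums = {}
    models = {}
    validation = {}
    curves = {}
    if emulate and not shortfall:
        xn = normalize(used[list(INPUT_NAMES)].to_numpy(), ranges)
        for out in outputs:
            y = used[out].to_numpy(float)
            ok = np.isfinite(y)
            model, report = gp.fit(xn[ok], y[ok], train_fraction=0.9, seed=seed)
            rep = gp.sensitivity_indices(model, input_variance=0.02)
            sens[out] = pd.Series(rep.indices, index=list(INPUT_NAMES))
            sums[out] = rep.total
            models[out] = model
            validation[out] = report
            if compute_main_effects:
                for w, name in enumerate(INPUT_NAMES):
                    curves[(out, name)] = gp.main_effect(model, w, others_variance=0.04)

        complete = used.dropna(subset=list(outputs))
        pls = fit_nipals(complete[list(INPUT_NAMES)], complete[list(outputs)])
        voltage_outputs = [o for o in outputs if o.endswith("V")]
        ratios = ratio_features(complete)
        pls_ratio = fit_nipals(ratios, complete[voltage_outputs])
        sens_df = pd.DataFrame(sens).T
        pls_df = pls.coefficients
        pls_ratio_df = pls_ratio.coefficients
        sum_series = pd.Series(sums)
    else:
        sens_df = pd.DataFrame()
        pls_df = pd.DataFrame()
        pls_ratio_df = pd.DataFrame()
        sum_series = pd.Series(dtype=float)

    return ScenarioReport(
        scenario=scenario,
        depth=depth,
        design=table,
        class_counts=counts,
        class_fractions=fractions,
        used=used,
        sensitivity=sens_df,
        index_sums=sum_series,
        validation=validation,
        gp_models=models,
        main_effects=curves,
        pls_coefficients=pls_df,
        pls_ratio_coefficients=pls_ratio_df,
        shortfall=shortfall,
    )


# ---------------------------------------------------------------------------
# outside-minimum position study


@dataclass
class AngminReport:
    design: pd.DataFrame
    rot_coefficient: float
    depth_coefficient: float
    pls: PLSModel


def run_angmin_study(
    n: int = 250,
    seed: int = 0,
    simulator: Simulator | None = None,
    depth_range: tuple[float, float] = (0.3, 0.8),
) -> AngminReport:
    """PLS correlations of the outside-minimum angle with ROT and depth.

    Fibre rotation spans its usual 60-140 degrees and the ischaemic depth
    the given range (30-80% keeps every pattern in the tripole or elevation
    class); conductivities are fixed at their means.
    """
    base = default_ranges()
    i_rot = base.index("ROT")
    ranges = ParameterRanges(
        names=("ROT", "depth"),
        minimum=np.array([base.minimum[i_rot], depth_range[0]]),
        mean=np.array([base.mean[i_rot], 0.5 * sum(depth_range)]),
        maximum=np.array([base.maximum[i_rot], depth_range[1]]),
    )
    design = latin_hypercube(n, ranges=ranges, seed=seed)
    phys = design.physical_frame()
    sim = simulator or Simulator()
    means = mean_conductivities()
    base_params = {name: getattr(means, name) for name in CONDUCTIVITY_NAMES}
    base_params["g_b"] = means.g_b

    rows = []
    for _, row in phys.iterrows():
        params = dict(base_params, ROT=row["ROT"])
        epd = sim(params, float(row["depth"]))
        rows.append(extract_features(epd).as_dict())
    table = pd.concat([phys, pd.DataFrame(rows, index=phys.index)], axis=1)

    complete = table.dropna(subset=["angmin"])
    pls = fit_nipals(complete[["ROT", "depth"]], complete[["angmin"]])
    return AngminReport(
        design=table,
        rot_coefficient=pls.coefficient("ROT", "angmin"),
        depth_coefficient=pls.coefficient("depth", "angmin"),
        pls=pls,
    )
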