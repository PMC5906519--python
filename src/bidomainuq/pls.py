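"""NIPALS partial-least-squares regression of EPD outputs on inputs.

PLS extracts components that jointly decompose inputs and outputs under the
constraint of maximal input-output covariance; on standardized columns its
regression coefficients are signed sensitivity measures comparable within a
single output.  The decomposition is delegated to scikit-learn's NIPALS
implementation; both inputs and outputs are standardized to zero mean and
unit variance here, so the reported coefficients are on the standardized
scale throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression

__all__ = ["PLSModel", "fit_nipals", "ratio_features", "RATIO_NAMES"]

#: Conductivity ratios examined alongside the raw conductivities.
RATIO_NAMES = (
    "g_il/g_el",
    "g_il/g_it",
    "g_it/g_et",
    "g_il/g_in",
    "g_in/g_en",
    "g_el/g_et",
    "g_el/g_en",
)


@dataclass
class PLSModel:
    """Standardized-scale PLS regression state."""

    coefficients: pd.DataFrame  # inputs x outputs, standardized
    n_components: int
    x_scores: np.ndarray
    x_mean: np.ndarray
    x_std: np.ndarray
    y_mean: np.ndarray
    y_std: np.ndarray

    def coefficient(self, input_name: str, output_name: str) -> float:
        return float(self.coefficients.loc[input_name, output_name])


def fit_nipals(
    x: pd.DataFrame | np.ndarray,
    y: pd.DataFrame | np.ndarray,
    n_components: int | None = None,
) -> PLSModel:
    """Fit NIPALS PLS on internally standardized columns.

    By default all min(p, 8) components are retained, so for well-
    conditioned designs the coefficients coincide with standardized
    least-squares coefficients; zero-variance columns are rejected.
    """
    xdf = pd.DataFrame(x)
    ydf = pd.DataFrame(y)
    if n_components is None:
        n_components = min(xdf.shape[1], 8)
    xs = xdf.std(ddof=1)
    ys = ydf.std(ddof=1)
    means = pd.concat([xdf.mean(), ydf.mean()])
    for (name, s), mu in zip(list(xs.items()) + list(ys.items()), means):
        if not np.isfinite(s) or s <= 1e-12 * max(1.0, abs(mu)):
            raise ValueError(f"column {name!r} has zero variance")
    xn = (xdf - xdf.mean()) / xs
    yn = (ydf - ydf.mean()) / ys
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(xn.to_numpy(), yn.to_numpy())
    coef = pd.DataFrame(
        pls.coef_.T, index=list(xdf.columns), columns=list(ydf.columns)
    )
    return PLSModel(
        coefficients=coef,
        n_components=n_components,
        x_scores=pls.x_scores_,
        x_mean=xdf.mean().to_numpy(),
        x_std=xs.to_numpy(),
        y_mean=ydf.mean().to_numpy(),
        y_std=ys.to_numpy(),
    )


def ratio_features(design: pd.DataFrame) -> pd.DataFrame:
    """The seven conductivity ratios per design point (physical units)."""
    out = pd.DataFrame(index=design.index)
    for name in RATIO_NAMES:
        num, den = name.split("/")
        out[name] = design[num] / design[den]
    return out
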