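"""Prediction maps: a trained two-feature regressor over the unit square.

A smooth (support-vector) regressor trained on two features can be
evaluated everywhere on [0, 1]^2, giving a continuous map of the predicted
outbreak size even though real nodes only occupy scattered points of the
feature plane.  The map is paired with an *achievability mask*: grid cells
containing no observed (feature1, feature2) point correspond to coordinates
no real graph of that size attains, and predictions there are
extrapolation, not evidence.

Map series vary either the transmission rate beta at fixed graph size, or
the graph size at fixed beta — in the latter case the plotted quantity is
Omega/N so sizes are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .dataset import ExperimentView, project_and_dedup
from .learn import RegressionConfig, run_experiment

__all__ = ["PredictionMap", "build_map", "map_series"]


@dataclass(frozen=True)
class PredictionMap:
    """Dense prediction grid plus achievability mask for one (N, beta)."""

    feature_pair: tuple[str, str]
    resolution: int
    omega: np.ndarray  # (resolution, resolution); [i, j] = (feature1 bin i, feature2 bin j)
    attainable: np.ndarray  # same shape, bool
    beta: float
    n_nodes: int | None
    normalized: bool = False  # True when the plotted quantity is Omega/N

    def to_frame(self) -> pd.DataFrame:
        """Tidy CSV-ready layout: one row per grid cell."""
        r = self.resolution
        centers = (np.arange(r) + 0.5) / r
        f1, f2 = np.meshgrid(centers, centers, indexing="ij")
        return pd.DataFrame(
            {
                self.feature_pair[0]: f1.ravel(),
                self.feature_pair[1]: f2.ravel(),
                "omega_pred": self.omega.ravel(),
                "attainable": self.attainable.ravel().astype(int),
            }
        )


def _attainability_mask(view: ExperimentView, resolution: int) -> np.ndarray:
    """A cell is attainable iff at least one observed point falls inside it."""
    x = view.X
    counts, _, _ = np.histogram2d(
        x[:, 0], x[:, 1], bins=resolution, range=[[0, 1], [0, 1]]
    )
    return counts > 0


def build_map(
    model, view: ExperimentView, feature_pair: Sequence[str], resolution: int = 100
) -> PredictionMap:
    """Evaluate a fitted two-feature model at every grid-cell centre.

    ``model`` must have been trained on exactly the two features named in
    ``feature_pair``, in that order, on data drawn from ``view`` (the view
    supplies the observed points for the mask).
    """
    pair = tuple(feature_pair)
    if len(pair) != 2:
        raise ValueError("feature_pair must name exactly two features")
    if view.feature_names != pair:
        raise ValueError(
            f"view features {view.feature_names} do not match map pair {pair}"
        )
    n_in = getattr(model, "n_features_in_", 2)
    if n_in != 2:
        raise ValueError(f"model was fitted on {n_in} features, expected 2")
    centers = (np.arange(resolution) + 0.5) / resolution
    f1, f2 = np.meshgrid(centers, centers, indexing="ij")
    grid = np.column_stack([f1.ravel(), f2.ravel()])
    pred = np.asarray(model.predict(grid), dtype=float).reshape(resolution, resolution)
    if not np.all(np.isfinite(pred)):
        raise ValueError("model produced non-finite predictions on the grid")
    return PredictionMap(
        feature_pair=pair,
        resolution=resolution,
        omega=pred,
        attainable=_attainability_mask(view, resolution),
        beta=view.beta,
        n_nodes=view.n_nodes,
    )


def map_series(
    records: pd.DataFrame | dict[int, pd.DataFrame],
    feature_pair: Sequence[str],
    betas: Iterable[float] | None = None,
    *,
    fixed_beta: float = 1.0,
    resolution: int = 100,
    config: RegressionConfig | None = None,
    seed: int = 0,
) -> list[PredictionMap]:
    """A sequence of prediction maps along beta or along graph size.

    Two modes:

    * ``records`` a single record table and ``betas`` an iterable — one map
      per beta at fixed N (a beta series);
    * ``records`` a dict mapping N to record tables and ``betas`` None —
      one map per N at ``fixed_beta``, with the target rescaled to Omega/N
      so sizes are comparable.

    Each map's regressor is a support-vector model tuned by the standard
    grid-search protocol on that map's own view.
    """
    pair = tuple(feature_pair)
    config = config or RegressionConfig(kind="svm")
    if config.kind != "svm":
        raise ValueError("prediction maps require the smooth (svm) regressor")
    maps = []
    if isinstance(records, dict):
        if betas is not None:
            raise ValueError("pass either a beta grid or a size-indexed dict, not both")
        for i, n in enumerate(sorted(records)):
            view = project_and_dedup(records[n], pair, fixed_beta)
            scaled = view.frame.copy()
            scaled["omega"] = scaled["omega"] / n
            view = ExperimentView(
                frame=scaled, feature_names=pair, beta=fixed_beta, n_nodes=n
            )
            m = _fit_one_map(view, pair, resolution, config, seed, i)
            maps.append(
                PredictionMap(
                    feature_pair=m.feature_pair,
                    resolution=m.resolution,
                    omega=m.omega,
                    attainable=m.attainable,
                    beta=m.beta,
                    n_nodes=n,
                    normalized=True,
                )
            )
        return maps
    if betas is None:
        raise ValueError("need a beta grid for a fixed-N series")
    for i, beta in enumerate(betas):
        view = project_and_dedup(records, pair, beta)
        maps.append(_fit_one_map(view, pair, resolution, config, seed, i))
    return maps


def _fit_one_map(view, pair, resolution, config, seed, index) -> PredictionMap:
    cell_seed = int(np.random.SeedSequence((seed, index)).generate_state(1)[0]) % (2**31)
    res = run_experiment(view, config, seed=cell_seed)
    return build_map(res.model, view, pair, resolution)
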