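"""Per-node records joining structural features to outbreak-size targets.

A record describes one node of one graph in the ensemble: its eight
predictor values plus the exact expected outbreak size Omega for each beta
on the grid, with that node as the infection seed.  The dataset for size N
therefore has N times as many records as there are nonisomorphic connected
graphs of N nodes (672 at N = 6; 117 million at N = 10).

Before any regression, the records projected onto the selected features and
one Omega(beta) target are stripped of exact duplicates — these arise
primarily from automorphically equivalent nodes — so that no test row can be
identical to a training row.  Rows that agree on every feature but differ in
the target are *not* duplicates and are kept: they are the irreducible
prediction error of that feature combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from .centrality import FEATURE_NAMES

__all__ = [
    "ExperimentView",
    "omega_column",
    "assemble",
    "project_and_dedup",
    "ensemble_records",
]


def omega_column(beta: float) -> str:
    """Column name for the Omega target at one transmission rate."""
    return f"omega_{beta:g}"


@dataclass(frozen=True)
class ExperimentView:
    """Deduplicated (features, target) table for one regression experiment."""

    frame: pd.DataFrame  # columns: feature_names + ["omega"]
    feature_names: tuple[str, ...]
    beta: float
    n_nodes: int | None = None

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def X(self):
        return self.frame[list(self.feature_names)].to_numpy()

    @property
    def y(self):
        return self.frame["omega"].to_numpy()


def assemble(features: pd.DataFrame, omega: pd.DataFrame) -> pd.DataFrame:
    """Join the feature table to the outbreak table on (graph_id, node).

    ``features`` comes from :func:`sirpredict.centrality.feature_table`;
    ``omega`` is tidy (graph_id, seed, beta, omega) from
    :func:`sirpredict.sir_exact.outbreak_table` output, possibly concatenated
    over many graphs.  Omega is pivoted wide, one column per beta, so each
    row is one complete record.  The two inputs must cover exactly the same
    (graph_id, node) pairs.
    """
    omega = omega.rename(columns={"seed": "node"})
    fkeys = set(map(tuple, features[["graph_id", "node"]].itertuples(index=False)))
    okeys = set(map(tuple, omega[["graph_id", "node"]].drop_duplicates().itertuples(index=False)))
    if fkeys != okeys:
        missing_o = sorted(fkeys - okeys)[:5]
        missing_f = sorted(okeys - fkeys)[:5]
        raise ValueError(
            "features and omega cover different (graph_id, node) sets; "
            f"missing from omega: {missing_o}; missing from features: {missing_f}"
        )
    wide = omega.pivot_table(
        index=["graph_id", "node"], columns="beta", values="omega"
    )
    wide.columns = [omega_column(b) for b in wide.columns]
    records = features.merge(wide.reset_index(), on=["graph_id", "node"], how="inner")
    return records.sort_values(["graph_id", "node"], ignore_index=True)


def project_and_dedup(
    records: pd.DataFrame, feature_combo: Sequence[str], beta: float
) -> ExperimentView:
    """Select feature columns and one target, drop exact duplicate rows.

    The duplicate key is the full selected record — features *and* target —
    so only rows carrying literally no new information are removed (first
    occurrence kept, order preserved).  The operation is idempotent.

    Values are rounded to 12 decimal places before comparison (and the view
    carries the rounded values): records of automorphically equivalent nodes
    are mathematically identical but the spectral centralities can differ in
    the last floating-point digit, and a duplicate rule blind to that would
    leak structurally identical rows across the train/test split.  12
    decimals is far below any difference of scientific interest here.
    """
    combo = tuple(feature_combo)
    if not combo:
        raise ValueError("feature_combo must be non-empty")
    unknown = [f for f in combo if f not in FEATURE_NAMES]
    if unknown:
        raise ValueError(f"unknown feature name(s) {unknown}; valid: {FEATURE_NAMES}")
    target = omega_column(beta)
    if target not in records.columns:
        raise ValueError(f"no target column {target!r} in records")
    frame = records[list(combo) + [target]].rename(columns={target: "omega"})
    frame = frame.round(12).drop_duplicates(keep="first", ignore_index=True)
    n_nodes = None
    if "node" in records.columns:
        n_nodes = int(records["node"].max()) + 1
    return ExperimentView(frame=frame, feature_names=combo, beta=beta, n_nodes=n_nodes)


def ensemble_records(n: int, params=None, centrality_config=None, graphs=None) -> pd.DataFrame:
    """Complete record table for the size-N ensemble: enumerate (or accept)
    the graphs, solve the exact outbreak sizes orbit-by-orbit, compute the
    centralities, and join.  Convenience wrapper over the stage functions."""
    from .centrality import feature_table
    from .graphspace import enumerate_connected_graphs
    from .sir_exact import outbreak_table

    if graphs is None:
        graphs = enumerate_connected_graphs(n)
    omega = pd.concat([outbreak_table(g, params) for g in graphs], ignore_index=True)
    return assemble(feature_table(graphs, centrality_config), omega)
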