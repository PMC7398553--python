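"""Exact expected SIR outbreak sizes on small graphs.

The continuous-time Markovian SIR model on a graph has two event types:
infection across an S-I edge at rate beta per edge, and recovery of an
infected node at rate nu = 1 (time is measured in units of the recovery
time, so beta is the only parameter).  From a configuration C — an
assignment of S/I/R to the nodes — the embedded jump chain moves to each
infection successor with probability beta / (beta * M_SI + N_I) per S-I
edge and to each recovery successor with probability 1 / (beta * M_SI + N_I)
per infected node, where M_SI counts S-I edges and N_I infected nodes.

Seeding one node infected and unfolding the full configuration tree
breadth-first, merging identical configurations by summing their
probability mass, yields the exact expected outbreak size

    Omega = sum over absorbing configurations (N_I = 0) of  P(C) * N_R(C),

a deterministic quantity despite the stochastic dynamics.  Every value of
beta is propagated through the same traversal at once, since the set of
reachable configurations does not depend on beta.

Two independent oracles validate the solver: a full 3^N absorbing-Markov
linear solve, and an event-driven (Gillespie) stochastic simulation.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.sparse
import scipy.sparse.linalg

from .graphspace import Graph, OrbitPartition, node_orbits

__all__ = [
    "SIRParameters",
    "DEFAULT_BETAS",
    "successor_distribution",
    "expected_outbreak_size",
    "outbreak_table",
    "markov_oracle",
    "gillespie_estimate",
]

S, I, R = 0, 1, 2

#: The nine transmission rates studied: a geometric sequence with common
#: ratio 2 from 1/16 to 16, bracketing the recovery rate nu = 1.
DEFAULT_BETAS: tuple[float, ...] = tuple(float(2.0**k) for k in range(-4, 5))


@dataclass(frozen=True)
class SIRParameters:
    """Transmission-rate grid for the SIR model (recovery rate fixed at 1)."""

    betas: tuple[float, ...] = DEFAULT_BETAS

    def __post_init__(self) -> None:
        b = tuple(self.betas)
        if not b:
            raise ValueError("need at least one beta")
        if any(x <= 0 for x in b):
            raise ValueError("all betas must be positive")
        if any(b[i] >= b[i + 1] for i in range(len(b) - 1)):
            raise ValueError("betas must be strictly increasing")
        object.__setattr__(self, "betas", b)


def _si_edges(state: Sequence[int], edges) -> list[tuple[int, int]]:
    """S-I edges as (susceptible endpoint, infected endpoint) pairs."""
    out = []
    for u, v in edges:
        su, sv = state[u], state[v]
        if su == S and sv == I:
            out.append((u, v))
        elif su == I and sv == S:
            out.append((v, u))
    return out


def successor_distribution(
    state: Sequence[int], g: Graph, beta: float
) -> list[tuple[tuple[int, ...], float]]:
    """One-step distribution of the embedded jump chain from ``state``.

    Returns (next state, probability) pairs: one infection successor per S-I
    edge with probability beta/(beta*M_SI + N_I) each, and one recovery
    successor per infected node with probability 1/(beta*M_SI + N_I) each.
    The probabilities sum to one.

    Raises if the state is absorbing (no infected nodes): absorbing states
    have no successors.
    """
    state = tuple(state)
    if len(state) != g.n_nodes:
        raise ValueError("state length does not match graph size")
    infected = [i for i, s in enumerate(state) if s == I]
    if not infected:
        raise ValueError("absorbing configuration (N_I = 0) has no successors")
    si = _si_edges(state, g.edges)
    denom = beta * len(si) + len(infected)
    out = []
    for s_node, _ in si:
        child = list(state)
        child[s_node] = I
        out.append((tuple(child), beta / denom))
    for i in infected:
        child = list(state)
        child[i] = R
        out.append((tuple(child), 1.0 / denom))
    return out


def _event_depth(state: Sequence[int]) -> int:
    """Number of events since seeding: (N_I + N_R - 1) infections + N_R
    recoveries.  Depends only on the configuration, so identical
    configurations always meet at the same breadth-first depth."""
    n_i = sum(1 for s in state if s == I)
    n_r = sum(1 for s in state if s == R)
    return n_i + 2 * n_r - 1


def expected_outbreak_size(
    g: Graph,
    seed: int,
    params: SIRParameters | None = None,
    *,
    exact: bool = False,
    check_conservation: bool = True,
) -> dict[float, float]:
    """Exact expected outbreak size Omega(beta) for an outbreak seeded at one node.

    Unfolds the configuration tree breadth-first from the all-susceptible
    configuration with ``seed`` infected, carrying a per-beta probability
    vector on every configuration and merging identical configurations by
    summing their mass.  All betas share one traversal.  Absorbing
    configurations (N_I = 0) contribute mass * N_R to Omega and leave the
    frontier immediately.

    Parameters
    ----------
    exact
        Carry probabilities as exact rationals (``fractions.Fraction``)
        instead of float64.  Slow; intended for oracle-grade checks on tiny
        graphs.  Betas are converted with ``Fraction(beta)`` which is exact
        for the default dyadic grid.
    check_conservation
        Assert at every depth that active + absorbed mass equals 1 per beta
        (to 1e-12 in float mode, exactly in rational mode).

    Returns
    -------
    dict mapping each beta to Omega, with 1 <= Omega <= N.
    """
    if params is None:
        params = SIRParameters()
    if not (0 <= seed < g.n_nodes):
        raise ValueError(f"seed {seed} out of range for {g.n_nodes} nodes")
    n = g.n_nodes
    nb = len(params.betas)
    if exact:
        betas = np.array([Fraction(b) for b in params.betas], dtype=object)
        one = np.array([Fraction(1)] * nb, dtype=object)
        omega = np.array([Fraction(0)] * nb, dtype=object)
    else:
        betas = np.asarray(params.betas, dtype=float)
        one = np.ones(nb)
        omega = np.zeros(nb)
    absorbed = omega.copy()

    init = tuple(I if i == seed else S for i in range(n))
    frontier: dict[tuple[int, ...], np.ndarray] = {init: one.copy()}
    depth = 0
    edges = sorted(g.edges)
    while frontier:
        nxt: dict[tuple[int, ...], np.ndarray] = {}
        for state, mass in frontier.items():
            infected = [i for i, s in enumerate(state) if s == I]
            si = _si_edges(state, edges)
            denom = betas * len(si) + len(infected)
            p_inf = betas / denom
            p_rec = one / denom
            for s_node, _ in si:
                child = list(state)
                child[s_node] = I
                _accumulate(nxt, tuple(child), mass * p_inf)
            for i in infected:
                child = list(state)
                child[i] = R
                child_t = tuple(child)
                if I not in child_t:
                    n_r = sum(1 for s in child_t if s == R)
                    omega = omega + mass * p_rec * n_r
                    absorbed = absorbed + mass * p_rec
                else:
                    _accumulate(nxt, child_t, mass * p_rec)
        depth += 1
        if nxt:
            assert all(_event_depth(s) == depth for s in nxt)
        if check_conservation:
            active = sum(nxt.values(), omega * 0)
            total = active + absorbed
            if exact:
                assert all(t == 1 for t in total)
            else:
                assert np.max(np.abs(total - 1.0)) < 1e-12, "probability leak"
        frontier = nxt
    if exact:
        return {b: w for b, w in zip(params.betas, omega)}
    return {b: float(w) for b, w in zip(params.betas, omega)}


def _accumulate(d: dict, key, value) -> None:
    if key in d:
        d[key] = d[key] + value
    else:
        d[key] = value


def outbreak_table(
    g: Graph,
    params: SIRParameters | None = None,
    orbits: OrbitPartition | None = None,
) -> pd.DataFrame:
    """Omega for every (seed node, beta) of one graph, as a tidy frame.

    The solver runs once per automorphism orbit — structurally equivalent
    seeds provably give identical Omega — and the result is copied to every
    orbit member, so the frame always has N * len(betas) rows.

    Columns: graph_id, seed, beta, omega.
    """
    if params is None:
        params = SIRParameters()
    if orbits is None:
        orbits = node_orbits(g)
    if orbits.graph_id != g.graph_id:
        raise ValueError("orbit partition belongs to a different graph")
    covered = sorted(i for orbit in orbits.orbits for i in orbit)
    if covered != list(range(g.n_nodes)):
        raise ValueError("orbit partition does not cover the graph's nodes")
    rows = []
    for orbit in orbits.orbits:
        omega = expected_outbreak_size(g, orbit[0], params)
        for node in orbit:
            for beta in params.betas:
                rows.append((g.graph_id, node, beta, omega[beta]))
    frame = pd.DataFrame(rows, columns=["graph_id", "seed", "beta", "omega"])
    return frame.sort_values(["seed", "beta"], ignore_index=True)


# ---------------------------------------------------------------------------
# independent oracles


def markov_oracle(g: Graph, seed: int, beta: float) -> float:
    """Omega via the full 3^N absorbing Markov chain (independent oracle).

    Enumerates every S/I/R configuration, builds the jump-chain transition
    matrix, and solves the linear system h = P h with h(C) = N_R(C) on
    absorbing states; h at the seeded configuration is the expected number of
    ever-infected nodes.  This route never unfolds the tree and shares no
    code with :func:`expected_outbreak_size` beyond the transition rule.

    Restricted to N <= 6 (the state space is 3^N).
    """
    n = g.n_nodes
    if n > 6:
        raise ValueError("markov_oracle supports N <= 6 only (3^N states)")
    if not (0 <= seed < n):
        raise ValueError("seed out of range")
    n_states = 3**n
    edges = sorted(g.edges)

    def decode(idx: int) -> tuple[int, ...]:
        out = []
        for _ in range(n):
            out.append(idx % 3)
            idx //= 3
        return tuple(out)

    def encode(state: Sequence[int]) -> int:
        idx = 0
        for s in reversed(state):
            idx = idx * 3 + s
        return idx

    rows, cols, vals = [], [], []
    b = np.zeros(n_states)
    for idx in range(n_states):
        state = decode(idx)
        if I not in state:
            rows.append(idx)
            cols.append(idx)
            vals.append(1.0)
            b[idx] = sum(1 for s in state if s == R)
            continue
        rows.append(idx)
        cols.append(idx)
        vals.append(1.0)
        for child, p in successor_distribution(state, g, beta):
            rows.append(idx)
            cols.append(encode(child))
            vals.append(-p)
    a = scipy.sparse.csr_matrix((vals, (rows, cols)), shape=(n_states, n_states))
    h = scipy.sparse.linalg.spsolve(a.tocsc(), b)
    init = tuple(I if i == seed else S for i in range(n))
    return float(h[encode(init)])


@dataclass(frozen=True)
class GillespieResult:
    mean: float
    stderr: float
    n_runs: int


def gillespie_estimate(
    g: Graph, seed: int, beta: float, n_runs: int, rng_seed: int
) -> GillespieResult:
    """Monte-Carlo estimate of Omega by event-driven simulation.

    Simulates the embedded jump chain directly (the final size depends only
    on the event sequence, not on holding times): at each step an infection
    happens with probability beta*M_SI/(beta*M_SI + N_I), with the S-I edge
    chosen uniformly, otherwise a uniformly chosen infected node recovers.
    Returns the sample mean of the final recovered count and its standard
    error.
    """
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    if not (0 <= seed < g.n_nodes):
        raise ValueError("seed out of range")
    rng = np.random.default_rng(rng_seed)
    masks = g.adjacency_masks()
    full = (1 << g.n_nodes) - 1
    total = 0.0
    total_sq = 0.0
    for _ in range(n_runs):
        inf_mask = 1 << seed
        rec_mask = 0
        n_inf = 1
        while n_inf:
            s_mask = full & ~inf_mask & ~rec_mask
            targets = []  # susceptible endpoints of S-I edges, w/ multiplicity
            m = inf_mask
            while m:
                i = (m & -m).bit_length() - 1
                m &= m - 1
                t = masks[i] & s_mask
                while t:
                    j = (t & -t).bit_length() - 1
                    t &= t - 1
                    targets.append(j)
            m_si = len(targets)
            if m_si and rng.random() < beta * m_si / (beta * m_si + n_inf):
                j = targets[rng.integers(m_si)]
                inf_mask |= 1 << j
                n_inf += 1
            else:
                # uniform infected node recovers
                k = int(rng.integers(n_inf))
                m = inf_mask
                for _ in range(k):
                    m &= m - 1
                node = (m & -m).bit_length() - 1
                inf_mask &= ~(1 << node)
                rec_mask |= 1 << node
                n_inf -= 1
        size = rec_mask.bit_count()
        total += size
        total_sq += size * size
    mean = total / n_runs
    var = max(total_sq / n_runs - mean * mean, 0.0) * n_runs / max(n_runs - 1, 1)
    return GillespieResult(mean=mean, stderr=float(np.sqrt(var / n_runs)), n_runs=n_runs)
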