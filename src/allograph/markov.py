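"""Markov transient half-times of a random walk started at the source.

A discrete-time random walker moves over the atomistic graph with
transition probabilities proportional to edge weights,

    P = alpha * I + (1 - alpha) * D^{-1} A,

where A is the weighted adjacency matrix, D the diagonal of weighted
degrees and alpha a laziness parameter.  Starting from the uniform
distribution over the source atoms, each atom's transient half-time
t_1/2 is the first time step at which its occupation probability
reaches half its stationary value pi_i = d_i / sum_j d_j.  Small
half-times mean fast, strong communication with the source.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse

from .graph_construction import AtomisticGraph
from .spectral import SourceSite, _source_distances

__all__ = [
    "TransientResult",
    "PeriodicityError",
    "ConvergenceError",
    "transition_operator",
    "stationary_distribution",
    "transient_half_times",
    "walker_snapshots",
    "markov_transients",
]


class PeriodicityError(RuntimeError):
    """The walk oscillates (bipartite graph with alpha = 0)."""


class ConvergenceError(RuntimeError):
    pass


def transition_operator(graph: AtomisticGraph, alpha: float = 0.0):
    """Row-stochastic transition matrix P = alpha I + (1-alpha) D^-1 A."""
    if not 0.0 <= alpha < 1.0:
        raise ValueError("laziness alpha must be in [0, 1)")
    A = graph.adjacency()
    deg = np.asarray(A.sum(axis=1)).ravel()
    if np.any(deg <= 0):
        isolated = np.flatnonzero(deg <= 0)
        raise ValueError(f"isolated atoms with zero degree: {isolated.tolist()}")
    P = sparse.diags(1.0 / deg) @ A
    if alpha > 0:
        P = alpha * sparse.eye(graph.n_atoms, format="csr") + (1 - alpha) * P
    return P.tocsr()


def stationary_distribution(graph: AtomisticGraph) -> np.ndarray:
    """pi_i proportional to weighted degree (alpha-independent)."""
    deg = graph.weighted_degree
    return deg / deg.sum()


def _initial_distribution(n: int, source_atoms: np.ndarray) -> np.ndarray:
    p0 = np.zeros(n)
    p0[source_atoms] = 1.0 / len(source_atoms)
    return p0


def transient_half_times(
    P,
    pi: np.ndarray,
    source_atoms: np.ndarray,
    t_max: int = 10**6,
    interpolate: bool = False,
) -> tuple[np.ndarray, int]:
    """First-crossing half-times for every node.

    Iterates p(t+1) = p(t) P from the uniform distribution over the
    source atoms and records, per node, the first t with
    p_i(t) >= pi_i / 2.  Probability mass is checked to be conserved to
    1e-12 at every step.  Returns (t_half, steps_run).
    """
    if t_max < 1:
        raise ValueError("t_max must be >= 1")
    n = P.shape[0]
    p = _initial_distribution(n, source_atoms)
    target = pi / 2.0
    t_half = np.full(n, -1.0)
    t_half[p >= target] = 0.0
    prev_prev = None
    t = 0
    while t < t_max and np.any(t_half < 0):
        prev = p
        p = p @ P
        t += 1
        mass = p.sum()
        if abs(mass - 1.0) > 1e-12:
            raise ConvergenceError(
                f"probability mass drifted to {mass!r} at step {t}"
            )
        p /= mass  # keep rounding error from accumulating over long runs
        newly = (t_half < 0) & (p >= target)
        if interpolate:
            frac = (target[newly] - prev[newly]) / (p[newly] - prev[newly])
            t_half[newly] = t - 1 + np.clip(frac, 0.0, 1.0)
        else:
            t_half[newly] = t
        # periodicity: state repeats with period 2 while nodes are unreached
        if t % 64 == 0:
            if prev_prev is not None and np.allclose(p, prev_prev, atol=1e-13):
                worst = int(np.argmax(np.where(t_half < 0, target - p, -np.inf)))
                raise PeriodicityError(
                    f"walk oscillates with period 2 (bipartite graph?); node "
                    f"{worst} unreached at step {t}; use laziness alpha > 0"
                )
            prev_prev = p.copy()
    if np.any(t_half < 0):
        worst = int(np.argmax(np.where(t_half < 0, target - p, -np.inf)))
        raise ConvergenceError(
            f"node {worst} did not reach half its stationary probability "
            f"within t_max={t_max} steps; consider laziness alpha > 0"
        )
    return t_half, t


def walker_snapshots(P, source_atoms: np.ndarray, times) -> dict[int, np.ndarray]:
    """Probability vectors p(t) for the requested time points."""
    times = sorted(set(int(t) for t in times))
    if times and times[0] < 0:
        raise ValueError("snapshot times must be non-negative")
    n = P.shape[0]
    p = _initial_distribution(n, source_atoms)
    out: dict[int, np.ndarray] = {}
    t = 0
    for target_t in times:
        while t < target_t:
            p = p @ P
            t += 1
        out[target_t] = p.copy()
    return out


@dataclass
class TransientResult:
    """Per-atom half-times and per-residue aggregates."""

    source: SourceSite
    alpha: float
    steps_run: int
    atom_table: pd.DataFrame = field(repr=False)
    residue_table: pd.DataFrame = field(repr=False)

    @property
    def t_half(self) -> np.ndarray:
        return self.atom_table["t_half"].to_numpy()


def markov_transients(
    graph: AtomisticGraph,
    source: SourceSite,
    alpha: float = 0.0,
    t_max: int = 10**6,
    interpolate: bool = False,
    auto_lazy: bool = True,
) -> TransientResult:
    """Transient half-times of every atom with respect to the source.

    Runs the pure walk (alpha = 0) by default and retries once with
    alpha = 0.5 if a period-2 oscillation is detected (bipartite
    graphs); the laziness actually used is recorded on the result.
    """
    pi = stationary_distribution(graph)
    try:
        P = transition_operator(graph, alpha)
        t_half, steps = transient_half_times(
            P, pi, source.source_atoms, t_max=t_max, interpolate=interpolate
        )
    except PeriodicityError:
        if not auto_lazy:
            raise
        alpha = 0.5
        P = transition_operator(graph, alpha)
        t_half, steps = transient_half_times(
            P, pi, source.source_atoms, t_max=t_max, interpolate=interpolate
        )

    dist = _source_distances(graph, graph.coords, source.source_atoms)
    residues = graph.residue_of_atom
    is_source = np.zeros(graph.n_atoms, dtype=bool)
    is_source[source.source_atoms] = True
    atom_table = pd.DataFrame(
        {
            "atom": np.arange(graph.n_atoms),
            "residue": [str(k) for k in residues],
            "distance_A": dist,
            "t_half": t_half,
            "pi": pi,
            "is_source": is_source,
        }
    )
    keys = list(dict.fromkeys(residues))
    by_res: dict = {}
    for i, k in enumerate(residues):
        by_res.setdefault(k, []).append(i)
    residue_table = pd.DataFrame(
        {
            "residue": [str(k) for k in keys],
            "residue_key": keys,
            "t_half_min": [t_half[by_res[k]].min() for k in keys],
            "t_half_mean": [t_half[by_res[k]].mean() for k in keys],
            "distance_A": [dist[by_res[k]].min() for k in keys],
            "is_source": [k in source.residues for k in keys],
        }
    )
    return TransientResult(
        source=source,
        alpha=alpha,
        steps_run=steps,
        atom_table=atom_table,
        residue_table=residue_table,
    )
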