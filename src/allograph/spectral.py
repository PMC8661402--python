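"""Bond-to-bond propensities via the weighted graph Laplacian.

Perturbations injected at a set of source bonds redistribute over the
other bonds of the structure.  The redistribution is governed by the
edge-to-edge transfer operator

    M = 1/2 * W * B^T * L^+ * B,

where B is the (node x edge) incidence matrix under an arbitrary but
fixed edge orientation, W the diagonal matrix of edge weights,
L = B W B^T the weighted Laplacian and L^+ its Moore-Penrose
pseudoinverse.  The propensity of bond b with respect to a source is
the summed magnitude of transfer from every source bond,

    Pi_b = sum_{b' in source} |M_{b, b'}|,

normalised over the non-source bonds so the redistributed fluctuation
sums to one.  One sparse linear solve per source bond is required; the
full m x m operator is never materialised.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse import csgraph
from scipy.sparse.linalg import splu

from .graph_construction import AtomisticGraph
from .structure_io import ResidueKey

__all__ = [
    "SourceSite",
    "SpectralCore",
    "PropensityResult",
    "SolverError",
    "SourceSiteError",
    "solve_laplacian",
    "transfer_column",
    "bond_propensities",
    "parse_residue_spec",
]


class SolverError(RuntimeError):
    pass


class SourceSiteError(ValueError):
    pass


def parse_residue_spec(spec: str) -> tuple[str, str | None, int, str]:
    """Parse ``chain:resname:number[icode]`` or ``chain:number[icode]``.

    Returns (chain_id, res_name or None, res_seq, i_code).
    """
    parts = spec.strip().split(":")
    if len(parts) == 2:
        chain, num = parts
        name = None
    elif len(parts) == 3:
        chain, name, num = parts
    else:
        raise ValueError(f"bad residue spec {spec!r}; use chain:resname:number")
    num = num.strip()
    icode = ""
    if num and num[-1].isalpha():
        icode = num[-1]
        num = num[:-1]
    return chain.strip(), (name.strip() or None) if name else None, int(num), icode


def _match_residues(graph: AtomisticGraph, specs) -> set[ResidueKey]:
    all_keys = set(graph.residue_of_atom)
    out: set[ResidueKey] = set()
    for item in specs:
        if isinstance(item, ResidueKey):
            if item not in all_keys:
                raise SourceSiteError(f"residue {item} not in structure")
            out.add(item)
            continue
        chain, name, num, icode = parse_residue_spec(item)
        hits = {
            k for k in all_keys
            if k.chain_id == chain and k.res_seq == num and k.i_code == icode
            and (name is None or k.res_name == name)
        }
        if not hits:
            raise SourceSiteError(f"residue spec {item!r} matches nothing")
        out |= hits
    return out


@dataclass
class SourceSite:
    """A set of residues acting as perturbation source.

    ``source_atoms`` are all atoms of those residues; ``source_bonds``
    are the collapsed bonds with at least one endpoint in the source.
    """

    residues: frozenset
    source_atoms: np.ndarray
    source_bonds: np.ndarray

    @classmethod
    def from_residues(cls, graph: AtomisticGraph, residues) -> "SourceSite":
        keys = _match_residues(graph, residues)
        if not keys:
            raise SourceSiteError("empty source site")
        atom_set = {
            i for i, k in enumerate(graph.residue_of_atom) if k in keys
        }
        if not atom_set:
            raise SourceSiteError("source residues contain no atoms")
        mask = np.zeros(graph.n_atoms, dtype=bool)
        mask[list(atom_set)] = True
        bonds = np.flatnonzero(mask[graph.pair_u] | mask[graph.pair_v])
        if bonds.size == 0:
            raise SourceSiteError("source residues have no incident bonds")
        return cls(
            residues=frozenset(keys),
            source_atoms=np.array(sorted(atom_set), dtype=int),
            source_bonds=bonds,
        )


class SpectralCore:
    """Incidence/Laplacian operators of a graph plus a cached factorization.

    The edge orientation is the fixed convention u -> v with u < v; all
    downstream quantities take absolute values, which makes results
    independent of this arbitrary choice.
    """

    def __init__(self, graph: AtomisticGraph):
        self.graph = graph
        n, m = graph.n_atoms, graph.n_bonds
        self.n, self.m = n, m
        rows = np.concatenate([graph.pair_u, graph.pair_v])
        cols = np.concatenate([np.arange(m), np.arange(m)])
        data = np.concatenate([np.ones(m), -np.ones(m)])
        self.B = sparse.csc_matrix((data, (rows, cols)), shape=(n, m))
        self.w = graph.pair_weight.copy()
        self.L = (self.B @ sparse.diags(self.w) @ self.B.T).tocsr()
        n_comp, labels = csgraph.connected_components(self.L, directed=False)
        self.n_components = int(n_comp)
        self.component_labels = labels
        self._comp_masks = [labels == c for c in range(n_comp)]
        # ground one node per component and factorize the reduced system
        grounded = np.array([np.flatnonzero(labels == c)[0] for c in range(n_comp)])
        keep = np.setdiff1d(np.arange(n), grounded)
        self._keep = keep
        self._lu = None
        if keep.size:
            L_red = self.L[np.ix_(keep, keep)].tocsc()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", sparse.SparseEfficiencyWarning)
                self._lu = splu(L_red)
        self.n_solves = 0

    def deflate(self, x: np.ndarray) -> np.ndarray:
        """Remove the per-component mean (projection onto range of L)."""
        out = x.astype(float).copy()
        for mask in self._comp_masks:
            out[mask] -= out[mask].mean()
        return out


def solve_laplacian(core: SpectralCore, rhs: np.ndarray) -> np.ndarray:
    """Solve L x = rhs for rhs orthogonal to per-component constants.

    Returns the deflated (minimum-norm) solution x = L^+ rhs, with
    relative residual at most 1e-10.
    """
    rhs = core.deflate(np.asarray(rhs, dtype=float))
    x = np.zeros(core.n)
    if core._lu is not None and core._keep.size:
        x[core._keep] = core._lu.solve(rhs[core._keep])
    x = core.deflate(x)
    core.n_solves += 1
    rhs_norm = np.linalg.norm(rhs)
    if rhs_norm > 0:
        resid = np.linalg.norm(core.L @ x - rhs) / rhs_norm
        if resid > 1e-10:
            raise SolverError(
                f"Laplacian solve did not reach tolerance: residual {resid:.3e}"
            )
    return x


def transfer_column(core: SpectralCore, source_bond: int) -> np.ndarray:
    """One column of the edge-to-edge transfer operator M.

    M_{., b'} = 1/2 * W * B^T * L^+ * (B e_{b'}), computed with a single
    deflated Laplacian solve.
    """
    if not (0 <= source_bond < core.m):
        raise IndexError(f"bond index {source_bond} out of range")
    rhs = np.asarray(core.B[:, source_bond].todense()).ravel()
    x = solve_laplacian(core, rhs)
    return 0.5 * core.w * (core.B.T @ x)


@dataclass
class PropensityResult:
    """Per-bond and per-residue propensities with distances from source."""

    source: SourceSite
    bond_table: pd.DataFrame = field(repr=False)
    residue_table: pd.DataFrame = field(repr=False)

    @property
    def raw(self) -> np.ndarray:
        return self.bond_table["raw_propensity"].to_numpy()

    @property
    def norm(self) -> np.ndarray:
        return self.bond_table["norm_propensity"].to_numpy()


def _source_distances(graph: AtomisticGraph, points: np.ndarray,
                      source_atoms: np.ndarray) -> np.ndarray:
    src = graph.coords[source_atoms]
    # min over source atoms of Euclidean distance
    d = np.linalg.norm(points[:, None, :] - src[None, :, :], axis=2)
    return d.min(axis=1)


def bond_propensities(core: SpectralCore, source: SourceSite) -> PropensityResult:
    """Propensity of every bond with respect to the source site.

    Pi_b sums |M_{b, b'}| over source bonds b'; the normalised value
    distributes over non-source bonds (summing to one).  Residue
    propensities add each non-source bond's normalised value to both
    endpoint residues (once for intra-residue bonds).
    """
    graph = core.graph
    labels = core.component_labels
    src_comps = set(labels[source.source_atoms].tolist())
    if len(src_comps) > 1:
        raise SourceSiteError(
            f"source atoms span {len(src_comps)} connected components"
        )
    if core.n_components > 1:
        warnings.warn(
            "graph is disconnected; propensities outside the source "
            "component are zero",
            stacklevel=2,
        )
    pi = np.zeros(core.m)
    for b in source.source_bonds:
        pi += np.abs(transfer_column(core, int(b)))

    is_source = np.zeros(core.m, dtype=bool)
    is_source[source.source_bonds] = True
    total = pi[~is_source].sum()
    norm = np.zeros(core.m)
    if total > 0:
        norm[~is_source] = pi[~is_source] / total

    mid = graph.bond_midpoints()
    dist = _source_distances(graph, mid, source.source_atoms)
    residues = graph.residue_of_atom
    bond_table = pd.DataFrame(
        {
            "bond": np.arange(core.m),
            "atom_u": graph.pair_u,
            "atom_v": graph.pair_v,
            "residue_u": [str(residues[u]) for u in graph.pair_u],
            "residue_v": [str(residues[v]) for v in graph.pair_v],
            "bond_type": graph.pair_types,
            "length_A": np.linalg.norm(
                graph.coords[graph.pair_u] - graph.coords[graph.pair_v], axis=1
            ),
            "distance_A": dist,
            "raw_propensity": pi,
            "norm_propensity": norm,
            "is_source": is_source,
        }
    )

    res_prop: dict[ResidueKey, float] = {}
    for b in np.flatnonzero(~is_source):
        ru = residues[graph.pair_u[b]]
        rv = residues[graph.pair_v[b]]
        res_prop[ru] = res_prop.get(ru, 0.0) + norm[b]
        if rv != ru:
            res_prop[rv] = res_prop.get(rv, 0.0) + norm[b]
    atom_dist = _source_distances(graph, graph.coords, source.source_atoms)
    res_dist: dict[ResidueKey, float] = {}
    for i, k in enumerate(residues):
        res_dist[k] = min(res_dist.get(k, np.inf), atom_dist[i])
    keys = list(dict.fromkeys(residues))  # file order
    residue_table = pd.DataFrame(
        {
            "residue": [str(k) for k in keys],
            "residue_key": keys,
            "propensity": [res_prop.get(k, 0.0) for k in keys],
            "distance_A": [res_dist[k] for k in keys],
            "is_source": [k in source.residues for k in keys],
        }
    )
    return PropensityResult(source=source, bond_table=bond_table,
                            residue_table=residue_table)
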