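"""Synthetic inputs: analytic toy graphs and miniature PDB structures.

Everything needed to exercise the package offline is generated here:
graph families with known spectral properties (paths, cycles, trees,
barbells, grids, random connected graphs) and small idealized
PDB-format structures (an extended tripeptide, an alpha-helical
10-mer, a stacked 4-mer nucleobase strand, a C2-symmetric dimer) built
from standard internal coordinates.
"""

from __future__ import annotations

import numpy as np
import networkx as nx

from .graph_construction import AtomisticGraph
from .structure_io import ResidueKey

__all__ = ["make_toy_graph", "make_mini_pdb", "place_atom"]


def _positions(G: nx.Graph, family: str, n: int, rng: np.random.Generator) -> np.ndarray:
    nodes = list(G.nodes)
    if family == "path":
        pts = np.zeros((n, 3))
        pts[:, 0] = 1.5 * np.arange(n)
    elif family == "cycle":
        ang = 2 * np.pi * np.arange(n) / n
        r = 1.5 / (2 * np.sin(np.pi / n))
        pts = np.column_stack([r * np.cos(ang), r * np.sin(ang), np.zeros(n)])
    elif family == "grid":
        pts = np.array([(1.5 * u, 1.5 * v, 0.0) for (u, v) in nodes])
    else:
        pts = 10.0 * rng.random((len(nodes), 3))
    return pts


def make_toy_graph(
    family: str,
    n: int = 10,
    m2: int | None = None,
    weight_scheme: str = "unit",
    seed: int = 0,
) -> AtomisticGraph:
    """Build a toy AtomisticGraph from a standard graph family.

    Families: path, cycle, tree, complete, barbell, grid,
    random-connected.  Weights are all 1 ('unit') or uniform in
    [0.5, 1.5] ('uniform-random', seeded).  Each node is assigned its
    own single-atom residue and a deterministic dummy coordinate so
    distance-based features exist.
    """
    if n < 2:
        raise ValueError("toy graphs need n >= 2")
    rng = np.random.default_rng(seed)
    if family == "path":
        G = nx.path_graph(n)
    elif family == "cycle":
        G = nx.cycle_graph(n)
    elif family == "tree":
        G = nx.random_labeled_tree(n, seed=int(rng.integers(2**31)))
    elif family == "complete":
        G = nx.complete_graph(n)
    elif family == "barbell":
        G = nx.barbell_graph(n, 0 if m2 is None else m2)
    elif family == "grid":
        side = int(np.ceil(np.sqrt(n)))
        G = nx.grid_2d_graph(side, side)
    elif family == "random-connected":
        p = max(0.1, 2.0 * np.log(n) / n)
        for attempt in range(100):
            G = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            if nx.is_connected(G):
                break
        else:
            raise RuntimeError("failed to draw a connected random graph")
    else:
        raise ValueError(f"unknown toy graph family {family!r}")
    nodes = list(G.nodes)
    relabel = {v: i for i, v in enumerate(nodes)}
    coords = _positions(G, family, len(nodes), rng)
    edges = []
    for u, v in sorted(tuple(sorted((relabel[a], relabel[b]))) for a, b in G.edges):
        w = 1.0 if weight_scheme == "unit" else float(rng.uniform(0.5, 1.5))
        edges.append((u, v, w))
    residues = [ResidueKey("A", i + 1, "", "GLY") for i in range(len(nodes))]
    return AtomisticGraph.from_edges(len(nodes), edges, coords, residues)


# --- idealized peptide geometry -------------------------------------------

# backbone bond lengths (A) and angles (deg)
_B_N_CA, _B_CA_C, _B_C_N, _B_C_O = 1.458, 1.525, 1.329, 1.231
_A_N_CA_C, _A_CA_C_N, _A_C_N_CA, _A_CA_C_O = 111.2, 116.2, 121.7, 120.8


def place_atom(a: np.ndarray, b: np.ndarray, c: np.ndarray,
               bond: float, angle_deg: float, dihedral_deg: float) -> np.ndarray:
    """Place atom d given three reference atoms and internal coordinates.

    Standard NeRF construction: |c-d| = bond, angle b-c-d and dihedral
    a-b-c-d as specified.
    """
    ang = np.deg2rad(angle_deg)
    dih = np.deg2rad(dihedral_deg)
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    d_local = np.array(
        [
            -bond * np.cos(ang),
            bond * np.sin(ang) * np.cos(dih),
            bond * np.sin(ang) * np.sin(dih),
        ]
    )
    return c + d_local[0] * bc + d_local[1] * m + d_local[2] * n


def _peptide_atoms(sequence: list[str], phi: float, psi: float,
                   chain: str = "A", start_serial: int = 1,
                   transform=None):
    """ATOM records (as dicts) for an ideal peptide with CB/OG side chains."""
    n_res = len(sequence)
    N = [np.array([0.0, 0.0, 0.0])]
    CA = [np.array([_B_N_CA, 0.0, 0.0])]
    ang = np.deg2rad(180.0 - _A_N_CA_C)
    C = [CA[0] + _B_CA_C * np.array([np.cos(ang), np.sin(ang), 0.0])]
    for i in range(1, n_res):
        N.append(place_atom(N[i - 1], CA[i - 1], C[i - 1], _B_C_N, _A_CA_C_N, psi))
        CA.append(place_atom(CA[i - 1], C[i - 1], N[i], _B_N_CA, _A_C_N_CA, 180.0))
        C.append(place_atom(C[i - 1], N[i], CA[i], _B_CA_C, _A_N_CA_C, phi))
    atoms = []
    serial = start_serial
    for i, res in enumerate(sequence):
        entries = [("N", "N", N[i]), ("CA", "C", CA[i]), ("C", "C", C[i])]
        if i + 1 < n_res:
            # carbonyl O anti to the next residue's N across the CA-C axis
            o = place_atom(N[i + 1], CA[i], C[i], _B_C_O, _A_CA_C_O, 180.0)
        else:
            o = place_atom(N[i], CA[i], C[i], _B_C_O, _A_CA_C_O, 0.0)
        entries.append(("O", "O", o))
        if res != "GLY":
            cb = place_atom(N[i], C[i], CA[i], 1.53, 110.1, -122.6)
            entries.append(("CB", "C", cb))
            if res == "SER":
                og = place_atom(N[i], CA[i], cb, 1.417, 110.8, 60.0)
                entries.append(("OG", "O", og))
        for name, el, xyz in entries:
            if transform is not None:
                xyz = transform(xyz)
            atoms.append(
                dict(serial=serial, name=name, element=el, res_name=res,
                     chain=chain, res_seq=i + 1, xyz=np.asarray(xyz, dtype=float),
                     hetero=False)
            )
            serial += 1
    return atoms


def _format(atoms) -> str:
    lines = []
    prev_chain = None
    for a in atoms:
        if prev_chain is not None and a["chain"] != prev_chain:
            lines.append("TER")
        record = "HETATM" if a["hetero"] else "ATOM"
        name = a["name"]
        name = f" {name:<3}" if len(a["element"]) == 1 and len(name) < 4 else f"{name:<4}"
        x, y, z = a["xyz"]
        lines.append(
            f"{record:<6}{a['serial']:>5} {name} {a['res_name']:>3} "
            f"{a['chain']:1}{a['res_seq']:>4}    "
            f"{x:8.3f}{y:8.3f}{z:8.3f}{1.0:6.2f}{0.0:6.2f}          "
            f"{a['element']:>2}"
        )
        prev_chain = a["chain"]
    lines.append("END")
    return "\n".join(lines) + "\n"


def _tripeptide_atoms(chain="A", start_serial=1, transform=None):
    return _peptide_atoms(["GLY", "ALA", "SER"], phi=-140.0, psi=135.0,
                          chain=chain, start_serial=start_serial,
                          transform=transform)


def make_mini_pdb(kind: str) -> str:
    """Generate miniature idealized PDB text fixtures.

    Kinds: 'tripeptide' (GLY-ALA-SER, extended, plus two waters),
    'helix10' (ALA 10-mer at alpha-helical phi/psi, i -> i+4 H-bond
    geometry), 'dna4' (four stacked six-membered nucleobase rings on a
    B-DNA-like helix axis) and 'dimer' (two C2-related tripeptide
    chains).  All outputs are deterministic, valid PDB v3.3 text.
    """
    if kind == "tripeptide":
        atoms = _tripeptide_atoms()
        serial = atoms[-1]["serial"] + 1
        for j, pos in enumerate(
            [np.array([8.0, 8.0, 5.0]), np.array([-6.0, 5.0, -4.0])]
        ):
            atoms.append(
                dict(serial=serial + j, name="O", element="O", res_name="HOH",
                     chain="A", res_seq=101 + j, xyz=pos, hetero=True)
            )
        return _format(atoms)
    if kind == "helix10":
        atoms = _peptide_atoms(["ALA"] * 10, phi=-57.0, psi=-47.0)
        return _format(atoms)
    if kind == "dna4":
        atoms = []
        serial = 1
        rise, twist, ring_r, axis_r = 3.4, 36.0, 1.39, 2.0
        for i in range(4):
            rot = np.deg2rad(twist * i)
            Rz = np.array(
                [[np.cos(rot), -np.sin(rot), 0],
                 [np.sin(rot), np.cos(rot), 0],
                 [0, 0, 1]]
            )
            centroid = Rz @ np.array([axis_r, 0.0, 0.0]) + np.array([0, 0, rise * i])
            names = ["N1", "C2", "N3", "C4", "C5", "C6"]
            for j, nm in enumerate(names):
                theta = np.deg2rad(60.0 * j)
                local = np.array(
                    [ring_r * np.cos(theta), ring_r * np.sin(theta), 0.0]
                )
                xyz = centroid + Rz @ local
                atoms.append(
                    dict(serial=serial, name=nm, element=nm[0], res_name="DA",
                         chain="X", res_seq=i + 1, xyz=xyz, hetero=False)
                )
                serial += 1
        return _format(atoms)
    if kind == "dimer":
        a_chain = _tripeptide_atoms(chain="A")
        # C2 rotation about the z axis through (4, 0): proper rigid transform
        center = np.array([4.0, 0.0, 0.0])

        def c2(p):
            q = p - center
            return center + np.array([-q[0], -q[1], q[2]])

        b_chain = _tripeptide_atoms(
            chain="B", start_serial=a_chain[-1]["serial"] + 1, transform=c2
        )
        return _format(a_chain + b_chain)
    raise ValueError(f"unknown fixture kind {kind!r}")
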