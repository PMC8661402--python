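"""Atomistic, energy-weighted graph construction.

Every atom of a filtered :class:`~allograph.structure_io.Structure`
becomes a graph node; covalent bonds and weak interactions (hydrogen
bonds, hydrophobic contacts, salt bridges / screened electrostatics and
pi-pi stacking) become edges weighted by interaction energy magnitudes
in kJ/mol.  The resulting graph encodes the physico-chemical coupling
through which fluctuations propagate across the structure.

The energy model is deliberately simple and fully tabulated in
:class:`EnergyConfig`: covalent edges carry mean bond-dissociation
energies, hydrogen bonds a 12-10 distance-angle potential, hydrophobic
contacts an exponentially decaying well, and charged-group contacts a
screened Coulomb term with a distance-dependent dielectric.  Downstream
quantile scores are rank-based, so they are robust to monotone changes
of these constants.
"""

from __future__ import annotations

import functools
from dataclasses import asdict, dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .structure_io import EmptySelectionError, ResidueKey, Structure

__all__ = [
    "BondType",
    "BondEdge",
    "AtomisticGraph",
    "EnergyConfig",
    "UnknownElementError",
    "detect_covalent",
    "detect_hydrogen_bonds",
    "detect_hydrophobic",
    "detect_electrostatic_and_salt_bridges",
    "detect_pi_pi",
    "build_graph",
]


class UnknownElementError(ValueError):
    pass


class EmptyGraphError(ValueError):
    pass


class BondType(str, Enum):
    COVALENT = "COVALENT"
    HYDROGEN = "HYDROGEN"
    HYDROPHOBIC = "HYDROPHOBIC"
    ELECTROSTATIC = "ELECTROSTATIC"
    SALT_BRIDGE = "SALT_BRIDGE"
    PI_PI = "PI_PI"


@dataclass(frozen=True)
class BondEdge:
    """One interaction between two atoms (indices into the structure)."""

    atom_u: int
    atom_v: int
    bond_type: BondType
    weight: float  # kJ/mol, stored as magnitude, > 0
    length: float  # Angstrom

    def pair(self) -> tuple[int, int]:
        return (self.atom_u, self.atom_v) if self.atom_u < self.atom_v else (
            self.atom_v,
            self.atom_u,
        )


@dataclass
class EnergyConfig:
    """All detection cutoffs (Angstrom) and energy constants (kJ/mol)."""

    # covalent
    covalent_tolerance: float = 0.45
    conect_tolerance_factor: float = 1.5
    # hydrogen bonds (Mayo-style 12-10 potential on the donor-acceptor
    # distance R, modulated by cos^2 of the D-H...A angle)
    hb_well_depth: float = 33.5  # V0, 8 kcal/mol
    hb_r0: float = 2.8  # equilibrium D...A distance
    hb_ha_cutoff: float = 3.0  # H...A, explicit-hydrogen route
    hb_da_cutoff: float = 3.5  # D...A, heavy-atom fallback route
    hb_angle_min_deg: float = 90.0
    hb_include_sulfur: bool = False
    # hydrophobic: |E(r)| = eps * exp(-(r - r0) / sigma)
    hydrophobic_eps: float = 4.6
    hydrophobic_r0: float = 3.8
    hydrophobic_sigma: float = 1.0
    hydrophobic_cutoff: float = 8.0
    # electrostatics: |E(r)| = k |q1 q2| / (eps_r(r) * r), eps_r = slope * r
    coulomb_k: float = 1389.35  # kJ/mol * Angstrom * e^-2
    dielectric_slope: float = 4.0  # per Angstrom
    salt_cutoff: float = 4.0
    elec_cutoff: float = 8.0
    # pi-pi stacking
    pi_cutoff: float = 5.5  # ring-centroid distance
    pi_angle_max_deg: float = 30.0
    pi_weight: float = 8.0
    pi_include_protein_rings: bool = False
    # detector switches
    enable_hydrogen: bool = True
    enable_hydrophobic: bool = True
    enable_electrostatic: bool = True
    enable_pi_pi: bool = True
    # extra formal charges: {(res_name, atom_name): charge}
    extra_charges: dict = field(default_factory=dict)

    def __post_init__(self):
        for name in (
            "covalent_tolerance",
            "hb_well_depth",
            "hb_r0",
            "hb_ha_cutoff",
            "hb_da_cutoff",
            "hydrophobic_eps",
            "hydrophobic_r0",
            "hydrophobic_sigma",
            "hydrophobic_cutoff",
            "coulomb_k",
            "dielectric_slope",
            "salt_cutoff",
            "elec_cutoff",
            "pi_cutoff",
            "pi_weight",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"EnergyConfig.{name} must be positive")

    @classmethod
    def from_file(cls, path: str | Path) -> "EnergyConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        return cls(**data)

    def to_file(self, path: str | Path) -> None:
        import yaml

        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=True))


# Covalent radii (Angstrom), Cordero et al. consensus values.
COVALENT_RADII = {
    "H": 0.31, "D": 0.31, "HE": 0.28, "LI": 1.28, "BE": 0.96, "B": 0.84,
    "C": 0.76, "N": 0.71, "O": 0.66, "F": 0.57, "NA": 1.66, "MG": 1.41,
    "AL": 1.21, "SI": 1.11, "P": 1.07, "S": 1.05, "CL": 1.02, "K": 2.03,
    "CA": 1.76, "MN": 1.39, "FE": 1.32, "CO": 1.26, "NI": 1.24, "CU": 1.32,
    "ZN": 1.22, "SE": 1.20, "BR": 1.20, "MO": 1.54, "I": 1.39, "W": 1.62,
}

# Mean bond-dissociation energies (kJ/mol) keyed by element pair and
# bond order; order 2 covers double and aromatic-double template bonds.
BOND_ENERGIES = {
    (("C", "C"), 1): 346.0, (("C", "C"), 2): 602.0, (("C", "C"), 3): 835.0,
    (("C", "H"), 1): 411.0, (("C", "N"), 1): 305.0, (("C", "N"), 2): 615.0,
    (("C", "O"), 1): 358.0, (("C", "O"), 2): 749.0, (("C", "S"), 1): 272.0,
    (("C", "F"), 1): 485.0, (("C", "CL"), 1): 327.0, (("C", "BR"), 1): 285.0,
    (("C", "I"), 1): 213.0, (("H", "H"), 1): 436.0, (("H", "N"), 1): 386.0,
    (("H", "O"), 1): 459.0, (("H", "S"), 1): 363.0, (("H", "P"), 1): 322.0,
    (("N", "N"), 1): 167.0, (("N", "N"), 2): 418.0, (("N", "O"), 1): 201.0,
    (("N", "O"), 2): 607.0, (("O", "O"), 1): 142.0, (("O", "P"), 1): 335.0,
    (("O", "P"), 2): 544.0, (("O", "S"), 1): 364.0, (("O", "S"), 2): 522.0,
    (("S", "S"), 1): 266.0, (("P", "S"), 1): 335.0,
}
DEFAULT_BOND_ENERGY = {1: 300.0, 2: 600.0, 3: 800.0}


def bond_energy(el_u: str, el_v: str, order: int = 1) -> float:
    key = (tuple(sorted((el_u.upper(), el_v.upper()))), order)
    val = BOND_ENERGIES.get(key)
    if val is None:
        val = DEFAULT_BOND_ENERGY.get(order, 300.0)
    return val


@functools.lru_cache(maxsize=256)
def _template_bonds(res_name: str) -> dict[frozenset, int] | None:
    """Bond orders of a chemical-component template, keyed by atom-name pair.

    Uses biotite's bundled component dictionary; returns None when the
    residue code is unknown (e.g. exotic ligands).
    """
    try:
        import biotite.structure.info as info

        res = info.residue(res_name)
    except Exception:
        return None
    if res is None or res.bonds is None:
        return None
    out: dict[frozenset, int] = {}
    names = res.atom_name
    for i, j, order in res.bonds.as_array():
        o = int(order)
        # biotite encodes aromatic bonds as 5 (single) / 6 (double)
        o = {5: 1, 6: 2, 7: 1, 0: 1}.get(o, o)
        out[frozenset((names[i], names[j]))] = min(o, 3)
    return out


# Hydrogen-bond donor/acceptor heavy atoms for the heavy-atom fallback
# route (no explicit hydrogens in the file).
_DONOR_ATOMS = {
    "ARG": {"NE", "NH1", "NH2"}, "ASN": {"ND2"}, "GLN": {"NE2"},
    "HIS": {"ND1", "NE2"}, "LYS": {"NZ"}, "TRP": {"NE1"},
    "SER": {"OG"}, "THR": {"OG1"}, "TYR": {"OH"}, "CYS": {"SG"},
}
_ACCEPTOR_ATOMS = {
    "ASN": {"OD1"}, "GLN": {"OE1"}, "ASP": {"OD1", "OD2"},
    "GLU": {"OE1", "OE2"}, "HIS": {"ND1", "NE2"}, "SER": {"OG"},
    "THR": {"OG1"}, "TYR": {"OH"}, "MET": {"SD"},
}

# Formal charges of ionisable groups (unit charges per listed atom).
CHARGED_ATOMS = {
    ("ARG", "NH1"): 1.0, ("ARG", "NH2"): 1.0, ("ARG", "NE"): 1.0,
    ("LYS", "NZ"): 1.0, ("HIS", "ND1"): 1.0, ("HIS", "NE2"): 1.0,
    ("ASP", "OD1"): -1.0, ("ASP", "OD2"): -1.0,
    ("GLU", "OE1"): -1.0, ("GLU", "OE2"): -1.0,
}
_PHOSPHATE_O = {"OP1", "OP2", "OP3", "O1P", "O2P", "O3P"}

_STANDARD_AA = {
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
}

# Aromatic ring atom names per residue code (6-membered rings for the
# nucleobases; protein rings are optional and off by default).
_NUCLEOBASE_RING = ("N1", "C2", "N3", "C4", "C5", "C6")
RING_ATOMS = {
    **{code: (_NUCLEOBASE_RING,) for code in
       ("DA", "DG", "DC", "DT", "DU", "A", "G", "C", "U", "T")},
}
_PROTEIN_RING_ATOMS = {
    "PHE": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TYR": (("CG", "CD1", "CD2", "CE1", "CE2", "CZ"),),
    "TRP": (("CD2", "CE2", "CE3", "CZ2", "CZ3", "CH2"),),
    "HIS": (("CG", "ND1", "CD2", "CE1", "NE2"),),
}


def _radii(structure: Structure) -> np.ndarray:
    out = np.empty(len(structure))
    for i, a in enumerate(structure.atoms):
        r = COVALENT_RADII.get(a.element.upper())
        if r is None:
            raise UnknownElementError(
                f"atom {a.serial} {a.name} in {a.residue_key}: "
                f"unknown element {a.element!r}"
            )
        out[i] = r
    return out


def _sorted_edge(u: int, v: int, bond_type: BondType, w: float, d: float) -> BondEdge:
    if u > v:
        u, v = v, u
    return BondEdge(u, v, bond_type, float(w), float(d))


def detect_covalent(structure: Structure, config: EnergyConfig | None = None) -> list[BondEdge]:
    """Detect covalent bonds by covalent-radii distance criterion.

    A pair is bonded when its distance is at most the sum of the two
    covalent radii plus a tolerance.  Bond order (for the energy lookup)
    comes from the chemical-component template of the residue where
    available; inter-residue links (peptide, phosphodiester, disulfide)
    are single bonds.  CONECT records are honoured as extra hints for
    hetero groups.
    """
    config = config or EnergyConfig()
    coords = structure.coords
    radii = _radii(structure)
    atoms = structure.atoms
    tree = cKDTree(coords)
    max_cut = 2 * radii.max() + config.covalent_tolerance
    pairs = tree.query_pairs(max_cut, output_type="ndarray")
    edges: dict[tuple[int, int], BondEdge] = {}
    for u, v in pairs:
        u, v = int(u), int(v)
        au, av = atoms[u], atoms[v]
        if au.element == "H" and av.element == "H":
            continue
        d = float(np.linalg.norm(coords[u] - coords[v]))
        if d > radii[u] + radii[v] + config.covalent_tolerance:
            continue
        order = 1
        if au.residue_key == av.residue_key:
            tmpl = _template_bonds(au.res_name)
            if tmpl is not None:
                order = tmpl.get(frozenset((au.name, av.name)), 1)
        w = bond_energy(au.element, av.element, order)
        e = _sorted_edge(u, v, BondType.COVALENT, w, d)
        edges[e.pair()] = e
    # CONECT hints: accept slightly longer hetero-group bonds
    if structure.conect_pairs:
        serial_to_idx = {a.serial: i for i, a in enumerate(atoms)}
        for s1, s2 in structure.conect_pairs:
            u = serial_to_idx.get(s1)
            v = serial_to_idx.get(s2)
            if u is None or v is None or u == v:
                continue
            if (min(u, v), max(u, v)) in edges:
                continue
            d = float(np.linalg.norm(coords[u] - coords[v]))
            lim = (radii[u] + radii[v] + config.covalent_tolerance)
            if d <= lim * config.conect_tolerance_factor:
                w = bond_energy(atoms[u].element, atoms[v].element, 1)
                e = _sorted_edge(u, v, BondType.COVALENT, w, d)
                edges[e.pair()] = e
    return [edges[k] for k in sorted(edges)]


def _adjacency_sets(n: int, edges: list[BondEdge]) -> list[set[int]]:
    adj: list[set[int]] = [set() for _ in range(n)]
    for e in edges:
        adj[e.atom_u].add(e.atom_v)
        adj[e.atom_v].add(e.atom_u)
    return adj


def _excluded(u: int, v: int, adj: list[set[int]]) -> bool:
    """True for covalently bonded (1-2) or angle (1-3) pairs."""
    return v in adj[u] or bool(adj[u] & adj[v])


def _mayo_12_10(R: float, cos2: float, config: EnergyConfig) -> float:
    x = config.hb_r0 / R
    e = config.hb_well_depth * abs(5.0 * x**12 - 6.0 * x**10) * cos2
    return max(e, 1e-6)


def detect_hydrogen_bonds(
    structure: Structure,
    config: EnergyConfig | None = None,
    covalent: list[BondEdge] | None = None,
) -> list[BondEdge]:
    """Detect hydrogen bonds between N/O (optionally S) donors and acceptors.

    With explicit hydrogens a donor-H...acceptor geometry criterion is
    used (H...A distance cutoff plus minimum D-H...A angle) and the
    12-10 potential is evaluated on the donor-acceptor distance with a
    cos^2 angular factor.  Without hydrogens the heavy-atom fallback
    applies a donor-acceptor distance cutoff, a table of donor/acceptor
    atoms per residue type and an outward-direction angle test at the
    donor, with the potential evaluated at ideal (linear) geometry.
    """
    config = config or EnergyConfig()
    covalent = covalent if covalent is not None else detect_covalent(structure, config)
    atoms = structure.atoms
    coords = structure.coords
    n = len(atoms)
    adj = _adjacency_sets(n, covalent)
    polar = {"N", "O"} | ({"S"} if config.hb_include_sulfur else set())
    angle_min = np.deg2rad(config.hb_angle_min_deg)

    # explicit-H route if any polar atom carries a hydrogen
    dh_pairs = [
        (d, h)
        for h in range(n)
        if atoms[h].element == "H"
        for d in adj[h]
        if atoms[d].element in polar
    ]
    edges: dict[tuple[int, int], BondEdge] = {}
    if dh_pairs:
        acceptors = [
            i for i in range(n)
            if atoms[i].element in polar
        ]
        acc_tree = cKDTree(coords[acceptors])
        for d_idx, h_idx in dh_pairs:
            near = acc_tree.query_ball_point(coords[h_idx], config.hb_ha_cutoff)
            for k in near:
                a_idx = acceptors[k]
                if a_idx == d_idx or _excluded(d_idx, a_idx, adj):
                    continue
                v1 = coords[d_idx] - coords[h_idx]
                v2 = coords[a_idx] - coords[h_idx]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                cosang = float(np.clip(v1 @ v2 / denom, -1, 1))
                theta = np.arccos(cosang)  # D-H...A angle
                if theta < angle_min:
                    continue
                R = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
                w = _mayo_12_10(R, cosang**2, config)
                e = _sorted_edge(d_idx, a_idx, BondType.HYDROGEN, w, R)
                prev = edges.get(e.pair())
                if prev is None or w > prev.weight:
                    edges[e.pair()] = e
        return [edges[k] for k in sorted(edges)]

    # heavy-atom fallback
    donors, accs = [], []
    for i, a in enumerate(atoms):
        if a.element not in polar:
            continue
        if a.res_name in _STANDARD_AA:
            if a.name == "N" and a.res_name != "PRO":
                donors.append(i)
            if a.name in ("O", "OXT"):
                accs.append(i)
            if a.name in _DONOR_ATOMS.get(a.res_name, ()):
                donors.append(i)
            if a.name in _ACCEPTOR_ATOMS.get(a.res_name, ()):
                accs.append(i)
        else:
            # hetero/nucleic: N, O with at most 2 heavy neighbours can both
            # donate and accept
            heavy_nb = sum(1 for j in adj[i] if atoms[j].element != "H")
            if heavy_nb <= 2:
                donors.append(i)
            accs.append(i)
    if not donors or not accs:
        return []
    acc_tree = cKDTree(coords[accs])
    for d_idx in donors:
        near = acc_tree.query_ball_point(coords[d_idx], config.hb_da_cutoff)
        for k in near:
            a_idx = accs[k]
            if a_idx == d_idx or _excluded(d_idx, a_idx, adj):
                continue
            ok = True
            for x in adj[d_idx]:
                v1 = coords[x] - coords[d_idx]
                v2 = coords[a_idx] - coords[d_idx]
                denom = np.linalg.norm(v1) * np.linalg.norm(v2)
                if denom == 0:
                    continue
                ang = np.arccos(float(np.clip(v1 @ v2 / denom, -1, 1)))
                if ang < angle_min:
                    ok = False
                    break
            if not ok:
                continue
            R = float(np.linalg.norm(coords[d_idx] - coords[a_idx]))
            w = _mayo_12_10(R, 1.0, config)
            e = _sorted_edge(d_idx, a_idx, BondType.HYDROGEN, w, R)
            prev = edges.get(e.pair())
            if prev is None or w > prev.weight:
                edges[e.pair()] = e
    return [edges[k] for k in sorted(edges)]


def _formal_charge(a, config: EnergyConfig) -> float:
    q = config.extra_charges.get((a.res_name, a.name))
    if q is not None:
        return float(q)
    q = CHARGED_ATOMS.get((a.res_name, a.name))
    if q is not None:
        return q
    if a.name == "OXT":
        return -1.0
    if a.name in _PHOSPHATE_O and a.res_name not in _STANDARD_AA:
        return -1.0
    return 0.0


def detect_hydrophobic(
    structure: Structure,
    config: EnergyConfig | None = None,
    covalent: list[BondEdge] | None = None,
) -> list[BondEdge]:
    """Detect hydrophobic contacts between apolar heavy atoms.

    Apolar atoms are carbons or sulfurs without covalent N/O neighbours
    and without formal charge in their group; contacts are inter-residue
    only, within the distance cutoff, weighted by a decaying exponential
    well.
    """
    config = config or EnergyConfig()
    covalent = covalent if covalent is not None else detect_covalent(structure, config)
    atoms = structure.atoms
    coords = structure.coords
    adj = _adjacency_sets(len(atoms), covalent)
    apolar = []
    for i, a in enumerate(atoms):
        if a.element not in ("C", "S"):
            continue
        if _formal_charge(a, config) != 0.0:
            continue
        if any(atoms[j].element in ("N", "O") or _formal_charge(atoms[j], config) != 0
               for j in adj[i]):
            continue
        apolar.append(i)
    if len(apolar) < 2:
        return []
    sub = cKDTree(coords[apolar])
    edges = []
    for ii, jj in sorted(sub.query_pairs(config.hydrophobic_cutoff)):
        u, v = apolar[ii], apolar[jj]
        if atoms[u].residue_key == atoms[v].residue_key:
            continue
        if _excluded(u, v, adj):
            continue
        d = float(np.linalg.norm(coords[u] - coords[v]))
        w = config.hydrophobic_eps * np.exp(
            -(d - config.hydrophobic_r0) / config.hydrophobic_sigma
        )
        edges.append(_sorted_edge(u, v, BondType.HYDROPHOBIC, w, d))
    return sorted(edges, key=lambda e: e.pair())


def detect_electrostatic_and_salt_bridges(
    structure: Structure,
    config: EnergyConfig | None = None,
    covalent: list[BondEdge] | None = None,
) -> list[BondEdge]:
    """Detect charged-group contacts with a screened Coulomb weight.

    Opposite-charge pairs within the salt-bridge cutoff become
    SALT_BRIDGE edges; pairs between that cutoff and the electrostatic
    cutoff become (weaker) ELECTROSTATIC edges.  The weight uses a
    distance-dependent dielectric eps_r(r) = slope * r, so
    |E| = k |q1 q2| / (slope * r^2).
    """
    config = config or EnergyConfig()
    covalent = covalent if covalent is not None else detect_covalent(structure, config)
    atoms = structure.atoms
    coords = structure.coords
    adj = _adjacency_sets(len(atoms), covalent)
    charges = np.array([_formal_charge(a, config) for a in atoms])
    charged = np.flatnonzero(charges)
    edges = []
    if len(charged) < 2:
        return []
    sub = cKDTree(coords[charged])
    for ii, jj in sorted(sub.query_pairs(config.elec_cutoff)):
        u, v = int(charged[ii]), int(charged[jj])
        if charges[u] * charges[v] >= 0:
            continue
        if atoms[u].residue_key == atoms[v].residue_key or _excluded(u, v, adj):
            continue
        d = float(np.linalg.norm(coords[u] - coords[v]))
        w = config.coulomb_k * abs(charges[u] * charges[v]) / (
            config.dielectric_slope * d * d
        )
        btype = BondType.SALT_BRIDGE if d <= config.salt_cutoff else BondType.ELECTROSTATIC
        edges.append(_sorted_edge(u, v, btype, w, d))
    return sorted(edges, key=lambda e: e.pair())


def _ring_tables(config: EnergyConfig):
    rings = dict(RING_ATOMS)
    if config.pi_include_protein_rings:
        rings.update(_PROTEIN_RING_ATOMS)
    return rings


def _plane_normal(pts: np.ndarray) -> np.ndarray:
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    return vt[2]


def detect_pi_pi(
    structure: Structure,
    config: EnergyConfig | None = None,
) -> list[BondEdge]:
    """Detect pi-pi stacking between aromatic rings (nucleobases by default).

    A ring pair within the centroid-distance cutoff and with near-parallel
    planes yields one constant-weight edge between the two atoms closest
    to their respective ring centroids; the edge length records the
    centroid-centroid distance.
    """
    config = config or EnergyConfig()
    tables = _ring_tables(config)
    atoms = structure.atoms
    coords = structure.coords
    by_res = structure.atoms_of_residue()
    rings = []  # (centroid, normal, representative atom index, residue)
    for key, idxs in by_res.items():
        for ring_names in tables.get(key.res_name, ()):
            name_to_idx = {atoms[i].name: i for i in idxs}
            if not all(nm in name_to_idx for nm in ring_names):
                continue
            ring_idx = [name_to_idx[nm] for nm in ring_names]
            pts = coords[ring_idx]
            centroid = pts.mean(axis=0)
            normal = _plane_normal(pts)
            rep = ring_idx[int(np.argmin(np.linalg.norm(pts - centroid, axis=1)))]
            rings.append((centroid, normal, rep, key))
    edges = []
    angle_max = np.deg2rad(config.pi_angle_max_deg)
    for i in range(len(rings)):
        for j in range(i + 1, len(rings)):
            c1, n1, r1, k1 = rings[i]
            c2, n2, r2, k2 = rings[j]
            if k1 == k2:
                continue
            d = float(np.linalg.norm(c1 - c2))
            if d > config.pi_cutoff:
                continue
            cosang = abs(float(np.clip(n1 @ n2, -1, 1)))
            if np.arccos(cosang) > angle_max:
                continue
            edges.append(_sorted_edge(r1, r2, BondType.PI_PI, config.pi_weight, d))
    return sorted(edges, key=lambda e: e.pair())


class AtomisticGraph:
    """Weighted undirected graph over the atoms of a structure.

    The itemized edge list keeps one entry per (pair, bond type); for
    matrix operations parallel edges are collapsed to a single edge with
    summed weight.
    """

    def __init__(
        self,
        n_atoms: int,
        edges: list[BondEdge],
        coords: np.ndarray,
        residue_of_atom: list[ResidueKey],
        structure: Structure | None = None,
    ):
        if not edges:
            raise EmptyGraphError("graph has no edges")
        for e in edges:
            if e.atom_u == e.atom_v:
                raise ValueError("self-loop edge")
            if e.weight <= 0:
                raise ValueError("edge weight must be positive")
        self.n_atoms = int(n_atoms)
        self.edges = list(edges)
        self.coords = np.asarray(coords, dtype=float)
        self.residue_of_atom = list(residue_of_atom)
        self.structure = structure
        # collapsed representation
        acc: dict[tuple[int, int], float] = {}
        types: dict[tuple[int, int], list[str]] = {}
        for e in self.edges:
            p = e.pair()
            acc[p] = acc.get(p, 0.0) + e.weight
            types.setdefault(p, []).append(e.bond_type.value)
        pairs = sorted(acc)
        self.pair_u = np.array([p[0] for p in pairs], dtype=int)
        self.pair_v = np.array([p[1] for p in pairs], dtype=int)
        self.pair_weight = np.array([acc[p] for p in pairs])
        self.pair_types = ["+".join(sorted(set(types[p]))) for p in pairs]
        self._pair_index = {p: i for i, p in enumerate(pairs)}

    @property
    def n_bonds(self) -> int:
        """Number of collapsed bonds (matrix-operation edges)."""
        return len(self.pair_weight)

    @property
    def weighted_degree(self) -> np.ndarray:
        deg = np.zeros(self.n_atoms)
        np.add.at(deg, self.pair_u, self.pair_weight)
        np.add.at(deg, self.pair_v, self.pair_weight)
        return deg

    def bond_index(self, u: int, v: int) -> int:
        """Collapsed-bond index of the unordered atom pair (u, v)."""
        p = (u, v) if u < v else (v, u)
        return self._pair_index[p]

    def bond_midpoints(self) -> np.ndarray:
        return 0.5 * (self.coords[self.pair_u] + self.coords[self.pair_v])

    def adjacency(self):
        from scipy import sparse

        n = self.n_atoms
        data = np.concatenate([self.pair_weight, self.pair_weight])
        rows = np.concatenate([self.pair_u, self.pair_v])
        cols = np.concatenate([self.pair_v, self.pair_u])
        return sparse.csr_matrix((data, (rows, cols)), shape=(n, n))

    def edge_table(self) -> pd.DataFrame:
        """Itemized edge list as a DataFrame (one row per typed edge)."""
        rows = []
        for e in self.edges:
            rows.append(
                {
                    "atom_u": e.atom_u,
                    "atom_v": e.atom_v,
                    "residue_u": str(self.residue_of_atom[e.atom_u]),
                    "residue_v": str(self.residue_of_atom[e.atom_v]),
                    "bond_type": e.bond_type.value,
                    "length_A": e.length,
                    "weight_kJ_mol": e.weight,
                }
            )
        return pd.DataFrame(rows)

    @classmethod
    def from_edges(
        cls,
        n_atoms: int,
        weighted_edges: list[tuple[int, int, float]],
        coords: np.ndarray | None = None,
        residue_of_atom: list[ResidueKey] | None = None,
    ) -> "AtomisticGraph":
        """Build a bare graph from (u, v, weight) triples (toy graphs)."""
        if coords is None:
            coords = np.zeros((n_atoms, 3))
            coords[:, 0] = np.arange(n_atoms)
        if residue_of_atom is None:
            residue_of_atom = [ResidueKey("A", i + 1, "", "GLY") for i in range(n_atoms)]
        coords = np.asarray(coords, dtype=float)
        edges = [
            BondEdge(
                min(u, v), max(u, v), BondType.COVALENT, float(w),
                float(np.linalg.norm(coords[u] - coords[v])),
            )
            for u, v, w in weighted_edges
        ]
        return cls(n_atoms, edges, coords, residue_of_atom)


def build_graph(structure: Structure, config: EnergyConfig | None = None) -> AtomisticGraph:
    """Run all enabled interaction detectors and assemble the graph."""
    if len(structure) == 0:
        raise EmptySelectionError("empty structure")
    config = config or EnergyConfig()
    covalent = detect_covalent(structure, config)
    edges = list(covalent)
    if config.enable_hydrogen:
        edges += detect_hydrogen_bonds(structure, config, covalent)
    if config.enable_hydrophobic:
        edges += detect_hydrophobic(structure, config, covalent)
    if config.enable_electrostatic:
        edges += detect_electrostatic_and_salt_bridges(structure, config, covalent)
    if config.enable_pi_pi:
        edges += detect_pi_pi(structure, config)
    return AtomisticGraph(
        n_atoms=len(structure),
        edges=edges,
        coords=structure.coords,
        residue_of_atom=structure.residue_of_atom(),
        structure=structure,
    )
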