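"""Reading, filtering and writing of PDB-format structures.

This module turns a PDB v3.3 file into a flat, filtered list of atom
records ready for atomistic graph construction.  Parsing is delegated to
gemmi; on top of that we apply the cleaning steps expected by the
signalling analysis: model selection, chain selection, water stripping,
alternate-location resolution and (optionally) expansion of the
biological assembly from REMARK 350 transforms.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import gemmi
import numpy as np

__all__ = [
    "AtomRecord",
    "ResidueKey",
    "Structure",
    "Assembly",
    "ComponentReport",
    "PDBFormatError",
    "ModelNotFoundError",
    "EmptySelectionError",
    "parse_pdb",
    "read_pdb",
    "fetch_pdb",
    "build_assembly",
    "connectivity_report",
    "write_pdb_with_bfactor",
    "format_pdb",
]

WATER_NAMES = frozenset({"HOH", "WAT", "DOD"})


class PDBFormatError(ValueError):
    """Raised for malformed PDB input."""


class ModelNotFoundError(KeyError):
    """Requested MODEL number absent from the file."""


class EmptySelectionError(ValueError):
    """No atoms survive the requested filters."""


class ResidueKey(NamedTuple):
    """Unique residue identifier within one structure model."""

    chain_id: str
    res_seq: int
    i_code: str
    res_name: str

    def __str__(self) -> str:  # e.g. "A:GLY:1"
        icode = self.i_code.strip()
        return f"{self.chain_id}:{self.res_name}:{self.res_seq}{icode}"


@dataclass(frozen=True)
class AtomRecord:
    serial: int
    name: str
    element: str
    alt_loc: str
    res_name: str
    chain_id: str
    res_seq: int
    i_code: str
    xyz: tuple[float, float, float]
    occupancy: float = 1.0
    is_hetero: bool = False

    @property
    def residue_key(self) -> ResidueKey:
        return ResidueKey(self.chain_id, self.res_seq, self.i_code, self.res_name)


@dataclass(frozen=True)
class Assembly:
    """One REMARK 350 biological assembly: chains plus rigid transforms."""

    name: str
    chain_ids: tuple[str, ...]
    rotations: tuple[np.ndarray, ...]  # each 3x3
    translations: tuple[np.ndarray, ...]  # each length 3


@dataclass
class Structure:
    """A single-model, filtered list of atoms from one PDB entry."""

    atoms: list[AtomRecord]
    model_id: int = 1
    source_id: str = "structure"
    assembly_applied: str | None = None
    assemblies: dict[str, Assembly] = field(default_factory=dict)
    conect_pairs: list[tuple[int, int]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.atoms)

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.xyz for a in self.atoms], dtype=float)

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]

    def residue_keys(self) -> list[ResidueKey]:
        """Ordered unique residues, in file order."""
        seen: dict[ResidueKey, None] = {}
        for a in self.atoms:
            seen.setdefault(a.residue_key, None)
        return list(seen)

    def residue_of_atom(self) -> list[ResidueKey]:
        return [a.residue_key for a in self.atoms]

    def atoms_of_residue(self) -> dict[ResidueKey, list[int]]:
        out: dict[ResidueKey, list[int]] = {}
        for i, a in enumerate(self.atoms):
            out.setdefault(a.residue_key, []).append(i)
        return out

    def chain_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for a in self.atoms:
            seen.setdefault(a.chain_id, None)
        return list(seen)


def _validate_fixed_width(text: str) -> None:
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line[:6].strip() in ("ATOM", "HETATM"):
            if len(line) < 54:
                raise PDBFormatError(
                    f"line {lineno}: ATOM/HETATM record shorter than coordinate fields"
                )
            try:
                float(line[30:38])
                float(line[38:46])
                float(line[46:54])
            except ValueError as exc:
                raise PDBFormatError(
                    f"line {lineno}: malformed coordinate field in {line[:6].strip()} record"
                ) from exc


def _extract_assemblies(st: gemmi.Structure) -> dict[str, Assembly]:
    out: dict[str, Assembly] = {}
    for asm in st.assemblies:
        chains: list[str] = []
        rots: list[np.ndarray] = []
        trans: list[np.ndarray] = []
        for gen in asm.generators:
            for ch in gen.chains:
                if ch not in chains:
                    chains.append(ch)
            for op in gen.operators:
                tr = op.transform
                rots.append(np.array(tr.mat.tolist(), dtype=float))
                trans.append(np.array(tr.vec.tolist(), dtype=float))
        out[asm.name] = Assembly(asm.name, tuple(chains), tuple(rots), tuple(trans))
    return out


def _resolve_altlocs(atoms: list[AtomRecord]) -> list[AtomRecord]:
    # Among duplicate (chain, seq, icode, name) records keep the highest
    # occupancy; ties go to the first in file.  Blank-altloc atoms are
    # unique and pass through unchanged.
    best: dict[tuple, int] = {}
    for i, a in enumerate(atoms):
        key = (a.chain_id, a.res_seq, a.i_code, a.res_name, a.name)
        j = best.get(key)
        if j is None or a.occupancy > atoms[j].occupancy:
            best[key] = i
    keep = sorted(best.values())
    return [atoms[i] for i in keep]


def parse_pdb(
    text: str,
    model: int = 1,
    chains: Iterable[str] | None = None,
    strip_waters: bool = True,
    strip_anisou: bool = True,
    keep_hetero: bool = True,
    source_id: str = "structure",
) -> Structure:
    """Parse PDB text into a filtered single-model :class:`Structure`.

    Parameters
    ----------
    text:
        PDB v3.3 fixed-width file content.
    model:
        MODEL number to keep (NMR ensembles contain several).
    chains:
        Chain identifiers to keep, or ``None`` for all.
    strip_waters:
        Remove HOH/WAT/DOD residues.
    strip_anisou:
        ANISOU records are never used by the graph methods; the flag is
        kept for interface symmetry (they are ignored either way).
    keep_hetero:
        Keep HETATM records (ligands, ions, cofactors).
    """
    _validate_fixed_width(text)
    try:
        st = gemmi.read_pdb_string(text)
    except (RuntimeError, ValueError) as exc:
        raise PDBFormatError(f"gemmi could not parse PDB text: {exc}") from exc
    if len(st) == 0:
        raise PDBFormatError("no ATOM or HETATM records found")

    available = [m.num for m in st]
    sel = None
    for m in st:
        if m.num == model:
            sel = m
            break
    if sel is None:
        raise ModelNotFoundError(
            f"model {model} not found; available models: {available}"
        )

    chain_filter = set(chains) if chains is not None else None
    atoms: list[AtomRecord] = []
    for chain in sel:
        if chain_filter is not None and chain.name not in chain_filter:
            continue
        for res in chain:
            if strip_waters and res.name.strip() in WATER_NAMES:
                continue
            is_het = res.het_flag == "H"
            if is_het and not keep_hetero:
                continue
            for at in res:
                el = "H" if at.element.is_hydrogen else at.element.name
                altloc = at.altloc if at.altloc != "\x00" else ""
                atoms.append(
                    AtomRecord(
                        serial=at.serial,
                        name=at.name,
                        element=el,
                        alt_loc=altloc,
                        res_name=res.name,
                        chain_id=chain.name,
                        res_seq=res.seqid.num,
                        i_code=res.seqid.icode.strip(),
                        xyz=(at.pos.x, at.pos.y, at.pos.z),
                        occupancy=at.occ,
                        is_hetero=is_het,
                    )
                )
    atoms = _resolve_altlocs(atoms)
    if not atoms:
        raise EmptySelectionError("no atoms after filtering")

    conect = [
        (s1, s2)
        for s1, partners in sorted(st.conect_map.items())
        for s2 in partners
        if s1 < s2
    ]
    return Structure(
        atoms=atoms,
        model_id=model,
        source_id=source_id,
        assemblies=_extract_assemblies(st),
        conect_pairs=conect,
    )


def read_pdb(path: str | Path, **kwargs) -> Structure:
    """Read a PDB file from disk (thin wrapper over :func:`parse_pdb`)."""
    p = Path(path)
    kwargs.setdefault("source_id", p.stem)
    return parse_pdb(p.read_text(), **kwargs)


def fetch_pdb(pdb_id: str, **kwargs) -> Structure:
    """Download an entry from the PDB by 4-letter code (needs network)."""
    import urllib.request

    if len(pdb_id) != 4:
        raise ValueError("PDB identifiers have exactly 4 characters")
    url = f"https://files.rcsb.org/download/{pdb_id.upper()}.pdb"
    with urllib.request.urlopen(url) as fh:  # pragma: no cover - network
        text = fh.read().decode()
    kwargs.setdefault("source_id", pdb_id.upper())
    return parse_pdb(text, **kwargs)


_CHAIN_LABELS = string.ascii_uppercase + string.ascii_lowercase + string.digits


def _fresh_chain_label(used: set[str]) -> str:
    for c in _CHAIN_LABELS:
        if c not in used:
            used.add(c)
            return c
    raise ValueError("ran out of single-character chain labels")


def build_assembly(structure: Structure, assembly_id: str) -> Structure:
    """Expand a biological assembly by applying its BIOMT transforms.

    Each rotation+translation is applied to the chains listed in the
    REMARK 350 block.  The identity transform keeps the original chain
    labels; every additional copy receives a fresh label.
    """
    if assembly_id not in structure.assemblies:
        raise KeyError(
            f"assembly {assembly_id!r} not found; "
            f"available: {sorted(structure.assemblies)}"
        )
    asm = structure.assemblies[assembly_id]
    for R in asm.rotations:
        det = float(np.linalg.det(R))
        if abs(det - 1.0) > 1e-3:
            raise ValueError(
                f"assembly {assembly_id!r}: BIOMT rotation determinant {det:.6f} "
                "outside 1 ± 1e-3"
            )

    base = [a for a in structure.atoms if a.chain_id in asm.chain_ids]
    if not base:
        raise EmptySelectionError(
            f"assembly {assembly_id!r} lists no chains present in the structure"
        )
    used_labels = set(structure.chain_ids())
    new_atoms: list[AtomRecord] = []
    new_conect: list[tuple[int, int]] = []
    serial = 0
    identity_used = False
    for R, t in zip(asm.rotations, asm.translations):
        is_identity = np.allclose(R, np.eye(3), atol=1e-6) and np.allclose(
            t, 0.0, atol=1e-6
        )
        chain_map: dict[str, str] = {}
        if is_identity and not identity_used:
            identity_used = True
            chain_map = {c: c for c in asm.chain_ids}
        else:
            for c in asm.chain_ids:
                chain_map[c] = _fresh_chain_label(used_labels)
        serial_map: dict[int, int] = {}
        for a in base:
            serial += 1
            serial_map[a.serial] = serial
            xyz = R @ np.asarray(a.xyz) + t
            new_atoms.append(
                replace(
                    a,
                    serial=serial,
                    chain_id=chain_map[a.chain_id],
                    xyz=(float(xyz[0]), float(xyz[1]), float(xyz[2])),
                )
            )
        for s1, s2 in structure.conect_pairs:
            if s1 in serial_map and s2 in serial_map:
                new_conect.append((serial_map[s1], serial_map[s2]))
    return Structure(
        atoms=new_atoms,
        model_id=structure.model_id,
        source_id=structure.source_id,
        assembly_applied=assembly_id,
        assemblies=structure.assemblies,
        conect_pairs=new_conect,
    )


@dataclass(frozen=True)
class ComponentReport:
    """Connected components of an atomistic graph, largest first."""

    sizes: tuple[int, ...]
    member_residues: tuple[frozenset, ...]
    labels: np.ndarray  # per-atom component rank (0 = largest)

    @property
    def is_connected(self) -> bool:
        return len(self.sizes) == 1


def connectivity_report(graph) -> ComponentReport:
    """Summarise connected components of an :class:`AtomisticGraph`."""
    from scipy.sparse.csgraph import connected_components

    n_comp, labels = connected_components(graph.adjacency(), directed=False)
    sizes = np.bincount(labels, minlength=n_comp)
    order = np.argsort(-sizes, kind="stable")
    rank = np.empty_like(order)
    rank[order] = np.arange(n_comp)
    residues = graph.residue_of_atom
    members = []
    for c in order:
        members.append(frozenset(residues[i] for i in np.flatnonzero(labels == c)))
    return ComponentReport(
        sizes=tuple(int(sizes[c]) for c in order),
        member_residues=tuple(members),
        labels=rank[labels],
    )


def _format_atom_line(a: AtomRecord, bfactor: float) -> str:
    record = "HETATM" if a.is_hetero else "ATOM"
    name = a.name
    if len(a.element) == 1 and len(name) < 4:
        name = f" {name:<3}"
    else:
        name = f"{name:<4}"
    b = min(max(bfactor, -99.99), 999.99)
    x, y, z = a.xyz
    return (
        f"{record:<6}{a.serial:>5} {name}{a.alt_loc or ' ':1}{a.res_name:>3} "
        f"{a.chain_id:1}{a.res_seq:>4}{a.i_code or ' ':1}   "
        f"{x:8.3f}{y:8.3f}{z:8.3f}{a.occupancy:6.2f}{b:6.2f}          "
        f"{a.element:>2}"
    )


def format_pdb(
    structure: Structure, bfactors: Sequence[float] | None = None
) -> str:
    """Render a Structure as PDB text, optionally with per-atom B-factors."""
    lines = []
    vals = bfactors if bfactors is not None else [0.0] * len(structure)
    prev_chain = None
    for a, b in zip(structure.atoms, vals):
        if prev_chain is not None and a.chain_id != prev_chain:
            lines.append("TER")
        lines.append(_format_atom_line(a, float(b)))
        prev_chain = a.chain_id
    for s1, s2 in structure.conect_pairs:
        lines.append(f"CONECT{s1:>5}{s2:>5}")
        lines.append(f"CONECT{s2:>5}{s1:>5}")
    lines.append("END")
    return "\n".join(lines) + "\n"


def write_pdb_with_bfactor(
    structure: Structure,
    per_atom_values: Mapping[int, float] | Sequence[float],
    path: str | Path,
) -> Path:
    """Write the structure with per-atom values in the B-factor column.

    ``per_atom_values`` maps atom index -> value (missing atoms get 0.00)
    or is a dense sequence over all atoms.  Values are clipped to the
    PDB column range [0, 999.99] on output.
    """
    n = len(structure)
    if isinstance(per_atom_values, Mapping):
        vals = np.zeros(n)
        for i, v in per_atom_values.items():
            vals[i] = v
    else:
        vals = np.asarray(per_atom_values, dtype=float)
        if vals.shape != (n,):
            raise ValueError("per_atom_values length must equal atom count")
    if not np.all(np.isfinite(vals)):
        raise ValueError("per-atom values must be finite")
    vals = np.clip(vals, 0.0, 999.99)
    out = Path(path)
    out.write_text(format_pdb(structure, vals))
    return out
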