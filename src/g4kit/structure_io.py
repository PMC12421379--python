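"""Read, write and transform atomic coordinate models.

PDB and mmCIF parsing is delegated to gemmi; this module converts gemmi's
hierarchy into a small, explicit in-memory model (:class:`StructureModel`)
that the rest of the package annotates.  Coordinates are kept in Angstrom,
right-handed Cartesian, exactly as deposited.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import gemmi
import numpy as np

__all__ = [
    "Atom",
    "Residue",
    "ResidueKind",
    "StructureModel",
    "StructureFormatError",
    "EmptyStructureError",
    "read_structure",
    "write_structure",
    "apply_symmetry",
]

GUANINE_NAMES = {"DG", "G", "GUA", "GTP", "GMP"}
CYTOSINE_NAMES = {"DC", "C", "CYT"}
BASE_NAMES = GUANINE_NAMES | CYTOSINE_NAMES | {"DA", "A", "ADE", "DT", "T", "THY", "DU", "U", "URA"}
ION_NAMES = {"K", "NA", "MG", "CA", "ZN", "SR", "TL", "NH4", "RB", "CS", "LI", "CL"}
WATER_NAMES = {"HOH", "WAT", "H2O", "DOD"}

#: heavy atoms of a complete guanine base ring system
GUANINE_RING_ATOMS = ("N9", "C8", "N7", "C5", "C6", "O6", "N1", "C2", "N2", "N3", "C4")
#: heavy atoms of a complete cytosine base ring
CYTOSINE_RING_ATOMS = ("N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6")


class StructureFormatError(ValueError):
    """Raised when a coordinate file cannot be parsed."""


class EmptyStructureError(ValueError):
    """Raised when a parsed file contains no atoms."""


class ResidueKind(enum.Enum):
    GUANINE = "guanine"
    CYTOSINE = "cytosine"
    OTHER_BASE = "other_base"
    ION = "ion"
    WATER = "water"
    OTHER = "other"


def residue_kind(res_name: str) -> ResidueKind:
    """Deterministic residue classification from the monomer code."""
    name = res_name.strip().upper()
    if name in GUANINE_NAMES:
        return ResidueKind.GUANINE
    if name in CYTOSINE_NAMES:
        return ResidueKind.CYTOSINE
    if name in BASE_NAMES:
        return ResidueKind.OTHER_BASE
    if name in ION_NAMES:
        return ResidueKind.ION
    if name in WATER_NAMES:
        return ResidueKind.WATER
    return ResidueKind.OTHER


@dataclass
class Atom:
    name: str
    element: str
    pos: np.ndarray  # shape (3,), Angstrom
    occupancy: float = 1.0
    altloc: str = ""

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        if self.pos.shape != (3,) or not np.all(np.isfinite(self.pos)):
            raise ValueError(f"atom {self.name}: position must be a finite 3-vector")
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not 0.0 <= self.occupancy <= 1.0:
            raise ValueError(f"atom {self.name}: occupancy {self.occupancy} outside [0, 1]")


@dataclass
class Residue:
    chain_id: str
    seq_num: int
    res_name: str
    ins_code: str = ""
    atoms: list[Atom] = field(default_factory=list)

    @property
    def kind(self) -> ResidueKind:
        return residue_kind(self.res_name)

    @property
    def label(self) -> str:
        """Short residue label, e.g. ``G1`` or ``C24`` (one-letter base + number)."""
        one = self.res_name.strip().upper().lstrip("DR")[:1] or self.res_name[:1]
        return f"{one}{self.seq_num}"

    def atom(self, name: str) -> Atom | None:
        for a in self.atoms:
            if a.name == name:
                return a
        # the sugar ring oxygen appears as either O4' or O1'
        if name in ("O4'", "O1'"):
            alt = "O1'" if name == "O4'" else "O4'"
            for a in self.atoms:
                if a.name == alt:
                    return a
        return None

    def coord(self, name: str) -> np.ndarray | None:
        a = self.atom(name)
        return None if a is None else a.pos

    def has_atoms(self, names: Iterable[str]) -> bool:
        return all(self.atom(n) is not None for n in names)

    @property
    def key(self) -> tuple[str, int, str]:
        return (self.chain_id, self.seq_num, self.ins_code)


@dataclass
class StructureModel:
    chains: dict[str, list[Residue]] = field(default_factory=dict)
    title: str = ""
    source_format: str = ""

    def add_residue(self, res: Residue) -> None:
        self.chains.setdefault(res.chain_id, []).append(res)

    def residues(self) -> Iterator[Residue]:
        for chain in self.chains.values():
            yield from chain

    def guanines(self) -> list[Residue]:
        return [r for r in self.residues() if r.kind is ResidueKind.GUANINE]

    def cytosines(self) -> list[Residue]:
        return [r for r in self.residues() if r.kind is ResidueKind.CYTOSINE]

    def ions(self) -> list[Residue]:
        return [r for r in self.residues() if r.kind is ResidueKind.ION]

    def waters(self) -> list[Residue]:
        return [r for r in self.residues() if r.kind is ResidueKind.WATER]

    def n_atoms(self) -> int:
        return sum(len(r.atoms) for r in self.residues())

    def sort(self) -> None:
        for chain in self.chains.values():
            chain.sort(key=lambda r: (r.seq_num, r.ins_code))

    def validate(self) -> None:
        seen: set[tuple] = set()
        for chain_id, chain in self.chains.items():
            keys = [(r.seq_num, r.ins_code) for r in chain]
            if keys != sorted(keys):
                raise ValueError(f"chain {chain_id}: residues not ordered by (seq_num, ins_code)")
            for res in chain:
                for a in res.atoms:
                    k = (chain_id, res.seq_num, res.ins_code, a.name, a.altloc)
                    if k in seen:
                        raise ValueError(f"duplicate atom {k}")
                    seen.add(k)


def _detect_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".cif", ".mmcif"):
        return "mmcif"
    if suffix in (".pdb", ".ent"):
        return "pdb"
    # fall back to content sniffing
    head = path.read_text(errors="replace")[:4096]
    if head.lstrip().startswith("data_") or "_atom_site." in head:
        return "mmcif"
    return "pdb"


def read_structure(path: str | Path, altloc_policy: str = "highest_occupancy") -> StructureModel:
    """Parse a PDB or mmCIF file into a :class:`StructureModel`.

    All ATOM/HETATM records of the first model are retained; waters and ions
    are flagged through :attr:`Residue.kind`.  Alternate locations are
    resolved per ``altloc_policy``:

    - ``"highest_occupancy"`` (default): keep the highest-occupancy altloc of
      each atom, ties broken toward altloc ``'A'`` (then alphabetically);
    - ``"all"``: keep every altloc.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _detect_format(path)
    try:
        if fmt == "mmcif":
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Mmcif)
        else:
            st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError) as exc:
        raise StructureFormatError(f"{path}: cannot parse as {fmt}: {exc}") from exc

    model = StructureModel(title=st.name, source_format=fmt)
    if len(st) == 0:
        raise EmptyStructureError(f"{path}: no models in file")
    first = st[0]
    for chain in first:
        for g_res in chain:
            res = Residue(
                chain_id=chain.name,
                seq_num=g_res.seqid.num,
                res_name=g_res.name,
                ins_code=(g_res.seqid.icode or "").strip(),
            )
            chosen: dict[str, Atom] = {}
            for g_atom in g_res:
                atom = Atom(
                    name=g_atom.name,
                    element=g_atom.element.name,
                    pos=np.array([g_atom.pos.x, g_atom.pos.y, g_atom.pos.z]),
                    occupancy=min(max(g_atom.occ, 0.0), 1.0),
                    altloc=(g_atom.altloc or "").strip(),
                )
                if altloc_policy == "all":
                    res.atoms.append(atom)
                    continue
                prev = chosen.get(atom.name)
                if prev is None or _altloc_better(atom, prev):
                    chosen[atom.name] = atom
            if altloc_policy != "all":
                res.atoms.extend(chosen.values())
            if res.atoms:
                model.add_residue(res)
    if model.n_atoms() == 0:
        raise EmptyStructureError(f"{path}: file parsed but contains no atoms")
    model.sort()
    return model


def _altloc_better(cand: Atom, prev: Atom) -> bool:
    if cand.occupancy != prev.occupancy:
        return cand.occupancy > prev.occupancy
    # tie: prefer blank, then 'A', then alphabetical
    order = lambda al: (al != "", al != "A", al)
    return order(cand.altloc) < order(prev.altloc)


def _to_gemmi(model: StructureModel) -> gemmi.Structure:
    st = gemmi.Structure()
    st.name = model.title or "g4kit"
    gm = gemmi.Model("1")
    for chain_id, residues in model.chains.items():
        gc = gemmi.Chain(chain_id)
        for res in residues:
            gr = gemmi.Residue()
            gr.name = res.res_name
            gr.seqid = gemmi.SeqId(res.seq_num, res.ins_code or " ")
            gr.het_flag = "H" if res.kind in (ResidueKind.ION, ResidueKind.WATER) else "A"
            for a in res.atoms:
                ga = gemmi.Atom()
                ga.name = a.name
                ga.element = gemmi.Element(a.element)
                ga.pos = gemmi.Position(*a.pos)
                ga.occ = a.occupancy
                ga.altloc = a.altloc or "\0"
                gr.add_atom(ga)
            gc.add_residue(gr)
        gm.add_chain(gc)
    st.add_model(gm)
    st.setup_entities()
    return st


def write_structure(model: StructureModel, path: str | Path, format: str | None = None) -> None:
    """Write ``model`` to PDB or mmCIF (inferred from the extension by default).

    The emitted file re-parses to an equal model with coordinates preserved
    to three decimals.  Ion residues serialize as HETATM records.
    """
    if model.n_atoms() == 0 or not model.chains or any(
        len(ch) == 0 for ch in model.chains.values()
    ):
        raise EmptyStructureError("refusing to write an empty structure/chain")
    path = Path(path)
    fmt = format or ("mmcif" if path.suffix.lower() in (".cif", ".mmcif") else "pdb")
    st = _to_gemmi(model)
    if fmt == "mmcif":
        st.make_mmcif_document().write_file(str(path))
    elif fmt == "pdb":
        st.write_pdb(str(path))
    else:
        raise ValueError(f"unknown format {fmt!r}")


def apply_symmetry(
    model: StructureModel,
    rotation: np.ndarray,
    translation: np.ndarray,
    chain_suffix: str = "2",
) -> StructureModel:
    """Return a transformed copy of ``model`` with chain ids suffixed.

    Used to expand a symmetry mate (e.g. the crystallographic two-fold that
    generates the 5'-5' stacked dimer from a single-strand asymmetric unit).
    The rotation part must be a proper orthonormal matrix.
    """
    R = np.asarray(rotation, dtype=float)
    t = np.asarray(translation, dtype=float).reshape(3)
    if R.shape != (3, 3):
        raise ValueError("rotation must be 3x3")
    if not np.allclose(R @ R.T, np.eye(3), atol=1e-8) or not np.isclose(
        np.linalg.det(R), 1.0, atol=1e-8
    ):
        raise ValueError("rotation part must be a proper orthonormal matrix")
    out = StructureModel(title=model.title, source_format=model.source_format)
    for chain_id, residues in model.chains.items():
        for res in residues:
            new = Residue(
                chain_id=chain_id + chain_suffix,
                seq_num=res.seq_num,
                res_name=res.res_name,
                ins_code=res.ins_code,
            )
            for a in res.atoms:
                new.atoms.append(
                    Atom(a.name, a.element, R @ a.pos + t, a.occupancy, a.altloc)
                )
            out.add_residue(new)
    return out


def merge_models(*models: StructureModel) -> StructureModel:
    """Concatenate models into one (chain ids must not collide)."""
    out = StructureModel(title=models[0].title if models else "")
    for m in models:
        for chain_id, residues in m.chains.items():
            if chain_id in out.chains:
                raise ValueError(f"chain id collision: {chain_id}")
            out.chains[chain_id] = [r for r in residues]
    return out
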