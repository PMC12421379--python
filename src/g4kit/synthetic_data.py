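"""Idealized G-quadruplex coordinate models and synthetic melting curves.

The builder emulates the geometry the annotation pipeline assumes: stacked
G-tetrad layers (~3.3 A rise) with cyclic Hoogsteen hydrogen-bond geometry,
four strand columns at 90-degree spacing, channel cations at layer-interval
midpoints, phosphate pseudo-backbones at groove-defining radii, schematic
CC loops with correct attachment faces, and optional 5'-5' stacked dimers
with a chosen stacking register.  Base geometry comes from the ideal DG/DC
heavy-atom templates of the chemical component dictionary bundled with
biotite; the in-plane placement of the guanine template is solved once per
Hoogsteen gap by least squares under exact four-fold symmetry.

The builder optimizes detector-relevant geometry (H-bond gaps, planarity,
stacking, P radii), not full stereochemical realism: sugars are reduced to
C1'/O4' anchors that realize the requested glycosidic angle, and loops are
schematic arcs.

``noise_sigma`` is the RMS positional displacement per atom in Angstrom
(isotropic Gaussian with per-component standard deviation sigma/sqrt(3)),
matching how overall coordinate error of a crystallographic model is
usually quoted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.optimize import least_squares

import biotite.structure.info as _ccd_info

from .melting import MeltingCurve, boltzmann, double_sigmoid
from .structure_io import (
    Atom,
    GUANINE_RING_ATOMS,
    CYTOSINE_RING_ATOMS,
    Residue,
    StructureModel,
    apply_symmetry,
    merge_models,
)

__all__ = [
    "G4BuildSpec",
    "MeltSimSpec",
    "build_g4",
    "simulate_melting",
    "backbone_from_torsions",
    "build_cc_quadruple",
    "place_flat_cytosine",
    "PARALLEL_P_RADIUS",
    "antiparallel_p_geometry",
]

RISE_DEFAULT = 3.3
TWIST_DEFAULT = 30.0
HBOND_GAP_DEFAULT = 2.9
CHI_ANTI = -120.0
CHI_SYN = 60.0

#: P radius giving four medium grooves of ~16 A (P-P = 2 R sin 45)
PARALLEL_P_RADIUS = 16.0 / (2.0 * math.sin(math.radians(45.0)))


def antiparallel_p_geometry(wide: float = 21.6, narrow: float = 8.7):
    """Common P radius and alternating azimuthal offset (degrees) that place
    adjacent P-P distances at ``wide`` / ``narrow`` around the core."""
    ratio = wide / narrow
    a = math.degrees(math.atan((ratio - 1.0) / (ratio + 1.0)))
    radius = wide / (2.0 * math.sin(math.radians(45.0 + a)))
    return radius, a


def _rot2(deg: float) -> np.ndarray:
    t = math.radians(deg)
    return np.array([[math.cos(t), -math.sin(t)], [math.sin(t), math.cos(t)]])


def _base_template_2d(res_name: str, atom_names) -> dict[str, np.ndarray]:
    """Planarized 2D coordinates of the base heavy atoms from the CCD ideal."""
    res = _ccd_info.residue(res_name)
    pts = []
    for n in atom_names:
        sel = res.coord[res.atom_name == n]
        if len(sel) == 0:
            raise ValueError(f"{res_name}: template lacks atom {n}")
        pts.append(sel[0])
    pts = np.asarray(pts, dtype=float)
    c = pts.mean(axis=0)
    _, _, vt = np.linalg.svd(pts - c)
    flat = (pts - c) @ vt[:2].T
    return {n: flat[i] for i, n in enumerate(atom_names)}


@lru_cache(maxsize=None)
def _tetrad_placement(hbond_gap: float) -> tuple[tuple[str, float, float], ...]:
    """In-plane coordinates of guanine 0 of an ideal four-fold tetrad.

    Solves for the rigid in-plane placement (tx, ty, theta) of the guanine
    template such that, under exact 90-degree rotational symmetry, the
    cyclic Hoogsteen contacts N1->O6 and N2->N7 equal ``hbond_gap``; weak
    regularizers keep the O6 ring radius (cation cage) and base centroid
    radius at values typical of experimental tetrads.  The solution is
    rotated so the ring centroid of guanine 0 sits at azimuth 0.
    """
    tmpl = _base_template_2d("DG", GUANINE_RING_ATOMS)
    r90 = _rot2(90.0)

    def placed(params):
        tx, ty, th = params
        rot = _rot2(math.degrees(th))
        return {n: rot @ tmpl[n] + np.array([tx, ty]) for n in GUANINE_RING_ATOMS}

    def resid(params):
        g0 = placed(params)
        g1 = {n: r90 @ g0[n] for n in GUANINE_RING_ATOMS}
        cen = np.mean([g0[n] for n in GUANINE_RING_ATOMS], axis=0)
        return [
            np.linalg.norm(g0["N1"] - g1["O6"]) - hbond_gap,
            np.linalg.norm(g0["N2"] - g1["N7"]) - hbond_gap,
            0.3 * (np.linalg.norm(g0["O6"]) - 2.45),
            0.3 * (np.linalg.norm(cen) - 4.30),
        ]

    best = None
    for th0 in np.arange(0.0, 2.0 * math.pi, math.pi / 12.0):
        for az in range(0, 360, 45):
            a = math.radians(az)
            sol = least_squares(resid, [4.3 * math.cos(a), 4.3 * math.sin(a), th0])
            if best is None or sol.cost < best.cost:
                best = sol
    g0 = placed(best.x)
    cen = np.mean([g0[n] for n in GUANINE_RING_ATOMS], axis=0)
    fix = _rot2(-math.degrees(math.atan2(cen[1], cen[0])))
    return tuple((n, *(fix @ g0[n])) for n in GUANINE_RING_ATOMS)


def _nerf(a, b, c, bond: float, angle_deg: float, torsion_deg: float) -> np.ndarray:
    """Place atom d given a-b-c with |cd| = bond, angle(b,c,d), torsion(a,b,c,d)."""
    a, b, c = (np.asarray(p, float) for p in (a, b, c))
    bc = c - b
    bc /= np.linalg.norm(bc)
    n = np.cross(b - a, bc)
    n /= np.linalg.norm(n)
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    tor = math.radians(torsion_deg)
    d2 = np.array(
        [
            -bond * math.cos(ang),
            bond * math.sin(ang) * math.cos(tor),
            bond * math.sin(ang) * math.sin(tor),
        ]
    )
    return c + d2[0] * bc + d2[1] * m + d2[2] * n


def _element_of(atom_name: str) -> str:
    return atom_name[0]


def _make_atom(name: str, pos) -> Atom:
    return Atom(name=name, element=_element_of(name), pos=np.asarray(pos, float))


@dataclass
class G4BuildSpec:
    """Parameters of one synthetic quadruplex build.

    ``backbone_radii``/``p_offsets`` override the per-column phosphate
    placement; defaults give four ~16 A medium grooves for the parallel
    preset and alternating ~21.6 / ~8.7 A wide/narrow grooves for the
    antiparallel preset.
    """

    n_layers: int = 4
    topology: str = "parallel"  # parallel | antiparallel | hybrid
    rise: float = RISE_DEFAULT
    twist: float = TWIST_DEFAULT
    hbond_gap: float = HBOND_GAP_DEFAULT
    backbone_radii: tuple[float, float, float, float] | None = None
    p_offsets: tuple[float, float, float, float] | None = None
    place_ions: bool = True
    loops: bool = True
    dimer: bool = False
    register: int = 0  # interface register: 0 -> Form-1/1, 1 -> Form-1/7
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_layers < 2:
            raise ValueError("n_layers must be >= 2")
        if self.topology not in ("parallel", "antiparallel", "hybrid"):
            raise ValueError(f"unknown topology {self.topology!r}")
        if self.rise <= 0:
            raise ValueError("rise must be positive")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.register not in (0, 1):
            raise ValueError("register must be 0 or 1")
        if self.dimer and self.topology != "parallel":
            raise ValueError("dimer builds are defined for the parallel topology only")

    @property
    def repeat_len(self) -> int:
        return self.n_layers + 2


def _column_directions(topology: str) -> tuple[int, int, int, int]:
    # +1: 5'->3' runs up (increasing z); -1: runs down
    if topology == "parallel":
        return (1, 1, 1, 1)
    if topology == "antiparallel":
        return (-1, 1, -1, 1)
    return (1, 1, 1, -1)


def _glycosidic_target(topology: str, col: int, layer: int) -> float:
    if topology == "parallel":
        return CHI_ANTI
    if topology == "antiparallel":
        return CHI_SYN if (col + layer) % 2 == 0 else CHI_ANTI
    return CHI_SYN if col == 3 else CHI_ANTI


def _p_geometry(spec: G4BuildSpec):
    if spec.backbone_radii is not None:
        radii = tuple(spec.backbone_radii)
        offsets = tuple(spec.p_offsets) if spec.p_offsets is not None else (0.0,) * 4
        return radii, offsets
    if spec.topology == "antiparallel":
        radius, a = antiparallel_p_geometry()
        return (radius,) * 4, (a, -a, a, -a)
    return (PARALLEL_P_RADIUS,) * 4, (0.0,) * 4


def _place_guanine(spec: G4BuildSpec, col: int, layer: int) -> dict[str, np.ndarray]:
    """3D heavy atoms of the guanine at (column, layer), plus C1'/O4'/P."""
    base2d = dict((n, np.array([x, y])) for n, x, y in _tetrad_placement(spec.hbond_gap))
    rot = _rot2(90.0 * col + spec.twist * layer)
    z = spec.rise * layer
    atoms = {n: np.array([*(rot @ p), z]) for n, p in base2d.items()}
    n9 = atoms["N9"]
    # C1' on the exterior bisector of C8-N9-C4 (well-conditioned chi axis)
    u1 = (n9 - atoms["C8"]) / np.linalg.norm(n9 - atoms["C8"])
    u2 = (n9 - atoms["C4"]) / np.linalg.norm(n9 - atoms["C4"])
    out_dir = (u1 + u2) / np.linalg.norm(u1 + u2)
    atoms["C1'"] = n9 + 1.47 * out_dir
    chi = _glycosidic_target(spec.topology, col, layer)
    atoms["O4'"] = _nerf(atoms["C4"], n9, atoms["C1'"], 1.42, 108.0, chi)
    radii, offsets = _p_geometry(spec)
    az = math.radians(90.0 * col + offsets[col] + spec.twist * layer)
    atoms["P"] = np.array([radii[col] * math.cos(az), radii[col] * math.sin(az), z])
    return atoms


def _place_cytosine(centroid, azimuth_deg: float, spin_deg: float = 0.0) -> dict[str, np.ndarray]:
    """Cytosine base with its plane containing the core axis (no stacking).

    The base normal points tangentially; ``spin_deg`` rotates the base in
    its own plane.
    """
    tmpl = _base_template_2d("DC", CYTOSINE_RING_ATOMS)
    az = math.radians(azimuth_deg)
    radial = np.array([math.cos(az), math.sin(az), 0.0])
    u = np.array([0.0, 0.0, 1.0])
    spin = _rot2(spin_deg)
    atoms = {}
    for n, p in tmpl.items():
        q = spin @ p
        atoms[n] = np.asarray(centroid, float) + q[0] * u + q[1] * radial
    n1 = atoms["N1"]
    u1 = (n1 - atoms["C2"]) / np.linalg.norm(n1 - atoms["C2"])
    u2 = (n1 - atoms["C6"]) / np.linalg.norm(n1 - atoms["C6"])
    d = (u1 + u2) / np.linalg.norm(u1 + u2)
    atoms["C1'"] = n1 + 1.47 * d
    return atoms


def _monomer(spec: G4BuildSpec, chain_id: str = "A") -> StructureModel:
    model = StructureModel(title=f"synthetic {spec.topology} G4")
    n = spec.n_layers
    rep = spec.repeat_len
    dirs = _column_directions(spec.topology)
    height = spec.rise * (n - 1)

    residues: dict[int, Residue] = {}
    for col in range(4):
        for layer in range(n):
            pos_in_tract = layer if dirs[col] > 0 else (n - 1 - layer)
            seq = rep * col + pos_in_tract + 1
            atoms = _place_guanine(spec, col, layer)
            res = Residue(chain_id=chain_id, seq_num=seq, res_name="DG")
            res.atoms = [_make_atom(name, p) for name, p in atoms.items()]
            residues[seq] = res

    if spec.loops:
        loop_radius = 13.0
        for col in range(3):
            nxt = col + 1
            # attachment faces follow the strand directions
            end_layer = (n - 1) if dirs[col] > 0 else 0
            start_layer = 0 if dirs[nxt] > 0 else (n - 1)
            z_end = spec.rise * end_layer
            z_start = spec.rise * start_layer
            for j, frac in enumerate((1.0 / 3.0, 2.0 / 3.0)):
                seq = rep * col + n + 1 + j
                az = 90.0 * col + 30.0 + 30.0 * j
                if abs(z_end - z_start) < 1e-9:  # lateral: bulge past the face
                    z = z_start + (2.5 if z_start > height / 2 else -2.5)
                else:  # propeller: run along the groove
                    z = z_end + frac * (z_start - z_end)
                cen = np.array(
                    [loop_radius * math.cos(math.radians(az)),
                     loop_radius * math.sin(math.radians(az)), z]
                )
                atoms = _place_cytosine(cen, az, spin_deg=40.0 * j)
                res = Residue(chain_id=chain_id, seq_num=seq, res_name="DC")
                res.atoms = [_make_atom(name, p) for name, p in atoms.items()]
                residues[seq] = res
        # 3' overhang beyond the last tract's exit face
        exit_z = height + 2.5 if dirs[3] > 0 else -2.5
        step = 2.0 if dirs[3] > 0 else -2.0
        for j in range(2):
            seq = rep * 3 + n + 1 + j
            az = 300.0 + 30.0 * j
            cen = np.array(
                [14.0 * math.cos(math.radians(az)), 14.0 * math.sin(math.radians(az)),
                 exit_z + step * j]
            )
            atoms = _place_cytosine(cen, az, spin_deg=25.0 * j)
            res = Residue(chain_id=chain_id, seq_num=seq, res_name="DC")
            res.atoms = [_make_atom(name, p) for name, p in atoms.items()]
            residues[seq] = res

    for seq in sorted(residues):
        model.add_residue(residues[seq])

    if spec.place_ions:
        for i in range(n - 1):
            ion = Residue(chain_id="I", seq_num=101 + i, res_name="K")
            ion.atoms = [Atom("K", "K", np.array([0.0, 0.0, spec.rise * (i + 0.5)]))]
            model.add_residue(ion)
    model.sort()
    return model


def build_g4(spec: G4BuildSpec) -> StructureModel:
    """Build a synthetic quadruplex coordinate model per ``spec``.

    Monomers place ``4 x n_layers`` guanines in four columns; dimer builds
    add a two-fold-related copy stacked 5'-5' below the first unit
    (register 0 aligns repeat 1 on repeat 1 -> Form-1/1; register 1 rotates
    the partner by one column step -> Form-1/7), with one interface cation.
    Gaussian coordinate noise (RMS ``noise_sigma`` per atom) is applied
    last, from ``seed``.
    """
    model = _monomer(spec)
    if spec.dimer:
        flip = np.diag([1.0, -1.0, -1.0])  # two-fold about x, perpendicular to the axis
        rot = np.array(
            [[math.cos(math.radians(90.0 * spec.register)),
              -math.sin(math.radians(90.0 * spec.register)), 0.0],
             [math.sin(math.radians(90.0 * spec.register)),
              math.cos(math.radians(90.0 * spec.register)), 0.0],
             [0.0, 0.0, 1.0]]
        ) @ flip
        mate = apply_symmetry(model, rot, np.array([0.0, 0.0, -spec.rise]), chain_suffix="2")
        model = merge_models(model, mate)
        if spec.place_ions:
            ion = Residue(chain_id="I", seq_num=100, res_name="K")
            ion.atoms = [Atom("K", "K", np.array([0.0, 0.0, -spec.rise / 2.0]))]
            model.add_residue(ion)
            model.sort()
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        comp_sigma = spec.noise_sigma / math.sqrt(3.0)
        for res in model.residues():
            for atom in res.atoms:
                atom.pos = atom.pos + rng.normal(0.0, comp_sigma, size=3)
    return model


# ---------------------------------------------------------------------------
# torsion-defined backbone (forward kinematics)
# ---------------------------------------------------------------------------

_BB_BONDS = {  # bond lengths, A
    ("P", "O5'"): 1.593,
    ("O5'", "C5'"): 1.440,
    ("C5'", "C4'"): 1.510,
    ("C4'", "C3'"): 1.524,
    ("C3'", "O3'"): 1.423,
    ("O3'", "P"): 1.607,
}
_BB_ANGLES = {  # bond angles at the middle atom, degrees
    ("O3'", "P", "O5'"): 104.0,
    ("P", "O5'", "C5'"): 120.9,
    ("O5'", "C5'", "C4'"): 111.5,
    ("C5'", "C4'", "C3'"): 115.5,
    ("C4'", "C3'", "O3'"): 110.2,
    ("C3'", "O3'", "P"): 119.7,
}
_BB_ORDER = ("P", "O5'", "C5'", "C4'", "C3'", "O3'")
_BB_TORSION_NAMES = ("alpha", "beta", "gamma", "delta", "epsilon", "zeta")


def backbone_from_torsions(torsions: list[dict], chain_id: str = "A") -> StructureModel:
    """Build a pure sugar-phosphate backbone chain from target torsions.

    ``torsions`` holds one dict per residue with keys among
    alpha/beta/gamma/delta/epsilon/zeta (degrees); values drive the
    placement of successive chain atoms P-O5'-C5'-C4'-C3'-O3' by forward
    kinematics (natural extension reference frames), so the recovered
    torsions reproduce the targets exactly.  Residues are emitted as DG
    with backbone atoms only.
    """
    chain_atoms: list[tuple[int, str, np.ndarray]] = []
    # seed the first three atoms of residue 1 in a canonical pose
    p0 = np.zeros(3)
    o5 = p0 + np.array([_BB_BONDS[("P", "O5'")], 0.0, 0.0])
    ang = math.radians(_BB_ANGLES[("P", "O5'", "C5'")])
    c5 = o5 + _BB_BONDS[("O5'", "C5'")] * np.array([-math.cos(ang), math.sin(ang), 0.0])
    chain_atoms += [(1, "P", p0), (1, "O5'", o5), (1, "C5'", c5)]

    flat = [(i + 1, name) for i in range(len(torsions)) for name in _BB_ORDER]
    torsion_for = {  # torsion that places each atom (about the preceding bond)
        "C5'": "alpha", "C4'": "beta", "C3'": "gamma", "O3'": "delta",
        "P": "epsilon", "O5'": "zeta",
    }
    for k in range(3, len(flat)):
        res_i, name = flat[k]
        a = chain_atoms[k - 3][2]
        b = chain_atoms[k - 2][2]
        c = chain_atoms[k - 1][2]
        prev_name, cur_name = flat[k - 1][1], name
        bond = _BB_BONDS[(prev_name, cur_name)]
        angle = _BB_ANGLES[(flat[k - 2][1], prev_name, cur_name)]
        tname = torsion_for[name]
        # the torsion that places atom k belongs to the residue owning the bond
        owner = res_i if name not in ("P", "O5'") else res_i - 1
        tor = torsions[owner - 1].get(tname)
        if tor is None:
            raise ValueError(f"residue {owner}: torsion {tname} required")
        chain_atoms.append((res_i, name, _nerf(a, b, c, bond, angle, tor)))

    model = StructureModel(title="torsion-defined backbone")
    by_res: dict[int, Residue] = {}
    for res_i, name, pos in chain_atoms:
        res = by_res.setdefault(res_i, Residue(chain_id=chain_id, seq_num=res_i, res_name="DG"))
        res.atoms.append(_make_atom(name, pos))
    for seq in sorted(by_res):
        model.add_residue(by_res[seq])
    model.sort()
    return model


# ---------------------------------------------------------------------------
# C·C+ pair / quadruple fixture
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _cc_pair_placement(gap: float = 2.8) -> tuple[tuple[float, float, float], ...]:
    """In-plane transform of the partner cytosine of a C·C+ pair.

    Solved so that N3-N3 and both symmetric N4-O2 contacts equal ``gap``.
    Returns the 2D atom positions of base A (template) and base B (placed).
    """
    tmpl = _base_template_2d("DC", CYTOSINE_RING_ATOMS)

    def placed(params):
        tx, ty, th = params
        rot = _rot2(math.degrees(th))
        return {n: rot @ tmpl[n] + np.array([tx, ty]) for n in CYTOSINE_RING_ATOMS}

    def resid(params):
        b = placed(params)
        return [
            np.linalg.norm(tmpl["N3"] - b["N3"]) - gap,
            np.linalg.norm(tmpl["N4"] - b["O2"]) - gap,
            np.linalg.norm(tmpl["O2"] - b["N4"]) - gap,
        ]

    best = None
    for th0 in np.arange(0.0, 2.0 * math.pi, math.pi / 8.0):
        for az in range(0, 360, 60):
            a = math.radians(az)
            sol = least_squares(resid, [5.5 * math.cos(a), 5.5 * math.sin(a), th0])
            if best is None or sol.cost < best.cost:
                best = sol
    b = placed(best.x)
    out = [("A", n, *tmpl[n]) for n in CYTOSINE_RING_ATOMS]
    out += [("B", n, *b[n]) for n in CYTOSINE_RING_ATOMS]
    return tuple(out)


@lru_cache(maxsize=None)
def _cc_quadruple_placement(junction_gap: float = 2.9):
    """Rigid in-plane transform placing the second C·C+ pair next to the first.

    Constrains the two junction hydrogen bonds (N4 of one pair's base to O2
    of its counterpart on each side) to ``junction_gap`` while penalizing
    steric overlap.
    """
    pair = _cc_pair_placement()
    a = {n: np.array([x, y]) for tag, n, x, y in pair if tag == "A"}
    b = {n: np.array([x, y]) for tag, n, x, y in pair if tag == "B"}
    all_pts = np.array([p for base in (a, b) for p in base.values()])

    def placed(params):
        tx, ty, th = params
        rot = _rot2(math.degrees(th))
        a2 = {n: rot @ a[n] + np.array([tx, ty]) for n in a}
        b2 = {n: rot @ b[n] + np.array([tx, ty]) for n in b}
        return a2, b2

    def resid(params):
        a2, b2 = placed(params)
        new_pts = np.array([p for base in (a2, b2) for p in base.values()])
        dmin = np.min(np.linalg.norm(all_pts[:, None, :] - new_pts[None, :, :], axis=2))
        return [
            np.linalg.norm(a["N4"] - a2["O2"]) - junction_gap,
            np.linalg.norm(b["O2"] - b2["N4"]) - junction_gap,
            3.0 * max(0.0, 2.6 - dmin),
        ]

    best = None
    for th0 in np.arange(0.0, 2.0 * math.pi, math.pi / 8.0):
        for az in range(0, 360, 45):
            r = math.radians(az)
            sol = least_squares(resid, [7.0 * math.cos(r), 7.0 * math.sin(r), th0])
            if best is None or sol.cost < best.cost:
                best = sol
    a2, b2 = placed(best.x)
    return (
        tuple((n, *a[n]) for n in CYTOSINE_RING_ATOMS),
        tuple((n, *b[n]) for n in CYTOSINE_RING_ATOMS),
        tuple((n, *a2[n]) for n in CYTOSINE_RING_ATOMS),
        tuple((n, *b2[n]) for n in CYTOSINE_RING_ATOMS),
    )


def build_cc_quadruple(
    z: float = 0.0,
    xy_offset=(0.0, 0.0),
    chain_ids=("E", "F"),
) -> StructureModel:
    """Four cytosines forming a C·C+·C·C+ quadruple base pair in the z-plane.

    Pairs are (C6' of chain 2)·(C23 of chain 1) and (C5' of chain 2)·
    (C24 of chain 1), joined by one junction hydrogen bond on each side.
    """
    pair1_a, pair1_b, pair2_a, pair2_b = _cc_quadruple_placement()
    quad_pts = [p[1:] for base in (pair1_a, pair1_b, pair2_a, pair2_b) for p in base]
    center = np.mean(np.asarray(quad_pts), axis=0)
    dx, dy = xy_offset
    model = StructureModel(title="synthetic C·C+·C·C+ quadruple")
    assignments = (
        (chain_ids[0], 23, pair1_a),  # C23
        (chain_ids[1], 6, pair1_b),  # C6'
        (chain_ids[0], 24, pair2_a),  # C24
        (chain_ids[1], 5, pair2_b),  # C5'
    )
    for chain_id, seq, base in assignments:
        res = Residue(chain_id=chain_id, seq_num=seq, res_name="DC")
        for n, x, y in base:
            res.atoms.append(_make_atom(n, [x - center[0] + dx, y - center[1] + dy, z]))
        model.add_residue(res)
    model.sort()
    return model


def place_flat_cytosine(
    center, tilt_deg: float = 0.0, chain_id: str = "Z", seq_num: int = 900
) -> Residue:
    """A lone cytosine base in an xy-parallel plane at ``center``.

    ``tilt_deg`` rotates the base about the x-axis; used to probe
    base-on-tetrad stacking detection (parallel vs tilted bases).
    """
    tmpl = _base_template_2d("DC", CYTOSINE_RING_ATOMS)
    t = math.radians(tilt_deg)
    rot = np.array(
        [[1.0, 0.0, 0.0],
         [0.0, math.cos(t), -math.sin(t)],
         [0.0, math.sin(t), math.cos(t)]]
    )
    res = Residue(chain_id=chain_id, seq_num=seq_num, res_name="DC")
    for n, p in tmpl.items():
        pos = rot @ np.array([p[0], p[1], 0.0]) + np.asarray(center, float)
        res.atoms.append(_make_atom(n, pos))
    return res


# ---------------------------------------------------------------------------
# melting-curve simulation
# ---------------------------------------------------------------------------

@dataclass
class MeltSimSpec:
    """Simulated CD melting curve: 25-95 C in 1 C steps by default."""

    model: str = "boltzmann"  # boltzmann | double
    tm: float = 80.0
    slope: float = 3.0
    tm1: float = 46.4
    tm2: float = 89.1
    slope1: float = 3.0
    slope2: float = 3.0
    fraction: float = 0.5
    t_start: float = 25.0
    t_stop: float = 95.0
    t_step: float = 1.0
    noise_sigma: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.t_step <= 0:
            raise ValueError("t_step must be positive")
        if self.model not in ("boltzmann", "double"):
            raise ValueError(f"unknown model {self.model!r}")
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")


def simulate_melting(spec: MeltSimSpec) -> MeltingCurve:
    """Exact sigmoid model curve plus i.i.d. Gaussian noise (reproducible)."""
    T = np.arange(spec.t_start, spec.t_stop + spec.t_step / 2.0, spec.t_step)
    if spec.model == "boltzmann":
        y = boltzmann(T, 0.0, 1.0, spec.tm, spec.slope)
    else:
        y = double_sigmoid(T, spec.fraction, spec.tm1, spec.slope1, spec.tm2, spec.slope2)
    if spec.noise_sigma > 0:
        rng = np.random.default_rng(spec.seed)
        y = y + rng.normal(0.0, spec.noise_sigma, size=T.shape)
    return MeltingCurve(T, y)
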