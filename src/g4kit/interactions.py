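"""Non-tetrad interactions around a G-quadruplex core.

Covers hemiprotonated C·C+ base pairs and the C·C+·C·C+ quadruple base
pair, base-on-tetrad pi-stacking, the 5'-5' dimer-interface stacking
register (Form-1/1 vs Form-1/7), auxiliary ion coordination spheres and
water-mediated bridges.

Protonation is not observable in X-ray models, so C·C+ is called purely
geometrically: a short N3-N3 contact between coplanar cytosines implies
hemiprotonation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point, Polygon

from .geometry import ls_plane, plane_angle
from .quadruplex import GTetrad, HBond, QuadruplexCore, base_ring_points
from .structure_io import Residue, ResidueKind, StructureModel

__all__ = [
    "BasePair",
    "QuadrupleBasePair",
    "StackContact",
    "IonSite",
    "detect_cc_pairs",
    "detect_quadruple_pair",
    "classify_interface",
    "base_tetrad_stacking",
    "ion_coordination",
    "water_bridges",
    "InterfaceNotApplicableError",
    "interaction_report",
]

_POLAR_ELEMENTS = {"N", "O"}


def _dist(res_a: Residue, atom_a: str, res_b: Residue, atom_b: str) -> float | None:
    ca, cb = res_a.coord(atom_a), res_b.coord(atom_b)
    if ca is None or cb is None:
        return None
    return float(np.linalg.norm(ca - cb))


def _base_plane(res: Residue):
    pts = base_ring_points(res)
    if len(pts) < 3:
        return None
    return ls_plane(pts)


@dataclass
class BasePair:
    res_a: Residue
    res_b: Residue
    hbonds: list[HBond]
    pair_class: str  # CC_plus | WC | other
    coplanarity_angle: float

    def label(self) -> str:
        return f"{self.res_a.label}·{self.res_b.label}"


@dataclass
class QuadrupleBasePair:
    pairs: tuple[BasePair, BasePair]
    inter_pair_hbonds: list[HBond]
    stacked_tetrad: GTetrad | None = None

    def label(self) -> str:
        return f"{self.pairs[0].label()}·{self.pairs[1].label()}"


@dataclass
class StackContact:
    unit_a: object  # Residue or GTetrad
    unit_b: object
    centroid_dist: float
    normal_angle: float


@dataclass
class IonSite:
    ion: Residue
    ligands: list[tuple[Residue, str, float]]
    geometry_label: str = "irregular"


def detect_cc_pairs(
    model: StructureModel,
    dist_cutoff: float = 3.5,
    coplanar_max: float = 35.0,
) -> list[BasePair]:
    """Cytosine-cytosine (C·C+) and cytosine-guanine (WC) base pairs.

    C·C+ is called when the N3-N3 distance and at least one of the two
    symmetric N4-O2 contacts are within ``dist_cutoff`` and the base planes
    are coplanar within ``coplanar_max`` degrees.
    """
    pairs: list[BasePair] = []
    cytosines = [c for c in model.cytosines() if c.has_atoms(("N3", "N4", "O2"))]
    for a, b in itertools.combinations(cytosines, 2):
        d_n3 = _dist(a, "N3", b, "N3")
        d_ab = _dist(a, "N4", b, "O2")
        d_ba = _dist(a, "O2", b, "N4")
        if d_n3 is None or d_n3 > dist_cutoff:
            continue
        if not any(d is not None and d <= dist_cutoff for d in (d_ab, d_ba)):
            continue
        pa, pb = _base_plane(a), _base_plane(b)
        if pa is None or pb is None:
            continue
        angle = plane_angle(pa.normal, pb.normal)
        if angle > coplanar_max:
            continue
        hbonds = [HBond(a, b, "N3", "N3", d_n3)]
        if d_ab is not None and d_ab <= dist_cutoff:
            hbonds.append(HBond(a, b, "N4", "O2", d_ab))
        if d_ba is not None and d_ba <= dist_cutoff:
            hbonds.append(HBond(b, a, "N4", "O2", d_ba))
        pairs.append(BasePair(a, b, hbonds, "CC_plus", angle))
    # Watson-Crick G-C pairs, for class routing
    for c in cytosines:
        for g in model.guanines():
            d1 = _dist(g, "N1", c, "N3")
            d2 = _dist(g, "N2", c, "O2")
            d3 = _dist(g, "O6", c, "N4")
            good = [d for d in (d1, d2, d3) if d is not None and d <= dist_cutoff]
            if len(good) < 2:
                continue
            pg, pc = _base_plane(g), _base_plane(c)
            if pg is None or pc is None:
                continue
            angle = plane_angle(pg.normal, pc.normal)
            if angle > coplanar_max:
                continue
            hb = []
            if d1 is not None and d1 <= dist_cutoff:
                hb.append(HBond(g, c, "N1", "N3", d1))
            if d2 is not None and d2 <= dist_cutoff:
                hb.append(HBond(g, c, "N2", "O2", d2))
            if d3 is not None and d3 <= dist_cutoff:
                hb.append(HBond(c, g, "N4", "O6", d3))
            pairs.append(BasePair(g, c, hb, "WC", angle))
    return pairs


def detect_quadruple_pair(
    pairs: list[BasePair],
    tetrads: list[GTetrad],
    dist_cutoff: float = 3.5,
    planarity_rms_max: float = 1.0,
    stack_dist_max: float = 4.5,
    stack_angle_max: float = 30.0,
) -> list[QuadrupleBasePair]:
    """Join two coplanar C·C+ pairs into a quadruple base pair.

    The two pairs must share one plane (rms of the 4 base rings within
    ``planarity_rms_max``) and carry at least one inter-pair hydrogen bond
    on each junction (each base of one pair matched to its nearest
    counterpart in the other).  ``stacked_tetrad`` is set when the
    quadruple's plane stacks onto a tetrad.
    """
    cc = [p for p in pairs if p.pair_class == "CC_plus"]
    out: list[QuadrupleBasePair] = []
    for p1, p2 in itertools.combinations(cc, 2):
        bases1 = (p1.res_a, p1.res_b)
        bases2 = (p2.res_a, p2.res_b)
        if {b.key for b in bases1} & {b.key for b in bases2}:
            continue
        ring_pts = np.vstack([base_ring_points(b) for b in bases1 + bases2])
        plane = ls_plane(ring_pts)
        if plane.rms_dev > planarity_rms_max:
            continue
        # junctions: a perfect matching of p1 bases to p2 bases with at least
        # one donor-acceptor bond on each edge (either matching may apply)
        bond_atoms = (("N4", "O2"), ("O2", "N4"), ("N4", "N3"), ("N3", "N4"))
        inter: list[HBond] = []
        for matching in (((0, 0), (1, 1)), ((0, 1), (1, 0))):
            cand: list[HBond] = []
            ok = True
            for i1, i2 in matching:
                x, y = bases1[i1], bases2[i2]
                found = []
                for da, aa in bond_atoms:
                    d = _dist(x, da, y, aa)
                    if d is not None and d <= dist_cutoff:
                        found.append(HBond(x, y, da, aa, d))
                if not found:
                    ok = False
                    break
                cand.extend(found)
            if ok:
                inter = cand
                break
        if not inter:
            continue
        qbp = QuadrupleBasePair((p1, p2), inter)
        for t in tetrads:
            cd = float(np.linalg.norm(plane.centroid - t.centroid))
            ang = plane_angle(plane.normal, t.normal)
            if cd <= stack_dist_max and ang <= stack_angle_max:
                qbp.stacked_tetrad = t
                break
        out.append(qbp)
    return out


class InterfaceNotApplicableError(ValueError):
    """The core has no inter-unit 5'-5' stacking interface."""


def classify_interface(core: QuadruplexCore, repeat_len: int = 6):
    """Stacking register of the 5'-5' interface between two G4 units.

    For each guanine of the interface tetrad of unit A, the overlap partner
    in unit B is the base whose ring centroid, projected along the interface
    normal, is nearest.  The register is named from the partner of the
    guanine in the first sequence repeat (G1): G1 over G1 -> ``Form_1_1``;
    G1 over the first guanine of an adjacent repeat (G7-type) ->
    ``Form_1_7``; anything else -> ``other``.

    Returns ``(form, overlap_map)`` where ``overlap_map`` maps residue
    labels of unit A to their unit-B partners.
    """
    units = core.units()
    interface = None
    for i in range(core.n_layers - 1):
        if units[i] != units[i + 1]:
            interface = i
            break
    if interface is None:
        raise InterfaceNotApplicableError("core contains a single monomer unit")
    tet_a, tet_b = core.tetrads[interface], core.tetrads[interface + 1]
    normal = core.axis

    def lateral(res):
        c = base_ring_points(res).mean(axis=0)
        return c - np.dot(c, normal) * normal

    overlap: dict[str, str] = {}
    partner_of: dict[tuple, Residue] = {}
    for ga in tet_a.members:
        la = lateral(ga)
        gb = min(tet_b.members, key=lambda r: np.linalg.norm(lateral(r) - la))
        overlap[ga.label] = gb.label
        partner_of[ga.key] = gb

    def repeat_ordinal(res):
        return (res.seq_num - 1) // repeat_len + 1

    def intra_index(res):
        return (res.seq_num - 1) % repeat_len + 1

    n_repeats = max(repeat_ordinal(r) for r in tet_a.members)
    g1 = min(tet_a.members, key=repeat_ordinal)
    p = partner_of[g1.key]
    if intra_index(p) != intra_index(g1):
        form = "other"
    elif repeat_ordinal(p) == repeat_ordinal(g1):
        form = "Form_1_1"
    elif (repeat_ordinal(p) - repeat_ordinal(g1)) % n_repeats in (1, n_repeats - 1):
        form = "Form_1_7"
    else:
        form = "other"
    return form, overlap


def base_tetrad_stacking(
    model: StructureModel,
    tetrads: list[GTetrad],
    dist_max: float = 4.5,
    angle_max: float = 30.0,
    footprint_margin: float = 2.0,
) -> list[StackContact]:
    """Non-core bases pi-stacked onto a tetrad face.

    A base stacks when its ring centroid lies within ``dist_max`` of the
    tetrad plane (perpendicular distance), its plane normal is within
    ``angle_max`` of the tetrad normal, and its lateral projection falls
    inside the convex hull of the tetrad ring atoms grown by
    ``footprint_margin``.
    """
    tetrad_keys = {m.key for t in tetrads for m in t.members}
    contacts: list[StackContact] = []
    for res in model.residues():
        if res.kind not in (ResidueKind.GUANINE, ResidueKind.CYTOSINE, ResidueKind.OTHER_BASE):
            continue
        if res.key in tetrad_keys:
            continue
        pts = base_ring_points(res)
        if len(pts) < 3:
            continue
        plane = ls_plane(pts)
        centroid = pts.mean(axis=0)
        for t in tetrads:
            perp = abs(t.plane.signed_distance(centroid))
            if perp > dist_max:
                continue
            ang = plane_angle(plane.normal, t.normal)
            if ang > angle_max:
                continue
            # project tetrad footprint and the base centroid onto the plane
            n = t.normal
            e1 = np.cross(n, [1.0, 0.0, 0.0])
            if np.linalg.norm(e1) < 1e-6:
                e1 = np.cross(n, [0.0, 1.0, 0.0])
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(n, e1)
            ring = np.vstack([base_ring_points(m) for m in t.members]) - t.centroid
            poly = Polygon([(p @ e1, p @ e2) for p in ring]).convex_hull.buffer(footprint_margin)
            v = centroid - t.centroid
            if poly.contains(Point(v @ e1, v @ e2)):
                contacts.append(StackContact(res, t, float(np.linalg.norm(centroid - t.centroid)), ang))
    return contacts


def ion_coordination(model: StructureModel, ion_res: Residue, cutoff: float = 3.6) -> IonSite:
    """Coordination sphere of one ion: all N/O atoms within ``cutoff``.

    The geometry label is a heuristic: ``antiprismatic`` when eight ligands
    split 4+4 between two near-parallel planes along the site axis.
    """
    if not ion_res.atoms:
        raise ValueError("ion residue has no atoms")
    pos = ion_res.atoms[0].pos
    ligands: list[tuple[Residue, str, float]] = []
    for res in model.residues():
        if res.kind is ResidueKind.ION:
            continue
        for a in res.atoms:
            if a.element.upper() not in _POLAR_ELEMENTS:
                continue
            d = float(np.linalg.norm(a.pos - pos))
            if d <= cutoff:
                ligands.append((res, a.name, d))
    ligands.sort(key=lambda t: t[2])
    site = IonSite(ion_res, ligands)
    if len(ligands) >= 8:
        pts = np.array([r.coord(a) for r, a, _ in ligands[:8]])
        rel = pts - pos
        axis = np.linalg.svd(rel - rel.mean(0))[2][2]  # least-varying direction
        proj = rel @ axis
        order = np.argsort(proj)
        lower, upper = proj[order[:4]], proj[order[4:]]
        if upper.min() - lower.max() > 1.0:
            site.geometry_label = "antiprismatic"
    return site


def water_bridges(model: StructureModel, dist_cutoff: float = 3.4):
    """Water molecules hydrogen-bonded to >= 2 polar atoms of distinct residues.

    Returns a list of ``(water, (res_a, atom_a, dist_a), (res_b, atom_b, dist_b))``
    bridge records, one per partner pair.
    """
    bridges = []
    for water in model.waters():
        o = water.coord("O") if water.coord("O") is not None else (
            water.atoms[0].pos if water.atoms else None
        )
        if o is None:
            continue
        partners = []
        for res in model.residues():
            if res.kind in (ResidueKind.WATER, ResidueKind.ION):
                continue
            for a in res.atoms:
                if a.element.upper() not in _POLAR_ELEMENTS:
                    continue
                d = float(np.linalg.norm(a.pos - o))
                if d <= dist_cutoff:
                    partners.append((res, a.name, d))
        for pa, pb in itertools.combinations(partners, 2):
            if pa[0].key == pb[0].key:
                continue
            bridges.append((water, pa, pb))
    return bridges


def interaction_report(
    model: StructureModel,
    tetrads: list[GTetrad],
    core: QuadruplexCore | None = None,
) -> dict:
    """Consolidated JSON-ready interaction annotation."""
    pairs = detect_cc_pairs(model)
    quads = detect_quadruple_pair(pairs, tetrads)
    stacks = base_tetrad_stacking(model, tetrads)
    ion_sites = [ion_coordination(model, ion) for ion in model.ions()]
    bridges = water_bridges(model)
    report = {
        "base_pairs": [
            {
                "pair": p.label(),
                "class": p.pair_class,
                "hbonds": [{"bond": h.label(), "dist": round(h.dist, 1)} for h in p.hbonds],
                "coplanarity_angle": round(p.coplanarity_angle, 1),
            }
            for p in pairs
        ],
        "quadruple_pairs": [
            {
                "quadruple": q.label(),
                "stacked_tetrad": q.stacked_tetrad.label() if q.stacked_tetrad else None,
                "inter_pair_hbonds": [
                    {"bond": h.label(), "dist": round(h.dist, 1)} for h in q.inter_pair_hbonds
                ],
            }
            for q in quads
        ],
        "stack_contacts": [
            {
                "base": s.unit_a.label,
                "tetrad": s.unit_b.label(),
                "centroid_dist": round(s.centroid_dist, 1),
                "normal_angle": round(s.normal_angle, 1),
            }
            for s in stacks
        ],
        "ion_sites": [
            {
                "ion": s.ion.label,
                "geometry": s.geometry_label,
                "ligands": [
                    {"residue": r.label, "atom": a, "dist": round(d, 1)}
                    for r, a, d in s.ligands
                ],
            }
            for s in ion_sites
        ],
        "water_bridges": [
            {
                "water": f"W{w.seq_num}",
                "partner_a": {"residue": pa[0].label, "atom": pa[1], "dist": round(pa[2], 1)},
                "partner_b": {"residue": pb[0].label, "atom": pb[1], "dist": round(pb[2], 1)},
            }
            for w, pa, pb in bridges
        ],
    }
    if core is not None:
        try:
            form, overlap = classify_interface(core)
            report["interface"] = {"form": form, "overlap_map": overlap}
        except InterfaceNotApplicableError:
            report["interface"] = None
    return report
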