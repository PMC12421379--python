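"""G-tetrad detection, quadruplex-core assembly and classification.

A G-tetrad is four guanines in a closed, directed Hoogsteen cycle: residue i
donates N1->O6 and N2->N7 hydrogen bonds to residue i+1.  Detection builds a
directed graph over guanines from heavy-atom donor-acceptor distances, finds
directed 4-cycles, and accepts a cycle as a tetrad when the mean of its eight
Hoogsteen distances is within the cutoff and the four bases are coplanar.
The mean-distance acceptance rule keeps detection stable on noisy or
moderate-resolution coordinates where individual bonds straddle a hard
threshold; candidate edges are therefore generated with a 1 A slack over the
cutoff and filtered by the mean criterion.

Stacked tetrads are assembled into cores; topology (parallel, antiparallel,
hybrid), groove widths/classes, loop classes and channel-ion occupancy are
derived from the assembled core.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.optimize import linear_sum_assignment

from .geometry import Plane, classify_glycosidic, dihedral, ls_plane, plane_angle
from .structure_io import GUANINE_RING_ATOMS, Residue, ResidueKind, StructureModel

__all__ = [
    "HBond",
    "GTetrad",
    "GrooveReport",
    "LoopAnnotation",
    "IonAssignment",
    "QuadruplexCore",
    "detect_hbonds",
    "detect_tetrads",
    "assemble_cores",
    "classify_topology",
    "groove_widths",
    "classify_loops",
    "channel_ions",
    "core_report",
]

# donor -> acceptor atom sets on base edges, heavy atoms only
_BASE_DONORS = {
    ResidueKind.GUANINE: ("N1", "N2"),
    ResidueKind.CYTOSINE: ("N4",),
    ResidueKind.OTHER_BASE: ("N6", "N3"),
}
_BASE_ACCEPTORS = {
    ResidueKind.GUANINE: ("O6", "N7", "N3"),
    ResidueKind.CYTOSINE: ("O2", "N3"),
    ResidueKind.OTHER_BASE: ("N1", "N7", "O2", "O4"),
}


@dataclass
class HBond:
    donor_res: Residue
    acceptor_res: Residue
    donor_atom: str
    acceptor_atom: str
    dist: float

    def label(self) -> str:
        return (
            f"{self.donor_res.label}{self.donor_atom}-"
            f"{self.acceptor_res.label}{self.acceptor_atom}"
        )


def _pair_dist(res_a: Residue, atom_a: str, res_b: Residue, atom_b: str) -> float | None:
    ca, cb = res_a.coord(atom_a), res_b.coord(atom_b)
    if ca is None or cb is None:
        return None
    return float(np.linalg.norm(ca - cb))


def detect_hbonds(
    model: StructureModel,
    dist_cutoff: float = 3.4,
    pair_set: str = "hoogsteen_G",
) -> list[HBond]:
    """Heavy-atom hydrogen bonds between bases.

    ``pair_set="hoogsteen_G"`` restricts to the tetrad-forming guanine pairs
    N1(donor)->O6(acceptor) and N2(donor)->N7(acceptor); ``"generic_base"``
    scans N/O donor-acceptor pairs on base edges.  Deposited models carry no
    hydrogens, so only donor/acceptor heavy-atom distance is tested.
    """
    bonds: list[HBond] = []
    if pair_set == "hoogsteen_G":
        guanines = model.guanines()
        for donor, acceptor in itertools.permutations(guanines, 2):
            for da, aa in (("N1", "O6"), ("N2", "N7")):
                d = _pair_dist(donor, da, acceptor, aa)
                if d is not None and d <= dist_cutoff:
                    bonds.append(HBond(donor, acceptor, da, aa, d))
    elif pair_set == "generic_base":
        bases = [
            r
            for r in model.residues()
            if r.kind in (ResidueKind.GUANINE, ResidueKind.CYTOSINE, ResidueKind.OTHER_BASE)
        ]
        for donor, acceptor in itertools.permutations(bases, 2):
            for da in _BASE_DONORS.get(donor.kind, ()):
                for aa in _BASE_ACCEPTORS.get(acceptor.kind, ()):
                    d = _pair_dist(donor, da, acceptor, aa)
                    if d is not None and d <= dist_cutoff:
                        bonds.append(HBond(donor, acceptor, da, aa, d))
    else:
        raise ValueError(f"unknown pair_set {pair_set!r}")
    return bonds


@dataclass
class GTetrad:
    """Four guanines in cyclic donor->acceptor order."""

    members: tuple[Residue, Residue, Residue, Residue]
    plane: Plane
    hbonds: list[HBond] = field(default_factory=list)
    mean_hbond_dist: float = float("nan")

    @property
    def centroid(self) -> np.ndarray:
        return self.plane.centroid

    @property
    def normal(self) -> np.ndarray:
        return self.plane.normal

    def member_keys(self) -> frozenset:
        return frozenset(r.key for r in self.members)

    def label(self) -> str:
        return "·".join(r.label for r in self.members)

    def directionality(self, reference_normal=None) -> str:
        """Circulation of the donor->acceptor cycle about a reference normal.

        Viewed from the tip of ``reference_normal`` looking back at the
        tetrad plane, a right-handed (counter-clockwise) circulation is
        reported as ``"anticlockwise"``.  Default reference: the fitted
        plane normal (deterministic sign, see :func:`g4kit.geometry.ls_plane`).
        Reversing the reference normal flips the call.
        """
        n = self.plane.normal if reference_normal is None else np.asarray(reference_normal, float)
        n = n / np.linalg.norm(n)
        cen = np.mean([_ring_centroid(r) for r in self.members], axis=0)
        circ = 0.0
        pts = [_ring_centroid(r) - cen for r in self.members]
        for i in range(4):
            circ += float(np.dot(np.cross(pts[i], pts[(i + 1) % 4]), n))
        return "anticlockwise" if circ > 0 else "clockwise"

    def glycosidic_pattern(self) -> tuple[str, str, str, str]:
        calls = []
        for r in self.members:
            atoms = [r.coord(n) for n in ("O4'", "C1'", "N9", "C4")]
            if any(a is None for a in atoms):
                calls.append("undefined")
            else:
                calls.append(classify_glycosidic(dihedral(*atoms)))
        return tuple(calls)


def _ring_centroid(res: Residue) -> np.ndarray:
    pts = [res.coord(n) for n in GUANINE_RING_ATOMS if res.coord(n) is not None]
    if not pts:
        raise ValueError(f"{res.label}: no base ring atoms")
    return np.mean(pts, axis=0)


def base_ring_points(res: Residue) -> np.ndarray:
    names = GUANINE_RING_ATOMS if res.kind is ResidueKind.GUANINE else (
        "N1", "C2", "O2", "N3", "C4", "N4", "C5", "C6",
    )
    return np.array([res.coord(n) for n in names if res.coord(n) is not None])


def detect_tetrads(
    model: StructureModel,
    dist_cutoff: float = 3.4,
    planarity_rms_max: float = 1.0,
    candidate_slack: float = 1.0,
) -> list[GTetrad]:
    """Detect G-tetrads as planar directed Hoogsteen 4-cycles.

    A directed edge u->v is a candidate when at least one of N1(u)-O6(v),
    N2(u)-N7(v) is within ``dist_cutoff + candidate_slack``; a 4-cycle is
    accepted when the mean of its eight Hoogsteen distances is within
    ``dist_cutoff`` and the 44 base ring atoms fit one plane within
    ``planarity_rms_max`` (rms).  Cycles are deduplicated by canonical
    rotation starting at the lowest (chain_id, seq_num).
    """
    guanines = [g for g in model.guanines() if g.has_atoms(("N1", "N2", "O6", "N7"))]
    gen_cut = dist_cutoff + candidate_slack
    graph = nx.DiGraph()
    graph.add_nodes_from(range(len(guanines)))
    dists: dict[tuple[int, int], tuple[float, float]] = {}
    for (i, u), (j, v) in itertools.permutations(enumerate(guanines), 2):
        d1 = _pair_dist(u, "N1", v, "O6")
        d2 = _pair_dist(u, "N2", v, "N7")
        if d1 is None or d2 is None:
            continue
        if min(d1, d2) <= gen_cut:
            graph.add_edge(i, j)
            dists[(i, j)] = (d1, d2)

    tetrads: list[GTetrad] = []
    seen: set[frozenset] = set()
    for cycle in nx.simple_cycles(graph, length_bound=4):
        if len(cycle) != 4:
            continue
        members = [guanines[i] for i in cycle]
        key = frozenset(r.key for r in members)
        if key in seen:
            continue
        bond_d = []
        for k in range(4):
            bond_d.extend(dists[(cycle[k], cycle[(k + 1) % 4])])
        mean_d = float(np.mean(bond_d))
        if mean_d > dist_cutoff:
            continue
        ring_pts = np.vstack([base_ring_points(r) for r in members])
        plane = ls_plane(ring_pts)
        if plane.rms_dev > planarity_rms_max:
            continue
        seen.add(key)
        # canonical rotation: start the cycle at the lowest (chain_id, seq_num)
        start = min(range(4), key=lambda k: members[k].key)
        ordered = tuple(members[(start + k) % 4] for k in range(4))
        cyc_idx = [cycle[(start + k) % 4] for k in range(4)]
        hbonds = []
        for k in range(4):
            u, v = cyc_idx[k], cyc_idx[(k + 1) % 4]
            d1, d2 = dists[(u, v)]
            hbonds.append(HBond(guanines[u], guanines[v], "N1", "O6", d1))
            hbonds.append(HBond(guanines[u], guanines[v], "N2", "N7", d2))
        tetrads.append(GTetrad(members=ordered, plane=plane, hbonds=hbonds, mean_hbond_dist=mean_d))
    tetrads.sort(key=lambda t: min(r.key for r in t.members))
    return tetrads


@dataclass
class GrooveReport:
    strand_pair: tuple[int, int]  # adjacent column indices
    width_per_layer: list[float]
    width_mean: float
    groove_class: str


@dataclass
class LoopAnnotation:
    residues: list[Residue]
    loop_class: str  # propeller | lateral | diagonal | unclassified
    anchor_5p: Residue | None = None
    anchor_3p: Residue | None = None
    spanned_groove: tuple[int, int] | None = None
    diagnostic: str = ""


@dataclass
class IonAssignment:
    ion: Residue
    interval: tuple[int, int]  # (lower layer, upper layer)
    n_O6: int
    interface: bool


@dataclass
class QuadruplexCore:
    """Ordered stack of tetrads with strand columns and derived annotation."""

    tetrads: list[GTetrad]
    columns: list[list[Residue]]  # cyclic order around the axis; bottom->top
    axis: np.ndarray
    topology: str = "undefined"
    grooves: list[GrooveReport] = field(default_factory=list)
    loops: list[LoopAnnotation] = field(default_factory=list)
    channel_ions: list[IonAssignment] = field(default_factory=list)
    diagnostics: list[str] = field(default_factory=list)

    @property
    def n_layers(self) -> int:
        return len(self.tetrads)

    def layer_of(self, res: Residue) -> int | None:
        for i, t in enumerate(self.tetrads):
            if res.key in (m.key for m in t.members):
                return i
        return None

    def column_of(self, res: Residue) -> int | None:
        for i, col in enumerate(self.columns):
            if res.key in (m.key for m in col):
                return i
        return None

    def units(self) -> list[str]:
        """Per-tetrad monomer unit (the common chain of the members)."""
        out = []
        for t in self.tetrads:
            chains = sorted({m.chain_id for m in t.members})
            out.append(chains[0] if len(chains) == 1 else "+".join(chains))
        return out


class CoreAssemblyError(ValueError):
    pass


def assemble_cores(
    tetrads: list[GTetrad],
    stack_centroid_max: float = 4.5,
    normal_angle_max: float = 30.0,
) -> list[QuadruplexCore]:
    """Group stacked tetrads into cores and build strand columns.

    Tetrads are linked when their centroids are within ``stack_centroid_max``
    and their plane normals within ``normal_angle_max`` (sign-free).  Columns
    link each guanine to its stacking partner in the adjacent tetrad by
    minimum ring-centroid distance under a bijective (optimal-assignment)
    matching; ambiguous assignments are flagged in ``diagnostics``.
    """
    if not tetrads:
        return []
    g = nx.Graph()
    g.add_nodes_from(range(len(tetrads)))
    for i, j in itertools.combinations(range(len(tetrads)), 2):
        cd = float(np.linalg.norm(tetrads[i].centroid - tetrads[j].centroid))
        if cd <= stack_centroid_max and plane_angle(tetrads[i].normal, tetrads[j].normal) <= normal_angle_max:
            g.add_edge(i, j)
    cores = []
    for comp in nx.connected_components(g):
        layer_tetrads = [tetrads[i] for i in comp]
        cores.append(_build_core(layer_tetrads))
    cores.sort(key=lambda c: min(r.key for t in c.tetrads for r in t.members))
    return cores


def _build_core(layer_tetrads: list[GTetrad]) -> QuadruplexCore:
    diagnostics: list[str] = []
    centroids = np.array([t.centroid for t in layer_tetrads])
    if len(layer_tetrads) > 1:
        axis = np.linalg.svd(centroids - centroids.mean(0))[2][0]
    else:
        axis = layer_tetrads[0].normal
    axis = axis / np.linalg.norm(axis)
    order = np.argsort(centroids @ axis)
    stack = [layer_tetrads[i] for i in order]

    # orient the axis 5'->3': from the tetrad holding the 5'-most core guanine
    # of the lowest-sorting chain toward the far end of the stack
    all_members = [r for t in stack for r in t.members]
    ref = min(all_members, key=lambda r: (r.chain_id, r.seq_num))
    ref_layer = next(i for i, t in enumerate(stack) if ref.key in (m.key for m in t.members))
    if ref_layer > (len(stack) - 1) / 2:
        axis = -axis
        stack = stack[::-1]

    # columns by chained optimal assignment between consecutive layers
    n = len(stack[0].members)
    columns: list[list[Residue]] = [[m] for m in stack[0].members]
    col_of_prev = {m.key: c for c, m in enumerate(stack[0].members)}
    for lower, upper in zip(stack, stack[1:]):
        cost = np.zeros((n, len(upper.members)))
        low_cent = [_ring_centroid(m) for m in lower.members]
        up_cent = [_ring_centroid(m) for m in upper.members]
        for a, ca in enumerate(low_cent):
            for b, cb in enumerate(up_cent):
                cost[a, b] = np.linalg.norm(ca - cb)
        rows, cols = linear_sum_assignment(cost)
        for a, b in zip(rows, cols):
            if cost[a, b] > 6.0:
                diagnostics.append(
                    f"ambiguous column link {lower.members[a].label}->{upper.members[b].label}"
                    f" ({cost[a, b]:.1f} A)"
                )
            c = col_of_prev[lower.members[a].key]
            columns[c].append(upper.members[b])
            col_of_prev[upper.members[b].key] = c

    # cyclic order of columns around the axis (right-handed about +axis)
    e1 = np.cross(axis, [1.0, 0.0, 0.0])
    if np.linalg.norm(e1) < 1e-6:
        e1 = np.cross(axis, [0.0, 1.0, 0.0])
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    center = centroids.mean(0)
    azimuth = []
    for col in columns:
        v = np.mean([_ring_centroid(m) for m in col], axis=0) - center
        azimuth.append(np.arctan2(v @ e2, v @ e1))
    columns = [columns[i] for i in np.argsort(azimuth)]

    core = QuadruplexCore(tetrads=stack, columns=columns, axis=axis, diagnostics=diagnostics)
    return core


class TopologyError(ValueError):
    pass


def _column_direction(core: QuadruplexCore, col: list[Residue]) -> int:
    """Sign of the 5'->3' progression of one column segment along the axis."""
    ordered = sorted(col, key=lambda r: (r.chain_id, r.seq_num))
    first, last = ordered[0], ordered[-1]
    c_first, c_last = first.coord("C1'"), last.coord("C1'")
    if c_first is None or c_last is None:  # fall back to glycosidic nitrogen
        c_first, c_last = first.coord("N9"), last.coord("N9")
    if c_first is None or c_last is None:
        raise TopologyError("column direction: no C1'/N9 anchors")
    proj = float(np.dot(c_last - c_first, core.axis))
    if abs(proj) < 1e-9:
        raise TopologyError("column perpendicular to axis: direction undefined")
    return 1 if proj > 0 else -1


def classify_topology(core: QuadruplexCore) -> str:
    """parallel (4 columns same direction), antiparallel (2+2), hybrid (3+1).

    For multi-unit cores (stacked dimers) each monomer unit is classified
    from its own column segments; the core call is the unit consensus.
    """
    units = sorted({r.chain_id for col in core.columns for r in col})
    calls = []
    for unit in units:
        signs = []
        for col in core.columns:
            seg = [r for r in col if r.chain_id == unit]
            if len(seg) >= 2:
                signs.append(_column_direction(core, seg))
        if len(signs) < 4:
            continue
        ups = sum(1 for s in signs if s > 0)
        ups = max(ups, len(signs) - ups)
        calls.append({4: "parallel", 2: "antiparallel"}.get(ups, "hybrid"))
    if not calls:
        raise TopologyError("no unit with 4 classifiable columns")
    core.topology = calls[0] if len(set(calls)) == 1 else "hybrid"
    return core.topology


def groove_widths(
    core: QuadruplexCore,
    narrow_max: float = 12.0,
    wide_min: float = 19.0,
) -> list[GrooveReport]:
    """Groove widths as same-layer P-P distances between adjacent columns.

    For each adjacent column pair around the tetrad cycle, the per-layer
    width is the distance between the phosphorus atoms of the two layer-mate
    guanines; the mean over defined layers is classified as
    narrow < ``narrow_max`` <= medium < ``wide_min`` <= wide.
    """
    n_cols = len(core.columns)
    grooves = []
    for i in range(n_cols):
        j = (i + 1) % n_cols
        widths = []
        for layer in range(core.n_layers):
            gi = _column_member_at_layer(core, i, layer)
            gj = _column_member_at_layer(core, j, layer)
            if gi is None or gj is None:
                continue
            pi, pj = gi.coord("P"), gj.coord("P")
            if pi is None or pj is None:
                continue
            widths.append(float(np.linalg.norm(pi - pj)))
        if not widths:
            grooves.append(GrooveReport((i, j), [], float("nan"), "undefined"))
            continue
        mean = float(np.mean(widths))
        cls = "narrow" if mean < narrow_max else ("medium" if mean < wide_min else "wide")
        grooves.append(GrooveReport((i, j), widths, mean, cls))
    core.grooves = grooves
    return grooves


def _column_member_at_layer(core: QuadruplexCore, col_idx: int, layer: int) -> Residue | None:
    layer_keys = {m.key for m in core.tetrads[layer].members}
    for r in core.columns[col_idx]:
        if r.key in layer_keys:
            return r
    return None


def classify_loops(model: StructureModel, core: QuadruplexCore) -> list[LoopAnnotation]:
    """Classify the loops between consecutive G-tracts of each chain.

    propeller: loop endpoints attach at opposite faces of the (per-chain)
    core span; lateral (edgewise): same face, adjacent columns; diagonal:
    same face, diagonal columns.  ``spanned_groove`` is set for lateral
    loops to the adjacent column pair they bridge.
    """
    n_cols = len(core.columns)
    core_keys = {r.key for col in core.columns for r in col}
    loops: list[LoopAnnotation] = []
    for chain_id, chain in model.chains.items():
        core_g = [r for r in chain if r.key in core_keys]
        if len(core_g) < 2:
            continue
        core_g.sort(key=lambda r: r.seq_num)
        layers = {r.key: core.layer_of(r) for r in core_g}
        chain_top = max(layers.values())
        chain_bottom = min(layers.values())
        # tracts: maximal runs of consecutive core guanines in one column
        tracts: list[list[Residue]] = [[core_g[0]]]
        for prev, cur in zip(core_g, core_g[1:]):
            same_col = core.column_of(prev) == core.column_of(cur)
            if cur.seq_num == prev.seq_num + 1 and same_col:
                tracts[-1].append(cur)
            else:
                tracts.append([cur])
        for t_a, t_b in zip(tracts, tracts[1:]):
            a3, b5 = t_a[-1], t_b[0]
            residues = [
                r for r in chain if a3.seq_num < r.seq_num < b5.seq_num
            ]
            ann = LoopAnnotation(residues=residues, loop_class="unclassified",
                                 anchor_5p=a3, anchor_3p=b5)
            face_a = _face(layers[a3.key], chain_bottom, chain_top)
            face_b = _face(layers[b5.key], chain_bottom, chain_top)
            col_a, col_b = core.column_of(a3), core.column_of(b5)
            if face_a == "mid" or face_b == "mid" or col_a is None or col_b is None:
                ann.diagnostic = "loop endpoints not at core faces"
            elif face_a != face_b:
                ann.loop_class = "propeller"
            else:
                sep = abs(col_a - col_b) % n_cols
                if min(sep, n_cols - sep) == 1:
                    ann.loop_class = "lateral"
                    i = min(col_a, col_b) if abs(col_a - col_b) == 1 else max(col_a, col_b)
                    ann.spanned_groove = (i, (i + 1) % n_cols)
                elif sep == 0:
                    ann.diagnostic = "loop endpoints in the same column"
                else:
                    ann.loop_class = "diagonal"
            loops.append(ann)
    core.loops = loops
    return loops


def _face(layer: int, bottom: int, top: int) -> str:
    if layer == top:
        return "top"
    if layer == bottom:
        return "bottom"
    return "mid"


def channel_ions(
    model: StructureModel,
    core: QuadruplexCore,
    ion_O6_max: float = 3.6,
) -> list[IonAssignment]:
    """Assign channel ions to tetrad-layer intervals.

    An ion is a channel ion when it lies within ``ion_O6_max`` of at least
    four guanine O6 atoms drawn from exactly two adjacent tetrad layers; it
    is flagged as an interface ion when those two tetrads belong to
    different monomer units (different chains).
    """
    units = core.units()
    out: list[IonAssignment] = []
    for ion in model.ions():
        if not ion.atoms:
            continue
        pos = ion.atoms[0].pos
        per_layer: dict[int, int] = {}
        for li, tet in enumerate(core.tetrads):
            cnt = 0
            for m in tet.members:
                o6 = m.coord("O6")
                if o6 is not None and np.linalg.norm(o6 - pos) <= ion_O6_max:
                    cnt += 1
            if cnt:
                per_layer[li] = cnt
        layers = sorted(per_layer)
        if len(layers) == 2 and layers[1] == layers[0] + 1 and sum(per_layer.values()) >= 4:
            interface = units[layers[0]] != units[layers[1]]
            out.append(IonAssignment(ion, (layers[0], layers[1]), sum(per_layer.values()), interface))
    core.channel_ions = out
    return out


def core_report(core: QuadruplexCore) -> dict:
    """JSON-ready summary of one assembled core."""
    return {
        "n_layers": core.n_layers,
        "topology": core.topology,
        "tetrads": [
            {
                "members": t.label(),
                "directionality": t.directionality(core.axis),
                "glycosidic_pattern": list(t.glycosidic_pattern()),
                "planarity_rms": round(t.plane.rms_dev, 3),
                "mean_hbond_dist": round(t.mean_hbond_dist, 3),
            }
            for t in core.tetrads
        ],
        "columns": [[r.label for r in col] for col in core.columns],
        "grooves": [
            {
                "strand_pair": list(g.strand_pair),
                "width_mean": None if np.isnan(g.width_mean) else round(g.width_mean, 2),
                "width_per_layer": [round(w, 2) for w in g.width_per_layer],
                "class": g.groove_class,
            }
            for g in core.grooves
        ],
        "loops": [
            {
                "residues": [r.label for r in lp.residues],
                "class": lp.loop_class,
                "spanned_groove": list(lp.spanned_groove) if lp.spanned_groove else None,
            }
            for lp in core.loops
        ],
        "channel_ions": [
            {
                "ion": ia.ion.label,
                "interval": list(ia.interval),
                "n_O6": ia.n_O6,
                "interface": ia.interface,
            }
            for ia in core.channel_ions
        ],
        "diagnostics": list(core.diagnostics),
    }
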