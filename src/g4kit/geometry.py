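"""Vector geometry for nucleic-acid structure analysis.

Provides torsion angles (IUPAC sign convention), least-squares planes,
rigid-body superposition, the six backbone torsions plus the glycosidic
angle chi, and Altona-Sundaralingam sugar-pseudorotation analysis with
36-degree pucker bins.

Angles are reported in degrees in the half-open interval (-180, 180];
pseudorotation phase in [0, 360).  Missing atoms degrade gracefully to
per-field ``None`` with a completeness flag instead of raising, because
deposited models routinely omit disordered loop residues.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .structure_io import Residue, ResidueKind

__all__ = [
    "DegenerateGeometryError",
    "Plane",
    "TorsionProfile",
    "normalize_angle",
    "dihedral",
    "ls_plane",
    "superpose_rmsd",
    "backbone_torsions",
    "sugar_pucker",
    "pucker_from_nus",
    "classify_glycosidic",
    "torsion_table",
]


class DegenerateGeometryError(ValueError):
    """Raised for geometrically undefined requests (collinear axes etc.)."""


def normalize_angle(deg: float) -> float:
    """Map an angle in degrees to (-180, 180]."""
    a = math.fmod(deg, 360.0)
    if a <= -180.0:
        a += 360.0
    elif a > 180.0:
        a -= 360.0
    return a


def dihedral(p1, p2, p3, p4) -> float:
    """Torsion angle p1-p2-p3-p4 in degrees, IUPAC sign convention.

    Looking from p2 toward p3, a clockwise rotation of the far bond relative
    to the near bond is positive.  Result lies in (-180, 180].
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b1), np.linalg.norm(b2), np.linalg.norm(b3)) < 1e-12:
        raise DegenerateGeometryError("consecutive points coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if np.linalg.norm(n1) < 1e-12 or np.linalg.norm(n2) < 1e-12:
        raise DegenerateGeometryError("collinear arms: torsion undefined")
    b2h = b2 / np.linalg.norm(b2)
    x = float(np.dot(n1, n2))
    y = float(np.dot(np.cross(n1, n2), b2h))
    ang = math.degrees(math.atan2(y, x))
    return normalize_angle(ang)


@dataclass
class Plane:
    normal: np.ndarray  # unit 3-vector
    centroid: np.ndarray
    rms_dev: float

    def signed_distance(self, point) -> float:
        return float(np.dot(np.asarray(point, float) - self.centroid, self.normal))


def ls_plane(points) -> Plane:
    """Least-squares plane through >= 3 non-collinear points.

    Minimizes the sum of squared perpendicular deviations (total least
    squares via SVD); the normal sign is fixed so its largest-magnitude
    component is positive, making the result deterministic.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 3 or pts.shape[0] < 3:
        raise ValueError("need >= 3 points of dimension 3")
    centroid = pts.mean(axis=0)
    centered = pts - centroid
    _, s, vt = np.linalg.svd(centered, full_matrices=False)
    if s[1] < 1e-9 * max(s[0], 1.0):
        raise DegenerateGeometryError("collinear points: plane undefined")
    normal = vt[2]
    i = int(np.argmax(np.abs(normal)))
    if normal[i] < 0:
        normal = -normal
    rms = float(np.sqrt(np.mean((centered @ normal) ** 2)))
    return Plane(normal=normal, centroid=centroid, rms_dev=rms)


def plane_angle(n1, n2) -> float:
    """Acute angle in degrees between two plane normals (sign-free)."""
    c = abs(float(np.dot(n1, n2)) / (np.linalg.norm(n1) * np.linalg.norm(n2)))
    return math.degrees(math.acos(min(1.0, c)))


def superpose_rmsd(ref_atoms, mov_atoms):
    """Least-squares rigid superposition (Kabsch, proper rotation only).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ mov + translation`` best fits ``ref``.
    """
    ref = np.asarray(ref_atoms, dtype=float)
    mov = np.asarray(mov_atoms, dtype=float)
    if ref.shape != mov.shape:
        raise ValueError("paired coordinate lists must have equal length")
    if ref.shape[0] < 3:
        raise ValueError("need >= 3 atom pairs")
    rc = ref.mean(axis=0)
    mc = mov.mean(axis=0)
    H = (mov - mc).T @ (ref - rc)
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = rc - R @ mc
    moved = (R @ mov.T).T + t
    rmsd = float(np.sqrt(np.mean(np.sum((moved - ref) ** 2, axis=1))))
    return R, t, rmsd


# ---------------------------------------------------------------------------
# backbone torsions, chi, sugar pucker
# ---------------------------------------------------------------------------

#: 36-degree pseudorotation bins starting at P = 0
PUCKER_BINS = (
    "C3'-endo",
    "C4'-exo",
    "O4'-endo",
    "C1'-exo",
    "C2'-endo",
    "C3'-exo",
    "C4'-endo",
    "O4'-exo",
    "C1'-endo",
    "C2'-exo",
)

_NU_ATOMS = (
    ("C4'", "O4'", "C1'", "C2'"),  # nu0
    ("O4'", "C1'", "C2'", "C3'"),  # nu1
    ("C1'", "C2'", "C3'", "C4'"),  # nu2
    ("C2'", "C3'", "C4'", "O4'"),  # nu3
    ("C3'", "C4'", "O4'", "C1'"),  # nu4
)


@dataclass
class TorsionProfile:
    """Per-residue backbone/glycosidic torsions and sugar pucker.

    Undefined angles (terminal residues, missing atoms) are ``None`` and the
    corresponding name is listed in :attr:`missing`.
    """

    chain_id: str
    seq_num: int
    res_name: str
    alpha: float | None = None
    beta: float | None = None
    gamma: float | None = None
    delta: float | None = None
    epsilon: float | None = None
    zeta: float | None = None
    chi: float | None = None
    nus: tuple = (None, None, None, None, None)
    phase_P: float | None = None
    amplitude: float | None = None
    pucker_class: str | None = None
    glycosidic: str = "undefined"
    missing: list[str] = field(default_factory=list)


def _torsion_or_none(profile: TorsionProfile, name: str, atoms) -> float | None:
    if any(a is None for a in atoms):
        profile.missing.append(name)
        return None
    try:
        return dihedral(*atoms)
    except DegenerateGeometryError:
        profile.missing.append(name)
        return None


def classify_glycosidic(chi: float) -> str:
    """syn iff chi in (-90, 90]; anti otherwise (declared boundary convention)."""
    c = normalize_angle(chi)
    return "syn" if -90.0 < c <= 90.0 else "anti"


def pucker_from_nus(nus) -> tuple[float | None, float, str | None]:
    """Altona-Sundaralingam pseudorotation from the five ring torsions.

    ``tan P = ((nu4 + nu1) - (nu3 + nu0)) / (2 nu2 (sin 36 + sin 72))``,
    with P shifted by 180 degrees when nu2 < 0, then wrapped to [0, 360).
    Returns ``(phase_P, amplitude, pucker_class)``; a flat ring (all nu = 0)
    yields ``(None, 0.0, None)``.
    """
    nu0, nu1, nu2, nu3, nu4 = (float(v) for v in nus)
    if all(abs(v) < 1e-9 for v in (nu0, nu1, nu2, nu3, nu4)):
        return None, 0.0, None
    denom_const = 2.0 * (math.sin(math.radians(36.0)) + math.sin(math.radians(72.0)))
    if abs(nu2) < 1e-12:
        # phase is exactly +/-90 depending on the numerator sign
        num = (nu4 + nu1) - (nu3 + nu0)
        P = 90.0 if num >= 0 else 270.0
        amplitude = abs(num) / denom_const
    else:
        P = math.degrees(math.atan(((nu4 + nu1) - (nu3 + nu0)) / (denom_const * nu2)))
        if nu2 < 0:
            P += 180.0
        P %= 360.0
        amplitude = nu2 / math.cos(math.radians(P))
    amplitude = abs(amplitude)
    cls = PUCKER_BINS[int(P // 36.0) % 10]
    return P, amplitude, cls


def sugar_pucker(residue: Residue):
    """Pseudorotation phase, amplitude and pucker class for one residue.

    Returns ``(phase_P, amplitude, pucker_class)``; ``(None, None, None)``
    when the sugar ring is incomplete.
    """
    coords = {}
    for name in ("C1'", "C2'", "C3'", "C4'", "O4'"):
        c = residue.coord(name)
        if c is None:
            return None, None, None
        coords[name] = c
    nus = []
    for quad in _NU_ATOMS:
        try:
            nus.append(dihedral(*(coords[n] for n in quad)))
        except DegenerateGeometryError:
            return None, None, None
    return pucker_from_nus(nus)


def _chi_atoms(residue: Residue):
    if residue.kind is ResidueKind.GUANINE or residue.res_name.strip().upper() in (
        "DA", "A", "ADE",
    ):
        return ("O4'", "C1'", "N9", "C4")
    return ("O4'", "C1'", "N1", "C2")


def backbone_torsions(chain: list[Residue]) -> list[TorsionProfile]:
    """Backbone torsion profile for an ordered chain of residues.

    Torsion definitions (i = current residue):

    - alpha:  O3'(i-1)-P-O5'-C5'
    - beta:   P-O5'-C5'-C4'
    - gamma:  O5'-C5'-C4'-C3'
    - delta:  C5'-C4'-C3'-O3'
    - epsilon: C4'-C3'-O3'-P(i+1)
    - zeta:   C3'-O3'-P(i+1)-O5'(i+1)
    - chi:    O4'-C1'-N9-C4 (purine) / O4'-C1'-N1-C2 (pyrimidine)

    Terminal residues get ``None`` for torsions that need a missing
    neighbor; individual missing atoms mark only that torsion undefined.
    """
    profiles: list[TorsionProfile] = []
    for i, res in enumerate(chain):
        prev = chain[i - 1] if i > 0 else None
        nxt = chain[i + 1] if i + 1 < len(chain) else None
        p = TorsionProfile(chain_id=res.chain_id, seq_num=res.seq_num, res_name=res.res_name)
        get = res.coord
        prev_o3 = prev.coord("O3'") if prev is not None else None
        next_p = nxt.coord("P") if nxt is not None else None
        next_o5 = nxt.coord("O5'") if nxt is not None else None
        p.alpha = _torsion_or_none(p, "alpha", (prev_o3, get("P"), get("O5'"), get("C5'")))
        p.beta = _torsion_or_none(p, "beta", (get("P"), get("O5'"), get("C5'"), get("C4'")))
        p.gamma = _torsion_or_none(p, "gamma", (get("O5'"), get("C5'"), get("C4'"), get("C3'")))
        p.delta = _torsion_or_none(p, "delta", (get("C5'"), get("C4'"), get("C3'"), get("O3'")))
        p.epsilon = _torsion_or_none(p, "epsilon", (get("C4'"), get("C3'"), get("O3'"), next_p))
        p.zeta = _torsion_or_none(p, "zeta", (get("C3'"), get("O3'"), next_p, next_o5))
        chi_atoms = tuple(get(n) for n in _chi_atoms(res))
        p.chi = _torsion_or_none(p, "chi", chi_atoms)
        if p.chi is not None:
            p.glycosidic = classify_glycosidic(p.chi)
        nus = []
        complete = True
        for quad in _NU_ATOMS:
            coords = tuple(get(n) for n in quad)
            if any(c is None for c in coords):
                complete = False
                break
            try:
                nus.append(dihedral(*coords))
            except DegenerateGeometryError:
                complete = False
                break
        if complete:
            p.nus = tuple(nus)
            p.phase_P, p.amplitude, p.pucker_class = pucker_from_nus(nus)
        else:
            p.missing.append("sugar_ring")
        profiles.append(p)
    return profiles


_TABLE_COLUMNS = [
    "chain_id", "seq_num", "res_name", "alpha", "beta", "gamma", "delta",
    "epsilon", "zeta", "chi", "glycosidic", "phase_P", "amplitude", "pucker_class",
]


def torsion_table(profiles: list[TorsionProfile]) -> pd.DataFrame:
    """Torsion/pucker table, one row per residue, stable column order."""
    rows = []
    for p in profiles:
        rows.append({c: getattr(p, c) for c in _TABLE_COLUMNS})
    return pd.DataFrame(rows, columns=_TABLE_COLUMNS)
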