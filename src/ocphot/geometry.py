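"""Chromophore geometry: dihedrals, bond rotations, TDM axes, H-bonds.

A minimal structural toolkit for the canthaxanthin backbone.  The two
collective variables of the bicycle-pedal coordinate are the torsions
CV1 = C14'-C15'-C15-C14 and CV2 = C15-C14-C13-C12; conformers are
generated from an all-trans polyene chain by rigid rotations about
single backbone bonds, and the emission-TDM direction is approximated
by the principal geometric axis of the conjugated backbone (the TDM
of a carotenoid is well aligned with the pi-conjugated isoprenoid
backbone; no quantum-chemical TDM is computed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.spatial.transform import Rotation

__all__ = [
    "Conformer",
    "HBondGeometry",
    "read_pdb_conformer",
    "write_pdb_conformer",
    "dihedral",
    "rotate_about_bond",
    "tdm_axis",
    "tdm_rotation_angle",
    "hbond_geometry",
    "make_polyene_chain",
    "CV1_ATOMS",
    "CV2_ATOMS",
]

#: Atom quadruples defining the bicycle-pedal collective variables.
CV1_ATOMS = ("C14'", "C15'", "C15", "C14")
CV2_ATOMS = ("C15", "C14", "C13", "C12")


def _normalize_name(name: str) -> str:
    # prime conventions in deposited structures: ', * or the unicode prime
    return name.strip().replace("*", "'").replace("′", "'")


@dataclass(frozen=True)
class Conformer:
    """An ordered set of named atoms with Cartesian coordinates in Angstrom."""

    names: tuple[str, ...]
    coords: np.ndarray
    elements: tuple[str, ...] = ()
    bonds: tuple[tuple[str, str], ...] = ()
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        names = tuple(_normalize_name(n) for n in self.names)
        coords = np.asarray(self.coords, dtype=float)
        if coords.shape != (len(names), 3):
            raise ValueError("coords must be (n_atoms, 3)")
        if not np.all(np.isfinite(coords)):
            raise ValueError("coordinates must be finite")
        if len(set(names)) != len(names):
            raise ValueError("atom names must be unique")
        elements = self.elements or tuple(n[0] for n in names)
        object.__setattr__(self, "names", names)
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "elements", tuple(elements))

    def index(self, name: str) -> int:
        try:
            return self.names.index(_normalize_name(name))
        except ValueError:
            raise KeyError(f"no atom named {name!r} in conformer") from None

    def xyz(self, name: str) -> np.ndarray:
        return self.coords[self.index(name)]

    def dihedral(self, a: str, b: str, c: str, d: str) -> float:
        return dihedral(self.xyz(a), self.xyz(b), self.xyz(c), self.xyz(d))


def read_pdb_conformer(path, res_name: str | None = None, chain: str | None = None) -> Conformer:
    """Read the atoms of one residue selection from a PDB file.

    Uses biotite for the record parsing; atom names are normalized so
    the ' and * prime conventions parse identically.  Raises when the
    selection matches nothing.
    """
    import biotite.structure.io.pdb as pdb

    atoms = pdb.PDBFile.read(str(path)).get_structure(model=1)
    sel = np.ones(atoms.array_length(), dtype=bool)
    if res_name is not None:
        sel &= atoms.res_name == res_name
    if chain is not None:
        sel &= atoms.chain_id == chain
    if not np.any(sel):
        raise ValueError(
            f"selection (res_name={res_name!r}, chain={chain!r}) matches no atoms in {path}"
        )
    picked = atoms[sel]
    return Conformer(
        names=tuple(picked.atom_name),
        coords=np.asarray(picked.coord, dtype=float),
        elements=tuple(picked.element),
        meta={"source": str(path), "res_name": res_name, "chain": chain},
    )


def write_pdb_conformer(path, c: Conformer, res_name: str = "LIG") -> None:
    """Write a conformer back out as a single-residue PDB file."""
    import biotite.structure as struc
    import biotite.structure.io.pdb as pdb

    n = len(c.names)
    atoms = struc.AtomArray(n)
    atoms.coord = c.coords
    atoms.atom_name = np.array(c.names)
    atoms.element = np.array([e.upper() for e in c.elements])
    atoms.res_name = np.array([res_name] * n)
    atoms.res_id = np.ones(n, dtype=int)
    atoms.chain_id = np.array(["A"] * n)
    atoms.hetero = np.array([True] * n)
    f = pdb.PDBFile()
    f.set_structure(atoms)
    f.write(str(path))


def dihedral(p1, p2, p3, p4) -> float:
    """Signed IUPAC torsion angle in degrees, wrapped to [-180, 180).

    Standard atan2 construction: positive when, looking down the
    p2 -> p3 axis, the far bond rotates clockwise from the near bond.
    Exact +180 wraps to -180 (half-open convention, matching the CV
    state of the metadynamics engine).
    """
    p1, p2, p3, p4 = (np.asarray(p, dtype=float) for p in (p1, p2, p3, p4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    if min(np.linalg.norm(b) for b in (b1, b2, b3)) < 1e-12:
        raise ValueError("consecutive points must not coincide")
    n1 = np.cross(b1, b2)
    n2 = np.cross(b2, b3)
    if min(np.linalg.norm(n) for n in (n1, n2)) < 1e-12:
        raise ValueError("three collinear points: torsion undefined")
    m = np.cross(n1, b2 / np.linalg.norm(b2))
    angle = np.degrees(np.arctan2(m @ n2, n1 @ n2))
    # wrap exact +180 into the half-open interval
    return float(((angle + 180.0) % 360.0) - 180.0)


def rotate_about_bond(c: Conformer, bond: tuple[str, str], moving_set, angle: float) -> Conformer:
    """Rigidly rotate ``moving_set`` about the bond axis by ``angle`` degrees.

    The axis runs from the first to the second bond atom and passes
    through the second; the dihedral through the bond changes by
    exactly ``angle`` (mod 360).  The bond atoms themselves must not be
    in the moving set.
    """
    a2, a3 = bond
    moving = [_normalize_name(m) for m in moving_set]
    for fixed in (a2, a3):
        if _normalize_name(fixed) in moving:
            raise ValueError("moving set must not contain the bond atoms themselves")
    p2 = c.xyz(a2)
    p3 = c.xyz(a3)
    axis = p2 - p3  # sign chosen so the through-bond torsion changes by +angle
    norm = np.linalg.norm(axis)
    if norm < 1e-12:
        raise ValueError("bond atoms coincide")
    rot = Rotation.from_rotvec(np.deg2rad(angle) * axis / norm)
    coords = c.coords.copy()
    idx = [c.index(m) for m in moving]
    coords[idx] = rot.apply(coords[idx] - p3) + p3
    return replace(c, coords=coords)


def tdm_axis(c: Conformer, backbone) -> np.ndarray:
    """Approximate TDM direction: principal axis of the backbone atoms.

    The largest-variance direction of the backbone coordinates (leading
    right singular vector of the centered coordinates), sign-fixed so
    the largest-magnitude component is positive.
    """
    names = list(backbone)
    if len(names) < 3:
        raise ValueError("need at least 3 backbone atoms")
    pts = np.array([c.xyz(n) for n in names])
    centered = pts - pts.mean(axis=0)
    _, _, vt = np.linalg.svd(centered, full_matrices=False)
    axis = vt[0]
    k = int(np.argmax(np.abs(axis)))
    return axis if axis[k] >= 0 else -axis


def tdm_rotation_angle(c1: Conformer, c2: Conformer, backbone) -> float:
    """Angle (degrees, [0, 90]) between the principal backbone axes.

    Sign-free — arccos(|a1 . a2|) — matching the theta-vs-(180 - theta)
    ambiguity of the anisotropy measurement.
    """
    a1 = tdm_axis(c1, backbone)
    a2 = tdm_axis(c2, backbone)
    return float(np.degrees(np.arccos(np.clip(abs(a1 @ a2), 0.0, 1.0))))


@dataclass(frozen=True)
class HBondGeometry:
    distance: float             # donor-heavy to acceptor, Angstrom
    angle: float | None         # donor-H-acceptor, degrees (None without H)
    is_hbond: bool


def hbond_geometry(
    donor_heavy,
    acceptor,
    hydrogen=None,
    distance_cutoff: float = 3.5,
    angle_cutoff: float = 120.0,
) -> HBondGeometry:
    """Hydrogen-bond distance/angle with a configurable classification.

    The donor-H-acceptor angle is only reported when the hydrogen is
    supplied (deposited structures often omit protons); classification
    then requires both distance <= cutoff and angle >= cutoff.
    """
    d = np.asarray(donor_heavy, dtype=float)
    a = np.asarray(acceptor, dtype=float)
    dist = float(np.linalg.norm(a - d))
    angle = None
    ok = dist <= distance_cutoff
    if hydrogen is not None:
        h = np.asarray(hydrogen, dtype=float)
        v1 = d - h
        v2 = a - h
        cosang = (v1 @ v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
        ok = ok and angle >= angle_cutoff
    return HBondGeometry(distance=dist, angle=angle, is_hbond=bool(ok))


def make_polyene_chain(
    n: int = 12,
    bond_length: float = 1.4,
    bond_angle: float = 120.0,
) -> Conformer:
    """Planar all-trans polyene toy chain with carotenoid-style names.

    Atoms run C10-C11-C12-C13-C14-C15-C15'-C14'-C13'-C12'-C11'-C10'
    (for n = 12), a zigzag in the xy plane; all backbone torsions are
    (-)180 degrees.  Used as the fixture for bicycle-pedal rotations.
    """
    if n < 4 or n % 2:
        raise ValueError("n must be an even number >= 4")
    half = n // 2
    start = 15 - half + 1  # e.g. n=12 -> C10..C15 then primed side
    names = [f"C{start + i}" for i in range(half)] + [f"C{15 - i}'" for i in range(half)]
    coords = np.zeros((n, 3))
    step_x = bond_length * np.sin(np.deg2rad(bond_angle / 2.0))
    step_y = bond_length * np.cos(np.deg2rad(bond_angle / 2.0))
    for i in range(n):
        coords[i] = (i * step_x, (i % 2) * step_y, 0.0)
    return Conformer(names=tuple(names), coords=coords, elements=tuple("C" for _ in range(n)))
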