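"""Idealized 3D structures of polybrominated biphenyls and their derivatives.

Builds rigid biphenyl skeletons with configurable inter-ring dihedral,
attaches substituents (Br and the design groups NO, ONO, OCN, OCHO) with
standard bond geometry, assigns Gasteiger (PEOE) partial charges through
RDKit, and enumerates the 209 constitutionally distinct bromination
patterns with Ballschmiter-style congener numbers.

Ring positions follow IUPAC biphenyl numbering: the two bridgehead carbons
are 1 and 1' and are never substituted; the substitutable positions are
2-6 and 2'-6'.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from rdkit import Chem
from rdkit.Chem import AllChem
from rdkit.Geometry import Point3D

# Idealized bond lengths, angstrom.
RING_CC = 1.39
INTER_RING_CC = 1.48
C_BR = 1.89
C_H = 1.08

#: substitutable ring positions (ASCII prime marks the second ring)
POSITIONS = ("2", "3", "4", "5", "6", "2'", "3'", "4'", "5'", "6'")

#: supported substituent groups
GROUPS = ("Br", "H", "NO", "ONO", "OCN", "OCHO")

# Group geometry templates: chains attached through the first atom.
# Each entry: (element, bond length to previous atom, bend angle at the
# previous atom in degrees; 180 = collinear) built as an in-plane zig-zag
# with alternating sides, anti-periplanar backbone.  Bond orders connect
# consecutive chain atoms; extra atoms (formate H) are listed separately.
_GROUP_CHAINS = {
    "Br": [("Br", C_BR, None, 1.0)],
    "H": [("H", C_H, None, 1.0)],
    # nitroso: C-N=O
    "NO": [("N", 1.40, None, 1.0), ("O", 1.21, 116.0, 2.0)],
    # nitrite ester: C-O-N=O
    "ONO": [("O", 1.36, None, 1.0), ("N", 1.40, 112.0, 1.0), ("O", 1.20, 114.0, 2.0)],
    # cyanate ester: C-O-C#N (sp carbon, linear O-C#N)
    "OCN": [("O", 1.36, None, 1.0), ("C", 1.29, 113.0, 1.0), ("N", 1.16, 180.0, 3.0)],
    # formate ester: C-O-CH=O
    "OCHO": [("O", 1.34, None, 1.0), ("C", 1.34, 115.0, 1.0), ("O", 1.20, 125.0, 2.0)],
}
# formate carbonyl hydrogen: attached to chain atom index 1, opposite the =O
_FORMATE_H = ("H", 1.09)


class CongenerError(ValueError):
    """Invalid substitution pattern or unsupported group."""


@dataclass(frozen=True)
class SubstitutionPattern:
    """Map from ring position to substituent group; unlisted positions are H."""

    substituents: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        for pos, grp in self.substituents.items():
            if pos in ("1", "1'"):
                raise CongenerError("positions 1 and 1' carry the inter-ring bond")
            if pos not in POSITIONS:
                raise CongenerError(f"unknown ring position {pos!r}")
            if grp not in GROUPS:
                raise CongenerError(f"unsupported group {grp!r}")

    @classmethod
    def from_bromines(cls, positions) -> "SubstitutionPattern":
        return cls({p: "Br" for p in positions})

    @property
    def bromine_positions(self) -> frozenset:
        return frozenset(p for p, g in self.substituents.items() if g == "Br")

    def n_bromines(self) -> int:
        return len(self.bromine_positions)


@dataclass
class Molecule3D:
    """A molecule as explicit atoms, coordinates, charges and bonds.

    The first 12 atoms are always the biphenyl skeleton carbons, labelled
    ``1``-``6`` and ``1'``-``6'`` via :attr:`ring_labels`.
    """

    congener_id: str
    elements: list[str]
    coords: np.ndarray  # (n_atoms, 3), angstrom
    charges: np.ndarray  # (n_atoms,), e; zeros until assign_charges
    bonds: list[tuple[int, int, float]]  # (i, j, order)
    ring_labels: dict[int, str]  # atom index -> ring position label
    pattern: SubstitutionPattern | None = None

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def skeleton_indices(self) -> list[int]:
        """Atom indices of the 12 ring carbons ordered 1..6, 1'..6'."""
        order = ["1", "2", "3", "4", "5", "6", "1'", "2'", "3'", "4'", "5'", "6'"]
        by_label = {lab: i for i, lab in self.ring_labels.items()}
        return [by_label[lab] for lab in order]

    def copy(self) -> "Molecule3D":
        return replace(
            self,
            elements=list(self.elements),
            coords=self.coords.copy(),
            charges=self.charges.copy(),
            bonds=list(self.bonds),
            ring_labels=dict(self.ring_labels),
        )


# ---------------------------------------------------------------------------
# geometry


def _rotation_about_x(theta_deg: float) -> np.ndarray:
    t = np.deg2rad(theta_deg)
    c, s = np.cos(t), np.sin(t)
    return np.array([[1.0, 0.0, 0.0], [0.0, c, -s], [0.0, s, c]])


def _ring_unit(primed: bool) -> tuple[np.ndarray, np.ndarray, dict[str, int]]:
    """Planar hexagon in the xy-plane for one ring of the skeleton.

    Returns carbon coordinates (6, 3) ordered position 1..6, outward radial
    unit vectors per carbon, and the label->row map.
    """
    r = RING_CC  # circumradius of a regular hexagon equals its side
    cx = INTER_RING_CC / 2.0 + r
    center = np.array([cx if primed else -cx, 0.0, 0.0])
    coords, radial = [], []
    for k in range(6):
        # position 1 points at the other ring
        ang = np.deg2rad(180.0 - 60.0 * k) if primed else np.deg2rad(60.0 * k)
        u = np.array([np.cos(ang), np.sin(ang), 0.0])
        coords.append(center + r * u)
        radial.append(u)
    suffix = "'" if primed else ""
    labels = {f"{k + 1}{suffix}": k for k in range(6)}
    return np.asarray(coords), np.asarray(radial), labels


def _in_plane_perp(u: np.ndarray, toward: np.ndarray) -> np.ndarray:
    """Unit vector in the xy-plane, perpendicular to u, pointing toward `toward`."""
    t = np.array([-u[1], u[0], 0.0])
    if np.dot(t, toward) < 0:
        t = -t
    return t


def _build_group(anchor: np.ndarray, u_out: np.ndarray, side: np.ndarray,
                 group: str) -> tuple[list[str], np.ndarray, list[tuple[int, int, float]]]:
    """Place a substituent chain starting from the ring-carbon anchor.

    ``u_out`` is the outward radial direction at the anchor; ``side`` is the
    in-plane lateral direction used for the first bend (toward the lower
    neighbouring position), with subsequent bends alternating sides
    (anti-periplanar zig-zag). Returns elements, coordinates and intra-group
    bonds with indices local to the chain (-1 = ring anchor).
    """
    chain = _GROUP_CHAINS[group]
    elements, coords, bonds = [], [], []
    prev_pos = anchor
    prev_dir = u_out
    lateral = side / np.linalg.norm(side)
    for ci, (elem, length, bend, order) in enumerate(chain):
        if bend is None or bend == 180.0:
            direction = prev_dir
        else:
            # bend away from the previous bond by (180 - bend) degrees
            phi = np.deg2rad(180.0 - bend)
            direction = np.cos(phi) * prev_dir + np.sin(phi) * lateral
            lateral = -lateral  # alternate -> extended zig-zag backbone
        direction = direction / np.linalg.norm(direction)
        pos = prev_pos + length * direction
        elements.append(elem)
        coords.append(pos)
        bonds.append((ci - 1, ci, order))
        prev_pos, prev_dir = pos, direction
    if group == "OCHO":
        # carbonyl H on the chain carbon, opposite the =O substituent
        c_pos = coords[1]
        o2 = coords[2]
        o1 = coords[0]
        h_dir = 2.0 * c_pos - o2 - o1
        h_dir = h_dir / np.linalg.norm(h_dir)
        elements.append("H")
        coords.append(c_pos + _FORMATE_H[1] * h_dir)
        bonds.append((1, len(coords) - 1, 1.0))
    return elements, np.asarray(coords), bonds


def build_congener(pattern: SubstitutionPattern, dihedral: float = 44.0,
                   congener_id: str | None = None) -> Molecule3D:
    """Construct an idealized 3D congener from a substitution pattern.

    The two rings are regular hexagons (C-C 1.39 angstrom) joined by a
    1.48 angstrom bond, twisted about the inter-ring axis by ``dihedral``
    degrees (default 44 deg, the free-biphenyl twist). Unsubstituted ring
    positions carry hydrogens.
    """
    if not 0.0 <= dihedral <= 90.0:
        raise ValueError("dihedral must lie in [0, 90] degrees")

    elements: list[str] = []
    coords: list[np.ndarray] = []
    bonds: list[tuple[int, int, float]] = []
    ring_labels: dict[int, str] = {}

    ring_data = {}
    for primed in (False, True):
        c, radial, labels = _ring_unit(primed)
        ring_data[primed] = (c, radial, labels)

    # skeleton carbons first: 1..6 then 1'..6'
    for primed in (False, True):
        c, _, labels = ring_data[primed]
        base = len(elements)
        for lab, row in sorted(labels.items(), key=lambda kv: kv[1]):
            ring_labels[base + row] = lab
        for row in range(6):
            elements.append("C")
            coords.append(c[row])
    # aromatic ring bonds, Kekule alternation
    for base in (0, 6):
        for k in range(6):
            bonds.append((base + k, base + (k + 1) % 6, 2.0 if k % 2 == 0 else 1.0))
    bonds.append((0, 6, 1.0))  # C1-C1'

    # substituents / hydrogens at positions 2..6 and 2'..6'
    sub_ring_of_atom: dict[int, bool] = {}
    for primed in (False, True):
        c, radial, labels = ring_data[primed]
        suffix = "'" if primed else ""
        base = 0 if not primed else 6
        for k in range(1, 6):  # positions 2..6
            pos_label = f"{k + 1}{suffix}"
            group = pattern.substituents.get(pos_label, "H")
            anchor = c[k]
            # lateral tie-break: toward the neighbouring position of lower index
            lower_nb = c[k - 1]
            side = _in_plane_perp(radial[k], lower_nb - anchor)
            g_elems, g_coords, g_bonds = _build_group(anchor, radial[k], side, group)
            offset = len(elements)
            elements.extend(g_elems)
            for p in g_coords:
                coords.append(p)
            for i, j, order in g_bonds:
                a = base + k if i == -1 else offset + i
                bonds.append((a, offset + j, order))
            for gi in range(len(g_elems)):
                sub_ring_of_atom[offset + gi] = primed

    xyz = np.asarray(coords)
    # twist the primed ring (skeleton atoms 6..11 plus its substituents)
    rot = _rotation_about_x(dihedral)
    primed_atoms = list(range(6, 12)) + [i for i, p in sub_ring_of_atom.items() if p]
    xyz[primed_atoms] = xyz[primed_atoms] @ rot.T

    if congener_id is None:
        congener_id = name_congener(pattern)
    return Molecule3D(
        congener_id=congener_id,
        elements=elements,
        coords=xyz,
        charges=np.zeros(len(elements)),
        bonds=bonds,
        ring_labels=ring_labels,
        pattern=pattern,
    )


def measure_dihedral(mol: Molecule3D) -> float:
    """Inter-ring torsion 2-1-1'-2' in degrees, in [0, 180]."""
    idx = {lab: i for i, lab in mol.ring_labels.items()}
    p = mol.coords[[idx["2"], idx["1"], idx["1'"], idx["2'"]]]
    b1, b2, b3 = p[1] - p[0], p[2] - p[1], p[3] - p[2]
    n1, n2 = np.cross(b1, b2), np.cross(b2, b3)
    x = np.dot(n1, n2)
    y = np.dot(np.cross(n1, n2), b2 / np.linalg.norm(b2))
    return abs(np.degrees(np.arctan2(y, x)))


# ---------------------------------------------------------------------------
# RDKit bridge and charges

_BOND_TYPES = {1.0: Chem.BondType.SINGLE, 1.5: Chem.BondType.AROMATIC,
               2.0: Chem.BondType.DOUBLE, 3.0: Chem.BondType.TRIPLE}


def to_rdkit(mol: Molecule3D) -> Chem.Mol:
    """Convert to an RDKit molecule with a 3D conformer; sanitizes."""
    rw = Chem.RWMol()
    for elem in mol.elements:
        rw.AddAtom(Chem.Atom(elem))
    for i, j, order in mol.bonds:
        rw.AddBond(int(i), int(j), _BOND_TYPES[float(order)])
    m = rw.GetMol()
    Chem.SanitizeMol(m)
    conf = Chem.Conformer(mol.n_atoms)
    for i, (x, y, z) in enumerate(mol.coords):
        conf.SetAtomPosition(i, Point3D(float(x), float(y), float(z)))
    m.AddConformer(conf)
    m.SetProp("_Name", mol.congener_id)
    m.SetProp("ring_labels",
              " ".join(f"{i}:{lab}" for i, lab in sorted(mol.ring_labels.items())))
    return m


def assign_charges(mol: Molecule3D, n_iter: int = 50) -> Molecule3D:
    """Assign iterative Gasteiger (PEOE) partial charges.

    Returns a copy with :attr:`Molecule3D.charges` filled; a neutral
    congener sums to zero within 1e-6 e.
    """
    rdmol = to_rdkit(mol)
    AllChem.ComputeGasteigerCharges(rdmol, nIter=n_iter)
    out = mol.copy()
    out.charges = np.array(
        [float(a.GetDoubleProp("_GasteigerCharge")) for a in rdmol.GetAtoms()]
    )
    if not np.all(np.isfinite(out.charges)):
        raise CongenerError(f"charge assignment failed for {mol.congener_id}")
    return out


# ---------------------------------------------------------------------------
# SDF round trip


def write_sdf(molecules, path) -> None:
    """Write molecules as a multi-record V2000 SDF, preserving order."""
    writer = Chem.SDWriter(str(path))
    writer.SetForceV3000(False)
    for mol in molecules:
        rd = to_rdkit(mol)
        if np.any(mol.charges):
            rd.SetProp("partial_charges",
                       " ".join(f"{q:.6f}" for q in mol.charges))
        writer.write(rd)
    writer.close()


def read_sdf(path, strict: bool = True):
    """Read molecules written by :func:`write_sdf` back to Molecule3D."""
    out = []
    try:
        supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=True)
    except OSError as exc:
        raise CongenerError(f"cannot read SDF {path}: {exc}") from exc
    for rd in supplier:
        if rd is None:
            if strict:
                raise CongenerError(f"malformed SDF record in {path}")
            continue
        Chem.Kekulize(rd, clearAromaticFlags=True)
        conf = rd.GetConformer()
        coords = np.array([[conf.GetAtomPosition(i).x,
                            conf.GetAtomPosition(i).y,
                            conf.GetAtomPosition(i).z]
                           for i in range(rd.GetNumAtoms())])
        labels = {}
        if rd.HasProp("ring_labels"):
            for tok in rd.GetProp("ring_labels").split():
                i, lab = tok.split(":")
                labels[int(i)] = lab
        charges = np.zeros(rd.GetNumAtoms())
        if rd.HasProp("partial_charges"):
            charges = np.array([float(v) for v in
                                rd.GetProp("partial_charges").split()])
        bonds = [(b.GetBeginAtomIdx(), b.GetEndAtomIdx(), b.GetBondTypeAsDouble())
                 for b in rd.GetBonds()]
        out.append(Molecule3D(
            congener_id=rd.GetProp("_Name") if rd.HasProp("_Name") else "",
            elements=[a.GetSymbol() for a in rd.GetAtoms()],
            coords=coords,
            charges=charges,
            bonds=bonds,
            ring_labels=labels,
        ))
    if not out:
        raise CongenerError(f"no molecules read from {path}")
    return out


# ---------------------------------------------------------------------------
# congener enumeration and numbering

_POSITION_SET = POSITIONS


def _symmetry_group():
    """The 8 graph automorphisms of the biphenyl substitution positions.

    Generated by flipping either ring about the 1-1' axis (2<->6, 3<->5,
    independently per ring, since rotation about the pivot bond is free)
    and swapping the two rings.
    """
    def flip(pos):
        digit, primed = int(pos[0]), pos.endswith("'")
        new = {2: 6, 6: 2, 3: 5, 5: 3}.get(digit, digit)
        suffix = "'" if primed else ""
        return f"{new}{suffix}"

    def swap(pos):
        return pos[:-1] if pos.endswith("'") else pos + "'"

    ops = []
    for fa in (False, True):
        for fb in (False, True):
            for sw in (False, True):
                def op(pos, fa=fa, fb=fb, sw=sw):
                    primed = pos.endswith("'")
                    if (not primed and fa) or (primed and fb):
                        pos = flip(pos)
                    if sw:
                        pos = swap(pos)
                    return pos
                ops.append(op)
    return ops


_SYMMETRY_OPS = _symmetry_group()


def _locant_key(positions) -> tuple:
    """Sort key for a set of bromine positions: pairs (digit, primed)."""
    return tuple(sorted((int(p[0]), p.endswith("'")) for p in positions))


def canonical_positions(positions) -> frozenset:
    """Symmetry-canonical representative of a bromine position set."""
    images = [frozenset(op(p) for p in positions) for p in [positions]
              for op in _SYMMETRY_OPS]
    return min(images, key=_locant_key)


def enumerate_congeners(n_bromines=range(1, 11)) -> list[SubstitutionPattern]:
    """All distinct bromination patterns for the given homolog levels.

    Patterns are deduplicated under the biphenyl symmetry group and returned
    in congener-number order; the full range 1..10 yields the 209 congeners.
    """
    if isinstance(n_bromines, int):
        n_bromines = [n_bromines]
    levels = sorted(set(int(n) for n in n_bromines))
    if levels and (levels[0] < 1 or levels[-1] > 10):
        raise ValueError("bromine counts must lie in 1..10")
    out = []
    for n in levels:
        seen = set()
        for combo in itertools.combinations(_POSITION_SET, n):
            canon = canonical_positions(frozenset(combo))
            if canon not in seen:
                seen.add(canon)
        for canon in sorted(seen, key=_locant_key):
            out.append(SubstitutionPattern.from_bromines(canon))
    return out


_NUMBERING: dict[frozenset, int] | None = None


def _numbering() -> dict[frozenset, int]:
    global _NUMBERING
    if _NUMBERING is None:
        _NUMBERING = {
            p.bromine_positions: i + 1
            for i, p in enumerate(enumerate_congeners(range(1, 11)))
        }
    return _NUMBERING


def congener_number(pattern: SubstitutionPattern) -> int:
    """Ballschmiter-style congener number (1..209) of a pure-Br pattern."""
    canon = canonical_positions(pattern.bromine_positions)
    return _numbering()[canon]


def name_congener(pattern: SubstitutionPattern) -> str:
    """Name a pattern: ``PBB-<number>`` for pure bromination, otherwise the
    derivative convention ``<pos>-<group>-...-PBB-<parent number>`` where the
    parent is the pattern with non-Br groups reverted to Br."""
    non_br = {p: g for p, g in pattern.substituents.items() if g not in ("Br", "H")}
    if not non_br:
        if not pattern.bromine_positions:
            return "biphenyl"
        return f"PBB-{congener_number(pattern)}"
    parent = SubstitutionPattern.from_bromines(
        pattern.bromine_positions | set(non_br))
    pos_key = lambda p: (int(p[0]), p.endswith("'"))
    by_group: dict[str, list[str]] = {}
    for p, g in sorted(non_br.items(), key=lambda kv: pos_key(kv[0])):
        by_group.setdefault(g, []).append(p)
    parts = sorted(((ps, g) for g, ps in by_group.items()),
                   key=lambda item: pos_key(item[0][0]))
    name = "-".join(f"{','.join(ps)}-{g}" for ps, g in parts)
    return name + f"-PBB-{congener_number(parent)}"


#: the study's design parent: 2,2',4,4',5,5'-hexabromobiphenyl
PBB_153 = SubstitutionPattern.from_bromines({"2", "4", "5", "2'", "4'", "5'"})
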